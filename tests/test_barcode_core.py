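from itertools import combinations, product

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import snpbarcode as sb
from oracles import brute_best_extension, brute_carriers, brute_top_k


def all_barcodes(n_snp, sizes):
    for size in sizes:
        for snps in combinations(range(1, n_snp + 1), size):
            for genos in product((1, 2, 3), repeat=size):
                yield sb.Barcode(snps, genos)


class TestBarcode:
    def test_canonical_order(self):
        b = sb.Barcode((19, 4), (2, 1))
        assert b.snp_indices == (4, 19) and b.genotypes == (1, 2)
        assert b == sb.Barcode((4, 19), (1, 2))

    def test_duplicate_snp_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            sb.Barcode((3, 3), (1, 2))

    def test_bad_genotype_rejected(self):
        with pytest.raises(ValueError):
            sb.Barcode((1, 2), (0, 4))

    def test_string_round_trip(self):
        b = sb.Barcode((4, 19), (1, 1))
        assert str(b) == "SNPs(4-19)-genotypes(1-1)"
        assert sb.parse_barcode(str(b)) == b
        assert sb.parse_barcode(b.to_json()) == b


class TestCountCarriers:
    def test_small_example(self):
        m = np.array([[1, 2], [2, 1], [2, 1]])
        assert sb.count_carriers(m, sb.Barcode((1, 2), (2, 1))) == 2

    def test_absent_genotype_gives_zero(self):
        m = np.full((5, 3), 2)
        assert sb.count_carriers(m, sb.Barcode((1, 2, 3), (2, 2, 1))) == 0

    def test_out_of_range_snp(self):
        m = np.ones((3, 2), dtype=int)
        with pytest.raises(IndexError):
            sb.count_carriers(m, sb.Barcode((1, 3), (1, 1)))

    def test_matches_row_scan_oracle(self, toy_dataset):
        m = toy_dataset.case_matrix[:6, :3]
        for b in all_barcodes(3, (1, 2, 3)):
            assert sb.count_carriers(m, b) == brute_carriers(
                m, b.snp_indices, b.genotypes
            )


class TestFitness:
    def test_difference_is_absolute(self, toy_dataset):
        for b in all_barcodes(toy_dataset.n_snp, (2,)):
            sc = sb.fitness(toy_dataset, b)
            assert sc.fitness == abs(sc.case_carriers - sc.control_carriers)

    def test_identical_groups_score_zero(self):
        m = np.random.default_rng(0).integers(1, 4, (20, 4)).astype(np.int8)
        ds = sb.GenotypeDataset(m, m.copy(), ("a", "b", "c", "d"))
        for b in all_barcodes(4, (2, 3)):
            assert sb.fitness(ds, b).fitness == 0

    def test_bounded_by_group_size(self, toy_dataset):
        cap = max(toy_dataset.n_case, toy_dataset.n_control)
        for b in all_barcodes(toy_dataset.n_snp, (2,)):
            assert sb.fitness(toy_dataset, b).fitness <= cap

    def test_evaluator_agrees_with_fitness(self, toy_dataset):
        ev = sb.BarcodeEvaluator(toy_dataset)
        for b in all_barcodes(toy_dataset.n_snp, (2, 3)):
            assert ev.score(b) == sb.fitness(toy_dataset, b)


class TestSubsetProperty:
    @given(st.data())
    def test_extension_never_gains_carriers(self, data):
        rng = np.random.default_rng(data.draw(st.integers(0, 10_000)))
        m = rng.integers(1, 4, (30, 5)).astype(np.int8)
        snps = tuple(sorted(data.draw(
            st.sets(st.integers(1, 5), min_size=2, max_size=4)
        )))
        genos = tuple(data.draw(st.integers(1, 3)) for _ in snps)
        parent = sb.Barcode(snps[:-1], genos[:-1])
        child = sb.Barcode(snps, genos)
        assert sb.count_carriers(m, child) <= sb.count_carriers(m, parent)


class TestExhaustiveTopK:
    def test_matches_brute_force(self, toy_dataset):
        for size in (2, 3):
            archive = sb.exhaustive_top_k(toy_dataset, size)
            expected = brute_top_k(toy_dataset, size, capacity=5)
            got = [
                (e.fitness, e.barcode.snp_indices, e.barcode.genotypes,
                 e.case_carriers, e.control_carriers)
                for e in archive
            ]
            assert got == expected

    def test_two_snp_dataset_archive(self):
        rng = np.random.default_rng(3)
        ds = sb.GenotypeDataset(
            rng.integers(1, 4, (25, 2)).astype(np.int8),
            rng.integers(1, 4, (25, 2)).astype(np.int8),
            ("a", "b"),
        )
        archive = sb.exhaustive_top_k(ds, 2)
        assert 1 <= len(archive) <= 5
        fits = [e.fitness for e in archive]
        assert fits == sorted(fits, reverse=True)

    def test_row_order_invariance(self, toy_dataset):
        rng = np.random.default_rng(0)
        shuffled = sb.GenotypeDataset(
            toy_dataset.case_matrix[rng.permutation(toy_dataset.n_case)],
            toy_dataset.control_matrix[rng.permutation(toy_dataset.n_control)],
            toy_dataset.snp_ids,
        )
        a = sb.exhaustive_top_k(toy_dataset, 2)
        b = sb.exhaustive_top_k(shuffled, 2)
        assert a.entries == b.entries

    def test_candidate_budget_guard(self, toy_dataset):
        with pytest.raises(ValueError, match="budget"):
            sb.exhaustive_top_k(toy_dataset, 4, candidate_budget=100)


class TestBestExtension:
    def test_matches_brute_force(self, toy_dataset):
        for parent in [sb.Barcode((1, 3), (1, 2)), sb.Barcode((2, 5), (3, 1))]:
            got = sb.best_extension(toy_dataset, parent)
            neg_fit, snps, genos, a, b = brute_best_extension(
                toy_dataset, parent.snp_indices, parent.genotypes
            )
            assert got.fitness == -neg_fit
            assert got.barcode.snp_indices == snps
            assert got.barcode.genotypes == genos
            assert (got.case_carriers, got.control_carriers) == (a, b)

    def test_parent_pairs_preserved(self, toy_dataset):
        parent = sb.Barcode((1, 4), (2, 2))
        child = sb.best_extension(toy_dataset, parent).barcode
        assert set(zip(parent.snp_indices, parent.genotypes)) <= set(
            zip(child.snp_indices, child.genotypes)
        )
        assert child.size == 3

    def test_no_unused_snp_raises(self, toy_dataset):
        full = sb.Barcode(tuple(range(1, 7)), (1,) * 6)
        with pytest.raises(ValueError, match="unused"):
            sb.best_extension(toy_dataset, full)


class TestConserveTopK:
    def test_dedup_sort_truncate(self):
        def scored(snps, genos, a, b):
            return sb.ScoredBarcode(sb.Barcode(snps, genos), a, b)

        cands = [
            scored((1, 2), (1, 1), 9, 0),
            scored((1, 2), (1, 1), 9, 0),   # duplicate barcode
            scored((1, 3), (1, 1), 9, 0),
            scored((1, 4), (1, 1), 5, 0),
            scored((1, 5), (1, 1), 5, 0),
            scored((1, 6), (1, 1), 5, 0),
            scored((1, 7), (1, 1), 2, 0),
            scored((1, 8), (1, 1), 1, 0),
        ]
        archive = sb.conserve_top_k(cands, capacity=5)
        assert len(archive) == 5
        assert [e.fitness for e in archive] == [9, 9, 5, 5, 5]
        assert archive.entries[0].barcode == sb.Barcode((1, 2), (1, 1))

    def test_fewer_than_capacity(self):
        one = sb.ScoredBarcode(sb.Barcode((1, 2), (1, 1)), 3, 0)
        assert len(sb.conserve_top_k([one, one])) == 1

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            sb.conserve_top_k([])

    @given(st.lists(
        st.tuples(st.integers(1, 4), st.integers(1, 3), st.integers(0, 30)),
        min_size=1, max_size=30,
    ))
    def test_matches_sort_dedup_oracle(self, raw):
        cands = [
            sb.ScoredBarcode(sb.Barcode((s, s + 1), (g, g)), a, 0)
            for s, g, a in raw
        ]
        archive = sb.conserve_top_k(cands, capacity=5)
        seen = {}
        for c in cands:
            seen.setdefault((c.barcode.snp_indices, c.barcode.genotypes), c)
        expected = sorted(
            seen.values(),
            key=lambda c: (-c.fitness, c.barcode.snp_indices, c.barcode.genotypes),
        )[:5]
        assert list(archive) == expected
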