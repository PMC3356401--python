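"""Independent brute-force oracles used only by the test suite.

Kept deliberately naive (pure-Python row scans and full enumerations) so
they share no code path with the package implementation.
"""

from itertools import combinations, product


def brute_carriers(matrix, snps, genos):
    """Row-by-row carrier count."""
    count = 0
    for row in matrix:
        if all(row[s - 1] == g for s, g in zip(snps, genos)):
            count += 1
    return count


def brute_fitness(dataset, snps, genos):
    a = brute_carriers(dataset.case_matrix, snps, genos)
    b = brute_carriers(dataset.control_matrix, snps, genos)
    return a, b, abs(a - b)


def enumerate_scored(dataset, size):
    """(fitness, snps, genos, case, control) for every size-SNP barcode."""
    out = []
    for snps in combinations(range(1, dataset.n_snp + 1), size):
        for genos in product((1, 2, 3), repeat=size):
            a, b, fit = brute_fitness(dataset, snps, genos)
            out.append((fit, snps, genos, a, b))
    return out


def brute_top_k(dataset, size, capacity=5):
    """Top-capacity barcodes under (fitness desc, canonical order)."""
    cands = enumerate_scored(dataset, size)
    cands.sort(key=lambda t: (-t[0], t[1], t[2]))
    return cands[:capacity]


def brute_best_extension(dataset, snps, genos):
    """Best one-SNP extension by full enumeration."""
    best = None
    for i in range(1, dataset.n_snp + 1):
        if i in snps:
            continue
        for g in (1, 2, 3):
            new_snps, new_genos = zip(
                *sorted(zip(snps + (i,), genos + (g,)))
            )
            a, b, fit = brute_fitness(dataset, new_snps, new_genos)
            cand = (-fit, new_snps, new_genos, a, b)
            if best is None or cand < best:
                best = cand
    return best
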