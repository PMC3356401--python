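"""SNP barcodes, the case/control difference fitness, and exhaustive search.

A *barcode* fixes a set of distinct SNPs each to one genotype; an
individual carries the barcode iff their genotype matches at every
selected SNP (exact match, logical AND).  The search objective is the
absolute difference between the number of carriers among cases and among
controls — a direction-agnostic measure whose large values flag
genotype combinations that are strongly enriched in one group.  A
barcode with more control than case carriers is "protective".
"""

from __future__ import annotations

import itertools
import json
import re
from dataclasses import dataclass
from typing import TYPE_CHECKING, Iterable, Sequence

import numpy as np

if TYPE_CHECKING:  # pragma: no cover
    from .genotype_data import GenotypeDataset

__all__ = [
    "Barcode",
    "ScoredBarcode",
    "TopKArchive",
    "BarcodeEvaluator",
    "count_carriers",
    "fitness",
    "exhaustive_top_k",
    "best_extension",
    "conserve_top_k",
    "parse_barcode",
]

DEFAULT_CAPACITY = 5
DEFAULT_CANDIDATE_BUDGET = 10**7

_BARCODE_RE = re.compile(r"^SNPs\(([\d-]+)\)-genotypes?\(([\d-]+)\)$")


@dataclass(frozen=True)
class Barcode:
    """Distinct 1-based SNP indices, each paired with a genotype code.

    Stored in canonical form: (SNP, genotype) pairs sorted by SNP index.
    """

    snp_indices: tuple[int, ...]
    genotypes: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.snp_indices) != len(self.genotypes):
            raise ValueError("snp_indices and genotypes must have equal length")
        if not self.snp_indices:
            raise ValueError("empty barcode")
        if len(set(self.snp_indices)) != len(self.snp_indices):
            raise ValueError(f"duplicate SNP indices in {self.snp_indices}")
        if any(i < 1 for i in self.snp_indices):
            raise ValueError("SNP indices are 1-based and must be >= 1")
        if any(g not in (1, 2, 3) for g in self.genotypes):
            raise ValueError("genotype codes must be 1, 2 or 3")
        if any(a > b for a, b in zip(self.snp_indices, self.snp_indices[1:])):
            order = np.argsort(self.snp_indices, kind="stable")
            object.__setattr__(
                self, "snp_indices", tuple(self.snp_indices[k] for k in order)
            )
            object.__setattr__(
                self, "genotypes", tuple(self.genotypes[k] for k in order)
            )

    @property
    def size(self) -> int:
        return len(self.snp_indices)

    @property
    def key(self) -> tuple[tuple[int, ...], tuple[int, ...]]:
        """Lexicographic tie-breaking key (canonical form)."""
        return (self.snp_indices, self.genotypes)

    def __str__(self) -> str:
        snps = "-".join(map(str, self.snp_indices))
        genos = "-".join(map(str, self.genotypes))
        return f"SNPs({snps})-genotypes({genos})"

    def to_json(self) -> str:
        return json.dumps(
            {"snps": list(self.snp_indices), "genotypes": list(self.genotypes)}
        )


def parse_barcode(text: str) -> Barcode:
    """Parse ``SNPs(4-19)-genotypes(1-1)`` notation or the JSON form."""
    text = text.strip()
    if text.startswith("{"):
        obj = json.loads(text)
        return Barcode(tuple(obj["snps"]), tuple(obj["genotypes"]))
    m = _BARCODE_RE.match(text)
    if m is None:
        raise ValueError(f"unrecognized barcode notation: {text!r}")
    snps = tuple(int(x) for x in m.group(1).split("-"))
    genos = tuple(int(x) for x in m.group(2).split("-"))
    return Barcode(snps, genos)


@dataclass(frozen=True)
class ScoredBarcode:
    """A barcode with its carrier counts in each group.

    ``fitness`` is the absolute case/control carrier difference.
    """

    barcode: Barcode
    case_carriers: int
    control_carriers: int

    @property
    def fitness(self) -> int:
        return abs(self.case_carriers - self.control_carriers)

    @property
    def is_protective(self) -> bool:
        return self.control_carriers > self.case_carriers

    @property
    def sort_key(self):
        """Higher fitness first, then canonical barcode order."""
        return (-self.fitness, *self.barcode.key)

    def __str__(self) -> str:
        return f"{self.barcode} diff={self.fitness}"


@dataclass(frozen=True)
class TopKArchive:
    """Elitist archive of the best-``capacity`` distinct scored barcodes."""

    capacity: int
    entries: tuple[ScoredBarcode, ...]

    def __post_init__(self) -> None:
        if self.capacity < 1:
            raise ValueError("capacity must be >= 1")
        if len(self.entries) > self.capacity:
            raise ValueError("archive exceeds capacity")
        keys = [e.barcode.key for e in self.entries]
        if len(set(keys)) != len(keys):
            raise ValueError("archive entries must be distinct barcodes")
        if list(self.entries) != sorted(self.entries, key=lambda e: e.sort_key):
            raise ValueError("archive entries must be sorted")

    @property
    def best(self) -> ScoredBarcode:
        return self.entries[0]

    def __iter__(self):
        return iter(self.entries)

    def __len__(self) -> int:
        return len(self.entries)


def conserve_top_k(
    candidates: Iterable[ScoredBarcode], capacity: int = DEFAULT_CAPACITY
) -> TopKArchive:
    """Deduplicate, sort by (fitness desc, canonical order), keep the top k.

    Duplicated barcodes keep a single entry (their scores are identical on
    a fixed dataset).
    """
    unique: dict = {}
    for cand in candidates:
        unique.setdefault(cand.barcode.key, cand)
    if not unique:
        raise ValueError("no candidates to conserve")
    ranked = sorted(unique.values(), key=lambda e: e.sort_key)
    return TopKArchive(capacity=capacity, entries=tuple(ranked[:capacity]))


def count_carriers(matrix: np.ndarray, barcode: Barcode) -> int:
    """Number of rows matching the barcode genotype at every barcode SNP."""
    n_snp = matrix.shape[1]
    if any(i > n_snp for i in barcode.snp_indices):
        raise IndexError(
            f"barcode SNP index out of range for matrix with {n_snp} SNPs"
        )
    cols = np.asarray(barcode.snp_indices) - 1
    genos = np.asarray(barcode.genotypes, dtype=matrix.dtype)
    return int(np.all(matrix[:, cols] == genos, axis=1).sum())


def fitness(dataset: "GenotypeDataset", barcode: Barcode) -> ScoredBarcode:
    """Score a barcode: |case carriers - control carriers|, counts retained."""
    return ScoredBarcode(
        barcode=barcode,
        case_carriers=count_carriers(dataset.case_matrix, barcode),
        control_carriers=count_carriers(dataset.control_matrix, barcode),
    )


class BarcodeEvaluator:
    """Cached per-(SNP, genotype) indicator masks for fast repeated scoring.

    Scores are identical to :func:`fitness`; this class only avoids
    re-deriving boolean columns inside optimizer loops.
    """

    def __init__(self, dataset: "GenotypeDataset"):
        self.dataset = dataset
        self.n_snp = dataset.n_snp
        # indicators[group][snp-1, genotype-1] is a boolean row mask
        self._case = self._indicators(dataset.case_matrix)
        self._control = self._indicators(dataset.control_matrix)

    @staticmethod
    def _indicators(matrix: np.ndarray) -> np.ndarray:
        n, m = matrix.shape
        ind = np.empty((m, 3, n), dtype=bool)
        for g in (1, 2, 3):
            ind[:, g - 1, :] = (matrix == g).T
        return ind

    def _carriers(self, ind: np.ndarray, snps: Sequence[int], genos: Sequence[int]) -> int:
        mask = ind[snps[0] - 1, genos[0] - 1]
        for i, g in zip(snps[1:], genos[1:]):
            mask = mask & ind[i - 1, g - 1]
        return int(np.count_nonzero(mask))

    def score(self, barcode: Barcode) -> ScoredBarcode:
        return ScoredBarcode(
            barcode=barcode,
            case_carriers=self._carriers(
                self._case, barcode.snp_indices, barcode.genotypes
            ),
            control_carriers=self._carriers(
                self._control, barcode.snp_indices, barcode.genotypes
            ),
        )

    def score_raw(self, snps: Sequence[int], genos: Sequence[int]) -> ScoredBarcode:
        """Like :meth:`score` for pre-validated canonical (snps, genos)."""
        return ScoredBarcode(
            barcode=Barcode(tuple(snps), tuple(genos)),
            case_carriers=self._carriers(self._case, snps, genos),
            control_carriers=self._carriers(self._control, snps, genos),
        )


def exhaustive_top_k(
    dataset: "GenotypeDataset",
    barcode_size: int = 2,
    capacity: int = DEFAULT_CAPACITY,
    candidate_budget: int = DEFAULT_CANDIDATE_BUDGET,
    evaluator: BarcodeEvaluator | None = None,
) -> TopKArchive:
    """Enumerate every ``barcode_size``-SNP barcode and keep the top k.

    The candidate count is C(n_snp, size) * 3**size; sizes whose count
    exceeds ``candidate_budget`` are refused (use the swarm search
    instead).  Deterministic: ties resolve by canonical barcode order.
    """
    if barcode_size < 2:
        raise ValueError("barcode_size must be >= 2")
    n_snp = dataset.n_snp
    if barcode_size > n_snp:
        raise ValueError(f"barcode_size {barcode_size} exceeds SNP count {n_snp}")
    n_candidates = _n_candidates(n_snp, barcode_size)
    if n_candidates > candidate_budget:
        raise ValueError(
            f"{n_candidates} candidates exceed the exhaustive budget "
            f"({candidate_budget}); use the swarm search for this size"
        )
    ev = evaluator or BarcodeEvaluator(dataset)
    if barcode_size == 2:
        candidates = _exhaustive_pairs(ev)
    else:
        geno_combos = list(itertools.product((1, 2, 3), repeat=barcode_size))
        candidates = [
            ev.score_raw(snps, genos)
            for snps in itertools.combinations(range(1, n_snp + 1), barcode_size)
            for genos in geno_combos
        ]
    return conserve_top_k(candidates, capacity=capacity)


def _n_candidates(n_snp: int, size: int) -> int:
    from math import comb

    return comb(n_snp, size) * 3**size


def _exhaustive_pairs(ev: BarcodeEvaluator) -> list[ScoredBarcode]:
    """All 2-SNP candidates via one indicator cross product per group."""
    m = ev.n_snp
    case_flat = ev._case.reshape(m * 3, -1).astype(np.float32)
    ctrl_flat = ev._control.reshape(m * 3, -1).astype(np.float32)
    case_pair = case_flat @ case_flat.T  # (3m, 3m) joint carrier counts
    ctrl_pair = ctrl_flat @ ctrl_flat.T
    out = []
    for i in range(m):
        for j in range(i + 1, m):
            for gi in (1, 2, 3):
                for gj in (1, 2, 3):
                    a = int(case_pair[3 * i + gi - 1, 3 * j + gj - 1])
                    b = int(ctrl_pair[3 * i + gi - 1, 3 * j + gj - 1])
                    out.append(
                        ScoredBarcode(
                            barcode=Barcode((i + 1, j + 1), (gi, gj)),
                            case_carriers=a,
                            control_carriers=b,
                        )
                    )
    return out


def best_extension(
    dataset: "GenotypeDataset",
    barcode: Barcode,
    evaluator: BarcodeEvaluator | None = None,
) -> ScoredBarcode:
    """Best one-SNP extension of a barcode.

    Evaluates every (unused SNP, genotype) addition — (n_snp - size) * 3
    candidates — and returns the maximum-fitness extension, parent pairs
    preserved, ties broken canonically.
    """
    ev = evaluator or BarcodeEvaluator(dataset)
    used = set(barcode.snp_indices)
    if len(used) >= ev.n_snp:
        raise ValueError("no unused SNP remains to extend the barcode")
    best: ScoredBarcode | None = None
    for i in range(1, ev.n_snp + 1):
        if i in used:
            continue
        for g in (1, 2, 3):
            cand = ev.score_raw(barcode.snp_indices + (i,), barcode.genotypes + (g,))
            if best is None or cand.sort_key < best.sort_key:
                best = cand
    return best
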