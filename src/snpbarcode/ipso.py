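"""Elitist swarm search over increasing barcode sizes (top-5 conservation).

The improved search iterates barcode sizes 2..K.  Size 2 is solved
exactly by exhaustive enumeration.  For each larger size k, the five
conserved (k-1)-SNP barcodes are each greedily extended by the single
best (SNP, genotype) addition; those five extensions seed the swarm by
replacing its worst initial particles, and after the swarm run the
archive for size k is conserved from the final personal bests plus the
seeds.  Because the seeds enter the swarm with their exact scores and
the archive always includes them, the reported best fitness at size k
can never fall below the best greedy extension of the size-(k-1)
archive — the elitism chain that makes repeated runs agree.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .barcode_core import (
    BarcodeEvaluator,
    ScoredBarcode,
    TopKArchive,
    best_extension,
    conserve_top_k,
    exhaustive_top_k,
)
from .genotype_data import GenotypeDataset
from .pso import PsoRun, SwarmConfig, run_pso

__all__ = ["SizeResult", "IpsoResult", "run_ipso", "conserve_top5"]


def conserve_top5(candidates, capacity: int = 5) -> TopKArchive:
    """Alias of :func:`snpbarcode.barcode_core.conserve_top_k` at capacity 5."""
    return conserve_top_k(candidates, capacity=capacity)


@dataclass(frozen=True)
class SizeResult:
    """Best barcode, conserved archive and swarm trace at one size."""

    best: ScoredBarcode
    archive: TopKArchive
    trace: tuple[int, ...]
    seeds: tuple[ScoredBarcode, ...] = ()


@dataclass(frozen=True)
class IpsoResult:
    """Per-size results of one elitist run, keyed by barcode size."""

    per_size: dict[int, SizeResult]

    @property
    def sizes(self) -> tuple[int, ...]:
        return tuple(sorted(self.per_size))

    def best_fitness(self) -> dict[int, int]:
        return {k: r.best.fitness for k, r in sorted(self.per_size.items())}


def run_ipso(
    dataset: GenotypeDataset,
    max_size: int = 10,
    config: SwarmConfig | None = None,
    rng: int | np.random.Generator | np.random.SeedSequence = 0,
    capacity: int = 5,
) -> IpsoResult:
    """Elitist barcode search over sizes 2..``max_size``.

    Size 2 comes from exhaustive enumeration (never the swarm).  Each
    subsequent size seeds its swarm with the greedy one-SNP extensions of
    the previous archive.  Deterministic given the seed.
    """
    if max_size < 2:
        raise ValueError("max_size must be >= 2")
    if max_size > dataset.n_snp:
        raise ValueError(
            f"max_size {max_size} exceeds SNP count {dataset.n_snp}"
        )
    if isinstance(rng, np.random.Generator):
        master = rng
    else:
        seed = rng if isinstance(rng, np.random.SeedSequence) else np.random.SeedSequence(int(rng))
        master = np.random.default_rng(seed)
    config = config or SwarmConfig(archive_capacity=capacity)
    evaluator = BarcodeEvaluator(dataset)

    per_size: dict[int, SizeResult] = {}
    archive = exhaustive_top_k(dataset, 2, capacity=capacity, evaluator=evaluator)
    per_size[2] = SizeResult(best=archive.best, archive=archive, trace=())

    for k in range(3, max_size + 1):
        extensions = [
            best_extension(dataset, entry.barcode, evaluator=evaluator)
            for entry in archive
        ]
        # identical extensions from different parents collapse to one seed
        seeds = tuple(conserve_top_k(extensions, capacity=capacity))
        run = run_pso(
            dataset,
            barcode_size=k,
            config=config,
            rng=master,
            seeds=seeds,
            evaluator=evaluator,
        )
        archive = run.archive
        per_size[k] = SizeResult(
            best=run.best, archive=archive, trace=run.trace, seeds=seeds
        )
    return IpsoResult(per_size=per_size)
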