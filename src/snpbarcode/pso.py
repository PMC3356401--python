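"""Particle swarm optimization over SNP-barcode space.

Particles carry a continuous position of 2k dimensions for a size-k
barcode: k SNP dimensions bounded by [1, n_snp] followed by k genotype
dimensions bounded by [1, 3].  The classic velocity/position updates

    v <- w*v + c1*r1*(pbest - x) + c2*r2*(gbest - x)
    x <- x + v

run on the continuous state; a decode step (round half-away-from-zero,
clamp, repair duplicate SNP picks with random unused SNPs) maps each
position to a valid barcode for evaluation.  The inertia weight w is
scheduled linearly over the run.  pbest/gbest update on strict fitness
improvement only, so the global best trace is non-decreasing and an
elite seed particle can never be lost before it is evaluated.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .barcode_core import (
    Barcode,
    BarcodeEvaluator,
    ScoredBarcode,
    TopKArchive,
    conserve_top_k,
)
from .genotype_data import GenotypeDataset

__all__ = [
    "SwarmConfig",
    "Particle",
    "SwarmState",
    "PsoRun",
    "decode_position",
    "update_velocity",
    "update_position",
    "step",
    "init_swarm",
    "run_pso",
]


@dataclass(frozen=True)
class SwarmConfig:
    """Swarm hyperparameters.

    Defaults: 50 particles, 100 iterations, c1 = c2 = 2, inertia weight
    scheduled linearly from 0.9 down to 0.4 (the canonical Shi–Eberhart
    range).  Position bounds derive from the problem ([1, n_snp] /
    [1, 3]); velocity bounds are ±(x_max − x_min) per dimension unless
    overridden.
    """

    population: int = 50
    iterations: int = 100
    c1: float = 2.0
    c2: float = 2.0
    w_start: float = 0.9
    w_end: float = 0.4
    x_min: np.ndarray | None = None
    x_max: np.ndarray | None = None
    v_min: np.ndarray | None = None
    v_max: np.ndarray | None = None
    archive_capacity: int = 5

    def __post_init__(self) -> None:
        if self.population < 1 or self.iterations < 0:
            raise ValueError("population must be >= 1 and iterations >= 0")

    def bounds(self, n_snp: int, barcode_size: int):
        """(x_lo, x_hi, v_lo, v_hi) arrays of length 2*barcode_size."""
        k = barcode_size
        x_lo = np.ones(2 * k) if self.x_min is None else np.asarray(self.x_min, float)
        if self.x_max is None:
            x_hi = np.concatenate([np.full(k, float(n_snp)), np.full(k, 3.0)])
        else:
            x_hi = np.asarray(self.x_max, float)
        v_hi = (x_hi - x_lo) if self.v_max is None else np.asarray(self.v_max, float)
        v_lo = -(x_hi - x_lo) if self.v_min is None else np.asarray(self.v_min, float)
        return x_lo, x_hi, v_lo, v_hi

    def inertia(self, iteration: int) -> float:
        """Linear inertia schedule w(t) for 0-based iteration t."""
        if self.iterations <= 1:
            return self.w_start
        frac = min(iteration, self.iterations - 1) / (self.iterations - 1)
        return self.w_start + (self.w_end - self.w_start) * frac


@dataclass
class Particle:
    """Continuous state plus personal-best bookkeeping for one particle."""

    position: np.ndarray
    velocity: np.ndarray
    pbest_position: np.ndarray | None = None
    pbest_score: ScoredBarcode | None = None

    @property
    def pbest_fitness(self) -> int:
        return -1 if self.pbest_score is None else self.pbest_score.fitness


@dataclass
class SwarmState:
    """Whole-swarm state; ``gbest_score`` never worsens across steps."""

    particles: list[Particle]
    gbest_position: np.ndarray | None = None
    gbest_score: ScoredBarcode | None = None
    iteration: int = 0
    trace: list[int] = field(default_factory=list)

    @property
    def gbest_fitness(self) -> int:
        return -1 if self.gbest_score is None else self.gbest_score.fitness


@dataclass(frozen=True)
class PsoRun:
    """Result of one swarm run."""

    best: ScoredBarcode
    archive: TopKArchive
    trace: tuple[int, ...]


def decode_position(
    position: np.ndarray, n_snp: int, rng: np.random.Generator
) -> Barcode:
    """Map a continuous 2k-position to a valid barcode.

    Dimensions are rounded half-away-from-zero and clamped to their
    integer ranges.  Duplicate SNP picks are repaired in place: later
    duplicates are replaced by uniformly random unused SNPs.
    """
    position = np.asarray(position, dtype=float)
    if not np.all(np.isfinite(position)):
        raise ValueError("position contains non-finite values")
    k = position.size // 2
    if n_snp < k:
        raise ValueError(f"cannot pick {k} distinct SNPs out of {n_snp}")
    rounded = np.floor(np.abs(position) + 0.5) * np.sign(position)
    snps = np.clip(rounded[:k], 1, n_snp).astype(int)
    genos = np.clip(rounded[k:], 1, 3).astype(int)
    seen: set[int] = set()
    duplicates: list[int] = []
    for d, s in enumerate(snps):
        if s in seen:
            duplicates.append(d)
        else:
            seen.add(int(s))
    if duplicates:
        unused = np.array(sorted(set(range(1, n_snp + 1)) - seen))
        picks = rng.choice(unused, size=len(duplicates), replace=False)
        for d, s in zip(duplicates, picks):
            snps[d] = s
    return Barcode(tuple(int(s) for s in snps), tuple(int(g) for g in genos))


def encode_barcode(barcode: Barcode, size_hint: int | None = None) -> np.ndarray:
    """Exact continuous position for a barcode (inverse of decode)."""
    return np.array(
        [*map(float, barcode.snp_indices), *map(float, barcode.genotypes)]
    )


def update_velocity(
    particle: Particle,
    gbest_position: np.ndarray,
    w: float,
    rng: np.random.Generator,
    c1: float,
    c2: float,
    v_lo: np.ndarray,
    v_hi: np.ndarray,
) -> np.ndarray:
    """Velocity update with per-dimension r1, r2 ~ U(0,1), then clamping."""
    d = particle.position.size
    r1 = rng.random(d)
    r2 = rng.random(d)
    v_new = (
        w * particle.velocity
        + c1 * r1 * (particle.pbest_position - particle.position)
        + c2 * r2 * (gbest_position - particle.position)
    )
    return np.clip(v_new, v_lo, v_hi)


def update_position(
    particle: Particle, x_lo: np.ndarray, x_hi: np.ndarray
) -> np.ndarray:
    """Position update x + v, clamped into the box bounds."""
    return np.clip(particle.position + particle.velocity, x_lo, x_hi)


def _evaluate(
    state: SwarmState, evaluator: BarcodeEvaluator, rng: np.random.Generator
) -> None:
    """Score every particle; update pbest/gbest on strict improvement."""
    for p in state.particles:
        barcode = decode_position(p.position, evaluator.n_snp, rng)
        score = evaluator.score(barcode)
        if p.pbest_score is None or score.fitness > p.pbest_score.fitness:
            p.pbest_score = score
            p.pbest_position = p.position.copy()
        if state.gbest_score is None or p.pbest_score.fitness > state.gbest_score.fitness:
            state.gbest_score = p.pbest_score
            state.gbest_position = p.pbest_position.copy()


def init_swarm(
    dataset: GenotypeDataset,
    barcode_size: int,
    config: SwarmConfig,
    rng: np.random.Generator,
    evaluator: BarcodeEvaluator | None = None,
    seeds: Sequence[ScoredBarcode] | None = None,
) -> tuple[SwarmState, BarcodeEvaluator]:
    """Random swarm; optional elite seeds replace the worst initial particles.

    Positions start uniform within bounds and velocities uniform within
    the velocity box.  When seeds are given, the ``len(seeds)`` worst
    particles of the initial population (by initial decoded fitness) are
    repositioned exactly at the seed barcodes with zero velocity, and
    their personal bests start at the seed scores so an elite solution is
    registered before any move.
    """
    ev = evaluator or BarcodeEvaluator(dataset)
    x_lo, x_hi, v_lo, v_hi = config.bounds(ev.n_snp, barcode_size)
    particles = []
    for _ in range(config.population):
        pos = rng.uniform(x_lo, x_hi)
        vel = rng.uniform(v_lo, v_hi)
        particles.append(Particle(position=pos, velocity=vel))
    state = SwarmState(particles=particles)
    _evaluate(state, ev, rng)  # initial scores define pbest and "worst"
    if seeds:
        order = sorted(
            range(len(particles)), key=lambda i: particles[i].pbest_score.sort_key
        )
        worst = order[::-1][: len(seeds)]
        for idx, seed in zip(worst, seeds):
            p = particles[idx]
            p.position = encode_barcode(seed.barcode)
            p.velocity = np.zeros_like(p.position)
            p.pbest_position = p.position.copy()
            p.pbest_score = seed
            if seed.fitness > state.gbest_fitness:
                state.gbest_score = seed
                state.gbest_position = p.position.copy()
    state.trace.append(state.gbest_fitness)
    return state, ev


def step(
    state: SwarmState,
    dataset_or_evaluator: GenotypeDataset | BarcodeEvaluator,
    config: SwarmConfig,
    rng: np.random.Generator,
) -> SwarmState:
    """One swarm iteration: move every particle, then re-evaluate.

    The inertia weight for the move is the linear schedule value at the
    current iteration counter; the counter then advances and the global
    best (which can only improve) is appended to the trace.
    """
    ev = (
        dataset_or_evaluator
        if isinstance(dataset_or_evaluator, BarcodeEvaluator)
        else BarcodeEvaluator(dataset_or_evaluator)
    )
    k = state.particles[0].position.size // 2
    x_lo, x_hi, v_lo, v_hi = config.bounds(ev.n_snp, k)
    w = config.inertia(state.iteration)
    for p in state.particles:
        p.velocity = update_velocity(
            p, state.gbest_position, w, rng, config.c1, config.c2, v_lo, v_hi
        )
        p.position = update_position(p, x_lo, x_hi)
    _evaluate(state, ev, rng)
    state.iteration += 1
    state.trace.append(state.gbest_fitness)
    return state


def run_pso(
    dataset: GenotypeDataset,
    barcode_size: int,
    config: SwarmConfig | None = None,
    rng: int | np.random.Generator = 0,
    seeds: Sequence[ScoredBarcode] | None = None,
    evaluator: BarcodeEvaluator | None = None,
) -> PsoRun:
    """Full swarm run; returns the global best, top-5 archive and trace.

    The archive is conserved from the final personal bests plus any seed
    barcodes, so with seeding it can never fall below the seeds.  Fully
    deterministic given (rng seed, config, dataset).
    """
    config = config or SwarmConfig()
    if barcode_size < 2:
        raise ValueError("barcode_size must be >= 2")
    if barcode_size > dataset.n_snp:
        raise ValueError(
            f"barcode_size {barcode_size} exceeds SNP count {dataset.n_snp}"
        )
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    state, ev = init_swarm(
        dataset, barcode_size, config, rng, evaluator=evaluator, seeds=seeds
    )
    for _ in range(config.iterations):
        step(state, ev, config, rng)
    candidates = [p.pbest_score for p in state.particles]
    if seeds:
        candidates.extend(seeds)
    archive = conserve_top_k(candidates, capacity=config.archive_capacity)
    return PsoRun(
        best=archive.best, archive=archive, trace=tuple(state.trace)
    )
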