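"""Synthetic benchmark: planted order-preserving submatrices.

The generator embeds a small number of order-preserving patterns (blocks of
genes sharing one strict descending-value order across a block of samples)
into a background of uniform noise, mirroring the standard planted-bicluster
design.  Planted values sit above the background, so in every planted sample
the planted genes occupy the top ranks in the planted order.  Gaussian noise
scaled to the planted inter-rank value gap perturbs the ranking; shuffling
destroys all structure for null runs.  A benchmark run mines each replicate
and scores sensitivity (planted patterns recovered), search complexity
(candidate support evaluations), and efficiency (recovered per candidate).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .exprseq import ExpressionMatrix, to_sequence_db
from .mining import PatternSet, SearchParams, sp_searching
from .oracle import naive_spm

__all__ = [
    "SimulationConfig",
    "TruePattern",
    "EmbeddedTruth",
    "BenchmarkResult",
    "generate_embedded_matrix",
    "add_noise",
    "shuffle_matrix",
    "sensitivity",
    "benchmark_run",
    "mean_result",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Planted-pattern design: ``n_patterns`` disjoint blocks of
    ``pattern_genes`` × ``pattern_samples`` embedded in an ``n_genes`` ×
    ``n_samples`` uniform background.  ``noise_sd`` is the Gaussian noise
    level as a fraction of the planted inter-rank value gap."""

    n_genes: int = 50
    n_samples: int = 50
    n_patterns: int = 5
    pattern_genes: int = 10
    pattern_samples: int = 10
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patterns < 0 or self.noise_sd < 0:
            raise ValueError("n_patterns and noise_sd must be nonnegative")
        if self.n_patterns and (
            self.pattern_genes > self.n_genes or self.pattern_samples > self.n_samples
        ):
            raise ValueError("planted block exceeds matrix dimensions")
        if self.n_patterns * self.pattern_genes > self.n_genes:
            raise ValueError("not enough genes for disjoint planted blocks")
        if self.n_patterns * self.pattern_samples > self.n_samples:
            raise ValueError("not enough samples for disjoint planted blocks")


@dataclass(frozen=True)
class TruePattern:
    genes: tuple[str, ...]  # planted descending-value order
    samples: frozenset[str]


@dataclass(frozen=True)
class EmbeddedTruth:
    patterns: tuple[TruePattern, ...]
    value_gap: float = 1.0  # mean adjacent planted-value gap (noise unit)


@dataclass(frozen=True)
class BenchmarkResult:
    sensitivity: float
    complexity: int  # candidate support evaluations during the search
    efficiency: float  # recovered planted patterns per candidate evaluated
    n_found: int = 0
    noise_sd: float = 0.0


def generate_embedded_matrix(
    cfg: SimulationConfig,
) -> tuple[ExpressionMatrix, EmbeddedTruth]:
    """Draw the background uniform on (0,1) and plant the patterns.

    Planted genes/samples form disjoint blocks chosen at random; within a
    block every planted sample gets the same strict descending values, evenly
    spaced on (1, 2] so they outrank the background with probability one.
    """
    rng = np.random.default_rng(cfg.seed)
    values = rng.uniform(0.0, 1.0, size=(cfg.n_genes, cfg.n_samples))
    gene_ids = tuple(f"g{i + 1}" for i in range(cfg.n_genes))
    sample_ids = tuple(f"s{j + 1}" for j in range(cfg.n_samples))

    truths: list[TruePattern] = []
    gap = 1.0 / max(cfg.pattern_genes, 1)
    if cfg.n_patterns:
        gene_pool = rng.permutation(cfg.n_genes)
        sample_pool = rng.permutation(cfg.n_samples)
        for p in range(cfg.n_patterns):
            gs = gene_pool[p * cfg.pattern_genes : (p + 1) * cfg.pattern_genes]
            ss = sample_pool[p * cfg.pattern_samples : (p + 1) * cfg.pattern_samples]
            # planted order = pool order; values 2, 2-gap, ... strictly descending
            planted = 2.0 - gap * np.arange(cfg.pattern_genes)
            values[np.ix_(gs, ss)] = planted[:, None]
            truths.append(
                TruePattern(
                    genes=tuple(gene_ids[g] for g in gs),
                    samples=frozenset(sample_ids[s] for s in ss),
                )
            )
    E = ExpressionMatrix(gene_ids, sample_ids, values)
    return E, EmbeddedTruth(patterns=tuple(truths), value_gap=gap)


def add_noise(
    E: ExpressionMatrix, noise_sd: float, seed: int, gap: float = 1.0
) -> ExpressionMatrix:
    """Add i.i.d. Gaussian noise with sd = noise_sd * gap, clamped at 0.

    ``gap`` is the planted inter-rank value gap (EmbeddedTruth.value_gap), so
    noise_sd = 1 means perturbations as large as the spacing that encodes the
    planted order.  noise_sd = 0 returns the input unchanged.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if noise_sd == 0:
        return E
    rng = np.random.default_rng(seed)
    noisy = E.values + rng.normal(0.0, noise_sd * gap, size=E.values.shape)
    return ExpressionMatrix(E.gene_ids, E.sample_ids, np.maximum(noisy, 0.0))


def shuffle_matrix(E: ExpressionMatrix, seed: int) -> ExpressionMatrix:
    """Uniformly permute all cell values across the whole matrix (null run);
    the multiset of values is preserved exactly."""
    rng = np.random.default_rng(seed)
    flat = E.values.ravel().copy()
    rng.shuffle(flat)
    return ExpressionMatrix(E.gene_ids, E.sample_ids, flat.reshape(E.values.shape))


def sensitivity(
    found: PatternSet, truth: EmbeddedTruth, params: SearchParams
) -> float:
    """Fraction of planted patterns recovered by the mined set.

    A planted pattern counts as recovered when some mined pattern shares at
    least min(l, pattern size) of its genes and min(u, planted support) of
    its samples.  At the benchmark settings (u = planted support, l = planted
    length) this demands exact recovery of the planted bi-set at zero noise
    and degrades gracefully under noise.  Empty truth is undefined -> NaN.
    """
    if not truth.patterns:
        return math.nan
    recovered = 0
    found_sets = [(frozenset(p.genes), p.samples) for p in found.patterns]
    for t in truth.patterns:
        need_g = min(params.l, len(t.genes))
        need_s = min(params.u, len(t.samples))
        tg = frozenset(t.genes)
        if any(
            len(tg & fg) >= need_g and len(t.samples & fs) >= need_s
            for fg, fs in found_sets
        ):
            recovered += 1
    return recovered / len(truth.patterns)


def _mine(miner: str, db, params: SearchParams) -> PatternSet:
    if miner == "windowed":
        return sp_searching(db, params)
    if miner == "naive":
        return naive_spm(db, params.u, params.l)
    raise ValueError(f"unknown miner {miner!r} (expected 'windowed' or 'naive')")


def benchmark_run(
    miner: str,
    cfg: SimulationConfig,
    params: SearchParams,
    replicates: int = 5,
    seed: int = 0,
) -> list[BenchmarkResult]:
    """Generate -> add noise -> rank -> mine -> score, per replicate.

    Replicate seeds are derived from ``seed``, so a repeated call reproduces
    every replicate exactly.
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    rng = np.random.default_rng(seed)
    rep_seeds = rng.integers(0, 2**31 - 1, size=(replicates, 2))
    out: list[BenchmarkResult] = []
    for r in range(replicates):
        gen_cfg = SimulationConfig(
            n_genes=cfg.n_genes,
            n_samples=cfg.n_samples,
            n_patterns=cfg.n_patterns,
            pattern_genes=cfg.pattern_genes,
            pattern_samples=cfg.pattern_samples,
            noise_sd=cfg.noise_sd,
            seed=int(rep_seeds[r, 0]),
        )
        E, truth = generate_embedded_matrix(gen_cfg)
        E = add_noise(E, cfg.noise_sd, int(rep_seeds[r, 1]), gap=truth.value_gap)
        db = to_sequence_db(E)
        found = _mine(miner, db, params)
        sens = sensitivity(found, truth, params)
        recovered = 0 if math.isnan(sens) else round(sens * len(truth.patterns))
        comp = found.candidates_evaluated
        out.append(
            BenchmarkResult(
                sensitivity=sens,
                complexity=comp,
                efficiency=recovered / comp if comp else 0.0,
                n_found=len(found),
                noise_sd=cfg.noise_sd,
            )
        )
    return out


def mean_result(results: Sequence[BenchmarkResult]) -> BenchmarkResult:
    """Average of per-replicate results (complexity rounded to nearest int)."""
    if not results:
        raise ValueError("no results to average")
    return BenchmarkResult(
        sensitivity=float(np.mean([r.sensitivity for r in results])),
        complexity=int(round(np.mean([r.complexity for r in results]))),
        efficiency=float(np.mean([r.efficiency for r in results])),
        n_found=int(round(np.mean([r.n_found for r in results]))),
        noise_sd=results[0].noise_sd,
    )
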