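"""Hypergeometric enrichment of modules and permutation-null calibration.

Each module's gene set is tested for over-representation in every annotation
term it touches (and its sample set against sample categories, symmetrically);
the module keeps the single most significant p-value and its term.  No
multiple-testing correction is applied per module — significance is
calibrated instead against a matched null: random modules drawn with the same
(length, support) distribution as the mined patterns, from which an empirical
false-discovery rate at a p-value threshold and quantile-quantile pairs are
computed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.stats import hypergeom

from .modules import RegulatoryModule

__all__ = [
    "AnnotationMap",
    "EnrichmentResult",
    "read_gmt",
    "hypergeom_upper_tail",
    "module_min_p",
    "random_pattern_set",
    "estimate_fdr",
    "qq_pairs",
    "context_table",
]


@dataclass(frozen=True)
class AnnotationMap:
    """Term -> member set, over a fixed universe of items.

    The universe is every item eligible for drawing (all genes of the
    expression matrix after exclusions, or all samples), not just annotated
    items; unannotated items simply never count as hits.
    """

    terms: dict[str, frozenset[str]]
    universe: frozenset[str]

    def __post_init__(self) -> None:
        if not self.universe:
            raise ValueError("annotation universe must be nonempty")
        for t, members in self.terms.items():
            if not members <= self.universe:
                raise ValueError(f"term {t!r} has members outside the universe")


def read_gmt(path: str | Path, universe: Iterable[str] | None = None) -> AnnotationMap:
    """Read a GMT file (term <tab> description <tab> member IDs...).

    If ``universe`` is given, members outside it are dropped with a warning;
    otherwise the universe is the union of all members.
    """
    raw: dict[str, frozenset[str]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError(f"malformed GMT line (need term, description, members): {line!r}")
        raw[fields[0]] = frozenset(m for m in fields[2:] if m)
    if universe is None:
        uni = frozenset().union(*raw.values()) if raw else frozenset()
    else:
        uni = frozenset(universe)
        dropped = sum(len(m - uni) for m in raw.values())
        if dropped:
            warnings.warn(
                f"{dropped} GMT member(s) absent from the universe were dropped",
                stacklevel=2,
            )
        raw = {t: m & uni for t, m in raw.items()}
    return AnnotationMap(terms=raw, universe=uni)


@dataclass(frozen=True)
class EnrichmentResult:
    module_id: str
    best_term: str | None
    p_value: float
    per_term: dict[str, float] = field(default_factory=dict)


def hypergeom_upper_tail(k: int, K: int, n: int, N: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, K, n).

    k hits in a module of size n, against a term of size K in a universe of
    size N.  k = 0 gives 1 exactly, as does a term covering the universe.
    """
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValueError(f"inconsistent counts: K={K}, n={n}, N={N}")
    if not (0 <= k <= min(K, n)):
        raise ValueError(f"hit count k={k} outside [0, min(K={K}, n={n})]")
    if k == 0:
        return 1.0
    return float(hypergeom.sf(k - 1, N, K, n))


def _axis_min_p(items: frozenset[str], ann: AnnotationMap, module_id: str) -> EnrichmentResult:
    N = len(ann.universe)
    n = len(items)
    per_term: dict[str, float] = {}
    for term in ann.terms:  # insertion order -> deterministic tie-break
        k = len(items & ann.terms[term])
        if k == 0:
            continue
        per_term[term] = hypergeom_upper_tail(k, len(ann.terms[term]), n, N)
    if not per_term:
        return EnrichmentResult(module_id, None, 1.0, {})
    best = min(per_term, key=lambda t: (per_term[t], list(per_term).index(t)))
    return EnrichmentResult(module_id, best, per_term[best], per_term)


def module_min_p(
    m: RegulatoryModule,
    genes_ann: AnnotationMap,
    samples_ann: AnnotationMap,
    module_id: str = "",
) -> tuple[EnrichmentResult, EnrichmentResult]:
    """Most significant term per axis: (gene-axis result, sample-axis result).

    Only terms with at least one hit are tested; a module hitting no term at
    all reports p = 1 with no best term.  Module items must belong to the
    respective universes.
    """
    if not m.gene_set <= genes_ann.universe:
        raise ValueError("module genes outside the gene universe")
    if not m.sample_set <= samples_ann.universe:
        raise ValueError("module samples outside the sample universe")
    return (
        _axis_min_p(m.gene_set, genes_ann, module_id),
        _axis_min_p(m.sample_set, samples_ann, module_id),
    )


def random_pattern_set(
    distribution: Mapping[tuple[int, int], int],
    gene_universe: Sequence[str],
    sample_universe: Sequence[str],
    seed: int = 0,
) -> list[RegulatoryModule]:
    """Matched random modules: for each (length, support) cell with count c,
    draw c modules of that many genes and samples uniformly without
    replacement.  This is the permutation null the mined modules are
    calibrated against."""
    if not distribution:
        raise ValueError("distribution must be nonempty")
    genes = list(gene_universe)
    samples = list(sample_universe)
    rng = np.random.default_rng(seed)
    out: list[RegulatoryModule] = []
    for (dg, ds), count in sorted(distribution.items()):
        if dg > len(genes):
            raise ValueError(f"pattern length {dg} exceeds gene universe {len(genes)}")
        if ds > len(samples):
            raise ValueError(f"support {ds} exceeds sample universe {len(samples)}")
        for _ in range(count):
            gs = rng.choice(len(genes), size=dg, replace=False)
            ss = rng.choice(len(samples), size=ds, replace=False)
            out.append(
                RegulatoryModule(
                    gene_set=frozenset(genes[i] for i in gs),
                    sample_set=frozenset(samples[i] for i in ss),
                )
            )
    return out


def estimate_fdr(
    p_real: Sequence[float], p_null: Sequence[float], threshold: float
) -> float:
    """Empirical FDR at a p-value threshold.

    The null significant count is rescaled to the real list's size:
    fdr = (#{null < t} * |real|/|null|) / max(1, #{real < t}).
    """
    if not (0 < threshold < 1):
        raise ValueError("threshold must lie in (0, 1)")
    p_real = np.asarray(p_real, float)
    p_null = np.asarray(p_null, float)
    if p_real.size == 0 or p_null.size == 0:
        raise ValueError("p-value lists must be nonempty")
    null_sig = np.count_nonzero(p_null < threshold) * p_real.size / p_null.size
    real_sig = np.count_nonzero(p_real < threshold)
    return float(null_sig / max(1, real_sig))


def qq_pairs(
    p_real: Sequence[float], p_null: Sequence[float]
) -> list[tuple[float, float]]:
    """Quantile-paired -log10 p-values: (null quantile, real quantile).

    Lists of unequal length are paired by linear quantile interpolation at
    min(len_real, len_null) levels.  Zero p-values are clamped to the smallest
    positive float with a warning.
    """
    def neglog(p: np.ndarray) -> np.ndarray:
        p = np.asarray(p, float)
        if np.any(p <= 0):
            warnings.warn("zero p-values clamped to smallest positive float", stacklevel=3)
            p = np.maximum(p, np.finfo(float).tiny)
        return -np.log10(p)

    a, b = neglog(p_real), neglog(p_null)
    if a.size == 0 or b.size == 0:
        raise ValueError("p-value lists must be nonempty")
    n = min(a.size, b.size)
    levels = np.linspace(0.0, 1.0, n) if n > 1 else np.array([0.5])
    # quantiles of -log10 p ascending: pair weakest with weakest
    qa = np.quantile(np.sort(a), levels)
    qb = np.quantile(np.sort(b), levels)
    return list(zip(qb.tolist(), qa.tolist()))


def context_table(
    results: Sequence[tuple[EnrichmentResult, EnrichmentResult]],
    p_threshold: float,
):
    """Cross-tab of best gene term × best sample category for modules that are
    significant (min p < threshold) on both axes; all-zero rows/columns are
    absent by construction.  Returns a DataFrame with marginal totals."""
    import pandas as pd

    rows = [
        {"gene_term": g.best_term, "sample_category": s.best_term}
        for g, s in results
        if g.p_value < p_threshold and s.p_value < p_threshold
        and g.best_term is not None and s.best_term is not None
    ]
    if not rows:
        return pd.DataFrame(
            [[0]], index=pd.Index(["Total"], name="gene_term"), columns=["Total"]
        )
    df = pd.DataFrame(rows)
    tab = pd.crosstab(
        df["gene_term"], df["sample_category"], margins=True, margins_name="Total"
    )
    return tab
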