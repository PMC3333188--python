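"""Regulatory modules and inter-module relations.

A regulatory module is the unordered bi-set (gene set, sample set) of a
sequential pattern: the co-regulated genes together with the samples under
which they are co-regulated.  Membership is non-exclusive — a gene or sample
may belong to many modules.  Pairs of modules are compared by their gene
overlap X_g and sample overlap X_s, classified into four relation types, and
summarised by k-medoid representatives under a bounded area-overlap distance.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .mining import SequentialPattern

__all__ = [
    "RegulatoryModule",
    "OverlapDegrees",
    "RelationType",
    "pattern_to_module",
    "overlap_degrees",
    "classify_relation",
    "module_distance",
    "distance_matrix",
    "kmedoid_representatives",
    "overlap_matrix",
    "write_modules_jsonl",
    "read_modules_jsonl",
]


@dataclass(frozen=True)
class RegulatoryModule:
    gene_set: frozenset[str]
    sample_set: frozenset[str]
    source_pattern: SequentialPattern | None = None

    def __post_init__(self) -> None:
        if not self.gene_set or not self.sample_set:
            raise ValueError("module gene and sample sets must be nonempty")

    @property
    def area(self) -> int:
        """Cells covered in the expression matrix: |genes| * |samples|."""
        return len(self.gene_set) * len(self.sample_set)


@dataclass(frozen=True)
class OverlapDegrees:
    X_g: float
    X_s: float


class RelationType(str, Enum):
    independent = "independent"
    conditionally_coregulated = "conditionally_coregulated"
    separately_coregulated = "separately_coregulated"
    similar = "similar"


def pattern_to_module(p: SequentialPattern) -> RegulatoryModule:
    """Forget gene order: the pattern's genes and samples become plain sets."""
    return RegulatoryModule(
        gene_set=frozenset(p.genes), sample_set=frozenset(p.samples), source_pattern=p
    )


def _overlap(a: frozenset, b: frozenset, method: str) -> float:
    inter = len(a & b)
    if method == "jaccard":
        union = len(a | b)
        return inter / union if union else 0.0
    if method == "overlap":  # overlap coefficient
        denom = min(len(a), len(b))
        return inter / denom if denom else 0.0
    raise ValueError(f"unknown overlap method {method!r}")


def overlap_degrees(
    m: RegulatoryModule, m2: RegulatoryModule, method: str = "jaccard"
) -> OverlapDegrees:
    """Degrees of gene overlap X_g and sample overlap X_s between two modules.

    Jaccard (|∩|/|∪|) by default; the overlap coefficient |∩|/min(|·|,|·|) is
    available as ``method="overlap"``.  Both are symmetric, 1 iff the sets are
    identical (Jaccard) and 0 iff disjoint.
    """
    return OverlapDegrees(
        X_g=_overlap(m.gene_set, m2.gene_set, method),
        X_s=_overlap(m.sample_set, m2.sample_set, method),
    )


def classify_relation(
    o: OverlapDegrees, t_g: float = 0.5, t_s: float = 0.5
) -> RelationType:
    """Map (X_g, X_s) to one of the four inter-module relation types.

    high/high -> similar; high gene, low sample -> conditionally co-regulated
    (same genes under different conditions); low gene, high sample ->
    separately co-regulated (distinct gene sets under the same conditions);
    low/low -> independent.  "High" means >= the threshold, so the mapping is
    total and mutually exclusive.
    """
    if not (0 < t_g < 1 and 0 < t_s < 1):
        raise ValueError("thresholds must lie in (0, 1)")
    g_high, s_high = o.X_g >= t_g, o.X_s >= t_s
    if g_high and s_high:
        return RelationType.similar
    if g_high:
        return RelationType.conditionally_coregulated
    if s_high:
        return RelationType.separately_coregulated
    return RelationType.independent


def module_distance(m: RegulatoryModule, m2: RegulatoryModule) -> float:
    """Bounded area-overlap distance: 1 - 2*A_inter / (A + A').

    A module's area is |genes| * |samples| cells; A_inter is the area of the
    shared block |genes ∩| * |samples ∩|.  0 for identical modules, 1 for
    modules disjoint on either axis; always in [0, 1].
    """
    a_inter = len(m.gene_set & m2.gene_set) * len(m.sample_set & m2.sample_set)
    return 1.0 - 2.0 * a_inter / (m.area + m2.area)


def distance_matrix(modules: Sequence[RegulatoryModule]) -> np.ndarray:
    n = len(modules)
    dm = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            dm[i, j] = dm[j, i] = module_distance(modules[i], modules[j])
    return dm


def kmedoid_representatives(
    modules: Sequence[RegulatoryModule], k: int, seed: int = 0
) -> tuple[list[int], np.ndarray]:
    """PAM k-medoids under :func:`module_distance`.

    Returns (medoid indices, assignment array mapping each module to a medoid
    index).  Initialisation is greedy maximin: the first medoid is drawn from
    the seed, each further medoid maximises its distance to the chosen set
    (ties by input order); the swap phase then applies best-improvement swaps
    until convergence.  Deterministic given the seed.
    """
    n = len(modules)
    if k <= 0:
        raise ValueError("k must be positive")
    if k > n:
        raise ValueError(f"k={k} exceeds number of modules {n}")
    dm = distance_matrix(modules)
    rng = np.random.default_rng(seed)
    medoids = [int(rng.integers(n))]
    while len(medoids) < k:
        mind = dm[:, medoids].min(axis=1)
        mind[medoids] = -1.0
        medoids.append(int(np.argmax(mind)))  # argmax takes first on ties
    medoids_arr = np.array(sorted(medoids))

    def cost(meds: np.ndarray) -> float:
        return dm[:, meds].min(axis=1).sum()

    best = cost(medoids_arr)
    improved = True
    while improved:
        improved = False
        best_swap = None
        med_set = set(medoids_arr.tolist())
        for mi in range(k):
            for h in range(n):
                if h in med_set:
                    continue
                trial = medoids_arr.copy()
                trial[mi] = h
                c = cost(trial)
                if c < best - 1e-12:
                    best, best_swap = c, (mi, h)
        if best_swap is not None:
            medoids_arr[best_swap[0]] = best_swap[1]
            medoids_arr = np.sort(medoids_arr)
            improved = True
    assignment = medoids_arr[np.argmin(dm[:, medoids_arr], axis=1)]
    return medoids_arr.tolist(), assignment


def overlap_matrix(
    modules: Sequence[RegulatoryModule],
    ids: Sequence[str] | None = None,
    method: str = "jaccard",
) -> pd.DataFrame:
    """Square grid: gene overlap X_g below the diagonal, sample overlap X_s above.

    Diagonal entries are 1.0.  Row/column labels default to m1, m2, ...
    """
    n = len(modules)
    if n < 2:
        raise ValueError("need at least 2 modules")
    if ids is None:
        ids = [f"m{i + 1}" for i in range(n)]
    grid = np.ones((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            o = overlap_degrees(modules[i], modules[j], method)
            grid[i, j] = o.X_s  # upper: samples
            grid[j, i] = o.X_g  # lower: genes
    return pd.DataFrame(grid, index=list(ids), columns=list(ids))


def write_modules_jsonl(
    modules: Iterable[RegulatoryModule], path: str | Path, header: str | None = None
) -> None:
    with open(path, "w") as fh:
        if header:
            for line in header.splitlines():
                fh.write(f"# {line}\n")
        for m in modules:
            fh.write(
                json.dumps({"genes": sorted(m.gene_set), "samples": sorted(m.sample_set)})
                + "\n"
            )


def read_modules_jsonl(path: str | Path) -> list[RegulatoryModule]:
    out = []
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        d = json.loads(line)
        out.append(
            RegulatoryModule(
                gene_set=frozenset(d["genes"]), sample_set=frozenset(d["samples"])
            )
        )
    return out
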