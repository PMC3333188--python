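"""Windowed order-preserving sequential pattern mining (the SPM-window search).

A pattern is an ordered gene list that re-occurs, rank-wise, across many
samples.  Starting from a reference rank position per sample, each appended
gene must fall inside a search window around the reference: up to ``w_f``
positions ahead (gaps are allowed) or up to ``w_b`` positions behind
(absorbing small rank jitter from measurement noise).  The reference only
advances on forward steps.  A gene list is a pattern when at least ``u``
samples embed it this way and forward steps outnumber backward ones over all
supporting samples.

The search is a depth-first enumeration from every single-gene prefix.
Support is anti-monotone — appending a gene can only shrink the supporting
sample set — so pruning at support < u is exact.  Because each sample sequence
is a permutation, the embedding of a gene list in a sample is unique, and the
per-sample window test doubles as the support computation: the candidate count
over supporting samples *is* the candidate's support.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .exprseq import SequenceDatabase

__all__ = [
    "SearchParams",
    "SequentialPattern",
    "PatternSet",
    "EmbedResult",
    "embed",
    "sp_searching",
    "filter_min_length",
    "summarize_maximal",
    "tabulate_distribution",
    "write_patterns_jsonl",
    "read_patterns_jsonl",
    "is_subsequence",
]


@dataclass(frozen=True)
class SearchParams:
    """Mining thresholds and window sizes.

    u: minimum support (samples), >= 1.
    l: minimum pattern length (genes), >= 2.
    w_f: forward window — how far ahead of the reference rank a gene may sit.
    w_b: backward window — how far behind; 0 disables backward lookup.

    Window bounds are clipped at sequence ends, so any w_f >= n covers the
    whole remaining sequence (the exhaustive "no window" case).
    """

    u: int
    l: int
    w_f: int
    w_b: int = 0

    def __post_init__(self) -> None:
        if self.u < 1:
            raise ValueError("u must be >= 1")
        if self.l < 2:
            raise ValueError("l must be >= 2")
        if self.w_f < 1:
            raise ValueError("w_f must be >= 1")
        if self.w_b < 0:
            raise ValueError("w_b must be >= 0")


@dataclass(frozen=True)
class SequentialPattern:
    """An ordered gene sequence with its supporting samples and step counts."""

    genes: tuple[str, ...]
    samples: frozenset[str]
    forward_steps: int = 0
    backward_steps: int = 0

    def __post_init__(self) -> None:
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("pattern genes must be distinct")
        if not self.samples:
            raise ValueError("pattern must be supported by at least one sample")

    @property
    def length(self) -> int:
        return len(self.genes)

    @property
    def support(self) -> int:
        return len(self.samples)


@dataclass
class PatternSet:
    """Mining result: patterns plus the search-complexity counter.

    ``candidates_evaluated`` counts the candidate extensions whose support was
    computed during the search — the complexity metric used for benchmarking.
    """

    patterns: list[SequentialPattern] = field(default_factory=list)
    params: SearchParams | None = None
    candidates_evaluated: int = 0

    def __len__(self) -> int:
        return len(self.patterns)

    def __iter__(self):
        return iter(self.patterns)

    def key_set(self) -> set[tuple[tuple[str, ...], frozenset[str]]]:
        """(gene sequence, sample set) pairs — the identity used for set equality."""
        return {(p.genes, p.samples) for p in self.patterns}


@dataclass(frozen=True)
class EmbedResult:
    supported: bool
    forward: int
    backward: int


def embed(
    positions: Mapping[str, int],
    genes: Sequence[str],
    w_f: int,
    w_b: int,
) -> EmbedResult:
    """Embed an ordered gene list in one sample's rank sequence.

    ``positions`` maps gene -> 1-based rank.  The reference starts at the
    first gene's rank; each next gene at rank q is in-window iff
    ref - w_b <= q <= ref + w_f (q != ref holds automatically in a
    permutation); the step is forward when q > ref and the reference advances
    to max(ref, q).  Embeddings are unique, so this is a yes/no test, not a
    search.
    """
    if len(genes) < 2:
        raise ValueError("need at least 2 genes to embed")
    try:
        ref = positions[genes[0]]
        forward = backward = 0
        for g in genes[1:]:
            q = positions[g]
            if not (ref - w_b <= q <= ref + w_f) or q == ref:
                return EmbedResult(False, forward, backward)
            if q > ref:
                forward += 1
                ref = q
            else:
                backward += 1
        return EmbedResult(True, forward, backward)
    except KeyError as exc:
        raise KeyError(f"gene {exc.args[0]!r} not present in sample positions") from None


def sp_searching(D: SequenceDatabase, params: SearchParams) -> PatternSet:
    """Depth-first enumeration of all windowed order-preserving patterns.

    Emits every gene sequence of length >= l supported by >= u samples with a
    strict forward-step majority (summed over all steps in all supporting
    samples).  Candidate extensions at each node are the genes falling inside
    some supporting sample's window; a candidate's in-window sample count is
    its exact support, so only candidates reaching count >= u are expanded
    (and counted in ``candidates_evaluated``).  DFS order is deterministic
    (by gene input order), so output order is stable.
    """
    n_s, n_g = D.n_samples, D.n_genes
    result = PatternSet(params=params)
    if params.u > n_s:
        warnings.warn(
            f"minimum support u={params.u} exceeds sample count {n_s}; empty result",
            stacklevel=2,
        )
        return result

    POS = D.positions  # (n_samples, n_genes), 1-based
    u, l, wf, wb = params.u, params.l, params.w_f, params.w_b
    all_samples = np.arange(n_s)
    zeros = np.zeros(n_s, dtype=np.int32)

    # node: (genes tuple of indices, sample indices, refs, fwd/bwd per sample)
    stack: list[tuple[tuple[int, ...], np.ndarray, np.ndarray, np.ndarray, np.ndarray]] = []
    for gi in range(n_g - 1, -1, -1):
        stack.append(((gi,), all_samples, POS[:, gi].astype(np.int64), zeros, zeros))

    emit = result.patterns.append
    gene_ids, sample_ids = D.gene_ids, D.sample_ids
    n_cand = 0
    while stack:
        genes, S, refs, fwd, bwd = stack.pop()
        k = len(genes)
        if k >= l:
            f, b = int(fwd.sum()), int(bwd.sum())
            if f > b:
                emit(
                    SequentialPattern(
                        genes=tuple(gene_ids[g] for g in genes),
                        samples=frozenset(sample_ids[j] for j in S),
                        forward_steps=f,
                        backward_steps=b,
                    )
                )
        sub = POS[S]  # (m, n_g)
        inwin = (sub >= (refs - wb)[:, None]) & (sub <= (refs + wf)[:, None])
        inwin[:, genes] = False
        counts = inwin.sum(axis=0)
        cand = np.flatnonzero(counts >= u)
        n_cand += cand.size
        for gi in cand[::-1]:  # reversed: lowest gene index explored first
            m = inwin[:, gi]
            q = sub[m, gi].astype(np.int64)
            r = refs[m]
            fstep = q > r
            stack.append(
                (
                    genes + (int(gi),),
                    S[m],
                    np.maximum(r, q),
                    fwd[m] + fstep,
                    bwd[m] + ~fstep,
                )
            )
    result.candidates_evaluated = n_cand
    return result


def filter_min_length(P: PatternSet, l: int) -> PatternSet:
    """Keep only patterns with at least ``l`` genes."""
    return PatternSet(
        patterns=[p for p in P.patterns if p.length >= l],
        params=P.params,
        candidates_evaluated=P.candidates_evaluated,
    )


def is_subsequence(short: Sequence[str], long: Sequence[str]) -> bool:
    """True iff ``short`` appears, in order, within ``long`` (gaps allowed)."""
    it = iter(long)
    return all(g in it for g in short)


def summarize_maximal(P: PatternSet) -> PatternSet:
    """Drop patterns enclosed by another pattern.

    A pattern is enclosed when its gene list is an order-preserving
    subsequence of another pattern's genes and its sample set is a subset of
    the other's.  The survivors are pairwise non-enclosing; applying the
    summary twice changes nothing.
    """
    # longer patterns can never be enclosed by shorter ones
    order = sorted(range(len(P.patterns)), key=lambda i: -P.patterns[i].length)
    kept: list[SequentialPattern] = []
    for i in order:
        p = P.patterns[i]
        if not any(
            p.length < q.length  # equal-length distinct sequences never enclose
            and p.samples <= q.samples
            and is_subsequence(p.genes, q.genes)
            for q in kept
        ):
            kept.append(p)
    # restore original order for stable output
    pos = {id(p): i for i, p in enumerate(P.patterns)}
    kept.sort(key=lambda p: pos[id(p)])
    return PatternSet(patterns=kept, params=P.params, candidates_evaluated=P.candidates_evaluated)


def tabulate_distribution(P: PatternSet) -> pd.DataFrame:
    """Cross-tabulate patterns by (length, support), with marginal totals.

    Rows are labelled by support, columns by length; the last row/column hold
    totals.  An empty pattern set yields an empty table with a zero total.
    """
    if not P.patterns:
        return pd.DataFrame(
            [[0]], index=pd.Index(["Total"], name="support"), columns=["Total"]
        )
    df = pd.DataFrame(
        {"length": [p.length for p in P.patterns], "support": [p.support for p in P.patterns]}
    )
    tab = pd.crosstab(df["support"], df["length"], margins=True, margins_name="Total")
    tab.index.name = "support"
    tab.columns.name = "length"
    return tab


def write_patterns_jsonl(
    P: Iterable[SequentialPattern], path: str | Path, header: str | None = None
) -> None:
    """One JSON object per pattern; optional '#' header lines are permitted."""
    with open(path, "w") as fh:
        if header:
            for line in header.splitlines():
                fh.write(f"# {line}\n")
        for p in P:
            fh.write(
                json.dumps(
                    {
                        "genes": list(p.genes),
                        "samples": sorted(p.samples),
                        "length": p.length,
                        "support": p.support,
                        "forward": p.forward_steps,
                        "backward": p.backward_steps,
                    }
                )
                + "\n"
            )


def read_patterns_jsonl(path: str | Path) -> list[SequentialPattern]:
    out = []
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        d = json.loads(line)
        out.append(
            SequentialPattern(
                genes=tuple(d["genes"]),
                samples=frozenset(d["samples"]),
                forward_steps=int(d.get("forward", 0)),
                backward_steps=int(d.get("backward", 0)),
            )
        )
    return out
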