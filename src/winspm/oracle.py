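"""Exhaustive order-preserving sequential pattern mining (SPM-naive).

The no-window search: a gene may be appended anywhere strictly ahead of the
reference, with any gap (equivalent to a backward window of 0 and a forward
window covering the whole sequence).  It enumerates every ordered gene tuple
of length >= l occurring as a gapped subsequence of at least u sample
sequences, so it misses nothing — at exponential cost.  It serves as the
correctness oracle for the windowed miner and as the benchmark baseline.

Implemented as prefix growth with exact anti-monotone support pruning; the
code path is independent of :func:`winspm.mining.sp_searching`.  Its
complexity counter charges one support evaluation per non-member gene at
every search node (the exhaustive candidate policy), which is what makes the
windowed miner's pruning visible in benchmarks.
"""

from __future__ import annotations

import warnings

import numpy as np

from .exprseq import SequenceDatabase
from .mining import PatternSet, SearchParams, SequentialPattern

__all__ = ["naive_spm"]


def naive_spm(D: SequenceDatabase, u: int, l: int) -> PatternSet:
    """Enumerate all gapped-subsequence patterns with support >= u, length >= l.

    Every step is forward by construction, so emitted patterns carry
    forward_steps = (length - 1) * support and no backward steps.
    """
    if u < 1:
        raise ValueError("u must be >= 1")
    if l < 2:
        raise ValueError("l must be >= 2")
    n_s, n_g = D.n_samples, D.n_genes
    params = SearchParams(u=u, l=l, w_f=max(n_g, 1), w_b=0)
    result = PatternSet(params=params)
    if u > n_s:
        warnings.warn(
            f"minimum support u={u} exceeds sample count {n_s}; empty result",
            stacklevel=2,
        )
        return result

    POS = D.positions
    gene_ids, sample_ids = D.gene_ids, D.sample_ids
    all_samples = np.arange(n_s)
    n_cand = 0
    emit = result.patterns.append

    # node: (gene index tuple, supporting sample indices, per-sample reference rank)
    stack: list[tuple[tuple[int, ...], np.ndarray, np.ndarray]] = []
    for gi in range(n_g - 1, -1, -1):
        stack.append(((gi,), all_samples, POS[:, gi].astype(np.int64)))
    while stack:
        genes, S, refs = stack.pop()
        k = len(genes)
        if k >= l:
            emit(
                SequentialPattern(
                    genes=tuple(gene_ids[g] for g in genes),
                    samples=frozenset(sample_ids[j] for j in S),
                    forward_steps=(k - 1) * len(S),
                    backward_steps=0,
                )
            )
        sub = POS[S]
        ahead = sub > refs[:, None]  # strictly forward, any gap
        ahead[:, genes] = False
        counts = ahead.sum(axis=0)
        n_cand += n_g - k  # support computed for every non-member gene
        cand = np.flatnonzero(counts >= u)
        for gi in cand[::-1]:
            m = ahead[:, gi]
            stack.append((genes + (int(gi),), S[m], sub[m, gi].astype(np.int64)))
    result.candidates_evaluated = n_cand
    return result
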