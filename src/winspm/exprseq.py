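"""Expression-matrix input and rank-sequence construction.

The miner does not look at expression values directly: each sample column is
converted into the permutation of all genes sorted by descending magnitude of
differential expression (absolute log-ratio).  This module owns that
transformation and the validated matrix container it starts from.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "SequenceDatabase",
    "read_expression_matrix",
    "read_exclusion_list",
    "to_sequence_db",
]


@dataclass(frozen=True)
class ExpressionMatrix:
    """A gene × sample grid of nonnegative differential-expression magnitudes.

    Values are absolute log-ratios: 0 means no differential expression, larger
    means stronger; only the within-sample ranking of values is ever used
    downstream.
    """

    gene_ids: tuple[str, ...]
    sample_ids: tuple[str, ...]
    values: np.ndarray  # shape (n_genes, n_samples), float64

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", vals)
        if vals.ndim != 2 or vals.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError(
                f"values shape {vals.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        for kind, ids in (("gene", self.gene_ids), ("sample", self.sample_ids)):
            if len(set(ids)) != len(ids):
                raise ValueError(f"duplicate {kind} identifiers")
        if not np.all(np.isfinite(vals)):
            i, j = np.argwhere(~np.isfinite(vals))[0]
            raise ValueError(
                f"non-finite value at gene {self.gene_ids[i]!r}, sample {self.sample_ids[j]!r}"
            )
        if np.any(vals < 0):
            i, j = np.argwhere(vals < 0)[0]
            raise ValueError(
                f"negative value {vals[i, j]} at gene {self.gene_ids[i]!r}, "
                f"sample {self.sample_ids[j]!r}; expected absolute log-ratios"
            )

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=list(self.gene_ids), columns=list(self.sample_ids)
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ExpressionMatrix":
        return cls(tuple(map(str, df.index)), tuple(map(str, df.columns)), df.to_numpy(float))

    def drop_genes(self, exclude: Iterable[str]) -> "ExpressionMatrix":
        """Remove the listed genes; unknown IDs raise a warning, not an error."""
        excl = set(exclude)
        missing = excl - set(self.gene_ids)
        if missing:
            warnings.warn(
                f"{len(missing)} exclusion ID(s) absent from matrix: "
                + ", ".join(sorted(missing)[:5]),
                stacklevel=2,
            )
        keep = [i for i, g in enumerate(self.gene_ids) if g not in excl]
        return ExpressionMatrix(
            tuple(self.gene_ids[i] for i in keep), self.sample_ids, self.values[keep]
        )


@dataclass(frozen=True)
class SequenceDatabase:
    """Per-sample permutations of all genes, ranked by descending expression.

    ``sequences[j]`` holds gene *indices* (into ``gene_ids``) in rank order;
    ``positions[j, g]`` is the 1-based rank of gene ``g`` in sample ``j``
    (1 = most differentially expressed), the exact inverse of ``sequences[j]``.
    """

    gene_ids: tuple[str, ...]
    sample_ids: tuple[str, ...]
    sequences: np.ndarray  # (n_samples, n_genes) int32 gene indices
    positions: np.ndarray  # (n_samples, n_genes) int32 1-based ranks

    def __post_init__(self) -> None:
        n_s, n_g = len(self.sample_ids), len(self.gene_ids)
        if self.sequences.shape != (n_s, n_g) or self.positions.shape != (n_s, n_g):
            raise ValueError("sequence/position arrays do not match ID counts")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def sequence_ids(self, j: int) -> tuple[str, ...]:
        """Gene IDs of sample ``j`` in rank order."""
        return tuple(self.gene_ids[g] for g in self.sequences[j])

    def position_map(self, j: int) -> dict[str, int]:
        """Gene ID -> 1-based rank for sample ``j``."""
        return {self.gene_ids[g]: int(self.positions[j, g]) for g in range(self.n_genes)}


def read_exclusion_list(path: str | Path) -> list[str]:
    """One gene ID per line; blank lines and '#' comments ignored."""
    out: list[str] = []
    for line in Path(path).read_text().splitlines():
        line = line.split("#", 1)[0].strip()
        if line:
            out.append(line)
    return out


def read_expression_matrix(
    path: str | Path, exclude: Sequence[str] | None = None
) -> ExpressionMatrix:
    """Read a TSV expression matrix (header: gene_id + sample IDs).

    Raises on duplicate identifiers and on negative or non-numeric cells,
    naming the offending coordinates.  ``exclude`` removes genes by ID after
    reading; IDs absent from the matrix only warn.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#", dtype=str)
    gene_ids = tuple(map(str, df.index))
    sample_ids = tuple(map(str, df.columns))
    try:
        values = df.to_numpy(dtype=float)
    except ValueError:
        # locate the first offending cell for the error message
        for i, g in enumerate(gene_ids):
            for j, s in enumerate(sample_ids):
                try:
                    float(df.iat[i, j])
                except (TypeError, ValueError):
                    raise ValueError(
                        f"non-numeric value {df.iat[i, j]!r} at gene {g!r}, sample {s!r}"
                    ) from None
        raise
    mat = ExpressionMatrix(gene_ids, sample_ids, values)
    if exclude:
        mat = mat.drop_genes(exclude)
    return mat


def to_sequence_db(
    E: ExpressionMatrix, tie_rule: str = "stable_by_input_order"
) -> SequenceDatabase:
    """Sort each sample's genes by strictly descending expression value.

    Ties are broken by input gene order (the only supported ``tie_rule``),
    making the result deterministic.  Only the ranking matters downstream, so
    the output is invariant under any strictly increasing transform of the
    values.
    """
    if tie_rule != "stable_by_input_order":
        raise ValueError(f"unknown tie_rule {tie_rule!r}")
    # stable argsort of -values keeps input order among equal values
    sequences = np.argsort(-E.values.T, axis=1, kind="stable").astype(np.int32)
    positions = np.empty_like(sequences)
    n_g = E.n_genes
    ranks = np.arange(1, n_g + 1, dtype=np.int32)
    for j in range(E.n_samples):
        positions[j, sequences[j]] = ranks
    return SequenceDatabase(E.gene_ids, E.sample_ids, sequences, positions)
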