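import numpy as np
import pytest

from winspm import ExpressionMatrix, to_sequence_db


def make_matrix(values, gene_ids=None, sample_ids=None) -> ExpressionMatrix:
    values = np.asarray(values, dtype=float)
    n_g, n_s = values.shape
    return ExpressionMatrix(
        tuple(gene_ids) if gene_ids else tuple(f"g{i + 1}" for i in range(n_g)),
        tuple(sample_ids) if sample_ids else tuple(f"s{j + 1}" for j in range(n_s)),
        values,
    )


def random_db(rng, n_genes, n_samples):
    """Sequence database from a random matrix (distinct values, no ties)."""
    return to_sequence_db(make_matrix(rng.random((n_genes, n_samples))))


@pytest.fixture
def identical_db():
    """Four samples, all ranking g1 > g2 > g3 > g4."""
    vals = np.tile(np.array([4.0, 3.0, 2.0, 1.0])[:, None], (1, 4))
    return to_sequence_db(make_matrix(vals, sample_ids=("a", "b", "c", "d")))


@pytest.fixture
def toy_tsv(tmp_path):
    p = tmp_path / "matrix.tsv"
    p.write_text(
        "gene_id\ts1\ts2\n"
        "g1\t0.5\t1.0\n"
        "g2\t2.0\t0.0\n"
        "g3\t1.0\t3.0\n"
    )
    return p
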