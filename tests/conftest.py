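import pandas as pd
import pytest

from reopair import reo


@pytest.fixture
def toy_labeled_matrix():
    """3 genes x 6 samples with a hand-built perfect reversal of (A, B)."""
    values = pd.DataFrame(
        {
            "T1": [5.0, 1.0, 3.0],
            "T2": [6.0, 2.0, 3.0],
            "T3": [4.0, 3.0, 3.0],
            "N1": [1.0, 5.0, 3.0],
            "N2": [2.0, 6.0, 3.0],
            "N3": [0.5, 4.0, 3.0],
        },
        index=["A", "B", "C"],
    )
    labels = pd.Series(
        ["tumor"] * 3 + ["normal"] * 3, index=values.columns, name="label"
    )
    return reo.LabeledExpressionMatrix(values=values, labels=labels)


def random_labeled_matrix(rng, n_genes, n_samples, tie_prone=False):
    """Random matrix for oracle-equivalence sweeps; integer grids force ties."""
    if tie_prone:
        vals = rng.integers(0, 4, size=(n_genes, n_samples)).astype(float)
    else:
        vals = rng.normal(size=(n_genes, n_samples))
    genes = [f"g{i}" for i in range(n_genes)]
    n_tumor = n_samples // 2
    samples = [f"s{i}" for i in range(n_samples)]
    values = pd.DataFrame(vals, index=genes, columns=samples)
    labels = pd.Series(
        ["tumor"] * n_tumor + ["normal"] * (n_samples - n_tumor),
        index=samples,
        name="label",
    )
    return reo.LabeledExpressionMatrix(values=values, labels=labels)
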