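import numpy as np
import pandas as pd
import pytest

from irondelta import CountMatrix


def make_count_matrix(counts, n_reps=None, lengths=None):
    """CountMatrix from a raw array, with a standard 2x2xN sample layout.

    Columns are ordered wildtype_plusFe, wildtype_minusFe, clf_plusFe,
    clf_minusFe, each block ``n_reps`` wide.
    """
    counts = np.asarray(counts)
    n_samples = counts.shape[1]
    if n_reps is None:
        assert n_samples % 4 == 0
        n_reps = n_samples // 4
    rows = []
    for g in ("wildtype", "clf"):
        for c in ("plusFe", "minusFe"):
            for r in range(n_reps):
                rows.append(
                    {
                        "sample_id": f"{g}_{c}_r{r + 1}",
                        "genotype": g,
                        "condition": c,
                        "replicate": r + 1,
                    }
                )
    samples = pd.DataFrame(rows[:n_samples])
    genes = [f"g{i}" for i in range(counts.shape[0])]
    if lengths is None:
        lengths = np.full(counts.shape[0], 1000)
    return CountMatrix(genes=genes, lengths_bp=lengths, samples=samples, counts=counts)


@pytest.fixture
def two_sample_matrix():
    """5 genes x 2 samples (two +Fe wildtype replicates)."""

    def build(counts):
        counts = np.asarray(counts)
        samples = pd.DataFrame(
            {
                "sample_id": ["A", "B"],
                "genotype": ["wildtype", "wildtype"],
                "condition": ["plusFe", "plusFe"],
                "replicate": [1, 2],
            }
        )
        genes = [f"g{i}" for i in range(counts.shape[0])]
        return CountMatrix(
            genes=genes,
            lengths_bp=np.full(counts.shape[0], 1000),
            samples=samples,
            counts=counts,
        )

    return build
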