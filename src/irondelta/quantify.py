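"""Normalization, FPKM and per-genotype -Fe vs +Fe fold changes.

Fold changes are the coordinates of the clf-vs-wildtype log2 fold-change
plane: for each genotype the ratio of mean normalized counts under iron
deficiency to iron sufficiency, with a symmetric pseudocount keeping
ratios finite on zero counts. ``delta = lfc_clf - lfc_wt`` measures how
much more strongly a gene is induced in the *clf* mutant; genes with
delta > 0 lie above the y = x diagonal.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .simulate import GENOTYPES, CONDITIONS, CountMatrix


def size_factors(counts: CountMatrix) -> np.ndarray:
    """Median-of-ratios size factors, normalized to geometric mean 1.

    Genes with a zero count in any sample (geometric mean 0) are excluded
    from the per-sample median, as in the DESeq convention.
    """
    c = counts.counts.astype(float)
    positive = (c > 0).all(axis=1)
    if not positive.any():
        raise ValueError("no gene with positive counts in every sample")
    logc = np.log(c[positive])
    log_geomean = logc.mean(axis=1)
    log_sf = np.median(logc - log_geomean[:, None], axis=0)
    log_sf -= log_sf.mean()  # geometric mean of factors = 1
    return np.exp(log_sf)


def fpkm(counts: CountMatrix) -> pd.DataFrame:
    """Fragments per kilobase of transcript per million sequenced fragments.

    fpkm(g, s) = count(g, s) * 1e9 / (length_bp(g) * total_counts(s)),
    with total counts taken from the raw matrix.
    """
    totals = counts.counts.sum(axis=0).astype(float)
    if (totals == 0).any():
        zero = counts.samples["sample_id"][totals == 0].tolist()
        raise ValueError(f"zero library total in sample(s): {zero}")
    vals = counts.counts * 1e9 / (counts.lengths_bp[:, None] * totals[None, :])
    return pd.DataFrame(vals, index=counts.genes, columns=counts.samples["sample_id"].tolist())


def normalized_counts(counts: CountMatrix) -> pd.DataFrame:
    """Counts divided by median-of-ratios size factors."""
    sf = size_factors(counts)
    return pd.DataFrame(
        counts.counts / sf[None, :],
        index=counts.genes,
        columns=counts.samples["sample_id"].tolist(),
    )


def _condition_means(
    mat: np.ndarray, counts: CountMatrix, genotype: str
) -> tuple[np.ndarray, np.ndarray]:
    means = []
    for cond in CONDITIONS:
        mask = counts.sample_mask(genotype, cond)
        if not mask.any():
            raise ValueError(f"missing design cell: ({genotype}, {cond})")
        means.append(mat[:, mask].mean(axis=1))
    plus, minus = means
    return minus, plus


def fold_changes(
    counts: CountMatrix, pseudocount: float = 0.5, use_fpkm: bool = False
) -> pd.DataFrame:
    """Per-gene -Fe/+Fe fold changes and log2 fold changes per genotype.

    For each genotype, fc = (mean normalized -Fe + pseudocount) /
    (mean normalized +Fe + pseudocount), means over replicates. Returns a
    DataFrame with columns gene_id, fc_wt, fc_clf, lfc_wt, lfc_clf, delta
    where lfc = log2(fc) and delta = lfc_clf - lfc_wt.
    """
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0")
    mat = (fpkm(counts) if use_fpkm else normalized_counts(counts)).to_numpy()
    out = {"gene_id": counts.genes}
    for geno, tag in zip(GENOTYPES, ("wt", "clf")):
        minus, plus = _condition_means(mat, counts, geno)
        fc = (minus + pseudocount) / (plus + pseudocount)
        out[f"fc_{tag}"] = fc
        out[f"lfc_{tag}"] = np.log2(fc)
    df = pd.DataFrame(out)
    df["delta"] = df["lfc_clf"] - df["lfc_wt"]
    return df
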