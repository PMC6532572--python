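"""Simplified negative-binomial differential-induction calling.

Per genotype, each gene is tested for -Fe vs +Fe differential expression
with a method-of-moments NB Wald test and Benjamini-Hochberg FDR control
at padj < 0.05. This is deliberately not a DESeq re-implementation: there
is no dispersion shrinkage across genes, no outlier filtering and no
independent filtering. It exists so synthetic pipelines run end to end
with the same decision rule (NB p-values, BH, padj threshold, sign
post-filter) as the published analysis.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .quantify import normalized_counts
from .simulate import CONDITIONS, CountMatrix

DISPERSION_FLOOR = 1e-8
LN2 = np.log(2.0)


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any() or not np.isfinite(p).all():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def nb_wald_test(
    counts: CountMatrix,
    genotype: str,
    pseudocount: float = 0.5,
    threshold: float = 0.05,
) -> pd.DataFrame:
    """Per-gene NB Wald test of -Fe vs +Fe within one genotype.

    Dispersion is estimated per gene by method of moments, pooled across
    the two conditions and floored at 1e-8; the per-condition variance of
    the mean is floored at the Poisson bound. The Wald statistic is
    lfc / SE(lfc) with a delta-method standard error on the log2 scale and
    a two-sided standard-normal p-value.

    Returns a DataFrame with columns gene_id, genotype, base_mean, lfc,
    p_value, padj, significant_up.
    """
    norm = normalized_counts(counts).to_numpy()
    groups = []
    for cond in CONDITIONS:
        mask = counts.sample_mask(genotype, cond)
        if mask.sum() < 2:
            raise ValueError(
                f"need >=2 replicates in ({genotype}, {cond}) to estimate variance"
            )
        groups.append(norm[:, mask])
    plus, minus = groups

    mus, var_of_mean = [], []
    alpha_terms = []
    for grp in (plus, minus):
        mu = grp.mean(axis=1)
        v = grp.var(axis=1, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            a = np.where(mu > 0, (v - mu) / np.maximum(mu, 1e-300) ** 2, 0.0)
        alpha_terms.append(a)
        mus.append(mu)
    alpha = np.maximum(np.mean(alpha_terms, axis=0), DISPERSION_FLOOR)

    for grp, mu in zip((plus, minus), mus):
        n = grp.shape[1]
        v_count = np.maximum(mu + alpha * mu**2, mu)  # floor at Poisson bound
        var_of_mean.append(v_count / n)
    v_plus, v_minus = var_of_mean
    mu_plus, mu_minus = mus

    lfc = np.log2(mu_minus + pseudocount) - np.log2(mu_plus + pseudocount)
    # delta method: var(log2 m) ~= var(m) / ((m + pc) * ln 2)^2
    se = np.sqrt(
        v_minus / ((mu_minus + pseudocount) * LN2) ** 2
        + v_plus / ((mu_plus + pseudocount) * LN2) ** 2
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, lfc / np.where(se > 0, se, 1.0), 0.0)
    p = 2.0 * stats.norm.sf(np.abs(z))
    p = np.minimum(p, 1.0)

    padj = bh_adjust(p)
    df = pd.DataFrame(
        {
            "gene_id": counts.genes,
            "genotype": genotype,
            "base_mean": np.concatenate([plus, minus], axis=1).mean(axis=1),
            "lfc": lfc,
            "p_value": p,
            "padj": padj,
        }
    )
    df["significant_up"] = (df["padj"] < threshold) & (df["lfc"] > 0)
    return df


def call_iron_regulated(
    records: pd.DataFrame, threshold: float = 0.05, direction: str = "up"
) -> list[str]:
    """Genes with padj < threshold and the requested lfc sign, sorted by id."""
    if direction not in ("up", "down"):
        raise ValueError("direction must be 'up' or 'down'")
    sign_ok = records["lfc"] > 0 if direction == "up" else records["lfc"] < 0
    hits = records.loc[(records["padj"] < threshold) & sign_ok, "gene_id"]
    return sorted(hits.tolist())
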