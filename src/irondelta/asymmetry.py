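"""Gene-set fold-change asymmetry test.

The central question: are FIT-dependent iron acquisition genes
disproportionately *more* induced by iron deficiency in the *clf* mutant
than in wild type, relative to PYE-dependent genes? Each gene contributes
``delta = lfc_clf - lfc_wt``; a gene with delta > 0 lies above the y = x
diagonal of the clf-vs-wildtype log2 fold-change plane. The test statistic
is the proportion of focal-set genes above the diagonal; its null
distribution is obtained by randomly reassigning the focal/comparator
labels within the pooled gene set (set sizes preserved), which is the
minimal exchangeability null for the claim "more induced than the
comparator set". A Mann-Whitney U test on the deltas themselves provides
a companion rank-based comparison of the induction differences.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy import stats


@dataclass(frozen=True)
class AsymmetryResult:
    """Observed proportions, randomization p and Mann-Whitney companion."""

    p_obs_focal: float
    p_obs_comparator: float
    diff_obs: float
    p_randomization: float
    n_perm: int
    mw_u: float
    mw_p: float
    alternative: str
    seed: int

    def to_dict(self) -> dict:
        return asdict(self)


def _set_deltas(deltas: pd.Series, gene_set) -> np.ndarray:
    gene_set = list(gene_set)
    missing = [g for g in gene_set if g not in deltas.index]
    if missing:
        raise KeyError(f"gene(s) missing from delta table: {missing}")
    return deltas.loc[gene_set].to_numpy(dtype=float)


def proportion_above_diagonal(deltas: pd.Series, gene_set) -> float:
    """Fraction of set genes with delta strictly > 0; ties count as not-above."""
    vals = _set_deltas(deltas, gene_set)
    if vals.size == 0:
        raise ValueError("empty gene set")
    return float((vals > 0).mean())


def mann_whitney(
    deltas_focal, deltas_comparator, alternative: str = "greater"
) -> tuple[float, float]:
    """Mann-Whitney U of focal vs comparator values.

    U counts pairs with focal > comparator plus half the ties (midrank
    convention). The p-value is exact (full U distribution) when
    n_focal * n_comparator <= 400 and there are no ties, otherwise the
    normal approximation with tie-corrected variance and continuity
    correction is used.
    """
    x = np.asarray(deltas_focal, dtype=float)
    y = np.asarray(deltas_comparator, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    if alternative not in ("greater", "two-sided"):
        raise ValueError("alternative must be 'greater' or 'two-sided'")

    ranks = stats.rankdata(np.concatenate([x, y]))
    u = float(ranks[: x.size].sum() - x.size * (x.size + 1) / 2.0)

    has_ties = np.unique(np.concatenate([x, y])).size < x.size + y.size
    method = "exact" if (x.size * y.size <= 400 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(
        x, y, alternative=alternative, method=method, use_continuity=True
    )
    return u, float(res.pvalue)


def randomization_test(
    deltas: pd.Series,
    focal_set,
    comparator_set,
    n_perm: int = 10000,
    seed: int = 0,
    alternative: str = "greater",
) -> AsymmetryResult:
    """Label-permutation test of the above-diagonal proportion.

    The focal and comparator sets are pooled; each of ``n_perm``
    permutations reassigns |focal| labels uniformly at random without
    replacement and records the proportion of permuted-focal genes with
    delta > 0. The one-sided p-value uses the add-one rule
    ``(1 + #{null >= observed}) / (1 + n_perm)`` and therefore never
    returns 0; the two-sided p doubles the smaller tail, capped at 1.
    Deterministic given ``seed``. Also runs the Mann-Whitney comparison
    of the two sets' deltas with the same alternative.
    """
    focal = list(focal_set)
    comparator = list(comparator_set)
    if not focal or not comparator:
        raise ValueError("focal and comparator sets must be non-empty")
    overlap = set(focal) & set(comparator)
    if overlap:
        raise ValueError(f"focal and comparator sets overlap: {sorted(overlap)}")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if alternative not in ("greater", "two-sided"):
        raise ValueError("alternative must be 'greater' or 'two-sided'")

    d_focal = _set_deltas(deltas, focal)
    d_comp = _set_deltas(deltas, comparator)
    p_obs_focal = float((d_focal > 0).mean())
    p_obs_comp = float((d_comp > 0).mean())

    above = np.concatenate([d_focal > 0, d_comp > 0]).astype(float)
    n_focal, n_pool = len(focal), above.size

    rng = np.random.default_rng(seed)
    # vectorized label permutations: first n_focal entries of each shuffled row
    order = np.argsort(rng.random((n_perm, n_pool)), axis=1)[:, :n_focal]
    null = above[order].mean(axis=1)

    p_greater = (1.0 + np.count_nonzero(null >= p_obs_focal)) / (1.0 + n_perm)
    if alternative == "greater":
        p_rand = p_greater
    else:
        p_less = (1.0 + np.count_nonzero(null <= p_obs_focal)) / (1.0 + n_perm)
        p_rand = min(1.0, 2.0 * min(p_greater, p_less))

    mw_u, mw_p = mann_whitney(d_focal, d_comp, alternative=alternative)
    return AsymmetryResult(
        p_obs_focal=p_obs_focal,
        p_obs_comparator=p_obs_comp,
        diff_obs=p_obs_focal - p_obs_comp,
        p_randomization=float(p_rand),
        n_perm=n_perm,
        mw_u=mw_u,
        mw_p=mw_p,
        alternative=alternative,
        seed=seed,
    )


def export_scatter_table(fc: pd.DataFrame, gene_sets: dict[str, list[str]]) -> pd.DataFrame:
    """Tidy (gene_id, set, lfc_wt, lfc_clf, delta) table for the scatter plot."""
    rows = []
    fc_idx = fc.set_index("gene_id")
    for name, genes in gene_sets.items():
        missing = [g for g in genes if g not in fc_idx.index]
        if missing:
            raise KeyError(f"gene(s) missing from fold-change table: {missing}")
        for g in genes:
            r = fc_idx.loc[g]
            rows.append(
                {
                    "gene_id": g,
                    "set": name,
                    "lfc_wt": r["lfc_wt"],
                    "lfc_clf": r["lfc_clf"],
                    "delta": r["delta"],
                }
            )
    return pd.DataFrame(rows, columns=["gene_id", "set", "lfc_wt", "lfc_clf", "delta"])


def export_density_table(fc: pd.DataFrame, gene_sets: dict[str, list[str]]) -> pd.DataFrame:
    """Per-set delta histogram with Freedman-Diaconis binning.

    Returns a tidy table (set, bin_left, bin_right, count); bin counts sum
    to the set size. Sets smaller than 2 genes fall back to a single bin.
    """
    scatter = export_scatter_table(fc, gene_sets)
    rows = []
    for name, grp in scatter.groupby("set", sort=False):
        vals = grp["delta"].to_numpy()
        if vals.size >= 2 and np.ptp(vals) > 0:
            edges = np.histogram_bin_edges(vals, bins="fd")
        else:
            edges = np.array([vals.min() - 0.5, vals.max() + 0.5]) if vals.size else np.array([0.0, 1.0])
        hist, edges = np.histogram(vals, bins=edges)
        for c, lo, hi in zip(hist, edges[:-1], edges[1:]):
            rows.append({"set": name, "bin_left": lo, "bin_right": hi, "count": int(c)})
    return pd.DataFrame(rows, columns=["set", "bin_left", "bin_right", "count"])
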