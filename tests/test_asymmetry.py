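"""Above-diagonal proportion, randomization null, Mann-Whitney."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from irondelta import (
    export_density_table,
    export_scatter_table,
    mann_whitney,
    proportion_above_diagonal,
    randomization_test,
)


def series(vals, prefix="g"):
    return pd.Series(vals, index=[f"{prefix}{i}" for i in range(len(vals))])


def exact_tail(above, n_focal, observed):
    """Exhaustive label-assignment oracle for the randomization null."""
    idx = range(len(above))
    stats = [
        np.mean([above[i] for i in sel])
        for sel in itertools.combinations(idx, n_focal)
    ]
    return np.mean([s >= observed for s in stats])


class TestProportion:
    def test_printed_fit_pairs_all_lie_above_diagonal(self):
        wt = np.log2([3.9, 13.7, 11.3])
        clf = np.log2([5.0, 40.8, 22.4])
        deltas = series(clf - wt)
        assert proportion_above_diagonal(deltas, deltas.index) == 1.0

    def test_ties_count_as_not_above(self):
        deltas = series([1.0, -2.0, 0.0, 3.0])
        assert proportion_above_diagonal(deltas, deltas.index) == 0.5

    def test_missing_gene_named_in_error(self):
        deltas = series([1.0, 2.0])
        with pytest.raises(KeyError, match="ghost"):
            proportion_above_diagonal(deltas, ["g0", "ghost"])


class TestMannWhitney:
    def test_complete_separation_exact(self):
        u, p = mann_whitney([4, 5, 6], [1, 2, 3], alternative="greater")
        assert u == 9.0
        assert p == pytest.approx(1 / math.comb(6, 3))  # 0.05

    def test_identical_samples_are_null(self):
        u, p = mann_whitney([1, 2, 3], [1, 2, 3], alternative="two-sided")
        assert u == 4.5  # n^2 / 2 with midrank ties
        assert p == pytest.approx(1.0)

    def test_u_matches_brute_force_pair_count(self):
        rng = np.random.default_rng(12)
        for _ in range(100):
            x = rng.integers(0, 10, size=8).astype(float)
            y = rng.integers(0, 10, size=8).astype(float)
            u, _ = mann_whitney(x, y)
            brute = sum(
                1.0 if xi > yj else 0.5 if xi == yj else 0.0
                for xi in x for yj in y
            )
            assert u == brute

    def test_matches_scipy_u_statistic(self):
        from scipy.stats import mannwhitneyu

        rng = np.random.default_rng(3)
        x, y = rng.normal(size=30), rng.normal(size=25)
        u, p = mann_whitney(x, y, alternative="greater")
        ref = mannwhitneyu(x, y, alternative="greater")
        assert u == pytest.approx(ref.statistic)
        assert p == pytest.approx(ref.pvalue)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney([], [1.0])


class TestRandomization:
    def test_exhaustive_enumeration_oracle_small_pools(self):
        # Monte-Carlo p at n_perm=1e5 vs the full C(n, k) enumeration
        rng = np.random.default_rng(0)
        n_perm = 100_000
        for n_focal, n_comp in [(2, 2), (3, 4), (5, 5), (6, 6)]:
            deltas = series(rng.normal(size=n_focal + n_comp))
            focal = list(deltas.index[:n_focal])
            comp = list(deltas.index[n_focal:])
            res = randomization_test(deltas, focal, comp, n_perm=n_perm, seed=5)
            above = (deltas.to_numpy() > 0).astype(float)
            tail = exact_tail(above, n_focal, res.p_obs_focal)
            expected = (1 + n_perm * tail) / (1 + n_perm)
            se = math.sqrt(max(tail * (1 - tail), 1e-12) / n_perm)
            assert abs(res.p_randomization - expected) <= 3 * se + 2 / n_perm

    def test_zero_observed_proportion_gives_p_one(self):
        deltas = series([-1.0, -2.0, 3.0, 4.0])
        res = randomization_test(deltas, ["g0", "g1"], ["g2", "g3"], n_perm=500, seed=1)
        assert res.p_obs_focal == 0.0
        assert res.p_randomization == 1.0

    def test_seeded_determinism(self):
        rng = np.random.default_rng(9)
        deltas = series(rng.normal(size=40))
        f, c = list(deltas.index[:20]), list(deltas.index[20:])
        a = randomization_test(deltas, f, c, n_perm=2000, seed=42)
        b = randomization_test(deltas, f, c, n_perm=2000, seed=42)
        assert a == b

    def test_invariant_to_strictly_monotone_delta_transform(self):
        rng = np.random.default_rng(10)
        deltas = series(rng.normal(size=30))
        f, c = list(deltas.index[:15]), list(deltas.index[15:])
        base = randomization_test(deltas, f, c, n_perm=1000, seed=7)
        for transform in (lambda d: d**3, lambda d: 2 * d, np.arcsinh):
            res = randomization_test(transform(deltas), f, c, n_perm=1000, seed=7)
            assert res.p_randomization == base.p_randomization
            assert res.p_obs_focal == base.p_obs_focal
            assert res.mw_u == base.mw_u  # ranks preserved

    def test_add_one_rule_lower_bound(self):
        deltas = series([5.0, 4.0, -1.0, -2.0])
        res = randomization_test(deltas, ["g0", "g1"], ["g2", "g3"], n_perm=999, seed=0)
        assert res.p_randomization >= 1 / (999 + 1)

    def test_overlapping_or_empty_sets_rejected(self):
        deltas = series([1.0, 2.0, 3.0])
        with pytest.raises(ValueError, match="overlap"):
            randomization_test(deltas, ["g0", "g1"], ["g1", "g2"], seed=0)
        with pytest.raises(ValueError, match="non-empty"):
            randomization_test(deltas, [], ["g1"], seed=0)

    @settings(deadline=None, max_examples=20, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_two_sided_p_at_least_one_sided(self, seed):
        rng = np.random.default_rng(seed)
        deltas = series(rng.normal(size=20))
        f, c = list(deltas.index[:10]), list(deltas.index[10:])
        one = randomization_test(deltas, f, c, n_perm=400, seed=seed % 1000)
        two = randomization_test(
            deltas, f, c, n_perm=400, seed=seed % 1000, alternative="two-sided"
        )
        # two-sided doubles the smaller tail, so it is capped at 1 and can
        # never exceed twice the one-sided (greater) p
        assert two.p_randomization <= 1.0
        assert two.p_randomization <= 2 * one.p_randomization + 1e-12


class TestExportTables:
    @staticmethod
    def fc_from_pairs():
        wt = [3.9, 13.7, 11.3, 4.9, 5.9, 17.5]
        clf = [5.0, 40.8, 22.4, 4.6, 5.7, 16.4]
        genes = ["FIT", "FRO2", "IRT1", "PYE", "BTS", "FRO3"]
        fc = pd.DataFrame({"gene_id": genes, "fc_wt": wt, "fc_clf": clf})
        fc["lfc_wt"] = np.log2(fc["fc_wt"])
        fc["lfc_clf"] = np.log2(fc["fc_clf"])
        fc["delta"] = fc["lfc_clf"] - fc["lfc_wt"]
        return fc

    def test_scatter_table_matches_log2_inputs(self):
        fc = self.fc_from_pairs()
        sets = {"FIT": ["FIT", "FRO2", "IRT1"], "PYE": ["PYE", "BTS", "FRO3"]}
        scatter = export_scatter_table(fc, sets)
        assert len(scatter) == 6
        row = scatter.set_index("gene_id").loc["FRO2"]
        assert row["lfc_wt"] == pytest.approx(np.log2(13.7))
        assert row["lfc_clf"] == pytest.approx(np.log2(40.8))

    def test_histogram_counts_sum_to_set_sizes(self):
        rng = np.random.default_rng(2)
        genes = [f"g{i}" for i in range(40)]
        fc = pd.DataFrame(
            {
                "gene_id": genes,
                "fc_wt": np.exp(rng.normal(size=40)),
                "fc_clf": np.exp(rng.normal(size=40)),
            }
        )
        fc["lfc_wt"] = np.log2(fc["fc_wt"])
        fc["lfc_clf"] = np.log2(fc["fc_clf"])
        fc["delta"] = fc["lfc_clf"] - fc["lfc_wt"]
        sets = {"A": genes[:25], "B": genes[25:]}
        dens = export_density_table(fc, sets)
        sums = dens.groupby("set")["count"].sum()
        assert sums["A"] == 25 and sums["B"] == 15

    def test_empty_sets_preserve_headers(self):
        fc = self.fc_from_pairs()
        scatter = export_scatter_table(fc, {})
        dens = export_density_table(fc, {})
        assert list(scatter.columns) == ["gene_id", "set", "lfc_wt", "lfc_clf", "delta"]
        assert list(dens.columns) == ["set", "bin_left", "bin_right", "count"]
        assert scatter.empty and dens.empty
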