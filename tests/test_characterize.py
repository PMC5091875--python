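import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.stats import hypergeom

import coca

from conftest import make_platform


def expand(counts):
    """Turn a {group: {level: n}} count table into per-sample series."""
    labels, levels, idx = [], [], []
    i = 0
    for g, level_counts in counts.items():
        for lvl, n in level_counts.items():
            for _ in range(n):
                idx.append(f"s{i}")
                labels.append(g)
                levels.append(lvl)
                i += 1
    return pd.Series(labels, index=idx), pd.Series(levels, index=idx)


def fisher_2x2_enumeration(table):
    """Exact two-sided Fisher p by enumerating all tables with the given
    margins and summing hypergeometric probabilities <= the observed one."""
    (a, b), (c, d) = table
    row1, col1, n = a + b, a + c, a + b + c + d
    p_obs = hypergeom.pmf(a, n, col1, row1)
    total = 0.0
    for x in range(max(0, row1 + col1 - n), min(row1, col1) + 1):
        p = hypergeom.pmf(x, n, col1, row1)
        if p <= p_obs * (1 + 1e-9):
            total += p
    return total


class TestAssociationTest:
    def test_tp53_style_contingency_matches_enumeration_oracle(self):
        # mutated/wild counts: 16/7 in the focus subgroup, 39/123 elsewhere
        lab, cov = expand({"S1": {"mut": 16, "wt": 7}, "rest": {"mut": 39, "wt": 123}})
        res = coca.association_test(lab, cov, test="fisher", name="TP53")
        table = res.contingency.loc[["S1", "rest"], ["mut", "wt"]].to_numpy()
        assert table.tolist() == [[16, 7], [39, 123]]
        assert res.p_value == pytest.approx(fisher_2x2_enumeration(table), rel=1e-9)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_random_2x2_tables_match_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        counts = {g: {"x": int(rng.integers(1, 30)), "y": int(rng.integers(1, 30))}
                  for g in ("A", "B")}
        lab, cov = expand(counts)
        res = coca.association_test(lab, cov, test="fisher")
        assert res.p_value == pytest.approx(
            fisher_2x2_enumeration(res.contingency.to_numpy()), rel=1e-9
        )

    def test_proportional_rows_give_p_one(self):
        lab, cov = expand({"A": {"x": 10, "y": 20}, "B": {"x": 5, "y": 10}})
        res = coca.association_test(lab, cov, test="fisher")
        assert res.p_value == pytest.approx(1.0)

    def test_single_level_covariate_rejected(self):
        lab, cov = expand({"A": {"x": 5}, "B": {"x": 5}})
        with pytest.raises(ValueError, match="single level"):
            coca.association_test(lab, cov)

    def test_p_invariant_to_row_and_column_permutation(self):
        lab, cov = expand({"A": {"x": 12, "y": 3}, "B": {"x": 4, "y": 11}})
        base = coca.association_test(lab, cov, test="fisher").p_value
        flipped_rows = coca.association_test(
            lab.map({"A": "B", "B": "A"}), cov, test="fisher").p_value
        flipped_cols = coca.association_test(
            lab, cov.map({"x": "y", "y": "x"}), test="fisher").p_value
        assert flipped_rows == pytest.approx(base)
        assert flipped_cols == pytest.approx(base)

    def test_rxc_fisher_uses_seeded_monte_carlo(self):
        rng = np.random.default_rng(3)
        lab = pd.Series(rng.integers(0, 3, 90).astype(str), index=[f"s{i}" for i in range(90)])
        cov = pd.Series(np.where(rng.random(90) < 0.4, "x", "y"), index=lab.index)
        a = coca.association_test(lab, cov, test="fisher", seed=5, n_simulations=2000)
        b = coca.association_test(lab, cov, test="fisher", seed=5, n_simulations=2000)
        assert a.p_value == b.p_value
        chi = coca.association_test(lab, cov, test="chi_square").p_value
        assert abs(a.p_value - chi) < 0.1  # same null, different approximations

    def test_strong_rxc_association_detected(self):
        lab, cov = expand({
            "A": {"x": 25, "y": 2}, "B": {"x": 3, "y": 24}, "C": {"x": 14, "y": 13},
        })
        res = coca.association_test(lab, cov, test="fisher", seed=1, n_simulations=3000)
        assert res.p_value < 0.01


class TestSubgroupProportions:
    GENDER = {
        "S1": {"Female": 2, "Male": 14}, "S2": {"Female": 27, "Male": 45},
        "S3": {"Female": 18, "Male": 39}, "S4": {"Female": 19, "Male": 15},
        "S5": {"Female": 8, "Male": 3},
    }

    def test_female_share_in_late_subgroups(self):
        lab, cov = expand(self.GENDER)
        _, pct = coca.subgroup_proportions(lab, cov, {"S4", "S5"}, "Female")
        assert pct == 60

    def test_female_share_elsewhere(self):
        lab, cov = expand(self.GENDER)
        _, pct = coca.subgroup_proportions(lab, cov, {"S1", "S2", "S3"}, "Female")
        assert pct == 32

    def test_all_focus_level_gives_100(self):
        lab, cov = expand({"A": {"x": 7}, "B": {"x": 2, "y": 5}})
        pct, rounded = coca.subgroup_proportions(lab, cov, {"A"}, "x")
        assert pct == 100.0 and rounded == 100

    def test_empty_focus_rejected(self):
        lab, cov = expand({"A": {"x": 3}})
        with pytest.raises(ValueError):
            coca.subgroup_proportions(lab, cov, set(), "x")


class TestFeatureAuc:
    def brute_force_auc(self, values, positive):
        pos = values[positive]
        neg = values[~positive]
        wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
        return wins / (len(pos) * len(neg))

    def test_perfect_separation_gives_one(self):
        vals = pd.Series([5.0, 6.0, 1.0, 2.0], index=list("abcd"))
        lab = pd.Series(["g", "g", "r", "r"], index=list("abcd"))
        rec = coca.feature_auc_onevsrest(vals, lab, "g")
        assert rec.auc == 1.0

    def test_constant_feature_gives_half(self):
        vals = pd.Series([3.0] * 6, index=[f"s{i}" for i in range(6)])
        lab = pd.Series(["g"] * 2 + ["r"] * 4, index=vals.index)
        rec = coca.feature_auc_onevsrest(vals, lab, "g")
        assert rec.auc == 0.5

    @pytest.mark.parametrize("seed,n", [(0, 20), (1, 77), (2, 200)])
    def test_auc_equals_mann_whitney_pair_counting(self, seed, n):
        rng = np.random.default_rng(seed)
        vals = pd.Series(rng.normal(size=n).round(1), index=[f"s{i}" for i in range(n)])
        positive = rng.random(n) < 0.4
        if positive.all() or not positive.any():
            positive[0] = ~positive[0]
        lab = pd.Series(np.where(positive, "g", "r"), index=vals.index)
        rec = coca.feature_auc_onevsrest(vals, lab, "g")
        assert rec.auc == pytest.approx(self.brute_force_auc(vals.to_numpy(), positive), abs=1e-12)
        assert rec.direction_free_auc == pytest.approx(max(rec.auc, 1 - rec.auc))

    def test_random_feature_mean_auc_near_half(self):
        rng = np.random.default_rng(3)
        aucs = []
        for _ in range(200):
            vals = pd.Series(rng.normal(size=30), index=[f"s{i}" for i in range(30)])
            lab = pd.Series(["g"] * 15 + ["r"] * 15, index=vals.index)
            aucs.append(coca.feature_auc_onevsrest(vals, lab, "g").auc)
        assert abs(np.mean(aucs) - 0.5) < 0.03

    def test_degenerate_subgroup_rejected(self):
        vals = pd.Series([1.0, 2.0], index=["a", "b"])
        lab = pd.Series(["g", "g"], index=["a", "b"])
        with pytest.raises(ValueError):
            coca.feature_auc_onevsrest(vals, lab, "g")


class TestSignatureTable:
    def test_planted_marker_is_top_hit(self):
        rng = np.random.default_rng(4)
        vals = rng.normal(size=(20, 60))
        labels = pd.Series([1] * 20 + [2] * 20 + [3] * 20,
                           index=[f"s{i}" for i in range(60)])
        vals[7, :20] += 3.0  # feature f7 shifted up in subgroup 1
        pm = make_platform(vals, kind="prot")
        table = coca.subgroup_signature_table({"prot": pm}, labels)
        hits = table[(table["subgroup"] == 1)]
        assert not hits.empty and hits.iloc[0]["feature_id"] == "f7"
        assert hits.iloc[0]["direction"] == "up"

    def test_null_data_mostly_empty(self):
        rng = np.random.default_rng(5)
        sig_counts = []
        for rep in range(10):
            vals = rng.normal(size=(15, 40))
            labels = pd.Series([1] * 20 + [2] * 20, index=[f"s{i}" for i in range(40)])
            pm = make_platform(vals, kind="prot")
            sig_counts.append(len(coca.subgroup_signature_table({"prot": pm}, labels)))
        assert np.mean(sig_counts) < 1.5  # BH at 0.05 admits almost nothing

    def test_identical_distributions_give_empty_signature(self):
        vals = np.tile(np.r_[np.linspace(0, 1, 6), np.linspace(0, 1, 6)], (4, 1))
        labels = pd.Series([1] * 6 + [2] * 6, index=[f"s{i}" for i in range(12)])
        pm = make_platform(vals, kind="prot")
        assert coca.subgroup_signature_table({"prot": pm}, labels).empty
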