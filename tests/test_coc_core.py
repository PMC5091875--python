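import numpy as np
import pandas as pd
import pytest

import coca
from coca.coc_core import binary_distance_matrix

from conftest import make_platform


def block_matrix(n_a=20, n_b=20, n_features=10, scale=1.0, seed=0):
    """Two anti-correlated feature blocks over two sample blocks."""
    rng = np.random.default_rng(seed)
    pattern = np.array([1.0] * n_a + [-1.0] * n_b)
    vals = np.empty((n_features, n_a + n_b))
    for f in range(n_features):
        sign = 1.0 if f < n_features // 2 else -1.0
        vals[f] = sign * pattern * scale + rng.normal(0, 0.05, n_a + n_b)
    return make_platform(vals)


class TestSubclusterFeatures:
    def test_anticorrelated_blocks_recovered_exactly(self):
        pm = block_matrix()
        sc = coca.subcluster_features(pm, k=2, seed=0)
        groups = {}
        for f, c in sc.assignment.items():
            groups.setdefault(c, set()).add(f)
        expected = {frozenset(f"f{i}" for i in range(5)), frozenset(f"f{i}" for i in range(5, 10))}
        assert {frozenset(g) for g in groups.values()} == expected

    def test_k_equals_feature_count_gives_singletons(self):
        pm = block_matrix(n_features=6)
        sc = coca.subcluster_features(pm, k=6)
        assert sorted(sc.assignment.values()) == [1, 2, 3, 4, 5, 6]

    def test_k_above_feature_count_rejected(self):
        pm = make_platform(np.zeros((2, 5)))
        with pytest.raises(ValueError, match="exceeds feature count"):
            coca.subcluster_features(pm, k=3)

    def test_every_cluster_nonempty(self):
        rng = np.random.default_rng(5)
        pm = make_platform(rng.normal(size=(30, 12)))
        for k in (2, 5, 10):
            sc = coca.subcluster_features(pm, k=k)
            assert set(sc.assignment.values()) == set(range(1, k + 1))

    def test_kmeans_option_deterministic(self):
        pm = block_matrix()
        a = coca.subcluster_features(pm, 2, seed=3, method="kmeans")
        b = coca.subcluster_features(pm, 2, seed=3, method="kmeans")
        assert a.assignment == b.assignment


class TestIndicatorFromSubcluster:
    def two_point_platform(self, n_pos, n_neg, n_features=4):
        vals = np.tile([1.0] * n_pos + [-1.0] * n_neg, (n_features, 1))
        rng = np.random.default_rng(1)
        vals = vals + rng.normal(0, 0.01, vals.shape)
        return make_platform(vals)

    def test_small_group_split_yields_all_na(self):
        pm = self.two_point_platform(14, 9)
        row = coca.indicator_from_subcluster(pm, pm.feature_ids, min_group_size=10)
        assert row.is_all_na

    def test_balanced_split_yields_binary_labels(self):
        pm = self.two_point_platform(20, 20)
        row = coca.indicator_from_subcluster(pm, pm.feature_ids, min_group_size=10)
        assert not row.labels.isna().any()
        assert set(row.labels.unique()) == {0.0, 1.0}

    def test_high_mean_group_labeled_one(self):
        pm = self.two_point_platform(20, 20)
        row = coca.indicator_from_subcluster(pm, pm.feature_ids, min_group_size=10)
        high = [f"s{i}" for i in range(20)]
        assert (row.labels[high] == 1.0).all()
        assert (row.labels.drop(high) == 0.0).all()

    def test_invariant_to_sample_order_and_positive_scaling(self):
        pm = self.two_point_platform(20, 20)
        base = coca.indicator_from_subcluster(pm, pm.feature_ids)
        rng = np.random.default_rng(2)
        perm = list(rng.permutation(pm.sample_ids))
        shuffled = coca.PlatformMatrix(pm.kind, pm.data[perm], pm.state)
        scaled = coca.PlatformMatrix(pm.kind, pm.data * 3.5, pm.state)
        for variant in (shuffled, scaled):
            row = coca.indicator_from_subcluster(variant, pm.feature_ids)
            pd.testing.assert_series_equal(
                row.labels.sort_index(), base.labels.sort_index(), check_names=False
            )

    def test_unknown_members_rejected(self):
        pm = self.two_point_platform(5, 5)
        with pytest.raises(ValueError, match="not found"):
            coca.indicator_from_subcluster(pm, ["nope"])


class TestAssembleCocMatrix:
    def row(self, samples, platform="mrna", idx=1, value=1.0):
        return coca.IndicatorRow(platform, idx, pd.Series(value, index=samples))

    def test_shape_and_row_order(self):
        samples = list("abcde")
        rows = [self.row(samples, "meth", 1), self.row(samples, "cnv", 2),
                self.row(samples, "cnv", 1)]
        coc = coca.assemble_coc_matrix(rows, samples)
        assert coc.values.shape == (3, 5)
        assert coc.row_meta == [("cnv", 1), ("cnv", 2), ("meth", 1)]

    def test_inconsistent_sample_sets_listed_in_error(self):
        rows = [self.row(list("abc")), self.row(list("bcd"))]
        with pytest.raises(ValueError, match="mismatch"):
            coca.assemble_coc_matrix(rows, list("abc"))

    def test_row_count_is_sum_of_platform_ks(self, small_dataset):
        plats = small_dataset.preprocessed_platforms()
        rows = []
        for kind, k in (("cnv", 2), ("mrna", 2), ("mirna", 2), ("meth", 2)):
            sc = coca.subcluster_features(plats[kind], k)
            rows.extend(coca.indicator_rows_for_platform(plats[kind], sc))
        coc = coca.assemble_coc_matrix(rows, small_dataset.sample_ids)
        assert coc.n_rows == 8


class TestBinaryDistance:
    def test_na_rows_ignored(self):
        samples = list("ab")
        rows = [
            coca.IndicatorRow("mrna", 1, pd.Series([1.0, 0.0], index=samples)),
            coca.IndicatorRow("mrna", 2, pd.Series([np.nan, np.nan], index=samples)),
            coca.IndicatorRow("mrna", 3, pd.Series([1.0, 1.0], index=samples)),
        ]
        coc = coca.assemble_coc_matrix(rows, samples)
        d = binary_distance_matrix(coc)
        assert d[0, 1] == pytest.approx(0.5)  # 1 mismatch over 2 observed rows

    def test_never_cosampled_pair_gets_half(self):
        samples = list("ab")
        rows = [coca.IndicatorRow("mrna", 1, pd.Series([np.nan, np.nan], index=samples))]
        coc = coca.assemble_coc_matrix(rows, samples)
        assert binary_distance_matrix(coc)[0, 1] == 0.5


class TestConsensusCluster:
    def test_perfect_blocks_give_binary_consensus_and_block_labels(self, two_block_coc):
        coc, samples = two_block_coc
        res = coca.consensus_cluster(coc, k=2, reps=30, sample_fraction=0.8, seed=4)
        res.validate()
        a = [s for s in samples if s.startswith("A")]
        b = [s for s in samples if s.startswith("B")]
        ia = [samples.index(s) for s in a]
        ib = [samples.index(s) for s in b]
        assert res.consensus[np.ix_(ia, ia)].min() == 1.0
        assert res.consensus[np.ix_(ia, ib)].max() == 0.0
        assert res.labels[a].nunique() == 1 and res.labels[b].nunique() == 1
        assert res.labels[a].iloc[0] != res.labels[b].iloc[0]

    def test_full_fraction_equals_single_partition_comembership(self, small_dataset):
        """With no resampling the consensus is exactly the co-membership
        matrix of one deterministic partition (oracle equivalence)."""
        plats = small_dataset.preprocessed_platforms()
        sc = coca.subcluster_features(plats["mrna"], 6)
        rows = coca.indicator_rows_for_platform(plats["mrna"], sc)
        coc = coca.assemble_coc_matrix(rows, small_dataset.sample_ids)
        res = coca.consensus_cluster(coc, k=3, reps=5, sample_fraction=1.0, seed=0)
        assert set(np.unique(res.consensus)) <= {0.0, 1.0}
        # oracle: one average-linkage partition of the full distance matrix
        from scipy.cluster.hierarchy import fcluster, linkage
        from scipy.spatial.distance import squareform

        D = binary_distance_matrix(coc)
        part = fcluster(linkage(squareform(D, checks=False), "average"), 3, "maxclust")
        com = (part[:, None] == part[None, :]).astype(float)
        assert np.array_equal(res.consensus, com)

    def test_k_larger_than_samples_rejected(self):
        samples = ["a"]
        rows = [coca.IndicatorRow("mrna", 1, pd.Series([1.0], index=samples))]
        coc = coca.assemble_coc_matrix(rows, samples)
        with pytest.raises(ValueError):
            coca.consensus_cluster(coc, k=2, reps=3)

    def test_invariants_hold_on_noise(self):
        rng = np.random.default_rng(6)
        samples = [f"s{i}" for i in range(25)]
        rows = [
            coca.IndicatorRow("mrna", i + 1,
                              pd.Series(rng.integers(0, 2, 25).astype(float), index=samples))
            for i in range(7)
        ]
        coc = coca.assemble_coc_matrix(rows, samples)
        for k in (2, 3, 4):
            res = coca.consensus_cluster(coc, k=k, reps=20, seed=k)
            res.validate()
            assert res.labels.nunique() == k

    def test_all_na_rows_do_not_change_labels(self, two_block_coc):
        coc, samples = two_block_coc
        res = coca.consensus_cluster(coc, k=2, reps=20, seed=1)
        na_row = coca.IndicatorRow("meth", 1, pd.Series(np.nan, index=samples))
        rows = [coca.IndicatorRow(p, i, coc.values.loc[f"{p}{i}"]) for p, i in coc.row_meta]
        coc2 = coca.assemble_coc_matrix(rows + [na_row], samples)
        res2 = coca.consensus_cluster(coc2, k=2, reps=20, seed=1)
        pd.testing.assert_series_equal(res.labels, res2.labels)


class TestSelectK:
    def test_two_block_data_chooses_two(self, two_block_coc):
        coc, _ = two_block_coc
        results = coca.consensus_sweep(coc, range(2, 6), reps=40, seed=2)
        assert coca.select_k_delta_area(results) == 2

    def test_five_block_synthetic_chooses_five(self, small_dataset):
        plats = small_dataset.preprocessed_platforms()
        res = coca.finalize_subgroups(
            plats, {"cnv": 5, "mrna": 10, "mirna": 5, "meth": 8}, seed=9, reps=50
        )
        assert res.final_k == 5

    def test_flat_random_matrix_returns_minimum_k(self):
        rng = np.random.default_rng(8)
        samples = [f"s{i}" for i in range(60)]
        rows = [
            coca.IndicatorRow("mrna", i + 1,
                              pd.Series(rng.integers(0, 2, 60).astype(float), index=samples))
            for i in range(30)
        ]
        coc = coca.assemble_coc_matrix(rows, samples)
        results = coca.consensus_sweep(coc, range(2, 7), reps=25, seed=8)
        # unstructured data: delta-area never certifies any k above the minimum
        assert coca.select_k_delta_area(results) == 2

    def test_single_result_returned_with_warning(self, two_block_coc, caplog):
        coc, _ = two_block_coc
        res = coca.consensus_cluster(coc, k=3, reps=10, seed=0)
        with caplog.at_level("WARNING"):
            assert coca.select_k_delta_area([res]) == 3
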