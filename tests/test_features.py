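"""Feature selection: voxelwise t tests, clusters, Fisher scores, MI."""
import numpy as np
import pandas as pd
import pytest
from scipy import stats

from fcdml.features import (
    build_feature_matrix,
    demographic_tests,
    extract_clusters,
    fisher_score,
    mutual_information_scores,
    voxelwise_ttest,
)
from fcdml.types import BrainMask, FCDMap, StatMap


def _maps(arrays, kind="gFCD"):
    return [FCDMap(a, kind, 0.6, np.eye(4), f"s{i}") for i, a in enumerate(arrays)]


def _mask(shape):
    return BrainMask(np.ones(shape, bool), np.eye(4))


class TestVoxelwiseTTest:
    def test_hand_example_per_voxel(self):
        """a=[1,2,3], b=[4,5,6] at one voxel reproduces the pooled-variance t."""
        shape = (2, 1, 1)
        a = [np.full(shape, v) for v in (1.0, 2.0, 3.0)]
        b = [np.full(shape, v) for v in (4.0, 5.0, 6.0)]
        stat = voxelwise_ttest(_maps(a), _maps(b), _mask(shape))
        t_ref, p_ref = stats.ttest_ind([1, 2, 3], [4, 5, 6])
        assert np.allclose(stat.t_values, t_ref)
        assert np.allclose(stat.p_values, p_ref)
        assert stat.df == 4

    def test_zero_pooled_variance_gives_p_one(self):
        shape = (1, 1, 1)
        a = [np.full(shape, 1.0)] * 3
        b = [np.full(shape, 2.0)] * 3
        stat = voxelwise_ttest(_maps(a), _maps(b), _mask(shape))
        assert stat.p_values[0, 0, 0] == 1.0 and stat.t_values[0, 0, 0] == 0.0

    def test_null_rejection_rate_near_alpha(self):
        """Groups from one distribution: ~0.5% of voxels reject at p<0.005."""
        rng = np.random.default_rng(0)
        shape = (20, 20, 20)
        a = [rng.standard_normal(shape) for _ in range(15)]
        b = [rng.standard_normal(shape) for _ in range(15)]
        stat = voxelwise_ttest(_maps(a), _maps(b), _mask(shape))
        rate = (stat.p_values < 0.005).mean()
        # 99.9% binomial band around 0.005 at 8000 voxels
        assert 0.0025 <= rate <= 0.0085

    def test_mixed_kinds_rejected(self):
        a = _maps([np.zeros((2, 1, 1))] * 2, "gFCD")
        b = _maps([np.zeros((2, 1, 1))] * 2, "lFCD")
        with pytest.raises(ValueError):
            voxelwise_ttest(a, b, _mask((2, 1, 1)))


def _stat_from_t(t_map, df=40):
    p = 2 * stats.t.sf(np.abs(t_map), df)
    return StatMap(t_map, p, df, "test", np.eye(4))


class TestExtractClusters:
    def test_null_map_gives_empty_table(self):
        stat = _stat_from_t(np.zeros((6, 6, 6)))
        assert len(extract_clusters(stat, 0.005, 5)) == 0

    def test_planted_contiguous_blob_recovered_with_sign(self):
        t = np.zeros((10, 10, 10))
        blob = np.zeros_like(t, bool)
        blob[2:5, 2:7, 3:5] = True  # 3*5*2 = 30 voxels
        t[blob] = -6.0
        t[3, 4, 4] = -8.0  # peak
        table = extract_clusters(_stat_from_t(t), 0.005, min_extent=20)
        assert len(table) == 1
        rec = table.records[0]
        assert rec.extent == 30 and rec.sign == "decrease"
        assert rec.peak_t == -8.0
        assert rec.peak_coordinate == (3.0, 4.0, 4.0)  # identity affine

    def test_min_extent_filters_small_clusters(self):
        t = np.zeros((8, 8, 8))
        t[1:3, 1, 1] = 7.0  # extent 2
        assert len(extract_clusters(_stat_from_t(t), 0.005, min_extent=3)) == 0
        assert len(extract_clusters(_stat_from_t(t), 0.005, min_extent=2)) == 1

    def test_corner_touch_connectivity_semantics(self):
        """Two voxels sharing only a corner: one cluster at 26, two at 6."""
        t = np.zeros((5, 5, 5))
        t[1, 1, 1] = 7.0
        t[2, 2, 2] = 7.0
        stat = _stat_from_t(t)
        assert len(extract_clusters(stat, 0.005, 1, connectivity=26)) == 1
        assert len(extract_clusters(stat, 0.005, 1, connectivity=6)) == 2

    def test_opposite_signs_clustered_separately(self):
        t = np.zeros((6, 6, 6))
        t[1:3, 1, 1] = 7.0
        t[3:5, 1, 1] = -7.0  # adjacent but opposite sign
        table = extract_clusters(_stat_from_t(t), 0.005, 1)
        assert len(table) == 2
        assert {r.sign for r in table.records} == {"increase", "decrease"}


class TestFeatureMatrix:
    def _setup(self, n_subjects=5, constant=None):
        t = np.zeros((8, 8, 8))
        t[1:4, 1:4, 1] = 6.0  # 9-voxel cluster
        table = extract_clusters(_stat_from_t(t), 0.005, 1)
        rng = np.random.default_rng(0)
        maps = {}
        for i in range(n_subjects):
            data = (np.full((8, 8, 8), constant) if constant is not None
                    else rng.standard_normal((8, 8, 8)))
            maps[f"s{i}"] = {"gFCD": FCDMap(data, "gFCD", 0.6, np.eye(4), f"s{i}")}
        return maps, table

    def test_cluster_mean_shape_and_values(self):
        maps, table = self._setup()
        fm = build_feature_matrix(maps, table, "cluster-mean")
        assert fm.values.shape == (5, 1)
        vox = table.records[0].voxel_index_list
        expected = maps["s0"]["gFCD"].data[tuple(vox.T)].mean()
        assert np.isclose(fm.values[0, 0], expected)

    def test_constant_map_gives_constant_feature(self):
        maps, table = self._setup(constant=2.5)
        fm = build_feature_matrix(maps, table, "cluster-mean")
        assert np.allclose(fm.values, 2.5)

    def test_voxel_mode_single_voxel_cluster_is_identity(self):
        t = np.zeros((6, 6, 6))
        t[2, 2, 2] = 7.0
        table = extract_clusters(_stat_from_t(t), 0.005, 1)
        rng = np.random.default_rng(1)
        maps = {f"s{i}": {"gFCD": FCDMap(rng.standard_normal((6, 6, 6)),
                                         "gFCD", 0.6, np.eye(4), f"s{i}")}
                for i in range(4)}
        fm = build_feature_matrix(maps, table, "voxel")
        for i in range(4):
            assert fm.values[i, 0] == maps[f"s{i}"]["gFCD"].data[2, 2, 2]

    def test_missing_kind_raises(self):
        maps, table = self._setup()
        del maps["s3"]["gFCD"]
        maps["s3"]["lFCD"] = FCDMap(np.zeros((8, 8, 8)), "lFCD", 0.6, np.eye(4), "s3")
        with pytest.raises(ValueError):
            build_feature_matrix(maps, table, "cluster-mean")

    def test_column_order_reproducible(self):
        maps, table = self._setup()
        fm1 = build_feature_matrix(maps, table, "cluster-mean")
        fm2 = build_feature_matrix(maps, table, "cluster-mean")
        assert np.array_equal(fm1.values, fm2.values)
        assert fm1.feature_provenance == fm2.feature_provenance


class TestFisherScore:
    def test_hand_evaluation_population_variance(self):
        """group1=[1,2], group2=[3,5] -> FS = 2.5 under population variance."""
        X = np.array([[1.0], [2.0], [3.0], [5.0]])
        y = np.array([0, 0, 1, 1])
        assert np.isclose(fisher_score(X, y)[0], 2.5)

    def test_identical_groups_zero(self):
        X = np.array([[1.0], [2.0], [1.0], [2.0]])
        y = np.array([0, 0, 1, 1])
        assert fisher_score(X, y)[0] == 0.0

    @pytest.mark.parametrize("a,b", [(10.0, 0.0), (-3.0, 7.0), (0.01, -2.0)])
    def test_affine_invariance(self, a, b):
        rng = np.random.default_rng(0)
        X = rng.standard_normal((12, 4))
        y = np.array([0] * 6 + [1] * 6)
        fs1 = fisher_score(X, y)
        fs2 = fisher_score(a * X + b, y)
        assert np.allclose(fs1, fs2)

    def test_zero_variance_separating_feature_is_inf(self):
        X = np.array([[1.0], [1.0], [2.0], [2.0]])
        y = np.array([0, 0, 1, 1])
        assert np.isinf(fisher_score(X, y)[0])


class TestMutualInformation:
    def test_identity_feature_ranks_highest_and_duplicates_tie(self):
        rng = np.random.default_rng(0)
        y = rng.standard_normal(60)
        X = np.column_stack([y, rng.standard_normal(60), y])
        mi = mutual_information_scores(X, y, seed=0)
        assert np.isclose(mi[0], mi.max())
        assert np.isclose(mi[0], mi[2], rtol=1e-6)
        assert mi[1] < mi[0]

    def test_independent_target_near_zero(self):
        rng = np.random.default_rng(1)
        vals = []
        for s in range(10):
            X = rng.standard_normal((40, 1))
            y = rng.standard_normal(40)
            vals.append(mutual_information_scores(X, y, seed=s)[0])
        assert np.mean(vals) < 0.15

    def test_too_few_subjects_raises(self):
        with pytest.raises(ValueError):
            mutual_information_scores(np.zeros((5, 2)), np.zeros(5))


class TestDemographics:
    def _table(self):
        return pd.DataFrame({
            "subject_id": [f"s{i}" for i in range(10)],
            "group": ["A"] * 5 + ["B"] * 5,
            "session": ["pre"] * 10,
            "age": [20, 21, 22, 23, 24, 20, 21, 22, 23, 24.0],
            "sex": ["m", "m", "f", "m", "f", "m", "m", "f", "m", "f"],
            "score_pre": [10.0] * 5 + [60.0] * 5,
            "score_post": [np.nan] * 5 + [45.0] * 5,
        })

    def test_identical_groups_all_null(self):
        rep = demographic_tests(self._table())
        age = rep[rep.variable == "age"].iloc[0]
        sex = rep[rep.variable == "sex"].iloc[0]
        assert age.p_value == 1.0
        assert sex.p_value == 1.0

    def test_chi_squared_matches_hand_formula(self):
        """2x2 table [[22,8],[22,5]] with continuity correction."""
        table = pd.DataFrame({
            "subject_id": [f"s{i}" for i in range(57)],
            "group": ["A"] * 30 + ["B"] * 27,
            "session": ["pre"] * 57,
            "sex": ["m"] * 22 + ["f"] * 8 + ["m"] * 22 + ["f"] * 5,
        })
        rep = demographic_tests(table)
        chi2_ref, p_ref, _, _ = stats.chi2_contingency(
            np.array([[8, 22], [5, 22]])
        )
        row = rep[rep.variable == "sex"].iloc[0]
        assert np.isclose(row.statistic, chi2_ref)
        assert np.isclose(row.p_value, p_ref)

    def test_paired_pre_equal_post_gives_zero_t(self):
        t = self._table()
        t.loc[t.group == "B", "score_post"] = t.loc[t.group == "B", "score_pre"]
        rep = demographic_tests(t)
        paired = rep[rep.test == "paired t"].iloc[0]
        assert paired.statistic == 0.0 and paired.p_value == 1.0


# ------------------------------------------------ property-based checks

from hypothesis import given, settings, strategies as st


@settings(max_examples=25, deadline=None, derandomize=True)
@given(
    a=st.floats(min_value=0.01, max_value=100.0),
    b=st.floats(min_value=-50.0, max_value=50.0),
    seed=st.integers(min_value=0, max_value=2**16),
)
def test_fisher_score_affine_invariance_property(a, b, seed):
    """FS is invariant under x -> a*x + b (a != 0) for any feature."""
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((10, 3))
    y = np.array([0] * 5 + [1] * 5)
    assert np.allclose(fisher_score(a * X + b, y), fisher_score(X, y),
                       rtol=1e-8, atol=1e-10)
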