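"""Preprocessing chain: discarding, FD, QC, regression, filtering, scrubbing."""
import numpy as np
import pytest
from scipy import stats

from fcdml.preprocess import (
    bandpass_filter,
    build_confound_matrix,
    build_friston24,
    compute_fd,
    discard_initial_volumes,
    extract_tissue_signals,
    group_motion_tests,
    qc_exclude,
    regress_nuisance,
    scrub_frames,
)
from fcdml.types import BoldRun, BrainMask, FDSeries, MotionParams


def _run(T=255, shape=(2, 2, 2), seed=0, tr=2.0):
    rng = np.random.default_rng(seed)
    return BoldRun(rng.standard_normal(shape + (T,)), tr, (3.0, 3.0, 3.0),
                   np.eye(4), "s01")


class TestDiscard:
    def test_255_minus_5_gives_250_and_motion_rows_drop(self):
        run = _run(255)
        mot = MotionParams(np.arange(255 * 6, dtype=float).reshape(255, 6))
        out, mout = discard_initial_volumes(run, 5, mot)
        assert out.n_frames == 250 and mout.n_frames == 250
        assert np.array_equal(out.data, run.data[..., 5:])
        assert np.array_equal(mout.values, mot.values[5:])

    def test_zero_discard_is_identity(self):
        run = _run(40)
        out = discard_initial_volumes(run, 0)
        assert np.array_equal(out.data, run.data)

    def test_discarding_all_frames_raises(self):
        with pytest.raises(ValueError):
            discard_initial_volumes(_run(255), 255)


class TestFriston24:
    def test_zero_motion_gives_zero_matrix(self):
        conf = build_friston24(MotionParams(np.zeros((10, 6))))
        assert conf.columns.shape == (10, 24)
        assert not conf.columns.any()

    def test_hand_expansion_of_linear_parameter(self):
        """p(t)=t: squared column t^2, lag column t-1 with 0 at t=0."""
        vals = np.zeros((5, 6))
        vals[:, 0] = np.arange(5.0)
        conf = build_friston24(MotionParams(vals))
        p, lag, sq, lagsq = (conf.columns[:, k] for k in (0, 6, 12, 18))
        assert np.array_equal(p, [0, 1, 2, 3, 4])
        assert np.array_equal(lag, [0, 0, 1, 2, 3])
        assert np.array_equal(sq, [0, 1, 4, 9, 16])
        assert np.array_equal(lagsq, [0, 0, 1, 4, 9])

    def test_shape_contract(self):
        conf = build_friston24(MotionParams(np.random.default_rng(0).normal(size=(20, 6))))
        assert conf.columns.shape == (20, 24)
        assert len(conf.column_names) == 24


class TestFD:
    def test_static_head_all_zero(self):
        for method in ("power", "jenkinson"):
            fd = compute_fd(MotionParams(np.ones((10, 6))), method=method)
            assert np.allclose(fd.values, 0)

    def test_power_single_translation_jump(self):
        vals = np.zeros((5, 6))
        vals[2:, 0] = 1.0  # 1 mm x jump at frame 2
        fd = compute_fd(MotionParams(vals), method="power")
        assert np.allclose(fd.values, [0, 0, 1.0, 0, 0])

    def test_power_pure_rotation_times_head_radius(self):
        vals = np.zeros((3, 6))
        vals[1:, 3] = 0.02  # rad
        fd = compute_fd(MotionParams(vals), method="power", head_radius_mm=50.0)
        assert np.isclose(fd.values[1], 1.0)

    def test_jenkinson_pure_translation_equals_step(self):
        vals = np.zeros((3, 6))
        vals[1:, 1] = 0.7
        fd = compute_fd(MotionParams(vals), method="jenkinson")
        assert np.isclose(fd.values[1], 0.7)

    def test_translation_additivity_of_power_fd(self):
        rng = np.random.default_rng(2)
        vals = np.zeros((30, 6))
        vals[:, :3] = rng.normal(0, 0.1, (30, 3)).cumsum(axis=0)
        fd1 = compute_fd(MotionParams(vals), method="power")
        fd2 = compute_fd(MotionParams(2 * vals), method="power")
        assert np.allclose(fd2.values, 2 * fd1.values)

    def test_unknown_method_raises(self):
        with pytest.raises(ValueError):
            compute_fd(MotionParams(np.zeros((5, 6))), method="nope")


class TestQC:
    def test_translation_over_limit_excludes(self):
        vals = np.zeros((10, 6))
        vals[5:, 2] = 2.5
        decision, reason = qc_exclude(MotionParams(vals))
        assert decision == "exclude" and reason == "translation"

    def test_zero_motion_keeps(self):
        assert qc_exclude(MotionParams(np.zeros((10, 6))))[0] == "keep"

    def test_rotation_exactly_at_limit_keeps(self):
        """Thresholds are strict ('more than'): exactly 2 degrees passes."""
        vals = np.zeros((10, 6))
        vals[5:, 4] = np.radians(2.0)
        assert qc_exclude(MotionParams(vals))[0] == "keep"
        vals[5:, 4] = np.radians(2.01)
        decision, reason = qc_exclude(MotionParams(vals))
        assert decision == "exclude" and reason == "rotation"


class TestTissueSignals:
    def test_constant_field_and_single_voxel(self):
        data = np.full((3, 3, 3, 8), 4.5)
        run = BoldRun(data, 2.0, (3.0,) * 3, np.eye(4), "s")
        m1 = np.zeros((3, 3, 3), bool); m1[0, 0, 0] = True
        m2 = np.zeros((3, 3, 3), bool); m2[1, 1, 1] = m2[2, 2, 2] = True
        csf, wm = extract_tissue_signals(run, BrainMask(m1, np.eye(4)), BrainMask(m2, np.eye(4)))
        assert np.allclose(csf, 4.5) and np.allclose(wm, 4.5)

    def test_two_voxel_mean(self):
        data = np.zeros((2, 1, 1, 4))
        data[0, 0, 0] = [1, 2, 3, 4]
        data[1, 0, 0] = [3, 4, 5, 6]
        run = BoldRun(data, 2.0, (3.0,) * 3, np.eye(4), "s")
        m = BrainMask(np.ones((2, 1, 1), bool), np.eye(4))
        s, _ = extract_tissue_signals(run, m, m)
        assert np.allclose(s, [2, 3, 4, 5])


class TestNuisanceRegression:
    def test_residuals_orthogonal_to_all_26_confounds(self):
        run = _run(120, shape=(3, 3, 3), seed=1)
        mask = BrainMask(np.ones((3, 3, 3), bool), np.eye(4))
        mot = MotionParams(np.random.default_rng(3).normal(0, 0.05, (120, 6)))
        csf = np.zeros((3, 3, 3), bool); csf[0, 0, :] = True
        wm = np.zeros((3, 3, 3), bool); wm[2, 2, :] = True
        conf = build_confound_matrix(mot, run, BrainMask(csf, np.eye(4)), BrainMask(wm, np.eye(4)))
        assert conf.columns.shape[1] == 26
        out = regress_nuisance(run, conf, mask)
        resid = out.data[mask.data].T
        for k in range(conf.columns.shape[1]):
            col = conf.columns[:, k]
            denom = np.linalg.norm(resid, axis=0) * np.linalg.norm(col) + 1e-30
            assert (np.abs(resid.T @ col) / denom.clip(1e-30)).max() < 1e-8

    def test_series_equal_to_confound_regresses_to_zero(self):
        T = 50
        conf_col = np.sin(np.arange(T))
        data = np.tile(conf_col, (1, 1, 1, 1))
        run = BoldRun(data, 2.0, (3.0,) * 3, np.eye(4), "s")
        from fcdml.types import ConfoundMatrix
        conf = ConfoundMatrix(conf_col[:, None], ["c0"])
        mask = BrainMask(np.ones((1, 1, 1), bool), np.eye(4))
        out = regress_nuisance(run, conf, mask)
        assert np.abs(out.data).max() < 1e-10

    def test_zero_confounds_removes_only_mean(self):
        run = _run(60, shape=(2, 2, 2), seed=4)
        from fcdml.types import ConfoundMatrix
        conf = ConfoundMatrix(np.zeros((60, 3)), ["a", "b", "c"])
        mask = BrainMask(np.ones((2, 2, 2), bool), np.eye(4))
        out = regress_nuisance(run, conf, mask)
        expected = run.data - run.data.mean(axis=3, keepdims=True)
        assert np.allclose(out.data, expected, atol=1e-10)


class TestBandpass:
    @pytest.mark.parametrize(
        "freq,low_bound,high_bound",
        [(0.04, 0.9, 1.1), (0.005, 0.0, 0.1), (0.2, 0.0, 0.1)],
    )
    def test_amplitude_response(self, freq, low_bound, high_bound):
        T, tr = 250, 2.0
        t = np.arange(T) * tr
        x = np.sin(2 * np.pi * freq * t)
        run = BoldRun(x.reshape(1, 1, 1, T), tr, (3.0,) * 3, np.eye(4), "s")
        y = bandpass_filter(run).data.ravel()
        sl = slice(25, T - 25)  # ignore edge transients
        ratio = y[sl].std() / x[sl].std()
        assert low_bound <= ratio <= high_bound

    def test_constant_series_removed(self):
        run = BoldRun(np.full((1, 1, 1, 100), 3.0), 2.0, (3.0,) * 3, np.eye(4), "s")
        assert np.abs(bandpass_filter(run).data).max() < 1e-10

    def test_band_outside_nyquist_raises(self):
        with pytest.raises(ValueError):
            bandpass_filter(_run(50), 0.01, 0.3)  # Nyquist = 0.25 Hz


class TestScrub:
    def test_no_scrubbing_when_fd_below_threshold(self):
        run = _run(120)
        fd = FDSeries(np.full(120, 0.1), "power")
        out, kept = scrub_frames(run, fd, 0.5)
        assert out.n_frames == 120 and np.array_equal(kept, np.arange(120))

    def test_exactly_suprathreshold_frames_removed(self):
        run = _run(250)
        rng = np.random.default_rng(0)
        fd_vals = np.full(250, 0.1)
        bad = rng.choice(np.arange(1, 250), 12, replace=False)
        fd_vals[bad] = 0.9
        out, kept = scrub_frames(run, FDSeries(fd_vals, "power"), 0.5)
        assert out.n_frames == 238
        assert np.array_equal(np.sort(np.concatenate([kept, bad])), np.arange(250))
        assert np.array_equal(out.data, run.data[..., kept])

    def test_too_few_surviving_frames_raises(self):
        run = _run(120)
        fd_vals = np.ones(120); fd_vals[0] = 0.0
        with pytest.raises(ValueError):
            scrub_frames(run, FDSeries(fd_vals, "power"), 0.0, min_frames=100)


class TestGroupMotionTests:
    def test_identical_groups_null(self):
        t, p = group_motion_tests([1.0, 2, 3], [1.0, 2, 3])
        assert t == 0.0 and p == 1.0

    def test_unpaired_matches_hand_formula(self):
        a, b = np.array([1.0, 2, 3]), np.array([2.0, 3, 4])
        t, p = group_motion_tests(a, b)
        t_ref, p_ref = stats.ttest_ind(a, b)
        assert np.isclose(t, t_ref) and np.isclose(p, p_ref)
        # hand pooled-variance evaluation
        sp = np.sqrt(((a - a.mean()) ** 2).sum() + ((b - b.mean()) ** 2).sum()) / 2
        t_hand = (a.mean() - b.mean()) / (sp * np.sqrt(1 / 3 + 1 / 3))
        assert np.isclose(t, t_hand)

    def test_paired_constant_difference_degenerate(self):
        t, p = group_motion_tests([1.0, 2, 3], [2.0, 3, 4], paired=True)
        assert p == np.nextafter(0, 1) and np.isinf(t)


# ------------------------------------------------ property-based checks

from hypothesis import given, settings, strategies as st


@settings(max_examples=25, deadline=None, derandomize=True)
@given(scale=st.floats(min_value=0.1, max_value=10.0),
       seed=st.integers(min_value=0, max_value=2**16))
def test_power_fd_scales_linearly_with_translations(scale, seed):
    """Scaling all translation increments scales power FD by the same factor."""
    rng = np.random.default_rng(seed)
    vals = np.zeros((20, 6))
    vals[:, :3] = rng.normal(0, 0.05, (20, 3)).cumsum(axis=0)
    fd1 = compute_fd(MotionParams(vals), method="power")
    fd2 = compute_fd(MotionParams(vals * scale), method="power")
    assert np.allclose(fd2.values, scale * fd1.values, rtol=1e-9)
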