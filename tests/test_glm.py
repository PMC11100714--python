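import numpy as np
import pytest

from adaptscan.glm import (
    BetaMap,
    CensorMask,
    build_design_matrix,
    default_drift_order,
    fit_glm,
    hrf,
    scale_and_censor,
    task_regressor,
)
from adaptscan.simcortex.signal import VoxelTuningParams, simulate_timeseries


class TestHRF:
    def test_double_gamma_unit_peak_at_6s(self):
        t = np.arange(0, 32, 0.01)
        vals = hrf("double_gamma", t)
        assert np.max(vals) == pytest.approx(1.0, abs=1e-9)
        assert t[np.argmax(vals)] == pytest.approx(6.0, abs=0.02)

    def test_double_gamma_undershoot(self):
        t = np.arange(10, 30, 0.01)
        assert hrf("double_gamma", t).min() < -0.01

    def test_gamma_unit_peak_at_pq(self):
        # (t/(p q))^p exp(p - t/q) peaks at t = p*q = 4.7042 with value 1
        assert hrf("gamma", 8.6 * 0.547) == pytest.approx(1.0)
        t = np.arange(0.1, 20, 0.001)
        assert t[np.argmax(hrf("gamma", t))] == pytest.approx(4.7042, abs=0.005)

    def test_zero_before_onset(self):
        for kind in ("double_gamma", "gamma"):
            assert hrf(kind, 0.0) == 0.0
            assert np.all(hrf(kind, np.array([-3.0, -0.1])) == 0.0)

    def test_unknown_kind(self):
        with pytest.raises(ValueError, match="unknown hrf kind"):
            hrf("boxcar", 1.0)


class TestDesignMatrix:
    def test_columns_localizer(self, localizer_design):
        X = build_design_matrix(localizer_design)
        assert set(X.task_names) == {"faces", "objects", "words", "houses", "scrambled"}
        # 368 s run: drift order 1 + floor(368/150) = 3, columns drift_0..3
        assert sum(k == "drift" for k in X.kinds) == 4
        assert X.matrix.shape[0] == localizer_design.n_volumes

    def test_columns_adaptation(self, adaptation_design):
        X = build_design_matrix(adaptation_design)
        assert len(X.task_names) == 9

    def test_motion_columns_demeaned(self, localizer_design, rng):
        motion = rng.normal(size=(localizer_design.n_volumes, 6))
        X = build_design_matrix(localizer_design, motion=motion)
        cols = [i for i, k in enumerate(X.kinds) if k == "motion"]
        assert len(cols) == 6
        assert np.allclose(X.matrix[:, cols].mean(axis=0), 0.0, atol=1e-12)

    def test_rank_check_names_offender(self, localizer_design):
        X = build_design_matrix(localizer_design)
        m = np.column_stack([X.matrix, X.matrix[:, 0]])
        from adaptscan.glm import DesignMatrix

        bad = DesignMatrix(m, X.names + ("dup",), X.kinds + ("task",))
        with pytest.raises(np.linalg.LinAlgError, match="rank deficient"):
            bad.check_rank()

    def test_default_drift_order(self):
        assert default_drift_order(100.0) == 1
        assert default_drift_order(368.0) == 3


class TestScaleAndCensor:
    def test_scaling_to_mean_100(self, localizer_design, rng):
        sig = 1000.0 + rng.normal(0, 5, size=(4, localizer_design.n_volumes))
        from adaptscan.simcortex.signal import TimeSeriesDataset

        ds = TimeSeriesDataset(signal=sig, design=localizer_design)
        scaled, mask = scale_and_censor(ds)
        assert np.allclose(scaled.signal.mean(axis=1), 100.0)
        assert mask.n_kept == localizer_design.n_volumes

    def test_motion_censoring(self, localizer_design, rng):
        from adaptscan.simcortex.signal import TimeSeriesDataset

        sig = 1000.0 + rng.normal(0, 1, size=(2, localizer_design.n_volumes))
        motion = np.zeros((localizer_design.n_volumes, 6))
        motion[50, 0] = 5.0  # a large jump at volume 50 (and back at 51)
        ds = TimeSeriesDataset(signal=sig, design=localizer_design, motion=motion)
        _, mask = scale_and_censor(ds, motion_threshold=1.0)
        assert not mask.keep[50] and not mask.keep[51]
        assert mask.reasons[50] == "motion"

    def test_outlier_censoring(self, localizer_design, rng):
        from adaptscan.simcortex.signal import TimeSeriesDataset

        sig = 1000.0 + rng.normal(0, 1, size=(20, localizer_design.n_volumes))
        sig[:, 30] += 200.0  # spike across all voxels
        ds = TimeSeriesDataset(signal=sig, design=localizer_design)
        _, mask = scale_and_censor(ds)
        assert mask.reasons[30] == "outlier"

    def test_nonpositive_mean_raises(self, localizer_design):
        from adaptscan.simcortex.signal import TimeSeriesDataset

        sig = np.full((2, localizer_design.n_volumes), 7.0)
        sig[1] = 0.0
        ds = TimeSeriesDataset(signal=sig, design=localizer_design)
        with pytest.raises(ValueError, match=r"\[1\]"):
            scale_and_censor(ds)

    def test_censor_mask_consistency(self):
        with pytest.raises(ValueError):
            CensorMask(keep=np.array([True, True]), reasons={0: "motion"})


class TestFitGLM:
    def test_noiseless_recovery_exact(self, localizer_design):
        sel = {"faces": 17.0, "objects": 15.2, "words": 14.0, "houses": 4.0, "scrambled": 4.0}
        ds = simulate_timeseries(
            localizer_design, [VoxelTuningParams(selectivity=sel)], seed=0
        )
        mean = ds.signal[0].mean()
        scaled, mask = scale_and_censor(ds)
        bm = fit_glm(scaled, build_design_matrix(localizer_design), mask=mask)
        for c in bm.conditions:
            assert bm.beta(c)[0] == pytest.approx(sel[c] * 100.0 / mean, abs=1e-10)

    def test_contrast_balanced(self):
        betas = np.array([[2.0, 1.0, 1.0, 1.0, 1.0]])
        bm = BetaMap(
            betas=betas,
            conditions=("faces", "objects", "words", "houses", "scrambled"),
            resid_var=np.array([1.0]),
            df=100,
            cov_task=np.eye(5),
        )
        con, t = bm.contrast("faces")
        assert con[0] == pytest.approx(1.0)
        # c = [1, -.25 x4]; var = 1 + 4 * 1/16 = 1.25
        assert t[0] == pytest.approx(1.0 / np.sqrt(1.25))

    def test_contrast_rejects_target_in_baseline(self):
        bm = BetaMap(
            betas=np.zeros((1, 2)),
            conditions=("a", "b"),
            resid_var=np.array([1.0]),
            df=10,
            cov_task=np.eye(2),
        )
        with pytest.raises(ValueError):
            bm.contrast("a", baselines=["a", "b"])

    def test_prewhitening_known_rho_recovers_noiseless(self, localizer_design):
        sel = {"faces": 10.0, "objects": 5.0, "words": 5.0, "houses": 5.0, "scrambled": 5.0}
        ds = simulate_timeseries(
            localizer_design, [VoxelTuningParams(selectivity=sel)], seed=0
        )
        scaled, mask = scale_and_censor(ds)
        X = build_design_matrix(localizer_design)
        b_ols = fit_glm(scaled, X, mask=mask)
        b_w = fit_glm(scaled, X, mask=mask, ar1=0.3)
        # noiseless: whitening must not change the estimates
        assert np.allclose(b_ols.betas, b_w.betas, atol=1e-8)

    def test_prewhitening_shrinks_se_under_ar1_noise(self, localizer_design):
        sel = {"faces": 10.0, "objects": 5.0, "words": 5.0, "houses": 5.0, "scrambled": 5.0}
        tun = VoxelTuningParams(selectivity=sel, noise_sd=5.0, ar1=0.6)
        ds = simulate_timeseries(localizer_design, [tun] * 40, seed=7)
        scaled, mask = scale_and_censor(ds)
        X = build_design_matrix(localizer_design, motion=ds.motion)
        b_est = fit_glm(scaled, X, mask=mask, prewhiten=True)
        # estimated rho path returns per-voxel covariance
        assert b_est.cov_task.ndim == 3
        con, t = b_est.contrast("faces")
        assert np.median(con) > 0

    def test_too_few_volumes_raises(self, localizer_design, rng):
        from adaptscan.simcortex.signal import TimeSeriesDataset

        sig = 1000.0 + rng.normal(0, 1, size=(1, localizer_design.n_volumes))
        ds = TimeSeriesDataset(signal=sig, design=localizer_design)
        keep = np.zeros(localizer_design.n_volumes, dtype=bool)
        keep[:5] = True
        reasons = {int(i): "motion" for i in np.where(~keep)[0]}
        with pytest.raises(ValueError, match="too few volumes"):
            fit_glm(ds, build_design_matrix(localizer_design), mask=CensorMask(keep, reasons))


class TestTaskRegressor:
    def test_weights_length_checked(self, localizer_design):
        with pytest.raises(ValueError, match="weights length"):
            task_regressor(localizer_design, "faces", weights=[1.0])

    def test_linearity_in_weights(self, adaptation_design):
        r1 = task_regressor(adaptation_design, "faces_same")
        r2 = task_regressor(
            adaptation_design,
            "faces_same",
            weights=[2.0] * sum(ev.trial_type == "faces_same" for ev in adaptation_design.events),
        )
        assert np.allclose(r2, 2.0 * r1, atol=1e-12)
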