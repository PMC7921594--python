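"""Sigmoid wash-in fitting and the tangent-at-inflection arrival time."""

import numpy as np
import pytest
from bolustrack.arrival import (
    ArrivalEstimate,
    LowContrastError,
    SigmoidFit,
    arrival_map,
    arrival_time,
    estimate_arrival,
    fit_sigmoid,
    sigmoid_model,
)
from bolustrack.synthetic import generate_first_pass_phantom, generate_voxel_curve
from bolustrack.timecurve import SampledCurve

FI = 21.5


def model_curve(A, D, B, C, n=186, fi=FI):
    t = fi * (1 + np.arange(n))
    return SampledCurve(t, sigmoid_model(t, A, D, B, C), fi)


def numeric_tangent_t0(A, D, B, C):
    """Independent oracle: finite-difference tangent at the inflection point
    (Richardson-extrapolated central differences) intersected numerically
    with the baseline level signal = A."""
    def f(t):
        return D + (A - D) / (1.0 + (t / C) ** B)

    h = 1e-4 * C
    d1 = (f(C + h) - f(C - h)) / (2 * h)
    d2 = (f(C + h / 2) - f(C - h / 2)) / h
    slope = (4 * d2 - d1) / 3
    return C + (A - f(C)) / slope


def make_fit(B, C, A=0.0, D=100.0, cov=None):
    cov = np.zeros((2, 2)) if cov is None else np.asarray(cov, float)
    return SigmoidFit(A=A, D=D, B=B, C=C, cov_BC=cov, residual_sd=0.0,
                      fit_window=(FI, 4000.0))


class TestFitSigmoid:
    def test_noiseless_model_recovered_exactly(self):
        curve = model_curve(A=0.0, D=100.0, B=5.0, C=1000.0)
        fit = fit_sigmoid(curve, A=0.0, D=100.0)
        assert fit.B == pytest.approx(5.0, rel=1e-6)
        assert fit.C == pytest.approx(1000.0, rel=1e-6)

    def test_noisy_mean_c_within_combined_standard_errors(self):
        """Monte Carlo over 50 seeds: the mean C estimate is unbiased."""
        cs, sds = [], []
        for seed in range(50):
            rng = np.random.default_rng(seed)
            clean = model_curve(A=0.0, D=100.0, B=5.0, C=1000.0)
            noisy = clean.with_signal(clean.y + rng.normal(0, 1.0, len(clean)))
            fit = fit_sigmoid(noisy, A=0.0, D=100.0)
            cs.append(fit.C)
            sds.append(np.sqrt(fit.cov_BC[1, 1]))
        mean_c = np.mean(cs)
        se = np.mean(sds) / np.sqrt(len(cs))
        assert abs(mean_c - 1000.0) < 3 * se

    def test_constant_curve_low_contrast(self):
        flat = SampledCurve(FI * (1 + np.arange(32)), np.full(32, 7.0), FI)
        with pytest.raises(LowContrastError):
            fit_sigmoid(flat, A=7.0, D=7.0)

    def test_fit_window_must_be_positive_time(self):
        curve = model_curve(0.0, 100.0, 5.0, 1000.0)
        with pytest.raises(ValueError, match="t > 0"):
            fit_sigmoid(curve, A=0.0, D=100.0, fit_window=(0.0, 2000.0))

    def test_covariance_symmetric_psd(self, rng):
        clean = model_curve(A=0.0, D=100.0, B=5.0, C=1000.0)
        noisy = clean.with_signal(clean.y + rng.normal(0, 0.5, len(clean)))
        fit = fit_sigmoid(noisy, A=0.0, D=100.0)
        assert np.allclose(fit.cov_BC, fit.cov_BC.T)
        assert np.all(np.linalg.eigvalsh(fit.cov_BC) >= -1e-12)


class TestArrivalTime:
    def test_half_rise_case_matches_oracle(self):
        est = arrival_time(make_fit(B=4.0, C=1000.0))
        assert est.t0 == pytest.approx(500.0, rel=1e-12)
        assert est.t0 == pytest.approx(numeric_tangent_t0(0.0, 100.0, 4.0, 1000.0), rel=1e-6)

    @pytest.mark.parametrize("B", [2.1, 3.0, 5.0, 10.0, 25.0, 50.0])
    @pytest.mark.parametrize("C", [100.0, 800.0, 1600.0, 3000.0])
    def test_closed_form_agrees_with_numeric_tangent(self, B, C):
        est = arrival_time(make_fit(B=B, C=C))
        assert est.t0 == pytest.approx(numeric_tangent_t0(0.0, 100.0, B, C), rel=1e-9)

    def test_step_limit_arrives_at_inflection(self):
        est = arrival_time(make_fit(B=1e7, C=1234.0))
        assert est.t0 == pytest.approx(1234.0, rel=1e-6)

    def test_boundary_steepness_flagged_unstable(self):
        est = arrival_time(make_fit(B=2.0, C=800.0))
        assert est.t0 == pytest.approx(0.0, abs=1e-9)
        assert est.quality_flag == "unstable"

    def test_sd_propagates_covariance_term(self):
        B, C = 5.0, 1000.0
        cov = np.array([[0.04, 0.3], [0.3, 25.0]])
        est = arrival_time(make_fit(B=B, C=C, cov=cov))
        g = np.array([2 * C / B**2, 1 - 2 / B])
        assert est.sd_t0 == pytest.approx(float(np.sqrt(g @ cov @ g)), rel=1e-12)

    def test_sd_shrinks_with_noise_averaging(self):
        """Averaging n independent noisy replicates shrinks sd_t0 ~ 1/sqrt(n)."""
        clean = model_curve(A=0.0, D=100.0, B=5.0, C=1000.0)

        def mean_sd(n_avg, n_rep=10):
            sds = []
            for rep in range(n_rep):
                rng = np.random.default_rng(1000 + rep)
                noisy = np.mean(
                    [clean.y + rng.normal(0, 2.0, len(clean)) for _ in range(n_avg)],
                    axis=0,
                )
                fit = fit_sigmoid(clean.with_signal(noisy), A=0.0, D=100.0)
                sds.append(arrival_time(fit).sd_t0)
            return np.mean(sds)

        ratio = mean_sd(1) / mean_sd(16)
        assert 2.5 < ratio < 6.5  # ideal sqrt(16) = 4


class TestEstimateArrival:
    def test_time_shift_equivariance_within_one_frame(self, noiseless_config):
        base = generate_voxel_curve("RV", noiseless_config)
        est0, _ = estimate_arrival(base, pre_window=400.0)
        delta = 10 * FI
        shifted = SampledCurve(base.t, np.interp(base.t - delta, base.t, base.y), FI)
        est1, _ = estimate_arrival(shifted, pre_window=400.0)
        assert est1.t0 - est0.t0 == pytest.approx(delta, abs=FI)


class TestArrivalMap:
    def test_noiseless_phantom_rv_voxels_hit_truth(self, noiseless_config):
        series, truth = generate_first_pass_phantom(noiseless_config)
        amap = arrival_map(series, truth.masks["RV"], noiseless_config.frame_interval,
                           pre_window=400.0)
        assert np.all(amap.quality[truth.masks["RV"]])
        errs = amap.t0[truth.masks["RV"]] - truth.arrival["RV"]
        assert np.max(np.abs(errs)) < FI

    def test_background_mask_yields_empty_quality(self, noiseless_config):
        series, truth = generate_first_pass_phantom(noiseless_config)
        bg = ~(truth.masks["RV"] | truth.masks["lung"] | truth.masks["LV"])
        sub = np.zeros_like(bg)
        sub[0, 0, 0] = sub[5, 0, 0] = True  # two background voxels suffice
        amap = arrival_map(series, sub & bg, noiseless_config.frame_interval)
        assert not amap.quality.any()

    def test_identical_curves_identical_estimates(self, noiseless_config):
        series, truth = generate_first_pass_phantom(noiseless_config)
        mask = np.zeros(noiseless_config.grid, dtype=bool)
        vox = np.argwhere(truth.masks["RV"])[:2]
        for v in vox:
            mask[tuple(v)] = True
        amap = arrival_map(series, mask, noiseless_config.frame_interval)
        t0s = amap.t0[mask]
        assert t0s[0] == t0s[1]

    def test_shape_mismatch_raises(self):
        with pytest.raises(ValueError):
            arrival_map(np.zeros((4, 4, 4, 10)), np.zeros((4, 4), bool), FI)
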