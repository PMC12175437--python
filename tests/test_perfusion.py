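"""Fermi-deconvolution perfusion: first-pass extraction, preprocessing,
fitting, and the MBF/MPR chain, checked against generator round trips and
a brute-force grid-search oracle."""

import numpy as np
import pytest

from hfpefcmr import (
    AIFParams,
    FermiFit,
    SignalCurve,
    TissueGenParams,
    compute_mpr,
    extract_first_pass,
    fermi_response,
    fit_fermi_deconvolution,
    gamma_variate_aif,
    mbf_from_fit,
    preprocess_pair,
    quantify_study,
    scale_aif,
    synth_perfusion_study,
    synth_tissue_curve,
)


class TestFermiResponse:
    def test_initial_value(self):
        # R(0) = A / (exp(-mu/k) + 1)
        assert fermi_response(0.0, 1.0, 0.0, 1.0) == pytest.approx(0.5)
        assert fermi_response(0.0, 2.0, 50.0, 1.0) == pytest.approx(2.0)

    def test_limits(self):
        assert fermi_response(1e6, 1.0, 2.0, 1.0) == pytest.approx(0.0, abs=1e-12)

    def test_monotone_non_increasing(self):
        t = np.linspace(0, 30, 301)
        r = fermi_response(t, 1.5, 4.0, 1.2)
        assert np.all(np.diff(r) <= 1e-15)

    def test_invalid_width_rejected(self):
        with pytest.raises(ValueError, match="k must be positive"):
            fermi_response(0.0, 1.0, 1.0, 0.0)


class TestFirstPassExtraction:
    def test_monotone_tail_runs_to_last_sample(self, aif_params, time_grid):
        aif = gamma_variate_aif(aif_params, time_grid)
        fp = extract_first_pass(aif)
        assert fp.times[-1] == time_grid[-1]
        # window opens on flat baseline at or before the bolus onset and
        # the baseline level is subtracted
        assert fp.times[0] <= 8.5
        assert fp.values[0] == pytest.approx(0.0, abs=1e-9)
        assert fp.values.max() == pytest.approx(50.0, rel=1e-9)

    def test_two_lobe_curve_stops_at_interlobe_minimum(self, time_grid):
        # bolus plus a later recirculation bump: exhaustive scan locates
        # the interior minimum the window must end at
        p1 = AIFParams(onset_time=8.0, amplitude=50.0, baseline=5.0)
        p2 = AIFParams(onset_time=30.0, amplitude=20.0, baseline=0.0)
        v = (gamma_variate_aif(p1, time_grid).values
             + gamma_variate_aif(p2, time_grid).values)
        curve = SignalCurve(time_grid, v, baseline_window=(0, 10))
        fp = extract_first_pass(curve, detect_width=1)
        peak = int(np.argmax(v))
        interior = [j for j in range(peak + 1, len(v) - 1)
                    if v[j] <= v[j - 1] and v[j] < v[j + 1]]
        assert fp.times[-1] == time_grid[interior[0]]
        # default smoothed detection lands within its stencil of the oracle
        fp_sm = extract_first_pass(curve)
        assert abs(fp_sm.times[-1] - time_grid[interior[0]]) <= 2 * curve.dt

    def test_flat_curve_raises(self):
        flat = SignalCurve(np.arange(20.0), np.full(20, 3.0), baseline_window=(0, 5))
        with pytest.raises(ValueError, match="no first pass"):
            extract_first_pass(flat)

    def test_noise_below_threshold_not_an_onset(self, rng):
        base = rng.normal(10.0, 0.5, 40)
        bump = np.r_[np.zeros(20), 40.0 * np.hanning(20)]
        curve = SignalCurve(np.arange(40.0), base + bump, baseline_window=(0, 15))
        fp = extract_first_pass(curve)
        # detection fires near the true bump start, not in the noise floor
        assert fp.times[0] >= 14.0


class TestPreprocessing:
    def test_width_one_is_identity(self, aif_params, time_grid):
        aif = extract_first_pass(gamma_variate_aif(aif_params, time_grid))
        tis = extract_first_pass(
            synth_tissue_curve(gamma_variate_aif(aif_params, time_grid),
                               TissueGenParams(true_mbf=1.0), seed=0))
        pair = preprocess_pair(aif, tis, smooth_width=1)
        n = pair.aif.n
        np.testing.assert_allclose(pair.aif.values, aif.values[:n])

    def test_constructed_delay_detected_as_three_samples(self, aif_params, time_grid):
        aif_full = gamma_variate_aif(aif_params, time_grid)
        tissue = synth_tissue_curve(aif_full, TissueGenParams(true_mbf=1.0), seed=0)
        delayed = SignalCurve(time_grid,
                              np.r_[np.zeros(3), tissue.values[:-3]],
                              baseline_window=(0, 10))
        pair = preprocess_pair(extract_first_pass(aif_full),
                               extract_first_pass(delayed))
        assert pair.shift_samples == 3

    def test_even_or_oversized_width_rejected(self, aif_params, time_grid):
        aif = extract_first_pass(gamma_variate_aif(aif_params, time_grid))
        with pytest.raises(ValueError, match="odd"):
            preprocess_pair(aif, aif, smooth_width=2)
        with pytest.raises(ValueError, match="length"):
            preprocess_pair(aif, aif, smooth_width=9999)

    def test_smoothing_preserves_interior_mean(self, time_grid):
        # interior-supported bump: moving average conserves mass
        v = np.r_[np.zeros(40), 10.0 * np.hanning(30), np.zeros(50)]
        c = SignalCurve(time_grid, v, baseline_window=(0, 20))
        fp = extract_first_pass(c)
        pair = preprocess_pair(fp, fp, smooth_width=3)
        assert pair.aif.values.mean() == pytest.approx(
            fp.values[: pair.aif.n].mean(), rel=0.01)


class TestAIFScaling:
    def test_identity_and_dose_ratio(self, aif_params, time_grid):
        aif = gamma_variate_aif(aif_params, time_grid)
        assert scale_aif(aif, 1.0).to_frame().equals(aif.to_frame())
        scaled = scale_aif(aif, 10.0)  # 0.0375 / 0.00375 dosing ratio
        assert scaled.values.max() == pytest.approx(10.0 * aif.values.max())

    def test_scaling_commutes_with_integration(self, aif_params, time_grid):
        aif = gamma_variate_aif(aif_params, time_grid)
        assert np.trapezoid(scale_aif(aif, 7.0).values, aif.times) == pytest.approx(
            7.0 * np.trapezoid(aif.values, aif.times))


def _fit_study_state(study, state="rest", smooth_width=3):
    from hfpefcmr.perfusion import PerfusionStudy  # noqa: F401 (doc import)

    aif_fp = extract_first_pass(study.aif_low_bolus)
    tissue = {"rest": study.tissue_high_bolus_rest,
              "stress": study.tissue_high_bolus_stress}[state]
    pair = preprocess_pair(aif_fp, extract_first_pass(tissue), smooth_width)
    aif_scaled = scale_aif(pair.aif, study.scaling_factor)
    return fit_fermi_deconvolution(aif_scaled, pair.tissue), pair


class TestFermiFit:
    def test_noiseless_round_trip_recovers_mbf(self, noiseless_study):
        fit, _ = _fit_study_state(noiseless_study, "rest")
        mbf = mbf_from_fit(fit, allow_unconverged=True).mbf
        assert mbf == pytest.approx(1.0, rel=1e-3)

    def test_null_tissue_gives_zero_mbf(self, aif_params, time_grid):
        aif_fp = extract_first_pass(gamma_variate_aif(aif_params, time_grid))
        pair = preprocess_pair(aif_fp, aif_fp, smooth_width=1)
        zero_tissue = pair.tissue.with_values(np.zeros(pair.tissue.n))
        fit = fit_fermi_deconvolution(pair.aif, zero_tissue)
        assert mbf_from_fit(fit, allow_unconverged=True).mbf == pytest.approx(
            0.0, abs=1e-9)

    def test_scale_equivariance_of_tissue(self, noiseless_study):
        fit1, pair = _fit_study_state(noiseless_study, "rest")
        aif_scaled = scale_aif(pair.aif, noiseless_study.scaling_factor)
        doubled = pair.tissue.with_values(2.0 * pair.tissue.values)
        fit2 = fit_fermi_deconvolution(aif_scaled, doubled)
        m1 = mbf_from_fit(fit1, allow_unconverged=True).mbf
        m2 = mbf_from_fit(fit2, allow_unconverged=True).mbf
        assert m2 == pytest.approx(2.0 * m1, rel=1e-6)

    def test_aif_scaling_reciprocity(self, noiseless_study):
        fit1, pair = _fit_study_state(noiseless_study, "rest")
        aif_scaled = scale_aif(pair.aif, noiseless_study.scaling_factor)
        aif_x3 = scale_aif(aif_scaled, 3.0)
        fit3 = fit_fermi_deconvolution(aif_x3, pair.tissue)
        m1 = mbf_from_fit(fit1, allow_unconverged=True).mbf
        m3 = mbf_from_fit(fit3, allow_unconverged=True).mbf
        assert m3 == pytest.approx(m1 / 3.0, rel=1e-6)

    def test_mismatched_grids_rejected(self, aif_params, time_grid):
        aif_fp = extract_first_pass(gamma_variate_aif(aif_params, time_grid))
        pair = preprocess_pair(aif_fp, aif_fp)
        other = SignalCurve(pair.tissue.times + 0.25, pair.tissue.values)
        with pytest.raises(ValueError, match="grid"):
            fit_fermi_deconvolution(pair.aif, other)

    def test_fermifit_invariants(self):
        with pytest.raises(ValueError):
            FermiFit(A=-1.0, mu=0.0, k=1.0)
        with pytest.raises(ValueError):
            FermiFit(A=1.0, mu=0.0, k=0.0)


class TestMBFAndMPR:
    def test_initial_value_conversion(self):
        fit = FermiFit(A=1.0, mu=0.0, k=1.0)
        assert mbf_from_fit(fit).mbf == pytest.approx(0.5)
        sat = FermiFit(A=2.0, mu=500.0, k=1.0)  # mu >> k saturates to A
        assert mbf_from_fit(sat).mbf == pytest.approx(2.0, rel=1e-9)
        assert mbf_from_fit(fit, unit_conversion=2.0).mbf == pytest.approx(1.0)

    def test_mpr_ratio_and_zero_rest_failure(self):
        fit = FermiFit(A=1.0, mu=4.0, k=1.0)
        rest = mbf_from_fit(fit, state="rest")
        stress = mbf_from_fit(FermiFit(A=2.0, mu=4.0, k=1.0), state="stress")
        assert compute_mpr(stress, rest).mpr == pytest.approx(2.0)
        zero = mbf_from_fit(FermiFit(A=0.0, mu=4.0, k=1.0))
        with pytest.raises(ZeroDivisionError):
            compute_mpr(stress, zero)

    def test_mpr_invariant_under_common_unit_conversion(self, noiseless_study):
        r1 = quantify_study(noiseless_study, unit_conversion=1.0)
        r2 = quantify_study(noiseless_study, unit_conversion=3.7)
        assert r2.mpr == pytest.approx(r1.mpr, rel=1e-9)
        assert r1.mpr == pytest.approx(2.27, rel=1e-3)


class TestGridSearchOracle:
    def test_grid_search_matches_damped_least_squares_rss(self):
        # 16-sample toy; exhaustive (mu, k) grid at 0.01 resolution with
        # the amplitude profiled out in closed form (the model is linear
        # in A), compared to the optimizer's minimum RSS
        dt = 1.0
        lags = np.arange(16) * dt
        aif_v = np.r_[0.0, 2.0, 8.0, 15.0, 18.0, 16.0, 12.0, 8.0, 5.0,
                      3.0, 2.0, 1.2, 0.8, 0.5, 0.3, 0.2]
        true = (0.8, 3.0, 1.5)
        r = true[0] / (np.exp((lags - true[1]) / true[2]) + 1.0)
        tissue_v = dt * np.convolve(aif_v, r)[:16]
        rng = np.random.default_rng(77)
        tissue_v = tissue_v + rng.normal(0.0, 0.02 * tissue_v.max(), 16)
        grid = np.arange(16) * dt
        aif = SignalCurve(grid, aif_v)
        tissue = SignalCurve(grid, tissue_v)
        fit = fit_fermi_deconvolution(aif, tissue)

        # brute force: conv matrix M[l, t] = dt * aif[t - l]
        M = np.zeros((16, 16))
        for l in range(16):
            M[l, l:] = dt * aif_v[: 16 - l]
        mus = np.arange(0.0, 8.0 + 1e-9, 0.01)
        ks = np.arange(0.1, 4.0 + 1e-9, 0.01)
        mu_g, k_g = np.meshgrid(mus, ks, indexing="ij")
        mu_f, k_f = mu_g.ravel(), k_g.ravel()
        R = 1.0 / (np.exp(np.clip((lags[None, :] - mu_f[:, None]) / k_f[:, None],
                                  -700, 700)) + 1.0)
        models = R @ M  # unit-amplitude predictions
        my = models @ tissue_v
        mm = np.einsum("ij,ij->i", models, models)
        a_opt = np.clip(my / mm, 0.0, None)
        rss = (tissue_v @ tissue_v) - 2.0 * a_opt * my + a_opt**2 * mm
        assert fit.rss == pytest.approx(float(rss.min()), rel=0.01)
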