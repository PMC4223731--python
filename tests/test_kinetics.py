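"""Mono-exponential model, Gauss-Newton fit, Neill test, QC classifier."""
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import o2kin as ok
from o2kin.kinetics import (
    LackOfFitNotComputable,
    fit_monoexponential,
    model_vo2,
    neill_lack_of_fit,
)

from conftest import window_midpoints


class TestModel:
    def test_lower_limit_at_zero(self):
        assert model_vo2(0.0, 300, 1300, 1.0) == pytest.approx(300.0)

    def test_asymptote(self):
        assert model_vo2(40.0, 300, 1300, 1.0) == pytest.approx(1300.0, abs=1e-9)

    def test_rise_fraction_at_tau_is_63pct(self):
        y = model_vo2(1.0, 300, 1300, 1.0)
        frac = 100 * (y - 300) / (1300 - 300)
        assert round(frac) == 63

    def test_tau_must_be_positive(self):
        with pytest.raises(ValueError):
            model_vo2(1.0, 300, 1300, 0.0)

    @given(st.floats(0.01, 30), st.floats(0.01, 30))
    @settings(max_examples=50, deadline=None)
    def test_strictly_increasing(self, a, b):
        lo, hi = sorted([a, b])
        if hi - lo < 1e-9:
            return
        assert model_vo2(hi, 300, 1300, 1.3) > model_vo2(lo, 300, 1300, 1.3)


class TestFit:
    @pytest.mark.parametrize("y1,y2,tau", [(300, 1300, 1.0), (250, 900, 0.6),
                                           (400, 2400, 1.5)])
    def test_exact_recovery_on_noiseless_grid(self, y1, y2, tau):
        t = window_midpoints()
        f = fit_monoexponential(t, model_vo2(t, y1, y2, tau))
        assert f.converged
        for est, true in ((f.y1, y1), (f.y2, y2), (f.tau, tau)):
            assert abs(est - true) / true < 1e-6

    def test_exact_recovery_on_raw_breaths(self, clean_series, clean_truth):
        walk = clean_series.phase("walk")
        t = (walk["time_s"].to_numpy() - clean_series.walk_start_s) / 60.0
        f = fit_monoexponential(t, walk["vo2_mlmin"].to_numpy())
        assert abs(f.tau - clean_truth.tau) < 1e-6
        assert abs(f.y1 - clean_truth.vo2_rest) / clean_truth.vo2_rest < 1e-6
        assert abs(f.y2 - clean_truth.vo2_ss) / clean_truth.vo2_ss < 1e-6

    def test_windowing_shifts_tau_less_than_1pct(self):
        """Smoothing bias: 20 s averaging of a noiseless exponential moves
        the recovered tau by under 1% relative to fitting raw breaths."""
        import pandas as pd
        from test_preprocess import make_series

        t_s = np.arange(0.6, 360, 2.7)  # regular ~22/min breathing
        y = model_vo2(t_s / 60.0, 300, 1300, 1.0)
        s = make_series(t_s, y)
        raw = fit_monoexponential(t_s / 60.0, y)
        win = ok.fit_kinetics(ok.window_average(s))
        assert abs(win.tau - raw.tau) / raw.tau < 0.01

    def test_matches_levenberg_marquardt_oracle(self, noisy_fit):
        """Independent optimizer (scipy curve_fit) finds the same minimum."""
        from scipy.optimize import curve_fit

        fit, w = noisy_fit
        t = w.midpoint_s / 60.0
        popt, _ = curve_fit(
            lambda t, y1, y2, tau: y2 - (y2 - y1) * np.exp(-t / tau),
            t, w.vo2_mlmin, p0=(300.0, 1300.0, 1.0),
        )
        assert np.allclose([fit.y1, fit.y2, fit.tau], popt, rtol=1e-4)

    def test_monte_carlo_tau_recovery(self):
        """18 windows with heavy window-level noise (SD 50 ml/min, 5% of
        the rise): tau-hat stays unbiased (2 SE) with bounded scatter."""
        t = window_midpoints()
        rng = np.random.default_rng(42)
        taus = []
        for _ in range(200):
            y = model_vo2(t, 300, 1300, 1.0) + rng.normal(0, 50, len(t))
            f = fit_monoexponential(t, y)
            if f.converged:
                taus.append(f.tau)
        taus = np.array(taus)
        assert len(taus) >= 190
        se = taus.std(ddof=1) / np.sqrt(len(taus))
        assert abs(taus.mean() - 1.0) < 2 * se
        assert np.sqrt(np.mean((taus - 1.0) ** 2)) < 0.15

    def test_constant_series_degenerate(self):
        with pytest.raises(ok.DegenerateFitError):
            fit_monoexponential(window_midpoints(), np.full(18, 700.0))

    def test_too_few_windows_rejected(self):
        with pytest.raises(ValueError):
            fit_monoexponential(np.array([0.1, 0.2, 0.3, 0.4]),
                                np.array([1.0, 2.0, 3.0, 4.0]))

    def test_translation_moves_limits_not_tau(self, noisy_fit):
        fit, w = noisy_fit
        t = w.midpoint_s / 60.0
        f2 = fit_monoexponential(t, w.vo2_mlmin + 500.0)
        assert f2.tau == pytest.approx(fit.tau, rel=1e-6)
        assert f2.y1 - fit.y1 == pytest.approx(500.0, rel=1e-6)
        assert f2.y2 - fit.y2 == pytest.approx(500.0, rel=1e-6)

    def test_seconds_axis_rescales_tau_by_60(self, noisy_fit):
        fit, w = noisy_fit
        fs = fit_monoexponential(w.midpoint_s, w.vo2_mlmin, time_unit="s")
        assert fs.tau == pytest.approx(60.0 * fit.tau, rel=1e-6)
        assert fs.tau_min == pytest.approx(fit.tau_min, rel=1e-6)
        # rise fraction at t = tau is unit-free
        for f, tt in ((fit, fit.tau), (fs, fs.tau)):
            frac = (f.predict(tt) - f.y1) / (f.y2 - f.y1)
            assert frac == pytest.approx(1 - np.exp(-1), rel=1e-9)

    def test_residuals_centred(self, noisy_fit):
        fit, _ = noisy_fit
        assert abs(fit.residuals.mean()) < 0.01 * fit.delta_vo2

    def test_gauss_newton_beats_coarse_grid(self, noisy_fit):
        """GN SSR never exceeds the best of a 50^3 brute-force grid."""
        fit, w = noisy_fit
        t = w.midpoint_s / 60.0
        y = w.vo2_mlmin
        g1 = np.linspace(y.min() - 100, y.min() + 200, 50)
        g2 = np.linspace(y.max() - 200, y.max() + 100, 50)
        gt = np.linspace(0.1, 3.0, 50)
        best = np.inf
        for tau in gt:
            e = np.exp(-t / tau)
            pred = (g2[None, :, None] -
                    (g2[None, :, None] - g1[:, None, None]) * e[None, None, :])
            ssr = ((y[None, None, :] - pred) ** 2).sum(axis=2)
            best = min(best, ssr.min())
        assert fit.ssr <= best + 1e-9


class TestNeill:
    def test_type_one_error_calibrated(self):
        """Under the true model the 5% Neill test rejects ~5% of series."""
        t = window_midpoints()
        rng = np.random.default_rng(7)
        rej = tot = 0
        for _ in range(400):
            y = model_vo2(t, 300, 1300, 1.0) + rng.normal(0, 15, len(t))
            f = fit_monoexponential(t, y)
            if not f.converged:
                continue
            _, p = neill_lack_of_fit(f)
            tot += 1
            rej += p < 0.05
        assert tot >= 380
        assert 0.02 <= rej / tot <= 0.08

    def test_detects_biphasic_misfit(self):
        t = window_midpoints()
        rng = np.random.default_rng(8)
        rej = tot = 0
        for _ in range(200):
            y = (1300 - 1000 * np.exp(-t / 0.3) - 300 * np.exp(-t / 4.0)
                 + rng.normal(0, 15, len(t)))
            f = fit_monoexponential(t, y)
            if not f.converged:
                continue
            _, p = neill_lack_of_fit(f)
            tot += 1
            rej += p < 0.05
        assert rej / tot > 0.5

    def test_zero_residuals_not_computable(self):
        t = window_midpoints()
        f = fit_monoexponential(t, model_vo2(t, 300, 1300, 1.0))
        with pytest.raises(LackOfFitNotComputable):
            neill_lack_of_fit(f)

    def test_bad_grouping_rejected(self, noisy_fit):
        fit, _ = noisy_fit
        with pytest.raises(ValueError):
            neill_lack_of_fit(fit, grouping=[0, 1])
        with pytest.raises(LackOfFitNotComputable):
            neill_lack_of_fit(fit, grouping=np.arange(18))  # singletons

    def test_unconverged_fit_rejected(self, noisy_fit):
        import dataclasses
        fit, _ = noisy_fit
        bad = dataclasses.replace(fit, converged=False)
        with pytest.raises(ValueError):
            neill_lack_of_fit(bad)


class TestQC:
    def test_failure_modes_recovered(self, noisy_truth, fixed_protocol):
        for mode in ("no_plateau", "variable_plateau"):
            spec = ok.FailureModeSpec(mode=mode)
            hits = 0
            for seed in range(50):
                s = ok.simulate_failure_mode(noisy_truth, spec, fixed_protocol,
                                             seed=seed)
                w = ok.window_average(s)
                try:
                    f = ok.fit_kinetics(w)
                except ok.DegenerateFitError:
                    continue
                hits += ok.classify_qc(f, w).status == mode
            assert hits >= 45, mode

    def test_clean_series_acceptable(self, noisy_truth, fixed_protocol):
        acc = 0
        for seed in range(50):
            s = ok.simulate_breath_series(noisy_truth, fixed_protocol, seed=seed)
            w = ok.window_average(s)
            f = ok.fit_kinetics(w)
            acc += ok.classify_qc(f, w).status == "acceptable"
        assert acc >= 48

    def test_not_converged_status(self, noisy_fit):
        import dataclasses
        fit, w = noisy_fit
        bad = dataclasses.replace(fit, converged=False)
        assert ok.classify_qc(bad, w).status == "not_converged"

    def test_cohort_adjustment_attached(self, noisy_fit):
        fit, w = noisy_fit
        _, p = neill_lack_of_fit(fit)
        qc = ok.classify_qc(fit, w, cohort_pvalues=[p, 0.5, 0.01, 0.9])
        assert qc.neill_p_adjusted >= qc.neill_p  # Holm never lowers p

    def test_adjusted_pvalues_monotone(self):
        raw = [0.001, 0.04, 0.2, 0.8]
        adj = ok.adjust_pvalues(raw)
        assert np.all(adj >= np.asarray(raw))
        assert np.all(adj <= 1.0)
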