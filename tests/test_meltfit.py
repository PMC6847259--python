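"""Plate normalization, two-state fitting, derivatives, hysteresis, kinetics."""

import numpy as np
import pytest

from tadsim.design import default_design, reaction_thermo
from tadsim.equilibrium import melt_profile, summarize
from tadsim.meltfit import (
    AlignmentError,
    DegenerateControlsError,
    KineticsModel,
    NormalizedCurve,
    TransitionRangeError,
    TwoStateMeltModel,
    UnidentifiableError,
    derivative,
    detect_hysteresis,
    fit_kinetics,
    normalize,
)
from tadsim.synth import SynthConfig, VantHoffTruth, generate_kinetics, generate_plate


def make_curve(T_d=50.0, dH=-80.0, b_lo=0.0, b_hi=1.0, lo=5.0, hi=65.0, step=1.0, sd=None):
    t = np.arange(lo, hi + 0.5 * step, step)
    f = VantHoffTruth(T_d=T_d, dH_vH=dH, b_lo=b_lo, b_hi=b_hi).f(t)
    return NormalizedCurve(T=t, f_mean=f, f_sd=sd if sd is not None else np.zeros_like(t))


class TestNormalize:
    def test_sample_identical_to_positive_control_is_one(self):
        cfg = SynthConfig(truth=VantHoffTruth(T_d=50.0), noise_sd=0.0)
        plate = generate_plate(cfg, seed=0)
        pos = plate[plate.role == "positive_control"].assign(role="sample", condition="copy")
        plate = __import__("pandas").concat([plate, pos], ignore_index=True)
        curves = normalize(plate)
        assert np.allclose(curves[("copy", "melt")].f_mean, 1.0, atol=1e-12)

    def test_sample_identical_to_negative_control_is_zero(self):
        cfg = SynthConfig(truth=VantHoffTruth(T_d=50.0), noise_sd=0.0)
        plate = generate_plate(cfg, seed=0)
        neg = plate[plate.role == "negative_control"].assign(role="sample", condition="copy")
        plate = __import__("pandas").concat([plate, neg], ignore_index=True)
        curves = normalize(plate)
        assert np.allclose(curves[("copy", "melt")].f_mean, 0.0, atol=1e-12)

    def test_idempotent_with_ideal_controls(self):
        cfg = SynthConfig(truth=VantHoffTruth(T_d=50.0), noise_sd=0.0, neg_level=0.0, gain=1.0)
        plate = generate_plate(cfg, seed=0)
        c1 = normalize(plate)[("sample", "melt")]
        # feed the normalized values back through as signals with 0/1 controls
        plate2 = plate.copy()
        key = plate2.role == "sample"
        plate2.loc[key, "signal"] = np.concatenate(
            [c1.f_mean[::-1] if r == "anneal" else c1.f_mean
             for r in ("anneal", "melt") for _ in range(cfg.replicates)]
        )
        c2 = normalize(plate2)[("sample", "melt")]
        assert np.allclose(c2.f_mean, c1.f_mean, atol=1e-12)

    def test_noisy_plate_mean_close_to_truth(self):
        # per-point sd of the replicate mean is ~0.011 (0.02 sample noise
        # plus independent control-well noise, averaged over 5 replicates);
        # bound the worst of ~61 grid points at 4 sigma and the mean at 1.5
        cfg = SynthConfig(truth=VantHoffTruth(T_d=50.0, dH_vH=-80.0), noise_sd=0.02, replicates=5)
        plate = generate_plate(cfg, seed=5)
        c = normalize(plate)[("sample", "melt")]
        truth = VantHoffTruth(T_d=50.0, dH_vH=-80.0).f(c.T)
        dev = np.abs(c.f_mean - truth)
        assert np.max(dev) < 0.045
        assert np.mean(dev) < 0.017

    def test_degenerate_controls_error_names_temperature(self):
        cfg = SynthConfig(truth=VantHoffTruth(T_d=50.0), noise_sd=0.0)
        plate = generate_plate(cfg, seed=0)
        bad = (plate.role == "positive_control") & (plate.temperature_C == 40.0)
        plate.loc[bad, "signal"] = 0.0
        with pytest.raises(DegenerateControlsError, match="40"):
            normalize(plate)


class TestTwoStateFit:
    def test_noiseless_self_consistency(self):
        fit = TwoStateMeltModel(make_curve(T_d=50.0, dH=-80.0)).fit()
        assert fit.T_half == pytest.approx(50.0, rel=1e-6, abs=1e-6)
        assert fit.dH_vH == pytest.approx(-80.0, rel=1e-6)
        assert fit.baseline_lo == pytest.approx(0.0, abs=1e-8)
        assert fit.baseline_hi == pytest.approx(1.0, abs=1e-8)

    def test_noisy_plate_recovers_T_d(self):
        cfg = SynthConfig(truth=VantHoffTruth(T_d=50.0, dH_vH=-80.0), noise_sd=0.02, replicates=5)
        c = normalize(generate_plate(cfg, seed=3))[("sample", "melt")]
        fit = TwoStateMeltModel(c).fit()
        assert fit.T_half == pytest.approx(50.0, abs=0.2)

    def test_midpoint_is_half_of_baselines(self):
        fit = TwoStateMeltModel(make_curve(T_d=47.0, dH=-95.0, b_lo=0.05, b_hi=0.92)).fit()
        mid = fit.predict(np.array([fit.T_half]))[0]
        assert mid == pytest.approx((fit.baseline_lo + fit.baseline_hi) / 2, abs=1e-9)

    def test_insufficient_span_raises(self):
        with pytest.raises(TransitionRangeError):
            TwoStateMeltModel(make_curve(T_d=80.0, lo=5.0, hi=40.0)).fit()

    def test_summary_mentions_estimates(self):
        fit = TwoStateMeltModel(make_curve()).fit()
        text = fit.summary()
        assert "T_d" in text and "dH_vH" in text

    def test_matches_equilibrium_model_T_d(self, cal_params):
        """Fitting the mechanistic equilibrium curve with the empirical
        two-state sigmoid reproduces its T_d within 0.3 C."""
        d = default_design(N=2, L=8)
        rt = reaction_thermo(d, cal_params)
        p = melt_profile(d, rt, 25.0, 70.0, 0.5)
        s = summarize(p)
        fit = TwoStateMeltModel.from_arrays(p.T_grid, p.f).fit()
        assert fit.T_half == pytest.approx(s.T_d, abs=0.3)


class TestDerivative:
    def test_extremum_at_midpoint(self):
        fit = TwoStateMeltModel(make_curve(T_d=50.0, dH=-80.0)).fit()
        grid = np.arange(30.0, 70.0, 0.05)
        _, dfdT = derivative(fit, grid)
        assert grid[np.argmin(dfdT)] == pytest.approx(fit.T_half, abs=0.1)

    def test_integral_equals_baseline_drop(self):
        fit = TwoStateMeltModel(make_curve(T_d=50.0, dH=-80.0)).fit()
        grid = np.arange(0.0, 100.0, 0.01)
        _, dfdT = derivative(fit, grid)
        assert np.trapezoid(dfdT, grid) == pytest.approx(fit.baseline_lo - fit.baseline_hi, abs=1e-3)

    def test_sharper_transition_has_deeper_extremum(self):
        f1 = TwoStateMeltModel(make_curve(dH=-60.0)).fit()
        f2 = TwoStateMeltModel(make_curve(dH=-120.0)).fit()
        g = np.arange(30.0, 70.0, 0.05)
        assert np.min(derivative(f2, g)[1]) < np.min(derivative(f1, g)[1])


class TestHysteresis:
    def test_identical_curves_no_flag(self):
        c = make_curve()
        rep = detect_hysteresis(c, c)
        assert rep.max_abs_gap == 0.0 and not rep.flag

    def test_shifted_steep_transition_flags(self):
        a = make_curve(T_d=50.0, dH=-120.0)
        m = make_curve(T_d=52.0, dH=-120.0)
        rep = detect_hysteresis(a, m)
        assert rep.flag and rep.max_abs_gap > 0.05

    def test_gap_exactly_at_threshold_does_not_flag(self):
        t = np.arange(5.0, 65.0, 1.0)
        a = NormalizedCurve(T=t, f_mean=np.zeros_like(t), f_sd=np.zeros_like(t))
        m = NormalizedCurve(T=t, f_mean=np.full_like(t, 0.05), f_sd=np.zeros_like(t))
        assert not detect_hysteresis(a, m, threshold=0.05).flag

    def test_grid_mismatch(self):
        with pytest.raises(AlignmentError):
            detect_hysteresis(make_curve(lo=5.0, hi=65.0), make_curve(lo=6.0, hi=66.0))


class TestKinetics:
    def test_recovers_half_life(self):
        tr = generate_kinetics(rate=np.log(2) / 10.0, plateau=1.0, f0=0.0, duration=120.0, dt=0.5)
        res = fit_kinetics(tr.time_s, tr.f)
        assert res.half_life == pytest.approx(10.0, rel=0.01)
        assert res.rate == pytest.approx(np.log(2) / 10.0, rel=0.01)

    def test_flat_trace_is_unidentifiable(self):
        t = np.arange(0.0, 60.0, 1.0)
        with pytest.raises(UnidentifiableError):
            fit_kinetics(t, np.full_like(t, 0.8))

    def test_short_trace_is_unidentifiable(self):
        tr = generate_kinetics(rate=np.log(2) / 1e4, plateau=1.0, f0=0.0, duration=20.0, dt=1.0)
        with pytest.raises(UnidentifiableError):
            fit_kinetics(tr.time_s, tr.f)

    def test_non_monotone_warns(self):
        t = np.arange(0.0, 60.0, 1.0)
        f = np.sin(t / 5.0) * 0.4 + 0.5
        with pytest.warns(UserWarning, match="non-monotone"):
            try:
                KineticsModel(t, f).fit()
            except (UnidentifiableError, RuntimeError):
                pass

    def test_deactivation_direction(self):
        tr = generate_kinetics(rate=0.1, plateau=0.0, f0=1.0, duration=100.0, dt=0.5)
        res = fit_kinetics(tr.time_s, tr.f, direction="deactivation")
        assert res.direction == "deactivation"
        assert res.plateau == pytest.approx(0.0, abs=1e-6)
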