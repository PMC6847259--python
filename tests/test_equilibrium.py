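"""Equilibrium solver: brute-force oracles, closed-form T_d, trends, calibration."""

import math

import numpy as np
import pytest
from scipy.optimize import brentq

from tadsim.design import DEFAULT_DOMAINS, default_design, reaction_thermo
from tadsim.equilibrium import (
    CalibrationError,
    MeltProfile,
    calibrate_junction,
    crossing_temperature,
    design_scan,
    melt_profile,
    melt_summary_exact,
    solve_at_T,
    summarize,
)
from tadsim.thermo import CELSIUS_OFFSET, R_KCAL, DomainSeq, EnergyTerm


def brute_force_f(d, rt, T_K, n_grid=1_000_000):
    """Extent scan oracle: minimise |ln K - ln Q| over a dense grid."""
    is0 = min(d.I_total, d.S_total)
    i_free0 = d.I_total - is0
    x_max = min(is0, d.C)
    x = np.linspace(x_max * 1e-9, x_max * (1 - 1e-9), n_grid)
    lnq = (
        np.log(x)
        + np.log(i_free0 + x)
        - np.log(is0 - x)
        - d.n_ac * np.log(d.C - x)
    )
    lnk = -rt.rxn.dG(T_K) / (R_KCAL * T_K)
    return x[np.argmin(np.abs(lnq - lnk))] / d.S_total


def random_design(rng):
    n = int(rng.choice([0, 2, 4]))
    length = int(rng.integers(4, 9))
    alpha = DomainSeq("alpha", "".join(rng.choice(list("ACGT"), size=length)))
    return default_design(N=n, L=int(rng.integers(6, 11)), C=float(rng.uniform(2e-6, 3e-5))).replace(alpha=alpha)


class TestSolveAtT:
    def test_strongly_favorable_gives_full_displacement(self, params):
        d = default_design(N=2, L=10)
        rt = reaction_thermo(d, params)
        st = solve_at_T(d, rt, 274.0)  # deep cold: K enormous
        assert st.f == pytest.approx(1.0, abs=1e-6)

    def test_strongly_unfavorable_gives_none(self, params):
        d = default_design(N=2, L=10)
        rt = reaction_thermo(d, params)
        st = solve_at_T(d, rt, 399.0)
        assert st.f == pytest.approx(0.0, abs=1e-6)

    def test_matches_brute_force_extent_scan(self, params):
        rng = np.random.default_rng(11)
        for _ in range(25):
            d = random_design(rng)
            rt = reaction_thermo(d, params)
            T = float(rng.uniform(285.0, 370.0))
            f = solve_at_T(d, rt, T).f
            assert f == pytest.approx(brute_force_f(d, rt, T), abs=1e-6)

    def test_strand_conservation(self, params):
        rng = np.random.default_rng(3)
        for _ in range(10):
            d = random_design(rng)
            rt = reaction_thermo(d, params)
            st = solve_at_T(d, rt, float(rng.uniform(285, 370)))
            assert st.conservation_residual(d) < 1e-9

    def test_le_chatelier_in_fuel_concentration(self, params):
        d = default_design(N=2, L=8)
        for T in (300.0, 320.0, 340.0):
            fs = [
                solve_at_T(dd, reaction_thermo(dd, params), T).f
                for dd in (d, d.replace(C=d.C * 2), d.replace(C=d.C * 4))
            ]
            assert fs[0] <= fs[1] <= fs[2]

    def test_out_of_range_temperature(self, params):
        d = default_design()
        rt = reaction_thermo(d, params)
        with pytest.raises(Exception):
            solve_at_T(d, rt, 500.0)


class TestMeltProfile:
    def test_monotone_non_increasing(self, cal_params):
        for N in (0, 2, 4):
            d = default_design(N=N)
            p = melt_profile(d, reaction_thermo(d, cal_params), 5.0, 95.0, 0.5)
            assert np.all(np.diff(p.f) <= 1e-12)
            assert np.all(p.dfdT <= 1e-9)

    def test_grid_points_match_oracle(self, params):
        d = default_design(N=2, L=8)
        rt = reaction_thermo(d, params)
        p = melt_profile(d, rt, 30.0, 60.0, 5.0)
        for t, f in zip(p.T_grid, p.f):
            assert f == pytest.approx(brute_force_f(d, rt, t + CELSIUS_OFFSET), abs=1e-6)

    def test_invalid_grid(self, params):
        d = default_design()
        rt = reaction_thermo(d, params)
        with pytest.raises(ValueError):
            melt_profile(d, rt, 60.0, 5.0, 1.0)


class TestSummarize:
    def test_closed_form_oracle_for_T_d(self, cal_params):
        """T_d from the profile must match the closed-form root of
        dG(T) + RT ln Q_half = 0 evaluated directly on the analytic
        expression (no extent solver involved)."""
        d = default_design(N=2, L=8)
        rt = reaction_thermo(d, cal_params)
        x = 0.5 * d.S_total
        q_half = (x * x) / ((d.S_total - x) * (d.C - x) ** d.n_ac)

        def g(T):
            return rt.rxn.dG(T) + R_KCAL * T * math.log(q_half)

        t_closed = brentq(g, 260.0, 399.0) - CELSIUS_OFFSET
        p = melt_profile(d, rt, t_closed - 30, t_closed + 30, 0.1)
        s = summarize(p)
        assert s.T_d == pytest.approx(t_closed, abs=0.01)
        assert crossing_temperature(d, rt, 0.5) == pytest.approx(t_closed, abs=0.01)

    def test_translation_invariance(self):
        t = np.arange(20.0, 80.0, 0.1)
        f = 1.0 / (1.0 + np.exp((t - 50.0) / 2.0))
        p1 = MeltProfile(T_grid=t, f=f, dfdT=np.gradient(f, t))
        p2 = MeltProfile(T_grid=t + 5.0, f=f, dfdT=np.gradient(f, t))
        s1, s2 = summarize(p1), summarize(p2)
        assert s2.T_d - s1.T_d == pytest.approx(5.0, abs=1e-9)
        assert s2.delta_T == pytest.approx(s1.delta_T, abs=1e-9)

    def test_ordering_invariant(self, cal_params):
        s = melt_summary_exact(default_design(N=2, L=8), cal_params)
        d = default_design(N=2, L=8)
        rt = reaction_thermo(d, cal_params)
        t99 = crossing_temperature(d, rt, 0.99)
        t01 = crossing_temperature(d, rt, 0.01)
        assert t99 < s.T_d < t01
        assert s.delta_T == pytest.approx(t01 - t99, abs=1e-6)

    def test_larger_enthalpy_narrows_delta_T(self, cal_params):
        narrow = melt_summary_exact(default_design(N=2, L=10), cal_params)
        wide = melt_summary_exact(default_design(N=2, L=6), cal_params)
        assert narrow.delta_T < wide.delta_T

    def test_unbracketed_threshold_is_named(self, params):
        t = np.arange(40.0, 60.0, 0.5)
        f = np.linspace(0.6, 0.4, len(t))
        p = MeltProfile(T_grid=t, f=f, dfdT=np.gradient(f, t))
        with pytest.raises(ValueError, match="0.99"):
            summarize(p)


class TestDesignScan:
    def test_stem_length_trend(self, cal_params):
        tab = design_scan(default_design(N=2, L=8), "L", [6, 8, 10], cal_params)
        assert tab["T_d_C"].is_monotonic_increasing
        assert tab["delta_T_C"].is_monotonic_decreasing

    def test_stem_count_trend(self, cal_params):
        tab = design_scan(default_design(N=2, L=8), "N", [0, 2, 4], cal_params)
        assert tab["T_d_C"].is_monotonic_decreasing
        assert tab["delta_T_C"].is_monotonic_decreasing

    def test_concentration_trend(self, cal_params):
        tab = design_scan(default_design(N=2, L=8), "C", [3.16e-6, 1e-5, 3.16e-5], cal_params)
        assert tab["T_d_C"].is_monotonic_increasing
        spread = tab["delta_T_C"].max() / tab["delta_T_C"].min()
        assert spread < 1.2  # similar widths across a decade of C

    def test_unknown_parameter(self, cal_params):
        with pytest.raises(ValueError):
            design_scan(default_design(), "H_L", [4, 6], cal_params)


class TestCalibration:
    def test_fixed_point(self, cal_params):
        d = default_design(N=0)
        current = crossing_temperature(d, reaction_thermo(d, cal_params), 0.5)
        p2 = calibrate_junction(d, current, cal_params)
        assert p2.junction.dS == pytest.approx(cal_params.junction.dS, abs=0.5)

    def test_observed_62C_reproduced(self, params):
        d = default_design(N=0, H_L=6, H_l=4)
        cal = calibrate_junction(d, 62.0, params)
        t_d = crossing_temperature(d, reaction_thermo(d, cal), 0.5)
        assert t_d == pytest.approx(62.0, abs=0.05)

    def test_post_calibration_concentration_direction(self, cal_params):
        lo = melt_summary_exact(default_design(N=0, C=5e-6), cal_params).T_d
        hi = melt_summary_exact(default_design(N=0, C=20e-6), cal_params).T_d
        assert hi > lo

    def test_unattainable_target_reports_range(self, params):
        with pytest.raises(CalibrationError):
            calibrate_junction(default_design(N=0), 300.0, params)


def test_multistrand_association_entropy_lowers_T_d(cal_params):
    """Designs with near-equal net base pairing: the one consuming an extra
    strand melts lower once concentration entropy applies."""
    stem = default_design(N=2, L=8).blunt_stem
    alpha_long = DomainSeq("alpha", DEFAULT_DOMAINS["alpha"].bases + stem + stem)
    d_one_strand = default_design(N=0).replace(alpha=alpha_long)  # delta_bp = 22, 1 strand
    d_two_strand = default_design(N=2, L=8)  # delta_bp = 22, 2 strands
    t_one = melt_summary_exact(d_one_strand, cal_params).T_d
    t_two = melt_summary_exact(d_two_strand, cal_params).T_d
    assert t_two < t_one
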