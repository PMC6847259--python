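"""Mass-action kinetics of a single TAD displacement reaction.

The lumped reaction I.S + sum(AC_i) <=> AC.S + I is integrated as a
one-dimensional ODE in the extent x (mol/L):

    dx/dt = k_f(T) (IS0 - x) prod_i (C_i - x)  -  k_f(T)/K(T) x (I_free0 + x)

with the reverse rate fixed by detailed balance against the equilibrium
constant, so kinetic endpoints always agree with the equilibrium module.
Forward rates optionally carry an Arrhenius temperature dependence
(slower at lower temperature), which reproduces the slower operation
observed when switching at lower temperatures.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .design import TADDesign, reaction_thermo
from .equilibrium import log_K, solve_at_T
from .thermo import CELSIUS_OFFSET, R_KCAL, ThermoParams

__all__ = ["DisplacementKinetics", "FirstOrderReversible"]


@dataclass
class DisplacementKinetics:
    """ODE simulator for one TAD design.

    ``k_f_ref`` is the forward rate constant at ``T_ref_C`` in units
    M^-(n_ac) s^-1; the default 1e5 * 1000^(n_ac - 1) keeps effective
    bimolecular encounter rates at the conventional 1e5 M^-1 s^-1 scale.
    ``Ea`` (kcal/mol) sets the Arrhenius temperature dependence of the
    forward rate (0 disables it).
    """

    design: TADDesign
    params: ThermoParams
    k_f_ref: float | None = None
    Ea: float = 10.0
    T_ref_C: float = 37.0
    rtol: float = 1e-8

    def __post_init__(self) -> None:
        self.rt = reaction_thermo(self.design, self.params)
        if self.k_f_ref is None:
            self.k_f_ref = 1e5 * 1000.0 ** (self.design.n_ac - 1)

    def k_f(self, T_C: float) -> float:
        TK = T_C + CELSIUS_OFFSET
        Tref = self.T_ref_C + CELSIUS_OFFSET
        return self.k_f_ref * math.exp(-(self.Ea / R_KCAL) * (1.0 / TK - 1.0 / Tref) * 1.0)

    def equilibrium_f(self, T_C: float) -> float:
        return solve_at_T(self.design, self.rt, T_C + CELSIUS_OFFSET).f

    def _rhs(self, T_C: float):
        d = self.design
        is0 = min(d.I_total, d.S_total)
        i_free0 = d.I_total - is0
        kf = self.k_f(T_C)
        kr = kf / math.exp(log_K(self.rt, T_C + CELSIUS_OFFSET))
        n = d.n_ac

        def rhs(_t, y):
            x = y[0]
            fwd = kf * (is0 - x) * (d.C - x) ** n
            rev = kr * x * (i_free0 + x)
            return [fwd - rev]

        return rhs, is0

    def relaxation_rate(self, T_C: float) -> float:
        """Approximate relaxation rate (1/s) near the current equilibrium."""
        d = self.design
        is0 = min(d.I_total, d.S_total)
        x_eq = self.equilibrium_f(T_C) * d.S_total
        kf = self.k_f(T_C)
        kr = kf / math.exp(log_K(self.rt, T_C + CELSIUS_OFFSET))
        n = d.n_ac
        i_free0 = d.I_total - is0
        # -d(rhs)/dx at equilibrium
        eps = 1e-3 * max(x_eq, is0 * 1e-3, 1e-12)
        x_eq = min(max(x_eq, eps), min(is0, d.C) - eps)

        def rate(x):
            return kf * (is0 - x) * (d.C - x) ** n - kr * x * (i_free0 + x)

        return max((rate(x_eq - eps) - rate(x_eq + eps)) / (2 * eps), 1e-30)

    def half_life(self, T_C: float) -> float:
        return math.log(2.0) / self.relaxation_rate(T_C)

    def relax(self, f0: float, T_C: float, duration: float) -> float:
        """Displacement fraction after holding ``duration`` s at ``T_C``."""
        rhs, _ = self._rhs(T_C)
        x0 = f0 * self.design.S_total
        sol = solve_ivp(rhs, (0.0, duration), [x0], method="LSODA",
                        rtol=self.rtol, atol=1e-18)
        if not sol.success:
            raise RuntimeError(f"kinetics integration failed at {T_C} C: {sol.message}")
        return float(sol.y[0, -1]) / self.design.S_total

    def trace(self, f0: float, T_C: float, duration: float, dt: float = 1.0) -> pd.DataFrame:
        """Time-resolved relaxation at fixed temperature."""
        rhs, _ = self._rhs(T_C)
        t_eval = np.arange(0.0, duration + 0.5 * dt, dt)
        sol = solve_ivp(rhs, (0.0, duration), [f0 * self.design.S_total], method="LSODA",
                        rtol=self.rtol, atol=1e-18, t_eval=t_eval)
        if not sol.success:
            raise RuntimeError(f"kinetics integration failed at {T_C} C: {sol.message}")
        return pd.DataFrame({
            "time_s": sol.t,
            "temperature_C": T_C,
            "f": sol.y[0] / self.design.S_total,
        })

    def simulate_protocol(self, waypoints: list[tuple[float, float]], f0: float = 0.0,
                          dt: float = 1.0) -> pd.DataFrame:
        """Piecewise-constant temperature program (instantaneous transitions)."""
        frames = []
        t0, f = 0.0, f0
        for T_C, dur in waypoints:
            if dur <= 0:
                raise ValueError("waypoint durations must be positive")
            seg = self.trace(f, T_C, dur, dt)
            f = float(seg["f"].iloc[-1])
            seg = seg.assign(time_s=seg["time_s"] + t0)
            t0 += dur
            frames.append(seg)
        return pd.concat(frames, ignore_index=True)


@dataclass
class FirstOrderReversible:
    """A <-> B with first-order rates per temperature: analytic relaxation.

    f is the fraction in state B; ``rates(T_C)`` returns (k_fwd, k_rev).
    Used as the reference system for periodic-steady-state analysis of
    thermal cycling: each hold maps f0 affinely, f(t) = f_eq + (f0 - f_eq)
    exp(-(k1+k2) t), so a two-phase cycle has a closed-form fixed point.
    """

    rate_table: dict[float, tuple[float, float]]

    def rates(self, T_C: float) -> tuple[float, float]:
        return self.rate_table[T_C]

    def equilibrium_f(self, T_C: float) -> float:
        k1, k2 = self.rates(T_C)
        return k1 / (k1 + k2)

    def half_life(self, T_C: float) -> float:
        k1, k2 = self.rates(T_C)
        return math.log(2.0) / (k1 + k2)

    def relax(self, f0: float, T_C: float, duration: float) -> float:
        k1, k2 = self.rates(T_C)
        feq = k1 / (k1 + k2)
        return feq + (f0 - feq) * math.exp(-(k1 + k2) * duration)

    def cycle_fixed_point(self, T_on: float, T_off: float, hold_on: float, hold_off: float) -> tuple[float, float]:
        """Closed-form per-cycle endpoints (f_on*, f_off*) of the two-phase map."""
        kon = sum(self.rates(T_on))
        koff = sum(self.rates(T_off))
        a_on, b_on = math.exp(-kon * hold_on), self.equilibrium_f(T_on)
        a_off, b_off = math.exp(-koff * hold_off), self.equilibrium_f(T_off)
        # f_on* = b_on + a_on * (b_off + a_off*(f_on* - b_off) ... ) composing off->on
        # compose: starting at f_off end, apply ON phase; then OFF phase.
        # f1 = b_on + a_on (f0 - b_on); f2 = b_off + a_off (f1 - b_off)
        # fixed point of f0 -> f2:
        A = a_on * a_off
        B = b_off + a_off * (b_on + a_on * (-b_on) - b_off)
        # f2 = A f0 + b_off + a_off*(b_on - a_on*b_on - b_off) = A f0 + B
        f_off_star = B / (1.0 - A)
        f_on_star = b_on + a_on * (f_off_star - b_on)
        return f_on_star, f_off_star
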