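"""Coupled mass-balance equilibrium of the TAD displacement reaction.

Solves, at each temperature, the single-extent equilibrium

    K(T) = ([AC.S][I]) / ([I.S] * prod_i [AC_i])        (1 M standard state)

for the lumped all-or-nothing displacement reaction, yielding the
displacement fraction f(T) = [AC.S]/S_total.  From f(T) the displacing
temperature T_d (f = 0.5) and displacing range Delta_T (the temperature
interval between the 99% and 1% displacement crossings) are extracted.
Also provides design-parameter scans and calibration of the four-way
junction entropy against an observed T_d.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .design import TADDesign, ReactionThermo, net_change, reaction_thermo
from .thermo import CELSIUS_OFFSET, R_KCAL, ThermoParams, EnergyTerm

__all__ = [
    "EquilibriumState",
    "MeltProfile",
    "MeltSummary",
    "EquilibriumError",
    "CalibrationError",
    "log_K",
    "solve_at_T",
    "melt_profile",
    "summarize",
    "displacement_fraction",
    "crossing_temperature",
    "melt_summary_exact",
    "design_scan",
    "calibrate_junction",
]

T_MIN_K, T_MAX_K = 250.0, 400.0


class EquilibriumError(RuntimeError):
    """Equilibrium solve failed (no bracketed root / non-finite K)."""


class CalibrationError(RuntimeError):
    """Junction calibration target outside the achievable range."""


@dataclass(frozen=True)
class EquilibriumState:
    """Species concentrations (mol/L) and displacement fraction at one T."""

    T: float  # kelvin
    conc: dict[str, float]
    f: float

    def conservation_residual(self, d: TADDesign) -> float:
        """Max relative per-strand mass-balance violation (should be ~0)."""
        c = self.conc
        is0 = min(d.I_total, d.S_total)
        res = []
        res.append(abs(c["IS"] + c["I"] - d.I_total) / d.I_total)
        res.append(abs(c["IS"] + c["ACS"] - d.S_total) / d.S_total)
        for i in range(d.n_ac):
            res.append(abs(c[f"AC{i + 1}"] + c["ACS"] - d.C) / d.C)
        del is0
        return max(res)


@dataclass(frozen=True)
class MeltProfile:
    """Displacement fraction over an ascending temperature grid (deg C)."""

    T_grid: np.ndarray  # deg C, ascending
    f: np.ndarray
    dfdT: np.ndarray  # per deg C, central differences

    def __post_init__(self) -> None:
        if np.any(np.diff(self.T_grid) <= 0):
            raise ValueError("T_grid must be strictly ascending")


@dataclass(frozen=True)
class MeltSummary:
    """T_d (deg C at f = 0.5) and Delta_T = T(f=0.01) - T(f=0.99), deg C."""

    T_d: float
    delta_T: float

    def __post_init__(self) -> None:
        if not self.delta_T > 0:
            raise ValueError("delta_T must be positive")


def log_K(rt: ReactionThermo, T: float) -> float:
    """ln K(T) of the displacement reaction at the 1 M standard state."""
    lnk = -rt.rxn.dG(T) / (R_KCAL * T)
    if not math.isfinite(lnk):
        raise EquilibriumError(f"non-finite equilibrium constant at T={T} K")
    return lnk


def _log_Q(x: float, is0: float, i_free0: float, cs: list[float], c0: float) -> float:
    """ln of the reaction quotient at extent x (concentrations in mol/L)."""
    num = math.log(x) + math.log(i_free0 + x)
    den = math.log(is0 - x)
    for c in cs:
        den += math.log(c - x)
    n_ac = len(cs)
    return num - den + (n_ac - 1) * math.log(c0)


def solve_at_T(d: TADDesign, rt: ReactionThermo, T: float) -> EquilibriumState:
    """Unique equilibrium extent at temperature ``T`` (kelvin) by bisection.

    The log-ratio residual g(x) = ln Q(x) - ln K(T) is strictly increasing
    in the extent x on (0, x_max) and diverges to -inf/+inf at the
    endpoints, so bisection converges unconditionally; iteration stops when
    |g| < 1e-12 or the bracket is exhausted at machine precision.
    """
    if not (T_MIN_K < T < T_MAX_K):
        raise EquilibriumError(f"temperature {T} K outside solvable range ({T_MIN_K}, {T_MAX_K})")
    lnk = log_K(rt, T)
    is0 = min(d.I_total, d.S_total)
    i_free0 = d.I_total - is0
    cs = [d.C] * d.n_ac
    x_max = min(is0, min(cs))
    c0 = 1.0  # params.ref_conc is 1 mol/L; quotient computed in mol/L

    lo, hi = 0.0, x_max
    x = 0.5 * x_max
    for _ in range(200):
        x = 0.5 * (lo + hi)
        if x == lo or x == hi:
            break
        g = _log_Q(x, is0, i_free0, cs, c0) - lnk
        if abs(g) < 1e-12:
            break
        if g < 0:
            lo = x
        else:
            hi = x

    conc = {"IS": is0 - x, "ACS": x, "I": i_free0 + x}
    for i in range(d.n_ac):
        conc[f"AC{i + 1}"] = d.C - x
    return EquilibriumState(T=T, conc=conc, f=x / d.S_total)


def displacement_fraction(d: TADDesign, rt: ReactionThermo, T_K: float) -> float:
    return solve_at_T(d, rt, T_K).f


def melt_profile(
    d: TADDesign,
    rt: ReactionThermo,
    T_lo: float = 5.0,
    T_hi: float = 65.0,
    step: float = 0.1,
) -> MeltProfile:
    """Equilibrium f over a temperature grid (``T_lo``..``T_hi`` deg C)."""
    if not T_lo < T_hi:
        raise ValueError("require T_lo < T_hi")
    if step <= 0:
        raise ValueError("step must be positive")
    grid = np.arange(T_lo, T_hi + 0.5 * step, step)
    f = np.empty_like(grid)
    for i, tc in enumerate(grid):
        try:
            f[i] = solve_at_T(d, rt, tc + CELSIUS_OFFSET).f
        except EquilibriumError as err:
            raise EquilibriumError(f"equilibrium solve failed at T = {tc} C: {err}") from err
    dfdT = np.gradient(f, grid)
    return MeltProfile(T_grid=grid, f=f, dfdT=dfdT)


def _logit(f: np.ndarray | float) -> np.ndarray | float:
    f = np.clip(f, 1e-15, 1.0 - 1e-15)
    return np.log(f / (1.0 - f))


def summarize(p: MeltProfile) -> MeltSummary:
    """T_d and Delta_T from a profile, by logit-linear interpolation.

    Crossings are interpolated linearly in (T, logit f), which removes most
    grid bias on sigmoidal curves.  Raises a range error naming the first
    threshold the profile does not bracket.
    """
    fmax, fmin = float(np.max(p.f)), float(np.min(p.f))
    for level in (0.99, 0.5, 0.01):
        if not (fmin <= level <= fmax):
            raise ValueError(
                f"profile range [{fmin:.4g}, {fmax:.4g}] does not bracket the f = {level} crossing"
            )
    # f is non-increasing in T; reverse for ascending interpolation
    lf = np.asarray(_logit(p.f))[::-1]
    tt = np.asarray(p.T_grid)[::-1]
    t99, t50, t01 = (float(np.interp(_logit(level), lf, tt)) for level in (0.99, 0.5, 0.01))
    return MeltSummary(T_d=t50, delta_T=t01 - t99)


def crossing_temperature(d: TADDesign, rt: ReactionThermo, level: float = 0.5) -> float:
    """Exact temperature (deg C) at which f(T) crosses ``level``.

    Bisection in T over the solvable window; f is monotone non-increasing in
    T for any displacement-favorable reaction (rxn.dH < 0).
    """
    lo, hi = T_MIN_K + 1e-6, T_MAX_K - 1e-6
    f_lo = displacement_fraction(d, rt, lo)
    f_hi = displacement_fraction(d, rt, hi)
    if not (f_hi <= level <= f_lo):
        raise EquilibriumError(
            f"f = {level} crossing outside solvable window: f({lo:.0f} K) = {f_lo:.4g}, "
            f"f({hi:.0f} K) = {f_hi:.4g}"
        )
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        if displacement_fraction(d, rt, mid) > level:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi) - CELSIUS_OFFSET


def melt_summary_exact(d: TADDesign, params: ThermoParams) -> MeltSummary:
    """T_d/Delta_T by direct root-finding (no grid)."""
    rt = reaction_thermo(d, params)
    t99 = crossing_temperature(d, rt, 0.99)
    t50 = crossing_temperature(d, rt, 0.5)
    t01 = crossing_temperature(d, rt, 0.01)
    return MeltSummary(T_d=t50, delta_T=t01 - t99)


def design_scan(
    base: TADDesign,
    vary: str,
    values: list,
    params: ThermoParams,
) -> pd.DataFrame:
    """One melt summary per value of ``vary`` in {"L", "N", "C"}.

    Returns a tidy frame with columns (``vary``, ``T_d_C``, ``delta_T_C``).
    """
    if vary not in {"L", "N", "C"}:
        raise ValueError(f"vary must be one of L, N, C; got {vary!r}")
    rows = []
    for v in values:
        d = base.replace(**{vary: v})
        s = melt_summary_exact(d, params)
        rows.append({vary: v, "T_d_C": s.T_d, "delta_T_C": s.delta_T})
    return pd.DataFrame(rows)


def calibrate_junction(
    d: TADDesign,
    observed_T_d: float,
    params: ThermoParams,
    tol_C: float = 0.05,
) -> ThermoParams:
    """Adjust the junction entropy so the predicted T_d matches ``observed_T_d``.

    The junction enthalpy is held at its current value; the per-junction
    ``dS`` is solved by bisection (predicted T_d is monotone increasing in
    the junction dS).  Raises :class:`CalibrationError`, reporting the
    achievable T_d range, if the target cannot be met.
    """

    def predicted(ds_j: float) -> float | None:
        p = params.with_junction(EnergyTerm(params.junction.dH, ds_j))
        try:
            return crossing_temperature(d, reaction_thermo(d, p), 0.5)
        except EquilibriumError:
            return None

    # expand a bracket around the current junction entropy
    lo, hi = params.junction.dS - 1.0, params.junction.dS + 1.0
    t_lo, t_hi = predicted(lo), predicted(hi)
    for _ in range(60):
        if t_lo is not None and t_lo <= observed_T_d:
            break
        lo = params.junction.dS - 2.0 * abs(lo - params.junction.dS)
        t_lo = predicted(lo)
    for _ in range(60):
        if t_hi is not None and t_hi >= observed_T_d:
            break
        hi = params.junction.dS + 2.0 * abs(hi - params.junction.dS)
        t_hi = predicted(hi)
    if t_lo is None or t_hi is None or not (t_lo <= observed_T_d <= t_hi):
        raise CalibrationError(
            f"target T_d = {observed_T_d} C unattainable; achievable range about "
            f"[{t_lo}, {t_hi}] C for junction dS in [{lo:.1f}, {hi:.1f}] cal/(mol K)"
        )
    for _ in range(100):
        mid = 0.5 * (lo + hi)
        t_mid = predicted(mid)
        if t_mid is None:
            raise CalibrationError("equilibrium became unsolvable during calibration")
        if abs(t_mid - observed_T_d) < 0.2 * tol_C:
            return params.with_junction(EnergyTerm(params.junction.dH, mid))
        if t_mid < observed_T_d:
            lo = mid
        else:
            hi = mid
    final = 0.5 * (lo + hi)
    t_final = predicted(final)
    if t_final is None or abs(t_final - observed_T_d) > tol_C:
        raise CalibrationError(f"calibration did not converge to {observed_T_d} +/- {tol_C} C")
    return params.with_junction(EnergyTerm(params.junction.dH, final))
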