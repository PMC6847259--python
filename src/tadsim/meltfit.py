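"""Fluorescence melt-curve processing and two-state van't Hoff fitting.

The measurement model follows the plate experiments the package emulates:
each well reports an arbitrary-units fluorescence signal; negative and
positive control wells define 0% and 100% displacement at every
temperature, so per-replicate normalization is

    f(T) = (signal - mean_neg(T)) / (mean_pos(T) - mean_neg(T))

followed by aggregation across replicates (normalize-then-aggregate, which
propagates control noise honestly).  Normalized curves are fitted to the
two-state van't Hoff sigmoid

    f(T) = b_lo + (b_hi - b_lo) / (1 + exp[(dH_vH/R) (1/T - 1/T_half)])

(temperatures in kelvin inside the exponent), which has f high at low
temperature for dH_vH < 0 — the displacement-favored-cold orientation.
``TwoStateMeltModel.fit`` returns a results object carrying estimates,
standard errors, diagnostics and a ``summary()`` table, statsmodels-style.
Also provides analytic derivative curves, hysteresis detection between
annealing and melting ramps, and single-exponential kinetics fitting.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import lmfit
import numpy as np
import pandas as pd

from .equilibrium import MeltSummary
from .thermo import CELSIUS_OFFSET, R_CAL

__all__ = [
    "PLATE_COLUMNS",
    "DegenerateControlsError",
    "TransitionRangeError",
    "UnidentifiableError",
    "AlignmentError",
    "NormalizedCurve",
    "HysteresisReport",
    "normalize",
    "TwoStateMeltModel",
    "MeltFitResult",
    "derivative",
    "detect_hysteresis",
    "KineticsModel",
    "KineticsResult",
    "fit_two_state",
    "fit_kinetics",
]

#: Bit-exact plate CSV column order.
PLATE_COLUMNS = ["well", "role", "condition", "replicate", "ramp", "temperature_C", "time_s", "signal"]

#: Replicate-sd floor used for inverse-variance weighting (fraction units).
SD_FLOOR = 0.005


class DegenerateControlsError(ValueError):
    """Positive-control signal does not exceed negative control at some T."""


class TransitionRangeError(ValueError):
    """Curve does not span enough of the 0-1 transition to be fitted."""


class UnidentifiableError(RuntimeError):
    """Kinetics trace carries no information about the rate."""


class AlignmentError(ValueError):
    """Two curves do not share a temperature grid."""


@dataclass(frozen=True)
class NormalizedCurve:
    """Per-temperature mean/sd of normalized displacement fraction."""

    T: np.ndarray  # deg C, ascending
    f_mean: np.ndarray
    f_sd: np.ndarray
    ramp: str = "melt"
    condition: str = ""
    n_replicates: int = 1


@dataclass(frozen=True)
class HysteresisReport:
    """Maximum |f_melt - f_anneal| over the shared grid, with flag."""

    max_abs_gap: float
    flag: bool
    T_at_max: float
    threshold: float


def normalize(plate: pd.DataFrame) -> dict[tuple[str, str], NormalizedCurve]:
    """Control-normalize a plate table into per-(condition, ramp) curves.

    Controls are averaged per temperature and ramp; each sample replicate is
    normalized against those means, then replicates are aggregated into
    mean and standard deviation.  Raises
    :class:`DegenerateControlsError` (naming the temperature) wherever the
    positive-control mean does not exceed the negative-control mean.
    """
    missing = [c for c in PLATE_COLUMNS if c not in plate.columns and c != "time_s"]
    if missing:
        raise ValueError(f"plate table missing columns {missing}")
    out: dict[tuple[str, str], NormalizedCurve] = {}
    for ramp, sub in plate.groupby("ramp", sort=False):
        neg = sub[sub.role == "negative_control"].groupby("temperature_C")["signal"].mean()
        pos = sub[sub.role == "positive_control"].groupby("temperature_C")["signal"].mean()
        if neg.empty or pos.empty:
            raise ValueError(f"ramp {ramp!r} lacks negative and/or positive controls")
        span = pos - neg
        bad = span[span <= 0]
        if not bad.empty:
            raise DegenerateControlsError(
                f"positive control <= negative control at T = {bad.index.tolist()} C (ramp {ramp!r})"
            )
        samples = sub[sub.role == "sample"]
        for condition, cond in samples.groupby("condition", sort=False):
            reps = []
            for _, rep in cond.groupby("replicate", sort=True):
                rep = rep.sort_values("temperature_C")
                t = rep["temperature_C"].to_numpy(float)
                f = (rep["signal"].to_numpy(float) - neg.loc[t].to_numpy()) / span.loc[t].to_numpy()
                reps.append((t, f))
            t0 = reps[0][0]
            for t, _ in reps[1:]:
                if not np.array_equal(t, t0):
                    raise AlignmentError(f"replicates of {condition!r} measured on different grids")
            fmat = np.vstack([f for _, f in reps])
            out[(condition, ramp)] = NormalizedCurve(
                T=t0,
                f_mean=fmat.mean(axis=0),
                f_sd=fmat.std(axis=0, ddof=1) if len(reps) > 1 else np.zeros_like(t0),
                ramp=str(ramp),
                condition=str(condition),
                n_replicates=len(reps),
            )
    return out


def _vant_hoff(T_C: np.ndarray, dH_vH: float, T_half: float, b_lo: float, b_hi: float) -> np.ndarray:
    TK = np.asarray(T_C, float) + CELSIUS_OFFSET
    ThK = T_half + CELSIUS_OFFSET
    u = (dH_vH * 1000.0 / R_CAL) * (1.0 / TK - 1.0 / ThK)
    return b_lo + (b_hi - b_lo) / (1.0 + np.exp(np.clip(u, -500, 500)))


@dataclass
class MeltFitResult:
    """Fitted two-state melting model with uncertainties and diagnostics.

    ``dH_vH`` is the van't Hoff transition enthalpy (kcal/mol, negative),
    ``T_half`` the midpoint (deg C); the derived ``melt_summary`` reports
    T_d = T_half and the 1-99% displacing range of the fitted sigmoid.
    """

    dH_vH: float
    T_half: float
    baseline_lo: float
    baseline_hi: float
    stderr: dict[str, float]
    residual_rms: float
    n_obs: int
    curve: NormalizedCurve | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if not self.dH_vH < 0:
            raise ValueError("fitted van't Hoff enthalpy must be negative")

    def predict(self, T_C: np.ndarray) -> np.ndarray:
        return _vant_hoff(np.asarray(T_C, float), self.dH_vH, self.T_half, self.baseline_lo, self.baseline_hi)

    def fraction(self, T_C: np.ndarray) -> np.ndarray:
        """Baseline-free transition fraction (1 cold -> 0 hot)."""
        pred = self.predict(T_C)
        return (pred - self.baseline_lo) / (self.baseline_hi - self.baseline_lo)

    def crossing(self, level: float) -> float:
        """Temperature (deg C) at which the transition fraction equals ``level``."""
        if not 0 < level < 1:
            raise ValueError("level must be in (0, 1)")
        a = self.dH_vH * 1000.0 / R_CAL
        ThK = self.T_half + CELSIUS_OFFSET
        # level = 1/(1+exp[a(1/T - 1/Th)])  =>  1/T = 1/Th + ln((1-level)/level)/a
        invT = 1.0 / ThK + math.log((1.0 - level) / level) / a
        return 1.0 / invT - CELSIUS_OFFSET

    @property
    def melt_summary(self) -> MeltSummary:
        return MeltSummary(T_d=self.T_half, delta_T=self.crossing(0.01) - self.crossing(0.99))

    def summary(self) -> str:
        s = self.melt_summary
        lines = [
            "Two-state van't Hoff melt fit",
            "=" * 46,
            f"{'n obs':<22}{self.n_obs:>24}",
            f"{'residual rms':<22}{self.residual_rms:>24.5f}",
            "-" * 46,
            f"{'parameter':<12}{'estimate':>16}{'std err':>16}",
        ]
        for name, val in [
            ("dH_vH", self.dH_vH),
            ("T_half", self.T_half),
            ("baseline_lo", self.baseline_lo),
            ("baseline_hi", self.baseline_hi),
        ]:
            se = self.stderr.get(name)
            lines.append(f"{name:<12}{val:>16.4f}{(f'{se:>16.4f}' if se is not None else f'{chr(45):>16}')}")
        lines += [
            "-" * 46,
            f"{'T_d (deg C)':<22}{s.T_d:>24.3f}",
            f"{'Delta_T (deg C)':<22}{s.delta_T:>24.3f}",
        ]
        return "\n".join(lines)

    def plot(self, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        if self.curve is not None:
            ax.errorbar(self.curve.T, self.curve.f_mean, yerr=self.curve.f_sd, fmt="o", ms=3, label="data")
            grid = np.linspace(self.curve.T.min(), self.curve.T.max(), 400)
        else:
            grid = np.linspace(self.T_half - 30, self.T_half + 30, 400)
        ax.plot(grid, self.predict(grid), label="fit")
        ax.set_xlabel("temperature (deg C)")
        ax.set_ylabel("displacement fraction f")
        ax.legend()
        return ax


class TwoStateMeltModel:
    """Weighted NLS model for a normalized melting curve.

    Construct from a :class:`NormalizedCurve` (or raw arrays via
    ``from_arrays``), then ``fit()`` to obtain a :class:`MeltFitResult`.
    Weights are inverse replicate variances with the sd floored at
    ``SD_FLOOR``; initialization takes T_half from the derivative extremum
    (tie-broken toward the median f = 0.5 crossing) and |dH| from the
    midpoint slope.
    """

    def __init__(self, curve: NormalizedCurve):
        if len(curve.T) < 5:
            raise ValueError("need at least 5 temperature points")
        self.curve = curve

    @classmethod
    def from_arrays(cls, T_C, f, sd=None, **kw) -> "TwoStateMeltModel":
        T_C = np.asarray(T_C, float)
        f = np.asarray(f, float)
        sd = np.zeros_like(f) if sd is None else np.asarray(sd, float)
        order = np.argsort(T_C)
        return cls(NormalizedCurve(T=T_C[order], f_mean=f[order], f_sd=sd[order], **kw))

    def _initial_guess(self) -> dict[str, float]:
        t, f = self.curve.T, self.curve.f_mean
        b_hi = float(np.percentile(f, 95))
        b_lo = float(np.percentile(f, 5))
        # smoothed derivative extremum
        win = max(3, len(t) // 20) | 1
        fs = np.convolve(f, np.ones(win) / win, mode="same")
        df = np.gradient(fs, t)
        # median of f = 0.5 crossings as tie-breaker
        half = b_lo + 0.5 * (b_hi - b_lo)
        sign = np.sign(f - half)
        xings = t[:-1][np.diff(sign) != 0]
        t_ref = float(np.median(xings)) if xings.size else float(t[np.argmin(df)])
        minima = np.where(df <= np.min(df) * 0.8)[0]
        t_half = float(t[minima[np.argmin(np.abs(t[minima] - t_ref))]]) if minima.size else t_ref
        slope = float(np.min(df))
        TK = t_half + CELSIUS_OFFSET
        span = max(b_hi - b_lo, 0.1)
        dH = 4.0 * R_CAL * TK * TK * slope / span / 1000.0  # kcal/mol, negative
        if not (dH < -5):
            dH = -60.0
        return {"dH_vH": dH, "T_half": t_half, "b_lo": b_lo, "b_hi": b_hi}

    def fit(self, check_span: bool = True) -> MeltFitResult:
        c = self.curve
        if check_span and (np.min(c.f_mean) > 0.2 or np.max(c.f_mean) < 0.8):
            raise TransitionRangeError(
                f"curve spans only [{np.min(c.f_mean):.3f}, {np.max(c.f_mean):.3f}]; "
                "need the transition to cover at least 0.2-0.8"
            )
        guess = self._initial_guess()
        weights = 1.0 / np.maximum(c.f_sd, SD_FLOOR)

        def build_params(dh_scale: float) -> lmfit.Parameters:
            p = lmfit.Parameters()
            p.add("dH_vH", value=guess["dH_vH"] * dh_scale, max=-1.0, min=-500.0)
            p.add("T_half", value=guess["T_half"], min=c.T.min() - 30.0, max=c.T.max() + 30.0)
            p.add("b_lo", value=guess["b_lo"], min=-0.5, max=0.7)
            p.add("b_hi", value=guess["b_hi"], min=0.3, max=1.5)
            return p

        def residual(p):
            pred = _vant_hoff(c.T, p["dH_vH"].value, p["T_half"].value, p["b_lo"].value, p["b_hi"].value)
            return (pred - c.f_mean) * weights

        best = None
        for scale in (1.0, 0.5, 2.0, 0.25, 4.0):
            res = lmfit.minimize(residual, build_params(scale), method="leastsq")
            if res.success and (best is None or res.chisqr < best.chisqr):
                best = res
                if scale == 1.0 and res.chisqr < 1e-16:
                    break
        if best is None:
            raise RuntimeError("two-state fit failed to converge from the restart grid")
        pv = best.params
        resid = residual(pv) / weights
        return MeltFitResult(
            dH_vH=pv["dH_vH"].value,
            T_half=pv["T_half"].value,
            baseline_lo=pv["b_lo"].value,
            baseline_hi=pv["b_hi"].value,
            stderr={k: (pv[n].stderr if pv[n].stderr is not None else float("nan"))
                    for k, n in [("dH_vH", "dH_vH"), ("T_half", "T_half"),
                                 ("baseline_lo", "b_lo"), ("baseline_hi", "b_hi")]},
            residual_rms=float(np.sqrt(np.mean(resid**2))),
            n_obs=len(c.T),
            curve=c,
        )


def fit_two_state(curve: NormalizedCurve, **kw) -> MeltFitResult:
    """Functional wrapper: ``TwoStateMeltModel(curve).fit()``."""
    return TwoStateMeltModel(curve).fit(**kw)


def derivative(fit: MeltFitResult, grid: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Analytic df/dT of the fitted model on ``grid`` (deg C)."""
    grid = np.asarray(grid, float)
    TK = grid + CELSIUS_OFFSET
    a = fit.dH_vH * 1000.0 / R_CAL
    sig = fit.fraction(grid)
    dfdT = (fit.baseline_hi - fit.baseline_lo) * sig * (1.0 - sig) * a / TK**2
    return grid, dfdT


def detect_hysteresis(anneal: NormalizedCurve, melt: NormalizedCurve, threshold: float = 0.05) -> HysteresisReport:
    """Maximum |f_melt - f_anneal| over the shared grid.

    The flag is set on strict exceedance of ``threshold`` (a gap exactly at
    threshold does not flag).  Raises :class:`AlignmentError` if the two
    curves were measured on different grids.
    """
    if not np.array_equal(anneal.T, melt.T):
        raise AlignmentError("annealing and melting curves are on different temperature grids")
    gap = np.abs(melt.f_mean - anneal.f_mean)
    i = int(np.argmax(gap))
    g = float(gap[i])
    return HysteresisReport(max_abs_gap=g, flag=g > threshold, T_at_max=float(anneal.T[i]), threshold=threshold)


@dataclass(frozen=True)
class KineticsResult:
    """Single-exponential relaxation fit: f(t) = plateau + (f0-plateau) e^(-rate t)."""

    direction: str
    rate: float  # 1/s
    plateau: float
    f0: float
    residual_rms: float
    rate_stderr: float

    @property
    def half_life(self) -> float:
        return math.log(2.0) / self.rate

    def predict(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, float)
        return self.plateau + (self.f0 - self.plateau) * np.exp(-self.rate * t)

    def summary(self) -> str:
        return (
            f"Exponential kinetics fit ({self.direction})\n"
            f"  rate       {self.rate:.6g} 1/s (se {self.rate_stderr:.2g})\n"
            f"  half-life  {self.half_life:.6g} s\n"
            f"  plateau    {self.plateau:.4f}\n"
            f"  f0         {self.f0:.4f}\n"
            f"  resid rms  {self.residual_rms:.4g}"
        )


class KineticsModel:
    """Single-exponential model for an activation/deactivation trace."""

    def __init__(self, t: np.ndarray, f: np.ndarray, direction: str = "activation"):
        t = np.asarray(t, float)
        f = np.asarray(f, float)
        if len(t) < 6:
            raise ValueError("need at least 6 time points")
        if direction not in ("activation", "deactivation"):
            raise ValueError("direction must be 'activation' or 'deactivation'")
        order = np.argsort(t)
        self.t, self.f, self.direction = t[order], f[order], direction

    def fit(self) -> KineticsResult:
        t, f = self.t, self.f
        span = float(np.max(f) - np.min(f))
        noise = float(np.std(np.diff(f)) / math.sqrt(2.0)) if len(f) > 3 else 0.0
        if span < max(5.0 * noise, 1e-3):
            raise UnidentifiableError(
                f"trace is flat (range {span:.3g} vs noise {noise:.3g}); rate is unidentifiable"
            )
        # monotone-trend check beyond noise: largest reversal against the
        # overall direction of travel
        g = np.sign(f[-1] - f[0]) * f
        reversal = float(np.max(np.maximum.accumulate(g) - g))
        if reversal > max(5.0 * noise, 0.02):
            warnings.warn("trace is non-monotone beyond noise; single-exponential model may be wrong")

        p = lmfit.Parameters()
        dur = t[-1] - t[0]
        p.add("rate", value=2.0 / max(dur, 1e-9), min=1e-12)
        p.add("plateau", value=float(f[-1]))
        p.add("f0", value=float(f[0]))

        def residual(p):
            return p["plateau"].value + (p["f0"].value - p["plateau"].value) * np.exp(
                -p["rate"].value * t
            ) - f

        res = lmfit.minimize(residual, p, method="leastsq")
        if not res.success:
            raise RuntimeError("kinetics fit failed to converge")
        rate = res.params["rate"].value
        se = res.params["rate"].stderr
        if rate * dur < 0.2 or (se is not None and math.isfinite(se) and se > rate):
            raise UnidentifiableError(
                f"trace too short relative to the fitted half-life ({math.log(2) / rate:.3g} s); "
                "rate is unidentifiable"
            )
        return KineticsResult(
            direction=self.direction,
            rate=rate,
            plateau=res.params["plateau"].value,
            f0=res.params["f0"].value,
            residual_rms=float(np.sqrt(np.mean(residual(res.params) ** 2))),
            rate_stderr=float(se) if se is not None else float("nan"),
        )


def fit_kinetics(t, f, direction: str = "activation") -> KineticsResult:
    """Functional wrapper: ``KineticsModel(t, f, direction).fit()``."""
    return KineticsModel(t, f, direction).fit()
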