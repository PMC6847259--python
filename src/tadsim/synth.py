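"""Synthetic plate-reader data with the statistical structure of qPCR melting runs.

Emulates the package's target experiments: five replicates per condition,
negative/positive control wells defining 0% and 100% displacement, 5-65 C
ramps at 1 C resolution measured in both directions (annealing then
melting), and additive Gaussian noise in signal space (plate-reader-like;
noise_sd is expressed in fraction units and scaled by the gain).  Control
wells receive independent noise so normalization error propagation is
exercised realistically.  Ground truth f*(T) comes either from an explicit
two-state van't Hoff curve or from the equilibrium model of a TAD design,
so generated tables are an oracle for every downstream analysis stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .design import TADDesign, reaction_thermo
from .equilibrium import solve_at_T
from .meltfit import PLATE_COLUMNS
from .thermo import CELSIUS_OFFSET, R_CAL, ThermoParams

__all__ = ["VantHoffTruth", "SynthConfig", "generate_plate", "generate_kinetics", "generate_hysteresis_plate"]


@dataclass(frozen=True)
class VantHoffTruth:
    """Explicit two-state ground truth: midpoint T_d (deg C), dH_vH (kcal/mol)."""

    T_d: float
    dH_vH: float = -80.0
    b_lo: float = 0.0
    b_hi: float = 1.0

    def f(self, T_C: np.ndarray) -> np.ndarray:
        TK = np.asarray(T_C, float) + CELSIUS_OFFSET
        u = (self.dH_vH * 1000.0 / R_CAL) * (1.0 / TK - 1.0 / (self.T_d + CELSIUS_OFFSET))
        return self.b_lo + (self.b_hi - self.b_lo) / (1.0 + np.exp(np.clip(u, -500, 500)))


@dataclass(frozen=True)
class SynthConfig:
    """Generator settings mirroring the characterization protocol.

    ``truth`` is a :class:`VantHoffTruth` or a :class:`TADDesign` (with
    ``params``).  Signal model per well: ``neg_level + gain * f*(T) +
    N(0, noise_sd * gain)``; positive controls have f* = 1, negatives 0.
    """

    truth: VantHoffTruth | TADDesign
    params: ThermoParams | None = None
    condition: str = "sample"
    replicates: int = 5
    T_lo: float = 5.0
    T_hi: float = 65.0
    T_step: float = 1.0
    ramps: tuple[str, ...] = ("anneal", "melt")
    noise_sd: float = 0.02
    neg_level: float = 200.0
    gain: float = 1000.0

    def __post_init__(self) -> None:
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.gain <= 0:
            raise ValueError("gain must be positive")
        if isinstance(self.truth, TADDesign) and self.params is None:
            raise ValueError("a TADDesign truth requires thermo params")

    def grid(self) -> np.ndarray:
        return np.arange(self.T_lo, self.T_hi + 0.5 * self.T_step, self.T_step)

    def truth_f(self, T_C: np.ndarray) -> np.ndarray:
        if isinstance(self.truth, VantHoffTruth):
            return self.truth.f(T_C)
        rt = reaction_thermo(self.truth, self.params)
        return np.array([solve_at_T(self.truth, rt, t + CELSIUS_OFFSET).f for t in np.asarray(T_C, float)])


def _well_ids(row: str, n: int) -> list[str]:
    return [f"{row}{i + 1:02d}" for i in range(n)]


def generate_plate(cfg: SynthConfig, seed: int, lag_C: float = 0.0) -> pd.DataFrame:
    """Synthetic plate table in the documented CSV dialect; seeded.

    ``lag_C`` shifts the melting ramp's true curve by +lag_C in temperature
    relative to annealing (hysteresis); the equilibrium generator uses 0.
    """
    if lag_C < 0:
        raise ValueError("lag_C must be >= 0")
    rng = np.random.default_rng(seed)
    grid = cfg.grid()
    f_anneal = cfg.truth_f(grid)
    sig_sd = cfg.noise_sd * cfg.gain
    rows = []
    roles = [
        ("sample", cfg.condition, _well_ids("A", cfg.replicates)),
        ("negative_control", "neg", _well_ids("B", cfg.replicates)),
        ("positive_control", "pos", _well_ids("C", cfg.replicates)),
    ]
    for ramp in cfg.ramps:
        f_true = cfg.truth_f(grid - lag_C) if (ramp == "melt" and lag_C > 0) else f_anneal
        t_order = grid[::-1] if ramp == "anneal" else grid
        f_order = f_true[::-1] if ramp == "anneal" else f_true
        for role, cond, wells in roles:
            base = {"sample": f_order, "negative_control": np.zeros_like(grid), "positive_control": np.ones_like(grid)}[role]
            for rep, well in enumerate(wells, start=1):
                noise = rng.normal(0.0, sig_sd, size=len(grid)) if sig_sd > 0 else np.zeros(len(grid))
                signal = cfg.neg_level + cfg.gain * base + noise
                for t, s in zip(t_order, signal):
                    rows.append((well, role, cond, rep, ramp, float(t), "", float(s)))
    df = pd.DataFrame(rows, columns=PLATE_COLUMNS)
    df.attrs["seed"] = seed
    return df


def generate_hysteresis_plate(cfg: SynthConfig, lag_C: float, seed: int) -> pd.DataFrame:
    """Plate whose melting ramp lags the annealing ramp by ``lag_C`` deg C."""
    return generate_plate(cfg, seed=seed, lag_C=lag_C)


def generate_kinetics(
    rate: float,
    plateau: float,
    f0: float,
    duration: float,
    dt: float = 1.0,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Seeded exponential-relaxation trace f(t) = plateau + (f0-plateau)e^(-rate t)."""
    if duration <= 0:
        raise ValueError("duration must be positive")
    rng = np.random.default_rng(seed)
    t = np.arange(0.0, duration + 0.5 * dt, dt)
    f = plateau + (f0 - plateau) * np.exp(-rate * t)
    if noise_sd > 0:
        f = f + rng.normal(0.0, noise_sd, size=len(t))
    df = pd.DataFrame({"time_s": t, "f": f})
    df.attrs["seed"] = seed
    return df
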