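"""Joint simulation of multiple sequence-orthogonal TAD designs in one pot.

Orthogonality is an input assertion: designs share no species, so the joint
equilibrium factorizes into independent per-design solves, and k designs
with disjoint displacing ranges partition the temperature axis into k + 1
distinct on/off patterns (e.g. both-on, one-on, both-off for two designs
with separated T_d).  No cross-hybridization scan is performed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .design import TADDesign, reaction_thermo
from .equilibrium import melt_profile
from .kinetics import DisplacementKinetics
from .thermo import ThermoParams

__all__ = ["StateMap", "joint_profile", "temperature_program"]


@dataclass(frozen=True)
class StateMap:
    """Per-design f over a temperature grid plus the on/off pattern per T."""

    T_grid: np.ndarray
    f: np.ndarray  # shape (n_designs, n_T)
    names: tuple[str, ...]
    pattern: tuple[tuple[bool, ...], ...]  # per-T tuple of (f > 0.5)
    distinct_patterns: frozenset

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"temperature_C": self.T_grid})
        for i, name in enumerate(self.names):
            df[f"f_{name}"] = self.f[i]
        return df


def joint_profile(
    designs: list[TADDesign],
    params: ThermoParams,
    T_lo: float = 5.0,
    T_hi: float = 80.0,
    step: float = 0.5,
) -> StateMap:
    """Independent equilibrium melt profiles for each design, plus patterns.

    Raises a range error naming any design whose f = 0.5 transition lies
    outside [T_lo, T_hi].
    """
    if len(designs) == 0:
        raise ValueError("need at least one design")
    profiles = []
    for d in designs:
        p = melt_profile(d, reaction_thermo(d, params), T_lo, T_hi, step)
        if not (p.f.min() <= 0.5 <= p.f.max()):
            raise ValueError(
                f"design {d.name!r}: transition (f = 0.5) outside scan range "
                f"[{T_lo}, {T_hi}] C (f in [{p.f.min():.3f}, {p.f.max():.3f}])"
            )
        profiles.append(p)
    grid = profiles[0].T_grid
    f = np.vstack([p.f for p in profiles])
    pattern = tuple(tuple(bool(v) for v in f[:, j] > 0.5) for j in range(f.shape[1]))
    return StateMap(
        T_grid=grid,
        f=f,
        names=tuple(d.name for d in designs),
        pattern=pattern,
        distinct_patterns=frozenset(pattern),
    )


def temperature_program(
    designs: list[TADDesign],
    waypoints: list[tuple[float, float]],
    params: ThermoParams,
    f0: float | list[float] = 0.0,
    dt: float = 1.0,
    **kinetics_kw,
) -> pd.DataFrame:
    """Time-resolved per-design f under a shared temperature program.

    Each design is integrated independently (no shared species); forward
    rates carry the default Arrhenius dependence, so operation at lower
    temperature approaches equilibrium more slowly.
    """
    f0s = [f0] * len(designs) if np.isscalar(f0) else list(f0)
    if len(f0s) != len(designs):
        raise ValueError("f0 must be scalar or one value per design")
    out = None
    for d, f_init in zip(designs, f0s):
        sim = DisplacementKinetics(d, params, **kinetics_kw)
        tr = sim.simulate_protocol(waypoints, f0=f_init, dt=dt)
        tr = tr.rename(columns={"f": f"f_{d.name}"})
        out = tr if out is None else out.merge(tr, on=["time_s", "temperature_C"])
    return out
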