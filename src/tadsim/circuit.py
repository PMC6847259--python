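"""Seesaw-style TAD logic gate: mass-action simulation under temperature protocols.

The reference network implements the four reactions of the gate, each one
itself a TAD reaction (forward-favored at the 35 C operate temperature,
reverse-favored at the 65 C reset temperature, midpoints in between):

    thresholding   w + Th            <=>  W_th                (fast, stoichiometric)
    initiation     w + G + AC_i      <=>  C_i + O             (input releases output)
    amplification  G + AC_a          <=>  C_a + O   (catalysed by free input w)
    reporting      O + I1.S1 + AC_r  <=>  C_r + I1  (unquenches the reporter)
    leak           G + AC_a          <=>  C_a + O   (uncatalysed, slow)

The amplification step is catalysed by the free input strand and is
therefore linear in input: a bigger (input - threshold) difference gives a
proportionally faster output rise, and sub-threshold input — sequestered by
the fast thresholding reaction — leaves the output at the circuit leak.
Thresholding at 0.6 uM implements two-input OR (one 1 uM input suffices);
1.2 uM implements AND (only 2 uM clears the threshold).  All reverse rates
are set by detailed balance against each reaction's van't Hoff K(T), so a
transient 65 C hold resets every species and the computation repeats
identically on the next cycle — the mechanism accumulates no waste.

Rate constants and per-reaction thermodynamics are design parameters of
this reference implementation (the gate's strand-level architecture is an
input, not a prediction); defaults are chosen so thresholding is >= 20x
faster than initiation and amplification runs on a minutes scale at 35 C.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .thermo import CELSIUS_OFFSET, R_KCAL, EnergyTerm

__all__ = [
    "SPECIES",
    "STRAND_COMPOSITION",
    "CircuitSpec",
    "Protocol",
    "Trace",
    "LogicConfig",
    "vant_hoff_from_K",
    "build_circuit",
    "simulate",
    "input_output_curve",
    "logic_eval",
]

#: State-vector species order (concentrations in mol/L).
SPECIES = ["w", "Th", "W_th", "G", "AC_i", "AC_a", "AC_r", "C_i", "C_a", "O", "I1S1", "I1", "C_r"]

#: Strand-level composition of each species (strand id -> copy count); the
#: gate complex G carries the gate-bottom strand b and the output top strand.
STRAND_COMPOSITION: dict[str, dict[str, int]] = {
    "w": {"w": 1},
    "Th": {"th": 1},
    "W_th": {"w": 1, "th": 1},
    "G": {"b": 1, "out": 1},
    "AC_i": {"aci": 1},
    "AC_a": {"aca": 1},
    "AC_r": {"acr": 1},
    "C_i": {"w": 1, "b": 1, "aci": 1},
    "C_a": {"b": 1, "aca": 1},
    "O": {"out": 1},
    "I1S1": {"i1": 1, "s1": 1},
    "I1": {"i1": 1},
    "C_r": {"out": 1, "s1": 1, "acr": 1},
}


def vant_hoff_from_K(K_35: float, K_65: float) -> EnergyTerm:
    """dH/dS of a reaction from its equilibrium constants at 35 and 65 C.

    Two-point van't Hoff inversion; K values are at the 1 M standard state
    (dimensionless after concentration scaling).
    """
    T1, T2 = 35.0 + CELSIUS_OFFSET, 65.0 + CELSIUS_OFFSET
    dH = R_KCAL * math.log(K_35 / K_65) / (1.0 / T2 - 1.0 / T1)
    dS = 1000.0 * (dH + R_KCAL * T1 * math.log(K_35)) / T1
    return EnergyTerm(dH, dS)


# Default per-reaction thermodynamics: strongly forward at 35 C, reverse at
# 65 C (midpoints between the operate and reset temperatures at working
# concentrations).  Thresholding is the most stable reaction so that an
# input titrated at the threshold leaves only ~nM free w.
_DEFAULT_THERMO = {
    "thresholding": vant_hoff_from_K(1e13, 1e3),
    "initiation": vant_hoff_from_K(1e9, 1e-1),
    "amplification": vant_hoff_from_K(1e2, 2e-7),
    "reporting": vant_hoff_from_K(1e10, 1e1),
}

# Forward rate constants.  Bimolecular thresholding at 2e6 M^-1 s^-1;
# trimolecular TAD steps as effective single-step rates (M^-2 s^-1) giving
# minutes-scale amplification at 35 C with 10 uM fuels.  The uncatalysed
# leak is 1e-7 of the amplification rate at a 1 uM reference concentration.
_DEFAULT_RATES = {
    "thresholding": 2e6,
    "initiation": 5e6,
    "amplification": 1e8,
    "reporting": 1e8,
    "leak": 1e-7 * 1e8 * 1e-6,
}


@dataclass(frozen=True)
class CircuitSpec:
    """Initial concentrations, per-reaction thermodynamics and rates."""

    initial: dict[str, float]
    thermo: dict[str, EnergyTerm] = field(default_factory=lambda: dict(_DEFAULT_THERMO))
    rates: dict[str, float] = field(default_factory=lambda: dict(_DEFAULT_RATES))

    def __post_init__(self) -> None:
        for sp in SPECIES:
            if sp not in self.initial:
                raise ValueError(f"initial concentrations missing species {sp!r}")
            if self.initial[sp] < 0:
                raise ValueError(f"negative initial concentration for {sp!r}")
        for r in _DEFAULT_THERMO:
            if r not in self.thermo:
                raise ValueError(f"thermo missing reaction {r!r}")
        for r in _DEFAULT_RATES:
            if r not in self.rates:
                raise ValueError(f"rates missing reaction {r!r}")

    def strand_totals(self) -> dict[str, float]:
        totals: dict[str, float] = {}
        for sp, conc in self.initial.items():
            for strand, k in STRAND_COMPOSITION[sp].items():
                totals[strand] = totals.get(strand, 0.0) + k * conc
        return totals

    def replace(self, **kw) -> "CircuitSpec":
        return replace(self, **kw)


@dataclass(frozen=True)
class Protocol:
    """Ordered (temperature deg C, duration s) phases, repeated ``cycles`` times."""

    phases: tuple[tuple[float, float], ...] = ((65.0, 300.0), (35.0, 28800.0))
    cycles: int = 1

    def __post_init__(self) -> None:
        if self.cycles < 1:
            raise ValueError("cycles must be >= 1")
        for T, dur in self.phases:
            if dur <= 0:
                raise ValueError("phase durations must be positive")

    def expanded(self) -> list[tuple[float, float]]:
        return list(self.phases) * self.cycles


@dataclass(frozen=True)
class Trace:
    """Species time courses with the temperature program and reporter output."""

    data: pd.DataFrame  # columns: time_s, temperature_C, <species...>, reporter_f
    spec: CircuitSpec

    @property
    def reporter_f(self) -> np.ndarray:
        return self.data["reporter_f"].to_numpy()

    def final(self, species: str | None = None) -> float:
        return float(self.data[species or "reporter_f"].iloc[-1])

    def conservation_residual(self) -> float:
        """Max relative per-strand mass-balance violation over the trace."""
        totals = self.spec.strand_totals()
        worst = 0.0
        for strand, total in totals.items():
            if total <= 0:
                continue
            acc = np.zeros(len(self.data))
            for sp, comp in STRAND_COMPOSITION.items():
                if strand in comp:
                    acc += comp[strand] * self.data[sp].to_numpy()
            worst = max(worst, float(np.max(np.abs(acc - total)) / total))
        return worst

    def plot(self, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        t_h = self.data["time_s"] / 3600.0
        ax.plot(t_h, self.data["reporter_f"], label="reporter f")
        ax2 = ax.twinx()
        ax2.plot(t_h, self.data["temperature_C"], color="0.6", lw=0.8, label="T")
        ax.set_xlabel("time (h)")
        ax.set_ylabel("reporter displacement fraction")
        ax2.set_ylabel("temperature (deg C)")
        return ax


@dataclass(frozen=True)
class LogicConfig:
    """Gate configuration: OR thresholds at 0.6 uM, AND at 1.2 uM."""

    gate_type: str = "OR"
    threshold_conc: float | None = None
    input_per_true: float = 1e-6
    on_cutoff: float = 0.5
    operate_T: float = 35.0
    operate_time: float = 28800.0

    def __post_init__(self) -> None:
        if self.gate_type not in ("OR", "AND"):
            raise ValueError("gate_type must be 'OR' or 'AND'")

    @property
    def threshold(self) -> float:
        if self.threshold_conc is not None:
            return self.threshold_conc
        return 0.6e-6 if self.gate_type == "OR" else 1.2e-6


def build_circuit(
    threshold_conc: float = 0.6e-6,
    input_conc: float = 0.0,
    reporter_conc: float = 1e-6,
    gate_conc: float = 2e-6,
    fuel_conc: float = 10e-6,
    thermo: dict[str, EnergyTerm] | None = None,
    rates: dict[str, float] | None = None,
) -> CircuitSpec:
    """Instantiate the default gate: reporter 1 uM, gate/output 2 uM, AC fuels
    10 uM each, threshold as specified (0.6 uM OR / 1.2 uM AND)."""
    for name, c in (("threshold", threshold_conc), ("input", input_conc),
                    ("reporter", reporter_conc), ("gate", gate_conc), ("fuel", fuel_conc)):
        if c < 0:
            raise ValueError(f"{name} concentration must be >= 0")
    initial = {sp: 0.0 for sp in SPECIES}
    initial.update({
        "w": input_conc,
        "Th": threshold_conc,
        "G": gate_conc,
        "AC_i": fuel_conc,
        "AC_a": fuel_conc,
        "AC_r": fuel_conc,
        "I1S1": reporter_conc,
    })
    kw = {}
    if thermo is not None:
        kw["thermo"] = {**_DEFAULT_THERMO, **thermo}
    if rates is not None:
        kw["rates"] = {**_DEFAULT_RATES, **rates}
    return CircuitSpec(initial=initial, **kw)


def _K(spec: CircuitSpec, reaction: str, T_K: float) -> float:
    return math.exp(-spec.thermo[reaction].dG(T_K) / (R_KCAL * T_K))


def _rhs_factory(spec: CircuitSpec, T_C: float):
    T_K = T_C + CELSIUS_OFFSET
    k_th, k_in, k_am, k_re, k_lk = (spec.rates[r] for r in
                                    ("thresholding", "initiation", "amplification", "reporting", "leak"))
    K_th, K_in, K_am, K_re = (_K(spec, r, T_K) for r in
                              ("thresholding", "initiation", "amplification", "reporting"))
    idx = {sp: i for i, sp in enumerate(SPECIES)}
    iw, ith, iwt, ig = idx["w"], idx["Th"], idx["W_th"], idx["G"]
    iaci, iaca, iacr = idx["AC_i"], idx["AC_a"], idx["AC_r"]
    ici, ica, io, iis, ii1, icr = idx["C_i"], idx["C_a"], idx["O"], idx["I1S1"], idx["I1"], idx["C_r"]

    def rhs(_t, y):
        w, th, wt, g = y[iw], y[ith], y[iwt], y[ig]
        aci, aca, acr = y[iaci], y[iaca], y[iacr]
        ci, ca, o, is_, i1, cr = y[ici], y[ica], y[io], y[iis], y[ii1], y[icr]
        r_th = k_th * (w * th - wt / K_th)
        r_in = k_in * (w * g * aci - ci * o / K_in)
        r_am = k_am * w * (g * aca - ca * o / K_am)  # catalysed by free input
        r_lk = k_lk * (g * aca - ca * o / K_am)
        r_re = k_re * (o * is_ * acr - cr * i1 / K_re)
        dy = np.zeros_like(y)
        dy[iw] = -r_th - r_in
        dy[ith] = -r_th
        dy[iwt] = r_th
        dy[ig] = -r_in - r_am - r_lk
        dy[iaci] = -r_in
        dy[ici] = r_in
        dy[iaca] = -r_am - r_lk
        dy[ica] = r_am + r_lk
        dy[io] = r_in + r_am + r_lk - r_re
        dy[iacr] = -r_re
        dy[icr] = r_re
        dy[iis] = -r_re
        dy[ii1] = r_re
        return dy

    return rhs


def simulate(
    spec: CircuitSpec,
    protocol: Protocol,
    record_dt: float = 60.0,
    rtol: float = 1e-8,
    atol: float = 1e-16,
    y0: np.ndarray | None = None,
) -> Trace:
    """Stiff ODE integration of the gate under a temperature protocol.

    Phases run back-to-back with instantaneous temperature switches; output
    is recorded on a ``record_dt`` grid (default one minute, plus each
    phase endpoint).  Raises with the last good state on integrator failure.
    """
    y = np.array([spec.initial[sp] for sp in SPECIES], float) if y0 is None else np.asarray(y0, float).copy()
    rep_total = spec.initial["I1S1"] + spec.initial["C_r"] + spec.initial["I1"]
    rows = []
    t0 = 0.0
    for T_C, dur in protocol.expanded():
        rhs = _rhs_factory(spec, T_C)
        t_eval = np.unique(np.concatenate([np.arange(0.0, dur, record_dt), [dur]]))
        sol = solve_ivp(rhs, (0.0, dur), y, method="LSODA", rtol=rtol, atol=atol, t_eval=t_eval)
        if not sol.success:
            raise RuntimeError(
                f"circuit integration failed at T = {T_C} C, t = {t0 + sol.t[-1]:.1f} s: "
                f"{sol.message}; last state {dict(zip(SPECIES, sol.y[:, -1]))}"
            )
        block = pd.DataFrame(sol.y.T, columns=SPECIES)
        block.insert(0, "temperature_C", T_C)
        block.insert(0, "time_s", sol.t + t0)
        rows.append(block)
        y = sol.y[:, -1].copy()
        t0 += dur
    data = pd.concat(rows, ignore_index=True)
    data["reporter_f"] = 1.0 - data["I1S1"] / rep_total if rep_total > 0 else 0.0
    return Trace(data=data, spec=spec)


def input_output_curve(
    threshold_conc: float = 0.6e-6,
    inputs: list[float] | np.ndarray | None = None,
    operate_time: float = 28800.0,
    operate_T: float = 35.0,
    **build_kw,
) -> pd.DataFrame:
    """End-of-operation reporter fraction for each input concentration.

    Defaults follow the characterization protocol: inputs 0 to 1 uM in
    0.1 uM steps against a 0.6 uM threshold, 8 h at 35 C.
    """
    if inputs is None:
        inputs = np.round(np.arange(0.0, 1.05, 0.1), 10) * 1e-6
    rows = []
    for inp in inputs:
        if inp < 0:
            raise ValueError("input concentrations must be >= 0")
        spec = build_circuit(threshold_conc=threshold_conc, input_conc=float(inp), **build_kw)
        tr = simulate(spec, Protocol(phases=((operate_T, operate_time),), cycles=1))
        rows.append({"input_M": float(inp), "reporter_f": tr.final()})
    return pd.DataFrame(rows)


def logic_eval(cfg: LogicConfig, true_inputs: int, **build_kw) -> tuple[str, float]:
    """Evaluate the gate for 0, 1 or 2 TRUE inputs; returns ("ON"/"OFF", f).

    Each TRUE input contributes ``input_per_true`` (1 uM) of input strand;
    the gate is ON when the end-of-operation reporter fraction reaches
    ``on_cutoff``.
    """
    if true_inputs not in (0, 1, 2):
        raise ValueError("true_inputs must be 0, 1 or 2")
    spec = build_circuit(
        threshold_conc=cfg.threshold,
        input_conc=true_inputs * cfg.input_per_true,
        **build_kw,
    )
    tr = simulate(spec, Protocol(phases=((cfg.operate_T, cfg.operate_time),), cycles=1))
    f = tr.final()
    return ("ON" if f >= cfg.on_cutoff else "OFF"), f
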