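"""Nearest-neighbor DNA thermodynamics.

Enthalpy/entropy bookkeeping for the helical elements that make up a TAD
(temperature-dependent associative strand displacement) system: duplexes,
hairpin stems with entropic loop penalties, and a tunable four-way-junction
term.  The built-in parameter set is the unified oligonucleotide
nearest-neighbor table (10 stacks + duplex initiation + terminal-AT penalty)
shipped as a plain TSV data file; users may substitute their own table.

Units follow the thermodynamics literature throughout this module:
``dH`` in kcal/mol, ``dS`` in cal/(mol K), temperatures in kelvin.  All
user-facing interfaces elsewhere in the package speak degrees Celsius.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Callable

__all__ = [
    "R_CAL",
    "CELSIUS_OFFSET",
    "AlphabetError",
    "DomainSeq",
    "EnergyTerm",
    "SaltModel",
    "ThermoParams",
    "default_params",
    "load_nn_table",
    "duplex_energy",
    "hairpin_energy",
    "free_energy",
    "salt_correct",
    "duplex_tm",
    "revcomp",
]

#: Gas constant in cal/(mol K).
R_CAL = 1.987204258640832
#: Gas constant in kcal/(mol K).
R_KCAL = R_CAL / 1000.0
CELSIUS_OFFSET = 273.15

_COMPLEMENT = str.maketrans("ACGT", "TGCA")
_ALPHABET = frozenset("ACGT")


class AlphabetError(ValueError):
    """Sequence contains a character outside {A, C, G, T}."""


def revcomp(seq: str) -> str:
    """Reverse complement of a 5'->3' DNA sequence (returned 5'->3')."""
    _check_alphabet(seq)
    return seq.translate(_COMPLEMENT)[::-1]


def _check_alphabet(seq: str) -> None:
    bad = set(seq) - _ALPHABET
    if bad:
        raise AlphabetError(f"non-ACGT character(s) {sorted(bad)} in {seq!r}")


@dataclass(frozen=True)
class DomainSeq:
    """A named DNA domain, written 5'->3' over {A, C, G, T}.

    Domains are the sequence-level building blocks of a TAD design (the
    toehold alpha and branch-migration domains beta/gamma of the substrate).
    """

    name: str
    bases: str

    def __post_init__(self) -> None:
        if not self.bases:
            raise ValueError(f"domain {self.name!r} must be non-empty")
        _check_alphabet(self.bases)

    def __len__(self) -> int:
        return len(self.bases)

    @property
    def gc_fraction(self) -> float:
        return (self.bases.count("G") + self.bases.count("C")) / len(self.bases)

    def revcomp(self, name: str | None = None) -> "DomainSeq":
        return DomainSeq(name or f"{self.name}*", revcomp(self.bases))


@dataclass(frozen=True)
class EnergyTerm:
    """An enthalpy/entropy pair: ``dH`` kcal/mol, ``dS`` cal/(mol K)."""

    dH: float = 0.0
    dS: float = 0.0

    def __post_init__(self) -> None:
        if not (math.isfinite(self.dH) and math.isfinite(self.dS)):
            raise ValueError("EnergyTerm components must be finite")

    def __add__(self, other: "EnergyTerm") -> "EnergyTerm":
        return EnergyTerm(self.dH + other.dH, self.dS + other.dS)

    def __sub__(self, other: "EnergyTerm") -> "EnergyTerm":
        return EnergyTerm(self.dH - other.dH, self.dS - other.dS)

    def __mul__(self, k: float) -> "EnergyTerm":
        return EnergyTerm(self.dH * k, self.dS * k)

    __rmul__ = __mul__

    def dG(self, T: float) -> float:
        """Standard free energy dH - T*dS/1000 (kcal/mol) at ``T`` kelvin."""
        return free_energy(self, T)


@dataclass(frozen=True)
class SaltModel:
    """Divalent-cation correction for helix stability (entropy-only).

    The magnesium concentration is folded into an equivalent monovalent
    concentration ``[Na+]_eq = [mono] + mg_coeff * sqrt([Mg2+])`` (molar) and
    the per-base-pair entropy correction ``dS += ds_per_bp * (n_bp - 1) *
    ln[Na+]_eq`` is applied once relative to the 1 M reference state.
    """

    mg_coeff: float = 3.795
    ds_per_bp: float = 0.368
    ref_na_M: float = 1.0

    def equivalent_na(self, mg_mM: float, mono_mM: float) -> float:
        if mg_mM < 0 or mono_mM < 0:
            raise ValueError("ionic concentrations must be non-negative")
        return mono_mM / 1e3 + self.mg_coeff * math.sqrt(mg_mM / 1e3)


@dataclass(frozen=True)
class ThermoParams:
    """Complete nearest-neighbor parameter set.

    ``nn_table`` maps the 10 unique stacks (keyed by the 5'->3' top-strand
    dinucleotide) to :class:`EnergyTerm`; ``initiation`` is the bimolecular
    duplex-initiation term and ``terminal_at`` the per-end A/T penalty.
    ``hairpin_loop_dS`` maps loop length (nt >= 3) to cal/(mol K).
    ``junction`` is the per-four-way-junction penalty, default (0, 0) and
    calibratable against an observed displacing temperature.  ``coaxial``
    is an optional stacking bonus per blunt-end stem junction (default off).
    """

    nn_table: dict[str, EnergyTerm]
    initiation: EnergyTerm
    terminal_at: EnergyTerm
    hairpin_loop_dS: Callable[[int], float]
    junction: EnergyTerm = EnergyTerm(0.0, 0.0)
    coaxial: EnergyTerm = EnergyTerm(0.0, 0.0)
    salt_model: SaltModel = field(default_factory=SaltModel)
    ref_conc: float = 1.0  # mol/L, bimolecular standard state

    def __post_init__(self) -> None:
        if len(self.nn_table) != 10:
            raise ValueError("nn_table must contain exactly the 10 unique stacks")

    def with_junction(self, junction: EnergyTerm) -> "ThermoParams":
        return replace(self, junction=junction)

    def stack(self, dinuc: str) -> EnergyTerm:
        """Energy of the stack whose top strand reads ``dinuc`` 5'->3'."""
        try:
            return self.nn_table[dinuc]
        except KeyError:
            # the 10 unique stacks cover each dinucleotide or its reverse
            # complement; map e.g. "AC" -> "GT"
            return self.nn_table[revcomp(dinuc)]


def _parse_tsv(name: str) -> list[tuple[str, float, float]]:
    rows = []
    text = resources.files("tadsim.data").joinpath(name).read_text()
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#") or line.startswith("stack\t") or line.startswith("loop_nt\t"):
            continue
        parts = line.split("\t")
        rows.append((parts[0], float(parts[1]), float(parts[2]) if len(parts) > 2 else math.nan))
    return rows


def load_nn_table(path: str | None = None) -> tuple[dict[str, EnergyTerm], EnergyTerm, EnergyTerm]:
    """Load (nn_table, initiation, terminal_at) from a TSV file.

    ``path=None`` loads the packaged unified table.  The file format is
    three tab-separated columns ``stack  dH  dS``; stacks are written
    ``XY/X'Y'`` with the two special rows ``init`` and ``term_AT``.
    """
    if path is None:
        rows = _parse_tsv("nn_unified.tsv")
    else:
        rows = []
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#") or line.startswith("stack\t"):
                    continue
                parts = line.split("\t")
                rows.append((parts[0], float(parts[1]), float(parts[2])))
    table: dict[str, EnergyTerm] = {}
    init = term = None
    for key, dh, ds in rows:
        if key == "init":
            init = EnergyTerm(dh, ds)
        elif key == "term_AT":
            term = EnergyTerm(dh, ds)
        else:
            top = key.split("/")[0]
            table[top] = EnergyTerm(dh, ds)
    if init is None or term is None or len(table) != 10:
        raise ValueError("NN table file incomplete: need 10 stacks + init + term_AT")
    return table, init, term


def _loop_ds_interpolator() -> Callable[[int], float]:
    rows = _parse_tsv("hairpin_loops.tsv")
    sizes = [int(r[0]) for r in rows]
    # entropic convention: dS = -1000 * dG37 / 310.15
    ds = [-1000.0 * r[1] / 310.15 for r in rows]

    def loop_ds(n: int) -> float:
        if n < 3:
            raise ValueError(f"hairpin loop must have >= 3 nt, got {n}")
        if n >= sizes[-1]:
            # Jacobson-Stockmayer extrapolation beyond the table
            return ds[-1] - 1.75 * R_CAL * math.log(n / sizes[-1])
        for i in range(1, len(sizes)):
            if n <= sizes[i]:
                lo, hi = sizes[i - 1], sizes[i]
                w = (n - lo) / (hi - lo)
                return ds[i - 1] * (1 - w) + ds[i] * w
        raise AssertionError("unreachable")

    return loop_ds


def default_params() -> ThermoParams:
    """The packaged unified NN parameter set with a zero junction penalty."""
    table, init, term = load_nn_table()
    return ThermoParams(
        nn_table=table,
        initiation=init,
        terminal_at=term,
        hairpin_loop_dS=_loop_ds_interpolator(),
    )


def stack_sum(seq: str, params: ThermoParams) -> EnergyTerm:
    """Sum of NN stack terms over consecutive base pairs of a helix."""
    _check_alphabet(seq)
    total = EnergyTerm()
    for i in range(len(seq) - 1):
        total = total + params.stack(seq[i : i + 2])
    return total


def terminal_penalties(seq: str, params: ThermoParams, ends: tuple[bool, bool] = (True, True)) -> EnergyTerm:
    """Terminal A/T penalties for the selected helix ends (5' end, 3' end)."""
    total = EnergyTerm()
    if ends[0] and seq[0] in "AT":
        total = total + params.terminal_at
    if ends[1] and seq[-1] in "AT":
        total = total + params.terminal_at
    return total


def duplex_energy(a: DomainSeq | str, params: ThermoParams) -> EnergyTerm:
    """Formation energy of the duplex of ``a`` with its exact complement.

    Sum of NN stacks over the ``len(a) - 1`` consecutive base-pair steps,
    plus one bimolecular initiation term and a terminal-AT penalty at each
    A/T-closing end.  Both components are negative for any natural sequence.
    """
    seq = a.bases if isinstance(a, DomainSeq) else a
    if len(seq) < 2:
        raise ValueError("duplex requires length >= 2")
    _check_alphabet(seq)
    return stack_sum(seq, params) + params.initiation + terminal_penalties(seq, params)


def hairpin_energy(stem: DomainSeq | str, loop_len: int, params: ThermoParams) -> EnergyTerm:
    """Formation energy of a hairpin: stem NN stacks + entropic loop penalty.

    Unimolecular, so no initiation term is included.  ``loop_len`` is the
    number of unpaired loop nucleotides (>= 3 for geometric closure).
    """
    seq = stem.bases if isinstance(stem, DomainSeq) else stem
    if len(seq) < 2:
        raise ValueError("hairpin stem requires length >= 2")
    if loop_len < 3:
        raise ValueError(f"hairpin loop must have >= 3 nt, got {loop_len}")
    _check_alphabet(seq)
    return stack_sum(seq, params) + EnergyTerm(0.0, params.hairpin_loop_dS(loop_len))


def free_energy(e: EnergyTerm, T: float) -> float:
    """Standard free energy dG = dH - T*dS/1000 in kcal/mol at ``T`` kelvin."""
    if T <= 0:
        raise ValueError(f"temperature must be positive kelvin, got {T}")
    return e.dH - T * e.dS / 1000.0


def salt_correct(e: EnergyTerm, n_bp: int, mg_mM: float, mono_mM: float, params: ThermoParams) -> EnergyTerm:
    """Entropy-only divalent correction of a helix energy.

    ``n_bp`` is the number of base pairs in the corrected helix.  The
    enthalpy is unchanged; the entropy is shifted by
    ``ds_per_bp * (n_bp - 1) * ln([Na+]_eq / ref)``.  At the model's 1 M
    reference condition the term is identically zero, so applying the
    correction twice at the same condition is not idempotent by accident
    but because the shift is computed relative to the reference each time
    it is applied; callers apply it exactly once at design construction.
    """
    sm = params.salt_model
    na_eq = sm.equivalent_na(mg_mM, mono_mM)
    if na_eq <= 0:
        raise ValueError("equivalent monovalent concentration must be positive")
    shift = sm.ds_per_bp * max(n_bp - 1, 0) * math.log(na_eq / sm.ref_na_M)
    return EnergyTerm(e.dH, e.dS + shift)


def duplex_tm(seq: str, params: ThermoParams, conc_M: float = 1e-3, mg_mM: float = 0.0, mono_mM: float = 1000.0) -> float:
    """Two-state melting temperature (kelvin) of a non-self-complementary duplex.

    Standard formula Tm = 1000*dH / (dS + R ln(C_T/4)) with total strand
    concentration ``conc_M`` and the entropy salt-corrected to the given
    ionic conditions.
    """
    e = duplex_energy(seq, params)
    e = salt_correct(e, len(seq), mg_mM, mono_mM, params)
    return 1000.0 * e.dH / (e.dS + R_CAL * math.log(conc_M / 4.0))
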