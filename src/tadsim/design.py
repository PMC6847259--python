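"""TAD system construction: design parameters -> reaction stoichiometry & thermodynamics.

A TAD (temperature-dependent associative strand displacement) system consists
of a substrate strand S carrying toehold (alpha) and branch-migration
(beta, gamma) domains, an incumbent strand I pre-hybridized to beta+gamma,
and one or more associative-complex (AC) strands that collectively hybridize
to alpha+beta+gamma and displace I:

    I.S + sum(AC_i)  <=>  AC.S + I

The displacement is driven cold by the net gain in base pairing
(``delta_bp = len(alpha) + N*L``: the toehold plus N blunt-end stems of
length L formed only in the AC.S complex) and opposed by the entropic cost
of sequestering ``delta_strands = n_AC - 1`` extra strands, plus a
four-way-junction penalty at the stem/substrate branch points.  Hairpin
stems (H_L bp, H_l-nt loop) on the AC strands stay folded off-substrate and
therefore cancel from the net reaction.

Topology per N (overridable via ``AC_TOPOLOGY``): N=0 -> one AC strand with
two hairpins flanking the alpha* region; N=2 -> two AC strands, one hairpin
each, meeting at two blunt-end stems; N=4 -> three AC strands with four
stems.  All three form a pair of four-way junctions with the substrate.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

from .thermo import (
    DomainSeq,
    EnergyTerm,
    ThermoParams,
    hairpin_energy,
    salt_correct,
    stack_sum,
    terminal_penalties,
)

__all__ = [
    "AC_TOPOLOGY",
    "TADDesign",
    "SpeciesSet",
    "NetChange",
    "ReactionThermo",
    "build_design",
    "net_change",
    "reaction_thermo",
    "default_design",
    "DEFAULT_DOMAINS",
]


class TopologyError(ValueError):
    """Unsupported AC-strand topology (e.g. odd N)."""


#: AC-strand count and hairpins-per-strand for each supported N.  The mapping
#: is the reference topology; advanced users may register other values.
AC_TOPOLOGY: dict[int, dict[str, int]] = {
    0: {"n_ac": 1, "n_hairpins": 2},
    2: {"n_ac": 2, "n_hairpins": 2},
    4: {"n_ac": 3, "n_hairpins": 2},
}

# Deterministic default stem sequences.  Blunt-end stems are AT-rich so their
# per-base-pair stability near the operating temperatures is modest, which is
# the regime in which the characterized designs sit (stem count trades off
# against strand-sequestration entropy).  Stems are shared across stems of one
# design, which keeps reaction energies exactly additive in N; hairpin stems
# cancel from the net reaction and only matter for stand-alone diagnostics.
_BLUNT_PATTERN = "ATTA" * 8
_HAIRPIN_PATTERN = "GCGAGT" * 6


def _topology_for(N: int) -> dict[str, int]:
    if N % 2 != 0 or N < 0:
        raise TopologyError(f"N must be an even count >= 0, got {N}")
    if N in AC_TOPOLOGY:
        return AC_TOPOLOGY[N]
    return {"n_ac": N // 2 + 1, "n_hairpins": 2}


@dataclass(frozen=True)
class TADDesign:
    """Full parameterization of one TAD system.

    Concentrations are mol/L: ``C`` per AC strand, ``I_total``/``S_total``
    for incumbent and substrate.  ``junction_count`` defaults to the pair of
    four-way junctions formed in the AC.S complex.
    """

    alpha: DomainSeq
    beta: DomainSeq
    gamma: DomainSeq
    N: int = 0
    L: int = 8
    H_L: int = 6
    H_l: int = 4
    C: float = 10e-6
    I_total: float = 1e-6
    S_total: float = 1e-6
    junction_count: int = 2
    mg_mM: float = 10.0
    mono_mM: float = 0.0
    stem_seq: str | None = None
    hairpin_stem_seq: str | None = None
    name: str = "tad"

    def __post_init__(self) -> None:
        _topology_for(self.N)  # validates N
        if self.N > 0 and self.L < 2:
            raise ValueError("blunt-end stem length L must be >= 2 when N > 0")
        if self.H_L < 2:
            raise ValueError("hairpin stem length H_L must be >= 2")
        if self.H_l < 3:
            raise ValueError("hairpin loop length H_l must be >= 3")
        for label, c in (("C", self.C), ("I_total", self.I_total), ("S_total", self.S_total)):
            if c <= 0:
                raise ValueError(f"concentration {label} must be positive")
        if self.junction_count < 0:
            raise ValueError("junction_count must be >= 0")

    @property
    def n_ac(self) -> int:
        """Number of AC strands (1 for N=0, N/2+1 otherwise)."""
        return _topology_for(self.N)["n_ac"]

    @property
    def blunt_stem(self) -> str:
        return self.stem_seq if self.stem_seq is not None else _BLUNT_PATTERN[: self.L]

    @property
    def hairpin_stem(self) -> str:
        return self.hairpin_stem_seq if self.hairpin_stem_seq is not None else _HAIRPIN_PATTERN[: self.H_L]

    def replace(self, **kw) -> "TADDesign":
        return replace(self, **kw)


@dataclass(frozen=True)
class SpeciesSet:
    """Strand inventory and complex composition maps for one design.

    ``complexes`` maps complex id ("IS", "ACS") to {strand id: copy count}.
    """

    incumbent: tuple[str, float]
    substrate: tuple[str, float]
    ac_strands: tuple[tuple[str, float], ...]
    complexes: Mapping[str, Mapping[str, int]]

    def strand_ids(self) -> list[str]:
        return [self.incumbent[0], self.substrate[0]] + [s for s, _ in self.ac_strands]

    def totals(self) -> dict[str, float]:
        out = {self.incumbent[0]: self.incumbent[1], self.substrate[0]: self.substrate[1]}
        out.update({s: c for s, c in self.ac_strands})
        return out


@dataclass(frozen=True)
class NetChange:
    """Net base pairs gained and net strands consumed on displacement."""

    delta_bp: int
    delta_strands: int


@dataclass(frozen=True)
class ReactionThermo:
    """Standard-state dH/dS of I.S + sum(AC) <=> AC.S + I (products - reactants).

    Includes the junction penalty and ``delta_strands`` bimolecular
    initiation terms; translational/concentration entropy beyond the 1 M
    standard state is carried by the reaction quotient in the equilibrium
    module, not here.
    """

    rxn: EnergyTerm
    delta_bp: int
    delta_strands: int

    def dG(self, T: float) -> float:
        return self.rxn.dG(T)


def build_design(
    alpha: DomainSeq,
    beta: DomainSeq,
    gamma: DomainSeq,
    N: int = 0,
    L: int = 8,
    H_L: int = 6,
    H_l: int = 4,
    C: float = 10e-6,
    I_total: float = 1e-6,
    S_total: float = 1e-6,
    **kw,
) -> tuple[TADDesign, SpeciesSet]:
    """Construct a validated design and its species inventory.

    Deterministic given inputs.  Raises :class:`TopologyError` for odd N and
    ``ValueError`` for invalid geometry or concentrations.
    """
    design = TADDesign(alpha, beta, gamma, N, L, H_L, H_l, C, I_total, S_total, **kw)
    ac_ids = tuple(f"AC{i + 1}" for i in range(design.n_ac))
    species = SpeciesSet(
        incumbent=("I", I_total),
        substrate=("S", S_total),
        ac_strands=tuple((a, C) for a in ac_ids),
        complexes={
            "IS": {"I": 1, "S": 1},
            "ACS": {"S": 1, **{a: 1 for a in ac_ids}},
        },
    )
    return design, species


def net_change(d: TADDesign) -> NetChange:
    """Net stoichiometric change on displacement.

    ``delta_bp = len(alpha) + N*L`` — hairpin stems are excluded because they
    remain base-paired in the free AC strands.  ``delta_strands = n_AC - 1``.
    """
    return NetChange(delta_bp=len(d.alpha) + d.N * d.L, delta_strands=d.n_ac - 1)


def reaction_thermo(d: TADDesign, params: ThermoParams) -> ReactionThermo:
    """Standard-state thermodynamics of the lumped displacement reaction.

    products - reactants =
      [alpha-domain helix + N blunt-end stems, each NN stacks + distal-end
       terminal penalty]
      + delta_strands x initiation
      + junction_count x junction penalty
      + optional coaxial bonus per blunt stem
    The beta/gamma branch-migration duplex and the AC hairpins are formed on
    both sides of the reaction and cancel exactly at the sequence level.
    The entropy is salt-corrected once over the net delta_bp base pairs.
    """
    nc = net_change(d)
    # alpha helix: formed only in AC.S; junction-side end carries no terminal
    # penalty, distal (toehold tip) end does.
    rxn = stack_sum(d.alpha.bases, params) + terminal_penalties(d.alpha.bases, params, ends=(True, False))
    if d.N > 0:
        stem = d.blunt_stem
        per_stem = stack_sum(stem, params) + terminal_penalties(stem, params, ends=(False, True)) + params.coaxial
        rxn = rxn + d.N * per_stem
    rxn = rxn + nc.delta_strands * params.initiation
    rxn = rxn + d.junction_count * params.junction
    rxn = salt_correct(rxn, nc.delta_bp, d.mg_mM, d.mono_mM, params)
    return ReactionThermo(rxn=rxn, delta_bp=nc.delta_bp, delta_strands=nc.delta_strands)


def hairpin_stability(d: TADDesign, params: ThermoParams) -> EnergyTerm:
    """Stand-alone formation energy of one AC hairpin (diagnostic)."""
    return hairpin_energy(d.hairpin_stem, d.H_l, params)


#: Default substrate domains used by the packaged example designs: a 6-nt
#: toehold and 12-nt branch-migration domains.
DEFAULT_DOMAINS: dict[str, DomainSeq] = {
    "alpha": DomainSeq("alpha", "TCACTC"),
    "beta": DomainSeq("beta", "ACCTTCCTACCA"),
    "gamma": DomainSeq("gamma", "TTCCACTCCTTC"),
}


def default_design(N: int = 0, L: int = 8, H_L: int = 6, H_l: int = 4, C: float = 10e-6, **kw) -> TADDesign:
    """The packaged reference design (1 uM I-S pair, 10 mM Mg buffer)."""
    d, _ = build_design(
        DEFAULT_DOMAINS["alpha"],
        DEFAULT_DOMAINS["beta"],
        DEFAULT_DOMAINS["gamma"],
        N=N,
        L=L,
        H_L=H_L,
        H_l=H_l,
        C=C,
        **kw,
    )
    return d
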