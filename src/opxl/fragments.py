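"""Theoretical b/y fragment ions for linear and cross-linked peptides.

Only the b and y series are generated: collision-induced dissociation
spectra of tryptic peptides are dominated by them, and they suffice for
site localization and cross-link validation. Fragments of a cross-linked
pair that span the linked residue carry the intact partner peptide plus
the bridge delta ("cross-link specific ions").
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .chem import (
    CONSTANTS,
    ElementalFormula,
    ModifiedPeptide,
    peptide_mass,
    residue_masses,
)

__all__ = [
    "FragmentIon",
    "BridgeDefinition",
    "CrossLinkCandidate",
    "linear_fragment_ions",
    "crosslink_fragment_ions",
    "crosslink_precursor_mz",
    "ion_table",
    "EK_ISOPEPTIDE",
    "YK_LOSS_WATER",
    "YK_LOSS_AMMONIA",
    "YK_ETHOXYPHOSPHORYL",
    "BUILTIN_BRIDGES",
]


@dataclass(frozen=True)
class FragmentIon:
    """One theoretical backbone fragment ion."""

    series: str  # "b" or "y"
    index: int  # 1 <= index < len(peptide)
    charge: int
    mz: float
    carries_bridge: bool = False
    parent_peptide: str = "sole"  # "sole", "a" or "b" of a pair
    label: str = ""

    def __post_init__(self) -> None:
        if self.mz <= 0:
            raise ValueError("fragment m/z must be positive")


@dataclass(frozen=True)
class BridgeDefinition:
    """A named cross-link chemistry.

    ``delta`` is the elemental change on forming the bridge; for the
    zero-length isopeptide bond it is the loss of one water (H-2 O-1).
    """

    name: str
    donor_residues: frozenset[str]
    acceptor_residues: frozenset[str]
    delta: ElementalFormula

    def __post_init__(self) -> None:
        if not self.donor_residues or not self.acceptor_residues:
            raise ValueError("donor and acceptor residue sets must be nonempty")
        object.__setattr__(self, "donor_residues", frozenset(self.donor_residues))
        object.__setattr__(self, "acceptor_residues", frozenset(self.acceptor_residues))

    @property
    def delta_mass(self) -> float:
        return self.delta.mass


# The observed chemistry: Glu gamma-carboxyl to Lys epsilon-amine with loss
# of water. Asp is admitted as a donor alongside Glu.
EK_ISOPEPTIDE = BridgeDefinition(
    "EK_isopeptide", frozenset("ED"), frozenset("K"), ElementalFormula.parse("H-2 O-1")
)
# Hypothetical Tyr-Lys chemistries, searched as expected-negative modes.
YK_LOSS_WATER = BridgeDefinition(
    "YK_loss_water", frozenset("Y"), frozenset("K"), ElementalFormula.parse("H-2 O-1")
)
YK_LOSS_AMMONIA = BridgeDefinition(
    "YK_loss_ammonia", frozenset("Y"), frozenset("K"), ElementalFormula.parse("H-3 N-1")
)
# Diethyl phosphate bridge minus ethanol: net C2H3O2P, +89.987 Da.
YK_ETHOXYPHOSPHORYL = BridgeDefinition(
    "YK_ethoxyphosphoryl",
    frozenset("Y"),
    frozenset("K"),
    ElementalFormula.parse("C2H3O2P"),
)

BUILTIN_BRIDGES = {
    b.name: b
    for b in (EK_ISOPEPTIDE, YK_LOSS_WATER, YK_LOSS_AMMONIA, YK_ETHOXYPHOSPHORYL)
}


@dataclass(frozen=True)
class CrossLinkCandidate:
    """Two peptides joined at specific sites by a bridge.

    ``peptide_a`` carries the donor site, ``peptide_b`` the acceptor site;
    both site indices are 1-based within their peptide.
    """

    peptide_a: ModifiedPeptide
    site_a: int
    peptide_b: ModifiedPeptide
    site_b: int
    bridge: BridgeDefinition

    def __post_init__(self) -> None:
        for pep, site, pool, role in (
            (self.peptide_a, self.site_a, self.bridge.donor_residues, "donor"),
            (self.peptide_b, self.site_b, self.bridge.acceptor_residues, "acceptor"),
        ):
            if not 1 <= site <= len(pep.sequence):
                raise ValueError(f"{role} site {site} outside peptide")
            if pep.sequence[site - 1] not in pool:
                raise ValueError(
                    f"residue {pep.sequence[site - 1]} at {role} site {site} "
                    f"not in bridge {role} set"
                )

    @property
    def neutral_mass(self) -> float:
        return (
            peptide_mass(self.peptide_a)
            + peptide_mass(self.peptide_b)
            + self.bridge.delta_mass
        )

    def swapped(self) -> "CrossLinkCandidate":
        """The same physical candidate with the peptide roles exchanged.

        Only meaningful when the bridge chemistry is symmetric enough for
        the swap to satisfy the donor/acceptor constraints.
        """
        return CrossLinkCandidate(
            self.peptide_b,
            self.site_b,
            self.peptide_a,
            self.site_a,
            BridgeDefinition(
                self.bridge.name,
                self.bridge.acceptor_residues,
                self.bridge.donor_residues,
                self.bridge.delta,
            ),
        )


def _prefix_masses(p: ModifiedPeptide) -> list[float]:
    """Cumulative residue+mod masses of prefixes 1..i (b-ion neutral part)."""
    masses = residue_masses(p.sequence)
    return [sum(masses[:i]) + p.span_mod_delta(1, i) for i in range(1, len(masses) + 1)]


def _suffix_masses(p: ModifiedPeptide) -> list[float]:
    """Residue+mod masses of suffixes of length 1..i (y-ion neutral part,
    before water)."""
    masses = residue_masses(p.sequence)
    n = len(masses)
    return [
        sum(masses[n - i :]) + p.span_mod_delta(n - i + 1, n) for i in range(1, n + 1)
    ]


def linear_fragment_ions(
    p: ModifiedPeptide,
    charges: Iterable[int] = (1,),
    series: Iterable[str] = ("b", "y"),
    parent_peptide: str = "sole",
) -> list[FragmentIon]:
    """All b/y ions of a linear peptide at the requested charges.

    b_i is the first i residues (plus their modifications) plus the ionizing
    protons; y_i is the last i residues plus water plus the protons.
    """
    charges = sorted(set(charges))
    series = [s for s in ("b", "y") if s in set(series)]
    if not charges:
        raise ValueError("empty charge set")
    if any(z < 1 for z in charges):
        raise ValueError("fragment charges must be >= 1")
    n = len(p.sequence)
    if n < 2:
        raise ValueError("peptide must have at least 2 residues to fragment")
    prefixes = _prefix_masses(p)
    suffixes = _suffix_masses(p)
    ions: list[FragmentIon] = []
    for i in range(1, n):
        for z in charges:
            if "b" in series:
                mz = (prefixes[i - 1] + z * CONSTANTS.proton) / z
                ions.append(
                    FragmentIon("b", i, z, mz, False, parent_peptide, f"b{i}^{z}+")
                )
            if "y" in series:
                mz = (suffixes[i - 1] + CONSTANTS.water + z * CONSTANTS.proton) / z
                ions.append(
                    FragmentIon("y", i, z, mz, False, parent_peptide, f"y{i}^{z}+")
                )
    return ions


def _crosslink_ions_one_side(
    pep: ModifiedPeptide,
    site: int,
    partner_mass: float,
    bridge_delta: float,
    charges: Sequence[int],
    parent: str,
) -> list[FragmentIon]:
    n = len(pep.sequence)
    prefixes = _prefix_masses(pep)
    suffixes = _suffix_masses(pep)
    appendage = partner_mass + bridge_delta
    ions: list[FragmentIon] = []
    for i in range(1, n):
        b_spans = i >= site  # b_i covers residues 1..i
        y_spans = i >= n - site + 1  # y_i covers residues n-i+1..n
        b_neutral = prefixes[i - 1] + (appendage if b_spans else 0.0)
        y_neutral = suffixes[i - 1] + CONSTANTS.water + (appendage if y_spans else 0.0)
        for z in charges:
            ions.append(
                FragmentIon(
                    "b",
                    i,
                    z,
                    (b_neutral + z * CONSTANTS.proton) / z,
                    b_spans,
                    parent,
                    f"{parent}:b{i}^{z}+" + ("*" if b_spans else ""),
                )
            )
            ions.append(
                FragmentIon(
                    "y",
                    i,
                    z,
                    (y_neutral + z * CONSTANTS.proton) / z,
                    y_spans,
                    parent,
                    f"{parent}:y{i}^{z}+" + ("*" if y_spans else ""),
                )
            )
    return ions


def crosslink_fragment_ions(
    x: CrossLinkCandidate, charges: Iterable[int] = (1, 2)
) -> list[FragmentIon]:
    """b/y ions of both peptides of a cross-linked pair.

    Fragments that span the linked site carry the whole partner peptide plus
    the bridge delta and are flagged ``carries_bridge`` — these are the
    cross-link specific ions, containing sequence from both peptides.
    An empty charge set yields an empty list.
    """
    charges = sorted(set(charges))
    if any(z < 1 for z in charges):
        raise ValueError("fragment charges must be >= 1")
    if not charges:
        return []
    mass_a = peptide_mass(x.peptide_a)
    mass_b = peptide_mass(x.peptide_b)
    delta = x.bridge.delta_mass
    ions = _crosslink_ions_one_side(x.peptide_a, x.site_a, mass_b, delta, charges, "a")
    ions += _crosslink_ions_one_side(x.peptide_b, x.site_b, mass_a, delta, charges, "b")
    return ions


def crosslink_precursor_mz(x: CrossLinkCandidate, charge: int) -> float:
    """Precursor m/z of the intact cross-linked pair at a given charge."""
    if charge < 1:
        raise ValueError(f"charge must be >= 1, got {charge}")
    return (x.neutral_mass + charge * CONSTANTS.proton) / charge


def ion_table(ions: Sequence[FragmentIon]) -> str:
    """Tab-separated text table of an ion list."""
    lines = ["series\tindex\tcharge\tmz\tcarries_bridge\tparent"]
    for ion in ions:
        lines.append(
            f"{ion.series}\t{ion.index}\t{ion.charge}\t{ion.mz:.4f}\t"
            f"{ion.carries_bridge}\t{ion.parent_peptide}"
        )
    return "\n".join(lines) + "\n"
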