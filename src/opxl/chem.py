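"""Monoisotopic mass arithmetic for modified peptides.

Everything downstream (fragment generation, candidate enumeration,
validation) reduces to sums of the quantities defined here: elemental
formula masses, residue masses, modification deltas, and charged-ion m/z.
All arithmetic is monoisotopic; average masses are unsupported.
"""

from __future__ import annotations

import json
import math
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from pyteomics import mass as _ptmass

__all__ = [
    "ElementalFormula",
    "Modification",
    "ModifiedPeptide",
    "CONSTANTS",
    "PhysicalConstants",
    "formula_mass",
    "peptide_mass",
    "residue_masses",
    "mz_from_mass",
    "mass_from_mz",
    "immonium_mz",
    "signature_ions",
    "nominal",
    "DEP",
    "MOX",
    "CARBAMIDOMETHYL",
    "BUILTIN_MODIFICATIONS",
    "load_modifications",
]


class FormulaError(ValueError):
    """Unknown element symbol or malformed formula text."""


class SequenceError(ValueError):
    """Residue letter outside the 20 standard amino acids."""


_KNOWN_ELEMENTS = ("C", "H", "N", "O", "P", "S")

#: Monoisotopic atomic masses (Da), most abundant isotope, from the NIST
#: table shipped with pyteomics. Restricted to CHNOPS.
ATOMIC_MASS: Mapping[str, float] = {
    el: _ptmass.nist_mass[el][0][0] for el in _KNOWN_ELEMENTS
}

#: Monoisotopic residue (not free amino acid) masses for the 20 standard
#: one-letter codes, from pyteomics.
RESIDUE_MASS: Mapping[str, float] = dict(_ptmass.std_aa_mass)

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(-?\d*)")


@dataclass(frozen=True)
class ElementalFormula:
    """A signed elemental composition, e.g. ``C4H9O3P`` or ``H-2 O-1``.

    Negative counts express net losses, as in the water loss of the
    zero-length isopeptide bridge.
    """

    element_counts: Mapping[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for el in self.element_counts:
            if el not in ATOMIC_MASS:
                raise FormulaError(f"unknown element symbol: {el!r}")
        object.__setattr__(self, "element_counts", dict(self.element_counts))

    @classmethod
    def parse(cls, text: str) -> "ElementalFormula":
        """Parse ``C4H9O3P``-style text; counts may be signed (``H-2 O-1``)."""
        counts: dict[str, int] = {}
        stripped = text.replace(" ", "")
        pos = 0
        while pos < len(stripped):
            m = _FORMULA_TOKEN.match(stripped, pos)
            if m is None or not m.group(1):
                raise FormulaError(f"malformed formula: {text!r} at offset {pos}")
            el, count = m.group(1), m.group(2)
            counts[el] = counts.get(el, 0) + (int(count) if count else 1)
            pos = m.end()
        return cls(counts)

    @property
    def mass(self) -> float:
        return sum(n * ATOMIC_MASS[el] for el, n in self.element_counts.items())

    def __add__(self, other: "ElementalFormula") -> "ElementalFormula":
        counts = dict(self.element_counts)
        for el, n in other.element_counts.items():
            counts[el] = counts.get(el, 0) + n
        return ElementalFormula({el: n for el, n in counts.items() if n != 0})

    def __str__(self) -> str:
        return " ".join(f"{el}{n}" for el, n in sorted(self.element_counts.items()))


def formula_mass(formula: ElementalFormula | str) -> float:
    """Signed monoisotopic mass of an elemental formula, in Da."""
    if isinstance(formula, str):
        formula = ElementalFormula.parse(formula)
    return formula.mass


@dataclass(frozen=True)
class PhysicalConstants:
    """Fixed mass constants used throughout. Immutable."""

    proton: float = 1.0072765
    water: float = ATOMIC_MASS["H"] * 2 + ATOMIC_MASS["O"]
    ammonia: float = ATOMIC_MASS["N"] + ATOMIC_MASS["H"] * 3
    ethylene: float = ATOMIC_MASS["C"] * 2 + ATOMIC_MASS["H"] * 4
    co: float = ATOMIC_MASS["C"] + ATOMIC_MASS["O"]


CONSTANTS = PhysicalConstants()

#: Terminus markers usable as modification positions.
N_TERM = "nterm"
C_TERM = "cterm"


@dataclass(frozen=True)
class Modification:
    """A named mass modification with its eligible targets.

    ``delta`` is the monoisotopic mass added to the peptide. When a formula
    is given the two must agree to 1e-4 Da.
    """

    name: str
    delta: float
    formula: ElementalFormula | None = None
    targets: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if self.formula is not None and abs(self.formula.mass - self.delta) > 1e-4:
            raise ValueError(
                f"modification {self.name}: delta {self.delta} disagrees with "
                f"formula mass {self.formula.mass}"
            )
        object.__setattr__(self, "targets", frozenset(self.targets))

    @classmethod
    def from_formula(
        cls, name: str, formula: str | ElementalFormula, targets: Iterable[str]
    ) -> "Modification":
        f = ElementalFormula.parse(formula) if isinstance(formula, str) else formula
        return cls(name=name, delta=f.mass, formula=f, targets=frozenset(targets))


# The diethyl phosphate adduct transferred by chlorpyrifos oxon: the full
# diethyl phosphate group minus the proton displaced from the nucleophile.
DEP = Modification.from_formula("Dep", "C4H9O3P", "EDKYSTHR")
MOX = Modification.from_formula("Mox", "O1", "M")
CARBAMIDOMETHYL = Modification.from_formula("Carbamidomethyl", "C2H3N1O1", "C")

BUILTIN_MODIFICATIONS: Mapping[str, Modification] = {
    m.name: m for m in (DEP, MOX, CARBAMIDOMETHYL)
}


def load_modifications(path_or_obj) -> dict[str, Modification]:
    """Load modifications from a JSON config.

    Accepts a path or an already-parsed list of dicts with keys
    ``name``, ``targets`` and either ``formula`` or ``delta``.
    """
    if isinstance(path_or_obj, (str,)) or hasattr(path_or_obj, "__fspath__"):
        with open(path_or_obj) as fh:
            entries = json.load(fh)
    else:
        entries = path_or_obj
    mods: dict[str, Modification] = {}
    for e in entries:
        targets = frozenset(e.get("targets", ""))
        if "formula" in e and e["formula"]:
            f = ElementalFormula.parse(e["formula"])
            delta = e.get("delta", f.mass)
            mods[e["name"]] = Modification(e["name"], delta, f, targets)
        else:
            mods[e["name"]] = Modification(e["name"], float(e["delta"]), None, targets)
    return mods


@dataclass(frozen=True)
class ModifiedPeptide:
    """A residue sequence with positioned modifications.

    Positions are 1-based residue indices, or the terminus markers
    ``"nterm"`` / ``"cterm"``. At most one modification per position;
    each modification's target set must contain the residue at its
    position (terminus mods must target the corresponding marker).
    """

    sequence: str
    mods: tuple[tuple[int | str, Modification], ...] = ()

    def __post_init__(self) -> None:
        if not self.sequence:
            raise SequenceError("empty peptide sequence")
        for ch in self.sequence:
            if ch not in RESIDUE_MASS:
                raise SequenceError(f"unknown residue letter: {ch!r}")
        object.__setattr__(self, "mods", tuple(self.mods))
        seen: set[int | str] = set()
        for pos, mod in self.mods:
            if pos in (N_TERM, C_TERM):
                if pos not in mod.targets:
                    raise ValueError(f"{mod.name} does not target {pos}")
            else:
                if not 1 <= pos <= len(self.sequence):
                    raise ValueError(f"mod position {pos} outside sequence")
                residue = self.sequence[pos - 1]
                if mod.targets and residue not in mod.targets:
                    raise ValueError(
                        f"{mod.name} does not target residue {residue} at {pos}"
                    )
            if pos in seen:
                raise ValueError(f"more than one modification at position {pos}")
            seen.add(pos)

    def __len__(self) -> int:
        return len(self.sequence)

    def with_mod(self, pos: int | str, mod: Modification) -> "ModifiedPeptide":
        return ModifiedPeptide(self.sequence, self.mods + ((pos, mod),))

    def mod_at(self, pos: int | str) -> Modification | None:
        for p, m in self.mods:
            if p == pos:
                return m
        return None

    def span_mod_delta(self, start: int, end: int) -> float:
        """Sum of modification deltas for residue positions start..end (1-based,
        inclusive). Terminus mods count when the span touches that terminus."""
        total = 0.0
        for pos, mod in self.mods:
            if pos == N_TERM:
                if start == 1:
                    total += mod.delta
            elif pos == C_TERM:
                if end == len(self.sequence):
                    total += mod.delta
            elif start <= pos <= end:
                total += mod.delta
        return total

    def __str__(self) -> str:
        marks = {p: m.name for p, m in self.mods if isinstance(p, int)}
        out = []
        for i, ch in enumerate(self.sequence, start=1):
            out.append(ch)
            if i in marks:
                out.append(f"({marks[i]})")
        return "".join(out)


def residue_masses(sequence: str) -> list[float]:
    try:
        return [RESIDUE_MASS[ch] for ch in sequence]
    except KeyError as exc:
        raise SequenceError(f"unknown residue letter: {exc.args[0]!r}") from None


def peptide_mass(p: ModifiedPeptide | str) -> float:
    """Neutral monoisotopic mass: residue sum + water + modification deltas."""
    if isinstance(p, str):
        p = ModifiedPeptide(p)
    total = sum(residue_masses(p.sequence)) + CONSTANTS.water
    total += sum(mod.delta for _, mod in p.mods)
    return total


def mz_from_mass(neutral_mass: float, charge: int) -> float:
    """m/z of the [M + zH]^z+ ion."""
    if charge < 1:
        raise ValueError(f"charge must be >= 1, got {charge}")
    return (neutral_mass + charge * CONSTANTS.proton) / charge


def mass_from_mz(mz: float, charge: int) -> float:
    """Neutral mass recovered from an observed m/z at a given charge."""
    if charge < 1:
        raise ValueError(f"charge must be >= 1, got {charge}")
    return mz * charge - charge * CONSTANTS.proton


def immonium_mz(residue: str) -> float:
    """Immonium ion m/z of a residue: residue mass − CO + proton."""
    masses = residue_masses(residue)
    if len(masses) != 1:
        raise ValueError("immonium_mz takes a single residue letter")
    return masses[0] - CONSTANTS.co + CONSTANTS.proton


def nominal(mz: float) -> int:
    """Nominal (integer) mass, round-half-up."""
    return int(math.floor(mz + 0.5))


def signature_ions(
    residue: str, adduct: Modification = DEP
) -> list[tuple[str, float]]:
    """Low-mass diagnostic ions for an adduct on K, Y or E.

    The base ion is the residue's immonium ion plus the adduct delta. The
    lysine adduct additionally loses ammonia; the tyrosine and glutamate
    adducts show sequential losses of ethylene (from the ethyl esters) and
    water: −C2H4, −(C2H4+H2O), −2×C2H4, −(2×C2H4+H2O).
    """
    if residue not in ("K", "Y", "E"):
        raise ValueError(f"signature ions defined for K, Y, E only; got {residue!r}")
    base = immonium_mz(residue) + adduct.delta
    name = f"{adduct.name}-{residue}"
    ions = [(f"{name}", base)]
    if residue == "K":
        ions.append((f"{name}-NH3", base - CONSTANTS.ammonia))
    else:
        c2h4, h2o = CONSTANTS.ethylene, CONSTANTS.water
        ions.extend(
            [
                (f"{name}-C2H4", base - c2h4),
                (f"{name}-C2H4-H2O", base - c2h4 - h2o),
                (f"{name}-2C2H4", base - 2 * c2h4),
                (f"{name}-2C2H4-H2O", base - 2 * c2h4 - h2o),
            ]
        )
    return ions
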