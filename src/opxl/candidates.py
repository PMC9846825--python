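"""In-silico tryptic digestion and precursor-mass-driven candidate enumeration.

An observed precursor constrains candidates by mass alone: a linear peptide
plus one diethyl phosphate adduct on an eligible residue, or two peptides
joined by a bridge chemistry. Enumeration returns every candidate whose
theoretical precursor m/z lies within a ppm tolerance of the observation;
validation then decides.
"""

from __future__ import annotations

import bisect
import itertools
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .chem import (
    DEP,
    Modification,
    ModifiedPeptide,
    SequenceError,
    mass_from_mz,
    mz_from_mass,
    peptide_mass,
    RESIDUE_MASS,
)
from .fragments import BridgeDefinition, CrossLinkCandidate

__all__ = [
    "DigestSpec",
    "DigestPeptide",
    "AdductCandidate",
    "digest",
    "enumerate_adduct_candidates",
    "enumerate_crosslink_candidates",
    "DEFAULT_DEP_TARGETS",
]

#: Residues searched for the diethyl phosphate adduct. The study searched
#: E, D, K, Y, H, R, S and T; adducts were found only on E, D, K, Y, S, T.
DEFAULT_DEP_TARGETS = frozenset("EDKYSTHR")


@dataclass(frozen=True)
class DigestSpec:
    """Trypsin digestion parameters: cleave after K/R, not before P.

    ``specificity``: "full" (both termini tryptic), "semi" (at least one),
    or "none" (any subsequence). Internal uncleaved K/R sites are counted
    as missed cleavages under every specificity.
    """

    specificity: str = "semi"
    max_missed_cleavages: int = 2
    min_length: int = 4
    max_length: int = 40

    def __post_init__(self) -> None:
        if self.specificity not in ("full", "semi", "none"):
            raise ValueError(f"unknown specificity: {self.specificity!r}")
        if self.max_missed_cleavages < 0:
            raise ValueError("max_missed_cleavages must be >= 0")
        if not 1 <= self.min_length <= self.max_length:
            raise ValueError("need 1 <= min_length <= max_length")


@dataclass(frozen=True)
class DigestPeptide:
    """A digestion product with its 1-based start position in the protein."""

    sequence: str
    protein_id: str
    start: int  # 1-based position of the first residue in the protein

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class AdductCandidate:
    """One peptide with a single adduct placed on a specific residue.

    ``site`` is 1-based within the peptide; ``protein_position`` is the
    1-based coordinate of that residue in the parent protein (the notation
    used for sites like E411 or K1635).
    """

    peptide: ModifiedPeptide
    site: int
    protein_id: str = ""
    protein_position: int = 0

    @property
    def site_label(self) -> str:
        return f"{self.peptide.sequence[self.site - 1]}{self.protein_position}"


def _cleavage_points(seq: str) -> list[int]:
    """0-based indices i such that trypsin cleaves between seq[i-1] and seq[i]."""
    return [
        i
        for i in range(1, len(seq))
        if seq[i - 1] in "KR" and seq[i] != "P"
    ]


def digest(
    protein: str, spec: DigestSpec = DigestSpec(), protein_id: str = ""
) -> list[DigestPeptide]:
    """Enumerate digestion products of one protein sequence.

    Yields every peptide compatible with the cleavage rule, specificity,
    missed-cleavage and length limits, each with its 1-based start.
    """
    if not protein:
        raise SequenceError("empty protein sequence")
    for ch in protein:
        if ch not in RESIDUE_MASS:
            raise SequenceError(f"unknown residue letter: {ch!r}")
    n = len(protein)
    cut_set = set(_cleavage_points(protein))
    boundaries = [0] + sorted(cut_set) + [n]

    def internal_missed(start: int, end: int) -> int:
        return sum(1 for c in cut_set if start < c < end)

    out: list[DigestPeptide] = []
    seen: set[tuple[int, int]] = set()

    def emit(start: int, end: int) -> None:
        if (start, end) in seen:
            return
        length = end - start
        if not spec.min_length <= length <= spec.max_length:
            return
        if internal_missed(start, end) > spec.max_missed_cleavages:
            return
        seen.add((start, end))
        out.append(DigestPeptide(protein[start:end], protein_id, start + 1))

    if spec.specificity == "none":
        for start in range(n):
            for end in range(start + spec.min_length, min(n, start + spec.max_length) + 1):
                emit(start, end)
    else:
        bset = set(boundaries)
        # fully tryptic products: consecutive boundary pairs
        for ai, start in enumerate(boundaries[:-1]):
            for end in boundaries[ai + 1 :]:
                if internal_missed(start, end) > spec.max_missed_cleavages:
                    break
                emit(start, end)
        if spec.specificity == "semi":
            # one ragged terminus: shrink one side of each fully tryptic span
            for ai, start in enumerate(boundaries[:-1]):
                for end in boundaries[ai + 1 :]:
                    if internal_missed(start, end) > spec.max_missed_cleavages:
                        break
                    for s2 in range(start + 1, end):
                        if s2 not in bset:
                            emit(s2, end)
                    for e2 in range(start + 1, end):
                        if e2 not in bset:
                            emit(start, e2)
    out.sort(key=lambda p: (p.start, len(p.sequence)))
    return out


def _ppm_error(theoretical: float, observed: float) -> float:
    return (observed - theoretical) / theoretical * 1e6


def enumerate_adduct_candidates(
    peptides: Iterable[DigestPeptide | str],
    target_residues: Iterable[str],
    adduct: Modification,
    precursor_mz: float,
    charge: int,
    tol_ppm: float = 10.0,
    fixed_mods: Sequence[Modification] = (),
) -> list[AdductCandidate]:
    """All single-adduct placements matching the observed precursor mass.

    One candidate per (peptide, eligible site). ``fixed_mods`` (e.g.
    carbamidomethyl-C) are applied to every eligible residue before the
    mass comparison.
    """
    targets = frozenset(target_residues)
    if not targets:
        raise ValueError("empty adduct target residue set")
    if tol_ppm <= 0:
        raise ValueError("tol_ppm must be positive")
    observed_mass = mass_from_mz(precursor_mz, charge)
    out: list[AdductCandidate] = []
    for pep in peptides:
        if isinstance(pep, str):
            pep = DigestPeptide(pep, "", 1)
        base = ModifiedPeptide(pep.sequence)
        for mod in fixed_mods:
            for i, ch in enumerate(pep.sequence, start=1):
                if ch in mod.targets:
                    base = base.with_mod(i, mod)
        base_mass = peptide_mass(base)
        theoretical = base_mass + adduct.delta
        if abs(_ppm_error(theoretical, observed_mass)) > tol_ppm:
            continue
        for i, ch in enumerate(pep.sequence, start=1):
            if ch in targets and ch in adduct.targets and base.mod_at(i) is None:
                out.append(
                    AdductCandidate(
                        peptide=base.with_mod(i, adduct),
                        site=i,
                        protein_id=pep.protein_id,
                        protein_position=pep.start + i - 1,
                    )
                )
    return out


def enumerate_crosslink_candidates(
    peptides: Sequence[DigestPeptide | str],
    bridge: BridgeDefinition,
    precursor_mz: float,
    charge: int,
    tol_ppm: float = 10.0,
) -> list[CrossLinkCandidate]:
    """All site-resolved peptide pairs matching the observed precursor mass.

    Pairs may come from the same protein (the data include an internal
    cross-link within one protein). The donor-site peptide is stored as
    ``peptide_a``; duplicates arising from role-symmetric pairs are
    suppressed with an order-insensitive key.
    """
    if tol_ppm <= 0:
        raise ValueError("tol_ppm must be positive")
    pool = [
        DigestPeptide(p, "", 1) if isinstance(p, str) else p for p in peptides
    ]
    observed_mass = mass_from_mz(precursor_mz, charge)
    masses = [peptide_mass(p.sequence) for p in pool]
    order = sorted(range(len(pool)), key=masses.__getitem__)
    sorted_masses = [masses[i] for i in order]
    half_width = observed_mass * tol_ppm * 1e-6 * 1.01  # prefilter; exact check below
    out: list[CrossLinkCandidate] = []
    seen: set[frozenset] = set()
    pairs: list[tuple[int, int]] = []
    for ia in range(len(pool)):
        need = observed_mass - bridge.delta_mass - masses[ia]
        lo = bisect.bisect_left(sorted_masses, need - half_width)
        hi = bisect.bisect_right(sorted_masses, need + half_width)
        pairs.extend((ia, order[j]) for j in range(lo, hi))
    for ia, ib in pairs:
        pa, pb = pool[ia], pool[ib]
        pair_mass = masses[ia] + masses[ib] + bridge.delta_mass
        if abs(_ppm_error(pair_mass, observed_mass)) > tol_ppm:
            continue
        donor_sites = [
            i
            for i, ch in enumerate(pa.sequence, start=1)
            if ch in bridge.donor_residues
        ]
        acceptor_sites = [
            i
            for i, ch in enumerate(pb.sequence, start=1)
            if ch in bridge.acceptor_residues
        ]
        for sa, sb in itertools.product(donor_sites, acceptor_sites):
            key = frozenset(
                [("donor", ia, sa), ("acceptor", ib, sb), ("bridge", bridge.name)]
            )
            if key in seen:
                continue
            seen.add(key)
            out.append(
                CrossLinkCandidate(
                    ModifiedPeptide(pa.sequence),
                    sa,
                    ModifiedPeptide(pb.sequence),
                    sb,
                    bridge,
                )
            )
    return out
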