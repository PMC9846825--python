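"""Peak matching, adduct-site localization and candidate validation.

A candidate identification is accepted only when the spectrum carries the
specific evidence the chemistry predicts. For an adduct: fragment ions that
pin the modified residue to a single position, plus a correct precursor
mass. For a cross-link: a high assigned-peak fraction, a run of at least
two cross-link-specific ions in one series, fragment support for both
peptides, survival of an alternative-explanation (false-positive) screen,
and a correct precursor mass.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

from .chem import (
    CONSTANTS,
    DEP,
    ModifiedPeptide,
    mz_from_mass,
    peptide_mass,
    signature_ions,
)
from .candidates import AdductCandidate
from .fragments import (
    CrossLinkCandidate,
    FragmentIon,
    crosslink_fragment_ions,
    crosslink_precursor_mz,
    linear_fragment_ions,
)

__all__ = [
    "Spectrum",
    "PeakAssignment",
    "ValidationVerdict",
    "ValidationConfig",
    "AMBIGUOUS",
    "match_peaks",
    "assigned_fraction",
    "localize_adduct",
    "evaluate_adduct",
    "evaluate_crosslink",
    "false_positive_screen",
]

AMBIGUOUS = "ambiguous"


@dataclass(frozen=True)
class Spectrum:
    """A centroided peak list with its precursor."""

    identifier: str
    precursor_mz: float
    precursor_charge: int
    mz: np.ndarray
    intensity: np.ndarray

    def __post_init__(self) -> None:
        mz = np.asarray(self.mz, dtype=float)
        inten = np.asarray(self.intensity, dtype=float)
        if mz.shape != inten.shape:
            raise ValueError("mz and intensity arrays differ in length")
        if np.any(np.diff(mz) < 0):
            raise ValueError("peaks must be sorted by m/z")
        if np.any(inten < 0):
            raise ValueError("intensities must be nonnegative")
        if self.precursor_charge < 1:
            raise ValueError("precursor charge must be >= 1")
        object.__setattr__(self, "mz", mz)
        object.__setattr__(self, "intensity", inten)

    @classmethod
    def from_peaks(
        cls,
        identifier: str,
        precursor_mz: float,
        precursor_charge: int,
        peaks: Iterable[tuple[float, float]],
    ) -> "Spectrum":
        pk = sorted(peaks)
        mz = np.array([p[0] for p in pk], dtype=float)
        inten = np.array([p[1] for p in pk], dtype=float)
        return cls(identifier, precursor_mz, precursor_charge, mz, inten)

    def __len__(self) -> int:
        return len(self.mz)


@dataclass(frozen=True)
class PeakAssignment:
    """One observed peak explained by one theoretical ion."""

    peak_index: int
    ion: FragmentIon
    error_da: float
    error_ppm: float


@dataclass(frozen=True)
class ValidationConfig:
    """Thresholds of the acceptance procedure.

    The assigned-fraction rule requires more than ``assigned_fraction_cutoff``
    of the ``top_n`` most intense peaks to be assigned; a cross-link further
    needs at least ``min_series_ions`` consecutive bridge-carrying ions in
    one series. Signature ions corroborate adducts and can be made
    mandatory per residue (they were never observed for Dep-Glu, so E is
    excluded from any mandatory set by default).
    """

    fragment_tol_da: float = 0.02
    precursor_tol_ppm: float = 10.0
    assigned_fraction_cutoff: float = 0.40
    top_n: int = 50
    min_series_ions: int = 2
    fragment_charges: tuple[int, ...] = (1, 2)
    require_signature_for: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if not 0 < self.assigned_fraction_cutoff < 1:
            raise ValueError("assigned_fraction_cutoff must be in (0,1)")


@dataclass(frozen=True)
class ValidationVerdict:
    """Per-criterion record and the accept/reject decision for a candidate."""

    candidate: object
    assigned_fraction: float = 0.0
    xl_specific_series_count: int = 0
    both_peptides_supported: bool = False
    fp_screen_passed: bool = True
    parent_mass_ok: bool = False
    localized_site: int | str = AMBIGUOUS
    signature_ions_found: tuple[str, ...] = ()
    decision: str = "reject"
    assignments: tuple[PeakAssignment, ...] = ()


def match_peaks(
    s: Spectrum, ions: Sequence[FragmentIon], tol_da: float
) -> list[PeakAssignment]:
    """Greedy 1:1 matching of theoretical ions to observed peaks.

    Candidate (peak, ion) pairs within ``tol_da`` are accepted in order of
    increasing absolute mass error; each peak and each ion is used at most
    once.
    """
    if tol_da <= 0:
        raise ValueError("tol_da must be positive")
    if len(s) == 0 or not ions:
        return []
    pairs: list[tuple[float, int, int]] = []
    for j, ion in enumerate(ions):
        lo = int(np.searchsorted(s.mz, ion.mz - tol_da, side="left"))
        hi = int(np.searchsorted(s.mz, ion.mz + tol_da, side="right"))
        for i in range(lo, hi):
            pairs.append((abs(s.mz[i] - ion.mz), i, j))
    pairs.sort()
    used_peaks: set[int] = set()
    used_ions: set[int] = set()
    out: list[PeakAssignment] = []
    for err, i, j in pairs:
        if i in used_peaks or j in used_ions:
            continue
        used_peaks.add(i)
        used_ions.add(j)
        ion = ions[j]
        out.append(
            PeakAssignment(
                peak_index=i,
                ion=ion,
                error_da=float(s.mz[i] - ion.mz),
                error_ppm=float((s.mz[i] - ion.mz) / ion.mz * 1e6),
            )
        )
    out.sort(key=lambda a: a.peak_index)
    return out


def assigned_fraction(
    s: Spectrum, assignments: Sequence[PeakAssignment], top_n: int = 50
) -> float:
    """Fraction of the ``top_n`` most intense peaks that carry an assignment."""
    if top_n < 1:
        raise ValueError("top_n must be >= 1")
    if len(s) == 0:
        return 0.0
    k = min(top_n, len(s))
    top = set(np.argsort(s.intensity, kind="stable")[::-1][:k].tolist())
    assigned = {a.peak_index for a in assignments}
    return len(top & assigned) / k


def _span_includes(ion: FragmentIon, site: int, n: int) -> bool:
    """Does this b/y fragment's residue span include 1-based position ``site``?"""
    if ion.series == "b":
        return ion.index >= site
    return ion.index >= n - site + 1  # y_i covers the last i residues


def localize_adduct(
    s: Spectrum,
    candidates: Sequence[AdductCandidate],
    tol_da: float = 0.02,
    charges: Iterable[int] = (1, 2),
) -> int | str:
    """Pin the adduct to one residue, or report ambiguity.

    For each candidate placement the spectrum is matched against that
    placement's theoretical ions. Matched fragments constrain the site: a
    mass-shifted fragment must contain it, an unshifted fragment must not.
    The placement is accepted only if it is the single candidate site
    compatible with its own constraints and it is supported by at least one
    shifted and one unshifted fragment.
    """
    if not candidates:
        return AMBIGUOUS
    sites = sorted({c.site for c in candidates})
    by_site = {c.site: c for c in candidates}
    n = len(candidates[0].peptide.sequence)
    winners: list[int] = []
    for site in sites:
        cand = by_site[site]
        ions = linear_fragment_ions(cand.peptide, charges=charges)
        assignments = match_peaks(s, ions, tol_da)
        lo, hi = 1, n  # feasible site interval implied by matched ions
        n_shifted = n_unshifted = 0
        for a in assignments:
            if _span_includes(a.ion, site, n):
                n_shifted += 1
                if a.ion.series == "b":
                    hi = min(hi, a.ion.index)
                else:
                    lo = max(lo, n - a.ion.index + 1)
            else:
                n_unshifted += 1
                if a.ion.series == "b":
                    lo = max(lo, a.ion.index + 1)
                else:
                    hi = min(hi, n - a.ion.index)
        if n_shifted == 0 or n_unshifted == 0:
            continue
        feasible = [t for t in sites if lo <= t <= hi]
        if feasible == [site]:
            winners.append(site)
    if len(winners) == 1:
        return winners[0]
    return AMBIGUOUS


def evaluate_adduct(
    s: Spectrum,
    c: AdductCandidate,
    config: ValidationConfig = ValidationConfig(),
    site_alternatives: Sequence[AdductCandidate] | None = None,
) -> ValidationVerdict:
    """Accept an adduct candidate iff its site is uniquely localized and the
    precursor mass matches.

    ``site_alternatives`` lists competing placements on the same peptide
    (defaults to every eligible placement per the adduct's target set);
    localization must rule all of them out. Signature ions are recorded as
    corroboration and required only for residues in
    ``config.require_signature_for``.
    """
    adduct = next(m for p, m in c.peptide.mods if p == c.site)
    if site_alternatives is None:
        plain = ModifiedPeptide(
            c.peptide.sequence, tuple((p, m) for p, m in c.peptide.mods if p != c.site)
        )
        site_alternatives = [
            replace(c, peptide=plain.with_mod(i, adduct), site=i,
                    protein_position=c.protein_position - c.site + i)
            for i, ch in enumerate(c.peptide.sequence, start=1)
            if ch in adduct.targets and (plain.mod_at(i) is None or i == c.site)
        ]
    theo_mz = mz_from_mass(peptide_mass(c.peptide), s.precursor_charge)
    parent_ok = (
        abs(s.precursor_mz - theo_mz) / theo_mz * 1e6 <= config.precursor_tol_ppm
    )
    site = localize_adduct(
        s, site_alternatives, config.fragment_tol_da, config.fragment_charges
    )
    ions = linear_fragment_ions(c.peptide, charges=config.fragment_charges)
    assignments = match_peaks(s, ions, config.fragment_tol_da)
    frac = assigned_fraction(s, assignments, config.top_n)

    residue = c.peptide.sequence[c.site - 1]
    sig_found: list[str] = []
    if residue in ("K", "Y", "E"):
        for label, mz in signature_ions(residue, adduct):
            lo = np.searchsorted(s.mz, mz - config.fragment_tol_da)
            hi = np.searchsorted(s.mz, mz + config.fragment_tol_da)
            if hi > lo:
                sig_found.append(label)
    sig_ok = residue not in config.require_signature_for or bool(sig_found)

    accept = parent_ok and site == c.site and sig_ok
    return ValidationVerdict(
        candidate=c,
        assigned_fraction=frac,
        parent_mass_ok=parent_ok,
        localized_site=site,
        signature_ions_found=tuple(sig_found),
        fp_screen_passed=True,
        both_peptides_supported=True,
        decision="accept" if accept else "reject",
        assignments=tuple(assignments),
    )


def _max_series_run(flagged: Sequence[PeakAssignment]) -> int:
    """Longest run of bridge-carrying ions with consecutive indices in one
    (peptide, series, charge) group. Consecutive indices guarantee the m/z
    step equals the intervening residue mass, so the run defines residues."""
    groups: dict[tuple[str, str, int], list[int]] = {}
    for a in flagged:
        key = (a.ion.parent_peptide, a.ion.series, a.ion.charge)
        groups.setdefault(key, []).append(a.ion.index)
    best = 1 if flagged else 0
    for idxs in groups.values():
        idxs = sorted(set(idxs))
        run = 1
        for prev, cur in zip(idxs, idxs[1:]):
            run = run + 1 if cur == prev + 1 else 1
            best = max(best, run)
    return best


def false_positive_screen(
    s: Spectrum,
    flagged: Sequence[PeakAssignment],
    alt_pool: Sequence[ModifiedPeptide | str],
    tol_da: float = 0.02,
    charges: Iterable[int] = (1, 2),
) -> bool:
    """Screen cross-link-specific peaks against unrelated linear peptides.

    Returns False (screen failed) when a single peptide from ``alt_pool``
    explains, with its ordinary b/y ions, at least as many of the flagged
    peaks as the cross-link hypothesis does — then the "cross-link specific"
    peaks are better read as an unrelated co-fragmented peptide. An empty
    pool or no flagged peaks passes.
    """
    if not flagged or not alt_pool:
        return True
    flagged_mz = np.array(sorted(s.mz[a.peak_index] for a in flagged))
    n_flagged = len(flagged_mz)
    for pep in alt_pool:
        if isinstance(pep, str):
            pep = ModifiedPeptide(pep)
        if len(pep.sequence) < 2:
            continue
        alt_ions = linear_fragment_ions(pep, charges=charges)
        explained = 0
        used = np.zeros(n_flagged, dtype=bool)
        for ion in alt_ions:
            i = int(np.searchsorted(flagged_mz, ion.mz))
            for k in (i - 1, i):
                if 0 <= k < n_flagged and not used[k] and abs(
                    flagged_mz[k] - ion.mz
                ) <= tol_da:
                    used[k] = True
                    explained += 1
                    break
        if explained >= n_flagged:
            return False
    return True


def evaluate_crosslink(
    s: Spectrum,
    x: CrossLinkCandidate,
    alt_pool: Sequence[ModifiedPeptide | str] = (),
    config: ValidationConfig = ValidationConfig(),
) -> ValidationVerdict:
    """Apply the five-part acceptance procedure to a cross-link candidate.

    (1) more than ``assigned_fraction_cutoff`` of the top-N peaks assigned;
    (2) a run of at least ``min_series_ions`` bridge-carrying ions in one
    series; (3) fragment support from both peptides; (4) the
    alternative-explanation screen; (5) precursor mass within tolerance.
    """
    ions = crosslink_fragment_ions(x, charges=config.fragment_charges)
    assignments = match_peaks(s, ions, config.fragment_tol_da)
    frac = assigned_fraction(s, assignments, config.top_n)
    frac_ok = frac > config.assigned_fraction_cutoff

    flagged = [a for a in assignments if a.ion.carries_bridge]
    series_count = _max_series_run(flagged)
    series_ok = series_count >= config.min_series_ions

    parents = {a.ion.parent_peptide for a in assignments}
    both_ok = parents >= {"a", "b"}

    fp_ok = false_positive_screen(
        s, flagged, alt_pool, config.fragment_tol_da, config.fragment_charges
    )

    theo_mz = crosslink_precursor_mz(x, s.precursor_charge)
    parent_ok = (
        abs(s.precursor_mz - theo_mz) / theo_mz * 1e6 <= config.precursor_tol_ppm
    )

    accept = frac_ok and series_ok and both_ok and fp_ok and parent_ok
    return ValidationVerdict(
        candidate=x,
        assigned_fraction=frac,
        xl_specific_series_count=series_count,
        both_peptides_supported=both_ok,
        fp_screen_passed=fp_ok,
        parent_mass_ok=parent_ok,
        decision="accept" if accept else "reject",
        assignments=tuple(assignments),
    )
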