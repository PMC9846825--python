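"""Seeded synthetic MS/MS spectra with ground-truth labels.

Emulates Orbitrap-style centroided peak lists of tryptic peptides: the
theoretical b/y (and, for K/Y adducts, signature) ions of a ground-truth
peptide or cross-linked pair, thinned by Bernoulli dropout, perturbed by
Gaussian ppm jitter, and contaminated with uniform noise peaks. Every
spectrum is reproducible from (master seed, spectrum index) alone.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .chem import (
    DEP,
    Modification,
    ModifiedPeptide,
    mz_from_mass,
    peptide_mass,
    signature_ions,
)
from .fragments import (
    BridgeDefinition,
    CrossLinkCandidate,
    EK_ISOPEPTIDE,
    crosslink_fragment_ions,
    crosslink_precursor_mz,
    linear_fragment_ions,
)
from .matching import Spectrum

__all__ = [
    "SimulationParams",
    "BenchmarkTruth",
    "simulate_spectrum",
    "simulate_confounded_spectrum",
    "generate_benchmark",
]


@dataclass(frozen=True)
class SimulationParams:
    """Noise model for synthetic spectra.

    ``dropout`` is the per-ion probability that a theoretical fragment is
    absent; ``jitter_ppm`` the standard deviation of the Gaussian mass
    error; ``n_noise_peaks`` uniform-random peaks are added over
    [100, precursor m/z x charge]. Intensities are log-normal in log10
    units — arbitrary, they matter only for the top-N rule.
    """

    dropout: float = 0.0
    jitter_ppm: float = 0.0
    n_noise_peaks: int = 0
    intensity_log10_mu: float = 0.0
    intensity_log10_sigma: float = 1.0
    fragment_charges: tuple[int, ...] = (1, 2)
    precursor_charge: int = 3
    include_signature_ions: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.dropout <= 1.0:
            raise ValueError("dropout must be in [0,1]")
        if self.jitter_ppm < 0 or self.n_noise_peaks < 0:
            raise ValueError("jitter_ppm and n_noise_peaks must be >= 0")


@dataclass(frozen=True)
class BenchmarkTruth:
    """Ground truth for one generated spectrum."""

    identifier: str
    kind: str  # linear | adduct | crosslink | confounder
    peptide_a: str
    peptide_b: str = ""
    site_a: int = 0
    site_b: int = 0
    bridge: str = ""
    confounder: str = ""
    expected_decision: str = "reject"


def _rng_for(params: SimulationParams, index: int) -> np.random.Generator:
    return np.random.default_rng([params.seed, index])


def _theoretical_peaks(
    truth: ModifiedPeptide | CrossLinkCandidate, params: SimulationParams
) -> tuple[list[float], float, int]:
    """Theoretical fragment m/z list, precursor m/z and charge for a truth."""
    charge = params.precursor_charge
    if isinstance(truth, CrossLinkCandidate):
        ions = crosslink_fragment_ions(truth, charges=params.fragment_charges)
        prec = crosslink_precursor_mz(truth, charge)
        mzs = [ion.mz for ion in ions]
    else:
        ions = linear_fragment_ions(truth, charges=params.fragment_charges)
        prec = mz_from_mass(peptide_mass(truth), charge)
        mzs = [ion.mz for ion in ions]
        if params.include_signature_ions:
            # the study saw diagnostic ions for Dep-K and Dep-Y but none for
            # Dep-E; the generator reproduces that asymmetry
            for pos, mod in truth.mods:
                if isinstance(pos, int) and mod.name == DEP.name:
                    residue = truth.sequence[pos - 1]
                    if residue in ("K", "Y"):
                        mzs.extend(mz for _, mz in signature_ions(residue, mod))
    return mzs, prec, charge


def simulate_spectrum(
    truth: ModifiedPeptide | CrossLinkCandidate,
    params: SimulationParams = SimulationParams(),
    identifier: str = "sim_0",
    index: int = 0,
) -> Spectrum:
    """One synthetic spectrum for a linear/modified peptide or a cross-link.

    With dropout, jitter and noise all zero the peak list is exactly the
    theoretical ion list and the precursor is exact.
    """
    rng = _rng_for(params, index)
    mzs, prec, charge = _theoretical_peaks(truth, params)
    mzs = np.array(sorted(set(mzs)), dtype=float)
    keep = rng.random(len(mzs)) >= params.dropout
    mzs = mzs[keep]
    if params.jitter_ppm > 0:
        mzs = mzs * (1.0 + rng.normal(0.0, params.jitter_ppm * 1e-6, len(mzs)))
    intensity = 10.0 ** rng.normal(
        params.intensity_log10_mu, params.intensity_log10_sigma, len(mzs)
    )
    if params.n_noise_peaks > 0:
        noise_mz = rng.uniform(100.0, prec * charge, params.n_noise_peaks)
        # noise drawn an order of magnitude below signal so the top-N rule
        # reflects real spectra, where annotated peaks dominate
        noise_int = 10.0 ** rng.normal(
            params.intensity_log10_mu - 1.0, params.intensity_log10_sigma, len(noise_mz)
        )
        mzs = np.concatenate([mzs, noise_mz])
        intensity = np.concatenate([intensity, noise_int])
    order = np.argsort(mzs, kind="stable")
    return Spectrum(identifier, prec, charge, mzs[order], intensity[order])


def simulate_confounded_spectrum(
    candidate: CrossLinkCandidate,
    confounder: ModifiedPeptide,
    params: SimulationParams = SimulationParams(),
    identifier: str = "confounded_0",
    index: int = 0,
) -> Spectrum:
    """A false-positive scenario: the candidate's precursor, an unrelated
    peptide's fragments.

    The peak list consists of the confounder's linear ions (plus noise)
    while the precursor m/z is the cross-link candidate's, so mass-based
    candidate generation proposes the cross-link but fragment evidence
    belongs to an unrelated co-eluting peptide. The confounder must share
    no subsequence of length >= 3 with either candidate peptide.
    """
    for pep in (candidate.peptide_a.sequence, candidate.peptide_b.sequence):
        for k in range(len(confounder.sequence) - 2):
            if confounder.sequence[k : k + 3] in pep:
                raise ValueError(
                    "confounder shares sequence with the candidate peptides"
                )
    spec = simulate_spectrum(confounder, params, identifier, index)
    prec = crosslink_precursor_mz(candidate, params.precursor_charge)
    return Spectrum(
        identifier, prec, params.precursor_charge, spec.mz, spec.intensity
    )


def _eligible_adduct_sites(seq: str, targets: frozenset[str]) -> list[int]:
    return [i for i, ch in enumerate(seq, start=1) if ch in targets]


def generate_benchmark(
    n: int,
    weights: Sequence[float],
    params: SimulationParams,
    peptide_pool: Sequence[str],
    bridge: BridgeDefinition = EK_ISOPEPTIDE,
    adduct: Modification = DEP,
) -> tuple[list[Spectrum], list[BenchmarkTruth]]:
    """Draw ``n`` labeled spectra from {linear, adduct, crosslink, confounder}.

    ``weights`` are the mixture proportions in that order and must sum to 1.
    Peptides come from ``peptide_pool`` (typically a digest). Cross-links
    pair a donor-bearing with an acceptor-bearing peptide; confounder
    spectra pair a cross-link candidate with a sequence-unrelated peptide
    and are labeled expected-reject.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if len(weights) != 4 or abs(sum(weights) - 1.0) > 1e-9 or min(weights) < 0:
        raise ValueError("weights must be 4 nonnegative numbers summing to 1")
    pool = [p for p in peptide_pool if len(p) >= 4]
    if not pool:
        raise ValueError("empty peptide pool")
    donors = [p for p in pool if any(c in bridge.donor_residues for c in p)]
    acceptors = [p for p in pool if any(c in bridge.acceptor_residues for c in p)]
    adductable = [p for p in pool if any(c in adduct.targets for c in p)]

    rng = np.random.default_rng([params.seed, 2**20])
    kinds = ("linear", "adduct", "crosslink", "confounder")
    spectra: list[Spectrum] = []
    truths: list[BenchmarkTruth] = []
    for idx in range(n):
        kind = kinds[rng.choice(4, p=list(weights))]
        ident = f"bench_{idx:05d}_{kind}"
        if kind in ("crosslink", "confounder") and (not donors or not acceptors):
            raise ValueError("pool lacks donor/acceptor peptides for cross-links")
        if kind == "adduct" and not adductable:
            raise ValueError("pool lacks adduct-eligible peptides")
        if kind == "linear":
            seq = pool[rng.integers(len(pool))]
            truth_obj: ModifiedPeptide | CrossLinkCandidate = ModifiedPeptide(seq)
            truths.append(BenchmarkTruth(ident, kind, seq, expected_decision="reject"))
            spectra.append(simulate_spectrum(truth_obj, params, ident, idx))
        elif kind == "adduct":
            seq = adductable[rng.integers(len(adductable))]
            sites = _eligible_adduct_sites(seq, adduct.targets)
            site = sites[rng.integers(len(sites))]
            truth_obj = ModifiedPeptide(seq).with_mod(site, adduct)
            truths.append(
                BenchmarkTruth(
                    ident, kind, seq, site_a=site, expected_decision="accept"
                )
            )
            spectra.append(simulate_spectrum(truth_obj, params, ident, idx))
        else:
            xl = None
            for _ in range(200):
                sa = donors[rng.integers(len(donors))]
                sb = acceptors[rng.integers(len(acceptors))]
                if sa == sb:
                    continue
                da = _eligible_adduct_sites(sa, bridge.donor_residues)
                db = _eligible_adduct_sites(sb, bridge.acceptor_residues)
                xl = CrossLinkCandidate(
                    ModifiedPeptide(sa),
                    da[rng.integers(len(da))],
                    ModifiedPeptide(sb),
                    db[rng.integers(len(db))],
                    bridge,
                )
                break
            if xl is None:
                raise ValueError("could not draw a cross-link pair from the pool")
            if kind == "crosslink":
                truths.append(
                    BenchmarkTruth(
                        ident,
                        kind,
                        xl.peptide_a.sequence,
                        xl.peptide_b.sequence,
                        xl.site_a,
                        xl.site_b,
                        bridge.name,
                        expected_decision="accept",
                    )
                )
                spectra.append(simulate_spectrum(xl, params, ident, idx))
            else:
                conf = None
                for _ in range(500):
                    cand = pool[rng.integers(len(pool))]
                    try:
                        spec = simulate_confounded_spectrum(
                            xl, ModifiedPeptide(cand), params, ident, idx
                        )
                    except ValueError:
                        continue
                    conf = cand
                    break
                if conf is None:
                    raise ValueError("no sequence-unrelated confounder in pool")
                truths.append(
                    BenchmarkTruth(
                        ident,
                        "confounder",
                        xl.peptide_a.sequence,
                        xl.peptide_b.sequence,
                        xl.site_a,
                        xl.site_b,
                        bridge.name,
                        confounder=conf,
                        expected_decision="reject",
                    )
                )
                spectra.append(spec)
    return spectra, truths
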