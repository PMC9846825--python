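"""Peak matching, site localization, and the acceptance criteria."""

import numpy as np
import pytest

from opxl import (
    AMBIGUOUS,
    DEP,
    EK_ISOPEPTIDE,
    AdductCandidate,
    CrossLinkCandidate,
    ModifiedPeptide,
    Spectrum,
    ValidationConfig,
    assigned_fraction,
    crosslink_fragment_ions,
    crosslink_precursor_mz,
    evaluate_adduct,
    evaluate_crosslink,
    false_positive_screen,
    linear_fragment_ions,
    localize_adduct,
    match_peaks,
    mz_from_mass,
    peptide_mass,
    SimulationParams,
    simulate_spectrum,
    simulate_confounded_spectrum,
)

ZERO_NOISE = SimulationParams(seed=0)


def spectrum_from_mzs(mzs, precursor_mz=500.0, charge=2, identifier="s"):
    mzs = sorted(mzs)
    return Spectrum(
        identifier, precursor_mz, charge, np.array(mzs), np.ones(len(mzs))
    )


class TestMatchPeaks:
    def test_exact_matches(self):
        ions = [
            i
            for i in linear_fragment_ions(ModifiedPeptide("STKSPR"), charges=[1])
            if i.series == "y" and i.index <= 5
        ]
        s = spectrum_from_mzs([i.mz for i in ions])
        out = match_peaks(s, ions, 0.02)
        assert len(out) == 5
        assert all(a.error_da == pytest.approx(0.0, abs=1e-12) for a in out)

    def test_empty_spectrum(self):
        ions = linear_fragment_ions(ModifiedPeptide("STKSPR"), charges=[1])
        assert match_peaks(spectrum_from_mzs([]), ions, 0.02) == []

    def test_offset_within_tolerance(self, dep_e_peptide):
        b10 = next(
            i
            for i in linear_fragment_ions(dep_e_peptide, charges=[1], series=["b"])
            if i.index == 10
        )
        s = spectrum_from_mzs([b10.mz + 0.005])
        out = match_peaks(s, [b10], 0.02)
        assert len(out) == 1
        assert out[0].error_da == pytest.approx(0.005, abs=1e-9)

    def test_one_to_one_tie_break_by_error(self):
        ions = linear_fragment_ions(ModifiedPeptide("STKSPR"), charges=[1])
        y1 = next(i for i in ions if i.series == "y" and i.index == 1)
        s = spectrum_from_mzs([y1.mz + 0.001, y1.mz + 0.01])
        out = match_peaks(s, [y1], 0.02)
        assert len(out) == 1
        assert out[0].error_da == pytest.approx(0.001, abs=1e-9)

    def test_unsorted_peaks_rejected(self):
        with pytest.raises(ValueError):
            Spectrum("bad", 500.0, 2, np.array([200.0, 100.0]), np.ones(2))


class TestAssignedFraction:
    def test_all_and_none(self):
        ions = linear_fragment_ions(ModifiedPeptide("STKSPR"), charges=[1])
        s = spectrum_from_mzs([i.mz for i in ions])
        full = match_peaks(s, ions, 0.02)
        assert assigned_fraction(s, full, top_n=50) == 1.0
        assert assigned_fraction(s, [], top_n=50) == 0.0

    def test_partial_fraction(self):
        mzs = [100.0 + 10 * k for k in range(8)]
        s = spectrum_from_mzs(mzs)
        from opxl.matching import PeakAssignment
        from opxl.fragments import FragmentIon

        ion = FragmentIon("b", 1, 1, 100.0)
        assignments = [PeakAssignment(k, ion, 0.0, 0.0) for k in range(5)]
        assert assigned_fraction(s, assignments, top_n=8) == pytest.approx(0.625)

    def test_monotone_in_tolerance(self, dep_e_peptide):
        ions = linear_fragment_ions(dep_e_peptide, charges=[1])
        rng = np.random.default_rng(0)
        s = spectrum_from_mzs([i.mz + rng.normal(0, 0.01) for i in ions])
        fracs = [
            assigned_fraction(s, match_peaks(s, ions, tol), top_n=50)
            for tol in (0.002, 0.01, 0.05)
        ]
        assert fracs == sorted(fracs)


def _adduct_site_candidates(seq, adduct=DEP, extra_mods=()):
    cands = []
    for i, ch in enumerate(seq, 1):
        if ch in adduct.targets:
            p = ModifiedPeptide(seq)
            for pos, mod in extra_mods:
                p = p.with_mod(pos, mod)
            cands.append(AdductCandidate(p.with_mod(i, adduct), i, "", i))
    return cands


class TestLocalizeAdduct:
    def test_site_pinned_by_shifted_b_ions(self, dep_e_peptide):
        # shifted b9/b10 plus unshifted b2-b8 and y1-y9 single out E9
        from opxl import MOX

        ions = linear_fragment_ions(dep_e_peptide, charges=[1])
        keep = [
            i.mz
            for i in ions
            if (i.series == "b" and 2 <= i.index <= 10)
            or (i.series == "y" and i.index <= 9)
        ]
        s = spectrum_from_mzs(keep)
        cands = _adduct_site_candidates(
            dep_e_peptide.sequence, extra_mods=[(11, MOX)]
        )
        assert localize_adduct(s, cands, 0.02, charges=[1]) == 9

    def test_only_unshifted_ions_is_ambiguous(self):
        seq = "AEKEA"
        unshifted = linear_fragment_ions(ModifiedPeptide(seq), charges=[1])
        s = spectrum_from_mzs([i.mz for i in unshifted if i.series == "y"])
        assert localize_adduct(s, _adduct_site_candidates(seq), 0.02) == AMBIGUOUS

    def test_minimal_bracketing_evidence(self):
        # shifted b2 and unshifted y3 pin the adduct to E2 of AEKEA
        p = ModifiedPeptide("AEKEA").with_mod(2, DEP)
        ions = linear_fragment_ions(p, charges=[1])
        b2 = next(i.mz for i in ions if i.series == "b" and i.index == 2)
        y3 = next(i.mz for i in ions if i.series == "y" and i.index == 3)
        s = spectrum_from_mzs([b2, y3])
        assert localize_adduct(s, _adduct_site_candidates("AEKEA"), 0.02, [1]) == 2

    @pytest.mark.parametrize(
        "seq", ["AEKEA", "STKSPR", "YTIGKEIIDL", "GHYTEGAELVD", "EEYPDR"]
    )
    def test_recovers_planted_site_from_full_coverage(self, seq):
        # noise-free full b/y coverage localizes every eligible site
        for cand in _adduct_site_candidates(seq):
            s = simulate_spectrum(cand.peptide, ZERO_NOISE, index=cand.site)
            got = localize_adduct(s, _adduct_site_candidates(seq), 0.02)
            assert got == cand.site


class TestEvaluateAdduct:
    def test_simulation_round_trip_accepts(self, dep_e_peptide):
        s = simulate_spectrum(dep_e_peptide, ZERO_NOISE)
        c = AdductCandidate(dep_e_peptide, 9, "tub_a1a", 411)
        v = evaluate_adduct(s, c)
        assert v.decision == "accept"
        assert v.localized_site == 9
        assert v.parent_mass_ok

    def test_wrong_site_rejected(self, dep_e_peptide):
        from opxl import MOX

        s = simulate_spectrum(dep_e_peptide, ZERO_NOISE)
        wrong = AdductCandidate(
            ModifiedPeptide(dep_e_peptide.sequence).with_mod(11, MOX).with_mod(12, DEP),
            12,
            "tub_a1a",
            414,
        )
        v = evaluate_adduct(s, wrong)
        assert v.decision == "reject"
        assert v.localized_site == 9  # evidence points at the true site

    def test_no_fragments_rejected(self, dep_e_peptide):
        prec = mz_from_mass(peptide_mass(dep_e_peptide), 3)
        s = Spectrum("empty", prec, 3, np.array([]), np.array([]))
        c = AdductCandidate(dep_e_peptide, 9, "tub_a1a", 411)
        assert evaluate_adduct(s, c).decision == "reject"

    def test_signature_ions_recorded_for_lysine(self):
        p = ModifiedPeptide("STKSPR").with_mod(3, DEP)
        s = simulate_spectrum(p, ZERO_NOISE)
        c = AdductCandidate(p, 3, "", 3)
        v = evaluate_adduct(s, c)
        assert v.decision == "accept"
        assert any(lab.startswith("Dep-K") for lab in v.signature_ions_found)

    def test_mandatory_signature_can_reject(self, dep_e_peptide):
        # Dep-E spectra carry no diagnostic ions; requiring them must reject
        s = simulate_spectrum(dep_e_peptide, ZERO_NOISE)
        c = AdductCandidate(dep_e_peptide, 9, "tub_a1a", 411)
        cfg = ValidationConfig(require_signature_for=frozenset("E"))
        assert evaluate_adduct(s, c, cfg).decision == "reject"


class TestEvaluateCrosslink:
    def test_simulation_round_trip_accepts(self, xl_pair):
        s = simulate_spectrum(xl_pair, ZERO_NOISE)
        v = evaluate_crosslink(s, xl_pair, alt_pool=["LNDLEEALQQAK"])
        assert v.decision == "accept"
        assert v.assigned_fraction > 0.4
        assert v.xl_specific_series_count >= 2
        assert v.both_peptides_supported
        assert v.fp_screen_passed
        assert v.parent_mass_ok

    def test_confounded_spectrum_rejected(self, xl_pair):
        s = simulate_confounded_spectrum(
            xl_pair, ModifiedPeptide("DSLSQQLNS"), ZERO_NOISE
        )
        v = evaluate_crosslink(s, xl_pair, alt_pool=["DSLSQQLNS"])
        assert v.decision == "reject"

    def test_parent_mass_mismatch_rejected(self, xl_pair):
        s0 = simulate_spectrum(xl_pair, ZERO_NOISE)
        s = Spectrum(
            s0.identifier, s0.precursor_mz + 5.0 / 3, 3, s0.mz, s0.intensity
        )
        v = evaluate_crosslink(s, xl_pair)
        assert not v.parent_mass_ok
        assert v.decision == "reject"

    def test_verdict_is_pure_function_of_criteria(self, xl_pair):
        s = simulate_spectrum(xl_pair, ZERO_NOISE)
        v = evaluate_crosslink(s, xl_pair)
        expected = (
            v.assigned_fraction > 0.40
            and v.xl_specific_series_count >= 2
            and v.both_peptides_supported
            and v.fp_screen_passed
            and v.parent_mass_ok
        )
        assert (v.decision == "accept") == expected


class TestFalsePositiveScreen:
    def _flagged_from(self, s, xl, tol=0.02):
        ions = crosslink_fragment_ions(xl, charges=[1, 2])
        return [a for a in match_peaks(s, ions, tol) if a.ion.carries_bridge]

    def test_alternative_peptide_explains_flagged_peaks(self, xl_pair):
        # flagged peaks constructed as y ions of an unrelated pool peptide
        alt = ModifiedPeptide("DSLSQQLNS")
        alt_y = [
            i for i in linear_fragment_ions(alt, charges=[1]) if i.series == "y"
        ][1:6]
        xl_ions = [
            i
            for i in crosslink_fragment_ions(xl_pair, charges=[1, 2])
            if i.carries_bridge
        ]
        # pretend each alt-y peak was (mis)assigned to a bridge ion
        s = spectrum_from_mzs([i.mz for i in alt_y])
        from opxl.matching import PeakAssignment

        flagged = [
            PeakAssignment(k, xl_ions[k], 0.0, 0.0) for k in range(len(alt_y))
        ]
        assert not false_positive_screen(s, flagged, ["DSLSQQLNS"], 0.02)

    def test_empty_pool_passes(self, xl_pair):
        s = simulate_spectrum(xl_pair, ZERO_NOISE)
        flagged = self._flagged_from(s, xl_pair)
        assert false_positive_screen(s, flagged, [])

    def test_unexplainable_peaks_pass(self, xl_pair):
        s = simulate_spectrum(xl_pair, ZERO_NOISE)
        flagged = self._flagged_from(s, xl_pair)
        assert flagged
        assert false_positive_screen(s, flagged, ["DSLSQQLNS", "GFEAVTK"])
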