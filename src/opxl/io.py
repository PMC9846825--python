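"""FASTA/MGF input-output, run configuration, and the end-to-end pipeline.

FASTA goes through Biopython, MGF through pyteomics; reports are pandas
DataFrames written as tab-separated text, with site notation matching the
field's convention of residue letter + protein position (E411, K1635).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from pyteomics import mgf as _mgf

from .chem import (
    BUILTIN_MODIFICATIONS,
    CARBAMIDOMETHYL,
    DEP,
    Modification,
    load_modifications,
    mz_from_mass,
    peptide_mass,
)
from .candidates import (
    DEFAULT_DEP_TARGETS,
    DigestPeptide,
    DigestSpec,
    digest,
    enumerate_adduct_candidates,
    enumerate_crosslink_candidates,
)
from .fragments import BUILTIN_BRIDGES, BridgeDefinition, crosslink_precursor_mz
from .matching import (
    Spectrum,
    ValidationConfig,
    evaluate_adduct,
    evaluate_crosslink,
    localize_adduct,
)

logger = logging.getLogger("opxl")

__all__ = [
    "RunConfig",
    "read_fasta",
    "read_mgf",
    "write_mgf",
    "run_pipeline",
]


class FormatError(ValueError):
    """Malformed input file."""


@dataclass(frozen=True)
class RunConfig:
    """All pipeline settings, JSON-serializable and round-trip stable."""

    digest: DigestSpec = DigestSpec()
    adduct: str = "Dep"
    adduct_targets: str = "".join(sorted(DEFAULT_DEP_TARGETS))
    fixed_mods: tuple[str, ...] = ("Carbamidomethyl",)
    bridges: tuple[str, ...] = ("EK_isopeptide",)
    validation: ValidationConfig = ValidationConfig()
    seed: int = 0

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        d["validation"]["require_signature_for"] = sorted(
            d["validation"]["require_signature_for"]
        )
        d["validation"]["fragment_charges"] = list(
            d["validation"]["fragment_charges"]
        )
        return json.dumps(d, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "RunConfig":
        d = json.loads(text)
        if "digest" in d:
            d["digest"] = DigestSpec(**d["digest"])
        if "validation" in d:
            v = d["validation"]
            v["fragment_charges"] = tuple(v.get("fragment_charges", (1, 2)))
            v["require_signature_for"] = frozenset(v.get("require_signature_for", ()))
            d["validation"] = ValidationConfig(**v)
        for key in ("fixed_mods", "bridges"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    def resolve_adduct(self) -> Modification:
        mod = BUILTIN_MODIFICATIONS[self.adduct]
        return mod

    def resolve_fixed_mods(self) -> tuple[Modification, ...]:
        return tuple(BUILTIN_MODIFICATIONS[name] for name in self.fixed_mods)

    def resolve_bridges(self) -> tuple[BridgeDefinition, ...]:
        return tuple(BUILTIN_BRIDGES[name] for name in self.bridges)


def read_fasta(path) -> list[tuple[str, str]]:
    """Read a FASTA file into (id, uppercase sequence) pairs, order preserved."""
    path = Path(path)
    records = []
    with open(path) as fh:
        first = fh.read(1)
        if first and first != ">":
            raise FormatError(f"{path}: line 1: FASTA must start with '>'")
    for rec in SeqIO.parse(str(path), "fasta"):
        records.append((rec.id, str(rec.seq).upper()))
    return records


def read_mgf(path) -> list[Spectrum]:
    """Read an MGF peak-list file.

    Blocks without a CHARGE line default to charge 2 with a logged warning;
    a block without PEPMASS is a format error naming the block.
    """
    spectra: list[Spectrum] = []
    with _mgf.MGF(str(path)) as reader:
        for i, entry in enumerate(reader):
            params = entry["params"]
            title = str(params.get("title", f"spectrum_{i}"))
            if "pepmass" not in params or params["pepmass"][0] is None:
                raise FormatError(f"MGF block {title!r}: missing PEPMASS")
            pepmass = float(params["pepmass"][0])
            if "charge" in params:
                charge = int(params["charge"][0])
            else:
                logger.warning("MGF block %r: no CHARGE, defaulting to 2+", title)
                charge = 2
            mz = np.asarray(entry["m/z array"], dtype=float)
            inten = np.asarray(entry["intensity array"], dtype=float)
            order = np.argsort(mz, kind="stable")
            spectra.append(Spectrum(title, pepmass, charge, mz[order], inten[order]))
    return spectra


def write_mgf(spectra: Iterable[Spectrum], path) -> None:
    """Write spectra as MGF; m/z to 5 decimals so read(write(x)) is stable."""
    entries = []
    for s in spectra:
        entries.append(
            {
                "m/z array": np.round(s.mz, 5),
                "intensity array": np.round(s.intensity, 4),
                "params": {
                    "title": s.identifier,
                    "pepmass": round(float(s.precursor_mz), 6),
                    "charge": f"{s.precursor_charge}+",
                },
            }
        )
    _mgf.write(entries, str(path), file_mode="w")


def _adduct_report_row(verdict, spectrum_id: str) -> dict:
    c = verdict.candidate
    return {
        "spectrum": spectrum_id,
        "adduct": f"Dep-{c.peptide.sequence[c.site - 1]}",
        "protein": c.protein_id,
        "sequence": str(c.peptide),
        "site": c.site_label,
        "assigned_fraction": round(verdict.assigned_fraction, 4),
        "signature_ions": ";".join(verdict.signature_ions_found),
        "decision": verdict.decision,
    }


def _xlink_report_row(verdict, spectrum_id: str, theo_mz: float) -> dict:
    x = verdict.candidate
    return {
        "spectrum": spectrum_id,
        "bridge": x.bridge.name,
        "peptide_a": x.peptide_a.sequence,
        "site_a": f"{x.peptide_a.sequence[x.site_a - 1]}{x.site_a}",
        "peptide_b": x.peptide_b.sequence,
        "site_b": f"{x.peptide_b.sequence[x.site_b - 1]}{x.site_b}",
        "theoretical_mz": round(theo_mz, 4),
        "assigned_fraction": round(verdict.assigned_fraction, 4),
        "xl_series_count": verdict.xl_specific_series_count,
        "decision": verdict.decision,
    }


def run_pipeline(
    config: RunConfig,
    fasta_path,
    mgf_path,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Digest, enumerate, match and validate every spectrum in an MGF file.

    Returns (adduct_report, crosslink_report) with one row per accepted
    candidate. Deterministic: identical inputs and config give identical
    reports.
    """
    logger.info("resolved config (seed=%d):\n%s", config.seed, config.to_json())
    proteins = read_fasta(fasta_path)
    spectra = read_mgf(mgf_path)
    pool: list[DigestPeptide] = []
    for pid, seq in proteins:
        pool.extend(digest(seq, config.digest, protein_id=pid))
    # dedupe identical (protein, start, sequence) rows across entries
    pool = sorted(set(pool), key=lambda p: (p.protein_id, p.start, p.sequence))
    adduct = config.resolve_adduct()
    fixed = config.resolve_fixed_mods()
    vcfg = config.validation
    alt_pool = sorted({p.sequence for p in pool})

    adduct_rows: list[dict] = []
    xlink_rows: list[dict] = []
    for s in spectra:
        try:
            cands = enumerate_adduct_candidates(
                pool,
                config.adduct_targets,
                adduct,
                s.precursor_mz,
                s.precursor_charge,
                vcfg.precursor_tol_ppm,
                fixed_mods=fixed,
            )
            # evaluate one representative per peptide; localization picks the site
            by_pep: dict[str, list] = {}
            for c in cands:
                by_pep.setdefault(c.peptide.sequence, []).append(c)
            for group in by_pep.values():
                site = localize_adduct(
                    s, group, vcfg.fragment_tol_da, vcfg.fragment_charges
                )
                winner = next((c for c in group if c.site == site), None)
                if winner is None:
                    continue
                verdict = evaluate_adduct(s, winner, vcfg, site_alternatives=group)
                if verdict.decision == "accept":
                    adduct_rows.append(_adduct_report_row(verdict, s.identifier))
            for bridge in config.resolve_bridges():
                xcands = enumerate_crosslink_candidates(
                    pool,
                    bridge,
                    s.precursor_mz,
                    s.precursor_charge,
                    vcfg.precursor_tol_ppm,
                )
                # several site placements of one pair can clear the criteria;
                # keep the best-supported placement per unordered pair
                best: dict[frozenset, object] = {}
                for x in xcands:
                    verdict = evaluate_crosslink(s, x, alt_pool, vcfg)
                    if verdict.decision != "accept":
                        continue
                    key = frozenset(
                        [x.peptide_a.sequence, x.peptide_b.sequence, bridge.name]
                    )
                    prev = best.get(key)
                    score = (
                        len(verdict.assignments),
                        verdict.xl_specific_series_count,
                        verdict.assigned_fraction,
                    )
                    if prev is None or score > prev[0]:
                        best[key] = (score, verdict)
                for _, verdict in best.values():
                    x = verdict.candidate
                    theo = crosslink_precursor_mz(x, s.precursor_charge)
                    xlink_rows.append(_xlink_report_row(verdict, s.identifier, theo))
        except Exception:
            logger.exception("spectrum %r: pipeline stage failed", s.identifier)
            raise
    adduct_report = pd.DataFrame(
        adduct_rows,
        columns=[
            "spectrum",
            "adduct",
            "protein",
            "sequence",
            "site",
            "assigned_fraction",
            "signature_ions",
            "decision",
        ],
    )
    xlink_report = pd.DataFrame(
        xlink_rows,
        columns=[
            "spectrum",
            "bridge",
            "peptide_a",
            "site_a",
            "peptide_b",
            "site_b",
            "theoretical_mz",
            "assigned_fraction",
            "xl_series_count",
            "decision",
        ],
    )
    return adduct_report, xlink_report
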