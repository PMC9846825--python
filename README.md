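# opxl

Search engine for **organophosphate-derived protein adducts and zero-length
isopeptide cross-links** in peptide tandem-MS data.

Chlorpyrifos oxon (CPO), the active metabolite of a widely used insecticide,
transfers a diethyl phosphate group (Dep, composition C4H9O3P, +136.0289 Da)
to nucleophilic side chains — Glu, Asp, Lys, Tyr, Ser, Thr. An activated
(Dep-bearing) Glu or Lys can then react with a nearby Lys ε-amine or Glu
γ-carboxyl to form a **zero-length ε-(γ-glutamyl)lysine isopeptide bond**,
cross-linking two peptides with a net loss of one water
(elemental change H₋₂O₋₁, −18.0106 Da). `opxl` finds both kinds of evidence
in centroided MS/MS peak lists:

- **Adducts.** Candidate peptides whose monoisotopic mass is increased by
  136.03 Da are enumerated from an in-silico tryptic digest; the adduct is
  accepted only when b/y fragment ions pin it to a single residue
  (a mass-shifted fragment must contain the site, an unshifted one must
  exclude it), corroborated by low-mass diagnostic ("signature") ions —
  immonium + adduct, with characteristic ethylene/water/ammonia losses.
- **Cross-links.** Peptide pairs whose combined mass minus one water matches
  the precursor are fragmented in silico; fragments spanning the linked
  residue carry the intact partner peptide plus the bridge ("cross-link
  specific ions"). A candidate is accepted only if (1) more than 40% of the
  top-50 peaks are assigned, (2) at least two consecutive cross-link-specific
  ions form a series that defines a residue, (3) both peptides have fragment
  support, (4) the flagged peaks are not better explained by an unrelated
  linear peptide (false-positive screen), and (5) the parent mass matches
  within tolerance.

For an ion of charge z, m/z = (M + z·m_H⁺)/z with m_H⁺ = 1.0072765 Da;
b_i = Σ residues 1..i (+mods) + z·H⁺, y_i = Σ last i residues (+mods) + H₂O
+ z·H⁺. All arithmetic is monoisotopic.

A fully seeded synthetic-spectrum generator (Orbitrap-like peak lists with
configurable dropout, ppm jitter, noise peaks, and confounder spectra)
provides ground-truth-labeled benchmarks, so the whole pipeline is testable
without any raw-data download.

## Worked example

The identified cross-link joins tubulin α 1A peptide `TIGGGDDSFNTFFSETGA`
(donor E15) to MAP2 peptide `STKSPR` (acceptor K3):

```python
from opxl import *

x = CrossLinkCandidate(ModifiedPeptide("TIGGGDDSFNTFFSETGA"), 15,
                       ModifiedPeptide("STKSPR"), 3, EK_ISOPEPTIDE)
print("MH3+ =", round(crosslink_precursor_mz(x, 3), 4))

dep_e = ModifiedPeptide("AFVHWYVGEGMEEGEFSEAR").with_mod(9, DEP).with_mod(11, MOX)
b = {i.index: i.mz for i in linear_fragment_ions(dep_e, charges=[1], series=["b"])}
print("b9  =", round(b[9], 4))
print("b10 =", round(b[10], 4))
print("Dep-K signature:", [(l, round(m, 2)) for l, m in signature_ions("K", DEP)])
```

prints

```
MH3+ = 827.0506
b9  = 1225.5442
b10 = 1282.5656
Dep-K signature: [('Dep-K', 237.14), ('Dep-K-NH3', 220.11)]
```

The MH³⁺ value is the triply protonated mass of the two peptides minus one
water — the cross-linked pair's observed precursor. The b9/b10 pair brackets
the ninth residue of the tubulin peptide: both carry the +136.03 Da shift
while b2–b8 and y1–y9 do not, which localizes the diethyl phosphate to that
glutamate. The signature ions are the Dep-lysine immonium ion and its
ammonia-loss companion.

## Command line

```sh
opxl digest proteins.fasta                # in-silico trypsin digest (TSV)
opxl ions STKSPR --dep-site 3             # theoretical b/y ion table
opxl simulate proteins.fasta --n 100      # seeded synthetic benchmark (MGF + truth)
opxl run proteins.fasta spectra.mgf       # full search -> adduct + cross-link reports
```

`search-adducts`, `search-xlinks` and `validate` expose the individual
stages; `--config config.json` overrides digestion, tolerance and
acceptance-threshold defaults (see `RunConfig`).

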