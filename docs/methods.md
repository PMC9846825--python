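# Methods

## Mass model

All arithmetic is monoisotopic. Atomic masses come from the NIST table
shipped with pyteomics, restricted to C, H, N, O, P, S; residue masses are
the standard 20-letter monoisotopic table. The proton mass is fixed at
1.0072765 Da; m/z of an ion of charge z is (M + z·m_H⁺)/z. Average-mass
mode and isotope-envelope prediction are deliberately out of scope: the
workflow operates on centroided, charge-deconvolved peak values.

The diethyl phosphate adduct (Dep) is stored as the elemental formula
C4H9O3P = 136.028931 Da — the transferred group minus the proton displaced
from the nucleophile; literature-style "136.03" is treated as a rounded
display value. Default fixed modification is carbamidomethyl-C
(+57.02146 Da, iodoacetamide alkylation); default variable modification is
Met oxidation (+15.99491 Da). Modifications and bridge chemistries are
loadable from JSON config (name, formula or delta, targets), with the
delta/formula consistency enforced to 1e-4 Da.

Signature (diagnostic) ions use the immonium convention
m/z = residue − CO + H⁺ (a net offset of −26.9871 Da). The Dep base ion is
immonium + adduct delta; lysine adds an ammonia loss, tyrosine and
glutamate show the ethyl-ester decomposition ladder −C2H4, −(C2H4+H2O),
−2C2H4, −(2C2H4+H2O). This convention reproduces all twelve published
nominal signature masses (K: 237, 220; Y: 272, 244, 226, 216, 198;
E: 238, 210, 192, 182, 164). Nominal masses are round-half-up integers.

## Fragments and cross-link ions

Only b and y series are generated: CID spectra of tryptic peptides are
dominated by them and the published annotations use nothing else.
Neutral-loss backbone variants (−H2O/−NH3) are excluded by default; the
flag is reserved. Fragment charges default to {1, 2}; precursor charges up
to 4. Modifications inside a fragment's residue span contribute their
delta; N-/C-terminal modifications attach to spans touching that terminus.

For a cross-linked pair, fragments of either peptide that do not span its
linked residue are ordinary linear ions; fragments that do span it carry
the intact partner peptide plus the bridge delta and are flagged as
cross-link specific. Built-in bridges: the observed `EK_isopeptide`
(donors E/D, acceptor K, H₋₂O₋₁ = −18.0106 Da) and three hypothetical
Tyr–Lys chemistries searched as expected-negative modes: water loss
(−18.0106), ammonia loss (H₋₃N₋₁, −17.0265), and ethoxyphosphoryl
(C2H3O2P, +89.9871 = Dep minus ethanol). Aspartate is admitted as a donor
alongside glutamate so that β-linked isopeptides are expressible; the
acceptance procedure, not the enumeration, decides.

Two invariants anchor the implementation and are property-tested:
b_i + y_(n−i) at 1+ equals M + 2·H⁺ for linear peptides, and for either
peptide of a pair a bridge-carrying y_i plus the complementary b_(n−i)
reconstructs the whole candidate mass.

## Digestion and candidate enumeration

Trypsin rule: cleave after K/R, not before P. Specificity is
full / semi / none; internal uncleaved K/R count as missed cleavages under
every specificity. Defaults: semi-specific, ≤2 missed cleavages, length
4–40 — several published adducted peptides are not fully tryptic, and a
Dep-blocked lysine shows up naturally as a missed cleavage. The "none" mode
exists to reproduce ragged observed forms exactly. Digestion is verified
against a brute-force substring oracle on random sequences up to 60
residues.

Adduct candidates place one Dep on each eligible residue of each peptide
whose modified mass matches the observed precursor within a ppm tolerance
(default 10 ppm, Orbitrap-class). The searched residue set defaults to
{E, D, K, Y, S, T, H, R}. Cross-link candidates pair peptides (same-protein
pairs allowed — an internal cross-link is among the identifications) whose
combined mass plus bridge delta matches the precursor; the pair search uses
a sorted-mass bisect so enumeration is near-linear in the digest size. The
donor-bearing peptide is always stored first; role-symmetric duplicates are
suppressed with an order-insensitive key. Every candidate re-verifies its
own precursor mass, and widening the tolerance can only add candidates.

## Matching and acceptance

Peak assignment is greedy 1:1: candidate (peak, ion) pairs within the
fragment tolerance (default 0.02 Da) are accepted in order of increasing
absolute error; each peak and each ion is used at most once.

**Site localization.** For each candidate placement the spectrum is matched
against that placement's ion set. Each matched fragment constrains the
site: a shifted b_i caps it at i, an unshifted b_i pushes it past i, and
symmetrically for y ions. A placement wins only if it is supported by at
least one shifted and one unshifted fragment and is the sole candidate
site inside its own feasibility interval; anything else is ambiguous.
An adduct is accepted iff the site is uniquely localized and the precursor
mass matches within 10 ppm. Signature ions are recorded as corroboration
and can be made mandatory per residue; they are never mandatory for
glutamate, whose diagnostic ions were not observed in practice.

**Cross-link acceptance** requires all five of: assigned fraction of the
top-50 most intense peaks > 0.40 (the denominator is capped because raw
Orbitrap spectra carry abundant low-level noise); a run of ≥2
consecutive-index, same-series, same-charge bridge-carrying ions
(consecutive indices guarantee the m/z step is the intervening residue
mass, so the run "defines an amino acid"); at least one assignment from
each peptide; the false-positive screen; precursor within 10 ppm of the
candidate MH^z+.

**False-positive screen.** The manual-evaluation step of the original
procedure is automated: the m/z values of the flagged (bridge-carrying)
assignments are compared against the ordinary b/y ions of every peptide in
an alternative pool (in the pipeline, the whole digest). If any single
unrelated peptide explains at least as many of those peaks as the
cross-link hypothesis does, the screen fails and the candidate is rejected.
The verdict object retains all assignments so a human can audit the
alternative explanation.

The verdict's decision is a pure function of the per-criterion fields.

## Synthetic data

The generator emulates Orbitrap-like centroided peak lists of the study's
material: tryptic/semi-tryptic peptides carrying +136.0289 Da adducts on
E/D/K/Y/S/T, cross-linked pairs with the −18.0106 Da bridge, and
false-positive ("confounder") spectra whose precursor matches a cross-link
candidate while the peaks belong to an unrelated linear peptide — the
classic co-isolation trap.

Peaks are the theoretical b/y ions (fragment charges {1,2} by default),
each retained with probability 1 − dropout, jittered with Gaussian ppm
noise, plus uniform noise peaks over [100, precursor·z] drawn one decade
below signal intensity. Intensities are log-normal (μ=0, σ=1 in log10
arbitrary units) — no intensity model is claimed beyond what the top-N
rule needs. Diagnostic signature ions are emitted for Dep-K and Dep-Y
truths but not Dep-E, mirroring the empirical asymmetry. Each spectrum's
RNG stream derives from (master seed, spectrum index), so individual
spectra are independently reproducible and MGF output is byte-stable for a
given seed.

What the generator does **not** model: isotope envelopes, chimeric spectra
beyond the single-confounder scenario, retention time, intensity structure
along the ion series, electron-transfer dissociation, or real noise
spectra. Passing the zero-noise benchmark therefore demonstrates the
correctness of the mass arithmetic, enumeration and decision logic — not
identification performance on real raw files, where search-engine scoring
and FDR control (both out of scope here) do the heavy lifting.

## Problem sizes and numerical choices

The default test benchmark uses two synthetic proteins (assembled from
tryptic units free of Cys and Pro), a ~12-peptide digest pool, and 100
spectra mixed over linear/adduct/cross-link/confounder kinds; the dropout
sweep uses 100 spectra per grid point. These sizes give exact expectations
(precision = recall = 1 at zero noise) while keeping the whole suite in a
few seconds. Ties in peak assignment break toward the smaller mass error;
duplicate theoretical m/z values within one simulated spectrum are
collapsed before dropout so peak counts follow a clean binomial.
Degenerate inputs are rejected loudly: empty sequences, empty charge sets,
nonpositive tolerances, unsorted peak lists, and confounders sharing a
3-mer with the candidate peptides all raise errors.

## Known limitations

- No probabilistic localization score or target-decoy FDR; acceptance is
  rule-based, as in the manual procedure it automates.
- Precursor mass alone drives candidate generation; no retention-time or
  intensity priors.
- The screen considers one alternative peptide at a time; a spectrum whose
  flagged peaks are split across two unrelated peptides is caught by the
  assigned-fraction and series criteria rather than the screen itself.
- Elements beyond CHNOPS and average masses are unsupported by design.
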