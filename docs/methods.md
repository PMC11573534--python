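# Methods

## The measurement being modeled

At a stop codon the termination machinery competes with near-cognate
tRNAs — tRNAs whose anticodon pairs with two of the three codon bases.
Aminoglycosides shift that competition toward mis-decoding, so a premature
termination codon (PTC) yields a family of full-length *readthrough
proteoforms* differing only at the stop position, alongside non-canonical
products (stop-skip, frameshifts). The experimental readout is bottom-up
LC-MS/MS: tryptic peptides covering the stop position identify which
residue was incorporated, and the area under each variant peptide's
extracted ion chromatogram (XIC) measures its relative abundance within the
sample. `ptcquant` implements every computational stage of that readout and
a synthetic-data generator that stands in for the instrument.

## Candidate prediction and dominance ranking

Near-cognate candidates of a stop codon are exactly the sense codons at
Hamming distance 1 (one entry per codon; a brute-force enumeration over all
64 codons is the test oracle). The ranking rests on one structural
argument: codon position 1 pairs with anticodon position 3, and a cognate
codon with C at position 1 puts a 3′ G in the anticodon opposite the stop
codon's 5′ U — a G:U wobble pair, more stable than the pyrimidine–
pyrimidine alternatives. Each stop codon has exactly one such candidate
(R via CGA at TGA; Q via CAA at TAA; Q via CAG at TAG), and that candidate
is ranked first. Below the top the order is a declared heuristic —
purine–pyrimidine before pyrimidine–pyrimidine, position order 1, 3, 2,
alphabetical tie-break — serialized with every ranking so downstream
consumers see which scheme produced it. The ranking deliberately encodes no
position- or context-dependent exceptions (observed, e.g., as W > R at some
opal positions): sequence context effects are out of scope.
Selenocysteine decoding of UGA is cognate, not near-cognate, and is off by
default (`include_selenocysteine=True` adds it).

## Proteoform enumeration

A `CodingConstruct` carries the CDS *through and beyond* its stop codons so
products that translate past a stop can run to the next in-frame stop.
Substitution proteoforms replace the stop triplet by a codon of the
candidate residue (preferring the Hamming-distance-1 codon, so the edit is
the biologically plausible one); the default candidate set is all 20 amino
acids — an "all possible readthrough" database — with the near-cognate
subset selectable for power studies. Stop-skip is modeled as deletion of
the 3-nt stop triplet with the frame preserved; frameshift(k) resumes
translation k bases after the stop's 3′ end. Every proteoform stores its
generating nucleotide sequence, so re-translation reproduces the protein —
the nucleotide-level oracle used in tests. Missing downstream stops are
flagged (`ran_off_end`), never raised, because partially annotated
constructs are common.

## Digestion, modifications, masses

Trypsin follows the Keil rule (cleave after K/R, not before P). The
proline exception is the common search-engine default; it is a
configuration flag because the underlying biochemistry is debated. Full
digestion with ≤ 2 missed cleavages has no length bounds; semi-tryptic
enumeration (exactly one tryptic terminus) is bounded to 5–45 residues and
≤ 6000 Da to keep the search space tractable — the observed semi-tryptic
products (peptides ending at the PTC itself) sit well inside these bounds.
Both paths are checked against a brute-force substring oracle.

Masses are monoisotopic: residue table to ≥ 5 decimals, water 18.010565,
proton 1.007276 Da. Modification deltas are derived from element
compositions (carbamidomethyl C2H3NO = +57.021, oxidation O = +15.995,
acetyl C2H2O = +42.011 Da). Fixed modifications apply everywhere; variable
ones expand combinatorially up to 3 sites per peptide. Protein N-terminal
acetylation is offered to peptides starting at residue 1 or 2 — the
start-2 allowance is a heuristic for initiator-Met clipping, which is not
modeled explicitly. b/y fragment m/z satisfy
b_i + y_(n−i) = M + 2·proton (singly charged) to < 1e-6 Da with
modifications localized to their residues; this is a tested invariant, and
peptide masses are additionally cross-checked against an independent
residue-composition table and against pyteomics.

Reported masses are compared at 2 decimal places (the precision at which
precursor masses are conventionally printed); internal precision is full
double.

## Search and FDR

The scorer sums `1 + log(1 + relative intensity)` over matched singly
charged b/y fragments, matching peak–fragment pairs greedily by smallest
Δm/z with each peak and each fragment used at most once. It is intentionally
simple: proprietary engine scores are not reproduction targets, and
everything the pipeline reports (masses, m/z, XIC areas, fractions) is
score-shape-independent. Defaults mirror a standard Orbitrap CID workflow:
10 ppm precursor (boundary inclusive), 0.6 Da fragment tolerance, semi-
tryptic secondary search on, rank-1 PSM per spectrum, 1% peptide FDR.
Searchable peptides are bounded to 5–45 residues; decoy peptide forms whose
sequence collides with a target sequence are dropped (the peptide-level
analogue of excluding palindromic decoy proteins).

q-values use the standard target-decoy recipe: sort PSMs by decreasing
score, running FDR = #decoys / max(1, #targets), q = cumulative minimum
from the bottom. Two choices matter for calibration and are deliberate:

* **Decoy scheme.** `make_decoys` offers whole-protein reversal and
  segment-wise pseudo-reversal (each inter-cleavage segment reversed, K/R
  anchors kept). The pipeline default is pseudo-reversal because it
  preserves the tryptic peptide *mass* distribution of the target database:
  a foreign peptide whose precursor mass falls on a target peptide then has
  a mass-matched decoy competitor as well. With plain reversal, decoy
  candidates at the right mass exist only coincidentally, the weak
  false-target matches face no decoy competition, and the estimator —
  which has no +1 correction — undercounts. Measured on null-spiked
  simulations, pseudo-reversal brings the realized false-target proportion
  at q ≤ 0.01 from ~1.7% to ~1.0%.
* **Ties.** An exact score-and-matched-count tie between a target and a
  decoy is resolved decoy-first. At 0.6 Da fragment tolerance exact ties
  between a peptide and its same-mass decoy are common (~30% of weak
  matches), and resolving them in the decoy's favor keeps the FDR estimate
  one-sidedly honest; the remaining tie-break is lexicographic for
  reproducibility.

Searching without any decoys and without declaring that a decoy database
was searched is an error (the estimate would be undefined); a clean search
that simply produced no decoy rank-1 PSMs is declared via
`decoys_searched=True`.

## Quantification

XIC area = trapezoidal integral over a ±0.5 min window around the
identified apex, after subtracting a baseline estimated as the median of
the first/last 3 in-window grid intensities, with the subtracted trace
floored at zero. The window half-width is a declared default (the manual
procedure it replaces is not parameterized); ±0.5 min covers ±5 elution
standard deviations at the default peak width. Chromatograms are assigned
to variants by precursor m/z within the precursor ppm tolerance.
Incorporation fractions are the variant areas normalized to their sum —
within-sample label-free quantification, no cross-sample normalization.
All areas zero flags the record as undefined rather than inventing
fractions. Fraction standard errors propagate the window-edge noise
estimate through the ratio by the delta method; they are exactly zero on
noise-free chromatograms and are diagnostics, not calibrated confidence
intervals.

## Synthetic data: what it emulates, what it does not

The generator's defaults are the study conditions of the built-in opal-129
model: mixture {R: 0.545, W: 0.308, C: 0.147} (the observed incorporation
shares), abundance scale 1e6 AU (the magnitude of reported ion
intensities), 2 ppm Gaussian mass error (calibrated-Orbitrap accuracy;
reported per-peptide errors are ~1 ppm), Gaussian elution peaks of SD 0.1
min placed ≥ 2 min apart on a 30 min gradient (so XIC windows never
overlap; placement is redrawn until spacing holds), 3 spectra per variant
near each apex, 10% fragment dropout, 10 uniform noise peaks per spectrum,
log-normal fragment intensities (median ~1e4 AU), singly charged fragments
(ion-trap CID read-out is dominantly low-charge), 2+ precursors. Each
variant contributes its *primary diagnostic peptide* — the site-covering
peptide of searchable length with fewest missed cleavages — which
reproduces the asymmetry created by K/R incorporation (SVTCTYSPR vs
SVTCTYSP{W,C}LNK). Optionally the zero-missed tryptic neighbour immediately
C-terminal to the diagnostic peptide is co-simulated, emulating the second
cleavage product of a restored K/R site.

Null datasets contain spectra of residue-shuffled peptides absent from the
target database — mass-matched, sequence-wrong foreigners used to verify
the FDR estimator; sources can be drawn from a pool of the database's own
tryptic peptides so the check is not tied to a handful of sequences.

Not emulated: profile-mode peaks, isotope envelopes, chimeric spectra,
retention-time drift, charge-state heterogeneity, and ionization
efficiency differences between variants. Passing tests therefore show the
*pipeline* is correct and calibrated under the stated statistical
structure; they do not show that XIC areas of different peptides are
comparable on real instruments (the within-site comparison the analysis
relies on assumes similar ionization of near-identical variant peptides).

## Fixture provenance

The built-in construct is a 435-residue p53–SBP fusion: canonical human
p53 (393 aa), a 4-residue synthetic linker (GSGS; only its length is
constrained by the fusion coordinate system), and the 38-residue
streptavidin-binding peptide tag, with the natural termination codon at
codon 436. The CDS is a synthetic back-translation (one fixed codon per
residue, codon 213 = CGA so the recurrent R213X nonsense alleles are
representable as single-base edits). The 3′ region after the terminal stop
is synthetic: six codons (ending in a TGT cysteine codon) before the next
in-frame stop — chosen to be consistent with the reported precursor mass
of the observed C-terminal stop-skip peptide — followed by a tail with
stops in all three frames so frameshift products terminate. No value
derived from the synthetic regions is used as ground truth.

## Problem sizes and defaults used in the shipped checks

The test-suite and the acceptance script run the full pipeline at desk
scale, chosen as the smallest sizes at which the statistical checks are
meaningful: mixture recovery over 10 seeded runs of 9 spectra each
(tolerance ±0.05 absolute, the spec of the recovery property); FDR
calibration pooled over 20 runs of 150 true + 30 null spectra (~3,000
accepted PSMs, enough to resolve a 1% rate against its one-sided binomial
envelope); digestion oracle on 200 random proteoforms ≤ 60 residues;
fragment complementarity on 1,000 random modified peptides. The peptide
index over the 21-proteoform database (plus decoys, semi-tryptic, modified)
holds ~12,000 forms and is built once and reused.

## Known limitations

* The dominance ranking is ordinal; it predicts no incorporation *rates*.
* Combinatorial events (e.g. a substitution at one PTC together with a
  skip at the terminal stop) are represented by composing constructs, not
  enumerated automatically.
* Fraction standard errors reflect chromatogram noise only, not
  identification or integration-window uncertainty.
* Protein-level FDR, retention-time alignment, match-between-runs and
  isobaric labeling are out of scope.
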