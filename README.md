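# ptcquant

**Which amino acid is incorporated at a premature termination codon (PTC)?**

Nonsense mutations replace a sense codon with a stop codon (UAA, UAG or
UGA), truncating the protein. Aminoglycosides such as gentamicin interfere
with termination and let *near-cognate* tRNAs — those whose anticodon pairs
with only two of the three stop-codon bases — decode the stop, producing
full-length protein with an a-priori unknown residue at the stop position.
Identifying and quantifying that residue requires mass spectrometry: digest
the protein with trypsin, match the MS/MS spectra against a database of all
possible readthrough products, and compare the extracted-ion-chromatogram
(XIC) areas of the site-variant peptides.

`ptcquant` is the computational side of that experiment, for proteomics and
gene-regulation researchers who work with PTC readthrough models (the
built-in construct is a p53–SBP fusion with synthetic opal/amber/ochre stop
codons):

* **candidate prediction** — enumerate the near-cognate decoding candidates
  of each stop codon and rank them by the wobble-stability argument: a
  cognate codon with C at position 1 puts a 3′ G in the anticodon opposite
  the stop codon's 5′ U, the comparatively stable G:U pair. That predicts R
  first at UGA (via CGA) and Q first at UAA/UAG (via CAA/CAG).
* **proteoform database** — all substitution-readthrough products, the
  stop-*skip* product (stop triplet bypassed in frame, translation extended
  to the next in-frame stop), and frameshift products (+1, +2, +4, +7, +8,
  +10, +19), written as FASTA.
* **digestion & mass arithmetic** — full and semi-tryptic digestion with
  missed cleavages (Keil rule), fixed/variable modifications
  (carbamidomethyl-C +57.021, Met oxidation +15.995, N-terminal acetyl
  +42.011 Da), monoisotopic masses, m/z = (M + z·1.007276)/z, and b/y
  fragment series with the complementarity b_i + y_(n−i) = M.
* **search & quantification** — target-decoy peptide-spectrum matching
  (10 ppm precursor / 0.6 Da fragment tolerances, q-values from the running
  decoy/target ratio, 1% peptide FDR) and per-site incorporation fractions
  `fraction_v = area_v / Σ areas` from baseline-subtracted trapezoidal XIC
  areas. No cross-sample normalization.
* **synthetic data** — a seeded generator emulating variant mixtures with
  Gaussian elution peaks, ppm-scale mass error, fragment dropout and noise
  peaks, with a ground-truth manifest, so the entire pipeline is testable
  without instrument files.

The search score is a deliberately simple matched-fragment/intensity sum —
a transparent stand-in for commercial engine scores, which this package
does not attempt to reproduce; masses, m/z and XIC quantification are
engine-independent.

## Worked example

The opal PTC nested in the reproducibly observed tryptic peptide
121-SVTCTYSPALNK-132 of p53 (stop codon at codon 129), with the observed
R/W/C incorporation mixture:

```bash
ptcquant run-all --config examples/tga129.yaml --seed 7 --out demo/
```

prints

```
                Readthrough incorporation quantification
========================================================================
spectra searched: 9      PSMs: 9      accepted (q <= 0.01): 9
database forms: 11901    decoy PSMs: 0
------------------------------------------------------------------------
site      variant  peptide                      area fraction      se
TGA129    C        SVTCTYSPCLNK             1.47e+05    0.147   0.000
TGA129    R        SVTCTYSPR                5.45e+05    0.545   0.000
TGA129    W        SVTCTYSPWLNK             3.08e+05    0.308   0.000
========================================================================
```

Reading the table: each MS/MS spectrum was matched against the digested
database of 21 proteoforms (20 substitutions + stop-skip) plus decoys; all
nine spectra were identified at q ≤ 0.01. Arginine incorporation at codon
129 creates a new tryptic cleavage site, so its diagnostic peptide is the
shorter SVTCTYSPR, while W and C sit inside SVTCTYSP{W,C}LNK (the C variant
carries two carbamidomethylated cysteines). The XIC areas normalize to
54.5% R, 30.8% W and 14.7% C — the simulated mixture, recovered. `demo/`
also receives the FASTA database, MGF spectra, chromatogram TSVs, the PSM
and quant tables, the ground-truth manifest and a `manifest.json` with the
config snapshot, seed and SHA-256 of every output.

The same analysis from Python:

```python
import ptcquant as pq

construct = pq.p53_sbp_construct("TGA129")
site = construct.site("TGA129")
db = pq.enumerate_substitution_proteoforms(construct, site)
db.append(pq.enumerate_skip_proteoform(construct, site))

dataset = pq.simulate_dataset(db, site, pq.SimulationConfig(seed=7))
results = pq.ReadthroughQuant(
    dataset.spectra, dataset.chromatograms, db, [site]
).fit()
print(results.summary())
print(results.params)   # per-(site, variant) fraction estimates
```

Other entry points: `ptcquant predict --stop TGA` (candidate table, R
flagged wobble-stabilized), `build-db`, `digest`, `simulate`, `search`,
`quantify`, `show-config`.

## Layout

```
src/ptcquant/
  genetic_code.py   translation, near-cognate candidates, wobble ranking
  proteoforms.py    constructs, codon edits, proteoform enumeration, FASTA
  digest.py         tryptic digestion, modifications, masses, b/y fragments
  search.py         decoys, peptide index, scoring, target-decoy q-values
  quant.py          XIC areas, incorporation fractions
  model.py          ReadthroughQuant / ReadthroughResults facade
  simulate.py       synthetic dataset + null (foreign-peptide) generator
  fixtures.py       p53–SBP fusion construct (synthetic back-translation)
  io.py             MGF (pyteomics) and chromatogram TSV round-trips
  cli.py            click command line
docs/methods.md     model assumptions, defaults, numerical choices, limits
```
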