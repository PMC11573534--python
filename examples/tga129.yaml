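# Opal PTC nested in the stable tryptic peptide 121-SVTCTYSPALNK-132:
# the TGA129 readthrough model with the observed R/W/C mixture.
construct:
  builtin: p53-sbp
  ptc: TGA129
database:
  candidates: all20
  include_skip: true
simulate:
  mixture: {R: 0.545, W: 0.308, C: 0.147}
  spectra_per_variant: 3
search:
  fdr_threshold: 0.01
  semi: true
quant:
  rt_window: 0.5
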