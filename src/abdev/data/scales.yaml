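# Per-residue scales used by the sequence featurizer. Each scale is averaged
# over the sequence (sum of per-residue values / length).
#
# mem: Kyte & Doolittle (1982) hydropathy index.
# fld: folding propensity, taken as mean fraction buried in folded proteins
#      (Rose et al. 1985).
# dis: intrinsic disorder propensity, TOP-IDP scale (Campen et al. 2008).
# bet: beta-strand conformational propensity (Chou & Fasman 1978).
mem:
  A: 1.8
  C: 2.5
  D: -3.5
  E: -3.5
  F: 2.8
  G: -0.4
  H: -3.2
  I: 4.5
  K: -3.9
  L: 3.8
  M: 1.9
  N: -3.5
  P: -1.6
  Q: -3.5
  R: -4.5
  S: -0.8
  T: -0.7
  V: 4.2
  W: -0.9
  Y: -1.3
fld:
  A: 0.74
  C: 0.91
  D: 0.62
  E: 0.62
  F: 0.88
  G: 0.72
  H: 0.78
  I: 0.88
  K: 0.52
  L: 0.85
  M: 0.85
  N: 0.63
  P: 0.64
  Q: 0.62
  R: 0.64
  S: 0.66
  T: 0.70
  V: 0.86
  W: 0.85
  Y: 0.76
dis:
  A: 0.06
  C: 0.02
  D: 0.192
  E: 0.736
  F: -0.697
  G: 0.166
  H: 0.303
  I: -0.486
  K: 0.586
  L: -0.326
  M: -0.397
  N: 0.007
  P: 0.987
  Q: 0.318
  R: 0.18
  S: 0.341
  T: 0.059
  V: -0.121
  W: -0.884
  Y: -0.51
bet:
  A: 0.83
  C: 1.19
  D: 0.54
  E: 0.37
  F: 1.38
  G: 0.75
  H: 0.87
  I: 1.60
  K: 0.74
  L: 1.30
  M: 1.05
  N: 0.89
  P: 0.55
  Q: 1.10
  R: 0.93
  S: 0.75
  T: 1.19
  V: 1.70
  W: 1.37
  Y: 1.47
# pKa values for the isoelectric-point model (EMBOSS defaults). Side chains
# D/E/C/Y titrate acid-side (lose a proton to become negative), H/K/R base-side.
pka:
  n_term: 8.6
  c_term: 3.6
  D: 3.9
  E: 4.1
  C: 8.5
  Y: 10.1
  H: 6.5
  K: 10.8
  R: 12.5
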