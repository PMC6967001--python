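# abdev

Sequence-based prediction of antibody developability across a 12-assay
biophysical panel.

Early identification of monoclonal antibodies with poor solution
behaviour — aggregation, self-interaction, polyspecificity, poor
expression — saves expensive late-stage failures, but the experimental
developability panels that measure these properties need purified
protein. abdev is for antibody engineers and discovery informaticians
who want a first-pass developability read from nothing but the paired
heavy/light variable-domain sequences (VH/VL): it trains one regression
model per assay on a reference panel of clinical-stage antibodies and
scores new candidates against that panel.

## The method in brief

For an Fv (the concatenation VH + VL) of length L, abdev computes a
35-component feature vector: the 20 composition fractions f_A…f_Y;
seven charge/aromatic composites (KmR = f_K − f_R, DmE = f_D − f_E,
KpR = f_K + f_R, DpE = f_D + f_E, PmN = f_K + f_R − f_D − f_E,
PpN = f_K + f_R + f_D + f_E, aro = f_F + f_W + f_Y); and eight
physicochemical summaries (mean folding, disorder and beta-strand
propensities; mean Kyte–Doolittle hydropathy; pI; absolute net charge
per residue absQ = |f_K + f_R − f_D − f_E|; composition entropy;
length).

Per assay platform the training pipeline is

1. censor filter (HIC values recorded at the 25-min ceiling are
   dropped);
2. optional ordered-quantile response transform,
   y(r) ↦ Φ⁻¹((r − ½)/n), for the skewed (approximately Gumbel)
   assay distributions;
3. variance-inflation-factor pruning (VIF_j = 1/(1 − R²_j), iteratively
   removing the worst feature ≥ 10) giving the *VIF all* set, then
   mixed stepwise selection minimizing AIC = n·ln(RSS/n) + 2(k+1)
   giving *VIF selected*;
4. z-scaling and a learner fit — elastic net, RBF-kernel SVM, or random
   forest — with hyperparameters tuned by nested cross-validation.

Candidates are compared by the mean absolute error of out-of-fold
predictions under 50× repeated 10-fold cross-validation, with every
pipeline stage refit inside each training fold. The packaged defaults
pin the winning algorithm/variable-set/transform combination per
platform. A scored candidate gets, per assay, a prediction and a 1–100
rank within the reference panel (1 best, 100 worst, direction-aware),
green/red threshold flags (HEK and DSF default to a worst-10%-of-panel
rule), and two combined scores: META X (mean rank over ELISA, BVP, PSR,
CSI, ACC-STAB, CIC) and META Y (mean rank over SMAC, HIC).

See `docs/methods.md` for assumptions, parameter defaults, and
limitations.

## Worked example

Train on a simulated 137-antibody panel (three assays shown; the
`simulate` subcommand writes sequences with valid CDR anchor motifs and
responses with known feature dependence), then score a candidate:

```sh
abdev simulate --n 137 --seed 42 --sequences panel.fasta --measurements panel.csv
abdev train --sequences panel.fasta --measurements panel3.csv \
      --out suite.json --summary summary.tsv --folds 10 --repeats 5 --seed 42
```

The training summary (`summary.tsv`):

```
platform  algorithm    variables     transformation    mae     r2
HIC       elastic_net  vif_selected  identity          0.773   0.606
SMAC      elastic_net  vif_selected  ordered_quantile  1.317   0.325
HEK       svm_rbf      vif_all       identity          47.116  0.030
```

MAE is on the raw assay scale (minutes for HIC retention); R² is the
squared Pearson correlation of out-of-fold predictions with
observations. The simulated HIC carries a strong aromatic/charge signal
(R² ≈ 0.6), while HEK was generated as a weak-signal assay — the near-
zero R² is the honest answer, not a failure.

```sh
abdev predict --suite suite.json --input cand.fasta --allow-partial
```

```json
{
 "predictions_raw": {"HIC": 10.12, "SMAC": 10.63, "HEK": 202.16},
 "ranks": {"HIC": 64.6, "SMAC": 89.2, "HEK": 22.0},
 "flags": {"HEK": "green"},
 "meta_y": 76.9
}
```

(abridged). This candidate is predicted mid-panel for HIC retention
(rank 64.6 of 100), near the bottom of the panel for SMAC (89.2), and
comfortably above the worst-10% HEK expression boundary (green flag).
META Y ≈ 77 puts it among the more hydrophobic panel members — a
candidate to watch on the chromatographic assays.

The other subcommands: `abdev featurize` (35-column TSV, `--cdr` adds
CDR-restricted features), `abdev correlate` (the 35 × 12 feature–assay
Pearson matrix), `abdev interaction` (the aromatic × absolute-charge
interaction model for HIC, with an exportable prediction surface).

Training on a real panel uses the same commands with your own FASTA
(`>id|VH` / `>id|VL` headers, or `>id` with a pre-concatenated Fv) and
a CSV of measured assay values. With the published 137-antibody
reference table, the packaged defaults reproduce the published
per-platform model choices; that data is not redistributed here.

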