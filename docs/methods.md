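# Methods

## Problem and model

abdev predicts how a candidate therapeutic antibody will behave on a
12-assay biophysical developability panel (HIC, SMAC, CIC, AC-SINS,
ELISA, BVP, SGAC-SINS, PSR, HEK titer, DSF, CSI, ACC-STAB) from nothing
but the paired variable-domain sequences (VH, VL). The working object is
the Fv: the concatenation VH + VL. One regression model is trained per
assay on a reference panel of antibodies with measured values; a
candidate is then scored by each model, located within the reference
panel by a 1–100 ranking, flagged against per-assay thresholds, and
summarized by two combined scores.

The premise is that solution behaviour of an Fv is substantially driven
by bulk sequence properties — amino-acid composition, net and absolute
charge, aromatic content, hydropathy — rather than requiring a 3D
structure. That premise holds unevenly across assays: chromatographic
and cross-interaction assays are predicted reasonably well; expression
titer and thermal stability are mostly not captured by composition.

## The 35-component feature vector

For an Fv sequence of length L:

* 20 composition fractions f_A … f_Y (count / L, alphabetical by
  one-letter code);
* 7 composites on the fraction scale: KmR = f_K − f_R, DmE = f_D − f_E,
  KpR = f_K + f_R, DpE = f_D + f_E, PmN = f_K + f_R − f_D − f_E
  (net positive charge), PpN = f_K + f_R + f_D + f_E (total titratable
  content), aro = f_F + f_W + f_Y (aromatic content);
* 8 physicochemical summaries: fld, dis, bet, mem — length-normalized
  means of per-residue scales (folding propensity from mean fraction
  buried, Rose et al. 1985; TOP-IDP disorder propensity, Campen et al.
  2008; Chou–Fasman beta-strand propensity; Kyte–Doolittle hydropathy);
  pI (pH units); absQ = |f_K + f_R − f_D − f_E| (per-residue absolute
  net charge; histidine deliberately excluded from the titratable set);
  entropy (Shannon entropy of the 20-letter composition, in bits — the
  log base is a package choice); and length (residue count, adopted as
  the eighth summary feature alongside the seven named physicochemical
  scores).

The scale tables ship as editable YAML (`abdev/data/scales.yaml`); the
cited scales were chosen as canonical published representatives of each
property class, and none of the package's statistical behaviour depends
on their exact numeric content.

pI is the root of the Henderson–Hasselbalch net-charge curve over side
chains D, E, C, Y (acid side) and H, K, R (base side) plus free termini,
with EMBOSS pKa values, found by bisection on pH (0, 14) to |charge| <
1e-4. The curve is monotone non-increasing in pH, so bisection always
converges; an all-acidic (or all-basic) sequence has no interior root
and the bisection settles at the appropriate boundary. With termini
excluded and no titratable group present, pI is undefined and the
defined fallback of 7.0 is returned with a warning.

Note the feature set is deliberately redundant: the composites and the
scale means are exact linear combinations of the composition fractions,
and the fractions themselves sum to 1. The collinearity stage below is
what resolves this redundancy, mirroring how the feature set is used in
practice.

## CDR identification

The six CDRs are located by sequence anchor rules, not by a numbering
scheme: L1 begins immediately after the framework-1 cysteine and ends at
the tryptophan that opens framework 2 (lengths 10–17); L2 sits a fixed
15 framework residues after L1 with fixed length 7; L3 begins right
after the framework-3 cysteine, 32 residues after L2 (lengths 7–11),
and is followed by F-G-x-G. On the heavy chain H1 begins four residues
after the framework-1 cysteine (lengths 10–12, Trp after), H2 begins 14
residues after H1 (lengths 16–19, Lys/Arg after), and H3 begins 32
residues after H2 with the conserved cysteine three positions before
its start, followed by W-G-x-G (lengths 3–25). When several lengths in
a window would satisfy the right-flank condition, the smallest is taken.
Constants live in `abdev/data/cdr_rules.yaml`. Coordinates are 0-based
half-open internally.

CDR-restricted features (the same 35 components computed on the
concatenation of the six loops) are available as optional extras; the
trained models consume the full-Fv features only.

## Preprocessing and variable selection

Per platform, in order, each step fitted on training rows only:

1. **Censoring.** Rows with the response at or above the platform's
   censor value are dropped. Only HIC has a default (25), the value
   recorded when a run exceeds the measurement window; `>=` rather than
   `==` makes the filter robust to float round trips.
2. **Response transform.** Identity, or the ordered-quantile (ORQ)
   normal-scores transform: the training value with average rank r of n
   maps to Φ⁻¹((r − 0.5)/n); ties share their average rank; new values
   interpolate linearly between bracketing training pairs and
   extrapolate linearly beyond the training range (the extrapolation
   rule is a package choice). The inverse is the piecewise-linear
   inverse. A constant response refuses the transform and falls back to
   identity with a warning. Several assay distributions are strongly
   right-skewed (approximately Gumbel), which is what the ORQ option is
   for; the transform is fitted after censoring so sentinel values never
   shape it.
3. **VIF pruning.** The variance inflation factor of feature j is
   1/(1 − R²_j) with R²_j from OLS of feature j on all other features
   (intercept included). The feature with the largest VIF ≥ 10 is
   removed, VIFs are recomputed, and the loop repeats until all VIFs
   are below 10. Exactly collinear features get an infinite VIF rather
   than an error. Ties within 1e-9 remove the later feature in the
   canonical 35-feature order, which keeps the simpler composition
   fractions and discards redundant composites deterministically. The
   surviving list is the **VIF all** variable set.
4. **Stepwise AIC.** Mixed (bidirectional) greedy search over the VIF
   all set, starting from the full set: at each step the single add or
   drop move that most lowers AIC = n·ln(RSS/n) + 2(k+1) is taken;
   termination when no move improves. Moves leaving fewer than three
   residual degrees of freedom are disallowed. The result is the
   **VIF selected** set. The search's start point and step rules are
   package choices; starting from the full set gives the backward-
   leaning variant of a mixed search.
5. **Scaling.** z-scores with training mean and sd (n−1 denominator);
   zero-spread features are dropped with a warning. Scaling happens
   after VIF computation, which is immaterial because VIF is
   scale-invariant.

## Training, cross-validation, model selection

Three learners are registered: elastic net (mixing 0.1/0.5/0.9 × 20
log-spaced penalties), RBF-kernel SVM (cost 0.25–4, kernel width at the
median heuristic × 0.5/1/2), and random forest (500 trees, one-third
feature subsampling). Grids live in config, not code, and are tuned by
an inner 3-fold CV on the training rows of each outer fold.

Generalization error is estimated by 50× repeated 10-fold
cross-validation (seeded, near-equal fold sizes). Within every training
fold the full pipeline — transform, VIF pruning, stepwise selection,
scaling, hyperparameter tuning — is refit from scratch, so no
information leaks from validation rows; a permutation test (shuffled
response) holding out-of-fold R² near zero is part of the test suite.

Candidates (algorithm × variable set × transform) are compared by the
MAE of pooled out-of-fold predictions. Because an MAE on a
normal-scores scale is not commensurable with one on a raw assay scale,
the default back-transforms out-of-fold predictions to the raw scale
before comparing; `paper_mode` compares each candidate on its native
scale instead. Ties break toward the simpler model (elastic net < SVM <
random forest, then VIF selected < VIF all, then identity transform).
R² is reported as the squared Pearson correlation of pooled out-of-fold
predictions against observations.

The packaged per-platform defaults pin the winning combination per
assay (e.g. HIC: elastic net + VIF selected + identity; SMAC: elastic
net + VIF selected + ORQ; ELISA/BVP: random forest + VIF all), so a
default `train` run cross-validates only the pinned candidate; setting
any field to `auto` re-opens the selection. A platform with fewer than
20 usable rows is refused (too shallow for 10-fold CV). The winner is
refit on all usable rows and its predictions over the reference panel
are stored with the suite.

Suites serialize as versioned JSON (selection logs, scaler, transform
pairs, reference values and predictions, inline linear coefficients)
plus an adjacent joblib blob holding the fitted learner states, since
forest and SVM state is not usefully JSON-representable; loading
reproduces predictions bit-identically.

## Ranking, flags, meta scores

A candidate's value on a platform is ranked within the reference panel:
references are ordered best to worst by the platform's direction
(lower is better for the chromatographic/interaction assays; higher is
better for SGAC-SINS, HEK, DSF — the direction table is editable
config), the candidate's position is 1 + the number of strictly better
references (ties take the average of the tied references' positions),
and position p ∈ [1, n+1] rescales to rank = 1 + 99(p − 1)/n, so 1 and
100 are exactly attainable. By default the panel consists of the refit
model's predictions over the reference antibodies, so candidate and
panel are compared on identical footing (a candidate sequence identical
to a reference gets exactly that reference's predicted value); ranking
against observed values is available.

Platforms with a published cutoff take it as user config on the raw
assay scale; HEK and DSF default to the worst-10% rule: the boundary is
the ⌈0.1 n⌉-th worst reference value, resolved and stored at
suite-build time. A prediction on the unfavourable side of its
threshold is flagged red; the comparison is direction-aware by default,
with a literal "above is red" mode available.

META X is the mean rank over ELISA, BVP, PSR, CSI, ACC-STAB, CIC (cross-
and self-interaction); META Y over SMAC and HIC (hydrophobic
interaction). Both lie in [1, 100]; closer to the origin of the
(META X, META Y) plane is better. Missing member platforms leave the
meta score absent unless partial averaging is explicitly allowed.

## Interpretive analyses

`feature_platform_correlations` computes the 35 × 12 Pearson matrix on
pairwise-complete rows, excluding censored HIC rows by default for
consistency with training (inclusion is a flag); cells with constant
input are marked undefined rather than zero. `fit_hic_interaction` fits
OLS of HIC on aro, absQ and their product — capturing the observation
that absolute charge suppresses retention mainly at long retention
times, where the decreasing ionic-strength gradient no longer screens
electrostatic repulsion — with aro and absQ unscaled so the fitted
surface's axes are directly interpretable (a scaled variant exists for
coefficient comparison).

## Synthetic data

The generator builds Fv records from fixed synthetic framework
scaffolds (deliberately not germline sequences) that carry exactly the
anchor motifs the CDR rules require; CDR contents and lengths are drawn
uniformly over each rule's permitted window from alphabets excluding
the anchor letters, so identification never fails and every permitted
length is exercised. Responses follow y = Σ β_f·feature_f + ε with
Gaussian or Gumbel noise scaled to a target signal fraction
(var(signal)/var(total)), optionally affine-mapped to a realistic assay
range, with the top fraction of HIC values replaced by the 25 sentinel.
The default configuration mirrors the study shape — 137 antibodies,
12 platforms, a positive-aromatic/negative-charge HIC with 10% censored
values at signal fraction 0.6, net-positive-charge effects on the
interaction assays, weak signal (0.15) on HEK/DSF/ACC-STAB, Gumbel
noise on the skewed assays.

What the simulation does not emulate: real immunogenetics (germline
V/J usage, somatic hypermutation), correlated assay errors, non-linear
sequence–property relationships beyond what the features induce, and
the covariance structure of clinical-stage antibodies. Passing
recovery tests therefore demonstrates that the machinery is correct and
leak-free under known ground truth, not that real-panel accuracies will
be reproduced; reproducing published per-assay accuracies requires the
external reference panel (see README).

## Numerical choices and problem sizes

* Bisection tolerance for pI: 1e-4 charge units; VIF infinity cutoff
  1 − R² ≤ 1e-12; stepwise improvement threshold 1e-10; scaler
  zero-spread cutoff 1e-12.
* Exact feature collinearity means the trained models represent, e.g.,
  an aromatic-content effect through the surviving f_F/f_W/f_Y
  fractions after pruning; recovery tests therefore read effect
  directions off the fitted predictions (regressing them on the planted
  features) rather than expecting a named coefficient.
* Tests and examples run at reduced sizes chosen to keep the default
  suite quick while preserving the statistical properties being
  checked: panels of 40–150 antibodies, 1–5 CV repeats with 5–10
  folds, 500-draw Monte-Carlo checks. Full-size runs (137 rows,
  50 × 10-fold) are the library defaults.

## Known limitations

* The anchor rules assume conventional framework architecture; heavily
  engineered or truncated domains can fail CDR identification (by
  design, with a named-region error).
* Per-platform models are trained independently; correlations between
  assays are exploited only implicitly through shared features.
* The worst-10% rule depends on the reference panel; suites trained on
  different panels yield different HEK/DSF boundaries.
* MAE comparability across response transforms is resolved by
  back-transformation; in `paper_mode` the comparison reproduces the
  native-scale convention and can prefer different winners.
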