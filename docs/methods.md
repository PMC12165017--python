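# Methods

This note documents the models, defaults and design choices behind
`maldiag`, and what the synthetic studies do and do not establish.

## The synthetic study generator

The generator emulates the statistical structure of a multicenter salivary
MALDI-TOF fingerprint screening study; it makes no attempt to simulate
metabolite chemistry, adducts or isotope envelopes.

**Cohort.** Default group sizes are 429 HC / 280 BD / 334 LC (1043 donors)
split 573/236/234 into discovery/validation/test with fixed per-group
counts (validation: 102 HC + 62 BD + 72 LC; test: 90 HC + 73 BD + 71 LC).
Categorical demographics (gender, smoking, family history, environmental
exposure, LC stage and histologic subtype) are matched *exactly* to the
configured per-group margins by shuffling label vectors; ages are
truncated-normal (means 57–58, SD 9–10, range 35–80). Stage I is split
80:20 into IA:IB because only the aggregate stage-I count is specified at
the cohort level. Serum CA125/CEA values are log-normal with a mildly
elevated, heavier-tailed LC distribution and ~40 % missingness — invented
but shaped so the biomarkers have the characteristically poor standalone
sensitivity for lung cancer. 46 detection batches each carry 3 pooled-QC
entries (138 QC measurements), and every sample is spotted in triplicate.

**Amplitude model.** Peak amplitudes are log-normal. On the natural-log
scale, sample *i*, feature *j*, replicate *r*:

```
log A_ijr = mu_j + ln(2)·log2FC_j·1[i ∈ LC]
          + bio_sd·(l_j z_ib + sqrt(1−l_j²) e_ij)
          + b_{batch(i),j} + u_ijr
```

with `bio_sd = 0.5` (biological variation), block factors `z_ib` giving
correlated feature groups (default loading 0.6), batch effects
`b ~ N(0, 0.06)` and replicate (spot) effects `u ~ N(0, 0.10)`. Class
effects act multiplicatively on the LC mean, matching non-negative MS
intensities and rank-based testing. The technical scales were fixed once
from the closed form CV = √(exp σ²−1): replicate σ=0.10 gives ~10 %
intra-batch CV and adding batch σ=0.06 gives ~11.7 % across-batch CV on QC
samples, the regime reported for stable fingerprint acquisition. QC samples
replace the donor term by the log of the arithmetic mean of a 50-donor
pool's linear amplitudes, so they carry only technical variance.

**Planted effects.** The default effect layout plants 35 informative
features: 10 strongly up- and 10 strongly down-regulated in LC
(|log2FC| ∈ [0.8, 1.5]) plus 15 weakly shifted (|log2FC| ≤ 0.15). At
study-scale n the strong 20 reach FDR < 0.05 under Mann–Whitney screening
while the weak 15 generally do not — i.e. roughly 20 of 35 panel features
are "significant", the regime a fingerprint panel typically shows.

**Spectra.** The acquisition grid is uniform with 65,536 points over m/z
66–350 (>60,000 points without modeling instrument-specific spacing). A
spectrum is a decaying baseline (amplitude 30, scale 80 Da) on a flat
chemical-noise floor (6× the additive-noise SD), plus Gaussian peaks with
reflectron-TOF-like widths (σ 0.008–0.022 Da), plus additive N(0,1) noise.
The positive floor matters: without it, zero-clipping skews the noise
distribution and inflates the false-peak rate of any MAD-based S/N gate.
The default panel has 800 peaks — 650 well above the S/N=5 detection
threshold (apex S/N 25–2000) and 150 hovering near it — calibrated once so
that roughly 650–670 features survive presence filtering, mirroring a
~646-feature fingerprint. Panel peaks are kept ≥0.25 Da apart so binning is
unambiguous.

## Preprocessing

Fixed stage order: smooth → SNIP baseline → TIC normalize → detect →
align/bin → presence filter → replicate average; the chain is deterministic
and bit-identical on identical input.

* **Smoothing**: Savitzky–Golay, degree 3. The *function* default
  half-window is 10 grid points; the *pipeline* default is 3, matched to
  the synthetic peak widths (σ ≈ 2–5 grid points on the 65,536-point grid —
  a 21-point window visibly rings on such narrow peaks). Users on coarser
  grids should scale the half-window with their peak width.
* **Baseline**: SNIP with increasing clipping window, 100 iterations
  default; the estimate is pointwise ≤ the signal and monotone
  non-increasing in the iteration count.
* **Noise**: scaled median absolute deviation of the baseline-subtracted
  spectrum; S/N is measured above the residual's median (the clipped
  residual floor), computed post-baseline and pre-normalization.
* **Peak detection**: strict local maxima over a ±10-point neighborhood
  with S/N > 5.
* **Binning**: greedy intensity-first clustering at 500 ppm; each peak
  joins at most one feature, feature m/z is the intensity-weighted member
  mean, and bins closer than the tolerance are merged afterwards so centers
  are strictly increasing and pairwise separated by more than the
  tolerance. When one spectrum contributes several peaks to a bin, the most
  intense is kept.
* **Presence filter**: strictly greater than 80 % of rows ("over 80 %" is a
  strict inequality); missing entries are imputed as 0 before modeling
  (absence = below the S/N gate).
* **Replicates**: arithmetic mean over the spots in which the feature was
  detected.

## QC filtering

CV = 100·sd/mean with the sample (n−1) standard deviation. Intra-batch CVs
are computed per (feature, batch) over that batch's QC replicates;
"inter-batch" summaries are reported both over batch means and over all QC
replicates pooled. The 25 % exclusion rule uses the pooled all-QC CV (the
single-number criterion); the batch-mean variant is selectable by flag.
Exactly 25.0 % is retained; the filter is idempotent.

## Feature selection

Mann–Whitney U tests are exact for group sizes ≤ 8 (and no ties), otherwise
tie-corrected normal approximation; Benjamini–Hochberg step-up controls
FDR. SFFS maximizes mean stratified K-fold out-of-fold AUC (default 10
folds; scores come from `decision_function` where available, avoiding
probability calibration inside the search). Forward steps must improve the
best known objective at the current size by `min_delta = 1e-4`; conditional
backward steps (only at subset size ≥ 3, never undoing the immediately
preceding addition) require strict improvement over the best known
objective at the smaller size. Every evaluated subset signature is cached,
which both avoids recomputation and prevents oscillation. The selector
returns the best subset seen, with a replayable add/remove trace. Classic
floating search does not guarantee a monotone objective along the accepted
event sequence (the backward step compares against the best at the smaller
size, not the current incumbent); the replay contract, not monotonicity, is
what the trace guarantees. Features are z-scored once on the training table
before the search (per-fold scaling is a config choice; for rank-based AUC
objectives the difference is negligible and the one-shot scaling makes the
search several-fold cheaper).

The learner registry provides regularized logistic regression, random
forest, k-NN, RBF and linear SVC, and a histogram gradient-boosted tree
family, each with a small documented tuning grid (`LEARNER_GRIDS`) usable
through `tuned_learner`. SVC variants score through their margin, squashed
to [0,1] by a logistic map when probability-scale scores are required.

## Ensemble and evaluation

The diagnostic model is a soft-voting ensemble: the weighted mean of the
base models' probability-scale scores, equal weights by default (weights
are config-exposed; whether the original ensemble weighted by AUC is not
determinable, so equal is the default). The decision threshold defaults to
0.5, with an optional Youden-J threshold chosen on the validation split.
Class weighting uses inverse-class-frequency loss weights. Biomarker
augmentation rescales CA125/CEA through the training split's empirical CDF
(raw U/mL and ng/mL are incommensurate with probabilities), imputes missing
values with the training median, and enters them as extra voting channels.

AUC confidence intervals use DeLong's placement variance by default (the
convention of standard ROC packages), with a seeded stratified bootstrap
for degenerate cases. Percentages are reported to two decimals, rounding
half-up. The decision-curve grid is 0.01–0.60 in steps of 0.01. Matched
operating points return the smallest threshold achieving a requested
specificity (or the largest keeping a requested sensitivity) on the
empirical ROC.

Odds ratios use a Newton–Raphson logistic fit with complete-separation
pre-checks and a divergence guard (|log-odds| > 30 aborts with a
quasi-separation error); Wald CIs and p-values match the reporting
convention of adjusted-OR tables. Propensity matching is greedy 1:1
nearest-neighbor without replacement within a caliper of 0.2 SD of the
logit propensity — a conventional default, config-exposed. The ML power
analysis subsamples n per group, fits the default learner on 70 %, and
tests held-out separation with a one-sided Mann–Whitney test; power is the
significant fraction of B repeats, optionally isotonic-smoothed.

## Orchestration

`run_all` executes simulate → preprocess → qc → select → train → evaluate →
stats into one directory. The single global seed expands into per-stage
seeds by a fixed offset scheme; `manifest.json` records every stage's
parameters, seed and output checksums. Re-running resumes from intact
cached outputs; a checksum mismatch raises a stage-named error instead of
silently recomputing. Model bundles are a versioned JSON manifest plus
per-model joblib blobs. Spectra are written as gzip two-column text with a
fixed gzip mtime so archives are byte-stable; a minimal mzML reader
(64/32-bit float arrays, plain or zlib-compressed) covers the standard
interchange format on the input side.

## Problem sizes used in validation

The validation suite and the results-reproduction script run scaled
studies chosen to exercise every stage at full fidelity while staying
single-CPU friendly: planted-recovery runs use 150 donors per group with
210 features, three fast registry learners (logreg, k-NN, linear SVC) and
5-fold CV inside SFFS; spectral-chain studies render 42-donor cohorts on
the full 65,536-point grid; null calibration uses 100 donors per group and
50 features. Larger configurations change runtimes, not code paths.

## What passing tests do and do not show

The generator's planted ground truth makes recovery measurable, but its
simplifications cut both ways: peaks are ideal Gaussians on a known grid
(no mass-calibration drift, warping, or adduct structure), batch effects
are purely multiplicative and feature-independent in scale, and biological
covariance is a few shared factors rather than a metabolic network.
Passing recovery and calibration suites therefore demonstrates the
*statistical machinery* — selection finds planted signal, the ensemble
generalizes, null data yields chance-level AUC and calibrated p-values —
not that real saliva spectra will yield the published effect sizes.
Real-data entry points (mzML/two-column spectra, CSV feature matrices and
metadata) bypass the generator entirely.

## Known limitations

* No drift correction or batch-effect removal — features failing QC are
  excluded, not corrected.
* No recalibration against external mass standards, isotope deconvolution
  or spectral warping beyond binning.
* SVC probability scores are logistic-squashed margins, not calibrated
  probabilities.
* The power-analysis statistic (held-out Mann–Whitney on classifier
  scores) is one reasonable interpretation of "ML-based power analysis";
  alternatives (e.g. accuracy-threshold rules) would shift absolute power
  values.
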