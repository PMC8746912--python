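# Methods

`microvasc` is a desk-scale re-creation of a retinal-microvasculature
analysis pipeline: fundus-like image simulation with ground-truth vessel
trees, automated image quality control, ensemble U-Net vessel segmentation,
quantification of two vascular geometry indices — box-counting fractal
dimension (FD) and vascular density — and the downstream epidemiological
and genetic machinery (PheWAS, GWAS, polygenic scores, one-sample Mendelian
randomization) exercised on a simulated cohort with known effects. This
note records the models, the defaults that matter, and the design choices
made where the design was genuinely open.

## Synthetic vasculature

The simulator's job is not photorealism; it is to give every downstream
stage a ground truth. A vascular tree is grown by recursive binary
bifurcation from `n_roots` trunks (default 4) at an optic-disc point offset
from the field-of-view (FOV) center. At each generation every terminal
segment splits into two children rotated by ±`branch_angle_deg` (default
35°, Gaussian jitter SD 18% of the half-angle), shortened by
`length_ratio` (default 0.78, jitter SD 8%) and thinned by a Murray-type
caliber split `w_child = w_parent · 2^(−1/γ)` with exponent γ = 3 (the
classical value for volumetric flow optimality). Widths never drop below
1 px. Tortuosity is a smooth sinusoidal in-plane perturbation that
vanishes at segment endpoints, so children stay attached. Generations are
capped at 12 (raster blow-up guard).

Rasterization stamps discs of radius width/2 along each (perturbed) path
and is hard binary — no anti-aliasing — because FD and density are defined
on binary segmentations. All vessel pixels are clipped to the FOV disc
(radius 0.48·min(H, W), canvas default 256×256; 128×128 in the training
benchmarks). Coordinates are pixel-centered (row, col), origin top-left.

Rendering places vessels *darker than background in the green channel*
(contrast 0.32), over a radial background gradient, a bright optic-disc
blob, and Gaussian pixel noise (SD 0.015); red/blue channels are offset
copies of green, which matches the empirical fact that fundus vasculature
contrast lives mainly in the green channel. Degradations come in three
modes — Gaussian blur (σ up to 6 px), occlusion by a uniform patch whose
radius grows with severity (severity 1 swallows the whole FOV), and
over-exposure toward saturation — each graded by a severity in [0, 1] with
severity 0 the exact identity.

What the simulator does *not* emulate: arteriole/venule distinction,
caliber pulsation, macula/disc anatomy beyond a bright blob, media
opacity, inter-eye asymmetry, or magnification variation. Passing
benchmarks therefore demonstrate that the machinery is correct and
well-calibrated on data of known structure — not that the trained networks
would transfer to real fundus photographs.

## Quality control

A three-block convolutional classifier (8/16/32 channels, each block conv
3×3 → ReLU → 2×2 max-pool, then global average pooling and a linear head)
maps a 64×64 standardized green channel to a poor-quality probability.
The synthetic "poor" label is any degradation with severity ≥ 0.4 — a
stand-in rule, since real quality grades are human judgments. Training:
Adam (lr 2·10⁻³), batch 16, 10 epochs, binary cross-entropy; the decision
threshold (default 0.5) is configurable and reported. On held-out
synthetic images the classifier reaches sensitivity and specificity ≥ 0.95
(the benchmark asserts this), which is expected: the classes are separable
by construction at these severities.

## Vessel segmentation

Each ensemble member is a U-Net: depth-3 encoder (16/32/64 channels, one
conv+ReLU per level), a 128-channel bottleneck, and a mirrored decoder
using nearest-neighbor upsampling, skip concatenation, and a 1×1 output
conv. The networks run on the package's own numpy NN core (hand-written
backpropagation over BLAS tensor contractions; gradients are verified
against finite differences in the test suite), sized so that training the
default three-member ensemble on 200 images takes a few minutes on one
CPU core.

Training samples one random 64×64 patch per image per epoch (default 4
epochs, batch 8, Adam lr 3·10⁻³), with flip and 90°-rotation augmentation,
under pixel-wise binary cross-entropy. Members share data and differ only
in seed (initialization, shuffle, patch draws); the ensemble probability
map is the arithmetic mean of member maps, and per-pixel member
disagreement (SD across members) is available. Binarization is
`prob ≥ threshold` (default 0.5) inside the FOV; the ≥ convention makes
the boundary case deterministic. Evaluation metrics (Dice, pixel
accuracy, rank-based ROC AUC) are computed over FOV pixels only and are
tested against brute-force definitions.

## Quantification

**Fractal dimension** is the monofractal Minkowski–Bouligand box-counting
estimate: dyadic box sizes s ∈ {2, 4, …, s_max} with s_max the largest
power of two ≤ min(H, W)/4 (≥ 4 sizes required), N(s) the number of
occupied grid cells, FD the OLS slope of log N(s) on log(1/s). The grid
is origin-anchored by default; a best-of-4-offsets policy (minimum count
over half-box shifts, a tighter covering) is available as config. FD is
computed on the full-width binary mask, not a skeleton — skeletonization
is a defensible alternative and is deliberately left out of the default
path so that density and FD are computed from the same object. Analytic
anchors: a 1-px line scores 1.00, a filled disc 1.91, a depth-5 Sierpinski
carpet 1.85 against the exact log 8/log 3 ≈ 1.893 (origin-aligned dyadic
grids on a 3^k fractal slightly under-measure; the estimate sits within
the ±0.05 band the benchmark requires).

**Vascular density** is the vessel pixel count inside the FOV, reported
both raw and as the FOV fraction; downstream analyses use the fraction
(with a fixed FOV the two are proportional).

Per-eye values are averaged to per-participant values (single-eye
participants keep their single value; duplicate eye labels are an error),
standardized to cohort z-scores with the sample SD (n−1), and flagged
"low" when ≤ mean − k·SD (default k = 2, inclusive at the boundary).
Right-left agreement is summarized by Spearman correlation and a paired
t-test on (right − left).

## Cohort simulation

Genotypes are independent Hardy–Weinberg dosages, `Binomial(2, MAF_j)`
with MAF uniform in a configurable range — no linkage disequilibrium, so
PRS and MR truths stay analytic and independence pruning is a no-op
(a greedy |r| > 0.1 pruner is included for correlated data). Covariates
mimic a middle-aged imaging cohort: age ~ N(56, 8), 55% female, 44%
ever-smokers, ten synthetic ancestry components, a genotyping-array
indicator. A quantitative exposure (the analogue of a standardized
retinal metric) is built from chosen causal variants, covariate terms, an
optional shared latent confounder, and Gaussian noise, then standardized.

Outcomes are generated strictly downstream of the exposure: prevalent
binary outcomes through a logistic link, quantitative traits through a
linear model, and incident outcomes as exponential event times
(proportional hazards holds exactly). Censoring uses per-subject
independent exponential censoring at rate h_i·c/(1−c), which censors each
subject with probability exactly c while remaining conditionally
independent of the event time — an earlier uniform-on-(0, T) scheme was
rejected because it is informative and visibly degraded Cox confidence
interval coverage.

## Association machinery

Prevalent outcomes are fit by logistic regression, incident outcomes by
Cox proportional hazards (Efron tie handling, as implemented in
lifelines; prevalent cases of the same outcome are excluded from the risk
set), quantitative traits by OLS — all adjusted for age, age², sex, and
smoking category by default. Effects are reported per 1-SD increase of
the exposure with the per-1-SD-decrease direction carried alongside
(risk associations for these metrics are conventionally quoted per SD
decrease). Non-convergence and complete separation yield flagged results,
never silent NaNs. Benjamini–Hochberg FDR is applied within each
exposure × analysis-class scan; outcomes with fewer than 20 cases
(configurable) are skipped with a log entry. Stratified analyses report
per-stratum fits plus Cochran's Q (inverse-variance weights, chi-square
with #strata − 1 df) for heterogeneity; an interaction-term test would be
an alternative, but Q operates directly on the stratum effect estimates
and matches how stratified hazard ratios are usually compared.

## Genetics

The GWAS scan is per-variant OLS of the standardized trait on dosage with
covariates (age, age², sex, ever-smoking, 10 PCs, array), vectorized by
Frisch–Waugh–Lovell residualization with the correct residual degrees of
freedom — the tests assert numerical identity with per-variant
statsmodels fits. Variants at or below the MAF floor (default 0.001) are
dropped and counted; monomorphic columns likewise. PRS weights are the
betas of variants passing the selection threshold (default 5·10⁻⁸), and
scores are plain weighted allele sums with per-variant mean imputation
for missing dosages. PRS discovery and evaluation can be forced onto
disjoint participant splits (`split_cohort`).

One-sample MR is explicit two-stage least squares with the PRS as
instrument: stage 1 regresses exposure on PRS + covariates, stage 2
regresses outcome on the fitted exposure + covariates, with the standard
2SLS residual variance computed from the *actual* exposure and a
first-stage partial-F strength statistic (estimates with F < 10 are
flagged weak). A direct reduced-form PRS-association mode is also
provided; under linearity the two coincide after rescaling by the
first-stage slope. Effects can be rescaled to any exposure unit (per 10
units, or per log 2 of a genetic log-odds exposure for "per 2-fold higher
genetic risk" readings).

## Pipeline

The `run` command executes simulate → QC → segment → quantify → cohort →
PheWAS → GWAS → PRS → MR from one YAML config. The global seed derives
per-stage seeds deterministically; every stage records parameters, input
names, output SHA-256 hashes, and timing in a run manifest, and an
identical config reproduces identical hashes end to end (asserted by the
benchmark). QC-rejected images never reach segmentation or
quantification, and the QC removal fraction is logged.

## Benchmark study conditions

The standing benchmarks use: FD fixtures at 256×256 (carpet 243×243); the
generations 1–8 sweep with 10 trees per depth; segmentation trained on
200 and tested on 20 images at 128×128 with the default K=3 ensemble; QC
trained on 200 clean + 200 degraded and tested on 50 + 50; PheWAS null
calibration over 5 replicates of 100 null outcomes at n = 2000; GWAS null
calibration on 10⁴ variants at n = 1000; Cox coverage over 500 replicates
at n = 5000 with true HR 1.5; MR recovery at n = 10⁴ with a planted slope
of 0.3, 30 causal variants of effect 0.22 (first-stage R² ≈ 0.27),
exposure-side confounder loading 0.8 and outcome-side 0.6; MR null
coverage over 500 replicates at n = 2000; determinism on a 12-image,
n = 1000 demo run. These sizes put the Monte-Carlo error of each measured
quantity well inside the tolerance asserted for it.

## Known limitations

- The NN core is single-threaded float64 numpy; it is deliberately small
  and has no batch norm, dropout, or learning-rate schedules.
- The QC "poor" label rule (severity ≥ 0.4) is a synthetic stand-in for
  human quality grades.
- The FD estimator is monofractal; multifractal spectra, skeleton-based
  FD, and size-range cuts are out of scope (offset policy and
  skeletonization hooks are the extension points).
- No linkage disequilibrium, population structure, or pleiotropy in the
  simulator; the MR benchmark therefore tests the estimator under its
  own assumptions, not robustness to their violation.
- Tortuosity is rendered but not quantified; arteriole/venule metrics are
  out of scope.
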