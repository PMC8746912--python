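# microvasc

Desk-scale analysis of the retinal microvasculature, end to end: simulate
fundus-like photographs with ground-truth vessel trees, flag poor-quality
images with a convolutional classifier, segment vessels with an ensemble
of U-Nets, quantify **fractal dimension (FD)** and **vascular density**,
and carry those indices through the epidemiological and genetic machinery
used in population imaging studies — phenome-wide association (PheWAS),
GWAS, polygenic risk scores (PRS), and one-sample Mendelian randomization
(MR).

The package is aimed at methods developers and students of population
ocular imaging: every stage runs in minutes on one CPU core against a
bundled simulator with known ground truth, so the whole chain — from raw
pixels to causal-effect estimates — is testable without any restricted
biobank or public fundus dataset.

## The quantities and models at the core

**Box-counting fractal dimension.** For a binary vessel mask, cover the
plane with grids of box size *s* ∈ {2, 4, …, s_max} and count occupied
boxes N(s). The FD is the OLS slope of log N(s) versus log(1/s): ≈ 1 for
a single vessel, → 2 for a space-filling network. **Vascular density** is
the vessel-pixel count within the circular field of view (FOV), reported
as a FOV fraction. Per-eye values are averaged per participant,
standardized to cohort z-scores, and flagged "low" at ≤ mean − 2 SD.

**Association scans.** An exposure x (a standardized vascular index or a
PRS) is tested against a phenotype panel: prevalent outcomes by logistic
regression, incident outcomes by Cox proportional hazards
(λ(t) = λ₀(t)·exp(βx + γᵀc), prevalent cases excluded from the risk set),
quantitative traits by OLS — all adjusted for covariates c (age, age²,
sex, smoking), with Benjamini–Hochberg FDR across each scan and Cochran's
Q for between-stratum heterogeneity.

**Genetics.** GWAS: per-variant OLS of the trait on dosage with covariate
adjustment (vectorized, numerically identical to per-variant fits). PRS:
Σⱼ wⱼ·gᵢⱼ over variants with p < 5×10⁻⁸. One-sample MR: two-stage least
squares with the PRS as instrument — stage 1 x ~ PRS + c, stage 2
y ~ x̂ + c — with a first-stage partial-F strength statistic and optional
rescaling to natural exposure units.

## Worked example

```python
import numpy as np
from microvasc import synth, quantify

# a vessel tree with 6 bifurcation generations, rasterized over a FOV
tree = synth.generate_tree(synth.TreeParams(generations=6, seed=3))
mask, fov = synth.rasterize_tree(tree, canvas=(256, 256))
print(len(tree.segments))                       # 508
print(quantify.box_counting_fd(mask, fov).fd)   # 1.528
print(quantify.vascular_density(mask, fov)[1])  # 0.183

# analytic anchors for the FD estimator
line = np.zeros((256, 256), bool); line[128, :] = True
print(quantify.box_counting_fd(line).fd)                      # 1.0
print(quantify.box_counting_fd(synth.make_fov((256,256))).fd) # 1.905
```

A line measures 1.0, a filled disc 1.905 (≈ 2), and the 6-generation tree
sits in between at 1.53 — denser branching pushes FD up, which is exactly
the property the downstream analyses rely on.

```python
from microvasc import benchmarks
out = benchmarks.mr_recovery(seed=1)
print(out["mr_estimate"], out["mr_se"])   # 0.2990 0.0230
print(out["naive_estimate"])              # 0.6066
```

Here the simulator plants a causal effect of 0.30 between a genetically
influenced exposure and an outcome, plus a shared confounder. Naive
regression reads 0.61 — badly biased — while the 2SLS-via-PRS estimate
recovers 0.299 ± 0.023. That is the entire argument for Mendelian
randomization in one run.

The full pipeline is also available from the shell:

```bash
microvasc show-config > config.yaml
microvasc run --config config.yaml
```

which writes images, QC flags, segmentations, per-participant metrics,
PheWAS/GWAS/PRS/MR outputs, and a run manifest with SHA-256 hashes (two
runs from one config are bit-identical).

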