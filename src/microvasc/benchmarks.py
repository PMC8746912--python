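"""End-to-end validation experiments at desk scale.

Each function sets up a self-contained experiment on simulated data —
analytic fractal-dimension fixtures, segmentation/QC recovery, statistical
calibration of the association and MR machinery, pipeline determinism —
and returns a flat dict of measured quantities.  These are the package's
standing benchmarks: the test suite asserts on their outputs and the
reproduction script serializes them.

All problem sizes here are fixed study conditions of the benchmark suite,
chosen once: they are large enough for the sampling error of each measured
quantity to sit well inside the tolerance being checked, and small enough
to run on a single CPU core in minutes.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from . import association as assoc
from . import cohort as co
from . import genetics as gen
from . import qc as qcmod
from . import quantify as qf
from . import segmentation as seg
from . import synth

__all__ = [
    "fd_analytic_fixtures",
    "fd_generation_monotonicity",
    "segmentation_recovery",
    "qc_separability",
    "phewas_null_calibration",
    "gwas_null_calibration",
    "cox_coverage",
    "mr_recovery",
    "mr_null_coverage",
    "pipeline_determinism",
]


def fd_analytic_fixtures() -> dict:
    """Box-counting FD on shapes with known dimension (line, disc, carpet)."""
    line = np.zeros((256, 256), dtype=bool)
    line[128, :] = True
    disc = synth.make_fov((256, 256))
    carpet = qf.sierpinski_carpet(5)
    return {
        "fd_line": qf.box_counting_fd(line).fd,
        "fd_disc": qf.box_counting_fd(disc).fd,
        "fd_sierpinski": qf.box_counting_fd(carpet).fd,
        "fd_sierpinski_expected": float(np.log(8) / np.log(3)),
    }


def fd_generation_monotonicity(seed: int = 0, generations=range(1, 9),
                               seeds_per_generation: int = 10) -> dict:
    """Ground-truth-mask FD should rise monotonically with branching depth."""
    rng = np.random.default_rng(seed)
    gens, fds = [], []
    for g in generations:
        for _ in range(seeds_per_generation):
            params = synth.TreeParams(generations=g, seed=int(rng.integers(0, 2**31 - 1)))
            mask, fov = synth.rasterize_tree(synth.generate_tree(params))
            gens.append(g)
            fds.append(qf.box_counting_fd(mask, fov).fd)
    rho = spearmanr(gens, fds).statistic
    return {"fd_generation_spearman": float(rho), "n_masks": len(fds)}


def segmentation_recovery(seed: int = 0, n_train: int = 200, n_test: int = 20,
                          canvas: int = 128) -> dict:
    """Train the default U-Net ensemble and measure held-out recovery.

    Reports mean Dice on held-out images and the Spearman correlation of
    FD and density computed from *predicted* masks against the same
    metrics from the ground-truth masks.
    """
    recs = synth.simulate_image_dataset(n_train + n_test, frac_degraded=0.0,
                                        seed=seed, canvas=(canvas, canvas))
    train, test = recs[:n_train], recs[n_train:]
    cfg = seg.SegConfig(seed=seed + 1)
    ens = seg.train_segmentation_ensemble([r.image for r in train],
                                          [r.mask for r in train], cfg)
    dices, fd_true, fd_pred, den_true, den_pred = [], [], [], [], []
    for r in test:
        prob = seg.segment(ens, r.image)
        pred = seg.binarize(prob, cfg.threshold, r.fov)
        dices.append(seg.segmentation_metrics(prob, pred, r.mask, r.fov).dice)
        fd_true.append(qf.box_counting_fd(r.mask, r.fov).fd)
        fd_pred.append(qf.box_counting_fd(pred, r.fov).fd)
        den_true.append(qf.vascular_density(r.mask, r.fov)[1])
        den_pred.append(qf.vascular_density(pred, r.fov)[1])
    return {
        "seg_mean_dice": float(np.mean(dices)),
        "seg_fd_spearman": float(spearmanr(fd_true, fd_pred).statistic),
        "seg_density_spearman": float(spearmanr(den_true, den_pred).statistic),
        "n_train": n_train,
        "n_test": n_test,
    }


def qc_separability(seed: int = 0, n_train_per_class: int = 200,
                    n_test_per_class: int = 50, canvas: int = 128) -> dict:
    """Train the QC classifier and measure held-out sensitivity/specificity."""
    clean = synth.simulate_image_dataset(n_train_per_class + n_test_per_class, 0.0,
                                         seed=seed, canvas=(canvas, canvas))
    poor = synth.simulate_image_dataset(n_train_per_class + n_test_per_class, 1.0,
                                        seed=seed + 1, canvas=(canvas, canvas))
    train = clean[:n_train_per_class] + poor[:n_train_per_class]
    test = clean[n_train_per_class:] + poor[n_train_per_class:]
    model = qcmod.train_qc([r.image for r in train], [r.label for r in train],
                           seed=seed + 2)
    probs = qcmod.predict_qc_batch(model, [r.image for r in test])
    m = qcmod.evaluate_qc(probs, [r.label for r in test], model.config.threshold)
    return {"qc_sensitivity": m.sensitivity, "qc_specificity": m.specificity,
            "n_test": len(test)}


def phewas_null_calibration(seed: int = 0, n_outcomes: int = 100, n: int = 2000,
                            replicates: int = 5) -> dict:
    """Fraction of null binary outcomes reaching p < 0.05 in the PheWAS scan."""
    hits = total = 0
    for rep in range(replicates):
        cov = co.simulate_covariates(n, seed=seed + rep)
        rng = np.random.default_rng(seed + 1000 + rep)
        expo = rng.normal(size=n)
        panel = {}
        for i in range(n_outcomes):
            spec = co.OutcomeSpec("prevalent-binary", effect=0.0, baseline=0.15,
                                  seed=seed + 10_000 + rep * n_outcomes + i)
            panel[f"null_{i:03d}"] = ("prevalent", co.simulate_outcomes(expo, cov, spec))
        df = assoc.phewas_scan(pd.DataFrame({"x": expo}), panel, cov).frame()
        hits += int((df["p"] < 0.05).sum())
        total += len(df)
    return {"phewas_null_p05_fraction": hits / total, "n_tests": total}


def gwas_null_calibration(seed: int = 0, m: int = 10_000, n: int = 1000) -> dict:
    """Fraction of null variants reaching p < 0.05 in the GWAS scan."""
    gt = co.simulate_genotypes(n, m, seed=seed)
    cov = co.simulate_covariates(n, seed=seed + 1)
    trait, _ = co.simulate_trait(gt, cov, co.TraitArchitecture(), seed=seed + 2)
    df = gen.gwas_scan(gt, trait, cov).frame()
    return {"gwas_null_p05_fraction": float((df["p"] < 0.05).mean()),
            "n_variants": len(df)}


def cox_coverage(seed: int = 0, replicates: int = 500, n: int = 5000,
                 hr: float = 1.5) -> dict:
    """95% CI coverage of a planted hazard ratio across replicates."""
    log_hr = np.log(hr)
    rng = np.random.default_rng(seed)
    covered = 0
    for rep in range(replicates):
        x = rng.normal(size=n)
        spec = co.OutcomeSpec("incident-survival", effect=log_hr, baseline=0.05,
                              censoring=0.3, seed=int(rng.integers(0, 2**31 - 1)))
        out = co.simulate_outcomes(x, None, spec)
        res = assoc.fit_association(x, out, None, "cox")
        lo, hi = res.ci95
        covered += int(lo <= log_hr <= hi)
    return {"cox_coverage": covered / replicates, "replicates": replicates, "n": n}


def _mr_world(n: int, causal_effect: float, seed: int):
    """Genotype -> exposure -> outcome chain with planted confounding."""
    gt = co.simulate_genotypes(n, 40, maf_range=(0.1, 0.5), seed=seed)
    cov = co.simulate_covariates(n, seed=seed + 1)
    rng = np.random.default_rng(seed + 2)
    confounder = rng.normal(size=n)
    causal = {f"rs{j:06d}": 0.22 for j in range(30)}
    arch = co.TraitArchitecture(causal_effects=causal, confounder_loading=0.8)
    expo, _ = co.simulate_trait(gt, cov, arch, seed=seed + 3, confounder=confounder)
    spec = co.OutcomeSpec("quantitative", effect=causal_effect,
                          confounder_loading=0.6, seed=seed + 4)
    out = co.simulate_outcomes(expo, cov, spec, confounder=confounder)
    score = gen.build_prs(gt, gen.PrsModel(list(causal), np.full(30, 0.22)))
    return cov, expo, out["value"].to_numpy(), score, confounder


def mr_recovery(seed: int = 0, n: int = 10_000, causal_effect: float = 0.3) -> dict:
    """2SLS recovery of a confounded causal slope, vs naive regression."""
    import statsmodels.api as sm

    cov, expo, y, score, confounder = _mr_world(n, causal_effect, seed)
    est = gen.one_sample_mr(score, expo, y, cov)
    naive = float(sm.OLS(y, sm.add_constant(expo)).fit().params[1])
    planted_bias = float(0.6 * np.cov(expo, confounder)[0, 1] / np.var(expo))
    return {
        "mr_estimate": est.effect,
        "mr_se": est.se,
        "mr_first_stage_f": est.first_stage_f,
        "mr_true_effect": causal_effect,
        "naive_estimate": naive,
        "naive_expected_bias": planted_bias,
        "n": n,
    }


def mr_null_coverage(seed: int = 0, replicates: int = 500, n: int = 2000) -> dict:
    """95% CI coverage of a zero causal effect under active confounding."""
    covered = 0
    for rep in range(replicates):
        cov, expo, y, score, _ = _mr_world(n, 0.0, seed + 17 * rep)
        est = gen.one_sample_mr(score, expo, y, cov)
        lo, hi = est.ci95
        covered += int(lo <= 0.0 <= hi)
    return {"mr_null_coverage": covered / replicates, "replicates": replicates, "n": n}


def pipeline_determinism(seed: int = 0, tmp_dir=None) -> dict:
    """Run the demo pipeline twice from one config; compare output hashes."""
    import tempfile
    from pathlib import Path

    from .pipeline import RunConfig, run_pipeline

    base = Path(tmp_dir) if tmp_dir else Path(tempfile.mkdtemp(prefix="microvasc_det_"))
    stages = {
        "images": {"n_images": 12},
        "qc": {"n_train_per_class": 24, "epochs": 3},
        "segment": {"n_train": 24, "ensemble_size": 2, "epochs": 2},
        "cohort": {"n": 1000, "m_variants": 200},
        "phewas": {"n_null_outcomes": 5},
    }
    hashes = []
    for tag in ("a", "b"):
        cfg = RunConfig.from_dict({"seed": seed, "out_dir": str(base / tag),
                                   "stages": stages})
        manifest = run_pipeline(cfg)
        hashes.append({s: v["outputs"] for s, v in manifest.stages.items()})
    return {"pipeline_identical_hashes": float(hashes[0] == hashes[1]),
            "n_stages": len(hashes[0])}
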