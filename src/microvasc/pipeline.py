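"""End-to-end pipeline: simulate -> QC -> segment -> quantify -> associate.

A single YAML config drives every stage; the global seed deterministically
derives per-stage seeds, so an identical config reproduces bit-identical
outputs (verified via the SHA-256 hashes recorded in the run manifest).
Images rejected by quality control are excluded from segmentation and
quantification, mirroring the filter-then-analyze order of a fundus
pipeline; the QC removal fraction is logged.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import association as assoc
from . import cohort as co
from . import genetics as gen
from . import qc as qcmod
from . import quantify as qf
from . import segmentation as seg
from . import synth

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "RunManifest", "run_pipeline", "default_config"]

STAGES = ("images", "qc", "segment", "quantify", "cohort", "phewas", "gwas", "prs", "mr")


@dataclass
class RunConfig:
    """Schema-checked pipeline configuration (see ``default_config``)."""

    seed: int = 0
    out_dir: str = "microvasc_run"
    stages: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        known_top = {"seed", "out_dir", "stages"}
        extra = set(raw) - known_top
        if extra:
            raise ValueError(f"unknown config keys: {sorted(extra)}")
        stages = raw.get("stages", {})
        bad = set(stages) - set(STAGES)
        if bad:
            raise ValueError(f"unknown stages: {sorted(bad)}")
        defaults = default_config()["stages"]
        merged = {}
        for name in STAGES:
            block = dict(defaults[name])
            user = stages.get(name, {})
            unknown = set(user) - set(block)
            if unknown:
                raise ValueError(f"unknown keys in stage {name!r}: {sorted(unknown)}")
            block.update(user)
            merged[name] = block
        return cls(seed=int(raw.get("seed", 0)), out_dir=str(raw.get("out_dir", "microvasc_run")),
                   stages=merged)

    def stage_seed(self, name: str) -> int:
        return (self.seed * 1009 + STAGES.index(name) * 7919 + 17) % (2**31 - 1)


def default_config() -> dict:
    return {
        "seed": 0,
        "out_dir": "microvasc_run",
        "stages": {
            "images": {"enabled": True, "n_images": 30, "canvas": 128, "frac_degraded": 0.3},
            "qc": {"enabled": True, "n_train_per_class": 60, "epochs": 6, "threshold": 0.5},
            "segment": {"enabled": True, "n_train": 60, "ensemble_size": 2, "epochs": 3},
            "quantify": {"enabled": True, "low_flag_sd": 2.0},
            "cohort": {"enabled": True, "n": 2000, "m_variants": 400, "n_causal": 8,
                       "heritability_effect": 0.3, "maf_min": 0.1, "maf_max": 0.5},
            "phewas": {"enabled": True, "n_null_outcomes": 10, "planted_log_or": 0.4,
                       "baseline_prevalence": 0.15},
            "gwas": {"enabled": True, "maf_floor": 0.001},
            "prs": {"enabled": True, "p_threshold": 5e-8},
            "mr": {"enabled": True, "causal_effect": 0.3, "confounding": 0.8,
                   "exposure_scale": 1.0},
        },
    }


@dataclass
class RunManifest:
    seed: int
    stages: dict = field(default_factory=dict)

    def record(self, stage: str, params: dict, inputs: list[str], outputs: list[Path],
               elapsed: float, **extra) -> None:
        self.stages[stage] = {
            "params": params,
            "inputs": inputs,
            "outputs": {str(p.name): _sha256(p) for p in outputs},
            "elapsed_s": round(elapsed, 3),
            **extra,
        }

    def write(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump({"seed": self.seed, "stages": self.stages}, fh, indent=2, sort_keys=True)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> RunManifest:
    """Execute enabled stages in dependency order; returns the run manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    st = config.stages
    # pre-flight dependency check, before any stage runs
    for name, deps in {"qc": ["images"], "segment": ["images"], "quantify": ["segment"],
                       "phewas": ["cohort"], "gwas": ["cohort"], "prs": ["gwas"],
                       "mr": ["prs"]}.items():
        if st[name]["enabled"]:
            for d in deps:
                if not st[d]["enabled"]:
                    raise ValueError(f"stage {name!r} requires stage {d!r} to be enabled")
    manifest = RunManifest(config.seed)

    records = kept = None
    if st["images"]["enabled"]:
        t0 = time.time()
        blk = st["images"]
        records = synth.simulate_image_dataset(
            blk["n_images"], frac_degraded=blk["frac_degraded"],
            seed=config.stage_seed("images"), canvas=(blk["canvas"], blk["canvas"]))
        img_dir = out / "images"
        mpath = synth.write_image_dataset(records, img_dir)
        outputs = sorted(img_dir.glob("*.png")) + [mpath]
        manifest.record("images", blk, [], outputs, time.time() - t0,
                        n_images=len(records))
        logger.info("images: %d written", len(records))

    if st["qc"]["enabled"]:
        t0 = time.time()
        blk = st["qc"]
        sd = config.stage_seed("qc")
        clean = synth.simulate_image_dataset(blk["n_train_per_class"], 0.0, seed=sd,
                                             canvas=records[0].mask.shape)
        poor = synth.simulate_image_dataset(blk["n_train_per_class"], 1.0, seed=sd + 1,
                                            canvas=records[0].mask.shape)
        model = qcmod.train_qc([r.image for r in clean + poor],
                               [r.label for r in clean + poor],
                               qcmod.QcConfig(epochs=blk["epochs"]), seed=sd + 2)
        probs = qcmod.predict_qc_batch(model, [r.image for r in records])
        keep_flags = probs < blk["threshold"]
        qc_tsv = out / "qc.tsv"
        pd.DataFrame({
            "image": [f"img_{i:05d}.png" for i in range(len(records))],
            "poor_probability": probs,
            "keep": keep_flags.astype(int),
        }).to_csv(qc_tsv, sep="\t", index=False)
        kept = [r for r, k in zip(records, keep_flags) if k]
        removed_frac = 1.0 - len(kept) / len(records)
        manifest.record("qc", blk, ["images/manifest.tsv"], [qc_tsv], time.time() - t0,
                        removed_fraction=round(removed_frac, 4))
        logger.info("qc: removed %.1f%% of images", 100 * removed_frac)
    elif records is not None:
        kept = list(records)

    ensemble = None
    if st["segment"]["enabled"]:
        t0 = time.time()
        blk = st["segment"]
        sd = config.stage_seed("segment")
        train = synth.simulate_image_dataset(blk["n_train"], 0.0, seed=sd,
                                             canvas=records[0].mask.shape)
        cfg = seg.SegConfig(ensemble_size=blk["ensemble_size"], epochs=blk["epochs"], seed=sd)
        ensemble = seg.train_segmentation_ensemble([r.image for r in train],
                                                   [r.mask for r in train], cfg)
        seg_dir = out / "segmentations"
        seg_dir.mkdir(exist_ok=True)
        rows = []
        outputs = []
        for i, rec in enumerate(kept):
            prob = seg.segment(ensemble, rec.image)
            pred = seg.binarize(prob, cfg.threshold, rec.fov)
            m = seg.segmentation_metrics(prob, pred, rec.mask, rec.fov)
            import imageio.v3 as iio

            ppath = seg_dir / f"prob_{i:05d}.png"
            bpath = seg_dir / f"pred_{i:05d}.png"
            iio.imwrite(ppath, (prob * 65535).round().astype(np.uint16))
            iio.imwrite(bpath, pred.astype(np.uint8) * 255)
            outputs += [ppath, bpath]
            rows.append({"index": i, "participant_id": rec.image.participant_id,
                         "eye": rec.image.eye, "dice": m.dice,
                         "pixel_accuracy": m.pixel_accuracy, "auc": m.auc})
        met_tsv = out / "segmentation_metrics.tsv"
        pd.DataFrame(rows).to_csv(met_tsv, sep="\t", index=False)
        outputs.append(met_tsv)
        manifest.record("segment", blk, ["images/manifest.tsv", "qc.tsv"], outputs,
                        time.time() - t0, n_segmented=len(kept))

    if st["quantify"]["enabled"]:
        t0 = time.time()
        blk = st["quantify"]
        rows = []
        for i, rec in enumerate(kept):
            prob = seg.segment(ensemble, rec.image)
            pred = seg.binarize(prob, ensemble.config.threshold, rec.fov)
            count, frac = qf.vascular_density(pred, rec.fov)
            fd = qf.box_counting_fd(pred, rec.fov).fd if pred.any() else np.nan
            rows.append({"participant_id": rec.image.participant_id, "eye": rec.image.eye,
                         "fd": fd, "density": frac, "vessel_pixels": count,
                         "fov_pixels": int(rec.fov.sum())})
        eye_tsv = out / "per_eye_metrics.tsv"
        per_eye = pd.DataFrame(rows).dropna()
        per_eye = per_eye.drop_duplicates(subset=["participant_id", "eye"], keep="first")
        per_eye.to_csv(eye_tsv, sep="\t", index=False)
        try:
            part = qf.participant_metrics(per_eye, k=blk["low_flag_sd"])
        except ValueError:
            # too few usable participants for cohort standardization
            part = qf.aggregate_eyes(per_eye) if len(per_eye) else pd.DataFrame(
                columns=["participant_id", "fd_mean", "density_mean", "n_eyes"])
            logger.warning("quantify: %d participants, skipping z-scores", len(part))
        part_tsv = out / "participant_metrics.tsv"
        part.to_csv(part_tsv, sep="\t", index=False)
        manifest.record("quantify", blk, ["segmentations"], [eye_tsv, part_tsv],
                        time.time() - t0, n_participants=len(part))

    gt = cov = trait = confounder = None
    if st["cohort"]["enabled"]:
        t0 = time.time()
        blk = st["cohort"]
        sd = config.stage_seed("cohort")
        gt = co.simulate_genotypes(blk["n"], blk["m_variants"],
                                   (blk["maf_min"], blk["maf_max"]), seed=sd)
        cov = co.simulate_covariates(blk["n"], seed=sd + 1)
        rng = np.random.default_rng(sd + 2)
        confounder = rng.normal(size=blk["n"])
        causal = {f"rs{j:06d}": blk["heritability_effect"] for j in range(blk["n_causal"])}
        arch = co.TraitArchitecture(causal_effects=causal,
                                    confounder_loading=st["mr"]["confounding"],
                                    covariate_effects={"age": -0.15})
        trait, truth = co.simulate_trait(gt, cov, arch, seed=sd + 3, confounder=confounder)
        geno_tsv = out / "genotypes.tsv"
        gt.to_tsv(geno_tsv)
        cov_tsv = out / "covariates.tsv"
        cov.to_csv(cov_tsv, sep="\t", index=False)
        trait_tsv = out / "exposure.tsv"
        pd.DataFrame({"participant_id": cov["participant_id"], "exposure": trait}).to_csv(
            trait_tsv, sep="\t", index=False)
        truth_json = out / "cohort_truth.json"
        with open(truth_json, "w") as fh:
            json.dump(truth, fh, indent=2, sort_keys=True)
        manifest.record("cohort", blk, [], [geno_tsv, cov_tsv, trait_tsv, truth_json],
                        time.time() - t0)

    if st["phewas"]["enabled"]:
        t0 = time.time()
        blk = st["phewas"]
        sd = config.stage_seed("phewas")
        panel = {}
        for i in range(blk["n_null_outcomes"]):
            spec = co.OutcomeSpec("prevalent-binary", effect=0.0,
                                  baseline=blk["baseline_prevalence"], seed=sd + i)
            panel[f"null_{i:03d}"] = ("prevalent", co.simulate_outcomes(trait, cov, spec))
        spec = co.OutcomeSpec("prevalent-binary", effect=blk["planted_log_or"],
                              baseline=blk["baseline_prevalence"], seed=sd + 999)
        panel["planted"] = ("prevalent", co.simulate_outcomes(trait, cov, spec))
        res = assoc.phewas_scan(pd.DataFrame({"exposure": trait}), panel, cov)
        ph_tsv = out / "phewas_results.tsv"
        res.frame().to_csv(ph_tsv, sep="\t", index=False)
        manifest.record("phewas", blk, ["exposure.tsv", "covariates.tsv"], [ph_tsv],
                        time.time() - t0)

    gwas_res = None
    if st["gwas"]["enabled"]:
        t0 = time.time()
        blk = st["gwas"]
        gwas_res = gen.gwas_scan(gt, trait, cov, maf_min=blk["maf_floor"])
        gw_tsv = out / "gwas_sumstats.tsv"
        gwas_res.frame().to_csv(gw_tsv, sep="\t", index=False)
        manifest.record("gwas", blk, ["genotypes.tsv", "exposure.tsv", "covariates.tsv"],
                        [gw_tsv], time.time() - t0, n_variants=len(gwas_res.rows))

    prs_model = score = None
    if st["prs"]["enabled"]:
        t0 = time.time()
        blk = st["prs"]
        prs_model = gen.select_significant(gwas_res, blk["p_threshold"])
        prs_tsv = out / "prs_model.tsv"
        prs_model.to_tsv(prs_tsv)
        score = gen.build_prs(gt, prs_model)
        score_tsv = out / "prs_scores.tsv"
        pd.DataFrame({"participant_id": cov["participant_id"], "score": score}).to_csv(
            score_tsv, sep="\t", index=False)
        manifest.record("prs", blk, ["gwas_sumstats.tsv", "genotypes.tsv"],
                        [prs_tsv, score_tsv], time.time() - t0,
                        n_variants=len(prs_model.variant_ids))

    if st["mr"]["enabled"]:
        t0 = time.time()
        blk = st["mr"]
        sd = config.stage_seed("mr")
        spec = co.OutcomeSpec("quantitative", effect=blk["causal_effect"], baseline=0.0,
                              confounder_loading=blk["confounding"], seed=sd)
        mr_out = co.simulate_outcomes(trait, cov, spec, confounder=confounder)
        if score is None or np.std(score) == 0:
            est = None
            logger.warning("mr: empty or degenerate PRS; skipping estimate")
            mr_json = out / "mr_estimate.json"
            with open(mr_json, "w") as fh:
                json.dump({"status": "degenerate instrument"}, fh)
        else:
            est = gen.one_sample_mr(score, trait, mr_out["value"].to_numpy(), cov,
                                    exposure_scale=blk["exposure_scale"])
            mr_json = out / "mr_estimate.json"
            with open(mr_json, "w") as fh:
                json.dump({"effect": est.effect, "se": est.se, "p": est.p,
                           "first_stage_f": est.first_stage_f, "n": est.n,
                           "true_effect": blk["causal_effect"]}, fh, indent=2, sort_keys=True)
        manifest.record("mr", blk, ["prs_scores.tsv", "exposure.tsv", "covariates.tsv"],
                        [mr_json], time.time() - t0)

    manifest.write(out / "run_manifest.json")
    return manifest
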