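"""Cohort simulation with known genetic and phenotypic effects.

Provides the ground truth for the association and genetics machinery:
independent Hardy–Weinberg genotypes, a quantitative exposure (the analogue
of a standardized retinal vascular metric) with chosen causal variants and
covariate structure, and prevalent/incident/quantitative outcomes generated
from that exposure with stated effect sizes.  Confounding is opt-in via a
latent variable loading on both exposure and outcome, which is what lets
Mendelian randomization demonstrate its advantage over naive regression.

Incident event times are exponential (constant hazard), so proportional
hazards holds exactly; censoring times are independent exponentials scaled
so each subject is censored with exactly the stated probability.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "GenotypeMatrix",
    "TraitArchitecture",
    "OutcomeSpec",
    "simulate_genotypes",
    "simulate_covariates",
    "simulate_trait",
    "simulate_outcomes",
]

SMOKING_LEVELS = ("never", "previous", "current")


@dataclass
class GenotypeMatrix:
    """n x m additive dosage matrix (0/1/2) with per-variant MAF."""

    dosages: np.ndarray  # (n, m) int8
    variant_ids: list[str]
    maf: np.ndarray  # (m,) generating MAF

    @property
    def n(self) -> int:
        return self.dosages.shape[0]

    @property
    def m(self) -> int:
        return self.dosages.shape[1]

    def empirical_maf(self) -> np.ndarray:
        f = self.dosages.mean(axis=0) / 2.0
        return np.minimum(f, 1.0 - f)

    def to_tsv(self, path) -> None:
        """Variants x participants dosage TSV."""
        df = pd.DataFrame(self.dosages.T, index=self.variant_ids)
        df.index.name = "variant_id"
        df.columns = [f"P{i:06d}" for i in range(self.n)]
        df.to_csv(path, sep="\t")

    def write_vcf(self, path) -> None:
        """Minimal unphased diploid GT-only VCF (synthetic positions)."""
        with open(path, "w") as fh:
            fh.write("##fileformat=VCFv4.2\n")
            fh.write("##source=microvasc-simulated\n")
            fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
            samples = "\t".join(f"P{i:06d}" for i in range(self.n))
            fh.write(f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{samples}\n")
            gt_map = {0: "0/0", 1: "0/1", 2: "1/1"}
            for j, vid in enumerate(self.variant_ids):
                gts = "\t".join(gt_map[int(d)] for d in self.dosages[:, j])
                fh.write(f"1\t{j + 1}\t{vid}\tA\tG\t.\tPASS\t.\tGT\t{gts}\n")


@dataclass(frozen=True)
class TraitArchitecture:
    """Generative model of a quantitative trait.

    causal_effects: variant id -> per-allele effect (in residual-SD units,
        before final standardization)
    residual_sd: SD of the independent noise term
    confounder_loading: weight of the shared latent confounder on the trait
    covariate_effects: column name -> linear effect (age, age2, sex,
        smoking_ever, ...)
    """

    causal_effects: dict = field(default_factory=dict)
    residual_sd: float = 1.0
    confounder_loading: float = 0.0
    covariate_effects: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.residual_sd <= 0:
            raise ValueError("residual_sd must be positive")


@dataclass(frozen=True)
class OutcomeSpec:
    """One simulated outcome.

    kind: 'prevalent-binary' | 'incident-survival' | 'quantitative'
    effect: true effect per 1-SD exposure (log OR, log HR, or beta)
    baseline: baseline prevalence (binary), baseline hazard rate per unit
        time (survival), or intercept (quantitative)
    censoring: Bernoulli censoring rate for survival outcomes
    confounder_loading: weight of the shared latent confounder
    seed: outcome-level RNG seed
    """

    kind: str
    effect: float = 0.0
    baseline: float = 0.1
    censoring: float = 0.3
    confounder_loading: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("prevalent-binary", "incident-survival", "quantitative"):
            raise ValueError(f"unknown outcome kind: {self.kind!r}")
        if self.kind == "prevalent-binary" and not (0.0 < self.baseline < 1.0):
            raise ValueError("baseline prevalence must be in (0, 1)")
        if not (0.0 <= self.censoring < 1.0):
            raise ValueError("censoring rate must be in [0, 1)")


def simulate_genotypes(n: int, m: int, maf_range: tuple[float, float] = (0.05, 0.5),
                       seed: int = 0) -> GenotypeMatrix:
    """Independent HWE dosages: dosage_ij ~ Binomial(2, maf_j)."""
    if n < 1 or m < 1:
        raise ValueError("n and m must be >= 1")
    lo, hi = maf_range
    if not (0.0 < lo <= hi <= 0.5):
        raise ValueError("maf_range must lie within (0, 0.5]")
    rng = np.random.default_rng(seed)
    maf = rng.uniform(lo, hi, size=m)
    dosages = rng.binomial(2, maf[None, :], size=(n, m)).astype(np.int8)
    ids = [f"rs{j:06d}" for j in range(m)]
    return GenotypeMatrix(dosages, ids, maf)


def simulate_covariates(n: int, seed: int = 0, n_pcs: int = 10) -> pd.DataFrame:
    """Covariate table: age, age^2, sex, smoking, ancestry PCs, array.

    Age ~ N(56, 8) years, 55% female, 44% ever-smokers — the demographic
    profile of a middle-aged population imaging cohort.
    """
    rng = np.random.default_rng(seed)
    age = rng.normal(56.0, 8.0, size=n).clip(40, 72)
    sex = (rng.uniform(size=n) < 0.55).astype(int)  # 1 = female
    smoking = rng.choice(SMOKING_LEVELS, size=n, p=[0.56, 0.33, 0.11])
    df = pd.DataFrame(
        {
            "participant_id": [f"P{i:06d}" for i in range(n)],
            "age": age,
            "age2": age**2,
            "sex": sex,
            "smoking": pd.Categorical(smoking, categories=SMOKING_LEVELS),
            "smoking_ever": (smoking != "never").astype(int),
            "array": (rng.uniform(size=n) < 0.9).astype(int),
        }
    )
    for k in range(1, n_pcs + 1):
        df[f"pc{k}"] = rng.normal(size=n)
    return df


def simulate_trait(
    genotypes: GenotypeMatrix,
    covariates: pd.DataFrame,
    arch: TraitArchitecture,
    seed: int = 0,
    confounder: np.ndarray | None = None,
):
    """Quantitative trait from genetics + covariates + confounder + noise.

    Returns ``(trait, truth)`` where ``trait`` is standardized to mean 0,
    SD 1 and ``truth`` records everything needed to regenerate it.
    """
    unknown = set(arch.causal_effects) - set(genotypes.variant_ids)
    if unknown:
        raise ValueError(f"causal variants not in genotype matrix: {sorted(unknown)}")
    rng = np.random.default_rng(seed)
    n = genotypes.n
    y = np.zeros(n)
    idx = {v: j for j, v in enumerate(genotypes.variant_ids)}
    for vid, beta in arch.causal_effects.items():
        d = genotypes.dosages[:, idx[vid]].astype(float)
        y += beta * (d - d.mean())
    for col, beta in arch.covariate_effects.items():
        x = covariates[col].to_numpy(dtype=float)
        y += beta * (x - x.mean()) / (x.std() if x.std() > 0 else 1.0)
    if arch.confounder_loading != 0.0:
        if confounder is None:
            confounder = rng.normal(size=n)
        y += arch.confounder_loading * confounder
    y += rng.normal(0.0, arch.residual_sd, size=n)
    scale = y.std()
    mean = y.mean()
    trait = (y - mean) / scale
    truth = {
        "causal_effects": dict(arch.causal_effects),
        "covariate_effects": dict(arch.covariate_effects),
        "confounder_loading": arch.confounder_loading,
        "residual_sd": arch.residual_sd,
        "seed": seed,
        "standardize_mean": float(mean),
        "standardize_scale": float(scale),
    }
    return trait, truth


def simulate_outcomes(
    exposure: np.ndarray,
    covariates: pd.DataFrame | None,
    spec: OutcomeSpec,
    confounder: np.ndarray | None = None,
) -> pd.DataFrame:
    """Generate one outcome column (plus time/event for survival).

    The exposure must be standardized; the generative direction is strictly
    exposure -> outcome (plus optional shared confounder), so causal truth
    is well defined.
    """
    x = np.asarray(exposure, dtype=float)
    n = x.size
    rng = np.random.default_rng(spec.seed)
    conf = np.zeros(n)
    if spec.confounder_loading != 0.0:
        if confounder is None:
            raise ValueError("confounder_loading set but no confounder supplied")
        conf = spec.confounder_loading * np.asarray(confounder, dtype=float)

    if spec.kind == "prevalent-binary":
        eta = np.log(spec.baseline / (1 - spec.baseline)) + spec.effect * x + conf
        p = 1.0 / (1.0 + np.exp(-eta))
        case = rng.uniform(size=n) < p
        return pd.DataFrame({"case": case.astype(int)})
    if spec.kind == "incident-survival":
        hazard = spec.baseline * np.exp(spec.effect * x + conf)
        t_event = rng.exponential(1.0 / hazard)
        if spec.censoring > 0:
            # independent exponential censoring at rate h_i * c/(1-c): each
            # subject is censored with probability exactly c, regardless of
            # their hazard, and censoring is conditionally independent of the
            # event time (so Cox partial likelihood stays unbiased)
            c_rate = hazard * spec.censoring / (1.0 - spec.censoring)
            t_cens = rng.exponential(1.0 / c_rate)
        else:
            t_cens = np.full(n, np.inf)
        event = t_event <= t_cens
        time = np.minimum(t_event, t_cens)
        return pd.DataFrame({"time": time, "event": event.astype(int)})
    # quantitative
    y = spec.baseline + spec.effect * x + conf + rng.normal(size=n)
    return pd.DataFrame({"value": y})
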