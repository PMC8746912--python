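"""Phenome-wide association machinery.

One exposure (a standardized microvascular metric such as fractal dimension
or vascular density, or a polygenic score) is tested against a panel of
outcomes: prevalent binary outcomes with logistic regression, incident
outcomes with Cox proportional hazards (time measured from image
acquisition; prevalent cases of the same outcome are excluded from the risk
set), and quantitative traits with linear regression.  All models adjust
for a covariate set (age, age squared, sex, smoking category by default)
and the scan-level p-values receive Benjamini–Hochberg FDR adjustment
within each exposure's scan.

Effects are reported per 1-SD *increase* of the exposure; the negated
per-1-SD-*decrease* effect is carried alongside, since risk associations
for these metrics are conventionally quoted per SD decrease.

Follows the statsmodels model/results idiom: build a :class:`PheWAS`,
call ``fit()``, get a :class:`PheWASResults` with a results frame and a
``summary()`` table.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from lifelines import CoxPHFitter
from scipy import stats
from statsmodels.stats.multitest import multipletests
from statsmodels.tools.sm_exceptions import PerfectSeparationError, PerfectSeparationWarning

logger = logging.getLogger(__name__)

__all__ = [
    "AssociationResult",
    "StratifiedResult",
    "PheWAS",
    "PheWASResults",
    "fit_association",
    "phewas_scan",
    "bh_fdr",
    "stratified_association",
]

DEFAULT_COVARIATES = ("age", "age2", "sex", "smoking")
MIN_CASES = 20


@dataclass
class AssociationResult:
    """One exposure-outcome fit."""

    outcome_id: str
    kind: str  # 'logistic' | 'cox' | 'linear'
    effect: float  # log OR / log HR / beta per 1-SD increase (or per flag)
    se: float
    p: float
    n: int
    events: int | None = None
    fdr_q: float | None = None
    converged: bool = True
    flag: str = ""

    @property
    def effect_per_sd_decrease(self) -> float:
        return -self.effect

    @property
    def ci95(self) -> tuple[float, float]:
        return self.effect - 1.96 * self.se, self.effect + 1.96 * self.se


@dataclass
class StratifiedResult:
    strata: dict  # label -> AssociationResult
    cochran_q: float
    heterogeneity_p: float
    df: int
    partial: bool = False


def covariate_design(covariates: pd.DataFrame, cols=DEFAULT_COVARIATES) -> pd.DataFrame:
    """Numeric design block; categorical columns are dummy-expanded."""
    parts = []
    for col in cols:
        s = covariates[col]
        if isinstance(s.dtype, pd.CategoricalDtype) or s.dtype == object:
            dummies = pd.get_dummies(s, prefix=col, drop_first=True, dtype=float)
            parts.append(dummies)
        else:
            parts.append(s.astype(float).to_frame(col))
    return pd.concat(parts, axis=1) if parts else pd.DataFrame(index=covariates.index)


def fit_association(
    exposure: np.ndarray,
    outcome: pd.DataFrame,
    covariates: pd.DataFrame | None,
    kind: str,
    covariate_cols=DEFAULT_COVARIATES,
    outcome_id: str = "outcome",
) -> AssociationResult:
    """Fit one covariate-adjusted association.

    ``outcome`` columns by kind: logistic -> ``case``; cox -> ``time`` and
    ``event``; linear -> ``value``.  Non-convergence and complete
    separation produce a flagged result rather than a silent NaN.
    """
    if kind not in ("logistic", "cox", "linear"):
        raise ValueError(f"unknown model kind: {kind!r}")
    x = np.asarray(exposure, dtype=float)
    n = x.size
    if covariates is not None:
        cdes = covariate_design(covariates.reset_index(drop=True), covariate_cols)
    else:
        cdes = pd.DataFrame(index=pd.RangeIndex(n))
    df = pd.concat([pd.DataFrame({"exposure": x}), cdes.reset_index(drop=True),
                    outcome.reset_index(drop=True)], axis=1)
    df = df.dropna()
    n_params = df.shape[1] - (2 if kind == "cox" else 1)
    if df.shape[0] < 10 * max(n_params, 1):
        raise ValueError(f"too few complete cases ({df.shape[0]}) for {n_params} parameters")

    if kind == "logistic":
        return _fit_logistic(df, outcome_id)
    if kind == "cox":
        return _fit_cox(df, outcome_id)
    return _fit_linear(df, outcome_id)


def _fit_logistic(df: pd.DataFrame, outcome_id: str) -> AssociationResult:
    y = df.pop("case").to_numpy(dtype=float)
    X = sm.add_constant(df.to_numpy(dtype=float))
    events = int(y.sum())
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error", PerfectSeparationWarning)
            res = sm.Logit(y, X).fit(disp=0, maxiter=100)
        conv = bool(res.mle_retvals.get("converged", True))
        return AssociationResult(outcome_id, "logistic", float(res.params[1]),
                                 float(res.bse[1]), float(res.pvalues[1]), len(y),
                                 events=events, converged=conv,
                                 flag="" if conv else "non-convergence")
    except (PerfectSeparationError, PerfectSeparationWarning, np.linalg.LinAlgError) as exc:
        return AssociationResult(outcome_id, "logistic", np.nan, np.nan, np.nan, len(y),
                                 events=events, converged=False, flag=f"separation: {exc}")


def _fit_cox(df: pd.DataFrame, outcome_id: str) -> AssociationResult:
    events = int(df["event"].sum())
    try:
        cph = CoxPHFitter()
        cph.fit(df, duration_col="time", event_col="event")
        return AssociationResult(outcome_id, "cox", float(cph.params_["exposure"]),
                                 float(cph.standard_errors_["exposure"]),
                                 float(cph.summary.loc["exposure", "p"]),
                                 df.shape[0], events=events)
    except Exception as exc:  # lifelines raises ConvergenceError and others
        return AssociationResult(outcome_id, "cox", np.nan, np.nan, np.nan, df.shape[0],
                                 events=events, converged=False, flag=str(exc))


def _fit_linear(df: pd.DataFrame, outcome_id: str) -> AssociationResult:
    y = df.pop("value").to_numpy(dtype=float)
    X = sm.add_constant(df.to_numpy(dtype=float))
    res = sm.OLS(y, X).fit()
    return AssociationResult(outcome_id, "linear", float(res.params[1]), float(res.bse[1]),
                             float(res.pvalues[1]), len(y))


def bh_fdr(p: np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (order preserving)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


class PheWAS:
    """Phenome-wide scan of one or more exposures against an outcome panel.

    Parameters
    ----------
    exposures : DataFrame
        One column per exposure (standardized).
    panel : dict
        outcome id -> ``(kind, outcome DataFrame)`` with kind in
        {'prevalent', 'incident', 'quantitative'}.  Incident outcome frames
        may carry a boolean ``prevalent`` column; those participants are
        excluded from that outcome's risk set.
    covariates : DataFrame or None
    min_cases : int
        Binary/survival outcomes with fewer cases/events are skipped (with
        a log entry).
    """

    KIND_MODEL = {"prevalent": "logistic", "incident": "cox", "quantitative": "linear"}

    def __init__(self, exposures: pd.DataFrame, panel: dict, covariates: pd.DataFrame | None,
                 covariate_cols=DEFAULT_COVARIATES, min_cases: int = MIN_CASES):
        self.exposures = exposures
        self.panel = panel
        self.covariates = covariates
        self.covariate_cols = covariate_cols
        self.min_cases = min_cases

    def fit(self) -> "PheWASResults":
        results: list[AssociationResult] = []
        skipped: list[str] = []
        for exp_name in self.exposures.columns:
            x = self.exposures[exp_name].to_numpy(dtype=float)
            per_class: dict[str, list[AssociationResult]] = {}
            for oid, (kind, odf) in self.panel.items():
                if kind not in self.KIND_MODEL:
                    raise ValueError(f"unknown outcome class {kind!r} for {oid}")
                model = self.KIND_MODEL[kind]
                odf = odf.copy()
                keep = np.ones(len(odf), dtype=bool)
                if kind == "incident" and "prevalent" in odf.columns:
                    keep = ~odf.pop("prevalent").to_numpy(dtype=bool)
                n_cases = (int(odf.loc[keep, "case"].sum()) if model == "logistic"
                           else int(odf.loc[keep, "event"].sum()) if model == "cox" else None)
                if n_cases is not None and n_cases < self.min_cases:
                    logger.info("skipping %s (%s): %d cases < %d", oid, kind, n_cases, self.min_cases)
                    skipped.append(oid)
                    continue
                cov = self.covariates.loc[keep] if self.covariates is not None else None
                res = fit_association(x[keep], odf.loc[keep], cov, model,
                                      self.covariate_cols, outcome_id=oid)
                res.scan_exposure = exp_name  # type: ignore[attr-defined]
                res.scan_class = kind  # type: ignore[attr-defined]
                per_class.setdefault(kind, []).append(res)
            # BH within each exposure x analysis-class scan
            for rs in per_class.values():
                ok = [r for r in rs if np.isfinite(r.p)]
                if ok:
                    q = bh_fdr(np.array([r.p for r in ok]))
                    for r, qi in zip(ok, q):
                        r.fdr_q = float(qi)
                results.extend(rs)
        return PheWASResults(results, skipped)


@dataclass
class PheWASResults:
    results: list[AssociationResult]
    skipped: list[str] = field(default_factory=list)

    def frame(self) -> pd.DataFrame:
        rows = []
        for r in self.results:
            rows.append(
                {
                    "exposure": getattr(r, "scan_exposure", ""),
                    "outcome": r.outcome_id,
                    "class": getattr(r, "scan_class", ""),
                    "model": r.kind,
                    "effect_per_sd_increase": r.effect,
                    "effect_per_sd_decrease": r.effect_per_sd_decrease,
                    "se": r.se,
                    "p": r.p,
                    "fdr_q": r.fdr_q,
                    "n": r.n,
                    "events": r.events,
                    "converged": r.converged,
                    "flag": r.flag,
                }
            )
        return pd.DataFrame(rows)

    def summary(self) -> str:
        df = self.frame()
        lines = ["PheWAS scan results", "=" * 72,
                 f"{len(df)} fits, {len(self.skipped)} outcomes skipped (too few cases)"]
        with pd.option_context("display.width", 120, "display.max_rows", 40):
            lines.append(str(df.sort_values("p").head(20)))
        return "\n".join(lines)


def phewas_scan(exposures: pd.DataFrame, panel: dict, covariates: pd.DataFrame | None,
                covariate_cols=DEFAULT_COVARIATES, min_cases: int = MIN_CASES) -> PheWASResults:
    """Functional wrapper over :class:`PheWAS`."""
    return PheWAS(exposures, panel, covariates, covariate_cols, min_cases).fit()


def stratified_association(
    exposure: np.ndarray,
    outcome: pd.DataFrame,
    covariates: pd.DataFrame | None,
    strata: np.ndarray,
    kind: str = "cox",
    covariate_cols=DEFAULT_COVARIATES,
) -> StratifiedResult:
    """Per-stratum fits plus Cochran Q heterogeneity.

    Q = sum_i w_i (b_i - b_w)^2 with w_i = 1/SE_i^2; the heterogeneity p
    comes from a chi-square with (#strata - 1) degrees of freedom.
    """
    strata = np.asarray(strata)
    labels = pd.unique(strata)
    if len(labels) < 2:
        raise ValueError("need at least 2 strata")
    fits: dict = {}
    partial = False
    for lab in labels:
        m = strata == lab
        cov = covariates.loc[m] if covariates is not None else None
        try:
            res = fit_association(np.asarray(exposure)[m], outcome.loc[m], cov, kind,
                                  covariate_cols, outcome_id=str(lab))
        except ValueError as exc:
            res = AssociationResult(str(lab), kind, np.nan, np.nan, np.nan, int(m.sum()),
                                    converged=False, flag=str(exc))
        if not np.isfinite(res.effect) or not np.isfinite(res.se):
            partial = True
        fits[lab] = res
    good = [r for r in fits.values() if np.isfinite(r.effect) and np.isfinite(r.se) and r.se > 0]
    if len(good) >= 2:
        b = np.array([r.effect for r in good])
        w = np.array([1.0 / r.se**2 for r in good])
        b_w = np.sum(w * b) / np.sum(w)
        q = float(np.sum(w * (b - b_w) ** 2))
        dof = len(good) - 1
        het_p = float(stats.chi2.sf(q, dof))
    else:
        q, dof, het_p = np.nan, len(labels) - 1, np.nan
        partial = True
    return StratifiedResult(fits, q, het_p, dof, partial)
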