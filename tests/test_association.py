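"""PheWAS engine: model fits, FDR, stratified heterogeneity."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from microvasc.association import (
    PheWAS,
    bh_fdr,
    fit_association,
    phewas_scan,
    stratified_association,
)
from microvasc.cohort import OutcomeSpec, simulate_covariates, simulate_outcomes


def bh_oracle(p):
    """Step-up oracle straight from the definition: q_i = min_{j>=i} m p_(j)/j."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p)
    q_sorted = np.minimum.accumulate((m * p[order] / np.arange(1, m + 1))[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


class TestFitAssociation:
    def test_logistic_matches_closed_form_2x2(self):
        x = np.r_[np.ones(100), np.zeros(100)]
        case = np.r_[np.ones(40), np.zeros(60), np.ones(20), np.zeros(80)]
        res = fit_association(x, pd.DataFrame({"case": case}), None, "logistic")
        assert res.effect == pytest.approx(np.log((40 * 80) / (60 * 20)), abs=1e-4)
        assert np.exp(res.effect) == pytest.approx(2.667, abs=1e-3)

    def test_linear_noiseless(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=100)
        res = fit_association(x, pd.DataFrame({"value": 2.0 * x}), None, "linear")
        assert res.effect == pytest.approx(2.0, abs=1e-10)
        assert res.p < 1e-50

    def test_cox_recovers_planted_hazard_ratio(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=4000)
        out = simulate_outcomes(x, None, OutcomeSpec("incident-survival",
                                                     effect=np.log(1.5), baseline=0.05,
                                                     censoring=0.3, seed=2))
        res = fit_association(x, out, None, "cox")
        assert res.effect == pytest.approx(np.log(1.5), abs=3 * res.se)
        assert res.events == int(out["event"].sum())

    def test_effect_direction_convention(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=200)
        res = fit_association(x, pd.DataFrame({"value": x}), None, "linear")
        assert res.effect_per_sd_decrease == -res.effect

    def test_separation_flagged_not_nan_crash(self):
        x = np.r_[np.full(30, 2.0), np.full(30, -2.0)] + np.random.default_rng(4).normal(
            0, 0.01, 60)
        case = (x > 0).astype(int)
        res = fit_association(x, pd.DataFrame({"case": case}), None, "logistic")
        assert (not res.converged) or res.se > 10  # flagged, never a silent NaN p

    def test_too_few_rows_rejected(self):
        with pytest.raises(ValueError, match="complete cases"):
            fit_association(np.ones(5), pd.DataFrame({"value": np.ones(5)}), None, "linear")

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError):
            fit_association(np.ones(50), pd.DataFrame({"value": np.ones(50)}), None, "probit")


class TestBhFdr:
    def test_worked_example(self):
        np.testing.assert_allclose(bh_fdr([0.01, 0.02, 0.03, 0.04]), [0.04] * 4)

    def test_single_p(self):
        assert bh_fdr([0.03]) == pytest.approx([0.03])

    def test_matches_step_up_oracle(self):
        rng = np.random.default_rng(5)
        for _ in range(25):
            p = rng.uniform(1e-6, 1.0, size=rng.integers(1, 120))
            np.testing.assert_allclose(bh_fdr(p), bh_oracle(p), atol=1e-12)

    @given(st.lists(st.floats(min_value=1e-9, max_value=1.0), min_size=1, max_size=60))
    @settings(deadline=None, max_examples=50, derandomize=True)
    def test_oracle_property(self, ps):
        np.testing.assert_allclose(bh_fdr(ps), bh_oracle(ps), atol=1e-12)

    @pytest.mark.parametrize("bad", [[0.0, 0.5], [0.5, 1.0001], [np.nan, 0.5]])
    def test_out_of_range_rejected(self, bad):
        with pytest.raises(ValueError):
            bh_fdr(bad)


@pytest.fixture(scope="module")
def small_cohort():
    n = 1500
    cov = simulate_covariates(n, seed=6)
    rng = np.random.default_rng(7)
    expo = rng.normal(size=n)
    return cov, expo


class TestPheWAS:
    def test_fdr_column_equals_bh_of_p(self, small_cohort):
        cov, expo = small_cohort
        panel = {}
        for i in range(8):
            spec = OutcomeSpec("prevalent-binary", effect=0.0, baseline=0.2, seed=30 + i)
            panel[f"o{i}"] = ("prevalent", simulate_outcomes(expo, cov, spec))
        res = phewas_scan(pd.DataFrame({"x": expo}), panel, cov)
        df = res.frame()
        np.testing.assert_allclose(df["fdr_q"], bh_oracle(df["p"].to_numpy()), atol=1e-12)

    def test_planted_outcome_ranks_first(self, small_cohort):
        cov, expo = small_cohort
        panel = {}
        for i in range(6):
            spec = OutcomeSpec("prevalent-binary", effect=0.0, baseline=0.2, seed=40 + i)
            panel[f"null{i}"] = ("prevalent", simulate_outcomes(expo, cov, spec))
        spec = OutcomeSpec("prevalent-binary", effect=0.6, baseline=0.2, seed=49)
        panel["planted"] = ("prevalent", simulate_outcomes(expo, cov, spec))
        df = phewas_scan(pd.DataFrame({"x": expo}), panel, cov).frame()
        assert df.sort_values("p").iloc[0]["outcome"] == "planted"

    def test_sparse_outcome_skipped(self, small_cohort):
        cov, expo = small_cohort
        rare = pd.DataFrame({"case": np.r_[np.ones(5), np.zeros(len(expo) - 5)].astype(int)})
        res = phewas_scan(pd.DataFrame({"x": expo}), {"rare": ("prevalent", rare)}, cov)
        assert res.skipped == ["rare"] and len(res.results) == 0

    def test_incident_excludes_prevalent_cases(self, small_cohort):
        cov, expo = small_cohort
        n = len(expo)
        spec = OutcomeSpec("incident-survival", effect=0.0, baseline=0.1,
                           censoring=0.2, seed=50)
        odf = simulate_outcomes(expo, cov, spec)
        prevalent = np.zeros(n, bool)
        prevalent[:100] = True
        odf["prevalent"] = prevalent
        res = phewas_scan(pd.DataFrame({"x": expo}), {"surv": ("incident", odf)}, cov)
        assert res.results[0].n == n - 100

    def test_mixed_model_classes(self, small_cohort):
        cov, expo = small_cohort
        panel = {
            "bin": ("prevalent", simulate_outcomes(
                expo, cov, OutcomeSpec("prevalent-binary", 0.3, 0.2, seed=60))),
            "surv": ("incident", simulate_outcomes(
                expo, cov, OutcomeSpec("incident-survival", 0.3, 0.05, seed=61))),
            "quant": ("quantitative", simulate_outcomes(
                expo, cov, OutcomeSpec("quantitative", 0.3, seed=62))),
        }
        df = phewas_scan(pd.DataFrame({"x": expo}), panel, cov).frame()
        assert dict(zip(df["outcome"], df["model"])) == {
            "bin": "logistic", "surv": "cox", "quant": "linear"}
        assert (df["p"] < 0.05).all()  # strong planted effects

    def test_summary_renders(self, small_cohort):
        cov, expo = small_cohort
        panel = {"o": ("prevalent", simulate_outcomes(
            expo, cov, OutcomeSpec("prevalent-binary", 0.0, 0.2, seed=63)))}
        s = PheWAS(pd.DataFrame({"x": expo}), panel, cov).fit().summary()
        assert "PheWAS" in s and "1 fits" in s


class TestStratified:
    def test_single_stratum_rejected(self, small_cohort):
        cov, expo = small_cohort
        out = simulate_outcomes(expo, cov, OutcomeSpec("quantitative", 0.0, seed=70))
        with pytest.raises(ValueError, match="2 strata"):
            stratified_association(expo, out, cov, np.zeros(len(expo)), "linear")

    def test_identical_strata_low_heterogeneity(self, small_cohort):
        cov, expo = small_cohort
        out = simulate_outcomes(expo, cov, OutcomeSpec("quantitative", 0.3, seed=71))
        strata = np.arange(len(expo)) % 2
        res = stratified_association(expo, out, cov, strata, "linear")
        assert res.df == 1 and res.cochran_q >= 0
        assert res.heterogeneity_p > 0.01

    def test_divergent_strata_detected(self):
        n = 3000
        cov = simulate_covariates(n, seed=72)
        rng = np.random.default_rng(73)
        expo = rng.normal(size=n)
        strata = (np.arange(n) < n // 2).astype(int)
        eff = np.where(strata == 0, 0.0, 0.8)
        y = eff * expo + rng.normal(size=n)
        res = stratified_association(expo, pd.DataFrame({"value": y}), cov, strata, "linear")
        assert res.heterogeneity_p < 1e-4
        assert abs(res.strata[1].effect - res.strata[0].effect) > 0.5
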