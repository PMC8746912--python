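"""GWAS scan, PRS construction, and Mendelian randomization."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from microvasc.cohort import (
    OutcomeSpec,
    TraitArchitecture,
    simulate_covariates,
    simulate_genotypes,
    simulate_outcomes,
    simulate_trait,
)
from microvasc.genetics import (
    GwasResults,
    GwasRow,
    MendelianRandomization,
    PrsModel,
    build_prs,
    gwas_scan,
    one_sample_mr,
    prs_phewas,
    prune_by_correlation,
    select_significant,
    split_cohort,
)


@pytest.fixture(scope="module")
def small_gwas():
    gt = simulate_genotypes(800, 30, seed=1)
    cov = simulate_covariates(800, seed=2)
    trait, _ = simulate_trait(gt, cov, TraitArchitecture(
        causal_effects={"rs000000": 0.5}), seed=3)
    return gt, cov, trait


class TestGwasScan:
    def test_matches_statsmodels_ols_no_covariates(self, small_gwas):
        gt, _, trait = small_gwas
        res = gwas_scan(gt, trait, None)
        by_id = {r.variant_id: r for r in res.rows}
        for j in (0, 7, 19):
            g = gt.dosages[:, j].astype(float)
            sm_fit = sm.OLS(trait, sm.add_constant(g)).fit()
            row = by_id[gt.variant_ids[j]]
            assert row.beta == pytest.approx(sm_fit.params[1], abs=1e-6)
            assert row.se == pytest.approx(sm_fit.bse[1], abs=1e-6)
            assert row.p == pytest.approx(sm_fit.pvalues[1], rel=1e-6)

    def test_matches_statsmodels_ols_with_covariates(self, small_gwas):
        gt, cov, trait = small_gwas
        res = gwas_scan(gt, trait, cov)
        scan = [r for r in res.rows if r.variant_id == "rs000005"][0]
        from microvasc.association import covariate_design

        C = covariate_design(cov, [c for c in ["age", "age2", "sex", "smoking_ever"]
                                   + [f"pc{k}" for k in range(1, 11)] + ["array"]])
        X = sm.add_constant(np.column_stack([gt.dosages[:, 5].astype(float),
                                             C.to_numpy(float)]))
        fit = sm.OLS(trait, X).fit()
        assert scan.beta == pytest.approx(fit.params[1], abs=1e-10)
        assert scan.se == pytest.approx(fit.bse[1], abs=1e-10)

    def test_causal_variant_most_significant(self, small_gwas):
        gt, cov, trait = small_gwas
        df = gwas_scan(gt, trait, cov).frame()
        assert df.nsmallest(1, "p")["variant_id"].iloc[0] == "rs000000"

    def test_maf_filter_contract(self):
        gt = simulate_genotypes(400, 50, maf_range=(0.01, 0.5), seed=4)
        res = gwas_scan(gt, np.random.default_rng(5).normal(size=400), None, maf_min=0.05)
        assert all(r.maf > 0.05 for r in res.rows)
        assert len(res.rows) + res.n_dropped_maf + res.n_dropped_monomorphic == 50

    def test_monomorphic_dropped(self):
        gt = simulate_genotypes(100, 5, seed=6)
        gt.dosages[:, 2] = 1  # constant column
        res = gwas_scan(gt, np.random.default_rng(7).normal(size=100), None)
        assert res.n_dropped_monomorphic == 1
        assert "rs000002" not in {r.variant_id for r in res.rows}

    def test_rows_sorted_by_variant_id(self, small_gwas):
        gt, cov, trait = small_gwas
        ids = [r.variant_id for r in gwas_scan(gt, trait, cov).rows]
        assert ids == sorted(ids)


class TestPrs:
    def _rows(self, ps):
        return GwasResults([GwasRow(f"rs{j:06d}", "G", 0.1 * (j + 1), 0.05, p, 0.3, 100)
                            for j, p in enumerate(ps)], 0, 0)

    def test_none_significant_gives_empty_model(self):
        model = select_significant(self._rows([0.5, 0.9]), 5e-8)
        assert model.variant_ids == []

    def test_threshold_one_selects_all(self):
        model = select_significant(self._rows([0.5, 0.9]), 1.0)
        assert len(model.variant_ids) == 2

    def test_selection_equals_brute_force_filter(self):
        rng = np.random.default_rng(8)
        ps = 10 ** rng.uniform(-12, 0, size=40)
        res = self._rows(list(ps))
        model = select_significant(res, 1e-6)
        expected = sorted(r.variant_id for r in res.rows if r.p < 1e-6)
        assert sorted(model.variant_ids) == expected

    def test_zero_weights_zero_scores(self):
        gt = simulate_genotypes(50, 5, seed=9)
        model = PrsModel(gt.variant_ids[:3], np.zeros(3))
        assert (build_prs(gt, model) == 0).all()

    def test_single_variant_unit_weight_equals_dosage(self):
        gt = simulate_genotypes(50, 5, seed=10)
        model = PrsModel([gt.variant_ids[2]], np.ones(1))
        np.testing.assert_array_equal(build_prs(gt, model), gt.dosages[:, 2].astype(float))

    def test_linearity_in_weights(self):
        gt = simulate_genotypes(60, 8, seed=11)
        rng = np.random.default_rng(12)
        w1, w2 = rng.normal(size=8), rng.normal(size=8)
        s1 = build_prs(gt, PrsModel(gt.variant_ids, w1))
        s2 = build_prs(gt, PrsModel(gt.variant_ids, w2))
        s12 = build_prs(gt, PrsModel(gt.variant_ids, w1 + w2))
        np.testing.assert_allclose(s12, s1 + s2, atol=1e-10)

    def test_unknown_variant_rejected_with_ids(self):
        gt = simulate_genotypes(20, 3, seed=13)
        with pytest.raises(KeyError, match="rs999999"):
            build_prs(gt, PrsModel(["rs999999"], np.ones(1)))

    def test_duplicate_variants_rejected(self):
        with pytest.raises(ValueError, match="unique"):
            PrsModel(["rs1", "rs1"], np.ones(2))

    def test_split_cohort_disjoint_exhaustive(self):
        train, test = split_cohort(101, 0.6, seed=14)
        assert len(np.intersect1d(train, test)) == 0
        assert len(train) + len(test) == 101

    def test_pruner_removes_correlated_duplicates(self):
        gt = simulate_genotypes(500, 4, seed=15)
        gt.dosages[:, 1] = gt.dosages[:, 0]  # perfect LD pair
        rows = GwasResults([GwasRow(v, "G", 0.1, 0.05, p, 0.3, 500)
                            for v, p in zip(gt.variant_ids, [1e-9, 1e-8, 0.5, 0.9])], 0, 0)
        pruned = prune_by_correlation(gt, rows, r_max=0.1)
        kept = {r.variant_id for r in pruned.rows}
        assert "rs000000" in kept and "rs000001" not in kept


@pytest.fixture(scope="module")
def mr_world():
    """Genotype -> exposure -> outcome chain with planted confounding."""
    n = 6000
    gt = simulate_genotypes(n, 40, maf_range=(0.1, 0.5), seed=20)
    cov = simulate_covariates(n, seed=21)
    rng = np.random.default_rng(22)
    confounder = rng.normal(size=n)
    causal = {f"rs{j:06d}": 0.18 for j in range(15)}
    arch = TraitArchitecture(causal_effects=causal, confounder_loading=0.8)
    expo, truth = simulate_trait(gt, cov, arch, seed=23, confounder=confounder)
    spec = OutcomeSpec("quantitative", effect=0.3, confounder_loading=0.9, seed=24)
    out = simulate_outcomes(expo, cov, spec, confounder=confounder)
    score = build_prs(gt, PrsModel(list(causal), np.full(15, 0.18)))
    return gt, cov, expo, out["value"].to_numpy(), score, confounder, truth


class TestMendelianRandomization:
    def test_recovers_causal_effect_despite_confounding(self, mr_world):
        gt, cov, expo, y, score, confounder, truth = mr_world
        est = one_sample_mr(score, expo, y, cov)
        assert est.effect == pytest.approx(0.3, abs=3 * est.se)
        assert est.first_stage_f > 10 and not est.weak_instrument

    def test_naive_regression_biased_by_planted_amount(self, mr_world):
        gt, cov, expo, y, score, confounder, truth = mr_world
        naive = sm.OLS(y, sm.add_constant(expo)).fit().params[1]
        planted_bias = 0.9 * np.cov(expo, confounder)[0, 1] / np.var(expo)
        assert naive == pytest.approx(0.3 + planted_bias, abs=0.05)
        assert abs(naive - 0.3) > 0.2  # confounding clearly visible

    def test_exposure_scale_is_linear_rescaling(self, mr_world):
        gt, cov, expo, y, score, *_ = mr_world
        e1 = one_sample_mr(score, expo, y, cov, exposure_scale=1.0)
        e10 = one_sample_mr(score, expo, y, cov, exposure_scale=10.0)
        assert e10.effect == pytest.approx(10 * e1.effect)
        assert e10.se == pytest.approx(10 * e1.se)
        assert e10.p == pytest.approx(e1.p)

    def test_prs_mode_agrees_with_2sls_after_scaling(self, mr_world):
        gt, cov, expo, y, score, *_ = mr_world
        tsls = one_sample_mr(score, expo, y, cov, mode="2sls")
        reduced = one_sample_mr(score, expo, y, cov, mode="prs")
        # reduced form = first-stage slope x causal slope
        z = (score - score.mean())
        x_on_z = np.cov(z, expo)[0, 1] / np.var(z)
        assert reduced.effect / x_on_z == pytest.approx(tsls.effect, rel=0.05)

    def test_zero_variance_instrument_rejected(self, mr_world):
        gt, cov, expo, y, *_ = mr_world
        with pytest.raises(ValueError, match="zero variance"):
            one_sample_mr(np.ones_like(expo), expo, y, cov)

    def test_weak_instrument_flagged(self):
        rng = np.random.default_rng(30)
        n = 500
        z = rng.normal(size=n)
        x = 0.02 * z + rng.normal(size=n)
        y = 0.3 * x + rng.normal(size=n)
        est = MendelianRandomization(z, x, y, None).fit()
        assert est.weak_instrument and est.first_stage_f < 10

    def test_summary_renders(self, mr_world):
        gt, cov, expo, y, score, *_ = mr_world
        s = one_sample_mr(score, expo, y, cov).summary()
        assert "2SLS" in s and "first-stage" in s


class TestPrsPhewas:
    def test_planted_outcome_found_and_null_calibrated(self):
        n = 2000
        cov = simulate_covariates(n, seed=40)
        rng = np.random.default_rng(41)
        score = rng.normal(size=n)
        panel = {}
        for i in range(5):
            spec = OutcomeSpec("prevalent-binary", 0.0, 0.2, seed=42 + i)
            panel[f"null{i}"] = ("prevalent", simulate_outcomes(score, cov, spec))
        spec = OutcomeSpec("prevalent-binary", 0.5, 0.2, seed=60)
        panel["planted"] = ("prevalent", simulate_outcomes(score, cov, spec))
        df = prs_phewas(score, panel, cov).frame()
        assert df.sort_values("p").iloc[0]["outcome"] == "planted"

    def test_zero_variance_score_rejected(self):
        with pytest.raises(ValueError):
            prs_phewas(np.zeros(100), {}, None)
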