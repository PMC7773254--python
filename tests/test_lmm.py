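"""Mixed-model fitting, AICc, stepwise selection, sub-models and
diagnostics."""

import numpy as np
import pytest

import phenoscreen as ps
from phenoscreen.lmm import FittedLMM, FitError, compute_aicc


def bare_fit(loglik, n, k):
    return FittedLMM(fixed_estimates={}, variance_components={},
                     loglik=loglik, n_obs=n, k_params=k, converged=True,
                     fallback_fixed_only=False, terms=[], random_groups=[],
                     criterion_mode="ML", aliased=[])


def make_ds(seed=3, framework="LMM", **cfg_kw):
    defaults = dict(n_control=200, n_batches=10,
                    beta={"intercept": 10.0, "genotype": 1.0, "sex": 0.5,
                          "interaction": 0.0, "bodyweight": 0.1})
    defaults.update(cfg_kw)
    df, truth = ps.gen_continuous_dataset(ps.SimConfig(seed=seed, **defaults))
    return ps.prepare(ps.RawTable(df), ps.default_spec(framework)), truth


class TestAICc:
    def test_closed_form_value(self):
        # -2(-100) + 2*4 + 2*4*5/(50-4-1)
        assert compute_aicc(bare_fit(-100.0, 50, 4)) == pytest.approx(
            200 + 8 + 40 / 45)

    def test_correction_vanishes_at_large_n(self):
        aicc = compute_aicc(bare_fit(-100.0, 10**6, 4))
        aic = 200 + 8
        assert abs(aicc - aic) < 1e-4

    def test_undefined_at_tiny_sample(self):
        with pytest.raises(FitError, match="AICc undefined"):
            compute_aicc(bare_fit(-10.0, 5, 4))

    def test_ols_aicc_matches_rss_oracle(self):
        # independent oracle: Gaussian loglik from the residual sum of squares
        ds, _ = make_ds(seed=9)
        fit = ps.fit_lmm(ds, ["Genotype", "BodyWeight"], [], "ML")
        assert fit.fallback_fixed_only
        n = fit.n_obs
        rss = float(np.sum(fit.residuals ** 2))
        llf = -n / 2 * (np.log(2 * np.pi * rss / n) + 1)
        k = len(fit.fixed_names) + 1
        expect = -2 * llf + 2 * k + 2 * k * (k + 1) / (n - k - 1)
        assert compute_aicc(fit) == pytest.approx(expect, rel=1e-10)


class TestFitLMM:
    def test_recovers_generating_parameters(self):
        ds, truth = make_ds(seed=3, n_control=400, n_batches=20)
        fit = ps.fit_lmm(ds, criterion_mode="REML")
        g = fit.fixed_estimates["Genotype[mutant]"]
        assert g["ci_low"] <= g["estimate"] <= g["ci_high"]
        assert abs(fit.variance_components["residual"] - 1.0) < 0.35
        assert fit.converged and not fit.fallback_fixed_only

    def test_single_batch_falls_back_to_ols(self):
        ds, _ = make_ds(seed=5, n_batches=1, n_mutant_batches=1)
        fit = ps.fit_lmm(ds, criterion_mode="REML")
        assert fit.fallback_fixed_only
        ols = ps.fit_lmm(ds, ds.spec.fixed_terms, [], "REML")
        for name in fit.fixed_names:
            assert fit.fixed_estimates[name]["estimate"] == pytest.approx(
                ols.fixed_estimates[name]["estimate"], abs=1e-10)

    def test_zero_batch_variance_agrees_with_fixed_only(self):
        agree = []
        for seed in range(6):
            ds, _ = make_ds(seed=100 + seed, batch_sd=1e-12)
            mixed = ps.fit_lmm(ds, criterion_mode="REML")
            fixed = ps.fit_lmm(ds, ds.spec.fixed_terms, [], "REML")
            agree.append(abs(mixed.fixed_estimates["Genotype[mutant]"]["p"]
                             - fixed.fixed_estimates["Genotype[mutant]"]["p"]))
        assert max(agree) < 0.02

    def test_aliased_column_dropped_and_recorded(self):
        ds, _ = make_ds(seed=7)
        ds.data["BodyWeight2"] = ds.data["BodyWeight"]  # collinear by hand
        fit = ps.fit_lmm(ds, ["Genotype", "BodyWeight", "BodyWeight2"],
                         ["Batch"], "ML")
        assert "BodyWeight2" in fit.aliased
        assert "BodyWeight2" not in fit.fixed_names

    def test_insufficient_data_is_hard_error(self):
        ds, _ = make_ds(seed=8)
        ds.data = ds.data.iloc[:4]
        with pytest.raises(FitError, match="insufficient data"):
            ps.fit_lmm(ds, ["Genotype", "Sex", "BodyWeight"], [], "ML")


class TestStepwise:
    def test_direction_none_returns_full_model(self):
        ds, _ = make_ds(seed=3)
        trace, fit = ps.stepwise_select(ds)
        assert trace.direction == "none"
        assert [s for s in trace.steps if s["accepted"]] == [trace.steps[0]]
        assert trace.final_terms == ds.spec.fixed_terms

    def test_backward_never_worse_than_full_and_keeps_genotype(self):
        for seed in (3, 4, 5):
            df, _ = ps.gen_continuous_dataset(ps.SimConfig(
                n_control=200, n_batches=10, seed=seed,
                beta={"intercept": 10, "genotype": 0.5, "sex": 1.0,
                      "interaction": 0.0, "bodyweight": 0.0}))
            ds = ps.prepare(ps.RawTable(df),
                            ps.default_spec("LMM", optimize="backward"))
            trace, fit = ps.stepwise_select(ds)
            full_aicc = next(s["aicc"] for s in trace.steps if s["accepted"])
            assert compute_aicc(fit) <= full_aicc + 1e-8
            assert "Genotype" in trace.final_terms
            accepted = [s["aicc"] for s in trace.steps if s["accepted"]]
            assert all(b <= a + 1e-8 for a, b in zip(accepted, accepted[1:]))

    def test_hierarchy_no_interaction_without_mains(self):
        ds, _ = make_ds(seed=3)
        ds.spec.optimize = "stepwise"
        trace, _ = ps.stepwise_select(ds)
        for step in trace.steps:
            terms = step["terms"]
            for t in terms:
                if ":" in t:
                    a, b = t.split(":")
                    assert a in terms and b in terms

    def test_forward_starts_from_genotype_only(self):
        ds, _ = make_ds(seed=3)
        ds.spec.optimize = "forward"
        trace, _ = ps.stepwise_select(ds)
        assert trace.steps[0]["terms"] == ["Genotype"]
        assert "Genotype" in trace.final_terms

    def test_cold_refit_reproduces_selected_model(self):
        ds, _ = make_ds(seed=3)
        ds.spec.optimize = "backward"
        trace, fit = ps.stepwise_select(ds)
        cold = ps.fit_lmm(ds, trace.final_terms, ds.spec.random_groups, "ML")
        for name in fit.fixed_names:
            assert fit.fixed_estimates[name]["estimate"] == pytest.approx(
                cold.fixed_estimates[name]["estimate"], abs=1e-6)


class TestSexSpecific:
    def test_dimorphic_effects_recovered(self):
        # female effect 2, male effect 0 (interaction -2)
        df, _ = ps.gen_continuous_dataset(ps.SimConfig(
            n_control=400, n_batches=20, seed=13,
            beta={"intercept": 10, "genotype": 2.0, "sex": 0.5,
                  "interaction": -2.0, "bodyweight": 0.0}))
        ds = ps.prepare(ps.RawTable(df), ps.default_spec("LMM"))
        final = ps.fit_lmm(ds, criterion_mode="REML")
        sub = ps.sex_specific_effects(ds, final)
        assert sub["female"]["ci_low"] <= 2.0 <= sub["female"]["ci_high"]
        assert sub["male"]["ci_low"] <= 0.0 <= sub["male"]["ci_high"]
        assert {"overall", "female", "male", "interaction"} <= set(sub)

    def test_single_sex_reports_overall_only(self):
        df, _ = ps.gen_continuous_dataset(ps.SimConfig(
            n_control=100, n_batches=5, seed=14))
        df = df[df["Sex"] == "Male"].reset_index(drop=True)
        ds = ps.prepare(ps.RawTable(df), ps.default_spec("LMM"))
        final = ps.fit_lmm(ds, criterion_mode="REML")
        sub = ps.sex_specific_effects(ds, final)
        assert "overall" in sub
        assert "female" not in sub and "male" not in sub


class TestEffectSizes:
    def test_cohens_d_arithmetic(self):
        ds, _ = make_ds(seed=3)
        fit = ps.fit_lmm(ds, criterion_mode="REML")
        es = ps.lmm_effect_sizes(fit)
        total_sd = np.sqrt(sum(fit.variance_components.values()))
        g = fit.fixed_estimates["Genotype[mutant]"]["estimate"]
        assert es["Genotype[mutant]"]["value"] == pytest.approx(g / total_sd)
        assert es["Genotype[mutant]"]["kind"] == "cohens_d"

    def test_standardized_coefficient_scale_invariant(self):
        ds, _ = make_ds(seed=3)
        fit = ps.fit_lmm(ds, ["Genotype", "BodyWeight"], ["Batch"], "REML")
        es = ps.lmm_effect_sizes(fit)["BodyWeight"]["value"]
        ds.data["BodyWeight"] = ds.data["BodyWeight"] * 10.0
        fit10 = ps.fit_lmm(ds, ["Genotype", "BodyWeight"], ["Batch"], "REML")
        es10 = ps.lmm_effect_sizes(fit10)["BodyWeight"]["value"]
        assert es == pytest.approx(es10, abs=1e-8)

    def test_degenerate_response_rejected(self):
        fit = bare_fit(-10.0, 50, 3)
        fit.response_sd = 0.0
        with pytest.raises(FitError, match="degenerate response"):
            ps.lmm_effect_sizes(fit)


class TestDiagnostics:
    def test_gaussian_residuals_pass_normality(self):
        ds, _ = make_ds(seed=3, n_control=400, n_batches=20)
        fit = ps.fit_lmm(ds, criterion_mode="REML")
        d = ps.residual_diagnostics(fit, seed=0)
        assert d["shapiro_wilk"]["p"] > 1e-4
        assert d["kolmogorov_smirnov"]["p"] > 1e-4

    def test_skewed_residuals_detected(self):
        rng = np.random.default_rng(2)
        fit = bare_fit(-10.0, 100, 3)
        fit.residuals = rng.exponential(1.0, 100) - 1.0
        d = ps.residual_diagnostics(fit, seed=0)
        assert d["shapiro_wilk"]["p"] < 0.01
        assert d["residual_skewness"] > 0.5

    def test_two_residuals_skip_shapiro_keep_ks(self):
        fit = bare_fit(-10.0, 2, 1)
        fit.residuals = np.array([-0.5, 0.5])
        d = ps.residual_diagnostics(fit)
        assert d["shapiro_wilk"] is None
        assert "3 residuals" in d["shapiro_wilk_reason"]
        assert d["kolmogorov_smirnov"] is not None

    def test_large_n_subsampled_deterministically(self):
        rng = np.random.default_rng(3)
        fit = bare_fit(-10.0, 8000, 3)
        fit.residuals = rng.normal(0, 1, 8000)
        d1 = ps.residual_diagnostics(fit, seed=42)
        d2 = ps.residual_diagnostics(fit, seed=42)
        assert d1["shapiro_wilk"]["n_used"] == 5000
        assert d1["shapiro_wilk"]["statistic"] == d2["shapiro_wilk"]["statistic"]


class TestAnalyzeContinuous:
    def test_full_analysis_bundle_coherent(self, continuous_ds):
        res = ps.analyze_continuous(continuous_ds)
        assert res.genotype_p is not None and 0 <= res.genotype_p <= 1
        assert res.final.criterion_mode == "REML"
        assert set(res.submodels) >= {"overall", "female", "male", "interaction"}
        assert res.diagnostics["n_residuals"] == res.final.n_obs
        for est in res.final.fixed_estimates.values():
            assert est["ci_low"] <= est["estimate"] <= est["ci_high"]
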