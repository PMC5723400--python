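"""Full-subset additive-model selection: AICc, weights, parsimony,
variable importance, collinearity rules."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from clonalscape.driver_models import (
    DriverConfig,
    ModelFit,
    ModelSizeError,
    ModelSpec,
    NULL_SPEC,
    aicc,
    apply_transforms,
    build_candidate_models,
    fit_additive_model,
    importance_from_weights,
    parse_model_label,
    predictor_correlations,
    prefilter_predictors,
    rank_models,
    run_driver_analysis,
    variable_importance,
)
from clonalscape.synthetic_data import DriverScenario, simulate_driver_dataset


def make_fit(label, aicc_value, predictors=()):
    terms = tuple(("smooth", p) for p in predictors)
    return ModelFit(spec=ModelSpec(terms=terms), label=label, n=16,
                    k=3, loglik=0.0, aicc=aicc_value, r2=0.5)


def covariate_frame(n=16, seed=0, **overrides):
    df, _ = simulate_driver_dataset(DriverScenario(n_sites=n, seed=seed,
                                                   **overrides))
    return df


class TestAICc:
    def test_formula(self):
        # -2*0 + 2*3 + 2*3*4/(10-3-1) = 6 + 4
        assert aicc(0.0, 3, 10) == pytest.approx(10.0)

    def test_infinite_at_boundary(self):
        assert math.isinf(aicc(0.0, 5, 6))

    def test_converges_to_aic_for_large_n(self):
        n, k = 10 ** 6, 3
        aic = -2 * 0.0 + 2 * k
        assert aicc(0.0, k, n) - aic < 1e-4


class TestPrefilter:
    def test_drops_latitude_against_sst(self):
        df = covariate_frame()
        corr = predictor_correlations(
            apply_transforms(df), ["sst", "latitude"], ())
        assert abs(corr.loc["sst", "latitude"]) > 0.9  # by construction
        retained, log = prefilter_predictors(
            apply_transforms(df),
            ["cyclone_pr", "dugong", "sst", "kd490", "dist_shore", "latitude"],
        )
        assert "latitude" not in retained and "sst" in retained
        dropped = {d["dropped"] for d in log}
        assert "latitude" in dropped

    def test_drops_dist_shore_correlated_with_cyclone(self):
        df = covariate_frame(dist_cyclone_corr=0.95)
        retained, log = prefilter_predictors(
            apply_transforms(df),
            ["cyclone_pr", "dugong", "sst", "kd490", "dist_shore"],
        )
        assert "dist_shore" not in retained and "cyclone_pr" in retained

    def test_uncorrelated_predictors_all_retained(self, rng):
        df = pd.DataFrame({
            "a": rng.normal(size=50), "b": rng.normal(size=50),
            "c": rng.normal(size=50),
        })
        df = apply_transforms(df, {})
        retained, log = prefilter_predictors(
            df, ["a", "b", "c"], keep_priority=("a", "b", "c"))
        assert retained == ["a", "b", "c"] and log == []

    def test_constant_predictor_dropped_with_warning(self, rng):
        df = pd.DataFrame({"a": rng.normal(size=20), "b": np.ones(20)})
        df = apply_transforms(df, {})
        retained, _ = prefilter_predictors(df, ["a", "b"],
                                           keep_priority=("a", "b"))
        assert retained == ["a"]


class TestBuildCandidates:
    def identity_corr(self, names):
        return pd.DataFrame(np.eye(len(names)), index=names, columns=names)

    def test_enumeration_matches_truncated_power_set(self):
        names = ["a", "b", "c"]
        specs = build_candidate_models(names, self.identity_corr(names))
        labels = {s.label({}) for s in specs}
        # oracle: power set truncated at size 2
        expected = {"null"} | {n for n in names} | {
            "+".join(c) for c in itertools.combinations(names, 2)}
        assert labels == expected and len(specs) == 7

    def test_correlated_pair_excluded_singles_kept(self):
        names = ["a", "b"]
        corr = self.identity_corr(names)
        corr.loc["a", "b"] = corr.loc["b", "a"] = 0.5
        labels = {s.label({}) for s in build_candidate_models(names, corr)}
        assert labels == {"null", "a", "b"}

    def test_interaction_specs_for_factor_smooth_pairs(self):
        names = ["sst", "dugong"]
        specs = build_candidate_models(
            names, self.identity_corr(names), include_interactions=True,
            factor_predictors=("dugong",))
        labels = {s.label() for s in specs}
        assert "SST.log+dugong" in labels or "dugong+SST.log" in labels
        assert "dugong+SST.log.by.dugong" in labels
        by = next(s for s in specs if ".by." in s.label())
        assert by.predictors == frozenset({"sst", "dugong"})


class TestFitAdditiveModel:
    def test_null_model_r2_zero(self):
        df = covariate_frame()
        fit = fit_additive_model(df, NULL_SPEC)
        assert fit.r2 == 0.0 and fit.k == 2

    def test_noiseless_linear_signal_recovered(self, rng):
        """A spline smooth must reproduce an exactly linear response; the
        closed-form least-squares line on the same data is the oracle."""
        x = np.linspace(0, 1, 16)
        y = 0.1 + 0.7 * x
        df = pd.DataFrame({"R": y, "p": x, "species": "sp"})
        spec = ModelSpec(terms=(("smooth", "p"),))
        fit = fit_additive_model(df, spec, DriverConfig(transforms={}))
        slope, intercept = np.polyfit(x, y, 1)
        assert np.allclose([slope, intercept], [0.7, 0.1])
        assert fit.r2 >= 0.999

    def test_refuses_insufficient_sample_size(self):
        df = covariate_frame(n=16).head(5)
        spec = ModelSpec(terms=(("smooth", "cyclone_pr"),))
        with pytest.raises(ModelSizeError, match="refus"):
            fit_additive_model(df, spec)

    def test_k_counts_mean_parameters_plus_scale(self):
        df = covariate_frame()
        single = fit_additive_model(
            df, ModelSpec(terms=(("smooth", "cyclone_pr"),)))
        factor = fit_additive_model(df, ModelSpec(terms=(("factor", "dugong"),)))
        both = fit_additive_model(
            df, ModelSpec(terms=(("smooth", "cyclone_pr"), ("factor", "dugong"))))
        assert single.k == 5       # intercept + 3 spline + scale
        assert factor.k == 3       # intercept + 1 dummy + scale
        assert both.k == 6

    def test_transforms_applied_exactly_once(self):
        df = covariate_frame()
        t1 = apply_transforms(df)
        t2 = apply_transforms(t1)
        assert np.allclose(t1["cyclone_pr_t"], np.sqrt(df["cyclone_pr"]))
        assert np.allclose(t1["cyclone_pr_t"], t2["cyclone_pr_t"])

    def test_location_random_intercept_flag(self):
        df = covariate_frame()
        df["location"] = [f"loc{i // 2}" for i in range(len(df))]
        cfg = DriverConfig(location_random_intercept=True)
        fit = fit_additive_model(
            df, ModelSpec(terms=(("smooth", "cyclone_pr"),)), cfg)
        assert math.isfinite(fit.aicc) and fit.k == 6


class TestRankModels:
    def test_weights_sum_to_one_and_top_delta_zero(self, rng):
        fits = [make_fit(f"m{i}", float(a))
                for i, a in enumerate(rng.uniform(0, 20, 12))]
        table = rank_models(fits)
        assert sum(f.weight for f in table.fits) == pytest.approx(1.0, abs=1e-9)
        assert table.fits[0].delta == 0.0
        deltas = [f.delta for f in table.fits]
        weights = [f.weight for f in table.fits]
        assert deltas == sorted(deltas)
        assert weights == sorted(weights, reverse=True)

    def test_equal_aicc_pair_shares_weight(self):
        fits = [make_fit("a", 1.0), make_fit("b", 1.0), make_fit("c", 30.0)]
        table = rank_models(fits)
        w = {f.label: f.weight for f in table.fits}
        assert w["a"] == pytest.approx(w["b"])
        assert w["a"] == pytest.approx(0.5 * (1 - w["c"]))

    def test_published_delta_pair_both_in_candidate_set(self):
        table = rank_models([make_fit("cyclone.sqrt", 1.114),
                             make_fit("SST.log+dugong", 3.078)])
        assert table.fits[1].delta == pytest.approx(1.964)
        assert len(table.candidate_set) == 2

    def test_delta_invariant_to_loglik_shift(self):
        base = [(-3.0, 3), (-5.0, 4), (-1.0, 2)]
        t1 = rank_models([
            make_fit(f"m{i}", aicc(ll, k, 16)) for i, (ll, k) in enumerate(base)])
        t2 = rank_models([
            make_fit(f"m{i}", aicc(ll + 7.5, k, 16))
            for i, (ll, k) in enumerate(base)])
        for f1, f2 in zip(t1.fits, t2.fits):
            assert f1.delta == pytest.approx(f2.delta)

    def test_nonfinite_aicc_excluded(self):
        table = rank_models([make_fit("a", 1.0), make_fit("b", math.inf)])
        assert [f.label for f in table.fits] == ["a"]

    def test_parsimony_prefers_fewest_predictors_then_lowest_aicc(self):
        fits = [
            make_fit("two", 0.0, ("a", "b")),
            make_fit("one", 1.5, ("a",)),
            make_fit("other_one", 1.9, ("b",)),
            make_fit("three_out", 5.0, ("c",)),
        ]
        table = rank_models(fits)
        assert table.parsimonious.label == "one"


class TestImportance:
    def test_importance_sums_weights_over_containing_models(self):
        fits = [
            make_fit("a", 0.0, ("a",)),
            make_fit("a+b", 1.0, ("a", "b")),
            make_fit("null", 4.0, ()),
        ]
        table = rank_models(fits)
        imp = variable_importance(table)
        w = {f.label: f.weight for f in table.fits}
        assert imp["a"] == pytest.approx(w["a"] + w["a+b"])
        assert imp["b"] == pytest.approx(w["a+b"])
        assert "absent" not in imp

    def test_label_parsing(self):
        assert parse_model_label("null") == frozenset()
        assert parse_model_label("cyclone.sqrt") == {"cyclone_pr"}
        assert parse_model_label("SST.log+dugong") == {"sst", "dugong"}
        assert parse_model_label("dugong+SST.log.by.dugong") == {"sst", "dugong"}
        assert parse_model_label("Dist.shore.sqrt+KD490.sqrt") == \
            {"dist_shore", "kd490"}

    def test_importance_from_weight_rows(self):
        imp = importance_from_weights([
            ("SST.log+dugong", 0.214), ("dugong", 0.135),
            ("dugong+SST.log.by.dugong", 0.021), ("cyclone.sqrt", 0.572),
        ])
        assert imp["dugong"] == pytest.approx(0.370)
        assert imp["cyclone_pr"] == pytest.approx(0.572)


class TestRunDriverAnalysis:
    def test_noiseless_cyclone_signal_top_ranked(self):
        df, _ = simulate_driver_dataset(
            DriverScenario(noise_sd=0.0, seed=11))
        res = run_driver_analysis(df)["synthetic"]
        assert res["table"].best.spec.predictors == {"cyclone_pr"}
        assert res["table"].parsimonious.spec.predictors == {"cyclone_pr"}

    def test_recovery_majority_over_replicates(self):
        """The generating predictor attains top rank and highest
        importance in >= 80% of seeded replicates at noise SD 0.05."""
        wins, imp_wins = 0, 0
        n_rep = 25
        for seed in range(n_rep):
            df, _ = simulate_driver_dataset(
                DriverScenario(noise_sd=0.05, seed=seed))
            res = run_driver_analysis(df)["synthetic"]
            if res["table"].best.spec.predictors == {"cyclone_pr"}:
                wins += 1
            imp = res["importance"]
            if max(imp, key=imp.get) == "cyclone_pr":
                imp_wins += 1
        assert wins >= 0.8 * n_rep
        assert imp_wins >= 0.8 * n_rep

    def test_single_variable_covariates(self):
        df, _ = simulate_driver_dataset(DriverScenario(seed=3))
        df = df.drop(columns=["sst", "kd490", "dist_shore", "latitude",
                              "dugong"])
        df["dugong"] = "absent"  # constant factor: dropped, not modelled
        res = run_driver_analysis(df)["synthetic"]
        labels = {f.label for f in res["table"].fits}
        assert labels == {"null", "cyclone.sqrt"}
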