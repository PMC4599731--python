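import math

import numpy as np
import pandas as pd
import pytest

from smoltroutes.routes import LINEAR, COUNTERCLOCKWISE
from smoltroutes.survival import (
    ModelFit,
    SurvivalModel,
    aicc,
    all_subsets,
    model_average,
    pseudo_r2,
    rank_models,
    standardize,
)

from _oracles import logistic_newton, subsets_with_marginality


class TestStandardize:
    def test_three_point_example(self):
        z, mean, sd = standardize([1.0, 2.0, 3.0])
        assert mean == 2.0 and sd == 1.0
        assert z == pytest.approx([-0.5, 0.0, 0.5])

    def test_result_has_half_sd(self, rng):
        z, _, _ = standardize(rng.normal(3.0, 7.0, 200))
        assert z.mean() == pytest.approx(0.0, abs=1e-12)
        assert z.std(ddof=1) == pytest.approx(0.5)

    def test_constant_vector_errors(self):
        with pytest.raises(ValueError, match="constant"):
            standardize([2.0, 2.0, 2.0])


class TestAicc:
    def test_formula(self):
        assert aicc(-10.0, 2, 100) == pytest.approx(24.0 + 12 / 97)

    def test_large_n_limit_is_aic(self):
        assert aicc(-10.0, 2, 10**9) == pytest.approx(24.0, abs=1e-6)

    def test_small_n_errors(self):
        with pytest.raises(ValueError):
            aicc(-10.0, 2, 3)


class TestAllSubsets:
    def test_three_mains(self):
        assert len(all_subsets(["A", "B", "C"], [])) == 8

    def test_interaction_requires_parents(self):
        models = all_subsets(["A", "B"], ["A:B"])
        assert set(models) == {(), ("A",), ("B",), ("A", "B"), ("A", "A:B", "B")}

    def test_empty_spec_is_intercept_only(self):
        assert all_subsets([], []) == [()]

    def test_orphan_interaction_rejected(self):
        with pytest.raises(ValueError):
            all_subsets(["A"], ["A:B"])

    @pytest.mark.parametrize(
        "mains, ints",
        [
            (["A", "B", "C", "D", "E"], ["A:B", "C:D"]),
            (["P", "J", "F", "Pop", "Y"], ["Pop:J", "Pop:P"]),
            (["A", "B", "C"], ["A:B", "A:C"]),
        ],
    )
    def test_matches_powerset_filter_oracle(self, mains, ints):
        assert set(all_subsets(mains, ints)) == subsets_with_marginality(mains, ints)


def _fake_fit(terms, aicc_value, coefs=None):
    coefs = coefs or {}
    params = pd.Series({"Intercept": 0.0, **coefs})
    bse = pd.Series(0.1, index=params.index)
    return ModelFit(tuple(terms), params, bse, -aicc_value / 2, len(params), 100, aicc_value, 0.1, 0.1)


class TestRankingAndAveraging:
    def test_weights_one_unit_apart(self):
        fits = rank_models([_fake_fit(["A"], 100.0), _fake_fit([], 101.0)])
        assert fits[0].delta_aicc == 0.0 and fits[1].delta_aicc == pytest.approx(1.0)
        e = math.exp(-0.5)
        assert fits[0].weight == pytest.approx(1 / (1 + e))
        assert fits[1].weight == pytest.approx(e / (1 + e))

    def test_single_model(self):
        (fit,) = rank_models([_fake_fit(["A"], 50.0)])
        assert fit.delta_aicc == 0.0 and fit.weight == 1.0

    def test_tied_models_equal_weights(self):
        fits = rank_models([_fake_fit(["A"], 80.0), _fake_fit(["B"], 80.0)])
        assert fits[0].weight == pytest.approx(0.5) and fits[1].weight == pytest.approx(0.5)

    def test_empty_candidate_set_errors(self):
        with pytest.raises(ValueError):
            rank_models([])

    def test_zero_substitution_average(self):
        # two models one AICc unit apart; term A only in the better one
        f1 = _fake_fit(["A"], 100.0, {"A": 1.0})
        f2 = _fake_fit([], 101.0)
        avg = model_average([f1, f2])
        w1 = 1 / (1 + math.exp(-0.5))
        assert avg.loc["A", "coef"] == pytest.approx(w1)
        assert avg.loc["A", "coef_conditional"] == pytest.approx(1.0)
        assert avg.loc["A", "n_models"] == 1

    def test_identical_coefficients_no_between_model_variance(self):
        f1 = _fake_fit(["A"], 100.0, {"A": 0.7})
        f2 = _fake_fit(["A", "B"], 100.5, {"A": 0.7, "B": 0.1})
        avg = model_average([f1, f2])
        assert avg.loc["A", "coef"] == pytest.approx(0.7)
        assert avg.loc["A", "se"] == pytest.approx(0.1)  # only within-model SE remains

    def test_one_model_average_is_that_model(self):
        f1 = _fake_fit(["A"], 100.0, {"A": 2.0})
        avg = model_average([f1])
        assert avg.loc["A", "coef"] == 2.0
        assert avg.loc["A", "ci_lower"] < 2.0 < avg.loc["A", "ci_upper"]


class TestPseudoR2:
    def test_examples(self):
        # at the null model the adjustment turns negative by k / |llf_null|
        assert pseudo_r2(-100.0, -100.0, 1) == pytest.approx((0.0, -0.01))
        r2, adj = pseudo_r2(-50.0, -100.0, 2)
        assert (r2, adj) == pytest.approx((0.5, 0.48))
        assert adj <= r2


def _route_records(rng, n=400, two_pops=True, species="sockeye"):
    pops = rng.choice(["Chilko", "Cultus"] if two_pops else ["Chilko"], n)
    p_init = rng.integers(1, 28, n).astype(float)
    julian = rng.integers(120, 170, n).astype(float)
    dur = rng.lognormal(3.5, 1.0, n)
    dx = -rng.lognormal(1.5, 0.8, n)
    zp = (p_init - p_init.mean()) / (2 * p_init.std(ddof=1))
    eta = -0.4 + 0.8 * zp
    surv = rng.uniform(size=n) < 1 / (1 + np.exp(-eta))
    return pd.DataFrame(
        {
            "tag_id": [f"t{i}" for i in range(n)],
            "species": species,
            "population": pops,
            "release_year": rng.choice([2012, 2013], n),
            "fork_length_mm": rng.normal(123, 2, n),
            "route": rng.choice([LINEAR, COUNTERCLOCKWISE], n),
            "p_initial": p_init,
            "julian_day": julian,
            "dx12_km": dx,
            "duration12_h": dur,
            "survived_qcs": surv,
        }
    )


class TestLogisticFit:
    def test_intercept_only_closed_form(self, rng):
        records = _route_records(rng, n=100)
        records["survived_qcs"] = np.r_[np.ones(30, bool), np.zeros(70, bool)]
        model = SurvivalModel(records, "sockeye", "entry")
        fit = model.fit_one(())
        assert fit.params["Intercept"] == pytest.approx(math.log(0.3 / 0.7), abs=1e-6)
        assert fit.loglik == pytest.approx(100 * (0.3 * math.log(0.3) + 0.7 * math.log(0.7)), abs=1e-6)

    def test_binary_predictor_log_odds(self, rng):
        # 2x2 layout survived x population: [[20,10],[10,20]] -> slope ln 4
        records = _route_records(rng, n=60)
        records["population"] = ["Chilko"] * 30 + ["Cultus"] * 30
        records["survived_qcs"] = np.r_[np.ones(20, bool), np.zeros(10, bool), np.ones(10, bool), np.zeros(20, bool)]
        fit = SurvivalModel(records, "sockeye", "entry").fit_one(("Population",))
        assert fit.params["Population[Cultus]"] == pytest.approx(-math.log(4.0), abs=1e-6)

    def test_matches_newton_oracle(self, rng):
        records = _route_records(rng, n=200, two_pops=False)
        model = SurvivalModel(records, "sockeye", "entry")
        fit = model.fit_one(("P_initial",))
        z = model.design.blocks["P_initial"]["P_initial"].to_numpy()
        beta, ll = logistic_newton(model.design.y, z)
        assert fit.params["Intercept"] == pytest.approx(beta[0], abs=1e-6)
        assert fit.params["P_initial"] == pytest.approx(beta[1], abs=1e-6)
        assert fit.loglik == pytest.approx(ll, abs=1e-6)

    def test_constant_response_is_degenerate(self, rng):
        records = _route_records(rng, n=50)
        records["survived_qcs"] = True
        with pytest.raises(ValueError, match="constant"):
            SurvivalModel(records, "sockeye", "entry").fit()

    def test_separated_predictor_flagged(self, rng):
        records = _route_records(rng, n=60)
        records["survived_qcs"] = records["p_initial"] > 14
        model = SurvivalModel(records, "sockeye", "entry")
        fit = model.fit_one(("P_initial",))
        assert fit.separation


class TestModelSets:
    def test_sockeye_entry_excludes_year_and_fl(self, rng):
        model = SurvivalModel(_route_records(rng), "sockeye", "entry")
        assert set(model.design.mains) == {"P_initial", "Julian", "Population"}
        assert set(model.design.interactions) == {"Population:Julian", "Population:P_initial"}

    def test_steelhead_entry_has_seven_terms(self, rng):
        records = _route_records(rng, species="steelhead")
        records["population"] = rng.choice(["Cheakamus", "Englishman"], len(records))
        model = SurvivalModel(records, "steelhead", "entry")
        assert set(model.design.mains) == {"P_initial", "Julian", "FL", "Population", "Year"}
        assert len(model.design.interactions) == 2

    def test_lateral_set_drops_seymour_steelhead(self, rng):
        records = _route_records(rng, species="steelhead")
        records["population"] = rng.choice(["Cheakamus", "Seymour"], len(records))
        model = SurvivalModel(records, "steelhead", "lateral")
        assert "Seymour" not in set(model.design.data["population"])
        assert {"Dx12", "Duration"} <= set(model.design.mains)

    def test_single_population_drops_interactions(self, rng):
        model = SurvivalModel(_route_records(rng, two_pops=False), "sockeye", "entry")
        assert model.design.interactions == []
        assert "Population" not in model.design.mains

    def test_records_missing_dx12_excluded_from_lateral(self, rng):
        records = _route_records(rng, n=100)
        records.loc[records.index[:40], "dx12_km"] = np.nan
        model = SurvivalModel(records, "sockeye", "lateral")
        assert model.nobs == 60


class TestResultsSurface:
    @pytest.fixture(scope="class")
    @staticmethod
    def results(rng=None):
        r = np.random.default_rng(42)
        return SurvivalModel(_route_records(r, n=600), "sockeye", "entry").fit()

    def test_ranking_table_well_formed(self, results):
        rk = results.ranking
        assert rk["delta_aicc"].iloc[0] == 0.0
        assert rk["weight"].sum() == pytest.approx(1.0)
        assert (rk["aicc"].diff().dropna() >= 0).all()

    def test_averaged_cis_bracket_estimates(self, results):
        av = results.averaged
        assert (av["ci_lower"] <= av["coef"]).all()
        assert (av["coef"] <= av["ci_upper"]).all()

    def test_positive_entry_effect_detected(self, results):
        # generated with a +0.8 standardized coefficient on entry position
        assert results.averaged.loc["P_initial", "coef"] > 0.3
        assert "P_initial" in results.significant_terms()

    def test_summary_mentions_key_pieces(self, results):
        text = results.summary()
        assert "AICc" in text and "sockeye" in text and "Intercept" in text

    def test_prediction_curves(self, results):
        curve = results.predict("P_initial")
        assert {"population", "value", "prob_survival"} <= set(curve.columns)
        assert curve["prob_survival"].between(0, 1).all()
        one_pop = curve[curve["population"] == curve["population"].iloc[0]]
        assert one_pop["prob_survival"].is_monotonic_increasing


class TestPredictionEdgeCases:
    def test_flat_when_all_coefficients_zero(self, rng):
        model = SurvivalModel(_route_records(rng, n=200), "sockeye", "entry")
        results = model.fit()
        results.averaged.loc[:, "coef"] = 0.0
        curve = results.predict("Julian", by_population=False)
        assert curve["prob_survival"].to_numpy() == pytest.approx(0.5)

    def test_intercept_only_inverse_logit(self, rng):
        model = SurvivalModel(_route_records(rng, n=200), "sockeye", "entry")
        results = model.fit()
        results.averaged.loc[:, "coef"] = 0.0
        results.averaged.loc["Intercept", "coef"] = math.log(0.3 / 0.7)
        curve = results.predict("Julian", by_population=False)
        assert curve["prob_survival"].to_numpy() == pytest.approx(0.3)

    def test_grid_truncated_to_observed_range(self, rng):
        results = SurvivalModel(_route_records(rng, n=200), "sockeye", "entry").fit()
        with pytest.warns(UserWarning, match="truncated"):
            curve = results.predict("Julian", grid=np.array([0.0, 500.0]), by_population=False)
        assert curve["value"].min() >= 120 and curve["value"].max() <= 170
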