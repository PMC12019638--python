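"""Transition model, annualization, housing scenarios and matrices."""
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from carecast import (
    GeneratorConfig,
    TransitionModelFit,
    annualize_probability,
    annualize_row,
    apply_housing_scenario,
    build_matrix_set,
    build_transition_matrix,
    fit_transition_model,
    predict_two_year_probs,
)
from carecast.config import STATES, TRANSITION_PREDICTORS
from carecast.synthetic import generate_mortality_schedule
from carecast.transitions import (
    default_covariate_means,
    make_lagged_pairs,
    uniform_housing_expansion,
)

_IDX = ["intercept"] + list(TRANSITION_PREDICTORS)
_OUT = ["mild", "moderate", "severe"]


def _fit_from_values(values: dict) -> TransitionModelFit:
    params = pd.DataFrame(0.0, index=_IDX, columns=_OUT)
    for (pred, out), v in values.items():
        params.loc[pred, out] = v
    bse = pd.DataFrame(0.0, index=_IDX, columns=_OUT)
    return TransitionModelFit(params, bse, n_used=0)


def _toy_panel(rows):
    """Analysis-style frame from (person, wave, state, next-covariates)."""
    recs = []
    for pid, wave, state, housing in rows:
        recs.append({"person_id": pid, "wave": wave, "age": 70.0,
                     "gender": "male", "tenure": "owner",
                     "education": "none", "income": 0.0,
                     "housing_problems": housing,
                     "depression_state": state})
    df = pd.DataFrame(recs)
    df["depression_state"] = pd.Categorical(df["depression_state"],
                                            categories=list(STATES),
                                            ordered=True)
    return df


class TestFit:
    def test_lagged_pairs_pool_consecutive_waves(self):
        df = _toy_panel([(1, 1, "none", 0), (1, 2, "mild", 0),
                         (1, 3, "none", 0), (2, 1, "none", 1),
                         (2, 3, "severe", 1)])  # gap of 2: not a pair
        pairs = make_lagged_pairs(df)
        assert len(pairs) == 2
        assert list(pairs["next_state"]) == ["mild", "none"]

    def test_fit_maximizes_brute_force_likelihood(self):
        """The fitted coefficients maximize the multinomial likelihood,
        checked with an independently coded likelihood evaluator: no
        random perturbation of the coefficient table may improve it."""
        from carecast import build_analysis_table, generate_panel
        cfg = GeneratorConfig(n_individuals=800, n_waves=2, seed=13,
                              attrition_rate=0.0)
        an = build_analysis_table(generate_panel(cfg))
        fit = fit_transition_model(an)
        pairs = make_lagged_pairs(an)

        def loglik(params: pd.DataFrame) -> float:
            ll = 0.0
            tmp = TransitionModelFit(params, fit.bse, 0)
            for _, r in pairs.iterrows():
                p = predict_two_year_probs(tmp, {
                    "current_state": r["depression_state"],
                    "age": r["age"], "gender": r["gender"],
                    "housing_problems": r["housing_problems"],
                    "tenure": r["tenure"], "education": r["education"],
                    "income": r["income"]})
                ll += math.log(p[list(STATES).index(r["next_state"])])
            return ll

        ll_hat = loglik(fit.params)
        rng = np.random.default_rng(3)
        for _ in range(5):
            delta = rng.normal(0, 1, fit.params.shape) * np.maximum(
                fit.bse.to_numpy(), 1e-3)
            assert loglik(fit.params + 0.5 * delta) < ll_hat + 1e-9

    def test_null_panel_recovers_rrr_of_one(self):
        """Outcome independent of predictors: non-intercept RRRs lie
        within their 95% CI of 1."""
        cfg = GeneratorConfig(
            n_individuals=6000, n_waves=2, seed=21, attrition_rate=0.0,
            transition_coefficients={
                "mild": {"intercept": 0.2}, "moderate": {"intercept": -0.6},
                "severe": {"intercept": -1.4}})
        from carecast import build_analysis_table, generate_panel
        an = build_analysis_table(generate_panel(cfg))
        fit = fit_transition_model(an)
        z = (fit.params.drop(index="intercept")
             / fit.bse.drop(index="intercept"))
        # 30 coefficients: allow the occasional |z| slightly above 1.96
        assert (z.abs() < 1.96).to_numpy().mean() > 0.85

    def test_empty_outcome_category_raises(self):
        df = _toy_panel([(1, 1, "none", 0), (1, 2, "mild", 0),
                         (2, 1, "mild", 0), (2, 2, "none", 0)])
        with pytest.raises(ValueError, match="no observations"):
            fit_transition_model(df)


class TestPredict:
    def test_zero_coefficients_give_uniform_probs(self):
        fit = _fit_from_values({})
        p = predict_two_year_probs(fit, {
            "current_state": "none", "age": 0, "gender": "male",
            "housing_problems": 0, "income": 0})
        assert np.allclose(p, 0.25)

    def test_hand_computed_softmax(self):
        fit = _fit_from_values({
            ("intercept", "mild"): 0.5, ("age", "mild"): 0.01,
            ("intercept", "severe"): -1.0, ("housing_problems", "severe"): 0.2})
        p = predict_two_year_probs(fit, {
            "current_state": "none", "age": 70, "gender": "male",
            "housing_problems": 2, "income": 0})
        lp = np.array([0.0, 0.5 + 0.7, 0.0, -1.0 + 0.4])
        expect = np.exp(lp) / np.exp(lp).sum()
        assert np.allclose(p, expect, atol=1e-12)

    def test_housing_rrr_acts_multiplicatively_on_severe_risk(self,
                                                              published_models):
        """One extra housing problem multiplies the severe-vs-none risk
        ratio by the published RRR of 1.28."""
        fit = published_models.transition
        base = {"current_state": "none", "age": 70, "gender": "female",
                "housing_problems": 0, "income": 392}
        p0 = predict_two_year_probs(fit, base)
        p1 = predict_two_year_probs(fit, {**base, "housing_problems": 1})
        ratio = (p1[3] / p1[0]) / (p0[3] / p0[0])
        assert ratio == pytest.approx(1.28, rel=1e-9)

    def test_brute_force_softmax_oracle_over_random_profiles(self,
                                                             published_models):
        fit = published_models.transition
        rng = np.random.default_rng(5)
        for _ in range(100):
            profile = {
                "current_state": STATES[rng.integers(4)],
                "age": float(rng.uniform(45, 100)),
                "gender": ("male", "female")[rng.integers(2)],
                "housing_problems": int(rng.integers(0, 13)),
                "tenure": ("owner", "rented")[rng.integers(2)],
                "education": ("none", "nvq_gce_cse",
                              "degree_or_below")[rng.integers(3)],
                "income": float(rng.uniform(0, 1000)),
            }
            p = predict_two_year_probs(fit, profile)
            # independent brute-force linear predictor
            lp = np.zeros(4)
            for j, out in enumerate(_OUT, start=1):
                v = fit.params.loc["intercept", out]
                v += fit.params.loc["housing_problems", out] * profile["housing_problems"]
                v += fit.params.loc[f"state_{profile['current_state']}", out] \
                    if profile["current_state"] != "none" else 0.0
                v += fit.params.loc["age", out] * profile["age"]
                v += fit.params.loc["female", out] * (profile["gender"] == "female")
                v += fit.params.loc["rented", out] * (profile["tenure"] == "rented")
                if profile["education"] != "none":
                    v += fit.params.loc[f"edu_{profile['education']}", out]
                v += fit.params.loc["income", out] * profile["income"]
                lp[j] = v
            expect = np.exp(lp - lp.max())
            expect /= expect.sum()
            assert np.allclose(p, expect, atol=1e-12)
            assert p.sum() == pytest.approx(1.0, abs=1e-9)

    def test_unseen_category_rejected(self, published_models):
        with pytest.raises(ValueError):
            predict_two_year_probs(published_models.transition, {
                "current_state": "none", "age": 70, "gender": "other",
                "housing_problems": 0})


class TestAnnualization:
    @pytest.mark.parametrize("p2,p1", [(0.0, 0.0), (1.0, 1.0), (0.19, 0.1)])
    def test_closed_form(self, p2, p1):
        assert annualize_probability(p2) == pytest.approx(p1, abs=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            annualize_probability(1.2)

    @given(st.floats(0, 1))
    @settings(derandomize=True, max_examples=50)
    def test_monotone_and_bounded(self, p2):
        p1 = annualize_probability(p2)
        assert 0 <= p1 <= p2 <= 1 or math.isclose(p1, p2)

    def test_identity_row_unchanged(self):
        row = annualize_row([0, 1, 0, 0], origin=1)
        assert np.allclose(row, [0, 1, 0, 0])

    def test_single_destination_matches_scalar_formula(self):
        row = annualize_row([0.81, 0.19, 0.0, 0.0], origin=0)
        assert row[1] == pytest.approx(0.1, abs=1e-12)
        assert row[0] == pytest.approx(0.9, abs=1e-12)

    @given(st.lists(st.floats(0.01, 1), min_size=4, max_size=4))
    @settings(derandomize=True, max_examples=50)
    def test_output_is_a_probability_row(self, raw):
        p2 = np.array(raw) / np.sum(raw)
        out = annualize_row(p2, origin=2)
        assert out.sum() == pytest.approx(1.0, abs=1e-9)
        assert (out >= -1e-12).all()

    def test_two_state_two_step_consistency(self):
        """Two annual steps reproduce the two-year leave probability
        exactly when the destination is absorbing."""
        p2 = 0.37
        p1 = annualize_probability(p2)
        m = np.array([[1 - p1, p1], [0.0, 1.0]])
        assert (m @ m)[0, 1] == pytest.approx(p2, abs=1e-12)


class TestHousingScenario:
    def test_cap_two_relocates_tail_mass(self):
        dist = uniform_housing_expansion((0.717, 0.182, 0.063, 0.038))
        capped = apply_housing_scenario(dist, 2)
        assert capped[0] == pytest.approx(0.717)
        assert capped[1] == pytest.approx(0.182)
        assert capped[2] == pytest.approx(0.101)
        assert capped[3:].sum() == 0.0

    def test_cap_zero_and_identity(self):
        dist = uniform_housing_expansion((0.7, 0.2, 0.06, 0.04))
        assert apply_housing_scenario(dist, 0)[0] == pytest.approx(1.0)
        assert np.allclose(apply_housing_scenario(dist, math.inf), dist)

    def test_negative_cap_rejected(self):
        with pytest.raises(ValueError):
            apply_housing_scenario([1.0] + [0.0] * 12, -1)

    @given(st.lists(st.floats(0.01, 1), min_size=13, max_size=13),
           st.integers(0, 12))
    @settings(derandomize=True, max_examples=50)
    def test_mass_conserved(self, raw, cap):
        dist = np.array(raw) / np.sum(raw)
        out = apply_housing_scenario(dist, cap)
        assert out.sum() == pytest.approx(1.0, abs=1e-9)
        assert out[cap + 1:].sum() == 0.0


class TestTransitionMatrix:
    def test_uniform_multipliers_give_constant_death_column(self,
                                                            published_models):
        m = build_transition_matrix(
            published_models.transition, 75, "female",
            GeneratorConfig().housing_distribution, 0.02,
            state_mortality_multipliers=(1, 1, 1, 1))
        assert np.allclose(m[:4, 4], 0.02)
        assert np.allclose(m.sum(axis=1), 1.0)

    def test_zero_mortality_leaves_annualized_mixture(self, published_models):
        dist = uniform_housing_expansion(GeneratorConfig().housing_distribution)
        m = build_transition_matrix(published_models.transition, 75, "male",
                                    dist, 0.0)
        assert np.allclose(m[:4, 4], 0.0)
        # hand mixture: sum_h dist(h) * annualized predicted row
        means = default_covariate_means()
        for s, state in enumerate(STATES):
            expect = np.zeros(4)
            for h, w in enumerate(dist):
                # hand linear predictor with stratum-mean tenure/education
                lp = np.zeros(4)
                fit = published_models.transition
                for j, out in enumerate(_OUT, start=1):
                    lp[j] = (fit.params.loc["intercept", out]
                             + fit.params.loc["housing_problems", out] * h
                             + (fit.params.loc[f"state_{state}", out]
                                if state != "none" else 0.0)
                             + fit.params.loc["age", out] * 75
                             + fit.params.loc["rented", out] * means["rented"]
                             + fit.params.loc["edu_nvq_gce_cse", out]
                             * means["edu_nvq_gce_cse"]
                             + fit.params.loc["edu_degree_or_below", out]
                             * means["edu_degree_or_below"]
                             + fit.params.loc["income", out] * means["income"])
                p2 = np.exp(lp - lp.max())
                p2 /= p2.sum()
                p1 = 1 - np.sqrt(1 - p2)
                p1[s] = 0.0
                p1[s] = 1 - p1.sum()
                expect += w * p1
            assert np.allclose(m[s, :4], expect, atol=1e-12)

    def test_scenario_monotonicity_none_to_severe(self, published_models):
        """Capping housing problems lower never increases the annual
        none-to-severe probability (all housing RRRs exceed 1)."""
        dist = uniform_housing_expansion(GeneratorConfig().housing_distribution)
        probs = []
        for cap in (math.inf, 2, 1, 0):
            m = build_transition_matrix(
                published_models.transition, 80, "female",
                apply_housing_scenario(dist, cap), 0.03)
            probs.append(m[0, 3])
        assert all(a >= b - 1e-15 for a, b in zip(probs, probs[1:]))

    def test_matrix_set_is_row_stochastic(self, published_models):
        mort = generate_mortality_schedule()
        mset = build_matrix_set(published_models.transition, mort,
                                GeneratorConfig().housing_distribution)
        sums = mset.matrices.sum(axis=-1)
        assert np.allclose(sums, 1.0, atol=1e-12)
        assert (mset.matrices >= -1e-15).all()
        assert np.allclose(mset.matrices[:, :, 4, :4], 0.0)
        assert np.allclose(mset.matrices[:, :, 4, 4], 1.0)

    def test_invalid_mortality_rejected(self, published_models):
        with pytest.raises(ValueError):
            build_transition_matrix(published_models.transition, 70, "male",
                                    [1.0] + [0] * 12, 1.5)


class TestCoefficientTableRoundTrip:
    def test_to_from_table(self, published_models):
        fit = published_models.transition
        back = TransitionModelFit.from_table(fit.to_table(), n_used=fit.n_used)
        pd.testing.assert_frame_equal(back.params, fit.params,
                                      check_names=False)
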