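"""Logistic stage: screening, ML fit, AIC ranking, significance, AUC."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.special import expit

from batdisturb.disturbance import (
    RankDeficientError,
    SingleClassError,
    aic,
    akaike_weights,
    auc,
    auc_score,
    fit_logistic,
    from_coefficients,
    model_selection,
    pearson_screen,
    planning_grid,
    predict_probability,
    term_significance,
)

PAPER_COEFS = (-3.817, 0.013, 0.472)
PAPER_TERMS = ("disturbance_factor", "mean_temp_c")


def _simulate_outcomes(rng, n=400, beta=PAPER_COEFS):
    df_value = rng.integers(3, 5, n) * rng.integers(19, 176, n)
    temp = rng.normal(-5.4, 3.0, n)
    eta = beta[0] + beta[1] * df_value + beta[2] * temp
    y = rng.random(n) < expit(eta)
    return pd.DataFrame(
        {
            "outcome": y.astype(int),
            "disturbance_factor": df_value.astype(float),
            "mean_temp_c": temp,
            "mean_wind_ms": rng.gamma(4.0, 0.75, n),
        }
    )


class TestPearsonScreen:
    def test_identical_candidate_excluded(self):
        frame = pd.DataFrame(
            {"disturbance_factor": [1.0, 2, 3, 4, 5], "twin": [2.0, 4, 6, 8, 10]}
        )
        res = pearson_screen(frame, ["twin"])
        assert res.excluded() == ["twin"]
        assert res.table["r"].iloc[0] == pytest.approx(1.0)

    def test_independent_candidate_usually_retained(self, rng):
        """A truly independent covariate survives screening ~95% of the time."""
        kept = 0
        for rep in range(300):
            frame = pd.DataFrame(
                {
                    "disturbance_factor": rng.normal(size=1000),
                    "noise": rng.normal(size=1000),
                }
            )
            kept += not pearson_screen(frame, ["noise"]).table["excluded"].iloc[0]
        assert kept / 300 >= 0.93

    def test_matches_textbook_formula(self):
        x = np.array([1.0, 2.0, 4.0, 5.0, 9.0])
        y = np.array([2.0, 1.0, 5.0, 4.0, 8.0])
        r_brute = (
            np.sum((x - x.mean()) * (y - y.mean()))
            / math.sqrt(np.sum((x - x.mean()) ** 2) * np.sum((y - y.mean()) ** 2))
        )
        frame = pd.DataFrame({"disturbance_factor": x, "cand": y})
        res = pearson_screen(frame, ["cand"])
        assert res.table["r"].iloc[0] == pytest.approx(r_brute, abs=1e-12)

    def test_zero_variance_degenerate(self):
        frame = pd.DataFrame(
            {"disturbance_factor": [1.0, 2, 3, 4], "flat": [7.0, 7, 7, 7]}
        )
        res = pearson_screen(frame, ["flat"])
        assert res.table["reason"].iloc[0] == "degenerate"


class TestFitLogistic:
    def test_intercept_only_closed_form(self):
        """3 successes of 17: intercept = logit(3/17) = log(3/14)."""
        frame = pd.DataFrame({"outcome": [1] * 3 + [0] * 14})
        fit = fit_logistic(frame, ())
        assert fit.coefficients[0] == pytest.approx(math.log(3 / 14), abs=1e-8)

    def test_all_zero_outcomes_boundary_flagged(self):
        frame = pd.DataFrame({"outcome": [0] * 10})
        fit = fit_logistic(frame, ())
        assert fit.boundary
        assert fit.predict(frame).max() < 1e-6

    def test_matches_statsmodels(self, rng):
        frame = _simulate_outcomes(rng, 300)
        fit = fit_logistic(frame, PAPER_TERMS)
        X = sm.add_constant(frame[list(PAPER_TERMS)].to_numpy())
        oracle = sm.Logit(frame["outcome"].to_numpy(), X).fit(disp=0)
        np.testing.assert_allclose(fit.coefficients, oracle.params, atol=1e-6)
        np.testing.assert_allclose(fit.loglik, oracle.llf, atol=1e-8)

    def test_rank_deficiency_names_terms(self, rng):
        frame = _simulate_outcomes(rng, 50)
        frame["df_copy"] = frame["disturbance_factor"]
        with pytest.raises(RankDeficientError, match="df_copy"):
            fit_logistic(frame, ("disturbance_factor", "df_copy"))

    def test_separation_detected(self):
        frame = pd.DataFrame(
            {"outcome": [0, 0, 0, 0, 1, 1, 1, 1],
             "disturbance_factor": [1.0, 2, 3, 4, 10, 11, 12, 13]}
        )
        fit = fit_logistic(frame, ("disturbance_factor",))
        assert fit.separation_detected
        assert not fit.converged

    def test_parameter_recovery_within_2se(self, rng):
        """Coverage of truth by +/- 2 SE over 200 datasets of 400 surveys."""
        hits = np.zeros(3)
        n_rep = 200
        for _ in range(n_rep):
            frame = _simulate_outcomes(rng)
            fit = fit_logistic(frame, PAPER_TERMS)
            se = np.sqrt(np.diag(fit.cov))
            hits += np.abs(fit.coefficients - PAPER_COEFS) <= 2 * se
        assert (hits / n_rep >= 0.90).all()


class TestAic:
    def test_intercept_only_closed_form(self):
        """AIC = 2 - 2[3 ln(3/17) + 14 ln(14/17)] ~ 17.84, coded independently."""
        frame = pd.DataFrame({"outcome": [1] * 3 + [0] * 14})
        fit = fit_logistic(frame, ())
        ll_oracle = 3 * math.log(3 / 17) + 14 * math.log(14 / 17)
        assert aic(fit) == pytest.approx(2 - 2 * ll_oracle, abs=1e-6)
        assert aic(fit) == pytest.approx(17.84, abs=0.005)

    def test_k_increments_per_term(self, rng):
        frame = _simulate_outcomes(rng, 100)
        ks = [
            fit_logistic(frame, terms).k
            for terms in [(), ("disturbance_factor",), PAPER_TERMS]
        ]
        assert ks == [1, 2, 3]

    def test_noise_covariate_changes_aic_by_2_minus_lrt(self, rng):
        frame = _simulate_outcomes(rng, 200)
        base = fit_logistic(frame, ("disturbance_factor",))
        frame["noise"] = rng.normal(size=len(frame))
        full = fit_logistic(frame, ("disturbance_factor", "noise"))
        chi2, _, _ = term_significance(full, "noise")
        assert aic(full) - aic(base) == pytest.approx(2 - chi2, abs=1e-6)


class TestModelSelection:
    def test_printed_aic_column_weights(self):
        """Akaike weights of the published AIC column: 2nd rank -> 0.23."""
        aics = [11.9, 12.7, 13.6, 13.6, 14.9, 15.6, 17.9, 27.9]
        w = akaike_weights(aics)
        assert round(float(w[1]), 2) == 0.23
        assert round(float(w[0]), 2) == 0.34

    def test_single_model_weight_one(self):
        assert akaike_weights([10.0]) == pytest.approx([1.0])

    def test_equal_aics_split_evenly(self):
        np.testing.assert_allclose(akaike_weights([5.0, 5.0]), [0.5, 0.5])

    @given(
        aics=st.lists(
            st.floats(min_value=1.0, max_value=200.0), min_size=2, max_size=8
        ),
        shift=st.floats(min_value=-50, max_value=50),
    )
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_weights_sum_to_one_and_shift_invariant(self, aics, shift):
        w = akaike_weights(aics)
        assert float(w.sum()) == pytest.approx(1.0, abs=1e-10)
        np.testing.assert_allclose(
            w, akaike_weights([a + shift for a in aics]), atol=1e-10
        )

    def test_eight_models_sorted_with_min_delta_zero(self, rng):
        frame = _simulate_outcomes(rng, 200)
        sel = model_selection(frame)
        assert len(sel.table) == 8
        assert sel.table["dAIC"].iloc[0] == 0.0
        assert sel.table["AIC"].is_monotonic_increasing
        assert sel.table["weight"].sum() == pytest.approx(1.0)
        # weights ordered with AIC
        assert sel.table["weight"].is_monotonic_decreasing

    def test_true_df_effect_ranks_df_models_on_top(self, rng):
        """When the truth contains DF, DF models dominate the top ranks."""
        top_has_df = 0
        for _ in range(20):
            frame = _simulate_outcomes(rng, 400)
            sel = model_selection(frame)
            top_has_df += "disturbance_factor" in sel.table["terms"].iloc[0]
        assert top_has_df >= 15


class TestTermSignificance:
    def test_definitional_identity(self, rng):
        frame = _simulate_outcomes(rng, 150)
        full = fit_logistic(frame, PAPER_TERMS)
        reduced = fit_logistic(frame, ("mean_temp_c",))
        chi2, df, _ = term_significance(full, "disturbance_factor")
        assert df == 1
        assert chi2 == pytest.approx(reduced.deviance - full.deviance, abs=1e-8)

    def test_null_p_values_roughly_uniform(self, rng):
        """Pure-noise covariate: LRT p-values approximately U(0,1)."""
        ps = []
        for _ in range(300):
            n = 150
            frame = pd.DataFrame(
                {
                    "outcome": (rng.random(n) < 0.3).astype(int),
                    "noise": rng.normal(size=n),
                }
            )
            fit = fit_logistic(frame, ("noise",))
            ps.append(term_significance(fit, "noise")[2])
        ps = np.array(ps)
        # coarse uniformity: mean ~ 0.5 and rejection rate ~ alpha
        assert ps.mean() == pytest.approx(0.5, abs=0.07)
        assert np.mean(ps <= 0.05) == pytest.approx(0.05, abs=0.04)

    def test_power_at_paper_truth(self, rng):
        ps = [
            term_significance(
                fit_logistic(_simulate_outcomes(rng), PAPER_TERMS),
                "disturbance_factor",
            )[2]
            for _ in range(30)
        ]
        assert np.median(ps) < 0.05


class TestAuc:
    def test_perfect_separation_is_one(self):
        assert auc_score([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1]) == 1.0

    def test_random_scores_near_half(self, rng):
        labels = (rng.random(10_000) < 0.5).astype(int)
        scores = rng.random(10_000)
        assert auc_score(scores, labels) == pytest.approx(0.5, abs=0.02)

    def test_matches_exhaustive_pair_counting(self):
        scores = np.array([0.2, 0.6, 0.6, 0.9])
        labels = np.array([0, 1, 0, 1])
        wins = ties = 0
        for i, j in itertools.product(range(4), range(4)):
            if labels[i] == 1 and labels[j] == 0:
                wins += scores[i] > scores[j]
                ties += scores[i] == scores[j]
        brute = (wins + 0.5 * ties) / (2 * 2)
        assert auc_score(scores, labels) == pytest.approx(brute, abs=1e-12)

    def test_single_class_is_error(self):
        with pytest.raises(SingleClassError):
            auc_score([0.1, 0.9], [1, 1])

    def test_fit_auc_uses_fitted_probabilities(self, rng):
        frame = _simulate_outcomes(rng, 200)
        fit = fit_logistic(frame, PAPER_TERMS)
        from sklearn.metrics import roc_auc_score

        assert auc(fit) == pytest.approx(
            roc_auc_score(frame["outcome"], fit.predict(frame)), abs=1e-12
        )


class TestPrediction:
    @pytest.mark.parametrize(
        "df_value,expected",
        [(500, 0.53), (700, 0.94)],
    )
    def test_published_model_evaluations(self, df_value, expected):
        fit = from_coefficients(PAPER_TERMS, PAPER_COEFS)
        pred = predict_probability(
            fit, disturbance_factor=df_value, mean_temp_c=-5.4
        )
        assert round(pred.p, 2) == expected

    def test_zero_coefficients_give_half(self):
        fit = from_coefficients(PAPER_TERMS, (0.0, 0.0, 0.0))
        pred = predict_probability(fit, disturbance_factor=123, mean_temp_c=9)
        assert pred.p == 0.5

    def test_band_from_covariance_inside_unit_interval(self, rng):
        frame = _simulate_outcomes(rng, 200)
        fit = fit_logistic(frame, PAPER_TERMS)
        pred = predict_probability(fit, disturbance_factor=500, mean_temp_c=-5.4)
        assert 0.0 < pred.lower < pred.p < pred.upper < 1.0

    @given(df_pair=st.tuples(
        st.floats(min_value=0, max_value=800),
        st.floats(min_value=0, max_value=800),
    ))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_strictly_increasing_in_df_iff_positive_coefficient(self, df_pair):
        lo, hi = sorted(df_pair)
        pos = from_coefficients(PAPER_TERMS, PAPER_COEFS)
        neg = from_coefficients(PAPER_TERMS, (-3.817, -0.013, 0.472))
        p_lo = predict_probability(pos, disturbance_factor=lo, mean_temp_c=-5.4).p
        p_hi = predict_probability(pos, disturbance_factor=hi, mean_temp_c=-5.4).p
        n_lo = predict_probability(neg, disturbance_factor=lo, mean_temp_c=-5.4).p
        n_hi = predict_probability(neg, disturbance_factor=hi, mean_temp_c=-5.4).p
        if hi > lo:
            assert p_hi > p_lo
            assert n_hi < n_lo


class TestPlanningGrid:
    def test_cell_equals_direct_prediction(self):
        fit = from_coefficients(PAPER_TERMS, PAPER_COEFS)
        grid = planning_grid(fit, researchers=[5], minutes=[100])
        direct = predict_probability(fit, disturbance_factor=500,
                                     mean_temp_c=-5.4)
        assert grid["p"].iloc[0] == pytest.approx(direct.p, abs=1e-12)

    def test_three_researchers_100_minutes_below_10_percent(self):
        """The published planning example: DF=300 -> <10% probability."""
        fit = from_coefficients(PAPER_TERMS, PAPER_COEFS)
        grid = planning_grid(fit, researchers=[3], minutes=[100])
        assert grid["p"].iloc[0] < 0.10

    def test_monotone_along_rows_and_columns(self):
        fit = from_coefficients(PAPER_TERMS, PAPER_COEFS)
        grid = planning_grid(fit, researchers=range(1, 6),
                             minutes=range(20, 201, 20))
        wide = grid.pivot(index="researchers", columns="minutes", values="p")
        assert (wide.diff(axis=0).iloc[1:] >= 0).all().all()
        assert (wide.diff(axis=1).iloc[:, 1:] >= 0).all().all()
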