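"""Logistic disturbance modelling of survey-night exceedance outcomes.

The binary outcome (did bats fly out of the cave more than the seasonal
model predicts the night after a survey) is regressed on a researcher
disturbance factor (researchers x minutes in cave), mean overnight
temperature and mean wind speed:

    logit P(response) = b0 + b_DF * DF + b_T * T [+ b_W * W]

Candidate covariates that are strongly Pearson-correlated with the
disturbance factor (cave length, bats counted, cluster counts/sizes)
are screened out first, mirroring the collinearity that arises because
larger caves with more bats take bigger crews longer to search.  All
subset models of the saturated term set are ranked by AIC with Akaike
weights; term importance is a drop-in-deviance likelihood-ratio test;
classification efficacy is the rank-based (Mann-Whitney) AUC; and the
fitted model yields a predictive probability surface over crew size and
survey duration for planning future hibernacula work.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit

__all__ = [
    "CovariateScreenResult",
    "LogisticFit",
    "PredictionResult",
    "pearson_screen",
    "fit_logistic",
    "from_coefficients",
    "aic",
    "akaike_weights",
    "model_selection",
    "term_significance",
    "auc",
    "auc_score",
    "predict_probability",
    "planning_grid",
]

TERM_LABELS = {
    "disturbance_factor": "Disturbance",
    "mean_temp_c": "Temperature",
    "mean_wind_ms": "Wind",
    "pressure_range_hpa": "Pressure",
}

DEFAULT_CANDIDATE_TERMS = ("disturbance_factor", "mean_temp_c", "mean_wind_ms")

_ETA_CLIP = 30.0
_SEPARATION_ETA = 20.0


class RankDeficientError(ValueError):
    """Design matrix is rank deficient; message names the collinear terms."""


class SingleClassError(ValueError):
    """A statistic requiring both outcome classes was asked of one class."""


@dataclass
class CovariateScreenResult:
    """Pearson screening of candidate covariates against a protected one."""

    protected: str
    alpha: float
    table: pd.DataFrame  # columns: candidate, r, p, excluded, reason

    def retained(self) -> list[str]:
        return list(self.table.loc[~self.table["excluded"], "candidate"])

    def excluded(self) -> list[str]:
        return list(self.table.loc[self.table["excluded"], "candidate"])


def pearson_screen(
    survey_table: pd.DataFrame,
    candidates: Sequence[str],
    protected: str = "disturbance_factor",
    alpha: float = 0.05,
) -> CovariateScreenResult:
    """Exclude candidates significantly correlated with the protected covariate.

    Pearson r with a t-based two-sided p-value per candidate; a
    candidate with p <= alpha is excluded in favour of the protected
    covariate.  Zero-variance candidates are excluded with reason
    ``"degenerate"``.
    """
    rows = []
    x = survey_table[protected].to_numpy(dtype=float)
    for cand in candidates:
        y = survey_table[cand].to_numpy(dtype=float)
        ok = ~(np.isnan(x) | np.isnan(y))
        if ok.sum() < 3:
            rows.append((cand, np.nan, np.nan, True, "fewer than 3 complete pairs"))
            continue
        if np.std(y[ok]) == 0 or np.std(x[ok]) == 0:
            rows.append((cand, np.nan, np.nan, True, "degenerate"))
            continue
        r, p = stats.pearsonr(x[ok], y[ok])
        excl = bool(p <= alpha)
        reason = (
            f"correlated with {protected} (p={p:.3g} <= {alpha})" if excl else ""
        )
        rows.append((cand, float(r), float(p), excl, reason))
    table = pd.DataFrame(rows, columns=["candidate", "r", "p", "excluded", "reason"])
    return CovariateScreenResult(protected=protected, alpha=alpha, table=table)


@dataclass
class LogisticFit:
    """A maximum-likelihood logistic regression fit.

    ``terms`` lists the covariate columns (intercept implicit and always
    first in ``coefficients``).  ``cov`` is the inverse observed
    information at the MLE, or ``None`` for a fit constructed from
    externally given coefficients.
    """

    terms: tuple[str, ...]
    coefficients: np.ndarray
    cov: np.ndarray | None
    loglik: float | None
    deviance: float | None
    n: int | None
    k: int
    converged: bool = True
    separation_detected: bool = False
    boundary: bool = False
    _data: pd.DataFrame | None = field(default=None, repr=False)

    def linear_predictor(self, X: np.ndarray) -> np.ndarray:
        return X @ self.coefficients

    def design(self, data: pd.DataFrame) -> np.ndarray:
        cols = [np.ones(len(data))]
        cols += [data[t].to_numpy(dtype=float) for t in self.terms]
        return np.column_stack(cols)

    def predict(self, data: pd.DataFrame | None = None) -> np.ndarray:
        if data is None:
            data = self._data
        eta = np.clip(self.design(data) @ self.coefficients, -_ETA_CLIP, _ETA_CLIP)
        return 1.0 / (1.0 + np.exp(-eta))


def _coerce_outcomes(outcomes) -> pd.DataFrame:
    if isinstance(outcomes, pd.DataFrame):
        return outcomes
    # duck-typed OutcomeSet from the exceedance stage
    if hasattr(outcomes, "to_frame"):
        return outcomes.to_frame()
    raise TypeError(f"cannot interpret outcomes of type {type(outcomes)!r}")


def fit_logistic(outcomes, terms: Sequence[str] = ()) -> LogisticFit:
    """Fit a logistic regression of ``outcome`` on ``terms`` by Newton-Raphson.

    ``outcomes`` is a DataFrame with an ``outcome`` column (or an
    :class:`~batdisturb.exceedance.OutcomeSet`).  Convergence tolerance
    1e-8 on the log-likelihood, at most 50 iterations with step
    halving.  A rank-deficient design raises
    :class:`RankDeficientError` naming the collinear terms; complete or
    quasi-complete separation (diverging coefficients driving fitted
    probabilities to 0/1) is detected and flagged on the returned fit
    rather than silently returned.
    """
    data = _coerce_outcomes(outcomes)
    terms = tuple(terms)
    y = data["outcome"].to_numpy(dtype=float)
    n = y.size
    X = np.column_stack(
        [np.ones(n)] + [data[t].to_numpy(dtype=float) for t in terms]
    )
    k = X.shape[1]
    if np.linalg.matrix_rank(X) < k:
        bad = _collinear_terms(X, ("intercept",) + terms)
        raise RankDeficientError(f"rank-deficient design; collinear terms: {bad}")

    beta = np.zeros(k)
    ll_old = _loglik(y, X, beta)
    converged = False
    for _ in range(50):
        eta = np.clip(X @ beta, -_ETA_CLIP, _ETA_CLIP)
        p = 1.0 / (1.0 + np.exp(-eta))
        w = np.maximum(p * (1.0 - p), 1e-12)
        grad = X.T @ (y - p)
        hess = (X.T * w) @ X
        try:
            step = np.linalg.solve(hess, grad)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(hess, grad, rcond=None)[0]
        # step halving on log-likelihood decrease
        scale = 1.0
        for _half in range(30):
            ll_new = _loglik(y, X, beta + scale * step)
            if ll_new >= ll_old - 1e-12:
                break
            scale *= 0.5
        beta = beta + scale * step
        if abs(ll_new - ll_old) < 1e-8:
            converged = True
            ll_old = ll_new
            break
        ll_old = ll_new

    eta = X @ beta
    separation = bool(np.max(np.abs(eta)) > _SEPARATION_ETA and _perfectly_split(y, eta))
    boundary = bool(y.min() == y.max())
    p = 1.0 / (1.0 + np.exp(-np.clip(eta, -_ETA_CLIP, _ETA_CLIP)))
    w = np.maximum(p * (1.0 - p), 1e-12)
    hess = (X.T * w) @ X
    try:
        cov = np.linalg.inv(hess)
    except np.linalg.LinAlgError:
        cov = np.linalg.pinv(hess)
    ll = _loglik(y, X, beta)
    return LogisticFit(
        terms=terms,
        coefficients=beta,
        cov=cov,
        loglik=ll,
        deviance=-2.0 * ll,
        n=n,
        k=k,
        converged=converged and not separation,
        separation_detected=separation,
        boundary=boundary,
        _data=data,
    )


def _loglik(y: np.ndarray, X: np.ndarray, beta: np.ndarray) -> float:
    eta = np.clip(X @ beta, -_ETA_CLIP, _ETA_CLIP)
    return float(np.sum(y * eta - np.log1p(np.exp(eta))))


def _perfectly_split(y: np.ndarray, eta: np.ndarray) -> bool:
    big = np.abs(eta) > _SEPARATION_ETA
    agree = (eta > 0) == (y > 0.5)
    return bool(np.all(agree[big])) and big.any()


def _collinear_terms(X: np.ndarray, names: tuple[str, ...]) -> list[str]:
    bad = []
    kept: list[int] = []
    for j in range(X.shape[1]):
        trial = X[:, kept + [j]]
        if np.linalg.matrix_rank(trial) < len(kept) + 1:
            bad.append(names[j])
        else:
            kept.append(j)
    return bad


def from_coefficients(terms: Sequence[str], coefficients: Sequence[float]) -> LogisticFit:
    """A :class:`LogisticFit` carrying externally given coefficients.

    Used to evaluate a published model (e.g. for planning predictions)
    when the underlying data are not available; no covariance, so
    predictions carry no uncertainty band.
    """
    beta = np.asarray(coefficients, dtype=float)
    if beta.size != len(terms) + 1:
        raise ValueError("need one coefficient per term plus an intercept")
    return LogisticFit(
        terms=tuple(terms), coefficients=beta, cov=None,
        loglik=None, deviance=None, n=None, k=beta.size,
    )


def aic(fit: LogisticFit) -> float:
    """Akaike information criterion, 2k - 2 logL."""
    if fit.loglik is None:
        raise ValueError("fit carries no likelihood (external coefficients)")
    return 2.0 * fit.k - 2.0 * fit.loglik


def aicc(fit: LogisticFit) -> float:
    """Small-sample corrected AIC: AIC + 2k(k+1)/(n-k-1)."""
    base = aic(fit)
    if fit.n is None or fit.n - fit.k - 1 <= 0:
        raise ValueError("AICc undefined: n - k - 1 <= 0")
    return base + 2.0 * fit.k * (fit.k + 1) / (fit.n - fit.k - 1)


def akaike_weights(aics: Sequence[float]) -> np.ndarray:
    """Akaike weights w_i = exp(-Delta_i/2) / sum_j exp(-Delta_j/2)."""
    a = np.asarray(aics, dtype=float)
    delta = a - a.min()
    w = np.exp(-delta / 2.0)
    return w / w.sum()


@dataclass
class ModelSelectionTable:
    """AIC ranking of all subset models, with Akaike weights."""

    table: pd.DataFrame  # columns: model, terms, K, AIC, dAIC, weight, status
    fits: dict[tuple[str, ...], LogisticFit]

    @property
    def best(self) -> LogisticFit:
        top_terms = self.table.iloc[0]["terms"]
        return self.fits[top_terms]


def model_label(terms: Sequence[str]) -> str:
    if not terms:
        return "Intercept only"
    return " + ".join(TERM_LABELS.get(t, t) for t in terms)


def model_selection(
    outcomes,
    candidate_terms: Sequence[str] = DEFAULT_CANDIDATE_TERMS,
    criterion: str = "aic",
) -> ModelSelectionTable:
    """Fit all subset models of the saturated term set and rank by AIC.

    Includes the intercept-only model: ``2**len(candidate_terms)``
    models in total.  Ties at equal AIC are broken by fewer parameters,
    then lexicographic term order.  A member fit that fails carries a
    failure status in its row instead of aborting the table.
    """
    crit = {"aic": aic, "aicc": aicc}[criterion]
    rows = []
    fits: dict[tuple[str, ...], LogisticFit] = {}
    for r in range(len(candidate_terms) + 1):
        for combo in itertools.combinations(candidate_terms, r):
            try:
                fit = fit_logistic(outcomes, combo)
                fits[combo] = fit
                status = "ok" if fit.converged else (
                    "separation" if fit.separation_detected else "not converged"
                )
                rows.append(
                    {
                        "model": model_label(combo),
                        "terms": combo,
                        "K": fit.k,
                        "AIC": crit(fit),
                        "status": status,
                    }
                )
            except (RankDeficientError, ValueError) as exc:
                rows.append(
                    {
                        "model": model_label(combo),
                        "terms": combo,
                        "K": len(combo) + 1,
                        "AIC": np.nan,
                        "status": f"failed: {exc}",
                    }
                )
    table = pd.DataFrame(rows)
    ok = table["AIC"].notna()
    table = pd.concat(
        [
            table[ok].sort_values(
                ["AIC", "K", "model"], kind="mergesort"
            ),
            table[~ok],
        ],
        ignore_index=True,
    )
    aics = table.loc[table["AIC"].notna(), "AIC"].to_numpy()
    table["dAIC"] = table["AIC"] - (aics.min() if aics.size else np.nan)
    table["weight"] = np.nan
    if aics.size:
        table.loc[table["AIC"].notna(), "weight"] = akaike_weights(aics)
    return ModelSelectionTable(
        table=table[["model", "terms", "K", "AIC", "dAIC", "weight", "status"]],
        fits=fits,
    )


def term_significance(fit: LogisticFit, term: str) -> tuple[float, int, float]:
    """Drop-in-deviance likelihood-ratio test for one term.

    Refits the model without ``term``; chi-square = deviance(reduced) -
    deviance(full) on 1 degree of freedom.
    """
    if term not in fit.terms:
        raise ValueError(f"term {term!r} not in fit {fit.terms}")
    if fit._data is None:
        raise ValueError("fit carries no data; cannot refit reduced model")
    reduced_terms = tuple(t for t in fit.terms if t != term)
    reduced = fit_logistic(fit._data, reduced_terms)
    chi2 = reduced.deviance - fit.deviance
    df = 1
    p = float(stats.chi2.sf(chi2, df))
    return float(chi2), df, p


def wald_significance(fit: LogisticFit, term: str) -> tuple[float, int, float]:
    """Wald chi-square test for one coefficient (alternative to the LRT)."""
    if fit.cov is None:
        raise ValueError("fit carries no covariance")
    j = 1 + fit.terms.index(term)
    z2 = fit.coefficients[j] ** 2 / fit.cov[j, j]
    return float(z2), 1, float(stats.chi2.sf(z2, 1))


def auc_score(scores: np.ndarray, labels: np.ndarray) -> float:
    """Rank-based (Mann-Whitney) AUC with ties counted half."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = labels == 1
    n1, n0 = int(pos.sum()), int((~pos).sum())
    if n1 == 0 or n0 == 0:
        raise SingleClassError("AUC undefined: both outcome classes required")
    ranks = stats.rankdata(scores)
    u = ranks[pos].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


def auc(fit: LogisticFit, outcomes=None) -> float:
    """AUC of the fitted probabilities against the observed outcomes."""
    data = _coerce_outcomes(outcomes) if outcomes is not None else fit._data
    if data is None:
        raise ValueError("no outcome data available")
    return auc_score(fit.predict(data), data["outcome"].to_numpy())


@dataclass
class PredictionResult:
    """Predicted response probability with a +/- 1 SE band.

    The band is computed on the linear-predictor scale from the
    coefficient covariance and transformed through the inverse logit,
    so it always stays inside (0, 1).  ``None`` bounds mean the fit
    carries no covariance.
    """

    p: float
    lower: float | None
    upper: float | None
    eta: float
    se_eta: float | None


def predict_probability(
    fit: LogisticFit,
    band: float = 1.0,
    **covariates: float,
) -> PredictionResult:
    """Inverse-logit prediction at given covariate values.

    Covariates are passed by term name, e.g.
    ``predict_probability(fit, disturbance_factor=500, mean_temp_c=-5.4)``.
    ``band`` is the number of standard errors of the fitted linear
    predictor to span (1 by default).
    """
    missing = [t for t in fit.terms if t not in covariates]
    if missing:
        raise ValueError(f"missing covariate values for terms: {missing}")
    x = np.array([1.0] + [float(covariates[t]) for t in fit.terms])
    eta = float(x @ fit.coefficients)
    p = float(expit(eta))
    if fit.cov is None:
        return PredictionResult(p=p, lower=None, upper=None, eta=eta, se_eta=None)
    se = float(np.sqrt(x @ fit.cov @ x))
    lo = float(expit(eta - band * se))
    hi = float(expit(eta + band * se))
    return PredictionResult(p=p, lower=lo, upper=hi, eta=eta, se_eta=se)


def planning_grid(
    fit: LogisticFit,
    researchers: Iterable[int] = range(1, 7),
    minutes: Iterable[int] = range(20, 201, 20),
    temp: float = -5.4,
    wind: float | None = None,
) -> pd.DataFrame:
    """Predicted disturbance probability per (crew size, minutes) cell.

    The disturbance factor of each cell is the product of its row and
    column; temperature (and wind, if the model includes it) are held
    fixed.  When the disturbance coefficient is positive the grid is
    monotone non-decreasing along rows and columns.
    """
    rows = []
    for n_res in researchers:
        for mins in minutes:
            cov: dict[str, float] = {"disturbance_factor": n_res * mins}
            if "mean_temp_c" in fit.terms:
                cov["mean_temp_c"] = temp
            if "mean_wind_ms" in fit.terms:
                cov["mean_wind_ms"] = 0.0 if wind is None else wind
            pred = predict_probability(fit, **cov)
            rows.append(
                {
                    "researchers": n_res,
                    "minutes": mins,
                    "disturbance_factor": n_res * mins,
                    "p": pred.p,
                    "lower": pred.lower,
                    "upper": pred.upper,
                }
            )
    return pd.DataFrame(rows)


def probability_curve(
    fit: LogisticFit,
    df_values: Iterable[float] = range(0, 801, 10),
    temp: float = -5.4,
    wind: float | None = None,
) -> pd.DataFrame:
    """Samples of the probability curve over the disturbance factor."""
    rows = []
    for df_value in df_values:
        cov: dict[str, float] = {"disturbance_factor": float(df_value)}
        if "mean_temp_c" in fit.terms:
            cov["mean_temp_c"] = temp
        if "mean_wind_ms" in fit.terms:
            cov["mean_wind_ms"] = 0.0 if wind is None else wind
        pred = predict_probability(fit, **cov)
        rows.append(
            {"disturbance_factor": df_value, "p": pred.p,
             "lower": pred.lower, "upper": pred.upper}
        )
    return pd.DataFrame(rows)
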