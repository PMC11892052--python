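"""Person-level regression layer.

Estimates the association between a person's exposure fractions (share of
their prescriptions that were contraindicated / broad-indicated) and health
status or utilisation outcomes, controlling for the observable confounders a
rich household survey provides: one dummy per 3-character condition code
present in the data, sex, single-year-of-age dummies, education, race,
survey-year dummies, a dummy per distinct prescription count (capped, pooled
above the cap), and the mean FDA approval year of the person's drugs.

Three estimators share the same design matrix:

* ``lpm``    — ordinary least squares (linear probability model for binary
  outcomes) with heteroskedasticity-robust (HC1) standard errors;
* ``probit`` — maximum-likelihood probit, reported as average marginal
  effects so the scale is comparable to the LPM;
* ``dml``    — cross-fitted double machine learning for the partially linear
  model Y = theta*D + g(X) + eps: nuisance functions E[Y|X] and E[D|X] are
  learned out-of-fold (random forest or regression tree), residuals formed,
  and theta estimated by the Neyman-orthogonal residual-on-residual score
  theta_hat = sum(v*(Y - l_hat)) / sum(v^2) with v = D - m_hat, with the
  influence-function variance for standard errors.

Every estimate is also expressed as a "mean percentage": 100 x estimate /
sample mean of the outcome, i.e. the association as a percentage of the
outcome's level.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.ensemble import RandomForestRegressor
from sklearn.linear_model import LinearRegression
from sklearn.model_selection import KFold
from sklearn.tree import DecisionTreeRegressor
import statsmodels.api as sm
from statsmodels.tools.sm_exceptions import PerfectSeparationError

from .errors import ConfigError, EstimationError
from .survey import SurveyDataset

__all__ = [
    "EXPOSURES",
    "ModelSpec",
    "EstimateResult",
    "build_analysis_table",
    "fit_lpm",
    "fit_probit",
    "fit_dml_plr",
    "summarize_models",
]

EXPOSURES = ("frac_contraindicated", "frac_indicated")

DML_DEFAULT_SEED = 20160101


@dataclass(frozen=True)
class ModelSpec:
    """Outcome, exposures and control-block switches for one regression."""

    outcome: str
    exposures: tuple[str, ...] = EXPOSURES
    estimator: str = "lpm"
    condition_dummies: bool = True
    age_dummies: bool = True
    sex: bool = True
    education: bool = True
    race: bool = True
    year_dummies: bool = True
    rx_count_dummies: bool = True
    rx_count_cap: int = 30
    mean_approval_year: bool = True
    extra_controls: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.outcome in self.exposures:
            raise ConfigError("outcome cannot be one of the exposures")
        if self.estimator not in ("lpm", "probit", "dml"):
            raise ConfigError(f"unknown estimator {self.estimator!r}")


@dataclass(frozen=True)
class EstimateResult:
    """One exposure-outcome estimate in the published-table layout."""

    outcome: str
    exposure: str
    estimator: str
    estimate: float
    std_error: float
    t_value: float
    p_value: float
    ci_low: float
    ci_high: float
    mean_percentage: float
    n: int
    note: str = ""


def build_analysis_table(exposures: pd.DataFrame, ds: SurveyDataset,
                         current_only: bool = True) -> pd.DataFrame:
    """Person-year analysis frame: exposures + person attributes + one
    ``cond_<code>`` dummy per condition code present in the data."""
    data = exposures.merge(ds.persons, on=["person_id", "year"], how="inner")
    data["ztotexp"] = np.log1p(data["total_expenditure"].astype(float))
    cond = ds.conditions
    if current_only:
        cond = cond[cond["is_current"].astype(int) == 1]
    if len(cond):
        dummies = (cond.assign(flag=1)
                   .pivot_table(index=["person_id", "year"], columns="icd10_3",
                                values="flag", aggfunc="max", fill_value=0))
        dummies.columns = [f"cond_{c}" for c in dummies.columns]
        data = data.merge(dummies.reset_index(), on=["person_id", "year"],
                          how="left")
        cond_cols = [c for c in data.columns if c.startswith("cond_")]
        data[cond_cols] = data[cond_cols].fillna(0).astype(int)
    return data


def _dummy_block(series: pd.Series, prefix: str) -> pd.DataFrame:
    """One-hot encode dropping the first (reference) level."""
    d = pd.get_dummies(series.astype(str), prefix=prefix, drop_first=True)
    return d.astype(float)


def _design(spec: ModelSpec, data: pd.DataFrame) -> tuple[pd.Series, pd.DataFrame]:
    """Build (y, X) with the exposure columns first and an intercept."""
    for col in (spec.outcome,) + spec.exposures:
        if col not in data.columns:
            raise ConfigError(f"column {col!r} not in analysis table")
    y = data[spec.outcome].astype(float)
    blocks: list[pd.DataFrame] = [data[list(spec.exposures)].astype(float)]
    if spec.sex and "sex" in data.columns:
        blocks.append(_dummy_block(data["sex"], "sex"))
    if spec.age_dummies and "age" in data.columns:
        blocks.append(_dummy_block(data["age"].astype(int), "age"))
    if spec.education and "education" in data.columns:
        blocks.append(_dummy_block(data["education"], "edu"))
    if spec.race and "race" in data.columns:
        blocks.append(_dummy_block(data["race"], "race"))
    if spec.year_dummies and "year" in data.columns:
        blocks.append(_dummy_block(data["year"].astype(int), "year"))
    if spec.rx_count_dummies and "n_rx" in data.columns:
        capped = data["n_rx"].astype(int).clip(upper=spec.rx_count_cap)
        blocks.append(_dummy_block(capped, "nrx"))
    if spec.mean_approval_year and "mean_approval_year" in data.columns:
        blocks.append(pd.DataFrame(
            {"mean_approval_year_c": data["mean_approval_year"].astype(float) - 2000.0}))
    if spec.condition_dummies:
        cond_cols = [c for c in data.columns if c.startswith("cond_")]
        if cond_cols:
            blocks.append(data[cond_cols].astype(float))
    if spec.extra_controls:
        blocks.append(data[list(spec.extra_controls)].astype(float))
    X = pd.concat([b.reset_index(drop=True) for b in blocks], axis=1)

    # drop constant control columns (e.g. codes nobody in the sample has);
    # a constant exposure is a genuine identification failure instead
    nunique = X.nunique()
    constant = [c for c in X.columns if nunique[c] <= 1]
    bad_exposures = [c for c in constant if c in spec.exposures]
    if bad_exposures:
        raise EstimationError(
            f"exposure(s) constant across persons: {bad_exposures}")
    X = X.drop(columns=[c for c in constant if c not in spec.exposures])
    X.insert(0, "const", 1.0)

    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        # locate a minimal set of culprit columns via pivoted QR
        from scipy.linalg import qr
        _, r, piv = qr(X.to_numpy(), mode="economic", pivoting=True)
        diag = np.abs(np.diag(r))
        tol = diag.max() * max(X.shape) * np.finfo(float).eps
        dropped = [X.columns[piv[i]] for i in range(len(diag)) if diag[i] < tol]
        dropped += [X.columns[p] for p in piv[len(diag):]]
        raise EstimationError(f"design matrix rank deficient; collinear columns: "
                              f"{sorted(map(str, dropped))}")
    if len(y) <= X.shape[1]:
        raise EstimationError(
            f"n = {len(y)} does not exceed the {X.shape[1]} parameters")
    return y.reset_index(drop=True), X


def _package(spec: ModelSpec, estimator: str, exposure: str, est: float,
             se: float, y_mean: float, n: int, df_resid: float | None = None,
             note: str = "") -> EstimateResult:
    if se > 0 and np.isfinite(se):
        t = est / se
        if df_resid is not None:
            p = float(2 * sps.t.sf(abs(t), df_resid))
            crit = float(sps.t.ppf(0.975, df_resid))
        else:
            p = float(2 * sps.norm.sf(abs(t)))
            crit = 1.959963984540054
        lo, hi = est - crit * se, est + crit * se
    else:
        t, p, lo, hi = float("nan"), float("nan"), float("nan"), float("nan")
    mean_pct = float(100.0 * est / y_mean) if y_mean != 0 else float("nan")
    return EstimateResult(spec.outcome, exposure, estimator, float(est),
                          float(se), float(t), p, float(lo), float(hi),
                          mean_pct, n, note)


def fit_lpm(spec: ModelSpec, data: pd.DataFrame) -> list[EstimateResult]:
    """OLS with HC1-robust standard errors; one result per exposure."""
    y, X = _design(spec, data)
    res = sm.OLS(y, X).fit(cov_type="HC1")
    return [
        _package(spec, "lpm", e, res.params[e], res.bse[e], y.mean(), len(y),
                 df_resid=res.df_resid)
        for e in spec.exposures
    ]


def fit_probit(spec: ModelSpec, data: pd.DataFrame) -> list[EstimateResult]:
    """Probit average marginal effects (delta-method standard errors).

    On perfect separation or non-convergence the model is refit with a small
    L2 penalty and the results carry a ``penalised`` note (standard errors
    are then unavailable).
    """
    y, X = _design(spec, data)
    uniq = set(np.unique(y))
    if not uniq <= {0.0, 1.0} or len(uniq) < 2:
        raise EstimationError(
            f"probit requires a non-degenerate binary outcome; got values {sorted(uniq)}")
    # dummy controls that perfectly predict the outcome in their on-group
    # have an unbounded MLE; drop them (the usual applied-probit convention)
    yv = y.to_numpy()
    separated = []
    for col in X.columns:
        if col == "const" or col in spec.exposures:
            continue
        v = X[col].to_numpy()
        if set(np.unique(v)) <= {0.0, 1.0}:
            on = yv[v == 1.0]
            if on.size and (on.min() == on.max()):
                separated.append(col)
    if separated:
        X = X.drop(columns=separated)
    sep_note = (f"dropped {len(separated)} perfectly-predicting dummies"
                if separated else "")
    model = sm.Probit(y, X)
    # warm start: LPM coefficients rescaled to the probit index scale,
    # 1/phi(Phi^-1(ybar)) — gets Newton into its quadratic-convergence zone
    ols = sm.OLS(y, X).fit()
    scale = 1.0 / sps.norm.pdf(sps.norm.ppf(np.clip(y.mean(), 0.05, 0.95)))
    start = (ols.params * scale).to_numpy()
    start[0] = sps.norm.ppf(np.clip(y.mean(), 0.001, 0.999))
    try:
        try:
            res = model.fit(start_params=start, disp=0, maxiter=200)
            # the convergence flag oscillates when quasi-separated rare
            # dummies drift; accept the solution if the score has vanished
            converged = (res.mle_retvals.get("converged", True)
                         or float(np.abs(model.score(res.params)).max()) < 1e-2)
        except (np.linalg.LinAlgError, PerfectSeparationError):
            converged = False
        if not converged:
            res = model.fit(method="bfgs", disp=0, maxiter=2000, gtol=1e-5)
            if not res.mle_retvals.get("converged", True):
                raise EstimationError("probit did not converge")
        margeff = res.get_margeff(at="overall", method="dydx")
        names = [c for c in X.columns if c != "const"]
        ame = dict(zip(names, margeff.margeff))
        ame_se = dict(zip(names, margeff.margeff_se))
        return [
            _package(spec, "probit", e, ame[e], ame_se[e], y.mean(), len(y),
                     note=sep_note)
            for e in spec.exposures
        ]
    except (np.linalg.LinAlgError, EstimationError, PerfectSeparationError) as exc:
        warnings.warn(f"probit fit failed ({exc}); falling back to a penalised "
                      "fit without standard errors", stacklevel=2)
        res = model.fit_regularized(method="l1", alpha=1e-4, disp=0)
        note = f"penalised fallback ({exc})"
        xb = X.to_numpy() @ res.params
        phi_bar = float(np.mean(sps.norm.pdf(xb)))
        return [
            _package(spec, "probit", e, phi_bar * res.params[e], float("nan"),
                     y.mean(), len(y), note=note)
            for e in spec.exposures
        ]


def _make_learner(learner: str, seed: int, params: dict | None):
    params = dict(params or {})
    if learner == "random_forest":
        params.setdefault("n_estimators", 500)
        params.setdefault("min_samples_leaf", 5)
        return RandomForestRegressor(random_state=seed, **params)
    if learner == "regression_tree":
        params.setdefault("max_depth", 8)
        return DecisionTreeRegressor(random_state=seed, **params)
    if learner == "linear":
        return LinearRegression(**params)
    raise ConfigError(f"unknown learner {learner!r}")


def _crossfit_predict(model_factory, X: np.ndarray, y: np.ndarray,
                      n_folds: int, seed: int) -> np.ndarray:
    """Out-of-fold predictions; ``n_folds=1`` fits and predicts in-sample."""
    pred = np.empty_like(y, dtype=float)
    if n_folds <= 1:
        m = model_factory()
        m.fit(X, y)
        return m.predict(X)
    kf = KFold(n_splits=n_folds, shuffle=True, random_state=seed)
    for train, test in kf.split(X):
        m = model_factory()
        m.fit(X[train], y[train])
        pred[test] = m.predict(X[test])
    return pred


def fit_dml_plr(spec: ModelSpec, data: pd.DataFrame,
                learner: str = "random_forest", n_folds: int = 5,
                seed: int = DML_DEFAULT_SEED,
                learner_params: dict | None = None) -> list[EstimateResult]:
    """Cross-fitted DML for the partially linear model, one exposure at a
    time (the other exposures join the controls)."""
    y_s, X_full = _design(spec, data)
    if n_folds > 1 and len(y_s) < 10 * n_folds:
        raise EstimationError(f"n = {len(y_s)} < 10 x n_folds = {10 * n_folds}")
    y = y_s.to_numpy(dtype=float)
    results = []
    for exposure in spec.exposures:
        d = X_full[exposure].to_numpy(dtype=float)
        ctrl_cols = [c for c in X_full.columns if c not in ("const", exposure)]
        X = X_full[ctrl_cols].to_numpy(dtype=float)
        for attempt in range(3):
            fold_seed = seed + 7919 * attempt
            factory_y = lambda: _make_learner(learner, fold_seed + 1, learner_params)
            factory_d = lambda: _make_learner(learner, fold_seed + 2, learner_params)
            l_hat = _crossfit_predict(factory_y, X, y, n_folds, fold_seed)
            m_hat = _crossfit_predict(factory_d, X, d, n_folds, fold_seed)
            v = d - m_hat
            if np.sum(v ** 2) > 1e-12 * len(v):
                break
        else:
            raise EstimationError(
                f"residualised exposure {exposure!r} is constant after 3 "
                "cross-fitting attempts")
        u = y - l_hat
        theta = float(np.sum(v * u) / np.sum(v ** 2))
        eps = u - theta * v
        n = len(y)
        j = np.mean(v ** 2)
        var = np.mean(v ** 2 * eps ** 2) / (j ** 2) / n
        se = float(np.sqrt(var))
        results.append(_package(spec, "dml", exposure, theta, se, y.mean(), n,
                                note=f"learner={learner}, n_folds={n_folds}"))
    return results


def summarize_models(results: Sequence[EstimateResult]) -> pd.DataFrame:
    """Tidy table (estimate, SE, t, p, CI bounds, mean percentage) for all
    outcome x exposure x estimator combinations, plus sign agreement across
    estimators of the same pair."""
    if not results:
        raise EstimationError("no results to summarise")
    df = pd.DataFrame([r.__dict__ for r in results])
    sign = (df.assign(sign=np.sign(df["estimate"]))
              .groupby(["outcome", "exposure"])["sign"]
              .agg(lambda s: len(set(s)) == 1)
              .rename("estimators_agree_on_sign"))
    return df.merge(sign.reset_index(), on=["outcome", "exposure"], how="left")
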