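"""Seasonal logistic models for the odds of MCI/dementia.

Two parameterizations of season are supported: the continuous cos/sin
quadrature pair (2-df likelihood-ratio test) and the categorical
winter/spring (January-June) vs summer/fall (July-December) contrast, whose
exponentiated coefficient is the seasonal odds ratio with a Wald interval.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, asdict
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .design import build_design, check_full_rank, complete_cases
from .exceptions import FitError, InputError
from .timeangles import PERIOD_DAYS, date_to_angle

logger = logging.getLogger(__name__)

MIN_EVENTS = 10
WINTER_SPRING = "winter_spring"
SUMMER_FALL = "summer_fall"

POSITIVE_DIAGNOSES = {"MCI", "mci", "dementia", "Dementia", "AD", "ad"}
NEGATIVE_DIAGNOSES = {"NCI", "nci"}


@dataclass
class LogisticSeasonalFit:
    beta_cos: float
    beta_sin: float
    covariate_betas: dict[str, float]
    covariate_se: dict[str, float]
    deviance_full: float
    deviance_reduced: float
    deviance_delta: float
    p_lrt: float
    n_cases: int
    n_total: int
    converged: bool

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class SeasonORFit:
    season_or: float
    season_or_ci: tuple[float, float]
    beta_season: float
    se_season: float
    p_wald: float
    deviance_delta: float
    p_lrt: float
    covariate_betas: dict[str, float]
    n_cases: int
    n_total: int
    n_winter_spring: int
    n_summer_fall: int

    def to_dict(self) -> dict:
        return asdict(self)


def binarize_diagnosis(series: pd.Series) -> pd.Series:
    """Map NCI -> 0, MCI/dementia -> 1; anything else (or NaN) -> NaN."""
    def _map(v):
        if pd.isna(v):
            return np.nan
        if isinstance(v, str):
            if v in POSITIVE_DIAGNOSES:
                return 1.0
            if v in NEGATIVE_DIAGNOSES:
                return 0.0
            return np.nan
        return float(v)

    return series.map(_map)


def categorical_season(dates):
    """January-June -> winter_spring; July-December -> summer_fall.

    Accepts a scalar (returns a string) or an array-like (returns an array).
    """
    scalar = np.ndim(dates) == 0 and not isinstance(dates, (list, tuple, pd.Series))
    dt = pd.DatetimeIndex(pd.to_datetime(np.atleast_1d(np.asarray(dates, dtype=object))))
    if dt.isna().any():
        raise InputError("invalid date(s) passed to categorical_season")
    out = np.where(dt.month <= 6, WINTER_SPRING, SUMMER_FALL)
    return str(out[0]) if scalar else out


def _binary_outcome(sub: pd.DataFrame, outcome: str) -> np.ndarray:
    y = sub[outcome]
    if y.dtype == object or isinstance(y.dtype, pd.CategoricalDtype):
        y = binarize_diagnosis(y)
    y = y.to_numpy(float)
    vals = np.unique(y[~np.isnan(y)])
    if not np.all(np.isin(vals, [0.0, 1.0])):
        raise InputError(f"outcome {outcome!r} is not binary (values {vals})")
    return y


def _check_events(y: np.ndarray, n_params: int) -> None:
    n_cases = int(y.sum())
    n_ctrl = int(len(y) - n_cases)
    if n_cases == 0 or n_ctrl == 0:
        raise InputError(
            f"degenerate binary outcome: {n_cases} events / {n_ctrl} non-events"
        )
    if n_cases < MIN_EVENTS:
        raise InputError(f"need at least {MIN_EVENTS} events, got {n_cases}")
    if min(n_cases, n_ctrl) < 5 * n_params:
        logger.warning(
            "fewer than 5 events per parameter (%d events, %d params)",
            min(n_cases, n_ctrl), n_params,
        )


def _logit_fit(X: np.ndarray, y: np.ndarray, names: Sequence[str]):
    import statsmodels.api as sm
    from statsmodels.tools.sm_exceptions import PerfectSeparationError

    try:
        res = sm.Logit(y, X).fit(disp=0, method="newton", maxiter=100, tol=1e-10)
    except PerfectSeparationError as exc:
        sep = _find_separating(X, y, names)
        raise FitError(f"complete separation detected (suspect columns: {sep})") from exc
    except np.linalg.LinAlgError as exc:
        raise FitError(f"logistic fit failed: {exc}") from exc
    if not res.mle_retvals.get("converged", False):
        sep = _find_separating(X, y, names)
        if sep:
            raise FitError(f"complete separation detected (suspect columns: {sep})")
        raise FitError(
            f"logistic fit did not converge: {res.mle_retvals}"
        )
    return res


def _find_separating(X: np.ndarray, y: np.ndarray, names: Sequence[str]) -> list[str]:
    """Heuristic: binary columns that perfectly split cases from controls."""
    sep = []
    for j, name in enumerate(names):
        if name == "intercept":
            continue
        col = X[:, j]
        vals = np.unique(col)
        if len(vals) != 2:
            continue
        hi, lo = col == vals.max(), col == vals.min()
        if (y[hi].min(initial=1) > y[lo].max(initial=0)) or \
           (y[lo].min(initial=1) > y[hi].max(initial=0)):
            sep.append(name)
    return sep


def fit_seasonal_logistic(
    table: pd.DataFrame,
    outcome: str = "diagnosis",
    covariates: Sequence[str] = (),
    *,
    date_col: str = "assess_date",
    cohort_col: str | None = "cohort",
    period_days: float = PERIOD_DAYS,
) -> LogisticSeasonalFit:
    """Logistic model with the cos/sin quadrature pair; 2-df LRT vs reduced."""
    covariates = list(covariates)
    if (
        cohort_col
        and cohort_col in table.columns
        and cohort_col not in covariates
        and table[cohort_col].dropna().nunique() > 1
    ):
        covariates.append(cohort_col)
    sub, _ = complete_cases(table, [outcome, date_col] + covariates)
    y = _binary_outcome(sub, outcome)
    keep = ~np.isnan(y)
    sub, y = sub[keep], y[keep]
    theta = date_to_angle(sub[date_col].to_numpy(), period_days)
    Xc, names_c = build_design(sub, covariates, add_intercept=True)
    X = np.column_stack([Xc[:, :1], np.cos(theta), np.sin(theta), Xc[:, 1:]])
    names = ["intercept", "cos", "sin"] + names_c[1:]
    _check_events(y, X.shape[1])
    check_full_rank(X, names)

    full = _logit_fit(X, y, names)
    red = _logit_fit(Xc, y, names_c)
    dev_full = float(-2.0 * full.llf)
    dev_red = float(-2.0 * red.llf)
    delta = dev_full - dev_red  # <= 0
    p_lrt = float(stats.chi2.sf(max(-delta, 0.0), 2))

    params = dict(zip(names, map(float, full.params)))
    ses = dict(zip(names, map(float, full.bse)))
    return LogisticSeasonalFit(
        beta_cos=params["cos"],
        beta_sin=params["sin"],
        covariate_betas=params,
        covariate_se=ses,
        deviance_full=dev_full,
        deviance_reduced=dev_red,
        deviance_delta=delta,
        p_lrt=p_lrt,
        n_cases=int(y.sum()),
        n_total=len(y),
        converged=bool(full.mle_retvals.get("converged", False)),
    )


def season_odds_ratio(
    table: pd.DataFrame,
    outcome: str = "diagnosis",
    covariates: Sequence[str] = (),
    *,
    date_col: str = "assess_date",
    cohort_col: str | None = "cohort",
    alpha: float = 0.05,
) -> SeasonORFit:
    """Odds ratio for winter/spring vs summer/fall with Wald CI and LRT.

    With no covariates this reduces exactly to the 2x2 cross-product ratio.
    """
    covariates = list(covariates)
    if (
        cohort_col
        and cohort_col in table.columns
        and cohort_col not in covariates
        and table[cohort_col].dropna().nunique() > 1
    ):
        covariates.append(cohort_col)
    sub, _ = complete_cases(table, [outcome, date_col] + covariates)
    y = _binary_outcome(sub, outcome)
    keep = ~np.isnan(y)
    sub, y = sub[keep], y[keep]
    season = categorical_season(sub[date_col].to_numpy())
    ws = (season == WINTER_SPRING).astype(float)

    for label, mask in ((WINTER_SPRING, ws == 1), (SUMMER_FALL, ws == 0)):
        if mask.sum() == 0 or y[mask].sum() == 0 or (1 - y[mask]).sum() == 0:
            raise InputError(
                f"season stratum {label!r} lacks events and/or non-events"
            )

    Xc, names_c = build_design(sub, covariates, add_intercept=True)
    X = np.column_stack([Xc[:, :1], ws, Xc[:, 1:]])
    names = ["intercept", "season[winter_spring]"] + names_c[1:]
    _check_events(y, X.shape[1])
    check_full_rank(X, names)

    full = _logit_fit(X, y, names)
    red = _logit_fit(Xc, y, names_c)
    delta = float(-2.0 * full.llf) - float(-2.0 * red.llf)
    p_lrt = float(stats.chi2.sf(max(-delta, 0.0), 1))

    beta = float(full.params[1])
    se = float(full.bse[1])
    zcrit = float(stats.norm.isf(alpha / 2.0))
    ci = (float(np.exp(beta - zcrit * se)), float(np.exp(beta + zcrit * se)))
    p_wald = float(2.0 * stats.norm.sf(abs(beta / se))) if se > 0 else 0.0
    return SeasonORFit(
        season_or=float(np.exp(beta)),
        season_or_ci=ci,
        beta_season=beta,
        se_season=se,
        p_wald=p_wald,
        deviance_delta=delta,
        p_lrt=p_lrt,
        covariate_betas=dict(zip(names, map(float, full.params))),
        n_cases=int(y.sum()),
        n_total=len(y),
        n_winter_spring=int(ws.sum()),
        n_summer_fall=int((1 - ws).sum()),
    )
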