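"""Single-component cosinor regression with covariates.

Fits ordinary least squares of an outcome on ``[1, cos(theta), sin(theta),
covariates]`` where ``theta`` is the annual angle of the assessment date.  The
quadrature (cos + sin) pair leaves the phase free; rhythmicity is tested with a
2-df nested F-test against the model without both quadrature terms.  Derived
quantities: amplitude, acrophase/nadir timing, standardized amplitude
(amplitude / reference SD), and the age-equivalent effect size
(2 * amplitude / |beta_age|).  Confidence intervals come from a participant-level
percentile bootstrap.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .design import build_design, check_full_rank, complete_cases, nested_f, ols
from .exceptions import FitError, InputError
from .timeangles import PERIOD_DAYS, TWO_PI, angle_to_day, date_to_angle, wrap_day

logger = logging.getLogger(__name__)

MIN_ROWS = 10
AGE_BETA_TOL = 1e-8


@dataclass
class SeasonalFit:
    """Result of a single cosinor fit."""

    outcome: str
    beta_cos: float
    beta_sin: float
    covariate_betas: dict[str, float]
    covariate_se: dict[str, float]
    amplitude: float
    acrophase_rad: float
    acrophase_date: float
    nadir_date: float
    amplitude_std: float
    sd_ref: float
    f_stat: float
    df_num: int
    df_den: int
    p_rhythm: float
    n_used: int
    n_dropped: int
    period_days: float = PERIOD_DAYS
    residual_sd: float = float("nan")
    amplitude_ci: tuple[float, float] | None = None
    amplitude_std_ci: tuple[float, float] | None = None
    age_equiv_years: float | None = None
    age_equiv_ci: tuple[float, float] | None = None
    age_equiv_defined: bool = field(default=False)

    def to_dict(self) -> dict:
        return asdict(self)


def amplitude_acrophase(beta_cos: float, beta_sin: float) -> tuple[float, float]:
    """Amplitude and acrophase (radians in [0, 2*pi)) from the quadrature pair.

    (0, 0) maps to amplitude 0 with acrophase 0 by convention.
    """
    amp = math.hypot(beta_cos, beta_sin)
    if amp == 0.0:
        return 0.0, 0.0
    acro = math.atan2(beta_sin, beta_cos) % TWO_PI
    return amp, acro


def standardized_amplitude(amplitude: float, sd_ref: float) -> float:
    """Amplitude expressed in SD units of the reference sample."""
    if sd_ref <= 0:
        raise InputError(f"sd_ref must be > 0, got {sd_ref}")
    return amplitude / sd_ref


def age_equivalent(amplitude: float, beta_age: float,
                   tol: float = AGE_BETA_TOL) -> float:
    """Peak-to-trough difference expressed in years of the fitted age effect."""
    if abs(beta_age) < tol:
        raise FitError(
            f"age coefficient {beta_age!r} is below tolerance {tol}; "
            "age-equivalence is undefined"
        )
    return 2.0 * amplitude / abs(beta_age)


def _prepare(table: pd.DataFrame, outcome: str, covariates: Sequence[str],
             date_col: str, cohort_col: str | None):
    covariates = list(covariates)
    if (
        cohort_col
        and cohort_col in table.columns
        and cohort_col not in covariates
        and table[cohort_col].dropna().nunique() > 1
    ):
        covariates.append(cohort_col)
        logger.info("added %r as a fixed effect (multiple cohorts present)", cohort_col)
    cols = [outcome, date_col] + covariates
    if outcome in table.columns and table[outcome].notna().sum() == 0:
        raise InputError(f"outcome column {outcome!r} is entirely missing")
    sub, n_dropped = complete_cases(table, cols)
    if len(sub) < MIN_ROWS:
        raise InputError(
            f"need at least {MIN_ROWS} complete rows, got {len(sub)}"
        )
    return sub, covariates, n_dropped


def _design_with_quadrature(sub: pd.DataFrame, covariates: Sequence[str],
                            date_col: str, period_days: float):
    theta = date_to_angle(sub[date_col].to_numpy(), period_days)
    Xc, names_c = build_design(sub, covariates, add_intercept=True)
    X = np.column_stack([Xc[:, :1], np.cos(theta), np.sin(theta), Xc[:, 1:]])
    names = ["intercept", "cos", "sin"] + names_c[1:]
    return X, names, Xc, names_c


def _fit_arrays(X, names, Xc, names_c, y, period_days, sd_ref, outcome,
                n_dropped, age_col):
    check_full_rank(X, names)
    full = ols(X, y, names)
    red = ols(Xc, y, names_c, compute_se=False)
    f_stat, p = nested_f(red.rss, full.rss, 2, full.df_resid)

    beta_cos = full.coef("cos")
    beta_sin = full.coef("sin")
    amp, acro = amplitude_acrophase(beta_cos, beta_sin)
    acro_day = angle_to_day(acro, period_days)
    nadir_day = wrap_day(acro_day + period_days / 2.0, period_days)

    if sd_ref is None:
        sd_ref = float(np.std(y, ddof=1))
    if sd_ref > 0:
        amp_std = standardized_amplitude(amp, sd_ref)
    else:
        logger.warning("outcome SD is 0; standardized amplitude undefined")
        amp_std = float("nan")

    cov_betas = {n: float(b) for n, b in zip(full.names, full.beta)}
    cov_se = {n: float(s) for n, s in zip(full.names, full.se)}

    fit = SeasonalFit(
        outcome=outcome,
        beta_cos=beta_cos,
        beta_sin=beta_sin,
        covariate_betas=cov_betas,
        covariate_se=cov_se,
        amplitude=amp,
        acrophase_rad=acro,
        acrophase_date=float(acro_day),
        nadir_date=float(nadir_day),
        amplitude_std=amp_std,
        sd_ref=sd_ref,
        f_stat=f_stat,
        df_num=2,
        df_den=full.df_resid,
        p_rhythm=p,
        n_used=full.n,
        n_dropped=n_dropped,
        period_days=period_days,
        residual_sd=float(np.sqrt(full.sigma2)) if full.df_resid > 0 else float("nan"),
    )
    if age_col in cov_betas:
        b_age = cov_betas[age_col]
        if abs(b_age) >= AGE_BETA_TOL:
            fit.age_equiv_years = age_equivalent(amp, b_age)
            fit.age_equiv_defined = True
        else:
            logger.warning("age coefficient ~0; age-equivalence flagged undefined")
    return fit


def fit_cosinor(
    table: pd.DataFrame,
    outcome: str,
    covariates: Sequence[str] = (),
    *,
    date_col: str = "assess_date",
    id_col: str = "participant_id",
    cohort_col: str | None = "cohort",
    period_days: float = PERIOD_DAYS,
    sd_ref: float | None = None,
    age_col: str = "age_years",
    n_boot: int = 0,
    seed: int | None = None,
) -> SeasonalFit:
    """Fit the free-phase annual cosine model to a continuous outcome.

    Parameters
    ----------
    table : long-format table, one row per participant-assessment
    outcome, covariates : column names; categorical covariates are dummy-coded
    cohort_col : added automatically as a fixed effect when the column exists
        with more than one level (pass None to disable)
    sd_ref : reference SD for the standardized amplitude; defaults to the SD
        of the outcome over the analysis sample
    n_boot : if > 0, attach percentile-bootstrap CIs (participant resampling)
    """
    sub, covariates, n_dropped = _prepare(table, outcome, covariates,
                                          date_col, cohort_col)
    X, names, Xc, names_c = _design_with_quadrature(sub, covariates, date_col,
                                                    period_days)
    y = sub[outcome].to_numpy(float)
    fit = _fit_arrays(X, names, Xc, names_c, y, period_days, sd_ref, outcome,
                      n_dropped, age_col)
    if n_boot > 0:
        ci = bootstrap_ci(table, outcome, covariates, date_col=date_col,
                          id_col=id_col, cohort_col=None, period_days=period_days,
                          sd_ref=sd_ref, age_col=age_col, n_boot=n_boot, seed=seed)
        fit.amplitude_ci = ci["amplitude"]
        fit.amplitude_std_ci = ci["amplitude_std"]
        fit.age_equiv_ci = ci.get("age_equiv_years")
    return fit


def rhythm_test(
    table: pd.DataFrame,
    outcome: str,
    covariates: Sequence[str] = (),
    *,
    date_col: str = "assess_date",
    cohort_col: str | None = "cohort",
    period_days: float = PERIOD_DAYS,
) -> tuple[float, int, int, float]:
    """Nested F-test of the cosine/sine pair: returns (F, df_num, df_den, p)."""
    fit = fit_cosinor(table, outcome, covariates, date_col=date_col,
                      cohort_col=cohort_col, period_days=period_days)
    return fit.f_stat, fit.df_num, fit.df_den, fit.p_rhythm


def bootstrap_ci(
    table: pd.DataFrame,
    outcome: str,
    covariates: Sequence[str] = (),
    *,
    date_col: str = "assess_date",
    id_col: str = "participant_id",
    cohort_col: str | None = "cohort",
    period_days: float = PERIOD_DAYS,
    sd_ref: float | None = None,
    age_col: str = "age_years",
    n_boot: int = 1000,
    seed: int | None = None,
    max_retries: int = 100,
) -> dict:
    """Participant-level case-resampling percentile bootstrap.

    Returns 2.5/97.5 percentile intervals for amplitude, standardized
    amplitude, and (when the age coefficient is in the model) the
    age-equivalent years.  Rank-deficient resamples are redrawn (logged), up
    to `max_retries` extra draws in total.
    """
    if n_boot < 200:
        raise InputError(f"n_boot must be >= 200, got {n_boot}")
    sub, covariates, _ = _prepare(table, outcome, covariates, date_col, cohort_col)
    X, names, Xc, names_c = _design_with_quadrature(sub, covariates, date_col,
                                                    period_days)
    y = sub[outcome].to_numpy(float)
    p_full = X.shape[1]
    has_age = age_col in names
    age_idx = names.index(age_col) if has_age else -1

    if id_col in sub.columns:
        codes, _ = pd.factorize(sub[id_col])
        groups = [np.flatnonzero(codes == g) for g in range(codes.max() + 1)]
    else:
        groups = [np.array([i]) for i in range(len(sub))]
    n_groups = len(groups)

    rng = np.random.default_rng(seed)
    amps = np.empty(n_boot)
    amp_stds = np.empty(n_boot)
    age_eqs = np.empty(n_boot) if has_age else None
    retries = 0
    b = 0
    while b < n_boot:
        pick = rng.integers(0, n_groups, n_groups)
        rows = np.concatenate([groups[g] for g in pick])
        Xb, yb = X[rows], y[rows]
        beta, _, rank, _ = np.linalg.lstsq(Xb, yb, rcond=None)
        if rank < p_full:
            retries += 1
            if retries > max_retries:
                raise FitError("too many rank-deficient bootstrap resamples")
            logger.info("redrawing rank-deficient bootstrap resample")
            continue
        amp, _ = amplitude_acrophase(beta[1], beta[2])
        sref = sd_ref if sd_ref is not None else float(np.std(yb, ddof=1))
        amps[b] = amp
        amp_stds[b] = amp / sref
        if has_age:
            b_age = beta[age_idx]
            age_eqs[b] = 2.0 * amp / abs(b_age) if abs(b_age) >= AGE_BETA_TOL else np.nan
        b += 1

    def pct(a):
        a = a[np.isfinite(a)]
        return (float(np.percentile(a, 2.5)), float(np.percentile(a, 97.5)))

    out = {"amplitude": pct(amps), "amplitude_std": pct(amp_stds),
           "n_redrawn": retries}
    if has_age:
        out["age_equiv_years"] = pct(age_eqs)
    return out
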