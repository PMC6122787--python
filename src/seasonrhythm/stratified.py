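"""Group-modulated cosinor models and confounder-adjustment sweeps.

A binary group (e.g., pathological AD) is allowed to shift both the level
(main effect) and the rhythm (group x cos, group x sin interactions) of an
outcome.  The rhythmicity difference is a joint 2-df F-test on the two
interaction terms; the level difference is the t-test on the main effect.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, asdict
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .cosinor import SeasonalFit, amplitude_acrophase, fit_cosinor
from .design import build_design, check_full_rank, complete_cases, nested_f, ols
from .exceptions import InputError
from .timeangles import PERIOD_DAYS, angle_to_day, date_to_angle, wrap_day

logger = logging.getLogger(__name__)


@dataclass
class GroupModulatedFit:
    outcome: str
    group_col: str
    group_levels: tuple
    group_level_beta: float
    group_level_se: float
    group_level_p: float
    group_rhythm_f: float
    group_rhythm_p: float
    per_group: dict
    covariate_betas: dict[str, float]
    n_per_group: dict
    n_used: int
    rss_full: float
    rss_pooled: float
    period_days: float = PERIOD_DAYS

    def to_dict(self) -> dict:
        return asdict(self)


def fit_group_modulated(
    table: pd.DataFrame,
    outcome: str,
    group: str,
    covariates: Sequence[str] = (),
    *,
    date_col: str = "assess_date",
    cohort_col: str | None = "cohort",
    period_days: float = PERIOD_DAYS,
) -> GroupModulatedFit:
    """OLS with group main effect plus group x cos and group x sin terms."""
    covariates = list(covariates)
    if (
        cohort_col
        and cohort_col in table.columns
        and cohort_col not in covariates
        and table[cohort_col].dropna().nunique() > 1
    ):
        covariates.append(cohort_col)
    sub, _ = complete_cases(table, [outcome, date_col, group] + covariates)
    levels = sorted(pd.unique(sub[group]))
    if len(levels) < 2:
        raise InputError(f"group column {group!r} has a single level: {levels}")
    if len(levels) > 2:
        raise InputError(f"group column {group!r} must be binary, got {levels}")
    g = (sub[group] == levels[1]).to_numpy(float)
    counts = {str(levels[0]): int((g == 0).sum()), str(levels[1]): int((g == 1).sum())}
    if min(counts.values()) < 10:
        raise InputError(f"each group needs >= 10 complete rows, got {counts}")

    theta = date_to_angle(sub[date_col].to_numpy(), period_days)
    c, s = np.cos(theta), np.sin(theta)
    Xc, names_c = build_design(sub, covariates, add_intercept=True)
    X_red = np.column_stack([Xc[:, :1], c, s, Xc[:, 1:], g])
    names_red = ["intercept", "cos", "sin"] + names_c[1:] + ["group"]
    X_full = np.column_stack([X_red, g * c, g * s])
    names_full = names_red + ["group:cos", "group:sin"]
    check_full_rank(X_full, names_full)

    y = sub[outcome].to_numpy(float)
    full = ols(X_full, y, names_full)
    red = ols(X_red, y, names_red, compute_se=False)
    f_int, p_int = nested_f(red.rss, full.rss, 2, full.df_resid)

    # pooled model without any group terms (for the nesting invariant)
    X_pool = np.column_stack([Xc[:, :1], c, s, Xc[:, 1:]])
    pooled = ols(X_pool, y, ["intercept", "cos", "sin"] + names_c[1:],
                 compute_se=False)

    b_level = full.coef("group")
    se_level = full.stderr("group")
    t_level = b_level / se_level if se_level > 0 else np.inf
    p_level = float(2.0 * stats.t.sf(abs(t_level), full.df_resid))

    bc, bs = full.coef("cos"), full.coef("sin")
    dbc, dbs = full.coef("group:cos"), full.coef("group:sin")
    per_group = {}
    for lev, (gc, gs) in ((levels[0], (bc, bs)), (levels[1], (bc + dbc, bs + dbs))):
        amp, acro = amplitude_acrophase(gc, gs)
        per_group[str(lev)] = {
            "beta_cos": gc,
            "beta_sin": gs,
            "amplitude": amp,
            "acrophase_rad": acro,
            "acrophase_date": float(angle_to_day(acro, period_days)),
            "nadir_date": float(wrap_day(angle_to_day(acro, period_days)
                                         + period_days / 2.0, period_days)),
        }

    return GroupModulatedFit(
        outcome=outcome,
        group_col=group,
        group_levels=tuple(levels),
        group_level_beta=b_level,
        group_level_se=se_level,
        group_level_p=p_level,
        group_rhythm_f=f_int,
        group_rhythm_p=p_int,
        per_group=per_group,
        covariate_betas={n: float(b) for n, b in zip(full.names, full.beta)},
        n_per_group=counts,
        n_used=full.n,
        rss_full=full.rss,
        rss_pooled=pooled.rss,
        period_days=period_days,
    )


def confounder_sweep(
    table: pd.DataFrame,
    outcome: str,
    confounder_sets: Sequence[Sequence[str]],
    base_covariates: Sequence[str] = (),
    *,
    labels: Sequence[str] | None = None,
    date_col: str = "assess_date",
    cohort_col: str | None = "cohort",
    period_days: float = PERIOD_DAYS,
    sd_ref: float | None = None,
) -> pd.DataFrame:
    """One cosinor fit per adjustment set (base covariates + the set).

    Each model keeps its own complete-case sample, so n_used can differ
    across rows.  Returns one row per set.
    """
    if len(confounder_sets) == 0:
        raise InputError("confounder_sets must not be empty")
    if labels is None:
        labels = ["+".join(s) if s else "base" for s in confounder_sets]
    rows = []
    for label, extra in zip(labels, confounder_sets):
        covs = list(base_covariates) + [c for c in extra
                                        if c not in base_covariates]
        fit = fit_cosinor(table, outcome, covs, date_col=date_col,
                          cohort_col=cohort_col, period_days=period_days,
                          sd_ref=sd_ref)
        rows.append({
            "adjustment": label,
            "covariates": ",".join(covs),
            "n_used": fit.n_used,
            "amplitude": fit.amplitude,
            "amplitude_std": fit.amplitude_std,
            "acrophase_date": fit.acrophase_date,
            "f_stat": fit.f_stat,
            "p_rhythm": fit.p_rhythm,
        })
    return pd.DataFrame(rows)


def effect_modifier_scan(
    table: pd.DataFrame,
    outcome: str,
    modifiers: Sequence[str],
    covariates: Sequence[str] = (),
    *,
    date_col: str = "assess_date",
    cohort_col: str | None = "cohort",
    period_days: float = PERIOD_DAYS,
) -> pd.DataFrame:
    """Per-modifier 2-df interaction test (modifier x cos, modifier x sin).

    One separate model per modifier.  Categorical modifiers are dummy-coded;
    the joint test then spans 2 * (levels - 1) df.
    """
    rows = []
    for mod in modifiers:
        covs = list(covariates)
        if (
            cohort_col
            and cohort_col in table.columns
            and cohort_col not in covs
            and mod != cohort_col
            and table[cohort_col].dropna().nunique() > 1
        ):
            covs.append(cohort_col)
        sub, _ = complete_cases(table, [outcome, date_col, mod] + covs)
        theta = date_to_angle(sub[date_col].to_numpy(), period_days)
        c, s = np.cos(theta), np.sin(theta)
        Xc, names_c = build_design(sub, covs, add_intercept=True)
        Xm, names_m = build_design(sub, [mod], add_intercept=False)
        base = np.column_stack([Xc[:, :1], c, s, Xc[:, 1:], Xm])
        names_b = ["intercept", "cos", "sin"] + names_c[1:] + names_m
        inter = np.column_stack([Xm * c[:, None], Xm * s[:, None]])
        names_i = [f"{n}:cos" for n in names_m] + [f"{n}:sin" for n in names_m]
        X_full = np.column_stack([base, inter])
        check_full_rank(X_full, names_b + names_i)
        y = sub[outcome].to_numpy(float)
        full = ols(X_full, y, names_b + names_i, compute_se=False)
        red = ols(base, y, names_b, compute_se=False)
        df_num = inter.shape[1]
        f, p = nested_f(red.rss, full.rss, df_num, full.df_resid)
        rows.append({"modifier": mod, "f_stat": f, "df_num": df_num,
                     "df_den": full.df_resid, "p_interaction": p,
                     "n_used": full.n})
    return pd.DataFrame(rows)
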