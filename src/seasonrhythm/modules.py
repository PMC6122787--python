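"""Gene co-expression module scoring, rhythm scans, and permutation FWER control.

Module scores are the per-sample mean of member-gene z-scores.  Each module is
tested for seasonal rhythmicity (cosinor on date of death) and association with
cognition proximate to death; family-wise adjusted p-values come from
max-statistic permutations of the gene -> module assignment vector (module
sizes preserved).  A module is a candidate when it is (1) rhythmic after
adjustment, (2) in phase or antiphase with the cognition rhythm within a
circular window (default one sixth of the period, ~2 months), and (3)
associated with cognition after adjustment.
"""

from __future__ import annotations

import logging
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .cosinor import fit_cosinor
from .design import build_design, check_full_rank, complete_cases
from .exceptions import InputError
from .timeangles import PERIOD_DAYS, circular_distance_days, date_to_angle

logger = logging.getLogger(__name__)

IN_PHASE = "in_phase"
ANTI_PHASE = "anti_phase"
NEITHER = "neither"


# ---------------------------------------------------------------------------
# scoring

def normalize_expression(expr: pd.DataFrame) -> pd.DataFrame:
    """Per-gene z-scores across samples (sample SD, ddof=1).

    Genes with zero variance are dropped with a logged warning.
    """
    values = expr.to_numpy(float)
    mean = values.mean(axis=1, keepdims=True)
    sd = values.std(axis=1, ddof=1, keepdims=True)
    keep = sd[:, 0] > 0
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.warning("dropping %d zero-variance genes: %s", n_dropped,
                       list(expr.index[~keep][:10]))
    z = (values[keep] - mean[keep]) / sd[keep]
    return pd.DataFrame(z, index=expr.index[keep], columns=expr.columns)


def _as_assignment_series(defs) -> pd.Series:
    """Accept a gene->module Series or a {module: [genes]} mapping."""
    if isinstance(defs, pd.Series):
        return defs.dropna()
    if isinstance(defs, Mapping):
        pairs = [(g, m) for m, genes in defs.items() for g in genes]
        genes = [g for g, _ in pairs]
        if len(set(genes)) != len(genes):
            raise InputError("a gene may belong to at most one module")
        return pd.Series({g: m for g, m in pairs})
    raise InputError(f"unsupported module definition type: {type(defs)}")


def summarize_modules(z: pd.DataFrame, defs, *,
                      min_fraction: float = 0.5) -> pd.DataFrame:
    """Module x sample matrix of unweighted means of member-gene z-scores.

    Modules with fewer than `min_fraction` of their genes present in `z` are
    skipped (logged).
    """
    assign = _as_assignment_series(defs)
    scores = {}
    for module, genes in assign.groupby(assign).groups.items():
        present = z.index.intersection(genes)
        if len(present) == 0 or len(present) / len(genes) < min_fraction:
            logger.warning("skipping module %s: %d/%d genes present",
                           module, len(present), len(genes))
            continue
        scores[module] = z.loc[present].to_numpy().mean(axis=0)
    if not scores:
        raise InputError("no module had sufficient gene overlap with the matrix")
    out = pd.DataFrame(scores, index=z.columns).T
    return out.sort_index()


# ---------------------------------------------------------------------------
# per-module scans

def module_rhythm_scan(
    scores: pd.DataFrame,
    meta: pd.DataFrame,
    covariates: Sequence[str] = (),
    *,
    date_col: str = "death_date",
    period_days: float = PERIOD_DAYS,
) -> tuple[pd.DataFrame, dict]:
    """Cosinor fit per module score (raw p-values).

    Returns (summary table indexed by module, dict of SeasonalFit objects).
    """
    samples = scores.columns.intersection(meta.index)
    if len(samples) < 10:
        raise InputError(f"only {len(samples)} samples shared between scores and meta")
    fits, rows = {}, []
    for module in scores.index:
        tbl = meta.loc[samples].copy()
        tbl["_score"] = scores.loc[module, samples].to_numpy(float)
        fit = fit_cosinor(tbl, "_score", covariates, date_col=date_col,
                          cohort_col=None, period_days=period_days)
        fits[module] = fit
        rows.append({
            "module": module, "n_used": fit.n_used,
            "amplitude": fit.amplitude, "amplitude_std": fit.amplitude_std,
            "acrophase_date": fit.acrophase_date, "nadir_date": fit.nadir_date,
            "f_stat": fit.f_stat, "p_rhythm": fit.p_rhythm,
        })
    return pd.DataFrame(rows).set_index("module").sort_index(), fits


def cognition_association_scan(
    scores: pd.DataFrame,
    cognition: pd.Series,
    meta: pd.DataFrame | None = None,
    covariates: Sequence[str] = (),
) -> pd.DataFrame:
    """Per-module OLS of cognition on the module score plus covariates."""
    samples = scores.columns.intersection(cognition.dropna().index)
    if meta is not None and covariates:
        meta_cc, _ = complete_cases(meta, list(covariates))
        samples = samples.intersection(meta_cc.index)
    if len(samples) < 10:
        raise InputError(f"only {len(samples)} matched samples")
    y = cognition.loc[samples].to_numpy(float)
    if meta is not None and covariates:
        Xc, names_c = build_design(meta.loc[samples], list(covariates),
                                   add_intercept=True)
    else:
        Xc, names_c = np.ones((len(samples), 1)), ["intercept"]
    check_full_rank(Xc, names_c)
    rows = []
    for module in scores.index:
        x = scores.loc[module, samples].to_numpy(float)
        X = np.column_stack([Xc, x])
        beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ beta
        df = len(y) - X.shape[1]
        sigma2 = resid @ resid / df
        xtx_inv = np.linalg.pinv(X.T @ X)
        se = float(np.sqrt(sigma2 * xtx_inv[-1, -1]))
        t = beta[-1] / se if se > 0 else np.inf
        rows.append({"module": module, "beta": float(beta[-1]), "se": se,
                     "t_stat": float(t),
                     "p_raw": float(2.0 * stats.t.sf(abs(t), df)),
                     "n_used": len(y)})
    return pd.DataFrame(rows).set_index("module").sort_index()


# ---------------------------------------------------------------------------
# permutation adjustment (max-statistic, add-one correction)

def _fwl_rhythm_prep(meta_sub: pd.DataFrame, covariates, date_col, period_days):
    theta = date_to_angle(meta_sub[date_col].to_numpy(), period_days)
    CS = np.column_stack([np.cos(theta), np.sin(theta)])
    Xc, names_c = build_design(meta_sub, list(covariates), add_intercept=True)
    check_full_rank(np.column_stack([Xc, CS]), names_c + ["cos", "sin"])
    Q, _ = np.linalg.qr(Xc)
    CSr = CS - Q @ (Q.T @ CS)
    k_full = Xc.shape[1] + 2
    return Q, CSr, k_full


def _rhythm_f_stats(Y: np.ndarray, Q: np.ndarray, CSr: np.ndarray,
                    k_full: int) -> np.ndarray:
    """Vectorized 2-df cosinor F statistics for columns of Y (samples x modules)."""
    n = Y.shape[0]
    Yr = Y - Q @ (Q.T @ Y)
    B, _, _, _ = np.linalg.lstsq(CSr, Yr, rcond=None)
    resid = Yr - CSr @ B
    rss_f = np.einsum("ij,ij->j", resid, resid)
    rss_r = np.einsum("ij,ij->j", Yr, Yr)
    df_den = n - k_full
    with np.errstate(divide="ignore", invalid="ignore"):
        f = ((rss_r - rss_f) / 2.0) / (rss_f / df_den)
    return np.where(rss_f <= 0, np.inf, f)


def _cognition_t_stats(Y: np.ndarray, Q: np.ndarray, y_resid: np.ndarray,
                       k0: int) -> np.ndarray:
    """Vectorized |t| for cognition ~ module score + covariates (FWL)."""
    n = Y.shape[0]
    Yr = Y - Q @ (Q.T @ Y)
    xx = np.einsum("ij,ij->j", Yr, Yr)
    xy = Yr.T @ y_resid
    with np.errstate(divide="ignore", invalid="ignore"):
        b = xy / xx
    yy = float(y_resid @ y_resid)
    rss = yy - b * xy
    df = n - k0 - 1
    with np.errstate(divide="ignore", invalid="ignore"):
        t = b / np.sqrt(np.maximum(rss, 0.0) / df / xx)
    return np.abs(np.where(np.isfinite(t), t, np.inf))


def permutation_adjust(
    z: pd.DataFrame,
    defs,
    *,
    statistic="rhythm",
    meta: pd.DataFrame | None = None,
    covariates: Sequence[str] = (),
    date_col: str = "death_date",
    period_days: float = PERIOD_DAYS,
    cognition: pd.Series | None = None,
    n_perm: int = 10000,
    seed: int | None = None,
    null: str = "modules",
    min_fraction: float = 0.5,
) -> pd.DataFrame:
    """Family-wise adjusted per-module p-values by max-statistic permutation.

    For each permutation the gene -> module assignment vector is shuffled
    (module sizes preserved), module scores are recomputed, and the chosen
    statistic (rhythmicity F or cognition-association |t|) is evaluated; the
    adjusted p for module m is (1 + #{b : max_stat_b >= stat_m}) / (n_perm + 1).
    `statistic` may be "rhythm", "cognition", or a sequence of both (the
    expensive permutation scores are then shared).  `null="dates"` instead
    permutes the sample dates (and cognition), keeping gene assignments fixed.
    """
    if n_perm < 100:
        raise InputError(f"n_perm must be >= 100, got {n_perm}")
    if n_perm < 999:
        logger.warning("n_perm=%d limits attainable adjusted p to %.4g",
                       n_perm, 1.0 / (n_perm + 1))
    statistics = [statistic] if isinstance(statistic, str) else list(statistic)
    for st in statistics:
        if st not in ("rhythm", "cognition"):
            raise InputError(f"unknown statistic {st!r}")
    if "rhythm" in statistics and meta is None:
        raise InputError("statistic 'rhythm' requires sample meta")
    if "cognition" in statistics and cognition is None:
        raise InputError("statistic 'cognition' requires a cognition vector")
    if null not in ("modules", "dates"):
        raise InputError(f"unknown null {null!r}")

    assign = _as_assignment_series(defs)
    genes = z.index.intersection(assign.index)
    assign = assign.loc[genes]
    # drop modules with insufficient coverage, mirroring summarize_modules
    full_counts = _as_assignment_series(defs).value_counts()
    cov_counts = assign.value_counts()
    keep_modules = [m for m in cov_counts.index
                    if cov_counts[m] / full_counts[m] >= min_fraction]
    assign = assign[assign.isin(keep_modules)]
    # canonical gene order => invariance to input labelling/ordering
    order = assign.reset_index()
    order.columns = ["gene", "module"]
    order = order.sort_values(["module", "gene"], key=lambda s: s.astype(str))
    modules = sorted(pd.unique(order["module"]), key=str)
    sizes = order["module"].value_counts().loc[modules].to_numpy()
    offsets = np.concatenate([[0], np.cumsum(sizes)[:-1]])

    samples = z.columns
    if meta is not None:
        cols = list(covariates) + ([date_col] if "rhythm" in statistics else [])
        meta_cc, _ = complete_cases(meta, cols)
        samples = samples.intersection(meta_cc.index)
    if cognition is not None:
        samples = samples.intersection(cognition.dropna().index)
    samples = pd.Index(samples)
    if len(samples) < 10:
        raise InputError(f"only {len(samples)} usable samples")

    Z = z.loc[order["gene"], samples].to_numpy(float)
    inv_sizes = (1.0 / sizes)[:, None]
    obs_scores = np.add.reduceat(Z, offsets, axis=0) * inv_sizes  # modules x samples

    prep = {}
    if "rhythm" in statistics:
        Qr, CSr, k_full = _fwl_rhythm_prep(meta.loc[samples], covariates,
                                           date_col, period_days)
        prep["rhythm"] = (Qr, CSr, k_full)
    if "cognition" in statistics:
        if meta is not None and covariates:
            Xc, names_c = build_design(meta.loc[samples], list(covariates),
                                       add_intercept=True)
        else:
            Xc, names_c = np.ones((len(samples), 1)), ["intercept"]
        check_full_rank(Xc, names_c)
        Qc, _ = np.linalg.qr(Xc)
        ycog = cognition.loc[samples].to_numpy(float)
        y_resid = ycog - Qc @ (Qc.T @ ycog)
        prep["cognition"] = (Qc, y_resid, Xc.shape[1])

    def compute_stats(S):  # S: modules x samples
        out = {}
        Y = S.T
        if "rhythm" in statistics:
            Qr, CSr_, k_full = prep["rhythm"]
            out["rhythm"] = _rhythm_f_stats(Y, Qr, CSr_, k_full)
        if "cognition" in statistics:
            Qc, y_resid, k0 = prep["cognition"]
            out["cognition"] = _cognition_t_stats(Y, Qc, y_resid, k0)
        return out

    obs = compute_stats(obs_scores)

    rng = np.random.default_rng(seed)
    exceed = {st: np.zeros(len(modules)) for st in statistics}
    n_genes = Z.shape[0]
    n_samp = len(samples)
    for _ in range(n_perm):
        if null == "modules":
            perm = rng.permutation(n_genes)
            S = np.add.reduceat(Z.take(perm, axis=0), offsets, axis=0) * inv_sizes
            stats_b = compute_stats(S)
        else:  # permute dates / cognition across samples
            perm = rng.permutation(n_samp)
            stats_b = {}
            Y = obs_scores.T
            if "rhythm" in statistics:
                Qr, CSr_, k_full = prep["rhythm"]
                stats_b["rhythm"] = _rhythm_f_stats(Y, Qr, CSr_[perm], k_full)
            if "cognition" in statistics:
                Qc, y_resid, k0 = prep["cognition"]
                stats_b["cognition"] = _cognition_t_stats(Y, Qc, y_resid[perm], k0)
        for st in statistics:
            exceed[st] += stats_b[st].max() >= obs[st]

    out = pd.DataFrame(index=pd.Index(modules, name="module"))
    n = n_samp
    for st in statistics:
        out[f"stat_{st}"] = obs[st]
        if st == "rhythm":
            _, _, k_full = prep["rhythm"]
            out["p_raw_rhythm"] = stats.f.sf(obs[st], 2, n - k_full)
        else:
            _, _, k0 = prep["cognition"]
            out["p_raw_cognition"] = 2.0 * stats.t.sf(obs[st], n - k0 - 1)
        out[f"p_adj_{st}"] = (exceed[st] + 1.0) / (n_perm + 1.0)
    return out


# ---------------------------------------------------------------------------
# selection and phenotype grid

def phase_concordance(
    module_acrophase_date: float,
    cognition_acrophase_date: float,
    window_days: float | None = None,
    period_days: float = PERIOD_DAYS,
) -> str:
    """Classify a module acrophase vs the cognition acrophase on the circle.

    in_phase if within `window_days` (default period/6, ~2 months) of the
    cognition acrophase, anti_phase if within the window of the cognition
    nadir, else neither.  Boundaries are inclusive (<= window).
    """
    if window_days is None:
        window_days = period_days / 6.0
    d_acro = circular_distance_days(module_acrophase_date,
                                    cognition_acrophase_date, period_days)
    d_nadir = circular_distance_days(module_acrophase_date,
                                     cognition_acrophase_date + period_days / 2.0,
                                     period_days)
    if d_acro <= window_days:
        return IN_PHASE
    if d_nadir <= window_days:
        return ANTI_PHASE
    return NEITHER


def select_candidate_modules(
    rhythm_table: pd.DataFrame,
    p_rhythm_adj: pd.Series,
    cognition_table: pd.DataFrame,
    p_cog_adj: pd.Series,
    cognition_acrophase_date: float,
    *,
    window_days: float | None = None,
    period_days: float = PERIOD_DAYS,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Conjunction of the three selection criteria, sorted by module id.

    rhythm_table is the output of :func:`module_rhythm_scan` (summary frame);
    cognition_table the output of :func:`cognition_association_scan`.
    """
    modules = sorted(rhythm_table.index.intersection(cognition_table.index), key=str)
    rows = []
    for m in modules:
        phase = phase_concordance(float(rhythm_table.loc[m, "acrophase_date"]),
                                  cognition_acrophase_date,
                                  window_days, period_days)
        in_phase_flag = phase in (IN_PHASE, ANTI_PHASE)
        pr = float(p_rhythm_adj.loc[m])
        pc = float(p_cog_adj.loc[m])
        rows.append({
            "module": m,
            "amplitude_std": float(rhythm_table.loc[m, "amplitude_std"]),
            "acrophase_date": float(rhythm_table.loc[m, "acrophase_date"]),
            "p_rhythm_adj": pr,
            "cognition_beta": float(cognition_table.loc[m, "beta"]),
            "p_cog_adj": pc,
            "phase": phase,
            "in_phase_flag": in_phase_flag,
            "selected_flag": (pr < alpha) and in_phase_flag and (pc < alpha),
        })
    return pd.DataFrame(rows).set_index("module")


def phenotype_correlation_grid(
    scores: pd.DataFrame,
    phenotypes: pd.DataFrame,
    *,
    min_pairs: int = 10,
    alpha: float = 0.05,
) -> dict[str, pd.DataFrame]:
    """Module x phenotype Spearman correlations with Bonferroni flags.

    Returns dict of frames: 'rho', 'p', 'z' (signed normal quantile for
    heatmaps), and boolean 'significant' (Bonferroni across the full grid).
    Cells with a constant variable or < min_pairs paired observations are NaN.
    """
    samples = scores.columns.intersection(phenotypes.index)
    rho = pd.DataFrame(index=scores.index, columns=phenotypes.columns, dtype=float)
    pval = rho.copy()
    for m in scores.index:
        x_all = scores.loc[m, samples].astype(float)
        for ph in phenotypes.columns:
            y_all = phenotypes.loc[samples, ph].astype(float)
            mask = x_all.notna() & y_all.notna()
            if mask.sum() < min_pairs:
                continue
            x, y = x_all[mask], y_all[mask]
            if x.nunique() < 2 or y.nunique() < 2:
                continue
            r, p = stats.spearmanr(x, y)
            rho.loc[m, ph] = r
            pval.loc[m, ph] = p
    n_tests = rho.size
    with np.errstate(divide="ignore"):
        z = np.sign(rho) * stats.norm.isf(np.clip(pval / 2.0, 1e-300, 1.0))
    sig = pval < (alpha / n_tests)
    return {"rho": rho, "p": pval, "z": z, "significant": sig}
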