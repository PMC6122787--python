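"""Design-matrix assembly and plain OLS helpers used by the fitting modules."""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np
import pandas as pd

from .exceptions import FitError, InputError

logger = logging.getLogger(__name__)


def complete_cases(df: pd.DataFrame, cols: Sequence[str]) -> tuple[pd.DataFrame, int]:
    """Strict complete-case filter on `cols`; returns (subset, n_dropped)."""
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise InputError(f"columns not found in table: {missing}")
    sub = df.dropna(subset=list(cols))
    n_dropped = len(df) - len(sub)
    if n_dropped:
        logger.info("complete-case filter dropped %d of %d rows", n_dropped, len(df))
    return sub, n_dropped


def _is_categorical(col: pd.Series) -> bool:
    return (
        col.dtype == object
        or isinstance(col.dtype, pd.CategoricalDtype)
        or col.dtype == bool
    )


def build_design(df: pd.DataFrame, columns: Sequence[str],
                 add_intercept: bool = True) -> tuple[np.ndarray, list[str]]:
    """Build a numeric design matrix.

    Numeric columns enter as-is; object/categorical/bool columns are
    dummy-coded with the first level (sorted) as reference.  Returns the
    matrix and the per-column names.
    """
    parts: list[np.ndarray] = []
    names: list[str] = []
    if add_intercept:
        parts.append(np.ones(len(df)))
        names.append("intercept")
    for c in columns:
        col = df[c]
        if _is_categorical(col):
            levels = sorted(pd.unique(col.astype(str)))
            for lev in levels[1:]:
                parts.append((col.astype(str) == lev).to_numpy(float))
                names.append(f"{c}[{lev}]")
        else:
            parts.append(col.to_numpy(float))
            names.append(c)
    X = np.column_stack(parts) if parts else np.empty((len(df), 0))
    return X, names


def check_full_rank(X: np.ndarray, names: Sequence[str], tol: float = 1e-8) -> None:
    """Raise FitError naming (near-)collinear columns if X is rank deficient."""
    if X.shape[1] == 0:
        return
    r = np.linalg.qr(X, mode="r")
    diag = np.abs(np.diag(r))
    scale = diag.max() if diag.max() > 0 else 1.0
    bad = [names[j] for j in range(len(diag)) if diag[j] < tol * scale]
    if bad:
        raise FitError(f"design matrix is rank deficient; collinear columns: {bad}")


class OLSResult:
    """Minimal OLS result: coefficients, residual sum of squares, SEs."""

    __slots__ = ("beta", "names", "rss", "df_resid", "n", "k", "se", "sigma2", "fitted")

    def __init__(self, X: np.ndarray, y: np.ndarray, names: Sequence[str],
                 compute_se: bool = True):
        n, k = X.shape
        beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
        fitted = X @ beta
        resid = y - fitted
        self.beta = beta
        self.names = list(names)
        self.fitted = fitted
        self.rss = float(resid @ resid)
        self.n = n
        self.k = k
        self.df_resid = n - k
        self.sigma2 = self.rss / self.df_resid if self.df_resid > 0 else np.nan
        if compute_se:
            xtx_inv = np.linalg.pinv(X.T @ X)
            self.se = np.sqrt(np.maximum(np.diag(xtx_inv), 0.0) * self.sigma2)
        else:
            self.se = None

    def coef(self, name: str) -> float:
        return float(self.beta[self.names.index(name)])

    def stderr(self, name: str) -> float:
        return float(self.se[self.names.index(name)])


def ols(X: np.ndarray, y: np.ndarray, names: Sequence[str],
        compute_se: bool = True) -> OLSResult:
    return OLSResult(X, y, names, compute_se=compute_se)


def nested_f(rss_reduced: float, rss_full: float, df_num: int,
             df_den: int) -> tuple[float, float]:
    """Nested-model F statistic and upper-tail p-value.

    Degenerate cases: a saturated full model (rss_full == 0) with any
    improvement gives F = inf / p = 0; no improvement at all gives F = 0 / p = 1.
    """
    from scipy import stats

    if df_den <= 0:
        raise FitError(f"no residual degrees of freedom (df_den={df_den})")
    num = max(rss_reduced - rss_full, 0.0) / df_num
    if rss_full <= 0.0:
        if num <= 0.0:
            return 0.0, 1.0
        return float("inf"), 0.0
    f = num / (rss_full / df_den)
    p = float(stats.f.sf(f, df_num, df_den))
    return float(f), p
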