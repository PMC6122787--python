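"""Transcription-factor binding-site proximity linking and module enrichment.

Genes are reduced to strand-aware TSS points (0-based); a gene is a target of
a TF when its TSS lies inside, or within `window_bp` of, any of that TF's
intervals on the same chromosome (BED dialect: 0-based half-open).  Per-module
enrichment is a logistic regression of module membership on the TF indicator
columns, Bonferroni-corrected across the TF catalogue.
"""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import FitError, InputError

logger = logging.getLogger(__name__)

DEFAULT_WINDOW_BP = 2000
DEFAULT_N_TF = 161
UNSTABLE_SE = 100.0


def bonferroni_threshold(n_tests: int, alpha: float = 0.05) -> float:
    """Per-test alpha for `n_tests` simultaneous tests."""
    if n_tests < 1:
        raise InputError(f"n_tests must be >= 1, got {n_tests}")
    return alpha / n_tests


def assign_tss(genes: pd.DataFrame) -> pd.DataFrame:
    """Strand-aware TSS point per gene (0-based coordinate).

    `genes` needs columns gene_id, chrom, start, end, strand (0-based
    half-open intervals).  TSS = start for '+', end - 1 for '-'.  Genes with
    missing/unknown strand are skipped with a warning.
    """
    bad_iv = genes[genes["start"] >= genes["end"]]
    if len(bad_iv):
        raise InputError(f"invalid intervals (start >= end): "
                         f"{bad_iv['gene_id'].tolist()[:5]}")
    known = genes["strand"].isin(["+", "-"])
    if (~known).any():
        logger.warning("skipping %d genes with missing strand: %s",
                       (~known).sum(), genes.loc[~known, "gene_id"].tolist()[:10])
    sub = genes[known]
    tss = np.where(sub["strand"] == "+", sub["start"], sub["end"] - 1)
    return pd.DataFrame({"gene_id": sub["gene_id"].to_numpy(),
                         "chrom": sub["chrom"].to_numpy(),
                         "tss": tss.astype(np.int64)})


def _merge_intervals(starts: np.ndarray, ends: np.ndarray):
    order = np.argsort(starts, kind="stable")
    s, e = starts[order], ends[order]
    ms, me = [s[0]], [e[0]]
    for i in range(1, len(s)):
        if s[i] <= me[-1]:
            me[-1] = max(me[-1], e[i])
        else:
            ms.append(s[i])
            me.append(e[i])
    return np.asarray(ms), np.asarray(me)


def _point_interval_distances(points: np.ndarray, starts: np.ndarray,
                              ends: np.ndarray) -> np.ndarray:
    """Min distance from each point to merged, sorted intervals (0 if inside)."""
    idx = np.searchsorted(starts, points, side="right")
    dist = np.full(len(points), np.iinfo(np.int64).max, dtype=np.int64)
    has_prev = idx > 0
    prev = np.clip(idx - 1, 0, None)
    inside = has_prev & (points < ends[prev])
    # gap to the end of the previous interval (0-based half-open: last base is end-1)
    gap_prev = np.where(has_prev, points - (ends[prev] - 1), np.iinfo(np.int64).max)
    has_next = idx < len(starts)
    nxt = np.clip(idx, 0, len(starts) - 1)
    gap_next = np.where(has_next, starts[nxt] - points, np.iinfo(np.int64).max)
    dist = np.minimum(np.where(has_prev, gap_prev, dist),
                      np.where(has_next, gap_next, dist))
    dist[inside] = 0
    return dist


def link_tfbs(tss: pd.DataFrame, tfbs: pd.DataFrame,
              window_bp: int = DEFAULT_WINDOW_BP) -> pd.DataFrame:
    """Gene x TF binary target matrix by TSS-to-interval proximity.

    `tss` is the output of :func:`assign_tss`; `tfbs` needs columns
    tf, chrom, start, end (0-based half-open).  Indicator is 1 iff the minimum
    distance from the TSS to any same-chromosome interval of that TF is
    <= window_bp (0 when the TSS falls inside an interval).
    """
    if window_bp < 0:
        raise InputError(f"window_bp must be >= 0, got {window_bp}")
    if (tfbs["start"] >= tfbs["end"]).any():
        raise InputError("tfbs contains invalid intervals (start >= end)")
    gene_chroms = set(tss["chrom"].unique())
    site_chroms = set(tfbs["chrom"].unique())
    if not gene_chroms & site_chroms:
        raise InputError(
            "no chromosome names shared between gene and TFBS files; "
            f"genes={sorted(gene_chroms)[:5]} tfbs={sorted(site_chroms)[:5]}"
        )
    orphan = gene_chroms - site_chroms
    if orphan:
        logger.warning("gene chromosomes with no TFBS entries: %s",
                       sorted(orphan)[:10])

    tfs = sorted(tfbs["tf"].unique())
    out = pd.DataFrame(0, index=pd.Index(tss["gene_id"], name="gene_id"),
                       columns=tfs, dtype=np.int8)
    points_by_chrom = {c: (g["tss"].to_numpy(np.int64), g["gene_id"].to_numpy())
                       for c, g in tss.groupby("chrom")}
    for (tf, chrom), grp in tfbs.groupby(["tf", "chrom"]):
        if chrom not in points_by_chrom:
            continue
        points, gene_ids = points_by_chrom[chrom]
        ms, me = _merge_intervals(grp["start"].to_numpy(np.int64),
                                  grp["end"].to_numpy(np.int64))
        dist = _point_interval_distances(points, ms, me)
        hit = dist <= window_bp
        if hit.any():
            out.loc[gene_ids[hit], tf] = 1
    return out


def module_tf_enrichment(
    targets: pd.DataFrame,
    membership: pd.Series,
    *,
    n_tf: int | None = None,
    min_targets: int = 10,
    mode: str = "multivariable",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Logistic regression of module membership on TF target indicators.

    `membership` is a boolean/0-1 Series over the analyzed genes (the rows of
    `targets`).  In the default multivariable mode a single model contains all
    TF indicators jointly; `mode="univariable"` fits one model per TF.  TFs
    with fewer than `min_targets` targets (or non-targets) among analyzed
    genes are excluded and logged.  The Bonferroni threshold uses `n_tf`
    (default: the size of the TF catalogue in `targets`).
    """
    import statsmodels.api as sm

    if mode not in ("multivariable", "univariable"):
        raise InputError(f"unknown mode {mode!r}")
    genes = targets.index.intersection(membership.index)
    y = membership.loc[genes].astype(float).to_numpy()
    if y.sum() < 20:
        raise InputError(f"module has only {int(y.sum())} member genes (< 20)")
    T = targets.loc[genes]
    if n_tf is None:
        n_tf = T.shape[1]
    threshold = bonferroni_threshold(n_tf, alpha)

    counts = T.sum(axis=0)
    testable = (counts >= min_targets) & (len(genes) - counts >= min_targets)
    skipped = list(T.columns[~testable])
    if skipped:
        logger.info("excluding %d TFs failing the min-target filter (%d): %s",
                    len(skipped), min_targets, skipped[:10])

    rows = {tf: {"tf": tf, "n_targets": int(counts[tf]), "tested": bool(testable[tf]),
                 "beta": np.nan, "se": np.nan, "p": np.nan,
                 "estimable": False, "significant": False}
            for tf in T.columns}

    tested_tfs = list(T.columns[testable])
    if tested_tfs:
        if mode == "multivariable":
            X = np.column_stack([np.ones(len(genes)),
                                 T[tested_tfs].to_numpy(float)])
            try:
                res = sm.Logit(y, X).fit(disp=0, method="lbfgs", maxiter=500)
                params, bse = res.params[1:], res.bse[1:]
            except Exception as exc:  # pragma: no cover - defensive
                raise FitError(f"multivariable enrichment fit failed: {exc}") from exc
            for tf, b, s in zip(tested_tfs, params, bse):
                _fill(rows[tf], b, s, threshold)
        else:
            for tf in tested_tfs:
                X = np.column_stack([np.ones(len(genes)),
                                     T[tf].to_numpy(float)])
                try:
                    res = sm.Logit(y, X).fit(disp=0, method="newton",
                                             maxiter=100, tol=1e-10)
                    _fill(rows[tf], res.params[1], res.bse[1], threshold)
                except Exception:
                    logger.warning("TF %s unestimable (separation?)", tf)
    out = pd.DataFrame(rows.values()).set_index("tf")
    out.attrs["bonferroni_threshold"] = threshold
    out.attrs["n_tf"] = n_tf
    return out


def _fill(row: dict, beta: float, se: float, threshold: float) -> None:
    estimable = bool(np.isfinite(beta) and np.isfinite(se) and 0 < se < UNSTABLE_SE)
    row["beta"] = float(beta)
    row["se"] = float(se)
    row["estimable"] = estimable
    if estimable:
        row["p"] = float(2.0 * stats.norm.sf(abs(beta / se)))
        row["significant"] = row["p"] < threshold


# ---------------------------------------------------------------------------
# readers

BED_GENE_COLS = ["chrom", "start", "end", "gene_id", "score", "strand"]


def read_gene_bed(path) -> pd.DataFrame:
    """BED6-style gene annotation (0-based half-open, strand in column 6)."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     names=BED_GENE_COLS, usecols=range(6))
    return df[["gene_id", "chrom", "start", "end", "strand"]]


def read_tfbs_bed(path) -> pd.DataFrame:
    """BED4 TFBS file: chrom, start, end, tf name (0-based half-open)."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     names=["chrom", "start", "end", "tf"], usecols=range(4))
    if df["tf"].isna().any() or (df["tf"].astype(str).str.len() == 0).any():
        raise InputError("tfbs BED contains empty TF names")
    return df


def read_gff_genes(path) -> pd.DataFrame:
    """Minimal GFF3 gene reader with explicit 1-based -> 0-based conversion.

    Uses rows of type 'gene' and the ID attribute as gene_id.
    """
    rows = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 9 or f[2] != "gene":
                continue
            attrs = dict(kv.split("=", 1) for kv in f[8].split(";") if "=" in kv)
            rows.append({
                "gene_id": attrs.get("ID", f"{f[0]}:{f[3]}-{f[4]}"),
                "chrom": f[0],
                "start": int(f[3]) - 1,  # GFF is 1-based inclusive
                "end": int(f[4]),
                "strand": f[6],
            })
    if not rows:
        raise InputError(f"no gene records found in {path}")
    return pd.DataFrame(rows)
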