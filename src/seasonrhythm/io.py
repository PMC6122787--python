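"""Readers and writers for the tabular formats the pipeline consumes.

Tables are CSV/TSV (delimiter inferred from the extension) with ISO-8601
dates; expression matrices are genes x samples TSV or MatrixMarket (MTX) with
sidecar row/column name files; module definitions are two-column TSV
(gene, module).  Column roles for the cohort analyses are declared in a YAML
config.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .exceptions import InputError


def _sep_for(path: Path) -> str:
    return "," if path.suffix.lower() == ".csv" else "\t"


def read_cohort_table(path, date_cols=("assess_date", "lp_date")) -> pd.DataFrame:
    """Read a long-format participant table, parsing known date columns."""
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path))
    for c in date_cols:
        if c in df.columns:
            try:
                df[c] = pd.to_datetime(df[c])
            except (ValueError, TypeError) as exc:
                raise InputError(f"column {c!r} has invalid dates: {exc}") from exc
    return df


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise InputError(f"config {path} did not parse to a mapping")
    return cfg


def read_expression(path, genes_file=None, samples_file=None) -> pd.DataFrame:
    """Genes x samples matrix from TSV (with header + index) or MTX + names."""
    path = Path(path)
    if path.suffix.lower() == ".mtx":
        from scipy.io import mmread

        if genes_file is None or samples_file is None:
            raise InputError("MTX input requires gene and sample name files")
        raw = mmread(path)
        mat = np.asarray(raw.toarray()) if hasattr(raw, "toarray") else np.asarray(raw)
        genes = [l.strip() for l in open(genes_file) if l.strip()]
        samples = [l.strip() for l in open(samples_file) if l.strip()]
        if mat.shape != (len(genes), len(samples)):
            raise InputError(
                f"matrix shape {mat.shape} does not match names "
                f"({len(genes)} genes, {len(samples)} samples)"
            )
        return pd.DataFrame(mat, index=genes, columns=samples)
    return pd.read_csv(path, sep=_sep_for(path), index_col=0)


def read_module_defs(path) -> pd.Series:
    """Two-column TSV (gene, module) -> gene-indexed Series."""
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path))
    if df.shape[1] < 2:
        raise InputError("module definition file needs two columns (gene, module)")
    gene_col, mod_col = df.columns[:2]
    if df[gene_col].duplicated().any():
        dup = df.loc[df[gene_col].duplicated(), gene_col].tolist()[:5]
        raise InputError(f"genes assigned to multiple modules: {dup}")
    return pd.Series(df[mod_col].to_numpy(), index=df[gene_col].to_numpy())


def read_sample_meta(path, date_cols=("death_date",)) -> pd.DataFrame:
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path), index_col=0)
    for c in date_cols:
        if c in df.columns:
            df[c] = pd.to_datetime(df[c])
    return df


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(dataclasses.asdict(obj))
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    if isinstance(obj, pd.Timestamp):
        return obj.isoformat()
    return obj


def write_json(obj, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(_jsonable(obj), fh, indent=2, default=str)
        fh.write("\n")


def write_fit_report(fits, path) -> None:
    """TSV report, one row per fitted model (SeasonalFit or dict)."""
    rows = []
    for fit in fits:
        d = fit.to_dict() if hasattr(fit, "to_dict") else dict(fit)
        flat = {}
        for k, v in d.items():
            if isinstance(v, dict):
                for kk, vv in v.items():
                    flat[f"{k}.{kk}"] = vv
            elif isinstance(v, (tuple, list)):
                for i, vv in enumerate(v):
                    flat[f"{k}.{i}"] = vv
            else:
                flat[k] = v
        rows.append(flat)
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_table(df: pd.DataFrame, path, index=True) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep=_sep_for(path), index=index)
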