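"""Delimited-text readers and writers.

All matrices follow the web-app convention: identifier (CpG or gene) as
the first column, one column per sample. Readers validate hard — range
violations, duplicate identifiers and non-numeric cells are explicit
errors, never silent coercions.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .clock import ClockModel
from .exceptions import ParseError

__all__ = [
    "read_beta_matrix",
    "write_beta_matrix",
    "read_matrix",
    "read_cohort",
    "read_gmt",
    "read_clock_model",
    "write_clock_model",
    "load_yaml_config",
]

_BETA_TOL = 1e-8


def read_matrix(path) -> pd.DataFrame:
    """Read an identifier-first-column delimited matrix (no range checks)."""
    path = Path(path)
    try:
        df = pd.read_csv(path, index_col=0)
    except Exception as exc:  # pandas raises several parse error types
        raise ParseError(f"{path}: {exc}") from exc
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise ParseError(f"{path}: duplicate row identifiers: {dups[:10]}")
    if df.columns.has_duplicates:
        raise ParseError(f"{path}: duplicate sample identifiers")
    non_numeric = [c for c in df.columns if not np.issubdtype(df[c].dtype, np.number)]
    if non_numeric:
        raise ParseError(f"{path}: non-numeric cells in columns {non_numeric[:10]}")
    return df


def read_beta_matrix(path, tol: float = _BETA_TOL) -> pd.DataFrame:
    """Read and validate a CpG x sample beta matrix (values in [0, 1])."""
    df = read_matrix(path)
    vals = df.to_numpy(dtype=float)
    if np.isnan(vals).any():
        r, c = np.argwhere(np.isnan(vals))[0]
        raise ParseError(f"{path}: missing beta at CpG {df.index[r]!r}, sample {df.columns[c]!r}")
    bad = (vals < -tol) | (vals > 1.0 + tol)
    if bad.any():
        r, c = np.argwhere(bad)[0]
        raise ParseError(
            f"{path}: beta value {vals[r, c]} out of [0, 1] at "
            f"CpG {df.index[r]!r}, sample {df.columns[c]!r}"
        )
    return df.clip(0.0, 1.0)


def write_beta_matrix(df: pd.DataFrame, path, id_label: str = "cpg") -> None:
    df.to_csv(path, index_label=id_label, float_format="%.10g")


def read_cohort(path) -> pd.DataFrame:
    """Read a participant table indexed by the first (id) column."""
    path = Path(path)
    try:
        df = pd.read_csv(path, index_col=0)
    except Exception as exc:
        raise ParseError(f"{path}: {exc}") from exc
    if df.index.has_duplicates:
        raise ParseError(f"{path}: duplicate participant ids")
    return df


def read_gmt(path) -> dict[str, list[str]]:
    """Read a GMT gene-set file: name, description, then member genes."""
    sets: dict[str, list[str]] = {}
    path = Path(path)
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.rstrip("\r\n").split("\t")
        if len(fields) < 3:
            raise ParseError(f"{path}:{lineno}: expected at least 3 tab-separated fields")
        name, _desc, *genes = fields
        members = list(dict.fromkeys(g for g in genes if g))
        if len(members) < len([g for g in genes if g]):
            warnings.warn(f"{path}:{lineno}: duplicate members in set {name!r} deduplicated")
        if not members:
            warnings.warn(f"{path}:{lineno}: empty set {name!r} skipped")
            continue
        sets[name] = members
    return sets


def write_clock_model(model: ClockModel, path) -> None:
    """Write coefficients as ``cpg,weight`` CSV with an ``(Intercept)`` row,
    plus a ``<stem>.meta.json`` sidecar holding metadata and training means."""
    path = Path(path)
    rows = [("(Intercept)", model.intercept)]
    rows += [(cpg, w) for cpg, w in model.weights.items()]
    pd.DataFrame(rows, columns=["cpg", "weight"]).to_csv(path, index=False, float_format="%.12g")
    meta = {
        "alpha": model.alpha,
        "penalty": model.penalty,
        "cv_mae": model.cv_mae,
        "cv_corr": model.cv_corr,
        "n_cpgs": model.n_cpgs,
        "training_means": (
            {k: float(v) for k, v in model.training_means.items()}
            if model.training_means is not None
            else None
        ),
    }
    path.with_suffix(path.suffix + ".meta.json").write_text(json.dumps(meta, indent=1))


def read_clock_model(path) -> ClockModel:
    """Read a coefficient CSV (any linear clock); metadata sidecar optional."""
    path = Path(path)
    df = pd.read_csv(path)
    if list(df.columns[:2]) != ["cpg", "weight"]:
        raise ParseError(f"{path}: expected header 'cpg,weight'")
    inter = df[df["cpg"] == "(Intercept)"]
    intercept = float(inter["weight"].iloc[0]) if len(inter) else 0.0
    coef = df[df["cpg"] != "(Intercept)"].set_index("cpg")["weight"].astype(float)
    if coef.index.has_duplicates:
        raise ParseError(f"{path}: duplicate CpG rows")
    meta_path = path.with_suffix(path.suffix + ".meta.json")
    kwargs = {}
    if meta_path.exists():
        meta = json.loads(meta_path.read_text())
        kwargs = {
            "alpha": meta.get("alpha"),
            "penalty": meta.get("penalty"),
            "cv_mae": meta.get("cv_mae"),
            "cv_corr": meta.get("cv_corr"),
        }
        if meta.get("training_means"):
            kwargs["training_means"] = pd.Series(meta["training_means"], dtype=float)
    return ClockModel(intercept=intercept, weights=coef, **kwargs)


def load_yaml_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ParseError(f"{path}: configuration must be a mapping")
    return cfg
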