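"""Health-marker analyses: an overall-health score from the first
principal component, logistic associations with extreme DNAm-IC groups and
Spearman screens of lifestyle features."""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .association import bh_fdr
from .exceptions import AlignmentError, ContractError, DegenerateDomainError, NonEstimableError

__all__ = ["overall_health_pc1", "logistic_assoc", "lifestyle_screen"]


def overall_health_pc1(
    health: pd.DataFrame,
    anchor: str | None = None,
    max_missing_frac: float = 0.2,
) -> pd.Series:
    """First-principal-component score of the column-standardized health matrix.

    Variables with more than ``max_missing_frac`` missing values are
    dropped first, then remaining rows are restricted to complete cases.
    Constant columns are filtered with a warning. The component sign is
    fixed so the score correlates positively with ``anchor`` (default:
    the first retained variable), making "higher = healthier" reproducible.
    """
    if health.shape[1] < 2:
        raise ContractError("need at least 2 variables")
    keep = health.columns[health.isna().mean() <= max_missing_frac]
    h = health[keep].dropna(axis=0)
    if h.shape[0] < 3:
        raise ContractError("need at least 3 complete samples")
    sds = h.std(ddof=1)
    const = sds[sds == 0].index
    if len(const):
        warnings.warn(f"dropping constant health variables: {list(const)}")
        h = h.drop(columns=const)
    if h.shape[1] < 2:
        raise DegenerateDomainError("fewer than 2 non-constant variables remain")
    Z = (h - h.mean()) / h.std(ddof=1)
    # PC1 via SVD of the standardized matrix
    u, s, vt = np.linalg.svd(Z.to_numpy(dtype=float), full_matrices=False)
    scores = u[:, 0] * s[0]
    anchor = anchor if anchor is not None else h.columns[0]
    if anchor not in h.columns:
        raise ContractError(f"anchor variable {anchor!r} not in the health matrix")
    r = np.corrcoef(scores, Z[anchor].to_numpy(dtype=float))[0, 1]
    if r < 0:
        scores = -scores
    return pd.Series(scores, index=h.index, name="overall_health")


def logistic_assoc(
    group,
    variable,
    covariates: pd.DataFrame | None = None,
) -> tuple[float, float]:
    """Logistic regression of high-vs-low group membership on one variable.

    ``group`` holds two labels ('high' coded 1, by sorted order the larger
    label). Returns (odds ratio per unit of the variable, two-sided Wald p).
    """
    g = np.asarray(group)
    levels = sorted(set(g.tolist()))
    if len(levels) != 2:
        raise ContractError(f"need exactly two group labels, got {levels}")
    y = (g == levels[1]).astype(float)
    x = np.asarray(variable, dtype=float)
    if not np.isfinite(x).all():
        raise ContractError("variable must be finite")
    if np.ptp(x) == 0:
        raise NonEstimableError("variable is constant")
    cols = [x]
    if covariates is not None:
        for c in covariates.columns:
            cols.append(np.asarray(covariates[c], dtype=float))
    X = sm.add_constant(np.column_stack(cols))
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error", sm.tools.sm_exceptions.PerfectSeparationWarning)
            fit = sm.Logit(y, X).fit(disp=0, maxiter=100)
    except (sm.tools.sm_exceptions.PerfectSeparationError,
            sm.tools.sm_exceptions.PerfectSeparationWarning) as exc:
        raise NonEstimableError(f"complete separation: {exc}") from exc
    if not fit.mle_retvals.get("converged", True):
        raise NonEstimableError("logistic fit did not converge")
    if abs(fit.params[1]) > 30:  # quasi-separation: unbounded estimate
        raise NonEstimableError("coefficient diverged; data are (quasi-)separated")
    return float(np.exp(fit.params[1])), float(fit.pvalues[1])


def lifestyle_screen(dnam_ic: pd.Series, features: pd.DataFrame, fdr_level: float = 0.05) -> pd.DataFrame:
    """Per-feature Spearman correlation with DNAm IC, BH-corrected.

    Constant features are flagged (rho/p/q set to NaN) and excluded from
    the BH denominator. Returns a table with rho, p, q and a significance
    flag at ``fdr_level``.
    """
    if not features.index.equals(dnam_ic.index):
        if set(features.index) != set(dnam_ic.index):
            raise AlignmentError("features and dnam_ic cover different samples")
        features = features.loc[dnam_ic.index]
    y = dnam_ic.to_numpy(dtype=float)
    rows = {}
    for c in sorted(features.columns):
        x = features[c].to_numpy(dtype=float)
        if np.ptp(x[np.isfinite(x)]) == 0:
            rows[c] = (np.nan, np.nan)
            continue
        rho, p = stats.spearmanr(x, y, nan_policy="omit")
        rows[c] = (float(rho), float(p))
    out = pd.DataFrame(rows, index=["rho", "p"]).T.reindex(features.columns)
    valid = out["p"].notna()
    out["q"] = np.nan
    if valid.any():
        out.loc[valid, "q"] = bh_fdr(out.loc[valid, "p"].to_numpy())
    out["significant"] = out["q"] < fdr_level
    return out
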