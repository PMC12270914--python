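"""Reference-based leukocyte deconvolution by constrained projection.

Each sample's beta profile is projected onto cell-type reference profiles
under nonnegativity and a sum-to-one constraint (proportions on the
probability simplex).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .exceptions import AlignmentError, ContractError, DegenerateDomainError

__all__ = ["estimate_proportions", "cellcount_ic_correlations"]


def _simplex_lsq(R: np.ndarray, x: np.ndarray) -> np.ndarray:
    """min ||R p - x||^2 subject to p >= 0, sum(p) = 1."""
    k = R.shape[1]
    RtR = R.T @ R
    Rtx = R.T @ x

    def obj(p):
        return 0.5 * p @ RtR @ p - Rtx @ p

    def grad(p):
        return RtR @ p - Rtx

    res = optimize.minimize(
        obj,
        np.full(k, 1.0 / k),
        jac=grad,
        method="SLSQP",
        bounds=[(0.0, 1.0)] * k,
        constraints=[{"type": "eq", "fun": lambda p: p.sum() - 1.0,
                      "jac": lambda p: np.ones(k)}],
        options={"ftol": 1e-14, "maxiter": 500},
    )
    p = np.clip(res.x, 0.0, None)
    return p / p.sum()


def estimate_proportions(
    betas: pd.DataFrame, reference: pd.DataFrame
) -> pd.DataFrame:
    """Estimate cell-type proportions per sample.

    ``betas`` is CpG x sample, ``reference`` CpG x cell type. Only CpGs
    shared by both (in reference order) are used; the reference must have
    full column rank on those CpGs. Returns a sample x cell-type table on
    the probability simplex.
    """
    shared = reference.index.intersection(betas.index)
    k = reference.shape[1]
    if len(shared) < k:
        raise AlignmentError(
            f"need at least {k} shared CpGs, found {len(shared)}"
        )
    R = reference.loc[shared].to_numpy(dtype=float)
    if np.linalg.matrix_rank(R) < k:
        raise DegenerateDomainError("reference columns are linearly dependent on shared CpGs")
    X = betas.loc[shared].to_numpy(dtype=float)
    out = np.empty((betas.shape[1], k))
    for j in range(betas.shape[1]):
        out[j] = _simplex_lsq(R, X[:, j])
    return pd.DataFrame(out, index=betas.columns, columns=reference.columns)


def _residualize(y: np.ndarray, x: np.ndarray) -> np.ndarray:
    X = np.column_stack([np.ones_like(x), x])
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    return y - X @ coef


def cellcount_ic_correlations(
    proportions: pd.DataFrame, age: pd.Series, dnam_ic: pd.Series
) -> pd.DataFrame:
    """Spearman correlations of cell proportions with age, and of
    age-adjusted proportions with age-adjusted DNAm IC.

    Returns one row per cell type with ``rho_age, p_age, rho_adj, p_adj``.
    """
    if not (proportions.index.equals(age.index) and proportions.index.equals(dnam_ic.index)):
        raise AlignmentError("proportions, age and dnam_ic must share sample index")
    a = age.to_numpy(dtype=float)
    ic_adj = _residualize(dnam_ic.to_numpy(dtype=float), a)
    rows = []
    for ct in proportions.columns:
        p = proportions[ct].to_numpy(dtype=float)
        if np.ptp(p) == 0:
            raise DegenerateDomainError(f"cell type {ct!r} has constant proportions")
        rho_age, p_age = stats.spearmanr(p, a)
        rho_adj, p_adj = stats.spearmanr(_residualize(p, a), ic_adj)
        rows.append((ct, rho_age, p_age, rho_adj, p_adj))
    return pd.DataFrame(
        rows, columns=["cell_type", "rho_age", "p_age", "rho_adj", "p_adj"]
    ).set_index("cell_type")
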