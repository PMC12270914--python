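"""Training, selection and application of the DNA-methylation IC predictor.

The training protocol: retain samples from well-populated 0.05-wide score
bins, run ten-fold cross-validated elastic net over a grid of mixing
parameters with mean absolute error as the tuning metric, then pick the
mixing parameter with the best rank sum across out-of-fold correlation,
CV MAE and sparsity, refitting it on all retained samples.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import enet_path

from .exceptions import AlignmentError, ContractError, DegenerateDomainError

__all__ = [
    "BinReport",
    "CVResult",
    "ClockModel",
    "bin_filter",
    "cv_elastic_net",
    "select_model",
    "predict_clock",
    "age_acceleration",
    "quintile_groups",
    "DEFAULT_ALPHAS",
]

DEFAULT_ALPHAS = tuple(np.round(np.arange(0.1, 1.01, 0.1), 1))


@dataclass
class BinReport:
    """Per-bin sample counts from the training filter."""

    edges: np.ndarray  # length n_bins + 1
    counts: np.ndarray  # length n_bins
    retained_bins: np.ndarray  # boolean, length n_bins
    excluded_fraction: float

    @property
    def n_bins(self) -> int:
        return len(self.counts)


@dataclass
class CVResult:
    """Cross-validation summary for one elastic-net mixing parameter."""

    alpha: float
    lambdas: np.ndarray
    cv_mae_path: np.ndarray
    n_nonzero_path: np.ndarray  # from the full-data path fit
    selected_lambda: float
    cv_mae: float
    cv_corr: float
    oof_pred: pd.Series  # out-of-fold predictions at the selected lambda
    n_cpgs: int  # nonzero weights of the full-data fit at selected lambda
    intercept: float = 0.0
    coef: pd.Series = field(default_factory=lambda: pd.Series(dtype=float))


@dataclass
class ClockModel:
    """A linear methylation predictor: ``score = intercept + sum(w * beta)``."""

    intercept: float
    weights: pd.Series  # CpG id -> coefficient (nonzero only)
    alpha: float | None = None
    penalty: float | None = None
    cv_mae: float | None = None
    cv_corr: float | None = None
    training_means: pd.Series | None = None  # per-CpG mean beta, for imputation

    @property
    def n_cpgs(self) -> int:
        return int((self.weights != 0).sum())


def bin_filter(
    ic, bin_width: float = 0.05, min_count: int = 10
) -> tuple[np.ndarray, BinReport]:
    """Mask samples falling in under-populated score bins.

    Bins partition [0, 1] as ``[k*w, (k+1)*w)`` with the last bin closed at
    1.0. Samples in bins with fewer than ``min_count`` members are dropped.
    """
    ic = np.asarray(ic, dtype=float)
    if np.any(ic < 0) or np.any(ic > 1):
        raise ContractError("scores must lie in [0, 1]")
    n_bins = int(round(1.0 / bin_width))
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    idx = np.minimum((ic / bin_width).astype(int), n_bins - 1)
    counts = np.bincount(idx, minlength=n_bins)
    retained_bins = counts >= min_count
    mask = retained_bins[idx]
    if not mask.any():
        raise ContractError("bin filter would drop every sample")
    report = BinReport(
        edges=edges,
        counts=counts,
        retained_bins=retained_bins,
        excluded_fraction=float(1.0 - mask.mean()),
    )
    return mask, report


def _stratified_folds(y: np.ndarray, n_folds: int, rng: np.random.Generator) -> np.ndarray:
    """Fold labels stratified by score decile: sort by y, deal folds within
    consecutive blocks in shuffled order."""
    n = y.size
    order = np.argsort(y, kind="stable")
    folds = np.empty(n, dtype=int)
    for start in range(0, n, n_folds):
        block = order[start : start + n_folds]
        labels = rng.permutation(n_folds)[: block.size]
        folds[block] = labels
    return folds


def _standardize(X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    return (X - mu) / sd, mu, sd


def cv_elastic_net(
    betas: pd.DataFrame,
    ic: pd.Series,
    alphas=DEFAULT_ALPHAS,
    folds: int = 10,
    seed: int = 0,
    n_lambdas: int = 100,
    lambda_min_ratio: float = 1e-2,
) -> list[CVResult]:
    """Ten-fold cross-validated elastic net for each mixing parameter.

    ``betas`` is CpG x sample; ``ic`` the target per sample. Predictors are
    standardized inside each fit and coefficients returned on the original
    beta scale. For each alpha the lambda minimizing the mean out-of-fold
    MAE is selected and the full-data path fit at that lambda is stored.
    """
    if not betas.columns.equals(ic.index):
        if set(betas.columns) != set(ic.index):
            raise AlignmentError("betas and ic cover different samples")
        ic = ic.loc[betas.columns]
    X = betas.to_numpy(dtype=float).T  # samples x cpgs
    y = ic.to_numpy(dtype=float)
    n = y.size
    if n < folds:
        raise ContractError(f"need at least {folds} samples for {folds}-fold CV")
    if not np.isfinite(X).all():
        raise ContractError("beta matrix contains non-finite values")

    rng = np.random.default_rng(seed)
    fold_of = _stratified_folds(y, folds, rng)
    Xs, _, _ = _standardize(X)
    yc = y - y.mean()

    results = []
    for alpha in alphas:
        alpha = float(alpha)
        if not 0.0 < alpha <= 1.0:
            raise ContractError(f"mixing parameter must be in (0, 1], got {alpha}")
        lam_max = np.abs(Xs.T @ yc).max() / (n * alpha)
        lambdas = np.geomspace(lam_max, lam_max * lambda_min_ratio, n_lambdas)

        oof = np.empty((n, n_lambdas))
        fold_mae = np.zeros((folds, n_lambdas))
        for k in range(folds):
            tr, va = fold_of != k, fold_of == k
            Xtr_s, mu, sd = _standardize(X[tr])
            ytr = y[tr]
            _, coefs, _ = enet_path(
                Xtr_s, ytr - ytr.mean(), l1_ratio=alpha, alphas=lambdas
            )
            pred = ((X[va] - mu) / sd) @ coefs + ytr.mean()
            oof[va] = pred
            fold_mae[k] = np.abs(pred - y[va][:, None]).mean(axis=0)
        cv_mae_path = fold_mae.mean(axis=0)
        best = int(np.argmin(cv_mae_path))

        # full-data fit along the same path (glmnet-style) for sparsity and refit
        Xf_s, mu_f, sd_f = _standardize(X)
        _, coefs_full, _ = enet_path(
            Xf_s, y - y.mean(), l1_ratio=alpha, alphas=lambdas
        )
        n_nonzero_path = (coefs_full != 0).sum(axis=0)
        b_std = coefs_full[:, best]
        b = b_std / sd_f
        intercept = float(y.mean() - b @ mu_f)

        oof_pred = pd.Series(oof[:, best], index=ic.index)
        nz = b != 0
        results.append(
            CVResult(
                alpha=alpha,
                lambdas=lambdas,
                cv_mae_path=cv_mae_path,
                n_nonzero_path=n_nonzero_path,
                selected_lambda=float(lambdas[best]),
                cv_mae=float(cv_mae_path[best]),
                cv_corr=float(np.corrcoef(y, oof[:, best])[0, 1]),
                oof_pred=oof_pred,
                n_cpgs=int(nz.sum()),
                intercept=intercept,
                coef=pd.Series(b[nz], index=betas.index[nz]),
            )
        )
    return results


def select_model(cv_results: list[CVResult], betas: pd.DataFrame | None = None) -> ClockModel:
    """Pick the mixing parameter with the minimal rank sum over three
    criteria: descending out-of-fold correlation, ascending CV MAE and
    ascending CpG count. Rank-sum ties break toward the larger (sparser)
    alpha. The winner's full-data fit becomes the clock; per-CpG training
    mean betas are attached when ``betas`` is supplied (for imputation)."""
    if not cv_results:
        raise ContractError("no CV results to select from")
    corr = np.array([r.cv_corr for r in cv_results])
    mae = np.array([r.cv_mae for r in cv_results])
    ncpg = np.array([r.n_cpgs for r in cv_results])
    ranksum = (
        stats.rankdata(-corr) + stats.rankdata(mae) + stats.rankdata(ncpg)
    )
    best = min(ranksum)
    tied = [r for r, s in zip(cv_results, ranksum) if s == best]
    winner = max(tied, key=lambda r: r.alpha)
    means = None
    if betas is not None and len(winner.coef):
        means = betas.loc[winner.coef.index].mean(axis=1)
    return ClockModel(
        intercept=winner.intercept,
        weights=winner.coef.copy(),
        alpha=winner.alpha,
        penalty=winner.selected_lambda,
        cv_mae=winner.cv_mae,
        cv_corr=winner.cv_corr,
        training_means=means,
    )


def predict_clock(
    model: ClockModel, betas: pd.DataFrame, impute_mean: bool = False
) -> pd.Series:
    """Apply a linear clock to a CpG x sample beta matrix.

    Missing model CpGs raise an error listing them, unless ``impute_mean``
    is set and the model carries training means, in which case the training
    mean beta is substituted per missing CpG.
    """
    needed = model.weights.index
    missing = needed.difference(betas.index)
    if len(missing):
        if not impute_mean:
            raise AlignmentError(
                f"{len(missing)} model CpGs absent from input: {sorted(missing)[:10]}"
            )
        if model.training_means is None:
            raise ContractError("model has no training means; cannot impute")
        filler = pd.DataFrame(
            np.tile(model.training_means.loc[missing].to_numpy()[:, None], len(betas.columns)),
            index=missing,
            columns=betas.columns,
        )
        betas = pd.concat([betas, filler])
    sub = betas.loc[needed]
    scores = model.intercept + sub.to_numpy(dtype=float).T @ model.weights.to_numpy()
    return pd.Series(scores, index=betas.columns, name="dnam_ic")


def age_acceleration(score: pd.Series, age: pd.Series, sex=None) -> pd.Series:
    """Residuals of score on age (optionally also sex) by ordinary least squares."""
    if len(score) < 3:
        raise ContractError("need at least 3 samples")
    age_v = np.asarray(age, dtype=float)
    if np.ptp(age_v) == 0:
        raise DegenerateDomainError("age is constant; residuals undefined")
    cols = [np.ones(len(score)), age_v]
    if sex is not None:
        sx = np.asarray(sex)
        if sx.dtype.kind in "OUS":
            sx = (sx == "male").astype(float)
        cols.append(sx.astype(float))
    X = np.column_stack(cols)
    y = np.asarray(score, dtype=float)
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    return pd.Series(resid, index=score.index, name="acceleration")


def quintile_groups(values: pd.Series) -> pd.Series:
    """Label the bottom and top 20% (by rank, stable order) of the values.

    Returns labels ``lowest20`` / ``mid`` / ``highest20``. Boundary ties are
    resolved by stable sort order (earlier rows enter the lower group),
    which makes the assignment deterministic even for constant input.
    """
    n = len(values)
    if n < 5:
        raise ContractError("need at least 5 samples for quintiles")
    k = max(1, int(np.floor(0.2 * n)))
    order = np.argsort(values.to_numpy(), kind="stable")
    labels = np.array(["mid"] * n, dtype=object)
    labels[order[:k]] = "lowest20"
    labels[order[-k:]] = "highest20"
    return pd.Series(labels, index=values.index, name="quintile_group")
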