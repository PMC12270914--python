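"""Transcriptome association with the methylation IC predictor.

Per-gene linear models against age-adjusted DNAm IC, Benjamini-Hochberg
FDR, a permutation test linking clock CpGs to the expression signature,
over-representation analysis, and a one-signed preranked gene set
enrichment analysis (weighted running sum, exponent 1).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import AlignmentError, ContractError

__all__ = [
    "linear_de",
    "bh_fdr",
    "LinkageResult",
    "cpg_gene_linkage",
    "per_gene_cpg_counts",
    "overrepresentation",
    "ranked_gsea",
]


def bh_fdr(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted values, returned in input order."""
    p = np.asarray(pvals, dtype=float)
    if p.ndim != 1:
        p = p.ravel()
    if np.any((p < 0) | (p > 1)) or not np.isfinite(p).all():
        raise ContractError("p values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    q_sorted = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def linear_de(
    expression: pd.DataFrame,
    predictor: pd.Series,
    covariates: pd.DataFrame | None = None,
    fdr_level: float = 0.05,
) -> pd.DataFrame:
    """Per-gene OLS of expression on the predictor (plus covariates).

    ``expression`` is gene x sample. Returns a table indexed by gene with
    ``effect`` (slope per unit predictor), ``t``, ``p`` (two-sided on the
    residual df) and BH-adjusted ``q``; ``significant`` flags q < fdr_level.
    """
    if not expression.columns.equals(predictor.index):
        if set(expression.columns) != set(predictor.index):
            raise AlignmentError("expression and predictor cover different samples")
        predictor = predictor.loc[expression.columns]
    n = expression.shape[1]
    cols = [np.ones(n), predictor.to_numpy(dtype=float)]
    if covariates is not None:
        cov = covariates.loc[expression.columns]
        for c in cov.columns:
            cols.append(cov[c].to_numpy(dtype=float))
    D = np.column_stack(cols)
    p_par = D.shape[1]
    if n <= p_par:
        raise ContractError("not enough samples for the design")
    DtD = D.T @ D
    try:
        DtD_inv = np.linalg.inv(DtD)
    except np.linalg.LinAlgError as exc:
        raise ContractError("singular design matrix") from exc
    Y = expression.to_numpy(dtype=float)  # genes x samples
    B = DtD_inv @ (D.T @ Y.T)  # params x genes
    resid = Y.T - D @ B
    df = n - p_par
    sigma2 = (resid**2).sum(axis=0) / df
    se = np.sqrt(sigma2 * DtD_inv[1, 1])
    effect = B[1]
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, effect / se, np.inf * np.sign(effect))
    p = 2.0 * stats.t.sf(np.abs(t), df)
    q = bh_fdr(p)
    out = pd.DataFrame(
        {"effect": effect, "t": t, "p": p, "q": q}, index=expression.index
    )
    out["significant"] = out["q"] < fdr_level
    return out


def _rank_rows_standardized(M: np.ndarray) -> np.ndarray:
    """Mid-rank each row and scale to zero mean, unit norm (so that the dot
    product of two rows is their Spearman correlation)."""
    r = stats.rankdata(M, axis=1)
    r = r - r.mean(axis=1, keepdims=True)
    norm = np.linalg.norm(r, axis=1, keepdims=True)
    norm = np.where(norm > 0, norm, 1.0)
    return r / norm


@dataclass
class LinkageResult:
    statistic: float
    p: float
    null: np.ndarray


def cpg_gene_linkage(
    clock_betas: pd.DataFrame,
    de_expression: pd.DataFrame,
    n_perm: int = 10000,
    seed: int = 0,
    aggregation: str = "mean_max",
) -> LinkageResult:
    """Permutation test of linkage between clock CpGs and DE genes.

    Statistic: mean over clock CpGs of the max over DE genes of the
    absolute Spearman correlation between CpG betas and gene expression.
    The null permutes the sample labels of the expression matrix; the p
    value uses the +1 convention.
    """
    if n_perm < 1000:
        raise ContractError("n_perm must be at least 1000")
    if not clock_betas.columns.equals(de_expression.columns):
        if set(clock_betas.columns) != set(de_expression.columns):
            raise AlignmentError("CpG and expression matrices cover different samples")
        de_expression = de_expression[clock_betas.columns]
    if aggregation != "mean_max":
        raise ContractError(f"unknown aggregation {aggregation!r}")
    Zb = _rank_rows_standardized(clock_betas.to_numpy(dtype=float))
    Zg = _rank_rows_standardized(de_expression.to_numpy(dtype=float))
    n = Zb.shape[1]

    def stat(zg):
        rho = Zb @ zg.T
        return float(np.abs(rho).max(axis=1).mean())

    observed = stat(Zg)
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    for i in range(n_perm):
        null[i] = stat(Zg[:, rng.permutation(n)])
    p = (1.0 + np.sum(null >= observed)) / (1.0 + n_perm)
    return LinkageResult(statistic=observed, p=float(p), null=null)


def per_gene_cpg_counts(
    clock_betas: pd.DataFrame,
    de_expression: pd.DataFrame,
    threshold: float = 0.05,
) -> pd.Series:
    """Per DE gene, the number of clock CpGs whose betas correlate
    significantly with its expression (BH over the full CpG x gene grid of
    Spearman p values, q < threshold)."""
    if not clock_betas.columns.equals(de_expression.columns):
        if set(clock_betas.columns) != set(de_expression.columns):
            raise AlignmentError("CpG and expression matrices cover different samples")
        de_expression = de_expression[clock_betas.columns]
    n = clock_betas.shape[1]
    Zb = _rank_rows_standardized(clock_betas.to_numpy(dtype=float))
    Zg = _rank_rows_standardized(de_expression.to_numpy(dtype=float))
    rho = np.clip(Zb @ Zg.T, -1.0, 1.0)  # cpgs x genes
    with np.errstate(divide="ignore"):
        t = rho * np.sqrt((n - 2) / np.maximum(1.0 - rho**2, 1e-300))
    p = 2.0 * stats.t.sf(np.abs(t), n - 2)
    q = bh_fdr(p.ravel()).reshape(p.shape)
    counts = (q < threshold).sum(axis=0)
    return pd.Series(counts, index=de_expression.index, name="n_correlated_cpgs")


def overrepresentation(
    sig_genes: Sequence[str],
    universe: Sequence[str],
    gene_sets: dict[str, Sequence[str]],
) -> pd.DataFrame:
    """One-sided hypergeometric over-representation of each gene set in the
    significant list, with BH correction across sets.

    Sets are intersected with the universe; sets disjoint from it are
    skipped. Returns a table with overlap counts, p and q per set.
    """
    universe = set(universe)
    if not universe:
        raise ContractError("empty universe")
    sig = set(sig_genes)
    if not sig <= universe:
        raise ContractError("significant genes must be a subset of the universe")
    N, n_draw = len(universe), len(sig)
    rows = []
    for name, members in gene_sets.items():
        inset = set(members) & universe
        if not inset:
            continue
        k = len(sig & inset)
        p = float(stats.hypergeom.sf(k - 1, N, len(inset), n_draw))
        rows.append((name, len(inset), k, p))
    out = pd.DataFrame(rows, columns=["set", "set_size", "overlap", "p"]).set_index("set")
    if len(out):
        out["q"] = bh_fdr(out["p"].to_numpy())
    else:
        out["q"] = np.nan
    return out


def _es_from_order(scores_ranked: np.ndarray, member_ranked: np.ndarray) -> float:
    """One-signed enrichment score of a ranked list: weighted KS running sum
    (member increment proportional to its score, constant non-member
    decrement); ES is the positive maximum of the running sum."""
    n = scores_ranked.size
    m = int(member_ranked.sum())
    nr = float(scores_ranked[member_ranked].sum())
    if nr <= 0:
        return 0.0
    inc = np.where(member_ranked, scores_ranked / nr, -1.0 / (n - m))
    return float(np.cumsum(inc).max())


def ranked_gsea(
    assoc: pd.DataFrame,
    gene_set: Sequence[str],
    n_perm: int = 10000,
    seed: int = 0,
) -> tuple[float, float]:
    """Preranked one-signed GSEA on -log10(p) with gene-label permutations.

    ``assoc`` must carry a ``p`` column indexed by gene. Genes are ranked
    by -log10(p) descending; the null redraws same-size gene sets at
    random; p uses the +1 convention.
    """
    if n_perm < 1000:
        raise ContractError("n_perm must be at least 1000")
    members = pd.Index(dict.fromkeys(gene_set))
    missing = members.difference(assoc.index)
    if len(missing):
        raise ContractError(f"gene set members not scoreable: {sorted(missing)[:10]}")
    n = len(assoc)
    m = len(members)
    if m == 0:
        raise ContractError("empty gene set")
    if m >= n:
        raise ContractError("gene set must be strictly smaller than the universe")
    scores = -np.log10(np.clip(assoc["p"].to_numpy(dtype=float), 1e-300, None))
    order = np.argsort(-scores, kind="stable")
    s_ranked = scores[order]
    memb = assoc.index.isin(members)[order]
    es = _es_from_order(s_ranked, memb)

    rng = np.random.default_rng(seed)
    nr_all = s_ranked.sum()
    null = np.empty(n_perm)
    dec = -1.0 / (n - m)
    for i in range(n_perm):
        pick = np.zeros(n, dtype=bool)
        pick[rng.choice(n, size=m, replace=False)] = True
        nr = float(s_ranked[pick].sum())
        if nr <= 0:
            null[i] = 0.0
            continue
        inc = np.where(pick, s_ranked / nr, dec)
        null[i] = np.cumsum(inc).max()
    p = (1.0 + np.sum(null >= es)) / (1.0 + n_perm)
    return float(es), float(p)
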