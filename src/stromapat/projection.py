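"""Transfer of learned patterns into new expression data ("projection").

Each target sample's expression vector (restricted to the genes shared
with the pattern basis W) is regressed by ordinary least squares on the
columns of W; the fitted coefficients are the per-sample *projection
scores*, with standard errors and two-sided t-test p-values from the usual
OLS machinery.  This is how learned factors are carried from a source
dataset (here, squamous cancer cell lines) to single cells or bulk tumors.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger("stromapat")


@dataclass
class ProjectionResult:
    scores: pd.DataFrame       # patterns × samples
    se: pd.DataFrame           # matching standard errors (≥ 0)
    p_values: pd.DataFrame     # matching two-sided p-values in [0, 1]
    n_shared_genes: int
    dropped_gene_ids: list = field(default_factory=list)


def project_patterns(Y, W, center_genes: bool = True) -> ProjectionResult:
    """Project pattern basis W (genes × k) into target expression Y (genes × samples).

    With ``center_genes`` on (default), each shared gene is centered by its
    mean across the target samples and an intercept column is included in
    the per-sample regression, so scores are invariant to adding a constant
    to a sample's profile.  With it off the regression is on W alone, so a
    noiseless Y = W·H returns exactly H.

    Genes of Y absent from W (and vice versa) are dropped and listed in
    ``dropped_gene_ids``.
    """
    Y = Y if isinstance(Y, pd.DataFrame) else pd.DataFrame(np.asarray(Y, float))
    W = W if isinstance(W, pd.DataFrame) else pd.DataFrame(np.asarray(W, float))
    k = W.shape[1]

    shared = Y.index.intersection(W.index)
    dropped = sorted(set(Y.index).symmetric_difference(W.index))
    if len(shared) < k + 2:
        raise ValueError(f"only {len(shared)} genes shared between target and "
                         f"basis; need at least k + 2 = {k + 2}")
    Ws = W.loc[shared].to_numpy(dtype=float)
    Ys = Y.loc[shared].to_numpy(dtype=float)

    rank = np.linalg.matrix_rank(Ws)
    if rank < k:
        # name the collinear patterns via the smallest singular directions
        _, s, vt = np.linalg.svd(Ws, full_matrices=False)
        bad = vt[rank:]
        involved = [str(W.columns[j]) for j in
                    sorted(set(np.abs(bad).argmax(axis=1)))]
        raise np.linalg.LinAlgError(
            f"pattern basis rank-deficient on shared genes "
            f"(rank {rank} < k={k}); collinear patterns include {involved}")

    if center_genes:
        Yc = Ys - Ys.mean(axis=1, keepdims=True)
        A = np.column_stack([np.ones(len(shared)), Ws])
        coef_rows = slice(1, k + 1)
    else:
        Yc = Ys
        A = Ws
        coef_rows = slice(0, k)

    n, p = A.shape
    AtA = A.T @ A
    AtA_inv = np.linalg.inv(AtA)
    coef = AtA_inv @ (A.T @ Yc)                     # p × samples
    resid = Yc - A @ coef
    df = n - p
    sigma2 = (resid ** 2).sum(axis=0) / df          # per-sample residual variance
    se = np.sqrt(np.outer(np.diag(AtA_inv), sigma2))
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = np.where(se > 0, coef / se, np.inf * np.sign(coef))
    pvals = 2.0 * stats.t.sf(np.abs(tstat), df)

    cols = Y.columns
    pats = W.columns
    return ProjectionResult(
        scores=pd.DataFrame(coef[coef_rows], index=pats, columns=cols),
        se=pd.DataFrame(se[coef_rows], index=pats, columns=cols),
        p_values=pd.DataFrame(pvals[coef_rows], index=pats, columns=cols),
        n_shared_genes=len(shared),
        dropped_gene_ids=dropped)


def filter_confident(pr: ProjectionResult, alpha: float = 0.05) -> list:
    """Samples whose projection p-value is below *alpha* for every pattern."""
    if not (0 < alpha < 1):
        raise ValueError("alpha must be in (0, 1)")
    keep = (pr.p_values < alpha).all(axis=0)
    return list(pr.p_values.columns[keep])


def correlate_signatures(scores_a: pd.DataFrame,
                         scores_b: pd.DataFrame) -> pd.DataFrame:
    """Pearson correlation of each score row of A against each row of B.

    Both frames must cover the same samples (columns).  Zero-variance rows
    yield NaN with a warning.
    """
    if not scores_a.columns.equals(scores_b.columns):
        common = scores_a.columns.intersection(scores_b.columns)
        if len(common) != len(scores_a.columns) or len(common) != len(scores_b.columns):
            raise ValueError("score frames must cover identical sample sets")
        scores_b = scores_b[scores_a.columns]
    A = scores_a.to_numpy(dtype=float)
    B = scores_b.to_numpy(dtype=float)
    sa = A.std(axis=1)
    sb = B.std(axis=1)
    if (sa == 0).any() or (sb == 0).any():
        logger.warning("correlate_signatures: zero-variance rows reported as NaN")
    Ac = (A - A.mean(axis=1, keepdims=True))
    Bc = (B - B.mean(axis=1, keepdims=True))
    n = A.shape[1]
    with np.errstate(divide="ignore", invalid="ignore"):
        corr = (Ac @ Bc.T) / (n * np.outer(sa, sb))
    corr[~np.isfinite(corr)] = np.nan
    out = pd.DataFrame(corr, index=scores_a.index, columns=scores_b.index)
    return out.clip(-1.0, 1.0)
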