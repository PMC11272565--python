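"""Pattern marker-gene extraction by the Kim–Park feature score.

For gene i with loadings W(i, 1..k), let p(i, q) = W(i, q) / Σ_q W(i, q).
The feature score is one minus the normalised entropy of that distribution,

    s(i) = 1 + (1 / log2 k) Σ_q p(i, q) log2 p(i, q),      0·log 0 ≡ 0,

so s = 1 for a gene loading on a single pattern and s = 0 for a gene
loading uniformly.  Markers are the genes whose score exceeds
median(s) + sigma_mult · MAD(s); each marker is assigned to its
argmax-loading pattern.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import median_abs_deviation

logger = logging.getLogger("stromapat")


@dataclass
class MarkerSet:
    scores: pd.Series                 # per gene, in [0, 1]; NaN = unscorable
    assignment: pd.Series             # marker gene -> pattern label
    threshold: float
    per_pattern: dict[str, list]      # pattern label -> marker gene list

    @property
    def genes(self) -> list:
        return list(self.assignment.index)


def feature_score(W) -> pd.Series:
    """Kim–Park per-gene pattern-specificity score in [0, 1].

    Rows with all-zero loadings have no defined loading distribution; their
    score is returned as NaN with a warning.
    """
    if not isinstance(W, pd.DataFrame):
        W = pd.DataFrame(np.asarray(W, dtype=float))
    k = W.shape[1]
    if k < 2:
        raise ValueError("feature score needs at least 2 patterns")
    A = W.to_numpy(dtype=float)
    if (A < 0).any():
        raise ValueError("loadings must be nonnegative")
    rowsum = A.sum(axis=1)
    zero = rowsum == 0
    if zero.any():
        logger.warning("feature_score: %d all-zero genes have undefined score",
                       int(zero.sum()))
    with np.errstate(divide="ignore", invalid="ignore"):
        p = A / rowsum[:, None]
        plogp = np.where(p > 0, p * np.log2(np.where(p > 0, p, 1.0)), 0.0)
    s = 1.0 + plogp.sum(axis=1) / np.log2(k)
    s[zero] = np.nan
    # exact closed-form endpoints despite floating point
    s = np.clip(s, 0.0, 1.0)
    return pd.Series(s, index=W.index, name="score")


def extract_markers(W, sigma_mult: float = 3.0,
                    scale_mad: bool = True) -> MarkerSet:
    """Select pattern markers: score > median + sigma_mult · MAD.

    MAD is scaled by 1.4826 by default (consistent with the standard
    deviation under normality); pass ``scale_mad=False`` for the raw MAD.
    Each selected gene is assigned to its argmax-loading pattern, ties
    broken toward the lowest pattern index.
    """
    if not isinstance(W, pd.DataFrame):
        W = pd.DataFrame(np.asarray(W, dtype=float))
    scores = feature_score(W)
    scorable = scores.dropna()
    if len(scorable) < 10:
        raise ValueError(f"only {len(scorable)} scorable genes; need ≥ 10")
    mad = median_abs_deviation(scorable, scale="normal" if scale_mad else 1.0)
    threshold = float(np.median(scorable) + sigma_mult * mad)
    selected = scorable[scorable > threshold]

    A = W.loc[selected.index].to_numpy(dtype=float)
    top = A.max(axis=1)
    if ((A == top[:, None]).sum(axis=1) > 1).any():
        logger.info("extract_markers: argmax ties broken toward lowest pattern index")
    labels = pd.Index(W.columns)[A.argmax(axis=1)]
    assignment = pd.Series(labels, index=selected.index, name="pattern")
    per_pattern = {str(p): assignment.index[assignment == p].tolist()
                   for p in W.columns}
    return MarkerSet(scores=scores, assignment=assignment,
                     threshold=threshold, per_pattern=per_pattern)


def marker_table(ms: MarkerSet, W: pd.DataFrame) -> pd.DataFrame:
    """Long-format marker report: gene_id, score, pattern, selected."""
    sel = ms.scores.index.isin(ms.assignment.index)
    pattern = pd.Series("", index=ms.scores.index, dtype=object)
    pattern.loc[ms.assignment.index] = ms.assignment.astype(str)
    return pd.DataFrame({
        "score": ms.scores,
        "pattern": pattern,
        "selected": sel.astype(int),
    })
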