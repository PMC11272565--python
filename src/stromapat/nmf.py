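"""Nonnegative matrix factorization with consensus rank selection.

A gene-by-sample expression matrix X (log-scale, nonnegative) is factored
as X ≈ W·H with W (genes × k patterns) and H (k × samples) nonnegative,
minimising the generalised Kullback-Leibler divergence

    D(X ‖ WH) = Σ_ij [ x_ij log(x_ij / (WH)_ij) − x_ij + (WH)_ij ]

by the classical multiplicative updates, which decrease D monotonically.
The number of patterns k is chosen by consensus clustering over random
restarts: samples are co-clustered by their dominant pattern, the mean
connectivity matrix over runs is summarised by its cophenetic correlation,
and the scan keeps the largest k before the cophenetic coefficient shows a
sustained drop.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import average, cophenet
from scipy.spatial.distance import squareform

logger = logging.getLogger("stromapat")

EPS = 1e-12  # guards denominators and log arguments


@dataclass
class PatternBasis:
    """NMF factorization result; columns of W are the patterns V1..Vk."""
    W: pd.DataFrame            # genes × patterns, column-normalised to unit L1
    H: pd.DataFrame            # patterns × samples
    k: int
    divergence_trace: np.ndarray
    seed: int
    dropped_genes: list = field(default_factory=list)

    @property
    def divergence(self) -> float:
        return float(self.divergence_trace[-1])


@dataclass
class ConsensusResult:
    k: int
    consensus: pd.DataFrame    # samples × samples, entries in [0, 1]
    cophenetic: float
    dispersion: float
    n_runs: int


def kl_divergence(X: np.ndarray, WH: np.ndarray) -> float:
    """Generalised KL divergence D(X ‖ WH), with 0·log 0 ≡ 0."""
    pos = X > 0
    d = WH.sum() - X.sum()
    d += float(np.sum(X[pos] * np.log(X[pos] / (WH[pos] + EPS))))
    return float(d)


def _as_array(X) -> tuple[np.ndarray, pd.Index, pd.Index]:
    if isinstance(X, pd.DataFrame):
        return X.to_numpy(dtype=float), X.index, X.columns
    X = np.asarray(X, dtype=float)
    return (X, pd.RangeIndex(X.shape[0]).astype(str),
            pd.RangeIndex(X.shape[1]).astype(str))


def nmf_factorize(X, k: int, seed: int = 0, max_iter: int = 500,
                  tol: float = 1e-6) -> PatternBasis:
    """Factor X (genes × samples, ≥ 0) into k patterns by KL multiplicative updates.

    Genes with all-zero expression are unidentifiable under the KL objective
    and are dropped before factorization (reported in ``dropped_genes``).
    Convergence: relative divergence change per iteration < *tol*, or
    *max_iter* iterations.  After convergence W's columns are normalised to
    unit L1 and H rescaled accordingly (D(X‖WH) is invariant to this gauge).
    """
    A, gene_ids, sample_ids = _as_array(X)
    if A.size == 0 or not np.isfinite(A).all():
        raise ValueError("expression matrix must be finite and non-empty")
    if (A < 0).any():
        raise ValueError("expression matrix has negative entries")
    zero_rows = A.sum(axis=1) == 0
    dropped = list(gene_ids[zero_rows])
    if dropped:
        logger.warning("nmf: dropping %d all-zero genes", len(dropped))
        A = A[~zero_rows]
        gene_ids = gene_ids[~zero_rows]
    n, m = A.shape
    if A.sum() == 0:
        raise ValueError("expression matrix is all zero")
    if not (2 <= k <= min(n, m)) and k != 1:
        raise ValueError(f"k={k} out of range for a {n}×{m} matrix")

    rng = np.random.default_rng(seed)
    scale = A.mean()
    W = rng.uniform(0, 1, size=(n, k)) * scale
    H = rng.uniform(0, 1, size=(k, m))

    # D(X‖WH) = Σ x log x − Σ x  − Σ x log(WH) + Σ WH ; the first two terms
    # are constant, so each iteration needs a single vectorised log.
    pos = A > 0
    const = float(np.sum(A[pos] * np.log(A[pos])) - A.sum())

    trace = []
    prev = np.inf
    R = np.empty_like(A)
    for _ in range(max_iter):
        WH = W @ H
        WH += EPS
        np.divide(A, WH, out=R)
        H *= (W.T @ R) / (W.sum(axis=0)[:, None] + EPS)
        WH = W @ H
        WH += EPS
        np.divide(A, WH, out=R)
        W *= (R @ H.T) / (H.sum(axis=1)[None, :] + EPS)
        WH = W @ H
        WH += EPS
        np.log(WH, out=R)
        d = const - float(np.einsum("ij,ij->", A, R)) + float(WH.sum())
        trace.append(d)
        if np.isfinite(prev) and prev - d < tol * max(abs(prev), 1.0):
            break
        prev = d

    # gauge fix: unit-L1 columns of W
    col = W.sum(axis=0)
    col[col == 0] = 1.0
    W /= col
    H *= col[:, None]

    patterns = [f"V{i + 1}" for i in range(k)]
    return PatternBasis(
        W=pd.DataFrame(W, index=gene_ids, columns=patterns),
        H=pd.DataFrame(H, index=patterns, columns=sample_ids),
        k=k, divergence_trace=np.asarray(trace), seed=seed,
        dropped_genes=dropped)


def connectivity_matrix(H) -> np.ndarray:
    """Binary co-membership of samples by dominant pattern (argmax of H columns).

    Ties in the argmax are broken toward the lowest pattern index.
    """
    Hv = H.to_numpy() if isinstance(H, pd.DataFrame) else np.asarray(H, dtype=float)
    if (Hv < 0).any():
        raise ValueError("H must be nonnegative")
    top = Hv.max(axis=0)
    ties = (Hv == top[None, :]).sum(axis=0) > 1
    if ties.any():
        logger.info("connectivity: %d samples with tied dominant pattern "
                    "(broken toward lowest index)", int(ties.sum()))
    labels = Hv.argmax(axis=0)
    return (labels[:, None] == labels[None, :]).astype(np.int8)


def consensus_run(X, k: int, n_runs: int, base_seed: int = 0,
                  max_iter: int = 200, tol: float = 1e-4) -> ConsensusResult:
    """Mean connectivity over *n_runs* factorizations (seeds base_seed..+n_runs−1).

    cophenetic: Pearson correlation between the consensus distances
    (1 − consensus) and the cophenetic distances of average-linkage
    hierarchical clustering on them; 1 means perfectly stable co-clustering.
    dispersion: mean of 4·(c − 0.5)² over consensus entries (1 when every
    entry is 0 or 1).
    """
    if n_runs < 2:
        raise ValueError("n_runs must be ≥ 2")
    _, _, sample_ids = _as_array(X)
    acc = None
    for r in range(n_runs):
        basis = nmf_factorize(X, k, seed=base_seed + r, max_iter=max_iter, tol=tol)
        C = connectivity_matrix(basis.H).astype(float)
        acc = C if acc is None else acc + C
    consensus = acc / n_runs

    dist = 1.0 - consensus
    np.fill_diagonal(dist, 0.0)
    condensed = squareform(dist, checks=False)
    if condensed.std() == 0:
        coph = 1.0  # degenerate: all samples always together (or apart)
    else:
        Z = average(condensed)
        coph, _ = cophenet(Z, condensed)
        coph = float(coph)
    dispersion = float(np.mean(4.0 * (consensus - 0.5) ** 2))
    return ConsensusResult(
        k=k,
        consensus=pd.DataFrame(consensus, index=sample_ids, columns=sample_ids),
        cophenetic=coph, dispersion=dispersion, n_runs=n_runs)


def select_rank(X, k_min: int = 2, k_max: int = 9, n_runs: int = 30,
                base_seed: int = 0, drop_tol: float = 0.01,
                max_iter: int = 200, tol: float = 1e-4,
                min_stability: float = 0.9,
                ) -> tuple[list[ConsensusResult], int]:
    """Scan k = k_min..k_max and choose the rank by consensus stability.

    Rule: walk k upward tracking the running maximum of the dispersion
    coefficient (how close consensus entries are to 0/1); a *sustained
    drop* is the first k from which every coefficient stays more than
    *drop_tol* below that running maximum.  The chosen k is the largest k
    before the drop whose coefficient is within *drop_tol* of the running
    maximum.  Dispersion rather than the cophenetic coefficient drives the
    rule because the cophenetic correlation stays near 1 whenever the
    consensus fuzziness is hierarchically structured — precisely what
    over-factorization produces — while dispersion degrades as soon as
    restarts disagree.  Both statistics are returned in the per-k table so
    callers can override.

    A rank is only eligible if its consensus is itself stable
    (dispersion ≥ *min_stability*, i.e. near-binary co-clustering); on
    structureless input no rank qualifies and the scan falls back to
    *k_min* with a warning.
    """
    if not (2 <= k_min < k_max):
        raise ValueError("need 2 ≤ k_min < k_max")
    results = [consensus_run(X, k, n_runs, base_seed=base_seed + 10_000 * k,
                             max_iter=max_iter, tol=tol)
               for k in range(k_min, k_max + 1)]
    stab = np.array([r.dispersion for r in results])
    runmax = np.maximum.accumulate(stab)
    below = stab < runmax - drop_tol
    # first index from which the drop is sustained (all later ks stay below)
    drop_at = len(stab)
    for j in range(len(stab)):
        if below[j:].all() and below[j]:
            drop_at = j
            break
    eligible = [i for i in range(drop_at)
                if stab[i] >= runmax[drop_at - 1] - drop_tol
                and stab[i] >= min_stability]
    if eligible:
        chosen = results[max(eligible)].k
    else:
        chosen = k_min
        logger.warning("select_rank: no rank with stable consensus "
                       "(max dispersion %.3f < %.2f); falling back to "
                       "k_min=%d", float(stab.max()), min_stability, k_min)
    return results, chosen


def rank_table(results: list[ConsensusResult]) -> pd.DataFrame:
    """Per-k summary of a rank scan."""
    return pd.DataFrame({
        "k": [r.k for r in results],
        "cophenetic": [r.cophenetic for r in results],
        "dispersion": [r.dispersion for r in results],
        "n_runs": [r.n_runs for r in results],
    }).set_index("k")
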