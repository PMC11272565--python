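"""Reference-guided methylation deconvolution and cell-type expression.

Bulk tumor methylation is modelled as a convex mixture of cell-type
methylation profiles: for sample j with beta vector b_j over informative
loci and class profiles S (loci × cell types),

    b_j ≈ S p_j,   p_j ≥ 0,  Σ_t p_jt = 1.

Informative loci are ranked by pairwise two-sample t statistics between
the labelled reference profiles.  Proportions are estimated per sample by
least squares constrained to the simplex (solved exactly by active-set
enumeration — cell-type counts are small); an optional refinement
alternates the simplex fit with a box-constrained re-fit of the class
profiles themselves, so the fitted profiles may drift from the reference
means while remaining highly correlated with them.

Given the proportions, per-group cell-type expression E (genes × types)
is recovered from bulk expression by nonnegative least squares across the
group's samples:  x_gj ≈ Σ_t p_jt E_gt,  E ≥ 0.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import lsq_linear, nnls

logger = logging.getLogger("stromapat")


@dataclass
class ReferencePanel:
    """Labelled reference methylation profiles (loci × profiles)."""
    beta: pd.DataFrame
    class_labels: pd.Series             # profile id -> cell-type label
    selected_loci: list = field(default_factory=list)

    def __post_init__(self):
        self.class_labels = self.class_labels.reindex(self.beta.columns)
        counts = self.class_labels.value_counts()
        if (counts < 2).any():
            bad = counts[counts < 2].index.tolist()
            raise ValueError(f"reference classes with < 2 profiles: {bad}")

    @property
    def classes(self) -> list:
        return sorted(self.class_labels.unique())

    @property
    def class_means(self) -> pd.DataFrame:
        """Per-class mean beta profile (loci × classes)."""
        return self.beta.T.groupby(self.class_labels).mean().T[self.classes]


@dataclass
class ProportionMatrix:
    """Per-sample cell-type fractions; rows on the simplex."""
    fractions: pd.DataFrame             # samples × cell types
    converged: bool = True
    n_iter: int = 0

    def __post_init__(self):
        rows = self.fractions.to_numpy().sum(axis=1)
        if not np.allclose(rows, 1.0, atol=1e-9):
            raise ValueError("proportion rows must sum to 1")


@dataclass
class CellTypeExpressionEstimate:
    estimate: pd.DataFrame              # genes × cell types, ≥ 0
    se: pd.DataFrame                    # from the unconstrained information
    group_label: str
    at_boundary: pd.DataFrame = None    # True where the fit hit E = 0


# ---------------------------------------------------------------------------
# locus selection
# ---------------------------------------------------------------------------

def select_informative_loci(panel: ReferencePanel, n_loci: int = 400) -> list:
    """Pick the loci that best distinguish the reference classes.

    For every unordered pair of classes, loci are ranked by the magnitude
    of the two-sample t statistic between the pair's reference profiles
    (loci with zero within-pair variance rank at ±∞ when the means differ,
    and at 0 when they do not).  Pairs then contribute equal shares
    round-robin by rank, skipping loci already taken, until *n_loci*
    unique loci are collected.
    """
    classes = panel.classes
    if len(classes) < 2:
        raise ValueError("need at least 2 reference classes")
    if n_loci > panel.beta.shape[0]:
        raise ValueError(f"n_loci={n_loci} exceeds available loci "
                         f"({panel.beta.shape[0]})")
    rankings = []
    for a, b in itertools.combinations(classes, 2):
        Xa = panel.beta.loc[:, panel.class_labels == a].to_numpy()
        Xb = panel.beta.loc[:, panel.class_labels == b].to_numpy()
        with np.errstate(divide="ignore", invalid="ignore"):
            t, _ = stats.ttest_ind(Xa, Xb, axis=1)
        t = np.asarray(t)
        diff = Xa.mean(axis=1) - Xb.mean(axis=1)
        degenerate = ~np.isfinite(t)
        t[degenerate] = np.where(diff[degenerate] != 0, np.inf, 0.0)
        order = np.argsort(-np.abs(t), kind="stable")
        rankings.append(panel.beta.index[order])

    chosen: list = []
    taken = set()
    cursors = [0] * len(rankings)
    while len(chosen) < n_loci:
        progressed = False
        for p, ranking in enumerate(rankings):
            while cursors[p] < len(ranking) and ranking[cursors[p]] in taken:
                cursors[p] += 1
            if cursors[p] < len(ranking):
                locus = ranking[cursors[p]]
                chosen.append(locus)
                taken.add(locus)
                cursors[p] += 1
                progressed = True
                if len(chosen) == n_loci:
                    break
        if not progressed:
            break
    return chosen


# ---------------------------------------------------------------------------
# simplex-constrained least squares (exact, small K)
# ---------------------------------------------------------------------------

def simplex_lstsq(A: np.ndarray, b: np.ndarray) -> np.ndarray:
    """argmin ‖A p − b‖² subject to p ≥ 0, Σ p = 1, solved exactly.

    The optimum of this convex QP lies on some face of the simplex, so we
    enumerate support sets (feasible for the handful of cell types used
    here), solve the equality-constrained problem on each support via the
    KKT system, and keep the best feasible solution.
    """
    K = A.shape[1]
    best_obj, best_p = np.inf, None
    for r in range(1, K + 1):
        for support in itertools.combinations(range(K), r):
            S = A[:, support]
            G = S.T @ S
            kkt = np.zeros((r + 1, r + 1))
            kkt[:r, :r] = 2.0 * G
            kkt[:r, r] = 1.0
            kkt[r, :r] = 1.0
            rhs = np.concatenate([2.0 * S.T @ b, [1.0]])
            try:
                sol = np.linalg.solve(kkt, rhs)
            except np.linalg.LinAlgError:
                continue
            x = sol[:r]
            if (x < -1e-10).any():
                continue
            res = S @ x - b
            obj = float(res @ res)
            if obj < best_obj - 1e-15:
                best_obj = obj
                p = np.zeros(K)
                p[list(support)] = np.clip(x, 0.0, None)
                best_p = p / p.sum()
    if best_p is None:  # pathological (e.g., all-zero A); fall back to uniform
        best_p = np.full(K, 1.0 / K)
    return best_p


def estimate_proportions(bulk: pd.DataFrame, panel: ReferencePanel,
                         mode: str = "refine", tol: float = 1e-6,
                         max_iter: int = 200,
                         ) -> tuple[ProportionMatrix, pd.DataFrame]:
    """Deconvolve bulk beta values into cell-type fractions.

    Parameters
    ----------
    bulk:
        Locus-by-sample beta matrix; restricted to ``panel.selected_loci``
        when that list is non-empty, otherwise to the loci shared with the
        panel.
    mode:
        ``reference_fixed`` — one simplex-constrained fit of each sample on
        the reference class means.  ``refine`` (default) — alternate the
        per-sample simplex fit with a per-locus box-constrained ([0, 1])
        re-fit of the class beta profiles, initialised at the class means,
        until the largest absolute proportion change < *tol* or *max_iter*
        alternations.

    Returns the proportions and the fitted class beta profiles.  In refine
    mode each fitted profile's Pearson correlation against its reference
    class mean is logged (the fitted compartments should remain
    recognisable as cancer / stroma / immune).
    """
    loci = panel.selected_loci if panel.selected_loci else \
        bulk.index.intersection(panel.beta.index).tolist()
    missing = [l for l in loci if l not in bulk.index]
    if missing:
        raise ValueError(f"bulk matrix lacks {len(missing)} selected loci "
                         f"(first: {missing[:3]})")
    classes = panel.classes
    S0 = panel.class_means.loc[loci].to_numpy(dtype=float)
    if np.linalg.matrix_rank(S0) < len(classes):
        raise np.linalg.LinAlgError(
            "reference class-mean profiles are collinear on the selected loci")
    B = bulk.loc[loci].to_numpy(dtype=float)
    n_samples = B.shape[1]

    def fit_all(S):
        return np.stack([simplex_lstsq(S, B[:, j]) for j in range(n_samples)])

    S = S0.copy()
    P = fit_all(S)
    converged, it = True, 0
    if mode == "refine":
        converged = False
        prev_obj = np.inf
        for it in range(1, max_iter + 1):
            # (b) per-locus class-beta re-fit given proportions, boxed to [0, 1]
            for i in range(S.shape[0]):
                S[i] = lsq_linear(P, B[i], bounds=(0.0, 1.0),
                                  method="bvls").x
            # (a) per-sample proportions given class beta
            P_new = fit_all(S)
            obj = float(((S @ P_new.T - B) ** 2).sum())
            if obj > prev_obj + 1e-9:
                logger.warning("estimate_proportions: objective increased at "
                               "alternation %d", it)
            prev_obj = obj
            delta = np.abs(P_new - P).max()
            P = P_new
            if delta < tol:
                converged = True
                break
        if not converged:
            logger.warning("estimate_proportions: refine mode did not converge "
                           "in %d alternations (max |Δp| still > %g)", max_iter, tol)
        for t, cls in enumerate(classes):
            r = np.corrcoef(S[:, t], S0[:, t])[0, 1]
            logger.info("fitted %s profile vs reference mean: r = %.3f", cls, r)
    elif mode != "reference_fixed":
        raise ValueError(f"unknown mode {mode!r}")

    fractions = pd.DataFrame(P, index=bulk.columns, columns=classes)
    fitted = pd.DataFrame(S, index=loci, columns=classes)
    return ProportionMatrix(fractions=fractions, converged=converged,
                            n_iter=it), fitted


def validate_purity(pm: ProportionMatrix, celltype: str,
                    purity: pd.Series) -> tuple[float, float]:
    """Pearson correlation of an estimated cell-type fraction with an
    externally supplied purity vector (e.g., copy-number based), on the
    overlapping samples.  Missing purity entries are dropped and counted."""
    frac = pm.fractions[celltype]
    purity = pd.Series(purity).dropna()
    common = frac.index.intersection(purity.index)
    n_missing = len(frac) - len(common)
    if n_missing:
        logger.info("validate_purity: %d samples without purity dropped", n_missing)
    if len(common) < 3:
        raise ValueError(f"only {len(common)} overlapping samples; need ≥ 3")
    x = frac.loc[common].to_numpy()
    y = purity.loc[common].to_numpy()
    if np.std(x) == 0 or np.std(y) == 0:
        logger.warning("validate_purity: constant vector, correlation undefined")
        return float("nan"), float("nan")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


# ---------------------------------------------------------------------------
# stage 2: cell-type expression from bulk expression + proportions
# ---------------------------------------------------------------------------

def estimate_celltype_expression(bulk_expr: pd.DataFrame, pm: ProportionMatrix,
                                 group_assignment: pd.Series,
                                 ) -> dict[str, CellTypeExpressionEstimate]:
    """Per-group, per-gene nonnegative least-squares cell-type expression.

    Within each group, for each gene g solve

        min_{E_g ≥ 0} Σ_j ( x_gj − Σ_t p_jt E_gt )²

    over the group's samples.  Standard errors come from the unconstrained
    information at the solution, σ̂² (FᵀF)⁻¹; coordinates pinned at zero
    are flagged in ``at_boundary`` (their SE is nominal).
    """
    groups = pd.Series(group_assignment)
    classes = list(pm.fractions.columns)
    K = len(classes)
    out = {}
    for g in sorted(groups.unique()):
        samples = groups.index[groups == g]
        samples = pd.Index(samples).intersection(bulk_expr.columns)
        missing_props = [s for s in samples if s not in pm.fractions.index]
        if missing_props:
            raise ValueError(f"group {g!r}: no proportions for samples "
                             f"{missing_props[:3]}")
        if len(samples) < K + 2:
            raise ValueError(f"group {g!r} has {len(samples)} samples; "
                             f"need ≥ {K + 2}")
        F = pm.fractions.loc[samples, classes].to_numpy(dtype=float)
        near_const = F.std(axis=0) < 1e-8
        if near_const.any():
            for t in np.nonzero(near_const)[0]:
                logger.warning("group %r: proportions of %s nearly constant — "
                               "its expression is weakly identified", g, classes[t])
        X = bulk_expr.loc[:, samples].to_numpy(dtype=float)
        n = len(samples)
        FtF = F.T @ F
        FtF_inv = np.linalg.inv(FtF)
        # unconstrained solution for every gene at once
        E = (FtF_inv @ (F.T @ X.T)).T                     # genes × K
        neg = (E < 0).any(axis=1)
        for gi in np.nonzero(neg)[0]:
            E[gi], _ = nnls(F, X[gi])
        resid = X - (F @ E.T).T
        sigma2 = (resid ** 2).sum(axis=1) / max(n - K, 1)
        se = np.sqrt(np.outer(sigma2, np.diag(FtF_inv)))
        out[str(g)] = CellTypeExpressionEstimate(
            estimate=pd.DataFrame(E, index=bulk_expr.index, columns=classes),
            se=pd.DataFrame(se, index=bulk_expr.index, columns=classes),
            group_label=str(g),
            at_boundary=pd.DataFrame(E == 0, index=bulk_expr.index,
                                     columns=classes))
    return out


def celltype_expression_contrast(est_a: CellTypeExpressionEstimate,
                                 est_b: CellTypeExpressionEstimate,
                                 bh_correct: bool = False) -> pd.DataFrame:
    """Per-gene, per-cell-type difference ΔE = E_a − E_b with z statistics.

    z = ΔE / sqrt(se_a² + se_b²); two-sided normal p-values, optionally
    Benjamini–Hochberg adjusted within each cell type.
    """
    delta = est_a.estimate - est_b.estimate
    pooled = np.sqrt(est_a.se ** 2 + est_b.se ** 2)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = delta / pooled
    z = z.replace([np.inf, -np.inf], np.nan)
    p = pd.DataFrame(2.0 * stats.norm.sf(np.abs(z.to_numpy())),
                     index=z.index, columns=z.columns)
    if bh_correct:
        for col in p.columns:
            pv = p[col].dropna()
            order = np.argsort(pv.to_numpy())
            m = len(pv)
            adj = np.empty(m)
            ranked = pv.to_numpy()[order] * m / (np.arange(m) + 1)
            adj[order] = np.minimum.accumulate(ranked[::-1])[::-1]
            p.loc[pv.index, col] = np.clip(adj, 0, 1)
    long = pd.concat({"delta": delta, "z": z, "p": p}, axis=1)
    long.columns.names = ["stat", "cell_type"]
    return long
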