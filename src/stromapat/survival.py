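"""Survival stratification of pattern scores (progression-free interval).

Kaplan–Meier curves, two-group log-rank tests and univariate Cox
proportional-hazards fits go through lifelines; cutpoint selection on a
continuous score follows the maximally-selected-rank-statistic idea: over
every threshold leaving at least ``minprop`` of the samples on each side,
pick the one maximising the standardised two-group log-rank statistic
z = (O − E) / √V.  Because the cutoff is optimised, downstream p-values
from that dichotomisation are selection-biased; results carry an explicit
flag saying so.  A plain median split is provided as the unbiased
alternative.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError
from lifelines.statistics import logrank_test as _ll_logrank

logger = logging.getLogger("stromapat")


def validate_survival_table(df: pd.DataFrame) -> pd.DataFrame:
    """Check a survival table: positive times, binary events, no missing."""
    for col in ("time", "event"):
        if col not in df.columns:
            raise ValueError(f"survival table lacks column {col!r}")
    if df[["time", "event"]].isna().any().any():
        raise ValueError("missing time/event values")
    if (df["time"] <= 0).any():
        raise ValueError("event/censoring times must be positive")
    if not df["event"].isin([0, 1]).all():
        raise ValueError("event indicator must be 0/1")
    return df


def km_estimate(df: pd.DataFrame, by_group: bool = True,
                group_col: str = "group") -> dict[str, pd.DataFrame]:
    """Product-limit survival curves, one per group (or one overall).

    Returns, per group, a frame with columns time, survival, at_risk.
    """
    validate_survival_table(df)
    if df["event"].sum() < 1:
        logger.warning("km_estimate: no events; curves are flat at 1")
    groups = df[group_col].unique() if by_group and group_col in df else ["all"]
    out = {}
    for g in groups:
        sub = df if g == "all" else df[df[group_col] == g]
        if len(sub) == 0:
            raise ValueError(f"empty group {g!r}")
        kmf = KaplanMeierFitter()
        kmf.fit(sub["time"], sub["event"])
        table = kmf.event_table
        out[str(g)] = pd.DataFrame({
            "time": kmf.survival_function_.index.to_numpy(),
            "survival": kmf.survival_function_["KM_estimate"].to_numpy(),
            "at_risk": table["at_risk"].reindex(
                kmf.survival_function_.index).to_numpy(),
        })
    return out


def two_group_logrank_terms(time, event, in_group_a) -> tuple[float, float]:
    """(O − E, V) for group A of the two-group log-rank statistic.

    At each distinct event time, with n at risk (n_a in group A) and d
    events (d_a in A), the expected A-events are d·n_a/n and the
    hypergeometric variance is d·(n_a/n)·(1 − n_a/n)·(n − d)/(n − 1);
    tied event times enter a single term.  This is also the Cox partial-
    likelihood score and information at β = 0 for the binary group
    covariate (exactly so in the absence of ties).
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    a = np.asarray(in_group_a, dtype=bool)
    order = np.argsort(time, kind="stable")
    time, event, a = time[order], event[order], a[order]
    o_minus_e = 0.0
    var = 0.0
    n = len(time)
    i = 0
    n_risk, n_risk_a = n, int(a.sum())
    while i < n:
        j = i
        d = d_a = removed = removed_a = 0
        while j < n and time[j] == time[i]:
            d += event[j]
            d_a += event[j] * a[j]
            removed += 1
            removed_a += int(a[j])
            j += 1
        if d > 0 and n_risk > 1:
            frac = n_risk_a / n_risk
            o_minus_e += d_a - d * frac
            var += d * frac * (1 - frac) * (n_risk - d) / (n_risk - 1)
        elif d > 0 and n_risk == 1:
            o_minus_e += d_a - d * (n_risk_a / n_risk)
        n_risk -= removed
        n_risk_a -= removed_a
        i = j
    return float(o_minus_e), float(var)


def logrank_test(df: pd.DataFrame, group_col: str = "group") -> tuple[float, float]:
    """Two-group log-rank test; returns (chi-square, p) with 1 df."""
    validate_survival_table(df)
    groups = pd.unique(df[group_col])
    if len(groups) != 2:
        raise ValueError(f"log-rank test needs exactly 2 groups, got {len(groups)}")
    mask = df[group_col] == groups[0]
    if df["event"].sum() < 1:
        raise ValueError("log-rank test needs at least one event")
    res = _ll_logrank(df.loc[mask, "time"], df.loc[~mask, "time"],
                      df.loc[mask, "event"], df.loc[~mask, "event"])
    return float(res.test_statistic), float(res.p_value)


@dataclass
class CoxResult:
    hazard_ratio: float
    ci_low: float
    ci_high: float
    p: float
    log_likelihood: float
    beta: float
    warning: str = ""


def cox_univariate(df: pd.DataFrame, covariate: str) -> CoxResult:
    """Univariate Cox proportional-hazards fit (Efron handling of ties).

    Degenerate cases are reported rather than raised: a constant covariate
    returns HR = 1, p = 1 with a warning; monotone likelihood (perfect
    separation) returns the capped coefficient with a warning flag.
    """
    validate_survival_table(df)
    x = df[covariate]
    if x.nunique() <= 1:
        logger.warning("cox_univariate: covariate %r constant; no information",
                       covariate)
        return CoxResult(1.0, np.nan, np.nan, 1.0, np.nan, 0.0,
                         warning="constant covariate")
    cph = CoxPHFitter()
    data = df[["time", "event", covariate]].copy()
    try:
        cph.fit(data, duration_col="time", event_col="event")
    except ConvergenceError as err:
        logger.warning("cox_univariate: %s", err)
        return CoxResult(np.nan, np.nan, np.nan, np.nan, np.nan, np.nan,
                         warning=f"non-convergence: {err}")
    beta = float(cph.params_[covariate])
    warning = ""
    if abs(beta) > 10:
        warning = "monotone likelihood suspected (capped coefficient)"
        logger.warning("cox_univariate: %s for %r", warning, covariate)
    ci = cph.confidence_intervals_.loc[covariate]
    return CoxResult(
        hazard_ratio=float(np.exp(beta)),
        ci_low=float(np.exp(ci.iloc[0])),
        ci_high=float(np.exp(ci.iloc[1])),
        p=float(cph.summary.loc[covariate, "p"]),
        log_likelihood=float(cph.log_likelihood_),
        beta=beta, warning=warning)


@dataclass
class CutpointResult:
    cutoff: float
    statistic: float            # standardised log-rank statistic |z| at the cutoff
    selection_biased: bool = True   # p-values after this dichotomisation are biased


def optimal_cutpoint(df: pd.DataFrame, score_col: str = "score",
                     minprop: float = 0.1) -> CutpointResult:
    """Maximally selected log-rank cutpoint on a continuous score.

    Candidate cutoffs are midpoints between adjacent distinct score values
    that leave at least ``minprop`` of the samples on each side; the cutoff
    maximising |z| = |O − E| / √V is returned (smallest cutoff on ties).
    """
    validate_survival_table(df)
    if len(df) < 10:
        raise ValueError("need at least 10 samples for cutpoint selection")
    score = df[score_col].to_numpy(dtype=float)
    if np.unique(score).size < 2:
        raise ValueError("score is constant; no cutpoint exists")
    n = len(score)
    distinct = np.unique(score)
    mids = (distinct[:-1] + distinct[1:]) / 2.0
    time = df["time"].to_numpy()
    event = df["event"].to_numpy()
    best = None
    for cut in mids:
        high = score > cut
        n_high = int(high.sum())
        if min(n_high, n - n_high) < minprop * n:
            continue
        ome, var = two_group_logrank_terms(time, event, high)
        if var <= 0:
            continue
        z = abs(ome) / np.sqrt(var)
        if best is None or z > best[1] + 1e-12:
            best = (float(cut), float(z))
    if best is None:
        raise ValueError("all admissible splits are degenerate "
                         "(no events or no variance)")
    return CutpointResult(cutoff=best[0], statistic=best[1])


def median_split(score: pd.Series) -> pd.Series:
    """Dichotomise at the median: high = score > median, low = score ≤ median."""
    score = pd.Series(score)
    if score.nunique() <= 1:
        raise ValueError("score is constant; median split undefined")
    med = float(score.median())
    return pd.Series(np.where(score > med, "high", "low"),
                     index=score.index, name="group")


def assign_groups(df: pd.DataFrame, score_col: str = "score",
                  cut: str = "optimal", minprop: float = 0.1,
                  ) -> tuple[pd.DataFrame, dict]:
    """Attach a high/low group column by the chosen cutpoint policy."""
    df = df.copy()
    if cut == "median":
        df["group"] = median_split(df[score_col])
        meta = {"cut": "median", "cutoff": float(df[score_col].median()),
                "selection_biased": False}
    elif cut == "optimal":
        res = optimal_cutpoint(df, score_col=score_col, minprop=minprop)
        df["group"] = np.where(df[score_col] > res.cutoff, "high", "low")
        meta = {"cut": "optimal", "cutoff": res.cutoff,
                "statistic": res.statistic, "selection_biased": True}
    else:
        raise ValueError(f"unknown cut policy {cut!r}")
    return df, meta
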