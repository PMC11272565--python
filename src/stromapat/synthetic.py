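"""Synthetic data with known ground truth for every pipeline stage.

Each generator plants the statistical structure its downstream consumer
assumes — nonnegative patterns for the factorization, labelled reference
beta profiles and Dirichlet mixtures for the deconvolution, per-type
pattern usage for single cells, and a proportional-hazards score effect
for survival — and returns the truth alongside the data so every stage
can be checked by parameter recovery.

All randomness flows through ``numpy.random.default_rng`` seeded per call;
identical seeds reproduce every field bit-identically.  Noise models are
deliberately simple (Gaussian, clipped to the valid range; independent
Bernoulli dropout): they match the least-squares objectives used
downstream and keep recovery tests well-posed.  No attempt is made at
realistic single-cell count distributions, library sizes or batch effects.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .deconvolution import ReferencePanel


@dataclass
class SyntheticTruth:
    """Ground-truth objects produced by the generators (fields fill in as
    the corresponding generators run)."""
    seed: int
    W_true: pd.DataFrame = None            # genes × patterns
    H_true: pd.DataFrame = None            # patterns × samples
    marker_assignment: pd.Series = None    # gene -> pattern label or "background"
    proportions_true: pd.DataFrame = None  # samples × cell types (simplex rows)
    E_true: dict = field(default_factory=dict)   # group -> genes × cell types
    informative_loci: list = field(default_factory=list)
    log_hr_true: float = None


def _rng(seed: int) -> np.random.Generator:
    return np.random.default_rng(seed)


def generate_patterns(n_genes: int, k: int, markers_per_pattern: int,
                      background_level: float = 0.05, seed: int = 0,
                      background_scale: float = 0.5,
                      ) -> tuple[pd.DataFrame, pd.Series]:
    """Plant k patterns: marker genes load (almost) one-hot, the rest uniformly.

    Marker gene rows carry loading 1 on their own pattern and
    ``background_level`` on every other; background gene rows load equally
    on all patterns, with a random per-gene magnitude (scaled by
    ``background_scale`` relative to marker loadings) so genes differ in
    overall expression while remaining pattern-uninformative.
    """
    if k < 2:
        raise ValueError("need k ≥ 2 patterns")
    if markers_per_pattern < 1 or n_genes < markers_per_pattern * k:
        raise ValueError("markers_per_pattern · k must be ≤ n_genes")
    if background_level < 0:
        raise ValueError("background_level must be ≥ 0")
    rng = _rng(seed)
    patterns = [f"P{i + 1}" for i in range(k)]
    genes = [f"g{i:05d}" for i in range(n_genes)]
    W = np.full((n_genes, k), 0.0)
    assignment = np.array(["background"] * n_genes, dtype=object)
    n_mark = markers_per_pattern * k
    for q in range(k):
        rows = slice(q * markers_per_pattern, (q + 1) * markers_per_pattern)
        W[rows, :] = background_level
        W[rows, q] = 1.0
        assignment[rows] = patterns[q]
    magnitude = rng.lognormal(mean=0.0, sigma=0.4, size=n_genes - n_mark)
    W[n_mark:, :] = background_scale * magnitude[:, None] / k
    return (pd.DataFrame(W, index=genes, columns=patterns),
            pd.Series(assignment, index=genes, name="marker_assignment"))


def generate_expression_matrix(W_true: pd.DataFrame, n_samples: int,
                               noise_sd: float = 0.0, seed: int = 0,
                               dominant_boost: float = 2.0,
                               idiosyncratic_frac: float = 0.1,
                               idiosyncratic_genes: int = 60,
                               idiosyncratic_scale: float = 20.0,
                               ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """X = W_true · H_true + noise, clipped at zero.

    H_true is gamma-distributed with each sample's dominant pattern
    (assigned round-robin so every pattern owns samples) raised to the
    sample's maximum weight plus ``dominant_boost``, giving the consensus
    clustering a recoverable block structure.  ``noise_sd`` is in
    expression units (pass a multiple of the noiseless signal sd for
    relative noise).

    The noise model has two parts, both vanishing at ``noise_sd = 0`` so
    the noiseless identity X = W_true·H_true is exact: i.i.d. Gaussian
    noise, plus sample-specific spike programs — a fraction
    ``idiosyncratic_frac`` of samples each over-express a random set of
    ``idiosyncratic_genes`` genes by ~``idiosyncratic_scale``·noise_sd.
    The spikes emulate line-specific expression programs of real cell
    lines; they are what bounds the recoverable factorization rank (extra
    patterns chase different spiky samples on different restarts, so
    over-factorized consensus runs lose stability, as over-factorization
    does on real data).
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be ≥ 0")
    rng = _rng(seed)
    k = W_true.shape[1]
    n_genes = W_true.shape[0]
    H = rng.gamma(shape=2.0, scale=0.5, size=(k, n_samples))
    dominant = np.arange(n_samples) % k
    H[dominant, np.arange(n_samples)] = H.max(axis=0) + dominant_boost
    samples = [f"s{j:04d}" for j in range(n_samples)]
    X = W_true.to_numpy() @ H
    if noise_sd > 0:
        n_spiky = int(round(idiosyncratic_frac * n_samples))
        spiky = rng.choice(n_samples, size=n_spiky, replace=False)
        for j in spiky:
            genes = rng.choice(n_genes, size=min(idiosyncratic_genes, n_genes),
                               replace=False)
            amp = rng.uniform(0.5, 1.0) * idiosyncratic_scale * noise_sd
            X[genes, j] += amp
        X = X + rng.normal(0.0, noise_sd, size=X.shape)
    X = np.clip(X, 0.0, None)
    return (pd.DataFrame(X, index=W_true.index, columns=samples),
            pd.DataFrame(H, index=W_true.columns, columns=samples))


def generate_reference_methylation(n_loci: int, cell_types: list,
                                   n_informative: int, profiles_per_type: int,
                                   delta: float = 0.5, noise_sd: float = 0.03,
                                   seed: int = 0,
                                   ) -> tuple[ReferencePanel, list]:
    """Labelled reference beta panel with planted informative loci.

    Non-informative loci share one mean across all classes.  Each
    informative locus shifts one randomly chosen class by ``delta``
    (direction chosen to stay inside [0, 1]), so every informative locus
    separates at least one class pair by ≥ delta in mean.  Profiles add
    Gaussian noise, clipped to [0, 1].  Returns the panel and the planted
    informative locus ids.
    """
    if not (0 < delta <= 1):
        raise ValueError("delta must be in (0, 1]")
    if n_informative > n_loci:
        raise ValueError("n_informative must be ≤ n_loci")
    if noise_sd < 0:
        raise ValueError("noise_sd must be ≥ 0")
    rng = _rng(seed)
    n_types = len(cell_types)
    loci = [f"cg{i:06d}" for i in range(n_loci)]
    base = rng.uniform(0.15, 0.85, size=n_loci)
    means = np.tile(base[:, None], (1, n_types))
    shift_class = rng.integers(0, n_types, size=n_informative)
    for i in range(n_informative):
        direction = 1.0 if base[i] + delta <= 1.0 else -1.0
        means[i, shift_class[i]] = base[i] + direction * delta
    cols, labels = [], []
    profiles = np.empty((n_loci, n_types * profiles_per_type))
    for t, ct in enumerate(cell_types):
        for rpl in range(profiles_per_type):
            j = t * profiles_per_type + rpl
            noise = rng.normal(0.0, noise_sd, size=n_loci) if noise_sd > 0 else 0.0
            profiles[:, j] = np.clip(means[:, t] + noise, 0.0, 1.0)
            cols.append(f"{ct}_{rpl:02d}")
            labels.append(ct)
    beta = pd.DataFrame(profiles, index=loci, columns=cols)
    panel = ReferencePanel(beta=beta, class_labels=pd.Series(labels, index=cols))
    return panel, loci[:n_informative]


def generate_bulk_mixtures(panel: ReferencePanel, n_samples: int,
                           dirichlet_alpha, noise_sd: float = 0.03,
                           seed: int = 0,
                           ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Bulk beta = class-mean profiles · Dirichlet proportions + noise, clipped.

    Returns the locus-by-sample bulk matrix and the true sample-by-type
    proportions (rows exactly on the simplex).
    """
    alpha = np.asarray(dirichlet_alpha, dtype=float)
    classes = panel.classes
    if len(alpha) != len(classes):
        raise ValueError("dirichlet_alpha length must equal number of cell types")
    if noise_sd < 0:
        raise ValueError("noise_sd must be ≥ 0")
    rng = _rng(seed)
    P = rng.dirichlet(alpha, size=n_samples)          # samples × types
    S = panel.class_means.to_numpy()                  # loci × types
    B = S @ P.T
    if noise_sd > 0:
        B = B + rng.normal(0.0, noise_sd, size=B.shape)
    B = np.clip(B, 0.0, 1.0)
    samples = [f"b{j:04d}" for j in range(n_samples)]
    return (pd.DataFrame(B, index=panel.beta.index, columns=samples),
            pd.DataFrame(P, index=samples, columns=classes))


def generate_bulk_expression(E_true: dict, proportions_true: pd.DataFrame,
                             group_labels: pd.Series, noise_sd: float = 0.0,
                             seed: int = 0) -> pd.DataFrame:
    """Bulk expression from per-group cell-type expression and mixing fractions.

    ``E_true`` maps group label -> genes × cell-types expression frame (so
    group-level cell-type differences can be planted); sample j of group g
    gets  x_j = E_true[g] · p_j + noise, clipped at 0.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be ≥ 0")
    rng = _rng(seed)
    groups = pd.Series(group_labels)
    first = next(iter(E_true.values()))
    genes = first.index
    classes = list(proportions_true.columns)
    X = np.empty((len(genes), len(proportions_true)))
    for j, sample in enumerate(proportions_true.index):
        E = E_true[groups.loc[sample]]
        X[:, j] = E[classes].to_numpy() @ proportions_true.loc[sample].to_numpy()
    if noise_sd > 0:
        X = X + rng.normal(0.0, noise_sd, size=X.shape)
    X = np.clip(X, 0.0, None)
    return pd.DataFrame(X, index=genes, columns=proportions_true.index)


def generate_single_cells(W_true: pd.DataFrame, type_usage: dict,
                          n_cells_per_type: int, dropout_rate: float = 0.0,
                          noise_sd: float = 0.0, seed: int = 0,
                          usage_jitter: float = 0.1,
                          ) -> tuple[pd.DataFrame, pd.Series]:
    """Single cells whose profiles live in the column space of W_true.

    Each cell of a type draws weights = type_usage[type] + nonnegative
    jitter, profile = W_true · weights (+ Gaussian noise), then entries
    are zeroed independently with probability ``dropout_rate`` — a minimal
    stand-in for single-cell sparsity.
    """
    if not (0 <= dropout_rate < 1):
        raise ValueError("dropout_rate must be in [0, 1)")
    if noise_sd < 0:
        raise ValueError("noise_sd must be ≥ 0")
    rng = _rng(seed)
    k = W_true.shape[1]
    Wv = W_true.to_numpy()
    cols, labels, profiles = [], [], []
    for ct, usage in type_usage.items():
        usage = np.asarray(usage, dtype=float)
        if usage.shape != (k,):
            raise ValueError(f"type_usage[{ct!r}] must have length k={k}")
        for c in range(n_cells_per_type):
            w = usage.copy()
            if usage_jitter > 0:
                w = w + rng.uniform(0.0, usage_jitter, size=k) * (usage > 0)
            prof = Wv @ w
            if noise_sd > 0:
                prof = prof + rng.normal(0.0, noise_sd, size=prof.shape)
            if dropout_rate > 0:
                prof = prof * (rng.uniform(size=prof.shape) >= dropout_rate)
            profiles.append(np.clip(prof, 0.0, None))
            cols.append(f"{ct}_c{c:04d}")
            labels.append(ct)
    X = pd.DataFrame(np.column_stack(profiles), index=W_true.index, columns=cols)
    return X, pd.Series(labels, index=cols, name="cell_type")


def generate_survival(score: pd.Series, log_hr: float,
                      baseline_rate: float, censor_rate: float,
                      seed: int = 0) -> pd.DataFrame:
    """Proportional-hazards event times driven by a standardised score.

    Event times are exponential with rate baseline_rate·exp(log_hr·z)
    where z is the standardised score; censoring times are independent
    exponential(censor_rate).  Returns a survival table with columns
    time, event, score.

    *seed* must be independent of whatever randomness produced *score*:
    reusing the score's seed restarts the same stream and correlates the
    times with the score even at log_hr = 0.
    """
    if baseline_rate <= 0 or censor_rate <= 0:
        raise ValueError("baseline_rate and censor_rate must be positive")
    rng = _rng(seed)
    score = pd.Series(score, dtype=float)
    sd = score.std(ddof=0)
    z = (score - score.mean()) / sd if sd > 0 else score * 0.0
    rate = baseline_rate * np.exp(log_hr * z.to_numpy())
    t_event = rng.exponential(1.0 / rate)
    t_cens = rng.exponential(1.0 / censor_rate, size=len(score))
    time = np.minimum(t_event, t_cens)
    event = (t_event <= t_cens).astype(int)
    return pd.DataFrame({"time": time, "event": event,
                         "score": score.to_numpy()}, index=score.index)


def truth_to_json(truth: SyntheticTruth) -> dict:
    """JSON-serialisable sidecar representation of the ground truth."""
    out: dict = {"seed": truth.seed, "log_hr_true": truth.log_hr_true,
                 "informative_loci": list(truth.informative_loci)}
    if truth.W_true is not None:
        out["W_true"] = truth.W_true.to_dict(orient="split")
    if truth.H_true is not None:
        out["H_true"] = truth.H_true.to_dict(orient="split")
    if truth.marker_assignment is not None:
        out["marker_assignment"] = truth.marker_assignment.to_dict()
    if truth.proportions_true is not None:
        out["proportions_true"] = truth.proportions_true.to_dict(orient="split")
    out["E_true"] = {g: df.to_dict(orient="split")
                     for g, df in truth.E_true.items()}
    return out
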