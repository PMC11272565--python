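# Methods

`stromapat` re-implements, as a tested and fully synthetic-verifiable
pipeline, an analysis chain for squamous-cell carcinoma transcriptomics:
discover malignant gene-expression patterns in cancer cell lines by
nonnegative matrix factorization (NMF), transfer them by projection into
single-cell and bulk tumor expression, attribute them to cell types via
reference-guided DNA-methylation deconvolution, and test their prognostic
value against progression-free survival.  Every stage has a synthetic
generator that plants the structure the stage assumes, so correctness is
established by parameter recovery rather than by re-analysis of the
original cohorts.

## Pattern discovery (NMF)

The gene-by-sample expression matrix X (nonnegative, log-scale) is
factored as X ≈ W·H by minimising the generalised Kullback–Leibler
divergence

    D(X ‖ WH) = Σ_ij [ x_ij log(x_ij/(WH)_ij) − x_ij + (WH)_ij ]

with the classical multiplicative updates

    H ← H ⊙ [Wᵀ(X ⊘ WH)] ⊘ [Wᵀ1],   W ← W ⊙ [(X ⊘ WH)Hᵀ] ⊘ [1Hᵀ].

These updates decrease D monotonically; the per-iteration divergence
trace is recorded and the monotonicity is asserted in tests at 1e-9
relative tolerance.  Numerical choices: ε = 1e-12 is added to every
denominator and log argument; factors are initialised uniform(0, 1)
scaled by mean(X) from a caller-supplied seed; iteration stops when the
relative divergence change drops below `tol` (default 1e-6 for a final
fit, 1e-4 inside consensus scans, where only the dominant-pattern
assignment matters) or at `max_iter`.  All-zero gene rows are
unidentifiable under KL and are dropped with a report.  After
convergence, W's columns are normalised to unit L1 and H rescaled —
D is invariant to this gauge, which the tests verify.

Expression is expected on a log scale (microarray intensities or
log2(count+1)); ingestion offers a `log2p1` flag for raw counts.

## Rank selection by consensus clustering

For each candidate k, `n_runs` factorizations from different seeds are
summarised by the mean *connectivity* matrix (samples co-cluster when
they share an argmax pattern in H; argmax ties break toward the lowest
pattern index).  Two stability statistics are computed:

- **dispersion** — mean of 4(c − ½)² over consensus entries; 1 exactly
  when every entry is 0 or 1, i.e. when all restarts agree;
- **cophenetic correlation** — agreement between consensus distances and
  the dendrogram distances of average-linkage clustering on them.

The scan chooses the largest k, before the first sustained drop, whose
**dispersion** is within `drop_tol` (default 0.01) of the running
maximum, and only among ranks whose dispersion is at least
`min_stability` (default 0.9).  The full per-k table (both statistics)
is always returned so a caller can override the rule.

Two aspects of this rule were genuinely open and are the package's own
choices:

1. *Dispersion, not cophenetic, drives the drop rule.*  Empirically, when
   k exceeds the true rank, restarts split the true clusters differently,
   the consensus goes fractional, and dispersion falls by 0.02–0.04 — but
   the cophenetic correlation stays above 0.999, because the fuzziness is
   hierarchically structured and average-linkage reproduces it almost
   perfectly.  Cophenetic correlation does, however, degrade on
   structureless input, where dispersion can rise spuriously (many
   near-singleton clusters); the `min_stability` floor covers that case,
   and on structureless input the scan falls back to `k_min` with a
   warning.
2. *The drop must be sustained* (every later k stays below the running
   maximum minus `drop_tol`) so a single noisy dip is not mistaken for
   the end of the stable range.

## Marker genes (Kim–Park feature score)

For gene i with loadings W(i, ·), let p(i, q) = W(i, q)/Σ_q W(i, q).
The feature score is one minus the normalised entropy,
s(i) = 1 + (1/log₂k) Σ_q p(i,q) log₂ p(i,q) (0·log 0 ≡ 0): 1 for a
pattern-specific gene, 0 for a uniform one.  Markers are genes with
s > median(s) + `sigma_mult`·MAD(s) (default sigma_mult = 3; MAD scaled
by 1.4826 for consistency with σ under normality — a flag restores the
raw MAD), each assigned to its argmax-loading pattern.  The score is
invariant to row scaling and equivariant under column permutation;
all-zero rows score NaN with a warning.

## Pattern projection (transfer learning)

Each target sample's expression over the genes shared with W is
regressed on W by ordinary least squares; coefficients are the
*projection scores*, with standard errors from the per-sample residual
variance and two-sided t-test p-values.  With `center_genes` on (the
default) each shared gene is centred by its mean across target samples
**and an intercept column is added** to the design; the intercept is what
makes scores exactly invariant to adding a constant to a sample's
profile (the residual degrees of freedom are then n_shared − k − 1).
With centring off the regression is on W alone (df = n_shared − k), and
a noiseless Y = W·H returns H to machine precision.  Genes absent from
either side are dropped and listed.  A sample is "confidently projected"
when every pattern's p-value is below `alpha` (default 0.05, no
multiplicity correction — the filter is deliberately conservative in the
other direction, demanding all k patterns be identified).

## Methylation deconvolution

Bulk beta values are modelled as convex mixtures of cell-type profiles,
b_j ≈ S p_j with p_j on the simplex.  Informative loci are selected by
ranking, for every unordered pair of reference classes, the two-sample
t statistic between the pair's profiles, then drawing equal shares per
pair round-robin by rank (skipping duplicates) until `n_loci` (default
400) unique loci are collected; loci with zero within-pair variance rank
at ±∞ when the class means differ and at 0 otherwise.

Per-sample simplex-constrained least squares is solved **exactly** by
active-set enumeration: the optimum of the convex QP lies on a face of
the simplex, and with a handful of cell types all supports can be
enumerated and the equality-constrained KKT system solved on each.
Tests verify the solution against an exhaustive simplex grid at 0.01
resolution.  The default `refine` mode alternates (a) the per-sample
simplex fit with (b) a per-locus box-constrained ([0, 1]) re-fit of the
class beta profiles, initialised at the reference class means, until the
largest proportion change is below 1e-6 or 200 alternations (the total
squared error is non-increasing across alternations; non-convergence
warns and flags the result).  The fitted class profiles typically remain
correlated r > 0.99 with the reference means on synthetic mixtures — the
refinement accommodates reference/tumor drift without losing the
compartment identities.  `reference_fixed` mode (a single pass of (a))
is retained for testing and for strictly reference-faithful fits.
An externally supplied tumor-purity vector can be validated against the
estimated cancer fraction by Pearson correlation on the overlapping
samples.

## Cell-type expression from bulk mixtures

Within a sample group, for each gene the model x_gj ≈ Σ_t p_jt·E_gt is
fit by nonnegative least squares over the group's samples (the
unconstrained solution is used when already nonnegative; otherwise NNLS).
Standard errors come from the unconstrained information σ̂²(FᵀF)⁻¹;
estimates pinned at zero are flagged as boundary values.  Group
contrasts report ΔE with z = ΔE/√(se₁² + se₂²) and two-sided normal
p-values (Benjamini–Hochberg available via a flag; off by default).  A
group needs at least (cell types + 2) samples, and a cell type whose
fractions are nearly constant within a group is warned about as weakly
identified.

## Survival stratification

Kaplan–Meier estimation, the two-group log-rank test and univariate Cox
proportional-hazards fits (Efron tie handling) go through lifelines.  A
small vectorised implementation of the log-rank (O − E, V) terms exists
in-package because the maximally-selected-cutpoint search evaluates one
pair per candidate threshold; it equals the Cox score test at β = 0 for
a binary group on tie-free data, which tests verify against lifelines to
1e-6.  `optimal_cutpoint` scans midpoints between adjacent distinct
score values leaving at least `minprop` (default 0.1) of samples on each
side and returns the threshold maximising |O − E|/√V; results carry an
explicit `selection_biased` flag, since p-values computed after an
optimised dichotomisation overstate significance.  `median_split`
(high = score > median) is the unbiased alternative.  Degenerate Cox
inputs are reported rather than raised: a constant covariate returns
HR = 1, p = 1 with a warning; suspected monotone likelihood flags the
capped coefficient.

## Synthetic data generator

The generator produces every input the chain consumes, with ground truth
retained:

- **Patterns** — marker genes load 1.0 on their own pattern and
  `background_level` (default 0.05) elsewhere; background genes load
  uniformly across patterns with lognormal per-gene magnitude, weighted
  0.5 relative to marker loadings.
- **Expression** — H_true is gamma(2, 0.5) with each sample's dominant
  pattern raised to the sample's maximum weight plus 2.0 (round-robin
  dominance), so planted cluster labels are unambiguous.  The noise
  model is Gaussian (clipped at 0) **plus sample-specific spike
  programs**: 10% of samples over-express 60 random genes by roughly
  20·noise_sd.  The spikes emulate line-specific expression programs of
  real cell lines, and they are what bounds the recoverable rank — on
  spike-free planted data, over-factorized consensus runs are perfectly
  stable and *no* consensus statistic can detect the true rank.  Both
  noise components vanish at noise_sd = 0, so the noiseless identity
  X = W_true·H_true is exact.
- **Methylation** — locus base means uniform(0.15, 0.85); each planted
  informative locus shifts one random class by `delta` (default 0.5)
  in the direction that stays inside [0, 1]; profiles add Gaussian noise
  (default σ = 0.03) clipped to [0, 1].  Bulk mixtures use Dirichlet
  proportions (default α = (2, 2, 2)) times the class means, plus
  clipped noise.
- **Single cells** — per-type pattern usage vectors, nonnegative jitter,
  optional Gaussian noise, and independent Bernoulli dropout (default
  rate 0.3).  This is a minimal sparsity stand-in: no negative-binomial
  counts, library-size variation, or batch effects are modelled, so
  passing projection tests demonstrates correctness of the transfer
  machinery, not robustness to realistic single-cell noise.
- **Survival** — event times exponential with rate
  baseline·exp(log_hr·z) for the standardised driving score (defaults:
  log_hr = log 2, baseline 0.002/day, censoring 0.001/day, giving
  roughly 60% events at the simulated scale); censoring is independent
  exponential.

All generators consume a `numpy` Generator seeded per call; the pipeline
fans one global seed into per-stage substreams, and identical seeds
reproduce every artifact byte-for-byte.

## Pipeline and problem sizes

The `pipeline` command chains simulate → nmf → markers → project →
deconvolve → ctexpr → survival and writes a JSON manifest with a sha256
checksum per artifact; the whole run is a pure function of
(config, seed).  The stromal pattern fed to the survival stage is chosen
by the method itself — the learned pattern whose bulk projection score
correlates best with the estimated (not true) stromal fraction — mirroring
how the original analysis attributed patterns to compartments before
testing prognosis.  Default study sizes follow the simulated-study
design: 900 genes (180 markers), 6 patterns, 60 cell-line samples, a
2 000-locus reference panel (200 informative) with 3 × 20 profiles,
100 bulk tumors, 100 cells per type.  The acceptance script runs the
rank-recovery study at 10 replicate seeds with 30 consensus runs per k
over k = 2..9, and survival calibrations at 200 (null) and 100 (HR
recovery) replicates; these sizes give stable rates while keeping a full
run in the minutes range on one core.

## Known limitations

- The KL-NMF implementation is plain (no sparse input path, no
  acceleration); it is sized for desk-scale matrices, not whole-genome
  single-cell atlases.
- Rank selection inherits the limits of argmax-based consensus: it sees
  only dominant-pattern changes, and its `min_stability` floor is a
  heuristic guard against structureless input.
- Deconvolution assumes the reference classes span the bulk mixture;
  missing cell types bias fractions toward the nearest available class.
- Cutpoint-derived p-values are selection-biased and are flagged, not
  corrected; no multivariable Cox models or competing risks.
- The generator's noise models are Gaussian/Bernoulli stand-ins chosen to
  keep recovery tests well-posed; they do not emulate count overdispersion,
  batch structure, or array normalisation artifacts, so recovery results
  bound correctness of the algorithms, not performance on real cohorts.
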