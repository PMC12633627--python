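# Methods

## Model

Spot-resolution spatial transcriptomics measures, at each of `p` capture
locations, the pooled expression of roughly 10–200 cells.  Given an annotated
scRNA-seq reference from matching tissue, deconvolution estimates the
fraction of each of `c` cell types at every spot.  We model the `n × p`
log1p-scale expression matrix as a nonnegative matrix factorization

    X = B V + E,

where `B` (`n × c`) holds the per-type mean expression of the reference and
`V` (`c × p`) the unknown proportions.  Three priors complete the model:

* **Noise.**  `E ~ MN(0, σ² I_n, L_pd⁻¹)`: matrix-normal noise whose column
  precision is a graph Laplacian built from spot coordinates (and optionally
  histology intensity), so residuals at neighboring spots covary — the
  Gaussian Markov random field expression of the observation that nearby
  spots share cellular composition.
* **Sparsity / nonnegativity.**  `V_ij ~ Exp(η)` i.i.d.  The exponential
  prior is the nonnegative half of a Laplace prior: it enforces `V ≥ 0` and
  pulls small proportions toward zero, sharpening region boundaries.
* **Conjugate hyperpriors.**  `σ² ~ InvGamma(a₁, b₁)` and `η ~ Gamma(a₂, b₂)`
  (shape–scale), with `a₁ = b₁ = a₂ = 1/b₂ = 10⁻⁴` so the data dominate.

All three conditionals are closed-form, giving an exact Gibbs sampler:

* `V | X, σ², η` is a truncated matrix normal on the nonnegative orthant
  with mean `M = (BᵀB)⁻¹(BᵀX − σ²η·J·L_pd⁻¹)` (`J` all-ones), row covariance
  `σ²(BᵀB)⁻¹` and column covariance `L_pd⁻¹`;
* `σ² | X, V ~ InvGamma(a₁ + np/2 + cp/2, b₁ + tr(L_pd EᵀE)/2)`;
* `η | V ~ Gamma(a₂ + cp, 1/(ΣᵢⱼV_ij + 1/b₂))`.

The `cp/2` term in the σ² shape is kept as the model states it even though
the exponential prior on `V` contributes no σ²-dependent exponent; a
`sigma2_shape="likelihood_only"` switch drops it (`a₁ + np/2`).  The
`log_joint_density` function implements the exact joint and is used only as
a validation oracle: the test suite checks the 1-D conditional of `V`
against it on a grid (sup-norm ≤ 10⁻⁶) and verifies that its gradient
vanishes at `M` (the joint is quadratic in `V`, so central differences are
exact to roundoff).

## Spatial graph

Edge weights are a Gaussian kernel,
`A_ij = exp(−(‖s_i−s_j‖² + μ(I_i−I_j)²)/σ_A²)`, zero diagonal.  `σ_A²`
defaults to 0.1 for array-style coordinates (magnitude ≤ ~10²) and 10⁴ for
pixel-style coordinates (10³–10⁴); `μ = 1` weights the intensity term of a
min-max-normalized histology image and is inactive without one.  Intensities
are extracted as the mean over a 5 × 5 pixel window (clipped at borders)
around each affine-mapped spot after resizing the image so its longer side
is 1024 px (aspect preserved — the aspect-ratio handling was an open choice).

`L = D − A` is singular (constant null vector), but the model inverts the
column covariance, so we always use `L_pd = L + εI`.  **The ridge ε is a
modeling parameter, not numerical fuzz.**  Because `L1 = 0`,
`L_pd⁻¹1 = (1/ε)1` exactly, so the sparsity correction in `M` scales as
`σ²η/ε` and the prior variance of the graph's smooth modes scales as
`σ²/ε`.  With σ² driven by `tr(L_pd EᵀE) ≈ σ_noise²·n·tr(L)`, a ridge of
`10⁻³·mean(D)` makes that shift ~2 on the proportion scale — every
conditional mean is pushed far below zero and the sampler lives in the deep
truncation tail.  We therefore default to `ε = 0.1·mean(D_ii)`, which keeps
the smooth-mode prior variance commensurate with the edge-level precision
while preserving the Laplacian's neighborhood structure; the proportionality
to the mean degree makes the model invariant to rescaling `A`.  The ridge is
exposed as `--ridge` for sensitivity analysis.

## Sampling the truncated matrix normal

Column-major vectorization gives `vec(V)` precision `Ω = L_pd ⊗ (BᵀB/σ²)`.
The exact sampler is coordinate-wise Gibbs: entry `(i, j)` has conditional
precision `P_ii·L_jj` (with `P = BᵀB/σ²`) and conditional mean
`M_ij − (S_ij − P_ii L_jj D_ij)/(P_ii L_jj)` where `D = V − M` and
`S = P D L_pd`.  Maintaining the running product `R = D L_pd` makes the mean
an O(c) dot product and its update an O(p) vector addition, so a full sweep
costs O(cp(c + p)) and the `cp × cp` precision is never formed.  Each outer
Gibbs iteration runs one sweep continuing from the previous `V`; the outer
chain supplies the mixing (configurable via `sweeps`).  The scan order is a
fixed row-major pass for reproducibility (`scan="random"` available).

Univariate truncated-normal draws use the inverse CDF through the survival
function in log space (`ndtri_exp(log1p(−u) + log_ndtr(−α))`), which stays
accurate when the truncation point is tens of standard deviations above the
mean — the regime where accept–reject samplers stall.

Above `c·p = 10⁴` dimensions the orthant probability is so small that
chain-based truncated sampling degrades, so the default switches to a
rectified matrix normal: draw `M + R Z Cᵀ` untruncated and clamp negatives
to zero.  Tests confirm the two samplers agree elementwise to < 0.01 when
the sub-zero mass is below 1%.  The threshold and the sampler are both
overridable.

## Chain orchestration

Each iteration draws σ², then η (both given the previous `V`), then `V`.
`V⁰` is the nonnegatively clipped least-squares fit, column-normalized —
close to the posterior bulk, so a burn-in of 5 iterations suffices (the
reference-based model has a single unknown matrix and mixes in a few
steps).  Defaults keep 2000 draws (`T = 2005`, `T_b = 5`).

Proportions are reported on the simplex.  The stored copy of each draw is
column-normalized; the chain itself propagates the raw draw so the σ²/η
conditionals remain consistent with the unnormalized model.  A literal
in-chain normalization (`normalize_in_chain=True`) is provided because the
algorithm statement can be read either way; the out-of-chain default is the
one whose conditionals match the written model.  An all-zero column (possible
under rectification) is stored as uniform `1/c` with a warning.

Summaries: per-entry posterior mean and sample SD (ddof = 1), the `c × c`
Pearson correlation matrix of mean-proportion maps across spots (constant
maps get zero off-diagonal), and per-spot binned histograms of the sampled
proportions.

## Preprocessing

Fixed order: (1) drop genes unexpressed in either dataset or private to
one, re-ordering both to a common gene order; (2) build `B` as within-type
means; (3) drop the `⌈0.10·n⌉` genes with the largest mean variance-to-mean
ratio across types (VMR computed on raw counts by default — it precedes the
log transform in the pipeline order — with a flag to compute it on log1p
values; a zero-mean gene has VMR 0 by convention and is never removed; ties
break by removing lexicographically smaller gene ids first, making the mask
deterministic); (4) keep only genes whose top per-type log1p-mean exceeds
the mean of the remaining types by ≥ ln(1.25) (the log base is not pinned
by convention, so log2 is available via `logfold_base="2"`; "all remaining
cell types" includes zero-expression types); (5) log1p-transform `X` and
`B`.  Both filters return keep-masks over genes.

## Synthetic data

The generator emulates a three-region tissue: spots on a regular grid,
regions as vertical thirds (or random Voronoi cells), one dominant type per
region.  Scheme 1 is piecewise constant (0.7 / 0.15 / 0.15); scheme 2
smooths that field with a Gaussian kernel; scheme 3 adds N(0, 0.05²) noise
to the scheme-1 means before the same smoothing; scheme 4 draws each spot
from Dirichlet(3, 1, 1) with the dominant index set by region.  Proportions
are clipped at zero and column-renormalized, in that order.  The smoothing
σ is interpreted in spot-grid units (default 0.5 spots, reflect boundaries);
a σ quoted in pixel units for a 40-wide kernel would be a near-delta, so
both σ and the effective kernel extent are configurable.

Expression is `X = max(BV + N(0, 0.5²), 0)` with a synthetic log-scale
reference: shared baseline Uniform(0.1, 0.5) per gene plus a disjoint
marker block per type elevated by exactly `separation` (default 2.0 on the
log1p scale, ≈ e²-fold — strong but realistic marker enrichment; `BᵀB` is
well conditioned for any positive separation and exactly singular at 0,
which the model surfaces as a collinearity error).

What this does *not* emulate: count-level noise (negative binomial
overdispersion, library-size variation), platform effects between ST and
scRNA-seq, imperfect reference annotation, or histology texture.  Passing
recovery tests therefore demonstrates correctness of the inference under
the stated generative model, not robustness to real-data artifacts.

## Problem sizes and numerical choices

Recovery experiments (tests and `scripts/acceptance.py`) use 3 types,
20 × 20 = 400 spots, 200 genes, separation 2.0, noise SD 0.5, 500 kept
draws after 5 burn-in — sizes at which the exact Gibbs sampler (1200
dimensions) runs in seconds and Monte-Carlo error is well below the
reported differences.  Under these conditions the posterior mean achieves
RMSE ≈ 0.025, SSIM ≈ 0.995, JSD ≈ 0.035 across all four schemes.

Other numerics: `BᵀB` is factorized once per run (Cholesky; failure raises
a collinearity error naming the fix); `L_pd` is factorized once and reused;
`tr(L_pd EᵀE)` is computed without forming the `p × p` Gram matrix; metric
SSIM uses the single-window formula with stabilizers `(0.01)²`, `(0.03)²`
for data range 1 (constant inputs are well defined); JSD uses base-2 logs
by default so distances live in [0, 1], with `0·log 0 := 0` and a 10⁻⁶
simplex tolerance on inputs.

## Limitations

* The ridge ε trades spatial-prior strength against sparsity-shift
  magnitude; it is degree-scaled by default but remains a knob users should
  vary on real data.
* The rectified sampler is biased near zero (mass piles at exactly 0);
  above 10⁴ dimensions that bias is accepted for speed.
* The σ² scale is interpretable as noise variance only relative to `L_pd`
  (exactly iid-noise variance when `L_pd = I`).
* Reference-free operation (unknown `B`) and tensor extensions are out of
  scope.
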