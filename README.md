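# basin

Reference-based cell-type deconvolution for spot-resolution spatial
transcriptomics, with full posterior uncertainty.

Spot-level platforms (e.g. 10x Visium) measure pooled expression of tens to
hundreds of cells per capture location.  Given an annotated scRNA-seq
reference from matching tissue, `basin` estimates the fraction of each cell
type at every spot — and, unlike point-estimate deconvolution methods, it
returns the full posterior distribution of those fractions, so every
proportion comes with a standard deviation and per-spot histograms that flag
ambiguous locations.

## Model

With `X` the `n × p` log1p expression matrix and `B` the `n × c` cell-type
mean-profile matrix built from the reference, the proportions `V` (`c × p`)
follow a Bayesian nonnegative matrix factorization

    X = B V + E,
    E ~ MN(0, σ² Iₙ, L_pd⁻¹),       V_ij ~ Exp(η),
    σ² ~ InvGamma(a₁, b₁),          η ~ Gamma(a₂, b₂),

where `L_pd = D − A + εI` is a ridge-regularized graph Laplacian over the
spots: edge weights `A_ij = exp(−(‖s_i−s_j‖² + μ(I_i−I_j)²)/σ_A²)` combine
spatial distance with (optional) histology-image intensity, so neighboring
spots covary.  The exponential prior enforces nonnegativity and sparsity of
the proportions.  All conditionals are closed-form; a Gibbs sampler draws

* `σ² | X, V ~ InvGamma(a₁ + np/2 + cp/2, b₁ + tr(L_pd EᵀE)/2)`,
* `η | V ~ Gamma(a₂ + cp, 1/(Σ V_ij + 1/b₂))`,
* `V | X, σ², η ~ TMN(M, σ²(BᵀB)⁻¹, L_pd⁻¹)` on `V ≥ 0`, with
  `M = (BᵀB)⁻¹(BᵀX − σ²η·J·L_pd⁻¹)`,

the last via an O(c + p)-per-coordinate truncated Gibbs sweep on the
Kronecker precision `L_pd ⊗ (BᵀB/σ²)`, or a rectified matrix-normal
approximation when `c·p > 10⁴`.  See `docs/methods.md` for the full account.

## Worked example

```python
import numpy as np
import basin

# synthetic three-region tissue: 10×10 spots, 120 genes, known truth
st, geometry, profiles, truth = basin.simulate_dataset(
    scheme=1, grid_shape=(10, 10), n_genes=120, separation=2.0, seed=42
)
graph = basin.build_graph(geometry)
draws = basin.run_basin(st, profiles, graph, basin.RunConfig(T=505, T_b=5, seed=0))
summary = basin.summarize(draws)

scores = basin.evaluate_deconvolution(truth.V_true, summary.mean_props)
print({k: round(v, 3) for k, v in scores.items()})
print("mean proportions at spot 0:", np.round(summary.mean_props[:, 0], 3))
print("posterior SDs at spot 0:   ", np.round(summary.sd_props[:, 0], 3))
```

prints

```
{'rmse': 0.033, 'ssim': 0.992, 'jsd': 0.046}
mean proportions at spot 0: [0.675 0.123 0.202]
posterior SDs at spot 0:    [0.05  0.047 0.045]
```

Spot 0 lies in the region dominated by the first cell type (true composition
0.7 / 0.15 / 0.15): the posterior mean recovers it to within a few percent,
and the posterior SDs (~0.05) quantify how much the 500 kept draws spread —
the uncertainty a point estimate would hide.  The three scores compare the
whole estimated proportion map with the ground truth: root-mean-square error
per entry, average per-type structural similarity, and average per-spot
Jensen–Shannon distance.

The same pipeline runs from the shell:

```sh
basin simulate --scheme 1 --seed 42 --out sim/
basin deconvolve --st-counts sim/counts.csv --st-coords sim/coords.csv \
      --reference sim/reference_profiles.csv --out run/
basin evaluate --truth sim/true_proportions.csv --est run/mean_proportions.csv
```

For real data, start from `basin preprocess`, which harmonizes genes between
the ST counts and the scRNA-seq reference, builds `B`, applies the
variance-to-mean-ratio and log-fold enrichment gene filters, and writes the
log1p-scale inputs that `basin deconvolve` expects.

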