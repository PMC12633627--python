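"""Synthetic data with known ground truth for validating the deconvolution.

Spots live on a regular 2-D grid partitioned into three contiguous tissue
regions, each dominated by one of three cell types.  Four proportion schemes
mimic increasingly realistic spatial structure:

1. piecewise constant — the dominant type takes 0.7, the others 0.15 each;
2. scheme 1 smoothed with a Gaussian kernel (soft region boundaries);
3. Gaussian noise (SD 0.05) around the scheme-1 means, then smoothed;
4. per-spot Dirichlet draws with concentration 3 for the region's dominant
   type and 1 for the rest (weak spatial structure).

Proportions are clipped at zero and column-renormalized to the simplex.
Expression is generated from the NMF model ``X = BV`` plus Gaussian noise
(SD 0.5), clipped at zero; the synthetic reference gives each type a disjoint
block of marker genes elevated by a fixed log-scale separation.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .io_preprocess import ExpressionMatrix, ReferenceProfiles, SpotGeometry

__all__ = [
    "RegionLayout",
    "SimulationTruth",
    "make_region_layout",
    "simulate_proportions",
    "simulate_expression",
    "simulate_reference",
    "simulate_dataset",
    "write_dataset_csv",
]

DOMINANT_PROPORTION = 0.7
PROPORTION_NOISE_SD = 0.05
EXPRESSION_NOISE_SD = 0.5
SMOOTH_SIGMA = 0.5           # in spot-grid units
DIRICHLET_MAIN = 3.0
DIRICHLET_OTHER = 1.0


@dataclass
class RegionLayout:
    """Grid spots with a contiguous region label per spot."""

    labels: np.ndarray       # length-p integers in [0, n_regions)
    coords: np.ndarray       # p × 2 grid coordinates (x, y)
    grid_shape: tuple[int, int]

    @property
    def n_spots(self) -> int:
        return self.labels.size

    @property
    def n_regions(self) -> int:
        return int(self.labels.max()) + 1

    def geometry(self) -> SpotGeometry:
        return SpotGeometry(coords=self.coords)


@dataclass
class SimulationTruth:
    """Ground-truth proportions for one simulated dataset."""

    V_true: np.ndarray       # c × p, columns on the simplex
    region_labels: np.ndarray
    scheme: int
    seed: int | None = None

    def __post_init__(self) -> None:
        if np.any(self.V_true < 0):
            raise ValueError("ground-truth proportions must be nonnegative")
        if not np.allclose(self.V_true.sum(axis=0), 1.0, atol=1e-9):
            raise ValueError("ground-truth columns must sum to one")


def make_region_layout(
    grid_shape: tuple[int, int] = (20, 20),
    n_regions: int = 3,
    style: str = "thirds",
    seed: int | None = None,
) -> RegionLayout:
    """Partition a regular grid of spots into contiguous regions.

    ``style="thirds"`` cuts vertical bands of near-equal width;
    ``style="voronoi"`` assigns each spot to the nearest of ``n_regions``
    random seed points, giving irregular contiguous regions.
    """
    rows, cols = grid_shape
    if rows < 1 or cols < 1:
        raise ValueError("grid_shape must be positive")
    p = rows * cols
    if n_regions > p:
        raise ValueError("more regions than spots")
    yy, xx = np.mgrid[0:rows, 0:cols]
    coords = np.column_stack([xx.ravel(), yy.ravel()]).astype(float)
    if style == "thirds":
        labels = (xx.ravel() * n_regions // cols).astype(int)
        labels = np.minimum(labels, n_regions - 1)
    elif style == "voronoi":
        rng = np.random.default_rng(seed)
        centers = rng.uniform([0, 0], [cols - 1, rows - 1], size=(n_regions, 2))
        d = ((coords[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
        labels = d.argmin(axis=1)
        # re-index so every region id occurs
        _, labels = np.unique(labels, return_inverse=True)
        if labels.max() + 1 < n_regions:
            raise ValueError("degenerate Voronoi layout; try another seed")
    else:
        raise ValueError(f"unknown layout style {style!r}")
    return RegionLayout(labels=labels, coords=coords, grid_shape=(rows, cols))


def _piecewise_constant(layout: RegionLayout, c: int) -> np.ndarray:
    """Scheme-1 field: dominant type 0.7 in its region, 0.15 elsewhere."""
    other = (1.0 - DOMINANT_PROPORTION) / (c - 1)
    V = np.full((c, layout.n_spots), other)
    V[layout.labels, np.arange(layout.n_spots)] = DOMINANT_PROPORTION
    return V


def _smooth_on_grid(V: np.ndarray, layout: RegionLayout, sigma: float) -> np.ndarray:
    """Per-type Gaussian smoothing on the 2-D grid (reflect boundaries)."""
    rows, cols = layout.grid_shape
    out = np.empty_like(V)
    for i in range(V.shape[0]):
        field = V[i].reshape(rows, cols)
        out[i] = gaussian_filter(field, sigma=sigma, mode="reflect").ravel()
    return out


def _clip_renormalize(V: np.ndarray) -> np.ndarray:
    V = np.maximum(V, 0.0)
    sums = V.sum(axis=0)
    sums[sums <= 0] = 1.0
    return V / sums


def simulate_proportions(
    layout: RegionLayout,
    scheme: int,
    seed: int | None = None,
    smooth_sigma: float = SMOOTH_SIGMA,
) -> SimulationTruth:
    """Ground-truth proportions under one of the four schemes.

    The number of cell types equals the number of regions (the canonical
    setting is three); type ``k`` dominates region ``k``.
    """
    c = layout.n_regions
    if c < 2:
        raise ValueError("need at least two regions/cell types")
    rng = np.random.default_rng(seed)
    if scheme == 1:
        V = _piecewise_constant(layout, c)
    elif scheme == 2:
        V = _smooth_on_grid(_piecewise_constant(layout, c), layout, smooth_sigma)
    elif scheme == 3:
        V = _piecewise_constant(layout, c)
        V = V + rng.normal(0.0, PROPORTION_NOISE_SD, size=V.shape)
        V = _smooth_on_grid(V, layout, smooth_sigma)
    elif scheme == 4:
        alpha = np.full((layout.n_spots, c), DIRICHLET_OTHER)
        alpha[np.arange(layout.n_spots), layout.labels] = DIRICHLET_MAIN
        gammas = rng.gamma(alpha)
        V = (gammas / gammas.sum(axis=1, keepdims=True)).T
    else:
        raise ValueError(f"unknown simulation scheme {scheme!r}")
    return SimulationTruth(
        V_true=_clip_renormalize(V),
        region_labels=layout.labels,
        scheme=scheme,
        seed=seed,
    )


def simulate_reference(
    n_genes: int = 200,
    c: int = 3,
    separation: float = 2.0,
    seed: int | None = None,
) -> ReferenceProfiles:
    """Synthetic log-scale reference profiles with disjoint marker blocks.

    Every gene gets a shared baseline level; each cell type additionally
    elevates its own contiguous block of ~``n_genes/c`` marker genes by
    exactly ``separation``, so ``BᵀB`` is well conditioned for
    ``separation > 0`` and exactly singular at 0.
    """
    if separation < 0:
        raise ValueError("separation must be nonnegative")
    rng = np.random.default_rng(seed)
    base = rng.uniform(0.1, 0.5, size=n_genes)
    B = np.tile(base[:, None], (1, c))
    bounds = np.linspace(0, n_genes, c + 1).astype(int)
    for k in range(c):
        B[bounds[k] : bounds[k + 1], k] += separation
    return ReferenceProfiles(
        B=B,
        gene_ids=[f"g{i:04d}" for i in range(n_genes)],
        cell_type_names=[f"type_{k}" for k in range(c)],
        log_scale=True,
    )


def simulate_expression(
    B: ReferenceProfiles | np.ndarray,
    truth: SimulationTruth,
    noise_sd: float = EXPRESSION_NOISE_SD,
    seed: int | None = None,
) -> ExpressionMatrix:
    """Expression from the NMF model: ``X = max(B V_true + N(0, noise_sd²), 0)``.

    The result is on the model's continuous (log-like) scale and is flagged
    as such, ready for deconvolution without further transformation.
    """
    Bv = B.B if isinstance(B, ReferenceProfiles) else np.asarray(B, dtype=float)
    if Bv.shape[1] != truth.V_true.shape[0]:
        raise ValueError("B columns do not match the number of simulated types")
    rng = np.random.default_rng(seed)
    X = Bv @ truth.V_true
    if noise_sd > 0:
        X = X + rng.normal(0.0, noise_sd, size=X.shape)
    X = np.maximum(X, 0.0)
    gene_ids = (
        B.gene_ids
        if isinstance(B, ReferenceProfiles)
        else [f"g{i:04d}" for i in range(Bv.shape[0])]
    )
    return ExpressionMatrix(
        values=X,
        gene_ids=list(gene_ids),
        spot_ids=[f"spot_{j}" for j in range(truth.V_true.shape[1])],
        log_scale=True,
    )


def simulate_dataset(
    scheme: int = 1,
    grid_shape: tuple[int, int] = (20, 20),
    n_genes: int = 200,
    n_regions: int = 3,
    separation: float = 2.0,
    noise_sd: float = EXPRESSION_NOISE_SD,
    style: str = "thirds",
    seed: int | None = 0,
) -> tuple[ExpressionMatrix, SpotGeometry, ReferenceProfiles, SimulationTruth]:
    """One fully synthetic dataset: expression, geometry, reference and truth.

    All randomness derives from ``seed`` through independent child streams.
    """
    ss = np.random.SeedSequence(seed)
    s_layout, s_props, s_ref, s_expr = [
        int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(4)
    ]
    layout = make_region_layout(grid_shape, n_regions=n_regions, style=style, seed=s_layout)
    truth = simulate_proportions(layout, scheme=scheme, seed=s_props)
    profiles = simulate_reference(n_genes=n_genes, c=n_regions, separation=separation, seed=s_ref)
    st = simulate_expression(profiles, truth, noise_sd=noise_sd, seed=s_expr)
    return st, layout.geometry(), profiles, truth


def write_dataset_csv(
    outdir: str | Path,
    st: ExpressionMatrix,
    geometry: SpotGeometry,
    profiles: ReferenceProfiles,
    truth: SimulationTruth,
) -> None:
    """Write counts, coords, B and V_true as CSV files."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(st.values, index=st.gene_ids, columns=st.spot_ids).to_csv(
        outdir / "counts.csv"
    )
    pd.DataFrame(
        geometry.coords, index=st.spot_ids, columns=["x", "y"]
    ).to_csv(outdir / "coords.csv")
    pd.DataFrame(
        profiles.B, index=profiles.gene_ids, columns=profiles.cell_type_names
    ).to_csv(outdir / "reference_profiles.csv")
    pd.DataFrame(
        truth.V_true.T, index=st.spot_ids, columns=profiles.cell_type_names
    ).to_csv(outdir / "true_proportions.csv")
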