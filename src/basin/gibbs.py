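"""Gibbs-sampler orchestration: iterate the three conditionals and summarize.

One iteration draws σ² | V, then η | V, then V | σ², η (the truncated
matrix-normal step).  The chain propagates the raw (unnormalized) V so the
σ²/η conditionals stay consistent with the model; each stored draw is a copy
whose columns are normalized to the simplex, which is what a proportion is.
Post-burn-in draws yield posterior means, per-entry standard deviations and
the cross-type spatial correlation matrix.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import linalg

from .io_preprocess import ExpressionMatrix, ReferenceProfiles
from .posterior import ModelHyperparams, sample_eta, sample_sigma2
from .spatial_graph import SpatialGraph
from .tmn_sampling import (
    SAMPLER_DIMENSION_THRESHOLD,
    TMNSpec,
    choose_sampler,
    sample_rectified_mn,
    sample_tmn_gibbs,
)

__all__ = [
    "RunConfig",
    "PosteriorDraws",
    "DeconvolutionSummary",
    "run_basin",
    "summarize",
    "spot_histogram",
    "save_results",
]

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Chain settings.

    ``T`` is the total number of iterations and ``T_b`` the burn-in, so
    ``T − T_b`` draws are kept (defaults keep 2000; a handful of burn-in
    iterations suffices because the reference-based model has a single
    unknown matrix and mixes fast).
    """

    T: int = 2005
    T_b: int = 5
    seed: int = 0
    sampler: str | None = None  # None = choose by dimension
    sweeps: int = 1
    scan: str = "row-major"
    normalize_in_chain: bool = False
    sigma2_shape: str = "standard"
    sampler_threshold: int = SAMPLER_DIMENSION_THRESHOLD
    hyper: ModelHyperparams = field(default_factory=ModelHyperparams)

    def __post_init__(self) -> None:
        if not 0 <= self.T_b < self.T:
            raise ValueError("need 0 <= T_b < T")
        if self.sampler not in (None, "tmn-gibbs", "rectified"):
            raise ValueError(f"unknown sampler {self.sampler!r}")

    @property
    def n_kept(self) -> int:
        return self.T - self.T_b


@dataclass
class PosteriorDraws:
    """Kept draws: stacked column-normalized V matrices plus σ² and η traces."""

    V_draws: np.ndarray        # (T − T_b) × c × p, columns on the simplex
    sigma2_draws: np.ndarray
    eta_draws: np.ndarray
    cell_type_names: list[str] | None = None
    spot_ids: list[str] | None = None

    @property
    def n_draws(self) -> int:
        return self.V_draws.shape[0]


@dataclass
class DeconvolutionSummary:
    """Posterior mean/SD proportions and the cross-type correlation matrix."""

    mean_props: np.ndarray         # c × p, columns sum to 1
    sd_props: np.ndarray           # c × p
    type_correlations: np.ndarray  # c × c Pearson matrix across spots
    cell_type_names: list[str] | None = None
    spot_ids: list[str] | None = None


def _normalize_columns(V: np.ndarray) -> np.ndarray:
    """Project each column onto the simplex by its sum; all-zero → uniform."""
    sums = V.sum(axis=0)
    zero = sums <= 0
    if zero.any():
        logger.warning("%d all-zero columns normalized to uniform", int(zero.sum()))
    out = V / np.where(zero, 1.0, sums)
    out[:, zero] = 1.0 / V.shape[0]
    return out


def _as_array(x, attr: str) -> np.ndarray:
    return getattr(x, attr) if hasattr(x, attr) else np.asarray(x, dtype=float)


def run_basin(
    X: ExpressionMatrix | np.ndarray,
    B: ReferenceProfiles | np.ndarray,
    graph: SpatialGraph,
    cfg: RunConfig | None = None,
    v_init: np.ndarray | None = None,
) -> PosteriorDraws:
    """Run the Gibbs sampler and return the post-burn-in draws.

    ``X`` must be on the log1p scale with genes aligned to ``B``.  By default
    the chain starts at the column-normalized, nonnegatively clipped
    least-squares fit, which sits close to the posterior bulk; pass
    ``v_init`` (c × p, nonnegative) to start elsewhere, e.g. for convergence
    checks across over-dispersed starting points.
    """
    cfg = cfg or RunConfig()
    type_names = B.cell_type_names if isinstance(B, ReferenceProfiles) else None
    spot_ids = X.spot_ids if isinstance(X, ExpressionMatrix) else None
    if isinstance(X, ExpressionMatrix) and not X.log_scale:
        raise ValueError("X must be log1p-transformed before deconvolution")
    Xv = _as_array(X, "values") if not isinstance(X, np.ndarray) else X
    Bv = B.B if isinstance(B, ReferenceProfiles) else np.asarray(B, dtype=float)
    Xv = np.asarray(Xv, dtype=float)
    n, p = Xv.shape
    c = Bv.shape[1]
    if Bv.shape[0] != n:
        raise ValueError("X and B must share the same genes in the same order")
    if graph.n_spots != p:
        raise ValueError("graph size does not match the number of spots")

    rng = np.random.default_rng(cfg.seed)
    btb = Bv.T @ Bv
    try:
        chol_btb = linalg.cholesky(btb, lower=True)
    except linalg.LinAlgError as exc:
        raise linalg.LinAlgError(
            "BᵀB is singular: cell-type profiles are collinear; "
            "consider removing or merging a cell type"
        ) from exc
    BtX = Bv.T @ Xv

    # mean components reused every iteration:
    #   M(σ², η) = M_ls − σ²η · K,  K = (BᵀB)⁻¹ J L_pd⁻¹ (identical rows)
    M_ls = linalg.cho_solve((chol_btb, True), BtX)
    u = graph.solve_L_pd(np.ones(p))
    row_weights = linalg.cho_solve((chol_btb, True), np.ones((c, 1)))
    K = row_weights @ u[None, :]

    if v_init is None:
        V = _normalize_columns(np.maximum(M_ls, 0.0))
    else:
        V = np.asarray(v_init, dtype=float).copy()
        if V.shape != (c, p) or np.any(V < 0):
            raise ValueError("v_init must be a nonnegative c × p matrix")
    sampler = cfg.sampler or choose_sampler(c, p, cfg.sampler_threshold)
    logger.info("running chain: c=%d, p=%d, sampler=%s, T=%d", c, p, sampler, cfg.T)

    kept_V = np.empty((cfg.n_kept, c, p))
    sigma2_draws = np.empty(cfg.n_kept)
    eta_draws = np.empty(cfg.n_kept)
    k = 0
    for t in range(1, cfg.T + 1):
        try:
            sigma2 = sample_sigma2(
                Xv, Bv, V, graph, cfg.hyper, rng, shape_mode=cfg.sigma2_shape
            )
            eta = sample_eta(V, cfg.hyper, rng)
            M = M_ls - sigma2 * eta * K
            spec = TMNSpec(M=M, row_prec=btb / sigma2, col_prec=graph.L_pd)
            if sampler == "tmn-gibbs":
                V = sample_tmn_gibbs(spec, V, sweeps=cfg.sweeps, rng=rng, scan=cfg.scan)
                clamped = 0.0
            else:
                V = sample_rectified_mn(spec, rng)
                clamped = float(np.mean(V == 0.0))
        except Exception:
            logger.error("conditional draw failed at iteration %d", t)
            raise
        V_stored = _normalize_columns(V)
        if cfg.normalize_in_chain:
            V = V_stored
        logger.debug(
            "iter %d: sigma2=%.4g eta=%.4g clamped=%.3f", t, sigma2, eta, clamped
        )
        if t > cfg.T_b:
            kept_V[k] = V_stored
            sigma2_draws[k] = sigma2
            eta_draws[k] = eta
            k += 1
    return PosteriorDraws(
        V_draws=kept_V,
        sigma2_draws=sigma2_draws,
        eta_draws=eta_draws,
        cell_type_names=type_names,
        spot_ids=spot_ids,
    )


def summarize(draws: PosteriorDraws) -> DeconvolutionSummary:
    """Posterior mean and SD per entry, plus cross-type Pearson correlations.

    The correlation matrix compares the mean-proportion maps of each pair of
    cell types across spots; spatially co-localized types correlate
    positively.  Types with a constant map get correlation 0 off-diagonal.
    """
    if draws.n_draws < 2:
        raise ValueError("need at least two kept draws to summarize")
    mean_props = draws.V_draws.mean(axis=0)
    sd_props = draws.V_draws.std(axis=0, ddof=1)
    centered = mean_props - mean_props.mean(axis=1, keepdims=True)
    norms = np.sqrt((centered**2).sum(axis=1))
    safe = np.where(norms > 0, norms, 1.0)
    corr = (centered @ centered.T) / np.outer(safe, safe)
    corr[norms == 0, :] = 0.0
    corr[:, norms == 0] = 0.0
    np.fill_diagonal(corr, 1.0)
    return DeconvolutionSummary(
        mean_props=mean_props,
        sd_props=sd_props,
        type_correlations=corr,
        cell_type_names=draws.cell_type_names,
        spot_ids=draws.spot_ids,
    )


def spot_histogram(
    draws: PosteriorDraws,
    spot: int | str,
    bins: int = 30,
) -> pd.DataFrame:
    """Binned per-type proportion samples at one spot, ready for plotting.

    Returns a long-format table with columns (cell_type, bin_left, bin_right,
    count); counts per type sum to the number of kept draws.
    """
    if isinstance(spot, str):
        if draws.spot_ids is None or spot not in draws.spot_ids:
            raise KeyError(f"unknown spot id {spot!r}")
        j = draws.spot_ids.index(spot)
    else:
        j = int(spot)
        if not 0 <= j < draws.V_draws.shape[2]:
            raise KeyError(f"spot index {j} out of range")
    c = draws.V_draws.shape[1]
    names = draws.cell_type_names or [f"type_{i}" for i in range(c)]
    rows = []
    for i in range(c):
        samples = draws.V_draws[:, i, j]
        counts, edges = np.histogram(samples, bins=bins, range=(0.0, 1.0))
        for k in range(bins):
            rows.append((names[i], edges[k], edges[k + 1], int(counts[k])))
    return pd.DataFrame(rows, columns=["cell_type", "bin_left", "bin_right", "count"])


def save_results(
    outdir: str | Path,
    draws: PosteriorDraws,
    summary: DeconvolutionSummary | None = None,
) -> None:
    """Write mean/SD proportion CSVs, the correlation CSV, a long-format
    table and the raw draws (HDF5)."""
    import h5py

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if summary is None:
        summary = summarize(draws)
    c, p = summary.mean_props.shape
    names = summary.cell_type_names or [f"type_{i}" for i in range(c)]
    spots = summary.spot_ids or [f"spot_{j}" for j in range(p)]
    mean_df = pd.DataFrame(summary.mean_props.T, index=spots, columns=names)
    mean_df.to_csv(outdir / "mean_proportions.csv")
    pd.DataFrame(summary.sd_props.T, index=spots, columns=names).to_csv(
        outdir / "sd_proportions.csv"
    )
    pd.DataFrame(summary.type_correlations, index=names, columns=names).to_csv(
        outdir / "type_correlations.csv"
    )
    long_df = mean_df.reset_index(names="spot_id").melt(
        id_vars="spot_id", var_name="cell_type", value_name="proportion"
    )
    long_df.to_csv(outdir / "proportions_long.csv", index=False)
    with h5py.File(outdir / "draws.h5", "w") as f:
        f.create_dataset("V_draws", data=draws.V_draws, compression="gzip")
        f.create_dataset("sigma2_draws", data=draws.sigma2_draws)
        f.create_dataset("eta_draws", data=draws.eta_draws)
        f.attrs["cell_type_names"] = [str(x) for x in names]
        f.attrs["spot_ids"] = [str(x) for x in spots]
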