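"""Closed-form conditional posteriors of the matrix-variate Bayesian NMF model.

Model:  X = BV + E with

* ``E ~ MN(0, σ²I_n, L_pd⁻¹)`` — matrix normal noise whose column precision
  is the (ridge-regularized) graph Laplacian, so residuals at neighboring
  spots covary;
* ``V_ij ~ Exp(η)`` i.i.d. — an exponential prior that induces both sparsity
  and nonnegativity of the proportions;
* conjugate hyperpriors ``σ² ~ InvGamma(a₁, b₁)`` and ``η ~ Gamma(a₂, b₂)``
  (shape–scale parameterization throughout).

The conditional of ``V`` is a truncated matrix normal on the nonnegative
orthant with mean ``M = (BᵀB)⁻¹(BᵀX − σ²η·J·L_pd⁻¹)``, row covariance
``σ²(BᵀB)⁻¹`` and column covariance ``L_pd⁻¹`` (``J`` the all-ones c × p
matrix).  σ² and η have inverse-gamma and gamma conditionals.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import linalg

from .spatial_graph import SpatialGraph

__all__ = [
    "ModelHyperparams",
    "VConditional",
    "GibbsState",
    "v_conditional",
    "sample_sigma2",
    "sample_eta",
    "log_joint_density",
]


@dataclass
class ModelHyperparams:
    """Shape/scale hyperparameters; defaults are weakly informative.

    a1, b1 are the inverse-gamma shape and scale for σ²; a2, b2 the gamma
    shape and scale for η.  Defaults set a1 = b1 = a2 = 1/b2 = 10⁻⁴ so the
    data dominate the conditionals.
    """

    a1: float = 1e-4
    b1: float = 1e-4
    a2: float = 1e-4
    b2: float = 1e4

    def __post_init__(self) -> None:
        if min(self.a1, self.b1, self.a2, self.b2) <= 0:
            raise ValueError("hyperparameters must be positive")


@dataclass
class VConditional:
    """Parameters of the truncated matrix-normal conditional of V (V ≥ 0)."""

    M: np.ndarray          # c × p mean
    row_prec: np.ndarray   # BᵀB / σ²  (c × c)
    col_prec: np.ndarray   # L_pd      (p × p)
    row_cov_factor: np.ndarray = field(repr=False, default=None)  # R, RRᵀ = σ²(BᵀB)⁻¹
    col_prec_factor: np.ndarray = field(repr=False, default=None)  # lower chol of L_pd

    @property
    def shape(self) -> tuple[int, int]:
        return self.M.shape


@dataclass
class GibbsState:
    """Current chain state (V, σ², η)."""

    V: np.ndarray
    sigma2: float
    eta: float
    iter: int = 0

    def __post_init__(self) -> None:
        if np.any(self.V < 0):
            raise ValueError("V must be elementwise nonnegative")
        if self.sigma2 <= 0 or self.eta <= 0:
            raise ValueError("sigma2 and eta must be positive")


def _btb_cholesky(B: np.ndarray) -> np.ndarray:
    btb = B.T @ B
    try:
        return linalg.cholesky(btb, lower=True)
    except linalg.LinAlgError as exc:
        raise linalg.LinAlgError(
            "BᵀB is singular: cell-type profiles are collinear; "
            "consider removing or merging a cell type"
        ) from exc


def v_conditional(
    X: np.ndarray,
    B: np.ndarray,
    graph: SpatialGraph,
    sigma2: float,
    eta: float,
) -> VConditional:
    """Truncated matrix-normal conditional of V given (X, σ², η).

    Mean ``M = (BᵀB)⁻¹(BᵀX − σ²η·J·L_pd⁻¹)``; because ``J·L_pd⁻¹`` has
    identical rows ``(L_pd⁻¹1)ᵀ``, the sparsity correction is a rank-one
    shift of the least-squares fit.
    """
    X = np.asarray(X, dtype=float)
    B = np.asarray(B, dtype=float)
    c = B.shape[1]
    chol_btb = _btb_cholesky(B)
    u = graph.solve_L_pd(np.ones(graph.n_spots))  # L_pd⁻¹ 1
    rhs = B.T @ X - sigma2 * eta * np.tile(u, (c, 1))
    M = linalg.cho_solve((chol_btb, True), rhs)
    btb = chol_btb @ chol_btb.T
    # RRᵀ = σ²(BᵀB)⁻¹ with R = √σ² · chol(BᵀB)⁻ᵀ
    row_cov_factor = np.sqrt(sigma2) * linalg.solve_triangular(
        chol_btb, np.eye(c), lower=True, trans="T"
    )
    return VConditional(
        M=M,
        row_prec=btb / sigma2,
        col_prec=graph.L_pd,
        row_cov_factor=row_cov_factor,
        col_prec_factor=graph.chol_L_pd,
    )


def _tr_L_EtE(E: np.ndarray, graph: SpatialGraph) -> float:
    """tr(L_pd EᵀE) without forming the p × p Gram matrix."""
    return float(np.sum((E @ graph.L_pd) * E))


def sample_sigma2(
    X: np.ndarray,
    B: np.ndarray,
    V: np.ndarray,
    graph: SpatialGraph,
    hyper: ModelHyperparams,
    rng: np.random.Generator,
    shape_mode: str = "standard",
) -> float:
    """Draw σ² from its inverse-gamma conditional.

    Shape ``a₁ + np/2 + cp/2`` and scale ``b₁ + tr(L_pd EᵀE)/2`` with
    ``E = X − BV``.  ``shape_mode="likelihood_only"`` drops the ``cp/2``
    term, leaving exactly the exponent the matrix-normal likelihood
    contributes.
    """
    n, p = X.shape
    c = V.shape[0]
    E = X - B @ V
    shape = hyper.a1 + n * p / 2
    if shape_mode == "standard":
        shape += c * p / 2
    elif shape_mode != "likelihood_only":
        raise ValueError(f"unknown shape_mode {shape_mode!r}")
    scale = hyper.b1 + 0.5 * _tr_L_EtE(E, graph)
    assert scale > 0, "inverse-gamma scale must be positive"
    # InvGamma(shape, scale): 1 / Gamma(shape, rate=scale)
    return float(scale / rng.gamma(shape))


def sample_eta(
    V: np.ndarray,
    hyper: ModelHyperparams,
    rng: np.random.Generator,
) -> float:
    """Draw η from its gamma conditional.

    Shape ``a₂ + cp`` and scale ``1 / (ΣᵢⱼVᵢⱼ + 1/b₂)`` — the exponential
    prior on the cp entries of V is conjugate for its rate.
    """
    c, p = V.shape
    shape = hyper.a2 + c * p
    scale = 1.0 / (float(V.sum()) + 1.0 / hyper.b2)
    return float(rng.gamma(shape, scale))


def log_joint_density(
    X: np.ndarray,
    B: np.ndarray,
    V: np.ndarray,
    sigma2: float,
    eta: float,
    graph: SpatialGraph,
    hyper: ModelHyperparams,
) -> float:
    """Un-normalized log joint density of (X, V, σ², η); validation oracle.

    Returns −inf for V outside the nonnegative orthant.  Constant terms not
    involving any variable are dropped.
    """
    V = np.asarray(V, dtype=float)
    if np.any(V < 0):
        return -np.inf
    n, p = X.shape
    c = V.shape[0]
    E = X - B @ V
    log_lik = (
        -0.5 * n * p * np.log(sigma2)
        + 0.5 * n * graph.logdet_L_pd()
        - _tr_L_EtE(E, graph) / (2.0 * sigma2)
    )
    log_prior_v = c * p * np.log(eta) - eta * float(V.sum())
    log_prior_sigma2 = -(hyper.a1 + 1.0) * np.log(sigma2) - hyper.b1 / sigma2
    log_prior_eta = (hyper.a2 - 1.0) * np.log(eta) - eta / hyper.b2
    return float(log_lik + log_prior_v + log_prior_sigma2 + log_prior_eta)
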