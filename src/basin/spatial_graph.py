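"""Spatial neighborhood graph: Gaussian-kernel weights, Laplacian, histology term.

Spots that are physically close (and, when a histology image is supplied,
similar in stain intensity) receive large edge weights.  The graph Laplacian
``L = D − A`` is used downstream as a column precision, so neighboring spots
covary.  ``L`` itself is singular (the constant vector is in its null space);
the model always works with the ridge-regularized ``L_pd = L + εI`` so the
matrix-normal column covariance ``L_pd⁻¹`` is proper.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import linalg
from scipy.spatial.distance import pdist, squareform

from .io_preprocess import SpotGeometry

__all__ = [
    "GraphConfig",
    "SpatialGraph",
    "default_sigma_A2",
    "build_weight_matrix",
    "build_laplacian",
    "build_graph",
    "extract_spot_intensity",
    "identity_graph",
]


@dataclass
class GraphConfig:
    """Kernel and regularization settings for the spot graph.

    sigma_A2
        Gaussian-kernel bandwidth σ_A²; ``None`` selects it from the
        coordinate magnitude (0.1 for coordinates up to ~10², 10⁴ for
        coordinates of magnitude 10³–10⁴).
    mu
        Weight μ of the squared histology-intensity difference; ignored when
        the geometry carries no intensities.
    ridge_eps
        Ridge ε added to the Laplacian diagonal; ``None`` uses
        0.1 · mean(D_ii).  The ridge bounds the prior variance of the
        graph's smooth modes, which otherwise diverges as ε → 0 and lets
        the sparsity prior's mean shift σ²η·J·L_pd⁻¹ blow up.
    knn
        Optional k-nearest-neighbor sparsification cutoff (dense by default).
    """

    sigma_A2: float | None = None
    mu: float = 1.0
    ridge_eps: float | None = None
    knn: int | None = None

    def __post_init__(self) -> None:
        if self.sigma_A2 is not None and self.sigma_A2 <= 0:
            raise ValueError("sigma_A2 must be positive")
        if self.mu < 0:
            raise ValueError("mu must be nonnegative")
        if self.ridge_eps is not None and self.ridge_eps < 0:
            raise ValueError("ridge_eps must be nonnegative")


@dataclass
class SpatialGraph:
    """Weight matrix ``A``, degrees, Laplacian and its positive-definite form."""

    A: np.ndarray
    degrees: np.ndarray
    L: np.ndarray
    L_pd: np.ndarray
    ridge_eps: float
    chol_L_pd: np.ndarray  # lower Cholesky factor of L_pd

    @property
    def n_spots(self) -> int:
        return self.A.shape[0]

    @property
    def D(self) -> np.ndarray:
        return np.diag(self.degrees)

    def solve_L_pd(self, rhs: np.ndarray) -> np.ndarray:
        """Solve ``L_pd x = rhs`` via the cached Cholesky factor."""
        return linalg.cho_solve((self.chol_L_pd, True), rhs)

    def logdet_L_pd(self) -> float:
        return 2.0 * float(np.sum(np.log(np.diag(self.chol_L_pd))))


def default_sigma_A2(coords: np.ndarray) -> float:
    """Bandwidth chosen by coordinate magnitude.

    Array-style coordinates (magnitude up to ~10²) get σ_A² = 0.1; large
    pixel-style coordinates (magnitude 10³–10⁴) get σ_A² = 10⁴.
    """
    magnitude = float(np.max(np.abs(coords))) if coords.size else 1.0
    return 1e4 if magnitude >= 1e3 else 0.1


def build_weight_matrix(geometry: SpotGeometry, cfg: GraphConfig | None = None) -> np.ndarray:
    """Gaussian-kernel weights with an optional histology-intensity term.

    ``A_ij = exp(−(‖s_i − s_j‖² + μ (I_i − I_j)²) / σ_A²)`` for ``i ≠ j``
    and 0 on the diagonal.  With ``cfg.knn`` set, entries outside each spot's
    k nearest neighbors are zeroed and the result re-symmetrized by max.
    """
    cfg = cfg or GraphConfig()
    coords = geometry.coords
    sigma_A2 = cfg.sigma_A2 if cfg.sigma_A2 is not None else default_sigma_A2(coords)
    if sigma_A2 <= 0:
        raise ValueError("sigma_A2 must be positive")
    sq_dist = squareform(pdist(coords, metric="sqeuclidean"))
    if geometry.intensity is not None and cfg.mu > 0:
        di = geometry.intensity[:, None] - geometry.intensity[None, :]
        sq_dist = sq_dist + cfg.mu * di**2
    A = np.exp(-sq_dist / sigma_A2)
    np.fill_diagonal(A, 0.0)
    if cfg.knn is not None:
        p = A.shape[0]
        k = min(cfg.knn, p - 1)
        keep = np.zeros_like(A, dtype=bool)
        nearest = np.argsort(-A, axis=1)[:, :k]
        rows = np.repeat(np.arange(p), k)
        keep[rows, nearest.ravel()] = True
        A = np.where(keep | keep.T, A, 0.0)
    return A


def build_laplacian(A: np.ndarray, ridge_eps: float | None = None) -> SpatialGraph:
    """Form ``L = D − A`` and the invertible ``L_pd = L + εI``.

    A Cholesky factor of ``L_pd`` is cached; its failure signals that the
    ridge is too small for the given graph.
    """
    A = np.asarray(A, dtype=float)
    if A.shape[0] != A.shape[1]:
        raise ValueError("weight matrix must be square")
    if not np.allclose(A, A.T):
        raise ValueError("weight matrix must be symmetric")
    if np.any(np.diag(A) != 0):
        raise ValueError("weight matrix must have a zero diagonal")
    degrees = A.sum(axis=1)
    L = np.diag(degrees) - A
    if ridge_eps is None:
        ridge_eps = 0.1 * float(degrees.mean())
        if ridge_eps <= 0:
            # disconnected geometry: fall back to a unit-scale ridge so the
            # column covariance stays proper
            warnings.warn("graph has no edges; using ridge_eps = 1e-6", stacklevel=2)
            ridge_eps = 1e-6
    L_pd = L + ridge_eps * np.eye(A.shape[0])
    try:
        chol = linalg.cholesky(L_pd, lower=True)
    except linalg.LinAlgError as exc:  # pragma: no cover - float PSD + eps > 0
        raise linalg.LinAlgError(
            f"L + εI is not positive definite (ε = {ridge_eps:g}); increase the ridge"
        ) from exc
    return SpatialGraph(
        A=A, degrees=degrees, L=L, L_pd=L_pd, ridge_eps=float(ridge_eps), chol_L_pd=chol
    )


def build_graph(geometry: SpotGeometry, cfg: GraphConfig | None = None) -> SpatialGraph:
    """Convenience wrapper: weights then Laplacian from one geometry."""
    cfg = cfg or GraphConfig()
    return build_laplacian(build_weight_matrix(geometry, cfg), ridge_eps=cfg.ridge_eps)


def identity_graph(p: int) -> SpatialGraph:
    """Spatially uninformative graph with ``L_pd = I`` (no edges, unit ridge).

    Useful for ablations: the error model reduces to i.i.d. Gaussian noise.
    """
    return build_laplacian(np.zeros((p, p)), ridge_eps=1.0)


def extract_spot_intensity(
    image: np.ndarray,
    coords: np.ndarray,
    affine: np.ndarray | None = None,
    resize_to: int = 1024,
    window: int = 5,
) -> np.ndarray:
    """Mean histology intensity in a small square around each mapped spot.

    The grayscale image (RGB input is converted by luminance) is resized so
    its longer side equals ``resize_to`` (aspect preserved), min-max
    normalized to [0, 1], and each spot's intensity is the mean over the
    ``window × window`` pixel square centered on its affine-mapped
    coordinate, clipped at the image borders.
    """
    from skimage.transform import resize

    image = np.asarray(image, dtype=float)
    if image.ndim == 3:
        # ITU-R 601 luminance
        image = image[..., :3] @ np.array([0.299, 0.587, 0.114])
    if image.ndim != 2:
        raise ValueError("image must be a 2-D grayscale raster")
    scale = resize_to / max(image.shape)
    out_shape = (
        max(1, round(image.shape[0] * scale)),
        max(1, round(image.shape[1] * scale)),
    )
    if out_shape != image.shape:
        image = resize(image, out_shape, anti_aliasing=scale < 1, preserve_range=True)
    lo, hi = float(image.min()), float(image.max())
    image = np.zeros_like(image) if hi == lo else (image - lo) / (hi - lo)

    coords = np.asarray(coords, dtype=float)
    if affine is None:
        affine = np.array([[scale, 0.0, 0.0], [0.0, scale, 0.0]])
    affine = np.asarray(affine, dtype=float).reshape(2, 3)
    # mapped (col, row) pixel positions of each spot
    xy = coords @ affine[:, :2].T + affine[:, 2]
    h, w = image.shape
    half = window // 2
    out = np.empty(coords.shape[0])
    for i, (cx, cy) in enumerate(xy):
        col, row = int(round(cx)), int(round(cy))
        if not (0 <= col < w and 0 <= row < h):
            raise ValueError(f"spot {i} maps outside the image at pixel ({col}, {row})")
        r0, r1 = max(0, row - half), min(h, row + half + 1)
        c0, c1 = max(0, col - half), min(w, col + half + 1)
        out[i] = image[r0:r1, c0:c1].mean()
    return out
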