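"""Evaluation metrics for proportion maps: RMSE, global SSIM, JSD, reference r.

RMSE is the Frobenius error per entry.  SSIM is computed globally over one
cell type's per-spot proportion vector (no sliding window) and averaged
across types.  JSD is the Jensen–Shannon distance between one spot's true
and estimated proportion vectors (base-2 logs by default, bounding it in
[0, 1]) and averaged across spots.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import jensenshannon
from scipy.stats import pearsonr

from .io_preprocess import SingleCellReference

__all__ = [
    "MetricsParams",
    "rmse",
    "ssim",
    "average_ssim",
    "jsd",
    "average_jsd",
    "reference_correlation",
    "evaluate_deconvolution",
]


@dataclass
class MetricsParams:
    """SSIM stabilizers and the JSD log base.

    The stabilizers follow the standard convention c1 = (0.01·R)²,
    c2 = (0.03·R)² with data range R = 1 for proportions.
    """

    c1: float = 0.01**2
    c2: float = 0.03**2
    jsd_log_base: float = 2.0

    def __post_init__(self) -> None:
        if self.c1 <= 0 or self.c2 <= 0:
            raise ValueError("stabilizers must be positive")


def rmse(a: np.ndarray, b: np.ndarray) -> float:
    """Frobenius error per entry: ``‖a − b‖_F / √(#entries)``."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("inputs must have the same shape")
    return float(np.linalg.norm(a - b) / np.sqrt(a.size))


def ssim(a: np.ndarray, b: np.ndarray, params: MetricsParams | None = None) -> float:
    """Global structural similarity of two equally shaped maps.

    Uses the single-window SSIM formula over all entries; the stabilizers
    keep constant inputs well defined (two identical constants give 1).
    """
    params = params or MetricsParams()
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.shape != b.shape:
        raise ValueError("inputs must have the same shape")
    mu_a, mu_b = a.mean(), b.mean()
    var_a, var_b = a.var(), b.var()
    cov = ((a - mu_a) * (b - mu_b)).mean()
    return float(
        (2 * mu_a * mu_b + params.c1)
        * (2 * cov + params.c2)
        / ((mu_a**2 + mu_b**2 + params.c1) * (var_a + var_b + params.c2))
    )


def average_ssim(
    V_true: np.ndarray, V_est: np.ndarray, params: MetricsParams | None = None
) -> float:
    """Mean over cell types of the global SSIM of each type's spot map."""
    V_true = np.atleast_2d(np.asarray(V_true, dtype=float))
    V_est = np.atleast_2d(np.asarray(V_est, dtype=float))
    if V_true.shape != V_est.shape:
        raise ValueError("inputs must have the same shape")
    return float(np.mean([ssim(t, e, params) for t, e in zip(V_true, V_est)]))


def jsd(a: np.ndarray, b: np.ndarray, params: MetricsParams | None = None) -> float:
    """Jensen–Shannon distance between two simplex vectors.

    The square root of ``½KL(a‖m) + ½KL(b‖m)`` with ``m = (a+b)/2``; zeros
    contribute nothing (0·log 0 := 0).  With base-2 logs the distance lies
    in [0, 1], reaching 1 for disjoint supports.
    """
    params = params or MetricsParams()
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    for v in (a, b):
        if np.any(v < -1e-12) or abs(v.sum() - 1.0) > 1e-6:
            raise ValueError("inputs must be probability vectors summing to 1")
    return float(jensenshannon(a, b, base=params.jsd_log_base))


def average_jsd(
    V_true: np.ndarray, V_est: np.ndarray, params: MetricsParams | None = None
) -> float:
    """Mean over spots of the per-spot Jensen–Shannon distance."""
    V_true = np.asarray(V_true, dtype=float)
    V_est = np.asarray(V_est, dtype=float)
    if V_true.shape != V_est.shape:
        raise ValueError("inputs must have the same shape")
    return float(
        np.mean([jsd(V_true[:, j], V_est[:, j], params) for j in range(V_true.shape[1])])
    )


def reference_correlation(
    mean_props: np.ndarray,
    sc: SingleCellReference | np.ndarray,
    cell_type_names: list[str] | None = None,
) -> float:
    """Pearson r between estimated overall type proportions and reference
    type frequencies.

    The estimate's length-c vector is the mean proportion of each type over
    all spots; the reference vector is each type's cell frequency in the
    scRNA-seq metadata (aligned by ``cell_type_names`` when given).
    """
    mean_props = np.asarray(mean_props, dtype=float)
    overall = mean_props.mean(axis=1)
    if isinstance(sc, SingleCellReference):
        labels = np.asarray(sc.cell_type_labels)
        order = cell_type_names or sc.cell_types
        freqs = np.array([(labels == t).mean() for t in order])
    else:
        freqs = np.asarray(sc, dtype=float)
    if overall.shape != freqs.shape:
        raise ValueError("cell types of the estimate and reference do not align")
    if overall.size < 3:
        warnings.warn("correlation over fewer than 3 cell types is uninformative",
                      stacklevel=2)
    return float(pearsonr(overall, freqs).statistic)


def evaluate_deconvolution(
    V_true: np.ndarray,
    V_est: np.ndarray,
    params: MetricsParams | None = None,
) -> dict[str, float]:
    """The three-metric summary table used throughout the evaluations."""
    return {
        "rmse": rmse(V_true, V_est),
        "ssim": average_ssim(V_true, V_est, params),
        "jsd": average_jsd(V_true, V_est, params),
    }
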