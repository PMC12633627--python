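"""Readers and gene-filtering pipeline for ST counts and the scRNA-seq reference.

The deconvolution model works on a genes × spots expression matrix ``X`` and a
genes × cell-types reference profile matrix ``B`` that share one gene order.
This module reads the raw tables, harmonizes the gene sets, builds ``B`` by
averaging the reference cells within each annotated type, applies two quality
filters (variance-to-mean ratio, log-fold enrichment) and the final ``log1p``
transform that maps integer counts to the continuous scale the model assumes.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "SingleCellReference",
    "ReferenceProfiles",
    "SpotGeometry",
    "read_st",
    "read_sc",
    "harmonize_genes",
    "build_reference_profiles",
    "filter_vmr",
    "filter_logfold",
    "log1p_transform",
    "preprocess",
]


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class ExpressionMatrix:
    """Genes × spots expression table.

    ``log_scale`` records whether values are raw counts or already
    ``log1p``-transformed; the model requires the latter.
    """

    values: np.ndarray
    gene_ids: list[str]
    spot_ids: list[str]
    log_scale: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.spot_ids = [str(s) for s in self.spot_ids]
        n, p = self.values.shape
        if n < 1 or p < 1:
            raise ValueError("expression matrix must have at least one gene and one spot")
        if len(self.gene_ids) != n or len(self.spot_ids) != p:
            raise ValueError("identifier lists do not match matrix shape")
        if len(set(self.gene_ids)) != n:
            raise ValueError("gene_ids must be unique")
        if len(set(self.spot_ids)) != p:
            raise ValueError("spot_ids must be unique")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("expression values must be finite")
        if np.any(self.values < 0):
            raise ValueError("expression values must be nonnegative")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_spots(self) -> int:
        return self.values.shape[1]


@dataclass
class SingleCellReference:
    """Genes × cells reference counts with one cell-type label per cell."""

    values: np.ndarray
    gene_ids: list[str]
    cell_ids: list[str]
    cell_type_labels: list[str]
    log_scale: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.cell_ids = [str(c) for c in self.cell_ids]
        self.cell_type_labels = [str(t) for t in self.cell_type_labels]
        n, m = self.values.shape
        if len(self.gene_ids) != n:
            raise ValueError("gene_ids do not match matrix shape")
        if len(self.cell_ids) != m or len(self.cell_type_labels) != m:
            raise ValueError("every cell needs exactly one id and one type label")
        if np.any(self.values < 0) or not np.all(np.isfinite(self.values)):
            raise ValueError("reference values must be finite and nonnegative")

    @property
    def cell_types(self) -> list[str]:
        """Distinct labels in first-appearance order."""
        return list(dict.fromkeys(self.cell_type_labels))


@dataclass
class ReferenceProfiles:
    """Genes × cell-types mean-expression matrix ``B``."""

    B: np.ndarray
    gene_ids: list[str]
    cell_type_names: list[str]
    log_scale: bool = False

    def __post_init__(self) -> None:
        self.B = np.asarray(self.B, dtype=float)
        if self.B.shape != (len(self.gene_ids), len(self.cell_type_names)):
            raise ValueError("B shape does not match identifier lists")
        if np.any(self.B < 0):
            raise ValueError("reference profiles must be nonnegative")

    @property
    def n_types(self) -> int:
        return self.B.shape[1]


@dataclass
class SpotGeometry:
    """Per-spot 2-D coordinates plus optional histology intensity in [0, 1].

    Rows are ordered identically to the companion :class:`ExpressionMatrix`.
    """

    coords: np.ndarray
    intensity: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 2:
            raise ValueError("coords must be a p × 2 array")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coordinates must be finite")
        if self.intensity is not None:
            self.intensity = np.asarray(self.intensity, dtype=float)
            if self.intensity.shape != (self.coords.shape[0],):
                raise ValueError("intensity must have one value per spot")

    @property
    def n_spots(self) -> int:
        return self.coords.shape[0]


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------


def _read_table(path: str | Path) -> pd.DataFrame:
    """Read a dense CSV/TSV table with a header row and an index column."""
    path = Path(path)
    sep = "\t" if path.name.endswith((".tsv", ".tsv.gz", ".txt", ".txt.gz")) else ","
    return pd.read_csv(path, sep=sep, index_col=0)


def read_st(
    path_counts: str | Path,
    path_coords: str | Path,
    transpose: bool = False,
) -> tuple[ExpressionMatrix, SpotGeometry]:
    """Read a spot-level count table and matching spot coordinates.

    The count table is genes × spots by default; pass ``transpose=True`` for
    spots × genes. The coordinate table needs one row per spot with two
    columns (x, y); spots are re-ordered to the count table's column order.
    """
    counts = _read_table(path_counts)
    if transpose:
        counts = counts.T
    coords = _read_table(path_coords)
    if coords.shape[1] < 2:
        raise ValueError("coordinate table must have two columns (x, y)")
    spot_ids = [str(s) for s in counts.columns]
    coords.index = coords.index.astype(str)
    missing = [s for s in spot_ids if s not in coords.index]
    if missing:
        raise ValueError(f"spots missing coordinates: {missing[:5]}")
    coords = coords.loc[spot_ids]
    st = ExpressionMatrix(
        values=counts.to_numpy(dtype=float),
        gene_ids=list(counts.index),
        spot_ids=spot_ids,
    )
    geometry = SpotGeometry(coords=coords.iloc[:, :2].to_numpy(dtype=float))
    return st, geometry


def read_sc(
    path_counts: str | Path,
    path_meta: str | Path,
    transpose: bool = False,
) -> SingleCellReference:
    """Read reference counts (genes × cells) plus a (cell_id, cell_type) table."""
    counts = _read_table(path_counts)
    if transpose:
        counts = counts.T
    meta = _read_table(path_meta)
    meta.index = meta.index.astype(str)
    cell_ids = [str(c) for c in counts.columns]
    missing = [c for c in cell_ids if c not in meta.index]
    if missing:
        raise ValueError(f"cells missing metadata: {missing[:5]}")
    labels = meta.loc[cell_ids].iloc[:, 0].astype(str).tolist()
    return SingleCellReference(
        values=counts.to_numpy(dtype=float),
        gene_ids=list(counts.index),
        cell_ids=cell_ids,
        cell_type_labels=labels,
    )


# ---------------------------------------------------------------------------
# Gene harmonization and reference construction
# ---------------------------------------------------------------------------


def harmonize_genes(
    st: ExpressionMatrix, sc: SingleCellReference
) -> tuple[ExpressionMatrix, SingleCellReference]:
    """Restrict both datasets to shared genes expressed in each.

    Genes all-zero in either dataset and genes present in only one dataset
    are dropped; both outputs are re-ordered to one common gene order (the
    ST order restricted to the intersection). Idempotent.
    """
    st_expressed = {
        g for g, keep in zip(st.gene_ids, st.values.sum(axis=1) > 0) if keep
    }
    sc_expressed = {
        g for g, keep in zip(sc.gene_ids, sc.values.sum(axis=1) > 0) if keep
    }
    common = [g for g in st.gene_ids if g in st_expressed and g in sc_expressed]
    if not common:
        raise ValueError("no shared expressed genes between ST and reference data")
    st_idx = {g: i for i, g in enumerate(st.gene_ids)}
    sc_idx = {g: i for i, g in enumerate(sc.gene_ids)}
    st_out = replace(
        st,
        values=st.values[[st_idx[g] for g in common]],
        gene_ids=list(common),
    )
    sc_out = replace(
        sc,
        values=sc.values[[sc_idx[g] for g in common]],
        gene_ids=list(common),
    )
    return st_out, sc_out


def build_reference_profiles(sc: SingleCellReference) -> ReferenceProfiles:
    """Average expression over the cells of each annotated type.

    ``B[g, k]`` is the mean expression of gene ``g`` in the cells labelled
    with type ``k``; column order follows first appearance of each label.
    """
    types = sc.cell_types
    if len(types) < 2:
        raise ValueError("reference must contain at least two cell types")
    labels = np.asarray(sc.cell_type_labels)
    cols = []
    for t in types:
        members = labels == t
        if not members.any():  # pragma: no cover - guarded by construction
            raise ValueError(f"cell type {t!r} has no cells")
        cols.append(sc.values[:, members].mean(axis=1))
    return ReferenceProfiles(
        B=np.column_stack(cols),
        gene_ids=list(sc.gene_ids),
        cell_type_names=types,
        log_scale=sc.log_scale,
    )


# ---------------------------------------------------------------------------
# Gene filters
# ---------------------------------------------------------------------------


def filter_vmr(sc: SingleCellReference, top_fraction: float = 0.10) -> np.ndarray:
    """Keep-mask dropping the genes with the largest mean variance-to-mean ratio.

    For each gene and cell type the VMR is the within-type variance divided by
    the within-type mean (defined as 0 when the mean is 0, so absent genes are
    never penalized); the per-gene score is the mean VMR across types. The
    ``ceil(top_fraction · n)`` highest-scoring genes are removed, ties broken
    by removing lexicographically smaller gene ids first.

    Returns a boolean array where ``True`` marks a retained gene.
    """
    if not 0 <= top_fraction < 1:
        raise ValueError("top_fraction must be in [0, 1)")
    labels = np.asarray(sc.cell_type_labels)
    n = len(sc.gene_ids)
    vmrs = []
    for t in sc.cell_types:
        block = sc.values[:, labels == t]
        mean = block.mean(axis=1)
        var = block.var(axis=1)  # population variance; ratio convention only
        with np.errstate(divide="ignore", invalid="ignore"):
            vmr = np.where(mean > 0, var / np.where(mean > 0, mean, 1.0), 0.0)
        vmrs.append(vmr)
    mean_vmr = np.mean(vmrs, axis=0)
    n_remove = math.ceil(top_fraction * n)
    keep = np.ones(n, dtype=bool)
    if n_remove == 0:
        return keep
    # sort by descending VMR, then ascending gene id, and remove the head
    order = np.lexsort((np.asarray(sc.gene_ids), -mean_vmr))
    keep[order[:n_remove]] = False
    return keep


def filter_logfold(
    profiles: ReferenceProfiles,
    threshold: float = 1.25,
    log_base: str = "e",
) -> np.ndarray:
    """Keep-mask for genes enriched in a single cell type.

    Operating on log-scale mean profiles, a gene is kept when its highest
    per-type value exceeds the mean of the remaining types by at least
    ``log(threshold)`` (natural log by default, ``log_base="2"`` for log2).

    Returns a boolean array where ``True`` marks a retained gene.
    """
    if not profiles.log_scale:
        raise ValueError("log-fold filter expects log-scale profiles")
    if profiles.n_types < 2:
        raise ValueError("log-fold filter needs at least two cell types")
    if threshold <= 0:
        cut = -math.inf
    else:
        cut = math.log2(threshold) if log_base == "2" else math.log(threshold)
    B = profiles.B
    top = np.argmax(B, axis=1)
    rows = np.arange(B.shape[0])
    best = B[rows, top]
    rest_mean = (B.sum(axis=1) - best) / (B.shape[1] - 1)
    return best - rest_mean >= cut


# ---------------------------------------------------------------------------
# Transform and full pipeline
# ---------------------------------------------------------------------------


def log1p_transform(x: ExpressionMatrix) -> ExpressionMatrix:
    """Map counts through ``x ↦ ln(1 + x)`` and flip the scale flag."""
    if x.log_scale:
        raise ValueError("matrix is already log1p-transformed")
    return replace(x, values=np.log1p(x.values), log_scale=True)


@dataclass
class PreprocessResult:
    st: ExpressionMatrix
    profiles: ReferenceProfiles
    sc: SingleCellReference
    n_genes_retained: int = field(init=False)

    def __post_init__(self) -> None:
        self.n_genes_retained = self.st.n_genes


def preprocess(
    st: ExpressionMatrix,
    sc: SingleCellReference,
    vmr_top_fraction: float = 0.10,
    logfold_threshold: float = 1.25,
    logfold_base: str = "e",
    vmr_on_log: bool = False,
) -> PreprocessResult:
    """Run the full gene pipeline in its fixed order.

    Steps: intersect/re-order genes, build the type-mean profiles, drop
    high-VMR genes, drop genes without single-type log-fold enrichment,
    then ``log1p``-transform both ``X`` and ``B``. The returned ST matrix and
    profiles share an identical gene order.
    """
    st, sc = harmonize_genes(st, sc)
    sc_for_vmr = sc
    if vmr_on_log:
        sc_for_vmr = replace(sc, values=np.log1p(sc.values), log_scale=True)
    keep_vmr = filter_vmr(sc_for_vmr, top_fraction=vmr_top_fraction)
    st = _subset_genes_st(st, keep_vmr)
    sc = _subset_genes_sc(sc, keep_vmr)
    profiles = build_reference_profiles(sc)
    log_profiles = replace(profiles, B=np.log1p(profiles.B), log_scale=True)
    keep_fold = filter_logfold(
        log_profiles, threshold=logfold_threshold, log_base=logfold_base
    )
    if not keep_fold.any():
        raise ValueError("log-fold filter removed every gene; lower the threshold")
    st = _subset_genes_st(st, keep_fold)
    sc = _subset_genes_sc(sc, keep_fold)
    final_profiles = replace(
        log_profiles,
        B=log_profiles.B[keep_fold],
        gene_ids=[g for g, k in zip(log_profiles.gene_ids, keep_fold) if k],
    )
    st = log1p_transform(st)
    return PreprocessResult(st=st, profiles=final_profiles, sc=sc)


def _subset_genes_st(st: ExpressionMatrix, keep: np.ndarray) -> ExpressionMatrix:
    return replace(
        st,
        values=st.values[keep],
        gene_ids=[g for g, k in zip(st.gene_ids, keep) if k],
    )


def _subset_genes_sc(sc: SingleCellReference, keep: np.ndarray) -> SingleCellReference:
    return replace(
        sc,
        values=sc.values[keep],
        gene_ids=[g for g, k in zip(sc.gene_ids, keep) if k],
    )


def write_profiles_csv(profiles: ReferenceProfiles, path: str | Path) -> None:
    """Write ``B`` as a CSV with gene rows and a cell-type header."""
    pd.DataFrame(
        profiles.B, index=profiles.gene_ids, columns=profiles.cell_type_names
    ).to_csv(path)
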