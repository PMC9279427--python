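"""QC filtering, normalization, clustering delegates and label reconciliation.

The QC rule follows droplet-scRNA-seq convention for this cohort: a cell is
retained iff it has **more than** ``min_genes_exclusive`` detected genes and
**less than** ``max_mito_frac_exclusive`` mitochondrial count fraction —
both strict inequalities, so boundary cells fail.

Clustering is a pluggable delegate: the default mirrors the standard
single-cell stack (scaled HVG -> PCA -> shared-nearest-neighbor graph ->
Leiden), a KMeans delegate is provided for small well-separated problems.
Flow-sort labels and clusters are reconciled by cluster purity: clusters
dominated by leukemic-sorted cells are treated as leukemia clusters,
nonleukemic-sorted cells inside them are relabeled leukemic, and
leukemic-sorted cells stranded in immune clusters are omitted from all
downstream statistics.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .containers import (
    LEUKEMIC_SORT,
    MRD_NEG,
    MRD_POS,
    CountMatrix,
    NormMatrix,
    validate_annotation,
)

__all__ = [
    "QCConfig",
    "QCReport",
    "RelabelConfig",
    "qc_filter",
    "log_normalize",
    "select_hvg",
    "cluster_cells",
    "relabel_malignancy",
    "assign_cell_types",
    "group_composition",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class QCConfig:
    """Cell-retention rule: > min_genes detected genes AND < max mito fraction."""

    min_genes_exclusive: int = 200
    max_mito_frac_exclusive: float = 0.30

    def __post_init__(self) -> None:
        if self.min_genes_exclusive < 0:
            raise ValueError("min_genes_exclusive must be >= 0")
        if not 0.0 < self.max_mito_frac_exclusive <= 1.0:
            raise ValueError("max_mito_frac_exclusive must be in (0, 1]")


@dataclass
class QCReport:
    """Per-run QC accounting; n_input = n_retained + cells failing >= 1 rule."""

    n_input_cells: int
    n_retained: int
    n_failed_genes: int
    n_failed_mito: int
    detected_genes: np.ndarray
    mito_fraction: np.ndarray
    retained_mask: np.ndarray

    def to_frame(self, barcodes) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "barcode": barcodes,
                "detected_genes": self.detected_genes,
                "mito_fraction": self.mito_fraction,
                "retained": self.retained_mask,
            }
        )


def qc_filter(counts: CountMatrix, config: QCConfig = QCConfig()) -> tuple[CountMatrix, QCReport]:
    """Retain cells with detected genes > threshold and mito fraction < threshold.

    Zero-count cells fail the gene rule before the mito division is ever
    taken, so no 0/0 arises.  An empty result is legal.
    """
    detected = counts.detected_genes()
    mito_frac = counts.mito_fraction()
    pass_genes = detected > config.min_genes_exclusive
    pass_mito = mito_frac < config.max_mito_frac_exclusive
    keep = pass_genes & pass_mito
    report = QCReport(
        n_input_cells=counts.shape[0],
        n_retained=int(keep.sum()),
        n_failed_genes=int((~pass_genes).sum()),
        n_failed_mito=int((~pass_mito).sum()),
        detected_genes=detected,
        mito_fraction=mito_frac,
        retained_mask=keep,
    )
    return counts.subset_cells(keep), report


def log_normalize(counts: CountMatrix, scale_factor: float = 1e4) -> NormMatrix:
    """Library-size log-normalization: ln(1 + scale * count / cell_total).

    Zero counts map to exactly 0, so the sparsity pattern is preserved and
    scaling all counts of a cell by a constant leaves values unchanged.
    """
    totals = counts.cell_totals().astype(float)
    if np.any(totals == 0):
        n_zero = int((totals == 0).sum())
        raise ValueError(
            f"{n_zero} cells have zero total counts; run qc_filter before log_normalize"
        )
    mat = counts.values.tocsr().astype(np.float64)
    # scale rows in place on the csr data array so the sparsity structure
    # (indptr/indices) of the counts is preserved exactly
    scale_per_cell = scale_factor / totals
    mat.data *= np.repeat(scale_per_cell, np.diff(mat.indptr))
    mat.data = np.log1p(mat.data)
    return NormMatrix(
        barcodes=list(counts.barcodes),
        genes=list(counts.genes),
        values=mat,
        scale_factor=scale_factor,
    )


def select_hvg(norm: NormMatrix, n_top: int) -> list[str]:
    """Top ``n_top`` genes by dispersion (variance / mean of normalized values).

    Constant and all-zero genes have zero dispersion and rank last; ties are
    broken deterministically by gene symbol.
    """
    n_genes = norm.shape[1]
    if n_top > n_genes:
        raise ValueError(f"n_top={n_top} exceeds number of genes ({n_genes})")
    dense = norm.values.tocsc()
    mean = np.asarray(dense.mean(axis=0)).ravel()
    mean_sq = np.asarray(dense.multiply(dense).mean(axis=0)).ravel()
    var = mean_sq - mean**2
    with np.errstate(invalid="ignore", divide="ignore"):
        dispersion = np.where(mean > 0, var / np.where(mean > 0, mean, 1.0), 0.0)
    dispersion = np.maximum(dispersion, 0.0)
    order = sorted(range(n_genes), key=lambda i: (-dispersion[i], norm.genes[i]))
    return [norm.genes[i] for i in order[:n_top]]


def _cluster_leiden(norm: NormMatrix, n_dims: int, resolution: float, seed: int) -> np.ndarray:
    import scanpy as sc
    from anndata import AnnData

    adata = AnnData(X=norm.values.copy())
    adata.obs_names = norm.barcodes
    adata.var_names = norm.genes
    sc.pp.scale(adata, max_value=10)
    n_comps = int(min(n_dims, adata.n_obs - 1, adata.n_vars - 1))
    sc.tl.pca(adata, n_comps=n_comps, svd_solver="arpack", random_state=seed)
    sc.pp.neighbors(adata, n_pcs=n_comps, random_state=seed)
    sc.tl.leiden(adata, resolution=resolution, random_state=seed, flavor="leidenalg")
    return adata.obs["leiden"].astype(int).to_numpy()


def _cluster_kmeans(norm: NormMatrix, n_dims: int, seed: int, n_clusters: int) -> np.ndarray:
    from sklearn.cluster import KMeans
    from sklearn.decomposition import PCA

    dense = norm.to_dense()
    dense = dense - dense.mean(axis=0)
    n_comps = int(min(n_dims, dense.shape[0] - 1, dense.shape[1]))
    pcs = PCA(n_components=n_comps, random_state=seed).fit_transform(dense)
    km = KMeans(n_clusters=n_clusters, n_init=10, random_state=seed)
    return km.fit_predict(pcs)


def cluster_cells(
    norm: NormMatrix,
    method: str = "leiden",
    n_dims: int = 35,
    resolution: float = 1.0,
    seed: int = 0,
    n_clusters: int | None = None,
) -> np.ndarray:
    """Partition cells into clusters via a pluggable delegate.

    ``method="leiden"`` runs the standard scaled-PCA / SNN-graph / Leiden
    stack (scanpy); ``method="kmeans"`` runs PCA + KMeans and requires
    ``n_clusters``.  Returns an integer cluster id per cell; same seed, same
    partition.
    """
    if norm.shape[0] < 1:
        raise ValueError("cannot cluster an empty matrix")
    if norm.shape[0] == 1:
        return np.zeros(1, dtype=int)
    try:
        if method == "leiden":
            return _cluster_leiden(norm, n_dims, resolution, seed)
        if method == "kmeans":
            if n_clusters is None:
                raise ValueError("kmeans delegate requires n_clusters")
            return _cluster_kmeans(norm, n_dims, seed, n_clusters)
    except ValueError:
        raise
    except Exception as exc:  # noqa: BLE001 - delegate failure with context
        raise RuntimeError(f"clustering delegate {method!r} failed: {exc}") from exc
    raise ValueError(f"unknown clustering method {method!r}")


@dataclass(frozen=True)
class RelabelConfig:
    """Cluster-purity rule for reconciling flow-sort labels with clusters."""

    leukemic_cluster_frac_tau: float = 0.90
    min_cluster_size: int = 10

    def __post_init__(self) -> None:
        if not 0.5 < self.leukemic_cluster_frac_tau <= 1.0:
            raise ValueError("leukemic_cluster_frac_tau must be in (0.5, 1]")
        if self.min_cluster_size < 1:
            raise ValueError("min_cluster_size must be >= 1")


def relabel_malignancy(
    annotation: pd.DataFrame, config: RelabelConfig = RelabelConfig()
) -> tuple[pd.DataFrame, dict]:
    """Reconcile flow-sort malignancy with cluster membership.

    Clusters whose leukemic-sorted fraction is >= tau are leukemia clusters:
    nonleukemic-sorted members are relabeled ``leukemic``.  Leukemic-sorted
    cells in the remaining (immune) clusters are set to ``omitted`` and must
    be excluded from every downstream statistic.  Clusters smaller than
    ``min_cluster_size`` are left untouched (logged).  Returns the updated
    annotation and a summary dict.
    """
    validate_annotation(annotation, require=("barcode", "patient_id", "mrd_group", "flow_label", "cluster_id"))
    ann = annotation.copy()
    is_leuk_sort = (ann["flow_label"] == LEUKEMIC_SORT).to_numpy()
    malignancy = np.where(is_leuk_sort, "leukemic", "nonleukemic").astype(object)

    n_relabeled = 0
    n_omitted = 0
    small = []
    for cid, idx in ann.groupby("cluster_id", sort=True).indices.items():
        if len(idx) < config.min_cluster_size:
            small.append(cid)
            continue
        frac_leuk = is_leuk_sort[idx].mean()
        if frac_leuk >= config.leukemic_cluster_frac_tau:
            sel = idx[~is_leuk_sort[idx]]
            malignancy[sel] = "leukemic"
            n_relabeled += len(sel)
        else:
            sel = idx[is_leuk_sort[idx]]
            malignancy[sel] = "omitted"
            n_omitted += len(sel)
    if small:
        logger.warning(
            "relabel_malignancy: %d clusters below min_cluster_size=%d left unmodified: %s",
            len(small), config.min_cluster_size, small,
        )
    ann["malignancy"] = malignancy
    summary = {
        "n_relabeled_to_leukemic": n_relabeled,
        "n_omitted": n_omitted,
        "n_small_clusters_skipped": len(small),
        "tau": config.leukemic_cluster_frac_tau,
    }
    return ann, summary


def assign_cell_types(
    norm: NormMatrix, cluster_id: np.ndarray, marker_map: dict[str, list[str]]
) -> dict:
    """Assign each cluster the type whose markers have highest mean expression.

    Markers absent from the matrix are dropped with a warning; ties break
    deterministically by type-name order.  Returns {cluster_id: type}.
    """
    if not marker_map:
        raise ValueError("marker_map is empty")
    gene_idx = norm.gene_index()
    usable: dict[str, list[int]] = {}
    for t in sorted(marker_map):
        cols = [gene_idx[g] for g in marker_map[t] if g in gene_idx]
        missing = [g for g in marker_map[t] if g not in gene_idx]
        if missing:
            logger.warning("assign_cell_types: markers missing from matrix for %s: %s", t, missing)
        if cols:
            usable[t] = cols
    if not usable:
        raise ValueError("no marker genes present in the matrix")

    cluster_id = np.asarray(cluster_id)
    assignment = {}
    mat = norm.values.tocsr()
    for cid in np.unique(cluster_id):
        rows = np.flatnonzero(cluster_id == cid)
        sub = mat[rows]
        best_type, best_score = None, -np.inf
        for t in sorted(usable):  # sorted => deterministic tie-break
            score = sub[:, usable[t]].mean()
            if score > best_score:
                best_type, best_score = t, score
        assignment[cid] = best_type
    return assignment


def group_composition(annotation: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Cell-type composition of the non-malignant compartment per MRD group.

    Returns ``(group_pct, patient_pct)``: percentage of each cell type among
    non-malignant, non-omitted cells pooled per group, and the same computed
    per patient (the unit a between-group test should use; the test itself
    is left to the caller / panel statistics).
    """
    for col in ("cell_type", "mrd_group", "malignancy"):
        if col not in annotation.columns or annotation[col].isna().all():
            raise ValueError(f"group_composition requires populated column {col!r}")
    scope = annotation[annotation["malignancy"] == "nonleukemic"]
    if scope.empty:
        raise ValueError("no non-malignant cells in scope")

    def pct(frame: pd.DataFrame, by: str) -> pd.DataFrame:
        counts = frame.groupby([by, "cell_type"], observed=True).size().unstack(fill_value=0)
        return counts.div(counts.sum(axis=1), axis=0) * 100.0

    group_pct = pct(scope, "mrd_group").reindex([MRD_POS, MRD_NEG]).dropna(how="all")
    patient_pct = pct(scope, "patient_id")
    patient_pct.insert(
        0, "mrd_group",
        scope.drop_duplicates("patient_id").set_index("patient_id")["mrd_group"].reindex(patient_pct.index),
    )
    return group_pct, patient_pct
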