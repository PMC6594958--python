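"""scRNA-seq QC, germ-cell selection, clustering and cluster annotation.

Implements the quantitative single-cell procedures of the study design:
per-library QC with strict printed-style thresholds (e.g. ">1300 genes",
"<25%" mitochondrial), germ-cell selection on Dazl/Ddx4 abundance,
normalisation and per-gene scaling, dispersion-based variable-gene
selection with expression-bin z-scores, KNN-graph modularity clustering,
an enrichment-based clustering-resolution criterion (the reference
population must be enriched within a single cluster), dotplot marker
statistics (scaled expression across clusters, detection fraction),
rule-based cluster identity scores, cluster-to-cluster overlap, and the
modified RV matrix correlation used to check replicate consistency.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import anndata as ad
import igraph
import leidenalg
import numpy as np
import pandas as pd
import scanpy as sc
import scipy.sparse as sp
from sklearn.decomposition import PCA
from sklearn.neighbors import NearestNeighbors

__all__ = [
    "LibraryFilterSpec",
    "ClusterResult",
    "MarkerStats",
    "ResolutionSelectionError",
    "qc_metrics",
    "qc_filter",
    "select_germ_cells",
    "normalize_log",
    "zscore_genes",
    "variable_genes",
    "cluster_graph",
    "select_resolution",
    "marker_stats",
    "passes_marker_criteria",
    "annotate_clusters",
    "cluster_overlap",
    "modified_rv",
    "pseudobulk",
    "replicate_rv_table",
    "write_counts_mtx",
    "read_counts_mtx",
]


@dataclass
class LibraryFilterSpec:
    """Per-library QC bounds, all strict (a cell exactly at a bound fails).

    ``None`` disables a bound.  ``max_mito_fraction`` defaults to 0.25 for
    every library — a conservative ceiling on mitochondrial content.
    """

    min_genes: int | None = None
    max_genes: int | None = None
    max_umi: int | None = None
    max_mito_fraction: float | None = 0.25

    def __post_init__(self) -> None:
        if (
            self.min_genes is not None
            and self.max_genes is not None
            and not self.min_genes < self.max_genes
        ):
            raise ValueError("min_genes must be below max_genes")

    def passes(self, n_genes: int, total_umi: int, mito_fraction: float) -> bool:
        if self.min_genes is not None and not n_genes > self.min_genes:
            return False
        if self.max_genes is not None and not n_genes < self.max_genes:
            return False
        if self.max_umi is not None and not total_umi < self.max_umi:
            return False
        if self.max_mito_fraction is not None and not mito_fraction < self.max_mito_fraction:
            return False
        return True


def _to_dense(X) -> np.ndarray:
    return np.asarray(X.todense()) if sp.issparse(X) else np.asarray(X)


def qc_metrics(adata: ad.AnnData, mito_prefix: str = "mt-") -> pd.DataFrame:
    """Per-cell detected-gene count, total UMI and mitochondrial fraction."""
    X = adata.X
    if sp.issparse(X):
        n_genes = np.asarray((X > 0).sum(axis=1)).ravel()
        total = np.asarray(X.sum(axis=1)).ravel()
    else:
        n_genes = (X > 0).sum(axis=1)
        total = X.sum(axis=1)
    mito = np.array([g.lower().startswith(mito_prefix) for g in adata.var_names])
    if mito.any():
        mito_sum = np.asarray(X[:, mito].sum(axis=1)).ravel()
    else:
        mito_sum = np.zeros(adata.n_obs)
    with np.errstate(invalid="ignore", divide="ignore"):
        mito_frac = np.where(total > 0, mito_sum / np.maximum(total, 1), 0.0)
    return pd.DataFrame(
        {"n_genes": n_genes.astype(int), "total_umi": total.astype(int),
         "mito_fraction": mito_frac},
        index=adata.obs_names,
    )


def qc_filter(
    adata: ad.AnnData,
    specs: Mapping[str, LibraryFilterSpec],
    library_key: str = "library",
) -> tuple[ad.AnnData, pd.DataFrame]:
    """Apply per-library QC bounds; returns the filtered data and a
    per-library pass/fail count table.

    Every library present in the data must have a spec.  All bounds are
    strict inequalities, matching printed thresholds of the form
    ">1300 genes" or "<25%".
    """
    libs = adata.obs[library_key].astype(str)
    unknown = sorted(set(libs) - set(specs))
    if unknown:
        raise ValueError(f"no QC spec for libraries: {unknown}")
    metrics = qc_metrics(adata)
    keep = np.array([
        specs[lib].passes(m.n_genes, m.total_umi, m.mito_fraction)
        for lib, (_, m) in zip(libs, metrics.iterrows())
    ])
    report = (
        pd.DataFrame({"library": libs.to_numpy(), "passed": keep})
        .groupby("library")["passed"]
        .agg(n_pass="sum", n_total="count")
        .reset_index()
    )
    report["n_fail"] = report["n_total"] - report["n_pass"]
    return adata[keep].copy(), report


def select_germ_cells(
    adata: ad.AnnData,
    marker_genes: Sequence[str] = ("Dazl", "Ddx4"),
    min_count: int = 1,
) -> ad.AnnData:
    """Keep cells whose summed germ-marker counts reach ``min_count``.

    Germ cells are distinguished from contaminating soma by Dazl and Ddx4
    transcript abundance; with the default ``min_count=1`` a single
    detected transcript of either marker suffices.
    """
    missing = [g for g in marker_genes if g not in adata.var_names]
    if missing:
        raise ValueError(f"marker genes absent from data: {missing}")
    sub = adata[:, list(marker_genes)].X
    total = np.asarray(sub.sum(axis=1)).ravel()
    return adata[total >= min_count].copy()


def normalize_log(adata: ad.AnnData, scale_factor: float = 1e4) -> ad.AnnData:
    """Library-size normalisation to ``scale_factor`` counts per cell,
    then log1p.  Raw counts are preserved in ``layers['counts']``."""
    out = adata.copy()
    out.layers["counts"] = out.X.copy()
    sc.pp.normalize_total(out, target_sum=scale_factor)
    out.layers["normalized_linear"] = out.X.copy()
    sc.pp.log1p(out)
    return out


def zscore_genes(adata: ad.AnnData) -> ad.AnnData:
    """Scale each gene to mean 0, sd 1 across cells.

    Zero-variance genes become all-zero rows and are flagged in
    ``var['zero_variance']``.
    """
    out = adata.copy()
    X = _to_dense(out.X).astype(np.float64)
    mean = X.mean(axis=0)
    sd = X.std(axis=0)
    zero = sd == 0
    sd_safe = np.where(zero, 1.0, sd)
    Z = (X - mean) / sd_safe
    Z[:, zero] = 0.0
    out.X = Z
    out.var["zero_variance"] = zero
    return out


def variable_genes(
    adata_norm: ad.AnnData, n_bins: int = 20, z_cutoff: float = 1.0
) -> list[str]:
    """Dispersion-based variable-gene selection.

    Per gene, dispersion = variance/mean of normalized expression; genes
    are binned by mean expression into ``n_bins`` equal-frequency bins and
    the dispersion is z-scored within each bin; genes with z above
    ``z_cutoff`` are returned.
    """
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    if adata_norm.n_vars < n_bins:
        raise ValueError("fewer genes than bins")
    X = _to_dense(adata_norm.X).astype(np.float64)
    mean = X.mean(axis=0)
    var = X.var(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        dispersion = np.where(mean > 0, var / np.maximum(mean, 1e-12), 0.0)
    # Equal-frequency bins over mean expression (ties broken by gene order).
    order = np.argsort(mean, kind="stable")
    bins = np.empty(len(mean), dtype=int)
    bins[order] = np.floor(np.arange(len(mean)) * n_bins / len(mean)).astype(int)
    z = np.zeros(len(mean))
    for b in range(n_bins):
        m = bins == b
        d = dispersion[m]
        sd = d.std()
        z[m] = (d - d.mean()) / sd if sd > 0 else 0.0
    return [g for g, zi in zip(adata_norm.var_names, z) if zi > z_cutoff]


@dataclass
class ClusterResult:
    """Cluster labels plus the settings that produced them.

    Labels are integers 0..k-1 relabelled by decreasing cluster size;
    ``age_distribution`` (clusters x ages) is filled when the data carry an
    age column.
    """

    labels: pd.Series
    resolution: float
    k_neighbors: int
    n_pcs: int
    age_distribution: pd.DataFrame | None = None

    def sizes(self) -> pd.Series:
        return self.labels.value_counts().sort_index()


class ResolutionSelectionError(RuntimeError):
    """No resolution on the grid met the enrichment criterion; carries the
    full per-resolution containment/purity table as ``.table``."""

    def __init__(self, message: str, table: pd.DataFrame):
        super().__init__(message)
        self.table = table


def _knn_graph(X: np.ndarray, n_pcs: int, k: int) -> tuple[igraph.Graph, np.ndarray]:
    n_cells, n_genes = X.shape
    if k >= n_cells:
        raise ValueError("k must be below the number of cells")
    if k < 2:
        raise ValueError("k must be >= 2")
    if n_pcs > min(n_cells, n_genes):
        raise ValueError("n_pcs cannot exceed min(cells, genes)")
    pcs = PCA(n_components=n_pcs, svd_solver="full").fit_transform(X)
    nn = NearestNeighbors(n_neighbors=k + 1, metric="euclidean").fit(pcs)
    _, idx = nn.kneighbors(pcs)
    edges = {(min(i, j), max(i, j)) for i, row in enumerate(idx) for j in row[1:]}
    graph = igraph.Graph(n=n_cells, edges=sorted(edges), directed=False)
    return graph, pcs


def _partition(graph: igraph.Graph, resolution: float, seed: int) -> np.ndarray:
    part = leidenalg.find_partition(
        graph,
        leidenalg.RBConfigurationVertexPartition,
        resolution_parameter=resolution,
        seed=seed,
        n_iterations=2,
    )
    raw = np.asarray(part.membership)
    # Relabel by decreasing size, ties by first occurrence.
    sizes = pd.Series(raw).value_counts()
    first_seen = {c: np.argmax(raw == c) for c in sizes.index}
    order = sorted(sizes.index, key=lambda c: (-sizes[c], first_seen[c]))
    remap = {old: new for new, old in enumerate(order)}
    return np.array([remap[c] for c in raw])


def cluster_graph(
    adata_scaled: ad.AnnData,
    n_pcs: int = 20,
    k: int = 15,
    resolution: float = 0.6,
    seed: int = 0,
    age_key: str = "age",
) -> ClusterResult:
    """PCA -> KNN graph -> modularity community detection.

    Cells are embedded in principal-component space, joined to their ``k``
    nearest Euclidean neighbours, and partitioned by modularity
    optimisation at the given resolution.  Deterministic under a fixed
    seed; labels are relabelled by decreasing cluster size.
    """
    X = _to_dense(adata_scaled.X).astype(np.float64)
    graph, _ = _knn_graph(X, n_pcs, k)
    labels = pd.Series(_partition(graph, resolution, seed), index=adata_scaled.obs_names)
    age_dist = None
    if age_key in adata_scaled.obs:
        age_dist = pd.crosstab(labels, adata_scaled.obs[age_key])
        age_dist.index.name = "cluster"
    return ClusterResult(labels=labels, resolution=resolution,
                         k_neighbors=k, n_pcs=n_pcs, age_distribution=age_dist)


def select_resolution(
    adata_scaled: ad.AnnData,
    reference_cells: Sequence[str] | np.ndarray,
    resolution_grid: Sequence[float] = (0.2, 0.4, 0.6, 0.8, 1.0, 1.2),
    enrichment_min: float = 0.5,
    containment_min: float = 0.8,
    n_pcs: int = 20,
    k: int = 15,
    seed: int = 0,
    age_key: str = "age",
) -> tuple[float, ClusterResult, pd.DataFrame]:
    """Choose the clustering resolution that isolates a reference population.

    For each resolution on the grid, the cluster holding the largest share
    of the reference cells is scored by containment (share of the reference
    inside it) and purity (share of the cluster that is reference).  The
    smallest resolution with containment >= ``containment_min`` and purity
    >= ``enrichment_min`` is chosen — the reference population is then
    "enriched within a single cluster".  Raises
    :class:`ResolutionSelectionError` (carrying the scan table) if no
    resolution qualifies.
    """
    ref = pd.Index(reference_cells)
    if len(ref) == 0:
        raise ValueError("reference cell set is empty")
    if len(resolution_grid) == 0:
        raise ValueError("resolution grid is empty")
    is_ref = adata_scaled.obs_names.isin(ref)
    X = _to_dense(adata_scaled.X).astype(np.float64)
    graph, _ = _knn_graph(X, n_pcs, k)

    rows = []
    results: dict[float, np.ndarray] = {}
    for res in sorted(resolution_grid):
        labels = _partition(graph, res, seed)
        results[res] = labels
        best_containment, best_purity, best_cluster = 0.0, 0.0, -1
        for c in np.unique(labels):
            inside = np.sum(is_ref & (labels == c))
            containment = inside / is_ref.sum()
            if containment > best_containment:
                best_containment = containment
                best_purity = inside / np.sum(labels == c)
                best_cluster = int(c)
        rows.append(dict(resolution=res, n_clusters=len(np.unique(labels)),
                         best_cluster=best_cluster, containment=best_containment,
                         purity=best_purity))
    table = pd.DataFrame(rows)
    ok = table[(table["containment"] >= containment_min)
               & (table["purity"] >= enrichment_min)]
    if ok.empty:
        raise ResolutionSelectionError(
            f"no resolution reached containment >= {containment_min} and "
            f"purity >= {enrichment_min}", table,
        )
    chosen = float(ok["resolution"].iloc[0])
    labels = pd.Series(results[chosen], index=adata_scaled.obs_names)
    age_dist = None
    if age_key in adata_scaled.obs:
        age_dist = pd.crosstab(labels, adata_scaled.obs[age_key])
        age_dist.index.name = "cluster"
    return chosen, ClusterResult(labels=labels, resolution=chosen,
                                 k_neighbors=k, n_pcs=n_pcs,
                                 age_distribution=age_dist), table


@dataclass
class MarkerStats:
    """Dotplot statistics: per gene x cluster scaled mean expression
    (z-scored across clusters, so each gene's values average to 0) and
    detection fraction (share of the cluster's cells with a nonzero raw
    count)."""

    scaled: pd.DataFrame  # genes x clusters
    detection: pd.DataFrame  # genes x clusters
    cluster_sizes: pd.Series


def marker_stats(
    adata_norm: ad.AnnData,
    labels: pd.Series,
    counts_layer: str = "counts",
) -> MarkerStats:
    """Compute dotplot statistics from normalized expression and raw counts.

    Mean normalized expression per cluster is z-scored across clusters for
    each gene; detection fraction uses the raw counts layer when available
    (falling back to the normalized matrix's nonzero pattern).
    """
    labels = labels.reindex(adata_norm.obs_names)
    if labels.isna().any():
        raise ValueError("labels must cover every cell")
    X = _to_dense(adata_norm.X).astype(np.float64)
    C = _to_dense(adata_norm.layers[counts_layer]) if counts_layer in adata_norm.layers else X
    clusters = sorted(pd.unique(labels))
    means, detects, sizes = {}, {}, {}
    for c in clusters:
        m = (labels == c).to_numpy()
        means[c] = X[m].mean(axis=0)
        detects[c] = (C[m] > 0).mean(axis=0)
        sizes[c] = int(m.sum())
    mean_df = pd.DataFrame(means, index=adata_norm.var_names)
    mu = mean_df.mean(axis=1)
    sd = mean_df.std(axis=1, ddof=0)
    scaled = mean_df.sub(mu, axis=0).div(sd.where(sd > 0, 1.0), axis=0)
    scaled[sd == 0] = 0.0
    return MarkerStats(
        scaled=scaled,
        detection=pd.DataFrame(detects, index=adata_norm.var_names),
        cluster_sizes=pd.Series(sizes),
    )


def passes_marker_criteria(
    stats: MarkerStats,
    gene: str,
    scaled_min: float = 0.0,
    detect_min: float = 0.10,
) -> bool:
    """Marker criterion: scaled expression above ``scaled_min`` AND
    detection above ``detect_min`` within at least one cluster (strict)."""
    if gene not in stats.scaled.index:
        raise ValueError(f"gene {gene!r} not present")
    s = stats.scaled.loc[gene]
    d = stats.detection.loc[gene]
    return bool(((s > scaled_min) & (d > detect_min)).any())


def annotate_clusters(
    stats: MarkerStats,
    panels: Mapping[str, Sequence[str]],
    ssc_key: str = "ssc",
    diff_key: str = "diff",
) -> tuple[pd.DataFrame, dict]:
    """Score clusters against marker panels and pick the SSC-like cluster.

    Per cluster, each panel's score is the mean scaled expression over the
    panel's genes; the SSC-like cluster maximises (SSC score -
    differentiation score).  The full score table is returned so no
    threshold is hidden.
    """
    scores = {}
    for name, genes in panels.items():
        if len(genes) == 0:
            raise ValueError(f"panel {name!r} is empty")
        missing = [g for g in genes if g not in stats.scaled.index]
        if missing:
            raise ValueError(f"panel {name!r} genes absent: {missing}")
        scores[name] = stats.scaled.loc[list(genes)].mean(axis=0)
    score_df = pd.DataFrame(scores)
    score_df.index.name = "cluster"
    labels: dict = {}
    if ssc_key in score_df and diff_key in score_df:
        delta = score_df[ssc_key] - score_df[diff_key]
        labels["ssc_like"] = delta.idxmax()
        labels["ssc_minus_diff"] = delta
    return score_df, labels


def cluster_overlap(labels_a: pd.Series, labels_b: pd.Series) -> pd.DataFrame:
    """Percent of each cluster in A contained in each cluster of B.

    Both labelings must cover the same cells; rows sum to 100.
    """
    if set(labels_a.index) != set(labels_b.index):
        raise ValueError("labelings must share the same cell universe")
    labels_b = labels_b.reindex(labels_a.index)
    table = pd.crosstab(labels_a, labels_b, normalize="index") * 100.0
    table.index.name, table.columns.name = "cluster_a", "cluster_b"
    return table


def modified_rv(X: np.ndarray | pd.DataFrame, Y: np.ndarray | pd.DataFrame) -> float:
    """Modified RV coefficient between two feature-matched matrices.

    Columns are centred, the feature-by-feature inner-product (configuration)
    matrices are formed and their diagonals set to zero — the adjustment
    that removes the self-similarity inflation of the plain RV — and the
    coefficient is their normalised Frobenius inner product, in [-1, 1].
    Returns NaN when either configuration matrix has zero norm (constant
    input).
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if Y.ndim == 1:
        Y = Y[:, None]
    if X.shape[0] != Y.shape[0]:
        raise ValueError("X and Y must share the feature (row) universe")
    if X.shape[0] < 2:
        raise ValueError("need at least two features")
    Xc = X - X.mean(axis=0)
    Yc = Y - Y.mean(axis=0)
    Sx = Xc @ Xc.T
    Sy = Yc @ Yc.T
    np.fill_diagonal(Sx, 0.0)
    np.fill_diagonal(Sy, 0.0)
    denom = np.linalg.norm(Sx) * np.linalg.norm(Sy)
    if denom == 0:
        return float("nan")
    return float(np.sum(Sx * Sy) / denom)


def pseudobulk(
    adata_norm: ad.AnnData, by: str = "library"
) -> pd.DataFrame:
    """Per-gene mean normalized expression per group (genes x groups)."""
    X = _to_dense(adata_norm.X).astype(np.float64)
    groups = adata_norm.obs[by].astype(str)
    cols = {}
    for g in sorted(groups.unique()):
        cols[g] = X[(groups == g).to_numpy()].mean(axis=0)
    return pd.DataFrame(cols, index=adata_norm.var_names)


def write_counts_mtx(adata: ad.AnnData, out_dir) -> None:
    """Write counts as Matrix Market (genes x cells) with gene/cell tables.

    Produces ``matrix.mtx`` (genes x cells, the market-matrix convention
    for droplet data), ``genes.tsv`` (one gene name per line) and
    ``cells.csv`` (per-cell metadata, index column ``cell``).
    """
    from pathlib import Path

    from scipy.io import mmwrite

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    X = adata.X if sp.issparse(adata.X) else sp.csr_matrix(adata.X)
    mmwrite(out / "matrix.mtx", X.T.tocoo())
    (out / "genes.tsv").write_text("\n".join(adata.var_names) + "\n")
    obs = adata.obs.copy()
    obs.index.name = "cell"
    obs.to_csv(out / "cells.csv")


def read_counts_mtx(in_dir) -> ad.AnnData:
    """Read a counts directory written by :func:`write_counts_mtx`."""
    from pathlib import Path

    from scipy.io import mmread

    src = Path(in_dir)
    X = sp.csr_matrix(mmread(src / "matrix.mtx").T)
    genes = (src / "genes.tsv").read_text().splitlines()
    obs = pd.read_csv(src / "cells.csv", index_col="cell")
    obs.index = obs.index.astype(str)
    return ad.AnnData(X=X, obs=obs, var=pd.DataFrame(index=pd.Index(genes, name="gene")))


def replicate_rv_table(
    adata_norm: ad.AnnData,
    library_key: str = "library",
    age_key: str = "age",
) -> pd.DataFrame:
    """Modified RV between every pair of replicate libraries within each age.

    Uses pseudobulk profiles (per-gene mean normalized expression per
    library) as the replicate feature matrices.
    """
    pb = pseudobulk(adata_norm, by=library_key)
    lib_age = (
        adata_norm.obs[[library_key, age_key]].drop_duplicates().set_index(library_key)[age_key]
    )
    rows = []
    for age in sorted(lib_age.unique()):
        libs = sorted(lib_age[lib_age == age].index)
        for i in range(len(libs)):
            for j in range(i + 1, len(libs)):
                rows.append(dict(
                    age=age, library_a=libs[i], library_b=libs[j],
                    modified_rv=modified_rv(pb[libs[i]].to_numpy(),
                                            pb[libs[j]].to_numpy()),
                ))
    return pd.DataFrame(rows)
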