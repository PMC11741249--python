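"""QC filtering, normalisation, clustering and clustering agreement.

The processing conventions mirror the standard droplet single-cell
toolchain: cells are kept if they express at least a minimum number of genes
and fall below a modality-specific mitochondrial-read fraction (20% for
single-cell, 5% for single-nucleus); genes are kept if expressed in more
than a minimum number of cells; multiome cells are additionally gated on
total ATAC and RNA read counts.  Expression is normalised to
log(1 + counts-per-10k) with the natural log.  Clustering scales genes,
projects onto principal components, builds a shared-nearest-neighbour
weighted kNN graph and optimises resolution-parameterised modularity
(seeded Leiden).  Agreement between two clusterings is measured by the
adjusted Rand index with an exchangeable-label permutation test.
"""

from __future__ import annotations

from dataclasses import dataclass

import igraph as ig
import leidenalg
import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.metrics import adjusted_rand_score
from sklearn.neighbors import NearestNeighbors

from .containers import ClusterLabels, CountMatrix

__all__ = [
    "QCThresholds",
    "apply_qc",
    "normalize_log_cp10k",
    "cluster_cells",
    "adjusted_rand_index",
    "ari_permutation_test",
]


@dataclass
class QCThresholds:
    """Modality-specific QC gates.

    ``min_genes_per_cell`` keeps cells expressing at least that many genes;
    ``min_cells_per_gene`` keeps genes expressed in strictly more than that
    many cells; ``max_mito_fraction`` removes cells at or above the cutoff.
    For the multiome modality, per-cell ATAC/RNA read totals must lie
    within the stated bounds (inclusive).
    """

    min_genes_per_cell: int = 200
    min_cells_per_gene: int = 3
    max_mito_fraction: float = 0.20
    modality: str = "single-cell"
    atac_read_bounds: tuple[int, int] | None = None
    rna_read_bounds: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        if self.modality not in ("single-cell", "single-nucleus", "multiome"):
            raise ValueError(f"unknown modality: {self.modality}")
        if not 0 <= self.max_mito_fraction <= 1:
            raise ValueError("max_mito_fraction must lie in [0, 1]")
        for b in (self.atac_read_bounds, self.rna_read_bounds):
            if b is not None and b[0] > b[1]:
                raise ValueError("read bounds must be ordered")
        if self.modality == "multiome" and (self.atac_read_bounds is None or self.rna_read_bounds is None):
            raise ValueError("multiome thresholds require atac/rna read bounds")

    @classmethod
    def for_modality(cls, modality: str) -> "QCThresholds":
        """Conventional defaults per modality (sn mito cutoff 5%, multiome
        ATAC reads in (500, 80000) and RNA reads in (500, 25000))."""
        if modality == "single-cell":
            return cls(modality="single-cell", max_mito_fraction=0.20)
        if modality == "single-nucleus":
            return cls(modality="single-nucleus", max_mito_fraction=0.05)
        if modality == "multiome":
            return cls(
                modality="multiome",
                max_mito_fraction=0.10,
                atac_read_bounds=(500, 80000),
                rna_read_bounds=(500, 25000),
            )
        raise ValueError(f"unknown modality: {modality}")


def apply_qc(
    cm: CountMatrix,
    thresholds: QCThresholds,
    atac_reads: np.ndarray | None = None,
) -> tuple[CountMatrix, dict]:
    """Filter cells then genes, returning the filtered matrix and a report.

    Cell rules: expressed-gene count >= ``min_genes_per_cell``,
    mitochondrial fraction < ``max_mito_fraction`` and, for multiome, read
    totals within the bounds.  Gene rule: expressed in
    > ``min_cells_per_gene`` cells (evaluated on the retained cells).
    """
    t = thresholds
    expressed = cm.counts > 0
    genes_per_cell = expressed.sum(axis=0)
    libsize = cm.counts.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        mito_frac = np.where(libsize > 0, cm.counts[cm.mito_flags].sum(axis=0) / np.maximum(libsize, 1), 0.0)

    low_genes = genes_per_cell < t.min_genes_per_cell
    high_mito = mito_frac >= t.max_mito_fraction
    cell_keep = ~(low_genes | high_mito)
    report = {
        "cells_removed_low_genes": int(low_genes.sum()),
        "cells_removed_high_mito": int(high_mito.sum()),
    }
    if t.modality == "multiome":
        rna_lo, rna_hi = t.rna_read_bounds
        bad_rna = (libsize < rna_lo) | (libsize > rna_hi)
        if atac_reads is None:
            raise ValueError("multiome QC requires per-cell atac_reads")
        atac_reads = np.asarray(atac_reads)
        a_lo, a_hi = t.atac_read_bounds
        bad_atac = (atac_reads < a_lo) | (atac_reads > a_hi)
        report["cells_removed_rna_reads"] = int((bad_rna & cell_keep).sum())
        report["cells_removed_atac_reads"] = int((bad_atac & ~bad_rna & cell_keep).sum())
        cell_keep &= ~(bad_rna | bad_atac)

    if not cell_keep.any():
        raise ValueError("all cells filtered by QC")

    cells_per_gene = (cm.counts[:, cell_keep] > 0).sum(axis=1)
    gene_keep = cells_per_gene > t.min_cells_per_gene
    report["genes_removed_low_cells"] = int((~gene_keep).sum())
    if not gene_keep.any():
        raise ValueError("all genes filtered by QC")

    filtered = cm.subset(gene_mask=gene_keep, cell_mask=cell_keep)
    report["cells_kept"] = filtered.n_cells
    report["genes_kept"] = filtered.n_genes
    return filtered, report


def normalize_log_cp10k(cm: CountMatrix) -> pd.DataFrame:
    """ln(1 + 10,000 * count / library size), genes x cells.

    The inverse identity holds per cell: sum_g expm1(value) == 10,000.
    """
    libsize = cm.counts.sum(axis=0).astype(float)
    if (libsize == 0).any():
        raise ValueError("cells with zero library size cannot be normalised")
    values = np.log1p(1e4 * cm.counts / libsize[None, :])
    return pd.DataFrame(values, index=cm.gene_ids, columns=cm.cell_ids)


def _scale_genes(norm: np.ndarray, cap: float = 10.0) -> np.ndarray:
    """Standardise genes across cells, capping values at +/- cap."""
    mu = norm.mean(axis=1, keepdims=True)
    sd = norm.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return np.clip((norm - mu) / sd, -cap, cap)


def _snn_graph(pcs: np.ndarray, k: int) -> ig.Graph:
    """Shared-nearest-neighbour weighted kNN graph (Jaccard weights)."""
    nn = NearestNeighbors(n_neighbors=k + 1).fit(pcs)
    _, idx = nn.kneighbors(pcs)
    n = pcs.shape[0]
    neigh = [set(row[1:]) | {i} for i, row in enumerate(idx)]
    edges: dict[tuple[int, int], float] = {}
    for i, row in enumerate(idx):
        for j in row[1:]:
            a, b = (i, int(j)) if i < j else (int(j), i)
            if (a, b) in edges:
                continue
            inter = len(neigh[a] & neigh[b])
            union = len(neigh[a] | neigh[b])
            w = inter / union
            if w > 1e-12:
                edges[(a, b)] = w
    g = ig.Graph(n=n, edges=list(edges.keys()))
    g.es["weight"] = list(edges.values())
    return g


def cluster_cells(
    norm: pd.DataFrame,
    resolution: float = 0.3,
    seed: int = 0,
    n_pcs: int = 30,
    k_neighbors: int = 20,
) -> ClusterLabels:
    """Unsupervised clustering of normalised expression.

    Pipeline: gene scaling (capped z-scores) -> top ``n_pcs`` principal
    components -> SNN-weighted kNN graph -> seeded Leiden optimisation of
    RB-configuration modularity at the given resolution.  Deterministic for
    a fixed seed.
    """
    x = np.asarray(norm, dtype=float)
    n_cells = x.shape[1]
    if n_cells < k_neighbors + 1:
        raise ValueError("need at least k_neighbors + 1 cells")
    n_pcs = min(n_pcs, n_cells - 1, x.shape[0])
    if n_pcs < 1:
        raise ValueError("fewer cells than components")
    scaled = _scale_genes(x).T  # cells x genes
    pcs = PCA(n_components=n_pcs, svd_solver="full", random_state=seed).fit_transform(scaled)
    g = _snn_graph(pcs, k_neighbors)
    part = leidenalg.find_partition(
        g,
        leidenalg.RBConfigurationVertexPartition,
        weights=g.es["weight"],
        resolution_parameter=resolution,
        seed=seed,
        n_iterations=-1,
    )
    raw = np.asarray(part.membership)
    # contiguous ids ordered by cluster size (ties by first occurrence)
    order = pd.Series(raw).value_counts(sort=True).index
    remap = {old: new for new, old in enumerate(order)}
    labels = pd.Series([remap[v] for v in raw], index=norm.columns)
    return ClusterLabels(labels=labels, resolution=resolution, seed=seed)


def adjusted_rand_index(a: ClusterLabels | pd.Series, b: ClusterLabels | pd.Series) -> float:
    """Pair-counting adjusted Rand index between two partitions."""
    sa = a.labels if isinstance(a, ClusterLabels) else pd.Series(a)
    sb = b.labels if isinstance(b, ClusterLabels) else pd.Series(b)
    if not sa.index.sort_values().equals(sb.index.sort_values()):
        raise ValueError("partitions must cover the same cell set")
    sb = sb.loc[sa.index]
    return float(adjusted_rand_score(sa.to_numpy(), sb.to_numpy()))


def ari_permutation_test(
    a: ClusterLabels | pd.Series,
    b: ClusterLabels | pd.Series,
    n_perm: int = 999,
    seed: int = 0,
) -> tuple[float, float]:
    """Permutation p-value for the observed ARI.

    The labels of ``b`` are permuted as a whole vector (exchangeable null);
    p = (1 + #{permuted ARI >= observed}) / (n_perm + 1).
    """
    if n_perm < 99:
        raise ValueError("n_perm must be >= 99")
    sa = (a.labels if isinstance(a, ClusterLabels) else pd.Series(a)).to_numpy()
    sb_series = b.labels if isinstance(b, ClusterLabels) else pd.Series(b)
    sa_series = a.labels if isinstance(a, ClusterLabels) else pd.Series(a)
    sb = sb_series.loc[sa_series.index].to_numpy()
    observed = float(adjusted_rand_score(sa, sb))
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(sb)
        if adjusted_rand_score(sa, perm) >= observed:
            count += 1
    p = (1 + count) / (n_perm + 1)
    return observed, float(p)
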