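"""In-memory containers shared across the pipeline stages.

Expression data live in a :class:`CountMatrix` (gene x cell integer counts
plus per-cell metadata), accessibility data in a
:class:`MotifAccessibilityBundle` (peak x cell counts, BED-style peak
intervals, motif membership and a TF-to-motif map).  Both are thin dataclass
wrappers over numpy arrays and pandas indexes: small enough to stay dense at
the scales this package targets, explicit enough that every downstream
operation can state its contract on them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CountMatrix",
    "MotifAccessibilityBundle",
    "ClusterLabels",
]


@dataclass
class CountMatrix:
    """Gene x cell non-negative integer counts with identifiers and metadata.

    Parameters
    ----------
    counts
        ``(n_genes, n_cells)`` integer array.
    gene_ids, cell_ids
        Unique labels for rows and columns.
    cell_meta
        Per-cell metadata indexed by ``cell_ids`` (columns such as
        ``genotype``, ``strain``, ``cell_class``).
    mito_flags
        Boolean per-gene flag marking mitochondrial genes, used by QC.
    """

    counts: np.ndarray
    gene_ids: pd.Index
    cell_ids: pd.Index
    cell_meta: pd.DataFrame = field(default=None)  # type: ignore[assignment]
    mito_flags: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        self.gene_ids = pd.Index(self.gene_ids)
        self.cell_ids = pd.Index(self.cell_ids)
        if self.counts.ndim != 2:
            raise ValueError("counts must be 2-dimensional (genes x cells)")
        n_genes, n_cells = self.counts.shape
        if len(self.gene_ids) != n_genes or len(self.cell_ids) != n_cells:
            raise ValueError("id lengths inconsistent with counts shape")
        if self.gene_ids.has_duplicates or self.cell_ids.has_duplicates:
            raise ValueError("gene/cell ids must be unique")
        if not np.isfinite(self.counts).all():
            raise ValueError("counts must be finite")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")
        if self.cell_meta is None:
            self.cell_meta = pd.DataFrame(index=self.cell_ids)
        else:
            self.cell_meta = self.cell_meta.loc[self.cell_ids]
        if self.mito_flags is None:
            self.mito_flags = np.zeros(n_genes, dtype=bool)
        else:
            self.mito_flags = np.asarray(self.mito_flags, dtype=bool)
            if self.mito_flags.shape != (n_genes,):
                raise ValueError("mito_flags length must equal number of genes")

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_cells(self) -> int:
        return self.counts.shape[1]

    def subset(self, gene_mask=None, cell_mask=None) -> "CountMatrix":
        """Return a new matrix restricted to the given boolean masks."""
        gm = np.ones(self.n_genes, bool) if gene_mask is None else np.asarray(gene_mask, bool)
        cm = np.ones(self.n_cells, bool) if cell_mask is None else np.asarray(cell_mask, bool)
        return CountMatrix(
            counts=self.counts[np.ix_(gm, cm)],
            gene_ids=self.gene_ids[gm],
            cell_ids=self.cell_ids[cm],
            cell_meta=self.cell_meta.loc[self.cell_ids[cm]],
            mito_flags=self.mito_flags[gm],
        )


@dataclass
class MotifAccessibilityBundle:
    """Peak x cell accessibility counts with motif annotation.

    ``peaks`` is a BED-convention DataFrame (chrom, start, end; 0-based,
    half-open).  ``motif_membership`` is a motif x peak 0/1 matrix and
    ``tf_to_motif`` maps transcription-factor names onto motif ids.  Every
    motif must own at least one member peak.
    """

    peak_counts: np.ndarray
    peaks: pd.DataFrame
    motif_membership: np.ndarray
    motif_ids: pd.Index
    cell_ids: pd.Index
    tf_to_motif: dict[str, str]

    def __post_init__(self) -> None:
        self.peak_counts = np.asarray(self.peak_counts)
        self.motif_membership = np.asarray(self.motif_membership).astype(bool)
        self.motif_ids = pd.Index(self.motif_ids)
        self.cell_ids = pd.Index(self.cell_ids)
        n_peaks, n_cells = self.peak_counts.shape
        if len(self.peaks) != n_peaks:
            raise ValueError("peaks table inconsistent with peak_counts")
        if self.motif_membership.shape != (len(self.motif_ids), n_peaks):
            raise ValueError("motif_membership inconsistent with motifs/peaks")
        if len(self.cell_ids) != n_cells:
            raise ValueError("cell_ids inconsistent with peak_counts")
        empty = ~self.motif_membership.any(axis=1)
        if empty.any():
            bad = list(self.motif_ids[empty][:5])
            raise ValueError(f"motifs with zero member peaks: {bad}")

    @property
    def n_peaks(self) -> int:
        return self.peak_counts.shape[0]

    @property
    def n_cells(self) -> int:
        return self.peak_counts.shape[1]


@dataclass
class ClusterLabels:
    """Cluster assignment for a fixed cell set.

    ``labels`` is a pandas Series indexed by cell id with small-integer
    cluster ids, contiguous from 0.
    """

    labels: pd.Series
    resolution: float | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        self.labels = pd.Series(self.labels).astype(int)
        uniq = np.unique(self.labels.to_numpy())
        if len(uniq) and (uniq.min() != 0 or not np.array_equal(uniq, np.arange(len(uniq)))):
            remap = {old: new for new, old in enumerate(uniq)}
            self.labels = self.labels.map(remap)

    @property
    def n_clusters(self) -> int:
        return int(self.labels.nunique())

    def to_array(self) -> np.ndarray:
        return self.labels.to_numpy()
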