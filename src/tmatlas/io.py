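"""On-disk formats.

Count matrices travel as an MTX triplet directory (``matrix.mtx`` with
genes as rows, ``genes.tsv``, ``barcodes.tsv``, ``cells_meta.tsv``); peaks
as 3-column BED (0-based, half-open); motif membership and TF expression as
TSV; cluster labels as a two-column TSV; sections, mitochondria and nuclei
as JSON arrays of polygon vertex lists in micrometres.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse
from shapely.geometry import Polygon

from .containers import ClusterLabels, CountMatrix, MotifAccessibilityBundle
from .morphometry import MitochondrionTrace, NucleusShape
from .zones import MarkerMask, SectionGeometry

__all__ = [
    "write_count_matrix",
    "read_count_matrix",
    "write_labels",
    "read_labels",
    "write_bundle",
    "read_bundle",
    "write_sections",
    "read_sections",
    "write_mitochondria",
    "read_mitochondria",
    "write_nuclei",
    "read_nuclei",
]


def write_count_matrix(cm: CountMatrix, outdir) -> None:
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    spio.mmwrite(out / "matrix.mtx", sparse.csr_matrix(cm.counts))
    pd.DataFrame({"gene_id": cm.gene_ids, "mito": cm.mito_flags.astype(int)}).to_csv(
        out / "genes.tsv", sep="\t", index=False
    )
    pd.Series(cm.cell_ids, name="cell_id").to_csv(out / "barcodes.tsv", sep="\t", index=False)
    cm.cell_meta.rename_axis("cell_id").to_csv(out / "cells_meta.tsv", sep="\t")


def read_count_matrix(indir) -> CountMatrix:
    ind = Path(indir)
    counts = np.asarray(spio.mmread(ind / "matrix.mtx").todense()).astype(np.int64)
    genes = pd.read_csv(ind / "genes.tsv", sep="\t")
    barcodes = pd.read_csv(ind / "barcodes.tsv", sep="\t")["cell_id"]
    meta = pd.read_csv(ind / "cells_meta.tsv", sep="\t", index_col="cell_id")
    return CountMatrix(
        counts=counts,
        gene_ids=pd.Index(genes["gene_id"]),
        cell_ids=pd.Index(barcodes),
        cell_meta=meta,
        mito_flags=genes["mito"].to_numpy(bool),
    )


def write_labels(labels: ClusterLabels, path) -> None:
    df = labels.labels.rename("cluster").rename_axis("cell_id").reset_index()
    df.to_csv(path, sep="\t", index=False)


def read_labels(path) -> ClusterLabels:
    df = pd.read_csv(path, sep="\t")
    return ClusterLabels(labels=pd.Series(df["cluster"].to_numpy(), index=df["cell_id"]))


def write_bundle(bundle: MotifAccessibilityBundle, outdir) -> None:
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    spio.mmwrite(out / "peak_counts.mtx", sparse.csr_matrix(bundle.peak_counts))
    bundle.peaks[["chrom", "start", "end"]].to_csv(
        out / "peaks.bed", sep="\t", header=False, index=False
    )
    pd.DataFrame(
        bundle.motif_membership.astype(int),
        index=bundle.motif_ids,
        columns=bundle.peaks.index,
    ).rename_axis("motif").to_csv(out / "motif_membership.tsv", sep="\t")
    pd.Series(bundle.cell_ids, name="cell_id").to_csv(out / "barcodes.tsv", sep="\t", index=False)
    pd.Series(bundle.tf_to_motif, name="motif").rename_axis("tf").to_csv(
        out / "tf_to_motif.tsv", sep="\t"
    )


def read_bundle(indir) -> MotifAccessibilityBundle:
    ind = Path(indir)
    counts = np.asarray(spio.mmread(ind / "peak_counts.mtx").todense()).astype(np.int64)
    peaks = pd.read_csv(ind / "peaks.bed", sep="\t", names=["chrom", "start", "end"])
    peaks.index = pd.Index([f"peak{i:05d}" for i in range(len(peaks))])
    membership = pd.read_csv(ind / "motif_membership.tsv", sep="\t", index_col="motif")
    cells = pd.read_csv(ind / "barcodes.tsv", sep="\t")["cell_id"]
    tf_map = pd.read_csv(ind / "tf_to_motif.tsv", sep="\t", index_col="tf")["motif"].to_dict()
    return MotifAccessibilityBundle(
        peak_counts=counts,
        peaks=peaks,
        motif_membership=membership.to_numpy(bool),
        motif_ids=membership.index,
        cell_ids=pd.Index(cells),
        tf_to_motif=tf_map,
    )


def _poly_coords(poly: Polygon) -> list[list[float]]:
    return [[float(x), float(y)] for x, y in list(poly.exterior.coords)[:-1]]


def write_sections(sections: list[tuple[SectionGeometry, MarkerMask]], path) -> None:
    records = []
    for sec, mask in sections:
        records.append(
            {
                "section_id": sec.section_id,
                "tm_polygon": _poly_coords(sec.tm_polygon),
                "marker": mask.marker,
                "subtype": mask.subtype,
                "positive_polygons": [_poly_coords(p) for p in mask.polygons],
            }
        )
    Path(path).write_text(json.dumps(records))


def read_sections(path) -> list[tuple[SectionGeometry, MarkerMask]]:
    records = json.loads(Path(path).read_text())
    out = []
    for r in records:
        sec = SectionGeometry(Polygon(r["tm_polygon"]), section_id=r["section_id"])
        mask = MarkerMask(
            marker=r["marker"],
            subtype=r["subtype"],
            polygons=[Polygon(p) for p in r["positive_polygons"]],
        )
        out.append((sec, mask))
    return out


def write_mitochondria(traces: dict[str, list[MitochondrionTrace]], path) -> None:
    records = [
        {
            "genotype": g,
            "cell_id": t.cell_id,
            "outer": [[float(x), float(y)] for x, y in t.outer],
            "cristae": [[[float(x), float(y)] for x, y in c] for c in t.cristae],
        }
        for g, ts in traces.items()
        for t in ts
    ]
    Path(path).write_text(json.dumps(records))


def read_mitochondria(path) -> dict[str, list[MitochondrionTrace]]:
    records = json.loads(Path(path).read_text())
    out: dict[str, list[MitochondrionTrace]] = {}
    for r in records:
        t = MitochondrionTrace(
            cell_id=r["cell_id"],
            outer=[tuple(v) for v in r["outer"]],
            cristae=[[tuple(v) for v in c] for c in r["cristae"]],
            genotype=r["genotype"],
        )
        out.setdefault(r["genotype"], []).append(t)
    return out


def write_nuclei(shapes: list[NucleusShape], path) -> None:
    pd.DataFrame(
        [{"subtype": s.subtype, "volume": s.volume, "surface_area": s.surface_area} for s in shapes]
    ).to_csv(path, sep="\t", index=False)


def read_nuclei(path) -> list[NucleusShape]:
    df = pd.read_csv(path, sep="\t")
    return [
        NucleusShape(volume=r.volume, surface_area=r.surface_area, subtype=r.subtype)
        for r in df.itertuples()
    ]
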