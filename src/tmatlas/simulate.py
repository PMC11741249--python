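"""Synthetic limbal data with planted ground truth.

Every generator here emulates one of the inputs the analysis consumes, with
the statistical structure the downstream methods assume and with the planted
truth emitted alongside (never embedded in) the data:

* :func:`generate_count_matrix` - negative-binomial gene x cell counts for a
  small panel of limbal cell classes, three of which are TM subtypes carrying
  disjoint planted marker-gene sets (and an optional TM1/TM2-shared block
  that makes those two subtypes molecularly closer to each other than to
  TM3).
* :func:`generate_multiome` - a peak x cell accessibility companion with a
  motif annotation and TF expression in which planted activator TFs are
  positively (repressors negatively) coupled to the accessibility of their
  motif's member peaks.
* :func:`generate_sections` - rectified TM wedge sections with marker-stain
  blobs placed with probability proportional to a per-zone bias.
* :func:`generate_mitochondria` - traced mitochondrion contours with
  genotype-dependent area and cristae-fraction effects.
* :func:`generate_nuclei` - ellipsoidal nuclei with subtype-dependent
  elongation.

All generators are pure functions of their configuration, including the
seed; one global seed is split into per-generator substreams by stable
hashing of the generator name.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from shapely.geometry import Point, Polygon

from ._rng import substream
from .containers import CountMatrix, MotifAccessibilityBundle
from .morphometry import MitochondrionTrace, NucleusShape, polygon_area
from .zones import MarkerMask, SectionGeometry, partition_eight_zones, partition_halves

__all__ = [
    "SimConfig",
    "MultiomeSimConfig",
    "SectionSimConfig",
    "generate_count_matrix",
    "generate_multiome",
    "generate_sections",
    "generate_mitochondria",
    "generate_nuclei",
]

TM_SUBTYPES = ("TM1", "TM2", "TM3")


# ---------------------------------------------------------------------------
# expression counts
# ---------------------------------------------------------------------------


@dataclass
class SimConfig:
    """Configuration for the limbal count-matrix generator.

    ``marker_fold`` multiplies the mean of each subtype's marker genes in
    that subtype only; ``nb_dispersion`` is the negative-binomial size
    parameter theta (var = mu + mu^2/theta); library sizes vary log-normally
    around ``library_size_mean``.  ``n_shared_tm12_markers`` genes are
    up-shifted in both TM1 and TM2, planting the expected topology in which
    TM1 and TM2 are molecularly closer to each other than to TM3.
    """

    n_cells_per_class: int = 300
    n_genes: int = 2000
    class_names: tuple[str, ...] = ("TM1", "TM2", "TM3", "CornealEndo", "IrisStroma", "Immune")
    n_markers_per_subtype: int = 20
    marker_fold: float = 8.0
    nb_dispersion: float = 2.0
    mito_gene_fraction: float = 0.05
    library_size_mean: int = 5000
    n_shared_tm12_markers: int = 10
    library_size_sigma: float = 0.25
    seed: int = 0

    def validate(self) -> None:
        if min(self.n_cells_per_class, self.n_genes, self.n_markers_per_subtype) < 1:
            raise ValueError("all counts must be >= 1")
        if self.library_size_mean < 1:
            raise ValueError("library_size_mean must be >= 1")
        for tm in TM_SUBTYPES:
            if tm not in self.class_names:
                raise ValueError(f"class_names must include {tm}")
        if len([c for c in self.class_names if c not in TM_SUBTYPES]) < 2:
            raise ValueError("need at least 2 non-TM classes")
        if len(set(self.class_names)) != len(self.class_names):
            raise ValueError("class names must be unique")
        if self.marker_fold < 1:
            raise ValueError("marker_fold must be >= 1")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be positive")
        if not 0 <= self.mito_gene_fraction <= 1:
            raise ValueError("mito_gene_fraction must lie in [0, 1]")
        needed = len(self.class_names) * self.n_markers_per_subtype + self.n_shared_tm12_markers
        if needed + int(self.mito_gene_fraction * self.n_genes) > self.n_genes:
            raise ValueError("n_genes too small for the requested marker/mito structure")


def generate_count_matrix(cfg: SimConfig) -> tuple[CountMatrix, dict]:
    """Draw a gene x cell count matrix with planted subtype markers.

    Returns the matrix and a truth dict with ``labels`` (per-cell class),
    ``markers`` (subtype -> planted marker gene ids), ``shared_tm12_markers``
    and ``mito_genes``.
    """
    cfg.validate()
    rng = substream(cfg.seed, "count_matrix")

    n_classes = len(cfg.class_names)
    n_cells = n_classes * cfg.n_cells_per_class
    labels = np.repeat(list(cfg.class_names), cfg.n_cells_per_class)

    # every class gets a disjoint identity-gene block: distinct limbal cell
    # types are separated by their own expression programmes, not only the
    # TM subtypes' signature genes
    nm = cfg.n_markers_per_subtype
    marker_idx = {cls: np.arange(i * nm, (i + 1) * nm) for i, cls in enumerate(cfg.class_names)}
    shared_start = len(cfg.class_names) * nm
    shared_idx = np.arange(shared_start, shared_start + cfg.n_shared_tm12_markers)
    n_mito = int(round(cfg.mito_gene_fraction * cfg.n_genes))
    mito_idx = np.arange(cfg.n_genes - n_mito, cfg.n_genes)

    gene_ids = [f"Gene{i:05d}" for i in range(cfg.n_genes)]
    for cls, idx in marker_idx.items():
        for j, g in enumerate(idx):
            gene_ids[g] = f"{cls}-mk{j:02d}"
    for j, g in enumerate(shared_idx):
        gene_ids[g] = f"TM12-shared{j:02d}"
    for j, g in enumerate(mito_idx):
        gene_ids[g] = f"mt-Gene{j:03d}"

    # base relative expression: heavy-tailed, normalised to the mean library;
    # the mitochondrial block is rescaled to a fixed share of expression so
    # per-cell mito fractions concentrate near the nominal gene fraction
    weights = rng.lognormal(mean=0.0, sigma=1.5, size=cfg.n_genes)
    # planted signature genes are at least median-expressed: real curated
    # markers are detectable, not drawn from the low-expression tail
    signature = np.concatenate([*marker_idx.values(), shared_idx]).astype(int)
    weights[signature] = np.maximum(weights[signature], np.median(weights))
    weights /= weights.sum()
    if n_mito:
        mito_share = weights[mito_idx].sum()
        if mito_share > 0:
            weights[mito_idx] *= cfg.mito_gene_fraction / mito_share
            weights /= weights.sum()
    base_mu = weights * cfg.library_size_mean

    # per-class fold matrix (genes x classes), markers boosted in their class
    fold = np.ones((cfg.n_genes, n_classes))
    for ci, cls in enumerate(cfg.class_names):
        fold[marker_idx[cls], ci] = cfg.marker_fold
        if cls in ("TM1", "TM2"):
            fold[shared_idx, ci] = cfg.marker_fold

    # log-normal library-size variation, unit mean
    lib = rng.lognormal(mean=-0.5 * cfg.library_size_sigma**2, sigma=cfg.library_size_sigma, size=n_cells)

    class_of_cell = np.repeat(np.arange(n_classes), cfg.n_cells_per_class)
    mu = base_mu[:, None] * fold[:, class_of_cell] * lib[None, :]

    theta = cfg.nb_dispersion
    p = theta / (theta + mu)
    counts = rng.negative_binomial(theta, p).astype(np.int64)

    cell_ids = pd.Index([f"cell{i:05d}" for i in range(n_cells)])
    mito_flags = np.zeros(cfg.n_genes, dtype=bool)
    mito_flags[mito_idx] = True
    meta = pd.DataFrame(
        {"cell_class": labels, "genotype": "WT", "strain": "B6"}, index=cell_ids
    )
    cm = CountMatrix(
        counts=counts,
        gene_ids=pd.Index(gene_ids),
        cell_ids=cell_ids,
        cell_meta=meta,
        mito_flags=mito_flags,
    )
    truth = {
        "labels": pd.Series(labels, index=cell_ids, name="cell_class"),
        "markers": {tm: [gene_ids[g] for g in marker_idx[tm]] for tm in TM_SUBTYPES},
        "class_markers": {cls: [gene_ids[g] for g in idx] for cls, idx in marker_idx.items()},
        "shared_tm12_markers": [gene_ids[g] for g in shared_idx],
        "mito_genes": [gene_ids[g] for g in mito_idx],
    }
    return cm, truth


# ---------------------------------------------------------------------------
# multiome companion
# ---------------------------------------------------------------------------


@dataclass
class MultiomeSimConfig:
    """Configuration for the accessibility + TF-expression companion.

    Each motif ``M###`` belongs to exactly one TF ``TF###``.  For a planted
    activator, a per-cell latent activity raises both the TF's expression
    and the accessibility of the motif's member peaks (lowers accessibility
    for a repressor); all other TFs are independent of their motifs.  The
    latent activity of each planted TF carries a subtype shift so planted
    motifs are also subtype-biased, as marker-peak programmes are in tissue.
    """

    n_peaks: int = 2000
    n_motifs: int = 150
    n_member_peaks: int = 40
    planted_activators: tuple[str, ...] = ()
    planted_repressors: tuple[str, ...] = ()
    coupling_strength: float = 1.0
    subtype_shift: float = 1.0
    peak_depth_mean: float = 5000.0
    tf_base_expr: float = 3.0
    rna_total_mean: float = 10000.0
    seed: int = 0

    def validate(self) -> None:
        if min(self.n_peaks, self.n_motifs) < 1:
            raise ValueError("n_peaks and n_motifs must be >= 1")
        if self.n_member_peaks < 1:
            raise ValueError("every motif needs at least one member peak")
        if self.n_member_peaks > self.n_peaks:
            raise ValueError("n_member_peaks exceeds n_peaks")
        if set(self.planted_activators) & set(self.planted_repressors):
            raise ValueError("activator and repressor sets must be disjoint")
        tfs = {f"TF{i:03d}" for i in range(self.n_motifs)}
        unknown = (set(self.planted_activators) | set(self.planted_repressors)) - tfs
        if unknown:
            raise ValueError(f"planted TFs not in the motif panel: {sorted(unknown)}")


def generate_multiome(
    cfg: MultiomeSimConfig, labels: pd.Series
) -> tuple[MotifAccessibilityBundle, pd.DataFrame, np.ndarray, dict]:
    """Simulate accessibility counts plus coupled TF expression.

    Parameters
    ----------
    cfg
        Generator configuration.
    labels
        Per-cell class labels (index = cell ids), e.g. the truth labels of
        :func:`generate_count_matrix`.

    Returns
    -------
    bundle, tf_expr, rna_totals, truth
        ``tf_expr`` is a TF x cell integer count frame; ``rna_totals`` the
        per-cell total RNA counts used for counts-per-10k normalisation.
    """
    cfg.validate()
    rng = substream(cfg.seed, "multiome")
    cell_ids = pd.Index(labels.index)
    n_cells = len(cell_ids)
    classes = labels.to_numpy()

    tf_ids = [f"TF{i:03d}" for i in range(cfg.n_motifs)]
    motif_ids = [f"M{i:03d}" for i in range(cfg.n_motifs)]
    tf_to_motif = dict(zip(tf_ids, motif_ids))

    membership = np.zeros((cfg.n_motifs, cfg.n_peaks), dtype=bool)
    for m in range(cfg.n_motifs):
        members = rng.choice(cfg.n_peaks, size=cfg.n_member_peaks, replace=False)
        membership[m, members] = True

    peak_w = rng.lognormal(0.0, 1.0, size=cfg.n_peaks)
    peak_w /= peak_w.sum()
    depth = rng.lognormal(np.log(cfg.peak_depth_mean), 0.2, size=n_cells)

    # latent activity per planted TF: standard normal plus a subtype shift
    planted = list(cfg.planted_activators) + list(cfg.planted_repressors)
    subtypes_cycle = [s for s in TM_SUBTYPES if s in set(classes)] or [classes[0]]
    latent: dict[str, np.ndarray] = {}
    planted_subtype: dict[str, str] = {}
    for i, tf in enumerate(planted):
        sub = subtypes_cycle[i % len(subtypes_cycle)]
        planted_subtype[tf] = sub
        latent[tf] = rng.normal(0.0, 1.0, size=n_cells) + cfg.subtype_shift * (classes == sub)

    log_factor = np.zeros((cfg.n_peaks, n_cells))
    for tf in cfg.planted_activators:
        m = motif_ids.index(tf_to_motif[tf])
        log_factor[membership[m]] += cfg.coupling_strength * latent[tf]
    for tf in cfg.planted_repressors:
        m = motif_ids.index(tf_to_motif[tf])
        log_factor[membership[m]] -= cfg.coupling_strength * latent[tf]

    peak_mu = depth[None, :] * peak_w[:, None] * np.exp(log_factor)
    peak_counts = rng.poisson(peak_mu).astype(np.int64)

    tf_mu = np.full((cfg.n_motifs, n_cells), cfg.tf_base_expr)
    for tf in planted:
        tf_mu[tf_ids.index(tf)] *= np.exp(cfg.coupling_strength * latent[tf])
    tf_counts = rng.poisson(tf_mu).astype(np.int64)
    rna_totals = rng.poisson(
        np.maximum(cfg.rna_total_mean + tf_counts.sum(axis=0), 1.0)
    ).astype(np.int64)

    starts = np.arange(cfg.n_peaks) * 1000
    peaks = pd.DataFrame(
        {"chrom": "chr1", "start": starts, "end": starts + 500},
        index=[f"peak{i:05d}" for i in range(cfg.n_peaks)],
    )
    bundle = MotifAccessibilityBundle(
        peak_counts=peak_counts,
        peaks=peaks,
        motif_membership=membership,
        motif_ids=pd.Index(motif_ids),
        cell_ids=cell_ids,
        tf_to_motif=tf_to_motif,
    )
    tf_expr = pd.DataFrame(tf_counts, index=tf_ids, columns=cell_ids)
    truth = {
        "activators": list(cfg.planted_activators),
        "repressors": list(cfg.planted_repressors),
        "planted_subtype": planted_subtype,
    }
    return bundle, tf_expr, rna_totals, truth


# ---------------------------------------------------------------------------
# tissue sections
# ---------------------------------------------------------------------------


@dataclass
class SectionSimConfig:
    """Configuration for wedge-shaped TM sections with biased stain blobs.

    ``zone_bias`` maps zone ids to non-negative relative densities; the zone
    scheme is inferred from the keys (``anterior``/``posterior``,
    ``inner``/``outer``, or the eight-zone ids).  AP length and IO depth are
    drawn uniformly from the stated ranges (um).
    """

    n_sections: int = 50
    ap_length_range: tuple[float, float] = (125.0, 200.0)
    io_depth_range: tuple[float, float] = (15.0, 30.0)
    zone_bias: dict = field(default_factory=lambda: {"anterior": 1.0, "posterior": 1.0})
    stain_blob_count: int = 40
    stain_blob_radius: float = 2.5
    edge_jitter: float = 0.06
    seed: int = 0

    def validate(self) -> None:
        if self.n_sections < 1 or self.stain_blob_count < 1:
            raise ValueError("n_sections and stain_blob_count must be >= 1")
        lo, hi = self.ap_length_range
        if not (0 < lo <= hi):
            raise ValueError("ap_length_range must be within (0, inf) and ordered")
        lo, hi = self.io_depth_range
        if not (0 < lo <= hi):
            raise ValueError("io_depth_range must be within (0, inf) and ordered")
        w = list(self.zone_bias.values())
        if any(x < 0 for x in w) or not any(x > 0 for x in w):
            raise ValueError("zone_bias weights must be >= 0 and not all zero")


def _disc_polygon(cx: float, cy: float, r: float, n: int = 16) -> Polygon:
    ang = np.linspace(0.0, 2.0 * np.pi, n, endpoint=False)
    return Polygon(np.c_[cx + r * np.cos(ang), cy + r * np.sin(ang)])


def _wedge_polygon(rng: np.random.Generator, length: float, depth: float, jitter: float) -> Polygon:
    """Rectangle-with-jitter: flat inner edge at depth 0, jittered outer edge."""
    n_edge = 8
    xs = np.linspace(0.0, length, n_edge)
    top = depth * (1.0 + rng.uniform(-jitter, jitter, size=n_edge))
    # keep the outer edge flat across the AP midpoint so the IO depth there
    # is exactly the drawn depth and the inclusion gate behaves predictably
    top[n_edge // 2 - 1 : n_edge // 2 + 1] = depth
    bottom = [(x, 0.0) for x in xs]
    upper = [(x, t) for x, t in zip(xs[::-1], top[::-1])]
    return Polygon(bottom + upper)


def _zones_for_bias(sec: SectionGeometry, bias: dict) -> dict[str, Polygon]:
    keys = set(bias)
    if keys <= {"anterior", "posterior"}:
        return partition_halves(sec, "AP")
    if keys <= {"inner", "outer"}:
        return partition_halves(sec, "IO")
    return partition_eight_zones(sec)


def generate_sections(
    cfg: SectionSimConfig, subtype: str, marker: str | None = None
) -> list[tuple[SectionGeometry, MarkerMask]]:
    """Simulate sections with stain blobs placed according to ``zone_bias``.

    Blob centroids are drawn by rejection sampling: a uniform point in the
    TM polygon is accepted with probability proportional to the bias of the
    zone containing it.
    """
    cfg.validate()
    rng = substream(cfg.seed, "sections")
    marker = marker or f"{subtype}-marker"
    w_max = max(cfg.zone_bias.values())
    out: list[tuple[SectionGeometry, MarkerMask]] = []
    for i in range(cfg.n_sections):
        length = rng.uniform(*cfg.ap_length_range)
        depth = rng.uniform(*cfg.io_depth_range)
        sec = SectionGeometry(_wedge_polygon(rng, length, depth, cfg.edge_jitter), section_id=f"sec{i:03d}")
        zones = _zones_for_bias(sec, cfg.zone_bias)
        minx, miny, maxx, maxy = sec.tm_polygon.bounds
        blobs: list[Polygon] = []
        guard = 0
        while len(blobs) < cfg.stain_blob_count:
            guard += 1
            if guard > 200000:
                raise RuntimeError("blob placement failed to converge")
            p = Point(rng.uniform(minx, maxx), rng.uniform(miny, maxy))
            if not sec.tm_polygon.contains(p):
                continue
            zid = next((z for z, poly in zones.items() if poly.intersects(p)), None)
            if zid is None:
                continue
            if rng.uniform() > cfg.zone_bias.get(zid, 0.0) / w_max:
                continue
            blob = _disc_polygon(p.x, p.y, cfg.stain_blob_radius).intersection(sec.tm_polygon)
            if blob.is_empty:
                continue
            pieces = [blob] if isinstance(blob, Polygon) else list(blob.geoms)
            blobs.extend(g for g in pieces if isinstance(g, Polygon) and g.area > 0)
        out.append((sec, MarkerMask(marker=marker, subtype=subtype, polygons=blobs)))
    return out


# ---------------------------------------------------------------------------
# mitochondria and nuclei
# ---------------------------------------------------------------------------

_WT_AREA_MEDIAN = 0.35      # um^2, typical TM mitochondrion cross-section
_WT_AREA_SIGMA = 0.30       # lognormal sigma of outer area
_WT_CRISTAE_MEAN = 0.40     # WT cristae fraction
_WT_CRISTAE_SD = 0.06


def _blob_polygon(rng: np.random.Generator, area: float, n: int = 24) -> list[tuple[float, float]]:
    """Jittered-ellipse contour with the requested area (star-shaped, simple, CCW)."""
    aspect = rng.uniform(1.0, 1.8)
    theta = rng.uniform(0, np.pi)
    r0 = math.sqrt(area / (np.pi * aspect))
    a, b = r0 * aspect, r0
    ang = np.linspace(0, 2 * np.pi, n, endpoint=False)
    rad = 1.0 + rng.uniform(-0.03, 0.03, size=n)
    x = a * rad * np.cos(ang)
    y = b * rad * np.sin(ang)
    ct, st = math.cos(theta), math.sin(theta)
    pts = [(float(ct * xi - st * yi), float(st * xi + ct * yi)) for xi, yi in zip(x, y)]
    scale = math.sqrt(area / polygon_area(pts))
    return [(px * scale, py * scale) for px, py in pts]


def _pack_cristae(
    rng: np.random.Generator, outer: list[tuple[float, float]], fraction: float
) -> list[list[tuple[float, float]]]:
    """Disjoint 16-gon discs inside ``outer`` summing to the target fraction.

    Discs sit on a jittered square grid whose pitch is chosen so that the
    per-cell disc coverage slightly exceeds the target (discs lost at the
    boundary account for the slack); the jitter amplitude keeps neighbouring
    discs disjoint by construction and the final disc is shrunk so the
    summed area hits the target exactly.
    """
    if fraction <= 0:
        return []
    poly = Polygon(outer)
    area = poly.area
    target = fraction * area
    pitch = math.sqrt(area) / 6.0
    for _ in range(8):  # refine the grid if boundary losses starve the packing
        cover = min(fraction * 1.3 + 0.02, 0.70)
        r = pitch * math.sqrt(cover / math.pi)
        r = min(r, 0.47 * pitch)
        inner = poly.buffer(-r * 1.02)
        if inner.is_empty:
            pitch *= 0.8
            continue
        minx, miny, maxx, maxy = poly.bounds
        xs = np.arange(minx + pitch / 2, maxx, pitch)
        ys = np.arange(miny + pitch / 2, maxy, pitch)
        centers = [(x, y) for x in xs for y in ys]
        rng.shuffle(centers)
        jmax = 0.9 * (pitch / 2 - r)
        cristae: list[Polygon] = []
        acc = 0.0
        for cx, cy in centers:
            jx, jy = rng.uniform(-jmax, jmax, size=2)
            c = Point(cx + jx, cy + jy)
            if not inner.contains(c):
                continue
            radius = r
            remaining = target - acc
            if math.pi * radius**2 > remaining:
                radius = math.sqrt(remaining / math.pi)
                if radius < 1e-4:
                    break
            disc = _disc_polygon(c.x, c.y, radius)
            cristae.append(disc)
            acc += disc.area
            if acc >= target * 0.999:
                break
        if acc >= target * 0.95:
            return [list(cr.exterior.coords)[:-1] for cr in cristae]
        pitch *= 0.8
    return [list(cr.exterior.coords)[:-1] for cr in cristae]


def generate_mitochondria(
    n_per_genotype: int,
    effect: dict | None = None,
    seed: int = 0,
    per_cell: int = 3,
) -> dict[str, list[MitochondrionTrace]]:
    """Traced mitochondria for WT and mutant genotypes.

    ``effect`` carries ``area_fold`` (mutant outer area multiplier) and
    ``cristae_fraction_shift`` (additive shift of the mutant cristae
    fraction).  A shift that pushes the mean fraction outside [0, 1] is a
    configuration error.
    """
    effect = dict(effect or {})
    area_fold = float(effect.get("area_fold", 1.0))
    shift = float(effect.get("cristae_fraction_shift", 0.0))
    if not (math.isfinite(area_fold) and math.isfinite(shift)):
        raise ValueError("effect values must be finite")
    if area_fold <= 0:
        raise ValueError("area_fold must be positive")
    if not 0.0 <= _WT_CRISTAE_MEAN + shift <= 1.0:
        raise ValueError("cristae_fraction_shift pushes the mean fraction outside [0, 1]")
    rng = substream(seed, "mitochondria")
    out: dict[str, list[MitochondrionTrace]] = {}
    for genotype, fold, fshift in (("WT", 1.0, 0.0), ("MUT", area_fold, shift)):
        traces = []
        for i in range(n_per_genotype):
            area = fold * rng.lognormal(math.log(_WT_AREA_MEDIAN), _WT_AREA_SIGMA)
            frac = float(np.clip(rng.normal(_WT_CRISTAE_MEAN + fshift, _WT_CRISTAE_SD), 0.02, 0.95))
            outer = _blob_polygon(rng, area)
            cristae = _pack_cristae(rng, outer, frac)
            traces.append(
                MitochondrionTrace(
                    cell_id=f"{genotype}_cell{i // per_cell:03d}",
                    outer=outer,
                    cristae=cristae,
                    genotype=genotype,
                )
            )
        out[genotype] = traces
    return out


_THOMSEN_P = 1.6075


def _ellipsoid_surface_area(a: float, b: float, c: float) -> float:
    """Thomsen's approximation (relative error < 1.1%)."""
    p = _THOMSEN_P
    term = ((a * b) ** p + (a * c) ** p + (b * c) ** p) / 3.0
    return 4.0 * math.pi * term ** (1.0 / p)


def generate_nuclei(
    n_per_subtype: dict[str, int],
    elongation: dict[str, float] | None = None,
    seed: int = 0,
) -> list[NucleusShape]:
    """Ellipsoidal nuclei with subtype-dependent elongation.

    Default elongation ratios give TM1 nearly spherical nuclei and TM2/TM3
    elongated, endothelial-like ones.
    """
    elongation = elongation or {"TM1": 1.2, "TM2": 2.5, "TM3": 2.8}
    rng = substream(seed, "nuclei")
    shapes: list[NucleusShape] = []
    for subtype in sorted(n_per_subtype):
        e0 = elongation.get(subtype, 1.5)
        for _ in range(n_per_subtype[subtype]):
            r = rng.lognormal(math.log(2.5), 0.1)
            e = max(1.0, rng.normal(e0, 0.15))
            a = b = r
            c = e * r
            vol = 4.0 / 3.0 * math.pi * a * b * c
            shapes.append(
                NucleusShape(volume=vol, surface_area=_ellipsoid_surface_area(a, b, c), subtype=subtype)
            )
    return shapes
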