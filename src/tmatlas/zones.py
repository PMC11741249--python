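"""Zonal partition of trabecular-meshwork sections and occupancy statistics.

Each sagittal section is represented in a rectified local frame: the first
coordinate runs anterior -> posterior along the TM (AP axis, um), the second
runs inner -> outer (IO axis, um) with the inner (anterior-chamber-facing)
edge toward depth 0.  The TM itself is a simple polygon in this frame and a
marker stain is a collection of positive polygons clipped to it.

Two partition schemes are provided: halves along either axis, and the
eight-zone scheme in which the TM is cut into three equal-length AP sectors
(anterior, central, posterior), the central and posterior sectors are split
into three equal-depth bands (inner / intermediate / outer) using each
sector's average depth, and the thinner anterior sector into two bands.

Occupancy is expressed per section as the percent of that section's total
marker area falling in each zone, which normalises away the very different
absolute staining levels of different markers.  Halves are compared with
Student's t-test, zones with one-way ANOVA followed by Tukey's HSD.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from shapely.geometry import LineString, MultiPolygon, Polygon, box
from shapely.ops import unary_union

__all__ = [
    "SectionGeometry",
    "MarkerMask",
    "EIGHT_ZONE_IDS",
    "partition_halves",
    "partition_eight_zones",
    "marker_zone_occupancy",
    "section_passes_inclusion",
    "compare_halves",
    "anova_tukey",
]

EIGHT_ZONE_IDS = ("A-in", "A-out", "C-in", "C-mid", "C-out", "P-in", "P-mid", "P-out")

_BIG = 1e6  # clipping boxes extend far beyond any realistic section


@dataclass
class SectionGeometry:
    """A TM wedge in the rectified local frame (um).

    ``tm_polygon`` vertices are (AP, IO) coordinates; anterior is at the
    minimum of the AP axis and the inner edge lies toward IO = 0.
    """

    tm_polygon: Polygon
    section_id: str = ""

    def __post_init__(self) -> None:
        if not isinstance(self.tm_polygon, Polygon):
            self.tm_polygon = Polygon(self.tm_polygon)
        if not self.tm_polygon.is_valid or not self.tm_polygon.is_simple:
            raise ValueError("TM polygon must be simple and valid")
        if self.tm_polygon.area <= 0:
            raise ValueError("TM polygon must have positive area")

    @property
    def ap_bounds(self) -> tuple[float, float]:
        x0, _, x1, _ = self.tm_polygon.bounds
        return float(x0), float(x1)

    @property
    def ap_length(self) -> float:
        x0, x1 = self.ap_bounds
        return x1 - x0

    def io_depth_at(self, s: float) -> float:
        """Total IO extent of the section at AP position ``s``."""
        cut = LineString([(s, -_BIG), (s, _BIG)])
        seg = self.tm_polygon.intersection(cut)
        return float(seg.length)


@dataclass
class MarkerMask:
    """Marker-positive polygons for one stain on one section."""

    marker: str
    subtype: str
    polygons: list[Polygon] = field(default_factory=list)

    def union(self) -> Polygon | MultiPolygon:
        if not self.polygons:
            return Polygon()
        return unary_union(self.polygons)

    def clipped_to(self, sec: SectionGeometry):
        return self.union().intersection(sec.tm_polygon)


def _clip_band(poly: Polygon, x0=None, x1=None, y0=None, y1=None):
    b = box(
        -_BIG if x0 is None else x0,
        -_BIG if y0 is None else y0,
        _BIG if x1 is None else x1,
        _BIG if y1 is None else y1,
    )
    return poly.intersection(b)


def partition_halves(sec: SectionGeometry, axis: str) -> dict[str, Polygon]:
    """Split the TM into two halves along the AP or IO axis.

    The AP cut is at half the anterior-posterior length; the IO cut is at
    half the IO depth measured at the AP midpoint, parallel to the AP axis.
    """
    poly = sec.tm_polygon
    x0, x1 = sec.ap_bounds
    if axis == "AP":
        mid = 0.5 * (x0 + x1)
        zones = {
            "anterior": _clip_band(poly, x1=mid),
            "posterior": _clip_band(poly, x0=mid),
        }
    elif axis == "IO":
        midpoint = 0.5 * (x0 + x1)
        depth = sec.io_depth_at(midpoint)
        if depth <= 0:
            raise ValueError("zero IO depth at the AP midpoint")
        _, y0, _, _ = poly.bounds
        cut = y0 + 0.5 * depth
        zones = {
            "inner": _clip_band(poly, y1=cut),
            "outer": _clip_band(poly, y0=cut),
        }
    else:
        raise ValueError("axis must be 'AP' or 'IO'")
    for name, z in zones.items():
        if z.area <= 0:
            raise ValueError(f"degenerate cut: zone '{name}' is empty")
    return zones


def _depth_bands(sector: Polygon, n_bands: int, prefix: str) -> dict[str, Polygon]:
    """Split a sector into equal-depth bands using its average depth."""
    x0, y0, x1, _ = sector.bounds
    length = x1 - x0
    if length <= 0 or sector.area <= 0:
        raise ValueError(f"sector '{prefix}' has zero extent")
    avg_depth = sector.area / length
    if avg_depth <= 0:
        raise ValueError(f"sector '{prefix}' has zero depth")
    step = avg_depth / n_bands
    names = {2: ["in", "out"], 3: ["in", "mid", "out"]}[n_bands]
    bands: dict[str, Polygon] = {}
    for i, nm in enumerate(names):
        lo = y0 + i * step
        hi = None if i == n_bands - 1 else y0 + (i + 1) * step
        bands[f"{prefix}-{nm}"] = _clip_band(sector, y0=lo, y1=hi)
    return bands


def partition_eight_zones(sec: SectionGeometry) -> dict[str, Polygon]:
    """Eight-zone scheme: 3 equal AP sectors, banded by sector average depth."""
    poly = sec.tm_polygon
    x0, x1 = sec.ap_bounds
    third = (x1 - x0) / 3.0
    sectors = {
        "A": _clip_band(poly, x1=x0 + third),
        "C": _clip_band(poly, x0=x0 + third, x1=x0 + 2 * third),
        "P": _clip_band(poly, x0=x0 + 2 * third),
    }
    zones: dict[str, Polygon] = {}
    zones.update(_depth_bands(sectors["A"], 2, "A"))
    zones.update(_depth_bands(sectors["C"], 3, "C"))
    zones.update(_depth_bands(sectors["P"], 3, "P"))
    return {zid: zones[zid] for zid in EIGHT_ZONE_IDS}


def marker_zone_occupancy(
    sec: SectionGeometry, mask: MarkerMask, zones: dict[str, Polygon], scheme: str = ""
) -> pd.DataFrame | None:
    """Percent of the section's marker area in each zone.

    Returns None when the marker area is zero (the section is excluded for
    that marker rather than zero-filled).
    """
    stained = mask.clipped_to(sec)
    total = stained.area
    if total <= 0:
        return None
    rows = []
    for zid, zone in zones.items():
        pct = 100.0 * stained.intersection(zone).area / total
        rows.append(
            {
                "section": sec.section_id,
                "marker": mask.marker,
                "subtype": mask.subtype,
                "scheme": scheme,
                "zone": zid,
                "percent": pct,
            }
        )
    return pd.DataFrame(rows)


def section_passes_inclusion(
    sec: SectionGeometry,
    ap_range: tuple[float, float] = (125.0, 200.0),
    io_range: tuple[float, float] = (15.0, 30.0),
) -> bool:
    """Quality gate: AP length and midpoint IO depth inside the stated ranges.

    Bounds are inclusive.
    """
    ap = sec.ap_length
    x0, x1 = sec.ap_bounds
    io = sec.io_depth_at(0.5 * (x0 + x1))
    return (ap_range[0] <= ap <= ap_range[1]) and (io_range[0] <= io <= io_range[1])


def compare_halves(values_a, values_b) -> dict:
    """Two-sample pooled Student's t (two-sided) on per-section percentages."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least 2 sections per group")
    if np.ptp(a) == 0 and np.ptp(b) == 0:
        if a[0] == b[0]:
            return {"t": 0.0, "p": 1.0, "mean_a": float(a.mean()), "mean_b": float(b.mean())}
        raise ValueError("zero pooled variance with unequal means")
    t, p = stats.ttest_ind(a, b, equal_var=True)
    return {"t": float(t), "p": float(p), "mean_a": float(a.mean()), "mean_b": float(b.mean())}


def anova_tukey(groups: dict[str, list[float]]) -> dict:
    """One-way ANOVA with Tukey HSD pairwise comparisons.

    Returns ``{"F", "p", "pairwise": {(g1, g2): p_adj}}``.
    """
    names = sorted(groups)
    if len(names) < 2:
        raise ValueError("need at least 2 groups")
    arrays = []
    for n in names:
        a = np.asarray(groups[n], dtype=float)
        if len(a) < 2:
            raise ValueError(f"group '{n}' needs at least 2 values")
        arrays.append(a)
    if all(np.ptp(a) == 0 for a in arrays) and len({a[0] for a in arrays}) == 1:
        pairwise = {(names[i], names[j]): 1.0 for i in range(len(names)) for j in range(i + 1, len(names))}
        return {"F": 0.0, "p": 1.0, "pairwise": pairwise}
    f, p = stats.f_oneway(*arrays)
    hsd = stats.tukey_hsd(*arrays)
    pairwise = {}
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            pairwise[(names[i], names[j])] = float(hsd.pvalue[i, j])
    return {"F": float(f), "p": float(p), "pairwise": pairwise}
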