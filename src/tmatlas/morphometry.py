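"""Mitochondrial and nuclear morphometry.

Electron-microscopy tracing of a mitochondrion yields its outer-membrane
contour and the contours of its cristae (inner-membrane folds); from these we
compute cross-sectional area, the cristae fraction (cristae area over total
mitochondrial area), and mitochondrial density normalised to 100 um^2 of
perinuclear cytoplasm.  Nuclear shape is summarised by sphericity,
``psi = pi^(1/3) (6 V)^(2/3) / A``, which is 1 for a sphere and falls below 1
as the nucleus elongates.  Genotype comparisons use the two-sample pooled
Student's t-test with the mitochondrion (or nucleus) as the replication unit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from shapely.geometry import Polygon

__all__ = [
    "MitochondrionTrace",
    "NucleusShape",
    "polygon_area",
    "cristae_fraction",
    "mito_density",
    "sphericity",
    "compare_genotypes",
    "sample_mitochondria_per_cell",
]


@dataclass
class MitochondrionTrace:
    """Traced mitochondrion: outer contour plus cristae contours, in um.

    Cristae polygons must be simple, pairwise non-overlapping and contained
    in the outer polygon; overlap is rejected rather than merged so that
    cristae area stays additive.
    """

    cell_id: str
    outer: list[tuple[float, float]]
    cristae: list[list[tuple[float, float]]] = field(default_factory=list)
    genotype: str = "WT"

    def validate(self) -> None:
        out = _as_polygon(self.outer)
        shapes = [_as_polygon(c) for c in self.cristae]
        for i, c in enumerate(shapes):
            if not out.buffer(1e-9).contains(c):
                raise ValueError(f"crista {i} not contained in outer membrane")
        for i in range(len(shapes)):
            for j in range(i + 1, len(shapes)):
                if shapes[i].intersection(shapes[j]).area > 1e-12:
                    raise ValueError(f"cristae {i} and {j} overlap")


@dataclass
class NucleusShape:
    """Nucleus summarised by volume (um^3) and surface area (um^2)."""

    volume: float
    surface_area: float
    subtype: str = ""

    def __post_init__(self) -> None:
        if self.volume <= 0 or self.surface_area <= 0:
            raise ValueError("volume and surface area must be positive")


def _as_polygon(vertices) -> Polygon:
    poly = Polygon(vertices)
    if len(poly.exterior.coords) < 4:  # closed ring: 3 vertices + repeat
        raise ValueError("polygon needs at least 3 vertices")
    if not poly.is_simple or not poly.is_valid:
        raise ValueError("polygon is self-intersecting or degenerate")
    return poly


def polygon_area(vertices) -> float:
    """Area of a simple polygon by the shoelace formula (absolute value)."""
    _as_polygon(vertices)  # raises on self-intersection
    v = np.asarray(vertices, dtype=float)
    x, y = v[:, 0], v[:, 1]
    return float(abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1))) / 2.0)


def cristae_fraction(trace: MitochondrionTrace) -> float:
    """Summed cristae area divided by outer-membrane area, in [0, 1]."""
    trace.validate()
    outer_area = polygon_area(trace.outer)
    if outer_area <= 0:
        raise ValueError("outer polygon has zero area")
    total = sum(polygon_area(c) for c in trace.cristae)
    return float(total / outer_area)


def mito_density(n_mito: int, region_area: float) -> float:
    """Mitochondria per 100 um^2 of region area.

    Per-cell densities are averaged across cells downstream (mean of
    per-cell ratios, not a pooled ratio).
    """
    if region_area <= 0:
        raise ValueError("region area must be positive")
    return 100.0 * n_mito / region_area


def sphericity(shape: NucleusShape) -> float:
    """psi = pi^(1/3) (6V)^(2/3) / A; 1 for a sphere, < 1 otherwise."""
    v, a = shape.volume, shape.surface_area
    return float(np.pi ** (1.0 / 3.0) * (6.0 * v) ** (2.0 / 3.0) / a)


def compare_genotypes(values_a, values_b) -> dict:
    """Pooled-variance two-sided Student's t-test with group means +/- SE."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least 2 values per genotype")
    if np.ptp(a) == 0 and np.ptp(b) == 0:
        if a[0] == b[0]:
            return {
                "t": 0.0, "p": 1.0,
                "mean_a": float(a.mean()), "se_a": 0.0,
                "mean_b": float(b.mean()), "se_b": 0.0,
            }
        raise ValueError("zero within-group variance")
    t, p = stats.ttest_ind(a, b, equal_var=True)
    return {
        "t": float(t),
        "p": float(p),
        "mean_a": float(a.mean()),
        "se_a": float(a.std(ddof=1) / np.sqrt(len(a))),
        "mean_b": float(b.mean()),
        "se_b": float(b.std(ddof=1) / np.sqrt(len(b))),
    }


def sample_mitochondria_per_cell(
    traces: list[MitochondrionTrace], max_per_cell: int = 3, seed: int = 0
) -> list[MitochondrionTrace]:
    """Randomly keep up to ``max_per_cell`` traces per cell, deterministically.

    Mirrors the EM sampling design in which up to 3 (typically 2-3)
    perinuclear mitochondria are analysed per cell.
    """
    rng = np.random.default_rng(seed)
    by_cell: dict[str, list[MitochondrionTrace]] = {}
    for t in traces:
        by_cell.setdefault(t.cell_id, []).append(t)
    kept: list[MitochondrionTrace] = []
    for cell in sorted(by_cell):
        group = by_cell[cell]
        if len(group) <= max_per_cell:
            kept.extend(group)
        else:
            idx = rng.choice(len(group), size=max_per_cell, replace=False)
            kept.extend(group[i] for i in sorted(idx))
    return kept
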