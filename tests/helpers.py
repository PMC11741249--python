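"""Independent oracles used by the tests.

Everything here is deliberately written from first principles (pair
counting, exhaustive enumeration, rasterisation) so that it shares no code
path with the implementation it checks.
"""

from __future__ import annotations

import math
from itertools import combinations

import numpy as np
import shapely


def brute_force_ari(a, b) -> float:
    """Adjusted Rand index by exhaustive iteration over all element pairs."""
    a = list(a)
    b = list(b)
    n = len(a)
    both = a_only = b_only = neither = 0
    for i, j in combinations(range(n), 2):
        sa = a[i] == a[j]
        sb = b[i] == b[j]
        if sa and sb:
            both += 1
        elif sa:
            a_only += 1
        elif sb:
            b_only += 1
        else:
            neither += 1
    total = both + a_only + b_only + neither
    sum_a = both + a_only
    sum_b = both + b_only
    expected = sum_a * sum_b / total
    max_index = 0.5 * (sum_a + sum_b)
    if max_index == expected:
        return 1.0 if both == max_index else 0.0
    return (both - expected) / (max_index - expected)


def hypergeom_upper_tail(k: int, n_universe: int, n_set: int, n_query: int) -> float:
    """P(overlap >= k) by direct summation of the hypergeometric pmf."""
    total = 0.0
    for x in range(k, min(n_set, n_query) + 1):
        total += (
            math.comb(n_set, x)
            * math.comb(n_universe - n_set, n_query - x)
            / math.comb(n_universe, n_query)
        )
    return min(total, 1.0)


def brute_force_es(genes_in_order, stats_in_order, members, weight=1.0) -> float:
    """GSEA enrichment score by explicit step-by-step running sum."""
    hits = [g in members for g in genes_in_order]
    n_hit = sum(hits)
    n_miss = len(genes_in_order) - n_hit
    hit_total = sum(abs(s) ** weight for g, s in zip(genes_in_order, stats_in_order) if g in members)
    running = 0.0
    best = 0.0
    for g, s, h in zip(genes_in_order, stats_in_order, hits):
        if h:
            running += (abs(s) ** weight / hit_total) if hit_total > 0 else 1.0 / n_hit
        else:
            running -= 1.0 / n_miss
        if abs(running) > abs(best):
            best = running
    return best


def brute_force_ligand_rule(profile: dict, high=1.0, fold=4.0):
    """Direct, case-by-case evaluation of the ligand assignment prose."""
    subtypes = list(profile)
    # rule 1: some subtype above the high threshold and >= fold x all others
    for s in subtypes:
        if profile[s] > high and all(
            profile[s] >= fold * profile[o] for o in subtypes if o != s
        ):
            return "exclusive", (s,)
    high_set = [s for s in subtypes if profile[s] > high]
    if high_set:
        top = max(profile[s] for s in high_set)
        shared = tuple(sorted(s for s in high_set if top < fold * profile[s]))
        return "shared-high", shared
    expressed = tuple(sorted(s for s in subtypes if profile[s] > 0))
    if expressed:
        return "shared-low", expressed
    return "unassigned", ()


def raster_area(geometry, pixel: float = 0.1) -> float:
    """Polygon area by pixel counting on a regular grid."""
    if geometry.is_empty:
        return 0.0
    minx, miny, maxx, maxy = geometry.bounds
    xs = np.arange(minx + pixel / 2, maxx, pixel)
    ys = np.arange(miny + pixel / 2, maxy, pixel)
    if len(xs) == 0 or len(ys) == 0:
        return 0.0
    gx, gy = np.meshgrid(xs, ys)
    inside = shapely.contains_xy(geometry, gx.ravel(), gy.ravel())
    return float(inside.sum() * pixel * pixel)


def pooled_t(a, b):
    """Two-sample pooled-variance t statistic, textbook formula."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    na, nb = len(a), len(b)
    sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    return (a.mean() - b.mean()) / math.sqrt(sp2 * (1 / na + 1 / nb))
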