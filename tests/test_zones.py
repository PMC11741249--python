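"""Zone partitions, occupancy percentages, and the halves / zones statistics."""

import math

import numpy as np
import pytest
from helpers import pooled_t, raster_area
from scipy import stats as sps
from shapely.geometry import Polygon, box

from tmatlas.simulate import SectionSimConfig, generate_sections
from tmatlas.zones import (
    EIGHT_ZONE_IDS,
    MarkerMask,
    SectionGeometry,
    anova_tukey,
    compare_halves,
    marker_zone_occupancy,
    partition_eight_zones,
    partition_halves,
    section_passes_inclusion,
)


def _rect(length, depth):
    return SectionGeometry(box(0, 0, length, depth), section_id="r")


class TestHalves:
    def test_rectangle_ap_halves(self):
        zones = partition_halves(_rect(150, 20), "AP")
        assert zones["anterior"].area == pytest.approx(1500.0)
        assert zones["posterior"].area == pytest.approx(1500.0)

    def test_rectangle_io_halves(self):
        zones = partition_halves(_rect(150, 20), "IO")
        assert zones["inner"].area == pytest.approx(1500.0)
        assert zones["outer"].area == pytest.approx(1500.0)
        assert zones["inner"].bounds[3] == pytest.approx(10.0)

    def test_trapezoid_matches_rasterisation(self):
        trap = SectionGeometry(Polygon([(0, 0), (160, 0), (160, 30), (0, 15)]), "t")
        zones = partition_halves(trap, "AP")
        for z in zones.values():
            assert z.area == pytest.approx(raster_area(z, 0.1), rel=0.005)
        assert sum(z.area for z in zones.values()) == pytest.approx(trap.tm_polygon.area)

    def test_bad_axis(self):
        with pytest.raises(ValueError):
            partition_halves(_rect(100, 10), "XY")


class TestEightZones:
    def test_rectangle_band_layout(self):
        zones = partition_eight_zones(_rect(150, 21))
        assert set(zones) == set(EIGHT_ZONE_IDS)
        # central/posterior sectors split into three 7-um bands of 50-um length
        for zid in ("C-in", "C-mid", "C-out", "P-in", "P-mid", "P-out"):
            assert zones[zid].area == pytest.approx(50 * 7.0)
        # the thinner anterior sector has two 10.5-um bands
        for zid in ("A-in", "A-out"):
            assert zones[zid].area == pytest.approx(50 * 10.5)

    def test_partition_conserves_area_on_random_sections(self):
        cfg = SectionSimConfig(n_sections=20, stain_blob_count=1, seed=1)
        for sec, _ in generate_sections(cfg, "TM1"):
            zones = partition_eight_zones(sec)
            total = sum(z.area for z in zones.values())
            assert abs(total - sec.tm_polygon.area) / sec.tm_polygon.area < 1e-9
            ids = list(zones)
            for i in range(len(ids)):
                for j in range(i + 1, len(ids)):
                    inter = zones[ids[i]].intersection(zones[ids[j]]).area
                    assert inter / sec.tm_polygon.area < 1e-9

    def test_zone_count_always_eight(self):
        assert len(partition_eight_zones(_rect(130, 18))) == 8


class TestOccupancy:
    def test_mask_inside_single_zone(self):
        sec = _rect(160, 24)
        zones = partition_eight_zones(sec)
        mask = MarkerMask("m", "TM1", [box(5, 1, 15, 5)])  # anterior-inner corner
        table = marker_zone_occupancy(sec, mask, zones, scheme="eight-zone")
        t = table.set_index("zone")["percent"]
        assert t["A-in"] == pytest.approx(100.0)
        assert t.drop("A-in").abs().max() < 1e-9

    def test_mask_equal_to_tm_tracks_zone_areas(self):
        sec = _rect(150, 21)
        zones = partition_eight_zones(sec)
        mask = MarkerMask("m", "TM1", [sec.tm_polygon])
        t = marker_zone_occupancy(sec, mask, zones, scheme="eight-zone").set_index("zone")["percent"]
        for zid, z in zones.items():
            assert t[zid] == pytest.approx(100.0 * z.area / sec.tm_polygon.area, abs=1e-9)

    def test_percentages_sum_to_hundred(self):
        cfg = SectionSimConfig(n_sections=5, stain_blob_count=30, seed=2)
        for sec, mask in generate_sections(cfg, "TM2"):
            t = marker_zone_occupancy(sec, mask, partition_eight_zones(sec), scheme="eight-zone")
            assert t["percent"].sum() == pytest.approx(100.0, abs=1e-6)

    def test_occupancy_matches_rasterisation(self):
        cfg = SectionSimConfig(n_sections=2, stain_blob_count=25, seed=3)
        for sec, mask in generate_sections(cfg, "TM3"):
            zones = partition_eight_zones(sec)
            t = marker_zone_occupancy(sec, mask, zones, scheme="eight-zone").set_index("zone")["percent"]
            stained = mask.clipped_to(sec)
            total_px = raster_area(stained, 0.1)
            for zid, z in zones.items():
                pct_px = 100.0 * raster_area(stained.intersection(z), 0.1) / total_px
                assert abs(t[zid] - pct_px) < 0.5

    def test_empty_marker_returns_none(self):
        sec = _rect(150, 20)
        assert marker_zone_occupancy(sec, MarkerMask("m", "TM1", []), partition_halves(sec, "AP")) is None

    def test_invariant_to_translation_and_scaling(self):
        sec = _rect(150, 20)
        mask = MarkerMask("m", "TM1", [box(10, 2, 30, 8), box(90, 5, 120, 15)])
        base = marker_zone_occupancy(sec, mask, partition_eight_zones(sec)).set_index("zone")["percent"]
        from shapely import affinity

        for xform in (
            lambda g: affinity.translate(g, 40.0, -7.0),
            lambda g: affinity.scale(g, 1.3, 1.3, origin=(0, 0)),
        ):
            sec2 = SectionGeometry(xform(sec.tm_polygon), "x")
            mask2 = MarkerMask("m", "TM1", [xform(p) for p in mask.polygons])
            moved = marker_zone_occupancy(sec2, mask2, partition_eight_zones(sec2)).set_index("zone")["percent"]
            assert np.allclose(base, moved, atol=1e-6)


class TestInclusionGate:
    @pytest.mark.parametrize(
        "ap,io,expected",
        [(150, 20, True), (210, 20, False), (125, 20, True), (200, 30, True), (150, 14.9, False)],
    )
    def test_gate(self, ap, io, expected):
        assert section_passes_inclusion(_rect(ap, io)) is expected


class TestStatistics:
    def test_identical_groups_null(self):
        res = compare_halves([50.0, 50.0, 50.0], [50.0, 50.0, 50.0])
        assert res["t"] == 0.0 and res["p"] == 1.0

    def test_three_vs_three_matches_hand_formula(self):
        a, b = [60.0, 66.0, 63.0], [40.0, 35.0, 42.0]
        res = compare_halves(a, b)
        t_hand = pooled_t(a, b)
        assert res["t"] == pytest.approx(t_hand, abs=1e-10)
        assert res["p"] == pytest.approx(2 * sps.t.sf(abs(t_hand), 4), abs=1e-10)

    def test_planted_anterior_bias_detected(self):
        cfg = SectionSimConfig(
            n_sections=25, stain_blob_count=40, zone_bias={"anterior": 4.0, "posterior": 1.0}, seed=4
        )
        ant, pos = [], []
        for sec, mask in generate_sections(cfg, "TM3"):
            t = marker_zone_occupancy(sec, mask, partition_halves(sec, "AP")).set_index("zone")["percent"]
            ant.append(t["anterior"])
            pos.append(t["posterior"])
        res = compare_halves(ant, pos)
        assert res["mean_a"] > res["mean_b"]
        assert res["p"] < 0.01

    def test_anova_identical_groups(self):
        res = anova_tukey({"a": [1.0, 1.0], "b": [1.0, 1.0], "c": [1.0, 1.0]})
        assert res["F"] == 0.0 and res["p"] == 1.0
        assert all(v == 1.0 for v in res["pairwise"].values())

    def test_anova_extreme_separation(self):
        rng = np.random.default_rng(5)
        groups = {
            "a": list(rng.normal(0, 1, 8)),
            "b": list(rng.normal(0, 1, 8)),
            "c": list(rng.normal(30, 1, 8)),
        }
        res = anova_tukey(groups)
        assert res["pairwise"][("a", "c")] < 1e-3
        assert res["pairwise"][("b", "c")] < 1e-3
        assert res["pairwise"][("a", "b")] > 0.05

    def test_anova_f_matches_hand_computation(self):
        groups = {
            "g1": [3.0, 4.0, 5.0, 4.0, 4.0],
            "g2": [6.0, 7.0, 6.5, 7.5, 6.0],
            "g3": [4.5, 5.0, 5.5, 5.0, 4.0],
        }
        res = anova_tukey(groups)
        all_vals = [v for g in groups.values() for v in g]
        grand = np.mean(all_vals)
        ss_between = sum(len(g) * (np.mean(g) - grand) ** 2 for g in groups.values())
        ss_within = sum((v - np.mean(g)) ** 2 for g in groups.values() for v in g)
        f_hand = (ss_between / 2) / (ss_within / 12)
        assert res["F"] == pytest.approx(f_hand, abs=1e-10)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            compare_halves([1.0], [2.0, 3.0])
        with pytest.raises(ValueError):
            anova_tukey({"a": [1.0, 2.0]})
        with pytest.raises(ValueError):
            anova_tukey({"a": [1.0, 2.0], "b": [3.0]})
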