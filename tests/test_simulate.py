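"""Generator contracts: determinism, planted effects, polygon validity."""

import numpy as np
import pandas as pd
import pytest
from shapely.geometry import Polygon

from tmatlas.morphometry import cristae_fraction, polygon_area, sphericity
from tmatlas.simulate import (
    MultiomeSimConfig,
    SectionSimConfig,
    SimConfig,
    generate_count_matrix,
    generate_mitochondria,
    generate_multiome,
    generate_nuclei,
    generate_sections,
)
from tmatlas.zones import partition_halves, section_passes_inclusion


class TestCountMatrix:
    def test_same_seed_is_bitwise_identical(self):
        cfg = SimConfig(n_cells_per_class=30, n_genes=300, seed=7)
        a, _ = generate_count_matrix(cfg)
        b, _ = generate_count_matrix(cfg)
        assert np.array_equal(a.counts, b.counts)
        assert list(a.gene_ids) == list(b.gene_ids)

    def test_different_seed_differs(self):
        a, _ = generate_count_matrix(SimConfig(n_cells_per_class=30, n_genes=300, seed=7))
        b, _ = generate_count_matrix(SimConfig(n_cells_per_class=30, n_genes=300, seed=8))
        assert not np.array_equal(a.counts, b.counts)

    def test_fold_one_means_no_class_differences(self):
        cfg = SimConfig(n_cells_per_class=400, n_genes=200, marker_fold=1.0, seed=5)
        cm, truth = generate_count_matrix(cfg)
        lab = truth["labels"].to_numpy()
        for tm, genes in truth["markers"].items():
            gi = cm.gene_ids.get_indexer(genes)
            in_mean = cm.counts[np.ix_(gi, lab == tm)].mean()
            out_mean = cm.counts[np.ix_(gi, lab != tm)].mean()
            assert in_mean == pytest.approx(out_mean, rel=0.15)

    def test_marker_fold_recovered_empirically(self):
        # Monte-Carlo check against the negative-binomial expectation
        cfg = SimConfig(n_cells_per_class=500, n_genes=300, marker_fold=8.0, seed=11)
        cm, truth = generate_count_matrix(cfg)
        lab = truth["labels"].to_numpy()
        for tm in ("TM1", "TM2", "TM3"):
            gi = cm.gene_ids.get_indexer(truth["markers"][tm])
            ratio = (
                cm.counts[np.ix_(gi, lab == tm)].mean()
                / cm.counts[np.ix_(gi, lab != tm)].mean()
            )
            assert 6.0 <= ratio <= 10.0

    def test_marker_sets_disjoint_and_mito_flagged(self):
        cfg = SimConfig(n_cells_per_class=20, n_genes=400, seed=0)
        cm, truth = generate_count_matrix(cfg)
        sets = [set(v) for v in truth["class_markers"].values()]
        for i in range(len(sets)):
            for j in range(i + 1, len(sets)):
                assert not sets[i] & sets[j]
        assert cm.mito_flags.sum() == int(round(cfg.mito_gene_fraction * cfg.n_genes))

    @pytest.mark.parametrize(
        "bad",
        [
            {"n_genes": 0},
            {"marker_fold": 0.5},
            {"nb_dispersion": 0.0},
            {"mito_gene_fraction": 1.5},
            {"class_names": ("TM1", "TM2", "TM3", "Other")},
        ],
    )
    def test_invalid_config_rejected(self, bad):
        with pytest.raises(ValueError):
            generate_count_matrix(SimConfig(**bad))


def _toy_labels(n=2000):
    reps = n // 4
    values = ["TM1"] * reps + ["TM2"] * reps + ["TM3"] * reps + ["Other"] * (n - 3 * reps)
    return pd.Series(values, index=[f"c{i}" for i in range(n)])


class TestMultiome:
    def test_zero_coupling_gives_independence(self):
        labels = _toy_labels(800)
        cfg = MultiomeSimConfig(
            n_peaks=300, n_motifs=20, planted_activators=("TF000",), coupling_strength=0.0, seed=4
        )
        bundle, tf_expr, _, _ = generate_multiome(cfg, labels)
        m = list(bundle.motif_ids).index(bundle.tf_to_motif["TF000"])
        acc = bundle.peak_counts[bundle.motif_membership[m]].sum(axis=0)
        r = np.corrcoef(tf_expr.loc["TF000"], acc)[0, 1]
        assert abs(r) < 0.12

    def test_planted_activator_positively_coupled(self):
        labels = _toy_labels(2000)
        cfg = MultiomeSimConfig(
            n_peaks=300, n_motifs=20, planted_activators=("TF000",), coupling_strength=1.0, seed=4
        )
        bundle, tf_expr, _, _ = generate_multiome(cfg, labels)
        m = list(bundle.motif_ids).index(bundle.tf_to_motif["TF000"])
        acc = bundle.peak_counts[bundle.motif_membership[m]].sum(axis=0)
        assert np.corrcoef(tf_expr.loc["TF000"], acc)[0, 1] > 0.3

    def test_seed_determinism(self):
        labels = _toy_labels(200)
        cfg = MultiomeSimConfig(n_peaks=100, n_motifs=10, seed=9)
        a = generate_multiome(cfg, labels)
        b = generate_multiome(cfg, labels)
        assert np.array_equal(a[0].peak_counts, b[0].peak_counts)
        assert a[1].equals(b[1])

    def test_zero_member_peaks_rejected(self):
        with pytest.raises(ValueError):
            MultiomeSimConfig(n_peaks=100, n_motifs=5, n_member_peaks=0).validate()

    def test_overlapping_planted_sets_rejected(self):
        with pytest.raises(ValueError):
            MultiomeSimConfig(
                planted_activators=("TF000",), planted_repressors=("TF000",)
            ).validate()


class TestSections:
    def test_sections_pass_inclusion_gate(self):
        cfg = SectionSimConfig(n_sections=10, seed=2)
        for sec, _ in generate_sections(cfg, "TM1"):
            assert section_passes_inclusion(sec)
            assert 125.0 <= sec.ap_length <= 200.0

    def test_anterior_only_bias_starves_posterior(self):
        cfg = SectionSimConfig(
            n_sections=6,
            stain_blob_count=80,
            zone_bias={"anterior": 1.0, "posterior": 0.0},
            seed=6,
        )
        for sec, mask in generate_sections(cfg, "TM3"):
            zones = partition_halves(sec, "AP")
            stained = mask.clipped_to(sec)
            posterior_share = stained.intersection(zones["posterior"]).area / stained.area
            # blob centres never land posterior; only edge spill-over remains
            assert posterior_share < 0.05

    def test_uniform_bias_tracks_zone_area(self):
        cfg = SectionSimConfig(n_sections=12, stain_blob_count=60, seed=8)
        shares = []
        for sec, mask in generate_sections(cfg, "TM2"):
            zones = partition_halves(sec, "AP")
            stained = mask.clipped_to(sec)
            shares.append(stained.intersection(zones["anterior"]).area / stained.area)
        area_share = 0.5  # AP halves have equal length; area shares are close to 1/2
        assert np.mean(shares) == pytest.approx(area_share, abs=0.05)

    def test_polygons_simple_ccw_and_rich_enough(self):
        for sec, mask in generate_sections(SectionSimConfig(n_sections=4, seed=3), "TM1"):
            assert sec.tm_polygon.is_simple
            assert sec.tm_polygon.exterior.is_ccw
            assert len(sec.tm_polygon.exterior.coords) - 1 >= 4
            for p in mask.polygons:
                assert p.is_simple


class TestMitochondriaAndNuclei:
    def test_zero_effect_matches_wt(self):
        traces = generate_mitochondria(120, {"area_fold": 1.0, "cristae_fraction_shift": 0.0}, seed=5)
        wt = np.mean([polygon_area(t.outer) for t in traces["WT"]])
        mut = np.mean([polygon_area(t.outer) for t in traces["MUT"]])
        assert mut == pytest.approx(wt, rel=0.15)

    def test_area_fold_two_recovered(self):
        traces = generate_mitochondria(150, {"area_fold": 2.0}, seed=1)
        wt = np.mean([polygon_area(t.outer) for t in traces["WT"]])
        mut = np.mean([polygon_area(t.outer) for t in traces["MUT"]])
        assert 1.8 <= mut / wt <= 2.2

    def test_cristae_contained_and_fraction_on_target(self):
        traces = generate_mitochondria(25, {"cristae_fraction_shift": -0.15}, seed=2)
        for genotype, expected in (("WT", 0.40), ("MUT", 0.25)):
            fracs = [cristae_fraction(t) for t in traces[genotype]]  # validates containment
            assert np.mean(fracs) == pytest.approx(expected, abs=0.04)

    def test_infeasible_shift_rejected(self):
        with pytest.raises(ValueError):
            generate_mitochondria(5, {"cristae_fraction_shift": 0.9}, seed=0)

    def test_outer_polygons_simple_with_enough_vertices(self):
        for t in generate_mitochondria(10, seed=4)["WT"]:
            assert Polygon(t.outer).is_simple
            assert len(t.outer) >= 4

    def test_nuclei_elongation_reduces_sphericity(self):
        nuclei = generate_nuclei({"TM1": 30, "TM3": 30}, seed=6)
        mean_sph = {
            s: np.mean([sphericity(n) for n in nuclei if n.subtype == s]) for s in ("TM1", "TM3")
        }
        assert mean_sph["TM1"] > mean_sph["TM3"]
        assert all(v <= 1.0 + 1e-9 for v in mean_sph.values())
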