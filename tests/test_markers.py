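"""Marker statistics, the panel gate, dendrogram topology, module scores."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from tmatlas.markers import (
    dendrogram_to_newick,
    filter_marker_panel,
    find_markers,
    module_score,
    subtype_dendrogram,
)


def _toy_norm(values, genes=None):
    values = np.asarray(values, float)
    g, c = values.shape
    return pd.DataFrame(
        values,
        index=genes or [f"g{i}" for i in range(g)],
        columns=[f"c{i}" for i in range(c)],
    )


class TestFindMarkers:
    def test_identical_gene_is_null(self):
        # both groups carry exactly the same value multiset per gene
        rng = np.random.default_rng(0)
        half = rng.normal(1.0, 0.2, size=(3, 10)).clip(0)
        norm = _toy_norm(np.hstack([half, half]))
        labels = pd.Series([0] * 10 + [1] * 10, index=norm.columns)
        res = find_markers(norm, labels, 0).set_index("gene")
        assert (res["p"] > 0.9).all()
        assert res["log_fc"].abs().max() < 1e-9

    def test_six_vs_six_matches_exact_enumeration(self):
        # tie-free toy: the asymptotic p must track the exact distribution
        rng = np.random.default_rng(1)
        for _ in range(20):
            vals = rng.normal(5.0, 1.0, size=12)  # positive, tie-free
            norm = _toy_norm(vals[None, :].repeat(3, axis=0) + rng.normal(0, 1e-6, (3, 12)))
            labels = pd.Series([0] * 6 + [1] * 6, index=norm.columns)
            res = find_markers(norm, labels, 0)
            exact = stats.mannwhitneyu(
                norm.iloc[0, :6], norm.iloc[0, 6:], alternative="two-sided", method="exact"
            ).pvalue
            approx = res.set_index("gene").loc["g0", "p"]
            assert abs(approx - exact) <= 0.02

    def test_planted_marker_ranks_high(self, small_clusters):
        norm, truth, labels = small_clusters
        true_labels = truth["labels"].loc[norm.columns]
        # identify the cluster matching TM1 by majority vote
        df = pd.DataFrame({"cl": labels.labels, "cls": true_labels})
        tm1_cluster = df[df.cls == "TM1"]["cl"].mode()[0]
        res = find_markers(norm, labels, tm1_cluster)
        top10 = set(res.nsmallest(10, "p_adj")["gene"])
        assert len(top10 & set(truth["markers"]["TM1"])) >= 5

    def test_logfc_antisymmetry(self):
        rng = np.random.default_rng(2)
        norm = _toy_norm(rng.normal(1.0, 0.5, size=(5, 30)).clip(0))
        labels = pd.Series([0] * 12 + [1] * 18, index=norm.columns)
        a = find_markers(norm, labels, 0).set_index("gene")["log_fc"]
        b = find_markers(norm, labels, 1).set_index("gene")["log_fc"]
        assert np.allclose(a, -b, atol=1e-9)

    def test_bh_adjustment_is_monotone(self):
        rng = np.random.default_rng(3)
        norm = _toy_norm(rng.normal(1.0, 0.5, size=(40, 40)).clip(0))
        labels = pd.Series([0] * 20 + [1] * 20, index=norm.columns)
        res = find_markers(norm, labels, 0).sort_values("p")
        assert (res["p_adj"].to_numpy() >= res["p"].to_numpy() - 1e-12).all()
        assert (np.diff(res["p_adj"].to_numpy()) >= -1e-12).all()

    def test_tiny_cluster_rejected(self):
        norm = _toy_norm(np.ones((3, 10)))
        labels = pd.Series([0] * 2 + [1] * 8, index=norm.columns)
        with pytest.raises(ValueError):
            find_markers(norm, labels, 0)


class TestFilterPanel:
    def _frame(self, pct, lfc, p=None):
        n = len(pct)
        return pd.DataFrame(
            {
                "gene": [f"g{i}" for i in range(n)],
                "pct_in": pct,
                "log_fc": lfc,
                "p": p if p is not None else np.linspace(1e-6, 1e-3, n),
            }
        )

    def test_boundary_pct_excluded(self):
        res = self._frame([0.10, 0.101], [1.0, 1.0])
        assert filter_marker_panel(res) == ["g1"]

    def test_boundary_logfc_excluded(self):
        res = self._frame([0.5, 0.5], [0.25, 0.2500001])
        assert filter_marker_panel(res) == ["g1"]

    def test_truncation_keeps_smallest_p(self):
        rng = np.random.default_rng(4)
        p = rng.uniform(0, 1, 600)
        res = self._frame([0.5] * 600, [1.0] * 600, p=p)
        panel = filter_marker_panel(res, top_n=500)
        assert len(panel) == 500
        kept_p = res.set_index("gene").loc[panel, "p"]
        assert kept_p.max() <= np.sort(p)[499] + 1e-15


class TestDendrogram:
    def test_identical_profiles_merge_first_at_zero(self):
        rng = np.random.default_rng(5)
        a = rng.normal(1.0, 1.0, size=8)
        b = rng.normal(5.0, 1.0, size=8)
        profiles = {0: a, 1: a, 2: b}
        cols = []
        data = []
        for cl, prof in profiles.items():
            for r in range(3):
                cols.append(f"c{cl}_{r}")
                data.append(prof)
        norm = pd.DataFrame(np.array(data).T, index=[f"g{i}" for i in range(8)], columns=cols)
        labels = pd.Series([0, 0, 0, 1, 1, 1, 2, 2, 2], index=cols)
        z, leaves = subtype_dendrogram(norm, labels, list(norm.index))
        first_merge = {leaves[int(z[0, 0])], leaves[int(z[0, 1])]}
        assert first_merge == {0, 1}
        assert z[0, 2] == pytest.approx(0.0, abs=1e-12)

    def test_average_linkage_matches_hand_computation(self):
        # four clusters with profiles engineered for known correlations
        rng = np.random.default_rng(6)
        base = rng.normal(0, 1, 12)
        profs = [
            base,
            base + rng.normal(0, 0.1, 12),
            -base,
            rng.normal(0, 1, 12),
        ]
        cols, data, lab = [], [], []
        for cl, prof in enumerate(profs):
            for r in range(2):
                cols.append(f"c{cl}_{r}")
                data.append(prof)
                lab.append(cl)
        norm = pd.DataFrame(np.array(data).T, index=[f"g{i}" for i in range(12)], columns=cols)
        labels = pd.Series(lab, index=cols)
        z, leaves = subtype_dendrogram(norm, labels, list(norm.index))

        # independent brute-force average-linkage agglomeration
        profiles = np.array(profs)
        d = 1.0 - np.corrcoef(profiles)
        clusters = {i: [i] for i in range(4)}
        merges = []
        while len(clusters) > 1:
            best = None
            for i in sorted(clusters):
                for j in sorted(clusters):
                    if i >= j:
                        continue
                    h = np.mean([d[a, b] for a in clusters[i] for b in clusters[j]])
                    if best is None or h < best[0]:
                        best = (h, i, j)
            h, i, j = best
            merges.append(h)
            clusters[min(i, j)] = clusters.pop(i) + clusters.pop(j)
        assert np.allclose(sorted(z[:, 2]), sorted(merges), atol=1e-10)

    def test_constant_profile_names_cluster(self):
        norm = _toy_norm(np.vstack([np.ones(6), np.ones(6)]))
        norm.iloc[0, 3:] = 2.0
        labels = pd.Series([0, 0, 0, 1, 1, 1], index=norm.columns)
        with pytest.raises(ValueError, match="0"):
            subtype_dendrogram(norm, labels, list(norm.index))

    def test_newick_roundtrip_shape(self):
        z = np.array([[0.0, 1.0, 0.1, 2], [2.0, 3.0, 0.5, 3]])
        nwk = dendrogram_to_newick(z, ["TM1", "TM2", "TM3"])
        assert nwk.startswith("(") and nwk.endswith(";")
        for leaf in ("TM1", "TM2", "TM3"):
            assert leaf in nwk


class TestModuleScore:
    def test_seed_determinism_and_dedup_invariance(self, small_norm):
        norm, truth = small_norm
        genes = truth["markers"]["TM2"]
        a = module_score(norm, genes, seed=5)
        b = module_score(norm, genes, seed=5)
        c = module_score(norm, genes + genes[:3], seed=5)
        assert a.equals(b)
        assert a.equals(c)

    def test_random_set_scores_near_zero(self, small_norm):
        norm, _ = small_norm
        rng = np.random.default_rng(7)
        genes = list(rng.choice(norm.index, size=25, replace=False))
        score = module_score(norm, genes, seed=1)
        assert abs(score.mean()) < 0.05

    def test_planted_signature_separates_subtype(self, small_norm):
        norm, truth = small_norm
        score = module_score(norm, truth["markers"]["TM3"], seed=2)
        lab = truth["labels"].loc[norm.columns]
        assert score[lab == "TM3"].mean() > score[lab != "TM3"].mean() + 0.5

    def test_empty_intersection_reports_missing(self, small_norm):
        norm, _ = small_norm
        with pytest.raises(ValueError, match="missing"):
            module_score(norm, ["nope1", "nope2"], seed=0)
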