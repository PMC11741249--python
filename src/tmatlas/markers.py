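"""Marker statistics, subtype dendrogram, and gene-set module scores.

Markers for a cluster are scored gene-by-gene with the two-sided Wilcoxon
rank-sum test (normal approximation with tie correction) of in-cluster
versus all other cells, with Benjamini-Hochberg adjustment across genes.
The log fold change is the natural log of the ratio of mean expm1-scale
expression, matching the convention under which the marker gate is
"expressed in >10% of cells with logFC > 0.25".  The subtype dendrogram
agglomerates mean cluster profiles over the marker panel with average
linkage on a 1 - Pearson-correlation distance.  Module scores follow the
binned-control construction: each set gene contributes its expression minus
the mean of expression-matched control genes sampled from the same
average-expression bin.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform
from statsmodels.stats.multitest import multipletests

from .containers import ClusterLabels

__all__ = [
    "find_markers",
    "filter_marker_panel",
    "subtype_dendrogram",
    "dendrogram_to_newick",
    "module_score",
]

_EPS = 1e-9


def _as_labels(labels) -> pd.Series:
    return labels.labels if isinstance(labels, ClusterLabels) else pd.Series(labels)


def find_markers(norm: pd.DataFrame, labels, cluster) -> pd.DataFrame:
    """Wilcoxon rank-sum marker statistics for one cluster vs the rest.

    Parameters
    ----------
    norm
        Genes x cells log-normalised expression.
    labels
        Cluster assignment covering the columns of ``norm``.
    cluster
        The target cluster id.

    Returns
    -------
    DataFrame with columns gene, cluster, log_fc, p, p_adj, pct_in,
    pct_out, sorted by p ascending.
    """
    lab = _as_labels(labels).loc[norm.columns]
    in_mask = (lab == cluster).to_numpy()
    if in_mask.sum() < 3:
        raise ValueError(f"cluster {cluster!r} has fewer than 3 cells")
    if (~in_mask).sum() < 1:
        raise ValueError("no out-of-cluster cells to compare against")

    x = np.asarray(norm, dtype=float)
    x_in, x_out = x[:, in_mask], x[:, ~in_mask]

    res = stats.mannwhitneyu(
        x_in, x_out, axis=1, alternative="two-sided", method="asymptotic"
    )
    p = np.asarray(res.pvalue, dtype=float)

    mean_in = np.expm1(x_in).mean(axis=1)
    mean_out = np.expm1(x_out).mean(axis=1)
    log_fc = np.log((mean_in + _EPS) / (mean_out + _EPS))

    out = pd.DataFrame(
        {
            "gene": norm.index,
            "cluster": cluster,
            "log_fc": log_fc,
            "p": p,
            "p_adj": multipletests(p, method="fdr_bh")[1],
            "pct_in": (x_in > 0).mean(axis=1),
            "pct_out": (x_out > 0).mean(axis=1),
        }
    )
    return out.sort_values("p", kind="stable").reset_index(drop=True)


def filter_marker_panel(
    results: pd.DataFrame,
    min_pct: float = 0.10,
    min_logfc: float = 0.25,
    top_n: int = 500,
) -> list[str]:
    """Gate markers (strictly > min_pct expressing cells, strictly
    > min_logfc) then truncate to the smallest-p ``top_n`` genes."""
    passing = results[(results["pct_in"] > min_pct) & (results["log_fc"] > min_logfc)]
    passing = passing.sort_values("p", kind="stable").head(top_n)
    return passing["gene"].tolist()


def subtype_dendrogram(
    norm: pd.DataFrame, labels, panel: list[str]
) -> tuple[np.ndarray, list]:
    """Average-linkage dendrogram of cluster mean profiles over a panel.

    Distance between clusters is 1 - Pearson correlation of their mean
    expression profiles over the panel genes.  Returns the scipy linkage
    matrix and the ordered list of cluster ids (leaves).
    """
    if not panel:
        raise ValueError("marker panel is empty")
    lab = _as_labels(labels).loc[norm.columns]
    clusters = sorted(lab.unique())
    if len(clusters) < 2:
        raise ValueError("need at least 2 clusters")
    sub = norm.loc[[g for g in panel if g in norm.index]]
    if sub.empty:
        raise ValueError("no panel genes present in the expression matrix")
    profiles = np.column_stack(
        [np.asarray(sub.loc[:, (lab == c).to_numpy()]).mean(axis=1) for c in clusters]
    )
    sds = profiles.std(axis=0)
    for c, sd in zip(clusters, sds):
        if sd == 0:
            raise ValueError(f"cluster {c!r} has a constant profile; correlation undefined")
    corr = np.corrcoef(profiles.T)
    dist = np.clip(1.0 - corr, 0.0, None)
    np.fill_diagonal(dist, 0.0)
    z = linkage(squareform(dist, checks=False), method="average")
    return z, clusters


def dendrogram_to_newick(z: np.ndarray, leaves: list) -> str:
    """Serialise a scipy linkage matrix as a Newick string."""
    n = len(leaves)
    nodes: dict[int, tuple[str, float]] = {i: (str(leaves[i]), 0.0) for i in range(n)}
    for k, (a, b, height, _) in enumerate(z):
        na, ha = nodes[int(a)]
        nb, hb = nodes[int(b)]
        nodes[n + k] = (f"({na}:{height - ha:.6g},{nb}:{height - hb:.6g})", float(height))
    return nodes[n + len(z) - 1][0] + ";"


def module_score(
    norm: pd.DataFrame,
    gene_set: list[str],
    n_bins: int = 24,
    n_ctrl: int = 100,
    seed: int = 0,
) -> pd.Series:
    """Per-cell gene-set score against expression-bin-matched controls.

    All genes are cut into ``n_bins`` equal-frequency bins of average
    expression.  For each (deduplicated) set gene, ``n_ctrl`` control genes
    are sampled from its bin (with replacement when the bin is smaller than
    ``n_ctrl``).  The score is the mean expression of the set genes minus
    the mean over the pooled control draw; deterministic for a fixed seed.
    """
    genes = list(dict.fromkeys(gene_set))  # dedupe, keep order
    present = [g for g in genes if g in norm.index]
    if not present:
        missing = [g for g in genes if g not in norm.index][:10]
        raise ValueError(f"gene set has no overlap with the data; missing e.g. {missing}")
    if norm.shape[0] < n_bins:
        raise ValueError("fewer genes than expression bins")

    rng = np.random.default_rng(seed)
    avg = np.asarray(norm, dtype=float).mean(axis=1)
    # equal-frequency bins; rank with random-free stable tie-break by index order
    order = pd.Series(avg, index=norm.index).rank(method="first")
    bins = pd.cut(order, bins=n_bins, labels=False)

    bin_members: dict[int, np.ndarray] = {
        int(b): np.flatnonzero(bins.to_numpy() == b) for b in range(n_bins)
    }
    gene_pos = {g: i for i, g in enumerate(norm.index)}

    ctrl_rows: list[np.ndarray] = []
    for g in present:
        b = int(bins.iloc[gene_pos[g]])
        members = bin_members[b]
        replace = len(members) < n_ctrl
        ctrl_rows.append(rng.choice(members, size=n_ctrl, replace=replace))
    ctrl_idx = np.concatenate(ctrl_rows)

    x = np.asarray(norm, dtype=float)
    set_mean = x[[gene_pos[g] for g in present]].mean(axis=0)
    ctrl_mean = x[ctrl_idx].mean(axis=0)
    return pd.Series(set_mean - ctrl_mean, index=norm.columns, name="module_score")
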