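"""Motif-deviation TF activity and the expression-activity influence screen.

Per-cell TF activity is quantified chromVAR-style: for each motif the
observed accessibility count over its member peaks is compared with the
expectation under the cell's sequencing depth and the peak's global
popularity, and the resulting raw deviation is z-scored against background
peak sets matched on mean accessibility.  A TF's activity is then screened
against its own RNA expression by correlating the two across randomly
subsampled cell neighborhoods; influential TFs are those with
|r| > 0.5, adjusted p < 0.01 and deviation variability above the 75th
percentile of all TFs, positive r marking activators and negative r
repressors.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .containers import MotifAccessibilityBundle

__all__ = [
    "DeviationMatrix",
    "raw_deviations",
    "compute_deviations",
    "expression_activity_correlation",
    "filter_tfs_by_expression",
    "deviation_variability_percentile",
    "classify_influential",
]


@dataclass
class DeviationMatrix:
    """Motif x cell deviation z-scores with the background bookkeeping."""

    z: pd.DataFrame
    n_background: int
    seed: int
    excluded_motifs: list[str]


def _accessibility_bins(peak_means: np.ndarray, n_bins: int) -> np.ndarray:
    """Equal-frequency accessibility bins (stable tie-break by peak order)."""
    order = pd.Series(peak_means).rank(method="first")
    return pd.cut(order, bins=n_bins, labels=False).to_numpy()


def raw_deviations(bundle: MotifAccessibilityBundle) -> pd.DataFrame:
    """Raw (observed - expected) / expected accessibility deviations.

    ``expected`` for motif m in cell c is the cell's total count times the
    global fraction of reads falling in m's member peaks.  Cells (or motifs)
    with zero expectation get a raw deviation of 0.
    """
    x = np.asarray(bundle.peak_counts, dtype=float)
    cell_totals = x.sum(axis=0)
    grand_total = cell_totals.sum()
    if grand_total <= 0:
        raise ValueError("peak totals must be positive")
    peak_frac = x.sum(axis=1) / grand_total
    m = bundle.motif_membership.astype(float)
    observed = m @ x
    expected = (m @ peak_frac)[:, None] * cell_totals[None, :]
    safe = np.where(expected > 0, expected, 1.0)
    raw = np.where(expected > 0, (observed - expected) / safe, 0.0)
    return pd.DataFrame(raw, index=bundle.motif_ids, columns=bundle.cell_ids)


def compute_deviations(
    bundle: MotifAccessibilityBundle,
    n_background: int = 50,
    n_bias_bins: int = 10,
    seed: int = 0,
) -> DeviationMatrix:
    """chromVAR-style motif deviation z-scores.

    For motif m and cell c with member peak set P_m:
    ``observed = sum of counts over P_m``, ``expected = cell_total * sum of
    global peak fractions over P_m`` and ``raw = (observed - expected) /
    expected``.  The z-score centers and scales raw against ``n_background``
    background peak sets in which each member peak is replaced by a random
    peak from the same mean-accessibility bin.  Motifs whose expectation is
    zero in every cell are excluded with a warning.
    """
    x = np.asarray(bundle.peak_counts, dtype=float)
    n_peaks, n_cells = x.shape
    if n_cells < 2:
        raise ValueError("need at least 2 cells")
    cell_totals = x.sum(axis=0)
    grand_total = cell_totals.sum()
    if grand_total <= 0:
        raise ValueError("peak totals must be positive")
    peak_frac = x.sum(axis=1) / grand_total

    bins = _accessibility_bins(x.mean(axis=1), n_bias_bins)
    bin_members = {b: np.flatnonzero(bins == b) for b in np.unique(bins)}

    rng = np.random.default_rng(seed)
    membership = bundle.motif_membership
    z_rows, kept, excluded = [], [], []
    for mi, motif in enumerate(bundle.motif_ids):
        members = np.flatnonzero(membership[mi])
        exp_frac = peak_frac[members].sum()
        expected = cell_totals * exp_frac
        if not (expected > 0).any():
            excluded.append(str(motif))
            continue
        safe_expected = np.where(expected > 0, expected, 1.0)
        raw = np.where(expected > 0, (x[members].sum(axis=0) - expected) / safe_expected, 0.0)

        # background sets: every member peak replaced by a random peak from
        # the same mean-accessibility bin (vectorised per bin)
        repl = np.empty((n_background, len(members)), dtype=int)
        member_bins = bins[members]
        for b in np.unique(member_bins):
            cols = np.flatnonzero(member_bins == b)
            pool = bin_members[b]
            repl[:, cols] = pool[rng.integers(0, len(pool), size=(n_background, len(cols)))]
        bg_obs = x[repl].sum(axis=1)  # (n_background, n_cells)
        bg_frac = peak_frac[repl].sum(axis=1)
        bg_expected = cell_totals[None, :] * bg_frac[:, None]
        safe_bg = np.where(bg_expected > 0, bg_expected, 1.0)
        bg_raw = np.where(bg_expected > 0, (bg_obs - bg_expected) / safe_bg, 0.0)
        mu = bg_raw.mean(axis=0)
        sd = bg_raw.std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
        z_rows.append((raw - mu) / sd)
        kept.append(str(motif))

    if excluded:
        warnings.warn(f"motifs excluded (zero expectation): {excluded[:5]}", stacklevel=2)
    z = pd.DataFrame(np.vstack(z_rows), index=kept, columns=bundle.cell_ids)
    return DeviationMatrix(z=z, n_background=n_background, seed=seed, excluded_motifs=excluded)


def expression_activity_correlation(
    dev: DeviationMatrix,
    tf_expr: pd.DataFrame,
    tf_to_motif: dict[str, str],
    n_neighborhoods: int = 100,
    neighborhood_size: int | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Correlate TF expression with motif deviation across cell neighborhoods.

    ``n_neighborhoods`` uniform random cell subsets are drawn; within each,
    the mean deviation and mean expression of every TF are computed, and the
    Pearson correlation over the paired neighborhood means gives the TF's
    (r, p), with BH adjustment across TFs.  TFs whose aggregated deviation
    or expression has zero variance get r = NaN with a note.
    """
    cells = dev.z.columns
    if not set(cells) <= set(tf_expr.columns):
        raise ValueError("deviation and expression matrices must share cells")
    expr = tf_expr[cells]
    n_cells = len(cells)
    if neighborhood_size is None:
        neighborhood_size = min(100, max(2, n_cells // 2))
    if neighborhood_size > n_cells:
        raise ValueError("neighborhood_size exceeds number of cells")
    rng = np.random.default_rng(seed)

    tfs = [tf for tf in expr.index if tf_to_motif.get(tf) in dev.z.index]
    dev_arr = dev.z.loc[[tf_to_motif[tf] for tf in tfs]].to_numpy()
    expr_arr = expr.loc[tfs].to_numpy(dtype=float)

    mean_dev = np.empty((len(tfs), n_neighborhoods))
    mean_expr = np.empty((len(tfs), n_neighborhoods))
    for j in range(n_neighborhoods):
        idx = rng.choice(n_cells, size=neighborhood_size, replace=False)
        mean_dev[:, j] = dev_arr[:, idx].mean(axis=1)
        mean_expr[:, j] = expr_arr[:, idx].mean(axis=1)

    rows = []
    df = n_neighborhoods - 2
    for i, tf in enumerate(tfs):
        d, e = mean_dev[i], mean_expr[i]
        if d.std() == 0 or e.std() == 0:
            rows.append({"tf": tf, "r": np.nan, "p": np.nan, "note": "zero-variance aggregate"})
            continue
        r = float(np.corrcoef(d, e)[0, 1])
        r = max(-1.0, min(1.0, r))
        if abs(r) == 1.0:
            p = 0.0
        else:
            t = r * np.sqrt(df / (1.0 - r * r))
            p = float(2.0 * stats.t.sf(abs(t), df))
        rows.append({"tf": tf, "r": r, "p": p, "note": ""})
    out = pd.DataFrame(rows).set_index("tf")
    valid = out["p"].notna()
    out["p_adj"] = np.nan
    if valid.any():
        out.loc[valid, "p_adj"] = multipletests(out.loc[valid, "p"], method="fdr_bh")[1]
    return out


def filter_tfs_by_expression(
    records: pd.DataFrame, expr_means_cp10k: pd.Series, prioritize: float = 0.5
) -> pd.DataFrame:
    """Drop TFs with zero mean RNA expression; flag CP10K > 0.5 as prioritized."""
    means = expr_means_cp10k.reindex(records.index).fillna(0.0)
    kept = records[means > 0].copy()
    kept["mean_cp10k"] = means[means > 0]
    kept["prioritized"] = kept["mean_cp10k"] > prioritize
    return kept


def deviation_variability_percentile(dev: DeviationMatrix) -> pd.Series:
    """Percentile rank (0-100) of each motif's deviation SD across cells."""
    sd = dev.z.std(axis=1, ddof=1)
    pct = 100.0 * (sd.rank(method="average") - 1) / max(len(sd) - 1, 1)
    return pct


def classify_influential(
    records: pd.DataFrame,
    r_thresh: float = 0.5,
    padj_thresh: float = 0.01,
    pctile_thresh: float = 75.0,
) -> pd.DataFrame:
    """Designate influential TFs from the correlation screen.

    ``records`` must carry columns r, p_adj and percentile (deviation
    variability).  Activator: r > r_thresh (strict), p_adj < padj_thresh and
    percentile > pctile_thresh; repressor: the same with r < -r_thresh.
    """
    for col in ("r", "p_adj", "percentile"):
        if col not in records.columns:
            raise ValueError(f"records missing column {col!r}")
    out = records.copy()
    strong = (out["p_adj"] < padj_thresh) & (out["percentile"] > pctile_thresh)
    out["class"] = "none"
    out.loc[strong & (out["r"] > r_thresh), "class"] = "activator"
    out.loc[strong & (out["r"] < -r_thresh), "class"] = "repressor"
    out.loc[out["r"].isna(), "class"] = "none"
    return out
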