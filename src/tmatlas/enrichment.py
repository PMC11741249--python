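"""Over-representation and gene-set enrichment analyses.

ORA scores each gene set with the upper-tail hypergeometric probability of
the observed overlap between a query gene list and the set, inside a stated
background universe (for subtype comparisons the universe is the genes
expressed in TM cells), with BH adjustment and a reporting cutoff of
p <= 0.01.  GSEA computes the weighted Kolmogorov-Smirnov running-sum
enrichment score over a signed gene ranking: positive scores mark sets
concentrated at the top of the ranking (enriched), negative scores sets
concentrated at the bottom (underrepresented).  Significance is assessed by
gene-label permutation and NES normalises the score by the same-sign
permutation mean.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = ["read_gmt", "ora_test", "gsea", "enrichment_score"]


def read_gmt(path) -> dict[str, list[str]]:
    """Read gene sets from a GMT file (term, description, genes...)."""
    sets: dict[str, list[str]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"malformed GMT line: {line[:60]!r}")
        sets[parts[0]] = list(dict.fromkeys(g for g in parts[2:] if g))
    return sets


def ora_test(
    query: list[str],
    universe: list[str],
    gene_sets: dict[str, list[str]],
    p_cutoff: float = 0.01,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Hypergeometric over-representation test for each gene set.

    Returns ``(significant, full)`` tables; ``significant`` retains rows
    with p <= ``p_cutoff`` (reporting convention), ``full`` has every set.
    Sets are intersected with the universe first and the query must be a
    subset of the universe.
    """
    uni = set(universe)
    if not uni:
        raise ValueError("empty background universe")
    q = set(query)
    if not q <= uni:
        raise ValueError("query genes must be a subset of the universe")
    n_uni, n_query = len(uni), len(q)
    rows = []
    for term in sorted(gene_sets):
        members = set(gene_sets[term]) & uni
        k = len(members & q)
        # upper tail including the observed overlap
        p = float(stats.hypergeom.sf(k - 1, n_uni, len(members), n_query)) if members else 1.0
        rows.append(
            {
                "term": term,
                "overlap": k,
                "set_size": len(members),
                "universe_size": n_uni,
                "query_size": n_query,
                "p": min(p, 1.0),
            }
        )
    full = pd.DataFrame(rows)
    if len(full):
        full["p_adj"] = multipletests(full["p"], method="fdr_bh")[1]
        full = full.sort_values("p", kind="stable").reset_index(drop=True)
    significant = full[full["p"] <= p_cutoff].reset_index(drop=True) if len(full) else full
    return significant, full


def _ranked_order(ranked: pd.Series) -> pd.Series:
    """Descending by statistic, ties broken by gene name (stable)."""
    if ranked.index.has_duplicates:
        raise ValueError("ranking contains duplicate genes")
    df = pd.DataFrame({"stat": ranked})
    df = df.sort_index(kind="stable").sort_values("stat", ascending=False, kind="stable")
    return df["stat"]


def enrichment_score(ranked: pd.Series, members: set, weight: float = 1.0) -> float:
    """Maximal-deviation weighted KS running-sum enrichment score.

    ``ranked`` must already be ordered.  Hit steps are proportional to
    |stat|^weight, miss steps uniform; the score is the extremum of the
    running sum, signed.
    """
    stats_arr = ranked.to_numpy(dtype=float)
    is_hit = np.fromiter((g in members for g in ranked.index), bool, len(ranked))
    n_hit = int(is_hit.sum())
    n_miss = len(ranked) - n_hit
    if n_hit == 0 or n_miss == 0:
        return 0.0
    hit_w = np.abs(stats_arr) ** weight
    hit_total = hit_w[is_hit].sum()
    if hit_total == 0:
        hit_inc = np.where(is_hit, 1.0 / n_hit, 0.0)
    else:
        hit_inc = np.where(is_hit, hit_w / hit_total, 0.0)
    steps = hit_inc - np.where(is_hit, 0.0, 1.0 / n_miss)
    running = np.cumsum(steps)
    return float(running[np.argmax(np.abs(running))])


def gsea(
    ranked: pd.Series,
    gene_sets: dict[str, list[str]],
    weight: float = 1.0,
    n_perm: int = 1000,
    seed: int = 0,
    min_size: int = 3,
) -> pd.DataFrame:
    """Preranked GSEA with a gene-label permutation null.

    Parameters
    ----------
    ranked
        Gene -> signed statistic (e.g. a DEG statistic); no duplicates.
    gene_sets
        term -> member genes; intersected with the ranking, sets smaller
        than ``min_size`` after intersection are dropped.

    Returns a table with ES, NES, direction, p and p_adj per term.  The
    permutation p-value for a term is computed among same-sign permuted
    scores; NES divides ES by the same-sign permutation mean magnitude.
    """
    order = _ranked_order(ranked)
    if np.ptp(order.to_numpy(dtype=float)) == 0:
        raise ValueError("all statistics equal; ranking undefined")
    rng = np.random.default_rng(seed)
    gene_names = list(order.index)

    kept = {}
    for term in sorted(gene_sets):
        members = set(gene_sets[term]) & set(gene_names)
        if len(members) >= min_size:
            kept[term] = members
    rows = []
    for term, members in kept.items():
        es = enrichment_score(order, members, weight=weight)
        size = len(members)
        perm_scores = np.empty(n_perm)
        for i in range(n_perm):
            perm_members = set(rng.choice(gene_names, size=size, replace=False))
            perm_scores[i] = enrichment_score(order, perm_members, weight=weight)
        same_sign = perm_scores[np.sign(perm_scores) == np.sign(es)] if es != 0 else perm_scores
        if es > 0:
            exceed = int((perm_scores >= es).sum())
        elif es < 0:
            exceed = int((perm_scores <= es).sum())
        else:
            exceed = n_perm
        p = (1 + exceed) / (n_perm + 1)
        denom = np.abs(same_sign).mean() if len(same_sign) else np.nan
        nes = es / denom if denom and np.isfinite(denom) and denom > 0 else np.nan
        rows.append(
            {
                "term": term,
                "set_size": size,
                "ES": es,
                "NES": nes,
                "direction": "enriched" if es > 0 else ("underrepresented" if es < 0 else "none"),
                "p": p,
            }
        )
    out = pd.DataFrame(rows)
    if len(out):
        out["p_adj"] = multipletests(out["p"], method="fdr_bh")[1]
        out = out.sort_values("p", kind="stable").reset_index(drop=True)
    return out
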