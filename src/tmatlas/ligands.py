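"""Rule-based assignment of ligands to TM subtypes from mean expression.

A ligand's mean expression per subtype (counts per 10,000, CP10K) is mapped
onto one of four mutually exclusive outcomes, applied in order:

1. *exclusive* - some subtype exceeds the high-expression threshold
   (1 CP10K) and its expression is at least ``fold_thresh`` (4x, inclusive)
   that of every other subtype; at most one subtype can satisfy this.
2. *shared-high* - otherwise, if any subtype exceeds the threshold, the
   ligand is shared among the above-threshold subtypes whose expression is
   within the fold threshold of the highest one (when the above-threshold
   subtypes are mutually comparable this is exactly the max/min-ratio < 4x
   rule).
3. *shared-low* - when no subtype reaches the threshold, the ligand goes to
   every subtype with non-zero expression.
4. *unassigned* - no expression anywhere.

The fold comparison of the exclusive rule is inclusive ("4x more" counts);
both thresholds are parameters.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

__all__ = ["LigandAssignment", "assign_ligand", "assign_panel"]


@dataclass
class LigandAssignment:
    ligand: str
    subtypes: tuple[str, ...]
    rule: str  # exclusive | shared-high | shared-low | unassigned

    def __post_init__(self) -> None:
        if self.rule == "exclusive" and len(self.subtypes) != 1:
            raise ValueError("exclusive assignment must name exactly one subtype")


def assign_ligand(
    profile: dict[str, float],
    ligand: str = "",
    high_thresh: float = 1.0,
    fold_thresh: float = 4.0,
) -> LigandAssignment:
    """Assign one ligand from its per-subtype mean CP10K expression."""
    if not profile:
        raise ValueError("empty expression profile")
    for sub, v in profile.items():
        if not (v >= 0):
            raise ValueError(f"negative or non-finite expression for {sub}: {v}")

    high = {s for s, v in profile.items() if v > high_thresh}

    for s in high:
        others = [profile[o] for o in profile if o != s]
        if all(profile[s] >= fold_thresh * v for v in others):
            return LigandAssignment(ligand, (s,), "exclusive")

    if high:
        top = max(profile[s] for s in high)
        shared = tuple(sorted(s for s in high if top / profile[s] < fold_thresh))
        return LigandAssignment(ligand, shared, "shared-high")

    expressed = tuple(sorted(s for s, v in profile.items() if v > 0))
    if expressed:
        return LigandAssignment(ligand, expressed, "shared-low")
    return LigandAssignment(ligand, (), "unassigned")


def assign_panel(
    profiles: pd.DataFrame,
    high_thresh: float = 1.0,
    fold_thresh: float = 4.0,
) -> tuple[pd.DataFrame, pd.Series]:
    """Apply :func:`assign_ligand` to a ligand x subtype table.

    Returns the assignment table and per-subtype assignment counts.
    """
    if profiles.empty or profiles.shape[1] == 0:
        raise ValueError("empty ligand panel")
    if profiles.index.has_duplicates:
        raise ValueError("duplicate ligand names")
    rows = []
    counts = {s: 0 for s in profiles.columns}
    for ligand, row in profiles.iterrows():
        a = assign_ligand(row.to_dict(), ligand=str(ligand), high_thresh=high_thresh, fold_thresh=fold_thresh)
        for s in a.subtypes:
            counts[s] += 1
        rows.append(
            {"ligand": a.ligand, "rule": a.rule, "subtypes": ",".join(a.subtypes)}
        )
    return pd.DataFrame(rows), pd.Series(counts, name="n_assigned")
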