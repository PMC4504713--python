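"""Concordance between two genetic maps sharing marker ids.

Used both to validate a built map against simulation truth and to compare
two independently built maps (the dot-plot style analysis: shared markers,
same-chromosome fraction, per-group rank correlation of positions).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import kendalltau, spearmanr

from .genmap import GeneticMap


@dataclass
class Concordance:
    n_shared: int
    n_same_group: int
    fraction_same_group: float
    group_matching: dict[str, str]              # map_a group -> map_b group
    spearman: dict[str, float]                  # per matched map_a group (signed)
    discordant: list[str] = field(default_factory=list)
    dot_plot: pd.DataFrame | None = None        # marker, pos_a, pos_b, groups


def _match_groups(pos_a: pd.DataFrame, pos_b: pd.DataFrame) -> dict[str, str]:
    """Greedy maximum shared-marker overlap, ties to the smaller group id."""
    merged = pos_a.merge(pos_b, on="marker", suffixes=("_a", "_b"))
    table = (merged.groupby(["group_a", "group_b"]).size()
             .reset_index(name="n"))
    table = table.sort_values(["n", "group_a", "group_b"],
                              ascending=[False, True, True])
    matching: dict[str, str] = {}
    used_b: set[str] = set()
    for _, row in table.iterrows():
        if row.group_a not in matching and row.group_b not in used_b:
            matching[row.group_a] = row.group_b
            used_b.add(row.group_b)
    return matching


def align_maps(map_a: GeneticMap, map_b: GeneticMap,
               group_matching: dict[str, str] | None = None) -> Concordance:
    """Shared-marker concordance of two maps.

    Group matching is user-supplied or inferred by maximal shared-marker
    overlap.  Spearman rank correlation of positions is reported per
    matched group with its sign (a reversed group gives rho = -1).
    """
    pos_a = map_a.marker_positions()[["marker", "group", "pos_cM"]]
    pos_b = map_b.marker_positions()[["marker", "group", "pos_cM"]]
    merged = pos_a.merge(pos_b, on="marker", suffixes=("_a", "_b"))
    if merged.empty:
        raise ValueError("maps share no marker ids")
    matching = group_matching or _match_groups(pos_a, pos_b)
    same = merged.apply(lambda r: matching.get(r.group_a) == r.group_b, axis=1)
    discordant = sorted(merged.loc[~same, "marker"])
    spearman: dict[str, float] = {}
    for ga, gb in matching.items():
        sub = merged[(merged.group_a == ga) & (merged.group_b == gb)]
        if len(sub) >= 2 and sub.pos_cM_a.nunique() > 1 and sub.pos_cM_b.nunique() > 1:
            rho = spearmanr(sub.pos_cM_a, sub.pos_cM_b).statistic
        else:
            rho = float("nan")
        spearman[ga] = float(rho)
    return Concordance(
        n_shared=len(merged),
        n_same_group=int(same.sum()),
        fraction_same_group=float(same.mean()),
        group_matching=matching,
        spearman=spearman,
        discordant=discordant,
        dot_plot=merged.rename(columns={"pos_cM_a": "pos_a", "pos_cM_b": "pos_b"}),
    )


def order_accuracy(built: GeneticMap, truth: GeneticMap,
                   displaced_cM: float = 5.0) -> pd.DataFrame:
    """Per-group order metrics of a built map against known true positions.

    After group matching, each group's built positions are aligned onto the
    true positions by an unconstrained least-squares affine fit (a negative
    slope absorbs a reversed orientation); reports |Spearman rho|, Kendall
    tau and the fraction of markers displaced beyond ``displaced_cM`` after
    alignment.  Groups with fewer than 3 shared markers get NaN metrics.
    """
    conc = align_maps(built, truth)
    merged = conc.dot_plot
    rows = []
    for ga, gb in conc.group_matching.items():
        sub = merged[(merged.group_a == ga) & (merged.group_b == gb)]
        if len(sub) < 3:
            rows.append({"group": ga, "truth_group": gb, "n_shared": len(sub),
                         "abs_spearman": np.nan, "kendall_tau": np.nan,
                         "frac_displaced": np.nan})
            continue
        x = sub.pos_a.to_numpy(dtype=float)
        t = sub.pos_b.to_numpy(dtype=float)
        rho = spearmanr(x, t).statistic
        tau = kendalltau(x, t).statistic
        coef = np.polyfit(x, t, 1)
        resid = np.abs(np.polyval(coef, x) - t)
        rows.append({"group": ga, "truth_group": gb, "n_shared": len(sub),
                     "abs_spearman": abs(float(rho)),
                     "kendall_tau": float(tau),
                     "frac_displaced": float((resid > displaced_cM).mean())})
    return pd.DataFrame(rows)
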