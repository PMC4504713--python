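"""Interval mapping and MQM-style cofactor scans for a DH population.

The scan uses Haley-Knott regression: at each evaluation point the expected
genotype score x in [-1, +1] is computed from the flanking bins via
no-interference (Haldane) conditional probabilities, and the phenotype is
regressed on x.  LOD = (n/2) log10(RSS0/RSS1); the additive effect is the
regression slope (half the difference between the two genotype-class means)
and PVE = 100 (1 - RSS1/RSS0).  Genome-wide significance comes from
permutation of the phenotypes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genmap import GeneticMap
from .linkage import haldane_r

logger = logging.getLogger(__name__)

LOD_CAP = 50.0   # reported LOD for a numerically perfect fit


@dataclass
class ScanDesign:
    """Evaluation grid + expected-genotype design for one genetic map."""

    points: pd.DataFrame          # columns: group, pos_cM, is_bin
    X: np.ndarray                 # (n_points, n_lines) expected genotype
    line_ids: list[str]


def _group_grid(positions: np.ndarray, step: float) -> np.ndarray:
    grid = np.arange(0.0, positions[-1] + 1e-9, step)
    return np.unique(np.concatenate([positions, grid]))


def build_design(genetic_map: GeneticMap, step_cM: float = 1.0) -> ScanDesign:
    """Expected genotype score at every bin position plus a regular grid.

    Per line, the score at a point uses the nearest informative (non-
    missing) bins on each side; with both flanks, conditional probabilities
    follow the no-interference Markov model; with one flank the marginal
    expectation from that flank alone; with none, 0.
    """
    if genetic_map.line_ids is None:
        raise ValueError("map has no genotype vectors: attach_genotypes first")
    n = len(genetic_map.line_ids)
    frames, designs = [], []
    for g in genetic_map.groups:
        pos = np.array([b.position for b in g.bins])
        geno = np.vstack([b.genotype for b in g.bins])     # bins x lines
        pts = _group_grid(pos, step_cM)
        Xg = np.zeros((pts.size, n))
        for li in range(n):
            calls = geno[:, li]
            inf = np.flatnonzero(calls != 0)
            if inf.size == 0:
                continue
            pi, gi = pos[inf], calls[inf].astype(float)
            left = np.searchsorted(pi, pts, side="right") - 1
            right = np.searchsorted(pi, pts, side="left")
            has_l, has_r = left >= 0, right < pi.size
            wa = np.ones(pts.size)
            wb = np.ones(pts.size)
            l_idx = np.clip(left, 0, None)
            rl = haldane_r(pts - pi[l_idx])
            ta = np.where(gi[l_idx] > 0, 1.0 - rl, rl)
            wa = np.where(has_l, wa * ta, wa)
            wb = np.where(has_l, wb * (1.0 - ta), wb)
            r_idx = np.clip(right, None, pi.size - 1)
            rr = haldane_r(pi[r_idx] - pts)
            ta = np.where(gi[r_idx] > 0, 1.0 - rr, rr)
            wa = np.where(has_r, wa * ta, wa)
            wb = np.where(has_r, wb * (1.0 - ta), wb)
            both = has_l | has_r
            Xg[both, li] = (wa[both] - wb[both]) / (wa[both] + wb[both])
        frames.append(pd.DataFrame({"group": g.name, "pos_cM": pts,
                                    "is_bin": np.isin(pts, pos)}))
        designs.append(Xg)
    points = pd.concat(frames, ignore_index=True)
    return ScanDesign(points=points, X=np.vstack(designs),
                      line_ids=list(genetic_map.line_ids))


def _align_phenotype(design: ScanDesign, phenotypes: pd.Series
                     ) -> tuple[np.ndarray, np.ndarray]:
    pheno = phenotypes.dropna()
    keep = [i for i, l in enumerate(design.line_ids) if l in pheno.index]
    if len(keep) < 10:
        raise ValueError(f"only {len(keep)} informative lines (need >= 10)")
    y = pheno.loc[[design.line_ids[i] for i in keep]].to_numpy(dtype=float)
    return design.X[:, keep], y


def _lod_from_rss(rss0: float, rss1: np.ndarray, n: int) -> np.ndarray:
    with np.errstate(divide="ignore"):
        lod = 0.5 * n * np.log10(rss0 / np.maximum(rss1, 0.0))
    capped = ~np.isfinite(lod) | (lod > LOD_CAP)
    if np.any(capped):
        logger.warning("LOD capped at %.0f for %d point(s) with a "
                       "numerically perfect fit", LOD_CAP, int(capped.sum()))
    return np.where(capped, LOD_CAP, lod)


def interval_scan(genetic_map: GeneticMap, phenotypes: pd.Series,
                  step_cM: float = 1.0, design: ScanDesign | None = None
                  ) -> pd.DataFrame:
    """Genome scan; returns group, pos_cM, lod, effect, pve per point."""
    design = design or build_design(genetic_map, step_cM)
    X, y = _align_phenotype(design, phenotypes)
    n = y.size
    yc = y - y.mean()
    rss0 = float(yc @ yc)
    out = design.points.copy()
    if rss0 == 0.0:
        out["lod"] = 0.0
        out["effect"] = 0.0
        out["pve"] = 0.0
        return out
    Xc = X - X.mean(axis=1, keepdims=True)
    sxx = (Xc ** 2).sum(axis=1)
    sxy = Xc @ yc
    ok = sxx > 1e-12
    effect = np.where(ok, sxy / np.where(ok, sxx, 1.0), 0.0)
    rss1 = np.where(ok, rss0 - sxy ** 2 / np.where(ok, sxx, 1.0), rss0)
    out["lod"] = _lod_from_rss(rss0, rss1, n)
    out["effect"] = effect
    out["pve"] = 100.0 * (1.0 - rss1 / rss0)
    return out


def permutation_threshold(genetic_map: GeneticMap, phenotypes: pd.Series,
                          n_perm: int = 10000, alpha: float = 0.05,
                          seed: int = 0, step_cM: float = 1.0,
                          design: ScanDesign | None = None) -> float:
    """Genome-wide LOD threshold: empirical (1-alpha) quantile of the
    permutation distribution of the maximum LOD (phenotypes shuffled
    across lines)."""
    if n_perm < 100:
        logger.warning("permutation_threshold: n_perm=%d gives an unstable "
                       "quantile estimate", n_perm)
    design = design or build_design(genetic_map, step_cM)
    X, y = _align_phenotype(design, phenotypes)
    n = y.size
    rng = np.random.default_rng(seed)
    yc = y - y.mean()
    rss0 = float(yc @ yc)
    if rss0 == 0.0:
        return 0.0
    Xc = X - X.mean(axis=1, keepdims=True)
    sxx = (Xc ** 2).sum(axis=1)
    ok = sxx > 1e-12
    perm = np.vstack([rng.permutation(n) for _ in range(n_perm)])
    Y = yc[perm]                                   # n_perm x n
    sxy = Xc @ Y.T                                 # points x n_perm
    with np.errstate(divide="ignore", invalid="ignore"):
        rss1 = rss0 - np.where(ok[:, None], sxy ** 2 / np.where(ok, sxx, 1.0)[:, None], 0.0)
        lod = 0.5 * n * np.log10(rss0 / np.maximum(rss1, 1e-300))
    lod = np.minimum(lod, LOD_CAP)
    max_lod = lod.max(axis=0)
    return float(np.quantile(max_lod, 1.0 - alpha))   # type-7 interpolation


def _residualize(M: np.ndarray, basis: np.ndarray) -> np.ndarray:
    """Residuals of the columns/vector M after projecting out `basis`."""
    q, _ = np.linalg.qr(basis)
    return M - q @ (q.T @ M)


def mqm_scan(genetic_map: GeneticMap, phenotypes: pd.Series,
             cofactor_markers: list[str], window_cM: float = 10.0,
             step_cM: float = 1.0, design: ScanDesign | None = None
             ) -> pd.DataFrame:
    """Interval scan with marker cofactors absorbing background QTL.

    Cofactors within ``window_cM`` of the evaluation point (same group) are
    dropped from the model at that point; LOD compares the models with and
    without the local QTL term only.  An empty cofactor list reduces
    exactly to :func:`interval_scan`.
    """
    design = design or build_design(genetic_map, step_cM)
    if not cofactor_markers:
        return interval_scan(genetic_map, phenotypes, step_cM, design=design)
    positions = genetic_map.marker_positions().set_index("marker")
    missing = [m for m in cofactor_markers if m not in positions.index]
    if missing:
        raise ValueError(f"cofactors not on the map: {missing}")
    X, y = _align_phenotype(design, phenotypes)
    n = y.size
    pts = design.points

    # cofactor design rows = expected genotype at the cofactor's own position
    cof_rows, cof_group, cof_pos = [], [], []
    for m in cofactor_markers:
        grp = positions.loc[m, "group"]
        pos = float(positions.loc[m, "pos_cM"])
        sel = (pts.group == grp) & np.isclose(pts.pos_cM, pos)
        row = int(np.flatnonzero(sel)[0])
        cof_rows.append(X[row])
        cof_group.append(grp)
        cof_pos.append(pos)
    C = np.vstack(cof_rows).T                       # n x n_cof
    if np.linalg.matrix_rank(np.column_stack([np.ones(n), C])) < C.shape[1] + 1:
        logger.warning("mqm_scan: collinear cofactors; least-squares fit "
                       "uses the pseudo-inverse")

    active = np.ones((len(pts), len(cofactor_markers)), dtype=bool)
    for k, (grp, pos) in enumerate(zip(cof_group, cof_pos)):
        same = (pts.group == grp).to_numpy()
        active[same & (np.abs(pts.pos_cM.to_numpy() - pos) <= window_cM), k] = False

    lod = np.zeros(len(pts))
    effect = np.zeros(len(pts))
    pve = np.zeros(len(pts))
    for sig in np.unique(active, axis=0):
        rows = np.flatnonzero((active == sig).all(axis=1))
        basis = np.column_stack([np.ones(n), C[:, sig]])
        yr = _residualize(y, basis)
        rss0 = float(yr @ yr)
        Xr = _residualize(X[rows].T, basis).T
        sxx = (Xr ** 2).sum(axis=1)
        sxy = Xr @ yr
        ok = sxx > 1e-12
        b = np.where(ok, sxy / np.where(ok, sxx, 1.0), 0.0)
        rss1 = np.where(ok, rss0 - sxy ** 2 / np.where(ok, sxx, 1.0), rss0)
        if rss0 == 0.0:
            continue
        lod[rows] = _lod_from_rss(rss0, rss1, n)
        effect[rows] = b
        pve[rows] = 100.0 * (1.0 - rss1 / rss0)
    out = pts.copy()
    out["lod"] = lod
    out["effect"] = effect
    out["pve"] = pve
    return out


def summarize_qtl(profile: pd.DataFrame, threshold: float,
                  genetic_map: GeneticMap | None = None) -> pd.DataFrame:
    """Merge contiguous super-threshold segments into declared QTL.

    Per segment: peak position and LOD, additive effect and PVE at the
    peak, nearest mapped bins left/right of the peak, and the 1-LOD
    support interval.  An empty frame (no point above threshold) is a
    valid result, not an error.
    """
    bin_pos: dict[str, list[tuple[float, str]]] = {}
    if genetic_map is not None:
        for g in genetic_map.groups:
            bin_pos[g.name] = [(b.position, b.name) for b in g.bins]
    rows = []
    for grp, sub in profile.groupby("group", sort=False):
        sub = sub.sort_values("pos_cM").reset_index(drop=True)
        above = (sub.lod >= threshold).to_numpy()
        if not above.any():
            continue
        edges = np.diff(above.astype(int))
        starts = list(np.flatnonzero(edges == 1) + 1)
        ends = list(np.flatnonzero(edges == -1) + 1)
        if above[0]:
            starts = [0] + starts
        if above[-1]:
            ends = ends + [len(sub)]
        for s, e in zip(starts, ends):
            seg = sub.iloc[s:e]
            peak = seg.loc[seg.lod.idxmax()]
            # 1-LOD support interval around the peak
            lo_i = hi_i = int(seg.lod.idxmax())
            while lo_i > 0 and sub.lod[lo_i - 1] >= peak.lod - 1.0:
                lo_i -= 1
            while hi_i < len(sub) - 1 and sub.lod[hi_i + 1] >= peak.lod - 1.0:
                hi_i += 1
            left = right = ""
            if grp in bin_pos:
                lefts = [(p, m) for p, m in bin_pos[grp] if p <= peak.pos_cM]
                rights = [(p, m) for p, m in bin_pos[grp] if p >= peak.pos_cM]
                left = max(lefts)[1] if lefts else ""
                right = min(rights)[1] if rights else ""
            rows.append({"group": grp, "peak_cM": float(peak.pos_cM),
                         "lod": float(peak.lod), "effect": float(peak.effect),
                         "pve": float(peak.pve), "left_marker": left,
                         "right_marker": right, "threshold": threshold,
                         "ci_lo_cM": float(sub.pos_cM[lo_i]),
                         "ci_hi_cM": float(sub.pos_cM[hi_i])})
    return pd.DataFrame(rows, columns=["group", "peak_cM", "lod", "effect",
                                       "pve", "left_marker", "right_marker",
                                       "threshold", "ci_lo_cM", "ci_hi_cM"])


def declare_qtl(genetic_map: GeneticMap, phenotypes: pd.Series,
                n_perm: int = 1000, alpha: float = 0.05, seed: int = 0,
                step_cM: float = 1.0
                ) -> tuple[pd.DataFrame, pd.DataFrame, float]:
    """Two-stage QTL declaration: interval scan, then an MQM pass.

    Interval analysis locates the strongest peak; the closest mapped
    marker becomes a cofactor and the final profile is the MQM scan, so
    linked shoulders of a major QTL are absorbed before segments are
    declared against the genome-wide permutation threshold.  Returns
    (final profile, QTL report, threshold).
    """
    design = build_design(genetic_map, step_cM)
    profile = interval_scan(genetic_map, phenotypes, design=design)
    threshold = permutation_threshold(genetic_map, phenotypes, n_perm=n_perm,
                                      alpha=alpha, seed=seed, design=design)
    peak = profile.loc[profile.lod.idxmax()]
    if peak.lod >= threshold:
        positions = genetic_map.marker_positions()
        grp = positions[positions.group == peak.group]
        cofactor = str(grp.iloc[(grp.pos_cM - peak.pos_cM).abs().argmin()].marker)
        profile = mqm_scan(genetic_map, phenotypes, [cofactor], design=design)
    report = summarize_qtl(profile, threshold, genetic_map)
    return profile, report, threshold


def forward_select_cofactors(genetic_map: GeneticMap, phenotypes: pd.Series,
                             threshold: float, max_cofactors: int = 5,
                             step_cM: float = 1.0) -> list[str]:
    """Greedy helper: repeatedly add the peak bin as a cofactor while the
    residual scan still clears the genome-wide threshold."""
    design = build_design(genetic_map, step_cM)
    positions = genetic_map.marker_positions()
    cofactors: list[str] = []
    for _ in range(max_cofactors):
        prof = mqm_scan(genetic_map, phenotypes, cofactors,
                        step_cM=step_cM, design=design)
        peak = prof.loc[prof.lod.idxmax()]
        if peak.lod < threshold:
            break
        grp = positions[positions.group == peak.group]
        nearest = grp.iloc[(grp.pos_cM - peak.pos_cM).abs().argmin()]
        name = str(nearest.marker)
        if name in cofactors:
            break
        cofactors.append(name)
    return cofactors
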