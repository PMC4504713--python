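"""De novo genetic-map construction for a DH population.

The procedure mirrors the classic MST-based mapping recipe: pairwise
recombination statistics, grouping at a Fisher-exact p-value cutoff,
collapse of co-segregating markers into bins (map loci), marker ordering by
a minimum-spanning-tree heuristic under the COUNT objective (minimize the
total number of recombination events between adjacent bins), Kosambi map
distances, one pass of double-recombinant ("bad data") cleaning, and
splitting of linkage groups at gaps above 35 cM.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np

from .genmap import Bin, GeneticMap, LinkageGroup
from .genotypes import MISSING, GenotypeMatrix
from .snp import fisher_exact_two_sided

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# map functions
# ---------------------------------------------------------------------------

def kosambi(r: float | np.ndarray) -> float | np.ndarray:
    """Kosambi map distance in cM: d = 25 ln((1+2r)/(1-2r))."""
    r = np.asarray(r, dtype=float)
    d = 25.0 * np.log((1.0 + 2.0 * r) / (1.0 - 2.0 * r))
    return float(d) if d.ndim == 0 else d


def kosambi_inverse(d: float | np.ndarray) -> float | np.ndarray:
    """Recombination fraction from Kosambi cM: r = tanh(d/50)/2."""
    d = np.asarray(d, dtype=float)
    r = 0.5 * np.tanh(d / 50.0)
    return float(r) if r.ndim == 0 else r


def haldane_r(d: float | np.ndarray) -> float | np.ndarray:
    """Haldane (no interference): r = (1 - exp(-2d/100))/2, d in cM."""
    d = np.asarray(d, dtype=float)
    r = 0.5 * (1.0 - np.exp(-2.0 * d / 100.0))
    return float(r) if r.ndim == 0 else r


def haldane_d(r: float | np.ndarray) -> float | np.ndarray:
    r = np.asarray(r, dtype=float)
    d = -50.0 * np.log(1.0 - 2.0 * r)
    return float(d) if d.ndim == 0 else d


# ---------------------------------------------------------------------------
# pairwise statistics
# ---------------------------------------------------------------------------

@dataclass
class LinkageStats:
    marker_ids: list[str]
    n_informative: np.ndarray     # int (m, m) co-non-missing lines
    n_recombinant: np.ndarray     # int (m, m) discordant calls
    r_hat: np.ndarray             # float (m, m), NaN when uninformative
    independence_p: np.ndarray    # float (m, m) two-sided Fisher exact


def pairwise_linkage(gm: GenotypeMatrix, compute_p: bool = True) -> LinkageStats:
    """Recombination counts, r_hat and Fisher independence p per marker pair.

    Counts run over lines where both markers are called; recombinant =
    opposite parental alleles.  Uninformative pairs get r_hat = NaN and
    p = 1 (flagged unlinked).
    """
    if gm.n_markers < 2:
        raise ValueError("need at least two markers")
    G = gm.line_calls.astype(np.int32)
    Apos = (G == 1).astype(np.int32)
    Bneg = (G == -1).astype(np.int32)
    n_aa = Apos @ Apos.T
    n_ab = Apos @ Bneg.T
    n_ba = Bneg @ Apos.T
    n_bb = Bneg @ Bneg.T
    informative = n_aa + n_ab + n_ba + n_bb
    recombinant = n_ab + n_ba
    with np.errstate(invalid="ignore", divide="ignore"):
        r_hat = np.where(informative > 0, recombinant / np.maximum(informative, 1),
                         np.nan)
    p = np.ones_like(r_hat, dtype=float)
    if compute_p:
        m = gm.n_markers
        iu = np.triu_indices(m, k=1)
        for i, j in zip(*iu):
            if informative[i, j] > 0:
                p[i, j] = p[j, i] = fisher_exact_two_sided(
                    int(n_aa[i, j]), int(n_ab[i, j]),
                    int(n_ba[i, j]), int(n_bb[i, j]))
    np.fill_diagonal(p, 0.0)
    return LinkageStats(marker_ids=list(gm.marker_ids),
                        n_informative=informative, n_recombinant=recombinant,
                        r_hat=r_hat, independence_p=p)


def group_markers(stats: LinkageStats, p_cutoff: float = 1e-6
                  ) -> tuple[list[list[int]], list[int]]:
    """Linkage groups as connected components of the significance graph.

    Edge between two markers when independence_p < p_cutoff and r_hat < 0.5.
    Returns (groups, unanchored) with groups = components of size >= 2,
    sorted deterministically; unanchored = singleton markers.
    """
    from scipy.sparse import csr_matrix
    from scipy.sparse.csgraph import connected_components

    m = len(stats.marker_ids)
    with np.errstate(invalid="ignore"):
        adj = (stats.independence_p < p_cutoff) & (stats.r_hat < 0.5)
    np.fill_diagonal(adj, False)
    n_comp, labels = connected_components(csr_matrix(adj), directed=False)
    comps: dict[int, list[int]] = {}
    for i, lab in enumerate(labels):
        comps.setdefault(int(lab), []).append(i)
    groups = [sorted(v, key=lambda i: stats.marker_ids[i])
              for v in comps.values() if len(v) >= 2]
    groups.sort(key=lambda g: (-len(g), stats.marker_ids[g[0]]))
    unanchored = sorted((v[0] for v in comps.values() if len(v) == 1),
                        key=lambda i: stats.marker_ids[i])
    logger.info("group_markers: %d markers -> %d groups, %d unanchored "
                "(p_cutoff=%g)", m, len(groups), len(unanchored), p_cutoff)
    return groups, unanchored


# ---------------------------------------------------------------------------
# binning
# ---------------------------------------------------------------------------

def bin_markers(gm: GenotypeMatrix, group: list[int],
                stats: LinkageStats | None = None) -> list[Bin]:
    """Collapse co-segregating markers of one group into bins (map loci).

    Two markers share a bin iff they show zero recombinants among
    co-non-missing lines; bins are the connected-component closure of that
    relation, with members ordered by marker id.  The bin consensus call is
    the union of member calls per line; a conflict introduced by the
    closure resolves to missing (logged).
    """
    from scipy.sparse import csr_matrix
    from scipy.sparse.csgraph import connected_components

    ids = [gm.marker_ids[i] for i in group]
    sub = gm.line_calls[group]
    if stats is not None:
        rec = stats.n_recombinant[np.ix_(group, group)]
        inf = stats.n_informative[np.ix_(group, group)]
    else:
        Apos = (sub == 1).astype(np.int32)
        Bneg = (sub == -1).astype(np.int32)
        rec = Apos @ Bneg.T + Bneg @ Apos.T
        inf = rec + Apos @ Apos.T + Bneg @ Bneg.T
    adj = (rec == 0) & (inf > 0)
    np.fill_diagonal(adj, False)
    _, labels = connected_components(csr_matrix(adj), directed=False)
    bins: list[Bin] = []
    for lab in sorted(set(labels)):
        members = np.flatnonzero(labels == lab)
        calls = sub[members]
        pos = (calls == 1).any(axis=0)
        neg = (calls == -1).any(axis=0)
        conflicts = int((pos & neg).sum())
        if conflicts:
            logger.info("bin_markers: %d conflicting consensus calls in bin "
                        "of %s set to missing", conflicts,
                        ids[members[0]])
        cons = np.zeros(calls.shape[1], dtype=np.int8)
        cons[pos & ~neg] = 1
        cons[neg & ~pos] = -1
        member_ids = tuple(sorted(ids[i] for i in members))
        bins.append(Bin(marker_ids=member_ids, genotype=cons))
    bins.sort(key=lambda b: b.name)
    return bins


def _bin_counts(bins: list[Bin]) -> tuple[np.ndarray, np.ndarray]:
    """(recombination count, informative count) matrices between bins."""
    G = np.vstack([b.genotype for b in bins]).astype(np.int32)
    Apos = (G == 1).astype(np.int32)
    Bneg = (G == -1).astype(np.int32)
    rec = Apos @ Bneg.T + Bneg @ Apos.T
    inf = rec + Apos @ Apos.T + Bneg @ Bneg.T
    return rec, inf


# ---------------------------------------------------------------------------
# ordering (MST heuristic, COUNT objective)
# ---------------------------------------------------------------------------

def _path_cost(order: list[int], D: np.ndarray) -> int:
    o = np.asarray(order)
    return int(D[o[:-1], o[1:]].sum())


def _mst_edges(D: np.ndarray, names: list[str]) -> list[tuple[int, int]]:
    """Kruskal MST with (weight, name, name) tie-breaking for determinism."""
    n = D.shape[0]
    edges = sorted(((int(D[i, j]), names[i], names[j], i, j)
                    for i in range(n) for j in range(i + 1, n)),
                   key=lambda e: e[:3])
    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    out = []
    for _w, _a, _b, i, j in edges:
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[ri] = rj
            out.append((i, j))
            if len(out) == n - 1:
                break
    return out


def _tree_longest_path(n: int, edges: list[tuple[int, int]],
                       names: list[str]) -> list[int]:
    adj: dict[int, list[int]] = {i: [] for i in range(n)}
    for i, j in edges:
        adj[i].append(j)
        adj[j].append(i)
    for v in adj.values():
        v.sort(key=lambda i: names[i])

    def bfs_far(src: int) -> tuple[int, dict[int, int]]:
        prev = {src: src}
        frontier, far = [src], src
        while frontier:
            nxt = []
            for u in frontier:
                for v in adj[u]:
                    if v not in prev:
                        prev[v] = u
                        nxt.append(v)
            if nxt:
                far = min(nxt, key=lambda i: names[i])
            frontier = nxt
        return far, prev

    u, _ = bfs_far(min(range(n), key=lambda i: names[i]))
    v, prev = bfs_far(u)
    path = [v]
    while path[-1] != u:
        path.append(prev[path[-1]])
    return path


def _insert_greedy(path: list[int], others: list[int], D: np.ndarray) -> list[int]:
    path = list(path)
    for x in others:
        best_cost, best_pos = None, None
        # ends
        options = [(int(D[x, path[0]]), 0), (int(D[path[-1], x]), len(path))]
        for k in range(len(path) - 1):
            a, b = path[k], path[k + 1]
            options.append((int(D[a, x] + D[x, b] - D[a, b]), k + 1))
        for cost, pos in options:
            if best_cost is None or cost < best_cost:
                best_cost, best_pos = cost, pos
        path.insert(best_pos, x)
    return path


def _two_opt(path: list[int], D: np.ndarray, window: int | None) -> list[int]:
    """2-opt segment reversals + single-node relocations to a local optimum."""
    path = list(path)
    n = len(path)
    improved = True
    guard = 0
    while improved and guard < 200:
        guard += 1
        improved = False
        # segment reversal [i, j]
        for i in range(n - 1):
            jmax = n if window is None else min(n, i + 1 + window)
            for j in range(i + 1, jmax):
                left = D[path[i - 1], path[j]] if i > 0 else 0
                right = D[path[i], path[j + 1]] if j < n - 1 else 0
                old_l = D[path[i - 1], path[i]] if i > 0 else 0
                old_r = D[path[j], path[j + 1]] if j < n - 1 else 0
                if left + right < old_l + old_r:
                    path[i:j + 1] = path[i:j + 1][::-1]
                    improved = True
        # or-opt: relocate a segment of 1..3 nodes (either orientation)
        for seg_len in (1, 2, 3):
            if seg_len >= n:
                continue
            for i in range(n - seg_len + 1):
                seg = path[i:i + seg_len]
                rest = path[:i] + path[i + seg_len:]
                removed = 0
                if i > 0:
                    removed += D[path[i - 1], seg[0]]
                if i + seg_len < n:
                    removed += D[seg[-1], path[i + seg_len]]
                if 0 < i and i + seg_len < n:
                    removed -= D[path[i - 1], path[i + seg_len]]
                best_gain, best_ins = 0, None
                for variant in (seg, seg[::-1]) if seg_len > 1 else (seg,):
                    for k in range(len(rest) + 1):
                        if k == 0:
                            added = D[variant[-1], rest[0]]
                        elif k == len(rest):
                            added = D[rest[-1], variant[0]]
                        else:
                            added = (D[rest[k - 1], variant[0]]
                                     + D[variant[-1], rest[k]]
                                     - D[rest[k - 1], rest[k]])
                        gain = removed - added
                        if gain > best_gain:
                            best_gain, best_ins = gain, (list(variant), k)
                if best_ins is not None:
                    variant, k = best_ins
                    path = rest[:k] + variant + rest[k:]
                    improved = True
                    n = len(path)
    return path


def order_bins(bins: list[Bin], window: int = 20, n_restarts: int = 4
               ) -> list[Bin]:
    """Order bins to (approximately) minimize the COUNT objective.

    Seed order = longest path of the minimum spanning tree over pairwise
    recombination counts, off-path bins inserted greedily, then polished by
    2-opt/relocation local search (full-width for small groups, windowed
    for large ones).  A few deterministic random restarts guard against
    local optima.  Orientation is canonical: the lexicographically smaller
    terminal-bin marker id sits at position 0.
    """
    if len(bins) <= 2:
        return sorted(bins, key=lambda b: b.name)
    D, _inf = _bin_counts(bins)
    n = len(bins)
    names = [b.name for b in bins]
    win = None if n <= 30 else window

    edges = _mst_edges(D, names)
    seed_path = _tree_longest_path(n, edges, names)
    on_path = set(seed_path)
    others = sorted((i for i in range(n) if i not in on_path),
                    key=lambda i: names[i])
    best = _two_opt(_insert_greedy(seed_path, others, D), D, win)
    best_cost = _path_cost(best, D)

    rng = np.random.default_rng(12345)  # fixed: restarts are part of the algorithm
    for _ in range((3 * n_restarts) if n <= 12 else 1):
        cand = _two_opt(list(rng.permutation(n)), D, win)
        cost = _path_cost(cand, D)
        if cost < best_cost or (cost == best_cost and cand < best):
            best, best_cost = cand, cost

    if names[best[-1]] < names[best[0]]:
        best = best[::-1]
    return [bins[i] for i in best]


def brute_force_order(bins: list[Bin]) -> tuple[list[int], int]:
    """Exhaustive COUNT-optimal order (reference, feasible for <= ~9 bins)."""
    D, _ = _bin_counts(bins)
    n = len(bins)
    best, best_cost = None, None
    for perm in itertools.permutations(range(n)):
        if perm[0] > perm[-1]:      # each order once, up to reversal
            continue
        cost = _path_cost(list(perm), D)
        if best_cost is None or cost < best_cost:
            best, best_cost = list(perm), cost
    return best, int(best_cost)


# ---------------------------------------------------------------------------
# distances, cleaning, splitting
# ---------------------------------------------------------------------------

def map_distances(bins: list[Bin]) -> list[Bin]:
    """Cumulative Kosambi positions from adjacent-bin recombination fractions.

    r >= 0.5 (possible under noise) is clamped to 0.4999 with a warning.
    """
    rec, inf = _bin_counts(bins)
    pos = 0.0
    bins[0].position = 0.0
    for k in range(1, len(bins)):
        a, b = k - 1, k
        if inf[a, b] == 0:
            r = 0.4999
            logger.warning("map_distances: uninformative adjacent bins "
                           "%s/%s", bins[a].name, bins[b].name)
        else:
            r = rec[a, b] / inf[a, b]
            if r >= 0.5:
                logger.warning("map_distances: r=%.3f clamped to 0.4999 "
                               "between %s and %s", r, bins[a].name, bins[b].name)
                r = 0.4999
        pos += kosambi(r)
        bins[k].position = pos
    return bins


def detect_bad_data(gm: GenotypeMatrix, genetic_map: GeneticMap,
                    window: int = 1) -> tuple[GenotypeMatrix, list[dict]]:
    """One pass of double-recombinant singleton cleaning.

    A line's call at a bin that differs from both immediately flanking
    bins' calls where those flanks agree is almost surely a genotyping
    error at tight spacing; it is set to missing in the returned copy of
    the genotype matrix (and in the bin consensus) and reported.
    """
    gm = GenotypeMatrix(marker_ids=list(gm.marker_ids),
                        individuals=list(gm.individuals),
                        calls=gm.calls.copy(), parent_ids=gm.parent_ids)
    line_cols = [k for k, i in enumerate(gm.individuals)
                 if i not in gm.parent_ids]
    midx = {m: i for i, m in enumerate(gm.marker_ids)}
    report: list[dict] = []
    for g in genetic_map.groups:
        if len(g.bins) < 3:
            continue
        G = np.vstack([b.genotype for b in g.bins])  # bins x lines
        for k in range(window, len(g.bins) - window):
            left, mid, right = G[k - window], G[k], G[k + window]
            bad = (left != MISSING) & (right != MISSING) & (left == right) \
                & (mid != MISSING) & (mid != left)
            for line in np.flatnonzero(bad):
                report.append({"group": g.name, "bin": k, "line": line,
                               "old_call": int(mid[line])})
                g.bins[k].genotype[line] = MISSING
                for m in g.bins[k].marker_ids:
                    if m in midx:
                        gm.calls[midx[m], line_cols[line]] = MISSING
    if report:
        logger.info("detect_bad_data: %d singleton calls set to missing",
                    len(report))
    return gm, report


def split_gaps(genetic_map: GeneticMap, threshold_cM: float = 35.0) -> GeneticMap:
    """Split linkage groups at adjacent-bin gaps strictly above threshold."""
    new_groups: list[LinkageGroup] = []
    for g in genetic_map.groups:
        segments: list[list[Bin]] = [[]]
        prev_pos = None
        for b in g.bins:
            if prev_pos is not None and b.position - prev_pos > threshold_cM:
                segments.append([])
            segments[-1].append(b)
            prev_pos = b.position
        for si, seg in enumerate(segments):
            base = seg[0].position
            for b in seg:
                b.position -= base
            suffix = "" if len(segments) == 1 else f".{si + 1}"
            new_groups.append(LinkageGroup(name=g.name + suffix, bins=seg))
        if len(segments) > 1:
            logger.info("split_gaps: group %s split into %d at gaps > %.1f cM",
                        g.name, len(segments), threshold_cM)
    renamed = [LinkageGroup(name=f"LG{k + 1:02d}", bins=g.bins)
               for k, g in enumerate(new_groups)]
    return GeneticMap(groups=renamed, line_ids=genetic_map.line_ids)


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------

def build_map(gm: GenotypeMatrix, p_cutoff: float = 1e-6,
              gap_threshold_cM: float = 35.0, detect_bad: bool = True
              ) -> tuple[GeneticMap, list[str], dict]:
    """Full map construction; returns (map, unanchored marker ids, report)."""
    stats = pairwise_linkage(gm)
    groups, unanchored_idx = group_markers(stats, p_cutoff=p_cutoff)
    lgs: list[LinkageGroup] = []
    for gi, group in enumerate(groups):
        bins = bin_markers(gm, group, stats=stats)
        bins = order_bins(bins)
        bins = map_distances(bins)
        lgs.append(LinkageGroup(name=f"G{gi + 1:02d}", bins=bins))
    gmap = GeneticMap(groups=lgs, line_ids=gm.line_ids)
    bad_report: list[dict] = []
    if detect_bad:
        gm, bad_report = detect_bad_data(gm, gmap)
        for g in gmap.groups:       # re-estimate distances on cleaned bins
            map_distances(g.bins)
    gmap = split_gaps(gmap, threshold_cM=gap_threshold_cM)
    unanchored = [gm.marker_ids[i] for i in unanchored_idx]
    report = {"n_markers": gm.n_markers, "n_groups": len(gmap.groups),
              "n_mapped": gmap.n_markers, "n_unanchored": len(unanchored),
              "n_bad_calls": len(bad_report),
              "total_length_cM": gmap.total_length_cM}
    logger.info("build_map: %s", report)
    return gmap, unanchored, report
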