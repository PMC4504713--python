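"""Reference-free SNP calling from a population tag catalog.

A candidate SNP is a pair of tags identical except at 1 or 2 positions (the
two alleles of one locus).  True alternative alleles in a doubled-haploid
population are mutually exclusive within a line, so a pair must show
significant *negative* association in a two-sided Fisher exact test of
presence/absence across the lines.  Genotypes are phased against the two
parents (A = the AC Metcalfe-analog parent's tag, B = the other parent's)
and the missing-data filters are applied in two tiers: markers with more
than 20 missing calls are removed outright, and the map-construction set
additionally requires a missing rate strictly below 7%.
"""

from __future__ import annotations

import hashlib
import logging
from collections import defaultdict
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy.stats import hypergeom

from .demux import TagCatalog
from .genotypes import A, B, MISSING, GenotypeMatrix

logger = logging.getLogger(__name__)


def marker_name(tag_a: str, tag_b: str) -> str:
    """Deterministic marker id from the unordered allele-tag pair."""
    lo, hi = sorted((tag_a, tag_b))
    digest = hashlib.blake2b(f"{lo}|{hi}".encode(), digest_size=6).hexdigest()
    # offset of the first mismatching base, for human readability
    off = next(i for i, (x, y) in enumerate(zip(lo, hi)) if x != y)
    return f"snp_{digest}_{off:02d}"


# ---------------------------------------------------------------------------
# Fisher exact kernel
# ---------------------------------------------------------------------------

@lru_cache(maxsize=1 << 20)
def fisher_exact_two_sided(n11: int, n10: int, n01: int, n00: int) -> float:
    """Two-sided Fisher exact probability of a 2x2 table.

    Sums, over the hypergeometric support of the top-left cell with margins
    fixed, every point probability not exceeding the observed one (with a
    1e-7 relative slack so mathematically tied tables are counted despite
    floating-point rounding).  Degenerate margins return 1 by convention.
    """
    r1, r2 = n11 + n10, n01 + n00
    c1 = n11 + n01
    n = r1 + r2
    if r1 == 0 or r2 == 0 or c1 == 0 or c1 == n:
        return 1.0
    lo, hi = max(0, c1 - r2), min(r1, c1)
    support = np.arange(lo, hi + 1)
    pmf = hypergeom.pmf(support, n, r1, c1)
    p_obs = pmf[n11 - lo]
    p = float(pmf[pmf <= p_obs * (1 + 1e-7)].sum())
    return min(p, 1.0)


# ---------------------------------------------------------------------------
# allele-pair discovery
# ---------------------------------------------------------------------------

@dataclass
class AllelePair:
    tag_a: str                       # lexicographically smaller tag
    tag_b: str
    mismatch_positions: tuple[int, ...]
    fisher_p: float | None = None
    presence_fraction: float | None = None

    @property
    def name(self) -> str:
        return marker_name(self.tag_a, self.tag_b)


def _hamming_pairs_index(tags: list[str], max_mismatch: int) -> set[tuple[int, int]]:
    """Candidate pairs by pigeonhole partition: split each tag into
    max_mismatch+1 blocks; two tags within max_mismatch mismatches must
    agree exactly on at least one block."""
    L = len(tags[0])
    n_blocks = max_mismatch + 1
    bounds = np.linspace(0, L, n_blocks + 1).astype(int)
    candidates: set[tuple[int, int]] = set()
    for b in range(n_blocks):
        lo, hi = bounds[b], bounds[b + 1]
        buckets: dict[str, list[int]] = defaultdict(list)
        for i, t in enumerate(tags):
            buckets[t[lo:hi]].append(i)
        for members in buckets.values():
            for k, i in enumerate(members):
                for j in members[k + 1:]:
                    candidates.add((i, j) if i < j else (j, i))
    return candidates


def find_allele_pairs(catalog: TagCatalog, max_mismatch: int = 2,
                      multi_pair: str = "discard") -> list[AllelePair]:
    """All unordered tag pairs at Hamming distance 1..max_mismatch.

    Candidates come from the pigeonhole block index and are verified by a
    full Hamming comparison, so the result equals a brute-force all-pairs
    scan.  A tag participating in more than one pair is a putative paralog:
    by default every pair touching it is discarded (``multi_pair='best'``
    keeps the lowest-Fisher-p pair after testing instead — the flag is
    honored by :func:`call_markers`).
    """
    if not catalog.tags:
        raise ValueError("empty tag catalog")
    lengths = {len(t) for t in catalog.tags}
    if len(lengths) != 1:
        raise ValueError(f"mixed tag lengths: {sorted(lengths)}")
    if multi_pair not in ("discard", "keep", "best"):
        raise ValueError("multi_pair must be 'discard', 'keep' or 'best'")

    tags = catalog.tags
    pairs: list[AllelePair] = []
    degree: dict[int, int] = defaultdict(int)
    for i, j in sorted(_hamming_pairs_index(tags, max_mismatch)):
        ti, tj = tags[i], tags[j]
        mm = tuple(k for k, (x, y) in enumerate(zip(ti, tj)) if x != y)
        if 1 <= len(mm) <= max_mismatch:
            a, b = sorted((ti, tj))
            pairs.append(AllelePair(tag_a=a, tag_b=b, mismatch_positions=mm))
            degree[i] += 1
            degree[j] += 1
    if multi_pair == "discard":
        multi = {tags[i] for i, d in degree.items() if d > 1}
        kept = [p for p in pairs
                if p.tag_a not in multi and p.tag_b not in multi]
        if len(kept) != len(pairs):
            logger.info("find_allele_pairs: discarded %d pairs touching %d "
                        "multi-pair tags", len(pairs) - len(kept), len(multi))
        pairs = kept
    return pairs


# ---------------------------------------------------------------------------
# Fisher screening and genotype calling
# ---------------------------------------------------------------------------

def fisher_independence(pair: AllelePair, catalog: TagCatalog) -> float:
    """Two-sided Fisher exact p for the presence/absence 2x2 of the two
    tags across the non-parent individuals; stored on the pair."""
    idx = catalog.tag_index()
    cols = catalog.line_columns
    pa = catalog.presence[idx[pair.tag_a]][cols]
    pb = catalog.presence[idx[pair.tag_b]][cols]
    n11 = int((pa & pb).sum())
    n10 = int((pa & ~pb).sum())
    n01 = int((~pa & pb).sum())
    n00 = int((~pa & ~pb).sum())
    pair.fisher_p = fisher_exact_two_sided(n11, n10, n01, n00)
    pair.presence_fraction = (n11 + n10 + n01) / max(len(cols), 1)
    return pair.fisher_p


def _negative_association(pa: np.ndarray, pb: np.ndarray) -> bool:
    n = pa.size
    if n == 0:
        return False
    n11 = float((pa & pb).sum())
    return n11 * n < pa.sum() * pb.sum()  # observed joint below independence


@dataclass
class MarkerCall:
    marker_id: str
    pair: AllelePair
    calls: np.ndarray        # int8 over catalog.individuals (parents included)
    missing: int             # missing among non-parent lines


def call_marker(pair: AllelePair, catalog: TagCatalog,
                parent_ids: tuple[str, str] | None = None
                ) -> tuple[MarkerCall | None, str]:
    """Phase a tested pair against the parents and call every line.

    Callable only when parent 1 carries exactly one tag of the pair and
    parent 2 only the other.  Per line: parent-1 tag only -> A, parent-2
    tag only -> B, both (heterozygous signal, impossible in a true DH) ->
    missing, neither -> missing.  Returns (call, reason) with call None
    when the pair is rejected.
    """
    parent_ids = parent_ids or catalog.parent_ids
    idx = catalog.tag_index()
    pres = catalog.presence
    col = {ind: k for k, ind in enumerate(catalog.individuals)}
    p1, p2 = (col[p] for p in parent_ids)
    a_row, b_row = pres[idx[pair.tag_a]], pres[idx[pair.tag_b]]

    p1_has = (bool(a_row[p1]), bool(b_row[p1]))
    p2_has = (bool(a_row[p2]), bool(b_row[p2]))
    if p1_has == (True, False) and p2_has == (False, True):
        parent1_tag_is_a = True
    elif p1_has == (False, True) and p2_has == (True, False):
        parent1_tag_is_a = False
    elif True not in p1_has or True not in p2_has:
        return None, "absent_in_parent"
    else:
        return None, "unphaseable"

    t1 = a_row if parent1_tag_is_a else b_row   # parent-1 allele presence
    t2 = b_row if parent1_tag_is_a else a_row
    calls = np.zeros(len(catalog.individuals), dtype=np.int8)
    calls[t1 & ~t2] = A
    calls[t2 & ~t1] = B
    calls[t1 & t2] = MISSING                    # heterozygous signal discarded
    calls[col[parent_ids[0]]] = A
    calls[col[parent_ids[1]]] = B
    line_cols = catalog.line_columns
    missing = int((calls[line_cols] == MISSING).sum())
    return MarkerCall(marker_id=pair.name, pair=pair,
                      calls=calls, missing=missing), "ok"


def call_markers(catalog: TagCatalog, max_mismatch: int = 2,
                 alpha: float = 0.01, multi_pair: str = "discard"
                 ) -> tuple[list[MarkerCall], dict[str, int]]:
    """Pair discovery + Fisher screen + parental phasing, with a funnel tally."""
    pairs = find_allele_pairs(catalog, max_mismatch=max_mismatch,
                              multi_pair=multi_pair)
    tally = {"pairs": len(pairs), "fisher_fail": 0, "absent_in_parent": 0,
             "unphaseable": 0, "called": 0}
    idx = catalog.tag_index()
    cols = catalog.line_columns
    tested: list[AllelePair] = []
    for pair in pairs:
        fisher_independence(pair, catalog)
        pa = catalog.presence[idx[pair.tag_a]][cols]
        pb = catalog.presence[idx[pair.tag_b]][cols]
        if pair.fisher_p < alpha and _negative_association(pa, pb):
            tested.append(pair)
        else:
            tally["fisher_fail"] += 1
    if multi_pair == "best":
        by_tag: dict[str, list[AllelePair]] = defaultdict(list)
        for p in tested:
            by_tag[p.tag_a].append(p)
            by_tag[p.tag_b].append(p)
        drop: set[str] = set()
        for tag, plist in by_tag.items():
            if len(plist) > 1:
                best = min(plist, key=lambda p: (p.fisher_p, p.name))
                drop.update(p.name for p in plist if p is not best)
        tested = [p for p in tested if p.name not in drop]
    markers: list[MarkerCall] = []
    for pair in tested:
        call, reason = call_marker(pair, catalog)
        if call is None:
            tally[reason] += 1
        else:
            markers.append(call)
            tally["called"] += 1
    logger.info("call_markers funnel: %s", tally)
    return markers, tally


def filter_markers(markers: list[MarkerCall], catalog: TagCatalog,
                   min_presence: float = 0.80, max_missing_abs: int = 20,
                   max_missing_rate: float = 0.07
                   ) -> tuple[GenotypeMatrix, GenotypeMatrix, dict[str, int]]:
    """Missing-data filters, applied in order.

    (1) drop markers whose tag-pair presence fraction is <= min_presence
    (strict >); (2) drop markers with more than ``max_missing_abs`` missing
    calls; (3) the map-construction tier additionally keeps only markers
    with missing rate strictly below ``max_missing_rate``.  Returns
    (selected, map_tier, tally) — the paper-style two-tier output.
    """
    n_lines = len(catalog.line_columns)
    tally = {"in": len(markers)}
    step1 = [m for m in markers if m.pair.presence_fraction is not None
             and m.pair.presence_fraction > min_presence]
    tally["after_presence"] = len(step1)
    step2 = [m for m in step1 if m.missing <= max_missing_abs]
    tally["after_missing_abs"] = len(step2)
    step3 = [m for m in step2 if m.missing / n_lines < max_missing_rate]
    tally["map_tier"] = len(step3)
    logger.info("filter_markers funnel: %s", tally)

    def build(subset: list[MarkerCall]) -> GenotypeMatrix:
        subset = sorted(subset, key=lambda m: m.marker_id)
        calls = (np.vstack([m.calls for m in subset]) if subset
                 else np.empty((0, len(catalog.individuals)), np.int8))
        return GenotypeMatrix(marker_ids=[m.marker_id for m in subset],
                              individuals=list(catalog.individuals),
                              calls=calls, parent_ids=catalog.parent_ids)

    return build(step2), build(step3), tally
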