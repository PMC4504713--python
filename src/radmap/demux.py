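"""Demultiplexing, tag clustering and the population tag catalog.

Reads are assigned to individuals by their 8 nt MID barcode prefix, trimmed
to the 92 bp tag, and identical tags within an individual are collapsed to
(tag, count) entries.  Tags backed by more than 100 reads are removed as
putative repetitive-region artifacts before any SNP calling.
"""

from __future__ import annotations

import contextlib
import gzip
import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio.SeqIO.QualityIO import FastqGeneralIterator

logger = logging.getLogger(__name__)

_ACGT = frozenset("ACGT")


@dataclass
class TagSet:
    """Per-individual mapping tag sequence -> read count."""

    individual: str
    counts: dict[str, int] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.counts)

    @property
    def n_reads(self) -> int:
        return sum(self.counts.values())


@dataclass
class TagCatalog:
    """Population-wide tag table: distinct tags x individuals read counts."""

    tags: list[str]
    individuals: list[str]
    counts: np.ndarray                       # int32 (n_tags, n_individuals)
    parent_ids: tuple[str, str]
    min_presence_reads: int = 1

    @property
    def presence(self) -> np.ndarray:
        return self.counts >= self.min_presence_reads

    @property
    def line_columns(self) -> list[int]:
        return [k for k, i in enumerate(self.individuals)
                if i not in self.parent_ids]

    def tag_index(self) -> dict[str, int]:
        return {t: i for i, t in enumerate(self.tags)}

    def write_tsv(self, path: str | Path) -> None:
        df = pd.DataFrame(self.counts, index=self.tags, columns=self.individuals)
        df.to_csv(path, sep="\t", index_label="tag")

    @classmethod
    def read_tsv(cls, path: str | Path,
                 parent_ids: tuple[str, str] = ("P1", "P2"),
                 min_presence_reads: int = 1) -> "TagCatalog":
        df = pd.read_csv(path, sep="\t", index_col="tag")
        return cls(tags=list(df.index), individuals=list(df.columns),
                   counts=df.to_numpy(dtype=np.int32), parent_ids=parent_ids,
                   min_presence_reads=min_presence_reads)


def _open_fastq(path):
    path = Path(path)
    return gzip.open(path, "rt") if path.suffix == ".gz" else open(path)


def read_barcode_table(path: str | Path) -> dict[str, str]:
    """TSV (individual id, barcode), no header."""
    out: dict[str, str] = {}
    with open(path) as fh:
        for raw in fh:
            if not raw.strip() or raw.startswith("#"):
                continue
            ind, bc = raw.split()[:2]
            out[ind] = bc.upper()
    return out


def write_barcode_table(barcodes: dict[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for ind, bc in barcodes.items():
            fh.write(f"{ind}\t{bc}\n")


def _check_barcode_distance(barcodes: dict[str, str], max_mismatch: int) -> None:
    seqs = list(barcodes.values())
    if len(set(seqs)) != len(seqs):
        raise ValueError("duplicate barcodes in barcode table")
    for i, a in enumerate(seqs):
        for b in seqs[i + 1:]:
            d = sum(x != y for x, y in zip(a, b))
            if d <= 2 * max_mismatch:
                raise ValueError(
                    f"barcodes {a}/{b} at Hamming {d} cannot be separated "
                    f"with max_barcode_mismatch={max_mismatch}")


def demultiplex(fastq, barcodes: dict[str, str], max_barcode_mismatch: int = 0
                ) -> tuple[dict[str, list[str]], dict[str, int]]:
    """Assign reads to individuals by MID barcode.

    Returns ({individual: [read sequences]}, stats) where stats counts
    assigned / unassigned reads.  Unassignable reads (no barcode within
    tolerance) are discarded and tallied.
    """
    _check_barcode_distance(barcodes, max_barcode_mismatch)
    bc_len = len(next(iter(barcodes.values())))
    lookup = {bc: ind for ind, bc in barcodes.items()}
    out: dict[str, list[str]] = {ind: [] for ind in barcodes}
    stats = {"total": 0, "assigned": 0, "unassigned": 0}
    cm = (_open_fastq(fastq) if isinstance(fastq, (str, Path))
          else contextlib.nullcontext(fastq))
    with cm as fh:
        for _title, seq, _q in FastqGeneralIterator(fh):
            stats["total"] += 1
            prefix = seq[:bc_len].upper()
            ind = lookup.get(prefix)
            if ind is None and max_barcode_mismatch > 0:
                for bc, cand in lookup.items():
                    if sum(x != y for x, y in zip(prefix, bc)) <= max_barcode_mismatch:
                        ind = cand
                        break
            if ind is None:
                stats["unassigned"] += 1
            else:
                stats["assigned"] += 1
                out[ind].append(seq.upper())
    if stats["total"] == 0:
        logger.warning("demultiplex: empty FASTQ input")
    logger.info("demultiplex: %(assigned)d assigned, %(unassigned)d unassigned",
                stats)
    return out, stats


def trim_and_cluster(reads: list[str], individual: str = "",
                     barcode_length: int = 8, tag_length: int = 92
                     ) -> tuple[TagSet, dict[str, int]]:
    """Strip the barcode, collapse identical 92 bp tags to counts.

    Reads shorter than barcode+tag or containing non-ACGT characters in the
    tag are dropped and tallied.
    """
    counts: Counter[str] = Counter()
    stats = {"reads": len(reads), "short": 0, "ambiguous": 0, "clustered": 0}
    full = barcode_length + tag_length
    for seq in reads:
        if len(seq) < full:
            stats["short"] += 1
            continue
        tag = seq[barcode_length:full].upper()
        if not _ACGT.issuperset(tag):
            stats["ambiguous"] += 1
            continue
        counts[tag] += 1
        stats["clustered"] += 1
    return TagSet(individual=individual, counts=dict(counts)), stats


def filter_repetitive(tagset: TagSet, max_reads: int = 100) -> TagSet:
    """Drop tags backed by more than ``max_reads`` reads (strict >)."""
    kept = {t: c for t, c in tagset.counts.items() if c <= max_reads}
    removed = len(tagset.counts) - len(kept)
    if removed:
        logger.info("filter_repetitive[%s]: removed %d of %d tags (> %d reads)",
                    tagset.individual, removed, len(tagset.counts), max_reads)
    return TagSet(individual=tagset.individual, counts=kept)


def build_catalog(tagsets: list[TagSet], parent_ids: tuple[str, str],
                  min_presence_reads: int = 1) -> TagCatalog:
    """Union all individuals' tags into one count matrix."""
    if len(tagsets) < 2:
        raise ValueError("need at least two individuals (the parents)")
    ids = [t.individual for t in tagsets]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate individual ids among tag sets")
    for p in parent_ids:
        if p not in ids:
            raise ValueError(f"parent {p!r} missing from tag sets")
    all_tags = sorted(set().union(*(t.counts.keys() for t in tagsets)))
    lengths = {len(t) for t in all_tags}
    if len(lengths) > 1:
        raise ValueError(f"mixed tag lengths in catalog: {sorted(lengths)}")
    index = {t: i for i, t in enumerate(all_tags)}
    counts = np.zeros((len(all_tags), len(tagsets)), dtype=np.int32)
    for j, ts in enumerate(tagsets):
        for tag, c in ts.counts.items():
            counts[index[tag], j] = c
    return TagCatalog(tags=all_tags, individuals=ids, counts=counts,
                      parent_ids=parent_ids,
                      min_presence_reads=min_presence_reads)


def demux_and_cluster(fastq, barcodes: dict[str, str],
                      parent_ids: tuple[str, str],
                      max_barcode_mismatch: int = 0,
                      barcode_length: int = 8, tag_length: int = 92,
                      max_tag_reads: int = 100,
                      min_presence_reads: int = 1
                      ) -> tuple[TagCatalog, dict]:
    """FASTQ -> TagCatalog in one streaming pass (pipeline convenience)."""
    _check_barcode_distance(barcodes, max_barcode_mismatch)
    bc_len = len(next(iter(barcodes.values())))
    lookup = {bc: ind for ind, bc in barcodes.items()}
    counters: dict[str, Counter] = {ind: Counter() for ind in barcodes}
    stats = {"total": 0, "assigned": 0, "unassigned": 0,
             "short": 0, "ambiguous": 0}
    full = bc_len + tag_length
    cm = (_open_fastq(fastq) if isinstance(fastq, (str, Path))
          else contextlib.nullcontext(fastq))
    with cm as fh:
        for _title, seq, _q in FastqGeneralIterator(fh):
            stats["total"] += 1
            seq = seq.upper()
            ind = lookup.get(seq[:bc_len])
            if ind is None and max_barcode_mismatch > 0:
                prefix = seq[:bc_len]
                for bc, cand in lookup.items():
                    if sum(x != y for x, y in zip(prefix, bc)) <= max_barcode_mismatch:
                        ind = cand
                        break
            if ind is None:
                stats["unassigned"] += 1
                continue
            stats["assigned"] += 1
            if len(seq) < full:
                stats["short"] += 1
                continue
            tag = seq[bc_len:full]
            if not _ACGT.issuperset(tag):
                stats["ambiguous"] += 1
                continue
            counters[ind][tag] += 1
    tagsets = [filter_repetitive(TagSet(ind, dict(counters[ind])), max_tag_reads)
               for ind in barcodes]
    catalog = build_catalog(tagsets, parent_ids=parent_ids,
                            min_presence_reads=min_presence_reads)
    logger.info("demux_and_cluster: %d reads -> %d catalog tags "
                "(%d unassigned)", stats["total"], len(catalog.tags),
                stats["unassigned"])
    return catalog, stats
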