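"""Genetic-map containers: bins (co-segregating marker groups), linkage
groups and whole maps, plus the map TSV format."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd


@dataclass
class Bin:
    """A map locus: markers with zero observed recombination."""

    marker_ids: tuple[str, ...]
    position: float = 0.0
    genotype: np.ndarray | None = None   # consensus int8 over lines

    @property
    def name(self) -> str:
        return min(self.marker_ids)


@dataclass
class LinkageGroup:
    name: str
    bins: list[Bin] = field(default_factory=list)

    @property
    def length_cM(self) -> float:
        return self.bins[-1].position if self.bins else 0.0

    @property
    def marker_ids(self) -> list[str]:
        return [m for b in self.bins for m in b.marker_ids]


@dataclass
class GeneticMap:
    groups: list[LinkageGroup]
    line_ids: list[str] | None = None    # order of genotype vectors in bins

    @property
    def n_markers(self) -> int:
        return sum(len(g.marker_ids) for g in self.groups)

    @property
    def total_length_cM(self) -> float:
        return float(sum(g.length_cM for g in self.groups))

    def marker_positions(self) -> pd.DataFrame:
        """One row per marker: marker, group, bin index, position cM."""
        rows = []
        for g in self.groups:
            for bi, b in enumerate(g.bins):
                for m in b.marker_ids:
                    rows.append((m, g.name, bi, b.position))
        return pd.DataFrame(rows, columns=["marker", "group", "bin", "pos_cM"])

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for g in self.groups:
            for bi, b in enumerate(g.bins):
                rows.append((g.name, bi, round(b.position, 3),
                             ",".join(sorted(b.marker_ids))))
        return pd.DataFrame(rows, columns=["group", "bin", "pos_cM", "markers"])

    def write_tsv(self, path: str | Path) -> None:
        df = self.to_frame()
        df["pos_cM"] = df["pos_cM"].map(lambda p: f"{p:.3f}")
        df.to_csv(path, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path: str | Path) -> "GeneticMap":
        df = pd.read_csv(path, sep="\t", dtype={"group": str})
        groups = []
        for name, sub in df.groupby("group", sort=False):
            sub = sub.sort_values("bin")
            bins = [Bin(marker_ids=tuple(str(m).split(",")),
                        position=float(p))
                    for m, p in zip(sub.markers, sub.pos_cM)]
            groups.append(LinkageGroup(name=str(name), bins=bins))
        return cls(groups=groups)

    def attach_genotypes(self, gm) -> None:
        """Fill each bin's consensus genotype from a GenotypeMatrix.

        Per line the consensus is the unique non-missing call among the
        bin's member markers (conflicts, which binning precludes for
        co-typed lines, resolve to missing).
        """
        self.line_ids = gm.line_ids
        calls = gm.line_calls
        index = {m: i for i, m in enumerate(gm.marker_ids)}
        for g in self.groups:
            for b in g.bins:
                rows = [index[m] for m in b.marker_ids if m in index]
                if not rows:
                    raise ValueError(
                        f"bin {b.name} has no markers in the genotype matrix")
                sub = calls[rows]
                pos = (sub == 1).any(axis=0)
                neg = (sub == -1).any(axis=0)
                cons = np.zeros(sub.shape[1], dtype=np.int8)
                cons[pos & ~neg] = 1
                cons[neg & ~pos] = -1
                b.genotype = cons
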