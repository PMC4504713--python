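"""Genotype matrix container and the MSTMap-dialect genotype format.

Calls are coded internally as int8: +1 = A (same allele as the AC
Metcalfe-analog parent), -1 = B, 0 = missing.  A doubled-haploid population
has no heterozygous code by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

A = np.int8(1)
B = np.int8(-1)
MISSING = np.int8(0)

_SYMBOL = {1: "A", -1: "B", 0: "U"}
_CODE = {"A": 1, "B": -1, "U": 0, "-": 0}

MSTMAP_HEADER = (
    ("population_type", "DH"),
    ("population_name", "synthDH"),
    ("distance_function", "kosambi"),
    ("cut_off_p_value", "0.000001"),
    ("no_map_dist", "25.0"),
    ("no_map_size", "0"),
    ("missing_threshold", "1.00"),
    ("estimation_before_clustering", "no"),
    ("detect_bad_data", "yes"),
    ("objective_function", "COUNT"),
)


@dataclass
class GenotypeMatrix:
    """markers x individuals call matrix with the two parents flagged."""

    marker_ids: list[str]
    individuals: list[str]
    calls: np.ndarray                       # int8 (n_markers, n_individuals)
    parent_ids: tuple[str, str] = ("P1", "P2")

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.marker_ids), len(self.individuals)):
            raise ValueError("calls matrix shape does not match ids")
        bad = set(np.unique(self.calls)) - {-1, 0, 1}
        if bad:
            raise ValueError(f"invalid genotype codes: {sorted(bad)}")

    @property
    def n_markers(self) -> int:
        return len(self.marker_ids)

    @property
    def line_ids(self) -> list[str]:
        return [i for i in self.individuals if i not in self.parent_ids]

    @property
    def line_calls(self) -> np.ndarray:
        """Calls restricted to the non-parent lines (markers x lines)."""
        idx = [k for k, i in enumerate(self.individuals)
               if i not in self.parent_ids]
        return self.calls[:, idx]

    def missing_per_marker(self) -> np.ndarray:
        return (self.line_calls == MISSING).sum(axis=1)

    def subset(self, marker_mask: np.ndarray) -> "GenotypeMatrix":
        idx = np.flatnonzero(marker_mask)
        return GenotypeMatrix(
            marker_ids=[self.marker_ids[i] for i in idx],
            individuals=list(self.individuals),
            calls=self.calls[idx].copy(),
            parent_ids=self.parent_ids,
        )

    def to_frame(self) -> pd.DataFrame:
        sym = np.vectorize(_SYMBOL.get)(self.calls.astype(int))
        return pd.DataFrame(sym, index=self.marker_ids, columns=self.individuals)

    # ------------------------------------------------------------------
    # MSTMap dialect: parameter header then one row per marker over the
    # population lines (parents excluded), symbols A/B/U.
    # ------------------------------------------------------------------
    def write_mstmap(self, path: str | Path) -> None:
        lines = self.line_ids
        idx = [k for k, i in enumerate(self.individuals) if i in lines]
        with open(path, "w") as fh:
            for key, val in MSTMAP_HEADER:
                fh.write(f"{key} {val}\n")
            fh.write(f"number_of_loci {self.n_markers}\n")
            fh.write(f"number_of_individual {len(lines)}\n\n")
            fh.write("locus_name\t" + "\t".join(lines) + "\n")
            for m, row in zip(self.marker_ids, self.calls[:, idx]):
                fh.write(m + "\t" + "\t".join(_SYMBOL[int(v)] for v in row) + "\n")

    @classmethod
    def read_mstmap(cls, path: str | Path) -> "GenotypeMatrix":
        path = Path(path)
        header_keys = {k for k, _ in MSTMAP_HEADER} | {
            "number_of_loci", "number_of_individual", "population_name"}
        marker_ids: list[str] = []
        rows: list[list[int]] = []
        individuals: list[str] | None = None
        with open(path) as fh:
            for lineno, raw in enumerate(fh, start=1):
                line = raw.rstrip("\n")
                if not line.strip():
                    continue
                first = line.split(None, 1)[0]
                if first in header_keys:
                    continue
                fields = line.split("\t")
                if first == "locus_name":
                    individuals = fields[1:]
                    continue
                if individuals is None:
                    raise ValueError(
                        f"{path}:{lineno}: data row before 'locus_name' header")
                if len(fields) != len(individuals) + 1:
                    raise ValueError(
                        f"{path}:{lineno}: expected {len(individuals) + 1} "
                        f"columns, found {len(fields)}")
                codes = []
                for col, sym in enumerate(fields[1:], start=2):
                    if sym not in _CODE:
                        raise ValueError(
                            f"{path}:{lineno}: unknown genotype symbol "
                            f"{sym!r} in column {col} (expected A, B or U)")
                    codes.append(_CODE[sym])
                marker_ids.append(fields[0])
                rows.append(codes)
        if individuals is None:
            raise ValueError(f"{path}: no 'locus_name' header line found")
        calls = np.array(rows, dtype=np.int8) if rows else \
            np.empty((0, len(individuals)), dtype=np.int8)
        return cls(marker_ids=marker_ids, individuals=individuals,
                   calls=calls, parent_ids=("", ""))

    # plain TSV keeps the parents (first two columns by convention)
    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index_label="marker")

    @classmethod
    def read_tsv(cls, path: str | Path,
                 parent_ids: tuple[str, str] = ("P1", "P2")) -> "GenotypeMatrix":
        df = pd.read_csv(path, sep="\t", index_col="marker", dtype=str)
        calls = np.zeros(df.shape, dtype=np.int8)
        for sym, code in _CODE.items():
            calls[(df == sym).to_numpy()] = code
        present = tuple(p for p in parent_ids if p in df.columns)
        return cls(marker_ids=list(df.index), individuals=list(df.columns),
                   calls=calls, parent_ids=present if len(present) == 2 else ("", ""))
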