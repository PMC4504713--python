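"""Synthetic RAD-seq experiments for a doubled-haploid (DH) population.

Emulates the study design behind a barley-style genotyping-by-sequencing
experiment: two inbred parents whose genomes differ by SNPs adjacent to
EcoRI restriction sites, a population of doubled-haploid lines derived from
their F1 by meiosis (so every line is fully homozygous and carries one of
the two parental alleles at every locus), multiplexed 100 bp single-end
reads with 8 nt MID barcodes, and an additive QTL phenotype.

Every simulated dataset carries a full :class:`TruthSet` (parental tag
sequences, per-line crossover breakpoints, true genotypes, QTL placement)
so downstream SNP calling, map construction and QTL scans can be validated
against ground truth.
"""

from __future__ import annotations

import gzip
import io
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .config import SimConfig

BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
# EcoRI (G^AATTC) leaves the AATTC overhang at the start of every RAD tag.
ECORI_OVERHANG = "AATTC"

A = np.int8(1)    # allele of parent 1 (the AC Metcalfe analog)
B = np.int8(-1)   # allele of parent 2 (the Baudin analog)
MISSING = np.int8(0)

PARENT1 = "P1"
PARENT2 = "P2"


def _rng(seed: int, stream: int) -> np.random.Generator:
    """Named substream of the top-level seed (stage-independent replay)."""
    return np.random.default_rng([int(seed) % (2**31), stream])


def decode_tags(tags: np.ndarray) -> list[str]:
    """uint8 ASCII base array -> ACGT strings."""
    return [bytes(row).decode() for row in np.atleast_2d(tags)]


@dataclass
class QTL:
    chrom: int          # 0-based chromosome index
    pos_cM: float
    effect: float       # additive effect a: half the parental-class difference


@dataclass
class TruthSet:
    """Ground truth of one simulated experiment."""

    config: SimConfig
    positions: list[np.ndarray]            # per chrom, sorted locus cM
    parent1_tags: list[np.ndarray]         # per chrom (n_sites, L) uint8
    parent2_tags: list[np.ndarray]
    is_snp: list[np.ndarray]               # per chrom bool
    # meiosis outcome (filled by simulate_dh_lines)
    start_phase: np.ndarray | None = None  # (n_lines, n_chrom) in {+1,-1}
    crossovers: list | None = None         # [line][chrom] -> sorted cM array
    qtl_spec: list[QTL] = field(default_factory=list)
    pheno_mu: float = 0.0
    pheno_sigma: float = 1.0

    # -- identities ---------------------------------------------------------
    @property
    def line_ids(self) -> list[str]:
        return [f"DH{i + 1:03d}" for i in range(self.config.n_lines)]

    @property
    def parent_ids(self) -> tuple[str, str]:
        return (PARENT1, PARENT2)

    @property
    def individual_ids(self) -> list[str]:
        return [PARENT1, PARENT2] + self.line_ids

    # -- genotypes ----------------------------------------------------------
    def genotype_at(self, chrom: int, pos: np.ndarray) -> np.ndarray:
        """True genotypes (n_lines, len(pos)) in {+1, -1} at arbitrary cM.

        Genotype segments are half-open [left, right): a position exactly at
        a crossover breakpoint takes the phase of the segment to its right.
        """
        if self.start_phase is None:
            raise ValueError("DH lines not simulated yet")
        pos = np.asarray(pos, dtype=float)
        out = np.empty((self.config.n_lines, pos.size), dtype=np.int8)
        for i in range(self.config.n_lines):
            bp = self.crossovers[i][chrom]
            flips = np.searchsorted(bp, pos, side="right")
            out[i] = self.start_phase[i, chrom] * np.where(flips % 2 == 0, 1, -1)
        return out

    def true_genotypes(self) -> np.ndarray:
        """(n_lines, total loci) over all RAD loci, chromosome-major order."""
        return np.hstack([self.genotype_at(c, self.positions[c])
                          for c in range(self.config.n_chromosomes)])

    def snp_loci(self) -> pd.DataFrame:
        """One row per polymorphic locus: chrom, locus index, cM, marker id."""
        from .snp import marker_name
        rows = []
        for c in range(self.config.n_chromosomes):
            idx = np.flatnonzero(self.is_snp[c])
            t1 = decode_tags(self.parent1_tags[c][idx]) if idx.size else []
            t2 = decode_tags(self.parent2_tags[c][idx]) if idx.size else []
            for k, j in enumerate(idx):
                rows.append((c, int(j), float(self.positions[c][j]),
                             marker_name(t1[k], t2[k])))
        return pd.DataFrame(rows, columns=["chrom", "locus", "pos_cM", "marker"])

    def true_genotype_matrix(self, polymorphic_only: bool = True):
        """GenotypeMatrix of true calls (parents included, no missing data).

        Marker ids follow the same tag-hash scheme the SNP caller uses, so
        a map built from called genotypes shares ids with the truth.
        """
        from .genotypes import GenotypeMatrix
        loci = self.snp_loci()
        if not polymorphic_only:
            raise NotImplementedError("only polymorphic loci carry markers")
        calls = []
        for c in range(self.config.n_chromosomes):
            sub = loci[loci.chrom == c]
            if len(sub):
                calls.append(self.genotype_at(c, sub.pos_cM.to_numpy()))
        geno = np.hstack(calls).T if calls else np.empty((0, self.config.n_lines), np.int8)
        n_markers = geno.shape[0]
        parents = np.empty((n_markers, 2), dtype=np.int8)
        parents[:, 0] = A
        parents[:, 1] = B
        return GenotypeMatrix(
            marker_ids=list(loci.marker),
            individuals=self.individual_ids,
            calls=np.hstack([parents, geno.astype(np.int8)]),
            parent_ids=self.parent_ids,
        )

    def true_map(self):
        """GeneticMap of the polymorphic loci at their true positions."""
        from .genmap import Bin, GeneticMap, LinkageGroup
        loci = self.snp_loci()
        groups = []
        for c in range(self.config.n_chromosomes):
            sub = loci[loci.chrom == c]
            if not len(sub):
                continue
            geno = self.genotype_at(c, sub.pos_cM.to_numpy())
            bins = [Bin(marker_ids=(m,), genotype=geno[:, k].copy(),
                        position=float(p) - float(sub.pos_cM.iloc[0]))
                    for k, (m, p) in enumerate(zip(sub.marker, sub.pos_cM))]
            groups.append(LinkageGroup(name=f"chr{c + 1}", bins=bins))
        return GeneticMap(groups=groups, line_ids=self.line_ids)


# ---------------------------------------------------------------------------
# simulation operations
# ---------------------------------------------------------------------------

def simulate_parents(config: SimConfig) -> TruthSet:
    """Draw RAD locus positions and the two parental tag sequences.

    Locus positions are uniform on [0, chrom_length_cM] and sorted. Each tag
    starts with the EcoRI overhang AATTC; a ``snp_fraction`` subset of loci
    is polymorphic, the second parent's tag differing at 1 or 2 positions
    (chosen uniformly) outside the overhang.
    """
    rng = _rng(config.seed, 1)
    L = config.tag_length
    k = len(ECORI_OVERHANG)
    overhang = np.frombuffer(ECORI_OVERHANG.encode(), dtype=np.uint8)
    code_of = {b: i for i, b in enumerate(BASES)}
    overhang_codes = np.array([code_of[b] for b in overhang], dtype=np.uint8)

    positions, p1, p2, is_snp = [], [], [], []
    for _ in range(config.n_chromosomes):
        pos = np.sort(rng.uniform(0.0, config.chrom_length_cM, config.n_sites))
        tags = rng.integers(0, 4, size=(config.n_sites, L), dtype=np.uint8)
        tags[:, :k] = overhang_codes
        snp = rng.random(config.n_sites) < config.snp_fraction
        other = tags.copy()
        for j in np.flatnonzero(snp):
            n_mut = rng.integers(1, 3)  # 1 or 2 substituted bases
            sites = rng.choice(np.arange(k, L), size=n_mut, replace=False)
            other[j, sites] = (other[j, sites] + 1 + rng.integers(0, 3, n_mut)) % 4
        positions.append(pos)
        p1.append(BASES[tags])
        p2.append(BASES[other])
        is_snp.append(snp)
    return TruthSet(config=config, positions=positions,
                    parent1_tags=p1, parent2_tags=p2, is_snp=is_snp)


def simulate_dh_lines(truth: TruthSet, config: SimConfig) -> TruthSet:
    """Simulate meiosis for each DH line.

    Crossovers form a Poisson process with rate 1 per 100 cM (Haldane, no
    interference); the genotype alternates between the two parental phases
    at each breakpoint, starting from a fair-coin phase.
    """
    rng = _rng(config.seed, 2)
    n, C = config.n_lines, config.n_chromosomes
    start = np.where(rng.random((n, C)) < 0.5, 1, -1).astype(np.int8)
    xovers: list[list[np.ndarray]] = []
    for i in range(n):
        per_chrom = []
        for c in range(C):
            k = rng.poisson(config.chrom_length_cM / 100.0)
            per_chrom.append(np.sort(rng.uniform(0.0, config.chrom_length_cM, k)))
        xovers.append(per_chrom)
    truth.start_phase = start
    truth.crossovers = xovers
    return truth


def make_barcodes(ids: list[str], seed: int = 0, length: int = 8,
                  min_distance: int = 3) -> dict[str, str]:
    """Random MID barcodes, pairwise Hamming distance >= ``min_distance``."""
    rng = _rng(seed, 3)
    chosen: list[np.ndarray] = []
    out: dict[str, str] = {}
    for ident in ids:
        for _ in range(10_000):
            cand = rng.integers(0, 4, length, dtype=np.uint8)
            if all(int((cand != c).sum()) >= min_distance for c in chosen):
                chosen.append(cand)
                out[ident] = bytes(BASES[cand]).decode()
                break
        else:  # pragma: no cover - 4^8 space makes this unreachable in practice
            raise RuntimeError("could not place all barcodes")
    return out


def _check_barcodes(barcodes: dict[str, str], min_distance: int = 3) -> None:
    seqs = list(barcodes.values())
    if len(set(seqs)) != len(seqs):
        raise ValueError("duplicate barcodes in barcode table")
    arr = np.frombuffer("".join(seqs).encode(), dtype=np.uint8).reshape(len(seqs), -1)
    for i in range(len(seqs)):
        d = (arr[i] != arr[i + 1:]).sum(axis=1)
        if d.size and int(d.min()) < min_distance:
            raise ValueError(
                f"barcodes closer than Hamming {min_distance}: ambiguous demultiplexing")


def simulate_rad_reads(truth: TruthSet, config: SimConfig,
                       barcodes: dict[str, str],
                       fastq_path: str | Path) -> pd.DataFrame:
    """Emit multiplexed FASTQ reads plus a read-level truth table.

    Per individual and locus the read count is Poisson(coverage_mean); each
    read is barcode + the individual's 92 bp allele tag with i.i.d.
    substitution errors at ``error_rate``. Quality strings are constant 'I'
    (Phred 40). Returns a DataFrame (read_id, individual, chrom, locus,
    allele).
    """
    _check_barcodes(barcodes)
    missing = [i for i in truth.individual_ids if i not in barcodes]
    if missing:
        raise ValueError(f"no barcode for individuals: {missing}")

    rng = _rng(config.seed, 4)
    code_of = np.zeros(256, dtype=np.uint8)
    for i, b in enumerate(BASES):
        code_of[b] = i

    # tag code arrays per chromosome per parent
    tags1 = [code_of[t] for t in truth.parent1_tags]
    tags2 = [code_of[t] for t in truth.parent2_tags]
    qual = "I" * config.read_length

    fastq_path = Path(fastq_path)
    opener = gzip.open if fastq_path.suffix == ".gz" else open
    geno_by_chrom = [truth.genotype_at(c, truth.positions[c])
                     for c in range(config.n_chromosomes)]
    rows = []
    read_no = 0
    with opener(fastq_path, "wt") as fh:
        buf = io.StringIO()
        for ind_idx, ind in enumerate(truth.individual_ids):
            bc = barcodes[ind]
            for c in range(config.n_chromosomes):
                n_sites = config.n_sites
                counts = rng.poisson(config.coverage_mean, n_sites)
                total = int(counts.sum())
                if total == 0:
                    continue
                loci = np.repeat(np.arange(n_sites), counts)
                if ind == PARENT1:
                    alleles = np.full(total, A, dtype=np.int8)
                elif ind == PARENT2:
                    alleles = np.full(total, B, dtype=np.int8)
                else:
                    alleles = geno_by_chrom[c][ind_idx - 2][loci]
                mat = np.where(alleles[:, None] == A,
                               tags1[c][loci], tags2[c][loci]).astype(np.uint8)
                if config.error_rate > 0:
                    err = rng.random(mat.shape) < config.error_rate
                    n_err = int(err.sum())
                    if n_err:
                        mat[err] = (mat[err] + 1 +
                                    rng.integers(0, 3, n_err, dtype=np.uint8)) % 4
                seqs = BASES[mat]
                for r in range(total):
                    rid = f"read{read_no:08d}"
                    read_no += 1
                    buf.write(f"@{rid}\n{bc}{bytes(seqs[r]).decode()}\n+\n{qual}\n")
                    rows.append((rid, ind, c, int(loci[r]), int(alleles[r])))
                fh.write(buf.getvalue())
                buf = io.StringIO()
    return pd.DataFrame(rows, columns=["read_id", "individual", "chrom",
                                       "locus", "allele"])


def simulate_phenotype(truth: TruthSet, seed: int | None = None) -> pd.DataFrame:
    """Additive-QTL phenotype: y_i = mu + sum_q a_q x_iq + N(0, sigma^2).

    x_iq is +1 when line i carries the parent-1 (A) allele at QTL q and -1
    otherwise; the expected variance explained by a lone QTL is
    a^2 / (a^2 + sigma^2).
    """
    rng = _rng(truth.config.seed if seed is None else seed, 5)
    n = truth.config.n_lines
    y = np.full(n, truth.pheno_mu, dtype=float)
    for q in truth.qtl_spec:
        if not (0.0 <= q.pos_cM <= truth.config.chrom_length_cM):
            raise ValueError(f"QTL position {q.pos_cM} outside chromosome")
        x = truth.genotype_at(q.chrom, np.array([q.pos_cM]))[:, 0]
        y += q.effect * x
    y += rng.normal(0.0, truth.pheno_sigma, n)
    return pd.DataFrame({"line": truth.line_ids, "value": y})


def simulate_experiment(config: SimConfig, qtl: list[QTL] | None = None,
                        pheno_mu: float = 0.0, pheno_sigma: float = 1.0) -> TruthSet:
    """Parents + DH lines in one call; reads/phenotypes are separate steps."""
    truth = simulate_parents(config)
    truth = simulate_dh_lines(truth, config)
    truth.qtl_spec = qtl or []
    truth.pheno_mu = pheno_mu
    truth.pheno_sigma = pheno_sigma
    return truth
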