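"""End-to-end orchestration: simulate -> demultiplex -> call SNPs ->
build map -> scan QTL, with a JSON manifest recording the resolved
configuration so runs are reproducible byte-for-byte."""

from __future__ import annotations

import logging
from pathlib import Path

import pandas as pd

from . import io
from .compare import align_maps, order_accuracy
from .config import RunConfig
from .demux import demux_and_cluster, write_barcode_table
from .genmap import GeneticMap
from .linkage import build_map
from .qtl import declare_qtl
from .sim import (QTL, TruthSet, make_barcodes, simulate_experiment,
                  simulate_phenotype, simulate_rad_reads)
from .snp import call_markers, filter_markers

logger = logging.getLogger(__name__)


def simulate_stage(cfg: RunConfig, outdir: Path) -> tuple[TruthSet, dict]:
    """Write FASTQ, barcode table, phenotype table and locus truth tables."""
    outdir.mkdir(parents=True, exist_ok=True)
    qtl = [QTL(chrom=int(c), pos_cM=float(p), effect=float(a))
           for c, p, a in cfg.qtl]
    truth = simulate_experiment(cfg.sim, qtl=qtl, pheno_mu=cfg.pheno_mu,
                                pheno_sigma=cfg.pheno_sigma)
    barcodes = make_barcodes(truth.individual_ids, seed=cfg.sim.seed)
    write_barcode_table(barcodes, outdir / "barcodes.tsv")
    reads = simulate_rad_reads(truth, cfg.sim, barcodes,
                               outdir / "reads.fastq")
    reads.to_csv(outdir / "read_truth.tsv", sep="\t", index=False)
    pheno = simulate_phenotype(truth)
    io.write_phenotypes(pheno, outdir / "phenotypes.tsv")
    truth.snp_loci().to_csv(outdir / "snp_truth.tsv", sep="\t", index=False,
                            float_format="%.6f")
    truth.true_map().write_tsv(outdir / "true_map.tsv")
    stats = {"n_reads": len(reads), "n_individuals": len(barcodes)}
    return truth, stats


def call_stage(cfg: RunConfig, fastq: Path, barcodes_path: Path, outdir: Path
               ) -> tuple[object, object, dict]:
    """FASTQ -> filtered genotype matrices (selected tier + map tier)."""
    from .demux import read_barcode_table
    outdir.mkdir(parents=True, exist_ok=True)
    barcodes = read_barcode_table(barcodes_path)
    catalog, demux_stats = demux_and_cluster(
        fastq, barcodes, parent_ids=("P1", "P2"),
        max_barcode_mismatch=cfg.max_barcode_mismatch,
        barcode_length=cfg.sim.barcode_length,
        tag_length=cfg.sim.tag_length,
        max_tag_reads=cfg.max_tag_reads,
        min_presence_reads=cfg.min_presence_reads)
    markers, funnel = call_markers(catalog, max_mismatch=cfg.max_mismatch,
                                   alpha=cfg.fisher_alpha)
    selected, map_tier, filter_tally = filter_markers(
        markers, catalog, min_presence=cfg.min_presence,
        max_missing_abs=cfg.max_missing_abs,
        max_missing_rate=cfg.max_missing_rate)
    selected.write_tsv(outdir / "genotypes_selected.tsv")
    map_tier.write_mstmap(outdir / "genotypes_map_tier.mstmap")
    map_tier.write_tsv(outdir / "genotypes_map_tier.tsv")
    stats = {"demux": demux_stats, "snp_funnel": funnel,
             "filters": filter_tally}
    return selected, map_tier, stats


def map_stage(cfg: RunConfig, gm, outdir: Path):
    outdir.mkdir(parents=True, exist_ok=True)
    gmap, unanchored, report = build_map(
        gm, p_cutoff=cfg.p_cutoff, gap_threshold_cM=cfg.gap_threshold_cM,
        detect_bad=cfg.detect_bad_data)
    gmap.write_tsv(outdir / "genetic_map.tsv")
    (outdir / "unanchored.txt").write_text("\n".join(unanchored) + "\n"
                                           if unanchored else "")
    return gmap, unanchored, report


def qtl_stage(cfg: RunConfig, gmap: GeneticMap, phenotypes: pd.Series,
              outdir: Path) -> tuple[pd.DataFrame, pd.DataFrame, float]:
    outdir.mkdir(parents=True, exist_ok=True)
    profile, report, threshold = declare_qtl(
        gmap, phenotypes, n_perm=cfg.n_perm, alpha=cfg.perm_alpha,
        seed=cfg.seed, step_cM=cfg.scan_step_cM)
    io.write_lod_profile(profile, outdir / "lod_profile.tsv")
    report.to_csv(outdir / "qtl_report.tsv", sep="\t", index=False,
                  float_format="%.6f")
    with open(outdir / "qtl_report.txt", "w") as fh:
        fh.write(f"genome-wide LOD threshold (alpha={cfg.perm_alpha}, "
                 f"{cfg.n_perm} permutations): {threshold:.3f}\n")
        if report.empty:
            fh.write("no QTL above threshold\n")
        for _, q in report.iterrows():
            fh.write(f"QTL on {q.group} at {q.peak_cM:.1f} cM: "
                     f"LOD {q.lod:.2f}, additive effect {q.effect:.2f}, "
                     f"PVE {q.pve:.1f}%, flanked by {q.left_marker} and "
                     f"{q.right_marker}\n")
    return profile, report, threshold


def run_pipeline(cfg: RunConfig, outdir: str | Path) -> dict:
    """Run every stage on one configuration; returns the summary manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    truth, sim_stats = simulate_stage(cfg, outdir / "sim")
    selected, map_tier, call_stats = call_stage(
        cfg, outdir / "sim" / "reads.fastq", outdir / "sim" / "barcodes.tsv",
        outdir / "snp")
    gmap, unanchored, map_report = map_stage(cfg, map_tier, outdir / "map")
    phenotypes = io.read_phenotypes(outdir / "sim" / "phenotypes.tsv")
    profile, qtl_report, threshold = qtl_stage(cfg, gmap, phenotypes,
                                               outdir / "qtl")
    # concordance of the built map with the simulation truth
    truth_map = truth.true_map()
    try:
        conc = align_maps(gmap, truth_map)
        acc = order_accuracy(gmap, truth_map)
        concordance = {
            "n_shared": conc.n_shared,
            "fraction_same_group": conc.fraction_same_group,
            "median_abs_spearman": float(acc.abs_spearman.median()),
        }
        conc.dot_plot.to_csv(outdir / "map" / "dot_plot.tsv", sep="\t",
                             index=False, float_format="%.3f")
    except ValueError:
        concordance = {"n_shared": 0}
    manifest = {
        "config": cfg.to_dict(),
        "seed": cfg.seed,
        "sim": sim_stats,
        "snp": call_stats,
        "map": map_report,
        "qtl": {"threshold": threshold,
                "n_qtl": int(len(qtl_report)),
                "peaks": qtl_report.to_dict("records")},
        "concordance": concordance,
    }
    io.write_manifest(manifest, outdir / "manifest.json")
    return manifest
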