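"""Linkage map construction: map functions, pairwise stats, grouping,
binning, MST ordering, distances, cleaning, gap splitting."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from radmap.config import SimConfig
from radmap.genmap import Bin, GeneticMap, LinkageGroup
from radmap.genotypes import GenotypeMatrix
from radmap.linkage import (bin_markers, brute_force_order, build_map,
                            _bin_counts, _path_cost, detect_bad_data,
                            group_markers, haldane_d, haldane_r, kosambi,
                            kosambi_inverse, map_distances, order_bins,
                            pairwise_linkage, split_gaps)
from radmap.sim import simulate_experiment


def gm_of(rows, n_parents=0):
    """GenotypeMatrix from a list of +1/-1/0 call rows (lines only)."""
    rows = np.asarray(rows, dtype=np.int8)
    inds = [f"DH{i:03d}" for i in range(1, rows.shape[1] + 1)]
    return GenotypeMatrix(marker_ids=[f"m{k:02d}" for k in range(len(rows))],
                          individuals=inds, calls=rows, parent_ids=("", ""))


class TestMapFunctions:
    def test_kosambi_quarter(self):
        assert kosambi(0.25) == pytest.approx(25 * np.log(3), rel=1e-12)
        assert kosambi(0.0) == 0.0

    def test_kosambi_roundtrip_exact(self):
        r = np.arange(0.001, 0.4995, 0.001)
        assert np.abs(kosambi_inverse(kosambi(r)) - r).max() < 1e-12

    def test_haldane_roundtrip(self):
        r = np.arange(0.001, 0.4995, 0.001)
        assert np.abs(haldane_r(haldane_d(r)) - r).max() < 1e-12

    @given(st.floats(min_value=1e-4, max_value=0.45))
    @settings(deadline=None, max_examples=50)
    def test_kosambi_shorter_than_haldane(self, r):
        # Kosambi allows interference, compressing distances
        assert kosambi(r) <= haldane_d(r) + 1e-12


class TestPairwise:
    def test_identical_vectors_no_recombinants(self):
        v = np.resize([1, -1], 94)
        stats = pairwise_linkage(gm_of([v, v]))
        assert stats.n_recombinant[0, 1] == 0
        assert stats.r_hat[0, 1] == 0.0

    def test_hand_counted_example(self):
        # AABB vs ABBB over 4 lines: 1 recombinant of 4 informative
        stats = pairwise_linkage(gm_of([[1, 1, -1, -1], [1, -1, -1, -1]]),
                                 compute_p=False)
        assert stats.n_informative[0, 1] == 4
        assert stats.n_recombinant[0, 1] == 1
        assert stats.r_hat[0, 1] == 0.25

    def test_missing_lines_excluded(self):
        stats = pairwise_linkage(gm_of([[1, 0, -1, 1], [1, 1, -1, 0]]),
                                 compute_p=False)
        assert stats.n_informative[0, 1] == 2
        assert stats.n_recombinant[0, 1] == 0

    def test_independent_vectors_r_half(self):
        rng = np.random.default_rng(0)
        v1, v2 = rng.choice([1, -1], (2, 20_000))
        stats = pairwise_linkage(gm_of([v1, v2]), compute_p=False)
        se = np.sqrt(0.25 / 20_000)
        assert abs(stats.r_hat[0, 1] - 0.5) < 3 * se

    def test_uninformative_pair_flagged(self):
        stats = pairwise_linkage(gm_of([[1, 0, 1], [0, -1, 0]]))
        assert np.isnan(stats.r_hat[0, 1])
        assert stats.independence_p[0, 1] == 1.0


class TestGrouping:
    def test_two_chromosomes_two_groups(self):
        cfg = SimConfig(n_chromosomes=2, chrom_length_cM=100, n_sites=20,
                        snp_fraction=1.0, n_lines=94, seed=21)
        truth = simulate_experiment(cfg)
        gm = truth.true_genotype_matrix()
        stats = pairwise_linkage(gm)
        groups, unanchored = group_markers(stats)
        assert len(groups) == 2
        # no cross-chromosome merges: each group is one truth chromosome
        truth_chrom = dict(zip(truth.snp_loci().marker, truth.snp_loci().chrom))
        for g in groups:
            assert len({truth_chrom[gm.marker_ids[i]] for i in g}) == 1

    def test_identical_markers_single_group(self):
        v = np.resize([1, -1, 1], 94)
        stats = pairwise_linkage(gm_of([v, v, v]))
        groups, unanchored = group_markers(stats)
        assert len(groups) == 1 and unanchored == []

    def test_zero_cutoff_isolates_everything(self):
        v = np.resize([1, -1], 94)
        stats = pairwise_linkage(gm_of([v, v]))
        groups, unanchored = group_markers(stats, p_cutoff=0.0)
        assert groups == [] and len(unanchored) == 2

    def test_grouping_monotone_in_cutoff(self):
        cfg = SimConfig(n_chromosomes=2, chrom_length_cM=150, n_sites=15,
                        snp_fraction=1.0, n_lines=94, seed=22)
        gm = simulate_experiment(cfg).true_genotype_matrix()
        stats = pairwise_linkage(gm)
        counts = [len(group_markers(stats, p)[0])
                  + len(group_markers(stats, p)[1])
                  for p in (1e-12, 1e-9, 1e-6, 1e-3)]
        assert counts == sorted(counts, reverse=True)


class TestBinning:
    def test_identical_vectors_share_bin(self):
        v = np.resize([1, -1], 94)
        bins = bin_markers(gm_of([v, v]), [0, 1])
        assert len(bins) == 1 and bins[0].marker_ids == ("m00", "m01")

    def test_one_recombinant_separates(self):
        v = np.resize([1, -1], 94)
        w = v.copy()
        w[0] = -v[0]
        assert len(bin_markers(gm_of([v, w]), [0, 1])) == 2

    def test_missing_compatible_vectors_merge(self):
        v = np.resize([1, -1], 10)
        w = v.copy()
        w[3] = 0
        bins = bin_markers(gm_of([v, w]), [0, 1])
        assert len(bins) == 1
        assert bins[0].genotype[3] == v[3]   # consensus fills the gap


class TestOrdering:
    def bins_of(self, genotypes, prefix="b"):
        return [Bin(marker_ids=(f"{prefix}{k:02d}",), genotype=np.asarray(g, np.int8))
                for k, g in enumerate(genotypes)]

    def test_triangle_forces_middle(self):
        # d(0,1)=1, d(1,2)=1, d(0,2)=2
        g0 = np.array([1] * 8 + [-1] * 0, np.int8)
        g1 = g0.copy(); g1[0] = -1
        g2 = g1.copy(); g2[1] = -1
        ordered = order_bins(self.bins_of([g0, g2, g1]))
        names = [b.name for b in ordered]
        assert names[1] == "b02"          # the g1 bin sits in the middle

    def test_small_instances_match_brute_force(self):
        rng = np.random.default_rng(23)
        for _ in range(30):
            k = int(rng.integers(3, 9))
            pos = np.sort(rng.uniform(0, 60, k))
            start = rng.choice([1, -1], 94)
            G = np.empty((k, 94), np.int8)
            for li in range(94):
                bp = np.sort(rng.uniform(0, 60, rng.poisson(1.2)))
                G[:, li] = start[li] * np.where(
                    np.searchsorted(bp, pos) % 2 == 0, 1, -1)
            perm = rng.permutation(k)
            bins = self.bins_of(G[perm])
            ordered = order_bins(bins)
            D, _ = _bin_counts(bins)
            idx = {b.name: i for i, b in enumerate(bins)}
            cost = _path_cost([idx[b.name] for b in ordered], D)
            _, best = brute_force_order(bins)
            assert cost == best

    def test_orientation_canonical(self):
        g = np.resize([1, -1], 20)
        bins = self.bins_of([g, np.roll(g, 1), np.roll(g, 2)])
        names = [b.name for b in order_bins(bins)]
        assert names[0] < names[-1]

    def test_error_free_chromosome_recovers_true_order(self):
        cfg = SimConfig(n_chromosomes=1, chrom_length_cM=120, n_sites=40,
                        snp_fraction=1.0, n_lines=94, seed=24)
        truth = simulate_experiment(cfg)
        gm = truth.true_genotype_matrix()
        stats = pairwise_linkage(gm)
        groups, _ = group_markers(stats)
        bins = order_bins(bin_markers(gm, groups[0], stats))
        # recovered order vs true positions: |Spearman| >= 0.99
        from scipy.stats import spearmanr
        pos = dict(zip(truth.snp_loci().marker, truth.snp_loci().pos_cM))
        built = [np.mean([pos[m] for m in b.marker_ids]) for b in bins]
        rho = spearmanr(built, np.arange(len(built))).statistic
        assert abs(rho) >= 0.99
        # COUNT objective never beats the true order on clean data
        D, _ = _bin_counts(bins)
        true_order = np.argsort(built)
        assert _path_cost(list(range(len(bins))), D) <= \
            _path_cost(list(true_order), D)


class TestDistances:
    def test_quarter_recombination_spacing(self):
        g1 = np.array([1, 1, -1, -1] * 25, np.int8)
        g2 = np.array([1, -1, -1, 1] * 25, np.int8)   # r = 0.5 -> clamped
        g3 = g1.copy()
        bins = [Bin(("a",), genotype=g1), Bin(("b",), genotype=g3),
                Bin(("c",), genotype=g2)]
        out = map_distances(bins)
        assert out[0].position == 0.0
        assert out[1].position == 0.0                  # identical bins
        assert out[2].position == pytest.approx(kosambi(0.4999))

    def test_positions_monotone(self):
        rng = np.random.default_rng(25)
        G = rng.choice([1, -1], (5, 94)).astype(np.int8)
        bins = [Bin((f"x{k}",), genotype=G[k]) for k in range(5)]
        out = map_distances(bins)
        pos = [b.position for b in out]
        assert pos == sorted(pos)


class TestBadData:
    def map_of(self, G):
        bins = [Bin((f"m{k:02d}",), genotype=np.asarray(g, np.int8), position=float(k))
                for k, g in enumerate(G)]
        ids = [f"m{k:02d}" for k in range(len(G))]
        gm = GenotypeMatrix(marker_ids=ids,
                            individuals=[f"DH{i:03d}" for i in range(1, len(G[0]) + 1)],
                            calls=np.asarray(G, np.int8), parent_ids=("", ""))
        gmap = GeneticMap(groups=[LinkageGroup("G01", bins)],
                          line_ids=gm.line_ids)
        return gm, gmap

    def test_double_recombinant_singleton_removed(self):
        G = [[1, 1, 1], [1, -1, 1], [1, 1, 1]]      # line 1: A-B-A
        gm, gmap = self.map_of(np.array(G).T.tolist())
        gm2, report = detect_bad_data(gm, gmap)
        assert len(report) == 1
        assert gm2.calls[1, 1] == 0

    def test_consistent_calls_untouched(self):
        G = [[1, 1, 1], [1, 1, 1], [-1, -1, -1]]
        gm, gmap = self.map_of(np.array(G).T.tolist())
        _, report = detect_bad_data(gm, gmap)
        assert report == []

    def test_error_injection_recall_and_specificity(self):
        cfg = SimConfig(n_chromosomes=1, chrom_length_cM=100, n_sites=60,
                        snp_fraction=1.0, n_lines=94, seed=26)
        truth = simulate_experiment(cfg)
        gm = truth.true_genotype_matrix()
        rng = np.random.default_rng(26)
        calls = gm.line_calls.copy()
        flip = rng.random(calls.shape) < 0.005
        noisy = gm.calls.copy()
        lines_cols = [k for k, i in enumerate(gm.individuals)
                      if i not in gm.parent_ids]
        noisy[:, lines_cols] = np.where(flip, -calls, calls)
        gm_noisy = GenotypeMatrix(gm.marker_ids, gm.individuals, noisy,
                                  gm.parent_ids)
        stats = pairwise_linkage(gm_noisy)
        groups, _ = group_markers(stats)
        bins = map_distances(order_bins(bin_markers(gm_noisy, groups[0], stats)))
        gmap = GeneticMap([LinkageGroup("G01", bins)], line_ids=gm.line_ids)
        corrected, report = detect_bad_data(gm_noisy, gmap)
        flagged = (corrected.line_calls == 0) & (gm_noisy.line_calls != 0)
        true_err = flip & (gm.line_calls != 0)
        recall = flagged[true_err].mean()
        false_rate = flagged[~true_err].mean()
        assert recall >= 0.70
        assert false_rate <= 0.001

    def test_binned_errors_share_fate(self):
        # the corrected matrix stays a valid GenotypeMatrix
        G = [[1, 1, 1], [1, -1, 1], [1, 1, 1]]
        gm, gmap = self.map_of(np.array(G).T.tolist())
        gm2, _ = detect_bad_data(gm, gmap)
        assert gm2.calls.dtype == np.int8


class TestGapSplitting:
    def map_with_gap(self, gap):
        g = np.resize([1, -1], 20)
        bins = [Bin(("a",), position=0.0, genotype=g),
                Bin(("b",), position=10.0, genotype=g),
                Bin(("c",), position=10.0 + gap, genotype=g)]
        return GeneticMap([LinkageGroup("G01", bins)])

    def test_gap_above_threshold_splits(self):
        out = split_gaps(self.map_with_gap(36.0))
        assert len(out.groups) == 2
        assert out.groups[1].bins[0].position == 0.0   # re-zeroed

    def test_gap_at_threshold_not_split(self):
        assert len(split_gaps(self.map_with_gap(35.0)).groups) == 1

    def test_no_gap_map_unchanged(self):
        out = split_gaps(self.map_with_gap(5.0))
        assert len(out.groups) == 1
        assert [b.position for b in out.groups[0].bins] == [0.0, 10.0, 15.0]


class TestBuildMap:
    def test_marker_conservation(self, small_truth):
        gm = small_truth.true_genotype_matrix()
        gmap, unanchored, report = build_map(gm)
        assert gmap.n_markers + len(unanchored) == gm.n_markers

    def test_map_tsv_roundtrip(self, small_truth, tmp_path):
        gm = small_truth.true_genotype_matrix()
        gmap, _, _ = build_map(gm)
        gmap.write_tsv(tmp_path / "map.tsv")
        back = GeneticMap.read_tsv(tmp_path / "map.tsv")
        assert [g.name for g in back.groups] == [g.name for g in gmap.groups]
        assert back.n_markers == gmap.n_markers
        back.attach_genotypes(gm)
        assert back.groups[0].bins[0].genotype is not None
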