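"""Tag-pair SNP calling: Fisher kernel, pair discovery, phasing, filters."""

import itertools
from fractions import Fraction
from math import comb

import numpy as np
import pytest

from radmap.demux import TagCatalog
from radmap.genotypes import GenotypeMatrix
from radmap.snp import (AllelePair, call_marker, call_markers,
                        fisher_exact_two_sided, fisher_independence,
                        filter_markers, find_allele_pairs, marker_name)
from conftest import mutate, random_tags


def fisher_enumeration(n11, n10, n01, n00):
    """Independent oracle: exact-rational hypergeometric enumeration."""
    r1, r2, c1 = n11 + n10, n01 + n00, n11 + n01
    n = r1 + r2
    if r1 == 0 or r2 == 0 or c1 == 0 or c1 == n:
        return 1.0

    def point(k):
        return Fraction(comb(r1, k) * comb(r2, c1 - k), comb(n, c1))

    obs = point(n11)
    total = sum(point(k) for k in range(max(0, c1 - r2), min(r1, c1) + 1)
                if point(k) <= obs)
    return float(total)


class TestFisherKernel:
    def test_perfect_mutual_exclusion_94_lines(self):
        # both one-sided extremes contribute: p = 2 / C(94, 47)
        assert fisher_exact_two_sided(0, 47, 47, 0) == pytest.approx(
            2 / comb(94, 47), rel=1e-12)

    def test_perfect_independence_gives_one(self):
        assert fisher_exact_two_sided(25, 25, 25, 25) == pytest.approx(1.0)

    def test_degenerate_margins_return_one(self):
        assert fisher_exact_two_sided(0, 0, 10, 5) == 1.0
        assert fisher_exact_two_sided(10, 0, 5, 0) == 1.0

    def test_matches_enumeration_small_margins(self):
        # every 2x2 table with all margins <= 12
        for n11, n10, n01, n00 in itertools.product(range(7), repeat=4):
            p = fisher_exact_two_sided(n11, n10, n01, n00)
            q = fisher_enumeration(n11, n10, n01, n00)
            assert abs(p - q) < 1e-12, (n11, n10, n01, n00)

    def test_matches_scipy_reference(self):
        from scipy.stats import fisher_exact
        rng = np.random.default_rng(0)
        for _ in range(200):
            a, b, c, d = (int(x) for x in rng.integers(0, 40, 4))
            if (a + b) and (c + d) and (a + c) and (b + d):
                assert fisher_exact_two_sided(a, b, c, d) == pytest.approx(
                    fisher_exact([[a, b], [c, d]]).pvalue, abs=1e-10)


def catalog_from_presence(tags, presence, parent_cols=("P1", "P2")):
    """Build a TagCatalog from a 0/1 presence matrix (tags x individuals)."""
    presence = np.asarray(presence, dtype=np.int32)
    inds = list(parent_cols) + [f"DH{i:03d}" for i in
                                range(1, presence.shape[1] - 1)]
    return TagCatalog(tags=list(tags), individuals=inds, counts=presence,
                      parent_ids=tuple(parent_cols))


class TestPairFinder:
    def test_single_substitution_found(self):
        rng = np.random.default_rng(1)
        x = random_tags(rng, 1)[0]
        y = mutate(x, [10], rng)
        cat = catalog_from_presence([x, y], np.ones((2, 3)))
        pairs = find_allele_pairs(cat)
        assert len(pairs) == 1
        assert pairs[0].mismatch_positions == (10,)

    def test_three_substitutions_excluded(self):
        rng = np.random.default_rng(2)
        x = random_tags(rng, 1)[0]
        y = mutate(x, [5, 40, 80], rng)
        cat = catalog_from_presence([x, y], np.ones((2, 3)))
        assert find_allele_pairs(cat) == []

    def test_matches_brute_force_scan(self):
        rng = np.random.default_rng(3)
        tags = random_tags(rng, 50)
        for k in range(10):
            tags.append(mutate(tags[k], rng.choice(92, 1 + k % 2,
                                                   replace=False), rng))
        tags = sorted(set(tags))
        enc = np.frombuffer("".join(tags).encode(), np.uint8).reshape(len(tags), 92)
        brute = set()
        for i in range(len(tags)):
            d = (enc[i] != enc[i + 1:]).sum(axis=1)
            for off in np.flatnonzero((d >= 1) & (d <= 2)):
                brute.add((tags[i], tags[i + 1 + off]))
        cat = catalog_from_presence(tags, np.ones((len(tags), 3)))
        found = {(p.tag_a, p.tag_b)
                 for p in find_allele_pairs(cat, multi_pair="keep")}
        assert found == brute

    def test_multi_pair_tags_discarded_by_default(self):
        rng = np.random.default_rng(4)
        x = random_tags(rng, 1)[0]
        y, z = mutate(x, [10], rng), mutate(x, [20], rng)
        cat = catalog_from_presence([x, y, z], np.ones((3, 3)))
        assert find_allele_pairs(cat) == []           # x pairs with both
        assert len(find_allele_pairs(cat, multi_pair="keep")) >= 2

    def test_mixed_lengths_rejected(self):
        cat = catalog_from_presence(["ACGT", "ACGTA"], np.ones((2, 3)))
        with pytest.raises(ValueError, match="length"):
            find_allele_pairs(cat)


class TestFisherScreen:
    def test_mutually_exclusive_alleles_pass(self):
        rng = np.random.default_rng(5)
        x = random_tags(rng, 1)[0]
        y = mutate(x, [30], rng)
        pres = np.zeros((2, 2 + 94), dtype=np.int32)
        pres[0, 0] = pres[1, 1] = 1                    # parents
        pres[0, 2:49] = 1
        pres[1, 49:] = 1                               # complementary lines
        cat = catalog_from_presence([x, y], pres)
        pair = AllelePair(*sorted((x, y)), mismatch_positions=(30,))
        p = fisher_independence(pair, cat)
        assert p == pytest.approx(2 / comb(94, 47), rel=1e-9)
        assert pair.presence_fraction == 1.0

    def test_cooccurring_tags_fail_screen(self):
        rng = np.random.default_rng(6)
        x = random_tags(rng, 1)[0]
        y = mutate(x, [30], rng)
        pres = np.ones((2, 2 + 94), dtype=np.int32)    # always co-occur
        cat = catalog_from_presence([x, y], pres)
        markers, tally = call_markers(cat)
        assert markers == [] and tally["fisher_fail"] == 1


class TestCalling:
    def make_catalog(self):
        rng = np.random.default_rng(7)
        x = random_tags(rng, 1)[0]
        y = mutate(x, [50], rng)
        # P1 carries x, P2 carries y, 6 lines: 3 A, 1 B, 1 het, 1 absent
        pres = np.array([
            [1, 0, 1, 1, 1, 0, 1, 0],
            [0, 1, 0, 0, 0, 1, 1, 0],
        ], dtype=np.int32)
        return catalog_from_presence([x, y], pres), x, y

    def test_calls_follow_parental_phase(self):
        cat, x, y = self.make_catalog()
        pair = AllelePair(*sorted((x, y)), mismatch_positions=(50,))
        call, reason = call_marker(pair, cat)
        assert reason == "ok"
        # columns: P1 P2 then lines -> A B | A A A B missing missing
        assert list(call.calls) == [1, -1, 1, 1, 1, -1, 0, 0]
        assert call.missing == 2

    def test_heterozygous_signal_set_missing(self):
        cat, x, y = self.make_catalog()
        pair = AllelePair(*sorted((x, y)), mismatch_positions=(50,))
        call, _ = call_marker(pair, cat)
        assert call.calls[6] == 0      # line with both tags

    def test_both_tags_in_one_parent_unphaseable(self):
        rng = np.random.default_rng(8)
        x = random_tags(rng, 1)[0]
        y = mutate(x, [50], rng)
        pres = np.array([[1, 0, 1, 0], [1, 1, 0, 1]], dtype=np.int32)
        cat = catalog_from_presence([x, y], pres)
        pair = AllelePair(*sorted((x, y)), mismatch_positions=(50,))
        call, reason = call_marker(pair, cat)
        assert call is None and reason == "unphaseable"

    def test_tag_absent_from_parents_rejected(self):
        rng = np.random.default_rng(9)
        x = random_tags(rng, 1)[0]
        y = mutate(x, [50], rng)
        pres = np.array([[0, 0, 1, 0], [0, 1, 0, 1]], dtype=np.int32)
        cat = catalog_from_presence([x, y], pres)
        pair = AllelePair(*sorted((x, y)), mismatch_positions=(50,))
        call, reason = call_marker(pair, cat)
        assert call is None and reason == "absent_in_parent"


class TestMissingFilters:
    def build(self, missing_counts, n_lines=94):
        """One synthetic MarkerCall per requested missing count."""
        from radmap.snp import MarkerCall
        rng = np.random.default_rng(10)
        markers, tags = [], random_tags(rng, len(missing_counts) * 2)
        inds = ["P1", "P2"] + [f"DH{i:03d}" for i in range(1, n_lines + 1)]
        cat = TagCatalog(tags=tags, individuals=inds,
                         counts=np.ones((len(tags), len(inds)), np.int32),
                         parent_ids=("P1", "P2"))
        for k, miss in enumerate(missing_counts):
            pair = AllelePair(*sorted(tags[2 * k:2 * k + 2]),
                              mismatch_positions=(1,))
            pair.presence_fraction = 1.0
            calls = np.ones(n_lines + 2, dtype=np.int8)
            calls[1] = -1
            calls[2:2 + miss] = 0
            markers.append(MarkerCall(marker_id=pair.name, pair=pair,
                                      calls=calls, missing=miss))
        return markers, cat

    def test_two_tier_missing_rules(self):
        # 21/94 missing: dropped outright; 7/94 = 7.45%: selected tier only;
        # 6/94 = 6.38%: reaches the map tier; 0: reaches everything.
        markers, cat = self.build([21, 7, 6, 0])
        selected, map_tier, tally = filter_markers(markers, cat)
        assert tally == {"in": 4, "after_presence": 4,
                         "after_missing_abs": 3, "map_tier": 2}
        assert selected.n_markers == 3 and map_tier.n_markers == 2

    def test_presence_fraction_is_strict(self):
        markers, cat = self.build([0, 0])
        markers[0].pair.presence_fraction = 0.80       # not > 0.80
        _, map_tier, tally = filter_markers(markers, cat)
        assert tally["after_presence"] == 1


class TestGenotypeIO:
    def roundtrip_matrix(self):
        calls = np.array([[1, -1, 1, 0, -1], [1, -1, -1, 1, 1]], dtype=np.int8)
        return GenotypeMatrix(marker_ids=["m1", "m2"],
                              individuals=["P1", "P2", "DH001", "DH002", "DH003"],
                              calls=calls)

    def test_mstmap_roundtrip(self, tmp_path):
        gm = self.roundtrip_matrix()
        gm.write_mstmap(tmp_path / "g.mstmap")
        text = (tmp_path / "g.mstmap").read_text()
        assert "population_type DH" in text
        assert "distance_function kosambi" in text
        back = GenotypeMatrix.read_mstmap(tmp_path / "g.mstmap")
        assert back.marker_ids == gm.marker_ids
        assert np.array_equal(back.calls, gm.line_calls)   # parents excluded

    def test_mstmap_bad_symbol_names_location(self, tmp_path):
        gm = self.roundtrip_matrix()
        gm.write_mstmap(tmp_path / "g.mstmap")
        bad = (tmp_path / "g.mstmap").read_text().replace("m2\tB", "m2\tH")
        (tmp_path / "bad.mstmap").write_text(bad)
        with pytest.raises(ValueError, match="unknown genotype symbol"):
            GenotypeMatrix.read_mstmap(tmp_path / "bad.mstmap")

    def test_plain_tsv_roundtrip(self, tmp_path):
        gm = self.roundtrip_matrix()
        gm.write_tsv(tmp_path / "g.tsv")
        back = GenotypeMatrix.read_tsv(tmp_path / "g.tsv")
        assert np.array_equal(back.calls, gm.calls)
        assert back.parent_ids == ("P1", "P2")


def test_marker_name_is_order_invariant():
    assert marker_name("AAAA", "AACA") == marker_name("AACA", "AAAA")
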