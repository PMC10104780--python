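import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from dsb3d.aggregation import (
    PileupResult,
    anchored_differential,
    cis_pairs,
    cluster_enrichment_score,
    convergent_loop_score,
    convergent_pairs,
    ctcf_pileup,
    pairwise_pileup,
)
from dsb3d.io import BinTable, SiteCatalog, ValidationError
from dsb3d.matrix import OEMaps
from dsb3d.simulate import mouse_like_cut_sites
from conftest import uniform_oe


class TestCisPairs:
    def test_three_sites_one_chromosome(self):
        cat = SiteCatalog.from_records([("chr1", 10), ("chr1", 30), ("chr1", 20)])
        pairs = cis_pairs(cat)
        assert len(pairs) == 3
        assert (pairs["pos1"] < pairs["pos2"]).all()

    def test_all_trans_sites_give_no_pairs(self):
        cat = SiteCatalog.from_records([(f"chr{i}", 100) for i in range(1, 6)])
        assert len(cis_pairs(cat)) == 0

    def test_mouse_like_97_sites_give_304_pairs(self):
        sites = mouse_like_cut_sites(seed=0)
        assert len(sites) == 97
        assert len(cis_pairs(sites)) == 304

    @settings(deadline=None, derandomize=True, max_examples=25)
    @given(st.lists(st.tuples(st.integers(1, 4), st.integers(0, 10_000)),
                    min_size=0, max_size=25, unique=True))
    def test_matches_per_chromosome_combination_count(self, raw):
        cat = SiteCatalog.from_records([(f"chr{c}", p) for c, p in raw])
        brute = sum(
            1
            for (c1, p1), (c2, p2) in itertools.combinations(raw, 2)
            if c1 == c2
        )
        assert len(cis_pairs(cat)) == brute


def planted_oe(n=200, bin_size=25_000, seed=0, noise=0.0):
    rng = np.random.default_rng(seed)
    mat = np.ones((n, n))
    if noise:
        sym = rng.normal(0, noise, (n, n))
        mat += (sym + sym.T) / 2
    bins = BinTable.from_chromsizes({"chr1": n * bin_size}, bin_size)
    return OEMaps(bins, {"chr1": mat}), bins


class TestPairwisePileup:
    def test_single_snippet_is_the_window(self):
        oe, bins = planted_oe(noise=0.2, seed=2)
        pairs = pd.DataFrame({"chrom": ["chr1"], "pos1": [50 * 25_000], "pos2": [150 * 25_000]})
        pu = pairwise_pileup(oe, pairs, flank=250_000)
        r = pu.radius
        np.testing.assert_allclose(
            pu.linear_mean, oe["chr1"][50 - r : 50 + r + 1, 150 - r : 150 + r + 1]
        )
        assert pu.n_used == 1

    def test_uniform_map_gives_flat_pileup(self):
        oe, bins = planted_oe()
        pos = np.arange(5, 200, 20) * 25_000
        pairs = cis_pairs(SiteCatalog.from_records([("chr1", int(p)) for p in pos]))
        pu = pairwise_pileup(oe, pairs, flank=100_000)
        np.testing.assert_allclose(pu.linear_mean, 1.0)
        np.testing.assert_allclose(pu.log2_mean, 0.0, atol=1e-12)

    def test_close_and_edge_pairs_dropped(self):
        oe, bins = planted_oe()
        pairs = pd.DataFrame(
            {
                "chrom": ["chr1"] * 3,
                "pos1": [10 * 25_000, 2 * 25_000, 40 * 25_000],
                "pos2": [40 * 25_000, 120 * 25_000, 160 * 25_000],
            }
        )
        # pair 1: separation 30 bins <= 2*flank(40 bins) -> dropped
        # pair 2: too close to chromosome start -> dropped
        pu = pairwise_pileup(oe, pairs, flank=500_000)
        assert pu.n_used == 1 and pu.n_dropped == 2

    def test_zero_usable_snippets_rejected(self):
        oe, bins = planted_oe()
        pairs = pd.DataFrame({"chrom": ["chr1"], "pos1": [0], "pos2": [25_000]})
        with pytest.raises(ValidationError):
            pairwise_pileup(oe, pairs, flank=500_000)

    def test_planted_center_boost_recovered(self):
        oe, bins = planted_oe(noise=0.05, seed=4)
        centers = [(30, 120), (60, 160), (25, 170)]
        for ci, cj in centers:
            oe["chr1"][ci, cj] = oe["chr1"][cj, ci] = 3.0
        pairs = pd.DataFrame(
            {
                "chrom": "chr1",
                "pos1": [c[0] * 25_000 for c in centers],
                "pos2": [c[1] * 25_000 for c in centers],
            }
        )
        pu = pairwise_pileup(oe, pairs, flank=250_000)
        r = pu.radius
        assert pu.linear_mean[r, r] == pytest.approx(3.0, rel=0.02)


class TestClusterEnrichmentScore:
    def _pileup(self, mat, resolution=25_000, flank=1_000_000):
        return PileupResult(
            linear_mean=mat,
            log2_mean=np.log2(mat),
            resolution=resolution,
            flank=flank,
            n_used=1,
            n_dropped=0,
        )

    def test_uniform_scores_one(self):
        assert cluster_enrichment_score(self._pileup(np.ones((81, 81)))) == pytest.approx(1.0)

    def test_center_three_ring_one_scores_three(self):
        mat = np.ones((81, 81))
        mat[38:43, 38:43] = 3.0
        assert cluster_enrichment_score(self._pileup(mat)) == pytest.approx(3.0)

    def test_matches_index_set_oracle_on_random_pileup(self):
        rng = np.random.default_rng(8)
        mat = rng.uniform(0.5, 2.0, (81, 81))
        score = cluster_enrichment_score(self._pileup(mat))
        center, ring = [], []
        for i in range(81):
            for j in range(81):
                d = max(abs(i - 40), abs(j - 40))
                if d <= 2:
                    center.append(mat[i, j])
                elif d <= 40:
                    ring.append(mat[i, j])
        assert score == pytest.approx(np.mean(center) / np.mean(ring), rel=1e-12)

    def test_empty_ring_rejected(self):
        mat = np.full((5, 5), np.nan)
        mat[2, 2] = 1.0
        pu = self._pileup(mat, flank=50_000)
        with pytest.raises(ValidationError):
            cluster_enrichment_score(pu, outer_radius=50_000)


class TestCtcfPileup:
    def test_uniform_map_is_flat(self):
        oe, bins = planted_oe()
        anchors = SiteCatalog.from_records(
            [("chr1", int(p), "+") for p in np.arange(20, 180, 20) * 25_000]
        )
        pu, lines = ctcf_pileup(oe, anchors, resolution=25_000, flank=100_000)
        np.testing.assert_allclose(pu.linear_mean, 1.0)
        assert lines["downstream"] == pytest.approx(0.0, abs=1e-12)

    def test_reflecting_all_strands_rotates_aggregate(self):
        oe, bins = planted_oe(noise=0.3, seed=9)
        pos = np.arange(20, 180, 15) * 25_000
        plus = SiteCatalog.from_records([("chr1", int(p), "+") for p in pos])
        minus = SiteCatalog.from_records([("chr1", int(p), "-") for p in pos])
        pu_p, _ = ctcf_pileup(oe, plus, resolution=25_000, flank=100_000)
        pu_m, _ = ctcf_pileup(oe, minus, resolution=25_000, flank=100_000)
        np.testing.assert_allclose(pu_m.linear_mean, pu_p.linear_mean[::-1, ::-1])

    def test_planted_one_sided_line_scores_downstream(self):
        oe, bins = planted_oe()
        mat = oe["chr1"]
        pos_bins = [50, 100, 150]
        for b in pos_bins:
            mat[b, b + 1 : b + 5] = 2.0  # extrusion line toward increasing coords
            mat[b + 1 : b + 5, b] = 2.0
        anchors = SiteCatalog.from_records([("chr1", b * 25_000, "+") for b in pos_bins])
        _, lines = ctcf_pileup(oe, anchors, resolution=25_000, flank=100_000)
        assert lines["downstream"] > lines["upstream"]


class TestConvergentLoops:
    def test_alternating_orientations_enumeration(self):
        # + - + - within range: pairs (1,2), (1,4), (3,4) are convergent
        pos = [1_000_000, 1_200_000, 1_400_000, 1_600_000]
        anchors = SiteCatalog.from_records(
            [("chr1", p, s) for p, s in zip(pos, "+-+-")]
        )
        pairs = convergent_pairs(anchors)
        assert len(pairs) == 3

    def test_enumeration_matches_brute_force(self):
        rng = np.random.default_rng(12)
        pos = np.sort(rng.choice(np.arange(100, 5000), 30, replace=False)) * 1000
        strands = rng.choice(["+", "-"], 30)
        anchors = SiteCatalog.from_records(
            [("chr1", int(p), s) for p, s in zip(pos, strands)]
        )
        got = convergent_pairs(anchors, min_sep=25_000, max_sep=1_000_000)
        brute = [
            (p1, p2)
            for (p1, s1), (p2, s2) in itertools.combinations(zip(pos, strands), 2)
            if s1 == "+" and s2 == "-" and 25_000 <= p2 - p1 <= 1_000_000
        ]
        assert len(got) == len(brute)

    def test_uniform_map_loop_score_one(self):
        oe, bins = planted_oe()
        anchors = SiteCatalog.from_records(
            [("chr1", int(b) * 25_000, s) for b, s in zip(range(30, 180, 20), "+-+-+-+-")]
        )
        pu, score, n = convergent_loop_score(oe, anchors, resolution=25_000)
        assert score == pytest.approx(1.0)

    def test_no_qualifying_pairs_rejected(self):
        oe, bins = planted_oe()
        anchors = SiteCatalog.from_records([("chr1", 1_000_000, "-"), ("chr1", 2_000_000, "+")])
        with pytest.raises(ValidationError):
            convergent_loop_score(oe, anchors, resolution=25_000)


class TestAnchoredDifferential:
    def test_identical_conditions_give_zero(self):
        oe, bins = planted_oe(noise=0.1, seed=3)
        diff = anchored_differential(oe, oe, ("chr1", 100 * 25_000))
        vals = diff.values[np.isfinite(diff.values)]
        np.testing.assert_allclose(vals, 0.0)

    def test_single_target_boost_localized(self):
        oe_c, bins = planted_oe()
        oe_d, _ = planted_oe()
        oe_d["chr1"][100, 150] += 0.5
        oe_d["chr1"][150, 100] += 0.5
        diff = anchored_differential(oe_d, oe_c, ("chr1", 100 * 25_000))
        assert diff.values[150] == pytest.approx(0.5)
        assert np.nansum(np.abs(diff.values)) == pytest.approx(0.5)

    def test_antisymmetric_under_condition_swap(self):
        oe_c, bins = planted_oe(noise=0.1, seed=6)
        oe_d, _ = planted_oe(noise=0.1, seed=7)
        d1 = anchored_differential(oe_d, oe_c, ("chr1", 50 * 25_000))
        d2 = anchored_differential(oe_c, oe_d, ("chr1", 50 * 25_000))
        np.testing.assert_allclose(d1.values, -d2.values, equal_nan=True)

    def test_mask_radius_blanks_local_diagonal(self):
        oe_c, bins = planted_oe()
        d = anchored_differential(oe_c, oe_c, ("chr1", 100 * 25_000), mask_radius_bins=3)
        assert np.isnan(d.values[97:104]).all()
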