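"""Anchor-centric enrichment analyses: arithmetic identities, degenerate
inputs, and planted-signal behavior at unit scale."""

import numpy as np
import pandas as pd
import pytest

from sonic4c.core import FeatureTrack, GenomeDef, GenomicInterval, GenomicSite
from sonic4c.association import (
    distance_density,
    gene_assignment_and_expression,
    peak_enrichment,
    rank_sum_test,
    replication_timing_profile,
    tf_tag_enrichment,
)


@pytest.fixture
def genome():
    return GenomeDef(("chr1", "chr2"), (2_000_000, 1_000_000))


def point_track(name, positions, chrom="chr1"):
    return FeatureTrack(
        name, [GenomicInterval(chrom, p, p + 1) for p in positions], kind="point"
    )


class TestPeakEnrichment:
    def test_planted_track_detected(self, genome, rng):
        sites = [GenomicSite("chr1", int(p)) for p in rng.integers(50_000, 1_950_000, 120)]
        near = [int(s.pos + d) for s in sites for d in rng.integers(-5_000, 5_000, 8)]
        track = point_track("planted", sorted(near))
        res = peak_enrichment(sites, track, genome, flank=10_000, seed=1)
        assert res.p_value < 1e-6

    def test_fewer_than_two_anchors_errors(self, genome):
        with pytest.raises(ValueError):
            peak_enrichment([GenomicSite("chr1", 5)], point_track("t", [1]), genome, seed=0)

    def test_default_flank_is_half_megabase(self, genome, rng):
        sites = [GenomicSite("chr1", int(p)) for p in rng.integers(0, 2_000_000, 10)]
        res = peak_enrichment(sites, point_track("t", range(0, 2_000_000, 1_000)), genome, seed=0)
        assert res.flank == 500_000


class TestTfTagEnrichment:
    def test_normalization_arithmetic(self, genome):
        # library of 20 M tags, raw count 30 in the window -> 15.0 per 10 M
        sites = [GenomicSite("chr1", 100_000), GenomicSite("chr1", 500_000)]
        tags = point_track("tf", [100_000 + i for i in range(30)])
        res = tf_tag_enrichment(
            sites, tags, None, chip_library_size=20_000_000,
            control_library_size=None, genome=genome, seed=0,
        )
        assert res.anchor_counts[0] == pytest.approx(15.0)
        assert res.anchor_counts[1] == pytest.approx(0.0)

    def test_scale_invariance_of_normalized_counts(self, genome, rng):
        sites = [GenomicSite("chr1", int(p)) for p in rng.integers(0, 2_000_000, 20)]
        pos = [int(p) for p in rng.integers(0, 2_000_000, 5_000)]
        one = tf_tag_enrichment(sites, point_track("t", pos), None, 1_000_000, None,
                                genome, seed=3)
        # doubling every raw count and the library size leaves values unchanged
        doubled = tf_tag_enrichment(sites, point_track("t", sorted(pos + pos)), None,
                                    2_000_000, None, genome, seed=3)
        assert np.allclose(one.anchor_counts, doubled.anchor_counts)

    def test_identical_chip_and_control_cancel(self, genome, rng):
        sites = [GenomicSite("chr1", int(p)) for p in rng.integers(0, 2_000_000, 15)]
        pos = [int(p) for p in rng.integers(0, 2_000_000, 3_000)]
        track = point_track("t", pos)
        res = tf_tag_enrichment(sites, track, track, 1_000_000, 1_000_000, genome, seed=2)
        assert np.all(res.anchor_counts == 0)
        assert res.p_value == pytest.approx(1.0)

    def test_zero_library_size_errors(self, genome):
        sites = [GenomicSite("chr1", 1), GenomicSite("chr1", 2)]
        with pytest.raises(ValueError):
            tf_tag_enrichment(sites, point_track("t", [5]), None, 0, None, genome, seed=0)


class TestReplicationTimingProfile:
    def test_constant_field_gives_mean_one_and_flat_p(self, genome, rng):
        segs = [
            GenomicInterval(c, s, min(s + 100_000, genome.length(c)), value=1.0)
            for c in genome.names
            for s in range(0, genome.length(c), 100_000)
        ]
        track = FeatureTrack("timing", segs, kind="valued_segment")
        sites = [GenomicSite("chr1", int(p)) for p in rng.integers(0, 2_000_000, 30)]
        prof = replication_timing_profile(sites, track, genome, seed=4)
        assert np.allclose(prof.site_means, 1.0)
        assert prof.p_value == pytest.approx(1.0)
        assert prof.early_fraction == 1.0

    def test_two_segment_weighted_mean(self, genome):
        track = FeatureTrack(
            "timing",
            [
                GenomicInterval("chr1", 0, 100_000, value=2.0),
                GenomicInterval("chr1", 100_000, 2_000_000, value=-1.0),
            ],
            kind="valued_segment",
        )
        # window [50_000, 150_001): 50 kb at +2, 50.001 kb at -1
        prof = replication_timing_profile(
            [GenomicSite("chr1", 100_000), GenomicSite("chr1", 1_000_000)],
            track, genome, flank=50_000, seed=0,
        )
        w1, w2 = 50_000, 50_001
        assert prof.site_means[0] == pytest.approx((2.0 * w1 - 1.0 * w2) / (w1 + w2))

    def test_uncovered_sites_skipped_and_all_uncovered_errors(self, genome):
        # chr1 fully covered, chr2 not covered at all
        track = FeatureTrack(
            "timing", [GenomicInterval("chr1", 0, 2_000_000, value=1.0)], kind="valued_segment"
        )
        prof = replication_timing_profile(
            [GenomicSite("chr1", 5_000), GenomicSite("chr1", 900_000), GenomicSite("chr2", 900_000)],
            track, genome, flank=1_000, seed=0,
        )
        assert prof.n_skipped == 1 and prof.site_means.size == 2
        with pytest.raises(ValueError):
            replication_timing_profile([GenomicSite("chr2", 900_000)], track, genome, seed=0)

    def test_weighted_mean_matches_brute_force_integral(self, genome, rng):
        edges = np.sort(rng.choice(np.arange(1, 2_000_000), 40, replace=False))
        bounds = [0, *edges.tolist(), 2_000_000]
        vals = rng.normal(size=len(bounds) - 1)
        track = FeatureTrack(
            "timing",
            [
                GenomicInterval("chr1", s, e, value=float(v))
                for s, e, v in zip(bounds[:-1], bounds[1:], vals)
            ],
            kind="valued_segment",
        )
        sites = [GenomicSite("chr1", int(p)) for p in rng.integers(0, 2_000_000, 10)]
        prof = replication_timing_profile(sites, track, genome, flank=77_000, seed=1)
        base = np.zeros(2_000_000)
        for s, e, v in zip(bounds[:-1], bounds[1:], vals):
            base[s:e] = v
        for site, m in zip(sites, prof.site_means):
            w0, w1 = max(0, site.pos - 77_000), min(2_000_000, site.pos + 77_000 + 1)
            assert m == pytest.approx(base[w0:w1].mean())


class TestDistanceDensity:
    def test_sites_on_anchors_peak_at_zero(self, genome, rng):
        anchors = point_track("tss", [int(p) for p in rng.integers(0, 2_000_000, 200)])
        sites = [GenomicSite("chr1", iv.start) for iv in list(anchors)[:100]]
        res = distance_density(sites, anchors, genome, bandwidth=2_000, seed=5)
        assert res.p_value < 1e-10
        mid = res.grid.size // 2
        assert res.density_sites[mid] == res.density_sites.max()

    def test_halving_bandwidth_sharpens_identity_peak(self, genome):
        anchors = point_track("tss", [1_000_000])
        sites = [GenomicSite("chr1", 1_000_000)] * 10
        wide = distance_density(sites, anchors, genome, bandwidth=10_000, seed=0)
        narrow = distance_density(sites, anchors, genome, bandwidth=5_000, seed=0)
        mid = wide.grid.size // 2
        assert narrow.density_sites[mid] >= wide.density_sites[mid]

    def test_empty_anchor_track_errors(self, genome):
        with pytest.raises(ValueError):
            distance_density([GenomicSite("chr1", 5)], point_track("t", []), genome, seed=0)


class TestGeneExpression:
    def _genes(self):
        ivs = [
            GenomicInterval("chr1", 100_000, 130_000, name="gA"),
            GenomicInterval("chr1", 120_000, 160_000, name="gB"),
            GenomicInterval("chr1", 800_000, 820_000, name="gC"),
        ] + [
            GenomicInterval("chr2", 10_000 * i, 10_000 * i + 5_000, name=f"g{i:02d}")
            for i in range(2, 40)
        ]
        return FeatureTrack("genes", ivs, kind="peak")

    def test_overlapping_genes_all_assigned(self):
        genes = self._genes()
        fpkm = pd.Series(1.0, index=[iv.name for iv in genes])
        res = gene_assignment_and_expression(
            [GenomicSite("chr1", 125_000), GenomicSite("chr2", 21_000)], genes, fpkm, seed=0
        )
        assert {"gA", "gB"} <= set(res.gene_ids)

    def test_nearest_gene_when_none_overlap(self):
        genes = self._genes()
        fpkm = pd.Series(1.0, index=[iv.name for iv in genes])
        res = gene_assignment_and_expression(
            [GenomicSite("chr1", 700_000), GenomicSite("chr2", 21_000)], genes, fpkm, seed=0
        )
        assert "gC" in res.gene_ids  # closest boundary wins

    def test_planted_expression_shift_detected(self, rng):
        genes = self._genes()
        ids = [iv.name for iv in genes]
        fpkm = pd.Series(rng.lognormal(0, 1, len(ids)), index=ids)
        hits = [iv for iv in genes if iv.chrom == "chr2"][:20]
        for iv in hits:
            fpkm[iv.name] = float(rng.lognormal(3.0, 0.5))
        sites = [GenomicSite("chr2", iv.start + 100) for iv in hits]
        res = gene_assignment_and_expression(sites, genes, fpkm, seed=6)
        assert res.p_value < 0.01  # 20 genes: Welch t at unit scale

    def test_empty_gene_track_errors(self):
        with pytest.raises(ValueError):
            gene_assignment_and_expression(
                [GenomicSite("chr1", 1)], FeatureTrack("g", []), pd.Series(dtype=float), seed=0
            )


class TestRankSumTest:
    def test_degenerate_identical_values_give_p_one(self):
        stat, p = rank_sum_test(np.ones(10), np.ones(12))
        assert p == 1.0

    def test_separated_samples_reject(self, rng):
        x = rng.normal(3, 1, 40)
        y = rng.normal(0, 1, 40)
        _, p = rank_sum_test(x, y, alternative="greater")
        assert p < 1e-6

    def test_too_small_groups_error(self):
        with pytest.raises(ValueError):
            rank_sum_test(np.array([1.0]), np.array([1.0, 2.0]))
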