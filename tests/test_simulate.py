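"""Generator contracts: determinism, truth consistency, null configs."""

import dataclasses

import numpy as np
import pytest

from sonic4c.core import GenomicSite
from sonic4c.junctions import JunctionClass, classify_junction, filter_tag_pairs
from sonic4c.simulate import (
    SimulationConfig,
    TruthTable,
    null_config,
    simulate_dataset,
    simulate_genome,
    simulate_interactome,
    simulate_read_pairs,
)

SMALL = SimulationConfig(
    chrom_lengths=(2_000_000, 2_000_000, 2_000_000),
    bait_start=1_000_000,
    n_hotspots=2,
    sites_per_hotspot=5,
    n_background_sites=60,
    n_genes=60,
    tf_names=("Oct4",),
    seed=7,
)


class TestSimulateGenome:
    def test_gene_count_and_tss_at_starts(self):
        g = simulate_genome(SMALL, np.random.default_rng(1), with_sequence=False)
        assert len(g.genes) == 60
        tss = {(iv.chrom, iv.start) for iv in g.tss}
        assert all((iv.chrom, iv.start) in tss for iv in g.genes)

    def test_genes_non_overlapping(self):
        g = simulate_genome(SMALL, np.random.default_rng(2), with_sequence=False)
        by_chrom = {}
        for iv in g.genes:
            by_chrom.setdefault(iv.chrom, []).append(iv)
        for ivs in by_chrom.values():
            ivs.sort(key=lambda v: v.start)
            assert all(a.end <= b.start for a, b in zip(ivs, ivs[1:]))

    def test_same_seed_identical_sequence(self):
        a = simulate_genome(SMALL, np.random.default_rng(5))
        b = simulate_genome(SMALL, np.random.default_rng(5))
        assert a.sequences == b.sequences

    def test_zero_cpg_density_empty_track(self):
        cfg = dataclasses.replace(SMALL, cpg_density=0.0)
        g = simulate_genome(cfg, np.random.default_rng(1), with_sequence=False)
        assert len(g.cpg) == 0


class TestSimulateInteractome:
    def test_counts_and_hotspot_membership(self):
        g = simulate_genome(SMALL, np.random.default_rng(3), with_sequence=False)
        truth = simulate_interactome(SMALL, g, np.random.default_rng(3))
        assert len(truth.true_sites) == 2 * 5 + 60
        assert len(truth.hotspot_regions) == 2
        in_hotspots = [
            s
            for s in truth.true_sites
            if any(
                h.chrom == s.chrom and h.start <= s.pos < h.end
                for h in truth.hotspot_regions
            )
        ]
        assert len(in_hotspots) >= 10  # every hotspot site lies inside its region

    def test_all_sites_distal_from_bait(self):
        g = simulate_genome(SMALL, np.random.default_rng(4), with_sequence=False)
        truth = simulate_interactome(SMALL, g, np.random.default_rng(4))
        bait = SMALL.bait
        for s in truth.true_sites:
            if s.chrom == bait.interval.chrom:
                assert bait.distance_to(s.pos) >= SMALL.min_bait_distance

    def test_min_separation_enforced(self):
        g = simulate_genome(SMALL, np.random.default_rng(5), with_sequence=False)
        truth = simulate_interactome(SMALL, g, np.random.default_rng(5))
        by_chrom = {}
        for s in truth.true_sites:
            by_chrom.setdefault(s.chrom, []).append(s.pos)
        for pos in by_chrom.values():
            pos.sort()
            assert min(np.diff(pos)) >= SMALL.min_site_separation

    def test_null_config_has_no_hotspots(self):
        cfg = null_config(SMALL)
        g = simulate_genome(cfg, np.random.default_rng(6), with_sequence=False)
        truth = simulate_interactome(cfg, g, np.random.default_rng(6))
        assert truth.hotspot_regions == []
        assert len(truth.true_sites) == 60

    def test_hotspots_restricted_to_configured_chromosomes(self):
        cfg = dataclasses.replace(SMALL, hotspot_chroms=("chr2", "chr3"))
        g = simulate_genome(cfg, np.random.default_rng(7), with_sequence=False)
        truth = simulate_interactome(cfg, g, np.random.default_rng(7))
        assert all(h.chrom in ("chr2", "chr3") for h in truth.hotspot_regions)


class TestSimulateReadPairs:
    def test_every_junction_pair_has_one_bait_tag(self):
        cfg = dataclasses.replace(SMALL, noise_fraction=0.0, duplicate_rate=0.0,
                                  mapq_degraded_fraction=0.0)
        ds = simulate_dataset(cfg, with_tracks=False)
        bait = cfg.bait
        for rec in ds.reads:
            n_in = bait.contains(rec.pair.tag1.chrom, rec.pair.tag1.pos) + bait.contains(
                rec.pair.tag2.chrom, rec.pair.tag2.pos
            )
            assert n_in == 1

    def test_truth_sites_reproducible_from_clean_tags(self):
        cfg = dataclasses.replace(SMALL, noise_fraction=0.0, duplicate_rate=0.0,
                                  mapq_degraded_fraction=0.0)
        ds = simulate_dataset(cfg, with_tracks=False)
        bait = cfg.bait
        # re-derive site positions from the emitted junction tag pairs
        site_tags = {}
        for rec in ds.reads:
            si = int(rec.label.split(":")[1])
            other = rec.pair.tag2 if bait.contains(rec.pair.tag1.chrom, rec.pair.tag1.pos) else rec.pair.tag1
            site_tags.setdefault(si, []).append((other.chrom, other.pos))
        for si, tags in site_tags.items():
            s = ds.truth.true_sites[si]
            assert all(c == s.chrom and abs(p - s.pos) <= cfg.jitter for c, p in tags)
            assert len(tags) == s.read_count

    def test_noise_fraction_and_labels(self):
        cfg = dataclasses.replace(SMALL, noise_fraction=0.25, duplicate_rate=0.0,
                                  mapq_degraded_fraction=0.0)
        ds = simulate_dataset(cfg, with_tracks=False)
        labels = [r.label for r in ds.reads]
        n_noise = sum(l == "noise" for l in labels)
        n_junc = sum(l.startswith("junction") for l in labels)
        assert n_noise == round(n_junc * 0.25 / 0.75)
        # noise never classifies as distal
        for rec in ds.reads:
            if rec.label == "noise":
                cls = classify_junction(rec.pair, cfg.bait)
                assert cls is JunctionClass.NON_JUNCTION

    def test_duplicates_are_exact_copies(self):
        cfg = dataclasses.replace(SMALL, duplicate_rate=0.3, mapq_degraded_fraction=0.0)
        ds = simulate_dataset(cfg, with_tracks=False)
        by_id = {r.read_id: r for r in ds.reads}
        n_dup = 0
        for rec in ds.reads:
            if rec.label.startswith("duplicate:"):
                n_dup += 1
                orig = by_id[rec.label.split(":")[1]]
                assert (rec.pair.tag1, rec.pair.tag2) == (orig.pair.tag1, orig.pair.tag2)
        assert n_dup > 0

    def test_degraded_pairs_fall_below_filter(self):
        cfg = dataclasses.replace(SMALL, mapq_degraded_fraction=0.2)
        ds = simulate_dataset(cfg, with_tracks=False)
        flagged = {r.read_id for r in ds.reads if "mapq_degraded" in r.label}
        assert len(flagged) == round(0.2 * len(ds.reads))
        kept = {p.read_id for p in filter_tag_pairs([r.pair for r in ds.reads])}
        assert flagged.isdisjoint(kept)

    def test_detection_prob_thins_sites(self):
        cfg = dataclasses.replace(SMALL, noise_fraction=0.0, mapq_degraded_fraction=0.0)
        ds = simulate_dataset(cfg, with_tracks=False)
        reads, truth = simulate_read_pairs(
            ds.truth, cfg, ds.genome, np.random.default_rng(9), detection_prob=0.5
        )
        detected = {int(r.label.split(":")[1]) for r in reads if r.label.startswith("junction")}
        assert 0 < len(detected) < len(ds.truth.true_sites)


class TestTrackSet:
    def test_null_track_enrichment_is_uniform_construction(self):
        cfg = null_config(SMALL)
        ds = simulate_dataset(cfg)
        # flat timing: overall mean ~ 0
        vals = [iv.value for iv in ds.tracks.timing]
        assert abs(np.mean(vals)) < 0.1
        # equal FPKM distributions: interacting flag exists but same lognormal
        assert ds.tracks.fpkm.size == cfg.n_genes

    def test_interacting_genes_have_higher_fpkm(self):
        ds = simulate_dataset(SMALL)
        fpkm = ds.tracks.fpkm
        inter = sorted(ds.truth.interacting_gene_ids)
        rest = fpkm.index.difference(inter)
        assert len(inter) > 3
        assert fpkm[inter].median() > 4 * fpkm[rest].median()

    def test_tf_library_sizes_match_track_lengths(self):
        ds = simulate_dataset(SMALL)
        for tf, track in ds.tracks.tf_chip.items():
            assert ds.tracks.tf_library_sizes[tf] == len(track)


class TestDeterminism:
    def test_dataset_fully_reproducible(self):
        a = simulate_dataset(SMALL, with_sequences=True)
        b = simulate_dataset(SMALL, with_sequences=True)
        assert a.genome.sequences == b.genome.sequences
        assert a.truth.true_sites == b.truth.true_sites
        assert [(r.read_id, r.label, r.pair, r.seq1, r.seq2) for r in a.reads] == [
            (r.read_id, r.label, r.pair, r.seq1, r.seq2) for r in b.reads
        ]
        assert all(
            list(a.tracks.peak_tracks[k]) == list(b.tracks.peak_tracks[k])
            for k in a.tracks.peak_tracks
        )
        assert a.tracks.fpkm.equals(b.tracks.fpkm)

    def test_truth_table_json_round_trip(self, tmp_path):
        ds = simulate_dataset(SMALL, with_tracks=True)
        path = tmp_path / "truth.json"
        ds.truth.to_json(path)
        back = TruthTable.from_json(path)
        assert back.true_sites == ds.truth.true_sites
        assert back.hotspot_regions == ds.truth.hotspot_regions
        assert back.read_labels == ds.truth.read_labels
        assert back.interacting_gene_ids == ds.truth.interacting_gene_ids
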