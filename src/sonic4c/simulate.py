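"""Synthetic 4C-seq data with full ground truth.

The generator emulates everything the pipeline consumes — a small
multi-chromosome genome, bait-junction read pairs, a pre-aligned tag-pair
table, and feature tracks whose co-localization with the planted
interacting sites is controlled — so every downstream stage can be tested
without any external download.

Model of the data, briefly: a ~0.6 kb bait locus interacts with a set of
planted 1-bp sites.  A few *hotspots* (short regions holding many sites)
sit on top of a uniform background of sites, mirroring the structure the
domain caller looks for.  Each site emits several junction read pairs: one
20-bp end tag inside the bait, the other within a small uniform jitter
(±50 bp by default) of the site, so the 100-bp merge rule reassembles the
site exactly.  Noise pairs (both tags outside the bait, or both inside),
PCR duplicates and MAPQ-degraded pairs are mixed in at configurable rates
and recorded in the truth table.  Feature tracks plant co-localization by
multiplying the feature-placement density near true sites by an odds
factor; replication timing, FPKM and TF tag tracks plant analogous shifts.

The simulator works at the abstraction the pipeline consumes (end tags);
it does not model sonication fragment sizes or ligation biochemistry, and
its only sequence-level realism is that reads are genuine genomic
substrings so the exact-match aligner reproduces the tag table.
"""

from __future__ import annotations

import bisect
import json
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

from .core import (
    FeatureTrack,
    GenomeDef,
    GenomicInterval,
    GenomicSite,
    merge_overlapping,
    write_bed,
)
from .junctions import BaitRegion, TagAlignment, TagPair

__all__ = [
    "SimulationConfig",
    "TruthTable",
    "SimulatedGenome",
    "ReadPair",
    "TrackSet",
    "SimulatedDataset",
    "simulate_genome",
    "simulate_interactome",
    "simulate_read_pairs",
    "simulate_feature_tracks",
    "simulate_dataset",
    "null_config",
    "write_fasta",
    "write_fastq",
]


@dataclass(frozen=True)
class SimulationConfig:
    """All knobs of the generator.  Defaults define the study conditions:
    a 30 Mb three-chromosome genome carrying 5 hotspots of 20 sites within
    50 kb over 1,000 background sites, 90-bp read pairs with 20-bp end
    tags, and feature tracks with a 10× placement-odds enrichment near
    true sites."""

    chrom_names: tuple[str, ...] = ("chr1", "chr2", "chr3")
    chrom_lengths: tuple[int, ...] = (10_000_000, 10_000_000, 10_000_000)
    bait_chrom: str = "chr1"
    bait_start: int = 5_000_000
    bait_length: int = 600
    # interactome
    n_hotspots: int = 5
    hotspot_width: int = 50_000
    sites_per_hotspot: int = 20
    n_background_sites: int = 1_000
    hotspot_chroms: tuple[str, ...] | None = None
    min_site_separation: int = 500
    min_bait_distance: int = 10_000
    site_tss_bias: float = 0.7  # fraction of background sites placed near a TSS
    tss_bias_window: int = 5_000
    # reads
    reads_per_site_mean: float = 3.0
    reads_per_site_min: int = 2
    read_length: int = 90
    tag_length: int = 20
    jitter: int = 50
    noise_fraction: float = 0.1
    duplicate_rate: float = 0.05
    mapq_degraded_fraction: float = 0.05
    site_detection_prob: float = 0.7  # per-replicate site sampling depth
    # annotation
    n_genes: int = 600
    gene_length_range: tuple[int, int] = (5_000, 50_000)
    cpg_density: float = 2e-5  # points per bp
    cpg_fraction_near_tss: float = 0.5
    cpg_tss_window: int = 2_000
    # feature tracks
    track_enrichment: float = 10.0  # placement-odds multiplier near true sites
    peak_track_density: float = 3e-5  # peaks per bp (ENCODE histone-mark scale)
    dhs_density: float = 1e-4
    hmc_density: float = 2e-5
    peak_width: int = 400
    colocalization_flank: int = 50_000  # feature co-localization zone around true sites
    timing_segment_bp: int = 40_000
    timing_shift: float = 1.0  # mean log2(early/late) near sites (0 = null)
    timing_sd: float = 0.4
    timing_flank: int = 50_000
    tf_names: tuple[str, ...] = ("Oct4", "Klf4", "Tcfcp2l1", "Esrrb", "Zfx")
    chip_tag_density: float = 5e-3  # tags per bp (~10M-read library scale)
    tf_flank: int = 1_000
    fpkm_lognormal: tuple[tuple[float, float], tuple[float, float]] = (
        (2.5, 1.0),  # interacting genes: (meanlog, sdlog)
        (0.0, 1.0),  # background genes
    )
    gene_neighborhood: int = 10_000  # gene ± this touching a site → interacting
    seed: int = 0

    def __post_init__(self):
        for frac in (
            self.noise_fraction,
            self.duplicate_rate,
            self.mapq_degraded_fraction,
            self.site_detection_prob,
            self.site_tss_bias,
            self.cpg_fraction_near_tss,
        ):
            if not (0 <= frac <= 1):
                raise ValueError("fractions must lie in [0, 1]")
        if self.hotspot_width >= min(self.chrom_lengths):
            raise ValueError("hotspot_width must be much smaller than chromosomes")
        if self.reads_per_site_min < 1:
            raise ValueError("reads_per_site_min must be >= 1")
        if self.reads_per_site_mean < self.reads_per_site_min:
            raise ValueError("reads_per_site_mean must be >= reads_per_site_min")

    @property
    def genome(self) -> GenomeDef:
        return GenomeDef(self.chrom_names, self.chrom_lengths)

    @property
    def bait(self) -> BaitRegion:
        return BaitRegion(
            GenomicInterval(self.bait_chrom, self.bait_start, self.bait_start + self.bait_length)
        )

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}

        def tup(x):
            return tuple(tup(v) if isinstance(v, list) else v for v in x)

        for key, val in list(d.items()):
            if isinstance(val, list):
                d[key] = tup(val)
        return cls(**d)


def null_config(base: SimulationConfig | None = None, **overrides) -> SimulationConfig:
    """A configuration with every planted effect switched off: no hotspots,
    feature placement independent of sites, flat replication timing, equal
    expression distributions, no TSS bias.  The null for every downstream
    statistical test."""
    base = base or SimulationConfig()
    fields = dict(
        n_hotspots=0,
        track_enrichment=1.0,
        timing_shift=0.0,
        site_tss_bias=0.0,
        fpkm_lognormal=((0.0, 1.0), (0.0, 1.0)),
    )
    fields.update(overrides)
    return replace(base, **fields)


# ---------------------------------------------------------------------------
# Genome


@dataclass
class SimulatedGenome:
    genome: GenomeDef
    sequences: dict[str, str] | None
    genes: FeatureTrack  # intervals named by gene id
    tss: FeatureTrack  # 1-bp points at gene starts
    cpg: FeatureTrack  # 1-bp points


_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def _random_sequence(rng: np.random.Generator, length: int) -> str:
    return _BASES[rng.integers(0, 4, size=length)].tobytes().decode("ascii")


def simulate_genome(
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
    with_sequence: bool = True,
) -> SimulatedGenome:
    """Random genome with gene/TSS/CpG annotation; deterministic per seed.

    Genes are non-overlapping intervals with one TSS at each gene start; a
    configurable fraction of CpG points clusters within ±2 kb of TSSs
    (gene-rich zones), the rest is uniform.
    """
    rng = rng or np.random.default_rng(config.seed)
    genome = config.genome
    sequences = (
        {c: _random_sequence(rng, genome.length(c)) for c in genome.names}
        if with_sequence
        else None
    )
    lengths = np.asarray(genome.lengths, dtype=float)
    n_per_chrom = np.floor(config.n_genes * lengths / lengths.sum()).astype(int)
    n_per_chrom[0] += config.n_genes - int(n_per_chrom.sum())
    lo, hi = config.gene_length_range
    genes: list[GenomicInterval] = []
    gi = 0
    for chrom, n in zip(genome.names, n_per_chrom):
        L = genome.length(chrom)
        if n * hi > L:
            raise ValueError(f"cannot fit {n} genes of up to {hi} bp on {chrom}")
        placed: list[tuple[int, int]] = []
        for _ in range(200):
            if len(placed) >= n:
                break
            need = n - len(placed)
            starts = np.sort(rng.integers(0, L - hi, size=need * 2))
            glens = rng.integers(lo, hi + 1, size=starts.size)
            for s, gl in zip(starts, glens):
                s, e = int(s), int(s + gl)
                i = bisect.bisect_left(placed, (s, e))
                if i > 0 and placed[i - 1][1] > s:
                    continue
                if i < len(placed) and placed[i][0] < e:
                    continue
                placed.insert(i, (s, e))
                if len(placed) == n:
                    break
        if len(placed) < n:
            raise ValueError(f"could not place {n} non-overlapping genes on {chrom}")
        for s, e in placed:
            genes.append(GenomicInterval(chrom, s, e, name=f"gene{gi:05d}"))
            gi += 1
    gene_track = FeatureTrack("genes", genes, kind="peak")
    tss = FeatureTrack(
        "tss",
        [GenomicInterval(g.chrom, g.start, g.start + 1, name=g.name) for g in genes],
        kind="point",
    )
    n_cpg = int(round(config.cpg_density * genome.total_length))
    cpg_points: list[GenomicInterval] = []
    tss_list = tss.intervals
    for _ in range(n_cpg):
        if tss_list and rng.random() < config.cpg_fraction_near_tss:
            t = tss_list[int(rng.integers(0, len(tss_list)))]
            p = int(
                np.clip(
                    t.start + rng.integers(-config.cpg_tss_window, config.cpg_tss_window + 1),
                    0,
                    genome.length(t.chrom) - 1,
                )
            )
            cpg_points.append(GenomicInterval(t.chrom, p, p + 1))
        else:
            chrom = genome.names[int(rng.integers(0, len(genome.names)))]
            p = int(rng.integers(0, genome.length(chrom)))
            cpg_points.append(GenomicInterval(chrom, p, p + 1))
    cpg = FeatureTrack("cpg", cpg_points, kind="point")
    return SimulatedGenome(genome=genome, sequences=sequences, genes=gene_track, tss=tss, cpg=cpg)


# ---------------------------------------------------------------------------
# Interactome truth


@dataclass
class TruthTable:
    """Ground truth: planted sites (read_count = expected surviving read
    support once reads exist), hotspot regions, per-read labels and the
    interacting gene set."""

    true_sites: list[GenomicSite]
    hotspot_regions: list[GenomicInterval]
    read_labels: dict[str, str] = field(default_factory=dict)
    interacting_gene_ids: set[str] = field(default_factory=set)

    def detectable_sites(self, min_reads: int = 2) -> list[GenomicSite]:
        """Sites whose expected surviving support clears the singleton
        filter — exactly what a perfect pipeline run should recover."""
        return sorted(s for s in self.true_sites if s.read_count >= min_reads)

    def to_json(self, path: str | Path) -> None:
        d = {
            "true_sites": [[s.chrom, s.pos, s.read_count] for s in self.true_sites],
            "hotspot_regions": [
                [iv.chrom, iv.start, iv.end] for iv in self.hotspot_regions
            ],
            "read_labels": dict(sorted(self.read_labels.items())),
            "interacting_gene_ids": sorted(self.interacting_gene_ids),
        }
        with open(path, "w") as fh:
            json.dump(d, fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path: str | Path) -> "TruthTable":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            true_sites=[GenomicSite(c, p, n) for c, p, n in d["true_sites"]],
            hotspot_regions=[GenomicInterval(c, s, e) for c, s, e in d["hotspot_regions"]],
            read_labels=d["read_labels"],
            interacting_gene_ids=set(d["interacting_gene_ids"]),
        )


class _SitePlacer:
    """Rejection placement of site positions under the separation and
    bait-distance constraints."""

    def __init__(self, config: SimulationConfig, genome: GenomeDef):
        self.config = config
        self.genome = genome
        self.placed: dict[str, list[int]] = {c: [] for c in genome.names}

    def admissible(self, chrom: str, pos: int) -> bool:
        cfg = self.config
        if not (0 <= pos < self.genome.length(chrom)):
            return False
        bait = cfg.bait.interval
        if chrom == bait.chrom:
            dist = max(bait.start - pos, pos - bait.end + 1, 0)
            if dist < cfg.min_bait_distance:
                return False
        arr = self.placed[chrom]
        i = bisect.bisect_left(arr, pos)
        if i > 0 and pos - arr[i - 1] < cfg.min_site_separation:
            return False
        if i < len(arr) and arr[i] - pos < cfg.min_site_separation:
            return False
        return True

    def place(self, chrom: str, pos: int) -> None:
        bisect.insort(self.placed[chrom], pos)


def simulate_interactome(
    config: SimulationConfig,
    genome: SimulatedGenome | GenomeDef,
    rng: np.random.Generator | None = None,
) -> TruthTable:
    """Plant hotspot regions and sites plus a uniform background.

    Hotspots are non-overlapping; every site is at least 10 kb from the
    bait (all sites are distal by construction) and at least
    ``min_site_separation`` from any other site so that tag jitter can
    never merge two planted sites.  A fraction ``site_tss_bias`` of
    background sites is drawn near a random TSS (gene-rich preference);
    the rest is uniform.  read_count fields stay 0 until reads are drawn.
    """
    rng = rng or np.random.default_rng(config.seed)
    sim_genome = genome if isinstance(genome, SimulatedGenome) else None
    gdef = genome.genome if isinstance(genome, SimulatedGenome) else genome
    placer = _SitePlacer(config, gdef)
    lengths = np.asarray(gdef.lengths, dtype=float)
    hotspot_chroms = config.hotspot_chroms or gdef.names
    hs_lengths = np.asarray([gdef.length(c) for c in hotspot_chroms], dtype=float)

    hotspots: list[GenomicInterval] = []
    for _ in range(config.n_hotspots):
        for attempt in range(1000):
            chrom = hotspot_chroms[
                int(rng.choice(len(hotspot_chroms), p=hs_lengths / hs_lengths.sum()))
            ]
            start = int(rng.integers(0, gdef.length(chrom) - config.hotspot_width))
            iv = GenomicInterval(chrom, start, start + config.hotspot_width)
            bait = config.bait.interval
            near_bait = (
                chrom == bait.chrom
                and iv.start < bait.end + config.min_bait_distance
                and bait.start - config.min_bait_distance < iv.end
            )
            if near_bait or any(iv.overlaps(h) for h in hotspots):
                continue
            hotspots.append(iv)
            break
        else:
            raise RuntimeError("could not place non-overlapping hotspots")

    sites: list[GenomicSite] = []
    for hs in hotspots:
        placed = 0
        for attempt in range(10_000):
            if placed == config.sites_per_hotspot:
                break
            pos = int(rng.integers(hs.start, hs.end))
            if placer.admissible(hs.chrom, pos):
                placer.place(hs.chrom, pos)
                sites.append(GenomicSite(hs.chrom, pos, 1))
                placed += 1
        if placed < config.sites_per_hotspot:
            raise RuntimeError("could not place hotspot sites under separation constraint")

    tss_list = sim_genome.tss.intervals if sim_genome is not None else []
    placed = 0
    for attempt in range(100 * max(1, config.n_background_sites)):
        if placed == config.n_background_sites:
            break
        if tss_list and rng.random() < config.site_tss_bias:
            t = tss_list[int(rng.integers(0, len(tss_list)))]
            chrom = t.chrom
            pos = int(t.start + rng.integers(-config.tss_bias_window, config.tss_bias_window + 1))
        else:
            chrom = gdef.names[int(rng.choice(len(gdef.names), p=lengths / lengths.sum()))]
            pos = int(rng.integers(0, gdef.length(chrom)))
        if placer.admissible(chrom, pos):
            placer.place(chrom, pos)
            sites.append(GenomicSite(chrom, pos, 1))
            placed += 1
    if placed < config.n_background_sites:
        raise RuntimeError("could not place background sites under separation constraint")

    return TruthTable(true_sites=sorted(sites), hotspot_regions=sorted(hotspots))


# ---------------------------------------------------------------------------
# Read pairs


@dataclass
class ReadPair:
    read_id: str
    label: str  # "junction:<site index>", "noise", "duplicate:<read id>"
    pair: TagPair
    seq1: str | None = None
    seq2: str | None = None


_COMP = str.maketrans("ACGT", "TGCA")


def _read_sequence(
    sequences: dict[str, str], chrom: str, pos: int, strand: str,
    read_length: int, tag_length: int,
) -> str:
    seq = sequences[chrom]
    if strand == "+":
        sub = seq[pos : pos + read_length]
    else:
        sub = seq[max(0, pos + tag_length - read_length) : pos + tag_length]
        sub = sub.translate(_COMP)[::-1]
    return sub + "A" * (read_length - len(sub))


def simulate_read_pairs(
    truth: TruthTable,
    config: SimulationConfig,
    genome: SimulatedGenome | GenomeDef,
    rng: np.random.Generator | None = None,
    detection_prob: float | None = None,
    read_prefix: str = "r",
    with_sequences: bool = False,
) -> tuple[list[ReadPair], TruthTable]:
    """Emit junction/noise/duplicate read pairs for a planted interactome.

    Returns the read-pair records (tag alignments always; sequences when
    requested and the genome carries sequence) and a truth table whose
    site read_counts hold the *expected surviving support*: junction reads
    plus their PCR duplicates, minus MAPQ-degraded pairs.  When
    *detection_prob* is set (a biological replicate at finite depth), each
    site independently enters the library with that probability;
    undetected sites keep read_count 0.
    """
    rng = rng or np.random.default_rng(config.seed)
    sim_genome = genome if isinstance(genome, SimulatedGenome) else None
    gdef = genome.genome if isinstance(genome, SimulatedGenome) else genome
    bait = config.bait
    biv = bait.interval
    p_geom = 1.0 / (config.reads_per_site_mean - config.reads_per_site_min + 1)
    lengths = np.asarray(gdef.lengths, dtype=float)

    records: list[ReadPair] = []
    site_of_record: list[int | None] = []

    def bait_tag() -> TagAlignment:
        pos = int(rng.integers(biv.start, biv.end - config.tag_length + 1))
        return TagAlignment(biv.chrom, pos, "+", 60, True)

    def random_tag(avoid_bait: bool) -> TagAlignment:
        while True:
            chrom = gdef.names[int(rng.choice(len(gdef.names), p=lengths / lengths.sum()))]
            pos = int(rng.integers(0, gdef.length(chrom) - config.tag_length))
            if avoid_bait and bait.contains(chrom, pos):
                continue
            strand = "+" if rng.random() < 0.5 else "-"
            return TagAlignment(chrom, pos, strand, 60, True)

    for si, site in enumerate(truth.true_sites):
        if detection_prob is not None and rng.random() >= detection_prob:
            continue
        n_reads = config.reads_per_site_min - 1 + int(rng.geometric(p_geom))
        L = gdef.length(site.chrom)
        for _ in range(n_reads):
            jit = int(rng.integers(-config.jitter, config.jitter + 1))
            pos = int(np.clip(site.pos + jit, 0, L - config.tag_length))
            strand = "+" if rng.random() < 0.5 else "-"
            partner = TagAlignment(site.chrom, pos, strand, 60, True)
            btag = bait_tag()
            if rng.random() < 0.5:
                tag1, tag2 = btag, partner
            else:
                tag1, tag2 = partner, btag
            records.append(
                ReadPair(read_id="", label=f"junction:{si}", pair=TagPair("", tag1, tag2))
            )
            site_of_record.append(si)

    n_junction = len(records)
    f = config.noise_fraction
    n_noise = int(round(n_junction * f / (1 - f))) if f < 1 else 0
    for _ in range(n_noise):
        if rng.random() < 0.5:
            tag1, tag2 = random_tag(avoid_bait=True), random_tag(avoid_bait=True)
        else:
            tag1, tag2 = bait_tag(), bait_tag()
        records.append(ReadPair(read_id="", label="noise", pair=TagPair("", tag1, tag2)))
        site_of_record.append(None)

    d = config.duplicate_rate
    n_dup = int(round(len(records) * d / (1 - d))) if d < 1 else 0
    n_originals = len(records)
    for _ in range(n_dup):
        k = int(rng.integers(0, n_originals))
        orig = records[k]
        records.append(
            ReadPair(read_id="", label=f"duplicate:{k}", pair=orig.pair)
        )
        site_of_record.append(site_of_record[k])

    # assign ids, then degrade MAPQ on a random subset of all pairs
    for i, rec in enumerate(records):
        rid = f"{read_prefix}{i:07d}"
        rec.read_id = rid
        rec.pair = TagPair(rid, rec.pair.tag1, rec.pair.tag2)
        if rec.label.startswith("duplicate:"):
            k = int(rec.label.split(":", 1)[1])
            rec.label = f"duplicate:{read_prefix}{k:07d}"
    n_degraded = int(round(config.mapq_degraded_fraction * len(records)))
    degraded_idx = (
        rng.choice(len(records), size=n_degraded, replace=False)
        if n_degraded
        else np.empty(0, dtype=int)
    )
    degraded = set(int(i) for i in degraded_idx)
    for i in degraded:
        rec = records[i]
        low = int(rng.integers(0, 21))
        which = rng.random() < 0.5
        t1, t2 = rec.pair.tag1, rec.pair.tag2
        if which:
            t1 = TagAlignment(t1.chrom, t1.pos, t1.strand, low, t1.unique)
        else:
            t2 = TagAlignment(t2.chrom, t2.pos, t2.strand, low, t2.unique)
        rec.pair = TagPair(rec.read_id, t1, t2)
        rec.label += "|mapq_degraded"

    support = np.zeros(len(truth.true_sites), dtype=int)
    for i, si in enumerate(site_of_record):
        if si is not None and i not in degraded:
            support[si] += 1

    if with_sequences:
        if sim_genome is None or sim_genome.sequences is None:
            raise ValueError("sequences requested but genome carries none")
        for rec in records:
            rec.seq1 = _read_sequence(
                sim_genome.sequences, rec.pair.tag1.chrom, rec.pair.tag1.pos,
                rec.pair.tag1.strand, config.read_length, config.tag_length,
            )
            rec.seq2 = _read_sequence(
                sim_genome.sequences, rec.pair.tag2.chrom, rec.pair.tag2.pos,
                rec.pair.tag2.strand, config.read_length, config.tag_length,
            )

    # read_count must stay >= 1 for the dataclass invariant; sites with
    # expected support 0 or 1 are equally undetectable past the singleton
    # filter, so both are stored as 1
    new_truth = TruthTable(
        true_sites=[
            GenomicSite(s.chrom, s.pos, max(1, int(n)))
            for s, n in zip(truth.true_sites, support)
        ],
        hotspot_regions=list(truth.hotspot_regions),
        read_labels={rec.read_id: rec.label for rec in records},
        interacting_gene_ids=set(truth.interacting_gene_ids),
    )
    return records, new_truth


# ---------------------------------------------------------------------------
# Feature tracks


@dataclass
class TrackSet:
    peak_tracks: dict[str, FeatureTrack]  # histone marks, DHS, 5-hmC
    tf_chip: dict[str, FeatureTrack]
    tf_input: FeatureTrack
    tf_library_sizes: dict[str, int]
    input_library_size: int
    timing: FeatureTrack
    fpkm: "object"  # pandas Series gene id -> FPKM


class _UnionSampler:
    """Vectorized uniform position sampler over a union of disjoint
    intervals."""

    def __init__(self, intervals: list[GenomicInterval]):
        self.intervals = intervals
        widths = np.asarray([iv.width for iv in intervals], dtype=np.int64)
        self.cum = np.concatenate([[0], np.cumsum(widths)])
        self.total = int(self.cum[-1])

    def draw(self, rng: np.random.Generator, n: int) -> list[tuple[str, int]]:
        if n == 0 or self.total == 0:
            return []
        g = rng.integers(0, self.total, size=n)
        idx = np.searchsorted(self.cum, g, side="right") - 1
        return [
            (self.intervals[i].chrom, self.intervals[i].start + int(g[k] - self.cum[i]))
            for k, i in enumerate(idx)
        ]


def _complement(intervals: list[GenomicInterval], genome: GenomeDef) -> list[GenomicInterval]:
    by_chrom: dict[str, list[GenomicInterval]] = {c: [] for c in genome.names}
    for iv in intervals:
        by_chrom[iv.chrom].append(iv)
    out = []
    for chrom in genome.names:
        prev = 0
        for iv in sorted(by_chrom[chrom], key=lambda v: v.start):
            if iv.start > prev:
                out.append(GenomicInterval(chrom, prev, iv.start))
            prev = max(prev, iv.end)
        if prev < genome.length(chrom):
            out.append(GenomicInterval(chrom, prev, genome.length(chrom)))
    return out


def _enriched_positions(
    n: int,
    enrichment: float,
    near: list[GenomicInterval],
    genome: GenomeDef,
    rng: np.random.Generator,
) -> list[tuple[str, int]]:
    """n positions with placement density multiplied by *enrichment* inside
    the *near* intervals."""
    far_sampler = _UnionSampler(_complement(near, genome))
    near_sampler = _UnionSampler(near)
    w_near = enrichment * near_sampler.total
    denom = w_near + far_sampler.total
    p_near = w_near / denom if denom > 0 else 0.0
    n_near = int(rng.binomial(n, p_near)) if 0 < p_near < 1 else (n if p_near >= 1 else 0)
    return near_sampler.draw(rng, n_near) + far_sampler.draw(rng, n - n_near)


def simulate_feature_tracks(
    truth: TruthTable,
    config: SimulationConfig,
    genome: SimulatedGenome,
    rng: np.random.Generator | None = None,
) -> tuple[TrackSet, TruthTable]:
    """Feature tracks with controlled co-localization around true sites.

    Active-like peak tracks (H3K4me1/H3K27ac/H3K4me3/H3K9ac, DHS, 5-hmC)
    multiply placement density by ``track_enrichment`` within ±0.5 Mb of
    true sites; repressive-like tracks (H3K27me3, H3K9me3) ignore the
    sites.  Replication-timing segments tile the genome with mean
    ``timing_shift`` near sites and 0 elsewhere.  TF ChIP tag tracks add
    ``(enrichment − 1) ×`` background density within ±1 kb of sites over a
    uniform background, with a uniform input library.  Genes whose body
    ±``gene_neighborhood`` touches a true site draw FPKM from the higher
    lognormal and are recorded as the interacting gene set.
    """
    import pandas as pd

    rng = rng or np.random.default_rng(config.seed)
    gdef = genome.genome
    site_points = [GenomicSite(s.chrom, s.pos) for s in truth.true_sites]

    def near_mask(flank: int) -> list[GenomicInterval]:
        ivs = [
            GenomicInterval(
                s.chrom,
                max(0, s.pos - flank),
                min(gdef.length(s.chrom), s.pos + flank + 1),
            )
            for s in site_points
        ]
        return merge_overlapping(ivs)

    mask_peaks = near_mask(config.colocalization_flank)
    total_L = gdef.total_length

    def peak_track(name: str, density: float, enrichment: float) -> FeatureTrack:
        n = int(round(density * total_L))
        pts = _enriched_positions(n, enrichment, mask_peaks, gdef, rng)
        ivs = [
            GenomicInterval(c, p, min(gdef.length(c), p + config.peak_width))
            for c, p in pts
            if p < gdef.length(c)
        ]
        return FeatureTrack(name, ivs, kind="peak")

    e = config.track_enrichment
    peak_tracks = {
        "H3K4me1": peak_track("H3K4me1", config.peak_track_density, e),
        "H3K27ac": peak_track("H3K27ac", config.peak_track_density, e),
        "H3K4me3": peak_track("H3K4me3", config.peak_track_density, e),
        "H3K9ac": peak_track("H3K9ac", config.peak_track_density, e),
        "H3K27me3": peak_track("H3K27me3", config.peak_track_density, 1.0),
        "H3K9me3": peak_track("H3K9me3", config.peak_track_density, 1.0),
        "DHS": peak_track("DHS", config.dhs_density, e),
        "5hmC": peak_track("5hmC", config.hmc_density, e),
    }

    # replication timing: fixed tiling, value ~ N(shift·near, sd)
    mask_timing = FeatureTrack("near_sites", near_mask(config.timing_flank), kind="peak")
    timing_ivs = []
    for chrom in gdef.names:
        L = gdef.length(chrom)
        starts = np.arange(0, L, config.timing_segment_bp)
        m_starts, m_ends, _ = mask_timing.arrays(chrom)
        for s in starts:
            e_seg = min(int(s + config.timing_segment_bp), L)
            k = np.searchsorted(m_starts, e_seg, side="left")
            near = bool((m_ends[:k] > s).any()) if k else False
            mean = config.timing_shift if near else 0.0
            timing_ivs.append(
                GenomicInterval(chrom, int(s), e_seg, value=float(rng.normal(mean, config.timing_sd)))
            )
    timing = FeatureTrack("timing", timing_ivs, kind="valued_segment")

    # TF tag tracks
    mask_tf = near_mask(config.tf_flank)
    n_bg = int(round(config.chip_tag_density * total_L))
    tf_sampler = _UnionSampler(mask_tf)

    def uniform_tag_track(name: str, n_extra_near: int) -> FeatureTrack:
        data: dict[str, list[np.ndarray]] = {c: [] for c in gdef.names}
        for chrom, n in zip(
            gdef.names, rng.multinomial(n_bg, np.asarray(gdef.lengths) / total_L)
        ):
            data[chrom].append(rng.integers(0, gdef.length(chrom), size=n))
        grouped: dict[str, list[int]] = {}
        for chrom, p in tf_sampler.draw(rng, n_extra_near):
            grouped.setdefault(chrom, []).append(p)
        for chrom, pts in grouped.items():
            data[chrom].append(np.asarray(pts, dtype=np.int64))
        arrays = {}
        for chrom, parts in data.items():
            starts = np.concatenate(parts)
            if starts.size:
                arrays[chrom] = (starts, starts + 1)
        return FeatureTrack.from_arrays(name, arrays, kind="point")

    tf_chip: dict[str, FeatureTrack] = {}
    tf_sizes: dict[str, int] = {}
    for tf in config.tf_names:
        n_extra = (
            int(rng.poisson(config.chip_tag_density * (e - 1) * tf_sampler.total))
            if e > 1 and tf_sampler.total
            else 0
        )
        tf_chip[tf] = uniform_tag_track(tf, n_extra)
        tf_sizes[tf] = len(tf_chip[tf])
    tf_input = uniform_tag_track("input", 0)

    # FPKM: interacting genes draw from the higher lognormal
    (mi, si_), (mb, sb) = config.fpkm_lognormal
    interacting: set[str] = set()
    site_track = FeatureTrack(
        "sites",
        [GenomicInterval(s.chrom, s.pos, s.pos + 1) for s in site_points],
        kind="point",
    )
    fpkm = {}
    for g in genome.genes:
        lo = max(0, g.start - config.gene_neighborhood)
        hi = g.end + config.gene_neighborhood
        hits = site_track.overlapping(g.chrom, lo, hi - 1)
        if hits:
            interacting.add(g.name)
            fpkm[g.name] = float(rng.lognormal(mi, si_))
        else:
            fpkm[g.name] = float(rng.lognormal(mb, sb))
    fpkm_series = pd.Series(fpkm, name="fpkm").sort_index()

    new_truth = TruthTable(
        true_sites=list(truth.true_sites),
        hotspot_regions=list(truth.hotspot_regions),
        read_labels=dict(truth.read_labels),
        interacting_gene_ids=interacting,
    )
    tracks = TrackSet(
        peak_tracks=peak_tracks,
        tf_chip=tf_chip,
        tf_input=tf_input,
        tf_library_sizes=tf_sizes,
        input_library_size=len(tf_input),
        timing=timing,
        fpkm=fpkm_series,
    )
    return tracks, new_truth


# ---------------------------------------------------------------------------
# One-call dataset + writers


@dataclass
class SimulatedDataset:
    config: SimulationConfig
    genome: SimulatedGenome
    truth: TruthTable
    reads: list[ReadPair]
    tracks: TrackSet


def simulate_dataset(
    config: SimulationConfig,
    with_sequences: bool = False,
    with_tracks: bool = True,
) -> SimulatedDataset:
    """Generate genome, interactome, reads and (optionally) tracks from one
    config; each stage runs on an independent child stream of the seed so
    artifacts are byte-reproducible."""
    ss = np.random.SeedSequence(config.seed)
    rng_genome, rng_sites, rng_reads, rng_tracks = (
        np.random.default_rng(c) for c in ss.spawn(4)
    )
    genome = simulate_genome(config, rng_genome, with_sequence=with_sequences)
    truth = simulate_interactome(config, genome, rng_sites)
    reads, truth = simulate_read_pairs(
        truth, config, genome, rng_reads, with_sequences=with_sequences
    )
    if with_tracks:
        tracks, truth = simulate_feature_tracks(truth, config, genome, rng_tracks)
    else:
        import pandas as pd

        tracks = TrackSet({}, {}, FeatureTrack("input", [], "point"), {}, 0,
                          FeatureTrack("timing", [], "valued_segment"), pd.Series(dtype=float))
    return SimulatedDataset(config=config, genome=genome, truth=truth, reads=reads, tracks=tracks)


def write_fasta(sequences: dict[str, str], path: str | Path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for chrom, seq in sequences.items():
            fh.write(f">{chrom}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_fastq(reads: Sequence[ReadPair], path1: str | Path, path2: str | Path) -> None:
    with open(path1, "w") as f1, open(path2, "w") as f2:
        for rec in reads:
            if rec.seq1 is None or rec.seq2 is None:
                raise ValueError("read pairs carry no sequence; simulate with sequences")
            f1.write(f"@{rec.read_id}/1\n{rec.seq1}\n+\n{'I' * len(rec.seq1)}\n")
            f2.write(f"@{rec.read_id}/2\n{rec.seq2}\n+\n{'I' * len(rec.seq2)}\n")
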