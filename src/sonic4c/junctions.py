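"""From read pairs (or pre-aligned end-tag pairs) to unique distal
interacting sites.

The sonication-based 4C library yields read pairs that are mosaics of the
bait locus and its ligated interaction partner.  The pipeline takes 20-bp
end tags from each mate, keeps pairs where both tags map uniquely with
MAPQ > 20, classifies a pair as a bait junction when exactly one tag lies
inside the ~0.6 kb bait region and the other maps > 300 bp away, and keeps
the distal subset (> 10 kb on the bait chromosome, or inter-chromosomal).
Distal non-bait tags within 100 bp of each other are interpreted as PCR
products of a single ligation event and merged into one site; sites
supported by a single read are discarded as background noise.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .core import GenomeDef, GenomicInterval, GenomicSite

__all__ = [
    "TagAlignment",
    "TagPair",
    "BaitRegion",
    "JunctionClass",
    "extract_end_tags",
    "filter_tag_pairs",
    "classify_junction",
    "call_distal_sites",
    "call_sites",
    "SiteCallReport",
    "read_tag_table",
    "write_tag_table",
]

DEFAULT_MAPQ_MIN = 20
DEFAULT_MERGE_WINDOW = 100
DEFAULT_MIN_READS = 2
DEFAULT_DISTAL_CUTOFF = 10_000
DEFAULT_JUNCTION_CUTOFF = 300


@dataclass(frozen=True)
class TagAlignment:
    """Alignment of one 20-bp end tag.  ``chrom=None`` means unmapped."""

    chrom: str | None
    pos: int
    strand: str = "+"
    mapq: int = 0
    unique: bool = False


@dataclass(frozen=True)
class TagPair:
    read_id: str
    tag1: TagAlignment
    tag2: TagAlignment


@dataclass(frozen=True)
class BaitRegion:
    """The fixed ~0.6 kb bait: nested-PCR primer locations plus a 300-bp
    extension.  ``source`` distinguishes the endogenous locus from a
    transgenic insertion."""

    interval: GenomicInterval
    source: str = "endogenous"

    @classmethod
    def from_string(cls, text: str, source: str = "endogenous") -> "BaitRegion":
        """Parse ``chrom:start-end`` (0-based half-open)."""
        chrom, _, rest = text.partition(":")
        lo, _, hi = rest.partition("-")
        return cls(GenomicInterval(chrom, int(lo), int(hi)), source=source)

    def contains(self, chrom: str | None, pos: int) -> bool:
        iv = self.interval
        return chrom == iv.chrom and iv.start <= pos < iv.end

    def distance_to(self, pos: int) -> int:
        """Distance from a tag start outside the bait to the nearest bait
        boundary; 0 inside."""
        iv = self.interval
        if pos < iv.start:
            return iv.start - pos
        if pos >= iv.end:
            return pos - iv.end + 1
        return 0


class JunctionClass(Enum):
    NON_JUNCTION = "non_junction"
    JUNCTION_PROXIMAL = "junction_proximal"
    DISTAL_INTRA = "distal_intra"
    INTER = "inter"


def extract_end_tags(
    seq1: str, seq2: str, tag_length: int = 20
) -> tuple[str, str] | None:
    """First ``tag_length`` bases (5' ends) of each mate; ``None`` when either
    read is too short (callers count dropped pairs)."""
    if len(seq1) < tag_length or len(seq2) < tag_length:
        return None
    return seq1[:tag_length], seq2[:tag_length]


def filter_tag_pairs(
    pairs: Iterable[TagPair], mapq_min: int = DEFAULT_MAPQ_MIN
) -> list[TagPair]:
    """Keep pairs where both tags are uniquely mapped with MAPQ strictly
    above *mapq_min*."""
    return [
        p
        for p in pairs
        if p.tag1.chrom is not None
        and p.tag2.chrom is not None
        and p.tag1.unique
        and p.tag2.unique
        and p.tag1.mapq > mapq_min
        and p.tag2.mapq > mapq_min
    ]


def classify_junction(
    pair: TagPair,
    bait: BaitRegion,
    distal_cutoff: int = DEFAULT_DISTAL_CUTOFF,
    junction_cutoff: int = DEFAULT_JUNCTION_CUTOFF,
) -> JunctionClass:
    """Assign exactly one junction class to a filtered pair.

    Exactly one tag inside the bait makes a junction candidate; the other
    tag then decides: different chromosome → INTER; same chromosome more
    than *distal_cutoff* from the bait → DISTAL_INTRA; more than
    *junction_cutoff* → JUNCTION_PROXIMAL.  Everything else (both tags in
    the bait, neither in the bait, or the partner within *junction_cutoff*)
    is NON_JUNCTION.
    """
    in1 = bait.contains(pair.tag1.chrom, pair.tag1.pos)
    in2 = bait.contains(pair.tag2.chrom, pair.tag2.pos)
    if in1 == in2:
        return JunctionClass.NON_JUNCTION
    other = pair.tag2 if in1 else pair.tag1
    if other.chrom != bait.interval.chrom:
        return JunctionClass.INTER
    dist = bait.distance_to(other.pos)
    if dist > distal_cutoff:
        return JunctionClass.DISTAL_INTRA
    if dist > junction_cutoff:
        return JunctionClass.JUNCTION_PROXIMAL
    return JunctionClass.NON_JUNCTION


def call_distal_sites(
    distal_tags: Sequence[tuple[str, int]],
    merge_window: int = DEFAULT_MERGE_WINDOW,
    min_reads: int = DEFAULT_MIN_READS,
) -> list[GenomicSite]:
    """Merge distal non-bait tags into unique interacting sites.

    Per chromosome, sorted tag positions chain into one cluster while the
    gap between consecutive tags is ≤ *merge_window* (single linkage, so the
    result is independent of input order).  A cluster becomes a site at the
    median tag position (rounded down) with read_count = cluster size;
    clusters with fewer than *min_reads* reads are discarded.
    """
    by_chrom: dict[str, list[int]] = {}
    for chrom, pos in distal_tags:
        by_chrom.setdefault(chrom, []).append(pos)
    sites: list[GenomicSite] = []
    for chrom in sorted(by_chrom):
        pos = np.sort(np.asarray(by_chrom[chrom], dtype=np.int64))
        if pos.size == 0:
            continue
        breaks = np.flatnonzero(np.diff(pos) > merge_window) + 1
        for cluster in np.split(pos, breaks):
            if cluster.size >= min_reads:
                sites.append(
                    GenomicSite(chrom, int(np.floor(np.median(cluster))), int(cluster.size))
                )
    return sorted(sites)


@dataclass
class SiteCallReport:
    """Read-pair accounting through the pipeline (per-class counts mirror a
    '# read pairs' / '# sites' summary table)."""

    n_pairs_total: int
    n_pairs_filtered: int
    class_counts: dict[str, int]
    n_distal_tags: int
    n_sites: int

    def to_frame(self) -> pd.DataFrame:
        rows = [
            ("total_pairs", self.n_pairs_total),
            ("pairs_passing_filter", self.n_pairs_filtered),
            *((f"class_{k}", v) for k, v in sorted(self.class_counts.items())),
            ("distal_tags", self.n_distal_tags),
            ("distal_sites", self.n_sites),
        ]
        return pd.DataFrame(rows, columns=["metric", "count"])


def call_sites(
    pairs: Sequence[TagPair],
    bait: BaitRegion,
    mapq_min: int = DEFAULT_MAPQ_MIN,
    merge_window: int = DEFAULT_MERGE_WINDOW,
    min_reads: int = DEFAULT_MIN_READS,
    distal_cutoff: int = DEFAULT_DISTAL_CUTOFF,
    junction_cutoff: int = DEFAULT_JUNCTION_CUTOFF,
) -> tuple[list[GenomicSite], SiteCallReport]:
    """Full tag-pair → distal-site pipeline with accounting."""
    kept = filter_tag_pairs(pairs, mapq_min=mapq_min)
    class_counts = {c.value: 0 for c in JunctionClass}
    distal_tags: list[tuple[str, int]] = []
    for p in kept:
        cls = classify_junction(p, bait, distal_cutoff, junction_cutoff)
        class_counts[cls.value] += 1
        if cls in (JunctionClass.DISTAL_INTRA, JunctionClass.INTER):
            other = p.tag2 if bait.contains(p.tag1.chrom, p.tag1.pos) else p.tag1
            distal_tags.append((other.chrom, other.pos))
    sites = call_distal_sites(distal_tags, merge_window=merge_window, min_reads=min_reads)
    report = SiteCallReport(
        n_pairs_total=len(pairs),
        n_pairs_filtered=len(kept),
        class_counts=class_counts,
        n_distal_tags=len(distal_tags),
        n_sites=len(sites),
    )
    return sites, report


# ---------------------------------------------------------------------------
# Tag-table I/O (tab-separated, one row per tag, two rows per read pair)

_TAG_COLUMNS = ["read_id", "end", "chrom", "pos", "strand", "mapq", "unique"]


def write_tag_table(pairs: Sequence[TagPair], path: str | Path) -> None:
    rows = []
    for p in pairs:
        for end, tag in ((1, p.tag1), (2, p.tag2)):
            rows.append(
                (
                    p.read_id,
                    end,
                    tag.chrom if tag.chrom is not None else "*",
                    tag.pos,
                    tag.strand,
                    tag.mapq,
                    int(tag.unique),
                )
            )
    pd.DataFrame(rows, columns=_TAG_COLUMNS).to_csv(path, sep="\t", index=False)


def read_tag_table(path: str | Path, genome: GenomeDef | None = None) -> list[TagPair]:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    missing = set(_TAG_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"tag table missing columns: {sorted(missing)}")
    pairs: list[TagPair] = []
    for read_id, group in df.groupby("read_id", sort=False):
        tags: dict[int, TagAlignment] = {}
        for row in group.itertuples(index=False):
            chrom = None if row.chrom == "*" else row.chrom
            if genome is not None and chrom is not None and chrom not in genome:
                raise ValueError(f"tag table chromosome {chrom!r} not in genome")
            tags[int(row.end)] = TagAlignment(
                chrom, int(row.pos), str(row.strand), int(row.mapq), bool(row.unique)
            )
        if set(tags) != {1, 2}:
            raise ValueError(f"read {read_id!r} does not have exactly tags 1 and 2")
        pairs.append(TagPair(str(read_id), tags[1], tags[2]))
    return pairs
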