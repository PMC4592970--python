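"""Genomic coordinate arithmetic, interval containers, and track I/O.

Conventions used throughout the package:

* Coordinates are 0-based, half-open ``[start, end)`` — the native BED
  convention.  1-based coordinates appear only in user-facing display
  strings.
* Strand is ignored everywhere: every analysis in this pipeline is
  strand-agnostic.
* Anchor windows (``pos ± flank``) are closed position ranges truncated at
  chromosome ends; counts are never rescaled for truncation, so observed and
  shuffled anchors are subject to identical edge effects.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np

__all__ = [
    "BedParseError",
    "GenomeDef",
    "GenomicInterval",
    "GenomicSite",
    "FeatureTrack",
    "read_bed",
    "write_bed",
    "read_chrom_sizes",
    "count_features_in_flank",
    "nearest_feature_distance",
    "shuffle_sites",
    "merge_overlapping",
]


class BedParseError(ValueError):
    """Malformed BED/bedGraph input; carries the 1-based line number."""

    def __init__(self, message: str, line_number: int | None = None):
        self.line_number = line_number
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)


@dataclass(frozen=True)
class GenomeDef:
    """Ordered chromosome names and lengths (bp)."""

    names: tuple[str, ...]
    lengths: tuple[int, ...]

    def __post_init__(self):
        if len(self.names) != len(self.lengths):
            raise ValueError("names and lengths differ in length")
        if len(set(self.names)) != len(self.names):
            raise ValueError("chromosome names must be unique")
        if any(l <= 0 for l in self.lengths):
            raise ValueError("chromosome lengths must be strictly positive")
        object.__setattr__(self, "_sizes", dict(zip(self.names, self.lengths)))

    @classmethod
    def from_dict(cls, sizes: dict[str, int]) -> "GenomeDef":
        return cls(tuple(sizes), tuple(sizes.values()))

    @classmethod
    def from_chrom_sizes(cls, path: str | Path) -> "GenomeDef":
        names, lengths = [], []
        with open(path) as fh:
            for i, line in enumerate(fh, 1):
                line = line.rstrip("\n")
                if not line:
                    continue
                parts = line.split("\t")
                if len(parts) < 2:
                    raise BedParseError("expected 'chrom\\tlength'", i)
                try:
                    n = int(parts[1])
                except ValueError as exc:
                    raise BedParseError(f"non-integer length {parts[1]!r}", i) from exc
                names.append(parts[0])
                lengths.append(n)
        return cls(tuple(names), tuple(lengths))

    def to_chrom_sizes(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for name, length in zip(self.names, self.lengths):
                fh.write(f"{name}\t{length}\n")

    def __contains__(self, chrom: str) -> bool:
        return chrom in self._sizes

    def length(self, chrom: str) -> int:
        try:
            return self._sizes[chrom]
        except KeyError:
            raise KeyError(f"unknown chromosome {chrom!r}") from None

    @property
    def total_length(self) -> int:
        return int(sum(self.lengths))


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """0-based half-open interval, optionally valued (e.g. log2 timing ratio)."""

    chrom: str
    start: int
    end: int
    value: float | None = field(default=None, compare=False)
    name: str | None = field(default=None, compare=False)

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )

    @property
    def width(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def __str__(self) -> str:  # 1-based display form
        return f"{self.chrom}:{self.start + 1}-{self.end}"


@dataclass(frozen=True, order=True)
class GenomicSite:
    """A 1-bp distal interacting locus (representative position of a merged
    tag cluster) with its supporting read count."""

    chrom: str
    pos: int
    read_count: int = 1

    def __post_init__(self):
        if self.pos < 0:
            raise ValueError("site position must be non-negative")
        if self.read_count < 1:
            raise ValueError("read_count must be positive")


TRACK_KINDS = ("peak", "valued_segment", "point")


class FeatureTrack:
    """A named, sorted set of genomic intervals.

    ``kind`` is one of ``peak`` (plain intervals), ``valued_segment``
    (intervals carrying a numeric value, e.g. replication-timing log2 ratios)
    or ``point`` (1-bp features such as TSSs, CpG positions or ChIP tags).
    Intervals are sorted by (chrom, start) on construction and exposed per
    chromosome as numpy arrays for the counting primitives.
    """

    def __init__(self, name: str, intervals: Iterable[GenomicInterval], kind: str = "peak"):
        if kind not in TRACK_KINDS:
            raise ValueError(f"kind must be one of {TRACK_KINDS}")
        self.name = name
        self.kind = kind
        self._intervals: list[GenomicInterval] | None = sorted(
            intervals, key=lambda iv: (iv.chrom, iv.start, iv.end)
        )
        if kind == "valued_segment":
            for iv in self._intervals:
                if iv.value is None:
                    raise ValueError(
                        f"valued_segment track {name!r} has an interval without a value"
                    )
        self._by_chrom: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        self._names: dict[str, list[str | None]] = {}
        chrom_slices: dict[str, list[GenomicInterval]] = {}
        for iv in self._intervals:
            chrom_slices.setdefault(iv.chrom, []).append(iv)
        for chrom, ivs in chrom_slices.items():
            starts = np.asarray([iv.start for iv in ivs], dtype=np.int64)
            ends = np.asarray([iv.end for iv in ivs], dtype=np.int64)
            values = np.asarray(
                [np.nan if iv.value is None else iv.value for iv in ivs], dtype=float
            )
            self._by_chrom[chrom] = (starts, ends, values)
            self._names[chrom] = [iv.name for iv in ivs]
        self._n = len(self._intervals)

    @classmethod
    def from_arrays(
        cls,
        name: str,
        data: dict[str, tuple[np.ndarray, np.ndarray] | tuple[np.ndarray, np.ndarray, np.ndarray]],
        kind: str = "peak",
    ) -> "FeatureTrack":
        """Bulk constructor from per-chromosome (starts, ends[, values])
        arrays; skips per-interval object creation (interval objects are
        materialized lazily on access).  Arrays are sorted by start."""
        if kind not in TRACK_KINDS:
            raise ValueError(f"kind must be one of {TRACK_KINDS}")
        self = cls.__new__(cls)
        self.name = name
        self.kind = kind
        self._intervals = None
        self._by_chrom = {}
        self._names = {}
        n = 0
        for chrom in sorted(data):
            arrs = data[chrom]
            starts = np.asarray(arrs[0], dtype=np.int64)
            ends = np.asarray(arrs[1], dtype=np.int64)
            values = (
                np.asarray(arrs[2], dtype=float)
                if len(arrs) > 2
                else np.full(starts.size, np.nan)
            )
            if starts.size and ((starts < 0).any() or (starts >= ends).any()):
                raise ValueError(f"invalid intervals on {chrom}")
            order = np.argsort(starts, kind="stable")
            self._by_chrom[chrom] = (starts[order], ends[order], values[order])
            self._names[chrom] = [None] * starts.size
            n += int(starts.size)
        self._n = n
        return self

    @property
    def intervals(self) -> list[GenomicInterval]:
        if self._intervals is None:
            out: list[GenomicInterval] = []
            for chrom in sorted(self._by_chrom):
                starts, ends, values = self._by_chrom[chrom]
                names = self._names[chrom]
                for s, e, v, nm in zip(starts, ends, values, names):
                    out.append(
                        GenomicInterval(
                            chrom, int(s), int(e),
                            value=None if np.isnan(v) else float(v), name=nm,
                        )
                    )
            self._intervals = out
        return self._intervals

    def __len__(self) -> int:
        return self._n

    def __iter__(self) -> Iterator[GenomicInterval]:
        return iter(self.intervals)

    @property
    def chroms(self) -> tuple[str, ...]:
        return tuple(self._by_chrom)

    def arrays(self, chrom: str) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(starts, ends, values) for one chromosome; empty arrays if absent."""
        empty = np.empty(0, dtype=np.int64)
        return self._by_chrom.get(chrom, (empty, empty, np.empty(0)))

    def overlapping(self, chrom: str, lo: int, hi: int) -> list[int]:
        """Indices (into the chromosome's sorted order) of intervals
        overlapping the closed position range [lo, hi]."""
        starts, ends, _ = self.arrays(chrom)
        k = int(np.searchsorted(starts, hi, side="right"))
        return [i for i in range(k) if ends[i] > lo]

    def total_covered(self) -> int:
        return sum(iv.width for iv in merge_overlapping(self.intervals))


# ---------------------------------------------------------------------------
# Track I/O


def read_bed(
    path: str | Path,
    kind: str = "peak",
    genome: GenomeDef | None = None,
    strict: bool = False,
    name: str | None = None,
) -> FeatureTrack:
    """Read BED3/BED4/BED6 or bedGraph into a :class:`FeatureTrack`.

    For ``kind="valued_segment"`` the 4th column is parsed as the numeric
    value (bedGraph).  Otherwise a 4th column is kept as the feature name and
    a 5th (score) column, when numeric, as the value.  Lines on chromosomes
    absent from *genome* are skipped, or rejected when ``strict=True``.
    ``track``/``browser``/``#`` lines are ignored.
    """
    intervals: list[GenomicInterval] = []
    path = Path(path)
    with open(path) as fh:
        for i, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("track", "browser", "#")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise BedParseError("fewer than 3 columns", i)
            chrom = parts[0]
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise BedParseError(f"non-integer coordinates {parts[1:3]}", i) from exc
            if start < 0 or start >= end:
                raise BedParseError(f"invalid coordinates start={start} end={end}", i)
            if genome is not None and chrom not in genome:
                if strict:
                    raise BedParseError(f"unknown chromosome {chrom!r}", i)
                continue
            value: float | None = None
            label: str | None = None
            if kind == "valued_segment":
                if len(parts) < 4:
                    raise BedParseError("valued_segment requires a 4th column", i)
                try:
                    value = float(parts[3])
                except ValueError as exc:
                    raise BedParseError(f"non-numeric value {parts[3]!r}", i) from exc
            else:
                if len(parts) >= 4:
                    label = parts[3]
                if len(parts) >= 5:
                    try:
                        value = float(parts[4])
                    except ValueError:
                        value = None
            intervals.append(GenomicInterval(chrom, start, end, value=value, name=label))
    return FeatureTrack(name or path.stem, intervals, kind=kind)


def write_bed(track: FeatureTrack | Sequence[GenomicInterval], path: str | Path) -> None:
    """Write intervals as BED (or bedGraph for valued_segment tracks)."""
    if isinstance(track, FeatureTrack):
        intervals = track.intervals
        valued = track.kind == "valued_segment"
    else:
        intervals = sorted(track, key=lambda iv: (iv.chrom, iv.start, iv.end))
        valued = False
    with open(path, "w") as fh:
        for iv in intervals:
            if valued:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.value:g}\n")
            elif iv.name is not None:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name}\n")
            else:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")


def read_chrom_sizes(path: str | Path) -> GenomeDef:
    return GenomeDef.from_chrom_sizes(path)


def sites_to_bed(sites: Sequence[GenomicSite], path: str | Path) -> None:
    """Write sites as BED4 with name = read_count."""
    with open(path, "w") as fh:
        for s in sorted(sites):
            fh.write(f"{s.chrom}\t{s.pos}\t{s.pos + 1}\t{s.read_count}\n")


def sites_from_bed(path: str | Path, genome: GenomeDef | None = None) -> list[GenomicSite]:
    track = read_bed(path, kind="point", genome=genome)
    sites = []
    for iv in track:
        try:
            count = int(iv.name) if iv.name is not None else 1
        except ValueError:
            count = 1
        sites.append(GenomicSite(iv.chrom, iv.start, count))
    return sites


# ---------------------------------------------------------------------------
# Counting primitives


def _anchor_window(pos: int, flank: int, chrom_len: int) -> tuple[int, int]:
    """Closed position range [lo, hi] of the ±flank window, truncated."""
    return max(0, pos - flank), min(chrom_len - 1, pos + flank)


def count_features_in_flank(
    anchors: Sequence[GenomicSite],
    track: FeatureTrack,
    flank: int,
    genome: GenomeDef,
) -> np.ndarray:
    """Number of track intervals overlapping ``pos ± flank`` per anchor.

    Windows truncate at chromosome ends; each anchor is counted
    independently, so one feature may contribute to several anchors.
    """
    if flank <= 0:
        raise ValueError("flank must be positive")
    if track.kind == "valued_segment":
        raise ValueError("count_features_in_flank expects a peak or point track")
    counts = np.zeros(len(anchors), dtype=np.int64)
    # counting trick on independently sorted starts and ends:
    # overlap(start <= hi AND end > lo)  ==  #(start <= hi) - #(end <= lo)
    sorted_ends: dict[str, np.ndarray] = {}
    for i, a in enumerate(anchors):
        chrom_len = genome.length(a.chrom)  # raises for unknown chromosome
        starts, ends, _ = track.arrays(a.chrom)
        if starts.size == 0:
            continue
        if a.chrom not in sorted_ends:
            sorted_ends[a.chrom] = np.sort(ends)
        lo, hi = _anchor_window(a.pos, flank, chrom_len)
        n_start_ok = np.searchsorted(starts, hi, side="right")
        n_end_before = np.searchsorted(sorted_ends[a.chrom], lo, side="right")
        counts[i] = int(n_start_ok - n_end_before)
    return counts


def nearest_feature_distance(
    anchors: Sequence[GenomicSite],
    track: FeatureTrack,
    missing: float = np.nan,
) -> np.ndarray:
    """Signed distance from each anchor to its nearest track element.

    0 when the anchor lies inside an element; positive when the anchor is
    downstream (to the right) of the element, negative when upstream.  Ties
    in absolute distance break toward the element with the lower coordinate.
    Anchors on chromosomes with no features get the declared *missing*
    sentinel (NaN by default), never a silent 0.
    """
    out = np.full(len(anchors), float(missing))
    chunk = 512
    by_chrom: dict[str, list[int]] = {}
    for i, a in enumerate(anchors):
        by_chrom.setdefault(a.chrom, []).append(i)
    for chrom, idxs in by_chrom.items():
        starts, ends, _ = track.arrays(chrom)
        if starts.size == 0:
            continue
        pos = np.asarray([anchors[i].pos for i in idxs], dtype=np.int64)
        idxs_arr = np.asarray(idxs)
        for k in range(0, pos.size, chunk):
            p = pos[k : k + chunk][:, None]  # (A, 1)
            # signed distance to every element: 0 inside, pos-start left of
            # element, pos-(end-1) right of element
            d = np.where(
                p < starts[None, :],
                p - starts[None, :],
                np.where(p >= ends[None, :], p - (ends[None, :] - 1), 0),
            )
            best = np.argmin(np.abs(d), axis=1)  # first occurrence = lowest start
            out[idxs_arr[k : k + chunk]] = d[np.arange(p.shape[0]), best]
    return out


def shuffle_sites(
    sites: Sequence[GenomicSite],
    genome: GenomeDef,
    seed: int | np.random.Generator,
    mode: str = "per_chromosome",
    exclude: FeatureTrack | None = None,
) -> list[GenomicSite]:
    """Random-site null: redraw site positions uniformly.

    ``per_chromosome`` (default) preserves the per-chromosome site counts,
    conditioning the null on the chromosomal distribution of the observed
    sites; ``genome_wide`` draws uniformly over the concatenated genome.
    *exclude* optionally masks regions (assembly gaps etc.) by rejection
    sampling.  Deterministic for a fixed seed; read counts are carried over.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if mode not in ("per_chromosome", "genome_wide"):
        raise ValueError("mode must be per_chromosome or genome_wide")

    def ok(chrom: str, p: int) -> bool:
        if exclude is None:
            return True
        starts, ends, _ = exclude.arrays(chrom)
        if starts.size == 0:
            return True
        j = np.searchsorted(starts, p, side="right") - 1
        return not (j >= 0 and ends[j] > p)

    out: list[GenomicSite] = []
    if mode == "per_chromosome":
        grouped: dict[str, list[GenomicSite]] = {}
        for s in sites:
            grouped.setdefault(s.chrom, []).append(s)
        for chrom in genome.names:
            group = grouped.get(chrom, [])
            if not group:
                continue
            L = genome.length(chrom)
            for s in group:
                while True:
                    p = int(rng.integers(0, L))
                    if ok(chrom, p):
                        break
                out.append(GenomicSite(chrom, p, s.read_count))
    else:
        lengths = np.asarray(genome.lengths, dtype=np.int64)
        edges = np.concatenate([[0], np.cumsum(lengths)])
        total = int(edges[-1])
        for s in sites:
            while True:
                g = int(rng.integers(0, total))
                ci = int(np.searchsorted(edges, g, side="right") - 1)
                chrom, p = genome.names[ci], g - int(edges[ci])
                if ok(chrom, p):
                    break
            out.append(GenomicSite(chrom, p, s.read_count))
    return out


def merge_overlapping(intervals: Iterable[GenomicInterval]) -> list[GenomicInterval]:
    """Merge overlapping and book-ended (end == start) intervals.

    Output is sorted and pairwise non-overlapping; the union of covered
    bases is preserved.  Values and names are dropped on merge.
    """
    ivs = sorted(intervals, key=lambda iv: (iv.chrom, iv.start, iv.end))
    merged: list[GenomicInterval] = []
    for iv in ivs:
        if merged and merged[-1].chrom == iv.chrom and iv.start <= merged[-1].end:
            last = merged[-1]
            if iv.end > last.end:
                merged[-1] = GenomicInterval(last.chrom, last.start, iv.end)
        else:
            merged.append(GenomicInterval(iv.chrom, iv.start, iv.end))
    return merged
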