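"""Replicate-concordance statistics.

Two complementary views of agreement between biological replicates:

* interaction counts in fixed genomic bins (2 Mb by default), correlated
  between replicates with Pearson's r;
* the relative-distance distribution between two site sets (for each query
  site, distance to the nearest reference site divided by the spacing of the
  two flanking reference sites), which is Uniform(0, 0.5) when the two sets
  are spatially independent and piles up near 0 when they co-localize.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .core import GenomeDef, GenomicSite

__all__ = [
    "BinVector",
    "RelativeDistanceResult",
    "bin_site_counts",
    "replicate_correlation",
    "relative_distance_distribution",
]


@dataclass
class BinVector:
    """Per-bin site counts tiling each chromosome (last bin truncated)."""

    genome: GenomeDef
    bin_size: int
    counts: dict[str, np.ndarray]

    def flatten(self) -> np.ndarray:
        return np.concatenate([self.counts[c] for c in self.genome.names])

    @property
    def n_sites(self) -> int:
        return int(self.flatten().sum())


def bin_site_counts(
    sites: Sequence[GenomicSite], genome: GenomeDef, bin_size: int = 2_000_000
) -> BinVector:
    """Count sites per half-open bin [k*bin, (k+1)*bin); all bins reported,
    zeros included."""
    if bin_size <= 0:
        raise ValueError("bin_size must be positive")
    counts = {
        chrom: np.zeros(int(np.ceil(genome.length(chrom) / bin_size)), dtype=np.int64)
        for chrom in genome.names
    }
    for s in sites:
        counts[s.chrom][s.pos // bin_size] += 1
    return BinVector(genome=genome, bin_size=bin_size, counts=counts)


def replicate_correlation(a: BinVector, b: BinVector, nonzero_only: bool = False):
    """Pearson r between two aligned bin vectors.

    All bins enter by default (empty bins carry replicate information); with
    ``nonzero_only=True`` bins empty in both replicates are dropped.
    Returns ``(r, x, y)`` where x, y are the compared vectors; r is NaN when
    either vector has zero variance (undefined correlation, never silently
    0).
    """
    if a.genome != b.genome or a.bin_size != b.bin_size:
        raise ValueError("bin vectors must share genome and bin size")
    x, y = a.flatten().astype(float), b.flatten().astype(float)
    if nonzero_only:
        keep = (x > 0) | (y > 0)
        x, y = x[keep], y[keep]
    if x.size < 2 or np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan"), x, y
    r = stats.pearsonr(x, y).statistic
    return float(r), x, y


@dataclass
class RelativeDistanceResult:
    values: np.ndarray  # in [0, 0.5]
    hist_counts: np.ndarray  # fixed bins of width 0.01
    bin_edges: np.ndarray
    ks_stat: float
    p_uniform: float
    n_skipped: int  # query sites without two flanking reference sites


def relative_distance_distribution(
    a: Sequence[GenomicSite], b: Sequence[GenomicSite]
) -> RelativeDistanceResult:
    """Relative distance of every a-site to the b-site set.

    For an a-site flanked by consecutive b-positions ``l <= pos <= r``, the
    value is ``min(pos - l, r - pos) / (r - l)``; a-sites coinciding with a
    b-site score 0.  a-sites before the first or after the last b-site on a
    chromosome are skipped (counted in ``n_skipped``).  Uniformity against
    Uniform(0, 0.5) is assessed with a one-sample Kolmogorov–Smirnov test.
    """
    b_by_chrom: dict[str, list[int]] = {}
    for s in b:
        b_by_chrom.setdefault(s.chrom, []).append(s.pos)
    if not any(
        chrom in b_by_chrom for chrom in {s.chrom for s in a}
    ):
        raise ValueError("reference set empty on every query chromosome")
    values: list[float] = []
    n_skipped = 0
    sorted_b = {c: np.sort(np.asarray(p, dtype=np.int64)) for c, p in b_by_chrom.items()}
    for s in a:
        bp = sorted_b.get(s.chrom)
        if bp is None or bp.size < 2:
            n_skipped += 1
            continue
        i = int(np.searchsorted(bp, s.pos, side="left"))
        if i < bp.size and bp[i] == s.pos:
            values.append(0.0)
            continue
        if i == 0 or i == bp.size:
            n_skipped += 1
            continue
        dl = s.pos - int(bp[i - 1])
        dr = int(bp[i]) - s.pos
        values.append(min(dl, dr) / (dl + dr))
    vals = np.asarray(values)
    edges = np.round(np.arange(0, 0.51, 0.01), 10)
    hist, _ = np.histogram(vals, bins=edges)
    if vals.size:
        ks = stats.kstest(vals, lambda x: np.clip(x / 0.5, 0.0, 1.0))
        ks_stat, p = float(ks.statistic), float(ks.pvalue)
    else:
        ks_stat, p = float("nan"), float("nan")
    return RelativeDistanceResult(
        values=vals,
        hist_counts=hist,
        bin_edges=edges,
        ks_stat=ks_stat,
        p_uniform=p,
        n_skipped=n_skipped,
    )
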