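"""Significantly enriched interacting domains.

Model
-----
Interacting sites arriving uniformly along a chromosome are the background
("random collisions within the nucleus").  For each observed site *i* on
chromosome *W* of length ``L_W`` carrying ``N_W`` sites, the number of sites
``C`` inside a centred window of length ``lw`` is compared against its
expectation under uniformity, ``mu = N_W * lw / L_W``, and standardized:

* ``model="poisson"`` (default): ``z = (C - mu) / sqrt(mu)``
* ``model="binomial"``: ``z = (C - mu) / sqrt(mu * (1 - lw / L_W))``

Significance is assessed by a permutation FDR: site positions are redrawn
uniformly per chromosome (preserving ``N_W``) ``n_permutations`` times, z is
recomputed on each draw, and for every observed ``z*``

    FDR(z*) = [mean permutation count of null z >= z*] / #{observed z >= z*}

clipped to [0, 1] and monotonized (q-value style) so that significance is a
threshold on z.  Sites with FDR <= 0.05 seed domains: each significant site
contributes a ±1 Mb interval, overlapping/book-ended seeds are merged
transitively, and every site falling in a merged seed (significant or not)
becomes a domain member.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .core import GenomeDef, GenomicInterval, GenomicSite, merge_overlapping

__all__ = [
    "DomainCallingParams",
    "SiteScore",
    "EnrichedDomain",
    "window_counts",
    "site_zscores",
    "permutation_fdr",
    "call_enriched_domains",
    "overlap_regions",
    "call_domains",
    "scores_to_frame",
]


@dataclass(frozen=True)
class DomainCallingParams:
    """Statistical-model constants for domain calling."""

    window_length: int = 2_000_000
    n_permutations: int = 100
    fdr_cutoff: float = 0.05
    merge_flank: int = 1_000_000
    seed: int = 0
    model: str = "poisson"

    def __post_init__(self):
        if self.window_length <= 0:
            raise ValueError("window_length must be positive")
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")
        if not (0 < self.fdr_cutoff < 1):
            raise ValueError("fdr_cutoff must be in (0, 1)")
        if self.model not in ("poisson", "binomial"):
            raise ValueError("model must be 'poisson' or 'binomial'")


@dataclass
class SiteScore:
    site: GenomicSite
    C: int
    mu: float
    z: float
    fdr: float = np.nan
    significant: bool = False


@dataclass
class EnrichedDomain:
    interval: GenomicInterval
    member_sites: list[GenomicSite]
    peak_z: float
    min_fdr: float


def _window_counts_sorted(pos: np.ndarray, half: float) -> np.ndarray:
    """C for sorted positions: sites j with |pos_j - pos_i| <= half,
    boundary inclusive, self included."""
    hi = np.searchsorted(pos, pos + half, side="right")
    lo = np.searchsorted(pos, pos - half, side="left")
    return (hi - lo).astype(np.int64)


def window_counts(
    sites: Sequence[GenomicSite], genome: GenomeDef, lw: int
) -> np.ndarray:
    """Number of sites within the centred lw window of each site (the site
    itself included; windows truncate at chromosome ends without rescaling).
    Returned in the order of *sites*."""
    half = lw / 2
    out = np.zeros(len(sites), dtype=np.int64)
    by_chrom: dict[str, list[int]] = {}
    for i, s in enumerate(sites):
        genome.length(s.chrom)  # validates chromosome
        by_chrom.setdefault(s.chrom, []).append(i)
    for chrom, idxs in by_chrom.items():
        pos = np.asarray([sites[i].pos for i in idxs], dtype=np.int64)
        order = np.argsort(pos, kind="stable")
        c = _window_counts_sorted(pos[order], half)
        out[np.asarray(idxs)[order]] = c
    return out


def _chrom_expectation(n: int, L: int, lw: int, model: str) -> tuple[float, float]:
    mu = n * lw / L
    var = mu if model == "poisson" else mu * max(1e-12, 1 - lw / L)
    return mu, var


def site_zscores(
    sites: Sequence[GenomicSite],
    genome: GenomeDef,
    lw: int,
    model: str = "poisson",
) -> list[SiteScore]:
    """Per-site z-scores of local site density (see module docstring)."""
    C = window_counts(sites, genome, lw)
    n_by_chrom: dict[str, int] = {}
    for s in sites:
        n_by_chrom[s.chrom] = n_by_chrom.get(s.chrom, 0) + 1
    scores = []
    for s, c in zip(sites, C):
        mu, var = _chrom_expectation(
            n_by_chrom[s.chrom], genome.length(s.chrom), lw, model
        )
        scores.append(SiteScore(site=s, C=int(c), mu=mu, z=(c - mu) / np.sqrt(var)))
    return scores


def _null_zscores(
    n_by_chrom: dict[str, int],
    genome: GenomeDef,
    lw: int,
    model: str,
    n_permutations: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """(n_permutations, n_sites) matrix of z-scores from uniform redraws,
    preserving per-chromosome site counts."""
    half = lw / 2
    total = sum(n_by_chrom.values())
    out = np.empty((n_permutations, total))
    for p in range(n_permutations):
        col = 0
        for chrom in genome.names:
            n = n_by_chrom.get(chrom, 0)
            if n == 0:
                continue
            L = genome.length(chrom)
            pos = np.sort(rng.integers(0, L, size=n))
            c = _window_counts_sorted(pos, half)
            mu, var = _chrom_expectation(n, L, lw, model)
            out[p, col : col + n] = (c - mu) / np.sqrt(var)
            col += n
    return out


def permutation_fdr(
    scores: Sequence[SiteScore],
    genome: GenomeDef,
    params: DomainCallingParams,
) -> list[SiteScore]:
    """Attach permutation FDR and significance flags to z-scored sites.

    Deterministic for a fixed ``params.seed``.  FDR values are monotonized
    along descending z (running minimum from the top) so a larger z never
    carries a larger FDR.
    """
    if not scores:
        return []
    rng = np.random.default_rng(params.seed)
    n_by_chrom: dict[str, int] = {}
    for sc in scores:
        n_by_chrom[sc.site.chrom] = n_by_chrom.get(sc.site.chrom, 0) + 1
    null = _null_zscores(
        n_by_chrom, genome, params.window_length, params.model,
        params.n_permutations, rng,
    )
    null_sorted = np.sort(null.ravel())
    z = np.asarray([sc.z for sc in scores])
    z_sorted = np.sort(z)
    # counts with >= (boundary inclusive on both sides)
    n_null_ge = null_sorted.size - np.searchsorted(null_sorted, z, side="left")
    n_obs_ge = z.size - np.searchsorted(z_sorted, z, side="left")
    fdr = np.clip((n_null_ge / params.n_permutations) / n_obs_ge, 0.0, 1.0)
    # q-value style monotonization: descending z gets non-decreasing FDR
    order = np.argsort(-z, kind="stable")
    fdr_desc = fdr[order]
    fdr_desc = np.minimum.accumulate(fdr_desc[::-1])[::-1]
    fdr_mono = np.empty_like(fdr)
    fdr_mono[order] = fdr_desc
    out = []
    for sc, q in zip(scores, fdr_mono):
        out.append(replace(sc, fdr=float(q), significant=bool(q <= params.fdr_cutoff)))
    return out


def call_enriched_domains(
    scores: Sequence[SiteScore],
    genome: GenomeDef,
    params: DomainCallingParams,
) -> list[EnrichedDomain]:
    """Merge significant sites (± merge_flank, truncated to the chromosome)
    into non-overlapping enriched domains; all sites inside a merged seed
    become members."""
    seeds = []
    for sc in scores:
        if not sc.significant:
            continue
        L = genome.length(sc.site.chrom)
        lo = max(0, sc.site.pos - params.merge_flank)
        hi = min(L, sc.site.pos + params.merge_flank + 1)
        seeds.append(GenomicInterval(sc.site.chrom, lo, hi))
    merged = merge_overlapping(seeds)
    domains: list[EnrichedDomain] = []
    by_chrom: dict[str, list[SiteScore]] = {}
    for sc in scores:
        by_chrom.setdefault(sc.site.chrom, []).append(sc)
    for iv in merged:
        members = [
            sc
            for sc in by_chrom.get(iv.chrom, [])
            if iv.start <= sc.site.pos < iv.end
        ]
        members.sort(key=lambda sc: sc.site.pos)
        domains.append(
            EnrichedDomain(
                interval=iv,
                member_sites=[sc.site for sc in members],
                peak_z=max(sc.z for sc in members),
                min_fdr=min(sc.fdr for sc in members),
            )
        )
    domains.sort(key=lambda d: (d.interval.chrom, d.interval.start))
    return domains


def overlap_regions(
    a: Sequence[EnrichedDomain | GenomicInterval],
    b: Sequence[EnrichedDomain | GenomicInterval],
) -> tuple[int, list[tuple[int, int]]]:
    """Venn-style overlap count between two internally non-overlapping
    region lists.

    Returns the number of merged overlap events — connected components of
    the bipartite interval-overlap graph — plus the raw overlapping (i, j)
    index pairs.  A single a-region spanning several b-regions therefore
    counts once.
    """

    def iv(x):
        return x.interval if isinstance(x, EnrichedDomain) else x

    pairs: list[tuple[int, int]] = []
    for i, da in enumerate(a):
        for j, db in enumerate(b):
            if iv(da).overlaps(iv(db)):
                pairs.append((i, j))
    # union-find over nodes ('a', i) / ('b', j) restricted to edge-connected ones
    parent: dict[tuple[str, int], tuple[str, int]] = {}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i, j in pairs:
        for node in (("a", i), ("b", j)):
            parent.setdefault(node, node)
        ra, rb = find(("a", i)), find(("b", j))
        if ra != rb:
            parent[ra] = rb
    components = {find(x) for x in parent}
    return len(components), pairs


def call_domains(
    sites: Sequence[GenomicSite],
    genome: GenomeDef,
    params: DomainCallingParams | None = None,
) -> tuple[list[SiteScore], list[EnrichedDomain]]:
    """Convenience wrapper: z-scores, permutation FDR and domain merging."""
    params = params or DomainCallingParams()
    scores = site_zscores(sites, genome, params.window_length, model=params.model)
    scores = permutation_fdr(scores, genome, params)
    domains = call_enriched_domains(scores, genome, params)
    return scores, domains


def scores_to_frame(scores: Sequence[SiteScore]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "chrom": [sc.site.chrom for sc in scores],
            "pos": [sc.site.pos for sc in scores],
            "reads": [sc.site.read_count for sc in scores],
            "C": [sc.C for sc in scores],
            "mu": [sc.mu for sc in scores],
            "z": [sc.z for sc in scores],
            "fdr": [sc.fdr for sc in scores],
            "significant": [sc.significant for sc in scores],
        }
    )
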