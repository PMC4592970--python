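"""Independent brute-force reference implementations.

Deliberately plain-Python O(N·M) scans and hand-rolled logic, kept free of
any sonic4c internals so they can arbitrate the vectorized code paths.
"""

from __future__ import annotations

import math


def bf_count_in_flank(anchors, intervals, flank, chrom_lengths):
    """anchors: (chrom, pos); intervals: (chrom, start, end)."""
    out = []
    for chrom, pos in anchors:
        lo = max(0, pos - flank)
        hi = min(chrom_lengths[chrom] - 1, pos + flank)
        n = 0
        for c, s, e in intervals:
            if c == chrom and s <= hi and e > lo:
                n += 1
        out.append(n)
    return out


def bf_nearest_signed_distance(anchors, intervals):
    """Signed distance to nearest element; ties to the lower coordinate;
    None when the chromosome has no elements."""
    out = []
    for chrom, pos in anchors:
        best = None
        for c, s, e in sorted(intervals):
            if c != chrom:
                continue
            if s <= pos < e:
                d = 0
            elif pos < s:
                d = pos - s
            else:
                d = pos - (e - 1)
            if best is None or abs(d) < abs(best):
                best = d
        out.append(best)
    return out


def bf_window_counts(sites, lw):
    """sites: (chrom, pos); count of sites within |dpos| <= lw/2, same chrom."""
    half = lw / 2
    out = []
    for c1, p1 in sites:
        out.append(
            sum(1 for c2, p2 in sites if c2 == c1 and abs(p2 - p1) <= half)
        )
    return out


def bf_zscores(sites, chrom_lengths, lw):
    """Poisson-standardized local-density z per site."""
    counts = bf_window_counts(sites, lw)
    n_chrom = {}
    for c, _ in sites:
        n_chrom[c] = n_chrom.get(c, 0) + 1
    out = []
    for (c, _p), cnt in zip(sites, counts):
        mu = n_chrom[c] * lw / chrom_lengths[c]
        out.append((cnt - mu) / math.sqrt(mu))
    return out


def bf_call_distal_sites(tags, merge_window, min_reads):
    """tags: (chrom, pos) -> [(chrom, median_pos_floor, count)], single
    linkage by explicit pairwise chaining."""
    by_chrom = {}
    for c, p in tags:
        by_chrom.setdefault(c, []).append(p)
    sites = []
    for c in sorted(by_chrom):
        pos = sorted(by_chrom[c])
        cluster = [pos[0]]
        clusters = []
        for p in pos[1:]:
            if p - cluster[-1] <= merge_window:
                cluster.append(p)
            else:
                clusters.append(cluster)
                cluster = [p]
        clusters.append(cluster)
        for cl in clusters:
            if len(cl) >= min_reads:
                n = len(cl)
                if n % 2 == 1:
                    med = cl[n // 2]
                else:
                    med = (cl[n // 2 - 1] + cl[n // 2]) / 2
                sites.append((c, math.floor(med), n))
    return sites


def bf_enriched_domains(site_positions, significant, merge_flank, chrom_length):
    """Single-chromosome domain oracle: per-base coverage of significant
    seeds, then contiguous covered runs.  Returns [(start, end, members)]."""
    covered = set()
    for p, sig in zip(site_positions, significant):
        if sig:
            for b in range(max(0, p - merge_flank), min(chrom_length, p + merge_flank + 1)):
                covered.add(b)
    if not covered:
        return []
    runs = []
    bases = sorted(covered)
    start = prev = bases[0]
    for b in bases[1:]:
        if b != prev + 1:
            runs.append((start, prev + 1))
            start = b
        prev = b
    runs.append((start, prev + 1))
    out = []
    for s, e in runs:
        members = sorted(p for p in site_positions if s <= p < e)
        out.append((s, e, members))
    return out


def bf_relative_distance(a_pos, b_pos):
    """Single-chromosome relative distances (skipping unflanked queries)."""
    b = sorted(b_pos)
    vals = []
    for p in a_pos:
        if p in set(b):
            vals.append(0.0)
            continue
        left = [x for x in b if x < p]
        right = [x for x in b if x > p]
        if not left or not right:
            continue
        dl = p - max(left)
        dr = min(right) - p
        vals.append(min(dl, dr) / (dl + dr))
    return vals
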