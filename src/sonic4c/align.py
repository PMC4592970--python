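"""Exact-match end-tag aligner for the synthetic genome.

Real 4C libraries are aligned with BWA; this package consumes those
alignments as a tag-pair table.  For the simulated genome — random sequence
with no repeats beyond chance 20-mer collisions — exact 20-mer lookup is a
complete aligner: every tag either matches the genome verbatim (forward or
reverse complement) or not at all.

The index packs every genomic 20-mer into a 40-bit integer (2 bits/base)
and binary-searches query tags against the sorted packed array, so
uniqueness is exact: a tag is uniquely mapped iff it has exactly one hit
across both strands (MAPQ 60), multi-mappers get MAPQ 0, and tags with no
hit are unmapped.
"""

from __future__ import annotations

import numpy as np

from .junctions import TagAlignment, TagPair, extract_end_tags

__all__ = ["TagIndex", "align_tag_pairs"]

_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i

_COMP = str.maketrans("ACGTacgt", "TGCATGCA")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def _pack(codes: np.ndarray, k: int) -> np.ndarray:
    """2-bit pack every k-mer starting position of a code array."""
    n = codes.size - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.uint64)
    out = np.zeros(n, dtype=np.uint64)
    for j in range(k):
        out = (out << np.uint64(2)) | codes[j : j + n].astype(np.uint64)
    return out


class TagIndex:
    """Sorted 20-mer index over a dict of chromosome sequences."""

    def __init__(self, sequences: dict[str, str], k: int = 20):
        if k > 31:
            raise ValueError("k must fit in 62 bits (k <= 31)")
        self.k = k
        hashes = []
        chrom_ids = []
        positions = []
        self.chrom_names = list(sequences)
        for ci, (chrom, seq) in enumerate(sequences.items()):
            codes = _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
            if (codes == 255).any():
                raise ValueError(f"non-ACGT base in synthetic chromosome {chrom!r}")
            h = _pack(codes, k)
            hashes.append(h)
            chrom_ids.append(np.full(h.size, ci, dtype=np.int32))
            positions.append(np.arange(h.size, dtype=np.int64))
        h = np.concatenate(hashes) if hashes else np.empty(0, dtype=np.uint64)
        order = np.argsort(h, kind="stable")
        self._hashes = h[order]
        self._chrom_ids = np.concatenate(chrom_ids)[order] if hashes else np.empty(0, np.int32)
        self._positions = np.concatenate(positions)[order] if hashes else np.empty(0, np.int64)

    def _lookup(self, tag: str) -> list[tuple[str, int]]:
        codes = _CODE[np.frombuffer(tag.encode("ascii"), dtype=np.uint8)]
        if codes.size != self.k or (codes == 255).any():
            return []
        h = _pack(codes, self.k)[0]
        lo = int(np.searchsorted(self._hashes, h, side="left"))
        hi = int(np.searchsorted(self._hashes, h, side="right"))
        return [
            (self.chrom_names[self._chrom_ids[i]], int(self._positions[i]))
            for i in range(lo, hi)
        ]

    def align(self, tag: str) -> TagAlignment:
        """Align one tag; hits on both strands pool for the uniqueness call.

        The reported position is always the forward-strand start of the
        matched 20-mer (downstream analyses are strand-agnostic).
        """
        fwd = self._lookup(tag)
        rev = self._lookup(_revcomp(tag))
        hits = [(c, p, "+") for c, p in fwd] + [(c, p, "-") for c, p in rev]
        if not hits:
            return TagAlignment(None, 0, "+", 0, False)
        chrom, pos, strand = hits[0]
        unique = len(hits) == 1
        return TagAlignment(chrom, pos, strand, 60 if unique else 0, unique)


def align_tag_pairs(
    reads: list[tuple[str, str, str]],
    index: TagIndex,
    tag_length: int = 20,
) -> tuple[list[TagPair], int]:
    """Align (read_id, seq1, seq2) triples; returns the tag pairs plus the
    count of pairs dropped because a mate was shorter than *tag_length*."""
    pairs = []
    n_dropped = 0
    for read_id, seq1, seq2 in reads:
        tags = extract_end_tags(seq1, seq2, tag_length)
        if tags is None:
            n_dropped += 1
            continue
        pairs.append(TagPair(read_id, index.align(tags[0]), index.align(tags[1])))
    return pairs, n_dropped
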