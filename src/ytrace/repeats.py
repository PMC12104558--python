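"""Repeat-unit tiling statistics and palindrome detection from alignment
hits.

A heterochromatic region tiled by irregular copies of a basic repeating
unit is summarized by aligning the unit against the region: hit clusters
covering at least half the unit count as full copies, smaller clusters as
partial copies, and the union of hit intervals gives the covered fraction.
Candidate units themselves are proposed from the off-diagonal offset
spectrum of a self-alignment (the modal offset of a tandem array is the
unit period).  Palindromes (inverted duplications) are read off minus-strand
self-hits with sufficiently long, non-overlapping arms.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .io_formats import AlignmentHit

__all__ = [
    "RepeatUnit",
    "TilingReport",
    "PalindromeCall",
    "tile_unit",
    "propose_unit",
    "detect_palindromes",
]


@dataclass
class RepeatUnit:
    chrom: str
    start: int
    end: int
    label: str = "unit"

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class TilingReport:
    region: tuple[str, int, int]
    unit_label: str
    copies: int
    partial_copies: int
    covered_bp: int
    coverage_fraction: float

    @property
    def total_copies(self) -> int:
        return self.copies + self.partial_copies


@dataclass
class PalindromeCall:
    chrom: str
    left_arm: tuple[int, int]
    right_arm: tuple[int, int]
    spacer_bp: int
    arm_identity: float

    @property
    def span_bp(self) -> int:
        return self.right_arm[1] - self.left_arm[0]


def _union_len(ivs: list[tuple[int, int]]) -> int:
    if not ivs:
        return 0
    ivs = sorted(ivs)
    total, cur_s, cur_e = 0, *ivs[0]
    for s, e in ivs[1:]:
        if s <= cur_e:
            cur_e = max(cur_e, e)
        else:
            total += cur_e - cur_s
            cur_s, cur_e = s, e
    return total + (cur_e - cur_s)


def tile_unit(
    unit_len: int,
    region: tuple[str, int, int],
    hits: Sequence[AlignmentHit],
    min_hit_len: int = 1_000,
    min_identity: float = 0.8,
    min_copy_fraction: float = 0.5,
) -> TilingReport:
    """Tile a region with a repeating unit from unit-vs-region hits.

    Hits (query = unit, target = region chromosome) are filtered by length
    and identity and grouped into copy clusters along the region: a hit
    joins the current cluster only while it is target-adjacent (gap at most
    one unit length) and contributes mostly new unit coverage - split
    alignments of one copy chain together, while the next tandem copy
    re-covers the same unit interval and opens a new cluster.  Each cluster
    is scored by the fraction of the unit it covers: >= ``min_copy_fraction``
    is a full copy, anything less a partial copy.  Covered bp is the union
    of hit intervals within the region.
    """
    chrom, rstart, rend = region
    if rend <= rstart:
        raise ValueError("region length must be positive")
    kept = [
        h for h in hits
        if h.target_name == chrom
        and (h.block_len or h.target_span) >= min_hit_len
        and (h.identity or 0.0) >= min_identity
        and h.target_start < rend and h.target_end > rstart
    ]
    kept.sort(key=lambda h: (h.target_start, h.target_end))
    clusters: list[list[AlignmentHit]] = []
    cover: list[tuple[int, int]] = []  # unit intervals of the open cluster
    last_end = None
    for h in kept:
        q_iv = (h.query_start, h.query_end)
        overlap = sum(
            max(0, min(q_iv[1], e) - max(q_iv[0], s)) for s, e in cover
        )
        novel = overlap < 0.5 * (q_iv[1] - q_iv[0])
        adjacent = last_end is not None and h.target_start - last_end <= unit_len
        if clusters and adjacent and novel:
            clusters[-1].append(h)
            cover.append(q_iv)
        else:
            clusters.append([h])
            cover = [q_iv]
        last_end = h.target_end
    copies = partial = 0
    for cl in clusters:
        unit_cov = _union_len([(h.query_start, h.query_end) for h in cl]) / unit_len
        if unit_cov >= min_copy_fraction:
            copies += 1
        else:
            partial += 1
    covered = _union_len(
        [(max(h.target_start, rstart), min(h.target_end, rend)) for h in kept]
    )
    return TilingReport((chrom, rstart, rend), "unit", copies, partial,
                        covered, covered / (rend - rstart))


def propose_unit(
    self_hits: Sequence[AlignmentHit],
    region: tuple[str, int, int],
    max_candidates: int = 5,
    offset_tolerance: float = 0.05,
) -> list[RepeatUnit]:
    """Propose candidate repeat units from region self-alignment hits.

    The candidate period is the modal off-diagonal offset of plus-strand
    self-hits (bp-weighted histogram with relative clustering tolerance);
    for each period the returned unit is the highest-coverage window of that
    length.  The ranked list leaves the final choice with the user,
    mirroring manual unit curation.
    """
    chrom, rstart, rend = region
    offsets = []
    for h in self_hits:
        if h.strand != "+" or h.target_name != chrom:
            continue
        off = h.target_start - h.query_start
        if off > 0:  # one of each symmetric pair, excluding the main diagonal
            offsets.append((off, (h.block_len or h.target_span)))
    if not offsets:
        return []
    offsets.sort()
    # cluster offsets within a relative tolerance
    groups: list[list[tuple[int, int]]] = []
    for off, w in offsets:
        if groups and off - groups[-1][-1][0] <= offset_tolerance * off:
            groups[-1].append((off, w))
        else:
            groups.append([(off, w)])
    scored = []
    for g in groups:
        weight = sum(w for _, w in g)
        period = int(round(np.average([o for o, _ in g], weights=[w for _, w in g])))
        scored.append((weight, period))
    scored.sort(reverse=True)
    units = []
    for rank, (weight, period) in enumerate(scored[:max_candidates], 1):
        start = _best_window(self_hits, chrom, rstart, rend, period)
        units.append(RepeatUnit(chrom, start, start + period, label=f"cand{rank}"))
    return units


def _best_window(hits, chrom, rstart, rend, period) -> int:
    """Start of the window of length ``period`` with maximal hit coverage."""
    ivs = sorted(
        (h.target_start, h.target_end) for h in hits
        if h.target_name == chrom and h.strand == "+"
    )
    if not ivs:
        return rstart
    best_start, best_cov = rstart, -1
    step = max(1, period // 10)
    for ws in range(rstart, max(rstart + 1, rend - period + 1), step):
        cov = _union_len(
            [(max(s, ws), min(e, ws + period)) for s, e in ivs if s < ws + period and e > ws]
        )
        if cov > best_cov:
            best_start, best_cov = ws, cov
    return best_start


def detect_palindromes(
    self_hits: Sequence[AlignmentHit],
    min_arm: int = 10_000,
    min_identity: float = 0.9,
) -> list[PalindromeCall]:
    """Palindromes from minus-strand self-hits: arms of at least ``min_arm``
    bp at ``min_identity``, non-overlapping, reported with their spacer;
    overlapping calls are merged to the maximal extent."""
    calls = []
    for h in self_hits:
        if h.strand != "-" or (h.identity or 0.0) < min_identity:
            continue
        left = (h.query_start, h.query_end)
        right = (h.target_start, h.target_end)
        if left[0] > right[0]:
            left, right = right, left
        if left == right or left[1] > right[0]:  # self-match or overlapping arms
            continue
        if left[1] - left[0] < min_arm or right[1] - right[0] < min_arm:
            continue
        calls.append(
            PalindromeCall(h.target_name, left, right, right[0] - left[1],
                           h.identity or 0.0)
        )
    # merge duplicates/overlaps (each palindrome appears twice in self-hits)
    calls.sort(key=lambda c: (c.chrom, c.left_arm, c.right_arm))
    merged: list[PalindromeCall] = []
    for c in calls:
        if merged:
            p = merged[-1]
            if (p.chrom == c.chrom
                    and c.left_arm[0] < p.left_arm[1] and c.right_arm[0] < p.right_arm[1]):
                la = (min(p.left_arm[0], c.left_arm[0]), max(p.left_arm[1], c.left_arm[1]))
                ra = (min(p.right_arm[0], c.right_arm[0]), max(p.right_arm[1], c.right_arm[1]))
                merged[-1] = PalindromeCall(p.chrom, la, ra, ra[0] - la[1],
                                            max(p.arm_identity, c.arm_identity))
                continue
        merged.append(c)
    return merged
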