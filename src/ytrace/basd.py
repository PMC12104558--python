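"""Iterative boundary-associated segmental duplication (BASD) detection.

The detection loop mirrors the iterative homology search used for
segmental-duplication discovery: align the current seed set to the genome,
drop alignments shorter than 500 bp, merge split alignments lying within
3,000 bp of each other on the same target strand, keep merged spans of at
least 3,000 bp as candidates, and feed the candidate sequences back in as
the next seed set until the candidate intervals stabilize.  Candidates
spanning at least 5,000 bp become final copies, named in coordinate order
(species prefix + zero-padded ordinal).

Downstream analyses assign flank provenance (which side of which ancestral
donor copy the sequence around each detected copy matches, the alpha/gamma
classes) and apply the boundary-order rule distinguishing a direct insertion
from integration of a circular (eccDNA) intermediate: an ancestral
alpha-BASD-gamma donor that arrives split as BASD-gamma ... alpha-BASD at
the two insertion boundaries must have traversed a circle.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from ._align import KmerAligner
from .io_formats import AlignmentHit, GenomeSequence

__all__ = [
    "BasdCopy",
    "FlankAssignment",
    "MechanismCall",
    "filter_hits_by_length",
    "merge_split_hits",
    "iterate_basd_detection",
    "count_by_region",
    "assign_flanks",
    "infer_mechanism",
    "cluster_by_identity",
]


@dataclass
class BasdCopy:
    """A detected segmental-duplication copy."""

    chrom: str
    start: int
    end: int
    identity_to_seed: float
    iteration_found: int
    name: str

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2


@dataclass
class FlankAssignment:
    """Provenance labels for the sequence around one copy: upstream alpha
    class, downstream gamma class, with aligned bp per flank."""

    copy_name: str
    upstream: str | None  # '1a', '2a' or None
    downstream: str | None  # '1g', '2g' or None
    upstream_bp: int = 0
    downstream_bp: int = 0


@dataclass
class MechanismCall:
    locus: str
    call: str  # 'direct-insertion' | 'circular-intermediate' | 'undetermined'
    evidence: list[tuple[str | None, str | None]]
    note: str = ""


# ---------------------------------------------------------------------------
# Hit-level rules
# ---------------------------------------------------------------------------

def filter_hits_by_length(hits: Iterable[AlignmentHit], min_len: int = 500) -> list[AlignmentHit]:
    """Exclude alignments shorter than ``min_len`` bp (keep >= min_len)."""
    return [h for h in hits if (h.block_len or h.target_span) >= min_len]


def merge_split_hits(
    hits: Iterable[AlignmentHit],
    max_gap: int = 3_000,
    min_candidate_span: int = 3_000,
) -> list[tuple[str, int, int]]:
    """Merge split alignments of the same query on the same target
    chromosome and strand whose target intervals lie within ``max_gap`` bp;
    merged spans of at least ``min_candidate_span`` bp become candidates.
    """
    groups: dict[tuple[str, str, str], list[AlignmentHit]] = {}
    for h in hits:
        groups.setdefault((h.query_name, h.target_name, h.strand), []).append(h)
    candidates: list[tuple[str, int, int]] = []
    for (_, tchrom, _), ghits in groups.items():
        ghits.sort(key=lambda h: h.target_start)
        cur_s, cur_e = ghits[0].target_start, ghits[0].target_end
        for h in ghits[1:]:
            if h.target_start - cur_e <= max_gap:
                cur_e = max(cur_e, h.target_end)
            else:
                if cur_e - cur_s >= min_candidate_span:
                    candidates.append((tchrom, cur_s, cur_e))
                cur_s, cur_e = h.target_start, h.target_end
        if cur_e - cur_s >= min_candidate_span:
            candidates.append((tchrom, cur_s, cur_e))
    return _union_intervals(candidates)


def _union_intervals(ivs: list[tuple[str, int, int]]) -> list[tuple[str, int, int]]:
    """Normalize candidate intervals: merge overlaps across queries."""
    out: list[tuple[str, int, int]] = []
    for chrom, s, e in sorted(ivs):
        if out and out[-1][0] == chrom and s <= out[-1][2]:
            out[-1] = (chrom, out[-1][1], max(out[-1][2], e))
        else:
            out.append((chrom, s, e))
    return out


# ---------------------------------------------------------------------------
# Iterative detection
# ---------------------------------------------------------------------------

def iterate_basd_detection(
    genome: GenomeSequence,
    seed_sequences: Sequence[str],
    min_final_len: int = 5_000,
    max_iter: int = 10,
    min_hit_len: int = 500,
    max_gap: int = 3_000,
    min_candidate_span: int = 3_000,
    min_identity: float = 0.85,
    name_prefix: str = "BASD",
    hits: Sequence[AlignmentHit] | None = None,
) -> list[BasdCopy]:
    """Iterative seeded duplication detection on one chromosome.

    Each round aligns the seed set against the genome (with the internal
    k-mer aligner, or a user-supplied first-round hit table, e.g. real
    BLASTN output read via io_formats), applies the length filter, merges
    split hits, and promotes merged spans to candidates; candidates seed the
    next round.  Iteration stops when the candidate interval set is stable
    (or at ``max_iter``, with a warning).  Candidates spanning at least
    ``min_final_len`` bp are returned as named copies in coordinate order.
    """
    aligner = KmerAligner(genome.seq, target_name=genome.name)
    seeds = list(seed_sequences)
    prev: list[tuple[str, int, int]] = []
    iteration = 0
    found_at: dict[tuple[str, int, int], int] = {}
    for iteration in range(1, max_iter + 1):
        if hits is not None and iteration == 1:
            round_hits = list(hits)
        else:
            round_hits = []
            for i, seed in enumerate(seeds):
                round_hits.extend(
                    aligner.align(seed, query_name=f"seed{i}",
                                  min_len=min_hit_len, min_identity=min_identity)
                )
        kept = filter_hits_by_length(round_hits, min_hit_len)
        cand = merge_split_hits(kept, max_gap, min_candidate_span)
        for iv in cand:
            found_at.setdefault(iv, iteration)
        if cand == prev:
            break
        prev = cand
        seeds = [genome.seq[s:e] for _, s, e in cand]
        if not seeds:
            break
    else:
        warnings.warn(f"BASD detection did not converge in {max_iter} iterations;"
                      " returning current candidate set")

    originals = list(seed_sequences)
    copies = []
    finals = [iv for iv in prev if iv[2] - iv[1] >= min_final_len]
    for i, (chrom, s, e) in enumerate(sorted(finals), 1):
        seq = genome.seq[s:e]
        ident = _best_identity(seq, originals)
        copies.append(
            BasdCopy(chrom, s, e, ident, found_at.get((chrom, s, e), iteration),
                     f"{name_prefix}{i:03d}")
        )
    return copies


def _best_identity(seq: str, refs: Sequence[str]) -> float:
    best = 0.0
    for ref in refs:
        sub = KmerAligner(seq, target_name="copy")
        for h in sub.align(ref, min_len=300, min_identity=0.5):
            if h.identity and h.identity > best and h.block_len:
                # weight by covered fraction of the shorter sequence
                if h.block_len >= 0.5 * min(len(seq), len(ref)):
                    best = max(best, h.identity)
    return best


# ---------------------------------------------------------------------------
# Region tables, flanks, mechanism
# ---------------------------------------------------------------------------

def _check_disjoint(regions: Sequence[tuple[str, int, int, str]]) -> None:
    by_chrom: dict[str, list[tuple[int, int, str]]] = {}
    for chrom, s, e, name in regions:
        by_chrom.setdefault(chrom, []).append((s, e, name))
    for chrom, ivs in by_chrom.items():
        ivs.sort()
        for (s1, e1, n1), (s2, e2, n2) in zip(ivs, ivs[1:]):
            if s2 < e1:
                raise ValueError(f"overlapping regions {n1} and {n2} on {chrom}")


def count_by_region(
    copies: Sequence[BasdCopy],
    regions: Sequence[tuple[str, int, int, str]],
) -> dict[str, int]:
    """Count copies per named region by midpoint; copies outside every
    region are tallied under 'unassigned'.  Regions must not overlap."""
    _check_disjoint(regions)
    counts = {name: 0 for _, _, _, name in regions}
    counts["unassigned"] = 0
    for c in copies:
        for chrom, s, e, name in regions:
            if c.chrom == chrom and s <= c.midpoint < e:
                counts[name] += 1
                break
        else:
            counts["unassigned"] += 1
    return counts


def assign_flanks(
    copies: Sequence[BasdCopy],
    genome: GenomeSequence,
    ancestral_flanks: Mapping[str, str],
    up_window: int = 1_800,
    down_window: int = 10_800,
    min_flank_bp: int = 500,
    min_identity: float = 0.9,
) -> list[FlankAssignment]:
    """Label the sequence windows around each copy with the best-matching
    ancestral donor flank: upstream against the alpha references, downstream
    against the gamma references.  A label needs >= ``min_flank_bp`` aligned
    bp at >= ``min_identity``."""
    for key in ("1a", "1g", "2a", "2g"):
        if key not in ancestral_flanks:
            raise ValueError(f"missing ancestral flank reference {key!r}")
    out = []
    for c in copies:
        up_seq = genome.seq[max(0, c.start - up_window) : c.start]
        down_seq = genome.seq[c.end : c.end + down_window]
        up = _best_flank(up_seq, {k: ancestral_flanks[k] for k in ("1a", "2a")},
                         min_flank_bp, min_identity)
        down = _best_flank(down_seq, {k: ancestral_flanks[k] for k in ("1g", "2g")},
                           min_flank_bp, min_identity)
        out.append(FlankAssignment(c.name, up[0], down[0], up[1], down[1]))
    return out


def _best_flank(window: str, refs: Mapping[str, str],
                min_flank_bp: int, min_identity: float) -> tuple[str | None, int]:
    best_label, best_bp = None, 0
    if len(window) < min_flank_bp:
        return None, 0
    aligner = KmerAligner(window, target_name="window")
    for label, ref in refs.items():
        bp = sum(
            h.block_len or 0
            for h in aligner.align(ref, min_len=min_flank_bp, min_identity=min_identity)
        )
        if bp > best_bp:
            best_label, best_bp = label, bp
    if best_bp < min_flank_bp:
        return None, 0
    return best_label, best_bp


def infer_mechanism(
    assignments: Sequence[FlankAssignment],
    locus: str = "locus",
) -> MechanismCall:
    """Classify a two-boundary insertion locus from the ordered flank labels.

    Boundary order (BASD-gamma ... alpha-BASD), i.e. the left copy trailed
    by a gamma flank and the right copy led by an alpha flank, is the split
    signature of a circular (eccDNA) intermediate; the unsplit order
    (alpha-BASD ... BASD-gamma) indicates a direct insertion; anything else
    is undetermined.
    """
    evidence = [(a.upstream, a.downstream) for a in assignments]
    if len(assignments) != 2:
        return MechanismCall(locus, "undetermined", evidence,
                             note=f"expected 2 boundary copies, got {len(assignments)}")
    left, right = assignments
    is_alpha = lambda x: x in ("1a", "2a")
    is_gamma = lambda x: x in ("1g", "2g")
    if is_gamma(left.downstream) and is_alpha(right.upstream):
        return MechanismCall(locus, "circular-intermediate", evidence)
    if is_alpha(left.upstream) and is_gamma(right.downstream):
        return MechanismCall(locus, "direct-insertion", evidence)
    return MechanismCall(locus, "undetermined", evidence)


def cluster_by_identity(
    copies: Sequence[BasdCopy],
    genome: GenomeSequence,
    linkage_threshold: float = 0.95,
) -> dict[str, int]:
    """Single-linkage clusters on pairwise copy identity; labels are
    deterministic (cluster ids numbered by first member in coordinate
    order).  Stands in for a full phylogeny at desk scale."""
    if len(copies) < 2:
        raise ValueError("need at least two copies to cluster")
    ordered = sorted(copies, key=lambda c: (c.chrom, c.start))
    seqs = [genome.seq[c.start : c.end] for c in ordered]
    n = len(ordered)
    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i in range(n):
        for j in range(i + 1, n):
            if _pairwise_identity(seqs[i], seqs[j]) >= linkage_threshold:
                ri, rj = find(i), find(j)
                if ri != rj:
                    parent[max(ri, rj)] = min(ri, rj)
    label_of_root: dict[int, int] = {}
    out = {}
    for i, c in enumerate(ordered):
        r = find(i)
        if r not in label_of_root:
            label_of_root[r] = len(label_of_root) + 1
        out[c.name] = label_of_root[r]
    return out


def _pairwise_identity(a: str, b: str) -> float:
    if len(a) == len(b):
        return sum(x == y for x, y in zip(a, b)) / len(a)
    return _best_identity(a, [b])
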