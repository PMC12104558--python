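"""Whole-chromosome synteny mapping and fusion-only karyotype parsimony.

Query genomes are cut into non-overlapping windows, aligned to a common
reference, and the filtered primary alignments are lifted back to source
coordinates.  Ancestral units are then the common refinement of the
reference genome under every species' chromosome correspondences: a species
chromosome covering k units implies k-1 fusion events in that lineage
(fissions are out of model and surfaced as violations).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .io_formats import AlignmentHit, GenomeSequence

__all__ = [
    "window_genome",
    "window_coords",
    "fragment_name",
    "parse_fragment_name",
    "filter_synteny_hits",
    "build_synteny_map",
    "SyntenyMap",
    "PairSynteny",
    "AncestralKaryotype",
    "infer_fusions",
    "ancestral_diploid_number",
]


# ---------------------------------------------------------------------------
# Windowing
# ---------------------------------------------------------------------------

def fragment_name(chrom: str, offset: int) -> str:
    return f"{chrom}:{offset}"


def parse_fragment_name(name: str) -> tuple[str, int]:
    chrom, _, off = name.rpartition(":")
    if not chrom:
        raise ValueError(f"fragment name {name!r} does not encode chrom:offset")
    try:
        return chrom, int(off)
    except ValueError:
        raise ValueError(f"fragment name {name!r} has non-integer offset") from None


def window_coords(length: int, window_bp: int = 500_000) -> list[tuple[int, int]]:
    """Non-overlapping (offset, size) windows covering [0, length); the final
    partial window is kept."""
    if window_bp < 1:
        raise ValueError("window must be >= 1 bp")
    return [(off, min(window_bp, length - off)) for off in range(0, length, window_bp)]


def window_genome(genome: GenomeSequence, window_bp: int = 500_000) -> list[GenomeSequence]:
    """Fragment a chromosome into non-overlapping windows (step = window);
    fragment names encode the origin chromosome and offset."""
    return [
        GenomeSequence(fragment_name(genome.name, off), genome.seq[off : off + size])
        for off, size in window_coords(genome.length, window_bp)
    ]


# ---------------------------------------------------------------------------
# Hit filtering and synteny maps
# ---------------------------------------------------------------------------

def filter_synteny_hits(hits: Iterable[AlignmentHit], min_len_bp: int = 100_000) -> list[AlignmentHit]:
    """Keep primary alignments whose block length strictly exceeds the
    threshold (default 100 kbp)."""
    return [h for h in hits if h.is_primary and (h.block_len or 0) > min_len_bp]


def _merge_intervals(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    if not intervals:
        return []
    intervals = sorted(intervals)
    merged = [list(intervals[0])]
    for s, e in intervals[1:]:
        if s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [tuple(x) for x in merged]


@dataclass
class PairSynteny:
    """Aggregate synteny between one query chromosome and one target
    chromosome: merged covered intervals and a bp-weighted orientation."""

    query_chrom: str
    target_chrom: str
    aligned_bp: int
    orientation: str  # '+', '-' or '=' for a tie
    target_intervals: list[tuple[int, int]]
    query_intervals: list[tuple[int, int]]
    # per-hit anchor list (tstart, tend, qstart, qend, strand) for lifting
    anchors: list[tuple[int, int, int, int, str]] = field(default_factory=list)


@dataclass
class SyntenyMap:
    """Per (query chromosome, target chromosome) synteny summary."""

    pairs: dict[tuple[str, str], PairSynteny]

    def query_total(self, qchrom: str) -> int:
        return sum(p.aligned_bp for (q, _), p in self.pairs.items() if q == qchrom)

    def target_total(self, tchrom: str) -> int:
        return sum(p.aligned_bp for (_, t), p in self.pairs.items() if t == tchrom)


def build_synteny_map(hits: Iterable[AlignmentHit]) -> SyntenyMap:
    """Lift windowed-fragment hits to source-chromosome coordinates and sum
    aligned bp per chromosome pair over merged target intervals (overlaps
    counted once)."""
    buckets: dict[tuple[str, str], list[AlignmentHit]] = {}
    lifted: dict[tuple[str, str], list[tuple[int, int, int, int, str]]] = {}
    for h in hits:
        chrom, offset = parse_fragment_name(h.query_name)
        key = (chrom, h.target_name)
        buckets.setdefault(key, []).append(h)
        lifted.setdefault(key, []).append(
            (h.target_start, h.target_end, h.query_start + offset, h.query_end + offset, h.strand)
        )
    pairs = {}
    for key, anchors in lifted.items():
        t_iv = _merge_intervals([(a[0], a[1]) for a in anchors])
        q_iv = _merge_intervals([(a[2], a[3]) for a in anchors])
        aligned = sum(e - s for s, e in t_iv)
        plus = sum(a[1] - a[0] for a in anchors if a[4] == "+")
        minus = sum(a[1] - a[0] for a in anchors if a[4] == "-")
        orient = "+" if plus > minus else ("-" if minus > plus else "=")
        pairs[key] = PairSynteny(key[0], key[1], aligned, orient, t_iv, q_iv, sorted(anchors))
    return SyntenyMap(pairs)


# ---------------------------------------------------------------------------
# Fusion-only ancestral karyotype
# ---------------------------------------------------------------------------

@dataclass
class AncestralUnit:
    id: str
    ref_chrom: str
    start: int
    end: int


@dataclass
class AncestralKaryotype:
    """Ancestral units plus per-species fusion events.

    Invariant (checked, violations reported): per species, extant haploid
    count + fusion count = ancestral haploid count.
    """

    units: list[AncestralUnit]
    species_units: dict[str, dict[str, list[str]]]  # species -> chrom -> ordered unit ids
    fusions: dict[str, list[tuple[str, str]]]
    violations: list[str] = field(default_factory=list)

    @property
    def ancestral_haploid(self) -> int:
        return len(self.units)

    def fusion_count(self, species: str) -> int:
        return len(self.fusions[species])

    def ancestral_2n(self, sex_system: str = "XY", restore_y: bool = False) -> int:
        species = next(iter(self.species_units))
        extant = len(self.species_units[species])
        return ancestral_diploid_number(extant, self.fusion_count(species),
                                        sex_system, restore_y)


def infer_fusions(
    maps: Mapping[str, SyntenyMap],
    ref_lengths: Mapping[str, int],
    min_fraction: float = 0.5,
) -> AncestralKaryotype:
    """Reconstruct ancestral units and per-species fusions from synteny maps
    of >=2 species against a common reference genome.

    Reference coordinates are partitioned by the union of all species'
    correspondence boundaries; maximal runs with a constant
    species-chromosome label vector are the ancestral units.  A whole-
    chromosome correspondence is called unambiguous when one partner holds
    at least ``min_fraction`` of the chromosome's aligned bp; chromosomes
    with no such partner (fused on both sides) are reported as ties in
    ``violations``, never resolved arbitrarily.
    """
    if len(maps) < 2:
        raise ValueError("need synteny maps for at least two species")
    species_names = sorted(maps)

    ties: list[str] = []
    # correspondence intervals per species per ref chrom
    cover: dict[str, dict[str, list[tuple[int, int, str, tuple]]]] = {
        sp: {c: [] for c in ref_lengths} for sp in species_names
    }
    for sp in species_names:
        smap = maps[sp]
        best: dict[str, int] = {}
        for (q, t), pair in smap.pairs.items():
            if t not in ref_lengths:
                raise ValueError(f"map for {sp} targets unknown chromosome {t!r}")
            best[q] = max(best.get(q, 0), pair.aligned_bp)
            for s, e in pair.target_intervals:
                cover[sp][t].append((s, e, q, tuple(pair.anchors)))
        for q, top in best.items():
            total = smap.query_total(q)
            if total and top / total < min_fraction:
                ties.append(f"{sp}: chromosome {q} has no single partner with "
                            f">= {min_fraction:.0%} of its aligned bp (tie reported)")

    # refine reference partition by all boundaries
    units: list[AncestralUnit] = []
    unit_labels: list[dict[str, str | None]] = []
    for chrom in sorted(ref_lengths):
        cuts = {0, ref_lengths[chrom]}
        for sp in species_names:
            for s, e, _, _ in cover[sp][chrom]:
                cuts.update((s, e))
        cuts = sorted(cuts)
        segs = []
        for s, e in zip(cuts, cuts[1:]):
            mid = (s + e) // 2
            label = {}
            for sp in species_names:
                covering = [q for cs, ce, q, _ in cover[sp][chrom] if cs <= mid < ce]
                label[sp] = covering[0] if covering else None
            segs.append((s, e, label))
        # merge consecutive segments with identical label vectors
        for s, e, label in segs:
            if all(v is None for v in label.values()):
                continue  # unaligned gap
            if units and units[-1].ref_chrom == chrom and unit_labels[-1] == label \
                    and units[-1].end == s:
                units[-1].end = e
            else:
                units.append(AncestralUnit("", chrom, s, e))
                unit_labels.append(label)
    for i, u in enumerate(units):
        u.id = f"U{i + 1:02d}"

    # order units along each species chromosome via lifted query coordinates
    species_units: dict[str, dict[str, list[str]]] = {}
    fusions: dict[str, list[tuple[str, str]]] = {}
    violations: list[str] = list(ties)
    for sp in species_names:
        per_chrom: dict[str, list[tuple[int, str]]] = {}
        for u, label in zip(units, unit_labels):
            qchrom = label[sp]
            if qchrom is None:
                violations.append(f"{sp}: unit {u.id} unplaced (possible fission signal)")
                continue
            qpos = _lift_midpoint(cover[sp][u.ref_chrom], u, qchrom)
            per_chrom.setdefault(qchrom, []).append((qpos, u.id))
        ordered = {c: [uid for _, uid in sorted(v)] for c, v in sorted(per_chrom.items())}
        species_units[sp] = ordered
        fusions[sp] = [
            (a, b) for uids in ordered.values() for a, b in zip(uids, uids[1:])
        ]
        if len(ordered) + len(fusions[sp]) != len(units):
            violations.append(
                f"{sp}: haploid {len(ordered)} + fusions {len(fusions[sp])} "
                f"!= ancestral {len(units)} (model violation)"
            )
    return AncestralKaryotype(units, species_units, fusions, violations)


def _lift_midpoint(cover_chrom, unit: AncestralUnit, qchrom: str) -> int:
    """Approximate query-coordinate position of a unit's midpoint."""
    mid = (unit.start + unit.end) // 2
    for cs, ce, q, anchors in cover_chrom:
        if q != qchrom or not (cs <= mid < ce):
            continue
        for ts, te, qs, qe, strand in anchors:
            if ts <= mid < te:
                return qs + (mid - ts) if strand == "+" else qs + (te - mid)
        return cs
    return 0


def ancestral_diploid_number(
    extant_haploid_count: int,
    fusion_count: int,
    sex_system: str = "XY",
    restore_y: bool = False,
) -> int:
    """Ancestral diploid number under a fusion-only model.

    The extant haploid count includes the X (autosomes + X).  Undoing the
    fusions gives the ancestral haploid count; the 2n is then assembled per
    sex system: XX/XY males carry 2 sex chromosomes (2n = 2*autosomes + 2);
    XO males carry a single X (2n = 2*autosomes + 1) unless the lost Y is
    restored for a pre-loss ancestor.
    """
    if extant_haploid_count < 0 or fusion_count < 0:
        raise ValueError("counts must be non-negative")
    if sex_system not in ("XY", "XO"):
        raise ValueError(f"unknown sex system {sex_system!r}")
    ancestral_haploid = extant_haploid_count + fusion_count
    autosomes = ancestral_haploid - 1  # one X among the haploid set
    if sex_system == "XY" or restore_y:
        return 2 * autosomes + 2
    return 2 * autosomes + 1
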