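"""Synthetic genomes, alignments and variant tracks with planted truth.

The generator emulates the study conditions every downstream stage assumes:
a ~24-chromosome ancestral karyotype related to three extant species by
species-specific fusions (11/1/2 by default); a focal X locus of ordered
signed blocks carrying a Y-derived insertion flanked by segmental-
duplication (BASD) copies; planted BASD copies (>=5 kb, >=90 % identity) and
tandem repeat arrays; heterozygous-SNP tracks with a PAR->stratum density
step; and Y-gene copies in intact and pseudogenized states.  Every feature
is recorded in a truth table so recovery tests can compare detector output
with what was planted.

All randomness flows from a single NumPy generator seeded by the config;
identical configs produce byte-identical outputs.  Mutations are
substitutions only by default (an indel rate option exists but defaults to
0), which keeps planted-identity arithmetic closed-form.  Emitted alignment
tables are computed from truth coordinates, not from running an aligner.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from ._align import revcomp
from .io_formats import AlignmentHit, GenomeSequence, SnpRecord
from .karyosynteny import fragment_name, window_coords
from .rearrange import (
    Arrangement,
    SignedBlock,
    apply_inversion,
    parse_arrangement,
)

BASES = np.frombuffer(b"ACGT", dtype="S1")

__all__ = [
    "BasdSpec", "RepeatSpec", "SnpSpec", "InsertionSpec", "SimConfig",
    "TruthTable", "simulate_karyotypes", "emit_karyotype_alignments",
    "simulate_locus_history", "random_dna", "mutate",
    "plant_basd_genome", "plant_insertion_locus", "plant_repeat_array",
    "plant_inverted_duplication", "plant_gene_copies",
    "simulate_snp_track", "write_snp_vcf", "emit_sequences",
]


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

def _default_fusion_plan() -> dict[str, list[tuple[str, str]]]:
    # species-specific fusion adjacencies: 11 / 1 / 2 events
    osi = [(chr(ord("A") + 2 * i), chr(ord("A") + 2 * i + 1)) for i in range(11)]
    return {
        "osimensis": osi,                      # (A,B) (C,D) ... (U,V)
        "tokunoshimensis": [("A", "C")],
        "muenninki": [("E", "X"), ("F", "G")],  # one fusion involves the X
    }


@dataclass
class BasdSpec:
    """Planted segmental-duplication copies: length, target pairwise
    identity between copies, and copy count."""

    copy_len: int = 6_000
    identity: float = 0.98
    n_copies: int = 4
    min_separation: int = 10_000  # > merge gap, keeps copies distinct

    def __post_init__(self) -> None:
        if not 0.9 < self.identity <= 1.0:
            raise ValueError("BASD identity must be in (0.9, 1]")


@dataclass
class RepeatSpec:
    """Tandem repeat array: unit length, copy count, per-copy mutation rate."""

    unit_len: int = 2_000
    n_copies: int = 52
    mutation_rate: float = 0.02


@dataclass
class SnpSpec:
    """Heterozygous-SNP track with a PAR -> stratum density step."""

    par_rate_per_kb: float = 0.1
    stratum_rate_per_kb: float = 2.0
    depth_mode: int = 42
    boundary_bp: int = 5_000_000
    chrom_len: int = 10_000_000
    chrom: str = "X"
    bad_fraction: float = 0.1  # records planted to violate the AF/depth filters

    def __post_init__(self) -> None:
        if self.par_rate_per_kb < 0 or self.stratum_rate_per_kb < 0:
            raise ValueError("densities must be >= 0")
        if not 0 <= self.boundary_bp <= self.chrom_len:
            raise ValueError("boundary outside chromosome")


@dataclass
class InsertionSpec:
    locus: tuple[str, str] = ("SB1", "SB2")
    blocks: str = "SB6- SB5-"


@dataclass
class SimConfig:
    seed: int = 0
    ancestral_n_chrom: int = 24  # haploid: 23 autosomes + X (Y tracked separately)
    fusion_plan: dict[str, list[tuple[str, str]]] = field(default_factory=_default_fusion_plan)
    block_layout: str = "SB1+ SB2+ SB3+ SB4+"
    insertion_spec: InsertionSpec = field(default_factory=InsertionSpec)
    inversions_per_lineage: int = 2
    basd_spec: BasdSpec = field(default_factory=BasdSpec)
    repeat_spec: RepeatSpec = field(default_factory=RepeatSpec)
    snp_spec: SnpSpec = field(default_factory=SnpSpec)
    indel_rate: float = 0.0

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)

    def chromosome_names(self) -> list[str]:
        n_auto = self.ancestral_n_chrom - 1
        if n_auto <= 23:
            letters = [c for c in "ABCDEFGHIJKLMNOPQRSTUVW"][:n_auto]
        else:
            letters = [f"A{i:02d}" for i in range(1, n_auto + 1)]
        return letters + ["X"]

    def __post_init__(self) -> None:
        names = set(self.chromosome_names())
        for sp, plan in self.fusion_plan.items():
            used: set[str] = set()
            for a, b in plan:
                for c in (a, b):
                    if c not in names:
                        raise ValueError(f"{sp}: fusion references unknown chromosome {c!r}")
                    if c in used:
                        raise ValueError(f"{sp}: fusion references consumed chromosome {c!r}")
                    used.add(c)


@dataclass
class TruthTable:
    """Ground truth for everything planted in one simulation run."""

    anc_lengths: dict[str, int] = field(default_factory=dict)
    fusions: dict[str, list[tuple[str, str]]] = field(default_factory=dict)
    species_layout: dict[str, dict[str, list[tuple[str, str]]]] = field(default_factory=dict)
    ancestor_arrangement: Arrangement | None = None
    arrangements: dict[str, Arrangement] = field(default_factory=dict)
    applied_inversions: dict[str, list[tuple[int, int]]] = field(default_factory=dict)
    basd_intervals: list[tuple[str, int, int]] = field(default_factory=list)
    flank_labels: dict[str, tuple[str | None, str | None]] = field(default_factory=dict)
    par_boundary_bp: int | None = None
    repeat_intervals: list[tuple[str, int, int]] = field(default_factory=list)
    gene_states: dict[str, str] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Sequence primitives
# ---------------------------------------------------------------------------

def random_dna(rng: np.random.Generator, length: int) -> str:
    return rng.choice(BASES, size=length).tobytes().decode()


def mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    """Substitute bases at the given per-base rate (always to a different
    base, so the realized mismatch fraction equals the rate in expectation)."""
    if rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype="S1").copy()
    n_mut = rng.binomial(len(arr), rate)
    if n_mut == 0:
        return seq
    pos = rng.choice(len(arr), size=n_mut, replace=False)
    for p in pos:
        choices = BASES[BASES != arr[p]]
        arr[p] = rng.choice(choices)
    return arr.tobytes().decode()


# ---------------------------------------------------------------------------
# Karyotypes
# ---------------------------------------------------------------------------

def simulate_karyotypes(config: SimConfig, rng: np.random.Generator | None = None):
    """Apply each species' fusion plan to the ancestral chromosome set.

    A fusion concatenates two chromosomes with a random orientation of the
    incoming partner; the haploid count drops by exactly one per fusion.
    Returns (genomes, truth) where genomes[species][chrom] is an ordered
    list of (ancestral chromosome, orientation) segments.
    """
    rng = rng if rng is not None else config.rng()
    names = config.chromosome_names()
    anc_lengths = {c: int(rng.integers(3, 9)) * 500_000 for c in names}
    truth = TruthTable(anc_lengths=anc_lengths)
    genomes: dict[str, dict[str, list[tuple[str, str]]]] = {}
    for sp in sorted(config.fusion_plan):
        plan = config.fusion_plan[sp]
        chroms: dict[str, list[tuple[str, str]]] = {c: [(c, "+")] for c in names}
        owner = {c: c for c in names}
        for a, b in plan:
            ca, cb = owner[a], owner[b]
            if ca == cb:
                raise ValueError(f"{sp}: fusion ({a},{b}) references a consumed chromosome")
            seg_b = chroms.pop(cb)
            if rng.random() < 0.5:
                seg_b = [(c, "-" if o == "+" else "+") for c, o in reversed(seg_b)]
            new = chroms.pop(ca) + seg_b
            new_name = ca + "+" + cb
            chroms[new_name] = new
            for c, _ in new:
                owner[c] = new_name
        genomes[sp] = chroms
        truth.fusions[sp] = list(plan)
        truth.species_layout[sp] = chroms
    return genomes, truth


def emit_karyotype_alignments(
    truth: TruthTable,
    ref_species: str,
    window_bp: int = 500_000,
) -> dict[str, list[AlignmentHit]]:
    """Windowed-fragment PAF-style hits of every species against a common
    reference species, computed exactly from the planted layout."""
    layouts = truth.species_layout
    if ref_species not in layouts:
        raise ValueError(f"unknown reference species {ref_species!r}")
    # ancestral chromosome -> (ref chrom, offset, orientation)
    ref_pos: dict[str, tuple[str, int, str]] = {}
    for chrom, segs in layouts[ref_species].items():
        off = 0
        for anc, orient in segs:
            ref_pos[anc] = (chrom, off, orient)
            off += truth.anc_lengths[anc]
    out: dict[str, list[AlignmentHit]] = {}
    for sp, layout in layouts.items():
        hits: list[AlignmentHit] = []
        for chrom, segs in layout.items():
            # per-bp segment boundaries on the species chromosome
            bounds = []
            off = 0
            for anc, orient in segs:
                bounds.append((off, off + truth.anc_lengths[anc], anc, orient))
                off += truth.anc_lengths[anc]
            chrom_len = off
            for w_off, w_size in window_coords(chrom_len, window_bp):
                for s, e, anc, orient in bounds:
                    lo, hi = max(s, w_off), min(e, w_off + w_size)
                    if hi <= lo:
                        continue
                    tchrom, t_off, t_orient = ref_pos[anc]
                    # position within the ancestral chromosome
                    if orient == "+":
                        a_lo, a_hi = lo - s, hi - s
                    else:
                        a_lo, a_hi = (e - hi), (e - lo)
                    if t_orient == "+":
                        ts, te = t_off + a_lo, t_off + a_hi
                    else:
                        alen = truth.anc_lengths[anc]
                        ts, te = t_off + alen - a_hi, t_off + alen - a_lo
                    strand = "+" if orient == t_orient else "-"
                    hits.append(
                        AlignmentHit(
                            query_name=fragment_name(chrom, w_off),
                            query_start=lo - w_off, query_end=hi - w_off,
                            target_name=tchrom, target_start=ts, target_end=te,
                            strand=strand, matches=hi - lo, block_len=hi - lo,
                            is_primary=True,
                        )
                    )
        out[sp] = hits
    return out


# ---------------------------------------------------------------------------
# Locus history
# ---------------------------------------------------------------------------

def simulate_locus_history(config: SimConfig, rng: np.random.Generator | None = None):
    """Insert the Y-derived blocks into the base layout, then apply
    ``inversions_per_lineage`` random inversions along each lineage."""
    rng = rng if rng is not None else config.rng()
    base = parse_arrangement(config.block_layout)
    ins = parse_arrangement(config.insertion_spec.blocks)
    if {b.id for b in base} & {b.id for b in ins}:
        raise ValueError("insertion blocks must be disjoint from the base layout")
    locus = tuple(config.insertion_spec.locus)
    gaps = {(base[i].id, base[i + 1].id): i for i in range(len(base) - 1)}
    if locus not in gaps:
        raise ValueError(f"insertion locus {locus} is not an inter-block gap of the base")
    gi = gaps[locus]
    ancestor = base[: gi + 1] + ins + base[gi + 1 :]
    truth = TruthTable(ancestor_arrangement=ancestor)
    arrangements: dict[str, Arrangement] = {}
    for sp in ("osimensis", "tokunoshimensis"):
        arr = ancestor
        applied = []
        for _ in range(config.inversions_per_lineage):
            i = int(rng.integers(0, len(arr)))
            j = int(rng.integers(i, len(arr)))
            arr = apply_inversion(arr, i, j)
            applied.append((i, j))
        arrangements[sp] = arr
        truth.arrangements[sp] = arr
        truth.applied_inversions[sp] = applied
    return arrangements, truth


# ---------------------------------------------------------------------------
# Planted features
# ---------------------------------------------------------------------------

def plant_basd_genome(
    rng: np.random.Generator,
    n_copies: int,
    copy_len: int = 6_000,
    identity: float = 0.98,
    genome_len: int = 200_000,
    min_separation: int = 10_000,
    chrom: str = "chrT",
    master: str | None = None,
):
    """Random backbone with mutated replicas of one master sequence planted
    at well-separated positions.

    Each copy is mutated from the master at rate (1 - identity)/2, so the
    expected pairwise identity between copies is the requested value.
    Returns (genome, master, copies) with copies as (start, end) intervals.
    """
    spacing = copy_len + min_separation
    need = n_copies * spacing + min_separation
    if genome_len < need:
        raise ValueError(f"genome_len {genome_len} too small for {n_copies} copies")
    backbone = random_dna(rng, genome_len)
    master = master if master is not None else random_dna(rng, copy_len)
    rate = (1.0 - identity) / 2.0
    starts = []
    slack = genome_len - need
    cursor = min_separation + int(rng.integers(0, slack + 1))
    for _ in range(n_copies):
        starts.append(cursor)
        cursor += spacing
    pieces, prev = [], 0
    copies = []
    for s in starts:
        pieces.append(backbone[prev:s])
        pieces.append(mutate(rng, master, rate))
        copies.append((s, s + copy_len))
        prev = s + copy_len
    pieces.append(backbone[prev:])
    return GenomeSequence(chrom, "".join(pieces)), master, copies


def plant_insertion_locus(
    rng: np.random.Generator,
    config: SimConfig | None = None,
    block_len: int = 20_000,
    flank_2a_len: int = 1_800,
    flank_2g_len: int = 10_800,
):
    """Realize the derived insertion locus with the split flank signature of
    a circular-intermediate integration.

    Layout: SB1 | BASD | 2g | inserted Y-derived blocks | 2a | BASD | SB2..
    The left boundary copy is followed by the downstream flank of the
    ancestral donor (2g) and the right boundary copy is preceded by its
    upstream flank (2a) - the split 2g-[insert]-2a configuration expected
    when an eccDNA intermediate (ancestrally 2a-BASD-2g) integrates by NAHR.
    """
    config = config or SimConfig()
    spec = config.basd_spec
    master = random_dna(rng, spec.copy_len)
    rate = (1.0 - spec.identity) / 2.0
    flanks = {
        "1a": random_dna(rng, flank_2a_len),
        "1g": random_dna(rng, flank_2g_len),
        "2a": random_dna(rng, flank_2a_len),
        "2g": random_dna(rng, flank_2g_len),
    }
    blocks = {f"SB{i}": random_dna(rng, block_len) for i in range(1, 7)}
    insert = blocks["SB6"] + blocks["SB5"]
    parts = [
        blocks["SB1"],
        mutate(rng, master, rate),
        mutate(rng, flanks["2g"], rate),
        insert,
        mutate(rng, flanks["2a"], rate),
        mutate(rng, master, rate),
        blocks["SB2"], blocks["SB3"], blocks["SB4"],
    ]
    seq = "".join(parts)
    left_start = block_len
    left_end = left_start + spec.copy_len
    right_start = left_end + flank_2g_len + len(insert) + flank_2a_len
    right_end = right_start + spec.copy_len
    truth = TruthTable(
        basd_intervals=[("locus", left_start, left_end), ("locus", right_start, right_end)],
        flank_labels={"left": (None, "2g"), "right": ("2a", None)},
    )
    return GenomeSequence("locus", seq), master, flanks, truth


def plant_repeat_array(
    rng: np.random.Generator,
    unit_len: int = 2_000,
    n_copies: int = 52,
    mutation_rate: float = 0.02,
    flank_len: int = 20_000,
    copy_fraction: float = 1.0,
    chrom: str = "het",
):
    """Tandem array of mutated unit replicas (optionally partial copies of
    ``copy_fraction`` of the unit) between random flanks.

    Returns (region, unit_master, intervals) with intervals in region
    coordinates.
    """
    unit = random_dna(rng, unit_len)
    copy_len = max(1, int(round(unit_len * copy_fraction)))
    pieces = [random_dna(rng, flank_len)]
    intervals = []
    pos = flank_len
    for _ in range(n_copies):
        c = mutate(rng, unit[:copy_len], mutation_rate)
        pieces.append(c)
        intervals.append((pos, pos + copy_len))
        pos += copy_len
    pieces.append(random_dna(rng, flank_len))
    return GenomeSequence(chrom, "".join(pieces)), unit, intervals


def plant_inverted_duplication(
    rng: np.random.Generator,
    arm_len: int = 30_000,
    spacer_len: int = 5_000,
    flank_len: int = 20_000,
    mutation_rate: float = 0.01,
    chrom: str = "pal",
):
    """Region containing one palindrome: arm ... spacer ... inverted arm."""
    arm = random_dna(rng, arm_len)
    left = flank_len
    seq = (
        random_dna(rng, flank_len)
        + arm
        + random_dna(rng, spacer_len)
        + mutate(rng, revcomp(arm), mutation_rate)
        + random_dna(rng, flank_len)
    )
    arms = ((left, left + arm_len),
            (left + arm_len + spacer_len, left + 2 * arm_len + spacer_len))
    return GenomeSequence(chrom, seq), arms


_STOPS = {"TAA", "TAG", "TGA"}


def _random_cds(rng: np.random.Generator, n_aa: int) -> str:
    """ATG + (n_aa - 1) random non-stop codons + TAA."""
    codons = ["ATG"]
    while len(codons) < n_aa:
        c = random_dna(rng, 3)
        if c not in _STOPS and "N" not in c:
            codons.append(c)
    return "".join(codons) + "TAA"


def plant_gene_copies(
    rng: np.random.Generator,
    gene: str = "Ddx3y",
    protein_len_aa: int = 300,
    n_intact: int = 1,
    n_pseudo: int = 1,
    spacer_len: int = 30_000,
    chrom: str = "chrY",
):
    """Plant intact and frameshifted (1-bp deletion) copies of one gene.

    Returns (genome, query_len_aa, loci) where loci are
    (start, end, true_state) intervals covering each planted CDS.
    """
    cds = _random_cds(rng, protein_len_aa)
    states = ["intact"] * n_intact + ["pseudo"] * n_pseudo
    pieces = [random_dna(rng, spacer_len)]
    pos = spacer_len
    loci = []
    for st in states:
        copy = cds
        if st == "pseudo":
            cut = len(cds) // 3  # frameshift in the first third of the CDS
            copy = cds[:cut] + cds[cut + 1 :]
        pieces.append(copy)
        loci.append((pos, pos + len(copy), st))
        pos += len(copy)
        pieces.append(random_dna(rng, spacer_len))
        pos += spacer_len
    return GenomeSequence(chrom, "".join(pieces)), protein_len_aa, loci


# ---------------------------------------------------------------------------
# SNP track
# ---------------------------------------------------------------------------

def simulate_snp_track(config: SimConfig, rng: np.random.Generator | None = None):
    """Poisson SNV track with PAR density before the boundary and stratum
    density after; a ``bad_fraction`` of records violate the AF/depth/SNV
    filters so filtering is exercised.  Returns (records, truth)."""
    rng = rng if rng is not None else config.rng()
    spec = config.snp_spec
    positions: list[int] = []
    for lo, hi, rate_kb in (
        (0, spec.boundary_bp, spec.par_rate_per_kb),
        (spec.boundary_bp, spec.chrom_len, spec.stratum_rate_per_kb),
    ):
        span = hi - lo
        if span <= 0 or rate_kb <= 0:
            continue
        n = rng.poisson(rate_kb * span / 1000.0)
        positions.extend(sorted(lo + rng.integers(0, span, size=n)))
    positions = sorted(set(int(p) for p in positions))
    records = []
    for p in positions:
        depth = int(rng.poisson(spec.depth_mode))
        depth = max(depth, 1)
        bad = rng.random() < spec.bad_fraction
        if not bad:
            alt_reads = rng.binomial(depth, 0.5)
            af = alt_reads / depth
            if not 0.25 <= af <= 0.75:
                af = 0.5
            ref, alt = "A", "G"
        else:
            kind = rng.integers(0, 3)
            if kind == 0:  # allele-fraction violation
                af = float(rng.choice([0.05, 0.95]))
                ref, alt = "A", "G"
            elif kind == 1:  # depth violation
                depth = int(rng.choice([spec.depth_mode // 4, spec.depth_mode * 3]))
                af = 0.5
                ref, alt = "A", "G"
            else:  # indel
                af = 0.5
                ref, alt = "A", "AT"
        records.append(SnpRecord(spec.chrom, p + 1, ref, alt, depth, af))
    truth = TruthTable(par_boundary_bp=spec.boundary_bp)
    return records, truth


def write_snp_vcf(records: Sequence[SnpRecord], path: str | Path,
                  chrom_lengths: Mapping[str, int], sample: str = "male1") -> None:
    """Write SnpRecords as a minimal VCF 4.2 with per-sample AD and DP."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom, length in chrom_lengths.items():
            fh.write(f"##contig=<ID={chrom},length={length}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        fh.write(f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{sample}\n")
        for r in records:
            alt_reads = int(round(r.allele_fraction * r.depth))
            ref_reads = r.depth - alt_reads
            fh.write(
                f"{r.chrom}\t{r.pos}\t.\t{r.ref}\t{r.alt}\t.\tPASS\t.\t"
                f"GT:AD:DP\t0/1:{ref_reads},{alt_reads}:{r.depth}\n"
            )


# ---------------------------------------------------------------------------
# Orchestrator
# ---------------------------------------------------------------------------

def emit_sequences(config: SimConfig, outdir: str | Path):
    """Run every generator under one seed and write FASTA / PAF / BLAST-tab /
    VCF plus truth TSVs into ``outdir``.  Returns the aggregate TruthTable."""
    from .io_formats import write_fasta, write_paf, write_blast_tab, write_tsv_report

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = config.rng()

    genomes, truth = simulate_karyotypes(config, rng)
    ref = min(truth.fusions, key=lambda sp: len(truth.fusions[sp]))
    paf = emit_karyotype_alignments(truth, ref_species=ref)
    for sp, hits in paf.items():
        write_paf(hits, outdir / f"{sp}_vs_{ref}.paf")

    arrangements, locus_truth = simulate_locus_history(config, rng)
    truth.ancestor_arrangement = locus_truth.ancestor_arrangement
    truth.arrangements = locus_truth.arrangements
    truth.applied_inversions = locus_truth.applied_inversions

    locus, master, flanks, basd_truth = plant_insertion_locus(rng, config)
    truth.basd_intervals = basd_truth.basd_intervals
    truth.flank_labels = basd_truth.flank_labels
    write_fasta([locus], outdir / "locus.fa")
    write_fasta([GenomeSequence("BASD_master", master)], outdir / "basd_seed.fa")
    write_fasta(
        [GenomeSequence(k, v) for k, v in flanks.items()], outdir / "flank_refs.fa"
    )
    # exact seed-vs-locus alignment table from truth
    basd_hits = []
    for chrom, s, e in truth.basd_intervals:
        copy = locus.seq[s:e]
        m = sum(a == b for a, b in zip(copy, master))
        basd_hits.append(
            AlignmentHit("BASD_master", 0, len(master), chrom, s, e,
                         "+", matches=m, block_len=len(master))
        )
    write_blast_tab(basd_hits, outdir / "basd_seed_hits.tsv")

    region, unit, intervals = plant_repeat_array(
        rng, config.repeat_spec.unit_len, config.repeat_spec.n_copies,
        config.repeat_spec.mutation_rate,
    )
    truth.repeat_intervals = [(region.name, s, e) for s, e in intervals]
    write_fasta([region], outdir / "repeat_region.fa")
    write_fasta([GenomeSequence("unit", unit)], outdir / "repeat_unit.fa")
    unit_hits = []
    for s, e in intervals:
        copy = region.seq[s:e]
        m = sum(a == b for a, b in zip(copy, unit))
        unit_hits.append(
            AlignmentHit("unit", 0, e - s, region.name, s, e, "+",
                         matches=m, block_len=e - s)
        )
    write_blast_tab(unit_hits, outdir / "repeat_unit_hits.tsv")

    records, snp_truth = simulate_snp_track(config, rng)
    truth.par_boundary_bp = snp_truth.par_boundary_bp
    write_snp_vcf(records, outdir / "hetsnps.vcf",
                  {config.snp_spec.chrom: config.snp_spec.chrom_len})

    gene_genome, qlen, loci = plant_gene_copies(rng)
    truth.gene_states = {f"copy{i + 1}": st for i, (_, _, st) in enumerate(loci)}
    write_fasta([gene_genome], outdir / "ygenes.fa")

    write_tsv_report(
        [{"feature": "basd", "chrom": c, "start": s, "end": e}
         for c, s, e in truth.basd_intervals]
        + [{"feature": "repeat", "chrom": c, "start": s, "end": e}
           for c, s, e in truth.repeat_intervals]
        + [{"feature": "par_boundary", "chrom": config.snp_spec.chrom,
            "start": truth.par_boundary_bp, "end": truth.par_boundary_bp}],
        outdir / "truth_features.tsv",
    )
    return truth
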