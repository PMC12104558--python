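"""Y-linked gene locus discovery and intact/pseudogene classification.

Loci come from protein-vs-genome hit tables (TBLASTN-style): hits of one
gene clustering on the genome are merged, the union of their query (amino
acid) intervals gives the hit coverage of the query protein, and loci
covering more than half the query are retained with a 10 kbp pad on each
side.  A locus is classified intact when its longest open reading frame
covers at least 80 % of the query protein length, otherwise pseudogene; a
gene with no locus above 50 % coverage is absent.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from ._align import revcomp
from .io_formats import GenomeSequence

__all__ = [
    "ProteinHit",
    "GeneLocus",
    "Orf",
    "GeneCall",
    "read_protein_hits",
    "find_loci",
    "find_orfs",
    "classify_gene",
    "copy_table",
]


@dataclass
class ProteinHit:
    """One protein-vs-genome alignment segment (query in amino acids,
    0-based half-open; target in bp, 0-based half-open)."""

    gene: str
    query_len_aa: int
    query_start: int
    query_end: int
    chrom: str
    target_start: int
    target_end: int
    strand: str = "+"


@dataclass
class GeneLocus:
    gene: str
    chrom: str
    start: int
    end: int
    strand: str
    query_len_aa: int
    coverage: float

    def __post_init__(self) -> None:
        if not 0 <= self.coverage <= 1:
            raise ValueError(f"coverage {self.coverage} outside [0,1]")


@dataclass
class Orf:
    start: int  # bp offset in the scanned sequence (forward-strand coords)
    end: int
    strand: str
    frame: int
    aa_len: int


@dataclass
class GeneCall:
    locus: GeneLocus
    status: str  # 'intact' | 'pseudo'
    longest_orf_aa: int
    orf_coverage: float


def read_protein_hits(path) -> list[ProteinHit]:
    """Read a protein-vs-genome hit table (TSV with header: gene,
    query_len_aa, query_start, query_end, chrom, target_start, target_end,
    strand; query coordinates in amino acids, 0-based half-open)."""
    df = pd.read_csv(path, sep="\t")
    return [
        ProteinHit(r.gene, int(r.query_len_aa), int(r.query_start),
                   int(r.query_end), r.chrom, int(r.target_start),
                   int(r.target_end), getattr(r, "strand", "+"))
        for r in df.itertuples()
    ]


def _union_len(ivs: list[tuple[int, int]]) -> int:
    ivs = sorted(ivs)
    total, cur_s, cur_e = 0, *ivs[0]
    for s, e in ivs[1:]:
        if s <= cur_e:
            cur_e = max(cur_e, e)
        else:
            total += cur_e - cur_s
            cur_s, cur_e = s, e
    return total + (cur_e - cur_s)


def find_loci(
    protein_hits: Sequence[ProteinHit],
    chrom_lengths: dict[str, int] | None = None,
    pad: int = 10_000,
    min_query_cov: float = 0.5,
) -> list[GeneLocus]:
    """Cluster hits of each gene on the genome (within 2x pad), compute the
    union query coverage per cluster, and keep loci with coverage strictly
    above ``min_query_cov``; intervals are padded and clipped."""
    by_key: dict[tuple[str, str], list[ProteinHit]] = {}
    for h in protein_hits:
        by_key.setdefault((h.gene, h.chrom), []).append(h)
    loci = []
    for (gene, chrom), hits in sorted(by_key.items()):
        hits.sort(key=lambda h: h.target_start)
        clusters: list[list[ProteinHit]] = [[hits[0]]]
        for h in hits[1:]:
            if h.target_start - clusters[-1][-1].target_end <= 2 * pad:
                clusters[-1].append(h)
            else:
                clusters.append([h])
        for cl in clusters:
            qlen = cl[0].query_len_aa
            cov = _union_len([(h.query_start, h.query_end) for h in cl]) / qlen
            if cov <= min_query_cov:
                continue
            start = max(0, min(h.target_start for h in cl) - pad)
            end = max(h.target_end for h in cl) + pad
            if chrom_lengths and chrom in chrom_lengths:
                end = min(end, chrom_lengths[chrom])
            plus = sum(h.target_end - h.target_start for h in cl if h.strand == "+")
            minus = sum(h.target_end - h.target_start for h in cl if h.strand == "-")
            loci.append(GeneLocus(gene, chrom, start, end,
                                  "+" if plus >= minus else "-",
                                  qlen, min(cov, 1.0)))
    return loci


_STOPS = {"TAA", "TAG", "TGA"}


def _scan_frame(seq: str, offset: int) -> list[tuple[int, int]]:
    """Maximal ATG..stop ORFs in one forward frame: (start, end) bp offsets,
    end exclusive of the stop codon.  Codons containing N break the chain."""
    orfs = []
    start = None
    i = offset
    while i + 3 <= len(seq):
        codon = seq[i : i + 3]
        if "N" in codon:
            start = None
        elif codon in _STOPS:
            if start is not None:
                orfs.append((start, i))
                start = None
        elif codon == "ATG" and start is None:
            start = i
        i += 3
    return orfs


def find_orfs(dna: str, min_len_aa: int = 50) -> list[Orf]:
    """All-frame ORF scan (ATG to in-frame stop, no internal stops, stop
    required).  Coordinates are on the forward strand; minus-strand ORFs are
    mapped back.  ``aa_len`` counts codons from ATG up to the stop."""
    dna = dna.upper()
    n = len(dna)
    out = []
    for frame in range(3):
        for s, e in _scan_frame(dna, frame):
            aa = (e - s) // 3
            if aa >= min_len_aa:
                out.append(Orf(s, e, "+", frame, aa))
    rc = revcomp(dna)
    for frame in range(3):
        for s, e in _scan_frame(rc, frame):
            aa = (e - s) // 3
            if aa >= min_len_aa:
                out.append(Orf(n - e, n - s, "-", frame, aa))
    out.sort(key=lambda o: (-o.aa_len, o.start, o.strand))
    return out


def classify_gene(
    locus: GeneLocus,
    genome: GenomeSequence,
    min_orf_cov: float = 0.8,
) -> GeneCall:
    """Intact iff the longest ORF in the locus covers >= ``min_orf_cov`` of
    the query protein length (in amino acids); otherwise pseudogene.
    Frameshifted copies truncate the longest ORF and classify as pseudo."""
    seq = genome.seq[locus.start : locus.end]
    orfs = find_orfs(seq, min_len_aa=1)
    longest = orfs[0].aa_len if orfs else 0
    cov = longest / locus.query_len_aa
    status = "intact" if cov >= min_orf_cov else "pseudo"
    return GeneCall(locus, status, longest, cov)


def copy_table(
    calls: Sequence[GeneCall],
    regions: Sequence[tuple[str, int, int, str]],
) -> pd.DataFrame:
    """Gene x region table of intact/pseudo copy counts (midpoint
    assignment; regions must not overlap; outside counts under
    'unassigned')."""
    by_chrom: dict[str, list[tuple[int, int, str]]] = {}
    for chrom, s, e, name in regions:
        by_chrom.setdefault(chrom, []).append((s, e, name))
    for ivs in by_chrom.values():
        ivs.sort()
        for (s1, e1, n1), (s2, e2, n2) in zip(ivs, ivs[1:]):
            if s2 < e1:
                raise ValueError(f"overlapping regions {n1} and {n2}")
    region_names = [name for _, _, _, name in regions] + ["unassigned"]
    genes = sorted({c.locus.gene for c in calls})
    index = pd.MultiIndex.from_product([region_names, ["intact", "pseudo"]],
                                       names=["region", "status"])
    table = pd.DataFrame(0, index=genes, columns=index)
    table.index.name = "gene"
    for c in calls:
        mid = (c.locus.start + c.locus.end) // 2
        assigned = "unassigned"
        for chrom, s, e, name in regions:
            if c.locus.chrom == chrom and s <= mid < e:
                assigned = name
                break
        table.loc[c.locus.gene, (assigned, c.status)] += 1
    return table
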