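"""Readers and writers for the external formats the pipeline touches.

All internal coordinates are 0-based half-open (BED/PAF convention).
1-based inclusive formats (BLAST outfmt 6, VCF, GFF3) are converted at the
boundary, in both directions.  BLAST minus-strand hits are normalised so
that ``target_start < target_end`` and the strand is recorded explicitly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

log = logging.getLogger(__name__)

__all__ = [
    "FormatError",
    "GenomeSequence",
    "AlignmentHit",
    "SnpRecord",
    "read_fasta",
    "write_fasta",
    "read_paf",
    "write_paf",
    "read_blast_tab",
    "write_blast_tab",
    "read_vcf_snps",
    "read_bed",
    "write_bed",
    "write_gff3",
    "write_tsv_report",
]


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


@dataclass
class GenomeSequence:
    """One chromosome / scaffold: a name and an uppercase DNA string."""

    name: str
    seq: str

    def __post_init__(self) -> None:
        self.seq = self.seq.upper()

    @property
    def length(self) -> int:
        return len(self.seq)

    def __len__(self) -> int:  # pragma: no cover - convenience
        return len(self.seq)


@dataclass
class AlignmentHit:
    """One pairwise local alignment, the shared currency of all stages.

    Coordinates are 0-based half-open on both sides; ``strand`` is '+' or
    '-'; ``identity`` is a fraction in [0, 1].
    """

    query_name: str
    query_start: int
    query_end: int
    target_name: str
    target_start: int
    target_end: int
    strand: str = "+"
    matches: int | None = None
    block_len: int | None = None
    identity: float | None = None
    is_primary: bool = True

    def __post_init__(self) -> None:
        if self.query_start >= self.query_end:
            raise ValueError(f"query interval empty: {self}")
        if self.target_start >= self.target_end:
            raise ValueError(f"target interval empty: {self}")
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")
        if self.identity is None and self.matches is not None and self.block_len:
            self.identity = self.matches / self.block_len
        if self.identity is not None and not 0.0 <= self.identity <= 1.0:
            raise ValueError(f"identity {self.identity} outside [0,1]")

    @property
    def target_span(self) -> int:
        return self.target_end - self.target_start


@dataclass
class SnpRecord:
    """A single called variant with the fields the strata filters need."""

    chrom: str
    pos: int  # 1-based, as in VCF
    ref: str
    alt: str
    depth: int
    allele_fraction: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.allele_fraction <= 1.0:
            raise ValueError(f"allele fraction {self.allele_fraction} outside [0,1]")

    @property
    def is_snv(self) -> bool:
        return len(self.ref) == 1 and len(self.alt) == 1


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> list[GenomeSequence]:
    """Read a FASTA file into :class:`GenomeSequence` records (uppercased)."""
    path = Path(path)
    records = []
    with open(path) as fh:
        first = fh.read(1)
        if first == "":
            raise FormatError(f"{path}: empty FASTA file")
        if first != ">":
            raise FormatError(f"{path}: line 1: expected '>' header, got {first!r}")
    for rec in SeqIO.parse(str(path), "fasta"):
        records.append(GenomeSequence(rec.id, str(rec.seq)))
    names = [r.name for r in records]
    if len(set(names)) != len(names):
        raise FormatError(f"{path}: duplicate sequence names")
    return records


def write_fasta(records: Iterable[GenomeSequence], path: str | Path, width: int = 60) -> None:
    seqs = [SeqRecord(Seq(r.seq), id=r.name, description="") for r in records]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(seqs)


# ---------------------------------------------------------------------------
# PAF (minimap2)
# ---------------------------------------------------------------------------

def read_paf(path: str | Path) -> list[AlignmentHit]:
    """Read minimap2-style PAF. ``is_primary`` derives from the tp:A tag.

    The 12 mandatory columns are required; unknown tags are ignored.
    """
    hits = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            cols = line.split("\t")
            if len(cols) < 12:
                raise FormatError(f"{path}: line {lineno}: PAF needs >=12 columns, got {len(cols)}")
            try:
                qs, qe = int(cols[2]), int(cols[3])
                ts, te = int(cols[7]), int(cols[8])
                matches, block_len = int(cols[9]), int(cols[10])
            except ValueError as exc:
                raise FormatError(f"{path}: line {lineno}: non-integer coordinate ({exc})") from None
            is_primary = True
            for tag in cols[12:]:
                if tag.startswith("tp:A:"):
                    is_primary = tag[5:] == "P"
            hits.append(
                AlignmentHit(
                    query_name=cols[0], query_start=qs, query_end=qe,
                    target_name=cols[5], target_start=ts, target_end=te,
                    strand=cols[4], matches=matches, block_len=block_len,
                    is_primary=is_primary,
                )
            )
    return hits


def write_paf(hits: Iterable[AlignmentHit], path: str | Path) -> None:
    with open(path, "w") as fh:
        for h in hits:
            matches = h.matches if h.matches is not None else h.target_span
            block_len = h.block_len if h.block_len is not None else h.target_span
            fields = [
                h.query_name, str(h.query_end), str(h.query_start), str(h.query_end),
                h.strand, h.target_name, str(h.target_end), str(h.target_start),
                str(h.target_end), str(matches), str(block_len), "60",
                "tp:A:" + ("P" if h.is_primary else "S"),
            ]
            fh.write("\t".join(fields) + "\n")


# ---------------------------------------------------------------------------
# BLAST tabular (outfmt 6)
# ---------------------------------------------------------------------------

_BLAST_COLS = 12


def read_blast_tab(path: str | Path) -> list[AlignmentHit]:
    """Read BLAST outfmt 6: 1-based inclusive coordinates are converted to
    0-based half-open, and sstart>send is encoded as strand '-' with swapped
    coordinates."""
    hits = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) < _BLAST_COLS:
                raise FormatError(f"{path}: line {lineno}: outfmt 6 needs 12 columns")
            qseqid, sseqid = cols[0], cols[1]
            try:
                pident = float(cols[2])
                length = int(cols[3])
                mismatch = int(cols[4])
                qstart, qend = int(cols[6]), int(cols[7])
                sstart, send = int(cols[8]), int(cols[9])
            except ValueError as exc:
                raise FormatError(f"{path}: line {lineno}: bad numeric field ({exc})") from None
            if not 0.0 <= pident <= 100.0:
                raise FormatError(f"{path}: line {lineno}: pident {pident} outside [0,100]")
            if sstart <= send:
                strand, ts, te = "+", sstart - 1, send
            else:
                strand, ts, te = "-", send - 1, sstart
            hits.append(
                AlignmentHit(
                    query_name=qseqid, query_start=qstart - 1, query_end=qend,
                    target_name=sseqid, target_start=ts, target_end=te,
                    strand=strand, matches=length - mismatch, block_len=length,
                    identity=pident / 100.0,
                )
            )
    return hits


def write_blast_tab(hits: Iterable[AlignmentHit], path: str | Path) -> None:
    with open(path, "w") as fh:
        for h in hits:
            block_len = h.block_len if h.block_len is not None else h.target_span
            matches = h.matches if h.matches is not None else block_len
            pident = 100.0 * (h.identity if h.identity is not None else matches / block_len)
            if h.strand == "+":
                sstart, send = h.target_start + 1, h.target_end
            else:
                sstart, send = h.target_end, h.target_start + 1
            fields = [
                h.query_name, h.target_name, f"{pident:.4f}", str(block_len),
                str(block_len - matches), "0", str(h.query_start + 1), str(h.query_end),
                str(sstart), str(send), "0.0", "0.0",
            ]
            fh.write("\t".join(fields) + "\n")


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def read_vcf_snps(path: str | Path, sample: str | None = None) -> list[SnpRecord]:
    """Read variants from a VCF, computing the allele fraction from the
    per-sample AD field (alt / (ref+alt)) when present, else from INFO/AF.

    Multiallelic sites are split into one record per alt allele.  Records
    with no usable depth information are skipped (count logged).
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    if sample is not None:
        if sample not in vcf.samples:
            raise FormatError(f"{path}: sample {sample!r} not in VCF ({vcf.samples})")
        sidx = vcf.samples.index(sample)
    else:
        sidx = 0 if vcf.samples else None

    records: list[SnpRecord] = []
    skipped = 0
    for v in vcf:
        ad = None
        if sidx is not None:
            try:
                ad_arr = v.format("AD")
            except KeyError:
                ad_arr = None
            if ad_arr is not None:
                ad = [int(x) for x in ad_arr[sidx]]
        depth = None
        if sidx is not None:
            try:
                dp_arr = v.format("DP")
            except KeyError:
                dp_arr = None
            if dp_arr is not None:
                depth = int(dp_arr[sidx][0])
        for ai, alt in enumerate(v.ALT):
            af = None
            if ad is not None and len(ad) > ai + 1:
                ref_d, alt_d = ad[0], ad[ai + 1]
                tot = ref_d + alt_d
                if tot > 0:
                    af = alt_d / tot
                if depth is None:
                    depth = sum(x for x in ad if x >= 0)
            if af is None:
                info_af = v.INFO.get("AF")
                if info_af is not None:
                    af = float(info_af[ai]) if isinstance(info_af, tuple) else float(info_af)
            if af is None or depth is None:
                skipped += 1
                continue
            records.append(SnpRecord(v.CHROM, v.POS, v.REF, alt, depth, min(max(af, 0.0), 1.0)))
    if skipped:
        log.info("read_vcf_snps: skipped %d allele records lacking depth/AF", skipped)
    return records


# ---------------------------------------------------------------------------
# BED / GFF3 / TSV
# ---------------------------------------------------------------------------

def read_bed(path: str | Path) -> list[tuple[str, int, int, str]]:
    """Read BED (>=3 columns) as (chrom, start, end, name) tuples."""
    regions = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            cols = line.split("\t")
            if len(cols) < 3:
                raise FormatError(f"{path}: line {lineno}: BED needs >=3 columns")
            try:
                start, end = int(cols[1]), int(cols[2])
            except ValueError:
                raise FormatError(f"{path}: line {lineno}: non-integer BED coordinate") from None
            name = cols[3] if len(cols) > 3 else f"region{lineno}"
            regions.append((cols[0], start, end, name))
    return regions


def write_bed(intervals: Iterable[Sequence], path: str | Path) -> None:
    """Write (chrom, start, end[, name[, score[, strand]]]) rows as BED."""
    with open(path, "w") as fh:
        for row in intervals:
            fh.write("\t".join(str(x) for x in row) + "\n")


def write_gff3(features: Iterable[dict], path: str | Path) -> None:
    """Write feature dicts as GFF3 (1-based inclusive on output).

    Expected keys: chrom, source, type, start, end (0-based half-open
    internally), strand, attributes (dict).
    """
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for f in features:
            attrs = ";".join(f"{k}={v}" for k, v in f.get("attributes", {}).items())
            fh.write(
                "\t".join(
                    [
                        f["chrom"], f.get("source", "ytrace"), f["type"],
                        str(f["start"] + 1), str(f["end"]),
                        str(f.get("score", ".")), f.get("strand", "."), ".",
                        attrs or ".",
                    ]
                )
                + "\n"
            )


def write_tsv_report(rows, path: str | Path, columns: Sequence[str] | None = None) -> None:
    """Write a pandas DataFrame or list of dicts/tuples as a TSV report."""
    import pandas as pd

    if not isinstance(rows, pd.DataFrame):
        rows = pd.DataFrame(rows, columns=columns)
    rows.to_csv(path, sep="\t", index=False)
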