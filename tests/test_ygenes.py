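"""Gene locus discovery and intact/pseudogene classification."""

import numpy as np
import pytest

from ytrace._align import revcomp
from ytrace.io_formats import GenomeSequence
from ytrace.syndata import plant_gene_copies, random_dna
from ytrace.ygenes import (
    GeneLocus,
    ProteinHit,
    classify_gene,
    copy_table,
    find_loci,
    find_orfs,
)

_STOPS = {"TAA", "TAG", "TGA"}


def orf_oracle(dna):
    """Independent maximal-ORF enumeration: for every in-frame stop, walk
    back over clean codons to the first ATG after the previous barrier."""
    out = set()
    n = len(dna)
    for strand, s in (("+", dna), ("-", revcomp(dna))):
        for f in range(3):
            codons = [s[i:i + 3] for i in range(f, n - 2, 3)]
            for j, c in enumerate(codons):
                if c not in _STOPS:
                    continue
                i, first_atg = j - 1, None
                while i >= 0 and codons[i] not in _STOPS and "N" not in codons[i]:
                    if codons[i] == "ATG":
                        first_atg = i
                    i -= 1
                if first_atg is not None:
                    lo, hi = f + 3 * first_atg, f + 3 * j
                    if strand == "-":
                        lo, hi = n - hi, n - lo
                    out.add((strand, lo, hi))
    return out


class TestFindLoci:
    def _hit(self, qs, qe, ts, te, qlen=100, gene="g", chrom="c"):
        return ProteinHit(gene, qlen, qs, qe, chrom, ts, te)

    def test_sixty_percent_coverage_padded(self):
        loci = find_loci([self._hit(0, 60, 50_000, 50_180)])
        assert len(loci) == 1
        assert (loci[0].start, loci[0].end) == (40_000, 60_180)
        assert loci[0].coverage == pytest.approx(0.6)

    def test_forty_percent_no_locus(self):
        assert find_loci([self._hit(0, 40, 50_000, 50_120)]) == []

    def test_clipped_at_chromosome_start(self):
        loci = find_loci([self._hit(0, 60, 2_000, 2_180)])
        assert loci[0].start == 0

    def test_split_hits_union_coverage(self):
        hits = [self._hit(0, 30, 10_000, 10_090),
                self._hit(40, 70, 12_000, 12_090)]
        loci = find_loci(hits)
        assert len(loci) == 1
        assert loci[0].coverage == pytest.approx(0.6)

    def test_distant_clusters_separate_loci(self):
        hits = [self._hit(0, 60, 10_000, 10_180),
                self._hit(0, 60, 500_000, 500_180)]
        assert len(find_loci(hits)) == 2


class TestFindOrfs:
    def test_minimal_example(self):
        orfs = find_orfs("ATGAAATAG", min_len_aa=1)
        assert len(orfs) == 1
        assert (orfs[0].start, orfs[0].end, orfs[0].aa_len) == (0, 6, 2)

    def test_no_atg_empty(self):
        assert find_orfs("CCCCCCTAGCCC", min_len_aa=1) == []

    def test_strand_symmetry(self, rng):
        seq = random_dna(rng, 600)
        n = len(seq)
        fwd = {(o.strand, o.start, o.end) for o in find_orfs(seq, min_len_aa=1)}
        mirrored = {
            ("+" if o.strand == "-" else "-", n - o.end, n - o.start)
            for o in find_orfs(revcomp(seq), min_len_aa=1)
        }
        assert fwd == mirrored

    def test_matches_bruteforce_oracle(self, rng_factory):
        for seed in range(5):
            seq = random_dna(rng_factory(seed), 1000)
            got = {(o.strand, o.start, o.end) for o in find_orfs(seq, min_len_aa=1)}
            assert got == orf_oracle(seq)

    def test_n_codon_breaks_orf(self):
        # ATG AAN AAA TAG: the N codon kills the reading
        assert find_orfs("ATGAANAAATAG", min_len_aa=1) == []


class TestClassify:
    def test_planted_intact_and_frameshift(self, rng_factory):
        rng = rng_factory(0)
        genome, qlen, loci = plant_gene_copies(rng, n_intact=1, n_pseudo=1)
        hits = [ProteinHit("Ddx3y", qlen, 0, qlen, genome.name, s, e)
                for s, e, _ in loci]
        calls = [classify_gene(l, genome) for l in find_loci(
            hits, {genome.name: genome.length})]
        statuses = sorted(c.status for c in calls)
        assert statuses == ["intact", "pseudo"]
        intact = next(c for c in calls if c.status == "intact")
        assert intact.orf_coverage >= 0.8

    def test_low_orf_coverage_is_pseudo(self, rng):
        seq = random_dna(rng, 5_000)
        locus = GeneLocus("g", "c", 0, 5_000, "+", 400, 0.55)
        call = classify_gene(locus, GenomeSequence("c", seq))
        assert call.status == "pseudo"

    def test_threshold_monotone(self, rng_factory):
        rng = rng_factory(1)
        genome, qlen, loci = plant_gene_copies(rng, n_intact=2, n_pseudo=2)
        hits = [ProteinHit("g", qlen, 0, qlen, genome.name, s, e)
                for s, e, _ in loci]
        found = find_loci(hits, {genome.name: genome.length})
        for lo, hi in [(0.6, 0.8), (0.8, 0.95)]:
            calls_lo = [classify_gene(l, genome, min_orf_cov=lo) for l in found]
            calls_hi = [classify_gene(l, genome, min_orf_cov=hi) for l in found]
            n_intact = lambda cs: sum(c.status == "intact" for c in cs)
            assert n_intact(calls_hi) <= n_intact(calls_lo)


class TestCopyTable:
    def _calls(self, rng, n_intact, n_pseudo):
        genome, qlen, loci = plant_gene_copies(
            rng, gene="Ddx3y", n_intact=n_intact, n_pseudo=n_pseudo)
        hits = [ProteinHit("Ddx3y", qlen, 0, qlen, genome.name, s, e)
                for s, e, _ in loci]
        found = find_loci(hits, {genome.name: genome.length})
        return genome, [classify_gene(l, genome) for l in found]

    def test_single_intact_copy(self, rng_factory):
        genome, calls = self._calls(rng_factory(0), 1, 0)
        table = copy_table(calls, [(genome.name, 0, genome.length, "regionA")])
        assert table.loc["Ddx3y", ("regionA", "intact")] == 1

    def test_empty_calls_all_zero(self):
        table = copy_table([], [("c", 0, 100, "r")])
        assert table.size == 0 or (table.to_numpy() == 0).all()

    def test_planted_mixture_recovered(self, rng_factory):
        genome, calls = self._calls(rng_factory(2), 5, 3)
        table = copy_table(calls, [(genome.name, 0, genome.length, "r")])
        assert table.loc["Ddx3y", ("r", "intact")] == 5
        assert table.loc["Ddx3y", ("r", "pseudo")] == 3

    def test_overlapping_regions_rejected(self):
        with pytest.raises(ValueError):
            copy_table([], [("c", 0, 100, "a"), ("c", 50, 150, "b")])
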