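# ytrace

Tools for tracing the dissolution of a mammalian Y chromosome from
chromosome-level genome assemblies, built around the spiny-rat genus
*Tokudaia*, in which two species (*T. osimensis*, *T. tokunoshimensis*) have
lost the Y entirely (XO/XO) while retaining Y-linked genes on the X, and a
third (*T. muenninki*) carries neo-sex chromosomes from an autosome fusion.

The package implements the computational inference stack such a study needs,
end to end, with a synthetic-genome generator that plants every feature the
detectors look for, so each stage is testable against ground truth:

- **io_formats** — FASTA / PAF / BLAST outfmt-6 / VCF / BED / GFF3 readers
  and writers with one internal coordinate convention (0-based half-open).
- **syndata** — seeded generator for karyotypes related by fusions, signed
  block arrangements with a Y-derived insertion, planted segmental
  duplications, tandem repeat arrays, heterozygous-SNP tracks with a
  PAR→stratum density step, and intact/frameshifted gene copies.
- **karyosynteny** — 500 kb windowing, >100 kb primary-hit filtering,
  synteny maps, and fusion-only parsimony reconstruction of the ancestral
  karyotype with its diploid number.
- **rearrange** — exact signed inversion (reversal) distance by
  Hannenhalli–Pevzner theory, `d = n + 1 − c + h + f` on the extended
  breakpoint graph, with a BFS oracle for verification; enumeration and
  parsimony scoring of the 24 candidate ancestral insertion configurations
  (3 loci × 8 signed orders of the two inserted blocks).
- **basd** — iterative boundary-associated segmental duplication (BASD)
  detection (drop hits <500 bp, merge splits within 3 kb, candidates ≥3 kb,
  final copies ≥5 kb), copy-number-by-region tables, flank provenance
  (α/γ classes) and the boundary-order rule that distinguishes a direct
  insertion from integration of a circular eccDNA intermediate.
- **strata** — heterozygous-SNV filtering (AF 0.25–0.75, depth between half
  and 1.5× the depth-histogram mode), windowed density with masking, and a
  least-squares change point for the pseudoautosomal (PAR/Strata 0) to
  Strata 1 boundary, with S1a/S1b subdivision.
- **repeats** — repeat-unit tiling statistics (full/partial copy counts,
  coverage), unit-period proposal from self-alignment offsets, and
  palindrome (inverted-duplication) detection.
- **ygenes** — gene locus discovery from protein-vs-genome hits (>50 % query
  coverage, ±10 kb extension) and intact/pseudogene classification by the
  longest-ORF ≥80 %-of-query rule.

A `ytrace` command-line interface wraps the main stages
(`simulate`, `synteny`, `scenarios`, `basd`, `strata`, `tile`,
`palindromes`, `genes`).

## Worked example

Score all 24 candidate ancestral configurations of the Y-derived blocks
(SB5, SB6) against the shipped encoding of the two extant arrangements
(the duplicated SB5′ excluded), then reconstruct the ancestral karyotype
from a simulated three-species dataset:

```python
from ytrace import syndata, karyosynteny
from ytrace.rearrange import (enumerate_ancestral_configs,
                              load_xq_arrangements, score_scenarios)

table = score_scenarios(enumerate_ancestral_configs(), load_xq_arrangements())
print(table.table[table.table.is_minimal].to_string(index=False))

cfg = syndata.SimConfig(seed=1)
genomes, truth = syndata.simulate_karyotypes(cfg)
paf = syndata.emit_karyotype_alignments(truth, ref_species="tokunoshimensis")
maps = {sp: karyosynteny.build_synteny_map(karyosynteny.filter_synteny_hits(h))
        for sp, h in paf.items()}
ref_lengths = {c: sum(truth.anc_lengths[a] for a, _ in segs)
               for c, segs in truth.species_layout["tokunoshimensis"].items()}
ak = karyosynteny.infer_fusions(maps, ref_lengths)
print("fusions per lineage:", {sp: ak.fusion_count(sp) for sp in ak.fusions})
print("2n (genus ancestor, Y restored):",
      karyosynteny.ancestral_diploid_number(13, 11, "XO", restore_y=True))
print("2n (post-Y-loss ancestor):",
      karyosynteny.ancestral_diploid_number(24, 0, "XO"))
```

prints

```
  locus  inserted  d_osimensis  d_tokunoshimensis  total  rank  is_minimal
SB1-SB2 SB5-,SB6-            2                  2      4     1        True
SB1-SB2 SB6-,SB5-            2                  2      4     1        True
fusions per lineage: {'muenninki': 2, 'osimensis': 11, 'tokunoshimensis': 1}
2n (genus ancestor, Y restored): 48
2n (post-Y-loss ancestor): 47
```

Two co-optimal scenarios tie at four inversions total (two per lineage),
both placing the Y-derived insertion between SB1 and SB2, in reverse
orientation — the parsimony core of the reconstruction.  The karyotype
stage recovers the planted 11/1/2 species-specific fusions and yields a
2n = 48 (XX/XY) genus ancestor and a 2n = 47 (XO) ancestor after Y loss.

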