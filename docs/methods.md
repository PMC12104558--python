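# Methods

This note records the models behind each stage, the defaults and why they
were chosen, what the synthetic-data generator does and does not emulate,
and the numerical choices a maintainer would want to know.

## Coordinate conventions

All internal coordinates are 0-based half-open (the BED/PAF convention).
BLAST outfmt-6, VCF and GFF3 are converted at the I/O boundary; BLAST
minus-strand hits are normalised so `target_start < target_end` with the
strand recorded, giving one uniform interval algebra everywhere.  Unknown
PAF tags are ignored (only `tp:A` is consumed, to set the primary flag).

## Signed inversion distance (rearrange)

Arrangements of oriented synteny blocks are compared under the signed
reversal model: one operation reverses a contiguous run of blocks and flips
their orientations.  The distance is computed exactly by
Hannenhalli–Pevzner theory on the extended breakpoint graph:

    d = n + 1 − c + h + f

with `n` blocks, `c` breakpoint-graph cycles, `h` hurdles and `f` a
fortress correction.  Linear arrangements are capped with fixed sentinels
(0 and n+1) that never move — the standard treatment for a linear
chromosome embedded in conserved flanking sequence.  Implementation
details:

- Each signed element is doubled (`+v → 2v−1, 2v`; `−v → 2v, 2v−1`);
  black edges join the doubled sequence across element gaps, gray edges
  join consecutive values.  Cycles are counted by the alternating walk.
- A gray edge is *oriented* when its two endpoint positions share parity;
  components are connected sets of interleaving nontrivial gray edges
  (edges spanning a single position are adjacencies and ignored).
- Hurdles are unoriented components whose endpoint occurrences form one
  circularly consecutive run in the position-ordered sequence of
  unoriented-component endpoints; a hurdle is a superhurdle when deleting
  it promotes a previously non-hurdle component, and `f = 1` only when the
  hurdle count is odd (≥3) and every hurdle is a superhurdle.

The implementation is verified against an independent breadth-first-search
oracle over the reversal Cayley graph: exhaustively for every signed
permutation up to n = 6 (46,080 permutations at n = 6) and on random pairs
at n = 7.  `sorting_scenario` produces one optimal sequence greedily: a
distance-reducing reversal always exists, so scanning all O(n²) reversals
per step terminates in exactly `d` steps.

A DCJ-style mode is deliberately *not* the default: the quantity of
interest is the minimum number of inversions, and for the block counts used
here (n ≤ 7) the exact reversal distance is cheap.

## Insertion-scenario parsimony

Candidate ancestral configurations place the two Y-derived blocks (SB5,
SB6), kept adjacent, into one of the three internal gaps of the ancestral
X layout SB1(+)–SB2(+)–SB3(+)–SB4(+), in every order and sign combination:
3 × 2! × 2² = 24 configurations.  Each is scored by the sum of inversion
distances to the extant arrangements (after removing duplicated blocks such
as SB5′, which the reversal model cannot represent); all configurations
attaining the minimum are reported — ties are never resolved arbitrarily,
because co-optimal scenarios are themselves a finding.

The shipped extant-arrangement encoding
(`ytrace/data/xq_region1_arrangements.yaml`) is this package's reading of
published synteny maps, which carry the signed orders graphically rather
than as text.  It was chosen to be consistent with the documented
boundary-duplication adjacencies and with a two-inversions-per-lineage
history, and it reproduces the two co-optimal scenarios at the SB1–SB2
locus.  Users analysing their own assemblies should supply their own
encoding (`score_scenarios` accepts any arrangement mapping).

## Karyotype reconstruction (karyosynteny)

Query genomes are fragmented into non-overlapping 500 kb windows (the
window step is not overlapping because the maps are used for coverage
accounting, where overlap would double-count) and aligned to a common
reference; only primary alignments strictly longer than 100 kb are kept.
Fragment hits are lifted to source coordinates and aggregated per
chromosome pair with union (not summed) interval lengths.

Ancestral units are the common refinement of the reference genome under
every species' chromosome correspondences: reference coordinates are cut at
all correspondence boundaries and maximal runs with a constant
species-chromosome label vector are merged.  The model is fusion-only: a
species chromosome covering k units implies k−1 fusions; fission-like
signals (units unplaced in some species) are surfaced as violations, never
silently resolved.  A chromosome with no single partner holding ≥50 % of
its aligned bp (`min_fraction`) is reported as a tie.  Orientation of
fusion joins is recorded in the maps but plays no role in the 2n
arithmetic.

Diploid numbers: with the extant haploid count including the X, undoing the
fusions gives the ancestral haploid count; XX/XY gives
2n = 2·autosomes + 2, XO gives 2n = 2·autosomes + 1, and an XO lineage's
pre-Y-loss ancestor adds the lost Y back on request.

## BASD detection (basd)

Detection iterates: align the seed set to the genome; exclude alignments
shorter than 500 bp (read as *keep ≥500*: "shorter than" excludes only
<500); merge split alignments of the same query on the same target
chromosome and strand whose target intervals lie within 3,000 bp (strand
partitioning prevents chimeric merges across palindromic hits; merging is
on target coordinates only); keep merged spans ≥3,000 bp as candidates; use
candidate sequences as the next seeds.  Convergence is an identical
candidate interval set between iterations (after merging overlapping
candidates across queries), capped at 10 iterations with a warning.
Candidates spanning ≥5,000 bp (merged span, not aligned bp) become final
copies, named in coordinate order with a species prefix and zero-padded
ordinal.

Desk-scale alignment uses an internal exact-k-mer anchored, gapless
extension aligner (k = 16, X-drop extension, per-diagonal clustering);
real BLASTN tables can be substituted through `read_blast_tab` and the
`hits=` argument.  The aligner shares the generator's substitution-only
mutation model and will fragment hits across indels — acceptable here
because the merge step reassembles splits within 3 kb.

Flank provenance aligns the window up to 1.8 kb upstream and 10.8 kb
downstream of each copy against the four ancestral donor flank references
(1α/2α upstream, 1γ/2γ downstream); a label requires ≥500 aligned bp at
≥90 % identity.  The mechanism rule at a two-boundary locus: left copy
trailed by a γ flank and right copy led by an α flank (the ancestral
α–BASD–γ arrangement arriving split) is called a circular-intermediate
(eccDNA) integration; the unsplit order is a direct insertion; anything
else is undetermined.  Copy relatedness at desk scale is summarised by
single-linkage clustering on pairwise identity (default threshold 0.95)
rather than a maximum-likelihood tree.

## Strata detection (strata)

Filters keep single-nucleotide substitutions with allele fraction in
[0.25, 0.75] and depth in [mode/2, 1.5·mode], bounds inclusive, with the
depth mode estimated from the integer depth histogram (ties to the smallest
depth).  The half/1.5× *rule* is primary and generalises across datasets;
fixed bounds can be supplied explicitly when a study's printed constants
are preferred.  Note the rule and a printed pair like (21, 65) cannot both
hold exactly for any single mode (mode 42 gives 21/63); the package
implements the rule and lets users override.

Windowed density uses 100 kb windows by default (resolving a ~100 Mb
chromosome into ~10³ windows); windows overlapping a mask (e.g.
heterochromatin) are excluded entirely.  The boundary is the split
minimizing the two-segment residual sum of squares of window densities
(single mean-shift change point — the original localisation was
descriptive, so the simplest well-defined estimator is used), accepted only
when the post-boundary mean exceeds the pre-boundary mean threefold
(configurable); otherwise "no boundary", the expected outcome for a female
(X–X) track.  Strata 1 can be subdivided at an inversion interval into
S1a/S1b with per-segment means; no test statistic is attached.

## Repeats and genes

`tile_unit` clusters unit-vs-region hits along the region: a hit extends
the current copy cluster only while target-adjacent (gap ≤ one unit length)
and contributing mostly new unit coverage, so split alignments of one copy
chain together while the next tandem copy reopens.  Clusters covering ≥50 %
of the unit (`min_copy_fraction`) count as full copies, the rest as partial
— reported separately because published partial-copy counts rarely state a
cutoff.  `propose_unit` takes the bp-weighted modal off-diagonal offset of
plus-strand self-hits as the candidate period (5 % relative clustering of
offsets) and returns ranked candidates; the final choice stays with the
user, mirroring manual unit curation.  Palindromes are minus-strand
self-hits with arms ≥10 kb at ≥90 % identity, non-overlapping, merged to
maximal extent.

Gene loci: hits of one protein clustered within 2×pad (pad 10 kb) on the
genome; hit coverage is the union of query (amino-acid) intervals over the
query length; loci require coverage strictly >0.5 ("more than 50 %"),
padded ±10 kb and clipped.  Classification: the longest ORF (ATG to
in-frame stop, stop required, N-containing codons break the chain, all six
frames) must cover ≥0.8 of the query protein length ("at least 80 %") for
an intact call; otherwise pseudogene.  The ≥80 % rule is applied uniformly
to all genes.  A 1-bp frameshift truncates the longest ORF well below the
threshold on realistic protein lengths, which is what the generator plants
for pseudo copies.

## Synthetic data: what it does and does not emulate

The generator reproduces, under one seeded NumPy stream per run
(byte-identical outputs for identical configs):

- a 24-chromosome haploid ancestor (23 autosomes + X) fused species-
  specifically 11/1/2 times by default, with random join orientations and
  chromosome lengths of 1.5–4 Mb (multiples of 500 kb so every unit spans
  ≥2 windows, down-scaled from real ~100 Mb chromosomes purely for
  problem size);
- signed block histories: insertion of SB6−, SB5− between SB1 and SB2,
  then 2 random inversions per lineage;
- segmental-duplication copies of 6 kb at target pairwise identity 0.98
  (each copy mutated from a master at rate (1−identity)/2, substitutions
  only, so planted-identity arithmetic stays closed-form; 3σ of pairwise
  identity for 6 kb copies at 0.98 is ≈ ±0.006);
- an insertion locus with the split 2γ-[insert]-2α flank signature;
- tandem repeat arrays (default 52 copies, 2 kb unit, 2 % mutation) and
  inverted duplications;
- Poisson SNV tracks (default 0.1/kb PAR vs 2.0/kb stratum, boundary at
  5 Mb of a 10 Mb chromosome, depth ~ Poisson(42), 10 % of records planted
  to violate the filters);
- gene copies as random no-internal-stop CDS (300 aa default), pseudo
  copies carrying a 1-bp deletion in the first third of the CDS.

Alignment tables are emitted from truth coordinates, not by running an
aligner, so detector tests are independent of aligner quirks.  Not
emulated: indels (rate option exists, default 0), sequencing error,
GC/repeat composition bias, gene conversion between duplication copies,
nested or overlapping rearrangements, and real chromosome scale.  Passing
recovery tests therefore demonstrates correctness of the detection logic
under the stated noise model, not performance on real assemblies, where
alignment quality and repeat structure dominate.

## Numerical choices and degenerate inputs

- Depth-mode ties break to the smallest depth; the mode needs ≥100 records.
- Change-point splits require ≥1 window on each side; a step at the first
  window yields a boundary after window 0.  A zero-density PAR accepts any
  positive step (the multiplicative factor is undefined at 0).
- Region tables assign copies by midpoint; overlapping regions are an
  error, features outside all regions count as "unassigned".
- `enumerate_ancestral_configs` deduplicates arrangements and is
  deterministic (loci in base order, orders and signs lexicographic).
- BLAST round-trips preserve identity to 4 decimals (pident is printed
  with 4); 1-bp minus-strand intervals cannot encode strand in BLAST
  coordinates and are avoided by construction.

## Known limitations

- The reversal model excludes duplicated blocks; SB5′-like duplicates are
  dropped before distance computation by contract.
- The fusion-only karyotype model cannot express fissions or
  translocations; it reports violations instead.
- The internal aligner is gapless; indel-rich duplications would be
  fragmented (mitigated by the 3 kb merge) and identity estimates would be
  biased downward.
- Single change point only; multi-strata chromosomes need repeated calls
  on sub-tracks.
- `infer_fusions` assumes every ancestral unit is separable in at least
  one species; adjacencies fused identically in *all* species are
  unrecoverable in principle and surface as a reduced unit count.
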