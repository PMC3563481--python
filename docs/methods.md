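# Methods

## Model and procedure

`trbackmap` analyses capture-enrichment resequencing data in two steps.

**Step 1 — target-region (TR) mapping and calling.** The TR reference is a
single sequence: each capture target is extended by `pad` bases on both
sides (default 49 — one less than the 50 bp reads the defaults assume, so a
read overlapping a target by a single base still fits the extended block),
overlapping extended targets are merged, and the merged blocks are
concatenated with runs of `spacer_len` N bases (default 50) between them.
Because an aligned base over an N always counts as a mismatch, no read with
a sane mismatch budget can span a junction; a read may legally hang up to
`max_mismatches` bases into a spacer, which the QC liftover handles by
clipping such records to their block. A transform table records
`(tr_start, tr_end, chrom, genome_start)` per block and provides exact
O(log n) liftover both ways; positions inside spacers raise a dedicated
error, genome positions outside every block return a "not in target"
result.

Genotypes are called per pileup column by counting: a site is **homozygous**
for the majority base when that base carries *strictly more than*
`hom_fraction` (default 0.80) of the reads; otherwise it is **heterozygous**
for the two most frequent bases, provided the minor allele has at least
`min_minor_reads` (default 2) reads and, by default, support on both
strands, and no third base reaches the minor-read threshold (tri-allelic
columns are no-calls). Sites below `min_depth` (default 8×, a common
minimum SNP-detection threshold) are no-calls. Base qualities do not enter
the rule; an ingest-level minimum quality can be applied to real data
upstream. Overlapping mates of one fragment count as two independent
observations — the simplest contract, and a conservative one given that the
both-strand requirement already guards against one-sided evidence.

**Step 2 — read-backmapping.** Every read observed at a candidate SNP
column — reference-supporting reads included, since re-typing needs them —
is extracted exactly once together with its mate and remapped against the
whole genome; duplicates are removed exactly as a conventional pipeline
would. A read survives for a SNP only if its single best whole-genome
placement (`n_best_hits == 1`) still covers the SNP's lifted genome
position; a read with an equal-best placement anywhere else is discarded
for every SNP. Each SNP is then re-typed from its surviving reads with the
same thresholds as step 1. Verdicts: *retained* (same genotype),
*genotype_changed*, or *eliminated* (re-typed homozygous reference, became
a no-call, or fell below the depth threshold — each with a distinct reason
code so genotype reversal and depth collapse can be separated in the
report). By default only heterozygous candidates are re-typed — force
mapping manufactures heterozygous artifacts, and homozygous non-reference
calls pass through lifted but unchanged — and a flag extends re-typing to
homozygous calls. "Maps better or equally well" is decided on the whole
read's mismatch count; mate placement affects pairing flags only.
Eliminated variants are written to a separate VCF with
`FILTER=backmap_removed` rather than discarded, because a variant in a
genuinely variant homologous region is indistinguishable, at this stage,
from a force-mapping artifact.

A weaker screen, `probe_backmap`, maps just the SNP plus 25 flanking
reference bases to the genome and flags multi-locus placements. It is kept
as a fast pre-filter but never eliminates anything on its own: a paralog
diverged by even a few bases leaves the 51-mer probe uniquely mappable
while its individual reads still force-map, which is precisely the case the
read-level method exists for (a test demonstrates this construction).

## The builtin aligner

The aligner is deliberately exact rather than fast: for a read and budget
*k* it returns *every* ungapped placement on either strand achieving the
minimum mismatch count, if that minimum is ≤ *k*. The search tiles the read
with at least *k*+1 disjoint exact-match windows (window length
`min(seed_len, len(read) // (k+1))`, `seed_len` default 12); by pigeonhole
any placement with ≤ *k* mismatches matches one window exactly, so index
lookup plus verification finds the complete hit set. Reads too short to
carry usable windows fall back to scanning every offset. The hit set is
verified against a brute-force all-offsets oracle in tests. Uniqueness
means `n_best_hits == 1` at the minimum mismatch count — the
operationalisation of "remains mapped uniquely". Gapped alignment,
quality-aware scoring and indels are out of scope; the cleanup mechanism
being modelled is substitution force-mapping, and keeping the aligner exact
keeps the oracle exact. External aligners interoperate through SAM (`NM`
for mismatches, `NH` for equal-best hit counts; mapping quality 0 is
treated as non-unique when `NH` is absent).

Paired-end mapping reduces each mate to its equal-best set first, then
prefers combinations forming a proper FR pair with insert inside
`insert_range` (default 50–400 bp), choosing deterministically among ties.
A mate's placement never alters the other read's own best-hit count.

## Enrichment QC

A read is on-target when its alignment span overlaps any target by ≥1 base.
The enrichment factor is `(on-target read fraction) / (target length /
genome size)` — the standard fold-enrichment form, dimensionless and equal
to 1 for uniform coverage. The coverage AUC is the exact Mann–Whitney rank
statistic `P(d_on > d_off) + ½·P(d_on = d_off)` over per-base depths
(positive class = target bases), never a trapezoid approximation;
off-target bases can be subsampled with a fixed seed on large genomes.
Strand bias is `|forward_fraction − 0.5| × 2` as a percentage (0 balanced,
100 one-sided). Completeness is the fraction of target bases at or above
each threshold in {1, 2, 5, 8, 15, 20, 30}. Cross-sample coverage
correlation is plain Pearson on paired per-base depths, with zero-variance
pairs reported as missing, not 0. Genotype concordance compares unordered
genotypes at sites called non-reference in both sets and also emits the
discordant-site list for replicate-validation filtering. Call-set overlap
reports all Venn regions for 2–3 sets plus pairwise fractions under both
the smaller-set and union denominators, since "overlap percentage" is
otherwise ambiguous.

## Synthetic data

The generator emulates the data regime the method targets: a small
multi-chromosome random genome; capture targets; planted heterozygous and
homozygous SNPs realised on two haplotypes; FR paired-end reads (50 bp,
insert 150 ± 20 bp, flat quality) with independent per-base substitution
errors at 1 %; strong enrichment (off-target background defaults to 1 % of
the on-target depth). The key device is the **paralogous decoy**: a donor
span is duplicated to an off-target location with independent per-base
divergence at a tunable rate, every divergence position is recorded, and
the copy is *also* sequenced at on-target depth — modelling capture probes
cross-hybridising to a close homolog, which is what makes paralog reads
abundant in real enriched libraries. Planted SNPs avoid divergence
positions. Everything regenerates byte-identically from (seed, parameters),
and a per-read truth table records origin, haplotype, orientation and
error positions.

Canonical scenarios (fixed, documented seeds):

| name | construction | purpose |
|---|---|---|
| `CLEAN` (seed 11) | 90 kb genome, 6×1.5 kb targets, 30×, no paralogy | soundness: nothing may be eliminated; both modes must agree exactly |
| `PARALOG95` (seed 42) | 200 kb genome, 19 kb targets incl. a 5 kb span duplicated at 95 % identity off-target, 30× | the force-mapping mechanism and its cleanup |
| `IDENTICAL_DUP` (seed 7) | same at divergence 0 | every decoy read has two equal-best placements and is removed wholesale |
| `LOWDEPTH` (seed 23) | `CLEAN` at 8× | the minimum-depth boundary |

Scenario sizes were chosen so the complete suite (fixtures built once per
session, both modes run on each) finishes in well under a minute while
keeping ~200 divergence sites in `PARALOG95` — enough for percentage-level
statements about elimination rates.

What the simulation does **not** model: indels and structural variation
(the aligner is ungapped by scope), quality-score profiles, GC- or
mappability-dependent coverage bias, chimeric fragments, barcode chemistry
(multiplexed replicates are emulated as independent seed-varied read sets
over the same haplotypes). Passing tests therefore demonstrate the
force-mapping mechanism and its cleanup under substitution-only divergence,
not performance on real libraries with indel paralogy or coverage bias.

## Known limitations and degenerate cases

- A heterozygous SNP *inside* a duplicated span is systematically diluted
  before cleanup: force-mapped homolog reads add reference-allele depth, and
  when the majority fraction crosses 80 % the site is called homozygous
  reference at step 1 and never re-examined. This is inherent to cleaning
  up after a count-based first pass rather than jointly modelling paralogs.
- In an identically duplicated region (divergence 0) every read is removed
  by the uniqueness filter, so true variants there are eliminated with the
  artifacts — the motivation for keeping the removed-variants VCF.
- The both-strands requirement rejects real hets whose minor-allele reads
  happen to land on one strand; at 30× this is a percent-level effect.
- The final VCF is restricted to the actual target intervals; calls in the
  ±pad fringe are kept separately (`final_calls_all`) because fringe sites
  see only the subset of reads that fit the block and are not comparable
  with whole-genome calling.
- Ties everywhere (equal counts, equal-best placements) break
  lexicographically / by coordinate, making every output byte-reproducible
  under a fixed seed.
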