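# trbackmap

Targeted-resequencing SNP calling with **read-backmapping** cleanup of
force-mapped false positives.

## The problem

Capture-enrichment experiments (exome or gene-panel resequencing) only care
about a small fraction of the genome, so mapping reads against a reference
built from just the target regions is much faster than whole-genome (WG)
mapping. The catch: a read whose true locus is *outside* the targets — most
commonly from a paralog of a targeted gene that co-hybridises with the
capture probes — has nowhere correct to go and gets **force-mapped** onto its
closest homolog inside the target reference. At every position where the
paralog diverges from the target copy, those reads pile up a convincing
non-reference allele, producing heterozygous false-positive SNP calls.

`trbackmap` implements the two-step remedy:

1. **TR mapping** — build a single concatenated *target-region (TR)
   reference*: targets padded by `pad` bases (default 49, one less than the
   read length), merged, and joined with 50-base N spacers so no read can
   align across a junction. Map all reads against it and call SNPs with a
   count-based rule (homozygous when one base carries **more than 80 %** of
   the reads, heterozygous otherwise, minimum depth 8×, minor allele on both
   strands). A transform table gives exact bidirectional liftover between TR
   and genome coordinates.
2. **Read-backmapping** — extract only the reads covering candidate SNPs
   (plus their mates), remap *those* to the whole genome, discard every read
   that maps equally well or better somewhere else, and re-type each SNP
   from the reads that remain uniquely mapped over it. SNPs that revert to
   homozygous reference or lose their support are eliminated as
   force-mapping artifacts.

The package also provides the surrounding QC surface (on-target percentage,
average depth of coverage, completeness ladder, enrichment factor, exact
rank-statistic coverage AUC, strand bias, cross-sample Pearson correlation,
genotype concordance, Venn-style call-set overlap) and a deterministic
synthetic-data generator whose *paralogous decoy* reproduces the
force-mapping mechanism end to end, so every stage is testable without any
downloads.

## Worked example

```bash
# generate the canonical paralog scenario: ~200 kb genome, a 5 kb duplicated
# segment at 95% identity with only one copy in the targets, 30 planted SNPs,
# 30x on-target coverage, 1% base error
trbackmap simulate --fixture PARALOG95 --out-dir sim

# run the two-step mode and the conventional WG mode, then compare
trbackmap run --mode both \
    --genome sim/genome.fasta --targets sim/targets.bed \
    --fastq1 sim/reads_1.fastq --fastq2 sim/reads_2.fastq \
    --out-dir run
```

prints

```
tr_backmap: 247 initial -> 30 final variants (217 eliminated)
wg: 30 variants in target
{
 "n_tr_backmap": 30,
 "n_wg": 30,
 "overlap_fraction_min": 1.0,
 "overlap_fraction_union": 1.0,
 "genotype_concordance": 1.0,
 "n_shared_sites": 30
 ...
}
```

Reading: TR-only calling reported 247 variants — the 30 planted SNPs plus
217 heterozygous false positives sitting exactly on paralog divergence
positions. Read-backmapping eliminated all 217 (their supporting reads map
uniquely back to the paralog locus, after which each site re-types as
homozygous reference) and kept the 30 real SNPs, whose genotypes agree 100 %
with the conventional whole-genome analysis — at a fraction of the mapping
work, since only SNP-covering reads ever touch the whole genome.

Artifacts land in `run/`: the TR reference FASTA and transform table, SAM
files per stage, initial/final/removed VCFs (final calls in genome
coordinates; eliminated calls kept with `FILTER=backmap_removed` since some
could be true variants in homologous regions), a per-variant backmapping
report (TSV + JSON) and the enrichment QC summary.

The same flow is available as a library:

```python
from trbackmap import RunConfig, RunInputs, run_tr_backmap, make_fixture

ts = make_fixture("PARALOG95")
res = run_tr_backmap(RunConfig(), inputs=RunInputs(ts.genome, ts.targets, ts.pairs))
print(res.report.summary())
# {'n_initial': 247, 'n_retained': 29, 'n_eliminated': 217,
#  'n_genotype_changed': 1, 'elimination_fraction': 0.878...}
```

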