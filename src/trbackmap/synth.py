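"""Deterministic synthetic data: genomes, paralogs, variants, reads, truth.

The generator emulates the data regime of a capture-enrichment experiment:
a small multi-chromosome genome, target intervals, planted heterozygous and
homozygous SNPs, and paired-end reads concentrated on the targets with a
thin genome-wide background. Its key feature is a *paralogous decoy*: a
duplicated segment, diverged at a tunable rate, whose copy lies outside the
targets but is still enriched (capture probes hybridise to close homologs).
Reads from the decoy force-map onto the in-target copy when mapping against
a target-region-only reference — exactly the false-positive mechanism the
read-backmapping cleanup exists to remove.

Everything is reproducible: the same seed and parameters give byte-identical
FASTA/FASTQ/VCF output, and every read is recorded in a machine-readable
truth table.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .align import ReadPair, revcomp
from .intervals import GenomicInterval, write_bed
from .pileup import VariantCall
from .reference import write_genome_fasta
from .samio import write_fastq_pairs
from .vcfio import write_vcf

_BASES = np.array(list("ACGT"))


# --- truth containers ----------------------------------------------------

@dataclass(frozen=True)
class Divergence:
    """One reference-vs-paralog difference (not a sample variant)."""

    donor_pos: int  # genome coordinate on the donor chromosome
    dest_pos: int  # genome coordinate on the destination chromosome
    donor_base: str
    dest_base: str


@dataclass(frozen=True)
class ParalogSpec:
    donor: GenomicInterval
    dest_chrom: str
    dest_start: int
    divergence: float


@dataclass
class ParalogMap:
    donor: GenomicInterval
    dest: GenomicInterval
    divergences: list[Divergence]

    def donor_divergence_sites(self) -> set[tuple[str, int]]:
        return {(self.donor.chrom, d.donor_pos) for d in self.divergences}


@dataclass(frozen=True)
class TruthVariant:
    chrom: str
    pos: int
    ref: str
    alt: str
    zygosity: str  # "het" | "hom"

    @property
    def genotype(self) -> tuple[str, str]:
        return (self.alt, self.alt) if self.zygosity == "hom" else tuple(sorted((self.ref, self.alt)))


@dataclass(frozen=True)
class ReadOrigin:
    chrom: str
    frag_start: int
    insert_len: int
    haplotype: int
    read1_is_left: bool
    origin: str  # "target" | "decoy" | "background"
    errors1: tuple[int, ...]  # error offsets within mate 1
    errors2: tuple[int, ...]
    duplicate_of: str | None = None


@dataclass
class TruthSet:
    """A complete synthetic scenario plus ground truth for every artifact."""

    seed: int
    params: dict
    genome: dict[str, str]
    targets: list[GenomicInterval]
    paralog: ParalogMap | None
    variants: list[TruthVariant]
    haplotypes: dict[str, tuple[str, str]]
    pairs: list[ReadPair] = field(default_factory=list)
    read_truth: dict[str, ReadOrigin] = field(default_factory=dict)

    @property
    def genome_lengths(self) -> dict[str, int]:
        return {c: len(s) for c, s in self.genome.items()}

    def truth_by_site(self) -> dict[tuple[str, int], TruthVariant]:
        return {(v.chrom, v.pos): v for v in self.variants}

    # --- writers --------------------------------------------------------
    def write(self, out_dir: str | Path) -> dict[str, Path]:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "genome": out / "genome.fasta",
            "targets": out / "targets.bed",
            "truth_vcf": out / "truth.vcf",
            "fastq1": out / "reads_1.fastq",
            "fastq2": out / "reads_2.fastq",
            "paralog_bed": out / "paralog.bed",
            "manifest": out / "manifest.json",
        }
        write_genome_fasta(self.genome, paths["genome"])
        write_bed(self.targets, paths["targets"])
        self.write_truth_vcf(paths["truth_vcf"])
        write_fastq_pairs(self.pairs, paths["fastq1"], paths["fastq2"])
        if self.paralog is not None:
            write_bed([self.paralog.donor, self.paralog.dest], paths["paralog_bed"])
        paths["manifest"].write_text(
            json.dumps(
                {
                    "seed": self.seed,
                    "params": self.params,
                    "n_variants": len(self.variants),
                    "n_pairs": len(self.pairs),
                    "n_divergences": len(self.paralog.divergences) if self.paralog else 0,
                },
                indent=1,
                default=str,
            )
        )
        return paths

    def write_truth_vcf(self, path: str | Path) -> None:
        calls = [
            VariantCall(
                ref_name=v.chrom,
                pos=v.pos,
                ref_base=v.ref,
                genotype=v.genotype,
                zygosity=v.zygosity,
                depth=0,
                stage="truth",
            )
            for v in self.variants
        ]
        write_vcf(calls, self.genome_lengths, path)


# --- generation ----------------------------------------------------------

def generate_genome(
    lengths: Mapping[str, int],
    paralog: ParalogSpec | None = None,
    seed: int = 0,
) -> tuple[dict[str, str], ParalogMap | None]:
    """Random genome with an optional diverged duplicate of a donor span.

    The donor span is copied into the destination location (overwriting the
    random bases there), with each base independently substituted at the
    divergence rate; every difference is recorded.
    """
    rng = np.random.default_rng([seed, 0])
    genome = {
        name: "".join(rng.choice(_BASES, size=n)) for name, n in lengths.items()
    }
    if paralog is None:
        return genome, None
    donor = paralog.donor
    if donor.chrom not in genome or donor.end > len(genome[donor.chrom]):
        raise ValueError(f"donor span {donor} exceeds chromosome")
    if not 0.0 <= paralog.divergence <= 1.0:
        raise ValueError("divergence rate must be in [0, 1]")
    dest_end = paralog.dest_start + len(donor)
    if paralog.dest_chrom not in genome or dest_end > len(genome[paralog.dest_chrom]):
        raise ValueError("destination span exceeds chromosome")

    donor_seq = list(genome[donor.chrom][donor.start : donor.end])
    copy = donor_seq.copy()
    divergences: list[Divergence] = []
    mutate = rng.random(len(copy)) < paralog.divergence
    for i in np.flatnonzero(mutate):
        old = copy[i]
        choices = [b for b in "ACGT" if b != old]
        new = choices[rng.integers(3)]
        copy[i] = new
        divergences.append(
            Divergence(donor.start + int(i), paralog.dest_start + int(i), old, new)
        )
    dest_chrom_seq = genome[paralog.dest_chrom]
    genome[paralog.dest_chrom] = (
        dest_chrom_seq[: paralog.dest_start] + "".join(copy) + dest_chrom_seq[dest_end:]
    )
    pmap = ParalogMap(
        donor=donor,
        dest=GenomicInterval(paralog.dest_chrom, paralog.dest_start, dest_end),
        divergences=divergences,
    )
    return genome, pmap


def plant_variants(
    genome: Mapping[str, str],
    targets: Sequence[GenomicInterval],
    n_het: int,
    n_hom: int,
    seed: int = 0,
    avoid: set[tuple[str, int]] | None = None,
) -> tuple[dict[str, tuple[str, str]], list[TruthVariant]]:
    """Plant SNPs at distinct target positions and build two haplotypes.

    Planted sites avoid the ``avoid`` set (typically paralog divergence
    positions) and each other. Heterozygous variants go on one haplotype
    (chosen at random), homozygous ones on both.
    """
    rng = np.random.default_rng([seed, 1])
    avoid = avoid or set()
    eligible = [
        (t.chrom, p)
        for t in sorted(targets)
        for p in range(t.start, t.end)
        if (t.chrom, p) not in avoid
    ]
    need = n_het + n_hom
    if need > len(eligible):
        raise ValueError(f"only {len(eligible)} eligible positions for {need} variants")
    picked_idx = rng.choice(len(eligible), size=need, replace=False)
    picked = [eligible[i] for i in sorted(picked_idx)]
    rng.shuffle(picked)

    haps = {c: [list(s), list(s)] for c, s in genome.items()}
    variants: list[TruthVariant] = []
    for k, (chrom, pos) in enumerate(picked):
        ref = genome[chrom][pos]
        alt = [b for b in "ACGT" if b != ref][rng.integers(3)]
        if k < n_het:
            hap = int(rng.integers(2))
            haps[chrom][hap][pos] = alt
            variants.append(TruthVariant(chrom, pos, ref, alt, "het"))
        else:
            haps[chrom][0][pos] = alt
            haps[chrom][1][pos] = alt
            variants.append(TruthVariant(chrom, pos, ref, alt, "hom"))
    variants.sort(key=lambda v: (v.chrom, v.pos))
    haplotypes = {c: ("".join(h[0]), "".join(h[1])) for c, h in haps.items()}
    return haplotypes, variants


def simulate_reads(
    haplotypes: Mapping[str, tuple[str, str]],
    targets: Sequence[GenomicInterval],
    mean_depth_on: float,
    mean_depth_off: float,
    read_len: int = 50,
    insert_mean: float = 150.0,
    insert_sd: float = 20.0,
    error_rate: float = 0.01,
    seed: int = 0,
    decoy_spans: Sequence[GenomicInterval] = (),
    duplicate_rate: float = 0.0,
) -> tuple[list[ReadPair], dict[str, ReadOrigin]]:
    """Simulate FR paired-end reads with enrichment on targets and decoys.

    Fragments are drawn at ``mean_depth_on`` from each target and decoy
    span (decoys model cross-hybridising paralogs: enriched but not part of
    the target set) and at ``mean_depth_off`` genome-wide. Each fragment
    picks one of the two haplotypes uniformly; mates are taken from the two
    fragment ends in FR orientation, with which physical strand is read
    first chosen at random. Substitution errors hit each base independently
    at ``error_rate``. ``duplicate_rate`` appends exact copies of finished
    pairs (errors included), emulating PCR duplicates.
    """
    rng = np.random.default_rng([seed, 2])
    chrom_lengths = {c: len(h[0]) for c, h in haplotypes.items()}
    genome_size = sum(chrom_lengths.values())

    plan: list[tuple[str, GenomicInterval | None, int]] = []
    for kind, spans, depth in (
        ("target", list(targets), mean_depth_on),
        ("decoy", list(decoy_spans), mean_depth_on),
    ):
        for span in spans:
            n = int(round(depth * len(span) / (2 * read_len)))
            plan.append((kind, span, n))
    n_bg = int(round(mean_depth_off * genome_size / (2 * read_len)))
    plan.append(("background", None, n_bg))

    pairs: list[ReadPair] = []
    truth: dict[str, ReadOrigin] = {}
    serial = 0
    chroms = list(chrom_lengths)
    weights = np.array([chrom_lengths[c] for c in chroms], dtype=float)
    weights /= weights.sum()

    for kind, span, n in plan:
        for _ in range(n):
            insert = int(round(rng.normal(insert_mean, insert_sd)))
            insert = max(read_len, insert)
            if span is not None:
                chrom = span.chrom
                lo = max(0, span.start - insert + 1)
                hi = max(lo + 1, span.end)
                start = int(rng.integers(lo, hi))
            else:
                chrom = chroms[int(rng.choice(len(chroms), p=weights))]
                start = int(rng.integers(0, max(1, chrom_lengths[chrom] - insert)))
            start = min(start, chrom_lengths[chrom] - insert)
            start = max(start, 0)
            insert = min(insert, chrom_lengths[chrom] - start)
            if insert < read_len:
                continue
            hap = int(rng.integers(2))
            frag = haplotypes[chrom][hap][start : start + insert]
            left = frag[:read_len]
            right = revcomp(frag[-read_len:])
            read1_is_left = bool(rng.random() < 0.5)
            seq1, seq2 = (left, right) if read1_is_left else (right, left)
            seq1, errs1 = _apply_errors(seq1, error_rate, rng)
            seq2, errs2 = _apply_errors(seq2, error_rate, rng)
            name = f"r{serial:07d}"
            serial += 1
            pairs.append(ReadPair(name, seq1, seq2))
            truth[name] = ReadOrigin(
                chrom, start, insert, hap, read1_is_left, kind, errs1, errs2
            )

    if duplicate_rate > 0:
        dups = []
        for pair in pairs:
            if rng.random() < duplicate_rate:
                dup_name = f"{pair.name}dup"
                dups.append(ReadPair(dup_name, pair.seq1, pair.seq2))
                src = truth[pair.name]
                truth[dup_name] = ReadOrigin(
                    src.chrom, src.frag_start, src.insert_len, src.haplotype,
                    src.read1_is_left, src.origin, src.errors1, src.errors2,
                    duplicate_of=pair.name,
                )
        pairs.extend(dups)
    return pairs, truth


def _apply_errors(
    seq: str, error_rate: float, rng: np.random.Generator
) -> tuple[str, tuple[int, ...]]:
    if error_rate <= 0:
        return seq, ()
    hits = np.flatnonzero(rng.random(len(seq)) < error_rate)
    if hits.size == 0:
        return seq, ()
    out = list(seq)
    for i in hits:
        out[i] = [b for b in "ACGT" if b != out[i]][rng.integers(3)]
    return "".join(out), tuple(int(i) for i in hits)


# --- canonical fixtures --------------------------------------------------

FIXTURE_SEEDS = {"CLEAN": 11, "PARALOG95": 42, "IDENTICAL_DUP": 7, "LOWDEPTH": 23}


def make_fixture(name: str, seed: int | None = None) -> TruthSet:
    """Build one of the canonical test scenarios.

    CLEAN          no paralogy, 30x on-target, 1% error.
    PARALOG95      a 5 kb duplicated segment at 95% identity; only one copy
                   is in the target set, the other is an enriched decoy —
                   target-region-only calling produces false positives at
                   its divergence sites.
    IDENTICAL_DUP  the same construction at divergence 0: decoy reads have
                   two equal-best genome placements and are removed
                   wholesale by the uniqueness filter.
    LOWDEPTH       CLEAN at the 8x minimum-depth boundary.
    """
    if name not in FIXTURE_SEEDS:
        raise KeyError(f"unknown fixture {name!r}; choose from {sorted(FIXTURE_SEEDS)}")
    seed = FIXTURE_SEEDS[name] if seed is None else seed

    if name in ("CLEAN", "LOWDEPTH"):
        lengths = {"chr1": 60_000, "chr2": 30_000}
        targets = [GenomicInterval("chr1", s, s + 1_500) for s in range(4_000, 60_000, 10_000)]
        pspec, decoys = None, []
        depth_on = 30.0 if name == "CLEAN" else 8.0
        n_het, n_hom = 12, 6
    else:
        lengths = {"chr1": 120_000, "chr2": 80_000}
        donor = GenomicInterval("chr1", 20_000, 25_000)
        divergence = 0.05 if name == "PARALOG95" else 0.0
        pspec = ParalogSpec(donor, "chr2", 40_000, divergence)
        targets = [donor] + [
            GenomicInterval("chr1", s, s + 2_000) for s in range(35_000, 100_000, 10_000)
        ]
        depth_on = 30.0
        n_het, n_hom = 20, 10

    genome, pmap = generate_genome(lengths, pspec, seed=seed)
    avoid = pmap.donor_divergence_sites() if pmap else set()
    haplotypes, variants = plant_variants(
        genome, targets, n_het=n_het, n_hom=n_hom, seed=seed + 1, avoid=avoid
    )
    decoy_spans = [pmap.dest] if pmap is not None else []
    params = {
        "lengths": lengths,
        "depth_on": depth_on,
        "depth_off": depth_on / 100.0,
        "read_len": 50,
        "insert_mean": 150.0,
        "insert_sd": 20.0,
        "error_rate": 0.01,
        "n_het": n_het,
        "n_hom": n_hom,
        "divergence": pspec.divergence if pspec else None,
    }
    pairs, read_truth = simulate_reads(
        haplotypes,
        targets,
        mean_depth_on=depth_on,
        mean_depth_off=depth_on / 100.0,
        read_len=50,
        insert_mean=150.0,
        insert_sd=20.0,
        error_rate=0.01,
        seed=seed + 2,
        decoy_spans=decoy_spans,
    )
    return TruthSet(
        seed=seed,
        params=params,
        genome=genome,
        targets=targets,
        paralog=pmap,
        variants=variants,
        haplotypes=haplotypes,
        pairs=pairs,
        read_truth=read_truth,
    )


def standard_fixtures() -> dict[str, TruthSet]:
    """All canonical scenarios, built with their documented seeds."""
    return {name: make_fixture(name) for name in FIXTURE_SEEDS}
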