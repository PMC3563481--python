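"""End-to-end orchestration of the two analysis modes.

``run_tr_backmap`` is the fast path: build a concatenated target-region
reference, map, call, then clean up force-mapped false positives by
read-backmapping. ``run_wg`` is the conventional path: map everything to
the whole genome, call, restrict to the targets. ``compare_modes`` reports
overlap and genotype concordance between the two.

Every stage writes its artifact into the output directory and logs read
and variant counts, so a run can be audited stage by stage.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

from . import backmap as bm
from .align import Aligner, AlignmentRecord, ReadPair, remove_duplicates
from .intervals import GenomicInterval, pad_and_merge, read_bed
from .metrics import (
    EnrichmentSummary,
    genotype_concordance,
    summarize_enrichment,
    variant_set_overlap,
)
from .pileup import (
    STAGE_INITIAL_TR,
    STAGE_POST_BACKMAP,
    GenotypeThresholds,
    VariantCall,
    build_pileups,
    call_variants,
)
from .reference import TRReference, build_tr_reference, read_genome_fasta
from .samio import read_fastq_pairs, write_fastq_pairs, write_sam
from .vcfio import FILTER_BACKMAP_REMOVED, write_vcf

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


@dataclass
class RunConfig:
    """Everything a run needs; paths may be ``None`` when objects are passed directly."""

    genome_fasta: str | None = None
    targets_bed: str | None = None
    fastq1: str | None = None
    fastq2: str | None = None
    out_dir: str | None = None
    pad: int = 49
    spacer_len: int = 50
    max_mismatches: int = 5
    insert_range: tuple[int, int] = (50, 400)
    min_depth: int = 8
    hom_fraction: float = 0.80
    min_minor_reads: int = 2
    require_both_strands: bool = True
    flank: int = 25
    include_hom_in_backmap: bool = False
    seed: int = 0

    def thresholds(self) -> GenotypeThresholds:
        return GenotypeThresholds(
            min_depth=self.min_depth,
            hom_fraction=self.hom_fraction,
            min_minor_reads=self.min_minor_reads,
            require_both_strands=self.require_both_strands,
        )

    def validate(self) -> None:
        for name in ("genome_fasta", "targets_bed", "fastq1"):
            value = getattr(self, name)
            if value is not None and not Path(value).exists():
                raise PipelineError(f"config: {name} path {value!r} does not exist")
        if not 0 < self.hom_fraction < 1:
            raise PipelineError("config: hom_fraction must be in (0, 1)")
        if self.pad < 0 or self.spacer_len < 1 or self.min_depth < 0:
            raise PipelineError("config: thresholds out of range")


@dataclass
class RunInputs:
    """In-memory inputs resolved from a config or passed directly."""

    genome: dict[str, str]
    targets: list[GenomicInterval]
    pairs: list[ReadPair]

    @classmethod
    def from_config(cls, config: RunConfig) -> "RunInputs":
        config.validate()
        genome = read_genome_fasta(config.genome_fasta)
        targets = read_bed(config.targets_bed)
        pairs = read_fastq_pairs(config.fastq1, config.fastq2)
        return cls(genome=genome, targets=targets, pairs=pairs)


@dataclass
class TrBackmapResult:
    tr_reference: TRReference
    initial_calls: list[VariantCall]
    final_calls: list[VariantCall]  # restricted to the actual targets
    final_calls_all: list[VariantCall]  # including calls in the padding
    removed_calls: list[VariantCall]
    report: bm.BackmapReport
    enrichment: EnrichmentSummary
    stage_counts: dict[str, int] = field(default_factory=dict)


@dataclass
class WgResult:
    calls: list[VariantCall]  # restricted to targets
    all_calls: list[VariantCall]
    enrichment: EnrichmentSummary
    stage_counts: dict[str, int] = field(default_factory=dict)


def _lift_records_to_genome(
    records: Sequence[AlignmentRecord], tr_ref: TRReference
) -> list[AlignmentRecord]:
    """Re-express TR alignments in genome coordinates (for QC metrics).

    A record may hang a few bases into a spacer (a force-mapped boundary
    placement pays one mismatch per N base); spacers are shorter than two
    read lengths apart, so each record touches exactly one block and is
    clipped to its overlap with it.
    """
    from bisect import bisect_right
    from dataclasses import replace

    blocks = tr_ref.table.blocks
    tr_starts = [b.tr_start for b in blocks]
    out = []
    for rec in records:
        if not rec.mapped:
            continue
        i = bisect_right(tr_starts, rec.end - 1) - 1
        b = blocks[i]
        lo = max(rec.pos, b.tr_start)
        hi = min(rec.end, b.tr_end)
        if hi <= lo:
            continue  # placement entirely inside a spacer; nothing to lift
        out.append(
            replace(
                rec,
                ref_name=b.chrom,
                pos=b.genome_start + (lo - b.tr_start),
                seq=rec.seq[lo - rec.pos : hi - rec.pos],
                mate_ref=None,
                mate_pos=None,
            )
        )
    return out


def run_tr_backmap(
    config: RunConfig,
    inputs: RunInputs | None = None,
    write_artifacts: bool = True,
) -> TrBackmapResult:
    """The fast two-step mode: TR mapping, calling, then read-backmapping."""
    inputs = inputs or RunInputs.from_config(config)
    if not inputs.pairs:
        raise PipelineError("stage read_input: no reads supplied")
    out_dir = Path(config.out_dir) if (config.out_dir and write_artifacts) else None
    if out_dir:
        out_dir.mkdir(parents=True, exist_ok=True)
        (out_dir / "resolved_config.json").write_text(json.dumps(asdict(config), indent=1))
    counts: dict[str, int] = {"reads_in": sum(2 if p.seq2 else 1 for p in inputs.pairs)}

    # stage 1: reference construction
    try:
        merged = pad_and_merge(
            inputs.targets, config.pad, {c: len(s) for c, s in inputs.genome.items()}
        )
        read_len = max(len(p.seq1) for p in inputs.pairs)
        tr_ref = build_tr_reference(
            inputs.genome, merged, spacer_len=config.spacer_len,
            source_targets=inputs.targets, max_read_len=read_len,
        )
    except Exception as exc:
        raise PipelineError(f"stage build_reference: {exc}") from exc
    counts["tr_blocks"] = len(tr_ref.table.blocks)
    if out_dir:
        tr_ref.write_fasta(out_dir / "tr_reference.fasta")
        tr_ref.table.to_tsv(out_dir / "transform_table.tsv")

    # stage 2: TR mapping + dedup
    tr_aligner = Aligner(tr_ref.as_mapping())
    tr_records = remove_duplicates(
        tr_aligner.map_pairs(inputs.pairs, config.max_mismatches, config.insert_range)
    )
    mapped = [r for r in tr_records if r.mapped and not r.is_duplicate]
    counts["tr_reads_mapped"] = len(mapped)
    if out_dir:
        write_sam(tr_records, {tr_ref.name: len(tr_ref.sequence)}, out_dir / "tr.sam")

    # stage 3: initial calling on the TR
    pileups = build_pileups(mapped, tr_ref.as_mapping())
    initial = call_variants(pileups, config.thresholds(), stage=STAGE_INITIAL_TR)
    counts["initial_variants"] = len(initial)
    if out_dir:
        write_vcf(initial, {tr_ref.name: len(tr_ref.sequence)}, out_dir / "initial_tr.vcf")
    logger.info("initial TR calling: %d variants from %d mapped reads", len(initial), len(mapped))

    # stage 4: read-backmapping cleanup
    result = bm.run_backmap(
        tr_records,
        initial,
        tr_ref.table,
        inputs.genome,
        max_mismatches=config.max_mismatches,
        insert_range=config.insert_range,
        thresholds=config.thresholds(),
        include_hom=config.include_hom_in_backmap,
    )
    # final restriction to the actual targets: calls in the +/-pad fringe of a
    # greater TR are supported only by the fraction of reads that fit the
    # block and are not comparable with conventional whole-genome calling
    final_in_target = [
        c
        for c in result.final_calls
        if any(t.contains_point(c.ref_name, c.pos) for t in inputs.targets)
    ]
    counts["extracted_pairs"] = len(result.extracted_pairs)
    counts["final_variants_all"] = len(result.final_calls)
    counts["final_variants"] = len(final_in_target)
    counts["removed_variants"] = len(result.removed_calls)
    glens = {c: len(s) for c, s in inputs.genome.items()}
    if out_dir:
        write_fastq_pairs(
            result.extracted_pairs, out_dir / "extracted_1.fastq", out_dir / "extracted_2.fastq"
        )
        write_sam(result.wg_records, glens, out_dir / "backmap_wg.sam")
        write_vcf(final_in_target, glens, out_dir / "final.vcf")
        write_vcf(result.removed_calls, glens, out_dir / "removed.vcf",
                  filter_code=FILTER_BACKMAP_REMOVED)
        result.report.to_frame().to_csv(out_dir / "backmap_report.tsv", sep="\t", index=False)
        (out_dir / "backmap_report.json").write_text(json.dumps(result.report.summary(), indent=1))

    # stage 5: enrichment QC (on lifted TR alignments)
    lifted = _lift_records_to_genome(mapped, tr_ref)
    enrichment = summarize_enrichment(lifted, inputs.targets, glens, seed=config.seed)
    if out_dir:
        (out_dir / "enrichment.json").write_text(json.dumps(enrichment.as_dict(), indent=1))
        (out_dir / "stage_counts.json").write_text(json.dumps(counts, indent=1))
    return TrBackmapResult(
        tr_reference=tr_ref,
        initial_calls=initial,
        final_calls=final_in_target,
        final_calls_all=result.final_calls,
        removed_calls=result.removed_calls,
        report=result.report,
        enrichment=enrichment,
        stage_counts=counts,
    )


def run_wg(
    config: RunConfig,
    inputs: RunInputs | None = None,
    write_artifacts: bool = True,
) -> WgResult:
    """The conventional mode: map everything to the genome, call, restrict."""
    inputs = inputs or RunInputs.from_config(config)
    if not inputs.pairs:
        raise PipelineError("stage read_input: no reads supplied")
    out_dir = Path(config.out_dir) if (config.out_dir and write_artifacts) else None
    if out_dir:
        out_dir.mkdir(parents=True, exist_ok=True)
    counts: dict[str, int] = {"reads_in": sum(2 if p.seq2 else 1 for p in inputs.pairs)}

    aligner = Aligner(inputs.genome)
    records = remove_duplicates(
        aligner.map_pairs(inputs.pairs, config.max_mismatches, config.insert_range)
    )
    mapped = [r for r in records if r.mapped and not r.is_duplicate]
    counts["wg_reads_mapped"] = len(mapped)
    glens = {c: len(s) for c, s in inputs.genome.items()}
    if out_dir:
        write_sam(records, glens, out_dir / "wg.sam")

    pileups = build_pileups(mapped, inputs.genome)
    all_calls = call_variants(pileups, config.thresholds(), stage=STAGE_POST_BACKMAP)
    in_target = [
        c
        for c in all_calls
        if any(t.contains_point(c.ref_name, c.pos) for t in inputs.targets)
    ]
    counts["wg_variants"] = len(all_calls)
    counts["wg_variants_in_target"] = len(in_target)
    if out_dir:
        write_vcf(in_target, glens, out_dir / "wg_in_target.vcf")
        write_vcf(all_calls, glens, out_dir / "wg_all.vcf")
    enrichment = summarize_enrichment(mapped, inputs.targets, glens, seed=config.seed)
    if out_dir:
        (out_dir / "wg_enrichment.json").write_text(json.dumps(enrichment.as_dict(), indent=1))
        (out_dir / "wg_stage_counts.json").write_text(json.dumps(counts, indent=1))
    return WgResult(
        calls=in_target, all_calls=all_calls, enrichment=enrichment, stage_counts=counts
    )


def compare_modes(
    calls_tr_backmap: Sequence[VariantCall],
    calls_wg: Sequence[VariantCall],
    known_sites: set | None = None,
) -> dict:
    """Overlap and concordance between the two modes' genome-coordinate calls."""
    def keyset(calls: Sequence[VariantCall]) -> set:
        return {(c.ref_name, c.pos, a) for c in calls if c.is_variant for a in c.alts}

    sets = {"tr_backmap": keyset(calls_tr_backmap), "wg": keyset(calls_wg)}
    overlap = variant_set_overlap(sets, known_sites)
    conc = genotype_concordance(calls_tr_backmap, calls_wg)
    return {
        "n_tr_backmap": len(sets["tr_backmap"]),
        "n_wg": len(sets["wg"]),
        "overlap_fraction_min": overlap.pairwise_min[("tr_backmap", "wg")],
        "overlap_fraction_union": overlap.pairwise_union[("tr_backmap", "wg")],
        "genotype_concordance": conc.concordance_rate,
        "n_shared_sites": conc.overlap_count,
        "discordant_sites": conc.discordant_sites,
        "exclusive_known_unknown": overlap.known_split,
    }
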