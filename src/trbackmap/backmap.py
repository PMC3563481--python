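"""Read-backmapping: cleanup of force-mapped false positives.

Mapping against a concatenated target-region (TR) reference is fast, but a
read whose true locus is absent from the TR gets *force-mapped* onto its
closest homolog inside the TR, planting spurious heterozygous calls at
paralog divergence positions. The cleanup re-examines every candidate SNP:

1. extract every read covering a candidate SNP (plus its mate, mapped or
   not) — each read once, even when it covers several SNPs;
2. remap only those reads against the whole genome (WG) and remove
   duplicates, exactly as a conventional pipeline would;
3. keep, per SNP, only reads whose single best WG placement still covers
   the SNP — a read with an equally good placement anywhere else is
   discarded for every SNP;
4. re-type each SNP from the surviving reads with the same genotype rule
   used initially. SNPs that re-type as homozygous reference, become
   no-calls, or lose their depth are eliminated; the rest are retained
   (possibly with a corrected genotype) in genome coordinates.

A weaker screen — mapping just the SNP plus 25 flanking reference bases —
is kept as :func:`probe_backmap`; it flags suspect sites but cannot catch a
diverged paralog whose probe is still unique, which is why the read-level
method exists.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import pandas as pd

from .align import Aligner, AlignmentRecord, ReadPair
from .pileup import (
    NOCALL_LOW_DEPTH,
    STAGE_POST_BACKMAP,
    GenotypeThresholds,
    PileupColumn,
    VariantCall,
    call_genotype,
)
from .reference import TransformTable, TRReference
from .samio import pairs_from_records

logger = logging.getLogger(__name__)

VERDICT_RETAINED = "retained"
VERDICT_ELIMINATED = "eliminated"
VERDICT_CHANGED = "genotype_changed"

REASON_NO_READS = "no_reads"
REASON_NOT_RETYPED = "not_retyped"
REASON_LOW_DEPTH = "low_depth_after_backmap"
REASON_AMBIGUOUS = "ambiguous_after_backmap"
REASON_HOM_REFERENCE = "genotype_reverted_to_reference"


@dataclass
class BackmapOutcome:
    """Per-variant account of what backmapping did."""

    tr_pos: int
    chrom: str
    genome_pos: int
    initial_genotype: tuple[str, ...]
    verdict: str
    reason: str | None
    n_supporting_reads: int
    n_reads_lost_to_other_loci: int
    final_genotype: tuple[str, ...] | None


@dataclass
class BackmapReport:
    outcomes: list[BackmapOutcome] = field(default_factory=list)

    @property
    def n_initial(self) -> int:
        return len(self.outcomes)

    def count(self, verdict: str) -> int:
        return sum(1 for o in self.outcomes if o.verdict == verdict)

    @property
    def elimination_fraction(self) -> float:
        return self.count(VERDICT_ELIMINATED) / self.n_initial if self.n_initial else 0.0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "chrom": o.chrom,
                    "genome_pos": o.genome_pos,
                    "tr_pos": o.tr_pos,
                    "initial_genotype": "/".join(o.initial_genotype),
                    "verdict": o.verdict,
                    "reason": o.reason or "",
                    "n_supporting_reads": o.n_supporting_reads,
                    "n_reads_lost_to_other_loci": o.n_reads_lost_to_other_loci,
                    "final_genotype": "/".join(o.final_genotype) if o.final_genotype else "",
                }
                for o in self.outcomes
            ]
        )

    def summary(self) -> dict:
        return {
            "n_initial": self.n_initial,
            "n_retained": self.count(VERDICT_RETAINED),
            "n_eliminated": self.count(VERDICT_ELIMINATED),
            "n_genotype_changed": self.count(VERDICT_CHANGED),
            "elimination_fraction": self.elimination_fraction,
        }


def _qualifies(v: VariantCall, include_hom: bool) -> bool:
    if not v.is_variant:
        return False
    return v.zygosity == "het" or (include_hom and v.zygosity == "hom")


def extract_snp_supporting_reads(
    records: Sequence[AlignmentRecord],
    variants: Sequence[VariantCall],
    include_hom: bool = False,
) -> list[ReadPair]:
    """Collect every read pair covering a candidate SNP, each exactly once.

    By default only heterozygous calls trigger extraction (homozygous
    non-reference calls are carried through unchanged); ``include_hom``
    extends extraction to them. All reads observed at a SNP column qualify,
    whichever base they showed — re-typing needs the reference-supporting
    reads too. Mates ride along whether mapped or not. Output is ordered by
    read id.
    """
    wanted: set[str] = set()
    for v in variants:
        if not _qualifies(v, include_hom):
            continue
        ids = v.all_supporting()
        if not ids:
            logger.warning(
                "variant %s:%d has no supporting reads; cannot be re-typed", v.ref_name, v.pos
            )
            continue
        wanted.update(ids)
    by_id = pairs_from_records(records)
    missing = wanted - by_id.keys()
    if missing:
        raise KeyError(f"supporting reads absent from alignment records: {sorted(missing)[:5]}")
    return [by_id[rid] for rid in sorted(wanted)]


def backmap_reads(
    pairs: Sequence[ReadPair],
    whole_genome: Aligner | Mapping[str, str],
    max_mismatches: int,
    insert_range: tuple[int, int] = (50, 400),
) -> list[AlignmentRecord]:
    """Remap the extracted reads against the whole genome and deduplicate."""
    from .align import remove_duplicates

    aligner = whole_genome if isinstance(whole_genome, Aligner) else Aligner(whole_genome)
    return remove_duplicates(aligner.map_pairs(pairs, max_mismatches, insert_range))


def unique_over_snp_filter(
    backmapped: Sequence[AlignmentRecord],
    variant_sites: Mapping[object, tuple[str, int]],
) -> dict[object, list[AlignmentRecord]]:
    """Per variant, the reads that remain uniquely mapped over the SNP.

    A read survives for a variant iff its WG placement is its single best
    one (``n_best_hits == 1``), it is not a duplicate, and it still covers
    the variant's genome position. A read with any equal-best placement
    elsewhere is removed for every variant.
    """
    usable = [r for r in backmapped if r.mapped and not r.is_duplicate and r.n_best_hits == 1]
    out: dict[object, list[AlignmentRecord]] = {}
    for key, (chrom, gpos) in variant_sites.items():
        out[key] = [r for r in usable if r.covers(chrom, gpos)]
    return out


def _column_at(
    records: Sequence[AlignmentRecord], chrom: str, pos: int, ref_base: str
) -> PileupColumn:
    col = PileupColumn(chrom, pos, ref_base)
    for rec in records:
        base = rec.seq[pos - rec.pos]
        if base != "N":
            col.add(base, rec.strand, rec.read_id)
    return col


def retype_after_backmap(
    variants: Sequence[VariantCall],
    table: TransformTable,
    surviving: Mapping[object, list[AlignmentRecord]],
    genome: Mapping[str, str],
    thresholds: GenotypeThresholds | None = None,
    include_hom: bool = False,
) -> tuple[list[VariantCall], list[VariantCall], BackmapReport]:
    """Re-type every initial variant from its surviving reads.

    Returns ``(final_calls, removed_calls, report)``; both call lists are in
    genome coordinates with ``stage=post_backmap``. Variants that did not
    qualify for extraction (homozygous calls under the default policy) are
    lifted and retained unchanged.
    """
    th = thresholds or GenotypeThresholds()
    final: list[VariantCall] = []
    removed: list[VariantCall] = []
    report = BackmapReport()

    for key, v in enumerate(variants):
        chrom, gpos = table.tr_to_genome(v.pos)
        lifted = replace(v, ref_name=chrom, pos=gpos, stage=STAGE_POST_BACKMAP)
        n_support = len(v.all_supporting())

        if not _qualifies(v, include_hom):
            final.append(lifted)
            report.outcomes.append(
                BackmapOutcome(v.pos, chrom, gpos, v.gt_key(), VERDICT_RETAINED,
                               REASON_NOT_RETYPED, n_support, 0, v.gt_key())
            )
            continue
        if n_support == 0:
            lifted.reason = REASON_NO_READS
            removed.append(lifted)
            report.outcomes.append(
                BackmapOutcome(v.pos, chrom, gpos, v.gt_key(), VERDICT_ELIMINATED,
                               REASON_NO_READS, 0, 0, None)
            )
            continue

        recs = surviving.get(key, [])
        n_lost = n_support - len({r.read_id for r in recs})
        col = _column_at(recs, chrom, gpos, genome[chrom][gpos])
        recall = call_genotype(col, th, stage=STAGE_POST_BACKMAP)

        if recall.zygosity == "no_call":
            reason = REASON_LOW_DEPTH if recall.reason == NOCALL_LOW_DEPTH else REASON_AMBIGUOUS
            verdict, final_gt = VERDICT_ELIMINATED, None
        elif not recall.is_variant:
            reason, verdict, final_gt = REASON_HOM_REFERENCE, VERDICT_ELIMINATED, recall.gt_key()
        elif recall.gt_key() == v.gt_key():
            reason, verdict, final_gt = None, VERDICT_RETAINED, recall.gt_key()
        else:
            reason, verdict, final_gt = None, VERDICT_CHANGED, recall.gt_key()

        report.outcomes.append(
            BackmapOutcome(v.pos, chrom, gpos, v.gt_key(), verdict, reason,
                           n_support, max(n_lost, 0), final_gt)
        )
        if verdict == VERDICT_ELIMINATED:
            lifted.reason = reason
            removed.append(lifted)
        else:
            final.append(recall)
    return final, removed, report


@dataclass
class BackmapResult:
    """Everything the backmapping stage produced."""

    final_calls: list[VariantCall]
    removed_calls: list[VariantCall]
    report: BackmapReport
    extracted_pairs: list[ReadPair]
    wg_records: list[AlignmentRecord]


def run_backmap(
    tr_records: Sequence[AlignmentRecord],
    variants: Sequence[VariantCall],
    table: TransformTable,
    genome: Mapping[str, str],
    max_mismatches: int,
    insert_range: tuple[int, int] = (50, 400),
    thresholds: GenotypeThresholds | None = None,
    include_hom: bool = False,
    wg_aligner: Aligner | None = None,
) -> BackmapResult:
    """Run the full extract -> remap -> filter -> re-type chain."""
    pairs = extract_snp_supporting_reads(tr_records, variants, include_hom)
    aligner = wg_aligner or Aligner(genome)
    wg_records = backmap_reads(pairs, aligner, max_mismatches, insert_range)
    sites = {
        key: table.tr_to_genome(v.pos)
        for key, v in enumerate(variants)
        if _qualifies(v, include_hom)
    }
    surviving = unique_over_snp_filter(wg_records, sites)
    final, removed, report = retype_after_backmap(
        variants, table, surviving, genome, thresholds, include_hom
    )
    return BackmapResult(final, removed, report, pairs, wg_records)


@dataclass(frozen=True)
class ProbeResult:
    verdict: str  # "unique" | "multi_locus"
    n_best_hits: int
    clipped: bool


def probe_backmap(
    variant: VariantCall,
    tr_reference: TRReference,
    whole_genome: Aligner | Mapping[str, str],
    flank: int = 25,
    probe_max_mismatches: int = 3,
) -> ProbeResult:
    """The weaker SNP-probe uniqueness screen.

    Builds the ``2*flank + 1``-mer of TR reference sequence around the
    variant (clipped at block edges, flagged when clipped) and maps it to
    the whole genome. Multiple equal-best placements flag the site as
    suspect; the screen never eliminates a variant on its own.
    """
    table = tr_reference.table
    block = next(
        b for b in table.blocks if b.tr_start <= variant.pos < b.tr_end
    )
    lo = max(block.tr_start, variant.pos - flank)
    hi = min(block.tr_end, variant.pos + flank + 1)
    clipped = (hi - lo) < 2 * flank + 1
    probe = tr_reference.sequence[lo:hi]
    aligner = whole_genome if isinstance(whole_genome, Aligner) else Aligner(whole_genome)
    hits = aligner.best_hits(probe, probe_max_mismatches)
    n = len(hits)
    return ProbeResult("multi_locus" if n > 1 else "unique", max(n, 1), clipped)
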