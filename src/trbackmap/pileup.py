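"""Per-position, per-strand pileups and count-based genotype calling.

The caller is deliberately simple and mirrors a manual-review rule: a site
is homozygous for the majority base when that base carries **more than** a
fixed fraction of the reads (default 80%); otherwise it is heterozygous for
the two most frequent bases — provided the minor allele is seen at least
``min_minor_reads`` times and (by default) on both strands, and no third
allele reaches the minor-read threshold. Sites below the minimum depth
(default 8x, a common minimum detection threshold) are no-calls. Base
qualities play no role in the caller itself.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .align import AlignmentRecord

STAGE_INITIAL_TR = "initial_TR"
STAGE_POST_BACKMAP = "post_backmap"

NOCALL_LOW_DEPTH = "low_depth"
NOCALL_AMBIGUOUS = "ambiguous"


@dataclass
class PileupColumn:
    """Stranded base counts at one reference position."""

    ref_name: str
    pos: int
    ref_base: str
    # base -> [forward_count, reverse_count]
    counts: dict[str, list[int]] = field(default_factory=dict)
    # base -> read ids contributing that base (template names, may repeat
    # when both mates of a template overlap the position)
    supporting: dict[str, list[str]] = field(default_factory=dict)

    @property
    def depth(self) -> int:
        return sum(f + r for f, r in self.counts.values())

    def count(self, base: str) -> int:
        f, r = self.counts.get(base, (0, 0))
        return f + r

    def add(self, base: str, strand: str, read_id: str) -> None:
        fr = self.counts.setdefault(base, [0, 0])
        fr[0 if strand == "+" else 1] += 1
        self.supporting.setdefault(base, []).append(read_id)


@dataclass
class GenotypeThresholds:
    """Knobs of the count-based caller (defaults are the working values)."""

    min_depth: int = 8
    hom_fraction: float = 0.80
    min_minor_reads: int = 2
    require_both_strands: bool = True


@dataclass
class VariantCall:
    """A genotype decision at one site, with its supporting evidence."""

    ref_name: str
    pos: int
    ref_base: str
    genotype: tuple[str, ...]  # () for a no-call, 2 alleles otherwise
    zygosity: str  # "hom" | "het" | "no_call"
    depth: int
    allele_fractions: dict[str, float] = field(default_factory=dict)
    both_strand_support: bool = True
    stage: str = STAGE_INITIAL_TR
    supporting_reads: dict[str, list[str]] = field(default_factory=dict)
    reason: str | None = None  # reason code for no-calls / eliminations

    @property
    def is_variant(self) -> bool:
        return self.zygosity in ("hom", "het") and any(a != self.ref_base for a in self.genotype)

    @property
    def alts(self) -> tuple[str, ...]:
        return tuple(sorted({a for a in self.genotype if a != self.ref_base}))

    def gt_key(self) -> tuple[str, ...]:
        """Unordered genotype, for concordance comparisons."""
        return tuple(sorted(self.genotype))

    def all_supporting(self) -> list[str]:
        """Deduplicated ids of every read observed at the column."""
        seen: dict[str, None] = {}
        for ids in self.supporting_reads.values():
            for rid in ids:
                seen.setdefault(rid)
        return list(seen)


def build_pileups(
    records: Sequence[AlignmentRecord],
    reference: Mapping[str, str],
    reads: Mapping[str, str] | None = None,
) -> dict[tuple[str, int], PileupColumn]:
    """Accumulate stranded base counts from mapped, non-duplicate records.

    Records normally carry their (reference-oriented) sequence; for records
    loaded from a SAM without stored sequence, ``reads`` must supply it by
    read id, and a missing id is an error.
    """
    columns: dict[tuple[str, int], PileupColumn] = {}
    for rec in records:
        if not rec.mapped or rec.is_duplicate:
            continue
        seq = rec.seq
        if not seq:
            if reads is None or rec.read_id not in reads:
                raise KeyError(f"no sequence available for read {rec.read_id!r}")
            seq = reads[rec.read_id]
        ref_seq = reference[rec.ref_name]
        for i, base in enumerate(seq):
            if base == "N":
                continue
            pos = rec.pos + i
            key = (rec.ref_name, pos)
            col = columns.get(key)
            if col is None:
                col = columns[key] = PileupColumn(rec.ref_name, pos, ref_seq[pos])
            col.add(base, rec.strand, rec.read_id)
    return columns


def call_genotype(
    col: PileupColumn,
    thresholds: GenotypeThresholds | None = None,
    stage: str = STAGE_INITIAL_TR,
) -> VariantCall:
    """Apply the majority-fraction rule to one pileup column."""
    th = thresholds or GenotypeThresholds()
    depth = col.depth
    fractions = {b: col.count(b) / depth for b in col.counts} if depth else {}
    call = VariantCall(
        ref_name=col.ref_name,
        pos=col.pos,
        ref_base=col.ref_base,
        genotype=(),
        zygosity="no_call",
        depth=depth,
        allele_fractions=fractions,
        stage=stage,
        supporting_reads={b: list(ids) for b, ids in col.supporting.items()},
    )
    if depth < th.min_depth:
        call.reason = NOCALL_LOW_DEPTH
        return call
    ranked = sorted(col.counts, key=lambda b: (-col.count(b), b))
    top = ranked[0]
    if col.count(top) / depth > th.hom_fraction:
        call.genotype = (top, top)
        call.zygosity = "hom"
        call.both_strand_support = _both_strands(col, top)
        return call
    if len(ranked) < 2:  # single observed base can only fail hom when hom_fraction >= 1
        call.reason = NOCALL_AMBIGUOUS
        return call
    minor = ranked[1]
    third_count = col.count(ranked[2]) if len(ranked) > 2 else 0
    minor_f, minor_r = col.counts[minor]
    ok = col.count(minor) >= th.min_minor_reads and third_count < th.min_minor_reads
    if th.require_both_strands:
        ok = ok and minor_f > 0 and minor_r > 0
    if not ok:
        call.reason = NOCALL_AMBIGUOUS
        return call
    call.genotype = tuple(sorted((top, minor)))
    call.zygosity = "het"
    call.both_strand_support = all(_both_strands(col, a) for a in call.genotype)
    return call


def _both_strands(col: PileupColumn, base: str) -> bool:
    f, r = col.counts.get(base, (0, 0))
    return f > 0 and r > 0


def call_variants(
    pileups: Mapping[tuple[str, int], PileupColumn],
    thresholds: GenotypeThresholds | None = None,
    stage: str = STAGE_INITIAL_TR,
) -> list[VariantCall]:
    """Call genotypes at every covered column and keep non-reference sites.

    Spacer columns (reference base ``N``) are skipped; no-calls are dropped.
    Output order is deterministic (reference name, position).
    """
    out = []
    for key in sorted(pileups):
        col = pileups[key]
        if col.ref_base == "N":
            continue
        call = call_genotype(col, thresholds, stage=stage)
        if call.is_variant:
            out.append(call)
    return out
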