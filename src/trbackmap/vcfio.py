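"""VCF 4.x output/input for variant calls (single-sample).

Positions are 0-based internally and 1-based on disk, handled by pysam.
The calling stage travels in ``INFO/STAGE``; eliminated variants are kept
in a separate VCF with ``FILTER=backmap_removed`` plus a ``REASON`` code.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import pysam

from .pileup import VariantCall

FILTER_BACKMAP_REMOVED = "backmap_removed"

_HEADER_LINES = [
    '##INFO=<ID=STAGE,Number=1,Type=String,Description="Calling stage (initial_TR or post_backmap)">',
    '##INFO=<ID=REASON,Number=1,Type=String,Description="Reason code for a filtered or removed call">',
    '##INFO=<ID=DP,Number=1,Type=Integer,Description="Read depth at the site">',
    '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
    '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Read depth per allele (ref first)">',
    f'##FILTER=<ID={FILTER_BACKMAP_REMOVED},Description="Eliminated by read-backmapping re-typing">',
]


def write_vcf(
    calls: Sequence[VariantCall],
    contig_lengths: Mapping[str, int],
    path: str | Path,
    sample: str = "SAMPLE",
    filter_code: str | None = None,
) -> None:
    header = pysam.VariantHeader()
    for name, length in contig_lengths.items():
        header.contigs.add(name, length=length)
    for line in _HEADER_LINES:
        header.add_line(line)
    header.add_sample(sample)
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for call in sorted(calls, key=lambda c: (c.ref_name, c.pos)):
            alts = call.alts or ("*",)
            rec = out.new_record(
                contig=call.ref_name,
                start=call.pos,
                stop=call.pos + 1,
                alleles=(call.ref_base, *alts),
            )
            rec.info["STAGE"] = call.stage
            rec.info["DP"] = call.depth
            if call.reason:
                rec.info["REASON"] = call.reason
            if filter_code:
                rec.filter.add(filter_code)
            else:
                rec.filter.add("PASS")
            allele_index = {a: i for i, a in enumerate((call.ref_base, *alts))}
            gt = tuple(allele_index.get(a) for a in call.genotype) or (None, None)
            rec.samples[sample]["GT"] = gt
            ad = [len(call.supporting_reads.get(a, [])) for a in (call.ref_base, *alts)]
            rec.samples[sample]["AD"] = ad
            out.write(rec)


@dataclass(frozen=True)
class VcfRecord:
    chrom: str
    pos: int  # 0-based
    ref: str
    alts: tuple[str, ...]
    genotype: tuple[str, ...]  # allele strings, unordered-comparable via sorted()
    stage: str | None
    filter: tuple[str, ...]

    def gt_key(self) -> tuple[str, ...]:
        return tuple(sorted(self.genotype))


def read_vcf(path: str | Path) -> list[VcfRecord]:
    out = []
    with pysam.VariantFile(str(path)) as fh:
        for rec in fh:
            sample = rec.samples[next(iter(rec.samples))]
            alleles = rec.alleles
            gt = tuple(
                alleles[i] for i in (sample["GT"] or ()) if i is not None
            )
            out.append(
                VcfRecord(
                    chrom=rec.contig,
                    pos=rec.start,
                    ref=rec.ref,
                    alts=tuple(rec.alts or ()),
                    genotype=gt,
                    stage=rec.info.get("STAGE"),
                    filter=tuple(rec.filter.keys()),
                )
            )
    return out
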