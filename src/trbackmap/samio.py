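"""SAM and FASTQ interchange.

The builtin aligner speaks :class:`~trbackmap.align.AlignmentRecord`; these
helpers translate to and from standard formats so external aligners can be
plugged in. Mapped records carry the ``NM`` tag (mismatch count) and the
``NH`` tag (number of equal-best placements). When a foreign SAM lacks
``NH``, mapping quality 0 is interpreted as "not unique".
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .align import AlignmentRecord, ReadPair, revcomp

_DEFAULT_QUAL = 40  # flat Phred score used when no qualities are tracked


def write_sam(
    records: Sequence[AlignmentRecord],
    reference_lengths: Mapping[str, int],
    path: str | Path,
) -> None:
    """Write records as headered SAM with standard FLAG semantics."""
    names = list(reference_lengths)
    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": n, "LN": reference_lengths[n]} for n in names],
    }
    tid = {n: i for i, n in enumerate(names)}
    with pysam.AlignmentFile(str(path), "w", header=header) as fh:
        for rec in records:
            seg = pysam.AlignedSegment(fh.header)
            seg.query_name = rec.read_id
            seg.query_sequence = rec.seq if rec.seq else None
            flag = 0
            if rec.mate:
                flag |= 0x1 | (0x40 if rec.mate == 1 else 0x80)
                if rec.proper_pair:
                    flag |= 0x2
                if not rec.mate_mapped:
                    flag |= 0x8
            if not rec.mapped:
                flag |= 0x4
            if rec.strand == "-":
                flag |= 0x10
            if rec.is_duplicate:
                flag |= 0x400
            seg.flag = flag
            if rec.mapped:
                seg.reference_id = tid[rec.ref_name]
                seg.reference_start = rec.pos
                seg.mapping_quality = 0 if rec.n_best_hits > 1 else 60
                seg.cigarstring = f"{len(rec.seq)}M"
                seg.set_tag("NM", rec.mismatches)
                seg.set_tag("NH", rec.n_best_hits)
            else:
                seg.reference_id = -1
                seg.reference_start = -1
                seg.mapping_quality = 0
            if rec.mate and rec.mate_mapped and rec.mate_ref is not None:
                seg.next_reference_id = tid[rec.mate_ref]
                seg.next_reference_start = rec.mate_pos
            else:
                seg.next_reference_id = -1
                seg.next_reference_start = -1
            fh.write(seg)


def read_sam(path: str | Path) -> list[AlignmentRecord]:
    """Load a SAM file into alignment records (sequence kept as stored)."""
    out: list[AlignmentRecord] = []
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as fh:
        for seg in fh:
            mate = 0
            if seg.is_paired:
                mate = 1 if seg.is_read1 else 2
            mapped = not seg.is_unmapped
            if mapped and seg.has_tag("NH"):
                n_best = int(seg.get_tag("NH"))
            elif mapped:
                n_best = 2 if seg.mapping_quality == 0 else 1
            else:
                n_best = 0
            out.append(
                AlignmentRecord(
                    read_id=seg.query_name,
                    mate=mate,
                    ref_name=seg.reference_name if mapped else None,
                    pos=seg.reference_start if mapped else None,
                    strand="-" if seg.is_reverse else "+",
                    mismatches=int(seg.get_tag("NM")) if mapped and seg.has_tag("NM") else 0,
                    mapped=mapped,
                    seq=seg.query_sequence or "",
                    mate_ref=seg.next_reference_name if seg.is_paired and not seg.mate_is_unmapped else None,
                    mate_pos=seg.next_reference_start
                    if seg.is_paired and not seg.mate_is_unmapped and seg.next_reference_start >= 0
                    else None,
                    mate_mapped=seg.is_paired and not seg.mate_is_unmapped,
                    proper_pair=seg.is_proper_pair,
                    is_duplicate=seg.is_duplicate,
                    n_best_hits=n_best,
                )
            )
    return out


# --- FASTQ ---------------------------------------------------------------

def write_fastq_pairs(
    pairs: Iterable[ReadPair], path1: str | Path, path2: str | Path | None
) -> None:
    """Write mate-split FASTQ files (``/1`` ``/2`` identifiers, flat quality)."""
    recs1, recs2 = [], []
    for pair in pairs:
        recs1.append(_fastq_record(f"{pair.name}/1" if pair.seq2 is not None else pair.name, pair.seq1))
        if pair.seq2 is not None:
            recs2.append(_fastq_record(f"{pair.name}/2", pair.seq2))
    SeqIO.write(recs1, str(path1), "fastq")
    if path2 is not None:
        SeqIO.write(recs2, str(path2), "fastq")


def read_fastq_pairs(path1: str | Path, path2: str | Path | None = None) -> list[ReadPair]:
    """Read mate-split FASTQ files back into pairs (or single-end reads)."""
    def strip(name: str) -> str:
        return name[:-2] if name.endswith(("/1", "/2")) else name

    reads1 = [(strip(r.id), str(r.seq)) for r in SeqIO.parse(str(path1), "fastq")]
    if path2 is None:
        return [ReadPair(name, seq) for name, seq in reads1]
    reads2 = {strip(r.id): str(r.seq) for r in SeqIO.parse(str(path2), "fastq")}
    pairs = []
    for name, seq in reads1:
        if name not in reads2:
            raise ValueError(f"read {name!r} has no mate in {path2}")
        pairs.append(ReadPair(name, seq, reads2[name]))
    return pairs


def _fastq_record(name: str, seq: str) -> SeqRecord:
    rec = SeqRecord(Seq(seq), id=name, description="")
    rec.letter_annotations["phred_quality"] = [_DEFAULT_QUAL] * len(seq)
    return rec


def pairs_from_records(
    records: Sequence[AlignmentRecord],
) -> dict[str, ReadPair]:
    """Reconstruct original read pairs from alignment records.

    Minus-strand records store the reverse-complemented sequence, so the
    original read orientation is restored first.
    """
    seqs: dict[str, dict[int, str]] = {}
    for rec in records:
        original = revcomp(rec.seq) if rec.mapped and rec.strand == "-" else rec.seq
        seqs.setdefault(rec.read_id, {})[rec.mate] = original
    out = {}
    for name, mates in seqs.items():
        if 0 in mates:
            out[name] = ReadPair(name, mates[0])
        else:
            out[name] = ReadPair(name, mates.get(1, ""), mates.get(2))
    return out
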