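"""Concatenated target-region (TR) reference construction and liftover.

The TR reference is a single sequence made of the merged, padded capture
targets laid end to end, with a run of N bases (the *spacer*, default 50)
between consecutive blocks so that no read can align across a block
junction. A :class:`TransformTable` records, for every block, where it came
from in the genome; it provides exact bidirectional liftover between TR and
genome coordinates.
"""

from __future__ import annotations

import json
import logging
import re
from bisect import bisect_right
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .intervals import GenomicInterval

logger = logging.getLogger(__name__)


class SpacerPositionError(ValueError):
    """A TR coordinate fell inside an N-spacer.

    Alignments should never produce such a position: any read overlapping a
    spacer accumulates one mismatch per N base and is penalised out.
    """


@dataclass(frozen=True)
class Block:
    """One contiguous TR block and its genomic origin (plus strand)."""

    tr_start: int
    tr_end: int
    chrom: str
    genome_start: int

    def __len__(self) -> int:
        return self.tr_end - self.tr_start


@dataclass
class TransformTable:
    """Ordered TR-block to genome mapping with O(log n) lookup."""

    blocks: list[Block]
    spacer_len: int
    _tr_starts: list[int] = field(init=False, repr=False)
    _by_chrom: dict[str, list[Block]] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self._reindex()

    def _reindex(self) -> None:
        self._tr_starts = [b.tr_start for b in self.blocks]
        self._by_chrom = {}
        for b in self.blocks:
            self._by_chrom.setdefault(b.chrom, []).append(b)
        for blist in self._by_chrom.values():
            blist.sort(key=lambda b: b.genome_start)

    @property
    def tr_length(self) -> int:
        if not self.blocks:
            return 0
        return self.blocks[-1].tr_end

    def tr_to_genome(self, tr_pos: int) -> tuple[str, int]:
        """Lift a TR coordinate to ``(chrom, genome_pos)``.

        Raises :class:`SpacerPositionError` for positions inside a spacer and
        ``IndexError`` for positions outside the TR sequence.
        """
        if tr_pos < 0 or tr_pos >= self.tr_length:
            raise IndexError(f"TR position {tr_pos} outside [0, {self.tr_length})")
        i = bisect_right(self._tr_starts, tr_pos) - 1
        b = self.blocks[i]
        if tr_pos >= b.tr_end:
            raise SpacerPositionError(f"TR position {tr_pos} lies in a spacer")
        return b.chrom, b.genome_start + (tr_pos - b.tr_start)

    def genome_to_tr(self, chrom: str, genome_pos: int) -> int | None:
        """Inverse liftover; returns ``None`` when the position is off-target.

        Raises ``KeyError`` for a chromosome the table has never seen.
        """
        if chrom not in self._by_chrom:
            raise KeyError(f"unknown chromosome {chrom!r}")
        blist = self._by_chrom[chrom]
        starts = [b.genome_start for b in blist]
        i = bisect_right(starts, genome_pos) - 1
        if i < 0:
            return None
        b = blist[i]
        if genome_pos >= b.genome_start + len(b):
            return None
        return b.tr_start + (genome_pos - b.genome_start)

    # --- serialization -------------------------------------------------
    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("tr_start\ttr_end\tchrom\tgenome_start\n")
            for b in self.blocks:
                fh.write(f"{b.tr_start}\t{b.tr_end}\t{b.chrom}\t{b.genome_start}\n")
        Path(str(path) + ".json").write_text(
            json.dumps({"spacer_len": self.spacer_len, "n_blocks": len(self.blocks)}, indent=1)
        )

    @classmethod
    def from_tsv(cls, path: str | Path) -> "TransformTable":
        sidecar = json.loads(Path(str(path) + ".json").read_text())
        blocks = []
        with open(path) as fh:
            next(fh)  # header
            for line in fh:
                ts, te, chrom, gs = line.rstrip("\n").split("\t")
                blocks.append(Block(int(ts), int(te), chrom, int(gs)))
        return cls(blocks=blocks, spacer_len=int(sidecar["spacer_len"]))


@dataclass
class TRReference:
    """The concatenated target-region reference sequence plus its liftover table."""

    name: str
    sequence: str
    table: TransformTable
    source_targets: list[GenomicInterval]

    def as_mapping(self) -> dict[str, str]:
        """View usable wherever a name->sequence reference mapping is expected."""
        return {self.name: self.sequence}

    def write_fasta(self, path: str | Path) -> None:
        rec = SeqRecord(Seq(self.sequence), id=self.name, description="")
        SeqIO.write([rec], str(path), "fasta")


def build_tr_reference(
    genome: Mapping[str, str],
    merged: Sequence[GenomicInterval],
    spacer_len: int = 50,
    name: str = "TR",
    source_targets: Sequence[GenomicInterval] | None = None,
    max_read_len: int | None = None,
) -> TRReference:
    """Concatenate merged target intervals into one reference with N spacers.

    ``merged`` must be sorted and non-overlapping (the ``pad_and_merge``
    contract). Blocks appear chromosome-major in genome order. When the
    caller states the intended read length and it exceeds ``spacer_len``, a
    warning is logged: reads longer than the spacer could bridge blocks.
    """
    if max_read_len is not None and max_read_len > spacer_len:
        logger.warning(
            "read length %d exceeds spacer length %d; reads may align across block junctions",
            max_read_len,
            spacer_len,
        )
    parts: list[str] = []
    blocks: list[Block] = []
    cursor = 0
    for i, iv in enumerate(merged):
        if iv.chrom not in genome:
            raise ValueError(f"interval {iv.chrom}:{iv.start}-{iv.end}: chromosome not in genome")
        chrom_seq = genome[iv.chrom]
        if iv.end > len(chrom_seq):
            raise ValueError(
                f"interval {iv.chrom}:{iv.start}-{iv.end} exceeds chromosome length {len(chrom_seq)}"
            )
        if i > 0:
            parts.append("N" * spacer_len)
            cursor += spacer_len
        parts.append(chrom_seq[iv.start : iv.end])
        blocks.append(Block(cursor, cursor + len(iv), iv.chrom, iv.start))
        cursor += len(iv)
    return TRReference(
        name=name,
        sequence="".join(parts),
        table=TransformTable(blocks=blocks, spacer_len=spacer_len),
        source_targets=list(source_targets if source_targets is not None else merged),
    )


# --- genome FASTA I/O ----------------------------------------------------

def read_genome_fasta(path: str | Path) -> dict[str, str]:
    """Load a (small) genome FASTA into an ordered name->sequence dict."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_genome_fasta(genome: Mapping[str, str], path: str | Path) -> None:
    recs = [SeqRecord(Seq(s), id=name, description="") for name, s in genome.items()]
    SeqIO.write(recs, str(path), "fasta")


# --- CCDS ingest ---------------------------------------------------------

_CCDS_LOC = re.compile(r"(\d+)-(\d+)")


def ccds_to_bed(
    path: str | Path,
    public_only: bool = True,
) -> list[GenomicInterval]:
    """Convert a CCDS flat file into per-exon BED intervals.

    The CCDS release format is tab-separated with a header line starting
    ``#chromosome``; the ``cds_locations`` column holds a bracketed list of
    inclusive exon spans (``[100-199, 300-349]``) which are emitted one
    interval per exon in 0-based half-open convention. Records whose
    ``ccds_status`` is not ``Public`` are dropped under the default filter;
    duplicate intervals (the same exon shared by several CCDS isoforms) are
    retained — merging happens later in ``pad_and_merge``. Records with a
    malformed or absent location list are skipped with a logged count.
    """
    out: list[GenomicInterval] = []
    n_skipped = 0
    with open(path) as fh:
        header = fh.readline().lstrip("#").rstrip("\n").split("\t")
        try:
            i_chrom = header.index("chromosome")
            i_status = header.index("ccds_status")
            i_loc = header.index("cds_locations")
        except ValueError as exc:
            raise ValueError("not a CCDS flat file: missing expected columns") from exc
        for line in fh:
            fields = line.rstrip("\n").split("\t")
            if len(fields) <= max(i_chrom, i_status, i_loc):
                n_skipped += 1
                continue
            status = fields[i_status].strip()
            if public_only and status != "Public":
                continue
            loc = fields[i_loc].strip()
            if not loc.startswith("[") or not loc.endswith("]"):
                n_skipped += 1
                continue
            spans = _CCDS_LOC.findall(loc)
            if not spans:
                n_skipped += 1
                continue
            chrom = fields[i_chrom]
            for lo, hi in spans:
                # CCDS spans are inclusive on both ends
                out.append(GenomicInterval(chrom, int(lo), int(hi) + 1))
    if n_skipped:
        logger.warning("ccds_to_bed: skipped %d malformed/locationless records", n_skipped)
    return out
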