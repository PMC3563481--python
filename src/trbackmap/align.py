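"""Deterministic, exhaustive k-mismatch ungapped read alignment.

This is a desk-scale aligner with an exact contract: for a read and a
mismatch budget *k* it reports **every** ungapped placement, on either
strand, achieving the minimum mismatch count, provided that minimum is at
most *k*. A read base aligned against a reference ``N`` always counts as a
mismatch, which is what keeps reads off the N-spacers of a concatenated
target-region reference.

The search is seed-and-filter with a pigeonhole guarantee: the read is
tiled with at least ``k+1`` disjoint exact-match windows, so any placement
with at most ``k`` mismatches must match one window exactly and is found by
index lookup. When a read is too short to carry ``k+1`` usable windows the
aligner falls back to scanning every offset. Either way the hit set equals
the brute-force answer.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")
_N_BYTE = ord("N")
_MIN_SEED = 4


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class ReadPair:
    """A sequenced fragment: mate 1, and mate 2 (``None`` for single-end)."""

    name: str
    seq1: str
    seq2: str | None = None


@dataclass
class AlignmentRecord:
    """One read placement (or an unmapped stub keeping the mate link)."""

    read_id: str
    mate: int = 0  # 0 = single-end, else 1 or 2
    ref_name: str | None = None
    pos: int | None = None  # 0-based leftmost
    strand: str = "+"
    mismatches: int = 0
    mapped: bool = False
    seq: str = ""  # stored in reference orientation
    mate_ref: str | None = None
    mate_pos: int | None = None
    mate_mapped: bool = False
    proper_pair: bool = False
    is_duplicate: bool = False
    n_best_hits: int = 0

    @property
    def end(self) -> int:
        assert self.pos is not None
        return self.pos + len(self.seq)

    def covers(self, ref_name: str, pos: int) -> bool:
        return (
            self.mapped
            and self.ref_name == ref_name
            and self.pos is not None
            and self.pos <= pos < self.pos + len(self.seq)
        )


@dataclass(frozen=True)
class _Hit:
    ref: str
    pos: int
    strand: str
    mismatches: int


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)


class Aligner:
    """Exact all-best-hits aligner over a small name->sequence reference."""

    def __init__(self, reference: Mapping[str, str], seed_len: int = 12):
        if seed_len < 1:
            raise ValueError("seed_len must be positive")
        self.seed_len = seed_len
        self.ref_seqs = {name: seq.upper() for name, seq in reference.items()}
        self.ref_arrays = {name: _encode(seq) for name, seq in self.ref_seqs.items()}
        self._indexes: dict[int, dict[str, list[tuple[str, int]]]] = {}

    # --- index ----------------------------------------------------------
    def _index_for(self, eff: int) -> dict[str, list[tuple[str, int]]]:
        idx = self._indexes.get(eff)
        if idx is None:
            idx = {}
            for name, seq in self.ref_seqs.items():
                for i in range(len(seq) - eff + 1):
                    idx.setdefault(seq[i : i + eff], []).append((name, i))
            self._indexes[eff] = idx
        return idx

    # --- core search ----------------------------------------------------
    def _mismatches(self, ref: str, pos: int, sarr: np.ndarray) -> int:
        window = self.ref_arrays[ref][pos : pos + sarr.size]
        return int(np.count_nonzero((window != sarr) | (window == _N_BYTE)))

    def _scan_all_offsets(self, s: str, strand: str, k: int) -> list[_Hit]:
        sarr = _encode(s)
        hits = []
        for name, arr in self.ref_arrays.items():
            for pos in range(len(arr) - sarr.size + 1):
                m = self._mismatches(name, pos, sarr)
                if m <= k:
                    hits.append(_Hit(name, pos, strand, m))
        return hits

    def _hits_one_strand(self, s: str, strand: str, k: int) -> list[_Hit]:
        eff = min(self.seed_len, len(s) // (k + 1))
        if eff < _MIN_SEED:
            return self._scan_all_offsets(s, strand, k)
        idx = self._index_for(eff)
        sarr = _encode(s)
        seen: set[tuple[str, int]] = set()
        hits: list[_Hit] = []
        n_windows = len(s) // eff
        for w in range(n_windows):
            off = w * eff
            for name, hit_pos in idx.get(s[off : off + eff], ()):
                pos = hit_pos - off
                if pos < 0 or pos + len(s) > len(self.ref_seqs[name]):
                    continue
                key = (name, pos)
                if key in seen:
                    continue
                seen.add(key)
                m = self._mismatches(name, pos, sarr)
                if m <= k:
                    hits.append(_Hit(name, pos, strand, m))
        return hits

    def all_hits(self, read: str, max_mismatches: int) -> list[_Hit]:
        """Every placement with mismatches <= budget, both strands, sorted."""
        if not read:
            raise ValueError("empty read")
        read = read.upper()
        hits = self._hits_one_strand(read, "+", max_mismatches)
        hits += self._hits_one_strand(revcomp(read), "-", max_mismatches)
        hits.sort(key=lambda h: (h.ref, h.pos, h.strand))
        return hits

    def best_hits(self, read: str, max_mismatches: int) -> list[_Hit]:
        """All equal-best placements (minimum mismatch count), sorted."""
        hits = self.all_hits(read, max_mismatches)
        if not hits:
            return []
        best = min(h.mismatches for h in hits)
        return [h for h in hits if h.mismatches == best]

    # --- public record-producing API ------------------------------------
    def map_read(
        self, read: str, max_mismatches: int, read_id: str = "read", mate: int = 0
    ) -> list[AlignmentRecord]:
        """All equal-best placements of one read as alignment records."""
        best = self.best_hits(read, max_mismatches)
        records = []
        for h in best:
            records.append(
                AlignmentRecord(
                    read_id=read_id,
                    mate=mate,
                    ref_name=h.ref,
                    pos=h.pos,
                    strand=h.strand,
                    mismatches=h.mismatches,
                    mapped=True,
                    seq=read.upper() if h.strand == "+" else revcomp(read.upper()),
                    n_best_hits=len(best),
                )
            )
        return records

    def map_pairs(
        self,
        pairs: Sequence[ReadPair],
        max_mismatches: int,
        insert_range: tuple[int, int] = (50, 400),
    ) -> list[AlignmentRecord]:
        """Map read pairs, preferring properly paired equal-best placements.

        Each mate is first reduced to its equal-best placement set. If some
        combination of those placements forms a proper FR pair (same
        reference, opposite strands, plus-strand mate leftmost, insert
        within ``insert_range``) the lexicographically first such
        combination with minimal total mismatches is reported; otherwise
        each mate falls back to its first equal-best placement with the
        pairing flag cleared. Mate placement never changes a read's own
        ``n_best_hits``.
        """
        out: list[AlignmentRecord] = []
        for pair in pairs:
            if pair.seq2 is None:
                recs = self.map_read(pair.seq1, max_mismatches, pair.name, mate=0)
                out.append(recs[0] if recs else _unmapped(pair.name, 0, pair.seq1))
                continue
            best1 = self.best_hits(pair.seq1, max_mismatches)
            best2 = self.best_hits(pair.seq2, max_mismatches)
            chosen: tuple[_Hit, _Hit] | None = None
            proper = False
            if best1 and best2:
                candidates = []
                for a in best1:
                    for b in best2:
                        if a.ref != b.ref or a.strand == b.strand:
                            continue
                        fwd, rev = (a, b) if a.strand == "+" else (b, a)
                        fwd_len = len(pair.seq1) if fwd is a else len(pair.seq2)
                        rev_len = len(pair.seq2) if rev is b else len(pair.seq1)
                        if rev.pos + rev_len < fwd.pos + fwd_len or rev.pos < fwd.pos:
                            continue
                        insert = rev.pos + rev_len - fwd.pos
                        if insert_range[0] <= insert <= insert_range[1]:
                            candidates.append((a.mismatches + b.mismatches, a, b))
                if candidates:
                    candidates.sort(key=lambda t: (t[0], t[1].ref, t[1].pos, t[1].strand, t[2].pos))
                    chosen = (candidates[0][1], candidates[0][2])
                    proper = True
            if chosen is None:
                h1 = best1[0] if best1 else None
                h2 = best2[0] if best2 else None
            else:
                h1, h2 = chosen
            r1 = _hit_to_record(pair.name, 1, pair.seq1, h1, len(best1))
            r2 = _hit_to_record(pair.name, 2, pair.seq2, h2, len(best2))
            r1.proper_pair = r2.proper_pair = proper
            _cross_link(r1, r2)
            out.extend([r1, r2])
        return out


def _unmapped(read_id: str, mate: int, seq: str) -> AlignmentRecord:
    return AlignmentRecord(read_id=read_id, mate=mate, mapped=False, seq=seq.upper())


def _hit_to_record(
    read_id: str, mate: int, seq: str, hit: _Hit | None, n_best: int
) -> AlignmentRecord:
    if hit is None:
        return _unmapped(read_id, mate, seq)
    return AlignmentRecord(
        read_id=read_id,
        mate=mate,
        ref_name=hit.ref,
        pos=hit.pos,
        strand=hit.strand,
        mismatches=hit.mismatches,
        mapped=True,
        seq=seq.upper() if hit.strand == "+" else revcomp(seq.upper()),
        n_best_hits=n_best,
    )


def _cross_link(r1: AlignmentRecord, r2: AlignmentRecord) -> None:
    r1.mate_ref, r1.mate_pos, r1.mate_mapped = r2.ref_name, r2.pos, r2.mapped
    r2.mate_ref, r2.mate_pos, r2.mate_mapped = r1.ref_name, r1.pos, r1.mapped


def remove_duplicates(records: Sequence[AlignmentRecord]) -> list[AlignmentRecord]:
    """Flag PCR/optical duplicates among mapped records.

    Records sharing ``(ref, strand, pos, mate_ref, mate_pos)`` are one
    duplicate group; the record with fewest mismatches survives (ties broken
    by read id, then mate number) and all others are flagged
    ``is_duplicate`` for downstream exclusion. Unmapped records pass
    through untouched. The input is not mutated.
    """
    groups: dict[tuple, list[AlignmentRecord]] = {}
    out: list[AlignmentRecord] = []
    for rec in records:
        rec = replace(rec)
        out.append(rec)
        if not rec.mapped:
            continue
        key = (rec.ref_name, rec.strand, rec.pos, rec.mate_ref, rec.mate_pos)
        groups.setdefault(key, []).append(rec)
    for members in groups.values():
        members.sort(key=lambda r: (r.mismatches, r.read_id, r.mate))
        for loser in members[1:]:
            loser.is_duplicate = True
    return out
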