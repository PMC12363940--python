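"""Read trimming and exact end-to-end alignment for 3'-end tags.

A raw PAS-seq read carries, 3' to 5' on the sequenced strand: a 6-nt
ligated linker, the poly(A) tail, and the genomic insert whose last base
is the cleavage/polyadenylation position.  Trimming strips the linker
(tolerating one mismatch) and then the maximal terminal A-run; reads with
no detectable tail or an insert below the length floor failed trimming and
are rejected.  Trimmed inserts are aligned full-length, exactly and
uniquely, to the toy genome; users with real data supply pre-aligned BED
instead.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

from .simulate import revcomp

VALID_BASES = frozenset("ACGTN")


@dataclass
class TrimmedRead:
    read_id: str
    sequence: str
    tail_len: int
    linker_found: bool


@dataclass
class AlignedTag:
    read_id: str
    contig: str
    start: int
    end: int  # 0-based half-open
    strand: str

    @property
    def three_prime(self) -> int:
        """Last transcribed base: end-1 on '+', start on '-'."""
        return self.end - 1 if self.strand == "+" else self.start


@dataclass
class Rejection:
    read_id: str
    reason: str  # no_tail / short_insert / multi / no_hit


def _hamming_le1(a: str, b: str) -> bool:
    mism = 0
    for x, y in zip(a, b):
        if x != y:
            mism += 1
            if mism > 1:
                return False
    return True


def trim_read(
    read_id: str, sequence: str, linker: str = "CTGTAG", min_tail: int = 3,
    min_insert: int = 20,
) -> TrimmedRead | Rejection:
    """Strip the terminal linker (<=1 mismatch) then the maximal A-run.

    Rejects reads whose A-run is shorter than ``min_tail`` ("failed
    trimming") or whose remaining insert is shorter than ``min_insert``.
    """
    if not sequence:
        raise ValueError("empty read")
    if set(sequence) - VALID_BASES:
        raise ValueError(f"non-ACGTN characters in read {read_id}")
    if len(linker) != 6:
        raise ValueError("linker must be 6 bases")

    seq = sequence
    linker_found = False
    if len(seq) >= 6 and _hamming_le1(seq[-6:], linker):
        seq = seq[:-6]
        linker_found = True

    tail = 0
    while tail < len(seq) and seq[len(seq) - 1 - tail] == "A":
        tail += 1
    if tail < min_tail:
        return Rejection(read_id, "no_tail")
    insert = seq[: len(seq) - tail]
    if len(insert) < min_insert:
        return Rejection(read_id, "short_insert")
    return TrimmedRead(read_id, insert, tail, linker_found)


def _find_all(haystack: str, needle: str, limit: int = 2) -> list[int]:
    hits, pos = [], haystack.find(needle)
    while pos != -1 and len(hits) < limit:
        hits.append(pos)
        pos = haystack.find(needle, pos + 1)
    return hits


def align_exact(
    tr: TrimmedRead, contigs: dict[str, str]
) -> AlignedTag | Rejection:
    """Full-length exact alignment of the insert or its reverse complement.

    Requires a unique best hit across both strands of all contigs;
    multi-mappers and no-hits are returned as rejections with a reason.
    """
    if not contigs:
        raise ValueError("empty genome")
    insert = tr.sequence
    rc = revcomp(insert)
    hits: list[tuple[str, int, str]] = []
    for name, seq in contigs.items():
        for pos in _find_all(seq, insert):
            hits.append((name, pos, "+"))
            if len(hits) > 1:
                return Rejection(tr.read_id, "multi")
        for pos in _find_all(seq, rc):
            hits.append((name, pos, "-"))
            if len(hits) > 1:
                return Rejection(tr.read_id, "multi")
    if not hits:
        return Rejection(tr.read_id, "no_hit")
    name, pos, strand = hits[0]
    return AlignedTag(tr.read_id, name, pos, pos + len(insert), strand)


def process_reads(
    reads: Iterable[tuple[str, str]],
    contigs: dict[str, str],
    linker: str = "CTGTAG",
    min_tail: int = 3,
    min_insert: int = 20,
) -> tuple[list[AlignedTag], list[Rejection]]:
    """Trim + align a read stream; returns (aligned tags, rejections)."""
    tags, rejects = [], []
    for rid, seq in reads:
        tr = trim_read(rid, seq, linker=linker, min_tail=min_tail, min_insert=min_insert)
        if isinstance(tr, Rejection):
            rejects.append(tr)
            continue
        al = align_exact(tr, contigs)
        if isinstance(al, Rejection):
            rejects.append(al)
        else:
            tags.append(al)
    return tags, rejects
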