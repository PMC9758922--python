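"""Telomere-tract screening and input read selection.

A read end is the sequence distal to the last (or proximal to the first)
GATC site.  An end is telomeric when it contains the 24-base unit
``(TTAGGG)x4`` — four consecutive perfect telomere repeats — at least twice,
counting non-overlapping occurrences on one strand (``CCCTAA`` mirrors the
opposite strand).  Reads are additionally screened against 1-copy anchor
probes; reads passing both screens are "mapped telomere reads" that identify
their telomere of origin.  Only reads of at least ``min_read_length`` bases
(default 40,000) enter the assembly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .alignment import AlignmentParams, LocalAlignment, align_local
from .seqio import Interval, SequenceRecord

__all__ = [
    "TELOMERE_MOTIF",
    "TELOMERE_MOTIF_RC",
    "ReadEnd",
    "TelomereCall",
    "ReadSelection",
    "extract_read_ends",
    "call_telomere",
    "probe_hits",
    "select_reads",
]

log = logging.getLogger(__name__)

TELOMERE_MOTIF = "TTAGGG"
TELOMERE_MOTIF_RC = "CCCTAA"
_SITE = "GATC"


@dataclass(frozen=True)
class ReadEnd:
    """One GATC-delimited read extremity (span in read coordinates)."""

    read_id: str
    side: str  # 'left' | 'right'
    span: Interval | None  # None encodes an empty end
    sequence: str


@dataclass(frozen=True)
class TelomereCall:
    read_id: str
    side: str
    is_telomeric: bool
    tract_iv: Interval | None = None  # read coordinates
    motif_strand: str | None = None  # TTAGGG or CCCTAA


@dataclass
class ReadSelection:
    telomeric: set[str] = field(default_factory=set)
    subtelomeric: set[str] = field(default_factory=set)
    mapped_telomere: set[str] = field(default_factory=set)
    probe_hits: dict[str, list[LocalAlignment]] = field(default_factory=dict)
    calls: dict[str, tuple[TelomereCall, TelomereCall]] = field(default_factory=dict)

    @property
    def selected(self) -> set[str]:
        return self.telomeric | self.subtelomeric


def extract_read_ends(read: SequenceRecord) -> tuple[ReadEnd, ReadEnd]:
    """(left, right) ends delimited by the first/last GATC site.

    If the read contains no GATC, both ends equal the whole read.
    """
    seq = read.sequence
    first = seq.find(_SITE)
    if first == -1:
        whole = Interval(0, len(seq)) if seq else None
        left = ReadEnd(read.id, "left", whole, seq)
        right = ReadEnd(read.id, "right", whole, seq)
        return left, right
    last = seq.rfind(_SITE)
    left_iv = Interval(0, first) if first > 0 else None
    right_start = last + len(_SITE)
    right_iv = Interval(right_start, len(seq)) if right_start < len(seq) else None
    return (
        ReadEnd(read.id, "left", left_iv, seq[:first]),
        ReadEnd(read.id, "right", right_iv, seq[right_start:]),
    )


def _count_runs(seq: str, pattern: str) -> tuple[int, int, int]:
    """Non-overlapping occurrences of ``pattern``; (count, first_start, last_end)."""
    count = 0
    first = -1
    last = -1
    pos = seq.find(pattern)
    while pos != -1:
        count += 1
        if first == -1:
            first = pos
        last = pos + len(pattern)
        pos = seq.find(pattern, last)
    return count, first, last


def call_telomere(end: ReadEnd, min_unit_run: int = 4,
                  min_occurrences: int = 2) -> TelomereCall:
    """Screen one read end for a terminal telomere tract.

    Counts non-overlapping matches of the perfect ``min_unit_run``-unit
    repeat (24 bases for the default of 4 units); both occurrences must lie
    on the same strand.  A pure run of >= 48 bases therefore passes.
    """
    if min_unit_run < 1 or min_occurrences < 1:
        raise ValueError("parameters must be >= 1")
    best = None
    for motif in (TELOMERE_MOTIF, TELOMERE_MOTIF_RC):
        pattern = motif * min_unit_run
        count, first, last = _count_runs(end.sequence, pattern)
        if count >= min_occurrences and (best is None or count > best[0]):
            best = (count, motif, first, last)
    if best is None or end.span is None:
        return TelomereCall(end.read_id, end.side, False)
    _, motif, first, last = best
    tract = Interval(end.span.start + first, end.span.start + last)
    return TelomereCall(end.read_id, end.side, True, tract, motif)


def probe_hits(read: SequenceRecord, probes: list[SequenceRecord],
               params: AlignmentParams, min_probe_identity: float,
               min_probe_cover: float) -> list[LocalAlignment]:
    """Qualifying anchor-probe alignments on one read."""
    hits = []
    for probe in probes:
        for aln in align_local(probe, read, params):
            if (aln.percent_identity >= min_probe_identity
                    and len(aln.query_iv) >= min_probe_cover * len(probe.sequence)):
                hits.append(aln)
                break  # one qualifying hit per probe suffices
    return hits


def select_reads(reads: list[SequenceRecord], one_copy_probes: list[SequenceRecord],
                 min_read_length: int = 40_000,
                 min_probe_identity: float = 85.0,
                 min_probe_cover: float = 0.5,
                 min_unit_run: int = 4, min_occurrences: int = 2,
                 params: AlignmentParams | None = None) -> ReadSelection:
    """Classify reads as telomeric / subtelomeric / mapped-telomere.

    ``mapped_telomere`` is the intersection of the two screens; every
    selected read has length >= ``min_read_length`` (boundary inclusive).
    """
    if not one_copy_probes:
        raise ValueError("probe set must be non-empty")
    if params is None:
        params = AlignmentParams(respect_mask=False)
    sel = ReadSelection()
    for read in sorted(reads, key=lambda r: r.id):
        if len(read.sequence) < min_read_length:
            continue
        left, right = extract_read_ends(read)
        cl = call_telomere(left, min_unit_run, min_occurrences)
        cr = call_telomere(right, min_unit_run, min_occurrences)
        sel.calls[read.id] = (cl, cr)
        if cl.is_telomeric or cr.is_telomeric:
            sel.telomeric.add(read.id)
        hits = probe_hits(read, one_copy_probes, params,
                          min_probe_identity, min_probe_cover)
        if hits:
            sel.subtelomeric.add(read.id)
            sel.probe_hits[read.id] = hits
    sel.mapped_telomere = sel.telomeric & sel.subtelomeric
    if not sel.selected:
        log.warning("telomere/probe screen selected no reads")
    return sel
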