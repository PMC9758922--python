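"""Detect and repair contig misassemblies against the cognate nanopore read.

A placed contig's colinear chain is scanned: wherever the nanopore-read gap
between consecutive chain alignments differs from the contig gap by more
than ``threshold_bp`` (strictly greater; 100 bp default), a discrepancy is
emitted.  Its breakpoints are localised by re-aligning the 1 kb contig
borders in unmasked mode, then classified:

* ``tandem_repeat`` — the contig's gap sequence matches multiple tiling
  positions of the read gap near-equally well, or the read gap segment is
  itself periodic: a collapsed tandem-repeat array.  The whole collapsed
  region is removed from the contig and the read's full-length array is
  patched in, so the nanopore read defines the total TR length.
* ``deletion`` — unique sequence missing from the contig; the contig is
  split at the refined coordinates and the read segment fills the gap.
  Contig expansions (read gap shorter) use the same split-and-patch
  mechanism, keeping the conservation invariant sign-agnostic.

Pieces are always verbatim substrings of the input contig; only nanopore
patches introduce read-derived sequence.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

from .alignment import AlignmentParams, align_local, longest_contiguous_segment
from .contig_mapping import ContigPlacement
from .seqio import Interval, SequenceRecord

__all__ = [
    "Discrepancy",
    "CorrectionEvent",
    "Segment",
    "CorrectedContig",
    "detect_discrepancies",
    "localize_breakpoints",
    "classify_discrepancy",
    "apply_correction",
    "correct_placement",
    "check_conservation",
]

log = logging.getLogger(__name__)

DISCREPANCY_THRESHOLD_BP = 100
BORDER_FLANK_BP = 1000
BORDER_MIN_IDENTITY = 75.0


@dataclass
class Discrepancy:
    """One inter-alignment length discrepancy (coordinates on the oriented
    contig and oriented read; gap bounds may be degenerate/empty)."""

    contig_id: str
    read_id: str
    contig_gap: tuple[int, int]
    read_gap: tuple[int, int]
    delta: int
    kind: str = "unclassified"  # deletion | tandem_repeat | unclassified
    refined: bool = False


@dataclass(frozen=True)
class CorrectionEvent:
    contig_id: str
    kind: str
    removed_contig_iv: tuple[int, int]
    inserted_read_iv: tuple[int, int]
    piece_ids: tuple[str, ...]


@dataclass(frozen=True)
class Segment:
    """A verbatim piece of a source sequence inside a corrected contig.

    ``iv`` is on the oriented source frame; ``orientation`` records how that
    frame relates to the original input record.
    """

    source_type: str  # 'contig' | 'nanopore'
    source_id: str
    iv: Interval
    orientation: str
    sequence: str


@dataclass
class CorrectedContig:
    contig_id: str
    segments: list[Segment]
    events: list[CorrectionEvent] = field(default_factory=list)
    lead: int = 0  # oriented-contig bases preceding the aligned span

    @property
    def sequence(self) -> str:
        return "".join(s.sequence for s in self.segments)

    def __len__(self) -> int:
        return sum(len(s.sequence) for s in self.segments)


def detect_discrepancies(placement: ContigPlacement,
                         threshold_bp: int = DISCREPANCY_THRESHOLD_BP
                         ) -> list[Discrepancy]:
    """Inter-alignment gaps of the chain whose length difference exceeds
    ``threshold_bp`` (strict)."""
    if placement.status != "placed" or not placement.chain:
        raise ValueError("placement must be placed with a non-empty chain")
    out = []
    chain = placement.chain
    for a, b in zip(chain, chain[1:]):
        cg = (a.query_iv.end, b.query_iv.start)
        rg = (a.target_iv.end, b.target_iv.start)
        delta = abs((rg[1] - rg[0]) - (cg[1] - cg[0]))
        if delta > threshold_bp:
            out.append(Discrepancy(
                contig_id=placement.contig_id, read_id=placement.read_id,
                contig_gap=cg, read_gap=rg, delta=delta,
            ))
    return out


def _border_params(params: AlignmentParams) -> AlignmentParams:
    return replace(params, respect_mask=False, min_score=30)


def localize_breakpoints(d: Discrepancy, contig_seq: str, read_seq: str,
                         flank_bp: int = BORDER_FLANK_BP,
                         border_min_identity: float = BORDER_MIN_IDENTITY,
                         params: AlignmentParams | None = None) -> Discrepancy:
    """Refine gap coordinates by unmasked alignment of the 1 kb borders.

    Borders are truncated at contig ends (one-sided refinement).  If a border
    fails to align at ``border_min_identity``, the discrepancy is returned
    unrefined with kind 'unclassified' and no correction is applied.
    """
    if params is None:
        params = AlignmentParams()
    params = _border_params(params)
    # chain blocks may overlap slightly, inverting the raw gap bounds
    cgs, cge = min(d.contig_gap), max(d.contig_gap)
    rgs, rge = min(d.read_gap), max(d.read_gap)
    pad = flank_bp + 500
    ws = max(0, rgs - pad)
    we = min(len(read_seq), rge + pad)
    window = SequenceRecord("w", read_seq[ws:we])

    def border_end(seq: str):
        """Refined (contig_delta_from_border_start, read_pos) of a left border."""
        if not seq:
            return 0, None
        alns = [a for a in align_local(SequenceRecord("b", seq), window, params)
                if a.strand == "+" and a.percent_identity >= border_min_identity]
        if not alns:
            return None, None
        a = alns[0]
        return a.query_iv.end, ws + a.target_iv.end

    def border_start(seq: str):
        if not seq:
            return 0, None
        alns = [a for a in align_local(SequenceRecord("b", seq), window, params)
                if a.strand == "+" and a.percent_identity >= border_min_identity]
        if not alns:
            return None, None
        a = alns[0]
        return a.query_iv.start, ws + a.target_iv.start

    lb_start = max(0, cgs - flank_bp)
    left_qend, left_rend = border_end(contig_seq[lb_start:cgs])
    rb_end = min(len(contig_seq), cge + flank_bp)
    right_qstart, right_rstart = border_start(contig_seq[cge:rb_end])
    if left_qend is None or right_qstart is None:
        return replace(d, kind="unclassified", refined=False)

    new_cgs = lb_start + left_qend
    new_cge = cge + right_qstart
    new_rgs = rgs if left_rend is None else left_rend
    new_rge = rge if right_rstart is None else right_rstart
    if new_cge < new_cgs or new_rge < new_rgs:
        return replace(d, kind="unclassified", refined=False)
    delta = abs((new_rge - new_rgs) - (new_cge - new_cgs))
    return replace(d, contig_gap=(new_cgs, new_cge), read_gap=(new_rgs, new_rge),
                   delta=delta, refined=True)


def _tandem_period(seq: str, k: int = 8,
                   min_mode_fraction: float = 0.05) -> int | None:
    """Unit period of a tandem array, or None for non-periodic sequence.

    Repeated k-mers in a tandem array recur overwhelmingly at the unit
    period; the histogram of recurrence distances must carry a mode of at
    least ``min_mode_fraction`` of the sequence length to qualify, which a
    random sequence's sparse coincidental k-mer repeats cannot reach.
    """
    import numpy as np

    from .alignment import _encode, _kmer_codes

    codes = _kmer_codes(_encode(seq), k)
    if codes.size < 8:
        return None
    order = np.argsort(codes, kind="stable")
    sc = codes[order]
    same = sc[1:] == sc[:-1]
    dists = np.abs(np.diff(order))[same & (sc[1:] >= 0)]
    dists = dists[(dists >= 4) & (dists <= len(seq) // 3)]
    if dists.size == 0:
        return None
    period = int(np.bincount(dists).argmax())
    mode_count = int((dists == period).sum())
    if mode_count < max(5, min_mode_fraction * (len(seq) - period)):
        return None
    return period


def classify_discrepancy(d: Discrepancy, contig_seq: str, read_seq: str,
                         params: AlignmentParams | None = None,
                         tr_max_divergence: float = 0.3) -> str:
    """'tandem_repeat' or 'deletion' for a refined discrepancy.

    TR evidence (either suffices): the contig's gap sequence — the collapsed
    units — matches multiple distinct tiling positions of the read gap
    segment equally well (edlib reports several co-optimal infix locations),
    or the read gap segment is periodic, its k-mer recurrence histogram
    carrying a dominant mode at one unit period (:func:`_tandem_period`).
    """
    import edlib

    if not d.refined:
        raise ValueError("discrepancy must be refined before classification")
    cgs, cge = d.contig_gap
    rgs, rge = d.read_gap
    gap_seq = read_seq[rgs:rge]
    contig_gap_seq = contig_seq[cgs:cge]
    if len(gap_seq) < 30:
        return "deletion"
    # (a) collapsed units tile multiple positions of the read gap
    if 25 <= len(contig_gap_seq) <= len(gap_seq):
        res = edlib.align(contig_gap_seq, gap_seq, mode="HW", task="locations")
        if res["editDistance"] <= tr_max_divergence * len(contig_gap_seq):
            starts = sorted({loc[0] for loc in res["locations"]
                             if loc[0] is not None})
            distinct = 1 + sum(1 for x, y in zip(starts, starts[1:])
                               if y - x >= 10)
            if distinct >= 3:
                return "tandem_repeat"
    # (b) read gap segment is periodic
    if _tandem_period(gap_seq) is not None:
        return "tandem_repeat"
    return "deletion"


def apply_correction(contig_seq: str, d: Discrepancy):
    """Split coordinates for one refined, classified discrepancy.

    Returns ((left_piece_iv, right_piece_iv), patch_read_iv); piece
    intervals may be empty tuples when a split lands on a contig end.
    """
    if not d.refined or d.kind not in ("deletion", "tandem_repeat"):
        raise ValueError("discrepancy must be refined and classified")
    cgs, cge = d.contig_gap
    if not (0 <= cgs <= cge <= len(contig_seq)):
        raise ValueError("breakpoints out of contig bounds")
    return (0, cgs), (cge, len(contig_seq)), d.read_gap


def correct_placement(placement: ContigPlacement,
                      oriented_contig: SequenceRecord,
                      oriented_read: SequenceRecord,
                      threshold_bp: int = DISCREPANCY_THRESHOLD_BP,
                      flank_bp: int = BORDER_FLANK_BP,
                      border_min_identity: float = BORDER_MIN_IDENTITY,
                      params: AlignmentParams | None = None
                      ) -> tuple[CorrectedContig, list[Discrepancy]]:
    """Detect, refine, classify, and apply all corrections for one contig.

    Events are applied in ascending contig coordinate; each piece stays a
    verbatim substring of the (oriented) input contig and each patch is a
    verbatim substring of the (oriented) read.
    """
    if params is None:
        params = AlignmentParams()
    contig_seq = oriented_contig.sequence
    read_seq = oriented_read.sequence
    raw = detect_discrepancies(placement, threshold_bp)
    refined: list[Discrepancy] = []
    for d in raw:
        r = localize_breakpoints(d, contig_seq, read_seq, flank_bp,
                                 border_min_identity, params)
        if not r.refined:
            log.info("contig %s: border alignment failed; discrepancy left "
                     "unclassified", placement.contig_id)
            refined.append(r)
            continue
        r.kind = classify_discrepancy(r, contig_seq, read_seq, params)
        refined.append(r)

    events: list[CorrectionEvent] = []
    segments: list[Segment] = []
    ori_c = placement.orientation or "+"
    prev = 0
    applicable = sorted(
        (d for d in refined if d.refined and d.kind != "unclassified"),
        key=lambda d: d.contig_gap[0],
    )
    n_piece = 0
    for d in applicable:
        cgs, cge = d.contig_gap
        if cgs < prev:  # overlapping event; keep the earlier one
            log.warning("contig %s: overlapping correction at %d skipped",
                        placement.contig_id, cgs)
            continue
        rgs, rge = d.read_gap
        piece_ids = []
        if cgs > prev:
            n_piece += 1
            pid = f"{placement.contig_id}.{n_piece}"
            piece_ids.append(pid)
            segments.append(Segment("contig", placement.contig_id,
                                    Interval(prev, cgs), ori_c,
                                    contig_seq[prev:cgs]))
        else:
            log.info("contig %s: zero-length piece before %d dropped",
                     placement.contig_id, cgs)
        if rge > rgs:
            segments.append(Segment("nanopore", placement.read_id,
                                    Interval(rgs, rge), "+",
                                    read_seq[rgs:rge]))
        events.append(CorrectionEvent(
            contig_id=placement.contig_id, kind=d.kind,
            removed_contig_iv=(cgs, cge), inserted_read_iv=(rgs, rge),
            piece_ids=tuple(piece_ids),
        ))
        prev = cge
    if prev < len(contig_seq):
        segments.append(Segment("contig", placement.contig_id,
                                Interval(prev, len(contig_seq)), ori_c,
                                contig_seq[prev:]))
    lead = min(a.query_iv.start for a in placement.chain)
    corrected = CorrectedContig(placement.contig_id, segments, events, lead=lead)
    return corrected, refined


def check_conservation(corrected: CorrectedContig, placement: ContigPlacement,
                       oriented_read: SequenceRecord,
                       threshold_bp: int = DISCREPANCY_THRESHOLD_BP,
                       params: AlignmentParams | None = None) -> bool:
    """True when the corrected contig re-aligns to its read span with no
    residual length discrepancy above ``threshold_bp``."""
    if params is None:
        params = AlignmentParams()
    t0 = min(a.target_iv.start for a in placement.chain)
    t1 = max(a.target_iv.end for a in placement.chain)
    pad = 500
    ws = max(0, t0 - pad)
    we = min(len(oriented_read.sequence), t1 + pad)
    window = SequenceRecord("w", oriented_read.sequence[ws:we])
    alns = [a for a in align_local(SequenceRecord("c", corrected.sequence),
                                   window, replace(params, respect_mask=False))
            if a.strand == "+"]
    if not alns:
        return False
    chain = longest_contiguous_segment(alns, max_chain_gap=max(
        params.max_chain_gap, 2 * threshold_bp))
    for a, b in zip(chain, chain[1:]):
        cg = b.query_iv.start - a.query_iv.end
        rg = b.target_iv.start - a.target_iv.end
        if abs(rg - cg) > threshold_bp:
            return False
    return True
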