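"""Orient and position linked-read (REXTAL) contigs on the scaffold reads.

The two-threshold procedure: contigs are first oriented using masked-mode
alignments of at least 75% identity, with conflicting orientations resolved
by higher local-alignment ("Segment Pair") score and then by aligned length;
oriented contigs are then positioned using alignments of at least 80%
identity, discarding residual reverse-strand alignments and contigs placed
completely within larger ones.  Final positions come from each contig's
longest contiguous (colinear chained) segment on its best-supporting read.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

from .alignment import (AlignmentParams, LocalAlignment, align_local,
                        chain_identity, chain_score, longest_contiguous_segment)
from .scaffolding import ScaffoldLayout
from .seqio import Interval, SequenceRecord, flip_interval

__all__ = [
    "ContigPlacement",
    "align_contigs_to_reads",
    "orient_from_alignments",
    "orient_contigs",
    "position_from_alignments",
    "position_contigs",
    "order_placements",
]

log = logging.getLogger(__name__)

ORIENT_MIN_IDENTITY = 75.0
POSITION_MIN_IDENTITY = 80.0


@dataclass
class ContigPlacement:
    contig_id: str
    read_id: str | None
    orientation: str | None
    placed_iv: Interval | None  # layout coordinates
    read_iv: Interval | None  # coordinates on the oriented read
    chain: list[LocalAlignment] = field(default_factory=list)
    status: str = "unplaced"  # placed | contained_removed | reverse_removed | unplaced

    @property
    def chain_identity(self) -> float:
        return chain_identity(self.chain)


def align_contigs_to_reads(contigs: list[SequenceRecord],
                           masked_reads: dict[str, SequenceRecord],
                           params: AlignmentParams
                           ) -> dict[str, dict[str, list[LocalAlignment]]]:
    """Masked-mode alignments of every contig against every scaffold read."""
    out: dict[str, dict[str, list[LocalAlignment]]] = {}
    for contig in sorted(contigs, key=lambda c: c.id):
        per_read = {}
        for rid in sorted(masked_reads):
            alns = align_local(contig, masked_reads[rid], params)
            if alns:
                per_read[rid] = alns
        out[contig.id] = per_read
    return out


def orient_from_alignments(alns_by_read: dict[str, list[LocalAlignment]],
                           min_identity: float = ORIENT_MIN_IDENTITY
                           ) -> str | None:
    """Orientation from qualifying alignments; None when none qualify.

    Conflicts resolve by higher score, then by longer aligned length
    (columns), then deterministically by coordinates.
    """
    best = None
    for rid in sorted(alns_by_read):
        for a in alns_by_read[rid]:
            if a.percent_identity < min_identity:
                continue
            key = (a.score, a.columns, -a.target_iv.start, -a.query_iv.start)
            if best is None or key > best[0]:
                best = (key, a.strand)
    return None if best is None else best[1]


def orient_contigs(contigs: list[SequenceRecord],
                   masked_reads: dict[str, SequenceRecord],
                   params: AlignmentParams | None = None,
                   min_identity: float = ORIENT_MIN_IDENTITY
                   ) -> tuple[dict[str, str | None],
                              dict[str, dict[str, list[LocalAlignment]]]]:
    """Assign each contig an orientation (or None = unplaced).

    Also returns the raw alignment tables so positioning can reuse them.
    """
    if params is None:
        params = AlignmentParams()
    tables = align_contigs_to_reads(contigs, masked_reads, params)
    orientation = {cid: orient_from_alignments(tbl, min_identity)
                   for cid, tbl in tables.items()}
    return orientation, tables


def _flip_alignment(a: LocalAlignment, contig_len: int) -> LocalAlignment:
    """Re-express an alignment in the reverse-complemented query frame."""
    return replace(
        a,
        query_iv=flip_interval(a.query_iv, contig_len),
        strand="-" if a.strand == "+" else "+",
    )


def position_from_alignments(contig_id: str, contig_len: int, orientation: str,
                             alns_by_read: dict[str, list[LocalAlignment]],
                             layout: ScaffoldLayout,
                             min_identity: float = POSITION_MIN_IDENTITY,
                             max_chain_gap: int = 2000) -> ContigPlacement:
    """Position one oriented contig from its alignment table.

    Alignments are re-expressed in the oriented-contig frame; residual
    reverse alignments are removed; the best-scoring colinear chain over any
    single read gives the position.
    """
    layout_ids = {e.read_id for e in layout.entries}
    had_reverse = False
    best_chain = None
    best_key = None
    for rid in sorted(alns_by_read):
        if rid not in layout_ids:
            continue
        usable = []
        for a in alns_by_read[rid]:
            if a.percent_identity < min_identity:
                continue
            oriented = a if orientation == "+" else _flip_alignment(a, contig_len)
            if oriented.strand == "-":
                had_reverse = True
                continue
            usable.append(oriented)
        if not usable:
            continue
        chain = longest_contiguous_segment(usable, max_chain_gap=max_chain_gap)
        if chain_identity(chain) < min_identity:
            continue
        key = (chain_score(chain), -layout.entry(rid).offset, rid)
        if best_key is None or key > best_key:
            best_key = key
            best_chain = (rid, chain)
    if best_chain is None:
        status = "reverse_removed" if had_reverse else "unplaced"
        return ContigPlacement(contig_id, None, orientation, None, None, [], status)
    rid, chain = best_chain
    offset = layout.entry(rid).offset
    t0 = min(a.target_iv.start for a in chain)
    t1 = max(a.target_iv.end for a in chain)
    return ContigPlacement(
        contig_id=contig_id, read_id=rid, orientation=orientation,
        placed_iv=Interval(offset + t0, offset + t1),
        read_iv=Interval(t0, t1), chain=chain, status="placed",
    )


def position_contigs(contigs: list[SequenceRecord],
                     orientation: dict[str, str | None],
                     tables: dict[str, dict[str, list[LocalAlignment]]],
                     layout: ScaffoldLayout,
                     min_identity: float = POSITION_MIN_IDENTITY,
                     max_chain_gap: int = 2000) -> list[ContigPlacement]:
    """Position all oriented contigs and apply the containment rule."""
    lengths = {c.id: len(c.sequence) for c in contigs}
    placements = []
    for cid in sorted(tables):
        ori = orientation.get(cid)
        if ori is None:
            placements.append(ContigPlacement(cid, None, None, None, None, [], "unplaced"))
            continue
        placements.append(position_from_alignments(
            cid, lengths[cid], ori, tables[cid], layout,
            min_identity, max_chain_gap,
        ))
    placed = [p for p in placements if p.status == "placed"]
    for p in placed:
        for q in placed:
            if p is q or q.status != "placed":
                continue
            if q.placed_iv.contains(p.placed_iv) and (
                len(q.placed_iv) > len(p.placed_iv)
                or (len(q.placed_iv) == len(p.placed_iv) and q.contig_id < p.contig_id)
            ):
                p.status = "contained_removed"
                log.info("contig %s contained within %s; removed", p.contig_id, q.contig_id)
                break
    return placements


def order_placements(placements: list[ContigPlacement],
                     layout: ScaffoldLayout) -> list[ContigPlacement]:
    """Placed contigs sorted along layout coordinates.

    Ties at equal start go to the longer placement, then lexicographic id.
    """
    layout_ids = {e.read_id for e in layout.entries}
    out = []
    for p in placements:
        if p.status != "placed":
            continue
        if p.read_id not in layout_ids:
            raise ValueError(f"placement of {p.contig_id} references read "
                             f"{p.read_id!r} absent from the layout")
        out.append(p)
    out.sort(key=lambda p: (p.placed_iv.start, -len(p.placed_iv), p.contig_id))
    return out
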