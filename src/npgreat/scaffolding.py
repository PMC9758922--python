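"""Orient nanopore reads against the telomere anchor and lay them out.

Canonical internal orientation puts the (TTAGGG)n tract at the RIGHT end of
the layout for both chromosome arms; p-arm output is reverse-complemented at
write time.  Telomeric reads are oriented a priori from their tract; the
remaining reads inherit orientation over the read-overlap graph by
maximum-score spanning-forest propagation (strand composition along tree
edges), which resolves any conflicting path by construction: each read
attaches through its highest-scoring overlap.  Offsets come from the same
tree via single-linkage chaining from the telomere-anchored origin read;
reads fully contained in another read are dropped from the layout.
"""

from __future__ import annotations

import heapq
import logging
from dataclasses import dataclass, field

from .alignment import (AlignmentParams, LocalAlignment, align_local,
                        chain_identity, chain_score, longest_contiguous_segment)
from .seqio import Interval, SequenceRecord, flip_interval
from .telomere_screen import TELOMERE_MOTIF, TELOMERE_MOTIF_RC, TelomereCall

__all__ = [
    "OverlapEdge",
    "LayoutEntry",
    "ScaffoldLayout",
    "orient_telomeric_read",
    "compute_overlaps",
    "orient_by_overlap",
    "build_layout",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class OverlapEdge:
    """Best colinear overlap chain between two reads (query vs target)."""

    query_id: str
    target_id: str
    strand: str
    chain: tuple[LocalAlignment, ...]
    score: int
    span: int
    identity: float


@dataclass(frozen=True)
class LayoutEntry:
    read_id: str
    orientation: str
    offset: int
    length: int
    role: str  # 'telomeric' | 'subtelomeric'


@dataclass
class ScaffoldLayout:
    arm: str
    entries: list[LayoutEntry] = field(default_factory=list)
    origin_read: str = ""

    @property
    def length(self) -> int:
        return max((e.offset + e.length for e in self.entries), default=0)

    def entry(self, read_id: str) -> LayoutEntry:
        for e in self.entries:
            if e.read_id == read_id:
                return e
        raise KeyError(read_id)


def orient_telomeric_read(read: SequenceRecord,
                          calls: tuple[TelomereCall, TelomereCall]
                          ) -> tuple[SequenceRecord, str]:
    """Orient a telomeric read so its tract sits at the right end as TTAGGG.

    Reads telomeric at both ends are rejected as chimeras.
    """
    left, right = calls
    if left.is_telomeric and right.is_telomeric:
        raise ValueError(f"read {read.id!r} is telomeric at both ends (chimera)")
    if right.is_telomeric and right.motif_strand == TELOMERE_MOTIF:
        return read, "+"
    if left.is_telomeric and left.motif_strand == TELOMERE_MOTIF_RC:
        return read.reverse_complement(), "-"
    raise ValueError(
        f"read {read.id!r}: no terminal tract in a canonical configuration"
    )


def _best_chain(alns: list[LocalAlignment], max_chain_gap: int):
    best = None
    for strand in "+-":
        sub = [a for a in alns if a.strand == strand]
        if not sub:
            continue
        chain = longest_contiguous_segment(sub, max_chain_gap=max_chain_gap)
        if best is None or chain_score(chain) > chain_score(best):
            best = chain
    return best


def compute_overlaps(reads: list[SequenceRecord],
                     params: AlignmentParams | None = None,
                     min_identity: float = 80.0,
                     min_length: int = 5000) -> list[OverlapEdge]:
    """All qualifying pairwise overlap edges among raw reads.

    Each unordered pair is aligned once (lexicographically larger id as the
    query) and the best per-strand colinear chain is kept when it spans at
    least ``min_length`` query bases at ``min_identity`` percent identity.
    """
    if params is None:
        params = AlignmentParams()
    edges = []
    ordered = sorted(reads, key=lambda r: r.id)
    for x in range(len(ordered)):
        for y in range(x + 1, len(ordered)):
            target, query = ordered[x], ordered[y]
            alns = [a for a in align_local(query, target, params)
                    if a.percent_identity >= min_identity]
            if not alns:
                continue
            chain = _best_chain(alns, params.max_chain_gap)
            if chain is None:
                continue
            span = sum(len(a.query_iv) for a in chain)
            ident = chain_identity(chain)
            if span < min_length or ident < min_identity:
                continue
            edges.append(OverlapEdge(
                query_id=query.id, target_id=target.id,
                strand=chain[0].strand, chain=tuple(chain),
                score=chain_score(chain), span=span, identity=ident,
            ))
    return edges


def _compose(ori: str, strand: str) -> str:
    return ori if strand == "+" else ("-" if ori == "+" else "+")


def orient_by_overlap(read_ids: list[str], anchors: dict[str, str],
                      edges: list[OverlapEdge]) -> dict[str, str]:
    """Propagate orientation from anchored reads over the overlap graph.

    Maximum-score spanning-forest propagation: reads attach to the oriented
    set through their highest-scoring edge, so two paths implying opposite
    strands resolve in favour of the higher-score attachment (the conflict is
    logged).  Reads unreachable from any anchor are absent from the result.
    """
    if not anchors:
        raise ValueError("at least one anchored read is required")
    adj: dict[str, list[tuple[int, str, OverlapEdge]]] = {r: [] for r in read_ids}
    for e in edges:
        if e.query_id in adj and e.target_id in adj:
            adj[e.query_id].append((e.score, e.target_id, e))
            adj[e.target_id].append((e.score, e.query_id, e))
    orientation = dict(sorted(anchors.items()))
    heap: list[tuple[int, str, str, int]] = []
    elist: list[OverlapEdge] = []

    def push_from(node: str) -> None:
        for score, other, e in adj[node]:
            if other not in orientation:
                elist.append(e)
                heapq.heappush(heap, (-score, other, node, len(elist) - 1))

    for a in orientation:
        push_from(a)
    while heap:
        negscore, node, parent, ei = heapq.heappop(heap)
        e = elist[ei]
        here = e.query_id if e.target_id == parent else e.target_id
        implied = _compose(orientation[parent], e.strand)
        if node in orientation:
            if orientation[node] != implied:
                log.debug(
                    "orientation conflict at %s via %s (score %d) ignored",
                    node, parent, -negscore,
                )
            continue
        orientation[node] = implied
        push_from(node)
    unreachable = set(read_ids) - set(orientation)
    for r in sorted(unreachable):
        log.info("read %s has no overlap path to an anchor; left unoriented", r)
    return orientation


def _oriented_block(e: OverlapEdge, orientation: dict[str, str],
                    lengths: dict[str, int]) -> tuple[int, int] | None:
    """First chain block's (target_start, query_start) in oriented frames.

    Returns None when the edge strand is inconsistent with the assigned
    orientations (a non-tree conflict edge).
    """
    oq = orientation[e.query_id]
    ot = orientation[e.target_id]
    if _compose(ot, e.strand) != oq:
        return None
    blk = min(e.chain, key=lambda a: a.query_iv.start)
    q_iv = blk.query_iv if oq == "+" else flip_interval(blk.query_iv, lengths[e.query_id])
    t_iv = blk.target_iv if ot == "+" else flip_interval(blk.target_iv, lengths[e.target_id])
    return t_iv.start, q_iv.start


def build_layout(reads: dict[str, SequenceRecord], orientation: dict[str, str],
                 edges: list[OverlapEdge], telomeric_ids: set[str],
                 arm: str = "q") -> tuple[ScaffoldLayout, dict[str, SequenceRecord]]:
    """Place oriented reads on a shared coordinate axis.

    The longest telomeric read is the coordinate origin; offsets follow
    maximum-score single-linkage chaining over orientation-consistent
    overlap edges.  Contained reads are dropped; offsets are normalised so
    the minimum is zero.  Returns the layout plus oriented sequence records.
    """
    anchored_tel = [r for r in telomeric_ids if r in orientation]
    if not anchored_tel:
        raise ValueError("cannot anchor a layout without a telomeric read")
    origin = max(anchored_tel, key=lambda r: (len(reads[r].sequence), r))
    lengths = {r: len(reads[r].sequence) for r in orientation}
    adj: dict[str, list[tuple[int, str, OverlapEdge]]] = {r: [] for r in orientation}
    for e in edges:
        if e.query_id in adj and e.target_id in adj:
            adj[e.query_id].append((e.score, e.target_id, e))
            adj[e.target_id].append((e.score, e.query_id, e))
    offsets: dict[str, int] = {origin: 0}
    heap: list[tuple[int, str, str, int]] = []
    elist: list[OverlapEdge] = []

    def push_from(node: str) -> None:
        for score, other, e in adj[node]:
            if other not in offsets:
                elist.append(e)
                heapq.heappush(heap, (-score, other, node, len(elist) - 1))

    push_from(origin)
    while heap:
        _, node, parent, ei = heapq.heappop(heap)
        if node in offsets:
            continue
        e = elist[ei]
        block = _oriented_block(e, orientation, lengths)
        if block is None:
            continue
        t_start, q_start = block
        if e.query_id == node:
            offsets[node] = offsets[parent] + (t_start - q_start)
        else:
            offsets[node] = offsets[parent] + (q_start - t_start)
        push_from(node)
    skipped = sorted(set(orientation) - set(offsets))
    for r in skipped:
        log.info("read %s unreachable from the telomeric origin; excluded", r)

    # drop contained reads (never the origin)
    spans = {r: (offsets[r], offsets[r] + lengths[r]) for r in offsets}
    kept = []
    for r in sorted(spans, key=lambda r: (spans[r][0], -lengths[r], r)):
        s, t = spans[r]
        contained = any(
            o != r and spans[o][0] <= s and t <= spans[o][1]
            and (lengths[o] > lengths[r] or (lengths[o] == lengths[r] and o < r))
            for o in spans
        )
        if contained and r != origin:
            log.info("read %s contained within another read; dropped", r)
            continue
        kept.append(r)

    base = min(offsets[r] for r in kept)
    entries = []
    oriented: dict[str, SequenceRecord] = {}
    for r in sorted(kept, key=lambda r: (offsets[r], r)):
        rec = reads[r]
        oriented[r] = rec if orientation[r] == "+" else rec.reverse_complement()
        entries.append(LayoutEntry(
            read_id=r, orientation=orientation[r], offset=offsets[r] - base,
            length=lengths[r],
            role="telomeric" if r in telomeric_ids else "subtelomeric",
        ))
    return ScaffoldLayout(arm=arm, entries=entries, origin_read=origin), oriented
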