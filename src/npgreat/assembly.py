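"""Merge corrected contigs, pick nanopore connector segments, and combine.

Neighbouring placed contigs either overlap — merged with the junction cut at
the overlap midpoint (after checking the two contigs agree over a junction
window) — or leave a gap.  Each gap collects one candidate connector segment
per layout read that spans it with enough flanking contig on both sides to
align; the filler is the candidate with the highest average percent identity
to the flanking contigs.  The final sequence concatenates, in layout order:
an optional proximal nanopore extension, contig blocks, chosen connectors,
and the distal nanopore extension running through the terminal telomere
tract.  Unbridgeable gaps emit an N-run sized by layout distance.  Every
output base carries provenance (source record, interval, orientation), and
the provenance rows partition the output exactly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

from .alignment import AlignmentParams, align_global_scored, align_local
from .contig_mapping import ContigPlacement
from .correction import CorrectedContig, Segment
from .scaffolding import ScaffoldLayout
from .seqio import Interval, SequenceRecord, flip_interval, reverse_complement

__all__ = [
    "ConnectorSegment",
    "ProvenanceRow",
    "AssemblyResult",
    "merge_overlapping_contigs",
    "extract_connectors",
    "select_gap_filler",
    "combine",
    "validate_provenance",
    "write_provenance_tsv",
    "write_agp",
]

log = logging.getLogger(__name__)

FLANK_LEN = 2000
FLANK_PAD = 3000
FLANK_MIN_IDENTITY = 60.0
MERGE_MAX_MISMATCH = 0.02
MERGE_WINDOW = 1000
MIN_EXTENSION = 50


@dataclass(frozen=True)
class ConnectorSegment:
    """A candidate nanopore bridge for one inter-contig gap."""

    read_id: str
    read_iv: tuple[int, int]  # oriented-read coords; may be empty (s == e)
    left_contig_id: str | None
    right_contig_id: str | None
    avg_flank_identity: float
    flank_columns: int
    sequence: str


@dataclass(frozen=True)
class ProvenanceRow:
    out_iv: Interval
    source_type: str  # 'contig' | 'nanopore' | 'gap'
    source_id: str
    source_iv: Interval | None  # original input-record coordinates
    orientation: str


@dataclass
class AssemblyResult:
    sequence: str
    provenance: list[ProvenanceRow]
    arm: str = "q"

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class BlockPiece:
    placement: ContigPlacement
    cut: tuple[int, int]  # layout coordinates contributed by this contig


@dataclass
class ContigBlock:
    pieces: list[BlockPiece]

    @property
    def layout_iv(self) -> tuple[int, int]:
        return self.pieces[0].cut[0], self.pieces[-1].cut[1]


def _slice_corrected(cc: CorrectedContig, a: int, b: int) -> list[Segment]:
    """Segments of a corrected contig restricted to corrected coords [a, b)."""
    a = max(0, a)
    b = min(len(cc), b)
    out = []
    pos = 0
    for seg in cc.segments:
        n = len(seg.sequence)
        lo = max(a, pos)
        hi = min(b, pos + n)
        if lo < hi:
            s0 = lo - pos
            s1 = hi - pos
            out.append(Segment(
                seg.source_type, seg.source_id,
                Interval(seg.iv.start + s0, seg.iv.start + s1),
                seg.orientation, seg.sequence[s0:s1],
            ))
        pos += n
    return out


def _layout_to_corrected(p: ContigPlacement, cc: CorrectedContig, pos: int) -> int:
    return cc.lead + (pos - p.placed_iv.start)


def _block_segments(block: ContigBlock,
                    corrected: dict[str, CorrectedContig]) -> list[Segment]:
    segs: list[Segment] = []
    for piece in block.pieces:
        cc = corrected[piece.placement.contig_id]
        a = _layout_to_corrected(piece.placement, cc, piece.cut[0])
        b = _layout_to_corrected(piece.placement, cc, piece.cut[1])
        segs.extend(_slice_corrected(cc, a, b))
    return segs


def _junction_agrees(left_seq: str, right_seq: str,
                     params: AlignmentParams,
                     max_mismatch: float = MERGE_MAX_MISMATCH) -> bool:
    """Infix comparison so small placement misregistration is tolerated."""
    if not left_seq or not right_seq:
        return True
    import edlib

    from .alignment import _cigar_stats

    if len(right_seq) > len(left_seq):
        left_seq, right_seq = right_seq, left_seq
    res = edlib.align(right_seq, left_seq, mode="HW", task="path")
    matches, columns, _ = _cigar_stats(res["cigar"], params)
    return (columns - matches) <= max_mismatch * columns


def merge_overlapping_contigs(ordered: list[ContigPlacement],
                              corrected: dict[str, CorrectedContig],
                              params: AlignmentParams | None = None
                              ) -> list[ContigBlock]:
    """Group overlapping placements into blocks, cutting junctions at the
    overlap midpoint; sequence disagreement over the junction window demotes
    the junction to a zero-length cut at the left contig's end."""
    if params is None:
        params = AlignmentParams()
    blocks: list[ContigBlock] = []
    for p in ordered:
        if not blocks:
            blocks.append(ContigBlock([BlockPiece(p, (p.placed_iv.start, p.placed_iv.end))]))
            continue
        block = blocks[-1]
        last = block.pieces[-1]
        cur_end = last.cut[1]
        if p.placed_iv.start < cur_end:
            mid = (p.placed_iv.start + cur_end) // 2
            half = MERGE_WINDOW // 2
            # clip the agreement window to the span both contigs cover
            wlo = max(mid - half, p.placed_iv.start, last.cut[0])
            whi = min(mid + half, cur_end, p.placed_iv.end)
            lcc = corrected[last.placement.contig_id]
            rcc = corrected[p.contig_id]
            pad = 300  # absorbs placement misregistration in the comparison
            la = _layout_to_corrected(last.placement, lcc, wlo) - pad
            lb = _layout_to_corrected(last.placement, lcc, whi) + pad
            ra = _layout_to_corrected(p, rcc, wlo)
            rb = _layout_to_corrected(p, rcc, whi)
            lseq = lcc.sequence[max(0, la):max(0, lb)]
            rseq = rcc.sequence[max(0, ra):max(0, rb)]
            if _junction_agrees(lseq, rseq, params):
                last.cut = (last.cut[0], mid)
                block.pieces.append(BlockPiece(p, (mid, p.placed_iv.end)))
            else:
                log.warning("overlap disagreement between %s and %s; joined "
                            "without merge at %d", last.placement.contig_id,
                            p.contig_id, cur_end)
                block.pieces.append(BlockPiece(p, (cur_end, p.placed_iv.end)))
        else:
            blocks.append(ContigBlock([BlockPiece(p, (p.placed_iv.start, p.placed_iv.end))]))
    return blocks


def _locate_flank(flank_seq: str, read: SequenceRecord, expected: tuple[int, int],
                  params: AlignmentParams, want: str):
    """Best unmasked alignment of a flank inside a padded read window.

    Returns (read_coordinate_of_cut, identity, columns) or None; ``want`` is
    'end' (left flank: cut at the alignment end) or 'start'.
    """
    ws = max(0, expected[0] - FLANK_PAD)
    we = min(len(read.sequence), expected[1] + FLANK_PAD)
    if we - ws < len(flank_seq) // 2 or not flank_seq:
        return None
    window = SequenceRecord("w", read.sequence[ws:we])
    p = replace(params, respect_mask=False, min_score=30)
    alns = [a for a in align_local(SequenceRecord("f", flank_seq), window, p)
            if a.strand == "+" and a.percent_identity >= FLANK_MIN_IDENTITY]
    if not alns:
        return None
    a = alns[0]
    pos = ws + (a.target_iv.end if want == "end" else a.target_iv.start)
    return pos, a.percent_identity, a.columns


def extract_connectors(left_tail: str | None, right_head: str | None,
                       gap: tuple[int, int], layout: ScaffoldLayout,
                       oriented_reads: dict[str, SequenceRecord],
                       left_contig_id: str | None, right_contig_id: str | None,
                       params: AlignmentParams | None = None,
                       flank_len: int = FLANK_LEN,
                       telomeric_only: bool = False) -> list[ConnectorSegment]:
    """Candidate connector segments for one gap.

    ``left_tail``/``right_head`` are the assembled flank sequences adjacent
    to the gap (None for a one-sided terminal gap); every layout read whose
    span covers the gap plus the required flanks contributes one candidate.
    """
    if params is None:
        params = AlignmentParams()
    out = []
    for e in layout.entries:
        if telomeric_only and e.role != "telomeric":
            continue
        need_lo = gap[0] - (flank_len if left_tail else 0)
        need_hi = gap[1] + (flank_len if right_head else 0)
        if not (e.offset <= need_lo and e.offset + e.length >= need_hi):
            continue
        read = oriented_reads[e.read_id]
        idents = []
        cols = 0
        if left_tail:
            exp = (gap[0] - flank_len - e.offset, gap[0] - e.offset)
            loc = _locate_flank(left_tail, read, exp, params, "end")
            if loc is None:
                continue
            cut_start, ident, c = loc
            idents.append(ident)
            cols += c
        else:
            cut_start = 0
        if right_head:
            exp = (gap[1] - e.offset, gap[1] + flank_len - e.offset)
            loc = _locate_flank(right_head, read, exp, params, "start")
            if loc is None:
                continue
            cut_end, ident, c = loc
            idents.append(ident)
            cols += c
        else:
            cut_end = len(read.sequence)
        if cut_end < cut_start:
            cut_end = cut_start
        out.append(ConnectorSegment(
            read_id=e.read_id, read_iv=(cut_start, cut_end),
            left_contig_id=left_contig_id, right_contig_id=right_contig_id,
            avg_flank_identity=sum(idents) / len(idents) if idents else 0.0,
            flank_columns=cols,
            sequence=read.sequence[cut_start:cut_end],
        ))
    return out


def select_gap_filler(candidates: list[ConnectorSegment]) -> ConnectorSegment:
    """Highest average flanking identity; ties to longer total flank
    alignment, then lexicographic read id."""
    if not candidates:
        raise ValueError("no connector candidates")
    return sorted(
        candidates,
        key=lambda c: (-c.avg_flank_identity, -c.flank_columns, c.read_id),
    )[0]


def combine(blocks: list[ContigBlock],
            fillers: list[ConnectorSegment | None],
            gaps: list[tuple[int, int]],
            corrected: dict[str, CorrectedContig],
            proximal: ConnectorSegment | None,
            distal: ConnectorSegment | None,
            read_orientation: dict[str, str],
            source_lengths: dict[str, int],
            arm: str = "q") -> AssemblyResult:
    """Concatenate extension + blocks + connectors into the final sequence.

    ``fillers[i]`` bridges ``gaps[i]`` between blocks i and i+1 (None emits
    an N-run sized by layout distance).  For the p arm the whole sequence is
    reverse-complemented at the end, provenance included.
    """
    segs: list[Segment] = []
    if proximal is not None and len(proximal.sequence) >= MIN_EXTENSION:
        segs.append(Segment("nanopore", proximal.read_id,
                            Interval(*proximal.read_iv), "+", proximal.sequence))
    for i, block in enumerate(blocks):
        segs.extend(_block_segments(block, corrected))
        if i < len(gaps):
            filler = fillers[i]
            if filler is not None:
                if filler.read_iv[1] > filler.read_iv[0]:
                    segs.append(Segment("nanopore", filler.read_id,
                                        Interval(*filler.read_iv), "+",
                                        filler.sequence))
            else:
                n = gaps[i][1] - gaps[i][0]
                if n > 0:
                    log.warning("gap %d-%d unbridged; emitting %d Ns", *gaps[i], n)
                    segs.append(Segment("gap", "", Interval(0, n), "+", "N" * n))
    if distal is not None and len(distal.sequence) > 0:
        segs.append(Segment("nanopore", distal.read_id,
                            Interval(*distal.read_iv), "+", distal.sequence))

    sequence = "".join(s.sequence for s in segs)
    provenance: list[ProvenanceRow] = []
    pos = 0
    for s in segs:
        n = len(s.sequence)
        if n == 0:
            continue
        if s.source_type == "gap":
            provenance.append(ProvenanceRow(Interval(pos, pos + n), "gap", "", None, "+"))
        else:
            ori = s.orientation
            if s.source_type == "nanopore":
                ori = read_orientation.get(s.source_id, "+")
            src_iv = (s.iv if ori == "+"
                      else flip_interval(s.iv, source_lengths[s.source_id]))
            provenance.append(ProvenanceRow(
                Interval(pos, pos + n), s.source_type, s.source_id, src_iv, ori))
        pos += n
    result = AssemblyResult(sequence=sequence, provenance=provenance, arm=arm)
    if arm == "p":
        total = len(sequence)
        flipped = [
            ProvenanceRow(
                flip_interval(r.out_iv, total), r.source_type, r.source_id,
                r.source_iv, r.orientation if r.source_type == "gap"
                else ("-" if r.orientation == "+" else "+"),
            )
            for r in reversed(result.provenance)
        ]
        result = AssemblyResult(reverse_complement(sequence), flipped, arm="p")
    _assert_partition(result)
    return result


def _assert_partition(result: AssemblyResult) -> None:
    pos = 0
    for row in result.provenance:
        if row.out_iv.start != pos:
            raise AssertionError("provenance does not partition the output")
        pos = row.out_iv.end
    if pos != len(result.sequence):
        raise AssertionError("provenance does not cover the output")


def validate_provenance(result: AssemblyResult,
                        sources: dict[str, SequenceRecord]) -> None:
    """Assert the partition plus verbatim-substring invariants."""
    _assert_partition(result)
    for row in result.provenance:
        out = result.sequence[row.out_iv.start:row.out_iv.end]
        if row.source_type == "gap":
            if out != "N" * len(out):
                raise AssertionError("gap row is not an N-run")
            continue
        src = sources[row.source_id].sequence[row.source_iv.start:row.source_iv.end]
        if row.orientation == "-":
            src = reverse_complement(src)
        if out != src:
            raise AssertionError(
                f"provenance row {row} is not verbatim from its source")


def write_provenance_tsv(result: AssemblyResult, path) -> None:
    with open(path, "w") as fh:
        fh.write("out_start\tout_end\tsource_type\tsource_id\t"
                 "source_start\tsource_end\torientation\n")
        for r in result.provenance:
            s = r.source_iv.start if r.source_iv else ""
            e = r.source_iv.end if r.source_iv else ""
            fh.write(f"{r.out_iv.start}\t{r.out_iv.end}\t{r.source_type}\t"
                     f"{r.source_id}\t{s}\t{e}\t{r.orientation}\n")


def write_agp(result: AssemblyResult, object_name: str, path) -> None:
    """AGP v2.1: W component lines for sequence pieces, N lines for gaps."""
    with open(path, "w") as fh:
        fh.write("##agp-version\t2.1\n")
        for i, r in enumerate(result.provenance, start=1):
            ob, oe = r.out_iv.start + 1, r.out_iv.end
            if r.source_type == "gap":
                fh.write(f"{object_name}\t{ob}\t{oe}\t{i}\tN\t{len(r.out_iv)}\t"
                         f"scaffold\tyes\talign_genus\n")
            else:
                cb, ce = r.source_iv.start + 1, r.source_iv.end
                fh.write(f"{object_name}\t{ob}\t{oe}\t{i}\tW\t{r.source_id}\t"
                         f"{cb}\t{ce}\t{r.orientation}\n")
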