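"""End-to-end orchestration: screen -> scaffold -> map -> correct -> assemble.

One subtelomere per invocation.  Defaults carry the method's published
constants: reads of at least 40,000 bases, the (TTAGGG)x4-at-least-twice
telomere screen on GATC-delimited read ends, 75% identity for contig
orientation, 80% for positioning, a 100 bp discrepancy threshold, and 1 kb
unmasked border flanks for breakpoint localisation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

from .alignment import AlignmentParams, mask_repeats
from .assembly import (AssemblyResult, ConnectorSegment, ContigBlock,
                       FLANK_LEN, MIN_EXTENSION, ProvenanceRow, combine,
                       extract_connectors, merge_overlapping_contigs,
                       select_gap_filler, write_agp, write_provenance_tsv)
from .contig_mapping import (ContigPlacement, order_placements, orient_contigs,
                             position_contigs)
from .correction import (CorrectedContig, Discrepancy, check_conservation,
                         correct_placement)
from .scaffolding import (ScaffoldLayout, build_layout, compute_overlaps,
                          orient_by_overlap, orient_telomeric_read)
from .seqio import Interval, SequenceRecord, write_fasta
from .telomere_screen import ReadSelection, select_reads

__all__ = ["PipelineConfig", "PipelineResult", "NoAnchorError", "run_pipeline"]

log = logging.getLogger(__name__)


class NoAnchorError(RuntimeError):
    """No telomeric read available to anchor the layout orientation."""


@dataclass
class PipelineConfig:
    arm: str = "q"
    min_read_length: int = 40_000
    min_unit_run: int = 4
    min_occurrences: int = 2
    min_probe_identity: float = 85.0
    min_probe_cover: float = 0.5
    orient_min_identity: float = 75.0
    position_min_identity: float = 80.0
    discrepancy_threshold_bp: int = 100
    border_flank_bp: int = 1000
    border_min_identity: float = 75.0
    overlap_min_identity: float = 80.0
    overlap_min_length: int = 5000
    mask_k: int = 15
    mask_max_occ: int = 8
    alignment: AlignmentParams = field(default_factory=AlignmentParams)

    def __post_init__(self) -> None:
        for name in ("min_probe_identity", "orient_min_identity",
                     "position_min_identity", "overlap_min_identity",
                     "border_min_identity"):
            v = getattr(self, name)
            if not 0 <= v <= 100:
                raise ValueError(f"{name} must be a percentage")


@dataclass
class PipelineResult:
    assembly: AssemblyResult
    selection: ReadSelection
    layout: ScaffoldLayout
    oriented_reads: dict[str, SequenceRecord]
    placements: list[ContigPlacement]
    corrected: dict[str, CorrectedContig]
    discrepancies: dict[str, list[Discrepancy]]
    connectors: list[ConnectorSegment | None]


def _block_sequence(block: ContigBlock, corrected) -> str:
    from .assembly import _block_segments
    return "".join(s.sequence for s in _block_segments(block, corrected))


def _nanopore_only(layout: ScaffoldLayout, oriented_reads, reads_orig,
                   config: PipelineConfig) -> AssemblyResult:
    origin = layout.origin_read
    read = oriented_reads[origin]
    ori = layout.entry(origin).orientation
    from .seqio import flip_interval, reverse_complement
    iv = Interval(0, len(read.sequence))
    src_iv = iv if ori == "+" else iv
    row = ProvenanceRow(iv, "nanopore", origin, src_iv, ori)
    seq = read.sequence
    if config.arm == "p":
        seq = reverse_complement(seq)
        row = ProvenanceRow(iv, "nanopore", origin, src_iv,
                            "+" if ori == "-" else "-")
    return AssemblyResult(sequence=seq, provenance=[row], arm=config.arm)


def run_pipeline(reads: list[SequenceRecord], contigs: list[SequenceRecord],
                 probes: list[SequenceRecord],
                 config: PipelineConfig | None = None,
                 out_dir: str | Path | None = None) -> PipelineResult:
    """Run the five operations and return the assembled sequence bundle.

    Raises :class:`NoAnchorError` when no telomeric read passes the screen.
    With no placeable contigs, a nanopore-only combination (the anchoring
    telomeric read) is emitted with a warning.
    """
    if config is None:
        config = PipelineConfig()
    params = config.alignment

    # 1. screen
    selection = select_reads(
        reads, probes,
        min_read_length=config.min_read_length,
        min_probe_identity=config.min_probe_identity,
        min_probe_cover=config.min_probe_cover,
        min_unit_run=config.min_unit_run,
        min_occurrences=config.min_occurrences,
        params=params,
    )
    if not selection.telomeric:
        raise NoAnchorError(
            "no telomere-containing read passed the screen; cannot anchor "
            "orientation (check read lengths and the tract screen parameters)")
    reads_by_id = {r.id: r for r in reads}
    selected = {rid: reads_by_id[rid] for rid in sorted(selection.selected)}
    log.info("screen: %d telomeric, %d subtelomeric, %d mapped-telomere reads",
             len(selection.telomeric), len(selection.subtelomeric),
             len(selection.mapped_telomere))

    # 2. scaffold
    anchors = {}
    for rid in sorted(selection.telomeric):
        try:
            _, ori = orient_telomeric_read(reads_by_id[rid], selection.calls[rid])
            anchors[rid] = ori
        except ValueError as exc:
            log.warning("%s; read excluded from anchoring", exc)
    if not anchors:
        raise NoAnchorError("all telomeric reads were rejected as chimeric or "
                            "non-canonical; cannot anchor orientation")
    edges = compute_overlaps(list(selected.values()), params,
                             min_identity=config.overlap_min_identity,
                             min_length=config.overlap_min_length)
    orientation = orient_by_overlap(sorted(selected), anchors, edges)
    layout, oriented_reads = build_layout(
        selected, orientation, edges, set(anchors), arm=config.arm)
    log.info("layout: %d reads, %d bp span, origin %s",
             len(layout.entries), layout.length, layout.origin_read)

    # 3. map contigs
    masked_reads = {
        e.read_id: mask_repeats(oriented_reads[e.read_id],
                                config.mask_k, config.mask_max_occ)
        for e in layout.entries
    }
    contig_ori, tables = orient_contigs(contigs, masked_reads, params,
                                        config.orient_min_identity)
    placements = position_contigs(contigs, contig_ori, tables, layout,
                                  config.position_min_identity,
                                  params.max_chain_gap)
    ordered = order_placements(placements, layout)
    log.info("mapping: %d/%d contigs placed", len(ordered), len(contigs))

    contigs_by_id = {c.id: c for c in contigs}
    source_lengths = {c.id: len(c.sequence) for c in contigs}
    source_lengths.update({r.id: len(r.sequence) for r in reads})
    read_orientation = {e.read_id: e.orientation for e in layout.entries}

    if not ordered:
        log.warning("no contigs placed; emitting a nanopore-only combination")
        assembly = _nanopore_only(layout, oriented_reads, reads_by_id, config)
        result = PipelineResult(assembly, selection, layout, oriented_reads,
                                placements, {}, {}, [])
        if out_dir is not None:
            _write_artifacts(result, config, Path(out_dir))
        return result

    # 4. correct
    corrected: dict[str, CorrectedContig] = {}
    discrepancies: dict[str, list[Discrepancy]] = {}
    for p in ordered:
        contig = contigs_by_id[p.contig_id]
        oc = contig if p.orientation == "+" else contig.reverse_complement()
        cc, discs = correct_placement(
            p, oc, oriented_reads[p.read_id],
            threshold_bp=config.discrepancy_threshold_bp,
            flank_bp=config.border_flank_bp,
            border_min_identity=config.border_min_identity,
            params=params,
        )
        if cc.events and not check_conservation(
                cc, p, oriented_reads[p.read_id],
                config.discrepancy_threshold_bp, params):
            log.warning("contig %s: residual discrepancy after correction",
                        p.contig_id)
        corrected[p.contig_id] = cc
        discrepancies[p.contig_id] = discs
        if cc.events:
            log.info("contig %s: %d correction(s): %s", p.contig_id,
                     len(cc.events), [e.kind for e in cc.events])

    # 5. assemble
    blocks = merge_overlapping_contigs(ordered, corrected, params)
    gaps = []
    for left, right in zip(blocks, blocks[1:]):
        gaps.append((left.layout_iv[1], right.layout_iv[0]))
    fillers: list[ConnectorSegment | None] = []
    for i, gap in enumerate(gaps):
        left_tail = _block_sequence(blocks[i], corrected)[-FLANK_LEN:]
        right_head = _block_sequence(blocks[i + 1], corrected)[:FLANK_LEN]
        cands = extract_connectors(
            left_tail, right_head, gap, layout, oriented_reads,
            blocks[i].pieces[-1].placement.contig_id,
            blocks[i + 1].pieces[0].placement.contig_id, params)
        fillers.append(select_gap_filler(cands) if cands else None)

    first_start = blocks[0].layout_iv[0]
    proximal = None
    if first_start > MIN_EXTENSION:
        head = _block_sequence(blocks[0], corrected)[:FLANK_LEN]
        cands = extract_connectors(
            None, head, (0, first_start), layout, oriented_reads,
            None, blocks[0].pieces[0].placement.contig_id, params)
        if cands:
            proximal = select_gap_filler(cands)

    last_end = blocks[-1].layout_iv[1]
    tail = _block_sequence(blocks[-1], corrected)[-FLANK_LEN:]
    dist_cands = extract_connectors(
        tail, None, (last_end, layout.length), layout, oriented_reads,
        blocks[-1].pieces[-1].placement.contig_id, None, params,
        telomeric_only=True)
    distal = select_gap_filler(dist_cands) if dist_cands else None
    if distal is None:
        log.warning("no telomeric read extends past the distal contig; "
                    "assembly will not reach the telomere tract")

    assembly = combine(blocks, fillers, gaps, corrected, proximal, distal,
                       read_orientation, source_lengths, arm=config.arm)
    log.info("assembly: %d bp, %d provenance rows, %d gap(s) filled",
             len(assembly.sequence), len(assembly.provenance),
             sum(f is not None for f in fillers))
    result = PipelineResult(assembly, selection, layout, oriented_reads,
                            placements, corrected, discrepancies,
                            fillers + [proximal, distal])
    if out_dir is not None:
        _write_artifacts(result, config, Path(out_dir))
    return result


def _write_artifacts(result: PipelineResult, config: PipelineConfig,
                     out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    sel = result.selection
    with open(out_dir / "selection.tsv", "w") as fh:
        fh.write("read_id\ttelomeric\tsubtelomeric\tmapped_telomere\t"
                 "tract_start\ttract_end\tstrand\n")
        for rid in sorted(sel.calls):
            calls = sel.calls[rid]
            call = next((c for c in calls if c.is_telomeric), None)
            ts = call.tract_iv.start if call and call.tract_iv else ""
            te = call.tract_iv.end if call and call.tract_iv else ""
            strand = call.motif_strand or "" if call else ""
            fh.write(f"{rid}\t{int(rid in sel.telomeric)}\t"
                     f"{int(rid in sel.subtelomeric)}\t"
                     f"{int(rid in sel.mapped_telomere)}\t{ts}\t{te}\t{strand}\n")
    with open(out_dir / "layout.tsv", "w") as fh:
        fh.write("read_id\torientation\toffset\tlength\trole\n")
        for e in result.layout.entries:
            fh.write(f"{e.read_id}\t{e.orientation}\t{e.offset}\t"
                     f"{e.length}\t{e.role}\n")
    with open(out_dir / "placements.tsv", "w") as fh:
        fh.write("contig_id\tread_id\torientation\tlayout_start\tlayout_end\t"
                 "chain_identity\tstatus\n")
        for p in result.placements:
            s = p.placed_iv.start if p.placed_iv else ""
            e = p.placed_iv.end if p.placed_iv else ""
            ci = f"{p.chain_identity:.3f}" if p.chain else ""
            fh.write(f"{p.contig_id}\t{p.read_id or ''}\t{p.orientation or ''}\t"
                     f"{s}\t{e}\t{ci}\t{p.status}\n")
    with open(out_dir / "corrections.tsv", "w") as fh:
        fh.write("contig_id\tkind\tcontig_start\tcontig_end\tread_id\t"
                 "read_start\tread_end\tdelta\n")
        for cid in sorted(result.corrected):
            cc = result.corrected[cid]
            rid = next((p.read_id for p in result.placements
                        if p.contig_id == cid), "")
            for ev in cc.events:
                delta = abs((ev.inserted_read_iv[1] - ev.inserted_read_iv[0])
                            - (ev.removed_contig_iv[1] - ev.removed_contig_iv[0]))
                fh.write(f"{cid}\t{ev.kind}\t{ev.removed_contig_iv[0]}\t"
                         f"{ev.removed_contig_iv[1]}\t{rid}\t"
                         f"{ev.inserted_read_iv[0]}\t{ev.inserted_read_iv[1]}\t"
                         f"{delta}\n")
    name = f"assembly_{config.arm}"
    write_fasta([SequenceRecord(name, result.assembly.sequence,
                                description=f"arm={config.arm}")],
                out_dir / "assembly.fasta")
    write_provenance_tsv(result.assembly, out_dir / "provenance.tsv")
    write_agp(result.assembly, name, out_dir / "assembly.agp")
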