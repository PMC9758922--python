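"""Contig merging, connector selection, combination, and provenance."""

import numpy as np
import pytest

from npgreat.assembly import (AssemblyResult, BlockPiece, ConnectorSegment,
                              ContigBlock, combine, merge_overlapping_contigs,
                              select_gap_filler, validate_provenance)
from npgreat.contig_mapping import ContigPlacement
from npgreat.correction import CorrectedContig, Segment
from npgreat.seqio import Interval, SequenceRecord, reverse_complement

from conftest import random_dna


def _corrected(cid, seq):
    return CorrectedContig(
        cid, [Segment("contig", cid, Interval(0, len(seq)), "+", seq)])


def _placement(cid, start, end):
    return ContigPlacement(cid, "r1", "+", Interval(start, end),
                           Interval(start, end), [], "placed")


def _setup(ref, spans):
    """Contigs as exact slices of ``ref`` placed at their true spans."""
    placements, corrected, sources = [], {}, {}
    for i, (s, e) in enumerate(spans, start=1):
        cid = f"c{i}"
        placements.append(_placement(cid, s, e))
        corrected[cid] = _corrected(cid, ref[s:e])
        sources[cid] = SequenceRecord(cid, ref[s:e])
    return placements, corrected, sources


class TestMerge:
    def test_overlap_cut_at_midpoint(self, rng):
        ref = random_dna(rng, 12_000)
        placements, corrected, _ = _setup(ref, [(0, 6000), (5000, 12_000)])
        (block,) = merge_overlapping_contigs(placements, corrected)
        assert [p.cut for p in block.pieces] == [(0, 5500), (5500, 12_000)]
        seq = "".join(
            corrected[p.placement.contig_id].sequence[
                p.cut[0] - p.placement.placed_iv.start:
                p.cut[1] - p.placement.placed_iv.start]
            for p in block.pieces)
        assert seq == ref

    def test_abutting_placements_stay_separate_blocks(self, rng):
        ref = random_dna(rng, 10_000)
        placements, corrected, _ = _setup(ref, [(0, 5000), (5000, 10_000)])
        blocks = merge_overlapping_contigs(placements, corrected)
        assert [b.layout_iv for b in blocks] == [(0, 5000), (5000, 10_000)]

    def test_three_overlaps_merge_left_to_right(self, rng):
        ref = random_dna(rng, 15_000)
        spans = [(0, 6000), (4000, 11_000), (9000, 15_000)]
        placements, corrected, _ = _setup(ref, spans)
        (block,) = merge_overlapping_contigs(placements, corrected)
        seq = "".join(
            corrected[p.placement.contig_id].sequence[
                p.cut[0] - p.placement.placed_iv.start:
                p.cut[1] - p.placement.placed_iv.start]
            for p in block.pieces)
        assert seq == ref  # all-at-once oracle: the reference itself
        assert [p.cut[1] for p in block.pieces] == [5000, 10_000, 15_000]

    def test_disagreeing_overlap_joined_without_merge(self, rng):
        ref = random_dna(rng, 12_000)
        placements, corrected, _ = _setup(ref, [(0, 6000), (5000, 12_000)])
        # corrupt the right contig's copy of the overlap
        bad = random_dna(rng, 1000) + ref[6000:12_000]
        corrected["c2"] = _corrected("c2", bad)
        (block,) = merge_overlapping_contigs(placements, corrected)
        assert [p.cut for p in block.pieces] == [(0, 6000), (6000, 12_000)]


class TestSelectGapFiller:
    def _cand(self, rid, ident, cols=100, iv=(0, 100)):
        return ConnectorSegment(rid, iv, "a", "b", ident, cols, "A" * (iv[1] - iv[0]))

    def test_argmax_identity(self):
        cands = [self._cand("r1", 95.2), self._cand("r2", 92.5),
                 self._cand("r3", 94.0)]
        assert select_gap_filler(cands).read_id == "r1"

    def test_tie_broken_by_flank_columns(self):
        cands = [self._cand("r1", 95.0, cols=5000),
                 self._cand("r2", 95.0, cols=8000)]
        assert select_gap_filler(cands).read_id == "r2"

    def test_final_tie_lexicographic(self):
        cands = [self._cand("rb", 95.0), self._cand("ra", 95.0)]
        assert select_gap_filler(cands).read_id == "ra"

    def test_single_candidate(self):
        c = self._cand("r1", 80.0)
        assert select_gap_filler([c]) is c

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            select_gap_filler([])

    def test_matches_brute_force_argmax(self, rng):
        for _ in range(40):
            cands = [
                self._cand(f"r{j}", float(rng.integers(80, 100)),
                           cols=int(rng.integers(1000, 9000)))
                for j in range(int(rng.integers(1, 7)))
            ]
            best = select_gap_filler(cands)
            oracle = max(cands, key=lambda c: (c.avg_flank_identity,
                                               c.flank_columns,
                                               [-ord(x) for x in c.read_id]))
            assert best is oracle


class TestCombine:
    def test_lengths_and_provenance_rows(self, rng):
        ref = random_dna(rng, 13_000)
        placements, corrected, sources = _setup(ref, [(0, 6000), (7500, 13_000)])
        blocks = [ContigBlock([BlockPiece(p, (p.placed_iv.start, p.placed_iv.end))])
                  for p in placements]
        read = SequenceRecord("r1", ref)
        sources["r1"] = read
        filler = ConnectorSegment("r1", (6000, 7500), "c1", "c2", 99.0, 4000,
                                  ref[6000:7500])
        result = combine(blocks, [filler], [(6000, 7500)], corrected,
                         None, None, {"r1": "+"},
                         {k: len(v.sequence) for k, v in sources.items()})
        assert result.sequence == ref
        assert len(result.provenance) == 3
        validate_provenance(result, sources)

    def test_unbridged_gap_emits_n_run(self, rng):
        ref = random_dna(rng, 10_000)
        placements, corrected, sources = _setup(ref, [(0, 4000), (6000, 10_000)])
        from npgreat.assembly import BlockPiece
        blocks = [ContigBlock([BlockPiece(p, (p.placed_iv.start, p.placed_iv.end))])
                  for p in placements]
        result = combine(blocks, [None], [(4000, 6000)], corrected,
                         None, None, {}, {k: len(v.sequence)
                                          for k, v in sources.items()})
        assert result.sequence[4000:6000] == "N" * 2000
        assert len(result.sequence) == 10_000
        validate_provenance(result, sources)

    def test_p_arm_output_is_reverse_complemented(self, rng):
        ref = random_dna(rng, 5000)
        placements, corrected, sources = _setup(ref, [(0, 5000)])
        from npgreat.assembly import BlockPiece
        blocks = [ContigBlock([BlockPiece(placements[0], (0, 5000))])]
        result = combine(blocks, [], [], corrected, None, None, {},
                         {"c1": 5000}, arm="p")
        assert result.sequence == reverse_complement(ref)
        validate_provenance(result, sources)

    def test_distal_extension_appended(self, rng):
        ref = random_dna(rng, 9000)
        placements, corrected, sources = _setup(ref, [(0, 5000)])
        read = SequenceRecord("r1", ref)
        sources["r1"] = read
        from npgreat.assembly import BlockPiece
        blocks = [ContigBlock([BlockPiece(placements[0], (0, 5000))])]
        distal = ConnectorSegment("r1", (5000, 9000), "c1", None, 99.0, 2000,
                                  ref[5000:9000])
        result = combine(blocks, [], [], corrected, None, distal, {"r1": "+"},
                         {k: len(v.sequence) for k, v in sources.items()})
        assert result.sequence == ref
        validate_provenance(result, sources)


class TestEndToEndProvenance:
    def test_error_free_assembly_provenance_verbatim(self, errorfree_scenario,
                                                     errorfree_result):
        sc = errorfree_scenario
        sources = {r.id: r for r in sc.reads + sc.contigs}
        validate_provenance(errorfree_result.assembly, sources)

    def test_output_length_is_sum_of_parts(self, errorfree_result):
        total = sum(len(r.out_iv) for r in errorfree_result.assembly.provenance)
        assert total == len(errorfree_result.assembly.sequence)
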