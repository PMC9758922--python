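"""Misassembly detection, breakpoint localisation, classification, repair."""

import numpy as np
import pytest

from npgreat.alignment import AlignmentParams, LocalAlignment, align_local
from npgreat.contig_mapping import ContigPlacement
from npgreat.correction import (CorrectedContig, Discrepancy, apply_correction,
                                check_conservation, classify_discrepancy,
                                correct_placement, detect_discrepancies,
                                localize_breakpoints)
from npgreat.seqio import Interval, SequenceRecord

from conftest import random_dna


def _chain_placement(blocks):
    chain = [
        LocalAlignment("c", "r", Interval(qs, qe), Interval(ts, te), "+",
                       qe - qs, qe - qs, qe - qs)
        for qs, qe, ts, te in blocks
    ]
    return ContigPlacement("c", "r", "+", Interval(chain[0].target_iv.start,
                                                   chain[-1].target_iv.end),
                           None, chain, "placed")


class TestDetect:
    def test_large_gap_difference_emitted(self):
        # read gap 1500 bp vs contig gap 200 bp
        p = _chain_placement([(0, 5000, 0, 5000), (5200, 9000, 6500, 10_300)])
        (d,) = detect_discrepancies(p)
        assert d.delta == 1300
        assert d.contig_gap == (5000, 5200)
        assert d.read_gap == (5000, 6500)

    def test_threshold_is_strictly_greater(self):
        at = _chain_placement([(0, 1000, 0, 1000), (1000, 2000, 1100, 2100)])
        above = _chain_placement([(0, 1000, 0, 1000), (1000, 2000, 1101, 2101)])
        assert detect_discrepancies(at) == []
        assert len(detect_discrepancies(above)) == 1

    def test_single_alignment_has_no_gaps(self):
        p = _chain_placement([(0, 5000, 0, 5000)])
        assert detect_discrepancies(p) == []


@pytest.fixture(scope="module")
def deletion_case():
    """Reference, a contig with a planted 1.5 kb deletion, and the read."""
    rng = np.random.default_rng(11)
    ref = random_dna(rng, 12_000)
    del_at, del_len = 5000, 1500
    contig = SequenceRecord("c", ref[:del_at] + ref[del_at + del_len:])
    read = SequenceRecord("r", ref)
    alns = [a for a in align_local(contig, read,
                                   AlignmentParams(respect_mask=False),
                                   method="seeded") if a.strand == "+"]
    from npgreat.alignment import longest_contiguous_segment
    chain = longest_contiguous_segment(alns)
    placement = ContigPlacement("c", "r", "+",
                                Interval(chain[0].target_iv.start,
                                         chain[-1].target_iv.end),
                                None, chain, "placed")
    return ref, contig, read, placement, del_at, del_len


class TestLocalize:
    def test_planted_deletion_breakpoints_recovered(self, deletion_case):
        ref, contig, read, placement, del_at, del_len = deletion_case
        (d,) = detect_discrepancies(placement)
        r = localize_breakpoints(d, contig.sequence, read.sequence)
        assert r.refined
        assert abs(r.contig_gap[0] - del_at) <= 10
        assert abs(r.contig_gap[1] - del_at) <= 10
        assert abs(r.read_gap[0] - del_at) <= 10
        assert abs(r.read_gap[1] - (del_at + del_len)) <= 10

    def test_unalignable_borders_stay_unclassified(self, rng):
        d = Discrepancy("c", "r", (1000, 1000), (1000, 2500), 1500)
        contig = random_dna(rng, 3000)
        read = random_dna(rng, 4000)  # unrelated: borders cannot align
        r = localize_breakpoints(d, contig, read)
        assert not r.refined
        assert r.kind == "unclassified"


@pytest.fixture(scope="module")
def vntr_case():
    """Read gap holds a 40x37 bp array; contig keeps only 3 units."""
    rng = np.random.default_rng(13)
    unit = random_dna(rng, 37)
    left = random_dna(rng, 4000)
    right = random_dna(rng, 4000)
    read = SequenceRecord("r", left + unit * 40 + right)
    contig = SequenceRecord("c", left + unit * 3 + right)
    return unit, contig, read


class TestClassify:
    def test_collapsed_vntr_called_tandem_repeat(self, vntr_case):
        unit, contig, read = vntr_case
        d = Discrepancy("c", "r", (4000, 4000 + 37 * 3),
                        (4000, 4000 + 37 * 40), 37 * 37, refined=True)
        assert classify_discrepancy(d, contig.sequence, read.sequence) == \
            "tandem_repeat"

    def test_unique_gap_called_deletion(self, deletion_case):
        ref, contig, read, placement, del_at, del_len = deletion_case
        (d,) = detect_discrepancies(placement)
        r = localize_breakpoints(d, contig.sequence, read.sequence)
        assert classify_discrepancy(r, contig.sequence, read.sequence) == \
            "deletion"

    def test_contig_expansion_called_deletion(self, rng):
        # contig carries 1 kb the read lacks: same mechanism, shorter patch
        base = random_dna(rng, 8000)
        insert = random_dna(rng, 1000)
        contig = SequenceRecord("c", base[:4000] + insert + base[4000:])
        read = SequenceRecord("r", base)
        d = Discrepancy("c", "r", (4000, 5000), (4000, 4000), 1000, refined=True)
        assert classify_discrepancy(d, contig.sequence, read.sequence) == \
            "deletion"

    def test_unrefined_rejected(self):
        with pytest.raises(ValueError):
            classify_discrepancy(Discrepancy("c", "r", (0, 0), (0, 10), 10),
                                 "ACGT", "ACGT")


class TestApply:
    def test_deletion_split_restores_read_segment(self, deletion_case):
        ref, contig, read, placement, del_at, del_len = deletion_case
        cc, discs = correct_placement(placement, contig, read)
        assert [e.kind for e in cc.events] == ["deletion"]
        # pieces + patch reproduce the reference around the deletion
        assert cc.sequence == ref
        assert check_conservation(cc, placement, read)

    def test_pieces_are_verbatim_contig_substrings(self, deletion_case):
        ref, contig, read, placement, *_ = deletion_case
        cc, _ = correct_placement(placement, contig, read)
        for seg in cc.segments:
            if seg.source_type == "contig":
                assert contig.sequence[seg.iv.start:seg.iv.end] == seg.sequence
            else:
                assert read.sequence[seg.iv.start:seg.iv.end] == seg.sequence

    def test_tr_patch_length_matches_read_gap(self, vntr_case):
        unit, contig, read = vntr_case
        params = AlignmentParams(respect_mask=False)
        alns = [a for a in align_local(contig, read, params, method="seeded")
                if a.strand == "+"]
        from npgreat.alignment import longest_contiguous_segment
        chain = longest_contiguous_segment(alns)
        placement = ContigPlacement("c", "r", "+",
                                    Interval(chain[0].target_iv.start,
                                             chain[-1].target_iv.end),
                                    None, chain, "placed")
        cc, _ = correct_placement(placement, contig, read)
        tr_events = [e for e in cc.events if e.kind == "tandem_repeat"]
        assert len(tr_events) == 1
        e = tr_events[0]
        # the patch restores at least the 37 missing copies (the kept units
        # may remain in the flanking pieces when borders align inside the
        # array); the reconstructed contig carries the full-length array
        patched = e.inserted_read_iv[1] - e.inserted_read_iv[0]
        assert 37 * 37 - 20 <= patched <= 37 * 40
        assert cc.sequence == read.sequence  # full-array reconstruction

    def test_terminal_tr_leaves_single_flanking_piece(self, rng):
        contig = SequenceRecord("c", random_dna(rng, 3000) + "ACGTACG" * 20)
        d = Discrepancy("c", "r", (3000, len(contig.sequence)), (5000, 7000),
                        2000 - 140, kind="tandem_repeat", refined=True)
        left_iv, right_iv, patch = apply_correction(contig.sequence, d)
        assert left_iv == (0, 3000)
        assert right_iv == (len(contig.sequence), len(contig.sequence))
        assert patch == (5000, 7000)

    def test_out_of_bounds_breakpoints_rejected(self):
        d = Discrepancy("c", "r", (10, 99), (0, 50), 100,
                        kind="deletion", refined=True)
        with pytest.raises(ValueError):
            apply_correction("ACGT" * 10, d)

    def test_two_events_applied_left_to_right(self, rng):
        unit1 = random_dna(rng, 31)
        unit2 = random_dna(rng, 43)
        a, b, c = (random_dna(rng, 4000) for _ in range(3))
        read = SequenceRecord("r", a + unit1 * 30 + b + unit2 * 25 + c)
        contig = SequenceRecord("c", a + unit1 * 3 + b + unit2 * 2 + c)
        params = AlignmentParams(respect_mask=False)
        alns = [x for x in align_local(contig, read, params, method="seeded")
                if x.strand == "+"]
        from npgreat.alignment import longest_contiguous_segment
        chain = longest_contiguous_segment(alns)
        placement = ContigPlacement("c", "r", "+",
                                    Interval(chain[0].target_iv.start,
                                             chain[-1].target_iv.end),
                                    None, chain, "placed")
        cc, _ = correct_placement(placement, contig, read)
        assert [e.kind for e in cc.events] == ["tandem_repeat", "tandem_repeat"]
        starts = [e.removed_contig_iv[0] for e in cc.events]
        assert starts == sorted(starts)
        assert cc.sequence == read.sequence
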