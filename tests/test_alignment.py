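"""Local aligner contract: exact-DP oracle agreement, strand symmetry,
masking, and colinear chaining."""

import numpy as np
import pytest

from npgreat.alignment import (AlignmentParams, LocalAlignment, align_local,
                               longest_contiguous_segment, mask_repeats,
                               percent_identity)
from npgreat.seqio import Interval, SequenceRecord, reverse_complement

from conftest import random_dna


def sw_score_oracle(q: str, t: str, match=1, mismatch=-1,
                    gap_open=-2, gap_extend=-1) -> int:
    """Textbook quadratic affine-gap local alignment, score only."""
    n, m = len(q), len(t)
    NEG = -(10 ** 9)
    H = [0] * (m + 1)
    F = [NEG] * (m + 1)
    best = 0
    for i in range(1, n + 1):
        diag = H[0]
        e = NEG
        for j in range(1, m + 1):
            e = max(e + gap_extend, H[j - 1] + gap_open + gap_extend)
            F[j] = max(F[j] + gap_extend, H[j] + gap_open + gap_extend)
            sub = match if q[i - 1] == t[j - 1] else mismatch
            h = max(0, diag + sub, e, F[j])
            diag = H[j]
            H[j] = h
            if h > best:
                best = h
    return best


def top_score(query: SequenceRecord, target: SequenceRecord,
              params: AlignmentParams) -> int:
    alns = align_local(query, target, params)
    return alns[0].score if alns else 0


class TestAlignLocal:
    def test_self_alignment_is_perfect(self, rng):
        seq = random_dna(rng, 1000)
        alns = align_local(SequenceRecord("q", seq), SequenceRecord("t", seq))
        a = alns[0]
        assert a.strand == "+"
        assert a.percent_identity == 100.0
        assert a.query_iv == Interval(0, 1000)
        assert a.target_iv == Interval(0, 1000)

    def test_reverse_complement_query_hits_minus_strand(self, rng):
        seq = random_dna(rng, 1000)
        alns = align_local(SequenceRecord("q", reverse_complement(seq)),
                           SequenceRecord("t", seq))
        assert alns[0].strand == "-"
        assert alns[0].percent_identity == 100.0

    def test_planted_substitution_density_sets_identity(self, rng):
        seq = random_dna(rng, 1000)
        chars = list(seq)
        # keep ends clean so the optimal local alignment spans everything
        pos = rng.choice(np.arange(20, 980), size=50, replace=False)
        for p in pos:
            chars[p] = "ACGT"[("ACGT".index(chars[p]) + 1) % 4]
        alns = align_local(SequenceRecord("q", "".join(chars)),
                           SequenceRecord("t", seq))
        assert alns[0].percent_identity == pytest.approx(95.0)

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            align_local(SequenceRecord("q", ""), SequenceRecord("t", "ACGT"))

    def test_seeded_engine_locates_long_substring(self, rng):
        seq = random_dna(rng, 60_000)
        alns = align_local(SequenceRecord("q", seq[10_000:50_000]),
                           SequenceRecord("t", seq))
        a = alns[0]
        assert a.percent_identity == 100.0
        assert a.target_iv == Interval(10_000, 50_000)

    def test_agrees_with_quadratic_oracle(self, rng):
        params = AlignmentParams(min_score=1)
        for _ in range(40):
            q = random_dna(rng, int(rng.integers(50, 160)))
            t = random_dna(rng, int(rng.integers(50, 160)))
            got = top_score(SequenceRecord("q", q), SequenceRecord("t", t), params)
            want = max(sw_score_oracle(q, t),
                       sw_score_oracle(reverse_complement(q), t))
            assert got == want

    def test_strand_symmetry(self, rng):
        params = AlignmentParams(min_score=1)
        for _ in range(20):
            base = random_dna(rng, 300)
            q = SequenceRecord("q", base[40:260])
            qrc = SequenceRecord("q", reverse_complement(base[40:260]))
            t = SequenceRecord("t", base)
            fwd = align_local(q, t, params)[0]
            rev = align_local(qrc, t, params)[0]
            assert fwd.score == rev.score
            assert {fwd.strand, rev.strand} == {"+", "-"}

    def test_deterministic(self, rng):
        seq = random_dna(rng, 30_000)
        q = SequenceRecord("q", seq[5000:25_000])
        t = SequenceRecord("t", seq)
        assert align_local(q, t) == align_local(q, t)


class TestPercentIdentity:
    @pytest.mark.parametrize("matches,columns,expected",
                             [(98, 100, 98.0), (100, 100, 100.0), (0, 100, 0.0)])
    def test_ratio(self, matches, columns, expected):
        a = LocalAlignment("q", "t", Interval(0, 100), Interval(0, 100), "+",
                           matches, columns, 1)
        assert percent_identity(a) == expected


class TestMaskRepeats:
    def test_pure_tandem_tract_fully_masked(self, rng):
        tract = "TTAGGG" * 100
        rec = mask_repeats(SequenceRecord("r", tract), k=12, max_occ=5)
        assert rec.mask == [Interval(0, len(tract))]

    def test_random_sequence_unmasked_matches_kmer_count_oracle(self, rng):
        seq = random_dna(rng, 1000)
        k, max_occ = 15, 2
        counts = {}
        for s in (seq, reverse_complement(seq)):
            for i in range(len(s) - k + 1):
                counts[s[i:i + k]] = counts.get(s[i:i + k], 0) + 1
        over = {km for km, c in counts.items() if c > max_occ}
        rec = mask_repeats(SequenceRecord("r", seq), k=k, max_occ=max_occ)
        if not over:
            assert rec.mask == []
        else:  # oracle says which positions must be covered
            covered = set()
            for iv in rec.mask:
                covered.update(range(iv.start, iv.end))
            for i in range(len(seq) - k + 1):
                if counts[seq[i:i + k]] + counts.get(
                        reverse_complement(seq[i:i + k]), 0) > max_occ:
                    assert set(range(i, i + k)) <= covered

    def test_idempotent(self, rng):
        seq = random_dna(rng, 2000) + "TTAGGG" * 50
        once = mask_repeats(SequenceRecord("r", seq))
        twice = mask_repeats(once)
        assert once.mask == twice.mask
        assert once.sequence == twice.sequence

    def test_short_sequence_unchanged(self):
        rec = SequenceRecord("r", "ACGTACGTAC")
        assert mask_repeats(rec, k=15, max_occ=2) is rec


def _aln(qs, qe, ts, te, score, strand="+"):
    cols = max(qe - qs, te - ts)
    return LocalAlignment("q", "t", Interval(qs, qe), Interval(ts, te),
                          strand, cols, cols, score)


def _colinear(chain, max_gap=2000, slack=100):
    for a, b in zip(chain, chain[1:]):
        qg = b.query_iv.start - a.query_iv.end
        tg = b.target_iv.start - a.target_iv.end
        if qg < -slack or tg < -slack or qg > max_gap or tg > max_gap:
            return False
    return True


def brute_force_chain(alns):
    """Enumerate all ordered subsets; maximal query length, then score."""
    from itertools import combinations

    best = None
    n = len(alns)
    for r in range(1, n + 1):
        for combo in combinations(sorted(alns, key=lambda a: a.query_iv.start), r):
            if not _colinear(combo):
                continue
            key = (sum(len(a.query_iv) for a in combo),
                   sum(a.score for a in combo),
                   -combo[0].target_iv.start)
            if best is None or key > best[0]:
                best = (key, list(combo))
    return best[1]


class TestChaining:
    def test_single_alignment_is_its_own_chain(self):
        a = _aln(0, 100, 0, 100, 100)
        assert longest_contiguous_segment([a]) == [a]

    def test_colinear_pair_beats_longer_offdiagonal(self):
        a = _aln(0, 400, 0, 400, 400)
        b = _aln(500, 800, 500, 800, 300)
        c = _aln(100, 600, 20_000, 20_500, 500)
        got = longest_contiguous_segment([a, b, c])
        assert got == [a, b] == brute_force_chain([a, b, c])

    def test_non_colinear_takes_argmax(self):
        a = _aln(0, 500, 0, 500, 500)
        b = _aln(100, 300, 30_000, 30_200, 200)
        assert longest_contiguous_segment([a, b]) == [a]

    def test_matches_brute_force_on_random_instances(self, rng):
        for _ in range(30):
            alns = []
            for _ in range(int(rng.integers(2, 6))):
                qs = int(rng.integers(0, 5000))
                qe = qs + int(rng.integers(50, 1500))
                ts = int(rng.integers(0, 5000))
                te = ts + (qe - qs)
                alns.append(_aln(qs, qe, ts, te, qe - qs))
            got = longest_contiguous_segment(alns)
            want = brute_force_chain(alns)
            assert (sum(len(a.query_iv) for a in got),
                    sum(a.score for a in got)) == \
                   (sum(len(a.query_iv) for a in want),
                    sum(a.score for a in want))

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            longest_contiguous_segment([])
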