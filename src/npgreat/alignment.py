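"""Deterministic pairwise local alignment, repeat masking, and chaining.

Two alignment engines sit behind one contract:

* an exact affine-gap Smith-Waterman (numba-compiled) used whenever the DP
  table fits a configurable cell budget — this is the canonical definition of
  the "Segment Pair" local score used to resolve orientation conflicts;
* a k-mer seed / colinear-chain / edlib-refined engine for ultralong inputs,
  which reports one scored local alignment per colinear anchor segment.
  Segments deliberately break at indels larger than ``seg_break`` so that
  downstream misassembly detection can read the inter-segment gaps.

Scoring convention: a gap of length L costs ``gap_open + L * gap_extend``
(both negative).  Percent identity is ``100 * matches / columns`` where
columns counts all aligned columns including gaps.
"""

from __future__ import annotations

import re
from bisect import bisect_left
from dataclasses import dataclass, replace
from functools import lru_cache

import edlib
import numpy as np
from numba import njit

from .seqio import Interval, SequenceRecord, reverse_complement

__all__ = [
    "AlignmentParams",
    "LocalAlignment",
    "align_local",
    "align_global_scored",
    "percent_identity",
    "mask_repeats",
    "longest_contiguous_segment",
    "chain_identity",
    "chain_score",
]

_CIGAR_RE = re.compile(r"(\d+)([=XIDM])")

_BASE_LUT = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _BASE_LUT[ord(_b)] = _i


@dataclass(frozen=True)
class AlignmentParams:
    """Scoring and engine parameters for :func:`align_local`."""

    match: int = 1
    mismatch: int = -1
    gap_open: int = -2
    gap_extend: int = -1
    min_score: int = 30
    respect_mask: bool = True
    # seeded-engine knobs
    seed_k: int = 13
    seed_max_occ: int = 50
    max_diag_jump: int = 500
    seg_break: int = 100
    max_anchor_gap: int = 2000
    min_segment_span: int = 25
    # exact-engine budget (DP cells)
    exact_dp_limit: int = 16_000_000
    # chaining
    max_chain_gap: int = 2000
    chain_overlap_slack: int = 100

    def __post_init__(self) -> None:
        if self.match <= 0:
            raise ValueError("match score must be positive")
        if self.mismatch > 0 or self.gap_open > 0 or self.gap_extend > 0:
            raise ValueError("penalties must be <= 0")


@dataclass(frozen=True)
class LocalAlignment:
    """A scored, stranded pairwise local match.

    ``query_iv`` is always on forward query coordinates; ``strand`` '-' means
    the reverse complement of the query segment matches the target segment.
    """

    query_id: str
    target_id: str
    query_iv: Interval
    target_iv: Interval
    strand: str
    matches: int
    columns: int
    score: int

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError("strand must be '+' or '-'")
        if not (0 <= self.matches <= self.columns):
            raise ValueError("matches must lie in [0, columns]")
        if self.columns < max(len(self.query_iv), len(self.target_iv)):
            raise ValueError("columns below interval length")

    @property
    def percent_identity(self) -> float:
        return 100.0 * self.matches / self.columns


def percent_identity(aln: LocalAlignment) -> float:
    """100 * matches / columns; error on zero columns."""
    if aln.columns == 0:
        raise ValueError("alignment has zero columns")
    return 100.0 * aln.matches / aln.columns


# ---------------------------------------------------------------------------
# exact affine Smith-Waterman (numba)
# ---------------------------------------------------------------------------

@njit(cache=False)
def _sw_fill(q, t, match, mismatch, gap_open, gap_extend):  # pragma: no cover
    n = q.shape[0]
    m = t.shape[0]
    NEG = -1 << 40
    H = np.zeros(m + 1, dtype=np.int64)
    Hdiag = np.int64(0)
    E = np.full(m + 1, NEG, dtype=np.int64)
    F = np.full(m + 1, NEG, dtype=np.int64)
    ptr = np.zeros((n + 1, m + 1), dtype=np.uint8)
    best = np.int64(0)
    bi = 0
    bj = 0
    for i in range(1, n + 1):
        Hdiag = H[0]
        H[0] = 0
        Eval = NEG
        for j in range(1, m + 1):
            # E: gap consuming target (horizontal)
            e_open = H[j - 1] + gap_open + gap_extend
            e_ext = Eval + gap_extend
            if e_ext > e_open:
                Eval = e_ext
                ebit = np.uint8(4)
            else:
                Eval = e_open
                ebit = np.uint8(0)
            # F: gap consuming query (vertical)
            f_open = H[j] + gap_open + gap_extend
            f_ext = F[j] + gap_extend
            if f_ext > f_open:
                F[j] = f_ext
                fbit = np.uint8(8)
            else:
                F[j] = f_open
                fbit = np.uint8(0)
            sub = match if q[i - 1] == t[j - 1] else mismatch
            diag = Hdiag + sub
            h = np.int64(0)
            src = np.uint8(0)
            if diag > h:
                h = diag
                src = np.uint8(1)
            if Eval > h:
                h = Eval
                src = np.uint8(2)
            if F[j] > h:
                h = F[j]
                src = np.uint8(3)
            Hdiag = H[j]
            H[j] = h
            ptr[i, j] = src | ebit | fbit
            if h > best:
                best = h
                bi = i
                bj = j
    return best, bi, bj, ptr


@njit(cache=False)
def _sw_traceback(q, t, ptr, bi, bj):  # pragma: no cover
    i = bi
    j = bj
    matches = 0
    columns = 0
    state = 0  # 0=H 1=E 2=F
    while True:
        p = ptr[i, j]
        if state == 0:
            src = p & 3
            if src == 0:
                break
            if src == 1:
                columns += 1
                if q[i - 1] == t[j - 1]:
                    matches += 1
                i -= 1
                j -= 1
            elif src == 2:
                state = 1
            else:
                state = 2
        elif state == 1:
            ext = p & 4
            columns += 1
            j -= 1
            if ext == 0:
                state = 0
        else:
            ext = p & 8
            columns += 1
            i -= 1
            if ext == 0:
                state = 0
    return i, j, matches, columns


def _encode(seq: str) -> np.ndarray:
    return _BASE_LUT[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def _exact_strand(qseq: str, tseq: str, params: AlignmentParams):
    q = _encode(qseq)
    t = _encode(tseq)
    score, bi, bj, ptr = _sw_fill(
        q, t, params.match, params.mismatch, params.gap_open, params.gap_extend
    )
    if score < params.min_score or score <= 0:
        return None
    qs, ts, matches, columns = _sw_traceback(q, t, ptr, bi, bj)
    return int(score), int(qs), int(bi), int(ts), int(bj), int(matches), int(columns)


# ---------------------------------------------------------------------------
# seeded engine
# ---------------------------------------------------------------------------

def _kmer_codes(arr: np.ndarray, k: int) -> np.ndarray:
    """Packed 2-bit k-mer codes; -1 where the window contains non-ACGT."""
    n = arr.shape[0]
    if n < k:
        return np.empty(0, dtype=np.int64)
    nk = n - k + 1
    codes = np.zeros(nk, dtype=np.int64)
    for off in range(k):
        codes = (codes << 2) | arr[off:off + nk].astype(np.int64)
    bad = (arr > 3).astype(np.int64)
    cs = np.concatenate(([0], np.cumsum(bad)))
    invalid = (cs[k:] - cs[:-k]) > 0
    codes[invalid] = -1
    return codes


def _window_blocked(mask_bool: np.ndarray, k: int) -> np.ndarray:
    """True at positions whose k-window touches a masked base."""
    cs = np.concatenate(([0], np.cumsum(mask_bool.astype(np.int64))))
    return (cs[k:] - cs[:-k]) > 0


def _mask_bool(record: SequenceRecord) -> np.ndarray:
    out = np.zeros(len(record.sequence), dtype=bool)
    for iv in record.mask:
        out[iv.start:iv.end] = True
    return out


class _TargetIndex:
    """Sorted k-mer index over one target sequence."""

    def __init__(self, tseq: str, k: int, blocked: np.ndarray | None):
        codes = _kmer_codes(_encode(tseq), k)
        if codes.size and blocked is not None:
            codes = codes.copy()
            codes[blocked[: codes.shape[0]]] = -1
        valid = codes >= 0
        self.pos = np.flatnonzero(valid)
        sub = codes[self.pos]
        order = np.argsort(sub, kind="stable")
        self.sorted_codes = sub[order]
        self.sorted_pos = self.pos[order]

    def anchors(self, qcodes: np.ndarray, max_occ: int):
        qvalid = np.flatnonzero(qcodes >= 0)
        if qvalid.size == 0 or self.sorted_codes.size == 0:
            return (np.empty(0, dtype=np.int64),) * 2
        qc = qcodes[qvalid]
        lo = np.searchsorted(self.sorted_codes, qc, side="left")
        hi = np.searchsorted(self.sorted_codes, qc, side="right")
        cnt = hi - lo
        keep = (cnt > 0) & (cnt <= max_occ)
        if not keep.any():
            return (np.empty(0, dtype=np.int64),) * 2
        starts = lo[keep]
        counts = cnt[keep]
        total = int(counts.sum())
        offs = np.arange(total, dtype=np.int64) - np.repeat(
            np.cumsum(counts) - counts, counts
        )
        j = self.sorted_pos[np.repeat(starts, counts) + offs]
        i = np.repeat(qvalid[keep], counts)
        return i.astype(np.int64), j


def _lis_chain(i_arr: np.ndarray, j_arr: np.ndarray):
    """Longest chain with strictly increasing i and j (anchors count)."""
    order = np.lexsort((-j_arr, i_arr))
    ii = i_arr[order]
    jj = j_arr[order]
    n = ii.shape[0]
    tails: list[int] = []
    tails_idx: list[int] = []
    parent = np.full(n, -1, dtype=np.int64)
    for a in range(n):
        v = jj[a]
        p = bisect_left(tails, v)
        if p > 0:
            parent[a] = tails_idx[p - 1]
        if p == len(tails):
            tails.append(v)
            tails_idx.append(a)
        else:
            tails[p] = v
            tails_idx[p] = a
    chain = []
    a = tails_idx[-1]
    while a >= 0:
        chain.append((int(ii[a]), int(jj[a])))
        a = parent[a]
    chain.reverse()
    return chain


def _cigar_stats(cigar: str, params: AlignmentParams):
    matches = 0
    columns = 0
    score = 0
    for num, op in _CIGAR_RE.findall(cigar):
        length = int(num)
        columns += length
        if op == "=":
            matches += length
            score += length * params.match
        elif op == "X":
            score += length * params.mismatch
        elif op in "ID":
            score += params.gap_open + length * params.gap_extend
        else:  # 'M' should not appear with edlib task=path, guard anyway
            raise ValueError("ambiguous 'M' op in cigar")
    return matches, columns, score


def _run_items(cigar: str, params: AlignmentParams):
    """Cigar runs as (score, dq, dt, matches, columns) items."""
    items = []
    for num, op in _CIGAR_RE.findall(cigar):
        n = int(num)
        if op == "=":
            items.append((n * params.match, n, n, n, n))
        elif op == "X":
            items.append((n * params.mismatch, n, n, 0, n))
        elif op == "I":  # consumes query only
            items.append((params.gap_open + n * params.gap_extend, n, 0, 0, n))
        elif op == "D":  # consumes target only
            items.append((params.gap_open + n * params.gap_extend, 0, n, 0, n))
        else:
            raise ValueError("ambiguous 'M' op in cigar")
    return items


def _trimmed_stats(qsub: str, tsub: str, params: AlignmentParams):
    """Maximal-scoring contiguous sub-alignment of the global qsub/tsub path.

    Seed-bounded segments can over-extend into non-homologous sequence when
    a chance k-mer collision joins the anchor chain; trimming to the best
    run-level sub-path (Kadane over homogeneous cigar runs, which is optimal
    because runs score uniformly) restores locally optimal ends.  Returns
    (q0, q1, t0, t1, matches, columns, score) as offsets into the inputs,
    or None if nothing scores positively.
    """
    if qsub == tsub:
        n = len(qsub)
        return 0, n, 0, n, n, n, n * params.match
    res = edlib.align(qsub, tsub, mode="NW", task="path")
    items = _run_items(res["cigar"], params)
    best_sum = 0
    best_range = None
    cur_sum = 0
    start = 0
    for idx, it in enumerate(items):
        if cur_sum <= 0:
            cur_sum = it[0]
            start = idx
        else:
            cur_sum += it[0]
        if cur_sum > best_sum:
            best_sum = cur_sum
            best_range = (start, idx + 1)
    if best_range is None:
        return None
    a, b = best_range
    pq = 0
    pt = 0
    for it in items[:a]:
        pq += it[1]
        pt += it[2]
    dq = sum(it[1] for it in items[a:b])
    dt = sum(it[2] for it in items[a:b])
    matches = sum(it[3] for it in items[a:b])
    columns = sum(it[4] for it in items[a:b])
    if dq == 0 or dt == 0 or columns == 0:
        return None
    return pq, pq + dq, pt, pt + dt, matches, columns, best_sum


def align_global_scored(qseq: str, tseq: str, params: AlignmentParams):
    """Global (NW) alignment of two strings, scored under ``params``.

    Returns (matches, columns, score).  Identical strings short-circuit.
    """
    if qseq == tseq:
        n = len(qseq)
        return n, n, n * params.match
    if not qseq or not tseq:
        length = max(len(qseq), len(tseq))
        return 0, length, params.gap_open + length * params.gap_extend
    res = edlib.align(qseq, tseq, mode="NW", task="path")
    return _cigar_stats(res["cigar"], params)


def _segments_from_chain(chain, k: int, params: AlignmentParams):
    """Split an anchor chain where the implied indel exceeds seg_break."""
    segs = []
    cur = [chain[0]]
    for (pi, pj), (ci, cj) in zip(chain, chain[1:]):
        di = ci - pi
        dj = cj - pj
        if abs(di - dj) > params.seg_break or di > params.max_anchor_gap or dj > params.max_anchor_gap:
            segs.append(cur)
            cur = [(ci, cj)]
        else:
            cur.append((ci, cj))
    segs.append(cur)
    return [
        (s[0][0], s[-1][0] + k, s[0][1], s[-1][1] + k)
        for s in segs
        if s[-1][0] + k - s[0][0] >= params.min_segment_span
    ]


def _seeded_strand(qseq: str, target: SequenceRecord, params: AlignmentParams,
                   index: _TargetIndex):
    k = params.seed_k
    qcodes = _kmer_codes(_encode(qseq), k)
    i_arr, j_arr = index.anchors(qcodes, params.seed_max_occ)
    if i_arr.size == 0:
        return []
    diag = j_arr - i_arr
    order = np.lexsort((i_arr, diag))
    i_arr = i_arr[order]
    j_arr = j_arr[order]
    diag = diag[order]
    breaks = np.flatnonzero(np.diff(diag) > params.max_diag_jump) + 1
    bounds = np.concatenate(([0], breaks, [diag.shape[0]]))
    results = []
    tseq = target.sequence
    for b in range(bounds.shape[0] - 1):
        lo, hi = int(bounds[b]), int(bounds[b + 1])
        if hi - lo < 1:
            continue
        chain = _lis_chain(i_arr[lo:hi], j_arr[lo:hi])
        for qs, qe, ts, te in _segments_from_chain(chain, k, params):
            st = _trimmed_stats(qseq[qs:qe], tseq[ts:te], params)
            if st is None:
                continue
            q0, q1, t0, t1, matches, columns, score = st
            if score >= params.min_score:
                results.append((score, qs + q0, qs + q1, ts + t0, ts + t1,
                                matches, columns))
    return results


# ---------------------------------------------------------------------------
# public aligner
# ---------------------------------------------------------------------------

def align_local(query: SequenceRecord, target: SequenceRecord,
                params: AlignmentParams | None = None,
                method: str = "auto") -> list[LocalAlignment]:
    """All local alignments between query and target with score >= min_score.

    Both strands are searched.  With ``respect_mask`` (default), seeds are not
    taken from soft-masked spans of the target; the exact engine, used for
    small inputs, ignores masking.  Output is sorted by
    (score desc, target start, query start) and is deterministic.
    """
    if params is None:
        params = AlignmentParams()
    if not query.sequence or not target.sequence:
        raise ValueError("cannot align empty sequences")
    nq = len(query.sequence)
    if method == "auto":
        exact = nq * len(target.sequence) <= params.exact_dp_limit
    elif method == "exact":
        exact = True
    elif method == "seeded":
        exact = False
    else:
        raise ValueError(f"unknown method {method!r}")

    raw: list[tuple] = []
    strands = [("+", query.sequence), ("-", reverse_complement(query.sequence))]
    if exact:
        for strand, qseq in strands:
            hit = _exact_strand(qseq, target.sequence, params)
            if hit is not None:
                raw.append((strand,) + hit)
    else:
        blocked = None
        if params.respect_mask and target.mask:
            blocked = _window_blocked(_mask_bool(target), params.seed_k)
        index = _TargetIndex(target.sequence, params.seed_k, blocked)
        for strand, qseq in strands:
            for score, qs, qe, ts, te, matches, columns in _seeded_strand(
                qseq, target, params, index
            ):
                raw.append((strand, score, qs, qe, ts, te, matches, columns))

    out = []
    seen = set()
    for strand, score, qs, qe, ts, te, matches, columns in raw:
        if strand == "-":
            q_iv = Interval(nq - qe, nq - qs)
        else:
            q_iv = Interval(qs, qe)
        key = (strand, q_iv.start, q_iv.end, ts, te)
        if key in seen:
            continue
        seen.add(key)
        out.append(
            LocalAlignment(
                query_id=query.id,
                target_id=target.id,
                query_iv=q_iv,
                target_iv=Interval(ts, te),
                strand=strand,
                matches=matches,
                columns=columns,
                score=score,
            )
        )
    out.sort(key=lambda a: (-a.score, a.target_iv.start, a.query_iv.start, a.strand))
    return out


# ---------------------------------------------------------------------------
# repeat masking
# ---------------------------------------------------------------------------

def mask_repeats(record: SequenceRecord, k: int = 15, max_occ: int = 8) -> SequenceRecord:
    """Soft-mask positions covered by k-mers occurring > max_occ times.

    Occurrences are counted over both strands within the record itself.  The
    operation is idempotent and never changes sequence letters.  With k odd
    there are no reverse-complement-palindromic k-mers, so no double counting.
    """
    if k < 8:
        raise ValueError("k must be >= 8")
    n = len(record.sequence)
    if k > n:
        return record
    arr = _encode(record.sequence)
    codes = _kmer_codes(arr, k)
    rc_codes = _kmer_codes(_encode(reverse_complement(record.sequence)), k)
    valid = codes >= 0
    uniq, counts = np.unique(codes[valid], return_counts=True)

    def lookup(vals: np.ndarray) -> np.ndarray:
        idx = np.searchsorted(uniq, vals)
        idx_c = np.clip(idx, 0, uniq.shape[0] - 1)
        hit = uniq[idx_c] == vals
        out = np.where(hit, counts[idx_c], 0)
        out[vals < 0] = 0
        return out

    occ = lookup(codes)
    # reverse complement of the k-mer at p is rc_codes[n - k - p]
    occ = occ + lookup(rc_codes[::-1])
    flagged = np.flatnonzero((occ > max_occ) & valid)
    if flagged.size == 0:
        return record
    cover = np.zeros(n + 1, dtype=np.int64)
    np.add.at(cover, flagged, 1)
    np.add.at(cover, flagged + k, -1)
    covered = np.cumsum(cover[:-1]) > 0
    # boolean runs -> intervals
    d = np.diff(covered.astype(np.int8), prepend=0, append=0)
    starts = np.flatnonzero(d == 1)
    ends = np.flatnonzero(d == -1)
    new = [Interval(int(s), int(e)) for s, e in zip(starts, ends)]
    return record.with_mask(record.mask + new)


# ---------------------------------------------------------------------------
# chaining of alignment blocks
# ---------------------------------------------------------------------------

def chain_score(chain: list[LocalAlignment]) -> int:
    return sum(a.score for a in chain)


def chain_identity(chain: list[LocalAlignment]) -> float:
    cols = sum(a.columns for a in chain)
    if cols == 0:
        raise ValueError("empty chain")
    return 100.0 * sum(a.matches for a in chain) / cols


def longest_contiguous_segment(alns: list[LocalAlignment],
                               max_chain_gap: int = 2000,
                               overlap_slack: int = 100) -> list[LocalAlignment]:
    """Maximal total-query-length chain of colinear alignments.

    Colinear: monotone in both query and target with inter-block gaps at most
    ``max_chain_gap`` (small overlaps up to ``overlap_slack`` tolerated).
    Ties break by higher summed score, then smaller target start.
    """
    if not alns:
        raise ValueError("no alignments to chain")
    ids = {(a.query_id, a.target_id, a.strand) for a in alns}
    if len(ids) > 1:
        raise ValueError("chain input must share query, target and strand")
    blocks = sorted(alns, key=lambda a: (a.query_iv.start, a.target_iv.start, -a.score))
    m = len(blocks)
    # DP over blocks: value = (total query length, total score)
    best_len = [len(b.query_iv) for b in blocks]
    best_sc = [b.score for b in blocks]
    parent = [-1] * m
    for x in range(m):
        bx = blocks[x]
        for y in range(x):
            by = blocks[y]
            qgap = bx.query_iv.start - by.query_iv.end
            tgap = bx.target_iv.start - by.target_iv.end
            if qgap < -overlap_slack or tgap < -overlap_slack:
                continue
            if qgap > max_chain_gap or tgap > max_chain_gap:
                continue
            cand_len = best_len[y] + len(bx.query_iv)
            cand_sc = best_sc[y] + bx.score
            if (cand_len, cand_sc) > (best_len[x], best_sc[x]):
                best_len[x] = cand_len
                best_sc[x] = cand_sc
                parent[x] = y
    order = sorted(
        range(m),
        key=lambda x: (-best_len[x], -best_sc[x], blocks[x].target_iv.start),
    )
    end = order[0]
    chain = []
    while end >= 0:
        chain.append(blocks[end])
        end = parent[end]
    chain.reverse()
    return chain
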