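"""Assembly evaluation: weighted percent identity and colinearity breaks.

The headline statistic is the alignment-length-weighted mean of per-block
percent identities, sum(L_i * id_i) / sum(L_i); with a single alignment it
is simply that alignment's identity.  Assembly-to-reference comparison
chains local alignments into colinear blocks; colinearity breaks (order or
strand violations, or internal gaps larger than ``misassembly_gap`` on both
sequences that cannot be aligned at a sanity identity floor) count as
misassemblies.  Seedless repeat regions (the terminal telomere tract, long
VNTR arrays) are recovered by globally aligning the matched gap pair, so
coverage is not lost where unique seeds do not exist.  Counts are
comparable, not bit-identical, to external evaluators.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace

import edlib

from .alignment import (AlignmentParams, align_global_scored, align_local,
                        longest_contiguous_segment)
from .assembly import AssemblyResult
from .seqio import Interval, SequenceRecord

__all__ = [
    "EvaluationRow",
    "EvaluationReport",
    "weighted_percent_identity",
    "compare_to_reference",
    "provenance_identity",
]

log = logging.getLogger(__name__)

MISASSEMBLY_GAP = 1000
PATCH_MIN_IDENTITY = 80.0
PATCH_MAX_RATIO = 3.0


@dataclass(frozen=True)
class EvaluationRow:
    reference_iv: Interval
    assembly_iv: Interval
    strand: str
    percent_identity: float
    columns: int


@dataclass
class EvaluationReport:
    rows: list[EvaluationRow] = field(default_factory=list)
    weighted_percent_identity: float = 0.0
    misassembly_count: int = 0
    covered_fraction: float = 0.0

    def to_json(self, path) -> None:
        payload = {
            "weighted_percent_identity": self.weighted_percent_identity,
            "misassembly_count": self.misassembly_count,
            "covered_fraction": self.covered_fraction,
            "alignments": [
                {
                    "reference_start": r.reference_iv.start,
                    "reference_end": r.reference_iv.end,
                    "assembly_start": r.assembly_iv.start,
                    "assembly_end": r.assembly_iv.end,
                    "strand": r.strand,
                    "percent_identity": r.percent_identity,
                    "columns": r.columns,
                }
                for r in self.rows
            ],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)


def weighted_percent_identity(rows: list[tuple[float, float]]) -> float:
    """sum(L_i * id_i) / sum(L_i) over (length, identity) rows.

    A single row returns that row's identity verbatim.
    """
    if not rows:
        raise ValueError("no alignment rows")
    if any(length <= 0 for length, _ in rows):
        raise ValueError("row lengths must be positive")
    if len(rows) == 1:
        return rows[0][1]
    total = sum(length for length, _ in rows)
    return sum(length * ident for length, ident in rows) / total


def _patch_gap(aseq: str, rseq: str, params: AlignmentParams):
    """Try to absorb a seedless gap pair by global alignment."""
    la, lr = len(aseq), len(rseq)
    if la == 0 or lr == 0:
        return None
    if max(la, lr) > PATCH_MAX_RATIO * min(la, lr):
        return None
    matches, columns, _ = align_global_scored(aseq, rseq, params)
    ident = 100.0 * matches / columns
    if ident < PATCH_MIN_IDENTITY:
        return None
    return matches, columns, ident


def compare_to_reference(assembly: AssemblyResult | SequenceRecord,
                         reference: SequenceRecord,
                         params: AlignmentParams | None = None,
                         misassembly_gap: int = MISASSEMBLY_GAP
                         ) -> EvaluationReport:
    """Colinear-block comparison of an assembly against a reference segment."""
    if params is None:
        params = AlignmentParams()
    seq = assembly.sequence if isinstance(assembly, AssemblyResult) else assembly.sequence
    asm = SequenceRecord("assembly", seq.replace("N", ""))  # N-runs never align
    if not asm.sequence or not reference.sequence:
        raise ValueError("assembly and reference must be non-empty")
    p = replace(params, respect_mask=False)
    alns = align_local(asm, reference, p, method="seeded")
    if not alns:
        return EvaluationReport(rows=[], weighted_percent_identity=0.0,
                                misassembly_count=0, covered_fraction=0.0)
    best_chain = None
    for strand in "+-":
        sub = [a for a in alns if a.strand == strand]
        if not sub:
            continue
        chain = longest_contiguous_segment(
            sub, max_chain_gap=max(len(asm.sequence), len(reference.sequence)))
        cols = sum(a.columns for a in chain)
        if best_chain is None or cols > best_chain[0]:
            best_chain = (cols, strand, chain)
    _, strand, chain = best_chain

    rows: list[EvaluationRow] = []
    miscount = 0

    def add_row(a_iv, r_iv, matches, columns):
        rows.append(EvaluationRow(
            reference_iv=r_iv, assembly_iv=a_iv, strand=strand,
            percent_identity=100.0 * matches / columns, columns=columns))

    # leading unaligned tails
    first = chain[0]
    patch = _patch_gap(asm.sequence[:first.query_iv.start],
                       reference.sequence[:first.target_iv.start], p)
    if patch:
        m, c, _ = patch
        add_row(Interval(0, first.query_iv.start),
                Interval(0, first.target_iv.start), m, c)
    for a in chain:
        add_row(a.query_iv, a.target_iv, a.matches, a.columns)
    for a, b in zip(chain, chain[1:]):
        qgap = b.query_iv.start - a.query_iv.end
        rgap = b.target_iv.start - a.target_iv.end
        patch = _patch_gap(asm.sequence[a.query_iv.end:b.query_iv.start],
                           reference.sequence[a.target_iv.end:b.target_iv.start], p)
        if patch:
            m, c, _ = patch
            add_row(Interval(a.query_iv.end, b.query_iv.start),
                    Interval(a.target_iv.end, b.target_iv.start), m, c)
        elif max(qgap, rgap) > misassembly_gap:
            miscount += 1
    last = chain[-1]
    patch = _patch_gap(asm.sequence[last.query_iv.end:],
                       reference.sequence[last.target_iv.end:], p)
    if patch:
        m, c, _ = patch
        add_row(Interval(last.query_iv.end, len(asm.sequence)),
                Interval(last.target_iv.end, len(reference.sequence)), m, c)

    covered = sorted((r.reference_iv.start, r.reference_iv.end) for r in rows)
    total = 0
    hi = -1
    for s, e in covered:
        s = max(s, hi)
        if e > s:
            total += e - s
            hi = e
    report = EvaluationReport(
        rows=rows,
        weighted_percent_identity=weighted_percent_identity(
            [(r.columns, r.percent_identity) for r in rows]),
        misassembly_count=miscount,
        covered_fraction=total / len(reference.sequence),
    )
    return report


def provenance_identity(result: AssemblyResult, reference: SequenceRecord,
                        source_type: str = "contig",
                        params: AlignmentParams | None = None) -> float:
    """Weighted percent identity of provenance intervals of one source type.

    Each qualifying output interval is located within the reference by
    infix (semi-global) alignment and scored by its percent identity.
    """
    if params is None:
        params = AlignmentParams()
    rows = []
    for row in result.provenance:
        if row.source_type != source_type or len(row.out_iv) < 100:
            continue
        seg = result.sequence[row.out_iv.start:row.out_iv.end]
        res = edlib.align(seg, reference.sequence, mode="HW", task="path")
        from .alignment import _cigar_stats  # local import to reuse parsing
        matches, columns, _ = _cigar_stats(res["cigar"], params)
        rows.append((columns, 100.0 * matches / columns))
    if not rows:
        raise ValueError(f"no provenance intervals of type {source_type!r}")
    return weighted_percent_identity(rows)
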