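"""Seeded synthetic subtelomeres, noisy ultralong reads, and contigs.

The generator emulates the architecture the assembler targets: a 1-copy
anchor region, a segmental-duplication (SD) region built from divergent
near-copies of one template, optional VNTR arrays inside the SD region, and
a terminal (TTAGGG)n telomere tract.  Ultralong reads (>= 40 kb) are sampled
as a tiled path across the reference with generous overlaps, the last read
pinned to run through the tract to the chromosome end; read errors follow a
40:30:30 substitution:insertion:deletion mix.  Contigs emulate linked-read
regional assemblies: high-accuracy reference substrings that never enter
the telomere tract, with planted defects — each VNTR collapsed to a few
units and an optional internal deletion.  Everything is reproducible
bit-exact from (spec, seed), and a truth table records source intervals,
strands, and planted defects for every read and contig.

Default dimensions give a ~150 kb reference, scaled down from the ~500 kb
windows of real subtelomere analyses so end-to-end runs finish in minutes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .seqio import Interval, SequenceRecord, reverse_complement

__all__ = [
    "VNTRSpec",
    "SubtelomereSpec",
    "ReadTruth",
    "ContigDefect",
    "ContigTruth",
    "TruthTable",
    "Scenario",
    "simulate_reference",
    "simulate_long_reads",
    "simulate_contigs",
    "default_probes",
    "simulate_screen_reads",
    "scenario",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
TELOMERE_UNIT = "TTAGGG"


@dataclass(frozen=True)
class VNTRSpec:
    """One tandem array planted in the SD region (offset is within the SD)."""

    sd_offset: int = 20_000
    unit_len: int = 37
    copies: int = 40
    collapsed_copies: int = 3


@dataclass(frozen=True)
class SubtelomereSpec:
    one_copy_len: int = 100_000
    sd_len: int = 45_000
    sd_blocks: int = 3
    sd_divergence: float = 0.02
    vntrs: tuple[VNTRSpec, ...] = (VNTRSpec(),)
    telomere_tract_len: int = 2_502  # rounded to whole TTAGGG units
    arm: str = "q"
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.one_copy_len, self.sd_len, self.telomere_tract_len) <= 0:
            raise ValueError("all lengths must be positive")
        if self.arm not in "pq":
            raise ValueError("arm must be 'p' or 'q'")
        for v in self.vntrs:
            if not (0 <= v.sd_offset <= self.sd_len):
                raise ValueError("VNTR offset outside the SD region")
            if v.copies < 1 or v.collapsed_copies < 1:
                raise ValueError("VNTR copy numbers must be >= 1")


@dataclass(frozen=True)
class ReadTruth:
    iv: Interval  # canonical reference coordinates
    strand: str


@dataclass(frozen=True)
class ContigDefect:
    kind: str  # 'tandem_repeat_collapse' | 'deletion'
    ref_iv: Interval  # affected canonical reference interval
    kept_bp: int  # bases retained in the contig across that interval


@dataclass(frozen=True)
class ContigTruth:
    iv: Interval
    strand: str
    defects: tuple[ContigDefect, ...] = ()


@dataclass
class TruthTable:
    canonical_reference: SequenceRecord
    vntrs: list[tuple[Interval, VNTRSpec]] = field(default_factory=list)
    reads: dict[str, ReadTruth] = field(default_factory=dict)
    contigs: dict[str, ContigTruth] = field(default_factory=dict)

    @property
    def vntr_ivs(self) -> list[Interval]:
        return [iv for iv, _ in self.vntrs]


@dataclass
class Scenario:
    spec: SubtelomereSpec
    reference: SequenceRecord  # arm-oriented, as a reference segment would be
    reads: list[SequenceRecord]
    contigs: list[SequenceRecord]
    probes: list[SequenceRecord]
    truth: TruthTable


def _random_dna(rng: np.random.Generator, n: int) -> str:
    return _BASES[rng.integers(0, 4, size=n)].tobytes().decode()


def _mutate(seq: str, rate: float, rng: np.random.Generator,
            mix: tuple[float, float, float] = (0.4, 0.3, 0.3)) -> str:
    """Plant substitutions/insertions/deletions at per-base ``rate``."""
    if rate <= 0 or not seq:
        return seq
    n = len(seq)
    pos = np.flatnonzero(rng.random(n) < rate)
    if pos.size == 0:
        return seq
    kinds = rng.choice(3, size=pos.size, p=mix)
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    parts = []
    prev = 0
    lut = {65: 0, 67: 1, 71: 2, 84: 3}
    for p, kind in zip(pos, kinds):
        p = int(p)
        parts.append(seq[prev:p])
        if kind == 0:  # substitution to a different base
            old = lut.get(int(arr[p]), 0)
            new = (old + 1 + int(rng.integers(0, 3))) % 4
            parts.append("ACGT"[new])
            prev = p + 1
        elif kind == 1:  # insertion before p
            parts.append("ACGT"[int(rng.integers(0, 4))])
            prev = p
        else:  # deletion
            prev = p + 1
    parts.append(seq[prev:])
    return "".join(parts)


def simulate_reference(spec: SubtelomereSpec
                       ) -> tuple[SequenceRecord, TruthTable]:
    """Build the reference and an initially read/contig-empty truth table.

    Canonical frame: 1-copy region ++ SD region (with VNTR arrays inserted)
    ++ terminal (TTAGGG)n tract.  For arm 'p' the emitted record is the
    reverse complement; truth coordinates stay canonical.
    """
    rng = np.random.default_rng(spec.seed)
    one_copy = _random_dna(rng, spec.one_copy_len)
    block_len = spec.sd_len // spec.sd_blocks
    template = _random_dna(rng, block_len)
    sd = "".join(
        _mutate(template, spec.sd_divergence, rng) for _ in range(spec.sd_blocks)
    )
    # insert VNTR arrays at ascending offsets, tracking absolute intervals
    vntrs: list[tuple[Interval, VNTRSpec]] = []
    parts = []
    prev = 0
    grown = 0
    for v in sorted(spec.vntrs, key=lambda v: v.sd_offset):
        unit = _random_dna(rng, v.unit_len)
        array = unit * v.copies
        parts.append(sd[prev:v.sd_offset])
        start = spec.one_copy_len + v.sd_offset + grown
        vntrs.append((Interval(start, start + len(array)), v))
        parts.append(array)
        grown += len(array)
        prev = v.sd_offset
    parts.append(sd[prev:])
    sd = "".join(parts)
    tract = TELOMERE_UNIT * (spec.telomere_tract_len // len(TELOMERE_UNIT))
    canonical = SequenceRecord("reference", one_copy + sd + tract)
    truth = TruthTable(canonical_reference=canonical, vntrs=vntrs)
    return canonical, truth


def _emit(record: SequenceRecord, arm: str) -> SequenceRecord:
    return record if arm == "q" else record.reverse_complement()


def simulate_long_reads(reference: SequenceRecord, truth: TruthTable,
                        rng: np.random.Generator,
                        error_rate: float = 0.0,
                        length_range: tuple[int, int] = (44_000, 54_000),
                        step: int = 30_000,
                        telomeric_length: int = 57_000) -> list[SequenceRecord]:
    """Tile ultralong reads across the reference (canonical frame).

    Reads start at 0 and advance by ``step`` with +-2 kb jitter; the last
    read is pinned to end at the chromosome end so it runs through the
    telomere tract.  Strands are random; errors are planted at
    ``error_rate`` with the 40:30:30 sub:ins:del mix.
    """
    if not 0 <= error_rate <= 0.15:
        raise ValueError("error_rate must be within [0, 0.15]")
    L = len(reference.sequence)
    if L < length_range[0]:
        raise ValueError("reference shorter than the minimum read length")
    starts = [0]
    while starts[-1] + step + length_range[1] < L - telomeric_length + step:
        jitter = int(rng.integers(-2000, 2001))
        starts.append(max(0, starts[-1] + step + jitter))
    ivs = []
    for s in starts:
        length = int(rng.integers(length_range[0], length_range[1] + 1))
        ivs.append(Interval(s, min(L, s + length)))
    tel_start = max(0, L - telomeric_length)
    ivs.append(Interval(tel_start, L))  # pinned telomeric read
    reads = []
    for i, iv in enumerate(ivs):
        raw = reference.sequence[iv.start:iv.end]
        noisy = _mutate(raw, error_rate, rng)
        strand = "+" if rng.random() < 0.5 else "-"
        seq = noisy if strand == "+" else reverse_complement(noisy)
        rid = f"read_{i:02d}"
        reads.append(SequenceRecord(rid, seq))
        truth.reads[rid] = ReadTruth(iv=iv, strand=strand)
    return reads


@dataclass(frozen=True)
class ContigPlan:
    iv: Interval  # canonical reference interval
    deletion: tuple[int, int] | None = None  # (ref_start, length)
    sub_rate: float = 0.0


def default_contig_plan(spec: SubtelomereSpec, truth: TruthTable,
                        deletion_len: int = 1500) -> list[ContigPlan]:
    """Four contigs tiling the non-tract region: two 2 kb overlaps, one 2 kb
    gap, one planted deletion, VNTRs collapsed by simulate_contigs."""
    L_nt = len(truth.canonical_reference.sequence) - (
        spec.telomere_tract_len // 6 * 6)
    cuts = [int(L_nt * f) for f in (0.27, 0.52, 0.75)]
    # nudge cut points off any VNTR array
    adj = []
    for c in cuts:
        for v in truth.vntr_ivs:
            if v.start - 3000 < c < v.end + 3000:
                c = v.start - 3000
        adj.append(c)
    q1, q2, q3 = adj
    plans = [
        ContigPlan(Interval(0, q1 + 1000)),
        ContigPlan(Interval(q1 - 1000, q2 + 1000),
                   deletion=((q1 + q2) // 2, deletion_len)),
        ContigPlan(Interval(q2 + 3000, q3 + 1000)),  # 2 kb gap before this one
        ContigPlan(Interval(q3 - 1000, L_nt)),
    ]
    return plans


def simulate_contigs(reference: SequenceRecord, truth: TruthTable,
                     plans: list[ContigPlan], rng: np.random.Generator
                     ) -> list[SequenceRecord]:
    """Materialise contigs from plans, collapsing VNTRs and planting
    deletions; contigs are emitted on random strands (orientation unknown,
    as for a real linked-read assembly)."""
    L = len(reference.sequence)
    contigs = []
    for i, plan in enumerate(plans, start=1):
        if not (0 <= plan.iv.start < plan.iv.end <= L):
            raise ValueError(f"contig plan {plan.iv} out of reference bounds")
        edits: list[tuple[Interval, str, ContigDefect]] = []
        for iv, v in truth.vntrs:
            if plan.iv.contains(iv):
                unit = reference.sequence[iv.start:iv.start + v.unit_len]
                kept = unit * v.collapsed_copies
                edits.append((iv, kept, ContigDefect(
                    "tandem_repeat_collapse", iv, len(kept))))
        if plan.deletion is not None:
            ds, dl = plan.deletion
            div = Interval(ds, ds + dl)
            if plan.iv.contains(div):
                edits.append((div, "", ContigDefect("deletion", div, 0)))
        edits.sort(key=lambda e: e[0].start, reverse=True)
        seq = reference.sequence[plan.iv.start:plan.iv.end]
        defects = []
        for iv, repl, defect in edits:
            a = iv.start - plan.iv.start
            b = iv.end - plan.iv.start
            seq = seq[:a] + repl + seq[b:]
            defects.append(defect)
        seq = _mutate(seq, plan.sub_rate, rng, mix=(1.0, 0.0, 0.0))
        strand = "+" if rng.random() < 0.5 else "-"
        cid = f"contig_{i}"
        contigs.append(SequenceRecord(
            cid, seq if strand == "+" else reverse_complement(seq)))
        truth.contigs[cid] = ContigTruth(
            iv=plan.iv, strand=strand,
            defects=tuple(sorted(defects, key=lambda d: d.ref_iv.start)))
    return contigs


def default_probes(spec: SubtelomereSpec, reference: SequenceRecord,
                   probe_len: int = 3000, spacing: int = 25_000
                   ) -> list[SequenceRecord]:
    """1-copy anchor probe slices spanning the 1-copy region, emulating a
    wide bait set; the distal-most probe sits just inside the SD boundary."""
    starts = list(range(2000, spec.one_copy_len - 2 * probe_len, spacing))
    starts.append(spec.one_copy_len - 2 * probe_len)
    probes = []
    for i, s in enumerate(starts, start=1):
        probes.append(SequenceRecord(
            f"probe_{i}", reference.sequence[s:s + probe_len]))
    return probes


def simulate_screen_reads(n: int, rng: np.random.Generator,
                          body_range: tuple[int, int] = (2000, 8000),
                          tract_max: int = 5000) -> list[SequenceRecord]:
    """Short synthetic reads with planted terminal tracts of 0..tract_max bp
    for exercising the telomere screen (both strands, degenerate variants)."""
    reads = []
    for i in range(n):
        body = _random_dna(rng, int(rng.integers(*body_range)))
        tract_len = int(rng.integers(0, tract_max + 1))
        tract = (TELOMERE_UNIT * (tract_len // 6 + 1))[:tract_len]
        if rng.random() < 0.3:  # degenerate tract: sprinkle errors into it
            tract = _mutate(tract, 0.02, rng)
        seq = body + tract
        if rng.random() < 0.5:
            seq = reverse_complement(seq)
        reads.append(SequenceRecord(f"s{i:04d}", seq))
    return reads


def scenario(seed: int, error_rate: float = 0.0,
             spec: SubtelomereSpec | None = None,
             contig_sub_rate: float = 0.0) -> Scenario:
    """The default study scenario: ~150 kb reference, tiled >= 40 kb reads,
    exact-substring contigs with one collapsed VNTR and one 1.5 kb deletion."""
    if spec is None:
        spec = SubtelomereSpec(seed=seed)
    else:
        spec = replace(spec, seed=seed)
    canonical, truth = simulate_reference(spec)
    rng = np.random.default_rng(seed + 1_000_003)
    reads = simulate_long_reads(canonical, truth, rng, error_rate=error_rate)
    plans = [replace(p, sub_rate=contig_sub_rate)
             for p in default_contig_plan(spec, truth)]
    contigs = simulate_contigs(canonical, truth, plans, rng)
    probes = default_probes(spec, canonical)
    return Scenario(
        spec=spec,
        reference=_emit(canonical, spec.arm),
        reads=reads,
        contigs=contigs,
        probes=probes,
        truth=truth,
    )
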