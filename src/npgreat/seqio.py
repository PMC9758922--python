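"""Sequence records, intervals, and FASTA/FASTQ input/output.

Coordinate convention: everything internal is 0-based half-open.  Conversion
to/from 1-based inclusive coordinates happens only at I/O boundaries.

Soft masking is carried as a list of :class:`Interval` spans on each record
rather than as letter case, so sequence comparisons are case-insensitive by
construction.  On input, lowercase FASTA letters become uppercase and their
spans are recorded in ``mask``; on output, masked spans are written lowercase.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from pathlib import Path

from Bio import SeqIO

__all__ = [
    "Interval",
    "SequenceRecord",
    "FormatError",
    "DuplicateIdError",
    "reverse_complement",
    "read_fasta",
    "read_fastq",
    "write_fasta",
    "write_fastq",
    "to_zero_based",
    "to_one_based",
    "merge_intervals",
    "flip_interval",
]

_DNA = frozenset("ACGTN")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
_LOWER_RE = re.compile(r"[a-z]+")


class FormatError(ValueError):
    """Malformed sequence file (message names the offending line)."""


class DuplicateIdError(ValueError):
    """Two records in one file share an id."""


@dataclass(frozen=True, order=True)
class Interval:
    """0-based half-open span ``[start, end)``."""

    start: int
    end: int

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid interval [{self.start}, {self.end})")

    def __len__(self) -> int:
        return self.end - self.start

    def contains(self, other: "Interval") -> bool:
        return self.start <= other.start and other.end <= self.end

    def overlaps(self, other: "Interval") -> bool:
        return self.start < other.end and other.start < self.end

    def shift(self, delta: int) -> "Interval":
        return Interval(self.start + delta, self.end + delta)


def to_zero_based(start_1b: int, end_1b: int) -> Interval:
    """Convert a 1-based inclusive pair ``[a, b]`` to an Interval."""
    return Interval(start_1b - 1, end_1b)


def to_one_based(iv: Interval) -> tuple[int, int]:
    """Convert an Interval back to 1-based inclusive coordinates."""
    return iv.start + 1, iv.end


def merge_intervals(ivs: list[Interval]) -> list[Interval]:
    """Sort and merge overlapping/adjacent intervals."""
    if not ivs:
        return []
    out: list[Interval] = []
    for iv in sorted(ivs):
        if out and iv.start <= out[-1].end:
            if iv.end > out[-1].end:
                out[-1] = Interval(out[-1].start, iv.end)
        else:
            out.append(iv)
    return out


def flip_interval(iv: Interval, length: int) -> Interval:
    """Mirror an interval onto the reverse-complemented coordinate frame."""
    return Interval(length - iv.end, length - iv.start)


@dataclass
class SequenceRecord:
    """A named uppercase DNA sequence with optional soft-mask intervals."""

    id: str
    sequence: str
    description: str = ""
    mask: list[Interval] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("record id must be non-empty")
        bad = set(self.sequence) - _DNA
        if bad:
            raise ValueError(
                f"record {self.id!r}: non-DNA characters {sorted(bad)!r}"
            )
        self.mask = merge_intervals(self.mask)
        if self.mask and self.mask[-1].end > len(self.sequence):
            raise ValueError(f"record {self.id!r}: mask outside sequence")

    def __len__(self) -> int:
        return len(self.sequence)

    def reverse_complement(self, new_id: str | None = None) -> "SequenceRecord":
        n = len(self.sequence)
        return SequenceRecord(
            id=new_id or self.id,
            sequence=reverse_complement(self.sequence),
            description=self.description,
            mask=[flip_interval(iv, n) for iv in reversed(self.mask)],
        )

    def with_mask(self, mask: list[Interval]) -> "SequenceRecord":
        return replace(self, mask=merge_intervals(list(mask)))


def reverse_complement(sequence: str) -> str:
    """Reverse complement of a DNA string; ``N`` maps to ``N``."""
    bad = set(sequence) - _DNA
    if bad:
        raise ValueError(f"non-DNA characters {sorted(bad)!r}")
    return sequence.translate(_COMPLEMENT)[::-1]


def _mask_from_case(raw: str) -> list[Interval]:
    return [Interval(m.start(), m.end()) for m in _LOWER_RE.finditer(raw)]


def _validate_fasta_layout(path: Path) -> None:
    """Pre-scan for structural problems so errors can name line numbers."""
    seen_header = False
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped:
                continue
            if stripped.startswith(">"):
                if len(stripped) == 1:
                    raise FormatError(f"{path}: empty FASTA header at line {lineno}")
                seen_header = True
            else:
                if not seen_header:
                    raise FormatError(
                        f"{path}: sequence data before any FASTA header at line {lineno}"
                    )
                bad = set(stripped.upper()) - _DNA
                if bad:
                    raise FormatError(
                        f"{path}: non-IUPAC residue {sorted(bad)!r} at line {lineno}"
                    )


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read a (multi-record) FASTA file.

    Lowercase spans become uppercase sequence plus soft-mask intervals.
    Raises :class:`FormatError` on malformed input and
    :class:`DuplicateIdError` on repeated ids.
    """
    path = Path(path)
    _validate_fasta_layout(path)
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise DuplicateIdError(f"{path}: duplicate record id {rec.id!r}")
        seen.add(rec.id)
        raw = str(rec.seq)
        records.append(
            SequenceRecord(
                id=rec.id,
                sequence=raw.upper(),
                description=rec.description[len(rec.id):].strip(),
                mask=_mask_from_case(raw),
            )
        )
    return records


def read_fastq(path: str | Path) -> list[SequenceRecord]:
    """Read FASTQ; qualities are discarded (the pipeline is sequence-only)."""
    path = Path(path)
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    try:
        for rec in SeqIO.parse(str(path), "fastq"):
            if rec.id in seen:
                raise DuplicateIdError(f"{path}: duplicate record id {rec.id!r}")
            seen.add(rec.id)
            raw = str(rec.seq)
            bad = set(raw.upper()) - _DNA
            if bad:
                raise FormatError(
                    f"{path}: non-IUPAC residue {sorted(bad)!r} in record {rec.id!r}"
                )
            records.append(
                SequenceRecord(
                    id=rec.id,
                    sequence=raw.upper(),
                    description=rec.description[len(rec.id):].strip(),
                    mask=_mask_from_case(raw),
                )
            )
    except ValueError as exc:
        if isinstance(exc, (FormatError, DuplicateIdError)):
            raise
        raise FormatError(f"{path}: {exc}") from exc
    return records


def write_fasta(records: list[SequenceRecord], path: str | Path, width: int = 80) -> None:
    """Write FASTA, lowercasing soft-masked spans, wrapped at ``width``."""
    with open(path, "w") as fh:
        for rec in records:
            seq = rec.sequence
            if rec.mask:
                chars = list(seq)
                for iv in rec.mask:
                    chars[iv.start:iv.end] = seq[iv.start:iv.end].lower()
                seq = "".join(chars)
            header = f">{rec.id}"
            if rec.description:
                header += f" {rec.description}"
            fh.write(header + "\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def write_fastq(records: list[SequenceRecord], path: str | Path) -> None:
    """Write FASTQ with uniform placeholder qualities."""
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f"@{rec.id}\n{rec.sequence}\n+\n{'I' * len(rec.sequence)}\n")
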