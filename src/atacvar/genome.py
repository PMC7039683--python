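"""Shared coordinate types, sequence utilities and flat-file readers/writers.

Coordinates are 0-based half-open (BED convention) everywhere; 1-based
inputs (SNP tables) are converted at the reader boundary.  Soft-masking
(lowercase) is the repeat representation.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

__all__ = [
    "GenomicInterval",
    "FragmentRecord",
    "Genome",
    "read_fasta",
    "write_fasta",
    "read_bed",
    "write_bed",
    "read_fragments",
    "write_fragments",
    "gc_fraction",
    "repeat_fraction",
    "reverse_complement",
    "merge_intervals",
    "sort_intervals",
]

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")
_DNA_OK = set("ACGTNacgtn")
_STRANDS = {"+", "-", "."}


@dataclass
class GenomicInterval:
    """A 0-based half-open genomic span ``[start, end)``."""

    chrom: str
    start: int
    end: int
    strand: str = "."
    name: str = ""
    score: float | None = None
    extra: tuple = ()

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )
        if self.strand not in _STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def __str__(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}"


@dataclass
class FragmentRecord:
    """One sequenced fragment, tagged with its cell-population sample label."""

    interval: GenomicInterval
    sample: str

    @property
    def length(self) -> int:
        return self.interval.length


class Genome:
    """In-memory genome: chrom -> DNA string (lowercase = repeat-masked)."""

    def __init__(self, sequences: dict[str, str]):
        self.sequences = dict(sequences)
        self.lengths = {c: len(s) for c, s in self.sequences.items()}

    @property
    def chroms(self) -> list[str]:
        return list(self.sequences)

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.sequences

    def fetch(self, chrom_or_interval, start: int | None = None, end: int | None = None) -> str:
        if isinstance(chrom_or_interval, GenomicInterval):
            iv = chrom_or_interval
            chrom, start, end = iv.chrom, iv.start, iv.end
        else:
            chrom = chrom_or_interval
        if chrom not in self.sequences:
            raise KeyError(f"unknown chromosome {chrom!r}")
        if start is None or end is None:
            return self.sequences[chrom]
        if start < 0 or end > self.lengths[chrom]:
            raise ValueError(
                f"interval {chrom}:{start}-{end} outside chromosome "
                f"(length {self.lengths[chrom]})"
            )
        return self.sequences[chrom][start:end]

    def total_length(self) -> int:
        return sum(self.lengths.values())


def read_fasta(path) -> Genome:
    """Read a (multi-record, possibly soft-masked) FASTA file.

    Case is preserved; ``N`` is allowed.  Duplicate record names and
    non-DNA characters raise a ``ValueError`` naming the offending line.
    """
    sequences: dict[str, str] = {}
    name: str | None = None
    chunks: list[str] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line:
                continue
            if line.startswith(">"):
                if name is not None:
                    sequences[name] = "".join(chunks)
                name = line[1:].split()[0] if len(line) > 1 else ""
                if not name:
                    raise ValueError(f"{path}: empty FASTA header at line {lineno}")
                if name in sequences:
                    raise ValueError(
                        f"{path}: duplicate record name {name!r} at line {lineno}"
                    )
                chunks = []
            else:
                if name is None:
                    raise ValueError(
                        f"{path}: sequence before first header at line {lineno}"
                    )
                if not set(line) <= _DNA_OK:
                    bad = sorted(set(line) - _DNA_OK)
                    raise ValueError(
                        f"{path}: non-DNA characters {bad} at line {lineno}"
                    )
                chunks.append(line)
    if name is not None:
        sequences[name] = "".join(chunks)
    return Genome(sequences)


def write_fasta(genome: Genome, path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for chrom, seq in genome.sequences.items():
            fh.write(f">{chrom}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_bed(path) -> list[GenomicInterval]:
    """Read BED3+ / narrowPeak.  Extra columns are kept in ``extra``."""
    out: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            cols = line.split("\t")
            if len(cols) < 3:
                raise ValueError(f"{path}: fewer than 3 columns at line {lineno}")
            try:
                start, end = int(cols[1]), int(cols[2])
            except ValueError as exc:
                raise ValueError(f"{path}: non-integer coordinate at line {lineno}") from exc
            if start >= end:
                raise ValueError(
                    f"{path}: start >= end ({start} >= {end}) at line {lineno}"
                )
            name = cols[3] if len(cols) > 3 else ""
            score = None
            if len(cols) > 4 and cols[4] not in (".", ""):
                score = float(cols[4])
            strand = cols[5] if len(cols) > 5 and cols[5] in _STRANDS else "."
            out.append(
                GenomicInterval(
                    cols[0], start, end,
                    strand=strand, name=name, score=score,
                    extra=tuple(cols[6:]),
                )
            )
    return out


def write_bed(intervals: Iterable[GenomicInterval], path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            cols = [iv.chrom, str(iv.start), str(iv.end)]
            has6 = iv.name or iv.score is not None or iv.strand != "." or iv.extra
            if has6:
                cols += [
                    iv.name or ".",
                    "." if iv.score is None else format(iv.score, "g"),
                    iv.strand,
                ]
                cols += [str(x) for x in iv.extra]
            fh.write("\t".join(cols) + "\n")


def read_fragments(path) -> list[FragmentRecord]:
    """Read a fragment TSV with header: chrom, start, end, strand, sample."""
    out: list[FragmentRecord] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        idx = {name: i for i, name in enumerate(header)}
        for col in ("chrom", "start", "end", "sample"):
            if col not in idx:
                raise ValueError(f"{path}: missing column {col!r} in header")
        for lineno, raw in enumerate(fh, start=2):
            line = raw.rstrip("\n")
            if not line:
                continue
            cols = line.split("\t")
            strand = cols[idx["strand"]] if "strand" in idx else "."
            try:
                iv = GenomicInterval(
                    cols[idx["chrom"]],
                    int(cols[idx["start"]]),
                    int(cols[idx["end"]]),
                    strand=strand,
                )
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: {exc}") from exc
            out.append(FragmentRecord(iv, cols[idx["sample"]]))
    return out


def write_fragments(fragments: Iterable[FragmentRecord], path) -> None:
    with open(path, "w") as fh:
        fh.write("chrom\tstart\tend\tstrand\tsample\n")
        for fr in fragments:
            iv = fr.interval
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.strand}\t{fr.sample}\n")


def gc_fraction(seq: str) -> float:
    """(G+C) / (A+C+G+T); N excluded from the denominator (0.0 if all-N)."""
    if not seq:
        raise ValueError("gc_fraction of empty sequence")
    s = seq.upper()
    gc = s.count("G") + s.count("C")
    acgt = gc + s.count("A") + s.count("T")
    if acgt == 0:
        return 0.0
    return gc / acgt


def repeat_fraction(seq: str) -> float:
    """Fraction of soft-masked (lowercase) bases."""
    if not seq:
        raise ValueError("repeat_fraction of empty sequence")
    return sum(c.islower() for c in seq) / len(seq)


def reverse_complement(seq: str) -> str:
    """Reverse complement, preserving case; N maps to N."""
    if not set(seq) <= _DNA_OK:
        bad = sorted(set(seq) - _DNA_OK)
        raise ValueError(f"non-DNA characters in sequence: {bad}")
    return seq.translate(_COMPLEMENT)[::-1]


def sort_intervals(intervals: Sequence[GenomicInterval]) -> list[GenomicInterval]:
    return sorted(intervals, key=lambda iv: (iv.chrom, iv.start, iv.end))


def merge_intervals(
    intervals: Sequence[GenomicInterval], gap: int = 0
) -> list[GenomicInterval]:
    """Merge intervals closer than ``gap`` bp (0 merges touching/overlapping)."""
    merged: list[GenomicInterval] = []
    for iv in sort_intervals(intervals):
        if merged and merged[-1].chrom == iv.chrom and iv.start <= merged[-1].end + gap:
            prev = merged[-1]
            if iv.end > prev.end:
                merged[-1] = GenomicInterval(prev.chrom, prev.start, iv.end)
        else:
            merged.append(GenomicInterval(iv.chrom, iv.start, iv.end))
    return merged
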