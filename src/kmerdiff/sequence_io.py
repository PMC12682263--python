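"""Reading and writing of the sequence and interval formats used by the pipeline.

FASTA and FASTQ input is gzip-transparent and parsed with Biopython; output of
window scores uses a BED-like 7-column TSV.  All coordinates are 0-based
half-open, matching the BED convention.
"""
from __future__ import annotations

import gzip
import io
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import IO, Iterable, Iterator, List

import numpy as np
from Bio import SeqIO

__all__ = [
    "SequenceRecord",
    "ParseError",
    "read_fasta",
    "read_reads",
    "write_fasta",
    "write_fastq",
    "write_bed",
]

_ALLOWED = frozenset("ACGTN")
# uppercase, drop whitespace, coerce anything outside {A,C,G,T,N} to N
_NORMALIZE = {}
for _c in range(256):
    ch = chr(_c).upper()
    if ch in _ALLOWED:
        _NORMALIZE[_c] = ch
    elif ch in " \t\r\n":
        _NORMALIZE[_c] = None
    else:
        _NORMALIZE[_c] = "N"
_NORM_TABLE = str.maketrans(_NORMALIZE)


class ParseError(ValueError):
    """Raised when a sequence file cannot be parsed."""


@dataclass(frozen=True)
class SequenceRecord:
    """A named nucleotide sequence (reference chromosome or sequencing read).

    The sequence is stored uppercase over the alphabet {A, C, G, T, N}.
    """

    name: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("sequence name must be non-empty")
        bad = set(self.sequence) - _ALLOWED
        if bad:
            raise ValueError(
                f"sequence {self.name!r} contains characters outside ACGTN: "
                f"{sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


def _normalize(raw: str) -> tuple[str, int]:
    """Uppercase, strip whitespace, coerce non-ACGTN to N; return (seq, n_coerced)."""
    clean = raw.translate(_NORM_TABLE)
    stripped = "".join(raw.split()).upper()
    n_coerced = sum(1 for a, b in zip(stripped, clean) if b == "N" and a != "N")
    return clean, n_coerced


def _open_text(path: str | Path) -> IO[str]:
    """Open a possibly gzip-compressed file as text, sniffing the magic bytes."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with open(path, "rb") as fh:
        magic = fh.read(2)
    if magic == b"\x1f\x8b":
        return io.TextIOWrapper(gzip.open(path, "rb"))
    return open(path, "rt")


def read_fasta(path: str | Path) -> List[SequenceRecord]:
    """Read a (possibly gzipped) FASTA file into an ordered list of records.

    Lowercase bases are uppercased; characters outside {A,C,G,T,N} are
    replaced with N (a single warning reports how many were coerced).
    """
    records: List[SequenceRecord] = []
    n_coerced = 0
    with _open_text(path) as fh:
        first = fh.read(1)
        while first and first.isspace():
            first = fh.read(1)
        if not first:
            raise ParseError(f"{path}: empty FASTA file")
        if first != ">":
            raise ParseError(f"{path}: line 1: expected FASTA header starting with '>'")
        fh.seek(0)
        for rec in SeqIO.parse(fh, "fasta"):
            if not rec.id:
                raise ParseError(f"{path}: FASTA record with empty name")
            seq, bad = _normalize(str(rec.seq))
            n_coerced += bad
            records.append(SequenceRecord(rec.id, seq))
    if n_coerced:
        warnings.warn(
            f"{path}: coerced {n_coerced} non-ACGTN characters to N", stacklevel=2
        )
    return records


def read_reads(path: str | Path) -> Iterator[SequenceRecord]:
    """Stream sequencing reads from FASTA or FASTQ (plain or gzipped).

    The format is auto-detected from the first non-whitespace character
    ('@' FASTQ, '>' FASTA).  Quality strings are discarded: the method uses
    raw k-mer counts only.  An empty file yields an empty stream.
    """
    fh = _open_text(path)
    try:
        first = fh.read(1)
        while first and first.isspace():
            first = fh.read(1)
        if not first:
            return
        if first == "@":
            fmt = "fastq"
        elif first == ">":
            fmt = "fasta"
        else:
            raise ParseError(
                f"{path}: cannot detect read format (first character {first!r})"
            )
        fh.seek(0)
        try:
            for rec in SeqIO.parse(fh, fmt):
                seq, _ = _normalize(str(rec.seq))
                yield SequenceRecord(rec.id, seq)
        except ValueError as exc:  # Biopython signals truncated FASTQ this way
            raise ParseError(f"{path}: {exc}") from exc
    finally:
        fh.close()


def _open_write(path: str | Path) -> IO[str]:
    path = Path(path)
    if path.suffix == ".gz":
        return io.TextIOWrapper(gzip.open(path, "wb"))
    return open(path, "wt")


def write_fasta(records: Iterable[SequenceRecord], path: str | Path) -> None:
    """Write records as FASTA (gzipped when the path ends in .gz)."""
    with _open_write(path) as fh:
        for rec in records:
            fh.write(f">{rec.name}\n{rec.sequence}\n")


def write_fastq(records: Iterable[SequenceRecord], path: str | Path) -> None:
    """Write records as FASTQ with uniform placeholder qualities."""
    with _open_write(path) as fh:
        for rec in records:
            fh.write(f"@{rec.name}\n{rec.sequence}\n+\n{'I' * len(rec.sequence)}\n")


def _sig6(x: float) -> str:
    """Format a float with 6 significant digits, fixed-point."""
    if x == 0:
        return "0.00000"
    return np.format_float_positional(
        x, precision=6, unique=False, fractional=False, trim="k"
    )


def write_bed(scores, path: str | Path) -> None:
    """Write window scores as a 7-column BED-like TSV.

    Columns: chrom, start, end, R, log2R, class, n_kmers.  Windows without
    any supporting k-mer position emit NA ratios and class ``no_data``.
    Scores must be sorted by (chromosome, start); unsorted input raises
    before anything is written.
    """
    scores = list(scores)
    seen: set[str] = set()
    prev_chrom = None
    prev_start = -1
    for s in scores:
        if s.chrom != prev_chrom:
            if s.chrom in seen:
                raise ValueError(
                    "window scores must be grouped by chromosome and sorted by start"
                )
            seen.add(s.chrom)
            prev_chrom = s.chrom
            prev_start = -1
        if s.start < prev_start:
            raise ValueError(
                "window scores must be grouped by chromosome and sorted by start"
            )
        prev_start = s.start
    with _open_write(path) as fh:
        for s in scores:
            if s.n_kmers == 0:
                r_txt = log_txt = "NA"
            else:
                r_txt = _sig6(s.r)
                log_txt = _sig6(s.log2r)
            fh.write(
                f"{s.chrom}\t{s.start}\t{s.end}\t{r_txt}\t{log_txt}\t"
                f"{s.label}\t{s.n_kmers}\n"
            )
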