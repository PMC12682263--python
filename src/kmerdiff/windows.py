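"""Non-overlapping window partitions of the reference genome."""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterator, List, Tuple

import pandas as pd

from .sequence_io import SequenceRecord

__all__ = ["WindowSet", "partition", "import_windows"]


@dataclass
class WindowSet:
    """Per-chromosome ordered lists of 0-based half-open intervals.

    Within a chromosome the intervals are sorted, non-overlapping, and
    contained in [0, chromosome length).
    """

    per_chrom: Dict[str, List[Tuple[int, int]]] = field(default_factory=dict)

    def __iter__(self) -> Iterator[Tuple[str, int, int]]:
        for chrom, ivals in self.per_chrom.items():
            for start, end in ivals:
                yield chrom, start, end

    def __len__(self) -> int:
        return sum(len(v) for v in self.per_chrom.values())

    def to_bed(self, path: str | Path) -> None:
        with open(path, "wt") as fh:
            for chrom, start, end in self:
                fh.write(f"{chrom}\t{start}\t{end}\n")


def partition(genome: List[SequenceRecord], window_size: int) -> WindowSet:
    """Tile every chromosome with consecutive windows of ``window_size``.

    The final window of each chromosome is truncated at the chromosome end
    (it is kept rather than dropped so that terminal regions are scored);
    chromosomes shorter than ``window_size`` yield one whole-chromosome
    window.
    """
    if window_size < 1:
        raise ValueError("window_size must be >= 1")
    ws = WindowSet()
    for rec in genome:
        length = len(rec.sequence)
        ivals = [
            (start, min(start + window_size, length))
            for start in range(0, length, window_size)
        ]
        ws.per_chrom[rec.name] = ivals
    return ws


def import_windows(path: str | Path, genome: List[SequenceRecord]) -> WindowSet:
    """Load window boundaries from a BED file (strict 0-based half-open).

    Intervals are validated against the genome: unknown chromosomes raise,
    intervals running past a chromosome end are clipped with a warning, and
    overlapping intervals raise because the scoring model assumes a
    partition.  Imported windows need not tile the genome.
    """
    bed = pd.read_csv(
        path,
        sep="\t",
        comment="#",
        header=None,
        usecols=[0, 1, 2],
        names=["chrom", "start", "end"],
        dtype={"chrom": str, "start": int, "end": int},
    )
    lengths = {rec.name: len(rec.sequence) for rec in genome}
    unknown = sorted(set(bed["chrom"]) - set(lengths))
    if unknown:
        raise ValueError(f"BED references chromosomes absent from genome: {unknown}")
    ws = WindowSet()
    n_clipped = 0
    for chrom, grp in bed.groupby("chrom", sort=True):
        ivals: List[Tuple[int, int]] = []
        for start, end in sorted(zip(grp["start"], grp["end"])):
            if start < 0 or end <= start:
                raise ValueError(f"invalid interval {chrom}:{start}-{end}")
            if end > lengths[chrom]:
                end = lengths[chrom]
                n_clipped += 1
                if end <= start:
                    continue
            if ivals and start < ivals[-1][1]:
                raise ValueError(
                    f"overlapping windows on {chrom}: "
                    f"{ivals[-1]} and ({start}, {end})"
                )
            ivals.append((start, end))
        ws.per_chrom[chrom] = ivals
    if n_clipped:
        warnings.warn(f"{path}: clipped {n_clipped} intervals at chromosome ends")
    return ws
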