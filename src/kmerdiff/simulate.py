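"""Synthetic genomes, misassembled references, and simulated read sets.

This module provides the full experimental surface of the tool without any
external data: random genomes, case/control genome pairs differing by a
duplicated region, four kinds of misassembled references (novel insertion,
partial deletion, repeat collapse, repeat expansion), uniform-coverage short
reads with i.i.d. substitution errors, and end-degraded read sets emulating
BAL31 nuclease digestion of chromosome termini.

All generators are bit-reproducible given their seed.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator, List, Optional, Sequence, Tuple

import numpy as np

from .kmer_core import decode, encode
from .sequence_io import SequenceRecord
from .windows import WindowSet

__all__ = [
    "ScenarioSpec",
    "ScenarioBundle",
    "MISASSEMBLY_TYPES",
    "random_genome",
    "build_scenario",
    "copy_number_bundle",
    "simulate_reads",
    "simulate_end_degradation",
    "expected_window_labels",
]

MISASSEMBLY_TYPES = (
    "none",
    "A_insertion",
    "B_deletion",
    "C_repeat_collapse",
    "D_repeat_expansion",
)
_TYPE_ALIASES = {"a": "A_insertion", "b": "B_deletion",
                 "c": "C_repeat_collapse", "d": "D_repeat_expansion",
                 "none": "none"}


@dataclass(frozen=True)
class ScenarioSpec:
    """Parameters of one simulated case/control/misassembly experiment.

    Defaults mirror the simulation design of the misassembly experiments:
    a 1000 bp region of a random control genome is duplicated in the case
    genome, 151 bp reads are drawn at 15x (case) and 20x (control) coverage
    with a small substitution error rate.
    """

    genome_length: int = 100_000
    dup_start: Optional[int] = None  # default: genome midpoint, 3 kb aligned
    dup_length: int = 1000
    misassembly_type: str = "none"
    case_coverage: float = 15.0
    control_coverage: float = 20.0
    read_length: int = 151
    error_rate: float = 0.001
    gc: float = 0.5
    seed: int = 0

    def resolved_dup_start(self) -> int:
        if self.dup_start is not None:
            return self.dup_start
        # align to 3 kb so the region boundaries coincide with window
        # boundaries for all the window sizes used in the experiments
        # (300, 500, 1000)
        return (self.genome_length // 2 // 3000) * 3000

    def __post_init__(self) -> None:
        mtype = _TYPE_ALIASES.get(self.misassembly_type.lower(), self.misassembly_type)
        object.__setattr__(self, "misassembly_type", mtype)
        if mtype not in MISASSEMBLY_TYPES:
            raise ValueError(f"unknown misassembly type {self.misassembly_type!r}")
        if not (0 <= self.error_rate < 1):
            raise ValueError("error_rate must be in [0, 1)")
        if self.case_coverage <= 0 or self.control_coverage <= 0:
            raise ValueError("coverages must be positive")
        start = self.resolved_dup_start()
        if start < 0 or start + self.dup_length > self.genome_length:
            raise ValueError("duplicated region does not fit inside the genome")


@dataclass
class ScenarioBundle:
    """Reference, case/control genomes, and ground-truth annotations.

    ``truth`` lists (chrom, start, end, label) intervals in reference
    coordinates for regions whose expected state differs from neutral;
    everything outside them is implicitly neutral.
    """

    reference: List[SequenceRecord]
    control_genome: List[SequenceRecord]
    case_genome: List[SequenceRecord]
    truth: List[Tuple[str, int, int, str]]


def random_genome(
    length: int, seed: int, gc: float = 0.5, name: str = "chr01"
) -> SequenceRecord:
    """I.i.d. random nucleotide sequence with a given GC fraction."""
    if length < 1:
        raise ValueError("length must be >= 1")
    if not (0 <= gc <= 1):
        raise ValueError("gc must be in [0, 1]")
    rng = np.random.default_rng(seed)
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]  # A, C, G, T
    arr = rng.choice(4, size=length, p=p).astype(np.uint8)
    return SequenceRecord(name, decode(arr))


def _insert(seq: str, pos: int, piece: str) -> str:
    return seq[:pos] + piece + seq[pos:]


def _expected_label(case_copies: int, control_copies: int) -> str:
    from .scoring import classify  # local import to avoid a cycle

    if control_copies == 0:
        return "enriched" if case_copies > 0 else "neutral"
    return classify(case_copies / control_copies)


def copy_number_bundle(
    genome_length: int,
    region_start: int,
    region_length: int,
    case_copies: int,
    control_copies: int,
    ref_copies: int = 1,
    seed: int = 0,
    gc: float = 0.5,
) -> ScenarioBundle:
    """Build genomes where a region occurs a chosen number of times per role.

    A base random genome carries one copy of the region at ``region_start``;
    extra tandem copies are inserted immediately after it to reach the
    requested copy numbers (0 copies deletes the region).  The truth label is
    the classification of the case:control copy ratio.
    """
    if min(case_copies, control_copies, ref_copies) < 0:
        raise ValueError("copy numbers must be non-negative")
    if region_start < 0 or region_start + region_length > genome_length:
        raise ValueError("region does not fit inside the genome")
    base = random_genome(genome_length, seed, gc).sequence
    region = base[region_start : region_start + region_length]
    end = region_start + region_length

    def with_copies(n: int) -> List[SequenceRecord]:
        if n == 0:
            seq = base[:region_start] + base[end:]
        else:
            seq = _insert(base, end, region * (n - 1))
        return [SequenceRecord("chr01", seq)]

    label = _expected_label(case_copies, control_copies)
    truth = []
    if label != "neutral" and ref_copies > 0:
        truth.append(
            ("chr01", region_start, region_start + ref_copies * region_length, label)
        )
    return ScenarioBundle(
        reference=with_copies(ref_copies),
        control_genome=with_copies(control_copies),
        case_genome=with_copies(case_copies),
        truth=truth,
    )


def build_scenario(spec: ScenarioSpec) -> ScenarioBundle:
    """Construct the reference/case/control genomes of one experiment.

    The case genome always carries one extra tandem copy of the affected
    region relative to the control.  The reference is a misassembled version
    of the control genome:

    - ``none``: reference identical to the control.
    - ``A_insertion``: a novel random 200 bp inserted at the region midpoint.
    - ``B_deletion``: the central 500 bp of the region removed.
    - ``C_repeat_collapse``: reference has one copy where the control has two
      (case three).
    - ``D_repeat_expansion``: reference has three copies where the control
      has one (case two).
    """
    s = spec.resolved_dup_start()
    L = spec.dup_length
    mtype = spec.misassembly_type

    if mtype == "C_repeat_collapse":
        return copy_number_bundle(
            spec.genome_length, s, L, case_copies=3, control_copies=2,
            ref_copies=1, seed=spec.seed, gc=spec.gc,
        )
    if mtype == "D_repeat_expansion":
        return copy_number_bundle(
            spec.genome_length, s, L, case_copies=2, control_copies=1,
            ref_copies=3, seed=spec.seed, gc=spec.gc,
        )

    bundle = copy_number_bundle(
        spec.genome_length, s, L, case_copies=2, control_copies=1,
        ref_copies=1, seed=spec.seed, gc=spec.gc,
    )
    control = bundle.control_genome[0].sequence
    if mtype == "none":
        return bundle
    if mtype == "A_insertion":
        ins = random_genome(200, _derived_seed(spec.seed, 17), gc=spec.gc).sequence
        ref_seq = _insert(control, s + L // 2, ins)
        # the inserted novel sequence is absent from both read sets (neutral);
        # the flanking duplicated material is the enriched truth
        truth = [
            ("chr01", s, s + L // 2, "enriched"),
            ("chr01", s + L // 2 + 200, s + L + 200, "enriched"),
        ]
    elif mtype == "B_deletion":
        keep = L // 2
        cut_lo = s + keep // 2
        cut_hi = s + L - keep // 2
        ref_seq = control[:cut_lo] + control[cut_hi:]
        truth = [("chr01", s, s + keep, "enriched")]
    else:  # pragma: no cover - exhausted by ScenarioSpec validation
        raise ValueError(mtype)
    return ScenarioBundle(
        reference=[SequenceRecord("chr01", ref_seq)],
        control_genome=bundle.control_genome,
        case_genome=bundle.case_genome,
        truth=truth,
    )


def _derived_seed(seed: int, salt: int) -> int:
    return (seed * 1_000_003 + salt) % (2**31)


def expected_window_labels(
    bundle: ScenarioBundle, windows: WindowSet
) -> List[Tuple[str, int, int, str]]:
    """Expected label per window by majority overlap with truth intervals.

    A window takes a truth label when more than half of its bases fall in
    truth intervals carrying that label (the window score is a median, so
    only a majority of positions determines the expected class); otherwise it
    is neutral.
    """
    out = []
    for chrom, start, end in windows:
        by_label: dict = {}
        for t_chrom, t_start, t_end, t_label in bundle.truth:
            if t_chrom != chrom:
                continue
            overlap = min(end, t_end) - max(start, t_start)
            if overlap > 0:
                by_label[t_label] = by_label.get(t_label, 0) + overlap
        label = "neutral"
        for t_label, bases in by_label.items():
            if bases * 2 > (end - start):
                label = t_label
        out.append((chrom, start, end, label))
    return out


def simulate_reads(
    genome: Sequence[SequenceRecord],
    coverage: float,
    read_length: int,
    error_rate: float,
    seed: int,
) -> Iterator[SequenceRecord]:
    """Uniform-coverage single-end reads with i.i.d. substitution errors.

    round(coverage * total_length / read_length) reads are drawn; each read
    picks a chromosome proportionally to its number of valid start positions,
    a start uniform over those positions, and a strand uniformly at random
    (minus-strand reads are reverse-complemented).  Each base is substituted
    with probability ``error_rate`` to a uniformly chosen different base.
    """
    yield from _simulate_core(genome, coverage, read_length, error_rate, seed,
                              erosion_bp_mean=0.0)


def simulate_end_degradation(
    genome: Sequence[SequenceRecord],
    coverage: float,
    read_length: int,
    erosion_bp_mean: float,
    seed: int,
    error_rate: float = 0.0,
) -> Iterator[SequenceRecord]:
    """Reads from molecules whose chromosome ends have been degraded.

    Each sampled molecule first loses an exponentially distributed number of
    bases (mean ``erosion_bp_mean``) from each chromosome end, then a read is
    drawn uniformly from the remainder, producing a coverage gradient from
    strong depletion at the termini to normal coverage in the interior.
    Molecules eroded below the read length are dropped.  With
    ``erosion_bp_mean=0`` the stream is identical to ``simulate_reads`` with
    the same seed.
    """
    if erosion_bp_mean < 0:
        raise ValueError("erosion_bp_mean must be non-negative")
    yield from _simulate_core(genome, coverage, read_length, error_rate, seed,
                              erosion_bp_mean=erosion_bp_mean)


def _simulate_core(
    genome: Sequence[SequenceRecord],
    coverage: float,
    read_length: int,
    error_rate: float,
    seed: int,
    erosion_bp_mean: float,
) -> Iterator[SequenceRecord]:
    if coverage <= 0:
        raise ValueError("coverage must be positive")
    if not genome:
        raise ValueError("empty genome")
    arrays = [encode(rec.sequence) for rec in genome]
    lengths = np.array([a.size for a in arrays], dtype=np.int64)
    if (lengths < read_length).any():
        short = [rec.name for rec, a in zip(genome, arrays) if a.size < read_length]
        raise ValueError(f"chromosomes shorter than the read length: {short}")
    rng = np.random.default_rng(seed)
    total = int(lengths.sum())
    n_reads = int(round(coverage * total / read_length))
    valid_starts = lengths - read_length + 1
    probs = valid_starts / valid_starts.sum()
    chrom_idx = rng.choice(len(arrays), size=n_reads, p=probs)
    ero_left = rng.standard_exponential(n_reads) * erosion_bp_mean
    ero_right = rng.standard_exponential(n_reads) * erosion_bp_mean
    u_start = rng.random(n_reads)
    minus = rng.integers(0, 2, size=n_reads).astype(bool)
    for i in range(n_reads):
        c = int(chrom_idx[i])
        lo = int(np.ceil(ero_left[i]))
        hi = int(lengths[c] - np.ceil(ero_right[i]))
        n_starts = hi - lo - read_length + 1
        if n_starts < 1:
            continue  # molecule fully degraded
        start = lo + int(u_start[i] * n_starts)
        read = arrays[c][start : start + read_length]
        if minus[i]:
            read = np.where(read < 4, 3 - read, 4)[::-1].astype(np.uint8)
        if error_rate > 0:
            err = (rng.random(read_length) < error_rate) & (read < 4)
            n_err = int(err.sum())
            if n_err:
                read = read.copy()
                shift = rng.integers(1, 4, size=n_err).astype(np.uint8)
                read[err] = (read[err] + shift) % 4
        strand = "-" if minus[i] else "+"
        yield SequenceRecord(
            f"read{i}_{genome[c].name}_{start}{strand}", decode(read)
        )
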