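"""Prepackaged simulation experiments used for validation.

Each function runs one of the synthetic study designs end to end — genome
construction, read simulation, counting, normalization, scoring — and
returns the measured quantities.  The defaults are the study conditions:
151 bp reads at 15x case / 20x control coverage with substitution rate
0.001, k = 21, and a 100 kb genome carrying a 1 kb affected region.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .kmer_core import count_reads, index_reference
from .scoring import (
    DepletionSummary,
    Thresholds,
    WindowScore,
    average_coverage,
    make_context,
    score_windows,
    summarize_depletion,
)
from .simulate import (
    ScenarioBundle,
    ScenarioSpec,
    build_scenario,
    copy_number_bundle,
    expected_window_labels,
    random_genome,
    simulate_end_degradation,
    simulate_reads,
)
from .windows import partition

__all__ = [
    "score_bundle",
    "copy_state_region_ratio",
    "run_misassembly_experiment",
    "run_end_degradation_experiment",
]


def _seed(base: int, salt: int) -> int:
    return (base * 1_000_003 + salt) % (2**31)


def score_bundle(
    bundle: ScenarioBundle,
    seed: int,
    k: int = 21,
    window_size: int = 1000,
    case_coverage: float = 15.0,
    control_coverage: float = 20.0,
    read_length: int = 151,
    error_rate: float = 0.001,
    eps: float = 0.0001,
    thresholds: Thresholds = Thresholds(),
) -> List[WindowScore]:
    """Simulate reads from a scenario bundle and score its reference windows."""
    case = count_reads(
        simulate_reads(bundle.case_genome, case_coverage, read_length,
                       error_rate, _seed(seed, 1)),
        k,
    )
    control = count_reads(
        simulate_reads(bundle.control_genome, control_coverage, read_length,
                       error_rate, _seed(seed, 2)),
        k,
    )
    index = index_reference(bundle.reference, k)
    ctx = make_context(
        average_coverage(case.total_count, index.n_positions),
        average_coverage(control.total_count, index.n_positions),
        eps,
    )
    windows = partition(bundle.reference, window_size)
    return score_windows(case, control, index, windows, ctx, thresholds)


def copy_state_region_ratio(
    case_copies: int,
    control_copies: int,
    seed: int,
    genome_length: int = 100_000,
    region_start: int = 48_000,
    region_length: int = 1000,
    **kwargs,
) -> float:
    """Median window ratio over a region with known case/control copy numbers.

    The region boundaries are aligned with the default 1 kb windows, so the
    returned value is the median R over windows fully inside the region.
    """
    bundle = copy_number_bundle(
        genome_length, region_start, region_length,
        case_copies, control_copies, ref_copies=1, seed=seed,
    )
    scores = score_bundle(bundle, seed, **kwargs)
    vals = [
        s.r for s in scores
        if s.r is not None
        and s.start >= region_start
        and s.end <= region_start + region_length
    ]
    if not vals:
        raise RuntimeError("no scored windows inside the region")
    return float(np.median(vals))


@dataclass
class MisassemblyResult:
    scores: List[WindowScore]
    expected: List[Tuple[str, int, int, str]]

    def enriched_recall(self) -> Tuple[int, int]:
        """(correctly enriched, truth-enriched) window counts."""
        hits = total = 0
        for s, (_, _, _, lab) in zip(self.scores, self.expected):
            if lab == "enriched":
                total += 1
                hits += s.label == "enriched"
        return hits, total

    def neutral_accuracy(self) -> float:
        ok = total = 0
        for s, (_, _, _, lab) in zip(self.scores, self.expected):
            if lab == "neutral" and s.n_kmers > 0:
                total += 1
                ok += s.label == "neutral"
        return ok / total if total else float("nan")

    def labels_in(self, start: int, end: int) -> List[str]:
        return [
            s.label for s in self.scores
            if s.start >= start and s.end <= end
        ]


def run_misassembly_experiment(
    misassembly_type: str,
    seed: int,
    window_size: int,
    k: int = 21,
    genome_length: int = 100_000,
) -> MisassemblyResult:
    """Run one misassembly scenario and pair scores with expected labels."""
    spec = ScenarioSpec(
        genome_length=genome_length, misassembly_type=misassembly_type,
        seed=seed,
    )
    bundle = build_scenario(spec)
    scores = score_bundle(
        bundle, seed, k=k, window_size=window_size,
        case_coverage=spec.case_coverage,
        control_coverage=spec.control_coverage,
        read_length=spec.read_length, error_rate=spec.error_rate,
    )
    expected = expected_window_labels(bundle, partition(bundle.reference,
                                                        window_size))
    return MisassemblyResult(scores=scores, expected=expected)


def run_end_degradation_experiment(
    seed: int,
    k: int,
    window_size: int,
    n_chroms: int = 10,
    chrom_length: int = 50_000,
    control_coverage: float = 17.0,
    treated_coverage: float = 15.0,
    erosion_means: Sequence[float] = (1000.0, 2500.0),
    read_length: int = 151,
    error_rate: float = 0.001,
    terminal_bp: int = 2500,
    _cache: Optional[dict] = None,
) -> List[DepletionSummary]:
    """Depletion summaries of end-degraded read sets versus an intact control.

    Emulates the nuclease-digestion design: one untreated control and one
    treated read set per erosion level, all compared against the same
    multi-chromosome reference.  ``_cache`` (optional dict) reuses count
    tables across calls that share everything but ``window_size``.
    """
    cache = _cache if _cache is not None else {}
    key = ("genome", seed)
    if key not in cache:
        cache[key] = [
            random_genome(chrom_length, _seed(seed, 10 + i),
                          name=f"chr{i + 1:02d}")
            for i in range(n_chroms)
        ]
    genome = cache[key]
    key = ("index", seed, k)
    if key not in cache:
        cache[key] = index_reference(genome, k)
    index = cache[key]
    key = ("control", seed, k)
    if key not in cache:
        cache[key] = count_reads(
            simulate_reads(genome, control_coverage, read_length, error_rate,
                           _seed(seed, 3)),
            k,
        )
    control = cache[key]
    summaries = []
    windows = partition(genome, window_size)
    for j, erosion in enumerate(erosion_means):
        key = ("treated", seed, k, j)
        if key not in cache:
            cache[key] = count_reads(
                simulate_end_degradation(
                    genome, treated_coverage, read_length, erosion,
                    _seed(seed, 4 + j), error_rate,
                ),
                k,
            )
        treated = cache[key]
        ctx = make_context(
            average_coverage(treated.total_count, index.n_positions),
            average_coverage(control.total_count, index.n_positions),
        )
        scores = score_windows(treated, control, index, windows, ctx)
        summaries.append(
            summarize_depletion(scores, index.chrom_lengths,
                                terminal_bp=terminal_bp)
        )
    return summaries
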