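"""Coverage normalization, abundance ratios, and window scoring.

The model: let X_i and Y_i be the occurrence counts of the canonical k-mer at
reference position i in the case and control read sets.  Counts are
normalized by the average k-mer coverage of each sample,

    c_X = (sum_i X_i) / N,    c_Y = (sum_i Y_i) / N,

where N is the number of k-mer positions in the reference.  The abundance
ratio at position i is

    r_i = ((X_i + eps_X) / c_X) / ((Y_i + eps_Y) / c_Y),

with depth-proportional pseudocounts

    eps_X = eps * c_X / (c_X + c_Y),    eps_Y = eps * c_Y / (c_X + c_Y),

so that a k-mer absent from both read sets scores exactly 1 (neutral).  The
score of a window is the median of r_i over the k-mer start positions it
contains, interpreted as the relative copy number of the window between the
two samples (0.5 = one of two copies lost, 1.5 = one gained, 2 = two
gained...).  Identical k-mers at different reference loci always receive the
same ratio, so multi-copy regions report their aggregate copy-number change.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd

from .kmer_core import KmerCountTable, ReferenceIndex
from .windows import WindowSet

__all__ = [
    "NormalizationContext",
    "WindowScore",
    "Thresholds",
    "DEFAULT_THRESHOLDS",
    "DEFAULT_EPS",
    "average_coverage",
    "make_context",
    "abundance_ratio",
    "score_windows",
    "classify",
    "summarize_depletion",
    "DepletionSummary",
]

DEFAULT_EPS = 0.0001
LOG2_FLOOR_R = 1e-12  # ratios below this are floored before taking log2


@dataclass(frozen=True)
class NormalizationContext:
    """Average k-mer coverages of the two samples and their pseudocounts."""

    c_x: float
    c_y: float
    eps: float
    eps_x: float
    eps_y: float


@dataclass(frozen=True)
class Thresholds:
    """Class boundaries on the window ratio R; lower bounds inclusive."""

    absent: float = 0.45
    depleted: float = 0.75
    neutral: float = 1.45

    def __post_init__(self) -> None:
        if not (self.absent < self.depleted < self.neutral):
            raise ValueError("classification thresholds must be strictly increasing")


DEFAULT_THRESHOLDS = Thresholds()


@dataclass(frozen=True)
class WindowScore:
    """Median abundance ratio of one reference window.

    ``r`` is None iff the window contains no valid k-mer start position, in
    which case the label is ``no_data``.
    """

    chrom: str
    start: int
    end: int
    r: Optional[float]
    log2r: Optional[float]
    n_kmers: int
    label: str


def average_coverage(total_count: int, n_positions: int) -> float:
    """Average k-mer coverage: total read k-mer count over reference positions."""
    if n_positions < 1:
        raise ValueError("reference has no valid k-mer positions")
    if total_count < 0:
        raise ValueError("total_count must be non-negative")
    if total_count == 0:
        warnings.warn("read set contributes no k-mers; coverage is 0", stacklevel=2)
    return total_count / n_positions


def make_context(c_x: float, c_y: float, eps: float = DEFAULT_EPS) -> NormalizationContext:
    """Build the normalization context with depth-proportional pseudocounts."""
    if eps <= 0:
        raise ValueError("eps must be positive")
    if c_x < 0 or c_y < 0 or c_x + c_y <= 0:
        raise ValueError("coverages must be non-negative with a positive sum")
    eps_x = eps * c_x / (c_x + c_y)
    eps_y = eps * c_y / (c_x + c_y)
    return NormalizationContext(c_x=c_x, c_y=c_y, eps=eps, eps_x=eps_x, eps_y=eps_y)


def abundance_ratio(x_i: float, y_i: float, ctx: NormalizationContext) -> float:
    """Normalized case/control abundance ratio of one k-mer.

    When the k-mer is absent from both read sets the depth-proportional
    pseudocounts make the ratio exactly 1 (neutral).
    """
    return ((x_i + ctx.eps_x) / ctx.c_x) / ((y_i + ctx.eps_y) / ctx.c_y)


def _ratios_vector(x: np.ndarray, y: np.ndarray, ctx: NormalizationContext) -> np.ndarray:
    return ((x + ctx.eps_x) / ctx.c_x) / ((y + ctx.eps_y) / ctx.c_y)


def classify(
    r: Optional[float], thresholds: Thresholds = DEFAULT_THRESHOLDS
) -> str:
    """Map a window ratio to {absent, depleted, neutral, enriched, no_data}."""
    if r is None:
        return "no_data"
    if r < 0:
        raise ValueError("window ratio cannot be negative")
    if r < thresholds.absent:
        return "absent"
    if r < thresholds.depleted:
        return "depleted"
    if r < thresholds.neutral:
        return "neutral"
    return "enriched"


def score_windows(
    case: KmerCountTable,
    control: KmerCountTable,
    index: ReferenceIndex,
    windows: WindowSet,
    ctx: NormalizationContext,
    thresholds: Thresholds = DEFAULT_THRESHOLDS,
) -> List[WindowScore]:
    """Score every window with the median abundance ratio of its k-mer starts.

    A k-mer belongs to the window containing its start position, even when it
    overhangs the window end; the last k-1 bases of a chromosome therefore
    contribute no positions.  Positions whose k-mer window contains an
    ambiguous base are excluded.  An even number of positions takes the mean
    of the two central ratios.
    """
    if case.k != index.k or control.k != index.k:
        raise ValueError(
            f"k mismatch: case={case.k} control={control.k} index={index.k}"
        )
    unknown = sorted(set(windows.per_chrom) - set(index.chroms))
    if unknown:
        raise ValueError(f"windows reference unknown chromosomes: {unknown}")
    scores: List[WindowScore] = []
    for chrom, ivals in windows.per_chrom.items():
        codes, valid = index.chroms[chrom]
        r_all = np.full(codes.size, np.nan)
        if valid.any():
            vcodes = codes[valid]
            x = case.lookup_codes(vcodes)
            y = control.lookup_codes(vcodes)
            r_all[valid] = _ratios_vector(x, y, ctx)
        for start, end in ivals:
            hi = min(end, codes.size)
            vals = r_all[start:hi]
            vals = vals[~np.isnan(vals)]
            if vals.size == 0:
                scores.append(
                    WindowScore(chrom, start, end, None, None, 0, "no_data")
                )
                continue
            r = float(np.median(vals))
            log2r = math.log2(max(r, LOG2_FLOOR_R))
            scores.append(
                WindowScore(chrom, start, end, r, log2r, int(vals.size),
                            classify(r, thresholds))
            )
    return scores


@dataclass
class DepletionSummary:
    """Genome-wide and chromosome-terminal depleted-window statistics.

    A window counts as depleted when log2(R) is at or below the cutoff
    (default -1, i.e. at most half the control abundance).  The terminal
    statistic covers windows overlapping the first or last ``terminal_bp``
    bases of any chromosome by at least one base.  ``no_data`` windows are
    excluded throughout.  ``terminal_pct_of_all`` additionally normalizes the
    terminal depleted count by all scored windows in the genome.
    """

    genome_pct_depleted: float
    terminal_pct_depleted: float
    terminal_pct_of_all: float
    per_chromosome: pd.DataFrame

    def to_frame(self) -> pd.DataFrame:
        """Report rows: scope, chromosome, windows_total, windows_depleted, pct."""
        totals = self.per_chromosome.groupby("scope")[
            ["windows_total", "windows_depleted"]
        ].sum()
        rows = []
        for scope in ("genome", "terminal"):
            tot = int(totals.loc[scope, "windows_total"]) if scope in totals.index else 0
            dep = int(totals.loc[scope, "windows_depleted"]) if scope in totals.index else 0
            rows.append(
                {
                    "scope": scope,
                    "chromosome": "ALL",
                    "windows_total": tot,
                    "windows_depleted": dep,
                    "pct": 100.0 * dep / tot if tot else float("nan"),
                }
            )
        return pd.concat([pd.DataFrame(rows), self.per_chromosome], ignore_index=True)


def summarize_depletion(
    scores: Sequence[WindowScore],
    chrom_lengths: Dict[str, int],
    terminal_bp: int = 2500,
    log2_cutoff: float = -1.0,
) -> DepletionSummary:
    """Summarize depleted windows genome-wide and at chromosome ends."""
    scores = [s for s in scores]
    if not scores:
        raise ValueError("no window scores to summarize")
    rows = []
    gen_tot = gen_dep = term_tot = term_dep = 0
    by_chrom: Dict[str, List[WindowScore]] = {}
    for s in scores:
        by_chrom.setdefault(s.chrom, []).append(s)
    for chrom, chrom_scores in by_chrom.items():
        length = chrom_lengths[chrom]
        c_tot = c_dep = ct_tot = ct_dep = 0
        for s in chrom_scores:
            if s.n_kmers == 0:
                continue
            depleted = s.log2r is not None and s.log2r <= log2_cutoff
            c_tot += 1
            c_dep += int(depleted)
            is_terminal = s.start < terminal_bp or s.end > length - terminal_bp
            if is_terminal:
                ct_tot += 1
                ct_dep += int(depleted)
        gen_tot += c_tot
        gen_dep += c_dep
        term_tot += ct_tot
        term_dep += ct_dep
        rows.append(
            {"scope": "genome", "chromosome": chrom, "windows_total": c_tot,
             "windows_depleted": c_dep,
             "pct": 100.0 * c_dep / c_tot if c_tot else float("nan")}
        )
        rows.append(
            {"scope": "terminal", "chromosome": chrom, "windows_total": ct_tot,
             "windows_depleted": ct_dep,
             "pct": 100.0 * ct_dep / ct_tot if ct_tot else float("nan")}
        )
    return DepletionSummary(
        genome_pct_depleted=100.0 * gen_dep / gen_tot if gen_tot else float("nan"),
        terminal_pct_depleted=100.0 * term_dep / term_tot if term_tot else float("nan"),
        terminal_pct_of_all=100.0 * term_dep / gen_tot if gen_tot else float("nan"),
        per_chromosome=pd.DataFrame(rows),
    )
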