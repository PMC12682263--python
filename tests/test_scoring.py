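import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import brute_canonical, brute_count, random_dna
from kmerdiff import (
    KmerCountTable,
    SequenceRecord,
    Thresholds,
    WindowSet,
    abundance_ratio,
    average_coverage,
    classify,
    count_reads,
    index_reference,
    make_context,
    partition,
    score_windows,
    summarize_depletion,
)
from kmerdiff.scoring import WindowScore

positive = st.floats(0.1, 1000, allow_nan=False, allow_infinity=False)


# --- normalization context -------------------------------------------------

def test_make_context_pseudocount_identities():
    ctx = make_context(8, 16, 0.0001)
    assert ctx.eps_x == pytest.approx(0.0001 * 8 / 24, rel=1e-15)
    assert ctx.eps_y == pytest.approx(0.0001 * 16 / 24, rel=1e-15)


def test_make_context_symmetric_coverages_split_eps_evenly():
    ctx = make_context(5, 5, 0.001)
    assert ctx.eps_x == ctx.eps_y == pytest.approx(0.0005)


@settings(derandomize=True, max_examples=100)
@given(positive, positive, st.floats(1e-8, 1.0))
def test_pseudocounts_always_sum_to_eps(c_x, c_y, eps):
    ctx = make_context(c_x, c_y, eps)
    assert ctx.eps_x + ctx.eps_y == pytest.approx(eps, rel=1e-12)


@pytest.mark.parametrize("c_x,c_y,eps", [(1, 1, 0), (1, 1, -1), (0, 0, 0.1)])
def test_make_context_rejects_degenerate_input(c_x, c_y, eps):
    with pytest.raises(ValueError):
        make_context(c_x, c_y, eps)


def test_average_coverage_direct_quotient():
    assert average_coverage(800, 100) == 8.0


def test_average_coverage_zero_mass_warns():
    with pytest.warns(UserWarning, match="coverage is 0"):
        assert average_coverage(0, 100) == 0.0


def test_average_coverage_requires_positions():
    with pytest.raises(ValueError, match="no valid k-mer positions"):
        average_coverage(10, 0)


def test_average_coverage_of_uniform_read_sampling():
    """At uniform coverage c with read length L, each reference k-mer is
    covered by reads starting in a window of L-k+1 positions, so the average
    k-mer coverage approaches c*(L-k+1)/L."""
    from kmerdiff import random_genome, simulate_reads

    k, L, cov = 21, 151, 20
    genome = [random_genome(10_000, seed=3)]
    table = count_reads(simulate_reads(genome, cov, L, 0.0, seed=4), k)
    ix = index_reference(genome, k)
    c = average_coverage(table.total_count, ix.n_positions)
    expected = cov * (L - k + 1) / L
    assert abs(c - expected) / expected < 0.15


# --- abundance ratio -------------------------------------------------------

def test_ratio_of_doubly_absent_kmer_is_neutral():
    ctx = make_context(8, 16, 0.0001)
    assert abundance_ratio(0, 0, ctx) == pytest.approx(1.0, abs=1e-12)


@settings(derandomize=True, max_examples=1000)
@given(
    st.integers(0, 10_000),
    st.integers(0, 10_000),
    positive,
    positive,
    st.floats(1e-6, 0.01),
)
def test_ratio_matches_direct_formula_evaluation(x, y, c_x, c_y, eps):
    ctx = make_context(c_x, c_y, eps)
    eps_x = eps * c_x / (c_x + c_y)
    eps_y = eps * c_y / (c_x + c_y)
    direct = ((x + eps_x) / c_x) / ((y + eps_y) / c_y)
    assert abundance_ratio(x, y, ctx) == pytest.approx(direct, rel=1e-12)


def test_ratio_limit_for_absent_case_kmer():
    ctx = make_context(8, 16, 0.0001)
    r = abundance_ratio(0, 10_000, ctx)
    approx = ctx.eps_x * ctx.c_y / (ctx.c_x * 10_000)
    assert r == pytest.approx(approx, rel=1e-3)
    assert r < 1e-7


def test_case_control_swap_inverts_every_ratio():
    ctx = make_context(8.3, 17.1, 0.0001)
    swapped = make_context(17.1, 8.3, 0.0001)
    for x, y in [(0, 0), (5, 12), (40, 3), (0, 9), (7, 0)]:
        r = abundance_ratio(x, y, ctx)
        assert abundance_ratio(y, x, swapped) == pytest.approx(1 / r, rel=1e-12)


# --- classification --------------------------------------------------------

@pytest.mark.parametrize(
    "r,label",
    [
        (0.0, "absent"),
        (0.44, "absent"),
        (0.45, "depleted"),  # lower bounds are inclusive
        (0.5, "depleted"),
        (0.74, "depleted"),
        (0.75, "neutral"),
        (1.0, "neutral"),
        (1.44, "neutral"),
        (1.45, "enriched"),
        (2.0, "enriched"),
        (None, "no_data"),
    ],
)
def test_classify_thresholds(r, label):
    assert classify(r) == label


def test_classify_rejects_negative_ratio():
    with pytest.raises(ValueError):
        classify(-0.1)


def test_thresholds_must_increase():
    with pytest.raises(ValueError):
        Thresholds(0.75, 0.45, 1.45)


# --- window scoring --------------------------------------------------------

def _ctx_and_tables(genome_seq, k, x_counts, y_counts, c_x=10.0, c_y=10.0):
    """Build tables from explicit per-k-mer counts over a toy genome."""
    index = index_reference([SequenceRecord("c1", genome_seq)], k)
    case = KmerCountTable.from_dict(k, x_counts)
    control = KmerCountTable.from_dict(k, y_counts)
    return case, control, index, make_context(c_x, c_y, 0.0001)


def test_window_median_odd_count():
    # genome AAACC: k-mer positions AAA, AAC, ACC with ratios 0.4, 0.5, 0.6
    case, control, ix, ctx = _ctx_and_tables(
        "AAACC", 3,
        {"AAA": 4, "AAC": 5, "ACC": 6},
        {"AAA": 10, "AAC": 10, "ACC": 10},
    )
    ws = WindowSet({"c1": [(0, 5)]})
    (score,) = score_windows(case, control, ix, ws, ctx)
    assert score.r == pytest.approx(0.5, abs=1e-4)
    assert score.n_kmers == 3


def test_window_median_even_count_averages_central_values():
    # AAACCC: positions AAA, AAC, ACC, CCC with ratios 0.2, 0.4, 0.6, 0.8
    case, control, ix, ctx = _ctx_and_tables(
        "AAACCC", 3,
        {"AAA": 2, "AAC": 4, "ACC": 6, "CCC": 8},
        {"AAA": 10, "AAC": 10, "ACC": 10, "CCC": 10},
    )
    ws = WindowSet({"c1": [(0, 6)]})
    (score,) = score_windows(case, control, ix, ws, ctx)
    assert score.r == pytest.approx(0.5, abs=1e-4)
    assert score.n_kmers == 4


def test_window_of_doubly_absent_kmers_is_neutral():
    case, control, ix, ctx = _ctx_and_tables("AAACC", 3, {}, {})
    ws = WindowSet({"c1": [(0, 5)]})
    (score,) = score_windows(case, control, ix, ws, ctx)
    assert score.r == pytest.approx(1.0, abs=1e-9)
    assert score.label == "neutral"


def test_identical_read_streams_score_neutral_everywhere(rng):
    genome = [SequenceRecord("c1", random_dna(rng, 3000))]
    reads = [
        SequenceRecord(f"r{i}", genome[0].sequence[s : s + 100])
        for i, s in enumerate(rng.integers(0, 2900, size=200))
    ]
    table = count_reads(reads, 11)
    ix = index_reference(genome, 11)
    c = average_coverage(table.total_count, ix.n_positions)
    ctx = make_context(c, c, 0.0001)
    for score in score_windows(table, table, ix, partition(genome, 500), ctx):
        assert score.r == pytest.approx(1.0, abs=1e-9)


def test_window_beyond_kmer_positions_is_no_data():
    case, control, ix, ctx = _ctx_and_tables("AAACC", 3, {"AAA": 1}, {"AAA": 1})
    ws = WindowSet({"c1": [(0, 3), (3, 5)]})  # last window has no k-mer starts
    first, last = score_windows(case, control, ix, ws, ctx)
    assert first.n_kmers == 3
    assert last.n_kmers == 0
    assert last.label == "no_data"
    assert last.r is None


def test_score_windows_rejects_unknown_chromosome():
    case, control, ix, ctx = _ctx_and_tables("AAACC", 3, {}, {})
    with pytest.raises(ValueError, match="unknown chromosome"):
        score_windows(case, control, ix, WindowSet({"cX": [(0, 5)]}), ctx)


def test_score_windows_rejects_k_mismatch():
    case, control, ix, ctx = _ctx_and_tables("AAACC", 3, {}, {})
    bad = KmerCountTable.from_dict(5, {})
    with pytest.raises(ValueError, match="mismatch"):
        score_windows(bad, control, ix, WindowSet({"c1": [(0, 5)]}), ctx)


def _oracle_scores(genome_seq, k, case_seqs, control_seqs, windows, eps=0.0001):
    """Per-position string-based rescoring, independent of the packed path."""
    x_counts = brute_count(case_seqs, k)
    y_counts = brute_count(control_seqs, k)
    positions = [
        brute_canonical(genome_seq[i : i + k])
        for i in range(len(genome_seq) - k + 1)
    ]
    n = sum(p is not None for p in positions)
    c_x = sum(x_counts.values()) / n
    c_y = sum(y_counts.values()) / n
    eps_x = eps * c_x / (c_x + c_y)
    eps_y = eps * c_y / (c_x + c_y)
    out = []
    for start, end in windows:
        vals = []
        for i in range(start, min(end, len(positions))):
            p = positions[i]
            if p is None:
                continue
            r = ((x_counts[p] + eps_x) / c_x) / ((y_counts[p] + eps_y) / c_y)
            vals.append(r)
        out.append(float(np.median(vals)) if vals else None)
    return out


def test_score_windows_matches_string_oracle(rng):
    """Full-pipeline equivalence with an independent string-based rescorer."""
    k = 5
    for _ in range(10):
        genome_seq = random_dna(rng, 240, alphabet="ACGTN" if rng.random() < 0.3 else "ACGT")
        case_seqs = [random_dna(rng, 60) for _ in range(15)]
        control_seqs = [random_dna(rng, 60) for _ in range(15)]
        genome = [SequenceRecord("c1", genome_seq)]
        case = count_reads([SequenceRecord(f"x{i}", s) for i, s in enumerate(case_seqs)], k)
        control = count_reads([SequenceRecord(f"y{i}", s) for i, s in enumerate(control_seqs)], k)
        ix = index_reference(genome, k)
        c_x = average_coverage(case.total_count, ix.n_positions)
        c_y = average_coverage(control.total_count, ix.n_positions)
        ctx = make_context(c_x, c_y)
        ws = partition(genome, 50)
        got = score_windows(case, control, ix, ws, ctx)
        expected = _oracle_scores(
            genome_seq, k, case_seqs, control_seqs, ws.per_chrom["c1"]
        )
        for g, e in zip(got, expected):
            if e is None:
                assert g.r is None
            else:
                assert g.r == pytest.approx(e, rel=1e-9)


def test_repeat_copies_share_identical_window_scores(rng):
    """Identical k-mers at different loci receive identical ratios, so two
    exact repeat copies score identically over their interiors."""
    k = 11
    left, copy, mid, right = (
        random_dna(rng, 100),
        random_dna(rng, 120),
        random_dna(rng, 150),
        random_dna(rng, 100),
    )
    genome_seq = left + copy + mid + copy + right
    genome = [SequenceRecord("c1", genome_seq)]
    reads = [
        SequenceRecord(f"r{i}", genome_seq[s : s + 50])
        for i, s in enumerate(rng.integers(0, len(genome_seq) - 50, size=150))
    ]
    case = count_reads(reads, k)
    control = count_reads(reads[::2], k)
    ix = index_reference(genome, k)
    ctx = make_context(
        average_coverage(case.total_count, ix.n_positions),
        average_coverage(control.total_count, ix.n_positions),
    )
    # interior windows of the two copies (clear of the k-1 junction overhang)
    c1, c2 = 100, 100 + 120 + 150
    ws = WindowSet({"c1": [(c1 + 15, c1 + 95), (c2 + 15, c2 + 95)]})
    s1, s2 = score_windows(case, control, ix, ws, ctx)
    assert s1.r == s2.r


def test_depth_invariance_exact_under_eps_rescaling(rng):
    """Duplicating one read set leaves every normalized abundance x/c_X fixed;
    the ratio is exactly invariant when the pseudocount scale is rescaled in
    proportion to the combined coverage (the shared pseudocount term
    eps/(c_X+c_Y) is then unchanged)."""
    c_x, c_y, eps = 9.7, 21.3, 0.0001
    ctx = make_context(c_x, c_y, eps)
    eps2 = eps * (2 * c_x + c_y) / (c_x + c_y)
    ctx2 = make_context(2 * c_x, c_y, eps2)
    for x, y in [(0, 0), (3, 17), (25, 4), (0, 40)]:
        assert abundance_ratio(2 * x, y, ctx2) == pytest.approx(
            abundance_ratio(x, y, ctx), rel=1e-12
        )


def test_depth_invariance_bounded_by_pseudocount_at_fixed_eps():
    """At fixed eps the perturbation from doubling one read set is bounded by
    the change in the shared pseudocount term, itself below eps."""
    c_x, c_y, eps = 9.7, 21.3, 0.0001
    ctx = make_context(c_x, c_y, eps)
    ctx2 = make_context(2 * c_x, c_y, eps)
    for x, y in [(3, 17), (25, 4), (13, 13), (1, 40)]:
        r1 = abundance_ratio(x, y, ctx)
        r2 = abundance_ratio(2 * x, y, ctx2)
        assert abs(r2 - r1) <= eps * max(r1, 1.0)


def test_median_absorbs_minority_outliers():
    """Corrupting a quarter of the positions with extreme ratios moves the
    window median far less than the corruption magnitude."""
    k = 3
    # 12 positions over genome of homopolymer-free 3-mers
    genome_seq = "AACAGATCCGCTGGTT"
    ix = index_reference([SequenceRecord("c1", genome_seq)], k)
    kmers = sorted({brute_canonical(genome_seq[i : i + 3]) for i in range(14)})
    clean_x = {km: 10 for km in kmers}
    y = {km: 10 for km in kmers}
    corrupt_x = dict(clean_x)
    for km in kmers[:3]:  # <= 25% of distinct k-mers get a 100x outlier
        corrupt_x[km] = 1000
    ctx = make_context(10.0, 10.0, 0.0001)
    ws = WindowSet({"c1": [(0, len(genome_seq))]})
    (clean,) = score_windows(
        KmerCountTable.from_dict(k, clean_x),
        KmerCountTable.from_dict(k, y), ix, ws, ctx,
    )
    (dirty,) = score_windows(
        KmerCountTable.from_dict(k, corrupt_x),
        KmerCountTable.from_dict(k, y), ix, ws, ctx,
    )
    assert abs(dirty.r - clean.r) < 0.5  # outliers were 100x


# --- depletion summary -----------------------------------------------------

def _mk_scores(chrom, length, w, log2rs):
    out = []
    for i, v in enumerate(log2rs):
        start = i * w
        end = min(start + w, length)
        out.append(WindowScore(chrom, start, end, 2.0**v, v, w, "x"))
    return out


def test_summarize_depletion_all_neutral():
    scores = _mk_scores("c1", 10_000, 1000, [0.0] * 10)
    s = summarize_depletion(scores, {"c1": 10_000})
    assert s.genome_pct_depleted == 0
    assert s.terminal_pct_depleted == 0


def test_summarize_depletion_all_depleted():
    scores = _mk_scores("c1", 10_000, 1000, [-2.0] * 10)
    s = summarize_depletion(scores, {"c1": 10_000})
    assert s.genome_pct_depleted == 100
    assert s.terminal_pct_depleted == 100


def test_summarize_depletion_terminal_only_depletion():
    """Only terminal windows depleted: genome percentage is diluted by the
    interior, terminal percentage is 100."""
    log2rs = [-2.0] + [0.0] * 8 + [-2.0]
    scores = _mk_scores("c1", 10_000, 1000, log2rs)
    s = summarize_depletion(scores, {"c1": 10_000}, terminal_bp=2500)
    # terminal windows: starts 0,1000,2000 and 7000(end 8000 > 7500),8000,9000
    assert s.terminal_pct_depleted == pytest.approx(100 * 2 / 6)
    assert s.genome_pct_depleted == pytest.approx(100 * 2 / 10)
    assert s.terminal_pct_of_all == pytest.approx(100 * 2 / 10)


def test_summarize_depletion_excludes_no_data_windows():
    scores = _mk_scores("c1", 10_000, 1000, [-2.0] * 10)
    scores[5] = WindowScore("c1", 5000, 6000, None, None, 0, "no_data")
    s = summarize_depletion(scores, {"c1": 10_000})
    assert s.genome_pct_depleted == 100  # 9 of 9 scored


def test_summarize_depletion_boundary_cutoff_inclusive():
    scores = _mk_scores("c1", 4000, 1000, [-1.0, -0.999, 0.0, 0.0])
    s = summarize_depletion(scores, {"c1": 4000})
    assert s.genome_pct_depleted == pytest.approx(25.0)


def test_summarize_depletion_empty_raises():
    with pytest.raises(ValueError):
        summarize_depletion([], {"c1": 100})


def test_depletion_report_frame_shape():
    scores = _mk_scores("c1", 10_000, 1000, [0.0] * 10)
    frame = summarize_depletion(scores, {"c1": 10_000}).to_frame()
    assert list(frame.columns) == [
        "scope", "chromosome", "windows_total", "windows_depleted", "pct",
    ]
    assert set(frame["scope"]) == {"genome", "terminal"}
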