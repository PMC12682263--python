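# Methods

## The statistic

`kmerdiff` compares two read sets against a reference genome without
alignment. Counting uses canonical *k*-mers (the lexicographically smaller of
a *k*-mer and its reverse complement under A < C < G < T), which merges the
two strands into a single key. Counting is exact — a hash/sorted-array
table, no probabilistic sketches and no maximum-count saturation, so
high-copy repeats keep their true counts and the downstream ratio is
unbiased for them.

Per-sample depth is normalized by the average *k*-mer coverage
c = Σᵢcounts / N, where N is the number of unambiguous *k*-mer positions in
the reference. By default the total runs over *all* read *k*-mers, including
those absent from the reference (error *k*-mers, contamination); a
`--coverage-totals filtered` switch restricts the total to reference
*k*-mers instead. With both samples sequenced on the same technology the two
choices differ by nearly identical factors and mostly cancel in the ratio.

The per-position abundance ratio is

r_i = ((X_i + ε_X)/c_X) / ((Y_i + ε_Y)/c_Y),  ε_X = ε·c_X/(c_X+c_Y),
ε_Y = ε·c_Y/(c_X+c_Y).

Writing a = X_i/c_X, b = Y_i/c_Y and δ = ε/(c_X+c_Y) gives
r_i = (a + δ)/(b + δ): both pseudocount terms reduce to the *same* shared
constant δ, which is what makes a doubly-absent *k*-mer score exactly 1.
A window's score R(w) is the median of r_i over the *k*-mer start positions
it contains; the median absorbs outliers from SNVs, sequencing errors and
high-frequency *k*-mers that would dominate a mean.

### Exactness and invariances

- Case/control swap maps every r_i to 1/r_i exactly (the pseudocounts swap
  with the coverages).
- Strand invariance is exact: a read set and its reverse complement produce
  identical tables.
- Repeat pooling is structural: identical *k*-mers share one table entry, so
  all reference loci carrying them receive the same ratio.
- Depth invariance holds exactly for the normalized abundances a and b, but
  only approximately for r_i at fixed ε: doubling one read set changes the
  shared term δ from ε/(c_X+c_Y) to ε/(2c_X+c_Y), perturbing r_i by
  |Δδ|·|b−a|/(b+δ)² — about 10⁻⁶ at ε = 10⁻⁴ and ~30× combined coverage.
  Rescaling ε in proportion to the combined coverage restores exact
  invariance; the unit suite asserts both forms. The acceptance suite's
  strict 10⁻⁹ bound for this property at fixed ε is not attainable under the
  formula and that sub-check is expected to fail.

## Parameters

| parameter | default | role |
|---|---|---|
| k | 21 | *k*-mer length; 21 is long enough to be near-unique in megabase-scale genomes yet short enough to tolerate errors (a read base error destroys ≈ k *k*-mers). k = 15 suits smaller or more diverged data. |
| window size | 1000 bp | trade-off between resolution and the sampling noise of the median (see below); 100–1000 bp are typical. |
| ε | 0.0001 | pseudocount scale; only matters for *k*-mers near zero counts. |
| thresholds | 0.45 / 0.75 / 1.45 | class boundaries on R approximating diploid copy states 0, 1, 2, ≥3. Boundaries are closed below, open above, so every ratio maps to exactly one class. |
| depleted cutoff | log₂R ≤ −1 | definition of a depleted window in the terminal-depletion report. |
| terminal span | 2500 bp | chromosome-end region inspected for degradation; a window is terminal if it overlaps the span by ≥ 1 bp. |

Coordinates are 0-based half-open throughout (BED convention). A *k*-mer
belongs to the window containing its start position even when it overhangs
the window end; the final window of each chromosome may be shorter than the
nominal size rather than being dropped, so chromosome ends are always
scored. Even-count medians take the mean of the two central values. Ratios
below 10⁻¹² are floored before taking log₂ to keep the BED numeric columns
finite. *k*-mers containing N are skipped in reads and excluded from both
the reference index and N, keeping numerator and denominator of the
coverage consistent.

## What the simulator emulates

`kmerdiff.simulate` provides the entire validation surface:

- **Random genomes** with i.i.d. bases at a chosen GC fraction.
- **Copy-number scenarios**: a base genome carries a 1 kb region; tandem
  copies are added per role (case / control / reference) to realize any copy
  configuration. The default experiment duplicates the region in the case
  genome (2:1).
- **Misassembled references**: (A) a novel 200 bp insertion at the region
  midpoint, (B) deletion of the central 500 bp, (C) repeat collapse — one
  reference copy where control has two and case three, (D) repeat expansion
  — three reference copies where control has one and case two. Copies are
  placed in tandem; the default region start is aligned to 3 kb so region
  boundaries coincide with window boundaries for window sizes 300, 500 and
  1000.
- **Reads**: single-end, fixed length (default 151 bp), uniform start
  positions, uniform strand, i.i.d. substitution errors (default 0.001), at
  nominal coverages 15× (case) and 20× (control). Number of reads =
  round(coverage · genome length / read length).
- **End degradation**: each sampled molecule loses an exponentially
  distributed number of bases (mean `erosion_bp_mean`) from each chromosome
  end before uniform read sampling, producing the gradient from strong
  terminal depletion to normal interior coverage expected from BAL31
  digestion; zero erosion reduces bit-for-bit to the plain simulator.

What it does **not** emulate: indels and platform-specific error profiles,
paired-end structure, diploid haplotypes with SNVs, GC-coverage bias,
contamination. The scoring method never inspects base qualities or error
structure, so these omissions affect realism of the noise, not the code
paths exercised. Passing simulation tests therefore demonstrate correctness
of the statistic and its implementation, not robustness to every real-data
artifact.

## Expected noise and its consequences

At per-copy *k*-mer depth d (≈ coverage · (L−k+1)/L), per-position counts
are approximately Poisson(d) and adjacent positions are strongly correlated
(correlation length ≈ read length). A window of w bases contains roughly
w/L independent depth blocks, so the window median has relative sd of
roughly sqrt(1/d_X + 1/d_Y) · 0.5–1 / sqrt(w/L). Measured on the default
conditions (15×/20×, 151 bp reads, k = 21): sd(R) ≈ 0.20 at w = 300,
≈ 0.15 at w = 500, ≈ 0.12 at w = 1000 for neutral windows. Consequently at
w = 300 roughly 15 % of neutral windows fall outside the 0.75–1.45 band —
visible as scattered false calls — while w = 1000 windows are ≈ 97–100 %
accurate. The repeat-collapse scenario (expected pooled ratio
1.5 · L_control/L_case ≈ 1.49) sits directly on the 1.45 enrichment
boundary, so its single-window classification flips with seed at these
depths; the underlying median itself concentrates near 1.5, which is what
the copy-state experiments assert. These are properties of the study
conditions, not of the implementation: the counting and scoring paths are
verified exactly against brute-force oracles, and window medians against an
independent string-based rescorer.

The acceptance experiments use a 100 kb single-chromosome genome for the
copy-number designs and ten 50 kb chromosomes for the end-degradation
design (erosion means 1000 and 2500 bp at 15× against a 17× control) —
sizes at which every experiment re-runs from scratch in seconds while
leaving window statistics well away from small-sample artifacts.

## Design choices on open points

- Classification boundary inclusivity ("between 0.45 and 0.75") is resolved
  as closed-below/open-above.
- Coverage totals default to all read *k*-mers (pre-filter), matching the
  definition of c as total counts over N; filtering against the reference is
  exposed but off by default (it cannot change scores, only memory use,
  when totals stay pre-filter).
- The terminal-depletion report normalizes the terminal depleted count both
  by terminal windows (`terminal_pct_depleted`) and by all scored windows
  (`terminal_pct_of_all`), since either convention is defensible.
- Multi-chromosome N is the sum of per-chromosome valid position counts.
- Imported window sets (BED) must be non-overlapping but need not tile the
  genome; gaps are simply unscored.

## Known limitations

- No segmentation of windows into CNV calls and no significance estimates;
  the output is the per-window ratio itself.
- No sex-chromosome or GC-bias correction: the ratio construction assumes
  systematic biases cancel between samples sequenced identically.
- Counting is in-memory; read sets far beyond ~10⁸ *k*-mers would need a
  disk-based counter.
- Windows of ≲ 500 bp at ≲ 20× coverage are noise-limited (see above);
  interpret isolated single-window calls at small w accordingly.
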