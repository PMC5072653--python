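# Methods

## Model and assumptions

The package analyzes a dense gene × sample matrix of log-scale, nonnegative
expression values (log2 microarray intensities or log2(x+1) counts). Input
is assumed already log-transformed and gene-level; the reader validates
nonnegativity and offers a `--log2p1` convenience flag, but deliberately
performs no platform normalization or probe-to-gene mapping.

Per-gene normalization divides each value by the gene's row sum and
subtracts the average share 1/N. Two consequences drive everything
downstream: (1) every retained gene's normalized row sums to exactly zero,
so "above/below average" is simply the sign of a score and the up/down
threshold is hard-coded at 0 rather than re-estimated; (2) the transform is
invariant to per-gene scaling, so genes contribute comparably to set scores
regardless of absolute expression. Genes whose row sum is zero carry no
between-sample signal and are dropped with a warning rather than imputed.

A gene set's score in a sample is the arithmetic mean of normalized values
over the genes shared between set and matrix. Because the matrix is dense,
the gene universe is the same in every sample, and set support is a per-set
count. Sets intersecting fewer than `min_support` genes (default 1) are
excluded and reported.

## Enrichment

Each set yields a 2×2 table of up/down sample counts (score > 0 vs ≤ 0)
split by control/case. Exact zeros count as "down": the table must
partition all samples, zeros are measure-zero for real data, and ties are
logged when they occur. The two-sided Fisher exact p sums hypergeometric
probabilities no larger than the observed table's (minimum-likelihood
convention). It is computed with exact integer binomial coefficients —
table-probability ties are compared exactly, the single floating-point
operation is the final division — which keeps the test reproducible against
rational-arithmetic enumeration at 1e-12. Adjustment is Benjamini–Hochberg
by default (Benjamini–Yekutieli available); direction (SUP/SDP) is taken
from the same up-fraction counts that confer significance, with exact
fraction ties yielding no call. The default significance threshold is
FDR < 0.01; a looser 0.05 is conventional for smaller cohorts and both are
exposed (`--fdr`).

Null behaviour: Fisher p-values on 2×2 tables are discrete and
conservative, so their null distribution is stochastically larger than
uniform — tests check the one-sided property (empirical cdf never above
the uniform line) and the realized false-positive rate at FDR 0.05, not
two-sided uniformity.

## Similarity and clustering

SMIC compares two samples' significant-set score vectors by sign: CGS
positions (product > 0), DGS positions (product < 0), ties (either value
exactly 0 — a zero has no direction, which also prevents the zero start
seed used in gene-set mode from matching everything). The similarity is
L(θ) = N_cgs·θ + N_dgs·(1−θ) with θ ∈ [0.5, 1]. L is linear in θ, so its
maximum over the interval is at an endpoint: smic_mle =
max(N_cgs, (N_cgs+N_dgs)/2). A fixed-θ variant and three quantitative
baselines (negated Euclidean distance, Pearson, Spearman — Euclidean
negated so "higher = more similar" holds uniformly) are provided;
zero-variance vectors give correlation 0 with a warning.

The accumulating clustering seeds with the per-set mean control score
(sample mode) or the zero vector (gene-set mode), then repeatedly moves the
candidate with the highest mean similarity to all current seeds — start
seed included on equal footing — into the seed set, recording the winner's
score at selection time in the trace. Ties are broken by lexicographic id
and logged; with the zero start seed every first-step candidate ties at 0,
so the gene-set-mode first pick is lexicographic by construction. The
implementation keeps incremental similarity sums for O(n²) vector
comparisons; tests verify it against a literal from-scratch per-step
re-implementation.

By default the pipeline clusters on SUP scores only: down-calls are
empirically more false-positive-prone and diluting the vectors with them
weakens the severity signal; `--direction-filter both|SDP` overrides.

## Segmentation

The trace is fitted against rank with a lowess smoother
(statsmodels; `loess_span` default 0.5 maps to `frac`). Flex points are
sign changes of the fitted curve's second difference, subject to two
robustness rules that the flex-point idea itself does not fix:

- **Persistence** — each curvature run must last at least `min_class_size`
  points (default 3). Transient wiggles are not arcs.
- **Strength** — the slope change accumulated across a run must be at least
  `flex_strength` (default 0.5) times the trace's mean absolute slope.
  Lowess residual noise on an essentially straight trace produces long but
  very weak curvature runs; requiring the arc to bend by a meaningful
  fraction of the overall slope removes them while leaving genuine
  curvature reversals (which accumulate several times the mean slope)
  untouched.

Curvature below 1e-8 of the fitted range is treated as zero so an exactly
linear trace is degenerate-safe. The cut is placed before the first point
carrying the new curvature sign: on synthetic two-arc traces the smoothed
sign change sits about one rank before the true junction, and this rule
localizes the boundary within ±1 rank across trace lengths 12–40, whereas
a midpoint-of-transition rule drifted two ranks early at n = 20. Boundaries
violating `min_class_size` are dropped left to right; classes are
contiguous, numbered 1..k in rank order, and a trace with no flex point is
a single class.

## Synthetic cohorts

The generator emulates cohorts with functional signal that amplifies with
disease progression: per-gene baselines Normal(7, 1) truncated at 0 on the
log2 scale, cell noise Normal(0, 0.3), disjoint gene sets drawn from a
shuffled gene list, and planted up/down sets shifted by ±effect·severity
with severity j/n_cases (linear) in case j, floored at 0. Defaults — 2000
genes, 20+20 samples, 100 sets of 15 genes, 15 up + 15 down planted,
effect 1.5 — give roughly a third of sets carrying signal, comparable to
real pathway screens of moderate-size cancer cohorts. All randomness flows
from one integer seed through a single generator.

What the simulation does **not** emulate: overlapping gene sets (a flagless
design choice so FDR accounting is unambiguous), batch effects, probe
saturation, correlated noise between genes, and heavy-tailed expression.
Passing recovery tests therefore shows the machinery is correct under
clean, disjoint signal; it does not certify performance on confounded real
cohorts.

Trace fixtures for the segmentation tests are a noisy line (one class
expected) and two quadratic arcs of opposite curvature joined at rank
n // 2 with noise sd 0.05 (junction reported as ground truth).

## Numerical and design choices

- Fisher p by exact integer enumeration; degenerate margins → p = 1.
- FDR via statsmodels `multipletests`; adjusted values clipped to 1 and
  order-preserving with the input.
- Problem sizes in tests and the acceptance script (cohorts of 2000 genes,
  up to 200 sets, 10–20 replicate seeds) keep every recovery experiment
  well-powered while a full run completes in seconds.
- Result tables render floats to 6 significant digits, fixed column
  orders, deterministic row order (p then set name; rank); identical
  config + seed reproduces every output byte for byte.

## Known limitations

- The sign-based test loses power when case and control up-fractions
  differ but both sit near 0 or 1, and with very few samples it degrades
  toward a per-cohort differential test; it also needs a reasonable
  control fraction to anchor the "average" at a healthy baseline.
- Severity recovery assumes the planted/real gradient is monotone in the
  number of aberrantly signed sets; non-monotone progression (distinct
  subtypes) will interleave in the ordering.
- Loess flex points depend on span: very smooth fits (large span) can
  erase genuine inflections, as the Euclidean-similarity trace tends to —
  `igsa segment` allows re-segmentation without re-clustering.
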