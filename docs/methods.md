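# Methods

## Model and problem

A DNA motif of width *n* is modelled as a probability matrix *I(i, a)*,
i = 1..n, a ∈ {A, C, G, T}; a background model is a single nucleotide
distribution *q* (positions i.i.d.). Scanning scores each length-*n*
window of a sequence by the log-odds sum Σᵢ log(I(i, sᵢ)/q_{sᵢ}) and
reports windows at or above a threshold *k*. With the exact-match
construction (score 1 for one symbol per column, 0 otherwise, k = n) the
problem degenerates to plain substring search, which the tests use as an
oracle.

Assumptions inherited by the statistics: window symbols are independent
and identically distributed under the background, and the same background
is used for the log-odds transform, the threshold dynamic program, and the
failure expectations. Neither higher-order (Markov) backgrounds nor
per-position backgrounds are supported.

## Preprocessing

Count matrices receive background-proportional pseudocounts before the
log transform: position i gets `total_weight` (default **1.0**)
pseudo-observations distributed as *q*, i.e.
I(i,a) = (c(i,a) + w·q_a)/(Σ_a c(i,a) + w). The default of one
pseudo-observation per column is the common Laplace-style choice; it only
matters for rare symbols in shallow count matrices. Probability matrices
read from files that contain exact zeros (e.g. written with finite
precision) are repaired the same way with a small blend (1% background
mass) before the log transform; in-memory probability matrices are
strictly positive by construction.

Log base is natural log by default (`log2` available via a flag). The
choice only rescales scores and thresholds; p-values and hit sets are
invariant to it.

## Score discretization

Real scores are mapped to an integer grid, `int_score = round(score ×
10^d)` with round-half-away-from-zero, **d = 3** by default. One grid
serves both the threshold dynamic program and all scanning engines — this
is a correctness decision, not a convenience: if the engines compared
real-valued scores against a grid-derived threshold, ties and rounding
could silently break the "hit ⇔ tail probability ≤ p" guarantee. d = 3
keeps the discretization error (≤ n·0.0005 in real units) far below
typical score gaps while bounding the DP table at roughly
n × max|score| × 10³ cells; a dense-array cap of 10⁷ cells raises an
actionable error suggesting a smaller d. For width-22 log-odds matrices
the grid is typically a few 10⁵ cells.

## Threshold dynamic program

The PMF of the random window score is built column by column,
f⁽ⁱ⁾(x) = Σ_a q_a f⁽ⁱ⁻¹⁾(x − sᵢ(a)), starting from a point mass at 0.
The complementary CDF is accumulated from the top of the grid downward so
the smallest tail masses are summed first. The quantile convention is
conservative on the discrete grid: k(p) is the **smallest** grid score
whose tail is ≤ p, and the attained tail (`p_achieved`) is reported. If
even the maximum score has tail > p, the threshold is one grid step above
the maximum and the scan correctly returns nothing (this happens for
short motifs: a width-6 motif cannot reach p = 10⁻⁴ when its consensus
word alone has background probability ≈ 2×10⁻⁴). Tests verify the DP
against exhaustive enumeration of all 4ⁿ words for widths ≤ 8 (agreement
to 1e-9) and its invariance to column permutation.

## Engines and pruning

`suffix_max[t]` sums the per-column maxima of the still-unmatched columns
t+1..n **in the permuted order**, so `thresholds[t] = k − suffix_max[t]`
and `thresholds[n] = k`. The prune check runs after adding the t-th
column's score: a window with R_t < T_t is abandoned immediately. Summing
the suffix bound from t+1 (not t) is required for soundness — including
column t would double-count it against R_t and can wrongly prune when a
column maximum is negative; adversarial matrices with all-negative columns
are part of the unit suite.

The FLS column order sorts the failure expectations
E_i = |min_a M(i,a)| + max_a M(i,a) − Σ_a q_a M(i,a) in decreasing order,
ties broken by ascending position (deterministic). The |min| term is
taken literally as an absolute value even when a column's minimum is
positive. Forcing the identity order makes FLS bit-identical to LS,
which is asserted in tests.

Engines compare integer grid scores only. Windows containing any
non-ACGT symbol are skipped and counted (`skipped_windows`), never scored
or penalized. Hits are reported in ascending position order with 1-based
inclusive coordinates in TSV and 0-based half-open in BED; reverse-strand
scanning (opt-in) scores the reverse-complement matrix and reports the
forward-strand window start with strand "−". Sequences shorter than the
motif yield an empty result with a warning, not an error.

Implementation note: the engines are vectorized over the set of
still-active windows (one numpy gather/compare per depth), which makes
the lookup counts exact by construction: `column_lookups` equals the sum
of active-set sizes over depths, and `windows_pruned_at[t]` the number of
windows abandoned at depth t+1.

## Cost instrumentation instead of wall-clock

All engine comparisons in tests and benchmarks use column lookups and
prune depths — deterministic, hardware-independent proxies for work.
Wall-clock is printed by `flscan bench` for orientation but never
asserted: cache sizes and interpreter overheads make it an unstable
contract, and the vectorized engines' real timing is dominated by numpy
dispatch rather than per-lookup cost.

## Synthetic data

`random_sequence` draws i.i.d. bases from a given background (uniform by
default, matching the artificial-sequence design); a 1 Mb draw recovers
its background to < 0.01 max-norm error and passes a χ² goodness-of-fit
test at α = 0.001 (seeded tests). Benchmark sequences default to
100 kb in the test and acceptance harnesses — large enough that per-scan
noise in pruning statistics is small — rather than the multi-megabase
scale a production benchmark would use.

`random_matrix_with_ic` targets a total information content, defined as
relative entropy against the background in bits, IC = Σᵢ Σ_a I(i,a)
log₂(I(i,a)/q_a) (equal to Σᵢ (2 − H(column)) under uniform background;
the feasible range is 0..2n bits). Each column is drawn from a symmetric
Dirichlet(1), then the whole matrix is sharpened by one exponent β
(column probabilities ∝ p^β, computed in log space with a 10⁻¹² floor and
renormalized). Total IC is continuous and monotone in β — β = 0 gives
uniform columns, β → ∞ one-hot columns — so bisection (cap 100 steps,
doubling upper bracket) reaches any feasible target; the default
tolerance is **0.1 bits**. This generator is a deliberate, simple
stand-in for generating-function-based samplers: it produces matrices
*of* a given IC with a specific (smooth, equi-sharpened) conservation
profile, not a uniform draw from all matrices of that IC. Consequences
of that profile are discussed below.

The standard sweeps are: fixed width 22 with integer IC targets 5..30
bits, and widths 5..30 with IC = 70% of the per-width maximum. Sweeps are
deterministic per seed (independent child generators per cell).

The packaged GATA-3 example matrix (width 6, with its published
background) is shipped verbatim as log-odds scores; its underlying count
matrix is not public, so it is a fixture, not a regeneration target.

## What the synthetic tests do and do not show

Passing the exactness, threshold-oracle and nestedness suites on i.i.d.
background sequences establishes the algorithmic contracts — identical
hit sets across engines, calibrated thresholds — which are
distribution-free properties and carry over to real genomes unchanged.
The *cost* results do not automatically carry over: real genomes have
repeats, composition bias and actual binding sites, all of which change
pruning behaviour; and the IC-targeted generator fixes one conservation
profile, whereas real JASPAR motifs concentrate information unevenly
across columns.

One empirical finding is worth stating explicitly. Under the stated
benchmark conditions (width 22, p = 10⁻⁴, uniform 100 kb background),
mean lookups per window are flat to within ~1% across total IC 5..35
bits (LS ≈ 8.2–8.5, FLS ≈ 5.4–5.7 of 22) and rise steeply only as IC
approaches the 44-bit maximum (≈ 9.4 at 40 bits, ≈ 10.8 at 43). The
rise has a clean explanation: for a near-consensus motif, the p = 10⁻⁴
threshold admits words with a sizeable mismatch budget (≈ 8 mismatches at
width 22), and a random window must accumulate one more than that budget
before it can be pruned. In the low-and-middle IC range, by contrast,
threshold and score fluctuations scale together and the prune depth is
roughly scale-invariant. A monotone cost increase across low and middle
IC levels should therefore *not* be expected from this generator, and
the acceptance suite records that honestly; the robust, strongly
reproducible facts are the orderings FLS ≤ LS ≤ NA at every level and
FLS's ~30–35% lookup saving over LS.

## Numerical and degenerate cases

- PMF conservation holds to < 1e-9 for every generated matrix (tested).
- Column-permutation invariance of the PMF is exact up to float addition
  order; asserted at 1e-12 absolute.
- p = 1 maps to the minimum grid score (every clean window is a hit);
  the total mass is clamped at 1 to guard against summation overshoot.
- Background estimation excludes non-ACGT symbols from numerator and
  denominator and warns when a nucleotide never occurs (the resulting
  zero probability would be rejected by the log-odds transform).
- Ties in the failure-expectation order and equal scores at the
  threshold are handled deterministically (stable sort; ≥ comparison),
  so identical inputs give byte-identical outputs.

## Known limitations

- DNA only; the 4-letter alphabet is a constant.
- Zeroth-order background; no Markov models.
- Single-threaded; the vectorized engines are fast enough for tens of
  megabases, but no parallel contract is offered.
- No index structures (suffix arrays/trees) — deliberately an online
  algorithm.
- The IC-targeted generator samples one conservation profile per matrix;
  it is not a uniform sampler over matrices of fixed IC.
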