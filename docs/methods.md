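# Methods

## Model

At one genomic position, each sample's reads are modelled as
`k ~ Binomial(n, p)` non-converted reads out of depth `n`, with the
methylation level `p` the unknown. Under a uniform Beta(1,1) prior the
posterior is `Beta(k+1, n−k+1)`; zero-depth samples are processed, not
rejected — their posterior is simply the prior. The pseudo-counts are
exposed as an option (default `(1, 1)`); non-integer pseudo-counts are legal
and route the comparison through quadrature instead of the exact walk.

The reported quantity is `g = P(p1 > p2)` under the two independent
posteriors. This is a posterior probability, not a p-value: it answers the
scientific question directly and remains informative at any coverage. The
direction convention is fixed — the program prints the probability that
**sample 1** is more methylated; the swap identity `g' = 1 − g` recovers the
other direction.

## Exact engine

For integer shapes, `g(a1, b1, a2, b2)` is computed by a walk from
`(1, 1, 1, 1)`, where the distributions are identical and `g = 1/2`, to the
target, applying one increment recurrence per unit step:

| step            | update        |
|-----------------|---------------|
| `a1 → a1 + 1`   | `g += h / a1` |
| `b1 → b1 + 1`   | `g −= h / b1` |
| `a2 → a2 + 1`   | `g −= h / a2` |
| `b2 → b2 + 1`   | `g += h / b2` |

with `h = B(a1+a2, b1+b2) / (B(a1,b1) B(a2,b2))` evaluated at the
pre-increment state. The recurrences follow from
`g = E_Y[1 − I_Y(a1, b1)]` and the standard one-parameter shift identities of
the regularised incomplete beta function `I`. Numerical choices:

* every `h` is computed as `exp` of a log-gamma combination — Beta-function
  ratios would overflow double precision near coverage ~1000 otherwise;
* the default walk order raises `a1` fully, then `b1`, `a2`, `b2`, fixing the
  output bits; an interleaved order is provided and a property test checks
  path independence to 1e−10;
* the result is clamped to `[0, 1]` (accumulated rounding can overshoot by
  ~1e−15 near the boundaries);
* walks beyond total parameter order 100 000 are refused — the cost is
  linear and such depths are far beyond realistic WGBS data;
* non-integer shapes are refused with a pointer to the quadrature routine:
  the unit-step recurrences cannot reach the integer base case from them.

Two independent oracles guard the engine: adaptive quadrature of
`∫₀¹ f_X(x) F_Y(x) dx` (scipy's adaptive Gauss–Kronrod, subdivision anchored
at the two posterior means, default tolerance 1e−10, raising `AccuracyError`
if the integrator's error estimate exceeds it) and Monte-Carlo sampling with
a binomial standard error. The tests require agreement to 1e−8 with
quadrature and 4 standard errors with Monte Carlo over randomized parameter
sweeps; observed quadrature deviations are ~1e−14.

## Comparator tests

Both comparators are one-tailed with the alternative "sample 1 more
methylated", matching the `g` convention so all three methods rank sites on
one axis.

* **Fisher**: hypergeometric upper tail `P(NC1 ≥ observed | fixed margins)`
  of the 2×2 table (rows = samples, columns = non-converted/converted),
  computed in log space via `scipy.stats.hypergeom`. No mid-p correction.
  Degenerate tables (a zero row or column sum) are flagged and given
  `p = 1.0` rather than raising, so streaming and simulation callers can
  process every site.
* **Z test**: each posterior Beta is moment-matched by a Gaussian
  (`mean = a/(a+b)`, `var = ab/((a+b)²(a+b+1))` — posterior moments, i.e.
  counts + 1, not raw proportions) and
  `p = 1 − Φ((m1 − m2)/√(v1 + v2))`. Beta posterior variances are strictly
  positive, so the statistic is always finite.

## Simulation benchmark

Negative controls draw both samples' non-converted counts from the same
binomial process; positives use markedly different underlying probabilities.
Defaults — null `p = 0.5`, alternatives `0.7` vs `0.3`, equal coverage per
sample over the grid {5, 10, 20, 50}, 2000 sites per class — are the
package's chosen study conditions; every one is overridable through
`SimulationConfig`. A single master seed deterministically derives the
per-class streams, so a config reproduces bit-identically.

Scores are folded to two-sided "evidence of any difference" so one threshold
grid serves all ROC curves: `2|g − ½|` for the exact method and
`1 − 2·min(p, 1−p)` for the one-tailed tests. Folding is monotone within
each method's own ranking. Degenerate Fisher tables score 0 (no evidence):
the test carries no information there, and treating its flagged `p = 1` as
an ordinary p-value would invert into maximal evidence. The threshold grid
is 512 even points on [0, 1] plus every attained score, making ROC steps
exact.

What the generator emulates: independent per-site binomial sampling at fixed
depth and fixed class probabilities. What it does not: spatial correlation
of methylation, depth variation across positions, bisulfite conversion
errors, or biological replicate variability. Passing benchmarks therefore
demonstrate the statistical ordering of the three methods under sampling
noise — the mechanism of interest — not performance on any particular real
dataset.

A 2-D histogram routine (`compare_histogram2d`) bins the exact probability
`g` against a comparator's one-tailed p-value over simulated sites.
Orientation: x = `g`, y = p-value; broad agreement concentrates mass near
the anti-diagonal `y ≈ 1 − x`.

## Probability tracks

Per-position `g` values form a track; all downstream outputs are tracks or
means — no hard DMR boundaries, minimum lengths, or gap rules are imposed
anywhere.

* **Kernel smoothing**: Nadaraya–Watson with a Gaussian kernel over genomic
  distance, evaluated at the covered positions only (no imputation), weights
  truncated beyond 4 bandwidths. The bandwidth is the user's model choice —
  methylation is spatially correlated but the correlation scale varies by
  sample. Output values are convex combinations of inputs, so [0, 1] is
  preserved. With the 4-bandwidth truncation the smoother is exactly the
  identity once the bandwidth falls below a quarter of the minimum
  inter-position gap.
* **Window averaging**: non-overlapping blocks of a fixed number of
  consecutive covered positions collapse to their mean at the block's first
  position; a trailing partial block averages over its own size, so the
  value total `Σ mean·size` is conserved exactly.
* **Region means**: arithmetic mean of track values inside half-open
  intervals; empty regions report NaN as an explicit no-data marker.
  Sampling of background regions for enrichment comparisons is left to the
  caller.
* **Certainty filter**: positions are filtered on `max(var1, var2)`, the
  worse sample's posterior variance, not on read depth — at equal depth an
  extreme count split (e.g. 10/0) has a tighter posterior than a balanced
  one (5/5), and a position is only as certain as its worse sample.

Coordinates: track positions are 1-based (as in position-file input);
intervals are half-open in that same space; bedGraph output and BED3 input
convert to/from those formats' 0-based half-open convention.

## Interfaces

The stream protocol reads whitespace-separated lines of four integers
(`nc1 c1 nc2 c2`) and prints one probability per line, fixed at 6
significant digits by default (the format is otherwise arbitrary; fixing one
makes output deterministic). Files with counts embedded among other columns
are served by `--columns`. Parse errors name the offending line and are
reported on stderr; the exit status is nonzero unless skip-and-warn is
requested. Processing is single-pass and constant-memory.

The synthetic fixture generator writes position files shaped like a real
two-sample methylation table: fixed spacing, half null sites and half
differential sites interleaved, counts from the same binomial generator as
the benchmark, byte-identical for a fixed seed.

## Problem sizes and limitations

The shipped tests and the acceptance script use 200-quadruple oracle sweeps
(shapes ≤ 25), 500-quadruple symmetry sweeps (shapes ≤ 100), 10⁴-site null
calibration at depth 20, and 2000-site-per-class benchmarks at depths 5 and
50 — sizes chosen to make sampling error negligible relative to the effects
measured. Known limitations: the exact engine is integer-only by design;
the quadrature oracle can lose accuracy for very large non-integer shapes
(it raises rather than returning a degraded value); the benchmark's
independence assumptions understate the difficulty of correlated real data;
and no multiple-testing machinery is included — the output is a posterior
probability per position, to be aggregated or thresholded by the caller.
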