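# Methods

## The model

`habsuit` builds habitat suitability models (HSMs) from presence-only
occurrence records and environmental raster layers.  Each environmental
variable `z` gets its own response curve `s(z) ∈ [0, 1]`: a single cubic
Bezier through four control points `(x_i, y_i)` with non-decreasing `x`.
The first control point is constrained to the left or bottom edge of the
graph and the last to the bottom or right edge, so the end points carry one
degree of freedom each and the interior points two — six estimated
parameters per variable (`k = 6`).  Because `x(t)` is monotone for an
x-ordered control polygon, the curve is a function of `z`; values left of
the first or right of the last control point are unsuitable (`s = 0`).
The multi-variable suitability map is the pixelwise product of the
per-variable curves (a geometric-mean combiner is available; it is a
monotone transform and leaves rank-based statistics unchanged).

## Histograms and the binned likelihood

Each variable is summarized by 256-bin histograms over its value range:
`f(z)` over all data pixels, `f1(z)` over the occurrence pixels, and the
availability-corrected ratio `f1/f` (zero where `f` is zero).  Curves are
fit by maximizing

    lnL = Σ_j w_j ln p(h_j),    p(h_j) = v_j / Σ_k v_k,

where `h_j` are bin centers, `v_j` the curve lookup at `h_j`, and the
"area under the model" normalization is the discrete sum over the 256
bins.  Probabilities are floored at 1e-12 before the log, so curves that
zero out occupied bins are heavily penalized but never produce `-inf`
during the search.  The weights `w_j` are either the occurrence counts
`C_j` (`target="f1"`) or, by default, the ratio histogram used as
pseudo-counts.  The ratio pseudo-counts are scaled to sum to the usable
occurrence count, which keeps log-likelihood and AIC magnitudes on the
familiar per-occurrence scale while retaining the availability correction;
a max-1 scaling would change every likelihood magnitude by a large constant
factor without changing the fitted shapes.  Because the sum runs over bins,
fitting cost is independent of the number of occurrences; on the synthetic
gradient system the AIC computed this way differs from a direct
per-occurrence evaluation by well under 0.1% (the package tests assert
< 0.5%).

AIC is reported as `2k − lnL` by default (`convention="paper"`, matching
the printed outputs of earlier habitat-modeling software this engine is
output-compatible with); the textbook `2k − 2 lnL` is available
(`convention="standard"`).  Since every per-variable model has
`k = 6`, model ranking is identical under both.  Multi-variable models
report the sum of per-variable log-likelihoods with `k = 6 ·` (number of
variables); the composition rule for multi-variable AIC is our convention,
stated here because the quantity is otherwise undefined.

## The grid search

Fitting enumerates candidate control-point positions on a grid — by default
10 columns over `[vmin, vmax]` and 10 rows over `[0, 1]`, with the two end
points restricted to their feasible edges — scores every x-ordered
combination, and recursively re-grids a ±1-cell neighborhood (scaled by
`shrink`) around the winner for `levels` rounds.  Degenerate combinations
whose first and last control points share one x (zero-width support) are
excluded.  For a fixed tuple of control-point x positions the lookup values
are linear in the control-point y values, so the implementation computes
one basis matrix per x-tuple (inverting the monotone `x(t)` by sampled
interpolation plus Newton polishing; basis matrices are cached across
calls) and scores all y-combinations with dense linear algebra in single
precision.  The selected candidate is always re-scored with the exact
double-precision bisection path, and the exact value is what `FitResult`
reports.

### Amplitude identification and the ridge rule

The normalized likelihood is invariant to a uniform scaling of the control
y values, and — less obviously — control polygons with quite different
absolute peaks can realize nearly identical *normalized* shapes.  Curve
amplitude is therefore not identified by the likelihood alone.  The search
resolves this ridge with a profile-likelihood-style rule: among candidates
whose score is within `ridge_tolerance` nats of the optimum (default 10,
about 0.1% of a typical |lnL| on the synthetic systems), the candidate
whose canonical curve peak (curve maximum after scaling the control y's to
a maximum of 1) is largest wins; remaining ties fall to the first candidate
in enumeration order, which runs x ascending and y descending and therefore
also prefers large amplitudes.  Fitted curves are reported in canonical
form (peak control weight 1, matching the max-1 rescaling of the displayed
histograms).  The default tolerance was chosen by truth-recovery
simulation: on the synthetic gradient system it recovers the truth habitat
map to a maximum absolute error of 0.09-0.13 across seeds, while a plain
argmax leaves the amplitude to floating-point accident and produces errors
of 0.3-0.4.  Setting `ridge_tolerance=0` restores the plain argmax.

## ROC and AUC

Performance is presence-versus-background: presence scores are the map
values at the occurrence pixels, background scores are all data pixels of
the study area (occurrence pixels included — the design has no true
absences).  The AUC is the exact rank statistic `(wins + 0.5 ties) /
(n_presence · n_background)`; the ROC polyline written to output sweeps the
257 bin edges of `[0, 1]` for plotting.  The rank statistic equals the
trapezoid area of the complete threshold sweep, which the tests verify
against both a direct sweep and scikit-learn.

## Monte Carlo uncertainty analysis

Each iteration: (1) Gaussian noise is added to occurrence coordinates;
(2) Gaussian noise — scalar or per-pixel raster parameters — is added to
each environmental raster (a fresh draw every iteration), clamped to the
raster's original range; (3) occurrences are split into training and test
sets (`|train| = round(n · fraction)`, default 0.7); (4) histograms are
rebuilt from the noised data over the variable's *original* range (so
curves stay comparable across iterations) and the model is refit on the
training set; (5) for sensitivity testing, Gaussian noise is added to the
fitted control-point coordinates, after which the curve is repaired: y
clamped to [0, 1], x to the variable range, points re-sorted by x, end
points projected to the nearest feasible edge (distances compared on the
unit square); (6) the suitability map is predicted; (7) lnL and AIC are
computed from the training weights of the (possibly perturbed) model, and
AUC from the test occurrences.  Occurrences pushed off the raster by noise
are dropped from histogram building and scoring for that iteration and the
dropped count is logged per iteration.

Aggregation: pixelwise mean, min, max, and population standard deviation
maps (streaming Welford accumulation); per-variable response-curve
envelopes at the 256 bin centers (mean, min, max, and a nonparametric
2.5-97.5 percentile interval across iterations); running cumulative means
and population sds of AIC and AUC for convergence assessment; histograms of
lnL, AIC, and AUC.  Every iteration draws from a generator seeded by
`(master seed, iteration index)`, so a run is a pure function of its inputs
and configuration, independent of execution order.

## Synthetic study systems

The *gradient system* emulates a study area with two independent,
perfectly measured environmental axes: "BottomToTop" and "LeftToRight"
vary linearly from 0 to 100 along y and x respectively (defaults: 1,000 ×
1,000 pixels, 1 map unit per pixel, so coordinate noise of "1% of the
extent" is 10 units).  Truth response curves — wide `(0,0),(25,1),(75,1),
(100,0)` and narrow `(30,0),(45,1),(55,1),(70,0)`, both peaking near 50 —
multiply into a truth habitat map, and occurrences are rejection-sampled:
20,000 uniform candidates by default, each kept with probability equal to
its pixel's suitability (roughly 2,000 survivors per 500-pixel system).
The truth-curve coordinates and candidate count are this package's
defaults, not published values; both are arguments of
`make_gradient_system`.  The *canyon system* is a sinuous vertical band of
optimal habitat (value 255 on a 0 background, default 512 × 512 pixels and
6% band width) with 1,000 occurrences uniform inside the band, plus
degraded variants: nearest-neighbor factor-8 downsampling (block-center
sample, ties toward the top-left), three successive factor-2 block
averagings ("bilinear", net factor 8), and a per-8×8-block population-sd
raster usable as a spatially varying noise field.

What the generators do *not* emulate: spatial autocorrelation of real
environmental layers, observation bias (roads, effort), species
interactions, and coordinate error structure beyond isotropic Gaussians.
Passing tests on these systems demonstrate that the engine recovers known
response curves and propagates injected noise correctly — not that any
real-world model is well specified.

## Numerical choices and degenerate inputs

- Curve evaluation inverts `x(t)` by bisection (40 fixed iterations; x
  accuracy far below 1e-9 of the range); results are clamped to [0, 1].
- Prediction maps raster values to lookup bins by the same floor rule used
  in histogram binning; values outside the curve range (possible after
  noise) clamp to the end bins.
- A constant raster yields a degenerate single-bin histogram and cannot be
  fit (degenerate-range error).  All-nodata rasters, empty occurrence
  sets, and curves that zero every bin raise or are flagged rather than
  silently producing numbers.
- Population (not sample) standard deviations are used for maps, running
  statistics, and iteration summaries.
- Train/test splitting uses banker's rounding for `|train|` and clamps so
  neither side is empty.

## Scaling of the bundled experiments

The package's acceptance tests and `scripts/acceptance.py` run the full
pipeline at reduced problem sizes chosen for quick turnaround: 250- or
500-pixel study areas and a 6 × 6 search grid with two refinement levels
(the default remains 10 × 10 with three levels).  The AUC-type statistics
they summarize change by well under 0.005 between these settings and the
defaults, and map-recovery checks use the default grid.

## Known limitations

- All rasters are held in memory; no tiled or out-of-core access.
- Continuous variables only; categorical responses are out of scope.
- The amplitude of a fitted curve is a convention (see the ridge rule), not
  an estimated quantity; only suitability *ratios* are data-identified.
- Presence-background AUC depends on the background definition and on how
  much of the study area has zero suitability; its absolute level is not
  comparable across background choices.
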