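# Methods

`canopyhsm` implements a habitat-suitability workflow for canopy-nesting
seabirds (marbled murrelet being the motivating species) whose nesting
habitat is old forest with very tall trees: from a canopy height surface
to individual-tree metrics, a balanced used/available sample, a
presence-background maximum-entropy model, predicted-to-expected (P/E)
habitat classes, and management-ready habitat patch polygons.  This note
records the models, the defaults and their units, the numerical choices,
and what the synthetic tests do and do not demonstrate.

## Synthetic landscapes

Real inputs — airborne LiDAR canopy models over managed timberland and
occupancy-survey polygons — are rarely shareable, so the package carries a
generator that reproduces their statistical structure:

* **Matrix (second/third growth).** Canopy-forming stems placed by a
  homogeneous Poisson process, default 150 stems/ha, heights from a
  truncated normal (mean 28 m, SD 9 m, support 2–50 m).  Real second
  growth is denser at ground level; 150/ha approximates the stems that
  actually reach the canopy surface and is all that matters for a
  surface-based analysis.
* **Old-growth patches.** Each patch polygon adds an independent Poisson
  population of tall trees, default 25 trees/ha with heights 60–110 m
  (truncated normal, mean 80 m, SD 12 m) — the density and height range
  over which habitat selection for this guild saturates.  Patch polygons
  double as the "used" (occupied) polygons, giving every downstream stage
  ground truth.
* **Crowns.** Each tree renders as a paraboloid: apex at tree height *h*,
  falling to zero at radius `crown_radius_coeff * h` (default coefficient
  0.1).  The cell value is the maximum over contributing crowns.  This is
  the simplest crown shape with exactly one strict maximum per tree, which
  is the property the local-maxima detector needs.  Default surface
  resolution is 1 m (0.25 m in tests that check sub-meter height
  recovery); resolution is a parameter everywhere.

What the generator does **not** emulate: terrain (ground is flat zero),
LiDAR noise and pulse-density artifacts, crown asymmetry and overlap
deformation, clustered stump-sprout "leaders", and spatial inhibition
between stems.  Tests passing on these landscapes show the pipeline's
logic and numerics are right, not that detection or model accuracy
transfers to any particular sensor or forest.

## Tree detection (TAOs)

A cell is a tree-approximate object iff its value is positive, at least
`min_height`, and no smaller than every cell whose center lies within
`window_radius` (default 2 m) of its own — a circular-window local-maxima
filter.  Plateaus of equal value collapse to one TAO at the cell nearest
the plateau centroid (row-major on ties); windows are clipped at the
raster edge, and the sampling design's 20-m boundary exclusion handles the
resulting edge bias downstream.  The 2-m default follows from redwood
stump sprouts producing leaders within a meter or two of each other: a
larger window merges distinct trees, a smaller one fragments crowns.

## Moving-window covariates

Statistics of TAOs within circular windows centered on each 5-m analysis
cell: count density, sum / mean / min / max of heights, and sample
(n−1) SD, filtered to TAOs at or above a height threshold.  Windows are
specified in acres because management practice there uses 1- and 5-acre
plots; the radii are 35.89 m and 80.25 m (`circle_radius_for_area`,
1 acre = 4046.8564224 m²).  Conventions the literature leaves open, fixed
here: the distance rule is inclusive (≤ radius), density is reported per
acre regardless of window size, SD of fewer than two trees is 0,
min/mean/max of an empty window are 0, and the cell value is evaluated at
the cell center.  The production implementation uses a KD-tree; a direct
O(cells × TAOs) scan ships alongside as the test oracle.

The final model's trio: density of TAOs ≥ 60 m (5-acre window), sum of
heights of TAOs ≥ 50 m, and SD of heights of TAOs ≥ 50 m
(`density_ge60_5ac`, `sumht_ge50_5ac`, `sdht_ge50_5ac`).

## Balanced acceptance sampling

Points come from the random-start 2-D Halton sequence (bases 2 and 3),
scaled to the region's bounding box and accepted inside the region until
*n* points are kept.  The random start is a pair of integer index offsets
drawn uniformly from [0, 10⁷) — the simplest published variant — and is
logged in the design metadata.  The design default is one point per
2.02 ha (a 5-acre spacing); both entry points (fixed *n*, or
hectares-per-point) are supported.  A point is "used" iff it falls inside
an occupied polygon at least 20 m from its boundary (inclusive at exactly
20 m); every point, used or not, stays in the available pool — the
two-sample design in which the background contains the presences.  The
20-m exclusion removes moving-window edge bias: it is deliberately smaller
than the smallest (1-acre, 35.89-m) window radius.

## Maximum-entropy model

With feature expansion f(x) and coefficients β, fitting maximizes the
penalized presence-background log-likelihood per presence

    (1/n_u) Σ_used β'f(x) − log Σ_avail exp(β'f(x)) − Σ_j λ_j |β_j|.

* **Features.** Linear, quadratic, product and hinge classes.  Covariates
  are clamped to the background range and standardized by background
  mean/SD; hinge features use 50 knots per direction (configurable) at
  equally spaced quantiles of the background, scaled to [0, 1].  Clamping
  makes points outside the background support behave like the boundary and
  keeps the objective bounded.
* **Penalties.** λ_j = RM × class base constant × sd_used(f_j) / √n_u,
  with the published default base tables (linear/quadratic/product
  interpolated over presence-sample sizes 0/10/30/100 → 1/1/0.2/0.05;
  hinge constant 0.5).  The used-sample SD is floored at 0.05 so features
  inactive on the presences keep a small positive penalty.  RM (the
  regularization multiplier) defaults to 2.0.
* **Solver.** Cyclic coordinate descent; each coordinate takes a
  soft-thresholded Newton step followed by a halving line search that
  keeps the best point along the sequence (the coordinate restriction is
  concave, so this brackets the 1-D maximizer).  The objective path is
  monotone by construction and checked in tests.  Convergence: relative
  objective change per full cycle below 10⁻⁵; cap 5000 cycles, with
  failure to converge raising an error carrying diagnostics.
* **Outputs.** Raw output e^{β'f(x) − log Z} sums to 1 over the fitting
  background.  The habitat suitability index (HSI) is the scaled logistic
  output r·e^H τ/(1−τ) / (1 + r·e^H τ/(1−τ)) with H the entropy of the
  background raw distribution and τ = 0.5 (so the null model scores 0.5
  everywhere).  Gain is the mean used log raw output plus log n_avail
  minus the penalty — 0 for the null model; a gain of 2.5 nats is an
  exp(2.5) ≈ 12.2-fold likelihood improvement.  AIC uses k = count of
  nonzero coefficients (the convention consistent with replicate-average
  parameter counts being fractional).
* **Bootstrap replicates.** Each replicate trains on a with-replacement
  draw of 80% of the used points; the held-out set is the points never
  drawn.  Test gain is unpenalized; test AUC compares held-out presences
  against the full background.

## Model-selection protocol

Four phases mirror common practice for large covariate libraries:
correlation screening (pairs with Pearson R² or Cramér's V above 0.65 may
not share a model; mixed continuous/categorical pairs use Cramér's V on
decile-binned values), per-covariate strength (percent contribution from
the solver's per-update objective credit, permutation importance as the
normalized training-AUC drop over 10 seeded permutations, and jackknife
only/without gains with advancement at influence ≥ 20 and only-gain
≥ 2.5), exhaustive enumeration of candidate models taking one covariate
per correlated group, and bootstrap AIC ranking.

AIC over bootstrap resamples is evaluated on the **original** used sample
(models fitted to the resamples): evaluating each fit on its own training
resample would reward within-resample overfitting and make candidate
likelihoods incomparable.  All candidates see the same resamples (common
random numbers).  The regularization sweep refits over RM = 1.0–5.0 in
steps of 0.5, reports replicate-mean k, log-likelihood and AIC (the mean
AIC equals 2·mean k − 2·mean lnL identically), and selects the RM with the
lowest median AIC.

## P/E classification

The continuous P/E curve bins the HSI axis with overlapping bins of width
0.02 at centers from 0.02 upward in steps of 0.002; per bin, P is the
share of used predictions and E the share of available predictions, and
bins with no available mass are flagged undefined and excluded.  The curve
is smoothed by a fixed-span local-linear running smoother (span 0.2 of the
defined bins); a cross-validated supersmoother would also do — breakpoints
move very little between raw and smoothed curves, so the smoother choice
is low-stakes and the span is configurable.

The first class boundary is forced at the largest bin center with smoothed
P/E below 1 (less use than expected by chance = unsuitable).  Above it, a
continuous piecewise-linear curve (hinge basis, OLS) is fitted by
exhaustive direct search over combinations of candidate breakpoints; ties
go to the lexicographically smallest set.  Candidates are the bin centers,
thinned evenly to at most `max_candidates` (default 40) when the grid is
large, which keeps C(m, k) search exact on the thinned grid and tractable
at the default k = 5.  Post-hoc merging of adjacent classes is an explicit
caller-supplied list of breakpoints to drop — a judgment step that is
logged, never automated.  Class intervals are left-closed (a boundary
value belongs to the upper class) with the top class closed above.

## Patch delineation

Cells of "low" or better habitat are polygonized with 4-connectivity and
buffered outward by 80.25 m — the 5-acre window radius, because TAOs that
far away contributed to the predictions inside the patch.  Overlapping
buffers dissolve; each dissolved region collects its TAOs ≥ 50 m and one
concave hull is computed per region (regions with fewer than 3 tall TAOs
cannot support a hull and are dropped with a warning).

The concave hull is an edge-digging algorithm in the concaveman family:
starting from the convex hull, an edge may be replaced by two edges
through the interior point nearest to it when (a) that distance is within
edge-length / concavity, (b) the new edges do not cross the current
boundary, and (c) no other point lies in the triangle being carved —
condition (c) guarantees every input point stays inside, and concavity
→ ∞ recovers the convex hull (checked against the standard convex-hull
oracle).  Default concavity 0.8, length threshold 0.

Perimeters are smoothed by a 60-m outward then 55-m inward buffer — a
morphological closing at 55 m plus a 5-m dilation.  The result always
contains its input, and bays narrower than ~110 m are filled.  Buffer arcs
are discretized at 16 segments per quadrant, so "equals the 5-m dilation"
for convex inputs holds to about one part in 10⁴ of the area.

A known edge case: an isolated planted tall tree at a patch corner can lie
more than 80.25 m from every low-or-better cell and is then excluded from
all patches.  This is the method behaving as designed (such a tree does
not raise local density enough to classify its surroundings as habitat),
and at default settings it affects well under 1% of planted tall stems.

## Evaluation

AUC is the Mann–Whitney probability that a random used score exceeds a
random non-used score, ties counting half.  Confusion-matrix metrics use
score ≥ threshold as "habitat" (inclusive, so a class lower bound counts
as habitat) and take negatives to be available points *not* labeled used —
the contingency-table convention — even though the model's background
includes the used points; both counts are exposed.  Kappa is computed in
exact integer arithmetic before the final division.  Marginal response
curves sweep one covariate over its background range with the others held
at background means, with a mean ± SD band over bootstrap replicates.

Because the background contains the used sample, the attainable AUC is
bounded below 1 by half the used share of the background; synthetic
scenarios that check "AUC near 1" keep that share small, as the real
design does.

## Problem sizes and defaults of the shipped pipeline

The demonstration pipeline runs a 2500 m × 2500 m landscape (625 ha) with
four old-growth patches of 300–450 m, a 1-m canopy surface, a 5-m analysis
grid, sampling at one point per 2.02 ha (~310 points, of which ~20–30 land
deep inside patches), hinge features at 10 knots per direction, 10
bootstrap replicates, and k = 3 interior breakpoints.  These sizes keep a
full run near ten seconds on one core while leaving every stage
statistically non-degenerate; all are `RunConfig` parameters.  At this
scale the used sample is small, so per-run sensitivity estimates move in
steps of ~4 percentage points, and the P/E curve is much noisier than a
study-scale curve — the classification machinery is exercised, not
precision-validated.

All randomness flows from one root seed through `numpy` `SeedSequence`
spawning; two runs with the same config are artifact-hash identical.

## Known limitations

* The solver is a dense cyclic coordinate descent; very large feature
  expansions (hundreds of thousands of background points × thousands of
  features) would want an active-set strategy.
* Cramér's V on decile-binned values is a coarse screen for
  continuous–categorical association; the original practice also
  inspected box plots, a judgment step not automated here.
* Patch polygons are planar (no holes are ever produced by the hull +
  closing construction at defaults, but inward smoothing of extreme
  shapes could in principle split a polygon; pieces are kept as separate
  patches).
* The generator's flat terrain means canopy height equals surface height;
  with real DSMs the caller must supply height-above-ground surfaces.
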