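# Methods

This note records the models, conventions, and numerical choices behind
`voxelnav`, and what the synthetic experiments do and do not establish.

## Terrain model and movement costs

The world is a height field: one integer elevation per (x, y) cell,
with an obstruction mask for impassable tiles (water, trees, fences,
cacti). Blocks are nodes of a directed graph; a step to one of the
eight horizontal neighbors is walkable iff neither cell is obstructed
and the elevation change lies in [−max_fall, +max_climb]
(defaults 3 and 2). Game descriptions of the climbing limit vary
between two and three blocks depending on context; the stricter
two-block limit is encoded as the default and the parameter is
configurable.

The edge weight is the 2D Euclidean step length plus an additive
vertical surcharge, `α_up·max(Δz,0) + α_down·max(−Δz,0)`. The exact
functional form and coefficients of the vertical term are a modelling
choice; this form was chosen because it (i) reduces to the 2D distance
on flat ground, (ii) grows with |Δz|, and (iii) makes ascent strictly
costlier than descent for any α_up > α_down > 0. Defaults are
α_up = 2.0, α_down = 1.0; every downstream quantity is conditional on
the configured `MovementRules`. Because the weights are asymmetric the
graph is directed, and the cost-to-go field toward a target is computed
by a single-source sweep on the edge-reversed graph (the transpose of
the sparse adjacency matrix, via `scipy.sparse.csgraph`). Single-pair
queries use an independent binary-heap Dijkstra with lexicographic
(x, y) tie-breaking, so the two routes cross-check each other in the
tests. Diagonal steps across obstructed corners are permitted when the
walkability predicate passes; no corner-cutting rule is imposed.

## Cost-difference curves

For a segment ending at an object, with per-second samples
P(t₀)…P(t_N):

* actual cost-to-go `A(t_j) = Σ_{k≥j} c(P(t_k), P(t_{k+1}))`, where a
  step between identical snapped blocks costs 0, a walkable edge costs
  its weight, and any other transition is charged the Dijkstra
  distance between the two blocks (this generalization keeps the
  triangle-inequality structure intact when a player covers more than
  one cell in a second);
* optimal cost-to-go `O(t_j) = d(P(t_j), P(t_N))`;
* cost difference `D = A − O`.

The cost-to-go reading is adopted deliberately: it guarantees A ≥ O at
every sample (no path beats the shortest path), forces D to decrease
to exactly zero at the segment end (by the triangle inequality each
real step pays at least what it can save), and reproduces the
qualitative cluster shapes observed in real cohorts — curves that drop
sharply before the middle for quickly-adapting navigators and curves
that stay high late for prolonged wanderers. Cumulative-from-start
formulations are non-decreasing by construction and cannot produce
those shapes.

Positions snap to blocks by flooring (cell boundaries belong to their
own cell); a block's z comes from the height field, not the recorded
z-coordinate. Segmentation uses half-open intervals (t_prev, t_next]:
the sample at an event time closes one segment and opens the next, and
trajectory recorded after the last found object is discarded because a
curve needs a destination. O(t) is evaluated at every sample. Segments
containing a step with no connecting path are excluded and counted,
never silently dropped.

Curves are normalized by linear rescaling of time to [0, T] and linear
interpolation onto a fixed grid; T = 100 with 101 grid points by
default (both configurable). Linear interpolation preserves endpoints
and monotone decrease, and the operation is idempotent on the unified
grid. Interpolation constants this coarse lose nothing that the
downstream 10–12-function spline representation could have seen.

## Functional clustering

Curves are represented by ordinary least-squares coefficients on a
cubic (order-4) B-spline basis with equally spaced knots, clamped at
the interval ends; 12 basis functions by default (cluster results are
insensitive to this in the sensitivity range 8–16, and the count is a
parameter). Coefficients are used raw, not standardized — they share
the curve's cost units, and standardizing would reweight the time axis.
K-means (scikit-learn) runs with 10 random restarts per seed, keeping
the best-inertia solution; clusters are relabelled largest-first so
"cluster 1" is always the dominant pattern. Curves from all sessions
and environments are pooled before clustering. K is chosen by the mean
silhouette score over a configurable range (2–8 by default, the full
score table is emitted); stability is the mean ± sd adjusted Rand
index between the reference partition and re-runs under seeds drawn
from the base seed.

## Segment triage, outcomes, and the regression

Segments are split at an optimal-cost cutoff of 70 (configurable);
the boundary value itself is high-cost, following the strict
"below 70" reading. High-cost segments are counted per participant
(removed curve count); the per-participant functional predictor is the
pointwise mean of the low-cost normalized curves. Cluster proportions
(shares of clusters 2–4) and average segment time are computed over
all of a participant's segments. A participant with no low-cost
segment is excluded from the functional regression and logged.

Placement-test outcomes: Y1 counts placements whose distance to the
true location is at most 10 blocks, with the Dijkstra distance as the
default metric (consistent with Y3, which is explicitly a Dijkstra
distance; Euclidean is available by option). Y2 averages the
entry-to-placement interval over correct trials; Y3 averages the
placement distances. Y2 and Y3 are undefined (NaN, excluded) when
Y1 = 0.

The regression minimizes

    Σᵢ (yᵢ − zᵢ'γ − ∫ Xᵢ(t) β(t) dt)² + λ ∫ β″(t)² dt

with β on a 10-function cubic B-spline basis and λ = 0.1 by default.
∫X(t)β(t)dt is evaluated by the trapezoid rule on the unified grid
(exact for the piecewise-linear curves up to basis-function
curvature); the curvature Gram matrix ∫B″ᵢB″ⱼ uses a fine-grid
trapezoid (2001 points; B″ of a cubic spline is piecewise linear, so
the error is negligible). The penalized solution is closed-form.
Standard errors use the effective-degrees-of-freedom sandwich
`σ̂²(M'M+Λ)⁻¹M'M(M'M+Λ)⁻¹` with σ̂² = RSS/(n − edf),
edf = tr[(M'M+Λ)⁻¹M'M], and t reference with n − edf degrees of
freedom; these are approximate under penalization and are flagged as
such. Categorical covariates are reference-coded (default baseline:
lexicographically first level; configurable). Covariate columns with
no variation in the analyzed sample are dropped with a logged warning
rather than producing a singular solve. Each outcome is fit
separately; on the synthetic cohorts the outcomes are generated with
independent noise and largely disjoint drivers, and their empirical
correlations are small, which is the situation in which separate
regressions are appropriate.

Bootstrap bands are pointwise 2.5/97.5 percentiles of β̂(t) over
case-resampled replicates (participants redrawn with replacement);
singular replicates are redrawn and counted. The bands are percentile
bands for the sampling distribution, not simultaneous bands.

## The synthetic cohort generator

The generator emulates the study design it stands in for: 12
hidden objects, 1 Hz sampling, two training sessions capped at 600 s,
four environments, placement trials capped at 180 s. Free quantities
are package choices, fixed once:

* **Terrain**: 64×64 cells, Gaussian-smoothed noise elevation with
  ~2.5 blocks standard deviation, 10% obstructed cells; regenerated
  under fresh sub-seeds until the mutually reachable core covers half
  the map and hosts all object cells with spacing. This scale makes
  the optimal-cost distribution straddle the cutoff of 70 the way the
  motivating histogram does: roughly 5% of segments are high-cost and
  about a third of participants have none, so the removed-curve count
  varies across participants instead of degenerating to zero.
* **Agents** move one cell per second on the lattice (a simplification
  of continuous player motion) and visit objects nearest-next with
  occasional second-nearest picks, since real search order is data,
  not model. The four styles shape the curves: *direct* walks the
  optimal path (D ≡ 0); *corrective* takes a short guaranteed
  excursion plus up to 8 random detours (moderate, shallowly declining
  D); *late adapter* makes an away-biased excursion sized to finish
  before the segment midpoint, then walks optimally (large early D,
  sharp drop); *prolonged wanderer* random-walks ~115 steps with weak
  goal bias (large D persisting past the midpoint). The excursion
  budgets carry floors so that style signatures stay separable on
  short segments; with the default mixture (55/25/10/10%), K-means on
  spline coefficients recovers the generating styles with ARI ≥ 0.9.
  Per-segment styles are drawn from a participant-specific Dirichlet
  tilt of the global mixture, so participants differ in their style
  profiles as real cohorts do.
* **Outcomes** follow the regression's own generative form, using each
  participant's simulated mean low-cost curve as X(t), with per-outcome
  coefficient sets that loosely mirror the motivating findings (skill
  and sex effects on Y1; removed-curve count and pacing on Y2; skill
  and cluster-2 share on Y3) and independent noise.
* All randomness flows from one master seed through named sub-streams
  (environments, agents, outcomes), so identical configurations give
  byte-identical data.

A separate lightweight generator (`generate_sofr_dataset`) draws
participants directly from the regression model with random smooth
functional predictors; the Monte-Carlo recovery and band-coverage
experiments use it so their sample sizes are not tied to agent
simulation cost. The archetype-curve generator plants the four
idealized shapes with smooth noise for clustering checks.

**What passing these tests shows — and does not.** The synthetic
cohorts verify the machinery: the invariants of the curve statistic,
exact agreement of the shortest-path code with enumeration, recovery
of planted cluster structure and regression coefficients, and
end-to-end determinism. They do not validate the behavioral model:
real participants are not mixture-of-four-styles lattice walkers,
real curve shapes are messier, and real cluster shares (e.g. the
dominance of near-optimal segments) depend on the population and
environment. Results on real data remain conditional on the
configured movement-cost parameters, which the data themselves do not
identify.

## Problem sizes in the shipped experiments

The test suite and acceptance script choose sizes that keep full runs
in the range of seconds to a couple of minutes while leaving the
statistical checks well-powered: 50-participant cohorts for the
invariant sweeps, 2,000 curves for planted-cluster recovery, 100
Monte-Carlo replicates at n = 200 for coefficient bias, 200 replicates
with 200 bootstrap resamples for band coverage, and exhaustive path
enumeration up to 5×5 grids. All sizes are parameters, and larger
values only tighten the same checks.

## Known limitations

* Dijkstra's distance treats every walkable step as available;
  sprinting, jumping, swimming, and fall damage short of the hard
  max-fall cutoff are out of scope.
* p-values from the penalized fit are approximate; exact inference
  would require an unpenalized refit or a full bootstrap of γ.
* The bootstrap bands are pointwise; reading them across the whole
  grid overstates joint coverage.
* Sub-second alignment of event times to 1 Hz samples uses the nearest
  sample and is flagged in logs; event positions take precedence over
  path samples where both exist.
* The silhouette criterion can legitimately select K = 2 on cohorts
  dominated by near-optimal curves (the direct/non-direct split
  explains most variance); the planted-archetype experiments, where
  four groups are guaranteed, are the calibration of the selection
  machinery.
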