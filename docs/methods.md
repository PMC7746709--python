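# Methods

This note documents the models, conventions and design decisions behind
`shapecorr`, in the order the pipeline uses them.

## Contours and arc positions

A closed contour is an ordered vertex loop; the closing edge is implicit.
All positions on a contour are *arc positions*: fractions of the perimeter
in `[0, 1)`, measured from a reference start along the canonical traversal
direction. Two conventions make everything downstream deterministic:

- **orientation** — contours are re-oriented at load to clockwise in screen
  coordinates (y grows downward; equivalently, positive shoelace area under
  that axis convention). One fixed direction is what makes heading
  inference and signed curvature meaningful.
- **reference start** — the vertex with minimal x (ties: minimal y). Model-
  specific start alignment (below) overrides it where needed.

Arc intervals are half-open `[start, end)` and cyclic. `arc_distance` is
the shortest along-contour distance, `min(|a−b|, 1−|a−b|) ∈ [0, 0.5]`.

For a pair of shapes, the test contour is uniformly rescaled so the two
axis-aligned bounding boxes have equal area (factor
`sqrt(area_base/area_test)`); only morphing uses 2D coordinates, so this is
applied there.

## Turning angles and surprisal

At `m` equidistant samples (default `m = 200`; the profile resolution, not
a property of the input polygon), the turning angle θ is measured between
the chord arriving from `window_w/2` behind the sample and the chord
leaving toward `window_w/2` ahead, with `window_w = 0.05` of the perimeter.
The window is split symmetrically — 2.5% per side — which is the standard
reading of a 5% integration window. On a circle this chord construction
yields `|θ| = 2π·(window_w/2)` exactly; on a straight edge θ = 0; on an
isolated right-angle corner `|θ| = π/2` regardless of window size.

Surprisal treats turning angles as draws from a von Mises distribution
centred on zero (straight continuation is the expectation):

    u(θ) = −log p(θ; μ=0, κ) = log(2π·I₀(κ)) − κ·cos θ

- `u_raw` is unsigned (convex and concave turns are treated symmetrically),
  strictly increasing in |θ|, and its *ranking* along the contour is
  invariant to κ.
- `u_norm = u_raw / max(u_raw)` — normalized by the contour's own maximum;
  this is what enters DTW.
- `u_signed ∈ [−1, 1]` keeps the turning direction as sign (positive =
  convex under the canonical orientation; configurable) with magnitude
  `u_raw / max|u_raw|`; this is what landmark detection uses.

κ defaults to 1.0. The absolute surprisal scale is κ-dependent, and the
source analyses do not pin it down; all normalized quantities are reported
alongside κ in output metadata, and ordering-based results are κ-invariant
by the ranking property above.

## Semantic part structure

The label vocabulary is fixed: 16 part labels (Head, Body, Eye/s, Neck,
Front leg/s, Hind leg/s, Foot/Feet, Ear/s, Trunk, Mouth, Antenna, Horn/s,
Beak, Wing/s, Tail, Fin/s) plus "None of these". Vocabulary order is the
deterministic tie-break everywhere (logged when used).

- **Vote aggregation** — each contour sample gets its modal label across
  labelers.
- **Segmentation** — maximal runs of identical per-point labels become
  labeled arcs; boundaries sit midway between adjacent samples with
  different labels; runs merge across the reference start. Arcs are
  pairwise disjoint, cover the contour, and adjacent arcs never share a
  label.
- **Label correspondence** — per-participant sorting tables are aggregated
  by co-occurrence counts: each base label maps to the test label it was
  most often sorted with; base labels sharing a winner merge into one
  group. Many-to-one groups are allowed in either direction, many-to-many
  is rejected (at input and at aggregation).
- **Heading** — the test contour is traversed either in the same or the
  reversed cyclic direction as the base. The direction is inferred by
  counting corresponding adjacent part pairs preserved under both
  traversals of the test segmentation. When a recurring connector part
  (typically the body, which separates every appendage) makes the two
  counts tie, the count is repeated on the uniquely-occurring parts only;
  remaining ties default to "same".

## The semantic organization model

For a probe at arc position s on the base shape:

1. find the base part containing s and its correspondence group;
2. concatenate, in contour order from the group's first boundary after the
   reference start, all base intervals of that group into one span of
   length ΔB, and compute the probe's offset Δb within it;
3. build the corresponding test span (length ΔT) the same way, traversed
   per heading (reversed traversal consumes each interval from its end);
4. predict the position at `Δt = ΔT·(Δb/ΔB)` along the test span.

The mapping is strictly monotone within a group, exactly invertible for
one-to-one correspondences (the same construction applied test→base with
the inverted correspondence returns the probe), and the identity for a
shape paired with itself.

Probes on "None of these" arcs, or in groups without a test-side span, are
flagged invalid rather than silently dropped; evaluation excludes them
pairwise.

*Known limitation*: for labels occupying several disjoint intervals (legs,
or the body between appendages), concatenation maps by global proportion of
the whole span, so when part scaling shifts the relative interval lengths a
probe near an interval boundary can land in the "wrong" interval of the
test span, producing local order reversals at part boundaries. The morphing
stage removes these; an interval-by-interval variant was considered and
rejected because it breaks the exact-inversion property.

## Alternative models

All alternative models share a **start alignment**: arc 0 on both shapes is
moved to the start boundary of the *leftmost semantic part* (the segment
whose interval midpoint has the smallest x; ties go to the lower arc
position). This deliberately gives the non-semantic models the benefit of a
semantically anchored origin.

- **Uniform sampling** — probe i of n maps to `(start_test ± i/n) mod 1`,
  `+` for heading same, `−` for reversed.
- **Curvature / DTW** — open-path dynamic time warping between the two
  `u_norm` profiles (squared-difference local cost, step set
  {(1,0),(0,1),(1,1)}, diagonal-preferred tie-break in the traceback).
  Open-path rather than cyclic alignment is meaningful precisely because
  both profiles are re-anchored at the leftmost part first; a reversed
  heading reverses the test profile around its fixed start before
  alignment. A probe snaps to its nearest base profile sample; the
  prediction is the mean test index matched to that sample, mapped back to
  an arc position (mean rather than median or first: the conventional
  reduction for one-to-many warps; the choice only matters for plateau
  warps). The implementation is verified against exhaustive path
  enumeration for short profiles.
- **Landmarks** — a sample of `u_signed` is a landmark iff it is a cyclic
  local extremum (plateaus count once, at their centre), the profile
  drops/rises by ≥ 0.05 on both flanks before exceeding the extremum
  again, and |value| > 0.02.
- **Combined model** — within the probe's part pair: if both parts contain
  the same number (≥ 1) of landmark *maxima*, anchors are (part start,
  landmarks in arc order, part end) and the prediction interpolates
  piecewise-linearly between matched anchors; otherwise the semantic
  prediction is returned unchanged. Maxima-only counting follows the
  "equal numbers of local maxima" criterion; matching is first-to-first in
  arc order. The prediction provably stays inside the corresponding test
  part.

## Evaluation statistics

- **Congruity** = `1 − d̄/0.25`, where d̄ is the grand mean (over probes) of
  the mean arc distance over unordered participant pairs. The 0.25 baseline
  is the exact expectation of `arc_distance` for two independent uniform
  positions; a seeded Monte-Carlo baseline is available for exact emulation
  of a random-placement panel. The formula is `1 − ratio` (not the literal
  "ratio − 1"): perfect agreement must give +1. Model congruity treats the
  model as one virtual participant against every human response.
- **Circular median** — the observed response minimizing summed arc
  distance (a medoid; deterministic, ties to the smaller position). An
  unconstrained grid-based geometric median is available behind a flag.
- **Ordering preservation** — medians are sorted cyclically in the test
  traversal direction; probe i counts as preserved iff its predecessor and
  successor in that order are probes i−1 and i+1. The rule is direction
  sensitive because same- and reversed-order response subgroups are
  analysed separately; a data-driven subgroup split (majority vote over
  per-step response directions) is provided.
- **Model comparison** — per probe, the mean participant distance to the
  median and the prediction's distance to the median (both in % of
  perimeter), compared by a paired t test. **JZS Bayes factors** integrate
  the Rouder g-prior integral (inverse-gamma(1/2, r²/2) on g, i.e. a
  Cauchy(0, r) effect-size prior, r = 0.707) by adaptive quadrature to
  relative tolerance 1e−9, with a seeded Monte-Carlo estimator of the same
  integral as an independent cross-check. Both one-sample and two-sample
  designs are implemented; the evaluation tables use the independent-
  samples convention with both group sizes equal to the number of probe
  points, which is the convention that reproduces the reference tables
  this package targets (the one-sample convention gives systematically
  smaller values, ~5.5 vs ~7.2 at t = 2.85, n = 50). Wilcoxon signed-rank
  tests (tie-corrected normal approximation; W is the positive-rank sum)
  cover the congruity-vs-random comparisons. Bonferroni-corrected
  significance levels are reported alongside raw p values.

## Morphing

Predictions that reverse order along the test contour are removed by a
greedy cyclic scan (keep a prediction iff it makes strictly positive
forward progress from the last kept one without lapping the circle);
greedy rather than maximum-subset because it is deterministic and O(n), and
the dropped points are logged. Fewer than 3 survivors is an error. Each
matched segment between consecutive anchors is resampled to
`k = max(2, round(mean(len_base, len_test)·density))` points
(`density = 200` by default — any density high enough for smooth morphs is
equivalent) and blended linearly in 2D after bounding-box-area
equalization. Morph level α = 0 reproduces the base, α = 1 the test;
self-intersections of intermediate shapes are permitted and logged, not
repaired. Shapes with interior holes are out of scope.

## Synthetic data

The generator emulates the structure of the study's stimuli and data, not
their appearance:

- **Shapes** — an elliptical body (aspect 1.7 for quadrupeds, 1.4 for
  birds) with appendages as compactly-supported radial bumps
  (`cos²` profile) at specified attachment angles. Radial bumps rather
  than welded appendage polygons: the outline stays simple (no
  self-intersection), the ground-truth segmentation is exact, and a pair
  sharing the angular parameter carries a dense ground-truth
  correspondence for free. The cost is realism — appendages are rounded
  protrusions, not articulated limbs — which is irrelevant to the
  arc-length bookkeeping the pipeline tests.
- **Pairs** — *different-geometry* pairs scale appendage width (and
  amplitude, by the square root) per part, with identity label
  correspondence: same part inventory, different part proportions.
  *Ambiguous* pairs reuse the identical outline with part labels
  reassigned in reversed cyclic order, so the ground-truth heading is
  reversed while the geometry is bit-identical.
- **Observers** — responses are the chosen signal (ground truth or a
  model's predictions) plus wrapped Gaussian noise with concentration
  `kappa_resp` (σ = kappa_resp^−1/2 of the perimeter; for small σ this is
  interchangeable with a von Mises of the same κ). A reversal subgroup
  (probability per participant) responds with the signal reflected about
  its first value, emulating the reversed-heading interpretation; lapses
  are uniform draws. Defaults mirror the study scale: 15 participants, 50
  probes, `kappa_resp = 625` (σ = 4% of the perimeter, putting simulated
  human-to-median distances in the observed 2.5–7% range), no reversals,
  no lapses.
- **Labelers** — each of 12 simulated labelers sees the true segmentation
  with every boundary independently shifted by uniform noise within
  ±jitter; majority vote recovers the truth everywhere farther than the
  jitter from a true boundary.
- **Battery** — 6 different-geometry + 5 ambiguous pairs; the per-part
  stretch factors (0.45–2.6) are chosen so the uniform-sampling model's
  deviation from the semantic prediction falls in the same 4–15%-of-
  perimeter range as in the reference tables.

What passing synthetic tests does **not** show: that real human responses
follow the semantic model (that is the empirical claim of the source
study, testable only on the deposited data), nor that real part labels are
as clean as simulated votes. The synthetic battery shows that *if*
responses are generated by a given correspondence rule, the pipeline's
statistics identify that rule and rank competing models correctly.

## Numerical choices and degenerate inputs

- Consecutive duplicate vertices are dropped at construction; contours
  with < 3 distinct vertices, zero perimeter, or (for scale normalization)
  collinear vertices are rejected.
- Quadrature: `scipy.integrate.quad` on the half-line, 400-subdivision
  limit; overflow-safe `log I₀` via the exponentially-scaled Bessel
  function.
- All ties (modal labels, correspondence winners, heading, medoid, DTW
  traceback, leftmost part) break deterministically and are logged.
- Every random quantity flows through `numpy.random.default_rng` with an
  explicit seed recorded in outputs; identical configs reproduce
  byte-identical CSV/JSON.

## Problem sizes used by the test suite

Profile resolution m = 200 and 50 probes match the study conditions; the
synthetic end-to-end checks use 10 pair replicates at 15 participants.
DTW optimality is verified exhaustively at profile lengths ≤ 6, the
circular median against brute force on 10⁴ random sets, and the congruity
null against 10³ random panels — sizes at which the oracles are exact and
the suite stays fast.
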