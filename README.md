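# shapecorr

Point-to-point correspondence between closed 2D contours, for computational
visual psychophysics.

When people see two animal-like outlines side by side and are asked "which
point on the right shape corresponds to this dot on the left shape?", their
answers are strikingly consistent — and well predicted by the shapes'
*semantic part organization*. This package implements that prediction
pipeline and the alternatives it is tested against:

- **semantic organization model** — locate the probe on its labeled part
  (Head, Trunk, Wing/s, ...), compute its relative position `p = Δb/ΔB`
  along the part, and transfer it to the corresponding part of the other
  shape at `Δt = ΔT·p`, following the inferred heading direction;
- **uniform sampling model** — equidistant positions replicated in order
  around the test contour after both shapes are re-anchored at their
  leftmost semantic part;
- **curvature model** — windowed turning angles are converted to von Mises
  *surprisal* `u = −log p(θ)`, and the two surprisal profiles are aligned
  by open-path dynamic time warping;
- **combined model** — semantic predictions refined by salient curvature
  landmarks within each part (local extrema of signed normalized surprisal
  with a 0.05 flank and 0.02 magnitude threshold), with fallback to the
  semantic prediction when landmark counts differ.

Predictions are evaluated against dot-matching response tables (real or
simulated) with the accompanying statistics battery:

- **congruity** `1 − d̄/d̄_random` (1 = all responses coincide, 0 = random
  agreement; `d̄_random = 0.25` of the perimeter, analytically);
- **ordering preservation** — how often a median response keeps both of its
  cyclic neighbours;
- per-probe **distance to the circular median response** (in % of
  perimeter), compared across models by paired *t* tests, Wilcoxon
  signed-rank tests, and **JZS Bayes factors** (Cauchy prior, scale 0.707);
- correspondence-driven **morphing** between shape pairs, after removing
  order-reversed predictions.

A fully seeded synthetic-data module generates labeled animal-like shape
pairs (elliptical body + radial-bump appendages), simulated dot-matching
panels with wrapped noise, planted heading-reversal subgroups and lapses,
and jittered part-label vote tables, so the entire pipeline is testable
without any external data.

## Worked example

```python
import numpy as np
from shapecorr import (congruity, distance_to_median, generate_pair,
                       ObserverSpec, PartSpec, ShapeSpec, simulate_responses)
from shapecorr.io import predict_all_models

spec = ShapeSpec(name="critter", parts={
    "Head": PartSpec(center=0.25, width=0.28, amplitude=0.55),
    "Tail": PartSpec(center=np.pi, width=0.26, amplitude=0.7),
})
pair = generate_pair(spec, {"Head": 2.0, "Tail": 0.5}, "different_geometry")
table = simulate_responses(pair, ObserverSpec(n_participants=15, seed=1))
preds = predict_all_models(pair.base, pair.base_seg, pair.test,
                           pair.test_seg, pair.corr, heading=pair.heading)
print(f"congruity: {congruity(table).congruity:.3f}")
for model_id in ("semantic", "uniform", "curvature"):
    _, model = distance_to_median(table, preds[model_id])
    print(f"{model_id:10s} mean distance to median: {model.mean():.2f}%")
```

prints

```
congruity: 0.827
semantic   mean distance to median: 2.35%
uniform    mean distance to median: 4.05%
curvature  mean distance to median: 14.28%
```

The simulated panel is highly congruent (0.83 on the 0–1 scale), and the
semantic model explains the responses to within the panel's own noise
(~2.4% of the perimeter), while uniform sampling misses by roughly twice
that and curvature alignment — thrown off by the doubled head and halved
tail — by 6× : the package's headline pattern.

The `analysis/` scripts run the same story at study scale (11 pairs,
15 participants, 50 probes, 12 labelers): `01_simulate.py` writes the
synthetic battery, `02_aggregate_labels.py` recovers part segmentations
from votes, `03_predict.py` runs all four models, `04_evaluate.py` builds
the summary table, `05_morph.py` writes morph sequences. A `shapecorr` CLI
(`simulate`, `labels`, `predict`, `evaluate`, `morph`, `run`) wraps the
same steps for on-disk data.

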