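"""Correspondence-driven morphing between a base and a test contour.

Predicted point correspondences anchor a piecewise interpolation: each arc
segment between consecutive anchor pairs is resampled to a shared number of
points and the two point sets are blended linearly.  Predictions whose
order reverses along the test contour are removed first, since crossing
anchors would make intermediate shapes self-intersect.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .contour import ClosedContour, cyclic_delta, normalize_pair_scale

logger = logging.getLogger(__name__)


class MorphInfeasibleError(ValueError):
    """Raised when too few order-consistent anchors remain for a morph."""


@dataclass
class MorphSequence:
    levels: list
    contours: list
    anchors: list              # (s_base, s_test) pairs actually used
    n_excluded: int


def filter_order_reversals(predictions, direction: str = "same"):
    """Greedy scan keeping predictions whose test position moves forward.

    Predictions are visited in probe order; one is kept iff its predicted
    position makes strictly positive cyclic progress (per the traversal
    direction) from the last kept prediction without lapping the start.
    Raises :class:`MorphInfeasibleError` if fewer than 3 survive.
    """
    preds = [p for p in predictions if getattr(p, "valid", True)]
    if len(preds) < 3:
        raise MorphInfeasibleError("need at least 3 valid predictions")
    kept = [preds[0]]
    progress = 0.0
    for p in preds[1:]:
        last = kept[-1].predicted
        step = float(cyclic_delta(last, p.predicted)) if direction == "same" else float(
            cyclic_delta(p.predicted, last)
        )
        if step > 0.0 and progress + step < 1.0:
            kept.append(p)
            progress += step
    n_dropped = len(preds) - len(kept)
    if n_dropped:
        logger.info("dropped %d order-reversed predictions", n_dropped)
    if len(kept) < 3:
        raise MorphInfeasibleError("fewer than 3 order-consistent anchors remain")
    return kept


def _segment_points(contour: ClosedContour, s_from: float, s_to: float, k: int):
    length = float(cyclic_delta(s_from, s_to))
    if length == 0.0:
        length = 1.0
    s = np.mod(s_from + np.arange(k) / k * length, 1.0)
    return contour.point_at(s)


def morph(
    base: ClosedContour,
    test: ClosedContour,
    anchors,
    alpha: float,
    density: int = 200,
    direction: str = "same",
    rescale: bool = True,
) -> ClosedContour:
    """Blend base and test at morph level ``alpha`` (0 = base, 1 = test).

    ``anchors`` are order-consistent predictions (see
    :func:`filter_order_reversals`).  Each matched segment is resampled to
    ``k = max(2, round(mean(len_base, len_test) * density))`` points and
    interpolated linearly in 2D, after equalizing bounding-box areas.
    """
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must lie in [0, 1]")
    if rescale:
        test = normalize_pair_scale(base, test)
    pairs = [(float(p.probe), float(p.predicted)) for p in anchors]
    n = len(pairs)
    points = []
    for idx in range(n):
        sb0, st0 = pairs[idx]
        sb1, st1 = pairs[(idx + 1) % n]
        lb = float(cyclic_delta(sb0, sb1)) or 1.0
        if direction == "same":
            lt = float(cyclic_delta(st0, st1)) or 1.0
        else:
            lt = float(cyclic_delta(st1, st0)) or 1.0
        k = max(2, int(round((lb + lt) / 2 * density)))
        pb = _segment_points(base, sb0, sb1, k)
        if direction == "same":
            pt = _segment_points(test, st0, st1, k)
        else:
            s = np.mod(st0 - np.arange(k) / k * lt, 1.0)
            pt = test.point_at(s)
        points.append((1 - alpha) * pb + alpha * pt)
    verts = np.vstack(points)
    return ClosedContour(verts, canonicalize=False)


def morph_sequence(
    base: ClosedContour,
    test: ClosedContour,
    predictions,
    levels=(0.0, 0.25, 0.5, 0.75, 1.0),
    density: int = 200,
    direction: str = "same",
) -> MorphSequence:
    """Morphs at several levels from raw (possibly inconsistent) predictions."""
    anchors = filter_order_reversals(predictions, direction=direction)
    n_excluded = sum(1 for _ in predictions) - len(anchors)
    contours = [
        morph(base, test, anchors, a, density=density, direction=direction)
        for a in levels
    ]
    return MorphSequence(
        levels=list(levels),
        contours=contours,
        anchors=[(p.probe, p.predicted) for p in anchors],
        n_excluded=n_excluded,
    )
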