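"""Alternative correspondence predictors: uniform sampling, curvature
surprisal + dynamic time warping, and the combined semantic + landmark model.

All models share a start-alignment step: both contours of a pair are
re-anchored at the starting boundary of their leftmost semantic part, so
that arc position 0 is comparable across shapes before uniform sampling or
profile warping.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .contour import ClosedContour, SurprisalProfile, cyclic_delta
from .parts import (
    CorrespondencePrediction,
    Heading,
    LabelCorrespondence,
    PartSegmentation,
    SAME,
    _group_span,
    _offset_in_span,
    _position_at_offset,
    semantic_predict,
)


@dataclass
class WarpingPath:
    """Monotone alignment between two profiles.

    ``pairs`` is an ordered integer array of (i, j) index pairs starting at
    (0, 0), ending at (mA-1, mB-1), with steps in {(1,0), (0,1), (1,1)}.
    """

    pairs: np.ndarray
    cost: float

    def test_indices_for(self, i: int) -> np.ndarray:
        return self.pairs[self.pairs[:, 0] == i, 1]


@dataclass
class Landmark:
    """Salient contour point: a thresholded extremum of signed surprisal."""

    position: float   # arc position
    index: int        # profile sample index
    polarity: str     # "max" | "min"
    value: float      # signed normalized surprisal


def align_start_to_leftmost_part(contour: ClosedContour, seg: PartSegmentation) -> float:
    """Arc position of the start boundary of the leftmost semantic part.

    The leftmost part is the segment whose interval midpoint has the
    smallest x coordinate; ties go to the lower start position.
    """
    best = None
    for lab, a, b in seg.segments:
        length = float(cyclic_delta(a, b)) if a != b else 1.0
        mid = (a + length / 2.0) % 1.0
        x = float(contour.point_at(mid)[0])
        key = (x, a)
        if best is None or key < best[0]:
            best = (key, a)
    return float(best[1])


def uniform_predict(
    probe_index: int,
    n: int,
    start_base: float,
    start_test: float,
    heading: Heading = SAME,
) -> CorrespondencePrediction:
    """Equidistant-sampling prediction: the i-th probe maps to the i-th
    equidistant position on the test contour, walked per heading."""
    if not 0 <= probe_index < n:
        raise ValueError("probe_index out of range")
    probe = float((start_base + probe_index / n) % 1.0)
    predicted = float((start_test + heading.sign * probe_index / n) % 1.0)
    return CorrespondencePrediction(probe, predicted, "uniform")


# ---------------------------------------------------------------------------
# dynamic time warping


def dtw_align(u_base: np.ndarray, u_test: np.ndarray) -> WarpingPath:
    """Minimum-cost monotone alignment under squared-difference local cost.

    Open-path DTW with step set {(1,0), (0,1), (1,1)} and a
    diagonal-preferring tie-break in the traceback.
    """
    a = np.asarray(u_base, dtype=float)
    b = np.asarray(u_test, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("empty profile")
    mA, mB = a.size, b.size
    local = (a[:, None] - b[None, :]) ** 2
    D = np.full((mA, mB), np.inf)
    D[0, 0] = local[0, 0]
    for j in range(1, mB):
        D[0, j] = D[0, j - 1] + local[0, j]
    for i in range(1, mA):
        D[i, 0] = D[i - 1, 0] + local[i, 0]
        # vectorized would need the running minimum; row loop is fast enough
        row_prev = D[i - 1]
        row = D[i]
        for j in range(1, mB):
            row[j] = local[i, j] + min(row_prev[j - 1], row_prev[j], row[j - 1])
    # traceback, diagonal preferred on ties
    i, j = mA - 1, mB - 1
    path = [(i, j)]
    while i > 0 or j > 0:
        if i == 0:
            j -= 1
        elif j == 0:
            i -= 1
        else:
            candidates = (
                (D[i - 1, j - 1], 0, i - 1, j - 1),
                (D[i - 1, j], 1, i - 1, j),
                (D[i, j - 1], 2, i, j - 1),
            )
            _, _, i, j = min(candidates, key=lambda t: (t[0], t[1]))
        path.append((i, j))
    path.reverse()
    return WarpingPath(pairs=np.array(path, dtype=int), cost=float(D[-1, -1]))


def dtw_cost_bruteforce(u_base: np.ndarray, u_test: np.ndarray) -> float:
    """Exhaustive enumeration of all monotone paths; oracle for tiny inputs."""
    a = np.asarray(u_base, dtype=float)
    b = np.asarray(u_test, dtype=float)
    local = (a[:, None] - b[None, :]) ** 2
    mA, mB = a.size, b.size
    best = [np.inf]

    def walk(i, j, cost):
        cost += local[i, j]
        if cost >= best[0]:
            return
        if i == mA - 1 and j == mB - 1:
            best[0] = cost
            return
        if i + 1 < mA and j + 1 < mB:
            walk(i + 1, j + 1, cost)
        if i + 1 < mA:
            walk(i + 1, j, cost)
        if j + 1 < mB:
            walk(i, j + 1, cost)

    walk(0, 0, 0.0)
    return best[0]


def _profile_values_for_heading(profile: SurprisalProfile, heading: Heading) -> np.ndarray:
    """u_norm in traversal order; reversed heading flips the test profile
    while keeping sample 0 (the aligned start) fixed."""
    u = profile.u_norm
    if heading.direction == "reversed":
        return np.concatenate([u[:1], u[1:][::-1]])
    return u


def curvature_predict(
    probe: float,
    path: WarpingPath,
    m_base: int,
    m_test: int,
    start_base: float = 0.0,
    start_test: float = 0.0,
    heading: Heading = SAME,
) -> CorrespondencePrediction:
    """Project a probe through a warping path between surprisal profiles.

    The probe snaps to its nearest base profile sample; the prediction is
    the mean test index matched to that sample, mapped back to an arc
    position (undoing the start alignment and any heading reversal).
    """
    probe = float(np.mod(probe, 1.0))
    i = int(np.round(cyclic_delta(start_base, probe) * m_base)) % m_base
    matched = path.test_indices_for(i)
    if matched.size == 0:  # pragma: no cover - cannot happen on a valid path
        return CorrespondencePrediction(probe, np.nan, "curvature", valid=False)
    j_mean = float(matched.mean())
    frac = j_mean / m_test
    if heading.direction == "reversed":
        predicted = float((start_test - frac) % 1.0)
    else:
        predicted = float((start_test + frac) % 1.0)
    return CorrespondencePrediction(probe, predicted, "curvature")


# ---------------------------------------------------------------------------
# landmarks and the combined model

FLANK_DROP = 0.05      # required rise/fall on both flanks of an extremum
MAGNITUDE_MIN = 0.02   # minimum |signed surprisal| for a landmark


def detect_landmarks(
    profile: SurprisalProfile,
    flank: float = FLANK_DROP,
    magnitude: float = MAGNITUDE_MIN,
) -> list:
    """Thresholded cyclic extrema of the signed surprisal profile.

    A sample is a landmark iff it is a cyclic local extremum (plateaus count
    once, at their centre), the profile drops/rises by at least ``flank`` on
    both sides before exceeding the extremum again, and its absolute value
    exceeds ``magnitude``.
    """
    u = np.asarray(profile.u_signed, dtype=float)
    m = u.size
    if np.allclose(u, u[0]):
        return []
    landmarks = []
    for polarity, sign in (("max", 1.0), ("min", -1.0)):
        v = u * sign
        i = 0
        visited = np.zeros(m, dtype=bool)
        for i in range(m):
            if visited[i]:
                continue
            # plateau of equal values containing i
            jl = i
            while v[(jl - 1) % m] == v[i]:
                jl = (jl - 1) % m
                if jl == i:
                    break
            jr = i
            while v[(jr + 1) % m] == v[i]:
                jr = (jr + 1) % m
                if jr == i:
                    break
            plateau = [jl]
            k = jl
            while k != jr:
                k = (k + 1) % m
                plateau.append(k)
            for k in plateau:
                visited[k] = True
            left = v[(jl - 1) % m]
            right = v[(jr + 1) % m]
            if left >= v[i] or right >= v[i]:
                continue  # not a strict local maximum of v
            # flank rule: drop by >= flank before rising above the extremum
            ok = True
            for step, edge in ((-1, jl), (1, jr)):
                k = edge
                dropped = False
                for _ in range(m):
                    k = (k + step) % m
                    if v[k] <= v[i] - flank:
                        dropped = True
                        break
                    if v[k] > v[i]:
                        break
                if not dropped:
                    ok = False
                    break
            if not ok or abs(u[plateau[0]]) <= magnitude:
                continue
            centre = plateau[len(plateau) // 2]
            landmarks.append(
                Landmark(
                    position=float(profile.positions[centre]),
                    index=int(centre),
                    polarity=polarity,
                    value=float(u[centre]),
                )
            )
    landmarks.sort(key=lambda lm: lm.position)
    return landmarks


def combined_predict(
    probe: float,
    base_seg: PartSegmentation,
    test_seg: PartSegmentation,
    corr: LabelCorrespondence,
    heading: Heading,
    landmarks_base: list,
    landmarks_test: list,
    use_polarity: str = "max",
) -> CorrespondencePrediction:
    """Semantic prediction refined by within-part landmark anchoring.

    If the probe's base part and its corresponding test part contain the
    same number (>= 1) of landmarks, the prediction interpolates
    piecewise-linearly between matched anchors (part start, landmarks in
    arc order, part end); otherwise the semantic prediction is returned
    unchanged.
    """
    sem = semantic_predict(probe, base_seg, test_seg, corr, heading)
    if not sem.valid:
        return CorrespondencePrediction(sem.probe, sem.predicted, "combined", valid=False)
    base_labels, test_labels = corr.groups[sem.frame.group_index]
    base_intervals, DeltaB = _group_span(base_seg, base_labels)
    reverse = heading.direction == "reversed"
    test_intervals, DeltaT = _group_span(test_seg, test_labels, reverse=reverse)

    def span_offsets(intervals, total, landmarks, rev):
        offs = []
        for lm in landmarks:
            if use_polarity != "both" and lm.polarity != use_polarity:
                continue
            if rev:
                # offset along the reversed traversal: intervals are consumed
                # from their end boundary backwards
                acc = 0.0
                off = None
                for a, b, length in intervals:
                    inside_fwd = float(cyclic_delta(a, lm.position))
                    if a == b or inside_fwd < length - 1e-12:
                        off = acc + (length - min(inside_fwd, length))
                        break
                    acc += length
            else:
                off = _offset_in_span(intervals, lm.position)
            if off is not None and 0.0 <= off <= total:
                offs.append(off)
        return sorted(offs)

    lb = span_offsets(base_intervals, DeltaB, landmarks_base, rev=False)
    lt = span_offsets(test_intervals, DeltaT, landmarks_test, rev=reverse)
    if len(lb) != len(lt) or len(lb) == 0:
        return CorrespondencePrediction(sem.probe, sem.predicted, "combined", valid=sem.valid)
    anchors_b = np.array([0.0] + lb + [DeltaB])
    anchors_t = np.array([0.0] + lt + [DeltaT])
    Deltat = float(np.interp(sem.frame.Deltab, anchors_b, anchors_t))
    predicted = _position_at_offset(test_intervals, Deltat, reverse=reverse)
    return CorrespondencePrediction(sem.probe, predicted, "combined", valid=True, frame=sem.frame)
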