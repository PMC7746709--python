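"""Closed-contour geometry: arc-length parameterization, resampling, and
turning-angle surprisal profiles.

A closed 2D contour is an ordered loop of planar vertices.  All locations on
a contour are expressed as *arc positions*: fractions of the perimeter in
``[0, 1)`` measured from a reference start vertex along the canonical
traversal direction.  The canonical direction is clockwise in screen
coordinates (y grows downward), i.e. positive shoelace area under the y-down
convention; contours are re-oriented on construction.

The information content ("surprisal") of a contour point is the negative log
probability of its windowed turning angle under a von Mises distribution
centred on zero: straight continuation is expected, sharp turns are
surprising.  Profiles of this quantity drive the curvature-based
correspondence model and landmark detection.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import i0e


class InvalidContourError(ValueError):
    """Raised for degenerate contours (too few vertices, zero perimeter...)."""


@dataclass
class ClosedContour:
    """Ordered planar vertex loop with canonical orientation.

    Parameters
    ----------
    vertices : (N, 2) array
        Ordered loop vertices; the closing edge from the last vertex back to
        the first is implicit and the first vertex is never repeated.
    canonicalize : bool
        If true (default) the loop is re-oriented clockwise in screen
        coordinates and rotated so that vertex 0 is the reference start
        (minimal x, ties broken by minimal y).
    """

    vertices: np.ndarray
    canonicalize: bool = True
    _cumlen: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        v = np.asarray(self.vertices, dtype=float)
        if v.ndim != 2 or v.shape[1] != 2 or v.shape[0] < 3:
            raise InvalidContourError("need at least 3 two-dimensional vertices")
        if np.any(np.all(v == np.roll(v, -1, axis=0), axis=1)):
            # drop exact consecutive duplicates rather than failing outright
            keep = ~np.all(v == np.roll(v, 1, axis=0), axis=1)
            keep[0] = True
            v = v[keep]
            if v.shape[0] < 3:
                raise InvalidContourError("contour degenerate after duplicate removal")
        if self.canonicalize:
            if signed_area(v) < 0:  # y-down screen convention: cw has area > 0
                v = v[::-1].copy()
            start = np.lexsort((v[:, 1], v[:, 0]))[0]
            v = np.roll(v, -start, axis=0)
        edges = np.linalg.norm(np.roll(v, -1, axis=0) - v, axis=1)
        per = float(edges.sum())
        if per <= 0:
            raise InvalidContourError("zero perimeter")
        self.vertices = v
        self._cumlen = np.concatenate([[0.0], np.cumsum(edges)])

    @property
    def n_vertices(self) -> int:
        return self.vertices.shape[0]

    @property
    def perimeter(self) -> float:
        return float(self._cumlen[-1])

    def point_at(self, s):
        """2D point(s) at arc position(s) ``s`` (fractions of perimeter)."""
        s = np.mod(np.asarray(s, dtype=float), 1.0)
        target = s * self.perimeter
        idx = np.searchsorted(self._cumlen, target, side="right") - 1
        idx = np.clip(idx, 0, self.n_vertices - 1)
        a = self.vertices[idx]
        b = self.vertices[(idx + 1) % self.n_vertices]
        seg = self._cumlen[idx + 1] - self._cumlen[idx]
        with np.errstate(invalid="ignore"):
            frac = np.where(seg > 0, (target - self._cumlen[idx]) / np.where(seg > 0, seg, 1.0), 0.0)
        return a + (b - a) * frac[..., None]

    def arc_of_vertex(self, i: int) -> float:
        """Arc position of vertex ``i``."""
        return float(self._cumlen[i % self.n_vertices] / self.perimeter)

    def bounding_box(self):
        lo = self.vertices.min(axis=0)
        hi = self.vertices.max(axis=0)
        return lo, hi


def signed_area(vertices: np.ndarray) -> float:
    """Shoelace signed area; positive = clockwise on screen (y down)."""
    v = np.asarray(vertices, dtype=float)
    x, y = v[:, 0], v[:, 1]
    return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


def arc_distance(a, b):
    """Shortest along-contour distance between arc positions, in [0, 0.5].

    Works elementwise on arrays; positions are fractions of perimeter.
    """
    d = np.abs(np.asarray(a, dtype=float) - np.asarray(b, dtype=float)) % 1.0
    return np.minimum(d, 1.0 - d)


def cyclic_delta(frm, to):
    """Forward arc step from ``frm`` to ``to`` along canonical direction, in [0, 1)."""
    return np.mod(np.asarray(to, dtype=float) - np.asarray(frm, dtype=float), 1.0)


def resample_equidistant(contour: ClosedContour, n: int, start: float = 0.0):
    """``n`` equidistant arc positions from ``start``, with their 2D points.

    Returns ``(s, points)`` where ``s[i] = (start + i/n) mod 1`` and points
    are linearly interpolated along the polygon edges.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    s = np.mod(start + np.arange(n) / n, 1.0)
    return s, contour.point_at(s)


def normalize_pair_scale(base: ClosedContour, test: ClosedContour) -> ClosedContour:
    """Uniformly scale ``test`` so both bounding boxes have equal area."""
    areas = []
    for c in (base, test):
        lo, hi = c.bounding_box()
        w, h = hi - lo
        area = w * h
        if area <= 0:
            raise InvalidContourError("zero-area bounding box (collinear contour)")
        areas.append(area)
    factor = float(np.sqrt(areas[0] / areas[1]))
    return ClosedContour(test.vertices * factor, canonicalize=False)


@dataclass
class AngularProfile:
    """Windowed turning angles at ``m`` equidistant arc positions."""

    positions: np.ndarray  # m arc positions
    theta: np.ndarray      # m signed turning angles, radians, |theta| <= pi
    window_w: float        # integration window, fraction of perimeter

    @property
    def m(self) -> int:
        return self.positions.size


@dataclass
class SurprisalProfile:
    """von Mises surprisal of windowed turning angles.

    ``u_raw`` is unsigned surprisal -log p(theta); ``u_norm`` divides by the
    contour maximum; ``u_signed`` keeps the turning direction as sign
    (positive = convex under the canonical clockwise orientation) with
    magnitude scaled to [-1, 1] by max |u_raw|.
    """

    kappa: float
    positions: np.ndarray
    theta: np.ndarray
    u_raw: np.ndarray
    u_norm: np.ndarray
    u_signed: np.ndarray

    @property
    def m(self) -> int:
        return self.positions.size


def turning_angle_profile(
    contour: ClosedContour, m: int = 200, window_w: float = 0.05, start: float = 0.0
) -> AngularProfile:
    """Signed turning angles with a centred arc-length window.

    At each sample the angle is measured between the chord arriving from
    ``window_w/2`` behind and the chord leaving toward ``window_w/2`` ahead;
    the wrap across the reference start is handled cyclically.
    """
    if m < 8:
        raise ValueError("m must be >= 8")
    if not 0 < window_w < 0.5:
        raise ValueError("window_w must lie in (0, 0.5)")
    s = np.mod(start + np.arange(m) / m, 1.0)
    p_before = contour.point_at(s - window_w / 2)
    p_center = contour.point_at(s)
    p_after = contour.point_at(s + window_w / 2)
    c1 = p_center - p_before
    c2 = p_after - p_center
    cross = c1[:, 0] * c2[:, 1] - c1[:, 1] * c2[:, 0]
    dot = np.einsum("ij,ij->i", c1, c2)
    theta = np.arctan2(cross, dot)
    return AngularProfile(positions=s, theta=theta, window_w=window_w)


def von_mises_surprisal(theta, kappa: float):
    """-log pdf of theta under von Mises(mu=0, kappa); overflow-safe."""
    if kappa <= 0:
        raise ValueError("kappa must be > 0")
    # log I0(k) = log i0e(k) + k keeps large kappa finite
    log_norm = np.log(2 * np.pi) + np.log(i0e(kappa)) + kappa
    return log_norm - kappa * np.cos(np.asarray(theta, dtype=float))


def surprisal_profile(angles: AngularProfile, kappa: float = 1.0) -> SurprisalProfile:
    """Surprisal of an angular profile: raw, max-normalized, and signed forms."""
    u_raw = von_mises_surprisal(angles.theta, kappa)
    umax = float(u_raw.max())
    u_norm = u_raw / umax if umax > 0 else np.ones_like(u_raw)
    amax = float(np.abs(u_raw).max())
    u_signed = np.sign(angles.theta) * u_raw / amax if amax > 0 else np.zeros_like(u_raw)
    return SurprisalProfile(
        kappa=float(kappa),
        positions=angles.positions.copy(),
        theta=angles.theta.copy(),
        u_raw=u_raw,
        u_norm=u_norm,
        u_signed=u_signed,
    )
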