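"""Synthetic stimuli and observers for end-to-end pipeline testing.

Shapes are animal-like closed outlines built from an elliptical body with
compactly-supported radial bumps for appendages (head, legs, tail, ...).
Every generated outline carries its exact ground-truth part segmentation,
and generated pairs carry a dense ground-truth correspondence, so each
pipeline stage can be validated without any external data.

Observers are simulated by taking a correspondence signal (ground truth or
a model's predictions), adding wrapped Gaussian noise on arc position, and
optionally planting reversed-heading participants and attentional lapses —
the response structure the evaluation pipeline assumes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .contour import ClosedContour, signed_area
from .metrics import ResponseTable
from .parts import (
    LabelCorrespondence,
    LabelVotes,
    PartSegmentation,
    REVERSED,
    SAME,
    UNLABELED,
    PART_VOCABULARY,
    segment_parts,
    semantic_predict,
)


class InvalidSpecError(ValueError):
    """Raised for overlapping appendages or out-of-range observer settings."""


@dataclass
class PartSpec:
    """One appendage: a radial bump on the body outline.

    ``center`` is the attachment angle in radians, ``width`` the half-width
    of the bump's compact support (radians), ``amplitude`` the relative
    radial extent.
    """

    center: float
    width: float
    amplitude: float


@dataclass
class ShapeSpec:
    """Recipe for one labeled outline."""

    name: str = "blob"
    parts: dict = field(default_factory=dict)   # label -> PartSpec; Body implicit
    aspect: float = 1.6                          # body semi-axis ratio a/b
    n_vertices: int = 360
    smoothing: float = 0.0                       # reserved; bumps are already smooth
    seed: int = 0

    def __post_init__(self) -> None:
        for label in self.parts:
            if label not in PART_VOCABULARY or label in ("Body", UNLABELED):
                raise InvalidSpecError(f"unknown or reserved part label: {label}")
        self.validate_no_overlap()

    def validate_no_overlap(self) -> None:
        items = sorted(self.parts.items(), key=lambda kv: kv[1].center % (2 * np.pi))
        for (la, pa), (lb, pb) in zip(items, items[1:] + items[:1]):
            gap = (pb.center - pa.center) % (2 * np.pi)
            if len(items) > 1 and gap < pa.width + pb.width:
                raise InvalidSpecError(f"appendages {la} and {lb} overlap at attachment")


@dataclass
class ObserverSpec:
    """Recipe for a simulated dot-matching participant panel."""

    n_participants: int = 15
    response_model: str = "truth"     # which signal the panel follows
    kappa_resp: float = 625.0         # wrapped-noise concentration (sigma = kappa**-0.5)
    reversal_prob: float = 0.0        # fraction responding in reversed order
    lapse_rate: float = 0.0           # uniform-random responses
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kappa_resp <= 0:
            raise InvalidSpecError("kappa_resp must be > 0")
        for p in (self.reversal_prob, self.lapse_rate):
            if not 0.0 <= p <= 1.0:
                raise InvalidSpecError("probabilities must lie in [0, 1]")

    @property
    def sigma(self) -> float:
        """Wrapped-normal standard deviation; ~ 1/sqrt(von Mises kappa)."""
        return self.kappa_resp ** -0.5


@dataclass
class ShapePair:
    pair_id: str
    base: ClosedContour
    base_seg: PartSegmentation
    test: ClosedContour
    test_seg: PartSegmentation
    corr: LabelCorrespondence
    heading: object
    mode: str
    _gt: tuple | None = field(default=None, repr=False)  # (s_base, s_test) dense arrays

    def ground_truth_map(self, s):
        """Dense ground-truth correspondence base arc -> test arc."""
        scalar = np.ndim(s) == 0
        s = np.mod(np.atleast_1d(np.asarray(s, dtype=float)), 1.0)
        if self._gt is not None:
            sb, st = self._gt
            k0 = int(np.argmin(sb))

            def unwrap(v):
                raw = np.concatenate([v[k0:], v[:k0], [v[k0]]])
                return raw[0] + np.concatenate(
                    [[0.0], np.cumsum(np.mod(np.diff(raw), 1.0))]
                )

            sb_u, st_u = unwrap(sb), unwrap(st)
            q = np.where(s < sb_u[0], s + 1.0, s)
            out = np.mod(np.interp(q, sb_u, st_u), 1.0)
        else:
            out = np.asarray(
                [
                    semantic_predict(
                        v, self.base_seg, self.test_seg, self.corr, self.heading
                    ).predicted
                    for v in s
                ],
                dtype=float,
            )
        return float(out[0]) if scalar else out


def _build_outline(spec: ShapeSpec):
    """Vertices + per-vertex labels for a spec; canonical orientation."""
    t = 2 * np.pi * np.arange(spec.n_vertices) / spec.n_vertices
    r = np.ones_like(t)
    labels = np.array(["Body"] * spec.n_vertices, dtype=object)
    for label, part in spec.parts.items():
        d = np.angle(np.exp(1j * (t - part.center)))
        inside = np.abs(d) < part.width
        r = r + np.where(inside, part.amplitude * np.cos(np.pi * d / (2 * part.width)) ** 2, 0.0)
        labels[inside] = label
    a = spec.aspect
    verts = np.column_stack([a * r * np.cos(t), r * np.sin(t)])
    if signed_area(verts) < 0:  # keep canonical screen-clockwise order
        verts = verts[::-1]
        labels = labels[::-1]
    start = np.lexsort((verts[:, 1], verts[:, 0]))[0]
    verts = np.roll(verts, -start, axis=0)
    labels = np.roll(labels, -start)
    return verts, list(labels)


def generate_shape(spec: ShapeSpec):
    """Labeled outline from a spec: contour plus ground-truth segmentation."""
    verts, labels = _build_outline(spec)
    contour = ClosedContour(verts)
    positions = np.array([contour.arc_of_vertex(i) for i in range(contour.n_vertices)])
    seg = segment_parts(labels, positions)
    return contour, seg


def generate_pair(
    spec: ShapeSpec,
    part_transforms: dict | None = None,
    mode: str = "different_geometry",
    pair_id: str | None = None,
) -> ShapePair:
    """Base/test pair with ground-truth correspondence.

    ``different_geometry``: the test shape reuses the base's part layout
    with per-part appendage scale factors (width and amplitude), an identity
    label correspondence, and a dense ground-truth map through the shared
    angular parameterization.

    ``ambiguous``: the test contour is bit-identical to the base but its
    semantic interpretation is reversed (part labels assigned in reversed
    cyclic order), so the ground-truth heading is reversed — the
    identical-geometry / different-labeling condition.
    """
    part_transforms = part_transforms or {}
    for label, f in part_transforms.items():
        if f <= 0:
            raise InvalidSpecError(f"transform for {label} must be positive")
    base_verts, base_labels = _build_outline(spec)
    base = ClosedContour(base_verts)
    base_pos = np.array([base.arc_of_vertex(i) for i in range(base.n_vertices)])
    base_seg = segment_parts(base_labels, base_pos)
    pid = pair_id or f"{spec.name}-{mode}"

    if mode == "different_geometry":
        t_parts = {
            lab: PartSpec(
                p.center,
                p.width * part_transforms.get(lab, 1.0),
                p.amplitude * part_transforms.get(lab, 1.0) ** 0.5,
            )
            for lab, p in spec.parts.items()
        }
        test_spec = ShapeSpec(
            name=spec.name + "-test", parts=t_parts, aspect=spec.aspect,
            n_vertices=spec.n_vertices, seed=spec.seed,
        )
        test_verts, test_labels = _build_outline(test_spec)
        test = ClosedContour(test_verts)
        test_pos = np.array([test.arc_of_vertex(i) for i in range(test.n_vertices)])
        test_seg = segment_parts(test_labels, test_pos)
        corr = LabelCorrespondence.identity(sorted(set(base_seg.labels), key=str))
        # shared angular index j: vertex j of base corresponds to vertex j of test
        sb_by_j = np.empty(base.n_vertices)
        st_by_j = np.empty(base.n_vertices)
        # _build_outline rolled each contour to its own min-x vertex; undo via
        # matching the roll offsets through the angular grid
        roll_b = _roll_offset(spec, base_verts)
        roll_t = _roll_offset(test_spec, test_verts)
        n = base.n_vertices
        for j in range(n):
            sb_by_j[j] = base.arc_of_vertex((j - roll_b) % n)
            st_by_j[j] = test.arc_of_vertex((j - roll_t) % n)
        return ShapePair(pid, base, base_seg, test, test_seg, corr, SAME,
                         mode, (sb_by_j, st_by_j))

    if mode == "ambiguous":
        test = ClosedContour(base_verts.copy())
        k = len(base_seg.segments)
        arcs = [(a, b) for _, a, b in base_seg.segments]
        labs = base_seg.labels
        relabeled = [(labs[(k - 1 - i) % k], a, b) for i, (a, b) in enumerate(arcs)]
        test_seg = PartSegmentation(relabeled)
        corr = LabelCorrespondence.identity(sorted(set(labs), key=str))
        return ShapePair(pid, base, base_seg, test, test_seg, corr, REVERSED, mode, None)

    raise InvalidSpecError(f"unknown mode: {mode}")


def _roll_offset(spec: ShapeSpec, rolled_verts: np.ndarray) -> int:
    """Index shift applied by _build_outline's canonical roll."""
    t = 2 * np.pi * np.arange(spec.n_vertices) / spec.n_vertices
    r = np.ones_like(t)
    for label, part in spec.parts.items():
        d = np.angle(np.exp(1j * (t - part.center)))
        inside = np.abs(d) < part.width
        r = r + np.where(inside, part.amplitude * np.cos(np.pi * d / (2 * part.width)) ** 2, 0.0)
    verts = np.column_stack([spec.aspect * r * np.cos(t), r * np.sin(t)])
    if signed_area(verts) < 0:
        verts = verts[::-1]
    start = np.lexsort((verts[:, 1], verts[:, 0]))[0]
    return int(start)


def simulate_responses(pair: ShapePair, observer: ObserverSpec, probes=None,
                       signal=None) -> ResponseTable:
    """Simulated dot-matching table: signal + wrapped noise + lapses.

    ``signal`` defaults to the pair's ground-truth correspondence at 50
    equidistant probes.  Reversal-group participants respond with the
    signal reflected about its first value, emulating a reversed-heading
    interpretation of the test shape.
    """
    rng = np.random.default_rng(observer.seed)
    if probes is None:
        probes = np.arange(50) / 50
    probes = np.mod(np.asarray(probes, dtype=float), 1.0)
    if signal is None:
        signal = pair.ground_truth_map(probes)
    signal = np.mod(np.asarray(signal, dtype=float), 1.0)
    n, P = probes.size, observer.n_participants
    reversed_flags = rng.uniform(size=P) < observer.reversal_prob
    rev_signal = np.mod(2 * signal[0] - signal, 1.0)
    responses = np.empty((n, P))
    groups = {}
    for j in range(P):
        s = rev_signal if reversed_flags[j] else signal
        noise = rng.normal(0.0, observer.sigma, size=n)
        resp = np.mod(s + noise, 1.0)
        lapses = rng.uniform(size=n) < observer.lapse_rate
        resp[lapses] = rng.uniform(size=int(lapses.sum()))
        responses[:, j] = resp
        groups[f"p{j:02d}"] = "reversed" if reversed_flags[j] else "same"
    return ResponseTable(pair.pair_id, probes, responses,
                         [f"p{j:02d}" for j in range(P)], groups)


def simulate_labelers(
    segmentation: PartSegmentation,
    n_labelers: int = 12,
    boundary_jitter: float = 0.01,
    seed: int = 0,
    m_points: int = 100,
) -> LabelVotes:
    """Vote table from labelers with jittered part boundaries.

    Each labeler sees the true segmentation with every boundary shifted by
    an independent uniform draw in [-jitter, jitter]; votes are collected at
    ``m_points`` equidistant contour samples.
    """
    lengths = segmentation.segment_lengths()
    if len(segmentation.segments) > 1 and boundary_jitter >= lengths.min() / 2:
        raise InvalidSpecError("boundary_jitter must be < half the smallest segment")
    rng = np.random.default_rng(seed)
    positions = np.arange(m_points) / m_points
    vocab = tuple(dict.fromkeys(list(PART_VOCABULARY)))
    counts = np.zeros((m_points, len(vocab)), dtype=int)
    segs = segmentation.segments
    for _ in range(n_labelers):
        if len(segs) == 1:
            jittered = segmentation
        else:
            bounds = [(a + rng.uniform(-boundary_jitter, boundary_jitter)) % 1.0
                      for _, a, _ in segs]
            jittered = PartSegmentation(
                [(segs[i][0], bounds[i], bounds[(i + 1) % len(segs)])
                 for i in range(len(segs))]
            )
        for i, s in enumerate(positions):
            counts[i, vocab.index(jittered.label_at(s))] += 1
    return LabelVotes(positions, vocab, counts, n_labelers)


# ---------------------------------------------------------------------------
# the default synthetic battery (paper-scale study conditions)


def _quadruped(name, seed, neck=0.5, tail=0.7, legs=0.45, head=0.55):
    return ShapeSpec(
        name=name,
        parts={
            "Head": PartSpec(0.25, 0.28, head),
            "Neck": PartSpec(1.45, 0.18, neck),
            "Front leg/s": PartSpec(-0.95, 0.26, legs),
            "Hind leg/s": PartSpec(-2.15, 0.26, legs),
            "Tail": PartSpec(np.pi, 0.26, tail),
        },
        aspect=1.7,
        seed=seed,
    )


def _bird(name, seed, wing=0.6, beak=0.5, tail=0.6):
    return ShapeSpec(
        name=name,
        parts={
            "Head": PartSpec(0.85, 0.28, 0.5),
            "Beak": PartSpec(-0.05, 0.14, beak),
            "Wing/s": PartSpec(2.05, 0.32, wing),
            "Tail": PartSpec(np.pi + 0.15, 0.26, tail),
            "Foot/Feet": PartSpec(-1.45, 0.22, 0.35),
        },
        aspect=1.4,
        seed=seed,
    )


#: Part-transform sets used for the six different-geometry pairs; chosen to
#: stretch/shrink appendages clearly beyond the response noise while keeping
#: attachments disjoint.
_EXP1_TRANSFORMS = (
    {"Head": 2.4, "Tail": 0.45, "Front leg/s": 0.55},
    {"Neck": 2.6, "Hind leg/s": 0.5, "Head": 1.7},
    {"Tail": 2.3, "Front leg/s": 0.5, "Head": 0.55},
    {"Beak": 2.2, "Wing/s": 0.5, "Tail": 1.8},
    {"Head": 0.5, "Tail": 2.2, "Neck": 1.9},
    {"Wing/s": 1.9, "Tail": 0.45, "Head": 1.6},
)


def exp1_battery(seed: int = 0):
    """Six different-geometry pairs with shared part inventories."""
    specs = [
        _quadruped("elephant", seed + 1),
        _quadruped("giraffe", seed + 2, neck=0.9),
        _quadruped("lizard", seed + 3, tail=1.0, legs=0.3),
        _bird("duck", seed + 4),
        _quadruped("lama", seed + 5, neck=0.7, head=0.45),
        _bird("owl", seed + 6, wing=0.8),
    ]
    return [
        generate_pair(s, tr, "different_geometry", pair_id=f"exp1-{s.name}")
        for s, tr in zip(specs, _EXP1_TRANSFORMS)
    ]


def exp2_battery(seed: int = 0):
    """Five identical-geometry pairs with reversed semantic interpretation."""
    specs = [
        _quadruped("swan-squirrel", seed + 11),
        _bird("parrot-goose", seed + 12),
        _quadruped("whale-snail", seed + 13, tail=0.9),
        _bird("duck-rabbit", seed + 14, beak=0.7),
        _quadruped("swan-cat", seed + 15, neck=0.8),
    ]
    return [generate_pair(s, None, "ambiguous", pair_id=f"exp2-{s.name}") for s in specs]
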