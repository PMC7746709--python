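"""Semantic part structure: label-vote aggregation, part segmentation,
cross-shape label correspondence, heading inference, and the semantic
organization correspondence model.

The semantic organization model predicts where an observer will place a
corresponding dot on a second ("test") shape given a probe dot on a first
("base") shape: the probe is located within its semantic part (Head, Trunk,
Wing/s ...), its relative position p = Δb/ΔB along that part is computed,
and the prediction is placed at the same relative position Δt = ΔT·p within
the corresponding part of the test shape, traversed along the inferred
heading direction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .contour import cyclic_delta

logger = logging.getLogger(__name__)

#: Fixed 16-label part vocabulary used by the labeling task, plus the
#: explicit "no part" option.  Order matters: it is the deterministic
#: tie-break for vote aggregation and label correspondence.
PART_VOCABULARY = (
    "Head", "Body", "Eye/s", "Neck", "Front leg/s", "Hind leg/s",
    "Foot/Feet", "Ear/s", "Trunk", "Mouth", "Antenna", "Horn/s",
    "Beak", "Wing/s", "Tail", "Fin/s", "None of these",
)

UNLABELED = "None of these"


def _vocab_rank(label: str) -> tuple:
    try:
        return (0, PART_VOCABULARY.index(label))
    except ValueError:
        return (1, label)


@dataclass
class LabelVotes:
    """Per-point label vote counts from ``n_labelers`` independent labelers.

    ``counts`` maps each sample point (row) and label (column) to the number
    of labelers that assigned that label.
    """

    positions: np.ndarray          # (m,) arc positions of the sample points
    labels: tuple                  # label vocabulary, column order of counts
    counts: np.ndarray             # (m, len(labels)) nonnegative ints
    n_labelers: int

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.counts = np.asarray(self.counts, dtype=int)
        if self.counts.size == 0:
            raise ValueError("empty vote table")
        if np.any(self.counts < 0) or np.any(self.counts.sum(axis=1) > self.n_labelers):
            raise ValueError("vote counts out of range")


@dataclass
class PartSegmentation:
    """Cyclically ordered cover of a contour by labeled half-open arcs.

    ``segments`` is a list of ``(label, s_start, s_end)`` with arcs read
    cyclically forward from ``s_start`` to ``s_end``; arcs are disjoint,
    cover the whole contour, and no two adjacent arcs share a label.
    """

    segments: list  # of (label, s_start, s_end)

    def __post_init__(self) -> None:
        lengths = [cyclic_delta(a, b) if a != b else 1.0 for _, a, b in self.segments]
        total = float(np.sum(lengths))
        if not np.isclose(total, 1.0, atol=1e-9):
            raise ValueError(f"segments must cover the contour (total {total})")

    @property
    def labels(self) -> list:
        return [lab for lab, _, _ in self.segments]

    def segment_lengths(self) -> np.ndarray:
        return np.array(
            [cyclic_delta(a, b) if a != b else 1.0 for _, a, b in self.segments]
        )

    def label_at(self, s: float) -> str:
        return self.segments[self.segment_index_at(s)][0]

    def segment_index_at(self, s: float) -> int:
        s = float(np.mod(s, 1.0))
        for i, (_, a, b) in enumerate(self.segments):
            if a == b:  # full circle
                return i
            if cyclic_delta(a, s) < cyclic_delta(a, b) - 1e-12 or np.isclose(s, a):
                if cyclic_delta(a, s) < cyclic_delta(a, b):
                    return i
        # numerical fallback: nearest segment start
        deltas = [cyclic_delta(a, s) for _, a, b in self.segments]
        return int(np.argmin(deltas))

    def mirrored(self) -> "PartSegmentation":
        """Segmentation of the same contour traversed in the opposite direction."""
        segs = [(lab, (1.0 - b) % 1.0, (1.0 - a) % 1.0) for lab, a, b in self.segments]
        segs = sorted(segs, key=lambda t: t[1])
        return PartSegmentation(segs)


@dataclass
class LabelCorrespondence:
    """Groups of matched part labels across a base/test shape pair.

    Many-to-one groupings are allowed in either direction but not
    many-to-many: within each group at least one side is a single label.
    """

    groups: list  # of (base_labels: tuple, test_labels: tuple)

    def __post_init__(self) -> None:
        for base_labels, test_labels in self.groups:
            if len(base_labels) > 1 and len(test_labels) > 1:
                raise ValueError("many-to-many label groups are forbidden")
            if not base_labels or not test_labels:
                raise ValueError("each group needs labels on both sides")

    def group_of_base(self, label: str):
        for gi, (bl, _) in enumerate(self.groups):
            if label in bl:
                return gi
        return None

    def group_of_test(self, label: str):
        for gi, (_, tl) in enumerate(self.groups):
            if label in tl:
                return gi
        return None

    def inverted(self) -> "LabelCorrespondence":
        return LabelCorrespondence([(tl, bl) for bl, tl in self.groups])

    @classmethod
    def identity(cls, labels) -> "LabelCorrespondence":
        return cls([((lab,), (lab,)) for lab in labels])


@dataclass
class Heading:
    """Traversal direction of the test contour relative to the base."""

    direction: str  # "same" | "reversed"

    def __post_init__(self) -> None:
        if self.direction not in ("same", "reversed"):
            raise ValueError("direction must be 'same' or 'reversed'")

    @property
    def sign(self) -> int:
        return 1 if self.direction == "same" else -1


SAME = Heading("same")
REVERSED = Heading("reversed")


@dataclass
class PartFrame:
    """Relative-position bookkeeping of one probe inside its part pair."""

    DeltaB: float   # base span arc length
    Deltab: float   # probe offset from the base span start, along heading
    DeltaT: float   # test span arc length
    group_index: int

    @property
    def p(self) -> float:
        return self.Deltab / self.DeltaB if self.DeltaB > 0 else 0.0

    @property
    def Deltat(self) -> float:
        return self.DeltaT * self.p


@dataclass
class CorrespondencePrediction:
    probe: float
    predicted: float
    model_id: str
    valid: bool = True
    frame: PartFrame | None = field(default=None, repr=False)


# ---------------------------------------------------------------------------
# vote aggregation and segmentation


def majority_labels(votes: LabelVotes) -> list:
    """Modal label per sample point; ties go to the lowest vocabulary index."""
    out = []
    for i in range(votes.counts.shape[0]):
        row = votes.counts[i]
        top = row.max()
        winners = [votes.labels[j] for j in np.flatnonzero(row == top)]
        winners.sort(key=_vocab_rank)
        if len(winners) > 1:
            logger.warning(
                "vote tie at point %d (%s); keeping %s", i, winners, winners[0]
            )
        out.append(winners[0])
    return out


def segment_parts(point_labels, positions=None) -> PartSegmentation:
    """Merge per-point modal labels into maximal labeled arcs.

    Boundaries are placed midway between adjacent samples that carry
    different labels; a run wrapping across arc position 0 is merged.
    """
    labels = list(point_labels)
    m = len(labels)
    if m == 0:
        raise ValueError("no point labels")
    if positions is None:
        positions = np.arange(m) / m
    positions = np.asarray(positions, dtype=float)
    if len(set(labels)) == 1:
        return PartSegmentation([(labels[0], 0.0, 0.0)])
    # rotate so index 0 starts a fresh run
    k = 0
    while labels[k - 1] == labels[k]:
        k += 1
    labels = labels[k:] + labels[:k]
    positions = np.concatenate([positions[k:], positions[:k]])
    boundaries = []  # (s_boundary, label of run starting here)
    run_start = 0
    for i in range(1, m + 1):
        if i == m or labels[i] != labels[i - 1]:
            prev = positions[run_start - 1] if run_start > 0 else positions[-1]
            mid = (prev + cyclic_delta(prev, positions[run_start]) / 2.0) % 1.0
            boundaries.append((mid, labels[run_start]))
            run_start = i
    segs = []
    for j, (s_a, lab) in enumerate(boundaries):
        s_b = boundaries[(j + 1) % len(boundaries)][0]
        segs.append((lab, s_a, s_b))
    segs.sort(key=lambda t: t[1])
    return PartSegmentation(segs)


def correspond_labels(sortings) -> LabelCorrespondence:
    """Aggregate per-participant label groupings into modal correspondences.

    ``sortings`` is a list of participant groupings; each grouping is a list
    of ``(base_labels, test_labels)`` tuples respecting the many-to-one
    constraint.  For every base label, the test label it was most often
    sorted with wins; base labels sharing a winner merge into one group.
    """
    if not sortings:
        raise ValueError("need at least one participant grouping")
    counts: dict = {}
    base_seen, test_seen = [], []
    for grouping in sortings:
        for base_labels, test_labels in grouping:
            if len(base_labels) > 1 and len(test_labels) > 1:
                raise ValueError("participant grouping violates many-to-one")
            for b in base_labels:
                if b not in base_seen:
                    base_seen.append(b)
                for t in test_labels:
                    counts[(b, t)] = counts.get((b, t), 0) + 1
            for t in test_labels:
                if t not in test_seen:
                    test_seen.append(t)
    mapping: dict = {}
    for b in base_seen:
        cands = [(t, c) for (bb, t), c in counts.items() if bb == b]
        top = max(c for _, c in cands)
        winners = sorted((t for t, c in cands if c == top), key=_vocab_rank)
        if len(winners) > 1:
            totals = {t: sum(c for (bb, tt), c in counts.items() if tt == t) for t in winners}
            best_total = max(totals.values())
            winners = sorted((t for t in winners if totals[t] == best_total), key=_vocab_rank)
            logger.warning("correspondence tie for %s; keeping %s", b, winners[0])
        mapping[b] = winners[0]
    groups: dict = {}
    for b, t in mapping.items():
        groups.setdefault(t, []).append(b)
    out = [(tuple(bs), (t,)) for t, bs in groups.items()]
    # unmatched test labels attach to their most frequent base partner
    for t in test_seen:
        if not any(t in tl for _, tl in out):
            cands = [(b, c) for (b, tt), c in counts.items() if tt == t]
            if cands:
                top = max(c for _, c in cands)
                winners = sorted((b for b, c in cands if c == top), key=_vocab_rank)
                b = winners[0]
                out = [
                    (bl, tl + (t,)) if (bl == (b,) and len(bl) == 1) else (bl, tl)
                    for bl, tl in out
                ]
    out.sort(key=lambda g: _vocab_rank(g[0][0]))
    return LabelCorrespondence(out)


# ---------------------------------------------------------------------------
# heading inference


def _group_sequence(seg: PartSegmentation, corr: LabelCorrespondence, side: str) -> list:
    lookup = corr.group_of_base if side == "base" else corr.group_of_test
    seq = []
    for lab in seg.labels:
        g = lookup(lab)
        if g is not None and (not seq or seq[-1] != g):
            seq.append(g)
    if len(seq) > 1 and seq[0] == seq[-1]:
        seq.pop()
    return seq


def _adjacency_agreements(base_seq: list, test_seq: list) -> int:
    if len(test_seq) < 2:
        return 0
    test_pairs = {
        (test_seq[i], test_seq[(i + 1) % len(test_seq)]) for i in range(len(test_seq))
    }
    n = len(base_seq)
    if n < 2:
        return 0
    return sum((base_seq[i], base_seq[(i + 1) % n]) in test_pairs for i in range(n))


def infer_heading(
    base: PartSegmentation, test: PartSegmentation, corr: LabelCorrespondence
) -> Heading:
    """Pick the test traversal direction that best preserves part order.

    Counts corresponding adjacent part pairs preserved under the same vs the
    reversed cyclic order of the test segmentation; ties resolve to "same".
    """
    base_seq = _group_sequence(base, corr, "base")
    test_seq = _group_sequence(test, corr, "test")
    if not base_seq or not test_seq:
        raise ValueError("no corresponding parts between the segmentations")
    fwd = _adjacency_agreements(base_seq, test_seq)
    rev = _adjacency_agreements(base_seq, test_seq[::-1])
    if fwd == rev:
        # a group recurring between every other part (typically the body)
        # makes adjacency pairs symmetric; re-count on unique groups only
        uniq = [
            g for g in set(base_seq)
            if base_seq.count(g) == 1 and test_seq.count(g) == 1
        ]
        b1 = [g for g in base_seq if g in uniq]
        t1 = [g for g in test_seq if g in uniq]
        fwd = _adjacency_agreements(b1, t1)
        rev = _adjacency_agreements(b1, t1[::-1])
        if fwd == rev:
            logger.info("heading tie (fwd=%d rev=%d); defaulting to same", fwd, rev)
    return SAME if fwd >= rev else REVERSED


# ---------------------------------------------------------------------------
# the semantic organization model


def _group_span(seg: PartSegmentation, group_labels, reverse: bool = False):
    """Concatenated intervals of a label group, in traversal order.

    Returns a list of ``(s_start, s_end, length)`` intervals ordered along
    the contour from the reference start (or along the reversed traversal
    when ``reverse``), plus the total span length.  For reversed traversal
    each interval is consumed from its end toward its start.
    """
    intervals = [
        (a, b, float(cyclic_delta(a, b)) if a != b else 1.0)
        for lab, a, b in seg.segments
        if lab in group_labels
    ]
    if not intervals:
        return [], 0.0
    if reverse:
        # traverse the contour backwards from the reference start
        intervals.sort(key=lambda t: cyclic_delta(t[1], 0.0) % 1.0)
    else:
        intervals.sort(key=lambda t: t[0])
    total = float(sum(l for _, _, l in intervals))
    return intervals, total


def _offset_in_span(intervals, s: float) -> float | None:
    """Arc offset of ``s`` from the span start, walking the span forward."""
    acc = 0.0
    for a, b, length in intervals:
        inside = float(cyclic_delta(a, s))
        if a == b or inside < length - 1e-12 or np.isclose(inside, 0.0):
            return acc + min(inside, length)
        acc += length
    return None


def _position_at_offset(intervals, offset: float, reverse: bool = False) -> float:
    acc = 0.0
    for a, b, length in intervals:
        if offset <= acc + length or (a, b, length) == intervals[-1]:
            within = min(max(offset - acc, 0.0), length)
            if reverse:
                return float((b - within) % 1.0)
            return float((a + within) % 1.0)
        acc += length
    raise RuntimeError("offset outside span")  # pragma: no cover


def semantic_predict(
    probe: float,
    base_seg: PartSegmentation,
    test_seg: PartSegmentation,
    corr: LabelCorrespondence,
    heading: Heading = SAME,
) -> CorrespondencePrediction:
    """Predict the corresponding test position of a base probe point.

    The probe's relative position p = Δb/ΔB within the concatenated span of
    its correspondence group on the base shape is transferred to the matched
    span on the test shape (traversed per heading): Δt = ΔT·p.
    """
    probe = float(np.mod(probe, 1.0))
    base_label = base_seg.label_at(probe)
    gi = corr.group_of_base(base_label)
    if gi is None or base_label == UNLABELED:
        return CorrespondencePrediction(probe, np.nan, "semantic", valid=False)
    base_labels, test_labels = corr.groups[gi]
    base_intervals, DeltaB = _group_span(base_seg, base_labels)
    reverse = heading.direction == "reversed"
    test_intervals, DeltaT = _group_span(test_seg, test_labels, reverse=reverse)
    if DeltaB <= 0 or DeltaT <= 0 or not test_intervals:
        return CorrespondencePrediction(probe, np.nan, "semantic", valid=False)
    Deltab = _offset_in_span(base_intervals, probe)
    if Deltab is None:  # numerical edge: clamp to nearest interval start
        Deltab = 0.0
    frame = PartFrame(DeltaB=DeltaB, Deltab=Deltab, DeltaT=DeltaT, group_index=gi)
    predicted = _position_at_offset(test_intervals, frame.Deltat, reverse=reverse)
    return CorrespondencePrediction(probe, predicted, "semantic", valid=True, frame=frame)
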