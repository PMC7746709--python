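import numpy as np
import pytest

from shapecorr import (
    ClosedContour,
    LabelCorrespondence,
    PartSegmentation,
    REVERSED,
    SAME,
    SurprisalProfile,
    align_start_to_leftmost_part,
    arc_distance,
    combined_predict,
    curvature_predict,
    detect_landmarks,
    dtw_align,
    semantic_predict,
    uniform_predict,
)
from shapecorr.models import Landmark, WarpingPath, dtw_cost_bruteforce
from shapecorr.io import predict_all_models


def make_profile(u_signed, positions=None):
    u = np.asarray(u_signed, dtype=float)
    pos = positions if positions is not None else np.arange(u.size) / u.size
    return SurprisalProfile(
        kappa=1.0, positions=np.asarray(pos), theta=np.sign(u),
        u_raw=np.abs(u), u_norm=np.abs(u) / max(np.abs(u).max(), 1e-12),
        u_signed=u,
    )


class TestStartAlignment:
    def test_leftmost_segment_start_returned(self, unit_square):
        # segment B's midpoint (arc 0.75) sits at x=0, left of A's (x=1)
        seg = PartSegmentation([("A", 0.0, 0.5), ("B", 0.5, 0.0)])
        assert align_start_to_leftmost_part(unit_square, seg) == pytest.approx(0.5)

    def test_full_circle_segment_keeps_reference_start(self, circle400):
        seg = PartSegmentation([("A", 0.0, 0.0)])
        assert align_start_to_leftmost_part(circle400, seg) == pytest.approx(0.0)

    def test_tie_resolved_by_lower_s_against_bruteforce(self, unit_square):
        # four quarter segments; two share the minimal midpoint x
        seg = PartSegmentation(
            [("A", 0.0, 0.25), ("B", 0.25, 0.5), ("C", 0.5, 0.75), ("D", 0.75, 0.0)]
        )
        mids = [(lab, (a + 0.125) % 1.0) for lab, a, b in seg.segments]
        xs = [(float(unit_square.point_at(m)[0]), a)
              for (_, m), (_, a, _) in zip(mids, seg.segments)]
        expected = min(xs)[1]
        assert align_start_to_leftmost_part(unit_square, seg) == pytest.approx(expected)


class TestUniformPredict:
    def test_identity_when_starts_match(self):
        for i in range(8):
            p = uniform_predict(i, 8, 0.0, 0.0, SAME)
            assert p.predicted == pytest.approx(p.probe)

    def test_offset_start_direct_formula(self):
        assert uniform_predict(2, 4, 0.0, 0.1, SAME).predicted == pytest.approx(0.6)

    def test_reversed_heading_walks_backwards(self):
        assert uniform_predict(1, 4, 0.0, 0.0, REVERSED).predicted == pytest.approx(0.75)

    def test_preserves_or_reverses_cyclic_order(self):
        n = 12
        fwd = [uniform_predict(i, n, 0.2, 0.7, SAME).predicted for i in range(n)]
        rev = [uniform_predict(i, n, 0.2, 0.7, REVERSED).predicted for i in range(n)]
        steps_f = np.mod(np.diff(fwd), 1.0)
        steps_r = np.mod(np.diff(rev), 1.0)
        assert np.allclose(steps_f, 1 / n)
        assert np.allclose(steps_r, 1 - 1 / n)


class TestDTW:
    def test_identical_profiles_zero_cost_diagonal(self):
        u = np.array([0.1, 0.5, 0.2, 0.8, 0.3])
        path = dtw_align(u, u)
        assert path.cost == pytest.approx(0.0)
        assert np.array_equal(path.pairs, np.column_stack([np.arange(5)] * 2))

    def test_small_example_matches_exhaustive_enumeration(self):
        a, b = np.array([0.0, 1.0, 0.0]), np.array([0.0, 0.0, 1.0, 0.0])
        path = dtw_align(a, b)
        assert path.cost == pytest.approx(dtw_cost_bruteforce(a, b))
        assert path.cost == pytest.approx(0.0)  # the insertion is free here

    def test_constant_profiles_prefer_diagonal(self):
        path = dtw_align(np.full(5, 0.3), np.full(5, 0.3))
        assert path.cost == pytest.approx(0.0)
        assert np.array_equal(path.pairs, np.column_stack([np.arange(5)] * 2))

    def test_optimality_against_bruteforce_all_small_sizes(self):
        rng = np.random.default_rng(11)
        for _ in range(120):
            mA = rng.integers(1, 7)
            mB = rng.integers(1, 7)
            a, b = rng.uniform(size=mA), rng.uniform(size=mB)
            assert dtw_align(a, b).cost == pytest.approx(dtw_cost_bruteforce(a, b))

    def test_path_boundary_and_monotonicity(self):
        rng = np.random.default_rng(3)
        a, b = rng.uniform(size=20), rng.uniform(size=25)
        path = dtw_align(a, b).pairs
        assert tuple(path[0]) == (0, 0) and tuple(path[-1]) == (19, 24)
        steps = set(map(tuple, np.diff(path, axis=0)))
        assert steps <= {(1, 0), (0, 1), (1, 1)}

    def test_empty_profile_rejected(self):
        with pytest.raises(ValueError):
            dtw_align(np.array([]), np.array([1.0]))


class TestCurvaturePredict:
    def test_identity_path_roundtrips_to_grid_resolution(self):
        m = 40
        path = WarpingPath(np.column_stack([np.arange(m)] * 2), 0.0)
        for probe in np.arange(0, 1, 0.11):
            pred = curvature_predict(probe, path, m, m)
            assert arc_distance(pred.predicted, probe) <= 0.5 / m + 1e-12

    def test_one_to_many_warp_uses_mean_index(self):
        pairs = [(0, 0), (1, 1), (2, 4), (2, 5), (2, 6), (3, 7)]
        path = WarpingPath(np.array(pairs), 0.0)
        pred = curvature_predict(2 / 8, path, 8, 8)
        assert pred.predicted == pytest.approx(5 / 8)

    def test_reversed_heading_unreverses_position(self):
        m = 8
        path = WarpingPath(np.column_stack([np.arange(m)] * 2), 0.0)
        pred = curvature_predict(2 / 8, path, m, m, heading=REVERSED)
        assert pred.predicted == pytest.approx((-2 / 8) % 1.0)


class TestLandmarks:
    def test_flat_profile_has_no_landmarks(self):
        assert detect_landmarks(make_profile(np.zeros(32))) == []

    def test_single_peak_above_thresholds_detected(self):
        u = np.zeros(32)
        u[10] = 0.5
        lms = detect_landmarks(make_profile(u))
        assert len(lms) == 1
        assert lms[0].polarity == "max" and lms[0].index == 10

    def test_small_peak_below_magnitude_rejected(self):
        u = np.zeros(32)
        u[10] = 0.015
        assert detect_landmarks(make_profile(u)) == []

    def test_flank_prominence_rule(self):
        # peak rising only 0.03 above its surroundings fails the 0.05 flank
        u = np.full(32, 0.30)
        u[10] = 0.33
        assert detect_landmarks(make_profile(u)) == []
        u[10] = 0.40
        maxima = [lm for lm in detect_landmarks(make_profile(u)) if lm.polarity == "max"]
        assert len(maxima) == 1 and maxima[0].index == 10

    def test_minima_detected_with_negative_values(self):
        u = np.zeros(32)
        u[5] = -0.4
        lms = detect_landmarks(make_profile(u))
        assert len(lms) == 1 and lms[0].polarity == "min"

    def test_plateau_counts_once_at_centre(self):
        u = np.zeros(33)
        u[10:13] = 0.5
        lms = detect_landmarks(make_profile(u))
        assert len(lms) == 1
        assert lms[0].index == 11


class TestCombinedPredict:
    def _segs(self):
        seg = PartSegmentation([("A", 0.0, 0.5), ("B", 0.5, 0.0)])
        corr = LabelCorrespondence.identity(["A", "B"])
        return seg, seg, corr

    def test_no_landmarks_falls_back_to_semantic(self):
        base, test, corr = self._segs()
        sem = semantic_predict(0.1, base, test, corr, SAME)
        comb = combined_predict(0.1, base, test, corr, SAME, [], [])
        assert comb.predicted == pytest.approx(sem.predicted)

    def test_unequal_counts_fall_back_to_semantic(self):
        base, test, corr = self._segs()
        lmb = [Landmark(0.1, 0, "max", 0.5), Landmark(0.3, 0, "max", 0.4)]
        lmt = [Landmark(0.1, 0, "max", 0.5)]
        sem = semantic_predict(0.2, base, test, corr, SAME)
        comb = combined_predict(0.2, base, test, corr, SAME, lmb, lmt)
        assert comb.predicted == pytest.approx(sem.predicted)

    def test_single_landmark_piecewise_linear_mapping(self):
        base, test, corr = self._segs()
        lmb = [Landmark(0.2, 0, "max", 0.5)]
        lmt = [Landmark(0.3, 0, "max", 0.5)]
        comb = combined_predict(0.1, base, test, corr, SAME, lmb, lmt)
        assert comb.predicted == pytest.approx(0.15)
        # after the landmark: remaining 0.3 of base maps onto 0.2 of test
        comb2 = combined_predict(0.35, base, test, corr, SAME, lmb, lmt)
        assert comb2.predicted == pytest.approx(0.3 + 0.15 / 0.3 * 0.2)

    def test_prediction_stays_inside_corresponding_part(self):
        base, test, corr = self._segs()
        lmb = [Landmark(0.05, 0, "max", 0.9)]
        lmt = [Landmark(0.45, 0, "max", 0.9)]
        for probe in np.linspace(0.0, 0.49, 25):
            comb = combined_predict(probe, base, test, corr, SAME, lmb, lmt)
            assert 0.0 <= comb.predicted < 0.5 + 1e-9


class TestAllModelsIdentity:
    def test_identity_pair_identity_map_all_models(self, self_pair):
        probes = np.arange(50) / 50
        preds = predict_all_models(
            self_pair.base, self_pair.base_seg, self_pair.test, self_pair.test_seg,
            self_pair.corr, heading=self_pair.heading, probes=probes, m_profile=100,
        )
        assert set(preds) == {"semantic", "uniform", "curvature", "combined"}
        for model_id, plist in preds.items():
            errs = arc_distance([p.predicted for p in plist], probes)
            grid = 1.0 / 100
            assert np.max(errs) <= grid + 1e-9, model_id
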