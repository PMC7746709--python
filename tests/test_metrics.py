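import numpy as np
import pytest

from shapecorr import (
    RANDOM_BASELINE,
    ResponseTable,
    UndefinedStatisticError,
    arc_distance,
    circular_median,
    congruity,
    distance_to_median,
    jzs_bayes_factor,
    median_responses,
    model_congruity,
    ordering_preservation,
    paired_ttest,
    split_heading_subgroups,
    wilcoxon_signed_rank,
)
from shapecorr.metrics import jzs_bayes_factor_mc, monte_carlo_baseline


def table_from(responses, pair_id="t"):
    responses = np.asarray(responses, dtype=float)
    return ResponseTable(pair_id, np.arange(responses.shape[0]) / responses.shape[0], responses)


class TestCongruity:
    def test_identical_responses_give_one(self):
        t = table_from(np.tile(np.linspace(0, 0.9, 10)[:, None], (1, 5)))
        assert congruity(t).congruity == pytest.approx(1.0)

    def test_uniform_random_responses_near_zero(self):
        rng = np.random.default_rng(0)
        vals = [congruity(table_from(rng.uniform(size=(50, 15)))).congruity
                for _ in range(50)]
        assert abs(np.mean(vals)) < 0.03

    def test_analytic_baseline_matches_grid_integration(self):
        # brute-force double integral of arc distance over the unit circle
        g = (np.arange(400) + 0.5) / 400
        grid_mean = arc_distance(g[:, None], g[None, :]).mean()
        assert grid_mean == pytest.approx(RANDOM_BASELINE, abs=1e-4)

    def test_monte_carlo_baseline_close_to_analytic(self):
        assert monte_carlo_baseline(50, 15, seed=5) == pytest.approx(0.25, abs=0.005)

    def test_invariant_to_joint_rotation_and_relabeling(self):
        rng = np.random.default_rng(1)
        r = rng.uniform(size=(20, 8))
        c0 = congruity(table_from(r)).congruity
        assert congruity(table_from((r + 0.37) % 1.0)).congruity == pytest.approx(c0)
        assert congruity(table_from(r[:, ::-1])).congruity == pytest.approx(c0)

    def test_decreases_with_wrapped_noise_magnitude(self):
        rng = np.random.default_rng(2)
        signal = np.linspace(0, 0.95, 25)
        scores = []
        for sigma in (0.01, 0.05, 0.12, 0.25):
            resp = (signal[:, None] + rng.normal(0, sigma, size=(25, 12))) % 1.0
            scores.append(congruity(table_from(resp)).congruity)
        assert np.all(np.diff(scores) < 0)

    def test_single_participant_rejected(self):
        with pytest.raises(ValueError):
            congruity(table_from(np.zeros((5, 1))))

    def test_model_congruity_perfect_when_on_responses(self):
        r = np.tile(np.linspace(0, 0.9, 10)[:, None], (1, 5))
        t = table_from(r)
        assert model_congruity(r[:, 0], t).congruity == pytest.approx(1.0)


class TestCircularMedian:
    @pytest.mark.parametrize(
        "vals,expected", [([0.3], 0.3), ([0.1, 0.2, 0.3], 0.2), ([0.95, 0.0, 0.05], 0.0)]
    )
    def test_examples_including_wraparound(self, vals, expected):
        assert circular_median(vals) == pytest.approx(expected)

    def test_matches_bruteforce_on_random_sets(self):
        rng = np.random.default_rng(9)
        for _ in range(500):
            vals = rng.uniform(size=rng.integers(1, 9))
            med = circular_median(vals)
            sums = arc_distance(vals[:, None], vals[None, :]).sum(axis=1)
            best = sums.min()
            assert arc_distance(vals, med).sum() == pytest.approx(best)
            # tie rule: no observed value with the same sum is smaller
            assert med <= vals[np.isclose(sums, best)].max()

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            circular_median([])


class TestOrdering:
    def test_identical_cyclic_order_fully_preserved(self):
        medians = (np.arange(10) / 10 + 0.13) % 1.0
        percent, reversals = ordering_preservation(medians)
        assert percent == 100.0 and reversals == 0

    def test_exactly_reversed_order_scores_zero(self):
        medians = np.array([0.9, 0.6, 0.3, 0.0])
        percent, _ = ordering_preservation(medians)
        assert percent == 0.0
        # but counted in the reversed traversal direction it is perfect
        percent_rev, _ = ordering_preservation(medians, direction="reversed")
        assert percent_rev == 100.0

    def test_single_swap_breaks_neighbours_only(self):
        med = np.arange(12) / 12.0
        med[[4, 5]] = med[[5, 4]]
        percent, reversals = ordering_preservation(med)
        assert reversals == 4  # the swapped pair and both flanking probes

    def test_uniform_random_matches_simulation_mean(self):
        rng = np.random.default_rng(4)
        sim = [ordering_preservation(rng.uniform(size=12))[0] for _ in range(4000)]
        rng2 = np.random.default_rng(5)
        sim2 = [ordering_preservation(rng2.uniform(size=12))[0] for _ in range(4000)]
        assert np.mean(sim) == pytest.approx(np.mean(sim2), abs=1.0)

    def test_too_few_medians_rejected(self):
        with pytest.raises(ValueError):
            ordering_preservation(np.array([0.1, 0.2]))


class TestSubgroupSplit:
    def test_planted_reversal_groups_recovered(self):
        rng = np.random.default_rng(6)
        probes = np.arange(50) / 50
        fwd = (probes[:, None] + rng.normal(0, 0.02, (50, 7))) % 1.0
        rev = (-probes[:, None] + rng.normal(0, 0.02, (50, 8))) % 1.0
        t = table_from(np.hstack([fwd, rev]))
        same, reversed_ = split_heading_subgroups(t)
        assert set(same) == set(range(7))
        assert set(reversed_) == set(range(7, 15))


class TestDistanceToMedian:
    def test_predictions_equal_medians_give_zero(self):
        rng = np.random.default_rng(7)
        t = table_from(rng.uniform(size=(8, 5)))
        med = median_responses(t)
        human, model = distance_to_median(t, med)
        assert np.allclose(model, 0.0)

    def test_symmetric_two_participants(self):
        t = table_from(np.array([[0.25, 0.35]] * 4))
        human, model = distance_to_median(t, np.full(4, 0.30))
        # the medoid is one of the two responses, so humans average 5%
        assert np.allclose(human, 5.0)

    def test_toy_table_matches_hand_computation(self):
        resp = np.array([
            [0.10, 0.20, 0.30],
            [0.40, 0.42, 0.50],
            [0.90, 0.95, 0.05],
            [0.60, 0.70, 0.62],
        ])
        t = table_from(resp)
        preds = np.array([0.25, 0.45, 0.99, 0.58])
        human, model = distance_to_median(t, preds)
        # medians (medoids): 0.20, 0.42, 0.95, 0.62
        assert np.allclose(human, [
            (0.10 + 0.00 + 0.10) / 3 * 100,
            (0.02 + 0.00 + 0.08) / 3 * 100,
            (0.05 + 0.00 + 0.10) / 3 * 100,
            (0.02 + 0.08 + 0.00) / 3 * 100,
        ])
        assert np.allclose(model, [5.0, 3.0, 4.0, 4.0])

    def test_invalid_predictions_excluded_pairwise(self):
        t = table_from(np.random.default_rng(0).uniform(size=(6, 4)))
        preds = np.array([0.1, np.nan, 0.3, 0.4, np.nan, 0.6])
        human, model = distance_to_median(t, preds)
        assert human.size == model.size == 4


class TestWilcoxon:
    def test_all_positive_differences_exact_p(self):
        d = np.arange(1, 11, dtype=float)
        W, Z, p = wilcoxon_signed_rank(d, method="exact")
        assert W == pytest.approx(55.0)
        assert p == pytest.approx(2 / 1024)

    def test_zero_differences_rejected(self):
        x = np.arange(8, dtype=float)
        with pytest.raises(UndefinedStatisticError):
            wilcoxon_signed_rank(x, x)

    def test_symmetric_differences_near_zero_z(self):
        d = np.array([1.0, -1.0, 2.0, -2.0, 3.0, -3.0, 4.0, -4.0])
        _, Z, p = wilcoxon_signed_rank(d)
        assert abs(Z) < 0.1 and p > 0.9


class TestPairedT:
    def test_known_small_sample_value(self):
        t, df, p = paired_ttest(np.array([1.0, 2.0, 3.0, 4.0]))
        assert t == pytest.approx(2.5 / (np.sqrt(5 / 3) / 2), abs=1e-9)
        assert t == pytest.approx(3.873, abs=1e-3)
        assert df == 3

    def test_matches_closed_form_on_random_inputs(self):
        rng = np.random.default_rng(12)
        for _ in range(20):
            d = rng.normal(size=rng.integers(5, 40))
            t, df, p = paired_ttest(d)
            expect = d.mean() / (d.std(ddof=1) / np.sqrt(d.size))
            assert t == pytest.approx(expect)
            assert df == d.size - 1

    def test_zero_variance_rejected(self):
        with pytest.raises(UndefinedStatisticError):
            paired_ttest(np.full(10, 2.0))


class TestJZSBayesFactor:
    def test_reference_value_two_sample_convention(self):
        # the convention used for the evaluation tables: both group sizes =
        # number of probe points
        bf = jzs_bayes_factor(2.85, (50, 50), r=0.707)
        assert bf == pytest.approx(7.17, abs=0.01)

    def test_one_sample_agrees_with_pingouin(self):
        pingouin = pytest.importorskip("pingouin")
        for t, n in [(2.85, 50), (1.2, 20), (-0.5, 15)]:
            ours = jzs_bayes_factor(t, n, design="one-sample")
            ref = float(pingouin.bayesfactor_ttest(t, n, paired=True, r=0.707))
            assert ours == pytest.approx(ref, rel=1e-6)

    def test_quadrature_agrees_with_monte_carlo(self):
        for design, n in (("one-sample", 50), ("two-sample", (50, 50))):
            q = jzs_bayes_factor(2.85, n, design=design)
            mc = jzs_bayes_factor_mc(2.85, n, design=design, seed=17)
            assert q == pytest.approx(mc, rel=0.01)

    def test_null_favored_at_t_zero(self):
        assert jzs_bayes_factor(0.0, 50, design="one-sample") < 1.0
        assert jzs_bayes_factor(0.0, (50, 50)) < 1.0

    def test_monotone_in_absolute_t(self):
        ts = [0.0, 0.5, 1.0, 2.0, 3.0, 5.0]
        bfs = [jzs_bayes_factor(t, (50, 50)) for t in ts]
        assert np.all(np.diff(bfs) > 0)
        assert jzs_bayes_factor(-2.0, (50, 50)) == pytest.approx(
            jzs_bayes_factor(2.0, (50, 50))
        )

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            jzs_bayes_factor(np.nan, 50)
        with pytest.raises(ValueError):
            jzs_bayes_factor(1.0, 50, r=0.0)
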