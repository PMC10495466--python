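"""State labelling, same-state probability, and state-conditioned analyses."""

import numpy as np
import pytest

from corticalstate import (
    EpochLayout,
    GeneratorConfig,
    PowerRatioTable,
    draw_latents,
    evoked_analysis,
    label_states,
    performance_by_state,
    pr_outcome_contrast,
    quartile_comparison,
    rt_state_correlation,
    same_state_probability,
)


def table_from(pr):
    return PowerRatioTable(pr=np.asarray(pr, float), window_ms=(-400, 0))


class TestLabelStates:
    def test_forced_split(self):
        labels = label_states(table_from(np.array([[1.0], [2.0], [3.0], [4.0]])))
        assert labels.electrode_labels[:, 0].tolist() == [False, False, True, True]

    def test_even_n_distinct_values_balanced(self):
        rng = np.random.default_rng(0)
        pr = rng.lognormal(2, 0.5, size=(40, 3))
        labels = label_states(table_from(pr))
        assert np.all(labels.electrode_labels.sum(axis=0) == 20)

    def test_invariant_under_monotone_transform(self):
        # per-electrode median splits depend only on ranks; the population
        # label uses min-max normalized values, which a nonlinear transform
        # rescales, so only the per-electrode labels are rank-invariant
        rng = np.random.default_rng(1)
        pr = rng.lognormal(2, 0.5, size=(31, 4))
        a = label_states(table_from(pr))
        b = label_states(table_from(np.log(pr)))
        assert np.array_equal(a.electrode_labels, b.electrode_labels)
        c = label_states(table_from(3.0 * pr + 2.0))  # affine: ranks and shape
        assert np.array_equal(a.population_labels, c.population_labels)

    def test_degenerate_electrode_flagged(self):
        pr = np.column_stack([np.ones(10), np.arange(1.0, 11.0)])
        labels = label_states(table_from(pr))
        assert labels.degenerate.tolist() == [True, False]


class TestSameStateProbability:
    def test_identical_series_gives_probability_one(self):
        series = np.random.default_rng(2).lognormal(2, 0.5, 50)
        labels = label_states(table_from(np.tile(series[:, None], (1, 6))))
        res = same_state_probability(labels, 0, n_permutations=50, seed=0)
        assert res.probability == 1.0

    def test_reversed_ranks_give_probability_zero(self):
        z = np.random.default_rng(3).standard_normal(50)
        pr = np.column_stack([np.exp(-z)] + [np.exp(z)] * 5)
        labels = label_states(table_from(pr))
        res = same_state_probability(labels, 0, n_permutations=50, seed=0)
        assert res.probability == 0.0

    def test_shuffle_null_centers_at_half(self, det_tables):
        res = same_state_probability(det_tables.labels, 2, n_permutations=4000, seed=5)
        assert res.null_mean == pytest.approx(0.5, abs=0.02)

    def test_population_subset_must_exclude_electrode(self, det_tables):
        with pytest.raises(ValueError):
            same_state_probability(det_tables.labels, 1, population_subset=[0, 1, 2])

    def test_too_few_trials_rejected(self):
        labels = label_states(table_from(np.random.default_rng(4).random((10, 3))))
        with pytest.raises(ValueError):
            same_state_probability(labels, 0)


class TestPerformanceByState:
    def test_null_coupling_bins_agree(self):
        rng = np.random.default_rng(5)
        state = rng.random(400) > 0.5
        outcomes = rng.random(400) < 0.7
        res = performance_by_state(state, outcomes, n_bootstrap=2000, seed=0)
        assert res.comparison.pvalue > 0.05
        assert abs(res.percent_correct[1] - res.percent_correct[0]) < 15

    def test_saturated_coupling(self):
        state = np.repeat([False, True], 30)
        res = performance_by_state(state, state.copy(), n_bootstrap=500, seed=1)
        assert res.percent_correct.tolist() == [0.0, 100.0]

    def test_weighted_mean_recovers_overall_performance(self):
        rng = np.random.default_rng(6)
        state = rng.random(200)
        outcomes = rng.random(200) < 0.6
        res = performance_by_state(state, outcomes, n_bins=2, n_bootstrap=100, seed=2)
        weighted = (res.percent_correct * res.n_trials).sum() / res.n_trials.sum()
        assert weighted == pytest.approx(100.0 * outcomes.mean(), abs=1e-9)

    def test_three_equal_width_bins(self):
        state = np.array([0.0, 0.1, 0.45, 0.55, 0.9, 1.0])
        outcomes = np.ones(6, bool)
        res = performance_by_state(state, outcomes, n_bins=3, n_bootstrap=100, seed=3)
        assert res.n_trials.tolist() == [2, 2, 2]

    def test_empty_bin_reported_not_merged(self):
        state = np.array([0.0, 0.01, 0.02, 1.0, 0.99])
        with pytest.raises(ValueError, match="empty state bin"):
            performance_by_state(state, np.ones(5, bool), n_bins=3, n_bootstrap=10)

    def test_detection_coupling_recovered(self, det_tables):
        res = performance_by_state(
            det_tables.labels.global_labels,
            np.asarray(det_tables.session.outcome, bool),
            n_bootstrap=2000,
            seed=4,
        )
        assert res.percent_correct[1] > res.percent_correct[0]


class TestOutcomeContrast:
    def test_arithmetic(self):
        pr = np.concatenate([np.full(10, 12.5), np.full(10, 10.0)])[:, None]
        outcomes = np.repeat([True, False], 10)
        res = pr_outcome_contrast(table_from(pr + 1e-9 * np.arange(20)[:, None]), outcomes)
        assert res.percent_difference[0] == pytest.approx(25.0, abs=0.01)

    def test_null_contrast_not_significant(self):
        rng = np.random.default_rng(7)
        pr = rng.lognormal(2, 0.5, size=(200, 20))
        outcomes = rng.random(200) < 0.6
        res = pr_outcome_contrast(table_from(pr), outcomes)
        assert res.test_two_sided.pvalue > 0.01
        assert abs(res.mean_percent_difference) < 10

    def test_coupled_generator_positive_contrast(self):
        cfg = GeneratorConfig(n_electrodes=50, n_trials=120)
        rng = np.random.default_rng(8)
        g, _, log_pr = draw_latents(cfg, rng, 120)
        p = 1 / (1 + np.exp(-(0.6 + cfg.detection_coupling * g)))
        outcomes = rng.random(120) < p
        res = pr_outcome_contrast(table_from(np.exp(log_pr)), outcomes)
        assert np.nanmedian(res.percent_difference) > 0
        assert res.test_one_sided.pvalue < 0.05

    def test_requires_both_outcomes(self):
        with pytest.raises(ValueError):
            pr_outcome_contrast(table_from(np.random.random((10, 2)) + 1), np.ones(10, bool))


def evoked_session(pr_power, rng, task="detection"):
    """Session whose stim-1 window mean-square power equals ``pr_power``."""
    from tests.conftest import build_session

    n, e = pr_power.shape
    layout = EpochLayout()
    markers = layout.markers(1000.0)
    v = rng.standard_normal((n, e, layout.n_samples(1000.0))).astype(np.float32)
    seg = slice(markers["stim1_on"], markers["stim1_off"])
    v[:, :, seg] = np.sqrt(pr_power)[:, :, None].astype(np.float32)
    return build_session(v, task=task)


class TestEvokedAnalysis:
    def test_perfect_coupling_gives_r_one(self, make_session):
        rng = np.random.default_rng(9)
        log_pr = rng.normal(2, 0.8, size=(60, 3))
        sess = evoked_session(10.0**log_pr, rng)
        res = evoked_analysis(sess, table_from(np.exp(log_pr)))
        assert np.all(res.pearson_r > 0.999)

    def test_independent_evoked_is_null(self):
        rng = np.random.default_rng(10)
        log_pr = rng.normal(2, 0.8, size=(100, 12))
        sess = evoked_session(rng.lognormal(3, 0.5, size=(100, 12)), rng)
        res = evoked_analysis(sess, table_from(np.exp(log_pr)))
        assert abs(np.median(res.pearson_r)) < 0.15
        assert res.r_test.pvalue > 0.01

    def test_generator_coupling_recovered(self, det_tables):
        res = evoked_analysis(det_tables.session, det_tables.pr_table, det_tables.labels)
        assert np.nanmean(res.pearson_r) > 0.2
        assert res.r_test.pvalue < 0.01

    def test_discrimination_state_split_sign(self, dis_tables):
        res = evoked_analysis(dis_tables.session, dis_tables.pr_table, dis_tables.labels)
        assert res.diff_low_db.mean() > res.diff_high_db.mean()

    def test_detection_has_no_test_difference(self, det_tables):
        res = evoked_analysis(det_tables.session, det_tables.pr_table, det_tables.labels)
        assert res.table.test_db is None
        with pytest.raises(ValueError):
            _ = res.table.diff_db


class TestRTCorrelation:
    def test_monotone_limit(self):
        log_pr = np.random.default_rng(11).normal(2, 0.8, 50)[:, None]
        rt = 900.0 - 50.0 * log_pr[:, 0]  # RT strictly decreasing in log PR
        res = rt_state_correlation(table_from(np.exp(log_pr)), rt, "negative")
        assert res.pearson_r[0] == pytest.approx(-1.0, abs=1e-9)

    def test_independent_rt_null(self):
        rng = np.random.default_rng(12)
        pr = rng.lognormal(2, 0.8, size=(200, 15))
        rt = rng.normal(600, 100, 200)
        res = rt_state_correlation(table_from(pr), rt, "negative")
        assert abs(np.median(res.pearson_r)) < 0.1

    def test_generator_slopes_recover_task_signs(self):
        from corticalstate import generate_session, prepare_task

        cfg = GeneratorConfig(n_electrodes=12, n_trials=120, seed=13, rt_slope_ms=80.0)
        sess = generate_session(cfg)
        det = prepare_task(sess, "detection", notch=False)
        dis = prepare_task(sess, "discrimination", notch=False)
        r_det = rt_state_correlation(
            det.pr_table, det.session.reaction_time_ms, "negative"
        )
        r_dis = rt_state_correlation(
            dis.pr_table, dis.session.reaction_time_ms, "positive"
        )
        assert np.median(r_det.pearson_r) < 0 < np.median(r_dis.pearson_r)
        assert r_det.r_test.pvalue < 0.05
        assert r_dis.r_test.pvalue < 0.05

    def test_too_few_correct_trials(self):
        pr = np.random.default_rng(14).random((30, 2)) + 1
        rt = np.full(30, np.nan)
        rt[:5] = 500.0
        with pytest.raises(ValueError):
            rt_state_correlation(table_from(pr), rt, "negative")


class TestQuartileComparison:
    def test_partition_is_exhaustive_and_balanced(self):
        rng = np.random.default_rng(15)
        res = quartile_comparison(rng.random(40), rng.standard_normal(40))
        counts = np.bincount(res.quartile_of, minlength=4)
        assert counts.tolist() == [10, 10, 10, 10]

    def test_iid_values_not_significant(self):
        rng = np.random.default_rng(16)
        res = quartile_comparison(rng.random(48), rng.standard_normal(48))
        assert res.test.pvalue > 0.05

    def test_constructed_shift_detected(self):
        rng = np.random.default_rng(17)
        probs = np.linspace(0.4, 0.8, 80)
        values = rng.normal(0, 0.5, 80)
        values[probs <= np.quantile(probs, 0.25)] += 1.0  # +1 dB in Q1
        res = quartile_comparison(probs, values)
        assert res.test.pvalue < 0.05

    def test_requires_eight_electrodes(self):
        with pytest.raises(ValueError):
            quartile_comparison(np.random.random(5), np.random.random(5))
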