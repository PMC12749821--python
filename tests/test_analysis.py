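import numpy as np
import pytest

import ioglmhmm as ig
from ioglmhmm.analyze import predictive_state_probs
from ioglmhmm.features import config_with_sd
from ioglmhmm.infer import forward_backward_all


@pytest.fixture(scope="module")
def cfg1():
    return ig.FeatureConfig(contrast_sd=1.0)


class TestPsychometricCurves:
    def test_zero_stimulus_weight_gives_flat_curve_at_logistic_bias(self, cfg1):
        params = ig.ModelParams(np.array([1.0]), np.array([[0.0, 0.0, 0.0, 1.2]]),
                                np.zeros((1, 6)), np.zeros((1, 1)))
        grid = np.linspace(-1, 1, 9)
        curves = ig.psychometric_curves(params, grid, cfg1)
        np.testing.assert_allclose(curves[0], 1 / (1 + np.exp(-1.2)), atol=1e-12)

    def test_unbiased_state_monotone_through_half(self, cfg1):
        params = ig.ModelParams(np.array([1.0]), np.array([[4.0, 0.0, 0.0, 0.0]]),
                                np.zeros((1, 6)), np.zeros((1, 1)))
        grid = np.linspace(-1, 1, 9)
        c = ig.psychometric_curves(params, grid, cfg1)[0]
        assert c[4] == pytest.approx(0.5)
        assert np.all(np.diff(c) > 0)

    def test_mixture_curve_inside_convex_hull(self, small_sim, small_fit, feature_config):
        _, _, designs, sd = small_sim
        grid = np.linspace(-1, 1, 9)
        cfg = config_with_sd(ig.FeatureConfig(), sd)
        bundles = forward_backward_all(designs, small_fit.params)
        mix = ig.model_psychometric_curve(small_fit.params, grid, cfg, bundles,
                                          [d.X_tr for d in designs])
        curves = ig.psychometric_curves(small_fit.params, grid, cfg)
        assert np.all(mix <= curves.max(axis=0) + 1e-12)
        assert np.all(mix >= curves.min(axis=0) - 1e-12)

    def test_predictive_probs_rows_stochastic(self, small_sim):
        _, truth, designs, _ = small_sim
        d = designs[0]
        b = ig.forward_backward(d.X_ob, d.X_tr, d.y, truth.params)
        pred = predictive_state_probs(b, d.X_tr, truth.params)
        np.testing.assert_allclose(pred.sum(axis=1), 1.0, atol=1e-10)
        np.testing.assert_allclose(pred[0], truth.params.pi)


class TestDwellTimes:
    def test_geometric_mean_holding_times(self):
        A = np.array([[0.9, 0.1], [0.0, 1.0]])
        d = ig.expected_dwell_times(A)
        assert d[0] == pytest.approx(10.0)
        assert np.isinf(d[1])

    def test_zero_self_transition_leaves_immediately(self):
        A = np.array([[0.0, 1.0], [1.0, 0.0]])
        np.testing.assert_allclose(ig.expected_dwell_times(A), [1.0, 1.0])

    def test_non_stochastic_input_rejected(self):
        with pytest.raises(ValueError):
            ig.expected_dwell_times(np.array([[0.5, 0.2], [0.1, 0.9]]))


class TestTransitionBiasAndMatrix:
    def test_zero_params_give_uniform_matrices(self, small_sim):
        _, _, designs, _ = small_sim
        K = 2
        params = ig.ModelParams(np.full(K, 0.5), np.zeros((K, 4)),
                                np.zeros((K, 6)), np.zeros((K, K)))
        bias, avg = ig.transition_bias_and_matrix(params, [d.X_tr for d in designs])
        np.testing.assert_allclose(bias, 0.5)
        np.testing.assert_allclose(avg, 0.5, atol=1e-12)

    def test_matrices_row_stochastic_and_bias_equals_avg_without_covariates(self, small_fit):
        X0 = [np.zeros((10, 6))]
        bias, avg = ig.transition_bias_and_matrix(small_fit.params, X0)
        np.testing.assert_allclose(bias.sum(axis=1), 1.0, atol=1e-10)
        np.testing.assert_allclose(avg, bias, atol=1e-12)

    def test_sticky_generator_yields_prominent_bias_diagonal(self, small_sim, small_fit):
        # the baseline (pre-modulation) matrix carries the stickiness;
        # the covariate-averaged matrix redistributes it but stays stochastic
        _, _, designs, _ = small_sim
        bias, avg = ig.transition_bias_and_matrix(small_fit.params,
                                                  [d.X_tr for d in designs])
        assert np.all(np.argmax(bias, axis=1) == np.arange(bias.shape[0]))
        np.testing.assert_allclose(avg.sum(axis=1), 1.0, atol=1e-10)


class TestStateSummaries:
    def test_single_state_labeling_trivial_summary(self):
        phi = np.tile([1.0, 0.0], (50, 1))
        b = ig.PosteriorBundle(phi, np.zeros((49, 2, 2)), 0.0, phi, phi, np.zeros(50))
        blocks = [np.repeat([0.8, 0.2], 25)]
        s = ig.state_summaries([b], blocks, congruent_states={0.8: np.array([0]),
                                                              0.2: np.array([0])})
        np.testing.assert_allclose(s.occupancy, [1.0, 0.0])
        assert s.state_changes == [0]
        assert s.first_transition_latency == [0, 0]

    def test_alternating_labels_count_changes(self):
        phi = np.zeros((40, 2))
        phi[::2, 0] = 1.0
        phi[1::2, 1] = 1.0
        b = ig.PosteriorBundle(phi, np.zeros((39, 2, 2)), 0.0, phi, phi, np.zeros(40))
        s = ig.state_summaries([b])
        assert s.state_changes == [39]

    def test_occupancy_converges_to_generator_long_run_frequency(self, feature_config):
        """With near-deterministic emissions the MAP occupancy matches the
        generating chain's empirical state frequency."""
        params = ig.default_params(2, style="static")
        params.W_ob = np.array([[12.0, 0, 0, -6.0], [0.0, 0, 0, 12.0]])
        task = ig.generate_task(ig.TaskConfig(n_sessions=6, trials_per_session=400), seed=40)
        data, truth = ig.simulate_agent(task, params, feature_config, seed=41)
        designs, _ = ig.prepare_designs(
            data, ig.FeatureConfig(contrast_sd=feature_config.contrast_sd))
        bundles = forward_backward_all(designs, params)
        s = ig.state_summaries(bundles)
        emp = np.bincount(np.concatenate(truth.states), minlength=2) / (6 * 400)
        np.testing.assert_allclose(s.occupancy, emp, atol=0.03)

    def test_timecourse_grid_shape_and_normalization(self, small_sim):
        _, truth, designs, _ = small_sim
        bundles = forward_backward_all(designs, truth.params)
        s = ig.state_summaries(bundles)
        assert s.state_prob_timecourse.shape == (2, 100)
        np.testing.assert_allclose(s.state_prob_timecourse.sum(axis=0), 1.0, atol=1e-8)

    def test_block_occupancy_concentrates_on_congruent_states(self, feature_config):
        """Directional block-congruence property: in right-biased blocks
        the right-preferring states carry most of the MAP-labeled trials."""
        params = ig.default_params(4)
        task = ig.generate_task(ig.TaskConfig(n_sessions=8, trials_per_session=500), seed=50)
        data, truth = ig.simulate_agent(task, params, feature_config, seed=51)
        designs, _ = ig.prepare_designs(
            data, ig.FeatureConfig(contrast_sd=feature_config.contrast_sd))
        bundles = forward_backward_all(designs, params)
        blocks = [d.block_p_right for d in designs]
        s = ig.state_summaries(bundles, blocks)
        right_states = [1, 3]  # Engaged-R, Biased-R in the template
        occ_r = s.occupancy_by_block[0.8][right_states].sum()
        occ_l = s.occupancy_by_block[0.2][right_states].sum()
        assert occ_r > occ_l
        assert occ_r > 0.5


class TestClassifyStates:
    def test_template_states_labeled_by_structure(self):
        labels = ig.classify_states(ig.default_params(4), ig.FeatureConfig())
        assert labels == ["engaged-L", "engaged-R", "biased-L", "biased-R"]


class TestRTSeparation:
    def test_constructed_shift_recovered(self):
        rng = np.random.default_rng(0)
        labels = np.repeat([0, 1], 2000)
        rt = np.concatenate([rng.exponential(0.5, 2000), 1.0 + rng.exponential(0.5, 2000)])
        out = ig.rt_engagement_separation(rt, labels, engaged_states=np.array([0]),
                                          n_boot=500, seed=1)
        assert out["delta_t90"] == pytest.approx(1.0, abs=0.25)
        lo, hi = out["ci95"]
        assert lo < out["delta_t90"] < hi

    def test_identical_distributions_ci_covers_zero(self):
        rng = np.random.default_rng(2)
        labels = np.repeat([0, 1], 1500)
        rt = rng.exponential(0.5, 3000)
        out = ig.rt_engagement_separation(rt, labels, engaged_states=np.array([0]),
                                          n_boot=500, seed=3)
        lo, hi = out["ci95"]
        assert lo <= 0.0 <= hi

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(4)
        labels = rng.integers(0, 2, 500)
        rt = rng.exponential(1.0, 500)
        a = ig.rt_engagement_separation(rt, labels, np.array([0]), n_boot=200, seed=9)
        b = ig.rt_engagement_separation(rt, labels, np.array([0]), n_boot=200, seed=9)
        assert a == b
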