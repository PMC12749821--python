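import numpy as np
import pytest

import ioglmhmm as ig
from ioglmhmm.simulate import (
    DEFAULT_CONTRAST_SD, block_switch_hazard, sample_block_length,
)


class TestBlockStructure:
    def test_hazard_solves_truncated_mean(self):
        cfg = ig.TaskConfig()
        h = block_switch_hazard(cfg)
        M = cfg.block_max - cfg.block_min
        mean = cfg.block_min + (1 - (1 - h) ** M) / h
        assert mean == pytest.approx(cfg.block_mean_target, abs=1e-9)

    def test_lengths_within_bounds(self):
        rng = np.random.default_rng(0)
        cfg = ig.TaskConfig()
        lengths = [sample_block_length(rng, cfg) for _ in range(2000)]
        assert min(lengths) >= 20 and max(lengths) <= 100

    def test_infeasible_mean_rejected(self):
        with pytest.raises(ValueError):
            ig.TaskConfig(block_mean_target=150.0)

    def test_unbiased_prefix_then_alternating_blocks(self):
        task = ig.generate_task(ig.TaskConfig(n_sessions=2, trials_per_session=400), seed=5)
        for s in task:
            bp = s.table["block_p_right"].to_numpy()
            assert np.all(bp[:90] == 0.5)
            assert set(np.unique(bp[90:])) <= {0.2, 0.8}
            # alternation: consecutive distinct block values differ
            runs = bp[90:][np.flatnonzero(np.r_[True, np.diff(bp[90:]) != 0])]
            assert np.all(runs[1:] != runs[:-1])

    def test_contrasts_from_declared_set(self):
        task = ig.generate_task(ig.TaskConfig(n_sessions=2, trials_per_session=300), seed=6)
        mags = np.abs(np.concatenate([s.signed_contrast for s in task]))
        assert set(np.unique(mags)) <= set(ig.TaskConfig().contrast_set)


class TestAgent:
    def test_seeded_regeneration_bit_identical(self, feature_config):
        cfg = ig.TaskConfig(n_sessions=2, trials_per_session=80)
        out = []
        for _ in range(2):
            task = ig.generate_task(cfg, seed=9)
            data, truth = ig.simulate_agent(task, ig.default_params(2), feature_config,
                                            seed=10)
            out.append((data, truth))
        (d1, t1), (d2, t2) = out
        for a, b in zip(d1, d2):
            assert a.table.equals(b.table)
        for za, zb in zip(t1.states, t2.states):
            np.testing.assert_array_equal(za, zb)

    def test_huge_stimulus_weight_saturates_accuracy(self, feature_config):
        params = ig.default_params(2)
        params.W_ob = np.array([[60.0, 0, 0, 0], [60.0, 0, 0, 0]])
        task = ig.generate_task(ig.TaskConfig(n_sessions=2, trials_per_session=300), seed=11)
        data, _ = ig.simulate_agent(task, params, feature_config, seed=12)
        df = data.to_frame()
        nonzero = df["signed_contrast"] != 0
        acc = (df.loc[nonzero, "reward"] == 1).mean()
        assert acc > 0.999

    def test_one_hot_pi_fixes_first_state(self, feature_config):
        params = ig.default_params(2)
        params.pi = np.array([0.0, 1.0])
        task = ig.generate_task(ig.TaskConfig(n_sessions=5, trials_per_session=30), seed=13)
        _, truth = ig.simulate_agent(task, params, feature_config, seed=14)
        assert all(z[0] == 1 for z in truth.states)

    def test_static_sticky_chain_dwell_times_are_geometric(self, feature_config):
        """W_tr = 0 with a strongly diagonal B: holding times should match
        the geometric law with mean 1/(1 - A_kk)."""
        params = ig.default_params(2, style="static")
        params.B = np.array([[np.log(9.0), 0.0], [0.0, np.log(9.0)]])  # A_kk = 0.9
        task = ig.generate_task(ig.TaskConfig(n_sessions=30, trials_per_session=400), seed=15)
        _, truth = ig.simulate_agent(task, params, feature_config, seed=16)
        dwells = []
        for z in truth.states:
            changes = np.flatnonzero(np.diff(z) != 0)
            bounds = np.r_[-1, changes, len(z) - 1]
            # interior (completed) dwells only
            dwells.extend(np.diff(bounds)[1:-1])
        dwells = np.asarray(dwells, dtype=float)
        assert dwells.mean() == pytest.approx(10.0, rel=0.1)

    def test_simulated_tables_pass_validation(self, small_sim):
        data, _, _, _ = small_sim
        assert ig.validate_sessions(data) == []


@pytest.fixture(scope="module")
def pair():
    return ig.make_benchmark_pair(
        K=2, task_config=ig.TaskConfig(n_sessions=6, trials_per_session=400), seed=17
    )


class TestBenchmarkPair:
    def test_static_arm_has_zero_filters_and_inputdriven_does_not(self, pair):
        assert np.all(pair["static"][1].params.W_tr == 0.0)
        assert np.any(pair["input-driven"][1].params.W_tr != 0.0)

    def test_reward_filter_drives_disengagement_in_input_driven_data(self, pair):
        """Transitions into the disengaged state should become more likely
        at high filtered reward (the satiety signature built into the
        template)."""
        data, truth = pair["input-driven"]
        f_rew, into_dis = [], []
        for z, X in zip(truth.states, truth.X_tr):
            enter = (z[1:] == 1) & (z[:-1] == 0)
            stay_pool = z[:-1] == 0
            f_rew.append(X[1:, 2][stay_pool])
            into_dis.append(enter[stay_pool])
        f_rew = np.concatenate(f_rew)
        into_dis = np.concatenate(into_dis)
        hi = f_rew > np.median(f_rew)
        assert into_dis[hi].mean() > into_dis[~hi].mean()

    def test_static_arm_transitions_independent_of_reward_history(self, pair):
        data, truth = pair["static"]
        f_rew, moved = [], []
        for z, X in zip(truth.states, truth.X_tr):
            f_rew.append(X[1:, 2])
            moved.append(z[1:] != z[:-1])
        f_rew, moved = np.concatenate(f_rew), np.concatenate(moved)
        terciles = np.quantile(f_rew, [1 / 3, 2 / 3])
        groups = np.digitize(f_rew, terciles)
        from scipy.stats import chi2_contingency

        table = np.array([
            [np.sum(moved & (groups == g)), np.sum(~moved & (groups == g))]
            for g in range(3)
        ])
        _, p, _, _ = chi2_contingency(table)
        assert p > 0.01


def test_default_contrast_sd_is_population_sd_of_contrast_set():
    c = np.array(ig.TaskConfig().contrast_set)
    assert DEFAULT_CONTRAST_SD == pytest.approx(np.sqrt(np.mean(c**2)))


def test_refit_simulate_roundtrip_preserves_summary_statistics(small_sim, small_fit,
                                                               feature_config):
    """Simulating from the fitted model reproduces the original data's
    headline statistics (right-choice rate, accuracy, switch rate)."""
    data, _, _, sd = small_sim
    task = ig.generate_task(ig.TaskConfig(n_sessions=10, trials_per_session=200), seed=77)
    import dataclasses

    cfg = dataclasses.replace(feature_config, contrast_sd=sd)
    resim, _ = ig.simulate_agent(task, small_fit.params, cfg, seed=78)

    def stats(ss):
        df = ss.to_frame()
        return np.array([
            df["choice"].mean(),
            (df["reward"] == 1).mean(),
            np.mean(np.abs(np.diff(df["choice"]))),
        ])
    a, b = stats(data), stats(resim)
    np.testing.assert_allclose(a, b, atol=0.06)
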