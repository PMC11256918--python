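"""Policy network, gradients, learning behaviour, and the design loop."""

import numpy as np
import pytest

from rnadesign.agent import (
    Policy,
    PolicyConfig,
    PolicyUpdater,
    TrainingConfig,
    build_policy,
    design,
    policy_gradient_dlogits,
    random_agent,
    train,
)
from rnadesign.design_space import (
    Task,
    parse_design_space,
    satisfies_folding_relation,
    satisfies_hard_constraints,
)
from rnadesign.environment import EnvConfig
from rnadesign.rewards import make_objective

SMALL = PolicyConfig(
    embedding_size=3,
    conv_layers=((3, 4),),
    lstm_layers=1,
    dense_units=(5,),
    learning_rate=1e-2,
    batch_size=4,
    entropy_weight=1e-2,
)


class TestPolicyNetwork:
    def test_output_is_a_distribution(self, rng):
        policy = build_policy(SMALL, kappa=2, seed=0)
        for _ in range(10):
            window = rng.integers(0, 21, size=5)
            probs = policy.probabilities(window)
            assert probs.shape == (4,)
            assert np.all(probs > 0)
            assert probs.sum() == pytest.approx(1.0, abs=1e-6)

    def test_seeding_reproducible(self):
        a = build_policy(SMALL, kappa=2, seed=7)
        b = build_policy(SMALL, kappa=2, seed=7)
        for k in a.params:
            np.testing.assert_array_equal(a.params[k], b.params[k])

    @pytest.mark.parametrize(
        "cfg",
        [
            SMALL,
            PolicyConfig(embedding_size=4, conv_layers=(), lstm_layers=0,
                         dense_units=(6,)),
            PolicyConfig(embedding_size=3, conv_layers=((2, 3), (3, 4)),
                         lstm_layers=2, dense_units=()),
        ],
        ids=["conv-lstm-dense", "dense-only", "stacked"],
    )
    def test_gradients_match_finite_differences(self, cfg, rng):
        """Manual backprop equals numerical gradients of the loss."""
        policy = build_policy(cfg, kappa=1, seed=3)
        windows = rng.integers(0, 21, size=(6, 3))
        actions = rng.integers(0, 4, size=6)
        advantages = rng.normal(size=6)

        def loss_value():
            probs, _ = policy.forward(windows)
            logp = np.log(probs[np.arange(6), actions])
            entropy = -(probs * np.log(probs)).sum(axis=1)
            return float(
                -(advantages * logp).mean() - 1e-2 * entropy.mean()
            )

        probs, cache = policy.forward(windows)
        dlogits = policy_gradient_dlogits(probs, actions, advantages, 1e-2)
        grads = policy.backward(cache, dlogits)
        eps = 1e-6
        for name in ["emb", "out_W", "out_b"] + [
            k for k in policy.params if "lstm" in k or "conv" in k
        ]:
            flat = policy.params[name].reshape(-1)
            idx = rng.integers(0, flat.size, size=min(4, flat.size))
            for i in idx:
                orig = flat[i]
                flat[i] = orig + eps
                up = loss_value()
                flat[i] = orig - eps
                down = loss_value()
                flat[i] = orig
                numeric = (up - down) / (2 * eps)
                analytic = grads[name].reshape(-1)[i]
                assert analytic == pytest.approx(numeric, abs=1e-5)

    def test_invalid_configuration_rejected(self):
        with pytest.raises(ValueError):
            PolicyConfig(conv_layers=(), lstm_layers=0, dense_units=())
        with pytest.raises(ValueError):
            PolicyConfig(lstm_layers=3)

    def test_checkpoint_round_trip(self, tmp_path):
        policy = build_policy(SMALL, kappa=2, seed=1)
        path = tmp_path / "policy.npz"
        policy.save(path, extra={"seed": 1})
        loaded = Policy.load(path)
        assert loaded.kappa == 2
        for k in policy.params:
            np.testing.assert_array_equal(policy.params[k], loaded.params[k])


class TestLearning:
    def test_two_armed_bandit_concentrates(self):
        """Reward 1 for one action drives its probability above 0.9."""
        cfg = PolicyConfig(
            embedding_size=4, conv_layers=(), lstm_layers=0,
            dense_units=(8,), learning_rate=5e-2, batch_size=8,
            entropy_weight=1e-3,
        )
        policy = build_policy(cfg, kappa=0, seed=0)
        updater = PolicyUpdater(policy)
        rng = np.random.default_rng(0)
        window = [19]  # a lone unconstrained position
        rewarded = 2
        for step in range(1000):
            batch = []
            for _ in range(8):
                a = policy.act(window, rng)
                batch.append(([(window, a)], 1.0 if a == rewarded else 0.0))
            updater.update(batch)
            if policy.probabilities(window)[rewarded] >= 0.9:
                break
        assert policy.probabilities(window)[rewarded] >= 0.9

    def test_training_progress_on_unpaired_target(self, nussinov):
        """Mean reward over the last 100 of 2000 episodes beats the first
        100 on the all-unpaired target (agent learns to avoid pairs)."""
        cfg = PolicyConfig(
            embedding_size=4, conv_layers=(), lstm_layers=0,
            dense_units=(8,), learning_rate=2e-2, batch_size=16,
            entropy_weight=1e-3,
        )
        policy = build_policy(cfg, kappa=1, seed=0)
        env_cfg = EnvConfig(state_radius=1)
        obj = make_objective("structure", env_cfg.reward_cfg, nussinov)
        task = Task("????????", "........")
        policy, log = train(
            policy, [task], env_cfg, nussinov, obj,
            TrainingConfig(episodes=2000, seed=0),
        )
        assert len(log) == 2000
        first = np.mean([e["reward"] for e in log[:100]])
        last = np.mean([e["reward"] for e in log[-100:]])
        assert last > first

    def test_zero_episodes_leaves_policy_unchanged(self, nussinov):
        policy = build_policy(SMALL, kappa=1, seed=5)
        before = policy.state_copy()
        env_cfg = EnvConfig(state_radius=1)
        obj = make_objective("structure", env_cfg.reward_cfg, nussinov)
        policy, log = train(
            policy, [Task("??", "..")], env_cfg, nussinov, obj,
            TrainingConfig(episodes=0, seed=0),
        )
        assert log == []
        for k in before:
            np.testing.assert_array_equal(policy.params[k], before[k])


@pytest.fixture
def design_setup(nussinov):
    cfg = PolicyConfig(
        embedding_size=4, conv_layers=(), lstm_layers=0, dense_units=(8,),
        batch_size=8,
    )
    env_cfg = EnvConfig(state_radius=2)
    obj = make_objective("structure", env_cfg.reward_cfg, nussinov)
    policy = build_policy(cfg, kappa=2, seed=0)
    return policy, env_cfg, obj


class TestDesignLoop:
    def test_candidate_budget_is_exact(self, design_setup, nussinov):
        policy, env_cfg, obj = design_setup
        space = parse_design_space("????????", "((....))")
        results = list(
            design(
                policy, space, obj, nussinov, env_cfg,
                np.random.default_rng(0), num_candidates=7,
            )
        )
        assert len(results) == 7

    def test_stream_reproducible_from_seed(self, design_setup, nussinov):
        policy, env_cfg, obj = design_setup
        space = parse_design_space("?*??GC?*", "?*?????*", 4, 9)

        def stream():
            p = build_policy(policy.cfg, kappa=2, seed=0)
            return [
                (r.candidate.sequence, r.reward, r.solved)
                for r in design(
                    p, space, obj, nussinov, env_cfg,
                    np.random.default_rng(11), num_candidates=12,
                )
            ]

        assert stream() == stream()

    def test_solved_flag_matches_constraint_relations(
        self, design_setup, nussinov
    ):
        policy, env_cfg, obj = design_setup
        space = parse_design_space("????????", "((....))")
        for r in design(
            policy, space, obj, nussinov, env_cfg,
            np.random.default_rng(3), num_candidates=40,
        ):
            expected = satisfies_hard_constraints(
                r.task, r.candidate
            ) and satisfies_folding_relation(r.candidate, r.task, nussinov)
            assert r.solved == expected

    def test_trivial_space_always_solved(self, design_setup, nussinov):
        policy, env_cfg, obj = design_setup
        space = parse_design_space("?", ".")
        results = list(
            design(
                policy, space, obj, nussinov, env_cfg,
                np.random.default_rng(5), num_candidates=400,
                adapt=False, use_lis=False,
            )
        )
        assert all(r.solved for r in results)

    def test_restart_restores_initial_parameters(self, design_setup, nussinov):
        policy, env_cfg, obj = design_setup
        initial = policy.state_copy()
        space = parse_design_space("????????", "((....))")
        list(
            design(
                policy, space, obj, nussinov, env_cfg,
                np.random.default_rng(1), num_candidates=30,
                adapt=True, restart_interval=1e-9,
            )
        )
        for k in initial:
            np.testing.assert_array_equal(policy.params[k], initial[k])


class TestRandomAgent:
    def test_uniform_action_frequencies(self, nussinov):
        env_cfg = EnvConfig(state_radius=0)
        obj = make_objective("structure", env_cfg.reward_cfg, nussinov)
        space = parse_design_space("?", "?")
        counts = np.zeros(4)
        for r in random_agent(
            space, obj, nussinov, env_cfg,
            np.random.default_rng(0), num_candidates=10_000,
        ):
            counts["AGCU".index(r.candidate.sequence)] += 1
        freq = counts / counts.sum()
        sigma = np.sqrt(0.25 * 0.75 / 10_000)
        assert np.all(np.abs(freq - 0.25) < 3 * sigma + 1e-9)

    def test_deterministic_under_fixed_seed(self, nussinov):
        env_cfg = EnvConfig(state_radius=0)
        obj = make_objective("structure", env_cfg.reward_cfg, nussinov)
        space = parse_design_space("??A??", "?????")

        def run():
            return [
                r.candidate.sequence
                for r in random_agent(
                    space, obj, nussinov, env_cfg,
                    np.random.default_rng(9), num_candidates=20,
                )
            ]

        assert run() == run()

    def test_respects_constrained_positions(self, nussinov):
        env_cfg = EnvConfig(state_radius=0)
        obj = make_objective("structure", env_cfg.reward_cfg, nussinov)
        space = parse_design_space("G?C?A", ".....")
        for r in random_agent(
            space, obj, nussinov, env_cfg,
            np.random.default_rng(2), num_candidates=30,
        ):
            s = r.candidate.sequence
            assert s[0] == "G" and s[2] == "C" and s[4] == "A"
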