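"""Objective functions, WL structure distance, and local refinement."""

import itertools
import math

import pytest
from hypothesis import given, settings, strategies as st

from rnadesign.design_space import Candidate, Task
from rnadesign.folding import nussinov_engine
from rnadesign.rewards import (
    RewardConfig,
    combined_reward,
    gc_improvement,
    gc_loss,
    local_improvement,
    make_objective,
    plugin_reward_transform,
    structure_loss,
    structure_reward,
    wl_distance,
)


class TestStructureLoss:
    @pytest.mark.parametrize(
        "omega,folded,expected",
        [
            ("(((...)))", "(((...)))", 0),
            ("((..))", "((()))", 2),
            ("((????))?", "((....)).", 0),
            ("???", "().", 0),
        ],
    )
    def test_examples(self, omega, folded, expected):
        assert structure_loss(omega, folded) == expected

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            structure_loss("..", "...")

    @given(
        pair=st.integers(4, 12).flatmap(
            lambda n: st.tuples(
                st.text(alphabet=".()", min_size=n, max_size=n),
                st.text(alphabet=".()", min_size=n, max_size=n),
            )
        )
    )
    @settings(max_examples=60, deadline=None)
    def test_reduces_to_hamming_distance_without_wildcards(self, pair):
        omega, folded = pair
        hamming = sum(a != b for a, b in zip(omega, folded))
        assert structure_loss(omega, folded) == hamming


class TestRewards:
    @pytest.mark.parametrize(
        "loss,length,alpha,expected",
        [(0, 8, 1.0, 1.0), (8, 8, 3.0, 0.0), (2, 8, 1.0, 0.75)],
    )
    def test_structure_reward_examples(self, loss, length, alpha, expected):
        assert structure_reward(loss, length, alpha) == pytest.approx(expected)

    @pytest.mark.parametrize(
        "seq,desired,eps,expected",
        [
            ("AUGC", 0.5, 0.01, 0.0),
            ("AUGC", 0.54, 0.01, 0.04),
            ("AUGC", 0.505, 0.01, 0.0),  # inside tolerance band
        ],
    )
    def test_gc_loss_examples(self, seq, desired, eps, expected):
        assert gc_loss(seq, desired, eps) == pytest.approx(expected)

    def test_gc_loss_permutation_invariant(self):
        for perm in itertools.permutations("AUGGC"):
            assert gc_loss("".join(perm), 0.7, 0.0) == pytest.approx(
                gc_loss("AUGGC", 0.7, 0.0)
            )

    def test_combined_reward_examples(self):
        cfg = RewardConfig(alpha=1.0, beta=1.0, gamma=1.0)
        assert combined_reward(0, 8, 0.0, cfg) == pytest.approx(1.0)
        # weighted loss above one clips to zero
        assert combined_reward(8, 10, 0.3, cfg) == 0.0
        assert combined_reward(2, 8, 0.1, cfg) == pytest.approx(0.65)

    def test_rewards_monotone_and_bounded(self):
        cfg = RewardConfig(alpha=2.0)
        prev_s, prev_c = 1.1, 1.1
        for loss in range(0, 11):
            s = structure_reward(loss, 10, 2.0)
            c = combined_reward(loss, 10, 0.05, cfg)
            assert 0.0 <= s <= 1.0 and 0.0 <= c <= 1.0
            assert s <= prev_s and c <= prev_c
            prev_s, prev_c = s, c


def _wl_oracle(a: str, b: str, h: int) -> float:
    """Independent WL cosine oracle built on networkx graphs."""
    import networkx as nx

    def graph(structure):
        g = nx.Graph()
        for i, c in enumerate(structure):
            g.add_node(i, label=c)
        g.add_edges_from((i, i + 1) for i in range(len(structure) - 1))
        stack = []
        for i, c in enumerate(structure):
            if c == "(":
                stack.append(i)
            elif c == ")" and stack:
                g.add_edge(stack.pop(), i)
        return g

    def features(g):
        labels = nx.get_node_attributes(g, "label")
        counts = {}
        for _ in range(h + 1):
            for lab in labels.values():
                counts[lab] = counts.get(lab, 0) + 1
            labels = {
                v: labels[v] + "|" + ",".join(sorted(labels[u] for u in g[v]))
                for v in g
            }
        return counts

    fa, fb = features(graph(a)), features(graph(b))
    dot = sum(v * fb.get(k, 0) for k, v in fa.items())
    na = math.sqrt(sum(v * v for v in fa.values()))
    nb = math.sqrt(sum(v * v for v in fb.values()))
    return 1.0 - dot / (na * nb)


class TestWLDistance:
    def test_identity_is_zero(self):
        for s in ["((....))", "...", "(((...)))"]:
            assert wl_distance(s, s, 2) == pytest.approx(0.0)

    def test_disjoint_label_multisets_give_one(self):
        assert wl_distance("...", "(((", 1) == pytest.approx(1.0)

    def test_symmetry(self):
        a, b = "((....))", "((...))."
        assert wl_distance(a, b, 2) == pytest.approx(wl_distance(b, a, 2))

    def test_matches_independent_oracle(self):
        a, b = "((....))", "((...))."
        value = wl_distance(a, b, 2)
        assert 0.0 < value < 1.0
        assert value == pytest.approx(_wl_oracle(a, b, 2))

    @pytest.mark.parametrize(
        "a,b",
        [("(((...)))", "((.....))"), ("(.)", "..."), ("((..))..", "..((..))")],
    )
    def test_oracle_agreement_across_inputs(self, a, b):
        for h in (1, 2, 3):
            assert wl_distance(a, b, h) == pytest.approx(_wl_oracle(a, b, h))


class TestPluginTransforms:
    def test_bitscore_no_match_floor(self):
        assert plugin_reward_transform(None, "bitscore") == -200.0

    def test_bitscore_passthrough(self):
        assert plugin_reward_transform(33.4, "bitscore") == 33.4

    @pytest.mark.parametrize(
        "energy,expected", [(-10.0, 1000.0), (0.0, 0.0), (-2.0, 8.0)]
    )
    def test_rri_energy_cubic(self, energy, expected):
        assert plugin_reward_transform(energy, "rri_energy") == pytest.approx(
            expected
        )

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError):
            plugin_reward_transform(1.0, "zscore")


class TestLocalImprovement:
    def test_zero_loss_input_unchanged(self, nussinov):
        task = Task("????", "????")
        cand = Candidate("ACGU", folded_structure=nussinov.fold("ACGU"))
        assert local_improvement(cand, task, nussinov).sequence == "ACGU"

    def test_gate_leaves_distant_candidates_unchanged(self, nussinov):
        task = Task("?????????", "(((...)))")
        cand = Candidate("AAAAAAAAA", folded_structure=".........")
        out = local_improvement(cand, task, nussinov, max_mismatches=5)
        assert out.sequence == cand.sequence

    def test_exhaustive_repair_finds_zero_loss(self, nussinov):
        # GGGAA AACCC folds to (((....))); breaking one closing position
        # leaves a single free position that enumeration must repair
        task = Task("GGGAAAACC?", "(((....)))")
        cand = Candidate("GGGAAAACCA")
        folded = nussinov.fold(cand.sequence)
        from rnadesign.rewards import structure_loss as sl

        assert sl(task.structure_constraints, folded) > 0
        out = local_improvement(cand, task, nussinov)
        assert (
            sl(task.structure_constraints, nussinov.fold(out.sequence)) == 0
        )
        # constrained prefix untouched
        assert out.sequence[:9] == "GGGAAAACC"

    def test_never_violates_sequence_constraints(self, nussinov, rng):
        task = Task("G???C??U", "((...).)")
        for _ in range(10):
            seq = "G" + "".join(
                "ACGU"[i] for i in rng.integers(0, 4, size=3)
            ) + "C" + "".join("ACGU"[i] for i in rng.integers(0, 4, size=2)) + "U"
            cand = Candidate(seq, folded_structure=nussinov.fold(seq))
            out = local_improvement(cand, task, nussinov)
            for i, c in enumerate(task.sequence_constraints):
                if c != "?":
                    assert out.sequence[i] == c


class TestGcImprovement:
    def test_within_tolerance_unchanged(self, nussinov):
        cfg = RewardConfig(gc_desired=0.5, gc_tolerance=0.01)
        task = Task("????", "????")
        cand = Candidate("AUGC", folded_structure="....")
        assert gc_improvement(cand, task, cfg, nussinov).sequence == "AUGC"

    def test_raises_gc_at_free_positions(self, nussinov):
        cfg = RewardConfig(gc_desired=1.0, gc_tolerance=0.01)
        task = Task("????", "????")
        cand = Candidate("AAAA", folded_structure="....")
        out = gc_improvement(cand, task, cfg, nussinov)
        assert set(out.sequence) <= set("GC")

    def test_no_free_positions_unchanged(self, nussinov):
        cfg = RewardConfig(gc_desired=1.0, gc_tolerance=0.01)
        task = Task("AUAU", "????")
        cand = Candidate("AUAU", folded_structure="....")
        assert gc_improvement(cand, task, cfg, nussinov).sequence == "AUAU"

    def test_moves_gc_toward_target_without_touching_constraints(
        self, nussinov
    ):
        cfg = RewardConfig(gc_desired=0.25, gc_tolerance=0.01)
        task = Task("G???C???", "????????")
        cand = Candidate("GGGGCGGG", folded_structure="........")
        out = gc_improvement(cand, task, cfg, nussinov)
        assert out.sequence[0] == "G" and out.sequence[4] == "C"
        assert abs(out.gc_content - 0.25) <= 0.01


class TestObjectives:
    def test_structure_objective_matches_reward_formula(self, nussinov):
        cfg = RewardConfig(alpha=2.0)
        obj = make_objective("structure", cfg, nussinov)
        task = Task("????", "....")
        cand = Candidate("GGGG", folded_structure="....")
        assert obj.reward(cand, task) == pytest.approx(1.0)
        assert obj.solved(cand, task)

    def test_structure_gc_objective_requires_target(self, nussinov):
        with pytest.raises(ValueError):
            make_objective("structure+gc", RewardConfig(), nussinov)

    def test_unknown_objective_rejected(self, nussinov):
        with pytest.raises(ValueError):
            make_objective("bitscore", RewardConfig(), nussinov)
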