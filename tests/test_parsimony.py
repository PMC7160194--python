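import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from karyotrace.parsimony import (FORBIDDEN, MISSING, CharacterMatrix,
                                  CostModel, ParsimonyError,
                                  enumerate_assignments_oracle,
                                  fitch_reconstruct, min_transition_count,
                                  sankoff_reconstruct)
from karyotrace.tree_io import parse_newick

from conftest import random_tree


def chars(mapping, states=None, name="c"):
    return CharacterMatrix.from_values(name, mapping, states=states)


def classic_fitch_length(tree, assignments):
    """Independent oracle: the textbook Fitch set-operation count of the
    parsimony length on a (possibly multifurcating) tree, generalized to
    polytomies by greedy majority-state intersection."""
    def down(node):
        if node.is_leaf():
            obs = assignments[node.taxon.label]
            return (set(obs) if obs is not MISSING else None), 0
        sets, cost = [], 0
        for child in node.child_nodes():
            s, c = down(child)
            cost += c
            if s is not None:
                sets.append(s)
        if not sets:
            return None, cost
        # state(s) present in the largest number of child sets; each child
        # set not containing them contributes one change
        counts = {}
        for s in sets:
            for state in s:
                counts[state] = counts.get(state, 0) + 1
        best = max(counts.values())
        keep = {state for state, n in counts.items() if n == best}
        return keep, cost + (len(sets) - best)
    return down(tree.root)[1]


class TestCharacterMatrix:
    def test_states_outside_domain_rejected(self):
        with pytest.raises(ParsimonyError):
            CharacterMatrix("c", ("0", "1"), {"A": frozenset({"2"})})

    def test_empty_state_set_rejected(self):
        with pytest.raises(ParsimonyError):
            CharacterMatrix("c", ("0", "1"), {"A": frozenset()})

    def test_from_tsv_parses_sets_and_missing(self):
        cm = CharacterMatrix.from_tsv("A\t26\nB\t26|28\nC\t?\n")
        assert cm.assignments["A"] == frozenset({"26"})
        assert cm.assignments["B"] == frozenset({"26", "28"})
        assert cm.assignments["C"] is MISSING
        assert cm.states == ("26", "28")


class TestCostModel:
    def test_nonzero_diagonal_rejected(self):
        with pytest.raises(ParsimonyError):
            CostModel(("0", "1"), np.array([[1.0, 1.0], [1.0, 0.0]]))

    def test_negative_cost_rejected(self):
        with pytest.raises(ParsimonyError):
            CostModel(("0", "1"), np.array([[0.0, -1.0], [1.0, 0.0]]))

    def test_json_round_trip_keeps_forbidden(self):
        model = CostModel.irreversible("0", "1")
        again = CostModel.from_json(model.to_json())
        assert again.states == model.states
        assert math.isinf(again.cost[1, 0])
        assert again.root_constraint == "0"


class TestFitch:
    def test_constant_character_costs_nothing(self):
        t = parse_newick("((A,B),(C,D));")
        r = fitch_reconstruct(t, chars({x: "0" for x in "ABCD"},
                                       states=("0", "1")))
        assert r.min_cost == 0
        assert all(m == frozenset({"0"}) for m in r.node_mpr.values())

    def test_single_cut_tree(self):
        t = parse_newick("((A,B),(C,D));")
        r = fitch_reconstruct(t, chars({"A": 0, "B": 0, "C": 1, "D": 1}))
        assert r.min_cost == 1
        assert r.node_mpr[("A", "B")] == frozenset({"0"})
        assert r.node_mpr[("C", "D")] == frozenset({"1"})
        assert r.node_mpr[("A", "B", "C", "D")] == frozenset({"0", "1"})

    def test_single_cut_change_falls_on_either_root_branch(self):
        # every MPR places the single change on one of the two root
        # branches, so no individual branch carries an obligate change
        t = parse_newick("((A,B),(C,D));")
        r = fitch_reconstruct(t, chars({"A": 0, "B": 0, "C": 1, "D": 1}))
        oracle = enumerate_assignments_oracle(
            t, chars({"A": 0, "B": 0, "C": 1, "D": 1}),
            CostModel.unit(("0", "1")))
        assert len(oracle.assignments) == 2
        assert (min_transition_count(r, "0", "1")
                + min_transition_count(r, "1", "0") == 0)
        assert sum(1 for pairs in r.branch_transitions.values()
                   if ("0", "1") in pairs or ("1", "0") in pairs) == 2

    def test_polytomy_counts_one_change_per_minority_state(self):
        t = parse_newick("(A,B,C,D,E);")
        r = fitch_reconstruct(t, chars({"A": 0, "B": 0, "C": 0,
                                        "D": 1, "E": 2}))
        assert r.min_cost == 2
        assert r.node_mpr[("A", "B", "C", "D", "E")] == frozenset({"0"})

    def test_missing_tip_contributes_nothing(self):
        t = parse_newick("((A,B),(C,D));")
        r = fitch_reconstruct(t, chars({"A": 0, "B": MISSING,
                                        "C": 1, "D": 1}))
        assert r.min_cost == 1

    def test_tip_absent_from_matrix_is_an_error(self):
        t = parse_newick("((A,B),C);")
        with pytest.raises(ParsimonyError, match="absent"):
            fitch_reconstruct(t, chars({"A": 0, "B": 1}))

    def test_all_missing_is_an_error(self):
        t = parse_newick("(A,B);")
        with pytest.raises(ParsimonyError, match="missing"):
            fitch_reconstruct(t, chars({"A": MISSING, "B": MISSING},
                                       states=("0", "1")))


class TestSankoff:
    def test_two_tip_gain(self):
        t = parse_newick("(A,B);")
        r = sankoff_reconstruct(t, chars({"A": 0, "B": 1}),
                                CostModel.irreversible("0", "1"))
        assert r.min_cost == 1
        assert r.node_mpr[("A", "B")] == frozenset({"0"})
        assert r.branch_transitions[("B",)] == {("0", "1"): "obligate"}

    def test_infeasible_reports_not_raises(self):
        # losses-only with an XX0 root can never produce a derived tip
        t = parse_newick("(A,B);")
        model = CostModel(("0", "1"),
                          np.array([[0.0, FORBIDDEN], [1.0, 0.0]]),
                          root_constraint="0")
        r = sankoff_reconstruct(t, chars({"A": 0, "B": 1}), model)
        assert not r.is_feasible
        oracle = enumerate_assignments_oracle(t, chars({"A": 0, "B": 1}),
                                              model)
        assert not math.isfinite(oracle.min_cost)

    def test_directional_cost_counts_origins(self):
        t = parse_newick("(((A,B),C),(D,E));")
        r = sankoff_reconstruct(
            t, chars({"A": 1, "B": 1, "C": 0, "D": 1, "E": 0}),
            CostModel.irreversible("0", "1"))
        assert r.min_cost == 2
        assert min_transition_count(r, "0", "1") == 2

    def test_character_states_must_be_in_model(self):
        t = parse_newick("(A,B);")
        with pytest.raises(ParsimonyError):
            sankoff_reconstruct(t, chars({"A": "x", "B": "y"}),
                                CostModel.unit(("0", "1")))

    def test_min_transition_count_rejects_unknown_state(self):
        t = parse_newick("(A,B);")
        r = fitch_reconstruct(t, chars({"A": 0, "B": 1}))
        with pytest.raises(ParsimonyError):
            min_transition_count(r, "0", "7")


class TestOracle:
    def test_guard_refuses_large_instances(self):
        rng = np.random.default_rng(0)
        t = random_tree(rng, 30)
        with pytest.raises(ParsimonyError, match="guard"):
            enumerate_assignments_oracle(
                t, chars({f"t{i}": i % 2 for i in range(1, 31)}),
                CostModel.unit(("0", "1")), guard=100)

    def test_single_cut_assignments_enumerated_exactly(self):
        t = parse_newick("((A,B),(C,D));")
        oracle = enumerate_assignments_oracle(
            t, chars({"A": 0, "B": 0, "C": 1, "D": 1}),
            CostModel.unit(("0", "1")))
        assert oracle.min_cost == 1
        roots = {a[("A", "B", "C", "D")] for a in oracle.assignments}
        assert roots == {"0", "1"}


def random_instance(rng, n_states):
    n_tips = int(rng.integers(4, 9)) if n_states == 2 else int(rng.integers(4, 7))
    tree = random_tree(rng, n_tips, allow_polytomy=True)
    states = tuple(str(i) for i in range(n_states))
    values = {}
    for label in tree.tip_labels:
        if rng.random() < 0.15:
            values[label] = MISSING
        else:
            values[label] = str(int(rng.integers(n_states)))
    cm = chars(values, states=states)
    if all(v is MISSING for v in values.values()):
        values[tree.tip_labels[0]] = "0"
        cm = chars(values, states=states)
    return tree, cm, states


class TestEngineProperties:
    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 2 ** 31 - 1), n_states=st.sampled_from([2, 3]))
    def test_dp_matches_oracle_and_classic_fitch(self, seed, n_states):
        rng = np.random.default_rng(seed)
        tree, cm, states = random_instance(rng, n_states)
        model = CostModel.unit(states)
        dp = sankoff_reconstruct(tree, cm, model)
        fitch = fitch_reconstruct(tree, cm)
        oracle = enumerate_assignments_oracle(tree, cm, model)
        assert dp.min_cost == pytest.approx(oracle.min_cost)
        assert fitch.min_cost == pytest.approx(oracle.min_cost)
        assert dp.node_mpr == oracle.node_mpr
        assert fitch.node_mpr == dp.node_mpr
        assert dp.min_cost == classic_fitch_length(tree, cm.assignments)

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 2 ** 31 - 1))
    def test_directional_dp_matches_oracle(self, seed):
        rng = np.random.default_rng(seed)
        tree, cm, states = random_instance(rng, 2)
        model = CostModel.irreversible("0", "1")
        dp = sankoff_reconstruct(tree, cm, model)
        oracle = enumerate_assignments_oracle(tree, cm, model)
        assert dp.min_cost == pytest.approx(oracle.min_cost) \
            or (not dp.is_feasible and not math.isfinite(oracle.min_cost))
        if dp.is_feasible:
            assert dp.node_mpr == oracle.node_mpr

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 2 ** 31 - 1))
    def test_constraints_never_decrease_cost(self, seed):
        rng = np.random.default_rng(seed)
        tree, cm, states = random_instance(rng, 2)
        free = sankoff_reconstruct(tree, cm, CostModel.unit(states))
        for root_state in states:
            pinned = sankoff_reconstruct(
                tree, cm, CostModel.unit(states, root_constraint=root_state))
            assert pinned.min_cost >= free.min_cost - 1e-9
        forbidden_cost = np.array([[0.0, 1.0], [FORBIDDEN, 0.0]])
        harder = sankoff_reconstruct(
            tree, cm, CostModel(states, forbidden_cost))
        assert (not harder.is_feasible
                or harder.min_cost >= free.min_cost - 1e-9)

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 2 ** 31 - 1))
    def test_blanking_one_tip_never_increases_cost(self, seed):
        rng = np.random.default_rng(seed)
        tree, cm, states = random_instance(rng, 2)
        base = fitch_reconstruct(tree, cm)
        observed = [t for t, v in cm.assignments.items() if v is not MISSING]
        if len(observed) < 2:
            return
        victim = observed[int(rng.integers(len(observed)))]
        blanked = dict(cm.assignments)
        blanked[victim] = MISSING
        relaxed = fitch_reconstruct(
            tree, CharacterMatrix(cm.character_name, states, blanked))
        assert relaxed.min_cost <= base.min_cost + 1e-9

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 2 ** 31 - 1))
    def test_obligate_transition_cost_bounded_by_min_cost(self, seed):
        rng = np.random.default_rng(seed)
        tree, cm, states = random_instance(rng, 3)
        r = fitch_reconstruct(tree, cm)
        obligate_cost = sum(1 for _, a, b in r.obligate_transitions())
        assert obligate_cost <= r.min_cost + 1e-9
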