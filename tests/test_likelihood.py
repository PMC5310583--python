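import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import corrtrait as ct
from corrtrait.likelihood import (
    PruningEngine,
    RootTreatment,
    pruning_loglik,
    stationary_distribution,
    transition_probabilities,
)
from conftest import random_dependent_q, random_small_tree
from oracles import enum_loglik


def test_transition_probabilities_identity_at_zero(rng):
    Q = random_dependent_q(rng)
    assert np.allclose(transition_probabilities(Q, 0.0), np.eye(4), atol=1e-12)


def test_symmetric_two_state_closed_form(rng):
    # symmetric binary chain: P(stay) = (1 + exp(-2 q t)) / 2
    for _ in range(5):
        q = float(10 ** rng.uniform(-2, 1))
        t = float(rng.uniform(0, 5))
        Q = ct.build_q(ct.mk2_model(), [q, q])
        P = transition_probabilities(Q, t)
        stay = 0.5 * (1 + np.exp(-2 * q * t))
        assert P[0, 0] == pytest.approx(stay, abs=1e-10)
        assert P[1, 1] == pytest.approx(stay, abs=1e-10)


def test_long_time_limit_is_stationary(rng):
    Q = random_dependent_q(rng)
    P = transition_probabilities(Q, 500.0)
    pi = stationary_distribution(Q)
    for row in P:
        assert np.allclose(row, pi, atol=1e-6)


def test_negative_branch_length_rejected(rng):
    with pytest.raises(ValueError):
        transition_probabilities(random_dependent_q(rng), -0.1)


def test_pruning_matches_enumeration_on_small_trees(rng):
    for _ in range(30):
        tree = random_small_tree(rng)
        Q = random_dependent_q(rng)
        states = {
            l.taxon.label: int(rng.integers(4)) for l in tree.leaf_node_iter()
        }
        assert pruning_loglik(tree, states, Q) == pytest.approx(
            enum_loglik(tree, states, Q), abs=1e-8
        )


def test_zero_branch_tree_reduces_to_root_prior():
    tree = ct.parse_newick("((A:0,B:0):0,(C:0,D:0):0);")
    Q = ct.build_q(ct.dependent_model(), np.full(8, 0.7))
    for k in range(4):
        states = dict.fromkeys("ABCD", k)
        assert pruning_loglik(tree, states, Q) == pytest.approx(np.log(0.25), abs=1e-12)


def test_rate_time_confounding(rng):
    tree = ct.simulate_tree(10, 1.0, 3)
    Q = random_dependent_q(rng)
    states = {l.taxon.label: int(rng.integers(4)) for l in tree.leaf_node_iter()}
    c = 3.7
    scaled = tree.clone(depth=1)
    for e in scaled.preorder_edge_iter():
        if e.length is not None:
            e.length = e.length / c
    assert pruning_loglik(tree, states, Q) == pytest.approx(
        pruning_loglik(scaled, states, Q * c), abs=1e-9
    )


def test_independent_model_factorises(rng):
    """Paired 4-state LL under independence = sum of the two Mk2 LLs."""
    for _ in range(20):
        tree = random_small_tree(rng, 4, 8)
        a01, a10, b01, b10 = 10.0 ** rng.uniform(-1, 0.5, 4)
        Qi = ct.build_q(ct.independent_model(), [a01, a10, b01, b10])
        Qa = ct.build_q(ct.mk2_model(), [a01, a10])
        Qb = ct.build_q(ct.mk2_model(), [b01, b10])
        s1 = {l.taxon.label: int(rng.integers(2)) for l in tree.leaf_node_iter()}
        s2 = {l.taxon.label: int(rng.integers(2)) for l in tree.leaf_node_iter()}
        pair = {k: ct.encode_pair(s1[k], s2[k]) for k in s1}
        assert pruning_loglik(tree, pair, Qi) == pytest.approx(
            pruning_loglik(tree, s1, Qa) + pruning_loglik(tree, s2, Qb), abs=1e-8
        )


def test_dependent_nests_independent(rng):
    """Dependent model at independence-satisfying rates = independent model."""
    tree = ct.simulate_tree(12, 1.0, 9)
    a01, a10, b01, b10 = 0.3, 0.6, 0.2, 0.4
    dep_rates = {
        "q02": a01, "q13": a01, "q20": a10, "q31": a10,
        "q01": b01, "q23": b01, "q10": b10, "q32": b10,
    }
    Qd = ct.build_q(ct.dependent_model(), dep_rates)
    Qi = ct.build_q(ct.independent_model(), [a01, a10, b01, b10])
    states = {l.taxon.label: int(rng.integers(4)) for l in tree.leaf_node_iter()}
    assert pruning_loglik(tree, states, Qd) == pytest.approx(
        pruning_loglik(tree, states, Qi), abs=1e-10
    )


def test_invariance_to_child_order_and_relabeling(rng):
    Q = random_dependent_q(rng)
    t1 = ct.parse_newick("((A:1,B:2):0.5,(C:0.3,D:1.1):0.9);")
    t2 = ct.parse_newick("((D:1.1,C:0.3):0.9,(B:2,A:1):0.5);")  # children swapped
    states = {"A": 0, "B": 3, "C": 1, "D": 2}
    assert pruning_loglik(t1, states, Q) == pytest.approx(
        pruning_loglik(t2, states, Q), abs=1e-10
    )
    # consistent relabeling of tips leaves the likelihood unchanged
    t3 = ct.parse_newick("((W:1,X:2):0.5,(Y:0.3,Z:1.1):0.9);")
    relabeled = {"W": 0, "X": 3, "Y": 1, "Z": 2}
    assert pruning_loglik(t1, states, Q) == pytest.approx(
        pruning_loglik(t3, relabeled, Q), abs=1e-10
    )


@settings(max_examples=25, deadline=None, derandomize=True)
@given(st.integers(0, 10_000), st.integers(3, 5))
def test_pruning_enumeration_property(seed, n_tips):
    rng = np.random.default_rng(seed)
    tree = ct.simulate_tree(n_tips, 1.0, seed)
    Q = random_dependent_q(rng)
    states = {l.taxon.label: int(rng.integers(4)) for l in tree.leaf_node_iter()}
    assert pruning_loglik(tree, states, Q) == pytest.approx(
        enum_loglik(tree, states, Q), abs=1e-8
    )


def test_root_treatments(rng):
    tree = ct.simulate_tree(6, 1.0, 4)
    Q = random_dependent_q(rng)
    states = {l.taxon.label: int(rng.integers(4)) for l in tree.leaf_node_iter()}
    lls = {
        mode: pruning_loglik(tree, states, Q, RootTreatment(mode))
        for mode in ("uniform", "stationary", "fitzjohn")
    }
    for ll in lls.values():
        assert np.isfinite(ll)
    ll_fixed = [
        pruning_loglik(tree, states, Q, RootTreatment("fixed", state=s))
        for s in range(4)
    ]
    # uniform root is the average of the fixed-root likelihoods
    assert np.log(np.mean(np.exp(ll_fixed))) == pytest.approx(lls["uniform"], abs=1e-8)
    with pytest.raises(ValueError):
        RootTreatment("fixed")
    with pytest.raises(ValueError):
        RootTreatment("banana")


def test_engine_rejects_mismatched_inputs(balanced_quartet):
    eng = PruningEngine(balanced_quartet, 4)
    with pytest.raises(ValueError, match="no state"):
        eng.loglik(np.eye(4) - np.eye(4), {"A": 0, "B": 1, "C": 2})
    with pytest.raises(ValueError, match="state space"):
        eng.states_array({"A": 0, "B": 1, "C": 2, "D": 7})
    with pytest.raises(ValueError, match="not on the tree"):
        pruning_loglik(
            balanced_quartet, {"A": 0, "B": 1, "C": 2, "D": 3, "E": 0},
            ct.build_q(ct.dependent_model(), np.ones(8)),
        )
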