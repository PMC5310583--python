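import numpy as np
import pytest

import corrtrait as ct
from corrtrait.simulate import (
    SimulationConfig,
    make_study_like_dataset,
    perturb_nni,
    simulate_tree,
    simulate_traits,
)
from corrtrait.treeio import check_ultrametric, tip_labels
from oracles import pattern_probabilities


def test_yule_tree_shape_and_determinism():
    t1 = simulate_tree(100, 1.0, 42)
    t2 = simulate_tree(100, 1.0, 42)
    assert t1.as_string("newick") == t2.as_string("newick")
    assert len(tip_labels(t1)) == 100
    ok, _ = check_ultrametric(t1, 1e-9)
    assert ok
    cherry = simulate_tree(2, 1.0, 1)
    assert len(tip_labels(cherry)) == 2
    ok, _ = check_ultrametric(cherry, 1e-9)
    assert ok
    with pytest.raises(ValueError):
        simulate_tree(1, 1.0, 1)


def test_yule_root_height_matches_closed_form():
    """Mean root height of a Yule tree is sum_{k=2..n} 1/(lambda k)."""
    lam, n, reps = 2.0, 20, 300
    expected = sum(1.0 / (lam * k) for k in range(2, n + 1))
    var = sum(1.0 / (lam * k) ** 2 for k in range(2, n + 1))
    heights = []
    for r in range(reps):
        tree = simulate_tree(n, lam, 10_000 + r)
        leaf = next(tree.leaf_node_iter())
        d, node = 0.0, leaf
        while node.parent_node is not None:
            d += node.edge.length
            node = node.parent_node
        heights.append(d)
    se = np.sqrt(var / reps)
    assert abs(np.mean(heights) - expected) < 4 * se


def test_traits_frozen_when_rates_vanish():
    tree = simulate_tree(10, 1.0, 3)
    Q = ct.build_q(ct.dependent_model(), np.full(8, 1e-300))
    ds = simulate_traits(tree, Q, 2, 4)
    assert ds.events == []
    assert all(s == 2 for s in ds.tip_states.values())


def test_event_log_replay_and_no_dual_transitions():
    tree = simulate_tree(80, 1.0, 5)
    Q = ct.build_q(ct.dependent_model(), ct.simulate.DEFAULT_TRUE_RATES)
    ds = simulate_traits(tree, Q, 0, 6)
    assert len(ds.events) > 0
    forbidden = {(0, 3), (3, 0), (1, 2), (2, 1)}
    for ev in ds.events:
        assert (ev.from_state, ev.to_state) not in forbidden
    assert ds.replay_tip_states() == ds.tip_states
    # visible counts never exceed event counts in total
    assert sum(ds.visible_transition_counts().values()) <= len(ds.events)


def test_simulator_matches_likelihood_pattern_probabilities():
    """Empirical tip-pattern frequencies agree with exp(Qt) probabilities.

    Small version of the master cross-validation (the acceptance suite runs
    it at 20k replicates): 3000 histories on a fixed 3-tip tree, every
    4-state pattern within 4 Monte-Carlo standard errors.
    """
    tree = ct.parse_newick("((A:0.6,B:1.1):0.5,C:1.6);")
    Q = ct.build_q(ct.dependent_model(), [0.4, 0.7, 0.3, 0.5, 0.9, 0.2, 0.4, 0.6])
    pi = np.zeros(4)
    pi[0] = 1.0  # root fixed at state 0
    expected = pattern_probabilities(tree, Q, pi)
    n = 3000
    counts = {}
    for r in range(n):
        ds = simulate_traits(tree, Q, 0, 50_000 + r)
        pat = tuple(ds.tip_states[l] for l in sorted(ds.tip_states))
        counts[pat] = counts.get(pat, 0) + 1
    assert abs(sum(expected.values()) - 1.0) < 1e-9
    for pat, p in expected.items():
        obs = counts.get(pat, 0) / n
        se = np.sqrt(p * (1 - p) / n)
        assert abs(obs - p) <= 4 * se + 1e-12, (pat, obs, p)


def test_study_like_dataset_roundtrip(tmp_path):
    cfg = SimulationConfig(n_tips=60, seed=9)
    ds = make_study_like_dataset(cfg, tmp_path)
    table = ct.load_trait_table(tmp_path / "traits.csv", cfg.codebook)
    tree = ct.read_tree(tmp_path / "tree.nwk")
    assert len(tip_labels(tree)) == 60
    counts = table.counts()
    # per-trait dropout yields unequal per-analysis sample sizes
    assert counts.loc["nest", "missing"] >= 0
    paired, pruned, report = ct.pair_and_align(table, "iris", "nest", tree)
    assert report.n_used == 60 - len(report.dropped_missing)
    assert set(paired.states) == tip_labels(pruned)
    # same seed, same dataset
    ds2 = make_study_like_dataset(SimulationConfig(n_tips=60, seed=9))
    assert ds2.tip_states == ds.tip_states
    assert ds2.trait_table.equals(ds.trait_table)


def test_simulation_config_validation():
    with pytest.raises(ValueError):
        SimulationConfig(n_tips=3)
    with pytest.raises(ValueError):
        SimulationConfig(missing_fraction={"iris": 1.0})
    with pytest.raises(ValueError):
        SimulationConfig(true_rates={"q01": -1.0})


def test_nni_perturbation_preserves_taxa():
    base = simulate_tree(30, 1.0, 77)
    moved = perturb_nni(base, n_moves=4, seed=1)
    assert tip_labels(moved) == tip_labels(base)
    ct.treeio.validate_tree(moved)
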