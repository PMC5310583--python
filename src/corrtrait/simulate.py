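"""Synthetic trees and trait histories with ground-truth event logs.

This module generates data with the statistical structure the analysis
assumes — an ultrametric pure-birth (Yule) tree and two binary traits
evolving jointly under a 4-state Markov chain in which only one trait
changes at a time — so every downstream stage (alignment, likelihood,
model comparison, ancestral reconstruction, transition counting) can be
validated against known truth without any external database.

Trait histories are simulated by the Gillespie algorithm along each branch
(exponential waiting times between competing transitions), and every change
is recorded in an event log, giving exact true transition counts and an
exact replay check.  All randomness flows through a single seeded
:class:`numpy.random.Generator`, so datasets are reproducible across
platforms.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd

from . import treeio
from .models import (
    RateModel,
    build_q,
    decode_pair,
    dependent_model,
)

__all__ = [
    "SimulationConfig",
    "SimulatedDataset",
    "Event",
    "simulate_tree",
    "simulate_traits",
    "make_study_like_dataset",
    "perturb_nni",
    "DEFAULT_CODEBOOK",
    "DEFAULT_TRUE_RATES",
]

DEFAULT_CODEBOOK = {
    "iris": {"dark": 0, "bright": 1},
    "nest": {"non-cavity": 0, "cavity": 1},
}

# Dependent-model truth emulating the inferred rate structure: a strongly
# elevated bright->dark iris rate in non-cavity nesters (q20), nest-loss
# rates equal across iris states (q10 = q32).  Baseline 0.15 changes per
# unit time puts roughly one expected change per trait on a root-to-tip
# path of a unit-birth-rate Yule tree with ~1500 tips (height ~ ln n).
DEFAULT_TRUE_RATES = {
    "q01": 0.15,  # nest gain, dark iris
    "q02": 0.15,  # iris brightening, non-cavity
    "q10": 0.15,  # nest loss, dark iris
    "q13": 0.15,  # iris brightening, cavity
    "q20": 1.50,  # iris darkening, non-cavity  (elevated: selection away
    #               from bright eyes in open nesters)
    "q23": 0.15,  # nest gain, bright iris
    "q31": 0.15,  # iris darkening, cavity
    "q32": 0.15,  # nest loss, bright iris
}


def simulate_tree(n_tips: int, birth_rate: float = 1.0, seed: int | None = None) -> dendropy.Tree:
    """Ultrametric Yule (pure-birth) tree with tips labelled t1..tn.

    Lineages split at rate ``birth_rate`` each; the process starts from the
    root's two daughters and stops one exponential interval after reaching
    ``n_tips`` lineages, so terminal branches have positive length and the
    root height is a sum of Exp(k*birth_rate) intervals for k = 2..n.
    """
    if n_tips < 2:
        raise ValueError("need at least 2 tips")
    if birth_rate <= 0:
        raise ValueError("birth rate must be positive")
    rng = np.random.default_rng(seed)

    tree = dendropy.Tree()
    tree.is_rooted = True
    root = tree.seed_node
    c1, c2 = dendropy.Node(), dendropy.Node()
    root.add_child(c1)
    root.add_child(c2)
    birth = {id(c1): 0.0, id(c2): 0.0}
    active = [c1, c2]
    t = 0.0
    k = 2
    while True:
        t += rng.exponential(1.0 / (birth_rate * k))
        if k == n_tips:
            break
        i = int(rng.integers(k))
        node = active.pop(i)
        node.edge.length = t - birth.pop(id(node))
        a, b = dendropy.Node(), dendropy.Node()
        node.add_child(a)
        node.add_child(b)
        birth[id(a)] = birth[id(b)] = t
        active.extend([a, b])
        k += 1
    for node in active:
        node.edge.length = t - birth[id(node)]

    for i, leaf in enumerate(tree.leaf_node_iter(), start=1):
        leaf.taxon = tree.taxon_namespace.new_taxon(label=f"t{i}")
    return tree


@dataclass
class Event:
    """One state change on the tree: on the edge above ``node_index``."""

    node_index: int  # postorder index of the edge's child node
    time: float  # time along the edge, measured from the parent end
    from_state: int
    to_state: int


@dataclass
class SimulatedDataset:
    tree: dendropy.Tree
    tip_states: dict[str, int]  # label -> combined (or binary) state
    node_states: dict[int, int]  # postorder node index -> state
    events: list[Event]
    Q: np.ndarray
    model: RateModel
    true_rates: dict[str, float]
    root_state: int
    seed: int | None = None
    trait_table: pd.DataFrame | None = None  # decoded, possibly with missing

    def true_transition_counts(self) -> dict[tuple[int, int], int]:
        counts: dict[tuple[int, int], int] = {}
        for ev in self.events:
            key = (ev.from_state, ev.to_state)
            counts[key] = counts.get(key, 0) + 1
        return counts

    def visible_transition_counts(self) -> dict[tuple[int, int], int]:
        """Edges whose true endpoint states differ, per (parent, child) pair.

        This is the node-level footprint of the history: same-edge
        reversals (A->B->A within one branch) cancel and are invisible to
        any node-state assignment, so reconstruction-based counts estimate
        this quantity rather than the raw event count.
        """
        nodes = list(self.tree.postorder_node_iter())
        index = {id(nd): i for i, nd in enumerate(nodes)}
        counts: dict[tuple[int, int], int] = {}
        for nd in nodes:
            if nd.parent_node is None:
                continue
            a = self.node_states[index[id(nd.parent_node)]]
            b = self.node_states[index[id(nd)]]
            if a != b:
                counts[(a, b)] = counts.get((a, b), 0) + 1
        return counts

    def replay_tip_states(self) -> dict[str, int]:
        """Recompute tip states by replaying the event log from the root."""
        nodes = list(self.tree.postorder_node_iter())
        index = {id(nd): i for i, nd in enumerate(nodes)}
        by_edge: dict[int, list[Event]] = {}
        for ev in self.events:
            by_edge.setdefault(ev.node_index, []).append(ev)
        state = {index[id(self.tree.seed_node)]: self.root_state}
        out = {}
        for nd in self.tree.preorder_node_iter():
            i = index[id(nd)]
            if nd.parent_node is not None:
                s = state[index[id(nd.parent_node)]]
                for ev in sorted(by_edge.get(i, []), key=lambda e: e.time):
                    assert ev.from_state == s, "event log inconsistent"
                    s = ev.to_state
                state[i] = s
            if nd.is_leaf():
                out[nd.taxon.label] = state[i]
        return out


def _draw_root_state(root_state, k, rng) -> int:
    if isinstance(root_state, (int, np.integer)):
        if not 0 <= root_state < k:
            raise ValueError(f"root state {root_state} outside 0..{k - 1}")
        return int(root_state)
    p = np.asarray(root_state, dtype=float)
    p = p / p.sum()
    return int(rng.choice(k, p=p))


def simulate_traits(
    tree: dendropy.Tree,
    Q: np.ndarray,
    root_state=0,
    seed: int | None = None,
    *,
    model: RateModel | None = None,
    rates: dict[str, float] | None = None,
) -> SimulatedDataset:
    """Gillespie simulation of a Markov chain along every branch.

    ``root_state`` may be an integer state or a probability vector to draw
    from.  Structural zeros in ``Q`` are respected automatically: a
    transition can only be drawn where its rate is positive, so a
    one-change-at-a-time generator never produces dual transitions.
    """
    Q = np.asarray(Q, dtype=float)
    k = Q.shape[0]
    rng = np.random.default_rng(seed)
    nodes = list(tree.postorder_node_iter())
    index = {id(nd): i for i, nd in enumerate(nodes)}

    root_s = _draw_root_state(root_state, k, rng)
    node_states = {index[id(tree.seed_node)]: root_s}
    events: list[Event] = []
    tip_states: dict[str, int] = {}

    for nd in tree.preorder_node_iter():
        if nd.parent_node is None:
            continue
        i = index[id(nd)]
        s = node_states[index[id(nd.parent_node)]]
        t, t_end = 0.0, float(nd.edge.length or 0.0)
        while True:
            total = -Q[s, s]
            if total <= 0.0:
                break
            t += rng.exponential(1.0 / total)
            if t >= t_end:
                break
            probs = Q[s].clip(min=0.0)
            probs[s] = 0.0
            probs /= probs.sum()
            nxt = int(rng.choice(k, p=probs))
            events.append(Event(node_index=i, time=t, from_state=s, to_state=nxt))
            s = nxt
        node_states[i] = s
        if nd.is_leaf():
            tip_states[nd.taxon.label] = s

    return SimulatedDataset(
        tree=tree,
        tip_states=tip_states,
        node_states=node_states,
        events=events,
        Q=Q,
        model=model or dependent_model(),
        true_rates=dict(rates) if rates else {},
        root_state=root_s,
        seed=seed,
    )


@dataclass
class SimulationConfig:
    """Study-scale synthetic dataset configuration.

    Defaults mirror the scale of a large passerine comparative dataset:
    ~1582 complete-case species for the nesting analysis, a dependent-model
    truth with a strongly elevated iris-darkening rate in non-cavity
    nesters, and light missing-data dropout applied independently per trait
    (missing completely at random), which yields unequal per-trait sample
    sizes as in real trait compilations.
    """

    n_tips: int = 1582
    birth_rate: float = 1.0
    true_rates: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_TRUE_RATES))
    root_state: int = 0  # dark iris, non-cavity
    missing_fraction: dict[str, float] = field(
        default_factory=lambda: {"iris": 0.02, "nest": 0.08}
    )
    codebook: dict[str, dict[str, int]] = field(
        default_factory=lambda: {t: dict(s) for t, s in DEFAULT_CODEBOOK.items()}
    )
    seed: int | None = None

    def __post_init__(self):
        if self.n_tips < 4:
            raise ValueError("n_tips must be >= 4")
        for t, f in self.missing_fraction.items():
            if not 0.0 <= f < 1.0:
                raise ValueError(f"missing fraction for {t!r} must be in [0, 1)")
        if any(v <= 0 for v in self.true_rates.values()):
            raise ValueError("true rates must be positive")


def make_study_like_dataset(
    config: SimulationConfig | None = None,
    out_dir: str | Path | None = None,
) -> SimulatedDataset:
    """Simulate a full study-like dataset; optionally write Newick + CSV.

    The returned dataset carries a decoded species-by-trait table (state
    names per the codebook, missing cells as ``?``) in ``trait_table``.
    When ``out_dir`` is given, ``tree.nwk`` and ``traits.csv`` are written
    there in the exact formats the loaders consume.
    """
    cfg = config or SimulationConfig()
    model = dependent_model()
    Q = build_q(model, cfg.true_rates)
    tree = simulate_tree(cfg.n_tips, cfg.birth_rate, cfg.seed)
    sub = None if cfg.seed is None else cfg.seed + 1
    ds = simulate_traits(tree, Q, cfg.root_state, sub, model=model, rates=cfg.true_rates)

    traits = list(cfg.codebook)
    decode = {
        t: {v: k for k, v in cfg.codebook[t].items()} for t in traits
    }
    rng = np.random.default_rng(None if cfg.seed is None else cfg.seed + 2)
    rows = []
    for label, combined in ds.tip_states.items():
        s = decode_pair(combined)
        row = {"species": label}
        for j, t in enumerate(traits[:2]):
            if rng.random() < cfg.missing_fraction.get(t, 0.0):
                row[t] = "?"
            else:
                row[t] = decode[t][s[j]]
        rows.append(row)
    table = pd.DataFrame(rows).set_index("species")
    ds.trait_table = table

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        treeio.write_trees(ds.tree, out_dir / "tree.nwk", "newick")
        table.to_csv(out_dir / "traits.csv")
    return ds


def perturb_nni(tree: dendropy.Tree, n_moves: int = 1, seed: int | None = None) -> dendropy.Tree:
    """Copy of ``tree`` after random nearest-neighbour interchanges.

    Used to manufacture posterior-like tree samples: a cloud of topologies
    concentrated around a base tree.  Branch lengths are left untouched
    (swapped subtrees keep their own edge lengths).
    """
    rng = np.random.default_rng(seed)
    out = tree.clone(depth=1)
    for _ in range(n_moves):
        internal = [
            nd
            for nd in out.preorder_node_iter()
            if nd.parent_node is not None
            and not nd.is_leaf()
            and nd.parent_node.parent_node is not None
        ]
        if not internal:
            break
        nd = internal[int(rng.integers(len(internal)))]
        parent = nd.parent_node
        sib = [c for c in parent.child_nodes() if c is not nd][0]
        child = nd.child_nodes()[int(rng.integers(2))]
        # swap `sib` (uncle) with `child`
        parent.remove_child(sib)
        nd.remove_child(child)
        parent.add_child(child)
        nd.add_child(sib)
    return out
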