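"""Marginal maximum-likelihood ancestral-state reconstruction.

For each internal node the marginal posterior of its state given all tip
data ("proportional likelihoods") is computed with the inside–outside
scheme: a post-order pass gives the inside (subtree) partials, a pre-order
pass propagates the outside contribution, and their product — normalised
per node — is the marginal.  This equals the classical re-rooting
construction but costs a single extra tree traversal.

Transition counting assigns a state to every node (argmax of the marginal,
or only where the marginal exceeds a confidence threshold — the
conservative reading of "at least N transitions") and counts edges whose
parent and child assignments differ, per ordered state pair.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .likelihood import (
    PruningEngine,
    RootTreatment,
    UNIFORM_ROOT,
    root_weights,
    transition_probabilities,
)

__all__ = [
    "Reconstruction",
    "TransitionCount",
    "marginal_asr",
    "count_transitions",
]


@dataclass
class Reconstruction:
    """Per-node marginal state probabilities on a tree.

    ``marginals[i]`` is the probability simplex for ``engine.nodes[i]``
    (postorder indexing); tips carry probability 1 on their observed state.
    """

    engine: PruningEngine
    marginals: np.ndarray  # (n_nodes, k), rows sum to 1
    Q: np.ndarray
    root: RootTreatment

    @property
    def n_states(self) -> int:
        return self.marginals.shape[1]

    def ml_states(self) -> np.ndarray:
        return self.marginals.argmax(axis=1)

    def root_marginal(self) -> np.ndarray:
        return self.marginals[self.engine.root_index]

    def collapse_trait(self, which: int) -> "Reconstruction":
        """Single-trait marginals from a 4-state pair reconstruction.

        ``which`` = 0 collapses onto trait 1 (sums over trait 2's states),
        ``which`` = 1 onto trait 2.  State order of the result is (0, 1).
        """
        if self.n_states != 4:
            raise ValueError("collapse_trait needs a 4-state reconstruction")
        m = self.marginals
        if which == 0:
            collapsed = np.stack([m[:, 0] + m[:, 1], m[:, 2] + m[:, 3]], axis=1)
        elif which == 1:
            collapsed = np.stack([m[:, 0] + m[:, 2], m[:, 1] + m[:, 3]], axis=1)
        else:
            raise ValueError("which must be 0 or 1")
        return Reconstruction(self.engine, collapsed, self.Q, self.root)

    def node_table(self) -> pd.DataFrame:
        rows = []
        for i, nd in enumerate(self.engine.nodes):
            row = {
                "node": i,
                "is_tip": nd.is_leaf(),
                "label": nd.taxon.label if nd.is_leaf() else "",
            }
            for s in range(self.n_states):
                row[f"p{s}"] = self.marginals[i, s]
            row["ml_state"] = int(self.marginals[i].argmax())
            rows.append(row)
        return pd.DataFrame(rows)

    def annotate_tree(self, prefix: str = "pl"):
        """Attach proportional likelihoods to tree nodes as annotations."""
        for i, nd in enumerate(self.engine.nodes):
            if nd.is_leaf():
                continue
            for s in range(self.n_states):
                nd.annotations.add_new(f"{prefix}{s}", round(float(self.marginals[i, s]), 6))


def marginal_asr(
    tree,
    states,
    Q,
    root: RootTreatment = UNIFORM_ROOT,
    *,
    engine: PruningEngine | None = None,
) -> Reconstruction:
    """Marginal ancestral reconstruction under generator ``Q``.

    ``states`` maps tip labels to integer states (or is a PairedStates).
    """
    Q = np.asarray(Q, dtype=float)
    k = Q.shape[0]
    if engine is None:
        engine = PruningEngine(tree, k)
    tips = states.states if hasattr(states, "states") else dict(states)
    arr = engine.states_array(tips)

    L, _ = engine.partials(Q, arr, return_all=True)

    # outside pass: G[v][i] = P(data outside v's subtree, state of v = i) up
    # to per-node rescaling, seeded at the root with the root weights
    G = np.zeros_like(L)
    pi = root_weights(root, Q, L[engine.root_index])
    G[engine.root_index] = pi

    if engine._equal_lengths:
        P = transition_probabilities(Q, engine._shared_t)
        Pmap = None
    else:
        Pmap = engine._edge_matrices(Q)

    for par, le, ri in reversed(engine.levels):
        if Pmap is None:
            B_le = L[le] @ P.T
            B_ri = L[ri] @ P.T
            G[le] = (G[par] * B_ri) @ P
            G[ri] = (G[par] * B_le) @ P
        else:
            B_le = np.einsum("nij,nj->ni", Pmap[le], L[le])
            B_ri = np.einsum("nij,nj->ni", Pmap[ri], L[ri])
            G[le] = np.einsum("ni,nij->nj", G[par] * B_ri, Pmap[le])
            G[ri] = np.einsum("ni,nij->nj", G[par] * B_le, Pmap[ri])
        # rescale to dodge underflow; marginals are normalised per node anyway
        for idx in (le, ri):
            s = G[idx].max(axis=1)
            s[s == 0.0] = 1.0
            G[idx] /= s[:, None]

    post = L * G
    total = post.sum(axis=1, keepdims=True)
    total[total == 0.0] = 1.0
    return Reconstruction(engine=engine, marginals=post / total, Q=Q, root=root)


@dataclass
class TransitionCount:
    counts: dict[tuple[int, int], int]
    rule: str
    n_edges: int
    n_assigned_edges: int  # edges where both endpoints met the rule

    def __getitem__(self, pair):
        return self.counts.get(tuple(pair), 0)

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"from": a, "to": b, "count": c}
            for (a, b), c in sorted(self.counts.items())
        ]
        return pd.DataFrame(rows, columns=["from", "to", "count"])


def count_transitions(
    recon: Reconstruction,
    rule: str = "argmax",
    threshold: float | None = None,
) -> TransitionCount:
    """Count state changes along edges of a reconstructed tree.

    rule:
        ``argmax``    — every node gets its most probable state; every edge
                        with differing endpoint states is a transition.
        ``threshold`` — only nodes whose top state has marginal probability
                        >= ``threshold`` (in (0.5, 1]) are assigned; edges
                        with an unassigned endpoint are skipped.  This gives
                        a conservative lower bound on the number of changes.
    """
    if rule not in ("argmax", "threshold"):
        raise ValueError(f"unknown counting rule {rule!r}")
    if rule == "threshold":
        if threshold is None or not (0.5 < threshold <= 1.0):
            raise ValueError("threshold rule needs a threshold in (0.5, 1]")

    engine = recon.engine
    ml = recon.ml_states()
    top_p = recon.marginals.max(axis=1)
    assigned = np.ones(engine.n_nodes, dtype=bool)
    if rule == "threshold":
        assigned = top_p >= threshold

    counts: dict[tuple[int, int], int] = {}
    n_edges = 0
    n_used = 0
    for par, le, ri in engine.levels:
        for child in (le, ri):
            n_edges += len(child)
            ok = assigned[par] & assigned[child]
            n_used += int(ok.sum())
            a = ml[par][ok]
            b = ml[child][ok]
            for x, y in zip(a, b):
                if x != y:
                    key = (int(x), int(y))
                    counts[key] = counts.get(key, 0) + 1
    label = rule if rule == "argmax" else f"threshold({threshold})"
    return TransitionCount(
        counts=counts, rule=label, n_edges=n_edges, n_assigned_edges=n_used
    )
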