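"""Exact Mk-model log-likelihoods on trees via Felsenstein pruning.

The engine computes the probability of observed tip states under a
continuous-time Markov chain with generator ``Q`` running along the
branches of a rooted binary tree.  Partial likelihoods are propagated
post-order through ``exp(Q * branch_length)`` and combined at the root
under a configurable root-state treatment.

Performance notes: the tree is preprocessed once into index arrays with
internal nodes grouped by topological level, so a likelihood evaluation is
a handful of vectorised operations per level rather than a Python loop per
node.  When all branch lengths are equal (the default analysis mode) a
single matrix exponential serves every branch.  Partial likelihoods are
rescaled per node with accumulated log-scalers to avoid underflow on large
trees.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import expm

__all__ = [
    "RootTreatment",
    "PruningEngine",
    "transition_probabilities",
    "stationary_distribution",
    "pruning_loglik",
]


@dataclass(frozen=True)
class RootTreatment:
    """How state probabilities are combined at the root.

    mode:
        ``uniform``   — equal weight 1/k per state (default).
        ``stationary``— weights are the stationary distribution of Q.
        ``fitzjohn``  — weights proportional to the root partial
                        likelihoods themselves (each state weighted by the
                        probability of the data given that root state).
        ``fixed``     — all mass on ``state``.
    """

    mode: str = "uniform"
    state: int | None = None

    def __post_init__(self):
        if self.mode not in ("uniform", "stationary", "fitzjohn", "fixed"):
            raise ValueError(f"unknown root treatment {self.mode!r}")
        if self.mode == "fixed" and self.state is None:
            raise ValueError("fixed root treatment needs a state")


UNIFORM_ROOT = RootTreatment("uniform")


def transition_probabilities(Q: np.ndarray, t: float) -> np.ndarray:
    """``exp(Q t)``: the stochastic matrix over a branch of length ``t``."""
    if t < 0:
        raise ValueError(f"branch length must be >= 0, got {t}")
    P = expm(np.asarray(Q, dtype=float) * t)
    # scaling-and-squaring can leave O(1e-16) negatives; clamp them
    np.clip(P, 0.0, None, out=P)
    return P


def stationary_distribution(Q: np.ndarray) -> np.ndarray:
    """Left null vector of Q, normalised to a probability vector."""
    Q = np.asarray(Q, dtype=float)
    k = Q.shape[0]
    # solve pi Q = 0 with sum(pi) = 1 as an augmented least-squares system
    A = np.vstack([Q.T, np.ones(k)])
    b = np.zeros(k + 1)
    b[-1] = 1.0
    pi, *_ = np.linalg.lstsq(A, b, rcond=None)
    pi = np.clip(pi, 0.0, None)
    s = pi.sum()
    if s <= 0:
        raise np.linalg.LinAlgError("no valid stationary distribution")
    return pi / s


def _expm_batch(Q: np.ndarray, times: np.ndarray) -> np.ndarray:
    """exp(Q t) for a vector of times, stacked (len(times), k, k)."""
    k = Q.shape[0]
    try:
        w, V = np.linalg.eig(Q)
        cond = np.linalg.cond(V)
        if np.isfinite(cond) and cond < 1e8:
            Vinv = np.linalg.inv(V)
            E = np.exp(np.multiply.outer(times, w))  # (n, k)
            P = np.einsum("ij,nj,jl->nil", V, E, Vinv).real
            np.clip(P, 0.0, None, out=P)
            err = np.abs(P.sum(axis=2) - 1.0).max()
            if err < 1e-9:
                return P
    except np.linalg.LinAlgError:
        pass
    # robust fallback: scaling-and-squaring per unique branch length
    out = np.empty((len(times), k, k))
    cache: dict[float, np.ndarray] = {}
    for i, ti in enumerate(times):
        key = round(float(ti), 12)
        if key not in cache:
            cache[key] = transition_probabilities(Q, key)
        out[i] = cache[key]
    return out


class PruningEngine:
    """Preprocessed pruning machinery bound to one tree.

    Parameters
    ----------
    tree:
        Rooted, fully resolved :class:`dendropy.Tree` with branch lengths.
    n_states:
        Size of the state space (2 for a single binary trait, 4 for a pair).
    """

    def __init__(self, tree, n_states: int):
        self.n_states = int(n_states)
        nodes = list(tree.postorder_node_iter())
        self.nodes = nodes  # postorder; index i in all arrays refers to nodes[i]
        self.n_nodes = len(nodes)
        index = {id(nd): i for i, nd in enumerate(nodes)}
        self.root_index = index[id(tree.seed_node)]

        self.tip_labels: list[str] = []
        self.tip_indices: list[int] = []
        left, right, parents = [], [], []
        lengths = np.zeros(self.n_nodes)
        level = np.zeros(self.n_nodes, dtype=int)
        for nd in nodes:
            i = index[id(nd)]
            if nd.parent_node is not None:
                if nd.edge.length is None:
                    raise ValueError("tree has missing branch lengths")
                lengths[i] = float(nd.edge.length)
            children = nd.child_nodes()
            if not children:
                self.tip_labels.append(nd.taxon.label)
                self.tip_indices.append(i)
            elif len(children) == 2:
                ci = [index[id(c)] for c in children]
                left.append(ci[0])
                right.append(ci[1])
                parents.append(i)
                level[i] = 1 + max(level[ci[0]], level[ci[1]])
            else:
                raise ValueError("tree is not fully resolved (binary)")
        self.n_tips = len(self.tip_labels)
        self.edge_lengths = lengths

        left = np.asarray(left, dtype=int)
        right = np.asarray(right, dtype=int)
        parents = np.asarray(parents, dtype=int)
        self.levels: list[tuple[np.ndarray, np.ndarray, np.ndarray]] = []
        for lev in range(1, level.max() + 1 if self.n_nodes > 1 else 1):
            m = level[parents] == lev
            if m.any():
                self.levels.append((parents[m], left[m], right[m]))

        uniq = np.unique(np.round(lengths[np.arange(self.n_nodes) != self.root_index], 12))
        self._equal_lengths = len(uniq) == 1
        self._shared_t = float(uniq[0]) if self._equal_lengths else None

    # ------------------------------------------------------------------
    def states_array(self, states: dict) -> np.ndarray:
        """Tip-state vector in engine order from a label -> state mapping."""
        missing = set(self.tip_labels) - set(states)
        if missing:
            raise ValueError(f"no state for tips: {sorted(missing)[:5]}...")
        arr = np.array([int(states[l]) for l in self.tip_labels], dtype=int)
        if arr.min() < 0 or arr.max() >= self.n_states:
            raise ValueError("tip state outside the model's state space")
        return arr

    def _edge_matrices(self, Q: np.ndarray) -> np.ndarray:
        """Per-node transition matrices, stacked (n_nodes, k, k).

        Fast path: diagonalise Q once and evaluate exp(Q t) for all branch
        lengths in one vectorised product.  Mk-type generators are almost
        always cleanly diagonalisable; if the eigenbasis is ill-conditioned
        the robust scaling-and-squaring exponential is used per unique
        branch length instead.
        """
        k = self.n_states
        t = self.edge_lengths.copy()
        t[self.root_index] = 0.0
        P = _expm_batch(Q, t)
        P[self.root_index] = np.eye(k)
        return P

    def partials(self, Q, tip_states, *, return_all: bool = False):
        """Post-order partial likelihoods.

        Returns ``(L, logscale)`` where ``L[root]`` is the rescaled root
        partial and ``logscale[root]`` the accumulated log rescaling.
        With ``return_all`` the full arrays are returned (used by the
        ancestral-state machinery).
        """
        Q = np.asarray(Q, dtype=float)
        k = self.n_states
        if Q.shape != (k, k):
            raise ValueError(f"Q shape {Q.shape} does not match {k} states")
        if isinstance(tip_states, dict):
            tip_states = self.states_array(tip_states)

        L = np.zeros((self.n_nodes, k))
        L[self.tip_indices, tip_states] = 1.0
        logsc = np.zeros(self.n_nodes)

        if self._equal_lengths:
            PT = transition_probabilities(Q, self._shared_t).T
            for par, le, ri in self.levels:
                A = L[le] @ PT
                B = L[ri] @ PT
                prod = A * B
                s = prod.max(axis=1)
                s[s == 0.0] = 1.0
                L[par] = prod / s[:, None]
                logsc[par] = np.log(s) + logsc[le] + logsc[ri]
        else:
            P = self._edge_matrices(Q)
            for par, le, ri in self.levels:
                A = np.einsum("nij,nj->ni", P[le], L[le])
                B = np.einsum("nij,nj->ni", P[ri], L[ri])
                prod = A * B
                s = prod.max(axis=1)
                s[s == 0.0] = 1.0
                L[par] = prod / s[:, None]
                logsc[par] = np.log(s) + logsc[le] + logsc[ri]
        if return_all:
            return L, logsc
        r = self.root_index
        return L[r], logsc[r]

    def loglik(self, Q, tip_states, root: RootTreatment = UNIFORM_ROOT) -> float:
        """Log-likelihood of the tip data under generator ``Q``."""
        Lr, logsc = self.partials(Q, tip_states)
        pi = root_weights(root, np.asarray(Q, dtype=float), Lr)
        total = float(pi @ Lr)
        if total <= 0.0:
            return -np.inf
        return float(np.log(total) + logsc)


def root_weights(root: RootTreatment, Q: np.ndarray, root_partials: np.ndarray) -> np.ndarray:
    k = Q.shape[0]
    if root.mode == "uniform":
        return np.full(k, 1.0 / k)
    if root.mode == "stationary":
        return stationary_distribution(Q)
    if root.mode == "fitzjohn":
        s = root_partials.sum()
        if s <= 0:
            return np.full(k, 1.0 / k)
        return root_partials / s
    # fixed
    w = np.zeros(k)
    w[root.state] = 1.0
    return w


def pruning_loglik(tree, states: dict, Q, root: RootTreatment = UNIFORM_ROOT) -> float:
    """One-shot log-likelihood: builds a :class:`PruningEngine` and evaluates.

    ``states`` maps tip label to integer state index; its key set must equal
    the tree's tip set.
    """
    Q = np.asarray(Q, dtype=float)
    engine = PruningEngine(tree, Q.shape[0])
    extra = set(states) - set(engine.tip_labels)
    if extra:
        raise ValueError(f"states given for labels not on the tree: {sorted(extra)[:5]}")
    return engine.loglik(Q, states, root)
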