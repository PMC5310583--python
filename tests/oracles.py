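"""Independent brute-force oracles used to validate the fast implementations.

These deliberately avoid the package's pruning/inside-outside code paths:
likelihoods are computed by exhaustively summing over all internal-node
state assignments, and marginals by renormalising those sums.  Only
feasible on tiny trees, which is the point.
"""

import itertools

import numpy as np
from scipy.linalg import expm


def _edge_Ps(tree, Q):
    return {
        id(n): expm(Q * n.edge.length)
        for n in tree.postorder_node_iter()
        if n.parent_node is not None
    }


def enum_likelihood_terms(tree, states, Q, pi):
    """Yield (assignment, probability) over all internal-state assignments."""
    Q = np.asarray(Q, dtype=float)
    k = Q.shape[0]
    nodes = list(tree.postorder_node_iter())
    internal = [n for n in nodes if not n.is_leaf()]
    P = _edge_Ps(tree, Q)
    for assign in itertools.product(range(k), repeat=len(internal)):
        st = {id(n): s for n, s in zip(internal, assign)}
        for n in nodes:
            if n.is_leaf():
                st[id(n)] = states[n.taxon.label]
        p = pi[st[id(tree.seed_node)]]
        for n in nodes:
            if n.parent_node is not None:
                p *= P[id(n)][st[id(n.parent_node)], st[id(n)]]
        yield assign, p


def enum_loglik(tree, states, Q, pi=None):
    """Exhaustive-enumeration log-likelihood (uniform root by default)."""
    k = np.asarray(Q).shape[0]
    if pi is None:
        pi = np.full(k, 1.0 / k)
    total = sum(p for _, p in enum_likelihood_terms(tree, states, Q, pi))
    return float(np.log(total))


def enum_marginals(tree, states, Q, pi=None):
    """Brute-force marginal state posteriors for every internal node.

    Returns a dict: internal node id -> probability vector.
    """
    Q = np.asarray(Q, dtype=float)
    k = Q.shape[0]
    if pi is None:
        pi = np.full(k, 1.0 / k)
    internal = [n for n in tree.postorder_node_iter() if not n.is_leaf()]
    sums = {id(n): np.zeros(k) for n in internal}
    total = 0.0
    for assign, p in enum_likelihood_terms(tree, states, Q, pi):
        total += p
        for n, s in zip(internal, assign):
            sums[id(n)][s] += p
    return {nid: v / total for nid, v in sums.items()}


def pattern_probabilities(tree, Q, pi):
    """Exact probability of every tip-state pattern (tiny trees only)."""
    Q = np.asarray(Q, dtype=float)
    k = Q.shape[0]
    tips = sorted(l.taxon.label for l in tree.leaf_node_iter())
    out = {}
    for pattern in itertools.product(range(k), repeat=len(tips)):
        states = dict(zip(tips, pattern))
        out[pattern] = float(
            sum(p for _, p in enum_likelihood_terms(tree, states, Q, pi))
        )
    return out
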