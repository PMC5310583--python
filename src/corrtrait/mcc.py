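"""Maximum clade credibility (MCC) tree selection from a posterior sample.

Clades are keyed by the frozenset of descendant tip labels, so posterior
frequencies are invariant to label order and file formatting.  The MCC tree
is always one of the sampled trees — never a consensus — chosen to maximise
either the sum (default) or the log-product of its clades' posterior
frequencies.  The posterior-probability limit controls annotation only:
clades at or above the limit receive a ``posterior`` annotation on the
selected tree; selection itself always uses every clade.
"""

from __future__ import annotations

from dataclasses import dataclass
import math

import dendropy
import pandas as pd

from .treeio import TreeSample

__all__ = ["CladeTable", "MCCResult", "clade_frequencies", "mcc_tree"]


@dataclass
class CladeTable:
    """Posterior frequency per clade (clade = frozenset of tip labels)."""

    frequencies: dict[frozenset, float]
    sample_size: int

    def __getitem__(self, clade):
        return self.frequencies[frozenset(clade)]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"clade": "|".join(sorted(c)), "size": len(c), "frequency": f}
            for c, f in sorted(
                self.frequencies.items(), key=lambda kv: (-kv[1], -len(kv[0]))
            )
        ]
        return pd.DataFrame(rows, columns=["clade", "size", "frequency"])


@dataclass
class MCCResult:
    tree_index: int
    tree: dendropy.Tree
    scores: list[float]
    score_mode: str
    clade_table: CladeTable


def _tree_clades(tree: dendropy.Tree):
    """Clades (tip-label frozensets) of all nodes: singletons, root included."""
    out = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            node._clade = frozenset([node.taxon.label])
        else:
            node._clade = frozenset().union(*(c._clade for c in node.child_nodes()))
        out[node._clade] = node
    return out


def clade_frequencies(sample: TreeSample, burnin: int = 0) -> CladeTable:
    """Exact relative clade frequencies over the post-burn-in trees."""
    trees = sample.trees if not isinstance(sample, list) else sample
    if burnin < 0 or burnin >= len(trees):
        raise ValueError(f"burnin {burnin} out of range for sample of {len(trees)}")
    kept = trees[burnin:]
    counts: dict[frozenset, int] = {}
    for t in kept:
        for clade in _tree_clades(t):
            counts[clade] = counts.get(clade, 0) + 1
    n = len(kept)
    return CladeTable(
        frequencies={c: k / n for c, k in counts.items()}, sample_size=n
    )


def _score(clades, table: CladeTable, mode: str) -> float:
    # singleton clades always have frequency 1 and carry no signal
    inner = [c for c in clades if len(c) > 1]
    if mode == "sum":
        return sum(table.frequencies[c] for c in inner)
    if mode == "log-product":
        return sum(math.log(table.frequencies[c]) for c in inner)
    raise ValueError(f"unknown score mode {mode!r}")


def mcc_tree(
    sample: TreeSample,
    burnin: int = 0,
    score: str = "sum",
    pp_limit: float = 0.5,
) -> MCCResult:
    """Select and annotate the maximum clade credibility tree.

    Ties in score are broken by the lowest tree index, making selection
    deterministic.  The returned tree is a clone of the winning sample tree
    with ``posterior`` annotations on internal nodes whose clade frequency
    is at least ``pp_limit``.
    """
    table = clade_frequencies(sample, burnin)
    trees = sample.trees[burnin:]
    scores = [_score(_tree_clades(t), table, score) for t in trees]
    best_rel = max(range(len(scores)), key=lambda i: (scores[i], -i))
    best_index = best_rel + burnin

    annotated = sample.trees[best_index].clone(depth=1)
    for clade, node in _tree_clades(annotated).items():
        if node.is_leaf():
            continue
        pp = table.frequencies[clade]
        if pp >= pp_limit:
            node.annotations.add_new("posterior", round(pp, 6))
    return MCCResult(
        tree_index=best_index,
        tree=annotated,
        scores=scores,
        score_mode=score,
        clade_table=table,
    )
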