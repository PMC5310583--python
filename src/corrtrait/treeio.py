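"""Tree input/output, validation and branch-length transforms.

Trees are held as :class:`dendropy.Tree` objects throughout the package; a
:class:`TreeSample` is an ordered collection of trees over one taxon set
(e.g. a posterior sample exported from a Bayesian analysis).  All readers
validate the invariants the downstream likelihood machinery relies on:
rooted, unique tip labels, non-negative branch lengths and (optionally)
full resolution — every internal node with exactly two children.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import dendropy

__all__ = [
    "TreeSample",
    "TreeValidationError",
    "read_trees",
    "read_tree",
    "validate_tree",
    "set_equal_branch_lengths",
    "check_ultrametric",
    "prune_to_taxa",
    "resolve_polytomies",
    "write_trees",
]


class TreeValidationError(ValueError):
    """A tree violates a structural invariant (labels, resolution, lengths)."""


@dataclass
class TreeSample:
    """An ordered list of trees sharing one tip-label set."""

    trees: list[dendropy.Tree]
    burnin: int = 0

    def __len__(self) -> int:
        return len(self.trees)

    def __getitem__(self, i):
        return self.trees[i]

    def __iter__(self):
        return iter(self.trees)

    @property
    def taxon_labels(self) -> frozenset[str]:
        return frozenset(t.taxon.label for t in self.trees[0].leaf_node_iter())


def tip_labels(tree: dendropy.Tree) -> frozenset[str]:
    return frozenset(leaf.taxon.label for leaf in tree.leaf_node_iter())


def validate_tree(
    tree: dendropy.Tree,
    *,
    require_binary: bool = True,
    require_lengths: bool = False,
) -> dendropy.Tree:
    """Check rootedness, label uniqueness, resolution and branch lengths.

    Raises :class:`TreeValidationError` with a specific message on the first
    violation found; returns the tree unchanged otherwise.
    """
    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    if len(labels) != len(set(labels)):
        dupes = sorted({l for l in labels if labels.count(l) > 1})
        raise TreeValidationError(f"duplicate tip labels: {dupes}")
    for node in tree.preorder_node_iter():
        nchild = len(node.child_nodes())
        if require_binary and nchild not in (0, 2) and node is not tree.seed_node:
            raise TreeValidationError(
                f"polytomy or unifurcation at internal node (degree {nchild}); "
                "trees must be fully resolved (use resolve_polytomies to fix)"
            )
        if require_binary and node is tree.seed_node and nchild not in (0, 2):
            raise TreeValidationError(
                f"root has {nchild} children; a rooted fully resolved tree "
                "has a bifurcating root"
            )
        if node.edge.length is not None and node.edge.length < 0:
            raise TreeValidationError(
                f"negative branch length {node.edge.length}"
            )
        if require_lengths and node is not tree.seed_node and node.edge.length is None:
            raise TreeValidationError("missing branch length")
    return tree


def _read_dendropy(path_or_handle, fmt: str) -> dendropy.TreeList:
    kwargs = {"schema": fmt}
    if fmt == "newick":
        kwargs["preserve_underscores"] = True
    try:
        if hasattr(path_or_handle, "read"):
            return dendropy.TreeList.get(file=path_or_handle, **kwargs)
        return dendropy.TreeList.get(path=str(path_or_handle), **kwargs)
    except Exception as exc:  # dendropy raises schema-specific errors
        raise TreeValidationError(f"could not parse {fmt} input: {exc}") from exc


def read_trees(
    path,
    format: str = "newick",
    *,
    require_binary: bool = True,
    validate_taxa: bool = True,
) -> TreeSample:
    """Read one or more trees and return a validated :class:`TreeSample`.

    All trees must share an identical tip-label set; a mismatch raises with
    the symmetric difference of the offending label sets.
    """
    if format not in ("newick", "nexus"):
        raise ValueError(f"unknown tree format {format!r}")
    tree_list = _read_dendropy(path, format)
    if len(tree_list) == 0:
        raise TreeValidationError("no trees found in input")
    trees = []
    for t in tree_list:
        t.is_rooted = True
        validate_tree(t, require_binary=require_binary)
        trees.append(t)
    if validate_taxa:
        ref = tip_labels(trees[0])
        for i, t in enumerate(trees[1:], start=1):
            lbl = tip_labels(t)
            if lbl != ref:
                raise TreeValidationError(
                    f"tree {i} taxon set differs from tree 0; "
                    f"symmetric difference: {sorted(ref ^ lbl)}"
                )
    return TreeSample(trees)


def read_tree(path, format: str = "newick", **kw) -> dendropy.Tree:
    """Read a single tree (first of the file)."""
    return read_trees(path, format, **kw).trees[0]


def parse_newick(s: str, **kw) -> dendropy.Tree:
    """Parse one tree from a Newick string (convenience for tests/scripts)."""
    return read_trees(io.StringIO(s), "newick", **kw).trees[0]


def write_trees(trees, path, format: str = "newick") -> None:
    """Write a tree, list of trees or TreeSample to Newick/NEXUS."""
    if isinstance(trees, dendropy.Tree):
        trees = [trees]
    if isinstance(trees, TreeSample):
        trees = trees.trees
    tl = dendropy.TreeList()
    for t in trees:
        tl.append(t.clone(depth=1))
    kwargs = {"schema": format}
    if format == "newick":
        kwargs["unquoted_underscores"] = True
    tl.write(path=str(path), **kwargs)


def set_equal_branch_lengths(tree: dendropy.Tree, value: float = 1.0) -> dendropy.Tree:
    """Return a copy with every edge length set to ``value``.

    Fitting on equal branch lengths treats every branch as one unit of
    opportunity for change; the absolute value is absorbed into the rate
    estimates, so 1.0 is the canonical choice.
    """
    if value <= 0:
        raise ValueError(f"branch length value must be > 0, got {value}")
    out = tree.clone(depth=1)
    for edge in out.preorder_edge_iter():
        if edge.head_node is not out.seed_node:
            edge.length = value
        else:
            edge.length = None
    return out


def check_ultrametric(tree: dendropy.Tree, tolerance: float = 1e-6):
    """Return ``(is_ultrametric, max_deviation)`` of root-to-tip depths.

    Deviation is the maximum absolute difference between any tip depth and
    the mean tip depth.
    """
    depths = []
    for leaf in tree.leaf_node_iter():
        d = 0.0
        node = leaf
        while node.parent_node is not None:
            d += node.edge.length or 0.0
            node = node.parent_node
        depths.append(d)
    if len(depths) <= 1:
        return True, 0.0
    mean = sum(depths) / len(depths)
    dev = max(abs(d - mean) for d in depths)
    return dev <= tolerance, dev


@dataclass
class PruneReport:
    kept: list[str] = field(default_factory=list)
    dropped: list[str] = field(default_factory=list)


def prune_to_taxa(
    tree: dendropy.Tree,
    keep,
    *,
    allow_single_tip: bool = False,
):
    """Induced subtree on ``keep``; returns ``(pruned_tree, PruneReport)``.

    Degree-two internal nodes created by pruning are suppressed with their
    incident branch lengths summed, so patristic distances among kept tips
    are preserved exactly.
    """
    keep = set(keep)
    present = tip_labels(tree)
    inter = keep & present
    if not inter:
        raise TreeValidationError("no requested taxa present on the tree")
    if len(inter) == 1 and not allow_single_tip:
        raise TreeValidationError(
            "pruning would leave a single tip (no likelihood information); "
            "pass allow_single_tip=True to permit"
        )
    out = tree.clone(depth=1)
    taxa = [t for t in out.taxon_namespace if t.label in inter]
    out.retain_taxa(taxa)
    out.purge_taxon_namespace()
    report = PruneReport(kept=sorted(inter), dropped=sorted(present - inter))
    return out, report


def resolve_polytomies(tree: dendropy.Tree, seed: int = 0) -> dendropy.Tree:
    """Randomly resolve polytomies with zero-length edges (seeded)."""
    import random

    out = tree.clone(depth=1)
    out.resolve_polytomies(rng=random.Random(seed))
    for edge in out.preorder_edge_iter():
        if edge.length is None and edge.head_node is not out.seed_node:
            edge.length = 0.0
    return out
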