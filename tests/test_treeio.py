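import io

import dendropy
import numpy as np
import pytest

import corrtrait as ct
from corrtrait.treeio import (
    TreeValidationError,
    check_ultrametric,
    prune_to_taxa,
    read_trees,
    set_equal_branch_lengths,
    tip_labels,
    write_trees,
)


def test_read_single_newick():
    sample = read_trees(io.StringIO("((A:1,B:1):1,(C:1,D:1):1);"))
    assert len(sample) == 1
    assert sample.taxon_labels == {"A", "B", "C", "D"}


def test_duplicate_tip_labels_rejected():
    with pytest.raises(TreeValidationError, match="duplicate"):
        read_trees(io.StringIO("((A:1,B:1):1,(A:1,C:1):1);"))


def test_polytomy_rejected_and_resolvable():
    src = "((A:1,B:1,C:1):1,D:2);"
    with pytest.raises(TreeValidationError, match="resolved"):
        read_trees(io.StringIO(src))
    sample = read_trees(io.StringIO(src), require_binary=False)
    fixed = ct.treeio.resolve_polytomies(sample.trees[0], seed=1)
    ct.treeio.validate_tree(fixed)  # now binary


def test_mismatched_taxa_across_sample():
    src = "((A:1,B:1):1,C:2);\n((A:1,B:1):1,D:2);\n"
    with pytest.raises(TreeValidationError, match="symmetric difference"):
        read_trees(io.StringIO(src))


def test_nexus_roundtrip(tmp_path):
    trees = [ct.simulate_tree(5, 1.0, s) for s in range(3)]
    # share one label set: relabel each tree identically
    path = tmp_path / "sample.nex"
    write_trees(trees, path, "nexus")
    back = read_trees(path, "nexus")
    assert len(back) == 3
    for orig, rt in zip(trees, back):
        assert tip_labels(orig) == tip_labels(rt)
        # topology and lengths survive the round trip
        tns = dendropy.TaxonNamespace()
        a = dendropy.Tree.get(data=orig.as_string("newick"), schema="newick",
                              taxon_namespace=tns)
        b = dendropy.Tree.get(data=rt.as_string("newick"), schema="newick",
                              taxon_namespace=tns)
        a.encode_bipartitions(); b.encode_bipartitions()
        assert dendropy.calculate.treecompare.symmetric_difference(a, b) == 0


def test_set_equal_branch_lengths(balanced_quartet):
    t = set_equal_branch_lengths(balanced_quartet, 2.5)
    lengths = [e.length for e in t.preorder_edge_iter() if e.head_node is not t.seed_node]
    assert all(l == 2.5 for l in lengths)
    # idempotent
    t2 = set_equal_branch_lengths(t, 2.5)
    assert all(
        e.length == 2.5 for e in t2.preorder_edge_iter() if e.head_node is not t2.seed_node
    )
    with pytest.raises(ValueError):
        set_equal_branch_lengths(balanced_quartet, 0.0)


def test_equal_branches_break_ultrametricity():
    tree = ct.parse_newick("((A:1,B:1):2,C:3);")
    ok, dev = check_ultrametric(tree, 1e-9)
    assert ok and dev == 0
    eq = set_equal_branch_lengths(tree, 1.0)
    ok2, dev2 = check_ultrametric(eq, 1e-9)
    assert not ok2 and dev2 > 0


def test_check_ultrametric_reports_deviation():
    ok, dev = check_ultrametric(ct.parse_newick("((A:1,B:2):1,C:2);"), 1e-9)
    assert not ok
    assert dev == pytest.approx(2 / 3)  # depths 2,3,2 vs mean 7/3


def test_prune_preserves_patristic_distances():
    rng = np.random.default_rng(5)
    for rep in range(5):
        tree = ct.simulate_tree(12, 1.0, rep)
        labels = sorted(tip_labels(tree))
        keep = set(rng.choice(labels, size=6, replace=False))
        pruned, report = prune_to_taxa(tree, keep)
        assert tip_labels(pruned) == keep
        assert set(report.dropped) == set(labels) - keep

        def pdm(t):
            m = t.phylogenetic_distance_matrix()
            return {
                frozenset([a.label, b.label]): m.patristic_distance(a, b)
                for a in t.taxon_namespace
                for b in t.taxon_namespace
                if a.label < b.label and a.label in keep and b.label in keep
            }

        before, after = pdm(tree), pdm(pruned)
        for pair, d in after.items():
            assert d == pytest.approx(before[pair], abs=1e-9)


def test_prune_identity_and_degenerate(balanced_quartet):
    same, report = prune_to_taxa(balanced_quartet, {"A", "B", "C", "D"})
    assert tip_labels(same) == {"A", "B", "C", "D"}
    assert report.dropped == []
    with pytest.raises(TreeValidationError):
        prune_to_taxa(balanced_quartet, {"A"})
    single, _ = prune_to_taxa(balanced_quartet, {"A"}, allow_single_tip=True)
    assert tip_labels(single) == {"A"}
    with pytest.raises(TreeValidationError):
        prune_to_taxa(balanced_quartet, {"X", "Y"})
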