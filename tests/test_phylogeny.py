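import math

import dendropy
import numpy as np
import pytest
from dendropy.calculate import treecompare

from famevol import phylogeny, simulate
from famevol.phylogeny import DistanceMatrix


# ---------------------------------------------------------------------------
# distances

def test_identical_rows_have_zero_distance():
    dm = phylogeny.protein_distance({"a": "MKVL", "b": "MKVL"})
    assert dm.matrix[0, 1] == 0.0


def test_poisson_correction_closed_form():
    # p = 0.1 over 10 shared columns -> d = -ln(0.9)
    dm = phylogeny.protein_distance({"a": "A" * 10, "b": "A" * 9 + "C"})
    assert dm.matrix[0, 1] == pytest.approx(-math.log(0.9))


def test_gapped_columns_pairwise_deleted():
    dm = phylogeny.protein_distance({"a": "MK-L", "b": "MKVL"})
    assert dm.matrix[0, 1] == 0.0  # only the 3 shared columns count


def test_saturated_distance_capped():
    dm = phylogeny.protein_distance({"a": "AAAA", "b": "CCCC"})
    assert dm.matrix[0, 1] == 20.0


def test_no_shared_columns_is_error():
    with pytest.raises(phylogeny.PhyloError):
        phylogeny.protein_distance({"a": "A---", "b": "--CC"})


# ---------------------------------------------------------------------------
# neighbor joining

def _leaf_path_lengths(tree):
    pdm = tree.phylogenetic_distance_matrix()
    out = {}
    taxa = list(tree.taxon_namespace)
    for i, t1 in enumerate(taxa):
        for t2 in taxa[i + 1:]:
            out[frozenset((t1.label, t2.label))] = pdm.distance(t1, t2)
    return out


def test_three_taxa_branch_lengths_solve_three_point_formulas():
    D = np.array([[0, 5, 9], [5, 0, 10], [9, 10, 0]], float)
    tree = phylogeny.neighbor_joining(DistanceMatrix(["A", "B", "C"], D))
    paths = _leaf_path_lengths(tree)
    assert paths[frozenset(("A", "B"))] == pytest.approx(5)
    assert paths[frozenset(("A", "C"))] == pytest.approx(9)
    assert paths[frozenset(("B", "C"))] == pytest.approx(10)


def _random_additive(rng, n_taxa):
    """A random binary tree; returns (dendropy tree, labels, matrix)."""
    labels = [f"t{i}" for i in range(n_taxa)]
    ns = dendropy.TaxonNamespace(labels)
    nodes = []
    for lbl in labels:
        node = dendropy.Node()
        node.taxon = ns.get_taxon(lbl)
        nodes.append(node)
    while len(nodes) > 2:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        parent = dendropy.Node()
        for k in (j, i):
            child = nodes.pop(k)
            parent.add_child(child)
            child.edge.length = float(rng.uniform(0.1, 1.0))
        nodes.append(parent)
    root = dendropy.Node()
    for child in nodes:
        root.add_child(child)
        child.edge.length = float(rng.uniform(0.1, 1.0))
    tree = dendropy.Tree(taxon_namespace=ns, seed_node=root)
    tree.is_rooted = False
    pdm = tree.phylogenetic_distance_matrix()
    D = np.zeros((n_taxa, n_taxa))
    for i, a in enumerate(labels):
        for j, b in enumerate(labels):
            if i < j:
                d = pdm.distance(ns.get_taxon(a), ns.get_taxon(b))
                D[i, j] = D[j, i] = d
    return tree, labels, D


def test_nj_recovers_random_additive_trees_exactly():
    """Topology and path lengths round-trip for 50 random tree metrics."""
    rng = np.random.default_rng(77)
    for _ in range(50):
        n = int(rng.integers(4, 13))
        true_tree, labels, D = _random_additive(rng, n)
        est = phylogeny.neighbor_joining(DistanceMatrix(labels, D))
        est2 = est.clone(depth=1)
        est2.migrate_taxon_namespace(true_tree.taxon_namespace)
        true_tree.encode_bipartitions()
        est2.encode_bipartitions()
        assert treecompare.symmetric_difference(true_tree, est2) == 0
        true_paths = _leaf_path_lengths(true_tree)
        est_paths = _leaf_path_lengths(est)
        for key, d in true_paths.items():
            assert est_paths[key] == pytest.approx(d, abs=1e-9)


def test_nj_agrees_with_dendropy_oracle():
    rng = np.random.default_rng(5)
    _, labels, D = _random_additive(rng, 9)
    mine = phylogeny.neighbor_joining(DistanceMatrix(labels, D))
    csv = "," + ",".join(labels) + "\n" + "\n".join(
        labels[i] + "," + ",".join(str(D[i, j]) for j in range(len(labels)))
        for i in range(len(labels)))
    pdm = dendropy.PhylogeneticDistanceMatrix.from_csv(
        src=__import__("io").StringIO(csv))
    oracle = pdm.nj_tree()
    mine2 = mine.clone(depth=1)
    mine2.migrate_taxon_namespace(oracle.taxon_namespace)
    oracle.encode_bipartitions()
    mine2.encode_bipartitions()
    assert treecompare.symmetric_difference(oracle, mine2) == 0


def test_nj_invariant_under_label_permutation():
    rng = np.random.default_rng(13)
    _, labels, D = _random_additive(rng, 8)
    t1 = phylogeny.neighbor_joining(DistanceMatrix(labels, D))
    perm = list(rng.permutation(len(labels)))
    labels_p = [labels[i] for i in perm]
    Dp = D[np.ix_(perm, perm)]
    t2 = phylogeny.neighbor_joining(DistanceMatrix(labels_p, Dp))
    t2b = t2.clone(depth=1)
    t2b.migrate_taxon_namespace(t1.taxon_namespace)
    t1.encode_bipartitions()
    t2b.encode_bipartitions()
    assert treecompare.symmetric_difference(t1, t2b) == 0


def test_zero_distance_pair_joined_as_cherry():
    D = np.array([[0, 0, 4, 4], [0, 0, 4, 4], [4, 4, 0, 2], [4, 4, 2, 0]],
                 float)
    tree = phylogeny.neighbor_joining(DistanceMatrix(list("ABCD"), D))
    for leaf in tree.leaf_node_iter():
        if leaf.taxon.label == "A":
            siblings = [c.taxon.label for c in leaf.parent_node.child_nodes()
                        if c.is_leaf()]
            assert "B" in siblings


def test_asymmetric_matrix_rejected():
    D = np.array([[0, 1], [2, 0]], float)
    with pytest.raises(phylogeny.PhyloError):
        DistanceMatrix(["a", "b"], D)


# ---------------------------------------------------------------------------
# bootstrap

def test_two_clade_split_gets_high_support():
    msa, clade_of = simulate.simulate_protein_clades(
        seed=21, n_clades=2, per_clade=4, length=150,
        between_p=0.5, within_p=0.03)
    tree = phylogeny.bootstrap_support(msa, n_reps=100, seed=1)
    supports = [int(n.label) for n in tree.preorder_node_iter()
                if n.label and not n.is_leaf()]
    clade1 = frozenset(k for k, v in clade_of.items() if v == 1)
    # find the inter-clade bipartition's support
    found = None
    labels = sorted(msa)
    for node in tree.preorder_node_iter():
        if node.is_leaf() or node.parent_node is None or not node.label:
            continue
        side = frozenset(lf.taxon.label for lf in node.leaf_iter())
        if side in (clade1, frozenset(labels) - clade1):
            found = int(node.label)
    assert found is not None and found >= 95


def test_bootstrap_deterministic_for_fixed_seed():
    msa, _ = simulate.simulate_protein_clades(seed=2, n_clades=2,
                                              per_clade=3, length=80)
    t1 = phylogeny.bootstrap_support(msa, n_reps=20, seed=9)
    t2 = phylogeny.bootstrap_support(msa, n_reps=20, seed=9)
    assert t1.as_string(schema="newick") == t2.as_string(schema="newick")


# ---------------------------------------------------------------------------
# subfamily assignment

def _star_free_tree(newick):
    return dendropy.Tree.get(data=newick, schema="newick",
                             preserve_underscores=True)


def test_leaf_sister_to_single_anchor_takes_its_label():
    tree = _star_free_tree("((q1:1,gt_anchor:1):1,(x:1,y:1):1);")
    out = phylogeny.assign_subfamilies(tree, {"gt_anchor": "GT-gamma",
                                              "x": "SIP1", "y": "SIP1"})
    assert out.assignments["q1"] == "GT-gamma"


def test_mixed_anchor_clade_leaves_query_unassigned():
    tree = _star_free_tree("((q1:1,(a_sip:1,a_sh4:1):1):1,(b:1,c:1):1);")
    out = phylogeny.assign_subfamilies(
        tree, {"a_sip": "SIP1", "a_sh4": "SH4", "b": "GT-1", "c": "GT-1"})
    assert out.assignments["q1"] == ""
    assert "mixes" in out.diagnostics["q1"]


def test_simulated_clades_assigned_perfectly():
    msa, clade_of = simulate.simulate_protein_clades(
        seed=31, n_clades=5, per_clade=7, length=200,
        between_p=0.5, within_p=0.04)
    tree = phylogeny.neighbor_joining(phylogeny.protein_distance(msa))
    fam_names = dict(enumerate(phylogeny.SUBFAMILIES, start=1))
    anchors = {}
    queries = {}
    for leaf, clade in clade_of.items():
        if leaf.endswith(("m1", "m2", "m3")):
            anchors[leaf] = fam_names[clade]
        else:
            queries[leaf] = fam_names[clade]
    out = phylogeny.assign_subfamilies(tree, anchors)
    assert all(out.assignments[q] == fam for q, fam in queries.items())


def test_missing_anchor_subfamily_is_error():
    tree = _star_free_tree("((a:1,b:1):1,c:1);")
    with pytest.raises(phylogeny.PhyloError, match="SH4"):
        phylogeny.assign_subfamilies(tree, {"a": "SIP1"},
                                     required=("SIP1", "SH4"))


def test_subfamily_percentages_sum_to_100():
    assign = phylogeny.SubfamilyAssignment(
        {"g1": "SIP1", "g2": "SIP1", "g3": "SH4", "g4": "SIP1"}, {})
    species = {"g1": "Pe", "g2": "Os", "g3": "Pe", "g4": "Pe"}
    pct = phylogeny.subfamily_percentages(assign, species)
    assert all(abs(row - 100.0) <= 0.5 for row in pct.sum(axis=1))
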