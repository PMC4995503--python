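"""Distance trees, NJ recovery, bootstrap and marker classification."""

import math

import dendropy
import numpy as np
import pytest

from glrfamevo.core_model import Alignment, read_newick
from glrfamevo.phylo_classify import (DistanceMatrix, bootstrap_support,
                                      classify_by_markers, neighbor_joining,
                                      protein_distance, sister_clade_test)


def _leafset_splits(tree):
    return {frozenset(lf.taxon.label for lf in n.leaf_iter())
            for n in tree.preorder_node_iter()
            if not n.is_leaf() and n.parent_node is not None}


def _topologies_equal(t1, t2):
    leaves = frozenset(lf.taxon.label for lf in t1.leaf_node_iter())

    def norm(splits):
        ref = min(leaves)
        return {s if ref not in s else leaves - s
                for s in splits if 1 < len(s) < len(leaves) - 1}

    return norm(_leafset_splits(t1)) == norm(_leafset_splits(t2))


# ---------------------------------------------------------------------------
# Distances
# ---------------------------------------------------------------------------

def test_identical_rows_zero_distance():
    aln = Alignment(["a", "b"], ["MKVL", "MKVL"])
    dm = protein_distance(aln)
    assert dm.get("a", "b") == 0.0


def test_saturated_pair_flagged_nan():
    aln = Alignment(["a", "b"], ["MMMM", "KKKK"])
    dm = protein_distance(aln, correction="kimura")
    assert math.isnan(dm.get("a", "b"))
    assert protein_distance(aln, correction="p").get("a", "b") == 1.0


def test_kimura_closed_form_at_p_tenth():
    # 1 mismatch in 10 comparable columns
    aln = Alignment(["a", "b"], ["MKVLWDEKRA", "MKVLWDEKRV"])
    dm = protein_distance(aln, correction="kimura")
    assert dm.get("a", "b") == pytest.approx(-math.log(1 - 0.1 - 0.01 / 5))


def test_gap_columns_excluded_from_comparison():
    aln = Alignment(["a", "b"], ["MKV-", "MKVL"])
    assert protein_distance(aln, correction="p").get("a", "b") == 0.0


# ---------------------------------------------------------------------------
# Neighbor joining
# ---------------------------------------------------------------------------

def test_two_taxa_splits_distance_evenly():
    dm = DistanceMatrix(["a", "b"], np.array([[0.0, 0.4], [0.4, 0.0]]))
    tree = neighbor_joining(dm)
    for lf in tree.leaf_node_iter():
        assert lf.edge.length == pytest.approx(0.2)


def test_three_taxa_closed_form_branch_lengths():
    d = np.array([[0.0, 0.3, 0.5], [0.3, 0.0, 0.6], [0.5, 0.6, 0.0]])
    tree = neighbor_joining(DistanceMatrix(["a", "b", "c"], d))
    lengths = {lf.taxon.label: lf.edge.length for lf in tree.leaf_node_iter()}
    assert lengths["a"] == pytest.approx((0.3 + 0.5 - 0.6) / 2)
    assert lengths["b"] == pytest.approx((0.3 + 0.6 - 0.5) / 2)
    assert lengths["c"] == pytest.approx((0.5 + 0.6 - 0.3) / 2)


def _random_additive_matrix(rng, n_taxa):
    """Random binary tree with positive branch lengths -> additive matrix."""
    taxa = [f"t{i}" for i in range(n_taxa)]
    tns = dendropy.TaxonNamespace(taxa)
    tree = dendropy.simulate.treesim.birth_death_tree(
        birth_rate=1.0, death_rate=0.0, num_extant_tips=n_taxa,
        taxon_namespace=tns, rng=__import__("random").Random(int(rng.integers(1e9))))
    for edge in tree.preorder_edge_iter():
        if edge.head_node.parent_node is not None:
            edge.length = float(rng.uniform(0.05, 1.0))
    pdm = tree.phylogenetic_distance_matrix()
    labels = [t.label for t in tns]
    D = np.zeros((n_taxa, n_taxa))
    for i in range(n_taxa):
        for j in range(i + 1, n_taxa):
            D[i, j] = D[j, i] = pdm.patristic_distance(tns[i], tns[j])
    return DistanceMatrix(labels, D), tree


@pytest.mark.parametrize("seed", range(5))
def test_nj_recovers_additive_topology(seed):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(6, 11))
    dm, true_tree = _random_additive_matrix(rng, n)
    nj_tree = neighbor_joining(dm)
    assert _topologies_equal(nj_tree, true_tree)


def test_nj_matches_skbio_on_additive_matrix():
    from skbio import DistanceMatrix as SkDM
    from skbio.tree import nj as sk_nj

    rng = np.random.default_rng(42)
    dm, _ = _random_additive_matrix(rng, 7)
    ours = neighbor_joining(dm)
    sk_tree = sk_nj(SkDM(dm.values, dm.ids))
    sk_nwk = read_newick(str(sk_tree).strip())
    assert _topologies_equal(ours, sk_nwk)


def test_nj_branch_lengths_non_negative():
    rng = np.random.default_rng(77)
    d = rng.uniform(0.1, 1.0, size=(6, 6))
    d = (d + d.T) / 2
    np.fill_diagonal(d, 0.0)
    tree = neighbor_joining(DistanceMatrix([f"x{i}" for i in range(6)], d))
    for edge in tree.preorder_edge_iter():
        if edge.length is not None:
            assert edge.length >= 0


# ---------------------------------------------------------------------------
# Bootstrap
# ---------------------------------------------------------------------------

def _two_clade_alignment():
    rows = {"a1": "MMMMMMKKKK", "a2": "MMMMMMKKKK",
            "b1": "WWWWWWEEEE", "b2": "WWWWWWEEEE"}
    # small within-clade noise so distances are non-degenerate
    rows["a2"] = "MMMMMLKKKK"
    rows["b2"] = "WWWWWFEEEE"
    return Alignment(list(rows), list(rows.values()))


def test_perfect_split_gets_full_support():
    tree = bootstrap_support(_two_clade_alignment(), n_reps=50,
                             correction="p", seed=0)
    supports = [int(n.label) for n in tree.preorder_node_iter()
                if not n.is_leaf() and n.parent_node is not None
                and n.label is not None]
    assert supports and all(s == 100 for s in supports)


def test_no_replicates_no_supports():
    tree = bootstrap_support(_two_clade_alignment(), n_reps=0, correction="p")
    labels = [n.label for n in tree.preorder_node_iter()
              if not n.is_leaf() and n.parent_node is not None]
    assert all(lb is None for lb in labels)


def test_bootstrap_seed_determinism():
    t1 = bootstrap_support(_two_clade_alignment(), 30, "p", seed=5)
    t2 = bootstrap_support(_two_clade_alignment(), 30, "p", seed=5)
    assert t1.as_string(schema="newick") == t2.as_string(schema="newick")


# ---------------------------------------------------------------------------
# Marker classification
# ---------------------------------------------------------------------------

def _subfamily_alignment(rng, n_queries_per=3):
    """Four divergent clusters + one marker each + a GLR0 outgroup marker."""
    bases = {"GLR1&2": "MKVLWDEKRA", "GLR3": "FFYYHHWWPP",
             "GLR4": "DDEEKKRRSS", "GLR0": "GGGGGCCCCC"}
    ids, rows, markers, truth = [], [], {}, {}
    for label, base in bases.items():
        marker_id = f"mk_{label.replace('&', '')}"
        ids.append(marker_id)
        rows.append(base * 3)
        markers[marker_id] = label
        n = 1 if label == "GLR0" else n_queries_per
        for q in range(n if label != "GLR0" else 0):
            qid = f"q_{label.replace('&', '')}_{q}"
            seq = list(base * 3)
            pos = rng.integers(0, len(seq))
            seq[pos] = "ACDEFGHIKLMNPQRSTVWY"[rng.integers(0, 20)]
            ids.append(qid)
            rows.append("".join(seq))
            truth[qid] = label
    return Alignment(ids, rows), markers, truth


def test_planted_subfamilies_classified_correctly():
    rng = np.random.default_rng(3)
    aln, markers, truth = _subfamily_alignment(rng)
    tree = bootstrap_support(aln, n_reps=20, correction="p", seed=1)
    assignments = classify_by_markers(tree, markers)
    got = {a.query: a.label for a in assignments}
    assert got == truth


def test_no_markers_reachable_unassigned():
    tree = read_newick("((q1:0.1,q2:0.1):0.1,q3:0.2);")
    assignments = classify_by_markers(tree, {})
    assert all(a.label == "unassigned" for a in assignments)


def test_classification_stable_under_rerooting():
    rng = np.random.default_rng(9)
    aln, markers, truth = _subfamily_alignment(rng)
    tree = bootstrap_support(aln, n_reps=0, correction="p")
    base = {a.query: a.label for a in classify_by_markers(tree, markers)}
    # reroot at an arbitrary non-outgroup leaf edge and classify again
    tree2 = tree.clone(depth=1)
    leaf = tree2.find_node_with_taxon_label("mk_GLR3")
    tree2.to_outgroup_position(leaf, update_bipartitions=False)
    again = {a.query: a.label for a in classify_by_markers(tree2, markers)}
    assert base == again


# ---------------------------------------------------------------------------
# Sister clades
# ---------------------------------------------------------------------------

def test_sister_clades_detected():
    tree = read_newick("(((A1:1,A2:1):1,(B1:1,B2:1):1):1,(C1:1,C2:1):1,D:2);")
    assert sister_clade_test(tree, ["A1", "A2"], ["B1", "B2"]) == "sister"


def test_nested_when_one_group_paraphyletic():
    tree = read_newick("(((A1:1,B1:1):1,(A2:1,B2:1):1):1,C1:1,C2:2);")
    assert sister_clade_test(tree, ["A1", "A2"], ["B1", "B2"]) == "nested"


def test_neither_when_interleaved():
    tree = read_newick("(((A1:1,C1:1):1,(B1:1,C2:1):1):1,(A2:1,B2:1):1,D:2);")
    assert sister_clade_test(tree, ["A1", "A2"], ["B1", "B2"]) == "neither"
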