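"""Distance trees with bootstrap and marker-anchored subfamily assignment.

Trees are built by neighbor joining on corrected protein distances, with
bootstrap supports from column resampling. Query sequences are classified
by their placement relative to labelled marker (anchor) sequences: the
smallest clade containing the query and at least one marker decides the
subfamily when its markers agree, otherwise the nearest marker by path
length decides (flagged ``method=nearest``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import dendropy
import numpy as np

from .core_model import Alignment, read_newick, write_tsv


@dataclass
class DistanceMatrix:
    ids: list[str]
    values: np.ndarray  # symmetric, zero diagonal; NaN = undefined

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValueError("shape mismatch")
        if not np.allclose(np.nan_to_num(self.values),
                           np.nan_to_num(self.values.T), atol=1e-12):
            raise ValueError("matrix not symmetric")

    def get(self, a: str, b: str) -> float:
        return float(self.values[self.ids.index(a), self.ids.index(b)])


@dataclass(frozen=True)
class SubfamilyAssignment:
    query: str
    label: str           # subfamily or 'unassigned'
    support: int | None  # bootstrap % of the anchoring clade
    method: str          # clade | nearest | none


# ---------------------------------------------------------------------------
# Distances
# ---------------------------------------------------------------------------

def protein_distance(aln: Alignment, correction: str = "kimura") -> DistanceMatrix:
    """Pairwise protein distances: p (mismatch proportion over comparable
    non-gap columns) or the Kimura correction -ln(1 - p - p^2/5).

    Saturated pairs (correction undefined) and pairs without comparable
    columns get NaN entries.
    """
    if correction not in ("p", "kimura"):
        raise ValueError(f"unknown correction {correction!r}")
    n = aln.n_rows
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            both = diff = 0
            for a, b in zip(aln.rows[i], aln.rows[j]):
                if a != "-" and b != "-":
                    both += 1
                    if a != b:
                        diff += 1
            if both == 0:
                d = math.nan
            else:
                p = diff / both
                if correction == "p":
                    d = p
                else:
                    arg = 1.0 - p - p * p / 5.0
                    d = -math.log(arg) if arg > 0 else math.nan
            D[i, j] = D[j, i] = d
    return DistanceMatrix(list(aln.ids), D)


# ---------------------------------------------------------------------------
# Neighbor joining
# ---------------------------------------------------------------------------

def neighbor_joining(dm: DistanceMatrix) -> dendropy.Tree:
    """Standard NJ agglomeration with deterministic id-order tie-breaks.

    Negative branch lengths are clamped to 0 with the deficit moved to the
    sibling edge. Returns an unrooted tree (trifurcating root for > 3 taxa).
    """
    if not np.isfinite(dm.values).all():
        raise ValueError("distance matrix contains undefined entries")
    n0 = len(dm.ids)
    if n0 < 2:
        raise ValueError("need >= 2 taxa")
    if n0 == 2:
        d = dm.values[0, 1]
        nw = f"({dm.ids[0]}:{d / 2:.9f},{dm.ids[1]}:{d / 2:.9f});"
        return read_newick(nw)

    # clusters: (newick fragment, representative label for tie-breaks)
    clusters = [(cid, cid) for cid in dm.ids]
    D = {}
    for i in range(n0):
        for j in range(i + 1, n0):
            D[frozenset((dm.ids[i], dm.ids[j]))] = float(dm.values[i, j])

    def dist(a, b):
        return D[frozenset((a[1], b[1]))]

    while len(clusters) > 3:
        m = len(clusters)
        r = {c[1]: sum(dist(c, o) for o in clusters if o is not c)
             for c in clusters}
        best = None
        for i in range(m):
            for j in range(i + 1, m):
                ci, cj = clusters[i], clusters[j]
                q = (m - 2) * dist(ci, cj) - r[ci[1]] - r[cj[1]]
                key = (q, min(ci[1], cj[1]), max(ci[1], cj[1]))
                if best is None or key < best[0]:
                    best = (key, i, j)
        _, i, j = best
        ci, cj = clusters[i], clusters[j]
        dij = dist(ci, cj)
        li = dij / 2 + (r[ci[1]] - r[cj[1]]) / (2 * (m - 2))
        lj = dij - li
        if li < 0:
            lj += li
            li = 0.0
        if lj < 0:
            li += lj
            lj = 0.0
        li, lj = max(li, 0.0), max(lj, 0.0)
        rep = min(ci[1], cj[1])
        frag = f"({ci[0]}:{li:.9f},{cj[0]}:{lj:.9f})"
        new = (frag, rep)
        for other in clusters:
            if other is ci or other is cj:
                continue
            duk = (dist(ci, other) + dist(cj, other) - dij) / 2
            D[frozenset((rep, other[1]))] = max(duk, 0.0)
        clusters = [c for c in clusters if c is not ci and c is not cj] + [new]

    (a, b, c) = sorted(clusters, key=lambda x: x[1])
    dab, dac, dbc = dist(a, b), dist(a, c), dist(b, c)
    la = max((dab + dac - dbc) / 2, 0.0)
    lb = max((dab + dbc - dac) / 2, 0.0)
    lc = max((dac + dbc - dab) / 2, 0.0)
    nw = f"({a[0]}:{la:.9f},{b[0]}:{lb:.9f},{c[0]}:{lc:.9f});"
    return read_newick(nw)


# ---------------------------------------------------------------------------
# Bootstrap
# ---------------------------------------------------------------------------

def _bipartitions(tree: dendropy.Tree, all_leaves: frozenset[str]
                  ) -> dict[frozenset[str], dendropy.Node]:
    """Non-trivial bipartitions as normalized leaf sets (the side not
    containing the alphabetically first leaf)."""
    ref = min(all_leaves)
    out = {}
    for node in tree.preorder_node_iter():
        if node.is_leaf() or node.parent_node is None:
            continue
        side = frozenset(lf.taxon.label for lf in node.leaf_iter())
        if len(side) < 2 or len(all_leaves - side) < 2:
            continue
        norm = all_leaves - side if ref in side else side
        out[norm] = node
    return out


def bootstrap_support(aln: Alignment, n_reps: int = 100,
                      correction: str = "kimura",
                      seed: int = 0) -> dendropy.Tree:
    """NJ tree with bootstrap supports: alignment columns are resampled
    with replacement per replicate and each original internal bipartition
    is annotated with the % of replicate trees containing it."""
    tree = neighbor_joining(protein_distance(aln, correction))
    if n_reps <= 0:
        return tree
    rng = np.random.default_rng(seed)
    leaves = frozenset(aln.ids)
    target = _bipartitions(tree, leaves)
    counts = {bp: 0 for bp in target}
    L = aln.length
    for _ in range(n_reps):
        cols = rng.integers(0, L, size=L)
        rows = ["".join(row[c] for c in cols) for row in aln.rows]
        rep_aln = Alignment(list(aln.ids), rows, aln.alphabet)
        try:
            rep_tree = neighbor_joining(protein_distance(rep_aln, correction))
        except ValueError:  # saturated replicate distances
            continue
        rep_bps = _bipartitions(rep_tree, leaves)
        for bp in counts:
            if bp in rep_bps:
                counts[bp] += 1
    for bp, node in target.items():
        node.label = str(round(100 * counts[bp] / n_reps))
    return tree


# ---------------------------------------------------------------------------
# Marker classification
# ---------------------------------------------------------------------------

def _reroot_for_markers(tree: dendropy.Tree, markers: dict[str, str],
                        outgroup_label: str = "GLR0") -> dendropy.Tree:
    tree = tree.clone(depth=1)
    out_ids = [m for m, lab in markers.items() if lab == outgroup_label]
    if out_ids:
        node = tree.find_node_with_taxon_label(sorted(out_ids)[0])
        if node is not None:
            tree.to_outgroup_position(node, update_bipartitions=False)
            return tree
    tree.reroot_at_midpoint(update_bipartitions=False)
    return tree


def classify_by_markers(tree: dendropy.Tree, markers: dict[str, str],
                        outgroup_label: str = "GLR0"
                        ) -> list[SubfamilyAssignment]:
    """Assign each non-marker leaf a subfamily by the smallest clade it
    shares with a marker (clade rule), falling back to the nearest marker
    by path length when that clade's markers disagree."""
    tree = _reroot_for_markers(tree, markers, outgroup_label)
    pdm = tree.phylogenetic_distance_matrix()
    taxa = {t.label: t for t in tree.taxon_namespace}
    assignments = []
    queries = sorted(t for t in taxa if t not in markers)
    marker_ids = sorted(m for m in markers if m in taxa)
    for q in queries:
        node = tree.find_node_with_taxon_label(q)
        assigned = None
        while node.parent_node is not None:
            node = node.parent_node
            clade_markers = [lf.taxon.label for lf in node.leaf_iter()
                             if lf.taxon.label in markers]
            if clade_markers:
                labels = {markers[m] for m in clade_markers}
                support = None
                if node.label is not None:
                    try:
                        support = int(float(node.label))
                    except ValueError:
                        support = None
                if len(labels) == 1:
                    assigned = SubfamilyAssignment(q, labels.pop(), support,
                                                   "clade")
                else:
                    nearest = min(
                        marker_ids,
                        key=lambda m: (pdm.patristic_distance(taxa[q], taxa[m]), m))
                    assigned = SubfamilyAssignment(q, markers[nearest], support,
                                                   "nearest")
                break
        if assigned is None:
            assigned = SubfamilyAssignment(q, "unassigned", None, "none")
        assignments.append(assigned)
    return assignments


# ---------------------------------------------------------------------------
# Sister-clade testing
# ---------------------------------------------------------------------------

def _is_split(side: frozenset[str], splits: set[frozenset[str]],
              all_leaves: frozenset[str]) -> bool:
    if len(side) == 1 or len(side) == len(all_leaves) - 1:
        return True  # trivial splits always exist on an unrooted tree
    return side in splits or (all_leaves - side) in splits


def sister_clade_test(tree: dendropy.Tree, group_a: list[str],
                      group_b: list[str]) -> str:
    """Test two leaf groups on an unrooted tree: 'sister' when A, B and
    A|B are all monophyletic; 'nested' when A|B is monophyletic but one of
    A, B is not; 'neither' otherwise."""
    all_leaves = frozenset(lf.taxon.label for lf in tree.leaf_node_iter())
    A, B = frozenset(group_a), frozenset(group_b)
    if not A or not B or (A & B):
        raise ValueError("groups must be non-empty and disjoint")
    if not (A <= all_leaves and B <= all_leaves):
        raise ValueError("group members missing from tree")
    splits = set()
    for node in tree.preorder_node_iter():
        if node.is_leaf() or node.parent_node is None:
            continue
        splits.add(frozenset(lf.taxon.label for lf in node.leaf_iter()))
    union_mono = _is_split(A | B, splits, all_leaves)
    a_mono = _is_split(A, splits, all_leaves)
    b_mono = _is_split(B, splits, all_leaves)
    if union_mono and a_mono and b_mono:
        return "sister"
    if union_mono:
        return "nested"
    return "neither"


def write_assignments(assignments: list[SubfamilyAssignment], path) -> None:
    write_tsv(path, ["query", "subfamily", "support", "method"],
              [[a.query, a.label, a.support, a.method] for a in assignments])
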