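"""Planted-truth validation benchmarks.

Each routine regenerates synthetic data under the package's study
conditions, runs the corresponding pipeline stage, and measures recovery
against the planted truth. They back both the acceptance test suite and
the ``scripts/acceptance.py`` reproduction script.
"""

from __future__ import annotations

import numpy as np

from . import conservation_structure as cons
from . import expression_analysis as expr
from . import phylo_classify as phylo
from . import synteny_duplication as dup
from . import synthetic_data as synth
from .selection_analysis import m0_fit, ng86_alignment

MODES = ("tandem", "wgd_segmental", "dispersed", "singleton")

# Family-composition grid spanning arrays-only, mixed, blocks-heavy and
# array-size extremes; cycled over seeds to give >= 20 distinct genomes.
FAMILY_GRID = (
    dict(n_tandem_arrays=1, array_sizes=(3,), n_segmental_blocks=0,
         n_dispersed=0, n_singletons=0),
    dict(n_tandem_arrays=2, array_sizes=(3, 2), n_segmental_blocks=1,
         n_dispersed=2, n_singletons=1),
    dict(n_tandem_arrays=3, array_sizes=(2, 2, 4), n_segmental_blocks=0,
         n_dispersed=1, n_singletons=0),
    dict(n_tandem_arrays=0, array_sizes=(), n_segmental_blocks=2,
         block_gene_count=6, n_dispersed=3, n_singletons=2),
    dict(n_tandem_arrays=2, array_sizes=(5, 2), n_segmental_blocks=1,
         block_gene_count=7, n_dispersed=0, n_singletons=1),
)


def duplication_mode_recovery(n_genomes: int = 20, seed: int = 0) -> dict:
    """Per-mode recovery of planted duplication modes over a grid of
    synthetic genomes (classification runs on the planted homology
    relation, so this isolates the chain/classification logic)."""
    correct = {m: 0 for m in MODES}
    total = {m: 0 for m in MODES}
    for i in range(n_genomes):
        spec = synth.FamilySpec(**FAMILY_GRID[i % len(FAMILY_GRID)])
        gs, truth, _ = synth.simulate_genome(4, 150, spec,
                                             seed=seed * 1000 + i)
        pairs = [dup.HomologPair(a, b) for a, b in truth.pairs]
        blocks = dup.detect_collinear_chains(pairs, gs)
        calls = dup.classify_duplications(
            gs, pairs, blocks, family_genes=sorted(truth.family_genes))
        pred = {c.gene_id: c.mode for c in calls}
        for g, m in truth.mode.items():
            total[m] += 1
            correct[m] += pred[g] == m
    per_mode = {m: (correct[m] / total[m] if total[m] else None)
                for m in MODES}
    observed = [v for v in per_mode.values() if v is not None]
    return {"per_mode": per_mode, "min_accuracy": min(observed),
            "n_genomes": n_genomes,
            "n_genes": sum(total.values())}


def _oracle_longest_chain(anchors: list[tuple[int, int]], max_gap: int) -> int:
    """Exhaustive longest collinear chain (forward or inverted)."""
    best = 1 if anchors else 0
    n = len(anchors)

    def extend(last: int, used: frozenset, inverted: bool) -> None:
        nonlocal best
        best = max(best, len(used))
        la, lb = anchors[last]
        for i in range(n):
            if i in used:
                continue
            ra, rb = anchors[i]
            da = ra - la
            db = (lb - rb) if inverted else (rb - lb)
            if 0 < da <= max_gap and 0 < db <= max_gap:
                extend(i, used | {i}, inverted)

    for inverted in (False, True):
        for i in range(n):
            extend(i, frozenset((i,)), inverted)
    return best


def chain_oracle_agreement(n_instances: int = 30, seed: int = 0) -> dict:
    """Compare DP chaining with brute-force enumeration on random
    instances of <= 12 anchors."""
    from .core_model import Gene, GeneSet

    rng = np.random.default_rng(seed)
    genes = [Gene(f"A_g{i:03d}", "A", 1 + i * 1000, 500 + i * 1000)
             for i in range(60)]
    genes += [Gene(f"B_g{i:03d}", "B", 1 + i * 1000, 500 + i * 1000)
              for i in range(60)]
    gs = GeneSet("t", genes)
    agree = 0
    for _ in range(n_instances):
        n = int(rng.integers(5, 13))
        ranks_a = sorted(rng.choice(60, size=n, replace=False).tolist())
        ranks_b = rng.choice(60, size=n, replace=False).tolist()
        pairs = [dup.HomologPair(f"A_g{ra:03d}", f"B_g{rb:03d}")
                 for ra, rb in zip(ranks_a, ranks_b)]
        blocks = dup.detect_collinear_chains(pairs, gs, min_block_pairs=2,
                                             max_rank_gap=25)
        dp_best = max((len(b.anchors) for b in blocks), default=1)
        oracle = max(_oracle_longest_chain(list(zip(ranks_a, ranks_b)), 25), 1)
        agree += dp_best == oracle
    return {"agreement": agree / n_instances, "n_instances": n_instances}


OMEGA_GRID = (0.1, 0.3, 1.0)
T_GRID = (0.2, 0.8)


def omega_recovery(n_replicates: int = 20, length: int = 500,
                   seed: int = 0, kappa: float = 2.0) -> dict:
    """Median omega recovery for NG86 and M0 over the (omega, t) grid."""
    grid = {}
    worst = {"NG86": 0.0, "M0": 0.0}
    for omega in OMEGA_GRID:
        for t in T_GRID:
            ng, m0 = [], []
            for rep in range(n_replicates):
                aln, _ = synth.evolve_codon_sequences(
                    length, omega, kappa, t, seed=seed * 1000 + rep)
                e = ng86_alignment(aln)
                if e.status == "ok":
                    ng.append(e.omega)
                m = m0_fit(aln, seed=seed)
                if m.status == "ok":
                    m0.append(m.omega)
            med_ng = float(np.median(ng))
            med_m0 = float(np.median(m0))
            grid[(omega, t)] = {"NG86": med_ng, "M0": med_m0}
            worst["NG86"] = max(worst["NG86"], abs(med_ng - omega) / omega)
            worst["M0"] = max(worst["M0"], abs(med_m0 - omega) / omega)
    return {"grid": grid, "worst_rel_err": worst,
            "n_replicates": n_replicates, "length": length}


def conserved_interval_recovery(n_seeds: int = 20, seed: int = 0) -> dict:
    """Fraction of seeds where planted conserved intervals exceed the
    background mean window score."""
    wins = 0
    for s in range(n_seeds):
        aln, truth = synth.simulate_msa(8, 100, [(31, 60)],
                                        seed=seed * 1000 + s)
        profile = cons.conservation_profile(aln)
        planted = cons.region_mean(profile, (31, 60))
        background = (cons.region_mean(profile, (1, 30))
                      + cons.region_mean(profile, (61, 100))) / 2
        wins += planted > background
    return {"fraction": wins / n_seeds, "n_seeds": n_seeds}


def nj_topology_recovery(n_trees: int = 20, seed: int = 0) -> dict:
    """NJ recovery of random additive-matrix topologies (6-10 taxa)."""
    import random

    import dendropy

    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_trees):
        n = int(rng.integers(6, 11))
        taxa = [f"t{i}" for i in range(n)]
        tns = dendropy.TaxonNamespace(taxa)
        tree = dendropy.simulate.treesim.birth_death_tree(
            birth_rate=1.0, death_rate=0.0, num_extant_tips=n,
            taxon_namespace=tns, rng=random.Random(int(rng.integers(2**31))))
        for edge in tree.preorder_edge_iter():
            if edge.head_node.parent_node is not None:
                edge.length = float(rng.uniform(0.05, 1.0))
        pdm = tree.phylogenetic_distance_matrix()
        D = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                D[i, j] = D[j, i] = pdm.patristic_distance(tns[i], tns[j])
        nj_tree = phylo.neighbor_joining(phylo.DistanceMatrix(taxa, D))
        leaves = frozenset(taxa)

        def splits(t):
            ref = min(leaves)
            out = set()
            for node in t.preorder_node_iter():
                if node.is_leaf() or node.parent_node is None:
                    continue
                s = frozenset(lf.taxon.label for lf in node.leaf_iter())
                if 1 < len(s) < n - 1:
                    out.add(s if ref not in s else leaves - s)
            return out

        hits += splits(nj_tree) == splits(tree)
    return {"recovery": hits / n_trees, "n_trees": n_trees}


def marker_classification_accuracy(n_trials: int = 5, seed: int = 0) -> dict:
    """Marker-anchored subfamily classification on planted 4-cluster
    alignments with one anchor per subfamily plus a GLR0 outgroup."""
    bases = {"GLR1&2": "MKVLWDEKRA", "GLR3": "FFYYHHWWPP",
             "GLR4": "DDEEKKRRSS", "GLR0": "GGGGGCCCCC"}
    correct = total = 0
    for trial in range(n_trials):
        rng = np.random.default_rng(seed * 100 + trial)
        ids, rows, markers, truth = [], [], {}, {}
        for label, base in bases.items():
            mid = f"mk_{label.replace('&', '')}"
            ids.append(mid)
            rows.append(base * 3)
            markers[mid] = label
            if label == "GLR0":
                continue
            for q in range(3):
                qid = f"q_{label.replace('&', '')}_{q}"
                seq = list(base * 3)
                pos = int(rng.integers(0, len(seq)))
                seq[pos] = "ACDEFGHIKLMNPQRSTVWY"[rng.integers(0, 20)]
                ids.append(qid)
                rows.append("".join(seq))
                truth[qid] = label
        from .core_model import Alignment

        aln = Alignment(ids, rows)
        tree = phylo.bootstrap_support(aln, n_reps=20, correction="p",
                                       seed=seed * 100 + trial)
        got = {a.query: a.label
               for a in phylo.classify_by_markers(tree, markers)}
        for q, lab in truth.items():
            total += 1
            correct += got[q] == lab
    return {"accuracy": correct / total, "n_queries": total}


def expression_cluster_recovery(n_seeds: int = 10, seed: int = 0) -> dict:
    """K-means ARI against planted clusters at 10-sigma separation."""
    tissues = ["root", "stem", "cambium"]
    sd = 0.5
    sep = 10 * sd
    specs = [synth.ExpressionClusterSpec("a", (sep, 0.0, 0.0), sd, 6),
             synth.ExpressionClusterSpec("b", (0.0, sep, 0.0), sd, 6),
             synth.ExpressionClusterSpec("c", (0.0, 0.0, sep), sd, 6)]
    aris = []
    for s in range(n_seeds):
        mat, truth = synth.simulate_expression(tissues, specs,
                                               seed=seed * 1000 + s)
        assignment = expr.kmeans_cluster(mat, k=3, seed=seed * 1000 + s)
        aris.append(expr.clustering_ari(assignment, truth["cluster"]))
    return {"min_ari": min(aris), "mean_ari": float(np.mean(aris)),
            "n_seeds": n_seeds}
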