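"""Homolog pairs, collinear chains and duplication-mode classification."""

import itertools

import numpy as np
import pytest

from glrfamevo.core_model import Gene, GeneSet, SequenceRecord
from glrfamevo.synteny_duplication import (HomologPair, classify_duplications,
                                           detect_collinear_chains,
                                           find_homolog_pairs,
                                           group_tandem_arrays,
                                           tandem_fraction_from_calls,
                                           tandem_related_fraction)


def _geneset(n_per_chrom: dict[str, int]) -> GeneSet:
    genes = []
    for chrom, n in n_per_chrom.items():
        for i in range(n):
            genes.append(Gene(f"{chrom}_g{i:03d}", chrom, 1 + i * 1000,
                              500 + i * 1000))
    return GeneSet("t", genes)


# ---------------------------------------------------------------------------
# Homolog pairs
# ---------------------------------------------------------------------------

def test_three_identical_proteins_all_pairs():
    prots = [SequenceRecord(f"p{i}", "MKVLWDEKRAGHILMNPQ") for i in range(3)]
    pairs = find_homolog_pairs(prots, score_threshold=20)
    assert len(pairs) == 3


def test_unrelated_background_yields_no_pairs(rng7):
    from conftest import random_protein

    fam = SequenceRecord("fam", random_protein(rng7, 80))
    bg = [SequenceRecord(f"bg{i}", random_protein(rng7, 80)) for i in range(3)]
    from glrfamevo.synteny_duplication import calibrate_pair_threshold

    thr = calibrate_pair_threshold([fam] + bg, n_shuffles=60, seed=1)
    pairs = find_homolog_pairs([fam] + bg, score_threshold=thr)
    assert pairs == []


def test_topk_closure_keeps_all_pairs_of_seven_identicals():
    prots = [SequenceRecord(f"p{i}", "MKVLWDEKRAGHILMNPQWY") for i in range(7)]
    pairs = find_homolog_pairs(prots, top_k=5, score_threshold=20)
    # each query keeps 5 hits but the symmetric closure restores all 21
    assert len(pairs) == 21
    per_gene = {}
    for p in pairs:
        per_gene[p.a] = per_gene.get(p.a, 0) + 1
        per_gene[p.b] = per_gene.get(p.b, 0) + 1
    assert all(v >= 5 for v in per_gene.values())


# ---------------------------------------------------------------------------
# Collinear chains
# ---------------------------------------------------------------------------

def _anchor_pairs(gs, ranks_a, ranks_b, chrom_a="A", chrom_b="B"):
    return [HomologPair(f"{chrom_a}_g{ra:03d}", f"{chrom_b}_g{rb:03d}")
            for ra, rb in zip(ranks_a, ranks_b)]


def test_planted_block_detected():
    gs = _geneset({"A": 30, "B": 30})
    pairs = _anchor_pairs(gs, [2, 5, 8, 11, 14], [3, 6, 9, 12, 15])
    blocks = detect_collinear_chains(pairs, gs)
    assert len(blocks) == 1 and len(blocks[0].anchors) == 5
    assert blocks[0].orientation == "same"


def test_large_gaps_break_chain():
    gs = _geneset({"A": 200, "B": 200})
    pairs = _anchor_pairs(gs, [0, 30, 60, 90, 120], [0, 30, 60, 90, 120])
    assert detect_collinear_chains(pairs, gs, max_rank_gap=25) == []


def test_inverted_block_detected():
    gs = _geneset({"A": 30, "B": 30})
    pairs = _anchor_pairs(gs, [2, 5, 8, 11, 14], [20, 17, 14, 11, 8])
    blocks = detect_collinear_chains(pairs, gs)
    assert len(blocks) == 1 and blocks[0].orientation == "inverted"


def _oracle_longest_chain(anchors, max_gap):
    """Exhaustive longest collinear chain over (rank_a, rank_b) anchors."""
    best = 1 if anchors else 0
    n = len(anchors)

    def extend(chain_last, used, inverted):
        nonlocal best
        best = max(best, len(used))
        for i in range(n):
            if i in used:
                continue
            ra, rb = anchors[i]
            la, lb = anchors[chain_last]
            da = ra - la
            db = (lb - rb) if inverted else (rb - lb)
            if 0 < da <= max_gap and 0 < db <= max_gap:
                extend(i, used | {i}, inverted)

    for inverted in (False, True):
        for i in range(n):
            extend(i, {i}, inverted)
    return best


@pytest.mark.parametrize("seed", range(6))
def test_chain_dp_matches_bruteforce_on_small_instances(seed):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(6, 13))
    ranks_a = sorted(rng.choice(60, size=n, replace=False).tolist())
    ranks_b = rng.choice(60, size=n, replace=False).tolist()
    gs = _geneset({"A": 60, "B": 60})
    pairs = _anchor_pairs(gs, ranks_a, ranks_b)
    anchors = list(zip(ranks_a, ranks_b))
    oracle_best = _oracle_longest_chain(anchors, max_gap=25)
    blocks = detect_collinear_chains(pairs, gs, min_block_pairs=2,
                                     max_rank_gap=25)
    dp_best = max((len(b.anchors) for b in blocks), default=1)
    assert dp_best == max(oracle_best, 1)


def test_unknown_gene_in_pair_errors():
    gs = _geneset({"A": 5})
    with pytest.raises(ValueError, match="unknown gene"):
        detect_collinear_chains([HomologPair("A_g000", "nope")], gs)


# ---------------------------------------------------------------------------
# Classification
# ---------------------------------------------------------------------------

def test_same_chromosome_close_homologs_are_tandem():
    gs = _geneset({"A": 20})
    pairs = [HomologPair("A_g002", "A_g008")]  # 5 intervening genes
    calls = classify_duplications(gs, pairs, [])
    assert {c.mode for c in calls} == {"tandem"}


def test_gene_without_homolog_is_singleton():
    gs = _geneset({"A": 5})
    calls = classify_duplications(gs, [], [], family_genes=["A_g000"])
    assert calls[0].mode == "singleton"


def test_block_anchor_priority_over_tandem():
    gs = _geneset({"A": 40, "B": 40})
    # fam pair close on chrom A AND members of a detected block
    chain = _anchor_pairs(gs, [2, 4, 6, 8, 10], [2, 4, 6, 8, 10])
    blocks = detect_collinear_chains(chain, gs)
    tandem_pair = HomologPair("A_g002", "A_g004")
    calls = classify_duplications(gs, chain + [tandem_pair], blocks,
                                  family_genes=["A_g002", "A_g004"])
    assert all(c.mode == "wgd_segmental" for c in calls)


def test_cross_chromosome_without_block_is_dispersed():
    gs = _geneset({"A": 10, "B": 10})
    pairs = [HomologPair("A_g001", "B_g001")]
    calls = classify_duplications(gs, pairs, [])
    assert {c.mode for c in calls} == {"dispersed"}


def test_boundary_exactly_ten_intervening_not_tandem():
    gs = _geneset({"A": 20})
    pairs = [HomologPair("A_g000", "A_g011")]  # 10 intervening
    calls = classify_duplications(gs, pairs, [])
    assert {c.mode for c in calls} == {"dispersed"}
    calls2 = classify_duplications(gs, [HomologPair("A_g000", "A_g010")], [])
    assert {c.mode for c in calls2} == {"tandem"}  # 9 intervening


def test_classification_invariant_under_relabeling_and_shift():
    gs1 = _geneset({"A": 20})
    pairs1 = [HomologPair("A_g002", "A_g005")]
    modes1 = [c.mode for c in classify_duplications(gs1, pairs1, [])]
    genes2 = [Gene(f"A_g{i:03d}", "chrZ", 50_000 + i * 777,
                   50_000 + i * 777 + 10) for i in range(20)]
    gs2 = GeneSet("t", genes2)
    modes2 = [c.mode for c in classify_duplications(gs2, pairs1, [])]
    assert modes1 == modes2


def test_every_gene_gets_exactly_one_call():
    gs = _geneset({"A": 30})
    fam = ["A_g000", "A_g003", "A_g020"]
    pairs = [HomologPair("A_g000", "A_g003")]
    calls = classify_duplications(gs, pairs, [], family_genes=fam)
    assert sorted(c.gene_id for c in calls) == sorted(fam)


# ---------------------------------------------------------------------------
# Tandem arrays and fractions
# ---------------------------------------------------------------------------

def test_single_array_of_three():
    gs = _geneset({"A": 30})
    pairs = [HomologPair("A_g002", "A_g004"), HomologPair("A_g004", "A_g006")]
    calls = classify_duplications(gs, pairs, [])
    arrays, summary = group_tandem_arrays(calls, gs)
    assert len(arrays) == 1 and arrays[0].members == ["A_g002", "A_g004", "A_g006"]


def test_two_arrays_mean_size():
    gs = _geneset({"A": 30, "B": 30})
    pairs = [HomologPair("A_g002", "A_g004"), HomologPair("A_g004", "A_g006"),
             HomologPair("B_g010", "B_g012")]
    calls = classify_duplications(gs, pairs, [])
    arrays, summary = group_tandem_arrays(calls, gs)
    assert summary["n_arrays"] == 2 and summary["mean_array_size"] == 2.5


def test_tandem_related_fraction_values():
    assert tandem_related_fraction(581, 881) == 65.95
    assert tandem_related_fraction(0, 50) == 0.00
    assert tandem_related_fraction(50, 50) == 100.00
    with pytest.raises(ValueError):
        tandem_related_fraction(5, 0)
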