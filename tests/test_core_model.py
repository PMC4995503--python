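"""Core types, format round-trips and pairwise alignment."""

import numpy as np
import pytest
from Bio.Align import substitution_matrices

from glrfamevo.core_model import (Alignment, Gene, GeneSet, ParseError,
                                  SequenceRecord, pairwise_align, read_fasta,
                                  read_gene_positions, read_newick,
                                  write_fasta, write_gene_positions,
                                  write_newick)

from conftest import random_protein


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def test_read_minimal_fasta(tmp_path):
    p = tmp_path / "x.fa"
    p.write_text(">a\nMKV\n")
    recs = read_fasta(p)
    assert len(recs) == 1 and recs[0].id == "a" and recs[0].residues == "MKV"


def test_fasta_round_trip(tmp_path):
    recs = [SequenceRecord("a", "MKVL"), SequenceRecord("b", "MMMM"),
            SequenceRecord("c", "ACDEFGHIKLMNPQRSTVWY" * 7)]
    p = tmp_path / "rt.fa"
    write_fasta(recs, p)
    back = read_fasta(p)
    assert [(r.id, r.residues) for r in back] == [(r.id, r.residues) for r in recs]


def test_fasta_duplicate_ids_rejected(tmp_path):
    p = tmp_path / "dup.fa"
    p.write_text(">a\nMKV\n>a\nMML\n")
    with pytest.raises(ParseError, match="duplicate"):
        read_fasta(p)


def test_fasta_malformed_header_reports_line(tmp_path):
    p = tmp_path / "bad.fa"
    p.write_text("MKV\n>a\nMKV\n")
    with pytest.raises(ParseError, match="line 1"):
        read_fasta(p)


# ---------------------------------------------------------------------------
# Gene positions
# ---------------------------------------------------------------------------

def test_bed_coordinate_conversion(tmp_path):
    p = tmp_path / "g.bed"
    p.write_text("chr1\t0\t100\tg1\t.\t+\n")
    gs = read_gene_positions(p, "bed")
    g = gs["g1"]
    assert (g.start, g.end, g.strand) == (1, 100, "+")


def test_ranks_by_start(tmp_path):
    p = tmp_path / "g.bed"
    p.write_text("chr1\t499\t600\tg2\t.\t-\nchr1\t9\t100\tg1\t.\t+\n")
    gs = read_gene_positions(p, "bed")
    assert gs.rank("g1") == 0 and gs.rank("g2") == 1


def test_gff3_end_before_start_errors(tmp_path):
    p = tmp_path / "g.gff3"
    p.write_text("chr1\tsrc\tgene\t500\t100\t.\t+\t.\tID=g1\n")
    with pytest.raises(ParseError, match="end"):
        read_gene_positions(p, "gff3")


def test_unknown_format_errors(tmp_path):
    with pytest.raises(ValueError, match="unknown format"):
        read_gene_positions(tmp_path / "x", "vcf")


@pytest.mark.parametrize("fmt", ["bed", "gff3"])
def test_position_round_trip_lossless(tmp_path, fmt, simple_geneset):
    p = tmp_path / f"rt.{fmt}"
    write_gene_positions(simple_geneset, p, fmt)
    back = read_gene_positions(p, fmt)
    for gid, g in simple_geneset.genes.items():
        b = back[gid]
        assert (b.chromosome, b.start, b.end, b.strand, b.rank) == \
            (g.chromosome, g.start, g.end, g.strand, g.rank)


def test_rank_order_matches_start_order(simple_geneset):
    for chrom, ids in simple_geneset.chromosomes.items():
        starts = [simple_geneset[g].start for g in ids]
        assert starts == sorted(starts)
        assert [simple_geneset[g].rank for g in ids] == list(range(len(ids)))


def test_tie_break_by_end_then_id():
    gs = GeneSet("t", [Gene("b", "c1", 10, 40), Gene("a", "c1", 10, 40),
                       Gene("z", "c1", 10, 20)])
    assert gs.chromosomes["c1"] == ["z", "a", "b"]


def test_duplicate_gene_ids_rejected():
    with pytest.raises(ValueError, match="duplicate"):
        GeneSet("t", [Gene("a", "c1", 1, 2), Gene("a", "c2", 1, 2)])


# ---------------------------------------------------------------------------
# Newick
# ---------------------------------------------------------------------------

def test_newick_two_leaves(tmp_path):
    tree = read_newick("(a:1,b:1);")
    assert sorted(lf.taxon.label for lf in tree.leaf_node_iter()) == ["a", "b"]


def test_newick_support_retained(tmp_path):
    tree = read_newick("((a:1,b:1)95:0.1,c:2);")
    internal = [n for n in tree.preorder_node_iter()
                if not n.is_leaf() and n.parent_node is not None]
    assert internal and internal[0].label == "95"


def test_newick_unbalanced_errors():
    with pytest.raises(ParseError):
        read_newick("((a,b);")


def test_newick_round_trip(tmp_path):
    p = tmp_path / "t.nwk"
    tree = read_newick("((a:0.123456,b:0.2)80:0.1,(c:0.3,d:0.4)60:0.2,e:0.5);")
    write_newick(tree, p)
    back = read_newick(p)
    orig = {frozenset(lf.taxon.label for lf in n.leaf_iter())
            for n in tree.preorder_node_iter() if not n.is_leaf()}
    rt = {frozenset(lf.taxon.label for lf in n.leaf_iter())
          for n in back.preorder_node_iter() if not n.is_leaf()}
    assert orig == rt


# ---------------------------------------------------------------------------
# Pairwise alignment
# ---------------------------------------------------------------------------

def test_global_identical():
    res = pairwise_align(SequenceRecord("x", "AAA"), SequenceRecord("y", "AAA"))
    blosum = substitution_matrices.load("BLOSUM62")
    assert res.percent_identity == 100.0
    assert res.score == 3 * blosum["A", "A"]


def test_local_finds_embedded_motif():
    res = pairwise_align(SequenceRecord("x", "WWWMKVWWW"),
                         SequenceRecord("y", "MKV"), mode="local")
    assert res.rows[0] == "MKV" and res.percent_identity == 100.0


def test_empty_sequence_errors():
    with pytest.raises(ValueError, match="empty"):
        pairwise_align(SequenceRecord("x", ""), SequenceRecord("y", "A"))


def _gotoh_global(a: str, b: str, open_pen=10.0, ext=1.0) -> float:
    """Independent affine-gap global DP (Gotoh); gap of length L costs
    open_pen + ext*L."""
    blosum = substitution_matrices.load("BLOSUM62")
    NEG = -1e18
    n, m = len(a), len(b)
    M = [[NEG] * (m + 1) for _ in range(n + 1)]
    X = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in b (a consumed)
    Y = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in a
    M[0][0] = 0.0
    for i in range(1, n + 1):
        X[i][0] = -(open_pen + ext * i)
    for j in range(1, m + 1):
        Y[0][j] = -(open_pen + ext * j)
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = blosum[a[i - 1], b[j - 1]]
            M[i][j] = max(M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1]) + s
            X[i][j] = max(M[i - 1][j] - (open_pen + ext), X[i - 1][j] - ext)
            Y[i][j] = max(M[i][j - 1] - (open_pen + ext), Y[i][j - 1] - ext)
    return max(M[n][m], X[n][m], Y[n][m])


def test_global_score_matches_dp_oracle(rng7):
    a = random_protein(rng7, 50)
    b = random_protein(rng7, 50)
    res = pairwise_align(SequenceRecord("a", a), SequenceRecord("b", b))
    assert res.score == pytest.approx(_gotoh_global(a, b))


def test_score_symmetric_under_swap(rng7):
    a = random_protein(rng7, 30)
    b = random_protein(rng7, 35)
    r1 = pairwise_align(SequenceRecord("a", a), SequenceRecord("b", b))
    r2 = pairwise_align(SequenceRecord("b", b), SequenceRecord("a", a))
    assert r1.score == r2.score


# ---------------------------------------------------------------------------
# Alignment invariants
# ---------------------------------------------------------------------------

def test_alignment_rejects_unequal_rows():
    with pytest.raises(ValueError):
        Alignment(["a", "b"], ["MKV", "MK"])


def test_codon_alignment_whole_codon_gaps():
    Alignment(["a", "b"], ["ATG---", "ATGAAA"], "codon")
    with pytest.raises(ValueError, match="whole-codon"):
        Alignment(["a", "b"], ["ATG-AA", "ATGAAA"], "codon")
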