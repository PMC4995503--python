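"""NG86 counting, M0 likelihood fitting and group comparison."""

import itertools

import numpy as np
import pytest

from glrfamevo.codons import AA_OF, CODONS, STOP_CODONS
from glrfamevo.core_model import Alignment, SequenceRecord
from glrfamevo.selection_analysis import (OmegaEstimate, build_codon_alignment,
                                          m0_fit, m0_loglik, ng86,
                                          ng86_alignment, omega_by_group,
                                          pathway_differences,
                                          syn_nonsyn_sites)
from glrfamevo.synthetic_data import evolve_codon_sequences


# ---------------------------------------------------------------------------
# Codon alignment construction
# ---------------------------------------------------------------------------

def test_identical_ungapped_protein_msa_passes_through():
    prot = Alignment(["a", "b"], ["MK", "MK"])
    cds = [SequenceRecord("a", "ATGAAA", "cds"),
           SequenceRecord("b", "ATGAAG", "cds")]
    codon = build_codon_alignment(prot, cds)
    assert codon.rows == ["ATGAAA", "ATGAAG"]


def test_gap_column_deleted():
    prot = Alignment(["a", "b"], ["MKV", "M-V"])
    cds = [SequenceRecord("a", "ATGAAAGTT", "cds"),
           SequenceRecord("b", "ATGGTG", "cds")]
    codon = build_codon_alignment(prot, cds)
    assert codon.length == 6  # 3 x (3 columns - 1 gap column)
    assert codon.rows == ["ATGGTT", "ATGGTG"]


def test_terminal_stop_stripped():
    prot = Alignment(["a", "b"], ["MK", "MK"])
    cds = [SequenceRecord("a", "ATGAAATAA", "cds"),
           SequenceRecord("b", "ATGAAA", "cds")]
    codon = build_codon_alignment(prot, cds)
    assert codon.rows[0] == "ATGAAA"


def test_translation_mismatch_names_gene_and_position():
    prot = Alignment(["a"], ["MV"])
    cds = [SequenceRecord("a", "ATGAAA", "cds")]
    with pytest.raises(ValueError, match="a.*residue 2"):
        build_codon_alignment(prot, cds)


def test_internal_stop_errors():
    prot = Alignment(["a"], ["M*K"])
    cds = [SequenceRecord("a", "ATGTAAAAA", "cds")]
    with pytest.raises(ValueError, match="stop"):
        build_codon_alignment(prot, cds)


# ---------------------------------------------------------------------------
# NG86 site counts and pathway differences vs exhaustive oracle
# ---------------------------------------------------------------------------

def _oracle_sites(codon):
    s = 0.0
    for k in range(3):
        alts = [codon[:k] + n + codon[k + 1:]
                for n in "ACGT" if n != codon[k]]
        alts = [a for a in alts if a not in STOP_CODONS]
        if alts:
            s += sum(AA_OF[a] == AA_OF[codon] for a in alts) / len(alts)
    return s


def _oracle_pathways(c1, c2):
    """Independent recursive enumeration of stop-free minimal pathways."""
    paths = []

    def walk(cur, remaining, sd, nd):
        if not remaining:
            paths.append((sd, nd))
            return
        for k in remaining:
            nxt = cur[:k] + c2[k] + cur[k + 1:]
            if nxt in STOP_CODONS:
                continue
            syn = AA_OF[cur] == AA_OF[nxt]
            walk(nxt, [r for r in remaining if r != k],
                 sd + syn, nd + (not syn))

    diff = [k for k in range(3) if c1[k] != c2[k]]
    walk(c1, diff, 0, 0)
    if not paths:
        return None
    return (sum(p[0] for p in paths) / len(paths),
            sum(p[1] for p in paths) / len(paths))


@pytest.mark.parametrize("codon", ["ATG", "TGG", "CTT", "CGA", "TTA", "AGG"])
def test_site_counts_match_oracle_and_sum_to_three(codon):
    s, n = syn_nonsyn_sites(codon)
    assert s == pytest.approx(_oracle_sites(codon), abs=1e-12)
    assert s + n == pytest.approx(3.0, abs=1e-9)


def test_all_sense_codons_sites_sum_to_three():
    for codon in CODONS:
        s, n = syn_nonsyn_sites(codon)
        assert s + n == pytest.approx(3.0, abs=1e-9)


def test_pathway_averaging_matches_oracle_on_random_pairs():
    rng = np.random.default_rng(13)
    for _ in range(200):
        c1, c2 = (CODONS[i] for i in rng.integers(0, len(CODONS), size=2))
        expected = _oracle_pathways(c1, c2)
        if expected is None:
            continue
        got = pathway_differences(c1, c2)
        assert got == pytest.approx(expected, abs=1e-12), (c1, c2)


def test_three_codon_pairs_match_oracle():
    rng = np.random.default_rng(17)
    for _ in range(30):
        idx = rng.integers(0, len(CODONS), size=6)
        r1 = CODONS[idx[0]] + CODONS[idx[1]] + CODONS[idx[2]]
        r2 = CODONS[idx[3]] + CODONS[idx[4]] + CODONS[idx[5]]
        est = ng86(r1, r2)
        # recompute from per-codon oracles
        S = N = Sd = Nd = 0.0
        skip = False
        for i in range(0, 9, 3):
            sa = _oracle_sites(r1[i:i + 3])
            sb = _oracle_sites(r2[i:i + 3])
            S += (sa + sb) / 2
            N += 3 - (sa + sb) / 2
            pw = _oracle_pathways(r1[i:i + 3], r2[i:i + 3])
            if pw is None:
                skip = True
                break
            Sd += pw[0]
            Nd += pw[1]
        if skip:
            continue
        ps, pn = Sd / S, Nd / N
        if ps >= 0.75 or pn >= 0.75:
            assert est.status == "saturated"
        else:
            expected_ds = -0.75 * np.log(1 - 4 * ps / 3)
            assert est.ds == pytest.approx(expected_ds, abs=1e-12)


def test_identical_rows_undefined_ds():
    est = ng86("ATGAAA", "ATGAAA")
    assert est.dn == 0.0 and est.ds == 0.0 and est.status == "undefined_dS"


def test_ng86_symmetric():
    aln, _ = evolve_codon_sequences(80, 0.4, 2.0, 0.6, seed=21)
    e1 = ng86(aln.rows[0], aln.rows[1])
    e2 = ng86(aln.rows[1], aln.rows[0])
    assert e1.dn == pytest.approx(e2.dn) and e1.ds == pytest.approx(e2.ds)


def test_ng86_recovers_simulated_omega():
    aln, _ = evolve_codon_sequences(500, 0.2, 2.0, 0.5, seed=11)
    est = ng86_alignment(aln)
    assert est.status == "ok"
    assert 0.1 <= est.omega <= 0.35


def test_ng86_matches_biopython_on_simulated_pair():
    from Bio.codonalign.codonseq import CodonSeq, cal_dn_ds

    aln, _ = evolve_codon_sequences(300, 0.3, 2.0, 0.4, seed=19)
    est = ng86_alignment(aln)
    dn, ds = cal_dn_ds(CodonSeq(aln.rows[0]), CodonSeq(aln.rows[1]),
                       method="NG86")
    assert est.dn == pytest.approx(dn, abs=0.01)
    assert est.ds == pytest.approx(ds, abs=0.02)


# ---------------------------------------------------------------------------
# M0
# ---------------------------------------------------------------------------

def test_m0_identical_rows_t_goes_to_zero():
    row = "ATGAAAGTTCCC" * 10
    est = m0_fit(Alignment(["a", "b"], [row, row], "codon"),
                 codon_freq="uniform")
    assert est.t < 1e-4
    assert est.status in ("ok", "undefined_dS")


def test_m0_recovers_simulated_parameters():
    aln, _ = evolve_codon_sequences(500, 0.5, 2.0, 0.4, seed=3)
    est = m0_fit(aln, codon_freq="uniform")
    assert est.status == "ok"
    assert abs(est.omega - 0.5) <= 0.15


def test_m0_optimum_at_least_truth_likelihood():
    aln, _ = evolve_codon_sequences(300, 0.5, 2.0, 0.4, seed=29)
    est = m0_fit(aln, codon_freq="uniform")
    lnl_truth = m0_loglik(aln, 0.5, 2.0, 0.4, codon_freq="uniform")
    assert est.lnl >= lnl_truth - 1e-6


def test_m0_close_to_ng86_on_easy_cases():
    diffs = []
    for seed in range(4):
        aln, _ = evolve_codon_sequences(500, 0.2, 2.0, 0.3, seed=100 + seed)
        ng = ng86_alignment(aln)
        m0 = m0_fit(aln, codon_freq="uniform")
        diffs.append(abs(m0.omega - ng.omega))
    assert max(diffs) <= 0.1


def test_m0_rejects_gapped_alignment():
    with pytest.raises(ValueError, match="gap"):
        m0_fit(Alignment(["a", "b"], ["ATG---", "ATGAAA"], "codon"))


# ---------------------------------------------------------------------------
# Group comparison
# ---------------------------------------------------------------------------

def _fake_estimates(omegas):
    return [OmegaEstimate("NG86", 0.1, 0.5, w, "ok") for w in omegas]


def test_identical_groups_not_significant():
    vals = [0.1, 0.2, 0.3, 0.4, 0.5]
    stats = omega_by_group({"A": _fake_estimates(vals),
                            "B": _fake_estimates(vals)})
    assert stats["pvalues"][("A", "B")] > 0.5


def test_separated_groups_median_order_and_significance():
    rng = np.random.default_rng(31)
    lo = _fake_estimates(rng.normal(0.1, 0.02, size=30).clip(0.01))
    hi = _fake_estimates(rng.normal(0.5, 0.05, size=30).clip(0.01))
    stats = omega_by_group({"low": lo, "high": hi})
    assert stats["median"]["low"] < stats["median"]["high"]
    assert stats["pvalues"][("high", "low")] < 0.01


def test_single_member_group_missing_p():
    stats = omega_by_group({"A": _fake_estimates([0.1]),
                            "B": _fake_estimates([0.2, 0.3])})
    assert stats["pvalues"][("A", "B")] is None
    assert stats["median"]["A"] == pytest.approx(0.1)
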