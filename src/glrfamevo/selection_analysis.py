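"""dN/dS (omega) estimation on codon alignments.

Two estimators are provided. NG86 is the Nei-Gojobori counting method:
synonymous/nonsynonymous site fractions per codon position (equal-weight
mutation fractions, changes to stop codons excluded from the denominator),
pairwise differences averaged over all minimal substitution pathways that
avoid stop codons, and Jukes-Cantor correction of the proportions. M0 is
the one-ratio GY94 codon model: a single omega for all sites, fitted by
maximizing the pairwise likelihood over (omega, kappa, t) from three fixed
starting points to escape local optima.

Gap columns are deleted before any omega calculation.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from math import inf, log

import numpy as np
from scipy.optimize import minimize
from scipy.stats import ranksums

from .codons import (AA_OF, CODON_INDEX, CODONS, STOP_CODONS, codon_diff,
                     empirical_f3x4, gy94_rate_matrix,
                     transition_probabilities, translate, uniform_codon_freqs)
from .core_model import Alignment, SequenceRecord, write_tsv

NUC_ALTS = {"A": "CGT", "C": "AGT", "G": "ACT", "T": "ACG"}


@dataclass
class OmegaEstimate:
    method: str            # NG86 | M0
    dn: float | None
    ds: float | None
    omega: float | None
    status: str = "ok"     # ok | saturated | undefined_dS | not_converged
    kappa: float | None = None
    t: float | None = None
    lnl: float | None = None


# ---------------------------------------------------------------------------
# Codon alignment construction
# ---------------------------------------------------------------------------

def build_codon_alignment(protein_aln: Alignment,
                          cds_records: list[SequenceRecord]) -> Alignment:
    """Back-translate a protein alignment into codons and delete every
    column containing a gap.

    Each CDS must translate (universal code, terminal stop stripped) to its
    ungapped protein row; an internal stop is an error — such sequences
    belong in the pseudogene bin, not here.
    """
    cds_by_id = {r.id: r.residues.upper() for r in cds_records}
    codon_rows = []
    for rid, row in zip(protein_aln.ids, protein_aln.rows):
        if rid not in cds_by_id:
            raise ValueError(f"no CDS for {rid}")
        cds = cds_by_id[rid]
        if len(cds) % 3 != 0:
            raise ValueError(f"{rid}: CDS length not a multiple of 3")
        if cds[-3:] in STOP_CODONS:
            cds = cds[:-3]
        prot = translate(cds)
        if "*" in prot:
            raise ValueError(
                f"{rid}: internal stop codon at residue {prot.index('*') + 1}")
        ungapped = row.replace("-", "")
        if prot != ungapped:
            for k, (x, y) in enumerate(zip(prot, ungapped), start=1):
                if x != y:
                    raise ValueError(
                        f"{rid}: CDS translation mismatch at residue {k} "
                        f"({x!r} vs aligned {y!r})")
            raise ValueError(
                f"{rid}: CDS translates to {len(prot)} residues but the "
                f"aligned row has {len(ungapped)}")
        codons = iter([cds[i:i + 3] for i in range(0, len(cds), 3)])
        codon_rows.append("".join(next(codons) if c != "-" else "---"
                                  for c in row))
    # Delete whole-codon columns containing any gap.
    keep = [i for i in range(0, protein_aln.length * 3, 3)
            if all(r[i:i + 3] != "---" for r in codon_rows)]
    rows = ["".join(r[i:i + 3] for i in keep) for r in codon_rows]
    return Alignment(list(protein_aln.ids), rows, "codon")


# ---------------------------------------------------------------------------
# NG86
# ---------------------------------------------------------------------------

def syn_nonsyn_sites(codon: str) -> tuple[float, float]:
    """Synonymous / nonsynonymous site counts for one codon.

    At each position the three single-nucleotide alternatives are weighted
    equally; changes creating stop codons are excluded from the denominator.
    The two counts always sum to 3.
    """
    if codon not in CODON_INDEX:
        raise ValueError(f"not a sense codon: {codon}")
    s = 0.0
    for k in range(3):
        syn = valid = 0
        for alt in NUC_ALTS[codon[k]]:
            mutant = codon[:k] + alt + codon[k + 1:]
            if mutant in STOP_CODONS:
                continue
            valid += 1
            if AA_OF[mutant] == AA_OF[codon]:
                syn += 1
        s += syn / valid if valid else 0.0
    return s, 3.0 - s


def pathway_differences(c1: str, c2: str) -> tuple[float, float]:
    """Synonymous / nonsynonymous difference counts between two codons,
    averaged over all minimal substitution pathways that avoid stop codons
    (all pathways if every one passes a stop)."""
    diff = codon_diff(c1, c2)
    if not diff:
        return 0.0, 0.0
    results = []
    for order in itertools.permutations(diff):
        cur = c1
        sd = nd = 0
        ok = True
        for k in order:
            nxt = cur[:k] + c2[k] + cur[k + 1:]
            if nxt in STOP_CODONS:
                ok = False
                break
            if AA_OF[cur] == AA_OF[nxt]:
                sd += 1
            else:
                nd += 1
            cur = nxt
        if ok:
            results.append((sd, nd))
    if not results:  # all pathways hit a stop: count steps ignoring stops
        for order in itertools.permutations(diff):
            cur = c1
            sd = nd = 0
            for k in order:
                nxt = cur[:k] + c2[k] + cur[k + 1:]
                syn = (nxt not in STOP_CODONS and cur not in STOP_CODONS
                       and AA_OF.get(cur) == AA_OF.get(nxt))
                sd, nd = (sd + 1, nd) if syn else (sd, nd + 1)
                cur = nxt
            results.append((sd, nd))
    sd = sum(r[0] for r in results) / len(results)
    nd = sum(r[1] for r in results) / len(results)
    return sd, nd


def _jukes_cantor(p: float) -> float | None:
    if p >= 0.75:
        return None
    return -0.75 * log(1.0 - 4.0 * p / 3.0)


def ng86(row_a: str, row_b: str) -> OmegaEstimate:
    """Nei-Gojobori (1986) pairwise dN/dS with Jukes-Cantor correction."""
    if len(row_a) != len(row_b):
        raise ValueError("row length mismatch")
    if len(row_a) % 3 != 0:
        raise ValueError("row length not a multiple of 3")
    S = N = Sd = Nd = 0.0
    for i in range(0, len(row_a), 3):
        ca, cb = row_a[i:i + 3], row_b[i:i + 3]
        sa, na = syn_nonsyn_sites(ca)
        sb, nb = syn_nonsyn_sites(cb)
        S += (sa + sb) / 2.0
        N += (na + nb) / 2.0
        sd, nd = pathway_differences(ca, cb)
        Sd += sd
        Nd += nd
    ps = Sd / S if S else 0.0
    pn = Nd / N if N else 0.0
    ds = _jukes_cantor(ps)
    dn = _jukes_cantor(pn)
    if ds is None or dn is None:
        return OmegaEstimate("NG86", dn, ds, None, "saturated")
    if ds == 0.0:
        return OmegaEstimate("NG86", dn, ds, None, "undefined_dS")
    return OmegaEstimate("NG86", dn, ds, dn / ds, "ok")


def ng86_alignment(aln: Alignment) -> OmegaEstimate:
    if aln.n_rows != 2:
        raise ValueError("ng86 expects a 2-row codon alignment")
    return ng86(aln.rows[0], aln.rows[1])


# ---------------------------------------------------------------------------
# M0 (GY94 one-ratio) maximum likelihood
# ---------------------------------------------------------------------------

# Fixed restart spread emulating "different input parameters".
M0_STARTS = ((0.2, 2.0, 0.3), (1.0, 1.0, 1.0), (3.0, 5.0, 0.1))
_BOUNDS = ((log(1e-4), log(50.0)),   # log omega
           (log(1e-2), log(100.0)),  # log kappa
           (log(1e-6), log(20.0)))   # log t


def _pair_counts(row_a: str, row_b: str) -> np.ndarray:
    n = len(CODONS)
    C = np.zeros((n, n))
    for i in range(0, len(row_a), 3):
        ca, cb = row_a[i:i + 3], row_b[i:i + 3]
        if ca in CODON_INDEX and cb in CODON_INDEX:
            C[CODON_INDEX[ca], CODON_INDEX[cb]] += 1
    return C


def _m0_sites(kappa: float, pi: np.ndarray) -> tuple[float, float]:
    """Synonymous/nonsynonymous site counts per codon under the mutation
    process (omega = 1), PAML-style, for converting t into dS and dN."""
    Q = gy94_rate_matrix(1.0, kappa, pi)
    rho_s = rho_n = 0.0
    for i, ci in enumerate(CODONS):
        for j, cj in enumerate(CODONS):
            if i == j or len(codon_diff(ci, cj)) != 1:
                continue
            if AA_OF[ci] == AA_OF[cj]:
                rho_s += pi[i] * Q[i, j]
            else:
                rho_n += pi[i] * Q[i, j]
    total = rho_s + rho_n
    return 3.0 * rho_s / total, 3.0 * rho_n / total


def m0_fit(aln: Alignment, codon_freq: str = "f3x4", n_restarts: int = 3,
           seed: int = 0) -> OmegaEstimate:
    """Fit the one-ratio codon model to a gap-free 2-row codon alignment.

    Maximizes sum_sites log(pi_i P_ij(t)) over (omega, kappa, t) with
    L-BFGS-B in log-parameter space from ``n_restarts`` fixed starting
    points; returns the best fit. dS and dN are derived from t via the
    omega=1 site decomposition (so omega = dN/dS exactly).
    """
    if aln.n_rows != 2:
        raise ValueError("m0_fit expects a 2-row codon alignment")
    row_a, row_b = aln.rows
    if "-" in row_a or "-" in row_b:
        raise ValueError("codon alignment must be gap-free (delete gap columns)")
    if codon_freq == "uniform":
        pi = uniform_codon_freqs()
    elif codon_freq == "f3x4":
        pi = empirical_f3x4([row_a, row_b])
    else:
        raise ValueError(f"unknown codon_freq {codon_freq!r}")
    C = _pair_counts(row_a, row_b)
    log_pi = np.log(pi)

    def neg_lnl(x: np.ndarray) -> float:
        omega, kappa, t = np.exp(x)
        Q = gy94_rate_matrix(omega, kappa, pi)
        P = transition_probabilities(Q, pi, t)
        ll = float(np.sum(C * (log_pi[:, None] + np.log(P))))
        return -ll

    best = None
    converged = False
    starts = M0_STARTS[:n_restarts] if n_restarts <= len(M0_STARTS) else M0_STARTS
    for start in starts:
        x0 = np.log(np.array(start))
        res = minimize(neg_lnl, x0, method="L-BFGS-B", bounds=_BOUNDS)
        if best is None or res.fun < best.fun:
            best = res
        converged = converged or bool(res.success)
    omega, kappa, t = (float(v) for v in np.exp(best.x))
    s_sites, n_sites = _m0_sites(kappa, pi)
    # Expected substitutions per codon split into syn/nonsyn components.
    Q = gy94_rate_matrix(omega, kappa, pi)
    rho_s = sum(pi[i] * Q[i, j]
                for i, ci in enumerate(CODONS) for j, cj in enumerate(CODONS)
                if i != j and len(codon_diff(ci, cj)) == 1
                and AA_OF[ci] == AA_OF[cj])
    rho_n = -np.dot(pi, np.diag(Q)) - rho_s
    ds = t * rho_s / s_sites if s_sites else None
    dn = t * rho_n / n_sites if n_sites else None
    status = "ok" if converged else "not_converged"
    if ds is not None and ds < 1e-9:
        status = "undefined_dS"
    return OmegaEstimate("M0", dn, ds, omega, status,
                         kappa=kappa, t=t, lnl=-float(best.fun))


def m0_loglik(aln: Alignment, omega: float, kappa: float, t: float,
              codon_freq: str = "f3x4") -> float:
    """Log-likelihood of a 2-row codon alignment at given parameters."""
    row_a, row_b = aln.rows
    pi = (uniform_codon_freqs() if codon_freq == "uniform"
          else empirical_f3x4([row_a, row_b]))
    C = _pair_counts(row_a, row_b)
    Q = gy94_rate_matrix(omega, kappa, pi)
    P = transition_probabilities(Q, pi, t)
    return float(np.sum(C * (np.log(pi)[:, None] + np.log(P))))


# ---------------------------------------------------------------------------
# Group comparison
# ---------------------------------------------------------------------------

def omega_by_group(estimates: dict[str, list[OmegaEstimate]]):
    """Per-group median omega over ok-status estimates plus pairwise
    two-sided Wilcoxon rank-sum p-values; groups with < 2 usable estimates
    get a missing ('.') p-value."""
    usable = {g: [e.omega for e in ests if e.status == "ok" and e.omega is not None]
              for g, ests in estimates.items()}
    medians = {g: (float(np.median(v)) if v else None) for g, v in usable.items()}
    pvals: dict[tuple[str, str], float | None] = {}
    for ga, gb in itertools.combinations(sorted(usable), 2):
        va, vb = usable[ga], usable[gb]
        if len(va) < 2 or len(vb) < 2:
            pvals[(ga, gb)] = None
        else:
            pvals[(ga, gb)] = float(ranksums(va, vb).pvalue)
    return {"median": medians, "pvalues": pvals,
            "n": {g: len(v) for g, v in usable.items()}}


def write_omega_reports(pair_estimates, group_stats, pairs_path, groups_path) -> None:
    rows = []
    for (a, b), est in pair_estimates.items():
        rows.append([a, b, est.method,
                     None if est.dn is None else round(est.dn, 6),
                     None if est.ds is None else round(est.ds, 6),
                     None if est.omega is None else round(est.omega, 6),
                     None if est.kappa is None else round(est.kappa, 4),
                     None if est.t is None else round(est.t, 6),
                     None if est.lnl is None else round(est.lnl, 4),
                     est.status])
    write_tsv(pairs_path,
              ["gene_a", "gene_b", "method", "dN", "dS", "omega", "kappa",
               "t", "lnL", "status"], rows,
              comment="assumptions: pairwise M0, F3x4 frequencies, gap columns deleted")
    grows = [[g, None if m is None else round(m, 6), group_stats["n"][g]]
             for g, m in group_stats["median"].items()]
    write_tsv(groups_path, ["group", "median_omega", "n"], grows)
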