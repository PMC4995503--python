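"""Codon-level machinery shared by the simulator and the selection module.

State space: the 61 sense codons of the universal genetic code (stop codons
excluded, as in the standard one-ratio M0 codon model). The GY94
instantaneous rate matrix allows single-nucleotide changes only; synonymous
transitions are weighted kappa, nonsynonymous changes omega, and every rate
carries the target codon's equilibrium frequency.
"""

from __future__ import annotations

import numpy as np
from Bio.Data.CodonTable import standard_dna_table

NUCS = "TCAG"
STOP_CODONS = tuple(sorted(standard_dna_table.stop_codons))  # TAA TAG TGA
CODONS: tuple[str, ...] = tuple(
    a + b + c for a in NUCS for b in NUCS for c in NUCS
    if a + b + c not in standard_dna_table.stop_codons
)
CODON_INDEX = {c: i for i, c in enumerate(CODONS)}
AA_OF = {c: standard_dna_table.forward_table[c] for c in CODONS}

_PURINES = {"A", "G"}
_PYRIMIDINES = {"C", "T"}


def is_transition(x: str, y: str) -> bool:
    """True for A<->G or C<->T single-nucleotide exchanges."""
    return (x in _PURINES and y in _PURINES) or (x in _PYRIMIDINES and y in _PYRIMIDINES)


def codon_diff(c1: str, c2: str) -> list[int]:
    """Positions (0..2) where two codons differ."""
    return [k for k in range(3) if c1[k] != c2[k]]


def translate(cds: str) -> str:
    """Translate a CDS (length divisible by 3) with the universal code;
    stop codons become '*'."""
    aas = []
    for i in range(0, len(cds) - len(cds) % 3, 3):
        cod = cds[i:i + 3].upper()
        if cod in standard_dna_table.forward_table:
            aas.append(standard_dna_table.forward_table[cod])
        elif cod in standard_dna_table.stop_codons:
            aas.append("*")
        else:
            aas.append("X")
    return "".join(aas)


def uniform_codon_freqs() -> np.ndarray:
    return np.full(len(CODONS), 1.0 / len(CODONS))


def f3x4_freqs(position_nuc_freqs: np.ndarray) -> np.ndarray:
    """F3x4 codon frequencies from a 3x4 table of per-codon-position
    nucleotide frequencies (columns ordered as T,C,A,G), renormalized over
    sense codons."""
    pos = np.asarray(position_nuc_freqs, dtype=float)
    if pos.shape != (3, 4):
        raise ValueError("expected a 3x4 nucleotide frequency table")
    pos = pos / pos.sum(axis=1, keepdims=True)
    nuc_idx = {n: i for i, n in enumerate(NUCS)}
    pi = np.array([
        pos[0, nuc_idx[c[0]]] * pos[1, nuc_idx[c[1]]] * pos[2, nuc_idx[c[2]]]
        for c in CODONS
    ])
    return pi / pi.sum()


def empirical_f3x4(rows: list[str]) -> np.ndarray:
    """F3x4 frequencies estimated from codon rows (gap-free strings)."""
    counts = np.ones((3, 4))  # +1 pseudocount keeps every codon reachable
    nuc_idx = {n: i for i, n in enumerate(NUCS)}
    for row in rows:
        for i in range(0, len(row), 3):
            for k in range(3):
                n = row[i + k]
                if n in nuc_idx:
                    counts[k, nuc_idx[n]] += 1
    return f3x4_freqs(counts)


def gy94_rate_matrix(omega: float, kappa: float, pi: np.ndarray) -> np.ndarray:
    """GY94/M0 rate matrix scaled so the mean rate is one substitution per
    codon site-triplet, i.e. branch length t is expected substitutions per
    codon."""
    n = len(CODONS)
    Q = np.zeros((n, n))
    for i, ci in enumerate(CODONS):
        for j, cj in enumerate(CODONS):
            if i == j:
                continue
            diff = codon_diff(ci, cj)
            if len(diff) != 1:
                continue
            k = diff[0]
            rate = pi[j]
            if is_transition(ci[k], cj[k]):
                rate *= kappa
            if AA_OF[ci] != AA_OF[cj]:
                rate *= omega
            Q[i, j] = rate
    np.fill_diagonal(Q, -Q.sum(axis=1))
    scale = -np.dot(pi, np.diag(Q))
    if scale <= 0:
        raise ValueError("degenerate rate matrix")
    return Q / scale


def transition_probabilities(Q: np.ndarray, pi: np.ndarray, t: float) -> np.ndarray:
    """P(t) = exp(Qt) via symmetric eigendecomposition (Q is reversible
    w.r.t. pi, so D^{1/2} Q D^{-1/2} is symmetric)."""
    sqrt_pi = np.sqrt(pi)
    S = Q * sqrt_pi[np.newaxis, :] / sqrt_pi[:, np.newaxis]
    S = 0.5 * (S + S.T)
    eigval, eigvec = np.linalg.eigh(S)
    expd = np.exp(eigval * t)
    P = (eigvec * expd) @ eigvec.T
    P = P * sqrt_pi[np.newaxis, :] / sqrt_pi[:, np.newaxis]
    np.clip(P, 1e-300, None, out=P)
    P /= P.sum(axis=1, keepdims=True)
    return P
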