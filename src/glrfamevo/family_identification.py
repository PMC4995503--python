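"""Candidate screening, pseudogene filtering and domain-architecture calls.

Pseudogene verdicts follow a fixed precedence — frameshift (CDS length not a
multiple of 3), then premature stop, then short fragment (translated length
below a fraction of the family reference length) — so structural defects
mask length defects.

Domain presence is decided by ungapped PSSM scans: a position-specific
log-odds matrix built from a seed alignment is slid over the protein, and a
domain is present when the best window score clears a threshold calibrated
from a shuffled-sequence null distribution.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import inf, log

import numpy as np

from .codons import translate
from .core_model import Alignment, SequenceRecord, write_tsv

AA20 = "ACDEFGHIKLMNPQRSTVWY"
_AA_INDEX = {a: i for i, a in enumerate(AA20)}

GLR_DOMAINS = ("ATD", "GlnH1", "M1", "M2-Pore", "M3", "GlnH2", "M4")


# ---------------------------------------------------------------------------
# Pseudogene filter
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PseudogeneCall:
    gene_id: str
    verdict: str  # complete | short_fragment | premature_stop | frameshift
    stop_position: int | None = None   # codon index (1-based) of first stop
    length_mod3: int | None = None
    length_ratio: float | None = None  # translated / reference length


def check_orf_integrity(cds: SequenceRecord, family_length_reference: int,
                        short_fraction: float = 0.5) -> PseudogeneCall:
    """Classify a CDS as complete or one of three pseudogene defect types.

    Verdicts are checked in the order frameshift -> premature_stop ->
    short_fragment; the first hit wins. ``family_length_reference`` is the
    family's reference protein length in residues.
    """
    seq = cds.residues.upper()
    if not seq:
        raise ValueError(f"{cds.id}: empty CDS")
    if len(seq) % 3 != 0:
        return PseudogeneCall(cds.id, "frameshift", length_mod3=len(seq) % 3)
    protein = translate(seq)
    # A stop as the final codon is a normal terminator.
    body = protein[:-1]
    if "*" in body:
        return PseudogeneCall(cds.id, "premature_stop",
                              stop_position=body.index("*") + 1)
    aa_len = len(body) if protein.endswith("*") else len(protein)
    ratio = aa_len / family_length_reference
    if ratio < short_fraction:
        return PseudogeneCall(cds.id, "short_fragment", length_ratio=round(ratio, 4))
    return PseudogeneCall(cds.id, "complete")


def filter_pseudogenes(cds_records: list[SequenceRecord],
                       family_length_reference: int | None = None,
                       short_fraction: float = 0.5
                       ) -> tuple[list[PseudogeneCall], dict[str, int]]:
    """Run the filter over a candidate set and return calls plus an
    accounting summary (candidates, pseudogenes, complete)."""
    if not cds_records:
        raise ValueError("no candidate CDS records")
    if family_length_reference is None:
        lengths = sorted(len(r.residues) // 3 for r in cds_records)
        family_length_reference = lengths[len(lengths) // 2]
    calls = [check_orf_integrity(r, family_length_reference, short_fraction)
             for r in cds_records]
    n_pseudo = sum(1 for c in calls if c.verdict != "complete")
    summary = {"candidates": len(calls), "pseudogenes": n_pseudo,
               "complete": len(calls) - n_pseudo}
    return calls, summary


def complete_gene_count(n_candidates: int, n_pseudogenes: int) -> int:
    """Filter accounting: complete genes retained after removing pseudogene
    calls from the candidate set."""
    if n_pseudogenes > n_candidates or min(n_candidates, n_pseudogenes) < 0:
        raise ValueError("invalid counts")
    return n_candidates - n_pseudogenes


# ---------------------------------------------------------------------------
# PSSM construction and scanning
# ---------------------------------------------------------------------------

@dataclass
class PSSM:
    """Ungapped position-specific scoring matrix over the 20 residues.

    ``log_odds`` has shape (motif length, 20), natural log of position
    probability over background. Residues outside the 20-letter alphabet
    (X, gaps) score the worst value at each position.
    """

    log_odds: np.ndarray
    background: np.ndarray
    threshold: float = 0.0
    name: str = "motif"

    @property
    def length(self) -> int:
        return self.log_odds.shape[0]


def build_pssm(seed_alignment: Alignment, pseudocount: float = 1.0,
               background: np.ndarray | None = None, name: str = "motif") -> PSSM:
    """Position probabilities (count + pseudocount*background) / (n + pseudocount),
    converted to log-odds against the background."""
    if background is None:
        background = np.full(20, 1.0 / 20)
    background = np.asarray(background, dtype=float)
    L = seed_alignment.length
    n = seed_alignment.n_rows
    probs = np.zeros((L, 20))
    for c in range(L):
        counts = np.zeros(20)
        for r in seed_alignment.rows:
            a = r[c]
            if a in _AA_INDEX:
                counts[_AA_INDEX[a]] += 1
        probs[c] = (counts + pseudocount * background) / (n + pseudocount)
    assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-9)
    log_odds = np.log(probs) - np.log(background)
    return PSSM(log_odds, background, name=name)


def scan_pssm(protein: SequenceRecord | str, pssm: PSSM
              ) -> tuple[float, tuple[int, int] | None, bool]:
    """Best ungapped window score over the protein.

    Returns (best score, best interval 1-based inclusive or None, present).
    Proteins shorter than the motif score -inf and are absent.
    """
    seq = protein.residues if isinstance(protein, SequenceRecord) else protein
    L = pssm.length
    if len(seq) < L:
        return -inf, None, False
    worst = pssm.log_odds.min(axis=1)
    best_score, best_start = -inf, 0
    for s in range(len(seq) - L + 1):
        score = 0.0
        for k in range(L):
            a = seq[s + k]
            score += pssm.log_odds[k, _AA_INDEX[a]] if a in _AA_INDEX else worst[k]
        if score > best_score:
            best_score, best_start = score, s
    interval = (best_start + 1, best_start + L)
    return best_score, interval, best_score >= pssm.threshold


def calibrate_threshold(pssm: PSSM, example_proteins: list[str],
                        n_shuffles: int = 100, quantile: float = 0.99,
                        seed: int = 0) -> float:
    """Set the presence threshold at a quantile of best-window scores on
    residue-shuffled proteins (a null that preserves composition)."""
    rng = np.random.default_rng(seed)
    scores = []
    for _ in range(n_shuffles):
        src = example_proteins[rng.integers(0, len(example_proteins))]
        shuffled = "".join(rng.permutation(list(src)))
        s, _, _ = scan_pssm(shuffled, pssm)
        if s > -inf:
            scores.append(s)
    if not scores:
        raise ValueError("no shuffled protein long enough for the motif")
    return float(np.quantile(scores, quantile))


# ---------------------------------------------------------------------------
# Domain architecture and loss statistics
# ---------------------------------------------------------------------------

@dataclass
class DomainArchitecture:
    gene_id: str
    presence: dict[str, bool]
    intervals: dict[str, tuple[int, int] | None]
    scores: dict[str, float]

    def missing(self) -> list[str]:
        return [d for d, p in self.presence.items() if not p]


def call_domain_architecture(protein: SequenceRecord,
                             pssms: dict[str, PSSM]) -> DomainArchitecture:
    """One presence flag per domain PSSM; hit order along the protein is
    reported via the intervals but not enforced."""
    presence, intervals, scores = {}, {}, {}
    for name, pssm in pssms.items():
        score, interval, present = scan_pssm(protein, pssm)
        presence[name] = present
        intervals[name] = interval if present else None
        scores[name] = score
    return DomainArchitecture(protein.id, presence, intervals, scores)


def domain_loss_rates(architectures: list[DomainArchitecture],
                      subfamily: dict[str, str]):
    """Per-domain loss rates, per-subfamily shares of all loss events, and
    the per-domain x subfamily rate table.

    loss_rate(d) = genes lacking d / genes; share(s) = loss events in s /
    total loss events (None when no losses exist).
    """
    import pandas as pd

    if not architectures:
        raise ValueError("no architectures")
    domains = list(architectures[0].presence)
    n = len(architectures)
    loss_rate = {d: sum(1 for a in architectures if not a.presence[d]) / n
                 for d in domains}
    events: dict[str, int] = {}
    cell = {}
    subfams = sorted(set(subfamily.values()))
    for s in subfams:
        members = [a for a in architectures if subfamily.get(a.gene_id) == s]
        events[s] = sum(len(a.missing()) for a in members)
        for d in domains:
            cell[(d, s)] = (sum(1 for a in members if not a.presence[d]) / len(members)
                            if members else None)
    total = sum(events.values())
    share = ({s: events[s] / total for s in subfams} if total
             else {s: None for s in subfams})
    per_cell = pd.DataFrame(
        [[cell[(d, s)] for s in subfams] for d in domains],
        index=domains, columns=subfams)
    return {"loss_rate": loss_rate, "subfamily_share": share,
            "rate_table": per_cell, "total_loss_events": total}


def write_domain_reports(architectures, loss_stats, arch_path, rates_path) -> None:
    domains = list(architectures[0].presence)
    write_tsv(arch_path, ["gene"] + domains,
              [[a.gene_id] + [int(a.presence[d]) for d in domains]
               for a in architectures])
    rows = [[d, round(loss_stats["loss_rate"][d], 4)] for d in domains]
    write_tsv(rates_path, ["domain", "loss_rate"], rows)
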