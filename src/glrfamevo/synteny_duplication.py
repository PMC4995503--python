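"""Homolog pairs, collinear chains, duplication-mode classification and
tandem-array statistics.

Classification rules (fixed precedence wgd_segmental > tandem > dispersed):
a family gene that anchors a collinear (synteny) block is a WGD/segmental
duplicate; otherwise a gene with a homolog on the same chromosome separated
by fewer than ``tandem_gap`` intervening genes is a tandem duplicate;
remaining genes with homologs are dispersed; genes without any homolog are
singletons.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

from .core_model import GeneSet, SequenceRecord, pairwise_align, write_tsv


@dataclass(frozen=True)
class HomologPair:
    """An undirected homolog pair stored in canonical id order."""

    a: str
    b: str
    score: float = 0.0
    percent_identity: float = 0.0

    def __post_init__(self):
        if self.a == self.b:
            raise ValueError(f"self-pair {self.a}")
        if self.a > self.b:
            object.__setattr__(self, "a", self.b)
            object.__setattr__(self, "b", self.a)

    @property
    def key(self) -> tuple[str, str]:
        return (self.a, self.b) if self.a < self.b else (self.b, self.a)


@dataclass
class SyntenyBlock:
    block_id: str
    anchors: list[tuple[str, str]]          # ordered along region A
    chrom_a: str
    chrom_b: str
    rank_range_a: tuple[int, int]
    rank_range_b: tuple[int, int]
    orientation: str                        # same | inverted
    score: float

    def member_genes(self) -> set[str]:
        out = set()
        for a, b in self.anchors:
            out.add(a)
            out.add(b)
        return out


@dataclass(frozen=True)
class DuplicationCall:
    gene_id: str
    mode: str  # singleton | wgd_segmental | tandem | dispersed
    support: tuple[str, ...] = ()


@dataclass
class TandemArray:
    members: list[str]  # ordered by rank
    chromosome: str

    def __len__(self) -> int:
        return len(self.members)


# ---------------------------------------------------------------------------
# Homolog pair detection
# ---------------------------------------------------------------------------

def find_homolog_pairs(proteins: list[SequenceRecord], top_k: int = 5,
                       score_threshold: float = 50.0) -> list[HomologPair]:
    """All-vs-all local alignment; each query keeps its top_k non-self hits
    with score >= threshold (hits tying the k-th best score are all kept),
    then the symmetric closure is taken (a pair survives if either
    direction retained it)."""
    if len(proteins) < 2:
        raise ValueError("need at least 2 proteins")
    by_id = {p.id: p for p in proteins}
    ids = sorted(by_id)
    scores: dict[tuple[str, str], tuple[float, float]] = {}
    for qa, qb in itertools.combinations(ids, 2):
        res = pairwise_align(by_id[qa], by_id[qb], mode="local")
        if res.score >= score_threshold:
            scores[(qa, qb)] = (res.score, res.percent_identity)
    kept: set[tuple[str, str]] = set()
    for q in ids:
        hits = [(other, scores[tuple(sorted((q, other)))])
                for other in ids if other != q
                and tuple(sorted((q, other))) in scores]
        hits.sort(key=lambda h: (-h[1][0], h[0]))
        if len(hits) > top_k:
            cutoff = hits[top_k - 1][1][0]
            hits = [h for h in hits if h[1][0] >= cutoff]
        for other, _ in hits:
            kept.add(tuple(sorted((q, other))))
    return [HomologPair(a, b, scores[(a, b)][0], scores[(a, b)][1])
            for a, b in sorted(kept)]


def calibrate_pair_threshold(proteins: list[SequenceRecord],
                             n_shuffles: int = 50,
                             quantile: float = 0.99999,
                             seed: int = 0) -> float:
    """Local-alignment score threshold from a shuffled-sequence null
    (surrogate for an E-value cutoff at toy scale)."""
    import numpy as np

    rng = np.random.default_rng(seed)
    null = []
    for _ in range(n_shuffles):
        i, j = rng.integers(0, len(proteins), size=2)
        sa = "".join(rng.permutation(list(proteins[i].residues)))
        sb = "".join(rng.permutation(list(proteins[j].residues)))
        res = pairwise_align(SequenceRecord("x", sa), SequenceRecord("y", sb),
                             mode="local")
        null.append(res.score)
    return float(np.quantile(null, quantile))


# ---------------------------------------------------------------------------
# Collinear chain detection
# ---------------------------------------------------------------------------

def _gene_lookup(genesets) -> dict[str, tuple[str, int, "GeneSet"]]:
    if isinstance(genesets, GeneSet):
        genesets = [genesets]
    lut = {}
    for gs in genesets:
        for gid, g in gs.genes.items():
            if gid in lut:
                raise ValueError(f"gene id {gid} present in multiple gene sets")
            lut[gid] = (g.chromosome, g.rank, gs)
    return lut


def _chain_dp(anchors: list[tuple[int, int, int]], max_gap: int, inverted: bool
              ) -> tuple[list[float], list[int]]:
    """Longest-chain DP over anchors sorted by rank on side A.

    anchors: (rank_a, rank_b, original index). Returns per-anchor best chain
    length ending there and parent pointers.
    """
    n = len(anchors)
    dp = [1.0] * n
    parent = [-1] * n
    for i in range(n):
        ra_i, rb_i, _ = anchors[i]
        for j in range(i):
            ra_j, rb_j, _ = anchors[j]
            da = ra_i - ra_j
            db = (rb_j - rb_i) if inverted else (rb_i - rb_j)
            if 0 < da <= max_gap and 0 < db <= max_gap:
                if dp[j] + 1 > dp[i]:
                    dp[i] = dp[j] + 1
                    parent[i] = j
    return dp, parent


def detect_collinear_chains(pairs: list[HomologPair], genesets,
                            min_block_pairs: int = 5,
                            max_rank_gap: int = 25) -> list[SyntenyBlock]:
    """Find collinear blocks by dynamic-programming chain extension.

    Anchors are grouped by chromosome pair; a chain extends a previous
    anchor when both rank increments lie in (0, max_rank_gap] (side B
    strictly decreasing for inverted chains). Maximal chains with
    >= min_block_pairs anchors are reported; each anchor joins at most one
    block, assigned greedily by chain score with ties broken by the first
    anchor's gene ids.
    """
    lut = _gene_lookup(genesets)
    for p in pairs:
        for gid in (p.a, p.b):
            if gid not in lut:
                raise ValueError(f"pair references unknown gene {gid}")

    groups: dict[tuple[str, str], list[tuple[int, int, HomologPair]]] = {}
    for p in pairs:
        ca, ra, _ = lut[p.a]
        cb, rb, _ = lut[p.b]
        if (ca, p.a) <= (cb, p.b):
            key, item = (ca, cb), (ra, rb, p)
        else:
            key, item = (cb, ca), (rb, ra, p)
        groups.setdefault(key, []).append(item)

    blocks: list[SyntenyBlock] = []
    counter = 0
    for (ca, cb), items in sorted(groups.items()):
        used: set[int] = set()
        while True:
            free = [(ra, rb, i) for i, (ra, rb, _) in enumerate(items)
                    if i not in used]
            free.sort()
            best_chain: list[int] | None = None
            best_key = None
            for inverted in (False, True):
                dp, parent = _chain_dp(free, max_rank_gap, inverted)
                for end in range(len(free)):
                    if dp[end] < min_block_pairs:
                        continue
                    chain = []
                    k = end
                    while k >= 0:
                        chain.append(free[k][2])
                        k = parent[k]
                    chain.reverse()
                    first = items[chain[0]][2]
                    key = (-dp[end], first.a, first.b, inverted)
                    if best_key is None or key < best_key:
                        best_key, best_chain = key, chain
            if best_chain is None:
                break
            used.update(best_chain)
            counter += 1
            chain_items = [items[i] for i in best_chain]
            ranks_a = [ra for ra, _, _ in chain_items]
            ranks_b = [rb for _, rb, _ in chain_items]
            anchors = []
            for _, _, p in chain_items:
                ca_p, _, _ = lut[p.a]
                anchors.append((p.a, p.b) if (ca_p, p.a) <= (cb, p.b) and ca_p == ca
                               else (p.b, p.a))
            blocks.append(SyntenyBlock(
                block_id=f"block{counter:03d}",
                anchors=anchors,
                chrom_a=ca, chrom_b=cb,
                rank_range_a=(min(ranks_a), max(ranks_a)),
                rank_range_b=(min(ranks_b), max(ranks_b)),
                orientation="inverted" if best_key[3] else "same",
                score=float(len(best_chain)),
            ))
    return blocks


# ---------------------------------------------------------------------------
# Duplication-mode classification
# ---------------------------------------------------------------------------

def classify_duplications(geneset: GeneSet, pairs: list[HomologPair],
                          blocks: list[SyntenyBlock],
                          family_genes: list[str] | None = None,
                          tandem_gap: int = 10,
                          rank_diff_rule: bool = False) -> list[DuplicationCall]:
    """Assign exactly one duplication mode to every family gene.

    ``rank_diff_rule`` switches the tandem test from "< tandem_gap
    intervening genes" (default, MCScanX convention) to "rank difference
    < tandem_gap".
    """
    partners: dict[str, list[str]] = {}
    for p in pairs:
        for gid in (p.a, p.b):
            if gid not in geneset:
                raise ValueError(f"pair references unknown gene {gid}")
        partners.setdefault(p.a, []).append(p.b)
        partners.setdefault(p.b, []).append(p.a)
    if family_genes is None:
        family_genes = sorted(partners)
    block_members: dict[str, str] = {}
    for blk in blocks:
        for gid in blk.member_genes():
            block_members.setdefault(gid, blk.block_id)

    calls = []
    for gid in family_genes:
        if gid not in geneset:
            raise ValueError(f"unknown family gene {gid}")
        mates = partners.get(gid, [])
        if not mates:
            calls.append(DuplicationCall(gid, "singleton"))
            continue
        if gid in block_members:
            calls.append(DuplicationCall(gid, "wgd_segmental",
                                         (block_members[gid],)))
            continue
        tandem_mates = []
        for m in mates:
            between = geneset.intervening(gid, m)
            if between is None:
                continue
            near = (abs(geneset.rank(gid) - geneset.rank(m)) < tandem_gap
                    if rank_diff_rule else between < tandem_gap)
            if near:
                tandem_mates.append(m)
        if tandem_mates:
            calls.append(DuplicationCall(gid, "tandem", tuple(sorted(tandem_mates))))
        else:
            calls.append(DuplicationCall(gid, "dispersed", tuple(sorted(mates))))
    return calls


# ---------------------------------------------------------------------------
# Tandem arrays and fractions
# ---------------------------------------------------------------------------

def group_tandem_arrays(calls: list[DuplicationCall], geneset: GeneSet,
                        tandem_gap: int = 10
                        ) -> tuple[list[TandemArray], dict[str, float]]:
    """Maximal runs of tandem-called genes: connected components of the
    proximity relation (< tandem_gap intervening genes on one chromosome),
    each ordered by rank."""
    tandem = [c.gene_id for c in calls if c.mode == "tandem"]
    by_chrom: dict[str, list[str]] = {}
    for gid in tandem:
        by_chrom.setdefault(geneset[gid].chromosome, []).append(gid)
    arrays = []
    for chrom in sorted(by_chrom):
        ordered = sorted(by_chrom[chrom], key=lambda g: geneset.rank(g))
        run = [ordered[0]]
        for gid in ordered[1:]:
            if geneset.rank(gid) - geneset.rank(run[-1]) - 1 < tandem_gap:
                run.append(gid)
            else:
                arrays.append(TandemArray(run, chrom))
                run = [gid]
        arrays.append(TandemArray(run, chrom))
    assert sum(len(a) for a in arrays) == len(tandem)
    summary = {
        "n_arrays": float(len(arrays)),
        "mean_array_size": (sum(len(a) for a in arrays) / len(arrays)
                            if arrays else 0.0),
    }
    return arrays, summary


def tandem_related_fraction(n_tandem_related: int, n_total: int) -> float:
    """Percentage of tandem-related genes, rounded to 2 decimals for
    reporting (e.g. 581 of 881 -> 65.95)."""
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    if not (0 <= n_tandem_related <= n_total):
        raise ValueError("count out of range")
    return round(100.0 * n_tandem_related / n_total, 2)


def tandem_fraction_from_calls(calls: list[DuplicationCall]) -> float:
    n_tandem = sum(1 for c in calls if c.mode == "tandem")
    return tandem_related_fraction(n_tandem, len(calls))


def write_duplication_reports(calls, arrays, blocks, calls_path, arrays_path,
                              blocks_path) -> None:
    write_tsv(calls_path, ["gene", "mode", "support"],
              [[c.gene_id, c.mode, ",".join(c.support) or None] for c in calls])
    write_tsv(arrays_path, ["array", "chromosome", "members"],
              [[i + 1, a.chromosome, ",".join(a.members)]
               for i, a in enumerate(arrays)])
    write_tsv(blocks_path,
              ["block", "chrom_a", "chrom_b", "orientation", "n_anchors",
               "anchors"],
              [[b.block_id, b.chrom_a, b.chrom_b, b.orientation,
                len(b.anchors),
                ";".join(f"{x}|{y}" for x, y in b.anchors)] for b in blocks])
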