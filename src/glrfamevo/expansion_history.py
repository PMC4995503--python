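"""Nearest-duplicate selection and linear expansion-series assembly, plus
cross-species orthology series and ancestral-anchor inference.

A gene's nearest duplicate is chosen lexicographically: highest percent
identity, then most shared flanking block-anchor genes, then lowest Ks
(synonymous distance, a proxy for duplication age), then partner id. The
undirected graph of nearest edges is pruned to maximum degree 2 (keeping
each node's two best edges) and cycles are broken at their worst edge, so
every component is a simple path — one linear expansion series.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .core_model import write_tsv
from .synteny_duplication import HomologPair, SyntenyBlock


@dataclass(frozen=True)
class Criteria:
    identity: float
    shared_flanking: int
    ks: float | None  # None = undefined (saturated / zero synonymous sites)

    def sort_key(self) -> tuple:
        ks = math.inf if self.ks is None else self.ks
        return (-self.identity, -self.shared_flanking, ks)


@dataclass(frozen=True)
class NearestDuplicateEdge:
    gene: str
    partner: str
    criteria: Criteria
    ks_undefined: bool = False


@dataclass
class ExpansionSeries:
    genes: list[str]  # ordered path

    def __len__(self) -> int:
        return len(self.genes)


@dataclass
class OrthologySeries:
    entries: dict[str, str | None]  # species -> gene id (None = gap)
    ancestral: bool = False


# ---------------------------------------------------------------------------
# Nearest duplicate
# ---------------------------------------------------------------------------

def shared_flanking_count(gene: str, partner: str,
                          blocks: list[SyntenyBlock]) -> int:
    """Number of non-family anchor pairs in blocks containing both genes —
    the operational reading of 'maximum number of flanking genes in
    segments'."""
    count = 0
    for blk in blocks:
        members = blk.member_genes()
        if gene in members and partner in members:
            count += sum(1 for a, b in blk.anchors
                         if gene not in (a, b) and partner not in (a, b))
    return count


def nearest_duplicate(gene: str,
                      candidates: dict[str, Criteria]) -> NearestDuplicateEdge:
    """Pick the gene's nearest duplicate by the lexicographic rule
    identity -> shared flanking -> Ks -> partner id. An undefined Ks is
    treated as +inf for the minimizing step and flagged."""
    if not candidates:
        raise ValueError(f"{gene}: no candidate partners")
    best = min(candidates.items(), key=lambda kv: kv[1].sort_key() + (kv[0],))
    partner, crit = best
    return NearestDuplicateEdge(gene, partner, crit,
                                ks_undefined=crit.ks is None)


# ---------------------------------------------------------------------------
# Series assembly
# ---------------------------------------------------------------------------

def _edge_key(u: str, v: str, crit: Criteria) -> tuple:
    a, b = sorted((u, v))
    return crit.sort_key() + (a, b)


def assemble_expansion_series(edges: list[NearestDuplicateEdge]
                              ) -> list[ExpansionSeries]:
    """Build simple paths from nearest-duplicate edges.

    Nodes of degree > 2 keep their two best incident edges (same
    lexicographic criteria) and drop the rest; any remaining cycle is broken
    at its worst edge. Deterministic: all ties resolve by gene ids.
    """
    import networkx as nx

    G = nx.Graph()
    for e in edges:
        G.add_node(e.gene)
        G.add_node(e.partner)
        key = _edge_key(e.gene, e.partner, e.criteria)
        if G.has_edge(e.gene, e.partner):
            if key < G.edges[e.gene, e.partner]["key"]:
                G.edges[e.gene, e.partner]["key"] = key
        else:
            G.add_edge(e.gene, e.partner, key=key)

    # Degree capping to force linearity; dropping one node's worst edges can
    # lower a neighbour's degree, so iterate to a fixed point.
    changed = True
    while changed:
        changed = False
        for node in sorted(G.nodes):
            incident = sorted(G.edges(node, data=True),
                              key=lambda uvd: uvd[2]["key"])
            for u, v, _ in incident[2:]:
                G.remove_edge(u, v)
                changed = True

    # Components now are paths or cycles; break each cycle at its worst edge.
    for cycle in nx.cycle_basis(G):
        cycle_edges = list(zip(cycle, cycle[1:] + cycle[:1]))
        worst = max(cycle_edges, key=lambda uv: G.edges[uv]["key"])
        G.remove_edge(*worst)

    series = []
    for comp in nx.connected_components(G):
        sub = G.subgraph(comp)
        if len(comp) == 1:
            series.append(ExpansionSeries([next(iter(comp))]))
            continue
        ends = sorted(n for n in sub.nodes if sub.degree(n) == 1)
        path = [ends[0]]
        prev = None
        while True:
            nxt = [n for n in sub.neighbors(path[-1]) if n != prev]
            if not nxt:
                break
            prev = path[-1]
            path.append(nxt[0])
        series.append(ExpansionSeries(path))
    series.sort(key=lambda s: s.genes[0])
    return series


# ---------------------------------------------------------------------------
# Orthology series across species
# ---------------------------------------------------------------------------

def build_orthology_series(family_by_species: dict[str, list[str]],
                           inter_genome_blocks: list[SyntenyBlock],
                           species_order: list[str]
                           ) -> list[OrthologySeries]:
    """Connected components of cross-species block-anchor pairs restricted
    to family genes; components spanning >= 2 species become series, and a
    component spanning every species marks its members ancestral anchors."""
    import networkx as nx

    species_of = {g: sp for sp, genes in family_by_species.items()
                  for g in genes}
    G = nx.Graph()
    for g in species_of:
        G.add_node(g)
    for blk in inter_genome_blocks:
        for a, b in blk.anchors:
            if a in species_of and b in species_of \
                    and species_of[a] != species_of[b]:
                G.add_edge(a, b)
    series = []
    for comp in sorted(nx.connected_components(G), key=min):
        spanned = {species_of[g] for g in comp}
        if len(spanned) < 2:
            continue
        entries: dict[str, str | None] = {}
        for sp in species_order:
            members = sorted(g for g in comp if species_of[g] == sp)
            entries[sp] = members[0] if members else None
        series.append(OrthologySeries(entries,
                                      ancestral=spanned == set(species_order)))
    return series


def write_series_reports(expansion: list[ExpansionSeries],
                         orthology: list[OrthologySeries],
                         species_order: list[str],
                         expansion_path, orthology_path) -> None:
    write_tsv(expansion_path, ["series", "length", "path"],
              [[i + 1, len(s), "->".join(s.genes)]
               for i, s in enumerate(expansion)])
    write_tsv(orthology_path, ["series", "ancestral"] + species_order,
              [[i + 1, int(s.ancestral)] + [s.entries.get(sp) for sp in species_order]
               for i, s in enumerate(orthology)])
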