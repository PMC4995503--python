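"""Synthetic genomes, sequences, alignments, gene structures and expression
matrices with planted ground truth.

Every generator is a pure function of (spec, seed). A single global seed
fans out to per-generator substreams by stable hashing of the generator
name, so adding parameters to one generator never perturbs another.

The genome generator plants a gene family shaped the way plant receptor
families expand: tandem arrays (consecutive copies with fewer than 10
intervening background genes), segmental/WGD blocks (two chromosome
intervals joined by a chain of collinear homologous gene pairs), dispersed
copies, and unrelated singletons. Plain background genes carry coordinates
only; family genes and segmental-block anchor pairs carry sequences so
homology is recoverable from the emitted FASTA alone.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np

from .codons import (CODONS, gy94_rate_matrix, transition_probabilities,
                     translate, uniform_codon_freqs, f3x4_freqs)
from .core_model import (Alignment, ExpressionMatrix, Gene, GeneSet,
                         SequenceRecord, write_tsv)

AA20 = "ACDEFGHIKLMNPQRSTVWY"

# Genes strictly closer than this many intervening genes count as tandem.
TANDEM_GAP = 10
# Planted features are separated by more than the collinear-chain rank gap
# (25), so a dispersed copy or array can never extend a planted block's
# anchor chain and every planted mode stays unambiguous.
_MARGIN = 28


def substream(seed: int, name: str) -> np.random.Generator:
    """Deterministic per-generator RNG derived from the global seed."""
    return np.random.default_rng([seed & 0x7FFFFFFF, zlib.crc32(name.encode())])


# ---------------------------------------------------------------------------
# Specs and truth containers
# ---------------------------------------------------------------------------

@dataclass
class FamilySpec:
    """Planted family composition for one synthetic genome."""

    n_tandem_arrays: int = 2
    array_sizes: tuple[int, ...] = (3, 2)
    n_segmental_blocks: int = 1
    block_gene_count: int = 5
    n_dispersed: int = 2
    n_singletons: int = 1
    intergenic_gap_genes: tuple[int, int] = (1, 5)  # uniform int range, < 10

    def __post_init__(self) -> None:
        if self.n_tandem_arrays != len(self.array_sizes):
            raise ValueError("array_sizes length must equal n_tandem_arrays")
        if any(s < 2 for s in self.array_sizes):
            raise ValueError("tandem array sizes must be >= 2")
        if self.n_segmental_blocks and self.block_gene_count < 5:
            raise ValueError("block_gene_count must be >= 5")
        lo, hi = self.intergenic_gap_genes
        if not (1 <= lo <= hi < TANDEM_GAP):
            raise ValueError("intergenic gaps must lie in [1, 9]")
        for name in ("n_tandem_arrays", "n_segmental_blocks", "n_dispersed",
                     "n_singletons"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass
class GenomeTruth:
    """Planted labels for one synthetic genome."""

    mode: dict[str, str] = field(default_factory=dict)       # gene -> mode
    arrays: list[list[str]] = field(default_factory=list)    # tandem arrays
    blocks: list[list[tuple[str, str]]] = field(default_factory=list)
    pairs: list[tuple[str, str]] = field(default_factory=list)  # homologs
    family_genes: list[str] = field(default_factory=list)

    def write(self, path) -> None:
        rows = [(g, m) for g, m in sorted(self.mode.items())]
        write_tsv(path, ["gene", "planted_mode"], rows)


# ---------------------------------------------------------------------------
# Sequence helpers
# ---------------------------------------------------------------------------

def _random_cds(rng: np.random.Generator, n_codons: int) -> str:
    idx = rng.integers(0, len(CODONS), size=n_codons)
    return "".join(CODONS[i] for i in idx)


def _mutate_cds(rng: np.random.Generator, cds: str, n_sub: int) -> str:
    """Substitute ~n_sub codons with random sense codons (never stops)."""
    codons = [cds[i:i + 3] for i in range(0, len(cds), 3)]
    for pos in rng.choice(len(codons), size=min(n_sub, len(codons)), replace=False):
        codons[pos] = CODONS[rng.integers(0, len(CODONS))]
    return "".join(codons)


def _random_protein(rng: np.random.Generator, n: int) -> str:
    return "".join(AA20[i] for i in rng.integers(0, 20, size=n))


# ---------------------------------------------------------------------------
# Genome simulation
# ---------------------------------------------------------------------------

def simulate_genome(n_chrom: int, genes_per_chrom: int, family_spec: FamilySpec,
                    seed: int, species: str = "synth",
                    family_cds_codons: int = 100,
                    ) -> tuple[GeneSet, GenomeTruth, dict[str, SequenceRecord]]:
    """Build a multi-chromosome genome with a planted gene family.

    Returns the GeneSet, the planted truth, and a dict of CDS records for
    every sequence-bearing gene (family genes and block anchors).
    Tandem arrays are runs of family genes with < 10 intervening background
    genes; all other planted features keep > 10 background genes from any
    family member so the planted mode is unambiguous.
    """
    rng = substream(seed, "genome")
    spec = family_spec

    # Per-chromosome slot lists; None = background, else gene id.
    slots: list[list[str | None]] = [[None] * genes_per_chrom for _ in range(n_chrom)]
    cursor = [0] * n_chrom  # next free slot index per chromosome
    truth = GenomeTruth()
    cds: dict[str, SequenceRecord] = {}

    ancestor = _random_cds(rng, family_cds_codons)
    fam_counter = 0

    def new_family_gene(parent_cds: str, n_sub: int) -> tuple[str, str]:
        nonlocal fam_counter
        fam_counter += 1
        gid = f"fam{fam_counter:03d}"
        gcds = _mutate_cds(rng, parent_cds, n_sub)
        cds[gid] = SequenceRecord(gid, gcds, "cds")
        truth.family_genes.append(gid)
        return gid, gcds

    def place(chrom: int, gid: str, gap_before: int) -> None:
        c = cursor[chrom] + gap_before
        if c >= genes_per_chrom:
            raise ValueError(
                f"infeasible spec: chromosome {chrom + 1} needs slot {c} "
                f"but has only {genes_per_chrom} gene slots")
        slots[chrom][c] = gid
        cursor[chrom] = c + 1

    def pick_chrom(needed: int, exclude: int | None = None) -> int:
        order = sorted(range(n_chrom), key=lambda c: cursor[c])
        for c in order:
            if c == exclude:
                continue
            if genes_per_chrom - cursor[c] >= needed + _MARGIN:
                return c
        raise ValueError(
            f"infeasible spec: no chromosome has {needed} + margin free gene slots")

    # Tandem arrays: consecutive family copies, each mutated from the
    # previous member so identity decays along the planted expansion order.
    for size in spec.array_sizes:
        span = _MARGIN + size * (spec.intergenic_gap_genes[1] + 1)
        chrom = pick_chrom(span)
        members = []
        parent = ancestor
        for k in range(size):
            gid, parent = new_family_gene(parent, n_sub=3 + 2 * k)
            gap = _MARGIN if k == 0 else int(rng.integers(
                spec.intergenic_gap_genes[0], spec.intergenic_gap_genes[1] + 1))
            place(chrom, gid, gap)
            members.append(gid)
        truth.arrays.append(members)
        for m in members:
            truth.mode[m] = "tandem"

    # Segmental blocks: two intervals on distinct chromosomes, each with
    # block_gene_count collinear anchor pairs; the middle pair is a family
    # pair, the rest are background-anchor homolog pairs.
    anchor_counter = 0
    for b in range(spec.n_segmental_blocks):
        npairs = spec.block_gene_count
        need = _MARGIN + npairs * 3
        ca = pick_chrom(need)
        cb = pick_chrom(need, exclude=ca) if n_chrom > 1 else ca
        fam_idx = npairs // 2
        pairs_ab: list[tuple[str, str]] = []
        ids_a, ids_b = [], []
        for k in range(npairs):
            if k == fam_idx:
                ga, _ = new_family_gene(ancestor, n_sub=5)
                gb, _ = new_family_gene(ancestor, n_sub=5)
                truth.mode[ga] = truth.mode[gb] = "wgd_segmental"
            else:
                anchor_counter += 1
                ga = f"anc{anchor_counter:03d}a"
                gb = f"anc{anchor_counter:03d}b"
                acds = _random_cds(rng, family_cds_codons)
                cds[ga] = SequenceRecord(ga, acds, "cds")
                cds[gb] = SequenceRecord(gb, _mutate_cds(rng, acds, 4), "cds")
            gap = _MARGIN if k == 0 else int(rng.integers(1, 3))
            place(ca, ga, gap)
            gap = _MARGIN if k == 0 else int(rng.integers(1, 3))
            place(cb, gb, gap)
            ids_a.append(ga)
            ids_b.append(gb)
            pairs_ab.append((ga, gb))
        truth.blocks.append(pairs_ab)
        truth.pairs.extend(pairs_ab)

    # Dispersed copies: isolated family genes far from any other member.
    for _ in range(spec.n_dispersed):
        gid, _ = new_family_gene(ancestor, n_sub=6)
        chrom = pick_chrom(1)
        place(chrom, gid, _MARGIN)
        truth.mode[gid] = "dispersed"

    # Singletons: family-annotated genes with no homolog anywhere.
    for s in range(spec.n_singletons):
        fam_counter += 1
        gid = f"fam{fam_counter:03d}"
        cds[gid] = SequenceRecord(gid, _random_cds(rng, family_cds_codons), "cds")
        truth.family_genes.append(gid)
        truth.mode[gid] = "singleton"
        chrom = pick_chrom(1)
        place(chrom, gid, _MARGIN)

    # All family genes except singletons are mutually homologous.
    non_single = [g for g in truth.family_genes if truth.mode[g] != "singleton"]
    for i in range(len(non_single)):
        for j in range(i + 1, len(non_single)):
            pair = tuple(sorted((non_single[i], non_single[j])))
            if pair not in truth.pairs:
                truth.pairs.append(pair)

    # Materialize genes: 1 kb loci on a 2 kb grid, background genes fill
    # the remaining slots.
    genes: list[Gene] = []
    bg_counter = 0
    for c in range(n_chrom):
        chrom_name = f"chr{c + 1}"
        for idx in range(genes_per_chrom):
            gid = slots[c][idx]
            if gid is None:
                bg_counter += 1
                gid = f"bg{bg_counter:04d}"
            start = 1 + idx * 2000
            strand = "+" if rng.random() < 0.5 else "-"
            genes.append(Gene(gid, chrom_name, start, start + 999, strand))
    return GeneSet(species, genes), truth, cds


def family_proteins(cds: dict[str, SequenceRecord]) -> list[SequenceRecord]:
    """Translate every sequence-bearing gene's CDS."""
    return [SequenceRecord(gid, translate(rec.residues), "protein")
            for gid, rec in sorted(cds.items())]


# ---------------------------------------------------------------------------
# Codon-pair evolution under GY94/M0
# ---------------------------------------------------------------------------

def evolve_codon_sequences(length_codons: int, omega: float, kappa: float,
                           t: float, codon_freq: str = "uniform",
                           freq_params: np.ndarray | None = None,
                           seed: int = 0) -> tuple[Alignment, dict]:
    """Evolve a codon pair at divergence t under the one-ratio (M0) model.

    The ancestor row is drawn from the equilibrium codon distribution; the
    second row is drawn codon-wise from exp(Qt), where Q is the GY94 rate
    matrix (single-nucleotide changes only, kappa on transitions, omega on
    nonsynonymous changes, target-codon frequency on every rate), scaled so
    t is expected substitutions per codon.
    """
    if length_codons < 1:
        raise ValueError("length_codons must be >= 1")
    if omega < 0 or kappa <= 0 or t < 0:
        raise ValueError("require omega >= 0, kappa > 0, t >= 0")
    rng = substream(seed, "codon_pair")
    if codon_freq == "uniform":
        pi = uniform_codon_freqs()
    elif codon_freq == "f3x4":
        if freq_params is None:
            raise ValueError("f3x4 requires a 3x4 nucleotide frequency table")
        pi = f3x4_freqs(freq_params)
    else:
        raise ValueError(f"unknown codon_freq {codon_freq!r}")
    Q = gy94_rate_matrix(max(omega, 1e-12), kappa, pi)
    anc_idx = rng.choice(len(CODONS), size=length_codons, p=pi)
    if t == 0:
        der_idx = anc_idx.copy()
    else:
        P = transition_probabilities(Q, pi, t)
        if omega == 0:
            # omega=0 leaves an absorbing-synonymous chain; forbid any
            # numerical leakage into nonsynonymous states.
            from .codons import AA_OF
            for i in range(len(CODONS)):
                for j in range(len(CODONS)):
                    if AA_OF[CODONS[i]] != AA_OF[CODONS[j]]:
                        P[i, j] = 0.0
            P /= P.sum(axis=1, keepdims=True)
        der_idx = np.array([rng.choice(len(CODONS), p=P[i]) for i in anc_idx])
    row_a = "".join(CODONS[i] for i in anc_idx)
    row_b = "".join(CODONS[i] for i in der_idx)
    aln = Alignment(["anc", "der"], [row_a, row_b], "codon")
    truth = {"omega": omega, "kappa": kappa, "t": t, "pi": pi}
    return aln, truth


# ---------------------------------------------------------------------------
# Protein MSA with planted conserved intervals
# ---------------------------------------------------------------------------

def simulate_msa(n_rows: int, length: int,
                 conserved_intervals: list[tuple[int, int]],
                 background_entropy: float = 1.0,
                 seed: int = 0) -> tuple[Alignment, dict]:
    """Protein alignment whose columns inside ``conserved_intervals``
    (1-based inclusive) repeat a single residue; background columns draw
    residues independently per row from a restricted alphabet whose breadth
    scales with ``background_entropy`` in (0, 1]."""
    if n_rows < 2 or length < 1:
        raise ValueError("need >= 2 rows and length >= 1")
    rng = substream(seed, "msa")
    conserved_cols: set[int] = set()
    for lo, hi in conserved_intervals:
        if not (1 <= lo <= hi <= length):
            raise ValueError(f"interval ({lo},{hi}) outside 1..{length}")
        conserved_cols.update(range(lo, hi + 1))
    k = max(2, int(round(20 * background_entropy)))
    cols = []
    for c in range(1, length + 1):
        if c in conserved_cols:
            res = AA20[rng.integers(0, 20)]
            cols.append(res * n_rows)
        else:
            idx = rng.integers(0, k, size=n_rows)
            cols.append("".join(AA20[i] for i in idx))
    rows = ["".join(col[r] for col in cols) for r in range(n_rows)]
    ids = [f"seq{r + 1:02d}" for r in range(n_rows)]
    truth = {"conserved_columns": sorted(conserved_cols),
             "conserved_intervals": list(conserved_intervals)}
    return Alignment(ids, rows, "protein"), truth


# ---------------------------------------------------------------------------
# Gene structures (intron positions/phases) on an alignment
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneModel:
    """CDS-relative intron placement: each offset n means an intron falls
    after CDS nucleotide n (1-based count of preceding nucleotides)."""

    gene_id: str
    cds_length: int
    intron_offsets: tuple[int, ...]


def simulate_gene_structures(alignment: Alignment,
                             conserved_intron_slots: list[tuple[int, int]],
                             noise_slots_per_gene: int = 0,
                             seed: int = 0) -> tuple[list[GeneModel], dict]:
    """Plant introns on the genes behind a protein alignment.

    ``conserved_intron_slots`` are (alignment column, phase) pairs placed in
    every row at the homologous position; noise slots are row-private random
    placements. Planted columns must be gap-free in all rows.
    """
    rng = substream(seed, "gene_structures")
    models = []
    truth_marks: dict[str, list[tuple[int, int]]] = {}
    for rid, row in zip(alignment.ids, alignment.rows):
        ungapped = row.replace("-", "")
        cds_len = 3 * len(ungapped)
        offsets: set[int] = set()
        marks = []
        for col, phase in conserved_intron_slots:
            if not (1 <= col <= alignment.length):
                raise ValueError(f"column {col} outside alignment")
            if row[col - 1] == "-":
                raise ValueError(
                    f"planted intron column {col} is a gap in row {rid}")
            residue = len(row[:col].replace("-", ""))  # 1-based ungapped index
            offsets.add(3 * (residue - 1) + phase)
            marks.append((col, phase))
        for _ in range(noise_slots_per_gene):
            offsets.add(int(rng.integers(1, cds_len)))
        models.append(GeneModel(rid, cds_len, tuple(sorted(offsets))))
        truth_marks[rid] = marks
    truth = {"conserved_slots": list(conserved_intron_slots),
             "marks": truth_marks}
    return models, truth


# ---------------------------------------------------------------------------
# Expression matrices with planted clusters
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ExpressionClusterSpec:
    """One planted cluster: mean log2 profile per tissue and noise sd."""

    name: str
    tissue_means: tuple[float, ...]
    sd: float
    n_genes: int


def simulate_expression(tissues: list[str],
                        cluster_specs: list[ExpressionClusterSpec],
                        n_replicates: int = 3,
                        seed: int = 0) -> tuple[ExpressionMatrix, dict]:
    """Planted-cluster expression matrix on the log2 scale; replicate-level
    noise is independent Gaussian."""
    import pandas as pd

    rng = substream(seed, "expression")
    samples, tissue_map, rep_map = [], {}, {}
    for t in tissues:
        for r in range(1, n_replicates + 1):
            s = f"{t}_r{r}"
            samples.append(s)
            tissue_map[s] = t
            rep_map[s] = r
    rows, gene_ids, labels = [], [], {}
    g = 0
    for spec in cluster_specs:
        if len(spec.tissue_means) != len(tissues):
            raise ValueError(f"cluster {spec.name}: means must cover all tissues")
        for _ in range(spec.n_genes):
            g += 1
            gid = f"gene{g:03d}"
            gene_ids.append(gid)
            labels[gid] = spec.name
            row = [spec.tissue_means[tissues.index(tissue_map[s])]
                   + (rng.normal(0.0, spec.sd) if spec.sd > 0 else 0.0)
                   for s in samples]
            rows.append(row)
    values = pd.DataFrame(rows, index=gene_ids, columns=samples)
    mat = ExpressionMatrix(values, tissue_map, rep_map)
    pref = {spec.name: tissues[int(np.argmax(spec.tissue_means))]
            for spec in cluster_specs}
    truth = {"cluster": labels, "preferred_tissue": pref}
    return mat, truth
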