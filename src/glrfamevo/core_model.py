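"""Core domain types and readers/writers for standard formats.

Coordinates are 1-based inclusive internally; BED input (0-based half-open)
is converted at the boundary. Gene ranks are 0-based per-chromosome positions
after ordering by start (ties broken by ascending end, then id).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Iterable, Literal

import dendropy
from Bio import SeqIO
from Bio.Align import PairwiseAligner, substitution_matrices
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


class ParseError(ValueError):
    """Raised for malformed input files; carries a line number when known."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Gene:
    """A gene locus. ``rank`` is its 0-based position among genes on its
    chromosome ordered by start coordinate."""

    id: str
    chromosome: str
    start: int  # 1-based, inclusive
    end: int    # inclusive, end >= start
    strand: str = "+"
    rank: int = -1

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise ValueError(f"gene {self.id}: end {self.end} < start {self.start}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.id}: bad strand {self.strand!r}")


class GeneSet:
    """All genes of one species, indexed by id and by chromosome order.

    Ranks are (re)assigned on construction: per chromosome, genes are sorted
    by (start, end, id) and numbered 0..n-1.
    """

    def __init__(self, species: str, genes: Iterable[Gene]):
        self.species = species
        raw = list(genes)
        seen: set[str] = set()
        for g in raw:
            if g.id in seen:
                raise ValueError(f"duplicate gene id {g.id!r}")
            seen.add(g.id)
        by_chrom: dict[str, list[Gene]] = {}
        for g in raw:
            by_chrom.setdefault(g.chromosome, []).append(g)
        self.genes: dict[str, Gene] = {}
        self.chromosomes: dict[str, list[str]] = {}
        for chrom in sorted(by_chrom):
            ordered = sorted(by_chrom[chrom], key=lambda g: (g.start, g.end, g.id))
            ids = []
            for rank, g in enumerate(ordered):
                g2 = Gene(g.id, g.chromosome, g.start, g.end, g.strand, rank)
                self.genes[g2.id] = g2
                ids.append(g2.id)
            self.chromosomes[chrom] = ids

    def __len__(self) -> int:
        return len(self.genes)

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self.genes

    def __getitem__(self, gene_id: str) -> Gene:
        return self.genes[gene_id]

    def rank(self, gene_id: str) -> int:
        return self.genes[gene_id].rank

    def intervening(self, a: str, b: str) -> int | None:
        """Number of genes strictly between a and b on their shared
        chromosome, or None if they sit on different chromosomes."""
        ga, gb = self.genes[a], self.genes[b]
        if ga.chromosome != gb.chromosome:
            return None
        return abs(ga.rank - gb.rank) - 1


@dataclass(frozen=True)
class SequenceRecord:
    """A named sequence; ``kind`` distinguishes protein / cds / intron."""

    id: str
    residues: str
    kind: Literal["protein", "cds", "intron"] = "protein"

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class Alignment:
    """Gapped equal-length rows; gap character is '-'."""

    ids: list[str]
    rows: list[str]
    alphabet: Literal["protein", "nucleotide", "codon"] = "protein"

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.rows):
            raise ValueError("ids and rows differ in count")
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("duplicate ids in alignment")
        lengths = {len(r) for r in self.rows}
        if len(lengths) > 1:
            raise ValueError(f"unequal row lengths: {sorted(lengths)}")
        if self.alphabet == "codon":
            if self.length % 3 != 0:
                raise ValueError("codon alignment length not divisible by 3")
            for rid, row in zip(self.ids, self.rows):
                for i in range(0, len(row), 3):
                    cod = row[i:i + 3]
                    if "-" in cod and cod != "---":
                        raise ValueError(
                            f"row {rid}: gap not in whole-codon units at {i}")

    @property
    def length(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    def row(self, rid: str) -> str:
        return self.rows[self.ids.index(rid)]

    def column(self, i: int) -> str:
        """0-based column as a string of one residue per row."""
        return "".join(r[i] for r in self.rows)

    def subset(self, ids: list[str]) -> "Alignment":
        return Alignment(list(ids), [self.row(i) for i in ids], self.alphabet)


class ExpressionMatrix:
    """Genes x samples expression values with tissue and replicate maps.

    ``values`` is a pandas DataFrame (index = gene ids, columns = sample
    ids); every sample maps to a tissue and a replicate index. No missing
    cells are permitted after ingestion.
    """

    def __init__(self, values, sample_tissue: dict[str, str],
                 sample_replicate: dict[str, int]):
        import pandas as pd

        self.values = pd.DataFrame(values).astype(float)
        if self.values.shape[1] < 2:
            raise ValueError("expression matrix needs at least 2 samples")
        if self.values.isna().any().any():
            raise ValueError("missing cells in expression matrix")
        missing = set(self.values.columns) - set(sample_tissue)
        if missing:
            raise ValueError(f"samples without tissue assignment: {sorted(missing)}")
        self.sample_tissue = dict(sample_tissue)
        self.sample_replicate = dict(sample_replicate)

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    def tissues(self) -> list[str]:
        seen: list[str] = []
        for s in self.samples:
            t = self.sample_tissue[s]
            if t not in seen:
                seen.append(t)
        return seen


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path, kind: str = "protein") -> list[SequenceRecord]:
    """Read a FASTA file into SequenceRecords; duplicate ids are rejected."""
    with open(path) as fh:
        text = fh.read()
    for lineno, line in enumerate(text.splitlines(), start=1):
        if line.strip():
            if not line.startswith(">"):
                raise ParseError(
                    f"{path}: line {lineno}: expected FASTA header, got {line[:30]!r}")
            break
    else:
        raise ParseError(f"{path}: empty FASTA file")
    records = []
    seen: set[str] = set()
    for rec in SeqIO.parse(io.StringIO(text), "fasta"):
        if rec.id in seen:
            raise ParseError(f"{path}: duplicate sequence id {rec.id!r}")
        seen.add(rec.id)
        records.append(SequenceRecord(rec.id, str(rec.seq), kind))
    return records


def write_fasta(records: list[SequenceRecord], path, width: int = 60) -> None:
    if not records:
        raise ValueError("refusing to write empty FASTA")
    if len({r.id for r in records}) != len(records):
        raise ValueError("duplicate ids")
    seqs = [SeqRecord(Seq(r.residues), id=r.id, description="") for r in records]
    with open(path, "w") as fh:
        SeqIO.write(seqs, fh, "fasta")


def read_alignment(path, alphabet: str = "protein") -> Alignment:
    recs = read_fasta(path)
    return Alignment([r.id for r in recs], [r.residues for r in recs], alphabet)


def write_alignment(aln: Alignment, path) -> None:
    write_fasta([SequenceRecord(i, r) for i, r in zip(aln.ids, aln.rows)], path)


# ---------------------------------------------------------------------------
# Gene positions (GFF3 / BED)
# ---------------------------------------------------------------------------

def read_gene_positions(path, format: str, species: str = "unknown") -> GeneSet:
    """Read gene coordinates from GFF3 (1-based inclusive) or BED
    (0-based half-open, converted on read)."""
    if format not in ("gff3", "bed"):
        raise ValueError(f"unknown format {format!r} (expected 'gff3' or 'bed')")
    genes: list[Gene] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if format == "bed":
                if len(fields) < 4:
                    raise ParseError(f"{path}: line {lineno}: BED needs >= 4 columns")
                chrom, start0, end0, name = fields[:4]
                strand = fields[5] if len(fields) > 5 and fields[5] in "+-" else "+"
                start, end = int(start0) + 1, int(end0)
            else:
                if len(fields) < 9:
                    raise ParseError(f"{path}: line {lineno}: GFF3 needs 9 columns")
                chrom, _src, ftype, s, e, _score, strand, _phase, attrs = fields[:9]
                if ftype not in ("gene", "pseudogene"):
                    continue
                start, end = int(s), int(e)
                name = None
                for kv in attrs.split(";"):
                    if kv.startswith("ID="):
                        name = kv[3:]
                        break
                if name is None:
                    raise ParseError(f"{path}: line {lineno}: gene feature lacks ID=")
                if strand not in "+-":
                    strand = "+"
            if end < start:
                raise ParseError(
                    f"{path}: line {lineno}: end {end} < start {start}")
            genes.append(Gene(name, chrom, start, end, strand))
    return GeneSet(species, genes)


def write_gene_positions(geneset: GeneSet, path, format: str = "bed") -> None:
    if format not in ("gff3", "bed"):
        raise ValueError(f"unknown format {format!r}")
    with open(path, "w") as fh:
        if format == "gff3":
            fh.write("##gff-version 3\n")
        for chrom in geneset.chromosomes:
            for gid in geneset.chromosomes[chrom]:
                g = geneset[gid]
                if format == "bed":
                    fh.write(f"{g.chromosome}\t{g.start - 1}\t{g.end}\t{g.id}\t.\t{g.strand}\n")
                else:
                    fh.write(f"{g.chromosome}\tglrfamevo\tgene\t{g.start}\t{g.end}\t.\t"
                             f"{g.strand}\t.\tID={g.id}\n")


# ---------------------------------------------------------------------------
# Newick trees (dendropy-backed)
# ---------------------------------------------------------------------------

def read_newick(path_or_string) -> dendropy.Tree:
    """Parse a Newick tree; internal-node labels are read as support values."""
    src = str(path_or_string)
    try:
        if src.lstrip().startswith("("):
            tree = dendropy.Tree.get(data=src, schema="newick",
                                     preserve_underscores=True)
        else:
            tree = dendropy.Tree.get(path=src, schema="newick",
                                     preserve_underscores=True)
    except Exception as exc:  # dendropy raises several error types
        raise ParseError(f"Newick parse failed: {exc}") from exc
    labels = [lf.taxon.label for lf in tree.leaf_node_iter()]
    if len(set(labels)) != len(labels):
        raise ParseError("duplicate leaf labels in tree")
    return tree


def write_newick(tree: dendropy.Tree, path) -> None:
    with open(path, "w") as fh:
        fh.write(tree.as_string(schema="newick", suppress_rooting=True,
                                unquoted_underscores=True))


# ---------------------------------------------------------------------------
# Pairwise alignment
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PairwiseResult:
    ids: tuple[str, str]
    rows: tuple[str, str]
    score: float
    percent_identity: float
    percent_identity_with_gaps: float


def _make_aligner(mode: str, matrix: str, gap_open: float, gap_extend: float,
                  match: float, mismatch: float, alphabet: str) -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = mode
    if alphabet == "protein":
        aligner.substitution_matrix = substitution_matrices.load(matrix)
    else:
        aligner.match_score = match
        aligner.mismatch_score = mismatch
    # Biopython gap scores are penalties expressed as negatives; the open
    # penalty applies to the first gap residue.
    aligner.open_gap_score = -(gap_open + gap_extend)
    aligner.extend_gap_score = -gap_extend
    return aligner


def pairwise_align(a: SequenceRecord, b: SequenceRecord,
                   mode: str = "global",
                   matrix: str = "BLOSUM62",
                   gap_open: float = 10.0, gap_extend: float = 1.0,
                   match: float = 2.0, mismatch: float = -1.0) -> PairwiseResult:
    """Optimal pairwise alignment (Needleman-Wunsch / Smith-Waterman with
    affine gaps).

    Percent identity uses only columns where both rows are non-gap
    (``percent_identity``); the variant over all aligned columns is also
    reported since the literature uses both conventions.
    """
    if mode not in ("global", "local"):
        raise ValueError(f"mode must be 'global' or 'local', got {mode!r}")
    if not a.residues or not b.residues:
        raise ValueError("empty sequence")
    alphabet = "protein" if a.kind == "protein" else "nucleotide"
    aligner = _make_aligner(mode, matrix, gap_open, gap_extend, match, mismatch,
                            alphabet)
    alns = aligner.align(a.residues, b.residues)
    best = alns[0]
    row_a, row_b = str(best[0]), str(best[1])
    both = ident = 0
    for x, y in zip(row_a, row_b):
        if x != "-" and y != "-":
            both += 1
            if x == y:
                ident += 1
    pid = 100.0 * ident / both if both else 0.0
    pid_gaps = 100.0 * ident / len(row_a) if row_a else 0.0
    return PairwiseResult((a.id, b.id), (row_a, row_b), float(best.score),
                          pid, pid_gaps)


# ---------------------------------------------------------------------------
# TSV convenience
# ---------------------------------------------------------------------------

MISSING = "."


def write_tsv(path, header: list[str], rows: Iterable[Iterable], comment: str | None = None) -> None:
    """Write a TSV report; None values become '.'."""
    with open(path, "w") as fh:
        if comment:
            fh.write(f"# {comment}\n")
        fh.write("\t".join(header) + "\n")
        for row in rows:
            fh.write("\t".join(MISSING if v is None else str(v) for v in row) + "\n")
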