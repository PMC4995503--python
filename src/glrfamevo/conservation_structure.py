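"""Physico-chemical conservation profiling and intron-structure comparison.

The per-column conservation index counts, out of ten residue property
classes (the Livingstone-Barton/AMAS set used by Jalview's conservation
shading), how many the aligned residues agree on — all members or all
non-members. A gap or X belongs to no class, so it breaks every "all-in"
agreement. The index is capped at 10 (no identity bonus) so "number of
conserved physico-chemical properties" stays literal; the Jalview-style
11-level variant is available via ``identity_bonus``.
"""

from __future__ import annotations

from dataclasses import dataclass
from statistics import mean

from .core_model import Alignment, SequenceRecord, pairwise_align, write_tsv
from .synthetic_data import GeneModel

# Livingstone & Barton residue property classes (as embedded in Jalview's
# ResidueProperties); membership is fixed data, not tunable.
PROPERTY_TABLE: dict[str, frozenset[str]] = {
    "hydrophobic": frozenset("ILVCAGMFYWHKT"),
    "polar": frozenset("YWHKREQDNSTC"),
    "small": frozenset("VCAGDNSTP"),
    "proline": frozenset("P"),
    "tiny": frozenset("AGS"),
    "aliphatic": frozenset("ILV"),
    "aromatic": frozenset("FYWH"),
    "charged": frozenset("HKRED"),
    "negative": frozenset("ED"),
    "positive": frozenset("HKR"),
}
PROPERTIES = tuple(PROPERTY_TABLE)


def column_conservation_index(column: str,
                              property_table: dict[str, frozenset[str]] | None = None,
                              ignore_gaps: bool = False,
                              identity_bonus: bool = False) -> int:
    """Count property classes on which every row of the column agrees.

    ``ignore_gaps`` drops gap/X rows before testing agreement instead of
    letting them veto membership. With ``identity_bonus`` an identical
    non-gap column scores 11 (Jalview's '*' level).
    """
    if not column:
        raise ValueError("empty column")
    table = property_table or PROPERTY_TABLE
    rows = [c for c in column.upper()]
    if ignore_gaps:
        rows = [c for c in rows if c not in "-X."] or ["-"]
    count = 0
    for members in table.values():
        flags = {(c in members) for c in rows}
        if len(flags) == 1:
            count += 1
    if identity_bonus and len(set(rows)) == 1 and rows[0] not in "-X.":
        count += 1
    return count


def conservation_profile(alignment: Alignment, **kwargs) -> list[int]:
    """Per-column conservation indices for a protein alignment."""
    return [column_conservation_index(alignment.column(i), **kwargs)
            for i in range(alignment.length)]


@dataclass(frozen=True)
class WindowMean:
    start: int  # 1-based column
    end: int    # inclusive
    mean: float
    truncated: bool = False


def sliding_window_profile(indices: list[float], window: int = 20,
                           slide: int = 10) -> list[WindowMean]:
    """Window means over a per-column profile; windows start at columns
    1, 1+slide, 1+2*slide, ... and a final shorter-than-window tail is
    reported flagged as truncated."""
    if not indices:
        raise ValueError("empty profile")
    L = len(indices)
    out = []
    start = 1
    while start <= L:
        end = min(start + window - 1, L)
        vals = indices[start - 1:end]
        out.append(WindowMean(start, end, mean(vals), truncated=end - start + 1 < window))
        if end == L:
            break
        start += slide
    return out


def region_mean(indices: list[float], interval: tuple[int, int]) -> float:
    """Mean conservation index over a 1-based inclusive column interval
    (e.g. a trans-membrane or pore domain region)."""
    lo, hi = interval
    if not (1 <= lo <= hi <= len(indices)):
        raise ValueError(f"interval ({lo},{hi}) outside 1..{len(indices)}")
    return mean(indices[lo - 1:hi])


# ---------------------------------------------------------------------------
# Group identity
# ---------------------------------------------------------------------------

def _consensus(rows: list[str]) -> str:
    out = []
    for i in range(len(rows[0])):
        col = [r[i] for r in rows]
        best = max(sorted(set(col)), key=col.count)
        out.append(best)
    return "".join(out)


def group_identity(alignment: Alignment, group_a: list[str],
                   group_b: list[str], mode: str = "mean_pairwise",
                   count_gap_columns: bool = False) -> float:
    """Percent identity between two groups of aligned rows.

    mean_pairwise: mean over all cross pairs of the two groups of pairwise
    percent identity (identical non-gap pairs / columns where both rows are
    non-gap, or / all columns when ``count_gap_columns``). consensus:
    identity between the groups' majority-consensus strings.
    """
    if mode not in ("mean_pairwise", "consensus"):
        raise ValueError(f"unknown mode {mode!r}")

    def pid(x: str, y: str) -> float:
        both = ident = 0
        for a, b in zip(x, y):
            if a != "-" and b != "-":
                both += 1
                if a == b:
                    ident += 1
        denom = len(x) if count_gap_columns else both
        return 100.0 * ident / denom if denom else 0.0

    if mode == "consensus":
        ca = _consensus([alignment.row(i) for i in group_a])
        cb = _consensus([alignment.row(i) for i in group_b])
        return pid(ca, cb)
    vals = [pid(alignment.row(a), alignment.row(b))
            for a in group_a for b in group_b]
    if not vals:
        raise ValueError("no cross pairs")
    return mean(vals)


def intron_group_identity(introns_a: list[SequenceRecord],
                          introns_b: list[SequenceRecord]) -> float:
    """Mean pairwise identity between two groups of (unaligned) intron
    sequences, via global nucleotide alignment of every cross pair."""
    vals = []
    for ra in introns_a:
        for rb in introns_b:
            res = pairwise_align(ra, rb, mode="global")
            vals.append(res.percent_identity)
    if not vals:
        raise ValueError("no cross pairs")
    return mean(vals)


# ---------------------------------------------------------------------------
# Intron projection onto the alignment
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class IntronMark:
    gene_id: str
    column: int  # 1-based alignment column
    phase: int   # 0 | 1 | 2


def project_introns(models: list[GeneModel],
                    alignment: Alignment) -> list[IntronMark]:
    """Map CDS-relative intron offsets onto protein alignment columns.

    An intron after CDS nucleotide n sits at protein residue floor(n/3)+1
    with phase n mod 3; the residue index is then mapped through the gapped
    row to its alignment column.
    """
    marks = []
    for model in models:
        row = alignment.row(model.gene_id)
        ungapped_len = len(row.replace("-", ""))
        if model.cds_length != 3 * ungapped_len:
            raise ValueError(
                f"{model.gene_id}: CDS length {model.cds_length} does not "
                f"match aligned protein length {ungapped_len}")
        # residue index -> alignment column
        col_of: dict[int, int] = {}
        r = 0
        for c, ch in enumerate(row, start=1):
            if ch != "-":
                r += 1
                col_of[r] = c
        for n in model.intron_offsets:
            if not (0 < n < model.cds_length):
                raise ValueError(f"{model.gene_id}: intron offset {n} outside CDS")
            residue = n // 3 + 1  # phase-0: the residue following the codon
            phase = n % 3
            marks.append(IntronMark(model.gene_id, col_of[residue], phase))
    return marks


def conserved_intron_positions(marks: list[IntronMark], n_genes: int,
                               min_fraction: float = 1.0,
                               require_same_phase: bool = True
                               ) -> list[tuple[int, int | None, list[str]]]:
    """Column (and phase) combinations carried by >= min_fraction of genes.

    Returns (column, phase, member gene ids); phase is None when phases are
    not required to match.
    """
    groups: dict[tuple, list[str]] = {}
    for m in marks:
        key = (m.column, m.phase) if require_same_phase else (m.column,)
        groups.setdefault(key, []).append(m.gene_id)
    out = []
    for key in sorted(groups):
        members = sorted(set(groups[key]))
        if len(members) / n_genes >= min_fraction:
            col = key[0]
            phase = key[1] if require_same_phase else None
            out.append((col, phase, members))
    return out


def write_conservation_reports(indices, windows, marks, conserved,
                               profile_path, windows_path, marks_path,
                               conserved_path) -> None:
    write_tsv(profile_path, ["column", "index"],
              [[i + 1, v] for i, v in enumerate(indices)])
    write_tsv(windows_path, ["start", "end", "mean", "truncated"],
              [[w.start, w.end, round(w.mean, 4), int(w.truncated)]
               for w in windows])
    write_tsv(marks_path, ["gene", "column", "phase"],
              [[m.gene_id, m.column, m.phase] for m in marks])
    write_tsv(conserved_path, ["column", "phase", "members"],
              [[c, p, ",".join(mem)] for c, p, mem in conserved])
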