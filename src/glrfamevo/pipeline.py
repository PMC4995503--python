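"""End-to-end orchestration: one flat config drives every stage on a
synthetic genome with planted truth, writing TSV/FASTA/Newick outputs.

Stage order: synthesize -> identify -> pairs -> chains -> classify ->
series -> conservation -> selection -> phylo -> expression. Outputs are
byte-identical across reruns of the same config (all randomness flows from
the config seed through named substreams; no timestamps in output files).
"""

from __future__ import annotations

import hashlib
import sys
from dataclasses import dataclass, field, asdict
from pathlib import Path

from . import conservation_structure as cons
from . import expansion_history as expand
from . import expression_analysis as expr
from . import family_identification as famid
from . import phylo_classify as phylo
from . import selection_analysis as sel
from . import synteny_duplication as dup
from . import synthetic_data as synth
from .codons import translate
from .core_model import (Alignment, SequenceRecord, write_fasta,
                         write_gene_positions, write_newick, write_tsv)

ALL_STAGES = ("synthesize", "identify", "pairs", "chains", "classify",
              "series", "conservation", "selection", "phylo", "expression")


@dataclass
class PipelineConfig:
    seed: int = 1
    n_chrom: int = 4
    genes_per_chrom: int = 120
    n_tandem_arrays: int = 2
    array_sizes: tuple[int, ...] = (3, 2)
    n_segmental_blocks: int = 1
    block_gene_count: int = 5
    n_dispersed: int = 2
    n_singletons: int = 1
    tandem_gap: int = 10
    min_block_pairs: int = 5
    max_rank_gap: int = 25
    top_k: int = 5
    window: int = 20
    slide: int = 10
    bootstrap_reps: int = 20
    k_clusters: int = 3
    m0_pairs: int = 2
    stages: tuple[str, ...] = ALL_STAGES

    def validate(self) -> None:
        if self.tandem_gap < 1:
            raise ValueError("tandem_gap must be >= 1")
        if self.min_block_pairs < 2:
            raise ValueError("min_block_pairs must be >= 2")
        if self.window < 1 or self.slide < 1:
            raise ValueError("window and slide must be >= 1")
        if self.k_clusters < 1:
            raise ValueError("k_clusters must be >= 1")
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")

    def config_hash(self) -> str:
        text = repr(sorted(asdict(self).items()))
        return hashlib.sha256(text.encode()).hexdigest()[:16]


_INT_KEYS = {"seed", "n_chrom", "genes_per_chrom", "n_tandem_arrays",
             "n_segmental_blocks", "block_gene_count", "n_dispersed",
             "n_singletons", "tandem_gap", "min_block_pairs", "max_rank_gap",
             "top_k", "window", "slide", "bootstrap_reps", "k_clusters",
             "m0_pairs"}


def validate_config(path) -> PipelineConfig:
    """Parse a flat ``key = value`` config file; unknown keys are rejected
    and defaults are filled for omitted ones."""
    cfg = PipelineConfig()
    valid = set(asdict(cfg))
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.split("#")[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{lineno}: expected key = value")
            key, _, val = (x.strip() for x in line.partition("="))
            if key not in valid:
                raise ValueError(f"{path}:{lineno}: unknown key {key!r}")
            if key in _INT_KEYS:
                setattr(cfg, key, int(val))
            elif key == "array_sizes":
                cfg.array_sizes = tuple(int(x) for x in val.split(",") if x)
            elif key == "stages":
                cfg.stages = tuple(x.strip() for x in val.split(",") if x.strip())
    cfg.validate()
    return cfg


@dataclass
class RunReport:
    config_hash: str
    row_counts: dict[str, int] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)
    parameters: dict = field(default_factory=dict)


def _log(stage: str, msg: str) -> None:
    print(f"[{stage}] {msg}", file=sys.stderr)


def run_pipeline(config: PipelineConfig, outdir) -> RunReport:
    """Run every enabled stage in dependency order; a stage failure aborts
    with the stage name. Returns the run report (also written as TSV)."""
    config.validate()
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    report = RunReport(config.config_hash(), parameters=asdict(config))
    on = set(config.stages)
    seed = config.seed

    stage = "synthesize"
    try:
        spec = synth.FamilySpec(
            n_tandem_arrays=config.n_tandem_arrays,
            array_sizes=tuple(config.array_sizes),
            n_segmental_blocks=config.n_segmental_blocks,
            block_gene_count=config.block_gene_count,
            n_dispersed=config.n_dispersed,
            n_singletons=config.n_singletons)
        geneset, truth, cds = synth.simulate_genome(
            config.n_chrom, config.genes_per_chrom, spec, seed)
        proteins = synth.family_proteins(cds)
        prot_by_id = {p.id: p for p in proteins}
        if "synthesize" in on:
            write_gene_positions(geneset, out / "genes.bed", "bed")
            write_fasta(proteins, out / "proteins.fasta")
            write_fasta(sorted(cds.values(), key=lambda r: r.id),
                        out / "cds.fasta")
            truth.write(out / "truth_modes.tsv")
            report.row_counts["synthesize"] = len(geneset)
            _log(stage, f"{len(geneset)} genes, {len(truth.family_genes)} family")

        family_prots = [prot_by_id[g] for g in sorted(truth.family_genes)]
        family_cds = {g: cds[g] for g in truth.family_genes}

        stage = "identify"
        if "identify" in on:
            calls, summary = famid.filter_pseudogenes(
                sorted(family_cds.values(), key=lambda r: r.id))
            write_tsv(out / "pseudogene_calls.tsv",
                      ["gene", "verdict"],
                      [[c.gene_id, c.verdict] for c in calls])
            report.row_counts["identify"] = len(calls)
            _log(stage, f"{summary['complete']} complete of {summary['candidates']}")

        stage = "pairs"
        pairs = []
        if "pairs" in on or "chains" in on or "classify" in on:
            threshold = dup.calibrate_pair_threshold(proteins, seed=seed)
            pairs = dup.find_homolog_pairs(proteins, top_k=max(config.top_k, 8),
                                           score_threshold=threshold)
            write_tsv(out / "homolog_pairs.tsv",
                      ["gene_a", "gene_b", "score", "identity"],
                      [[p.a, p.b, p.score, round(p.percent_identity, 2)]
                       for p in pairs])
            report.row_counts["pairs"] = len(pairs)
            _log(stage, f"{len(pairs)} pairs (threshold {threshold:.1f})")

        stage = "chains"
        blocks = []
        if "chains" in on or "classify" in on:
            blocks = dup.detect_collinear_chains(
                pairs, geneset, config.min_block_pairs, config.max_rank_gap)
            dup.write_duplication_reports([], [], blocks,
                                          out / "_calls_tmp.tsv",
                                          out / "_arrays_tmp.tsv",
                                          out / "synteny_blocks.tsv")
            (out / "_calls_tmp.tsv").unlink()
            (out / "_arrays_tmp.tsv").unlink()
            report.row_counts["chains"] = len(blocks)
            _log(stage, f"{len(blocks)} blocks")

        stage = "classify"
        calls, arrays = [], []
        if "classify" in on:
            calls = dup.classify_duplications(
                geneset, pairs, blocks,
                family_genes=sorted(truth.family_genes),
                tandem_gap=config.tandem_gap)
            arrays, summary = dup.group_tandem_arrays(calls, geneset,
                                                      config.tandem_gap)
            dup.write_duplication_reports(
                calls, arrays, blocks, out / "duplication_calls.tsv",
                out / "tandem_arrays.tsv", out / "synteny_blocks.tsv")
            frac = dup.tandem_fraction_from_calls(calls)
            write_tsv(out / "tandem_fraction.tsv",
                      ["n_tandem", "n_total", "percent"],
                      [[sum(1 for c in calls if c.mode == "tandem"),
                        len(calls), frac]])
            report.row_counts["classify"] = len(calls)
            _log(stage, f"{len(calls)} calls, tandem fraction {frac}%")

        # Pairwise identity and Ks for the series criteria.
        stage = "series"
        if "series" in on and calls:
            from .core_model import pairwise_align

            identities, ks = {}, {}
            fam_pairs = [p for p in pairs
                         if p.a in family_cds and p.b in family_cds]
            for p in fam_pairs:
                identities[(p.a, p.b)] = p.percent_identity
                est = sel.ng86(family_cds[p.a].residues, family_cds[p.b].residues)
                ks[(p.a, p.b)] = est.ds if est.status == "ok" else None
            edges = []
            for gid in sorted({g for p in fam_pairs for g in (p.a, p.b)}):
                cands = {}
                for p in fam_pairs:
                    if gid in (p.a, p.b):
                        other = p.b if p.a == gid else p.a
                        cands[other] = expand.Criteria(
                            identities[(p.a, p.b)],
                            expand.shared_flanking_count(gid, other, blocks),
                            ks[(p.a, p.b)])
                if cands:
                    edges.append(expand.nearest_duplicate(gid, cands))
            series = expand.assemble_expansion_series(edges)
            expand.write_series_reports(series, [], [],
                                        out / "expansion_series.tsv",
                                        out / "orthology_series.tsv")
            report.row_counts["series"] = len(series)
            _log(stage, f"{len(series)} series")

        # Family protein alignment: equal-length proteins by construction.
        fam_aln = Alignment([p.id for p in family_prots],
                            [p.residues for p in family_prots], "protein")

        stage = "conservation"
        if "conservation" in on:
            profile = cons.conservation_profile(fam_aln)
            windows = cons.sliding_window_profile(profile, config.window,
                                                 config.slide)
            models, _ = synth.simulate_gene_structures(
                fam_aln, [(10, 0), (40, 1)], noise_slots_per_gene=1, seed=seed)
            marks = cons.project_introns(models, fam_aln)
            conserved = cons.conserved_intron_positions(
                marks, len(models), min_fraction=1.0)
            cons.write_conservation_reports(
                profile, windows, marks, conserved,
                out / "conservation_profile.tsv", out / "window_means.tsv",
                out / "intron_marks.tsv", out / "conserved_introns.tsv")
            report.row_counts["conservation"] = len(profile)
            _log(stage, f"{len(windows)} windows, {len(conserved)} conserved introns")

        stage = "selection"
        if "selection" in on and calls:
            mode_of = {c.gene_id: c.mode for c in calls}
            estimates = {}
            by_group: dict[str, list] = {}
            fam_pairs = [p for p in pairs
                         if p.a in family_cds and p.b in family_cds]
            for i, p in enumerate(fam_pairs):
                est = sel.ng86(family_cds[p.a].residues,
                               family_cds[p.b].residues)
                estimates[(p.a, p.b)] = est
                by_group.setdefault(mode_of.get(p.a, "?"), []).append(est)
            for p in fam_pairs[:config.m0_pairs]:
                aln = Alignment([p.a, p.b], [family_cds[p.a].residues,
                                             family_cds[p.b].residues], "codon")
                estimates[(p.a + "(M0)", p.b)] = sel.m0_fit(aln, seed=seed)
            stats = sel.omega_by_group(by_group)
            sel.write_omega_reports(estimates, stats, out / "omega_pairs.tsv",
                                    out / "omega_groups.tsv")
            report.row_counts["selection"] = len(estimates)
            _log(stage, f"{len(estimates)} estimates")

        stage = "phylo"
        if "phylo" in on and len(fam_aln.ids) >= 4:
            # p-distance: the family set includes unrelated singletons whose
            # distances would saturate the Kimura correction
            tree = phylo.bootstrap_support(fam_aln, config.bootstrap_reps,
                                           correction="p", seed=seed)
            write_newick(tree, out / "family_tree.nwk")
            report.row_counts["phylo"] = len(fam_aln.ids)
            _log(stage, f"tree over {len(fam_aln.ids)} leaves")

        stage = "expression"
        if "expression" in on:
            tissues = ["root", "stem", "leaf", "cambium"]
            specs = [
                synth.ExpressionClusterSpec("c_root", (8.0, 2.0, 2.0, 2.0), 0.3, 6),
                synth.ExpressionClusterSpec("c_stem", (2.0, 8.0, 2.0, 2.0), 0.3, 6),
                synth.ExpressionClusterSpec("c_camb", (2.0, 2.0, 2.0, 8.0), 0.3, 6),
            ]
            mat, etruth = synth.simulate_expression(tissues, specs, seed=seed)
            # planted values are already log2-scale; standardize rows only
            z, flagged = expr.log2_standardize(
                expr.ExpressionMatrix(2.0 ** mat.values, mat.sample_tissue,
                                      mat.sample_replicate))
            assignment = expr.kmeans_cluster(z, config.k_clusters, seed=seed)
            prefs = expr.tissue_preference(z, assignment.labels)
            expr.write_expression_reports(z, assignment, prefs,
                                          out / "standardized.tsv",
                                          out / "clusters.tsv",
                                          out / "tissue_preference.tsv")
            ari = expr.clustering_ari(assignment, etruth["cluster"])
            write_tsv(out / "expression_summary.tsv",
                      ["k", "inertia", "ari_vs_planted"],
                      [[assignment.k, round(assignment.inertia, 6), ari]])
            report.row_counts["expression"] = len(z.genes)
            _log(stage, f"k={assignment.k}, ARI vs planted {ari}")
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    write_tsv(out / "run_report.tsv", ["stage", "rows"],
              sorted(report.row_counts.items()),
              comment=f"config_hash={report.config_hash}")
    return report
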