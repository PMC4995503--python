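"""qPCR/RNA-seq expression processing: Cq conversion, log2 standardization,
K-means clustering and tissue-preference calls.

Relative expression from quantification cycles uses the delta-Cq rule:
relative = E^-(Cq_gene - mean Cq_reference) per sample, with amplification
efficiency E = 2 by default (perfect doubling). Replicates are averaged
after transformation. Genes undetected in every sample are dropped and
listed; a missing Cq in some samples becomes relative 0 there.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.metrics import adjusted_rand_score

from .core_model import ExpressionMatrix, write_tsv


@dataclass
class CqTable:
    """Long-format Cq measurements: one row per (gene, sample, replicate)."""

    data: pd.DataFrame  # columns: gene, sample, replicate, cq
    reference_genes: list[str]
    sample_tissue: dict[str, str]
    efficiency: float = 2.0
    per_gene_efficiency: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        need = {"gene", "sample", "replicate", "cq"}
        if not need <= set(self.data.columns):
            raise ValueError(f"CqTable needs columns {sorted(need)}")
        if not self.reference_genes:
            raise ValueError("at least one reference gene required")
        if (self.data["cq"].dropna() <= 0).any():
            raise ValueError("Cq values must be positive")


@dataclass
class ClusterAssignment:
    labels: dict[str, int]
    centroids: np.ndarray  # k x samples
    k: int
    seed: int
    inertia: float


# ---------------------------------------------------------------------------
# Cq -> relative expression
# ---------------------------------------------------------------------------

def cq_to_relative(cq: CqTable) -> tuple[ExpressionMatrix, list[str]]:
    """Delta-Cq relative expression per sample, replicates averaged after
    the E^-dCq transform. Returns the matrix and the list of genes dropped
    because they were undetected in every sample."""
    df = cq.data
    samples = sorted(df["sample"].unique())
    genes = sorted(g for g in df["gene"].unique()
                   if g not in cq.reference_genes)
    ref_mean: dict[tuple[str, int], float] = {}
    for (sample, rep), grp in df.groupby(["sample", "replicate"]):
        refs = grp[grp["gene"].isin(cq.reference_genes)]["cq"].dropna()
        if refs.empty:
            raise ValueError(f"no reference Cq in sample {sample} rep {rep}")
        ref_mean[(sample, rep)] = float(refs.mean())
    values = pd.DataFrame(0.0, index=genes, columns=samples)
    detected = {g: False for g in genes}
    for (gene, sample, rep), grp in df.groupby(["gene", "sample", "replicate"]):
        if gene in cq.reference_genes:
            continue
        cqv = grp["cq"].iloc[0]
        if pd.isna(cqv):
            continue
        E = cq.per_gene_efficiency.get(gene, cq.efficiency)
        values.loc[gene, sample] += E ** (-(cqv - ref_mean[(sample, rep)]))
        detected[gene] = True
    # average over replicates per sample
    reps_per_sample = df.groupby("sample")["replicate"].nunique()
    for s in samples:
        values[s] /= reps_per_sample[s]
    dropped = sorted(g for g in genes if not detected[g])
    values = values.drop(index=dropped)
    if values.empty:
        raise ValueError("no detected genes")
    rep_map = {s: 1 for s in samples}
    return ExpressionMatrix(values, cq.sample_tissue, rep_map), dropped


# ---------------------------------------------------------------------------
# Transformation
# ---------------------------------------------------------------------------

def log2_standardize(mat: ExpressionMatrix, pseudocount: float | None = None
                     ) -> tuple[ExpressionMatrix, list[str]]:
    """log2(v + pseudocount), then per-gene centering and scaling by the
    population standard deviation (ddof=0). Constant rows become all-zero
    and are returned in the flagged list. The default pseudocount is 1e-4
    of the smallest positive value in the matrix."""
    v = mat.values
    if pseudocount is None:
        positive = v.values[v.values > 0]
        pseudocount = 1e-4 * positive.min() if positive.size else 1e-4
    logged = np.log2(v + pseudocount)
    mu = logged.mean(axis=1)
    sd = logged.std(axis=1, ddof=0)
    flagged = sorted(logged.index[sd == 0])
    sd_safe = sd.replace(0, 1.0)
    z = logged.sub(mu, axis=0).div(sd_safe, axis=0)
    return ExpressionMatrix(z, mat.sample_tissue, mat.sample_replicate), flagged


# ---------------------------------------------------------------------------
# Clustering
# ---------------------------------------------------------------------------

def kmeans_cluster(mat: ExpressionMatrix, k: int, n_init: int = 10,
                   seed: int = 0) -> ClusterAssignment:
    """Best-of-n_init k-means++ on genes x samples; deterministic given
    seed."""
    if not (1 <= k <= len(mat.genes)):
        raise ValueError(f"k={k} outside 1..{len(mat.genes)}")
    km = KMeans(n_clusters=k, n_init=n_init, init="k-means++",
                random_state=seed & 0x7FFFFFFF)
    labels = km.fit_predict(mat.values.values)
    return ClusterAssignment(dict(zip(mat.genes, (int(x) for x in labels))),
                             km.cluster_centers_, k, seed, float(km.inertia_))


def clustering_ari(assignment: ClusterAssignment,
                   truth: dict[str, str]) -> float:
    """Adjusted Rand index of a clustering against planted labels."""
    genes = sorted(assignment.labels)
    return float(adjusted_rand_score([truth[g] for g in genes],
                                     [assignment.labels[g] for g in genes]))


# ---------------------------------------------------------------------------
# Tissue preference
# ---------------------------------------------------------------------------

def tissue_preference(mat: ExpressionMatrix,
                      group_labels: dict[str, int | str] | None = None):
    """Per-gene preferred tissue = argmax of per-tissue mean value (exact
    ties list every argmax tissue); optional per-group fractions of members
    preferring each tissue."""
    tissues = mat.tissues()
    per_tissue = pd.DataFrame(
        {t: mat.values[[s for s in mat.samples
                        if mat.sample_tissue[s] == t]].mean(axis=1)
         for t in tissues})
    preferred: dict[str, list[str]] = {}
    for g in mat.genes:
        row = per_tissue.loc[g]
        best = row.max()
        preferred[g] = [t for t in tissues if row[t] == best]
    fractions = None
    if group_labels is not None:
        fractions = {}
        groups = sorted(set(group_labels.values()), key=str)
        for grp in groups:
            members = [g for g in mat.genes if group_labels.get(g) == grp]
            if not members:
                continue
            fractions[grp] = {
                t: sum(1 for g in members if preferred[g] == [t]) / len(members)
                for t in tissues}
    return {"preferred": preferred, "group_fractions": fractions}


def write_expression_reports(mat, assignment, prefs, matrix_path,
                             clusters_path, prefs_path) -> None:
    mat.values.to_csv(matrix_path, sep="\t")
    write_tsv(clusters_path, ["gene", "cluster"],
              sorted(assignment.labels.items()))
    write_tsv(prefs_path, ["gene", "preferred_tissue"],
              [[g, ",".join(ts)] for g, ts in sorted(prefs["preferred"].items())])
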