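# Methods

This note documents the models and procedures implemented in `glrfamevo`,
the defaults and why they were chosen, what the synthetic-data generators
do and do not emulate, and the numerical choices that affect results.

## Coordinate and data model

Gene coordinates are 1-based inclusive internally; BED input (0-based,
half-open) is converted at the boundary. Within a chromosome, genes are
ranked 0..n−1 by start coordinate, ties broken by ascending end then
lexicographic id, so ranks are always deterministic. All duplication logic
operates on ranks ("intervening genes"), never on base-pair distances.

Percent identity between two aligned rows defaults to identical pairs over
columns where *both* rows are non-gap; the all-columns variant is exposed
because the literature uses both conventions and rarely says which.
Pairwise alignment uses BLOSUM62 with affine gap penalties (open 10,
extend 1) — standard protein-search defaults.

## Homology, synteny and duplication modes

Homolog pairs come from all-vs-all Smith–Waterman; each query keeps its
top-k (default 5) hits above a score threshold, with ties at the k-th
score all retained (as hit lists behave under ties) and a symmetric
closure so a pair survives if either direction kept it. The threshold is
calibrated as a high quantile (99.999% at toy scale) of scores between
residue-shuffled sequences — a composition-preserving null standing in for
an E-value cutoff, whose statistics are out of scope.

Collinear chains are found per chromosome pair by longest-chain dynamic
programming over anchors sorted by rank on one side: an anchor extends a
chain when both rank increments are in (0, 25], with the second side
strictly decreasing for inverted chains. Chains with ≥ 5 anchors are
reported; anchors join at most one block, assigned greedily by chain score
with id-order tie-breaks. The defaults (5 anchors, gap 25) are the
published MCScanX defaults. The DP is verified against exhaustive chain
enumeration on instances of ≤ 12 anchors.

Duplication-mode precedence is WGD/segmental > tandem > dispersed (the
ascending-privilege scheme of MCScanX); "tandem" means a same-chromosome
homolog with strictly fewer than 10 intervening genes (the alternative
rank-difference reading is available behind a flag). No separate
"proximal" category exists: proximal cases fold into dispersed. Tandem
arrays are connected components of the proximity relation restricted to
tandem-called genes, ordered by rank.

## Expansion and orthology series

A gene's nearest duplicate is selected lexicographically: highest percent
identity, then most shared flanking block anchors (non-family anchor pairs
of blocks containing both genes — our operationalization of "flanking
genes in segments"), then lowest Ks, then partner id. Ks is the NG86 dS
(fast, closed form); undefined Ks (saturated or zero-synonymous pairs)
sorts last and is flagged. The criteria precedence follows their order of
mention in the field's usage; it is configurable.

The nearest-edge graph is forced linear: nodes of degree > 2 keep their
two best incident edges (same criteria), iterated to a fixed point, and
any remaining cycle is broken at its worst edge. Components are then
simple paths, each one expansion series. Orthology series are connected
components of cross-species block-anchor pairs restricted to family genes;
a component spanning every species marks its members as ancestral anchors.

## Conservation index

The per-column index counts, out of the ten Livingstone–Barton/AMAS
residue property classes (as embedded in Jalview's conservation shading),
how many the column's residues agree on — all members or all non-members.
Gaps and X belong to no class, so they veto every "all-in" agreement
(ignoring gap rows is available behind a flag). The index is capped at 10;
Jalview's identity level (11) is available via `identity_bonus` but off by
default so "number of conserved properties" stays literal. Windows are 20
columns slid by 10; a truncated final window is reported but flagged, and
excluded from region means by default.

Introns are projected from CDS offsets: an intron after CDS nucleotide n
sits at residue ⌊n/3⌋+1 with phase n mod 3, then maps through the gapped
row to its alignment column. Conserved intron positions require the same
column (and, by default, the same phase) in at least `min_fraction`
(default all) of the genes.

## Selection analysis

Codon alignments are built by back-translating a protein alignment
(terminal stops stripped; internal stops are an error — such sequences are
pseudogenes and should have been filtered) and deleting every column that
contains a gap.

**NG86.** Synonymous site fractions per codon position weight the three
single-nucleotide alternatives equally, excluding changes that create stop
codons from the denominator, so S + N = 3 per codon exactly. Differences
between codons are averaged over all minimal substitution pathways that
avoid stop codons (over all pathways if none avoids them). Proportions are
Jukes–Cantor corrected, d = −(3/4)·ln(1 − 4p/3); p ≥ 3/4 is flagged
saturated, dS = 0 flagged undefined. Implementation is checked against an
independently written recursive pathway enumerator and against Biopython's
NG86.

**M0.** The one-ratio Goldman–Yang model on the 61 sense codons of the
universal code: rates allow single-nucleotide changes only, weighted by
the target codon frequency, κ for transitions and ω for nonsynonymous
changes, with the matrix scaled so t is expected substitutions per codon.
P(t) comes from a symmetric eigendecomposition (the chain is reversible).
The pairwise likelihood is maximized over (log ω, log κ, log t) with
L-BFGS-B from three fixed starting points, (0.2, 2, 0.3), (1, 1, 1),
(3, 5, 0.1) — a deterministic spread standing in for "different input
parameters" restarts. Codon frequencies default to F3x4 estimated from the
data (uniform available for oracle tests). dS and dN are derived from t by
the ω = 1 site decomposition, so ω = dN/dS holds exactly. Pairwise M0 (two
sequences, 3 free parameters) suffices for every statistic reported here;
tree-wide branch models are out of scope.

Group comparisons use per-group median ω over ok-status estimates and
two-sided Wilcoxon rank-sum tests; groups with fewer than two usable
estimates report a missing p-value.

## Trees and marker classification

Protein distances are p or Kimura-corrected (−ln(1 − p − p²/5)); saturated
pairs are flagged undefined rather than silently clamped. Neighbor joining
is implemented directly because the spec-level details matter: negative
branch lengths are clamped to zero with the deficit moved to the sibling
edge, and every tie (in the Q criterion and final joins) resolves by id
order, making trees reproducible. NJ output is verified against additive
matrices from random birth–death trees and against scikit-bio's NJ.

Bootstrap supports resample alignment columns with replacement and report
the percentage of replicates containing each original internal
bipartition (default 100 replicates at desk scale; scale up as needed).

Marker classification roots the tree at the GLR0-labelled marker when
present (GLR0 is treated as the family's original/outgroup lineage), else
at the midpoint. Each query takes the label of the smallest clade it
shares with ≥ 1 marker when those markers agree; disagreement falls back
to the nearest marker by patristic distance (ties by id), and the fallback
is flagged `method=nearest` per assignment since no published decision
rule exists for this case.

## Expression

ΔCq relative expression is E^−(Cq_gene − mean Cq_refs) per sample with
E = 2 by default (perfect doubling; per-gene efficiencies accepted),
replicates averaged after transformation. Genes undetected everywhere are
dropped and listed; genes undetected in some samples get relative 0
there. The exact Cq→expression rule is a documented assumption — ΔCq with
exponentiation is the minimal defensible choice. log2 standardization uses
the population sd (ddof = 0); constant rows become zeros and are flagged;
the default pseudocount is 1e−4 of the smallest positive value. K-means is
scikit-learn's k-means++ with n_init = 10; k is always explicit and
recorded because no single default is defensible. Tissue preference is the
argmax of per-tissue means with exact ties listing every argmax.

## Synthetic data: what it emulates, what it does not

`simulate_genome` plants a family shaped like real receptor-family
expansions — tandem arrays (gaps of 1–5 background genes, always < 10),
segmental blocks (two intervals on different chromosomes joined by
collinear anchor pairs, the middle pair being family genes), dispersed
copies and unrelated singletons — on a uniform gene grid (1 kb loci every
2 kb). Planted features keep > 25 gene slots from each other so no planted
mode is ambiguous under the chain gap rule; real genomes offer no such
guarantee, which is why mode recovery of 100% here bounds only the logic,
not real-data accuracy. Background genes carry coordinates but no
sequence; block anchor pairs that are not family genes do carry (shared,
mutated) sequences so chains are recoverable from FASTA alone. Family
sequences derive from one ancestor CDS with per-copy substitutions;
within arrays each member mutates from the previous one, so identity
decays along the planted expansion order. There are no indels, no
intergenic sequence, no pseudogenization in place.

The codon simulator draws an ancestor from the equilibrium distribution
and evolves the partner via exp(Qt) of the same GY94 matrix the fitter
uses, with ω = 0 handled exactly (nonsynonymous transitions zeroed). The
MSA generator plants perfectly conserved intervals against iid background
columns; the expression generator plants Gaussian log2-scale clusters with
independent replicate noise. All generators are pure functions of
(spec, seed); a global seed fans out to named substreams by stable
hashing, so changing one generator's use never perturbs another's stream.

## Problem sizes and validation battery

The standard validation battery (shared by the test suite and
`scripts/acceptance.py`) uses: 20 synthetic genomes of 4 × 150 genes
cycling a five-point family-composition grid; 30 random chain instances of
≤ 12 anchors against exhaustive enumeration; 500-codon pairs at
ω ∈ {0.1, 0.3, 1.0} × t ∈ {0.2, 0.8}, κ = 2, 20 replicates each, judged
by the median; 20 planted-interval alignments (8 × 100); 20 random
additive matrices of 6–10 taxa; five 4-subfamily marker alignments; ten
planted 3-cluster expression matrices at 10σ separation; and a double
pipeline run compared byte-for-byte.

## Known limitations

- NG86 under κ = 2 simulations shows the classical downward ω bias (the
  Jukes–Cantor correction ignores transition bias, inflating dS): median
  relative error reaches ~17–19% on the grid above. M0, which models κ,
  stays within ~10%. Prefer M0 where the distinction matters.
- The PSSM domain scan is ungapped; it reproduces domain presence/absence
  calls at toy scale but is not a substitute for profile-HMM sensitivity
  on real diverged domains.
- Pairwise M0 only; no branch or site models, no positive-selection site
  identification.
- Chain detection assigns each anchor to one block greedily by score;
  overlapping block resolution schemes differ between published tools.
- Bootstrap + NJ quantifies column-resampling stability of a distance
  tree, not model-based phylogenetic uncertainty.
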