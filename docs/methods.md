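# Methods

This note documents the models and procedures implemented in `embryonet`,
the parameters that matter, what the synthetic generator does and does not
emulate, and the design choices made where the design was genuinely open.

## Study design emulated by the synthetic generator

The generator (`embryonet.synthetic`) mirrors a small human preimplantation
profiling study: four ordered stages — oocyte, 4-cell, 8-cell, blastocyst —
with 4/4/3/4 replicate embryos, eight single blastomeres disaggregated from
one 8-cell embryo, and a few ICM/TE reference profiles for lineage
assignment. All randomness flows from `SyntheticConfig.seed` through
per-operation substreams, so each artifact is bit-reproducible regardless
of the order in which generators are called.

**Interactome.** A planted-partition graph: `n_planted_modules` (default 6)
dense subgraphs of 8–15 genes (within-module edge probability 0.9) laid
over an Erdős–Rényi background (`background_edge_prob`, default 0.01 at 300
genes, i.e. mean background degree ≈ 3). Consecutive modules share
`round(module_overlap_frac · size)` genes (default 0.2), forming an overlap
chain; a spanning backbone joins disconnected components. The planted gene
sets are the module-recovery ground truth.

**Stage expression.** Each gene's stage means form a step function with
steps of height `de_effect_size` (default 3, in log2 units) at its planted
change points, plus N(0, `noise_sd`²) replicate noise (default sd 1, so the
default effect is 3σ). Planted module genes step together at their module's
assigned boundary — modules are thereby enriched in stage-specific DE
genes. Background genes step at a random boundary with probability
`de_background_frac` (default 0.5): cleavage-to-blastocyst development
remodels much of the transcriptome (maternal clearance plus EGA), and an
almost-flat background would make the multiple-testing burden unrealistically
light. A `n_changepoint_classes` mode instead assigns all genes to a fixed
set of distinct step shapes (used for the 7-shape-class recovery analysis).

**Blastomeres.** Intensities come from a two-state model: unexpressed
N(4, 1) and expressed N(8, 1) in log2 units. Cells split into ICM-like and
TE-like halves. Group markers (30 per group) are drawn from the unexpressed
mean shifted up by `lineage_separation` (default δ = 4, i.e. the expressed
level) in their own group and from the unexpressed component elsewhere, so
δ = 0 collapses the groups exactly. Housekeeping genes are expressed
everywhere; remaining genes are constitutively on or off. The EIF-style
panel is fully expressed in ICM-like cells and 3-of-10 in TE-like cells
(graded loss of translation-initiation expression); the epigenetic panel is
the union of 10 markers per group. qPCR plates draw expressed reactions
around cycle 28 and unexpressed around 39.5 (past the 37-cycle rule).

**What the generator does not emulate:** probe-level array artifacts, batch
effects beyond embryo-of-origin shifts, read-count noise, dropout, or a
scale-free interactome degree distribution. Passing tests therefore show
that the *methods* behave as specified under controlled conditions; they do
not certify performance on real arrays or RNA-seq.

## Stage statistics

*Presence.* A gene is expressed at a stage when detected in at least the
nearest integer (half up) to `stage_fraction · n` of the stage's n samples;
at the default 0.75 this is 2 of 3 and 3 of 4 — the two printed readings of
the rule. Detection comes from platform flags or an intensity threshold;
the pipeline's default threshold is the midpoint of a pooled two-Gaussian
mixture fit.

*Differential expression.* One-way fixed-effects equal-variance ANOVA per
gene (vectorised sums of squares, cross-checked against
`scipy.stats.f_oneway`), BH adjustment over all tested genes, discoveries
at q ≤ 0.05. Genes with zero between- and within-group variance are flagged
degenerate with p = 1. An omnibus test over all stages is the default; a
pairwise mode (reference stage vs each other stage, per-gene minimum q) is
available because the study's phrasing admits both readings.

*Projection filter.* Genes are ranked by per-gene SD and cut at a
user-supplied threshold; the retained, gene-centered submatrix gets a
projection score — the top-k singular-energy fraction minus its mean over
≥ 20 per-gene-permutation nulls. Printed cutoffs from commercial software
(1.2, 0.21) live on an unpublished internal scale, so cutoffs here are
plain SD units and the score is reported for whatever grid is requested.
For i.i.d. noise the score fluctuates around zero with spread ≈ 0.02 at
60 × 12; it is a diagnostic, not a test statistic.

*Outliers.* Samples whose distance from the centroid in the top-2 PC plane
exceeds 3 robust z-scores (median/MAD) are dropped in one pass — an
explicit, reproducible surrogate for interactive visual outlier removal.
Removing more than half the samples aborts, signalling misconfiguration.

## Change points

Per-gene mean-shift segmentation minimising total within-segment SSE +
penalty · (#breakpoints), solved *exactly* by dynamic programming — series
here are at most a few dozen points, so exhaustive optimality is cheap and
is verified against full enumeration in the tests. The default penalty is
BIC-like, 2σ̂²·log n with σ̂ from the MAD of first differences (robust to
the steps themselves). The default segmentation path runs on the
replicate-ordered series with breakpoints restricted to stage boundaries
(transitions happen between stages, not between replicates); this also
stabilises the penalty estimate — under default noise it recovers ~90% of
planted breakpoints exactly, versus ~63% when segmenting 4-point stage-mean
series. Ties are broken toward fewer, earlier breakpoints.

Segment-averaged profiles are clustered by average-linkage hierarchical
clustering. The correlation metric is computed on row-standardised profiles
(‖z_i − z_j‖² = 2(1 − r)), with constant profiles standardised to zero so
they cluster together and the linkage is defined for every gene. k defaults
to 7 to mirror the number of developmental transitions the pipeline is
organised around, but is a free parameter. Groups get maternal/EGA labels
by majority vote of a per-gene rule over presence calls: expressed in the
oocyte and not later → maternal-only; oocyte and later → maternal+embryonic;
absent from the oocyte and first expressed at later stage j → EGA-early/mid/
late by tercile of j.

## Network inference

Seed genes (stage DE sets, or a cell's barcode-present genes) are joined
into one model by a greedy Steiner-style approximation: start from the
largest seed-induced connected component, repeatedly merge the nearest
remaining seed component along a shortest interactome path, adding path
interiors as connectors, then induce all interactome edges on the included
nodes. `max_connector_path` bounds the number of *edges* in a merging path
(default 2, i.e. at most one intermediate connector per merge). Ties among
equally short paths prefer fewer new nodes, then higher total degree, then
lexicographic order. Seeds unreachable within the bound are retained as
isolated, reported nodes. The greedy connector count can exceed the true
Steiner minimum; on 200 random ≤ 12-node instances it equals the exhaustive
optimum ≥ 95% of the time and never beats it (impossible by construction,
asserted anyway).

## Overlapping modules

The landscape: for every node v a restart-walk vector π_v solves
π = α e_v + (1 − α) Pᵀ π (α = 0.15, power iteration to 1e-10); the height
h(u) = Σ_v π_v(u). Heights are strictly positive on connected graphs, equal
on vertex-transitive graphs, and match a dense linear solve (oracle test).

Module extraction departs from a pure "local maxima + fixed membership
threshold" reading, which we measured to merge overlapping planted cliques
(overlap junctions acquire the highest degree, become the only local
maxima, and their influence basins swallow whole overlap chains — 0/30
planted modules recovered across seeds; basin decomposition, higher
restart, and self-influence seeding variants failed similarly). Instead,
every node seeds a candidate local community in the Andersen–Chung–Lang
style: the support of its walk vector (nodes holding ≥ 5% of the vector
maximum) is swept in decreasing influence-per-degree order and cut at the
minimum-conductance proper prefix; if no prefix has conductance ≤ 0.5 (a
clique-like graph has no community-scale cut) the whole support is the
module. Identical candidates are deduplicated keeping the highest-landscape
seed. Membership weights are the seed's influence normalised to (0, 1];
nodes covered by no candidate are attached to their argmax-membership
module, so modules cover the network. Modules are ranked by the
membership-weighted closeness of their members — proximity to the network
centre — and the most central member (metanode) labels the module. With
this extractor the planted-module recovery acceptance (Jaccard ≥ 0.5 for
≥ 80% of planted modules at 20% overlap) passes at 48/48 across seeds, and
the two-cliques-one-bridge, complete-graph and star fixtures behave as
specified.

Known limitation: recovery is monotone in background edge probability only
while background noise is the limiting factor (empirically down to ~0.02 at
150 genes); at extreme sparsity the minimum-conductance criterion prefers
whole overlap chains (their cut tends to zero) and recovery dips.

## Module comparison

Tracking links module m (stage i) to module n (stage i+1) when they share
more than 2 members (≥ 3); modules with no link either way are flagged.
Similarity between two cells' module sets marks pairs sharing ≥ 5 genes,
with an upper-tail hypergeometric p per pair (population = the configured
gene universe, defaulting to the measured/collapsed gene set — published
overlap p-values are not reproducible without knowing the universe, so the
universe is explicit here). BH q-values are reported within each entity
pair alongside raw p. The causal z-score for a regulator with n scored
signed targets is (n_consistent − n_inconsistent)/√n, flagged strictly at
|z| > 2; the regulon database is user-supplied (TSV regulator/target/sign),
as the commercial knowledge base behind such scores is proprietary.

## Barcodes, panels, qPCR

Absolute presence calls use a two-component Gaussian mixture in log-
intensity space (frozen-reference barcoding needs platform reference
distributions, an external resource; the mixture caller implements the same
contract — binary calls from absolute intensity). EM is initialised from
the quartiles, which makes the fit — and therefore the calls — equivariant
under adding a constant to all intensities. A per-gene fit is only trusted
when clearly bimodal (components ≥ 2 pooled SDs apart, each supported by
≥ 2 points, separation not far below the pooled global separation);
otherwise the gene falls back to the pooled-mixture midpoint threshold, and
the decision provenance is recorded per gene. Values at the posterior
boundary (0.5) are called present. Measured accuracy at 4σ component
separation is ≥ 95%.

The variable-gene filter keeps genes present in 2–5 of the 8 blastomeres.
Panel profiles count present panel genes per cell (or per stage via the
presence rule). Cells are grouped by panel barcodes with 1 − Jaccard
distance and average linkage, cut at k = 2, lexicographic processing order
for deterministic ties. qPCR: ΔCt = 40 − mean replicate Ct, expressed at
mean Ct ≤ 37 (a majority-of-replicates alternative is a flag), cells kept
with ≥ 4 expressed targets (the strict reading of "greater than 3"), and
gene–gene association by Pearson chi-square without continuity correction
(warning logged when an expected cell < 5; zero-margin tables return
χ² = 0, p = 1).

## Embedding and lineage assignment

PCA is an SVD of the gene-centered sample matrix with a fixed sign
convention (largest-|loading| positive). Isomap builds a symmetric kNN
graph (default k = 5) on Euclidean distances, takes all-pairs shortest-path
geodesics, and applies classical MDS (negative eigenvalues dropped;
residual variance = 1 − retained positive-eigenvalue fraction). A
disconnected kNN graph is bridged through the closest inter-component pair,
logged. With k = n − 1 the geodesics are Euclidean and Isomap reproduces
classical MDS to 1e-8 (tested, plus a cross-check against scikit-learn's
Isomap). Lineage assignment is nearest reference-class centroid in
embedding coordinates with per-query distances and margin; exact ties are
"unassigned" rather than guessed.

## Pipeline and consensus

`run_pipeline` executes the stages in dependency order from a JSON config
(simulate block or input paths), writes every artifact with a manifest of
parameters, seed and SHA-256 checksums, and is bit-deterministic under a
fixed seed. The consensus report formalises a narrative synthesis: per
blastomere, four evidence lines vote — module-similarity lean (more similar
modules with ICM-reference networks or TE-reference networks), embedding
assignment, EIF panel count (above the median count leans ICM, matching the
biology in which ICM-primed cells retain the full translation-initiation
complement), and epigenetic panel group (the two unlabeled clusters are
oriented by the majority embedding call within each, so this line can only
reinforce or abstain, never outvote an unanimous embedding). Majority wins;
ties are "unresolved". With the default generator (δ = 4) the consensus
recovers both planted groups 8/8; with δ = 0 embedding margins collapse
toward zero and no confident structure is reported.

## Problem sizes

Default analyses run at 300 genes, 15 stage samples, 8 blastomeres + 6
references, interactomes of ~800 edges; calibration uses 50 null replicates
of 2000 genes; oracle checks use instances small enough for exhaustive
enumeration (series ≤ 10, populations ≤ 12, graphs ≤ 12 nodes). These sizes
keep every analysis exact or well-replicated while the full suite runs in
about a minute.
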