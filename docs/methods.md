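# Methods

This note documents the models behind each stage, the defaults and why
they were chosen, what the synthetic generator does and does not
emulate, and the numerical choices that affect results.

## Synthetic count model

Counts for gene *g* in sample *s* are negative binomial with mean
`L_s · exp(b_g + λ_g z_{m(g),s} + Δ_{g,s})` and dispersion φ
(variance = μ + φμ²):

- `b_g ~ Normal(baseline_logmean_mean, baseline_logmean_sd)` sets the
  gene's baseline on the natural-log scale. Defaults 5.0 ± 1.0 put the
  median expected count near 150 with a realistic spread (≈20–1100),
  comfortably above the regime where counting noise swamps biology.
- `z_{m,s} ~ Normal(0, 1)` is one latent factor per (module, sample),
  shared by all genes of the module and independent across modules.
  The loading λ_g is `module_loading` for module genes (default 0.8),
  `hub_loading` for planted hubs (default 0.95), and 0 for background
  genes. Because all module genes load on the same factor, their
  log-means — and hence ranks — co-vary: the population Spearman
  correlation of a within-module pair is approximately
  λ²/(λ² + CV²) with CV² = φ + 1/μ, so λ maps monotonically to
  correlation strength. Hubs, loading more strongly, correlate more
  tightly with every module member and emerge as high-degree,
  high-authority nodes after network inference; hub recovery therefore
  exercises the entire inference chain rather than a wiring shortcut.
- `Δ_{g,s} = ±de_logfc·ln2` for planted DE genes in the treated
  arm(s) of their assigned contrast, at every timepoint. Each DE gene
  is assigned to treatment A, treatment B, or both (uniformly), with a
  random sign; `|de_genes| = round(de_fraction · n_genes)`. DE genes
  are drawn module-first: the downstream networks are built on the
  DE-filtered gene union, so planting DE on module genes keeps the
  planted modules eligible for network construction, mirroring a study
  design in which the co-expressed genes are the responsive ones.
- `L_s ~ Uniform(libsize_range)` (default 0.7–1.3) is a relative
  library depth; no per-library depths are published for the original
  design, so uniform factors are used rather than an empirical
  distribution.
- Dispersion default φ = 0.04, i.e. a biological coefficient of
  variation of 0.2 — the standard figure for isogenic model organisms
  under controlled conditions. Calibration and parameter-recovery
  simulations in the test suite use φ = 0.1 where a moderately noisier
  setting is the stated condition.

The default design is the full factorial 3 conditions × 3 timepoints
(48, 72, 96 h) × 3 replicates = 27 libraries. Everything is drawn from
one `numpy` Generator seeded by `seed`; identical seeds give
bit-identical counts and truth.

### What the generator does not emulate

- **Condition-coherent module activity.** The latent factor varies
  per sample, also across replicates within a condition. Real response
  modules are driven by the treatment, so their activity is largely
  shared by replicates. The consequence is a real trade-off inside the
  simulator: the factor variance that creates co-expression also
  inflates a module gene's apparent dispersion (effective
  φ ≈ e^{λ²}(1+φ) − 1), so strongly co-expressed planted genes are
  hard to call DE at 3 replicates, whereas in real data both signals
  coexist. End-to-end runs at the default thresholds therefore produce
  sparse stimulated networks and say so in their warnings; structure
  recovery (communities, hubs, robustness) is validated on runs where
  networks are built directly over module genes.
- **Batch effects, library-preparation biases, and read-level noise**
  (no FASTQ simulation).
- **Majority-scale perturbations.** TMM assumes most genes are
  unchanged between libraries; if planted modules cover most of the
  simulated genome, the shared factor is absorbed into the
  normalization factors and the planted correlation is (correctly)
  removed. Simulated experiments should keep modules a minority of
  genes, as in any real transcriptome.

Passing tests on this generator demonstrate that the statistics and
algorithms behave as specified under known ground truth; they do not
certify performance on real data with structured confounders.

## Differential expression

TMM follows the standard recipe: reference = library whose
depth-normalized 75th percentile is closest to the mean of that
statistic; per library, the factor is 2^(weighted trimmed mean of
M-values) over genes positive in both libraries, trimming 30% of the
tails by M and 5% by A, weighting by inverse delta-method variances;
factors are rescaled to geometric mean 1. The implementation agrees
with edgeR's `calcNormFactors` to ~1e-15 on random NB matrices (tested
via Rscript). A depth-only change between libraries yields factors of
exactly 1 — the defining scale-invariance of the method.

Dispersions are method-of-moments within each (condition, timepoint)
group on depth-rescaled counts, pooled across groups with df weights,
then shrunk toward the common (median) dispersion with prior weight
w = 10: φ_g = (w·φ_common + n·φ̂_g)/(w + n), floored at 1e-6. This is
deliberately simpler than edgeR's empirical-Bayes machinery; the shared
prior weight stabilizes small-replicate estimates at the cost of some
shrinkage bias for outlier genes.

The per-gene test is a genuine NB likelihood-ratio test: full model
log μ = β₀ + β₁·treated + log(effective library size), reduced model
drops β₁; both are fitted by IRLS (vectorized across genes; convergence
at max|Δβ| < 1e-8, 60 iterations, non-converged genes get p = 1 and a
counted warning), and 2(ℓ_full − ℓ_reduced) is referred to χ²(1). The
original analysis used edgeR's quasi-likelihood F-test; the LRT was
chosen as a self-contained, exactly specified alternative and is
validated by calibration instead of by replicating gene lists: on a
2000-gene null (φ = 0.1, 5 vs 5) the empirical type-I error at
α = 0.05 falls in [0.025, 0.08], and with known dispersion the null
p-values are uniform. With estimated dispersions the test is mildly
anticonservative (α ≈ 0.06–0.07) — the price of moment estimation at
small n.

Per-timepoint contrasts are aggregated to a per-treatment DE set by
union over timepoints; the original report does not state its
aggregation rule, and the union is the permissive reading. Thresholds
are strict inequalities (FDR < 0.001, |logFC| > 1.5). Cross-treatment
comparison of shared genes uses a paired t-test (genes are matched)
with a Wilcoxon signed-rank companion; the unpaired variants are Welch
and the exact rank-sum.

## Co-expression networks

Spearman ρ_s is the Pearson correlation of mid-ranks (average ranks on
ties); constant genes are dropped with a logged warning since their
rank correlation is undefined. Significance uses the t-approximation
(exact permutation enumeration is available for n ≤ 8); BH runs over
the off-diagonal upper triangle — each unordered pair tested once. An
edge requires q < 0.001 **and** |ρ_s| ≥ 0.8; absolute-value
thresholding is the default (negative correlations count), with signed
mode as an option. Isolated nodes are retained. At n = 9 samples per
arm these joint thresholds admit only correlations ≳0.92 in practice —
an intrinsic property of the t-approximation plus BH at this sample
size, worth keeping in mind when interpreting sparse stimulus networks.

Which samples feed a correlation matrix is a user decision; the
pipeline pools a condition's samples across timepoints (9 per arm in
the default design) and builds each stimulated network on the union of
that condition's DE genes, reusing the same genes for the matched
control network.

## Walktrap communities

The transition matrix is P = D⁻¹A on nodes of positive degree
(unweighted by default; a weighted variant uses |ρ_s| as edge weight —
on a thresholded graph where all |ρ_s| ≥ 0.8 the weights are
near-uniform, which is why unweighted is the default). Each community
carries the size-weighted average of its members' t-step distributions
(t = 4, the conventional default); only adjacent communities may
merge, the pair minimizing
Δσ = (1/n)·(|C₁||C₂|/(|C₁|+|C₂|))·r²(C₁,C₂) with
r²(C₁,C₂) = Σ_k (P_C₁k − P_C₂k)²/d(k). Merge costs are non-negative by
construction (Ward property). Modularity
Q = Σ_c (e_c/m − (d_c/2m)²) is tracked incrementally along the merge
sequence, and the reported partition is the cut with maximal Q, ties
resolved toward fewer communities. Degree-zero nodes are excluded from
the walk and returned as singleton communities. On an edgeless graph
the partition is all singletons with Q reported as 0 (the modularity
function itself refuses m = 0).

The implementation matches igraph's `cluster_walktrap` partitions on
separable graphs and recovers a 2 × 50 planted partition
(p_in = 0.5, p_out = 0.02) with ARI 1.0. Cost is O(m·n) per run at the
package's scale (networks up to a few thousand nodes).

## Hub analysis

Centralities: raw degree (normalization cancels in within-network
ranking); closeness (|C_v|−1)/Σ_u d(v,u) within v's component (0 for
isolated nodes); authority = principal adjacency eigenvector. On an
undirected graph HITS authority coincides with eigenvector centrality,
computed here by power iteration with a 0.5·I shift (guards bipartite
oscillation), L2-renormalized per step, stopping at ‖Δ‖∞ < 1e-10 or
1000 iterations (error on non-convergence). It is computed **per
connected component**, each component scaled to max 1: thresholded
networks are routinely multi-component with near-equal blocks, where a
single global eigenvector is degenerate and power iteration provably
stalls; the per-component vector is also the quantity that makes
per-community ranking meaningful. For connected graphs this equals the
global principal eigenvector.

Hub score = degree × closeness × authority ("centrality" in the
source's product is read as degree, per its own metric list); ranks are
descending with deterministic ties broken by gene id. Selection takes
the top k = 50 per community of ≥ 100 nodes (all members if smaller).
The end-to-end pipeline, when no community reaches 100 nodes, falls
back to communities of at least k nodes (else the single largest) with
a warning — selecting the top-50 of a 10-node community would
degenerate to selecting everything.

Removal analysis recomputes the cohesion summary (nodes, edges,
density, components, diameter of the largest component, mean geodesic)
on the induced subgraph. The mean geodesic averages over reachable
pairs only, with the unreachable-pair fraction reported separately —
this keeps the mean finite but means fragmentation can show up in
either number, so both directions (longer paths, or a shattered graph
with shorter surviving paths) are visible per run. The random-removal
baseline draws size-matched node sets from the non-removed nodes, with
its own seed, so hub-vs-random comparisons are paired by count.

## Differential network comparison

Two networks on an identical gene list, each inferred from its own
samples with identical thresholds. Reported: per-network node/edge
counts and density, edge-set Jaccard, degree histograms on shared bin
edges computed from the pooled degree range (default 10 bins), the
empirical CDF of retained |ρ_s| on a fixed grid (rho_min to 1.00, step
0.01), per-network minimum retained |ρ_s|, and a two-sample KS
statistic as a scalar summary of the weight distributions. The control
filter defaults to the FDR threshold; a p-value-based filter is
available where that reading is preferred.

## Enrichment

For a study set of n genes in a universe of N with K term members,
p = P[X ≥ k], X ~ Hypergeometric(N, K, n), fold enrichment
(k/n)/(K/N), BH across tested terms; terms with no universe members
are skipped and logged. One-sided overrepresentation is the default
(two-sided Fisher available). The universe defaults to all genes of
the count matrix — the expressed set — rather than a genome-wide list.

## Pipeline and reproducibility

Configuration is a single dataclass/YAML with the canonical thresholds
as defaults (DE FDR 0.001, |logFC| 1.5, network FDR 0.001, ρ_s 0.8,
min community 100, hub k 50, walk length 4). Gene and sample order is
canonicalized lexicographically on load; every file is written
atomically (temp + rename); all randomness derives from the config
seed, so a rerun with the same config is bit-identical. A stage failure
aborts with the stage name, preserving earlier artifacts.

## Problem sizes

Simulation-based checks run at desk scale: 2000-gene null calibrations,
networks of 120–690 genes over 27–45 samples, planted-partition graphs
of 100 nodes, preferential-attachment graphs of 300 nodes, and
exhaustive oracles on graphs of ≤ 50 nodes and p-vectors of length
≤ 6. The published networks' only role is the density arithmetic on
their printed node/edge counts; their gene lists, community counts, and
diameters derive from a specific experimental dataset and annotation
release and are not reproduced here.

## Known limitations

- The NB-LRT with moment/shrinkage dispersions is mildly liberal at
  3–5 replicates; edgeR's quasi-likelihood machinery is the safer
  choice when exact error control matters.
- The latent-factor generator cannot make a gene set simultaneously
  strongly co-expressed within arms and powerfully DE at few
  replicates (see above); interpret end-to-end synthetic runs
  accordingly.
- Soft-thresholding (WGCNA-style), partial correlations, per-pair
  differential co-expression statistics, overlapping communities, and
  GO-graph-aware enrichment are out of scope.
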