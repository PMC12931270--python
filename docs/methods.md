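# Methods

This note documents the models, conventions and design choices behind
`bpdnet`: a pipeline linking neonatal lower-airway microbiome co-occurrence
network architecture to ordinal bronchopulmonary dysplasia (BPD) severity
(none, I, II, III).

## Synthetic cohort generator

The deposited sequencing data behind a study of this kind is not needed to
test the analysis machinery; what is needed is data with the same *structure*.
`synth.generate_cohort` draws, for each sample, latent log-basis abundances
`x ~ N(mu, Sigma_g)` where `Sigma_g` is a correlation matrix containing
group-specific planted blocks (pairwise basis correlation `rho` inside a
block, identity elsewhere), exponentiates, closes to fractions, and draws
counts `Multinomial(depth, fractions)`. This is exactly the generative model
compositionally robust correlation methods assume, which makes the planted
blocks a usable ground truth for network recovery. A Dirichlet-multinomial
overdispersion flag (`dm_overdispersion`) is available but off by default.

Defaults emulate the study conditions: 98 samples in groups of 31/31/20/16,
per-sample depths uniform on [22,026, 72,630], 300 core ASVs plus 10
organelle-contaminant ASVs (Chloroplast / Mitochondria lineages) and 20
exact-singleton ASVs, and heavy-tailed per-taxon log-means (sd 2.0) so a
handful of genera dominate, as in real airway communities. Planted modules
default to one block per group — sizes 20/25/30/5 at rho 0.7/0.7/0.75/0.6 —
so that co-occurrence structure is substantial in the milder groups and
collapsed in grade III; the true effect size of that collapse is not known
from published summaries, so it is an explicit free parameter rather than an
asserted value. Clinical covariates are drawn with means linear in grade
rank (gestational age −0.9 weeks/grade from 30.6; birth weight −130 g/grade
from 1,500 g), matching the direction of the reported clinical gradients.

What the generator does **not** emulate: read-level errors, chimeras,
taxonomic mis-assignment, batch effects, or longitudinal structure. Passing
tests therefore demonstrate the statistical machinery is correct under its
own assumptions, not that those assumptions hold for any particular dataset.

Two construction details keep the contracts exact: row sums equal the drawn
depths (singleton reads are carved out of their host sample's multinomial
budget), and a post-pass folds any *accidental* basis-taxon singleton into
that sample's most abundant taxon so "taxa with grand total 1" is exactly
the designed singleton set.

## Preprocessing

Filter order: singleton removal (grand total = 1), organelle removal
(case-insensitive substring "mitochondria"/"chloroplast" at any rank),
rarefaction (for diversity only), then the joint network filter — taxon
total / grand total strictly greater than 0.01% AND prevalence at least
`ceil(0.05 n)` samples (5 of 98). The abundance clause reads "sum of
relative abundance" as taxon total over grand total (scale-free, consistent
with the 0.01% magnitude); a per-sample-mean variant is available by flag.
Rarefaction subsamples without replacement (multivariate hypergeometric) and
drops samples below the target depth with a warning.

## Diversity

Alpha indices follow the common conventions: bias-corrected Chao1
`S_obs + F1(F1-1)/(2(F2+1))` (classical form by flag), Shannon in nats,
Simpson reported as the complement `1 - sum p_i^2` with the raw dominance
alongside, Good's coverage `1 - F1/N`. ANOSIM, PERMANOVA and PERMDISP run on
Bray-Curtis matrices via scikit-bio with explicit seeds; all permutation
p-values use the add-one estimator `(1 + #{>= obs}) / (n_perm + 1)` so p = 0
never occurs. PERMANOVA R² is computed in-module from the Gower-centred
sums of squares. PERMDISP uses distances to group centroids in
principal-coordinate space. Pairwise ANOSIM p-values are Bonferroni-adjusted
by multiplication with the number of pairs, capped at 1. Because the common
effect-size convention for Kruskal-Wallis on alpha indices is ambiguous,
both epsilon-squared and eta-squared are emitted and neither is asserted
against any published value.

## SparCC

The correlation estimator is implemented from scratch. From strictly
positive fractions, the log-ratio variance matrix is computed through the
log-abundance covariance, `T_ij = C_ii + C_jj - 2 C_ij`, which is invariant
to per-sample scaling of the basis. Under sparsity, basis variances solve
`M w = rowsums(T)` with `M = (D-2) I + 11'`; correlations follow as
`rho_ij = (w_i + w_j - T_ij) / (2 sqrt(w_i w_j))`, clipped to [−1, 1]. The
strongest off-diagonal pair with `|rho|` above 0.1 is then excluded from the
row sums (decrementing the touched diagonal entries of M), the system
re-solved, and so on for at most 10 rounds — the original defaults. If
over-exclusion ever makes M singular (possible at small D), the previous
round's estimate is kept. Non-positive basis-variance estimates are clamped
to 1e−6 with a logged warning. Fraction uncertainty is integrated out by
drawing per-sample fractions from Dirichlet(counts + 1) over 20 outer
iterations (prior +1 is the original convention; +0.5 by flag) and taking
the elementwise median.

Edge significance defaults to a **permutation** null: each resample shuffles
every taxon's counts across samples independently and recomputes the
correlation, with the add-one p. The resampled correlations use fewer outer
iterations (5) than the point estimate; the null needs only the location of
the resampled distribution. A **bootstrap** mode (resample samples with
replacement; p = add-one fraction of replicates whose correlation crosses
zero) is provided for users who prefer a sign-stability reading of "edge
stability"; the add-one form is used in both modes so p ∈ (0, 1] always
holds. A Benjamini-Hochberg adjustment over the distinct pairs is available
but off by default; note that at 100 resamples the p-value resolution floor
(1/101) makes FDR control over tens of thousands of pairs uninformative, so
turning it on is only meaningful with many more resamples.

Spearman correlation on relative abundances (mid-rank ties, Pearson on
ranks) shares the same permutation-significance machinery and serves as the
method-comparison baseline; constant taxa are reported as r = 0 and flagged.

## Networks

An edge requires `|r|` strictly above the threshold (default 0.3;
sensitivity grid 0.2/0.3/0.4) AND p below alpha (default 0.05). Isolated
nodes are dropped, so node counts are connected ASVs. Before inference every
group is down-sampled to the smallest group's size, because spurious-edge
counts depend strongly on n and unequal group sizes would masquerade as
biology.

Topology metrics: path metrics average over connected pairs only, in hop
counts by default or with dissimilarity weights `1 - |r|`
(`dissimilarity_weighted` mode) — the latter is supplied because published
sub-1 "average path length" and "diameter" values are impossible for hop
counts. The clustering coefficient is global transitivity (mean local
clustering also emitted). Modularity is the value of a seeded Louvain
partition. Centralizations use Freeman's form, `sum(c_max - c_i)` normalised
by the same sum evaluated on the star graph of equal order; this is exactly
zero for vertex-transitive graphs and 1 for the star, and is computed with a
documented convention (networkx's component-scaled closeness) on
disconnected graphs. Eigenvector centrality is computed by dense symmetric
eigendecomposition rather than an iterative solver, so results are
deterministic. Degree assortativity is the Pearson correlation of degrees
over edge endpoints.

Keystone score: `w_deg z(degree) + w_close z(closeness) + w_trans z(local
transitivity) - w_betw z(betweenness)` with within-network z-scores (sample
sd; constant metrics contribute 0). The published "differential weights" are
not recoverable, so the default is equal weights (0.25 each) and reports
must state the weights used. Exactly `ceil(0.10 N)` nodes are flagged, ties
broken by higher degree then lexicographic id.

## Network comparison

`permute_compare` tests a topology-metric difference by pooling the two
groups' samples, re-splitting at the original sizes, and re-running the
inference per permutation. To keep hundreds of permutations tractable, the
null runs at reduced fidelity (fewer outer iterations; threshold-only edges
without the resampling significance step, since the permutation relabelling
itself supplies the null); a full-fidelity mode is one parameter away. The
library default is 1,000 permutations; the orchestrated pipeline defaults to
100 with count-based metrics (edges, density, average degree) so a complete
default run finishes in minutes — both counts are recorded in every output.

The overall dissimilarity is a Schieber-style D-measure with weights
0.45/0.45/0.10: Jensen-Shannon divergence between the averaged node-distance
distributions (unreachable pairs occupy a dedicated bin), the difference in
network node dispersion (mean KL of node distributions to their average,
normalised by log(diameter + 1)), and the alpha-centrality profile
divergence of the graphs and their complements (alpha = 1/n, profiles sorted
and zero-padded). It is zero on identical graphs and symmetric; the
triangle inequality is not claimed. A plain Euclidean distance on scaled
topology vectors is available as the simple alternative.

Top-central node sets (per-network 0.75 quantile, configurable) are compared
by Jaccard with hypergeometric tail probabilities over the union of the two
node sets. Method agreement (SparCC vs Spearman) reports edge counts and
edge-set Jaccard at identical thresholds.

## Ordinal outcome model

Proportional odds with `logit P(Y <= k) = theta_k - x beta`: OR = exp(beta)
> 1 means higher odds of a **more severe** grade per standardized predictor
unit. The likelihood is maximised by damped Newton iterations (analytic
gradient and observed information; step halving preserves likelihood ascent
and cutpoint ordering; convergence at gradient max-norm < 1e−8 or 100
iterations). Wald standard errors come from the observed information. Two
guards make pathologies visible instead of fatal: the information matrix is
declared singular when its reciprocal condition number falls below 1e−10,
and a separation guard withdraws the convergence flag when coefficients or
standard errors diverge (|beta| > 50 or se > 1e3 on standardized inputs) —
a flat likelihood with a tiny gradient is not a maximum.

Forward stepwise adds covariates in the stated order of clinical importance;
a covariate that produces singular information or non-convergence is
recorded as dropped with its reason and skipped. There is no p-value entry
gate by default (the gate is stability); a significance-gated variant is a
flag. Abundance predictors are log-transformed with a pseudocount of half
the smallest positive value, then z-scored (sample sd).

How a group-level network metric becomes a per-sample regressor is not
derivable from published summaries, so two explicit modes exist, neither
asserted as canonical: `group_assigned` (each sample inherits the metric of
one fixed equal-sized network of its group) and `leave_one_out` (the
default: each sample gets the metric of an equal-sized network drawn from
its group excluding that sample, at reduced fidelity). Both always build
networks on subsets of the smallest group's size for the same reason the
groups are down-sampled: otherwise the n-dependence of spurious edges leaks
group size into the predictor.

## Orchestration and reproducibility

`run_pipeline` derives one sub-seed per stage from the config seed by
hashing `"{seed}:{stage}"`, so stages are independently reproducible and a
rerun with an identical config is bit-identical (the manifest records the
config — minus the output path, which is not a scientific parameter — a
parameter hash, per-stage shapes and attrition counts, and all sub-seeds).

## Problem sizes used for validation

The validation experiments run at sizes chosen to make each property
measurable with clean margins: planted-pair recovery at D = 30 taxa, n = 200
samples, 20 seeds; null quietness at D = 50, n = 200; spurious-correlation
suppression on 25-taxon dominant-taxon (80%) nulls over 10 seeds; type-I
calibration with 200-resample tests replicated 100 times at D = 10 (one
fixed pair per replicate, so the rejection count is binomial);
proportional-odds coverage at n = 500 over 100 seeds; and the determinism
check on the full default 98-sample, 300-taxon cohort. The default
synthetic scale (300 taxa rather than several thousand) keeps a complete
desk run in minutes; every size is configurable.

## Known limitations

* SparCC's sparsity assumption fails on densely correlated communities; the
  exclusion heuristic mitigates but does not remove the bias.
* At n = 16 samples per group, |r| > 0.3 with per-pair alpha = 0.05 retains
  roughly 5% of null pairs; on the synthetic cohort this noise floor
  dominates edge counts, so group contrasts should be read from the
  *relative* topology profiles and permutation tests, not absolute counts.
* The permutation null for edge significance assumes exchangeable samples
  within a table; it is not valid under strong per-sample covariate
  structure.
* The D-measure's third term uses a specific alpha-centrality convention
  (alpha = 1/n, sorted profiles); other implementations may differ in that
  term while agreeing on the first two.
* Group-level network predictors remain partially confounded with group
  membership in any mode; ordinal-model findings on them are exploratory,
  which is also how the underlying study frames its network comparisons.
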