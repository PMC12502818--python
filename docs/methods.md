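# Methods

`dysbiome` implements the statistical workflow of a family-based gut
microbiome study of inflammatory bowel disease (IBD): amplicon sequence
variant (ASV) count tables with per-sample clinical covariates and pedigree
links are turned into dysbiosis scores, differential-abundance calls,
diversity and dispersion contrasts, community types, co-abundance networks,
and heritability estimates. This note records the models, the defaults, and
the design choices that were genuinely open.

## Data model and normalisation

All stages consume a samples x taxa integer `CountTable`. Three
normalisations are used, matching what each downstream model assumes:

* **Median-of-ratios size factors** for count-scale models. The reference is
  the per-taxon geometric mean over samples; taxa with any zero drop out of
  the reference, and factors are rescaled to geometric mean 1. Sparse ASV
  tables often have no all-zero-free taxon, so `robust_size_factors` falls
  back to a pseudo-count (+1) reference; the strict function raises instead,
  so the fallback is always an explicit or logged choice.
* **Relative abundance** for Bray-Curtis / Jaccard dissimilarities.
* **CLR** (centered log-ratio, natural log, default pseudocount 0.5) for
  correlation, network, and heritability phenotypes. The pseudocount is
  configurable; CLR with pseudocount 0 is exactly scale-invariant.

The prevalence filter retains taxa whose size-factor-normalised count
reaches 5 in at least `ceil(0.01 * n)` samples (both thresholds
configurable, boundary inclusive). One shared size-factor vector is used for
filtering and testing.

## Dysbiosis (MD) index

Disease-up taxa are those significantly more abundant (BH-FDR <= 0.05,
configurable) in CD or UC versus controls; health-up taxa the mirror image.
Taxa significant in opposite directions across the two contrasts are dropped
to keep the sets disjoint. The per-sample score is

    MD = log1p(sum normalised abundance over disease-up taxa)
       / log1p(sum over health-up taxa)

with natural logs; a zero health-up sum gives a missing value that is counted
and reported. The abundance basis is size-factor-normalised counts by
default (`basis="relative"` switches to proportions); the basis is recorded
on the result. The score is non-negative, equals 1 at equal sums, and is
strictly monotone in each set member's abundance.

The dysbiosis-diversity relation is summarised by the minimum-AIC fit among
a linear model, a one-breakpoint continuous segmented model (breakpoint
profiled on a 200-point grid between the 5th and 95th MD percentile; profile
chi-square 95% CI), and a quadratic model. AIC counts the breakpoint as one
extra parameter (linear 3, quadratic 4, segmented 5, sigma included). A
caveat discovered by simulation: because the breakpoint is profiled over a
grid, the segmented model occasionally gains more fit on pure-linear data
than its 2-parameter penalty, so linear truth is selected in roughly 4 of 5
replicates, not almost always. Breakpoint *recovery* on genuinely piecewise
data is accurate to about +-0.02 at n = 500.

## Differential abundance

Each taxon is fitted by a log-link NB2 GLM with `log(size factor)` offsets
and covariates sex, scaled BMI, scaled age (plus time point when several are
present), and a two-level group factor. The NB dispersion is estimated per
taxon by maximising the Cox-Reid adjusted profile likelihood, then
(optionally, on by default) shrunk on the log scale toward a fitted trend
`alpha(mu) = a/mu + b`; the shrinkage weight is derived from the fraction of
log-dispersion spread attributable to estimation noise and clipped to
[0.2, 0.9]. This is a deliberately simplified stand-in for full empirical-
Bayes machinery: the contract is behavioural (type-I error within [0.03,
0.07] on Poisson nulls; planted log2 fold changes of 2 recovered within
+-0.5 at ~300 samples), not coefficient-identical output of any particular
tool. Wald z-tests on the group coefficient are BH-corrected within each
contrast. Contrasts are CD/UC/IBD (CD+UC pooled) versus Control plus CD vs
UC; the small uIBD group is excluded from contrasts. Non-converged taxa are
flagged and excluded from the FDR family.

One property of the generative model worth knowing: when IBD samples carry
inflated compositional noise (see below), the *arithmetic* group means of
non-dominant taxa genuinely differ even at zero planted log fold change,
because `E[exp(eps)]` grows with the noise variance while compositions
renormalise through the abundant taxa. Mean-scale NB estimates faithfully
report this. Effect-recovery experiments therefore switch the inflation off
(`dispersion_inflation_ibd = 1`), isolating the location effect.

## Ecology statistics

* **Alpha diversity**: bias-corrected Chao1 `S + f1(f1-1)/(2(f2+1))` and the
  Shannon numbers equivalent `exp(H)` (natural log).
* **Dissimilarity**: Bray-Curtis on abundances, Jaccard on presence/absence;
  all-zero sample pairs are NaN-flagged.
* **Ordination**: PCoA by Gower double-centering and eigendecomposition
  (negative eigenvalues reported; axes from positive eigenvalues, a Lingoes
  additive correction available by flag); NMDS by stress majorisation with
  isotonic regression (scikit-learn), 20 restarts, max 300 iterations,
  stress-1 reported, warning above 0.2.
* **PERMANOVA**: the McArdle-Anderson partition of the Gower-centred
  squared-distance matrix with sequential (Type-I) sums of squares in the
  given term order; pseudo-F per term against the residual; p-values by
  permutation with `p = (#{F* >= F} + 1)/(n_perm + 1)`. Conditioning terms
  are projected out of both the distance space and the design before the
  partition, and permutations act on the conditioned residual matrix
  (Freedman-Lane style). On univariate Euclidean data the pseudo-F equals
  the classical one-way ANOVA F exactly. The output is labelled as
  distance-based permutation ANOVA regardless of whether callers think of it
  as dbRDA.
* **Dispersion test**: samples are embedded by PCoA keeping all axes;
  squared distance to the own-group centroid adds positive-eigenvalue
  contributions and subtracts negative-eigenvalue (imaginary) ones,
  clamped at zero. The one-way F on those distances is assessed by
  permuting group membership and recomputing centroids and distances under
  each permuted grouping. Group centroids (not spatial medians) are used;
  singleton groups are excluded with a warning. Because the distances are
  measured to *fitted* centroids they are only asymptotically exchangeable:
  type-I error is ~0.06 at 20 samples per group and nominal (0.045-0.05) by
  50 per group, so the calibration experiments use 50 per group.

## Associations

* **Adjusted linear models** are two-stage by default: residualise the
  response on sex + scaled BMI + scaled age, then model the residuals on
  diagnosis (x phenotype). Backward-forward stepwise AIC respects the model
  hierarchy. Pairwise group contrasts of means (and slopes when the
  interaction survives) are Wald tests, BH-corrected within each family;
  contrasts involving groups under 3 observations are suppressed.
* **Partial correlations** use the precision-matrix identity
  `rho = -P_xy / sqrt(P_xx P_yy)` on the Pearson, rank-transformed
  (Spearman), or Kendall-tau correlation matrix of (x, y, covariates).
  Kendall through the precision matrix is an approximation, kept because the
  three methods enter only as an ensemble. P-values: t with
  `df = n - n_cov - 2` (Pearson/Spearman), normal tau approximation
  (Kendall).
* **Brown's method** combines the three correlation p-values:
  `X = -2 sum ln p` referred to a moment-matched scaled chi-square with
  `E[X] = 2k` and `Var[X] = 4k + 2 sum cov`, the pairwise covariance from
  the Kost-McDermott polynomial `3.263 rho + 0.710 rho^2 + 0.027 rho^3`.
  With zero correlations this is exactly Fisher's method; with perfectly
  correlated identical p-values it returns that p. The inter-test
  correlation is estimated empirically from the `-2 ln p` vectors across
  taxa of the same scan (a fixed matrix can be supplied).
* **Rank tests**: Kruskal-Wallis omnibus for >2 groups, two-sided Wilcoxon
  rank-sum for pairs (BH within the pairwise family), paired t for paired
  two-group designs.

## Community typing (DMM)

Counts are clustered by an EM fit of a K-component Dirichlet-multinomial
mixture. The M-step applies Minka's fixed-point update (20 inner iterations)
to each component's alpha, a minorise-maximise step, so the observed-data
log-likelihood trace is monotone; initialisation seeds component alphas at
the compositions of randomly chosen samples, best of `n_init = 5` kept.
DMM is fitted on raw counts: running a multinomial-likelihood model on CLR
scores is internally inconsistent, so the CLR-first reading is available
only behind a discouraged flag-equivalent (feed a rounded, shifted CLR table
explicitly).

K is selected over 1..15 by a Laplace-approximate negative log evidence:
`-log L - log prior - (d/2) log 2pi + 0.5 log det(-H)` with parameters
log-alpha (vague N(0, 10^2) prior) plus mixture weights (flat Dirichlet;
multinomial information determinant `N^(K-1)/prod w_k`). The explicit prior
volume matters: without it the determinant term is offset by the `2 pi`
term and extra components are nearly free. Curvature eigenvalues are floored
at 1 so flat directions of degenerate components cannot reward complexity,
and any K whose best fit contains a component supported by fewer than 2
samples (non-identified) is skipped with a warning. On data drawn from an
actual DM mixture with well-separated components this selects the true
K ∈ {1, 3} reliably and recovers labels at ARI > 0.9. On the family-cohort
generator's log-normal noise (which no DM can represent) the "true" K is
ill-defined; cluster-label recovery there requires the planted separation to
exceed the within-cluster Aitchison spread (~ `noise_sd * sqrt(2 p)`).

## Co-abundance networks

Per cohort subset, taxa are CLR-transformed and each taxon lasso-regressed
on all others over a 20-point log-spaced penalty path (neighbourhood
selection). The penalty is chosen by stability selection: 30 subsamples of
size 0.8n, edge instability = mean Bernoulli variance of OR-rule selection,
monotonised from the sparse side, densest penalty with instability <= 0.05.
The reported edges are those selected in >= 80% of subsamples at that
penalty — the instability boundary alone leaves ~2-3% spurious density under
a global null, while the stability threshold keeps null networks essentially
empty and recovers strongly coupled pairs. Signs and weights come from the
full-data fit. Constant taxa are dropped with a warning; below 50 samples a
warning is emitted.

Topology summaries: degree, betweenness, PageRank (damping 0.85),
eigenvector centrality, mean neighbour degree; density, average clustering,
degree assortativity, diameter/radius on the largest component, and natural
connectivity `ln((1/n) sum exp(lambda_i))` from the full adjacency spectrum
(non-negative for any graph; strictly increasing in edge addition, verified
exhaustively on all 6-node graphs). Centrality significance uses a
degree-preserving double-edge-swap ensemble with one-sided Z-tests (default
10,000 rewirings; an Erdos-Renyi fallback covers graphs too sparse to
rewire). Note that degree itself is degenerate under this null by
construction — the test is informative for centralities *beyond* degree,
and nodes with zero null variance are flagged.

Graphlet profiles count the nine connected 2-4-node induced subgraphs
exactly, via degree/adjacency identities plus Moebius inversion over the
4-node lattice, validated against brute-force subset enumeration up to 30
nodes. Between-network distances: 1 - Spearman correlation of graphlet
frequency vectors, or 1 - Jaccard of edge sets (shared node universe
required); both feed the ordination/PERMANOVA machinery.

## Heritability

The additive relationship matrix `A = 2 Phi` comes from the classical
recursive kinship algorithm on reported parent links (handles inbreeding;
singletons get identity rows; cycles are rejected by name). Phenotypes (CLR
abundances at a 10% prevalence gate, or the MD index) are fitted under
`y = X beta + g + e`, `g ~ N(0, sigma_g^2 A)`, by REML: one
eigendecomposition of A rotates the model to independent observations and
the restricted likelihood is profiled down to a bounded one-dimensional
search over h^2 (the phenotype is standardised internally, so estimates are
scale-invariant up to optimiser precision ~1e-7 on flat likelihoods).
The "null" model has intercept only; the "full" model adds age, sex, BMI
and IBD status (categoricals dummy-coded, numerics standardised); both are
refitted by ML for AIC and compared as `delta AIC = AIC_null - AIC_full` on
the identical subject set (rows with any missing covariate are dropped from
both). `h^2` at a boundary is clipped and flagged; `A ~ I` is reported as
unidentifiable rather than an arbitrary variance split. A household/shared-
environment component is deliberately not included (single genetic random
effect), matching the one-random-effect model the pipeline targets.

## Synthetic cohorts

The generator exists so that every stage is testable without restricted
data. Per sample, log abundances are

    lambda_st = baseline_t + ln(2) * log2fc_t * IBD_s + g_st + eps_st

with `softmax` composition, log-normal library sizes (meanlog 9.2 ≈ 10k
reads, sdlog 0.35), and Gamma-Poisson (NB, default size 1) counts. Defaults:
150 nuclear families (1-3 children, probabilities 0.30/0.45/0.25), 120 taxa
on a smooth rank-abundance gradient spanning e^6, subject-level IBD
prevalence 0.45 (split CD/UC/uIBD = 0.54/0.43/0.03), 12 health-associated
abundant taxa down and 12 mid-rank disease taxa up at |log2FC| = 2,
compositional noise sd 0.8 with the IBD noise sd multiplied by 2 (the
"Anna Karenina" inflation). Genetic effects for nominated taxa are one
MVN(0, sigma_g^2 A) draw with sigma_g chosen so the latent-scale h^2 hits
its target relative to the control-group noise (counting noise attenuates
estimates from counts — intended). Biomarkers are linear-Gaussian in a
latent dysbiosis score (the standardised projection of lambda onto the
disease-effect direction); BSS is rounded and clipped to 1..7; PRS columns
are unit normals shifted +0.5 in the matching diagnosis. Optional planted
structure: community clusters (zero-sum orthonormal offsets at a configured
pairwise Aitchison separation) and taxon-taxon couplings (correlation
injected into the noise field, with a disease-only list). Time points are
not modelled (i.i.d. redraws would carry no autocorrelation, so only BL is
emitted). Everything is drawn from a single seeded generator;
identical config and seed give byte-identical output.

What the generator does *not* emulate — and hence what green tests do not
establish about real data: read-level artifacts (chimeras, primer bias),
longitudinal autocorrelation, taxon-specific library-size biases, household
effects distinct from kinship, and DM-consistent overdispersion (its noise
is log-normal, deliberately heavier-tailed than a Dirichlet-multinomial).

## Problem sizes in the shipped checks

The test suite and `scripts/acceptance.py` run the calibration experiments
at 100-200 replicates (type-I bands are the central 99% binomial interval
around 0.05), the NB null at 500-2000 taxa, effect-size recovery as the
mean over 4 replicate ~300-sample cohorts (the per-cohort estimate is
unbiased but its spread is dominated by biological log-normal variability,
sd ~0.55 in log2 units), heritability recovery at 50-100 replicates on 150
two-child families, DMM selection over K = 1..5-6 on ~100-120 samples, and
network comparison on 8 networks of 60 taxa from ~240-sample cohorts.
These sizes were chosen as the smallest at which the binomial/Monte-Carlo
error is well inside each asserted band.
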