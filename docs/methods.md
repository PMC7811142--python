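# Methods

`viroflux` implements an inference chain linking the composition of
eukaryotic-virus marker genes in ocean survey samples to carbon export
efficiency (CEE), together with downstream host prediction and
functional-trait analysis of network partners. This note documents the
models, the numerical choices, what the synthetic-data generator does and
does not emulate, and the known limitations.

## Compositional preprocessing

Marker-gene read counts are compositional: only relative information
survives sequencing. The pipeline's "relative abundance" is the centered
log-ratio (CLR) of gene-length-normalized counts,

    x_ij = count_ij / (length_i / 1000)          (reads per kilobase)
    clr_ij = ln x_ij − mean_over_group( ln x_·j )

so each sample's values sum to zero within a closure group.

**Closure groups.** PolB markers come from prokaryote-enriched metagenomes
while RdRP and Rep markers come from eukaryotic metatranscriptomes; the two
catalogs are distinct sequencing compositions, so CLR closure is applied
separately within {PolB} and {RdRP ∪ Rep} by default (`closure="by_library"`).
A single-composition mode (`"single"`) is available for data from one
library type.

**Zero replacement.** CLR requires strictly positive values. The default
policy (`"half-min"`) replaces zeros with half the smallest non-zero
length-normalized value in the closure group, a standard multiplicative-
style replacement that keeps the transform finite without distorting the
ranking of observed values; a fixed pseudocount is selectable. A sample
with no reads at all in a closure group is an error, not a silent fill.

**CEE.** Carbon export efficiency is the ratio of the carbon flux at depth
to the flux at the surface, CEE = CE_deep / CE_surface, computed from the
flux columns of the sample metadata. Flux estimation itself (from in-situ
particle imaging) is upstream of this package; CE_surface, CE_deep, CE150,
NPP and T100 are consumed as given.

**Marker filter.** Before regression a marker must (i) be present —
at least `presence_reads = 2` mapped reads — in at least `min_samples = 5`
samples, and (ii) have |Spearman ρ| strictly greater than
`rho_threshold = 0.2` between its profile and the response. The stages are
ordered: occurrence gate first, CLR on the occurrence-passing set (so the
modelling composition is closed over markers with data), then the
correlation gate on the CLR profiles. Correlating on raw normalized counts
instead is selectable (`correlate_on="normalized"`); the two usually agree
closely because Spearman is rank-based. Samples with a missing response are
dropped (logged) before any gate.

## PLS regression, LOOCV, permutation test, VIP

With n samples and often many more markers than samples, ordinary least
squares is unusable; partial least squares (PLS1) regression extracts a few
latent components that maximize covariance with the response. The fit is
NIPALS on autoscaled X (centered, unit variance; the convention under which
VIP thresholds near 2 are interpretable) and centered y:

    w_a ∝ X_a' y (unit norm),  t_a = X_a w_a,
    p_a = X_a' t_a / t_a't_a,  q_a = y' t_a / t_a't_a,
    X_{a+1} = X_a − t_a p_a'

with coefficients β = W (P'W)⁻¹ q. The default is A = 2 components
(overridable); if a later component has no residual covariance with y
(exact fits), the model truncates with a warning rather than producing
numerical noise.

**Assessment.** Predictions are evaluated by leave-one-out cross-validation
(LOOCV): autoscaling and the full NIPALS fit are re-estimated on each n−1
subset. Reported are the Pearson correlation r between observed and
predicted values and R² = 1 − SSE/SST. R² is not clamped; a model worse
than the mean gives R² < 0, and under the null LOOCV R² is negatively
biased — both are features used by the test suite.

**Pre-filtering is not nested.** The marker filter is applied once, on the
full data, before LOOCV and before the permutation loop. This mirrors the
pipeline's intended workflow but lets the held-out sample influence marker
selection, which biases LOOCV statistics optimistically. The permutation
test is the guard: the same non-nested selection applies to every permuted
response, so the null distribution carries the same optimism.

**Permutation test.** The statistic is the Pearson r between a permuted
response and its own LOOCV predictions (R² selectable); y is permuted
uniformly at random `n_perm` times (default 10,000; 999 is a practical
desk-scale setting) and the one-sided p-value uses the add-one rule
p = (1 + #{r_perm ≥ r_obs}) / (1 + n_perm), counting ties against the
observed value (conservative). The LOOCV loop is recomputed in full for
every permutation; a batched NIPALS implementation shares each fold's
autoscaled X across permutations, which is what makes 10⁴ permutations
affordable.

**VIP scores.** Variable importance in the projection for marker j,

    VIP_j = sqrt( p · Σ_a SS_a (w_ja/‖w_a‖)² / Σ_a SS_a ),
    SS_a = q_a² t_a't_a,

normalized so that Σ VIP² = p. Markers with VIP > 2 (strict) are the
model's key predictors, split into positive and negative sets by the sign
of β_j. Note that VIP > 2 means "four times the average share of the
explained response variance"; when a planted or real signal is spread
evenly over many similarly-informative markers, no single marker need
exceed the threshold — an empty VIP set is a meaningful outcome, not an
error.

**Multiple responses.** `run_response_models` repeats filter → fit → LOOCV
(→ permutation) per response, each with its own correlation gate, and
tabulates pairwise VIP-set overlaps. `compare_predictor_overlap` is a
pooled two-proportion z-test; its denominators are passed explicitly by the
caller because the appropriate baseline (filtered set, union, fixed panel)
depends on the question.

## Phylogeny-guided, network-based host prediction

Direct virus–host pairs are rarely observable in surveys. The host
prediction stage combines two indirect signals: co-occurrence (a virus and
its host covary across samples, so network partners are host candidates,
albeit noisy ones) and phylogeny (related viruses infect related hosts, so
a *clade* consistently associated with one eukaryotic order is far stronger
evidence than any single edge).

Each viral leaf is annotated with the set of orders of its network
partners (binary presence; edge weights are ignored). For every internal
node with ≥ `min_leaves = 3` annotated descendant leaves and every taxon
seen below it, a one-sided Fisher exact test (hypergeometric upper tail)
compares taxon frequency under the node against the rest of the tree,
restricted to annotated leaves — unannotated leaves are excluded from both
margins since they dilute all taxa identically. Benjamini–Hochberg
correction runs over the full (node × taxon) grid of executed tests
(per-taxon correction selectable); records with Q ≤ α = 0.05 are
significant. Unrooted input trees are midpoint-rooted deterministically.

**Nested detections.** An enriched clade usually drags a chain of
ancestors and sub-clades to significance (an ancestor separated from the
clade only by unannotated leaves has the *identical* contingency table).
Three derived quantities handle this:

- ranking (`rank_enrichments`) orders by Q, then p, then total clade size,
  so exact ties resolve to the most specific clade;
- `has_parent_child` flags a significant record when another significant
  record for the same taxon sits on an ancestor or descendant node, and
  `n_independent` counts unflagged records (the "N nodes, M without
  parent-to-child relationships" summary shape);
- `n_lineages` counts connected ancestor–descendant components among a
  taxon's significant nodes — the number of distinct clades supporting the
  taxon. A single enriched clade reports many nodes, zero unflagged ones,
  and exactly one lineage.

## Trait enrichment of network partners

Given virus groups (e.g. positive VIPs vs non-VIPs), their eukaryote
partner sets are compared trait by trait (chloroplast, silicification,
calcification): one 2×2 table per trait (present/absent × group), a
two-sided Fisher exact test under the minimum-likelihood rule (all tables
with point probability ≤ the observed one), and BH correction across the
traits of one contrast (m = number of traits actually tested). OTUs with
unknown trait status are dropped from that trait's table only — which is
why denominators legitimately differ between traits. Partner sets are
"any-edge" by default; an exclusive mode drops OTUs connected to both
groups. Degenerate tables (empty partner set, zero margin) produce a
reported row with the test skipped, never a silent omission.

## Synthetic data

The generator produces every input the pipeline consumes, with planted and
therefore recoverable structure.

**Community counts.** Relative abundances follow a log-normal field
(per-marker mean ~ N(0,1) plus per-cell N(0,1) variation), thinned by
i.i.d. Bernoulli dropout at the scenario's `sparsity` (default 0.6,
emulating a sparse survey table of ~59 samples × ~1,500 markers at the
default scale); reads are Poisson at a log-uniform library size in
[5·10⁴, 5·10⁵]. Two deliberate floors keep the design non-degenerate:
cells that survive dropout receive at least one read (so the realized zero
fraction equals the dropout rate, and `sparsity=0` is exactly dense), and
each closure group retains at least one marker per sample (every
sequencing library yields some reads).

**Planted response.** CEE_i = baseline + Σ_j β_j clr_ij + ε_i, with the
same CLR convention the pipeline uses, β alternating ±1 over
`n_true_predictors = 10` markers drawn among those present in at least half
the samples, and ε ~ N(0, σ). σ can be given directly (`noise_sd`) or
derived from a target population R² (`target_r2`, default 0.7) using the
realized signal variance. The baseline (default 1.0) keeps the
export-efficiency ratio positive; CE_surface = 1 and CE_deep = CEE so the
ratio round-trips exactly. Secondary responses are independent noise unless
configured to share the planted predictors. Ground truth (marker ids, β)
is returned as a sidecar table, never embedded in the inputs.

**Tree and network.** A random binary tree (random pairwise joins,
exponential branch lengths) in which each planted (size, taxon) pair is one
monophyletic clade whose leaves link to an OTU of that taxon with
probability 0.9; every leaf additionally links to a random-taxon OTU with
probability `background_edge_rate`. Trait tables are i.i.d. Bernoulli per
trait with an optional rate × factor bias on a designated OTU subset.

**What the generator does not emulate — and what that means for the
tests.** No spatial/temporal autocorrelation between samples, no
phylogenetic correlation between marker profiles, no compositional
interaction between the planted response and unrelated markers, no
network inference noise (edges are drawn directly, not estimated from
abundances), and no trait correlation structure. Passing recovery tests
therefore show that the chain of estimators is correct and well calibrated
under its own assumptions; they do not show robustness to the confounding
that real survey data carry.

**A property of the evenly-spread default signal.** With the planted R²
split evenly over k = 10 markers, each true marker's marginal correlation
with the response is ≈ √(R²/k) ≈ 0.26 — just above the 0.2 filter gate.
Consequently (i) a third of the true predictors are dropped by the filter
in a typical draw, capping pipeline LOOCV R² near 0.5 when the planted
population value is 0.7, and (ii) no marker reaches VIP > 2 in the default
1,500-marker scenario, because no marker is individually indispensable.
Both are faithful consequences of spreading a fixed signal thinly, and the
test suite documents them as such; recovery checks assess the ranking of
retained true predictors and the identification of the planted clade
lineage, which are robust under these conditions.

## Numerical choices and degenerate inputs

- Autoscaling uses the sample standard deviation (ddof = 1); zero-variance
  predictors are an error naming the marker.
- NIPALS guards divisions with 1e-15; CLR zero-sum holds to 1e-9; VIP
  normalization to 1e-8; score orthogonality to 1e-8 relative.
- Ties in the permutation count use ≥ (conservative); the add-one rule
  keeps p > 0.
- Constant responses or profiles raise an undefined-statistic error rather
  than returning NaN.
- Midpoint rooting follows dendropy's deterministic implementation; node
  ids are stable preorder labels assigned after rooting.
- Problem sizes in the test-suite simulations (n = 59 samples, 300 markers
  for regression recovery; 64-leaf trees; 40-seed batches; 999 or 199
  permutations where a distribution is needed) are chosen to estimate each
  rate with usable Monte-Carlo precision at desk scale.

## Known limitations

- The non-nested filter makes LOOCV statistics optimistic (see above); the
  permutation p-value is calibrated, the point estimates of r and R² are
  not. A strict workflow would nest selection inside every fold.
- PLS1 only (single response per model); no sparse PLS, no coefficient
  confidence intervals.
- Host prediction inherits the limits of co-occurrence networks: indirect
  associations (e.g. symbioses) produce enrichments that are real signals
  of association but wrong as host assignments.
- The two-sided Fisher convention is the minimum-likelihood rule; mid-p
  variants are not offered.
- T100 and the flux estimates are consumed as inputs; their derivation is
  out of scope.
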