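# Methods

This note documents the models implemented in `synovnet`, the defaults and
why they were chosen, what the synthetic cohort does and does not emulate,
and the numerical choices that affect results.

## Data model and QC

NPX values are treated as log2-scale relative abundances. LOD and ULOQ are
per-assay constants on the NPX scale; per-plate variation is out of scope.
The QC chain applies, in order:

1. **Dilution selection.** For each assay measured at several dilutions, the
   retained dilution minimises the *median* over samples of
   `|npx - (lod + uloq)/2|`; ties go to the smaller dilution factor. The
   median replaces the visual judgement of a dilution plot with a statistic
   robust to one or two outlying samples.
2. **Linearity exclusion.** For each sample and each adjacent dilution pair
   `(d1 < d2)`, the observed shift `npx(d1) - npx(d2)` is compared with the
   ideal `log2(d2/d1)`; the score is the mean absolute deviation. Assays
   scoring above 1.0 log2 units (a config knob) are excluded as non-linear.
   An assay run at a single dilution has no score and is retained.
3. **Below-LOD rule.** An assay is excluded when more than two samples *in
   the same group* fall below the LOD at the chosen dilution. In retained
   assays, below-LOD cells become missing values — never imputed at LOD/2 —
   because a censored cell carries no usable quantitative information at
   these sample sizes.
4. **Standardization.** Per protein, pooled over both groups: subtract the
   mean, divide by the sample SD (ddof = 1), ignoring missing cells.
   Pooled (not per-group) standardization preserves between-group variance
   differences, which the co-expression slopes are allowed to see.

## Hierarchical differential abundance

All proteins enter one linear mixed model:

```
npx ~ protein + group + protein:group + age_c + sex + bmi_c + (1 | person)
```

with treatment coding (control and the alphabetically first protein as
references) and age/BMI mean-centred so the group contrast is evaluated at
average covariates. Estimation is REML. Missing cells are dropped from the
likelihood (unbalanced fit), not imputed.

The engine (`synovnet.lmm`) profiles out the residual variance analytically
and optimises the restricted likelihood over the variance *ratio*
`lambda = tau^2/sigma^2`, evaluating every quadratic form through the
Woodbury identity so the cost scales with the number of random-effect levels
(24 persons) rather than observations. This keeps the 274-protein fit (~550
fixed effects, ~6,500 observations) under a second where a generic
mixed-model optimiser takes tens of seconds and can fail to converge; the
generic implementation (statsmodels MixedLM) is retained as an independent
cross-check in the test suite.

Per protein, the case-minus-control contrast is
`delta = group effect + that protein's interaction`, with a Wald 95% CI
using normal critical values, exponentiated base 2 to the fold-change scale.
`direction` is `inconclusive` exactly when the CI contains 0. **No
multiplicity correction is applied anywhere** — the outputs are nominal
intervals, mirroring the single-model hierarchical analysis this package
implements, and the tests assert no adjusted-p columns exist.

Two pooling modes resolve a genuine ambiguity in how much information is
shared across proteins:

- `fixed_interaction` (default): protein x group terms are fixed effects;
  contrasts are unshrunken. This matches the literal model statement above.
- `shrunken_interaction`: the protein-specific group deviation is a second
  (crossed) random effect; contrasts are empirical BLUPs partially pooled
  toward the common group effect, with prediction SEs from Henderson's
  mixed-model equations. Offered because "borrowing information between
  proteins" is sometimes the stated intent of an all-protein model; it pulls
  extreme proteins toward the mean and is the right choice when most
  proteins are exchangeable.

A single shared residual variance is used; per-protein residual variances
are a known limitation (proteins plausibly differ) accepted for speed and
stability at n = 24.

## Pairwise differential co-expression

For each ordered pair (outcome y, predictor x) on standardized data:
`y = b0 + b1 x + b2 g + b3 x g`, OLS, with t CIs on `n_used - 4` df; rows
with a missing value in either protein are dropped pairwise, maximising n
per pair. Both orders of each unordered pair are fitted because OLS slopes
are not symmetric; when both orders pass a selection rule, the direction
with the larger |slope difference| is kept (ties: lexicographic).

Selection rules:

- **Enrichment sets**: `|b3| >= 1` and the difference CI excludes 0. The
  pair's proteins join the control-dominant or OA-dominant set according to
  which group shows the larger |slope|.
- **Network edges**: additionally, the group's own slope must satisfy
  `|slope| >= 1` with its CI excluding 0; the edge is signed by that slope.
  Both CI clauses are independently toggleable (`EdgeSelectionRule`)
  because reasonable analysts disagree on which interval the magnitude rule
  should be paired with; the default requires both.

With ~75,000 pair models and no multiplicity correction (deliberate,
matching the package's exploratory stance), these selections admit many
chance qualifiers at n = 24 — the enrichment sets are large and should be
read as exploratory. This is flagged in output metadata rather than
"fixed", because correcting here would change the method being emulated.

The vectorised implementation computes all pairwise-complete group moments
with five matrix products per group; it is algebraically identical to the
single-pair OLS path (asserted to 1e-10 in tests) and fits 74,802 ordered
pairs in well under a minute on one CPU.

## Fused joint graphical lasso

Group precision matrices are estimated by minimising

```
sum_k n_k (tr(S_k Θ_k) - log det Θ_k)
  + λ1 sum_k sum_{i≠j} |Θ_k,ij|  +  λ2 sum_{i,j} |Θ_1,ij - Θ_2,ij|
```

by ADMM: the Θ-update is an eigendecomposition, the auxiliary update is the
closed-form fused-pair prox followed by soft-thresholding (diagonal never
sparsity-penalised), and convergence is declared when primal and dual
Frobenius residuals drop below 1e-5 (rho = 10, defaults). The reported Θ is
the sparse auxiliary iterate when positive definite, so zeros are exact.
S_k are within-group pairwise-complete covariances (denominator n_k) with an
eigenvalue-clip PSD repair at 1e-8 — pairwise completion can break
definiteness; this repair is a documented approximation. Entries with
`|Θ_ij| > edge_tol` (default 1e-5) define the adjacency.

Model selection scans a (λ1, λ2) grid and reports
`AIC_k = n_k tr(S_k Θ_k) - n_k log det Θ_k + 2 E_k` (BIC with `log(n_k) E_k`),
`E_k` = upper-triangle nonzeros. Three models are marked: the BIC optimum,
the AIC optimum, and the densest converged fit. Grid guidance: penalties
should be read per observation; `λ1/n ≈ sqrt(log p / n)` is the natural
scale (≈ 0.3 at n = 100, p = 20). Below that scale, information criteria
evaluated on shrunken-likelihood lasso fits are known to over-select, so
grids extending far into the dense region will hand BIC models with many
small spurious edges.

At the emulated cohort size (13 + 11), a partial correlation of 0.3
contributes roughly `n r^2 ≈ 1` to the log-likelihood — below even the AIC
penalty per edge — so the criteria legitimately prefer empty graphs. The
analysis driver reports this rather than hiding it: conditional-dependence
results at this n are hypothesis-generating.

Protein subset: the full pipeline runs the JGL on a 50-protein subset
(config) ranked by the strongest within-group marginal correlation, or an
explicit protein list. At n = 24 no marginal statistic reliably separates
truly co-varying proteins from chance (spurious |r| up to ~0.9 across 37k
pairs), another documented small-n limitation.

## Pathway enrichment

Hypergeometric upper-tail over-representation, `p = P(X >= q)` with
population |background|, successes `m = |members ∩ background|`, draws
|query|. The background is the set of proteins detected on the panels — not
a whole-genome background, which would wildly overstate enrichment for
panel data. Pathways with `m < 5` are dropped; rows are sorted by ratio
`q/m` descending then p ascending; symbols match case-insensitively. Raw
p-values only (no correction). The annotation is a plain GMT file
(name, top-level category, members); no pathway-hierarchy or topology logic
is applied, and p-values from hierarchy-aware services will differ.

## The synthetic cohort

`simulate.default_config` emulates the study conditions: 13 control / 11 OA
persons; three 92-assay panels; covariates age ~ U(55, 80), sex
Bernoulli(0.7 F), BMI ~ N(27, 4²) with small effects (0.01/yr, 0.1 for M,
0.02 per BMI unit); person random intercept SD 0.3; residual SD 0.5 — both
on the log2 scale, values a practitioner would call typical biological and
assay variation for immunoassay panels (the emulated study reports no
variance figures, so these are the package's stated choice). Half the
proteins carry a case shift from N(0, 1.2²) truncated at |3.4|, with
sentinels at ±3.4 (FC 10.6 / 0.095). A 20-protein subset gets group-specific
chain precisions (unit diagonal, off-diagonal -0.3; diagonally dominant so
PD by construction); control and case chains differ, defining the true
differential edges as those present in exactly one group. Dilutions 1:1,
1:20, 1:200 with LOD/ULOQ quantiles (0.02 / 0.995) taken at the middle
dilution, so 1:20 is genuinely mid-range; one assay is corrupted with a
hook-effect response (ideal values above a saturation cap are reflected
about it), and one assay's LOD sits at the 0.35 quantile so the below-LOD
rule has real work. Noise is multivariate normal on the log2 scale;
censoring is applied after dilution simulation, per dilution. One seed
feeds named substreams per stage, so changing the protein count does not
perturb the sampled covariates.

The planted-pair generator (`simulate_planted_pairs`) used for edge-recovery
studies works directly on the analysis scale: control-group outcome =
±1.5 x predictor + N(0, 0.5); in the case group every protein is independent
N(0, 0.5). Keeping the case-group scales homogeneous matters: regressing
onto a variance-compressed protein inflates null slopes and, with the
|slope| >= 1 rule, manufactures false edges — a genuine hazard of the edge
rule on heteroscedastic data that the test suite demonstrates is absent in
the homogeneous design.

What the simulator does **not** emulate: plate/batch effects, counts-to-NPX
normalization chemistry, per-plate LOD variation, non-normal tails, and
correlated missingness. Passing tests therefore certify the statistical
machinery and its calibration under the stated generative model, not
robustness to those artefacts.

## Numerical choices

- Mixed model: variance-ratio search over log-lambda in [-23, 18]; REML
  surface optimised by bounded scalar search (one component) or Nelder-Mead
  (two); rank-deficient fixed designs rejected up front; a "person variance
  pinned at zero" mode gives the exact OLS limit.
- Pair models: pairs with fewer than 4 complete cases per group, or a
  within-group constant predictor, are flagged unestimable and excluded
  from selection (never silently dropped).
- ADMM: objective evaluated at the PD primal iterate each iteration; the
  trace is checked non-increasing (1e-8 slack) in tests. λ2 → ∞ provably
  forces Θ_1 = Θ_2; checked at λ2 = 1e4.
- PCA overview: column-centred SVD with per-protein mean imputation of
  missing cells — an overview-only convenience; inferential stages each use
  their own missing-data rules.
- Determinism: the pipeline is a pure function of (inputs, config, seed);
  reruns are byte-identical, asserted in tests.

## Problem sizes used in the checks

Simulation-based checks run at the sizes stated in their tests: 500
replicates for mixed-model bias/coverage and null calibration (5 and 4
proteins per replicate at n = 12 + 12), 100 replicates for pair-oracle and
edge-recovery studies, 50 replicates at p = 20, n = 100/group for
graphical-lasso structure recovery, and one full 276-assay cohort for the
end-to-end scale and determinism checks. These sizes give stable medians
and percentile bounds while keeping the whole suite fast enough to run
habitually.
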