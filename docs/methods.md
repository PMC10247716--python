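# Methods

This note documents the statistical procedures implemented in
`gutmediate`, the defaults and why they were chosen, what the synthetic
data generator does and does not emulate, and the numerical conventions
that matter for reproducing results.

## Study design assumed throughout

A two-level treatment factor (control vs. hypoxia) over a modest number of
animals per group (default 6, the scale of exploratory rodent studies),
with four feature tables sharing the same samples: a genus-level 16S count
table, fecal and serum LC–MS metabolite intensity matrices, and a serum
hormone panel (CRH, ACTH, CORT, TRH, tT4, TSH, fT4, tT3, fT3). All stages
treat the treatment as the biological contrast of interest; the mediation
stage additionally treats it as an adjustment covariate.

## Elementary tests (`stats_core`)

* **t-test** — two-tailed, unpaired; the default pools variances
  (Student), matching the common Prism-style analysis of hormone panels;
  Welch is available via `variant="welch"`. The equal-variance assumption
  for hormone data is genuinely undecidable from a published figure
  caption, so both are exposed and the method used is recorded in every
  result. Zero-variance inputs are resolved by convention (equal means →
  p = 1, unequal → p = 0 flagged degenerate) rather than returning NaN.
* **Mann–Whitney** — exact permutation null when the pooled sample is
  ≤ 20 observations and tie-free, because at n = 6/group the normal
  approximation is visibly coarse (the smallest achievable two-sided p is
  2/C(12,6) ≈ 0.0022); tie-corrected normal approximation otherwise.
* **Kruskal–Wallis** — tie-corrected H; for two groups its α = 0.05
  decision coincides with Mann–Whitney on tie-free small samples, which is
  the documented contract the LEfSe-style screen relies on.
* **Hypergeometric enrichment** — upper-tail P(overlap ≥ observed);
  empty selections or pathways are unenrichable (p = 1) by convention.
* No multiple-testing correction is applied by default anywhere: every
  screen gates on raw p < 0.05, reproducing the analysis style this
  pipeline re-implements. `benjamini_hochberg` is provided for users who
  want FDR control across features or triads.

## Microbiome screen

* **Rarefaction** draws each sample without replacement to a common depth
  (default: the minimum observed sample total, i.e. data-derived rather
  than hard-coded) via multivariate hypergeometric sampling.
* **Alpha diversity**: Shannon in bits (log₂, the QIIME-1 convention;
  natural log available), observed richness, Gini–Simpson 1 − Σpᵢ², and
  Chao1 S + F₁²/(2F₂) with the bias-corrected form
  S + F₁(F₁−1)/(2(F₂+1)) when no doubletons exist (avoids the 0/0).
* **CSS normalization** divides each sample by the cumulative count of its
  features at or below its median nonzero count (quantile fixed at 0.5
  rather than adaptively selected: with 6 samples/group the adaptive
  criterion is unstable, and a fixed quantile keeps the pipeline
  deterministic), then rescales by 1000.
* **PCoA** is classical Gower double-centering + eigendecomposition.
  Negative eigenvalues — expected for Bray–Curtis, which is not metric —
  are dropped, and proportions explained are computed over the positive
  spectrum only; no Cailliez/Lingoes correction is applied. Bray–Curtis
  itself is bounded in [0,1] and symmetric but does not satisfy the
  triangle inequality; nothing downstream assumes it does.
* **LDA effect-size screen** (two-class LEfSe-style): per-sample total-sum
  scaling to 10⁶ counts-per-million; per-feature Kruskal–Wallis keeping
  p < α; then 30 seeded bootstrap rounds, each subsampling 2/3 of each
  group and fitting a two-class LDA on the kept features with the pooled
  covariance shrunk halfway toward its diagonal (at n = 6/group the pooled
  covariance is singular without shrinkage). Each round scores feature j
  as (|w_j·d_j| + |d_j|)/2 with w the unit-norm discriminant direction
  and d the group mean difference in per-million units, and the reported
  LDA score is log₁₀(1 + mean round score). A feature passes at
  kw_p < 0.05 AND score > 3. The subclass/pairwise-Wilcoxon stage of
  original LEfSe is a no-op in this two-group design and is intentionally
  not implemented. Bootstrap draws are keyed to id-sorted samples, so
  results are invariant to the column order of the input table.
* The screen runs on rarefied counts (TSS is applied internally); whether
  the original toolchain ran LEfSe on rarefied or CSS-normalized counts is
  not determinable, so the input table is the caller's choice.

## Metabolome screen

* **Missingness filter**: a zero intensity is a missing ion; features with
  zeros in strictly more than 60% of samples are removed. 7/12 (58.3%)
  survives, 8/12 (66.7%) does not.
* **OPLS-DA** (single y = ±1 class encoding, Trygg–Wold): features are
  mean-centered and unit-variance scaled by default (Pareto exposed as an
  option, as metabolomics workflows often prefer it); orthogonal
  components w_o ∝ p − (wᵀp/wᵀw)w are iteratively extracted and deflated,
  then one predictive component t = Xw is taken. Defaults: one orthogonal
  component (the minimal OPLS-DA); component counts were not stated by the
  analysis being reproduced and are configuration, not fact. R²Y is the
  training fraction of class variance explained; Q² = 1 − PRESS/SS over
  seeded 7-fold cross-validation (each fold refits scaling and the full
  decomposition; with fewer samples than folds the split degrades to
  leave-one-out with a warning). The "7 rounds excluding 1/7 of samples"
  scheme is realized as a shuffled partition into 7 near-equal held-out
  folds, each sample predicted exactly once. Median Q² ≤ 0 under label
  permutation is the standard overfitting guard and is asserted in tests.
* **VIP** is computed over predictive components only (orthogonal
  components carry no class information by construction); with one
  predictive component and unit-norm weights, VIP_j = √J·|w_j| and
  Σ VIP² = J exactly — asserted to 1e-8 as a numerical identity.
* **Selection** is strict: VIP > 1 AND two-tailed t-test p < 0.05;
  boundary values are excluded. The t-test runs on log₁₀(x+1)-transformed
  filtered intensities by default ("normalized peak areas" is not a
  defined normalization; raw mode is available), while up/down direction
  is always computed on raw group means (ties → "up" in the treatment
  group).
* **Hotelling's T²**: T²crit = A(N²−1)/(N(N−A))·F₁₋α(A, N−A) over all A
  score columns; the per-sample T² flags multivariate outliers at the 95%
  ellipse.
* **Pathway enrichment** delegates to the hypergeometric test per pathway
  of a supplied annotation table; there is no live pathway-database
  lookup.
* Positive/negative ESI mode merging is modeled as row concatenation with
  mode-tagged feature ids; the same mechanism tags fecal vs. serum
  metabolites (`fecal:`/`serum:`) in the combined mediator table.

## Mediation engine

Three OLS regressions per (X, M, Y) triad with the binary treatment Z
always included (total, mediator, outcome models; see README for the
equations). Transforms entering the regressions: genus abundances as
log₁₀(relative abundance + 10⁻⁶) of rarefied counts, metabolites as
log₁₀(intensity + 1), hormones raw. These are variance-stabilizing
choices for skewed omics features, configurable and recorded in output.

* **Point estimates**: ACME = β₂β₃, ADE = β₄, total = β₁. For OLS on
  identical samples and covariates, β₁ = β₄ + β₂β₃ is an algebraic
  identity; it is asserted to 1e-10 on every fit.
* **Assumption gate** (applied before effect estimation by default,
  toggleable): p(β₁) < α, p(β₂) < α, p(β₃) < α, and strict |β₄| < |β₁|.
  The weakening criterion has no published magnitude threshold; the strict
  inequality is the most conservative parameter-free reading.
* **Uncertainty** is quasi-Bayesian Monte Carlo: 1000 draws of β₂ from the
  mediator model and (β₃, β₄) jointly from the outcome model, independent
  across models. Draws use each model's multivariate *t* with the
  residual degrees of freedom — the exact coefficient posterior under the
  standard noninformative OLS prior — rather than the asymptotic Gaussian;
  at n = 12 the Gaussian approximation measurably inflates the ACME
  type-I error, while the t version stays below the nominal 5%
  (nonparametric bootstrap is out of scope). Intervals are 2.5/97.5
  percentiles; p-values are two-sided sign fractions floored at 2/n_sims.
  Note the empirical-percentile intervals are not guaranteed to contain
  the point estimate in pathological cases, though at n_sims = 1000 they
  essentially always do.
* **Screen**: both directions are enumerated over the candidate sets from
  the upstream screens (significant hormones × LDA-passed genera ×
  VIP-selected metabolites). Per-triad seeds derive from the master seed
  plus a CRC32 of the triad label, so results are independent of
  enumeration order and safe to parallelize. A triad whose X is collinear
  with Z (e.g. constant within groups) is skipped with a recorded reason.
  "Significant mediation" defaults to gate-passing AND ACME p < 0.05;
  ungated mode reports effect estimates for every fit.
* Linear Gaussian chains are **not directionally identifiable**: if
  X → M → Y is planted, the reversed triad fits comparably well, and the
  screen reports both orientations when both pass. This is a property of
  the model class, not an implementation artifact; direction claims rest
  on the design, not the statistics.

## Synthetic studies

`generate_study` emulates the statistical shape of the assumed design:

* **Genus counts**: a log-normal base composition (log-weights
  N(0, 1.5²)) with group log₂ fold changes (default ±2) on the chosen
  differential genera, per-sample Dirichlet perturbation (concentration
  300) and multinomial draws at log-normal library sizes (mean 30 000,
  σ = 0.2). Columns therefore sum exactly to their drawn library sizes.
* **Metabolites**: per-feature log₁₀ intensities N(μ_f, σ_f²) with
  μ_f ~ U(4, 7), σ_f ~ U(0.15, 0.4); differential features shifted by
  log₂FC·log₁₀2 in alternating directions. Zero inflation is post-hoc
  masking with per-feature zero probabilities drawn Beta(1, (1−r)/r)
  (mean r, default 0.15): the heavy right tail is what makes some
  features exceed the 60% missingness cut at realistic sample sizes — a
  single flat rate almost never would at n = 12.
* **Hormones**: Gaussian panels (mean U(10, 100), CV 10%) with the first
  five hormones group-shifted by 3 within-group SDs in an HPA/HPT-style
  pattern (three up, two down).
* **Planted triads** are defined on standardized latent variables
  (X* = shift·Z_c + N(0,1), M* = aX* + ε, Y* = bM* + c′X* + δZ_c + ε′)
  and mapped affinely onto each table's native scale; the default group
  shift on X (2 SD) is what makes planted features upstream-screen
  candidates. Planted mediator/outcome rows are overwritten wholesale,
  exempted from zero masking, and recorded in the ground truth together
  with all path coefficients. Genus-hosted triad variables are written
  into the pre-multinomial proportion matrix (other genera renormalized),
  so they carry realistic counting noise.
* Desk-scale defaults (60 genera, 300/150 metabolites) keep the test
  suite fast; `paper_scale_config()` provides a full-size preset
  (254 genera, 2945/1457 metabolites, 13/233/66 differential features).
* What the generator does **not** emulate: phylogenetic correlation among
  genera, feature-feature correlation beyond compositional closure and
  the planted chains, batch/run-order effects, intensity-dependent
  missingness, or longitudinal structure. Passing tests therefore
  demonstrate correctness of the computations and calibration under
  idealized independence — not robustness to those real-data features.

## Validation problem sizes

The validation suite and `scripts/acceptance.py` use: 1000 random triads
for the decomposition identity; 500 replicates at n = 200 for ACME
recovery/coverage of β₂β₃ = 0.42; 1000 replicates at n = 12 for the null
type-I rate; 500 replicates each at n ∈ {12, 24, 48} for the power curve;
100 random fits for the VIP identity; 50 label permutations for the null
Q²; an all-null study with 200 genera and 500 metabolites at n = 6/group
for screen calibration; and a 3-triad study (a = b = 1.2, 30/group) for
end-to-end recovery. These sizes give Monte-Carlo standard errors
comfortably inside the asserted bounds while keeping a full run in tens
of seconds.

## Known limitations

* Mediation estimates carry no sensitivity analysis for sequential
  ignorability; reported triads are screening output, not certified
  causal claims.
* Only Gaussian identity-link models are implemented (no binary/count
  outcomes, no multi-mediator joint models).
* The LEfSe variant implements the two-class case only.
* PD_whole_tree and UniFrac are out of scope (no phylogeny is
  constructed), as are raw 16S read processing and LC–MS peak picking.
* At n = 6/group the mediation screen is underpowered for moderate
  effects; planted-truth recovery experiments use 30/group for exactly
  the reason the underlying study design calls its own findings
  exploratory.
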