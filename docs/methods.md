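# Methods

This note records the statistical model, the conventions behind each
estimator, what the synthetic-data generator does and does not emulate, and
the design choices made where the field offers more than one defensible
option.

## Two-sample MR model

All computation is on GWAS summary statistics.  For SNP *j* the observed
exposure effect is β̂_Xj ~ N(γ_j, σ²_Xj) and the outcome effect
β̂_Yj ~ N(βγ_j + δ_j, σ²_Yj), where β is the causal effect of interest and
δ_j a horizontal-pleiotropy term (zero for valid instruments).  Exposures
are quantitative (standardized units); the outcome is binary, so β̂_Yj and
β are on the log-odds scale and reports exponentiate to odds ratios.

### Estimators

- **Wald ratio** (single instrument): β̂ = β̂_Y/β̂_X with first-order SE
  σ_Y/|β̂_X|.  The first-order form ignores the exposure-side noise term;
  for the strong instruments retained by the F > 10 filter the omitted term
  is below 10 % of the SE (checked against a Monte-Carlo ratio
  distribution in the tests).
- **IVW**: weighted regression through the origin, weights 1/σ²_Yj.  We
  use *multiplicative random effects with a fixed-effect floor*: reported
  SE = fixed SE × max(1, σ̂), σ̂² = Σw_j r²_j/(n−1).  Under homogeneity this
  reduces to fixed effects; under heterogeneity it widens the interval
  without reweighting.  Fixed-effects and unfloored variants differ only
  through this guard.  Inference is normal.
- **Weighted median**: per-SNP ratios b_j weighted by β̂²_Xj/σ²_Yj (the
  inverse first-order ratio variance); sort ratios, form cumulative
  standardized weights s_j = Σ_{i≤j} p_i − p_j/2, and interpolate at 0.5.
  SE from a parametric bootstrap (default 1000 draws, seeded) resampling
  β̂_Xj and β̂_Yj from their sampling normals; normal inference.
- **MR-Egger**: instruments oriented so β̂_Xj ≥ 0, then weighted regression
  *with* intercept.  Slope and intercept are both tested against t with
  n−2 df; this df convention (rather than normal inference) reproduces the
  reference report's Egger p-values exactly.  Confidence intervals for all
  methods, Egger included, use the normal z quantile — the convention of
  the standard MR toolkits, and the one the reference report's printed CIs
  follow.
- **MVMR**: β̂_Yj regressed on the exposure and mediator effect columns,
  no intercept, weights 1/σ²_Yj, SEs floored as in IVW with σ̂² on n−2 df.

### Instrument selection

Criteria applied in order, each logged with its removal count: exposure
p < 1e-5 (the loose threshold conventional for microbiome GWAS, where
genome-wide 5e-8 leaves too few instruments); greedy p-value-sorted LD
clumping at r² < 0.001 within 10,000 kb, ties broken by (p, chromosome,
position, rsID) so results are order-independent; harmonization (below);
outcome association p ≤ 1e-5 excluded; per-SNP F > 10 (strict) with
F = (R²/(1−R²))·(n−k−1)/k, k = 1, R² = 2·MAF·(1−MAF)·β² — β assumed
standardized; and removal of a user-supplied confounder-SNP list, which
replaces an interactive PhenoScanner lookup.  The outcome-association
filter can be disabled (`outcome_p_threshold=None`): it presumes an
underpowered outcome GWAS, and with a powered outcome and a real effect it
would strip exactly the valid instruments (see Mediation).

LD is supplied as an explicit pairwise r² table rather than computed from a
reference panel; pairs absent from the table count as r² = 0 and are
tallied.  Positions are 1-based and used only for clump windows; matching
across tables is by rsID.

### Harmonization

Outcome records are aligned to the exposure's effect allele: swapped
alleles negate the beta and complement the EAF; strand flips are resolved
by complementing; palindromic (A/T, C/G) SNPs cannot be strand-resolved, so
those with either EAF within 0.08 of 0.5 are dropped (window configurable),
and the rest are aligned by matching minor-allele status (`infer`) or
dropped wholesale (`drop_palindromic`).  Harmonization is idempotent and
the drop counts are reported.

## Sensitivity battery

- **Cochran's Q** over per-SNP ratios with weights β̂²_Xj/σ²_Yj (equivalent
  to fixed-effect IVW); p from χ²(n−1).  A regression-form Q would differ
  only under Egger-style fits and is not used.
- **Egger intercept test**: the intercept of the MR-Egger fit; p > 0.05
  read as "no detected horizontal pleiotropy".
- **MR-PRESSO**: observed statistic RSS = Σ_j w_j(β̂_Yj − b̂_(−j)β̂_Xj)²
  with b̂_(−j) the leave-one-out fixed IVW slope and w_j = 1/σ²_Yj; null
  distribution from 1000 parametric simulations around the leave-one-out
  fit; empirical p-values with add-one smoothing (global and per-SNP, the
  latter Bonferroni-adjusted by n); outliers at adjusted p < 0.05 trigger
  a corrected IVW without them.  The distortion test is not implemented:
  the study setting never reports it, and the corrected-vs-original
  comparison is available directly from the two estimates.
- **Leave-one-out**: IVW without each SNP in turn; a SNP is flagged
  *influential* when its removal loses significance at α = 0.05 or flips
  the sign of the estimate.  This operationalizes the usual visual
  reading of leave-one-out forest plots; no standard formula exists.
- **Multi-trait removal**: instruments associated (p < 1e-5) with another
  analysed trait can be dropped, guarding the exclusion restriction when
  several exposures are studied jointly.

## Mediation

`mediation_summary` runs three univariable MRs (exposure→mediator,
mediator→outcome, exposure→outcome) under the same selection rules, then an
MVMR on the union of the exposure's and mediator's instruments,
de-duplicated and re-clumped at the same r² threshold (union SNPs are
ordered by the better of their exposure/mediator p-values).  Conventions:

- Step 1 (exposure→mediator) never applies the outcome-association filter:
  the mediator is hypothesised to be downstream, so mediator-associated
  SNPs are the signal, not a violation.
- Step 2 (mediator→outcome) applies multi-trait removal against the
  exposure by default: an exposure-associated SNP instrumenting the
  mediator carries the exposure's direct effect (ratio β/α instead of β₂)
  and biases the step.  Measured on the standard recovery scenario, the
  mean estimated proportion moves from 0.46 (biased) to 0.394 (truth 0.4)
  with removal on.  Switch off with `multitrait_removal=False`.
- Indirect effects: α·β₂ (two-step) and β − β₁ (MVMR); proportion
  mediated = indirect/total, reported unclipped (suppression makes it
  negative; strong mediation can push it past 1), with the
  mediation/suppression label carrying the interpretation: *mediation* when
  indirect and total effects share a sign, *suppression* when they oppose.
- Proportion inference: delta method for the product (SE² =
  α²σ²_β₂ + β₂²σ²_α) treating the total effect as fixed.  This understates
  uncertainty when the total effect is imprecise; the recovery scenario
  therefore uses a powered outcome (below).

## Synthetic-data generator

Summary-level generation only: no individual genotypes, no winner's-curse
modelling, no real LD panels.  Per SNP: MAF ~ U(0.1, 0.5); exposure effect
γ_j ~ N(0, 0.15²); SEs follow the analytic forms
σ_X = (2·MAF·(1−MAF)·n_X)^(−1/2) for quantitative traits and
σ_Y = (2·MAF·(1−MAF)·n_Y·cf·(1−cf))^(−1/2) for the binary outcome
(logistic-score approximation with prevalence cf).  Observed effects add
N(0, σ²) noise.  Defaults mirror the target cohorts: n_exposure = 18,340,
n_mediator = 8,299, n_outcome = 247,540 with cf = 261/247,540 — the rare
outcome gives per-SNP outcome SEs near 0.1, the regime that makes the
screen hard.  γ_sd = 0.15 puts selected-instrument F statistics in the
12–155 range with a median near 60, matching what microbiome-scale
exposures yield after the p < 1e-5 screen.

Structure switches: `pleiotropy_frac/mean/sd` add direct outcome (and
mediator) effects to a random SNP subset, *sign-aligned with the
exposure-increasing allele* — so "directional" pleiotropy is directional on
the orientation MR-Egger fits, and the mean Egger intercept equals
pleiotropy_mean × pleiotropy_frac (verified property).  `swap_frac` and
`palindromic_frac` scramble allele labelling to exercise harmonization.
`ld_blocks` emits blocks of correlated SNPs (within-block r² = 0.95 in the
emitted LdInfo) placed inside the clump window, for clumping tests.
Mediation datasets assign disjoint SNP roles — exposure SNPs (γ ≠ 0,
μ = 0) and mediator SNPs (γ = 0, μ ~ N(0, 0.15²)), default half/half —
because MVMR is unidentified without mediator-specific instrument
variation; the outcome effect is βγ_j + β₂μ_j + δ_j with
β = β₁ + α·β₂ enforced.  One root seed drives per-table substreams, so
adding a table does not perturb existing draws and equal seeds give
byte-identical tables.

What the generator does **not** emulate: sample overlap between cohorts,
fine-scale LD and proxy lookup, allele-frequency mismatch between studies,
non-normal effect distributions, and selection (winner's curse) on the
exposure associations.  Passing tests therefore show the estimators and
pipeline are correct and calibrated under the stated model, not that any
particular real dataset satisfies that model.

## Simulation study sizes

Chosen to give tight Monte-Carlo error at interactive runtimes: IVW type-I
error over 1000 replicates × 30 SNPs; recovery (bias and 95 % CI coverage)
at β = 0.3 over 500 replicates with n_exposure = 20,000; MR-PRESSO outlier
power (one SNP shifted by 10 outcome SEs among 20) and null size over 100
replicates of 1000 simulations; Egger-intercept power over 200 replicates
at pleiotropy mean 0.1; mediation recovery over 200 replicates of the
standard scenario (α = 0.4, β₂ = 0.5, β₁ = 0.3, truth proportion 0.4).
The mediation recovery scenario uses a common outcome (case fraction 0.2)
rather than the rare-outcome default: the mediated proportion divides by
the estimated total effect, and with 261 cases the per-replicate total SE
(~0.2 on a truth of 0.5) makes that ratio unstable — mirroring why real
studies only quantify mediation for exposures with firmly established
totals.  The selection config for that scenario disables the
outcome-association filter for the reason given above.

## Numerical notes

- Weighted least squares is solved by normal equations (2×2 at most);
  rank-deficient MVMR designs (for example a zero mediator column) raise
  a collinearity error rather than silently dropping a column.
- Weighted-median interpolation is linear in the cumulative-weight domain;
  ratios from zero exposure betas are excluded with a warning.
- Empirical MR-PRESSO p-values use (1 + #{sim ≥ obs})/(n_sim + 1), so they
  are never zero and are bit-reproducible for a fixed seed.
- Clump ties are broken lexicographically by (p, chromosome, position,
  rsID); the retained set is invariant to input row order.
- Report files are rendered with fixed formats (3 decimals for beta/SE/OR,
  two-decimal scientific for p) and stable ordering; identical inputs and
  seeds produce byte-identical report directories.

## Known limitations

One mediator per model (no joint multi-mediator decomposition); no
mode-based estimators, MR-RAPS, or Steiger filtering; no reference-panel
LD computation, proxy SNPs, or VCF input; plot data tables are emitted but
no figures are rendered.  The per-SNP k = 1 convention for F statistics is
a documented default — the joint-k variant changes F by a factor
(n−k−1)/(k(n−2)) and is not exposed.
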