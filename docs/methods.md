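# Methods

This note documents the statistical models implemented in `apoeprot`, the
assumptions behind the synthetic cohort generator, and the numerical
choices a user may want to audit.  Nothing here states an empirical result
that the test suite or `scripts/acceptance.py` does not itself compute.

## Carrier contrasts and covariates

Allele effects are estimated as binary carrier contrasts against the
ε3/ε3 reference: ε4 analyses compare ε3/ε4 + ε4/ε4 carriers with ε3/ε3
and exclude every ε2-carrying genotype; ε2 analyses compare ε2/ε2 + ε2/ε3
with ε3/ε3 and exclude every ε4-carrying genotype.  ε2/ε4 heterozygotes
are excluded from both contrasts because they confound the two allele
effects.  For descriptive six-group displays, ε2/ε2 and ε2/ε3 are merged
into one "22/23" group, since ε2 homozygotes are rare (~0.6% of a
Hardy–Weinberg population at ε2 = 0.08).

Default covariates are age, sex (female = 0, male = 1), the per-subject
mean protein abundance, and — when more than one cohort label is present —
cohort indicators treatment-coded against the largest cohort.  The
mean-abundance covariate absorbs global per-sample abundance shifts; on
the PEA platform it is computed only over analytes above the limit of
detection in >90% of subjects, falling back to all retained analytes
(with a warning) when none qualifies.

## Differential abundance

Each analyte is analyzed by ordinary least squares on the z-scored
protein, so coefficients are in protein-SD units (a raw-scale option
exists behind `zscore=False`).  Model type 1 regresses protein on the
carrier contrast plus covariates; type 2 on the disease variable
(clinical diagnosis AD vs CU, with MCI dropped from the binary coding, or
amyloid status) plus covariates; type 3 on both.  Rows enter a fit only
with complete data for the outcome, predictors, and covariates, and the
single-pass >5 SD outlier rule is applied to the outcome immediately
before each fit (analysis-local, never a global matrix edit).  Covariate
columns that are constant within an analysis sample (e.g. sex in a
single-sex stratum) are dropped with a warning; a constant outcome or
constant predictor yields a flagged degenerate record instead of a fit.

Benjamini–Hochberg FDR is applied within each (contrast × model type ×
stratum × term) family — the narrowest family consistent with per-analysis
reporting.  This is a declared choice; the alternative of pooling strata
into one family is stricter and can be had by concatenating tables before
`bh_fdr`.

Stratified analyses reuse the same machinery over subgroup predicates
(all, CU, AD, amyloid-negative/-positive, and median-age halves), with
strata below 30 subjects skipped with a warning.  Group displays use
residuals from a covariate-only regression, compared pairwise by Welch's
t-test with Holm adjustment across the pairs of one analyte.  Concordance
of effect sizes between two analyses (e.g. whole cohort vs CU) is
Spearman rank correlation over shared analytes with a two-sided test.

## Mediation

The estimator is counterfactual g-computation with no exposure–mediator
interaction, chosen so that results are fully reproducible from the two
fitted component models; the quasi-Bayesian approximation used by some
mediation software is deliberately not implemented.

**Upstream (genotype → protein → disease).**  The mediator model is
linear (`P ~ x + Z`, residual SD σ̂) and the outcome model logistic
(`D ~ x + P + Z`).  For each subject and each exposure arm the mediator's
counterfactual distribution is its model prediction plus normal error,
integrated by Monte-Carlo with `mc_draws` shared standard-normal draws
(default 200, sub-seeded).  The four arm means p̄(x′, x) — outcome
exposure x′, mediator arm x — are averaged over subjects, and

    ACME = ½[(p̄(1,1) − p̄(1,0)) + (p̄(0,1) − p̄(0,0))]
    ADE  = ½[(p̄(1,1) − p̄(0,1)) + (p̄(1,0) − p̄(0,0))]
    total = p̄(1,1) − p̄(0,0)

so ACME + ADE = total holds exactly on point estimates.  Effects are on
the risk-difference scale, on which the proportion mediated ACME/total is
scale-coherent.  Because the models carry no interaction, the four arms
are scalar shifts of one linear-predictor grid; the implementation
evaluates that grid once per fit (float32 — the decomposition identity is
exact in the returned float64 means regardless of grid precision).  The
logistic fits inside the bootstrap use a dedicated Newton–Raphson solver
with step-halving and warm starts from the full-sample fit; its agreement
with the statsmodels MLE is pinned by a unit test.

**Downstream (genotype → disease → protein).**  The mediator model is
logistic (`D ~ x + Z`) and the outcome model linear (`P ~ x + D + Z`).
Linearity in the mediator gives the closed form ACME = (risk difference
of disease w.r.t. exposure) × (disease coefficient), in protein-SD units.

**Continuous outcomes.**  With a continuous outcome (e.g. the CSF
Aβ42/40 ratio) both models are linear and the ACME reduces exactly to the
product of the fitted exposure→mediator and mediator→outcome
coefficients.

**Uncertainty.**  Nonparametric subject-resampling percentile bootstrap
(default 1,000 replicates).  The two-sided ACME p-value is the +1
corrected sign-crossing proportion of the bootstrap distribution.  The
proportion mediated is reported as the ratio of point estimates (not the
median of bootstrap ratios); its CI comes from the bootstrap ratio
distribution, suppressed with a `small_total_effect` flag when
|total| < 0.5 × bootstrap SE(total), and sign-inconsistent resamples are
flagged rather than truncated.  Logistic non-convergence in a resample
drops that resample; a record with fewer than max(20, half) surviving
resamples is flagged unstable.  Scale decisions (risk difference;
point-estimate ratio) are declared here, not inferred from any external
convention.

**Gate.**  The screen tests only analytes whose type-1 genotype
association passes FDR < 0.05 (the causal-steps requirement), runs both
directions with per-analyte sub-seeds, and applies BH to the ACME
p-values within each direction.

## Classification

Decision order per analyte: (i) exactly one direction FDR-significant →
that direction's category (upstream → mediator, downstream →
pathology-mediated); (ii) both significant → larger |proportion mediated|
wins, ties to upstream because the genotype is fixed at birth and hence
temporally prior; (iii) genotype-significant only → genotype-specific;
(iv) both associations significant without mediation → nonspecific;
(v) disease-significant only → disease-specific; (vi) otherwise
unassigned.  "Complete mediation" is operationalized as a significant
ACME with an ADE CI covering zero in the dominant direction — a declared
rule, since completeness is otherwise only a typographic convention in
figure labels.

The discriminant check projects analyte feature vectors (e.g. per-subject
residual profiles) onto Fisher axes.  With far more feature dimensions
than labelled analytes the within-class scatter is singular, so features
are first compressed to the leading principal axes explaining 95% of the
labelled variance (capped at n_labelled − n_classes), and the generalized
eigenproblem S_b·w = λ·S_w·w is solved there; a residual singular S_w
falls back to a ridge of 1e-6 × mean diagonal, flagged in the result.
Separation is summarized as trace(WᵀS_bW)/trace(WᵀS_wW).  The two-class
solution is verified against the closed-form Fisher direction and against
scikit-learn's eigen-solver LDA in the test suite.

## Enrichment

For a gene set and a gene × cell-type mean-expression reference, the
statistic is the set's mean expression per cell type.  The null is the
same statistic over `n_perm` (default 10,000) random gene sets of
identical size drawn **without replacement** from the assayed background
— size is the only matching variable, and with/without replacement is a
declared choice.  The one-sided upper-tail p is (#null ≥ observed + 1) /
(n_perm + 1); the +1 correction avoids zero p-values and keeps BH across
cell types well defined.  Backgrounds small enough to enumerate
(`exact_limit`, default 2×10⁵ subsets) can be evaluated exactly, without
the +1 correction.  Multi-analyte genes collapse to one gene
(first-occurrence, logged) before set construction.

## Moderation and Johnson–Neyman intervals

The interaction model is `amyloid ~ x + P + x·P + Z` with the protein
z-scored.  The printed form of such models does not name a link, so both
are implemented: logistic (default) and linear-probability.  Simple
slopes report the conditional genotype effect θ(m) = β_x + β_int·m at
m ∈ {−1, 0, +1} (protein SD units) with Wald CIs.  Johnson–Neyman bounds
solve |θ(m)| = c·SE(θ(m)) — a quadratic in m — using the normal quantile
for the logistic link and the t quantile for the linear-probability link;
the record states whether significance holds inside or outside the
bounds, or everywhere ("all") or nowhere ("none") when the quadratic has
no real roots.  Perfect separation flags the record unstable with no
bounds.

## QC rules and boundary conventions

Analytes with strictly more than 15% missing values are removed, then
(when below-LOD flags exist) analytes above the LOD in fewer than 70% of
subjects, then subjects with strictly more than 15% missing values over
the retained analytes.  The order — analyte filters before the subject
filter, covariate computed last — is a declared choice so the
mean-abundance covariate reflects the final analyte set.  The outlier
rule excludes values whose single-pass z-score exceeds 5 strictly;
exactly 5.0 SD is retained.  Amyloid ratio cutoffs (0.080 Roche, 0.072
Lumipulse, 0.077 MSD) and the 880 pg/ml Aβ42 cutoff all classify
"positive" strictly below the cutoff; the strict convention is applied
uniformly.  Aptamer input is assumed already normalized upstream; only a
log2 transform is applied if flagged linear-scale.  The RNA-seq chain
retains genes with FPKM > 0.1 in ≥85% of samples, renormalizes to TPM
over retained genes (columns sum to 10⁶), applies log2(x+1), then
per-gene z-scores with ddof = 1 (matching R's `scale`).

## The synthetic cohort generator

The generator emulates the statistical structure the analysis assumes —
it is the package's test bed, not a biophysical model.  Generative order:
genotype (six diplotypes, Hardy–Weinberg at ε2 = 0.08, ε3 = 0.78,
ε4 = 0.14) → covariates (age ~ N(70, 8²) clipped to 30–95, sex
Bernoulli(0.47 male), cohort uniform over 3 labels with N(0, 0.15²)
shared shifts) → upstream protein components (allele-carrier effects in
SD units plus covariate loadings and unit noise) → disease (logistic in
the carrier indicators, centered age at 0.05 log-odds/year, and the
planted mediator proteins at their `b` coefficients, with the intercept
calibrated by 1-D root-finding so expected prevalence equals the 0.35
target) → downstream disease shifts `d`.  ε2/ε4 heterozygotes receive
both allele effects.  A binary amyloid status equal to the disease state
and a noisy continuous Aβ42/40-like ratio are emitted alongside the
clinical diagnosis so every outcome variant downstream is exercised.

Per-analyte effects live in `AnalyteSpec`; each truth class constrains
which parameters may be nonzero (a mediator needs a ≠ 0, b ≠ 0, d = 0; a
pathology-mediated protein d ≠ 0 with at most a small a; and so on).  The
default plan is a 400-plex, mostly-null panel: 3 mediators (a = 0.7 SD,
b = 0.3 log-odds/SD), 5 pathology-mediated (d = 1.5 SD), 5
genotype-specific (a = 0.4), 5 disease-specific (d = 0.25), 5 nonspecific
(a = 0.3, d = 0.05), 377 nulls, with direct genotype→disease log-odds of
+0.3 (ε4) and −0.3 (ε2).  These defaults were fixed by design analysis,
for statistical testability rather than biological realism:

* the large null fraction keeps the genotype signal carried by the
  mean-abundance covariate negligible (the covariate averages the panel,
  so the affected fraction — not the panel size — sets the induced bias,
  exactly as on real 7,000-plex platforms where affected proteins are a
  small minority);
* a true upstream mediator also shows a genuine nonzero downstream ACME
  (disease carries protein information backwards through the outcome
  model), and its upstream share falls as the total genotype→disease
  effect grows; the modest direct effect and strong per-mediator `a·b`
  keep the upstream proportion clearly dominant;
* pathology-mediated proteins must clear the causal-steps gate through
  their induced marginal association d × Δrisk, which sets the 1.5 SD
  disease shift — the scale of the most disease-responsive proteins on
  real panels;
* planted "nonspecific" proteins sit at the power boundary by
  construction: in this causal world a protein associated with both
  genotype and disease but mediating in neither direction can only arise
  from limited power, so their disease effect is deliberately
  under-powered and the classifier may legitimately resolve them as
  genotype-specific.

Seed scheme: every stream (genotype, covariates, disease, each analyte,
missingness, oracle draws) derives from the master seed by hashing a name
path, so outputs are bit-reproducible and adding an analyte never
perturbs the others.  Planted missingness is independent Bernoulli per
entry; the LOD is the per-analyte quantile of observed values, recorded
in metadata with values flagged (never deleted — retention is the QC
module's decision).

What the generator does **not** emulate: plate/batch effects, bridging
between platforms, ANML-style normalization internals,
missing-not-at-random censoring, correlated protein modules, or MCI as a
distinct biological state (diagnosis is binary CU/AD).  Passing tests
therefore demonstrate correctness of the estimators under the assumed
causal structure, not robustness to real-platform artifacts.

The truth table's expected upstream proportion comes from a Monte-Carlo
g-computation oracle (10⁵ draws per analyte by default; the acceptance
checks use 10⁶): exposure Bernoulli at the carrier fraction of the
contrast subpopulation, covariate offsets resampled from the realized
disease linear predictor minus the exposure and own-mediated terms, and
the intercept recalibrated to the target prevalence.  The linear-outcome
oracle is the closed form a·b/(a·b + direct), exact to machine precision.

## Problem sizes in the checks

The acceptance checks run at sizes chosen for a single-CPU desk run:
identities on 30–50 fixtures of n = 300; oracle recovery over 20 cohorts
of n = 4,000; bootstrap coverage over 100 cohorts (60 in the script) of
n = 2,000 with 200 resamples and 100 Monte-Carlo draws; classification
recovery over 20 replicate screens (10 in the script) of the default
4,000-subject cohort with 200 resamples and 50 draws; type-I calibration
on 1,000 null analytes at n = 2,000.  Production analyses should keep the
defaults (1,000 bootstrap resamples, 200 draws, 10,000 permutations).

## Known limitations

* Sequential ignorability is assumed, untested, and untestable from the
  data; no sensitivity analysis is provided.
* Single-mediator models only; correlated mediators load each other's
  effects onto the direct path.
* The downstream "reverse-regression" ACME of a true upstream mediator is
  a genuine feature of the bidirectional framework, not a bug; dominance
  classification, not either direction alone, carries the mechanistic
  interpretation.
* The linear-probability moderation link can predict outside [0, 1]; it
  exists for comparability with linear formulations, and the logistic
  link is the default.
* Bootstrap percentile CIs are first-order accurate; no BCa correction.
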