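# Methods

## The model

The unit of analysis is an ordered gene pair.  For expression matrix
`x` (genes × samples) and pair k = (former, latter), the indicator
`I_k(s) = 1{x[former, s] > x[latter, s]}` is a binary covariate; ties
give 0 (the definition only asserts the 1-case for a strict ordering, so
the complement, including equality, is 0).  Survival is modeled by Cox
proportional hazards on these indicators,

    h(t | s) = h0(t) · exp( Σ_k α_k I_k(s) ),

and the fitted linear predictor Σ α_k I_k is the risk score.  Because
every covariate is a within-sample comparison, the whole analysis is
invariant under strictly monotone per-sample transforms of expression;
this is asserted exactly in the test suite, not just claimed.

## Pipeline stages and their parameters

* **Normalization** (`diffexpr.normalize_log2cpm`): counts-per-million per
  sample, then log2(x + pseudocount), pseudocount 1.0.  Normalization only
  matters for the differential-expression stage; the pair indicators are
  unaffected by any per-sample scaling.
* **Differential expression** (`diffexpr.differential_expression`): Welch
  two-sample t per gene, two-sided.  The DEG rule is |log2FC| > 1 and
  p < 0.05, both strict, on raw p-values; a `fdr` flag switches to
  Benjamini–Hochberg.  A negative-binomial count model is deliberately
  not used: the signature consumes only orderings, and the DEG stage is a
  pre-filter whose threshold semantics are what matters.  The run log of
  the pipeline records this choice.
* **Prevalence filter** (`pairs.prevalence_filter`): retain pairs with
  indicator mean in the closed interval [0.2, 0.8].  A pair constant in
  exactly 80% of samples is retained; removal requires *more than* 80%.
* **Split** (`risk.split_cohort`): seeded permutation; the training side
  gets round(n·ratio) samples, so 387 samples at ratio 0.5 give 194/193.
* **Univariate screen** (`survival.univariate_screen`): one
  single-covariate Cox fit per pair, keep Wald p < 0.01 (strict).
* **Penalized fit** (`coxnet`): L1-penalized Breslow partial likelihood,
  minimized as −(1/n)·logPL + λ‖b‖₁ by IRLS with cyclic coordinate
  descent over an active set and full KKT checks.  Covariates are
  standardized internally (zero mean, unit 1/n variance) for the penalty;
  coefficients are reported on the original scale.  λ grid: geometric,
  100 points from λ_max (computed from the null-model score, so the first
  solution is exactly zero) down to λ_max/100.  Warm starts along the
  path.  Tolerances: outer 1e-7 relative objective, inner 1e-9 on
  coefficient updates.  Cross-validation: seeded permutation into
  near-equal folds (10 by default, not event-stratified; a fold holding
  out fewer than 3 events triggers a warning), scored by the
  Verweij–van Houwelingen held-out deviance −2[logPL_all(β₋ₖ) −
  logPL_₋ₖ(β₋ₖ)]; λ is the minimizer (λ_min rule; the more conservative
  one-standard-error rule is available via `rule="1se"`).  The λ_min rule
  keeps small-coefficient proxy pairs along with the true signal — the
  familiar behavior of minimum-deviance selection — which is why fitted
  signatures are usually a superset of the planted pairs.
* **Cox solver** (`survival.cox_fit`): Newton–Raphson with step-halving
  (the partial likelihood never decreases), Efron tie correction by
  default (Breslow by flag; the two coincide exactly without tied event
  times).  Convergence: largest Newton step below 1e-9 or 50 iterations.
  Monotone likelihood is detected by a coefficient reaching ±20; it is
  capped, flagged non-converged, and a warning is issued.  Constant
  covariates get coefficient 0 with infinite standard error.  Hazard
  ratios are exp(coef) with 95% CI exp(coef ± 1.96·se).
* **One-year ROC** (`risk.one_year_roc`): positives are deaths at or
  before the horizon (365 days), negatives are samples followed past the
  horizon regardless of later status, and samples censored before the
  horizon are excluded.  This simple exclusion (rather than
  inverse-probability-of-censoring weighting) biases nothing under
  censoring independent of the score, which is what the generator
  produces; IPCW would be the upgrade for informative censoring.  AUC is
  the Mann–Whitney concordance (ties count 1/2), identical to the
  trapezoid area.  Candidate cutoffs are midpoints between adjacent
  distinct scores plus sentinels, so a perfectly separating score yields
  a cutoff strictly between the groups.
* **Cutoff** (`risk.select_cutoff`): maximizer of Youden's
  J = sensitivity + specificity − 1, ties toward the smaller threshold.
  The training-cohort cutoff is frozen and applied to the test cohort.
* **Stratification**: high risk iff score > cutoff (strict), so the
  placement of boundary samples is reproducible.
* **Independence analysis** (`risk.multivariate_independence`): age enters
  continuously; gender as male=1/female=0; grade, stage, T and N status
  as ordinal ranks (Roman numerals and prefixed forms are parsed).
  Missing covariate values are dropped per-model, never imputed, with
  drop counts reported.  The joint model includes the risk score
  (continuous by default, binary group by flag) and drops constant or
  collinear columns (later columns first) with warnings.
* **Mutation summaries** (`maf`): classification and variant-type counts;
  SNV substitution classes collapsed onto the pyrimidine reference frame
  (G>A counted as C>T); per-sample burden with median and maximum; genes
  ranked by number of mutated samples (maftools' waterfall convention),
  ties alphabetical, with raw mutation counts also reported.  A gene
  mutated twice in one sample counts once for frequency and twice for
  burden.  Which samples constitute the "high-risk group" is an explicit
  input (a sample list), since recomputing it requires the expression
  pipeline.

## The synthetic cohort generator

`simulate` draws cohorts with exactly the structure the analysis assumes:

* Expression: log2 x ~ Normal(μ_g, σ) with μ_g ~ Uniform(3, 10) and
  σ = 1 by default.  Planted differential genes receive a tumor-only mean
  shift of ±2 log2 units.  Both genes of a planted survival pair share a
  baseline mean and the same DE shift, so the pair's indicator is a fair
  coin per sample (prevalence ≈ 0.5, surviving the prevalence filter)
  while both genes still pass the DEG stage.  Log-normal noise was chosen
  over negative-binomial counts because only orderings reach the model;
  a count layer would change nothing downstream while complicating the
  generator.
* Survival: T ~ Exponential(h0 · exp(Σ β_k I_k)) with h0 = 1/1000 per
  day; censoring C ~ Exponential(1/900) truncated at an administrative
  cutoff of 1825 days (five years).  These rates give roughly 40–60%
  censoring, typical of registry follow-up.  Clinical covariates (age,
  gender, grade, stage, T/N) are drawn independently of the hazard, so
  the independence analysis has a built-in negative control; an optional
  `age_effect` adds a log-hazard age slope as a positive control.
* Mutations: per-sample Poisson counts (rate 1 by default) assigned to
  genes by relative propensity, with a C>T-dominant substitution law
  emitted on a random strand, written as standard MAF.
* Defaults (390 tumor / 32 normal samples, 600 genes, 25% immune, 60
  planted DE genes) mirror the cohort scale this class of study uses.
* The truth set records planted effects, realized indicators and the
  exact linear predictor; tests assert the recorded indicators equal a
  recomputation from the emitted matrix bit-for-bit.

What the generator does *not* emulate: batch effects, gene–gene
correlation beyond the planted pairs, realistic marginal expression
distributions, informative censoring, or real mutational signatures.
Passing tests therefore demonstrate correctness of the statistics and
recovery under the stated model, not robustness to those real-data
complications.

## Validation experiments

`validation` packages the experiments used by both the test suite and
`scripts/acceptance.py`, at these problem sizes:

* Planted-pair recovery: 5 disjoint pairs with β = ±1 among 100 candidate
  pairs, n = 500, 10-fold CV, 20 seeded runs; a run succeeds when at
  least 4 of 5 planted pairs are selected with the generating sign.
* Null calibrations: log-rank type-I error over 1000 two-group replicates
  (n = 50 per group); univariate-screen type-I error over 1000 noise
  indicators (n = 200); both should sit at 0.05 ± 0.02.
* One-year AUC: ≈ 0.5 for a score independent of outcome (n = 1000);
  the true-coefficient score on planted cohorts clears 0.75 in ≥ 90% of
  runs.
* Null sparsity: on pure noise (50 candidates, n = 300) the λ_min rule
  keeps ≤ 5 covariates in ≥ 90% of runs.

## Numerical and design notes

* Gene symbols are uppercased at load; pair tokens use `A|B`; the
  coefficient parser accepts both the ASCII hyphen-minus and the Unicode
  minus that appears in published tables (the shipped 17-pair fixture is
  transcribed verbatim, Unicode minus included).
* Each unordered pair is emitted once, oriented by input order; the
  reverse orientation is 1 − indicator except at ties and would only
  duplicate features.
* Tab-separated text with a header row is the one tabular dialect; floats
  are written with `%.10g`, which makes pipeline reruns byte-identical
  under a fixed config and seed.
* The partial-likelihood implementations center the linear predictor
  before exponentiating (the likelihood is invariant to the shift), which
  keeps the risk-set sums finite for extreme coefficients.
* All randomness flows through `numpy.random.default_rng` seeds carried
  in configs or passed explicitly; no global state.

## Known limitations

* The one-year ROC excludes early-censored samples instead of weighting
  them (see above).
* The penalized path supports the pure L1 penalty only — no elastic-net
  mixing, time-varying covariates or stratified baselines.
* The DEG stage's Welch test is a deliberate simplification; results on
  real count data will differ from dispersion-modeling DE tools near the
  significance boundary.
* The immune gene list shipped with the package is a small working subset
  for demonstrations and tests; real analyses should supply a full
  immune-annotation catalogue.
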