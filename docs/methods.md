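# Methods

## Model and procedure

The pipeline estimates a logistic risk model for VTE among combined-oral-
contraceptive users from case-control data. The estimand is the vector of
per-unit (clinical) and per-effect-allele (genotype, additive 0/1/2
coding) log odds ratios. Because stepwise selection on a single data set
both overfits and overstates the effects it picks (winner's curse), the
procedure resamples: R independent replicates each impute missing data,
split the cohort into equal halves, and run stepwise-AIC logistic
selection on the training half; the reported model is the across-replicate
median with unselected runs counted as zero. The test halves supply a
genuinely out-of-sample AUC for every model compared.

Assumptions: additive allele effects on the log-odds scale; independence
of variables in the generator (no linkage disequilibrium); missingness
ignorable given the control-donor hot-deck (the structured masking is by
design a removal of biased values, not of random ones); case-control
sampling, so the intercept is a nuisance (retrospective sampling leaves
all other logistic coefficients identifiable).

## Numerical choices

- **Logistic MLE**: Newton iteration with step halving; convergence when
  the log-likelihood improves by < 1e-8, cap 100 iterations; SEs from the
  inverse observed information. A fit is flagged non-converged — and its
  coefficients never used silently — when the iteration cap is hit, the
  information matrix is singular, or any |β| exceeds 30 (quasi-complete
  separation; a rare allele can separate a half-cohort).
- **AIC**: 2k − 2ℓ with k counting the intercept.
- **Stepwise**: bidirectional from the intercept-only model (forward-only
  and backward-from-full available by flag). All single-variable
  additions, then deletions, are evaluated per iteration; the lowest-AIC
  move is applied iff strictly below the current AIC (tolerance 1e-10),
  so the accepted AIC path is strictly decreasing and termination is
  guaranteed. Ties break deterministically by evaluation order:
  additions before deletions, lexicographic variable-name order within
  each. Non-converged moves are skipped and counted. Force-included
  variables start in the model and are never deletion candidates.
- **Aggregation**: per-variable median coefficient over all replicates
  (zero when unselected), median SE over selected-only replicates, Wald
  z = median β / median SE with normal two-sided p, Benjamini–Hochberg
  q over all candidates with a defined p, 95% CI = exp(β ± 1.96·SE). The
  intercept is the median over all replicates so the final model can emit
  probabilities, not just scores.
- **Splits**: uniform unstratified halves (stratified available by flag,
  off by default); odd n gives the training half the extra sample.
- **Hot-deck**: donors are all non-missing control values of the variable,
  drawn with replacement; imputation precedes splitting, which leaks a
  small amount of donor information between halves — the most literal
  reading of the protocol. A strict mode (donor pool = training-half
  controls, split first) is available; the default is the literal one.
- **Seed schedule**: replicate i uses a fresh generator seeded
  (master ⊕ i) & 0x7FFFFFFF, consumed by impute-then-split; any two
  pipeline runs on the same cohort with the same master seed therefore
  share identical replicate data, making model comparisons paired and
  every run byte-reproducible. Truncating R only truncates the replicate
  list.
- **AUC**: Mann–Whitney rank form with 0.5 tie credit; CI is the
  2.5/97.5 percentile of the per-replicate AUC distribution — the only
  construction the resampling design itself supports. ROC curves are
  rendered both pooled (all test scores together) and split-averaged
  (mean TPR on an FPR grid); the two differ slightly and are labelled.
- **Fisher AF filter**: two-sided exact test (sum of table probabilities
  ≤ the observed) on cohort-control vs reference allele counts; a variant
  is kept iff p strictly exceeds alpha (default 0.01). Variants with no
  reference entry pass with a logged warning.
- **Wilcoxon rank-sum**: exact enumeration when both groups have ≤ 25
  observations and the pooled data are tie-free, otherwise the normal
  approximation with tie and continuity corrections; a degenerate pooled
  sample (a single distinct value) reports p = 1.

## Synthetic cohorts

The generator emulates the study design the pipeline targets: 794 cases /
828 controls; nine effect SNPs at control effect-allele frequencies
0.01–0.51 with per-allele ORs 0.60–6.46; four clinical factors — age
(truncated normal, mean 31.5, SD 9.0, range 18–51 years, OR 1.01/year),
BMI (mean 23, SD 4.2, range 17.5–33.5 kg/m², OR 1.07/unit), smoking
(prevalence 25%, OR 1.63), family history (prevalence 15%, OR 2.13) —
plus configurable null decoy SNPs (default 30, frequencies uniform on
[0.05, 0.5]) standing in for the remainder of a 46-SNP candidate panel,
and two null SNPs (rs2066865, rs2036914) so published comparison scores
resolve. Genotypes are two Bernoulli allele draws (HWE); continuous
covariates are redrawn until inside their truncation brackets; disease is
Bernoulli on logistic(β₀ + Σβx). Individuals are simulated in batches
(grown adaptively so case accrual stays cheap) and accepted by status
until both strata fill; the default β₀ = −9.0 puts the population
prevalence near 0.3% — the rare-disease regime of VTE among
contraceptive users — where the marginal case allele-frequency enrichment
approaches exp(log-OR) and the generated case frequencies reproduce the
reported ones (≈0.11 vs 0.015 for the F5-Leiden-like variant, printed
0.09 vs 0.02). Structured missingness reproduces the design's
ascertainment correction — family history and the two thrombophilia
genotypes masked in the first 523 controls — plus a 2% missing-completely-
at-random rate for sporadic genotyping failure. Family history is an
independent Bernoulli risk factor, not derived from relatives' genotypes.

What the generator does **not** emulate: linkage disequilibrium between
SNPs, the control ascertainment bias itself (only its masking-based
neutralisation), covariate correlations (e.g. BMI–age), proxy-SNP
substitution, and genotyping error. Passing tests therefore demonstrate
the pipeline's correctness and calibration under the stated generative
model, not the field behaviour of any fitted score on real populations.

## Problem sizes in tests and the acceptance script

The default replicate count is 10 000; simulation-based tests run at
40–1000 replicates and the acceptance script at 1000 (selection
stability, full 30-decoy panel) and 500 (parameter recovery,
13-variable panel), sizes at which the monitored quantities' Monte-Carlo
error is far below their tolerances. Recovery tolerances are two
cohort-level standard errors (back-derived from the reported Wald
intervals), since a single 794/828 cohort draw — not the replicate
count — dominates the estimator's dispersion.

## Known limitations

- Hot-deck-before-split leaks donor information across halves (default
  literal mode); the strict mode (training-half donors only) exists for
  sensitivity analysis.
- The median-with-zeros aggregate is not a maximum-likelihood estimate;
  its Wald inference (median SE) is approximate and slightly
  conservative for variables selected in nearly all runs, optimistic for
  rarely selected ones — mitigated by reporting selection frequencies and
  BH q-values alongside.
- Coefficients of masked-and-imputed variables (the two thrombophilia
  SNPs, family history) are attenuated toward the control distribution by
  construction; their ensemble ORs under-shoot generating values, as the
  worked example shows.
- No interaction search: a post-hoc pairwise Wald screen
  (`interaction_screen`) is provided as a diagnostic only.
- No penalised-regression alternative, no PLINK formats, no calibration
  or clinical-threshold analysis.
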