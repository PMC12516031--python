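# Methods

This note documents the statistical model, the synthetic-data generator, the
numerical choices and the known limitations of `huimin_hcm`.

## The hybrid choice model

The package implements an integrated choice and latent-variable (ICLV) model
for a discrete choice experiment on complementary inclusive health
insurance. Three components are estimated **jointly**:

1. **Structural model.** Three latent constructs — health-risk perception
   (HR), scheme awareness (AW), perceived scheme value (VAL) — are recursive
   linear functions of six observed covariates *z* (female gender, two upper
   age bands, urban residence, catastrophic-disease experience in the
   household, prior private-insurance purchase) and of the upstream
   constructs, with independent standard-normal disturbances. The recursion
   order HR → AW → VAL encodes the sequential theory of insurance choice:
   one first perceives risk, then becomes aware of a product, then values
   it. Identification: disturbance variances fixed at 1, no structural or
   measurement intercepts (the thresholds absorb location), loadings free.

2. **Measurement model.** Eleven five-point Likert indicators (5 for HR, 3
   for AW, 3 for VAL) follow ordered logits with loadings ζᵢ and four
   strictly increasing thresholds τᵢ each. An ordered logit, rather than a
   continuous-linear measurement equation, is the natural likelihood for
   bounded 5-category responses; this was a genuinely open design choice and
   is documented as such. Missing indicator responses contribute nothing to
   the measurement product (within-indicator deletion).

3. **Choice model.** Panel mixed logit over six experimental tasks of three
   alternatives (two insurance packages + opt-out). Attribute coding:
   premium in RMB/year (levels 130/170/210), deductible in units of
   10 000 RMB (12/15/18), reimbursement rate in percentage points
   (50/65/80), dummy coding for government involvement (reference: purely
   commercial) and value-added services (reference: basic). The coding was
   inferred from the magnitude scale of the reported coefficients (e.g.
   premium ≈ −0.007 per RMB) since units are not stated explicitly in the
   source tables. Seven attribute levels carry normal random coefficients
   (all but the moderate-involvement dummy, whose taste variation is
   negligible); draws are respondent-level, shared across that respondent's
   tasks, independent across coefficients. Interactions shift the **mean**
   of a coefficient, never its SD, matching the separate SD and interaction
   columns of the reporting layout; the candidate set is 7 random attribute
   levels × 9 variables (3 latents + 6 covariates) = 63 terms. The opt-out
   has an alternative-specific constant δ and latent shifts φ.

The simulated likelihood per respondent is
L = (1/R) Σᵣ Πₜ P(choiceₜ | draw r) · Πᵢ P(Iᵢ | draw r); the objective is
Σₙ ln Lₙ. The quality-control task never enters the likelihood — it is used
only for the attentiveness filter.

## Experimental design

The design engine minimizes the MNL D-error det(I(β))^(−1/K) over 24 paired
choice sets via coordinate exchange: balanced random start, sweeps over
set × alternative × attribute accepting strict improvements, 20 restarts by
default, deterministic under a fixed seed. The opt-out enters the
information matrix as a third alternative whose utility is a fixed ASC prior
(default 0), mirroring the estimation model. Strictly dominated pairs
(under the hypothesized signs: premium −, deductible −, reimbursement +,
non-reference dummies +, value-added expansions mutually incomparable,
moderate ≤ strong involvement only weakly ordered) are never admitted —
they carry no trade-off information. Exchange moves that would leave any
attribute level in fewer distinct sets than there are blocks are rejected,
which keeps per-block level coverage feasible; blocking then proceeds
greedily on squared deviation from perfect level balance followed by a
penalty-driven pairwise-swap search, and raises with the offending block if
coverage cannot be achieved. The QC set pairs the best level of every
attribute against the worst (taking Expanded 1 as the dominant value-added
level) and is excluded from the D-error.

## Synthetic-data generator

No public microdata exist for this survey (available only on request), so
the generator *is* the study population for every downstream test. Its
defaults are the study's observed conditions:

* covariate proportions: female 0.514, urban 0.707, age bands
  0.210/0.510/0.281 (18–34 reference), college+ 0.204, above-average income
  0.306, private insurance 0.467, catastrophic experience 0.1699.
  Education and income are sampled but excluded from the structural and
  choice models, matching the reported specification. The two covariates
  are retained in descriptives only.
* structural, measurement-loading and choice parameters: the published
  point estimates (`default_true_params()`), including the 21 reported
  significant interaction terms; unreported interactions are zero.
* thresholds τ = (−2, −0.5, 0.5, 2) for every indicator — a documented
  default, not a published value (the published tables print loadings but
  not thresholds). The resulting Likert marginals are realistic (mode at
  the agreeing categories for high-loading indicators) but are not claimed
  to match the study's.
* sample: 1203 completers, 6 experimental tasks (one block of the design)
  plus one QC task each; exactly round(67/1203 · n) respondents are
  programmed to pick the dominated QC alternative, all others the dominant
  one. Opting out of the QC task is allowed and retains the respondent —
  the filter excludes only dominated-choosers, by a literal reading of the
  exclusion rule.

What the generator does **not** emulate: quota-sampling mechanics, item
nonresponse, straight-lining and other satisficing behaviors beyond the
binary attentiveness mechanism, city-level stratification. Passing tests
therefore certify the estimator against its own assumed data-generating
process, not against field-data pathologies.

The study's descriptive prose and its variable-coding table disagree on
gender (the prose counts 584 respondents (51%) as men; the coding table
codes those 584 as female, 51.4%). The generator follows the coding table
(1 = female, 0.514).
Similarly, age-band boundaries differ between sections (20/40/60 cuts vs
18–34/35–59/60–75); the package uses three ordered bands with the youngest
as reference and parameterizes the labels.

## Estimation numerics

* **Draws:** scrambled Halton (scipy's qmc engine, leading zero point
  skipped, inverse-normal transform), one joint block of
  3 + 7 dimensions per respondent; MLHS and pseudo-random are available.
  Default R = 500 per respondent.
* **Gradients:** fully analytic for all parameter blocks (choice, SDs,
  interactions, structural, loadings, thresholds), verified against central
  finite differences to 1e-4 relative in the test suite. Scores are
  available per respondent for the sandwich estimator.
* **σ sign:** the likelihood uses |σ|, so it is exactly invariant to sign
  flips at finite draws and SDs are reported as absolute values by
  construction.
* **Thresholds:** optimized as (τ₁, log-increments), guaranteeing strict
  monotonicity; reported on the τ scale.
* **Scaling:** internally, coded columns are rescaled to O(1) magnitude
  (premium in hundreds of RMB etc.) and the parameter vector inversely, so
  L-BFGS sees a well-conditioned problem; results are mapped back exactly.
* **Optimizer:** L-BFGS-B (memory 25), analytic jacobian, objective = mean
  log-likelihood per respondent, gradient tolerance 1e-6 (sup-norm, scaled
  space), max 1000 iterations. Starting values: plain-MNL fit for the fixed
  choice coefficients, 0.1 for SDs and latent effects, 0 for structural
  weights and interactions, loadings 1, thresholds logit-quantile-matched to
  the pooled indicator frequencies. The `converged` flag reports the
  gradient criterion honestly; simulated likelihoods often terminate on
  line-search stagnation slightly above it, with parameter movement far
  below estimation noise.
* **Standard errors:** classical from a finite-difference Hessian of the
  analytic gradient; robust sandwich H⁻¹BH⁻¹ with B the outer product of
  per-respondent scores; a cheap BHHH option (B⁻¹) is available and is what
  the recovery tests use. P-values are two-sided normal on
  estimate/robust-SE with stars at 1/5/10%.
* **Degenerate cases:** with all SDs and latent effects zero the simulated
  likelihood equals the closed-form conditional logit exactly (tested to
  1e-10); a one-dimensional random coefficient agrees with Gauss–Hermite
  quadrature to 1e-3 at R = 1e5.
* **WTP:** −bₖ/b_premium in RMB/year with delta-method SEs from the robust
  covariance; the ratio is refused when |b_premium| < 1e-6.

## Scale diagnostics

Cronbach's α uses the sample-covariance formula k/(k−1)(1 − Σvarᵢ/var_total).
Composite reliability and AVE operate on standardized loadings; loadings
estimated on the ordered-logit scale are standardized as
λ = ζ/√(ζ² + π²/3), the logistic measurement-error variance. Percentages in
the descriptive table are rounded half-up at 1 decimal (2 for the rarest
binary field).

## Problem sizes in the shipped tests

The full-scale recovery harness simulates n = 1000 respondents, 6 tasks,
R = 500 draws, three Monte-Carlo replicates, and requires every choice-model
mean to fall within three (BHHH) standard errors of truth; its optimizer cap
is 150 iterations, at which the well-identified choice block has converged
while the measurement block is still drifting at a scale far below its
standard errors. Supporting tests run at reduced sizes (a few hundred
respondents, 100–200 draws) chosen to keep the whole suite in the tens of
minutes on a single core; the acceptance script fits the 1136 retained
respondents with R = 300.

## Known limitations

* Random coefficients are independent normals; correlated or log-normal
  tastes and WTP-space estimation are out of scope.
* The supplementary material specifying the original study's exact
  measurement likelihood and threshold identification is not public; the
  ordered-logit ICLV here is a documented reconstruction, and simulated
  indicator levels depend on the default thresholds.
* The D-efficient optimizer is a local (multi-start) search; it matches
  exhaustive enumeration on toy problems but global optimality at the full
  design size is not guaranteed (nor is it for any practical design tool).
* BHHH standard errors coincide with the sandwich only under correct
  specification; the full sandwich is available where that matters.
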