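# Methods

## The measurement model

`latclass` measures a behavior that is hard to observe directly — here,
whether a person consistently uses a latrine for defecation — as a latent
class inferred from polytomous psychosocial survey indicators. The model is
a finite mixture of independent multinomials: individual *i* belongs to one
of *K* unobserved classes with prevalence π<sub>k</sub>, and given class
membership answers item *j* with category *c* with probability
ρ<sub>jkc</sub>, independently across items ("local independence"). The
observed-data likelihood is

    L = prod_i sum_k pi_k prod_{j in obs(i)} rho[j, k, y_ij]

where obs(*i*) skips items the person did not answer — full-information
maximum likelihood under a missing-at-random assumption. "Don't know" is a
substantive third response category, never missingness; a separate sentinel
(`-1` / empty cell) encodes true item nonresponse.

Estimation is EM with random restarts (default 50; Dirichlet(1) draws for
each ρ row, uniform-on-the-simplex π; absolute log-likelihood tolerance
1e-8; iteration cap 5000). Identical response patterns are collapsed to
weighted patterns before iterating, so fits at N in the tens of thousands
cost the same as fits at a few hundred distinct patterns. ρ is floored at
1e-10 inside E-step logarithms only; reported estimates may sit exactly on
the boundary. Classes are relabeled by descending prevalence, so "class 1"
is always the largest (here: consistent latrine use).

Posterior class memberships follow Bayes' rule,
τ<sub>ik</sub> ∝ π<sub>k</sub> Π ρ, with an all-missing response vector
returning the prevalence vector itself.

### Fit statistics

* **BIC** = −2ℓ + p·ln N with p = (K−1) + K·Σ<sub>j</sub>(C<sub>j</sub>−1).
* **Relative entropy** E = 1 − Σ<sub>ik</sub>(−τ<sub>ik</sub> ln τ<sub>ik</sub>)/(N ln K),
  1 for perfect assignment, 0 for uninformative posteriors, defined as 1
  when K=1.
* **Pearson X²** over distinct fully observed response patterns plus one
  aggregate cell holding the expected mass of unobserved patterns. With
  3^J possible patterns the asymptotic chi-square reference is meaningless
  at survey scale (observed statistics in such analyses reach 10^13), so
  the p-value comes from a parametric bootstrap: simulate from the fitted
  model, refit, recompute X² (default 200 replicates). Individuals with
  missing items are excluded from the X² table but still contribute to
  estimation.

### Standard errors

Default is observed information: the Hessian of the observed-data
log-likelihood in multinomial-logit coordinates (central differences of the
analytic score), inverted and delta-methoded back to probabilities. A
household-clustered sandwich (score sums per household, G/(G−1)
small-sample factor) is available as `method="sandwich"`; with singleton
clusters it degenerates to the ordinary robust sandwich. Cells estimated on
the boundary (ρ̂ ∈ {0,1}) are excluded from the free parameterization and
reported with SE 0 and a boundary flag, matching the "1.00 (0.00)"
convention of published tables.

## Model selection and pruning

`compare_class_solutions` fits each candidate K and prefers the lowest BIC,
subject to two guards: any solution containing a class with expected count
below `min_class_n` (default 10) is rejected outright — a class of three
people cannot be carried into a multivariable model — and solutions with
relative entropy below 0.80 are flagged. BIC near-ties (ΔBIC < 2) go to
the smaller K. The bootstrap GOF p-value is reported but does not gate the
decision by default.

`prune_uninformative` implements the CI-overlap rule for K=2: per indicator
and response category, Wald 95% intervals ρ̂ ± 1.96·SE (truncated to
[0,1]) are compared across the two classes; the indicator is retained iff
at least one category's intervals are disjoint. Boundary cells need care:
their Wald SE is 0, and a zero-width interval at ρ̂ = 0 — typically a rare
category with zero observed count in the smaller class — would count as
"disjoint" from any narrow interval excluding zero, spuriously retaining
indicators that carry no class information. Boundary cells therefore get a
one-sided rule-of-three width (3 / expected class count) on their open
side, the standard interval for a zero count; a boundary estimate of 1.00
remains decisively separable from anything bounded away from 1, so the
strongest indicators stay decidable. Two caveats this rule inherits from
the published values themselves: the household-sharing indicator's printed
conditionals (0.52 ± 0.03 vs 0.70 ± 0.07) overlap in every category, so at
study scale the rule drops it more often than not, and the
neighbor's-latrine gap sits just above the disjointness threshold, so
sampling variability at N = 251 removes it in a sizable minority of
replicates. Verdicts are computed in a single
pass over one full-indicator fit, followed by exactly one refit on the
retained set; the procedure is order-independent by construction, not
backward elimination.

`polychoric_correlation` is the classical two-step estimator (thresholds
from inverse-normal cumulative marginals, then the bivariate-normal cell
likelihood maximized over the correlation), used as a screening diagnostic
for indicator pairs.

## Pseudo-class imputation and pooled regression

Modal class assignment understates uncertainty. Instead, M (default 5)
class labels per person are drawn from their posterior by inverse-CDF
sampling of independent uniforms. Each draw defines a binary outcome
(membership in the consistent-use class), regressed on basic sanitation
access (private improved facility vs anything less) by maximum-likelihood
logistic regression with a household-clustered sandwich covariance
(G/(G−1) factor). The adjusted model adds education (3 dummies against
less-than-primary), Afro-Ecuadorian ethnicity, female sex, cement walls and
non-asset-deprivation, with missing covariate codes handled complete-case
per regression (dropped-row counts are recorded). The M coefficient vectors
are combined by Rubin's rules: pooled mean Q̄, within-variance W̄,
between-variance B, total T = W̄ + (1+1/M)B, Barnard–Rubin degrees of
freedom, and t-based 95% CIs on the log-odds scale exponentiated to odds
ratios.

## The synthetic-data generator

No individual-level data were deposited with the reference analysis, so the
generator rebuilds its data-generating process from the published summary
tables: 2-class weights (0.78, 0.22), the printed modal class-conditional
probability of each of the five final indicators, and every indicator's
3-category marginal. The remaining conditional cells are completed from the
mixture constraint marginal = Σ<sub>k</sub> π<sub>k</sub> ρ<sub>k</sub>:

* a category in which exactly one class is unknown is solved directly from
  its mixture equation;
* when both printed conditionals sit in the same category the system is
  rank-deficient by one, and each class's leftover probability mass is
  allocated across the unresolved categories in proportion to their
  observed marginals (the two classes share the composition of categories
  the printed table does not distinguish — the least-assumptive completion);
* negative cells produced by printed rounding are clipped at 0 and the free
  cells rescaled so rows sum to one with printed entries preserved exactly;
  a printed boundary value (1.00) therefore forces the rest of its row to
  zero. Clipped mass and implied-marginal residuals above 0.03 raise an
  error; realized residuals are ≤ 0.002 except the boundary-clipped
  indicator (0.013).

Surveys are drawn around this measurement core: household sizes are
zero-truncated Poisson calibrated to 251/98 ≈ 2.56 members; sanitation,
wall material and asset deprivation are household-level draws from the
published covariate marginals, sex/ethnicity/education/payment individual-
level; age is 13 + an exponential calibrated to the published median 23 and
SD 14. Latent class follows a logistic model with a household-level normal
random intercept (SD = `concordance`, default 0.3 — clustering the original
analysis corrected for implies nonzero within-household concordance, but no
value was published; 0.3 gives mild clustering) and an optional exposure
effect on the class-1 log-odds (`exposure_effect`, default 0, matching the
published null). Item nonresponse is injected MCAR at `missing_rate`
(default 0: the published item Ns are all 251). The 11 pruned indicators
can be added as class-independent noise at their observed marginals — their
true conditionals were never printed.

What the generator does **not** emulate: violations of local independence,
differential item functioning by sex or ethnicity, informative missingness,
and any true covariate–class association beyond the configured exposure
effect. Passing recovery tests therefore demonstrates correctness of the
estimator under the model's own assumptions, not robustness to their
failure on real data.

### A known limitation: entropy of the reconstructed model

The reconstruction reproduces the printed prevalences and conditionals
almost exactly, yet its population relative entropy is 0.947 (exact
enumeration of all 3^5 response patterns), and K=2 fits to N=251 replicates
average ≈ 0.95 — above the 0.86 published for the real data. The printed
boundary conditional (class-1 "agree" of 1.00 on the rainy-season-neighbors
item) classifies any non-agree respondent with certainty; without that item
the population entropy drops to 0.66. A model with the printed parameters
and local independence is thus necessarily more separated than the real
data were, which indicates the real responses were positively correlated
within class (or the 1.00 is a rounded 0.99x). The generator deliberately
keeps the printed values rather than retuning them.

## Problem sizes used in the shipped checks

Recovery of prevalence and conditionals uses one simulated sample of
N = 25,100 (100× the study) with 50 EM restarts; entropy reproduction uses
100 replicates at the study's own N = 251; pruning operating
characteristics use 100 replicates of the 16-indicator design at N = 251;
null-coverage of the pooled exposure CI uses 200 simulated studies of 98
households with M = 5 imputations. Grid-search verification of EM uses
2-item binary instances with N = 12, where a dense hierarchical grid over
(π₁, ρ) down to step 0.01 is tractable and the check is one-sided (EM must
reach the grid maximum within 1e-3).

## Numerical choices

* EM convergence on absolute log-likelihood change (1e-8); monotonicity is
  asserted in tests at every iteration.
* Posterior rows are validated to sum to 1 within 1e-8 before entropy or
  pseudo-class draws.
* Pseudo-class modal labels break ties toward the lower label and set a
  tie flag (impossible for K=2 with odd M).
* Logistic separation is detected both from optimizer warnings and from
  coefficients exceeding ±15 on the logit scale, and raises a dedicated
  error rather than returning an untrustworthy fit.
* Degenerate inputs: K=1 fits are closed-form (observed proportions,
  entropy 1); empty generated datasets are legal; K exceeding the number
  of distinct response patterns warns (or errors in strict mode).
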