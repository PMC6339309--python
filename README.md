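# latclass

Latent-class measurement of sensitive or hard-to-observe behaviors from
polytomous psychosocial survey indicators, with the uncertainty of latent
assignment carried into downstream regression by pseudo-class multiple
imputation.

The package was built around a concrete use case from environmental health
epidemiology: measuring **consistent latrine use for defecation** — a
behavior that self-report misclassifies badly — in a rural Ecuadorian
study population (251 people aged ≥13 in 98 households), using 16
agree/disagree/don't-know survey indicators of social norms, convenience,
safety and latrine condition, and then asking whether household access to
*basic sanitation* (a private improved facility) predicts membership in
the consistent-use class. Everything is general, though: any survey with
categorical indicators, cluster structure and a binary structural exposure
fits the same pipeline.

## The model

Individuals belong to one of *K* unobserved classes with prevalences
π = (π₁, …, π_K); given class *k*, indicator *j* takes category *c* with
probability ρ_{jkc}, independently across indicators. With missing items
handled by full-information maximum likelihood,

  L = ∏ᵢ Σₖ πₖ ∏_{j ∈ obs(i)} ρ_{j,k,y_{ij}}.

Fitting is EM with random restarts; the results object carries π, ρ, the
posterior memberships τ, observed-information or household-clustered
sandwich standard errors, BIC, a parametric-bootstrap Pearson X², and the
relative entropy E = 1 − Σ(−τ ln τ)/(N ln K). Model workflow:

1. `compare_class_solutions` — choose K by BIC with interpretability
   guards (no class thinner than 10 expected people, entropy ≥ 0.80);
2. `prune_uninformative` — drop indicators whose class-conditional
   response CIs overlap between classes; refit on the survivors;
3. `run_structural_pipeline` — draw M pseudo-class memberships per person
   from their posterior, fit M cluster-robust logistic regressions of
   membership on sanitation access (± covariates), and pool by Rubin's
   rules.

A known-truth synthetic-data generator reproduces the study's structure —
class weights (0.78, 0.22), the five published indicator conditionals
completed from mixture constraints, covariate marginals, household
clustering — so every stage is testable against ground truth. See
`docs/methods.md` for the full account.

## Worked example

```python
import latclass as lc

model = lc.reference_model()                       # reconstructed 2-class truth
ds, labels = lc.generate_survey(model, n_households=98, seed=1)
fit = lc.LatentClassModel.from_dataset(ds, 2).fit(n_starts=50, seed=2)
print(fit.summary())
```

```
Latent class measurement model
================================================================
N = 244   classes = 2   items = 5
logLik = -660.623   params = 21   BIC = 1436.69
relative entropy = 0.949   converged = True

Class weights (pi):
  class 1: 0.814 (0.034)
  class 2: 0.186 (0.034)

Item-response probabilities rho (rows: categories):
  men_dry
    agree      0.83 (0.03)  0.06 (0.04)
    disagree   0.10 (0.02)  0.40 (0.07)
    dont_know  0.07 (0.02)  0.55 (0.08)
  ...
```

Class 1 (81% of this synthetic sample; the generator's truth is 78%) is
the *consistent latrine use* profile — its members overwhelmingly agree
that men, neighbors and children in the village use latrines and that they
would use a neighbor's latrine; class 2 concentrates the don't-know and
disagree responses. The 2-decimal "estimate (SE)" layout mirrors the
published tables; `0.00 (0.00)` marks a boundary estimate.

```python
out = lc.run_structural_pipeline(fit, ds, n_imputations=5, seed=3)
print(out["adjusted"].pooled.summary())
```

```
Rubin-pooled logistic regression (M = 5)
========================================================================
term                      coef      se     OR    2.5%   97.5%       df
const                    1.979   0.659   7.24    1.98   26.53    217.6
basic_sanitation        -0.206   0.342   0.81    0.41    1.61     93.6
...
```

The exposure OR of 0.81 with 95% CI (0.41, 1.61) covers 1: in this
synthetic study — generated with a zero class–exposure effect, the null
structure the original analysis reported — owning a basic sanitation
facility shows no association with consistent latrine use once the
classification uncertainty is propagated through the five imputations.

A command-line interface wraps the same stages
(`latclass simulate | fit | select | prune | impute | regress | run-all |
report`), driven by a YAML config with mandatory explicit seeds.

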