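# bcnkit

Bayesian causal network (BCN) analysis for longitudinal cohort tables:
score-based, constraint-based and hybrid structure learning over Gaussian
data, bootstrap aggregation of learned networks into arc
strength/direction coefficients, and direction-restricted model
comparison — the workflow used in developmental neuroimaging studies that
ask *which way* an association points (for example, whether adolescent
cannabis use drives accelerated dorsal prefrontal cortical (DPFC)
thinning or the reverse), when only observational cohort data exist.

It is written for analysts of cohort studies (imaging + substance-use +
demographic batteries) who would otherwise reach for an R workflow: the
same algorithm families are exposed as scikit-learn-style estimators plus
a small CLI, and a linear-Gaussian SEM simulator generates realistic
synthetic cohorts so every stage is testable without access-restricted
study data.

## The method

A Bayesian network over variables X₁…X_p is a DAG G in which each node is
a linear-Gaussian function of its parents.  Structure is learned by
maximizing the penalized network fit

    score(G) = Σ_v [ ℓ̂(X_v | Pa_G(v)) − pen(k_v, n) ]

with ℓ̂ the maximized Gaussian log-likelihood, k_v = |Pa(v)| + 2, and
pen = (k/2)·ln n (BIC) or k (AIC); or by conditional-independence tests on
partial correlations (Gaussian mutual information G = −n·ln(1 − r²),
Fisher's z = √(n − |z| − 3)·atanh(r), or the exact Pearson t).  Six
learners are provided: hill climbing and tabu search (score-based),
Grow-Shrink and IAMB (constraint-based, returning partially directed
graphs), MMHC and RSMAX2 (hybrid restrict–maximize).  All accept an arc
blacklist built from temporal logic (nothing may cause an exogenous
trait such as a polygenic risk score; a change score may not cause a
baseline measure).

Learned structures are aggregated over B nonparametric bootstrap
resamples into, per variable pair,

* **strength** S = fraction of the B networks containing the edge in
  either orientation, and
* **direction** D(x→y) = fraction of those networks orienting it x→y
  (so D(x→y) + D(y→x) = 1),

with edges of strength under a reporting threshold (default 90%) removed
from the rendered summary graph.  A complementary top-down check fits the
network twice with one focal orientation blacklisted at a time and
reports ΔBIC between the two restricted models.

## Worked example

```python
from bcnkit import (default_ground_truth, simulate, prepare_cohort,
                    default_roles, build_blacklist, bootstrap_learn,
                    strength_direction, threshold_network,
                    directional_bic_comparison, LearnerConfig)

model = default_ground_truth()            # 17-variable SEM, focal beta = -0.2
cohort = simulate(model, n=637, seed=11)  # raw table + site/sex covariates
table, diagnostics = prepare_cohort(cohort)

roles = default_roles()
constraints = build_blacklist(roles)      # temporal-logic blacklist
ensemble = bootstrap_learn(table, LearnerConfig(algorithm="hc", score="bic"),
                           constraints, B=500, seed=7)
averaged = strength_direction(ensemble)
s = averaged.strength("cannabis_change", "dpfc_change")
d = averaged.direction("cannabis_change", "dpfc_change")
print(f"focal arc strength S = {100*s:.1f}%, direction D = {100*d:.1f}%")

comparison = directional_bic_comparison(table, roles.focal_pair, roles)
print(f"delta-BIC = {comparison.delta_bic:.2f}")
```

Output:

```
focal arc strength S = 92.6%, direction D = 96.1%
delta-BIC = 4.49
```

The hemispheric thickness composites come out with first-PC eigenvalue
≈ 1.78 (≈ 89% variance explained), reflecting the generator's
inter-hemisphere correlation of 0.8; the planted cannabis → ΔDPFC arc is
recovered with high strength, oriented toward the thickness change in
96% of bootstrapped networks, and the direction-restricted comparison
favours the same orientation (ΔBIC > 0).  These are statements of
directional dependence under the model's assumptions, not experimental
proof of causation.

The same pipeline is scriptable from the shell:

```bash
bcnkit simulate --n 637 --seed 11 --out cohort.csv
bcnkit preprocess --data cohort.csv --out analysis.csv
bcnkit blacklist --out blacklist.csv
bcnkit bootstrap --data analysis.csv -B 10000 --blacklist blacklist.csv \
    --seed 7 --out edges.tsv
bcnkit compare-direction --data analysis.csv \
    --from cannabis_change --to dpfc_change --blacklist blacklist.csv
```

## Documentation

`docs/methods.md` describes the model, the synthetic-cohort generator and
its limits, numerical conventions (score penalties, tie-breaking,
thresholding boundary rules) and known limitations.
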