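# Methods

## Model

All analysis variables are treated as jointly Gaussian.  A network
structure is a DAG G over the variable names; its likelihood factorizes
into per-node linear regressions on the node's parents.  The penalized
network score is decomposable,

    score(G) = Σ_v  ℓ̂(X_v | Pa(v)) − pen(k_v, n),
    ℓ̂ = −n/2 · (ln(2π σ̂²_v) + 1),

where σ̂²_v is the maximum-likelihood (1/n) residual variance and
k_v = |Pa(v)| + 2 counts intercept, slopes and residual variance.
pen = (k/2)·ln n for BIC, k for AIC, on a higher-is-better scale.  The
1/n variance estimator is deliberate: it makes the score *exactly* equal
across Markov-equivalent DAGs, which the searches, the equivalence-class
tests and the ΔBIC comparison all rely on.  Any constant-offset
convention would leave all comparisons invariant, so only differences of
scores are meaningful.

Conditional-independence tests are functions of the sample partial
correlation r(x, y | z), computed from the covariance matrix by Schur
complement (algebraically identical to correlating OLS residuals; the
test suite checks both identities to 1e-10):

* Gaussian mutual information: G = −n·ln(1 − r²) ~ χ²(1);
* Fisher's z: √(n − |z| − 3)·atanh(r) ~ N(0, 1), two-sided;
* Pearson: t = r·√((n − |z| − 2)/(1 − r²)) ~ t(n − |z| − 2), two-sided.

Two-sided p-values throughout; the default α = 0.05 for all
constraint-based learners is a documented, configurable convention and is
recorded in every run report.

## Learners

* **Hill climbing** — greedy add/delete/reverse single-arc moves.
  Score-equivalent moves tie only to floating-point precision, so deltas
  within 1e-6 are treated as exact ties and the lexicographically first
  (parent, child) move wins; this keeps searches deterministic across
  platforms and stops orientation flapping.  The restart policy
  alternates between perturbing the incumbent (``perturbations`` random
  legal moves) and a fresh sparse random start (each admissible arc
  included with probability 2/(V−1) under a random topological order):
  perturbation alone rarely escapes deep spurious optima, random starts
  alone rarely refine the incumbent, and the alternation reached the
  exhaustive-enumeration optimum on essentially all seeded 4-node
  benchmarks where either pure policy plateaued in the mid-80% range.
* **Tabu search** — same move set, but non-improving moves are accepted
  while the last `tabu_length` (default 10) visited structures are
  forbidden; search stops after `tabu_length` consecutive non-improving
  steps and the best structure visited is returned.  `tabu_length = 0`
  degenerates to hill climbing.
* **Grow-Shrink / IAMB** — Markov-blanket discovery per node (greedy
  growth + shrinkage, or incremental max-association + backward
  removal), AND-rule symmetrization, neighbour identification by subset
  search within the smaller blanket, collider orientation from recorded
  separating sets, then Meek rules 1–3 to closure.  Rule 4 is omitted:
  it only fires given background-knowledge orientations that rules 1–3
  cannot reach, which these learners never produce.  Output is a PDAG;
  a Dor–Tarsi consistent extension is attached when one exists *and*
  violates no blacklist (otherwise the ensemble falls back to
  half-weight counting).
* **MMHC / RSMAX2** — restrict–maximize: an MMPC skeleton (forward
  max-min heuristic over subsets of the current candidate set, backward
  removal, AND symmetry) restricts which pairs hill climbing may
  connect; delete/reverse moves are unrestricted.  RSMAX2 exposes the
  restrict algorithm as a parameter (`"mmpc"` or `"none"`); the
  maximize phase is always hill climbing here.

Constraints: blacklisted arcs are excluded from every add/orient step;
pairs blacklisted in both directions are excluded from skeletons and
blanket candidacies; an undirected edge with exactly one orientation
blacklisted is resolved to the permitted orientation unless doing so
closes a directed cycle, in which case the edge is left undirected and
the cycle repair demotes, deterministically, the largest arc whose
reverse is not blacklisted.  Whitelisted arcs are forced present and are
never deleted or reversed; a whitelist that forces a cycle is a
configuration error.

## Bootstrap aggregation

B resamples of n rows with replacement (resample size = n), one learned
graph each.  A DAG contributes 1 to each of its arcs; an undirected PDAG
edge contributes 1/2 to each orientation (default), or the PDAG is first
extended to a DAG when `extend_pdags=True`.  Both conventions preserve
the identity D(x→y) + D(y→x) = 1 for every pair with S > 0.  One master
seed spawns an independent substream per replicate, so increasing B
appends replicates without reshuffling earlier ones.  A replicate whose
learner fails is logged and redrawn; more than 1% failures aborts the
run.  The 90% strength threshold is reporting-only: the full table is
always serialized, edges with strength strictly under the threshold are
removed from the rendered summary, and the boundary case (exactly 0.90)
is retained.  The default B is 10,000; tests and the acceptance script
use B = 200–500, which resolves strength/direction to ±2–5 percentage
points and keeps a full run in minutes on one core.

## Directional model comparison

For a focal ordered pair (x, y), the network is fit twice by hill
climbing under the study blacklist: once with y→x additionally
blacklisted (only x→y possible) and once with x→y blacklisted.  The
reported ΔBIC is score(only x→y allowed) − score(only y→x allowed) on
the higher-is-better scale, so positive values favour the x→y
direction; the sign convention is printed in the report header.
Swapping the pair negates ΔBIC exactly.  On a two-variable problem the
two restrictions are Markov equivalent and ΔBIC is 0 to numerical
precision — directional evidence can only come from the surrounding
structure (colliders and multi-parent nodes), never from the pair in
isolation.

## Preprocessing

Nuisance residualization regresses every analysis column on an intercept,
treatment contrasts of acquisition site (reference level =
lexicographically first; the choice cannot affect residuals) and binary
sex; residuals are exactly orthogonal to every nuisance indicator.
Hemispheric composites are the first principal component of the left and
right columns on the correlation scale (standardized inputs), so two
inputs with correlation r give leading eigenvalue 1 + r; the component
sign is fixed by requiring a positive loading on the lexicographically
first input.  Change scores are simple follow-up minus baseline
differences computed per hemisphere before compositing.  The default
order is residualize, then PCA; the stages are composable transformers,
so the reverse order is available if wanted.  Rows with missing analysis
values are dropped with a logged count; no imputation.

## Synthetic cohort generator

The generator is a standardized linear-Gaussian SEM over 17 analysis
variables typical of an adolescent imaging/substance-use battery
(baseline and change thickness factors; cannabis, tobacco, alcohol use;
demographics, puberty, polygenic risk, socioeconomic status, trauma,
ADHD, sensation seeking).  Noise variances are solved so every node has
unit marginal variance, making the edge weights standardized
coefficients and the implied correlation matrix available in closed
form (used as the simulation oracle in tests).  Design choices:

* The focal arc cannabis_change → dpfc_change is planted at β = −0.2;
  the model-implied marginal correlation is −0.19, and the correlation
  observed through the full pipeline is ≈ −0.17.  Remaining weights were
  chosen once to reproduce the magnitude pattern of published
  adolescent-cohort correlation tables (e.g. baseline→change thickness
  −0.50, tobacco-change→cannabis 0.45, SES→tobacco −0.16,
  puberty→alcohol 0.15) and are versioned in the model's YAML
  serialization.
* The focal pair is deliberately surrounded by colliders and
  multi-parent nodes (cannabis has six parents, the thickness change
  three) so its orientation is partially compelled; a two-variable
  model would be unidentifiable under score equivalence.
* Thickness factors are observed as left/right hemisphere columns with
  inter-hemisphere correlation 0.8 at two waves (wave 19 = baseline +
  change, so site effects persist across waves); first-PC composites
  therefore show eigenvalue ≈ 1.8 and correlate ≈ 0.94 with the latent
  factor, mildly attenuating the effective focal effect (≈ −0.17
  through the pipeline).
* Eight sites with mean-zero Gaussian offsets (sd 0.15) and a Gaussian
  sex effect (sd 0.15) per observed column, drawn once from a
  model-level seed (part of the model definition, not of the sampling
  seed).
* Variables are continuous by default; opt-in ordinal coarsening maps
  the substance-use columns through fixed cutpoints onto a right-skewed
  7-point lifetime-use scale.  The analysis treats variables as
  Gaussian, so the coarsening exists to study robustness (it attenuates
  correlations without reversing signs), not as the default condition.

What passing tests on this generator do **not** show: real cohort data
are non-Gaussian (zero-inflated use scores), contain missingness and
attrition, and have an unknown true graph; recovery rates here
quantify behaviour under a favourable, correctly specified model, and
transfer to real data only qualitatively.

## Numerical conventions and degenerate inputs

Scores and partial correlations are computed from means and the ML
covariance matrix, so each local evaluation is O(k³) in the parent-set
size and independent of n; parent Gram matrices are validated by
Cholesky factorization and rank problems raise a collinearity error
rather than returning unstable values.  Constant columns are degenerate
inputs everywhere.  |r| = 1 in a CI test is flagged and handled as
p = 0.  All tie-breaks (move enumeration, blanket candidate order,
extension order, majority orientation at exactly 50/50) follow
lexicographic name order.  Suite runs with identical seeds produce
byte-identical reports; reports carry no timestamps for this reason.

## Problem sizes used in the shipped checks

Unit and property tests run on 2–8 variable problems (n = 200–5000);
exhaustive enumeration oracles are guarded to ≤ 5 nodes (543 DAGs at 4
nodes).  The end-to-end recovery checks use the default cohort size
n = 637 with B = 500 bootstraps over 10 seeds, and the directional
comparison over 20 seeds — sizes chosen so the full suite completes in a
few minutes on a single core while leaving the qualitative pattern of
the full-scale analysis (B = 10,000) intact.

## Known limitations

* Only linear-Gaussian models: no discrete scores (BDeu), no
  permutation tests, no latent-variable classes (PAGs/FCI), no cyclic
  models, no exact global search.
* Greedy hill climbing without restarts has known deep local optima on
  collider-rich graphs (documented in the test suite); tabu search or
  the alternating restart policy should be preferred when compute
  allows.
* Direction coefficients are only as stable as the compelling structure
  around the focal pair is strong.  At the effect sizes this generator
  plants (|r| ≈ 0.17 for the focal pair), per-resample directional
  preferences average ≈ 3 BIC units with spread of the same order, so
  bootstrap direction coefficients vary substantially across cohort
  draws even when the average clearly favours the planted orientation.
* The MMPC subset search is exponential in the candidate-set size;
  `max_cond_size` caps it if needed on dense problems.
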