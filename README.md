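# swarmfs

Dual-task competitive-swarm wrapper feature selection for high-dimensional
labeled data — the d ≫ n regime of gene-expression and similar omics
classification problems (thousands of features, tens to a few hundred
samples, a small informative core buried in redundant and noise features).

## The method

**Dual-task construction.** Two relevance filters are computed per feature:
Relief-F (neighborhood-based instance discrimination) and the Fisher score
(between-class over within-class scatter). After min-max normalization they
are fused linearly,

    w_i = α · w_i^RF + β · w_i^FS          (defaults α = β = 0.5),

the fused scores are ranked in descending order, and the **knee point** of
the ranked curve — the point at maximum perpendicular distance from the
chord joining the curve's endpoints — sets an adaptive cut-off. Features at
or above the knee define a compact *auxiliary* search task; the *primary*
task keeps the full feature space.

**Elite-guided competitive search.** Each task is searched by a competitive
swarm: particles hold continuous positions in [0,1]^d (thresholded at 0.6
into feature masks), are randomly paired each generation, and only the loser
of each pair updates. A per-task elite pool (the top-K particles) and two
Bernoulli draws — transfer with probability P_trans, elite learning with
probability P_k, both 0.6 by default — select one of four velocity updates:

    cross & elite   : V ← r1·V + r2·(E_own − X) + r3·(E_other − X)
    cross & ¬elite  : V ← r1·V + r2·(X_W − X)  + r3·(W_other − X)
    ¬cross & elite  : V ← r1·V + r2·(E_own − X) + φ·r3·(Ē_own − X)
    ¬cross & ¬elite : V ← r1·V + r2·(X_W − X)  + φ·r3·(X̄ − X)

with X_W the pair's winner, E_* random elite-pool members, Ē_own the elite
mean, X̄ the swarm mean, and r1, r2, r3 per-dimension U[0,1] draws. The last
mode is the classical competitive-swarm update; the cross-task modes let
elites of one task guide losers of the other.

**Fitness.** A decoded mask S is scored by a plug-in classifier (default:
1-nearest-neighbor, z-scored per fold) under stratified inner
cross-validation:

    fitness = α_f · γ_R + (1 − α_f) · |S|/|N|,     γ_R = 1 − (1/C) Σ_i TPR_i,

with α_f = 0.999999, so the balanced error γ_R dominates and subset size
breaks ties. Lower is better; the empty subset scores the worst-possible 1.

Ablation variants are built in: `plain_cso` (single full-space task,
classical updates only), `ec_pso` (dual task + elite learning, no
cross-task transfer) and `ec_pso_transfer` (the full algorithm).

## Worked example

Generate a planted-signal benchmark (120 samples, 500 features of which 10
are informative and 20 are redundant copies, 3 classes), rank features and
run the full search:

```sh
$ swarmfs synth demo.csv --samples 120 --features 500 --seed 7
wrote demo.csv (120x500) and demo.truth.json

$ swarmfs score demo.csv --seed 7
knee at rank 34 (score 0.0769035); auxiliary task keeps 35 of 500 features

$ swarmfs run demo.csv --seed 7
variant=ec_pso_transfer seed=7 fitness=8e-09 selected=4/500 (task 1)
f210, f326, f466, f471
```

The knee cuts the fused score curve after 35 features, so the auxiliary task
searches a 35-dimensional subspace instead of the full 500. The best subset
found contains 4 features with fitness 8e-09: its inner-CV balanced error is
exactly 0 and only the sparsity term 1e-6 · 4/500 remains. All four selected
columns are planted signal — `f466` and `f471` are informative originals,
`f210` and `f326` redundant copies of them (see `demo.truth.json`).

`swarmfs benchmark` runs the outer protocol: feature selection repeated
inside each training fold, held-out balanced accuracy (100·(1 − γ_R), in %)
and subset size aggregated over repeated runs, with a built-in check that no
held-out row is touched during selection. `swarmfs.compare_variants` applies
the pairwise Wilcoxon signed-rank test (α = 0.05) to per-run results.

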