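# Methods

This note documents the models and procedures implemented in `agewalk`,
the parameters that matter, the numerical conventions, and the design
choices made where the design was genuinely open.

## Problem setting

Given an entire context-unspecific protein–protein interaction (PPI)
network, a gene × age expression table, and curated gene lists
(aging-related positives, non-aging negatives, cancer-related genes),
the package infers aging-specific subnetworks, extracts node features
from them, and trains cross-validated classifiers to predict
aging-related genes. The central objects are the *weighted dynamic*
subnetwork — per-age propagation weights on every interaction, turned
into per-transition differential weights — and node features built from
the *distribution of edge weights* in a node's neighbourhood.

## Activity-biased propagation

Expression at one age is mapped to strictly positive node activities.
Two assignments are supported: **option 1** gives measured expression to
significantly expressed (active) genes only and a dummy value ε to every
other network node; **option 2** gives measured expression to every
measured gene, active or not, reserving ε for unmeasured nodes. Option 2
is the default throughout, since keeping measured-but-inactive levels
preserves more quantitative signal. If any assigned value would fall
below ε (e.g. negative log-ratios), all values are shifted so the
minimum equals ε. ε defaults to 1% of the smallest positive measured
expression at the age.

A random walk with restart diffuses the activities. From node *i* the
walker steps to neighbour *j* with probability `value(j) / Σ_{k∈N(i)}
value(k)`; with probability *r* it restarts to a node drawn
proportionally to activity. The stationary distribution *p* solves
`p = (1−r) Tᵀ p + r q` (power iteration, L1 tolerance 1e−10, at most
10 000 iterations; non-convergence is an error carrying the residual).
The **edge flux** of interaction {i, j} is `p_i (1−r) T_ij + p_j (1−r)
T_ji`. Summed over edges the fluxes equal `1 − r` exactly, which the
test suite verifies to 1e−8 together with agreement against a dense
linear solve.

Three internal choices are not uniquely determined by the published
descriptions of propagation-based subnetwork inference and are fixed
here as: target-value-proportional transition probabilities,
activity-proportional restart distribution, and flux excluding restart
mass. Each is pinned by the conservation invariant above, and the
restart distribution and flux definition are isolated in
`propagation.py` should alternatives be needed. Defaults: `r = 0.15`,
conventional for restart walks; configurable via `WalkParams`.

Propagation requires a connected network; disconnected inputs are
rejected rather than silently pruned, and callers are expected to take
the largest connected component first (as the pipeline commands do).

## The eight (sub)network variants

From an entire network and an N-age expression series, `build_suite`
constructs:

| name | type | construction |
|---|---|---|
| entire | static, unweighted | the input itself |
| induced_dynamic | dynamic, unweighted | per-age induced subgraph on active genes |
| induced_static | static, unweighted | node/edge union of the above |
| netwalk_dynamic | dynamic, unweighted | per-age flux snapshots, thresholded |
| netwalk_static | static, unweighted | union of the thresholded snapshots |
| netwalk_static_star | static, unweighted | aggregated-activity flux, thresholded to match netwalk_static's edge count |
| w_netwalk_dynamic | dynamic, weighted | N−1 differential snapshots (below) |
| w_netwalk_static_star | static, weighted | aggregated-activity flux, no threshold |

plus the **non-differential counterpart** of the weighted dynamic (the N
normalized flux snapshots), retained as a first-class output because the
conventional weighted centrality features are computed on it.

Weighted construction: the N flux snapshots keep *every* entire-network
edge; weights are normalized linearly into [0.01, 1] with the minimum
and maximum taken **jointly over all snapshots** (order-preserving; a
degenerate all-equal input maps to 1.0 with a warning). For each pair of
consecutive snapshots the **differential weight** of an edge is the
symmetric percentage change

    d(w_i, w_{i+1}) = 100 · (w_{i+1} − w_i) / (w_{i+1} + w_i),

antisymmetric under swap and bounded in [−100, 100] for positive
weights (positivity is guaranteed by the normalization floor of 0.01).

Thresholding of the unweighted propagation dynamic defaults to keeping
the top 25% of entire-network edges per snapshot; the exact fraction
used in earlier unweighted constructions was chosen empirically there
and is exposed as configuration here, recorded in the run manifest. Ties
at the cut weight are all kept, making the rule deterministic and
order-independent; for the star variant this means the edge count can
minimally exceed its target, which is logged. Aggregated activity for
the star variants uses OR over ages for the activity flag and the mean
over measured ages for the value (the value rule is a package choice;
only the OR rule is forced by the construction).

## Weighted node features

Four neighbourhood types around a node *v*: **T1** edges from *v* to
its one-hop neighbours; **T2** edges among one-hop neighbours; **T3**
edges between one-hop and two-hop neighbours; **T4** edges among
two-hop neighbours. "Two-hop" means shortest-path distance exactly 2 —
the reading consistent with T1–T4 being disjoint edge classes. **ALL**
combines the four.

Weight distributions are encoded two ways. **Raw** (`nobin`): the
vocabulary of distinct weights over all snapshots jointly, where
distinctness is decided after rounding half-away-from-zero to
`rounding_decimals` (default 2; how distinctness was decided for
continuous weights is not otherwise specified, and rounding bounds the
vocabulary at 20 001 entries for differential weights). **Binned**
(`bin`): 200 unit-width bins spanning [−100, 100], half-open [a, a+1)
with the last bin closed — the only partition of that interval into
bins of size 1.

Three approaches map per-snapshot neighbourhood weight counts to a
feature vector (lengths for W vocabulary entries and N snapshots):

1. concatenated per-snapshot count vectors — `W·N` per type, `W·4·N`
   for ALL (ALL interleaves the four type blocks within each snapshot);
2. Pearson correlations of count vectors between snapshot pairs — upper
   triangle, `N(N−1)/2` per type; a zero-variance count vector yields
   correlation 0 (a constant vector carries no co-variation signal);
3. per-snapshot two-sample Cramér–von Mises distance between the
   neighbourhood weight distribution and the pooled distribution of all
   edge weights over all snapshots — `N` per type. The statistic is
   `T = nm/(n+m)² Σ (F_a − F_b)²` summed over both samples' points. An
   empty neighbourhood contributes distance 0 (no evidence of
   deviation). Pooling over all snapshots is the default reference; a
   per-snapshot mode is provided, as the pooled reading follows from
   comparing against "the whole dynamic network".

Crossing {approach} × {T1–T4, ALL} × {nobin, bin} gives the 30 dynamic
feature matrices, named `Diff-{nobin|bin}[-cor|-cvm]-{1|2|3|4|all}`.
Static counterparts treat a weighted static network as a one-snapshot
dynamic; approach 2 is undefined at N = 1 and falls back to approach 1
(so the static analogue of a correlation feature on T2 is
`Static-nobin-2`).

Comparator features on the non-differential dynamic: per-snapshot
strength, weighted clustering (geometric-mean/Onnela variant — the
weighted-clustering literature offers several definitions and this one
is recorded in the feature metadata so alternatives can be swapped),
closeness and betweenness with edge length 1/weight, and eigenvector
centrality of the weighted adjacency. Closeness uses the harmonic form
normalized by n−1, which degrades gracefully on disconnected snapshots
(per reachable set) and agrees with ordinary closeness in ranking on
connected ones.

## Predictive models

`GenePredictionModel(features, labels, dim_reduction, classifier, cv)`
follows the statsmodels model/results convention: construction validates
that every labelled gene has a feature vector; `fit()` returns a results
object with out-of-fold scores, per-repeat AUPR, aggregated hard
predictions, and `summary()`. `fit_model_grid` crosses features with
{none, PCA} × {LR, NB, SVM-rbf} and selects the best model by mean
AUPR (ties: higher F-score, then the simpler model — no reduction
before PCA, LR before NB before SVM-rbf).

Cross-validation is stratified k-fold (default 5) repeated (default 10)
with a recorded seed. PCA is fitted on training folds only and retains
the smallest number of components explaining ≥ 90% of training-fold
variance. LR and SVM use balanced class weights (the label sets are
heavily imbalanced) and feature standardization fitted on training
folds; other hyperparameters are scikit-learn defaults. Scores are
class-1 probabilities where available, decision-function margins for the
SVM; hard labels use each classifier's native decision rule. AUPR is
the step-wise (interpolation-free) area under the precision–recall
curve. Precision/recall/F are computed on the majority-vote aggregated
predictions over repeats; with no predicted positives all three are
reported as 0 with a warning.

Significance against chance uses a seeded label-permutation baseline
under the same CV scheme; the one-sided empirical p-value is
`(1 + #{baseline ≥ observed}) / (1 + n_draws)`. Multiple-testing
adjustment defaults to Benjamini–Hochberg (the method is configurable;
the choice of adjustment in comparable published analyses is not
specified beyond "adjusted"). Overlap analysis reports the Jaccard
index and the upper-tail hypergeometric p-value of the intersection;
validation of novel predictions (predicted positives currently labelled
negative) reports the percentage present in the cancer gene list, and
is reported as not-applicable when there are no novel predictions.

Label assembly mirrors the study design: positives are the
positive-source genes present in **all eight** suite members; negatives
are the common genes absent from *every* aging-related source; the same
labels are used on every member so accuracy is comparable across
members.

## Synthetic benchmark

The generator emulates the real inputs at desk scale: a seeded
preferential-attachment network (heavy-tailed degrees; attachment
parameter derived from `n_edges_target`), lognormal baseline expression
(log-mean 1, log-sd 1), i.i.d. Gaussian log-noise (`noise_sd`, default
0.5), and a planted monotone trend of total magnitude `effect_size`
(default 2.0) added to the log-expression of `n_aging_genes` seeded
genes across the age range. Defaults: 300 genes, 10 ages, 30 aging
genes, 5 negatives per positive — mirroring the roughly 1:5–1:8
imbalance of curated aging labels. The synthetic cancer list includes
positives at rate 0.25 and negatives at rate 0.06, matching the partial
overlap seen between cancer driver lists and aging annotations.

The signal is planted in *expression*, never in features: recovery
therefore requires activity mapping, propagation, normalization, the
differential construction, and feature extraction to all transmit it —
the honest end-to-end test of the claim that weight dynamics carry
label signal. What the generator does **not** emulate: realistic PPI
motif structure beyond heavy-tailed degrees, age-correlated noise,
batch effects, or missingness patterns of microarray data; passing the
recovery test shows the pipeline transmits a planted monotone signal,
not that it matches published accuracy on curated data.

The recovery benchmark in the test suite runs 20 replicates per arm at
200 genes / ~600 edges / 10 ages / 30 planted genes, with a
strong-signal arm (`effect_size = 4.0`, i.e. 8× the noise sd — the
regime the recovery claim addresses) and a null arm (`effect_size =
0`). Per replicate the `Diff-bin-1` feature with logistic regression is
cross-validated (3-fold × 2 repeats) and compared to 19 label
permutations; across replicates the mean AUPR must exceed the 95th
percentile of the pooled permutation draws in the strong-signal arm and
must not in the null arm. These problem sizes keep the benchmark at
about a minute while leaving wide margins on both sides (observed:
per-replicate exceedance ≈ 95% with signal, ≈ 5% without).

## Numerical conventions and degenerate inputs

- Self-loops in edge lists are dropped (counted in the log); duplicate
  unweighted edges collapse; duplicate weighted edges are errors.
- Largest-connected-component ties break by the lexicographically
  smallest member node.
- Missing expression (empty cell/`NA`) marks a gene inactive at that
  age; an all-missing gene row is retained, inactive everywhere.
- Activity rule is configurable (callable, per-age mean, or within-age
  z-score threshold); the default — active where measured and ≥ the
  per-age mean — is a simple reproducible stand-in, since the activity
  calls behind the original curated series came from earlier work and
  are not reconstructible.
- `top_k` thresholds keep all edges tied at the cut; `min_weight` is
  inclusive.
- Half-away-from-zero rounding everywhere a vocabulary is built, so
  results do not depend on the platform's banker's rounding.
- Seeds: every stochastic component takes an explicit seed; repeated CV
  derives per-repeat fold seeds as `seed + 7919·rep (mod 2³¹)`.

## Known limitations

- Raw (`nobin`) feature matrices are dense; at full PPI scale (tens of
  thousands of distinct weights) approaches 1–2 on the ALL
  neighbourhood become memory-heavy. A sparse representation would be
  the natural extension.
- The monotonicity of a node's incident flux in its own activity is
  checked empirically on small graphs as a sanity property; it is not a
  theorem of the walk and rare violations are tolerated by the test.
- Betweenness and closeness on large dense snapshots dominate the
  centrality-feature runtime (all-pairs shortest paths per snapshot).
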