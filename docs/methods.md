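# Methods

This note records the modelling and numerical choices behind `gwanfis`, the
parameters that matter, and what the synthetic experiments do and do not
demonstrate.

## Data model and preprocessing

The canonical container is a samples × genes real matrix with a binary label
per sample (`ExpressionDataset`). Matrices are z-scored per gene with the
**population** standard deviation (divide by *n*): the transformation is
`z = (x − μ)/σ` and no Bessel correction is applied, a convention fixed once
for reproducibility. Zero-variance genes (flat probes, common in real
microarray exports) map to all-zero columns instead of raising; the selection
stage can still discard them. Z-scores are not clipped: values typically fall
in roughly ±3 for near-Gaussian genes, but outliers are left intact.

By default normalization is fit on the full matrix before any
cross-validation split, matching the preprocess-first convention of the
pipelines this package emulates. That leaks fold means/SDs into training;
`PipelineConfig(normalize_per_fold=True)` refits μ and σ on each training
fold for leakage-free experiments. On the synthetic fixture the two options
differ by at most a few pooled percentage points.

## Grey-wolf wrapper feature selection

The selector searches `[0,1]^D` (one coordinate per gene). A position maps to
a subset by thresholding at 0.5 (strict inequality); an empty mask is
repaired to the single largest coordinate. Subset quality `γ(S)` is the
stratified 3-fold cross-validated accuracy of a 5-nearest-neighbour
classifier on the selected columns — fast, deterministic given its seed, and
the conventional choice for wrapper objectives where the final classifier is
too expensive to train inside the search loop. The scored fitness is
`0.9·γ(S) + 0.1·(|D|−|S|)/|D|`: quality dominates, subset size breaks ties.

Each iteration every wolf moves to the mean of three leader-guided candidates
`X_k − A_k·|C_k·X_k − X|` (k over the three best solutions), with
`A ∈ [−b, b]`, `C ∈ [0, 2]` resampled per leader and `b` decaying linearly
from 2 to 0 over the run; positions are clipped to the unit cube. The
adaptive β-hill climber then refines the current best position: each inner
step perturbs every dimension by `±U(0,1)·N` and independently resets each
dimension to `U(0,1)` with probability `beta_rate` (the β operator — its
exact form is a design choice here, adopted from the published βHC
formulation), accepting only strict improvements. The bandwidth
`N = 1 − (t/T)^{1/K}` is advanced by **global** progress
`(outer·inner + j)/(outer_total·inner)`, so a single long refinement and a
per-iteration refinement follow the same shrinking schedule; at the end of
the schedule N = 0 and, with `beta_rate = 0`, the operator is the identity.

Defaults: pack 10, 100 outer iterations, hill-climber K = 4 with
`beta_rate = 0.05` and 30 inner steps applied once per outer iteration to the
leader only (budget choice). The 100-iteration default matters: the parsimony
weight is only 0.1, so subset shrinkage is slow, and shorter budgets stop
while many background genes are still selected. Fitness evaluations are
memoized by mask, which roughly halves runtime late in the run when the pack
has converged. One `run_igwo_fs` call on 60 × 200 data takes ~10 s on one
CPU.

## Sugeno ANFIS classifier

The classifier is a first-order Sugeno system with generalized bell
memberships `μ(x) = 1/(1 + |(x−c)/a|^{2b})` and the standard five layers
(fuzzify, product firing, normalize, linear consequents, sum). Because the
textbook two-input exposition cannot apply literally to tens of genes, rules
are generated by **scatter partitioning**: seeded k-means with `n_rules`
clusters (default 4), centers `c` at the centroids, widths `a` at the
per-dimension cluster SD floored at 1e-3, shape `b = 2`. Grid partitioning is
not offered — with d selected genes it would need `m^d` rules.

Classification is 0/1 regression on the single output with threshold 0.5
(ties to class 1, documented). Consequents `{p, r}` are linear in the output,
so they are fit jointly by least squares with design rows `w̄ᵢ·[x, 1]`;
rank-deficient systems (usual when rules×(d+1) exceeds n) take the
minimum-norm solution. Firing strengths are computed in the **log domain**
(`log w = −Σ log1p(|(x−c)/a|^{2b})`): a rule's strength is a product of up to
hundreds of membership degrees and underflows linearly long before the
normalized strengths are ill-conditioned.

## Role-based parameter tuning

ANFIS parameters are tuned by a population metaheuristic in which the four
best agents act as attacker, barrier, chaser and driver: each agent moves to
the mean of four candidates `x_k − a_k·|c_k·x_k − m_k·x|` with
`a ∈ [−f, f]`, `c ∈ [0, 2]` and chaotic `m` from a logistic map (`r = 4`,
one stream per agent, reset to its seed if the state leaves (0,1)). The
driving coefficient decays as `f(t) = 2.5·(1 − t/T)²` — the published
description requires only a nonlinear decay from 2.5 to 0, and this curve
meets both endpoints; it is configurable. With `f = 0` every agent collapses
to the role mean in one step, which is the exploitation limit.

Tuning modes: **hybrid** (default) searches only the premise parameters and
refits consequents by least squares inside every objective evaluation;
**full** searches the complete flattened vector. Bounds: `c` within each
input's observed range ± 1 SD, `a ∈ [1e-3, 3·SD]`, `b ∈ [0.5, 5]`,
consequents ± 10 in full mode. The incumbent parameter vector seeds the
initial population and best-so-far bookkeeping is elitist, so tuning can
never raise the training MSE; a zero iteration budget returns the incumbent
unchanged (up to the consequent refit). The objective is the training MSE of
the continuous output against 0/1 labels.

## Metrics and protocols

Per-class metrics treat class k as positive: recall TP/(TP+FN), specificity
TN/(TN+FP), precision TP/(TP+FP), F = 2PR/(P+R), G-measure = √(P·R) — the
geometric mean of precision and recall, the only common G definition
consistent with the benchmark tables this package reproduces (the
√(recall·specificity) alternative is not). Macro values are unweighted means
over the two classes; macro accuracy equals overall accuracy, and
specificity of class k equals recall of class 1−k by construction. Undefined
precision (no predicted positives) is reported as 0 with an explicit flag so
macro averages stay defined; a class with no actual samples raises. Displayed
percentages are rounded half-up to 2 decimals; raw fractions are kept
internally.

Both stratified k-fold CV with a pooled confusion matrix and a single
stratified holdout split are provided; published pipelines of this kind are
ambiguous about which they used, so neither is privileged. If the smaller
class has fewer members than folds, the splitter degrades to unstratified
shuffled folds with a warning.

## Synthetic generator and what the tests show

`generate_synthetic` draws standard-normal background genes and shifts the
first `n_informative` genes by `shift` SD in class 1; labels follow
`class1_fraction` (default 0.4, mildly imbalanced as in the cancer benchmark
tables) and are shuffled against sample order. Defaults — 60 samples, 200
genes, 10 informative, shift 2 — are scaled-down study conditions chosen so
a selector must cope with genes ≫ samples while single runs stay in seconds;
informative indices are recorded for recovery scoring.

This emulates the *shape* of microarray data, not its biology: no
gene–gene correlation, no batch effects, no heavy-tailed intensities, no
probe-level noise structure. Passing recovery tests therefore show that the
search machinery finds planted univariate mean-shift signal against Gaussian
noise — not that the pipeline ranks genes correctly on real arrays.

On this fixture the seeded selector attains ≥5-fold enrichment of planted
genes over random expectation (5.3–12.5 across probe seeds), and the full
seeded 5-fold pipeline pools roughly 73–92% accuracy depending on seed;
because the signal is redundant (any few informative genes suffice for
perfect wrapper accuracy), the selector keeps only a subset of the planted
genes, and the pooled accuracy of individual runs fluctuates by several
points around the low-to-mid 80s. The per-run problem sizes (60 × 200, pack 10, 100 FS iterations,
tuner population 20 × 40 iterations) keep a full pipeline run near a minute
on one CPU.

## Known limitations

- Binary labels only; multi-class would change the Sugeno output encoding
  and every metric definition.
- The wrapper objective uses Euclidean 5-NN; with very many selected genes
  distance concentration can saturate `γ(S)` at 1.0 early, leaving only the
  weak parsimony gradient (visible on the synthetic fixture).
- Min-norm consequent fits do not regularize: with few samples and many
  selected genes the ANFIS can interpolate its training fold; generalization
  then rests on the feature selector having discarded noise genes.
- The tuner treats premise parameters as a flat bounded box; it does not
  exploit rule structure or reorder rules (the model output is invariant to
  rule order anyway).
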