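# Methods

This note records the model assumptions, parameter choices and numerical
decisions behind `imfuse`, in the order the pipeline runs.

## Data model and conventions

Input is an `n × d` matrix of finite reals with binary labels. Label 1
is always the minority ("positive") class: every stage (sample weights,
SMOTE, AUC) needs to know which class is rare, and readers enforce the
convention by mapping the rarer raw label to 1 (overridable). Only
binary problems are supported; multi-class files are rejected rather
than silently collapsed.

Readers/writers use 17-significant-digit decimal text, which round-trips
IEEE doubles bit-exactly; numeric conversion goes through the
correctly-rounded `strtod` path rather than pandas' fast parser for the
same reason. The KEEL dialect is restricted to numeric inputs and a
binary nominal output — the form the standard imbalance benchmarks use.

## Sample weights

For anchor `i` with own class `c`:

    w_i = (δ_n + δ_p) / ( |N_c| · d(x_i, x̄_c) )

* `δ_n = 1 / mean(k nearest majority-class distances)`,
  `δ_p = 1 / mean(h nearest minority-class distances)`, computed in the
  space the optimizer works in, excluding the anchor itself. Defaults
  `k = h = 5`. Large `δ_n + δ_p` marks samples close to both classes —
  the decision boundary — or in locally dense regions.
* `x̄_c` is the **mean** of class `c`. A raw coordinate sum would scale
  with class size and is not a geometric center; class size already
  enters through the explicit `|N_c|` factor.
* `c` is the anchor's own class: the center distance exists to
  down-weight outliers *of their own class*.
* Any distance below `ε = 1e-12` (duplicates, a sample exactly at its
  class mean) is clamped to `ε`, keeping every weight finite and
  strictly positive.

With equal densities and center distances, the weight ratio between a
minority and a majority sample is exactly `|N_maj| / |N_min|` — the
class-size correction in its purest form (this is asserted in the
tests on a hand-constructed mirrored fixture).

## Metric learning

**Triplets.** Each anchor is paired with its `k_targets = 3` nearest
same-class neighbors (standard LMNN practice), fixed once in the
(standardized) input space; distance ties break toward the lower index.
Every different-class sample serves as impostor for every pull pair —
full enumeration, which is affordable at the low-thousands sample sizes
this package targets and avoids a heuristic impostor-mining step.
Target neighbors are static; dynamic re-mining is out of scope.

**Loss.** The anchor's weight multiplies both its pull and its push
terms; the impostor's own weight does not enter. The hinge margin is
fixed at 1 (exposed in the config). With unit weights the loss reduces
identically to plain LMNN, which is the ablation used in the
evaluation (`transform="lmnn"`).

**Standardization.** Per-feature zero mean / unit variance, fitted on
the training partition only and carried inside the returned transform,
is ON by default: margin-based losses are scale-sensitive, and a fixed
margin of 1 is only meaningful on commensurable features. Constant
features get scale 1 instead of a division by zero.

**Optimizer.** Deterministic gradient descent on `L`, initialized at
the identity truncated to `output_dim` rows (default: full dimension),
with step-halving: a step that would not strictly decrease the loss
halves the learning rate and retries, up to 20 times, so the accepted
loss sequence is non-increasing by construction. Stops at `max_iters`
(200), on relative improvement below `1e-6`, or when no decreasing step
exists. Defaults: learning rate `1e-3` on standardized features.

One refinement over textbook gradient descent: the loss is not
scale-anchored — shrinking `L` globally shrinks the pull term while
carrying no discriminative information, and unconstrained descent
exploits exactly that mode, producing maps whose absolute margins
*shrink* even as their direction structure improves. Each accepted
iterate is therefore retracted to the sphere `‖L‖_F = ‖L_init‖_F`
(projected gradient descent at fixed Frobenius norm). Descent must then
reallocate scale across directions — suppressing noise directions,
amplifying discriminative ones — and the monotone-descent guarantee is
unchanged because the retraction happens before the acceptance test.

The exact subgradient is used; triplets exactly at the hinge kink
contribute zero. Gradient and loss share cached difference-vector
structures (unique `(i,j)` and `(i,l)` pairs), making one iteration
O((pairs + impostor pairs) · d) plus two `d × d` matrix products.

## SMOTE

Synthetic minority rows are convex combinations `x_i + (x_n − x_i)·r`
with `r ~ U[0,1]`, `x_n` drawn uniformly from the seed's `k = 5`
nearest minority neighbors (the classical default; clipped to minority
size − 1 with a warning). Exactly `n_maj − n_min` rows are appended so
the output is balanced; originals are preserved verbatim and first.
Seed samples cycle through the minority in a shuffled order, so every
minority sample contributes before any repeats — the quota allocation
the classical formulation leaves open. Neighbor search runs in the
coordinates the data arrives in, i.e. inside each feature subspace of
the transformed data, since balancing happens per subspace. An optional
provenance log (seed, neighbor, `r` per synthetic row) makes the
convexity guarantee auditable.

## Ensemble and voting

Subspaces are independent uniform `M`-subsets of the transformed
columns, `M = max(1, floor(feature_ratio · r))`; defaults 15 subspaces
at ratio 0.7 (ratio 0.1 is the sensible choice when `d` approaches `n`,
as with flattened images). Independence means occasional duplicate
subspaces are possible and accepted. The default base classifier is a
linear max-margin classifier (soft-margin linear SVM, C = 1, primal
solve for determinism) whose signed hyperplane distance is the member
score; any object with `fit`/`score` can be substituted.

Member outputs are **continuous scores, not hard labels**: both AUC
evaluation and the GA fitness need a ranking, which 0/1 votes cannot
provide. The fused score is the simplex-weighted sum of member scores;
hard prediction thresholds it at 0.

## GA weight optimization

Genes are vectors in `[0,1]^N`, normalized to the simplex when applied
(an all-zero gene falls back to uniform weights rather than erroring).
Per generation: parent pairs drawn uniformly without replacement,
single-position crossover with probability 0.9, per-position mutation
with probability 0.1 (fresh uniform draw), children evaluated, and each
child strictly fitter than the current worst population member replaces
it — elitist replacement, so best fitness is non-decreasing, exactly.
Defaults: population 30, 30 children/generation, ≤ 100 generations,
early stop after 25 stalled generations.

Fitness is AUC on an internal stratified validation split (default 25 %
of the training partition) held out from *both* the metric learning and
the member training: fitness on training predictions would reward
overfit members. When the minority is too small to split, the GA is
skipped and weights stay uniform.

## Evaluation protocol

Repeated stratified cross-validation, defaults 5 runs × 5 folds. The
whole pipeline — transform, subspaces, SMOTE, members, GA — is refitted
on each training partition; the test fold never enters any stage.
Reported: mean AUC and the population standard deviation over all
run-fold AUCs, plus the run-level std (papers differ on which "±" they
print). A fold whose test partition is single-class (possible at
imbalance ratios near 30) is skipped with a warning, not an error. One
master seed drives fold shuffling, subspace draws, SMOTE, member
training and the GA through hashed seed derivation
(`imfuse.seeding.derive_seed`), so any experiment is reproducible from
one integer; two identical calls give bit-identical AUC tables.

## Synthetic data: what it does and does not emulate

The generator draws both classes as isotropic unit-variance Gaussians,
the minority mean `class_separation` within-class SDs from the majority
mean along the first informative axis, plus pure-noise standard-normal
dimensions shared by both classes. It emulates the regimes of the
standard imbalance benchmarks — imbalance ratios ~3–30, tens to low
thousands of samples, a minority of informative features — with
controllable overlap. It does **not** emulate multimodal or curved
class boundaries, heteroscedastic or correlated features, label noise,
or discrete/mixed attributes; a pipeline that passes here is validated
for its contracts (no leakage, determinism, balance, margin behavior,
ranking quality), not certified on any real dataset.

Problem sizes used in the shipped checks (5-fold CV at n = 550 with
imbalance ratio 10; margin fits at n = 150; GA fixtures at n = 200)
were chosen so the full suite exercises every stage at realistic
imbalance without requiring downloads.

## Known limitations

* Binary classification only; the voting scheme has no multi-class
  extension here.
* Full impostor enumeration is quadratic in class sizes; beyond ~10⁴
  samples an impostor-mining variant would be needed.
* The learned transform is a dense linear map; no PSD Mahalanobis
  (`M = LᵀL`) semidefinite formulation and no rank selection by
  cross-validation.
* GA hyper-parameters are conventional defaults, not tuned; the
  optimizer is a simple elitist scheme, not a state-of-the-art
  evolutionary strategy.
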