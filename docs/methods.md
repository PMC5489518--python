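# Methods

## Problem setting

Given a labeled matrix of `n` samples by `p` features with `n ≪ p`
(expression-style data), find a binary feature mask whose induced
sub-matrix maximizes classification accuracy. The search space has
`2^p − 1` nonempty masks; subset search is NP-hard, so the package treats
it as binary stochastic optimization with a wrapper fitness.

## Wrapper fitness

`FitnessEvaluator` maps a mask to the mean validation accuracy of an
extreme learning machine trained on the masked columns.

* **Splits are frozen per evaluator** (stratified, seeded), and the ELM's
  hidden weights are drawn from a fixed seed, so fitness is a
  deterministic function of the mask. Without this the optimizer chases
  classifier noise rather than signal.
* **Search-time fitness is 3-fold CV** rather than the 10-fold used for
  reporting: the inner loop runs tens of thousands of times, and 3-fold
  cuts that cost roughly threefold. The tests assert that inner 3-fold
  scores track the repeated 10-fold report within 0.15 absolute on
  synthetic data. The fold count is configurable.
* **Scores are cached by mask** (bit-packed key). A cache hit returns the
  identical float; all selectors in a comparison can share one evaluator
  so the fitness function is held fixed across methods.
* **The all-zero mask scores 0.0** without touching the classifier. It is
  not repaired; the escape and rebirth moves take wolves off it, and a run
  aborts only if every wolf's mask stays empty for 5 straight iterations.

## Extreme learning machine

A single-hidden-layer network: hidden weights `W ∈ [−1,1]^{L×d}` and
biases `b ∈ [−1,1]^L` drawn uniformly from a seeded generator; hidden
activations `H = g(XW' + b)` with sigmoid `g` (tanh available); output
weights the minimum-norm least-squares solution of `HB ≈ T` for one-hot
(+1/0) targets; prediction is argmax with ties to the earlier class in
first-appearance order.

Choices the ELM literature leaves open, fixed here and exposed as config:

* `L = min(100, 2·n_train)` by default — bounded by sample count so a
  60-sample dataset does not get a needlessly wide random map.
* Features are standardized inside `elm_train` (mean 0, SD 1; constant
  columns map to 0) because the sigmoid saturates on raw expression
  scales; the parameters live in the model and re-apply at prediction.
* Each hidden unit's weights and bias are drawn as one contiguous block,
  so hidden maps are nested across `L` on the same seed; the training
  residual is then non-increasing in `L`, which the tests assert.

## Search dynamics

Positions live in `[−0.5, 1.5)` per coordinate and project to bits by
`1 iff 0.5 ≤ x < 1.5`. After every move, coordinates are clipped to
`[−0.5, 1.5 − 1e−9]`: the margin keeps a wolf pushed hard toward "select"
from wrapping out of the half-open selection band.

Per wolf and iteration: (1) a weighted prey step
`x ← x + s·(W_i·P)·U(−1,1)`; (2) attraction to the nearest better peer
within Minkowski radius `r` — ties broken by better fitness then lower
index — via `x ← x + β₀·e^(−d²)·(x_j − x_i)·(W_i·P)` plus a small jitter
of magnitude `s·(W_i·P)` (the attraction formula's trailing escape term,
read here as a per-move perturbation; switchable off), or a second prey
step if no peer is visible; (3) with probability `1 − p_a`, an escape
jump. Every candidate position is re-drawn if its mask is remembered as a
worst position (see Memory). Fitness is evaluated after each accepted
move and the best mask ever seen is tracked, so the reported
`fitness_history` is non-decreasing by construction.

**Escape.** The jump `x ← x + s·(W_i·P)·(z − x)` draws targets `z`
uniformly in the bounds and accepts the first whose applied displacement
exceeds the visual radius in Minkowski norm (≤ 100 tries, then the
largest seen) — a minimum-length constraint that takes the wolf outside
its visual field when the geometry allows it at all.

**Weight economy.** With `γ` the improvers' total weight,
`σ = ½·ln((1−γ)/γ)` (0 at `γ ∈ {0, ½, 1}`); improvers scale by `e^σ`,
others by `e^(−σ)`; weights renormalize to 1. The sign convention makes
`σ > 0` exactly when improvers hold less than half the resource, so a
struggling pack concentrates resource on whoever is making progress —
this is the direction consistent with the mechanism's own description,
and the one implemented. Degenerate `γ` (no improver, all improvers)
short-circuits to `σ = 0`. At the first iteration the previous fitness is
initialized to the current one, so no wolf counts as improved before it
has moved.

**Rebirth.** After the update, weights below `1/(100·P)` trigger rebirth
(uniform re-randomized position, memory-checked; weight reset `1/P`);
weights above `1/2` are multiplied by a uniform draw; then renormalize.

**Memory.** A FIFO of capacity 50 (default) storing *binary masks*, not
continuous positions — equality of continuous vectors is measure-zero,
and the mask is what a position means here. When full, the oldest
`memory_forget_count` (default 1) entries are evicted. A candidate whose
mask is remembered is re-drawn up to 10 times with the same move law;
because small steps often cannot flip any bit, re-generation then
escalates to fresh uniform positions (10 more tries) before the bounded
fallback accepts a remembered mask with a warning. The escalation is what
keeps the no-revisit contract effective in practice; the fallback only
fires when the mask space is tiny relative to the memory.

**Defaults.** `P = 15`, `T = 100` iterations (the benchmark protocol's
settings), `r = 0.2·√p` (scales with dimension so the visual circle
neither sees everything nor nothing), `s = 0.15`, `β₀ = 1`, `p_a = 0.25`,
Minkowski order 2, memory capacity 50. All are config fields and are
echoed into every result.

## Baselines

`run_wsa` is the plain wolf search: the same prey/attract/escape loop
with unit step scaling, no weights, no memory, no rebirth — implemented
as its own loop so the reduction claim (EBWSA with `elitist=False` and
`memory_capacity=0` follows the same trajectory law) is a genuine
two-implementation check, tested by a Kolmogorov–Smirnov comparison of
best-fitness distributions over seeds. `run_bpso` uses inertia 0.8,
`c₁ = c₂ = 2`, velocity clamp `±4` and the sigmoid transfer into per-bit
flip probabilities — the canonical binary PSO. `run_pso` keeps continuous
positions on the same box and scores through the binary projection, which
is what makes a continuous swarm a well-defined feature selector.

## Synthetic data

`generate(SynthSpec)` draws class-conditional Gaussians: informative
features shift the second class by `effect_size` noise-SDs; redundant
features are `1·source + 0 + N(0, 0.1·noise_sd)`; the rest are
class-independent noise. Class sizes are deterministic
(`round(n·class_balance)`), rows are shuffled, and the informative
indices are returned, so recall of the planted truth is measurable.
Defaults (100 samples, 2,000 features, 20 informative, `δ = 2`, balanced)
mirror the shape regime of public expression benchmarks with a moderate,
recoverable signal.

What the generator deliberately does **not** model: heavy-tailed and
count-like marginals, batch effects, normalization artifacts, correlated
noise blocks, label noise. Passing tests therefore demonstrate that the
machinery optimizes its objective and recovers planted structure — not
that it will rank features correctly under real microarray artifacts.

## Evaluation protocol

`final_evaluate` runs repeated stratified k-fold CV (10-fold default) on
the masked data; each repeat pools out-of-fold predictions into one
confusion matrix and scores accuracy, kappa, precision and recall, with
mean ± sd across repeats. Pooling (rather than averaging per-fold
metrics) keeps kappa and precision stable on datasets where a fold holds
only a handful of a class; for accuracy with near-equal stratified folds
the two conventions agree to rounding. If the smallest class has fewer
members than folds, the fold count drops to it with a warning.
Precision/recall averaging is support-weighted by default (macro
available) since benchmark tables rarely state the convention.
`experiment` repeats the whole selection `R` times with derived seeds and
reports mean ± sd per metric — the usual benchmark row shape — with the
aggregate recomputable from the stored per-run results.

Note the distinction surfaced in the README example: the search fitness
is an optimistic, selection-biased quantity (the optimizer maximized it
on fixed inner splits); the repeated-CV report on the final mask is the
number to quote.

## Determinism and seeds

Every stochastic component takes an explicit seed; one master seed fans
out through `seeding.derive_seed(master, stream)` (SeedSequence-based,
children < 2³¹) to the search RNG, ELM weights, inner splits and
evaluation folds. Identical config + seed reproduces results bit-for-bit,
including the serialized JSON.

## Problem sizes in the test and acceptance runs

The oracle-equivalence checks use 8-feature problems (255 nonempty masks,
exhaustively enumerable) with 100 samples; conservation checks run 50
iterations at 25 features; feature recovery uses 200 features with 10
informative at `δ = 2.5`, 150 search samples and 150 held out, the full
`P = 15`, `T = 100` budget, and 10 (tests) or 5 (acceptance script)
seeds. These sizes make the planted truth unambiguous while keeping a
complete run of the suite in the minutes range on a single CPU.

## Known limitations

* Wrapper fitness on fixed splits overfits those splits; masks should be
  re-scored with `final_evaluate` (done automatically in `experiment`).
* The ELM is unregularized; with `L` close to the training count it can
  interpolate, which inflates inner fitness plateaus (many masks tie at
  1.0 on easy problems).
* Exhaustive validation is only feasible to ~16 features; beyond that,
  quality is assessed against planted synthetic truth, not global optima.
* ARFF support covers numeric attributes with one nominal class; sparse
  ARFF and date/string attributes are out of scope, as is the `.mat`
  container some repositories use.
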