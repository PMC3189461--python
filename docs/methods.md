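# Methods

## Signal model and preprocessing

A sustained vowel is modeled as a quasi-periodic train of glottal cycles.
All analysis works on amplitude-normalized samples: the affine map
(x − min)/(max − min) onto [0, 1], with the degenerate constant signal
mapped to 0.5 everywhere so the output stays in range and deterministic.
The derivative path takes the first forward difference of the normalized
signal and re-normalizes it, so both network paths see inputs on the same
[0, 1] scale the logistic output unit can produce. Whether to re-normalize
the derivative was a genuinely open choice; without it the difference
signal occupies a narrow band around 0 and the output unit would have to
saturate to track it.

Windowing is not automated reliably for clinical material, so two modes
ship: a fixed-length mode (default; reproducible and used throughout the
tests) and a peak-based mode that delimits windows by successive
above-mean local maxima at least `min_distance` apart, approximating one
glottal cycle per window. Samples after the last complete window are
dropped — leading/trailing portions of clinical recordings are noisy and
are not fed to the network.

## Recurrent networks

All three architectures are single-input single-output with one hidden
layer of `n_hidden` logistic units (default 40) and a logistic output:

* **Elman**: hidden activations at t−1 are copied into a context layer that
  feeds the hidden layer (weights `W_ctx`).
* **Jordan**: the delayed output feeds the hidden layer through one context
  unit (`W_jordan`); there is no hidden-copy context.
* **Modified Elman-Jordan**: both contexts plus a delayed self-connection
  on the output neuron (`w_self`). The output feedback is implemented as a
  weighted unit-delay self-loop added to the output pre-activation — the
  most literal reading of an output-layer feedback through z⁻¹; an
  alternative (an extra context unit feeding only the output through a
  squashing stage) would be behaviorally similar but adds a parameter with
  no clear interpretation.

Training is the classical scheme for simple recurrent networks: truncated
gradient descent in which context values are treated as constant inputs
during each update (no backpropagation through time), with online updates
after every (x(t) → x(t+1)) pair. Contexts are reset to zero at each epoch
start and before every test pass, making window evaluations
order-independent. The epoch's online MSE (computed with the evolving
weights) is the convergence statistic; training stops when it reaches
`target_mse` or at `max_epochs`.

Defaults and why:

| parameter | default | rationale |
| --- | --- | --- |
| `n_hidden` | 40 | reference network size for this task |
| `max_epochs` | 10000 | reference training cap |
| `learning_rate` | 0.1 | stable for logistic nets on [0,1] signals; 0 allowed (no-op training) |
| `target_mse` | 1e-3 | comfortably below the variance of a normalized vowel (~0.05–0.1) yet reachable within a few hundred epochs by the hybrid |
| weight init | uniform [−0.5, 0.5], seeded | conventional symmetric init; seeding makes every run reproducible |

Weights shared by all architectures are drawn first from the seeded
generator, so an Elman net and a hybrid with the same seed share identical
common weights; with the extra feedbacks zeroed the hybrid's forward pass
is then numerically identical to the Elman net's (verified in the tests).

The training inner loop is compiled with numba for speed; the pure
numpy `forward_step` is the reference semantics, and a test pins the
compiled loop to it (a zero-learning-rate epoch must reproduce the
reference forward-pass MSE exactly).

Divergence (non-finite weights or epoch MSE) raises a dedicated error that
the batch pipeline catches per patient, flagging the row and continuing.

## Deformation coefficient

For one signal path: divide into windows, select k at random (default
k = 4, window 256 samples), then let every selected window take one turn
as the training window of a freshly initialized network while the others
are test windows. The per-repeat error is the mean of per-window MSEs —
windows are weighted equally rather than pooling all errors, so a long
window cannot dominate. E̅ is the mean over repeats, and n̄ the matching
mean epoch count. Each repeat's network gets a seed derived
deterministically from the call seed and the repeat index; reusing one
network across repeats would leak the previous training window. The two
signal paths (a1: normalized signal; a2: re-normalized derivative) use
independently derived seeds and, consequently, independent window
selections.

## Synthetic vowel generator

Each cycle is a Rosenberg-style asymmetric glottal pulse (raised-cosine
opening over 40% of the cycle, cosine closing over 20%, closed phase at
zero) evaluated analytically on the cycle's own phase grid. Cycle c has
period `base_period · (1 + jitter · z_c)` (rounded to samples) and
amplitude `1 + shimmer · z'_c`, with z, z' independent standard-normal
draws; Gaussian noise of standard deviation `noise_level` is added and the
result normalized. Evaluating the pulse per-period, rather than resampling
a fixed template, keeps waveform sharpness independent of the drawn period
— resampling low-pass-filters long cycles and would make jittered signals
systematically *easier* to predict.

Cohort presets (chosen once as the package's study conditions): healthy
voices get jitter 0.5%, shimmer 2%, noise 1% — inside normal ranges for
sustained phonation; pathological voices get jitter 5%, shimmer 12%, noise
8% — above the conventional clinical flags (roughly 1% jitter, 4%
shimmer), with the noise level standing in for the markedly reduced
harmonics-to-noise ratio of dysphonic voices. Cohorts default to 40 cycles
of period 64 samples.

What the generator does *not* emulate: formant structure and vocal-tract
filtering, intonation and amplitude drift, subharmonics/diplophonia,
aperiodic breaks, and recording-chain compression. Passing cohort tests
therefore demonstrates that the pipeline detects elevated cycle-level
perturbations, not that it reaches clinical accuracy on real recordings;
the absolute score scale of synthetic cohorts is far below the packaged
clinical data's, which is why classifiers must be induced on features from
the same scale they will classify.

The deformation score has a floor: the network cannot test better than it
was trained, so E̅ ≳ `target_mse` (or the plateau reached at `max_epochs`)
plus the irreducible noise variance. Separation experiments therefore keep
the floor below the pathological effect size — the batch pipeline defaults
to a 400-epoch cap, which the jitter-monotonicity test tightens to
`target_mse` 1e-4 with noise-free signals so the small jitter effect is
not masked.

## Rule induction

The decision system is Pawlak's S = (U, A, d) with A = {a1, a2} and d in
{no, yes}.

**Discretization** is the greedy maximal-discernibility (Boolean
reasoning) heuristic. Candidate cuts are class-boundary midpoints computed
within each region (equivalence class of the cuts chosen so far) that
still mixes labels; the cut discerning the most still-undiscerned
differently-labeled pairs is chosen, ties broken by attribute declaration
order then lower threshold. Recomputing candidates per region matters:
on the packaged data the second cut (a2 at 0.0695, the midpoint of 0.0537
and 0.0853) is a boundary midpoint only within the low-a1 region, not in
the global a2 ordering. An inconsistent table (identical attribute values,
different labels) is reported with the offending case ids.

**LEM2** grows covering rules per decision concept over the discretized
blocks: repeatedly add the attribute-interval pair covering most of the
current goal (ties: smallest block, then attribute order, then lower
interval) until the rule's block is consistent, then prune redundant
conditions. Rule growing for a concept stops once `coverage_fraction`
(default 0.9) of the concept is covered — the standard way to tolerate
outliers instead of fabricating single-case rules; on the packaged data
this leaves exactly one borderline case uncovered. Rule intervals are open
at cut values; cuts are midpoints, so no observed value ever falls on one.

**Decision tree**: recursive binary splitting by information gain over
class-boundary midpoints of the node's cases; the recorded threshold snaps
to the largest attribute value in the *full* training set not exceeding
the gain-optimal midpoint (the classical C4.5 convention, which keeps
printed thresholds at observed values — no training value lies between
the snapped threshold and the midpoint, so the partition is unchanged).
Plain information gain is used rather than gain ratio: with binary splits
on two numeric attributes the choice does not alter the result on the
packaged data, and gain admits a simple exhaustive-search oracle in the
tests. Recursion stops on pure nodes and nodes smaller than `min_leaf`
(default 2; a split may still produce a smaller pure child, which becomes
a leaf). No pruning. Tree rules are read off root-to-leaf paths with
(−∞, t] / (t, ∞) interval ends.

Classification by rules returns the first matching rule's decision or
"uncovered"; trees always cover. The training report computes the error
percentage over covered cases and tallies uncovered ones (an empty rule
set reports 0% with a warning).

## Determinism and problem sizes

Every stochastic step — weight init, window selection, cycle perturbations
— flows from explicit seeds; batch runs derive per-patient seeds from one
master seed, so cohorts are reproducible while patients stay independent.
The experiment scales used by the shipped tests (20 trials for the
learning-speed comparison at a 1500-epoch cap; 10 + 10 signals of 40
cycles for the cohort separation at a 400-epoch cap; 3 × 20 runs for jitter
monotonicity at a 600-epoch cap; 100 random tables per induction oracle)
were chosen as the smallest sizes at which the compared medians are stable
across reruns with different seed bases.

## Known limitations

* The recorded clinical scores in the packaged dataset cannot be
  recomputed here — the underlying recordings are not available; the
  packaged table is used as classifier input only.
* One-step-ahead prediction with a single logistic output assumes signals
  normalized to [0, 1]; raw bipolar audio must pass through `normalize`.
* The screening decision is binary; the (a1, a2) plane does not separate
  laryngeal polyp from Reinke's edema.
* Peak-based windowing assumes one dominant peak per glottal cycle and
  will mis-segment strongly breathy or diplophonic material.
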