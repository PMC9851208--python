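# Methods

## Model and phases

A `LayeredNetwork` holds one forward weight matrix per adjacent layer pair
(entry `w[pre, post]`), one bias vector per non-input layer, optional
square lateral matrices with a hard-zero diagonal, a feedback gain `γ ≥ 0`,
and an activation (`sigmoid` = logistic; `hard_sigmoid` = `clip((z+1)/2, 0, 1)`).
Top-down feedback weights are not stored separately: they are the transpose
of the forward weights scaled by `γ`, the symmetric convention of the
equilibrium-propagation literature (only one matrix per layer pair receives
updates, so a free-standing feedback matrix would be untrainable anyway).

All phases are explicit Euler integrations of

`x_l ← x_l + h ( −x_l + p( W_{l−1}ᵀ x_{l−1} + γ W_l x_{l+1} + L_l x_l + b_l ) )`

with the feedback term present only for layers that have a successor and
all right-hand sides evaluated at the previous step (synchronous update).
The input layer is clamped to the stimulus throughout.

* **Free phase** — non-input activities start at zero (a conventional,
  reproducible choice; the steady state does not depend on it) and relax
  for `n_free` steps toward the fixed point `x̌* = p(·)`.
* **Clamped phase** — starts from the free final state (or, for the
  convolutional model, from the free-phase state recorded at
  `clamp_init_step`). For the first `teach_delay` steps the target has not
  arrived and the dynamics are identical to the free phase; afterwards the
  output layer is either set to `y` exactly (hard clamp) or receives the
  extra term `h β (y − x_o)` (soft clamp, `β > 0`).
* **Adaptation** — `n_adapt` steps of `x ← (1−c) x + c x̌*` applied to every
  non-input unit simultaneously, including hard-clamped outputs; no other
  dynamics run during these steps. Closed form:
  `x̂_adp = x̌* + (1−c)^n (x̂ − x̌*)`. `c ∈ [0, 1]`; `c = 0` or `n_adapt = 0`
  is exactly the identity, `c = 1` snaps onto the free state after one step.

Degenerate inputs (NaN/Inf in weights, activities, stimuli or targets)
abort the phase with a diagnostic rather than propagating.

## Learning rules and optimizer

All rules are local products of pre/post activities, averaged over the
mini-batch (so learning rates are on a per-example scale), and *added* to
the parameters:

| rule | delta per connection |
|---|---|
| `ep` | `(α/β) (x̂_pre x̂_post − x̌_pre x̌_post)` |
| `chl` | `α (x̂_pre x̂_post − x̌_pre x̌_post)` |
| `predictive_ep` | `(α/β) x̂_pre (x̂_post − x̌_post)` |
| `predictive_chl` | `α x̂_pre (x̂_post − x̌_post)` |

`x̂` is the adapted state when adaptation steps ran (identical to the
clamped state otherwise). Biases are treated as weights from a constant-1
presynaptic unit; lateral matrices use the same rule with pre and post in
the same layer and the diagonal re-zeroed after every update. Whether
lateral weights receive the `1/β` factor in EP mode is an open choice; they
are treated identically to feedforward weights here.

**AdaGrad.** The rule deltas carry the learning rate `α`, so the optimizer
first recovers the unscaled pseudo-gradient `g = Δ/α`, accumulates `g²`,
and applies `α g / (√acc + ε)` with `ε = 1e−8`. Folding `α` into the
accumulated quantity instead would cancel the learning rate out of the
recursion entirely, which would make the distinct rates of the different
architectures (0.1 vs 0.03) and the reduced-rate control sweep meaningless.
The convolutional model applies `α Δ` directly (no optimizer), per its
training protocol.

Defaults where the protocol is silent: batch size 20 with batch-averaged
(not summed) updates; Glorot-uniform initial weights from the run seed;
zero initial lateral weights and biases. All randomness (weight
initialization, data order, evaluation batches) derives from a single
user-supplied seed, and the per-epoch metrics log is bit-reproducible given
that seed (wall time excepted).

**Feedback gain for dense networks.** The benchmark protocol never states
`γ`. Under CHL the only error pathway into hidden layers is the `γ`-scaled
feedback, so a substantial gain is needed for hidden learning to express;
the package default for the dense presets is `γ = 0.5`. The EP–BP limit
experiments use `γ = 0.05` instead because the correspondence argued below
is a small-coupling statement.

## Backprop reference and gradient angles

`bp_reference_gradient` returns the exact gradient of
`½‖x_out − y‖²` for the *pure feedforward skeleton*
`x_{l+1} = p(W_l x_l + b_l)` sharing the network's current weights —
feedback and lateral terms are excluded because they have no standard
feedforward counterpart — with descent polarity, so it can be added like a
rule update. Squared error (not cross-entropy) is the cost implied by the
soft clamp's quadratic nudging. The hard-sigmoid derivative is defined as
0.5 strictly inside (−1, 1) and 0 outside, with the kinks assigned to the
zero branch.

`gradient_angle` flattens each weight-matrix delta and reports
`θ = arccos(|a·b| / (‖a‖‖b‖))` per layer, in degrees. The absolute value
folds opposing vectors to 0°, so `θ ∈ [0°, 90°]`; a signed mode exists for
debugging but is never the default. Zero-norm layers have no direction and
are reported as NaN with a warning.

`angle_curve` trains each requested variant (with adaptation / without,
i.e. `n_adapt = 0`) from identical initial weights, and at epoch 0 and
after every epoch computes per-sample rule updates and per-sample BP
gradients on a shared evaluation batch, averaging per-sample angles
(mean ± SD over the batch). The optimizer never touches these diagnostics;
positive per-layer scale factors (α, 1/β) are omitted since the angle is
scale-invariant.

## Convolutional variant

Stride-1, zero-padded "same" convolutions with odd kernels; feedback is the
exact adjoint (transposed convolution, spatially flipped kernels) of the
forward kernel, gain fixed at 1 by default; one dense readout; hard-sigmoid
units; `h = 1`, so the Euler step becomes a damped synchronous map. No
pooling: the minimal EP-CNN lineage this follows uses learned dynamics
rather than pooling, and the benchmark protocol names only filter counts
and sizes — recorded as an approximation. Soft clamp only; the clamped
phase starts from the free-phase snapshot at `clamp_init_step` (110 of 130
in the full protocol), which plays the role of the teaching delay. Kernel
updates are the predictive-EP correlation summed over spatial positions
(weight sharing) and averaged over the batch. A 1×1-kernel network on 1×1
images reproduces the dense implementation exactly (up to float summation
order), which the test suite uses as an oracle for all phases and update
tensors.

## Synthetic data

`make_blobs` places `k` class centroids in the unit hypercube with pairwise
distance ≥ `separation · noise_sd` (rejection sampling; infeasible
geometries are detected by a cube-diameter check and a sphere-packing
bound) and adds isotropic Gaussian noise of SD `noise_sd`, so `separation`
is the centroid spacing in noise units and the pairwise Bayes error of
neighbouring classes is at most `Φ(−separation/2)`. Features are min-max
scaled to [0, 1] — the operating range of the sigmoid dynamics — and the
train/test split is stratified. Because centroids are sampled, typical
spacings exceed the minimum; difficulty is controlled by `noise_sd`
relative to the unit cube.

What the generator does *not* emulate: correlated pixel structure,
class-conditional manifolds, label noise, or the 784-dimensional scale of
the image benchmarks. Passing desk-scale tests therefore demonstrates the
mechanisms (stability, gradient alignment, directional benefit of
adaptation), not benchmark error rates.

## Desk-scale study conditions

The benchmark comparison (`eqadapt.experiments.adaptation_comparison`, also
behind `scripts/acceptance.py`) uses: blobs with `n = 800, d = 8, k = 4,
separation = 3, noise_sd = 0.35` (overlapping classes; a linear baseline
errs a few percent); network 8-16-4, `γ = 0.5`, sigmoid; predictive CHL
with hard clamp, 120 + 120 steps, 12-step delay, `h = 0.1`; adaptation 20
steps at `c = 0.1` versus `n_adapt = 0`; plain updates (no optimizer) at
base rate 1.0; batch 20; 30 epochs; 5 paired seeds.

Why no optimizer here: AdaGrad is invariant to a uniform rescaling of the
update stream, and adaptation's dominant first-order effect is precisely a
geometric rescaling of the clamped/free gaps — at this problem size AdaGrad
cancels it (the angle effect survives, the stability effect does not).
Plain updates expose the mechanism the adaptation is designed for: large
gaps produce abrupt weight jumps, visible as oscillating learning curves
and updates that decorrelate from backprop. The base rate 1.0 puts the
*unadapted* model in that jump-prone regime while the adapted model's
effective per-update scale, `(1−c)^20 ≈ 0.12`, lands at the classic 0.1.
This mirrors the optimizer-free training protocol of the convolutional
benchmark, applied to a dense network.

At this scale the error and smoothness advantages are real but noisy over
5 seeds; the gradient-alignment advantage (mean angles to backprop of
roughly 6°/8° with adaptation versus 55–70° without) is the robust
signature and holds for every seed tried.

## Numerical choices

* Fixed step counts, never tolerance-based early stopping; steady-state
  quality is verified separately (residual `‖−x + p(·)‖∞ < 1e−6` after
  relaxation, checked against an independent damped fixed-point solver).
* Activation boundary of the hard sigmoid assigned to the zero-derivative
  branch (affects only measure-zero inputs, stated for reproducibility).
* Angle computations clip cosines into [−1, 1] before `arccos`.
* Min-max scaling guards zero-range features (constant column → 0.5).
* Checkpoints are single HDF5 files (layer sizes, matrices, γ, activation,
  creating seed); schedules and run configs round-trip through YAML/JSON.

## Known limitations

* **The EP-vs-backprop angle is nearly independent of the nudging strength
  β.** The soft clamp adds `β(y − x_o)` *outside* the activation, so at the
  clamped fixed point the output gap is `(β/(1+β))(y − x̌_o)` — a uniform
  scalar times a β-independent direction — and the finite-β bias of the EP
  update relative to its own β→0 limit is tiny (≤ 0.25° at β = 1 on small
  networks, though perfectly monotone in β). Meanwhile the β→0 limit itself
  differs from the feedforward squared-error gradient by a per-output
  `p′(z_o)` weighting (the nudge bypasses the activation derivative),
  leaving a β-independent offset of ~1.8° median on random 3-4-2 networks.
  Consequently the angle to backprop does **not** grow measurably with β;
  the dedicated acceptance test states the idealised monotone property and
  fails, by design, to document this.
* Hidden units do not continue their relaxation dynamics during adaptation
  steps (pure geometric relaxation); the alternative concurrent-dynamics
  reading is not implemented.
* The feedforward BP reference ignores feedback and lateral terms, so for
  large `γ` part of the measured angle reflects architecture mismatch, not
  rule quality.
* No momentum/Adam, weight decay, augmentation, or early stopping; none
  are part of the protocols implemented.
* Full-scale image benchmarks are shipped as presets/scripts only and are
  not exercised by the test suite (external data, multi-hour compute).
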