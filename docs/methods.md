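# Methods

## Model

A binarized neural network (BNN) stores a real *hidden weight* `W^h` per
synapse and uses only its sign `W^b = sign(W^h)` — together with sign
activations — in the forward and backward passes; the sign non-linearity is
bridged by the straight-through estimator (STE), which passes the upstream
gradient where the pre-activation magnitude is at most 1 and blocks it
elsewhere. Training updates the hidden weights with gradients computed at the
binary point, so a synapse whose binary value is already correct keeps
receiving same-signed updates and its hidden weight grows without affecting
the loss. That growth is the consolidation signal.

Metaplastic training modifies one step of the standard Adam-BNN loop. Let
`U_W` be the Adam composite update for a hidden weight. If `U_W * W^b > 0`
(the update pushes the hidden weight back toward zero, i.e. toward a sign
flip), the applied update is attenuated:

    W^h  <-  W^h - eta * U_W * f_meta(m, W^h),      f_meta(m, x) = 1 - tanh^2(m x)

otherwise the update is applied in full. `f_meta` equals 1 at `m = 0` and at
`x = 0`, is even, has zero slope at the origin, and decays exponentially with
`|x|`; `m >= 0` is the only new hyper-parameter and `m = 0` reproduces plain
Adam-BNN training exactly (verified elementwise against an independent
implementation). Batch-norm parameters are real-valued and never attenuated.
The branch condition uses strict inequality, so a zero update is a no-op, and
`f_meta` is evaluated at the pre-update hidden value. A hard-zero variant
clips `f_meta` to exactly 0 beyond a threshold (default: the magnitude where
the smooth function falls below 1e-3), making consolidation definitive.

Numerical note: `1 - tanh^2` underflows to exactly 0 in float64 once
`|m x| > ~19`; `f_meta` is therefore computed as `sech^2` from exponentials,
which stays strictly positive to `|m x| ~ 350`, preserving the "any finite
weight can eventually flip" property at realistic magnitudes.

Hidden weights are deliberately *not* clipped to `[-1, 1]` (many BNN recipes
clip): unbounded growth carries the consolidation state. `sign(0) = +1` by
convention, binarization is deterministic, initialization is uniform on
`(-1/sqrt(fan_in), +1/sqrt(fan_in))`, the first layer consumes real inputs
scaled to `[-1, 1]`, and the output layer produces real scores. The
full-precision control network shares the whole code path but uses real
weights in both passes and a `tanh` hidden activation.

## Quadratic binary task

The tractable counterpart of BNN training: minimize
`L(W) = 1/2 (W - W*)^T H (W - W*)` (H symmetric positive definite) while
evaluating the gradient at `sign(W^h)`:

    W^h_{t+1} = W^h_t - eta * H (sign(W^h_t) - W*)

The quadratic form is the unique loss (up to a constant) whose gradient in
`W^b` matches this printed scheme. With diagonal `H = diag(lambda_i)`, any
coordinate with `|W*_i| > 1` diverges linearly with slope
`eta * lambda_i * (|W*_i| - 1) * sign(W*_i)`, and the loss increase from
flipping that coordinate approaches `2 lambda_i + 2 |slope_i| / eta` — for
the diagonal case this equals the exact flip delta `2 lambda_i |W*_i|` at
every step once the sign pattern settles, which is why the verification
errors are at rounding level rather than simulation level. Slopes are
estimated by least squares on the last half of the recorded trajectory; a
coordinate is flagged diverging when `|slope| > 1e-3 * eta * max_eig(H)`.

Random curvatures come from the subgroup algorithm: eigenvalues drawn from a
uniform or normal spec (non-positive draws resampled), a random rotation
built from a 2-D rotation lifted one dimension at a time through the
reflection `(I - 2 x x^T)` with `x = (e1 - v)/||e1 - v||`, `v` uniform on the
sphere; `H = R^T D R`.

The binned flip analysis sorts synapses into bins of `|W^h|` normalized by
the per-layer (or per-task) maximum. On the quadratic task each coordinate is
flipped alone; on a trained BNN a fixed number of weights per bin is flipped
simultaneously, the cost variation is normalized per flipped weight and
averaged over 100 random draws of the flipped set.

## Consolidation baselines

Elastic weight consolidation (EWC) adds `(lambda/2) * sum_i F_i (W^b_i -
W^b*_i)^2` per completed task, with `lambda = 5e3`; both the Fisher diagonal
`F` and the penalty use *binary* weight values (the network's response
depends on nothing else), and the penalty gradient reaches the hidden
weights through an identity straight-through pass. Since weights are binary,
each term is either 0 or `2 lambda F_i`. The Fisher diagonal is the mean of
squared log-likelihood gradients over minibatches of task data (100 batches
at the training batch size by default; the estimation batch is configurable
because squared minibatch gradients carry a `var/batch` sampling-noise floor
that flattens the importance distribution). One anchored penalty is kept per
past task. The random-consolidation control shuffles the importance multiset
uniformly across all synapses, anchors unchanged. The learning-rate-decay
control divides the learning rate by ten per task. The path-integral
(synaptic-intelligence-style) importance accumulates `-grad * delta_param`
per synapse and normalizes by squared total displacement plus damping 0.1;
on a BNN the binary displacement is in {0, +/-2}, so the importance
concentrates entirely on flipped synapses — the reason the method transfers
poorly to binary weights, reproduced here as a documented negative result.

## Synthetic task generator

The generator emulates the structure of the image benchmarks without
downloads: 10 Gaussian classes in 64 dimensions, labels by construction.
Half of the coordinates are informative (prototype entries ~ N(0, 1.4^2),
isotropic noise sd 2.0); the other half are constant zeros, like blank
image background. 200 training and 50 test examples per class; features
rescaled to `[-1, 1]`. Permuted tasks apply one fixed coordinate permutation
per task (task 0 is the identity), which relocates the informative set the
way pixel permutation does.

These choices are deliberate: separation/noise are set so a 2x128 BNN
reaches the low-to-mid 90s in percent with a *non-vanishing* loss (a
saturated, zero-gradient likelihood makes every Fisher estimate degenerate,
a regime the image benchmarks are not in), and the constant background gives
the heterogeneous, concentrated synaptic-importance structure that
importance-based consolidation relies on. What the generator does *not*
emulate: correlated pixel neighborhoods, within-class style variation,
class imbalance, and benchmark-scale overparameterization. The last point
matters for one result: with millions of synapses, importance is
concentrated in a tiny fraction of weights and randomly shuffled importance
collapses almost to the no-consolidation level; at desk scale the shuffled
control is several times worse than true Fisher EWC (and significantly so)
but retains more than its full-scale counterpart. Passing tests show the
mechanism and the ordering, not full-scale magnitudes.

## Study conditions (desk scale)

* **Retention grid** — 3 permuted tasks, 2x128 binary MLP, 40 epochs per
  task, batch 32, Adam lr 2e-2, task-specific batch-norm slots, m in
  {0, 0.5, 1.0, 1.35}, 5 seeds. The epoch count and learning rate put the
  product (steps per task) x (learning rate) near the regime of the
  full-scale experiments, where consistently reinforced hidden weights grow
  to several units and `m * |W^h|` reaches saturation depth; with much
  shorter tasks the consolidation mechanism has no room to act.
* **Baseline comparison** — same protocol at 2x256 and 25 epochs per task
  (the anchoring penalty needs no deep hidden-weight growth, and the
  Fisher-vs-shuffled contrast needs the wider net's importance
  concentration), methods: none / EWC / shuffled EWC / lr-decay, all at
  m=0, lambda = 5e3.
* **Stream learning** — one harder dataset (noise sd 2.5, 500 train per
  class), split into 20 stratified shards of 250 examples, 10 epochs per
  shard, m = 1.35, against (a) the same net on pooled data for an equal
  number of optimization steps and (b) the m=0 net on the same shards.
  Shard size is set so a single shard underdetermines the task while the
  pooled data supports high accuracy.
* **Quadratic-task verification** — diagonal d=20 (lambda in [0.5, 2],
  |W*| in [1.2, 3], eta 0.1, 1e4 steps), boundedness at 1e5 steps, and the
  binned analysis at d=500 (uniform eigenvalues in [0.5, 2], optima uniform
  in [-2, 2], 3000 steps, 10 bins).

## Design choices and degenerate inputs

* Attenuation multiplies the whole Adam composite update, not the raw
  gradient; the branch compares the update with `W^b`, not `W^h` (identical
  except at `W^h = 0`, where the `sign(0)=+1` convention decides).
* Batch norm keeps one complete state (affine + running statistics) per task
  slot; training with batch size 1 is an error (undefined variance). Stream
  learning uses a single common slot — no task boundaries exist there.
* Multi-task EWC keeps one quadratic penalty per past task rather than
  merging Fisher estimates; anchors from different tasks may disagree, in
  which case their forces partially cancel, which is the literal reading of
  per-task surrogate losses.
* The chain synapse (multi-timescale extension) attaches N=4 levels per
  synapse with couplings `g_k ∝ 2^{-2k}` (top coupling 0.01 per step);
  only the top level receives training updates and is read out. Stored
  consolidation leaks toward deeper, slower levels and back, producing
  steady-state forgetting (most recent tasks sharpest) instead of the
  capacity wall of the scalar synapse. The flow-modulation gain hook is
  neutral by default; the specific modulated rule of the full-scale variant
  is not claimed, only the mechanism class.
* Checkpoints are zip archives of raw arrays with fixed member order and
  zeroed timestamps, so save -> load -> save is byte-identical.
* Empty bins in the flip analysis are reported as missing (NaN), never as
  zero; Spearman correlations are computed over occupied bins only and are
  NaN when fewer than 3 bins are occupied or all means tie.

## Known limitations

* The conv stack (binary VGG-7) is fully constructible and differentiable
  but is not exercised at benchmark scale here; gradients are verified by
  finite differences on small instances.
* Importance-based results quote desk-scale magnitudes; see the generator
  section for which aspects scale and which do not.
* The SGD/momentum/RMSprop variants of the update rule are out of scope;
  Adam is the tested path.
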