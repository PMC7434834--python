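# Methods

## The model

`sctrnnpb` implements a stochastic continuous-time recurrent neural network
with parametric bias (S-CTRNNPB): a predictive-coding RNN that, at every
time step, predicts both the mean `y_t` and the variance `v_t` of its next
sensory input.  Neuron groups:

- **input** (N_I = 10): current sensory state `x_t` (8 joint angles + 2
  ball-position coordinates, all normalized to [-0.8, 0.8]);
- **context** (N_C = 100 full scale): leaky integrators,
  `u_t = (1/tau) (W_x x_t + W_c c_{t-1} + W_p p + b) + (1 - 1/tau) u_{t-1}`,
  `c_t = tanh(u_t)`, shared time constant tau = 4;
- **parametric bias** (N_P = 2): `u_t = u_{t-1}` — constant internal state
  within a sequence, optimized per sequence; `p = tanh(u)` is the network's
  latent "intention" (which behavior is being generated);
- **mean / variance** (N_M = N_V = 10): instantaneous readouts of the
  current context outputs, `y = tanh(u)`, `v = exp(u)`.

Learning minimizes the summed heteroscedastic Gaussian negative
log-likelihood (the precision-weighted prediction error)

    L_{t,i} = ln(2 pi v_{t,i})/2 + (yhat_{t,i} - y_{t,i})^2 / (2 v_{t,i}),
    L = sum_s sum_t sum_{i in mean dims} L_{t,i},

with one-step-ahead teacher forcing: the target at step t is the (noisy)
input at t+1 — the only alignment consistent with closed-loop generation,
where `y_t` is fed back as the next input.  Updates are momentum gradient
descent, `theta += delta`, `delta = -alpha dL/dtheta + eta delta_prev`,
with gradients by backpropagation through time.

**The manipulated variable** is the neuron-to-neuron variance k of the
context biases: `b_context ~ N(bias_mean, k)`, drawn once and *never
updated*, so k is the network's fixed heterogeneity of intrinsic
excitability.  k in {0.1, 1} is the homogeneous regime, {10, 100}
heterogeneous; k = 1000 typically fails to learn.  `bias_mean` is nonzero
only for the mean-excitability-shift control.

## Synthetic data

The generator replaces robot recordings with analytically defined periodic
waveforms that preserve the statistical structure the analysis needs: two
distinguishable periodic behaviors plus a known Gaussian noise floor.

- Proprioception: 8 phase-shifted raised-cosine bump trains; the behavior
  decides which half of the channels is the "active arm" (full amplitude
  0.8) versus idle (0.24).
- Vision: the horizontal ball coordinate dwells at the behavior's side and
  sweeps to the robot once per cycle; left/right are exact mirror images in
  that channel.  The depth coordinate is behavior-independent.
- Noise: i.i.d. N(0, 0.002) added to every element; results clipped at
  +/-0.999 (clip probability is negligible at these amplitudes).
- Splits: train sequences differ in noise realization only; test sequences
  additionally get a uniform integer phase jitter of +/-3 steps, emulating
  timing differences between recordings.  The jitter size is a config knob;
  whether the original test recordings differed in timing as well as noise
  is unknowable from the data, so this is a modeling choice.

What the generator does **not** emulate: contact dynamics (the scripted
ball ignores the arm), camera noise structure, kinematic correlations
between joints, or drift between recording sessions.  Passing tests
therefore show that the *analysis machinery* reproduces the phenomenon on
data with the right statistical skeleton, not that it would on any given
robot's recordings.

## Scales

Full scale (the robot experiment's protocol): T = 1,060 steps (10 cycles of 106), 3 train +
3 test sequences per behavior, N_C = 100, 300,000 epochs.  This is
available through the config but takes CPU-days.

Desk scale (package default for tests and the acceptance script): cycle 40,
5 cycles (T = 200), 2 train + 2 test per behavior, N_C = 30, 40,000
epochs.  The time-scale ratio T >> tau is preserved.  A full desk sweep
(4 + 2 + 4 + 2 replicates over k = 0.1, 1, 10, 100) trains in roughly 10
CPU-minutes with the numba kernels.

## Optimization at desk scale

Two numerical guards beyond plain momentum descent proved necessary:

1. **Variance cap with straight-through gradient.**  Variance internal
   states are clipped to +/-20 before `exp`.  The clip's gradient is
   treated as identity: computed at the clipped `v`, so an excursion past
   the cap is pushed back.  A masked (true-zero) gradient makes the cap an
   absorbing state: one overshoot pins `v` at `e^{+/-20}`, precision
   `1/v` explodes the mean-pathway gradients, and the run dies.

2. **Learning rate and gradient-norm clip.**  Full-batch descent
   sums the loss over sequences x steps x dimensions, so the gradient
   magnitude scales with the data volume, and the stable learning rate
   scales inversely with it.  At desk scale the full-scale rate
   alpha = 1e-4 diverges within tens of epochs (the variance pathway
   undershoots, precision explodes, tanh units saturate irrecoverably).
   The desk default is alpha = 3e-6 with momentum eta = 0.9 — the largest
   rate that converges reliably across seeds — plus a global
   gradient-norm clip of 2e4, which sits above the typical converged
   gradient norm (1e3-1e4; precision weighting keeps gradients large even
   at the optimum) and only truncates the rare spikes that otherwise
   kill a small fraction of runs.  Both guards leave converged behavior
   unchanged: the clip is inactive in equilibrium, and the cap region is
   never visited by a healthy run.

Training is strict full-batch (one update per epoch on the summed
gradient, no shuffling), loss is logged every 100 epochs, and runs whose
loss goes non-finite abort with the epoch index.  Divergent runs inside a
sweep are recorded and skipped.

## Real-time adaptation (postdiction)

During interaction only the PB internal state adapts; weights are frozen.
At step t, the window [t-W+1, t] (W = 10) is regenerated closed-loop from
frozen anchors and the precision-weighted error of the regenerated vision
predictions against the buffered observations is backpropagated — through
the entire closed-loop graph, including the prediction-to-input feedback —
to the PB state, which takes `pb_updates_per_step` = 50 momentum steps.

Anchor choices the source text leaves open, fixed here as:

- the **context anchor** at the window start is the context internal state
  logged when that step was the current step (frozen pre-window context;
  postdiction happens only inside the window);
- the joint input at the window start is the logged mean prediction of the
  previous step; the vision input is the observation at the window start;
- with these anchors a window of W observations yields W-1 regenerated
  prediction steps, hence W-1 error terms;
- the error sum runs over the vision dimensions (the operative
  description), with an `error_dims="all"` option;
- PB momentum velocity persists across time steps within a trial;
- for the first W steps (warm-up) the PB state is held at its initial
  value while observations accumulate.

The virtual environment is open-loop: the scripted ball follows the active
behavior's vision template (situation switches exactly once, at step 120
of 300) and ignores the joint commands.  Task success is therefore judged
by trajectory similarity, not ball physics — consistent with the
PB-at-trial-end flexibility criterion, which is physics-free anyway.

## Evaluation

- **Similarity score (SS):** each dimension's series is compressed along
  time into a histogram on (-1, 1) with N_bin = 50 bins; SS is the summed
  per-dimension KL divergence, computed over the joint (proprioceptive)
  dimensions as the decision variable, with the all-dimension variant
  always reported alongside.  Histograms get a Laplace pseudo-count of
  1e-6 per bin before normalization — unsmoothed KL is infinite whenever
  the reference misses a bin, and the source text does not address empty
  bins.
- **Success threshold:** xi = 0.5 x the minimum SS over ordered
  cross-behavior pairs of training sequences (same-behavior pairs
  excluded, following the subscripts of the defining expression).
- **Mental simulation:** one closed-loop trial per training sequence,
  started from the sequence's first state with its trained PB; success iff
  SS against the behavior's best-matching training sequence (best-match,
  since the per-trial correspondence is not specified) is below xi.
- **Flexibility:** closed-loop generation from the PB state at trial end
  must match the post-switch behavior's training data (SS < xi).
- **Generalization:** in place of the ball-over-the-line criterion (which
  needs contact physics), the joint commands of the pre-switch phase are
  compared against the initial behavior's training data (SS < xi).
- **Overfitting metrics:** open-loop mean squared error ("prediction
  error" is taken as *squared* error, consistent with the Gaussian
  likelihood) and mean predicted variance, averaged over steps x
  dimensions x sequences, per split.
- **PB maps:** open-loop training error on a 41 x 41 grid of PB
  activities (atanh-converted to internal states; |p| >= 1 nodes
  excluded).  The "area" of a behavior's representation is the fraction
  of cells with error below 2 x the map minimum — a relative threshold,
  since absolute error levels differ across conditions.
- **Weight statistics:** std and fraction of |w| < 0.01 of the pooled
  context-to-context weights.
- **Periodicity:** per-neuron ratio of spectral power within +/-1 bin of
  the template frequency to total non-DC power.

## Known limitations

- The desk-scale learning rate and epoch count were chosen for optimizer
  stability, not matched to the original training budget; absolute error
  and variance levels at convergence depend on both.
- The homogeneous/heterogeneous contrast in train/test error is present
  but weaker at desk scale than the published full-scale contrast; the
  orderings are asserted on condition means over replicates.
- The scripted environment cannot test true sensorimotor generalization —
  only pattern-similarity generalization.
- Checkpoints are NPZ + JSON (bit-exact round-trip); HDF5 is not used.
- The in-silico generalization judgment (similarity of pre-switch joint
  commands to training data) is phase-insensitive by construction: a
  network that mistimes an otherwise intact motor pattern still matches
  the training-state distribution and passes.  The homogeneous condition's
  generalization deficit in a physical ball-return task (mistimed contact)
  is therefore outside what this criterion can detect, and at desk scale
  both conditions pass it at ceiling; the flexibility, error, variance,
  weight-structure and PB-map contrasts carry the condition comparison.
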