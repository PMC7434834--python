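"""S-CTRNNPB core: forward dynamics, heteroscedastic NLL, BPTT, momentum GD.

The stochastic continuous-time RNN with parametric bias predicts the mean
``y`` and variance ``v`` of its next sensory input.  Context neurons are
leaky integrators with time constant tau; parametric-bias (PB) neurons hold
a constant internal state within a sequence (infinite time constant) that is
optimized per sequence and acts as the network's latent behavior label.
Training minimizes the summed Gaussian negative log-likelihood

    L_{t,i} = ln(2 pi v_{t,i}) / 2 + (yhat_{t,i} - y_{t,i})^2 / (2 v_{t,i}),

i.e. the precision-weighted prediction error, by momentum gradient descent.
Context-neuron biases are drawn once from N(bias_mean, k) and never updated:
their neuron-to-neuron variance k is the experiment's "heterogeneity of
intrinsic excitability" manipulation.

The functions here are a plain-numpy reference implementation; the training
and real-time adaptation loops use equivalent numba kernels in
:mod:`sctrnnpb._kernels` for speed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, fields, replace
from pathlib import Path

import numpy as np

#: Internal states of variance neurons are clipped to +/-VARIANCE_CAP before
#: exponentiation.  The clip's gradient is treated as identity
#: (straight-through), so an excursion beyond the cap is actively pushed
#: back instead of being frozen there.
VARIANCE_CAP = 20.0


@dataclass(frozen=True)
class ModelConfig:
    """Architecture and optimization settings.

    Defaults are the full-scale experiment: 10 input/mean/variance neurons,
    100 context neurons with tau=4, 2 PB neurons, learning rate 1e-4,
    momentum 0.9, 300,000 epochs, adaptation window W=10 with 50 PB updates
    per step.  ``bias_variance_k`` is the heterogeneity parameter k;
    ``bias_mean`` is nonzero only for the mean-excitability-shift control.
    """

    n_input: int = 10
    n_mean: int = 10
    n_variance: int = 10
    n_context: int = 100
    n_pb: int = 2
    tau: float = 4.0
    alpha: float = 1e-4
    eta: float = 0.9
    bias_mean: float = 0.0
    bias_variance_k: float = 10.0
    n_epochs: int = 300_000
    window_W: int = 10
    pb_updates_per_step: int = 50
    grad_clip_norm: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.tau < 1:
            raise ValueError(f"tau must be >= 1, got {self.tau}")
        if self.alpha <= 0:
            raise ValueError(f"alpha must be > 0, got {self.alpha}")
        if not (0 <= self.eta < 1):
            raise ValueError(f"eta must lie in [0, 1), got {self.eta}")
        if self.bias_variance_k < 0:
            raise ValueError(
                f"bias_variance_k must be >= 0, got {self.bias_variance_k}")
        if self.grad_clip_norm < 0:
            raise ValueError(
                f"grad_clip_norm must be >= 0 (0 disables), got {self.grad_clip_norm}")
        if not (self.n_mean == self.n_variance == self.n_input):
            raise ValueError("n_mean, n_variance and n_input must be equal")
        for name in ("n_input", "n_context", "n_pb", "window_W",
                     "pb_updates_per_step", "n_epochs"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")


def desk_config(k: float = 10.0, **overrides) -> ModelConfig:
    """Desk-scale config: 30 context neurons, 40,000 epochs.

    The learning rate is scaled down to 3e-6: the update acts on the
    *summed* gradient, whose magnitude grows with the data volume, and the
    momentum iteration at the full-scale rate diverges at this scale.  The
    gradient-norm clip (2e4) sits above typical converged gradient norms
    and only removes the rare spikes that can otherwise saturate a run
    irrecoverably.
    """
    kw = dict(n_context=30, n_epochs=40_000, bias_variance_k=k,
              alpha=3e-6, grad_clip_norm=2e4)
    kw.update(overrides)
    return ModelConfig(**kw)


@dataclass
class NetworkParameters:
    """All weights and biases; ``b_context`` is fixed after initialization."""

    W_input_to_context: np.ndarray      # (n_context, n_input)
    W_context_to_context: np.ndarray    # (n_context, n_context)
    W_pb_to_context: np.ndarray         # (n_context, n_pb)
    W_context_to_mean: np.ndarray       # (n_mean, n_context)
    W_context_to_variance: np.ndarray   # (n_variance, n_context)
    b_context: np.ndarray               # (n_context,) FIXED
    b_mean: np.ndarray                  # (n_mean,)
    b_variance: np.ndarray              # (n_variance,)
    u0_pb: np.ndarray                   # (n_sequences, n_pb)
    tau: np.ndarray                     # (n_context,)

    TRAINABLE = ("W_input_to_context", "W_context_to_context",
                 "W_pb_to_context", "W_context_to_mean",
                 "W_context_to_variance", "b_mean", "b_variance", "u0_pb")

    @property
    def n_context(self) -> int:
        return self.b_context.shape[0]

    @property
    def n_input(self) -> int:
        return self.W_input_to_context.shape[1]

    @property
    def n_mean(self) -> int:
        return self.W_context_to_mean.shape[0]

    @property
    def n_pb(self) -> int:
        return self.W_pb_to_context.shape[1]

    def copy(self) -> "NetworkParameters":
        return NetworkParameters(**{f.name: getattr(self, f.name).copy()
                                    for f in fields(self)})


@dataclass
class Gradients:
    """Gradients (or momentum velocities) for the trainable parameter subset.

    There is deliberately no ``b_context`` field: context biases are outside
    the update path entirely, not merely zero-gradient.
    """

    W_input_to_context: np.ndarray
    W_context_to_context: np.ndarray
    W_pb_to_context: np.ndarray
    W_context_to_mean: np.ndarray
    W_context_to_variance: np.ndarray
    b_mean: np.ndarray
    b_variance: np.ndarray
    u0_pb: np.ndarray

    @classmethod
    def zeros_like(cls, params: NetworkParameters) -> "Gradients":
        return cls(**{name: np.zeros_like(getattr(params, name))
                      for name in NetworkParameters.TRAINABLE})

    def max_abs(self) -> float:
        return max(float(np.max(np.abs(getattr(self, f.name))))
                   for f in fields(self))


@dataclass
class NetworkState:
    """Instantaneous state of one forward pass."""

    u_context: np.ndarray
    c: np.ndarray
    u_pb: np.ndarray
    p: np.ndarray
    y: np.ndarray
    v: np.ndarray


@dataclass
class PredictionTrace:
    """Per-step record of one open- or closed-loop run (T-1 prediction steps)."""

    y: np.ndarray          # (Tp, n_mean)
    v: np.ndarray          # (Tp, n_variance)
    c: np.ndarray          # (Tp, n_context)
    u_context: np.ndarray  # (Tp, n_context)
    p: np.ndarray          # (n_pb,)
    loss: np.ndarray | None  # (Tp, n_mean); None for closed loop without targets
    mode: str = "open_loop"

    @property
    def n_steps(self) -> int:
        return self.y.shape[0]


def init_parameters(config: ModelConfig, rng: np.random.Generator | int,
                    n_sequences: int = 1) -> NetworkParameters:
    """Draw initial parameters.

    Synaptic weights are uniform on [-1/sqrt(N_src), 1/sqrt(N_src)] where
    N_src is the source-layer size (inputs: N_I; context/PB sources and the
    context-to-output weights: N_C).  Mean/variance biases are uniform on
    [-1, 1].  Context biases are N(bias_mean, k) and FIXED thereafter.
    PB initial internal states are zero, one row per training sequence.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    nc, ni, npb = config.n_context, config.n_input, config.n_pb
    bi = 1.0 / np.sqrt(ni)
    bc = 1.0 / np.sqrt(nc)
    k = config.bias_variance_k
    if k > 0:
        b_context = rng.normal(config.bias_mean, np.sqrt(k), size=nc)
    else:
        b_context = np.full(nc, config.bias_mean, dtype=float)
    return NetworkParameters(
        W_input_to_context=rng.uniform(-bi, bi, size=(nc, ni)),
        W_context_to_context=rng.uniform(-bc, bc, size=(nc, nc)),
        W_pb_to_context=rng.uniform(-bc, bc, size=(nc, npb)),
        W_context_to_mean=rng.uniform(-bc, bc, size=(config.n_mean, nc)),
        W_context_to_variance=rng.uniform(-bc, bc, size=(config.n_variance, nc)),
        b_context=b_context,
        b_mean=rng.uniform(-1.0, 1.0, size=config.n_mean),
        b_variance=rng.uniform(-1.0, 1.0, size=config.n_variance),
        u0_pb=np.zeros((n_sequences, npb)),
        tau=np.full(nc, float(config.tau)),
    )


def initial_state(params: NetworkParameters, u0_pb: np.ndarray) -> NetworkState:
    """State before the first step: zero context internal states."""
    u_pb = np.asarray(u0_pb, dtype=float).reshape(-1)
    nc = params.n_context
    return NetworkState(
        u_context=np.zeros(nc), c=np.zeros(nc),
        u_pb=u_pb.copy(), p=np.tanh(u_pb),
        y=np.zeros(params.n_mean), v=np.ones(params.n_mean))


def forward_step(params: NetworkParameters, state: NetworkState,
                 x_t: np.ndarray) -> NetworkState:
    """One step of the forward dynamics.

    PB internal states pass through unchanged; context neurons leak-integrate
    their synaptic drive with time constant tau; mean and variance neurons
    read the *current* context outputs.
    """
    x_t = np.asarray(x_t, dtype=float)
    if x_t.shape != (params.n_input,):
        raise ValueError(
            f"input must have shape ({params.n_input},), got {x_t.shape}")
    if not np.all(np.isfinite(x_t)):
        raise ValueError("input must be finite")
    inv_tau = 1.0 / params.tau
    h = (params.W_input_to_context @ x_t
         + params.W_context_to_context @ state.c
         + params.W_pb_to_context @ state.p
         + params.b_context)
    u = inv_tau * h + (1.0 - inv_tau) * state.u_context
    c = np.tanh(u)
    u_y = params.W_context_to_mean @ c + params.b_mean
    y = np.tanh(u_y)
    u_v = params.W_context_to_variance @ c + params.b_variance
    v = np.exp(np.clip(u_v, -VARIANCE_CAP, VARIANCE_CAP))
    return NetworkState(u_context=u, c=c, u_pb=state.u_pb.copy(),
                        p=state.p.copy(), y=y, v=v)


def stepwise_nll(y: np.ndarray, v: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Per-dimension Gaussian negative log-likelihood.

    May legitimately be negative when v < 1/(2 pi).
    """
    y, v, target = (np.asarray(a, dtype=float) for a in (y, v, target))
    if np.any(v <= 0):
        raise ValueError("predicted variance must be strictly positive")
    return 0.5 * np.log(2.0 * np.pi * v) + (target - y) ** 2 / (2.0 * v)


def sequence_nll(traces) -> float:
    """Total loss: plain sum over sequences, steps and mean dimensions."""
    if isinstance(traces, PredictionTrace):
        traces = [traces]
    total = 0.0
    for trace in traces:
        if trace.loss is None:
            raise ValueError("trace has no targets, so no loss")
        total += float(np.sum(trace.loss))
    return total


def _as_values(seq) -> np.ndarray:
    return seq.values if hasattr(seq, "values") else np.asarray(seq, dtype=float)


def run_open_loop(params: NetworkParameters, u0_pb: np.ndarray,
                  seq) -> PredictionTrace:
    """Teacher-driven pass: input seq[t], target seq[t+1], T-1 steps."""
    X = _as_values(seq)
    T = X.shape[0]
    if T < 2:
        raise ValueError("open-loop run needs a sequence of length >= 2")
    state = initial_state(params, u0_pb)
    Tp = T - 1
    ys = np.empty((Tp, params.n_mean))
    vs = np.empty((Tp, params.n_mean))
    cs = np.empty((Tp, params.n_context))
    us = np.empty((Tp, params.n_context))
    for t in range(Tp):
        state = forward_step(params, state, X[t])
        ys[t], vs[t], cs[t], us[t] = state.y, state.v, state.c, state.u_context
    loss = stepwise_nll(ys, vs, X[1:])
    return PredictionTrace(y=ys, v=vs, c=cs, u_context=us, p=state.p,
                           loss=loss, mode="open_loop")


def run_closed_loop(params: NetworkParameters, u0_pb: np.ndarray,
                    x0: np.ndarray, T: int) -> PredictionTrace:
    """Mental simulation: the mean prediction is fed back as the next input."""
    if T < 1:
        raise ValueError("closed-loop run needs T >= 1")
    state = initial_state(params, u0_pb)
    x = np.asarray(x0, dtype=float)
    ys = np.empty((T, params.n_mean))
    vs = np.empty((T, params.n_mean))
    cs = np.empty((T, params.n_context))
    us = np.empty((T, params.n_context))
    for t in range(T):
        state = forward_step(params, state, x)
        ys[t], vs[t], cs[t], us[t] = state.y, state.v, state.c, state.u_context
        x = state.y
    return PredictionTrace(y=ys, v=vs, c=cs, u_context=us, p=state.p,
                           loss=None, mode="closed_loop")


def closed_loop_batch(params: NetworkParameters, U0: np.ndarray,
                      X0: np.ndarray, T: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized closed-loop generation for B (PB, initial input) pairs.

    Returns (Y, V, C) with shapes (B, T, n_mean/n_mean/n_context).
    """
    U0 = np.atleast_2d(np.asarray(U0, dtype=float))
    X0 = np.atleast_2d(np.asarray(X0, dtype=float))
    B = U0.shape[0]
    if X0.shape[0] == 1 and B > 1:
        X0 = np.broadcast_to(X0, (B, X0.shape[1]))
    inv_tau = 1.0 / params.tau
    one_m = 1.0 - inv_tau
    P = np.tanh(U0)
    hpb = P @ params.W_pb_to_context.T + params.b_context
    U = np.zeros((B, params.n_context))
    C = np.zeros((B, params.n_context))
    x = np.array(X0, dtype=float)
    Y = np.empty((B, T, params.n_mean))
    V = np.empty((B, T, params.n_mean))
    Cs = np.empty((B, T, params.n_context))
    for t in range(T):
        H = x @ params.W_input_to_context.T + C @ params.W_context_to_context.T + hpb
        U = inv_tau * H + one_m * U
        C = np.tanh(U)
        y = np.tanh(C @ params.W_context_to_mean.T + params.b_mean)
        uv = C @ params.W_context_to_variance.T + params.b_variance
        V[:, t] = np.exp(np.clip(uv, -VARIANCE_CAP, VARIANCE_CAP))
        Y[:, t] = y
        Cs[:, t] = C
        x = y
    return Y, V, Cs


def open_loop_batch(params: NetworkParameters, U0: np.ndarray,
                    X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized teacher-driven pass for B PB vectors sharing one input
    sequence X of shape (T, n_input).  Returns (Y, V) of shape (B, T-1, n_mean)."""
    U0 = np.atleast_2d(np.asarray(U0, dtype=float))
    B = U0.shape[0]
    X = np.asarray(X, dtype=float)
    Tp = X.shape[0] - 1
    inv_tau = 1.0 / params.tau
    one_m = 1.0 - inv_tau
    P = np.tanh(U0)
    hpb = P @ params.W_pb_to_context.T + params.b_context
    U = np.zeros((B, params.n_context))
    C = np.zeros((B, params.n_context))
    Y = np.empty((B, Tp, params.n_mean))
    V = np.empty((B, Tp, params.n_mean))
    for t in range(Tp):
        hx = params.W_input_to_context @ X[t]
        H = hx[None, :] + C @ params.W_context_to_context.T + hpb
        U = inv_tau * H + one_m * U
        C = np.tanh(U)
        Y[:, t] = np.tanh(C @ params.W_context_to_mean.T + params.b_mean)
        uv = C @ params.W_context_to_variance.T + params.b_variance
        V[:, t] = np.exp(np.clip(uv, -VARIANCE_CAP, VARIANCE_CAP))
    return Y, V


def dataset_nll(params: NetworkParameters, sequences) -> float:
    """Total summed NLL of the current parameters on a list of sequences."""
    total = 0.0
    for s, seq in enumerate(sequences):
        trace = run_open_loop(params, params.u0_pb[s], seq)
        total += float(np.sum(trace.loss))
    return total


def bptt_gradients(params: NetworkParameters, sequences) -> Gradients:
    """Backpropagation through time of the summed NLL.

    ``sequences`` is an ordered list (SensorySequence or raw arrays); row s
    of ``params.u0_pb`` belongs to sequence s.  Gradients are exact
    derivatives of :func:`dataset_nll`; the context-bias gradient is not
    produced at all.
    """
    if len(sequences) == 0:
        raise ValueError("dataset must contain at least one sequence")
    if params.u0_pb.shape[0] < len(sequences):
        raise ValueError("params.u0_pb has fewer rows than there are sequences")
    grads = Gradients.zeros_like(params)
    inv_tau = 1.0 / params.tau
    one_m = 1.0 - inv_tau
    for s, seq in enumerate(sequences):
        X = _as_values(seq)
        Tp = X.shape[0] - 1
        p = np.tanh(params.u0_pb[s])
        # forward, storing what backward needs
        u = np.zeros(params.n_context)
        c = np.zeros(params.n_context)
        C = np.empty((Tp, params.n_context))
        Y = np.empty((Tp, params.n_mean))
        Vv = np.empty((Tp, params.n_mean))
        hpb = params.W_pb_to_context @ p + params.b_context
        for t in range(Tp):
            h = params.W_input_to_context @ X[t] + params.W_context_to_context @ c + hpb
            u = inv_tau * h + one_m * u
            c = np.tanh(u)
            C[t] = c
            uy = params.W_context_to_mean @ c + params.b_mean
            Y[t] = np.tanh(uy)
            uv = params.W_context_to_variance @ c + params.b_variance
            Vv[t] = np.exp(np.clip(uv, -VARIANCE_CAP, VARIANCE_CAP))
        # backward
        du_next = np.zeros(params.n_context)
        dp = np.zeros(params.n_pb)
        for t in range(Tp - 1, -1, -1):
            y, v, c = Y[t], Vv[t], C[t]
            e = y - X[t + 1]
            gy = (e / v) * (1.0 - y * y)
            # straight-through gradient at the variance cap: evaluated with
            # the clipped v, so an overshoot beyond the cap is pushed back
            # rather than frozen (the cap must not be an absorbing state)
            gv = 0.5 * (1.0 - e * e / v)
            dc = (params.W_context_to_mean.T @ gy
                  + params.W_context_to_variance.T @ gv
                  + params.W_context_to_context.T @ (du_next * inv_tau))
            du = (1.0 - c * c) * dc + one_m * du_next
            r = du * inv_tau
            grads.W_context_to_mean += np.outer(gy, c)
            grads.b_mean += gy
            grads.W_context_to_variance += np.outer(gv, c)
            grads.b_variance += gv
            grads.W_input_to_context += np.outer(r, X[t])
            c_prev = C[t - 1] if t > 0 else np.zeros_like(c)
            grads.W_context_to_context += np.outer(r, c_prev)
            grads.W_pb_to_context += np.outer(r, p)
            dp += params.W_pb_to_context.T @ r
            du_next = du
        grads.u0_pb[s] = (1.0 - p * p) * dp
    for f in fields(grads):
        if not np.all(np.isfinite(getattr(grads, f.name))):
            raise FloatingPointError(f"non-finite gradient in {f.name}")
    return grads


def apply_momentum_update(params: NetworkParameters, gradients: Gradients,
                          velocity: Gradients, alpha: float, eta: float
                          ) -> tuple[NetworkParameters, Gradients]:
    """theta += delta;  delta = -alpha * grad + eta * delta_prev.

    Updates in place and returns (params, velocity).  ``b_context`` and
    ``tau`` are untouched by construction: Gradients has no such fields.
    """
    for name in NetworkParameters.TRAINABLE:
        g = getattr(gradients, name)
        d = getattr(velocity, name)
        theta = getattr(params, name)
        if g.shape != theta.shape:
            raise ValueError(f"shape mismatch for {name}: "
                             f"{g.shape} vs {theta.shape}")
        d *= eta
        d -= alpha * g
        theta += d
    return params, velocity


def save_checkpoint(path: str | Path, params: NetworkParameters,
                    config: ModelConfig, extra: dict | None = None) -> None:
    """NPZ archive + JSON sidecar; round-trips bit-exactly."""
    path = Path(path)
    arrays = {f.name: getattr(params, f.name) for f in fields(params)}
    np.savez(path.with_suffix(".npz"), **arrays)
    sidecar = {"config": vars(config).copy(), "extra": extra or {}}
    with open(path.with_suffix(".json"), "w") as fh:
        json.dump(sidecar, fh, indent=2)


def load_checkpoint(path: str | Path) -> tuple[NetworkParameters, ModelConfig, dict]:
    path = Path(path)
    with np.load(path.with_suffix(".npz")) as archive:
        params = NetworkParameters(**{k: archive[k] for k in archive.files})
    with open(path.with_suffix(".json")) as fh:
        sidecar = json.load(fh)
    return params, ModelConfig(**sidecar["config"]), sidecar.get("extra", {})
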