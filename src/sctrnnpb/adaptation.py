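"""Real-time intention inference: sliding-window PB updates (postdiction).

During interaction all synaptic weights are frozen; only the PB internal
state (the network's "intention") is optimized, by gradient descent with
momentum on the precision-weighted prediction error of the last W steps.
Each time step, the window [t-W+1, t] is regenerated closed-loop from
frozen anchors (the logged context state at t-W, the logged mean joint
prediction at t-W and the observed ball position at t-W+1) under the
current PB state; the error of the regenerated vision predictions against
the buffered observations is backpropagated through the whole closed-loop
graph to the PB state.  Because the regeneration re-interprets *past* steps
with the present intention, this is a postdiction process.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import model as _m
from ._kernels import adapt_pb, window_forward
from .model import ModelConfig, NetworkParameters
from .synthetic import VirtualEnvironment


@dataclass
class WindowBuffer:
    """Frozen anchors + observations for one sliding-window PB update."""

    anchor_context: np.ndarray   # context internal state at t-W
    anchor_input: np.ndarray     # [joints: mean prediction at t-W, vision: obs at t-W+1]
    observations: np.ndarray     # (W-1, n_err) observed error-dim values, t-W+2 .. t
    u_pb: np.ndarray             # current PB internal state (updated in place)
    velocity: np.ndarray         # PB momentum velocity (updated in place)
    error_lo: int                # error dims are [error_lo:n_input]

    def __post_init__(self) -> None:
        if self.observations.ndim != 2 or self.observations.shape[0] < 1:
            raise ValueError("observations must be a non-empty (K, n_err) array")
        n_err = self.anchor_input.shape[0] - self.error_lo
        if self.observations.shape[1] != n_err:
            raise ValueError(
                f"observations have {self.observations.shape[1]} dims, "
                f"expected {n_err} (error_lo={self.error_lo})")


@dataclass
class InteractionTrial:
    """Log of one simulated real-time interaction."""

    observations: np.ndarray    # (L, n_vision)
    commands: np.ndarray        # (L, n_joints) mean proprioceptive predictions
    pb: np.ndarray              # (L, n_pb) PB activity after each step's update
    windowed_error: np.ndarray  # (L,) precision-weighted window loss (nan in warm-up)
    situations: list[str]
    switch_step: int
    initial_behavior: str
    u_pb_final: np.ndarray = field(default=None)

    @property
    def n_steps(self) -> int:
        return self.observations.shape[0]

    def to_csv(self, path) -> None:
        L = self.n_steps
        cols = [self.observations, self.commands, self.pb,
                self.windowed_error[:, None]]
        names = ([f"obs_{i}" for i in range(self.observations.shape[1])]
                 + [f"cmd_{i}" for i in range(self.commands.shape[1])]
                 + [f"pb_{i}" for i in range(self.pb.shape[1])]
                 + ["windowed_error"])
        np.savetxt(path, np.hstack(cols), delimiter=",",
                   header=",".join(names), comments="")


def window_loss(params: NetworkParameters, buffer: WindowBuffer,
                u_pb: np.ndarray | None = None) -> float:
    """Windowed precision-weighted error under a PB state (no update).

    Pure function used both for logging and as the quantity whose gradient
    drives :func:`adapt_pb_window`; finite-difference tests differentiate
    this directly.
    """
    u_pb = buffer.u_pb if u_pb is None else np.asarray(u_pb, dtype=float)
    K = buffer.observations.shape[0]
    _, _, Y, V, _ = window_forward(
        params.W_input_to_context, params.W_context_to_context,
        params.W_pb_to_context, params.W_context_to_mean,
        params.W_context_to_variance, params.b_context, params.b_mean,
        params.b_variance, params.tau, buffer.anchor_context,
        buffer.anchor_input, u_pb, K, _m.VARIANCE_CAP)
    lo = buffer.error_lo
    err = Y[:, lo:] - buffer.observations
    return float(np.sum(0.5 * np.log(2.0 * np.pi * V[:, lo:])
                        + err**2 / (2.0 * V[:, lo:])))


def adapt_pb_window(params: NetworkParameters, buffer: WindowBuffer,
                    iterations: int, alpha: float, eta: float) -> np.ndarray:
    """Run ``iterations`` momentum updates of the PB state on one window.

    Mutates ``buffer.u_pb`` and ``buffer.velocity``; returns the updated
    PB internal state.  The update reads only the buffer contents — never
    observations beyond it.
    """
    if iterations < 1:
        raise ValueError("iterations must be >= 1")
    adapt_pb(params.W_input_to_context, params.W_context_to_context,
             params.W_pb_to_context, params.W_context_to_mean,
             params.W_context_to_variance, params.b_context, params.b_mean,
             params.b_variance, params.tau, buffer.anchor_context,
             buffer.anchor_input, buffer.observations, buffer.error_lo,
             buffer.u_pb, buffer.velocity, iterations, alpha, eta,
             _m.VARIANCE_CAP)
    return buffer.u_pb


def run_interaction_trial(params: NetworkParameters, config: ModelConfig,
                          env: VirtualEnvironment, initial_u0_pb: np.ndarray,
                          initial_joints: np.ndarray,
                          error_dims: str = "vision") -> InteractionTrial:
    """Simulated real-time interaction with PB inference at every step.

    The robot's intention starts at ``initial_u0_pb`` (the trained PB state
    of a learned behavior).  At each step the environment's ball position is
    observed, the PB state is updated ``config.pb_updates_per_step`` times
    on the sliding window (after a W-1-step warm-up during which PB is
    held), and the joint command for the next step is the mean
    proprioceptive prediction.  Weights stay frozen throughout.
    """
    if error_dims not in ("vision", "all"):
        raise ValueError("error_dims must be 'vision' or 'all'")
    W = config.window_W
    L = env.state.trial_length
    nv = env.vision_dim
    ni = params.n_input
    nj = ni - nv
    err_lo = nj if error_dims == "vision" else 0

    u_pb = np.asarray(initial_u0_pb, dtype=float).copy()
    vel = np.zeros_like(u_pb)
    inv_tau = 1.0 / params.tau

    obs_log = np.zeros((L, nv))
    cmd_log = np.zeros((L, nj))
    pb_log = np.zeros((L, params.n_pb))
    werr_log = np.full(L, np.nan)
    ctx_log = np.zeros((L, params.n_context))   # context internal state after step t
    pred_log = np.zeros((L, ni))                # mean prediction emitted at step t

    weights_before = params.W_context_to_context.copy()
    cmd = np.asarray(initial_joints, dtype=float).copy()
    u_prev = np.zeros(params.n_context)
    c_prev = np.zeros(params.n_context)

    for t in range(L):
        o_t = env.step(cmd)
        obs_log[t] = o_t
        joints_in = cmd
        u_start = None
        if t >= W:
            anchor_input = np.concatenate([pred_log[t - W][:nj],
                                           obs_log[t - W + 1]])
            if error_dims == "vision":
                window_obs = obs_log[t - W + 2: t + 1]
            else:
                window_obs = np.hstack([pred_log[t - W + 1: t][:, :nj],
                                        obs_log[t - W + 2: t + 1]])
            buffer = WindowBuffer(anchor_context=ctx_log[t - W].copy(),
                                  anchor_input=anchor_input,
                                  observations=np.ascontiguousarray(window_obs),
                                  u_pb=u_pb, velocity=vel, error_lo=err_lo)
            adapt_pb_window(params, buffer, config.pb_updates_per_step,
                            config.alpha, config.eta)
            werr_log[t] = window_loss(params, buffer)
            if not np.all(np.isfinite(u_pb)):
                raise FloatingPointError(f"PB state non-finite at step {t}")
            # regenerate the window under the final PB to obtain the
            # postdicted context state and joint estimate for time t
            U, _, Y, _, _ = window_forward(
                params.W_input_to_context, params.W_context_to_context,
                params.W_pb_to_context, params.W_context_to_mean,
                params.W_context_to_variance, params.b_context,
                params.b_mean, params.b_variance, params.tau,
                buffer.anchor_context, buffer.anchor_input, u_pb,
                W - 1, _m.VARIANCE_CAP)
            u_prev = U[-1]
            c_prev = np.tanh(u_prev)
            joints_in = Y[-1][:nj]
        x_t = np.concatenate([joints_in, o_t])
        p = np.tanh(u_pb)
        h = (params.W_input_to_context @ x_t
             + params.W_context_to_context @ c_prev
             + params.W_pb_to_context @ p + params.b_context)
        u_now = inv_tau * h + (1.0 - inv_tau) * u_prev
        c_now = np.tanh(u_now)
        y = np.tanh(params.W_context_to_mean @ c_now + params.b_mean)
        ctx_log[t] = u_now
        pred_log[t] = y
        pb_log[t] = p
        cmd = y[:nj]
        cmd_log[t] = cmd
        u_prev, c_prev = u_now, c_now

    assert np.array_equal(weights_before, params.W_context_to_context), \
        "weights must stay frozen during interaction"
    return InteractionTrial(observations=obs_log, commands=cmd_log,
                            pb=pb_log, windowed_error=werr_log,
                            situations=list(env.situation_log),
                            switch_step=env.state.switch_step,
                            initial_behavior=env._initial_situation,
                            u_pb_final=u_pb.copy())
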