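"""Numba kernels for the training and real-time adaptation inner loops.

These mirror the reference implementation in :mod:`sctrnnpb.model` exactly
(same operation order, same variance-cap guard); tests assert agreement with
both the numpy path and central finite differences.  Kept free of Python
objects so the whole epoch loop compiles.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=False)
def train_loop(Wxc, Wcc, Wpc, Wcy, Wcv, b_c, b_y, b_v, U0, tau, X,
               n_epochs, alpha, eta, thin, cap, clip_norm):
    """Full-batch momentum gradient descent on the summed NLL.

    X: (T, S, n_input) — S equal-length sequences, time-major.
    Parameters are updated in place; ``b_c`` and ``tau`` are read-only.
    ``clip_norm`` > 0 rescales the whole gradient to that global L2 norm
    whenever it exceeds it (0 disables the guard).
    Returns (loss_log, final_loss, diverged_epoch) where diverged_epoch is
    -1 on success and the 0-based epoch of the first non-finite loss
    otherwise (parameters are then left at their last finite state).
    """
    T, S, NI = X.shape
    NC = Wcc.shape[0]
    NM = Wcy.shape[0]
    NP = U0.shape[1]
    Tp = T - 1
    inv_tau = 1.0 / tau
    one_m = 1.0 - inv_tau
    log2pi = np.log(2.0 * np.pi)

    # flattened (t, s) views of inputs/targets; constant across epochs
    X2 = np.ascontiguousarray(X[:Tp]).reshape(Tp * S, NI)
    T2 = np.ascontiguousarray(X[1:]).reshape(Tp * S, NI)

    C = np.zeros((Tp, S, NC))
    R = np.zeros((Tp, S, NC))

    vWxc = np.zeros_like(Wxc)
    vWcc = np.zeros_like(Wcc)
    vWpc = np.zeros_like(Wpc)
    vWcy = np.zeros_like(Wcy)
    vWcv = np.zeros_like(Wcv)
    vby = np.zeros_like(b_y)
    vbv = np.zeros_like(b_v)
    vU0 = np.zeros_like(U0)

    n_logs = (n_epochs + thin - 1) // thin
    loss_log = np.zeros(n_logs)
    final_loss = np.nan
    diverged = -1

    for epoch in range(n_epochs):
        WxcT = np.ascontiguousarray(Wxc.T)
        WccT = np.ascontiguousarray(Wcc.T)
        WpcT = np.ascontiguousarray(Wpc.T)
        WcyT = np.ascontiguousarray(Wcy.T)
        WcvT = np.ascontiguousarray(Wcv.T)

        P = np.tanh(U0)
        hpb = np.dot(P, WpcT)

        # ---- forward: recurrent context loop, then batched readouts ----
        HX = np.dot(X2, WxcT)  # input drive for every (t, s) at once
        Uprev = np.zeros((S, NC))
        Cprev = np.zeros((S, NC))
        for t in range(Tp):
            Hc = np.dot(Cprev, WccT)
            for s in range(S):
                base = t * S + s
                for j in range(NC):
                    h = HX[base, j] + Hc[s, j] + hpb[s, j] + b_c[j]
                    u = h * inv_tau[j] + Uprev[s, j] * one_m[j]
                    Uprev[s, j] = u
                    C[t, s, j] = np.tanh(u)
            Cprev = C[t]
        C2 = C.reshape(Tp * S, NC)
        Y2 = np.tanh(np.dot(C2, WcyT) + b_y)
        UV2 = np.dot(C2, WcvT) + b_v
        n2 = Tp * S
        V2 = np.empty((n2, NM))
        for r in range(n2):
            for i in range(NM):
                uv = UV2[r, i]
                if uv > cap:
                    uv = cap
                elif uv < -cap:
                    uv = -cap
                V2[r, i] = np.exp(uv)
        E2 = Y2 - T2
        loss = np.sum(0.5 * (log2pi + np.log(V2)) + E2 * E2 / (2.0 * V2))

        if not np.isfinite(loss):
            diverged = epoch
            break
        final_loss = loss
        if epoch % thin == 0:
            loss_log[epoch // thin] = loss

        # ---- backward: batched output grads, recurrent adjoint loop ----
        GY2 = (E2 / V2) * (1.0 - Y2 * Y2)
        # straight-through gradient at the variance cap (see model.py)
        GV2 = 0.5 * (1.0 - E2 * E2 / V2)
        DCout = np.dot(GY2, Wcy) + np.dot(GV2, Wcv)
        dU_next = np.zeros((S, NC))
        zero_sc = np.zeros((S, NC))
        for t in range(Tp - 1, -1, -1):
            # R[t+1] already holds dU_{t+1} * inv_tau, the scaled adjoint
            Rnext = R[t + 1] if t < Tp - 1 else zero_sc
            Dc = np.dot(Rnext, Wcc)
            for s in range(S):
                base = t * S + s
                for j in range(NC):
                    c = C[t, s, j]
                    dc = DCout[base, j] + Dc[s, j]
                    du = (1.0 - c * c) * dc + dU_next[s, j] * one_m[j]
                    dU_next[s, j] = du
                    R[t, s, j] = du * inv_tau[j]
        R2 = R.reshape(Tp * S, NC)
        R2T = np.ascontiguousarray(R2.T)
        gWcy = np.dot(np.ascontiguousarray(GY2.T), C2)
        gWcv = np.dot(np.ascontiguousarray(GV2.T), C2)
        gby = np.sum(GY2, axis=0)
        gbv = np.sum(GV2, axis=0)
        gWxc = np.dot(R2T, X2)
        # context recurrence pairs R[t] with C[t-1]; flattened rows shift by S
        gWcc = np.dot(np.ascontiguousarray(R2[S:].T), C2[:n2 - S])
        Rsum = np.sum(R, axis=0)
        gWpc = np.dot(np.ascontiguousarray(Rsum.T), P)
        dP = np.dot(Rsum, Wpc)
        gU0 = (1.0 - P * P) * dP

        if clip_norm > 0.0:
            sq = (np.sum(gWxc * gWxc) + np.sum(gWcc * gWcc)
                  + np.sum(gWpc * gWpc) + np.sum(gWcy * gWcy)
                  + np.sum(gWcv * gWcv) + np.sum(gby * gby)
                  + np.sum(gbv * gbv) + np.sum(gU0 * gU0))
            gnorm = np.sqrt(sq)
            if gnorm > clip_norm:
                scale = clip_norm / gnorm
                gWxc *= scale; gWcc *= scale; gWpc *= scale
                gWcy *= scale; gWcv *= scale
                gby *= scale; gbv *= scale; gU0 *= scale

        # ---- momentum update: theta += delta, delta = -a*g + eta*delta ----
        vWxc *= eta; vWxc -= alpha * gWxc; Wxc += vWxc
        vWcc *= eta; vWcc -= alpha * gWcc; Wcc += vWcc
        vWpc *= eta; vWpc -= alpha * gWpc; Wpc += vWpc
        vWcy *= eta; vWcy -= alpha * gWcy; Wcy += vWcy
        vWcv *= eta; vWcv -= alpha * gWcv; Wcv += vWcv
        vby *= eta; vby -= alpha * gby; b_y += vby
        vbv *= eta; vbv -= alpha * gbv; b_v += vbv
        vU0 *= eta; vU0 -= alpha * gU0; U0 += vU0

    return loss_log, final_loss, diverged


@njit(cache=False)
def window_forward(Wxc, Wcc, Wpc, Wcy, Wcv, b_c, b_y, b_v, tau,
                   u_start, x_anchor, u_pb, K, cap):
    """Closed-loop regeneration of a K-step window from frozen anchors.

    Starts from context internal state ``u_start`` and input ``x_anchor``;
    every subsequent input is the previous mean prediction.  Returns
    (U, C, Y, V, Xin) arrays of length K.
    """
    NC = Wcc.shape[0]
    NM = Wcy.shape[0]
    NI = Wxc.shape[1]
    inv_tau = 1.0 / tau
    one_m = 1.0 - inv_tau
    p = np.tanh(u_pb)
    hpb = np.dot(Wpc, p) + b_c
    U = np.zeros((K, NC))
    C = np.zeros((K, NC))
    Y = np.zeros((K, NM))
    V = np.zeros((K, NM))
    Xin = np.zeros((K, NI))
    u = u_start.copy()
    c = np.tanh(u_start)
    x = x_anchor.copy()
    for t in range(K):
        Xin[t] = x
        h = np.dot(Wxc, x) + np.dot(Wcc, c) + hpb
        u = h * inv_tau + u * one_m
        c = np.tanh(u)
        y = np.tanh(np.dot(Wcy, c) + b_y)
        uv = np.dot(Wcv, c) + b_v
        for i in range(NM):
            z = uv[i]
            if z > cap:
                z = cap
            elif z < -cap:
                z = -cap
            V[t, i] = np.exp(z)
        U[t] = u
        C[t] = c
        Y[t] = y
        x = y
    return U, C, Y, V, Xin


@njit(cache=False)
def adapt_pb(Wxc, Wcc, Wpc, Wcy, Wcv, b_c, b_y, b_v, tau,
             u_start, x_anchor, obs, err_lo, u_pb, vel,
             iterations, alpha, eta, cap):
    """Iterative PB inference on one sliding window (postdiction).

    obs: (K, NI - err_lo) observed values for error dimensions
    [err_lo:NI] at the K regenerated prediction steps.  Each iteration
    regenerates the window closed-loop under the current PB state,
    accumulates the precision-weighted prediction error on the error
    dimensions, backpropagates through the *entire* closed-loop graph
    (including prediction-to-input feedback) to the PB internal state, and
    applies one momentum step.  ``u_pb`` and ``vel`` are updated in place.
    Returns the windowed loss from the last completed iteration.
    """
    K = obs.shape[0]
    NC = Wcc.shape[0]
    NM = Wcy.shape[0]
    NP = u_pb.shape[0]
    inv_tau = 1.0 / tau
    one_m = 1.0 - inv_tau
    log2pi = np.log(2.0 * np.pi)
    WxcT = np.ascontiguousarray(Wxc.T)
    WccT = np.ascontiguousarray(Wcc.T)
    WpcT = np.ascontiguousarray(Wpc.T)
    WcyT = np.ascontiguousarray(Wcy.T)
    WcvT = np.ascontiguousarray(Wcv.T)
    last_loss = np.nan
    for _ in range(iterations):
        U, C, Y, V, Xin = window_forward(
            Wxc, Wcc, Wpc, Wcy, Wcv, b_c, b_y, b_v, tau,
            u_start, x_anchor, u_pb, K, cap)
        p = np.tanh(u_pb)
        loss = 0.0
        for t in range(K):
            for i in range(err_lo, NM):
                e = Y[t, i] - obs[t, i - err_lo]
                loss += 0.5 * (log2pi + np.log(V[t, i])) + e * e / (2.0 * V[t, i])
        last_loss = loss
        dp = np.zeros(NP)
        dU_next = np.zeros(NC)
        dx_next = np.zeros(NM)
        for t in range(K - 1, -1, -1):
            y = Y[t]
            v = V[t]
            c = C[t]
            gy = dx_next.copy()  # feedback: x_{t+1} = y_t
            gv = np.zeros(NM)
            for i in range(err_lo, NM):
                e = y[i] - obs[t, i - err_lo]
                gy[i] += e / v[i]
                gv[i] = 0.5 * (1.0 - e * e / v[i])
            guy = gy * (1.0 - y * y)
            dC = (np.dot(WcyT, guy) + np.dot(WcvT, gv)
                  + np.dot(WccT, dU_next * inv_tau))
            dU = (1.0 - c * c) * dC + dU_next * one_m
            r = dU * inv_tau
            dp += np.dot(WpcT, r)
            dx_next = np.dot(WxcT, r)
            dU_next = dU
        g0 = (1.0 - p * p) * dp
        for j in range(NP):
            vel[j] = eta * vel[j] - alpha * g0[j]
            u_pb[j] += vel[j]
    return last_loss
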