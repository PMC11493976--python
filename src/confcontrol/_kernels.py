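"""Numba inner loops for trial simulation.

These kernels duplicate the dynamics of the vectorised reference path in
:mod:`confcontrol.accumulators` but terminate each simulated trial at its
bound crossing, which makes them the fast path for the Monte-Carlo
likelihood.  A consistency test holds the two paths together.
"""

import numpy as np
from numba import njit


@njit(cache=False)
def ema_path(alpha, x):
    """Exponentially weighted moving average with time-varying coefficient.

    ``y[t] = y[t-1] + alpha[t] * (x[t] - y[t-1])`` with ``y[-1] = 0``,
    applied row-wise to ``(n, T)`` arrays.
    """
    n, T = x.shape
    y = np.empty_like(x)
    for i in range(n):
        yi = 0.0
        for t in range(T):
            yi = yi + alpha[i, t] * (x[i, t] - yi)
            y[i, t] = yi
    return y


@njit(cache=False)
def simulate_motor_batch(nu_l, nu_r, sd, w, pc, use_conf, alpha_const, b,
                         z_l, z_r, tie):
    """Race of two motor accumulators fed by leaky re-integration.

    Primary accumulators sum ``nu + sd*z``; the motor accumulators
    re-integrate them with leakage ``alpha`` set either from online
    confidence (``use_conf``) or held constant (``alpha_const``).  Returns
    (choice, frame, conf_commit, timed_out); choice 0=left, 1=right; frame
    is the 0-based crossing frame (last frame if timed out).
    """
    n, T = z_l.shape
    choice = np.empty(n, np.int8)
    frame = np.empty(n, np.int64)
    conf = np.empty(n)
    timed = np.zeros(n, np.bool_)
    for i in range(n):
        x_l = 0.0
        x_r = 0.0
        y_l = 0.0
        y_r = 0.0
        c_l = 0.5
        done = False
        for t in range(T):
            x_l += nu_l[t] + sd[t] * z_l[i, t]
            x_r += nu_r[t] + sd[t] * z_r[i, t]
            if use_conf:
                c_l = 1.0 / (1.0 + np.exp(-(x_l - x_r) * w[t]))
                a_l = c_l - pc[t] if c_l > pc[t] else 0.0
                c_r = 1.0 - c_l
                a_r = c_r - pc[t] if c_r > pc[t] else 0.0
            else:
                a_l = alpha_const
                a_r = alpha_const
            y_l = y_l + a_l * (x_l - y_l)
            y_r = y_r + a_r * (x_r - y_r)
            hit_l = y_l >= b
            hit_r = y_r >= b
            if hit_l or hit_r:
                if hit_l and hit_r:
                    if y_l > y_r:
                        choice[i] = 0
                    elif y_r > y_l:
                        choice[i] = 1
                    else:
                        choice[i] = 0 if tie[i] < 0.5 else 1
                else:
                    choice[i] = 0 if hit_l else 1
                frame[i] = t
                conf[i] = c_l if choice[i] == 0 else 1.0 - c_l
                done = True
                break
        if not done:
            timed[i] = True
            frame[i] = T - 1
            if y_l > y_r:
                choice[i] = 0
            elif y_r > y_l:
                choice[i] = 1
            else:
                choice[i] = 0 if tie[i] < 0.5 else 1
            conf[i] = c_l if choice[i] == 0 else 1.0 - c_l
    return choice, frame, conf, timed


@njit(cache=False)
def simulate_primary_batch(nu_l, nu_r, sd, nu_weight, bound, z_l, z_r, tie):
    """Race of the primary accumulators to a (possibly collapsing) bound.

    ``nu_weight`` multiplies the evidence increment (1 for the classic
    model, the bottom-up weight otherwise); ``bound`` is the per-frame bound
    height.  Returns (choice, frame, timed_out).
    """
    n, T = z_l.shape
    choice = np.empty(n, np.int8)
    frame = np.empty(n, np.int64)
    timed = np.zeros(n, np.bool_)
    for i in range(n):
        x_l = 0.0
        x_r = 0.0
        done = False
        for t in range(T):
            x_l += nu_weight[t] * nu_l[t] + sd[t] * z_l[i, t]
            x_r += nu_weight[t] * nu_r[t] + sd[t] * z_r[i, t]
            b = bound[t]
            hit_l = x_l >= b
            hit_r = x_r >= b
            if hit_l or hit_r:
                if hit_l and hit_r:
                    if x_l > x_r:
                        choice[i] = 0
                    elif x_r > x_l:
                        choice[i] = 1
                    else:
                        choice[i] = 0 if tie[i] < 0.5 else 1
                else:
                    choice[i] = 0 if hit_l else 1
                frame[i] = t
                done = True
                break
        if not done:
            timed[i] = True
            frame[i] = T - 1
            if x_l > x_r:
                choice[i] = 0
            elif x_r > x_l:
                choice[i] = 1
            else:
                choice[i] = 0 if tie[i] < 0.5 else 1
    return choice, frame, timed
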