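"""Trial simulation for single- and double-integration decision models.

Five model variants share the same momentary evidence input (an
:class:`~confcontrol.evidence.EvidenceTrace`):

``classic``
    Race of two primary accumulators ``x = cumsum(nu + eps)`` to a fixed
    bound ``b`` (equivalent to a drift-diffusion model on the evidence
    difference).
``weibull``
    Classic race with a bound that collapses along a cumulative Weibull.
``bottom_up``
    Classic race with the evidence increment down-weighted by
    ``beta / (beta + sigma2_cum)`` as it is accumulated.
``static_lit``
    Leaky Integrating Threshold: a secondary motor accumulator re-integrates
    ``x`` with a constant leakage ``alpha`` and triggers the choice at its
    own bound.
``conf_control``
    Double integration with confidence control: the motor leakage is set
    on-line from confidence in each choice, ``alpha = max(c - p_c, 0)``,
    where ``c`` is a logistic read-out of the primary evidence difference
    weighted by ``beta / (beta + sigma2_cum)`` and ``p_c`` decays linearly
    from 0.5 to 0 between an urgency onset ``t_d`` and stimulus offset.

Internal noise is Gaussian per frame with variance ``sigma**2`` scaled by
the momentary circular variance of the stimulus, in every variant (the
scaling can be switched off).  After stimulus offset (2 s) the evidence
holds at log(0.5) per side and the simulation runs to a hard 4 s horizon,
after which the larger accumulator determines the choice and the trial is
flagged as timed out.  Non-decision time is folded-Gaussian,
``|N(mu_U, sigma_U**2)|``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from . import _kernels
from .evidence import DT, EvidenceTrace, InvalidParameterError

#: stimulus offset (s): evidence is uninformative afterwards
T_OFFSET = 2.0
#: log probability of an uninformative frame; accumulated increments are
#: measured against this baseline (log-likelihood ratio vs. chance), which
#: keeps the left-right evidence difference unchanged while making a
#: positive bound reachable and post-offset increments exactly zero
LOG_HALF = float(np.log(0.5))
#: hard simulation horizon (s)
T_HORIZON = 4.0

VARIANTS = ("classic", "weibull", "bottom_up", "static_lit", "conf_control")

LEFT, RIGHT = 0, 1


@dataclass(frozen=True)
class WeibullBound:
    """Collapsing-bound parameters: ``b(t) = b*(1-(1-floor)*W(t))`` with
    ``W`` the cumulative Weibull of the given scale (s) and shape."""

    scale: float
    shape: float
    floor: float

    def __post_init__(self):
        if self.scale <= 0 or self.shape <= 0 or not 0 <= self.floor <= 1:
            raise InvalidParameterError("invalid Weibull bound parameters")


@dataclass(frozen=True)
class ClassicParams:
    sigma: float
    b: float
    mu_U: float = 0.3
    sigma_U: float = 0.15
    weibull: WeibullBound | None = None

    def __post_init__(self):
        if self.sigma < 0 or self.b <= 0 or self.sigma_U < 0:
            raise InvalidParameterError("invalid classic parameters")


@dataclass(frozen=True)
class BottomUpParams:
    sigma: float
    b: float
    beta: float
    mu_U: float = 0.3
    sigma_U: float = 0.15

    def __post_init__(self):
        if self.sigma < 0 or self.b <= 0 or self.beta <= 0 or self.sigma_U < 0:
            raise InvalidParameterError("invalid bottom-up parameters")


@dataclass(frozen=True)
class StaticLITParams:
    sigma: float
    b: float
    alpha_static: float
    mu_U: float = 0.3
    sigma_U: float = 0.15

    def __post_init__(self):
        if self.sigma < 0 or self.b <= 0 or self.sigma_U < 0:
            raise InvalidParameterError("invalid static-LIT parameters")
        if not 0 < self.alpha_static <= 1:
            raise InvalidParameterError("alpha_static must lie in (0, 1]")


@dataclass(frozen=True)
class ConfControlParams:
    """Confidence-control parameters.

    Free decision parameters are the internal noise ``sigma``, the
    confidence weight ``beta`` and the urgency onset ``t_d``; the motor
    bound ``b`` is fixed across subjects (default calibrated once on pilot
    simulations).  ``p_c_base`` is the pre-urgency lower confidence bound.
    """

    sigma: float
    beta: float
    t_d: float
    b: float = 6.0
    mu_U: float = 0.3
    sigma_U: float = 0.15
    p_c_base: float = 0.5

    def __post_init__(self):
        if self.sigma < 0 or self.beta <= 0 or self.b <= 0 or self.sigma_U < 0:
            raise InvalidParameterError("invalid confidence-control parameters")
        if not 0 <= self.t_d <= T_OFFSET:
            raise InvalidParameterError("t_d must lie in [0, 2] s")


@dataclass
class SimOutcome:
    """One simulated trial's observable outcome."""

    choice: str  # "left" | "right"
    decision_time: float
    ndt: float
    rt: float
    confidence_at_commit: float
    timed_out: bool
    seed: int | None = None


@dataclass
class SimTrace:
    """Latent time courses of one simulated trial (full horizon)."""

    time: np.ndarray
    x_left: np.ndarray
    x_right: np.ndarray
    y_left: np.ndarray
    y_right: np.ndarray
    c_left: np.ndarray
    c_right: np.ndarray
    alpha_left: np.ndarray
    alpha_right: np.ndarray
    sigma2_momentary: np.ndarray
    sigma2_cum: np.ndarray


@dataclass
class SimBatch:
    """Vectorised outcomes of ``n`` simulations of one stimulus."""

    choice: np.ndarray  # int8, 0=left 1=right
    decision_frame: np.ndarray
    decision_time: np.ndarray
    ndt: np.ndarray
    rt: np.ndarray
    conf_commit: np.ndarray
    timed_out: np.ndarray
    dt: float = DT

    @property
    def n(self) -> int:
        return self.choice.shape[0]


# ---------------------------------------------------------------------------
# elementary operations


def momentary_noise(sigma, circ_var_t, rng, size=None):
    """Gaussian momentary noise with variance ``sigma**2 * circ_var``."""
    if sigma < 0:
        raise InvalidParameterError("sigma must be >= 0")
    sd = sigma * np.sqrt(np.asarray(circ_var_t, dtype=float))
    return sd * rng.standard_normal(size if size is not None else np.shape(sd))


def step_primary(x_prev, nu_t, eps_t):
    """One accumulation step of the primary accumulator (Euler sum)."""
    return x_prev + nu_t + eps_t


def step_motor(y_prev, x_t, alpha_t):
    """One leaky re-integration step of the motor accumulator."""
    a = np.asarray(alpha_t, dtype=float)
    if np.any((a < 0) | (a > 1)):
        raise InvalidParameterError("alpha must lie in [0, 1]")
    return y_prev + a * (x_t - y_prev)


def online_confidence(x_left, x_right, sigma2_cum, beta):
    """Confidence in a leftward choice from the primary evidence.

    ``c_left = logistic((x_left - x_right) * beta / (beta + sigma2_cum))``;
    the rightward confidence is its complement.  As ``beta`` grows this
    approaches the exact Bayesian posterior ``logistic(x_left - x_right)``.
    """
    w = beta / (beta + np.asarray(sigma2_cum, dtype=float))
    z = (np.asarray(x_left, dtype=float) - np.asarray(x_right, dtype=float)) * w
    with np.errstate(over="ignore"):
        return 1.0 / (1.0 + np.exp(-z))


def leakage_from_confidence(c, p_c):
    """Motor leakage: confidence above the lower bound, rectified at 0."""
    c = np.asarray(c, dtype=float)
    return np.where(c > p_c, c - p_c, 0.0)


def urgency_pc(t, t_d, t_off=T_OFFSET, p_base=0.5):
    """Lower confidence bound with urgency.

    Constant at ``p_base`` up to the urgency onset ``t_d``, then decays
    linearly to 0 at stimulus offset ``t_off``, and stays 0 afterwards.
    """
    if not 0 <= t_d <= t_off:
        raise InvalidParameterError("t_d must lie in [0, t_off]")
    t = np.asarray(t, dtype=float)
    if t_d >= t_off:
        out = np.where(t >= t_off, 0.0, p_base * np.ones_like(t))
    else:
        out = p_base * np.clip((t_off - t) / (t_off - t_d), 0.0, 1.0)
        out = np.minimum(out, p_base)
    return float(out) if out.ndim == 0 else out


def sample_ndt(mu_U, sigma_U, rng, size=None):
    """Folded-Gaussian non-decision time ``|N(mu_U, sigma_U**2)|`` (s)."""
    if sigma_U < 0:
        raise InvalidParameterError("sigma_U must be >= 0")
    return np.abs(mu_U + sigma_U * rng.standard_normal(size))


def bound_at(t, params):
    """Bound height at time(s) ``t`` for classic/Weibull parameters."""
    t = np.asarray(t, dtype=float)
    w = getattr(params, "weibull", None)
    if w is None:
        out = np.full_like(t, params.b, dtype=float)
    else:
        cdf = 1.0 - np.exp(-((np.maximum(t, 0.0) / w.scale) ** w.shape))
        out = params.b * (1.0 - (1.0 - w.floor) * cdf)
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# batch simulation


def extend_trace(trace: EvidenceTrace, horizon: float = T_HORIZON):
    """Pad an evidence trace to the simulation horizon.

    After stimulus offset both log evidences hold at log(0.5) and the
    circular variance holds at its final value.
    """
    n_total = int(round(horizon / trace.dt))
    n_obs = trace.n_frames
    nu_l = np.full(n_total, np.log(0.5))
    nu_r = np.full(n_total, np.log(0.5))
    cv = np.full(n_total, trace.circ_var[-1])
    k = min(n_obs, n_total)
    nu_l[:k] = trace.nu_left[:k]
    nu_r[:k] = trace.nu_right[:k]
    cv[:k] = trace.circ_var[:k]
    return nu_l, nu_r, cv


def _noise_sd(params, cv, scale_noise):
    return params.sigma * np.sqrt(cv) if scale_noise else np.full_like(cv, params.sigma)


def _draw_noise(n, T, rng, dtype=np.float32):
    z = rng.standard_normal((2, n, T)).astype(dtype)
    return z[0], z[1]


def simulate_batch(variant: str, params, trace: EvidenceTrace, n_sims: int,
                   rng, scale_noise: bool = True, horizon: float = T_HORIZON,
                   noise=None, ndt_z=None, tie=None) -> SimBatch:
    """Simulate ``n_sims`` trials of one stimulus under a model variant.

    ``noise`` may supply pre-drawn standard-normal arrays ``(z_left,
    z_right)`` of shape ``(n_sims, T)`` (and ``ndt_z``, ``tie`` the matching
    per-trial draws) to hold the random numbers fixed across calls; this is
    how the likelihood keeps common random numbers across parameter
    evaluations.
    """
    if variant not in VARIANTS:
        raise InvalidParameterError(f"unknown variant {variant!r}")
    nu_l, nu_r, cv = extend_trace(trace, horizon)
    nu_l = nu_l - LOG_HALF
    nu_r = nu_r - LOG_HALF
    T = nu_l.shape[0]
    if noise is None:
        z_l, z_r = _draw_noise(n_sims, T, rng)
    else:
        z_l, z_r = noise
    if ndt_z is None:
        ndt_z = rng.standard_normal(n_sims)
    if tie is None:
        tie = rng.random(n_sims)
    sd = _noise_sd(params, cv, scale_noise)
    times = (np.arange(T) + 1) * trace.dt
    z_l64 = np.ascontiguousarray(z_l, dtype=np.float64)
    z_r64 = np.ascontiguousarray(z_r, dtype=np.float64)

    if variant in ("classic", "weibull", "bottom_up"):
        if variant == "bottom_up":
            s2cum = np.cumsum(sd**2)
            nu_weight = params.beta / (params.beta + s2cum)
        else:
            nu_weight = np.ones(T)
        bnd = np.broadcast_to(np.asarray(bound_at(times, params), dtype=float),
                              (T,)).copy()
        choice, frame, timed = _kernels.simulate_primary_batch(
            nu_l, nu_r, sd, nu_weight, bnd, z_l64, z_r64, tie)
        conf = np.full(n_sims, np.nan)
    else:
        s2cum = np.cumsum(sd**2)
        if variant == "conf_control":
            w = params.beta / (params.beta + s2cum)
            pc = urgency_pc(times, params.t_d, p_base=params.p_c_base)
            use_conf, alpha_const = True, 0.0
        else:  # static_lit
            w = np.ones(T)
            pc = np.zeros(T)
            use_conf, alpha_const = False, params.alpha_static
        choice, frame, conf, timed = _kernels.simulate_motor_batch(
            nu_l, nu_r, sd, w, pc, use_conf, alpha_const, params.b,
            z_l64, z_r64, tie)

    ndt = np.abs(params.mu_U + params.sigma_U * ndt_z)
    decision_time = (frame + 1) * trace.dt
    return SimBatch(choice=choice, decision_frame=frame,
                    decision_time=decision_time, ndt=ndt,
                    rt=decision_time + ndt, conf_commit=conf,
                    timed_out=timed, dt=trace.dt)


def simulate_paths(variant: str, params, trace: EvidenceTrace, n_sims: int,
                   rng, scale_noise: bool = True, horizon: float = T_HORIZON,
                   noise=None):
    """Vectorised reference simulation returning full latent paths.

    Returns a dict of ``(n_sims, T)`` arrays (``x_left``, ``x_right``,
    ``y_left``, ``y_right``, ``c_left``, ``alpha_left``, ...) plus the
    deterministic per-frame arrays.  The trial dynamics have no post-commit
    feedback, so first bound crossings derived from these paths equal the
    terminating kernel's outcomes; a test pins the two paths together.
    """
    nu_l, nu_r, cv = extend_trace(trace, horizon)
    nu_l = nu_l - LOG_HALF
    nu_r = nu_r - LOG_HALF
    T = nu_l.shape[0]
    if noise is None:
        z_l, z_r = _draw_noise(n_sims, T, rng)
    else:
        z_l, z_r = noise
    sd = _noise_sd(params, cv, scale_noise)
    times = (np.arange(T) + 1) * trace.dt
    x_l = np.cumsum(nu_l[None, :] + sd[None, :] * z_l.astype(np.float64), axis=1)
    x_r = np.cumsum(nu_r[None, :] + sd[None, :] * z_r.astype(np.float64), axis=1)
    s2mom = sd**2
    s2cum = np.cumsum(s2mom)
    out = dict(time=times, x_left=x_l, x_right=x_r,
               sigma2_momentary=s2mom, sigma2_cum=s2cum)
    if variant in ("static_lit", "conf_control"):
        if variant == "conf_control":
            c_l = online_confidence(x_l, x_r, s2cum[None, :], params.beta)
            pc = urgency_pc(times, params.t_d, p_base=params.p_c_base)
            a_l = leakage_from_confidence(c_l, pc[None, :])
            a_r = leakage_from_confidence(1.0 - c_l, pc[None, :])
        else:
            c_l = np.full_like(x_l, 0.5)
            a_l = np.full_like(x_l, params.alpha_static)
            a_r = a_l
        out.update(
            c_left=c_l, c_right=1.0 - c_l, alpha_left=a_l, alpha_right=a_r,
            y_left=_kernels.ema_path(np.ascontiguousarray(a_l),
                                     np.ascontiguousarray(x_l)),
            y_right=_kernels.ema_path(np.ascontiguousarray(a_r),
                                      np.ascontiguousarray(x_r)),
        )
    return out


def outcomes_from_paths(variant: str, params, paths, trace_dt: float = DT,
                        tie=None):
    """Derive first-crossing outcomes from full latent paths."""
    times = paths["time"]
    T = times.shape[0]
    if variant in ("static_lit", "conf_control"):
        a_l, a_r = paths["y_left"], paths["y_right"]
        bnd = np.full(T, params.b)
    else:
        a_l, a_r = paths["x_left"], paths["x_right"]
        bnd = np.broadcast_to(np.asarray(bound_at(times, params), dtype=float),
                              (T,))
    n = a_l.shape[0]
    hit_l = a_l >= bnd[None, :]
    hit_r = a_r >= bnd[None, :]
    hit = hit_l | hit_r
    has = hit.any(axis=1)
    first = np.where(has, hit.argmax(axis=1), T - 1)
    idx = np.arange(n)
    vl = a_l[idx, first]
    vr = a_r[idx, first]
    both = has & hit_l[idx, first] & hit_r[idx, first]
    choice = np.where(hit_r[idx, first] & ~hit_l[idx, first], RIGHT, LEFT)
    choice = np.where(both | ~has, np.where(vl > vr, LEFT, RIGHT), choice)
    exact = (both | ~has) & (vl == vr)
    if np.any(exact):
        t = tie if tie is not None else np.full(n, 0.0)
        choice = np.where(exact, np.where(t < 0.5, LEFT, RIGHT), choice)
    return choice.astype(np.int8), first, ~has


def simulate_trial(variant: str, params, trace: EvidenceTrace, rng,
                   scale_noise: bool = True, return_trace: bool = False,
                   seed: int | None = None):
    """Simulate a single trial; optionally return its latent time courses."""
    if seed is not None:
        rng = np.random.default_rng(seed)
    batch = simulate_batch(variant, params, trace, 1, rng,
                           scale_noise=scale_noise)
    out = SimOutcome(
        choice="left" if batch.choice[0] == LEFT else "right",
        decision_time=float(batch.decision_time[0]),
        ndt=float(batch.ndt[0]), rt=float(batch.rt[0]),
        confidence_at_commit=float(batch.conf_commit[0]),
        timed_out=bool(batch.timed_out[0]), seed=seed,
    )
    if not return_trace:
        return out
    rng2 = np.random.default_rng(seed) if seed is not None else rng
    paths = simulate_paths(variant, params, trace, 1, rng2,
                           scale_noise=scale_noise)
    nan_row = np.full((1, paths["time"].shape[0]), np.nan)
    trace_out = SimTrace(
        time=paths["time"],
        x_left=paths["x_left"][0], x_right=paths["x_right"][0],
        y_left=paths.get("y_left", paths["x_left"])[0],
        y_right=paths.get("y_right", paths["x_right"])[0],
        c_left=paths.get("c_left", nan_row)[0],
        c_right=paths.get("c_right", nan_row)[0],
        alpha_left=paths.get("alpha_left", nan_row)[0],
        alpha_right=paths.get("alpha_right", nan_row)[0],
        sigma2_momentary=paths["sigma2_momentary"],
        sigma2_cum=paths["sigma2_cum"],
    )
    return out, trace_out


# ---------------------------------------------------------------------------
# termination-rule comparison


def compare_termination_rules(params: ConfControlParams, traces, n_reps: int,
                              seed: int, b_primary: float | None = None,
                              scale_noise: bool = True):
    """Paired speed-accuracy comparison of the two termination rules.

    For every evidence trace, ``n_reps`` primary-accumulator paths are
    simulated once and terminated either (a) by the confidence-controlled
    motor accumulator at the fixed motor bound, or (b) directly by the
    primary accumulator at bound ``b_primary``.  Both rules therefore see
    identical evidence and identical noise.  If ``b_primary`` is None it is
    tuned by bisection so the primary-bound rule matches the
    confidence-controlled rule's overall accuracy as closely as possible.

    Parameters
    ----------
    traces:
        list of EvidenceTrace with ``condition_id`` and ``side`` metadata.
    Returns
    -------
    (per_condition, overall, b_primary) where the tables map condition ->
    dict of accuracy and median decision time per rule.
    """
    rng = np.random.default_rng(seed)
    conds, sides, all_paths = [], [], []
    conf_choice, conf_frame = [], []
    for tr in traces:
        paths = simulate_paths("conf_control", params, tr, n_reps, rng,
                               scale_noise=scale_noise)
        choice, frame, _ = outcomes_from_paths("conf_control", params, paths)
        conf_choice.append(choice)
        conf_frame.append(frame)
        all_paths.append((paths["x_left"], paths["x_right"], paths["time"]))
        conds.append(tr.condition_id)
        sides.append(LEFT if tr.side == "left" else RIGHT)

    def primary_outcomes(b):
        ch, fr = [], []
        for x_l, x_r, times in all_paths:
            T = times.shape[0]
            hit = (x_l >= b) | (x_r >= b)
            has = hit.any(axis=1)
            first = np.where(has, hit.argmax(axis=1), T - 1)
            idx = np.arange(x_l.shape[0])
            vl, vr = x_l[idx, first], x_r[idx, first]
            both = has & (vl >= b) & (vr >= b)
            choice = np.where((vr >= b) & ~(vl >= b), RIGHT, LEFT)
            choice = np.where(both | ~has, np.where(vl > vr, LEFT, RIGHT), choice)
            ch.append(choice)
            fr.append(first)
        return ch, fr

    def accuracy(choices):
        correct = [np.mean(c == s) for c, s in zip(choices, sides)]
        return float(np.mean(correct))

    acc_conf = accuracy(conf_choice)
    if b_primary is None:
        # bisect to the largest bound whose accuracy is still below the
        # confidence-controlled rule's, so the comparison bound never
        # exceeds it in accuracy
        lo, hi = 1e-3, 200.0
        for _ in range(40):
            mid = 0.5 * (lo + hi)
            if accuracy(primary_outcomes(mid)[0]) < acc_conf:
                lo = mid
            else:
                hi = mid
        b_primary = lo
    prim_choice, prim_frame = primary_outcomes(b_primary)

    dt = DT
    per_condition = {}
    for cid in sorted(set(conds)):
        sel = [i for i, c in enumerate(conds) if c == cid]
        cc = np.concatenate([conf_choice[i] for i in sel])
        cf = np.concatenate([conf_frame[i] for i in sel])
        pc_ = np.concatenate([prim_choice[i] for i in sel])
        pf = np.concatenate([prim_frame[i] for i in sel])
        truth = np.concatenate([np.full(n_reps, sides[i]) for i in sel])
        per_condition[cid] = {
            "acc_conf": float(np.mean(cc == truth)),
            "acc_primary": float(np.mean(pc_ == truth)),
            "median_dt_conf": float(np.median((cf + 1) * dt)),
            "median_dt_primary": float(np.median((pf + 1) * dt)),
        }
    overall = {
        "acc_conf": acc_conf,
        "acc_primary": accuracy(prim_choice),
        "median_dt_conf": float(np.median(
            np.concatenate([(f + 1) * dt for f in conf_frame]))),
        "median_dt_primary": float(np.median(
            np.concatenate([(f + 1) * dt for f in prim_frame]))),
    }
    return per_condition, overall, float(b_primary)
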