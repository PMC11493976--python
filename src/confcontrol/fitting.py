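"""Quantile-based Monte-Carlo likelihood fitting and model comparison.

Choices and response times are summarised per (condition, choice) cell by
the counts of observed RTs in (by default) 10 empirical quantile bins.  A
candidate parameter set is scored by simulating each stimulus many times,
estimating the probability mass the model places in every cell, and
accumulating the multinomial negative log-likelihood of the observed
counts.  Simulations reuse the same random numbers across parameter
evaluations (common random numbers), which makes the stochastic objective a
deterministic function of the parameters and smooth enough for bounded
derivative-free search.

Model comparison uses BIC (2*NLL + k*ln n) and random-effects Bayesian
model selection: a variational Dirichlet estimate of the model frequencies,
exceedance probabilities by Monte-Carlo Dirichlet sampling, and the
protected version that accounts for the Bayes omnibus risk that model
frequencies are all equal.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, special
from scipy.stats import qmc

from .accumulators import (
    LEFT,
    RIGHT,
    BottomUpParams,
    ClassicParams,
    ConfControlParams,
    StaticLITParams,
    WeibullBound,
    simulate_batch,
)

CHOICE_CODE = {"left": LEFT, "right": RIGHT}

#: free-parameter names per variant (conf_control's bound is fixed)
PARAM_NAMES = {
    "classic": ("sigma", "b", "mu_U", "sigma_U"),
    "weibull": ("sigma", "b", "mu_U", "sigma_U", "w_scale", "w_shape", "w_floor"),
    "bottom_up": ("sigma", "b", "beta", "mu_U", "sigma_U"),
    "static_lit": ("sigma", "b", "alpha_static", "mu_U", "sigma_U"),
    "conf_control": ("sigma", "beta", "t_d", "mu_U", "sigma_U"),
}

DEFAULT_BOUNDS = {
    "sigma": (0.05, 4.0),
    "b": (0.2, 30.0),
    "beta": (0.05, 20.0),
    "t_d": (0.0, 2.0),
    "alpha_static": (0.01, 1.0),
    "mu_U": (0.0, 1.0),
    "sigma_U": (0.01, 0.8),
    "w_scale": (0.1, 4.0),
    "w_shape": (0.5, 6.0),
    "w_floor": (0.0, 1.0),
}


def make_params(variant: str, values: dict, fixed: dict | None = None):
    """Build the variant's parameter object from a name->value mapping."""
    v = dict(values)
    if fixed:
        v.update(fixed)
    if variant == "classic":
        return ClassicParams(sigma=v["sigma"], b=v["b"], mu_U=v["mu_U"],
                             sigma_U=v["sigma_U"])
    if variant == "weibull":
        return ClassicParams(
            sigma=v["sigma"], b=v["b"], mu_U=v["mu_U"], sigma_U=v["sigma_U"],
            weibull=WeibullBound(v["w_scale"], v["w_shape"], v["w_floor"]))
    if variant == "bottom_up":
        return BottomUpParams(sigma=v["sigma"], b=v["b"], beta=v["beta"],
                              mu_U=v["mu_U"], sigma_U=v["sigma_U"])
    if variant == "static_lit":
        return StaticLITParams(sigma=v["sigma"], b=v["b"],
                               alpha_static=v["alpha_static"],
                               mu_U=v["mu_U"], sigma_U=v["sigma_U"])
    if variant == "conf_control":
        return ConfControlParams(sigma=v["sigma"], beta=v["beta"],
                                 t_d=v["t_d"], mu_U=v["mu_U"],
                                 sigma_U=v["sigma_U"],
                                 b=v.get("b", ConfControlParams(1, 1, 1).b))
    raise ValueError(f"unknown variant {variant!r}")


# ---------------------------------------------------------------------------
# quantile bins


@dataclass
class QuantileBins:
    """Per-(condition, choice) empirical RT quantile bins.

    ``edges[cell]`` holds the internal edges (length ``q - 1``) of ``q``
    half-open bins ``[e_i, e_{i+1})`` with open outer edges; ``counts[cell]``
    the observed trial counts per bin.  Cells with fewer trials than the
    requested number of quantiles collapse to one bin per trial.
    """

    edges: dict
    counts: dict
    n_quantiles: int

    @property
    def n_trials(self) -> int:
        return int(sum(c.sum() for c in self.counts.values()))


def build_quantile_bins(trials: pd.DataFrame, n_quantiles: int = 10) -> QuantileBins:
    """Empirical choice-RT quantile bins from a behavioural trial table."""
    if len(trials) == 0:
        raise ValueError("empty trial table")
    edges, counts = {}, {}
    for (cond, choice), grp in trials.groupby(["condition_id", "choice"]):
        rts = np.sort(grp["rt"].to_numpy(dtype=float))
        q = min(n_quantiles, rts.size)
        e = np.quantile(rts, np.arange(1, q) / q) if q > 1 else np.empty(0)
        idx = np.searchsorted(e, rts, side="right")
        cell = (cond, choice)
        edges[cell] = e
        counts[cell] = np.bincount(idx, minlength=q).astype(float)
    return QuantileBins(edges=edges, counts=counts, n_quantiles=n_quantiles)


# ---------------------------------------------------------------------------
# common random numbers


class NoiseBank:
    """Deterministic per-stimulus noise for common-random-number likelihoods.

    Every stimulus id gets its own seeded generator derived from
    ``(base_seed, index)``; draws are cached up to ``max_bytes`` so repeated
    objective evaluations see identical noise without unbounded memory.
    """

    def __init__(self, base_seed: int, n_sims: int, n_frames: int,
                 max_bytes: int = 500_000_000):
        self.base_seed = int(base_seed)
        self.n_sims = int(n_sims)
        self.n_frames = int(n_frames)
        self.max_bytes = max_bytes
        self._cache = {}
        self._bytes = 0

    def _draw(self, index: int):
        # antithetic pairs: the second half mirrors the first, which reduces
        # the Monte-Carlo variance of the estimated cell masses at no cost
        rng = np.random.default_rng((self.base_seed, index))
        half = (self.n_sims + 1) // 2
        zh = rng.standard_normal((2, half, self.n_frames)).astype(np.float32)
        z = np.concatenate([zh, -zh], axis=1)[:, : self.n_sims]
        nh = rng.standard_normal(half)
        ndt_z = np.concatenate([nh, -nh])[: self.n_sims]
        tie = rng.random(self.n_sims)
        return z, ndt_z, tie

    def get(self, index: int):
        if index in self._cache:
            return self._cache[index]
        item = self._draw(index)
        nbytes = item[0].nbytes + item[1].nbytes + item[2].nbytes
        if self._bytes + nbytes <= self.max_bytes:
            self._cache[index] = item
            self._bytes += nbytes
        return item


# ---------------------------------------------------------------------------
# likelihood


def qmle_nll(variant: str, params, stimuli: dict, trials: pd.DataFrame,
             bins: QuantileBins, n_sims: int = 2000, seed: int = 0,
             noise_bank: NoiseBank | None = None,
             scale_noise: bool = True) -> float:
    """Quantile-based Monte-Carlo negative log-likelihood.

    ``stimuli`` maps stimulus id -> EvidenceTrace.  Each unique stimulus is
    simulated ``n_sims`` times; per condition, the predicted mass of every
    (choice, RT-bin) cell is the trial-frequency-weighted mixture over that
    condition's stimuli, floored at ``1/(2*n_sims)`` so empty simulated
    cells cannot zero the likelihood.
    """
    stim_ids = sorted(set(trials["stimulus_id"]))
    stim_index = {sid: i for i, sid in enumerate(stim_ids)}
    if noise_bank is None:
        any_trace = stimuli[stim_ids[0]]
        from .accumulators import T_HORIZON
        n_frames = int(round(T_HORIZON / any_trace.dt))
        noise_bank = NoiseBank(seed, n_sims, n_frames)
    weights = trials.groupby(["condition_id", "stimulus_id"]).size()
    cond_totals = trials.groupby("condition_id").size()

    # predicted mass per cell
    pred = {}
    rng = np.random.default_rng(seed)
    for (cond, sid), n_tr in weights.items():
        trace = stimuli[sid]
        z, ndt_z, tie = noise_bank.get(stim_index[sid])
        batch = simulate_batch(variant, params, trace, n_sims, rng,
                               scale_noise=scale_noise,
                               noise=(z[0], z[1]), ndt_z=ndt_z, tie=tie)
        w = n_tr / cond_totals[cond]
        for choice_name, code in CHOICE_CODE.items():
            cell = (cond, choice_name)
            if cell not in bins.counts:
                continue
            sel = batch.choice == code
            idx = np.searchsorted(bins.edges[cell], batch.rt[sel], side="right")
            mass = np.bincount(idx, minlength=bins.counts[cell].size) / n_sims
            pred[cell] = pred.get(cell, 0.0) + w * mass

    floor = 1.0 / (2.0 * n_sims)
    nll = 0.0
    for cell, counts in bins.counts.items():
        p = np.maximum(pred.get(cell, np.zeros_like(counts)), floor)
        nll -= float(np.dot(counts, np.log(p)))
    return nll


def bic(nll: float, k: int, n: int) -> float:
    """Bayesian Information Criterion, ``2*nll + k*ln(n)``."""
    if n < 1:
        raise ValueError("n must be >= 1")
    return 2.0 * nll + k * math.log(n)


# ---------------------------------------------------------------------------
# fitting


@dataclass
class OptimizerConfig:
    """Bounded derivative-free search settings.

    A Latin-hypercube screen of ``n_screen`` points seeds ``n_starts``
    Powell runs (scale parameters are searched in log space); the best
    point can optionally be refined on a higher-precision objective with
    ``refine_n_sims`` simulations per stimulus.
    """

    n_starts: int = 3
    n_screen: int = 30
    maxfev: int = 200
    xtol: float = 1e-3
    ftol: float = 1e-3
    refine_n_sims: int | None = None
    refine_maxfev: int = 80


#: parameters searched on a log scale (strictly positive scale parameters)
LOG_SCALE_PARAMS = {"sigma", "b", "beta", "sigma_U", "w_scale", "w_shape"}


@dataclass
class FitResult:
    variant: str
    params: object
    param_dict: dict
    nll: float
    bic: float
    k_params: int
    n_trials: int
    n_sims_per_stimulus: int
    seed: int
    starts: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "variant": self.variant,
            "params": {k: float(v) for k, v in self.param_dict.items()},
            "nll": float(self.nll), "bic": float(self.bic),
            "k_params": self.k_params, "n_trials": self.n_trials,
            "n_sims_per_stimulus": self.n_sims_per_stimulus,
            "seed": self.seed, "starts": self.starts,
        }


def fit_model(variant: str, trials: pd.DataFrame, stimuli: dict,
              bounds: dict | None = None, n_sims: int = 2000,
              seed: int = 0, optimizer: OptimizerConfig | None = None,
              fixed: dict | None = None, n_quantiles: int = 10,
              scale_noise: bool = True) -> FitResult:
    """Fit one model variant to a subject's choice/RT data.

    Bounded Powell search from Latin-hypercube multistarts, on the
    common-random-number QMLE objective.  ``fixed`` pins parameters that are
    not free for the variant (e.g. the confidence-control motor bound).
    """
    opt = optimizer or OptimizerConfig()
    names = PARAM_NAMES[variant]
    bnds = {**DEFAULT_BOUNDS, **(bounds or {})}
    is_log = np.array([p in LOG_SCALE_PARAMS for p in names])
    lo_n = np.array([bnds[p][0] for p in names])
    hi_n = np.array([bnds[p][1] for p in names])
    with np.errstate(divide="ignore"):
        lo = np.where(is_log, np.log(lo_n), lo_n)
        hi = np.where(is_log, np.log(hi_n), hi_n)
    bins = build_quantile_bins(trials, n_quantiles)
    from .accumulators import T_HORIZON
    n_frames = int(round(T_HORIZON / stimuli[next(iter(stimuli))].dt))
    banks = {n_sims: NoiseBank(seed, n_sims, n_frames)}

    def natural(theta):
        theta = np.clip(theta, lo, hi)
        return np.where(is_log, np.exp(theta), theta)

    def objective(theta, sims=n_sims):
        if sims not in banks:
            banks[sims] = NoiseBank(seed, sims, n_frames)
        params = make_params(variant, dict(zip(names, natural(theta))), fixed)
        return qmle_nll(variant, params, stimuli, trials, bins,
                        n_sims=sims, seed=seed, noise_bank=banks[sims],
                        scale_noise=scale_noise)

    sampler = qmc.LatinHypercube(d=len(names), seed=seed)
    cand = lo + sampler.random(max(opt.n_screen, opt.n_starts)) * (hi - lo)
    screen = np.array([objective(x) for x in cand])
    x0s = cand[np.argsort(screen)[: opt.n_starts]]
    best, starts = None, []
    for x0 in x0s:
        res = optimize.minimize(
            objective, x0, method="Powell",
            bounds=list(zip(lo, hi)),
            options={"maxfev": opt.maxfev, "xtol": opt.xtol, "ftol": opt.ftol},
        )
        starts.append({"x0": [float(v) for v in natural(x0)],
                       "nll": float(res.fun), "nfev": int(res.nfev)})
        if best is None or res.fun < best.fun:
            best = res
    theta, nll = best.x, float(best.fun)
    if opt.refine_n_sims:
        res = optimize.minimize(
            objective, theta, args=(opt.refine_n_sims,), method="Powell",
            bounds=list(zip(lo, hi)),
            options={"maxfev": opt.refine_maxfev, "xtol": opt.xtol,
                     "ftol": opt.ftol},
        )
        theta, nll = res.x, float(res.fun)
    param_dict = dict(zip(names, (float(v) for v in natural(theta))))
    params = make_params(variant, param_dict, fixed)
    n = len(trials)
    return FitResult(variant=variant, params=params, param_dict=param_dict,
                     nll=nll, bic=bic(nll, len(names), n), k_params=len(names),
                     n_trials=n, n_sims_per_stimulus=n_sims, seed=seed,
                     starts=starts)


# ---------------------------------------------------------------------------
# random-effects Bayesian model selection


def protected_exceedance_probability(log_evidence: np.ndarray,
                                     n_samples: int = 1_000_000,
                                     seed: int = 0):
    """Protected exceedance probabilities from a subjects-by-models
    log-evidence matrix (log evidence is typically ``-BIC/2``).

    Runs the variational random-effects scheme (Dirichlet posterior over
    model frequencies), estimates exceedance probabilities by Dirichlet
    Monte-Carlo, and protects them by the Bayes omnibus risk — the posterior
    probability that all models are equally frequent, under which each model
    is best with probability 1/K.

    Returns a dict with ``pxp``, ``ep``, ``bor`` and the Dirichlet ``alpha``.
    """
    L = np.asarray(log_evidence, dtype=float)
    if L.ndim != 2 or L.shape[1] < 2:
        raise ValueError("need a (subjects x models>=2) log-evidence matrix")
    n, K = L.shape
    alpha0 = np.ones(K)
    alpha = alpha0.copy()
    for _ in range(200):
        logu = L + (special.digamma(alpha) - special.digamma(alpha.sum()))
        z = np.exp(logu - special.logsumexp(logu, axis=1, keepdims=True))
        alpha_new = alpha0 + z.sum(axis=0)
        if np.max(np.abs(alpha_new - alpha)) < 1e-10:
            alpha = alpha_new
            break
        alpha = alpha_new

    rng = np.random.default_rng(seed)
    draws = rng.dirichlet(alpha, size=int(n_samples))
    ep = np.bincount(draws.argmax(axis=1), minlength=K) / n_samples

    # free energy of the random-effects model
    Elogr = special.digamma(alpha) - special.digamma(alpha.sum())
    with np.errstate(divide="ignore", invalid="ignore"):
        zlogz = np.where(z > 0, z * np.log(z), 0.0)
    f1 = (
        float((z * L).sum())
        + float((z * Elogr[None, :]).sum())
        - float(zlogz.sum())
        + special.gammaln(alpha0.sum()) - special.gammaln(alpha0).sum()
        - special.gammaln(alpha.sum()) + special.gammaln(alpha).sum()
        + float(((alpha0 - alpha) * Elogr).sum())
    )
    # null model: frequencies fixed and equal
    f0 = float(special.logsumexp(L, axis=1).sum() - n * np.log(K))
    bor = 1.0 / (1.0 + np.exp(f1 - f0))
    pxp = ep * (1.0 - bor) + bor / K
    return {"pxp": pxp, "ep": ep, "bor": float(bor), "alpha": alpha}


def compare_models(fits: dict) -> dict:
    """Summarise fits of several variants to the same subjects.

    ``fits`` maps variant name -> list of FitResult (one per subject, same
    order).  Returns summed BICs, per-subject BIC preferences, and PXP.
    """
    variants = sorted(fits)
    n_subj = len(fits[variants[0]])
    bic_matrix = np.array([[fits[v][s].bic for v in variants]
                           for s in range(n_subj)])
    res = protected_exceedance_probability(-bic_matrix / 2.0)
    return {
        "variants": variants,
        "bic_sum": {v: float(bic_matrix[:, i].sum())
                    for i, v in enumerate(variants)},
        "best_count": {v: int((bic_matrix.argmin(axis=1) == i).sum())
                       for i, v in enumerate(variants)},
        "pxp": {v: float(res["pxp"][i]) for i, v in enumerate(variants)},
        "bor": res["bor"],
    }
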