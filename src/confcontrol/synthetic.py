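"""Fully synthetic datasets with known ground truth.

Emulates the study design end-to-end: a bank of dynamic dot stimuli under
the nine conditions, subjects behaving according to the
confidence-controlled double-integration model (100 trials per condition,
900 per subject, by default), confidence ratings generated from the
model's online confidence with Gaussian noise on the log-odds scale, and
multichannel sensor epochs produced by a linear forward mixture of latent
accumulator regressors plus Gaussian noise.

What this emulates — and what it does not: the generated data share the
task structure, the trial counts, and the generative decision model, but
real observers bring parameter drift, lapses, and sensor artefacts that are
deliberately absent here.  Passing recovery tests on these data shows the
pipeline is correct and identifiable under the model, not that the model is
true of any particular dataset.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .accumulators import LEFT, ConfControlParams, simulate_batch
from .encoding import SensorEpochs
from .evidence import compute_evidence_trace
from .stimuli import CONDITION_IDS, ConditionConfig, make_condition_set, \
    sample_dot_directions


@dataclass
class ParamPrior:
    """Truncated Gaussian over one subject-level parameter."""

    mean: float
    sd: float
    lo: float
    hi: float

    def sample(self, rng) -> float:
        for _ in range(1000):
            v = self.mean + self.sd * rng.standard_normal()
            if self.lo <= v <= self.hi:
                return float(v)
        return float(np.clip(self.mean, self.lo, self.hi))


@dataclass
class SyntheticCohortSpec:
    """Study-level description of a synthetic cohort."""

    n_subjects: int = 20
    trials_per_condition: int = 100
    stimuli_per_condition: int = 4
    fixed_b: float = 6.0
    rating_noise_sd: float = 0.5  # log-odds scale
    priors: dict = field(default_factory=lambda: {
        "sigma": ParamPrior(1.2, 0.25, 0.5, 2.0),
        "beta": ParamPrior(2.0, 0.6, 0.3, 6.0),
        "t_d": ParamPrior(1.0, 0.3, 0.2, 1.8),
        "mu_U": ParamPrior(0.3, 0.05, 0.1, 0.6),
        "sigma_U": ParamPrior(0.15, 0.03, 0.05, 0.4),
    })
    condition_config: ConditionConfig = field(default_factory=ConditionConfig)
    master_seed: int = 0


def make_stimulus_bank(condition_config: ConditionConfig | None = None,
                       per_condition: int = 4, seed: int = 0,
                       n_grid: int = 4096):
    """Sample a bank of stimuli and their evidence traces.

    Returns ``(traces, manifest)`` where ``traces`` maps stimulus id ->
    EvidenceTrace (with condition and correct side recorded) and the
    manifest is a DataFrame of ids.  Half of each condition's stimuli are
    leftward, half rightward.
    """
    schedules = make_condition_set(condition_config)
    ss = np.random.SeedSequence(seed)
    seeds = ss.generate_state(len(CONDITION_IDS) * per_condition)
    traces, rows = {}, []
    k = 0
    for cid in CONDITION_IDS:
        for i in range(per_condition):
            side = "left" if i % 2 == 0 else "right"
            sid = f"{cid}/{side}/{i}"
            stim = sample_dot_directions(schedules[cid], side=side,
                                         seed=int(seeds[k]))
            tr = compute_evidence_trace(stim, n_grid=n_grid)
            tr.stimulus_id = sid
            traces[sid] = tr
            rows.append({"stimulus_id": sid, "condition_id": cid,
                         "side": side, "seed": int(seeds[k])})
            k += 1
    return traces, pd.DataFrame(rows)


def _logistic(x):
    return 1.0 / (1.0 + np.exp(-x))


def _logit(p):
    p = np.clip(p, 1e-6, 1 - 1e-6)
    return np.log(p / (1 - p))


def generate_subject(params: ConfControlParams, traces: dict,
                     trials_per_condition: int, subject_id: str,
                     seed: int, rating_noise_sd: float = 0.5,
                     scale_noise: bool = True) -> pd.DataFrame:
    """Simulate one subject's behavioural session.

    Each trial draws a stimulus (with replacement) from its condition's
    bank, runs the confidence-control model once, and reports a rating
    ``logistic(logit(c_commit) + noise)``.  Returns a trial table with the
    ground-truth commit confidence retained.
    """
    rng = np.random.default_rng(seed)
    by_cond = {}
    for sid, tr in traces.items():
        by_cond.setdefault(tr.condition_id, []).append(sid)
    rows = []
    for cid in sorted(by_cond):
        sids = rng.choice(by_cond[cid], size=trials_per_condition)
        uniq, counts = np.unique(sids, return_counts=True)
        for sid, cnt in zip(uniq, counts):
            tr = traces[sid]
            batch = simulate_batch("conf_control", params, tr, int(cnt), rng,
                                   scale_noise=scale_noise)
            c = np.clip(batch.conf_commit, 1e-6, 1 - 1e-6)
            rating = _logistic(_logit(c) + rating_noise_sd
                               * rng.standard_normal(int(cnt)))
            truth = LEFT if tr.side == "left" else 1 - LEFT
            for j in range(int(cnt)):
                choice = "left" if batch.choice[j] == LEFT else "right"
                rows.append({
                    "subject_id": subject_id, "condition_id": cid,
                    "stimulus_id": sid, "choice": choice,
                    "rt": float(batch.rt[j]),
                    "confidence": float(rating[j]), "axis": "down",
                    "correct": bool(batch.choice[j] == truth),
                    "c_commit": float(batch.conf_commit[j]),
                    "timed_out": bool(batch.timed_out[j]),
                })
    return pd.DataFrame(rows)


def generate_cohort(spec: SyntheticCohortSpec):
    """Generate a cohort of synthetic subjects plus a ground-truth manifest.

    Returns ``(trials, traces, manifest)``: the concatenated trial table,
    the shared stimulus bank, and one manifest row per subject holding the
    true parameters and the per-subject seed.
    """
    ss = np.random.SeedSequence(spec.master_seed)
    stim_seed, param_seed = ss.generate_state(2)
    traces, _ = make_stimulus_bank(spec.condition_config,
                                   spec.stimuli_per_condition,
                                   seed=int(stim_seed))
    prng = np.random.default_rng(int(param_seed))
    subj_seeds = ss.generate_state(spec.n_subjects + 2)[2:]
    all_trials, manifest = [], []
    for i in range(spec.n_subjects):
        subject_id = f"synth{i:02d}"
        pvals = {k: prior.sample(prng) for k, prior in spec.priors.items()}
        params = ConfControlParams(b=spec.fixed_b, **pvals)
        df = generate_subject(params, traces, spec.trials_per_condition,
                              subject_id, int(subj_seeds[i]),
                              rating_noise_sd=spec.rating_noise_sd)
        all_trials.append(df)
        manifest.append({"subject_id": subject_id, "seed": int(subj_seeds[i]),
                         "b": spec.fixed_b, **pvals})
    return (pd.concat(all_trials, ignore_index=True), traces,
            pd.DataFrame(manifest))


def generate_sensor_epochs(regressors: np.ndarray, times: np.ndarray,
                           weights: np.ndarray, snr: float, seed: int = 0,
                           sfreq: float = 250.0):
    """Forward-mix latent regressors into noisy sensor epochs.

    ``regressors``: (trials, time, p); ``weights``: (p, sensors).  The
    noiseless signal is ``X @ W``; white Gaussian noise is added at
    ``sd = rms(signal) / snr`` (``snr=inf`` gives clean data).  Returns
    ``(SensorEpochs, weights)``.
    """
    X = np.asarray(regressors, dtype=float)
    W = np.asarray(weights, dtype=float)
    if X.shape[1] != times.size:
        raise ValueError("regressor time axis must match `times`")
    signal = X @ W  # (trials, time, sensors)
    rng = np.random.default_rng(seed)
    if np.isfinite(snr):
        sd = float(np.sqrt(np.mean(signal**2))) / snr
        signal = signal + sd * rng.standard_normal(signal.shape)
    data = np.moveaxis(signal, 2, 1)
    return SensorEpochs(data=data, times=np.asarray(times, dtype=float),
                        sfreq=sfreq), W


def random_mixing_weights(p: int, n_sensors: int, seed: int = 0,
                          focal: dict | None = None) -> np.ndarray:
    """Random forward weights, optionally concentrating a regressor's
    loading on designated sensors (``focal = {regressor_idx: [sensors]}``)."""
    rng = np.random.default_rng(seed)
    W = 0.1 * rng.standard_normal((p, n_sensors))
    if focal:
        for j, sensors in focal.items():
            W[j, list(sensors)] += 1.0
    return W
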