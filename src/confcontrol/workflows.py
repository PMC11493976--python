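"""End-to-end study workflows on synthetic cohorts.

Each function runs one of the package's headline analyses from scratch at a
stated problem size: the termination-rule comparison, parameter and model
recovery for the confidence-control model, confidence prediction, and the
sensor-encoding recovery checks.  The default sizes are scaled-down
versions of the study design (sizes are documented in the methods note);
every function is deterministic given its seed.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .accumulators import ConfControlParams, compare_termination_rules
from .confidence import fisher_z, predict_confidence_ratings
from .encoding import crossval_precision, fit_encoding, invert_predict
from .fitting import OptimizerConfig, compare_models, fit_model
from .synthetic import (
    SyntheticCohortSpec,
    generate_cohort,
    generate_sensor_epochs,
    generate_subject,
    make_stimulus_bank,
    random_mixing_weights,
)

#: reference decision parameters for single-subject demonstrations
REFERENCE_PARAMS = ConfControlParams(sigma=1.2, beta=2.0, t_d=1.0, b=6.0,
                                     mu_U=0.3, sigma_U=0.15)


def _derive(seed: int, k: int) -> int:
    return int(np.random.SeedSequence([seed, k]).generate_state(1)[0] % (2**31))


def termination_workflow(seed: int = 0, per_condition: int = 4,
                         n_reps: int = 250, params=None):
    """Paired speed-accuracy comparison of the two termination rules.

    ``per_condition * n_reps`` paired simulations per condition (default
    1000), identical evidence and noise under both rules, with the primary
    bound matched to the confidence-controlled rule's mean accuracy.
    """
    params = params or REFERENCE_PARAMS
    traces, _ = make_stimulus_bank(per_condition=per_condition,
                                   seed=_derive(seed, 1))
    per_cond, overall, b_primary = compare_termination_rules(
        params, list(traces.values()), n_reps, seed=_derive(seed, 2))
    return {"per_condition": per_cond, "overall": overall,
            "b_primary": b_primary,
            "n_sims_per_condition": per_condition * n_reps}


def recovery_workflow(seed: int = 0, n_subjects: int = 10,
                      trials_per_condition: int = 100, n_sims: int = 500,
                      optimizer: OptimizerConfig | None = None):
    """Parameter recovery for the confidence-control model.

    Subjects lie on a grid spanning the cohort parameter ranges (the grids
    of the three decision parameters are independently permuted so they are
    uncorrelated across subjects); each subject's 900-trial session is
    refit from scratch.  Returns the per-subject true/recovered table plus
    median relative errors (over the first five subjects) and Spearman
    correlations (over the full grid).
    """
    optimizer = optimizer or OptimizerConfig(n_starts=3, maxfev=200,
                                             refine_n_sims=2000,
                                             refine_maxfev=60)
    traces, _ = make_stimulus_bank(per_condition=2, seed=_derive(seed, 1))
    rng = np.random.default_rng(_derive(seed, 2))
    grid = {
        "sigma": rng.permutation(np.linspace(0.9, 1.5, n_subjects)),
        "beta": rng.permutation(np.geomspace(1.0, 4.0, n_subjects)),
        "t_d": rng.permutation(np.linspace(0.6, 1.4, n_subjects)),
    }
    rows = []
    for i in range(n_subjects):
        true = ConfControlParams(sigma=float(grid["sigma"][i]),
                                 beta=float(grid["beta"][i]),
                                 t_d=float(grid["t_d"][i]), b=6.0,
                                 mu_U=0.3, sigma_U=0.15)
        trials = generate_subject(true, traces, trials_per_condition,
                                  f"rec{i:02d}", seed=_derive(seed, 100 + i))
        res = fit_model("conf_control", trials, traces, n_sims=n_sims,
                        seed=_derive(seed, 200 + i), fixed={"b": 6.0},
                        optimizer=optimizer)
        row = {"subject": i}
        for k in ("sigma", "beta", "t_d"):
            row[f"true_{k}"] = getattr(true, k)
            row[f"est_{k}"] = res.param_dict[k]
            row[f"relerr_{k}"] = abs(res.param_dict[k] - getattr(true, k)) \
                / getattr(true, k)
        rows.append(row)
    table = pd.DataFrame(rows)
    head = table.head(5)
    summary = {}
    for k in ("sigma", "beta", "t_d"):
        summary[f"median_relerr_{k}"] = float(head[f"relerr_{k}"].median())
        summary[f"spearman_{k}"] = float(stats.spearmanr(
            table[f"true_{k}"], table[f"est_{k}"]).statistic)
    return table, summary


def model_recovery_workflow(seed: int = 0, n_subjects: int = 10,
                            trials_per_condition: int = 34,
                            n_sims: int = 500,
                            optimizer: OptimizerConfig | None = None):
    """Model recovery: refit conf-control-generated subjects with both the
    confidence-control and the classic model, then compare by BIC and
    protected exceedance probability."""
    optimizer = optimizer or OptimizerConfig(n_starts=2, n_screen=24,
                                             maxfev=200, refine_n_sims=1500,
                                             refine_maxfev=50)
    spec = SyntheticCohortSpec(n_subjects=n_subjects,
                               trials_per_condition=trials_per_condition,
                               stimuli_per_condition=2,
                               master_seed=_derive(seed, 1))
    trials, traces, manifest = generate_cohort(spec)
    fits = {"conf_control": [], "classic": []}
    for i, subj in enumerate(manifest["subject_id"]):
        sub = trials[trials.subject_id == subj]
        for variant, fixed in (("conf_control", {"b": spec.fixed_b}),
                               ("classic", None)):
            fits[variant].append(fit_model(
                variant, sub, traces, n_sims=n_sims,
                seed=_derive(seed, 300 + i), fixed=fixed,
                optimizer=optimizer))
    comparison = compare_models(fits)
    n = len(manifest)
    comparison["frac_prefer_conf_control"] = \
        comparison["best_count"]["conf_control"] / n
    comparison["delta_bic_sum"] = (comparison["bic_sum"]["classic"]
                                   - comparison["bic_sum"]["conf_control"])
    return comparison


def confidence_workflow(seed: int = 0, n_subjects: int = 6,
                        trials_per_condition: int = 10, n: int = 1000):
    """Confidence-prediction recovery on a rated synthetic cohort.

    Ratings are the model's commit confidence perturbed by log-odds noise
    (sd 0.5); prediction uses each subject's true choice/RT parameters and
    1000 conditioned simulations per trial.
    """
    spec = SyntheticCohortSpec(n_subjects=n_subjects,
                               trials_per_condition=trials_per_condition,
                               stimuli_per_condition=2,
                               master_seed=_derive(seed, 1))
    trials, traces, manifest = generate_cohort(spec)
    params = {
        r.subject_id: ConfControlParams(sigma=r.sigma, beta=r.beta,
                                        t_d=r.t_d, b=r.b, mu_U=r.mu_U,
                                        sigma_U=r.sigma_U)
        for r in manifest.itertuples()
    }
    per_trial, per_subject, group = predict_confidence_ratings(
        trials, traces, params, n=n, seed=_derive(seed, 2))
    return per_trial, per_subject, group


def encoding_workflow(seed: int = 0, n_topography_runs: int = 100,
                      n_shuffles: int = 50):
    """Inverted-encoding recovery checks on forward-generated sensor data.

    Returns exactness of the noiseless round trip, the trial-shuffle null,
    and the known-topography recovery rate at SNR 1.
    """
    rng = np.random.default_rng(_derive(seed, 1))
    n_trials, n_time, n_sensors = 40, 20, 12
    times = np.arange(n_time) / 250.0

    def design(r):
        return np.stack([r.standard_normal((n_trials, n_time)),
                         r.standard_normal((n_trials, n_time)),
                         np.ones((n_trials, n_time))], axis=-1)

    # noiseless round trip
    X = design(rng)
    W_true = random_mixing_weights(3, n_sensors, seed=_derive(seed, 2))
    ep, _ = generate_sensor_epochs(X, times, W_true, snr=np.inf)
    W_hat = fit_encoding(X.reshape(-1, 3),
                         np.moveaxis(ep.data, 1, 2).reshape(-1, n_sensors))
    x_hat = invert_predict(W_hat, np.moveaxis(ep.data, 1, 2)
                           .reshape(-1, n_sensors))
    round_trip = {
        "weight_err": float(np.abs(W_hat.w - W_true).max()),
        "x_err": float(np.abs(x_hat - X.reshape(-1, 3)).max()),
    }

    # trial-shuffle null at moderate SNR
    Xn = design(rng)
    epn, _ = generate_sensor_epochs(Xn, times, W_true, snr=1.0,
                                    seed=_derive(seed, 3))
    zs = []
    for s in range(n_shuffles):
        perm = np.random.default_rng(_derive(seed, 500 + s)).permutation(n_trials)
        res = crossval_precision(Xn, epn.data[perm], folds=10, seed=s,
                                 sensor_map=False)
        zs.append(res["z"][:2])
    shuffle_mean_z = float(np.mean(zs))

    # known-topography recovery at SNR 1
    hits = 0
    for r in range(n_topography_runs):
        rr = np.random.default_rng(_derive(seed, 1000 + r))
        Xr = design(rr)
        Wr = random_mixing_weights(3, n_sensors, seed=_derive(seed, 2000 + r),
                                   focal={1: [4, 5]})
        epr, _ = generate_sensor_epochs(Xr, times, Wr, snr=1.0,
                                        seed=_derive(seed, 3000 + r))
        res = crossval_precision(Xr, epr.data, folds=10, seed=r)
        if int(np.nanargmax(res["sensor_z"][:, 1])) in (4, 5):
            hits += 1
    return {
        "round_trip": round_trip,
        "shuffle_mean_z": shuffle_mean_z,
        "topography_hit_rate": hits / n_topography_runs,
    }


def pipeline_encoding_workflow(seed: int = 0, trials_per_condition: int = 6,
                               n_conditioned: int = 300, snr: float = 1.0,
                               n_sensors: int = 16):
    """Full latent-to-sensor pipeline on one synthetic subject.

    Conditioned-simulation median traces are forward-mixed into sensor
    epochs (motor loading concentrated on two designated sensors) and
    decoded back with the slope encoding analysis; reports the
    cross-validated precisions and the raw vs slope regressor correlations.
    """
    from .confidence import conditioned_simulation
    from .encoding import encode_accumulators, resample_traces

    traces, _ = make_stimulus_bank(per_condition=2, seed=_derive(seed, 1))
    params = REFERENCE_PARAMS
    trials = generate_subject(params, traces, trials_per_condition, "enc0",
                              seed=_derive(seed, 2))
    rng = np.random.default_rng(_derive(seed, 3))
    prim, mot = [], []
    for _, t in trials.iterrows():
        ct = conditioned_simulation(t.choice, t.rt, params,
                                    traces[t.stimulus_id], n=n_conditioned,
                                    rng=rng, return_traces=True,
                                    pre_s=0.5, post_s=0.2)
        prim.append(ct.x_chosen)
        mot.append(ct.y_chosen)
    prim, mot = np.array(prim), np.array(mot)
    t120 = ct.times
    t250 = np.arange(-0.5, 0.2001, 1 / 250)
    X250 = np.stack([resample_traces(prim, t120, t250),
                     resample_traces(mot, t120, t250),
                     np.ones((len(prim), t250.size))], axis=-1)
    W = random_mixing_weights(3, n_sensors, seed=_derive(seed, 4),
                              focal={0: [2, 3], 1: [10, 11]})
    ep, _ = generate_sensor_epochs(X250, t250, W, snr=snr,
                                   seed=_derive(seed, 5))
    res = encode_accumulators(ep, prim, mot, t120, window=(-0.4, 0.0),
                              folds=10, seed=_derive(seed, 6))
    return {
        "z_primary": float(res["z"][0]),
        "z_motor": float(res["z"][1]),
        "corr_raw_z": fisher_z(res["corr_raw"]),
        "corr_slope_z": fisher_z(res["corr_slope"]),
        "motor_topography_argmax": int(np.nanargmax(res["sensor_z"][:, 1])),
        "n_trials": len(trials),
    }
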