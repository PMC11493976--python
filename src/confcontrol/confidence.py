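"""Post-decision confidence prediction by trial-conditioned simulation.

The fitted model (parameters estimated from choices and response times
only — never from confidence ratings) is simulated many times on each
trial's stimulus; instances reproducing the observed choice within a small
RT window are kept, and the median of their latent time courses provides a
trial-wise estimate of the accumulators and of online confidence.  The
final online confidence of the chosen side is the model's prediction of the
post-decision confidence rating.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .accumulators import LEFT, RIGHT, outcomes_from_paths, simulate_paths


def fisher_z(r):
    """Fisher transform ``atanh(r)``; |r| >= 1 is clipped with a warning."""
    r = np.asarray(r, dtype=float)
    if np.any(np.abs(r) >= 1):
        warnings.warn("correlation at or beyond +/-1 clipped before atanh")
        r = np.clip(r, -1 + 1e-12, 1 - 1e-12)
    out = np.arctanh(r)
    return float(out) if out.ndim == 0 else out


@dataclass
class ConditionedTraces:
    """Median latent traces of simulations consistent with one trial."""

    n_matched: int
    fallback_level: int  # 0: base window; 1/2: doubled; 3: nearest-RT
    c_final_chosen: float
    times: np.ndarray | None = None  # response-locked seconds
    x_chosen: np.ndarray | None = None
    y_chosen: np.ndarray | None = None
    c_chosen: np.ndarray | None = None


def _response_locked(arr, frames, pre, post):
    """Stack rows of ``arr`` aligned to each row's commit frame.

    Pads with the resting value 0 before stimulus onset and holds the last
    sample beyond the simulation horizon.
    """
    n, T = arr.shape
    out = np.empty((n, pre + post + 1))
    for i in range(n):
        f = frames[i]
        lo = f - pre
        take_lo = max(lo, 0)
        seg = arr[i, take_lo:min(f + post + 1, T)]
        left_pad = take_lo - lo
        right_pad = pre + post + 1 - left_pad - seg.size
        out[i] = np.concatenate([
            np.zeros(left_pad), seg,
            np.full(right_pad, seg[-1] if seg.size else 0.0)])
    return out


def conditioned_simulation(choice: str, rt: float, params, stimulus_trace,
                           n: int = 1000, rt_window: float = 0.1,
                           rng=None, seed=None, scale_noise: bool = True,
                           return_traces: bool = False,
                           pre_s: float = 0.4, post_s: float = 0.2) -> ConditionedTraces:
    """Simulate ``n`` noisy instances of a trial and keep the consistent ones.

    Instances must make the observed choice within ``rt_window`` seconds of
    the observed RT.  If none match, the window is doubled (up to 4x); if
    still none, the nearest-RT instance with the observed choice is used
    (or, failing even that, the nearest-RT instance overall).
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    paths = simulate_paths("conf_control", params, stimulus_trace, n, rng,
                           scale_noise=scale_noise)
    ch, frames, _ = outcomes_from_paths("conf_control", params, paths)
    dt = stimulus_trace.dt
    ndt = np.abs(params.mu_U + params.sigma_U * rng.standard_normal(n))
    rt_sim = (frames + 1) * dt + ndt
    code = LEFT if choice == "left" else RIGHT
    same = ch == code

    level = 0
    window = rt_window
    matched = same & (np.abs(rt_sim - rt) <= window)
    while not matched.any() and window < 4 * rt_window:
        window *= 2
        level += 1
        matched = same & (np.abs(rt_sim - rt) <= window)
    if not matched.any():
        level = 3
        pool = np.flatnonzero(same) if same.any() else np.arange(n)
        matched = np.zeros(n, dtype=bool)
        matched[pool[np.argmin(np.abs(rt_sim[pool] - rt))]] = True

    idx = np.flatnonzero(matched)
    x_ch = paths["x_left"] if code == LEFT else paths["x_right"]
    y_ch = paths["y_left"] if code == LEFT else paths["y_right"]
    c_ch = paths["c_left"] if code == LEFT else paths["c_right"]
    c_commit = c_ch[idx, frames[idx]]
    result = ConditionedTraces(
        n_matched=int(idx.size), fallback_level=level,
        c_final_chosen=float(np.median(c_commit)),
    )
    if return_traces:
        pre = int(round(pre_s / dt))
        post = int(round(post_s / dt))
        result.times = np.arange(-pre, post + 1) * dt
        result.x_chosen = np.median(
            _response_locked(x_ch[idx], frames[idx], pre, post), axis=0)
        result.y_chosen = np.median(
            _response_locked(y_ch[idx], frames[idx], pre, post), axis=0)
        result.c_chosen = np.median(
            _response_locked(c_ch[idx], frames[idx], pre, post), axis=0)
    return result


def predict_confidence_ratings(trials: pd.DataFrame, stimuli: dict,
                               params_by_subject: dict, n: int = 1000,
                               rt_window: float = 0.1, seed: int = 0,
                               scale_noise: bool = True,
                               min_rated: int = 10):
    """Predict every trial's confidence rating and correlate with the data.

    Returns ``(per_trial, per_subject, group)``: per-trial predictions,
    per-subject Pearson correlations between within-subject z-scored
    ratings and predicted confidence (Fisher transformed), and a group
    summary with the mean z plus mean predicted confidence split by
    correct/error and fast/slow (within-subject median RT) trials.
    Subjects with fewer than ``min_rated`` rated trials are excluded from
    the group statistics with a warning.
    """
    ss = np.random.SeedSequence(seed)
    rows = []
    for (subj,), grp in trials.groupby(["subject_id"]):
        params = params_by_subject[subj]
        child = np.random.default_rng(ss.spawn(1)[0])
        for _, t in grp.iterrows():
            ct = conditioned_simulation(t["choice"], float(t["rt"]), params,
                                        stimuli[t["stimulus_id"]], n=n,
                                        rt_window=rt_window, rng=child,
                                        scale_noise=scale_noise)
            rows.append({
                "subject_id": subj, "trial": t.name,
                "condition_id": t["condition_id"], "rt": float(t["rt"]),
                "correct": bool(t["correct"]) if "correct" in t else np.nan,
                "rating": float(t["confidence"]) if pd.notna(t.get("confidence")) else np.nan,
                "c_final_chosen": ct.c_final_chosen,
                "n_matched": ct.n_matched, "fallback": ct.fallback_level,
            })
    per_trial = pd.DataFrame(rows)

    subj_rows = []
    for subj, grp in per_trial.groupby("subject_id"):
        rated = grp.dropna(subset=["rating"])
        if len(rated) < min_rated:
            warnings.warn(f"subject {subj}: fewer than {min_rated} rated "
                          "trials, excluded from group statistics")
            continue
        ratings = rated["rating"].to_numpy()
        zr = (ratings - ratings.mean()) / ratings.std(ddof=0)
        pred = rated["c_final_chosen"].to_numpy()
        if np.std(pred) == 0 or np.std(ratings) == 0:
            r = 0.0
        else:
            r = float(np.corrcoef(zr, pred)[0, 1])
        med_rt = grp["rt"].median()
        subj_rows.append({
            "subject_id": subj, "r": r, "z": fisher_z(r),
            "pred_correct": grp.loc[grp["correct"] == True, "c_final_chosen"].mean(),
            "pred_error": grp.loc[grp["correct"] == False, "c_final_chosen"].mean(),
            "pred_fast": grp.loc[grp["rt"] <= med_rt, "c_final_chosen"].mean(),
            "pred_slow": grp.loc[grp["rt"] > med_rt, "c_final_chosen"].mean(),
        })
    per_subject = pd.DataFrame(subj_rows)
    group = {
        "mean_z": float(per_subject["z"].mean()) if len(per_subject) else np.nan,
        "mean_pred_correct": float(per_subject["pred_correct"].mean()),
        "mean_pred_error": float(per_subject["pred_error"].mean()),
        "mean_pred_fast": float(per_subject["pred_fast"].mean()),
        "mean_pred_slow": float(per_subject["pred_slow"].mean()),
        "n_subjects": int(len(per_subject)),
    }
    return per_trial, per_subject, group
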