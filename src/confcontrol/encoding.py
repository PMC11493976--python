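"""Inverted linear encoding of latent accumulator signals in sensor data.

Multichannel response-locked epochs ``Y`` are modelled as a linear mixture
of latent regressors ``X`` (here: the slopes of the simulated primary and
motor accumulators, plus an intercept), ``Y = X w``.  Weights are estimated
by ordinary least squares and then inverted — the latent variables are
predicted from held-out sensor data by least squares on the weight matrix.
Decoding precision is the Fisher-transformed Pearson correlation between
predicted and simulated regressors under 10-fold cross-validation with
whole trials per fold.

Slopes rather than raw accumulator values are encoded because the raw
primary and motor traces are strongly correlated ramps; their derivatives
separate the near-linear primary profile from the accelerating motor
profile.  Sensor slopes use a 6-sample window at 250 Hz and evidence slopes
a 3-sample window after interpolating the 120 Hz model traces to the sensor
grid, matching the two effective rates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal
from sklearn.model_selection import KFold

from .confidence import fisher_z


@dataclass
class SensorEpochs:
    """Response-locked multichannel epochs, ``data`` (trials, sensors, time)."""

    data: np.ndarray
    times: np.ndarray  # seconds, response at 0
    sfreq: float = 250.0
    labels: list = field(default_factory=list)

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.data.ndim != 3 or self.data.shape[2] != self.times.size:
            raise ValueError("data must be (trials, sensors, time)")
        if not self.labels:
            self.labels = [f"S{i:02d}" for i in range(self.data.shape[1])]

    def window(self, lo: float, hi: float):
        """Boolean mask of timepoints with ``lo <= t <= hi``."""
        return (self.times >= lo - 1e-9) & (self.times <= hi + 1e-9)


@dataclass
class EncodingWeights:
    """Regressors-by-sensors weight matrix with provenance."""

    w: np.ndarray  # (p, sensors)
    regressors: tuple
    info: dict = field(default_factory=dict)


class RankDeficientError(np.linalg.LinAlgError):
    pass


def lowpass(epochs: SensorEpochs, cutoff: float = 8.0) -> SensorEpochs:
    """Zero-phase 4th-order Butterworth lowpass along the time axis."""
    nyq = epochs.sfreq / 2.0
    if cutoff >= nyq:
        raise ValueError(f"cutoff {cutoff} Hz >= Nyquist {nyq} Hz")
    sos = signal.butter(4, cutoff, btype="low", fs=epochs.sfreq, output="sos")
    data = signal.sosfiltfilt(sos, epochs.data, axis=-1)
    return SensorEpochs(data=data, times=epochs.times.copy(),
                        sfreq=epochs.sfreq, labels=list(epochs.labels))


def windowed_slope(series, window_samples: int, sfreq: float = 1.0):
    """Sliding-window OLS slope along the last axis, in units per second.

    The slope of each length-``window_samples`` window is assigned to the
    window's final sample, so the output loses ``window_samples - 1``
    leading samples.
    """
    if window_samples < 2:
        raise ValueError("window_samples must be >= 2")
    y = np.asarray(series, dtype=float)
    if y.shape[-1] < window_samples:
        raise ValueError("series shorter than the slope window")
    m = window_samples
    t = np.arange(m) - (m - 1) / 2.0
    coef = t / np.dot(t, t)  # OLS slope weights, per sample
    windows = np.lib.stride_tricks.sliding_window_view(y, m, axis=-1)
    return windows @ coef * sfreq


def fit_encoding(X: np.ndarray, Y: np.ndarray) -> EncodingWeights:
    """OLS weights ``(X'X)^-1 X'Y`` mapping regressors to sensors."""
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise RankDeficientError("design matrix is rank deficient")
    w, *_ = np.linalg.lstsq(X, Y, rcond=None)
    return EncodingWeights(w=w, regressors=tuple(range(X.shape[1])))


def invert_predict(W: EncodingWeights | np.ndarray, Y: np.ndarray,
                   require_full_rank: bool = True) -> np.ndarray:
    """Invert the encoding map: least-squares prediction of X from Y.

    With noiseless ``Y = X w`` and at least as many sensors as regressors
    the recovery is exact.
    """
    w = W.w if isinstance(W, EncodingWeights) else np.asarray(W, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if require_full_rank and np.linalg.matrix_rank(w) < w.shape[0]:
        raise RankDeficientError("weight matrix rank deficient in regressors")
    return Y @ np.linalg.pinv(w)


def _precision(x_true, x_pred):
    """Fisher-z precision per regressor; NaN for zero-variance regressors."""
    p = x_true.shape[1]
    out = np.full(p, np.nan)
    for j in range(p):
        if np.std(x_true[:, j]) == 0 or np.std(x_pred[:, j]) == 0:
            continue
        out[j] = fisher_z(np.corrcoef(x_true[:, j], x_pred[:, j])[0, 1])
    return out


def crossval_precision(design: np.ndarray, epochs_data: np.ndarray,
                       folds: int = 10, seed: int = 0,
                       sensor_map: bool = True):
    """Cross-validated decoding precision of the inverted encoding model.

    ``design``: (trials, time, p) regressors; ``epochs_data``: (trials,
    sensors, time) matching samples.  Folds are assigned by whole trials.
    Returns a dict with ``z`` (per regressor, pooled held-out samples),
    ``r``, and (optionally) ``sensor_z`` of shape (sensors, p) from
    single-sensor decoding.
    """
    X = np.asarray(design, dtype=float)
    Yd = np.asarray(epochs_data, dtype=float)
    n_trials, n_time, p = X.shape
    n_sensors = Yd.shape[1]
    if n_trials < folds:
        raise ValueError("fewer trials than folds")
    Y = np.moveaxis(Yd, 1, 2)  # (trials, time, sensors)
    kf = KFold(n_splits=folds, shuffle=True, random_state=seed)
    pred = np.empty((n_trials, n_time, p))
    sensor_pred = (np.empty((n_sensors, n_trials, n_time, p))
                   if sensor_map else None)
    for train, test in kf.split(np.arange(n_trials)):
        Xtr = X[train].reshape(-1, p)
        Ytr = Y[train].reshape(-1, n_sensors)
        W = fit_encoding(Xtr, Ytr)
        pred[test] = invert_predict(W, Y[test].reshape(-1, n_sensors)).reshape(
            len(test), n_time, p)
        if sensor_map:
            for s in range(n_sensors):
                ws = np.linalg.lstsq(Xtr, Ytr[:, [s]], rcond=None)[0]
                sensor_pred[s, test] = (
                    Y[test][..., [s]].reshape(-1, 1) @ np.linalg.pinv(ws)
                ).reshape(len(test), n_time, p)
    x_all = X.reshape(-1, p)
    z = _precision(x_all, pred.reshape(-1, p))
    out = {"z": z, "r": np.tanh(z)}
    if sensor_map:
        out["sensor_z"] = np.stack([
            _precision(x_all, sensor_pred[s].reshape(-1, p))
            for s in range(n_sensors)])
    return out


def resample_traces(series: np.ndarray, times_from: np.ndarray,
                    times_to: np.ndarray) -> np.ndarray:
    """Linear interpolation of (trials, time) latent traces onto a new grid."""
    s = np.atleast_2d(np.asarray(series, dtype=float))
    return np.stack([np.interp(times_to, times_from, row) for row in s])


def encode_accumulators(epochs: SensorEpochs, primary: np.ndarray,
                        motor: np.ndarray, trace_times: np.ndarray,
                        window=(-0.4, 0.0), folds: int = 10,
                        evid_slope: int = 3, sensor_slope: int = 6,
                        lowpass_hz: float | None = 8.0, seed: int = 0):
    """Full slope-encoding analysis of primary/motor accumulator traces.

    Lowpass-filters the sensor epochs, computes 6-sample sensor slopes and
    3-sample slopes of the latent traces (after interpolation to the sensor
    grid), pairs them sample-by-sample inside the pre-response window (each
    slope is assigned to its window's final sample), and runs the
    cross-validated inverted encoding model.

    Returns the ``crossval_precision`` dict plus the design and the pooled
    raw/slope regressor correlations (the derivative step should decorrelate
    the two accumulators).
    """
    ep = lowpass(epochs, lowpass_hz) if lowpass_hz else epochs
    prim250 = resample_traces(primary, trace_times, ep.times)
    mot250 = resample_traces(motor, trace_times, ep.times)
    y_slope = windowed_slope(ep.data, sensor_slope, ep.sfreq)
    p_slope = windowed_slope(prim250, evid_slope, ep.sfreq)
    m_slope = windowed_slope(mot250, evid_slope, ep.sfreq)
    # each slope series is aligned to its window's last sample
    t_y = ep.times[sensor_slope - 1:]
    t_x = ep.times[evid_slope - 1:]
    mask_y = (t_y >= window[0] - 1e-9) & (t_y <= window[1] + 1e-9)
    common = t_y[mask_y]
    sel_x = np.isin(np.round(t_x, 9), np.round(common, 9))
    X = np.stack([p_slope[:, sel_x], m_slope[:, sel_x],
                  np.ones_like(m_slope[:, sel_x])], axis=-1)
    Y = y_slope[:, :, mask_y]
    res = crossval_precision(X, Y, folds=folds, seed=seed)
    res["times"] = common
    res["design"] = X
    mask250 = (ep.times >= window[0] - 1e-9) & (ep.times <= window[1] + 1e-9)
    res["corr_raw"] = float(np.corrcoef(prim250[:, mask250].ravel(),
                                        mot250[:, mask250].ravel())[0, 1])
    res["corr_slope"] = float(np.corrcoef(X[..., 0].ravel(),
                                          X[..., 1].ravel())[0, 1])
    return res


def decode_confidence_weights(epochs: SensorEpochs, ratings: np.ndarray,
                              search_window=(0.0, 0.2), folds: int = 10,
                              seed: int = 0):
    """Confidence-decoding weights from the best post-response timepoint.

    Each trial carries a single rating; the rating (plus intercept) is
    encoded at every timepoint within the search window, and the timepoint
    with the greatest cross-validated precision is selected.  Returns the
    winning ``EncodingWeights`` and the timepoint (s).
    """
    ratings = np.asarray(ratings, dtype=float)
    if np.std(ratings) == 0:
        raise ValueError("ratings have zero variance")
    mask = epochs.window(*search_window)
    if not mask.any():
        raise ValueError("search window outside the epoch time axis")
    tidx = np.flatnonzero(mask)
    n = ratings.size
    X = np.column_stack([ratings, np.ones(n)])
    kf = KFold(n_splits=folds, shuffle=True, random_state=seed)
    best = (-np.inf, None)
    for ti in tidx:
        Y = epochs.data[:, :, ti]
        pred = np.empty(n)
        for train, test in kf.split(np.arange(n)):
            W = fit_encoding(X[train], Y[train])
            pred[test] = invert_predict(W, Y[test])[:, 0]
        if np.std(pred) == 0:
            continue
        z = fisher_z(np.corrcoef(ratings, pred)[0, 1])
        if z > best[0]:
            best = (z, ti)
    z_best, ti = best
    if ti is None:
        raise ValueError("no timepoint produced a varying prediction")
    W = fit_encoding(X, epochs.data[:, :, ti])
    W.regressors = ("confidence", "intercept")
    W.info = {"timepoint_s": float(epochs.times[ti]), "cv_z": float(z_best),
              "folds": folds, "seed": seed}
    return W, float(epochs.times[ti])


def online_confidence_signal(W: EncodingWeights, epochs: SensorEpochs,
                             window=(-0.4, 0.0)) -> np.ndarray:
    """Apply confidence-decoding weights over pre-response time.

    Returns the (trials, time) predicted-confidence series on the epochs'
    timepoints within ``window``.
    """
    mask = epochs.window(*window)
    if not mask.any():
        raise ValueError("window outside the epoch time axis")
    n_trials = epochs.data.shape[0]
    Y = np.moveaxis(epochs.data[:, :, mask], 1, 2).reshape(
        -1, epochs.data.shape[1])
    pred = invert_predict(W, Y)[:, 0]
    return pred.reshape(n_trials, int(mask.sum()))


def control_strength_split(conf_series: np.ndarray,
                           motor_slope_series: np.ndarray,
                           trials, series_times: np.ndarray,
                           window=(-0.2, 0.0)):
    """Median split of trials by within-trial confidence-motor coupling.

    Correlates, per trial, the predicted online-confidence series with the
    motor-accumulator slope series inside the window, median-splits the
    correlations within subject and condition, and summarises accuracy and
    median RT per split half.

    Returns (per_trial correlations, summary DataFrame indexed by split).
    """
    import pandas as pd

    t = np.asarray(series_times, dtype=float)
    mask = (t >= window[0] - 1e-9) & (t <= window[1] + 1e-9)
    if mask.sum() < 2:
        raise ValueError("fewer than 2 samples in the correlation window")
    a = np.asarray(conf_series, dtype=float)[:, mask]
    b = np.asarray(motor_slope_series, dtype=float)[:, mask]
    n = a.shape[0]
    r = np.full(n, np.nan)
    for i in range(n):
        if np.std(a[i]) > 0 and np.std(b[i]) > 0:
            r[i] = np.corrcoef(a[i], b[i])[0, 1]
    df = trials.reset_index(drop=True).copy()
    df["coupling_r"] = r
    df["split"] = ""
    for (_, _), grp in df.groupby(["subject_id", "condition_id"]):
        med = grp["coupling_r"].median()
        df.loc[grp.index, "split"] = np.where(
            grp["coupling_r"] > med, "stronger", "weaker")
    summary = df.groupby("split").agg(
        accuracy=("correct", "mean"), median_rt=("rt", "median"),
        n=("rt", "size"))
    return df, summary
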