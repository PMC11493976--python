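"""Inverted encoding model: filtering, slopes, OLS, inversion, decoding."""

import numpy as np
import pandas as pd
import pytest

from confcontrol import encoding as enc
from confcontrol import synthetic as syn


def make_epochs(data, sfreq=250.0, t0=-0.5):
    n_time = data.shape[2]
    times = t0 + np.arange(n_time) / sfreq
    return enc.SensorEpochs(data=data, times=times, sfreq=sfreq)


class TestLowpass:
    def test_dc_preserved(self):
        ep = make_epochs(np.full((2, 3, 200), 1.7))
        out = enc.lowpass(ep, 8.0)
        assert np.allclose(out.data, 1.7, atol=1e-9)

    @pytest.mark.parametrize("freq,check", [
        (40.0, lambda g: g < 0.1),   # > 20 dB attenuation in the stopband
        (1.0, lambda g: g > 0.95),   # < 5% loss in the passband
    ])
    def test_frequency_response(self, freq, check):
        t = np.arange(1000) / 250.0
        x = np.sin(2 * np.pi * freq * t)
        ep = make_epochs(x[None, None, :])
        y = enc.lowpass(ep, 8.0).data[0, 0]
        gain = np.ptp(y[200:-200]) / np.ptp(x[200:-200])
        assert check(gain)

    def test_cutoff_above_nyquist_rejected(self):
        ep = make_epochs(np.zeros((1, 1, 100)))
        with pytest.raises(ValueError):
            enc.lowpass(ep, 200.0)


class TestWindowedSlope:
    def test_linear_series(self):
        sfreq = 250.0
        t = np.arange(100) / sfreq
        y = 3.0 * t + 1.0
        s = enc.windowed_slope(y, 6, sfreq)
        assert np.allclose(s, 3.0, atol=1e-9)
        assert s.shape[-1] == 95

    def test_constant_series(self):
        s = enc.windowed_slope(np.full(50, 2.0), 3, 250.0)
        assert np.allclose(s, 0.0, atol=1e-12)

    def test_quadratic_matches_ols_oracle(self):
        sfreq = 100.0
        t = np.arange(30) / sfreq
        y = t**2
        m = 5
        s = enc.windowed_slope(y, m, sfreq)
        for i, out in enumerate(s):
            seg_t = t[i:i + m]
            seg_y = y[i:i + m]
            slope = np.polyfit(seg_t, seg_y, 1)[0]
            assert out == pytest.approx(slope, abs=1e-9)

    def test_short_series_rejected(self):
        with pytest.raises(ValueError):
            enc.windowed_slope(np.zeros(4), 6)


class TestFitInvert:
    def test_exact_recovery_and_round_trip(self):
        rng = np.random.default_rng(0)
        X = np.column_stack([rng.standard_normal((200, 2)), np.ones(200)])
        W_true = rng.standard_normal((3, 8))
        Y = X @ W_true
        W = enc.fit_encoding(X, Y)
        assert np.allclose(W.w, W_true, atol=1e-10)
        X_hat = enc.invert_predict(W, Y)
        assert np.allclose(X_hat, X, atol=1e-8)

    def test_orthonormal_design_identity(self):
        Q, _ = np.linalg.qr(np.random.default_rng(1).standard_normal((50, 3)))
        Y = np.random.default_rng(2).standard_normal((50, 4))
        W = enc.fit_encoding(Q, Y)
        assert np.allclose(W.w, Q.T @ Y, atol=1e-10)

    def test_square_invertible_case(self):
        rng = np.random.default_rng(3)
        X = rng.standard_normal((40, 3))
        W_true = rng.standard_normal((3, 3))
        X_hat = enc.invert_predict(enc.fit_encoding(X, X @ W_true), X @ W_true)
        assert np.allclose(X_hat, X, atol=1e-8)

    def test_duplicated_regressors_rejected(self):
        x = np.random.default_rng(4).standard_normal(30)
        X = np.column_stack([x, x, np.ones(30)])
        with pytest.raises(enc.RankDeficientError):
            enc.fit_encoding(X, np.random.default_rng(5).standard_normal((30, 4)))


class TestCrossval:
    @staticmethod
    def forward_data(n_trials=40, n_time=20, n_sensors=12, snr=np.inf,
                     seed=0, focal=None):
        rng = np.random.default_rng(seed)
        X = np.stack([rng.standard_normal((n_trials, n_time)),
                      rng.standard_normal((n_trials, n_time)),
                      np.ones((n_trials, n_time))], axis=-1)
        W = syn.random_mixing_weights(3, n_sensors, seed=seed + 1, focal=focal)
        times = np.arange(n_time) / 250.0
        ep, _ = syn.generate_sensor_epochs(X, times, W, snr=snr, seed=seed + 2)
        return X, ep

    def test_noiseless_precision_is_perfect(self):
        X, ep = self.forward_data()
        res = enc.crossval_precision(X, ep.data, folds=10, sensor_map=False)
        assert np.all(np.tanh(res["z"][:2]) > 0.999)

    def test_fewer_trials_than_folds_rejected(self):
        X, ep = self.forward_data(n_trials=5)
        with pytest.raises(ValueError):
            enc.crossval_precision(X, ep.data, folds=10)

    def test_known_topography_recovered(self):
        X, ep = self.forward_data(snr=1.0, focal={1: [4, 5]}, seed=3)
        res = enc.crossval_precision(X, ep.data, folds=10)
        assert int(np.nanargmax(res["sensor_z"][:, 1])) in (4, 5)

    def test_crossval_below_in_sample(self):
        gaps = []
        for s in range(12):
            X, ep = self.forward_data(snr=0.7, seed=10 + s, n_trials=30)
            res = enc.crossval_precision(X, ep.data, folds=10, seed=s,
                                         sensor_map=False)
            n, t, p = X.shape
            W = enc.fit_encoding(X.reshape(-1, p),
                                 np.moveaxis(ep.data, 1, 2).reshape(n * t, -1))
            pred = enc.invert_predict(W, np.moveaxis(ep.data, 1, 2).reshape(n * t, -1))
            z_in = enc._precision(X.reshape(-1, p), pred)
            gaps.append(np.nanmean(z_in[:2] - res["z"][:2]))
        assert np.mean(gaps) > 0


class TestConfidenceDecoding:
    @staticmethod
    def latency_data(latent_t=0.12, n_trials=60, n_sensors=8, seed=0,
                     noise=0.3):
        rng = np.random.default_rng(seed)
        ratings = rng.uniform(0, 1, n_trials)
        times = np.arange(-0.3, 0.3001, 1 / 250)
        data = noise * rng.standard_normal((n_trials, n_sensors, times.size))
        w = rng.standard_normal(n_sensors)
        ti = int(np.argmin(np.abs(times - latent_t)))
        data[:, :, ti] += np.outer(ratings, w)
        return enc.SensorEpochs(data=data, times=times), ratings

    def test_known_latency_recovered(self):
        ep, ratings = self.latency_data()
        W, t_best = enc.decode_confidence_weights(ep, ratings, seed=1)
        assert abs(t_best - 0.12) <= 0.012

    def test_higher_snr_timepoint_wins(self):
        rng = np.random.default_rng(5)
        ratings = rng.uniform(0, 1, 50)
        times = np.arange(0.0, 0.2001, 1 / 250)
        data = 0.5 * rng.standard_normal((50, 6, times.size))
        w = rng.standard_normal(6)
        ia, ib = 10, 30
        data[:, :, ia] += 0.5 * np.outer(ratings, w)
        data[:, :, ib] += 2.0 * np.outer(ratings, w)
        ep = enc.SensorEpochs(data=data, times=times)
        _, t_best = enc.decode_confidence_weights(ep, ratings, seed=2)
        assert t_best == pytest.approx(times[ib])

    def test_constant_ratings_rejected(self):
        ep, _ = self.latency_data()
        with pytest.raises(ValueError):
            enc.decode_confidence_weights(ep, np.full(ep.data.shape[0], 0.5))

    def test_window_outside_epoch_rejected(self):
        ep, ratings = self.latency_data()
        with pytest.raises(ValueError):
            enc.decode_confidence_weights(ep, ratings, search_window=(2.0, 2.2))


class TestOnlineConfidenceSignal:
    def test_forward_ramp_recovered(self):
        rng = np.random.default_rng(0)
        n_trials, n_sensors = 40, 8
        times = np.arange(-0.5, 0.2001, 1 / 250)
        ramp = np.linspace(0, 1, times.size)[None, :] \
            * rng.uniform(0.5, 1.5, n_trials)[:, None]
        X = np.stack([ramp, np.ones_like(ramp)], axis=-1)
        W_true = rng.standard_normal((2, n_sensors))
        ep, _ = syn.generate_sensor_epochs(X, times, W_true, snr=5.0, seed=1)
        W = enc.EncodingWeights(w=W_true, regressors=("confidence", "intercept"))
        pred = enc.online_confidence_signal(W, ep, window=(-0.4, 0.0))
        mask = ep.window(-0.4, 0.0)
        r = np.corrcoef(pred.ravel(), ramp[:, mask].ravel())[0, 1]
        assert r > 0.9

    def test_zeroed_sensors_give_constant(self):
        times = np.arange(-0.5, 0.1, 1 / 250)
        ep = enc.SensorEpochs(data=np.zeros((5, 4, times.size)), times=times)
        W = enc.EncodingWeights(w=np.random.default_rng(1).standard_normal((2, 4)),
                                regressors=("confidence", "intercept"))
        pred = enc.online_confidence_signal(W, ep)
        assert np.allclose(pred, pred[0, 0])

    def test_linearity_in_sensor_scale(self):
        rng = np.random.default_rng(2)
        times = np.arange(-0.5, 0.0, 1 / 250)
        data = rng.standard_normal((6, 5, times.size))
        ep1 = enc.SensorEpochs(data=data, times=times)
        ep2 = enc.SensorEpochs(data=2 * data, times=times)
        W = enc.EncodingWeights(w=rng.standard_normal((2, 5)),
                                regressors=("confidence", "intercept"))
        p1 = enc.online_confidence_signal(W, ep1)
        p2 = enc.online_confidence_signal(W, ep2)
        assert np.allclose(p2, 2 * p1, atol=1e-9)


class TestControlStrengthSplit:
    @staticmethod
    def trials_frame(n, seed=0):
        rng = np.random.default_rng(seed)
        return pd.DataFrame({
            "subject_id": np.repeat("s0", n),
            "condition_id": np.tile(["a", "b"], n // 2),
            "correct": rng.random(n) < 0.8,
            "rt": rng.gamma(3.0, 0.3, n),
        })

    def test_identical_series_give_unit_correlation(self):
        times = np.arange(-0.3, 0.0, 1 / 250)
        series = np.random.default_rng(1).standard_normal((20, times.size))
        df, summary = enc.control_strength_split(
            series, series, self.trials_frame(20), times)
        assert np.allclose(df["coupling_r"], 1.0)

    def test_median_split_is_balanced(self):
        times = np.arange(-0.3, 0.0, 1 / 250)
        rng = np.random.default_rng(2)
        a = rng.standard_normal((40, times.size))
        b = rng.standard_normal((40, times.size))
        df, summary = enc.control_strength_split(
            a, b, self.trials_frame(40), times)
        for _, grp in df.groupby(["subject_id", "condition_id"]):
            counts = grp["split"].value_counts()
            assert abs(counts.get("stronger", 0) - counts.get("weaker", 0)) <= 1

    def test_too_few_samples_rejected(self):
        times = np.array([-0.1])
        with pytest.raises(ValueError):
            enc.control_strength_split(np.zeros((4, 1)), np.zeros((4, 1)),
                                       self.trials_frame(4), times)
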