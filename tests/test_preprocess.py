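"""Filtering, blink removal, epoching, DSS and robust averaging oracles."""

import numpy as np
import pandas as pd
import pytest
from scipy import signal

from duplescales import preprocess, synth
from duplescales.containers import EpochsSet, Recording
from duplescales.montage import CHANNELS_64, positions_2d
from duplescales.preprocess import (dss_denoise, dss_evoked_ratio,
                                    epoch_tones, filter_chain, remove_blinks,
                                    rereference_average, robust_average,
                                    zero_phase_filter)


def _recording(data, fs=1024.0, events=None):
    n_ch = data.shape[0]
    names = list(CHANNELS_64[:n_ch])
    if events is None:
        events = pd.DataFrame({"sample": [0], "onset": [0.0],
                               "role": ["plain"], "condition": ["isochronous"],
                               "half": ["first"], "trial_index": [0],
                               "scale_index": [0], "position": [0],
                               "f0_hz": [440.0], "level_db": [0.0]})
    return Recording(data=data, sample_rate_hz=fs, channel_names=names,
                     channel_positions=positions_2d(names), events=events)


class TestFilterChain:
    fs = 1024.0
    t = np.arange(int(60 * fs)) / fs

    def test_notch_kills_50hz(self):
        rec = _recording(np.sin(2 * np.pi * 50 * self.t)[None].repeat(2, 0))
        out = filter_chain(rec)
        mid = out.data[:, out.n_samples // 3:-out.n_samples // 3]
        assert np.abs(mid).max() < 0.01           # >99% attenuation

    def test_highpass_removes_dc(self):
        rec = _recording(np.full((2, len(self.t)), 10.0))
        out = filter_chain(rec)
        mid = out.data[:, out.n_samples // 3:-out.n_samples // 3]
        assert np.abs(mid).max() < 0.1

    def test_analysis_band_preserved_zero_lag(self):
        x = np.cos(2 * np.pi * 4.048 * self.t)
        rec = _recording(x[None].repeat(2, 0))
        out = filter_chain(rec)
        t300 = np.arange(out.n_samples) / 300.0
        ref = np.cos(2 * np.pi * 4.048 * t300)
        sl = slice(out.n_samples // 3, -out.n_samples // 3)
        a, b = out.data[0, sl].astype(float), ref[sl]
        # amplitude within 1%
        assert np.ptp(a) == pytest.approx(np.ptp(b), rel=0.01)
        # zero-phase: cross-correlation peaks at lag 0
        lags = signal.correlation_lags(len(a), len(b))
        xc = signal.correlate(a - a.mean(), b - b.mean())
        assert lags[np.argmax(xc)] == 0

    def test_linearity(self, rng):
        x = rng.standard_normal((2, 8192))
        y = rng.standard_normal((2, 8192))
        both = filter_chain(_recording(x + y)).data
        sep = filter_chain(_recording(x)).data + filter_chain(_recording(y)).data
        assert np.allclose(both, sep, atol=1e-4)

    def test_low_rate_rejected(self):
        rec = _recording(np.zeros((2, 1000)), fs=100.0)
        with pytest.raises(ValueError):
            filter_chain(rec)


class TestRereference:
    def test_column_means_zero_and_idempotent(self, rng):
        rec = _recording(rng.standard_normal((4, 500)) + 3.0, fs=300.0)
        out = rereference_average(rec)
        assert np.abs(out.data.mean(axis=0)).max() < 1e-10
        again = rereference_average(out)
        assert np.allclose(again.data, out.data)

    def test_single_channel_rejected(self):
        rec = _recording(np.zeros((1, 100)), fs=300.0)
        rec.channel_names = ["Fpz"]
        rec.channel_positions = rec.channel_positions[:1]
        with pytest.raises(ValueError):
            rereference_average(rec)


class TestBlinkRemoval:
    @pytest.fixture(scope="class")
    def blinky(self):
        fs = 300.0
        rng = np.random.default_rng(8)
        n = int(120 * fs)
        pos = positions_2d()
        topo = synth.topographies(pos)["blink"]
        data = rng.standard_normal((64, n)) * 2.0
        tmpl = synth.blink_template(np.arange(int(0.4 * fs)) / fs)
        onsets = np.arange(5, 115, 4.0)
        for on in onsets:
            i = int(on * fs)
            data[:, i:i + len(tmpl)] += 150.0 * topo[:, None] * tmpl[None, :]
        return _recording(data, fs=fs), onsets, fs

    def test_blink_locked_rms_reduced(self, blinky):
        rec, onsets, fs = blinky
        out = remove_blinks(rec)

        def blink_rms(r):
            segs = [r.data[:, int(o * fs):int(o * fs) + int(0.4 * fs)]
                    for o in onsets]
            return np.sqrt(np.mean(np.stack(segs) ** 2))
        assert blink_rms(out) < 0.2 * blink_rms(rec) + 2.5  # >=80% of blink power

        # cleaner check: the blink-locked average shrinks by >= 80%
        def locked(r):
            segs = [r.data[:, int(o * fs):int(o * fs) + int(0.4 * fs)]
                    for o in onsets]
            return np.sqrt(np.mean(np.mean(np.stack(segs), axis=0) ** 2))
        assert locked(out) <= 0.2 * locked(rec)

    def test_removed_subspace_rank_two(self, blinky):
        rec, _, _ = blinky
        out = remove_blinks(rec)
        resid = rec.data.astype(float) - out.data.astype(float)
        s = np.linalg.svd(resid, compute_uv=False)
        assert s[1] > 1e3 * s[2]      # exactly two dominant directions

    def test_blink_free_recording_unchanged(self):
        rng = np.random.default_rng(2024)
        rec = _recording(rng.standard_normal((64, 3000)), fs=300.0)
        with pytest.warns(UserWarning):
            out = remove_blinks(rec)
        for c in range(0, 64, 16):
            r = np.corrcoef(rec.data[c], out.data[c])[0, 1]
            assert r > 0.999


class TestEpoching:
    def test_epoch_length_and_counts(self, schedule_mid):
        params = synth.SynthEEGParams(blink_rate_hz=0.0)
        rec = synth.synth_recording(schedule_mid, params, seed=2)
        rec = preprocess.filter_chain(rec)
        ep = epoch_tones(rec)
        assert ep.data.shape[1:] == (64, 90)
        counts = ep.labels.groupby(["content", "condition"]).size()
        # 12 trials per condition -> 12 deviants per type, 24 pooled standards
        for cond in ("isochronous", "interval_based", "beat_based"):
            assert counts[("deviant_ID", cond)] == 12
            assert counts[("deviant_BD", cond)] == 12
            assert counts[("standard", cond)] == 24

    def test_constant_channel_zero_after_baseline(self):
        fs = 300.0
        data = np.full((2, 3000), 5.0)
        ev = pd.DataFrame({"sample": [1000], "onset": [1000 / fs],
                           "role": ["deviant_ID"], "condition": ["isochronous"],
                           "half": ["first"], "trial_index": [0],
                           "scale_index": [2], "position": [7],
                           "f0_hz": [700.0], "level_db": [0.0]})
        ep = epoch_tones(_recording(data, fs=fs, events=ev))
        assert np.allclose(ep.data, 0.0, atol=1e-12)

    def test_out_of_bounds_event_skipped(self, rng):
        fs = 300.0
        ev = pd.DataFrame({"sample": [5, 1000], "onset": [0.016, 3.33],
                           "role": ["deviant_ID", "deviant_BD"],
                           "condition": ["isochronous"] * 2,
                           "half": ["first"] * 2, "trial_index": [0, 0],
                           "scale_index": [2, 3], "position": [7, 6],
                           "f0_hz": [700.0, 700.0], "level_db": [0.0, 0.0]})
        with pytest.warns(UserWarning, match="skipped"):
            ep = epoch_tones(_recording(rng.standard_normal((2, 2000)),
                                        fs=fs, events=ev))
        assert ep.data.shape[0] == 1


class TestDSS:
    def _epochs(self, data, fs=300.0):
        n_ch = data.shape[1]
        labels = pd.DataFrame({"content": ["standard"] * data.shape[0]})
        return EpochsSet(data=data, times=np.arange(data.shape[2]) / fs,
                         labels=labels, sample_rate_hz=fs,
                         channel_names=list(CHANNELS_64[:n_ch]),
                         channel_positions=positions_2d(CHANNELS_64[:n_ch]))

    def test_repeated_signal_dominates_first_component(self, rng):
        n_tr, n_ch, n_t = 40, 16, 90
        sig = np.sin(2 * np.pi * 10 * np.arange(n_t) / 300.0)
        mix = rng.standard_normal(n_ch)
        data = rng.standard_normal((n_tr, n_ch, n_t))
        data += 2.0 * mix[None, :, None] * sig[None, None, :]
        ep = self._epochs(data)
        ratios = dss_evoked_ratio(ep)
        # channel-wise evoked/total ratio for comparison
        evoked = data.mean(axis=0)
        chan_ratio = (evoked ** 2).mean(axis=1) / (data ** 2).mean(axis=(0, 2))
        assert ratios[0] > chan_ratio.max()

    def test_keep_all_components_is_identity(self, rng):
        data = rng.standard_normal((20, 8, 50))
        ep = self._epochs(data)
        out = dss_denoise(ep, n_keep=8)
        assert np.allclose(out.data, data, atol=1e-6)

    def test_output_shape_preserved_and_denoises(self, rng):
        n_tr, n_ch, n_t = 30, 16, 90
        sig = np.cos(2 * np.pi * 7 * np.arange(n_t) / 300.0)
        mix = rng.standard_normal(n_ch)
        clean = mix[None, :, None] * sig[None, None, :]
        data = clean + rng.standard_normal((n_tr, n_ch, n_t))
        out = dss_denoise(self._epochs(data), n_keep=2)
        assert out.data.shape == data.shape
        err_raw = np.mean((data - clean) ** 2)
        err_dss = np.mean((out.data - clean) ** 2)
        assert err_dss < err_raw


class TestRobustAverage:
    def test_identical_trials_equal_plain_mean(self):
        x = np.tile(np.linspace(-1, 1, 60), (5, 3, 1))
        out = robust_average(x, lowpass_hz=None)
        assert np.allclose(out, x[0], atol=1e-12)

    def test_outlier_downweighted(self, rng):
        x = rng.standard_normal((100, 2, 40)) * 0.01
        x[0] += 1000.0
        plain = x.mean(axis=0)
        robust = robust_average(x, lowpass_hz=None)
        assert np.abs(robust).max() < np.abs(plain).max()
        assert np.abs(robust).max() < 1.0

    def test_clean_gaussian_matches_mean_within_2se(self, rng):
        x = rng.standard_normal((60, 2, 30))
        se = x.std(axis=0, ddof=1) / np.sqrt(60)
        robust = robust_average(x, lowpass_hz=None)
        assert np.all(np.abs(robust - x.mean(axis=0)) < 2 * se)

    def test_contaminated_average_closer_to_truth(self, rng):
        truth = np.sin(2 * np.pi * 5 * np.arange(90) / 300.0)[None, :]
        x = truth[None] + rng.standard_normal((50, 1, 90)) * 0.5
        x[:5] += 30.0 * rng.standard_normal((5, 1, 90))
        plain_err = np.mean((x.mean(axis=0) - truth) ** 2)
        robust_err = np.mean((robust_average(x, lowpass_hz=None) - truth) ** 2)
        assert robust_err < plain_err
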