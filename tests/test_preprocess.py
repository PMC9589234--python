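"""Preprocessing chain: filtering, epoching, cleaning, screening, export."""

import numpy as np
import pytest

from eegdep.montage import CHANNELS_19
from eegdep.preprocess import (
    ScreeningFailure,
    bandpass_notch_filter,
    detect_bad_channels,
    interpolate_channels,
    make_epochs,
    preprocess_recording,
    reject_amplitude,
    remove_blinks_ica,
    screen_recording,
    export_effective,
)
from eegdep.recording import Recording, read_edf
from eegdep.synth import SubjectRecord, generate_recording

from conftest import clean_config


def _sine_recording(freq, fs=500.0, dur=20.0, amp=10.0):
    t = np.arange(int(dur * fs)) / fs
    sig = amp * np.sin(2 * np.pi * freq * t)
    return Recording("sine", fs, CHANNELS_19, np.tile(sig, (19, 1)))


def _rms(x):
    return float(np.sqrt(np.mean(np.square(x))))


class TestFilter:
    @pytest.mark.parametrize(
        "freq, check",
        [
            (10.0, "pass"),   # in-band: amplitude preserved within 5%
            (50.0, "stop"),   # notch target: >= 20 dB down
            (0.1, "stop"),    # drift: >= 20 dB down
        ],
    )
    def test_band_edges(self, freq, check):
        rec = _sine_recording(freq, dur=40.0)
        out = bandpass_notch_filter(rec)
        sl = slice(int(5 * rec.fs), int(35 * rec.fs))  # trim edge transients
        ratio = _rms(out.data[0, sl]) / _rms(rec.data[0, sl])
        if check == "pass":
            assert abs(1.0 - ratio) < 0.05
        else:
            assert ratio < 0.1  # -20 dB

    def test_invalid_band_rejected(self):
        rec = _sine_recording(10.0, fs=80.0, dur=5.0)
        with pytest.raises(ValueError):
            bandpass_notch_filter(rec, low=0.5, high=50.0)


class TestEpoching:
    @pytest.mark.parametrize(
        "dur_s, expected",
        [(600.0, 300), (10.0, 5), (601.0, 300)],
    )
    def test_epoch_counts(self, dur_s, expected):
        n = int(dur_s * 500)
        rec = Recording("e", 500.0, CHANNELS_19, np.zeros((19, n)))
        ep = make_epochs(rec)
        assert ep.n_epochs == expected
        assert ep.epochs.shape[2] == 1000

    def test_short_recording_yields_zero_epochs(self):
        rec = Recording("s", 500.0, CHANNELS_19, np.zeros((19, 400)))
        assert make_epochs(rec).n_epochs == 0


class TestBadChannels:
    def test_flat_channel_flagged(self, rng):
        data = rng.normal(size=(19, 5000))
        data[4] = 0.0
        rec = Recording("b", 500.0, CHANNELS_19, data)
        assert detect_bad_channels(rec) == [CHANNELS_19[4]]

    def test_high_variance_channel_flagged(self, rng):
        data = rng.normal(size=(19, 5000))
        data[7] *= np.sqrt(20.0)  # 20x variance vs i.i.d. peers
        rec = Recording("b", 500.0, CHANNELS_19, data)
        assert CHANNELS_19[7] in detect_bad_channels(rec)

    def test_iid_channels_all_clean(self, rng):
        data = rng.normal(size=(19, 5000))
        rec = Recording("b", 500.0, CHANNELS_19, data)
        assert detect_bad_channels(rec) == []


class TestInterpolation:
    def test_no_bads_is_identity(self, rng):
        rec = Recording("i", 500.0, CHANNELS_19, rng.normal(size=(19, 1000)))
        out = interpolate_channels(rec, [])
        assert np.array_equal(out.data, rec.data)

    def test_constant_field_reproduced(self, rng):
        sig = rng.normal(size=2500)
        data = np.tile(sig, (19, 1))
        data[3] = 0.0  # F4 lost
        rec = Recording("i", 500.0, CHANNELS_19, data)
        out = interpolate_channels(rec, ["F4"])
        assert np.abs(out.data[3] - sig).max() < 1e-6

    def test_smooth_gradient_reconstruction(self, rng):
        # spatially smooth field: amplitude varies with electrode y-pos
        from eegdep.montage import make_info, to_mne_name

        info = make_info(CHANNELS_19, 500.0)
        pos = np.array([info["chs"][i]["loc"][:3] for i in range(19)])
        base = rng.normal(size=2500)
        gains = 1.0 + pos[:, 1] / np.abs(pos[:, 1]).max()
        data = np.outer(gains, base)
        true_f4 = data[3].copy()
        data[3] = 0.0
        rec = Recording("i", 500.0, CHANNELS_19, data)
        out = interpolate_channels(rec, ["F4"])
        err = _rms(out.data[3] - true_f4) / _rms(true_f4)
        assert err < 0.2

    def test_too_many_bad_channels_fails_screening(self, rng):
        rec = Recording("i", 500.0, CHANNELS_19, rng.normal(size=(19, 1000)))
        with pytest.raises(ScreeningFailure):
            interpolate_channels(rec, list(CHANNELS_19[:10]))


class TestICA:
    def test_blink_free_recording_untouched(self, clean_recording):
        filtered = bandpass_notch_filter(clean_recording)
        out, n = remove_blinks_ica(filtered, seed=3)
        assert n == 0
        for i in range(19):
            r = np.corrcoef(filtered.data[i], out.data[i])[0, 1]
            assert r > 0.95

    def test_injected_blinks_removed(self):
        cfg = clean_config(duration_s=80.0, blink_rate=12.0)
        prof = SubjectRecord("b1", "healthy", 0.1, sds=40.0, sas=45.0)
        rec = generate_recording(prof, cfg)
        base = generate_recording(prof, clean_config(duration_s=80.0))
        blink_wave = rec.data[0] - base.data[0]  # pure injected component
        filtered = bandpass_notch_filter(rec)
        out, n = remove_blinks_ica(filtered, seed=3)
        assert n >= 1
        r = np.corrcoef(out.data[0], blink_wave)[0, 1]
        assert abs(r) < 0.2

    def test_ica_deterministic(self, clean_recording):
        filtered = bandpass_notch_filter(clean_recording)
        a, _ = remove_blinks_ica(filtered, seed=5)
        b, _ = remove_blinks_ica(filtered, seed=5)
        assert np.array_equal(a.data, b.data)


class TestAmplitudeRejection:
    def _epochs_with_peaks(self, peaks):
        n = len(peaks)
        data = np.zeros((19, n * 1000))
        for i, p in enumerate(peaks):
            data[2, i * 1000 + 10] = p
        rec = Recording("r", 500.0, CHANNELS_19, data)
        return make_epochs(rec)

    def test_strict_threshold_boundary(self):
        ep = reject_amplitude(self._epochs_with_peaks([71.0, 70.0, 69.0]))
        assert ep.keep_flags.tolist() == [False, True, True]

    def test_injected_count_arithmetic(self, rng):
        peaks = np.full(300, 30.0)
        bad = rng.choice(300, size=40, replace=False)
        peaks[bad] = 120.0
        ep = reject_amplitude(self._epochs_with_peaks(list(peaks)))
        assert ep.n_kept == 260

    def test_idempotent(self, rng):
        ep = self._epochs_with_peaks(list(rng.uniform(0, 140, size=50)))
        once = reject_amplitude(ep)
        twice = reject_amplitude(once)
        assert np.array_equal(once.keep_flags, twice.keep_flags)

    def test_threshold_monotonicity(self, rng):
        ep = self._epochs_with_peaks(list(rng.uniform(0, 140, size=50)))
        kept = [
            reject_amplitude(ep, thr).n_kept for thr in (40.0, 70.0, 100.0, 150.0)
        ]
        assert kept == sorted(kept)

    def test_conservation(self, rng):
        ep = reject_amplitude(self._epochs_with_peaks(list(rng.uniform(0, 140, 50))))
        n_rejected = int((~ep.keep_flags).sum())
        assert ep.n_kept + n_rejected == ep.n_epochs


class TestScreening:
    def _epoched(self, n_total, n_kept):
        ep = make_epochs(
            Recording("s", 500.0, CHANNELS_19, np.zeros((19, n_total * 1000)))
        )
        ep.keep_flags[:] = False
        ep.keep_flags[:n_kept] = True
        return ep

    @pytest.mark.parametrize(
        "kept, included", [(150, False), (151, True), (300, True), (0, False)]
    )
    def test_strict_majority_rule(self, kept, included):
        report = screen_recording(self._epoched(300, kept))
        assert report.included is included
        assert report.n_epochs_effective == kept

    def test_empty_recording_excluded(self):
        rec = Recording("s", 500.0, CHANNELS_19, np.zeros((19, 100)))
        report = screen_recording(make_epochs(rec))
        assert not report.included and report.n_epochs_total == 0


class TestExport:
    def test_duration_follows_kept_epochs(self, tmp_path, rng):
        data = rng.normal(0, 10, size=(19, 240 * 1000))
        rec = Recording("x", 500.0, CHANNELS_19, data)
        ep = make_epochs(rec)
        ep.keep_flags[231:] = False
        report = screen_recording(ep)
        path = export_effective(rec, ep, report, tmp_path / "x.edf")
        back = read_edf(path)
        assert back.duration_s == 462.0
        assert back.channels == rec.channels
        assert back.fs == rec.fs

    def test_refuses_failed_screening(self, tmp_path):
        rec = Recording("x", 500.0, CHANNELS_19, np.zeros((19, 10 * 1000)))
        ep = make_epochs(rec)
        ep.keep_flags[:] = False
        report = screen_recording(ep)
        with pytest.raises(ScreeningFailure):
            export_effective(rec, ep, report, tmp_path / "x.edf")


class TestFullChain:
    def test_clean_cohort_fully_included_and_effect_survives(self):
        from scipy.signal import welch

        cfg = clean_config(duration_s=60.0, effect_size=1.0, seed=9)
        sick = SubjectRecord("m1", "major", 0.9, sds=85.0, sas=75.0)
        well = SubjectRecord("h1", "healthy", 0.05, sds=35.0, sas=40.0)
        ratios = {}
        for prof in (well, sick):
            rec = generate_recording(prof, cfg)
            res = preprocess_recording(rec, seed=1, run_ica=False)
            # inclusion rate on clean data is 100%; individual epochs may
            # still cross +/-70 uV through Gaussian tails
            assert res.report.included
            assert res.report.effective_fraction > 0.9
            i3 = rec.channels.index("F3")
            i4 = rec.channels.index("F4")
            f, p3 = welch(res.effective.data[i3], fs=500.0, nperseg=2048)
            _, p4 = welch(res.effective.data[i4], fs=500.0, nperseg=2048)
            band = (f >= 8) & (f <= 13)
            ratios[prof.subject_id] = np.log(p3[band].sum() / p4[band].sum())
        assert ratios["h1"] - ratios["m1"] > 0.5
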