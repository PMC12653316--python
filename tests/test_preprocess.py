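"""Contracts of the preprocessing chain."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from qeegratio import (
    InsufficientCleanDataError,
    PreprocessConfig,
    average_reference,
    bandpass,
    enforce_min_clean,
    extract_epochs,
    reject_artifacts,
)
from qeegratio.montage import ChannelMontage

from conftest import make_recording, sinusoid_recording


class TestAverageReference:
    def test_antisymmetric_pair_is_unchanged(self, montage2):
        sig = np.vstack([np.ones(100), -np.ones(100)])
        rec = average_reference(make_recording(sig, montage2))
        assert np.array_equal(rec.signal, sig)

    def test_common_mode_offset_is_removed(self, montage3):
        rng = np.random.default_rng(0)
        base = rng.normal(size=(3, 50))
        out_plain = average_reference(make_recording(base, montage3))
        out_offset = average_reference(make_recording(base + 17.3, montage3))
        np.testing.assert_allclose(out_offset.signal, out_plain.signal,
                                   atol=1e-12)

    def test_matches_direct_subtraction_and_is_idempotent(self, montage3):
        rng = np.random.default_rng(1)
        sig = rng.normal(size=(3, 8))
        rec = average_reference(make_recording(sig, montage3))
        np.testing.assert_allclose(rec.signal, sig - sig.mean(axis=0),
                                   atol=1e-12)
        assert np.abs(rec.signal.mean(axis=0)).max() < 1e-10
        twice = average_reference(rec)
        np.testing.assert_allclose(twice.signal, rec.signal, atol=1e-10)

    def test_single_channel_is_rejected(self):
        montage1 = ChannelMontage(labels=("Cz",), lobe_map={"Cz": "central"})
        rec = make_recording(np.ones((1, 10)), montage1)
        with pytest.raises(ValueError, match="at least 2 channels"):
            average_reference(rec)

    @settings(deadline=None, derandomize=True, max_examples=20)
    @given(st.integers(0, 2 ** 31 - 1), st.floats(-100, 100))
    def test_linearity_under_common_mode(self, seed, offset):
        montage = ChannelMontage(labels=("C3", "Cz", "C4"),
                                 lobe_map=dict.fromkeys(("C3", "Cz", "C4"),
                                                        "central"))
        sig = np.random.default_rng(seed).normal(size=(3, 32))
        a = average_reference(make_recording(sig, montage)).signal
        b = average_reference(make_recording(sig + offset, montage)).signal
        np.testing.assert_allclose(a, b, atol=1e-9)


class TestBandpass:
    def test_dc_is_rejected(self, montage2):
        rec = make_recording(np.full((2, 2500), 50.0), montage2)
        out = bandpass(rec, 0.5, 100.0)
        trimmed = out.signal[:, 500:-500]
        assert np.abs(trimmed).max() < 1.0

    def test_passband_tone_is_preserved(self, montage2):
        fs = 250.0
        t = np.arange(int(10 * fs)) / fs
        sig = np.tile(np.sin(2 * np.pi * 10.0 * t), (2, 1))
        out = bandpass(make_recording(sig, montage2, fs=fs), 0.5, 100.0)
        mid = slice(500, -500)
        ratio = out.signal[0, mid].std() / sig[0, mid].std()
        assert abs(ratio - 1.0) < 0.05

    def test_stopband_attenuation_at_contract_frequencies(self, montage2):
        # >= 20 dB at low/4 and at (high + Nyquist)/2.
        fs = 500.0
        t = np.arange(int(80 * fs)) / fs
        for f_test in (0.125, 175.0):
            sig = np.tile(np.sin(2 * np.pi * f_test * t), (2, 1))
            out = bandpass(make_recording(sig, montage2, fs=fs), 0.5, 100.0)
            mid = slice(int(10 * fs), -int(10 * fs))
            ratio = out.signal[0, mid].std() / sig[0, mid].std()
            assert ratio < 10 ** (-20 / 20), f_test

    def test_corner_above_nyquist_is_an_error(self, montage2):
        rec = make_recording(np.zeros((2, 1000)), montage2)
        with pytest.raises(ValueError, match="Nyquist"):
            bandpass(rec, 0.5, 125.0)


class TestExtractEpochs:
    def test_thirty_second_trial_gives_seven_epochs(self):
        rec = sinusoid_recording([(10.0, 5.0)], duration=30.0)
        es = extract_epochs(rec, 4.0)
        assert es.n_epochs == 7
        assert es.epochs.shape[2] == 1000
        assert es.retained.all()

    def test_concatenated_recording_without_trial_marks(self):
        rec = sinusoid_recording([(10.0, 5.0)], duration=300.0)
        assert extract_epochs(rec, 4.0).n_epochs == 75

    def test_trial_boundaries_are_respected(self):
        rec = sinusoid_recording([(10.0, 5.0)], duration=300.0,
                                 trial_length=30.0)
        es = extract_epochs(rec, 4.0)
        assert es.n_epochs == 70          # 7 per 30 s trial, 2 s dropped each
        spt = int(30.0 * 250.0)
        assert all((s % spt) + 1000 <= spt for s in es.starts)

    def test_round_trip_reproduces_original_samples(self):
        rng = np.random.default_rng(3)
        rec = make_recording(rng.normal(size=(19, 7500)), trial_length=10.0)
        es = extract_epochs(rec, 4.0)
        for k, start in enumerate(es.starts):
            np.testing.assert_array_equal(
                es.epochs[k], rec.signal[:, start:start + 1000])

    def test_too_short_recording_is_an_error(self):
        rec = sinusoid_recording([(10.0, 5.0)], duration=2.0)
        with pytest.raises(ValueError, match="shorter than one"):
            extract_epochs(rec, 4.0)


class TestRejection:
    def _epochs(self, signal):
        return extract_epochs(make_recording(signal), 4.0)

    def test_clean_epochs_are_retained(self):
        rec = sinusoid_recording([(10.0, 30.0)], duration=20.0)
        es = reject_artifacts(extract_epochs(rec, 4.0), PreprocessConfig())
        assert es.retained.all()

    def test_blink_sized_deflection_is_rejected(self):
        rec = sinusoid_recording([(10.0, 30.0)], duration=20.0)
        sig = rec.signal.copy()
        sig[0, 1200] += 400.0             # inside epoch 1
        es = reject_artifacts(self._epochs(sig), PreprocessConfig())
        assert not es.retained[1]
        assert es.retained[[0, 2, 3, 4]].all()

    def test_matches_brute_force_ptp_scan(self):
        rng = np.random.default_rng(7)
        sig = rng.normal(scale=30.0, size=(19, 10000))
        cfg = PreprocessConfig(reject_ptp_threshold=150.0)
        es = reject_artifacts(self._epochs(sig), cfg)
        expected = []
        for k in range(es.n_epochs):
            worst = max(es.epochs[k, c].max() - es.epochs[k, c].min()
                        for c in range(19))
            expected.append(worst <= cfg.reject_ptp_threshold)
        assert list(es.retained) == expected

    def test_invariant_to_channel_ordering(self):
        rng = np.random.default_rng(8)
        sig = rng.normal(scale=40.0, size=(19, 5000))
        cfg = PreprocessConfig(reject_ptp_threshold=150.0)
        es = reject_artifacts(self._epochs(sig), cfg)
        perm = rng.permutation(19)
        es_perm = reject_artifacts(self._epochs(sig[perm]), cfg)
        assert np.array_equal(es.retained, es_perm.retained)

    def test_flags_only_move_towards_rejection(self):
        rec = sinusoid_recording([(10.0, 30.0)], duration=20.0)
        es = extract_epochs(rec, 4.0)
        es.retained[2] = False            # e.g. a previous pass
        out = reject_artifacts(es, PreprocessConfig())
        assert not out.retained[2]


class TestMinClean:
    def _with_retained(self, n_retained, n_total=75):
        rec = sinusoid_recording([(10.0, 5.0)], duration=300.0)
        es = extract_epochs(rec, 4.0)
        es.retained[:] = False
        es.retained[:n_retained] = True
        return es

    def test_forty_five_epochs_pass(self):
        es = self._with_retained(45)
        assert enforce_min_clean(es, PreprocessConfig()) is es
        assert es.retained_seconds == 180.0

    def test_fourteen_epochs_exclude_the_subject(self):
        with pytest.raises(InsufficientCleanDataError) as err:
            enforce_min_clean(self._with_retained(14), PreprocessConfig())
        assert err.value.retained_seconds == 56.0

    def test_exactly_sixty_seconds_is_inclusive(self):
        es = self._with_retained(15)
        assert enforce_min_clean(es, PreprocessConfig()) is es
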