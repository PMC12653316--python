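"""Shared fixtures: small montages and deterministic waveform builders."""

from __future__ import annotations

import numpy as np
import pytest

from qeegratio import ChannelMontage, DEFAULT_MONTAGE, EEGRecording


@pytest.fixture
def montage2() -> ChannelMontage:
    return ChannelMontage(labels=("C3", "C4"),
                          lobe_map={"C3": "central", "C4": "central"})


@pytest.fixture
def montage3() -> ChannelMontage:
    return ChannelMontage(labels=("C3", "Cz", "C4"),
                          lobe_map={"C3": "central", "Cz": "central",
                                    "C4": "central"})


def make_recording(signal: np.ndarray, montage=None, fs: float = 250.0,
                   subject_id: str = "S0001", condition: str = "EO",
                   trial_length: float | None = None) -> EEGRecording:
    if montage is None:
        montage = DEFAULT_MONTAGE
    return EEGRecording(subject_id=subject_id, condition=condition,
                        sampling_rate=fs, signal=signal, montage=montage,
                        trial_length=trial_length)


def sinusoid_recording(freq_amp_phase, duration: float = 60.0,
                       fs: float = 250.0, montage=None,
                       phase_spread: bool = True, **kwargs) -> EEGRecording:
    """19-channel recording of summed sinusoids.

    ``freq_amp_phase`` is a list of (freq_hz, amplitude_uv) pairs.  With
    ``phase_spread`` the phase of each component is advanced by
    2*pi*k/n_channels on channel k, which makes the cross-channel mean
    vanish identically, so the recording is average-reference neutral.
    """
    if montage is None:
        montage = DEFAULT_MONTAGE
    n_ch = montage.n_channels
    t = np.arange(int(round(duration * fs))) / fs
    signal = np.zeros((n_ch, t.size))
    for ci in range(n_ch):
        for f, a in freq_amp_phase:
            phase = 2 * np.pi * ci / n_ch if phase_spread else 0.0
            signal[ci] += a * np.sin(2 * np.pi * f * t + phase)
    return make_recording(signal, montage=montage, fs=fs, **kwargs)
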