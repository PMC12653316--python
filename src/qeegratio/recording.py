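"""Continuous multichannel EEG container."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Any

import numpy as np

from .montage import ChannelMontage, DEFAULT_MONTAGE

CONDITIONS = ("EO", "EC")


@dataclass
class ArtifactEvent:
    """Ground-truth record of an injected artifact (synthetic data only).

    ``t_peak`` is in seconds from the start of the recording; ``weights``
    is the per-channel scalp weighting applied to the waveform.
    """

    kind: str                 # "blink" or "emg"
    t_peak: float
    width: float              # blink: Gaussian scale s; emg: burst duration
    amplitude: float          # blink: peak uV; emg: RMS uV
    weights: np.ndarray


@dataclass
class EEGRecording:
    """One subject x condition continuous signal in microvolts.

    ``signal`` is channels x samples, ordered as ``montage.labels``.
    ``trial_length`` (seconds), when set, marks the recording as a
    concatenation of equal-length trials; epoching then never spans a
    trial boundary.
    """

    subject_id: str
    condition: str
    sampling_rate: float
    signal: np.ndarray
    montage: ChannelMontage = DEFAULT_MONTAGE
    trial_length: float | None = None
    artifacts: list[ArtifactEvent] = field(default_factory=list)

    def __post_init__(self):
        self.signal = np.asarray(self.signal, dtype=np.float64)
        if self.signal.ndim != 2:
            raise ValueError("signal must be a channels x samples matrix")
        if self.signal.shape[0] != self.montage.n_channels:
            raise ValueError(
                f"signal has {self.signal.shape[0]} channels but montage "
                f"has {self.montage.n_channels}"
            )
        if not np.isfinite(self.signal).all():
            raise ValueError("signal contains non-finite samples")
        if self.condition not in CONDITIONS:
            raise ValueError(
                f"unknown condition {self.condition!r}; expected one of {CONDITIONS}"
            )

    @property
    def n_samples(self) -> int:
        return self.signal.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.sampling_rate

    def replace(self, **changes: Any) -> "EEGRecording":
        return dataclasses.replace(self, **changes)
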