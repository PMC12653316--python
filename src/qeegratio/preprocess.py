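"""Pre-processing: re-referencing, bandpass filtering, epoching, rejection.

The chain is order-fixed and fully deterministic:

    average_reference -> bandpass -> extract_epochs -> reject_artifacts
        -> enforce_min_clean

Artifact handling is a deterministic peak-to-peak threshold (default
100 uV) applied per epoch and channel.  An ICA-based cleaner can be
substituted through the ``rejector`` hook of :func:`reject_artifacts`;
the default rule is seed-free and reproducible, which manual component
selection is not.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Callable

import numpy as np
from scipy import signal as sps

from .errors import ConfigurationError, InsufficientCleanDataError
from .recording import EEGRecording


@dataclass(frozen=True)
class PreprocessConfig:
    """Constants of the pre-processing stage.

    band_low/band_high      bandpass corner frequencies, Hz
    epoch_length            epoch duration, seconds
    reject_ptp_threshold    per-channel peak-to-peak rejection bound, uV
    min_clean_seconds       minimum retained clean data per condition, s
    filter_order            Butterworth order (applied forward-backward)
    """

    band_low: float = 0.5
    band_high: float = 100.0
    epoch_length: float = 4.0
    reject_ptp_threshold: float = 100.0
    min_clean_seconds: float = 60.0
    filter_order: int = 4

    def validate(self, sampling_rate: float) -> None:
        if not 0 < self.band_low < self.band_high:
            raise ConfigurationError("band_low", "need 0 < band_low < band_high")
        if self.band_high >= sampling_rate / 2:
            raise ConfigurationError(
                "band_high", f"must be below Nyquist ({sampling_rate / 2:g} Hz)"
            )
        if self.epoch_length <= 0:
            raise ConfigurationError("epoch_length", "must be positive")
        if self.min_clean_seconds < self.epoch_length:
            raise ConfigurationError(
                "min_clean_seconds", "must be at least one epoch long"
            )
        if self.reject_ptp_threshold <= 0:
            raise ConfigurationError("reject_ptp_threshold", "must be positive")


@dataclass
class EpochSet:
    """Fixed-length epochs cut from one recording.

    ``epochs`` is epoch x channel x sample (uV); ``retained`` flags which
    epochs are still considered clean; ``starts`` holds the sample index
    of each epoch in the source recording.
    """

    epochs: np.ndarray
    epoch_length: float
    sampling_rate: float
    retained: np.ndarray
    starts: np.ndarray
    channel_names: tuple[str, ...]
    subject_id: str
    condition: str

    def __post_init__(self):
        self.retained = np.asarray(self.retained, dtype=bool)
        expected = int(round(self.epoch_length * self.sampling_rate))
        if self.epochs.shape[2] != expected:
            raise ValueError(
                f"epoch sample count {self.epochs.shape[2]} != "
                f"epoch_length*sampling_rate = {expected}"
            )

    @property
    def n_epochs(self) -> int:
        return self.epochs.shape[0]

    @property
    def n_retained(self) -> int:
        return int(self.retained.sum())

    @property
    def retained_seconds(self) -> float:
        return self.n_retained * self.epoch_length

    def retained_epochs(self) -> np.ndarray:
        return self.epochs[self.retained]

    def replace(self, **changes) -> "EpochSet":
        return dataclasses.replace(self, **changes)


def average_reference(rec: EEGRecording) -> EEGRecording:
    """Re-reference every channel to the instantaneous mean of all channels.

    Idempotent and linear; removes any common-mode component.  Undefined
    (and rejected) for single-channel input.
    """
    if rec.signal.shape[0] < 2:
        raise ValueError("average reference requires at least 2 channels")
    return rec.replace(signal=rec.signal - rec.signal.mean(axis=0, keepdims=True))


def bandpass(rec: EEGRecording, low: float = 0.5, high: float = 100.0,
             order: int = 4) -> EEGRecording:
    """Zero-phase Butterworth bandpass (applied forward-backward).

    Edge transients are handled by even (reflective) padding of at least
    three time constants of the low corner.
    """
    nyquist = rec.sampling_rate / 2
    if not 0 < low < high:
        raise ValueError(f"need 0 < low < high, got ({low}, {high})")
    if high >= nyquist:
        raise ValueError(f"high corner {high} Hz must be below Nyquist {nyquist} Hz")
    sos = sps.butter(order, [low, high], btype="bandpass",
                     fs=rec.sampling_rate, output="sos")
    n = rec.n_samples
    padlen = int(round(3.0 * rec.sampling_rate / (2.0 * np.pi * low)))
    padlen = min(n - 1, max(padlen, 3 * (2 * sos.shape[0] + 1)))
    filtered = sps.sosfiltfilt(sos, rec.signal, axis=-1,
                               padtype="even", padlen=padlen)
    return rec.replace(signal=filtered)


def extract_epochs(rec: EEGRecording, epoch_length: float = 4.0) -> EpochSet:
    """Cut consecutive non-overlapping epochs; trailing partials are dropped.

    When the recording carries a ``trial_length``, epochs are cut within
    trials so that no epoch spans a trial boundary.
    """
    fs = rec.sampling_rate
    spe = int(round(epoch_length * fs))
    if rec.n_samples < spe:
        raise ValueError(
            f"recording of {rec.duration:g} s shorter than one "
            f"{epoch_length:g} s epoch"
        )
    starts: list[int] = []
    if rec.trial_length is not None:
        spt = int(round(rec.trial_length * fs))
        n_trials = rec.n_samples // spt
        for t in range(n_trials):
            base = t * spt
            starts.extend(base + k * spe for k in range(spt // spe))
    else:
        starts.extend(k * spe for k in range(rec.n_samples // spe))
    starts_arr = np.asarray(starts, dtype=np.intp)
    epochs = np.stack([rec.signal[:, s:s + spe] for s in starts_arr], axis=0)
    return EpochSet(
        epochs=epochs,
        epoch_length=epoch_length,
        sampling_rate=fs,
        retained=np.ones(len(starts_arr), dtype=bool),
        starts=starts_arr,
        channel_names=rec.montage.labels,
        subject_id=rec.subject_id,
        condition=rec.condition,
    )


def reject_artifacts(
    es: EpochSet,
    cfg: PreprocessConfig,
    rejector: Callable[[np.ndarray, PreprocessConfig], np.ndarray] | None = None,
) -> EpochSet:
    """Flag epochs whose peak-to-peak amplitude exceeds the threshold.

    An epoch is rejected iff any channel's max-minus-min within the epoch
    exceeds ``cfg.reject_ptp_threshold``.  Flags only ever move from
    retained to rejected.  A custom ``rejector(epochs, cfg) -> bad_mask``
    may be plugged in (e.g. an ICA-based cleaner).
    """
    if rejector is None:
        ptp = es.epochs.max(axis=2) - es.epochs.min(axis=2)   # epoch x channel
        bad = (ptp > cfg.reject_ptp_threshold).any(axis=1)
    else:
        bad = np.asarray(rejector(es.epochs, cfg), dtype=bool)
        if bad.shape != (es.n_epochs,):
            raise ValueError("rejector must return one flag per epoch")
    return es.replace(retained=es.retained & ~bad)


def enforce_min_clean(es: EpochSet, cfg: PreprocessConfig) -> EpochSet:
    """Check the minimum-clean-data rule (boundary inclusive).

    Returns the EpochSet unchanged when the retained duration reaches
    ``cfg.min_clean_seconds``; otherwise raises
    :class:`InsufficientCleanDataError`, which the pipeline consumes as a
    per-subject x condition exclusion.
    """
    if es.retained_seconds >= cfg.min_clean_seconds - 1e-9:
        return es
    raise InsufficientCleanDataError(
        es.subject_id, es.condition, es.retained_seconds, cfg.min_clean_seconds
    )


def preprocess_recording(rec: EEGRecording, cfg: PreprocessConfig) -> EpochSet:
    """Run the fixed chain: reference -> filter -> epoch -> reject -> min-clean."""
    cfg.validate(rec.sampling_rate)
    rec = average_reference(rec)
    rec = bandpass(rec, cfg.band_low, cfg.band_high, cfg.filter_order)
    es = extract_epochs(rec, cfg.epoch_length)
    es = reject_artifacts(es, cfg)
    return enforce_min_clean(es, cfg)
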