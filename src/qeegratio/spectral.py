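"""Welch spectral estimation and relative band power.

The PSD of each retained epoch is estimated with Welch's method (2 s
Hamming windows, 50% overlap, one-sided density scaling) and averaged
over retained epochs.  Relative band power divides the summed density of
the bins whose *center* frequency falls in [f_low, f_high) by the same
sum over the 0.5-100 Hz normalization range (endpoints included).  The
half-open band rule assigns shared edges to the upper band (8 Hz counts
as alpha, not theta) and prevents double counting.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal as sps

from .preprocess import EpochSet

_TOL = 1e-9

DEFAULT_BANDS = (
    ("delta", 0.5, 4.0),
    ("theta", 4.0, 8.0),
    ("alpha", 8.0, 13.0),
    ("beta", 13.0, 30.0),
)

NORMALIZATION_RANGE = (0.5, 100.0)


@dataclass(frozen=True)
class BandDefinition:
    """A named frequency band [f_low, f_high) in Hz."""

    name: str
    f_low: float
    f_high: float

    def __post_init__(self):
        if not self.f_low < self.f_high:
            raise ValueError(f"band {self.name}: need f_low < f_high")


def default_bands() -> tuple[BandDefinition, ...]:
    return tuple(BandDefinition(n, lo, hi) for n, lo, hi in DEFAULT_BANDS)


@dataclass
class PSDEstimate:
    """One-sided Welch PSD, averaged over retained epochs.

    ``power`` is channel x frequency in uV^2/Hz; frequency resolution is
    1/window_length.
    """

    frequencies: np.ndarray
    power: np.ndarray
    window_length: float
    overlap_fraction: float
    n_epochs_averaged: int
    channel_names: tuple[str, ...]

    @property
    def df(self) -> float:
        return float(self.frequencies[1] - self.frequencies[0])

    def total_power(self, f_low: float = 0.0, f_high: float = np.inf) -> np.ndarray:
        """Integrated power per channel over [f_low, f_high] (bin centers)."""
        mask = (self.frequencies >= f_low - _TOL) & (self.frequencies <= f_high + _TOL)
        return self.power[:, mask].sum(axis=1) * self.df


@dataclass
class RelativeBandPowerTable:
    """Per channel x band relative power (unitless fractions in [0, 1])."""

    values: pd.DataFrame          # index: channels, columns: band names
    normalization_range: tuple[float, float]

    def band(self, name: str) -> pd.Series:
        return self.values[name]


def welch_psd(es: EpochSet, window_length: float = 2.0, overlap: float = 0.5,
              window: str = "hamming") -> PSDEstimate:
    """Average per-epoch Welch estimates over retained epochs only."""
    if es.n_retained < 1:
        raise ValueError("no retained epochs to estimate a PSD from")
    fs = es.sampling_rate
    nperseg = int(round(window_length * fs))
    if nperseg > es.epochs.shape[2]:
        raise ValueError(
            f"window_length {window_length:g} s exceeds epoch length "
            f"{es.epoch_length:g} s"
        )
    noverlap = int(round(nperseg * overlap))
    freqs, pxx = sps.welch(
        es.retained_epochs(), fs=fs, window=window, nperseg=nperseg,
        noverlap=noverlap, detrend="constant", scaling="density", axis=-1,
    )
    return PSDEstimate(
        frequencies=freqs,
        power=pxx.mean(axis=0),
        window_length=window_length,
        overlap_fraction=overlap,
        n_epochs_averaged=es.n_retained,
        channel_names=es.channel_names,
    )


def band_mask(frequencies: np.ndarray, f_low: float, f_high: float) -> np.ndarray:
    """Bins whose center frequency lies in [f_low, f_high)."""
    return (frequencies >= f_low - _TOL) & (frequencies < f_high - _TOL)


def relative_band_power(
    psd: PSDEstimate,
    bands: tuple[BandDefinition, ...] | None = None,
    normalization_range: tuple[float, float] = NORMALIZATION_RANGE,
) -> RelativeBandPowerTable:
    """Band power as a fraction of total power over the normalization range.

    The normalization sum runs over bins in [lo, hi] inclusive of both
    endpoints; the density-vs-power scaling convention cancels in the
    fraction.
    """
    if bands is None:
        bands = default_bands()
    lo, hi = normalization_range
    f = psd.frequencies
    if lo < f[0] - _TOL or hi > f[-1] + _TOL:
        raise ValueError(
            f"normalization range [{lo}, {hi}] Hz outside the frequency "
            f"grid [{f[0]:g}, {f[-1]:g}] Hz"
        )
    norm_bins = (f >= lo - _TOL) & (f <= hi + _TOL)
    total = psd.power[:, norm_bins].sum(axis=1)
    if np.any(total <= 0):
        dead = [psd.channel_names[i] for i in np.flatnonzero(total <= 0)]
        raise ValueError(f"zero total power in normalization range: {dead}")
    data = {}
    for band in bands:
        mask = band_mask(f, band.f_low, band.f_high)
        data[band.name] = psd.power[:, mask].sum(axis=1) / total
    values = pd.DataFrame(data, index=list(psd.channel_names))
    return RelativeBandPowerTable(values=values, normalization_range=(lo, hi))
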