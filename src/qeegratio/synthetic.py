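"""Synthetic resting-state EEG cohort with a planted OAb -> log-TBR coupling.

The study data this package analyzes are private, so every downstream
stage is exercised against a generator whose ground truth is known.

Signal model (per channel, microvolts):

    x(t) = pink background (1/f over 0.5-100 Hz)
         + band-limited stochastic oscillators (delta, theta, alpha, beta)
         + optional artifact transients (blinks, EMG bursts)

Oscillators are filtered white noise, normalized to an exact per-trial
variance, so expected band powers are controllable in closed form.  The
coupling between plasma oligomeric amyloid-beta (OAb, ng/mL) and the
lobar theta-beta ratio is imposed directly on the *expected* log10 TBR:

    log10 TBR(lobe, cond) = level(lobe) + slope(lobe, cond) * (oab - E[oab])
                            + N(0, ratio_noise_sd)

Theta and beta band-power targets are then placed symmetrically around a
fixed geometric mean, alpha follows from the TAR level (larger with eyes
closed -- alpha reactivity), and per-channel variances are
pre-compensated for the average reference so the planted ratios survive
re-referencing exactly (to first order).
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .montage import LOBES, ChannelMontage, DEFAULT_MONTAGE
from .recording import CONDITIONS, ArtifactEvent, EEGRecording

# Analysis bands used for power targeting (matching the spectral module).
_ANALYSIS_BANDS = {"delta": (0.5, 4.0), "theta": (4.0, 8.0),
                   "alpha": (8.0, 13.0), "beta": (13.0, 30.0)}

# Oscillators occupy the band interior so Hamming-window leakage across
# band edges stays negligible.
_DEFAULT_OSC_BANDS = {"delta": (1.0, 3.75), "theta": (4.25, 7.75),
                      "alpha": (8.5, 12.5), "beta": (13.5, 29.5)}

_BACKGROUND_RANGE = (0.5, 100.0)

# Blink scalp topography: frontal-polar dominant with smooth falloff.
_BLINK_WEIGHTS = {"Fp1": 1.0, "Fp2": 1.0, "F3": 0.35, "F4": 0.35,
                  "F7": 0.35, "F8": 0.35, "Fz": 0.35,
                  "C3": 0.15, "C4": 0.15, "Cz": 0.15}
_BLINK_OTHER = 0.05

_EDUCATION_LEVELS = (
    ("below_elementary", 0.24, 0, 6),
    ("middle_school", 0.27, 7, 9),
    ("high_school", 0.16, 10, 12),
    ("college", 0.33, 13, 18),
)


def _default_tbr_levels() -> dict[str, float]:
    # Cohort-mean log10 TBR per lobe (elderly resting-state scale).
    return {"frontal": 0.77, "central": 0.55, "parietal": 0.59,
            "occipital": 0.70, "temporal": 0.74}


def _default_tar_levels() -> dict[str, float]:
    # Cohort-mean log10 TAR per lobe, eyes-open.
    return {"frontal": 0.21, "central": 0.04, "parietal": 0.01,
            "occipital": -0.15, "temporal": 0.04}


def _default_slopes() -> dict[tuple[str, str], float]:
    """Planted log10-TBR slopes per (lobe, condition), log-ratio per ng/mL.

    Defaults reflect the weak negative coupling regime the pipeline is
    meant to detect; set all to 0.0 for a null cohort.
    """
    return {
        ("frontal", "EO"): -0.04, ("central", "EO"): -0.05,
        ("parietal", "EO"): -0.05, ("occipital", "EO"): -0.05,
        ("temporal", "EO"): -0.05,
        ("frontal", "EC"): -0.03, ("central", "EC"): -0.06,
        ("parietal", "EC"): -0.07, ("occipital", "EC"): -0.07,
        ("temporal", "EC"): -0.05,
    }


@dataclass
class SubjectRecord:
    subject_id: str
    age: float
    sex: str                  # "female" | "male"
    education_years: int
    kmmse: int                # 0-30
    oab: float                # ng/mL, > 0
    amyloid_group: str        # "high" iff oab >= cutoff


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic cohort.

    Defaults emulate the acquisition protocol (19 channels at 250 Hz,
    ten 30 s trials per condition) and a cohort whose plasma OAb
    distribution straddles the 0.78 ng/mL clinical cutoff.
    """

    n_subjects: int = 174
    seed: int = 0
    sampling_rate: float = 250.0
    n_trials_per_condition: int = 10
    trial_length: float = 30.0

    # Plasma OAb: lognormal with median at the clinical cutoff.
    oab_log_mean: float = math.log(0.78)
    oab_log_sd: float = 0.55
    cutoff: float = 0.78

    # Coupling and ratio dispersion (log10-ratio units).
    planted_slopes: dict[tuple[str, str], float] = field(
        default_factory=_default_slopes)
    ratio_noise_sd: float = 0.33
    tar_noise_sd: float = 0.25
    tbr_levels: dict[str, float] = field(default_factory=_default_tbr_levels)
    tar_levels_eo: dict[str, float] = field(default_factory=_default_tar_levels)
    alpha_reactivity: float = 0.2   # log10 TAR drop from EO to EC

    # Spectral scale (uV^2 per channel).
    theta_beta_geomean_power: float = 2.5
    delta_power: float = 3.0
    background_power: float = 1.5
    osc_bands: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(_DEFAULT_OSC_BANDS))

    # Artifact transients.
    blink_per_minute: float = 3.0
    emg_burst_per_minute: float = 2.0
    blink_amplitude: float = 400.0   # peak uV, caught by the 100 uV rule
    blink_width: float = 0.12        # Gaussian scale, s
    emg_rms: float = 45.0            # uV
    emg_duration: float = 0.5        # s

    # Covariate model (independent of OAb unless couplings are set).
    age_mean: float = 74.87
    age_sd: float = 8.52
    female_fraction: float = 0.707
    kmmse_mean: float = 23.4
    kmmse_sd: float = 4.85
    age_coupling: float = 0.0        # log-oab shift per year above age_mean
    kmmse_coupling: float = 0.0      # log-oab shift per K-MMSE point above mean

    montage: ChannelMontage = field(default_factory=lambda: DEFAULT_MONTAGE)

    def validate(self) -> None:
        if self.n_subjects < 2:
            raise ConfigurationError("n_subjects", "must be at least 2")
        if self.sampling_rate <= 2 * 100.0:
            raise ConfigurationError(
                "sampling_rate",
                "must exceed 200 Hz so Nyquist covers the 0.5-100 Hz range",
            )
        if self.trial_length * self.n_trials_per_condition < 60.0:
            raise ConfigurationError(
                "n_trials_per_condition",
                "trial_length * n_trials must give at least 60 s per condition",
            )
        if self.oab_log_sd <= 0:
            raise ConfigurationError("oab_log_sd", "must be positive")
        if self.cutoff <= 0:
            raise ConfigurationError("cutoff", "must be positive")
        if self.ratio_noise_sd < 0 or self.tar_noise_sd < 0:
            raise ConfigurationError("ratio_noise_sd", "must be non-negative")
        if self.theta_beta_geomean_power <= 0 or self.background_power < 0:
            raise ConfigurationError(
                "theta_beta_geomean_power", "power scales must be positive")
        if self.blink_per_minute < 0 or self.emg_burst_per_minute < 0:
            raise ConfigurationError("blink_per_minute", "rates must be >= 0")
        for key in self.planted_slopes:
            lobe, cond = key
            if lobe not in LOBES or cond not in CONDITIONS:
                raise ConfigurationError(
                    "planted_slopes", f"unknown lobe x condition key {key!r}")

    @property
    def oab_mean(self) -> float:
        """Analytic mean of the lognormal OAb distribution."""
        return math.exp(self.oab_log_mean + self.oab_log_sd ** 2 / 2)

    def high_fraction(self) -> float:
        """Analytic P(oab >= cutoff) under the lognormal model."""
        from scipy.stats import norm
        z = (math.log(self.cutoff) - self.oab_log_mean) / self.oab_log_sd
        return float(norm.sf(z))


def _stream(*keys: int | str) -> np.random.Generator:
    """Deterministic child RNG from a tuple of integer/string keys.

    Strings are hashed with CRC-32 so per-subject streams are stable and
    cohorts extend without reshuffling existing subjects.
    """
    ints = [zlib.crc32(k.encode()) if isinstance(k, str) else int(k) & 0x7FFFFFFF
            for k in keys]
    return np.random.default_rng(np.random.SeedSequence(ints))


def simulate_metadata(config: SimulationConfig) -> list[SubjectRecord]:
    """Draw the subject table: demographics, cognition, and plasma OAb.

    Covariates are independent of OAb unless ``age_coupling`` or
    ``kmmse_coupling`` are non-zero.  Deterministic given the seed, and
    prefix-stable: growing ``n_subjects`` leaves earlier records intact.
    """
    config.validate()
    rng = _stream(config.seed, "metadata")
    probs = np.array([p for _, p, _, _ in _EDUCATION_LEVELS])
    records = []
    for i in range(config.n_subjects):
        sid = f"S{i + 1:04d}"
        age = float(np.clip(rng.normal(config.age_mean, config.age_sd), 55.0, 95.0))
        sex = "female" if rng.random() < config.female_fraction else "male"
        level = rng.choice(len(_EDUCATION_LEVELS), p=probs)
        _, _, lo, hi = _EDUCATION_LEVELS[level]
        education = int(rng.integers(lo, hi + 1))
        kmmse = int(np.clip(round(rng.normal(config.kmmse_mean, config.kmmse_sd)),
                            0, 30))
        log_oab = rng.normal(config.oab_log_mean, config.oab_log_sd)
        log_oab += config.age_coupling * (age - config.age_mean)
        log_oab += config.kmmse_coupling * (kmmse - config.kmmse_mean)
        oab = float(math.exp(log_oab))
        records.append(SubjectRecord(
            subject_id=sid, age=age, sex=sex, education_years=education,
            kmmse=kmmse, oab=oab,
            amyloid_group="high" if oab >= config.cutoff else "low",
        ))
    return records


def metadata_frame(records: Iterable[SubjectRecord]) -> pd.DataFrame:
    return pd.DataFrame([{
        "subject_id": r.subject_id, "age": r.age, "sex": r.sex,
        "education_years": r.education_years, "kmmse": r.kmmse,
        "oab_ng_ml": r.oab, "amyloid_group": r.amyloid_group,
    } for r in records])


def subject_targets(subject: SubjectRecord, config: SimulationConfig) -> dict:
    """Per-condition planted log-ratio targets and band-power targets.

    Returns ``{cond: {"logs": {lobe: (log_tbr, log_tar)},
    "powers": {lobe: {band: uV^2}}}}``.  Both conditions are derived from
    one condition-independent stream so alpha reactivity (EC alpha power
    strictly above EO) can be enforced consistently.
    """
    rng = _stream(config.seed, subject.subject_id, "targets")
    eps_tbr = rng.normal(0.0, config.ratio_noise_sd, size=(2, len(LOBES)))
    eps_tar = rng.normal(0.0, config.tar_noise_sd, size=(2, len(LOBES)))
    c = config.theta_beta_geomean_power
    out: dict[str, dict] = {}
    for ci, cond in enumerate(CONDITIONS):
        logs: dict[str, tuple[float, float]] = {}
        powers: dict[str, dict[str, float]] = {}
        for li, lobe in enumerate(LOBES):
            slope = config.planted_slopes.get((lobe, cond), 0.0)
            log_tbr = (config.tbr_levels[lobe]
                       + slope * (subject.oab - config.oab_mean)
                       + eps_tbr[ci, li])
            log_tar = config.tar_levels_eo[lobe] + eps_tar[ci, li]
            if cond == "EC":
                log_tar -= config.alpha_reactivity
            p_theta = c * 10.0 ** (log_tbr / 2)
            p_beta = c * 10.0 ** (-log_tbr / 2)
            p_alpha = p_theta / 10.0 ** log_tar
            logs[lobe] = (log_tbr, log_tar)
            powers[lobe] = {"delta": config.delta_power, "theta": p_theta,
                            "alpha": p_alpha, "beta": p_beta}
        out[cond] = {"logs": logs, "powers": powers}
    # Alpha reactivity: eyes-closed alpha strictly above eyes-open.
    for lobe in LOBES:
        p_eo = out["EO"]["powers"][lobe]["alpha"]
        p_ec = out["EC"]["powers"][lobe]["alpha"]
        if p_ec <= p_eo * 1.05:
            p_ec = p_eo * 1.15
            out["EC"]["powers"][lobe]["alpha"] = p_ec
            log_tbr, _ = out["EC"]["logs"][lobe]
            p_theta = out["EC"]["powers"][lobe]["theta"]
            out["EC"]["logs"][lobe] = (log_tbr, math.log10(p_theta / p_ec))
    return out


def _background_band_power(config: SimulationConfig, band: str) -> float:
    """Pink-background power falling inside an analysis band (1/f shares)."""
    lo, hi = _ANALYSIS_BANDS[band]
    b_lo, b_hi = _BACKGROUND_RANGE
    return config.background_power * math.log(hi / lo) / math.log(b_hi / b_lo)


def _invert_reference_powers(target: np.ndarray) -> np.ndarray:
    """Pre-compensate per-channel band powers for the average reference.

    For independent channels, re-referencing maps per-channel variances
    p to p' = (1 - 2/N) p + S/N^2 with S = sum(p).  Inverting this gives
    signals whose planted band powers hold *after* re-referencing.
    """
    n = target.size
    s_post = target.sum()
    s_pre = s_post / (1.0 - 1.0 / n)
    pre = (target - s_pre / n ** 2) / (1.0 - 2.0 / n)
    if np.any(pre <= 0):
        # Extreme tail draw: fall back to uncompensated targets (tiny bias).
        return np.maximum(target, 1e-3)
    return pre


def _coeff_block(rng: np.random.Generator, n_channels: int, n_bins: int
                 ) -> np.ndarray:
    """Complex Gaussian Fourier coefficients for one component."""
    return (rng.standard_normal((n_channels, n_bins))
            + 1j * rng.standard_normal((n_channels, n_bins)))


def _normalize_block(z: np.ndarray, n: int, variances) -> np.ndarray:
    """Scale coefficient rows so the synthesized time series has the exact
    requested per-channel variance (Parseval: var = 2*sum|X_k|^2 / n^2
    for a spectrum with zero DC and Nyquist terms)."""
    realized = 2.0 * (np.abs(z) ** 2).sum(axis=1) / n ** 2
    realized[realized == 0] = 1.0
    return z * np.sqrt(np.asarray(variances, dtype=float) / realized)[:, None]


def _synthesize_trial(rng: np.random.Generator, config: SimulationConfig,
                      osc_var: Mapping[str, np.ndarray], n: int) -> np.ndarray:
    """One trial of pink background plus band-limited oscillators.

    All components are drawn directly in the frequency domain (disjoint
    oscillator bands; an independent draw for the broadband background)
    and synthesized with a single inverse FFT per trial.
    """
    fs = config.sampling_rate
    n_ch = config.montage.n_channels
    freqs = np.fft.rfftfreq(n, 1.0 / fs)
    spec = np.zeros((n_ch, freqs.size), dtype=complex)
    # Interior bins only: DC and Nyquist stay zero.
    interior = np.ones_like(freqs, dtype=bool)
    interior[0] = interior[-1] = False

    for band, (f1, f2) in config.osc_bands.items():
        mask = interior & (freqs >= f1) & (freqs < f2)
        z = _coeff_block(rng, n_ch, int(mask.sum()))
        spec[:, mask] += _normalize_block(z, n, osc_var[band])

    if config.background_power > 0:
        mask = (interior & (freqs >= _BACKGROUND_RANGE[0])
                & (freqs <= _BACKGROUND_RANGE[1]))
        z = _coeff_block(rng, n_ch, int(mask.sum()))
        z *= (1.0 / np.sqrt(freqs[mask]))[None, :]
        spec[:, mask] += _normalize_block(
            z, n, np.full(n_ch, config.background_power))

    return np.fft.irfft(spec, n=n, axis=1)


def _band_limited_noise(rng: np.random.Generator, n_channels: int, n: int,
                        fs: float, f_low: float, f_high: float,
                        variances: np.ndarray) -> np.ndarray:
    """Gaussian noise confined to [f_low, f_high) with exact per-channel variance."""
    freqs = np.fft.rfftfreq(n, 1.0 / fs)
    mask = (freqs >= f_low) & (freqs < f_high)
    mask[0] = mask[-1] = False
    spec = np.zeros((n_channels, freqs.size), dtype=complex)
    z = _coeff_block(rng, n_channels, int(mask.sum()))
    spec[:, mask] = _normalize_block(z, n, variances)
    return np.fft.irfft(spec, n=n, axis=1)


def _blink_weights(montage: ChannelMontage) -> np.ndarray:
    return np.array([_BLINK_WEIGHTS.get(lab, _BLINK_OTHER)
                     for lab in montage.labels])


def blink_waveform(t: np.ndarray, t_peak: float, width: float,
                   amplitude: float) -> np.ndarray:
    """Biphasic (Gaussian-derivative) deflection with peak ``amplitude`` uV."""
    u = (t - t_peak) / width
    return amplitude * u * np.exp(0.5 - 0.5 * u * u)


def _inject_artifacts(rng: np.random.Generator, trial: np.ndarray,
                      config: SimulationConfig, trial_offset: float,
                      events: list[ArtifactEvent]) -> None:
    fs = config.sampling_rate
    n = trial.shape[1]
    t = np.arange(n) / fs
    duration_min = n / fs / 60.0
    montage = config.montage

    n_blinks = rng.poisson(config.blink_per_minute * duration_min)
    for _ in range(n_blinks):
        t0 = rng.uniform(0.4, n / fs - 0.4)
        w = _blink_weights(montage)
        wave = blink_waveform(t, t0, config.blink_width, config.blink_amplitude)
        trial += w[:, None] * wave[None, :]
        events.append(ArtifactEvent("blink", trial_offset + t0,
                                    config.blink_width,
                                    config.blink_amplitude, w))

    n_bursts = rng.poisson(config.emg_burst_per_minute * duration_min)
    temporal = [i for i, lab in enumerate(montage.labels)
                if montage.lobe_map[lab] == "temporal"]
    for _ in range(n_bursts):
        dur = config.emg_duration
        t0 = rng.uniform(0.2, n / fs - dur - 0.2)
        main = int(rng.choice(temporal))
        w = np.full(montage.n_channels, 0.05)
        w[main] = 1.0
        m = int(round(dur * fs))
        start = int(round(t0 * fs))
        hf_hi = min(95.0, config.sampling_rate / 2 - 5.0)
        burst = _band_limited_noise(rng, 1, m, fs, 35.0, hf_hi,
                                    np.array([config.emg_rms ** 2]))[0]
        window = np.hanning(m)
        trial[:, start:start + m] += w[:, None] * (burst * window)[None, :]
        events.append(ArtifactEvent("emg", trial_offset + t0 + dur / 2,
                                    dur, config.emg_rms, w))


def simulate_recording(subject: SubjectRecord, condition: str,
                       config: SimulationConfig) -> EEGRecording:
    """Generate one subject x condition recording from the planted targets.

    Deterministic given (seed, subject_id, condition).
    """
    if condition not in CONDITIONS:
        raise ValueError(
            f"unknown condition {condition!r}; expected one of {CONDITIONS}")
    config.validate()
    montage = config.montage
    fs = config.sampling_rate
    targets = subject_targets(subject, config)[condition]["powers"]

    # Post-reference per-channel band-power targets -> pre-reference
    # oscillator variances (background share subtracted).
    osc_var: dict[str, np.ndarray] = {}
    for band in _ANALYSIS_BANDS:
        post = np.array([targets[montage.lobe_map[lab]][band]
                         for lab in montage.labels])
        pre = _invert_reference_powers(post)
        v = pre - _background_band_power(config, band)
        osc_var[band] = np.maximum(v, 0.0)

    n_trial = int(round(config.trial_length * fs))
    trials = []
    events: list[ArtifactEvent] = []
    for k in range(config.n_trials_per_condition):
        rng = _stream(config.seed, subject.subject_id, condition, "trial", k)
        trial = _synthesize_trial(rng, config, osc_var, n_trial)
        _inject_artifacts(rng, trial, config, k * config.trial_length, events)
        trials.append(trial)

    return EEGRecording(
        subject_id=subject.subject_id,
        condition=condition,
        sampling_rate=fs,
        signal=np.concatenate(trials, axis=1),
        montage=montage,
        trial_length=config.trial_length,
        artifacts=events,
    )


def generate_cohort(config: SimulationConfig,
                    conditions: tuple[str, ...] = CONDITIONS):
    """Yield (subject, {condition: recording}) for the whole cohort."""
    for subject in simulate_metadata(config):
        yield subject, {cond: simulate_recording(subject, cond, config)
                        for cond in conditions}


def simulate_ratio_records(config: SimulationConfig,
                           conditions: tuple[str, ...] = CONDITIONS,
                           ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw lobar log-ratio records directly from the generating equation.

    Skips signal synthesis and spectral estimation; useful for
    statistics-level simulation studies (type-I error, consistency)
    where the spectral stage's sampling noise is not under test.
    Returns (metadata, ratios) frames shaped like the pipeline output.
    """
    subjects = simulate_metadata(config)
    rows = []
    for subject in subjects:
        t = subject_targets(subject, config)
        for cond in conditions:
            for lobe in LOBES:
                log_tbr, log_tar = t[cond]["logs"][lobe]
                rows.append({
                    "subject_id": subject.subject_id, "condition": cond,
                    "lobe": lobe, "tar": 10.0 ** log_tar,
                    "tbr": 10.0 ** log_tbr,
                    "log_tar": log_tar, "log_tbr": log_tbr,
                })
    return metadata_frame(subjects), pd.DataFrame(rows)


def null_slopes() -> dict[tuple[str, str], float]:
    """A planted-slope map with no coupling anywhere."""
    return {(lobe, cond): 0.0 for lobe in LOBES for cond in CONDITIONS}


def single_slope(lobe: str, condition: str,
                 slope: float) -> dict[tuple[str, str], float]:
    """A planted-slope map with coupling in exactly one lobe x condition."""
    slopes = null_slopes()
    slopes[(lobe, condition)] = slope
    return slopes
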