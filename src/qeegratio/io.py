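"""Reading and writing recordings and metadata.

Two interchangeable on-disk formats:

* delimited text: one CSV per subject x condition, rows = samples,
  columns = channels, header = 10-20 labels, values in microvolts;
* EDF (European Data Format): read through MNE; written by a minimal
  16-bit EDF writer (1 s data records), sufficient for round-tripping
  synthetic recordings.

Channel labels are matched to the montage case-insensitively, ignoring
an optional "EEG " prefix; extra channels are dropped with a warning and
missing montage channels are an error naming the channel.
"""

from __future__ import annotations

import struct
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .montage import ChannelMontage, DEFAULT_MONTAGE
from .recording import EEGRecording
from .synthetic import SubjectRecord, metadata_frame


def write_recording_delimited(rec: EEGRecording, path: str | Path,
                              decimals: int = 4) -> None:
    """Write samples x channels CSV with channel labels as header (uV)."""
    df = pd.DataFrame(rec.signal.T, columns=list(rec.montage.labels))
    df.to_csv(path, index=False, float_format=f"%.{decimals}f")


def _normalize_label(label: str) -> str:
    lab = label.strip()
    if lab.upper().startswith("EEG "):
        lab = lab[4:].strip()
    return lab.upper()


def _match_channels(file_labels: list[str], montage: ChannelMontage,
                    source: str) -> list[int]:
    """Indices of file channels matching the montage order; errors name
    missing channels, extras warn."""
    norm = {_normalize_label(lab): i for i, lab in enumerate(file_labels)}
    indices = []
    missing = []
    for lab in montage.labels:
        key = _normalize_label(lab)
        if key in norm:
            indices.append(norm[key])
        else:
            missing.append(lab)
    if missing:
        raise ValueError(f"{source}: missing montage channel(s) {missing}")
    matched = set(indices)
    extra = [file_labels[i] for i in range(len(file_labels)) if i not in matched]
    if extra:
        warnings.warn(f"{source}: dropping extra channel(s) {extra}",
                      stacklevel=2)
    return indices


def _ids_from_stem(path: Path, subject_id: str | None,
                   condition: str | None) -> tuple[str, str]:
    if subject_id is None or condition is None:
        parts = path.stem.rsplit("_", 1)
        if len(parts) != 2:
            raise ValueError(
                f"cannot infer subject/condition from {path.name!r}; "
                "expected '<subject>_<EO|EC>' naming or explicit arguments")
        subject_id = subject_id or parts[0]
        condition = condition or parts[1].upper()
    return subject_id, condition


def read_recording_delimited(path: str | Path, sampling_rate: float,
                             montage: ChannelMontage = DEFAULT_MONTAGE,
                             subject_id: str | None = None,
                             condition: str | None = None,
                             trial_length: float | None = None) -> EEGRecording:
    path = Path(path)
    subject_id, condition = _ids_from_stem(path, subject_id, condition)
    df = pd.read_csv(path)
    idx = _match_channels(list(df.columns), montage, path.name)
    signal = df.to_numpy(dtype=np.float64).T[idx]
    return EEGRecording(subject_id=subject_id, condition=condition,
                        sampling_rate=sampling_rate, signal=signal,
                        montage=montage, trial_length=trial_length)


# ---------------------------------------------------------------------------
# EDF


def _edf_field(value, width: int) -> bytes:
    s = str(value)
    if len(s) > width:
        s = s[:width]
    return s.ljust(width).encode("ascii")


def write_edf(rec: EEGRecording, path: str | Path) -> None:
    """Minimal EDF writer: int16 samples, 1 s data records, uV units.

    The sampling rate must be an integer; a trailing partial second is
    dropped.  Quantization error is (pmax - pmin) / 65535.
    """
    fs = rec.sampling_rate
    if abs(fs - round(fs)) > 1e-9:
        raise ValueError("EDF writer requires an integer sampling rate")
    fs = int(round(fs))
    n_ch = rec.signal.shape[0]
    n_records = rec.n_samples // fs
    if n_records < 1:
        raise ValueError("recording shorter than one 1 s EDF record")
    data = rec.signal[:, :n_records * fs]

    pmax = float(np.ceil(max(1.0, np.abs(data).max()) + 1.0))
    pmin = -pmax
    dmax, dmin = 32767, -32768
    scale = (dmax - dmin) / (pmax - pmin)
    digital = np.round((data - pmin) * scale + dmin).astype("<i2")

    header = b"".join([
        _edf_field("0", 8),
        _edf_field(rec.subject_id, 80),
        _edf_field(f"{rec.subject_id} {rec.condition}", 80),
        _edf_field("01.01.20", 8),
        _edf_field("00.00.00", 8),
        _edf_field(256 * (n_ch + 1), 8),
        _edf_field("", 44),
        _edf_field(n_records, 8),
        _edf_field(1, 8),
        _edf_field(n_ch, 4),
    ])
    fields = []
    for width, values in (
        (16, [f"EEG {lab}" for lab in rec.montage.labels]),
        (80, [""] * n_ch),
        (8, ["uV"] * n_ch),
        (8, [f"{pmin:g}"] * n_ch),
        (8, [f"{pmax:g}"] * n_ch),
        (8, [str(dmin)] * n_ch),
        (8, [str(dmax)] * n_ch),
        (80, [""] * n_ch),
        (8, [str(fs)] * n_ch),
        (32, [""] * n_ch),
    ):
        fields.extend(_edf_field(v, width) for v in values)
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(b"".join(fields))
        for r in range(n_records):
            block = digital[:, r * fs:(r + 1) * fs]
            fh.write(block.tobytes())


def read_edf(path: str | Path, montage: ChannelMontage = DEFAULT_MONTAGE,
             subject_id: str | None = None, condition: str | None = None,
             trial_length: float | None = None) -> EEGRecording:
    """Read an EDF file through MNE; output is microvolts."""
    import mne

    path = Path(path)
    subject_id, condition = _ids_from_stem(path, subject_id, condition)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    idx = _match_channels(list(raw.ch_names), montage, path.name)
    signal = raw.get_data()[idx] * 1e6   # MNE loads EEG in volts
    return EEGRecording(subject_id=subject_id, condition=condition,
                        sampling_rate=float(raw.info["sfreq"]), signal=signal,
                        montage=montage, trial_length=trial_length)


def read_eeg(path: str | Path, fmt: str | None = None,
             sampling_rate: float = 250.0,
             montage: ChannelMontage = DEFAULT_MONTAGE,
             subject_id: str | None = None, condition: str | None = None,
             trial_length: float | None = None) -> EEGRecording:
    """Dispatch on format ('edf' or 'delimited'; inferred from the suffix)."""
    path = Path(path)
    if fmt is None:
        fmt = "edf" if path.suffix.lower() == ".edf" else "delimited"
    if fmt == "edf":
        return read_edf(path, montage, subject_id, condition, trial_length)
    if fmt == "delimited":
        return read_recording_delimited(path, sampling_rate, montage,
                                        subject_id, condition, trial_length)
    raise ValueError(f"unknown format {fmt!r}; expected 'edf' or 'delimited'")


def write_recording(rec: EEGRecording, path: str | Path,
                    fmt: str = "delimited") -> None:
    if fmt == "edf":
        write_edf(rec, path)
    elif fmt == "delimited":
        write_recording_delimited(rec, path)
    else:
        raise ValueError(f"unknown format {fmt!r}; expected 'edf' or 'delimited'")


# ---------------------------------------------------------------------------
# Metadata


def write_metadata(records: list[SubjectRecord] | pd.DataFrame,
                   path: str | Path) -> None:
    df = records if isinstance(records, pd.DataFrame) else metadata_frame(records)
    df.to_csv(path, index=False, float_format="%.6g")


def read_metadata(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"subject_id", "age", "sex", "education_years", "kmmse",
                "oab_ng_ml"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: metadata missing column(s) {sorted(missing)}")
    return df
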