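"""Lobar theta-alpha and theta-beta ratios and their log transforms.

Relative band powers are first averaged (unweighted) over the lobe's
electrodes, then the ratios are formed:

    TAR = theta / alpha        TBR = theta / beta

and log-transformed (base 10 by default).  The alternative aggregation
order -- per-channel ratios averaged afterwards -- is available through
``per_channel_first`` for sensitivity analysis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

from .montage import LOBES, ChannelMontage
from .spectral import RelativeBandPowerTable


@dataclass(frozen=True)
class LobarRatioRecord:
    subject_id: str
    condition: str
    lobe: str
    tar: float
    tbr: float
    log_tar: float
    log_tbr: float


def lobar_band_power(rbp: RelativeBandPowerTable, montage: ChannelMontage,
                     lobe: str) -> dict[str, float]:
    """Unweighted mean of per-channel relative band power over a lobe."""
    channels = montage.lobe_channels(lobe)
    missing = [ch for ch in channels if ch not in rbp.values.index]
    if missing:
        raise ValueError(
            f"lobe {lobe!r}: channel(s) {missing} missing from the "
            "relative band power table"
        )
    sub = rbp.values.loc[list(channels)]
    return {band: float(sub[band].mean()) for band in rbp.values.columns}


def compute_ratios(lobar_powers: dict[str, float]) -> tuple[float, float]:
    """(TAR, TBR) from a band -> fraction map."""
    theta = lobar_powers["theta"]
    alpha = lobar_powers["alpha"]
    beta = lobar_powers["beta"]
    if alpha <= 0 or beta <= 0:
        raise ValueError(
            f"degenerate spectrum: alpha={alpha:g}, beta={beta:g} "
            "(both denominators must be positive)"
        )
    return theta / alpha, theta / beta


def log_transform(ratio: float, base: float = 10.0) -> float:
    """Logarithm of a positive ratio; base 10 by default, base e supported."""
    if ratio <= 0:
        raise ValueError(f"ratio must be positive, got {ratio:g}")
    return math.log(ratio, base)


def compute_lobar_ratios(
    rbp: RelativeBandPowerTable,
    montage: ChannelMontage,
    subject_id: str,
    condition: str,
    log_base: float = 10.0,
    per_channel_first: bool = False,
) -> list[LobarRatioRecord]:
    """One LobarRatioRecord per lobe for a subject x condition table."""
    records = []
    for lobe in LOBES:
        if per_channel_first:
            channels = montage.lobe_channels(lobe)
            missing = [ch for ch in channels if ch not in rbp.values.index]
            if missing:
                raise ValueError(
                    f"lobe {lobe!r}: channel(s) {missing} missing from the "
                    "relative band power table"
                )
            sub = rbp.values.loc[list(channels)]
            tars, tbrs = zip(*(
                compute_ratios(sub.loc[ch].to_dict()) for ch in channels
            ))
            tar = sum(tars) / len(tars)
            tbr = sum(tbrs) / len(tbrs)
        else:
            tar, tbr = compute_ratios(lobar_band_power(rbp, montage, lobe))
        records.append(LobarRatioRecord(
            subject_id=subject_id,
            condition=condition,
            lobe=lobe,
            tar=tar,
            tbr=tbr,
            log_tar=log_transform(tar, log_base),
            log_tbr=log_transform(tbr, log_base),
        ))
    return records


def records_to_frame(records: list[LobarRatioRecord]) -> pd.DataFrame:
    """Long-format table: subject_id, condition, lobe, tar, tbr, log_tar, log_tbr."""
    columns = ["subject_id", "condition", "lobe", "tar", "tbr",
               "log_tar", "log_tbr"]
    rows = [[r.subject_id, r.condition, r.lobe, r.tar, r.tbr,
             r.log_tar, r.log_tbr] for r in records]
    return pd.DataFrame(rows, columns=columns)
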