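"""The 19-channel international 10-20 montage and its lobar grouping.

Lobar indices (TAR, TBR) are computed per cortical lobe by averaging
relative band powers over the lobe's electrodes.  The default grouping is

* frontal   : Fp1, Fp2, F3, F4, F7, F8, Fz
* central   : C3, C4, Cz
* temporal  : T3, T4, T5, T6
* parietal  : P3, P4, Pz
* occipital : O1, O2

using the older T3/T4/T5/T6 naming for the temporal chain.
"""

from __future__ import annotations

from dataclasses import dataclass, field

LOBES = ("frontal", "central", "parietal", "occipital", "temporal")

_DEFAULT_LABELS = (
    "Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8",
    "T3", "C3", "Cz", "C4", "T4",
    "T5", "P3", "Pz", "P4", "T6",
    "O1", "O2",
)

_DEFAULT_LOBE_SETS = {
    "frontal": ("Fp1", "Fp2", "F3", "F4", "F7", "F8", "Fz"),
    "central": ("C3", "C4", "Cz"),
    "temporal": ("T3", "T4", "T5", "T6"),
    "parietal": ("P3", "P4", "Pz"),
    "occipital": ("O1", "O2"),
}


def _default_lobe_map() -> dict[str, str]:
    out: dict[str, str] = {}
    for lobe, labels in _DEFAULT_LOBE_SETS.items():
        for lab in labels:
            out[lab] = lobe
    return out


@dataclass(frozen=True)
class ChannelMontage:
    """An ordered channel list plus a label -> lobe assignment.

    Every label must be assigned to exactly one lobe.
    """

    labels: tuple[str, ...] = _DEFAULT_LABELS
    lobe_map: dict[str, str] = field(default_factory=_default_lobe_map)

    def __post_init__(self):
        missing = [lab for lab in self.labels if lab not in self.lobe_map]
        if missing:
            raise ValueError(f"labels without a lobe assignment: {missing}")
        extra = [lab for lab in self.lobe_map if lab not in self.labels]
        if extra:
            raise ValueError(f"lobe_map entries not in labels: {extra}")
        bad = [l for l in self.lobe_map.values() if l not in LOBES]
        if bad:
            raise ValueError(f"unknown lobes: {sorted(set(bad))}")

    @property
    def n_channels(self) -> int:
        return len(self.labels)

    def lobe_channels(self, lobe: str) -> tuple[str, ...]:
        if lobe not in LOBES:
            raise ValueError(f"unknown lobe {lobe!r}; expected one of {LOBES}")
        return tuple(lab for lab in self.labels if self.lobe_map[lab] == lobe)

    def index_of(self, label: str) -> int:
        return self.labels.index(label)


DEFAULT_MONTAGE = ChannelMontage()
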