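"""Electrode montage bookkeeping.

A montage is an ordered list of electrode labels from the extended 10-20
system, a scalp-region assignment (frontal / central / temporal / parietal)
and the label of the reference electrode.  The default montage is the
26-electrode layout of a 32-channel cap after dropping the three occipital
electrodes (O1, Oz, O2) and referencing to the vertex Cz.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

REGIONS = ("frontal", "central", "temporal", "parietal")

# 26 retained electrodes of the 32-channel extended 10-20 cap, in cap order.
DEFAULT_LABELS = (
    "FP1", "FP2", "F7", "F3", "Fz", "F4", "F8",
    "FT7", "FC3", "FCz", "FC4", "FT8",
    "T3", "C3", "C4", "T4",
    "TP7", "CP3", "CPz", "CP4", "TP8",
    "T5", "P3", "Pz", "P4", "T6",
)

_DEFAULT_REGIONS = {
    "frontal": ("FP1", "FP2", "F7", "F3", "Fz", "F4", "F8"),
    "central": ("FC3", "FCz", "FC4", "C3", "C4"),
    "temporal": ("FT7", "FT8", "T3", "T4", "TP7", "TP8", "T5", "T6"),
    "parietal": ("CP3", "CPz", "CP4", "P3", "Pz", "P4"),
}


@dataclass(frozen=True)
class ChannelMontage:
    """Ordered electrode labels with region assignment and reference.

    Parameters
    ----------
    labels : tuple of str
        Analysis electrodes, in canonical channel order.  The reference
        electrode is *not* part of ``labels``.
    region_of : dict
        Maps every label to one of ``REGIONS``.
    reference_label : str
        Electrode used as reference for the analysis montage.
    """

    labels: tuple[str, ...]
    region_of: dict[str, str] = field(compare=False)
    reference_label: str = "Cz"

    def __post_init__(self) -> None:
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("montage labels must be unique")
        missing = [lab for lab in self.labels if lab not in self.region_of]
        if missing:
            raise ValueError(f"labels without region assignment: {missing}")
        bad = {lab: r for lab, r in self.region_of.items() if r not in REGIONS}
        if bad:
            raise ValueError(f"unknown regions: {bad}")

    @property
    def n_channels(self) -> int:
        return len(self.labels)

    def region(self, name: str) -> tuple[str, ...]:
        """Labels belonging to region ``name``, in montage order."""
        if name not in REGIONS:
            raise ValueError(f"unknown region {name!r}; expected one of {REGIONS}")
        return tuple(lab for lab in self.labels if self.region_of[lab] == name)

    def index(self, label: str) -> int:
        try:
            return self.labels.index(label)
        except ValueError:
            raise KeyError(f"electrode {label!r} not in montage") from None

    def pairs(self) -> list[tuple[str, str]]:
        """All unordered electrode pairs, ordered lexicographically by
        (index_i, index_j) with i < j in montage order."""
        labs = self.labels
        return [(labs[i], labs[j]) for i in range(len(labs)) for j in range(i + 1, len(labs))]


def make_default_montage() -> ChannelMontage:
    """The default 26-electrode montage referenced to Cz.

    The frontal region has seven electrodes (FP1, FP2, F7, F3, Fz, F4, F8);
    the four regions partition the 26 labels.
    """
    region_of = {lab: reg for reg, labs in _DEFAULT_REGIONS.items() for lab in labs}
    return ChannelMontage(labels=DEFAULT_LABELS, region_of=region_of, reference_label="Cz")


def make_montage(
    labels: "list[str] | tuple[str, ...]",
    region_of: dict[str, str],
    reference_label: str = "Cz",
) -> ChannelMontage:
    """Build a custom montage (e.g., a reduced layout for simulations)."""
    return ChannelMontage(tuple(labels), dict(region_of), reference_label)


def read_montage(path: "str | Path", reference_label: str = "Cz") -> ChannelMontage:
    """Read a montage from a delimited text file with columns electrode,region."""
    labels: list[str] = []
    region_of: dict[str, str] = {}
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter=_sniff_delim(path))
        for row in reader:
            if not row or row[0].strip().lower() in ("electrode", "#"):
                continue
            lab, reg = row[0].strip(), row[1].strip().lower()
            labels.append(lab)
            region_of[lab] = reg
    return ChannelMontage(tuple(labels), region_of, reference_label)


def write_montage(montage: ChannelMontage, path: "str | Path") -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["electrode", "region"])
        for lab in montage.labels:
            writer.writerow([lab, montage.region_of[lab]])


def _sniff_delim(path: "str | Path") -> str:
    with open(path) as fh:
        first = fh.readline()
    return "\t" if "\t" in first else ","
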