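"""Raw recordings, re-referencing, band-pass filtering and epoch segmentation.

The acquisition protocol this package targets records 90 s of eyes-open
resting-state EEG at 500 Hz, on-line referenced to the right mastoid (A2).
Preprocessing re-references to the vertex Cz, band-pass filters to 2-50 Hz
and cuts the recording into 15 non-overlapping 6 s epochs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
from scipy import signal

CLASS_LABELS = ("MDD", "HC", "unknown")


@dataclass
class RawRecording:
    """One subject's multichannel EEG in microvolts.

    ``data`` rows correspond one-to-one, in order, to ``channel_labels``.
    """

    subject_id: str
    site_id: str
    class_label: str
    fs: float
    channel_labels: tuple[str, ...]
    data: np.ndarray  # channels x samples
    reference_label: str = "A2"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.channel_labels = tuple(self.channel_labels)
        if self.class_label not in CLASS_LABELS:
            raise ValueError(f"class_label must be one of {CLASS_LABELS}")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if self.data.ndim != 2 or self.data.shape[0] != len(self.channel_labels):
            raise ValueError(
                f"data must be (n_channels={len(self.channel_labels)}) x samples, "
                f"got shape {self.data.shape}"
            )

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs

    def channel(self, label: str) -> np.ndarray:
        try:
            idx = self.channel_labels.index(label)
        except ValueError:
            raise KeyError(f"channel {label!r} not in recording") from None
        return self.data[idx]


@dataclass
class EpochSet:
    """Non-overlapping, contiguous, fixed-length epochs of one recording."""

    subject_id: str
    site_id: str
    class_label: str
    fs: float
    channel_labels: tuple[str, ...]
    data: np.ndarray  # epochs x channels x samples

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.channel_labels = tuple(self.channel_labels)
        if self.data.ndim != 3:
            raise ValueError("epoch data must be epochs x channels x samples")
        if self.data.shape[1] != len(self.channel_labels):
            raise ValueError("channel axis does not match channel_labels")
        if self.data.shape[0] < 1:
            raise ValueError("need at least one epoch")

    @property
    def n_epochs(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples_per_epoch(self) -> int:
        return self.data.shape[2]


def rereference(rec: RawRecording, new_ref: str) -> RawRecording:
    """Subtract the ``new_ref`` channel from every other channel.

    The new reference channel is removed from the output (its re-referenced
    trace is identically zero), which is how a 27-channel cap segment becomes
    the 26-electrode analysis montage after referencing to Cz.
    """
    if new_ref not in rec.channel_labels:
        raise KeyError(
            f"reference electrode {new_ref!r} is not a channel of the recording "
            f"(channels: {list(rec.channel_labels)})"
        )
    ref_idx = rec.channel_labels.index(new_ref)
    keep = [i for i in range(rec.n_channels) if i != ref_idx]
    data = rec.data[keep] - rec.data[ref_idx]
    labels = tuple(rec.channel_labels[i] for i in keep)
    return replace(rec, channel_labels=labels, data=data, reference_label=new_ref)


def bandpass(rec: RawRecording, low_hz: float = 2.0, high_hz: float = 50.0,
             order: int = 8) -> RawRecording:
    """Zero-phase Butterworth band-pass filter (applied forward-backward).

    The default order (8 per band edge) keeps a 60 Hz mains tone below 5 %
    residual RMS for the 2-50 Hz analysis band while leaving in-band tones
    untouched.  Shape and channel ordering are preserved.
    """
    nyq = rec.fs / 2.0
    if not (0.0 < low_hz < high_hz < nyq):
        raise ValueError(
            f"band ({low_hz}, {high_hz}) Hz must satisfy 0 < low < high < "
            f"Nyquist ({nyq} Hz)"
        )
    sos = signal.butter(order, [low_hz, high_hz], btype="bandpass", fs=rec.fs,
                        output="sos")
    data = signal.sosfiltfilt(sos, rec.data, axis=-1)
    return replace(rec, data=data)


def segment(rec: RawRecording, epoch_seconds: float = 6.0) -> EpochSet:
    """Cut the recording into non-overlapping epochs; trailing samples that
    do not fill a whole epoch are discarded."""
    n_per = int(round(epoch_seconds * rec.fs))
    if n_per < 1 or rec.n_samples < n_per:
        raise ValueError(
            f"recording of {rec.n_samples} samples is shorter than one "
            f"{epoch_seconds} s epoch ({n_per} samples)"
        )
    n_epochs = rec.n_samples // n_per
    data = rec.data[:, : n_epochs * n_per]
    data = data.reshape(rec.n_channels, n_epochs, n_per).transpose(1, 0, 2)
    return EpochSet(
        subject_id=rec.subject_id,
        site_id=rec.site_id,
        class_label=rec.class_label,
        fs=rec.fs,
        channel_labels=rec.channel_labels,
        data=data.copy(),
    )


# ---------------------------------------------------------------------------
# I/O: plain delimited matrices with a JSON sidecar, and EDF via MNE.
# ---------------------------------------------------------------------------

def write_recording(rec: RawRecording, path: "str | Path") -> None:
    """Write a recording as a TSV matrix (header row of channel labels, one
    row per sample) plus a ``.json`` sidecar with the metadata."""
    path = Path(path)
    header = "\t".join(rec.channel_labels)
    np.savetxt(path, rec.data.T, delimiter="\t", header=header, comments="",
               fmt="%.6f")
    sidecar = {
        "subject_id": rec.subject_id,
        "site_id": rec.site_id,
        "class_label": rec.class_label,
        "fs": rec.fs,
        "reference_label": rec.reference_label,
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=1))


def read_recording(path: "str | Path") -> RawRecording:
    """Read a recording written by :func:`write_recording`."""
    path = Path(path)
    sidecar_path = path.with_suffix(path.suffix + ".json")
    if not sidecar_path.exists():
        raise FileNotFoundError(f"missing metadata sidecar {sidecar_path}")
    meta = json.loads(sidecar_path.read_text())
    with open(path) as fh:
        labels = tuple(fh.readline().rstrip("\n").split("\t"))
    data = np.loadtxt(path, delimiter="\t", skiprows=1, ndmin=2).T
    return RawRecording(
        subject_id=meta["subject_id"],
        site_id=meta["site_id"],
        class_label=meta["class_label"],
        fs=float(meta["fs"]),
        channel_labels=labels,
        data=data,
        reference_label=meta.get("reference_label", "A2"),
    )


def read_edf(path: "str | Path", subject_id: str = "", site_id: str = "",
             class_label: str = "unknown",
             reference_label: str = "A2") -> RawRecording:
    """Read an EDF file into a :class:`RawRecording` (channel labels and
    sampling rate are taken from the EDF header; data converted to µV)."""
    import mne  # heavy import kept local

    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    data_uv = raw.get_data() * 1e6  # MNE loads EEG in volts
    return RawRecording(
        subject_id=subject_id or Path(path).stem,
        site_id=site_id,
        class_label=class_label,
        fs=float(raw.info["sfreq"]),
        channel_labels=tuple(raw.ch_names),
        data=data_uv,
        reference_label=reference_label,
    )
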