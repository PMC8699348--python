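"""End-to-end helpers binding preprocessing and feature extraction.

The canonical chain per subject is: re-reference to the montage reference
(Cz), 2-50 Hz zero-phase band-pass, optional artifact-cleaning hook, and
segmentation into 6 s epochs; features are then extracted per epoch and
averaged.
"""

from __future__ import annotations

from typing import Callable, Iterable

from .features import BandScheme, DEFAULT_KMAX, FeatureTable, extract_all
from .montage import ChannelMontage, make_default_montage
from .recording import EpochSet, RawRecording, bandpass, rereference, segment

Cleaner = Callable[[RawRecording], RawRecording]


def preprocess(rec: RawRecording, montage: ChannelMontage | None = None,
               low_hz: float = 2.0, high_hz: float = 50.0,
               epoch_seconds: float = 6.0,
               cleaner: Cleaner | None = None) -> EpochSet:
    """Re-reference, band-pass filter, optionally clean, and segment.

    ``cleaner`` is a pass-through hook for an external artifact-removal step
    (e.g. an ICA-based eye-blink remover); it receives and must return a
    RawRecording.  Channels are reordered to montage order.
    """
    if montage is None:
        montage = make_default_montage()
    out = rec
    if montage.reference_label in out.channel_labels:
        out = rereference(out, montage.reference_label)
    out = bandpass(out, low_hz, high_hz)
    if cleaner is not None:
        out = cleaner(out)
    missing = set(montage.labels) - set(out.channel_labels)
    if missing:
        raise ValueError(f"recording lacks montage channels {sorted(missing)}")
    order = [out.channel_labels.index(lab) for lab in montage.labels]
    out.data = out.data[order]
    out.channel_labels = tuple(montage.labels)
    return segment(out, epoch_seconds)


def extract_cohort(recordings: Iterable[RawRecording],
                   montage: ChannelMontage | None = None,
                   scheme: BandScheme = BandScheme(),
                   kmax_list: tuple[int, ...] = DEFAULT_KMAX,
                   low_hz: float = 2.0, high_hz: float = 50.0,
                   epoch_seconds: float = 6.0,
                   cleaner: Cleaner | None = None,
                   coherence_average: str = "coherence") -> FeatureTable:
    """Preprocess every recording and assemble the full feature table."""
    eps = [preprocess(r, montage, low_hz, high_hz, epoch_seconds, cleaner)
           for r in recordings]
    return extract_all(eps, scheme=scheme, kmax_list=kmax_list,
                       coherence_average=coherence_average)
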