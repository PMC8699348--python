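"""Subject-level EEG features: log band power, band coherence, Higuchi and
Katz fractal dimensions, and the 1859-column feature table.

Every feature is computed per 6 s epoch and averaged across epochs, so each
subject contributes exactly one value per feature.  With the default
26-electrode montage and five frequency bands the full table has

    130 log band powers  (26 electrodes x 5 bands)
  + 1625 band coherences (26*25/2 electrode pairs x 5 bands)
  +   78 Higuchi fractal dimensions (26 electrodes x kmax in {50, 100, 150})
  +   26 Katz fractal dimensions
  = 1859 features.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import signal

from .montage import ChannelMontage
from .recording import EpochSet

DEFAULT_BANDS = (
    ("delta", 2.0, 4.0),
    ("theta", 4.0, 8.0),
    ("alpha", 8.0, 13.0),
    ("beta", 13.0, 30.0),
    ("gamma", 30.0, 45.0),
)

DEFAULT_KMAX = (50, 100, 150)

KINDS = ("BP", "COH", "HFD", "KFD")


@dataclass(frozen=True)
class BandScheme:
    """Ordered, interior-disjoint frequency bands.

    Band edges are treated half-open, [low, high), so a shared edge such as
    8 Hz belongs to the upper band only and is never counted twice.
    """

    bands: tuple[tuple[str, float, float], ...] = DEFAULT_BANDS

    def __post_init__(self) -> None:
        prev_high = -np.inf
        prev_low = -np.inf
        for name, low, high in self.bands:
            if not low < high:
                raise ValueError(f"band {name}: low must be < high")
            if low < prev_high or low < prev_low:
                raise ValueError("bands must be ordered and non-overlapping")
            prev_low, prev_high = low, high

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(b[0] for b in self.bands)

    def edges(self, name: str) -> tuple[float, float]:
        for n, low, high in self.bands:
            if n == name:
                return low, high
        raise KeyError(f"unknown band {name!r}")


@dataclass(frozen=True)
class FeatureDescriptor:
    """Typed name of one feature column.

    kind BP  -> band + single electrode
    kind COH -> band + electrode pair
    kind HFD -> single electrode + kmax
    kind KFD -> single electrode
    """

    kind: str
    band: str | None = None
    electrodes: tuple[str, ...] = ()
    kmax: int | None = None

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"kind must be one of {KINDS}")
        n_el = len(self.electrodes)
        if self.kind == "BP" and (self.band is None or n_el != 1):
            raise ValueError("BP descriptor needs a band and one electrode")
        if self.kind == "COH" and (self.band is None or n_el != 2):
            raise ValueError("COH descriptor needs a band and an electrode pair")
        if self.kind == "HFD" and (n_el != 1 or self.kmax is None):
            raise ValueError("HFD descriptor needs one electrode and kmax")
        if self.kind == "KFD" and n_el != 1:
            raise ValueError("KFD descriptor needs exactly one electrode")

    def __str__(self) -> str:
        if self.kind == "BP":
            return f"BP|{self.band}|{self.electrodes[0]}"
        if self.kind == "COH":
            return f"COH|{self.band}|{self.electrodes[0]}-{self.electrodes[1]}"
        if self.kind == "HFD":
            return f"HFD|k{self.kmax}|{self.electrodes[0]}"
        return f"KFD|{self.electrodes[0]}"

    @classmethod
    def parse(cls, text: str) -> "FeatureDescriptor":
        parts = text.split("|")
        kind = parts[0]
        if kind == "BP":
            return cls("BP", band=parts[1], electrodes=(parts[2],))
        if kind == "COH":
            a, b = parts[2].split("-")
            return cls("COH", band=parts[1], electrodes=(a, b))
        if kind == "HFD":
            return cls("HFD", electrodes=(parts[2],), kmax=int(parts[1][1:]))
        if kind == "KFD":
            return cls("KFD", electrodes=(parts[1],))
        raise ValueError(f"cannot parse feature descriptor {text!r}")


@dataclass
class FeatureTable:
    """Subjects x named features, with class and site labels."""

    subject_ids: list[str]
    site_ids: list[str]
    class_labels: list[str]
    descriptors: list[FeatureDescriptor]
    values: np.ndarray  # subjects x features

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.subject_ids), len(self.descriptors)):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.subject_ids)} subjects x {len(self.descriptors)} features"
            )

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def columns_of_kind(self, kind: str) -> list[int]:
        return [i for i, d in enumerate(self.descriptors) if d.kind == kind]

    def select(self, columns: "list[int] | np.ndarray") -> "FeatureTable":
        columns = list(columns)
        return FeatureTable(
            subject_ids=list(self.subject_ids),
            site_ids=list(self.site_ids),
            class_labels=list(self.class_labels),
            descriptors=[self.descriptors[i] for i in columns],
            values=self.values[:, columns].copy(),
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=[str(d) for d in self.descriptors])
        df.insert(0, "class_label", self.class_labels)
        df.insert(0, "site_id", self.site_ids)
        df.insert(0, "subject_id", self.subject_ids)
        return df


# ---------------------------------------------------------------------------
# Spectral helpers
# ---------------------------------------------------------------------------

def _band_mask(freqs: np.ndarray, low: float, high: float) -> np.ndarray:
    """Half-open band selection [low, high)."""
    return (freqs >= low) & (freqs < high)


def epoch_band_powers(epoch: np.ndarray, fs: float, scheme: BandScheme) -> np.ndarray:
    """Raw band powers of one epoch, channels x bands.

    PSD by FFT periodogram (rectangular window); band power by trapezoidal
    integration of the PSD over [low, high).
    """
    epoch = np.atleast_2d(np.asarray(epoch, dtype=float))
    freqs, psd = signal.periodogram(epoch, fs=fs, window="boxcar", axis=-1)
    out = np.empty((epoch.shape[0], len(scheme.bands)))
    for b, (_, low, high) in enumerate(scheme.bands):
        m = _band_mask(freqs, low, high)
        if m.sum() < 2:
            raise ValueError(
                f"band [{low}, {high}) Hz covers fewer than two frequency bins; "
                "epoch too short for this band"
            )
        out[:, b] = np.trapezoid(psd[:, m], freqs[m], axis=-1)
    return out


def cross_spectra(epoch: np.ndarray, fs: float, nperseg: int | None = None,
                  noverlap: int | None = None, window: str = "hann"):
    """Welch auto-/cross-power spectral matrix of one multichannel epoch.

    Returns ``(freqs, G)`` with ``G[i, j, f]`` the averaged cross-power
    density between channels i and j.  Defaults: 1 s segments, 50 % overlap
    (11 segments for a 6 s epoch).
    """
    epoch = np.atleast_2d(np.asarray(epoch, dtype=float))
    if nperseg is None:
        nperseg = int(round(fs))
    nperseg = min(nperseg, epoch.shape[-1])
    if noverlap is None:
        noverlap = nperseg // 2
    freqs, G = signal.csd(epoch[:, None, :], epoch[None, :, :], fs=fs,
                          window=window, nperseg=nperseg, noverlap=noverlap)
    return freqs, G


def _coherence_from_spectra(G: np.ndarray) -> np.ndarray:
    """Magnitude-squared coherence per frequency bin from a cross-spectral
    matrix, channels x channels x freqs."""
    auto = np.real(np.einsum("iif->if", G))
    denom = auto[:, None, :] * auto[None, :, :]
    with np.errstate(invalid="ignore", divide="ignore"):
        coh = np.abs(G) ** 2 / denom
    return coh


def band_coherence(x: np.ndarray, y: np.ndarray, fs: float,
                   band: tuple[float, float], nperseg: int | None = None,
                   noverlap: int | None = None, window: str = "hann") -> float:
    """Squared band coherence of two equal-length epoch signals, in [0, 1].

    Welch auto-/cross-spectra within the epoch, magnitude-squared coherence
    per bin, mean over the bins in [low, high).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D signals")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("coherence is undefined for a zero-variance signal")
    low, high = band
    if not 0 <= low < high <= fs / 2:
        raise ValueError(f"band {band} outside [0, Nyquist={fs / 2}]")
    freqs, G = cross_spectra(np.stack([x, y]), fs, nperseg, noverlap, window)
    coh = _coherence_from_spectra(G)[0, 1]
    m = _band_mask(freqs, low, high)
    if not m.any():
        raise ValueError(f"no frequency bins inside band {band}")
    return float(np.mean(coh[m]))


# ---------------------------------------------------------------------------
# Fractal dimensions
# ---------------------------------------------------------------------------

def higuchi_curve_lengths(x: np.ndarray, kmax: int) -> np.ndarray:
    """Mean curve length L(k) for k = 1..kmax.

    For each time interval k and starting offset m = 1..k the curve length of
    the decimated subseries X(m), X(m+k), ... is the normalized sum of
    absolute increments; L(k) averages over the k offsets.
    """
    x = np.asarray(x, dtype=float)
    ns = x.size
    if not 2 <= kmax < ns:
        raise ValueError(f"need 2 <= kmax < signal length, got kmax={kmax}, N={ns}")
    lengths = np.empty(kmax)
    for k in range(1, kmax + 1):
        d = np.abs(x[k:] - x[:-k])  # d[j] = |X(j+1+k) - X(j+1)|, j 0-based
        n_blocks = -(-d.size // k)  # ceil
        padded = np.zeros(n_blocks * k)
        padded[: d.size] = d
        sums = padded.reshape(n_blocks, k).sum(axis=0)  # per offset m-1
        m = np.arange(1, k + 1)
        n_m = (ns - m) // k  # number of increments for offset m
        lengths[k - 1] = np.mean(sums * (ns - 1) / (n_m * k) / k)
    return lengths


def higuchi_fd(x: np.ndarray, kmax: int = 50) -> float:
    """Higuchi fractal dimension: least-squares slope of log L(k) against
    log(1/k), k = 1..kmax.

    Close to 1 for a deterministic signal and close to 2 for white noise.
    """
    lengths = higuchi_curve_lengths(x, kmax)
    if np.any(lengths <= 0):
        raise ValueError("constant (or piecewise-constant) signal: curve length "
                         "is zero, HFD undefined")
    k = np.arange(1, kmax + 1)
    slope, _ = np.polyfit(np.log(1.0 / k), np.log(lengths), 1)
    return float(slope)


def _higuchi_fd_from_lengths(lengths: np.ndarray, kmax: int) -> float:
    sub = lengths[:kmax]
    if np.any(sub <= 0):
        raise ValueError("constant signal: HFD undefined")
    k = np.arange(1, kmax + 1)
    slope, _ = np.polyfit(np.log(1.0 / k), np.log(sub), 1)
    return float(slope)


@dataclass(frozen=True)
class WaveformGeometry:
    """Planar geometry of a sampled waveform: total curve length L, planar
    extent D (max distance from the first sample) and mean step A = L/(N-1)."""

    total_length: float
    planar_extent: float
    mean_step: float


def waveform_geometry(x: np.ndarray) -> WaveformGeometry:
    """Geometry of the waveform (i, x_i) embedded with the time step equal
    to the signal's mean absolute increment.

    This dimensionless embedding makes the geometry — and hence the Katz
    fractal dimension — invariant to amplitude rescaling and to the physical
    units of the recording, while a straight ramp keeps D = L exactly.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        raise ValueError("need at least two samples")
    if np.ptp(x) == 0:
        raise ValueError("KFD undefined for a constant signal")
    dx = np.diff(x)
    unit = np.mean(np.abs(dx))
    if unit == 0:
        raise ValueError("KFD undefined for a constant signal")
    xn = x / unit
    step = np.hypot(1.0, np.diff(xn))
    total = float(step.sum())
    idx = np.arange(x.size)
    extent = float(np.hypot(idx, xn - xn[0]).max())
    return WaveformGeometry(total_length=total, planar_extent=extent,
                            mean_step=total / (x.size - 1))


def katz_fd(x: np.ndarray) -> float:
    """Katz fractal dimension of a waveform.

    With L the total curve length (sum of successive point-to-point planar
    distances), D the planar extent (max planar distance from the first
    sample) and A = L/(N-1) the mean step, KFD = log(L/A) / (log(D/L) +
    log(L/A)).  The waveform is embedded as in :func:`waveform_geometry`, so
    the estimate is amplitude-invariant; a straight ramp of any slope has
    D = L and hence KFD = 1 exactly.
    """
    geom = waveform_geometry(x)
    n = np.asarray(x).size - 1  # L/A = N-1
    return float(np.log(n) / (np.log(geom.planar_extent / geom.total_length)
                              + np.log(n)))


# ---------------------------------------------------------------------------
# Epoch-set -> feature blocks
# ---------------------------------------------------------------------------

def _meta(eps: list[EpochSet]):
    return (
        [e.subject_id for e in eps],
        [e.site_id for e in eps],
        [e.class_label for e in eps],
    )


def extract_bp(epoch_sets: "EpochSet | list[EpochSet]",
               scheme: BandScheme = BandScheme()) -> FeatureTable:
    """Log10 band powers per electrode per band, epoch-averaged.

    Canonical order: band-major, then electrode order of the montage.
    """
    eps = [epoch_sets] if isinstance(epoch_sets, EpochSet) else list(epoch_sets)
    labels = eps[0].channel_labels
    descriptors = [
        FeatureDescriptor("BP", band=bname, electrodes=(lab,))
        for bname in scheme.names for lab in labels
    ]
    rows = []
    for ep in eps:
        bp = np.stack([epoch_band_powers(e, ep.fs, scheme) for e in ep.data])
        mean_bp = bp.mean(axis=0)  # channels x bands
        if np.any(mean_bp <= 0):
            ch, band = np.argwhere(mean_bp <= 0)[0]
            raise ValueError(
                f"subject {ep.subject_id}: zero band power at channel "
                f"{labels[ch]!r}, band {scheme.names[band]!r}; log power undefined"
            )
        rows.append(np.log10(mean_bp).T.ravel())  # band-major
    subj, site, cls = _meta(eps)
    return FeatureTable(subj, site, cls, descriptors, np.array(rows))


def extract_coherence(epoch_sets: "EpochSet | list[EpochSet]",
                      scheme: BandScheme = BandScheme(),
                      nperseg: int | None = None, noverlap: int | None = None,
                      window: str = "hann",
                      average: str = "coherence") -> FeatureTable:
    """Band coherence per unordered electrode pair per band.

    ``average="coherence"`` (default) computes the squared coherence per
    epoch and averages the per-epoch values; ``average="spectra"`` averages
    the cross-spectra over all epochs before forming the coherence ratio.

    Canonical order: band-major, then pairs ordered by (i, j) channel index.
    """
    if average not in ("coherence", "spectra"):
        raise ValueError("average must be 'coherence' or 'spectra'")
    eps = [epoch_sets] if isinstance(epoch_sets, EpochSet) else list(epoch_sets)
    labels = eps[0].channel_labels
    nch = len(labels)
    if nch < 2:
        raise ValueError("coherence needs at least two channels")
    pair_idx = [(i, j) for i in range(nch) for j in range(i + 1, nch)]
    descriptors = [
        FeatureDescriptor("COH", band=bname, electrodes=(labels[i], labels[j]))
        for bname in scheme.names for i, j in pair_idx
    ]
    ii = np.array([p[0] for p in pair_idx])
    jj = np.array([p[1] for p in pair_idx])
    rows = []
    for ep in eps:
        flat = np.ptp(ep.data, axis=2) == 0
        if flat.any():
            e, c = np.argwhere(flat)[0]
            raise ValueError(
                f"subject {ep.subject_id}: zero-variance epoch {e} at channel "
                f"{labels[c]!r}; coherence undefined"
            )
        if average == "coherence":
            acc = None
            for e in ep.data:
                freqs, G = cross_spectra(e, ep.fs, nperseg, noverlap, window)
                coh = _coherence_from_spectra(G)
                acc = coh if acc is None else acc + coh
            coh = acc / ep.n_epochs
        else:
            acc = None
            for e in ep.data:
                freqs, G = cross_spectra(e, ep.fs, nperseg, noverlap, window)
                acc = G if acc is None else acc + G
            coh = _coherence_from_spectra(acc / ep.n_epochs)
        row = np.empty(len(descriptors))
        col = 0
        for _, low, high in scheme.bands:
            m = _band_mask(freqs, low, high)
            if not m.any():
                raise ValueError(f"no frequency bins inside band [{low}, {high})")
            band_coh = coh[:, :, m].mean(axis=2)
            row[col: col + len(pair_idx)] = band_coh[ii, jj]
            col += len(pair_idx)
        rows.append(row)
    subj, site, cls = _meta(eps)
    return FeatureTable(subj, site, cls, descriptors, np.array(rows))


def extract_hfd(epoch_sets: "EpochSet | list[EpochSet]",
                kmax_list: tuple[int, ...] = DEFAULT_KMAX) -> FeatureTable:
    """Higuchi FD per electrode per kmax, epoch-averaged.

    Canonical order: kmax-major, then electrode.  L(k) is computed once up to
    max(kmax_list); smaller kmax settings reuse the prefix.
    """
    eps = [epoch_sets] if isinstance(epoch_sets, EpochSet) else list(epoch_sets)
    labels = eps[0].channel_labels
    kmax_list = tuple(kmax_list)
    kbig = max(kmax_list)
    descriptors = [
        FeatureDescriptor("HFD", electrodes=(lab,), kmax=km)
        for km in kmax_list for lab in labels
    ]
    rows = []
    for ep in eps:
        if ep.n_samples_per_epoch <= kbig:
            raise ValueError(
                f"epoch length {ep.n_samples_per_epoch} must exceed max kmax {kbig}"
            )
        vals = np.empty((len(kmax_list), len(labels)))
        per_epoch = np.empty((ep.n_epochs, len(kmax_list), len(labels)))
        for e_i, e in enumerate(ep.data):
            for c_i in range(len(labels)):
                try:
                    lengths = higuchi_curve_lengths(e[c_i], kbig)
                    for k_i, km in enumerate(kmax_list):
                        per_epoch[e_i, k_i, c_i] = _higuchi_fd_from_lengths(lengths, km)
                except ValueError as err:
                    raise ValueError(
                        f"subject {ep.subject_id}, channel {labels[c_i]!r}: {err}"
                    ) from None
        vals = per_epoch.mean(axis=0)
        rows.append(vals.ravel())
    subj, site, cls = _meta(eps)
    return FeatureTable(subj, site, cls, descriptors, np.array(rows))


def extract_kfd(epoch_sets: "EpochSet | list[EpochSet]") -> FeatureTable:
    """Katz FD per electrode, epoch-averaged."""
    eps = [epoch_sets] if isinstance(epoch_sets, EpochSet) else list(epoch_sets)
    labels = eps[0].channel_labels
    descriptors = [FeatureDescriptor("KFD", electrodes=(lab,)) for lab in labels]
    rows = []
    for ep in eps:
        vals = np.empty((ep.n_epochs, len(labels)))
        for e_i, e in enumerate(ep.data):
            for c_i in range(len(labels)):
                try:
                    vals[e_i, c_i] = katz_fd(e[c_i])
                except ValueError as err:
                    raise ValueError(
                        f"subject {ep.subject_id}, channel {labels[c_i]!r}: {err}"
                    ) from None
        rows.append(vals.mean(axis=0))
    subj, site, cls = _meta(eps)
    return FeatureTable(subj, site, cls, descriptors, np.array(rows))


_KIND_ORDER = {k: i for i, k in enumerate(KINDS)}


def assemble(*blocks: FeatureTable) -> FeatureTable:
    """Concatenate feature blocks into one table in canonical order
    BP -> COH -> HFD -> KFD, preserving descriptors.

    All blocks must share the same subjects in the same order.
    """
    if not blocks:
        raise ValueError("no blocks to assemble")
    ref = blocks[0]
    for b in blocks[1:]:
        if b.subject_ids != ref.subject_ids:
            raise ValueError("blocks do not share the same subjects in order")
    ordered = sorted(blocks, key=lambda b: min(
        (_KIND_ORDER[d.kind] for d in b.descriptors), default=len(KINDS)))
    descriptors = [d for b in ordered for d in b.descriptors]
    values = np.hstack([b.values for b in ordered])
    return FeatureTable(list(ref.subject_ids), list(ref.site_ids),
                        list(ref.class_labels), descriptors, values)


def extract_all(epoch_sets: "EpochSet | list[EpochSet]",
                scheme: BandScheme = BandScheme(),
                kmax_list: tuple[int, ...] = DEFAULT_KMAX,
                nperseg: int | None = None, noverlap: int | None = None,
                coherence_average: str = "coherence") -> FeatureTable:
    """Full feature extraction: BP + COH + HFD + KFD in canonical order."""
    eps = [epoch_sets] if isinstance(epoch_sets, EpochSet) else list(epoch_sets)
    return assemble(
        extract_bp(eps, scheme),
        extract_coherence(eps, scheme, nperseg, noverlap,
                          average=coherence_average),
        extract_hfd(eps, kmax_list),
        extract_kfd(eps),
    )


def car_normalize_bp(table: FeatureTable) -> FeatureTable:
    """Common-average normalization of the BP block: per subject and band,
    subtract the mean log band power over all electrodes of that band.

    Non-BP columns are left untouched.  Adding a constant to every channel of
    one band leaves the normalized values unchanged; within-band differences
    between channels are preserved exactly.
    """
    values = table.values.copy()
    bands = {d.band for d in table.descriptors if d.kind == "BP"}
    for band in bands:
        cols = [i for i, d in enumerate(table.descriptors)
                if d.kind == "BP" and d.band == band]
        block = values[:, cols]
        values[:, cols] = block - block.mean(axis=1, keepdims=True)
    return replace(table, values=values,
                   subject_ids=list(table.subject_ids),
                   site_ids=list(table.site_ids),
                   class_labels=list(table.class_labels),
                   descriptors=list(table.descriptors))
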