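"""Seeded simulator of multi-site resting-state EEG cohorts.

The generator emulates the acquisition protocol of the classification
pipeline (26-channel extended 10-20 cap plus the Cz reference channel,
500 Hz, 90 s per subject) with controllable class effects, so every
pipeline stage is testable without clinical data.

Signal model, per channel i and band b:

    x_i = sum_b amp_b * ( sqrt(rho_ib) * s_b + sqrt(1 - rho_ib) * e_ib )
          + w_bg * n_i(1/f^beta) + w_white * white_i + line noise

where s_b is a band-limited shared source (one per band), e_ib are
band-limited private sources, and rho_ib in [0, 1) is the shared-source
mixing fraction.  Because the band component has unit variance regardless of
rho, a class effect on rho moves inter-channel coherence (roughly
COH^2 ~ rho_i * rho_j) while leaving band powers untouched; band-power
effects are applied as dB gains on amp_b instead.  Site profiles apply a
multiplicative per-channel gain, a noise-floor scale and optional mains line
noise, mimicking inter-site variability; a pure gain change shifts log band
powers but leaves coherence and both fractal dimensions invariant.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal

from .montage import ChannelMontage, make_default_montage
from .recording import RawRecording

DEFAULT_BAND_EDGES = {
    "delta": (2.0, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 13.0),
    "beta": (13.0, 30.0),
    "gamma": (30.0, 45.0),
}

# Per-band amplitude scales (relative), a coarse resting-state spectrum shape.
DEFAULT_BAND_AMP = {
    "delta": 1.0,
    "theta": 0.8,
    "alpha": 0.9,
    "beta": 0.6,
    "gamma": 0.4,
}

BASE_SHARED_FRACTION = 0.3  # baseline rho for every channel and band
BACKGROUND_WEIGHT = 0.4     # 1/f^beta background amplitude
WHITE_WEIGHT = 0.15         # broadband sensor-noise amplitude
OUTPUT_SCALE_UV = 20.0      # overall microvolt scale


@dataclass(frozen=True)
class CoherenceEffect:
    """Class-dependent boost of the shared-source fraction in one band.

    For MDD subjects the mixing fraction of every listed electrode is raised
    by ``delta``, which raises the band coherence of all pairs among (and
    with) the listed electrodes without changing band power.
    """

    band: str
    electrodes: tuple[str, ...]
    delta: float

    def __post_init__(self) -> None:
        if self.delta < 0:
            raise ValueError("mixing delta must be >= 0")


@dataclass(frozen=True)
class EffectConfig:
    """Class effects of the generator; all default to zero, in which case
    the two class generators are identical in distribution."""

    coherence: tuple[CoherenceEffect, ...] = ()
    band_power_db: tuple[tuple[str, float], ...] = ()  # (band, dB delta)
    background_beta_delta: float = 0.0  # 1/f exponent shift for MDD
    # Relative spread of a per-subject effect-expression multiplier
    # (truncated normal, mean 1, clipped at 0).  Models clinical
    # heterogeneity: not every affected subject expresses the effect equally,
    # so the class overlap is irreducible even for an ideal classifier.
    expression_sd: float = 0.0

    def bp_delta(self, band: str) -> float:
        return dict(self.band_power_db).get(band, 0.0)


@dataclass(frozen=True)
class SiteProfile:
    """Per-site acquisition quirks."""

    site_id: str
    gain_mean: float = 1.0
    gain_log_sd: float = 0.05  # lognormal spread of per-channel gains
    noise_scale: float = 1.0
    line_amp: float = 0.0      # mains interference amplitude (a.u.)
    line_freq: float = 60.0

    def __post_init__(self) -> None:
        if self.gain_mean <= 0:
            raise ValueError("channel gains must be positive")


@dataclass(frozen=True)
class CohortSpec:
    """Cohort layout: per-site class counts and the recording protocol."""

    n_mdd: int
    n_hc: int
    sites: tuple[SiteProfile, ...] = (SiteProfile("site1"),)
    seed: int = 0
    fs: float = 500.0
    duration: float = 90.0
    montage: ChannelMontage = field(default_factory=make_default_montage)
    background_beta: float = 1.0
    subject_rho_sd: float = 0.1  # per-subject global synchronization trait
    subject_prefix: str = "S"   # subject ids are <prefix>0001, <prefix>0002, ...

    def __post_init__(self) -> None:
        if self.n_mdd < 0 or self.n_hc < 0:
            raise ValueError("cohort counts must be >= 0")
        if not self.sites:
            raise ValueError("need at least one site")


def _bandpassed_noise(rng: np.random.Generator, n: int, fs: float,
                      band: tuple[float, float]) -> np.ndarray:
    """Unit-variance band-limited Gaussian noise."""
    low, high = band
    sos = signal.butter(4, [low, min(high, fs / 2 * 0.99)], btype="bandpass",
                        fs=fs, output="sos")
    x = signal.sosfiltfilt(sos, rng.standard_normal(n))
    sd = x.std()
    return x / sd if sd > 0 else x


def _pink_noise(rng: np.random.Generator, n: int, beta: float) -> np.ndarray:
    """Unit-variance 1/f^beta noise via spectral shaping."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=1.0)
    shape = np.ones_like(freqs)
    shape[1:] = freqs[1:] ** (-beta / 2.0)
    shape[0] = 0.0
    x = np.fft.irfft(spec * shape, n=n)
    sd = x.std()
    return x / sd if sd > 0 else x


def simulate_recording(class_label: str, site: SiteProfile, eff: EffectConfig,
                       rng: np.random.Generator,
                       montage: ChannelMontage | None = None,
                       fs: float = 500.0, duration: float = 90.0,
                       subject_id: str = "sim", background_beta: float = 1.0,
                       band_edges: dict | None = None,
                       subject_rho_sd: float = 0.1) -> RawRecording:
    """One synthetic subject.

    The emitted recording contains the montage's analysis electrodes plus
    its reference electrode as a recorded channel (referenced to A2), so the
    standard preprocessing chain (re-reference to Cz, band-pass, segment)
    applies unchanged.
    """
    if montage is None:
        montage = make_default_montage()
    if band_edges is None:
        band_edges = DEFAULT_BAND_EDGES
    n = int(round(fs * duration))
    channels = list(montage.labels) + [montage.reference_label]
    n_ch = len(channels)
    is_mdd = class_label == "MDD"

    # Per-subject effect expression (drawn for every subject so the rng
    # stream is identical across classes; it only scales MDD effects).
    expression = max(0.0, 1.0 + eff.expression_sd * rng.standard_normal())

    coh_boost = {ch: {} for ch in channels}
    if is_mdd:
        for ce in eff.coherence:
            for el in ce.electrodes:
                if el in coh_boost:
                    coh_boost[el][ce.band] = (coh_boost[el].get(ce.band, 0.0)
                                              + ce.delta * expression)

    # Subject-level global synchronization trait: a single draw shifts the
    # shared fraction of every channel and band.  It creates realistic
    # between-subject coherence variability that no single channel pair can
    # disentangle from a class effect on its own.
    rho_trait = subject_rho_sd * rng.standard_normal()

    data = np.zeros((n_ch, n))
    for band, edges in band_edges.items():
        amp = DEFAULT_BAND_AMP.get(band, 0.5)
        if is_mdd:
            amp *= 10.0 ** (eff.bp_delta(band) * expression / 20.0)
        shared = _bandpassed_noise(rng, n, fs, edges)
        for c_i, ch in enumerate(channels):
            # The reference channel carries no shared band source: this keeps
            # a mixing (coherence) effect out of the band powers after
            # re-referencing, since cov(channel, reference) then does not
            # depend on the channel's shared fraction.
            if ch == montage.reference_label:
                rho = 0.0
            else:
                rho = np.clip(BASE_SHARED_FRACTION + rho_trait
                              + coh_boost[ch].get(band, 0.0), 0.0, 0.95)
            private = _bandpassed_noise(rng, n, fs, edges)
            data[c_i] += amp * (np.sqrt(rho) * shared
                                + np.sqrt(1.0 - rho) * private)

    beta = background_beta + (eff.background_beta_delta * expression
                              if is_mdd else 0.0)
    for c_i in range(n_ch):
        data[c_i] += BACKGROUND_WEIGHT * _pink_noise(rng, n, beta)
        data[c_i] += WHITE_WEIGHT * site.noise_scale * rng.standard_normal(n)

    if site.line_amp > 0:
        t = np.arange(n) / fs
        for c_i in range(n_ch):
            phase = rng.uniform(0, 2 * np.pi)
            data[c_i] += site.line_amp * np.sin(2 * np.pi * site.line_freq * t
                                                + phase)

    gains = site.gain_mean * np.exp(site.gain_log_sd * rng.standard_normal(n_ch))
    data *= OUTPUT_SCALE_UV * gains[:, None]

    return RawRecording(
        subject_id=subject_id,
        site_id=site.site_id,
        class_label=class_label,
        fs=fs,
        channel_labels=tuple(channels),
        data=data,
        reference_label="A2",
    )


def simulate_cohort(spec: CohortSpec,
                    eff: EffectConfig = EffectConfig()) -> list[RawRecording]:
    """Independent subjects with subject/site/class labels attached.

    ``spec.n_mdd`` and ``spec.n_hc`` are per-site counts.  The cohort is a
    pure function of the spec seed: the same spec yields bit-identical
    recordings.
    """
    root = np.random.SeedSequence(spec.seed)
    n_subjects = (spec.n_mdd + spec.n_hc) * len(spec.sites)
    children = root.spawn(n_subjects)
    recordings = []
    idx = 0
    for site in spec.sites:
        for class_label, count in (("MDD", spec.n_mdd), ("HC", spec.n_hc)):
            for _ in range(count):
                rng = np.random.default_rng(children[idx])
                rec = simulate_recording(
                    class_label, site, eff, rng,
                    montage=spec.montage, fs=spec.fs, duration=spec.duration,
                    subject_id=f"{spec.subject_prefix}{idx + 1:04d}",
                    background_beta=spec.background_beta,
                    subject_rho_sd=spec.subject_rho_sd,
                )
                recordings.append(rec)
                idx += 1
    return recordings
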