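"""Feature extraction: band powers, coherence, fractal dimensions, assembly.

The coherence and fractal estimators are checked against independent
brute-force oracles (explicit DFT cross-spectra; literal loop transcriptions
of the curve-length and waveform-geometry definitions).
"""

import numpy as np
import pytest

import eegmdd as m
from eegmdd.features import (BandScheme, FeatureDescriptor, higuchi_fd,
                             higuchi_curve_lengths, katz_fd)
from .conftest import make_epochs


# ---------------------------------------------------------------------------
# Independent oracles
# ---------------------------------------------------------------------------

def dft_band_coherence(x, y, fs, band, nperseg, noverlap):
    """Explicit-DFT Welch coherence: no library spectral helper."""
    step = nperseg - noverlap
    starts = range(0, len(x) - nperseg + 1, step)
    n = np.arange(nperseg)
    w = 0.5 - 0.5 * np.cos(2 * np.pi * n / nperseg)  # periodic Hann
    dft = np.exp(-2j * np.pi * np.outer(np.arange(nperseg // 2 + 1), n) / nperseg)
    gxx = gyy = gxy = 0
    for s in starts:
        xs = x[s:s + nperseg] - np.mean(x[s:s + nperseg])
        ys = y[s:s + nperseg] - np.mean(y[s:s + nperseg])
        X = dft @ (w * xs)
        Y = dft @ (w * ys)
        gxx = gxx + np.abs(X) ** 2
        gyy = gyy + np.abs(Y) ** 2
        gxy = gxy + X * np.conj(Y)
    freqs = np.arange(nperseg // 2 + 1) * fs / nperseg
    coh = np.abs(gxy) ** 2 / (gxx * gyy)
    mask = (freqs >= band[0]) & (freqs < band[1])
    return float(np.mean(coh[mask]))


def higuchi_literal(x, kmax):
    """Literal transcription of the subseries curve-length definition."""
    ns = len(x)
    lk = []
    for k in range(1, kmax + 1):
        lmk = []
        for mm in range(1, k + 1):
            n_i = int((ns - mm) / k)
            s = sum(abs(x[mm + i * k - 1] - x[mm + (i - 1) * k - 1])
                    for i in range(1, n_i + 1))
            lmk.append(s * (ns - 1) / (n_i * k) / k)
        lk.append(np.mean(lmk))
    kk = np.arange(1, kmax + 1)
    slope, _ = np.polyfit(np.log(1.0 / kk), np.log(lk), 1)
    return float(slope)


def katz_literal(x):
    unit = sum(abs(x[i + 1] - x[i]) for i in range(len(x) - 1)) / (len(x) - 1)
    x = [v / unit for v in x]
    L = sum(np.sqrt(1.0 + (x[i + 1] - x[i]) ** 2) for i in range(len(x) - 1))
    D = max(np.sqrt(i ** 2 + (x[i] - x[0]) ** 2) for i in range(len(x)))
    A = L / (len(x) - 1)
    return float(np.log(L / A) / (np.log(D / L) + np.log(L / A)))


# ---------------------------------------------------------------------------
# Band scheme / descriptors
# ---------------------------------------------------------------------------

def test_default_band_scheme():
    scheme = BandScheme()
    assert scheme.names == ("delta", "theta", "alpha", "beta", "gamma")
    assert scheme.edges("alpha") == (8.0, 13.0)


def test_overlapping_bands_rejected():
    with pytest.raises(ValueError):
        BandScheme((("a", 2.0, 8.0), ("b", 6.0, 12.0)))


@pytest.mark.parametrize("text", ["BP|beta|Pz", "COH|alpha|F8-FT7",
                                  "HFD|k50|C3", "KFD|F7"])
def test_descriptor_string_round_trip(text):
    assert str(FeatureDescriptor.parse(text)) == text


# ---------------------------------------------------------------------------
# Band power
# ---------------------------------------------------------------------------

class TestBandPower:
    def test_column_count_and_order(self, rng):
        eps = make_epochs(rng.normal(size=(2, 26, 300)), fs=100.0)
        table = m.extract_bp(eps)
        assert table.n_features == 130
        # band-major ordering: first 26 columns are delta
        assert all(d.band == "delta" for d in table.descriptors[:26])

    def test_sinusoid_power_matches_parseval(self):
        fs, amp = 500.0, 3.0
        t = np.arange(3000) / fs
        x = amp * np.sin(2 * np.pi * 10.0 * t)
        from eegmdd.features import epoch_band_powers
        powers = epoch_band_powers(x[None, :], fs, BandScheme())[0]
        names = BandScheme().names
        alpha = powers[names.index("alpha")]
        assert alpha == pytest.approx(amp ** 2 / 2, rel=0.02)
        for i, name in enumerate(names):
            if name != "alpha":
                assert powers[i] < 0.01 * alpha

    def test_gain_of_10_shifts_log_power_by_2(self, rng):
        data = rng.normal(size=(3, 2, 300))
        t1 = m.extract_bp(make_epochs(data, fs=100.0))
        t2 = m.extract_bp(make_epochs(10.0 * data, fs=100.0))
        np.testing.assert_allclose(t2.values - t1.values, 2.0, atol=1e-12)

    def test_zero_channel_rejected(self, rng):
        data = rng.normal(size=(2, 2, 300))
        data[:, 1, :] = 0.0
        with pytest.raises(ValueError, match="ch1"):
            m.extract_bp(make_epochs(data, fs=100.0))


# ---------------------------------------------------------------------------
# Coherence
# ---------------------------------------------------------------------------

class TestBandCoherence:
    def test_identical_signals_fully_coherent(self, rng):
        x = rng.normal(size=3000)
        for band in [(2, 4), (4, 8), (8, 13), (13, 30), (30, 45)]:
            assert m.band_coherence(x, x, 500.0, band) == pytest.approx(1.0, abs=1e-9)

    def test_amplitude_and_sign_invariance(self, rng):
        x = rng.normal(size=3000)
        assert m.band_coherence(x, -2.0 * x, 500.0, (8, 13)) == pytest.approx(1.0, abs=1e-9)

    def test_independent_noise_bias_is_small(self, rng):
        # 11 Welch segments -> coherence bias ~ 1/11 per bin
        vals = [m.band_coherence(rng.normal(size=3000), rng.normal(size=3000),
                                 500.0, (8, 13)) for _ in range(30)]
        assert np.mean(vals) < 0.2

    def test_matches_explicit_dft_oracle(self, rng):
        fs, nseg, nov = 64.0, 64, 32
        for _ in range(5):
            x = rng.normal(size=128)
            y = 0.6 * x + rng.normal(size=128)
            for band in [(2.0, 8.0), (8.0, 13.0), (13.0, 30.0)]:
                ours = m.band_coherence(x, y, fs, band, nperseg=nseg, noverlap=nov)
                ref = dft_band_coherence(x, y, fs, band, nseg, nov)
                assert ours == pytest.approx(ref, abs=1e-6)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="zero-variance"):
            m.band_coherence(np.zeros(300), np.ones(300), 100.0, (8, 13))

    def test_symmetry_and_affine_invariance(self, rng):
        x = rng.normal(size=1500)
        y = 0.5 * x + rng.normal(size=1500)
        a = m.band_coherence(x, y, 250.0, (8, 13))
        b = m.band_coherence(y, x, 250.0, (8, 13))
        c = m.band_coherence(3.7 * x, -0.2 * y, 250.0, (8, 13))
        assert a == pytest.approx(b, abs=1e-12)
        assert a == pytest.approx(c, abs=1e-9)


class TestExtractCoherence:
    def test_column_count_26_channels(self, rng):
        eps = make_epochs(rng.normal(size=(1, 26, 300)), fs=100.0)
        table = m.extract_coherence(eps)
        assert table.n_features == 1625

    def test_duplicated_channel_pair_fully_coherent(self, rng):
        x = rng.normal(size=(1, 1, 500))
        data = np.concatenate([x, x, rng.normal(size=(1, 1, 500))], axis=1)
        table = m.extract_coherence(make_epochs(data, fs=100.0))
        pair01 = [i for i, d in enumerate(table.descriptors)
                  if set(d.electrodes) == {"ch0", "ch1"}]
        np.testing.assert_allclose(table.values[0, pair01], 1.0, atol=1e-9)

    def test_values_bounded_in_unit_interval(self, tiny_cohort):
        _, table = tiny_cohort
        coh = table.values[:, table.columns_of_kind("COH")]
        assert coh.min() >= 0.0 and coh.max() <= 1.0

    def test_spectra_averaging_mode_differs_but_bounded(self, rng):
        eps = make_epochs(rng.normal(size=(3, 3, 500)), fs=100.0)
        t1 = m.extract_coherence(eps, average="coherence")
        t2 = m.extract_coherence(eps, average="spectra")
        assert t2.values.min() >= 0 and t2.values.max() <= 1
        assert not np.allclose(t1.values, t2.values)


# ---------------------------------------------------------------------------
# Fractal dimensions
# ---------------------------------------------------------------------------

class TestHiguchi:
    def test_ramp_has_unit_dimension(self):
        assert higuchi_fd(np.arange(1.0, 3001.0), 50) == pytest.approx(1.0, abs=0.05)

    def test_white_noise_approaches_two(self, rng):
        vals = [higuchi_fd(rng.standard_normal(3000), 50) for _ in range(100)]
        assert np.mean(vals) == pytest.approx(2.0, abs=0.1)

    @pytest.mark.parametrize("signal", [
        np.sin(2 * np.pi * 7 * np.arange(1500) / 500),
        np.cumsum(np.random.default_rng(0).standard_normal(1500)),
        np.random.default_rng(1).standard_normal(1500),
    ], ids=["sine", "random-walk", "white-noise"])
    def test_estimates_stay_near_theoretical_range(self, signal):
        assert 0.9 <= higuchi_fd(signal, 50) <= 2.1

    def test_matches_literal_transcription(self, rng):
        for _ in range(5):
            x = rng.normal(size=100)
            assert higuchi_fd(x, 8) == pytest.approx(higuchi_literal(x, 8), abs=1e-9)

    def test_constant_signal_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            higuchi_fd(np.ones(100), 8)

    def test_prefix_lengths_are_shared(self, rng):
        x = rng.normal(size=500)
        full = higuchi_curve_lengths(x, 60)
        np.testing.assert_allclose(full[:20], higuchi_curve_lengths(x, 20))


class TestKatz:
    def test_any_straight_ramp_is_one(self):
        for slope in (0.1, 1.0, -42.0):
            assert katz_fd(slope * np.arange(200.0)) == pytest.approx(1.0, abs=1e-9)

    def test_white_noise_between_one_and_two(self, rng):
        vals = [katz_fd(rng.standard_normal(3000)) for _ in range(100)]
        assert 1.0 < np.mean(vals) <= 2.0

    def test_sine_between_ramp_and_noise(self, rng):
        n = 3000
        ramp = katz_fd(np.linspace(-1, 1, n))
        sine = katz_fd(np.sin(2 * np.pi * 10 * np.arange(n) / 500))
        noise = np.mean([katz_fd(rng.standard_normal(n)) for _ in range(20)])
        assert ramp < sine < noise

    def test_matches_literal_transcription(self, rng):
        for _ in range(5):
            x = rng.normal(size=100)
            assert katz_fd(x) == pytest.approx(katz_literal(x), abs=1e-9)

    def test_constant_signal_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            katz_fd(np.zeros(50))


class TestFDBlocks:
    def test_hfd_column_counts(self, rng):
        eps = make_epochs(rng.normal(size=(2, 26, 300)), fs=100.0)
        assert m.extract_hfd(eps, kmax_list=(50, 100, 150)).n_features == 78
        eps5 = make_epochs(rng.normal(size=(2, 5, 300)), fs=100.0)
        assert m.extract_hfd(eps5, kmax_list=(50,)).n_features == 5

    def test_kfd_column_counts(self, rng):
        eps = make_epochs(rng.normal(size=(2, 26, 300)), fs=100.0)
        assert m.extract_kfd(eps).n_features == 26
        assert m.extract_kfd(make_epochs(rng.normal(size=(1, 3, 300)))).n_features == 3

    def test_identical_epochs_mean_equals_single_epoch(self, rng):
        one = rng.normal(size=(1, 4, 400))
        three = np.repeat(one, 3, axis=0)
        for extract in (m.extract_kfd, lambda e: m.extract_hfd(e, (30,))):
            np.testing.assert_allclose(extract(make_epochs(three)).values,
                                       extract(make_epochs(one)).values)

    def test_epoch_order_permutation_invariance(self, rng):
        data = rng.normal(size=(4, 3, 500))
        perm = data[[2, 0, 3, 1]]
        a = m.extract_all(make_epochs(data, fs=100.0))
        b = m.extract_all(make_epochs(perm, fs=100.0))
        np.testing.assert_allclose(a.values, b.values, atol=1e-12)


# ---------------------------------------------------------------------------
# Assembly and normalization
# ---------------------------------------------------------------------------

class TestAssemble:
    def test_canonical_order_and_partition(self, tiny_cohort):
        _, table = tiny_cohort
        kinds = [d.kind for d in table.descriptors]
        nb, nc = kinds.count("BP"), kinds.count("COH")
        nh, nk = kinds.count("HFD"), kinds.count("KFD")
        assert (nb, nc, nh, nk) == (30, 75, 18, 6)
        assert kinds == ["BP"] * nb + ["COH"] * nc + ["HFD"] * nh + ["KFD"] * nk

    def test_block_order_is_canonicalized(self, rng):
        eps = make_epochs(rng.normal(size=(1, 3, 500)), fs=100.0)
        bp, coh = m.extract_bp(eps), m.extract_coherence(eps)
        hfd, kfd = m.extract_hfd(eps, (30,)), m.extract_kfd(eps)
        a = m.assemble(bp, coh, hfd, kfd)
        b = m.assemble(kfd, hfd, coh, bp)
        assert [str(d) for d in a.descriptors] == [str(d) for d in b.descriptors]
        np.testing.assert_array_equal(a.values, b.values)

    def test_subject_mismatch_rejected(self, rng):
        e1 = make_epochs(rng.normal(size=(1, 2, 400)), subject_id="a")
        e2 = make_epochs(rng.normal(size=(1, 2, 400)), subject_id="b")
        with pytest.raises(ValueError, match="subjects"):
            m.assemble(m.extract_bp(e1), m.extract_kfd(e2))


class TestCARNormalization:
    def test_per_band_mean_is_zero(self, tiny_cohort):
        _, table = tiny_cohort
        out = m.car_normalize_bp(table)
        for band in ("delta", "theta", "alpha", "beta", "gamma"):
            cols = [i for i, d in enumerate(out.descriptors)
                    if d.kind == "BP" and d.band == band]
            np.testing.assert_allclose(out.values[:, cols].mean(axis=1), 0.0,
                                       atol=1e-12)

    def test_common_mode_invariance_and_contrast_preservation(self, tiny_cohort):
        _, table = tiny_cohort
        shifted = table.select(range(table.n_features))
        alpha_cols = [i for i, d in enumerate(table.descriptors)
                      if d.kind == "BP" and d.band == "alpha"]
        shifted.values[:, alpha_cols] += 3.3  # same offset on all channels
        a = m.car_normalize_bp(table)
        b = m.car_normalize_bp(shifted)
        np.testing.assert_allclose(a.values, b.values, atol=1e-12)
        # within-band channel differences preserved exactly
        d0 = table.values[:, alpha_cols[0]] - table.values[:, alpha_cols[1]]
        d1 = a.values[:, alpha_cols[0]] - a.values[:, alpha_cols[1]]
        np.testing.assert_allclose(d0, d1, atol=1e-12)

    def test_non_bp_columns_untouched(self, tiny_cohort):
        _, table = tiny_cohort
        out = m.car_normalize_bp(table)
        other = [i for i, d in enumerate(table.descriptors) if d.kind != "BP"]
        np.testing.assert_array_equal(out.values[:, other],
                                      table.values[:, other])
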