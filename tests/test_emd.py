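"""Sifting correctness, completeness, and the behaviour of the ensemble variants."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from emgfatigue.emd import (
    DecompConfigError,
    DecompParams,
    DegenerateSignalError,
    decompose,
    emd,
    ensemble_emd,
    find_extrema,
    iceemdan,
    local_mean,
    sift,
)

FS = 1000.0


def two_tone(n=4000, f_low=5.0, f_high=50.0, amp_high=0.5):
    t = np.arange(n) / FS
    return (
        np.sin(2 * np.pi * f_low * t) + amp_high * np.sin(2 * np.pi * f_high * t),
        np.sin(2 * np.pi * f_low * t),
        amp_high * np.sin(2 * np.pi * f_high * t),
    )


def corr(a, b):
    return abs(np.corrcoef(a, b)[0, 1])


def mean_freq(x):
    spec = np.abs(np.fft.rfft(x)) ** 2
    freqs = np.fft.rfftfreq(len(x), 1 / FS)
    return np.sum(freqs * spec) / np.sum(spec)


class TestFindExtrema:
    def test_sinusoid_counts(self):
        t = np.linspace(0, 4, 4000, endpoint=False)
        maxima, minima = find_extrema(np.sin(2 * np.pi * t))
        assert maxima.size == 4 and minima.size == 4

    def test_monotone_ramp_has_none(self):
        maxima, minima = find_extrema(np.linspace(0, 1, 100))
        assert maxima.size == 0 and minima.size == 0

    def test_plateau_resolved_to_floor_midpoint(self):
        maxima, minima = find_extrema(np.array([0.0, 1.0, 1.0, 0.0]))
        assert list(maxima) == [1] and minima.size == 0
        maxima, _ = find_extrema(np.array([0.0, 1.0, 1.0, 1.0, 0.0]))
        assert list(maxima) == [2]


class TestLocalMean:
    def test_sinusoid_mean_near_zero(self):
        t = np.linspace(0, 20, 8000, endpoint=False)
        m = local_mean(np.sin(2 * np.pi * t))
        assert np.max(np.abs(m)) < 0.01

    def test_offset_recovered(self):
        t = np.linspace(0, 20, 8000, endpoint=False)
        m = local_mean(np.sin(2 * np.pi * t) + 0.7)
        assert np.max(np.abs(m - 0.7)) < 0.02

    def test_ramp_is_degenerate(self):
        with pytest.raises(DegenerateSignalError):
            local_mean(np.linspace(0, 1, 50))


class TestSift:
    def test_pure_sinusoid_is_fixed_point(self):
        t = np.linspace(0, 20, 8000, endpoint=False)
        x = np.sin(2 * np.pi * t)
        out = sift(x)
        assert np.sqrt(np.mean((out - x) ** 2)) < 0.01

    def test_imf_property_extrema_vs_zero_crossings(self):
        rng = np.random.default_rng(5)
        x = rng.standard_normal(2000)
        imf = sift(x)
        maxima, minima = find_extrema(imf)
        zc = np.sum(np.diff(np.signbit(imf)) != 0)
        assert abs((maxima.size + minima.size) - zc) <= 1

    def test_extracts_fast_tone_first(self):
        x, _, high = two_tone()
        assert corr(sift(x), high) > 0.95


class TestEMD:
    def test_completeness(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal(3000)
        dec = emd(x)
        err = np.linalg.norm(x - dec.reconstruct()) / np.linalg.norm(x)
        assert err < 1e-10

    def test_monotone_input_yields_no_imfs(self):
        x = np.linspace(0, 1, 500)
        dec = emd(x)
        assert dec.n_imfs == 0
        np.testing.assert_array_equal(dec.residual, x)

    def test_two_tone_separation(self):
        x, low, high = two_tone()
        dec = emd(x)
        assert dec.n_imfs >= 2
        assert corr(dec.imfs[0], high) > 0.95
        assert corr(dec.imfs[1], low) > 0.95

    @settings(max_examples=10, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_completeness_property(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(300, 1500))
        x = np.cumsum(rng.standard_normal(n)) + rng.standard_normal(n)
        dec = emd(x)
        assert np.linalg.norm(x - dec.reconstruct()) <= 1e-10 * np.linalg.norm(x)

    def test_spectral_ordering_of_modes(self):
        rng = np.random.default_rng(2)
        x = rng.standard_normal(4000)
        dec = emd(x)
        freqs = [mean_freq(c) for c in dec.imfs]
        inversions = sum(f2 > f1 for f1, f2 in zip(freqs, freqs[1:]))
        assert inversions <= 1


class TestEnsembleVariants:
    def test_zero_noise_degenerates_to_emd(self):
        x, _, _ = two_tone(n=1500)
        plain = emd(x)
        for variant in ("EEMD", "CEEMD", "CEEMDAN"):
            dec = ensemble_emd(x, DecompParams(variant=variant, ensemble_size=5, noise_strength=0.0))
            assert dec.n_imfs == plain.n_imfs
            for a, b in zip(dec.imfs, plain.imfs):
                np.testing.assert_allclose(a, b, atol=1e-12)

    def test_seeded_determinism(self):
        x, _, _ = two_tone(n=1000)
        p = DecompParams(variant="EEMD", ensemble_size=8, seed=4)
        a, b = ensemble_emd(x, p), ensemble_emd(x, p)
        for ca, cb in zip(a.imfs, b.imfs):
            assert np.array_equal(ca, cb)

    def test_eemd_reconstruction_error_shrinks_with_ensemble(self):
        t = np.arange(600) / FS
        x = np.sin(2 * np.pi * 5 * t) + 0.5 * np.sin(2 * np.pi * 60 * t)
        wins = 0
        for seed in range(20):
            small = ensemble_emd(x, DecompParams(variant="EEMD", ensemble_size=10, seed=seed))
            large = ensemble_emd(x, DecompParams(variant="EEMD", ensemble_size=100, seed=seed))
            err = lambda d: np.linalg.norm(x - d.reconstruct())
            wins += err(large) < err(small)
        assert wins >= 15

    def test_variant_validation(self):
        with pytest.raises(DecompConfigError):
            DecompParams(variant="WAVELET")
        with pytest.raises(DecompConfigError):
            ensemble_emd(np.zeros(10), DecompParams(variant="ICEEMDAN"))


class TestICEEMDAN:
    def test_completeness_any_noise(self):
        rng = np.random.default_rng(3)
        x = rng.standard_normal(1200)
        for eps in (0.0, 0.2, 0.5):
            dec = iceemdan(x, DecompParams(ensemble_size=10, noise_strength=eps, seed=0))
            err = np.linalg.norm(x - dec.reconstruct()) / np.linalg.norm(x)
            assert err < 1e-10

    def test_seeded_determinism(self):
        x = np.random.default_rng(0).standard_normal(800)
        p = DecompParams(ensemble_size=8, seed=11)
        a, b = iceemdan(x, p), iceemdan(x, p)
        assert a.n_imfs == b.n_imfs
        for ca, cb in zip(a.imfs, b.imfs):
            assert np.array_equal(ca, cb)

    def test_resolves_mode_mixing_better_than_emd(self):
        """Tone + intermittent bursts: the classic mode-mixing stimulus."""
        t = np.arange(2000) / FS
        tone = np.sin(2 * np.pi * 6 * t)
        wins = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            burst = np.zeros_like(t)
            for c in rng.uniform(0.1, 1.9, 6):
                mask = np.abs(t - c) < 0.03
                burst[mask] += 0.3 * np.sin(2 * np.pi * 150 * (t[mask] - c))
            x = tone + burst

            def tone_corr(dec):
                return max((corr(c, tone) for c in dec.imfs), default=0.0)

            c_emd = tone_corr(emd(x))
            c_ice = tone_corr(iceemdan(x, DecompParams(ensemble_size=30, seed=seed)))
            wins += c_ice >= c_emd
        assert wins >= 8

    def test_dispatch(self):
        x = np.random.default_rng(1).standard_normal(600)
        assert decompose(x, DecompParams(variant="EMD")).method == "EMD"
        assert decompose(x, DecompParams(variant="ICEEMDAN", ensemble_size=5)).method == "ICEEMDAN"
        assert decompose(x, DecompParams(variant="CEEMD", ensemble_size=5)).method == "CEEMD"
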