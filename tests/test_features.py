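"""Feature extraction oracles: time, frequency, time-frequency, nonlinear."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.signal import chirp
from scipy.stats import ttest_ind

from conftest import clean_config, fgn, sampen_bruteforce
from emgfatigue.emd import DecompParams, emd
from emgfatigue.features import (
    Spectrum,
    UndefinedEntropyError,
    WindowConfig,
    extract_feature_table,
    instantaneous_frequencies,
    hurst_exponent,
    mean_frequency,
    median_frequency,
    power_spectrum,
    read_feature_table,
    sample_entropy,
    time_domain_features,
    write_feature_table,
)
from emgfatigue.synthetic import generate_dataset, generate_trial

FS = 1000.0


class TestTimeDomain:
    def test_known_values(self):
        mav, var, rms = time_domain_features([1.0, -2.0, 3.0])
        assert mav == pytest.approx(2.0)
        assert var == pytest.approx(np.mean((np.array([1, -2, 3]) - 2 / 3) ** 2))
        assert rms == pytest.approx(np.sqrt(14 / 3))

    def test_constant_window(self):
        mav, var, rms = time_domain_features(np.full(10, -3.0))
        assert (mav, var, rms) == (3.0, 0.0, 3.0)

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(a=st.floats(-10, 10, allow_nan=False), seed=st.integers(0, 50))
    def test_scale_equivariance(self, a, seed):
        x = np.random.default_rng(seed).standard_normal(64)
        mav, var, rms = time_domain_features(x)
        mav2, var2, rms2 = time_domain_features(a * x)
        assert mav2 == pytest.approx(abs(a) * mav, abs=1e-12)
        assert var2 == pytest.approx(a * a * var, rel=1e-9, abs=1e-12)
        assert rms2 == pytest.approx(abs(a) * rms, abs=1e-12)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            time_domain_features([])


class TestSpectra:
    def test_tone_power_concentrated(self):
        t = np.arange(1024) / FS
        f0 = 125.0  # exactly on a 256-point bin
        spec = power_spectrum(np.sin(2 * np.pi * f0 * t), FS)
        peak = np.argmax(spec.powers)
        assert spec.freqs[peak] == pytest.approx(f0, abs=spec.freqs[1])
        near = np.abs(spec.freqs - f0) <= 2 * spec.freqs[1]
        assert spec.powers[near].sum() >= 0.99 * spec.powers.sum()

    def test_zero_window_zero_spectrum(self):
        spec = power_spectrum(np.zeros(512), FS)
        assert np.all(spec.powers == 0)

    def test_parseval_for_broadband_noise(self):
        rng = np.random.default_rng(0)
        ratios = []
        for _ in range(20):
            x = rng.standard_normal(1000)
            spec = power_spectrum(x, FS)
            df = spec.freqs[1] - spec.freqs[0]
            ratios.append(spec.powers.sum() * df / x.var())
        assert 0.9 < np.mean(ratios) < 1.1

    def test_mean_frequency_oracles(self):
        t = np.arange(2048) / FS
        spec = power_spectrum(np.sin(2 * np.pi * 100 * t), FS)
        df = spec.freqs[1]
        assert mean_frequency(spec) == pytest.approx(100, abs=df)
        two = power_spectrum(
            np.sin(2 * np.pi * 50 * t) + np.sin(2 * np.pi * 150 * t), FS
        )
        assert mean_frequency(two) == pytest.approx(100, abs=df)
        flat = Spectrum(freqs=np.linspace(1, 200, 200), powers=np.ones(200))
        assert mean_frequency(flat) == pytest.approx(100.5)

    def test_median_frequency_oracles(self):
        t = np.arange(2048) / FS
        spec = power_spectrum(np.sin(2 * np.pi * 100 * t), FS)
        df = spec.freqs[1]
        assert median_frequency(spec) == pytest.approx(100, abs=df)
        flat = Spectrum(freqs=np.linspace(1, 200, 200), powers=np.ones(200))
        assert median_frequency(flat) == pytest.approx(100.5, abs=1.0)
        cum = np.cumsum(spec.powers)
        f_med = median_frequency(spec)
        frac = np.interp(f_med, spec.freqs, cum) / cum[-1]
        assert 0.5 - 1e-9 <= frac <= 0.5 + spec.powers.max() / cum[-1]

    def test_zero_power_rejected(self):
        spec = Spectrum(freqs=np.array([1.0, 2.0]), powers=np.zeros(2))
        with pytest.raises(ValueError):
            mean_frequency(spec)
        with pytest.raises(ValueError):
            median_frequency(spec)


class TestInstantaneousFrequencies:
    def test_stationary_tone_constant_series(self):
        t = np.arange(2000) / FS
        res = instantaneous_frequencies(np.sin(2 * np.pi * 100 * t), FS)
        df = FS / 256
        assert np.all(np.abs(res.imdf_series - 100) < 2 * df)
        assert np.all(np.abs(res.imnf_series - 100) < df)
        assert abs(res.imdf_slope) < 2.0 and abs(res.imnf_slope) < 2.0

    def test_chirp_tracked(self):
        t = np.arange(2000) / FS
        res = instantaneous_frequencies(chirp(t, 50, 2.0, 150), FS)
        assert res.imdf_series[0] == pytest.approx(50, abs=10)
        assert res.imdf_series[-1] == pytest.approx(150, abs=10)
        assert np.all(np.diff(res.imdf_series) > -1e-9)
        assert res.imdf_slope > 0

    def test_fatigue_trial_has_negative_mdf_slope(self):
        cfg = clean_config(duration=10.0)
        n_neg = 0
        n_seeds = 40
        for seed in range(n_seeds):
            x = generate_trial(cfg, seed=seed).samples
            res = instantaneous_frequencies(x, cfg.fs)
            n_neg += res.imnf_slope < 0
        assert n_neg >= 0.95 * n_seeds

    def test_too_short_window_rejected(self):
        with pytest.raises(ValueError):
            instantaneous_frequencies(np.ones(300), FS)


class TestSampleEntropy:
    def test_constant_series_zero(self):
        assert sample_entropy(np.full(50, 2.0), m=2, r=0.1) == 0.0

    def test_alternating_series_zero(self):
        x = np.tile([1.0, 2.0], 30)
        assert sample_entropy(x, m=2, r=0.1) == 0.0

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_bruteforce_oracle(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.standard_normal(200)
        r = 0.2 * x.std()
        assert sample_entropy(x, 2, r) == pytest.approx(sampen_bruteforce(x, 2, r), abs=1e-12)

    def test_white_noise_reference_value(self):
        rng = np.random.default_rng(42)
        vals = [sample_entropy(rng.standard_normal(1000)) for _ in range(50)]
        assert np.mean(vals) == pytest.approx(2.2, abs=0.3)

    def test_sine_more_regular_than_its_permutation(self):
        t = np.arange(1000) / FS
        x = np.sin(2 * np.pi * 10 * t)
        r = 0.2 * x.std()
        for seed in range(20):
            perm = np.random.default_rng(seed).permutation(x)
            assert sample_entropy(x, 2, r) < sample_entropy(perm, 2, r)

    def test_undefined_entropy_flagged(self):
        x = np.arange(30.0)  # monotone: no m+1 template repeats at tiny r
        with pytest.raises(UndefinedEntropyError):
            sample_entropy(x, 2, 1e-9)


class TestHurst:
    def test_white_noise_half(self):
        rng = np.random.default_rng(7)
        vals = [hurst_exponent(rng.standard_normal(4096)) for _ in range(50)]
        assert np.mean(vals) == pytest.approx(0.5, abs=0.1)

    def test_persistent_fgn_recovered(self):
        rng = np.random.default_rng(8)
        vals = [hurst_exponent(fgn(4096, 0.8, rng)) for _ in range(50)]
        assert np.mean(vals) == pytest.approx(0.8, abs=0.1)

    def test_constant_and_short_series_rejected(self):
        with pytest.raises(ValueError):
            hurst_exponent(np.full(1000, 1.0))
        with pytest.raises(ValueError):
            hurst_exponent(np.random.default_rng(0).standard_normal(100))


class TestFeatureTable:
    def brute_force_window_count(self, n, window_len, step, spans):
        count = 0
        for start in range(0, n - window_len + 1, step):
            for s, e, _ in spans:
                if s <= start and start + window_len <= e:
                    count += 1
        return count

    def test_window_count_matches_enumerator(self):
        cfg = clean_config(duration=60.0, label_fraction=1 / 3)
        record = generate_trial(cfg, seed=0)
        wcfg = WindowConfig()
        table = extract_feature_table([record], wcfg)
        expected = self.brute_force_window_count(
            record.n_samples, wcfg.window_len, wcfg.step, record.label_windows
        )
        assert len(table) == expected
        assert set(table["source"]) == {"raw"}

    def test_rows_finite_with_defaults(self):
        cfg = clean_config(duration=10.0)
        record = generate_trial(cfg, seed=1)
        table = extract_feature_table([record])
        feature_cols = ["MAV", "VAR", "RMS", "MF", "MPF", "IMNF_mean", "IMDF_mean", "SampEn", "H"]
        assert np.isfinite(table[feature_cols].to_numpy(float)).all()

    def test_row_count_with_imfs(self):
        cfg = clean_config(duration=6.0)
        record = generate_trial(cfg, seed=2)
        dec = emd(record.samples, DecompParams(variant="EMD"))
        table = extract_feature_table([record], imf_sets={record.key: dec}, k_keep=5)
        per_window = table.groupby("window").size()
        assert (per_window == 6).all()  # raw + 5 IMFs

    def test_fatigue_group_separation(self):
        """Difficult windows: lower MF/MPF, higher RMS/MAV (one-sided, p<0.01)."""
        cfg = clean_config(n_subjects=1, n_trials=10, n_channels=1, duration=30.0)
        table = extract_feature_table(generate_dataset(cfg))
        easy = table[table.label == "easy"]
        hard = table[table.label == "difficult"]
        for col in ("MF", "MPF"):
            p = ttest_ind(easy[col], hard[col], equal_var=False, alternative="greater").pvalue
            assert p < 0.01, col
        for col in ("RMS", "MAV"):
            p = ttest_ind(easy[col], hard[col], equal_var=False, alternative="less").pvalue
            assert p < 0.01, col

    def test_roundtrip_csv(self, tmp_path):
        record = generate_trial(clean_config(duration=4.0), seed=3)
        table = extract_feature_table([record])
        path = tmp_path / "features.csv"
        write_feature_table(table, path)
        back = read_feature_table(path)
        assert list(back.columns) == list(table.columns)
        np.testing.assert_allclose(
            back["MPF"].to_numpy(), table["MPF"].to_numpy(), rtol=1e-8
        )

    def test_mixed_sampling_rates_rejected(self):
        a = generate_trial(clean_config(duration=2.0), seed=0)
        b = generate_trial(clean_config(duration=2.0, fs=2000.0), seed=0)
        with pytest.raises(ValueError):
            extract_feature_table([a, b])

    def test_window_longer_than_record_rejected(self):
        record = generate_trial(clean_config(duration=0.5), seed=0)
        with pytest.raises(ValueError):
            extract_feature_table([record], WindowConfig())
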