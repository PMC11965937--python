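"""Shared oracles and fixtures.

The helpers here are deliberately independent of the implementation
paths they check: spectral medians come from a plain Welch periodogram,
sample entropy from a triple-loop template count, fractional Gaussian
noise from circulant-embedding spectral synthesis, and trend detection
from an all-pairs (Mann-Kendall) sign statistic.
"""

from __future__ import annotations

import math

import numpy as np
import pytest
from scipy.signal import welch
from scipy.stats import norm

from emgfatigue.synthetic import SynthConfig, generate_dataset
from emgfatigue.preprocess import preprocess_record


def welch_mdf(x: np.ndarray, fs: float, nperseg: int = 512) -> float:
    """Half-power median frequency from an averaged periodogram."""
    nperseg = min(nperseg, len(x))
    freqs, powers = welch(x, fs, nperseg=nperseg, noverlap=nperseg // 2)
    cum = np.cumsum(powers)
    return float(np.interp(0.5 * cum[-1], cum, freqs))


def windowed_rms(x: np.ndarray, window: int) -> np.ndarray:
    n = (len(x) // window) * window
    return np.sqrt(np.mean(x[:n].reshape(-1, window) ** 2, axis=1))


def mann_kendall_p(values: np.ndarray, alternative: str) -> float:
    """All-pairs sign-test p-value for a monotone trend (normal approximation)."""
    v = np.asarray(values, dtype=float)
    n = v.size
    s = sum(np.sign(v[j] - v[i]) for i in range(n) for j in range(i + 1, n))
    var = n * (n - 1) * (2 * n + 5) / 18.0
    z = (s - np.sign(s)) / math.sqrt(var)
    return float(norm.cdf(z)) if alternative == "less" else float(1 - norm.cdf(z))


def sampen_bruteforce(x: np.ndarray, m: int, r: float) -> float:
    """Triple-loop sample entropy; the reference for the vectorised path."""
    n = len(x)
    nt = n - m

    def count(length: int) -> int:
        c = 0
        for i in range(nt):
            for j in range(i + 1, nt):
                if max(abs(x[i + k] - x[j + k]) for k in range(length)) <= r:
                    c += 1
        return c

    b = count(m)
    a = count(m + 1)
    return -math.log(a / b)


def fgn(n: int, hurst: float, rng: np.random.Generator) -> np.ndarray:
    """Fractional Gaussian noise by circulant-embedding spectral synthesis."""
    g = np.arange(n + 1)
    r = 0.5 * (np.abs(g - 1) ** (2 * hurst) - 2 * g ** (2 * hurst) + (g + 1) ** (2 * hurst))
    row = np.concatenate([r, r[-2:0:-1]])
    lam = np.fft.fft(row).real
    lam[lam < 0] = 0
    m = len(row)
    w = rng.standard_normal(m) + 1j * rng.standard_normal(m)
    return np.fft.fft(np.sqrt(lam) * w / np.sqrt(2 * m)).real[:n]


def clean_config(**overrides) -> SynthConfig:
    """Generator config with all measurement artifacts switched off."""
    defaults = dict(powerline_amp=0.0, drift_amp=0.0, sensor_noise_sd=0.0)
    defaults.update(overrides)
    return SynthConfig(**defaults)


@pytest.fixture(scope="session")
def small_dataset():
    """4 subjects x 2 trials x 1 channel, 20 s, artifacts on, preprocessed."""
    config = SynthConfig(n_subjects=4, n_trials=2, n_channels=1, duration=20.0, master_seed=0)
    return [preprocess_record(r) for r in generate_dataset(config)]
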