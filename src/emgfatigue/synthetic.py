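"""Synthetic fatiguing isometric-contraction surface-EMG generator.

Surface EMG during a sustained isometric contraction is well approximated by
band-limited Gaussian noise whose spectrum compresses toward lower
frequencies and whose amplitude grows as the muscle fatigues.  The
generator emulates exactly that, with controllable ground truth:

* a *carrier*: white Gaussian noise shaped frame-by-frame by a 4th-order
  Butterworth band-pass magnitude response whose centre is steered so that
  the instantaneous median frequency tracks a prescribed trajectory
  (linear ``mdf_start`` → ``mdf_end`` over the trial);
* an amplitude gain ramping linearly from 1 to ``rms_gain_end``
  (the carrier is normalised to unit initial RMS, so all artifact
  amplitudes below are in units of the initial signal RMS);
* measurement artifacts: 50 Hz powerline interference, a slow sinusoidal
  baseline drift, and broadband sensor noise;
* binary perceived-fatigue labels: the earliest ``label_fraction`` of each
  trial is labelled ``"easy"``, the latest ``label_fraction`` is
  ``"difficult"``, and the middle is left unlabelled.

Everything is reproducible bit-exactly from ``master_seed``; per-record
streams are derived from the seed and the (subject, trial, channel) keys.
No motor-unit physiology is modelled — the point is a testable ground
truth for the downstream decomposition/feature/classification stages.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, replace

import numpy as np
from scipy.signal import get_window

from emgfatigue.records import EMGRecord

_FRAME_LEN = 256  # shaping-filter frame, samples
_HOP = _FRAME_LEN // 2


class InvalidConfigError(ValueError):
    """A configuration violates its invariants."""


@dataclass(frozen=True)
class SynthConfig:
    """Study-design and signal-model parameters for the generator.

    Defaults correspond to the emulated study: 10 subjects x 10 trials x
    3 quadriceps channels at 1000 Hz, wall squats held ~60 s, median
    frequency declining 90 -> 60 Hz while RMS grows by a factor 1.8.
    """

    n_subjects: int = 10
    n_trials: int = 10
    n_channels: int = 3
    duration: float = 60.0          # s
    fs: float = 1000.0              # Hz
    mdf_start: float = 90.0         # Hz, target median frequency at trial start
    mdf_end: float = 60.0           # Hz, at trial end
    rms_gain_end: float = 1.8       # multiple of initial RMS at trial end
    bandwidth: float = 60.0         # Hz, shaping-filter width
    powerline_amp: float = 0.1      # units of initial RMS
    drift_amp: float = 0.5          # units of initial RMS
    drift_freq: float = 0.3         # Hz
    sensor_noise_sd: float = 0.2    # units of initial RMS
    subject_jitter: float = 0.1     # +-fractional jitter on mdf endpoints and gain
    label_fraction: float = 1.0 / 3.0
    master_seed: int = 0

    def __post_init__(self) -> None:
        if self.duration <= 0 or self.fs <= 0:
            raise InvalidConfigError("duration and fs must be positive")
        if not (0 < self.mdf_end <= self.mdf_start):
            raise InvalidConfigError("require 0 < mdf_end <= mdf_start")
        if self.fs <= 2 * (self.mdf_start + self.bandwidth):
            raise InvalidConfigError(
                "fs must exceed 2*(mdf_start + bandwidth) so the shaper respects Nyquist"
            )
        if self.rms_gain_end < 1:
            raise InvalidConfigError("rms_gain_end must be >= 1")
        if not (0 < self.label_fraction <= 0.5):
            raise InvalidConfigError("label_fraction must lie in (0, 0.5]")
        for name in ("n_subjects", "n_trials", "n_channels"):
            if getattr(self, name) < 1:
                raise InvalidConfigError(f"{name} must be >= 1")
        if min(self.powerline_amp, self.drift_amp, self.sensor_noise_sd) < 0:
            raise InvalidConfigError("artifact amplitudes must be non-negative")

    @property
    def n_samples(self) -> int:
        return int(round(self.duration * self.fs))


def make_fatigue_trajectory(config: SynthConfig) -> tuple[np.ndarray, np.ndarray]:
    """Per-sample fatigue trajectory.

    Returns
    -------
    target_mdf : ndarray
        Target median frequency, linear from ``mdf_start`` to ``mdf_end``.
    target_gain : ndarray
        Amplitude gain, linear from 1 to ``rms_gain_end``.
    """
    n = config.n_samples
    target_mdf = np.linspace(config.mdf_start, config.mdf_end, n)
    target_gain = np.linspace(1.0, config.rms_gain_end, n)
    return target_mdf, target_gain


def _butter_bp_mag2(freqs: np.ndarray, center: np.ndarray, bandwidth: float) -> np.ndarray:
    """|H|^2 of a 4-pole Butterworth band-pass, vectorised over frame centres.

    ``freqs``: (n_bins,), ``center``: (n_frames, 1) -> (n_frames, n_bins).
    """
    f1 = np.maximum(center - bandwidth / 2.0, 1e-6)
    f2 = center + bandwidth / 2.0
    w0sq = f1 * f2
    b = f2 - f1
    f = np.maximum(freqs, 1e-9)
    x = (f**2 - w0sq) / (f * b)
    return 1.0 / (1.0 + x**8)


def _centered_response(
    freqs: np.ndarray, target_mdf: np.ndarray, bandwidth: float
) -> np.ndarray:
    """Per-frame |H|^2 whose spectral median equals ``target_mdf``.

    The Butterworth band's median sits slightly above its nominal centre,
    so the centre is steered by a few fixed-point iterations
    ``c <- c - (median(c) - target)`` (the offset varies slowly with c,
    so this converges to well under the spectral bin width).
    """
    target = target_mdf[:, None]
    center = target.copy()
    for _ in range(3):
        h2 = _butter_bp_mag2(freqs, center, bandwidth)
        cum = np.cumsum(h2, axis=1)
        cum /= cum[:, -1:]
        med = np.array(
            [np.interp(0.5, cum[i], freqs) for i in range(cum.shape[0])]
        )[:, None]
        center = center - (med - target)
    return _butter_bp_mag2(freqs, center, bandwidth)


def _shaped_carrier(rng: np.random.Generator, config: SynthConfig) -> np.ndarray:
    """Nonstationary band-limited Gaussian carrier with unit global RMS start.

    Weighted overlap-add: sqrt-Hann analysis/synthesis windows at 50%
    overlap (their product tiles to one), each frame's spectrum multiplied
    by the frame's centred band-pass magnitude.
    """
    n = config.n_samples
    pad = _FRAME_LEN
    noise = rng.standard_normal(n + 2 * pad)
    win = np.sqrt(get_window("hann", _FRAME_LEN, fftbins=True))
    freqs = np.fft.rfftfreq(_FRAME_LEN, d=1.0 / config.fs)

    starts = np.arange(0, noise.size - _FRAME_LEN + 1, _HOP)
    target_mdf, _ = make_fatigue_trajectory(config)
    # frame centre time mapped into the (clipped) trajectory
    centers = np.clip(starts + _FRAME_LEN // 2 - pad, 0, n - 1)
    h2 = _centered_response(freqs, target_mdf[centers], config.bandwidth)
    gain = np.sqrt(h2)

    out = np.zeros(noise.size)
    frames = np.lib.stride_tricks.sliding_window_view(noise, _FRAME_LEN)[::_HOP]
    spec = np.fft.rfft(frames * win, axis=1) * gain
    shaped = np.fft.irfft(spec, n=_FRAME_LEN, axis=1) * win
    for k, s in enumerate(starts):
        out[s : s + _FRAME_LEN] += shaped[k]
    carrier = out[pad : pad + n]
    rms0 = np.sqrt(np.mean(carrier[: max(int(2 * config.fs), 1)] ** 2))
    return carrier / rms0


def _label_windows(n: int, label_fraction: float) -> list[tuple[int, int, str]]:
    k = int(round(label_fraction * n))
    k = min(k, n // 2)
    if k == 0:
        return []
    return [(0, k, "easy"), (n - k, n, "difficult")]


def _record_rng(config: SynthConfig, subject_id: int, trial_id: int, channel_id: int) -> np.random.Generator:
    seq = np.random.SeedSequence(
        entropy=config.master_seed, spawn_key=(subject_id, trial_id, channel_id)
    )
    return np.random.default_rng(seq)


def generate_trial(
    config: SynthConfig,
    subject_id: int = 0,
    trial_id: int = 0,
    channel_id: int = 0,
    seed: int | np.random.SeedSequence | None = None,
) -> EMGRecord:
    """Generate one channel-trial.

    ``seed`` overrides the stream otherwise derived deterministically from
    ``config.master_seed`` and the identity keys; identical inputs give
    bit-identical samples.
    """
    if seed is None:
        rng = _record_rng(config, subject_id, trial_id, channel_id)
    else:
        rng = np.random.default_rng(seed)

    n = config.n_samples
    t = np.arange(n) / config.fs
    _, target_gain = make_fatigue_trajectory(config)

    signal = _shaped_carrier(rng, config) * target_gain
    if config.powerline_amp > 0:
        signal = signal + config.powerline_amp * np.sin(
            2 * np.pi * 50.0 * t + rng.uniform(0, 2 * np.pi)
        )
    if config.drift_amp > 0:
        signal = signal + config.drift_amp * np.sin(
            2 * np.pi * config.drift_freq * t + rng.uniform(0, 2 * np.pi)
        )
    if config.sensor_noise_sd > 0:
        signal = signal + rng.normal(0.0, config.sensor_noise_sd, n)

    return EMGRecord(
        samples=signal,
        fs=config.fs,
        subject_id=subject_id,
        trial_id=trial_id,
        channel_id=channel_id,
        label_windows=_label_windows(n, config.label_fraction),
        meta={
            "mdf_start": config.mdf_start,
            "mdf_end": config.mdf_end,
            "rms_gain_end": config.rms_gain_end,
        },
    )


def _jittered(config: SynthConfig, factors: np.ndarray) -> SynthConfig:
    """Subject-specific config: multiplicative jitter on mdf endpoints and gain."""
    m_start = config.mdf_start * factors[0]
    m_end = min(config.mdf_end * factors[1], m_start)
    return replace(
        config,
        mdf_start=m_start,
        mdf_end=m_end,
        rms_gain_end=max(config.rms_gain_end * factors[2], 1.0),
    )


def generate_dataset(config: SynthConfig) -> list[EMGRecord]:
    """Generate the full subject x trial x channel dataset.

    Exactly ``n_subjects * n_trials * n_channels`` records.  Each subject
    gets its own multiplicative jitter (drawn from the master seed) on the
    median-frequency endpoints and the gain, so subjects differ; record
    noise streams are independent of the jitter draws.
    """
    jitter_rng = np.random.default_rng(
        np.random.SeedSequence(entropy=config.master_seed, spawn_key=(2**31,))
    )
    records: list[EMGRecord] = []
    for subject in range(config.n_subjects):
        factors = 1.0 + jitter_rng.uniform(
            -config.subject_jitter, config.subject_jitter, size=3
        )
        subj_config = _jittered(config, factors)
        for trial, channel in itertools.product(
            range(config.n_trials), range(config.n_channels)
        ):
            records.append(
                generate_trial(
                    subj_config,
                    subject_id=subject,
                    trial_id=trial,
                    channel_id=channel,
                    seed=np.random.SeedSequence(
                        entropy=config.master_seed, spawn_key=(subject, trial, channel)
                    ),
                )
            )
    return records
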