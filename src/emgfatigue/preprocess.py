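"""Surface-EMG conditioning: band-pass, powerline notch, baseline removal.

Standard sEMG practice at fs = 1000 Hz: a 4th-order Butterworth band-pass
(20–450 Hz) removes motion artifact and out-of-band noise, an IIR notch
(Q = 30) suppresses 50 Hz mains interference, and mean subtraction centres
the signal.  Both filters are applied zero-phase (forward–backward with
reflective padding) by default so feature timing is preserved; mean
subtraction runs last so the output mean is exactly zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from emgfatigue.records import EMGRecord


class FilterConfigError(ValueError):
    """Filter parameters incompatible with the sampling rate."""


@dataclass(frozen=True)
class PreprocessConfig:
    band_low: float = 20.0     # Hz
    band_high: float = 450.0   # Hz
    filter_order: int = 4
    notch_freq: float = 50.0   # Hz
    notch_q: float = 30.0
    zero_phase: bool = True

    def validate(self, fs: float) -> None:
        if not (0 < self.band_low < self.band_high < fs / 2):
            raise FilterConfigError(
                f"band edges ({self.band_low}, {self.band_high}) must satisfy "
                f"0 < low < high < fs/2 = {fs / 2}"
            )
        if not (0 < self.notch_freq < fs / 2):
            raise FilterConfigError("notch_freq must lie in (0, fs/2)")
        if self.filter_order < 1 or self.notch_q <= 0:
            raise FilterConfigError("filter_order and notch_q must be positive")


def _apply(b: np.ndarray, a: np.ndarray, x: np.ndarray, order: int, zero_phase: bool) -> np.ndarray:
    if zero_phase:
        padlen = min(3 * max(len(a), len(b), order + 1), x.size - 1)
        return sps.filtfilt(b, a, x, padtype="even", padlen=padlen)
    return sps.lfilter(b, a, x)


def bandpass_filter(samples: np.ndarray, fs: float, config: PreprocessConfig = PreprocessConfig()) -> np.ndarray:
    """Butterworth band-pass; zero-phase when ``config.zero_phase``."""
    config.validate(fs)
    x = np.asarray(samples, dtype=float)
    sos = sps.butter(
        config.filter_order,
        [config.band_low, config.band_high],
        btype="bandpass",
        fs=fs,
        output="sos",
    )
    if config.zero_phase:
        padlen = min(9 * config.filter_order, x.size - 1)
        return sps.sosfiltfilt(sos, x, padtype="even", padlen=padlen)
    return sps.sosfilt(sos, x)


def notch_filter(samples: np.ndarray, fs: float, config: PreprocessConfig = PreprocessConfig()) -> np.ndarray:
    """IIR notch at ``config.notch_freq`` (mains interference)."""
    config.validate(fs)
    x = np.asarray(samples, dtype=float)
    b, a = sps.iirnotch(config.notch_freq, config.notch_q, fs=fs)
    return _apply(b, a, x, 2, config.zero_phase)


def remove_baseline(samples: np.ndarray) -> np.ndarray:
    """Centre the signal by subtracting its mean."""
    x = np.asarray(samples, dtype=float)
    if x.size == 0:
        raise ValueError("cannot remove baseline of an empty signal")
    return x - x.mean()


def preprocess_record(record: EMGRecord, config: PreprocessConfig = PreprocessConfig()) -> EMGRecord:
    """Band-pass → notch → mean subtraction; keys and labels pass through."""
    x = bandpass_filter(record.samples, record.fs, config)
    x = notch_filter(x, record.fs, config)
    x = remove_baseline(x)
    return replace_samples(record, x)


def replace_samples(record: EMGRecord, samples: np.ndarray) -> EMGRecord:
    return EMGRecord(
        samples=samples,
        fs=record.fs,
        subject_id=record.subject_id,
        trial_id=record.trial_id,
        channel_id=record.channel_id,
        label_windows=list(record.label_windows),
        meta=dict(record.meta),
    )
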