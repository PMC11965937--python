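"""Windowed fatigue features across four domains.

Nine features per analysis window, computed on the raw (preprocessed)
signal and on each retained IMF:

=========  ==================================================================
MAV        mean absolute value, ``(1/N) sum |x_i|``
VAR        population variance, ``(1/N) sum (x_i - mean)^2``
RMS        root mean square, ``sqrt((1/N) sum x_i^2)``
MF         mean frequency of the Welch spectrum, ``sum f_i P_i / sum P_i``
MPF        median frequency: the half-total-power point of the spectrum
IMDF_mean  time-average of the framewise *mean* frequency (STFT)
IMNF_mean  time-average of the framewise *median* frequency (STFT)
SampEn     sample entropy (m = 2, r = 0.2 * SD by default), in nats
H          Hurst exponent by corrected rescaled-range (R/S) analysis
=========  ==================================================================

Naming note: IMDF here denotes the *instantaneous mean frequency* and
IMNF the *instantaneous median frequency*.  Part of the sEMG literature
uses the two acronyms with exactly the opposite assignment; this package
keeps the assignment above consistently everywhere, so check the
definitions rather than the acronyms when comparing against other tools.

During fatiguing isometric contraction the spectral features (MF, MPF,
and both instantaneous series) drift downward while the amplitude
features (MAV, RMS) grow — the discriminative signal the classifiers use.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view
from scipy import signal as sps
from scipy.special import gammaln

from emgfatigue.emd import IMFSet
from emgfatigue.records import EMGRecord

FEATURE_COLUMNS = ["MAV", "VAR", "RMS", "MF", "MPF", "IMNF_mean", "IMDF_mean", "SampEn", "H"]
KEY_COLUMNS = ["subject_id", "trial_id", "channel_id", "window", "source"]
TABLE_COLUMNS = KEY_COLUMNS + FEATURE_COLUMNS + ["label"]


class UndefinedEntropyError(ValueError):
    """No template matches at length m or m+1; SampEn is undefined."""


@dataclass(frozen=True)
class WindowConfig:
    window_len: int = 1000        # samples (1 s at 1000 Hz)
    overlap: float = 0.5          # fraction of window_len
    welch_segment: int = 256
    welch_overlap: int = 128
    stft_window: int = 256
    stft_hop: int = 64
    sampen_m: int = 2
    sampen_r_factor: float = 0.2  # r = factor * SD(window)
    hurst_min_scale: int = 16
    hurst_n_scales: int = 10

    def __post_init__(self) -> None:
        if not (0 <= self.overlap < 1):
            raise ValueError("overlap must lie in [0, 1)")
        if self.welch_segment > self.window_len:
            raise ValueError("welch_segment must not exceed window_len")
        if self.sampen_m < 1:
            raise ValueError("sampen_m must be >= 1")

    @property
    def step(self) -> int:
        return max(int(round(self.window_len * (1 - self.overlap))), 1)


@dataclass
class Spectrum:
    freqs: np.ndarray   # Hz, strictly increasing
    powers: np.ndarray  # power density, >= 0

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=float)
        self.powers = np.asarray(self.powers, dtype=float)
        if np.any(np.diff(self.freqs) <= 0):
            raise ValueError("frequencies must be strictly increasing")
        if np.any(self.powers < -1e-12):
            raise ValueError("powers must be non-negative")

    @property
    def total_power(self) -> float:
        return float(np.sum(self.powers))


# ------------------------------------------------------------- time domain

def time_domain_features(window: np.ndarray) -> tuple[float, float, float]:
    """(MAV, VAR, RMS) of one window."""
    x = np.asarray(window, dtype=float)
    if x.size == 0:
        raise ValueError("empty window")
    mav = float(np.mean(np.abs(x)))
    var = float(np.mean((x - x.mean()) ** 2))
    rms = float(np.sqrt(np.mean(x**2)))
    return mav, var, rms


# -------------------------------------------------------- frequency domain

def power_spectrum(window: np.ndarray, fs: float, config: WindowConfig = WindowConfig()) -> Spectrum:
    """Welch-averaged power spectral density (Hann taper, mean-detrended)."""
    x = np.asarray(window, dtype=float)
    if x.size < config.welch_segment:
        raise ValueError(
            f"window of {x.size} samples shorter than welch_segment={config.welch_segment}"
        )
    freqs, powers = sps.welch(
        x,
        fs=fs,
        window="hann",
        nperseg=config.welch_segment,
        noverlap=config.welch_overlap,
        detrend="constant",
        scaling="density",
    )
    return Spectrum(freqs=freqs, powers=powers)


def mean_frequency(spectrum: Spectrum) -> float:
    """Power-weighted mean frequency, ``sum f P / sum P``."""
    total = spectrum.total_power
    if total <= 0:
        raise ValueError("zero total power")
    return float(np.sum(spectrum.freqs * spectrum.powers) / total)


def median_frequency(spectrum: Spectrum) -> float:
    """Half-total-power frequency, linearly interpolated between bins."""
    total = spectrum.total_power
    if total <= 0:
        raise ValueError("zero total power")
    cum = np.cumsum(spectrum.powers)
    return float(np.interp(0.5 * total, cum, spectrum.freqs))


# --------------------------------------------------- time-frequency domain

@dataclass
class InstantaneousFrequencies:
    """Framewise mean (IMDF) and median (IMNF) frequency series with summaries."""

    times: np.ndarray        # frame centres, s
    imdf_series: np.ndarray  # framewise mean frequency, Hz
    imnf_series: np.ndarray  # framewise median frequency, Hz
    imdf_mean: float
    imnf_mean: float
    imdf_slope: float        # Hz/s, least squares
    imnf_slope: float


def _frame_spectra(x: np.ndarray, fs: float, frame_len: int, hop: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Hann-tapered periodogram of every full frame; no edge padding."""
    frames = sliding_window_view(x, frame_len)[::hop]
    win = sps.get_window("hann", frame_len)
    spec = np.abs(np.fft.rfft(frames * win, axis=1)) ** 2
    freqs = np.fft.rfftfreq(frame_len, d=1.0 / fs)
    starts = np.arange(frames.shape[0]) * hop
    times = (starts + frame_len / 2) / fs
    return times, freqs, spec


def instantaneous_frequencies(
    window: np.ndarray, fs: float, config: WindowConfig = WindowConfig()
) -> InstantaneousFrequencies:
    """Short-time evolution of the spectral centre (see module naming note)."""
    x = np.asarray(window, dtype=float)
    n_frames = (x.size - config.stft_window) // config.stft_hop + 1
    if x.size < config.stft_window or n_frames < 4:
        raise ValueError("window too short for at least 4 STFT frames")
    times, freqs, spec = _frame_spectra(x, fs, config.stft_window, config.stft_hop)
    totals = spec.sum(axis=1)
    if np.any(totals <= 0):
        raise ValueError("zero-power frame")
    imdf = (spec @ freqs) / totals
    cum = np.cumsum(spec, axis=1)
    imnf = np.array(
        [np.interp(0.5 * totals[i], cum[i], freqs) for i in range(spec.shape[0])]
    )
    slope_mean = float(np.polyfit(times, imdf, 1)[0])
    slope_med = float(np.polyfit(times, imnf, 1)[0])
    return InstantaneousFrequencies(
        times=times,
        imdf_series=imdf,
        imnf_series=imnf,
        imdf_mean=float(imdf.mean()),
        imnf_mean=float(imnf.mean()),
        imdf_slope=slope_mean,
        imnf_slope=slope_med,
    )


# ---------------------------------------------------------------- nonlinear

def sample_entropy(series: np.ndarray, m: int = 2, r: float | None = None) -> float:
    """Sample entropy ``-ln(A/B)`` with self-matches excluded.

    ``B`` counts template pairs of length ``m`` within Chebyshev distance
    ``r``; ``A`` the same at length ``m+1``.  ``r`` defaults to
    ``0.2 * SD(series)``.  Raises :class:`UndefinedEntropyError` when
    either count is zero (entropy undefined, not zero).
    """
    x = np.asarray(series, dtype=float)
    if x.size <= m + 1:
        raise ValueError("series too short for the template length")
    if r is None:
        r = 0.2 * float(np.std(x))
    if r < 0:
        raise ValueError("r must be non-negative")

    n_templates = x.size - m  # same count at both lengths

    # Chebyshev distances of length-m templates, built dimension by
    # dimension; the length-(m+1) distances reuse them (shared prefix).
    d = np.zeros((n_templates, n_templates))
    for j in range(m):
        np.maximum(d, np.abs(x[j : j + n_templates, None] - x[None, j : j + n_templates]), out=d)
    b = int(((d <= r).sum() - n_templates) // 2)  # self-matches excluded
    np.maximum(d, np.abs(x[m : m + n_templates, None] - x[None, m : m + n_templates]), out=d)
    a = int(((d <= r).sum() - n_templates) // 2)
    if b == 0 or a == 0:
        raise UndefinedEntropyError(f"no template matches (A={a}, B={b})")
    return float(-math.log(a / b))


def _expected_rs(scale: int) -> float:
    """Anis–Lloyd–Peters expected R/S of white noise at a given block size."""
    s = scale
    i = np.arange(1, s)
    total = float(np.sum(np.sqrt((s - i) / i)))
    if s <= 340:
        front = math.exp(gammaln((s - 1) / 2) - gammaln(s / 2)) / math.sqrt(math.pi)
    else:
        front = 1.0 / math.sqrt(s * math.pi / 2)
    return (s - 0.5) / s * front * total


def hurst_exponent(series: np.ndarray, config: WindowConfig = WindowConfig()) -> float:
    """Hurst exponent by rescaled-range analysis with small-sample correction.

    For log-spaced block sizes the R/S statistic is averaged over
    non-overlapping blocks; the estimate is ``0.5`` plus the least-squares
    slope of ``log(R/S) - log(E[R/S | H=0.5])`` against ``log(scale)``,
    which removes the well-known upward small-sample bias of raw R/S.
    """
    x = np.asarray(series, dtype=float)
    if x.size < 256:
        raise ValueError("need at least 256 samples for R/S analysis")
    if np.ptp(x) == 0:
        raise ValueError("constant series has no rescaled range")
    scales = np.unique(
        np.round(
            np.geomspace(config.hurst_min_scale, x.size // 4, config.hurst_n_scales)
        ).astype(int)
    )
    log_s, log_rs = [], []
    for s in scales:
        n_blocks = x.size // s
        blocks = x[: n_blocks * s].reshape(n_blocks, s)
        dev = blocks - blocks.mean(axis=1, keepdims=True)
        walk = np.cumsum(dev, axis=1)
        rng = walk.max(axis=1) - walk.min(axis=1)
        sd = blocks.std(axis=1)
        ok = sd > 0
        if not np.any(ok):
            continue
        rs = float(np.mean(rng[ok] / sd[ok]))
        log_s.append(math.log(s))
        log_rs.append(math.log(rs) - math.log(_expected_rs(int(s))))
    if len(log_s) < 3:
        raise ValueError("too few usable scales for a slope")
    slope = float(np.polyfit(log_s, log_rs, 1)[0])
    return 0.5 + slope


# ------------------------------------------------------------ feature table

def iter_labeled_windows(record: EMGRecord, config: WindowConfig):
    """Yield ``(window_index, start, label)`` for windows fully inside a span."""
    idx = 0
    for start in range(0, record.n_samples - config.window_len + 1, config.step):
        end = start + config.window_len
        label = None
        for s, e, lab in record.label_windows:
            if s <= start and end <= e:
                label = lab
                break
        if label is not None:
            yield idx, start, label
        idx += 1


def _window_features(x: np.ndarray, fs: float, config: WindowConfig) -> dict:
    mav, var, rms = time_domain_features(x)
    out = {"MAV": mav, "VAR": var, "RMS": rms}
    try:
        spec = power_spectrum(x, fs, config)
        out["MF"] = mean_frequency(spec)
        out["MPF"] = median_frequency(spec)
    except ValueError:
        out["MF"] = out["MPF"] = np.nan
    try:
        inst = instantaneous_frequencies(x, fs, config)
        out["IMDF_mean"] = inst.imdf_mean
        out["IMNF_mean"] = inst.imnf_mean
    except ValueError:
        out["IMDF_mean"] = out["IMNF_mean"] = np.nan
    try:
        out["SampEn"] = sample_entropy(x, config.sampen_m, config.sampen_r_factor * float(np.std(x)))
    except (UndefinedEntropyError, ValueError):
        out["SampEn"] = np.nan
    try:
        out["H"] = hurst_exponent(x, config)
    except ValueError:
        out["H"] = np.nan
    return out


def extract_feature_table(
    records: list[EMGRecord],
    config: WindowConfig = WindowConfig(),
    imf_sets: dict[tuple[int, int, int], IMFSet] | None = None,
    k_keep: int | None = None,
) -> pd.DataFrame:
    """One row per (record, labelled window, source component).

    Sources are the raw record plus, when ``imf_sets`` provides a
    decomposition for the record's key, its first ``k_keep`` IMFs.
    Undefined features (e.g. sample entropy with no template matches)
    appear as NaN so the affected row stays visible rather than silently
    zeroed.
    """
    fs_values = {r.fs for r in records}
    if len(fs_values) > 1:
        raise ValueError(f"records mix sampling rates: {sorted(fs_values)}")
    rows = []
    for record in records:
        if record.n_samples < config.window_len:
            raise ValueError("window longer than record")
        sources: list[tuple[str, np.ndarray]] = [("raw", record.samples)]
        if imf_sets is not None and record.key in imf_sets:
            dec = imf_sets[record.key]
            k = dec.n_imfs if k_keep is None else min(k_keep, dec.n_imfs)
            sources += [(f"imf{i + 1}", dec.imfs[i]) for i in range(k)]
        for widx, start, label in iter_labeled_windows(record, config):
            for source, samples in sources:
                window = samples[start : start + config.window_len]
                row = {
                    "subject_id": record.subject_id,
                    "trial_id": record.trial_id,
                    "channel_id": record.channel_id,
                    "window": widx,
                    "source": source,
                    **_window_features(window, record.fs, config),
                    "label": label,
                }
                rows.append(row)
    return pd.DataFrame(rows, columns=TABLE_COLUMNS)


def write_feature_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index=False, float_format="%.10g")


def read_feature_table(path) -> pd.DataFrame:
    table = pd.read_csv(path)
    missing = [c for c in TABLE_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"feature table missing columns: {missing}")
    return table[TABLE_COLUMNS]
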