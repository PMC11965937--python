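"""Empirical mode decomposition and its noise-assisted ensemble variants.

EMD sifts a signal into intrinsic mode functions (IMFs): oscillatory
components whose extrema and zero-crossing counts differ by at most one
and whose spline-envelope local mean is near zero.  Plain EMD suffers
from mode mixing — one IMF carrying widely different scales — which the
ensemble variants mitigate by perturbing the signal with controlled
white noise:

* **EEMD**   — average the EMD modes of ``N`` noisy copies ``x + eps*sd(x)*w_i``.
* **CEEMD**  — the same with complementary ``+w_i`` / ``-w_i`` noise pairs,
  cancelling most residual noise in the average.
* **CEEMDAN** — stagewise: at stage k the k-th EMD mode of each stored noise
  realization is added to the running residual before extracting and
  averaging the next mode; reconstruction is exact by telescoping.
* **ICEEMDAN** — like CEEMDAN but each stage averages *local means* rather
  than modes: stage 1 computes ``r1 = <M(x + b0*E1(w_i))>`` and
  ``c1 = x - r1``; stage k computes ``r_k = <M(r_{k-1} + b_{k-1}*E_k(w_i))>``
  and ``c_k = r_{k-1} - r_k``, with ``b0 = eps*sd(x)/sd(E1(w_i))`` and
  ``b_k = eps*sd(r_k)`` thereafter.  ``M(y) = y - first_imf(y)`` is the
  local-mean operator realised by one full sifting, and ``E_k(w)`` is the
  k-th EMD mode of the stored white-noise realization.  This variant
  leaves almost no residual noise in the modes and reconstructs exactly.

Numerical conventions: natural cubic splines through the extrema, with
each envelope extended by mirroring two extrema beyond both ends;
sifting stops on the Cauchy criterion ``SD < sd_stop`` (default 0.2) or
after ``max_sift_iter`` passes; decomposition stops when the residual
has fewer than three extrema or ``max_imfs`` (default 13) is reached.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline

VARIANTS = ("EMD", "EEMD", "CEEMD", "CEEMDAN", "ICEEMDAN")


class DegenerateSignalError(ValueError):
    """Too few extrema to build envelopes (monotone or constant signal)."""


class DecompConfigError(ValueError):
    pass


@dataclass(frozen=True)
class DecompParams:
    """Decomposition controls shared by the whole EMD family."""

    variant: str = "ICEEMDAN"
    max_imfs: int = 13
    max_sift_iter: int = 100
    sd_stop: float = 0.2          # Cauchy stopping threshold
    ensemble_size: int = 100      # N noisy realizations
    noise_strength: float = 0.2   # eps, fraction of signal SD
    seed: int = 0

    def __post_init__(self) -> None:
        if self.variant not in VARIANTS:
            raise DecompConfigError(f"variant must be one of {VARIANTS}")
        if self.max_imfs < 1 or self.ensemble_size < 1:
            raise DecompConfigError("max_imfs and ensemble_size must be >= 1")
        if self.noise_strength < 0 or self.sd_stop <= 0 or self.max_sift_iter < 1:
            raise DecompConfigError("invalid stopping/noise parameters")


@dataclass
class IMFSet:
    """Ordered IMFs plus the final residual for one record."""

    imfs: list[np.ndarray]
    residual: np.ndarray
    method: str
    params: DecompParams
    meta: dict = field(default_factory=dict)

    @property
    def n_imfs(self) -> int:
        return len(self.imfs)

    def reconstruct(self) -> np.ndarray:
        out = self.residual.copy()
        for c in self.imfs:
            out += c
        return out

    def to_frame(self, fs: float | None = None) -> pd.DataFrame:
        data = {}
        if fs is not None:
            data["time_s"] = np.arange(self.residual.size) / fs
        for k, c in enumerate(self.imfs, start=1):
            data[f"imf{k}"] = c
        data["residual"] = self.residual
        return pd.DataFrame(data)

    def write_csv(self, path: str | Path, fs: float | None = None) -> Path:
        path = Path(path)
        self.to_frame(fs).to_csv(path, index=False, float_format="%.10g")
        return path


# ---------------------------------------------------------------- extrema

def find_extrema(samples: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Indices of strict local maxima and minima.

    Plateaus (runs of equal values) count once, at the floor-midpoint of
    the run.  Endpoints are never extrema.
    """
    x = np.asarray(samples, dtype=float)
    if x.size < 3:
        return np.array([], dtype=int), np.array([], dtype=int)
    d = np.diff(x)
    keep = np.concatenate(([True], d != 0))
    run_starts = np.flatnonzero(keep)
    v = x[run_starts]
    if v.size < 3:
        return np.array([], dtype=int), np.array([], dtype=int)
    run_ends = np.append(run_starts[1:] - 1, x.size - 1)
    dv = np.sign(np.diff(v))
    turns = dv[:-1] * dv[1:]  # < 0 at a turning run (index into v[1:-1])
    inner = np.flatnonzero(turns < 0) + 1
    mid = (run_starts[inner] + run_ends[inner]) // 2
    is_max = dv[inner - 1] > 0
    return mid[is_max], mid[~is_max]


def _extend_knots(idx: np.ndarray, vals: np.ndarray, n: int) -> tuple[np.ndarray, np.ndarray]:
    """Mirror up to two extrema beyond each end (envelope end-swing cure)."""
    k = min(2, idx.size)
    left_i = (-idx[:k])[::-1]
    left_v = vals[:k][::-1]
    right_i = (2 * (n - 1) - idx[-k:])[::-1]
    right_v = vals[-k:][::-1]
    xi = np.concatenate([left_i, idx, right_i]).astype(float)
    yi = np.concatenate([left_v, vals, right_v])
    xi, keep = np.unique(xi, return_index=True)
    return xi, yi[keep]


def local_mean(samples: np.ndarray) -> np.ndarray:
    """Mean of the upper and lower natural-cubic-spline envelopes."""
    x = np.asarray(samples, dtype=float)
    maxima, minima = find_extrema(x)
    if maxima.size < 2 or minima.size < 2:
        raise DegenerateSignalError(
            f"need >= 2 maxima and minima, got {maxima.size}/{minima.size}"
        )
    t = np.arange(x.size)
    ti, vi = _extend_knots(maxima, x[maxima], x.size)
    upper = CubicSpline(ti, vi, bc_type="natural")(t)
    ti, vi = _extend_knots(minima, x[minima], x.size)
    lower = CubicSpline(ti, vi, bc_type="natural")(t)
    return (upper + lower) / 2.0


# ---------------------------------------------------------------- sifting

def _imf_property_holds(x: np.ndarray) -> bool:
    maxima, minima = find_extrema(x)
    zero_crossings = int(np.sum(np.diff(np.signbit(x)) != 0))
    return abs((maxima.size + minima.size) - zero_crossings) <= 1


def sift(samples: np.ndarray, params: DecompParams = DecompParams()) -> np.ndarray:
    """Extract one IMF: iterate ``h <- h - M(h)`` until the Cauchy criterion.

    Stops once ``SD = sum((h_prev - h)^2) / sum(h_prev^2) < sd_stop`` *and*
    the extrema/zero-crossing IMF property holds, or after
    ``max_sift_iter`` passes.
    """
    h = np.asarray(samples, dtype=float).copy()
    m = local_mean(h)  # degenerate input propagates from the first pass
    for _ in range(params.max_sift_iter):
        h_new = h - m
        denom = float(np.sum(h**2))
        sd = float(np.sum(m**2)) / denom if denom > 0 else 0.0
        h = h_new
        if sd < params.sd_stop and _imf_property_holds(h):
            break
        try:
            m = local_mean(h)
        except DegenerateSignalError:
            break
    return h


def _is_degenerate(x: np.ndarray) -> bool:
    maxima, minima = find_extrema(x)
    return maxima.size + minima.size < 3


def emd(samples: np.ndarray, params: DecompParams = DecompParams(variant="EMD")) -> IMFSet:
    """Plain EMD: sift the running residual until it is degenerate.

    Reconstruction ``sum(imfs) + residual == x`` is exact by telescoping.
    """
    x = np.asarray(samples, dtype=float)
    if x.size == 0:
        raise ValueError("empty signal")
    residual = x.copy()
    imfs: list[np.ndarray] = []
    while len(imfs) < params.max_imfs and not _is_degenerate(residual):
        try:
            c = sift(residual, params)
        except DegenerateSignalError:
            break
        imfs.append(c)
        residual = residual - c
    return IMFSet(imfs=imfs, residual=residual, method="EMD", params=params)


def _first_imf(x: np.ndarray, params: DecompParams) -> np.ndarray | None:
    if _is_degenerate(x):
        return None
    try:
        return sift(x, params)
    except DegenerateSignalError:
        return None


def _local_mean_op(x: np.ndarray, params: DecompParams) -> np.ndarray:
    """M(y) = y - first_imf(y); a degenerate y is its own local mean."""
    c = _first_imf(x, params)
    return x if c is None else x - c


def _noise_bank(n: int, params: DecompParams) -> np.ndarray:
    rng = np.random.default_rng(np.random.SeedSequence(params.seed))
    return rng.standard_normal((params.ensemble_size, n))


def _noise_modes(noise: np.ndarray, params: DecompParams) -> list[list[np.ndarray]]:
    """Full EMD modes of each stored noise realization (for E_k(w_i))."""
    return [emd(w, params).imfs for w in noise]


def _pad_stack(mode_lists: list[list[np.ndarray]], n: int) -> np.ndarray:
    k_max = max((len(m) for m in mode_lists), default=0)
    out = np.zeros((len(mode_lists), k_max, n))
    for i, modes in enumerate(mode_lists):
        for k, c in enumerate(modes):
            out[i, k] = c
    return out


def ensemble_emd(samples: np.ndarray, params: DecompParams) -> IMFSet:
    """EEMD / CEEMD / CEEMDAN noise-assisted decomposition (see module docs)."""
    if params.variant not in ("EEMD", "CEEMD", "CEEMDAN"):
        raise DecompConfigError(f"ensemble_emd got variant {params.variant!r}")
    x = np.asarray(samples, dtype=float)
    n = x.size
    eps = params.noise_strength
    noise = _noise_bank(n, params)
    sd_x = float(np.std(x))

    if params.variant in ("EEMD", "CEEMD"):
        realizations = [x + eps * sd_x * w for w in noise]
        if params.variant == "CEEMD":
            realizations += [x - eps * sd_x * w for w in noise]
        decs = [emd(r, params) for r in realizations]
        modes = _pad_stack([d.imfs for d in decs], n)
        # the residual averages the per-realization residuals, so the
        # reconstruction error is the leftover ensemble noise (~eps/sqrt(N))
        residual = np.mean([d.residual for d in decs], axis=0)
        if modes.shape[1] == 0:
            return IMFSet(imfs=[], residual=residual, method=params.variant, params=params)
        avg = modes.mean(axis=0)
        imfs = [avg[k] for k in range(avg.shape[0])]
        return IMFSet(imfs=imfs, residual=residual, method=params.variant, params=params)

    # CEEMDAN: stagewise with the k-th noise mode injected at stage k
    noise_modes = _noise_modes(noise, params)
    imfs = []
    first = [
        _first_imf(x + (eps * sd_x * nm[0] if nm else 0.0), params)
        for nm in noise_modes
    ]
    stack = [c for c in first if c is not None]
    if not stack:
        return IMFSet(imfs=[], residual=x.copy(), method="CEEMDAN", params=params)
    c1 = np.mean(stack, axis=0)
    imfs.append(c1)
    residual = x - c1
    while len(imfs) < params.max_imfs and not _is_degenerate(residual):
        k = len(imfs)
        beta = eps * float(np.std(residual))
        stage = []
        for nm in noise_modes:
            pert = residual + beta * nm[k] if len(nm) > k else residual
            c = _first_imf(pert, params)
            if c is not None:
                stage.append(c)
        if not stage:
            break
        ck = np.mean(stage, axis=0)
        imfs.append(ck)
        residual = residual - ck
    return IMFSet(imfs=imfs, residual=residual, method="CEEMDAN", params=params)


def iceemdan(samples: np.ndarray, params: DecompParams = DecompParams()) -> IMFSet:
    """Improved CEEMDAN: stagewise averaging of local means (see module docs)."""
    x = np.asarray(samples, dtype=float)
    n = x.size
    eps = params.noise_strength
    noise = _noise_bank(n, params)
    noise_modes = _noise_modes(noise, params)

    # stage 1: r1 = <M(x + b0 E1(w_i))>, c1 = x - r1
    means = []
    for nm in noise_modes:
        if eps > 0 and nm:
            e1 = nm[0]
            b0 = eps * float(np.std(x)) / max(float(np.std(e1)), 1e-300)
            means.append(_local_mean_op(x + b0 * e1, params))
        else:
            means.append(_local_mean_op(x, params))
    residual = np.mean(means, axis=0)
    imfs = [x - residual]

    while len(imfs) < params.max_imfs and not _is_degenerate(residual):
        k = len(imfs)  # extracting IMF k+1 using noise mode E_{k+1}
        beta = eps * float(np.std(residual))
        means = []
        for nm in noise_modes:
            pert = residual + beta * nm[k] if (beta > 0 and len(nm) > k) else residual
            means.append(_local_mean_op(pert, params))
        new_residual = np.mean(means, axis=0)
        ck = residual - new_residual
        if not np.any(ck):
            break
        imfs.append(ck)
        residual = new_residual
    return IMFSet(imfs=imfs, residual=residual, method="ICEEMDAN", params=params)


def decompose(samples: np.ndarray, params: DecompParams) -> IMFSet:
    """Dispatch on ``params.variant``."""
    if params.variant == "EMD":
        return emd(samples, params)
    if params.variant == "ICEEMDAN":
        return iceemdan(samples, params)
    return ensemble_emd(samples, params)
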