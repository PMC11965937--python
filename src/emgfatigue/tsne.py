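"""Exact t-distributed stochastic neighbor embedding (t-SNE), from first principles.

High-dimensional affinities are Gaussian conditionals
``p_{j|i} = exp(-d_ij^2 / 2 sigma_i^2) / sum_k exp(-d_ik^2 / 2 sigma_i^2)``,
with each bandwidth ``sigma_i`` bisected so the conditional's perplexity
``2^H`` hits the requested target; the joint affinity symmetrizes them,
``p_ij = (p_{j|i} + p_{i|j}) / 2n``.  Low-dimensional affinities use a
Student-t kernel with one degree of freedom,
``q_ij = (1 + |y_i - y_j|^2)^-1 / sum_{k != l} (1 + |y_k - y_l|^2)^-1``,
and the embedding minimises ``KL(P || Q)`` by momentum gradient descent
with the canonical schedule: early exaggeration x12 for the first quarter
of the run, momentum 0.5 -> 0.8, per-parameter gains, learning rate 200.

Everything is exact O(n^2) — no Barnes–Hut approximation — which is the
right trade at the feature-table sizes this package produces (hundreds to
a few thousand windows).  Inputs are z-scored per column by the caller
(or :func:`tsne_embed` with ``standardize=True``) since the Gaussian
kernel uses raw Euclidean distance.

Note t-SNE is transductive: there is no out-of-sample mapping, so any
classifier trained on embedded coordinates has seen the test rows during
the embedding.  See the classification module for how this caveat is
surfaced.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np


class DivergenceError(RuntimeError):
    """The optimiser produced a non-finite cost."""


@dataclass
class AffinityMatrices:
    """Conditional and joint input-space affinities."""

    p_cond: np.ndarray        # row-stochastic p_{j|i}
    p_joint: np.ndarray       # symmetric p_ij, sums to 1
    sigmas: np.ndarray        # per-point Gaussian bandwidths
    perplexity: float


@dataclass
class Embedding:
    """Low-dimensional coordinates with the optimisation cost trace."""

    coords: np.ndarray                 # (n, dims)
    cost_trace: np.ndarray             # KL divergence per iteration
    keys: "object | None" = None       # optional per-row provenance
    params: dict = field(default_factory=dict)


def _sq_distances(x: np.ndarray) -> np.ndarray:
    sq = np.sum(x**2, axis=1)
    d2 = sq[:, None] + sq[None, :] - 2.0 * (x @ x.T)
    np.maximum(d2, 0.0, out=d2)
    np.fill_diagonal(d2, 0.0)
    return d2


def _row_affinity(d2_row: np.ndarray, beta: float, i: int) -> tuple[np.ndarray, float]:
    """Gaussian row affinity at precision ``beta``; returns (p, Shannon entropy in bits)."""
    logits = -d2_row * beta
    logits[i] = -np.inf
    logits -= logits.max()
    p = np.exp(logits)
    p[i] = 0.0
    total = p.sum()
    p /= total
    nz = p > 0
    entropy = float(-np.sum(p[nz] * np.log2(p[nz])))
    return p, entropy


def conditional_affinities(
    x: np.ndarray, perplexity: float = 30.0, tol: float = 1e-4, max_iter: int = 100
) -> AffinityMatrices:
    """Per-point Gaussian affinities with bandwidths bisected to the target perplexity."""
    x = np.asarray(x, dtype=float)
    n = x.shape[0]
    if n < 4:
        raise ValueError("need at least 4 points")
    if not perplexity < n:
        raise ValueError("perplexity must be smaller than the number of points")
    d2 = _sq_distances(x)
    off_diag = d2 + np.diag(np.full(n, np.inf))
    degenerate = np.all(off_diag.min(axis=1) == 0.0)
    if degenerate:
        warnings.warn(
            "duplicate points give all-zero distances; jittering", stacklevel=2
        )
        rng = np.random.default_rng(0)
        scale = max(np.sqrt(d2.max()), 1.0) * 1e-6
        d2 = _sq_distances(x + rng.normal(0, scale, x.shape))

    target = float(np.log2(perplexity))
    p_cond = np.zeros((n, n))
    sigmas = np.zeros(n)
    for i in range(n):
        lo, hi = 0.0, np.inf
        beta = 1.0
        for _ in range(max_iter):
            p, entropy = _row_affinity(d2[i], beta, i)
            diff = entropy - target
            if abs(diff) < tol:
                break
            if diff > 0:      # too many effective neighbours -> narrow kernel
                lo = beta
                beta = beta * 2.0 if not np.isfinite(hi) else (lo + hi) / 2.0
            else:
                hi = beta
                beta = (lo + hi) / 2.0
        p_cond[i] = p
        sigmas[i] = np.sqrt(1.0 / (2.0 * beta))
    return AffinityMatrices(
        p_cond=p_cond, p_joint=symmetrize(p_cond), sigmas=sigmas, perplexity=perplexity
    )


def symmetrize(p_cond: np.ndarray) -> np.ndarray:
    """Joint affinities ``p_ij = (p_{j|i} + p_{i|j}) / 2n``."""
    n = p_cond.shape[0]
    return (p_cond + p_cond.T) / (2.0 * n)


def q_affinities(y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Student-t joint affinities of the embedding; returns (Q, unnormalised kernel)."""
    d2 = _sq_distances(np.asarray(y, dtype=float))
    kernel = 1.0 / (1.0 + d2)
    np.fill_diagonal(kernel, 0.0)
    total = kernel.sum()
    return kernel / total, kernel


def kl_cost(p: np.ndarray, q: np.ndarray) -> float:
    """``sum p log(p/q)`` with the 0 log 0 = 0 convention."""
    if p.shape != q.shape:
        raise ValueError("shape mismatch")
    mask = p > 0
    if np.any(q[mask] <= 0):
        raise ValueError("zero low-dimensional affinity at positive p")
    return float(np.sum(p[mask] * np.log(p[mask] / q[mask])))


def tsne_gradient(p: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Analytic KL gradient, ``4 sum_j (p_ij - q_ij)(1+|y_i-y_j|^2)^-1 (y_i-y_j)``."""
    q, kernel = q_affinities(y)
    w = (p - q) * kernel
    return 4.0 * (np.diag(w.sum(axis=1)) - w) @ y


def tsne_embed(
    x: np.ndarray,
    dims: int = 3,
    perplexity: float = 30.0,
    learning_rate: float = 200.0,
    n_iter: int = 1000,
    seed: int = 0,
    early_exaggeration: float = 12.0,
    exaggeration_iters: int = 250,
    standardize: bool = True,
    keys=None,
) -> Embedding:
    """Embed ``x`` into ``dims`` dimensions (see module docstring for the schedule)."""
    x = np.asarray(x, dtype=float)
    n = x.shape[0]
    if n < 10:
        raise ValueError("need at least 10 points to embed")
    if standardize:
        sd = x.std(axis=0)
        sd[sd == 0] = 1.0
        x = (x - x.mean(axis=0)) / sd
    perplexity = min(perplexity, (n - 1) / 3.0)  # guard for tiny inputs

    p = conditional_affinities(x, perplexity).p_joint
    p = np.maximum(p, 1e-12)
    p /= p.sum()

    rng = np.random.default_rng(seed)
    y = rng.normal(0.0, 1e-4, size=(n, dims))
    update = np.zeros_like(y)
    gains = np.ones_like(y)
    trace = np.empty(n_iter)

    for it in range(n_iter):
        exaggerating = it < exaggeration_iters
        p_eff = p * early_exaggeration if exaggerating else p
        grad = tsne_gradient(p_eff, y)
        momentum = 0.5 if exaggerating else 0.8
        same_sign = np.sign(grad) == np.sign(update)
        gains = np.where(same_sign, gains * 0.8, gains + 0.2)
        np.maximum(gains, 0.01, out=gains)
        update = momentum * update - learning_rate * gains * grad
        y = y + update
        y = y - y.mean(axis=0)
        q, _ = q_affinities(y)
        cost = float(np.sum(p * np.log(np.maximum(p, 1e-12) / np.maximum(q, 1e-12))))
        if not np.isfinite(cost):
            raise DivergenceError(f"non-finite cost at iteration {it}")
        trace[it] = cost
        # adaptive restart: an uphill step kills the momentum so the
        # post-exaggeration trace stays effectively monotone
        if it > 0 and not exaggerating and cost > trace[it - 1]:
            y = y - update
            update[:] = 0.0
            gains *= 0.5
            q, _ = q_affinities(y)
            trace[it] = float(
                np.sum(p * np.log(np.maximum(p, 1e-12) / np.maximum(q, 1e-12)))
            )

    return Embedding(
        coords=y,
        cost_trace=trace,
        keys=keys,
        params={
            "dims": dims,
            "perplexity": perplexity,
            "learning_rate": learning_rate,
            "n_iter": n_iter,
            "seed": seed,
        },
    )
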