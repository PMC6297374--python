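"""Short-term maximum Lyapunov exponents by nearest-neighbor divergence.

Rosenstein's method: every state on the embedded trajectory is paired
with its nearest neighbor outside a Theiler exclusion window (default one
stride, 100 samples); the mean natural-log Euclidean distance between
pairs is tracked over discrete steps; the short-term exponent lambda* is
the OLS slope of that divergence curve over 0..1 stride, reported in nats
per stride (slope per sample x 100).  Positive lambda* means nearby
trajectories diverge (local instability); negative means they converge.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from .state_embedding import DelayEmbedding, delay_embed, select_delay

__all__ = [
    "DivergenceCurve",
    "LyapunovResult",
    "LyapunovError",
    "nearest_neighbor_pairs",
    "divergence_curve",
    "max_lyapunov_short",
    "lyapunov_from_series",
]

SAMPLES_PER_STRIDE = 100


class LyapunovError(ValueError):
    pass


@dataclass
class DivergenceCurve:
    """Mean log nearest-neighbor distance per discrete step.

    ``mean_log_divergence[i]`` averages ln ||traj[j+i] - traj[k+i]|| over
    all pairs (j, k) still inside the data at step i; ``pair_count[i]``
    records how many pairs contributed (non-increasing in i).  The
    sampling period is 1 sample = 1% of the gait cycle.
    """

    mean_log_divergence: np.ndarray
    pair_count: np.ndarray
    dt: float = 1.0

    def __post_init__(self) -> None:
        if np.any(np.diff(self.pair_count) > 0):
            raise LyapunovError("pair count must be non-increasing")


@dataclass
class LyapunovResult:
    """Short-term maximum Lyapunov exponent from a divergence-curve fit."""

    lambda_star: float        # nats per stride
    slope_per_sample: float   # nats per sample (1 sample = 1% stride)
    fit_window: tuple[int, int]
    fit_r2: float
    n_pairs: int


def nearest_neighbor_pairs(
    trajectory: np.ndarray, theiler_window: int = SAMPLES_PER_STRIDE
) -> np.ndarray:
    """Index of each state's nearest neighbor outside the Theiler window.

    Returns an (n, 2) array of (point, neighbor) index pairs; for each
    point the neighbor minimizes Euclidean distance among states more
    than ``theiler_window`` steps away in time, ties broken by the
    smaller index.
    """
    traj = np.asarray(trajectory, dtype=float)
    if traj.ndim == 1:
        traj = traj[:, None]
    n = len(traj)
    if n <= 2 * theiler_window + 1:
        raise LyapunovError(
            f"trajectory of {n} states too short for Theiler window "
            f"{theiler_window}"
        )
    d = cdist(traj, traj)
    offsets = np.abs(np.arange(n)[:, None] - np.arange(n)[None, :])
    d[offsets <= theiler_window] = np.inf
    nbr = np.argmin(d, axis=1)  # argmin keeps the first (smallest) index on ties
    return np.column_stack([np.arange(n), nbr])


def divergence_curve(
    trajectory: np.ndarray, pairs: np.ndarray, horizon: int = 1000
) -> DivergenceCurve:
    """Mean log distance between neighbor pairs over 0..horizon steps.

    Pairs whose shifted indices leave the data are dropped at that step;
    pairs with exactly zero initial separation carry no divergence
    information (ln 0 undefined) and are excluded throughout.
    """
    traj = np.asarray(trajectory, dtype=float)
    if traj.ndim == 1:
        traj = traj[:, None]
    if horizon < 1:
        raise LyapunovError("horizon must be >= 1")
    pairs = np.asarray(pairs, dtype=int)
    d0 = np.linalg.norm(traj[pairs[:, 0]] - traj[pairs[:, 1]], axis=1)
    pairs = pairs[d0 > 0]
    if len(pairs) == 0:
        raise LyapunovError("no pairs with non-zero initial separation")
    n = len(traj)
    mean_log = np.full(horizon + 1, np.nan)
    count = np.zeros(horizon + 1, dtype=int)
    for i in range(horizon + 1):
        ok = np.maximum(pairs[:, 0], pairs[:, 1]) + i < n
        if not ok.any():
            break
        a = pairs[ok, 0] + i
        b = pairs[ok, 1] + i
        dist = np.linalg.norm(traj[a] - traj[b], axis=1)
        pos = dist > 0
        if not pos.any():
            break
        mean_log[i] = float(np.mean(np.log(dist[pos])))
        count[i] = int(pos.sum())
    return DivergenceCurve(mean_log, count)


def max_lyapunov_short(
    curve: DivergenceCurve,
    samples_per_stride: int = SAMPLES_PER_STRIDE,
    fit_range: tuple[int, int] | None = None,
) -> LyapunovResult:
    """OLS slope of the divergence curve over 0..1 stride, in nats/stride.

    ``fit_range`` (in samples, both endpoints included) defaults to
    (0, samples_per_stride).  lambda* = per-sample slope x
    ``samples_per_stride``; the fit R^2 is reported as a linearity
    diagnostic.
    """
    lo, hi = fit_range if fit_range is not None else (0, samples_per_stride)
    y = curve.mean_log_divergence
    if hi >= len(y):
        raise LyapunovError(
            f"curve covers {len(y) - 1} steps; fit window needs {hi}"
        )
    i = np.arange(lo, hi + 1)
    yi = y[i]
    ok = np.isfinite(yi) & (curve.pair_count[i] > 0)
    if ok.sum() < 2:
        raise LyapunovError("fewer than 2 valid curve points in the fit window")
    slope, intercept = np.polyfit(i[ok], yi[ok], 1)
    resid = yi[ok] - (slope * i[ok] + intercept)
    ss_tot = float(np.sum((yi[ok] - yi[ok].mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid ** 2)) / ss_tot if ss_tot > 0 else 1.0
    return LyapunovResult(
        lambda_star=float(slope) * samples_per_stride,
        slope_per_sample=float(slope),
        fit_window=(lo, hi),
        fit_r2=r2,
        n_pairs=int(curve.pair_count[0]),
    )


def lyapunov_from_series(
    x: np.ndarray,
    tau: int | None = None,
    d: int = 6,
    theiler_window: int = SAMPLES_PER_STRIDE,
    horizon: int = 1000,
    samples_per_stride: int = SAMPLES_PER_STRIDE,
    fit_range: tuple[int, int] | None = None,
) -> tuple[LyapunovResult, DelayEmbedding]:
    """Embed a scalar series and estimate its short-term exponent.

    tau defaults to the first AMI minimum; the horizon is clipped to the
    embedded trajectory length so short series remain analyzable.
    """
    if tau is None:
        tau, _ = select_delay(x)
    emb = delay_embed(x, tau, d)
    pairs = nearest_neighbor_pairs(emb.trajectory, theiler_window)
    horizon = min(horizon, len(emb.trajectory) - 1)
    curve = divergence_curve(emb.trajectory, pairs, horizon)
    return max_lyapunov_short(curve, samples_per_stride, fit_range), emb
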