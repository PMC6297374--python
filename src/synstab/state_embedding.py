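"""Delay-coordinate state-space reconstruction for synergy activations.

A scalar activation series q(t) on the 100-points-per-cycle phase grid is
embedded as S(t) = [q(t), q(t+tau), ..., q(t+(d_E-1)tau)].  The delay tau
is the first local minimum of the average mutual information (AMI) curve;
the dimension d_E comes from global false-nearest-neighbor (FNN) analysis,
optionally overridden by a unified dimension (default 6) shared across
subjects and synergies.  Time unit: 1 sample = 1% of the gait cycle.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

__all__ = [
    "DelayEmbedding",
    "EmbeddingError",
    "average_mutual_information",
    "first_local_minimum",
    "false_nearest_neighbors",
    "select_embedding_dimension",
    "select_delay",
    "delay_embed",
    "UNIFIED_DIMENSION",
]

UNIFIED_DIMENSION = 6  # unified embedding dimension across subjects/synergies


class EmbeddingError(ValueError):
    pass


@dataclass
class DelayEmbedding:
    """A delay-coordinate trajectory with its embedding parameters."""

    trajectory: np.ndarray  # (n_states, d_E)
    tau: int
    d_E: int
    source_length: int

    def __post_init__(self) -> None:
        expected = self.source_length - (self.d_E - 1) * self.tau
        if self.trajectory.shape != (expected, self.d_E):
            raise EmbeddingError(
                f"trajectory shape {self.trajectory.shape} violates the length "
                f"contract ({expected}, {self.d_E})"
            )


def average_mutual_information(
    x: np.ndarray, max_lag: int = 100, n_bins: int = 16
) -> np.ndarray:
    """AMI (in bits) between x_t and x_{t+lag} for lag = 0..max_lag.

    Estimated from the joint histogram on ``n_bins`` equal-width bins over
    the observed range.  AMI(0) equals the binned marginal entropy, the
    curve's maximum; AMI is invariant to affine rescaling of x because the
    bin edges are recomputed from the data range.
    """
    x = np.asarray(x, dtype=float).ravel()
    n = len(x)
    if max_lag >= n / 2:
        raise EmbeddingError(f"max_lag {max_lag} too large for series of length {n}")
    lo, hi = x.min(), x.max()
    if hi == lo:
        raise EmbeddingError("constant series has zero entropy; AMI undefined")
    edges = np.linspace(lo, hi, n_bins + 1)
    # digitize once; clip the right edge into the last bin
    binned = np.clip(np.searchsorted(edges, x, side="right") - 1, 0, n_bins - 1)
    ami = np.empty(max_lag + 1)
    for lag in range(max_lag + 1):
        a = binned[: n - lag]
        b = binned[lag:]
        joint = np.zeros((n_bins, n_bins))
        np.add.at(joint, (a, b), 1.0)
        joint /= joint.sum()
        px = joint.sum(axis=1)
        py = joint.sum(axis=0)
        nz = joint > 0
        ami[lag] = float(
            np.sum(joint[nz] * np.log2(joint[nz] / (px[:, None] * py[None, :])[nz]))
        )
    return ami


def first_local_minimum(curve: np.ndarray) -> tuple[int, bool]:
    """First index m with curve[m] < curve[m-1] and curve[m] <= curve[m+1].

    Plateaus resolve to their first index.  If no local minimum exists in
    range, returns the global minimum with the fallback flag set.
    Returns ``(lag, fallback)``.
    """
    c = np.asarray(curve, dtype=float)
    if len(c) < 3:
        raise EmbeddingError("curve must have at least 3 points")
    for m in range(1, len(c) - 1):
        if c[m] < c[m - 1] and c[m] <= c[m + 1]:
            return m, False
    return int(np.argmin(c)), True


def select_delay(x: np.ndarray, max_lag: int = 100, n_bins: int = 16) -> tuple[int, bool]:
    """Embedding delay = first local minimum of the AMI curve (with fallback flag)."""
    return first_local_minimum(average_mutual_information(x, max_lag, n_bins))


def delay_embed(x: np.ndarray, tau: int, d: int) -> DelayEmbedding:
    """Build the delay-coordinate trajectory; row t = (x_t, x_{t+tau}, ...)."""
    x = np.asarray(x, dtype=float).ravel()
    if tau < 1 or d < 1:
        raise EmbeddingError(f"tau and d must be >= 1, got tau={tau}, d={d}")
    n_states = len(x) - (d - 1) * tau
    if n_states <= 0:
        raise EmbeddingError(
            f"series of length {len(x)} too short for d={d}, tau={tau}"
        )
    idx = np.arange(n_states)[:, None] + tau * np.arange(d)[None, :]
    return DelayEmbedding(x[idx], tau, d, len(x))


def false_nearest_neighbors(
    x: np.ndarray,
    tau: int,
    d_max: int,
    Rtol: float = 15.0,
    Atol: float = 2.0,
    theiler_window: int = 0,
) -> np.ndarray:
    """Fraction of false nearest neighbors for each dimension d = 1..d_max.

    Kennel criterion: the nearest neighbor of a point in dimension d is
    false when the extra (d+1)-th coordinate grows the distance by more
    than ``Rtol`` relative to the d-dimensional distance, or pushes the
    (d+1)-dimensional distance beyond ``Atol`` times the series SD.
    """
    x = np.asarray(x, dtype=float).ravel()
    sd = x.std()
    if sd == 0:
        raise EmbeddingError("constant series cannot be embedded")
    fractions = np.empty(d_max)
    for d in range(1, d_max + 1):
        full = delay_embed(x, tau, d).trajectory
        n_use = len(x) - d * tau  # points whose (d+1)-th coordinate exists
        if n_use < 2:
            raise EmbeddingError(
                f"series too short for FNN at d={d} with tau={tau}"
            )
        pts = full[:n_use]
        tree = cKDTree(pts)
        k = min(2 + 2 * theiler_window, n_use)
        dist, nbr = tree.query(pts, k=k)
        n_false = 0
        n_valid = 0
        for i in range(n_use):
            j = -1
            for cand, dc in zip(nbr[i], dist[i]):
                if cand != i and abs(int(cand) - i) > theiler_window:
                    j, dij = int(cand), float(dc)
                    break
            if j < 0:
                continue
            extra = abs(x[i + d * tau] - x[j + d * tau])
            new_d = np.hypot(dij, extra)
            n_valid += 1
            # near-duplicate states (exactly periodic signals) make the
            # ratio test 0/0-unstable; such pairs can only be judged by
            # the absolute-size criterion
            floor = 1e-9 * sd
            if dij > floor and extra / dij > Rtol:
                n_false += 1
            elif new_d > Atol * sd:
                n_false += 1
        fractions[d - 1] = n_false / n_valid if n_valid else 1.0
    return fractions


def select_embedding_dimension(
    fnn_fractions: np.ndarray,
    threshold: float = 0.01,
    unified: int | None = None,
) -> tuple[int, str]:
    """Smallest d whose FNN fraction is <= threshold.

    Returns ``(d, flag)`` where flag is "ok", "fallback" (no fraction met
    the threshold; argmin used) or "unified" (the pipeline-level override,
    default 6, was requested and returned regardless of the fractions).
    """
    if unified is not None:
        return int(unified), "unified"
    f = np.asarray(fnn_fractions, dtype=float)
    hits = np.nonzero(f <= threshold)[0]
    if len(hits):
        return int(hits[0]) + 1, "ok"
    return int(np.argmin(f)) + 1, "fallback"
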