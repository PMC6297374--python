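"""Raw EMG conditioning and gait-cycle normalization.

Turns multi-channel surface EMG plus right-heel-contact events into the
muscles x (cycles x 100) analysis matrix consumed by the synergy and
stability stages.  The chain is: zero-lag high-pass (40 Hz) -> full-wave
rectification -> zero-lag low-pass (10 Hz) -> segmentation into gait
cycles -> linear time-interpolation of each cycle onto a 100-point phase
grid -> cycle selection (drop warm-up and cool-down strides) -> per-muscle
peak normalization -> per-muscle unit-variance normalization.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal as sps

__all__ = [
    "EmgRecording",
    "CycleTensor",
    "EmgMatrix",
    "PreprocessError",
    "DegenerateChannelError",
    "InsufficientCyclesError",
    "filter_zero_lag",
    "rectify",
    "segment_cycles",
    "time_normalize",
    "select_cycles",
    "normalize_emg_matrix",
    "preprocess",
    "read_emg_csv",
    "read_events_csv",
]

PHASE_POINTS = 100  # phase grid resolution: 1 point = 1% of the gait cycle


class PreprocessError(ValueError):
    """Invalid input to the EMG preprocessing chain."""


class DegenerateChannelError(PreprocessError):
    """A muscle channel is constant and cannot be variance-normalized."""


class InsufficientCyclesError(PreprocessError):
    """Too few recorded gait cycles for the requested retention rule."""


@dataclass
class EmgRecording:
    """Raw multi-channel EMG with sampling rate and heel-contact events.

    Parameters
    ----------
    samples : ndarray, shape (n_samples, n_channels)
        Signed EMG amplitudes in arbitrary voltage units.
    fs : float
        Sampling rate in Hz.
    channels : list of str
        Channel (muscle) names, one per column.
    heel_contacts : ndarray of int
        Strictly increasing sample indices of right heel contact (0-based).
    """

    samples: np.ndarray
    fs: float
    channels: list[str]
    heel_contacts: np.ndarray

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        self.heel_contacts = np.asarray(self.heel_contacts, dtype=int)
        if self.samples.ndim != 2:
            raise PreprocessError("samples must be a 2-D (samples x channels) array")
        if not np.isfinite(self.samples).all():
            raise PreprocessError("EMG contains missing or non-finite values")
        if self.fs <= 0:
            raise PreprocessError(f"sampling rate must be positive, got {self.fs}")
        if len(self.channels) != self.samples.shape[1]:
            raise PreprocessError(
                f"{len(self.channels)} channel names for "
                f"{self.samples.shape[1]} signal columns"
            )
        hc = self.heel_contacts
        if hc.ndim != 1 or len(hc) == 0:
            raise PreprocessError("heel_contacts must be a non-empty 1-D index array")
        if np.any(np.diff(hc) <= 0):
            raise PreprocessError("heel-contact indices must be strictly increasing")
        if hc[0] < 0 or hc[-1] >= self.samples.shape[0]:
            raise PreprocessError("heel-contact index outside the recording")

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]

    @property
    def n_channels(self) -> int:
        return self.samples.shape[1]


@dataclass
class CycleTensor:
    """Phase-normalized envelope amplitudes, (cycle, phase 1..100, muscle)."""

    values: np.ndarray
    muscles: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3 or self.values.shape[1] != PHASE_POINTS:
            raise PreprocessError(
                "cycle tensor must have shape (cycles, 100, muscles), "
                f"got {self.values.shape}"
            )
        if np.any(self.values < 0):
            raise PreprocessError("cycle tensor must be non-negative (post-rectification)")

    @property
    def n_cycles(self) -> int:
        return self.values.shape[0]


@dataclass
class EmgMatrix:
    """Fully normalized analysis matrix, muscles x (cycles_kept x 100).

    ``normalization`` records the per-muscle peak and standard deviation
    that were divided out, so either convention can be audited downstream.
    """

    values: np.ndarray
    muscles: list[str]
    cycles_kept: int
    normalization: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise PreprocessError("EmgMatrix values must be 2-D (muscles x T)")
        if self.values.shape[1] % PHASE_POINTS != 0:
            raise PreprocessError("T must be a multiple of 100 phase points")

    @property
    def n_muscles(self) -> int:
        return self.values.shape[0]

    @property
    def T(self) -> int:
        return self.values.shape[1]

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(self.values, index=self.muscles).to_csv(path, header=False)

    def save_normalization(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.normalization, fh, indent=2)


def filter_zero_lag(
    signal: np.ndarray,
    fs: float,
    cutoff: float,
    mode: str,
    order: int = 4,
) -> np.ndarray:
    """Zero-lag Butterworth filter (forward-backward application).

    The filter is applied once forward and once backward (``filtfilt``),
    cancelling the phase response; the magnitude response is consequently
    the squared response of a single ``order``-th order Butterworth.

    Parameters
    ----------
    signal : ndarray
        1-D series or 2-D (samples x channels) array, filtered along axis 0.
    fs, cutoff : float
        Sampling rate and cutoff frequency, Hz.
    mode : {"high", "low"}
        High-pass or low-pass.
    order : int
        Order of the underlying one-pass Butterworth design.
    """
    if mode not in ("high", "low"):
        raise PreprocessError(f"mode must be 'high' or 'low', got {mode!r}")
    if cutoff <= 0 or cutoff >= fs / 2:
        raise PreprocessError(
            f"cutoff {cutoff} Hz must lie strictly inside (0, Nyquist={fs / 2} Hz)"
        )
    x = np.asarray(signal, dtype=float)
    sos = sps.butter(order, cutoff, btype="highpass" if mode == "high" else "lowpass",
                     fs=fs, output="sos")
    # reflective padding of 3x the section count x order, sosfiltfilt default
    padlen = 3 * (2 * sos.shape[0] + 1)
    if x.shape[0] <= padlen:
        raise PreprocessError(
            f"signal of length {x.shape[0]} is too short for zero-lag filtering "
            f"(needs > {padlen} samples)"
        )
    return sps.sosfiltfilt(sos, x, axis=0)


def rectify(signal: np.ndarray) -> np.ndarray:
    """Full-wave rectification (elementwise absolute value); idempotent."""
    x = np.asarray(signal, dtype=float)
    if not np.isfinite(x).all():
        raise PreprocessError("cannot rectify non-finite values")
    return np.abs(x)


def segment_cycles(envelopes: np.ndarray, heel_contacts: np.ndarray) -> list[np.ndarray]:
    """Split envelopes into gait cycles [hc_k, hc_{k+1}).

    Returns ``len(heel_contacts) - 1`` variable-length segments; the last
    recorded heel contact only terminates the final cycle.
    """
    x = np.atleast_2d(np.asarray(envelopes, dtype=float).T).T  # ensure 2-D, samples x ch
    hc = np.asarray(heel_contacts, dtype=int)
    if len(hc) < 2:
        raise PreprocessError("at least 2 heel contacts are required to form a cycle")
    if np.any(np.diff(hc) <= 0):
        raise PreprocessError("heel-contact indices must be strictly increasing")
    if hc[0] < 0 or hc[-1] > x.shape[0]:
        raise PreprocessError("heel-contact index outside the data")
    return [x[hc[k]: hc[k + 1]] for k in range(len(hc) - 1)]


def time_normalize(segment: np.ndarray) -> np.ndarray:
    """Linearly interpolate one cycle onto the uniform 100-point phase grid.

    Phase k (k = 0..99) maps to time k/100 of the cycle duration; the
    endpoint is excluded so consecutive cycles tile without duplicating
    the heel-contact sample.  A cycle already sampled on the 100-point
    grid is reproduced exactly.
    """
    seg = np.atleast_2d(np.asarray(segment, dtype=float).T).T
    n = seg.shape[0]
    if n < 2:
        raise PreprocessError(f"cycle of {n} sample(s) cannot be time-normalized")
    pos = np.arange(PHASE_POINTS) * n / PHASE_POINTS
    out = np.empty((PHASE_POINTS, seg.shape[1]))
    grid = np.arange(n, dtype=float)
    for c in range(seg.shape[1]):
        out[:, c] = np.interp(pos, grid, seg[:, c])
    if segment.ndim == 1:
        return out[:, 0]
    return out


def select_cycles(
    tensor: CycleTensor,
    drop_head: int = 10,
    drop_tail: int = 10,
    keep: int = 30,
) -> CycleTensor:
    """Retain ``keep`` steady-state cycles.

    Drops exactly the first ``drop_head`` cycles (gait initiation), keeps
    the next ``keep``, and requires at least ``drop_tail`` cycles after
    them (gait termination) — so recordings longer than the minimum keep
    the same early steady-state strides.
    """
    n = tensor.n_cycles
    needed = drop_head + keep + drop_tail
    if n < needed:
        raise InsufficientCyclesError(
            f"{n} recorded cycles < {drop_head} (head) + {keep} (keep) + "
            f"{drop_tail} (tail) = {needed} required"
        )
    return CycleTensor(tensor.values[drop_head: drop_head + keep], tensor.muscles)


def normalize_emg_matrix(matrix: np.ndarray, muscles: list[str] | None = None,
                         cycles_kept: int | None = None) -> EmgMatrix:
    """Peak- then variance-normalize each muscle row.

    Step 1 divides each row by its own maximum; step 2 divides each row by
    its post-step-1 population standard deviation, giving unit variance.
    Both divisors are stored in the normalization record.
    """
    M = np.asarray(matrix, dtype=float)
    if M.ndim != 2:
        raise PreprocessError("expected a 2-D muscles x T matrix")
    if np.any(M < 0):
        raise PreprocessError("normalization expects non-negative envelope values")
    if muscles is None:
        muscles = [f"m{i}" for i in range(M.shape[0])]
    peaks = M.max(axis=1)
    for name, p in zip(muscles, peaks):
        if p <= 0:
            raise DegenerateChannelError(f"muscle {name!r} has zero peak activity")
    peaked = M / peaks[:, None]
    sds = peaked.std(axis=1)  # population SD (divide by n)
    for name, s in zip(muscles, sds):
        if s <= 0:
            raise DegenerateChannelError(f"muscle {name!r} has zero variance")
    values = peaked / sds[:, None]
    if cycles_kept is None:
        cycles_kept = M.shape[1] // PHASE_POINTS
    record = {
        "peak": dict(zip(muscles, peaks.tolist())),
        "sd": dict(zip(muscles, sds.tolist())),
        "sd_convention": "population (ddof=0)",
        "peak_scope": "per-muscle",
    }
    return EmgMatrix(values, list(muscles), cycles_kept, record)


def preprocess(
    recording: EmgRecording,
    highpass_hz: float = 40.0,
    lowpass_hz: float = 10.0,
    drop_head: int = 10,
    drop_tail: int = 10,
    keep: int = 30,
) -> EmgMatrix:
    """Run the full conditioning chain on a raw recording.

    high-pass -> rectify -> low-pass -> segment -> time-normalize ->
    select cycles -> peak-normalize -> SD-normalize.
    """
    hp = filter_zero_lag(recording.samples, recording.fs, highpass_hz, "high")
    env = filter_zero_lag(rectify(hp), recording.fs, lowpass_hz, "low")
    # the low-pass envelope can slightly undershoot zero; the tensor domain
    # is the rectified envelope, so clip the numerical ringing
    env = np.clip(env, 0.0, None)
    segments = segment_cycles(env, recording.heel_contacts)
    cycles = np.stack([time_normalize(seg) for seg in segments])
    tensor = select_cycles(CycleTensor(cycles, recording.channels),
                           drop_head=drop_head, drop_tail=drop_tail, keep=keep)
    # (cycle, phase, muscle) -> muscles x (cycles*100)
    flat = tensor.values.transpose(2, 0, 1).reshape(len(recording.channels), -1)
    return normalize_emg_matrix(flat, recording.channels, cycles_kept=keep)


def read_emg_csv(path: str | Path, fs: float, events: np.ndarray,
                 events_in_seconds: bool = False) -> EmgRecording:
    """Load a delimited EMG file (header row of channel names, one row per sample)."""
    df = pd.read_csv(path)
    ev = np.asarray(events)
    if events_in_seconds:
        ev = np.round(ev * fs).astype(int)
    return EmgRecording(df.to_numpy(dtype=float), fs, list(df.columns), ev)


def read_events_csv(path: str | Path) -> np.ndarray:
    """Load a single-column CSV of 0-based heel-contact sample indices."""
    return pd.read_csv(path, header=None).to_numpy().ravel().astype(int)
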