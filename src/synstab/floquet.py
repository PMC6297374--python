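"""Orbital stability via Poincare maps and maximum Floquet multipliers.

The embedded activation trajectory is sampled once per stride at each
percent of the gait cycle, defining 100 Poincare sections per trial.  At
each section, the fixed point S* is the mean state across strides (the
average trajectory), and the linearized stride-to-stride map
S_{k+1} - S* ~= J (S_k - S*) is fit by least squares over consecutive
strides.  The Floquet multipliers are the eigenvalues of J; the limit
cycle is orbitally stable when the maximum multiplier magnitude is < 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .state_embedding import delay_embed, select_delay

__all__ = [
    "PoincareSection",
    "FloquetResult",
    "FloquetError",
    "build_sections",
    "fit_jacobian",
    "max_floquet_multiplier",
    "floquet_summary",
    "floquet_from_series",
    "N_SECTIONS",
]

N_SECTIONS = 100


class FloquetError(ValueError):
    pass


@dataclass
class PoincareSection:
    """Per-stride embedded states at one percent of the gait cycle."""

    phase: int                 # % gait cycle, 1..100
    states: np.ndarray         # (n_strides_usable, d_E)
    strides: np.ndarray        # stride indices the states came from

    def __post_init__(self) -> None:
        self.states = np.atleast_2d(np.asarray(self.states, dtype=float))
        self.strides = np.asarray(self.strides, dtype=int)

    @property
    def fixed_point(self) -> np.ndarray:
        """S*: the mean state across strides (average-trajectory fixed point)."""
        return self.states.mean(axis=0)


@dataclass
class FloquetResult:
    """Per-trial summary of maximum Floquet multiplier magnitudes."""

    per_section: np.ndarray          # magnitude per Poincare section
    summary_policy: str = "mean"
    flags: list[str] = field(default_factory=list)

    @property
    def fm_mean(self) -> float:
        return float(self.per_section.mean())

    @property
    def fm_max(self) -> float:
        return float(self.per_section.max())

    @property
    def orbitally_stable(self) -> bool:
        stat = self.fm_mean if self.summary_policy == "mean" else self.fm_max
        return stat < 1.0


def build_sections(
    x: np.ndarray,
    tau: int,
    d: int,
    samples_per_stride: int = 100,
) -> list[PoincareSection]:
    """Cut the embedded trajectory into 100 Poincare sections.

    Stride k's state at phase p (1..100) starts at sample k*100 + (p-1)
    and spans the embedding window (d-1)*tau ahead; strides whose window
    runs past the series end are dropped from the affected sections only,
    so the section count is always 100.
    """
    x = np.asarray(x, dtype=float).ravel()
    T = len(x)
    n_strides = T // samples_per_stride
    if n_strides < 2:
        raise FloquetError("need at least 2 strides to define a Poincare map")
    emb = delay_embed(x, tau, d)
    n_states = len(emb.trajectory)
    sections = []
    for p in range(1, N_SECTIONS + 1):
        starts = np.arange(n_strides) * samples_per_stride + (p - 1)
        usable = starts < n_states
        if usable.sum() < d + 1:
            raise FloquetError(
                f"phase {p}%: {int(usable.sum())} usable strides < d_E + 1 = {d + 1} "
                "required for Jacobian fitting"
            )
        sections.append(
            PoincareSection(p, emb.trajectory[starts[usable]], np.nonzero(usable)[0])
        )
    return sections


def fit_jacobian(section: PoincareSection) -> tuple[np.ndarray, list[str]]:
    """Least-squares Jacobian of the Poincare map at one section.

    Minimizes sum ||(S_{k+1} - S*) - J (S_k - S*)||^2 over consecutive-
    stride pairs via pseudoinverse.  Rank-deficient deviations yield the
    least-norm solution with a "rank_deficient" flag rather than an error.
    """
    d = section.states.shape[1]
    consec = np.nonzero(np.diff(section.strides) == 1)[0]
    if len(consec) < d:
        raise FloquetError(
            f"phase {section.phase}%: {len(consec)} consecutive-stride pairs "
            f"< d_E = {d} needed to determine the Jacobian"
        )
    dev = section.states - section.fixed_point
    X = dev[consec]        # S_k - S*
    Y = dev[consec + 1]    # S_{k+1} - S*
    B, _, rank, _ = np.linalg.lstsq(X, Y, rcond=None)
    flags = [] if rank == d else ["rank_deficient"]
    return B.T, flags


def max_floquet_multiplier(J: np.ndarray) -> float:
    """Maximum modulus over the (complex) eigenvalues of J."""
    J = np.asarray(J, dtype=float)
    if J.ndim != 2 or J.shape[0] != J.shape[1]:
        raise FloquetError(f"Jacobian must be square, got shape {J.shape}")
    return float(np.abs(np.linalg.eigvals(J)).max())


def floquet_summary(
    per_section_magnitudes: np.ndarray,
    policy: str = "mean",
    flags: list[str] | None = None,
) -> FloquetResult:
    """Aggregate the 100 per-section magnitudes into a trial summary.

    The stability verdict applies the magnitude-<1 criterion to the
    summary statistic chosen by ``policy`` ("mean", the default
    convention, or "max"); both statistics are always reported.
    """
    mags = np.asarray(per_section_magnitudes, dtype=float)
    if np.any(mags < 0):
        raise FloquetError("multiplier magnitudes must be non-negative")
    if policy not in ("mean", "max"):
        raise FloquetError(f"summary policy must be 'mean' or 'max', got {policy!r}")
    return FloquetResult(mags, policy, flags or [])


def floquet_from_series(
    x: np.ndarray,
    tau: int | None = None,
    d: int = 6,
    policy: str = "mean",
) -> FloquetResult:
    """Full orbital-stability analysis of one activation series."""
    if tau is None:
        tau, _ = select_delay(x)
    sections = build_sections(x, tau, d)
    mags = np.empty(len(sections))
    flags: list[str] = []
    for i, sec in enumerate(sections):
        J, f = fit_jacobian(sec)
        mags[i] = max_floquet_multiplier(J)
        flags.extend(f"phase{sec.phase}:{flag}" for flag in f)
    return floquet_summary(mags, policy, flags)
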