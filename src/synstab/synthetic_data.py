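"""Synthetic walking EMG with known synergy structure, plus estimator oracles.

The gait generator inverts the analysis model: a fixed non-negative
weighting matrix W_true (12 muscles x 5 synergies, unit-norm columns,
pairwise cosine < 0.6) drives periodic activation waveforms C_true —
one circular Gaussian bump per synergy per gait cycle, centered at the
phase where that functional synergy peaks in level walking (body support,
forward propulsion near 40% of the cycle, swing initiation, mid-swing,
leg deceleration in late swing).  Cycle-to-cycle variability enters
through the bump parameters: per-cycle center and amplitude follow a
seeded AR(1) process with coefficient rho, so local divergence between
strides is controllable while the mean cycle stays fixed.  Additive
sensor noise is clipped at zero, respecting the non-negative domain of
rectified EMG envelopes (the clipping introduces a small positive bias at
near-zero phases, documented rather than corrected).

A raw mode up-samples the envelopes to 1,000 Hz with +-10% stride-duration
jitter and multiplies in a band-limited (40-450 Hz) carrier, producing an
interference-pattern signal the preprocessing chain can be tested on
end-to-end.

Two dynamical-system oracles with known answers are included: the
logistic map at r = 4 (maximum Lyapunov exponent exactly ln 2 per step)
for the divergence estimator, and a linear stride map with prescribed
spectral radius for the Floquet pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import signal as sps

from .emg_preprocess import PHASE_POINTS, EmgRecording
from .synergy_nmf import cosine_similarity

__all__ = [
    "SynthConfig",
    "SynthError",
    "make_weightings",
    "make_activations",
    "observed_activations",
    "synthesize_emg",
    "synthesize_raw_recording",
    "logistic_map",
    "linear_stride_system",
    "DEFAULT_CENTERS",
    "DEFAULT_WIDTHS",
]


class SynthError(ValueError):
    pass


# bump centers/widths (% of gait cycle): loading response / body support,
# forward propulsion (peak near 40%), swing initiation, mid-swing,
# late-swing leg deceleration
DEFAULT_CENTERS = (15.0, 40.0, 60.0, 80.0, 95.0)
DEFAULT_WIDTHS = (7.0, 6.0, 6.0, 5.0, 5.0)


@dataclass
class SynthConfig:
    """Study-condition parameters for the gait generator.

    Defaults emulate the recorded data the pipeline targets: 12 muscles
    sampled at 1,000 Hz, 50 gait cycles of ~1,000 samples (+-10% duration
    jitter), activity generated by 5 synergies with phase-localized
    activation bumps, moderate cycle-to-cycle amplitude/phase variability
    and 5% additive noise.
    """

    n_muscles: int = 12
    n_synergies: int = 5
    n_cycles: int = 50
    samples_per_cycle: int = 1000
    duration_jitter_frac: float = 0.10
    centers: tuple[float, ...] = DEFAULT_CENTERS
    widths: tuple[float, ...] = DEFAULT_WIDTHS
    amp_noise_sd: float = 0.10      # relative, per cycle
    phase_jitter_sd: float = 1.0    # % gait cycle, per cycle
    rho: float = 0.3                # AR(1) coefficient of the cycle dynamics
    additive_noise_sd: float = 0.05  # fraction of the signal SD
    fs: float = 1000.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.rho < 1:
            raise SynthError(f"rho must be in [0, 1), got {self.rho}")
        if min(self.amp_noise_sd, self.phase_jitter_sd, self.additive_noise_sd) < 0:
            raise SynthError("noise standard deviations must be >= 0")
        if len(self.centers) < self.n_synergies or len(self.widths) < self.n_synergies:
            raise SynthError("need a bump center and width per synergy")
        if any(not 0 <= c < 100 for c in self.centers):
            raise SynthError("bump centers must lie in [0, 100)")

    def to_dict(self) -> dict:
        return asdict(self)


def make_weightings(
    n_muscles: int = 12,
    n_synergies: int = 5,
    min_separation: float = 0.6,
    seed: int = 0,
    max_attempts: int = 500,
) -> np.ndarray:
    """Random non-negative unit-norm weighting columns, pairwise cosine < ``min_separation``.

    Muscles are partitioned into disjoint dominant groups (one per
    synergy, sizes as even as possible) with a small non-negative
    baseline everywhere else — mimicking the largely distinct functional
    muscle clusters of level walking (plantarflexor, dorsiflexor+RF,
    support, swing-initiation, deceleration).  The cosine-separation
    constraint is enforced by seeded rejection sampling.
    """
    if n_synergies > n_muscles:
        raise SynthError("cannot have more synergies than muscles")
    rng = np.random.default_rng(seed)
    for _ in range(max_attempts):
        W = rng.uniform(0.0, 0.08, size=(n_muscles, n_synergies))
        groups = np.array_split(rng.permutation(n_muscles), n_synergies)
        for j, dom in enumerate(groups):
            W[dom, j] += rng.uniform(0.5, 1.0, size=len(dom))
        W /= np.linalg.norm(W, axis=0)[None, :]
        cosines = [
            cosine_similarity(W[:, a], W[:, b])
            for a in range(n_synergies) for b in range(a + 1, n_synergies)
        ]
        if not cosines or max(cosines) < min_separation:
            return W
    raise SynthError(
        f"could not draw weightings with pairwise cosine < {min_separation} "
        f"in {max_attempts} attempts"
    )


def _ar1(rng: np.random.Generator, n: int, rho: float, sd: float) -> np.ndarray:
    """Stationary AR(1) series with innovation SD ``sd``."""
    z = np.empty(n)
    if sd == 0:
        return np.zeros(n)
    z[0] = rng.normal(0.0, sd / np.sqrt(1.0 - rho ** 2) if rho > 0 else sd)
    for k in range(1, n):
        z[k] = rho * z[k - 1] + rng.normal(0.0, sd)
    return z


def _circular_bump(phases: np.ndarray, center: float, width: float) -> np.ndarray:
    """Gaussian bump on the circular 0..100 phase axis (wraps continuously)."""
    delta = (phases - center + 50.0) % 100.0 - 50.0
    return np.exp(-0.5 * (delta / width) ** 2)


def make_activations(config: SynthConfig) -> tuple[np.ndarray, dict]:
    """Synergy activations on the phase grid, (n_synergies x n_cycles*100).

    Each cycle of each synergy is one circular Gaussian bump whose center
    and amplitude follow AR(1) dynamics around the configured means; the
    per-cycle parameter log is returned for ground-truth comparisons.
    """
    rng = np.random.default_rng(config.seed)
    phases = np.arange(PHASE_POINTS, dtype=float)
    C = np.empty((config.n_synergies, config.n_cycles * PHASE_POINTS))
    log = {"center": [], "amplitude": []}
    for i in range(config.n_synergies):
        centers = config.centers[i] + _ar1(rng, config.n_cycles, config.rho,
                                           config.phase_jitter_sd)
        amps = 1.0 + _ar1(rng, config.n_cycles, config.rho, config.amp_noise_sd)
        amps = np.clip(amps, 0.0, None)
        log["center"].append(centers.tolist())
        log["amplitude"].append(amps.tolist())
        for k in range(config.n_cycles):
            C[i, k * PHASE_POINTS:(k + 1) * PHASE_POINTS] = (
                amps[k] * _circular_bump(phases, centers[k] % 100.0,
                                         config.widths[i])
            )
    return C, log


def observed_activations(config: SynthConfig | None = None) -> tuple[np.ndarray, dict]:
    """Activations as the analysis would observe them: bumps + sensor noise.

    Adds the configured additive noise (a fraction of each series' SD,
    clipped at zero) to the clean bump activations, emulating the
    estimation/sensor noise that activation coefficients extracted from
    real EMG always carry.  Stability estimators should be exercised on
    these rather than on the noise-free bumps: perfectly smooth periodic
    series make the Poincare-map regression rank-deficient in a way real
    activations never are.
    """
    config = config or SynthConfig()
    C, log = make_activations(config)
    rng = np.random.default_rng(config.seed + 7)
    sd = C.std(axis=1, keepdims=True)
    noisy = np.clip(C + config.additive_noise_sd * sd
                    * rng.standard_normal(C.shape), 0.0, None)
    return noisy, log


def synthesize_emg(
    W_true: np.ndarray,
    C_true: np.ndarray,
    additive_noise_sd: float = 0.05,
    seed: int = 0,
) -> tuple[np.ndarray, dict]:
    """Envelope-domain EMG matrix M = W_true @ C_true + noise, clipped at 0.

    ``additive_noise_sd`` is a fraction of the clean signal's SD.  Returns
    the matrix and a ground-truth bundle (W_true, C_true, noise scale).
    """
    signal = np.asarray(W_true) @ np.asarray(C_true)
    rng = np.random.default_rng(seed)
    scale = additive_noise_sd * signal.std()
    M = np.clip(signal + rng.normal(0.0, scale, size=signal.shape), 0.0, None)
    truth = {"W_true": np.asarray(W_true), "C_true": np.asarray(C_true),
             "noise_sd_absolute": float(scale)}
    return M, truth


def synthesize_raw_recording(config: SynthConfig | None = None) -> tuple[EmgRecording, dict]:
    """Raw-mode synthetic recording: envelopes x band-limited carrier at 1 kHz.

    Per-cycle envelopes are linearly up-sampled to a jittered stride
    duration (~1,000 samples +-10%) and multiplied by a 40-450 Hz
    band-limited carrier, so the preprocessing chain (40 Hz high-pass,
    rectification, 10 Hz low-pass, phase normalization) can recover the
    synergy structure from a raw-like signal.  Heel contacts fall at the
    cycle boundaries.
    """
    config = config or SynthConfig()
    rng = np.random.default_rng(config.seed + 1)
    W = make_weightings(config.n_muscles, config.n_synergies,
                        seed=config.seed)
    C, log = make_activations(config)
    env_cycles = (W @ C).reshape(config.n_muscles, config.n_cycles, PHASE_POINTS)

    durations = np.round(
        config.samples_per_cycle
        * (1.0 + rng.uniform(-config.duration_jitter_frac,
                             config.duration_jitter_frac,
                             size=config.n_cycles))
    ).astype(int)
    total = int(durations.sum())
    # n_cycles + 1 contacts delimit n_cycles complete cycles; one trailing
    # sample is appended so the final contact lies inside the recording
    heel_contacts = np.concatenate([[0], np.cumsum(durations)])

    # band-limited carrier shared spectrum, independent per channel
    sos = sps.butter(4, [40.0, min(450.0, config.fs / 2 * 0.98)],
                     btype="bandpass", fs=config.fs, output="sos")
    carrier = sps.sosfilt(sos, rng.standard_normal((total, config.n_muscles)),
                          axis=0)
    carrier /= carrier.std(axis=0, keepdims=True)

    raw = np.empty((total + 1, config.n_muscles))
    phase_grid = np.arange(PHASE_POINTS, dtype=float)
    for k, (start, dur) in enumerate(zip(heel_contacts, durations)):
        t = np.arange(dur) * PHASE_POINTS / dur  # phase of each raw sample
        for m in range(config.n_muscles):
            env = np.interp(t, phase_grid, env_cycles[m, k])
            raw[start:start + dur, m] = env * carrier[start:start + dur, m]
    raw[total] = raw[total - 1]
    noise_sd = config.additive_noise_sd * np.abs(raw[:total]).std()
    raw += rng.normal(0.0, noise_sd, size=raw.shape)

    muscles = [f"m{i + 1:02d}" for i in range(config.n_muscles)]
    rec = EmgRecording(raw, config.fs, muscles, heel_contacts)
    truth = {"W_true": W, "C_true": C, "parameter_log": log,
             "durations": durations, "config": config.to_dict()}
    return rec, truth


def logistic_map(r: float, x0: float, n: int) -> np.ndarray:
    """Iterates of x_{t+1} = r x_t (1 - x_t); values stay in [0, 1].

    At r = 4 the maximum Lyapunov exponent is exactly ln 2 per step,
    making this the estimator oracle for the divergence method.
    """
    if not 0 < x0 < 1:
        raise SynthError(f"x0 must be in (0, 1), got {x0}")
    if not 0 < r <= 4:
        raise SynthError(f"r must be in (0, 4], got {r}")
    x = np.empty(n)
    x[0] = x0
    for t in range(1, n):
        x[t] = r * x[t - 1] * (1.0 - x[t - 1])
    return x


def linear_stride_system(
    A: np.ndarray,
    S_star: np.ndarray,
    n_strides: int,
    noise_sd: float = 0.0,
    seed: int = 0,
    S0: np.ndarray | None = None,
) -> np.ndarray:
    """Stride states from S_{k+1} = S* + A (S_k - S*) + noise.

    The caller knows A's spectral radius, so the fitted Jacobian and
    multiplier estimates can be checked exactly (noise-free) or
    statistically (noisy).
    """
    A = np.asarray(A, dtype=float)
    S_star = np.asarray(S_star, dtype=float)
    d = len(S_star)
    if A.shape != (d, d):
        raise SynthError(f"A must be {d}x{d} to match S*, got {A.shape}")
    rng = np.random.default_rng(seed)
    states = np.empty((n_strides, d))
    states[0] = S0 if S0 is not None else S_star + rng.standard_normal(d)
    for k in range(1, n_strides):
        states[k] = (S_star + A @ (states[k - 1] - S_star)
                     + rng.normal(0.0, noise_sd, size=d))
    return states
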