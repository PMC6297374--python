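"""Muscle-synergy extraction by non-negative matrix factorization.

The preprocessed EMG matrix M (muscles x time) is approximated as W @ C
with W >= 0 the muscle weightings (one column per synergy, unit norm) and
C >= 0 the time-varying activation coefficients.  The number of synergies
is chosen by cross-validated variability-accounted-for (VAF): W is fit on
60% of the gait cycles, C is re-estimated on the held-out 40% with W
fixed, and the smallest N whose 95% CI lower bound exceeds 90% global VAF
and 75% per-muscle VAF is selected.  A row-shuffled control destroys the
between-muscle structure while preserving each muscle's value multiset.
Synergies from different trials/subjects are grouped by cosine similarity
of W or of the cycle-averaged activation waveform, with the acceptance
threshold set at the two-tailed critical Pearson correlation (alpha=0.01,
df=10), which rounds to 0.71.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .emg_preprocess import PHASE_POINTS

__all__ = [
    "SynergySet",
    "VafTable",
    "SynergyGrouping",
    "NmfError",
    "NoSelectionError",
    "nmf",
    "update_activations_fixed_w",
    "vaf",
    "cross_validated_vaf",
    "select_num_synergies",
    "shuffle_control",
    "normalize_synergy",
    "cosine_similarity",
    "match_synergies",
    "critical_correlation",
    "mean_waveform",
]

_EPS = 1e-12  # guards multiplicative-update denominators


class NmfError(ValueError):
    """Invalid input to a factorization routine."""


class NoSelectionError(RuntimeError):
    """No synergy count satisfied the VAF selection rule."""

    def __init__(self, message: str, table: "VafTable"):
        super().__init__(message)
        self.table = table


@dataclass
class SynergySet:
    """One NMF factorization: W (muscles x N, unit-norm columns), C (N x T)."""

    W: np.ndarray
    C: np.ndarray
    n_synergies: int
    reconstruction_error: float
    n_iter: int = 0

    def reconstruct(self) -> np.ndarray:
        return self.W @ self.C


@dataclass
class VafTable:
    """Cross-validated VAF statistics per candidate synergy count.

    All VAF values are percentages evaluated on the held-out cycles.
    CI bounds use the t-distribution with n_repeats - 1 degrees of freedom.
    """

    n_range: np.ndarray                  # candidate synergy counts
    global_vaf: np.ndarray               # (n_candidates, n_repeats)
    muscle_vaf: np.ndarray               # (n_candidates, n_repeats, n_muscles)
    muscles: list[str] = field(default_factory=list)
    n_repeats: int = 0

    def __post_init__(self) -> None:
        if self.n_repeats == 0:
            self.n_repeats = self.global_vaf.shape[1]

    def _ci(self, samples: np.ndarray, axis: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        mean = samples.mean(axis=axis)
        sem = samples.std(axis=axis, ddof=1) / np.sqrt(self.n_repeats)
        tcrit = stats.t.ppf(0.975, df=self.n_repeats - 1)
        return mean, mean - tcrit * sem, mean + tcrit * sem

    @property
    def global_mean(self) -> np.ndarray:
        return self._ci(self.global_vaf, axis=1)[0]

    @property
    def global_ci_lower(self) -> np.ndarray:
        return self._ci(self.global_vaf, axis=1)[1]

    @property
    def global_ci_upper(self) -> np.ndarray:
        return self._ci(self.global_vaf, axis=1)[2]

    @property
    def muscle_ci_lower(self) -> np.ndarray:
        """(n_candidates, n_muscles) lower 95% CI bound per muscle."""
        return self._ci(self.muscle_vaf, axis=1)[1]

    def to_frame(self) -> pd.DataFrame:
        mean, lo, hi = self._ci(self.global_vaf, axis=1)
        df = pd.DataFrame({
            "n_synergies": self.n_range,
            "global_vaf_mean": mean,
            "global_vaf_ci_lower": lo,
            "global_vaf_ci_upper": hi,
        })
        mlo = self.muscle_ci_lower
        names = self.muscles or [f"m{i}" for i in range(mlo.shape[1])]
        df["min_muscle_vaf_ci_lower"] = mlo.min(axis=1)
        for j, name in enumerate(names):
            df[f"muscle_vaf_ci_lower_{name}"] = mlo[:, j]
        return df


@dataclass
class SynergyGrouping:
    """Group labels assigned to each trial's synergies by similarity matching.

    ``labels[t][i]`` is the group of synergy i in trial t, or -1 when the
    synergy matched nothing above threshold (flagged, never forced).
    """

    labels: list[np.ndarray]
    similarities: list[np.ndarray]
    threshold: float
    metric: str
    reference: str

    @property
    def unmatched(self) -> list[np.ndarray]:
        return [lab == -1 for lab in self.labels]


# ---------------------------------------------------------------------------
# core factorization


def _init_factors(M: np.ndarray, n: int, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    # uniform random in (0, 1], scaled to the matrix mean
    scale = np.sqrt(max(M.mean(), _EPS) / n)
    W = scale * (1.0 - rng.random((M.shape[0], n)))
    C = scale * (1.0 - rng.random((n, M.shape[1])))
    return W, C


def _multiplicative_fit(
    M: np.ndarray,
    W: np.ndarray,
    C: np.ndarray,
    max_iter: int,
    tol: float,
    update_w: bool,
) -> tuple[np.ndarray, np.ndarray, float, int]:
    """Lee-Seung multiplicative updates for the Euclidean objective."""
    err_prev = np.linalg.norm(M - W @ C)
    it = 0
    for it in range(1, max_iter + 1):
        if update_w:
            W *= (M @ C.T) / (W @ (C @ C.T) + _EPS)
        C *= (W.T @ M) / ((W.T @ W) @ C + _EPS)
        err = np.linalg.norm(M - W @ C)
        if err_prev > 0 and (err_prev - err) / err_prev < tol:
            err_prev = err
            break
        err_prev = err
    return W, C, float(err_prev), it


def _check_nonneg(M: np.ndarray) -> np.ndarray:
    M = np.asarray(M, dtype=float)
    if np.any(M < 0):
        raise NmfError("input matrix must be elementwise non-negative")
    return M


def nmf(
    M: np.ndarray,
    n_synergies: int,
    seed: int = 0,
    max_iter: int = 1000,
    tol: float = 1e-6,
    n_restarts: int = 20,
) -> SynergySet:
    """Factorize M ~= W @ C, keeping the best of ``n_restarts`` seeded runs.

    Multiplicative updates minimizing the Frobenius residual; the residual
    is non-increasing within each restart, and the restart with the lowest
    final residual wins.  Deterministic given ``seed``.
    """
    M = _check_nonneg(M)
    if not 1 <= n_synergies <= M.shape[0]:
        raise NmfError(
            f"n_synergies must be in [1, {M.shape[0]}], got {n_synergies}"
        )
    rng = np.random.default_rng(seed)
    best: tuple[float, np.ndarray, np.ndarray, int] | None = None
    for _ in range(n_restarts):
        W0, C0 = _init_factors(M, n_synergies, rng)
        W, C, err, it = _multiplicative_fit(M, W0, C0, max_iter, tol, update_w=True)
        if best is None or err < best[0]:
            best = (err, W, C, it)
    err, W, C, it = best
    W, C = normalize_synergy(W, C)
    return SynergySet(W, C, n_synergies, err, it)


def update_activations_fixed_w(
    M_test: np.ndarray,
    W_fixed: np.ndarray,
    seed: int = 0,
    max_iter: int = 1000,
    tol: float = 1e-6,
) -> np.ndarray:
    """Re-estimate activations C on held-out data with the weightings frozen."""
    M_test = _check_nonneg(M_test)
    W_fixed = np.asarray(W_fixed, dtype=float)
    if W_fixed.shape[0] != M_test.shape[0]:
        raise NmfError(
            f"W has {W_fixed.shape[0]} muscle rows but M_test has {M_test.shape[0]}"
        )
    rng = np.random.default_rng(seed)
    _, C0 = _init_factors(M_test, W_fixed.shape[1], rng)
    _, C, _, _ = _multiplicative_fit(M_test, W_fixed.copy(), C0, max_iter, tol,
                                     update_w=False)
    return C


def vaf(original: np.ndarray, reconstructed: np.ndarray, scope: str = "global") -> np.ndarray | float:
    """Variability accounted for, in percent.

    VAF = 100 * (1 - SS_res / SS_tot) with *uncentered* sums of squares,
    either over the whole matrix (``global``) or per muscle row
    (``per_muscle``).
    """
    o = np.asarray(original, dtype=float)
    r = np.asarray(reconstructed, dtype=float)
    if o.shape != r.shape:
        raise NmfError(f"shape mismatch {o.shape} vs {r.shape}")
    if scope == "global":
        ss_tot = float(np.sum(o ** 2))
        if ss_tot == 0:
            raise NmfError("VAF undefined: original matrix is all zero")
        return 100.0 * (1.0 - np.sum((o - r) ** 2) / ss_tot)
    if scope == "per_muscle":
        ss_tot = np.sum(o ** 2, axis=1)
        if np.any(ss_tot == 0):
            raise NmfError("VAF undefined: a muscle row is all zero")
        return 100.0 * (1.0 - np.sum((o - r) ** 2, axis=1) / ss_tot)
    raise NmfError(f"scope must be 'global' or 'per_muscle', got {scope!r}")


# ---------------------------------------------------------------------------
# model selection


def _split_cycles(n_cycles: int, train_frac: float, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    n_train = int(round(train_frac * n_cycles))
    perm = rng.permutation(n_cycles)
    return np.sort(perm[:n_train]), np.sort(perm[n_train:])


def _cycle_columns(cycles: np.ndarray) -> np.ndarray:
    # the 100 phase columns of a cycle always travel together
    return (cycles[:, None] * PHASE_POINTS + np.arange(PHASE_POINTS)[None, :]).ravel()


def cross_validated_vaf(
    M: np.ndarray,
    n_range: range | list[int] | np.ndarray = range(1, 13),
    n_repeats: int = 10,
    train_frac: float = 0.6,
    seed: int = 0,
    muscles: list[str] | None = None,
    n_restarts: int = 2,
    max_iter: int = 500,
    tol: float = 1e-6,
) -> VafTable:
    """Cross-validated VAF over candidate synergy counts.

    Each repetition draws a seeded random split of whole gait cycles
    (default 18 train / 12 test from 30 at 60%), fits W on the training
    cycles, re-fits C on the test cycles with W fixed, and scores global
    and per-muscle VAF on the held-out reconstruction.
    """
    M = _check_nonneg(M)
    if M.shape[1] % PHASE_POINTS != 0:
        raise NmfError("M's columns must form whole 100-point cycles")
    if n_repeats < 2:
        raise NmfError("n_repeats must be >= 2 to form a confidence interval")
    n_cycles = M.shape[1] // PHASE_POINTS
    n_range = np.asarray(list(n_range), dtype=int)
    rng = np.random.default_rng(seed)
    rep_seeds = rng.integers(0, 2 ** 31 - 1, size=n_repeats)
    g = np.empty((len(n_range), n_repeats))
    m = np.empty((len(n_range), n_repeats, M.shape[0]))
    for r, rs in enumerate(rep_seeds):
        rep_rng = np.random.default_rng(rs)
        train, test = _split_cycles(n_cycles, train_frac, rep_rng)
        M_train = M[:, _cycle_columns(train)]
        M_test = M[:, _cycle_columns(test)]
        for a, n in enumerate(n_range):
            fit = nmf(M_train, n, seed=int(rs) + a, max_iter=max_iter, tol=tol,
                      n_restarts=n_restarts)
            C_test = update_activations_fixed_w(M_test, fit.W, seed=int(rs) + a,
                                                max_iter=max_iter, tol=tol)
            rec = fit.W @ C_test
            g[a, r] = vaf(M_test, rec, "global")
            m[a, r] = vaf(M_test, rec, "per_muscle")
    return VafTable(n_range, g, m, muscles or [], n_repeats)


def select_num_synergies(
    table: VafTable,
    global_threshold: float = 90.0,
    muscle_threshold: float = 75.0,
) -> int:
    """Smallest N whose 95% CI lower bounds exceed both VAF thresholds.

    The global-VAF lower bound must exceed ``global_threshold`` and every
    muscle's lower bound must exceed ``muscle_threshold`` (strict >).
    """
    glo = table.global_ci_lower
    mlo = table.muscle_ci_lower
    for i, n in enumerate(table.n_range):
        if glo[i] > global_threshold and np.all(mlo[i] > muscle_threshold):
            return int(n)
    raise NoSelectionError(
        f"no synergy count in {table.n_range.tolist()} cleared the "
        f"{global_threshold}% global / {muscle_threshold}% per-muscle rule",
        table,
    )


def shuffle_control(M: np.ndarray, seed: int = 0) -> np.ndarray:
    """Independently permute each muscle row over all time columns.

    Preserves every muscle's values, range and variance while destroying
    the between-muscle relationships that synergies encode.
    """
    M = np.asarray(M, dtype=float)
    rng = np.random.default_rng(seed)
    out = np.empty_like(M)
    for i in range(M.shape[0]):
        out[i] = M[i, rng.permutation(M.shape[1])]
    return out


# ---------------------------------------------------------------------------
# similarity and sorting


def normalize_synergy(W: np.ndarray, C: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Rescale so each weighting column is a unit vector; W@C is unchanged."""
    W = np.asarray(W, dtype=float)
    C = np.asarray(C, dtype=float)
    norms = np.linalg.norm(W, axis=0)
    if np.any(norms == 0):
        raise NmfError("degenerate synergy: a weighting column is all zero")
    return W / norms[None, :], C * norms[:, None]


def cosine_similarity(u: np.ndarray, v: np.ndarray) -> float:
    """dot(u, v) / (||u|| ||v||); in [0, 1] for non-negative inputs."""
    u = np.asarray(u, dtype=float).ravel()
    v = np.asarray(v, dtype=float).ravel()
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0 or nv == 0:
        raise NmfError("cosine similarity undefined for a zero vector")
    return float(u @ v / (nu * nv))


def critical_correlation(alpha: float = 0.01, df: int = 10) -> float:
    """Two-tailed critical Pearson correlation for the given alpha and df.

    r_crit = t / sqrt(df + t^2) with t the two-tailed critical t value.
    At alpha = 0.01 and df = 10 this is ~0.708, i.e. 0.71 at two decimals
    — the similarity threshold used for synergy sorting.
    """
    t = stats.t.ppf(1.0 - alpha / 2.0, df)
    return float(t / np.sqrt(df + t ** 2))


def mean_waveform(C: np.ndarray) -> np.ndarray:
    """Average each activation row over gait cycles -> (N, 100) waveforms."""
    C = np.atleast_2d(np.asarray(C, dtype=float))
    if C.shape[1] % PHASE_POINTS != 0:
        raise NmfError("activation length must be a multiple of 100")
    return C.reshape(C.shape[0], -1, PHASE_POINTS).mean(axis=1)


def _similarity(u, v, metric: str) -> float:
    if metric == "cosine":
        return cosine_similarity(u, v)
    if metric == "pearson":
        return float(np.corrcoef(np.ravel(u), np.ravel(v))[0, 1])
    raise NmfError(f"unknown similarity metric {metric!r}")


def _match_one_trial(
    W: np.ndarray,
    wave: np.ndarray,
    ref_W: np.ndarray,
    ref_wave: np.ndarray,
    threshold: float,
    metric: str,
) -> tuple[np.ndarray, np.ndarray]:
    """Greedy best-first matching of one trial's synergies to reference groups.

    A (synergy, group) pair is eligible when the similarity of W *or* of
    the activation waveform exceeds the threshold; within-trial conflicts
    keep the highest-similarity pair and re-queue the loser.
    """
    n, n_ref = W.shape[1], ref_W.shape[1]
    score = np.full((n, n_ref), -np.inf)
    for i in range(n):
        for j in range(n_ref):
            sw = _similarity(W[:, i], ref_W[:, j], metric)
            sc = _similarity(wave[i], ref_wave[j], metric)
            if sw > threshold or sc > threshold:
                score[i, j] = max(sw, sc)
    labels = np.full(n, -1, dtype=int)
    sims = np.zeros(n)
    order = np.dstack(np.unravel_index(np.argsort(score, axis=None)[::-1], score.shape))[0]
    taken_syn, taken_grp = set(), set()
    for i, j in order:
        if score[i, j] == -np.inf:
            break
        if i in taken_syn or j in taken_grp:
            continue
        labels[i] = j
        sims[i] = score[i, j]
        taken_syn.add(i)
        taken_grp.add(j)
    return labels, sims


def match_synergies(
    trial_sets: list[SynergySet],
    threshold: float = 0.71,
    metric: str = "cosine",
) -> SynergyGrouping:
    """Sort synergies across trials into functional groups.

    Two-stage procedure: (1) match every trial against an arbitrary
    reference trial (the first), accepting a match when the similarity of
    W or of the cycle-averaged activation waveform exceeds the threshold;
    (2) average the matched groups and re-match all trials against the
    group means under the same rule.  Synergies below threshold stay
    unmatched (label -1) rather than being forced into a group.
    """
    if not trial_sets:
        raise NmfError("no trials to match")
    n_muscles = trial_sets[0].W.shape[0]
    for s in trial_sets:
        if s.W.shape[0] != n_muscles:
            raise NmfError("all trials must share the same muscle ordering/count")
    waves = [mean_waveform(s.C) for s in trial_sets]

    ref_W, ref_wave = trial_sets[0].W, waves[0]
    stage1 = [
        _match_one_trial(s.W, w, ref_W, ref_wave, threshold, metric)
        for s, w in zip(trial_sets, waves)
    ]

    # group means over stage-1 assignments
    n_groups = ref_W.shape[1]
    mean_W = np.zeros((n_muscles, n_groups))
    mean_wave = np.zeros((n_groups, PHASE_POINTS))
    counts = np.zeros(n_groups)
    for (labels, _), s, w in zip(stage1, trial_sets, waves):
        for i, g in enumerate(labels):
            if g >= 0:
                mean_W[:, g] += s.W[:, i]
                mean_wave[g] += w[i]
                counts[g] += 1
    nonempty = counts > 0
    mean_W[:, nonempty] /= counts[nonempty]
    mean_wave[nonempty] /= counts[nonempty, None]
    # empty groups keep the reference's entry so stage 2 is total
    mean_W[:, ~nonempty] = ref_W[:, ~nonempty]
    mean_wave[~nonempty] = ref_wave[~nonempty]

    labels, sims = [], []
    for s, w in zip(trial_sets, waves):
        lab, sim = _match_one_trial(s.W, w, mean_W, mean_wave, threshold, metric)
        labels.append(lab)
        sims.append(sim)
    return SynergyGrouping(labels, sims, threshold, metric, "group-mean (two-stage)")
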