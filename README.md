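# synstab

Stability analysis of muscle-synergy activations extracted from
multi-channel walking EMG.

During walking, the central nervous system appears to coordinate muscles
through a small number of *muscle synergies*: fixed non-negative muscle
weightings **W** driven by shared time-varying activation coefficients
**C**.  `synstab` extracts these synergies from surface EMG by
non-negative matrix factorization and then asks how stable the activation
time courses themselves are, in two complementary senses:

- **Local dynamic stability** — how fast infinitesimally close
  trajectories of the activation's reconstructed state space diverge,
  measured by the short-term maximum Lyapunov exponent λ\*
  (Rosenstein nearest-neighbor divergence over 0–1 stride).
- **Orbital stability** — how strongly the activation's limit cycle
  pulls back stride-to-stride perturbations, measured by maximum Floquet
  multiplier magnitudes of linearized Poincaré maps fit at each percent
  of the gait cycle.

The package is aimed at motor-control and gait researchers who have
multi-channel EMG with heel-contact events (or want to prototype against
synthetic data with known ground truth) and want the full chain —
preprocessing, factorization, model selection, embedding, and both
stability estimators — as tested, scriptable building blocks.

## The model

The preprocessed EMG matrix **M** (muscles × time, 100 phase points per
gait cycle) is factorized as

    M = Σᵢ Wᵢ Cᵢ + ε ,   Wᵢ ≥ 0, Cᵢ ≥ 0

by Lee–Seung multiplicative updates minimizing the Frobenius residual,
with each weighting column normalized to a unit vector.  Reconstruction
quality is the variability accounted for,

    VAF = [1 − Σ(M − M̂)² / ΣM²] × 100 ,

with uncentered sums of squares, computed globally and per muscle on
held-out gait cycles (60/40 cross-validation over whole cycles, 10
repetitions).  The number of synergies is the smallest N whose 95% CI
lower bounds exceed 90% (global) and 75% (every muscle).

Each activation Cᵢ is embedded by delay coordinates,

    S(t) = [q(t), q(t+τ), …, q(t+(d_E−1)τ)] ,

with τ from the first minimum of average mutual information and d_E from
global false-nearest-neighbor analysis (unified to d_E = 6 by default).
λ\* is the slope of the mean log nearest-neighbor divergence curve over
one stride (in nats/stride); Floquet multipliers are eigenvalues of the
least-squares Jacobian J of the stride-to-stride return map
S_{k+1} − S* ≈ J (S_k − S*) at each of the 100 Poincaré sections, with
the fixed point S* taken as the mean trajectory.  |FM| < 1 means
orbitally stable.

## Worked example

No recordings are needed: the synthetic-data module generates raw-like
12-channel EMG at 1 kHz from 5 known synergies with controllable
cycle-to-cycle variability.

```python
import synstab as ss

rec, truth = ss.synthesize_raw_recording(ss.SynthConfig(seed=0))
matrix = ss.preprocess(rec)                      # 12 muscles x 3000 steps

table = ss.cross_validated_vaf(matrix.values, range(1, 9), n_repeats=10, seed=0)
n = ss.select_num_synergies(table)               # 95% CI rule: >90% / >75%
print("selected synergies:", n)

fit = ss.nmf(matrix.values, n, seed=0, n_restarts=20)
for i in range(n):
    lres, emb = ss.lyapunov_from_series(fit.C[i], d=6)
    fres = ss.floquet_from_series(fit.C[i], tau=emb.tau, d=6)
    print(f"synergy {i+1}: tau={emb.tau:>2}  lambda*={lres.lambda_star:+.3f} "
          f"nats/stride  FM={fres.fm_mean:.3f}  stable={fres.orbitally_stable}")
```

prints

```
selected synergies: 5
synergy 1: tau=23  lambda*=+0.486 nats/stride  FM=0.520  stable=True
synergy 2: tau=16  lambda*=+1.092 nats/stride  FM=0.507  stable=True
synergy 3: tau=19  lambda*=+0.808 nats/stride  FM=0.607  stable=True
synergy 4: tau=28  lambda*=+0.359 nats/stride  FM=0.520  stable=True
synergy 5: tau=23  lambda*=+0.500 nats/stride  FM=0.544  stable=True
```

The selection finds the 5 generating synergies; every λ\* is positive
(nearby trajectories diverge locally — the stochastic cycle-to-cycle
variability guarantees this) while every Floquet summary is well below 1
(the limit cycle reabsorbs stride-scale perturbations).  Embedding delays
fall around 20% of the gait cycle.  Raising the generator's variability
scale raises λ\* monotonically and leaves FM essentially unchanged.

A CLI mirrors the library: `synstab simulate`, `synstab preprocess`,
`synstab synergies`, `synstab stability`, `synstab trends`, and
`synstab run` for the end-to-end pipeline with a JSON run manifest.

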