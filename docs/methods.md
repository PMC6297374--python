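# Methods

## Overview

`synstab` implements a complete chain for quantifying the stability of
muscle-synergy activations during treadmill walking: EMG conditioning and
gait-cycle normalization, non-negative matrix factorization (NMF) with
cross-validated model selection, delay-coordinate state-space
reconstruction, short-term maximum Lyapunov exponents (local dynamic
stability), maximum Floquet multipliers (orbital stability), and
speed-band regression slopes.  A synthetic-data module generates every
input the chain needs with known ground truth, so all stages are testable
without recordings.

## EMG preprocessing

Raw multi-channel EMG plus right-heel-contact sample indices become a
normalized muscles × 3000 matrix through a fixed order of operations:
zero-lag 4th-order Butterworth high-pass at 40 Hz, full-wave
rectification, zero-lag 4th-order low-pass at 10 Hz (the linear
envelope), segmentation into gait cycles `[hc_k, hc_{k+1})`, linear
time-interpolation of each cycle onto 100 phase points, retention of 30
steady-state cycles, then per-muscle peak normalization followed by
per-muscle unit-variance normalization.

Choices where the convention was open:

- *Zero lag* is realized as forward–backward application (`sosfiltfilt`
  with its default reflective padding), so the effective magnitude
  response is the squared 4th-order Butterworth.  The test suite checks a
  200 Hz carrier against the analytic squared response.
- *Interpolation grid*: phase k maps to time k/100 of the cycle duration,
  k = 0..99, endpoint excluded, so consecutive cycles tile without
  duplicating the heel-contact sample; a cycle already on the grid
  round-trips exactly.
- *Cycle retention*: drop exactly the first 10 cycles, keep the next 30,
  and require ≥ 10 after them.  Recordings longer than the 50-cycle
  minimum therefore keep the same early steady-state window.
- *Normalization*: the peak is each muscle's own maximum (per-muscle
  reading of the convention), and the SD is the population SD (ddof 0).
  Both divisors are stored in a JSON normalization record so either
  convention can be audited.  Display-only demeaning is not applied
  anywhere in the analysis path.
- The envelope is clipped at zero after low-pass filtering: the filter
  can undershoot slightly, and the downstream domain is non-negative.

## Synergy extraction and model selection

NMF uses Lee–Seung multiplicative updates for the Euclidean objective,
with 1e-12 added to denominators, convergence at relative residual change
< 1e-6 or 1,000 iterations, and best-of-20 seeded restarts (W and C
initialized uniform in (0, 1] scaled to the matrix mean).  Weighting
columns are rescaled to unit vectors with the inverse scale folded into
the activations, leaving W·C unchanged.

Selection works on cross-validated VAF (uncentered, in percent): each of
10 repetitions draws a seeded random split of whole cycles — 18 training
/ 12 test from 30 at a 60% fraction, the 100 columns of a cycle always
traveling together — fits W on the training cycles, re-fits C on the test
cycles with W frozen, and scores global and per-muscle VAF on the
held-out reconstruction.  The 95% CI across repetitions uses the
t-distribution (df = 9).  The selected N is the smallest whose global
lower bound strictly exceeds 90% and every muscle's lower bound strictly
exceeds 75%; per-muscle thresholds apply to all muscles.  Inside
cross-validation the per-fit budget is reduced (2 restarts, 500
iterations) — the repetition-and-CI machinery, not per-fit polish, is
what stabilizes the VAF estimates, and the acceptance checks confirm
selection is correct with wide margins at this budget.

The shuffled control permutes each muscle row independently over all time
columns, preserving each muscle's value multiset (hence range and
variance) while destroying between-muscle structure; its cross-validated
VAF at the selected N falls far below the original's.

Synergy sorting across trials/subjects accepts a match when the cosine
similarity of the weighting vectors *or* of the cycle-averaged 100-point
activation waveforms exceeds 0.71 — the two-tailed critical Pearson
correlation at α = 0.01 with df = 10, which the package recomputes rather
than hard-codes.  Matching is two-stage (first against an arbitrary
reference trial, then against group means), greedy best-first with
conflict re-queuing; below-threshold synergies stay flagged unmatched.
Pearson correlation is available as an alternative metric.

## State-space reconstruction

Activations live on the 100-points-per-cycle grid, so 1 sample = 1% of
the gait cycle throughout.  The delay τ is the first local minimum of the
average mutual information (joint histogram, 16 equal-width bins over the
observed range, max lag 100); plateaus resolve to their first index and a
curve with no interior minimum falls back to the global minimum with a
flag.  On the generator's default activations the selected τ falls in
17–29 samples.  A caveat worth knowing: for *noiseless deterministic*
periodic signals the histogram AMI is nearly lag-independent (the lagged
copy is a deterministic function of the signal at every lag), so the
first-minimum rule is only meaningful for stochastic series — which
measured activations always are.

The dimension comes from Kennel's global false-nearest-neighbors analysis
(Rtol = 15, Atol = 2, the method's canonical values).  Pairs whose
d-dimensional distance is below 1e-9 of the series SD are judged by the
absolute-size criterion only, since the distance-ratio test is
0/0-unstable for the near-duplicate states exactly periodic signals
produce.  Because cycle-to-cycle stochasticity keeps FNN fractions from
vanishing on gait-like data (true of real recordings too), the pipeline
defaults to a unified embedding dimension d_E = 6 across subjects and
synergies, recorded as "unified" in outputs; per-activation FNN selection
remains available.

## Local dynamic stability (short-term maximum Lyapunov exponent)

Rosenstein's method on the embedded trajectory: each state is paired with
its nearest Euclidean neighbor more than a Theiler window of 100 samples
(one stride, the mean period) away in time, ties broken toward the
smaller index.  The divergence curve averages ln‖·‖ of pair separations
over discrete steps to a horizon of 1,000 samples (clipped to the
trajectory length); pairs truncate at the data boundary and exact
duplicates (ln 0 undefined, no divergence information) are excluded.  λ\*
is the ordinary least-squares slope over steps 0–100 inclusive, times 100
— i.e. nats per stride, the unit recorded in all outputs.  Positive λ\*
means local divergence.  The estimator reproduces the logistic map's
analytic exponent (ln 2 at r = 4) within a few tenths of a percent at
n = 3000, and an exact linear contraction's slope to machine precision.

## Orbital stability (maximum Floquet multipliers)

The embedded activation is sampled once per stride at each percent of the
gait cycle, giving exactly 100 Poincaré sections per trial; stride k's
state at phase p starts at sample k·100 + (p−1), and strides whose
embedding window (d_E−1)τ runs past the series end are dropped from the
affected sections only (with 30 strides, d_E = 6, τ = 20 every section
keeps ≥ 27 states).  At each section the fixed point S* is the mean state
(the average trajectory), and J is the least-squares solution of
S_{k+1} − S* ≈ J (S_k − S*) over consecutive-stride pairs via
pseudoinverse (machine-default tolerance; rank-deficient deviations yield
the least-norm solution plus a flag).  The per-section statistic is the
maximum eigenvalue modulus of J; the trial summary reports both the mean
across sections (the default stability verdict, < 1 ⇒ orbitally stable)
and the max.

Estimator accuracy is checked on linear stride systems with known
spectral radius.  Identifiability needs the section states to excite all
d_E directions: a single noiseless contracting orbit decays onto its
leading eigendirection and cannot determine J, so the oracle sections
combine several short orbits from random (sign-symmetric) starts — then
noiseless recovery is exact to machine precision and a radius-0.5 system
observed with ~1% noise is recovered within 10% across seeds.

## Speed trends

The "increasing rate" of a stability measure is its OLS slope against
walking speed, fit separately in a slower band (2.0–5.0 km/h) and a
faster band (5.0–8.0 km/h; the 5.0 point belongs to both, following the
figure convention — a 5.5 km/h lower edge, stated elsewhere in the source
conventions, is available as a switch and flagged in output metadata).
A (subject, synergy) that covers fewer than half of a band's speeds (e.g.
a synergy recruited only from the band's upper edge) is returned as
not-computed rather than fit from the edge.  Paired fast-minus-slow slope
differences are returned for downstream testing; the hypothesis tests
themselves (ANOVA, post hoc, normality, paired t) are delegated to
standard statistical routines and deliberately not reimplemented.

## Synthetic data: what it emulates, and what it does not

The generator inverts the analysis model.  Defaults are the study
conditions the pipeline targets: 12 muscles at 1,000 Hz, 50 gait cycles
of ~1,000 samples with ±10% duration jitter, 5 synergies, 5% additive
noise.  Weightings are unit-norm columns with disjoint dominant muscle
clusters (pairwise cosine < 0.6 enforced by seeded rejection), mirroring
the largely distinct functional groups of level walking.  Each synergy's
activation is one circular Gaussian bump per cycle — centers at
(15, 40, 60, 80, 95)% of the cycle with widths (7, 6, 6, 5, 5)% —
representing loading response/body support, forward propulsion (peaking
at 40% of the cycle), swing initiation, mid-swing and late-swing leg
deceleration.  Cycle-to-cycle variability enters through the bump
parameters: per-cycle center and amplitude follow stationary AR(1)
dynamics (ρ = 0.3; innovation SDs 1% of the cycle and 10% relative,
respectively), so local divergence is controllable while the mean cycle
stays fixed; a single variability scale multiplying both innovation SDs
is the "speed-like" knob for sweeps.  `observed_activations` adds the
5% noise to the activation series themselves, emulating the estimation
noise extracted coefficients always carry — noise-free bumps would leave
the per-section deviation cloud effectively rank-2 and the Jacobian fit
overdetermined only in appearance.  Raw mode up-samples the envelopes to
1 kHz and multiplies in a 40–450 Hz band-limited carrier so the
preprocessing chain is exercised from raw-like input; n_cycles + 1 heel
contacts delimit n_cycles complete cycles.

What passing tests on this generator do *not* show about real data: the
bumps are unimodal and symmetric where real activations can be multimodal
and skewed; muscle weightings are constant across speeds by construction;
duration jitter is independent across cycles (no long-range stride-time
correlations); noise is white and clipping at zero slightly biases
near-zero phases upward; and no crosstalk, electrode, or movement
artifacts are simulated.  Absolute λ\* and FM values from the generator
are therefore not comparable to recordings — only the estimators'
correctness and the qualitative pattern (rising λ\*, flat FM under rising
variability) transfer.

## Problem sizes

Matrices are 12 × 3000 throughout (30 cycles × 100 phases).
Cross-validation scans N = 1..8 with 10 repetitions in the acceptance
checks; multi-seed checks use 10 seeds for selection/recovery and the
variability sweep, 5 seeds for the shuffle control; the sweep covers 5
variability scales.  The full test suite runs in about 4 minutes and the
acceptance script in about half a minute on one CPU.

## Known limitations

- The AMI first-minimum rule is undefined in principle for noiseless
  deterministic periodic series (see above); the fallback flag reports
  when no interior minimum exists.
- Short-term λ\* and FM need not agree on "stability": divergence curves
  of stochastic periodic processes always show positive short-term
  slopes, so positive λ\* coexists with FM < 1.  The package reports both
  without reconciling them.
- The Floquet Jacobian is fit without regularization; with few strides
  and large d_E the per-section estimates are noisy, which is why the
  trial summary averages 100 sections.
- Multipliers are reported as magnitudes with a verdict; the full Floquet
  spectrum and long-term Lyapunov exponents are out of scope.
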