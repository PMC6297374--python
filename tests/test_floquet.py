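"""Poincare sections, Jacobian fits and maximum Floquet multipliers."""

import numpy as np
import pytest

import synstab as ss
from synstab.floquet import (
    PoincareSection,
    build_sections,
    fit_jacobian,
    floquet_summary,
    max_floquet_multiplier,
)


def _random_contraction(rng, d, radius):
    A = rng.uniform(-0.4, 0.4, (d, d))
    return A * (radius / np.abs(np.linalg.eigvals(A)).max())


def _multi_orbit_section(A, n_orbit_pairs, strides_per_orbit, noise_sd, seed):
    """Section states from several short orbits of the stride recurrence.

    Starts come in sign-symmetric pairs so the sample-mean fixed point
    equals the true S* (= 0) exactly in the noiseless case.
    """
    rng = np.random.default_rng(seed)
    d = A.shape[0]
    blocks, ids = [], []
    off = 0
    for o in range(n_orbit_pairs):
        S0 = rng.standard_normal(d)
        for sgn in (1.0, -1.0):
            st = ss.linear_stride_system(A, np.zeros(d), strides_per_orbit,
                                         noise_sd, seed=seed * 97 + off,
                                         S0=sgn * S0)
            blocks.append(st)
            ids.append(np.arange(strides_per_orbit) + off * (strides_per_orbit + 1))
            off += 1
    return PoincareSection(1, np.vstack(blocks), np.concatenate(ids))


class TestBuildSections:
    def test_always_100_sections(self, activation_series):
        sections = build_sections(activation_series, tau=20, d=6)
        assert len(sections) == 100
        assert [s.phase for s in sections] == list(range(1, 101))

    def test_boundary_rule_index_arithmetic(self, activation_series):
        # 30 strides, d=6, tau=20: embedding window 100 samples; states
        # starting at sample >= 2900 have no full window, so stride 30 is
        # dropped wherever affected and every section keeps >= 27 states
        sections = build_sections(activation_series, tau=20, d=6)
        n_states = 3000 - 5 * 20
        for s in sections:
            starts = s.strides * 100 + (s.phase - 1)
            assert np.all(starts < n_states)
            assert len(s.states) >= 27

    def test_fixed_point_is_mean_state(self, activation_series):
        sec = build_sections(activation_series, tau=20, d=6)[39]
        assert np.allclose(sec.fixed_point, sec.states.mean(axis=0), atol=1e-12)

    def test_too_few_strides_rejected(self):
        with pytest.raises(ss.FloquetError):
            build_sections(np.random.default_rng(0).random(200), tau=5, d=6)


class TestFitJacobian:
    def test_noiseless_multi_orbit_recovery_exact(self):
        rng = np.random.default_rng(42)
        A = _random_contraction(rng, 6, 0.5)
        sec = _multi_orbit_section(A, 4, 5, 0.0, seed=3)
        J, flags = fit_jacobian(sec)
        assert np.abs(J - A).max() < 1e-8
        assert flags == []

    def test_all_states_at_fixed_point_degenerate(self):
        states = np.tile(np.array([1.0, 2.0, 3.0]), (10, 1))
        sec = PoincareSection(1, states, np.arange(10))
        J, flags = fit_jacobian(sec)
        assert np.allclose(J, 0.0)
        assert "rank_deficient" in flags

    def test_noisy_radius_recovered_within_10pct(self):
        errs = []
        for seed in range(10):
            rng = np.random.default_rng(100 + seed)
            A = _random_contraction(rng, 4, 0.5)
            sec = _multi_orbit_section(A, 3, 5, 0.006, seed=seed)  # ~1% of dev SD
            J, _ = fit_jacobian(sec)
            errs.append(abs(max_floquet_multiplier(J) - 0.5) / 0.5)
        assert max(errs) < 0.10

    def test_too_few_pairs_rejected(self):
        states = np.random.default_rng(1).standard_normal((4, 6))
        sec = PoincareSection(1, states, np.arange(4))
        with pytest.raises(ss.FloquetError):
            fit_jacobian(sec)


class TestMaxMultiplier:
    def test_diagonal(self):
        assert max_floquet_multiplier(np.diag([0.5, 0.2, 0.1])) == 0.5

    def test_rotation_on_unit_circle(self):
        th = 0.7
        R = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        assert np.isclose(max_floquet_multiplier(R), 1.0)

    def test_companion_double_root(self):
        # z^2 - z + 0.25 = (z - 0.5)^2
        Cm = np.array([[1.0, -0.25], [1.0, 0.0]])
        assert np.isclose(max_floquet_multiplier(Cm), 0.5)

    def test_non_square_rejected(self):
        with pytest.raises(ss.FloquetError):
            max_floquet_multiplier(np.ones((2, 3)))


class TestSummary:
    def test_uniform_sections(self):
        res = floquet_summary(np.full(100, 0.7))
        assert res.fm_mean == pytest.approx(0.7)
        assert res.fm_max == pytest.approx(0.7)
        assert res.orbitally_stable

    def test_policy_changes_verdict(self):
        mags = np.full(100, 0.5)
        mags[17] = 1.2
        mean_res = floquet_summary(mags, "mean")
        max_res = floquet_summary(mags, "max")
        assert np.isclose(mean_res.fm_mean, 0.507)
        assert mean_res.orbitally_stable
        assert max_res.fm_max == 1.2 and not max_res.orbitally_stable

    def test_stride_system_summary_brackets_radius(self):
        # periodic orbit whose per-stride return map has radius 0.5: the
        # trial summary should land near 0.5 across seeds
        ests = []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            A = _random_contraction(rng, 4, 0.5)
            sec = _multi_orbit_section(A, 4, 5, 0.004, seed=seed)
            J, _ = fit_jacobian(sec)
            ests.append(max_floquet_multiplier(J))
        assert 0.45 <= np.mean(ests) <= 0.55


class TestLinearizationProperties:
    def test_multiplier_converges_as_noise_vanishes(self):
        rng = np.random.default_rng(7)
        A = _random_contraction(rng, 4, 0.6)
        errs = []
        for noise in (0.0, 0.001, 0.01):
            sec = _multi_orbit_section(A, 4, 5, noise, seed=11)
            J, _ = fit_jacobian(sec)
            errs.append(abs(max_floquet_multiplier(J) - 0.6))
        assert errs[0] < 1e-8
        assert errs[0] <= errs[1] <= errs[2] + 1e-6

    def test_fitted_map_contracts_toward_fixed_point(self):
        rng = np.random.default_rng(8)
        A = _random_contraction(rng, 4, 0.5)
        sec = _multi_orbit_section(A, 4, 5, 0.004, seed=12)
        J, _ = fit_jacobian(sec)
        dev = np.ones(4)
        for _ in range(20):
            dev = J @ dev
        assert np.linalg.norm(dev) < 1e-3

    def test_fitted_unstable_map_grows(self):
        rng = np.random.default_rng(9)
        A = _random_contraction(rng, 4, 1.3)
        sec = _multi_orbit_section(A, 4, 5, 0.004, seed=13)
        J, _ = fit_jacobian(sec)
        assert max_floquet_multiplier(J) > 1.0
        dev0 = np.ones(4)
        dev = dev0.copy()
        for _ in range(20):
            dev = J @ dev
        assert np.linalg.norm(dev) > np.linalg.norm(dev0)

    def test_similarity_invariance(self):
        rng = np.random.default_rng(10)
        A = _random_contraction(rng, 4, 0.5)
        P = rng.standard_normal((4, 4)) + 4 * np.eye(4)
        B = P @ A @ np.linalg.inv(P)  # same spectrum
        est = []
        for M in (A, B):
            sec = _multi_orbit_section(M, 4, 5, 0.0, seed=14)
            J, _ = fit_jacobian(sec)
            est.append(max_floquet_multiplier(J))
        assert np.isclose(est[0], est[1], rtol=1e-6)


class TestEndToEndSeries:
    def test_gait_activation_is_orbitally_stable(self, activation_series):
        res = ss.floquet_from_series(activation_series, d=6)
        assert len(res.per_section) == 100
        assert res.fm_mean <= res.fm_max
        assert res.orbitally_stable

    def test_flat_across_variability_sweep(self):
        fms = []
        for sc in (0.5, 1.5, 2.5):
            cfg = ss.SynthConfig(seed=2, phase_jitter_sd=1.0 * sc,
                                 amp_noise_sd=0.10 * sc)
            C, _ = ss.observed_activations(cfg)
            vals = [ss.floquet_from_series(C[i, 1000:4000], d=6).fm_mean
                    for i in range(5)]
            fms.append(np.mean(vals))
        assert (max(fms) - min(fms)) / np.mean(fms) < 0.15
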