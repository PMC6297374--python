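"""NMF extraction, VAF model selection, shuffle control and synergy sorting."""

import numpy as np
import pytest

import synstab as ss
from synstab.synergy_nmf import _multiplicative_fit, _init_factors


def _random_factors(rng, n_muscles=8, n_syn=3, T=400):
    W = rng.random((n_muscles, n_syn)) + 0.1
    C = rng.random((n_syn, T)) + 0.1
    return W, C


class TestNmf:
    def test_exact_product_recovered(self):
        rng = np.random.default_rng(0)
        W0, C0 = _random_factors(rng, n_syn=2)
        M = W0 @ C0
        fit = ss.nmf(M, 2, seed=1, n_restarts=5)
        assert ss.vaf(M, fit.reconstruct()) > 99.9

    def test_capacity_monotone_in_n(self, gait_matrix):
        M, _ = gait_matrix
        M = M[:, :600]
        errs = [ss.nmf(M, n, seed=2, n_restarts=3, max_iter=300).reconstruction_error
                for n in (2, 5, 12)]
        assert errs[2] <= errs[1] <= errs[0]

    def test_negative_entries_rejected(self):
        M = np.ones((3, 100))
        M[0, 0] = -1e-3
        with pytest.raises(ss.NmfError):
            ss.nmf(M, 2)

    def test_n_out_of_range_rejected(self):
        with pytest.raises(ss.NmfError):
            ss.nmf(np.ones((3, 100)), 4)

    def test_factors_nonnegative_and_unit_norm(self):
        rng = np.random.default_rng(3)
        M = rng.random((6, 300))
        fit = ss.nmf(M, 3, seed=3, n_restarts=2, max_iter=200)
        assert np.all(fit.W >= 0) and np.all(fit.C >= 0)
        assert np.allclose(np.linalg.norm(fit.W, axis=0), 1.0, atol=1e-9)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_residual_monotone_under_updates(self, seed):
        rng = np.random.default_rng(seed)
        M = rng.random((6, 200))
        W, C = _init_factors(M, 3, rng)
        errs = [np.linalg.norm(M - W @ C)]
        for _ in range(30):
            W, C, err, _ = _multiplicative_fit(M, W, C, max_iter=1, tol=0.0,
                                               update_w=True)
            errs.append(err)
        assert np.all(np.diff(errs) <= 1e-10)

    def test_deterministic_given_seed(self):
        M = np.random.default_rng(4).random((5, 200))
        a = ss.nmf(M, 2, seed=9, n_restarts=3, max_iter=100)
        b = ss.nmf(M, 2, seed=9, n_restarts=3, max_iter=100)
        assert np.array_equal(a.W, b.W) and np.array_equal(a.C, b.C)


class TestFixedWUpdate:
    def test_indicator_design_recovers_traces(self):
        rng = np.random.default_rng(5)
        n_muscles, T = 6, 500
        W_fixed = np.eye(n_muscles)[:, :3] + 0.01 * rng.random((n_muscles, 3))
        C0 = rng.random((3, T))
        M = W_fixed @ C0
        C = ss.update_activations_fixed_w(M, W_fixed, seed=5)
        for i in range(3):
            r = np.corrcoef(C[i], M[i])[0, 1]
            assert r > 0.99

    def test_exact_product_vaf(self):
        rng = np.random.default_rng(6)
        W0, C0 = _random_factors(rng)
        M = W0 @ C0
        C = ss.update_activations_fixed_w(M, W0, seed=6)
        assert ss.vaf(M, W0 @ C) > 99.9

    def test_nonnegative_output(self):
        rng = np.random.default_rng(7)
        M = rng.random((5, 200))
        W = rng.random((5, 2))
        assert np.all(ss.update_activations_fixed_w(M, W, seed=7) >= 0)

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ss.NmfError):
            ss.update_activations_fixed_w(np.ones((4, 50)), np.ones((5, 2)))


class TestVaf:
    def test_perfect_reconstruction_is_100(self):
        M = np.random.default_rng(8).random((3, 40))
        assert ss.vaf(M, M) == 100.0

    def test_zero_reconstruction_is_0(self):
        M = np.random.default_rng(9).random((3, 40))
        assert np.isclose(ss.vaf(M, np.zeros_like(M)), 0.0)

    def test_hand_computed_value(self):
        o = np.array([[1.0, 2.0], [3.0, 4.0]])
        r = np.array([[1.0, 2.0], [3.0, 0.0]])
        assert np.isclose(ss.vaf(o, r), 100 * (1 - 16 / 30))

    def test_per_muscle_scope(self):
        o = np.array([[1.0, 2.0], [3.0, 4.0]])
        r = np.array([[1.0, 2.0], [0.0, 0.0]])
        per = ss.vaf(o, r, "per_muscle")
        assert np.allclose(per, [100.0, 0.0])

    def test_all_zero_original_rejected(self):
        with pytest.raises(ss.NmfError):
            ss.vaf(np.zeros((2, 10)), np.ones((2, 10)))


class TestCrossValidation:
    def test_split_is_18_train_12_test(self):
        from synstab.synergy_nmf import _split_cycles
        rng = np.random.default_rng(0)
        train, test = _split_cycles(30, 0.6, rng)
        assert len(train) == 18 and len(test) == 12
        assert len(np.intersect1d(train, test)) == 0

    def test_rank4_structure_selects_4(self):
        # constructed-rank oracle: 4 well-separated synergies + tiny noise
        cfg = ss.SynthConfig(seed=41, n_synergies=4,
                             centers=(15.0, 40.0, 65.0, 90.0),
                             widths=(7.0, 6.0, 6.0, 5.0))
        W = ss.make_weightings(n_synergies=4, seed=41)
        C, _ = ss.make_activations(cfg)
        M, _ = ss.synthesize_emg(W, C, 0.05, seed=41)
        em = ss.normalize_emg_matrix(M[:, 1000:4000])
        table = ss.cross_validated_vaf(em.values, range(3, 6), seed=41)
        assert ss.select_num_synergies(table) == 4
        # at N=3 the global bound must fail the 90% rule or a muscle the 75% rule
        i3 = 0
        assert (table.global_ci_lower[i3] <= 90.0
                or table.muscle_ci_lower[i3].min() <= 75.0)

    def test_deterministic_given_seed(self, gait_matrix):
        M, _ = gait_matrix
        a = ss.cross_validated_vaf(M, [3], n_repeats=3, seed=5, max_iter=100)
        b = ss.cross_validated_vaf(M, [3], n_repeats=3, seed=5, max_iter=100)
        assert np.array_equal(a.global_vaf, b.global_vaf)
        assert np.array_equal(a.muscle_vaf, b.muscle_vaf)

    def test_vaf_bounded_above_by_100(self, gait_matrix):
        M, _ = gait_matrix
        t = ss.cross_validated_vaf(M, [2, 5], n_repeats=3, seed=6, max_iter=200)
        assert np.all(t.global_vaf <= 100.0) and np.all(t.muscle_vaf <= 100.0)

    def test_single_repeat_rejected(self, gait_matrix):
        M, _ = gait_matrix
        with pytest.raises(ss.NmfError):
            ss.cross_validated_vaf(M, [2], n_repeats=1)


class TestSelection:
    def _table(self, glo_lo, mus_lo):
        n = len(glo_lo)
        reps = 5
        glo = np.asarray(glo_lo)[:, None] + np.zeros((n, reps))
        mus = np.asarray(mus_lo)[:, :, None].transpose(0, 2, 1) + np.zeros(
            (n, reps, np.asarray(mus_lo).shape[1]))
        return ss.VafTable(np.arange(1, n + 1), glo, mus)

    def test_first_n_meeting_both_rules(self):
        glo = [50, 80, 89, 95, 97]
        mus = [[40] * 3, [60] * 3, [70] * 3, [80] * 3, [90] * 3]
        assert ss.select_num_synergies(self._table(glo, mus)) == 4

    def test_muscle_rule_can_delay_selection(self):
        glo = [50, 80, 95, 96, 97]
        mus = [[40] * 3, [60] * 3, [70, 95, 95], [74, 95, 95], [80, 95, 95]]
        assert ss.select_num_synergies(self._table(glo, mus)) == 5

    def test_no_selection_carries_table(self):
        glo = [50, 60, 70]
        mus = [[40] * 2, [50] * 2, [60] * 2]
        with pytest.raises(ss.NoSelectionError) as exc:
            ss.select_num_synergies(self._table(glo, mus))
        assert isinstance(exc.value.table, ss.VafTable)

    def test_threshold_is_strict(self):
        # CI lower exactly at the threshold must NOT qualify
        glo = [90.0, 95.0]
        mus = [[80.0], [80.0]]
        assert ss.select_num_synergies(self._table(glo, mus)) == 2


class TestShuffleControl:
    def test_rows_are_permutations(self, gait_matrix):
        M, _ = gait_matrix
        S = ss.shuffle_control(M, seed=1)
        for i in range(M.shape[0]):
            assert np.array_equal(np.sort(S[i]), np.sort(M[i]))

    def test_between_muscle_correlation_drops(self, gait_matrix):
        M, _ = gait_matrix
        S = ss.shuffle_control(M, seed=2)
        def mean_abs_corr(X):
            c = np.corrcoef(X)
            return np.abs(c[np.triu_indices_from(c, k=1)]).mean()
        assert mean_abs_corr(S) < 0.5 * mean_abs_corr(M)

    def test_shuffled_vaf_below_original(self, gait_matrix):
        M, _ = gait_matrix
        orig = ss.cross_validated_vaf(M, [5], n_repeats=4, seed=3, max_iter=300)
        shuf = ss.cross_validated_vaf(ss.shuffle_control(M, seed=3), [5],
                                      n_repeats=4, seed=3, max_iter=300)
        assert shuf.global_mean[0] < orig.global_mean[0]


class TestSortingPrimitives:
    def test_normalize_preserves_product(self):
        rng = np.random.default_rng(10)
        W = rng.random((6, 3)) + 0.1
        C = rng.random((3, 50))
        Wu, Cs = ss.normalize_synergy(W, C)
        assert np.allclose(Wu @ Cs, W @ C, atol=1e-12)
        assert np.allclose(np.linalg.norm(Wu, axis=0), 1.0)

    def test_hand_scaled_column(self):
        W = np.array([[3.0, 1.0], [4.0, 0.0], [0.0, 0.0]])
        C = np.ones((2, 4))
        Wu, Cs = ss.normalize_synergy(W, C)
        assert np.allclose(Wu[:, 0], [0.6, 0.8, 0.0])
        assert np.allclose(Cs[0], 5.0)

    def test_zero_column_rejected(self):
        with pytest.raises(ss.NmfError):
            ss.normalize_synergy(np.zeros((3, 1)), np.ones((1, 4)))

    def test_cosine_identities(self):
        u = np.array([1.0, 0.0, 1.0])
        v = np.array([1.0, 1.0, 0.0])
        assert np.isclose(ss.cosine_similarity(u, u), 1.0)
        assert np.isclose(ss.cosine_similarity([1, 0], [0, 1]), 0.0)
        assert np.isclose(ss.cosine_similarity(u, v), 0.5)

    def test_zero_vector_rejected(self):
        with pytest.raises(ss.NmfError):
            ss.cosine_similarity([0.0, 0.0], [1.0, 0.0])

    def test_critical_correlation_at_sorting_convention(self):
        # two-tailed alpha=0.01 with df=10 -> 0.71 at two decimals
        assert round(ss.critical_correlation(0.01, 10), 2) == 0.71


class TestMatching:
    def _set(self, seed):
        rng = np.random.default_rng(seed)
        W = ss.make_weightings(8, 3, seed=seed)
        C = np.tile(rng.random((3, 100)) + 0.05, (1, 5))
        return ss.SynergySet(W, C, 3, 0.0)

    def test_identical_copies_identity_grouping(self):
        s = self._set(1)
        g = ss.match_synergies([s, s, s])
        for lab, sim in zip(g.labels, g.similarities):
            assert np.array_equal(lab, [0, 1, 2])
            assert np.allclose(sim, 1.0)

    def test_permuted_copy_recovered(self):
        s = self._set(2)
        perm = np.array([2, 0, 1])
        s2 = ss.SynergySet(s.W[:, perm], s.C[perm], 3, 0.0)
        g = ss.match_synergies([s, s2])
        assert np.array_equal(g.labels[1], perm)

    def test_dissimilar_synergies_flagged_unmatched(self):
        s = self._set(3)
        # reference with activity in completely different muscles
        W2 = np.zeros_like(s.W)
        W2[6, 0] = W2[7, 1] = W2[5, 2] = 1.0
        C2 = np.tile(np.random.default_rng(4).random((3, 100)), (1, 5))
        # make waveforms anti-aligned in time too
        C2 = np.roll(C2, 50, axis=1)
        s2 = ss.SynergySet(W2, C2, 3, 0.0)
        g = ss.match_synergies([s, s2], threshold=0.99)
        assert g.unmatched[1].any()

    def test_muscle_count_mismatch_rejected(self):
        a = self._set(5)
        W = np.random.default_rng(6).random((9, 3))
        b = ss.SynergySet(W, a.C.copy(), 3, 0.0)
        with pytest.raises(ss.NmfError):
            ss.match_synergies([a, b])
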