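import numpy as np
import pandas as pd
import pytest
from scipy.stats import ortho_group

from popcode import geometry as geo


def _random_psd(rng, n, rank=None):
    A = rng.standard_normal((n, rank or n))
    return A @ A.T


class TestSoftNormalize:
    def test_max_45_becomes_09(self):
        X = np.zeros((10, 1))
        X[3, 0] = 45.0
        assert geo.soft_normalize(X).max() == pytest.approx(0.9)

    def test_silent_unit_zeros(self):
        X = np.zeros((10, 2))
        X[:, 1] = 3.0
        out = geo.soft_normalize(X)
        np.testing.assert_array_equal(out[:, 0], 0.0)

    def test_c_zero_limit(self):
        X = np.zeros((5, 1))
        X[2, 0] = 7.0
        assert geo.soft_normalize(X, c=0.0).max() == pytest.approx(1.0)


class TestPca:
    def test_rank_one(self, rng):
        X = np.outer(rng.standard_normal(30), rng.standard_normal(6))
        p = geo.pca_decompose(X, center=False)
        assert p.explained_variance_fractions[0] == pytest.approx(1.0)

    def test_full_rank_reconstruction(self, rng):
        X = rng.standard_normal((20, 8))
        p = geo.pca_decompose(X)
        recon = p.scores @ p.loadings + p.column_means
        np.testing.assert_allclose(recon, X, atol=1e-10)

    def test_loadings_orthonormal(self, rng):
        X = rng.standard_normal((20, 8))
        p = geo.pca_decompose(X)
        np.testing.assert_allclose(p.loadings @ p.loadings.T, np.eye(8),
                                   atol=1e-10)

    def test_isotropic_noise_fractions(self, rng):
        N = 10
        fracs = []
        for T in (100, 10000):
            X = rng.standard_normal((T, N))
            p = geo.pca_decompose(X)
            fracs.append(p.explained_variance_fractions)
        # fractions approach 1/N as T grows
        assert np.abs(fracs[1] - 1 / N).max() < np.abs(fracs[0] - 1 / N).max()
        assert np.abs(fracs[1] - 1 / N).max() < 0.02

    def test_too_small_errors(self):
        with pytest.raises(ValueError):
            geo.pca_decompose(np.ones((1, 5)))


class TestParticipationRatio:
    def test_identity_dim7(self):
        assert geo.participation_ratio(np.eye(7)) == pytest.approx(7.0)

    def test_rank_one(self, rng):
        v = rng.standard_normal(9)
        assert geo.participation_ratio(np.outer(v, v)) == pytest.approx(1.0)

    def test_eigenvalues_2_1_1(self):
        Q = ortho_group.rvs(3, random_state=0)
        C = Q @ np.diag([2.0, 1.0, 1.0]) @ Q.T
        assert geo.participation_ratio(C) == pytest.approx(16.0 / 6.0)

    def test_agrees_with_eigenvalue_oracle(self, rng):
        for _ in range(20):
            C = _random_psd(rng, 12)
            lam = np.linalg.eigvalsh(C)
            oracle = lam.sum() ** 2 / (lam**2).sum()
            assert geo.participation_ratio(C) == pytest.approx(oracle, abs=1e-10)


class TestFirstPrincipalAngle:
    def test_identical_subspaces(self, rng):
        Q = np.linalg.qr(rng.standard_normal((8, 3)))[0].T
        assert geo.first_principal_angle(Q, Q) == pytest.approx(0.0, abs=1e-6)

    def test_orthogonal_1d(self):
        a = np.array([[1.0, 0.0, 0.0]])
        b = np.array([[0.0, 1.0, 0.0]])
        assert geo.first_principal_angle(a, b) == pytest.approx(90.0)

    def test_45_degrees(self):
        a = np.array([[1.0, 0.0]])
        b = np.array([[1.0, 1.0]]) / np.sqrt(2.0)
        assert geo.first_principal_angle(a, b) == pytest.approx(45.0)

    def test_symmetry_and_rotation_invariance(self, rng):
        for _ in range(10):
            Qa = np.linalg.qr(rng.standard_normal((10, 2)))[0].T
            Qb = np.linalg.qr(rng.standard_normal((10, 2)))[0].T
            ang = geo.first_principal_angle(Qa, Qb)
            assert ang == pytest.approx(geo.first_principal_angle(Qb, Qa),
                                        abs=1e-8)
            R = ortho_group.rvs(2, random_state=rng.integers(1 << 31))
            assert geo.first_principal_angle(R @ Qa, Qb) == pytest.approx(
                ang, abs=1e-8)

    def test_gram_oracle(self, rng):
        # brute-force: cos^2(theta_1) is the top eigenvalue of the Gram
        # matrix of the cross-projection
        for _ in range(20):
            Qa = np.linalg.qr(rng.standard_normal((12, 3)))[0].T
            Qb = np.linalg.qr(rng.standard_normal((12, 3)))[0].T
            M = Qa @ Qb.T
            cos2 = np.max(np.linalg.eigvalsh(M @ M.T))
            oracle = np.degrees(np.arccos(np.sqrt(np.clip(cos2, 0, 1))))
            assert geo.first_principal_angle(Qa, Qb) == pytest.approx(
                oracle, abs=1e-8)


class TestAlignmentIndex:
    def test_same_loadings_unity(self, rng):
        C = _random_psd(rng, 15)
        evals, evecs = np.linalg.eigh(C)
        Q = evecs[:, ::-1][:, :5].T
        assert geo.alignment_index(C, Q, d=5) == pytest.approx(1.0)

    def test_orthogonal_complement_zero(self, rng):
        # C supported on the first 5 directions; Q spans directions 5..9
        basis = ortho_group.rvs(12, random_state=1)
        C = basis[:, :5] @ np.diag([5, 4, 3, 2, 1.0]) @ basis[:, :5].T
        Q = basis[:, 5:10].T
        assert geo.alignment_index(C, Q, d=5) == pytest.approx(0.0, abs=1e-10)

    def test_full_dimension_unity(self, rng):
        C = _random_psd(rng, 8)
        Q = ortho_group.rvs(8, random_state=2)
        assert geo.alignment_index(C, Q, d=8) == pytest.approx(1.0)

    def test_eigendecomposition_oracle(self, rng):
        for _ in range(50):
            C = _random_psd(rng, 14)
            Q = np.linalg.qr(rng.standard_normal((14, 10)))[0].T
            num = sum(q @ C @ q for q in Q)
            den = np.sort(np.linalg.eigvalsh(C))[::-1][:10].sum()
            assert geo.alignment_index(C, Q, d=10) == pytest.approx(
                num / den, abs=1e-10)


class TestJointProjections:
    def test_recovers_orthogonal_structure(self):
        basis = ortho_group.rvs(20, random_state=3)
        C1 = basis[:, :3] @ np.diag([3, 2, 1.0]) @ basis[:, :3].T
        C2 = basis[:, 3:6] @ np.diag([3, 2, 1.0]) @ basis[:, 3:6].T
        (Q1, Q2), hist = geo.maximize_joint_projections(
            [C1, C2], [3, 3], return_history=True)
        # captured variance is complete: tr(Q C Q^T) = tr(C)
        assert np.sum(Q1 @ C1 * Q1) == pytest.approx(6.0, abs=1e-8)
        assert np.sum(Q2 @ C2 * Q2) == pytest.approx(6.0, abs=1e-8)
        np.testing.assert_allclose(Q1 @ Q2.T, 0.0, atol=1e-8)

    def test_objective_non_decreasing(self, rng):
        C1, C2 = _random_psd(rng, 16), _random_psd(rng, 16)
        _, hist = geo.maximize_joint_projections([C1, C2], [4, 4],
                                                 return_history=True)
        assert np.all(np.diff(hist) >= -1e-9)

    def test_joint_orthonormality(self, rng):
        C1, C2 = _random_psd(rng, 16), _random_psd(rng, 16)
        Q1, Q2 = geo.maximize_joint_projections([C1, C2], [4, 4])
        stacked = np.vstack([Q1, Q2])
        np.testing.assert_allclose(stacked @ stacked.T, np.eye(8), atol=1e-9)

    def test_dimension_overflow_errors(self, rng):
        with pytest.raises(ValueError, match="ambient"):
            geo.maximize_joint_projections(
                [_random_psd(rng, 4), _random_psd(rng, 4)], [3, 3])


def _trial_peths(rng, n_trials=12, T=40, N=24, noise=0.5, shared=True):
    basis = ortho_group.rvs(N, random_state=7)
    latent = np.cumsum(rng.standard_normal((T, 2)), axis=0)
    out = {}
    for i, cond in enumerate(("ipsilateral", "contralateral")):
        load = basis[:, :2] if shared else basis[:, 2 * i:2 * i + 2]
        mean = latent @ load.T
        out[cond] = mean[None] + noise * rng.standard_normal((n_trials, T, N))
    return out


class TestBootstrapPredictions:
    def test_noiseless_identical_trials(self, rng):
        tp = _trial_peths(rng, noise=0.0)
        ang, ali = geo.bootstrap_invariant_prediction(
            tp, ("ipsilateral", "contralateral"), n_boot=20, seed=0)
        np.testing.assert_allclose(ang, 0.0, atol=1e-5)
        np.testing.assert_allclose(ali, 1.0, atol=1e-8)

    def test_width_shrinks_with_trials(self, rng):
        widths = {}
        for n_trials in (10, 40):
            tp = _trial_peths(rng, n_trials=n_trials, noise=1.0)
            ang, _ = geo.bootstrap_invariant_prediction(
                tp, ("ipsilateral", "contralateral"), n_boot=100, seed=1)
            widths[n_trials] = np.subtract(*np.percentile(ang, [97.5, 2.5]))
        assert abs(widths[40]) < abs(widths[10])

    def test_orthogonal_prediction_on_orthogonal_data_noiseless(self, rng):
        # exactly orthogonal condition subspaces, no noise: the prediction
        # collapses to 90 degrees / zero alignment
        tp = _trial_peths(rng, noise=0.0, shared=False, n_trials=16)
        ang, ali = geo.bootstrap_orthogonal_prediction(
            tp, "laterality", n_boot=10, seed=2, subspace_dim=2, d=2)
        assert np.median(ang) > 89.99
        assert np.median(ali) < 1e-6

    def test_orthogonal_prediction_on_noisy_orthogonal_data(self, rng):
        tp = _trial_peths(rng, noise=0.1, shared=False, n_trials=16)
        ang, ali = geo.bootstrap_orthogonal_prediction(
            tp, "laterality", n_boot=15, seed=2, subspace_dim=2, d=2)
        assert np.median(ang) > 80.0
        assert np.median(ali) < 0.2

    def test_unknown_mode_errors(self, rng):
        with pytest.raises(ValueError, match="mode"):
            geo.bootstrap_orthogonal_prediction(
                _trial_peths(rng), "temporal", n_boot=2, seed=0)


class TestAreaPermutationTest:
    def _frame(self, rng, delta, n=8):
        rows = []
        for area, mu in (("flM1", 0.0), ("LOM", delta)):
            for r in range(n):
                rows.append({"mouse": f"{area}m{r}", "day": "d1", "probe": "p1",
                             "area": area, "value": mu + rng.normal(0, 1.0)})
        return pd.DataFrame(rows)

    def test_identical_groups_high_p(self, rng):
        obs, p, perm = geo.area_permutation_difference_test(
            self._frame(rng, 0.0), ("flM1", "LOM"), n_perm=300, seed=0)
        assert p > 0.05

    def test_permutation_distribution_centered(self, rng):
        _, _, perm = geo.area_permutation_difference_test(
            self._frame(rng, 0.0), ("flM1", "LOM"), n_perm=500, seed=1)
        assert abs(np.mean(perm)) < 3 * np.std(perm) / np.sqrt(len(perm)) + 0.05

    def test_planted_difference_power(self):
        # scaled-down power check: 10 recordings per group, 20 replicates
        hits = 0
        for rep in range(20):
            rng = np.random.default_rng(100 + rep)
            df = self._frame(rng, 4.0, n=10)
            _, p, _ = geo.area_permutation_difference_test(
                df, ("flM1", "LOM"), n_perm=300, seed=rep)
            hits += p < 0.01
        assert hits >= 18
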