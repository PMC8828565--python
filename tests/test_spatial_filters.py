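"""Generalized-eig core, CSP, beamformer, and the adaptive variants."""

import numpy as np
import pytest

from beamadapt.model_core import CovarianceEstimate, EpochSet
from beamadapt.spatial_filters import (
    adapt_and_filter,
    adapt_step_covariance,
    csp_from_covariances,
    identity_bank,
    init_adaptation,
    solve_rayleigh,
    train_beamformer,
    train_csp,
)

from conftest import make_epochs, random_spd


def _cov(sigma, band="broadband"):
    return CovarianceEstimate(np.asarray(sigma, float), 1, 0.0, band)


class TestSolveRayleigh:
    def test_diagonal_case(self):
        res = solve_rayleigh(np.diag([4.0, 1.0]), np.diag([5.0, 5.0]))
        np.testing.assert_allclose(res.eigenvalues, [0.8, 0.2], atol=1e-12)
        # eigenvectors along the coordinate axes (up to scale/sign)
        for k, axis in enumerate(np.eye(2)):
            v = res.eigenvectors[:, k]
            assert abs(abs(v @ axis) / np.linalg.norm(v) - 1.0) < 1e-10

    def test_equal_matrices_give_unit_eigenvalues(self):
        rng = np.random.default_rng(0)
        s = random_spd(rng, 4)
        res = solve_rayleigh(s, s)
        np.testing.assert_allclose(res.eigenvalues, 1.0, atol=1e-10)

    def test_top_eigenvalue_beats_random_search(self):
        rng = np.random.default_rng(1)
        num, den = random_spd(rng, 4), random_spd(rng, 4)
        res = solve_rayleigh(num, den)
        w = rng.standard_normal((4, 10_000))
        quotients = np.einsum("ij,ik,kj->j", w, num, w) / np.einsum("ij,ik,kj->j", w, den, w)
        assert res.eigenvalues[0] - quotients.max() >= -1e-9

    def test_residual_invariant(self):
        rng = np.random.default_rng(2)
        num, den = random_spd(rng, 5), random_spd(rng, 5)
        res = solve_rayleigh(num, den)
        for mu, w in zip(res.eigenvalues, res.eigenvectors.T):
            assert np.linalg.norm(num @ w - mu * den @ w) <= 1e-8 * np.linalg.norm(num @ w)

    def test_non_pd_denominator_errors(self):
        with pytest.raises(np.linalg.LinAlgError, match="positive definite"):
            solve_rayleigh(np.eye(2), np.diag([1.0, 0.0]))


class TestCsp:
    def _two_class_epochs(self, rng, sigma1, sigma2, n=40):
        e1 = make_epochs(rng, n, sigma1.shape[0], 250, sigma=sigma1, label="high")
        e2 = make_epochs(rng, n, sigma2.shape[0], 250, sigma=sigma2, label="low")
        return e1, e2

    def test_variance_ratio_recovery(self):
        rng = np.random.default_rng(3)
        e1, e2 = self._two_class_epochs(rng, np.diag([4.0, 1, 1, 1]), np.diag([1.0, 1, 1, 4]))
        bank = train_csp(e1, e2, n_per_end=1, shrinkage_gamma=0.0)
        assert bank.n_components == 2
        assert abs(bank.eigenvalues[0] - 0.8) < 0.05
        assert abs(bank.eigenvalues[-1] - 0.2) < 0.05

    def test_identical_classes_give_half_eigenvalues(self):
        rng = np.random.default_rng(4)
        s = random_spd(rng, 4)
        e1, e2 = self._two_class_epochs(rng, s, s, n=100)
        bank = train_csp(e1, e2, n_per_end=2, shrinkage_gamma=0.0)
        np.testing.assert_allclose(bank.eigenvalues, 0.5, atol=0.06)

    def test_default_keeps_exactly_six_components(self):
        rng = np.random.default_rng(5)
        e1, e2 = self._two_class_epochs(rng, np.eye(8), np.eye(8), n=20)
        bank = train_csp(e1, e2)
        assert bank.n_components == 6

    def test_too_few_channels_error(self):
        rng = np.random.default_rng(6)
        e1, e2 = self._two_class_epochs(rng, np.eye(4), np.eye(4), n=5)
        with pytest.raises(ValueError, match="channels"):
            train_csp(e1, e2, n_per_end=3)

    def test_eigenvalue_pairing_and_whitening(self):
        rng = np.random.default_rng(7)
        s1, s2 = random_spd(rng, 5), random_spd(rng, 5)
        res1 = solve_rayleigh(s1, s1 + s2)
        res2 = solve_rayleigh(s2, s1 + s2)
        assert np.all(res1.eigenvalues >= -1e-10) and np.all(res1.eigenvalues <= 1 + 1e-10)
        np.testing.assert_allclose(
            np.sort(res1.eigenvalues), np.sort(1 - res2.eigenvalues), atol=1e-8
        )
        # whitening: full eigenvector set diagonalises the denominator
        W = res1.eigenvectors
        d = W.T @ (s1 + s2) @ W
        np.testing.assert_allclose(d - np.diag(np.diag(d)), 0.0, atol=1e-8)

    def test_invariance_under_channel_transform(self):
        rng = np.random.default_rng(8)
        s1, s2 = random_spd(rng, 4), random_spd(rng, 4)
        t = rng.standard_normal((4, 4)) + 2 * np.eye(4)
        base = solve_rayleigh(s1, s1 + s2).eigenvalues
        moved = solve_rayleigh(t @ s1 @ t.T, t @ (s1 + s2) @ t.T).eigenvalues
        np.testing.assert_allclose(base, moved, atol=1e-8)

    def test_channel_permutation_permutes_filter_rows(self):
        rng = np.random.default_rng(9)
        s1, s2 = random_spd(rng, 5), random_spd(rng, 5)
        perm = np.array([2, 0, 4, 1, 3])
        p = np.eye(5)[perm]
        bank = csp_from_covariances(_cov(s1), _cov(s2), n_per_end=1)
        bank_p = csp_from_covariances(
            _cov(p @ s1 @ p.T), _cov(p @ s2 @ p.T), n_per_end=1
        )
        for k in range(bank.n_components):
            a, b = bank_p.W[:, k], (p @ bank.W)[:, k]
            cos = abs(a @ b) / (np.linalg.norm(a) * np.linalg.norm(b))
            assert cos > 1 - 1e-8


class TestBeamformer:
    def test_rank_one_roi_matches_mvdr_direction(self):
        rng = np.random.default_rng(10)
        l = rng.standard_normal(6)
        sigma_x = np.outer(l, l) + 0.5 * np.eye(6)
        bank = train_beamformer(_cov(np.outer(l, l)), _cov(sigma_x))
        w_top = bank.W[:, 0]
        w_mvdr = np.linalg.solve(sigma_x, l)
        cos = abs(w_top @ w_mvdr) / (np.linalg.norm(w_top) * np.linalg.norm(w_mvdr))
        assert cos > 1 - 1e-8

    def test_noiseless_single_source_recovery(self):
        rng = np.random.default_rng(11)
        l = rng.standard_normal(5)
        l /= np.linalg.norm(l)
        s = rng.standard_normal(300)  # source time course
        x = np.outer(l, s)  # noiseless mixture
        sigma_x = x @ x.T / (x.shape[1] - 1) + 1e-9 * np.eye(5)
        bank = train_beamformer(_cov(np.outer(l, l)), _cov(sigma_x))
        recovered = bank.W[:, 0] @ x
        corr = abs(np.corrcoef(recovered, s)[0, 1])
        assert corr > 1 - 1e-6

    def test_equal_matrices_and_all_components(self):
        rng = np.random.default_rng(12)
        s = random_spd(rng, 64)
        bank = train_beamformer(_cov(s), _cov(s))
        assert bank.n_components == 64
        np.testing.assert_allclose(bank.eigenvalues, 1.0, atol=1e-8)


class TestAdaptation:
    def _trained_bank(self, rng, n=6):
        sigma_roi = random_spd(rng, n)
        sigma_x = random_spd(rng, n)
        return train_beamformer(_cov(sigma_roi), _cov(sigma_x))

    def test_tiny_lambda_keeps_bank_unchanged(self):
        rng = np.random.default_rng(13)
        bank = self._trained_bank(rng)
        state = init_adaptation(bank, lam=1e-12)
        eps = make_epochs(rng, 1, 6, 100)
        filtered, new_bank, state = adapt_and_filter(bank, state, eps)
        np.testing.assert_allclose(new_bank.W, bank.W, atol=1e-6)
        # output produced with the pre-update bank
        np.testing.assert_allclose(
            filtered.epochs[0], bank.W.T @ eps.epochs[0], atol=1e-12
        )

    def test_bfa_equals_bf_on_training_covariance(self):
        rng = np.random.default_rng(14)
        bank = self._trained_bank(rng)
        state = init_adaptation(bank, lam=0.5)
        # feed the exact training covariance: running matrix is a fixed point
        new_bank, _ = adapt_step_covariance(bank, state, bank.denominator_cov.sigma)
        np.testing.assert_allclose(new_bank.W, bank.W, atol=1e-8)
        np.testing.assert_allclose(new_bank.eigenvalues, bank.eigenvalues, atol=1e-8)

    def test_cspa_initialisation_is_consistent(self):
        rng = np.random.default_rng(15)
        s1, s2 = random_spd(rng, 6), random_spd(rng, 6)
        bank = csp_from_covariances(_cov(s1), _cov(s2))
        state = init_adaptation(bank, lam=0.5)
        assert state.method == "cspa"
        # fixed point: feeding the pooled data covariance reproduces the bank
        new_bank, _ = adapt_step_covariance(bank, state, (s1 + s2) / 2.0)
        np.testing.assert_allclose(new_bank.W, bank.W, atol=1e-8)

    def test_filter_drift_settles_on_a_stationary_stream(self):
        """Starting from mismatched training statistics, successive top-
        subspace principal angles shrink as the running covariance converges
        to the (stationary) stream covariance."""

        def principal_angle(w1, w2):
            q1, _ = np.linalg.qr(w1)
            q2, _ = np.linalg.qr(w2)
            s = np.linalg.svd(q1.T @ q2, compute_uv=False)
            return float(np.arccos(np.clip(s.min(), 0.0, 1.0)))

        ratios = []
        for seed in (16, 17, 18, 19, 20):
            rng = np.random.default_rng(seed)
            sigma_train = random_spd(rng, 5)
            sigma_stream = random_spd(rng, 5)
            bank = train_beamformer(_cov(random_spd(rng, 5)), _cov(sigma_train))
            state = init_adaptation(bank, lam=0.1)
            drifts = []
            prev = bank.W[:, :3]
            for _ in range(40):
                eps = make_epochs(rng, 1, 5, 2000, sigma=sigma_stream)
                _, bank, state = adapt_and_filter(bank, state, eps)
                drifts.append(principal_angle(prev, bank.W[:, :3]))
                prev = bank.W[:, :3]
            early = np.mean(drifts[:5])
            late = np.mean(drifts[-10:])
            ratios.append(late / early)
        assert np.median(ratios) < 1.0

    def test_step_change_recovery(self):
        """After an artifact power step, only the adaptive bank re-normalises
        its top component's output variance back toward the pre-change level."""
        recovered, frozen_recovered = [], []
        for seed in range(1, 11):
            rng = np.random.default_rng(seed)
            n = 8
            mix = random_spd(rng, n)
            sigma0 = mix @ mix.T / n + np.eye(n)
            bank0 = train_beamformer(_cov(random_spd(rng, n)), _cov(sigma0))
            state = init_adaptation(bank0, lam=0.1)
            bank = bank0
            # artifact: channel 0 power x10
            step = sigma0.copy()
            step[0, 0] *= 10.0
            w0 = bank0.W[:, 0]
            pre = w0 @ sigma0 @ w0
            var_adapted = var_frozen = None
            for i in range(20):
                eps = make_epochs(rng, 1, n, 400, sigma=step)
                filtered, bank, state = adapt_and_filter(bank, state, eps)
                var_adapted = bank.W[:, 0] @ step @ bank.W[:, 0]
                var_frozen = w0 @ step @ w0
            recovered.append(var_adapted / pre)
            frozen_recovered.append(var_frozen / pre)
        assert np.median(recovered) < 2.0
        assert np.median(frozen_recovered) > np.median(recovered)

    def test_unsupervised_labels_never_read(self):
        rng = np.random.default_rng(19)
        bank = self._trained_bank(rng)
        state = init_adaptation(bank, lam=0.3)
        eps = make_epochs(rng, 1, 6, 100, label="high")
        _, b1, _ = adapt_and_filter(bank, state, eps)
        eps_relabeled = EpochSet(
            eps.epochs, np.array(["low"]), eps.block_ids, eps.band, eps.fs, eps.epoch_length_s
        )
        _, b2, _ = adapt_and_filter(bank, state, eps_relabeled)
        np.testing.assert_array_equal(b1.W, b2.W)

    def test_identity_bank(self):
        bank = identity_bank(4, "alpha")
        assert bank.method == "none"
        np.testing.assert_array_equal(bank.W, np.eye(4))
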