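"""Tests of the influence-weighted multiple-kernel fuzzy C-means.

Includes an independent plain-loop kernel-FCM reference used to check
that the algorithm with the influence factor switched off (beta = 0) and
a single Gaussian collapses to classical kernel FCM.
"""

import math

import numpy as np
import pytest

from craniofcm import (
    ClusterCenters,
    FeatureMatrix,
    FitConfig,
    FuzzyPartition,
    MKFCMConfig,
    fcm_fit,
    gaussian_spec,
    generate_dimorphic,
    mkfcm_centers,
    mkfcm_fit,
    mkfcm_memberships,
    mkfcm_objective,
    one_hot,
    validate_partition,
    weight_coefficients,
)
from craniofcm.datamodel import harden
from craniofcm.evaluation import aligned_accuracy
from craniofcm.kernels import eval_multi_kernel
from craniofcm.weighting import WeightMatrix

TWO_GAUSSIANS = gaussian_spec((3.0, 0.7), (0.5, 0.3))


def brute_force_objective(X, U, V, W, spec, beta, s):
    """Triple-loop evaluation of the weighted kernel objective."""
    c, n = U.shape
    total = 0.0
    for i in range(c):
        for k in range(n):
            Kxx = eval_multi_kernel(spec, X[k], X[k])
            Kvv = eval_multi_kernel(spec, V[i], V[i])
            Kxv = eval_multi_kernel(spec, X[k], V[i])
            D = max(float(Kxx + Kvv - 2 * Kxv), 0.0)
            w = max(W[i, k], 1e-12)
            total += U[i, k] ** s * (1.0 / w) ** beta * D
    return total


def brute_force_mk_centers(X, U, V_prev, spec, s):
    """Triple-loop evaluation of the kernel-weighted mean."""
    c, n = U.shape
    m = X.shape[1]
    V = np.zeros((c, m))
    for i in range(c):
        num = np.zeros(m)
        den = 0.0
        for k in range(n):
            Kik = float(eval_multi_kernel(spec, X[k], V_prev[i]))
            num += U[i, k] ** s * Kik * X[k]
            den += U[i, k] ** s * Kik
        V[i] = num / den
    return V


def random_instance(rng, n_max=30, m_max=5, c_max=4):
    n = int(rng.integers(3, n_max + 1))
    m = int(rng.integers(1, m_max + 1))
    c = int(rng.integers(2, c_max + 1))
    X = rng.normal(scale=3.0, size=(n, m))
    M = rng.random((c, n)) + 1e-3
    M /= M.sum(axis=0, keepdims=True)
    V = rng.normal(scale=3.0, size=(c, m))
    return X, M, V


class TestObjective:
    def test_zero_when_samples_sit_on_their_crisp_centres(self):
        pts = np.array([[0.0, 0.0], [4.0, 4.0], [0.0, 0.0]])
        X = FeatureMatrix(pts)
        U = one_hot([0, 1, 0], 2)
        V = ClusterCenters(np.array([[0.0, 0.0], [4.0, 4.0]]))
        W = weight_coefficients(U)
        J = mkfcm_objective(X, U, V, W, TWO_GAUSSIANS, beta=0.5, s=2.0)
        assert J == pytest.approx(0.0, abs=1e-12)

    def test_beta_zero_equals_unweighted_kernel_objective(self, worked_example):
        X, V, U = worked_example
        W = weight_coefficients(U)
        spec = gaussian_spec((3.0, 1.0))
        J = mkfcm_objective(X, U, V, W, spec, beta=0.0, s=2.0)
        uniform_W = WeightMatrix(np.full_like(U.memberships, 1.0))
        J_plain = mkfcm_objective(X, U, V, uniform_W, spec, beta=1.0, s=2.0)
        assert J == pytest.approx(J_plain, rel=1e-14)

    def test_matches_triple_loop_oracle_on_random_instances(self, rng):
        for _ in range(40):
            X, M, V = random_instance(rng)
            W = weight_coefficients(FuzzyPartition(M))
            beta = float(rng.uniform(0, 1.5))
            s = float(rng.uniform(1.3, 3.0))
            J = mkfcm_objective(
                FeatureMatrix(X), FuzzyPartition(M), ClusterCenters(V),
                W, TWO_GAUSSIANS, beta, s,
            )
            expected = brute_force_objective(X, M, V, W.coefficients, TWO_GAUSSIANS, beta, s)
            assert J == pytest.approx(expected, rel=1e-10)


class TestMemberships:
    def test_sample_coinciding_with_centre_is_crisp(self):
        X = FeatureMatrix(np.array([[1.0, 0.0], [9.0, 9.0]]))
        V = ClusterCenters(np.array([[1.0, 0.0], [5.0, 5.0]]))
        W = WeightMatrix(np.full((2, 2), 0.5))
        for mode in ("objective_consistent", "closed_form"):
            U = mkfcm_memberships(X, V, W, TWO_GAUSSIANS, 0.5, 2.0, mode)
            np.testing.assert_allclose(U.memberships[:, 0], [1.0, 0.0])

    def test_symmetric_configuration_gives_uniform_column(self):
        X = FeatureMatrix(np.array([[0.0, 0.0], [9.0, 9.0]]))
        V = ClusterCenters(np.array([[1.0, 0.0], [-1.0, 0.0], [0.0, -1.0]]))
        W = WeightMatrix(np.full((3, 2), 1 / 2))
        for mode in ("objective_consistent", "closed_form"):
            U = mkfcm_memberships(X, V, W, TWO_GAUSSIANS, 0.5, 2.0, mode)
            np.testing.assert_allclose(U.memberships[:, 0], 1 / 3, rtol=1e-10)

    def test_objective_consistent_update_minimizes_column_cost(self, rng):
        """The returned column beats 10^4 random valid membership columns."""
        X, M, V = random_instance(rng, n_max=8, m_max=3, c_max=3)
        W = weight_coefficients(FuzzyPartition(M))
        s, beta = 2.0, 0.7
        U = mkfcm_memberships(
            FeatureMatrix(X), ClusterCenters(V), W, TWO_GAUSSIANS, beta, s,
            "objective_consistent",
        )
        c, n = M.shape
        for k in range(n):
            cost = np.array([
                (1.0 / max(W.coefficients[i, k], 1e-12)) ** beta
                * max(
                    float(
                        eval_multi_kernel(TWO_GAUSSIANS, X[k], X[k])
                        + eval_multi_kernel(TWO_GAUSSIANS, V[i], V[i])
                        - 2 * eval_multi_kernel(TWO_GAUSSIANS, X[k], V[i])
                    ),
                    0.0,
                )
                for i in range(c)
            ])
            returned = float(np.sum(U.memberships[:, k] ** s * cost))
            trials = rng.random((10_000, c))
            trials /= trials.sum(axis=1, keepdims=True)
            best_random = float(np.min(np.sum(trials**s * cost, axis=1)))
            assert returned <= best_random * (1 + 1e-10)


class TestCenters:
    def test_wide_kernel_uniform_memberships_give_grand_mean(self, rng):
        X = FeatureMatrix(rng.normal(size=(15, 3)))
        U = FuzzyPartition(np.full((2, 15), 0.5))
        V_prev = ClusterCenters(rng.normal(size=(2, 3)))
        wide = gaussian_spec((1e6, 1.0))
        V = mkfcm_centers(X, U, V_prev, wide, s=2.0)
        np.testing.assert_allclose(
            V.centers, np.tile(X.values.mean(axis=0), (2, 1)), rtol=1e-8
        )

    def test_wide_kernel_crisp_memberships_give_class_means(self, rng):
        X = FeatureMatrix(rng.normal(size=(12, 2)))
        labels = np.array([0] * 5 + [1] * 7)
        V_prev = ClusterCenters(rng.normal(size=(2, 2)))
        wide = gaussian_spec((1e6, 1.0))
        V = mkfcm_centers(X, one_hot(labels, 2), V_prev, wide, s=2.0)
        np.testing.assert_allclose(V.centers[0], X.values[:5].mean(axis=0), rtol=1e-8)
        np.testing.assert_allclose(V.centers[1], X.values[5:].mean(axis=0), rtol=1e-8)

    def test_matches_triple_loop_oracle_on_random_instances(self, rng):
        for _ in range(30):
            X, M, V_prev = random_instance(rng)
            s = float(rng.uniform(1.3, 3.0))
            V = mkfcm_centers(
                FeatureMatrix(X), FuzzyPartition(M), ClusterCenters(V_prev),
                TWO_GAUSSIANS, s,
            )
            np.testing.assert_allclose(
                V.centers, brute_force_mk_centers(X, M, V_prev, TWO_GAUSSIANS, s),
                rtol=1e-10,
            )


def reference_kernel_fcm(X, c, s, sigma, seed, tol, max_iter):
    """Independent plain-loop kernel FCM (single Gaussian, no weighting)."""
    n, m = X.shape
    rng = np.random.default_rng(seed)
    U = rng.random((c, n))
    U /= U.sum(axis=0, keepdims=True)
    V = np.zeros((c, m))
    for i in range(c):  # fuzzified-mean initial centres
        V[i] = (U[i] ** s) @ X / np.sum(U[i] ** s)
    trajectory = []
    prev = np.inf
    for _ in range(max_iter):
        K = np.zeros((c, n))
        for i in range(c):
            for k in range(n):
                K[i, k] = math.exp(-np.sum((X[k] - V[i]) ** 2) / (2 * sigma**2))
        D = 2 - 2 * K
        U_new = np.zeros((c, n))
        for k in range(n):
            if np.any(D[:, k] <= 1e-300):
                hot = D[:, k] <= 1e-300
                U_new[hot, k] = 1.0 / hot.sum()
            else:
                p = D[:, k] ** (-1.0 / (s - 1.0))
                U_new[:, k] = p / p.sum()
        U = U_new
        V_new = np.zeros((c, m))
        for i in range(c):
            coef = U[i] ** s * K[i]
            V_new[i] = coef @ X / coef.sum()
        V = V_new
        K2 = np.exp(
            -np.sum((X[None, :, :] - V[:, None, :]) ** 2, axis=-1) / (2 * sigma**2)
        )
        J = float(np.sum(U**s * (2 - 2 * K2)))
        trajectory.append(J)
        if abs(prev - J) < tol:
            break
        prev = J
    return U, trajectory


class TestFit:
    def test_separable_blobs_recovered_for_ten_seeds(self, rng):
        centers = np.array([[0.0, 0.0, 0.0], [10.0, 10.0, 10.0]])
        labels = np.array([0] * 25 + [1] * 25)
        X = FeatureMatrix(centers[labels] + rng.normal(size=(50, 3)))
        spec = gaussian_spec((5.0, 0.7), (2.0, 0.3))
        for seed in range(10):
            cfg = MKFCMConfig(base=FitConfig(n_clusters=2, seed=seed), kernel=spec)
            result = mkfcm_fit(X, cfg)
            assert aligned_accuracy(result.hard_labels, labels) == 100.0
            assert validate_partition(result.partition, 50)

    def test_beta_zero_single_gaussian_matches_reference_kernel_fcm(self, rng):
        X = FeatureMatrix(rng.normal(scale=2.0, size=(25, 3)))
        sigma, s, tol = 4.0, 2.0, 1e-7
        for seed in (0, 7):
            cfg = MKFCMConfig(
                base=FitConfig(
                    n_clusters=3, influence_factor=0.0, seed=seed,
                    tolerance=tol, max_iter=120,
                ),
                kernel=gaussian_spec((sigma, 1.0)),
            )
            result = mkfcm_fit(X, cfg)
            U_ref, traj_ref = reference_kernel_fcm(
                X.values, 3, s, sigma, seed, tol, 120
            )
            assert len(result.objective_trajectory) == len(traj_ref)
            np.testing.assert_allclose(
                result.objective_trajectory, traj_ref, rtol=1e-10
            )
            np.testing.assert_allclose(result.partition.memberships, U_ref, atol=1e-10)

    def test_wide_kernel_beta_zero_reduces_to_plain_fcm_partition(self, rng):
        centers = np.array([[0.0, 0.0], [6.0, 6.0]])
        for seed in range(10):
            local = np.random.default_rng(1000 + seed)
            labels = local.integers(0, 2, size=30)
            X = FeatureMatrix(centers[labels] + local.normal(size=(30, 2)))
            diam = float(
                np.max(
                    np.linalg.norm(
                        X.values[:, None, :] - X.values[None, :, :], axis=-1
                    )
                )
            )
            sigma = 1e3 * diam
            base = FitConfig(n_clusters=2, influence_factor=0.0, seed=seed,
                             tolerance=1e-5)
            fcm_result = fcm_fit(X, base)
            kernel_base = FitConfig(
                n_clusters=2, influence_factor=0.0, seed=seed,
                tolerance=1e-5 / sigma**2,  # objective scales as 1/sigma^2
            )
            cfg = MKFCMConfig(base=kernel_base, kernel=gaussian_spec((sigma, 1.0)))
            mk_result = mkfcm_fit(X, cfg)
            np.testing.assert_array_equal(mk_result.hard_labels, fcm_result.hard_labels)

    def test_every_point_its_own_cluster_drives_objective_to_zero(self, rng):
        pts = rng.normal(scale=4.0, size=(6, 2))
        X = FeatureMatrix(pts)
        cfg = MKFCMConfig(
            base=FitConfig(n_clusters=6, influence_factor=0.0, seed=0,
                           tolerance=1e-12, max_iter=500),
            kernel=gaussian_spec((3.0, 1.0)),
        )
        result = mkfcm_fit(X, cfg)
        assert result.objective_trajectory[-1] == pytest.approx(0.0, abs=1e-6)

    def test_default_synthetic_dataset_is_seed_stable(self):
        """At least 49 of 50 random starts give the identical hard partition."""
        X = generate_dimorphic()
        partitions = []
        for seed in range(50):
            cfg = MKFCMConfig(base=FitConfig(seed=seed))
            result = mkfcm_fit(X, cfg)
            mapping = {}
            # canonicalize cluster indices by first occurrence
            canon = []
            for lab in result.hard_labels:
                if lab not in mapping:
                    mapping[lab] = len(mapping)
                canon.append(mapping[lab])
            partitions.append(tuple(canon))
        counts = {}
        for p in partitions:
            counts[p] = counts.get(p, 0) + 1
        assert max(counts.values()) >= 49


class TestPartitionLaws:
    def test_constraints_hold_after_every_update(self, rng):
        """All three membership constraints survive >= 1000 update steps."""
        checks = 0
        for _ in range(340):
            X, M, V = random_instance(rng, n_max=15, m_max=3, c_max=3)
            fm = FeatureMatrix(X)
            W = weight_coefficients(FuzzyPartition(M))
            for mode in ("objective_consistent", "closed_form"):
                U = mkfcm_memberships(
                    fm, ClusterCenters(V), W, TWO_GAUSSIANS,
                    float(rng.uniform(0, 1)), float(rng.uniform(1.3, 3.0)), mode,
                )
                assert validate_partition(U, X.shape[0])
                checks += 1
            from craniofcm import fcm_memberships
            U = fcm_memberships(fm, ClusterCenters(V), float(rng.uniform(1.3, 3.0)))
            assert validate_partition(U, X.shape[0])
            checks += 1
            # hardened labels always agree with the column argmax
            assert np.array_equal(harden(U), np.argmax(U.memberships, axis=0))
        assert checks >= 1000  # three membership updates per instance

    def test_u_update_never_increases_objective_at_fixed_w_and_v(self, rng):
        s, beta = 2.0, 0.5
        for _ in range(200):
            X, M, V = random_instance(rng, n_max=12, m_max=3, c_max=3)
            fm, cc = FeatureMatrix(X), ClusterCenters(V)
            U0 = FuzzyPartition(M)
            W = weight_coefficients(U0)
            U1 = mkfcm_memberships(fm, cc, W, TWO_GAUSSIANS, beta, s,
                                   "objective_consistent")
            before = mkfcm_objective(fm, U0, cc, W, TWO_GAUSSIANS, beta, s)
            after = mkfcm_objective(fm, U1, cc, W, TWO_GAUSSIANS, beta, s)
            assert after <= before * (1 + 1e-12) + 1e-12
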