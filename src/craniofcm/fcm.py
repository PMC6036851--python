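"""Generic fuzzy C-means: the Euclidean baseline the kernel method extends.

Alternating minimization of J = Σ_i Σ_k u_ik^s ‖x_k − v_i‖² subject to the
column-stochastic membership constraint.  Both half-steps are the exact
coordinate minimizers, so J is nonincreasing across iterations.
"""

from __future__ import annotations

import logging

import numpy as np

from .datamodel import (
    ClusterCenters,
    FeatureMatrix,
    FitConfig,
    FitResult,
    FuzzyPartition,
    ValidationError,
    harden,
)

logger = logging.getLogger(__name__)

#: squared distances below this count as "at a centre" for the membership
#: singularity rule
_SINGULARITY_EPS = 1e-300


def random_partition(c: int, n: int, rng: np.random.Generator) -> FuzzyPartition:
    """Random memberships in [0, 1], columns renormalized to sum to 1."""
    M = rng.random((c, n))
    M /= M.sum(axis=0, keepdims=True)
    return FuzzyPartition(M)


def fcm_centers(X: FeatureMatrix, U: FuzzyPartition, s: float) -> ClusterCenters:
    """Fuzzified weighted means: v_i = Σ_k u_ik^s x_k / Σ_k u_ik^s."""
    Us = U.memberships**s
    denom = Us.sum(axis=1)
    if np.any(denom <= 0):
        raise ValidationError(
            "degenerate cluster with zero fuzzified mass: "
            f"{np.where(denom <= 0)[0].tolist()}"
        )
    return ClusterCenters((Us @ X.values) / denom[:, None])


def _memberships_from_costs(costs: np.ndarray, s: float) -> np.ndarray:
    """Column-normalized u ∝ cost^{−1/(s−1)} with the coincidence rule.

    ``costs`` is (c, n) and nonnegative.  A column containing zeros gets
    crisp membership split uniformly over its zero entries.
    """
    c, n = costs.shape
    U = np.empty((c, n))
    zero = costs <= _SINGULARITY_EPS
    singular = zero.any(axis=0)
    if singular.any():
        Z = zero[:, singular].astype(float)
        U[:, singular] = Z / Z.sum(axis=0, keepdims=True)
    regular = ~singular
    if regular.any():
        # u_ik = 1 / Σ_j (cost_ik / cost_jk)^{1/(s−1)}, computed via powers
        p = costs[:, regular] ** (-1.0 / (s - 1.0))
        U[:, regular] = p / p.sum(axis=0, keepdims=True)
    return U


def fcm_memberships(X: FeatureMatrix, V: ClusterCenters, s: float) -> FuzzyPartition:
    """Closed-form membership update from squared Euclidean distances.

    u_ik = 1 / Σ_j (d_ik/d_jk)^{2/(s−1)}.  A specimen coinciding with one
    or more centres splits its membership uniformly over those centres.
    """
    if not s > 1:
        raise ValidationError("fuzzifier must be > 1")
    diff = X.values[None, :, :] - V.centers[:, None, :]  # (c, n, m)
    d2 = np.sum(diff**2, axis=-1)
    return FuzzyPartition(_memberships_from_costs(d2, s))


def fcm_objective(X: FeatureMatrix, U: FuzzyPartition, V: ClusterCenters, s: float) -> float:
    diff = X.values[None, :, :] - V.centers[:, None, :]
    d2 = np.sum(diff**2, axis=-1)
    return float(np.sum(U.memberships**s * d2))


def fcm_fit(X: FeatureMatrix, config: FitConfig) -> FitResult:
    """Seeded random start, then alternate centres/memberships to tolerance.

    Stops when successive objective values differ by less than
    ``config.tolerance`` or after ``config.max_iter`` iterations (the
    result is then flagged ``converged=False``, not raised).
    """
    data = X.standardized() if config.standardize else X
    rng = np.random.default_rng(config.seed)
    U = random_partition(config.n_clusters, data.n_specimens, rng)
    s = config.fuzzifier
    trajectory: list[float] = []
    prev = np.inf
    converged = False
    for it in range(1, config.max_iter + 1):
        V = fcm_centers(data, U, s)
        U = fcm_memberships(data, V, s)
        J = fcm_objective(data, U, V, s)
        trajectory.append(J)
        logger.info("fcm iteration %d: J = %.6g", it, J)
        if abs(prev - J) < config.tolerance:
            converged = True
            break
        prev = J
    return FitResult(
        partition=U,
        centers=V,
        objective_trajectory=trajectory,
        n_iterations=len(trajectory),
        hard_labels=harden(U),
        converged=converged,
    )
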