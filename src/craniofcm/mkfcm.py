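"""Influence-weighted multiple-kernel fuzzy C-means.

The algorithm minimizes

    J_s(U, V) = Σ_i Σ_k u_ik^s (1/w_ik)^β · D_ik,

where D_ik is the kernel-induced squared distance between specimen x_k and
centre v_i under a convex kernel mixture K*, and w_ik is the
distance-weighting share of cluster i's membership mass held by specimen k
(recomputed once per outer iteration).  Iteration structure:

1. fix cluster count c and fuzzifier s;
2. draw a random column-normalized membership matrix U (seeded);
3. initial centres from U by the plain-FCM fuzzified mean;
4. distance-weighting shares W from the current U;
5. update U from kernel distances (and W, in objective-consistent mode),
   then update centres by the kernel-weighted mean evaluated at the
   previous centres;
6. stop when successive objective values differ by less than ε, else
   return to step 4.

Two membership updates are offered.  ``objective_consistent`` (default)
uses the exact Lagrangian minimizer of J_s at fixed W and V, so the
U-half-step never increases the objective.  ``closed_form`` uses the
unweighted closed form u_ik ∝ (1 − K*(x_k, v_i))^{−1/(s−1)}, in which W
enters the fit only through the objective used for the stopping rule.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .datamodel import (
    ClusterCenters,
    FeatureMatrix,
    FitConfig,
    FitResult,
    FuzzyPartition,
    MembershipMode,
    ValidationError,
    harden,
)
from .fcm import _memberships_from_costs, fcm_centers, random_partition
from .kernels import KernelSpec, cross_gram, cross_sq_distance, gaussian_spec
from .weighting import WeightMatrix, influence_scale, weight_coefficients

logger = logging.getLogger(__name__)

#: floor for the centre-update denominator against Gaussian underflow
_CENTER_DENOM_FLOOR = 1e-300

#: kernel mixture used for the craniometric (mm-scale) defaults: two
#: Gaussian widths at the scale of within- and between-class spread
DEFAULT_KERNEL = gaussian_spec((30.0, 0.9), (110.0, 0.1))


@dataclass
class MKFCMConfig:
    """Base fit settings plus the kernel mixture."""

    base: FitConfig = field(default_factory=FitConfig)
    kernel: KernelSpec = DEFAULT_KERNEL


def mkfcm_objective(
    X: FeatureMatrix,
    U: FuzzyPartition,
    V: ClusterCenters,
    W: WeightMatrix,
    kernel: KernelSpec,
    beta: float,
    s: float,
) -> float:
    """J_s = Σ_i Σ_k u_ik^s (1/w_ik)^β · D_ik with kernel distances D."""
    D = cross_sq_distance(kernel, V.centers, X.values)  # (c, n)
    scale = influence_scale(W.coefficients, beta)
    return float(np.sum(U.memberships**s * scale * D))


def mkfcm_memberships(
    X: FeatureMatrix,
    V: ClusterCenters,
    W: WeightMatrix,
    kernel: KernelSpec,
    beta: float,
    s: float,
    mode: MembershipMode = "objective_consistent",
) -> FuzzyPartition:
    """Membership update from kernel distances.

    objective_consistent: u_ik ∝ ((1/w_ik)^β · D_ik)^{−1/(s−1)}, the exact
    minimizer of the weighted objective at fixed W and V.  closed_form:
    u_ik ∝ (1 − K*(x_k, v_i))^{−1/(s−1)}, ignoring W.  In both modes a
    specimen whose kernel distance to a centre vanishes (K* = 1 exactly)
    is assigned crisply there, split uniformly over coinciding centres.
    """
    if not s > 1:
        raise ValidationError("fuzzifier must be > 1")
    if mode == "closed_form":
        K = cross_gram(kernel, V.centers, X.values)  # (c, n)
        costs = np.maximum(1.0 - K, 0.0)
    elif mode == "objective_consistent":
        D = cross_sq_distance(kernel, V.centers, X.values)
        costs = influence_scale(W.coefficients, beta) * D
    else:
        raise ValidationError(f"unknown membership mode {mode!r}")
    return FuzzyPartition(_memberships_from_costs(costs, s))


def mkfcm_centers(
    X: FeatureMatrix,
    U: FuzzyPartition,
    V_prev: ClusterCenters,
    kernel: KernelSpec,
    s: float,
) -> ClusterCenters:
    """Kernel-weighted mean v_i = Σ_k u_ik^s K*(x_k, v_i) x_k / Σ_k u_ik^s K*(x_k, v_i).

    This is a fixed-point form: the kernel values are taken at the previous
    centres, one evaluation per outer iteration.  The denominator is
    floored against underflow of narrow Gaussians.
    """
    K = cross_gram(kernel, V_prev.centers, X.values)  # (c, n)
    coef = U.memberships**s * K
    denom = coef.sum(axis=1)
    if np.any(~np.isfinite(denom)) or np.any(denom < 0):
        raise ValidationError("degenerate centre update (non-finite kernel mass)")
    if np.any(denom <= _CENTER_DENOM_FLOOR):
        raise ValidationError(
            "degenerate cluster: kernel-weighted mass vanished for cluster(s) "
            f"{np.where(denom <= _CENTER_DENOM_FLOOR)[0].tolist()}"
        )
    return ClusterCenters((coef @ X.values) / denom[:, None])


def mkfcm_fit(X: FeatureMatrix, config: MKFCMConfig) -> FitResult:
    """Run the full iterative loop described in the module docstring."""
    base = config.base
    kernel = config.kernel
    s, beta = base.fuzzifier, base.influence_factor
    data = X.standardized() if base.standardize else X

    rng = np.random.default_rng(base.seed)
    U = random_partition(base.n_clusters, data.n_specimens, rng)
    V = fcm_centers(data, U, s)

    trajectory: list[float] = []
    prev = np.inf
    converged = False
    for it in range(1, base.max_iter + 1):
        W = weight_coefficients(U)
        U_new = mkfcm_memberships(
            data, V, W, kernel, beta, s, base.membership_mode
        )
        if base.membership_mode == "objective_consistent":
            # the exact-minimizer half-step must never increase J at fixed W, V
            before = mkfcm_objective(data, U, V, W, kernel, beta, s)
            after = mkfcm_objective(data, U_new, V, W, kernel, beta, s)
            if after > before * (1 + 1e-10) + 1e-12:
                raise RuntimeError(
                    f"membership update increased the objective ({before} -> {after})"
                )
        U = U_new
        V = mkfcm_centers(data, U, V, kernel, s)
        J = mkfcm_objective(data, U, V, W, kernel, beta, s)
        trajectory.append(J)
        logger.info("mkfcm iteration %d: J_s = %.6g", it, J)
        if abs(prev - J) < base.tolerance:
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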