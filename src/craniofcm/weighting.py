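"""Distance-weighting coefficients with influence factor.

Each cluster distributes its total membership mass over the specimens:
``w_ik = u_ik / Σ_k u_ik`` is specimen k's share of cluster i's mass, so
each row of the coefficient matrix sums to 1.  The influence factor beta
rescales squared distances by ``(1/w_ik)**beta``; because the w_ik are
shares (< 1 for any non-trivial cluster), a positive beta inflates all
distances but inflates weakly-attached (small-share) specimens' distances
the most — distances polarize, sharpening cluster boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .datamodel import FuzzyPartition, ValidationError

#: floor applied to w_ik before the reciprocal power; the weighting is
#: singular at w_ik = 0, which crisp partitions produce
WEIGHT_FLOOR = 1e-12


@dataclass
class WeightMatrix:
    """``(c, n)`` matrix of per-(cluster, specimen) distance-weighting shares."""

    coefficients: np.ndarray

    def __post_init__(self) -> None:
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        if self.coefficients.ndim != 2:
            raise ValidationError("coefficients must be a 2-D (c, n) array")


def cluster_mass(U: FuzzyPartition) -> np.ndarray:
    """Total membership mass per cluster: the c row sums of U."""
    return U.memberships.sum(axis=1)


def weight_coefficients(U: FuzzyPartition) -> WeightMatrix:
    """Normalize each row of U by its mass: w_ik = u_ik / w_i.

    Raises on a cluster with zero total mass (degenerate cluster).
    """
    mass = cluster_mass(U)
    if np.any(mass <= 0):
        raise ValidationError(
            f"degenerate cluster(s) with zero mass: {np.where(mass <= 0)[0].tolist()}"
        )
    return WeightMatrix(U.memberships / mass[:, None])


def influence_scale(w: np.ndarray, beta: float) -> np.ndarray:
    """The distance multiplier (1/w)**beta with w floored at WEIGHT_FLOOR."""
    w = np.maximum(np.asarray(w, dtype=float), WEIGHT_FLOOR)
    return (1.0 / w) ** beta


def weighted_sq_distance(
    x: np.ndarray, v: np.ndarray, w_ik: float, beta: float
) -> float:
    """Influence-weighted squared Euclidean distance (1/w_ik)**beta · ‖x−v‖².

    beta = 0 returns the plain squared distance; beta > 0 with w_ik < 1
    inflates it.  ``w_ik`` must be positive after flooring.
    """
    if not w_ik >= 0:  # also rejects NaN
        raise ValidationError("weight coefficient must be nonnegative")
    x = np.asarray(x, dtype=float)
    v = np.asarray(v, dtype=float)
    return float(influence_scale(w_ik, beta) * np.sum((x - v) ** 2))
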