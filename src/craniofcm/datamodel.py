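"""Shared domain types for fuzzy clustering of craniometric feature tables.

Conventions
-----------
The fuzzy partition matrix ``U`` is stored cluster-major, shape ``(c, n)``:
``U[i, k]`` is the membership of specimen ``k`` in cluster ``i``.  Columns are
probability vectors (they sum to 1), rows carry each cluster's total
membership mass, which must be strictly between 0 and ``n``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

#: tolerance for the column-stochastic constraint; repeated renormalization
#: in floating point makes exact sums of 1 unattainable
COLUMN_SUM_TOL = 1e-9

MembershipMode = str  # "objective_consistent" | "closed_form"
_MEMBERSHIP_MODES = ("objective_consistent", "closed_form")


class ValidationError(ValueError):
    """Raised when a domain object violates its structural invariants."""


@dataclass
class FeatureMatrix:
    """A specimens-by-measurements table.

    Parameters
    ----------
    values
        ``(n, m)`` float array; rows are specimens, columns are measurements
        (craniometric interlandmark distances in mm, or arbitrary units).
    feature_names
        ``m`` unique column names.
    labels
        Optional length-``n`` categorical ground-truth labels (e.g. F/M).
    ids
        Optional length-``n`` specimen identifiers.
    """

    values: np.ndarray
    feature_names: list[str] = field(default_factory=list)
    labels: np.ndarray | None = None
    ids: list[str] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValidationError("values must be a 2-D array")
        n, m = self.values.shape
        if n < 2:
            raise ValidationError(f"need at least 2 specimens, got {n}")
        if m < 1:
            raise ValidationError("need at least 1 feature")
        if not np.isfinite(self.values).all():
            bad = np.argwhere(~np.isfinite(self.values))[0]
            raise ValidationError(
                f"non-finite value at row {bad[0]}, column {bad[1]}; "
                "impute or drop incomplete specimens upstream"
            )
        if not self.feature_names:
            self.feature_names = [f"m{j + 1:02d}" for j in range(m)]
        if len(self.feature_names) != m:
            raise ValidationError(
                f"{len(self.feature_names)} feature names for {m} columns"
            )
        if len(set(self.feature_names)) != m:
            raise ValidationError("feature names must be unique")
        if self.labels is not None:
            self.labels = np.asarray(self.labels)
            if self.labels.shape != (n,):
                raise ValidationError("labels length must equal specimen count")
        if self.ids is not None and len(self.ids) != n:
            raise ValidationError("ids length must equal specimen count")

    @property
    def n_specimens(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def standardized(self) -> "FeatureMatrix":
        """Return a copy with each feature z-scored (zero mean, unit sd)."""
        sd = self.values.std(axis=0, ddof=0)
        sd = np.where(sd == 0, 1.0, sd)
        z = (self.values - self.values.mean(axis=0)) / sd
        return FeatureMatrix(z, list(self.feature_names), self.labels, self.ids)


@dataclass
class FuzzyPartition:
    """A ``(c, n)`` fuzzy membership matrix."""

    memberships: np.ndarray

    def __post_init__(self) -> None:
        self.memberships = np.asarray(self.memberships, dtype=float)
        if self.memberships.ndim != 2:
            raise ValidationError("memberships must be a 2-D (c, n) array")

    @property
    def n_clusters(self) -> int:
        return self.memberships.shape[0]

    @property
    def n_specimens(self) -> int:
        return self.memberships.shape[1]


@dataclass
class ClusterCenters:
    """``(c, m)`` cluster centre coordinates."""

    centers: np.ndarray

    def __post_init__(self) -> None:
        self.centers = np.asarray(self.centers, dtype=float)
        if self.centers.ndim != 2 or self.centers.shape[0] < 1:
            raise ValidationError("centers must be a (c>=1, m) array")
        if not np.isfinite(self.centers).all():
            raise ValidationError("centers must be finite")


@dataclass
class FitConfig:
    """Settings shared by the plain-FCM and multiple-kernel fits.

    ``fuzzifier`` is the exponent s > 1 controlling membership softness;
    ``influence_factor`` is the exponent beta applied to the reciprocal
    distance-weighting coefficient (beta = 0 disables the weighting);
    ``membership_mode`` selects between the update that exactly minimizes
    the weighted objective ("objective_consistent") and the unweighted
    closed form ("closed_form").
    """

    n_clusters: int = 2
    fuzzifier: float = 2.0
    influence_factor: float = 0.5
    tolerance: float = 1e-5
    max_iter: int = 300
    seed: int = 0
    membership_mode: MembershipMode = "objective_consistent"
    standardize: bool = False

    def __post_init__(self) -> None:
        if self.n_clusters < 2:
            raise ValidationError("n_clusters must be >= 2")
        if not self.fuzzifier > 1:
            raise ValidationError("fuzzifier must be > 1")
        if not self.tolerance > 0:
            raise ValidationError("tolerance must be > 0")
        if self.max_iter < 1:
            raise ValidationError("max_iter must be >= 1")
        if self.membership_mode not in _MEMBERSHIP_MODES:
            raise ValidationError(
                f"membership_mode must be one of {_MEMBERSHIP_MODES}"
            )


@dataclass
class FitResult:
    """Outcome of an alternating-minimization fit."""

    partition: FuzzyPartition
    centers: ClusterCenters
    objective_trajectory: list[float]
    n_iterations: int
    hard_labels: np.ndarray
    converged: bool


def validate_partition(
    U: FuzzyPartition, n: int, *, tol: float = COLUMN_SUM_TOL
) -> bool:
    """Check the three fuzzy-partition constraints.

    Every membership lies in [0, 1], every column sums to 1 (within ``tol``)
    and every row mass is strictly inside (0, n).  Returns ``True`` iff all
    hold; raises :class:`ValidationError` on a shape mismatch.  Never
    mutates ``U``.
    """
    M = U.memberships
    if M.shape[1] != n:
        raise ValidationError(f"partition has {M.shape[1]} columns, expected {n}")
    if M.shape[0] < 1:
        raise ValidationError("partition needs at least one cluster")
    if np.any(M < -tol) or np.any(M > 1 + tol):
        return False
    col_sums = M.sum(axis=0)
    if np.any(np.abs(col_sums - 1.0) > tol):
        return False
    row_sums = M.sum(axis=1)
    if np.any(row_sums <= 0) or np.any(row_sums >= n):
        return False
    return True


def harden(U: FuzzyPartition) -> np.ndarray:
    """Hard labels: index of the maximal membership in each column.

    Ties break toward the lowest cluster index (argmax convention), keeping
    hard labels deterministic.
    """
    return np.argmax(U.memberships, axis=0)


def one_hot(labels: Sequence[int], c: int) -> FuzzyPartition:
    """Crisp partition with a single unit entry per column."""
    labels = np.asarray(labels, dtype=int)
    M = np.zeros((c, labels.size))
    M[labels, np.arange(labels.size)] = 1.0
    return FuzzyPartition(M)
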