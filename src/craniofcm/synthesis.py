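"""Built-in worked-example fixture and a synthetic craniometric generator.

The generator draws two multivariate-normal classes (female/male) over m
interlandmark-style measurements in mm, with configurable per-feature
dimorphism (male − female offsets expressed as within-class effect sizes),
shared per-feature standard deviations and a single equicorrelation shared
by all feature pairs.  It is calibration infrastructure for the clustering
code — a stand-in with known ground truth, not a model of real skulls.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .datamodel import ClusterCenters, FeatureMatrix, FuzzyPartition, ValidationError

# Default template: 40 measurements, 100 female / 86 male specimens,
# mm-scale means and sds spanning small (orbital) to large (cranial
# length) distances, and an offset of 3 within-class sd on every feature —
# a cleanly separable two-class regime with known labels.
DEFAULT_N_FEMALE = 100
DEFAULT_N_MALE = 86
DEFAULT_N_FEATURES = 40
DEFAULT_EFFECT_SIZE = 3.0
DEFAULT_CORRELATION = 0.1


def _default_female_means(m: int) -> np.ndarray:
    # plausible interlandmark distances, 22–175 mm
    return np.linspace(22.0, 175.0, m)


def _default_sds(m: int) -> np.ndarray:
    # measurement spread grows loosely with size, 2–7 mm
    return np.linspace(2.0, 7.0, m)


@dataclass
class DimorphismConfig:
    """Parameters of the two-class Gaussian measurement model (units: mm)."""

    n_female: int = DEFAULT_N_FEMALE
    n_male: int = DEFAULT_N_MALE
    n_features: int = DEFAULT_N_FEATURES
    female_means: np.ndarray | None = None
    male_means: np.ndarray | None = None
    within_class_sd: np.ndarray | None = None
    correlation: float = DEFAULT_CORRELATION
    seed: int = 0
    effect_size: float = DEFAULT_EFFECT_SIZE  # used when male_means is None

    def __post_init__(self) -> None:
        if self.n_female < 1 or self.n_male < 1:
            raise ValidationError("class counts must be >= 1")
        if self.n_features < 1:
            raise ValidationError("n_features must be >= 1")
        m = self.n_features
        if self.female_means is None:
            self.female_means = _default_female_means(m)
        self.female_means = np.asarray(self.female_means, dtype=float)
        if self.within_class_sd is None:
            self.within_class_sd = _default_sds(m)
        self.within_class_sd = np.asarray(self.within_class_sd, dtype=float)
        if self.male_means is None:
            self.male_means = self.female_means + self.effect_size * self.within_class_sd
        self.male_means = np.asarray(self.male_means, dtype=float)
        for name, vec in (
            ("female_means", self.female_means),
            ("male_means", self.male_means),
            ("within_class_sd", self.within_class_sd),
        ):
            if vec.shape != (m,):
                raise ValidationError(f"{name} must have length n_features={m}")
        if np.any(self.within_class_sd <= 0):
            raise ValidationError("within_class_sd entries must be > 0")
        # equicorrelation matrix is positive definite iff −1/(m−1) < rho < 1
        if not 0 <= self.correlation < 1:
            raise ValidationError("correlation must lie in [0, 1)")


def worked_example_fixture() -> tuple[FeatureMatrix, ClusterCenters, FuzzyPartition]:
    """Three 2-D samples, two centres and an initial membership matrix.

    The classic pencil-and-paper configuration for the distance-weighting
    coefficient: samples a=(1,1), b=(1,2), c=(4,4), centres v1=(1,0) and
    v2=(5,5), memberships to v1 of (0.7, 0.6, 0.2).  Euclidean distances
    to v1 are 1, 2 and 5.
    """
    X = FeatureMatrix(
        np.array([[1.0, 1.0], [1.0, 2.0], [4.0, 4.0]]),
        feature_names=["x", "y"],
        ids=["a", "b", "c"],
    )
    V = ClusterCenters(np.array([[1.0, 0.0], [5.0, 5.0]]))
    U = FuzzyPartition(np.array([[0.7, 0.6, 0.2], [0.3, 0.4, 0.8]]))
    return X, V, U


def generate_dimorphic(config: DimorphismConfig | None = None) -> FeatureMatrix:
    """Draw a labelled two-class Gaussian measurement table.

    Females first, then males; deterministic per seed.  The shared
    covariance is ``diag(sd) @ R @ diag(sd)`` with R the equicorrelation
    matrix of the configured correlation.
    """
    cfg = config if config is not None else DimorphismConfig()
    m = cfg.n_features
    rng = np.random.default_rng(cfg.seed)
    R = np.full((m, m), cfg.correlation)
    np.fill_diagonal(R, 1.0)
    try:
        L = np.linalg.cholesky(R)
    except np.linalg.LinAlgError as exc:
        raise ValidationError("correlation structure is not positive definite") from exc
    scale = cfg.within_class_sd[None, :]
    zf = rng.standard_normal((cfg.n_female, m)) @ L.T
    zm = rng.standard_normal((cfg.n_male, m)) @ L.T
    females = cfg.female_means[None, :] + zf * scale
    males = cfg.male_means[None, :] + zm * scale
    values = np.vstack([females, males])
    labels = np.array(["F"] * cfg.n_female + ["M"] * cfg.n_male)
    ids = [f"S{i + 1:03d}" for i in range(values.shape[0])]
    names = [f"m{j + 1:02d}" for j in range(m)]
    return FeatureMatrix(values, feature_names=names, labels=labels, ids=ids)


class FixtureUnavailableError(RuntimeError):
    """An optional external dataset is not installed locally."""


def load_iris_fixture() -> FeatureMatrix:
    """The canonical 150×4 Iris table, three species of 50 each.

    Loaded from scikit-learn's bundled copy; raises
    :class:`FixtureUnavailableError` when that is not installed.  Core
    functionality never depends on this dataset.
    """
    try:
        from sklearn.datasets import load_iris
    except ImportError as exc:
        raise FixtureUnavailableError(
            "external fixture missing: scikit-learn (for the Iris table) "
            "is not installed"
        ) from exc
    data = load_iris()
    labels = np.asarray([data.target_names[t] for t in data.target])
    return FeatureMatrix(
        np.asarray(data.data, dtype=float),
        feature_names=[n.replace(" (cm)", "").replace(" ", "_") for n in data.feature_names],
        labels=labels,
    )
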