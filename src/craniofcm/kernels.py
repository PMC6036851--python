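"""Base kernels, their convex combination and the kernel-induced distance.

A multiple kernel K* is a convex combination of base kernels (Gaussian,
polynomial, hyperbolic tangent) with weights summing to 1.  The squared
distance between two points in the implicit feature space is

    d²(x, y) = K*(x, x) + K*(y, y) − 2 K*(x, y),

which for a mixture of Gaussians (where every K(x, x) = 1) reduces to
2 − 2 K*(x, y), bounded in [0, 2).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .datamodel import ValidationError

WEIGHT_SUM_TOL = 1e-12

_FAMILIES = ("gaussian", "polynomial", "tanh")


@dataclass(frozen=True)
class KernelComponent:
    """One base kernel with its mixture weight.

    params by family — gaussian: ``sigma`` (width, > 0); polynomial:
    ``c`` (offset, >= 0) and ``d`` (degree, natural); tanh: ``b`` (slope)
    and ``c`` (offset).
    """

    family: str
    weight: float
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.family not in _FAMILIES:
            raise ValidationError(f"unknown kernel family {self.family!r}")
        if not 0 <= self.weight <= 1:
            raise ValidationError("kernel weight must lie in [0, 1]")
        if self.family == "gaussian":
            if self.params.get("sigma", 0.0) <= 0:
                raise ValidationError("gaussian width sigma must be > 0")
        elif self.family == "polynomial":
            if self.params.get("c", 0.0) < 0:
                raise ValidationError("polynomial offset c must be >= 0")
            d = self.params.get("d", 1)
            if d < 1 or int(d) != d:
                raise ValidationError("polynomial degree d must be a natural number")


@dataclass(frozen=True)
class KernelSpec:
    """Ordered convex combination of base kernels."""

    components: tuple[KernelComponent, ...]

    def __post_init__(self) -> None:
        if not self.components:
            raise ValidationError("kernel spec needs at least one component")
        object.__setattr__(self, "components", tuple(self.components))
        total = sum(c.weight for c in self.components)
        if abs(total - 1.0) > WEIGHT_SUM_TOL:
            raise ValidationError(
                f"kernel weights must sum to 1, got {total!r}"
            )

    @property
    def all_gaussian(self) -> bool:
        return all(c.family == "gaussian" for c in self.components)


def gaussian_spec(*sigma_weight: tuple[float, float]) -> KernelSpec:
    """Convenience constructor: ``gaussian_spec((30, 0.9), (110, 0.1))``."""
    return KernelSpec(
        tuple(
            KernelComponent("gaussian", w, {"sigma": s}) for s, w in sigma_weight
        )
    )


def eval_kernel(component: KernelComponent, x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Evaluate one base kernel.

    ``x`` and ``y`` are single m-vectors or broadcastable batches with the
    feature axis last; the result drops that axis.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if component.family == "gaussian":
        sigma = component.params["sigma"]
        sq = np.sum((x - y) ** 2, axis=-1)
        return np.exp(-sq / (2.0 * sigma**2))
    dot = np.sum(x * y, axis=-1)
    if component.family == "polynomial":
        return (dot + component.params["c"]) ** component.params["d"]
    # tanh family, literal sign convention tanh(−b·⟨x,y⟩ − c)
    return np.tanh(-component.params["b"] * dot - component.params["c"])


def eval_multi_kernel(spec: KernelSpec, x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """K*(x, y) = Σ_k weight_k · K_k(x, y)."""
    out = None
    for comp in spec.components:
        term = comp.weight * eval_kernel(comp, x, y)
        out = term if out is None else out + term
    return out


def kernel_sq_distance(spec: KernelSpec, x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Squared feature-space distance K*(x,x) + K*(y,y) − 2 K*(x,y).

    For all-Gaussian specs this is exactly 2 − 2 K*(x, y).  Non-Mercer
    components (the tanh family for most parameters) can push the value
    below zero in floating point or in exact arithmetic; negative results
    are clamped at 0 with a warning.
    """
    if spec.all_gaussian:
        d = 2.0 - 2.0 * eval_multi_kernel(spec, x, y)
    else:
        d = (
            eval_multi_kernel(spec, x, x)
            + eval_multi_kernel(spec, y, y)
            - 2.0 * eval_multi_kernel(spec, x, y)
        )
    neg = np.minimum(d, 0.0)
    if np.any(neg < -1e-9):
        warnings.warn(
            "kernel-induced squared distance went negative "
            f"(min {float(np.min(d)):.3g}); clamping at 0 — the kernel spec "
            "is likely non-Mercer",
            RuntimeWarning,
            stacklevel=2,
        )
    return np.maximum(d, 0.0)


def cross_gram(spec: KernelSpec, X: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """K*(X[a], Y[b]) for all pairs; X is (n1, m), Y is (n2, m) → (n1, n2)."""
    return eval_multi_kernel(spec, X[:, None, :], Y[None, :, :])


def cross_sq_distance(spec: KernelSpec, X: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Pairwise kernel-induced squared distances, shape (n1, n2)."""
    return kernel_sq_distance(spec, X[:, None, :], Y[None, :, :])


def format_spec(spec: KernelSpec) -> str:
    """Serialize to ``family:key=val,...,weight=w;...`` (lossless round-trip)."""
    parts = []
    for comp in spec.components:
        kv = ",".join(f"{k}={v!r}" for k, v in comp.params.items())
        sep = "," if kv else ""
        parts.append(f"{comp.family}:{kv}{sep}weight={comp.weight!r}")
    return ";".join(parts)


def parse_spec(text: str) -> KernelSpec:
    """Parse the serialization produced by :func:`format_spec`.

    Example: ``gaussian:sigma=30,weight=0.9;gaussian:sigma=110,weight=0.1``.
    """
    components = []
    for chunk in text.strip().split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        try:
            family, rest = chunk.split(":", 1)
        except ValueError:
            raise ValidationError(
                f"bad kernel component {chunk!r}: expected 'family:key=val,...'"
            ) from None
        params: dict[str, float] = {}
        weight = None
        for item in rest.split(","):
            item = item.strip()
            if not item:
                continue
            try:
                key, val = item.split("=", 1)
            except ValueError:
                raise ValidationError(
                    f"bad kernel parameter {item!r} in {chunk!r}"
                ) from None
            num = float(val)
            if key.strip() == "weight":
                weight = num
            else:
                params[key.strip()] = num
        if weight is None:
            raise ValidationError(f"kernel component {chunk!r} lacks a weight")
        if family.strip() == "polynomial" and "d" in params:
            params["d"] = int(params["d"])
        components.append(KernelComponent(family.strip(), weight, params))
    return KernelSpec(tuple(components))
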