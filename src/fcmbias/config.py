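"""Algorithm hyperparameter containers with validation.

The solver's behaviour is controlled by a small set of scalars: the
global/local balance ``alpha``, the grayscale-preservation weight ``gamma``,
the fuzzifier exponent ``n`` (> 1), the number of tissue classes ``d``, the
convergence tolerance ``epsilon`` on the cluster-center shift, and the
neighbourhood geometry (spatial-weight window and truncated Gaussian kernel).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields
from typing import Any, Mapping


@dataclass(frozen=True)
class NeighborhoodSpec:
    """Geometry of the two neighbourhood systems used by the model.

    Parameters
    ----------
    spatial_weight_radius : int
        Half-width of the square window ``M_k`` over which the local
        spatial-continuity weights ``omega_kp`` are computed (pixels).
    kernel_sigma : float
        Standard deviation (pixels) of the truncated Gaussian kernel ``K``
        that localises the intensity model and smooths the bias field.
    kernel_radius : int or None
        Half-width of the kernel support.  ``None`` selects
        ``ceil(2 * kernel_sigma)``.
    """

    spatial_weight_radius: int = 1
    kernel_sigma: float = 4.0
    kernel_radius: int | None = None

    def __post_init__(self) -> None:
        if int(self.spatial_weight_radius) != self.spatial_weight_radius or self.spatial_weight_radius < 0:
            raise ValueError("spatial_weight_radius must be a nonnegative integer")
        if not (self.kernel_sigma > 0):
            raise ValueError("kernel_sigma must be positive")
        if self.kernel_radius is not None and (
            int(self.kernel_radius) != self.kernel_radius or self.kernel_radius < 0
        ):
            raise ValueError("kernel_radius must be a nonnegative integer or None")

    @property
    def effective_kernel_radius(self) -> int:
        if self.kernel_radius is not None:
            return int(self.kernel_radius)
        return int(math.ceil(2.0 * self.kernel_sigma))


@dataclass(frozen=True)
class ModelConfig:
    """Complete hyperparameter set for one correction run.

    ``seed`` is reserved for randomized initialization variants; the default
    quantile initialization is deterministic and does not consume it.
    """

    n_classes: int = 3
    alpha: float = 0.5
    gamma: float = 0.01
    fuzzifier: float = 2.0
    epsilon: float = 1e-4
    max_iterations: int = 100
    neighborhood: NeighborhoodSpec = field(default_factory=NeighborhoodSpec)
    background_threshold_fraction: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if int(self.n_classes) != self.n_classes or self.n_classes < 1:
            raise ValueError("n_classes must be a positive integer")
        if not (0.0 <= self.alpha <= 1.0):
            raise ValueError("alpha must lie in [0, 1]")
        if not (self.gamma > 0):
            raise ValueError("gamma must be positive")
        if not (self.fuzzifier > 1):
            raise ValueError("fuzzifier must exceed 1")
        if not (self.epsilon > 0):
            raise ValueError("epsilon must be positive")
        if int(self.max_iterations) != self.max_iterations or self.max_iterations < 1:
            raise ValueError("max_iterations must be a positive integer")
        if not (0.0 <= self.background_threshold_fraction < 1.0):
            raise ValueError("background_threshold_fraction must lie in [0, 1)")

    # -- interop -----------------------------------------------------------

    def to_estimator_kwargs(self) -> dict[str, Any]:
        """Flat keyword arguments for :class:`fcmbias.correction.FCMBiasCorrector`."""
        return {
            "n_classes": self.n_classes,
            "alpha": self.alpha,
            "gamma": self.gamma,
            "fuzzifier": self.fuzzifier,
            "epsilon": self.epsilon,
            "max_iter": self.max_iterations,
            "spatial_weight_radius": self.neighborhood.spatial_weight_radius,
            "kernel_sigma": self.neighborhood.kernel_sigma,
            "kernel_radius": self.neighborhood.kernel_radius,
            "background_threshold_fraction": self.background_threshold_fraction,
        }

    def to_flat_dict(self) -> dict[str, Any]:
        d = self.to_estimator_kwargs()
        d["seed"] = self.seed
        return d

    @classmethod
    def from_mapping(cls, mapping: Mapping[str, Any]) -> "ModelConfig":
        """Build a config from a flat key/value mapping, rejecting unknown keys."""
        flat_keys = {
            "n_classes",
            "alpha",
            "gamma",
            "fuzzifier",
            "epsilon",
            "max_iterations",
            "max_iter",
            "spatial_weight_radius",
            "kernel_sigma",
            "kernel_radius",
            "background_threshold_fraction",
            "seed",
        }
        unknown = set(mapping) - flat_keys
        if unknown:
            raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
        m = dict(mapping)
        neigh = NeighborhoodSpec(
            spatial_weight_radius=m.pop("spatial_weight_radius", 1),
            kernel_sigma=m.pop("kernel_sigma", 4.0),
            kernel_radius=m.pop("kernel_radius", None),
        )
        if "max_iter" in m:
            m["max_iterations"] = m.pop("max_iter")
        valid = {f.name for f in fields(cls)}
        return cls(neighborhood=neigh, **{k: v for k, v in m.items() if k in valid})
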