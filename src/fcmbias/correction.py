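"""Scikit-learn style estimator running the full correction pipeline.

``fit`` executes: foreground masking -> spatial-continuity weighting ->
convex pre-filtering -> deterministic initialization -> alternating
closed-form updates (membership -> labels -> centers -> bias) until the
Euclidean norm of the center shift drops below ``epsilon`` or
``max_iter`` is reached.  Intensities are divided by the foreground maximum
internally (the multiplicative bias model is scale-equivariant, so this
makes ``gamma`` and ``epsilon`` scale-free) and the corrected image is
rescaled back on output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
from sklearn.base import BaseEstimator

from . import solver
from .config import NeighborhoodSpec
from .kernels import build_kernel
from .preprocessing import (
    compute_filtered_image,
    compute_foreground_mask,
    compute_spatial_weights,
)


@dataclass
class CorrectionResult:
    """Everything a correction run produces, on the input intensity scale."""

    corrected: np.ndarray = field(repr=False)
    bias_field: np.ndarray = field(repr=False)
    membership: np.ndarray = field(repr=False)
    centers: np.ndarray
    labels: np.ndarray = field(repr=False)
    filtered: np.ndarray = field(repr=False)
    mask: np.ndarray = field(repr=False)
    energy_trace: np.ndarray
    block_energies: np.ndarray = field(repr=False)
    n_iter: int = 0
    converged: bool = False
    config: dict[str, Any] = field(default_factory=dict)


class FCMBiasCorrector(BaseEstimator):
    """Grayscale-preserving bias field correction by fuzzy clustering.

    Parameters
    ----------
    n_classes : int
        Number of tissue classes ``d``.
    alpha : float in [0, 1]
        Balance between the label-gated global intensity term (``alpha``)
        and the kernel-localized term (``1 - alpha``).
    gamma : float > 0
        Weight of the grayscale-preservation penalty ``sum (1 - h_k)^2``
        on unit-normalized intensities.  ``numpy.inf`` freezes the bias at
        1 and reduces the model to spatially-filtered fuzzy c-means.
    fuzzifier : float > 1
        Membership exponent ``n``.
    kernel_sigma, kernel_radius :
        Truncated Gaussian kernel; ``kernel_radius=None`` uses
        ``ceil(2 * kernel_sigma)``.
    spatial_weight_radius : int
        Window half-width for the pre-filter weights ``omega_kp``.
    epsilon : float
        Convergence tolerance on ``||U_new - U_old||`` (normalized scale).
    max_iter : int
        Iteration cap; hitting it is flagged, not an error.
    background_threshold_fraction : float in [0, 1)
        Foreground cut as a fraction of the maximum intensity.
    divide_raw : bool
        Divide the raw (instead of the pre-filtered) image by the bias
        field for the corrected output.

    Attributes
    ----------
    centers_ : ndarray of shape (n_classes,), sorted ascending (input scale).
    membership_ : ndarray (n_classes, H, W); rows sum to 1 on foreground.
    bias_field_ : ndarray (H, W), 1 on background.
    labels_ : ndarray (H, W) int; 1..n_classes on foreground, 0 background.
    corrected_ : ndarray (H, W), the bias-corrected image.
    filtered_ : ndarray (H, W), the pre-filtered input (input scale).
    mask_ : ndarray (H, W) bool foreground mask.
    energy_trace_ : objective value after each completed outer iteration
        (computed on normalized intensities).
    block_energies_ : ndarray (n_iter_, 4): objective after the membership,
        label, center, and bias updates of each iteration.
    n_iter_ : int; converged_ : bool.
    """

    def __init__(self, n_classes: int = 3, alpha: float = 0.5, gamma: float = 0.01,
                 fuzzifier: float = 2.0, kernel_sigma: float = 4.0,
                 kernel_radius: int | None = None, spatial_weight_radius: int = 1,
                 epsilon: float = 1e-4, max_iter: int = 100,
                 background_threshold_fraction: float = 0.05,
                 divide_raw: bool = False):
        self.n_classes = n_classes
        self.alpha = alpha
        self.gamma = gamma
        self.fuzzifier = fuzzifier
        self.kernel_sigma = kernel_sigma
        self.kernel_radius = kernel_radius
        self.spatial_weight_radius = spatial_weight_radius
        self.epsilon = epsilon
        self.max_iter = max_iter
        self.background_threshold_fraction = background_threshold_fraction
        self.divide_raw = divide_raw

    # -- validation --------------------------------------------------------

    def _check_params(self) -> None:
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
        if int(self.max_iter) != self.max_iter or self.max_iter < 1:
            raise ValueError("max_iter must be a positive integer")

    # -- fitting -----------------------------------------------------------

    def fit(self, X: np.ndarray, y: None = None) -> "FCMBiasCorrector":
        """Run the full correction on a 2D grayscale image."""
        self._check_params()
        raw = np.asarray(X, dtype=float)
        if raw.ndim != 2 or raw.size == 0:
            raise ValueError("X must be a nonempty 2D grayscale image")

        mask = compute_foreground_mask(raw, self.background_threshold_fraction)
        scale = float(raw[mask].max())
        work = raw / scale

        spec = NeighborhoodSpec(
            spatial_weight_radius=self.spatial_weight_radius,
            kernel_sigma=self.kernel_sigma,
            kernel_radius=self.kernel_radius,
        )
        kernel = build_kernel(spec)
        weights = compute_spatial_weights(work, mask, spec)
        filtered = compute_filtered_image(work, weights)

        centers, bias, labels = solver.initialize(filtered, mask, self.n_classes)
        alpha, n, gamma = self.alpha, self.fuzzifier, self.gamma

        def energy(v: np.ndarray, c: np.ndarray, h: np.ndarray,
                   lab: np.ndarray) -> float:
            nik = solver.compute_dissimilarity(filtered, mask, c, h, lab,
                                               kernel, alpha)
            return solver.compute_energy(v, nik, h, mask, gamma, n)

        trace: list[float] = []
        blocks: list[tuple[float, float, float, float]] = []
        converged = False
        it = 0
        for it in range(1, int(self.max_iter) + 1):
            nik = solver.compute_dissimilarity(filtered, mask, centers, bias,
                                               labels, kernel, alpha)
            membership = solver.update_membership(nik, mask, n)
            e_v = solver.compute_energy(membership, nik, bias, mask, gamma, n)
            labels = solver.update_labels_guarded(membership, labels, filtered,
                                                  bias, centers, mask, alpha, n)
            e_t = energy(membership, centers, bias, labels)
            new_centers = solver.update_centers(filtered, membership, bias,
                                                labels, kernel, mask, alpha, n)
            e_u = energy(membership, new_centers, bias, labels)
            bias = solver.update_bias_field(filtered, membership, new_centers,
                                            labels, kernel, mask, alpha, n, gamma)
            e_h = energy(membership, new_centers, bias, labels)
            blocks.append((e_v, e_t, e_u, e_h))
            trace.append(e_h)
            shift = float(np.linalg.norm(new_centers - centers))
            centers = new_centers
            if shift < self.epsilon:
                converged = True
                break

        corrected_src = work if self.divide_raw else filtered
        corrected = solver.correct_image(corrected_src, bias, mask)
        labels = solver.update_labels(membership, mask)  # hard segmentation

        # deterministic output: sort classes by ascending center intensity
        order = np.argsort(centers, kind="stable")
        centers = centers[order]
        membership = membership[order]
        relabel = np.zeros(self.n_classes + 1, dtype=int)
        relabel[order + 1] = np.arange(1, self.n_classes + 1)
        labels = relabel[labels]

        self.mask_ = mask
        self.scale_ = scale
        self.filtered_ = filtered * scale
        self.corrected_ = corrected * scale
        self.bias_field_ = bias
        self.membership_ = membership
        self.centers_ = centers * scale
        self.labels_ = labels
        self.energy_trace_ = np.asarray(trace)
        self.block_energies_ = np.asarray(blocks)
        self.n_iter_ = it
        self.converged_ = converged
        return self

    def fit_predict(self, X: np.ndarray, y: None = None) -> np.ndarray:
        """Fit and return the hard segmentation labels."""
        return self.fit(X).labels_

    def fit_transform(self, X: np.ndarray, y: None = None) -> np.ndarray:
        """Fit and return the bias-corrected image."""
        return self.fit(X).corrected_

    def to_result(self) -> CorrectionResult:
        """Bundle the fitted attributes into a :class:`CorrectionResult`."""
        if not hasattr(self, "corrected_"):
            raise ValueError("estimator is not fitted")
        return CorrectionResult(
            corrected=self.corrected_,
            bias_field=self.bias_field_,
            membership=self.membership_,
            centers=self.centers_,
            labels=self.labels_,
            filtered=self.filtered_,
            mask=self.mask_,
            energy_trace=self.energy_trace_,
            block_energies=self.block_energies_,
            n_iter=self.n_iter_,
            converged=self.converged_,
            config=self.get_params(),
        )


def correct_bias_field(image: np.ndarray, n_classes: int,
                       **params: Any) -> CorrectionResult:
    """One-call functional interface over :class:`FCMBiasCorrector`."""
    est = FCMBiasCorrector(n_classes=n_classes, **params)
    est.fit(image)
    return est.to_result()
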