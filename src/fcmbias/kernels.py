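"""Truncated Gaussian kernel and separable convolution.

The kernel ``K(r - k)`` weights the influence of a center pixel on its
neighbourhood; its value decreases with Euclidean distance from the center
and its support is truncated to a ``(2*radius+1)**2`` square window.  The 2D
kernel factorizes exactly into the outer product of its (normalized) 1D
profile, so every convolution in the solver runs as two 1D passes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import convolve1d

from .config import NeighborhoodSpec


@dataclass(frozen=True)
class GaussianKernel:
    radius: int
    sigma: float
    weights_1d: np.ndarray = field(repr=False)

    @property
    def weights(self) -> np.ndarray:
        """Full 2D weight grid, normalized to sum 1."""
        return np.outer(self.weights_1d, self.weights_1d)


def build_kernel(spec: NeighborhoodSpec | None = None, *, radius: int | None = None,
                 sigma: float | None = None) -> GaussianKernel:
    """Build a truncated, normalized Gaussian kernel.

    Accepts either a :class:`NeighborhoodSpec` (kernel fields are used) or
    explicit ``radius``/``sigma`` keywords.
    """
    if spec is not None:
        radius = spec.effective_kernel_radius if radius is None else radius
        sigma = spec.kernel_sigma if sigma is None else sigma
    if radius is None or sigma is None:
        raise ValueError("radius and sigma are required when no spec is given")
    if int(radius) != radius or radius < 0:
        raise ValueError("kernel radius must be a nonnegative integer")
    if not (sigma > 0):
        raise ValueError("kernel sigma must be positive")
    radius = int(radius)
    x = np.arange(-radius, radius + 1, dtype=float)
    w = np.exp(-(x**2) / (2.0 * float(sigma) ** 2))
    w /= w.sum()
    return GaussianKernel(radius=radius, sigma=float(sigma), weights_1d=w)


def convolve_kernel(field_2d: np.ndarray, kernel: GaussianKernel) -> np.ndarray:
    """Convolve a 2D field with the kernel (zero padding outside the grid)."""
    out = convolve1d(np.asarray(field_2d, dtype=float), kernel.weights_1d,
                     axis=0, mode="constant", cval=0.0)
    return convolve1d(out, kernel.weights_1d, axis=1, mode="constant", cval=0.0)
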