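"""Foreground masking, spatial-continuity weights, and pre-filtering.

Before clustering, the image domain Omega is restricted to foreground tissue
(background air/noise is excluded by an intensity threshold), and the image
is smoothed by a data-adaptive convex filter: each foreground pixel is
replaced by a weighted average of its window ``M_k``, where the weight of a
neighbour ``p`` combines an intensity-deviation factor ``exp(-delta_kp)``
and a spatial decay ``exp(-Chebyshev(p, k))``.  The deviation statistic
``delta_kp`` is dimensionless, so the weights — and hence the relative
effect of the filter — are invariant when the image is multiplied by a
positive constant.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import convolve1d

from .config import NeighborhoodSpec


class NoForegroundError(ValueError):
    """Raised when no pixel exceeds the background threshold."""


def _validate_image(image: np.ndarray) -> np.ndarray:
    arr = np.asarray(image, dtype=float)
    if arr.ndim != 2 or arr.size == 0:
        raise ValueError("image must be a nonempty 2D array")
    if not np.all(np.isfinite(arr)):
        raise ValueError("image intensities must be finite")
    if np.any(arr < 0):
        raise ValueError("image intensities must be nonnegative")
    return arr


def compute_foreground_mask(image: np.ndarray,
                            background_threshold_fraction: float = 0.05) -> np.ndarray:
    """Binary tissue mask: foreground iff intensity > fraction * max intensity."""
    arr = _validate_image(image)
    if not (0.0 <= background_threshold_fraction < 1.0):
        raise ValueError("background_threshold_fraction must lie in [0, 1)")
    peak = arr.max()
    if peak <= 0:
        raise NoForegroundError("no foreground: image is identically zero")
    return arr > background_threshold_fraction * peak


def _shift(arr: np.ndarray, dy: int, dx: int, fill: float = 0.0) -> np.ndarray:
    """out[k] = arr[k + (dy, dx)], with ``fill`` outside the grid."""
    out = np.full_like(arr, fill)
    h, w = arr.shape
    ys = slice(max(0, -dy), min(h, h - dy))
    xs = slice(max(0, -dx), min(w, w - dx))
    out[ys, xs] = arr[ys.start + dy: ys.stop + dy, xs.start + dx: xs.stop + dx]
    return out


def _window_sum(arr: np.ndarray, radius: int) -> np.ndarray:
    ones = np.ones(2 * radius + 1)
    s = convolve1d(np.asarray(arr, dtype=float), ones, axis=0, mode="constant", cval=0.0)
    return convolve1d(s, ones, axis=1, mode="constant", cval=0.0)


def _offsets(radius: int) -> list[tuple[int, int]]:
    return [(dy, dx) for dy in range(-radius, radius + 1)
            for dx in range(-radius, radius + 1)]


@dataclass
class SpatialWeightField:
    """Per-pixel neighbour weights ``omega_kp`` and deviations ``delta_kp``.

    ``weights[j, k]`` is the weight of neighbour ``k + offsets[j]`` in the
    window of pixel ``k``; weights over each foreground pixel's window sum
    to 1, background neighbours carry weight 0.
    """

    offsets: list[tuple[int, int]]
    delta: np.ndarray = field(repr=False)    # (n_offsets, H, W)
    weights: np.ndarray = field(repr=False)  # (n_offsets, H, W)
    valid: np.ndarray = field(repr=False)    # (n_offsets, H, W) bool


def compute_delta(image: np.ndarray, mask: np.ndarray,
                  spec: NeighborhoodSpec) -> np.ndarray:
    """Dimensionless neighbour-deviation statistic ``delta_kp``.

    ``delta_kp = a_kp / mean_{p' in M_k} a_kp'`` with
    ``a_kp = sqrt(var_{M_p}(I) + (I_p - I_k)**2)`` taken over foreground
    pixels.  Degenerate windows (constant patch, or fewer than two
    foreground pixels) yield the neutral value 1.  Returned as a stack of
    shape ``(n_offsets, H, W)``; entries for invalid neighbours are 1.
    """
    a, valid = _neighbor_deviations(image, mask, spec.spatial_weight_radius)
    return _delta_from_deviations(a, valid)


def _neighbor_deviations(image: np.ndarray, mask: np.ndarray,
                         radius: int) -> tuple[np.ndarray, np.ndarray]:
    arr = _validate_image(image)
    m = np.asarray(mask, dtype=bool)
    if radius < 1:
        raise ValueError("spatial_weight_radius must be >= 1 for delta")
    mf = m.astype(float)
    cnt = _window_sum(mf, radius)
    s1 = _window_sum(arr * mf, radius)
    s2 = _window_sum(arr * arr * mf, radius)
    safe = np.maximum(cnt, 1.0)
    mean = s1 / safe
    var = np.clip(s2 / safe - mean * mean, 0.0, None)

    offs = _offsets(radius)
    n = len(offs)
    a = np.zeros((n,) + arr.shape)
    valid = np.zeros((n,) + arr.shape, dtype=bool)
    for j, (dy, dx) in enumerate(offs):
        nb_mask = _shift(mf, dy, dx) > 0.5
        v = m & nb_mask
        nb_val = _shift(arr, dy, dx)
        nb_var = _shift(var, dy, dx)
        a[j] = np.sqrt(nb_var + (nb_val - arr) ** 2)
        valid[j] = v
    return a, valid


def _delta_from_deviations(a: np.ndarray, valid: np.ndarray) -> np.ndarray:
    nvalid = valid.sum(axis=0)
    mean_a = np.where(nvalid > 0, (a * valid).sum(axis=0) / np.maximum(nvalid, 1), 0.0)
    ok = (nvalid >= 2) & (mean_a > 0)
    delta = np.ones_like(a)
    ratio = np.divide(a, mean_a, out=np.ones_like(a), where=(mean_a > 0))
    delta = np.where(valid & ok, ratio, 1.0)
    return delta


def compute_spatial_weights(image: np.ndarray, mask: np.ndarray,
                            spec: NeighborhoodSpec) -> SpatialWeightField:
    """Normalized local spatial-continuity weights ``omega_kp``.

    ``omega_kp ∝ exp(-delta_kp) * exp(-max(|dy|, |dx|))`` over foreground
    neighbours of each foreground pixel, normalized to sum 1 per pixel.
    """
    a, valid = _neighbor_deviations(image, mask, spec.spatial_weight_radius)
    delta = _delta_from_deviations(a, valid)
    offs = _offsets(spec.spatial_weight_radius)
    cheb = np.array([max(abs(dy), abs(dx)) for dy, dx in offs], dtype=float)
    w = np.exp(-delta) * np.exp(-cheb)[:, None, None] * valid
    norm = w.sum(axis=0)
    m = np.asarray(mask, dtype=bool)
    weights = np.divide(w, norm, out=np.zeros_like(w), where=(norm > 0))
    weights *= m[None]
    return SpatialWeightField(offsets=offs, delta=delta, weights=weights, valid=valid)


def compute_filtered_image(image: np.ndarray,
                           weights: SpatialWeightField) -> np.ndarray:
    """Replace each foreground pixel by its omega-weighted window average.

    Background pixels pass through unchanged.  Each filtered value is a
    convex combination of its window, so it lies within the window's
    intensity range.
    """
    arr = _validate_image(image)
    out = arr.copy()
    acc = np.zeros_like(arr)
    for j, (dy, dx) in enumerate(weights.offsets):
        acc += weights.weights[j] * _shift(arr, dy, dx)
    fg = weights.weights.sum(axis=0) > 0
    out[fg] = acc[fg]
    return out
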