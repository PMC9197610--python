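"""The variational core: dissimilarity, energy, and the three closed-form updates.

The model clusters a pre-filtered image ``I`` into ``d`` tissue classes with
centers ``u_i`` while estimating a smooth multiplicative bias field ``h``.
The objective combines, per foreground pixel ``k`` and class ``i``,

* a global intensity term ``alpha * T_i(k) * (I_k - h_k u_i)^2`` gated by the
  one-hot label function ``T``,
* a local intensity term ``(1-alpha) * sum_{r in O_k} K(r-k) (I_k - h_r u_i)^2``
  that couples the bias field across the truncated-Gaussian window ``O_k``
  and thereby enforces its smoothness, and
* a grayscale-preservation penalty ``gamma * sum_k (1 - h_k)^2`` pulling the
  bias toward 1 so the corrected image ``I / h`` keeps the intensity level of
  the input.

Fuzzy memberships ``v_ik`` (rows summing to 1 over classes) weight the data
terms as ``v_ik^n``.  Each of the three blocks — memberships ``V``, centers
``U``, bias ``h`` — has a closed-form exact minimizer with the other blocks
fixed; the solver alternates them.  Kernel windows are renormalized over the
foreground at image borders, so all formulas below use the normalized
convolution ``(f *~ K)(k) = sum_r K(r-k) mask_r f_r / Z_k`` with
``Z_k = sum_r K(r-k) mask_r``.
"""

from __future__ import annotations

import warnings

import numpy as np

from .kernels import GaussianKernel, convolve_kernel

_BIAS_FLOOR = 1e-6


def _kernel_mass(mask: np.ndarray, kernel: GaussianKernel) -> np.ndarray:
    """Per-pixel foreground kernel mass Z_k (border/mask renormalizer)."""
    z = convolve_kernel(mask.astype(float), kernel)
    return np.maximum(z, 1e-300)


def _normalized_conv(field: np.ndarray, mask: np.ndarray, kernel: GaussianKernel,
                     z: np.ndarray | None = None) -> np.ndarray:
    if z is None:
        z = _kernel_mass(mask, kernel)
    return convolve_kernel(field * mask, kernel) / z


def _one_hot(labels: np.ndarray, n_classes: int) -> np.ndarray:
    return np.stack([(labels == i + 1).astype(float) for i in range(n_classes)])


# ---------------------------------------------------------------------------
# initialization
# ---------------------------------------------------------------------------

def initialize(filtered: np.ndarray, mask: np.ndarray,
               n_classes: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Deterministic start: quantile centers, unit bias, nearest-center labels.

    Centers sit at the ``(2j-1)/(2d)`` quantiles (``j = 1..d``) of the
    foreground intensities; the bias field starts at 1 everywhere; labels are
    the nearest-center assignment (ties to the lowest class index).
    """
    m = np.asarray(mask, dtype=bool)
    vals = np.asarray(filtered, dtype=float)[m]
    if vals.size == 0:
        raise ValueError("foreground is empty")
    if np.unique(vals).size < n_classes:
        raise ValueError(
            f"n_classes={n_classes} exceeds the number of distinct foreground intensities"
        )
    q = (2.0 * np.arange(1, n_classes + 1) - 1.0) / (2.0 * n_classes)
    centers = np.quantile(vals, q)
    bias = np.ones_like(np.asarray(filtered, dtype=float))
    dist = np.abs(vals[None, :] - centers[:, None])
    lab_fg = np.argmin(dist, axis=0) + 1
    labels = np.zeros(m.shape, dtype=int)
    labels[m] = lab_fg
    return centers, bias, labels


# ---------------------------------------------------------------------------
# dissimilarity and energy
# ---------------------------------------------------------------------------

def compute_dissimilarity(filtered: np.ndarray, mask: np.ndarray,
                          centers: np.ndarray, bias: np.ndarray,
                          labels: np.ndarray, kernel: GaussianKernel,
                          alpha: float) -> np.ndarray:
    """Per-class, per-pixel dissimilarity ``N_ik`` (nonnegative, 0 on background).

    ``N_ik = alpha T_i(k) (I_k - h_k u_i)^2
           + (1-alpha) sum_{r in O_k} K(r-k) (I_k - h_r u_i)^2``
    with the window sum expanded through the normalized convolutions of
    ``h`` and ``h^2``.
    """
    arr = np.asarray(filtered, dtype=float)
    m = np.asarray(mask, dtype=bool)
    mf = m.astype(float)
    z = _kernel_mass(m, kernel)
    s1 = _normalized_conv(bias, mf, kernel, z)
    s2 = _normalized_conv(bias * bias, mf, kernel, z)
    d = len(centers)
    n_field = np.zeros((d,) + arr.shape)
    for i, u in enumerate(centers):
        t = (labels == i + 1).astype(float)
        g = (arr - bias * u) ** 2
        loc = np.clip(arr * arr - 2.0 * arr * u * s1 + u * u * s2, 0.0, None)
        n_field[i] = (alpha * t * g + (1.0 - alpha) * loc) * mf
    return n_field


def compute_energy(membership: np.ndarray, dissimilarity: np.ndarray,
                   bias: np.ndarray, mask: np.ndarray, gamma: float,
                   fuzzifier: float) -> float:
    """Objective value: fuzzy-weighted dissimilarity plus bias penalty."""
    m = np.asarray(mask, dtype=bool)
    data = float(((membership ** fuzzifier) * dissimilarity)[:, m].sum())
    resid = (1.0 - bias[m]) ** 2
    if np.isinf(gamma):
        pen = 0.0 if np.all(resid == 0.0) else np.inf
    else:
        pen = float(gamma * resid.sum())
    return data + pen


# ---------------------------------------------------------------------------
# the three block updates and the label function
# ---------------------------------------------------------------------------

def update_membership(dissimilarity: np.ndarray, mask: np.ndarray,
                      fuzzifier: float) -> np.ndarray:
    """Exact minimizer of the fuzzy data term on the probability simplex.

    ``v_ik = [sum_a (N_ik / N_ak)^(1/(n-1))]^(-1)``; if some ``N_ik`` are
    exactly zero the membership splits equally among the zero-dissimilarity
    classes.  Background rows are zero (membership-template masking).
    """
    m = np.asarray(mask, dtype=bool)
    n_f = dissimilarity[:, m]
    d = n_f.shape[0]
    out = np.zeros_like(dissimilarity)
    if d == 1:
        v = np.ones_like(n_f)
    else:
        zero = n_f <= 0.0
        nzero = zero.sum(axis=0)
        nmin = np.maximum(n_f.min(axis=0), 1e-300)
        ratio = n_f / nmin
        with np.errstate(over="ignore", divide="ignore", invalid="ignore"):
            w = ratio ** (-1.0 / (fuzzifier - 1.0))
            v = w / w.sum(axis=0)
        split = zero.astype(float) / np.maximum(nzero, 1)
        v = np.where(nzero > 0, split, v)
    out[:, m] = v
    return out


def update_labels(membership: np.ndarray, mask: np.ndarray | None = None) -> np.ndarray:
    """One-hot label function ``T``: argmax membership, ties to the lowest index.

    Returns integer labels (1..d on foreground, 0 on background).
    """
    if mask is None:
        mask = membership.sum(axis=0) > 0
    m = np.asarray(mask, dtype=bool)
    labels = np.argmax(membership, axis=0) + 1
    labels[~m] = 0
    return labels


def update_labels_guarded(membership: np.ndarray, labels_old: np.ndarray,
                          filtered: np.ndarray, bias: np.ndarray,
                          centers: np.ndarray, mask: np.ndarray,
                          alpha: float, fuzzifier: float) -> np.ndarray:
    """Label update used inside the solver loop: argmax membership, kept
    monotone.

    A pixel's label moves to the membership argmax only when the move does
    not increase the objective's global term
    ``alpha * v_i^n (I_k - h_k u_i)^2``; otherwise the previous label is
    kept.  With ``alpha = 0`` labels do not enter the energy and the plain
    argmax is taken.  This preserves the guidance role of ``T`` while
    guaranteeing that the label step never increases the energy.
    """
    m = np.asarray(mask, dtype=bool)
    proposed = update_labels(membership, m)
    if alpha == 0.0:
        return proposed
    arr = np.asarray(filtered, dtype=float)
    u = np.asarray(centers, dtype=float)
    vn = membership ** fuzzifier
    d = len(u)

    def gated_cost(lab: np.ndarray) -> np.ndarray:
        cost = np.zeros_like(arr)
        for i in range(d):
            sel = lab == i + 1
            cost[sel] = (vn[i] * (arr - bias * u[i]) ** 2)[sel]
        return cost

    old_valid = (labels_old >= 1) & (labels_old <= d) & m
    keep = gated_cost(proposed) > gated_cost(labels_old)
    out = np.where(keep & old_valid, labels_old, proposed)
    out[~m] = 0
    return out


def update_centers(filtered: np.ndarray, membership: np.ndarray, bias: np.ndarray,
                   labels: np.ndarray, kernel: GaussianKernel, mask: np.ndarray,
                   alpha: float, fuzzifier: float) -> np.ndarray:
    """Exact stationary point of the energy in each center ``u_i``.

    ``u_i = sum_k v_ik^n I_k [alpha h_k T_i(k) + (1-alpha)(h *~ K)_k]
          / sum_k v_ik^n [alpha h_k^2 T_i(k) + (1-alpha)(h^2 *~ K)_k]``.

    An empty class (zero denominator) is re-seeded at the foreground
    intensity farthest from all current centers, with a warning.
    """
    arr = np.asarray(filtered, dtype=float)
    m = np.asarray(mask, dtype=bool)
    mf = m.astype(float)
    z = _kernel_mass(m, kernel)
    s1 = _normalized_conv(bias, mf, kernel, z)
    s2 = _normalized_conv(bias * bias, mf, kernel, z)
    d = membership.shape[0]
    vn = membership ** fuzzifier
    centers = np.empty(d)
    empty: list[int] = []
    for i in range(d):
        t = (labels == i + 1).astype(float)
        num = (vn[i] * arr * (alpha * t * bias + (1.0 - alpha) * s1))[m].sum()
        den = (vn[i] * (alpha * t * bias * bias + (1.0 - alpha) * s2))[m].sum()
        if den <= 1e-300:
            empty.append(i)
            centers[i] = np.nan
        else:
            centers[i] = num / den
    if empty:
        warnings.warn(
            f"re-seeding empty classes {empty} at the worst-fit intensity",
            RuntimeWarning, stacklevel=2,
        )
        vals = arr[m]
        for i in empty:
            ref = centers[~np.isnan(centers)]
            if ref.size == 0:
                centers[i] = vals.mean()
            else:
                gap = np.abs(vals[None, :] - ref[:, None]).min(axis=0)
                centers[i] = vals[int(np.argmax(gap))]
    return centers


def update_bias_field(filtered: np.ndarray, membership: np.ndarray,
                      centers: np.ndarray, labels: np.ndarray,
                      kernel: GaussianKernel, mask: np.ndarray,
                      alpha: float, fuzzifier: float, gamma: float) -> np.ndarray:
    """Exact per-pixel minimizer of the energy in the bias field ``h``.

    With ``A1^(1) = sum_i v_i^n u_i T_i``, ``A1^(2) = sum_i v_i^n u_i^2 T_i``,
    ``A2^(1) = sum_i v_i^n u_i``, ``A2^(2) = sum_i v_i^n u_i^2``:

    ``h_k = [alpha I_k A1^(1)_k + (1-alpha) sum_r K(k-r) I_r A2^(1)_r / Z_r + gamma]
          / [alpha A1^(2)_k + (1-alpha) sum_r K(k-r) A2^(2)_r / Z_r + gamma]``

    The local sums are the adjoint of the border-renormalized window average,
    hence the division by ``Z_r`` inside the convolution.  ``gamma > 0``
    keeps the denominator positive; the result is floored at 1e-6 and set to
    1 on background.  ``gamma = inf`` returns the plain-FCM limit ``h = 1``.
    """
    arr = np.asarray(filtered, dtype=float)
    m = np.asarray(mask, dtype=bool)
    if np.isinf(gamma):
        return np.ones_like(arr)
    mf = m.astype(float)
    z = _kernel_mass(m, kernel)
    vn = membership ** fuzzifier
    u = np.asarray(centers, dtype=float)
    t = _one_hot(labels, len(u))
    a11 = np.tensordot(u, vn * t, axes=(0, 0))
    a12 = np.tensordot(u * u, vn * t, axes=(0, 0))
    a21 = np.tensordot(u, vn, axes=(0, 0))
    a22 = np.tensordot(u * u, vn, axes=(0, 0))
    cnum = convolve_kernel(mf * arr * a21 / z, kernel)
    cden = convolve_kernel(mf * a22 / z, kernel)
    num = alpha * arr * a11 + (1.0 - alpha) * cnum + gamma
    den = alpha * a12 + (1.0 - alpha) * cden + gamma
    h = np.where(m, num / den, 1.0)
    return np.maximum(h, _BIAS_FLOOR)


def correct_image(filtered: np.ndarray, bias: np.ndarray,
                  mask: np.ndarray) -> np.ndarray:
    """Pixel-wise division ``I / h`` on foreground; background unchanged."""
    arr = np.asarray(filtered, dtype=float)
    m = np.asarray(mask, dtype=bool)
    out = arr.copy()
    out[m] = arr[m] / np.maximum(bias[m], _BIAS_FLOOR)
    return out
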