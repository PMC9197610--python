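"""Synthetic MR-like phantoms with known labels and known bias field.

A phantom is a piecewise-constant tissue image (one intensity level per
class) multiplied by a smooth, strictly positive bias surface with
foreground mean 1, plus additive noise, surrounded by a zero background
margin.  Because the ground-truth labels and bias are retained, correction
and segmentation quality can be measured exactly — this is what the solver
is validated against in place of patient data.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml
from scipy.ndimage import gaussian_filter

LAYOUTS = ("stripes", "nested-disks", "voronoi-blobs")


@dataclass(frozen=True)
class PhantomSpec:
    """Generation parameters.  The defaults are the standard evaluation
    phantom used throughout the test-suite: 128x128, three tissue classes
    with means 0.25/0.55/0.85 in nested disks, +-30% bias with a 32 px
    smoothness scale, additive Gaussian noise sigma 0.02, an 8 px zero
    margin, seed 17."""

    shape: tuple[int, int] = (128, 128)
    class_means: tuple[float, ...] = (0.25, 0.55, 0.85)
    layout: str = "nested-disks"
    bias_amplitude: float = 0.3
    bias_smoothness: float = 32.0
    noise_sigma: float = 0.02
    background_margin: int = 8
    seed: int = 17
    noise_model: str = "gaussian"

    def __post_init__(self) -> None:
        if len(self.shape) != 2 or min(self.shape) < 1:
            raise ValueError("shape must be a (height, width) pair")
        means = np.asarray(self.class_means, dtype=float)
        if means.size < 1 or np.any(means <= 0) or np.unique(means).size != means.size:
            raise ValueError("class_means must be distinct positive values")
        if not (0.0 <= self.bias_amplitude < 1.0):
            raise ValueError("bias_amplitude must lie in [0, 1)")
        if not (self.bias_smoothness > 0):
            raise ValueError("bias_smoothness must be positive")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be nonnegative")
        if self.background_margin < 0:
            raise ValueError("background_margin must be nonnegative")
        if self.layout not in LAYOUTS:
            raise ValueError(f"layout must be one of {LAYOUTS}")
        if self.noise_model not in ("gaussian", "rician"):
            raise ValueError("noise_model must be 'gaussian' or 'rician'")


@dataclass
class Phantom:
    image: np.ndarray = field(repr=False)
    true_labels: np.ndarray = field(repr=False)
    true_bias: np.ndarray = field(repr=False)
    spec: PhantomSpec = field(default_factory=PhantomSpec)

    @property
    def foreground(self) -> np.ndarray:
        return self.true_labels > 0


def generate_bias_surface(shape: Sequence[int], amplitude: float,
                          smoothness: float, seed: int,
                          mask: np.ndarray | None = None) -> np.ndarray:
    """Smooth strictly positive multiplicative gain with mean exactly 1.

    Seeded white noise is heavily Gaussian-smoothed, affinely rescaled to
    ``[1 - amplitude, 1 + amplitude]``, and divided by its mean over
    ``mask`` (whole field when ``mask`` is None).  Deterministic per seed.
    """
    if not (0.0 <= amplitude < 1.0):
        raise ValueError("amplitude must lie in [0, 1)")
    shape = tuple(int(s) for s in shape)
    if amplitude == 0.0:
        return np.ones(shape)
    rng = np.random.default_rng(seed)
    raw = rng.standard_normal(shape)
    smooth = gaussian_filter(raw, sigma=float(smoothness), mode="reflect")
    lo, hi = smooth.min(), smooth.max()
    if hi <= lo:
        return np.ones(shape)
    surf = 1.0 - amplitude + (smooth - lo) * (2.0 * amplitude / (hi - lo))
    m = np.ones(shape, dtype=bool) if mask is None else np.asarray(mask, dtype=bool)
    return surf / surf[m].mean()


def _interior(spec: PhantomSpec) -> tuple[slice, slice]:
    m = spec.background_margin
    h, w = spec.shape
    if h - 2 * m < 1 or w - 2 * m < 1:
        raise ValueError("background_margin leaves no interior")
    return slice(m, h - m), slice(m, w - m)


def _layout_labels(spec: PhantomSpec, rng: np.random.Generator) -> np.ndarray:
    """Integer label map: 0 background, 1..d tissue classes."""
    d = len(spec.class_means)
    labels = np.zeros(spec.shape, dtype=int)
    ys, xs = _interior(spec)
    ih, iw = ys.stop - ys.start, xs.stop - xs.start
    if spec.layout == "stripes":
        rows = np.arange(ih)
        band = np.minimum((rows * d) // ih, d - 1)
        labels[ys, xs] = (band + 1)[:, None]
    elif spec.layout == "nested-disks":
        yy, xx = np.mgrid[0:ih, 0:iw]
        cy, cx = (ih - 1) / 2.0, (iw - 1) / 2.0
        r = np.hypot(yy - cy, xx - cx)
        # equal-area annuli via distance quantiles; class 1 innermost
        edges = np.quantile(r, np.arange(1, d) / d)
        labels[ys, xs] = np.digitize(r, edges) + 1
    else:  # voronoi-blobs
        flat = rng.choice(ih * iw, size=d, replace=False)
        seeds = np.stack(np.unravel_index(flat, (ih, iw)), axis=1)
        yy, xx = np.mgrid[0:ih, 0:iw]
        dist = (yy[None] - seeds[:, 0, None, None]) ** 2 + \
               (xx[None] - seeds[:, 1, None, None]) ** 2
        labels[ys, xs] = np.argmin(dist, axis=0) + 1
    present = np.unique(labels[labels > 0])
    if present.size != d:
        raise ValueError(
            f"layout '{spec.layout}' produced {present.size} regions for {d} classes"
        )
    return labels


def generate_phantom(spec: PhantomSpec | None = None, **kwargs) -> Phantom:
    """Deterministic-per-seed phantom: image, true labels, true bias."""
    if spec is None:
        spec = PhantomSpec(**kwargs)
    elif kwargs:
        raise TypeError("pass either a PhantomSpec or keyword fields, not both")
    rng = np.random.default_rng(spec.seed)
    labels = _layout_labels(spec, rng)
    fg = labels > 0
    bias = generate_bias_surface(spec.shape, spec.bias_amplitude,
                                 spec.bias_smoothness, spec.seed, mask=fg)
    means = np.concatenate([[0.0], np.asarray(spec.class_means, dtype=float)])
    clean = means[labels] * bias
    image = np.where(fg, clean, 0.0)
    if spec.noise_sigma > 0:
        if spec.noise_model == "rician":
            n1 = rng.normal(0.0, spec.noise_sigma, spec.shape)
            n2 = rng.normal(0.0, spec.noise_sigma, spec.shape)
            noisy = np.hypot(image + n1, n2)
        else:
            noisy = image + rng.normal(0.0, spec.noise_sigma, spec.shape)
        image = np.where(fg, noisy, 0.0)
    image = np.clip(image, 0.0, None)
    return Phantom(image=image, true_labels=labels, true_bias=bias, spec=spec)


# ---------------------------------------------------------------------------
# file round-trip
# ---------------------------------------------------------------------------

def phantom_to_files(phantom: Phantom, directory: str | Path) -> dict[str, Path]:
    """Write image/bias (NIfTI float), labels (NIfTI int), and the spec (YAML)."""
    import nibabel as nib

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "image": directory / "image.nii",
        "bias": directory / "true_bias.nii",
        "labels": directory / "true_labels.nii",
        "spec": directory / "phantom_spec.yaml",
    }
    try:
        nib.save(nib.Nifti1Image(phantom.image.astype(np.float64), np.eye(4)),
                 paths["image"])
        nib.save(nib.Nifti1Image(phantom.true_bias.astype(np.float64), np.eye(4)),
                 paths["bias"])
        nib.save(nib.Nifti1Image(phantom.true_labels.astype(np.int16), np.eye(4)),
                 paths["labels"])
        spec_dict = asdict(phantom.spec)
        spec_dict["shape"] = list(spec_dict["shape"])
        spec_dict["class_means"] = [float(v) for v in spec_dict["class_means"]]
        paths["spec"].write_text(yaml.safe_dump(spec_dict, sort_keys=True))
    except OSError as exc:
        raise OSError(f"failed writing phantom files under {directory}: {exc}") from exc
    return paths


def phantom_from_files(directory: str | Path) -> Phantom:
    """Inverse of :func:`phantom_to_files`."""
    import nibabel as nib

    directory = Path(directory)
    spec_dict = yaml.safe_load((directory / "phantom_spec.yaml").read_text())
    spec_dict["shape"] = tuple(spec_dict["shape"])
    spec_dict["class_means"] = tuple(spec_dict["class_means"])
    spec = PhantomSpec(**spec_dict)
    image = np.asarray(nib.load(directory / "image.nii").get_fdata())
    bias = np.asarray(nib.load(directory / "true_bias.nii").get_fdata())
    labels = np.asarray(nib.load(directory / "true_labels.nii").get_fdata()).astype(int)
    return Phantom(image=image, true_labels=labels, true_bias=bias, spec=spec)
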