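"""Reading and writing images, run outputs, and run configuration.

Supported input formats: NIfTI (``.nii``/``.nii.gz``) through nibabel, and
single-channel PNG/TIFF through imageio.  3D NIfTI volumes are processed
slice-wise: ``read_image`` returns a requested slice, or the caller iterates
slices.  Continuous outputs (corrected image, bias field) are written as
NIfTI or float TIFF; PNG cannot hold floats, so a PNG input also yields
float-TIFF continuous outputs (labels stay PNG).
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Any

import numpy as np
import yaml

from .correction import CorrectionResult

logger = logging.getLogger("fcmbias")

NIFTI_SUFFIXES = (".nii", ".nii.gz")


class ImageFormatError(ValueError):
    """Unsupported or invalid image input."""


def _suffix(path: Path) -> str:
    name = path.name.lower()
    if name.endswith(".nii.gz"):
        return ".nii.gz"
    return path.suffix.lower()


def read_image(path: str | Path, slice_index: int | None = None) -> np.ndarray:
    """Read a grayscale image as a float 2D array (or 3D NIfTI volume).

    For 3D NIfTI, ``slice_index`` selects one axial (last-axis) slice; when
    it is None the full volume is returned for the caller to iterate.
    Multi-channel (RGB/RGBA) inputs are rejected.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"unreadable file: {path} does not exist")
    suffix = _suffix(path)
    if suffix in NIFTI_SUFFIXES:
        import nibabel as nib

        data = np.asarray(nib.load(path).get_fdata(), dtype=float)
        data = np.squeeze(data)
        if data.ndim == 2:
            if slice_index is not None and slice_index != 0:
                raise IndexError("slice requested from a 2D image")
            return data
        if data.ndim == 3:
            if slice_index is not None:
                return data[:, :, slice_index]
            return data
        raise ImageFormatError(f"unsupported NIfTI dimensionality {data.ndim}")
    if suffix in (".png", ".tif", ".tiff"):
        import imageio.v3 as iio

        data = np.asarray(iio.imread(path))
        if data.ndim == 3:
            raise ImageFormatError(
                f"multi-channel image not supported: {path} has shape {data.shape}"
            )
        if data.ndim != 2:
            raise ImageFormatError(f"expected a 2D grayscale image, got {data.shape}")
        return data.astype(float)
    raise ImageFormatError(f"unknown format '{suffix}' for {path}")


def _write_scalar(arr: np.ndarray, path: Path) -> None:
    suffix = _suffix(path)
    if suffix in NIFTI_SUFFIXES:
        import nibabel as nib

        nib.save(nib.Nifti1Image(np.asarray(arr, dtype=np.float64), np.eye(4)), path)
    elif suffix in (".tif", ".tiff"):
        import imageio.v3 as iio

        iio.imwrite(path, np.asarray(arr, dtype=np.float32))
    elif suffix == ".png":
        import imageio.v3 as iio

        iio.imwrite(path, np.asarray(arr, dtype=np.uint16))
    else:
        raise ImageFormatError(f"unknown output format '{suffix}'")


def write_outputs(result: CorrectionResult, directory: str | Path,
                  family: str = "nifti") -> dict[str, Path]:
    """Write corrected image, bias field, labels, energy trace, and config.

    ``family`` is ``"nifti"`` (default) or ``"tiff"`` — the format family of
    the continuous outputs, normally matched to the input format.
    """
    import pandas as pd

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    if family == "nifti":
        cont, lab = ".nii", ".nii"
    elif family == "tiff":
        cont, lab = ".tif", ".png"
    else:
        raise ValueError("family must be 'nifti' or 'tiff'")
    paths = {
        "corrected": directory / f"corrected{cont}",
        "filtered": directory / f"filtered{cont}",
        "bias": directory / f"bias_field{cont}",
        "labels": directory / f"labels{lab}",
        "energy": directory / "energy_trace.csv",
        "config": directory / "config.yaml",
        "log": directory / "run.log",
    }
    try:
        _write_scalar(result.corrected, paths["corrected"])
        _write_scalar(result.filtered, paths["filtered"])
        _write_scalar(result.bias_field, paths["bias"])
        if lab == ".nii":
            import nibabel as nib

            nib.save(nib.Nifti1Image(result.labels.astype(np.int16), np.eye(4)),
                     paths["labels"])
        else:
            import imageio.v3 as iio

            iio.imwrite(paths["labels"], result.labels.astype(np.uint8))
        pd.DataFrame({
            "iteration": np.arange(1, result.n_iter + 1),
            "energy": result.energy_trace,
        }).to_csv(paths["energy"], index=False)
        cfg = dict(result.config)
        cfg["n_iter"] = int(result.n_iter)
        cfg["converged"] = bool(result.converged)
        cfg["centers"] = [float(c) for c in result.centers]
        paths["config"].write_text(yaml.safe_dump(cfg, sort_keys=True))
        lines = [
            f"iteration={i + 1} energy={e:.10g}"
            for i, e in enumerate(result.energy_trace)
        ]
        lines.append(f"centers={list(map(float, result.centers))}")
        paths["log"].write_text("\n".join(lines) + "\n")
    except OSError as exc:
        raise OSError(f"failed writing outputs under {directory}: {exc}") from exc
    return paths


def read_run_config(path: str | Path) -> dict[str, Any]:
    """Read a plain-text (YAML key/value) run configuration.

    Unknown keys are rejected; validation of the values happens in
    :class:`fcmbias.config.ModelConfig`.
    """
    from .config import ModelConfig

    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"configuration file {path} must contain a key/value mapping")
    path_keys = {"input", "output", "slice_index", "divide_raw"}
    model_part = {k: v for k, v in raw.items() if k not in path_keys}
    ModelConfig.from_mapping(model_part)  # validates keys and values
    return raw
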