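"""Volume I/O and geometric preprocessing.

NIfTI is the on-disk format (via nibabel); spacing is carried in the header
zooms and origin in the affine translation.  Resampling is implemented on
``scipy.ndimage.map_coordinates`` with the package-wide convention that a
voxel's world position is ``origin + index * spacing`` (see ``core``).

Preprocessing mirrors a two-stage pipeline: full-resolution volumes are
converted to isotropic voxels for segmentation, and additionally
down-sampled by a configurable factor (default 3.2, taking a 512x512
in-plane grid to 160x160) for the coarse region-of-interest stage.
"""

from __future__ import annotations

import logging
from pathlib import Path

import nibabel as nib
import numpy as np
from scipy import ndimage

from .core import LabelMask, Volume

__all__ = [
    "read_volume",
    "write_volume",
    "read_mask",
    "write_mask",
    "resample_isotropic",
    "downsample_for_roi",
    "normalize_intensity",
    "ROI_DOWNSAMPLE_FACTOR",
    "DEFAULT_WINDOW",
]

log = logging.getLogger(__name__)

#: In-plane/axial down-sampling factor for the ROI-detection stage
#: (512 -> 160 in-plane).
ROI_DOWNSAMPLE_FACTOR = 3.2

#: Default soft-tissue display window (HU-like) for intensity normalization.
DEFAULT_WINDOW = (-100.0, 400.0)


def _affine(spacing, origin) -> np.ndarray:
    a = np.eye(4)
    a[:3, :3] = np.diag(spacing)
    a[:3, 3] = origin
    return a


def write_volume(v: Volume, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    img = nib.Nifti1Image(np.asarray(v.data), _affine(v.spacing, v.origin))
    img.header.set_zooms(v.spacing)
    nib.save(img, str(path))
    log.info("wrote %s shape=%s spacing=%s", path, v.shape, v.spacing)
    return path


def write_mask(m: LabelMask, path: str | Path) -> Path:
    return write_volume(Volume(m.data.astype(np.uint8), m.spacing, m.origin), path)


def _load(path: str | Path):
    try:
        img = nib.load(str(path))
        data = np.asanyarray(img.dataobj)
    except Exception as exc:  # nibabel raises several header/format errors
        raise ValueError(f"cannot read NIfTI volume {path}: {exc}") from exc
    data = np.squeeze(data)
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3D payload, got shape {data.shape}")
    zooms = img.header.get_zooms()[:3]
    origin = tuple(np.asarray(img.affine[:3, 3], dtype=float))
    return data, tuple(float(z) for z in zooms), origin


def read_volume(path: str | Path) -> Volume:
    data, spacing, origin = _load(path)
    return Volume(data.astype(np.float32), spacing, origin)


def read_mask(path: str | Path) -> LabelMask:
    data, spacing, origin = _load(path)
    return LabelMask(np.rint(data).astype(np.uint8), spacing, origin)


# ----------------------------------------------------------------------


def _round_half_away(x: np.ndarray) -> np.ndarray:
    return np.sign(x) * np.floor(np.abs(x) + 0.5)


def _resample_to(v: Volume, new_shape: tuple[int, int, int],
                 new_spacing: tuple[float, float, float], order: int) -> np.ndarray:
    scale = np.asarray(new_spacing) / np.asarray(v.spacing)
    ax = [np.arange(n) * s for n, s in zip(new_shape, scale)]
    coords = np.meshgrid(*ax, indexing="ij")
    out = ndimage.map_coordinates(np.asarray(v.data, dtype=np.float32), coords,
                                  order=order, mode="nearest")
    return out


def resample_isotropic(v: Volume, target_mm: float = 1.0,
                       interpolation: str = "linear") -> Volume:
    """Resample to isotropic voxels of ``target_mm``.

    ``interpolation`` is ``"linear"`` for images or ``"nearest"`` for label
    payloads; a :class:`LabelMask` input always uses nearest and returns a
    :class:`LabelMask` (the label set is preserved, never interpolated).
    """
    if target_mm <= 0:
        raise ValueError("target_mm must be positive")
    if interpolation not in ("linear", "nearest"):
        raise ValueError(f"unknown interpolation {interpolation!r}")
    is_mask = isinstance(v, LabelMask)
    order = 0 if (is_mask or interpolation == "nearest") else 1
    extent = v.extent_mm()
    new_shape = tuple(int(max(1, _round_half_away(e / target_mm))) for e in extent)
    new_spacing = (target_mm,) * 3
    out = _resample_to(v, new_shape, new_spacing, order)
    log.info("isotropic resample %s%s -> %s@%.3gmm", v.shape, v.spacing,
             new_shape, target_mm)
    if is_mask:
        return LabelMask(np.rint(out).astype(np.uint8), new_spacing, v.origin)
    return Volume(out, new_spacing, v.origin)


def downsample_for_roi(v: Volume, factor: float = ROI_DOWNSAMPLE_FACTOR) -> Volume:
    """Down-sample all axes by ``factor`` for the coarse ROI stage.

    Output dimensions are ``round(n / factor)`` with round-half-away-from-
    zero, so 512 -> 160 at the default factor 3.2; spacing grows by the same
    factor, preserving physical extent to within one output voxel.
    """
    if factor <= 1.0:
        raise ValueError("down-sampling factor must exceed 1")
    is_mask = isinstance(v, LabelMask)
    new_shape = tuple(int(max(1, _round_half_away(n / factor))) for n in v.shape)
    new_spacing = tuple(s * factor for s in v.spacing)
    out = _resample_to(v, new_shape, new_spacing, 0 if is_mask else 1)
    log.info("ROI down-sample x%.2f %s -> %s", factor, v.shape, new_shape)
    if is_mask:
        return LabelMask(np.rint(out).astype(np.uint8), new_spacing, v.origin)
    return Volume(out, new_spacing, v.origin)


def normalize_intensity(v: Volume, window: tuple[float, float] = DEFAULT_WINDOW
                        ) -> Volume:
    """Clip to ``window`` then map affinely to [0, 1]."""
    low, high = window
    if low >= high:
        raise ValueError(f"window low must be < high, got {window}")
    data = (np.clip(v.data, low, high) - low) / (high - low)
    return v.with_data(data.astype(np.float32))
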