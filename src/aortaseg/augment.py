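"""Joint image/mask augmentation.

Two mechanisms, mirroring an offline/online split:

* **Divergence warps** (offline, 10:1): sums of Gaussian-windowed radial
  displacement bumps placed at predefined locations,
  ``u(x) = sum_k m_k * (x - c_k)/|x - c_k| * exp(-|x - c_k|^2 / 2 sigma_k^2)``,
  applied by backward warping.  A positive magnitude locally dilates the
  structure around its control point, a negative one contracts it.
* **Random 3D affine** (online, per training sample): rotation 0-15 degrees
  about a random axis, isotropic scaling 0.7-1.3, translation within +/-10%
  of the field of view.

The image is interpolated linearly, the mask with nearest neighbour, always
with the identical transform, so the pair stays aligned and the mask never
acquires labels absent from its input.  Every augmentation is a pure
function of (input, parameters, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .core import LabelMask, Volume, require_same_geometry

__all__ = [
    "WarpField",
    "AffineParams",
    "TrainingCase",
    "divergence_warp",
    "sample_warp_field",
    "offline_augment",
    "random_affine_3d",
    "apply_affine_3d",
    "AUGMENT_RATIO",
    "ROTATION_RANGE_DEG",
    "SCALE_RANGE",
    "TRANSLATION_FRACTION",
]

#: Offline augmentation ratio (each original yields this many warped copies).
AUGMENT_RATIO = 10
ROTATION_RANGE_DEG = (0.0, 15.0)
SCALE_RANGE = (0.7, 1.3)
TRANSLATION_FRACTION = 0.10

# divergence-warp sampling defaults (documented constants)
WARP_N_CONTROL = 3
WARP_MAGNITUDE_MM = 5.0
WARP_SIGMA_MM = 15.0


@dataclass(frozen=True)
class WarpField:
    """Gaussian radial-bump displacement field.

    ``control_points`` are fractional voxel indices; magnitudes (signed) and
    radii (Gaussian sigma) are in mm.
    """

    control_points: np.ndarray  # (k, 3) voxel indices
    magnitudes: np.ndarray  # (k,) mm
    radii: np.ndarray  # (k,) mm

    def __post_init__(self) -> None:
        object.__setattr__(self, "control_points",
                           np.atleast_2d(np.asarray(self.control_points, float)))
        object.__setattr__(self, "magnitudes",
                           np.atleast_1d(np.asarray(self.magnitudes, float)))
        object.__setattr__(self, "radii",
                           np.atleast_1d(np.asarray(self.radii, float)))
        if not (len(self.control_points) == len(self.magnitudes) == len(self.radii)):
            raise ValueError("control_points, magnitudes, radii must align")
        if (self.radii <= 0).any():
            raise ValueError("warp radii must be positive")
        if not np.isfinite(self.magnitudes).all():
            raise ValueError("warp magnitudes must be finite")

    def to_dict(self) -> dict:
        return {
            "control_points": self.control_points.tolist(),
            "magnitudes": self.magnitudes.tolist(),
            "radii": self.radii.tolist(),
        }


@dataclass(frozen=True)
class AffineParams:
    angle_deg: float
    axis: tuple[float, float, float]
    scale: float
    translation_mm: tuple[float, float, float]

    def to_dict(self) -> dict:
        return {
            "angle_deg": self.angle_deg,
            "axis": list(self.axis),
            "scale": self.scale,
            "translation_mm": list(self.translation_mm),
        }


@dataclass
class TrainingCase:
    """An image/mask pair with provenance, the unit the trainers consume."""

    image: Volume
    mask: LabelMask
    case_id: str
    provenance: dict = field(default_factory=dict)


# ----------------------------------------------------------------------


def _displacement_mm(field_: WarpField, vol: Volume) -> np.ndarray:
    """Displacement (mm) of every voxel center, shape (3, *grid)."""
    spacing = np.asarray(vol.spacing)
    grids = np.meshgrid(*[np.arange(n) * s for n, s in zip(vol.shape, spacing)],
                        indexing="ij")
    pos = np.stack(grids)  # (3, X, Y, Z) mm
    disp = np.zeros_like(pos)
    for cp, m, sig in zip(field_.control_points, field_.magnitudes, field_.radii):
        c = cp * spacing
        d = pos - c.reshape(3, 1, 1, 1)
        r2 = np.sum(d * d, axis=0)
        r = np.sqrt(np.maximum(r2, 1e-12))
        w = m * np.exp(-r2 / (2.0 * sig * sig)) / r
        disp += w * d
    return disp


def divergence_warp(img: Volume, mask: LabelMask, field_: WarpField
                    ) -> tuple[Volume, LabelMask]:
    """Backward-warp an image/mask pair by a radial-bump field.

    The output at voxel x samples the input at ``x - u(x)``; with all
    magnitudes zero this is the identity.
    """
    require_same_geometry(img, mask)
    disp = _displacement_mm(field_, img)
    spacing = np.asarray(img.spacing).reshape(3, 1, 1, 1)
    idx = np.stack(np.meshgrid(*[np.arange(n, dtype=float) for n in img.shape],
                               indexing="ij"))
    coords = idx - disp / spacing
    out_img = ndimage.map_coordinates(np.asarray(img.data, np.float32), coords,
                                      order=1, mode="nearest")
    out_msk = ndimage.map_coordinates(mask.data, coords, order=0, mode="nearest")
    return (img.with_data(out_img),
            LabelMask(out_msk.astype(np.uint8), mask.spacing, mask.origin))


def sample_warp_field(mask: LabelMask, rng: np.random.Generator,
                      n_control: int = WARP_N_CONTROL,
                      magnitude_mm: float = WARP_MAGNITUDE_MM,
                      sigma_mm: float = WARP_SIGMA_MM) -> WarpField:
    """Draw a warp field with control points inside the dilated foreground,
    so deformations target the vessel rather than empty background."""
    fg = mask.foreground()
    if fg.any():
        fg = ndimage.binary_dilation(fg, iterations=3)
        cand = np.argwhere(fg)
    else:  # degenerate mask: anywhere
        cand = np.argwhere(np.ones(mask.shape, bool))
    pick = cand[rng.integers(0, len(cand), size=n_control)]
    mags = rng.uniform(-magnitude_mm, magnitude_mm, size=n_control)
    return WarpField(pick.astype(float), mags, np.full(n_control, sigma_mm))


def offline_augment(cases: list[TrainingCase], ratio: int = AUGMENT_RATIO,
                    seed: int = 0, **warp_kw) -> list[TrainingCase]:
    """Expand a cohort ``ratio``:1 by divergence warps, keeping originals.

    Output size is ``len(cases) * (ratio + 1)``; each augmented case records
    its parent id, draw seed and warp parameters in ``provenance``.
    """
    if ratio < 0:
        raise ValueError("ratio must be >= 0")
    rng = np.random.default_rng(seed)
    out: list[TrainingCase] = []
    for case in cases:
        out.append(case)
        for j in range(ratio):
            draw_seed = int(rng.integers(0, 2**31 - 1))
            sub = np.random.default_rng(draw_seed)
            fieldj = sample_warp_field(case.mask, sub, **warp_kw)
            wi, wm = divergence_warp(case.image, case.mask, fieldj)
            out.append(TrainingCase(
                image=wi, mask=wm, case_id=f"{case.case_id}-aug{j}",
                provenance={"parent": case.case_id, "seed": draw_seed,
                            "warp": fieldj.to_dict()},
            ))
    return out


# ----------------------------------------------------------------------


def draw_affine_params(rng: np.random.Generator, extent_mm: np.ndarray
                       ) -> AffineParams:
    angle = float(rng.uniform(*ROTATION_RANGE_DEG))
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    scale = float(rng.uniform(*SCALE_RANGE))
    t = rng.uniform(-TRANSLATION_FRACTION, TRANSLATION_FRACTION, 3) * extent_mm
    return AffineParams(angle, tuple(axis), scale, tuple(t))


def _rotation_matrix(axis: np.ndarray, angle_deg: float) -> np.ndarray:
    a = np.deg2rad(angle_deg)
    u = np.asarray(axis, float)
    u = u / np.linalg.norm(u)
    K = np.array([[0, -u[2], u[1]], [u[2], 0, -u[0]], [-u[1], u[0], 0]])
    return np.eye(3) + np.sin(a) * K + (1 - np.cos(a)) * (K @ K)


def apply_affine_3d(img: Volume, mask: LabelMask, params: AffineParams
                    ) -> tuple[Volume, LabelMask]:
    """Apply a rotation/scale/translation about the volume center to both
    members of the pair (linear for image, nearest for mask)."""
    require_same_geometry(img, mask)
    spacing = np.asarray(img.spacing)
    center = (np.asarray(img.shape) - 1) / 2.0
    R = _rotation_matrix(np.asarray(params.axis), params.angle_deg) * params.scale
    # backward map in voxel space: in = S^-1 R^-1 S (out - c - t) + c
    S = np.diag(spacing)
    M = np.linalg.inv(S) @ np.linalg.inv(R) @ S
    t_vox = np.asarray(params.translation_mm) / spacing
    offset = center - M @ (center + t_vox)
    out_img = ndimage.affine_transform(np.asarray(img.data, np.float32), M,
                                       offset=offset, order=1, mode="nearest")
    out_msk = ndimage.affine_transform(mask.data, M, offset=offset, order=0,
                                       mode="constant", cval=0)
    return (img.with_data(out_img),
            LabelMask(out_msk.astype(np.uint8), mask.spacing, mask.origin))


def random_affine_3d(img: Volume, mask: LabelMask, seed: int
                     ) -> tuple[Volume, LabelMask, AffineParams]:
    """Draw and apply a random affine; reproducible per seed."""
    rng = np.random.default_rng(seed)
    params = draw_affine_params(rng, img.extent_mm())
    wi, wm = apply_affine_3d(img, mask, params)
    return wi, wm, params
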