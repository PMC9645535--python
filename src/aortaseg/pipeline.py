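"""Two-stage segmentation cascade.

Stage 1 segments the aorta on a heavily down-sampled rendition of the scan
and derives axis-aligned bounding boxes from the prediction: two for a
contrast scan (thoracic and descending/abdominal) and one for a
non-contrast scan (abdominal).  Stage 2 crops the full-resolution volume to
each (padded) box, runs the corresponding high-resolution network, and
stitches the per-box predictions back into a full-volume label mask.

The thoracic/abdominal split is geometric: scanning axial slices from
superior, the thoracic box ends at the most inferior slice where the
thresholded aorta shows >= 2 in-plane components (ascending + descending,
i.e. below the arch) plus a margin; the abdominal box spans from that slice
minus the margin down to the inferior foreground extent.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .core import LabelMask, Volume
from .io import ROI_DOWNSAMPLE_FACTOR, DEFAULT_WINDOW, downsample_for_roi, \
    normalize_intensity
from .nn.training import predict
from .nn.unet import AttentionUNet3D

__all__ = [
    "BoundingBox",
    "EmptyDetectionError",
    "PipelineStageError",
    "detect_rois",
    "crop",
    "stitch",
    "run_contrast",
    "run_noncontrast",
    "DEFAULT_BOX_PADDING",
    "SPLIT_MARGIN_MM",
    "MIN_COMPONENT_MM3",
]

log = logging.getLogger(__name__)

#: Padding (high-resolution voxels each side) applied to detected boxes,
#: absorbing low-resolution localisation error.
DEFAULT_BOX_PADDING = 10
#: Margin (mm) added around the thoracic/abdominal split slice.
SPLIT_MARGIN_MM = 20.0
#: Connected components smaller than this are discarded as noise.
MIN_COMPONENT_MM3 = 1000.0


class EmptyDetectionError(RuntimeError):
    """No voxel above the detection threshold."""


class PipelineStageError(RuntimeError):
    """A stage failed; carries the stage identity."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage '{stage}' failed: {cause}")
        self.stage = stage
        self.__cause__ = cause


@dataclass(frozen=True)
class BoundingBox:
    """Half-open voxel-index box tagged with an anatomical region."""

    lo: tuple[int, int, int]
    hi: tuple[int, int, int]
    region: str  # "thoracic" | "abdominal"
    padding: int = 0

    def __post_init__(self) -> None:
        if any(l >= h for l, h in zip(self.lo, self.hi)):
            raise ValueError(f"degenerate box lo={self.lo} hi={self.hi}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return tuple(h - l for l, h in zip(self.lo, self.hi))

    def slices(self) -> tuple[slice, slice, slice]:
        return tuple(slice(l, h) for l, h in zip(self.lo, self.hi))

    def to_dict(self) -> dict:
        return {"lo": list(self.lo), "hi": list(self.hi),
                "region": self.region, "padding": self.padding}


# ----------------------------------------------------------------------


def _clean_foreground(prob: Volume, threshold: float) -> np.ndarray:
    data = np.asarray(prob.data)
    if data.min() < -1e-6 or data.max() > 1 + 1e-6:
        raise ValueError("probability volume must lie in [0, 1]")
    fg = data >= threshold
    if not fg.any():
        raise EmptyDetectionError(
            f"no voxel above threshold {threshold} (max prob "
            f"{float(data.max()):.3f})")
    lab, n = ndimage.label(fg, structure=np.ones((3, 3, 3), int))
    sizes = ndimage.sum_labels(np.ones_like(lab), lab, index=range(1, n + 1))
    min_vox = MIN_COMPONENT_MM3 / prob.voxel_volume_mm3
    big = np.flatnonzero(sizes >= min_vox) + 1
    if len(big) == 0:
        big = np.array([1 + int(np.argmax(sizes))])
    keep = 1 + int(np.argmax(sizes))  # largest component wins
    return lab == keep


def _box_from_voxels(vox: np.ndarray, region: str) -> tuple[np.ndarray, np.ndarray, str]:
    return vox.min(axis=0), vox.max(axis=0) + 1, region


def detect_rois(prob: Volume, contrast: bool, threshold: float = 0.5,
                factor: float = ROI_DOWNSAMPLE_FACTOR,
                full_shape: tuple[int, int, int] | None = None,
                padding: int = DEFAULT_BOX_PADDING,
                split_margin_mm: float = SPLIT_MARGIN_MM) -> list[BoundingBox]:
    """Bounding boxes from a low-resolution foreground-probability volume.

    Boxes are computed in the low-resolution grid, mapped to high-resolution
    indices by ``factor``, padded and clipped to ``full_shape``.  Contrast
    scans yield a thoracic and an abdominal box (one abdominal box if no
    arch geometry is present, logged); non-contrast scans yield one
    abdominal box.
    """
    comp = _clean_foreground(prob, threshold)
    vox = np.argwhere(comp)
    raw: list[tuple[np.ndarray, np.ndarray, str]] = []
    if not contrast:
        raw.append(_box_from_voxels(vox, "abdominal"))
    else:
        margin = max(int(round(split_margin_mm / prob.spacing[2])), 1)
        split = _arch_split_slice(comp)
        if split is None:
            log.warning("contrast ROI: no two-component slice found (no arch); "
                        "emitting a single abdominal box")
            raw.append(_box_from_voxels(vox, "abdominal"))
        else:
            zmin, zmax = vox[:, 2].min(), vox[:, 2].max()
            thor = vox[vox[:, 2] <= min(split + margin, zmax)]
            abdo = vox[vox[:, 2] >= max(split - margin, zmin)]
            raw.append(_box_from_voxels(thor, "thoracic"))
            raw.append(_box_from_voxels(abdo, "abdominal"))

    boxes = []
    for lo, hi, region in raw:
        lo_hr = np.floor(lo * factor).astype(int) - padding
        hi_hr = np.ceil(hi * factor).astype(int) + padding
        if full_shape is not None:
            lo_hr = np.clip(lo_hr, 0, np.asarray(full_shape) - 1)
            hi_hr = np.clip(hi_hr, 1, np.asarray(full_shape))
        if (lo_hr >= hi_hr).any():
            raise ValueError(f"{region} box empty after clipping")
        boxes.append(BoundingBox(tuple(int(v) for v in lo_hr),
                                 tuple(int(v) for v in hi_hr), region, padding))
    log.info("detected %d ROI box(es): %s", len(boxes),
             [b.to_dict() for b in boxes])
    return boxes


def _arch_split_slice(comp: np.ndarray) -> int | None:
    """Most inferior axial slice with >= 2 in-plane components."""
    split = None
    for z in range(comp.shape[2]):
        sl = comp[:, :, z]
        if not sl.any():
            continue
        _, n = ndimage.label(sl)
        if n >= 2:
            split = z
    return split


# ----------------------------------------------------------------------


def crop(v: Volume, box: BoundingBox) -> Volume:
    """Crop with spacing/origin bookkeeping preserved."""
    for l, h, n in zip(box.lo, box.hi, v.shape):
        if l < 0 or h > n:
            raise ValueError(f"box {box.lo}-{box.hi} outside grid {v.shape}")
    data = np.asarray(v.data)[box.slices()]
    origin = tuple(o + l * s for o, l, s in zip(v.origin, box.lo, v.spacing))
    if isinstance(v, LabelMask):
        return LabelMask(data, v.spacing, origin)
    return Volume(data, v.spacing, origin)


def stitch(parts: list[tuple[np.ndarray, BoundingBox]],
           full_shape: tuple[int, int, int],
           spacing: tuple[float, float, float],
           origin: tuple[float, float, float] = (0.0, 0.0, 0.0)) -> LabelMask:
    """Place per-box class-probability stacks into the full grid.

    Overlaps are resolved per voxel by maximum class probability across
    parts; voxels outside every box stay background.
    """
    if not parts:
        raise ValueError("nothing to stitch")
    n_classes = parts[0][0].shape[0]
    acc = np.zeros((n_classes,) + tuple(full_shape), np.float32)
    acc[0] = 1.0  # background prior outside all boxes
    for probs, box in parts:
        if probs.shape[0] != n_classes:
            raise ValueError("parts disagree on class count")
        if tuple(probs.shape[1:]) != box.shape:
            raise ValueError(f"part shape {probs.shape[1:]} != box {box.shape}")
        sl = (slice(None),) + box.slices()
        region = acc[sl]
        # inside a box the background prior is replaced, not maxed, so a
        # confident foreground prediction cannot lose to the prior
        first_touch = region[0] >= 1.0 - 1e-6
        region[0] = np.where(first_touch, probs[0], np.maximum(region[0], probs[0]))
        region[1:] = np.maximum(region[1:], probs[1:])
        acc[sl] = region
    labels = np.argmax(acc, axis=0).astype(np.uint8)
    return LabelMask(labels, spacing, origin)


# ----------------------------------------------------------------------


def _foreground_prob(probs: np.ndarray, like: Volume) -> Volume:
    return Volume((1.0 - probs[0]).astype(np.float32), like.spacing, like.origin)


def _run(v: Volume, models: dict[str, AttentionUNet3D], contrast: bool,
         threshold: float = 0.5, factor: float = ROI_DOWNSAMPLE_FACTOR,
         window: tuple[float, float] = DEFAULT_WINDOW,
         padding: int = DEFAULT_BOX_PADDING
         ) -> tuple[LabelMask, dict]:
    provenance: dict = {"mode": "contrast" if contrast else "noncontrast",
                        "threshold": threshold, "factor": factor,
                        "window": list(window)}
    try:
        norm = normalize_intensity(v, window)
        low = downsample_for_roi(norm, factor)
    except Exception as exc:
        raise PipelineStageError("preprocess", exc) from exc
    try:
        roi_probs = predict(models["roi"], low)
        fg = _foreground_prob(roi_probs, low)
    except Exception as exc:
        raise PipelineStageError("roi-detection", exc) from exc
    try:
        boxes = detect_rois(fg, contrast=contrast, threshold=threshold,
                            factor=factor, full_shape=v.shape, padding=padding)
    except Exception as exc:
        raise PipelineStageError("roi-boxes", exc) from exc
    provenance["boxes"] = [b.to_dict() for b in boxes]
    parts = []
    for box in boxes:
        model_key = box.region if contrast else "abdominal"
        try:
            sub = crop(norm, box)
            probs = predict(models[model_key], sub)
        except Exception as exc:
            raise PipelineStageError(f"segment-{box.region}", exc) from exc
        parts.append((probs, box))
    try:
        mask = stitch(parts, v.shape, v.spacing, v.origin)
    except Exception as exc:
        raise PipelineStageError("stitch", exc) from exc
    return mask, provenance


def run_contrast(v: Volume, models: dict[str, AttentionUNet3D], **kw
                 ) -> tuple[LabelMask, dict]:
    """End-to-end contrast cascade: ROI net -> thoracic + abdominal nets.

    ``models`` maps ``{"roi", "thoracic", "abdominal"}`` to trained networks
    (the thoracic and abdominal entries may share one network).  Returns the
    stitched mask with classes {0, 1 lumen, 2 wall/thrombus} and a
    provenance record of every stage.
    """
    return _run(v, models, contrast=True, **kw)


def run_noncontrast(v: Volume, models: dict[str, AttentionUNet3D], **kw
                    ) -> tuple[LabelMask, dict]:
    """End-to-end non-contrast cascade: ROI net -> abdominal net; output is
    single-class foreground {0, 1}."""
    return _run(v, models, contrast=False, **kw)
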