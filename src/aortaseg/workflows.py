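"""Desk-scale workflow helpers.

Bundles the recurring experiment recipes — building a phantom training
cohort, training the coarse ROI network and the high-resolution
segmentation network, and evaluating the full cascade — so scripts, tests
and the CLI all run the identical procedure.  Problem sizes default to the
desk scale (64^3 phantoms, depth-3 / 8-channel networks) at which the whole
workflow runs in minutes on one CPU.
"""

from __future__ import annotations

import numpy as np

from .augment import TrainingCase
from .core import LabelMask, Volume
from .io import ROI_DOWNSAMPLE_FACTOR, downsample_for_roi, normalize_intensity
from .nn import ModelConfig, build_model, train
from .nn.training import TrainHistory
from .nn.unet import AttentionUNet3D
from . import phantom as ph

__all__ = [
    "build_phantom_cohort",
    "smoke_segmentation_config",
    "roi_model_config",
    "roi_training_cases",
    "train_roi_model",
    "train_segmentation_model",
]


def build_phantom_cohort(n: int, seed: int, grid: tuple[int, int, int] = (64, 64, 64),
                         spacing: tuple[float, float, float] = (1.5, 1.5, 1.5)
                         ) -> tuple[list[TrainingCase], list[ph.PhantomTruth],
                                    list[Volume]]:
    """Randomized contrast phantoms as normalized training cases.

    Returns (cases, truths, raw contrast volumes); the raw volumes feed the
    end-to-end cascade, which does its own normalization.
    """
    base = ph.default_abdominal_spec(grid=grid, spacing=spacing)
    specs = ph.generate_cohort(n, base, seed=seed)
    cases, truths, raws = [], [], []
    for i, s in enumerate(specs):
        contrast, _, truth = ph.generate_phantom(s)
        cases.append(TrainingCase(normalize_intensity(contrast),
                                  truth.label_mask, f"p{i}"))
        truths.append(truth)
        raws.append(contrast)
    return cases, truths, raws


def smoke_segmentation_config(seed: int = 0) -> ModelConfig:
    """Desk-scale high-resolution segmentation network: depth 3, base 8
    channels, 32^3 patches, 3 classes, soft-DICE/Adam for <= 30 epochs."""
    return ModelConfig(depth=3, base_channels=8, out_classes=3, patch_size=32,
                       epochs=30, seed=seed)


def roi_model_config(seed: int = 0) -> ModelConfig:
    """Coarse ROI network (binary aorta-vs-background on the 3.2x
    down-sampled rendition): depth 2, base 8 channels, 16^3 patches."""
    return ModelConfig(depth=2, base_channels=8, out_classes=2, patch_size=16,
                       epochs=15, seed=seed)


def roi_training_cases(cases: list[TrainingCase],
                       factor: float = ROI_DOWNSAMPLE_FACTOR
                       ) -> list[TrainingCase]:
    """Down-sampled, binarized renditions of a cohort for the ROI stage."""
    out = []
    for c in cases:
        low_img = downsample_for_roi(c.image, factor)
        binary = LabelMask((c.mask.data != 0).astype(np.uint8),
                           c.mask.spacing, c.mask.origin)
        low_msk = downsample_for_roi(binary, factor)
        out.append(TrainingCase(low_img, low_msk, f"{c.case_id}-roi"))
    return out


def train_roi_model(cases: list[TrainingCase], seed: int = 0,
                    epochs: int | None = None
                    ) -> tuple[AttentionUNet3D, TrainHistory]:
    model = build_model(roi_model_config(seed))
    history = train(model, roi_training_cases(cases), epochs=epochs,
                    online_augment=False, seed=seed + 1)
    return model, history


def train_segmentation_model(cases: list[TrainingCase],
                             val_cases: list[TrainingCase] | None = None,
                             seed: int = 0, epochs: int | None = None
                             ) -> tuple[AttentionUNet3D, TrainHistory]:
    model = build_model(smoke_segmentation_config(seed))
    history = train(model, cases, val_cases=val_cases, epochs=epochs,
                    seed=seed + 1, val_every=5)
    return model, history
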