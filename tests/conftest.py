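"""Shared fixtures: phantoms and (one, expensive) trained smoke model.

Everything is generated programmatically at fixed seeds; the heavy training
fixture is session-scoped so the learning smoke test and the end-to-end
cascade test share a single run.
"""

from __future__ import annotations

import pytest

from aortaseg import phantom as ph
from aortaseg.workflows import build_phantom_cohort, train_segmentation_model


@pytest.fixture(scope="session")
def tube():
    """Straight axial cylinder, radius 10 mm, wall 2 mm, 1 mm voxels."""
    spec = ph.straight_tube_spec(radius=10.0, wall=2.0, grid=(40, 40, 50),
                                 spacing=(1.0, 1.0, 1.0))
    contrast, noncontrast, truth = ph.generate_phantom(spec)
    return spec, contrast, noncontrast, truth


@pytest.fixture(scope="session")
def abdominal():
    """Curved aneurysmal phantom with crescentic thrombus, 1.5 mm voxels."""
    spec = ph.default_abdominal_spec(grid=(64, 64, 64), spacing=(1.5, 1.5, 1.5))
    contrast, noncontrast, truth = ph.generate_phantom(spec)
    return spec, contrast, noncontrast, truth


@pytest.fixture(scope="session")
def smoke_cohort():
    """Nine randomized 64^3 phantoms: (normalized cases, truths, raw
    contrast volumes)."""
    return build_phantom_cohort(9, seed=7)


@pytest.fixture(scope="session")
def smoke_model(smoke_cohort):
    """Attention U-Net (depth 3, base 8) trained on 8 phantoms, 30 epochs;
    the ninth phantom is held out."""
    cases, truths, _ = smoke_cohort
    model, history = train_segmentation_model(cases[:8], val_cases=cases[8:],
                                              seed=3)
    return model, history, cases, truths
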