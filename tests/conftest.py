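"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from roitex import RoiSpec, generate_intensity_volume, generate_label_volume


def glcm_count_oracle(levels, mask, offset, n_levels):
    """Naive per-voxel pair enumeration for one direction (symmetric counts).

    Deliberately loop-based and independent of the vectorized engine.
    """
    counts = np.zeros((n_levels, n_levels), dtype=np.int64)
    shape = levels.shape
    for z, y, x in np.argwhere(mask):
        z2, y2, x2 = z + offset[0], y + offset[1], x + offset[2]
        if 0 <= z2 < shape[0] and 0 <= y2 < shape[1] and 0 <= x2 < shape[2]:
            if mask[z2, y2, x2]:
                i, j = levels[z, y, x] - 1, levels[z2, y2, x2] - 1
                counts[i, j] += 1
                counts[j, i] += 1
    return counts


def contrast_oracle(levels, mask, n_levels, directions):
    """Averaged-GLCM contrast by brute-force enumeration over directions."""
    mats = []
    for off in directions:
        c = glcm_count_oracle(levels, mask, off, n_levels)
        if c.sum() > 0:
            mats.append(c / c.sum())
    P = np.mean(mats, axis=0)
    idx = np.arange(1, n_levels + 1)
    return float((((idx[:, None] - idx[None, :]) ** 2) * P).sum())


@pytest.fixture
def two_roi_specs():
    """A grey-matter ROI plus the CSF reference compartment."""
    return [
        RoiSpec(1, "hippocampus", "temporal", 400.0, 1000,
                texture_sigma=15.0, smooth_fwhm_vox=2.5, smooth_sigma=15.0),
        RoiSpec(2, "lateral ventricles", "csf", 100.0, 343),
    ]


@pytest.fixture
def zero_noise_volume():
    """Two constant-intensity regions (hippocampus 400, CSF 100), no noise."""
    specs = [
        RoiSpec(1, "hippocampus", "temporal", 400.0, 1000),
        RoiSpec(2, "lateral ventricles", "csf", 100.0, 343),
    ]
    labels = generate_label_volume(specs)
    vol = generate_intensity_volume(labels, specs, noise_floor_sigma=0.0, seed=0)
    return vol, specs
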