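"""Pre-texture intensity chain: partial-volume trimming, CSF-referenced
normalization, and fixed-bin-number grey-level quantization.

The chain is applied per ROI in the order trim -> CSF-normalize -> quantize.
Trimming retains voxels inside [mu - k*sigma, mu + k*sigma] (inclusive; mu and
sigma are the ROI's own mean and population SD, k = 3 by default), which caps
partial-volume outliers at ROI boundaries. Intensities are then divided by the
subject's mean lateral-ventricle CSF intensity, and the retained values are
re-binned to L grey levels (default 32) by per-ROI min-max linear binning.
The whole chain is invariant to any global rescaling of the raw volume.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "RoiIntensitySample",
    "QuantizedRoi",
    "trim_partial_volume",
    "csf_reference_mean",
    "normalize_to_csf",
    "quantize_to_levels",
    "prepare_quantized_roi",
]


@dataclass
class RoiIntensitySample:
    """Raw intensities of the voxels inside one ROI mask.

    ``mu`` / ``sigma`` are always recomputed from ``values`` (population-SD
    convention, i.e. divide by n).
    """

    values: np.ndarray
    roi_label: int = 0
    mu: float = field(init=False)
    sigma: float = field(init=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.size == 0:
            raise ValueError("empty intensity sample")
        self.mu = float(self.values.mean())
        self.sigma = float(self.values.std())  # ddof=0


@dataclass
class QuantizedRoi:
    """Grey levels over an ROI: integer levels in 1..n_levels on retained
    voxels, 0 (the excluded sentinel) elsewhere."""

    levels: np.ndarray
    retained_mask: np.ndarray
    n_levels: int

    def __post_init__(self) -> None:
        retained = self.levels[self.retained_mask]
        if retained.size and (retained.min() < 1 or retained.max() > self.n_levels):
            raise ValueError("retained levels must lie in 1..n_levels")


def trim_partial_volume(sample: RoiIntensitySample | np.ndarray, n_sigma: float = 3.0) -> np.ndarray:
    """Boolean mask of voxels with mu - n_sigma*sigma <= v <= mu + n_sigma*sigma.

    If sigma is 0 every voxel is retained. Accepts a raw value array for
    convenience; statistics always come from the sample itself.
    """
    if not isinstance(sample, RoiIntensitySample):
        sample = RoiIntensitySample(values=np.asarray(sample))
    if sample.sigma == 0:
        return np.ones(sample.values.shape, dtype=bool)
    lo = sample.mu - n_sigma * sample.sigma
    hi = sample.mu + n_sigma * sample.sigma
    return (sample.values >= lo) & (sample.values <= hi)


def csf_reference_mean(intensity: np.ndarray, labels: np.ndarray, csf_labels) -> float:
    """Mean intensity over all voxels carrying a CSF label."""
    csf_labels = np.atleast_1d(np.asarray(csf_labels))
    mask = np.isin(labels, csf_labels)
    if not mask.any():
        raise ValueError(f"no voxels carry a CSF label from {csf_labels.tolist()}")
    mean = float(intensity[mask].mean())
    if mean <= 0:
        raise ValueError(f"CSF reference mean must be positive, got {mean}")
    return mean


def normalize_to_csf(values: np.ndarray, csf_mean: float) -> np.ndarray:
    """Divide intensities by the subject's CSF reference mean."""
    if csf_mean <= 0:
        raise ValueError(f"csf_mean must be positive, got {csf_mean}")
    return np.asarray(values, dtype=np.float64) / csf_mean


def quantize_to_levels(values: np.ndarray, n_levels: int = 32) -> np.ndarray:
    """Linear min-max binning of values into integer levels 1..n_levels.

    level(v) = min(L, floor((v - vmin) / (vmax - vmin) * L) + 1); if all
    values are equal every voxel maps to level 1.
    """
    values = np.asarray(values, dtype=np.float64)
    if values.size == 0:
        raise ValueError("cannot quantize an empty value set")
    if n_levels < 2:
        raise ValueError("n_levels must be >= 2")
    vmin, vmax = values.min(), values.max()
    if vmax == vmin:
        return np.ones(values.shape, dtype=np.int32)
    lev = np.floor((values - vmin) / (vmax - vmin) * n_levels).astype(np.int32) + 1
    return np.minimum(lev, n_levels)


def prepare_quantized_roi(
    intensity: np.ndarray,
    roi_mask: np.ndarray,
    csf_mean: float,
    n_levels: int = 32,
    trim_sigma: float = 3.0,
    trim_scope_values: np.ndarray | None = None,
) -> QuantizedRoi:
    """Run trim -> CSF-normalize -> quantize over an ROI mask.

    ``trim_scope_values`` optionally supplies the value population used for the
    trim statistics (e.g. whole-brain voxels when trimming is configured
    globally); by default the ROI's own voxels are used.
    """
    vals = intensity[roi_mask]
    if vals.size == 0:
        raise ValueError("ROI mask selects no voxels")
    if trim_scope_values is None:
        keep = trim_partial_volume(RoiIntensitySample(vals), n_sigma=trim_sigma)
    else:
        scope = RoiIntensitySample(np.asarray(trim_scope_values))
        if scope.sigma == 0:
            keep = np.ones(vals.shape, dtype=bool)
        else:
            lo = scope.mu - trim_sigma * scope.sigma
            hi = scope.mu + trim_sigma * scope.sigma
            keep = (vals >= lo) & (vals <= hi)
    if not keep.any():
        raise ValueError("trimming removed every ROI voxel")
    normalized = normalize_to_csf(vals[keep], csf_mean)
    lev_vals = quantize_to_levels(normalized, n_levels=n_levels)
    levels = np.zeros(intensity.shape, dtype=np.int32)
    retained = np.zeros(intensity.shape, dtype=bool)
    idx = np.argwhere(roi_mask)[keep]
    levels[tuple(idx.T)] = lev_vals
    retained[tuple(idx.T)] = True
    return QuantizedRoi(levels=levels, retained_mask=retained, n_levels=n_levels)
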