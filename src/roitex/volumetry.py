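"""Per-ROI volumetry, total brain volume (TBV) and lobe-level aggregates.

Volumes are voxel-count based: volume_cc = n_voxels * voxel_volume_mm3 / 1000.
TBV defaults to the sum over all nonzero labels (all segmented structures,
including ventricular CSF), mirroring a whole-segmentation sum. An
intensity-sum variant is available for sensitivity analyses.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .glcm import TextureFeatureSet, roi_texture_profile

__all__ = [
    "VolumeRecord",
    "roi_volume_cc",
    "total_brain_volume",
    "normalize_to_tbv",
    "lobe_aggregate_volumes",
    "lobe_texture",
    "LOBE_TITLES",
]

LOBE_TITLES = {
    "temporal": "Temporal lobe",
    "frontal": "Frontal lobe",
    "parietal": "Parietal lobe",
    "occipital": "Occipital lobe",
    "subcortical": "Subcortical gray matter",
    "cerebellum": "Cerebellum",
}


@dataclass
class VolumeRecord:
    roi: str
    n_voxels: int
    volume_cc: float
    volume_tbv_norm: float | None = None
    empty: bool = False  # warning flag for an absent label


def _voxel_volume_mm3(voxel_dims) -> float:
    dims = np.asarray(voxel_dims, dtype=np.float64)
    if (dims <= 0).any():
        raise ValueError("voxel dimensions must be positive")
    return float(np.prod(dims))


def roi_volume_cc(
    labels: np.ndarray,
    roi_label: int,
    voxel_dims=(1.0, 1.0, 1.0),
    roi_name: str | None = None,
    intensity: np.ndarray | None = None,
    mode: str = "count",
) -> VolumeRecord:
    """Volume of one ROI in cc.

    mode="count" (default) uses the voxel count; mode="intensity_sum" sums the
    in-mask intensities instead (then scaled by voxel volume / 1000). An
    absent label yields a zero-count record flagged ``empty``.
    """
    vv = _voxel_volume_mm3(voxel_dims)
    mask = labels == roi_label
    n = int(mask.sum())
    if mode == "count":
        measure = float(n)
    elif mode == "intensity_sum":
        if intensity is None:
            raise ValueError("intensity volume required for mode='intensity_sum'")
        measure = float(intensity[mask].sum())
    else:
        raise ValueError(f"unknown volume mode {mode!r}")
    return VolumeRecord(
        roi=roi_name if roi_name is not None else str(roi_label),
        n_voxels=n,
        volume_cc=measure * vv / 1000.0,
        empty=(n == 0),
    )


def total_brain_volume(
    labels: np.ndarray, voxel_dims=(1.0, 1.0, 1.0), tbv_labels=None
) -> float:
    """Sum of member-structure volumes in cc (default: every nonzero label)."""
    vv = _voxel_volume_mm3(voxel_dims)
    if tbv_labels is None:
        n = int((labels != 0).sum())
    else:
        tbv_labels = np.atleast_1d(np.asarray(tbv_labels))
        if tbv_labels.size == 0:
            raise ValueError("tbv_labels must be non-empty")
        n = int(np.isin(labels, tbv_labels).sum())
    return n * vv / 1000.0


def normalize_to_tbv(volume_cc: float, tbv_cc: float) -> float:
    """TBV-normalized volume fraction."""
    if tbv_cc <= 0:
        raise ValueError(f"TBV must be positive, got {tbv_cc}")
    return volume_cc / tbv_cc


def lobe_aggregate_volumes(records: pd.DataFrame, lobe_map: dict[str, str]) -> pd.DataFrame:
    """Lobe volume = exact sum of member-ROI volumes.

    ``records`` needs columns roi, n_voxels, volume_cc (plus optional
    volume_tbv_norm, which is additive for disjoint ROIs).
    """
    missing = [r for r in records["roi"] if r not in lobe_map]
    if missing:
        raise ValueError(f"ROIs missing from lobe map: {missing}")
    out = records.assign(lobe=[lobe_map[r] for r in records["roi"]])
    agg_cols = {"n_voxels": "sum", "volume_cc": "sum"}
    if "volume_tbv_norm" in out:
        agg_cols["volume_tbv_norm"] = "sum"
    return out.groupby("lobe", sort=False).agg(agg_cols).reset_index()


def lobe_texture(
    intensity: np.ndarray,
    labels: np.ndarray,
    member_labels,
    csf_labels,
    n_levels: int = 32,
    trim_sigma: float = 3.0,
    csf_mean: float | None = None,
    mode: str = "merged_mask",
) -> TextureFeatureSet:
    """Lobe-level texture features.

    mode="merged_mask" (default) runs the full chain once on the union of the
    member-ROI masks, so trimming and quantization see the lobe as a single
    region; mode="mean_of_rois" averages the members' feature values instead.
    """
    if mode == "merged_mask":
        return roi_texture_profile(
            intensity,
            labels,
            member_labels,
            csf_labels,
            n_levels=n_levels,
            trim_sigma=trim_sigma,
            csf_mean=csf_mean,
        )
    if mode == "mean_of_rois":
        feats = [
            roi_texture_profile(
                intensity, labels, lab, csf_labels,
                n_levels=n_levels, trim_sigma=trim_sigma, csf_mean=csf_mean,
            )
            for lab in np.atleast_1d(np.asarray(member_labels))
        ]
        valid = [f for f in feats if f.valid]
        if not valid:
            return TextureFeatureSet(np.nan, np.nan, np.nan, 0)
        return TextureFeatureSet(
            contrast=float(np.mean([f.contrast for f in valid])),
            entropy=float(np.mean([f.entropy for f in valid])),
            autocorrelation=float(np.mean([f.autocorrelation for f in valid])),
            n_directions_used=min(f.n_directions_used for f in valid),
        )
    raise ValueError(f"unknown lobe texture mode {mode!r}")
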