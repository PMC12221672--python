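"""Symmetric 3D grey-level co-occurrence matrices and Haralick features.

Co-occurrences are counted at voxel distance 1 over the 13 unique direction
offsets of the 26-neighbourhood (one of each +-pair). Each ordered voxel pair
with both members inside the retained ROI mask is accumulated symmetrically
(C[i,j] and C[j,i]), each direction's matrix is normalized to sum 1, and the
per-direction matrices are averaged with equal weight (directions with zero
valid pairs are skipped). Features on the averaged matrix:

    contrast         = sum_ij (i - j)^2 P_ij      (local grey-level variation)
    entropy          = -sum_ij P_ij ln P_ij       (nats; 0 ln 0 := 0)
    autocorrelation  = sum_ij i * j * P_ij

with grey levels indexed 1..N.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .normalize import QuantizedRoi, csf_reference_mean, prepare_quantized_roi

__all__ = [
    "GLCM",
    "TextureFeatureSet",
    "enumerate_directions",
    "build_glcm",
    "average_glcms",
    "feature_contrast",
    "feature_entropy",
    "feature_autocorrelation",
    "roi_texture_profile",
]

_NORM_TOL = 1e-6


@dataclass
class GLCM:
    """Normalized N x N co-occurrence matrix and its raw pair count."""

    P: np.ndarray
    n_levels: int
    pair_count: int


@dataclass
class TextureFeatureSet:
    contrast: float
    entropy: float
    autocorrelation: float
    n_directions_used: int

    @property
    def valid(self) -> bool:
        return self.n_directions_used > 0


def enumerate_directions() -> list[tuple[int, int, int]]:
    """The 13 canonical distance-1 offsets (first nonzero component positive).

    Together with their negations they cover all 26 neighbours; no canonical
    offset is the negation of another. Order is fixed (lexicographic).
    """
    dirs = []
    for dx in (-1, 0, 1):
        for dy in (-1, 0, 1):
            for dz in (-1, 0, 1):
                off = (dx, dy, dz)
                if off == (0, 0, 0):
                    continue
                first = next(v for v in off if v != 0)
                if first > 0:
                    dirs.append(off)
    return sorted(dirs)


def _shift_slices(offset, shape):
    src, dst = [], []
    for o, _ in zip(offset, shape):
        if o >= 0:
            src.append(slice(0, None if o == 0 else -o))
            dst.append(slice(o, None))
        else:
            src.append(slice(-o, None))
            dst.append(slice(0, o))
    return tuple(src), tuple(dst)


def build_glcm(quantized: QuantizedRoi, offset: tuple[int, int, int]) -> GLCM:
    """Symmetric co-occurrence matrix for one direction offset.

    Every ordered pair (v, v + offset) with both voxels retained contributes
    to C[i, j] and C[j, i]; P = C / sum(C). A direction with no valid pair
    returns pair_count 0 and a zero matrix (callers must skip it).
    """
    n = quantized.n_levels
    levels, mask = quantized.levels, quantized.retained_mask
    retained = levels[mask]
    if retained.size and (retained.min() < 1 or retained.max() > n):
        raise ValueError("quantized levels must lie in 1..n_levels")
    src, dst = _shift_slices(offset, levels.shape)
    both = mask[src] & mask[dst]
    i = levels[src][both] - 1
    j = levels[dst][both] - 1
    counts = np.bincount(i * n + j, minlength=n * n).reshape(n, n)
    counts = counts + counts.T
    pair_count = int(counts.sum())
    if pair_count == 0:
        return GLCM(P=np.zeros((n, n)), n_levels=n, pair_count=0)
    return GLCM(P=counts / pair_count, n_levels=n, pair_count=pair_count)


def average_glcms(glcms: list[GLCM]) -> tuple[GLCM, int]:
    """Equal-weight elementwise mean of the normalized matrices.

    Directions with zero valid pairs are excluded (not averaged as zeros);
    the mean is renormalized to sum exactly 1 to absorb floating drift.
    Returns the averaged GLCM and the number of directions used.
    """
    used = [g for g in glcms if g.pair_count > 0]
    if not used:
        raise ValueError("no direction produced any co-occurrence pair")
    n = used[0].n_levels
    if any(g.n_levels != n for g in used):
        raise ValueError("all GLCMs must share the same grey-level count")
    P = np.mean([g.P for g in used], axis=0)
    P = P / P.sum()
    return GLCM(P=P, n_levels=n, pair_count=sum(g.pair_count for g in used)), len(used)


def _check_normalized(glcm: GLCM) -> np.ndarray:
    total = float(glcm.P.sum())
    if abs(total - 1.0) > _NORM_TOL:
        raise ValueError(f"GLCM is not normalized (sum = {total})")
    return glcm.P


def feature_contrast(glcm: GLCM) -> float:
    """sum_ij (i - j)^2 P_ij; in [0, (N-1)^2]."""
    P = _check_normalized(glcm)
    idx = np.arange(1, glcm.n_levels + 1)
    diff2 = (idx[:, None] - idx[None, :]) ** 2
    return float((diff2 * P).sum())


def feature_entropy(glcm: GLCM) -> float:
    """-sum_ij P_ij ln P_ij in nats, with 0 ln 0 = 0."""
    P = _check_normalized(glcm)
    nz = P[P > 0]
    return float(-(nz * np.log(nz)).sum())


def feature_autocorrelation(glcm: GLCM) -> float:
    """sum_ij i * j * P_ij with 1-based level indices."""
    P = _check_normalized(glcm)
    idx = np.arange(1, glcm.n_levels + 1, dtype=np.float64)
    return float((np.outer(idx, idx) * P).sum())


def roi_texture_profile(
    intensity: np.ndarray,
    labels: np.ndarray,
    roi_label,
    csf_labels,
    n_levels: int = 32,
    trim_sigma: float = 3.0,
    csf_mean: float | None = None,
) -> TextureFeatureSet:
    """Full texture chain for one ROI (or a merged set of labels).

    trim -> CSF-normalize -> quantize -> 13 per-direction GLCMs -> average ->
    contrast / entropy / autocorrelation. ``roi_label`` may be an int or a
    collection of ints (a merged lobe mask). An ROI with no adjacent retained
    pair yields a flagged record (NaN features, n_directions_used 0).
    """
    roi_labels = np.atleast_1d(np.asarray(roi_label))
    mask = np.isin(labels, roi_labels)
    if not mask.any():
        raise ValueError(f"labels {roi_labels.tolist()} select no voxels")
    if csf_mean is None:
        csf_mean = csf_reference_mean(intensity, labels, csf_labels)
    # crop to the ROI bounding box (plus one voxel) before building matrices
    loc = np.argwhere(mask)
    lo = np.maximum(loc.min(axis=0) - 1, 0)
    hi = loc.max(axis=0) + 2
    sl = tuple(slice(a, b) for a, b in zip(lo, hi))
    quantized = prepare_quantized_roi(
        intensity[sl], mask[sl], csf_mean, n_levels=n_levels, trim_sigma=trim_sigma
    )
    glcms = [build_glcm(quantized, off) for off in enumerate_directions()]
    if all(g.pair_count == 0 for g in glcms):
        return TextureFeatureSet(np.nan, np.nan, np.nan, n_directions_used=0)
    avg, n_used = average_glcms(glcms)
    return TextureFeatureSet(
        contrast=feature_contrast(avg),
        entropy=feature_entropy(avg),
        autocorrelation=feature_autocorrelation(avg),
        n_directions_used=n_used,
    )
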