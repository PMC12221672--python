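"""Monte-Carlo studies of the full pipeline on miniature phantom cohorts.

Two designed experiments back the statistical claims of the pipeline:

* :func:`null_calibration` — cohorts with no injected effect; the per-ROI
  ANCOVA omnibus should reject at the nominal rate and post hoc patterns
  should be empty except for false positives.
* :func:`dissociation_study` — a texture effect injected at both
  neurodegeneration-positive stages but atrophy only at the MCI stage; the
  pipeline should report texture group differences at both stages while the
  volume difference appears only at the MCI stage.

Both run on a deliberately small 5-region parcellation (a few hundred voxels
per region) so hundreds of cohorts fit in minutes; the statistical structure,
not anatomical scale, is what these studies exercise.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .phantom import Cohort, CohortSpec, GroupEffect, RoiSpec, generate_cohort
from .pipeline import RunConfig, extract_cohort_features
from .stats import build_results_table

__all__ = [
    "study_roi_specs",
    "null_cohort_spec",
    "dissociation_cohort_spec",
    "null_calibration",
    "dissociation_study",
]


def study_roi_specs() -> list[RoiSpec]:
    """Miniature parcellation: four grey-matter regions, white matter, CSF."""
    common = dict(texture_sigma=15.0, smooth_fwhm_vox=2.5, smooth_sigma=15.0)
    return [
        RoiSpec(1, "hippocampus", "temporal", 400.0, 729, **common),
        RoiSpec(2, "entorhinal", "temporal", 380.0, 512, **common),
        RoiSpec(3, "putamen", "subcortical", 420.0, 729, **common),
        RoiSpec(4, "precuneus", "parietal", 410.0, 512, **common),
        RoiSpec(5, "cerebral white matter", "other", 620.0, 729,
                texture_sigma=8.0, smooth_fwhm_vox=2.5, smooth_sigma=10.0),
        RoiSpec(6, "lateral ventricles", "csf", 100.0, 343,
                texture_sigma=4.0, smooth_fwhm_vox=2.5, smooth_sigma=4.0),
    ]


def null_cohort_spec(n_per_group=(20, 20, 20), seed: int = 0) -> CohortSpec:
    """No injected effects: all multipliers 1, all atrophy fractions 0."""
    return CohortSpec(
        n_per_group=tuple(n_per_group),
        roi_specs=study_roi_specs(),
        group_effects=[GroupEffect(g) for g in ("N-CN", "N+CN", "N+MCI")],
        noise_floor_sigma=8.0,
        seed=seed,
    )


def dissociation_cohort_spec(
    n_per_group=(40, 40, 40),
    seed: int = 0,
    target_roi: str = "entorhinal",
    texture_multipliers: tuple[float, float] = (1.6, 2.0),
    mci_atrophy: float = 0.15,
) -> CohortSpec:
    """Texture effect at both N+ stages; atrophy only at the MCI stage."""
    mb, mc = texture_multipliers
    return CohortSpec(
        n_per_group=tuple(n_per_group),
        roi_specs=study_roi_specs(),
        group_effects=[
            GroupEffect("N-CN"),
            GroupEffect("N+CN", texture_sigma_multiplier={target_roi: mb}),
            GroupEffect(
                "N+MCI",
                texture_sigma_multiplier={target_roi: mc},
                atrophy_fraction={target_roi: mci_atrophy},
            ),
        ],
        noise_floor_sigma=8.0,
        seed=seed,
    )


_FAST_CONFIG = RunConfig(include_lobe_rows=False)


def _cohort_tables(cohort: Cohort, alpha: float = 0.05):
    features = extract_cohort_features(cohort, _FAST_CONFIG)
    subj = cohort.subjects
    vol, vol_long = build_results_table(features, subj, "volume", alpha=alpha)
    tex, tex_long = build_results_table(features, subj, "texture", alpha=alpha)
    return vol, tex, vol_long, tex_long


def null_calibration(
    n_cohorts: int = 500,
    n_per_group=(20, 20, 20),
    seed: int = 0,
    alpha: float = 0.05,
) -> dict:
    """Type-I behaviour of the per-ROI pipeline over null phantom cohorts.

    Returns omnibus rejection rates (pooled over grey-matter ROIs and over
    both analysis kinds), the non-empty post hoc pattern rate, and the test
    counts needed for binomial intervals.
    """
    rej_vol, rej_tex, nonempty = [], [], []
    for rep in range(n_cohorts):
        spec = null_cohort_spec(n_per_group=n_per_group, seed=(seed * 1_000_003 + rep) % 2**31)
        cohort = generate_cohort(spec)
        vol, tex, _, _ = _cohort_tables(cohort, alpha=alpha)
        rej_vol.extend((vol["p"] < alpha).tolist())
        rej_tex.extend((tex["p"] < alpha).tolist())
        nonempty.extend((vol["pattern"] != "").tolist())
        nonempty.extend((tex["pattern"] != "").tolist())
    n_vol, n_tex = len(rej_vol), len(rej_tex)
    return {
        "alpha": alpha,
        "n_cohorts": n_cohorts,
        "n_tests_volume": n_vol,
        "n_tests_texture": n_tex,
        "rejection_rate_volume": float(np.mean(rej_vol)),
        "rejection_rate_texture": float(np.mean(rej_tex)),
        "rejection_rate_overall": float(np.mean(rej_vol + rej_tex)),
        "pattern_nonempty_rate": float(np.mean(nonempty)),
    }


def _pair_p(long: pd.DataFrame, roi: str, pair: str) -> float:
    sel = long[(long["roi"] == roi) & (long["pair"] == pair)]
    return float(sel["p_adj"].iloc[0])


def dissociation_study(
    n_reps: int = 100,
    n_per_group=(40, 40, 40),
    seed: int = 0,
    alpha: float = 0.05,
    target_roi: str = "entorhinal",
) -> dict:
    """Recovery rate of the texture-before-volume signature.

    A replicate counts as recovered when, in the target region, the texture
    post hoc comparisons a-b and a-c are both significant (Bonferroni-adjusted
    p < alpha) while the volume comparison a-c is significant and a-b is not.
    """
    recovered, tex_both, vol_only_mci = [], [], []
    for rep in range(n_reps):
        spec = dissociation_cohort_spec(
            n_per_group=n_per_group, seed=(seed * 2_000_003 + rep) % 2**31,
            target_roi=target_roi,
        )
        cohort = generate_cohort(spec)
        _, _, vol_long, tex_long = _cohort_tables(cohort, alpha=alpha)
        t_ab = _pair_p(tex_long, target_roi, "a-b") < alpha
        t_ac = _pair_p(tex_long, target_roi, "a-c") < alpha
        v_ab = _pair_p(vol_long, target_roi, "a-b") < alpha
        v_ac = _pair_p(vol_long, target_roi, "a-c") < alpha
        tex_both.append(t_ab and t_ac)
        vol_only_mci.append(v_ac and not v_ab)
        recovered.append(t_ab and t_ac and v_ac and not v_ab)
    return {
        "n_reps": n_reps,
        "recovery_rate": float(np.mean(recovered)),
        "texture_both_stages_rate": float(np.mean(tex_both)),
        "volume_only_mci_rate": float(np.mean(vol_only_mci)),
    }
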