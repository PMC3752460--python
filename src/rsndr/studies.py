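"""Replicated simulation studies: FWER calibration, power, confound control.

These harnesses run the full synthetic-cohort -> dual-regression ->
permutation-inference chain many times and summarize error rates, so the
same code backs both the validation test suite and the reproduction
script. Problem sizes default to desk scale: a 24x24x16 grid with a ~550
voxel analysis mask, 6 networks, 250 permutations.
"""

from __future__ import annotations

import dataclasses
from typing import Optional

import numpy as np

from .dualreg import collect_ic_blocks, dual_regression_volumes
from .groupica import template_from_atlas
from .inference import TfceParams, permutation_test, split_blocks, yconcat
from .synthetic_data import (
    CohortConfig,
    EffectSpec,
    SyntheticCohort,
    simulate_cohort,
)
from .volio import mask_to_matrix

__all__ = [
    "FwerStudyResult",
    "PowerStudyResult",
    "ConfoundStudyResult",
    "null_cohort_config",
    "fwer_null_study",
    "power_study",
    "confound_study",
]

#: desk-scale mask fraction giving ~550 in-mask voxels on a 24x24x16 grid
DESK_BRAIN_FRAC = 0.48


def null_cohort_config(
    n_per_group: int = 8,
    n_networks: int = 6,
    grid_shape: tuple[int, int, int] = (24, 24, 16),
    effects: tuple[EffectSpec, ...] = (),
) -> CohortConfig:
    """Desk-scale cohort config used by the replicated studies."""
    return CohortConfig(
        grid_shape=grid_shape,
        n_patients=n_per_group,
        n_controls=n_per_group,
        n_networks=n_networks,
        brain_frac=DESK_BRAIN_FRAC,
        width_range=(1.2, 1.8),
        min_center_separation=3.5,
        effects=effects,
    )


def _cohort_to_dataset(cohort: SyntheticCohort, des_norm: bool, with_gm: bool):
    """Dual-regress a cohort against its truth atlas; return a ConcatDataset."""
    template = template_from_atlas(cohort.atlas, cohort.mask)
    dr = dual_regression_volumes(
        cohort.subjects,
        cohort.design.subject_ids,
        template,
        des_norm=des_norm,
        mask=cohort.mask,
    )
    blocks = collect_ic_blocks(dr)
    gm = None
    if with_gm:
        stacked, _ = mask_to_matrix(cohort.gm_maps, cohort.mask)
        gm = stacked[:, 0, :]  # (S, V)
    return yconcat(blocks, cohort.design, cohort.mask, gm_covariate=gm)


@dataclasses.dataclass
class FwerStudyResult:
    n_cohorts: int
    alpha: float
    any_sig_joint: np.ndarray    # (n_cohorts,) bool, inter-IC corrected
    any_sig_single: np.ndarray   # (n_cohorts,) bool, first block only

    @property
    def fwer_joint(self) -> float:
        return float(self.any_sig_joint.mean())

    @property
    def fwer_single(self) -> float:
        return float(self.any_sig_single.mean())


def fwer_null_study(
    n_cohorts: int = 200,
    n_perm: int = 250,
    alpha: float = 0.05,
    seed: int = 1,
    n_per_group: int = 8,
    n_networks: int = 6,
    tfce_params: Optional[TfceParams] = None,
    progress: bool = False,
) -> FwerStudyResult:
    """Empirical FWER of the corrected tests on global-null cohorts.

    Each replicate simulates a cohort with no planted group effect, runs
    dual regression against the truth template and the joint inter-IC
    permutation test. A replicate counts as a family-wise error when any
    voxel in any block has corrected p < alpha. The single-map error rate
    is measured on the first block with the identical permutation stream
    (the per-block null maxima of the joint run).
    """
    params = tfce_params or TfceParams()
    any_joint = np.zeros(n_cohorts, dtype=bool)
    any_single = np.zeros(n_cohorts, dtype=bool)
    config = null_cohort_config(n_per_group=n_per_group, n_networks=n_networks)
    for i in range(n_cohorts):
        cohort_seed = seed * 1_000_003 + i
        cohort = simulate_cohort(config, seed=cohort_seed)
        data = _cohort_to_dataset(cohort, des_norm=True, with_gm=False)
        res = permutation_test(
            data,
            n_perm=n_perm,
            seed=cohort_seed + 7,
            tfce_params=params,
            direction="patient>control",
        )
        # any corrected p < alpha <=> p at the best voxel < alpha
        p_min = min(p.min() for p in res.pmaps)
        any_joint[i] = p_min < alpha
        # single-map correction for block 0: same stream, block-0 null only
        null0 = res.null_max_blocks[:, 0]
        tf0 = res.tfce_maps[0].max()
        p0 = (1.0 + (null0 >= tf0).sum()) / (1.0 + res.n_perm)
        any_single[i] = p0 < alpha
        if progress and (i + 1) % 20 == 0:
            print(f"  null cohort {i + 1}/{n_cohorts}")
    return FwerStudyResult(
        n_cohorts=n_cohorts,
        alpha=alpha,
        any_sig_joint=any_joint,
        any_sig_single=any_single,
    )


@dataclasses.dataclass
class PowerStudyResult:
    n_replicates: int
    detected: np.ndarray  # (n_replicates,) bool

    @property
    def power(self) -> float:
        return float(self.detected.mean())


def power_study(
    n_replicates: int = 50,
    amplitude_ratio: float = 2.0,
    n_per_group: int = 10,
    n_perm: int = 250,
    alpha: float = 0.05,
    seed: int = 1,
    n_networks: int = 6,
    effect_network: int = 0,
) -> PowerStudyResult:
    """Detection rate of a planted pure-amplitude group difference.

    One network's time-course std is scaled by ``amplitude_ratio`` in
    patients; dual regression runs with variance normalization (des_norm=1)
    so the amplitude difference reaches the betas. A replicate counts as
    detected when the jointly corrected significant mask of the planted
    network's block overlaps the truth blob (map weight >= 0.5).
    """
    detected = np.zeros(n_replicates, dtype=bool)
    config = null_cohort_config(
        n_per_group=n_per_group,
        n_networks=n_networks,
        effects=(EffectSpec(network_index=effect_network, amplitude_ratio=amplitude_ratio),),
    )
    for i in range(n_replicates):
        rep_seed = seed * 2_000_003 + i
        cohort = simulate_cohort(config, seed=rep_seed)
        data = _cohort_to_dataset(cohort, des_norm=True, with_gm=False)
        res = permutation_test(
            data, n_perm=n_perm, seed=rep_seed + 7, direction="patient>control"
        )
        block = split_blocks(res, alpha=alpha)[effect_network]
        truth_blob = cohort.atlas.maps[effect_network] >= 0.5
        detected[i] = bool((block.sig_mask & truth_blob).any())
    return PowerStudyResult(n_replicates=n_replicates, detected=detected)


@dataclasses.dataclass
class ConfoundStudyResult:
    n_replicates: int
    sig_counts_with_gm: np.ndarray     # total significant voxels, GM covariate in
    sig_counts_without_gm: np.ndarray  # covariate omitted
    any_sig_with_gm: np.ndarray
    any_sig_without_gm: np.ndarray


def confound_study(
    n_replicates: int = 20,
    gm_reduction: float = 0.35,
    bold_attenuation: float = 0.35,
    atrophy_radius: float = 2.5,
    n_per_group: int = 10,
    n_perm: int = 250,
    alpha: float = 0.05,
    seed: int = 1,
    n_networks: int = 6,
    effect_network: int = 0,
) -> ConfoundStudyResult:
    """Voxel-wise GM covariate adjustment of an atrophy-induced difference.

    Patients carry an atrophy sphere at one network's center that reduces
    gray matter and attenuates BOLD weights by matching fractions; network
    amplitudes are identical between groups, so every group difference in
    the betas is GM-mediated. The joint test runs once with the voxel-wise
    GM covariate (Freedman-Lane) and once without, on the same cohorts.
    """
    effects = (
        EffectSpec(
            network_index=effect_network,
            atrophy=(None, atrophy_radius, gm_reduction, bold_attenuation),
        ),
    )
    config = null_cohort_config(n_per_group=n_per_group, n_networks=n_networks, effects=effects)
    counts_gm = np.zeros(n_replicates, dtype=int)
    counts_raw = np.zeros(n_replicates, dtype=int)
    any_gm = np.zeros(n_replicates, dtype=bool)
    any_raw = np.zeros(n_replicates, dtype=bool)
    for i in range(n_replicates):
        rep_seed = seed * 3_000_017 + i
        cohort = simulate_cohort(config, seed=rep_seed)
        for with_gm in (True, False):
            data = _cohort_to_dataset(cohort, des_norm=True, with_gm=with_gm)
            res = permutation_test(
                data,
                n_perm=n_perm,
                seed=rep_seed + 7,
                direction="control>patient",  # attenuation lowers patient betas
            )
            n_sig = sum(int((p < alpha).sum()) for p in res.pmaps)
            if with_gm:
                counts_gm[i] = n_sig
                any_gm[i] = n_sig > 0
            else:
                counts_raw[i] = n_sig
                any_raw[i] = n_sig > 0
    return ConfoundStudyResult(
        n_replicates=n_replicates,
        sig_counts_with_gm=counts_gm,
        sig_counts_without_gm=counts_raw,
        any_sig_with_gm=any_gm,
        any_sig_without_gm=any_raw,
    )
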