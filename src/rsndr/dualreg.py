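"""Two-stage dual regression.

Stage A regresses each timepoint's voxel pattern on the (demeaned) group
component maps, giving a subject-specific time course per component.
Stage B regresses each voxel's time series on those time courses, giving
subject-specific spatial beta maps.

The variance-normalization switch (``des_norm``) scales the stage-B design
columns to unit standard deviation. With it on, a network whose time
course simply fluctuates more strongly in one group shows up as larger
betas (amplitude + spatial spread); with it off, betas reflect spatial
shape only and pure amplitude differences cancel.
"""

from __future__ import annotations

import dataclasses
from typing import Callable, Optional, Sequence

import numpy as np

from .groupica import SpatialMapSet
from .volio import BrainMask, DesignTable, Volume4D, mask_to_matrix, read_volume4d

__all__ = [
    "TimeCourseMatrix",
    "SubjectMaps",
    "DualRegressionResult",
    "CollinearTemplateError",
    "stage_a_timecourses",
    "stage_b_maps",
    "dual_regression",
    "dual_regression_volumes",
    "collect_ic_blocks",
]

RANK_RTOL = 1e-10


class CollinearTemplateError(ValueError):
    """Template maps are rank deficient over the mask."""


@dataclasses.dataclass
class TimeCourseMatrix:
    subject_id: str
    values: np.ndarray  # (T, C)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError("time courses must be (T, C)")
        if not np.isfinite(self.values).all():
            raise ValueError("non-finite time-course values")


@dataclasses.dataclass
class SubjectMaps:
    subject_id: str
    betas: np.ndarray  # (C, V)
    des_norm: bool
    zero_variance_components: np.ndarray  # (C,) bool


@dataclasses.dataclass
class DualRegressionResult:
    timecourses: list[TimeCourseMatrix]
    maps: list[SubjectMaps]
    des_norm: bool
    template_order: int

    def __len__(self) -> int:
        return len(self.maps)


# ---------------------------------------------------------------------------


def _demeaned_template(template: SpatialMapSet) -> np.ndarray:
    """(V, C) design of template maps, demeaned over the mask, rank-checked."""
    g = template.zmaps.T - template.zmaps.mean(axis=1)  # (V, C)
    sv = np.linalg.svd(g, compute_uv=False)
    rank = int((sv > RANK_RTOL * sv[0] * max(g.shape)).sum())
    if rank < g.shape[1]:
        c = np.corrcoef(g.T)
        pairs = [
            (template.labels[i], template.labels[j])
            for i in range(len(c))
            for j in range(i + 1, len(c))
            if abs(c[i, j]) > 0.999
        ]
        raise CollinearTemplateError(
            f"template rank {rank} < {g.shape[1]}; near-collinear pairs: {pairs}"
        )
    return g


def stage_a_timecourses(
    subject: Volume4D, template: SpatialMapSet, mask: BrainMask
) -> TimeCourseMatrix:
    """OLS of every timepoint's voxel pattern on the demeaned template maps.

    All maps enter one multiple regression per timepoint; the voxel pattern
    is demeaned over the mask, which plays the role of an intercept.
    """
    (stacked, _) = mask_to_matrix([subject], mask)
    y = stacked[0]  # (T, V)
    g = _demeaned_template(template)
    yd = y - y.mean(axis=1, keepdims=True)
    coef, *_ = np.linalg.lstsq(g, yd.T, rcond=None)  # (C, T)
    return TimeCourseMatrix(subject_id="", values=coef.T)


def stage_b_maps(
    subject: Volume4D,
    tcs: TimeCourseMatrix,
    des_norm: bool,
    mask: BrainMask,
) -> SubjectMaps:
    """Per-voxel OLS of the time series on the (demeaned, optionally
    unit-std) stage-A time courses; returns one beta map per component."""
    (stacked, _) = mask_to_matrix([subject], mask)
    y = stacked[0]  # (T, V)
    if tcs.values.shape[0] != y.shape[0]:
        raise ValueError(
            f"time courses T={tcs.values.shape[0]} != subject T={y.shape[0]}"
        )
    d = tcs.values - tcs.values.mean(axis=0)
    sd = d.std(axis=0, ddof=1)
    zero = sd <= 1e-12 * max(1.0, float(np.abs(tcs.values).max()))
    if des_norm:
        d = d / np.where(zero, 1.0, sd)
    d = d[:, ~zero]
    yd = y - y.mean(axis=0)
    betas = np.zeros((tcs.values.shape[1], y.shape[1]))
    if d.shape[1]:
        coef, *_ = np.linalg.lstsq(d, yd, rcond=None)
        betas[~zero] = coef
    return SubjectMaps(
        subject_id=tcs.subject_id,
        betas=betas,
        des_norm=bool(des_norm),
        zero_variance_components=zero,
    )


def dual_regression_volumes(
    vols: Sequence[Volume4D],
    subject_ids: Sequence[str],
    template: SpatialMapSet,
    des_norm: bool,
    mask: BrainMask,
) -> DualRegressionResult:
    """Stage A then stage B for each subject, in order; no cross-subject
    coupling, so outputs permute exactly with the input order."""
    if len(vols) != len(subject_ids):
        raise ValueError("vols and subject_ids length mismatch")
    tcs_list, maps_list, failures = [], [], []
    for vol, sid in zip(vols, subject_ids):
        try:
            tcs = stage_a_timecourses(vol, template, mask)
            tcs.subject_id = str(sid)
            maps = stage_b_maps(vol, tcs, des_norm, mask)
            maps.subject_id = str(sid)
        except Exception as exc:  # noqa: BLE001 - collected and re-raised
            failures.append(f"{sid}: {exc}")
            continue
        tcs_list.append(tcs)
        maps_list.append(maps)
    if failures:
        raise RuntimeError(
            "dual regression failed for "
            f"{len(failures)} subject(s):\n" + "\n".join(failures)
        )
    return DualRegressionResult(
        timecourses=tcs_list,
        maps=maps_list,
        des_norm=bool(des_norm),
        template_order=template.order,
    )


def dual_regression(
    design: DesignTable,
    template: SpatialMapSet,
    des_norm: bool,
    mask: BrainMask,
    loader: Callable[[str], Volume4D] = read_volume4d,
) -> DualRegressionResult:
    """Dual regression over a design table, loading each subject's volume."""
    vols = [loader(p) for p in design.frame["bold_path"]]
    return dual_regression_volumes(
        vols, design.subject_ids, template, des_norm, mask
    )


def collect_ic_blocks(
    result: DualRegressionResult, labels: Optional[Sequence[int]] = None
) -> list[tuple[int, np.ndarray]]:
    """Rearrange per-subject betas into per-IC (label, subjects x voxel) blocks,
    the layout the joint permutation inference consumes."""
    if not result.maps:
        return []
    order = result.maps[0].betas.shape[0]
    labels = list(labels) if labels is not None else list(range(order))
    stacked = np.stack([m.betas for m in result.maps])  # (S, C, V)
    return [(int(labels[k]), stacked[:, k, :].copy()) for k in range(order)]
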