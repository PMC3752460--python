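"""Synthetic resting-state cohorts with planted group effects.

The generator emulates the statistical structure a group-ICA /
dual-regression analysis assumes: each subject's BOLD signal is a sum of
fixed spatial network maps weighted by band-limited (< 0.08 Hz by default)
time courses, plus i.i.d. Gaussian noise. Group differences can be planted
as network-amplitude ratios, extra spatial blobs, or focal "atrophy"
spheres that simultaneously reduce gray-matter density and attenuate BOLD
weights — the centrifugal atrophy/connectivity geometry the analysis is
meant to probe.

Everything is deterministic: a cohort is a pure function of (config, seed),
with per-subject seeds derived from the cohort seed via SeedSequence.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .volio import BrainMask, DesignTable, Volume4D, write_design, write_mask, write_volume

__all__ = [
    "TruthAtlas",
    "EffectSpec",
    "CohortConfig",
    "SyntheticCohort",
    "make_network_atlas",
    "make_brain_mask",
    "simulate_subject",
    "simulate_cohort",
    "write_cohort",
]


@dataclasses.dataclass
class TruthAtlas:
    """Ground-truth spatial networks: Gaussian blobs, each with max 1."""

    maps: np.ndarray            # (K, X, Y, Z), non-negative, max 1 per map
    centers: np.ndarray         # (K, 3) voxel coordinates
    widths: np.ndarray          # (K,) isotropic sigma in voxels
    seed: int

    @property
    def n_networks(self) -> int:
        return self.maps.shape[0]

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.maps.shape[1:]


@dataclasses.dataclass
class EffectSpec:
    """A planted patient-vs-control difference on one network.

    amplitude_ratio scales the patient time-course std of the network;
    spatial_shift adds an extra blob (center, sigma, weight) to the patient
    map; atrophy is (center, radius_voxels, gm_reduction, bold_attenuation)
    with center None meaning "at the network's center".
    """

    network_index: int
    amplitude_ratio: float = 1.0
    spatial_shift: Optional[tuple[tuple[float, float, float], float, float]] = None
    atrophy: Optional[
        tuple[Optional[tuple[float, float, float]], float, float, float]
    ] = None

    def __post_init__(self) -> None:
        if self.amplitude_ratio <= 0:
            raise ValueError("amplitude_ratio must be > 0")
        if self.atrophy is not None:
            _, radius, red, att = self.atrophy
            if not (0 <= red <= 1 and 0 <= att <= 1):
                raise ValueError("atrophy fractions must lie in [0, 1]")
            if radius <= 0:
                raise ValueError("atrophy radius must be positive")


@dataclasses.dataclass
class CohortConfig:
    """Study conditions for one simulated cohort.

    Defaults mirror the acquisition being emulated: 19 patients vs 19
    controls, 285 timepoints at TR 1.8 s, network time courses band-limited
    below 0.08 Hz. The desk-scale grid (24x24x16, nominally 4 mm voxels)
    keeps full pipeline runs cheap while preserving 3D geometry.
    """

    grid_shape: tuple[int, int, int] = (24, 24, 16)
    n_patients: int = 19
    n_controls: int = 19
    t_points: int = 285
    tr_seconds: float = 1.8
    lowpass_hz: float = 0.08
    n_networks: int = 8
    width_range: tuple[float, float] = (1.5, 2.5)
    min_center_separation: float = 5.0
    amp_std: float = 1.0
    noise_std: float = 1.0
    brain_frac: float = 0.9      # brain ellipsoid semi-axes as fraction of half-grid
    gm_baseline: float = 0.7
    gm_jitter: float = 0.02
    voxel_size_mm: float = 4.0
    effects: tuple[EffectSpec, ...] = ()

    def validate(self) -> None:
        problems = []
        if self.n_patients < 1 or self.n_controls < 1:
            problems.append("both groups must be non-empty")
        if self.t_points < 2:
            problems.append("t_points must be >= 2")
        if self.tr_seconds <= 0:
            problems.append("tr_seconds must be > 0")
        nyquist = 1.0 / (2.0 * self.tr_seconds) if self.tr_seconds > 0 else np.inf
        if not (0 < self.lowpass_hz < nyquist):
            problems.append(f"lowpass_hz must lie in (0, Nyquist={nyquist:.4g})")
        if self.n_networks < 1:
            problems.append("n_networks must be >= 1")
        if self.noise_std < 0 or self.amp_std < 0:
            problems.append("amp_std and noise_std must be >= 0")
        if not (0 < self.brain_frac <= 1):
            problems.append("brain_frac must lie in (0, 1]")
        for i, e in enumerate(self.effects):
            if not (0 <= e.network_index < self.n_networks):
                problems.append(f"effect {i}: network_index out of range")
        if problems:
            raise ValueError("invalid cohort config: " + "; ".join(problems))


@dataclasses.dataclass
class SyntheticCohort:
    subjects: list[Volume4D]
    design: DesignTable
    gm_maps: list[Volume4D]
    mask: BrainMask
    atlas: TruthAtlas
    effects: tuple[EffectSpec, ...]
    truth_timecourses: np.ndarray   # (subjects, K, T) planted c_k(t)
    config: CohortConfig
    seed: int


# ---------------------------------------------------------------------------


def make_brain_mask(
    grid_shape: Sequence[int], brain_frac: float = 0.9, voxel_size_mm: float = 4.0
) -> BrainMask:
    """Ellipsoidal 'brain' centered in the grid; semi-axes = frac * half-grid."""
    shape = tuple(int(s) for s in grid_shape)
    center = (np.array(shape) - 1) / 2.0
    semi = brain_frac * np.array(shape) / 2.0
    ijk = np.indices(shape, dtype=np.float64)
    r2 = sum(((ijk[a] - center[a]) / semi[a]) ** 2 for a in range(3))
    affine = np.diag([voxel_size_mm] * 3 + [1.0])
    return BrainMask(data=r2 <= 1.0, affine=affine)


def _gaussian_blob(grid_shape, center, sigma) -> np.ndarray:
    ijk = np.indices(grid_shape, dtype=np.float64)
    d2 = sum((ijk[a] - center[a]) ** 2 for a in range(3))
    return np.exp(-d2 / (2.0 * sigma**2))


def make_network_atlas(
    n_networks: int,
    grid_shape: Sequence[int],
    width_range: tuple[float, float] = (1.5, 2.5),
    min_center_separation: float = 5.0,
    seed: int = 0,
    center_semiaxes: Optional[Sequence[float]] = None,
    max_tries: int = 5000,
) -> TruthAtlas:
    """Place ``n_networks`` Gaussian blobs with pairwise-separated centers.

    Centers are rejection-sampled inside an ellipsoid (default: 75% of the
    half-grid, so blobs stay inside a typical brain mask). Each map is
    normalized to max 1.
    """
    if n_networks < 1:
        raise ValueError("n_networks must be >= 1")
    shape = tuple(int(s) for s in grid_shape)
    rng = np.random.default_rng(seed)
    gcenter = (np.array(shape) - 1) / 2.0
    semi = (
        np.asarray(center_semiaxes, dtype=float)
        if center_semiaxes is not None
        else 0.75 * np.array(shape) / 2.0
    )
    centers: list[np.ndarray] = []
    tries = 0
    while len(centers) < n_networks:
        if tries >= max_tries:
            raise RuntimeError(
                f"could not place {n_networks} centers >= {min_center_separation} "
                f"voxels apart in {shape} after {max_tries} tries; "
                "reduce n_networks or min_center_separation"
            )
        tries += 1
        u = rng.uniform(-1.0, 1.0, size=3)
        if (u**2).sum() > 1.0:
            continue
        cand = gcenter + u * semi
        if all(np.linalg.norm(cand - c) >= min_center_separation for c in centers):
            centers.append(cand)
    widths = rng.uniform(width_range[0], width_range[1], size=n_networks)
    maps = np.stack(
        [_gaussian_blob(shape, centers[k], widths[k]) for k in range(n_networks)]
    )
    maps /= maps.reshape(n_networks, -1).max(axis=1)[:, None, None, None]
    return TruthAtlas(
        maps=maps, centers=np.array(centers), widths=widths, seed=int(seed)
    )


def _band_limited_course(rng, t_points, tr_seconds, lowpass_hz, target_std):
    """White noise, hard-masked in frequency below lowpass, exact-std scaled."""
    white = rng.standard_normal(t_points)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(t_points, d=tr_seconds)
    spec[freqs > lowpass_hz] = 0.0
    spec[0] = 0.0  # demeaned course
    c = np.fft.irfft(spec, n=t_points)
    s = c.std()
    if s > 0 and target_std > 0:
        c *= target_std / s
    else:
        c[:] = 0.0
    return c


def _sphere_mask(grid_shape, center, radius) -> np.ndarray:
    ijk = np.indices(grid_shape, dtype=np.float64)
    d2 = sum((ijk[a] - center[a]) ** 2 for a in range(3))
    return d2 <= radius**2


def _effective_maps_and_amps(
    atlas: TruthAtlas,
    effects: Sequence[EffectSpec],
    amp_std: float,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Apply EffectSpec modifications; returns (maps, amp per network, atrophy mask)."""
    maps = atlas.maps.copy()
    amps = np.full(atlas.n_networks, amp_std, dtype=np.float64)
    atrophy_total = np.zeros(atlas.grid_shape, dtype=bool)
    for e in effects or ():
        k = e.network_index
        amps[k] *= e.amplitude_ratio
        if e.spatial_shift is not None:
            center, sigma, weight = e.spatial_shift
            maps[k] = maps[k] + weight * _gaussian_blob(atlas.grid_shape, center, sigma)
        if e.atrophy is not None:
            center, radius, _red, att = e.atrophy
            if center is None:
                center = atlas.centers[k]
            sph = _sphere_mask(atlas.grid_shape, center, radius)
            atrophy_total |= sph
            maps[:, sph] *= 1.0 - att
    return maps, amps, atrophy_total


def effective_network_maps(
    atlas: TruthAtlas,
    amp_std: float,
    noise_std: float,
    effects: Optional[Sequence[EffectSpec]] = None,
) -> np.ndarray:
    """Planted maps as they appear after per-voxel variance normalization.

    Scaling every voxel time series to unit variance reshapes a planted map
    m_k into amp_k * m_k(v) / sigma(v) with
    sigma(v) = sqrt(sum_j amp_j^2 m_j(v)^2 + noise^2); this analytic form is
    the right ground truth to correlate recovered components against.
    """
    maps, amps, _ = _effective_maps_and_amps(atlas, effects or (), amp_std)
    sigma = np.sqrt(
        np.tensordot(amps**2, maps**2, axes=([0], [0])) + noise_std**2
    )
    return amps[:, None, None, None] * maps / sigma


def atrophy_mask(config: CohortConfig, atlas: TruthAtlas) -> np.ndarray:
    """Union of the atrophy spheres planted in the patient group."""
    total = np.zeros(atlas.grid_shape, dtype=bool)
    for e in config.effects:
        if e.atrophy is not None:
            center, radius, _red, _att = e.atrophy
            if center is None:
                center = atlas.centers[e.network_index]
            total |= _sphere_mask(atlas.grid_shape, center, radius)
    return total


def simulate_subject(
    atlas: TruthAtlas,
    effects: Optional[Sequence[EffectSpec]],
    t_points: int,
    tr_seconds: float,
    amp_std: float,
    noise_std: float,
    lowpass_hz: float,
    seed,
    brain: Optional[BrainMask] = None,
    gm_baseline: float = 0.7,
    gm_jitter: float = 0.02,
    voxel_size_mm: float = 4.0,
) -> tuple[Volume4D, Volume4D, np.ndarray]:
    """Simulate one subject: signal = sum_k map_k(v) c_k(t) + noise.

    Returns the BOLD volume, the gray-matter density map (values in [0,1])
    and the planted (K, T) time-course matrix.
    """
    nyq = 1.0 / (2.0 * tr_seconds)
    if not (0 < lowpass_hz < nyq):
        raise ValueError(f"lowpass_hz must lie in (0, Nyquist={nyq:.4g} Hz)")
    rng = np.random.default_rng(seed)
    shape = atlas.grid_shape
    if brain is None:
        brain = make_brain_mask(shape, voxel_size_mm=voxel_size_mm)

    maps, amps, atro = _effective_maps_and_amps(atlas, effects or (), amp_std)

    courses = np.stack(
        [
            _band_limited_course(rng, t_points, tr_seconds, lowpass_hz, amps[k])
            for k in range(atlas.n_networks)
        ]
    )  # (K, T)
    signal = np.tensordot(maps, courses, axes=([0], [0]))  # (X,Y,Z,T)
    signal += noise_std * rng.standard_normal(signal.shape)

    gm = np.where(brain.data, gm_baseline, 0.0)
    for e in effects or ():
        if e.atrophy is not None:
            center, radius, red, _att = e.atrophy
            if center is None:
                center = atlas.centers[e.network_index]
            sph = _sphere_mask(shape, center, radius)
            gm[sph] *= 1.0 - red
    gm = gm + gm_jitter * rng.standard_normal(shape) * brain.data
    gm = np.clip(gm, 0.0, 1.0)

    affine = np.diag([voxel_size_mm] * 3 + [1.0])
    vol = Volume4D(data=signal, affine=affine, tr_seconds=tr_seconds)
    gm_vol = Volume4D(data=gm, affine=affine, tr_seconds=tr_seconds)
    return vol, gm_vol, courses


def simulate_cohort(config: CohortConfig, seed: int) -> SyntheticCohort:
    """Simulate a full two-group cohort; patients get the planted effects."""
    config.validate()
    root = np.random.SeedSequence(seed)
    atlas_ss, subj_ss = root.spawn(2)
    brain = make_brain_mask(
        config.grid_shape, config.brain_frac, config.voxel_size_mm
    )
    semi = config.brain_frac * np.array(config.grid_shape) / 2.0
    atlas = make_network_atlas(
        config.n_networks,
        config.grid_shape,
        config.width_range,
        config.min_center_separation,
        seed=atlas_ss.generate_state(1)[0] % (2**31),
        center_semiaxes=0.8 * semi,
    )
    n_total = config.n_patients + config.n_controls
    child_seeds = subj_ss.spawn(n_total)
    subjects, gm_maps, courses, rows = [], [], [], []
    for i in range(n_total):
        is_patient = i < config.n_patients
        group = "patient" if is_patient else "control"
        vol, gm, c = simulate_subject(
            atlas,
            config.effects if is_patient else None,
            config.t_points,
            config.tr_seconds,
            config.amp_std,
            config.noise_std,
            config.lowpass_hz,
            seed=child_seeds[i],
            brain=brain,
            gm_baseline=config.gm_baseline,
            gm_jitter=config.gm_jitter,
            voxel_size_mm=config.voxel_size_mm,
        )
        subjects.append(vol)
        gm_maps.append(gm)
        courses.append(c)
        rows.append(
            {
                "subject_id": f"{group[:3]}{i:03d}",
                "group": group,
                "bold_path": "",
                "gm_path": "",
            }
        )
    design = DesignTable(frame=pd.DataFrame(rows))
    return SyntheticCohort(
        subjects=subjects,
        design=design,
        gm_maps=gm_maps,
        mask=brain,
        atlas=atlas,
        effects=config.effects,
        truth_timecourses=np.stack(courses),
        config=config,
        seed=int(seed),
    )


def write_cohort(cohort: SyntheticCohort, outdir: str | Path) -> Path:
    """Write a cohort to disk: NIfTI volumes, TSV design, JSON truth sidecar."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_mask(outdir / "mask.nii", cohort.mask)
    rows = []
    for i, sid in enumerate(cohort.design.subject_ids):
        bold = outdir / f"{sid}_bold.nii"
        gm = outdir / f"{sid}_gm.nii"
        write_volume(bold, cohort.subjects[i], dtype=np.float32)
        write_volume(gm, cohort.gm_maps[i], dtype=np.float32)
        rows.append(
            {
                "subject_id": sid,
                "group": cohort.design.frame.loc[i, "group"],
                "bold_path": str(bold),
                "gm_path": str(gm),
            }
        )
    design = DesignTable(frame=pd.DataFrame(rows))
    write_design(outdir / "design.tsv", design)
    atlas_vol = Volume4D(
        data=np.moveaxis(cohort.atlas.maps, 0, -1),
        affine=cohort.mask.affine,
        tr_seconds=1.0,
    )
    write_volume(outdir / "truth_atlas.nii", atlas_vol, dtype=np.float32)
    truth = {
        "seed": cohort.seed,
        "n_networks": cohort.atlas.n_networks,
        "centers": cohort.atlas.centers.tolist(),
        "widths": cohort.atlas.widths.tolist(),
        "effects": [dataclasses.asdict(e) for e in cohort.effects],
        "config": {
            k: (list(v) if isinstance(v, tuple) and k != "effects" else v)
            for k, v in dataclasses.asdict(cohort.config).items()
            if k != "effects"
        },
    }
    (outdir / "truth.json").write_text(json.dumps(truth, indent=2))
    return outdir
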