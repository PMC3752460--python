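"""Group-difference inference: GLM t-maps, TFCE, and max-statistic
permutation FWER correction with inter-component y-concatenation.

The joint ("y-concatenated") test stacks the per-component subject-map
datasets into one block-structured dataset and records, for every
permutation of group labels, the maximum TFCE value across *all* blocks
and voxels. A single null-maximum distribution then corrects each voxel's
p-value simultaneously over space and over components. Blocks are joined
statistically, not geometrically: clusters can never bridge two
components.

A voxel-wise gray-matter covariate is handled per block by Freedman-Lane
residual permutation: fit the reduced (covariate-only) model, permute its
residuals, add back the reduced fit, and re-test the group term in the
full model.
"""

from __future__ import annotations

import dataclasses
import itertools
import math
import warnings
from typing import Optional, Sequence, Union

import numpy as np
from numba import njit
from scipy import ndimage

from .volio import BrainMask, DesignTable, Volume4D, unmask

__all__ = [
    "TfceParams",
    "ConcatDataset",
    "PermutationResult",
    "BlockResult",
    "two_sample_tmap",
    "tfce",
    "yconcat",
    "permutation_test",
    "per_map_test",
    "split_blocks",
    "smooth_volume",
]

DIRECTIONS = ("patient>control", "control>patient")


@dataclasses.dataclass
class TfceParams:
    """Threshold-free cluster enhancement parameters.

    Standard values: height exponent H=2, extent exponent E=0.5, 100
    integration steps (dh = max/n_steps, midpoint rule) and 26-connectivity.
    """

    height_exponent: float = 2.0
    extent_exponent: float = 0.5
    n_steps: int = 100
    connectivity: int = 26

    def __post_init__(self) -> None:
        if self.height_exponent < 0 or self.extent_exponent < 0:
            raise ValueError("exponents must be >= 0")
        if self.n_steps < 10:
            raise ValueError("n_steps must be >= 10")
        if self.connectivity not in (6, 18, 26):
            raise ValueError("connectivity must be 6, 18 or 26")


@dataclasses.dataclass
class ConcatDataset:
    """Block-structured stack of per-IC subject maps, the unit of joint
    permutation inference. ``blocks`` is a list of (ic_label, S x V betas);
    all blocks share the subject axis; covariate blocks, when present,
    align block-for-block."""

    blocks: list[tuple[int, np.ndarray]]
    design: DesignTable
    mask: BrainMask
    covariate_blocks: Optional[list[np.ndarray]] = None

    def __post_init__(self) -> None:
        if not self.blocks:
            raise ValueError("no blocks")
        n_subj = len(self.design)
        for lab, b in self.blocks:
            if b.shape != (n_subj, self.mask.n_voxels):
                raise ValueError(
                    f"block {lab}: shape {b.shape} != "
                    f"({n_subj}, {self.mask.n_voxels})"
                )
        if self.covariate_blocks is not None:
            if len(self.covariate_blocks) != len(self.blocks):
                raise ValueError("covariate blocks do not align with data blocks")
            for (lab, b), c in zip(self.blocks, self.covariate_blocks):
                if c.shape != b.shape:
                    raise ValueError(f"covariate block {lab}: shape mismatch")

    @property
    def n_blocks(self) -> int:
        return len(self.blocks)

    @property
    def labels(self) -> list[int]:
        return [lab for lab, _ in self.blocks]

    @property
    def block_index(self) -> np.ndarray:
        """(sum V, 2) array mapping concatenated row -> (ic_label, local voxel)."""
        parts = [
            np.column_stack([np.full(b.shape[1], lab), np.arange(b.shape[1])])
            for lab, b in self.blocks
        ]
        return np.concatenate(parts, axis=0)


@dataclasses.dataclass
class PermutationResult:
    labels: list[int]
    tmaps: list[np.ndarray]        # per block, (V,)
    tfce_maps: list[np.ndarray]    # per block, (V,)
    pmaps: list[np.ndarray]        # per block, corrected p in (0, 1]
    null_max: np.ndarray           # (n_draws,) shared across blocks
    null_max_blocks: np.ndarray    # (n_draws, n_blocks) per-block maxima
    n_perm: int
    exhaustive: bool
    seed: Optional[int]
    direction: str
    mask: BrainMask
    tfce_params: TfceParams


@dataclasses.dataclass
class BlockResult:
    """One component's result restored to the 3D grid."""

    ic_label: int
    t_vol: np.ndarray
    tfce_vol: np.ndarray
    p_vol: np.ndarray       # corrected p; out-of-mask voxels carry 1
    sig_mask: np.ndarray    # p < alpha, strict
    alpha: float


# ---------------------------------------------------------------------------
# TFCE


def _conn_deltas(connectivity: int) -> np.ndarray:
    deltas = []
    for di in (-1, 0, 1):
        for dj in (-1, 0, 1):
            for dk in (-1, 0, 1):
                if di == dj == dk == 0:
                    continue
                order = abs(di) + abs(dj) + abs(dk)
                if connectivity == 6 and order > 1:
                    continue
                if connectivity == 18 and order > 2:
                    continue
                deltas.append((di, dj, dk))
    return np.array(deltas, dtype=np.int64)


@njit(cache=True)
def _uf_find(parent, v):
    root = v
    while parent[root] != root:
        root = parent[root]
    while parent[v] != root:
        nxt = parent[v]
        parent[v] = root
        v = nxt
    return root


@njit(cache=True)
def _tfce_kernel(vals, nx, ny, nz, deltas, n_steps, h_exp, e_exp, out):
    """Accumulate sum_h extent(h)^E * h^H * dh per voxel (midpoint rule).

    Thresholds are processed in descending order; supra-threshold voxels
    join an incremental union-find so each voxel's connected-component size
    at every threshold is available in near-linear total time.
    """
    n = vals.size
    max_v = 0.0
    for i in range(n):
        if vals[i] > max_v:
            max_v = vals[i]
    if max_v <= 0.0:
        return
    dh = max_v / n_steps
    order = np.argsort(vals)[::-1]
    parent = np.full(n, -1, dtype=np.int64)
    size = np.zeros(n, dtype=np.int64)
    active = np.empty(n, dtype=np.int64)
    n_active = 0
    ptr = 0
    for step in range(n_steps, 0, -1):
        h = (step - 0.5) * dh
        while ptr < n and vals[order[ptr]] >= h:
            v = order[ptr]
            ptr += 1
            parent[v] = v
            size[v] = 1
            active[n_active] = v
            n_active += 1
            i = v // (ny * nz)
            rem = v - i * ny * nz
            j = rem // nz
            k = rem - j * nz
            for d in range(deltas.shape[0]):
                ii = i + deltas[d, 0]
                jj = j + deltas[d, 1]
                kk = k + deltas[d, 2]
                if 0 <= ii < nx and 0 <= jj < ny and 0 <= kk < nz:
                    w = (ii * ny + jj) * nz + kk
                    if parent[w] >= 0:
                        rv = _uf_find(parent, v)
                        rw = _uf_find(parent, w)
                        if rv != rw:
                            if size[rv] < size[rw]:
                                rv, rw = rw, rv
                            parent[rw] = rv
                            size[rv] += size[rw]
        hfac = h**h_exp * dh
        for a in range(n_active):
            v = active[a]
            r = _uf_find(parent, v)
            out[v] += size[r] ** e_exp * hfac


def tfce(statmap: np.ndarray, params: Optional[TfceParams] = None) -> np.ndarray:
    """Enhance the positive part of a 3D statistic map.

    Only positive values are enhanced (one-sided); to enhance deficits,
    negate the map first. The integral runs over ``n_steps`` midpoint
    thresholds up to the map maximum.
    """
    params = params or TfceParams()
    arr = np.asarray(statmap, dtype=np.float64)
    if arr.ndim != 3:
        raise ValueError("statmap must be 3D")
    if not np.isfinite(arr).all():
        raise ValueError("statmap contains non-finite values")
    out = np.zeros_like(arr)
    pos = arr > 0
    if not pos.any():
        return out
    idx = np.argwhere(pos)
    lo = idx.min(axis=0)
    hi = idx.max(axis=0) + 1
    crop = np.where(
        pos[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]],
        arr[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]],
        0.0,
    )
    nx, ny, nz = crop.shape
    res = np.zeros(crop.size, dtype=np.float64)
    _tfce_kernel(
        crop.ravel(),
        nx,
        ny,
        nz,
        _conn_deltas(params.connectivity),
        params.n_steps,
        params.height_exponent,
        params.extent_exponent,
        res,
    )
    out[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]] = res.reshape(crop.shape)
    return out


class _MaskGeometry:
    """Precomputed crop-box embedding of a mask, reused across TFCE calls."""

    def __init__(self, mask: BrainMask, params: TfceParams):
        pos = np.argwhere(mask.data)
        self.lo = pos.min(axis=0)
        hi = pos.max(axis=0) + 1
        crop = mask.data[self.lo[0] : hi[0], self.lo[1] : hi[1], self.lo[2] : hi[2]]
        self.crop_shape = crop.shape
        self.idx = np.flatnonzero(crop.ravel())
        self.deltas = _conn_deltas(params.connectivity)
        self.params = params
        self._buf = np.zeros(crop.size, dtype=np.float64)
        self._out = np.zeros(crop.size, dtype=np.float64)

    def enhance(self, tvals: np.ndarray) -> np.ndarray:
        """TFCE of a masked stat vector; returns the masked enhanced vector."""
        nx, ny, nz = self.crop_shape
        self._buf[self.idx] = np.maximum(tvals, 0.0)
        self._out[:] = 0.0
        _tfce_kernel(
            self._buf,
            nx,
            ny,
            nz,
            self.deltas,
            self.params.n_steps,
            self.params.height_exponent,
            self.params.extent_exponent,
            self._out,
        )
        res = self._out[self.idx].copy()
        self._buf[self.idx] = 0.0
        return res


# ---------------------------------------------------------------------------
# t statistics


def _group_t(y: np.ndarray, is_patient: np.ndarray) -> np.ndarray:
    """Pooled-variance two-sample t (patient minus control), vectorized."""
    g1 = y[is_patient]
    g2 = y[~is_patient]
    n1, n2 = g1.shape[0], g2.shape[0]
    m1 = g1.mean(axis=0)
    m2 = g2.mean(axis=0)
    ss = ((g1 - m1) ** 2).sum(axis=0) + ((g2 - m2) ** 2).sum(axis=0)
    sp2 = ss / (n1 + n2 - 2)
    se = np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, (m1 - m2) / se, 0.0)
    return t


class _CovariateGLM:
    """Per-voxel GLM y ~ 1 + group + covariate with precomputed inverses.

    The design depends on the voxel (through the covariate) but not on the
    permuted response, so the normal-equation inverses are computed once.
    """

    def __init__(self, is_patient: np.ndarray, cov: np.ndarray):
        n, v = cov.shape
        self.n = n
        x = np.empty((n, v, 3))
        x[:, :, 0] = 1.0
        x[:, :, 1] = is_patient[:, None].astype(np.float64)
        x[:, :, 2] = cov
        self.x = x
        xtx = np.einsum("nvp,nvq->vpq", x, x)
        self.m = np.linalg.pinv(xtx)  # (V, 3, 3)
        self.dof = n - 3
        if self.dof < 1:
            raise ValueError("need at least 4 subjects for the covariate GLM")

    def t_group(self, y: np.ndarray) -> np.ndarray:
        xty = np.einsum("nvp,nv->vp", self.x, y)
        beta = np.einsum("vpq,vq->vp", self.m, xty)
        rss = (y**2).sum(axis=0) - (beta * xty).sum(axis=1)
        rss = np.maximum(rss, 0.0)
        var_b = rss / self.dof * self.m[:, 1, 1]
        with np.errstate(divide="ignore", invalid="ignore"):
            t = np.where(var_b > 1e-300, beta[:, 1] / np.sqrt(var_b), 0.0)
        return t


def two_sample_tmap(
    block: np.ndarray,
    design: DesignTable,
    covariate: Optional[np.ndarray] = None,
    direction: str = "patient>control",
) -> np.ndarray:
    """Voxel-wise group-difference t statistic for one subjects x voxel block.

    Without a covariate this is the pooled-variance two-sample t; with a
    voxel-wise covariate it is the t of the group coefficient in the
    per-voxel regression on [intercept, group, covariate]. Voxels with zero
    residual variance get t = 0.
    """
    if direction not in DIRECTIONS:
        raise ValueError(f"direction must be one of {DIRECTIONS}")
    g = design.is_patient
    if g.sum() < 2 or (~g).sum() < 2:
        raise ValueError("need >= 2 subjects per group")
    y = np.asarray(block, dtype=np.float64)
    if covariate is None:
        t = _group_t(y, g)
    else:
        t = _CovariateGLM(g, np.asarray(covariate, dtype=np.float64)).t_group(y)
    return t if direction == "patient>control" else -t


# ---------------------------------------------------------------------------
# y-concatenation and the permutation engine


def yconcat(
    per_ic_maps: Sequence[tuple[int, np.ndarray]],
    design: DesignTable,
    mask: BrainMask,
    gm_covariate: Optional[Union[np.ndarray, Sequence[np.ndarray]]] = None,
) -> ConcatDataset:
    """Stack per-IC subject-map blocks into one joint dataset.

    ``gm_covariate`` may be a single subjects x voxel matrix (replicated to
    every block, mirroring a gray-matter regressor image concatenated the
    same way as the data) or one matrix per block.
    """
    blocks = [(int(lab), np.asarray(b, dtype=np.float64)) for lab, b in per_ic_maps]
    cov_blocks = None
    if gm_covariate is not None:
        if isinstance(gm_covariate, np.ndarray):
            cov_blocks = [np.asarray(gm_covariate, dtype=np.float64)] * len(blocks)
        else:
            cov_blocks = [np.asarray(c, dtype=np.float64) for c in gm_covariate]
    return ConcatDataset(
        blocks=blocks, design=design, mask=mask, covariate_blocks=cov_blocks
    )


def split_blocks(
    result: PermutationResult, alpha: float = 0.05
) -> list[BlockResult]:
    """Restore per-IC t/TFCE/p volumes to the 3D grid and threshold.

    Significance is strict: a voxel whose corrected p exactly equals
    ``alpha`` is excluded.
    """
    out = []
    for lab, t, tf, p in zip(
        result.labels, result.tmaps, result.tfce_maps, result.pmaps
    ):
        p_vol = unmask(p, result.mask, fill=1.0)
        out.append(
            BlockResult(
                ic_label=lab,
                t_vol=unmask(t, result.mask),
                tfce_vol=unmask(tf, result.mask),
                p_vol=p_vol,
                sig_mask=(p_vol < alpha) & result.mask.data,
                alpha=alpha,
            )
        )
    return out


def _arrangements(g: np.ndarray, n_perm: int, seed, exhaustive_ok: bool):
    """Group-label vectors for the null: exhaustive when feasible, else
    seeded Monte-Carlo permutations of the observed labels."""
    n = g.size
    n1 = int(g.sum())
    total = math.comb(n, n1)
    if exhaustive_ok and total <= n_perm:
        labels = np.zeros((total, n), dtype=bool)
        for i, subset in enumerate(itertools.combinations(range(n), n1)):
            labels[i, list(subset)] = True
        return labels, True
    rng = np.random.default_rng(seed)
    labels = np.empty((n_perm, n), dtype=bool)
    for i in range(n_perm):
        labels[i] = g[rng.permutation(n)]
    return labels, False


def permutation_test(
    data: ConcatDataset,
    n_perm: int = 5000,
    seed: int = 0,
    tfce_params: Optional[TfceParams] = None,
    direction: str = "patient>control",
    allow_exhaustive: bool = True,
) -> PermutationResult:
    """Joint max-statistic permutation test over all blocks of a dataset.

    Per permutation, group labels are re-assigned (Freedman-Lane residual
    permutation when a covariate is present) and the maximum TFCE value
    across every block and voxel is recorded. Corrected
    p(v) = (1 + #{null_max >= tfce(v)}) / (1 + n_perm), so p is never 0.
    When the number of distinct label arrangements is <= n_perm (and no
    covariate is in play) the null is enumerated exhaustively instead.
    """
    if direction not in DIRECTIONS:
        raise ValueError(f"direction must be one of {DIRECTIONS}")
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    if n_perm < 1000:
        warnings.warn(
            f"n_perm={n_perm} < 1000: corrected p-values will be coarse",
            RuntimeWarning,
            stacklevel=2,
        )
    params = tfce_params or TfceParams()
    g = data.design.is_patient
    if g.sum() < 2 or (~g).sum() < 2:
        raise ValueError("need >= 2 subjects per group")
    sign = 1.0 if direction == "patient>control" else -1.0
    geom = _MaskGeometry(data.mask, params)
    has_cov = data.covariate_blocks is not None

    # observed statistics
    glms = []
    tmaps = []
    for bi, (lab, y) in enumerate(data.blocks):
        if has_cov:
            glm = _CovariateGLM(g, data.covariate_blocks[bi])
            glms.append(glm)
            tmaps.append(sign * glm.t_group(y))
        else:
            tmaps.append(sign * _group_t(y, g))
    tfce_maps = [geom.enhance(t) for t in tmaps]

    if has_cov:
        # Freedman-Lane: reduced model (intercept + covariate) fits/residuals
        reduced = []
        for bi, (lab, y) in enumerate(data.blocks):
            c = data.covariate_blocks[bi]
            z = np.stack(
                [np.ones_like(c), c], axis=2
            )  # (n, V, 2)
            ztz = np.einsum("nvp,nvq->vpq", z, z)
            mz = np.linalg.pinv(ztz)
            zty = np.einsum("nvp,nv->vp", z, y)
            gamma = np.einsum("vpq,vq->vp", mz, zty)
            fit = np.einsum("nvp,vp->nv", z, gamma)
            reduced.append((fit, y - fit))
        rng = np.random.default_rng(seed)
        n_draws = n_perm
        exhaustive = False
        null_blocks = np.empty((n_draws, data.n_blocks))
        n_subj = len(data.design)
        for j in range(n_draws):
            perm = rng.permutation(n_subj)
            for bi in range(data.n_blocks):
                fit, resid = reduced[bi]
                ystar = fit + resid[perm]
                t = sign * glms[bi].t_group(ystar)
                null_blocks[j, bi] = geom.enhance(t).max()
    else:
        labels, exhaustive = _arrangements(g, n_perm, seed, exhaustive_ok=allow_exhaustive)
        n_draws = labels.shape[0]
        null_blocks = np.empty((n_draws, data.n_blocks))
        for j in range(n_draws):
            gj = labels[j]
            for bi, (lab, y) in enumerate(data.blocks):
                t = sign * _group_t(y, gj)
                null_blocks[j, bi] = geom.enhance(t).max()

    null_max = null_blocks.max(axis=1)
    pmaps = []
    for tf in tfce_maps:
        counts = (null_max[:, None] >= tf[None, :]).sum(axis=0)
        if exhaustive:
            p = counts / n_draws
        else:
            p = (1.0 + counts) / (1.0 + n_draws)
        pmaps.append(p)

    return PermutationResult(
        labels=data.labels,
        tmaps=tmaps,
        tfce_maps=tfce_maps,
        pmaps=pmaps,
        null_max=null_max,
        null_max_blocks=null_blocks,
        n_perm=n_draws,
        exhaustive=exhaustive,
        seed=int(seed),
        direction=direction,
        mask=data.mask,
        tfce_params=params,
    )


def per_map_test(
    block: tuple[int, np.ndarray],
    design: DesignTable,
    mask: BrainMask,
    covariate: Optional[np.ndarray] = None,
    n_perm: int = 5000,
    seed: int = 0,
    tfce_params: Optional[TfceParams] = None,
    direction: str = "patient>control",
) -> PermutationResult:
    """Voxel-level-only correction: the same engine on a single block."""
    data = ConcatDataset(
        blocks=[(int(block[0]), np.asarray(block[1], dtype=np.float64))],
        design=design,
        mask=mask,
        covariate_blocks=[np.asarray(covariate, dtype=np.float64)]
        if covariate is not None
        else None,
    )
    return permutation_test(
        data, n_perm=n_perm, seed=seed, tfce_params=tfce_params, direction=direction
    )


# ---------------------------------------------------------------------------


def smooth_volume(vol: Volume4D, sigma_mm: float) -> Volume4D:
    """Gaussian-smooth each frame spatially (sigma in mm; FWHM = 2.355 sigma).

    Intended for gray-matter covariate maps, which the analysis expects
    smoothed the same way the structural pipeline smooths them.
    """
    voxel_mm = np.abs(np.diag(vol.affine)[:3])
    sigma_vox = sigma_mm / voxel_mm
    out = np.empty_like(vol.data)
    for t in range(vol.n_timepoints):
        out[..., t] = ndimage.gaussian_filter(vol.data[..., t], sigma=sigma_vox)
    return Volume4D(data=out, affine=vol.affine, tr_seconds=vol.tr_seconds)
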