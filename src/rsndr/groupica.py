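"""Temporal-concatenation group spatial ICA with mixture-model thresholding.

The group decomposition follows the standard multi-subject recipe: each
subject's time x voxel matrix is variance-normalized per voxel, subjects
are stacked along time, the stack is reduced to the requested model order
and unmixed with fixed-point ICA (tanh contrast, symmetric decorrelation).
Components are returned as z-scored spatial maps with a positive-skew sign
convention.

Map thresholding fits a three-class mixture to the z-value histogram —
a Gaussian "null" plus an offset gamma for the positive (activation) tail
and a mirrored gamma for the negative tail — and keeps voxels whose local
false-discovery rate (posterior null probability) falls below a cut,
0.5 by default.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Optional, Sequence

import numpy as np
from scipy import special, stats
from sklearn.decomposition import FastICA
from sklearn.exceptions import ConvergenceWarning

from .synthetic_data import TruthAtlas
from .volio import BrainMask, Volume4D, mask_to_matrix

__all__ = [
    "SpatialMapSet",
    "MixtureFit",
    "ICAConvergenceError",
    "variance_normalize",
    "run_group_ica",
    "template_from_atlas",
    "fit_mixture_threshold",
    "select_components",
    "match_components_to_truth",
]


class ICAConvergenceError(RuntimeError):
    """Fixed-point ICA failed to converge within the iteration budget."""


@dataclasses.dataclass
class SpatialMapSet:
    """Group-level component maps over a mask, z-scored per component."""

    zmaps: np.ndarray                 # (C, V) z-score units over the mask
    mask: BrainMask
    group_timecourses: Optional[np.ndarray] = None  # (sum T, C) mixing courses
    source_group: str = "control"
    seed: Optional[int] = None
    labels: Optional[list[int]] = None  # original component indices

    def __post_init__(self) -> None:
        self.zmaps = np.asarray(self.zmaps, dtype=np.float64)
        if self.zmaps.ndim != 2:
            raise ValueError("zmaps must be (components, voxels)")
        if self.zmaps.shape[1] != self.mask.n_voxels:
            raise ValueError("zmaps voxel axis does not match mask")
        if self.labels is None:
            self.labels = list(range(self.zmaps.shape[0]))

    @property
    def order(self) -> int:
        return self.zmaps.shape[0]


@dataclasses.dataclass
class MixtureFit:
    """Gaussian null + positive/negative offset-gamma mixture over z values."""

    weight_null: float
    weight_pos: float
    weight_neg: float
    null_mean: float
    null_std: float
    pos_shape: float
    pos_scale: float
    pos_offset: float
    neg_shape: float
    neg_scale: float
    neg_offset: float
    converged: bool
    loglik_trace: np.ndarray

    def local_fdr(self, z: np.ndarray) -> np.ndarray:
        """Posterior null probability at each z value."""
        f0, fp, fn = _mixture_densities(z, self)
        total = self.weight_null * f0 + self.weight_pos * fp + self.weight_neg * fn
        total = np.maximum(total, 1e-300)
        return self.weight_null * f0 / total


# ---------------------------------------------------------------------------


def variance_normalize(matrix: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Demean and scale each voxel column to unit variance.

    Returns (normalized matrix, zero-variance flags). Columns with (near-)
    zero variance are set to all-zero and flagged rather than divided.
    """
    matrix = np.asarray(matrix, dtype=np.float64)
    if matrix.ndim != 2 or matrix.shape[0] < 2:
        raise ValueError("matrix must be (time >= 2, voxels)")
    out = matrix - matrix.mean(axis=0)
    sd = out.std(axis=0, ddof=1)
    zero = sd <= 1e-12 * max(1.0, float(np.abs(matrix).max()))
    sd_safe = np.where(zero, 1.0, sd)
    out /= sd_safe
    out[:, zero] = 0.0
    return out, zero


def run_group_ica(
    subjects: Sequence[Volume4D],
    mask: BrainMask,
    order: int,
    seed: int,
    max_iter: int = 1000,
    tol: float = 1e-6,
    source_group: str = "control",
    strict: bool = True,
) -> SpatialMapSet:
    """Temporal-concatenation group spatial ICA at a user-set model order.

    Per-subject variance normalization, stacking along time, SVD reduction
    to ``order`` and fixed-point ICA (tanh contrast, symmetric
    decorrelation) on the voxel x time matrix, so the estimated sources are
    spatial maps and the mixing matrix holds the concatenated group time
    courses. Maps are z-scored over the mask and sign-flipped to positive
    spatial skewness.

    With ``strict`` (default) non-convergence raises ICAConvergenceError;
    otherwise the best iterate is returned with a warning.
    """
    stacked, _ = mask_to_matrix(subjects, mask)
    n_subj, t_len, n_vox = stacked.shape
    total_t = n_subj * t_len
    if not (1 <= order <= min(total_t, n_vox)):
        raise ValueError(
            f"order {order} must lie in [1, min(total T={total_t}, V={n_vox})]"
        )
    concat = np.empty((total_t, n_vox))
    for i in range(n_subj):
        concat[i * t_len : (i + 1) * t_len], _ = variance_normalize(stacked[i])

    ica = FastICA(
        n_components=order,
        algorithm="parallel",
        fun="logcosh",
        whiten="unit-variance",
        max_iter=max_iter,
        tol=tol,
        random_state=int(seed),
    )
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always", ConvergenceWarning)
        sources = ica.fit_transform(concat.T)  # (V, C)
        not_converged = any(
            issubclass(w.category, ConvergenceWarning) for w in caught
        )
    if not_converged:
        msg = f"ICA did not converge within {max_iter} iterations (n_iter={ica.n_iter_})"
        if strict:
            raise ICAConvergenceError(msg)
        warnings.warn(msg, RuntimeWarning, stacklevel=2)

    zmaps = sources.T  # (C, V)
    zmaps = zmaps - zmaps.mean(axis=1, keepdims=True)
    zmaps /= zmaps.std(axis=1, keepdims=True)
    mixing = ica.mixing_  # (sum T, C)
    flip = np.where(stats.skew(zmaps, axis=1) < 0, -1.0, 1.0)
    zmaps *= flip[:, None]
    mixing = mixing * flip[None, :]
    return SpatialMapSet(
        zmaps=zmaps,
        mask=mask,
        group_timecourses=mixing,
        source_group=source_group,
        seed=int(seed),
    )


def template_from_atlas(atlas: TruthAtlas, mask: BrainMask) -> SpatialMapSet:
    """z-scored SpatialMapSet built directly from ground-truth network maps.

    Useful when the analysis should be run against known spatial truth
    (validation studies) instead of an estimated decomposition.
    """
    flat = atlas.maps.reshape(atlas.n_networks, -1)[:, mask.indices]
    z = flat - flat.mean(axis=1, keepdims=True)
    sd = z.std(axis=1, keepdims=True)
    z = z / np.where(sd > 0, sd, 1.0)
    return SpatialMapSet(zmaps=z, mask=mask, source_group="truth", seed=atlas.seed)


# ---------------------------------------------------------------------------
# Gaussian/gamma mixture thresholding


def _mixture_densities(z: np.ndarray, fit: "MixtureFit"):
    f0 = stats.norm.pdf(z, fit.null_mean, fit.null_std)
    fp = np.zeros_like(z)
    up = z > fit.pos_offset
    if fit.weight_pos > 0 and np.any(up):
        fp[up] = stats.gamma.pdf(z[up] - fit.pos_offset, fit.pos_shape, scale=fit.pos_scale)
    fn = np.zeros_like(z)
    dn = z < fit.neg_offset
    if fit.weight_neg > 0 and np.any(dn):
        fn[dn] = stats.gamma.pdf(fit.neg_offset - z[dn], fit.neg_shape, scale=fit.neg_scale)
    return f0, fp, fn


def _weighted_gamma_mle(y: np.ndarray, w: np.ndarray, shape0: float) -> tuple[float, float]:
    """Weighted gamma MLE via Newton on the shape; y > 0, weights >= 0."""
    wsum = w.sum()
    if wsum <= 1e-12:
        return shape0, 1.0
    m = float((w * y).sum() / wsum)
    ml = float((w * np.log(y)).sum() / wsum)
    s = np.log(max(m, 1e-300)) - ml
    if s <= 0:  # numerically degenerate (all y equal)
        return shape0, m / max(shape0, 1e-12)
    a = max(shape0, 1e-3)
    for _ in range(50):
        g = np.log(a) - special.digamma(a) - s
        h = 1.0 / a - special.polygamma(1, a)
        step = g / h
        a_new = a - step
        if a_new <= 0:
            a_new = a / 2.0
        if abs(a_new - a) < 1e-10 * a:
            a = a_new
            break
        a = a_new
    a = float(np.clip(a, 1e-3, 1e4))
    return a, m / a


def fit_mixture_threshold(
    zmap: np.ndarray,
    local_fdr_cut: float = 0.5,
    max_iter: int = 500,
    tol: float = 1e-8,
    min_voxels: int = 1000,
) -> tuple[MixtureFit, np.ndarray]:
    """Fit the null-Gaussian / tail-gamma mixture and threshold by local FDR.

    The EM keeps the gamma offsets fixed at the initial null-center estimate
    (exact M-steps then guarantee a monotone log-likelihood). A tail weight
    collapsing toward zero is legitimate (no activation of that sign) and is
    reported, not raised. Voxels pass when their posterior null probability
    is below ``local_fdr_cut``.
    """
    z = np.asarray(zmap, dtype=np.float64).ravel()
    if z.size < min_voxels:
        raise ValueError(f"need >= {min_voxels} voxels for a stable fit, got {z.size}")

    med = float(np.median(z))
    q75, q25 = np.percentile(z, [75, 25])
    sig = max(float((q75 - q25) / 1.349), 1e-3)
    off_pos = med
    off_neg = med
    hi = z > med + 2.0 * sig
    lo = z < med - 2.0 * sig
    w_pos = max(float(hi.mean()) * 0.5, 1e-3)
    w_neg = max(float(lo.mean()) * 0.5, 1e-3)
    w0 = 1.0 - w_pos - w_neg
    shape_p, scale_p = 3.0, max((float(z[hi].mean()) - off_pos) / 3.0, 0.1) if hi.any() else (3.0, 1.0)
    if not hi.any():
        shape_p, scale_p = 3.0, 1.0
    shape_n, scale_n = 3.0, max((off_neg - float(z[lo].mean())) / 3.0, 0.1) if lo.any() else (3.0, 1.0)
    if not lo.any():
        shape_n, scale_n = 3.0, 1.0

    fit = MixtureFit(
        weight_null=w0, weight_pos=w_pos, weight_neg=w_neg,
        null_mean=med, null_std=sig,
        pos_shape=shape_p, pos_scale=scale_p, pos_offset=off_pos,
        neg_shape=shape_n, neg_scale=scale_n, neg_offset=off_neg,
        converged=False, loglik_trace=np.empty(0),
    )

    trace = []
    prev_ll = -np.inf
    converged = False
    for _ in range(max_iter):
        f0, fp, fn = _mixture_densities(z, fit)
        num0 = fit.weight_null * f0
        nump = fit.weight_pos * fp
        numn = fit.weight_neg * fn
        total = np.maximum(num0 + nump + numn, 1e-300)
        ll = float(np.log(total).sum())
        trace.append(ll)
        r0 = num0 / total
        rp = nump / total
        rn = numn / total
        # M-step
        n = z.size
        w0 = float(r0.sum()) / n
        wp = float(rp.sum()) / n
        wn = float(rn.sum()) / n
        mu = float((r0 * z).sum() / max(r0.sum(), 1e-12))
        var = float((r0 * (z - mu) ** 2).sum() / max(r0.sum(), 1e-12))
        fit.null_mean, fit.null_std = mu, max(np.sqrt(var), 1e-4)
        fit.weight_null, fit.weight_pos, fit.weight_neg = w0, wp, wn
        if wp > 1e-8:
            up = z > fit.pos_offset
            fit.pos_shape, fit.pos_scale = _weighted_gamma_mle(
                z[up] - fit.pos_offset, rp[up], fit.pos_shape
            )
        else:
            fit.weight_pos = 0.0
            fit.weight_null = 1.0 - fit.weight_pos - fit.weight_neg
        if wn > 1e-8:
            dn = z < fit.neg_offset
            fit.neg_shape, fit.neg_scale = _weighted_gamma_mle(
                fit.neg_offset - z[dn], rn[dn], fit.neg_shape
            )
        else:
            fit.weight_neg = 0.0
            fit.weight_null = 1.0 - fit.weight_pos - fit.weight_neg
        if np.isfinite(prev_ll) and abs(ll - prev_ll) <= tol * (abs(prev_ll) + 1.0):
            converged = True
            prev_ll = ll
            break
        prev_ll = ll

    fit.converged = converged
    fit.loglik_trace = np.array(trace)
    lfdr = fit.local_fdr(z)
    passed = (lfdr < local_fdr_cut).reshape(np.shape(zmap))
    return fit, passed


# ---------------------------------------------------------------------------
# Component selection


def match_components_to_truth(
    maps: SpatialMapSet, truth: TruthAtlas
) -> tuple[np.ndarray, np.ndarray]:
    """Best one-to-one assignment of components to truth networks.

    Returns (component index per network, |spatial correlation| per network)
    from a Hungarian assignment on the absolute correlation matrix.
    """
    from scipy.optimize import linear_sum_assignment

    flat_truth = truth.maps.reshape(truth.n_networks, -1)[:, maps.mask.indices]
    c = np.corrcoef(np.vstack([flat_truth, maps.zmaps]))
    corr = np.abs(c[: truth.n_networks, truth.n_networks :])  # (K, C)
    rows, cols = linear_sum_assignment(-corr)
    assigned = np.empty(truth.n_networks, dtype=int)
    score = np.empty(truth.n_networks)
    assigned[rows] = cols
    score[rows] = corr[rows, cols]
    return assigned, score


def select_components(
    maps: SpatialMapSet,
    keep: Optional[Sequence[int]] = None,
    truth: Optional[TruthAtlas] = None,
    min_corr: float = 0.5,
) -> SpatialMapSet:
    """Subset a map set by explicit indices or by matching against truth.

    With ``truth``, a component is kept when it is some network's best
    (assigned) match with |correlation| >= min_corr. Original component
    indices are preserved as labels.
    """
    if (keep is None) == (truth is None):
        raise ValueError("give exactly one of keep= or truth=")
    if keep is not None:
        idx = sorted(int(i) for i in keep)
        if any(i < 0 or i >= maps.order for i in idx):
            raise IndexError(f"component index out of range 0..{maps.order - 1}")
    else:
        assigned, score = match_components_to_truth(maps, truth)
        idx = sorted(int(c) for c, s in zip(assigned, score) if s >= min_corr)
    return SpatialMapSet(
        zmaps=maps.zmaps[idx],
        mask=maps.mask,
        group_timecourses=(
            maps.group_timecourses[:, idx] if maps.group_timecourses is not None else None
        ),
        source_group=maps.source_group,
        seed=maps.seed,
        labels=[maps.labels[i] for i in idx],
    )
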