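import inspect

import numpy as np
import pandas as pd
import pytest
from scipy import ndimage

from rsndr.inference import (
    ConcatDataset,
    PermutationResult,
    TfceParams,
    per_map_test,
    permutation_test,
    smooth_volume,
    split_blocks,
    tfce,
    two_sample_tmap,
    yconcat,
)
from rsndr.volio import BrainMask, DesignTable, Volume4D


def brute_force_tfce(arr, h_exp=2.0, e_exp=0.5, n_steps=1000, connectivity=26):
    """Independent fine-step TFCE: explicit per-threshold labelling."""
    arr = np.maximum(np.asarray(arr, dtype=float), 0.0)
    out = np.zeros_like(arr)
    mx = arr.max()
    if mx <= 0:
        return out
    dh = mx / n_steps
    struct = ndimage.generate_binary_structure(3, {6: 1, 18: 2, 26: 3}[connectivity])
    for i in range(1, n_steps + 1):
        h = (i - 0.5) * dh
        supra = arr >= h
        labels, n = ndimage.label(supra, structure=struct)
        if n == 0:
            continue
        sizes = np.bincount(labels.ravel())
        out[supra] += sizes[labels[supra]] ** e_exp * h**h_exp * dh
    return out


def _design(n_pat, n_con):
    return DesignTable(
        frame=pd.DataFrame(
            {
                "subject_id": [f"s{i}" for i in range(n_pat + n_con)],
                "group": ["patient"] * n_pat + ["control"] * n_con,
                "bold_path": [""] * (n_pat + n_con),
            }
        )
    )


def _ball_mask(shape=(10, 10, 8), radius=4):
    ijk = np.indices(shape)
    c = [(s - 1) / 2 for s in shape]
    data = sum((ijk[a] - c[a]) ** 2 for a in range(3)) <= radius**2
    return BrainMask(data=data, affine=np.diag([4.0, 4.0, 4.0, 1.0]))


class TestTwoSampleTmap:
    def test_hand_computed_pooled_t(self):
        """{2,3,4} controls vs {1,2,3} patients: t = 1/sqrt(2/3) = 1.2247."""
        design = _design(3, 3)
        block = np.array([[1.0], [2.0], [3.0], [2.0], [3.0], [4.0]])
        t = two_sample_tmap(block, design, direction="control>patient")
        assert t[0] == pytest.approx(1.224744871, abs=1e-6)
        t2 = two_sample_tmap(block, design, direction="patient>control")
        assert t2[0] == pytest.approx(-1.224744871, abs=1e-6)

    def test_identical_groups_give_zero(self):
        design = _design(3, 3)
        block = np.tile(np.array([[1.0, 5.0, 9.0]]).T, (2, 4)).reshape(6, 4)
        t = two_sample_tmap(block, design)
        np.testing.assert_array_equal(t, 0.0)

    def test_orthogonal_covariate_changes_only_residual_dof(self, rng):
        """Covariate orthogonal to intercept, group and data leaves the
        group estimate and residual untouched; only the residual dof drops,
        so t scales exactly by sqrt((n-3)/(n-2))."""
        n = 16
        design = _design(8, 8)
        y = rng.standard_normal((n, 20))
        g = design.is_patient.astype(float)
        gc = g - g.mean()
        c = rng.standard_normal(n)
        c -= c.mean()
        c -= gc * (c @ gc) / (gc @ gc)
        basis = np.column_stack([np.ones(n), gc, c])
        y = y - basis @ np.linalg.lstsq(basis, y, rcond=None)[0] + np.outer(gc, rng.standard_normal(20))
        cov = np.tile(c[:, None], (1, 20))
        t_plain = two_sample_tmap(y, design)
        t_cov = two_sample_tmap(y, design, covariate=cov)
        np.testing.assert_allclose(
            t_cov, t_plain * np.sqrt((n - 3) / (n - 2)), atol=1e-6
        )

    def test_requires_two_per_group(self):
        design = _design(1, 3)
        with pytest.raises(ValueError, match="2 subjects"):
            two_sample_tmap(np.zeros((4, 3)), design)


class TestTfce:
    def test_zero_map_stays_zero(self):
        out = tfce(np.zeros((5, 5, 5)))
        np.testing.assert_array_equal(out, 0.0)

    def test_single_voxel_closed_form(self):
        """Isolated voxel of height 3: integral of h^2 dh = 27/3 = 9."""
        m = np.zeros((5, 5, 5))
        m[2, 2, 2] = 3.0
        out = tfce(m)
        assert out[2, 2, 2] == pytest.approx(9.0, rel=0.02)
        assert np.count_nonzero(out) == 1

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_agrees_with_fine_step_brute_force(self, seed):
        arr = np.random.default_rng(seed).standard_normal((5, 5, 5))
        ours = tfce(arr)
        oracle = brute_force_tfce(arr)
        assert np.abs(ours - oracle).max() <= 0.01 * oracle.max()

    @pytest.mark.parametrize("connectivity", [6, 18, 26])
    def test_connectivity_variants_match_oracle(self, connectivity):
        arr = np.random.default_rng(7).standard_normal((6, 6, 6))
        ours = tfce(arr, TfceParams(connectivity=connectivity))
        oracle = brute_force_tfce(arr, n_steps=1000, connectivity=connectivity)
        assert np.abs(ours - oracle).max() <= 0.01 * oracle.max()

    @pytest.mark.parametrize("scale", [1.5, 3.0])
    def test_monotone_under_positive_scaling(self, scale):
        """Scaling the stat map by c > 1 never decreases any enhanced value."""
        arr = np.random.default_rng(5).standard_normal((6, 6, 5))
        base = tfce(arr)
        boosted = tfce(arr * scale)
        assert (boosted >= base - 1e-12).all()

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            TfceParams(connectivity=4)
        with pytest.raises(ValueError):
            TfceParams(n_steps=5)
        with pytest.raises(ValueError):
            TfceParams(height_exponent=-1)


class TestYConcat:
    def test_single_block_round_trip(self, rng):
        mask = _ball_mask()
        design = _design(3, 3)
        block = rng.standard_normal((6, mask.n_voxels))
        data = yconcat([(5, block)], design, mask)
        assert data.n_blocks == 1
        np.testing.assert_array_equal(data.blocks[0][1], block)
        idx = data.block_index
        assert idx.shape == (mask.n_voxels, 2)
        assert (idx[:, 0] == 5).all()
        np.testing.assert_array_equal(idx[:, 1], np.arange(mask.n_voxels))

    def test_study_scale_36_blocks(self, rng):
        mask = _ball_mask((6, 6, 5), 2)
        design = _design(2, 2)
        blocks = [(k, rng.standard_normal((4, mask.n_voxels))) for k in range(36)]
        data = yconcat(blocks, design, mask)
        assert data.n_blocks == 36
        assert data.labels == list(range(36))

    def test_covariate_must_align(self, rng):
        mask = _ball_mask()
        design = _design(2, 2)
        block = rng.standard_normal((4, mask.n_voxels))
        with pytest.raises(ValueError, match="align"):
            yconcat([(0, block), (1, block)], design, mask,
                    gm_covariate=[block])

    def test_subject_axis_mismatch_rejected(self, rng):
        mask = _ball_mask()
        design = _design(2, 2)
        with pytest.raises(ValueError, match="shape"):
            yconcat([(0, rng.standard_normal((5, mask.n_voxels)))], design, mask)


class TestPermutationTest:
    def test_default_permutation_count_is_5000(self):
        sig = inspect.signature(permutation_test)
        assert sig.parameters["n_perm"].default == 5000

    def test_constant_data_gives_zero_t_and_p_one(self, rng):
        mask = _ball_mask((8, 8, 6), 3)
        design = _design(4, 4)
        row = rng.standard_normal(mask.n_voxels)
        block = np.tile(row, (8, 1))
        data = yconcat([(0, block)], design, mask)
        res = permutation_test(data, n_perm=120, seed=0)
        np.testing.assert_array_equal(res.tmaps[0], 0.0)
        np.testing.assert_array_equal(res.pmaps[0], 1.0)

    def test_exhaustive_enumeration_auto_enabled(self, rng):
        mask = _ball_mask((8, 8, 6), 3)
        design = _design(4, 4)
        block = rng.standard_normal((8, mask.n_voxels))
        data = yconcat([(0, block)], design, mask)
        res = permutation_test(data, n_perm=200, seed=0)
        assert res.exhaustive
        assert res.n_perm == 70  # C(8,4) label arrangements
        assert (res.pmaps[0] >= 1 / 70 - 1e-12).all()

    def test_monte_carlo_tracks_exhaustive_oracle(self, rng):
        """n=4+4: 5000 random draws land within 0.02 of full enumeration."""
        mask = _ball_mask((8, 8, 6), 3)
        design = _design(4, 4)
        block = rng.standard_normal((8, mask.n_voxels))
        block[design.is_patient] += 0.8  # some structure so p varies
        data = yconcat([(0, block)], design, mask)
        exact = permutation_test(data, n_perm=200, seed=0)
        mc = permutation_test(data, n_perm=5000, seed=1, allow_exhaustive=False)
        assert exact.exhaustive and not mc.exhaustive
        assert np.abs(exact.pmaps[0] - mc.pmaps[0]).max() <= 0.02

    def test_per_map_equals_single_block_joint(self, rng):
        mask = _ball_mask((8, 8, 6), 3)
        design = _design(5, 5)
        block = rng.standard_normal((10, mask.n_voxels))
        data = yconcat([(3, block)], design, mask)
        joint = permutation_test(data, n_perm=150, seed=9)
        single = per_map_test((3, block), design, mask, n_perm=150, seed=9)
        np.testing.assert_array_equal(joint.pmaps[0], single.pmaps[0])
        np.testing.assert_array_equal(joint.null_max, single.null_max)

    def test_joint_correction_is_more_conservative(self, rng):
        """Shared permutation stream: per-map corrected p <= joint corrected
        p voxel-wise, and significant-IC counts order the same way."""
        mask = _ball_mask((8, 8, 6), 3)
        design = _design(5, 5)
        blocks = [(k, rng.standard_normal((10, mask.n_voxels))) for k in range(6)]
        for k, b in blocks:
            b[design.is_patient] += 0.5 * (k + 1) / 6
        data = yconcat(blocks, design, mask)
        joint = permutation_test(data, n_perm=300, seed=4)
        alpha = 0.05
        n_sig_joint, n_sig_single = 0, 0
        for k, b in blocks:
            single = per_map_test((k, b), design, mask, n_perm=300, seed=4)
            assert (single.pmaps[0] <= joint.pmaps[k] + 1e-12).all()
            n_sig_single += int((single.pmaps[0] < alpha).any())
            n_sig_joint += int((joint.pmaps[k] < alpha).any())
        assert n_sig_joint <= n_sig_single

    def test_p_monotone_in_tfce_and_bounded(self, rng):
        mask = _ball_mask((8, 8, 6), 3)
        design = _design(5, 5)
        block = rng.standard_normal((10, mask.n_voxels))
        data = yconcat([(0, block)], design, mask)
        res = permutation_test(data, n_perm=150, seed=2)
        p, tf = res.pmaps[0], res.tfce_maps[0]
        assert (p >= 1.0 / (res.n_perm + 1) - 1e-12).all() and (p <= 1.0).all()
        order = np.argsort(tf)
        assert (np.diff(p[order]) <= 1e-12).all()

    def test_small_n_perm_rejected_and_coarse_warned(self, rng):
        mask = _ball_mask((8, 8, 6), 3)
        design = _design(4, 4)
        data = yconcat([(0, rng.standard_normal((8, mask.n_voxels)))], design, mask)
        with pytest.raises(ValueError, match="n_perm"):
            permutation_test(data, n_perm=50)
        with pytest.warns(RuntimeWarning, match="coarse"):
            permutation_test(data, n_perm=150, seed=0)


class TestSplitBlocks:
    def _result(self, mask, pvals):
        v = mask.n_voxels
        return PermutationResult(
            labels=[2],
            tmaps=[np.linspace(-1, 3, v)],
            tfce_maps=[np.linspace(0, 9, v)],
            pmaps=[pvals],
            null_max=np.zeros(10),
            null_max_blocks=np.zeros((10, 1)),
            n_perm=10,
            exhaustive=False,
            seed=0,
            direction="patient>control",
            mask=mask,
            tfce_params=TfceParams(),
        )

    def test_boundary_p_exactly_alpha_excluded(self):
        mask = _ball_mask((8, 8, 6), 3)
        p = np.full(mask.n_voxels, 0.5)
        p[0] = 0.05   # exactly alpha: not significant
        p[1] = 0.049  # just below: significant
        blocks = split_blocks(self._result(mask, p), alpha=0.05)
        sig_flat = blocks[0].sig_mask[mask.data]
        assert not sig_flat[0]
        assert sig_flat[1]
        assert sig_flat.sum() == 1

    def test_volumes_restored_to_grid(self):
        mask = _ball_mask((8, 8, 6), 3)
        p = np.full(mask.n_voxels, 0.2)
        blk = split_blocks(self._result(mask, p))[0]
        assert blk.ic_label == 2
        assert blk.t_vol.shape == mask.data.shape
        assert (blk.p_vol[~mask.data] == 1.0).all()
        np.testing.assert_array_equal(blk.p_vol[mask.data], p)


def test_smooth_volume_preserves_mean_and_spreads(rng):
    data = np.zeros((12, 12, 10, 1))
    data[6, 6, 5, 0] = 1.0
    vol = Volume4D(data=data, affine=np.diag([4.0, 4.0, 4.0, 1.0]), tr_seconds=1.0)
    sm = smooth_volume(vol, sigma_mm=3.0)
    assert sm.data.sum() == pytest.approx(1.0, rel=1e-6)
    assert sm.data.max() < 1.0
    # sigma 3 mm on a 4 mm grid = 0.75 voxels
    assert sm.data[6, 6, 5, 0] == pytest.approx(
        (1 / (np.sqrt(2 * np.pi) * 0.75)) ** 3, rel=0.05
    )
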