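"""FC profiles, Fisher-Z, group averaging and lobe partial correlations."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from knit.connectivity import (ProfileMap, fisher_z, group_average_profiles,
                               lobe_mean_series, partial_corr_lobes,
                               roi_mean_series, voxel_roi_fc, bilateral_merge)
from knit.io_formats import BoldSeries, LabelInfo, LabelVolume, RoiSet
from tests.conftest import make_profiles


def grid_bold(series_by_voxel, shape=(4, 4, 4), t=None):
    """Place explicit series at chosen voxels; everything else mild noise."""
    t = t if t is not None else len(next(iter(series_by_voxel.values())))
    rng = np.random.default_rng(99)
    data = rng.normal(size=shape + (t,))
    for vox, series in series_by_voxel.items():
        data[vox] = series
    return BoldSeries(data, tr=1.0, affine=np.eye(4))


def single_roi_setup(roi_series, seed_series, t=None):
    """One seed voxel at (0,0,0), one single-voxel ROI (id 1) at (3,3,3)."""
    bold = grid_bold({(0, 0, 0): seed_series, (3, 3, 3): roi_series}, t=t)
    labels = np.zeros((4, 4, 4), dtype=int)
    labels[3, 3, 3] = 1
    lv = LabelVolume(labels, np.eye(4), {1: LabelInfo("roi", "mid", "none")})
    roiset = RoiSet((1,), {1: LabelInfo("roi", "mid", "none")})
    mask = np.zeros((4, 4, 4), dtype=bool)
    mask[0, 0, 0] = True
    return bold, mask, lv, roiset


class TestVoxelRoiFC:
    def test_identical_series_give_r_one(self):
        s = np.sin(np.arange(60) * 0.3)
        bold, mask, lv, rs = single_roi_setup(s, s.copy())
        pm = voxel_roi_fc(bold, mask, lv, rs)
        assert pm.values[0, 0] == pytest.approx(1.0, abs=1e-12)

    def test_negated_series_give_r_minus_one(self):
        s = np.sin(np.arange(60) * 0.3)
        bold, mask, lv, rs = single_roi_setup(-s, s.copy())
        assert voxel_roi_fc(bold, mask, lv, rs).values[0, 0] == pytest.approx(-1.0, abs=1e-12)

    def test_independent_noise_has_small_r(self):
        rng = np.random.default_rng(7)
        t = 2295
        bold, mask, lv, rs = single_roi_setup(rng.normal(size=t),
                                              rng.normal(size=t))
        # null sd of Pearson r is ~1/sqrt(t) ~ 0.021
        assert abs(voxel_roi_fc(bold, mask, lv, rs).values[0, 0]) < 0.05

    def test_mean_of_correlations_not_correlation_of_mean(self):
        # two anti-correlated ROI voxels: mean-of-correlations cancels to ~0
        # while the mean ROI series is degenerate noise
        rng = np.random.default_rng(8)
        s = rng.normal(size=80)
        v = rng.normal(size=80)
        bold = grid_bold({(0, 0, 0): v, (3, 3, 3): s, (3, 3, 2): -s})
        labels = np.zeros((4, 4, 4), dtype=int)
        labels[3, 3, 3] = labels[3, 3, 2] = 1
        lv = LabelVolume(labels, np.eye(4), {1: LabelInfo("roi", "mid", "none")})
        rs = RoiSet((1,), {1: LabelInfo("roi", "mid", "none")})
        mask = np.zeros((4, 4, 4), dtype=bool)
        mask[0, 0, 0] = True
        pm = voxel_roi_fc(bold, mask, lv, rs)
        assert abs(pm.values[0, 0]) < 1e-10  # r and -r average to exactly 0

    def test_positive_rescaling_leaves_profile_unchanged(self):
        s = np.sin(np.arange(60) * 0.3)
        bold, mask, lv, rs = single_roi_setup(s, 0.5 * s + 3)
        a = voxel_roi_fc(bold, mask, lv, rs).values
        bold2, *_ = single_roi_setup(s, 0.5 * s + 3)
        bold2.data[0, 0, 0] *= 17.0
        b = voxel_roi_fc(bold2, mask, lv, rs).values
        np.testing.assert_allclose(a, b, atol=1e-12)

    def test_empty_roi_is_error(self):
        s = np.arange(10.0)
        bold, mask, lv, rs = single_roi_setup(s, s.copy())
        lv2 = LabelVolume(np.zeros((4, 4, 4), dtype=int), np.eye(4))
        with pytest.raises(ValueError, match="empty"):
            voxel_roi_fc(bold, mask, lv2, rs)


class TestRoiMeanSeries:
    def test_single_voxel_roi_returns_its_series(self):
        s = np.arange(20.0)
        bold, _, lv, _ = single_roi_setup(s, s.copy())
        np.testing.assert_array_equal(roi_mean_series(bold, lv, 1), s)

    def test_identical_voxels_average_to_same_series(self):
        s = np.sin(np.arange(30) * 0.2)
        bold = grid_bold({(1, 1, 1): s, (1, 1, 2): s.copy()})
        labels = np.zeros((4, 4, 4), dtype=int)
        labels[1, 1, 1] = labels[1, 1, 2] = 2
        lv = LabelVolume(labels, np.eye(4), {2: LabelInfo("r", "mid", "none")})
        np.testing.assert_allclose(roi_mean_series(bold, lv, 2), s, atol=1e-12)

    def test_empty_roi_is_error(self):
        bold = grid_bold({}, t=5)
        with pytest.raises(ValueError, match="empty"):
            roi_mean_series(bold, LabelVolume(np.zeros((4, 4, 4), dtype=int),
                                              np.eye(4)), 1)


class TestFisherZ:
    def test_known_values(self):
        pm = make_profiles([[0.0, 0.5, -0.5]])
        z = fisher_z(pm).values[0]
        assert z[0] == pytest.approx(0.0, abs=1e-12)
        assert z[1] == pytest.approx(0.5 * np.log(1.5 / 0.5), abs=1e-12)
        assert z[2] == pytest.approx(-z[1], abs=1e-12)

    def test_clipping_keeps_z_finite(self):
        z = fisher_z(make_profiles([[1.0, -1.0]])).values
        assert np.all(np.isfinite(z))

    @given(st.floats(-0.999, 0.999), st.floats(-0.999, 0.999))
    @settings(deadline=None, max_examples=50)
    def test_monotone_and_odd(self, a, b):
        za, zb = fisher_z(make_profiles([[a, b]])).values[0]
        if a < b:
            assert za < zb
        z_neg = fisher_z(make_profiles([[-a]])).values[0, 0]
        assert z_neg == pytest.approx(-za, abs=1e-12)

    def test_requires_pearson_scale(self):
        pm = make_profiles([[0.2]], scale="fisher_z")
        with pytest.raises(ValueError, match="pearson_r"):
            fisher_z(pm)


class TestGroupAverage:
    def test_single_map_is_identity(self):
        pm = make_profiles([[0.1, 0.2]], scale="fisher_z")
        out = group_average_profiles([pm])
        np.testing.assert_array_equal(out.values, pm.values)

    def test_opposite_maps_cancel(self):
        a = make_profiles([[0.3, -0.2]], scale="fisher_z")
        b = make_profiles([[-0.3, 0.2]], scale="fisher_z")
        np.testing.assert_allclose(group_average_profiles([a, b]).values, 0.0)

    def test_sign_flip_commutes_with_averaging(self):
        rng = np.random.default_rng(1)
        maps = [make_profiles(rng.normal(size=(3, 4)), scale="fisher_z")
                for _ in range(4)]
        flipped = [make_profiles(-m.values, scale="fisher_z") for m in maps]
        np.testing.assert_allclose(group_average_profiles(flipped).values,
                                   -group_average_profiles(maps).values)

    def test_mismatched_axes_rejected(self):
        a = make_profiles([[0.1, 0.2]])
        b = make_profiles([[0.1, 0.2, 0.3]])
        with pytest.raises(ValueError, match="mismatch|axes"):
            group_average_profiles([a, b])

    def test_averaging_reduces_profile_noise(self, small_truth):
        """Group-mean profile is closer to the planted direction than the
        median single subject (variance reduction)."""
        from knit.phantom import simulate_subject

        P = small_truth.profile_matrix
        Pn = P / np.linalg.norm(P, axis=1, keepdims=True)
        own = small_truth.true_labels - 1
        interior = ~small_truth.border_mask
        maps = []
        cosines = []
        for s in range(8):
            bold = simulate_subject(small_truth, subject_seed=100 + s)
            pm = voxel_roi_fc(bold, small_truth.seed_mask.data > 0,
                              small_truth.roi_parcels, small_truth.roiset)
            zm = fisher_z(pm)
            maps.append(zm)
            V = zm.values / np.linalg.norm(zm.values, axis=1, keepdims=True)
            cosines.append(np.einsum("ij,ij->i", V, Pn[own])[interior].mean())
        mean_map = group_average_profiles(maps)
        V = mean_map.values / np.linalg.norm(mean_map.values, axis=1,
                                             keepdims=True)
        mean_cos = np.einsum("ij,ij->i", V, Pn[own])[interior].mean()
        assert mean_cos >= np.median(cosines)


class TestBilateralMerge:
    def test_pairs_average_and_midline_passes(self, toy_roiset):
        pm = make_profiles([[0.2, 0.4, 0.0, 0.6, 1.0, -1.0]])
        merged = bilateral_merge(pm, toy_roiset)
        np.testing.assert_allclose(merged.values[0], [0.3, 0.3, 0.0])
        assert merged.roi_ids == (1, 3, 5)


class TestPartialCorrelation:
    def _setup(self, voxel_series, lobe_sources, t):
        """Six single-voxel ROIs, lobes = temporal/parietal/frontal pairs of
        the toy ROI set; each lobe's two ROI voxels carry its source."""
        shape = (6, 6, 6)
        rng = np.random.default_rng(11)
        data = rng.normal(size=shape + (t,)) * 0.01
        labels = np.zeros(shape, dtype=int)
        info = {}
        lobes5 = ["temporal", "parietal", "frontal", "occipital", "limbic"]
        pairs = {}
        for j, lobe in enumerate(lobes5):
            lid, rid = 2 * j + 1, 2 * j + 2
            labels[5, j, 0] = lid
            labels[5, j, 1] = rid
            data[5, j, 0] = lobe_sources[j] + 0.05 * rng.normal(size=t)
            data[5, j, 1] = lobe_sources[j] + 0.05 * rng.normal(size=t)
            info[lid] = LabelInfo(f"{lobe}_L", "L", lobe)
            info[rid] = LabelInfo(f"{lobe}_R", "R", lobe)
            pairs[lid] = rid
            pairs[rid] = lid
        data[0, 0, 0] = voxel_series
        mask = np.zeros(shape, dtype=bool)
        mask[0, 0, 0] = True
        roiset = RoiSet(tuple(range(1, 11)), info, pairs)
        bold = BoldSeries(data, tr=1.0, affine=np.eye(4))
        return bold, mask, LabelVolume(labels, np.eye(4), info), roiset

    def test_driving_lobe_has_maximal_partial_corr(self):
        t = 600
        rng = np.random.default_rng(21)
        sources = rng.normal(size=(5, t))
        voxel = sources[1] + 0.5 * rng.normal(size=t)   # parietal-driven
        bold, mask, lv, rs = self._setup(voxel, sources, t)
        lp = partial_corr_lobes(bold, mask, lv, rs)
        assert np.argmax(lp.values[0]) == 1

    def test_orthogonal_voxel_has_near_zero_profile(self):
        t = 600
        rng = np.random.default_rng(22)
        sources = rng.normal(size=(5, t))
        voxel = rng.normal(size=t)   # independent of every lobe
        bold, mask, lv, rs = self._setup(voxel, sources, t)
        lp = partial_corr_lobes(bold, mask, lv, rs)
        assert np.all(np.abs(lp.values[0]) < 0.15)

    def test_duplicated_lobe_series_raise_rank_error(self):
        t = 200
        rng = np.random.default_rng(23)
        sources = rng.normal(size=(5, t))
        sources[2] = sources[0]   # frontal duplicates temporal
        bold, mask, lv, rs = self._setup(rng.normal(size=t), sources, t)
        # make the duplication exact at the ROI-voxel level
        bold.data[5, 2, 0] = bold.data[5, 0, 0]
        bold.data[5, 2, 1] = bold.data[5, 0, 1]
        with pytest.raises(ValueError, match="rank"):
            partial_corr_lobes(bold, mask, lv, rs)

    def test_lobe_series_shape(self):
        t = 100
        rng = np.random.default_rng(24)
        bold, mask, lv, rs = self._setup(rng.normal(size=t),
                                         rng.normal(size=(5, t)), t)
        L = lobe_mean_series(bold, lv, rs)
        assert L.shape == (t, 5)
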