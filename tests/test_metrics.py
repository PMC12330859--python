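"""Cluster profiles, volumes, symmetry, laterality and connectivity metrics."""

import numpy as np
import pandas as pd
import pytest

from knit.clustering import Parcellation
from knit.metrics import (cluster_profiles, global_thalamic_connectivity,
                          laterality_indices, relative_volumes,
                          roi_roi_connectivity, symmetry_index)
from tests.conftest import make_parcellation, make_profiles


class TestClusterProfiles:
    def test_median_within_cluster(self, toy_roiset):
        vals = np.zeros((3, 6))
        vals[:, 0] = [0.1, 0.2, 0.9]
        vals[:, 1] = [0.4, 0.5, 0.6]
        pm = make_profiles(vals)
        parc = make_parcellation([1, 1, 1], k=1, voxels=pm.voxels)
        table = cluster_profiles([pm], [parc], toy_roiset)
        roi1 = table[(table.cluster == 1) & (table.roi_id == 1)]
        assert roi1["median_fc"].iloc[0] == pytest.approx(0.2)

    def test_constant_profile_zero_variance_error(self, toy_roiset):
        pm = make_profiles(np.full((4, 6), 0.3))
        parc = make_parcellation([1] * 4, k=1, voxels=pm.voxels)
        with pytest.raises(ValueError, match="zero variance"):
            cluster_profiles([pm], [parc], toy_roiset)

    def test_z_flags_invariant_to_common_affine_rescale(self, toy_roiset):
        rng = np.random.default_rng(0)
        vals = rng.uniform(0, 0.8, size=(10, 6))
        pm = make_profiles(vals)
        parc = make_parcellation(rng.integers(1, 3, size=10), k=2,
                                 voxels=pm.voxels)
        base = cluster_profiles([pm], [parc], toy_roiset)
        pm2 = make_profiles(np.clip(0.9 * vals + 0.05, -1, 1))
        scaled = cluster_profiles([pm2], [parc], toy_roiset)
        pd.testing.assert_series_equal(base["connected"], scaled["connected"])
        pd.testing.assert_series_equal(base["disconnected"],
                                       scaled["disconnected"])

    def test_driving_roi_flagged_connected(self, small_study, toy_roiset):
        """Each planted cluster's dominant ROI pair stands out at z > 1."""
        from knit.connectivity import group_average_profiles
        study = small_study
        member_means = [group_average_profiles(
            [study.subject_profiles_z[i] for i in subset])
            for subset in study.knit_ensemble.subsets]
        table = cluster_profiles(member_means, study.knit_ensemble.members,
                                 study.truth.roiset, bilateral=True)
        # map each consensus cluster to its dominant planted cluster by
        # voxel overlap, then expect that cluster's planted ROI pair on top
        P = study.truth.profile_matrix
        true = study.truth.true_labels
        matched = 0
        for c in range(1, study.knit_consensus.k + 1):
            sel = study.knit_consensus.labels == c
            planted = int(np.bincount(true[sel]).argmax())
            planted_pair = int(np.argmax(P[planted - 1])) // 2
            sub = table[table.cluster == c]
            top = sub.loc[sub["z"].idxmax(), "roi_id"]
            if top == 2 * planted_pair + 1:   # merged pair keeps the L id
                matched += 1
        assert matched >= study.knit_consensus.k - 1


class TestRelativeVolumes:
    def test_single_member_fractions(self):
        parc = make_parcellation([1] * 30 + [2] * 70, k=2, shape=(10, 10, 10))
        table = relative_volumes([parc])
        assert dict(zip(table.cluster, table["mean"])) == {1: 0.3, 2: 0.7}

    def test_rows_sum_to_one(self):
        rng = np.random.default_rng(1)
        members = [make_parcellation(rng.integers(1, 4, size=50), k=3,
                                     shape=(10, 10, 10)) for _ in range(6)]
        table = relative_volumes(members)
        assert table["mean"].sum() == pytest.approx(1.0, abs=1e-12)

    def test_two_member_hand_arithmetic(self):
        a = make_parcellation([1] * 30 + [2] * 70, k=2, shape=(10, 10, 10))
        b = make_parcellation([1] * 50 + [2] * 50, k=2, shape=(10, 10, 10))
        table = relative_volumes([a, b])
        means = dict(zip(table.cluster, table["mean"]))
        sds = dict(zip(table.cluster, table["sd"]))
        assert means == {1: pytest.approx(0.4), 2: pytest.approx(0.6)}
        assert sds[1] == pytest.approx(0.14142, abs=1e-4)
        assert sds[2] == pytest.approx(0.14142, abs=1e-4)


def two_sided_parcellation(left_labels, right_labels, shape=(8, 4, 4)):
    """Left column of voxels at x=1, right at x=6 (mirror partner)."""
    vol = np.zeros(shape, dtype=int)
    left = np.zeros(shape, dtype=bool)
    right = np.zeros(shape, dtype=bool)
    coords = [(j, k) for j in range(2) for k in range(3)]
    for (j, k), lab in zip(coords, left_labels):
        vol[1, j, k] = lab
        left[1, j, k] = True
    for (j, k), lab in zip(coords, right_labels):
        vol[6, j, k] = lab
        right[6, j, k] = True
    voxels = np.argwhere(vol > 0)
    parc = Parcellation(voxels, vol[tuple(voxels.T)], 3, shape, np.eye(4))
    return parc, left, right


class TestSymmetryIndex:
    def test_perfect_mirror_symmetry(self):
        parc, L, R = two_sided_parcellation([1, 2, 3, 1, 2, 3],
                                            [1, 2, 3, 1, 2, 3])
        assert symmetry_index(parc, L, R) == 1.0

    def test_completely_asymmetric(self):
        parc, L, R = two_sided_parcellation([1] * 6, [2] * 6)
        assert symmetry_index(parc, L, R) == 0.0

    def test_hand_built_four_of_six_matching(self):
        parc, L, R = two_sided_parcellation([1, 1, 1, 2, 2, 2],
                                            [1, 1, 1, 2, 3, 3])
        assert symmetry_index(parc, L, R) == pytest.approx(4 / 6, abs=1e-12)

    def test_reflection_invariance(self):
        parc, L, R = two_sided_parcellation([1, 1, 2, 2, 3, 3],
                                            [1, 2, 2, 3, 3, 1])
        mirrored_vol = parc.to_volume()[::-1, :, :]
        voxels = np.argwhere(mirrored_vol > 0)
        mirrored = Parcellation(voxels, mirrored_vol[tuple(voxels.T)], 3,
                                parc.shape, parc.affine)
        assert symmetry_index(parc, L, R) == pytest.approx(
            symmetry_index(mirrored, R[::-1, :, :], L[::-1, :, :]), abs=1e-12)

    def test_empty_hemisphere_rejected(self):
        parc, L, R = two_sided_parcellation([1] * 6, [1] * 6)
        with pytest.raises(ValueError, match="empty"):
            symmetry_index(parc, np.zeros_like(L), R)


class TestLaterality:
    def _profiles(self, left_block, right_block, toy_roiset):
        """2 seed voxels (one per hemisphere) x 6 ROIs (L ids 1,3,5)."""
        vox = np.array([[0, 0, 0], [5, 0, 0]])   # left seed, right seed
        vals = np.zeros((2, 6))
        vals[0] = left_block
        vals[1] = right_block
        pm = make_profiles(vals, voxels=vox)
        L = np.zeros((6, 1, 1), dtype=bool)
        R = np.zeros((6, 1, 1), dtype=bool)
        L[0, 0, 0] = True
        R[5, 0, 0] = True
        return pm, L, R

    def test_exchange_symmetric_fc_gives_unity(self, toy_roiset):
        # right seed <-> left seed with L and R ROI columns swapped
        pm, L, R = self._profiles([0.4, 0.2, 0.4, 0.2, 0.4, 0.2],
                                  [0.2, 0.4, 0.2, 0.4, 0.2, 0.4], toy_roiset)
        out = laterality_indices(pm, L, R, toy_roiset)
        assert out["Ri"] == pytest.approx(1.0)
        assert out["Rc"] == pytest.approx(1.0)

    def test_doubled_right_fc_doubles_both(self, toy_roiset):
        pm, L, R = self._profiles([0.3, 0.1, 0.3, 0.1, 0.3, 0.1],
                                  [0.2, 0.6, 0.2, 0.6, 0.2, 0.6], toy_roiset)
        out = laterality_indices(pm, L, R, toy_roiset)
        pm2, _, _ = self._profiles([0.3, 0.1, 0.3, 0.1, 0.3, 0.1],
                                   [0.1, 0.3, 0.1, 0.3, 0.1, 0.3], toy_roiset)
        base = laterality_indices(pm2, L, R, toy_roiset)
        assert out["Ri"] == pytest.approx(2 * base["Ri"])
        assert out["Rc"] == pytest.approx(2 * base["Rc"])

    def test_hemisphere_swap_inverts_ratio(self, toy_roiset):
        rng = np.random.default_rng(4)
        a, b = rng.uniform(0.1, 0.5, 6), rng.uniform(0.1, 0.5, 6)
        pm, L, R = self._profiles(a, b, toy_roiset)
        out = laterality_indices(pm, L, R, toy_roiset)
        # swap hemispheres of both seed masks and ROI columns
        swap = [1, 0, 3, 2, 5, 4]
        pm2, _, _ = self._profiles(b[swap], a[swap], toy_roiset)
        swapped = laterality_indices(pm2, L, R, toy_roiset)
        assert swapped["Ri"] == pytest.approx(1 / out["Ri"], abs=1e-12)

    def test_symmetric_phantom_near_unity(self):
        from knit.connectivity import voxel_roi_fc
        from knit.phantom import PhantomSpec, make_phantom_anatomy, \
            simulate_subject
        spec = PhantomSpec(seed=2, n_timepoints=2000, noise_sd=0.5)
        truth = make_phantom_anatomy(spec)
        bold = simulate_subject(truth, subject_seed=6)
        pm = voxel_roi_fc(bold, truth.seed_mask.data > 0, truth.roi_parcels,
                          truth.roiset)
        out = laterality_indices(pm, truth.left_mask, truth.right_mask,
                                 truth.roiset)
        assert 0.9 <= out["Ri"] <= 1.1
        assert 0.9 <= out["Rc"] <= 1.1


class TestGlobalConnectivity:
    def test_absolute_value_applied(self, toy_roiset):
        pm = make_profiles(np.full((5, 6), -0.3))
        table = global_thalamic_connectivity([pm], toy_roiset)
        assert np.allclose(table["global_fc"], 0.3)

    def test_bilateral_pair_merged(self, toy_roiset):
        vals = np.zeros((4, 6))
        vals[:, 0] = 0.2    # roi 1 (L)
        vals[:, 1] = 0.4    # roi 2 (R)
        table = global_thalamic_connectivity([make_profiles(vals)], toy_roiset)
        assert table.loc[table.name == "temporal", "global_fc"].iloc[0] == \
            pytest.approx(0.3)

    def test_dominant_planted_roi_has_largest_value(self, small_study):
        table = global_thalamic_connectivity(small_study.subject_profiles_r,
                                             small_study.truth.roiset)
        P = small_study.truth.profile_matrix
        W = small_study.truth.voxel_weights
        per_roi_weight = W.mean(axis=0)
        pair_weight = per_roi_weight.reshape(-1, 2).mean(axis=1)
        assert int(np.argmax(table["global_fc"])) == int(np.argmax(pair_weight))


class TestRoiRoi:
    def _cohort(self, n=4, groups=("g0", "g1"), source_map=None):
        from knit.phantom import PhantomSpec, make_phantom_anatomy, \
            simulate_cohort
        spec = PhantomSpec(seed=1, n_timepoints=300, noise_sd=0.5,
                           roi_source_map=source_map)
        truth = make_phantom_anatomy(spec)
        bolds, meta = simulate_cohort(truth, n, 13, age_groups=groups)
        return truth, bolds, meta

    def test_matrix_properties_and_consecutive_diffs(self):
        truth, bolds, meta = self._cohort()
        mats, diffs, glob = roi_roi_connectivity(bolds, truth.roi_parcels,
                                                 truth.roiset, meta,
                                                 n_subjects=2)
        for m in mats.values():
            np.testing.assert_allclose(np.diag(m), 1.0, atol=1e-12)
            np.testing.assert_allclose(m, m.T, atol=1e-12)
        assert set(diffs) == {"g1-g0"}
        np.testing.assert_allclose(diffs["g1-g0"], mats["g1"] - mats["g0"])
        assert set(glob.index) == {"g0", "g1"}
        assert (glob > 0).all()

    def test_paired_rois_more_connected_than_independent(self):
        # ROIs 1 and 2 share one source; all other ROIs are independent
        truth, bolds, meta = self._cohort(groups=("g0",),
                                          source_map=(0, 0, 1, 2, 3, 4))
        mats, _, _ = roi_roi_connectivity(bolds, truth.roi_parcels,
                                          truth.roiset, meta, n_subjects=4)
        m = mats["g0"]
        same_pair = m[0, 1]
        cross = max(abs(m[0, 2]), abs(m[0, 3]), abs(m[1, 2]))
        assert same_pair > cross

    def test_small_group_rejected(self):
        truth, bolds, meta = self._cohort()
        with pytest.raises(ValueError, match="subjects"):
            roi_roi_connectivity(bolds, truth.roi_parcels, truth.roiset,
                                 meta, n_subjects=10)
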