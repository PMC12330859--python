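"""Shared fixtures: tiny ROI sets, phantom anatomies and one small end-to-end
study reused across test modules (session-scoped to keep the suite fast)."""

from __future__ import annotations

import numpy as np
import pytest

from knit.clustering import Parcellation
from knit.connectivity import ProfileMap
from knit.io_formats import LabelInfo, RoiSet
from knit.phantom import PhantomSpec, make_phantom_anatomy
from knit.pipeline import RunConfig, run_phantom_study


@pytest.fixture(scope="session")
def toy_roiset() -> RoiSet:
    """Six ROIs: two bilateral pairs (temporal, parietal) + two more pairs."""
    info = {}
    pairs = {}
    lobes = ["temporal", "parietal", "frontal"]
    for j, lobe in enumerate(lobes):
        lid, rid = 2 * j + 1, 2 * j + 2
        info[lid] = LabelInfo(f"{lobe}_L", "L", lobe)
        info[rid] = LabelInfo(f"{lobe}_R", "R", lobe)
        pairs[lid] = rid
        pairs[rid] = lid
    return RoiSet(roi_ids=tuple(range(1, 7)), info=info, bilateral_pairs=pairs)


@pytest.fixture(scope="session")
def small_truth():
    """Default-sized anatomy with 3 planted bilateral clusters."""
    return make_phantom_anatomy(PhantomSpec(seed=0))


@pytest.fixture(scope="session")
def small_study():
    """One complete small phantom study shared by stability/metric tests."""
    cfg = RunConfig(master_seed=7, n_subjects=6, k=3, n_subject_bootstraps=12,
                    phantom={"seed": 0, "n_rois": 10, "k_true": 3,
                             "noise_sd": 1.0, "n_timepoints": 300})
    return run_phantom_study(cfg)


def make_parcellation(labels, k, shape=(4, 4, 4), voxels=None) -> Parcellation:
    """Hand-built parcellation over an explicit voxel list."""
    labels = np.asarray(labels)
    if voxels is None:
        voxels = np.argwhere(np.ones(shape, dtype=bool))[: len(labels)]
    return Parcellation(np.asarray(voxels), labels, k, shape, np.eye(4))


def make_profiles(values, voxels=None, scale="pearson_r") -> ProfileMap:
    values = np.asarray(values, dtype=float)
    if voxels is None:
        voxels = np.column_stack([np.arange(len(values))] * 3)
    return ProfileMap(voxels, values, tuple(range(1, values.shape[1] + 1)), scale)
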