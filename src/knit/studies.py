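"""Reference phantom studies: the packaged evaluation scenarios.

Three canned synthetic studies exercise the method end to end; tests and the
reproduction script both run them, so their conditions live in one place.

* recovery — five planted bilateral clusters, moderate noise, the standard
  bootstrap depth: measures how well the consensus parcellation recovers the
  planted truth (border-blend voxels excluded) and where uncertainty
  concentrates.
* comparison — four clusters of which two have genuinely mixed lobe
  profiles: one shares each of its lobes with a dominant single-lobe cluster
  (so a winner-takes-all assignment can only merge it away) and one mixes
  two lobes no other cluster uses (so WTA splits it noisily).  Measures the
  qualitative advantage of profile clustering: a dedicated cluster for the
  mixed-profile region and higher bilateral symmetry.
* variability — smaller three-cluster phantoms probing how bootstrap
  variability (mean CoV of IoU) behaves when k exceeds the true cluster
  count and when the number of timepoints grows.

The phantom anatomy seeds are fixed study conditions; the caller's
``master_seed`` drives subject noise, bootstrap resampling and k-means
initialization.
"""

from __future__ import annotations

import numpy as np

from .connectivity import fisher_z, voxel_roi_fc
from .phantom import PhantomSpec, make_phantom_anatomy, iter_cohort, derive_seed
from .pipeline import RunConfig
from .preprocess import preprocess
from .stability import cov_iou, subjects_bootstrap, timepoints_bootstrap


def recovery_config(master_seed: int) -> RunConfig:
    """k_true = 5, 10 subjects, 600 timepoints, unit noise, 40 bootstraps."""
    return RunConfig(master_seed=master_seed, n_subjects=10, k=5,
                     n_subject_bootstraps=40,
                     phantom={"seed": 0, "n_rois": 10, "k_true": 5,
                              "noise_sd": 1.0, "n_timepoints": 600})


#: cluster 3 of the comparison phantom: the "pulvinar analogue" whose profile
#: is a balanced mix of two lobes that both also drive single-lobe clusters
PULVINAR_CLUSTER = 3


def comparison_profile_matrix() -> np.ndarray:
    # ROI pairs cycle through temporal, parietal, frontal, occipital, limbic
    P = np.full((4, 10), 0.10)
    P[0, 0] = P[0, 1] = 1.0                   # temporal-dominant
    P[1, 2] = P[1, 3] = 1.0                   # parietal-dominant
    P[2, 0] = P[2, 1] = P[2, 2] = P[2, 3] = 1.0   # temporal+parietal mix
    P[3, 4] = P[3, 5] = P[3, 6] = P[3, 7] = 1.0   # frontal+occipital mix
    return P


def comparison_config(master_seed: int) -> RunConfig:
    """The KNIT-vs-WTA phantom: mixed-profile clusters, sharp borders."""
    return RunConfig(master_seed=master_seed, n_subjects=8, k=4,
                     n_subject_bootstraps=30,
                     phantom={"seed": 0, "n_rois": 10, "k_true": 4,
                              "noise_sd": 2.0, "n_timepoints": 400,
                              "border_mix_width": 0.0,
                              "profile_matrix": comparison_profile_matrix()})


def best_jaccard(labels: np.ndarray, target_mask: np.ndarray,
                 k: int) -> float:
    """Highest IoU between any cluster label and a target voxel set."""
    best = 0.0
    for c in range(1, k + 1):
        sel = labels == c
        union = int((sel | target_mask).sum())
        if union:
            best = max(best, float((sel & target_mask).sum() / union))
    return best


# ---------------------------------------------------------------------------
# variability studies


def _variability_spec(n_timepoints: int = 400, noise_sd: float = 1.0,
                      border_mix_width: float = 1.0) -> PhantomSpec:
    return PhantomSpec(seed=0, n_rois=6, k_true=3, noise_sd=noise_sd,
                       n_timepoints=n_timepoints,
                       border_mix_width=border_mix_width)


def _cohort_profiles(truth, n_subjects: int, cohort_seed: int,
                     keep_bold: bool = False):
    seed_mask = truth.seed_mask.data > 0
    analysis = seed_mask | (truth.roi_parcels.data > 0)
    profs, bolds = [], []
    for bold in iter_cohort(truth, n_subjects, cohort_seed):
        pp = preprocess(bold, mask=analysis)
        profs.append(fisher_z(voxel_roi_fc(pp, seed_mask, truth.roi_parcels,
                                           truth.roiset)))
        if keep_bold:
            bolds.append(pp)
    return profs, bolds


def variability_vs_k(master_seed: int, ks: tuple[int, int] = (3, 5),
                     n_subjects: int = 6, n_bootstraps: int = 20,
                     n_replicates: int = 6) -> dict[int, float]:
    """Mean summary CoV-of-IoU of subjects bootstraps at the given k values.

    The phantom plants 3 clusters in substantial noise; requesting more
    forces arbitrary splits whose placement varies across bootstraps.  On
    any single cohort the surplus split can occasionally lock onto one
    noise pattern, so the summary is averaged over independent cohort
    replicates.
    """
    truth = make_phantom_anatomy(_variability_spec(noise_sd=2.0))
    out = {}
    for k in ks:
        vals = []
        for rep in range(n_replicates):
            profs, _ = _cohort_profiles(truth, n_subjects,
                                        derive_seed(master_seed, 50, rep))
            ens = subjects_bootstrap(profs, k, 0.75, n_bootstraps,
                                     derive_seed(master_seed, 51, k, rep))
            vals.append(cov_iou(ens).summary_cov)
        out[k] = float(np.mean(vals))
    return out


def variability_vs_timepoints(master_seed: int,
                              timepoints: tuple[int, int] = (600, 2400),
                              n_subjects: int = 4, n_bootstraps: int = 10,
                              n_replicates: int = 5) -> dict[int, float]:
    """Median summary CoV-of-IoU of timepoints bootstraps per series length.

    Longer acquisitions estimate FC more precisely, so resampled replicates
    agree more — the mechanism behind falling variability with data quantity.
    """
    out = {}
    for t in timepoints:
        truth = make_phantom_anatomy(_variability_spec(t))
        seed_mask = truth.seed_mask.data > 0
        vals = []
        for rep in range(n_replicates):
            _, bolds = _cohort_profiles(
                truth, n_subjects, derive_seed(master_seed, 60, t, rep),
                keep_bold=True)
            ens = timepoints_bootstrap(
                bolds, seed_mask, truth.roi_parcels, truth.roiset, k=3,
                n_subjects=n_subjects, n_bootstraps=n_bootstraps,
                master_seed=derive_seed(master_seed, 61, t, rep))
            vals.append(cov_iou(ens).summary_cov)
        out[t] = float(np.median(vals))
    return out
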