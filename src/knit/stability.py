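"""Bootstrap ensembles, voxel-wise uncertainty and model selection.

Two resampling schemes probe the stability of the parcellation:

* subjects bootstraps — each replicate group-averages the Fisher-Z profiles
  of a random 75% of subjects (ceil, without replacement) and re-clusters;
  40 replicates by default.  They feed the consensus (majority vote), the
  per-voxel uncertainty map and the per-k variability curves.
* timepoints bootstraps — a fixed subject subset, each replicate recomputing
  FC from a random order-preserving 75% of timepoints (floor, without
  replacement); 10 replicates by default.  Holding the subject count fixed
  removes the sample-size confound when comparing variability across groups.

Uncertainty is the complement of the majority-label proportion,
U(v) = 1 - N_c*(v)/N_total, zero where every replicate agrees and at most
1 - 1/N_total.  The scalar summary sums U(v) over consensus-cluster voxels
and normalizes by the group's subject count.

Variability is summarized by the coefficient of variation (sd/mean) of the
per-cluster intersection-over-union across all replicate pairs, averaged
over clusters; silhouette scores (cosine metric, matching the clusterer)
complement it for choosing k.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import silhouette_score

from .clustering import Parcellation, knit_cluster, majority_vote, match_labels
from .connectivity import ProfileMap, fisher_z, group_average_profiles, voxel_roi_fc
from .io_formats import BoldSeries, LabelVolume, RoiSet
from .phantom import derive_seed


@dataclass
class ParcellationEnsemble:
    """Ordered, label-matched bootstrap parcellations plus their provenance."""

    members: list[Parcellation]
    scheme: str                      # subjects | timepoints
    fraction: float
    master_seed: int
    k: int
    subsets: list[np.ndarray] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError("ensemble needs at least one member")
        first = self.members[0]
        for m in self.members[1:]:
            if not m.same_mask(first):
                raise ValueError("ensemble members cover different voxel lists")
            if m.k != first.k:
                raise ValueError("ensemble members disagree on k")

    @property
    def n_bootstraps(self) -> int:
        return len(self.members)

    @property
    def voxels(self) -> np.ndarray:
        return self.members[0].voxels

    def label_stack(self) -> np.ndarray:
        return np.stack([m.labels for m in self.members])

    def consensus(self) -> Parcellation:
        return majority_vote(self.members)


@dataclass
class UncertaintyMap:
    """Per-voxel disagreement U(v) in [0, 1 - 1/N_total] plus its summary."""

    voxels: np.ndarray
    u: np.ndarray
    ubar: float
    n_total: int
    n_subjects_norm: int

    def to_volume(self, shape: tuple[int, int, int]) -> np.ndarray:
        vol = np.zeros(shape)
        vol[tuple(self.voxels.T)] = self.u
        return vol


@dataclass
class StabilityResult:
    """Pairwise IoU table and its CoV summaries for one ensemble."""

    pair_iou: pd.DataFrame        # columns: cluster, member_a, member_b, iou
    per_cluster: pd.DataFrame     # columns: cluster, mean_iou, sd_iou, cov, degenerate
    summary_cov: float
    excluded_clusters: tuple[int, ...] = ()
    degenerate: bool = False


# ---------------------------------------------------------------------------
# ensemble construction


def subjects_bootstrap(subject_profiles: Sequence[ProfileMap], k: int,
                       fraction: float = 0.75, n_bootstraps: int = 40,
                       master_seed: int = 0,
                       reference: Parcellation | None = None) -> ParcellationEnsemble:
    """Cluster group-averaged Fisher-Z profiles of resampled subject subsets.

    Each replicate samples ``ceil(fraction * N)`` subjects without
    replacement, averages their profiles, clusters, and is label-matched to
    ``reference`` (default: the first replicate).  Deterministic given
    ``master_seed``.
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    n_subj = len(subject_profiles)
    if n_subj < 2:
        raise ValueError("subjects bootstrap needs at least 2 subjects")
    n_take = math.ceil(fraction * n_subj)
    members: list[Parcellation] = []
    subsets: list[np.ndarray] = []
    for b in range(n_bootstraps):
        rng = np.random.default_rng(derive_seed(master_seed, b, 1))
        subset = np.sort(rng.choice(n_subj, size=n_take, replace=False))
        mean = group_average_profiles([subject_profiles[i] for i in subset])
        parc = knit_cluster(mean, k, seed=derive_seed(master_seed, b, 2))
        parc.provenance.update(bootstrap=b, scheme="subjects",
                               subjects=subset.tolist())
        if reference is None and b == 0:
            reference = parc
        members.append(match_labels(parc, reference) if b or reference is not parc
                       else parc)
        subsets.append(subset)
    return ParcellationEnsemble(members, "subjects", fraction, master_seed, k, subsets)


def timepoints_bootstrap(bolds: Sequence[BoldSeries], seed_mask: np.ndarray,
                         labels: LabelVolume, roiset: RoiSet, k: int,
                         n_subjects: int = 25, fraction: float = 0.75,
                         n_bootstraps: int = 10, master_seed: int = 0,
                         reference: Parcellation | None = None,
                         min_timepoints: int = 30) -> ParcellationEnsemble:
    """Cluster FC recomputed from resampled timepoints of a fixed subject set.

    Timepoints are drawn without replacement and kept in temporal order
    (``floor(fraction * t)`` samples) so the low-pass structure survives;
    the subject subset is fixed once from the master seed.
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    if len(bolds) < n_subjects:
        raise ValueError(f"need {n_subjects} subjects, have {len(bolds)}")
    t = bolds[0].n_timepoints
    n_keep = math.floor(fraction * t)
    if n_keep < min_timepoints:
        raise ValueError(f"{n_keep} resampled timepoints < minimum {min_timepoints}")
    rng = np.random.default_rng(derive_seed(master_seed, 0, 3))
    subj_idx = np.sort(rng.choice(len(bolds), size=n_subjects, replace=False))
    chosen = [bolds[i] for i in subj_idx]

    members: list[Parcellation] = []
    subsets: list[np.ndarray] = []
    for b in range(n_bootstraps):
        rng_b = np.random.default_rng(derive_seed(master_seed, b, 4))
        keep = np.sort(rng_b.choice(t, size=n_keep, replace=False))
        zmaps = []
        for bold in chosen:
            sub = bold.with_data(bold.data[..., keep])
            zmaps.append(fisher_z(voxel_roi_fc(sub, seed_mask, labels, roiset)))
        mean = group_average_profiles(zmaps)
        parc = knit_cluster(mean, k, seed=derive_seed(master_seed, b, 5))
        parc.provenance.update(bootstrap=b, scheme="timepoints",
                               subjects=subj_idx.tolist())
        if reference is None and b == 0:
            reference = parc
        members.append(match_labels(parc, reference) if b or reference is not parc
                       else parc)
        subsets.append(keep)
    return ParcellationEnsemble(members, "timepoints", fraction, master_seed, k,
                                subsets)


# ---------------------------------------------------------------------------
# uncertainty


def uncertainty_map(ensemble: ParcellationEnsemble, consensus: Parcellation,
                    n_subjects_norm: int) -> UncertaintyMap:
    """U(v) = 1 - N_c*(v)/N_total for the consensus (majority) label c*.

    The summary sums U(v) over the voxels of every consensus cluster and
    divides by the group's subject count, making groups of different size
    comparable.
    """
    if not consensus.same_mask(ensemble.members[0]):
        raise ValueError("consensus does not match the ensemble's voxel list")
    stack = ensemble.label_stack()
    n_total = ensemble.n_bootstraps
    agree = (stack == consensus.labels[None, :]).sum(axis=0)
    u = 1.0 - agree / n_total
    in_cluster = consensus.labels > 0
    ubar = float(u[in_cluster].sum() / n_subjects_norm)
    return UncertaintyMap(ensemble.voxels, u, ubar, n_total, n_subjects_norm)


# ---------------------------------------------------------------------------
# variability


def pairwise_iou(a: Parcellation, b: Parcellation, label: int) -> float:
    ma = a.labels == label
    mb = b.labels == label
    union = int((ma | mb).sum())
    if union == 0:
        return np.nan
    return float((ma & mb).sum() / union)


def cov_iou(ensemble: ParcellationEnsemble) -> StabilityResult:
    """CoV (sd/mean) of per-cluster IoU over all unordered replicate pairs.

    Clusters empty in every member are reported and excluded.  With a single
    pair the sd of one value is taken as 0 and the result flagged degenerate
    rather than silently trusted.
    """
    members = ensemble.members
    if len(members) < 2:
        raise ValueError("variability needs at least 2 ensemble members")
    k = ensemble.k
    stack = ensemble.label_stack()
    present = [c for c in range(1, k + 1) if np.any(stack == c)]
    excluded = tuple(c for c in range(1, k + 1) if c not in present)

    rows = []
    for c in present:
        masks = stack == c
        for i in range(len(members)):
            for j in range(i + 1, len(members)):
                inter = int((masks[i] & masks[j]).sum())
                union = int((masks[i] | masks[j]).sum())
                iou = inter / union if union else np.nan
                rows.append({"cluster": c, "member_a": i, "member_b": j, "iou": iou})
    pair_df = pd.DataFrame(rows)

    n_pairs = len(members) * (len(members) - 1) // 2
    degenerate = n_pairs < 2
    per_rows = []
    for c in present:
        vals = pair_df.loc[pair_df.cluster == c, "iou"].dropna().to_numpy()
        mean = float(vals.mean()) if vals.size else np.nan
        sd = float(vals.std(ddof=1)) if vals.size > 1 else 0.0
        if not np.isfinite(mean) or mean == 0:
            cov = np.nan
            deg = True
        else:
            cov = sd / mean
            deg = degenerate
        per_rows.append({"cluster": c, "mean_iou": mean, "sd_iou": sd,
                         "cov": cov, "degenerate": deg})
    per_df = pd.DataFrame(per_rows)
    finite = per_df["cov"].dropna()
    summary = float(finite.mean()) if len(finite) else np.nan
    return StabilityResult(pair_df, per_df, summary, excluded, degenerate)


def silhouette(profiles: ProfileMap, parc: Parcellation) -> float:
    """Mean cosine-metric silhouette over clustered seed voxels."""
    labels = parc.labels
    active = labels > 0
    present = np.unique(labels[active])
    if len(present) < 2:
        raise ValueError("silhouette needs at least 2 nonempty clusters")
    return float(silhouette_score(profiles.values[active], labels[active],
                                  metric="cosine"))


# ---------------------------------------------------------------------------
# model selection


def select_k(subject_profiles: Sequence[ProfileMap],
             k_grid: Sequence[int] = (2, 3, 4, 5, 6, 7),
             fraction: float = 0.75, n_bootstraps: int = 40,
             master_seed: int = 0,
             timepoint_inputs: dict | None = None) -> pd.DataFrame:
    """Per-k variability and silhouette report; ranks, does not decide.

    For each k: subjects-bootstrap summary CoV-of-IoU, silhouette mean +/- sd
    over the replicates' group profiles, and (when ``timepoint_inputs``
    supplies ``bolds``, ``seed_mask``, ``labels``, ``roiset``) the
    timepoints-bootstrap CoV.  The choice of k stays with the analyst.
    """
    rows = []
    for k in k_grid:
        ens = subjects_bootstrap(subject_profiles, k, fraction, n_bootstraps,
                                 derive_seed(master_seed, k, 6))
        stab = cov_iou(ens)
        sils = []
        for b, member in enumerate(ens.members):
            mean = group_average_profiles(
                [subject_profiles[i] for i in ens.subsets[b]])
            sils.append(silhouette(mean, member))
        row = {"k": k, "cov_iou_subjects": stab.summary_cov,
               "silhouette_mean": float(np.mean(sils)),
               "silhouette_sd": float(np.std(sils, ddof=1)) if len(sils) > 1 else 0.0}
        if timepoint_inputs is not None:
            tens = timepoints_bootstrap(
                timepoint_inputs["bolds"], timepoint_inputs["seed_mask"],
                timepoint_inputs["labels"], timepoint_inputs["roiset"], k,
                n_subjects=timepoint_inputs.get("n_subjects", 25),
                fraction=fraction,
                n_bootstraps=timepoint_inputs.get("n_bootstraps", 10),
                master_seed=derive_seed(master_seed, k, 7))
            row["cov_iou_timepoints"] = cov_iou(tens).summary_cov
        rows.append(row)
    return pd.DataFrame(rows)
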