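"""End-to-end orchestration: simulate -> preprocess -> FC -> bootstrap ->
consensus -> uncertainty -> metrics, with a fixed master seed fanned out to
every stage and a manifest that suffices to reconstruct the run.

The driver is built around the synthetic phantom (the packaged way to
exercise the full method); external data can be run by constructing the
profile maps with :mod:`knit.connectivity` and calling the stage functions
directly.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .clustering import (Parcellation, majority_vote, prune_small_components,
                         wta_assign)
from .connectivity import (LobeProfileMap, ProfileMap, fisher_z,
                           group_average_profiles, partial_corr_lobes,
                           voxel_roi_fc)
from .io_formats import LabelVolume, write_lut, write_parcellation
from .metrics import (adjusted_rand_index, cluster_profiles,
                      global_thalamic_connectivity, laterality_indices,
                      relative_volumes, symmetry_index)
from .phantom import (PhantomSpec, PhantomTruth, derive_seed, iter_cohort,
                      cohort_metadata, make_phantom_anatomy)
from .preprocess import preprocess
from .stability import (ParcellationEnsemble, StabilityResult, cov_iou,
                        subjects_bootstrap, uncertainty_map, UncertaintyMap)


@dataclass
class RunConfig:
    """All stage parameters of one reproducible run.

    Defaults are the method's standard settings: discard 5 volumes, 3 mm
    FWHM smoothing, 0.08 Hz low-pass, k = 5 clusters, 40 subjects bootstraps
    at a 75% sampling fraction, 10 timepoints bootstraps over 25 subjects,
    16-voxel component pruning, +/-1 z-score significance.
    """

    master_seed: int = 0
    n_subjects: int = 10
    k: int = 5
    n_discard: int = 5
    fwhm_mm: float = 3.0
    lowpass_hz: float = 0.08
    fraction: float = 0.75
    n_subject_bootstraps: int = 40
    n_timepoint_bootstraps: int = 10
    timepoint_subjects: int = 25
    min_component: int = 16
    z_threshold: float = 1.0
    k_grid: tuple[int, ...] = (2, 3, 4, 5, 6, 7)
    age_groups: tuple[str, ...] = ("grp0",)
    phantom: dict = field(default_factory=dict)   # PhantomSpec overrides

    def __post_init__(self) -> None:
        if self.k < 2:
            raise ValueError("k must be >= 2 for a parcellation run")
        if not 0 < self.fraction <= 1:
            raise ValueError("fraction must be in (0, 1]")
        if self.n_subjects < 2:
            raise ValueError("need at least 2 subjects")

    def phantom_spec(self) -> PhantomSpec:
        kw = dict(self.phantom)
        kw.setdefault("seed", derive_seed(self.master_seed, 0, 10))
        kw.setdefault("k_true", self.k)
        return PhantomSpec(**kw)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "k_grid" in raw:
            raw["k_grid"] = tuple(raw["k_grid"])
        if "age_groups" in raw:
            raw["age_groups"] = tuple(raw["age_groups"])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["k_grid"] = list(self.k_grid)
        d["age_groups"] = list(self.age_groups)
        return d


@dataclass
class StudyResult:
    """Everything one phantom study produced, ready for metrics and export."""

    config: RunConfig
    truth: PhantomTruth
    metadata: pd.DataFrame
    subject_profiles_r: list[ProfileMap]      # pearson scale, per subject
    subject_profiles_z: list[ProfileMap]      # fisher-z, per subject
    subject_lobe_profiles: list[LobeProfileMap]
    knit_ensemble: ParcellationEnsemble
    knit_consensus: Parcellation              # pruned
    wta_members: list[Parcellation]
    wta_consensus: Parcellation               # pruned
    uncertainty: UncertaintyMap
    stability: StabilityResult

    @property
    def interior(self) -> np.ndarray:
        return ~self.truth.border_mask

    def knit_ari(self) -> float:
        """Consensus agreement with the planted truth on border-free voxels."""
        sel = self.interior
        return adjusted_rand_index(self.truth.true_labels[sel],
                                   self.knit_consensus.labels[sel])

    def wta_ari(self) -> float:
        sel = self.interior
        return adjusted_rand_index(self.truth.true_labels[sel],
                                   self.wta_consensus.labels[sel])


def compute_subject_maps(truth: PhantomTruth, cfg: RunConfig,
                         with_lobes: bool = True
                         ) -> tuple[pd.DataFrame, list[ProfileMap],
                                    list[ProfileMap], list[LobeProfileMap]]:
    """Simulate, preprocess and map every subject of the cohort (streaming)."""
    spec = truth.spec
    seed_mask = truth.seed_mask.data > 0
    analysis_mask = seed_mask | (truth.roi_parcels.data > 0)
    meta = cohort_metadata(cfg.n_subjects, derive_seed(cfg.master_seed, 0, 11),
                           cfg.age_groups)
    profiles_r: list[ProfileMap] = []
    profiles_z: list[ProfileMap] = []
    lobes: list[LobeProfileMap] = []
    for bold in iter_cohort(truth, cfg.n_subjects,
                            derive_seed(cfg.master_seed, 0, 11), cfg.age_groups):
        pp = preprocess(bold, cfg.n_discard, cfg.fwhm_mm, cfg.lowpass_hz,
                        mask=analysis_mask)
        prof = voxel_roi_fc(pp, seed_mask, truth.roi_parcels, truth.roiset)
        profiles_r.append(prof)
        profiles_z.append(fisher_z(prof))
        if with_lobes:
            lobes.append(partial_corr_lobes(pp, seed_mask, truth.roi_parcels,
                                            truth.roiset))
    return meta, profiles_r, profiles_z, lobes


def wta_subjects_bootstrap(lobe_profiles: Sequence[LobeProfileMap],
                           fraction: float, n_bootstraps: int,
                           master_seed: int) -> list[Parcellation]:
    """WTA replicates over the same subject subsets as the main bootstrap.

    Subset draws reuse the main scheme's seed derivation, so the KNIT and
    WTA ensembles see identical subject resamples.  Lobe labels carry fixed
    anatomical identity, so no Hungarian matching is needed.
    """
    n_subj = len(lobe_profiles)
    n_take = math.ceil(fraction * n_subj)
    members = []
    for b in range(n_bootstraps):
        rng = np.random.default_rng(derive_seed(master_seed, b, 1))
        subset = np.sort(rng.choice(n_subj, size=n_take, replace=False))
        mean_vals = np.mean([lobe_profiles[i].values for i in subset], axis=0)
        first = lobe_profiles[0]
        mean_map = LobeProfileMap(first.voxels, mean_vals, first.lobes,
                                  shape=first.shape, affine=first.affine)
        parc = wta_assign(mean_map)
        parc.provenance.update(bootstrap=b, subjects=subset.tolist())
        members.append(parc)
    return members


def run_phantom_study(cfg: RunConfig) -> StudyResult:
    """Execute the full method on a synthetic cohort, deterministically."""
    truth = make_phantom_anatomy(cfg.phantom_spec())
    meta, profiles_r, profiles_z, lobe_profiles = compute_subject_maps(truth, cfg)

    ensemble = subjects_bootstrap(profiles_z, cfg.k, cfg.fraction,
                                  cfg.n_subject_bootstraps,
                                  derive_seed(cfg.master_seed, 0, 12))
    consensus = ensemble.consensus()
    unc = uncertainty_map(ensemble, consensus, n_subjects_norm=cfg.n_subjects)
    knit_final = prune_small_components(consensus, cfg.min_component)
    stab = cov_iou(ensemble)

    wta_members = wta_subjects_bootstrap(lobe_profiles, cfg.fraction,
                                         cfg.n_subject_bootstraps,
                                         derive_seed(cfg.master_seed, 0, 12))
    wta_consensus = prune_small_components(majority_vote(wta_members),
                                           cfg.min_component)

    return StudyResult(cfg, truth, meta, profiles_r, profiles_z, lobe_profiles,
                       ensemble, knit_final, wta_members, wta_consensus,
                       unc, stab)


def compare_methods(study: StudyResult) -> pd.DataFrame:
    """Side-by-side KNIT vs WTA summary on one study."""
    truth = study.truth
    rows = []
    for name, parc, ari in (("knit", study.knit_consensus, study.knit_ari()),
                            ("wta", study.wta_consensus, study.wta_ari())):
        labelled = parc.labels[parc.labels > 0]
        fracs = np.bincount(labelled, minlength=parc.k + 1)[1:] / len(labelled)
        rows.append({
            "method": name,
            "symmetry_index": symmetry_index(parc, truth.left_mask,
                                             truth.right_mask),
            "ari_vs_truth_interior": ari,
            "n_clusters_used": int((fracs > 0).sum()),
            "largest_cluster_fraction": float(fracs.max()),
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# persistence


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def write_study(study: StudyResult, out_dir: str | Path) -> Path:
    """Write consensus/uncertainty volumes, metric tables and the manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg = study.config
    truth = study.truth

    write_parcellation(study.knit_consensus.to_label_volume(),
                       out / "consensus_knit.nii.gz")
    write_parcellation(study.wta_consensus.to_label_volume(),
                       out / "consensus_wta.nii.gz")
    write_parcellation(truth.true_parcellation, out / "truth_parcellation.nii.gz")
    unc_vol = study.uncertainty.to_volume(study.knit_consensus.shape)
    import nibabel as nib
    nib.save(nib.Nifti1Image(unc_vol.astype(np.float32),
                             study.knit_consensus.affine),
             str(out / "uncertainty.nii.gz"))
    write_lut(truth.roi_parcels.lut, out / "roi_lut.tsv")
    study.metadata.to_csv(out / "metadata.tsv", sep="\t", index=False)

    member_means = [group_average_profiles(
        [study.subject_profiles_z[i] for i in subset])
        for subset in study.knit_ensemble.subsets]
    cluster_profiles(member_means, study.knit_ensemble.members, truth.roiset,
                     bilateral=True, z_threshold=cfg.z_threshold
                     ).to_csv(out / "cluster_profiles.tsv", sep="\t", index=False)
    relative_volumes(study.knit_ensemble.members).to_csv(
        out / "volumes.tsv", sep="\t", index=False)
    compare_methods(study).to_csv(out / "comparison.tsv", sep="\t", index=False)
    study.stability.per_cluster.to_csv(out / "cov_iou.tsv", sep="\t", index=False)

    pooled = group_average_profiles(study.subject_profiles_r)
    lat = laterality_indices(pooled, truth.left_mask, truth.right_mask,
                             truth.roiset)
    pd.DataFrame([lat]).to_csv(out / "laterality.tsv", sep="\t", index=False)
    global_thalamic_connectivity(study.subject_profiles_r, truth.roiset
                                 ).to_csv(out / "global_fc.tsv", sep="\t",
                                          index=False)

    files = sorted(p.name for p in out.iterdir() if p.name != "manifest.json")
    manifest = {
        "package_version": __version__,
        "config": cfg.to_dict(),
        "summary": {
            "knit_ari_interior": study.knit_ari(),
            "wta_ari_interior": study.wta_ari(),
            "mean_cov_iou": study.stability.summary_cov,
            "normalized_uncertainty": study.uncertainty.ubar,
        },
        "checksums": {name: _sha256(out / name) for name in files},
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return out


def run_pipeline(cfg: RunConfig, out_dir: str | Path) -> Path:
    """Validate, run the phantom study and persist it; returns the run dir."""
    study = run_phantom_study(cfg)
    return write_study(study, out_dir)
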