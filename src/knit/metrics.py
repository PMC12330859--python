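"""Post-hoc cluster characterization and across-group developmental metrics.

All metrics operate on the outputs of the clustering/stability stages:

* cluster connectivity profiles — per ROI, the median FC inside each cluster
  in every subjects-bootstrap replicate, averaged across replicates, then
  z-scored across the ROI axis; |z| > 1 flags significantly (dis)connected
  regions.
* relative cluster volumes — cluster size over seed size, mean +/- sd across
  replicates (rows sum to one per replicate).
* clustering symmetry index — mirror the left-hemisphere labels onto the
  right and count agreements (and vice versa); the average of the two
  agreement rates, 1 for perfect bilateral symmetry, 0 for none.
* ipsi-/contralateral connectivity indices — Ri is mean FC of the right seed
  to right-hemisphere ROIs over mean FC of the left seed to left-hemisphere
  ROIs; Rc pairs the crossed combinations.  Both equal 1 under exact
  hemispheric exchange symmetry.  Signed FC by default (absolute optional).
* global seed connectivity — mean |FC| per ROI over all seed voxels and all
  pooled subjects, bilaterally averaged per ROI pair (no bootstrapping).
* ROI-ROI connectivity — per group, Pearson correlation of ROI-averaged time
  series, averaged over a fixed number of subjects; differences between
  consecutive groups; a global scalar (mean |off-diagonal|).
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .clustering import Parcellation
from .connectivity import ProfileMap, bilateral_merge, roi_mean_series
from .io_formats import BoldSeries, LabelVolume, RoiSet


# ---------------------------------------------------------------------------
# cluster connectivity profiles


def cluster_profiles(member_profiles: Sequence[ProfileMap],
                     member_parcs: Sequence[Parcellation], roiset: RoiSet,
                     bilateral: bool = False,
                     z_threshold: float = 1.0) -> pd.DataFrame:
    """Median-FC connectivity pattern of each cluster, z-scored across ROIs.

    For each ROI the median FC over the cluster's voxels is taken in every
    replicate and averaged across replicates; the resulting per-cluster
    profile is z-scored across the ROI axis and thresholded at +/-1 into
    ``connected`` / ``disconnected`` flags.  ``bilateral`` first averages
    L/R ROI column pairs (the reporting convention for z-score plots).
    """
    if len(member_profiles) != len(member_parcs) or not member_profiles:
        raise ValueError("need one profile map per parcellation member")
    if bilateral:
        member_profiles = [bilateral_merge(p, roiset) for p in member_profiles]
    roi_ids = member_profiles[0].roi_ids
    k = member_parcs[0].k
    per_member = np.full((len(member_parcs), k, len(roi_ids)), np.nan)
    for m, (prof, parc) in enumerate(zip(member_profiles, member_parcs)):
        if len(prof.voxels) != len(parc.labels):
            raise ValueError("profile map and parcellation cover different voxels")
        for c in range(1, k + 1):
            sel = parc.labels == c
            if sel.any():
                per_member[m, c - 1] = np.median(prof.values[sel], axis=0)

    rows = []
    for c in range(1, k + 1):
        vals = per_member[:, c - 1, :]
        ok = ~np.isnan(vals[:, 0])
        if not ok.any():
            raise ValueError(f"cluster {c} is empty in every bootstrap")
        mean_prof = vals[ok].mean(axis=0)
        sd = mean_prof.std()
        if sd == 0:
            raise ValueError(f"cluster {c}: zero variance across ROIs, "
                             "z-score undefined")
        z = (mean_prof - mean_prof.mean()) / sd
        for j, roi in enumerate(roi_ids):
            rows.append({
                "cluster": c, "roi_id": roi,
                "roi_name": roiset.info[roi].name if roi in roiset.info else str(roi),
                "median_fc": mean_prof[j], "z": z[j],
                "connected": bool(z[j] > z_threshold),
                "disconnected": bool(z[j] < -z_threshold),
            })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# volumes


def relative_volumes(member_parcs: Sequence[Parcellation]) -> pd.DataFrame:
    """Cluster volume fractions (of the seed) per replicate: mean and sd.

    Per-replicate fractions are over labelled voxels and sum to one.
    """
    if not member_parcs:
        raise ValueError("no parcellations")
    k = member_parcs[0].k
    fracs = np.zeros((len(member_parcs), k))
    for m, parc in enumerate(member_parcs):
        labelled = parc.labels > 0
        total = int(labelled.sum())
        if total == 0:
            raise ValueError(f"member {m} has no labelled voxels")
        for c in range(1, k + 1):
            fracs[m, c - 1] = (parc.labels == c).sum() / total
    rows = [{"cluster": c + 1,
             "mean": float(fracs[:, c].mean()),
             "sd": float(fracs[:, c].std(ddof=1)) if len(member_parcs) > 1 else 0.0}
            for c in range(k)]
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# symmetry


def mirror_index(shape: tuple[int, int, int], axis: int = 0) -> np.ndarray:
    """Voxel-index reflection across the mid-sagittal grid plane."""
    idx = np.indices(shape)
    idx[axis] = shape[axis] - 1 - idx[axis]
    return idx


def symmetry_index(parc: Parcellation, left_mask: np.ndarray,
                   right_mask: np.ndarray, mirror_axis: int = 0) -> float:
    """Bilateral agreement of cluster labels under mid-sagittal reflection.

    Left labels are mirrored onto the right hemisphere and compared voxel by
    voxel (1 if the same cluster, 0 otherwise), and symmetrically right onto
    left; the two agreement rates are averaged.  Mirrored voxels that land
    outside the opposite seed mask count as disagreement.
    """
    left_mask = np.asarray(left_mask, dtype=bool)
    right_mask = np.asarray(right_mask, dtype=bool)
    if not left_mask.any() or not right_mask.any():
        raise ValueError("empty hemisphere mask")
    vol = parc.to_volume()
    n = parc.shape[mirror_axis]

    def agree(src_mask: np.ndarray, dst_mask: np.ndarray) -> float:
        coords = np.argwhere(src_mask)
        mirrored = coords.copy()
        mirrored[:, mirror_axis] = n - 1 - mirrored[:, mirror_axis]
        inside = dst_mask[tuple(mirrored.T)]
        src_lab = vol[tuple(coords.T)]
        dst_lab = vol[tuple(mirrored.T)]
        same = inside & (src_lab == dst_lab) & (src_lab > 0)
        return float(same.sum() / len(coords))

    return 0.5 * (agree(left_mask, right_mask) + agree(right_mask, left_mask))


# ---------------------------------------------------------------------------
# laterality


def laterality_indices(profiles: ProfileMap, left_mask: np.ndarray,
                       right_mask: np.ndarray, roiset: RoiSet,
                       absolute: bool = False) -> dict[str, float]:
    """Ipsilateral (Ri) and contralateral (Rc) connectivity ratios.

    Ri = mean FC(right seed -> right-hemisphere ROIs)
       / mean FC(left seed -> left-hemisphere ROIs);
    Rc = mean FC(right seed -> left ROIs) / mean FC(left seed -> right ROIs).
    Midline ROIs are excluded.  Signed FC by default.
    """
    left_mask = np.asarray(left_mask, dtype=bool)
    right_mask = np.asarray(right_mask, dtype=bool)
    lin = {tuple(v): i for i, v in enumerate(map(tuple, profiles.voxels))}

    def rows_for(mask: np.ndarray) -> np.ndarray:
        coords = [lin.get(tuple(v)) for v in np.argwhere(mask)]
        if any(c is None for c in coords):
            raise ValueError("hemisphere mask has voxels outside the profile map")
        return np.asarray(coords, dtype=np.intp)

    cols = {h: [profiles.roi_ids.index(i) for i in roiset.hemisphere_ids(h)]
            for h in ("L", "R")}
    if not cols["L"] or not cols["R"]:
        raise ValueError("ROI set lacks lateralized ROIs")
    vals = np.abs(profiles.values) if absolute else profiles.values
    rt, lt = rows_for(right_mask), rows_for(left_mask)

    def block(rows: np.ndarray, hemi: str) -> float:
        return float(vals[np.ix_(rows, cols[hemi])].mean())

    denom_i, denom_c = block(lt, "L"), block(lt, "R")
    if denom_i == 0 or denom_c == 0:
        raise ValueError("zero denominator in laterality index")
    return {"Ri": block(rt, "R") / denom_i, "Rc": block(rt, "L") / denom_c}


# ---------------------------------------------------------------------------
# global seed connectivity


def global_thalamic_connectivity(pooled_profiles: Sequence[ProfileMap],
                                 roiset: RoiSet) -> pd.DataFrame:
    """Mean |FC| per ROI over all voxels of all pooled subjects, L/R averaged.

    Midline ROIs are reported unmerged.  No bootstrapping.
    """
    if not pooled_profiles:
        raise ValueError("no profiles")
    roi_ids = pooled_profiles[0].roi_ids
    stack = np.concatenate([np.abs(p.values) for p in pooled_profiles], axis=0)
    per_roi = stack.mean(axis=0)
    rows = []
    for group in roiset.merged_pairs():
        idx = [roi_ids.index(i) for i in group]
        name = roiset.info[group[0]].name
        if len(group) == 2:
            name = name[:-2] if name.endswith(("_L", "_R")) else name
        rows.append({"roi_ids": group, "name": name,
                     "global_fc": float(per_roi[idx].mean())})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# ROI-ROI connectivity


def roi_roi_connectivity(bolds: Sequence[BoldSeries], labels: LabelVolume,
                         roiset: RoiSet, metadata: pd.DataFrame,
                         n_subjects: int = 25,
                         group_order: Sequence[str] | None = None
                         ) -> tuple[dict[str, np.ndarray],
                                    dict[str, np.ndarray], pd.Series]:
    """Group-mean ROI-ROI correlation matrices and their consecutive changes.

    Per group the first ``n_subjects`` subjects (in metadata order) each
    contribute the correlation matrix of their ROI-averaged time series;
    matrices are averaged across subjects.  Differences are later minus
    earlier for adjacent group keys in the declared order; the global scalar
    is the mean absolute off-diagonal value.
    """
    meta = metadata.reset_index(drop=True)
    if group_order is None:
        group_order = list(dict.fromkeys(meta["age_group"]))
    mats: dict[str, np.ndarray] = {}
    for g in group_order:
        idx = meta.index[meta["age_group"] == g].tolist()
        if len(idx) < n_subjects:
            raise ValueError(f"group {g!r} has {len(idx)} subjects < {n_subjects}")
        acc = np.zeros((roiset.n_rois, roiset.n_rois))
        for i in idx[:n_subjects]:
            series = np.column_stack(
                [roi_mean_series(bolds[i], labels, r) for r in roiset.roi_ids])
            acc += np.corrcoef(series.T)
        mats[g] = acc / n_subjects

    diffs = {f"{b}-{a}": mats[b] - mats[a]
             for a, b in zip(group_order[:-1], group_order[1:])}
    off = ~np.eye(roiset.n_rois, dtype=bool)
    glob = pd.Series({g: float(np.abs(m[off]).mean()) for g, m in mats.items()},
                     name="global_roi_roi_fc")
    return mats, diffs, glob


# ---------------------------------------------------------------------------
# agreement with a reference partition


def adjusted_rand_index(labels_a: np.ndarray, labels_b: np.ndarray) -> float:
    """Chance-corrected agreement between two partitions of the same voxels."""
    from sklearn.metrics import adjusted_rand_score

    return float(adjusted_rand_score(labels_a, labels_b))
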