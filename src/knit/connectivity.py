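"""Voxel-wise functional connectivity profiles.

Seed-voxel FC to an ROI is the *mean of correlations*: the Pearson
correlation between the (z-scored) seed-voxel series and every voxel series
in the ROI, averaged across the ROI.  Because Pearson r between z-scored
series is a scaled dot product, this equals the dot product of the z-scored
seed series with the ROI's mean z-scored series divided by t — the identity
the implementation exploits for speed.  Note this is not the correlation with
the ROI's mean raw series; that alternative order is used only by the ROI-ROI
module, which is defined on averaged time series.

The winner-takes-all baseline instead uses partial correlations between each
seed voxel and the five merged lobe signals, each controlling for the other
four lobes (residualization with intercept).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .io_formats import LOBE_ORDER, BoldSeries, LabelVolume, RoiSet

logger = logging.getLogger(__name__)

#: |r| is clipped here before the Fisher transform so z stays finite on
#: degenerate (perfectly correlated) synthetic inputs
FISHER_CLIP = 1.0 - 1e-7


@dataclass
class ProfileMap:
    """Per seed-voxel FC vector to R ROIs, on the pearson_r or fisher_z scale."""

    voxels: np.ndarray            # (V, 3) int grid indices
    values: np.ndarray            # (V, R)
    roi_ids: tuple[int, ...]
    scale: str = "pearson_r"      # pearson_r | fisher_z
    shape: tuple[int, int, int] | None = None   # analysis grid, if known
    affine: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=np.intp)
        self.values = np.asarray(self.values, dtype=float)
        self.roi_ids = tuple(int(i) for i in self.roi_ids)
        if self.voxels.ndim != 2 or self.voxels.shape[1] != 3:
            raise ValueError("voxels must be (V, 3)")
        if self.values.shape != (len(self.voxels), len(self.roi_ids)):
            raise ValueError(f"values shape {self.values.shape} inconsistent with "
                             f"{len(self.voxels)} voxels x {len(self.roi_ids)} ROIs")
        if self.scale not in ("pearson_r", "fisher_z"):
            raise ValueError(f"unknown scale {self.scale!r}")
        if self.scale == "pearson_r" and self.values.size:
            lo, hi = self.values.min(), self.values.max()
            if lo < -1.0 - 1e-9 or hi > 1.0 + 1e-9:
                raise ValueError(f"pearson_r values outside [-1, 1]: [{lo}, {hi}]")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("non-finite FC values")

    @property
    def n_voxels(self) -> int:
        return len(self.voxels)

    def same_axes(self, other: "ProfileMap") -> bool:
        return (self.roi_ids == other.roi_ids
                and np.array_equal(self.voxels, other.voxels))


@dataclass
class LobeProfileMap:
    """Per seed-voxel partial correlations to the five merged lobes."""

    voxels: np.ndarray
    values: np.ndarray            # (V, 5)
    lobes: tuple[str, ...] = LOBE_ORDER
    shape: tuple[int, int, int] | None = None
    affine: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=np.intp)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.voxels), len(self.lobes)):
            raise ValueError("values shape inconsistent with voxels/lobes")
        if self.values.size and (self.values.min() < -1 - 1e-9
                                 or self.values.max() > 1 + 1e-9):
            raise ValueError("partial correlations outside [-1, 1]")


def _zscore_rows(x: np.ndarray, what: str) -> np.ndarray:
    mean = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, keepdims=True)
    n_flat = int((sd == 0).sum())
    if n_flat:
        raise ValueError(f"{n_flat} zero-variance series in {what}")
    return (x - mean) / sd


def roi_mean_series(bold: BoldSeries, labels: LabelVolume, roi_id: int) -> np.ndarray:
    """Mean raw time series over the ROI's voxels (for ROI-ROI connectivity)."""
    sel = labels.data == int(roi_id)
    if not sel.any():
        raise ValueError(f"ROI {roi_id} is empty")
    return bold.data[sel].mean(axis=0)


def voxel_roi_fc(bold: BoldSeries, seed_mask: np.ndarray, labels: LabelVolume,
                 roiset: RoiSet) -> ProfileMap:
    """FC profile of every seed voxel: mean Pearson r to each ROI's voxels."""
    seed_mask = np.asarray(seed_mask, dtype=bool)
    if not seed_mask.any():
        raise ValueError("seed mask is empty")
    voxels = np.argwhere(seed_mask)
    t = bold.n_timepoints
    z_seed = _zscore_rows(bold.data[seed_mask], "seed mask")
    cols = np.empty((len(voxels), roiset.n_rois))
    for j, roi_id in enumerate(roiset.roi_ids):
        sel = labels.data == roi_id
        if not sel.any():
            raise ValueError(f"ROI {roi_id} is empty")
        z_roi = _zscore_rows(bold.data[sel], f"ROI {roi_id}")
        # mean over ROI voxels u of corr(v, u) == corr of z_v with mean z_u
        cols[:, j] = z_seed @ z_roi.mean(axis=0) / t
    np.clip(cols, -1.0, 1.0, out=cols)
    return ProfileMap(voxels, cols, roiset.roi_ids, "pearson_r",
                      shape=bold.shape, affine=bold.affine)


def fisher_z(profiles: ProfileMap) -> ProfileMap:
    """Variance-stabilize r -> z = arctanh(r); |r| clipped to 1 - 1e-7 first."""
    if profiles.scale != "pearson_r":
        raise ValueError(f"expected pearson_r input, got {profiles.scale}")
    r = profiles.values
    n_clip = int((np.abs(r) > FISHER_CLIP).sum())
    if n_clip:
        logger.info("fisher_z clipped %d near-unit correlations", n_clip)
    z = np.arctanh(np.clip(r, -FISHER_CLIP, FISHER_CLIP))
    return ProfileMap(profiles.voxels, z, profiles.roi_ids, "fisher_z",
                      shape=profiles.shape, affine=profiles.affine)


def group_average_profiles(maps: list[ProfileMap],
                           weights: np.ndarray | None = None) -> ProfileMap:
    """Voxel-wise / ROI-wise (weighted) mean of Fisher-Z profile maps."""
    if not maps:
        raise ValueError("no profile maps to average")
    first = maps[0]
    for m in maps[1:]:
        if m.scale != first.scale:
            raise ValueError("mixed scales in group average")
        if not m.same_axes(first):
            raise ValueError("profile maps have mismatched voxel lists or ROI axes")
    stack = np.stack([m.values for m in maps])
    mean = np.average(stack, axis=0, weights=weights)
    return ProfileMap(first.voxels, mean, first.roi_ids, first.scale,
                      shape=first.shape, affine=first.affine)


def bilateral_merge(profiles: ProfileMap, roiset: RoiSet) -> ProfileMap:
    """Average each L/R ROI column pair; midline columns pass through.

    Merged columns keep the pair's lower ROI id.  Used for reporting
    (z-scored cluster profiles), not for clustering.
    """
    pairs = roiset.merged_pairs()
    cols = np.empty((profiles.n_voxels, len(pairs)))
    ids = []
    for j, group in enumerate(pairs):
        idx = [profiles.roi_ids.index(i) for i in group]
        cols[:, j] = profiles.values[:, idx].mean(axis=1)
        ids.append(group[0])
    return ProfileMap(profiles.voxels, cols, tuple(ids), profiles.scale,
                      shape=profiles.shape, affine=profiles.affine)


def available_lobes(roiset: RoiSet) -> tuple[str, ...]:
    """The merged lobe groups this ROI set populates, in canonical order."""
    groups = roiset.lobe_groups
    return tuple(l for l in LOBE_ORDER if groups[l])


def lobe_mean_series(bold: BoldSeries, labels: LabelVolume, roiset: RoiSet,
                     lobes: tuple[str, ...] | None = None) -> np.ndarray:
    """(t, n_lobes) matrix of merged-lobe mean series.

    ``lobes`` defaults to every lobe group the ROI set populates.
    """
    if lobes is None:
        lobes = available_lobes(roiset)
    if not lobes:
        raise ValueError("ROI set assigns no ROI to any lobe group")
    groups = roiset.lobe_groups
    out = np.empty((bold.n_timepoints, len(lobes)))
    for j, lobe in enumerate(lobes):
        ids = groups.get(lobe, ())
        if not ids:
            raise ValueError(f"lobe group {lobe!r} has no ROIs in this ROI set")
        sel = labels.mask(ids)
        if not sel.any():
            raise ValueError(f"lobe group {lobe!r} is empty in the label volume")
        out[:, j] = bold.data[sel].mean(axis=0)
    return out


def partial_corr_lobes(bold: BoldSeries, seed_mask: np.ndarray,
                       labels: LabelVolume, roiset: RoiSet,
                       lobes: tuple[str, ...] | None = None) -> LobeProfileMap:
    """Partial correlation of each seed voxel with each lobe, controlling the rest.

    For lobe l the voxel series and the lobe-l series are both residualized
    on the other lobes' series (plus intercept); the Pearson correlation of
    the residuals is the partial correlation.
    """
    if lobes is None:
        lobes = available_lobes(roiset)
    seed_mask = np.asarray(seed_mask, dtype=bool)
    voxels = np.argwhere(seed_mask)
    X = bold.data[seed_mask].T                       # (t, V)
    L = lobe_mean_series(bold, labels, roiset, lobes)  # (t, n_lobes)
    t, n_lobes = L.shape
    design_full = np.column_stack([np.ones(t), L])
    if np.linalg.matrix_rank(design_full) < n_lobes + 1:
        raise ValueError("lobe mean series are rank-deficient (collinear lobes)")
    out = np.empty((len(voxels), n_lobes))
    for j in range(n_lobes):
        Z = np.column_stack([np.ones(t), np.delete(L, j, axis=1)])
        coef_x, *_ = np.linalg.lstsq(Z, X, rcond=None)
        rx = X - Z @ coef_x
        coef_l, *_ = np.linalg.lstsq(Z, L[:, j], rcond=None)
        rl = L[:, j] - Z @ coef_l
        denom = np.linalg.norm(rx, axis=0) * np.linalg.norm(rl)
        if np.any(denom == 0):
            raise ValueError("zero-variance residual in partial correlation")
        out[:, j] = (rx.T @ rl) / denom
    np.clip(out, -1.0, 1.0, out=out)
    return LobeProfileMap(voxels, out, lobes, shape=bold.shape, affine=bold.affine)
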