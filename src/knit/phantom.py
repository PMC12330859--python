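"""Synthetic multi-subject BOLD phantoms with planted connectivity structure.

The phantom emulates exactly the statistical structure the parcellation
pipeline consumes: a bilateral seed structure (two hemispheric blobs standing
in for the thalamus) split into ``k_true`` spatially contiguous sub-regions
per hemisphere, surrounded by a ring of disjoint ROI parcels.  Each ROI is
driven by its own independent unit-variance Gaussian source signal; each seed
voxel's series is a nonnegative mixture of the ROI sources whose weights are
the planted connectivity profile of its sub-region, plus i.i.d. Gaussian
noise.  Pearson FC profiles of seed voxels therefore recover the planted
mixing weights (up to normalization), which makes every downstream stage —
FC, clustering, bootstrapping, uncertainty and the developmental metrics —
testable against known ground truth without any data download.

Across true-cluster borders the mixing weights are blended linearly (in
Euclidean distance to the nearest voxel of another sub-region) within
``border_mix_width`` voxels, producing the graded border ambiguity that the
uncertainty machinery is designed to localize.

Sources are white Gaussian by design: the temporal filtering stage is
validated separately on sinusoids, and a common linear filter applied to all
series leaves their correlation structure unchanged, so hemodynamic realism
is deliberately not modelled.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterator, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .io_formats import LOBE_ORDER, BoldSeries, LabelInfo, LabelVolume, RoiSet

SEED_LEFT, SEED_RIGHT = 1, 2

#: minimum voxels per hemispheric sub-region for a spec to count as feasible
MIN_CLUSTER_VOXELS = 30


class InfeasibleSpecError(ValueError):
    """The requested phantom does not fit the requested grid."""


def derive_seed(*entropy: int) -> int:
    """Fixed hash from (master seed, stream index, ...) to a 31-bit seed.

    Uses numpy's SeedSequence mixing so any subject/bootstrap is reproducible
    in isolation from the master seed and its index alone.
    """
    return int(np.random.SeedSequence(entropy).generate_state(1)[0] & 0x7FFFFFFF)


@dataclass
class PhantomSpec:
    """Parameters of a synthetic study.

    ``profile_matrix`` (k_true x n_rois, nonnegative) gives each planted
    sub-region's mixing weights over ROI sources; ``None`` selects the default
    construction: a small baseline weight on every ROI plus a dominant weight
    on one bilateral ROI pair per cluster (requires k_true <= n_rois // 2).
    Rows must be pairwise non-collinear: cosine distance between any two rows
    at least ``min_profile_separation``.
    """

    shape: tuple[int, int, int] = (24, 24, 24)
    n_rois: int = 6
    k_true: int = 3
    profile_matrix: np.ndarray | None = None
    n_timepoints: int = 600
    tr: float = 0.392
    noise_sd: float = 0.5
    border_mix_width: float = 1.0
    symmetry: bool = True
    seed: int = 0
    voxel_size_mm: float = 2.0
    min_profile_separation: float = 0.2
    roi_lobes: tuple[str, ...] | None = None  # lobe per bilateral pair
    roi_source_map: tuple[int, ...] | None = None  # ROI index -> source index

    def __post_init__(self) -> None:
        self.shape = tuple(int(s) for s in self.shape)
        if len(self.shape) != 3 or min(self.shape) < 8:
            raise InfeasibleSpecError(f"grid too small: {self.shape}")
        if self.n_rois < 1:
            raise ValueError("need at least one ROI")
        if self.k_true < 1:
            raise ValueError("k_true must be >= 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.border_mix_width < 0:
            raise ValueError("border_mix_width must be >= 0")
        if self.n_timepoints < 2:
            raise ValueError("need at least 2 timepoints")
        if self.profile_matrix is None:
            self.profile_matrix = default_profile_matrix(self.k_true, self.n_rois)
        self.profile_matrix = np.asarray(self.profile_matrix, dtype=float)
        _validate_profiles(self.profile_matrix, self.k_true, self.n_rois,
                           self.min_profile_separation)
        if self.roi_source_map is not None:
            self.roi_source_map = tuple(int(i) for i in self.roi_source_map)
            if len(self.roi_source_map) != self.n_rois:
                raise ValueError("roi_source_map needs one source per ROI")

    @property
    def affine(self) -> np.ndarray:
        aff = np.eye(4)
        aff[0, 0] = aff[1, 1] = aff[2, 2] = self.voxel_size_mm
        return aff


def default_profile_matrix(k_true: int, n_rois: int, base: float = 0.15) -> np.ndarray:
    """One dominant bilateral ROI pair per cluster over a small common baseline."""
    n_pairs = n_rois // 2
    if k_true > n_pairs:
        raise InfeasibleSpecError(
            f"default profiles support k_true <= n_rois//2 pairs "
            f"({k_true} > {n_pairs}); supply profile_matrix explicitly")
    mat = np.full((k_true, n_rois), base)
    for c in range(k_true):
        mat[c, 2 * c] = 1.0
        mat[c, 2 * c + 1] = 1.0
    return mat


def _validate_profiles(mat: np.ndarray, k_true: int, n_rois: int,
                       min_sep: float) -> None:
    if mat.shape != (k_true, n_rois):
        raise ValueError(f"profile_matrix shape {mat.shape} != ({k_true}, {n_rois})")
    if np.any(mat < 0):
        raise ValueError("profile_matrix must be nonnegative")
    norms = np.linalg.norm(mat, axis=1)
    if np.any(norms == 0):
        raise ValueError("every profile row needs at least one positive weight")
    unit = mat / norms[:, None]
    cos = unit @ unit.T
    for a in range(k_true):
        for b in range(a + 1, k_true):
            if 1.0 - cos[a, b] < min_sep:
                raise ValueError(
                    f"profile rows {a} and {b} nearly collinear "
                    f"(cosine distance {1.0 - cos[a, b]:.3f} < {min_sep})")


@dataclass
class PhantomTruth:
    """Ground truth of one phantom anatomy.

    ``voxel_weights`` holds the per-seed-voxel mixing rows (border-blended);
    ``border_mask`` flags seed voxels inside the blend zone, which recovery
    scores exclude.
    """

    spec: PhantomSpec
    seed_mask: LabelVolume          # 1 = left blob, 2 = right blob
    true_parcellation: LabelVolume  # 1..k_true, bilateral
    roi_parcels: LabelVolume
    roiset: RoiSet
    profile_matrix: np.ndarray
    seed_voxels: np.ndarray         # (V, 3) int
    voxel_weights: np.ndarray       # (V, n_rois)
    border_mask: np.ndarray         # (V,) bool

    @property
    def true_labels(self) -> np.ndarray:
        """Planted sub-region label per seed voxel, aligned with seed_voxels."""
        i, j, k = self.seed_voxels.T
        return self.true_parcellation.data[i, j, k]

    @property
    def left_mask(self) -> np.ndarray:
        return self.seed_mask.data == SEED_LEFT

    @property
    def right_mask(self) -> np.ndarray:
        return self.seed_mask.data == SEED_RIGHT


# ---------------------------------------------------------------------------
# anatomy construction


def _seed_boxes(shape: tuple[int, int, int]) -> tuple[tuple[slice, ...], tuple[slice, ...]]:
    nx, ny, nz = shape
    wx = max(4, nx // 4)
    wy = max(4, ny // 3)
    wz = max(4, nz // 3)
    x_hi = nx // 2 - 2            # leave a 4-voxel midline gap
    x_lo = x_hi - wx
    y0 = (ny - wy) // 2
    z0 = (nz - wz) // 2
    if x_lo < 1:
        raise InfeasibleSpecError(f"grid {shape} too narrow for two seed blobs")
    left = (slice(x_lo, x_hi), slice(y0, y0 + wy), slice(z0, z0 + wz))
    right = (slice(nx - x_hi, nx - x_lo), slice(y0, y0 + wy), slice(z0, z0 + wz))
    return left, right


def _farthest_point_sites(coords: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    """Greedy farthest-point sampling of k site coordinates among coords."""
    sites = [coords[rng.integers(len(coords))]]
    d2 = ((coords - sites[0]) ** 2).sum(axis=1).astype(float)
    for _ in range(1, k):
        nxt = coords[int(np.argmax(d2))]
        sites.append(nxt)
        d2 = np.minimum(d2, ((coords - nxt) ** 2).sum(axis=1))
    return np.asarray(sites)


def _voronoi_labels(coords: np.ndarray, sites: np.ndarray) -> np.ndarray:
    d2 = ((coords[:, None, :] - sites[None, :, :]) ** 2).sum(axis=2)
    return np.argmin(d2, axis=1) + 1


def make_phantom_anatomy(spec: PhantomSpec) -> PhantomTruth:
    """Construct ROI parcels, the bilateral seed structure and its planted split.

    Deterministic given ``spec.seed``.  Raises :class:`InfeasibleSpecError`
    when the grid cannot host two hemispheric blobs of at least
    ``k_true * 30`` voxels plus ``n_rois`` disjoint peripheral parcels.
    """
    nx, ny, nz = spec.shape
    left_box, right_box = _seed_boxes(spec.shape)
    seed = np.zeros(spec.shape, dtype=np.int32)
    seed[left_box] = SEED_LEFT
    seed[right_box] = SEED_RIGHT
    hemi_vox = int((seed == SEED_LEFT).sum())
    if hemi_vox < spec.k_true * MIN_CLUSTER_VOXELS:
        raise InfeasibleSpecError(
            f"hemispheric seed blob has {hemi_vox} voxels < "
            f"{spec.k_true} clusters x {MIN_CLUSTER_VOXELS}")

    rois, roiset = _place_rois(spec, seed)

    # planted split: Voronoi of farthest-point sites inside the (convex) blob,
    # hence contiguous sub-regions; mirrored to the right under symmetry
    rng = np.random.default_rng(derive_seed(spec.seed, 0xA11))
    parc = np.zeros(spec.shape, dtype=np.int32)
    left_coords = np.argwhere(seed == SEED_LEFT)
    for attempt in range(8):
        sites = _farthest_point_sites(left_coords, spec.k_true, rng)
        lab = _voronoi_labels(left_coords, sites)
        sizes = np.bincount(lab, minlength=spec.k_true + 1)[1:]
        if sizes.min() >= max(8, MIN_CLUSTER_VOXELS // 3):
            break
    else:
        raise InfeasibleSpecError("could not place balanced contiguous sub-regions")
    parc[tuple(left_coords.T)] = lab
    right_coords = np.argwhere(seed == SEED_RIGHT)
    if spec.symmetry:
        mirrored = right_coords.copy()
        mirrored[:, 0] = nx - 1 - mirrored[:, 0]
        parc[tuple(right_coords.T)] = parc[tuple(mirrored.T)]
    else:
        sites_r = _farthest_point_sites(right_coords, spec.k_true, rng)
        parc[tuple(right_coords.T)] = _voronoi_labels(right_coords, sites_r)

    seed_voxels = np.argwhere(seed > 0)
    weights, border = _blend_weights(spec, seed, parc, seed_voxels)

    aff = spec.affine
    seed_lut = {SEED_LEFT: LabelInfo("thalamus_L", "L", "none"),
                SEED_RIGHT: LabelInfo("thalamus_R", "R", "none")}
    parc_lut = {c: LabelInfo(f"cluster{c}", "mid", "none")
                for c in range(1, spec.k_true + 1)}
    return PhantomTruth(
        spec=spec,
        seed_mask=LabelVolume(seed, aff, seed_lut),
        true_parcellation=LabelVolume(parc, aff, parc_lut),
        roi_parcels=rois,
        roiset=roiset,
        profile_matrix=spec.profile_matrix.copy(),
        seed_voxels=seed_voxels,
        voxel_weights=weights,
        border_mask=border,
    )


def _place_rois(spec: PhantomSpec, seed: np.ndarray) -> tuple[LabelVolume, RoiSet]:
    nx, ny, nz = spec.shape
    n_pairs, midline = divmod(spec.n_rois, 2)
    lobes = spec.roi_lobes
    if lobes is None:
        lobes = tuple(LOBE_ORDER[j % len(LOBE_ORDER)] for j in range(n_pairs))
    if len(lobes) != n_pairs:
        raise ValueError(f"roi_lobes needs one lobe per pair ({n_pairs})")

    data = np.zeros(spec.shape, dtype=np.int32)
    lut: dict[int, LabelInfo] = {}
    pairs: dict[int, int] = {}
    cy, cz = (ny - 1) / 2.0, (nz - 1) / 2.0
    radius = min(ny, nz) / 2.0 - 2.5
    half = 2
    x_left = slice(2, 2 + 2 * half)
    x_right = slice(nx - 2 - 2 * half, nx - 2)

    def put(box: tuple[slice, slice, slice], label: int) -> None:
        region = data[box]
        if region.size == 0:
            raise InfeasibleSpecError(f"ROI {label} clipped to nothing on grid {spec.shape}")
        if np.any(region != 0) or np.any(seed[box] != 0):
            raise InfeasibleSpecError(
                f"ROI {label} overlaps existing structure; grid {spec.shape} "
                f"too small for {spec.n_rois} ROIs")
        data[box] = label

    for j in range(n_pairs):
        theta = 2.0 * math.pi * j / max(n_pairs, 1)
        yc = cy + radius * math.cos(theta)
        zc = cz + radius * math.sin(theta)
        y_sl = slice(max(1, int(round(yc)) - half), min(ny - 1, int(round(yc)) + half))
        z_sl = slice(max(1, int(round(zc)) - half), min(nz - 1, int(round(zc)) + half))
        lid, rid = 2 * j + 1, 2 * j + 2
        put((x_left, y_sl, z_sl), lid)
        put((x_right, y_sl, z_sl), rid)
        lut[lid] = LabelInfo(f"roi{j + 1:02d}_L", "L", lobes[j])
        lut[rid] = LabelInfo(f"roi{j + 1:02d}_R", "R", lobes[j])
        pairs[lid] = rid
        pairs[rid] = lid
    if midline:
        mid = spec.n_rois
        box = (slice(nx // 2 - half, nx // 2 + half),
               slice(int(cy) - half, int(cy) + half), slice(1, 1 + 2 * half))
        put(box, mid)
        lut[mid] = LabelInfo(f"roi{n_pairs + 1:02d}_mid", "mid", "none")

    roiset = RoiSet(roi_ids=tuple(range(1, spec.n_rois + 1)), info=lut,
                    bilateral_pairs=pairs)
    return LabelVolume(data, spec.affine, lut), roiset


def _blend_weights(spec: PhantomSpec, seed: np.ndarray, parc: np.ndarray,
                   seed_voxels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-voxel mixing rows, linearly blended near sub-region borders.

    A voxel at Euclidean distance d (voxels) from the nearest voxel of a
    different sub-region in the same hemisphere mixes a fraction
    m = 0.5 * max(0, 1 - (d - 1)/w) of that neighbour's profile into its own
    (w = border_mix_width): 50/50 right at the border face, pure profile at
    depth w + 1 and beyond.
    """
    V = len(seed_voxels)
    R = spec.n_rois
    P = spec.profile_matrix
    idx = tuple(seed_voxels.T)
    own = parc[idx]
    weights = P[own - 1].astype(float).copy()
    border = np.zeros(V, dtype=bool)
    w = spec.border_mix_width
    if w <= 0 or spec.k_true == 1:
        return weights, border

    # distance (and identity) of the nearest other-cluster voxel, per cluster
    dist = np.full(V, np.inf)
    other = np.zeros(V, dtype=np.int32)
    for c in range(1, spec.k_true + 1):
        sel = own == c
        if not sel.any():
            continue
        other_mask = (seed > 0) & (parc != c)
        d_map, (ix, iy, iz) = ndimage.distance_transform_edt(
            ~other_mask, return_indices=True)
        vox = seed_voxels[sel]
        d = d_map[tuple(vox.T)]
        nearest = parc[ix[tuple(vox.T)], iy[tuple(vox.T)], iz[tuple(vox.T)]]
        dist[sel] = d
        other[sel] = nearest
    m = 0.5 * np.clip(1.0 - (dist - 1.0) / w, 0.0, 1.0)
    border = m > 0
    weights[border] = ((1.0 - m[border, None]) * weights[border]
                       + m[border, None] * P[other[border] - 1])
    return weights, border


# ---------------------------------------------------------------------------
# signal simulation


def simulate_subject(truth: PhantomTruth, spec: PhantomSpec | None = None,
                     subject_seed: int = 0, subject_id: str = "",
                     age_group: str = "") -> BoldSeries:
    """Simulate one subject's 4D BOLD series from the planted truth.

    ROI sources are independent unit-variance Gaussian series (two ROIs can
    be made to share one source via ``spec.roi_source_map``); each ROI voxel
    carries its source plus noise, each seed voxel the weighted source mixture
    of its (border-blended) profile plus noise, and background voxels unit
    Gaussian noise.  Deterministic given ``subject_seed``.
    """
    spec = spec or truth.spec
    rng = np.random.default_rng(subject_seed)
    t, R = spec.n_timepoints, spec.n_rois
    src_of = spec.roi_source_map or tuple(range(R))
    sources = rng.standard_normal((t, max(src_of) + 1))[:, src_of]  # (t, R)
    data = rng.standard_normal(spec.shape + (t,))

    roi_data = truth.roi_parcels.data
    for r_idx, roi_id in enumerate(truth.roiset.roi_ids):
        sel = roi_data == roi_id
        data[sel] = sources[:, r_idx] + spec.noise_sd * data[sel]

    idx = tuple(truth.seed_voxels.T)
    signal = truth.voxel_weights @ sources.T  # (V, t)
    data[idx] = signal + spec.noise_sd * data[idx]
    return BoldSeries(data, tr=spec.tr, affine=spec.affine,
                      subject_id=subject_id, age_group=age_group)


def iter_cohort(truth: PhantomTruth, n_subjects: int, cohort_seed: int,
                age_groups: Sequence[str] = ("grp0",),
                spec: PhantomSpec | None = None) -> Iterator[BoldSeries]:
    """Lazily yield the cohort's subjects (memory-friendly for large t)."""
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    meta = cohort_metadata(n_subjects, cohort_seed, age_groups)
    for _, row in meta.iterrows():
        yield simulate_subject(truth, spec, subject_seed=int(row["subject_seed"]),
                               subject_id=row["subject_id"],
                               age_group=row["age_group"])


def cohort_metadata(n_subjects: int, cohort_seed: int,
                    age_groups: Sequence[str] = ("grp0",)) -> pd.DataFrame:
    """Deterministic cohort table: subject_id, age_group, per-subject seed.

    Subjects are split over ``age_groups`` in declared order, as evenly as
    possible (earlier groups take the remainder).
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    groups = list(age_groups)
    base, extra = divmod(n_subjects, len(groups))
    assignment: list[str] = []
    for gi, g in enumerate(groups):
        assignment.extend([g] * (base + (1 if gi < extra else 0)))
    rows = [{"subject_id": f"sub-{i:03d}", "age_group": assignment[i],
             "subject_seed": derive_seed(cohort_seed, i)}
            for i in range(n_subjects)]
    return pd.DataFrame(rows)


def simulate_cohort(truth: PhantomTruth, n_subjects: int, cohort_seed: int,
                    age_groups: Sequence[str] = ("grp0",),
                    spec: PhantomSpec | None = None
                    ) -> tuple[list[BoldSeries], pd.DataFrame]:
    """Simulate ``n_subjects`` independent subjects plus their metadata table."""
    meta = cohort_metadata(n_subjects, cohort_seed, age_groups)
    bolds = list(iter_cohort(truth, n_subjects, cohort_seed, age_groups, spec))
    return bolds, meta.drop(columns=["subject_seed"])
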