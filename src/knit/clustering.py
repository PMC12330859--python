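"""Connectivity-profile clustering of the seed structure.

The main parcellation route clusters each seed voxel's R-dimensional FC
profile with k-means under cosine distance, realized as spherical k-means:
rows are unit-normalized, centroids are renormalized means, assignment
maximizes the dot product.  Scale information is deliberately ignored — two
voxels with proportional profiles connect to the same places and belong
together regardless of overall FC strength.

The winner-takes-all baseline instead assigns each voxel to the merged lobe
with the largest partial correlation.

Bootstrap replicates are aligned by solving the linear assignment problem on
negative label-overlap counts (Hungarian algorithm), combined by per-voxel
majority vote, and finally cleaned by absorbing small connected components
that are enclosed by a dominant neighbouring cluster.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage
from scipy.optimize import linear_sum_assignment
from sklearn.cluster import kmeans_plusplus

from .connectivity import LobeProfileMap, ProfileMap
from .io_formats import LabelInfo, LabelVolume


@dataclass
class Parcellation:
    """Cluster labels over the seed-voxel list.

    Labels are 1..k; 0 marks unassigned voxels (zero-norm profiles before
    consensus).  ``provenance`` records method, seeds and vote counts.
    """

    voxels: np.ndarray          # (V, 3)
    labels: np.ndarray          # (V,)
    k: int
    shape: tuple[int, int, int]
    affine: np.ndarray
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=np.intp)
        self.labels = np.asarray(self.labels, dtype=np.int32)
        if self.labels.shape != (len(self.voxels),):
            raise ValueError("labels must align with voxel list")
        if self.labels.min(initial=0) < 0 or self.labels.max(initial=0) > self.k:
            raise ValueError(f"labels outside 0..k={self.k}")
        self.shape = tuple(int(s) for s in self.shape)

    @property
    def n_voxels(self) -> int:
        return len(self.voxels)

    def same_mask(self, other: "Parcellation") -> bool:
        return np.array_equal(self.voxels, other.voxels)

    def to_volume(self) -> np.ndarray:
        vol = np.zeros(self.shape, dtype=np.int32)
        vol[tuple(self.voxels.T)] = self.labels
        return vol

    def to_label_volume(self, names: dict[int, str] | None = None) -> LabelVolume:
        lut = {c: LabelInfo((names or {}).get(c, f"cluster{c}"), "mid", "none")
               for c in range(1, self.k + 1) if np.any(self.labels == c)}
        return LabelVolume(self.to_volume(), self.affine, lut)

    def replace_labels(self, labels: np.ndarray, **prov) -> "Parcellation":
        return Parcellation(self.voxels, labels, self.k, self.shape, self.affine,
                            {**self.provenance, **prov})


def parcellation_from_volume(volume: np.ndarray, seed_mask: np.ndarray,
                             k: int, affine: np.ndarray, **prov) -> Parcellation:
    voxels = np.argwhere(np.asarray(seed_mask, dtype=bool))
    labels = np.asarray(volume)[tuple(voxels.T)]
    return Parcellation(voxels, labels, k, np.asarray(volume).shape, affine, prov)


def _geometry_of(profiles) -> tuple[tuple[int, int, int], np.ndarray]:
    """Grid shape/affine from a profile map, with a minimal fallback."""
    shape = getattr(profiles, "shape", None)
    affine = getattr(profiles, "affine", None)
    if shape is None:
        shape = tuple(np.asarray(profiles.voxels).max(axis=0) + 1) \
            if len(profiles.voxels) else (1, 1, 1)
    if affine is None:
        affine = np.eye(4)
    return tuple(int(s) for s in shape), np.asarray(affine, dtype=float)


# ---------------------------------------------------------------------------
# spherical k-means


def _spherical_kmeans_once(X: np.ndarray, k: int, rng_seed: int,
                           max_iter: int, tol: float) -> tuple[np.ndarray, np.ndarray, float]:
    """One spherical k-means run; returns (labels0, centers, objective).

    X must be unit-normalized rows.  The objective sum(1 - cos) is
    non-increasing across Lloyd iterations; empty clusters are reseeded at
    the worst-fit point.
    """
    centers, _ = kmeans_plusplus(X, n_clusters=k, random_state=rng_seed)
    norms = np.linalg.norm(centers, axis=1, keepdims=True)
    centers = centers / np.where(norms == 0, 1.0, norms)
    prev_obj = np.inf
    labels = np.zeros(len(X), dtype=np.intp)
    for _ in range(max_iter):
        sims = X @ centers.T
        labels = np.argmax(sims, axis=1)
        best = sims[np.arange(len(X)), labels]
        for c in range(k):
            if not np.any(labels == c):   # reseed empty cluster
                worst = int(np.argmin(best))
                labels[worst] = c
                best[worst] = 1.0
        obj = float(np.sum(1.0 - best))
        new_centers = np.zeros_like(centers)
        for c in range(k):
            m = X[labels == c].mean(axis=0)
            n = np.linalg.norm(m)
            new_centers[c] = m / n if n > 0 else centers[c]
        centers = new_centers
        if prev_obj - obj < tol:
            break
        prev_obj = obj
    sims = X @ centers.T
    labels = np.argmax(sims, axis=1)
    obj = float(np.sum(1.0 - sims[np.arange(len(X)), labels]))
    return labels, centers, obj


def knit_cluster(profiles: ProfileMap, k: int, seed: int, n_init: int = 10,
                 max_iter: int = 300, tol: float = 1e-6) -> Parcellation:
    """Cluster FC profiles with cosine k-means (spherical k-means).

    Zero-norm profile rows are pre-assigned label 0 and excluded from the
    fit.  Deterministic given ``seed``; the best of ``n_init`` k-means++
    initializations by the cosine-distance objective is kept.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    X = profiles.values
    norms = np.linalg.norm(X, axis=1)
    active = norms > 0
    Xn = X[active] / norms[active, None]
    if k > len(Xn):
        raise ValueError(f"k={k} exceeds {len(Xn)} clusterable voxels")
    n_distinct = len(np.unique(np.round(Xn, 9), axis=0))
    if k > n_distinct:
        raise ValueError(f"k={k} exceeds {n_distinct} distinct profile directions")

    if k == 1:
        best_labels = np.zeros(len(Xn), dtype=np.intp)
    else:
        ss = np.random.SeedSequence(seed)
        init_seeds = [int(s) for s in ss.generate_state(n_init) & 0x7FFFFFFF]
        best_obj = np.inf
        best_labels = None
        for s in init_seeds:
            labels, _, obj = _spherical_kmeans_once(Xn, k, s, max_iter, tol)
            if obj < best_obj - 1e-12:
                best_obj = obj
                best_labels = labels

    out = np.zeros(profiles.n_voxels, dtype=np.int32)
    out[active] = best_labels + 1
    shape, affine = _geometry_of(profiles)
    return Parcellation(profiles.voxels, out, k, shape, affine,
                        {"method": "knit", "seed": int(seed)})


def with_geometry(parc: Parcellation, shape: tuple[int, int, int],
                  affine: np.ndarray) -> Parcellation:
    """Attach the analysis grid's shape/affine to a parcellation."""
    return Parcellation(parc.voxels, parc.labels, parc.k, shape, affine,
                        parc.provenance)


# ---------------------------------------------------------------------------
# winner-takes-all baseline


def wta_assign(lobe_profiles: LobeProfileMap) -> Parcellation:
    """Assign each voxel to the lobe with maximal partial correlation.

    Ties resolve to the earliest lobe in the axis order (temporal first).
    """
    values = lobe_profiles.values
    if not np.all(np.isfinite(values)):
        raise ValueError("non-finite lobe profiles")
    labels = np.argmax(values, axis=1).astype(np.int32) + 1
    shape, affine = _geometry_of(lobe_profiles)
    return Parcellation(lobe_profiles.voxels, labels, values.shape[1], shape,
                        affine, {"method": "wta",
                                 "lobes": tuple(lobe_profiles.lobes)})


# ---------------------------------------------------------------------------
# label alignment and consensus


def overlap_matrix(parc: Parcellation, reference: Parcellation) -> np.ndarray:
    """(k_ref, k_parc) voxel-overlap counts between nonzero labels."""
    k = max(parc.k, reference.k)
    counts = np.zeros((k, k), dtype=np.int64)
    both = (parc.labels > 0) & (reference.labels > 0)
    np.add.at(counts, (reference.labels[both] - 1, parc.labels[both] - 1), 1)
    return counts


def match_labels(parc: Parcellation, reference: Parcellation) -> Parcellation:
    """Permute ``parc``'s labels to maximize voxel overlap with ``reference``.

    Solved exactly as a linear assignment problem with cost = -overlap
    (Hungarian formulation); labels of ``parc`` that are empty map to
    whatever reference labels remain (zero-cost padding).
    """
    if not parc.same_mask(reference):
        raise ValueError("parcellation and reference cover different voxel lists")
    counts = overlap_matrix(parc, reference)
    ref_idx, parc_idx = linear_sum_assignment(-counts)
    mapping = np.zeros(counts.shape[1] + 1, dtype=np.int32)
    for r, p in zip(ref_idx, parc_idx):
        mapping[p + 1] = r + 1
    new_labels = mapping[parc.labels]
    new_labels[parc.labels == 0] = 0
    return parc.replace_labels(new_labels, matched_to=reference.provenance.get("method"))


def majority_vote(members: Sequence[Parcellation]) -> Parcellation:
    """Per-voxel most frequent label across label-matched members.

    Ties resolve to the smallest label id; vote counts are kept in provenance
    for the uncertainty map.  Voxels unassigned in every member stay 0.
    """
    members = list(members)
    if not members:
        raise ValueError("empty ensemble")
    first = members[0]
    k = max(m.k for m in members)
    for m in members[1:]:
        if not m.same_mask(first):
            raise ValueError("ensemble members cover different voxel lists")
    stack = np.stack([m.labels for m in members])          # (M, V)
    counts = np.stack([(stack == c).sum(axis=0) for c in range(1, k + 1)])  # (k, V)
    majority = np.argmax(counts, axis=0).astype(np.int32) + 1
    majority[counts.sum(axis=0) == 0] = 0
    return Parcellation(first.voxels, majority, k, first.shape, first.affine,
                        {"method": "consensus", "n_members": len(members),
                         "vote_counts": counts})


# ---------------------------------------------------------------------------
# small-component pruning

_STRUCT_26 = np.ones((3, 3, 3), dtype=bool)
_STRUCT_6 = ndimage.generate_binary_structure(3, 1)


def prune_small_components(parc: Parcellation, min_size: int = 16,
                           surround_fraction: float = 0.5,
                           component_connectivity: int = 26) -> Parcellation:
    """Absorb small enclosed components into their dominant neighbour.

    Connected components (26-connectivity by default) with fewer than
    ``min_size`` voxels are relabelled to the dominant label among their
    face-adjacent outside neighbours when that label holds more than
    ``surround_fraction`` of them.  Neighbours outside the seed mask count in
    the denominator but can never dominate, so components at the structure
    boundary are left alone.  Run to a fixed point, so the operation is
    idempotent; it never introduces labels absent from the input.
    """
    struct = _STRUCT_26 if component_connectivity == 26 else _STRUCT_6
    vol = parc.to_volume()
    mask = np.zeros(parc.shape, dtype=bool)
    mask[tuple(parc.voxels.T)] = True

    for _ in range(100):  # fixed-point loop; terminates (label count shrinks)
        changed = False
        for label in np.unique(vol[mask]):
            if label == 0:
                continue
            comp, n_comp = ndimage.label(vol == label, structure=struct)
            for ci in range(1, n_comp + 1):
                sel = comp == ci
                if int(sel.sum()) >= min_size:
                    continue
                ring = ndimage.binary_dilation(sel, structure=_STRUCT_6) & ~sel
                neigh = vol[ring & mask]
                neigh = neigh[neigh != label]
                if neigh.size == 0:
                    continue
                ids, freq = np.unique(neigh, return_counts=True)
                top = int(np.argmax(freq))
                if freq[top] / ring.sum() > surround_fraction and ids[top] != 0:
                    vol[sel] = ids[top]
                    changed = True
        if not changed:
            break

    new_labels = vol[tuple(parc.voxels.T)]
    return parc.replace_labels(new_labels, pruned_min_size=min_size)
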