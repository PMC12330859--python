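"""Volume, label-table and ROI-configuration I/O.

All spatial data live on a single voxel grid shared by every volume of an
analysis: a 4D BOLD series per subject, a 3D integer label volume holding the
ROI parcels and the seed-structure (thalamus) mask, and parcellation outputs.
Volumes are exchanged as NIfTI-1 (``.nii``/``.nii.gz``); label lookup tables
as 4-column TSV (``id  name  hemisphere  lobe``); the ROI set (the ordered
profile axis, bilateral pairs and lobe groups) as YAML.

Spatial registration is deliberately out of scope: every volume entering an
analysis must already share one grid shape and affine (checked to 1e-4,
mismatches are hard errors).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, NamedTuple, Sequence

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)

#: hemisphere codes; midline structures are "mid" and never bilaterally merged
HEMISPHERES = ("L", "R", "mid")

#: the five merged lobe groups used by the winner-takes-all baseline, in the
#: fixed axis order used everywhere (ties in WTA resolve to the earliest)
LOBE_ORDER = ("temporal", "parietal", "frontal", "occipital", "limbic")

#: valid lobe assignments; "none" marks ROIs outside the five WTA groups
LOBE_GROUPS = LOBE_ORDER + ("none",)

GRID_ATOL = 1e-4


class GridMismatchError(ValueError):
    """Two volumes of one analysis do not share shape/affine."""


class LabelInfo(NamedTuple):
    name: str
    hemisphere: str  # L | R | mid
    lobe: str        # temporal | parietal | frontal | occipital | limbic | none


def _check_affine(affine: np.ndarray) -> np.ndarray:
    affine = np.asarray(affine, dtype=float)
    if affine.shape != (4, 4):
        raise ValueError(f"affine must be 4x4, got {affine.shape}")
    return affine


@dataclass
class BoldSeries:
    """One subject's 4D BOLD acquisition on the common grid.

    Parameters
    ----------
    data
        ``(x, y, z, t)`` array; stored as float64 regardless of file dtype.
    tr
        Repetition time in seconds (> 0).
    affine
        4x4 grid-to-world mapping (NIfTI convention).
    subject_id, age_group
        Cohort bookkeeping carried through the pipeline.
    """

    data: np.ndarray
    tr: float
    affine: np.ndarray
    subject_id: str = ""
    age_group: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 4:
            raise ValueError(f"BOLD volume is not 4D (got {self.data.ndim}D)")
        if self.data.shape[3] < 2:
            raise ValueError(f"need at least 2 timepoints, got {self.data.shape[3]}")
        if not self.tr > 0:
            raise ValueError(f"tr must be positive, got {self.tr}")
        n_bad = int(np.size(self.data) - np.isfinite(self.data).sum())
        if n_bad:
            raise ValueError(f"BOLD volume contains {n_bad} non-finite voxel values")
        self.affine = _check_affine(self.affine)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape[:3]

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[3]

    def voxel_sizes(self) -> np.ndarray:
        """Voxel edge lengths in mm per spatial axis, from the affine."""
        return np.sqrt((self.affine[:3, :3] ** 2).sum(axis=0))

    def with_data(self, data: np.ndarray) -> "BoldSeries":
        return BoldSeries(data, self.tr, self.affine, self.subject_id, self.age_group)


@dataclass
class LabelVolume:
    """3D non-negative integer labels with a lookup table.

    Label 0 is reserved for background; every nonzero label present in
    ``data`` must appear in ``lut``.
    """

    data: np.ndarray
    affine: np.ndarray
    lut: dict[int, LabelInfo] = field(default_factory=dict)

    def __post_init__(self) -> None:
        data = np.asarray(self.data)
        if data.ndim != 3:
            raise ValueError(f"label volume is not 3D (got {data.ndim}D)")
        if not np.issubdtype(data.dtype, np.integer):
            if not np.all(np.isfinite(data)) or not np.all(data == np.round(data)):
                raise ValueError("label volume has non-integer values")
            data = np.round(data).astype(np.int32)
        if data.min() < 0:
            raise ValueError("label volume has negative labels")
        self.data = data.astype(np.int32, copy=False)
        self.affine = _check_affine(self.affine)
        self.lut = {int(k): LabelInfo(*v) for k, v in self.lut.items()}
        present = set(int(v) for v in np.unique(self.data)) - {0}
        missing = sorted(present - set(self.lut))
        if missing:
            raise ValueError(f"labels present in volume but missing from lut: {missing}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def mask(self, label_ids: Iterable[int] | None = None) -> np.ndarray:
        """Boolean mask of the given labels (default: all nonzero)."""
        if label_ids is None:
            return self.data > 0
        return np.isin(self.data, np.fromiter((int(i) for i in label_ids), dtype=np.int32))


@dataclass
class RoiSet:
    """Ordered ROI axis, bilateral pairing and lobe grouping.

    The ROI order is the profile axis and is fixed: connectivity profiles,
    configs and TSV outputs all follow it.  ``bilateral_pairs`` maps each
    lateral ROI to its contralateral partner (both directions); midline ROIs
    are absent from it.  ``lobe_groups`` partitions the ROIs assigned to one
    of the five lobe groups (ROIs with lobe "none" belong to no group).
    """

    roi_ids: tuple[int, ...]
    info: dict[int, LabelInfo]
    bilateral_pairs: dict[int, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.roi_ids = tuple(int(i) for i in self.roi_ids)
        if len(set(self.roi_ids)) != len(self.roi_ids):
            raise ValueError("duplicate ROI ids in config")
        self.info = {int(k): LabelInfo(*v) for k, v in self.info.items()}
        missing = [i for i in self.roi_ids if i not in self.info]
        if missing:
            raise ValueError(f"ROI ids without metadata: {missing}")
        for i, entry in self.info.items():
            if entry.hemisphere not in HEMISPHERES:
                raise ValueError(f"ROI {i}: bad hemisphere {entry.hemisphere!r}")
            if entry.lobe not in LOBE_GROUPS:
                raise ValueError(f"ROI {i}: bad lobe group {entry.lobe!r}")
        self.bilateral_pairs = {int(a): int(b) for a, b in self.bilateral_pairs.items()}
        for a, b in self.bilateral_pairs.items():
            if self.bilateral_pairs.get(b) != a:
                raise ValueError(f"asymmetric bilateral pair: {a}->{b} but {b}->"
                                 f"{self.bilateral_pairs.get(b)}")
            if a not in self.roi_ids or b not in self.roi_ids:
                raise ValueError(f"bilateral pair ({a},{b}) references unknown ROI")
            if {self.info[a].hemisphere, self.info[b].hemisphere} != {"L", "R"}:
                raise ValueError(f"bilateral pair ({a},{b}) must join one L and one R ROI")

    def __len__(self) -> int:
        return len(self.roi_ids)

    @property
    def n_rois(self) -> int:
        return len(self.roi_ids)

    def index_of(self, roi_id: int) -> int:
        return self.roi_ids.index(int(roi_id))

    @property
    def lobe_groups(self) -> dict[str, tuple[int, ...]]:
        groups: dict[str, list[int]] = {lobe: [] for lobe in LOBE_ORDER}
        for i in self.roi_ids:
            lobe = self.info[i].lobe
            if lobe != "none":
                groups[lobe].append(i)
        return {lobe: tuple(ids) for lobe, ids in groups.items()}

    def hemisphere_ids(self, hemisphere: str) -> tuple[int, ...]:
        return tuple(i for i in self.roi_ids if self.info[i].hemisphere == hemisphere)

    def merged_pairs(self) -> list[tuple[int, ...]]:
        """L/R pairs plus singleton midline ROIs, in profile-axis order."""
        out: list[tuple[int, ...]] = []
        seen: set[int] = set()
        for i in self.roi_ids:
            if i in seen:
                continue
            j = self.bilateral_pairs.get(i)
            if j is None:
                out.append((i,))
                seen.add(i)
            else:
                out.append(tuple(sorted((i, j))))
                seen.update((i, j))
        return out


# ---------------------------------------------------------------------------
# grid compatibility


def assert_same_grid(a, b, atol: float = GRID_ATOL) -> None:
    """Raise :class:`GridMismatchError` unless a and b share shape and affine."""
    if a.shape[:3] != b.shape[:3]:
        raise GridMismatchError(f"grid shape mismatch: {a.shape[:3]} vs {b.shape[:3]}")
    if not np.allclose(a.affine, b.affine, atol=atol):
        raise GridMismatchError("affine mismatch beyond tolerance "
                                f"{atol}:\n{a.affine}\nvs\n{b.affine}")


# ---------------------------------------------------------------------------
# NIfTI readers / writers


def read_bold(path: str | Path, tr: float | None = None,
              subject_id: str = "", age_group: str = "") -> BoldSeries:
    """Load a 4D BOLD NIfTI.

    ``tr`` overrides the header pixdim[4] (pass it when headers are untrusted);
    if omitted it is taken from the header.  Fails loudly on non-4D files and
    on any non-finite voxel.
    """
    img = nib.load(str(path))
    data = np.asarray(img.get_fdata(dtype=np.float64))
    if data.ndim != 4:
        raise ValueError(f"{path}: not 4D (got {data.ndim}D)")
    if tr is None:
        tr = float(img.header.get_zooms()[3])
    return BoldSeries(data, tr=float(tr), affine=img.affine,
                      subject_id=subject_id, age_group=age_group)


def write_bold(bold: BoldSeries, path: str | Path) -> None:
    """Write a BOLD series as float32 NIfTI with tr in the header."""
    img = nib.Nifti1Image(bold.data.astype(np.float32), bold.affine)
    zooms = img.header.get_zooms()
    img.header.set_zooms(zooms[:3] + (bold.tr,))
    nib.save(img, str(path))


def read_lut(path: str | Path) -> dict[int, LabelInfo]:
    """Read a 4-column TSV lookup table (id, name, hemisphere, lobe)."""
    table = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    required = ["id", "name", "hemisphere", "lobe"]
    missing = [c for c in required if c not in table.columns]
    if missing:
        raise ValueError(f"{path}: lut missing columns {missing}")
    lut: dict[int, LabelInfo] = {}
    for _, row in table.iterrows():
        lut[int(row["id"])] = LabelInfo(str(row["name"]), str(row["hemisphere"]),
                                        str(row["lobe"]))
    return lut


def write_lut(lut: Mapping[int, LabelInfo], path: str | Path) -> None:
    rows = [{"id": i, "name": e.name, "hemisphere": e.hemisphere, "lobe": e.lobe}
            for i, e in sorted(lut.items())]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_labels(nifti_path: str | Path, lut_path: str | Path) -> LabelVolume:
    """Load an integer label volume and validate it against its TSV lut.

    Float-valued volumes are accepted when every value sits exactly on an
    integer (common after lossless resampling); anything else is an error.
    """
    img = nib.load(str(nifti_path))
    data = np.asarray(img.get_fdata(dtype=np.float64))
    if data.ndim != 3:
        raise ValueError(f"{nifti_path}: label volume is not 3D (got {data.ndim}D)")
    return LabelVolume(data, affine=img.affine, lut=read_lut(lut_path))


def write_parcellation(parc: LabelVolume, path: str | Path,
                       lut_path: str | Path | None = None) -> None:
    """Write a label volume (and optionally its lut TSV) to disk."""
    path = Path(path)
    if path.is_dir():
        raise ValueError(f"{path} is a directory, expected a file path")
    if not np.any(parc.data):
        logger.warning("writing background-only parcellation to %s", path)
    img = nib.Nifti1Image(parc.data.astype(np.int32), parc.affine)
    nib.save(img, str(path))
    if lut_path is not None:
        write_lut(parc.lut, lut_path)


# ---------------------------------------------------------------------------
# ROI configuration


def load_roi_config(path: str | Path) -> RoiSet:
    """Load a YAML ROI-set config.

    Expected layout::

        rois:
          - {id: 1, name: frontal_lobe_L, hemisphere: L, lobe: frontal}
          - ...
        bilateral_pairs:
          - [1, 2]

    The declared ``rois`` order defines the profile axis.
    """
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    rois = cfg.get("rois", [])
    if not rois:
        raise ValueError(f"{path}: config declares no ROIs")
    ids = [int(r["id"]) for r in rois]
    info = {int(r["id"]): LabelInfo(str(r["name"]), str(r["hemisphere"]),
                                    str(r.get("lobe", "none")))
            for r in rois}
    pairs: dict[int, int] = {}
    for a, b in cfg.get("bilateral_pairs", []):
        pairs[int(a)] = int(b)
        pairs[int(b)] = int(a)
    return RoiSet(roi_ids=tuple(ids), info=info, bilateral_pairs=pairs)


def default_roi_config_path() -> Path:
    """Path of the bundled 40-ROI configuration."""
    return Path(__file__).parent / "data" / "roiset_dhcp40.yaml"


def roiset_from_labels(labels: LabelVolume,
                       roi_ids: Sequence[int] | None = None) -> RoiSet:
    """Build a RoiSet directly from a label volume's lut.

    Bilateral pairs are inferred by matching names that differ only in a
    trailing ``_L``/``_R`` suffix.
    """
    if roi_ids is None:
        roi_ids = sorted(labels.lut)
    info = {i: labels.lut[i] for i in roi_ids}
    by_stem: dict[str, dict[str, int]] = {}
    for i in roi_ids:
        e = info[i]
        if e.hemisphere in ("L", "R") and e.name.endswith(("_L", "_R")):
            by_stem.setdefault(e.name[:-2], {})[e.hemisphere] = i
    pairs: dict[int, int] = {}
    for sides in by_stem.values():
        if set(sides) == {"L", "R"}:
            pairs[sides["L"]] = sides["R"]
            pairs[sides["R"]] = sides["L"]
    return RoiSet(roi_ids=tuple(roi_ids), info=info, bilateral_pairs=pairs)
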