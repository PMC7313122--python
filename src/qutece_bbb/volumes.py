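"""Volume and table I/O with validation.

NIfTI-1 is the on-disk format for all 3D grids. Orientation and affine
information beyond the voxel size is carried through untouched but never
interpreted: phantom cohorts and their atlas are generated on a common grid,
and real data is expected to be pre-registered (or handled by the simplified
rigid stage in :mod:`qutece_bbb.alignment`).

Voxel sizes are stored in micrometres throughout. Voxel indexing is 0-based.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

#: Reserved label for the blood-pool compartment; never collides with the
#: 1..173 atlas region ids.
BLOOD_LABEL = 999

#: Number of regions in the canonical rat brain atlas table.
N_REGIONS = 173

VALID_GROUPS = ("control", "diabetic")


class VolumeError(ValueError):
    """Raised for invalid volumes or volume files."""


@dataclass
class IntensityVolume:
    """A 3D scalar signal grid (arbitrary scanner units, non-negative).

    Parameters
    ----------
    data
        3D float array of signal intensities. Must be finite and >= 0.
    voxel_size
        Edge length per axis in micrometres.
    """

    data: np.ndarray
    voxel_size: tuple[float, float, float] = (167.0, 167.0, 167.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3 or min(self.data.shape) < 1:
            raise VolumeError(f"expected a non-empty 3D volume, got shape {self.data.shape}")
        if not np.all(np.isfinite(self.data)):
            raise VolumeError("intensity volume contains NaN or infinite voxels")
        if np.any(self.data < 0):
            raise VolumeError("intensity volume contains negative voxels")
        self.voxel_size = tuple(float(v) for v in self.voxel_size)
        if len(self.voxel_size) != 3 or any(v <= 0 for v in self.voxel_size):
            raise VolumeError(f"voxel_size must be 3 positive lengths, got {self.voxel_size}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape


@dataclass
class LabelVolume:
    """A 3D integer grid assigning voxels to atlas regions.

    Label 0 is background; region labels 1..173 follow the canonical region
    table; ``blood_label`` marks the blood-pool compartment.
    """

    labels: np.ndarray
    voxel_size: tuple[float, float, float] = (167.0, 167.0, 167.0)
    blood_label: int = BLOOD_LABEL

    def __post_init__(self) -> None:
        labels = np.asarray(self.labels)
        if labels.ndim != 3 or min(labels.shape) < 1:
            raise VolumeError(f"expected a non-empty 3D label volume, got shape {labels.shape}")
        if not np.issubdtype(labels.dtype, np.integer):
            if not np.all(labels == np.round(labels)):
                raise VolumeError("label volume contains non-integer values")
        if labels.min() < 0:
            raise VolumeError("label volume contains negative labels")
        self.labels = labels.astype(np.uint16)
        self.voxel_size = tuple(float(v) for v in self.voxel_size)
        if any(v <= 0 for v in self.voxel_size):
            raise VolumeError(f"voxel_size must be positive, got {self.voxel_size}")
        if not 0 < self.blood_label < 2**16 or 1 <= self.blood_label <= N_REGIONS:
            raise VolumeError(f"blood_label {self.blood_label} collides with region ids or is out of range")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape

    @property
    def region_ids(self) -> np.ndarray:
        """Sorted atlas region ids present (background and blood excluded)."""
        ids = np.unique(self.labels)
        return ids[(ids != 0) & (ids != self.blood_label)]

    def region_voxel_counts(self) -> pd.Series:
        """Voxel count per present region id, for QC."""
        ids, counts = np.unique(self.labels, return_counts=True)
        keep = (ids != 0) & (ids != self.blood_label)
        return pd.Series(counts[keep], index=ids[keep], name="n_voxels")


def _voxel_size_um(img: nib.Nifti1Image) -> tuple[float, float, float]:
    zooms = img.header.get_zooms()[:3]
    unit = img.header.get_xyzt_units()[0]
    scale = {"meter": 1e6, "mm": 1e3, "micron": 1.0}.get(unit, 1e3)  # NIfTI default mm
    return tuple(float(z) * scale for z in zooms)


def read_volume(path: str | Path) -> IntensityVolume:
    """Read a 3D NIfTI-1 intensity volume; voxel size converted to µm."""
    path = Path(path)
    if not path.exists():
        raise VolumeError(f"volume file not found: {path}")
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise VolumeError(f"{path}: expected 3D data, got {data.ndim}D")
    if not np.all(np.isfinite(data)):
        raise VolumeError(f"{path}: volume contains NaN or infinite voxels")
    if data.min() < 0:
        raise VolumeError(f"{path}: volume contains negative voxels")
    return IntensityVolume(data=np.asarray(data, dtype=np.float64), voxel_size=_voxel_size_um(img))


def read_label_volume(path: str | Path, blood_label: int = BLOOD_LABEL) -> LabelVolume:
    """Read a 3D NIfTI-1 integer label volume."""
    path = Path(path)
    if not path.exists():
        raise VolumeError(f"label file not found: {path}")
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise VolumeError(f"{path}: expected 3D labels, got {data.ndim}D")
    return LabelVolume(labels=data, voxel_size=_voxel_size_um(img), blood_label=blood_label)


def write_volume(vol, path: str | Path) -> Path:
    """Write a volume as NIfTI-1; labels as uint16, intensities/maps as float32.

    The voxel size is encoded in the header (µm units flagged). Returns the
    path written.
    """
    path = Path(path)
    if isinstance(vol, LabelVolume):
        data, voxel_size = vol.labels.astype(np.uint16), vol.voxel_size
    elif isinstance(vol, IntensityVolume):
        data, voxel_size = vol.data.astype(np.float32), vol.voxel_size
    else:  # VascularFractionMap or similar duck-typed carrier
        data = np.asarray(vol.data, dtype=np.float32)
        voxel_size = getattr(vol, "voxel_size", (167.0, 167.0, 167.0))
    if data.ndim != 3 or data.size == 0:
        raise VolumeError(f"refusing to write empty or non-3D volume of shape {data.shape}")
    affine = np.diag(list(voxel_size) + [1.0])
    img = nib.Nifti1Image(data, affine)
    img.header.set_zooms(voxel_size)
    img.header.set_xyzt_units(xyz="micron")
    try:
        nib.save(img, str(path))
    except OSError as exc:
        raise VolumeError(f"cannot write volume to {path}: {exc}") from exc
    return path


@dataclass
class RegionTable:
    """Lookup table mapping atlas region ids to region names."""

    table: pd.DataFrame  # columns: region_id (int), region_name (str)

    def __post_init__(self) -> None:
        t = self.table
        missing = {"region_id", "region_name"} - set(t.columns)
        if missing:
            raise VolumeError(f"region table missing columns: {sorted(missing)}")
        ids = t["region_id"]
        if not np.issubdtype(np.asarray(ids).dtype, np.integer):
            raise VolumeError("region ids must be integers")
        if (ids <= 0).any():
            raise VolumeError("region ids must be positive")
        if ids.duplicated().any():
            dup = sorted(ids[ids.duplicated()].unique().tolist())
            raise VolumeError(f"duplicate region ids: {dup}")
        if t["region_name"].duplicated().any():
            dup = sorted(t["region_name"][t["region_name"].duplicated()].unique().tolist())
            raise VolumeError(f"duplicate region names: {dup}")
        self.table = t.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.table)

    @property
    def ids(self) -> np.ndarray:
        return self.table["region_id"].to_numpy()

    def name_of(self, region_id: int) -> str:
        row = self.table.loc[self.table["region_id"] == region_id, "region_name"]
        if row.empty:
            raise KeyError(f"region id {region_id} not in table")
        return str(row.iloc[0])


def read_region_table(path: str | Path) -> RegionTable:
    """Read a CSV region lookup table with columns ``id,name``."""
    df = pd.read_csv(path)
    cols = {c.lower().strip(): c for c in df.columns}
    id_col = cols.get("id") or cols.get("region_id")
    name_col = cols.get("name") or cols.get("region_name")
    if id_col is None or name_col is None:
        raise VolumeError(f"{path}: region table needs 'id' and 'name' columns, got {list(df.columns)}")
    ids = df[id_col]
    if not np.issubdtype(ids.dtype, np.integer):
        raise VolumeError(f"{path}: region ids must be integers")
    return RegionTable(pd.DataFrame({"region_id": ids.astype(int), "region_name": df[name_col].astype(str)}))


def _reference_stats() -> pd.DataFrame:
    with resources.files("qutece_bbb.data").joinpath("regional_reference_stats.csv").open() as fh:
        return pd.read_csv(fh)


def canonical_region_table() -> RegionTable:
    """The canonical 173-region atlas lookup table shipped with the package."""
    df = _reference_stats()
    return RegionTable(df[["region_id", "region_name"]].copy())


def reference_region_params() -> pd.DataFrame:
    """Published per-region cohort statistics used to calibrate phantoms.

    One row per atlas region with the control and diabetic group mean and SD
    of the regional vascular-fraction mode, the direction of the printed
    difference, and the reported rank-sum p-value. These are the study's
    regional reference values for the BBZDR/Wor type 2 diabetes rat model
    versus non-diabetic littermate controls.
    """
    return _reference_stats().copy()


@dataclass
class CohortManifest:
    """Cohort description: one row per subject with group and file paths."""

    table: pd.DataFrame  # subject_id, group, body_mass, pre_path, post_path
    REQUIRED = ("subject_id", "group", "body_mass", "pre_path", "post_path")

    def __post_init__(self) -> None:
        t = self.table.copy()
        missing = set(self.REQUIRED) - set(t.columns)
        if missing:
            raise VolumeError(f"manifest missing columns: {sorted(missing)}")
        t["group"] = t["group"].astype(str).str.strip().str.lower()
        bad = sorted(set(t["group"]) - set(VALID_GROUPS))
        if bad:
            raise VolumeError(f"unknown group labels: {bad} (expected {VALID_GROUPS})")
        if (t["body_mass"] <= 0).any():
            raise VolumeError("body_mass must be positive (grams)")
        if t["subject_id"].duplicated().any():
            raise VolumeError("duplicate subject ids in manifest")
        for g in VALID_GROUPS:
            if not (t["group"] == g).any():
                raise VolumeError(f"manifest has no '{g}' subjects")
        self.table = t.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.table)

    def group_sizes(self) -> dict[str, int]:
        return self.table["group"].value_counts().to_dict()


def read_manifest(path: str | Path) -> CohortManifest:
    """Read and validate a cohort manifest CSV."""
    return CohortManifest(pd.read_csv(path))
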