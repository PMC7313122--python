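"""Synthetic phantom cohorts with known per-region vascular fractions.

The generator inverts the blood-normalized contrast-change score used by the
mapping stage: for each subject, each atlas region r is assigned a true
vascular fraction ``f_r`` drawn around its group's published regional mean,
and the post-contrast volume is the pre-contrast volume plus
``f_r * blood_delta`` plus voxel noise. Pure-blood voxels use ``f = 1``
exactly, so the blood-pool normalization recovers the scale. A truth table of
the drawn ``f_r`` per subject and region supports recovery tests downstream.

Geometry is deliberately schematic: an ellipsoidal "brain" partitioned into
173 contiguous parcels by centroidal Voronoi relaxation, plus a tubular
blood-pool structure outside the brain. Only the label bookkeeping matters to
the analysis stages; no anatomical realism is attempted.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from scipy.stats import truncnorm

from .volumes import (
    BLOOD_LABEL,
    CohortManifest,
    IntensityVolume,
    LabelVolume,
    RegionTable,
    VolumeError,
    write_volume,
)

#: Minimum voxels any generated region may have; generation fails below this.
MIN_REGION_VOXELS = 50

#: Subject-level fractions are truncated to this interval rather than [0, 1]
#: so near-blood regions (e.g. the pineal gland at 0.86-0.90) keep symmetric
#: sampling and an unbiased mode.
F_BOUNDS = (0.0, 1.2)


@dataclass
class RegionParams:
    """Per-region generative parameters: group means/SDs of the regional mode."""

    region_id: int
    control_mode_mean: float
    control_mode_sd: float
    diabetic_mode_mean: float
    diabetic_mode_sd: float

    def __post_init__(self) -> None:
        for m in (self.control_mode_mean, self.diabetic_mode_mean):
            if not 0.0 <= m <= 1.0:
                raise ValueError(f"region {self.region_id}: mode mean {m} outside [0, 1]")
        for s in (self.control_mode_sd, self.diabetic_mode_sd):
            if s < 0:
                raise ValueError(f"region {self.region_id}: negative SD {s}")

    def group_params(self, group: str) -> tuple[float, float]:
        if group == "control":
            return self.control_mode_mean, self.control_mode_sd
        if group == "diabetic":
            return self.diabetic_mode_mean, self.diabetic_mode_sd
        raise ValueError(f"unknown group {group!r}")


def params_from_reference(df: pd.DataFrame) -> list[RegionParams]:
    """Build RegionParams from a reference-statistics frame.

    Expects columns region_id, control_mean, control_sd, diabetic_mean,
    diabetic_sd (the layout of
    :func:`qutece_bbb.volumes.reference_region_params`).
    """
    return [
        RegionParams(
            region_id=int(r.region_id),
            control_mode_mean=float(r.control_mean),
            control_mode_sd=float(r.control_sd),
            diabetic_mode_mean=float(r.diabetic_mean),
            diabetic_mode_sd=float(r.diabetic_sd),
        )
        for r in df.itertuples()
    ]


@dataclass
class PhantomConfig:
    """Study-design parameters of a simulated cohort.

    Defaults mirror the study being emulated: 7 control and 8 diabetic
    subjects. Signal units are arbitrary scanner units; ``blood_delta`` is
    the post-minus-pre change of pure blood that normalizes the score.
    ``subject_sd_floor`` replaces published SDs printed as 0.00, which are
    rounded, not literally zero.
    """

    grid_shape: tuple[int, int, int] = (64, 64, 64)
    n_control: int = 7
    n_diabetic: int = 8
    baseline_signal: float = 100.0
    blood_delta: float = 100.0
    voxel_noise_sd: float = 2.0
    subject_sd_floor: float = 0.005
    voxel_size: tuple[float, float, float] = (167.0, 167.0, 167.0)
    rng_seed: int = 0

    def __post_init__(self) -> None:
        self.grid_shape = tuple(int(n) for n in self.grid_shape)
        if len(self.grid_shape) != 3 or min(self.grid_shape) < 1:
            raise ValueError(f"grid_shape must be 3 positive ints, got {self.grid_shape}")
        if self.n_control < 1 or self.n_diabetic < 1:
            raise ValueError("need at least one subject per group")
        if self.voxel_noise_sd < 0 or self.subject_sd_floor < 0:
            raise ValueError("noise parameters must be >= 0")
        if self.blood_delta <= 0:
            raise ValueError("blood_delta must be positive")

    def to_dict(self) -> dict:
        return asdict(self)


def _brain_mask(shape: tuple[int, int, int]) -> np.ndarray:
    """Ellipsoid centered in the grid with semi-axes 0.42 * extent."""
    grids = np.ogrid[tuple(slice(0, n) for n in shape)]
    center = [(n - 1) / 2.0 for n in shape]
    semi = [0.42 * n for n in shape]
    r2 = sum(((g - c) / s) ** 2 for g, c, s in zip(grids, center, semi))
    return r2 <= 1.0


def _blood_tube(shape: tuple[int, int, int], radius: float = 2.0) -> np.ndarray:
    """Tube along the first axis near one grid corner, clear of the brain."""
    nx, ny, nz = shape
    y0, z0 = 0.93 * (ny - 1), 0.93 * (nz - 1)
    yy, zz = np.ogrid[0:ny, 0:nz]
    disk = (yy - y0) ** 2 + (zz - z0) ** 2 <= radius**2
    return np.broadcast_to(disk[None, :, :], shape).copy()


def generate_atlas(
    config: PhantomConfig,
    region_table: RegionTable,
    n_lloyd_iter: int = 5,
) -> LabelVolume:
    """Partition an ellipsoidal brain into one parcel per atlas region.

    Seeded centroids inside the ellipsoid are relaxed with a few Lloyd
    iterations (centroidal Voronoi) so parcel sizes are roughly equal, then
    every brain voxel takes the label of its nearest centroid. A tubular
    blood-pool structure is labeled ``blood_label``. Deterministic given
    ``config.rng_seed``.
    """
    n_regions = len(region_table)
    mask = _brain_mask(config.grid_shape)
    n_brain = int(mask.sum())
    if n_brain < n_regions * MIN_REGION_VOXELS:
        raise VolumeError(
            f"grid {config.grid_shape} too small: {n_brain} brain voxels "
            f"< {n_regions} regions x {MIN_REGION_VOXELS} voxels"
        )
    coords = np.argwhere(mask).astype(np.float64)
    rng = np.random.default_rng(config.rng_seed)
    centroids = coords[rng.choice(len(coords), size=n_regions, replace=False)]
    for _ in range(n_lloyd_iter):
        assign = cKDTree(centroids).query(coords, k=1)[1]
        for k in range(n_regions):
            pts = coords[assign == k]
            if len(pts):
                centroids[k] = pts.mean(axis=0)
    assign = cKDTree(centroids).query(coords, k=1)[1]

    labels = np.zeros(config.grid_shape, dtype=np.uint16)
    ids = region_table.ids
    labels[mask] = ids[assign]
    tube = _blood_tube(config.grid_shape)
    labels[tube & ~mask] = BLOOD_LABEL

    vol = LabelVolume(labels=labels, voxel_size=config.voxel_size, blood_label=BLOOD_LABEL)
    counts = vol.region_voxel_counts()
    if len(counts) < n_regions or counts.min() < MIN_REGION_VOXELS:
        small = counts[counts < MIN_REGION_VOXELS]
        raise VolumeError(
            f"atlas generation produced undersized regions (min {counts.min()} voxels): "
            f"{small.index.tolist()[:5]}..."
        )
    if int((labels == BLOOD_LABEL).sum()) < 20:
        raise VolumeError("blood-pool tube has fewer than 20 voxels")
    return vol


def _draw_fraction(mean: float, sd: float, floor: float, rng: np.random.Generator) -> float:
    sd = max(sd, floor)
    lo, hi = F_BOUNDS
    if sd == 0:  # degenerate draw: deterministic fraction
        return float(np.clip(mean, lo, hi))
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return float(truncnorm.rvs(a, b, loc=mean, scale=sd, random_state=rng))


def generate_subject(
    atlas: LabelVolume,
    params: list[RegionParams] | dict[int, RegionParams],
    group: str,
    config: PhantomConfig,
    subject_seed: int,
) -> tuple[IntensityVolume, IntensityVolume, dict[int, float]]:
    """Simulate one subject's pre/post-contrast pair plus its truth map.

    Per region r the subject-level fraction is drawn
    ``f_r ~ Normal(group_mean, max(group_sd, floor))`` truncated to [0, 1.2];
    every voxel of r then gets ``post = pre + f_r * blood_delta`` plus
    independent voxel noise on both volumes. Blood-pool voxels use ``f = 1``
    exactly; background stays at baseline.
    """
    if not isinstance(params, dict):
        params = {p.region_id: p for p in params}
    present = atlas.region_ids
    missing = [int(i) for i in present if int(i) not in params]
    if missing:
        raise VolumeError(f"atlas regions missing from params: {missing[:10]}")

    rng = np.random.default_rng(subject_seed)
    truth: dict[int, float] = {}
    # fraction lookup by label value, then one gather over the grid
    f_lut = np.zeros(int(atlas.labels.max()) + 1, dtype=np.float64)
    for rid in present:
        mean, sd = params[int(rid)].group_params(group)
        f = _draw_fraction(mean, sd, config.subject_sd_floor, rng)
        truth[int(rid)] = f
        f_lut[int(rid)] = f
    f_lut[atlas.blood_label] = 1.0
    f_field = f_lut[atlas.labels]

    noise = config.voxel_noise_sd
    pre = config.baseline_signal + rng.normal(0.0, noise, atlas.shape) if noise > 0 else np.full(
        atlas.shape, config.baseline_signal
    )
    post = pre + f_field * config.blood_delta + (rng.normal(0.0, noise, atlas.shape) if noise > 0 else 0.0)
    pre = np.clip(pre, 0.0, None)
    post = np.clip(post, 0.0, None)
    return (
        IntensityVolume(pre, voxel_size=config.voxel_size),
        IntensityVolume(post, voxel_size=config.voxel_size),
        truth,
    )


def subject_seeds(config: PhantomConfig) -> list[tuple[str, str, int]]:
    """Deterministic (subject_id, group, seed) triples for a cohort."""
    root = np.random.default_rng(config.rng_seed)
    seeds = root.integers(0, 2**31 - 1, size=config.n_control + config.n_diabetic)
    out = []
    for i in range(config.n_control):
        out.append((f"C{i + 1:02d}", "control", int(seeds[i])))
    for j in range(config.n_diabetic):
        out.append((f"D{j + 1:02d}", "diabetic", int(seeds[config.n_control + j])))
    return out


def generate_cohort(
    config: PhantomConfig,
    region_params: list[RegionParams],
    region_table: RegionTable,
    out_dir: str | Path,
) -> CohortManifest:
    """Write a full phantom cohort to disk and return its manifest.

    Outputs under ``out_dir``: ``atlas.nii.gz``, per-subject
    ``<id>_pre.nii.gz``/``<id>_post.nii.gz``, ``manifest.csv``,
    ``truth.csv`` (subject_id, region_id, f_true), ``region_params.csv``
    and ``phantom_config.json``. Fully reproducible from ``config.rng_seed``.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    atlas = generate_atlas(config, region_table)
    write_volume(atlas, out_dir / "atlas.nii.gz")

    params_by_id = {p.region_id: p for p in region_params}
    rows, truth_rows = [], []
    body_mass = 400.0  # nominal adult rat mass in grams
    for subject_id, group, seed in subject_seeds(config):
        pre, post, truth = generate_subject(atlas, params_by_id, group, config, seed)
        pre_path = out_dir / f"{subject_id}_pre.nii.gz"
        post_path = out_dir / f"{subject_id}_post.nii.gz"
        write_volume(pre, pre_path)
        write_volume(post, post_path)
        rows.append(
            dict(subject_id=subject_id, group=group, body_mass=body_mass,
                 pre_path=str(pre_path), post_path=str(post_path))
        )
        truth_rows.extend(
            dict(subject_id=subject_id, region_id=rid, f_true=f) for rid, f in sorted(truth.items())
        )

    manifest = CohortManifest(pd.DataFrame(rows))
    manifest.table.to_csv(out_dir / "manifest.csv", index=False)
    pd.DataFrame(truth_rows).to_csv(out_dir / "truth.csv", index=False, float_format="%.10g")
    pd.DataFrame([asdict(p) for p in region_params]).to_csv(out_dir / "region_params.csv", index=False)
    (out_dir / "phantom_config.json").write_text(json.dumps(config.to_dict(), indent=2))
    return manifest
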