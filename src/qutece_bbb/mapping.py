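"""Voxel-wise blood-normalized contrast-change ("vascular fraction") maps.

The score for a voxel v is ``(post(v) - pre(v)) / (blood_post - blood_pre)``:
0 for tissue whose signal did not change, about 1 for pure blood. Values are
kept as dimensionless fractions internally; rendering as percentages is a
report-time concern only. Negative values are legitimate noise around zero
and are never clipped.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .volumes import IntensityVolume, LabelVolume, VolumeError

#: Minimum number of blood-pool voxels required for a reliable blood estimate.
MIN_BLOOD_VOXELS = 20


@dataclass
class VascularFractionMap:
    """Per-voxel blood-normalized contrast change for one subject."""

    data: np.ndarray
    blood_pre: float
    blood_post: float
    voxel_size: tuple[float, float, float] = (167.0, 167.0, 167.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise VolumeError(f"expected 3D map, got shape {self.data.shape}")
        if self.blood_delta <= 0:
            raise VolumeError(
                f"blood signal change must be positive (pre={self.blood_pre}, post={self.blood_post})"
            )

    @property
    def blood_delta(self) -> float:
        return self.blood_post - self.blood_pre

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def qc_record(self, subject_id: str, n_blood_voxels: int) -> dict:
        return dict(
            subject_id=subject_id,
            blood_pre=self.blood_pre,
            blood_post=self.blood_post,
            blood_delta=self.blood_delta,
            n_blood_voxels=n_blood_voxels,
        )


def estimate_blood_signal(
    vol: IntensityVolume,
    labels: LabelVolume,
    blood_label: int | None = None,
    estimator: str = "median",
) -> float:
    """Blood-pool signal of one volume: median (default) over blood voxels.

    The median is robust to inflow and partial-volume edge voxels; the mean
    is available for comparison.
    """
    if blood_label is None:
        blood_label = labels.blood_label
    mask = labels.labels == blood_label
    n = int(mask.sum())
    if n < MIN_BLOOD_VOXELS:
        raise VolumeError(f"only {n} blood-pool voxels (label {blood_label}); need >= {MIN_BLOOD_VOXELS}")
    values = vol.data[mask]
    if estimator == "median":
        return float(np.median(values))
    if estimator == "mean":
        return float(values.mean())
    raise ValueError(f"unknown blood estimator {estimator!r}")


def compute_vf_map(
    pre: IntensityVolume,
    post: IntensityVolume,
    blood_pre: float,
    blood_post: float,
) -> VascularFractionMap:
    """Normalize the voxel-wise signal change by the blood signal change."""
    if pre.shape != post.shape:
        raise VolumeError(f"pre/post shape mismatch: {pre.shape} vs {post.shape}")
    delta = blood_post - blood_pre
    if delta <= 0:
        raise VolumeError(
            f"blood_post ({blood_post}) must exceed blood_pre ({blood_pre}); normalization undefined"
        )
    data = (post.data - pre.data) / delta
    return VascularFractionMap(data=data, blood_pre=blood_pre, blood_post=blood_post, voxel_size=pre.voxel_size)


def map_for_subject(
    pre: IntensityVolume,
    post: IntensityVolume,
    labels: LabelVolume,
    blood_label: int | None = None,
    estimator: str = "median",
) -> tuple[VascularFractionMap, int]:
    """Estimate blood signals from the blood-pool label and build the map.

    Returns the map and the blood-pool voxel count (for QC logging).
    """
    blood_pre = estimate_blood_signal(pre, labels, blood_label, estimator)
    blood_post = estimate_blood_signal(post, labels, blood_label, estimator)
    n_blood = int((labels.labels == (blood_label or labels.blood_label)).sum())
    return compute_vf_map(pre, post, blood_pre, blood_post), n_blood
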