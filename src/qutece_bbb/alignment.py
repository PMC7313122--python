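"""Simplified rigid alignment and label resampling.

This stage exists so the pipeline contract is complete for real, imperfectly
aligned acquisitions: a 6-DOF rigid transform (3 voxel translations, 3 Euler
angles in degrees) estimated by exhaustive search over a caller-supplied
parameter grid, maximizing normalized cross-correlation, initialized at the
center-of-mass translation. Synthetic cohorts are generated pre-aligned, so
the estimated transform there is the identity and the stage is a no-op
(``--skip-align`` bypasses it entirely). Nonlinear atlas fitting and scaling
are out of scope.

Labels are always resampled nearest-neighbour (never interpolated);
intensities trilinearly.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import ndimage

from .volumes import IntensityVolume, LabelVolume, VolumeError

#: Peak normalized cross-correlation below this flags an unreliable fit.
WEAK_CORRELATION = 0.2


@dataclass
class RigidTransform:
    """Rigid motion: translation in voxels, rotation in degrees (XYZ Euler)."""

    translation: tuple[float, float, float] = (0.0, 0.0, 0.0)
    rotation: tuple[float, float, float] = (0.0, 0.0, 0.0)
    peak_correlation: float | None = None
    weak: bool = False

    @property
    def is_identity(self) -> bool:
        return all(t == 0 for t in self.translation) and all(r == 0 for r in self.rotation)

    def matrix(self) -> np.ndarray:
        """3x3 rotation matrix for the XYZ Euler angles."""
        ax, ay, az = np.deg2rad(self.rotation)
        cx, sx = np.cos(ax), np.sin(ax)
        cy, sy = np.cos(ay), np.sin(ay)
        cz, sz = np.cos(az), np.sin(az)
        rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
        ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
        rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
        return rz @ ry @ rx

    def inverse(self) -> "RigidTransform":
        # exact only for pure translations; rotations are inverted separately
        if any(r != 0 for r in self.rotation):
            raise NotImplementedError("inverse of rotations not supported; invert the grid search instead")
        return RigidTransform(translation=tuple(-t for t in self.translation))

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(
            json.dumps(
                dict(
                    translation_voxels=list(self.translation),
                    rotation_degrees=list(self.rotation),
                    peak_correlation=self.peak_correlation,
                    weak=self.weak,
                ),
                indent=2,
            )
        )
        return path

    @classmethod
    def from_json(cls, path: str | Path) -> "RigidTransform":
        d = json.loads(Path(path).read_text())
        return cls(
            translation=tuple(d["translation_voxels"]),
            rotation=tuple(d["rotation_degrees"]),
            peak_correlation=d.get("peak_correlation"),
            weak=d.get("weak", False),
        )


def _apply(data: np.ndarray, t: RigidTransform, order: int, output_shape=None) -> np.ndarray:
    """Pull-back resampling of ``data`` under t (rotation about volume center)."""
    shape = output_shape or data.shape
    rot = t.matrix()
    center_out = (np.array(shape) - 1) / 2.0
    center_in = (np.array(data.shape) - 1) / 2.0
    # forward model: out_coord = R @ (in_coord - c_in) + c_in + translation
    # pull-back: in_coord = R^-1 @ (out_coord - c_in - translation) + c_in
    inv = rot.T
    offset = center_in - inv @ (center_in + np.asarray(t.translation))
    return ndimage.affine_transform(
        data, inv, offset=offset, output_shape=tuple(shape), order=order,
        mode="constant", cval=0.0, prefilter=(order > 1),
    )


def apply_rigid(vol: IntensityVolume, t: RigidTransform, output_shape=None) -> IntensityVolume:
    """Trilinear resampling of an intensity volume under ``t``."""
    data = _apply(vol.data, t, order=1, output_shape=output_shape)
    return IntensityVolume(np.clip(data, 0.0, None), voxel_size=vol.voxel_size)


def resample_labels(atlas: LabelVolume, t: RigidTransform, target_shape=None) -> LabelVolume:
    """Nearest-neighbour resampling of labels; out-of-source maps to background."""
    data = _apply(atlas.labels.astype(np.float64), t, order=0, output_shape=target_shape)
    return LabelVolume(
        labels=data.astype(np.uint16), voxel_size=atlas.voxel_size, blood_label=atlas.blood_label
    )


def _ncc(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    denom = np.sqrt((a * a).sum() * (b * b).sum())
    if denom == 0:
        return 0.0
    return float((a * b).sum() / denom)


def default_search_grid(max_shift: int = 3, shift_step: int = 1,
                        max_angle: float = 0.0, angle_step: float = 2.0):
    """Cartesian grid of candidate (translation, rotation) pairs."""
    shifts = np.arange(-max_shift, max_shift + 1, shift_step, dtype=float)
    angles = (
        np.arange(-max_angle, max_angle + angle_step, angle_step, dtype=float)
        if max_angle > 0 else np.array([0.0])
    )
    return [
        (tuple(tr), tuple(rot))
        for tr in itertools.product(shifts, repeat=3)
        for rot in itertools.product(angles, repeat=3)
    ]


def estimate_rigid(
    moving: IntensityVolume,
    fixed: IntensityVolume,
    search: list[tuple[tuple, tuple]] | None = None,
) -> RigidTransform:
    """Grid-search rigid transform mapping ``moving`` onto ``fixed``.

    The transform maximizing normalized cross-correlation over the search
    grid wins; candidates are offset by the center-of-mass translation as
    initialization. If the peak correlation is below 0.2 the returned
    transform carries ``weak=True``.
    """
    if moving.voxel_size != fixed.voxel_size:
        raise VolumeError(f"voxel sizes differ: {moving.voxel_size} vs {fixed.voxel_size}")
    if search is None:
        search = default_search_grid()
    if len(search) == 0:
        raise ValueError("empty search grid")

    com_m = np.array(ndimage.center_of_mass(moving.data))
    com_f = np.array(ndimage.center_of_mass(fixed.data))
    init = np.round(com_f - com_m)

    best: RigidTransform | None = None
    best_score = -np.inf
    for tr, rot in search:
        cand = RigidTransform(
            translation=tuple(float(v) for v in (np.asarray(tr) + init)),
            rotation=tuple(float(r) for r in rot),
        )
        moved = _apply(moving.data, cand, order=1, output_shape=fixed.shape)
        score = _ncc(moved, fixed.data)
        if score > best_score:
            best_score, best = score, cand
    assert best is not None
    best.peak_correlation = best_score
    best.weak = best_score < WEAK_CORRELATION
    return best
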