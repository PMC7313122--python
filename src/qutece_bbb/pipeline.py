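"""End-to-end orchestration: volumes in, result tables and overlays out.

``run_pipeline`` drives the file-based pipeline a user runs on a cohort
directory; ``run_phantom_study`` is the in-memory equivalent for simulation
studies (no intermediate files), used for power/calibration experiments and
by the acceptance harness.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, asdict
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from . import __version__
from .alignment import apply_rigid, default_search_grid, estimate_rigid
from .comparison import compare_regions, split_tables
from .mapping import map_for_subject
from .phantom import PhantomConfig, RegionParams, generate_atlas, generate_subject, subject_seeds
from .regional import DEFAULT_BIN_WIDTH, DEFAULT_MIN_REGION_SIZE, regional_mode_table
from .volumes import (
    BLOOD_LABEL,
    CohortManifest,
    LabelVolume,
    RegionTable,
    canonical_region_table,
    read_label_volume,
    read_manifest,
    read_region_table,
    read_volume,
    write_volume,
)

logger = logging.getLogger(__name__)

#: Fixed column order of the written comparison tables, for stable diffs.
TABLE_COLUMNS = [
    "region_id", "region_name", "control_mean", "control_sd",
    "diabetic_mean", "diabetic_sd", "rank_sum_statistic",
    "p_value", "q_value", "significant", "direction",
]


@dataclass
class RunConfig:
    """Everything a pipeline run depends on; serialized into the output."""

    manifest_path: str
    atlas_path: str
    region_table_path: str | None = None  # None -> canonical 173-region table
    out_dir: str = "qutece_run"
    blood_label: int = BLOOD_LABEL
    alpha: float = 0.05
    bin_width: float = DEFAULT_BIN_WIDTH
    mode_estimator: str = "histogram"
    min_region_size: int = DEFAULT_MIN_REGION_SIZE
    skip_align: bool = True
    blood_estimator: str = "median"
    rng_seed: int = 0

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class PipelineResult:
    out_dir: Path
    mode_table: pd.DataFrame
    comparisons: pd.DataFrame
    significant: pd.DataFrame
    nonsignificant: pd.DataFrame


def _align_subject(pre, post):
    """Motion-correct post onto pre with a small rigid grid search."""
    t = estimate_rigid(post, pre, search=default_search_grid(max_shift=2))
    if t.weak:
        logger.warning("weak alignment (peak NCC %.3f); check inputs", t.peak_correlation)
    if t.is_identity:
        return post, t
    return apply_rigid(post, t, output_shape=pre.shape), t


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Run maps -> regional modes -> group comparison on a cohort directory."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    manifest = read_manifest(config.manifest_path)
    atlas = read_label_volume(config.atlas_path, blood_label=config.blood_label)
    region_table = (
        read_region_table(config.region_table_path)
        if config.region_table_path
        else canonical_region_table()
    )
    logger.info("cohort: %s", manifest.group_sizes())

    maps = {}
    for rec in manifest.table.itertuples():
        try:
            pre = read_volume(rec.pre_path)
            post = read_volume(rec.post_path)
            if not config.skip_align:
                post, t = _align_subject(pre, post)
                t.to_json(out_dir / f"{rec.subject_id}_transform.json")
            vf_map, n_blood = map_for_subject(
                pre, post, atlas, config.blood_label, config.blood_estimator
            )
        except Exception as exc:
            raise RuntimeError(f"stage 'mapping', subject {rec.subject_id}: {exc}") from exc
        maps[rec.subject_id] = vf_map
        write_volume(vf_map, out_dir / f"{rec.subject_id}_vfmap.nii.gz")
        (out_dir / f"{rec.subject_id}_qc.json").write_text(
            json.dumps(vf_map.qc_record(rec.subject_id, n_blood), indent=2)
        )

    try:
        mode_table = regional_mode_table(
            manifest, maps, atlas, region_table,
            bin_width=config.bin_width,
            min_region_size=config.min_region_size,
            estimator=config.mode_estimator,
        )
    except Exception as exc:
        raise RuntimeError(f"stage 'regional modes': {exc}") from exc
    mode_table.to_csv(out_dir / "regional_modes.csv", index=False)

    try:
        comparisons = compare_regions(mode_table, alpha=config.alpha)
    except Exception as exc:
        raise RuntimeError(f"stage 'group comparison': {exc}") from exc
    sig, nonsig = split_tables(comparisons)
    comparisons[TABLE_COLUMNS].to_csv(out_dir / "comparisons.csv", index=False)
    sig[TABLE_COLUMNS].to_csv(out_dir / "table1_significant.csv", index=False)
    nonsig[TABLE_COLUMNS].to_csv(out_dir / "table2_nonsignificant.csv", index=False)

    overlay = significance_overlay(atlas, sig["region_id"].tolist())
    write_volume(overlay, out_dir / "significance_overlay.nii.gz")
    render_slice_overlay(
        atlas, comparisons, axis=2, index=atlas.shape[2] // 2,
        out_path=out_dir / "overlay_midslice.png",
    )

    (out_dir / "run_metadata.json").write_text(
        json.dumps(
            dict(
                tool="qutece-bbb",
                version=__version__,
                config=config.to_dict(),
                n_subjects=len(manifest),
                group_sizes=manifest.group_sizes(),
                n_regions_analyzed=int(comparisons.shape[0]),
                n_significant=int(sig.shape[0]),
                alpha=config.alpha,
                mode_estimator=config.mode_estimator,
            ),
            indent=2,
        )
    )
    logger.info("significant regions: %d / %d", len(sig), len(comparisons))
    return PipelineResult(out_dir, mode_table, comparisons, sig, nonsig)


def significance_overlay(atlas: LabelVolume, significant_ids) -> LabelVolume:
    """Label volume keeping only voxels of significant regions (ids retained)."""
    sig = np.zeros(int(atlas.labels.max()) + 1, dtype=np.uint16)
    for rid in significant_ids:
        sig[int(rid)] = int(rid)
    return LabelVolume(
        labels=sig[atlas.labels], voxel_size=atlas.voxel_size, blood_label=atlas.blood_label
    )


def render_slice_overlay(
    labels: LabelVolume,
    comparisons: pd.DataFrame,
    axis: int = 2,
    index: int | None = None,
    out_path: str | Path = "overlay.png",
    background: np.ndarray | None = None,
) -> Path:
    """Write a 2D slice with significant regions tinted red.

    ``background`` (a 3D intensity array) is rendered in grayscale when
    given; otherwise the labeled mask itself serves as anatomy. Colors are
    deterministic: one fixed red for significant voxels.
    """
    if index is None:
        index = labels.shape[axis] // 2
    if not 0 <= index < labels.shape[axis]:
        raise IndexError(f"slice index {index} out of range for axis {axis} (size {labels.shape[axis]})")
    sl = [slice(None)] * 3
    sl[axis] = index
    label_slice = labels.labels[tuple(sl)]
    bg = (
        background[tuple(sl)]
        if background is not None
        else (label_slice > 0).astype(float)
    )
    sig_ids = set(int(r) for r in comparisons.loc[comparisons["significant"], "region_id"])
    tint = np.isin(label_slice, list(sig_ids)) if sig_ids else np.zeros_like(label_slice, bool)

    fig, ax = plt.subplots(figsize=(5, 5))
    ax.imshow(bg.T, cmap="gray", origin="lower")
    rgba = np.zeros(label_slice.T.shape + (4,))
    rgba[tint.T] = (0.85, 0.1, 0.1, 0.6)
    ax.imshow(rgba, origin="lower")
    ax.set_axis_off()
    ax.set_title(f"significant regions, slice {index} / axis {axis}")
    out_path = Path(out_path)
    fig.savefig(out_path, dpi=120, bbox_inches="tight")
    plt.close(fig)
    return out_path


def run_phantom_study(
    phantom_config: PhantomConfig,
    region_params: list[RegionParams],
    region_table: RegionTable | None = None,
    alpha: float = 0.05,
    bin_width: float = DEFAULT_BIN_WIDTH,
    min_region_size: int = DEFAULT_MIN_REGION_SIZE,
    mode_estimator: str = "histogram",
) -> PipelineResult:
    """Simulate a cohort and compare groups entirely in memory.

    Identical statistics path to :func:`run_pipeline` (maps -> modes ->
    comparison) without file I/O; for simulation studies and calibration
    checks.
    """
    if region_table is None:
        region_table = canonical_region_table()
    atlas = generate_atlas(phantom_config, region_table)
    params_by_id = {p.region_id: p for p in region_params}

    rows, maps = [], {}
    for subject_id, group, seed in subject_seeds(phantom_config):
        pre, post, _truth = generate_subject(atlas, params_by_id, group, phantom_config, seed)
        vf_map, _ = map_for_subject(pre, post, atlas)
        maps[subject_id] = vf_map
        rows.append(
            dict(subject_id=subject_id, group=group, body_mass=400.0,
                 pre_path="<memory>", post_path="<memory>")
        )
    manifest = CohortManifest(pd.DataFrame(rows))
    mode_table = regional_mode_table(
        manifest, maps, atlas, region_table,
        bin_width=bin_width, min_region_size=min_region_size, estimator=mode_estimator,
    )
    comparisons = compare_regions(mode_table, alpha=alpha)
    sig, nonsig = split_tables(comparisons)
    return PipelineResult(Path("<memory>"), mode_table, comparisons, sig, nonsig)
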