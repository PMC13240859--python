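"""End-to-end orchestration: stacks in, profiles + PCA + manifest out.

Stage order is fixed: background subtraction, cropping, shift-and-max
projection, blob detection, impurity filtering, binning, smoothing,
antibody-peak cutoff, PCA.  One detection configuration applies to
every lane of a scan.  A failing lane is logged and recorded in the
manifest; remaining lanes continue.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

from . import __version__
from .config import PipelineConfig
from .detect import detect_blobs, filter_particles, overlay_image
from .io import (
    read_stack,
    write_matrix,
    write_overlay,
    write_particles,
    write_pca,
    write_profiles,
    write_projection,
)
from .pca import run_pca
from .preprocess import preprocess_stack
from .profiles import build_matrix, build_profile
from .project import geometric_shift_px, project_shift_max

__all__ = ["RunManifest", "run_pipeline"]

log = logging.getLogger("tiltgel")

#: maximum tolerated gap between the configured integer shift and the
#: per-frame in-plane displacement implied by the acquisition geometry.
SHIFT_CONSISTENCY_TOL_PX = 0.5


@dataclass
class RunManifest:
    """Record of one pipeline run: config snapshot and per-lane counts."""

    config: dict
    version: str = __version__
    lanes: dict[str, dict] = field(default_factory=dict)
    started_at: float = 0.0
    finished_at: float = 0.0

    def to_json(self) -> str:
        return json.dumps(
            {
                "version": self.version,
                "started_at": self.started_at,
                "finished_at": self.finished_at,
                "config": self.config,
                "lanes": self.lanes,
            },
            indent=2,
            sort_keys=True,
        )

    def write(self, path: "str | Path") -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        path.write_text(self.to_json())
        return path


def run_pipeline(config: PipelineConfig) -> RunManifest:
    """Process every configured lane and write all outputs.

    Emits per lane: the projection TIFF, the particle CSV and an
    overlay PNG; per run: profile CSVs, the profile matrix, PCA tables
    and the manifest.  Given identical inputs, config and seed, every
    output file except the manifest timestamps is byte-identical across
    runs.
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config=config.to_dict(), started_at=time.time())

    shift = (
        geometric_shift_px(config.optics)
        if config.use_geometric_shift
        else float(config.shift_px)
    )
    implied = geometric_shift_px(config.optics)
    if abs(implied - config.shift_px) > SHIFT_CONSISTENCY_TOL_PX:
        log.warning(
            "configured shift %s px differs from the geometric value %.2f px "
            "by more than %.1f px",
            config.shift_px, implied, SHIFT_CONSISTENCY_TOL_PX,
        )
    log.info(
        "pipeline: %d lanes, shift=%.3f px, background radius=%d px, "
        "detection threshold=%g, bins=%d px",
        len(config.lanes), shift, config.background_radius_px,
        config.detection.log_threshold, config.binning.bin_width_px,
    )

    profiles = []
    for lane_cfg in config.lanes:
        record: dict = {"path": lane_cfg.path}
        try:
            stack = read_stack(lane_cfg.path, config.optics, lane_cfg.lane_id)
            record["frames_read"] = stack.n_frames
            cropped = preprocess_stack(stack, lane_cfg.crop, config.background_radius_px)
            projection = project_shift_max(cropped, shift, config.optics)
            write_projection(projection, out / f"{lane_cfg.lane_id}_projection.tif")
            particles = detect_blobs(projection, config.detection)
            kept, removed = filter_particles(particles, config.detection)
            import pandas as pd

            all_particles = pd.concat([kept, removed], ignore_index=True)
            write_particles(
                all_particles, out / f"{lane_cfg.lane_id}_particles.csv",
                lane_cfg.lane_id, config.optics.pixel_um,
            )
            write_overlay(
                overlay_image(projection, all_particles),
                out / f"{lane_cfg.lane_id}_overlay.png",
            )
            from .config import BinningConfig, ParameterError

            try:
                profile = build_profile(
                    kept, config.binning, config.optics.pixel_um,
                    origin_px=0.0, lane_id=lane_cfg.lane_id,
                    condition_label=lane_cfg.condition_label,
                )
            except ParameterError:
                # lane too short (or empty) for the antibody search window:
                # keep every bin rather than dropping the lane
                log.warning(
                    "lane %s does not cover the antibody search window; "
                    "skipping the cutoff", lane_cfg.lane_id,
                )
                fallback = BinningConfig(
                    bin_width_px=config.binning.bin_width_px,
                    smooth_window=config.binning.smooth_window,
                    n_bins=config.binning.n_bins,
                    cutoff_mode="none",
                )
                profile = build_profile(
                    kept, fallback, config.optics.pixel_um,
                    origin_px=0.0, lane_id=lane_cfg.lane_id,
                    condition_label=lane_cfg.condition_label,
                )
            profiles.append(profile)
            record.update(
                detected=int(len(particles)),
                kept=int(len(kept)),
                removed_intensity=int((removed["removal_reason"] == "intensity").sum()),
                removed_diameter=int((removed["removal_reason"] == "diameter").sum()),
                remainder=int(profile.remainder),
                cutoff_um=profile.cutoff_um,
            )
            log.info(
                "lane %s: %d detected, %d kept, %d removed",
                lane_cfg.lane_id, len(particles), len(kept), len(removed),
            )
        except Exception as exc:  # noqa: BLE001 - lane isolation is intentional
            log.exception("lane %s failed", lane_cfg.lane_id)
            record["error"] = f"{type(exc).__name__}: {exc}"
        manifest.lanes[lane_cfg.lane_id] = record

    if profiles:
        # pad profiles to a common bin count before stacking
        n_bins = max(len(p.raw_counts) for p in profiles)
        uniform = []
        for p in profiles:
            if len(p.raw_counts) != n_bins:
                import numpy as np

                pad = n_bins - len(p.raw_counts)
                p.raw_counts = np.pad(p.raw_counts, (0, pad))
                p.smoothed_counts = np.pad(p.smoothed_counts, (0, pad))
                step = p.bin_edges_um[1] - p.bin_edges_um[0]
                p.bin_edges_um = p.bin_edges_um[0] + step * np.arange(n_bins + 1)
            uniform.append(p)
        write_profiles(uniform, out / "profiles.csv")
        if len(uniform) >= 2:
            matrix = build_matrix(uniform)
            write_matrix(matrix, out / "profile_matrix.csv")
            max_comp = min(matrix.values.shape[0] - 1, matrix.values.shape[1])
            n_comp = min(config.pca.n_components, max_comp)
            if n_comp >= 1:
                write_pca(run_pca(matrix, n_comp), out)

    manifest.finished_at = time.time()
    manifest.write(out / "manifest.json")
    return manifest
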