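"""Reading and writing the pipeline's file formats.

Stacks are 16-bit grayscale TIFF (multi-page, or a directory of
numbered single-page files); tables are CSV; overlays are 8-bit RGB
PNG.  Every writer is deterministic given identical inputs, so runs are
byte-reproducible.
"""

from __future__ import annotations

import re
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

from .config import OpticsConfig
from .profiles import MigrationProfile, ProfileMatrix
from .project import ProjectionImage
from .simulate import GroundTruth
from .stack import ScanStack

__all__ = [
    "read_stack",
    "write_stack",
    "write_projection",
    "read_projection",
    "write_ground_truth",
    "write_particles",
    "write_profiles",
    "write_matrix",
    "write_pca",
    "write_overlay",
]

_NUM_SUFFIX = re.compile(r"(\d+)(?=\.[^.]+$)")


def _numeric_key(path: Path) -> int:
    match = _NUM_SUFFIX.search(path.name)
    if match is None:
        raise ValueError(f"frame file {path.name} has no numeric suffix")
    return int(match.group(1))


def read_stack(
    path_or_dir: "str | Path",
    optics: OpticsConfig | None = None,
    lane_id: str | None = None,
) -> ScanStack:
    """Load one lane scan from a multi-page TIFF or a frame directory.

    Directory frames are ordered by the numeric suffix in their file
    names (never by modification time); all frames must share one shape
    and be 16-bit unsigned.
    """
    path = Path(path_or_dir)
    if path.is_dir():
        files = sorted(
            (p for p in path.iterdir() if p.suffix.lower() in (".tif", ".tiff")),
            key=_numeric_key,
        )
        if not files:
            raise ValueError(f"no TIFF frames found in directory {path}")
        frames = [tifffile.imread(f) for f in files]
    else:
        data = tifffile.imread(path)
        frames = list(data) if data.ndim == 3 else [data]
    shapes = {f.shape for f in frames}
    if len(shapes) != 1:
        raise ValueError(f"frames have mixed shapes: {sorted(shapes)}")
    dtypes = {f.dtype for f in frames}
    if dtypes != {np.dtype(np.uint16)}:
        raise ValueError(f"frames must be 16-bit unsigned, got {sorted(map(str, dtypes))}")
    return ScanStack(
        frames=np.stack(frames),
        optics=optics if optics is not None else OpticsConfig(),
        lane_id=lane_id if lane_id is not None else path.stem,
    )


def write_stack(
    stack: ScanStack, path: "str | Path", multipage: bool = True
) -> Path:
    """Write a stack as one multi-page TIFF, or numbered frames in a directory."""
    path = Path(path)
    if multipage:
        path.parent.mkdir(parents=True, exist_ok=True)
        tifffile.imwrite(path, stack.frames)
        return path
    path.mkdir(parents=True, exist_ok=True)
    width = len(str(stack.n_frames - 1))
    for i in range(stack.n_frames):
        tifffile.imwrite(path / f"frame_{i:0{width}d}.tif", stack.frames[i])
    return path


def write_projection(projection: ProjectionImage, path: "str | Path") -> Path:
    """Save a projection as a single 16-bit TIFF."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    pixels = np.clip(np.rint(np.asarray(projection.pixels, dtype=np.float64)), 0, 65535)
    tifffile.imwrite(path, pixels.astype(np.uint16))
    return path


def read_projection(path: "str | Path", pixel_um: float = 0.8) -> ProjectionImage:
    pixels = tifffile.imread(path)
    return ProjectionImage(pixels=pixels, pixel_um=pixel_um)


def write_ground_truth(truth: GroundTruth, path: "str | Path") -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    truth.to_frame().to_csv(path, index=False)
    return path


def write_particles(
    particles: pd.DataFrame, path: "str | Path", lane_id: str, pixel_um: float = 0.8
) -> Path:
    """Particle table CSV with migration distances attached."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    out = particles.copy()
    out.insert(0, "lane_id", lane_id)
    out["migration_um"] = out["y_px"] * pixel_um
    out.to_csv(path, index=False)
    return path


def write_profiles(profiles: list[MigrationProfile], path: "str | Path") -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    pd.concat([p.to_frame() for p in profiles], ignore_index=True).to_csv(
        path, index=False
    )
    return path


def write_matrix(matrix: ProfileMatrix, path: "str | Path") -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    matrix.to_frame().to_csv(path)
    return path


def write_pca(result, out_dir: "str | Path", prefix: str = "pca") -> list[Path]:
    """Scores, loadings and explained variance as three CSVs."""
    from .pca import loading_heatmap_table

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    scores = pd.DataFrame(
        result.scores,
        index=result.lane_ids,
        columns=[f"PC{k + 1}" for k in range(result.component_count)],
    )
    scores.insert(0, "condition", result.condition_labels)
    scores.index.name = "lane_id"
    paths = [out_dir / f"{prefix}_scores.csv"]
    scores.to_csv(paths[0])
    paths.append(out_dir / f"{prefix}_loadings.csv")
    loading_heatmap_table(result).to_csv(paths[1], index=False)
    paths.append(out_dir / f"{prefix}_explained_variance.csv")
    pd.DataFrame(
        {
            "component": np.arange(1, result.component_count + 1),
            "explained_variance_ratio": result.explained_variance_ratio,
        }
    ).to_csv(paths[2], index=False)
    return paths


def write_overlay(rgb: np.ndarray, path: "str | Path") -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    iio.imwrite(path, rgb)
    return path
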