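"""Single-molecule focus detection and impurity filtering.

Foci are local maxima of the scale-normalized Laplacian-of-Gaussian
response over a ladder of scales (``skimage.feature.blob_log``).
Detected particles carrying the fingerprints of impurities — protein
aggregates, bubbles, dust — are removed by two strict-inequality rules:
peak signal intensity above 15,000 counts or blob diameter above
2 pixels.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
from skimage.feature import blob_log

from .config import DetectionConfig, ParameterError
from .project import ProjectionImage

__all__ = [
    "PARTICLE_COLUMNS",
    "detect_blobs",
    "particle_diameter",
    "filter_particles",
    "match_points",
    "overlay_image",
]

PARTICLE_COLUMNS = [
    "y_px", "x_px", "sigma_px", "diameter_px", "intensity", "kept", "removal_reason",
]


def particle_diameter(sigma_px: "float | np.ndarray") -> "float | np.ndarray":
    """Blob diameter from the detected LoG scale: ``2 * sqrt(2) * sigma``.

    The LoG response of a Gaussian blob peaks when ``sqrt(2) * sigma``
    equals the blob radius; doubling gives the diameter.  With the 2-px
    diameter cutoff this means particles survive only up to
    ``sigma = 1/sqrt(2) ~ 0.707 px``.
    """
    return 2.0 * math.sqrt(2.0) * sigma_px


def _empty_particles() -> pd.DataFrame:
    df = pd.DataFrame({c: pd.Series(dtype=float) for c in PARTICLE_COLUMNS})
    df["kept"] = df["kept"].astype(bool)
    df["removal_reason"] = df["removal_reason"].astype(str)
    return df


def detect_blobs(projection: ProjectionImage, cfg: DetectionConfig) -> pd.DataFrame:
    """Detect foci in a projection image.

    Returns one row per particle with its center (projection
    coordinates), detected scale, derived diameter and the peak pixel
    value at the rounded center.  All particles start out kept; apply
    :func:`filter_particles` for the impurity rules.
    """
    img = np.asarray(projection.pixels, dtype=np.float64)
    if img.size == 0:
        raise ParameterError("projection image is empty")
    if cfg.n_sigma_steps < 1:
        raise ParameterError("empty sigma ladder")
    blobs = blob_log(
        img,
        min_sigma=cfg.min_sigma_px,
        max_sigma=cfg.max_sigma_px,
        num_sigma=cfg.n_sigma_steps,
        threshold=cfg.log_threshold,
        overlap=cfg.overlap,
    )
    if len(blobs) == 0:
        return _empty_particles()
    y, x, sigma = blobs[:, 0], blobs[:, 1], blobs[:, 2]
    iy = np.clip(np.rint(y).astype(int), 0, img.shape[0] - 1)
    ix = np.clip(np.rint(x).astype(int), 0, img.shape[1] - 1)
    return pd.DataFrame(
        {
            "y_px": y,
            "x_px": x,
            "sigma_px": sigma,
            "diameter_px": particle_diameter(sigma),
            "intensity": img[iy, ix],
            "kept": np.ones(len(y), dtype=bool),
            "removal_reason": ["none"] * len(y),
        }
    )


def filter_particles(
    particles: pd.DataFrame, cfg: DetectionConfig
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Partition particles into (kept, removed) by the impurity rules.

    A particle is removed iff its intensity exceeds ``cfg.intensity_max``
    (strictly) or its diameter exceeds ``cfg.diameter_max_px``
    (strictly); boundary values are kept.  ``removal_reason`` records
    the first violated rule, intensity checked first.
    """
    particles = particles.copy()
    too_bright = particles["intensity"].to_numpy(float) > cfg.intensity_max
    too_big = particles["diameter_px"].to_numpy(float) > cfg.diameter_max_px
    reason = np.where(too_bright, "intensity", np.where(too_big, "diameter", "none"))
    particles["removal_reason"] = reason
    particles["kept"] = reason == "none"
    kept = particles[particles["kept"]].reset_index(drop=True)
    removed = particles[~particles["kept"]].reset_index(drop=True)
    return kept, removed


def match_points(
    detected: np.ndarray, truth: np.ndarray, tol_px: float = 2.0
) -> list[tuple[int, int]]:
    """Greedy nearest-neighbor matching between two point sets.

    Pairs are accepted in order of increasing distance, each point used
    at most once, up to ``tol_px``.  Returns (detected_index,
    truth_index) pairs.
    """
    detected = np.asarray(detected, dtype=float).reshape(-1, 2)
    truth = np.asarray(truth, dtype=float).reshape(-1, 2)
    if len(detected) == 0 or len(truth) == 0:
        return []
    d2 = ((detected[:, None, :] - truth[None, :, :]) ** 2).sum(axis=2)
    order = np.argsort(d2, axis=None)
    used_d: set[int] = set()
    used_t: set[int] = set()
    pairs: list[tuple[int, int]] = []
    tol2 = tol_px * tol_px
    for flat in order:
        if d2.flat[flat] > tol2:
            break
        i, j = divmod(int(flat), truth.shape[0])
        if i in used_d or j in used_t:
            continue
        used_d.add(i)
        used_t.add(j)
        pairs.append((i, j))
    return pairs


def overlay_image(
    projection: ProjectionImage,
    particles: pd.DataFrame,
    radius_px: int = 4,
) -> np.ndarray:
    """8-bit RGB overlay: projection with circles around detections.

    Kept particles are circled yellow, removed ones red — the rendering
    used to choose detection thresholds by eye.
    """
    from skimage.draw import circle_perimeter

    img = np.asarray(projection.pixels, dtype=np.float64)
    hi = np.percentile(img, 99.9) if img.size else 1.0
    base = np.clip(img / max(hi, 1.0) * 255.0, 0, 255).astype(np.uint8)
    rgb = np.stack([base, base, base], axis=-1)
    colors = {"kept": (255, 255, 0), "removed": (255, 64, 64)}
    for _, row in particles.iterrows():
        color = colors["kept"] if bool(row["kept"]) else colors["removed"]
        rr, cc = circle_perimeter(
            int(round(row["y_px"])), int(round(row["x_px"])), radius_px,
            shape=rgb.shape[:2],
        )
        rgb[rr, cc] = color
    return rgb
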