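"""Per-frame background subtraction and gel-region cropping.

The pipeline order is fixed: rolling-ball background subtraction first,
then cropping to the gel region with a vertical offset interpolated
linearly between the interface heights measured at the first and last
frame.
"""

from __future__ import annotations

import math

import numpy as np
from skimage.restoration import rolling_ball

from .config import CropSpec, ParameterError
from .stack import ScanStack

__all__ = [
    "subtract_background",
    "rolling_ball_background",
    "interpolate_offsets",
    "crop_frame",
    "preprocess_stack",
    "find_interface_row",
]


def rolling_ball_background(frame: np.ndarray, radius_px: int = 25) -> np.ndarray:
    """Sternberg rolling-ball background estimate.

    The background is the upper envelope of a ball of the given radius
    rolled under the intensity surface: a grayscale erosion followed by
    a dilation with a hemisphere structuring element.  Both passes are
    computed with :func:`skimage.restoration.rolling_ball`, which
    returns the ball-apex height (erosion plus the radius); negating and
    re-applying it yields the dilation.
    """
    if radius_px < 1:
        raise ParameterError(f"radius_px must be >= 1, got {radius_px}")
    if 2 * radius_px + 1 > min(frame.shape):
        raise ParameterError(
            f"rolling-ball radius {radius_px} is too large for frame shape {frame.shape}"
        )
    f = frame.astype(np.float64, copy=False)
    eroded = rolling_ball(f, radius=radius_px) - radius_px
    background = -(rolling_ball(-eroded, radius=radius_px) - radius_px)
    return background


def subtract_background(frame: np.ndarray, radius_px: int = 25) -> np.ndarray:
    """Subtract the rolling-ball background from one frame.

    The result is clipped at zero; integer inputs come back in the same
    dtype (rounded), float inputs stay float.  A flat frame maps to an
    all-zero frame, and the operation is idempotent on two-level images
    whose peaks are narrower than the ball.
    """
    frame = np.asarray(frame)
    if frame.ndim != 2:
        raise ParameterError("subtract_background expects a single 2D frame")
    background = rolling_ball_background(frame, radius_px)
    residual = np.clip(frame.astype(np.float64) - background, 0.0, None)
    if np.issubdtype(frame.dtype, np.integer):
        return np.rint(residual).astype(frame.dtype)
    return residual.astype(frame.dtype)


def interpolate_offsets(
    start_height_px: float, end_height_px: float, n_frames: int
) -> list[int]:
    """Integer crop offsets interpolated linearly across the scan.

    ``offset_i = round(start + (end - start) * i / (n_frames - 1))``
    with round-half-up; a single frame gets ``[round(start)]``.
    """
    if n_frames < 1:
        raise ParameterError("n_frames must be >= 1")

    def round_half_up(v: float) -> int:
        return int(math.floor(v + 0.5))

    if n_frames == 1:
        return [round_half_up(start_height_px)]
    span = end_height_px - start_height_px
    return [
        round_half_up(start_height_px + span * i / (n_frames - 1))
        for i in range(n_frames)
    ]


def crop_frame(
    frame: np.ndarray, spec: CropSpec, frame_index: int, offsets: list[int]
) -> np.ndarray:
    """Integer-aligned copy of the gel window of one frame.

    The window starts at row ``offsets[frame_index]`` and column
    ``spec.width_offset_px``; no resampling is performed.
    """
    r0 = offsets[frame_index]
    c0 = spec.width_offset_px
    r1, c1 = r0 + spec.height_px, c0 + spec.width_px
    h, w = frame.shape
    if r0 < 0 or c0 < 0 or r1 > h or c1 > w:
        raise ParameterError(
            f"crop window rows {r0}:{r1}, cols {c0}:{c1} exceeds frame "
            f"shape {frame.shape} at frame index {frame_index}"
        )
    return frame[r0:r1, c0:c1].copy()


def preprocess_stack(
    stack: ScanStack, spec: CropSpec, radius_px: int = 25
) -> np.ndarray:
    """Background-subtract then crop every frame of a lane scan.

    Returns a float-free (same dtype as input) array of shape
    ``(n_frames, spec.height_px, spec.width_px)``.
    """
    offsets = interpolate_offsets(
        spec.start_height_px, spec.end_height_px, stack.n_frames
    )
    out = np.empty(
        (stack.n_frames, spec.height_px, spec.width_px), dtype=stack.frames.dtype
    )
    for i in range(stack.n_frames):
        cleaned = subtract_background(stack.frames[i], radius_px)
        out[i] = crop_frame(cleaned, spec, i, offsets)
    return out


def find_interface_row(frame: np.ndarray) -> int:
    """Row of maximum mean intensity — the bright gel/glass interface.

    Optional helper for configuring crop heights; the pipeline treats
    interface heights as inputs and never calls this automatically.
    """
    return int(np.argmax(np.asarray(frame, dtype=np.float64).mean(axis=1)))
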