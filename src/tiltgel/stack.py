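"""In-memory container for one lane scan."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .config import OpticsConfig


@dataclass
class ScanStack:
    """Ordered frames of one lane scan plus acquisition geometry.

    ``frames`` has shape (n_frames, height, width), dtype uint16, with
    frame i acquired at stage position ``i * optics.step_um`` along the
    electrophoresis axis.  ``origin_frame`` is the frame containing the
    lane origin (the bead pellet); by simulator convention it is 0.
    """

    frames: np.ndarray
    optics: OpticsConfig = field(default_factory=OpticsConfig)
    lane_id: str = "lane"
    origin_frame: int = 0

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3 or self.frames.shape[0] < 1:
            raise ValueError("frames must be a (n>=1, height, width) array")
        if self.frames.dtype != np.uint16:
            raise ValueError(f"frames must be uint16, got {self.frames.dtype}")

    @property
    def n_frames(self) -> int:
        return int(self.frames.shape[0])

    @property
    def frame_shape(self) -> tuple[int, int]:
        return (int(self.frames.shape[1]), int(self.frames.shape[2]))
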