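import numpy as np
import pandas as pd
import pytest

from tiltgel.config import CropSpec, LaneGeometry, NoiseConfig, OpticsConfig
from tiltgel.simulate import GroundTruth, _empty_impurities, _empty_molecules


@pytest.fixture
def tiny_optics() -> OpticsConfig:
    """Small frames for fast geometric tests; full-scale physics otherwise."""
    return OpticsConfig(frame_shape=(64, 56))


@pytest.fixture
def tiny_lane() -> LaneGeometry:
    return LaneGeometry(
        n_frames=12,
        lane_width_um=24.0,
        depth_min_um=3.0,
        depth_max_um=12.0,
        width_offset_px=8,
        interface_start_px=8.0,
        interface_end_px=10.0,
    )


@pytest.fixture
def tiny_crop() -> CropSpec:
    return CropSpec(
        height_px=40, width_px=40, start_height_px=8.0, end_height_px=10.0,
        width_offset_px=4, allowed_widths=(40,),
    )


@pytest.fixture
def quiet_noise() -> NoiseConfig:
    return NoiseConfig(background=0.0, read_sd=0.0)


def make_truth(
    molecules: "list[tuple[float, float, float, float]]",
    lane: LaneGeometry,
    lane_length_um: float = 700.0,
    seed: int = 0,
) -> GroundTruth:
    """Ground truth from explicit (migration, lateral, depth, brightness)."""
    if molecules:
        table = pd.DataFrame(
            molecules, columns=["migration_um", "lateral_um", "depth_um", "brightness"]
        )
        table.insert(0, "band_id", np.zeros(len(molecules), dtype=int))
    else:
        table = _empty_molecules()
    return GroundTruth(
        molecules=table,
        impurities=_empty_impurities(),
        noise_seed=seed,
        lane_length_um=lane_length_um,
        lane=lane,
    )
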