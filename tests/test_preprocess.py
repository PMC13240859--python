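"""Background subtraction, offset interpolation and cropping."""

import numpy as np
import pytest
from scipy import ndimage as ndi

from tiltgel.config import CropSpec, ParameterError
from tiltgel.preprocess import (
    crop_frame,
    find_interface_row,
    interpolate_offsets,
    rolling_ball_background,
    subtract_background,
)
from tiltgel.simulate import render_stack

from conftest import make_truth


def scipy_ball_opening(frame: np.ndarray, radius: int) -> np.ndarray:
    """Independent rolling-ball oracle: grayscale opening with a
    hemisphere structuring element via scipy nonflat morphology."""
    yy, xx = np.mgrid[-radius : radius + 1, -radius : radius + 1]
    d2 = yy**2 + xx**2
    mask = d2 <= radius * radius
    heights = np.where(mask, np.sqrt(np.clip(radius * radius - d2, 0, None)), 0.0)
    f = frame.astype(np.float64)
    eroded = ndi.grey_erosion(f, structure=heights, footprint=mask, mode="nearest")
    return ndi.grey_dilation(eroded, structure=heights, footprint=mask, mode="nearest")


class TestSubtractBackground:
    def test_constant_frame_maps_to_zero(self):
        frame = np.full((80, 80), 137, dtype=np.uint16)
        assert (subtract_background(frame, 25) == 0).all()

    def test_isolated_peak_survives_subtraction(self):
        frame = np.full((80, 80), 50, dtype=np.uint16)
        frame[40, 40] = 5050  # peak height h = 5000 over the plateau
        out = subtract_background(frame, 25)
        assert out[40, 40] >= 0.9 * 5000

    def test_matches_scipy_ball_opening_oracle(self):
        rng = np.random.default_rng(0)
        frame = rng.poisson(300, size=(90, 90)).astype(np.uint16)
        ours = rolling_ball_background(frame, 25)
        oracle = scipy_ball_opening(frame, 25)
        assert np.allclose(ours, oracle, atol=1e-9)

    def test_idempotent_on_two_level_images(self):
        frame = np.full((80, 80), 40, dtype=np.uint16)
        frame[20, 30] = 3000
        frame[55, 60] = 1500
        once = subtract_background(frame, 25)
        twice = subtract_background(once, 25)
        assert np.array_equal(once, twice)

    def test_preserves_integer_dtype(self):
        frame = np.full((60, 60), 99, dtype=np.uint16)
        assert subtract_background(frame, 25).dtype == np.uint16

    @pytest.mark.parametrize("radius", [0, -3])
    def test_invalid_radius_rejected(self, radius):
        with pytest.raises(ParameterError):
            subtract_background(np.zeros((60, 60), dtype=np.uint16), radius)

    def test_radius_larger_than_frame_rejected(self):
        with pytest.raises(ParameterError):
            subtract_background(np.zeros((30, 30), dtype=np.uint16), 25)


class TestInterpolateOffsets:
    @pytest.mark.parametrize(
        "start, end, n, expected",
        [
            (10, 10, 5, [10, 10, 10, 10, 10]),
            (0, 4, 5, [0, 1, 2, 3, 4]),
            (0, 1, 3, [0, 1, 1]),  # round-half-up at the midpoint
            (7, 7, 1, [7]),
        ],
    )
    def test_linear_interpolation(self, start, end, n, expected):
        assert interpolate_offsets(start, end, n) == expected

    def test_monotone_between_endpoints(self):
        offsets = interpolate_offsets(3, 19, 37)
        assert len(offsets) == 37
        assert all(b >= a for a, b in zip(offsets, offsets[1:]))

    def test_zero_frames_rejected(self):
        with pytest.raises(ParameterError):
            interpolate_offsets(0, 1, 0)


class TestCropFrame:
    def test_top_left_block(self):
        frame = np.arange(512 * 512, dtype=np.uint16).reshape(512, 512)
        spec = CropSpec(height_px=150, width_px=312)
        out = crop_frame(frame, spec, 0, [0])
        assert out.shape == (150, 312)
        assert np.array_equal(out, frame[:150, :312])

    def test_default_widths_match_gel_geometry(self):
        assert CropSpec().height_px == 150
        assert CropSpec().allowed_widths == (312, 412)
        CropSpec(width_px=412)  # both published widths are accepted
        with pytest.raises(ParameterError):
            CropSpec(width_px=300)

    def test_out_of_bounds_error_names_frame(self):
        frame = np.zeros((100, 100), dtype=np.uint16)
        spec = CropSpec(height_px=80, width_px=60, allowed_widths=(60,))
        with pytest.raises(ParameterError, match="frame index 3"):
            crop_frame(frame, spec, 3, [0, 0, 0, 50])

    def test_cropping_only_selects_pixels(self):
        rng = np.random.default_rng(2)
        frame = rng.integers(0, 1000, size=(100, 100), dtype=np.uint16)
        spec = CropSpec(height_px=40, width_px=40, width_offset_px=10,
                        allowed_widths=(40,))
        out = crop_frame(frame, spec, 0, [20])
        assert np.array_equal(out, frame[20:60, 10:50])
        assert out.sum() <= frame.sum()

    def test_drifting_interface_lands_on_constant_row(
        self, tiny_optics, tiny_lane, quiet_noise
    ):
        """With offsets interpolated from the interface drift, the bright
        interface line sits at a constant row in every cropped frame."""
        truth = make_truth([], tiny_lane)
        stack = render_stack(truth, tiny_optics, quiet_noise, seed=0)
        # crop a window that includes the scatter line (it sits
        # line_clearance_px above the gel window)
        clearance = int(tiny_lane.line_clearance_px)
        offsets = [
            o - clearance - 2
            for o in interpolate_offsets(
                tiny_lane.interface_start_px, tiny_lane.interface_end_px, stack.n_frames
            )
        ]
        spec = CropSpec(height_px=20, width_px=40, width_offset_px=4,
                        allowed_widths=(40,))
        rows = []
        for i in range(stack.n_frames):
            rows.append(find_interface_row(crop_frame(stack.frames[i], spec, i, offsets)))
        assert max(rows) - min(rows) <= 1
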