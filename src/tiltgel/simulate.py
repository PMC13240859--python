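"""Synthetic tilted light-sheet gel-scan generator with ground truth.

The simulator emulates the acquisition this package analyzes: bands of
fluorescently labeled molecules resolved along a gel lane, imaged by an
optical slice tilted ``tilt_deg`` from the gel plane while the stage
steps ``step_um`` along the electrophoresis axis.

Geometry
--------
Lab coordinates are ``y`` (stage/electrophoresis axis, um), ``z`` (depth
above the glass, um) and ``x`` (lateral, um).  Frame ``i`` images the
plane through ``(y = i * step_um, z = 0)`` whose in-plane direction in
(y, z) is ``(cos t, sin t)``; the signed perpendicular distance of a
point to that plane is ``d = (y - s_i) sin t - z cos t``.  A molecule is
visible in frame ``i`` iff ``|d| <= slab_thickness_um / 2`` and renders
as a 2D Gaussian whose peak is attenuated by ``exp(-d^2 / (2 (slab/4)^2))``.

Migration positions are expressed on the projected-axis scale
``m = y cos t + z sin t`` (um along the tilted plane), the same scale on
which the downstream shift-and-max projection and the migration
profiles report distances.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .config import (
    BandSpec,
    ImpuritySpec,
    LaneGeometry,
    NoiseConfig,
    OpticsConfig,
    ParameterError,
)
from .stack import ScanStack

__all__ = [
    "GroundTruth",
    "sample_molecules",
    "inject_impurities",
    "render_stack",
    "visible_frames",
    "frames_to_cover",
    "covered_migration_range",
    "expected_spots",
]

MOLECULE_COLUMNS = ["band_id", "migration_um", "lateral_um", "depth_um", "brightness"]
IMPURITY_COLUMNS = ["migration_um", "lateral_um", "depth_um", "brightness", "diameter_px"]


@dataclass
class GroundTruth:
    """True molecule and impurity record of one simulated lane.

    ``molecules`` and ``impurities`` are DataFrames with the columns in
    :data:`MOLECULE_COLUMNS` / :data:`IMPURITY_COLUMNS`.  The seed and
    lane geometry are recorded so stacks are exactly reproducible.
    """

    molecules: pd.DataFrame
    impurities: pd.DataFrame
    noise_seed: int
    lane_length_um: float
    lane: LaneGeometry = field(default_factory=LaneGeometry)

    @property
    def interface_heights(self) -> tuple[float, float]:
        return (self.lane.interface_start_px, self.lane.interface_end_px)

    @property
    def n_molecules(self) -> int:
        return len(self.molecules)

    def to_frame(self) -> pd.DataFrame:
        """Combined long-format table (one row per molecule or impurity)."""
        mol = self.molecules.copy()
        mol["is_impurity"] = False
        mol["diameter_px"] = np.nan
        imp = self.impurities.copy()
        imp["is_impurity"] = True
        imp["band_id"] = -1
        cols = ["band_id", "migration_um", "lateral_um", "depth_um",
                "brightness", "is_impurity", "diameter_px"]
        return pd.concat([mol[cols], imp[cols]], ignore_index=True)


def _empty_molecules() -> pd.DataFrame:
    return pd.DataFrame({c: pd.Series(dtype=float) for c in MOLECULE_COLUMNS})


def _empty_impurities() -> pd.DataFrame:
    return pd.DataFrame({c: pd.Series(dtype=float) for c in IMPURITY_COLUMNS})


def sample_molecules(
    bands: list[BandSpec],
    lane_length_um: float,
    seed: int,
    lane: LaneGeometry | None = None,
) -> GroundTruth:
    """Draw the true molecule population of one lane.

    Per band the molecule count is Poisson(``expected_count``); migration
    positions are Normal(center, width) truncated to ``[0, lane_length_um]``;
    lateral and depth positions are uniform over the lane cross-section.
    """
    if lane_length_um <= 0:
        raise ParameterError("lane_length_um must be > 0")
    lane = lane if lane is not None else LaneGeometry()
    rng = np.random.default_rng(seed)
    parts = []
    for band_id, band in enumerate(bands):
        n = int(rng.poisson(band.expected_count))
        if n == 0:
            continue
        a = (0.0 - band.center_um) / band.width_um
        b = (lane_length_um - band.center_um) / band.width_um
        migration = stats.truncnorm.rvs(
            a, b, loc=band.center_um, scale=band.width_um, size=n, random_state=rng
        )
        brightness = np.maximum(
            rng.normal(band.brightness_mean, band.brightness_sd, size=n), 1.0
        )
        parts.append(
            pd.DataFrame(
                {
                    "band_id": np.full(n, band_id, dtype=int),
                    "migration_um": migration,
                    "lateral_um": rng.uniform(0.0, lane.lane_width_um, size=n),
                    "depth_um": rng.uniform(lane.depth_min_um, lane.depth_max_um, size=n),
                    "brightness": brightness,
                }
            )
        )
    molecules = (
        pd.concat(parts, ignore_index=True) if parts else _empty_molecules()
    )
    return GroundTruth(
        molecules=molecules,
        impurities=_empty_impurities(),
        noise_seed=int(seed),
        lane_length_um=float(lane_length_um),
        lane=lane,
    )


def inject_impurities(truth: GroundTruth, spec: ImpuritySpec, seed: int) -> GroundTruth:
    """Append random impurities to a lane; molecules are unchanged.

    Impurities are placed over the central part of the lane (30-90 % of
    its length) so that every one of them falls inside the scanned
    migration window and is actually rendered.
    """
    rng = np.random.default_rng(seed)
    n = spec.count
    if n == 0:
        return replace(truth, impurities=truth.impurities.copy())
    lane = truth.lane
    imp = pd.DataFrame(
        {
            "migration_um": rng.uniform(
                0.3 * truth.lane_length_um, 0.9 * truth.lane_length_um, size=n
            ),
            "lateral_um": rng.uniform(
                0.1 * lane.lane_width_um, 0.9 * lane.lane_width_um, size=n
            ),
            "depth_um": rng.uniform(lane.depth_min_um, lane.depth_max_um, size=n),
            "brightness": rng.uniform(*spec.intensity_range, size=n),
            "diameter_px": rng.uniform(*spec.diameter_range, size=n),
        }
    )
    return replace(
        truth, impurities=pd.concat([truth.impurities, imp], ignore_index=True)
    )


# ---------------------------------------------------------------------------
# geometry helpers


def _angles(optics: OpticsConfig) -> tuple[float, float]:
    t = math.radians(optics.tilt_deg)
    return math.sin(t), math.cos(t)


def _y_from_migration(m: np.ndarray, z: np.ndarray, optics: OpticsConfig) -> np.ndarray:
    sin_t, cos_t = _angles(optics)
    return (m - z * sin_t) / cos_t


def visible_frames(
    migration_um: float, depth_um: float, optics: OpticsConfig, n_frames: int
) -> list[int]:
    """Frame indices whose tilted slab contains the given point.

    The geometric oracle for visibility: frame ``i`` sees the point iff
    its perpendicular distance to plane ``i`` is at most slab/2.
    """
    sin_t, cos_t = _angles(optics)
    y = (migration_um - depth_um * sin_t) / cos_t
    half = optics.slab_thickness_um / 2.0
    s_lo = y - (depth_um * cos_t + half) / sin_t
    s_hi = y - (depth_um * cos_t - half) / sin_t
    i_lo = max(0, math.ceil(s_lo / optics.step_um - 1e-9))
    i_hi = min(n_frames - 1, math.floor(s_hi / optics.step_um + 1e-9))
    return list(range(i_lo, i_hi + 1))


def frames_to_cover(
    migration_um: float, optics: OpticsConfig, lane: LaneGeometry
) -> int:
    """Number of frames needed so every molecule up to ``migration_um``
    (at any depth in the lane) is imaged in at least one frame."""
    sin_t, cos_t = _angles(optics)
    y_max = (migration_um - lane.depth_min_um * sin_t) / cos_t
    s_max = y_max - (lane.depth_min_um * cos_t - optics.slab_thickness_um / 2.0) / sin_t
    return int(math.ceil(s_max / optics.step_um)) + 1


def covered_migration_range(
    optics: OpticsConfig, lane: LaneGeometry
) -> tuple[float, float]:
    """Conservative migration interval fully covered by the scan.

    Molecules whose migration position lies inside the returned interval
    are guaranteed visible in at least one frame, at any depth in the
    lane cross-section.
    """
    sin_t, cos_t = _angles(optics)
    half = optics.slab_thickness_um / 2.0
    m_lo = lane.depth_max_um / sin_t + half * cos_t / sin_t + optics.step_um * cos_t
    s_max = (lane.n_frames - 1) * optics.step_um
    m_hi = (
        s_max * cos_t
        + lane.depth_min_um / sin_t
        - half * cos_t / sin_t
        - optics.step_um * cos_t
    )
    return (m_lo, m_hi)


def _interface_height(lane: LaneGeometry, i: int, n_frames: int) -> float:
    if n_frames == 1:
        return lane.interface_start_px
    frac = i / (n_frames - 1)
    return lane.interface_start_px + (lane.interface_end_px - lane.interface_start_px) * frac


def _emitter_placements(
    truth: GroundTruth, optics: OpticsConfig, lane: LaneGeometry, n_frames: int
) -> "list[tuple[int, float, float, float, float]]":
    """Expand emitters to per-frame stamps: (frame, row, col, amplitude, sigma_px).

    Rows are relative to the interface height of the frame (the crop
    origin); the caller adds the per-frame interface row.
    """
    sin_t, cos_t = _angles(optics)
    atten_sd = optics.slab_thickness_um / 4.0
    out = []
    # molecules are point emitters and dim with distance from the slab
    # center; impurities (aggregates, dust) are extended objects that
    # span the slab and render at full brightness in every frame that
    # sees them.
    tables = [
        (truth.molecules, float(optics.psf_sigma_px), None),
        (truth.impurities, None, "diameter_px"),
    ]
    for table, fixed_sigma, diam_col in tables:
        if len(table) == 0:
            continue
        m = table["migration_um"].to_numpy(float)
        x = table["lateral_um"].to_numpy(float)
        z = table["depth_um"].to_numpy(float)
        bright = table["brightness"].to_numpy(float)
        sigma = (
            np.full(len(table), fixed_sigma)
            if diam_col is None
            else table[diam_col].to_numpy(float) / (2.0 * math.sqrt(2.0))
        )
        y = (m - z * sin_t) / cos_t
        for k in range(len(table)):
            for i in visible_frames(m[k], z[k], optics, n_frames):
                s_i = i * optics.step_um
                d = (y[k] - s_i) * sin_t - z[k] * cos_t
                if diam_col is None:
                    amp = bright[k] * math.exp(-(d * d) / (2.0 * atten_sd * atten_sd))
                else:
                    amp = bright[k]
                row = ((y[k] - s_i) * cos_t + z[k] * sin_t) / optics.pixel_um
                col = lane.width_offset_px + x[k] / optics.pixel_um
                out.append((i, row, col, amp, float(sigma[k])))
    return out


def _stamp_gaussian(
    frame: np.ndarray, row: float, col: float, amp: float, sigma: float
) -> None:
    h, w = frame.shape
    halfwin = int(math.ceil(4.0 * sigma)) + 1
    r0, r1 = int(math.floor(row)) - halfwin, int(math.floor(row)) + halfwin + 1
    c0, c1 = int(math.floor(col)) - halfwin, int(math.floor(col)) + halfwin + 1
    r0c, r1c = max(r0, 0), min(r1, h)
    c0c, c1c = max(c0, 0), min(c1, w)
    if r0c >= r1c or c0c >= c1c:
        return
    rr = np.arange(r0c, r1c, dtype=float)[:, None] - row
    cc = np.arange(c0c, c1c, dtype=float)[None, :] - col
    frame[r0c:r1c, c0c:c1c] += amp * np.exp(-(rr * rr + cc * cc) / (2.0 * sigma * sigma))


def render_stack(
    truth: GroundTruth,
    optics: OpticsConfig,
    noise: NoiseConfig | None = None,
    seed: int | None = None,
    lane_id: str = "lane",
) -> ScanStack:
    """Render a ground-truth lane into a 16-bit frame stack.

    The noiseless signal is the sum of a bright gel/glass interface line
    (drifting linearly across frames), the molecule spots and the
    impurity spots; camera noise is Poisson(signal + background) shot
    noise plus Gaussian read noise, quantized to integers and clipped to
    ``[0, bit_depth_max]``.  Identical (truth, optics, noise, seed)
    produce a bit-identical stack.
    """
    noise = noise if noise is not None else NoiseConfig()
    seed = truth.noise_seed if seed is None else seed
    lane = truth.lane
    n = lane.n_frames
    h, w = optics.frame_shape
    signal = np.zeros((n, h, w), dtype=np.float64)

    rows = np.arange(h, dtype=float)
    for i in range(n):
        # bright scatter line at the glass side of the interface, just
        # above the gel crop window (which starts at the interface height)
        line_row = _interface_height(lane, i, n) - lane.line_clearance_px
        line = lane.interface_intensity * np.exp(
            -((rows - line_row) ** 2) / (2.0 * 0.8**2)
        )
        signal[i] += line[:, None]

    for i, row, col, amp, sigma in _emitter_placements(truth, optics, lane, n):
        h_i = _interface_height(lane, i, n)
        _stamp_gaussian(signal[i], h_i + row, col, amp, sigma)

    rng = np.random.default_rng(seed)
    img = rng.poisson(signal + noise.background).astype(np.float64)
    if noise.read_sd > 0:
        img += rng.normal(0.0, noise.read_sd, size=img.shape)
    img = np.clip(np.rint(img), 0, optics.bit_depth_max).astype(np.uint16)
    return ScanStack(frames=img, optics=optics, lane_id=lane_id, origin_frame=0)


def expected_spots(
    truth: GroundTruth,
    optics: OpticsConfig,
    crop,
    shift_px: float = 11.0,
    include_impurities: bool = False,
) -> pd.DataFrame:
    """Predicted projection coordinates of every ground-truth emitter.

    Propagates each emitter through the ideal imaging geometry *and* the
    pipeline's actual discretization: the frame in which it appears
    brightest, the crop offsets rounded exactly as the preprocessing
    stage rounds them, and the integer per-frame shift of the
    projection.  Used to match detections back to ground truth.
    """
    from .preprocess import interpolate_offsets
    from .project import placement_offsets

    lane = truth.lane
    n = lane.n_frames
    offsets = interpolate_offsets(crop.start_height_px, crop.end_height_px, n)
    shifts = placement_offsets(shift_px, n)
    sin_t, cos_t = _angles(optics)
    atten_sd = optics.slab_thickness_um / 4.0

    tables = [truth.molecules]
    kinds = [np.zeros(len(truth.molecules), dtype=bool)]
    if include_impurities:
        tables.append(truth.impurities)
        kinds.append(np.ones(len(truth.impurities), dtype=bool))

    recs = []
    for table, is_imp in zip(tables, kinds):
        for k in range(len(table)):
            m = float(table["migration_um"].iloc[k])
            x = float(table["lateral_um"].iloc[k])
            z = float(table["depth_um"].iloc[k])
            y = (m - z * sin_t) / cos_t
            frames = visible_frames(m, z, optics, n)
            if not frames:
                continue
            best, best_amp, best_row = None, -1.0, 0.0
            for i in frames:
                s_i = i * optics.step_um
                d = (y - s_i) * sin_t - z * cos_t
                amp = math.exp(-(d * d) / (2.0 * atten_sd * atten_sd))
                if amp > best_amp:
                    row = ((y - s_i) * cos_t + z * sin_t) / optics.pixel_um
                    best, best_amp, best_row = i, amp, row
            h_i = _interface_height(lane, best, n)
            cropped_row = h_i + best_row - offsets[best]
            p = cropped_row + shifts[best]
            col = lane.width_offset_px + x / optics.pixel_um - crop.width_offset_px
            recs.append((p, col, bool(is_imp[k])))
    return pd.DataFrame(recs, columns=["p_px", "col_px", "is_impurity"])
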