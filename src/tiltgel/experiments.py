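"""Desk-scale synthetic studies validating the full pipeline.

Full-scale gel scans (1.6 cm, ~1490 frames of 512 x 512 px) are far
larger than needed to exercise every stage, so the validation studies
run on a proportionally scaled-down lane: 80 frames of 168 x 96 px
covering ~700 um of migration, with an antibody-analogue band at
250 um and three sample bands at 330, 470 and 610 um (the full-scale
analogues sit at 3500 um and at 4500/6500/11000 um).  All acquisition
physics — tilt, stage step, pixel size, slab thickness, camera noise,
crop height, rolling-ball radius, detection and filter settings,
binning — keep their full-scale values.

Each study returns a plain dict of measured quantities; the same
functions back the test suite and the acceptance script.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .config import (
    BandSpec,
    BinningConfig,
    CropSpec,
    DetectionConfig,
    ImpuritySpec,
    LaneGeometry,
    NoiseConfig,
    OpticsConfig,
)
from .detect import detect_blobs, filter_particles, match_points
from .pca import run_pca
from .preprocess import preprocess_stack
from .profiles import build_matrix, build_profile, replicate_sd
from .project import deskew_oracle, project_shift_max
from .simulate import (
    GroundTruth,
    expected_spots,
    inject_impurities,
    render_stack,
    sample_molecules,
)

__all__ = [
    "StudyConditions",
    "desk_conditions",
    "simulate_lane",
    "process_lane",
    "study_projection_equivalence",
    "study_detection_recovery",
    "study_dilution_linearity",
    "study_replicate_variability",
    "study_pca_heterogeneity",
]

#: integer per-frame shift of the projection (the pipeline default)
SHIFT_PX = 11

#: sample bands of the desk-scale lane (migration um, SD um, mean
#: count); spaced wider than the 80-um smoothing span so adjacent bands
#: remain resolvable in smoothed profiles
DESK_BANDS = [
    BandSpec(center_um=c, width_um=30.0, expected_count=120)
    for c in (340.0, 430.0, 520.0, 610.0, 700.0, 790.0)
]
#: the three bands boosted in the heterogeneous sub-population of the
#: PCA study, interleaved with unboosted bands so the band-specific
#: contrast is distinct from the overall expression level
DESK_DESIGNATED_UM = (430.0, 610.0, 790.0)
#: antibody-analogue band excluded by the cutoff stage; like the
#: full-length antibody peak it dominates the profile, which is what
#: makes the trailing-half-maximum cutoff well defined
DESK_ANTIBODY = BandSpec(center_um=250.0, width_um=28.0, expected_count=1600)
DESK_LANE_LENGTH_UM = 1000.0


@dataclass
class StudyConditions:
    """The fixed desk-scale acquisition and analysis conditions."""

    optics: OpticsConfig = field(
        default_factory=lambda: OpticsConfig(frame_shape=(168, 96))
    )
    lane: LaneGeometry = field(
        default_factory=lambda: LaneGeometry(
            n_frames=114,
            lane_width_um=56.0,
            width_offset_px=12,
            interface_start_px=8.0,
            interface_end_px=12.0,
        )
    )
    crop: CropSpec = field(
        default_factory=lambda: CropSpec(
            height_px=150,
            width_px=80,
            start_height_px=8.0,
            end_height_px=12.0,
            width_offset_px=8,
            allowed_widths=(80,),
        )
    )
    detection: DetectionConfig = field(default_factory=DetectionConfig)
    binning: BinningConfig = field(
        default_factory=lambda: BinningConfig(
            n_bins=70, search_window_um=(180.0, 320.0)
        )
    )
    noise: NoiseConfig = field(default_factory=NoiseConfig)


def desk_conditions() -> StudyConditions:
    return StudyConditions()


def simulate_lane(
    bands: list[BandSpec],
    conds: StudyConditions,
    sample_seed: int,
    noise_seed: int | None = None,
    impurities: ImpuritySpec | None = None,
    min_separation_px: float = 0.0,
):
    """Sample and render one desk-scale lane; returns (truth, stack).

    ``min_separation_px`` > 0 sequentially thins molecules closer than
    that distance in the projection — the well-separated sparse regime
    in which per-molecule recovery is meaningful.
    """
    truth = sample_molecules(bands, DESK_LANE_LENGTH_UM, sample_seed, conds.lane)
    if min_separation_px > 0 and truth.n_molecules:
        spots = expected_spots(truth, conds.optics, conds.crop, SHIFT_PX)
        pts = spots[["p_px", "col_px"]].to_numpy(float)
        keep = np.ones(len(pts), dtype=bool)
        for i in range(1, len(pts)):
            d = np.hypot(*(pts[:i][keep[:i]] - pts[i]).T)
            if len(d) and d.min() < min_separation_px:
                keep[i] = False
        truth = replace(truth, molecules=truth.molecules[keep].reset_index(drop=True))
    if impurities is not None:
        truth = inject_impurities(truth, impurities, sample_seed + 7919)
    stack = render_stack(
        truth, conds.optics, conds.noise,
        seed=noise_seed if noise_seed is not None else sample_seed,
    )
    return truth, stack


def process_lane(stack, conds: StudyConditions, shift_px: float = SHIFT_PX):
    """Run the analysis stages on one stack: (projection, kept, removed)."""
    cropped = preprocess_stack(stack, conds.crop)
    projection = project_shift_max(cropped, shift_px, conds.optics)
    particles = detect_blobs(projection, conds.detection)
    kept, removed = filter_particles(particles, conds.detection)
    return projection, kept, removed


def _aligned_match_pct(
    spots_a: np.ndarray, spots_b: np.ndarray, tol_px: float = 2.0
) -> float:
    """Fraction (%) of spots matching within tol after global translation.

    The two projections use different canvas origins, so the point sets
    are registered by the median offset of loosely matched pairs before
    the strict comparison.
    """
    pairs = match_points(spots_a, spots_b, tol_px=6.0)
    if not pairs:
        return 0.0
    deltas = np.array([spots_a[i] - spots_b[j] for i, j in pairs])
    offset = np.median(deltas, axis=0)
    pairs = match_points(spots_a - offset, spots_b, tol_px=tol_px)
    return 100.0 * len(pairs) / max(len(spots_a), len(spots_b))


def study_projection_equivalence(
    seed: int, n_stacks: int = 12, tol_px: float = 2.0
) -> dict:
    """Shift-and-max vs brute-force deskew on sparse 20-frame stacks.

    Each stack holds ~5 sparse molecules; spots are detected in both
    projections and matched one-to-one.  Reports the percentage of
    spots agreeing within ``tol_px``.
    """
    conds = desk_conditions()
    conds.lane = replace(conds.lane, n_frames=20)
    band = [BandSpec(center_um=130.0, width_um=20.0, expected_count=5,
                     brightness_mean=8000.0, brightness_sd=800.0)]
    matched_pct = []
    n_spots = 0
    for k in range(n_stacks):
        truth, stack = simulate_lane(
            band, conds, sample_seed=seed + 101 * k, min_separation_px=4.0
        )
        if truth.n_molecules == 0:
            continue
        cropped = preprocess_stack(stack, conds.crop)
        proj = project_shift_max(cropped, SHIFT_PX, conds.optics)
        oracle_img = deskew_oracle(cropped, conds.optics)
        from .project import ProjectionImage

        blobs_a = detect_blobs(proj, conds.detection)
        blobs_b = detect_blobs(
            ProjectionImage(pixels=oracle_img, pixel_um=conds.optics.pixel_um),
            conds.detection,
        )
        kept_a, _ = filter_particles(blobs_a, conds.detection)
        kept_b, _ = filter_particles(blobs_b, conds.detection)
        a = kept_a[["y_px", "x_px"]].to_numpy(float)
        b = kept_b[["y_px", "x_px"]].to_numpy(float)
        if len(a) == 0 or len(b) == 0:
            continue
        matched_pct.append(_aligned_match_pct(a, b, tol_px) * max(len(a), len(b)))
        n_spots += max(len(a), len(b))
    pct = float(np.sum(matched_pct) / n_spots) if n_spots else 0.0
    return {"match_pct": pct, "n_spots": int(n_spots)}


def study_detection_recovery(seed: int, n_lanes: int = 3) -> dict:
    """End-to-end recall / spurious rate / impurity removal.

    High-SNR sparse lanes (molecules thinned to > 3 px separation in
    projection) with injected impurities violating the filter rules.
    """
    conds = desk_conditions()
    bands = [
        BandSpec(200.0, 25.0, 40, brightness_mean=8000.0, brightness_sd=800.0),
        BandSpec(350.0, 40.0, 40, brightness_mean=8000.0, brightness_sd=800.0),
        BandSpec(520.0, 45.0, 40, brightness_mean=8000.0, brightness_sd=800.0),
    ]
    imp_spec = ImpuritySpec(count=5)
    matched = n_truth = n_kept = spurious = 0
    impurities_total = impurities_removed = 0
    for k in range(n_lanes):
        truth, stack = simulate_lane(
            bands, conds, sample_seed=seed + 977 * k,
            impurities=imp_spec, min_separation_px=3.0,
        )
        _, kept, _removed = process_lane(stack, conds)
        spots = expected_spots(
            truth, conds.optics, conds.crop, SHIFT_PX, include_impurities=True
        )
        mol = spots[~spots["is_impurity"]][["p_px", "col_px"]].to_numpy(float)
        imp = spots[spots["is_impurity"]][["p_px", "col_px"]].to_numpy(float)
        det = kept[["y_px", "x_px"]].to_numpy(float)
        pairs = match_points(det, mol, tol_px=2.0)
        matched += len(pairs)
        n_truth += len(mol)
        n_kept += len(det)
        spurious += len(det) - len(pairs)
        impurities_total += len(imp)
        imp_hits = match_points(det, imp, tol_px=2.5)
        impurities_removed += len(imp) - len(imp_hits)
    return {
        "recall_pct": 100.0 * matched / n_truth if n_truth else 0.0,
        "spurious_pct": 100.0 * spurious / n_kept if n_kept else 0.0,
        "impurity_removed_pct": (
            100.0 * impurities_removed / impurities_total if impurities_total else 0.0
        ),
        "n_molecules": int(n_truth),
        "n_impurities": int(impurities_total),
    }


def study_dilution_linearity(
    seed: int, loadings: tuple[float, ...] = (0.25, 0.5, 1.0), n_reps: int = 3
) -> dict:
    """Total kept counts at relative loadings of one fixed band set.

    The analogue of serial lysate dilution: every band's expected count
    is scaled by the loading; the measured totals should recover the
    loading ratios within Poisson counting error.
    """
    conds = desk_conditions()
    # moderate counts keep the scene sparse enough that blob merging is
    # negligible relative to Poisson error - the regime in which the
    # linearity comparison is meaningful
    base = [
        BandSpec(330.0, 45.0, 80), BandSpec(470.0, 50.0, 85),
        BandSpec(610.0, 55.0, 80),
    ]
    totals = {}
    for li, loading in enumerate(loadings):
        bands = [replace(b, expected_count=b.expected_count * loading) for b in base]
        count = 0
        for r in range(n_reps):
            _, stack = simulate_lane(
                bands, conds, sample_seed=seed + 1009 * li + 131 * r
            )
            _, kept, _ = process_lane(stack, conds)
            count += len(kept)
        totals[loading] = count
    ref = max(loadings)
    out = {"totals": {str(k): int(v) for k, v in totals.items()}}
    for loading in loadings:
        if loading == ref:
            continue
        ratio = totals[loading] / totals[ref]
        se = ratio * math.sqrt(1.0 / max(totals[loading], 1) + 1.0 / max(totals[ref], 1))
        out[f"ratio_{loading}"] = float(ratio)
        out[f"se_{loading}"] = float(se)
    return out


def _variability_profiles(
    seed: int, n_reps: int, mode: str, conds: StudyConditions, band_cv: float = 0.35
):
    """Replicate lanes in 'pseudo' (shared truth, camera noise only) or
    'single' (per-lane band-count resampling) mode."""
    bands = [DESK_ANTIBODY] + DESK_BANDS
    profiles = []
    rng = np.random.default_rng(seed + 555)
    shared_truth: GroundTruth | None = None
    for r in range(n_reps):
        if mode == "pseudo":
            if shared_truth is None:
                shared_truth = sample_molecules(
                    bands, DESK_LANE_LENGTH_UM, seed, conds.lane
                )
            truth = shared_truth
        else:
            factors = np.exp(rng.normal(0.0, band_cv, size=len(bands)))
            lane_bands = [
                replace(b, expected_count=b.expected_count * f)
                for b, f in zip(bands, factors)
            ]
            truth = sample_molecules(
                lane_bands, DESK_LANE_LENGTH_UM, seed + 31 * (r + 1), conds.lane
            )
        stack = render_stack(truth, conds.optics, conds.noise, seed=seed + 7000 + r)
        _, kept, _ = process_lane(stack, conds)
        profiles.append(
            build_profile(
                kept, conds.binning, conds.optics.pixel_um,
                lane_id=f"{mode}_{r}", condition_label=mode,
            )
        )
    return profiles


def study_replicate_variability(seed: int, n_reps: int = 4) -> dict:
    """Median per-bin SD: technical replicates vs single-cell replicates.

    Pseudo-single-cell lanes share one ground truth and differ only in
    camera noise; single-cell lanes resample every band's molecule count
    per lane.  The single-cell median SD must exceed the technical one.
    """
    conds = desk_conditions()
    pseudo = _variability_profiles(seed, n_reps, "pseudo", conds)
    single = _variability_profiles(seed, n_reps, "single", conds)
    cutoff = max(p.cutoff_um for p in pseudo + single if p.cutoff_um is not None)
    _, median_pseudo = replicate_sd(pseudo, cutoff_um=cutoff)
    _, median_single = replicate_sd(single, cutoff_um=cutoff)
    return {
        "median_sd_pseudo": float(median_pseudo),
        "median_sd_single": float(median_single),
        "n_reps": n_reps,
        "cutoff_um": float(cutoff),
    }


#: migration-axis compression of the integer-11 shift relative to the
#: exact geometric shift (11 / 11.146); used to predict where a band
#: lands on the projected axis.
def _projected_band_um(center_um: float, conds: StudyConditions) -> float:
    from .project import geometric_shift_px

    return center_um * SHIFT_PX / geometric_shift_px(conds.optics)


def study_pca_heterogeneity(
    seed: int, n_untreated: int = 8, n_treated: int = 8, top_k: int = 9
) -> dict:
    """Two-sub-population simulation and PCA decomposition.

    Untreated lanes draw from the baseline band set (Poisson noise
    only).  Treated lanes get a global 1.5x boost of every sample band
    and split into two sub-populations, one of which additionally
    doubles the three designated bands (interleaved with unboosted
    bands).  Reports the cluster separation of the treated sub-groups
    along the best-separating component, the untreated/treated score
    spread ratio, and how many designated bands appear among that
    component's top-|loading| bins.
    """
    conds = desk_conditions()
    bands = [DESK_ANTIBODY] + DESK_BANDS
    designated = list(DESK_DESIGNATED_UM)
    profiles = []
    labels = []
    for r in range(n_untreated):
        truth = sample_molecules(bands, DESK_LANE_LENGTH_UM, seed + 11 * r, conds.lane)
        stack = render_stack(truth, conds.optics, conds.noise, seed=seed + 900 + r)
        _, kept, _ = process_lane(stack, conds)
        profiles.append(build_profile(kept, conds.binning, conds.optics.pixel_um,
                                      lane_id=f"untreated_{r}", condition_label="untreated"))
        labels.append("untreated")
    for r in range(n_treated):
        subpop = "hi" if r % 2 else "lo"
        lane_bands = []
        for b in bands:
            factor = 1.0 if b is DESK_ANTIBODY else 1.5
            if subpop == "hi" and b.center_um in designated:
                factor *= 2.0
            lane_bands.append(replace(b, expected_count=b.expected_count * factor))
        truth = sample_molecules(
            lane_bands, DESK_LANE_LENGTH_UM, seed + 2203 + 17 * r, conds.lane
        )
        stack = render_stack(truth, conds.optics, conds.noise, seed=seed + 990 + r)
        _, kept, _ = process_lane(stack, conds)
        profiles.append(build_profile(kept, conds.binning, conds.optics.pixel_um,
                                      lane_id=f"treated_{subpop}_{r}",
                                      condition_label=f"treated_{subpop}"))
        labels.append(f"treated_{subpop}")
    matrix = build_matrix(profiles)
    n_comp = min(5, len(profiles) - 1, matrix.values.shape[1])
    result = run_pca(matrix, n_comp)

    labels = np.array(labels)
    lo = result.scores[labels == "treated_lo"]
    hi = result.scores[labels == "treated_hi"]
    unt = result.scores[labels == "untreated"]
    sep = np.abs(hi.mean(axis=0) - lo.mean(axis=0)) / np.sqrt(
        (hi.var(axis=0, ddof=1) + lo.var(axis=0, ddof=1)) / 2.0 + 1e-12
    )
    k_best = int(np.argmax(sep))
    a, b = hi[:, k_best], lo[:, k_best]
    if a.mean() < b.mean():
        a, b = b, a
    gap = float(a.min() - b.max())
    load = np.abs(result.loadings[k_best])
    top_bins = result.bin_centers_um[np.argsort(load)[::-1][:top_k]]
    # a band counts as covered if a top bin lies within half the
    # smoothing span (2 bins = 32 um) of its projected position - the
    # localization limit of a 5-bin moving-averaged profile
    hits = 0
    for center in designated:
        target = _projected_band_um(center, conds)
        if np.any(np.abs(top_bins - target) <= 2.0 * 16.0):
            hits += 1
    treated_spread = np.concatenate([lo[:, k_best], hi[:, k_best]]).std(ddof=1)
    untreated_spread = unt[:, k_best].std(ddof=1)
    return {
        "separating_component": k_best + 1,
        "cluster_separation_d": float(sep[k_best]),
        "cluster_gap": gap,
        "designated_band_hits": int(hits),
        "n_designated": len(designated),
        "untreated_spread": float(untreated_spread),
        "treated_spread": float(treated_spread),
        "explained_variance_ratio": [float(v) for v in result.explained_variance_ratio],
    }
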