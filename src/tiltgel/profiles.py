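"""Migration-distance profiles from kept particles.

Counts of kept single-molecule foci are binned at 20 pixels (16 um at
0.8 um/px) along the projected axis, smoothed with a 5-bin centered
moving average, and truncated below the trailing edge of the
full-length-antibody peak (~3500 um), whose strong signal would
otherwise swamp sample-derived counts.  Replicate variability is
summarized as the per-bin sample SD and its median over the retained
bins.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import BinningConfig, ParameterError

__all__ = [
    "MigrationProfile",
    "ProfileMatrix",
    "bin_counts",
    "smooth_profile",
    "antibody_cutoff",
    "replicate_sd",
    "build_profile",
    "build_matrix",
]


@dataclass
class MigrationProfile:
    """Binned and smoothed single-molecule counts for one lane."""

    lane_id: str
    bin_edges_um: np.ndarray
    raw_counts: np.ndarray
    smoothed_counts: np.ndarray
    bin_width_px: int = 20
    remainder: int = 0
    cutoff_um: float | None = None
    condition_label: str = ""

    @property
    def bin_centers_um(self) -> np.ndarray:
        return (self.bin_edges_um[:-1] + self.bin_edges_um[1:]) / 2.0

    def beyond_cutoff(self) -> np.ndarray:
        """Boolean mask of bins retained for analysis (start >= cutoff)."""
        if self.cutoff_um is None:
            return np.ones(len(self.raw_counts), dtype=bool)
        return self.bin_edges_um[:-1] >= self.cutoff_um

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "lane_id": self.lane_id,
                "bin_start_um": self.bin_edges_um[:-1],
                "bin_end_um": self.bin_edges_um[1:],
                "raw_count": self.raw_counts,
                "smoothed_count": self.smoothed_counts,
                "beyond_cutoff": self.beyond_cutoff(),
            }
        )


@dataclass
class ProfileMatrix:
    """Samples x bins matrix of smoothed counts beyond the cutoff."""

    values: np.ndarray
    lane_ids: list[str]
    bin_centers_um: np.ndarray
    cutoff_um: float
    condition_labels: list[str] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.values, index=self.lane_ids,
            columns=[f"{c:.1f}" for c in self.bin_centers_um],
        )
        df.index.name = "lane_id"
        return df


def bin_counts(
    positions_px: np.ndarray,
    bin_width_px: int = 20,
    origin_px: float = 0.0,
    n_bins: int | None = None,
) -> tuple[np.ndarray, int]:
    """Histogram particle positions into half-open bins from the origin.

    Bin ``k`` counts particles with projected-axis coordinate in
    ``[origin + k*w, origin + (k+1)*w)``; particles outside
    ``[origin, origin + n_bins*w)`` are dropped and reported in the
    remainder.  Returns ``(counts, remainder)``.
    """
    if n_bins is not None and n_bins < 1:
        raise ParameterError("n_bins must be >= 1")
    positions = np.asarray(positions_px, dtype=float)
    rel = positions - origin_px
    if n_bins is None:
        top = int(np.floor(rel.max() / bin_width_px)) + 1 if len(rel) else 1
        n_bins = max(top, 1)
    idx = np.floor(rel / bin_width_px).astype(int)
    inside = (idx >= 0) & (idx < n_bins)
    counts = np.bincount(idx[inside], minlength=n_bins).astype(int)
    return counts, int((~inside).sum())


def smooth_profile(raw_counts: np.ndarray, window: int = 5) -> np.ndarray:
    """Centered moving average with symmetrically shrinking edges.

    At positions closer than ``window // 2`` to an edge the window
    shrinks symmetrically (e.g. a 3-bin average one bin from the edge,
    the bin itself at the very edge), so the output has the same length
    as the input and a constant profile is preserved exactly.
    """
    if window < 1 or window % 2 == 0:
        raise ParameterError(f"window must be odd and >= 1, got {window}")
    raw = np.asarray(raw_counts, dtype=float)
    n = len(raw)
    half = window // 2
    out = np.empty(n, dtype=float)
    for i in range(n):
        k = min(half, i, n - 1 - i)
        out[i] = raw[i - k : i + k + 1].mean()
    return out


def antibody_cutoff(
    smoothed_counts: np.ndarray,
    bin_edges_um: np.ndarray,
    search_window_um: tuple[float, float] = (2500.0, 4500.0),
    fraction: float = 0.5,
) -> float:
    """Trailing edge of the full-length-antibody peak, in um.

    Finds the tallest local maximum of the smoothed profile whose bin
    center lies inside the search window, then walks toward larger
    migration distances until the profile first falls below ``fraction``
    of the peak height; the left edge of that bin is the cutoff.  If the
    profile is flat inside the window (no peak) a warning is emitted and
    the window end is returned.
    """
    smoothed = np.asarray(smoothed_counts, dtype=float)
    edges = np.asarray(bin_edges_um, dtype=float)
    centers = (edges[:-1] + edges[1:]) / 2.0
    lo, hi = search_window_um
    in_window = np.where((centers >= lo) & (centers <= hi))[0]
    if len(in_window) == 0:
        raise ParameterError(
            f"profile does not cover the search window {search_window_um}"
        )
    window_vals = smoothed[in_window]
    peak_pos = in_window[int(np.argmax(window_vals))]
    peak = smoothed[peak_pos]
    if not np.any(window_vals < peak):
        warnings.warn(
            "no local maximum inside the antibody search window; "
            "using the window end as cutoff",
            stacklevel=2,
        )
        return float(hi)
    for j in range(peak_pos + 1, len(smoothed)):
        if smoothed[j] < fraction * peak:
            return float(edges[j])
    warnings.warn(
        "antibody peak never decays below the cutoff fraction; "
        "using the window end as cutoff",
        stacklevel=2,
    )
    return float(hi)


def replicate_sd(
    profiles: list[MigrationProfile],
    cutoff_um: float | None = None,
) -> tuple[np.ndarray, float]:
    """Per-bin sample SD across replicate profiles and its median.

    The SD uses the n-1 denominator.  The median is taken over bins
    beyond the cutoff (explicit argument, else the profiles' shared
    cutoff, else all bins).
    """
    if len(profiles) < 2:
        raise ParameterError("need at least two profiles")
    edges = profiles[0].bin_edges_um
    for p in profiles[1:]:
        if len(p.bin_edges_um) != len(edges) or not np.allclose(p.bin_edges_um, edges):
            raise ParameterError("profiles have mismatched binning")
    values = np.stack([p.smoothed_counts for p in profiles])
    per_bin_sd = values.std(axis=0, ddof=1)
    if cutoff_um is None:
        cutoffs = {p.cutoff_um for p in profiles}
        cutoff_um = max((c for c in cutoffs if c is not None), default=None)
    mask = (
        edges[:-1] >= cutoff_um
        if cutoff_um is not None
        else np.ones(len(per_bin_sd), dtype=bool)
    )
    return per_bin_sd, float(np.median(per_bin_sd[mask]))


def build_profile(
    kept_particles: pd.DataFrame,
    binning: BinningConfig,
    pixel_um: float = 0.8,
    origin_px: float = 0.0,
    n_bins: int | None = None,
    lane_id: str = "lane",
    condition_label: str = "",
) -> MigrationProfile:
    """Full profile construction for one lane: bin, smooth, cutoff."""
    n_bins = n_bins if n_bins is not None else binning.n_bins
    positions = kept_particles["y_px"].to_numpy(float) if len(kept_particles) else np.array([])
    raw, remainder = bin_counts(positions, binning.bin_width_px, origin_px, n_bins)
    smoothed = smooth_profile(raw, binning.smooth_window)
    edges_px = origin_px + binning.bin_width_px * np.arange(len(raw) + 1)
    edges_um = edges_px * pixel_um
    cutoff: float | None
    if binning.cutoff_mode == "auto":
        cutoff = antibody_cutoff(
            smoothed, edges_um, binning.search_window_um, binning.cutoff_fraction
        )
    elif binning.cutoff_mode == "manual":
        cutoff = binning.cutoff_um
    else:
        cutoff = None
    return MigrationProfile(
        lane_id=lane_id,
        bin_edges_um=edges_um,
        raw_counts=raw,
        smoothed_counts=smoothed,
        bin_width_px=binning.bin_width_px,
        remainder=remainder,
        cutoff_um=cutoff,
        condition_label=condition_label,
    )


def build_matrix(
    profiles: list[MigrationProfile], cutoff_um: float | None = None
) -> ProfileMatrix:
    """Stack replicate profiles into a samples x bins matrix.

    All profiles must share bin edges; columns are restricted to bins
    beyond the cutoff (shared profile cutoff by default).
    """
    if not profiles:
        raise ParameterError("need at least one profile")
    edges = profiles[0].bin_edges_um
    for p in profiles[1:]:
        if len(p.bin_edges_um) != len(edges) or not np.allclose(p.bin_edges_um, edges):
            raise ParameterError("profiles have mismatched binning")
    if cutoff_um is None:
        cutoffs = {p.cutoff_um for p in profiles}
        cutoff_um = max((c for c in cutoffs if c is not None), default=0.0)
    mask = edges[:-1] >= cutoff_um
    centers = (edges[:-1] + edges[1:]) / 2.0
    values = np.stack([p.smoothed_counts[mask] for p in profiles])
    return ProfileMatrix(
        values=values,
        lane_ids=[p.lane_id for p in profiles],
        bin_centers_um=centers[mask],
        cutoff_um=float(cutoff_um),
        condition_labels=[p.condition_label for p in profiles],
    )
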