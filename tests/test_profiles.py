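"""Binning, smoothing, antibody cutoff and replicate variability."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tiltgel.config import BinningConfig, ParameterError
from tiltgel.profiles import (
    MigrationProfile,
    antibody_cutoff,
    bin_counts,
    build_matrix,
    build_profile,
    replicate_sd,
    smooth_profile,
)


class TestBinCounts:
    def test_no_particles_gives_zero_counts(self):
        counts, remainder = bin_counts(np.array([]), 20, 0.0, n_bins=5)
        assert counts.tolist() == [0, 0, 0, 0, 0]
        assert remainder == 0

    def test_half_open_convention_by_hand(self):
        counts, remainder = bin_counts(np.array([5.0, 19.0, 20.0]), 20, 0.0, n_bins=4)
        assert counts.tolist() == [2, 1, 0, 0]
        assert remainder == 0

    def test_default_bin_width_is_sixteen_micrometers(self):
        assert BinningConfig().bin_width_px * 0.8 == pytest.approx(16.0)

    @given(st.lists(st.floats(-50, 450), max_size=60))
    @settings(deadline=None, max_examples=50)
    def test_counts_plus_remainder_conserve_particles(self, positions):
        counts, remainder = bin_counts(np.array(positions), 20, 0.0, n_bins=10)
        assert counts.sum() + remainder == len(positions)


class TestSmoothProfile:
    def test_constant_profile_preserved(self):
        out = smooth_profile(np.full(9, 4.0), window=5)
        assert np.allclose(out, 4.0)

    def test_impulse_with_shrinking_edges_by_hand(self):
        out = smooth_profile(np.array([0, 0, 0, 0, 5, 0, 0, 0, 0]), window=5)
        assert np.allclose(out, [0, 0, 1, 1, 1, 1, 1, 0, 0])

    def test_window_default_is_five(self):
        assert BinningConfig().smooth_window == 5

    def test_even_window_rejected(self):
        with pytest.raises(ParameterError):
            smooth_profile(np.arange(6.0), window=4)

    @given(st.lists(st.integers(0, 50), min_size=5, max_size=40))
    @settings(deadline=None, max_examples=50)
    def test_interior_mass_is_conserved(self, interior):
        """Counts supported >= 4 bins away from both edges (where every
        covering window is full-width) keep their total under the 5-bin
        moving average."""
        raw = np.array([0] * 4 + interior + [0] * 4, dtype=float)
        out = smooth_profile(raw, window=5)
        assert out.sum() == pytest.approx(raw.sum(), rel=1e-12)


class TestAntibodyCutoff:
    def _edges(self, n_bins, width_um=16.0):
        return width_um * np.arange(n_bins + 1)

    def test_gaussian_peak_cutoff_in_expected_interval(self):
        """Peak at 3500 um with ~200 um half-width: the half-maximum
        trailing edge lies between the peak and 4100 um."""
        edges = self._edges(320)  # covers 0..5120 um
        centers = (edges[:-1] + edges[1:]) / 2
        profile = 80.0 * np.exp(-((centers - 3500.0) ** 2) / (2 * 170.0**2))
        cutoff = antibody_cutoff(profile, edges)
        assert 3500.0 < cutoff < 4100.0

    def test_flat_profile_falls_back_to_window_end(self):
        edges = self._edges(320)
        with pytest.warns(UserWarning):
            cutoff = antibody_cutoff(np.full(320, 3.0), edges)
        assert cutoff == 4500.0

    def test_default_window_targets_full_length_antibody_peak(self):
        lo, hi = BinningConfig().search_window_um
        assert lo < 3500.0 < hi

    def test_profile_not_covering_window_rejected(self):
        edges = self._edges(10)  # only 0..160 um
        with pytest.raises(ParameterError):
            antibody_cutoff(np.zeros(10), edges)


def make_profile(smoothed, lane_id="p", cutoff=None):
    smoothed = np.asarray(smoothed, dtype=float)
    edges = 16.0 * np.arange(len(smoothed) + 1)
    return MigrationProfile(
        lane_id=lane_id,
        bin_edges_um=edges,
        raw_counts=smoothed.copy(),
        smoothed_counts=smoothed,
        cutoff_um=cutoff,
    )


class TestReplicateSD:
    def test_identical_profiles_have_zero_sd(self):
        profiles = [make_profile([3, 4, 5, 6]) for _ in range(4)]
        per_bin, median = replicate_sd(profiles)
        assert np.allclose(per_bin, 0.0)
        assert median == 0.0

    def test_two_profiles_differing_by_two_in_one_bin(self):
        a = make_profile([5, 5, 5, 5])
        b = make_profile([5, 7, 5, 5])
        per_bin, _ = replicate_sd([a, b])
        assert per_bin[1] == pytest.approx(np.sqrt(2.0))
        assert per_bin[[0, 2, 3]].tolist() == [0.0, 0.0, 0.0]

    def test_median_restricted_beyond_cutoff(self):
        a = make_profile([9, 0, 0, 0], cutoff=16.0)
        b = make_profile([1, 0, 0, 0], cutoff=16.0)
        _, median = replicate_sd([a, b])
        assert median == 0.0  # the differing bin lies before the cutoff

    def test_mismatched_binning_rejected(self):
        with pytest.raises(ParameterError):
            replicate_sd([make_profile([1, 2, 3]), make_profile([1, 2, 3, 4])])

    def test_single_profile_rejected(self):
        with pytest.raises(ParameterError):
            replicate_sd([make_profile([1, 2, 3])])


class TestBuildProfileAndMatrix:
    def test_build_profile_counts_kept_particles(self):
        kept = pd.DataFrame({"y_px": [5.0, 19.0, 20.0, 2000.0]})
        binning = BinningConfig(n_bins=4, cutoff_mode="none")
        profile = build_profile(kept, binning)
        assert profile.raw_counts.tolist() == [2, 1, 0, 0]
        assert profile.remainder == 1
        assert profile.bin_edges_um[1] == pytest.approx(16.0)

    def test_matrix_restricts_to_bins_beyond_cutoff(self):
        profiles = [make_profile([5, 6, 7, 8], lane_id=f"l{i}", cutoff=32.0)
                    for i in range(3)]
        matrix = build_matrix(profiles)
        assert matrix.values.shape == (3, 2)
        assert matrix.bin_centers_um.tolist() == [40.0, 56.0]
        assert matrix.lane_ids == ["l0", "l1", "l2"]
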