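import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from phenorow.isolation import (
    PeakParams,
    call_peak_segments,
    column_cut,
    column_profile,
    cuts_from_peaks,
    row_cut,
    row_profile,
    smooth_profile,
)

from .conftest import brute_force_segments


class TestProfiles:
    def test_all_ones_mask(self):
        np.testing.assert_allclose(row_profile(np.ones((4, 5))), np.ones(4))

    def test_single_pixel(self):
        m = np.zeros((4, 5))
        m[2, 3] = 1
        np.testing.assert_allclose(row_profile(m), [0, 0, 0.2, 0])
        np.testing.assert_allclose(column_profile(m), [0, 0, 0, 0.25, 0])

    def test_transpose_equivariance(self):
        rng = np.random.default_rng(0)
        m = (rng.random((12, 17)) > 0.6).astype(int)
        np.testing.assert_allclose(column_profile(m), row_profile(m.T))


class TestSmoothProfile:
    def test_constant_unchanged(self):
        np.testing.assert_allclose(smooth_profile(np.full(30, 3.0), span=0.3), 3.0)

    def test_linear_exact(self):
        y = np.linspace(0, 5, 40)
        np.testing.assert_allclose(smooth_profile(y, span=0.25), y, atol=1e-8)

    def test_quadratic_exact(self):
        x = np.arange(50, dtype=float)
        y = 0.02 * x**2 - x + 3
        np.testing.assert_allclose(smooth_profile(y, span=0.2), y, atol=1e-7)

    def test_noise_variance_reduced_on_flat_parts(self):
        rng = np.random.default_rng(1)
        y = np.concatenate([np.zeros(100), np.ones(100)]) + rng.normal(0, 0.1, 200)
        s = smooth_profile(y, span=0.1)
        flat = slice(10, 90)
        assert s[flat].var() < y[flat].var()

    def test_short_profile_rejected(self):
        with pytest.raises(ValueError):
            smooth_profile(np.ones(5))


class TestCallPeakSegments:
    def test_plateau_tie_goes_to_first_index(self):
        segs = call_peak_segments(np.array([0, 0, 5, 5, 0, 0.0]), PeakParams(0.1, 1))
        assert segs.segments == ((2, 3),)
        assert segs.peak_indices == (2,)
        assert segs.peak_values == (5.0,)

    def test_gap_of_exactly_min_gap_separates(self):
        profile = np.array([3.0] + [0.0] * 10 + [3.0])
        segs = call_peak_segments(profile, PeakParams(0.1, 10))
        assert len(segs) == 2
        # one fewer zero between the runs → merged
        profile = np.array([3.0] + [0.0] * 9 + [3.0])
        segs = call_peak_segments(profile, PeakParams(0.1, 10))
        assert len(segs) == 1
        assert segs.segments == ((0, 10),)

    def test_min_gap_one_means_any_gap_separates(self):
        profile = np.array([2.0, 0.0, 2.0, 2.0, 0.0, 2.0])
        segs = call_peak_segments(profile, PeakParams(0.5, 1))
        assert segs.segments == ((0, 0), (2, 3), (5, 5))

    def test_all_zero_profile_rejected(self):
        with pytest.raises(ValueError, match="no peaks"):
            call_peak_segments(np.zeros(10), PeakParams(0.1, 1))

    def test_matches_brute_force_oracle_random(self):
        rng = np.random.default_rng(42)
        for _ in range(200):
            n = int(rng.integers(50, 300))
            profile = rng.random(n) * (rng.random(n) > 0.4)
            if profile.max() <= 0:
                continue
            rel = float(rng.uniform(0.05, 0.9))
            gap = int(rng.integers(1, 30))
            got = call_peak_segments(profile, PeakParams(rel, gap))
            segs, peaks = brute_force_segments(profile, rel, gap)
            assert list(got.segments) == segs
            assert list(got.peak_indices) == peaks

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=50, deadline=None)
    def test_oracle_equivalence_property(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(20, 120))
        profile = np.round(rng.random(n) * (rng.random(n) > 0.3), 3)
        if profile.max() <= 0:
            return
        rel = float(rng.uniform(0.05, 0.95))
        gap = int(rng.integers(1, 20))
        got = call_peak_segments(profile, PeakParams(rel, gap))
        segs, peaks = brute_force_segments(profile, rel, gap)
        assert list(got.segments) == segs and list(got.peak_indices) == peaks


class TestRowCut:
    def test_solid_band_boundaries(self):
        m = np.zeros((100, 50))
        m[60:81, :] = 1
        rc = row_cut(m, span=0.05)
        assert 57 <= rc.upper_row <= 61
        assert 79 <= rc.lower_row <= 83
        assert rc.upper_row <= rc.peak_row <= rc.lower_row

    def test_bottom_band_selected(self):
        m = np.zeros((100, 50))
        m[20:31, :] = 1
        m[60:81, :] = 1
        rc = row_cut(m, span=0.05)
        assert rc.peak_row >= 55  # the lower band

    def test_band_contains_peak_row(self):
        rng = np.random.default_rng(2)
        for seed in range(5):
            m = (rng.random((120, 60)) > 0.9).astype(int)
            m[80:100, :] = 1
            rc = row_cut(m)
            assert rc.upper_row <= rc.peak_row <= rc.lower_row

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError, match="no plant pixels|no front row"):
            row_cut(np.zeros((50, 50)))


class TestColumnCut:
    def _band_with_columns(self, cols, n_cols=400, height=10):
        band = np.zeros((height, n_cols))
        for c in cols:
            band[:, c] = 1
        return band

    def test_margin_and_midpoint_formulas(self):
        band = self._band_with_columns([100, 200, 320])
        cc = column_cut(band)
        assert cc.peak_cols == (100, 200, 320)
        assert cc.margin == 60.0  # max spacing 120 halved
        assert cc.cuts == (40, 150, 260, 380)

    def test_right_margin_clips_to_band(self):
        band = self._band_with_columns([100, 200, 320], n_cols=360)
        cc = column_cut(band)
        assert cc.cuts[-1] == 359

    def test_single_plant_degenerate_margins(self):
        band = np.zeros((10, 200))
        band[:, 30:51] = 1
        cc = column_cut(band)
        assert cc.n_plants == 1
        left, right = cc.cuts
        assert left < cc.peak_cols[0] < right
        assert len(cc.cuts) == 2  # no interior cuts

    def test_cuts_interleave_peaks(self):
        band = self._band_with_columns([60, 150, 230, 330])
        cc = column_cut(band)
        for j in range(cc.n_plants):
            assert cc.cuts[j] < cc.peak_cols[j] < cc.cuts[j + 1]

    def test_translation_equivariance(self):
        band = self._band_with_columns([100, 200, 320], n_cols=500)
        shifted = np.roll(band, 40, axis=1)
        cc0 = column_cut(band)
        cc1 = column_cut(shifted)
        assert tuple(p + 40 for p in cc0.peak_cols) == cc1.peak_cols
        assert tuple(c + 40 for c in cc0.cuts) == cc1.cuts

    def test_squaring_preserves_argmax(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            p = rng.random(80)
            assert np.argmax(p) == np.argmax(p**2)

    def test_zero_band_rejected(self):
        with pytest.raises(ValueError, match="zero band"):
            column_cut(np.zeros((5, 100)))

    def test_detects_true_plants_on_field_scene(self, small_field_config):
        from phenorow.fixtures import make_field_scene
        from phenorow.isolation import band_mask

        scene = make_field_scene(small_field_config, seed=11)
        rc = row_cut(scene.truth_mask)
        cc = column_cut(band_mask(scene.truth_mask, rc), min_gap=40)
        assert cc.n_plants == len(scene.plant_centers)
        for j, center in enumerate(scene.plant_centers):
            assert cc.cuts[j] <= center <= cc.cuts[j + 1]


def test_cuts_from_peaks_matches_column_cut_geometry():
    peaks = [100.0, 200.0, 320.0]
    cuts, d_i = cuts_from_peaks(np.array(peaks), 400)
    assert cuts == (40, 150, 260, 380)
    assert d_i == 60.0
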