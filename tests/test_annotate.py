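import math

import numpy as np
import pytest

from chromaplot import (
    Curve,
    DegenerateInputError,
    EmptySelectionError,
    Selection,
    SynthSpec,
    apply_zoom,
    integrate_auc,
    normalize_curve,
    restrict_to_range,
    synth_chromatogram,
)
from _oracles import piecewise_linear_integral


class TestNormalize:
    def test_shift_min_zero(self):
        c = normalize_curve(Curve("c", [0, 1, 2], [2.0, 3.0, 4.0]), "shift_min_zero")
        assert list(c.y) == [0.0, 1.0, 2.0]

    def test_minmax_01(self):
        c = normalize_curve(Curve("c", [0, 1, 2], [2.0, 3.0, 4.0]), "minmax_01")
        assert list(c.y) == [0.0, 0.5, 1.0]

    def test_none_is_identity(self):
        c = Curve("c", [0, 1, 2], [2.0, 3.0, 4.0])
        assert normalize_curve(c, "none") is c

    def test_constant_curve_cannot_be_minmax_scaled(self):
        with pytest.raises(DegenerateInputError):
            normalize_curve(Curve("c", [0, 1], [3.0, 3.0]), "minmax_01")

    @pytest.mark.parametrize("method", ["shift_min_zero", "minmax_01"])
    def test_idempotent_and_shape_preserving(self, method):
        rng = np.random.default_rng(8)
        for _ in range(20):
            n = int(rng.integers(5, 200))
            c = Curve("c", np.sort(rng.uniform(0, 10, n)), rng.normal(5, 3, n))
            once = normalize_curve(c, method)
            twice = normalize_curve(once, method)
            assert np.allclose(once.y, twice.y, atol=1e-12)
            assert np.array_equal(once.x, c.x)  # x untouched
            assert np.argmax(once.y) == np.argmax(c.y)


class TestRestrictToRange:
    def test_interpolated_boundary_points(self):
        c = Curve("c", [0.0, 1.0, 2.0, 3.0], [0.0, 10.0, 10.0, 0.0])
        r = restrict_to_range(c, 0.5, 2.5)
        assert list(r.x) == [0.5, 1.0, 2.0, 2.5]
        assert list(r.y) == [5.0, 10.0, 10.0, 5.0]

    def test_full_extent_is_identity(self):
        c = Curve("c", [0.0, 1.0, 2.0], [1.0, 2.0, 3.0])
        r = restrict_to_range(c, 0.0, 2.0)
        assert np.array_equal(r.x, c.x) and np.array_equal(r.y, c.y)

    def test_no_overlap_is_empty_selection(self):
        c = Curve("c", [0.0, 1.0], [1.0, 2.0])
        with pytest.raises(EmptySelectionError):
            restrict_to_range(c, 5.0, 6.0)

    def test_random_ranges_stay_inside_and_keep_endpoints(self):
        rng = np.random.default_rng(21)
        for _ in range(100):
            n = int(rng.integers(5, 100))
            x = np.sort(rng.uniform(0, 10, n))
            c = Curve("c", x, rng.normal(0, 5, n))
            lo = rng.uniform(x[0], x[-1] - 1e-3)
            hi = rng.uniform(lo + 1e-3, x[-1])
            r = restrict_to_range(c, lo, hi)
            assert r.x[0] == lo and r.x[-1] == hi
            assert np.all((r.x >= lo) & (r.x <= hi))


class TestIntegrateAuc:
    def test_unit_rectangle(self):
        c = Curve("c", [0.0, 0.5, 1.0], [1.0, 1.0, 1.0])
        assert integrate_auc(c, (0.0, 1.0)) == pytest.approx(1.0, abs=1e-12)

    def test_gaussian_peak_matches_closed_form(self):
        a, sigma, center = 100.0, 0.05, 2.0
        x = np.arange(center - 6 * sigma, center + 6 * sigma + 1e-12, 0.002)
        y = a * np.exp(-0.5 * ((x - center) / sigma) ** 2)
        area = integrate_auc(Curve("peak", x, y), (center - 6 * sigma, center + 6 * sigma))
        assert area == pytest.approx(a * sigma * math.sqrt(2 * math.pi), rel=1e-3)

    def test_additive_over_fraction_intervals(self, small_chrom):
        c = small_chrom.primary_curve()
        ivs = small_chrom.intervals()
        total = sum(integrate_auc(c, iv) for iv in ivs)
        union = integrate_auc(c, (ivs[0].start_ml, ivs[-1].end_ml))
        assert abs(total - union) <= 1e-9 * abs(union)

    def test_matches_analytic_interpolant_integral(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            n = int(rng.integers(4, 60))
            x = np.sort(rng.uniform(0, 10, n))
            x[0], x[-1] = 0.0, 10.0
            c = Curve("c", x, rng.normal(0, 20, n))
            lo = rng.uniform(0, 9)
            hi = rng.uniform(lo + 0.1, 10)
            got = integrate_auc(c, (lo, hi))
            ref = piecewise_linear_integral(c.x, c.y, lo, hi)
            assert got == pytest.approx(ref, rel=1e-6, abs=1e-9)

    def test_baseline_subtraction_can_go_negative(self):
        from chromaplot import fit_baseline_als

        c = Curve("c", np.linspace(0, 5, 100), 10.0 + np.linspace(0, 5, 100))
        m = fit_baseline_als(c, lambda_smooth=1e4, p_asymmetry=0.5)
        area = integrate_auc(c, (0.0, 5.0), baseline=m)
        assert abs(area) < 1.0  # corrected linear ramp integrates to ~0


class TestZoom:
    def test_full_window_is_identity(self, small_chrom):
        view = apply_zoom(Selection(), small_chrom)
        assert len(view.curves) == len(small_chrom.curves)
        for orig, seg in zip(small_chrom.curves, view.curves):
            assert np.array_equal(orig.x, seg.x)
        assert len(view.intervals) == len(small_chrom.fraction_events)

    def test_partial_interval_truncated_fully_outside_dropped(self):
        spec = SynthSpec(
            peaks=((10.0, 50.0, 0.5),),
            x_end=20.0,
            step=0.05,
            fraction_start=5.0,
            fraction_width=1.0,
            n_fractions=10,
            noise_sd=0.0,
        )
        chrom, _ = synth_chromatogram(spec)
        view = apply_zoom(Selection(zoom=(7.0, 14.0)), chrom)
        assert view.intervals[0].start_ml == 7.0  # truncated
        assert all(iv.end_ml > 7.0 and iv.start_ml < 14.0 for iv in view.intervals)
        assert view.intervals[-1].end_ml == 14.0

    def test_zoom_never_changes_inwindow_areas(self, small_chrom):
        rng = np.random.default_rng(17)
        c = small_chrom.primary_curve()
        for _ in range(25):
            w0 = rng.uniform(0.0, 4.0)
            w1 = rng.uniform(w0 + 1.0, 6.0)
            view = apply_zoom(Selection(zoom=(w0, w1)), small_chrom)
            zoomed = next(v for v in view.curves if v.name == c.name)
            lo = rng.uniform(w0, w1 - 0.5)
            hi = rng.uniform(lo + 0.1, w1)
            a_full = integrate_auc(c, (lo, hi))
            a_zoom = integrate_auc(zoomed, (lo, hi))
            assert abs(a_zoom - a_full) <= 1e-12 * max(1.0, abs(a_full))

    def test_window_excluding_all_data_rejected(self, small_chrom):
        with pytest.raises(EmptySelectionError):
            apply_zoom(Selection(zoom=(50.0, 60.0)), small_chrom)

    def test_volume_range_clipped_to_window(self, small_chrom):
        sel = Selection(volume_range=(1.0, 5.0), zoom=(2.0, 4.0))
        view = apply_zoom(sel, small_chrom)
        assert view.volume_range == (2.0, 4.0)
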