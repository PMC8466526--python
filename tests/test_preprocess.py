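"""Preprocessing operators: EMSC, SNV, unit-vector, baselines, SG derivatives."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cosanftirm.preprocess import (emsc_correct, linear_baseline_correct,
                                   lower_hull_baseline, rubber_band_correct,
                                   savgol_derivative, sg_edge_width,
                                   snv_normalize, unit_vector_normalize)
from cosanftirm.spectra import Spectrum
from conftest import make_set


def _grid(n=200, lo=1000.0, step=2.0):
    return np.arange(lo, lo + n * step, step)


class TestEMSC:
    def test_reference_spectrum_maps_to_itself(self):
        w = _grid()
        ref = np.exp(-0.5 * ((w - 1200.0) / 30.0) ** 2)
        sset = make_set(w, [ref, ref * 1.5 + 0.1])
        corrected, models = emsc_correct(sset, poly_order=2,
                                         reference=Spectrum(w, ref))
        assert models[0].offset == pytest.approx(0.0, abs=1e-10)
        assert models[0].gain == pytest.approx(1.0, abs=1e-10)
        np.testing.assert_allclose(corrected.absorbance[0], ref, atol=1e-10)

    def test_affine_distortion_recovered_exactly(self):
        w = _grid()
        ref = np.exp(-0.5 * ((w - 1200.0) / 30.0) ** 2)
        raw = 0.5 + 2.0 * ref
        corrected, models = emsc_correct(make_set(w, [raw, ref]),
                                         reference=Spectrum(w, ref))
        assert models[0].offset == pytest.approx(0.5, abs=1e-10)
        assert models[0].gain == pytest.approx(2.0, abs=1e-10)
        np.testing.assert_allclose(corrected.absorbance[0], ref, atol=1e-10)

    def test_linear_drift_removed_vs_explicit_lstsq(self):
        """Oracle: explicit 3-column least squares on the same design."""
        w = _grid()
        ref = np.exp(-0.5 * ((w - 1200.0) / 30.0) ** 2)
        raw = ref + 0.001 * w
        corrected, models = emsc_correct(make_set(w, [raw, ref]), poly_order=1,
                                         reference=Spectrum(w, ref))
        nu = 2.0 * (w - w[0]) / (w[-1] - w[0]) - 1.0
        X = np.column_stack([ref, np.ones_like(w), nu])
        beta = np.linalg.lstsq(X, raw, rcond=None)[0]
        assert models[0].gain == pytest.approx(beta[0], rel=1e-10)
        assert models[0].offset == pytest.approx(beta[1], rel=1e-10)
        np.testing.assert_allclose(corrected.absorbance[0], ref, atol=1e-8)

    def test_idempotence(self):
        w = _grid()
        rng = np.random.default_rng(5)
        base = np.exp(-0.5 * ((w - 1200.0) / 40.0) ** 2)
        rows = [g * base + o + d * (w / 1000.0)
                for g, o, d in rng.uniform(0.7, 1.3, size=(4, 3))]
        ref = Spectrum(w, base)
        once, _ = emsc_correct(make_set(w, rows), reference=ref)
        twice, _ = emsc_correct(once, reference=ref)
        assert np.max(np.abs(twice.absorbance - once.absorbance)) < 1e-8

    def test_constant_reference_is_singular(self):
        w = _grid()
        sset = make_set(w, [np.ones(w.size), 2 * np.ones(w.size)])
        with pytest.raises(ValueError, match="collinear"):
            emsc_correct(sset, reference=Spectrum(w, np.ones(w.size)))


class TestSNV:
    def test_closed_form_three_points(self):
        w = np.arange(1000.0, 1018.0, 2.0)  # 9 points min grid
        s = Spectrum(w, [1, 2, 3, 1, 2, 3, 1, 2, 3])
        out = snv_normalize(s)
        assert out.absorbance.mean() == pytest.approx(0.0, abs=1e-12)
        assert out.absorbance.std(ddof=1) == pytest.approx(1.0, abs=1e-12)

    @given(st.lists(st.floats(-10, 10), min_size=9, max_size=40).filter(
        lambda xs: np.std(xs) > 1e-6))
    @settings(max_examples=50, deadline=None)
    def test_contract_mean_zero_sd_one(self, values):
        w = np.arange(1000.0, 1000.0 + 2 * len(values), 2.0)
        out = snv_normalize(Spectrum(w, values))
        assert abs(out.absorbance.mean()) < 1e-12
        assert abs(out.absorbance.std(ddof=1) - 1.0) < 1e-12

    def test_constant_spectrum_rejected(self):
        w = np.arange(1000.0, 1018.0, 2.0)
        with pytest.raises(ValueError, match="zero variance"):
            snv_normalize(Spectrum(w, np.full(9, 5.0)))


class TestUnitVector:
    def test_three_four_five(self):
        w = np.arange(1000.0, 1018.0, 2.0)
        v = np.array([3.0, 4.0, 0, 0, 0, 0, 0, 0, 0])
        out = unit_vector_normalize(Spectrum(w, v))
        np.testing.assert_allclose(out.absorbance[:2], [0.6, 0.8], rtol=1e-15)

    def test_scale_invariance_and_idempotence(self):
        w = _grid()
        rng = np.random.default_rng(6)
        v = rng.normal(size=w.size)
        a = unit_vector_normalize(Spectrum(w, v)).absorbance
        b = unit_vector_normalize(Spectrum(w, 7.0 * v)).absorbance
        np.testing.assert_allclose(a, b, atol=1e-14)
        c = unit_vector_normalize(Spectrum(w, a)).absorbance
        np.testing.assert_allclose(c, a, atol=1e-14)
        assert np.linalg.norm(a) == pytest.approx(1.0, abs=1e-12)


def brute_force_lower_hull(w, a):
    """Oracle: baseline from all pairwise chords that no point undercuts."""
    n = w.size
    base = np.full(n, -np.inf)
    for i in range(n):
        for j in range(i + 1, n):
            slope = (a[j] - a[i]) / (w[j] - w[i])
            chord = a[i] + slope * (w - w[i])
            if np.all(a >= chord - 1e-12):
                seg = (w >= w[i]) & (w <= w[j])
                base[seg] = np.maximum(base[seg], chord[seg])
    base[0], base[-1] = a[0], a[-1]
    return base


class TestRubberBand:
    def test_straight_line_corrects_to_zero(self):
        w = _grid(50)
        s = Spectrum(w, 0.002 * w + 1.0)
        out = rubber_band_correct(s)
        np.testing.assert_allclose(out.absorbance, 0.0, atol=1e-12)

    def test_peak_on_slope_recovers_height(self):
        w = np.arange(1500.0, 1800.0 + 1e-9, 2.0)
        peak = 0.5 * np.exp(-0.5 * ((w - 1650.0) / 12.0) ** 2)
        s = Spectrum(w, peak + 0.001 * w)
        out = rubber_band_correct(s)
        assert abs(out.absorbance.max() - 0.5) < 1e-3

    def test_matches_brute_force_hull_on_random_spectra(self):
        rng = np.random.default_rng(7)
        w = np.linspace(1000.0, 1500.0, 50)
        for _ in range(5):
            a = rng.normal(0.0, 1.0, w.size).cumsum() * 0.1
            fast = lower_hull_baseline(w, a)
            brute = brute_force_lower_hull(w, a)
            np.testing.assert_allclose(fast, brute, atol=1e-9)

    @given(st.integers(0, 2 ** 31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_output_nonnegative_and_zero_at_ends(self, seed):
        rng = np.random.default_rng(seed)
        w = _grid(60)
        a = rng.normal(0.2, 0.3, w.size)
        out = rubber_band_correct(Spectrum(w, a))
        assert np.all(out.absorbance >= 0.0)
        assert out.absorbance[0] == 0.0 and out.absorbance[-1] == 0.0


class TestLinearBaseline:
    def test_zero_at_anchors_and_line_removed(self):
        w = np.arange(1600.0, 1702.0, 2.0)
        line = 0.003 * w - 1.0
        out = linear_baseline_correct(Spectrum(w, line), 1600.0, 1700.0)
        np.testing.assert_allclose(out.absorbance, 0.0, atol=1e-12)

    def test_gaussian_plus_line_residual(self):
        w = np.arange(1600.0, 1701.0, 1.0)
        gauss = np.exp(-0.5 * ((w - 1652.0) / 8.0) ** 2)
        s = Spectrum(w, gauss + 0.002 * w + 0.3)
        out = linear_baseline_correct(s, 1600.0, 1700.0)
        # compare with analytic line subtraction through the Gaussian tails
        expected = gauss - (gauss[0] + (gauss[-1] - gauss[0]) * (w - w[0]) / 100.0)
        np.testing.assert_allclose(out.absorbance, expected, atol=1e-10)

    def test_equal_anchors_rejected(self):
        w = np.arange(1600.0, 1701.0, 1.0)
        with pytest.raises(ValueError, match="differ"):
            linear_baseline_correct(Spectrum(w, np.zeros(w.size)), 1650.0, 1650.0)


class TestSavitzkyGolay:
    def test_second_derivative_exact_on_quadratic(self):
        w = np.arange(1000.0, 1200.0, 2.0)
        s = Spectrum(w, (w - 1100.0) ** 2)
        out = savgol_derivative(s, window=9, poly=3, order=2)
        e = sg_edge_width(9)
        np.testing.assert_allclose(out.absorbance[e:-e], 2.0, rtol=1e-8)

    def test_smoothing_preserves_cubic(self):
        w = np.arange(1000.0, 1200.0, 2.0)
        y = ((w - 1100.0) / 50.0) ** 3
        out = savgol_derivative(Spectrum(w, y), window=9, poly=3, order=0)
        e = sg_edge_width(9)
        np.testing.assert_allclose(out.absorbance[e:-e], y[e:-e], atol=1e-10)

    def test_gaussian_second_derivative_vs_analytic(self):
        # sampling fine enough that the 9-point window spans << sigma,
        # keeping the filter's smoothing bias below the 1% check
        w = np.arange(1600.0, 1700.1, 0.25)
        mu, sig = 1652.0, 10.0
        g = np.exp(-0.5 * ((w - mu) / sig) ** 2)
        out = savgol_derivative(Spectrum(w, g), order=2)
        z = (w - mu) / sig
        analytic = (z ** 2 - 1.0) / sig ** 2 * g
        e = sg_edge_width(9)
        err = np.abs(out.absorbance[e:-e] - analytic[e:-e])
        assert err.max() < 0.01 * np.abs(analytic).max()

    def test_uneven_grid_rejected(self):
        w = np.concatenate([np.arange(1000.0, 1100.0, 2.0),
                            np.arange(1100.0, 1200.0, 4.0)])
        with pytest.raises(ValueError, match="resample"):
            savgol_derivative(Spectrum(w, np.zeros(w.size)))
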