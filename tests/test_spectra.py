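"""Data model, table/JCAMP I/O, region extraction and resampling."""

import numpy as np
import pytest

from cosanftirm.spectra import (Region, Spectrum, SpectraFormatError,
                                extract_region, load_jcamp, load_map,
                                load_spectra, resample_to_grid, save_map,
                                save_spectra, HyperMap)
from conftest import make_set


class TestIngestion:
    def test_descending_input_is_flipped_with_values(self):
        w = np.arange(4000.0, 798.0, -2.0)
        a = np.linspace(0.0, 1.0, w.size)
        s = Spectrum(w, a)
        assert s.wavenumbers[0] == 800.0 and s.wavenumbers[-1] == 4000.0
        # the value attached to 4000 must still be the first original value
        assert s.absorbance[-1] == a[0]

    def test_grid_validation_rejects_short_unsorted_outofrange(self):
        with pytest.raises(ValueError):
            Spectrum(np.arange(5), np.zeros(5))
        with pytest.raises(ValueError):
            Spectrum([800, 802, 802, 804, 806, 808, 810, 812, 814],
                     np.zeros(9))
        with pytest.raises(ValueError):
            Spectrum(np.linspace(100, 300, 20), np.zeros(20))

    def test_nonfinite_absorbance_rejected(self):
        w = np.arange(800.0, 900.0, 2.0)
        a = np.zeros(w.size)
        a[3] = np.nan
        with pytest.raises(ValueError, match="finite"):
            Spectrum(w, a)


class TestTableIO:
    def test_round_trip_is_lossless(self, tmp_path, small_grid):
        rng = np.random.default_rng(0)
        sset = make_set(small_grid, rng.normal(0.3, 0.1, (3, small_grid.size)))
        path = tmp_path / "cells.csv"
        save_spectra(sset, path, provenance="seed=0")
        back = load_spectra(path)
        np.testing.assert_allclose(back.wavenumbers, sset.wavenumbers, rtol=1e-12)
        np.testing.assert_allclose(back.absorbance, sset.absorbance, rtol=1e-12)
        assert back.labels.equals(sset.labels)

    def test_descending_table_loads_ascending(self, tmp_path):
        w = np.arange(4000.0, 798.0, -2.0)
        lines = ["wavenumber,GIC7/control/a,GIC7/200uM/b"]
        for i, wv in enumerate(w):
            lines.append(f"{wv},{0.001 * i},{0.002 * i}")
        path = tmp_path / "desc.csv"
        path.write_text("\n".join(lines))
        sset = load_spectra(path)
        assert len(sset) == 2
        assert np.all(np.diff(sset.wavenumbers) > 0)
        # first row of the file (4000) must map to the last grid point
        assert sset.absorbance[0, -1] == 0.0

    def test_row_order_does_not_matter(self, tmp_path):
        w = np.arange(800.0, 900.0, 2.0)
        rng = np.random.default_rng(1)
        a = rng.normal(size=(2, w.size))
        header = "wavenumber\tGIC7/control/a\tGIC7/control/b"
        rows = [f"{w[j]}\t{a[0, j]}\t{a[1, j]}" for j in range(w.size)]
        (tmp_path / "fwd.tsv").write_text("\n".join([header] + rows))
        (tmp_path / "rev.tsv").write_text("\n".join([header] + rows[::-1]))
        fwd = load_spectra(tmp_path / "fwd.tsv")
        rev = load_spectra(tmp_path / "rev.tsv")
        np.testing.assert_array_equal(fwd.absorbance, rev.absorbance)

    @pytest.mark.parametrize("body,err", [
        ("800,0.1,0.2\n802,0.1\n", "ragged"),
        ("800,0.1,0.2\n802,x,0.2\n", "non-numeric"),
        ("800,0.1,0.2\n800,0.1,0.2\n", "duplicate"),
    ])
    def test_malformed_tables_raise(self, tmp_path, body, err):
        path = tmp_path / "bad.csv"
        path.write_text("wavenumber,a/b/c,d/e/f\n" + body)
        with pytest.raises(SpectraFormatError, match=err):
            load_spectra(path)


class TestJcamp:
    JCAMP = """##TITLE=hand-written ten-point test
##JCAMP-DX=4.24
##DATA TYPE=INFRARED SPECTRUM
##XUNITS=1/CM
##YUNITS=ABSORBANCE
##FIRSTX=2000
##LASTX=1100
##DELTAX=-100
##XFACTOR=1
##YFACTOR=0.001
##NPOINTS=10
##XYDATA=(X++(Y..Y))
2000 10 20 30 40 50
1500 60 70 80 90 100
##END=
"""

    def oracle_decode(self, text):
        """Independent line-by-line decoder for the fixture above."""
        fields = {}
        ys = []
        in_data = False
        for ln in text.splitlines():
            if ln.startswith("##"):
                key, _, val = ln[2:].partition("=")
                if key.strip() == "XYDATA":
                    in_data = True
                elif key.strip() == "END":
                    in_data = False
                else:
                    fields[key.strip()] = val.strip()
                continue
            if in_data:
                toks = ln.split()
                ys.extend(float(t) * float(fields["YFACTOR"]) for t in toks[1:])
        x = np.linspace(float(fields["FIRSTX"]), float(fields["LASTX"]), len(ys))
        return x, np.asarray(ys)

    def test_descending_xydata_matches_oracle(self, tmp_path):
        path = tmp_path / "ten.jdx"
        path.write_text(self.JCAMP)
        spec = load_jcamp(path)
        x_or, y_or = self.oracle_decode(self.JCAMP)
        # oracle is descending; the reader must deliver it flipped
        np.testing.assert_allclose(spec.wavenumbers, x_or[::-1])
        np.testing.assert_allclose(spec.absorbance, y_or[::-1])
        assert spec.wavenumbers[0] == 1100.0 and spec.wavenumbers[-1] == 2000.0

    def test_npoints_mismatch_raises(self, tmp_path):
        bad = self.JCAMP.replace("##NPOINTS=10", "##NPOINTS=11")
        path = tmp_path / "bad.jdx"
        path.write_text(bad)
        with pytest.raises(SpectraFormatError, match="NPOINTS"):
            load_jcamp(path)


class TestRegions:
    def test_point_count_closed_interval(self):
        # multiples of 2 in [900, 1350]: 900, 902, ..., 1350 -> 226 points
        w = np.arange(800.0, 4000.0 + 1e-9, 2.0)
        s = Spectrum(w, np.zeros(w.size))
        sub = extract_region(s, Region("dna", 900.0, 1350.0))
        assert len(sub) == 226
        assert sub.wavenumbers[0] == 900.0 and sub.wavenumbers[-1] == 1350.0

    def test_full_span_region_is_identity(self, small_grid):
        s = Spectrum(small_grid, np.linspace(0, 1, small_grid.size))
        sub = extract_region(s, Region("all", 800.0, 4000.0))
        np.testing.assert_array_equal(sub.absorbance, s.absorbance)

    def test_empty_intersection_raises(self):
        w = np.arange(800.0, 1800.0, 2.0)
        s = Spectrum(w, np.zeros(w.size))
        with pytest.raises(ValueError, match="does not intersect"):
            extract_region(s, Region("lipids", 2800.0, 3000.0))

    def test_nested_extraction_equals_inner(self, small_grid):
        rng = np.random.default_rng(2)
        s = Spectrum(small_grid, rng.normal(size=small_grid.size))
        outer = extract_region(s, Region("fp", 1000.0, 1800.0))
        inner_of_outer = extract_region(outer, Region("amide", 1600.0, 1700.0))
        direct = extract_region(s, Region("amide", 1600.0, 1700.0))
        np.testing.assert_array_equal(inner_of_outer.absorbance, direct.absorbance)


class TestResample:
    def test_identity_on_own_grid(self, small_grid):
        s = Spectrum(small_grid, np.sin(small_grid / 100.0))
        out = resample_to_grid(s, small_grid)
        np.testing.assert_array_equal(out.absorbance, s.absorbance)

    def test_linear_function_exact_at_midpoints(self):
        w = np.arange(1000.0, 1100.0, 4.0)
        s = Spectrum(w, w.copy())  # A(nu) = nu
        mid = (w[:-1] + w[1:]) / 2.0
        target = np.sort(np.concatenate([w, mid]))
        out = resample_to_grid(s, target)
        np.testing.assert_allclose(out.absorbance, target, rtol=1e-14)

    @pytest.mark.parametrize("sigma", [8.0, 20.0])
    def test_gaussian_refinement_obeys_interp_error_bound(self, sigma):
        # linear interpolation error is bounded by (dx^2 / 8) * max|f''|,
        # with max|f''| = 1/sigma^2 for a unit-height Gaussian
        w = np.arange(1500.0, 1800.0 + 1e-9, 4.0)
        mu = 1652.0
        s = Spectrum(w, np.exp(-0.5 * ((w - mu) / sigma) ** 2))
        fine = np.arange(1500.0, 1800.0 + 1e-9, 1.0)
        out = resample_to_grid(s, fine)
        analytic = np.exp(-0.5 * ((fine - mu) / sigma) ** 2)
        err = np.max(np.abs(out.absorbance - analytic))
        assert err <= (4.0 ** 2 / 8.0) / sigma ** 2 * 1.01
        # values at shared grid points are untouched
        shared = np.isin(fine, w)
        np.testing.assert_array_equal(out.absorbance[shared], s.absorbance)

    def test_extrapolation_refused(self, small_grid):
        s = Spectrum(small_grid, np.zeros(small_grid.size))
        with pytest.raises(ValueError, match="xtrapolation"):
            resample_to_grid(s, np.arange(700.0, 900.0, 2.0))


class TestMapIO:
    def test_map_round_trip_and_geometry(self, tmp_path):
        w = np.arange(2400.0, 2700.0, 2.0)
        rng = np.random.default_rng(3)
        cube = rng.normal(0.1, 0.02, size=(4, 5, w.size))
        hmap = HyperMap(w, cube, step_um=1.5)
        assert hmap.extent_um == (4 * 1.5, 3 * 1.5)
        save_map(hmap, tmp_path / "map")
        back = load_map(tmp_path / "map")
        assert back.nx == 5 and back.ny == 4 and back.step_um == 1.5
        np.testing.assert_allclose(back.cube, cube, rtol=1e-12)
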