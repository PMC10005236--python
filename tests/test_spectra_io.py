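"""Spectrum domain type, file round trips, resampling, and excision."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mbspec.spectra import (
    CANONICAL_GRID,
    ParseError,
    Region,
    Spectrum,
    SpectrumError,
    SpectrumSet,
    excise_regions,
    read_spectrum,
    resample_to_grid,
    write_spectrum,
)


class TestSpectrumInvariants:
    def test_rejects_length_mismatch(self):
        with pytest.raises(SpectrumError, match="length mismatch"):
            Spectrum(np.arange(3.0), np.zeros(4))

    def test_rejects_single_point(self):
        with pytest.raises(SpectrumError):
            Spectrum(np.array([800.0]), np.array([0.1]))

    def test_rejects_non_monotone_grid(self):
        with pytest.raises(SpectrumError, match="strictly increasing"):
            Spectrum(np.array([800.0, 800.0, 801.0]), np.zeros(3))

    def test_rejects_non_finite_absorbance(self):
        with pytest.raises(SpectrumError, match="finite"):
            Spectrum(np.array([800.0, 801.0]), np.array([0.1, np.nan]))

    def test_canonical_grid_has_two_uniform_segments(self):
        s = Spectrum(CANONICAL_GRID, np.zeros_like(CANONICAL_GRID))
        segs = s.segments()
        assert len(segs) == 2
        assert segs[0].stop - segs[0].start == 1001  # 800..1800
        assert segs[1].stop - segs[1].start == 701   # 2800..3500


class TestReadWrite:
    def test_minimal_two_row_csv(self, tmp_path):
        p = tmp_path / "s.csv"
        p.write_text("800,0.1\n801,0.2\n")
        s = read_spectrum(p)
        assert len(s) == 2
        np.testing.assert_array_equal(s.wavenumbers, [800.0, 801.0])

    def test_descending_input_is_normalized(self, tmp_path):
        up = tmp_path / "up.csv"
        dn = tmp_path / "dn.csv"
        up.write_text("800,0.1\n801,0.2\n")
        dn.write_text("801,0.2\n800,0.1\n")
        a, b = read_spectrum(up), read_spectrum(dn)
        np.testing.assert_array_equal(a.wavenumbers, b.wavenumbers)
        np.testing.assert_array_equal(a.absorbance, b.absorbance)

    def test_duplicate_wavenumber_named_in_error(self, tmp_path):
        p = tmp_path / "dup.csv"
        p.write_text("999,0.1\n1000,0.2\n1000,0.3\n1001,0.4\n")
        with pytest.raises(ParseError, match="1000"):
            read_spectrum(p)

    def test_non_numeric_row_names_line(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text("800,0.1\noops,0.2\n")
        with pytest.raises(ParseError, match="2"):
            read_spectrum(p)

    def test_header_line_is_tolerated(self, tmp_path):
        p = tmp_path / "h.csv"
        p.write_text("wavenumber_cm1,absorbance\n800,0.1\n801,0.2\n")
        assert len(read_spectrum(p)) == 2

    def test_round_trip_exact(self, tmp_path):
        rng = np.random.default_rng(0)
        s = Spectrum(np.arange(800.0, 900.0), rng.normal(size=100))
        write_spectrum(s, tmp_path / "rt.csv")
        back = read_spectrum(tmp_path / "rt.csv")
        np.testing.assert_allclose(back.wavenumbers, s.wavenumbers, atol=1e-12)
        np.testing.assert_allclose(back.absorbance, s.absorbance, atol=1e-12)

    def test_full_grid_row_count(self, tmp_path):
        # 800-3500 at 1 cm^-1 without the gap: 2701 data rows plus header
        grid = np.arange(800.0, 3501.0)
        s = Spectrum(grid, np.zeros_like(grid))
        path = tmp_path / "full.csv"
        write_spectrum(s, path)
        lines = path.read_text().strip().splitlines()
        assert len(lines) == 2701 + 1

    def test_jcamp_minimal_dialect(self, tmp_path):
        p = tmp_path / "s.jdx"
        p.write_text(
            "##TITLE=test\n##XUNITS=1/CM\n##YUNITS=ABSORBANCE\n"
            "##FIRSTX=800\n##LASTX=805\n##NPOINTS=6\n"
            "##XYDATA=(X++(Y..Y))\n"
            "800 0.1 0.2 0.3\n803 0.4 0.5 0.6\n##END=\n"
        )
        s = read_spectrum(p, format="jcamp")
        np.testing.assert_allclose(s.wavenumbers, np.arange(800.0, 806.0))
        np.testing.assert_allclose(s.absorbance, [0.1, 0.2, 0.3, 0.4, 0.5, 0.6])

    def test_jcamp_rejects_other_dialects(self, tmp_path):
        p = tmp_path / "bad.jdx"
        p.write_text("##XUNITS=MICROMETERS\n##XYDATA=(X++(Y..Y))\n800 1\n##END=\n")
        with pytest.raises(ParseError, match="XUNITS"):
            read_spectrum(p, format="jcamp")
        p2 = tmp_path / "bad2.jdx"
        p2.write_text("##XUNITS=1/CM\n##XYDATA=(XY..XY)\n800 1\n##END=\n")
        with pytest.raises(ParseError, match="dialect"):
            read_spectrum(p2, format="jcamp")


class TestResample:
    def test_identity_on_own_grid(self):
        rng = np.random.default_rng(1)
        s = Spectrum(np.arange(800.0, 900.0), rng.normal(size=100))
        r = resample_to_grid(s, s.wavenumbers)
        np.testing.assert_array_equal(r.absorbance, s.absorbance)

    def test_midpoint_of_linear_interpolant(self):
        s = Spectrum(np.array([800.0, 802.0]), np.array([0.0, 1.0]))
        r = resample_to_grid(s, np.array([800.0, 801.0, 802.0]))
        assert r.absorbance[1] == pytest.approx(0.5)

    def test_collinear_stays_collinear_on_finer_grid(self):
        grid = np.arange(800.0, 811.0, 2.0)
        s = Spectrum(grid, 0.3 * grid + 1.0)
        fine = np.arange(800.0, 810.1, 0.5)
        r = resample_to_grid(s, fine)
        np.testing.assert_allclose(r.absorbance, 0.3 * fine + 1.0, atol=1e-12)

    def test_no_extrapolation(self):
        s = Spectrum(np.array([800.0, 810.0]), np.array([0.0, 1.0]))
        with pytest.raises(SpectrumError, match="beyond"):
            resample_to_grid(s, np.array([795.0, 805.0]))


class TestExcise:
    def test_paraffin_excision_point_count(self, fingerprint_grid):
        s = Spectrum(fingerprint_grid, np.zeros_like(fingerprint_grid))
        out = excise_regions(s, [Region(1350, 1500)])
        assert len(s) == 1001
        assert len(out) == 1001 - 151

    def test_empty_drop_list_is_identity(self, fingerprint_grid):
        s = Spectrum(fingerprint_grid, np.zeros_like(fingerprint_grid))
        out = excise_regions(s, [])
        np.testing.assert_array_equal(out.wavenumbers, s.wavenumbers)

    def test_region_outside_span_errors(self, fingerprint_grid):
        s = Spectrum(fingerprint_grid, np.zeros_like(fingerprint_grid))
        with pytest.raises(SpectrumError, match="outside"):
            excise_regions(s, [Region(2000, 2100)])

    def test_removing_everything_errors(self):
        g = np.arange(1000.0, 1011.0)
        s = Spectrum(g, np.zeros_like(g))
        with pytest.raises(SpectrumError, match="every grid point"):
            excise_regions(s, [Region(999, 1012)])

    def test_excised_regions_are_recorded(self, fingerprint_grid):
        s = Spectrum(fingerprint_grid, np.zeros_like(fingerprint_grid))
        out = excise_regions(s, [Region(1350, 1500)])
        assert [(r.lo, r.hi) for r in out.excised] == [(1350, 1500)]

    @settings(max_examples=30, deadline=None)
    @given(
        lo1=st.integers(850, 1000), w1=st.integers(5, 50),
        lo2=st.integers(1200, 1400), w2=st.integers(5, 50),
    )
    def test_sequential_equals_joint_excision_for_disjoint_regions(self, lo1, w1, lo2, w2):
        grid = np.arange(800.0, 1801.0)
        s = Spectrum(grid, np.sin(grid / 37.0))
        r1, r2 = Region(lo1, lo1 + w1), Region(lo2, lo2 + w2)
        seq = excise_regions(excise_regions(s, [r1]), [r2])
        joint = excise_regions(s, [r1, r2])
        np.testing.assert_array_equal(seq.wavenumbers, joint.wavenumbers)
        np.testing.assert_array_equal(seq.absorbance, joint.absorbance)


class TestSpectrumSet:
    def test_rejects_mixed_grids(self):
        a = Spectrum(np.arange(800.0, 900.0), np.zeros(100))
        b = Spectrum(np.arange(801.0, 901.0), np.zeros(100))
        with pytest.raises(SpectrumError, match="shared grid"):
            SpectrumSet([a, b])

    def test_select_missing_group_errors(self):
        a = Spectrum(np.arange(800.0, 900.0), np.zeros(100), group="classic")
        with pytest.raises(SpectrumError, match="control"):
            SpectrumSet([a]).select("control")
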