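"""Spectrum container, grid handling, file round-trips, group statistics."""

import numpy as np
import pytest

from ftirfg.spectra import (
    CANONICAL_GRID, ParseError, ReferenceMeasures, SampleMeta, Spectrum,
    SpectrumError, group_mean_spectrum, read_reference_measures,
    read_sample_meta, read_spectrum, resample, to_canonical,
    write_reference_measures, write_sample_meta, write_spectrum,
)


def test_canonical_grid_is_901_points_descending():
    # (4000 - 400) / 4 + 1 grid points at 4 cm-1 spacing
    assert CANONICAL_GRID.size == (4000 - 400) // 4 + 1 == 901
    assert CANONICAL_GRID[0] == 4000.0 and CANONICAL_GRID[-1] == 400.0
    assert np.all(np.diff(CANONICAL_GRID) == -4.0)


class TestSpectrumInvariants:
    def test_rejects_length_mismatch(self):
        with pytest.raises(SpectrumError):
            Spectrum("x", np.array([1.0, 2.0, 3.0]), np.array([0.0, 1.0]))

    def test_rejects_non_monotone_grid(self):
        with pytest.raises(SpectrumError, match="monotone"):
            Spectrum("x", np.array([2000.0, 2000.0, 1990.0]), np.zeros(3))

    def test_rejects_non_finite(self):
        with pytest.raises(SpectrumError):
            Spectrum("x", np.array([1000.0, 996.0]), np.array([0.0, np.nan]))

    def test_negatives_preserved_and_flagged(self):
        s = Spectrum("x", np.array([1000.0, 996.0, 992.0, 988.0]),
                     np.array([0.1, -0.05, 0.2, -0.01]))
        assert s.negative_fraction == pytest.approx(0.5)
        assert s.absorbance.min() < 0  # never clipped


class TestReadWrite:
    def test_two_row_file(self, tmp_path):
        p = tmp_path / "s.csv"
        p.write_text("wavenumber_cm-1,absorbance\n4000,0.0\n3996,0.1\n")
        s = read_spectrum(p)
        assert len(s) == 2 and s.stage == "raw"
        assert s.absorbance[1] == pytest.approx(0.1)

    def test_duplicate_wavenumber_is_parse_error(self, tmp_path):
        p = tmp_path / "s.csv"
        p.write_text("2004,0.0\n2000,0.1\n2000,0.2\n")
        with pytest.raises(ParseError):
            read_spectrum(p)

    def test_non_numeric_row_names_line(self, tmp_path):
        p = tmp_path / "s.csv"
        p.write_text("4000,0.0\n3996,oops\n")
        with pytest.raises(ParseError, match=":2"):
            read_spectrum(p)

    def test_empty_file_rejected(self, tmp_path):
        p = tmp_path / "s.csv"
        p.write_text("")
        with pytest.raises(ParseError):
            read_spectrum(p)

    def test_full_grid_file_has_901_points(self, tmp_path):
        p = tmp_path / "s.csv"
        rows = "\n".join(f"{w},0.0" for w in CANONICAL_GRID)
        p.write_text(rows + "\n")
        assert len(read_spectrum(p)) == 901

    def test_round_trip_full_precision(self, tmp_path):
        rng = np.random.default_rng(0)
        s = Spectrum("rt", np.asarray(CANONICAL_GRID), rng.normal(size=901))
        write_spectrum(s, tmp_path / "rt.csv")
        back = read_spectrum(tmp_path / "rt.csv")
        np.testing.assert_array_equal(back.wavenumbers, s.wavenumbers)
        np.testing.assert_array_equal(back.absorbance, s.absorbance)

    def test_jcampdx_xypoints(self, tmp_path):
        p = tmp_path / "s.jdx"
        p.write_text(
            "##TITLE=demo\n##XFACTOR=1\n##YFACTOR=1\n"
            "##XYPOINTS=(XY..XY)\n4000,0.0 3996,0.1 3992,0.2\n##END=\n"
        )
        s = read_spectrum(p, dialect="jcampdx")
        assert len(s) == 3
        assert s.absorbance[2] == pytest.approx(0.2)


class TestResample:
    def test_identity_on_same_grid(self):
        s = Spectrum("x", np.asarray(CANONICAL_GRID), np.linspace(0, 1, 901))
        out = resample(s, CANONICAL_GRID)
        np.testing.assert_allclose(out.absorbance, s.absorbance)

    def test_exact_on_linear_ramp(self):
        wn = np.arange(2000.0, 1000.0, -2.0)
        s = Spectrum("x", wn, 0.5 * wn + 3.0)
        mid = wn[:-1] - 1.0
        out = resample(s, mid)
        np.testing.assert_allclose(out.absorbance, 0.5 * mid + 3.0)

    def test_gaussian_peak_height_preserved(self):
        wn2 = np.arange(1700.0, 1500.0, -2.0)
        g = 0.3 * np.exp(-0.5 * ((wn2 - 1600.0) / 20.0) ** 2)
        s = Spectrum("x", wn2, g)
        wn4 = np.arange(1696.0, 1504.0, -4.0)
        out = resample(s, wn4)
        analytic = 0.3 * np.exp(-0.5 * ((wn4 - 1600.0) / 20.0) ** 2)
        assert abs(out.absorbance.max() - analytic.max()) / analytic.max() < 0.005

    def test_no_extrapolation(self):
        s = Spectrum("x", np.array([2000.0, 1996.0, 1992.0]), np.zeros(3))
        with pytest.raises(SpectrumError, match="span"):
            resample(s, np.array([2004.0, 2000.0]))

    def test_to_canonical_identity(self):
        s = Spectrum("x", np.asarray(CANONICAL_GRID), np.ones(901))
        assert to_canonical(s) is s


class TestGroupMean:
    def test_single_spectrum_mean_is_itself_sd_zero(self, make_spectrum):
        s = make_spectrum(np.linspace(0, 1, 901))
        mean, sd = group_mean_spectrum([s])
        np.testing.assert_allclose(mean.absorbance, s.absorbance)
        assert np.all(sd.absorbance == 0.0)

    def test_two_point_sd_uses_n_minus_1(self, make_spectrum):
        a = make_spectrum(np.zeros(901))
        b = make_spectrum(np.full(901, 2.0))
        mean, sd = group_mean_spectrum([a, b])
        assert np.all(mean.absorbance == 1.0)
        # sample sd of {0, 2}: sqrt(((0-1)^2 + (2-1)^2) / (2-1)) = sqrt(2)
        np.testing.assert_allclose(sd.absorbance, np.sqrt(2.0))

    def test_energy_weighting_gives_emission_factor_spectrum(self, make_spectrum):
        s = make_spectrum(np.ones(901))
        mean, _ = group_mean_spectrum([s], weights=[1.0 / 2.0])  # 2 MJ delivered
        np.testing.assert_allclose(mean.absorbance, 0.5)

    def test_replicated_spectrum_has_zero_sd(self, make_spectrum):
        s = make_spectrum(np.linspace(0, 1, 901))
        mean, sd = group_mean_spectrum([s] * 5)
        np.testing.assert_allclose(mean.absorbance, s.absorbance)
        np.testing.assert_allclose(sd.absorbance, 0.0, atol=1e-12)

    def test_grid_mismatch_rejected(self, make_spectrum):
        s = make_spectrum(np.ones(901))
        other = Spectrum("y", np.array([1000.0, 996.0]), np.zeros(2))
        with pytest.raises(SpectrumError):
            group_mean_spectrum([s, other])


class TestMetadataTables:
    def test_sample_meta_round_trip(self, tmp_path):
        m = SampleMeta(id="S1", fuel="red_oak", stove="three_stone", phase="CS",
                       energy_delivered=5.2, sample_flow=16.7, tunnel_flow=4.0,
                       duration=35.0, deposit_area=11.95)
        write_sample_meta([m], tmp_path / "meta.csv")
        back = read_sample_meta(tmp_path / "meta.csv")
        assert back["S1"] == m

    def test_sample_meta_validates_positivity(self):
        with pytest.raises(ValueError):
            SampleMeta(id="S1", fuel="red_oak", stove="x", phase="CS",
                       energy_delivered=0.0, sample_flow=16.7, tunnel_flow=4.0,
                       duration=35.0, deposit_area=11.95)

    def test_reference_round_trip_with_pah_table(self, tmp_path):
        r = ReferenceMeasures(id="S1", oc_front=120.0, oc_back=30.0, ec=80.0,
                              pm25_mass=400.0, pah_table={"pyrene": 1.5})
        write_reference_measures([r], tmp_path / "refs.csv")
        back = read_reference_measures(tmp_path / "refs.csv")
        assert back["S1"].pah_table == {"pyrene": 1.5}
        assert back["S1"].pah_total == pytest.approx(1.5)

    def test_negative_reference_flagged_not_rejected(self):
        r = ReferenceMeasures(id="S1", oc_front=2.0, oc_back=3.0, ec=-0.5,
                              pm25_mass=10.0)
        assert r.has_negative
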