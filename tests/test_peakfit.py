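"""Multi-peak Gaussian fitting and the carboxylic-acid signature rule."""

import math

import numpy as np
import pytest

from ftirfg.bands import BandDefinition, DEFAULT_BAND_TABLE, FIT_REGIONS, bands_in_window
from ftirfg.peakfit import (
    SQRT_2PI, collect_band_fits, detect_acid_signature, fit_all_regions, fit_window,
)
from ftirfg.spectra import CANONICAL_GRID, Spectrum, SpectrumError
from ftirfg.synthetic import ARCHETYPES, generate_sample

from conftest import gaussian

WN = np.asarray(CANONICAL_GRID)


def corrected(absorbance, sid="x"):
    return Spectrum(id=sid, wavenumbers=WN, absorbance=np.asarray(absorbance, float),
                    stage="blank_subtracted")


ACH_BANDS = [b for b in DEFAULT_BAND_TABLE if b.name in ("aCH_2850", "aCH_2920")]
OOP_BAND = [b for b in DEFAULT_BAND_TABLE if b.name == "rCH_oop_750"]


class TestFitWindow:
    def test_zero_spectrum_gives_zero_amplitudes_and_rmse(self):
        res = fit_window(corrected(np.zeros(WN.size)), ACH_BANDS, (2300.0, 3700.0))
        assert res.converged
        assert res.rmse < 1e-6
        for bf in res.bands.values():
            assert bf.height == pytest.approx(0.0, abs=1e-6)

    def test_two_overlapping_gaussians_recovered_within_1pct(self):
        a1 = 1.5  # AU·cm⁻¹ areas
        a2 = 0.9
        y = (gaussian(WN, 2920.0, 14.0, a1 / (14.0 * SQRT_2PI))
             + gaussian(WN, 2850.0, 13.0, a2 / (13.0 * SQRT_2PI)))
        res = fit_window(corrected(y), ACH_BANDS, (2300.0, 3700.0))
        assert res["aCH_2920"].area == pytest.approx(a1, rel=0.01)
        assert res["aCH_2850"].area == pytest.approx(a2, rel=0.01)

    def test_single_oop_band_height_within_1pct(self):
        y = gaussian(WN, 750.0, 8.0, 0.05)
        res = fit_window(corrected(y), OOP_BAND, (650.0, 900.0))
        assert res["rCH_oop_750"].height == pytest.approx(0.05, rel=0.01)

    def test_gaussian_area_identity_exact(self):
        y = gaussian(WN, 750.0, 8.0, 0.05)
        res = fit_window(corrected(y), OOP_BAND, (650.0, 900.0))
        bf = res["rCH_oop_750"]
        assert bf.area == pytest.approx(bf.height * bf.sigma * SQRT_2PI, rel=1e-12)

    def test_requires_blank_subtracted_stage(self):
        raw = Spectrum(id="x", wavenumbers=WN, absorbance=np.zeros(WN.size), stage="raw")
        with pytest.raises(SpectrumError, match="blank_subtracted"):
            fit_window(raw, OOP_BAND, (650.0, 900.0))

    def test_window_off_grid_rejected(self):
        with pytest.raises(SpectrumError, match="off the grid"):
            fit_window(corrected(np.zeros(WN.size)), [], (5000.0, 6000.0))

    def test_band_outside_window_rejected(self):
        with pytest.raises(ValueError, match="not within"):
            fit_window(corrected(np.zeros(WN.size)), OOP_BAND, (1350.0, 1850.0))

    @pytest.mark.parametrize("c", [0.5, 3.7])
    def test_scale_equivariance(self, c):
        y = (gaussian(WN, 2920.0, 14.0, 0.08) + gaussian(WN, 2850.0, 13.0, 0.05))
        r1 = fit_window(corrected(y), ACH_BANDS, (2300.0, 3700.0))
        r2 = fit_window(corrected(c * y), ACH_BANDS, (2300.0, 3700.0))
        for name in ("aCH_2920", "aCH_2850"):
            assert r2[name].area == pytest.approx(c * r1[name].area, rel=1e-3)

    def test_zero_amplitude_extra_band_leaves_others_unchanged(self):
        y = gaussian(WN, 2920.0, 14.0, 0.08)
        band_2920 = next(b for b in ACH_BANDS if b.name == "aCH_2920")
        one = fit_window(corrected(y), [band_2920], (2300.0, 3700.0))
        both = fit_window(corrected(y), ACH_BANDS, (2300.0, 3700.0))
        assert both["aCH_2920"].area == pytest.approx(one["aCH_2920"].area, rel=0.01)
        assert both["aCH_2850"].area < 0.01 * one["aCH_2920"].area


class TestFitAllRegions:
    def test_regions_exclude_ptfe_window(self):
        for lo, hi in FIT_REGIONS:
            assert hi <= 1000.0 or lo >= 1300.0

    def test_archetype_band_truth_recovered(self):
        # noiseless sum of the generating Gaussians: every band comes back
        _, tr = generate_sample(ARCHETYPES["red_oak"], seed=77, noise_sd=0.0)
        y = tr.signal_values(WN)
        fits = collect_band_fits(fit_all_regions(corrected(y)))
        for name, (h, c, s, a) in tr.band_truth.items():
            if h < 1e-3:
                continue
            bf = fits[name]
            got = bf.height if bf.response == "height" else bf.area
            want = h if bf.response == "height" else a
            assert got == pytest.approx(want, rel=0.05), name

    def test_every_band_belongs_to_exactly_one_region(self):
        seen = []
        for region in FIT_REGIONS:
            seen += [b.name for b in bands_in_window(DEFAULT_BAND_TABLE, region)]
        assert sorted(seen) == sorted(b.name for b in DEFAULT_BAND_TABLE)


class TestAcidSignature:
    def test_flat_spectrum_is_false(self):
        ok, ev = detect_acid_signature(corrected(np.zeros(WN.size)))
        assert not ok

    def test_both_doublets_at_5x_noise_is_true(self):
        rng = np.random.default_rng(5)
        noise = 0.002
        y = (gaussian(WN, 2600.0, 25.0, 5 * 3 * noise)
             + gaussian(WN, 2400.0, 22.0, 5 * 3 * noise)
             + rng.normal(0, noise, WN.size))
        ok, ev = detect_acid_signature(corrected(y))
        assert ok
        assert ev.height_2600 > 3 * ev.noise and ev.height_2400 > 3 * ev.noise

    def test_single_doublet_is_false(self):
        y = gaussian(WN, 2600.0, 25.0, 0.05)
        ok, _ = detect_acid_signature(corrected(y))
        assert not ok

    def test_tiny_doublets_below_absolute_floor_are_false(self):
        y = (gaussian(WN, 2600.0, 25.0, 5e-4) + gaussian(WN, 2400.0, 22.0, 5e-4))
        ok, _ = detect_acid_signature(corrected(y))
        assert not ok


class TestBandTable:
    def test_default_centers_match_assignments(self):
        centers = {b.name: b.center for b in DEFAULT_BAND_TABLE}
        assert centers["aCOH_3500"] == 3500.0
        assert centers["rCH_oop_750"] == 750.0
        assert centers["lignin_1515"] == 1515.0
        assert centers["nitrate_1400"] == 1400.0 and centers["nitrate_830"] == 830.0

    def test_oop_band_reports_height_others_area(self):
        for b in DEFAULT_BAND_TABLE:
            expected = "height" if b.name == "rCH_oop_750" else "area"
            assert b.response == expected

    def test_center_must_lie_in_window(self):
        with pytest.raises(ValueError):
            BandDefinition("bad", 2000.0, 10.0, (5.0, 20.0), (650.0, 900.0))

    def test_round_trip_csv(self, tmp_path):
        from ftirfg.bands import read_band_table, write_band_table
        write_band_table(DEFAULT_BAND_TABLE, tmp_path / "bands.csv")
        back = read_band_table(tmp_path / "bands.csv")
        assert back == list(DEFAULT_BAND_TABLE)
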