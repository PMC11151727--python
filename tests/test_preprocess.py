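"""Smoothing-spline baseline, blank matching/subtraction, EC-baseline OLS."""

import numpy as np
import pytest

from ftirfg.preprocess import (
    DEFAULT_ANCHOR_REGIONS, PreprocessError, ec_baseline_regression,
    fit_baseline, ptfe_peak_height, select_blank, subtract_blank,
)
from ftirfg.spectra import CANONICAL_GRID, Spectrum
from ftirfg.synthetic import generate_blank, ptfe_profile

from conftest import gaussian

WN = np.asarray(CANONICAL_GRID)


class TestFitBaseline:
    def test_cubic_polynomial_fully_anchored_is_removed(self, make_spectrum):
        t = (WN - 2200.0) / 1800.0
        y = 0.1 + 0.05 * t + 0.2 * t**2 + 0.03 * t**3
        # anchors covering the whole range: the spline must reproduce y
        s = make_spectrum(y)
        res = fit_baseline(s, anchor_regions=[(400.0, 4000.0)])
        assert np.abs(res.corrected.absorbance).max() < 1e-6

    def test_quadratic_plus_band_recovered_within_2pct(self, make_spectrum):
        base = 0.3 * (WN / 4000.0) ** 2 + 0.05
        band = gaussian(WN, 1600.0, 25.0, 0.2)
        res = fit_baseline(make_spectrum(base + band))
        i = int(np.argmin(np.abs(WN - 1600.0)))
        assert res.corrected.absorbance[i] == pytest.approx(0.2, rel=0.02)

    def test_flat_zero_spectrum(self, make_spectrum):
        res = fit_baseline(make_spectrum(np.zeros(WN.size)))
        assert np.abs(res.baseline.absorbance).max() < 1e-9
        assert abs(res.baseline_at_4000) < 1e-9

    def test_baseline_at_4000_matches_construction(self, make_spectrum):
        base = 0.4 * (WN / 4000.0) ** 2 + 0.02
        res = fit_baseline(make_spectrum(base))
        assert res.baseline_at_4000 == pytest.approx(0.42, abs=1e-4)

    def test_corrected_equals_input_minus_baseline(self, make_spectrum):
        s = make_spectrum(0.2 * (WN / 4000.0) ** 2 + gaussian(WN, 1700, 14, 0.1))
        res = fit_baseline(s)
        np.testing.assert_allclose(
            res.corrected.absorbance,
            s.absorbance - res.baseline.absorbance, atol=1e-12,
        )

    def test_insufficient_anchor_points(self, make_spectrum):
        with pytest.raises(PreprocessError, match="anchor"):
            fit_baseline(make_spectrum(np.zeros(WN.size)),
                         anchor_regions=[(3998.0, 4000.0)])

    def test_nonpositive_smoothing_rejected(self, make_spectrum):
        with pytest.raises(PreprocessError):
            fit_baseline(make_spectrum(np.zeros(WN.size)), smoothing=0.0)

    def test_idempotence(self, make_spectrum):
        base = 0.3 * (WN / 4000.0) ** 2 + 0.05
        band = gaussian(WN, 1600.0, 25.0, 0.2)
        first = fit_baseline(make_spectrum(base + band))
        again = fit_baseline(first.corrected.with_absorbance(
            first.corrected.absorbance, stage="raw"))
        change = np.abs(again.corrected.absorbance - first.corrected.absorbance).max()
        assert change < 0.01 * np.abs(first.corrected.absorbance).max()

    def test_infinite_smoothing_tends_to_anchor_least_squares_line(self, make_spectrum):
        rng = np.random.default_rng(3)
        y = 0.1 + 5e-5 * WN + rng.normal(0, 0.002, WN.size)
        s = make_spectrum(y)
        res = fit_baseline(s, smoothing=1e14)
        mask = np.zeros(WN.size, bool)
        for lo, hi in DEFAULT_ANCHOR_REGIONS:
            mask |= (WN >= min(lo, hi)) & (WN <= max(lo, hi))
        coef = np.polyfit(WN[mask], y[mask], 1)
        line = np.polyval(coef, WN)
        assert np.abs(res.baseline.absorbance - line).max() < 0.01 * np.ptp(line)


class TestBlankHandling:
    def test_select_nearest_ptfe_height(self, make_spectrum):
        prof = ptfe_profile(WN)
        blanks = [make_spectrum(h * prof, stage="baselined", sid=f"b{h}", kind="blank")
                  for h in (0.5, 1.0, 2.0)]
        sample = make_spectrum(1.1 * prof, stage="baselined")
        assert select_blank(sample, blanks) == "b1.0"

    def test_exact_match_selected(self, make_spectrum):
        prof = ptfe_profile(WN)
        blanks = [make_spectrum(h * prof, stage="baselined", sid=f"b{h}", kind="blank")
                  for h in (0.5, 1.3, 2.0)]
        assert select_blank(blanks[1], blanks) == "b1.3"

    def test_tie_breaks_to_smallest_id(self, make_spectrum):
        prof = ptfe_profile(WN)
        b1 = make_spectrum(0.9 * prof, stage="baselined", sid="bB", kind="blank")
        b2 = make_spectrum(1.1 * prof, stage="baselined", sid="bA", kind="blank")
        sample = make_spectrum(1.0 * prof, stage="baselined")
        assert select_blank(sample, [b1, b2]) == "bA"

    def test_empty_library_rejected(self, make_spectrum):
        with pytest.raises(PreprocessError):
            select_blank(make_spectrum(np.zeros(WN.size)), [])

    def test_self_subtraction_gives_unit_scale(self, make_spectrum):
        blank = make_spectrum(ptfe_profile(WN), stage="baselined", kind="blank")
        out, match = subtract_blank(blank, blank)
        assert match.scale == pytest.approx(1.0, abs=1e-12)
        assert np.abs(out.absorbance).max() < 1e-12
        assert out.stage == "blank_subtracted"

    def test_known_scale_recovered_and_signal_preserved(self, make_spectrum):
        blank = fit_baseline(generate_blank(17, noise_sd=0.0)).corrected
        signal = gaussian(WN, 1600.0, 25.0, 0.2)  # no support in the PTFE window
        sample = make_spectrum(signal + 0.7 * blank.absorbance, stage="baselined")
        out, match = subtract_blank(sample, blank)
        assert match.scale == pytest.approx(0.70, abs=0.01)
        i = int(np.argmin(np.abs(WN - 1600.0)))
        assert out.absorbance[i] == pytest.approx(0.2, rel=0.01)

    def test_degenerate_blank_rejected(self, make_spectrum):
        blank = make_spectrum(np.zeros(WN.size), stage="baselined", kind="blank")
        sample = make_spectrum(np.ones(WN.size), stage="baselined")
        with pytest.raises(PreprocessError, match="degenerate"):
            subtract_blank(sample, blank)

    @pytest.mark.parametrize("c", [0.0, 0.4, 1.5])
    def test_subtraction_linearity_in_added_blank(self, make_spectrum, c):
        blank = fit_baseline(generate_blank(23, noise_sd=0.0)).corrected
        signal = gaussian(WN, 1700.0, 14.0, 0.1)
        base = make_spectrum(signal + 0.5 * blank.absorbance, stage="baselined")
        plus = make_spectrum(base.absorbance + c * blank.absorbance, stage="baselined")
        _, m0 = subtract_blank(base, blank)
        _, m1 = subtract_blank(plus, blank)
        assert m1.scale == pytest.approx(m0.scale + c, abs=1e-9)

    def test_ptfe_height_ratio_diagnostic(self, make_spectrum):
        blank = make_spectrum(ptfe_profile(WN), stage="baselined", kind="blank")
        sample = make_spectrum(1.4 * ptfe_profile(WN), stage="baselined")
        _, match = subtract_blank(sample, blank)
        ratio = match.ptfe_height_sample / match.ptfe_height_blank
        assert ratio == pytest.approx(1.4, rel=1e-9)


class TestEcBaselineRegression:
    def test_exact_generator_recovered(self):
        rng = np.random.default_rng(1)
        ec = rng.uniform(50, 500, 20)
        oc = rng.uniform(50, 500, 20)
        b = 5e-4
        records = [(2.2 * b * e + b * o, o, e) for e, o in zip(ec, oc)]
        coef_ec, coef_oc, ratio, r2 = ec_baseline_regression(records)
        assert ratio == pytest.approx(2.2, rel=1e-9)
        assert r2 == pytest.approx(1.0, abs=1e-12)

    def test_zero_ec_column_is_collinearity_error(self):
        records = [(0.1 * o, o, 0.0) for o in (10.0, 20.0, 30.0, 40.0)]
        with pytest.raises(PreprocessError, match="rank"):
            ec_baseline_regression(records)

    def test_too_few_records(self):
        with pytest.raises(PreprocessError):
            ec_baseline_regression([(0.1, 1.0, 1.0), (0.2, 2.0, 1.5)])
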