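"""Baseline correction, blank selection/subtraction, and the EC–baseline diagnostic.

The raw transmission spectrum of a loaded PTFE filter rides on a smooth
background from light scattering by the membrane and particles and from the
electronic-transition absorption of elemental carbon, which rises toward high
wavenumber.  That background is removed with a penalized smoothing spline
fitted only inside anchor regions — windows free of organic absorption bands —
and evaluated over the whole grid.  The spline value at 4000 cm⁻¹ is retained
as an EC proxy and can be regressed against collocated thermal–optical EC/OC
loadings (:func:`ec_baseline_regression`).

PTFE itself absorbs strongly at 1300–1000 cm⁻¹.  Each baselined sample is
paired with the library blank whose PTFE reference peak (≈1150 cm⁻¹) height
is closest, and a scaled version of that baseline-corrected blank is
subtracted; the scale is estimated by least squares over the PTFE-dominated
window, which uses all PTFE band structure rather than a single peak-height
ratio (the height ratio is retained as a diagnostic).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import statsmodels.api as sm
from scipy.interpolate import make_smoothing_spline

from .spectra import Spectrum, SpectrumError

__all__ = [
    "DEFAULT_ANCHOR_REGIONS",
    "ACID_SENSITIVE_ANCHOR",
    "PTFE_WINDOW",
    "PTFE_PEAK_WINDOW",
    "BaselineResult",
    "BlankMatch",
    "fit_baseline",
    "ptfe_peak_height",
    "select_blank",
    "subtract_blank",
    "ec_baseline_regression",
]

#: Absorption-free anchor windows (cm⁻¹), avoiding every assigned organic band.
DEFAULT_ANCHOR_REGIONS: tuple[tuple[float, float], ...] = (
    (3750.0, 4000.0),
    (2500.0, 2750.0),
    (1800.0, 1900.0),
    (900.0, 980.0),
    (620.0, 680.0),
)

#: Anchor dropped when the broad dimerized carboxylic-acid OH (3400–2400 cm⁻¹)
#: is present: its tail would pull the baseline up inside this window.
ACID_SENSITIVE_ANCHOR: tuple[float, float] = (2500.0, 2750.0)

#: PTFE-dominated window used for blank-scale estimation (cm⁻¹).
PTFE_WINDOW: tuple[float, float] = (1000.0, 1300.0)

#: Window for the PTFE reference peak height around 1150 cm⁻¹.
PTFE_PEAK_WINDOW: tuple[float, float] = (1120.0, 1180.0)


class PreprocessError(ValueError):
    pass


@dataclass(frozen=True)
class BaselineResult:
    """Output of :func:`fit_baseline`: corrected = input − baseline pointwise."""

    corrected: Spectrum
    baseline: Spectrum
    baseline_at_4000: float
    anchor_regions: tuple[tuple[float, float], ...]
    smoothing: float | str


@dataclass(frozen=True)
class BlankMatch:
    """Diagnostics of a blank subtraction.

    `scale` is the fitted non-negative multiplier s in sample − s·blank;
    `residual_norm` is the RMS of the residual over the PTFE window; the two
    peak heights give the simple height-ratio alternative estimate s ≈
    ptfe_height_sample / ptfe_height_blank.
    """

    blank_id: str
    scale: float
    residual_norm: float
    ptfe_height_sample: float
    ptfe_height_blank: float


def _anchor_mask(spectrum: Spectrum, regions: Sequence[tuple[float, float]]) -> np.ndarray:
    mask = np.zeros(len(spectrum), dtype=bool)
    for lo, hi in regions:
        lo, hi = min(lo, hi), max(lo, hi)
        mask |= spectrum.window(lo, hi)
    return mask


def _anchor_noise(x: np.ndarray, y: np.ndarray) -> float:
    """Robust noise sd from second differences of adjacent anchor points.

    Second differences annihilate linear (and nearly quadratic) baseline
    trend, so only genuine point-to-point noise survives; for white noise
    they have variance 6σ².  Only grid-adjacent triples (within one anchor
    window) are used so gaps between windows do not inflate the estimate.
    """
    dx = np.diff(x)
    step = float(np.median(dx[dx > 0]))
    adjacent = (dx[:-1] <= 1.5 * step) & (dx[1:] <= 1.5 * step)
    d2 = (y[2:] - 2 * y[1:-1] + y[:-2])[adjacent]
    if d2.size < 5:
        d2 = y[2:] - 2 * y[1:-1] + y[:-2]
    mad = float(np.median(np.abs(d2 - np.median(d2))))
    return 1.4826 * mad / math.sqrt(6.0)


def _auto_penalty(x: np.ndarray, y: np.ndarray) -> float | None:
    """Automatic spline-penalty selection over the anchor points.

    Effectively noiseless anchors (robust noise < 1e-6 AU) fall back to
    generalized cross-validation, which then interpolates the smooth anchor
    signal exactly.  Otherwise GCV badly undersmooths on clustered anchor
    windows (it happily interpolates the noise, letting the spline swing
    across the wide unanchored gaps), so λ is chosen by the discrepancy
    principle instead: the smallest λ whose anchor residual RMS reaches the
    noise estimate, found by bisection in log λ.
    """
    noise = _anchor_noise(x, y)
    if noise < 1e-6:
        return None  # GCV
    lo, hi = 0.0, 24.0  # log10 λ bounds
    for _ in range(40):
        mid = 0.5 * (lo + hi)
        spl = make_smoothing_spline(x, y, lam=10.0**mid)
        rms = float(np.sqrt(np.mean((y - spl(x)) ** 2)))
        if rms < noise:
            lo = mid
        else:
            hi = mid
    return 10.0 ** (0.5 * (lo + hi))


def fit_baseline(
    spectrum: Spectrum,
    anchor_regions: Sequence[tuple[float, float]] = DEFAULT_ANCHOR_REGIONS,
    smoothing: float | str = "auto",
) -> BaselineResult:
    """Fit a penalized smoothing-spline baseline through anchor regions.

    Parameters
    ----------
    spectrum : Spectrum
        A raw (or already corrected, for idempotence checks) spectrum.
    anchor_regions : sequence of (lo, hi) cm⁻¹ intervals
        Only grid points inside these windows constrain the spline; it is
        then evaluated over the full grid and subtracted.
    smoothing : float or "auto"
        Spline penalty λ; "auto" selects it by generalized cross-validation
        over the anchor points.

    Returns
    -------
    BaselineResult
        With `corrected.stage == "baselined"` and the 4000 cm⁻¹ baseline
        value recorded as an elemental-carbon proxy.
    """
    if isinstance(smoothing, str):
        if smoothing != "auto":
            raise PreprocessError(f"smoothing must be a positive number or 'auto', got {smoothing!r}")
        lam = "auto"
    else:
        if not smoothing > 0:
            raise PreprocessError(f"smoothing penalty must be > 0, got {smoothing}")
        lam = float(smoothing)

    mask = _anchor_mask(spectrum, anchor_regions)
    if int(mask.sum()) < 10:
        raise PreprocessError(
            f"anchor regions cover only {int(mask.sum())} grid points (< 10)"
        )

    x = spectrum.wavenumbers[mask]
    y = spectrum.absorbance[mask]
    order = np.argsort(x)  # spline wants ascending abscissae
    xs, ys = x[order], y[order]
    if lam == "auto":
        lam = _auto_penalty(xs, ys)
    spl = make_smoothing_spline(xs, ys, lam=lam)
    baseline_vals = spl(spectrum.wavenumbers)

    corrected = spectrum.with_absorbance(
        spectrum.absorbance - baseline_vals, stage="baselined"
    )
    baseline = Spectrum(
        id=f"{spectrum.id}__baseline", wavenumbers=spectrum.wavenumbers,
        absorbance=baseline_vals, stage=spectrum.stage, filter_kind=spectrum.filter_kind,
    )
    at4000 = float(spl(4000.0))
    return BaselineResult(
        corrected=corrected, baseline=baseline, baseline_at_4000=at4000,
        anchor_regions=tuple((float(a), float(b)) for a, b in anchor_regions),
        smoothing=smoothing,
    )


def ptfe_peak_height(spectrum: Spectrum, window: tuple[float, float] = PTFE_PEAK_WINDOW) -> float:
    """Maximum absorbance over the PTFE reference-peak window (≈1150 cm⁻¹)."""
    mask = spectrum.window(*window)
    if not mask.any():
        raise PreprocessError("PTFE peak window does not intersect the grid")
    return float(spectrum.absorbance[mask].max())


def select_blank(sample: Spectrum, blanks: Sequence[Spectrum]) -> str:
    """Pick the blank whose PTFE reference-peak height best matches the sample's.

    Ties are broken toward the lexicographically smallest blank id
    (deterministic, no seed involved).
    """
    if not blanks:
        raise PreprocessError("blank library is empty")
    target = ptfe_peak_height(sample)
    best_id: str | None = None
    best_d = np.inf
    for b in sorted(blanks, key=lambda s: s.id):
        d = abs(ptfe_peak_height(b) - target)
        if d < best_d - 1e-15:
            best_d, best_id = d, b.id
    assert best_id is not None
    return best_id


def subtract_blank(
    sample: Spectrum,
    blank: Spectrum,
    window: tuple[float, float] = PTFE_WINDOW,
) -> tuple[Spectrum, BlankMatch]:
    """Subtract a scaled baseline-corrected blank from a baseline-corrected sample.

    The scale s ≥ 0 minimises ‖sample − s·blank‖² over the PTFE-dominated
    window; the returned spectrum (sample − s·blank over the full grid) has
    stage ``blank_subtracted``.
    """
    if sample.wavenumbers.shape != blank.wavenumbers.shape or not np.array_equal(
        sample.wavenumbers, blank.wavenumbers
    ):
        raise SpectrumError("sample and blank must share one grid")
    mask = sample.window(*window)
    bw = blank.absorbance[mask]
    denom = float(bw @ bw)
    if denom <= 0.0 or not np.isfinite(denom):
        raise PreprocessError(
            f"blank {blank.id!r} has zero energy in the PTFE window — degenerate blank"
        )
    s = float(sample.absorbance[mask] @ bw) / denom
    s = max(s, 0.0)
    residual = sample.absorbance - s * blank.absorbance
    resid_norm = float(np.sqrt(np.mean(residual[mask] ** 2)))
    out = Spectrum(
        id=sample.id, wavenumbers=sample.wavenumbers, absorbance=residual,
        stage="blank_subtracted", filter_kind=sample.filter_kind,
    )
    match = BlankMatch(
        blank_id=blank.id, scale=s, residual_norm=resid_norm,
        ptfe_height_sample=ptfe_peak_height(sample),
        ptfe_height_blank=ptfe_peak_height(blank),
    )
    return out, match


def ec_baseline_regression(
    records: Sequence[tuple[float, float, float]],
) -> tuple[float, float, float, float]:
    """OLS of the 4000 cm⁻¹ baseline value on EC and OC loadings.

    Parameters
    ----------
    records : sequence of (baseline_at_4000 AU, oc µg, ec µg) triples

    Returns
    -------
    (coef_ec, coef_oc, ratio, r_squared)
        Slopes of the fit baseline ~ EC + OC + intercept, their ratio
        coef_ec / coef_oc, and the coefficient of determination.  A large
        ratio indicates elemental carbon dominates the spectral baseline
        through its electronic-transition absorption.
    """
    if len(records) < 3:
        raise PreprocessError("need at least 3 records for the EC/OC regression")
    arr = np.asarray(records, dtype=float)
    y = arr[:, 0]
    X = arr[:, [2, 1]]  # columns: EC, OC
    if np.linalg.matrix_rank(np.column_stack([X, np.ones(len(y))])) < 3:
        raise PreprocessError("EC/OC design is rank-deficient (collinear or constant)")
    model = sm.OLS(y, sm.add_constant(X)).fit()
    coef_ec, coef_oc = float(model.params[1]), float(model.params[2])
    ratio = coef_ec / coef_oc if coef_oc != 0 else np.inf
    return coef_ec, coef_oc, float(ratio), float(model.rsquared)
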