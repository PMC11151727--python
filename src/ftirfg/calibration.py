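"""Beer–Lambert calibration: band response ↔ µmol of bond.

Under Beer–Lambert behaviour a band's fitted response (peak area or peak
height after baseline and blank correction) is proportional to the number of
absorbing bonds on the filter deposit: response = ε · n.  The slope ε is an
empirical response-per-µmol constant estimated from laboratory standards by
through-origin least squares (a blank filter carries zero analyte), and its
inverse converts fitted responses to bond abundances.

The aromatic CH out-of-plane (OOP) bend near 750 cm⁻¹ is calibrated with
anthracene (C₁₄H₁₀) standards: each anthracene molecule carries 10 aromatic
CH bonds, so a known areal mass loading converts directly to µmol of CH bond
(:func:`anthracene_moles_ch`).  The OOP band uses the fitted peak HEIGHT as
its response; all other bands use peak area.  The default absorptivity for
the OOP height response is 0.017 AU µmol⁻¹ of CH bond under this package's
normalization; the remaining defaults are literature-lineage placeholders
shipped as configurable constants (see the absorptivity table), not asserted
calibration results.

Unit convention: bond abundances are µmol per filter throughout; heights are
AU and areas AU·cm⁻¹.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .peakfit import BandFit

__all__ = [
    "M_ANTHRACENE", "CalibrationModel", "anthracene_moles_ch",
    "build_calibration", "apply_calibration",
    "DEFAULT_ABSORPTIVITIES", "read_absorptivity_table", "write_absorptivity_table",
    "abundances_from_fits",
]

#: Standard atomic masses (g mol⁻¹).
M_C = 12.011
M_H = 1.008
#: Molar mass of anthracene C₁₄H₁₀.
M_ANTHRACENE = 14 * M_C + 10 * M_H  # 178.234 g mol⁻¹

#: Aromatic CH bonds per anthracene molecule.
CH_PER_ANTHRACENE = 10


class CalibrationError(ValueError):
    pass


@dataclass(frozen=True)
class CalibrationModel:
    """A through-origin (by default) Beer–Lambert line for one band.

    absorptivity is the slope: response units per µmol of bond (AU µmol⁻¹
    for height responses, AU·cm⁻¹ µmol⁻¹ for area responses).
    """

    band_name: str
    response: str                    # 'height' or 'area'
    absorptivity: float
    r_squared: float
    n_standards: int
    forced_through_origin: bool = True
    intercept: float = 0.0

    def __post_init__(self) -> None:
        if not self.absorptivity > 0:
            raise CalibrationError(
                f"{self.band_name}: absorptivity must be > 0, got {self.absorptivity}"
            )


def anthracene_moles_ch(mass_loading: float, deposit_area: float) -> float:
    """µmol of aromatic CH bond on an anthracene calibration deposit.

    Parameters
    ----------
    mass_loading : µg cm⁻² of anthracene
    deposit_area : cm² of the collection spot

    Returns
    -------
    float
        µmol CH = (mass_loading · deposit_area / M_anthracene) · 10,
        since each C₁₄H₁₀ molecule carries 10 aromatic CH bonds.
    """
    if not (mass_loading > 0 and deposit_area > 0):
        raise CalibrationError("mass loading and deposit area must both be > 0")
    total_ug = mass_loading * deposit_area
    umol_molecule = total_ug / M_ANTHRACENE  # µg / (g mol⁻¹) = µmol
    return umol_molecule * CH_PER_ANTHRACENE


def build_calibration(
    standards: Sequence[tuple[float, float]],
    band_name: str = "rCH_oop_750",
    response: str = "height",
    through_origin: bool = True,
) -> CalibrationModel:
    """Fit a Beer–Lambert line to (response, µmol-of-bond) standards.

    The slope of response on moles is the absorptivity; R² is reported
    against the fitted line using the conventional centered total sum of
    squares.  Requires ≥ 3 standards with non-degenerate abscissae.
    """
    if len(standards) < 3:
        raise CalibrationError(f"need ≥ 3 standards, got {len(standards)}")
    arr = np.asarray(standards, dtype=float)
    y, x = arr[:, 0], arr[:, 1]  # response, moles
    if np.ptp(x) <= 0:
        raise CalibrationError("all standards share one abundance — zero-variance abscissae")
    if through_origin:
        slope = float(x @ y) / float(x @ x)
        intercept = 0.0
    else:
        slope, intercept = np.polyfit(x, y, 1)
        slope, intercept = float(slope), float(intercept)
    fitted = slope * x + intercept
    ss_res = float(np.sum((y - fitted) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return CalibrationModel(
        band_name=band_name, response=response, absorptivity=slope,
        r_squared=float(np.clip(r2, 0.0, 1.0)), n_standards=len(standards),
        forced_through_origin=through_origin, intercept=intercept,
    )


def apply_calibration(fit: BandFit | float, model: CalibrationModel) -> tuple[float, bool]:
    """Invert the Beer–Lambert line: µmol = (response − intercept) / ε.

    Accepts a :class:`BandFit` (its declared response kind must match the
    model) or a raw response value.  Negative responses map to 0 µmol with
    a True clipped-flag in the second return slot.
    """
    if isinstance(fit, BandFit):
        if fit.response != model.response:
            raise CalibrationError(
                f"{model.band_name}: model expects {model.response!r} response, "
                f"band reports {fit.response!r}"
            )
        value = fit.response_value
    else:
        value = float(fit)
    moles = (value - model.intercept) / model.absorptivity
    if moles < 0:
        return 0.0, True
    return float(moles), False


# ---------------------------------------------------------------------------
# absorptivity table

#: Default absorptivity constants (response per µmol of bond).
#: The rCH OOP height value 0.017 is the anthracene-derived constant; the
#: others are placeholder constants of literature lineage, shipped for
#: configuration rather than asserted — replace with laboratory values when
#: available.  Area responses are AU·cm⁻¹ µmol⁻¹; height responses AU µmol⁻¹.
DEFAULT_ABSORPTIVITIES: dict[str, CalibrationModel] = {
    name: CalibrationModel(band_name=name, response=resp, absorptivity=eps,
                           r_squared=float("nan"), n_standards=0)
    for name, resp, eps in (
        ("aCH3_2960", "area", 0.35),
        ("aCH_2920", "area", 0.35),
        ("aCH_2850", "area", 0.35),
        ("rCH_stretch_3050", "area", 0.10),
        ("rCH_oop_750", "height", 0.017),
        ("aCOH_3500", "area", 1.20),
        ("COOH_OH_broad", "area", 2.00),
        ("COOH_doublet_2600", "area", 0.20),
        ("COOH_doublet_2400", "area", 0.20),
        ("carbonyl_CO_1700", "area", 0.50),
    )
}

#: Bands that feed each functional group's abundance.
FG_BAND_MAP: dict[str, tuple[str, ...]] = {
    "aCH": ("aCH_2850", "aCH_2920", "aCH3_2960"),
    "rCH": ("rCH_oop_750",),
    "aCOH": ("aCOH_3500",),
    "acid_OH": ("COOH_OH_broad",),
    "carbonyl": ("carbonyl_CO_1700",),
}


def abundances_from_fits(
    band_fits: Mapping[str, BandFit],
    absorptivities: Mapping[str, CalibrationModel] = DEFAULT_ABSORPTIVITIES,
) -> dict[str, float]:
    """Convert fitted band responses to per-group µmol abundances.

    aCH sums its three CH-stretch sub-bands; rCH comes from the OOP height;
    the broad acid OH and the carbonyl are reported separately and
    apportioned into COOH / non-acid carbonyl downstream.  Missing or
    negative responses contribute 0.
    """
    out: dict[str, float] = {}
    for fg, band_names in FG_BAND_MAP.items():
        total = 0.0
        for bn in band_names:
            if bn not in band_fits or bn not in absorptivities:
                continue
            moles, _ = apply_calibration(band_fits[bn], absorptivities[bn])
            total += moles
        out[fg] = total
    return out


def write_absorptivity_table(models: Mapping[str, CalibrationModel], path: str | Path) -> None:
    rows = [
        {"band_name": m.band_name, "response": m.response,
         "absorptivity": m.absorptivity, "r_squared": m.r_squared,
         "n_standards": m.n_standards}
        for m in models.values()
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_absorptivity_table(path: str | Path) -> dict[str, CalibrationModel]:
    df = pd.read_csv(path, dtype={"band_name": str, "response": str})
    out = {}
    for _, row in df.iterrows():
        out[row["band_name"]] = CalibrationModel(
            band_name=row["band_name"], response=row["response"],
            absorptivity=float(row["absorptivity"]),
            r_squared=float(row["r_squared"]),
            n_standards=int(row["n_standards"]),
        )
    return out
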