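"""The vibrational band table: fixed band definitions and their fit windows.

Band centers follow standard mid-infrared assignments for combustion organic
aerosol on PTFE filters: the broad alcohol COH stretch near 3500 cm⁻¹,
aromatic CH stretch near 3050 cm⁻¹, the aliphatic CH stretches (asymmetric
CH₃ ≈2960, asymmetric CH₂ ≈2920, symmetric CH₂ ≈2850 cm⁻¹), the very broad
dimerized carboxylic-acid OH (3400–2400 cm⁻¹) with its doublets near 2600 and
2400 cm⁻¹, the carbonyl C=O near 1700 cm⁻¹, aromatic ring C=C near 1600 cm⁻¹,
the lignin aromatic ring stretch at 1515 cm⁻¹, inorganic nitrate at 1400 and
830 cm⁻¹, and the aromatic CH out-of-plane (OOP) bend near 750 cm⁻¹ used for
PAH quantification.  The PTFE interference region 1300–1000 cm⁻¹ carries no
bands and is excluded from all fitting and reporting.

All bands are Gaussian.  Every band reports its integrated area except the
OOP bend, whose calibrated response is the fitted peak height.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd

__all__ = ["BandDefinition", "DEFAULT_BAND_TABLE", "FIT_REGIONS",
           "read_band_table", "write_band_table", "bands_in_window"]


@dataclass(frozen=True)
class BandDefinition:
    """One fixed vibrational band.

    center_tol bounds how far the fitted center may move from the nominal
    center (cm⁻¹); sigma_bounds bound the Gaussian width; window is the fit
    region the band belongs to; response says which fitted quantity the
    calibration consumes ('area' in AU·cm⁻¹ or 'height' in AU).
    """

    name: str
    center: float
    center_tol: float
    sigma_bounds: tuple[float, float]
    window: tuple[float, float]
    response: str = "area"
    profile: str = "gaussian"

    def __post_init__(self) -> None:
        lo, hi = self.window
        if not (min(lo, hi) <= self.center <= max(lo, hi)):
            raise ValueError(f"{self.name}: center {self.center} outside window {self.window}")
        slo, shi = self.sigma_bounds
        if not (0 < slo <= shi):
            raise ValueError(f"{self.name}: sigma bounds must be positive and ordered")
        if self.response not in ("area", "height"):
            raise ValueError(f"{self.name}: response must be 'area' or 'height'")
        if self.profile != "gaussian":
            raise ValueError(f"{self.name}: only gaussian profiles are supported")


#: Fit regions (cm⁻¹), excluding the PTFE interference window 1300–1000.
#: The OH/CH stretch super-region 3700–2300 is fitted as ONE window: the
#: broad dimerized-acid OH (σ up to ~300 cm⁻¹) spans both the 3500 and the
#: 3000–2400 neighbourhoods, and splitting it across two windows makes its
#: truncated halves degenerate with each window's local baseline term.
FIT_REGIONS: tuple[tuple[float, float], ...] = (
    (2300.0, 3700.0),
    (1350.0, 1850.0),
    (650.0, 900.0),
)

_R12, _R3, _R4 = FIT_REGIONS
_R1 = _R2 = _R12

DEFAULT_BAND_TABLE: tuple[BandDefinition, ...] = (
    BandDefinition("aCOH_3500", 3500.0, 20.0, (40.0, 90.0), _R1),
    BandDefinition("rCH_stretch_3050", 3050.0, 10.0, (8.0, 25.0), _R2),
    BandDefinition("aCH3_2960", 2960.0, 10.0, (8.0, 20.0), _R2),
    BandDefinition("aCH_2920", 2920.0, 10.0, (8.0, 20.0), _R2),
    BandDefinition("aCH_2850", 2850.0, 10.0, (8.0, 20.0), _R2),
    BandDefinition("COOH_OH_broad", 2900.0, 50.0, (150.0, 350.0), _R2),
    BandDefinition("COOH_doublet_2600", 2600.0, 15.0, (15.0, 40.0), _R2),
    BandDefinition("COOH_doublet_2400", 2400.0, 15.0, (15.0, 35.0), _R2),
    BandDefinition("carbonyl_CO_1700", 1700.0, 12.0, (8.0, 25.0), _R3),
    BandDefinition("aromatic_CC_1600", 1600.0, 10.0, (15.0, 40.0), _R3),
    BandDefinition("lignin_1515", 1515.0, 8.0, (8.0, 20.0), _R3),
    BandDefinition("nitrate_1400", 1400.0, 10.0, (10.0, 30.0), _R3),
    BandDefinition("nitrate_830", 830.0, 10.0, (8.0, 20.0), _R4),
    BandDefinition("rCH_oop_750", 750.0, 10.0, (4.0, 15.0), _R4, response="height"),
)


def bands_in_window(
    bands: tuple[BandDefinition, ...] | list[BandDefinition],
    window: tuple[float, float],
) -> list[BandDefinition]:
    lo, hi = min(window), max(window)
    return [b for b in bands if min(b.window) >= lo - 1e-9 and max(b.window) <= hi + 1e-9]


_COLS = ["name", "center", "center_tol", "sigma_lo", "sigma_hi",
         "window_lo", "window_hi", "response"]


def write_band_table(bands: list[BandDefinition] | tuple[BandDefinition, ...],
                     path: str | Path) -> None:
    rows = [
        {"name": b.name, "center": b.center, "center_tol": b.center_tol,
         "sigma_lo": b.sigma_bounds[0], "sigma_hi": b.sigma_bounds[1],
         "window_lo": b.window[0], "window_hi": b.window[1], "response": b.response}
        for b in bands
    ]
    pd.DataFrame(rows, columns=_COLS).to_csv(path, index=False)


def read_band_table(path: str | Path) -> list[BandDefinition]:
    df = pd.read_csv(path, dtype={"name": str, "response": str})
    return [
        BandDefinition(
            name=row["name"], center=float(row["center"]),
            center_tol=float(row["center_tol"]),
            sigma_bounds=(float(row["sigma_lo"]), float(row["sigma_hi"])),
            window=(float(row["window_lo"]), float(row["window_hi"])),
            response=row["response"],
        )
        for _, row in df.iterrows()
    ]
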