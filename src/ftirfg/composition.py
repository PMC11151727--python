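"""Functional-group abundances → OC, OM, OM/OC, PAH mass, and emission factors.

Each functional group carries an attributed number of carbon atoms per bond
and a per-bond organic-matter mass (the group's own atoms plus the attributed
carbon), so that

    OC = Σ_g n_g · c_g · 12.011   [µg, n_g in µmol]
    OM = Σ_g n_g · m_g            [µg]

with OM/OC their ratio.  PAH mass follows from aromatic-CH bond abundance
under an effective C/H molar ratio of 1.4 (anthracene-like):
mass = n_rCH · (1.008 + 1.4·12.011) µg per µmol.

The carbonyl band counts both carboxylic-acid C=O and non-acid carbonyls;
it is apportioned against the measured acid-OH abundance (each COOH carries
one acid OH and one C=O): COOH = min(carbonyl, acid OH), the remainder being
non-acid carbonyl.

Emission factors convert filter mass to emitted mass per MJ of energy
delivered to the pot using the dilution-tunnel geometry:
EF = mass · (tunnel_flow / sample_flow) / energy_delivered.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .calibration import M_C, M_H
from .spectra import SampleMeta

__all__ = [
    "AttributionRow", "AttributionTable", "DEFAULT_ATTRIBUTION",
    "CompositionResult", "fg_to_oc_om", "pah_mass", "artifact_correct",
    "emission_factor", "apportion_carbonyl", "compare_pah_estimates",
]


class CompositionError(ValueError):
    pass


@dataclass(frozen=True)
class AttributionRow:
    """Carbon and OM mass attributed to one functional group, per µmol of bond."""

    carbon_per_bond: float   # mol C per mol bond
    om_mass_per_bond: float  # g mol⁻¹ (µg per µmol): group atoms + attributed C

    def __post_init__(self) -> None:
        if not self.om_mass_per_bond > M_C * self.carbon_per_bond:
            raise CompositionError(
                "om_mass_per_bond must exceed the attributed carbon mass "
                f"({self.om_mass_per_bond} ≤ {M_C * self.carbon_per_bond})"
            )


AttributionTable = Mapping[str, AttributionRow]

#: Default attribution per µmol of bond/group.  aCH: half a carbon per CH
#: bond (CH₂ assumption, mass CH₂/2 = 7.014).  rCH: 1.4 carbons per aromatic
#: CH bond, anthracene-like, mass 1.008 + 1.4·12.011.  aCOH: one carbon,
#: mass C+O+H.  COOH: one carbon, mass C+2O+H.  naCO: one carbon, mass C+O.
DEFAULT_ATTRIBUTION: dict[str, AttributionRow] = {
    "aCH": AttributionRow(0.5, 7.014),
    "rCH": AttributionRow(1.4, M_H + 1.4 * M_C),  # 17.8234
    "aCOH": AttributionRow(1.0, 29.018),
    "COOH": AttributionRow(1.0, 45.017),
    "naCO": AttributionRow(1.0, 28.010),
}

#: Effective PAH carbon-to-hydrogen molar ratio (anthracene C₁₄H₁₀ has 14/10).
DEFAULT_C_TO_H = 1.4


@dataclass
class CompositionResult:
    """OC/OM/PAH composition of one filter deposit (masses in µg)."""

    oc: float
    om: float
    om_oc: float | None              # None when OC = 0
    per_fg_om: dict[str, float]      # µg OM contributed by each group
    pah_mass: float = 0.0
    ec_tc: float | None = None       # EC/(EC+OC), needs external EC
    emission_factors: dict[str, float] = field(default_factory=dict)  # mg MJ⁻¹
    flags: list[str] = field(default_factory=list)


def fg_to_oc_om(
    abundances: Mapping[str, float],
    table: AttributionTable = DEFAULT_ATTRIBUTION,
) -> CompositionResult:
    """Convert per-group bond abundances (µmol) to OC and OM mass (µg).

    Groups absent from the attribution table are ignored with a flag; an
    all-zero abundance vector yields OC = OM = 0 with OM/OC reported as
    missing (None), not an error.
    """
    flags: list[str] = []
    oc = 0.0
    per_fg: dict[str, float] = {}
    for fg, n in abundances.items():
        if n < 0:
            raise CompositionError(f"negative abundance for {fg}: {n}")
        if fg not in table:
            flags.append(f"no attribution row for {fg!r}; skipped")
            continue
        row = table[fg]
        oc += n * row.carbon_per_bond * M_C
        per_fg[fg] = n * row.om_mass_per_bond
    om = float(sum(per_fg.values()))
    om_oc = om / oc if oc > 0 else None
    if om_oc is None:
        flags.append("OC is zero; OM/OC undefined")
    return CompositionResult(oc=float(oc), om=om, om_oc=om_oc,
                             per_fg_om=per_fg, flags=flags)


def pah_mass(rch_moles: float, c_to_h: float = DEFAULT_C_TO_H) -> float:
    """PAH mass (µg) from aromatic CH bond abundance (µmol).

    Each measured aromatic CH bond is assigned one hydrogen and `c_to_h`
    carbons: mass = n · (M_H + c_to_h · M_C).
    """
    if rch_moles < 0:
        raise CompositionError(f"negative rCH abundance: {rch_moles}")
    if c_to_h <= 0:
        raise CompositionError(f"C/H ratio must be > 0, got {c_to_h}")
    return rch_moles * (M_H + c_to_h * M_C)


def artifact_correct(front: float, back: float) -> tuple[float, bool]:
    """Back-filter artifact correction: front − back.

    The quartz back filter captures vapour adsorption; subtracting it makes
    filter media comparable.  Negative results are retained (back/front
    ratios above 1 do occur for semivolatile-rich emissions) and flagged.
    """
    corrected = front - back
    return corrected, corrected < 0


def emission_factor(mass_on_filter: float, meta: SampleMeta) -> float:
    """Emission factor in mg per MJ of energy delivered to the pot.

    Scales the filter mass by the dilution ratio tunnel_flow/sample_flow
    (the tunnel flow is m³ min⁻¹, the filter sample flow L min⁻¹; the
    1000 L/m³ conversion is handled here) and divides by delivered energy.
    """
    if mass_on_filter < 0:
        raise CompositionError(f"negative filter mass: {mass_on_filter}")
    # SampleMeta validates flows/energy > 0 at construction
    dilution = (meta.tunnel_flow * 1000.0) / meta.sample_flow
    ef_ug = mass_on_filter * dilution / meta.energy_delivered
    return ef_ug / 1000.0  # µg MJ⁻¹ → mg MJ⁻¹


def apportion_carbonyl(carbonyl_moles: float, acid_oh_moles: float) -> tuple[float, float]:
    """Split total carbonyl into carboxylic-acid and non-acid carbonyl.

    Each COOH carries exactly one acid OH and one C=O, so the acid fraction
    cannot exceed either measurement: COOH = min(carbonyl, acid OH); the
    remainder is non-acid carbonyl.  Conserves moles: COOH + naCO = carbonyl.
    """
    if carbonyl_moles < 0 or acid_oh_moles < 0:
        raise CompositionError("carbonyl apportionment needs non-negative inputs")
    cooh = min(carbonyl_moles, acid_oh_moles)
    return cooh, carbonyl_moles - cooh


def compare_pah_estimates(
    ftir: Mapping[str, float],
    gcms: Mapping[str, float],
) -> tuple[float, float, float]:
    """Compare spectroscopic and chromatographic PAH mass per sample.

    Through-origin regression of the FTIR (aromatic-CH-derived) PAH mass on
    the GC–MS summed PAH mass over samples present in both tables.

    Returns
    -------
    (slope, r_squared, ratio_of_totals)
        slope of FTIR on GC–MS through the origin, R² about the fitted
        line (centered total SS), and Σ FTIR / Σ GC–MS.
    """
    ids = sorted(set(ftir) & set(gcms))
    if len(ids) < 3:
        raise CompositionError(
            f"need ≥ 3 paired samples, got {len(ids)} overlapping ids"
        )
    x = np.array([gcms[i] for i in ids], dtype=float)
    y = np.array([ftir[i] for i in ids], dtype=float)
    denom = float(x @ x)
    if denom <= 0:
        raise CompositionError("GC–MS values are all zero")
    slope = float(x @ y) / denom
    ss_res = float(np.sum((y - slope * x) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    totals = float(y.sum()) / float(x.sum()) if x.sum() != 0 else np.inf
    return slope, float(r2), totals
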