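"""Forward-model generator of spectra, blanks, standards, and pseudo-references.

A synthetic sample spectrum is built additively, mirroring the physics of a
loaded PTFE filter in transmission:

    A(ν̃) = baseline(ν̃; EC, scatter) + i·PTFE(ν̃) + Σ_g n_g ε_g profile_g(ν̃) + noise

* the baseline is a smooth curve rising toward high wavenumber whose
  4000 cm⁻¹ value grows linearly in elemental carbon (electronic-transition
  absorption) and, more weakly, in organic carbon — with the EC coefficient
  2.2× the OC coefficient so the EC–baseline regression diagnostic is
  recoverable;
* PTFE contributes a fixed band cluster in 1300–1000 cm⁻¹ with a per-filter
  intensity;
* each functional group contributes Gaussian bands whose responses follow
  the same absorptivity table the quantification inverts;
* band abundances are lognormal per fuel archetype (positive, right-skewed,
  as emission-factor spreads are), with charcoal / kerosene / red-oak
  archetypes encoding the qualitative spectral profiles of those emissions
  (red oak: strong broad alcohol OH; kerosene: prominent aromatics, frequent
  carboxylic-acid signature, CH₃-rich aliphatics; charcoal: strong aliphatic
  CH and aromatic C=C).

Every generated quantity is recorded in a :class:`TruthRecord`, and
:func:`generate_study` adds self-consistent pseudo-reference tables:
pseudo-TOT OC = FG OC·(1+δ)+noise (δ defaults to +0.67, i.e. spectroscopic
OC recovering ~60 % of thermal–optical OC) and pseudo-GC–MS PAH sum =
spectroscopic PAH mass / k + noise (k defaults to 19.6).  Identical seeds
give bit-identical datasets.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .calibration import DEFAULT_ABSORPTIVITIES, M_C, M_H
from .composition import DEFAULT_ATTRIBUTION, DEFAULT_C_TO_H, fg_to_oc_om
from .spectra import CANONICAL_GRID, ReferenceMeasures, SampleMeta, Spectrum

__all__ = [
    "Archetype", "TruthRecord", "StudyData", "ARCHETYPES",
    "generate_blank", "generate_sample", "generate_study",
    "ptfe_profile", "generate_anthracene_standards",
]

SQRT_2PI = math.sqrt(2.0 * math.pi)

#: Baseline coefficients: AU at 4000 cm⁻¹ per µg of EC / OC on the filter.
#: The EC coefficient is 2.2× the OC coefficient by construction.
BASELINE_COEF_OC = 5.0e-4
BASELINE_COEF_EC = 2.2 * BASELINE_COEF_OC

#: Fixed Gaussian band shapes (center cm⁻¹, σ cm⁻¹) used by the generator;
#: every σ lies inside the fit table's bounds for that band.
BAND_SHAPES: dict[str, tuple[float, float]] = {
    "aCOH_3500": (3500.0, 60.0),
    "rCH_stretch_3050": (3050.0, 15.0),
    "aCH3_2960": (2960.0, 12.0),
    "aCH_2920": (2920.0, 14.0),
    "aCH_2850": (2850.0, 13.0),
    "COOH_OH_broad": (2900.0, 220.0),
    "COOH_doublet_2600": (2600.0, 25.0),
    "COOH_doublet_2400": (2400.0, 22.0),
    "carbonyl_CO_1700": (1700.0, 14.0),
    "aromatic_CC_1600": (1600.0, 25.0),
    "lignin_1515": (1515.0, 12.0),
    "nitrate_1400": (1400.0, 18.0),
    "nitrate_830": (830.0, 12.0),
    "rCH_oop_750": (750.0, 8.0),
}

#: PTFE band cluster (center, σ, relative height), unit peak height overall.
_PTFE_BANDS = ((1210.0, 20.0, 1.0), (1152.0, 15.0, 0.95), (1110.0, 12.0, 0.30))


def _gauss(x: np.ndarray, center: float, sigma: float) -> np.ndarray:
    return np.exp(-0.5 * ((x - center) / sigma) ** 2)


def _ptfe_unnormalized(wn: np.ndarray) -> np.ndarray:
    prof = np.zeros_like(wn)
    for c, s, h in _PTFE_BANDS:
        prof += h * _gauss(wn, c, s)
    return prof


#: Peak height of the raw cluster (on a dense grid), fixed so the profile is
#: unit-height regardless of the grid it is evaluated on.
_PTFE_NORM = float(_ptfe_unnormalized(np.linspace(1000.0, 1300.0, 3001)).max())


def ptfe_profile(wavenumbers: np.ndarray = CANONICAL_GRID) -> np.ndarray:
    """Unit-height PTFE absorption cluster in the 1300–1000 cm⁻¹ window."""
    wn = np.asarray(wavenumbers, dtype=float)
    return _ptfe_unnormalized(wn) / _PTFE_NORM


@dataclass(frozen=True)
class Archetype:
    """Fuel-specific generating distribution of band abundances.

    fg_median gives per-group median abundances in µmol of bond (aCH is the
    total over its three sub-bands, split per ach_split); fg_gsd the common
    geometric standard deviation; ec_median/ec_gsd the lognormal elemental
    carbon loading (µg); acid_prob the probability a sample carries the
    dimerized carboxylic-acid signature (otherwise its COOH abundance is
    scaled down by acid_off_factor); aux_height median peak heights (AU) of
    the structural bands not converted to mass (aromatic C=C, lignin,
    nitrates).
    """

    fuel: str
    fg_median: Mapping[str, float]        # aCH, rCH, aCOH, COOH, naCO (µmol)
    fg_gsd: float
    ach_split: tuple[float, float, float]  # fractions for 2850 / 2920 / 2960
    ec_median: float
    ec_gsd: float
    acid_prob: float
    acid_off_factor: float = 0.15
    aux_height: Mapping[str, float] = field(default_factory=dict)
    aux_gsd: float = 1.5
    rch_stretch_fraction: float = 1.0     # stretch band sees this × rCH moles

    def __post_init__(self) -> None:
        if not np.isclose(sum(self.ach_split), 1.0):
            raise ValueError(f"{self.fuel}: ach_split must sum to 1")
        for k, v in self.fg_median.items():
            if v < 0:
                raise ValueError(f"{self.fuel}: negative median for {k}")
        if not (0 <= self.acid_prob <= 1):
            raise ValueError(f"{self.fuel}: acid_prob must be in [0, 1]")


ARCHETYPES: dict[str, Archetype] = {
    "red_oak": Archetype(
        fuel="red_oak",
        fg_median={"aCH": 8.0, "rCH": 4.0, "aCOH": 18.0, "COOH": 1.5, "naCO": 5.0},
        fg_gsd=1.6, ach_split=(0.35, 0.45, 0.20),
        ec_median=300.0, ec_gsd=1.8, acid_prob=0.15,
        aux_height={"aromatic_CC_1600": 0.08, "lignin_1515": 0.03,
                    "nitrate_1400": 0.015, "nitrate_830": 0.008},
    ),
    "kerosene": Archetype(
        fuel="kerosene",
        fg_median={"aCH": 3.0, "rCH": 10.0, "aCOH": 6.0, "COOH": 4.0, "naCO": 3.0},
        fg_gsd=1.5, ach_split=(0.20, 0.40, 0.40),  # CH₃-rich
        ec_median=150.0, ec_gsd=1.6, acid_prob=0.7,
        aux_height={"aromatic_CC_1600": 0.04},
    ),
    "charcoal": Archetype(
        fuel="charcoal",
        fg_median={"aCH": 12.0, "rCH": 5.0, "aCOH": 8.0, "COOH": 0.5, "naCO": 1.5},
        fg_gsd=1.8, ach_split=(0.35, 0.45, 0.20),
        ec_median=400.0, ec_gsd=2.0, acid_prob=0.05,
        aux_height={"aromatic_CC_1600": 0.10, "lignin_1515": 0.005},
    ),
    "alcohol": Archetype(
        fuel="alcohol",
        fg_median={"aCH": 0.2, "rCH": 0.05, "aCOH": 0.3, "COOH": 0.05, "naCO": 0.1},
        fg_gsd=1.5, ach_split=(0.35, 0.45, 0.20),
        ec_median=10.0, ec_gsd=1.5, acid_prob=0.0,
    ),
    "lpg": Archetype(
        fuel="lpg",
        fg_median={"aCH": 0.15, "rCH": 0.05, "aCOH": 0.2, "COOH": 0.05, "naCO": 0.1},
        fg_gsd=1.5, ach_split=(0.35, 0.45, 0.20),
        ec_median=8.0, ec_gsd=1.5, acid_prob=0.0,
    ),
}


@dataclass(frozen=True)
class TruthRecord:
    """Generating ground truth for one synthetic sample."""

    id: str
    fuel: str
    seed: int
    fg_moles: dict[str, float]               # aCH, rCH, aCOH, COOH, naCO (µmol)
    band_truth: dict[str, tuple[float, float, float, float]]  # name → (height, center, sigma, area)
    ec: float                                # µg
    oc: float                                # µg, from fg_moles via the default table
    om: float                                # µg
    pah_mass: float                          # µg, rCH · (M_H + 1.4 M_C)
    ptfe_intensity: float
    baseline_coef: float                     # AU amplitude of the ν̃² term
    baseline_flat: float                     # AU constant offset
    baseline_at_4000: float
    noise_sd: float
    acid: bool

    def baseline_values(self, wavenumbers: np.ndarray) -> np.ndarray:
        wn = np.asarray(wavenumbers, dtype=float)
        return self.baseline_coef * (wn / 4000.0) ** 2 + self.baseline_flat

    def signal_values(self, wavenumbers: np.ndarray, include_ptfe: bool = False) -> np.ndarray:
        """True band signal (optionally plus PTFE) on a grid."""
        wn = np.asarray(wavenumbers, dtype=float)
        sig = np.zeros_like(wn)
        for h, c, s, _ in self.band_truth.values():
            sig += h * _gauss(wn, c, s)
        if include_ptfe:
            sig += self.ptfe_intensity * ptfe_profile(wn)
        return sig


def _lognormal(rng: np.random.Generator, median: float, gsd: float) -> float:
    if median <= 0:
        return 0.0
    return float(median * math.exp(rng.normal(0.0, math.log(gsd))))


def generate_blank(seed: int, noise_sd: float = 0.0015) -> Spectrum:
    """A raw blank-filter spectrum: smooth scatter + PTFE cluster + noise."""
    rng = np.random.default_rng(seed)
    wn = CANONICAL_GRID
    intensity = float(rng.uniform(0.6, 1.6))
    scatter = float(rng.uniform(0.02, 0.08))
    flat = float(rng.uniform(0.005, 0.02))
    ab = scatter * (wn / 4000.0) ** 2 + flat + intensity * ptfe_profile(wn)
    if noise_sd > 0:
        ab = ab + rng.normal(0.0, noise_sd, size=wn.size)
    return Spectrum(id=f"blank{seed:05d}", wavenumbers=wn, absorbance=ab,
                    stage="raw", filter_kind="blank")


def generate_sample(
    archetype: Archetype,
    seed: int,
    noise_sd: float = 0.002,
    sample_id: str | None = None,
) -> tuple[Spectrum, TruthRecord]:
    """One raw sample spectrum plus its generating truth.

    noise_sd is the white-noise standard deviation in AU (0 for noiseless
    recovery tests; the default 0.002 AU is ~2 % of a typical strong band
    height).
    """
    if not isinstance(archetype, Archetype):
        raise TypeError(f"archetype must be an Archetype, got {type(archetype).__name__}")
    rng = np.random.default_rng(seed)
    wn = CANONICAL_GRID

    fg = {k: _lognormal(rng, v, archetype.fg_gsd) for k, v in archetype.fg_median.items()}
    acid = bool(rng.random() < archetype.acid_prob)
    if not acid:
        fg["COOH"] *= archetype.acid_off_factor

    # per-band abundances (µmol)
    f2850, f2920, f2960 = archetype.ach_split
    band_moles = {
        "aCH_2850": fg["aCH"] * f2850,
        "aCH_2920": fg["aCH"] * f2920,
        "aCH3_2960": fg["aCH"] * f2960,
        "rCH_oop_750": fg["rCH"],
        "rCH_stretch_3050": fg["rCH"] * archetype.rch_stretch_fraction,
        "aCOH_3500": fg["aCOH"],
        "COOH_OH_broad": fg["COOH"],
        "COOH_doublet_2600": fg["COOH"],
        "COOH_doublet_2400": fg["COOH"],
        "carbonyl_CO_1700": fg["COOH"] + fg["naCO"],
    }

    band_truth: dict[str, tuple[float, float, float, float]] = {}
    for name, (center, sigma) in BAND_SHAPES.items():
        c = center + float(rng.uniform(-3.0, 3.0))
        s = sigma * float(rng.uniform(0.92, 1.08))
        if name in band_moles:
            model = DEFAULT_ABSORPTIVITIES[name]
            if model.response == "height":
                h = band_moles[name] * model.absorptivity
            else:
                h = band_moles[name] * model.absorptivity / (s * SQRT_2PI)
        elif name in archetype.aux_height:
            h = _lognormal(rng, archetype.aux_height[name], archetype.aux_gsd)
        else:
            continue
        if h <= 0:
            continue
        band_truth[name] = (h, c, s, h * s * SQRT_2PI)

    comp = fg_to_oc_om(fg)
    ec = _lognormal(rng, archetype.ec_median, archetype.ec_gsd)
    ptfe_intensity = float(rng.uniform(0.6, 1.6))
    scatter = float(rng.uniform(0.02, 0.08))
    flat = float(rng.uniform(0.005, 0.02))
    b_coef = scatter + BASELINE_COEF_EC * ec + BASELINE_COEF_OC * comp.oc

    ab = b_coef * (wn / 4000.0) ** 2 + flat + ptfe_intensity * ptfe_profile(wn)
    for h, c, s, _ in band_truth.values():
        ab = ab + h * _gauss(wn, c, s)
    if noise_sd > 0:
        ab = ab + rng.normal(0.0, noise_sd, size=wn.size)

    sid = sample_id if sample_id is not None else f"S{seed:06d}"
    spec = Spectrum(id=sid, wavenumbers=wn, absorbance=ab, stage="raw",
                    filter_kind="sample")
    truth = TruthRecord(
        id=sid, fuel=archetype.fuel, seed=seed, fg_moles=fg,
        band_truth=band_truth, ec=ec, oc=comp.oc, om=comp.om,
        pah_mass=fg["rCH"] * (M_H + DEFAULT_C_TO_H * M_C),
        ptfe_intensity=ptfe_intensity, baseline_coef=b_coef,
        baseline_flat=flat, baseline_at_4000=b_coef + flat,
        noise_sd=noise_sd, acid=acid,
    )
    return spec, truth


#: GC–MS compound split used for the pseudo PAH tables.
_PAH_SPLIT = {
    "naphthalene": 0.30, "phenanthrene": 0.25, "fluoranthene": 0.20,
    "pyrene": 0.15, "benzo[a]pyrene": 0.10,
}


@dataclass
class StudyData:
    """A self-consistent synthetic study keyed by sample id."""

    samples: list[Spectrum]
    blanks: list[Spectrum]
    meta: dict[str, SampleMeta]
    references: dict[str, ReferenceMeasures]
    truth: dict[str, TruthRecord]
    seed: int


def generate_study(
    n: int,
    archetype_mix: Mapping[str, float] | None = None,
    seed: int = 0,
    noise_sd: float = 0.002,
    delta_oc: float = 0.67,
    pah_slope: float = 19.6,
    ref_noise: float = 0.05,
    n_blanks: int = 8,
) -> StudyData:
    """Generate a full synthetic study: spectra, blanks, metadata, references.

    Parameters
    ----------
    n : number of samples (0 gives empty tables).
    archetype_mix : fuel → weight; defaults to the three FG-analysable fuels
        in proportions mirroring a realistic stove-testing campaign
        (red_oak 0.45, charcoal 0.35, kerosene 0.20).
    delta_oc : relative bias of pseudo thermal–optical OC over spectroscopic
        FG OC (pseudo-TOT = FG-OC·(1+δ)); default +0.67 so FG OC recovers
        ~60 % of pseudo-TOT OC.
    pah_slope : k in pseudo-GC–MS PAH sum = spectroscopic PAH mass / k.
    ref_noise : relative sd of the multiplicative noise on every reference.
    """
    if n < 0:
        raise ValueError("n must be ≥ 0")
    if archetype_mix is None:
        archetype_mix = {"red_oak": 0.45, "charcoal": 0.35, "kerosene": 0.20}
    fuels = sorted(archetype_mix)
    weights = np.array([archetype_mix[f] for f in fuels], dtype=float)
    if weights.sum() <= 0:
        raise ValueError("archetype mix weights must sum to > 0")
    weights = weights / weights.sum()

    rng = np.random.default_rng(seed)
    blanks = [generate_blank(int(rng.integers(2**31)), noise_sd=min(noise_sd, 0.0015))
              for _ in range(n_blanks)]

    samples: list[Spectrum] = []
    meta: dict[str, SampleMeta] = {}
    refs: dict[str, ReferenceMeasures] = {}
    truth: dict[str, TruthRecord] = {}
    phases = ("CS", "HS", "SIM")
    for i in range(n):
        fuel = fuels[int(rng.choice(len(fuels), p=weights))]
        arch = ARCHETYPES[fuel]
        sid = f"S{i:04d}"
        sub = int(rng.integers(2**31))
        spec, tr = generate_sample(arch, sub, noise_sd=noise_sd, sample_id=sid)
        samples.append(spec)
        truth[sid] = tr

        tunnel = float(rng.choice([4.0, 26.8]))
        meta[sid] = SampleMeta(
            id=sid, fuel=fuel, stove=f"stove_{fuel}", phase=phases[i % 3],
            energy_delivered=_lognormal(rng, 5.0, 1.3),
            sample_flow=16.7, tunnel_flow=tunnel,
            duration=float(rng.uniform(25.0, 50.0)), deposit_area=11.95,
        )

        def noisy(v: float) -> float:
            return v * (1.0 + ref_noise * float(rng.normal())) if ref_noise > 0 else v

        oc_corrected = noisy(tr.oc * (1.0 + delta_oc))
        back_ratio = float(rng.uniform(0.06, 0.50)) if ref_noise > 0 else 0.0
        oc_back = back_ratio * oc_corrected
        ec_ref = noisy(tr.ec)
        gcms_total = noisy(tr.pah_mass / pah_slope)
        pah_table = {k: gcms_total * v for k, v in _PAH_SPLIT.items()}
        refs[sid] = ReferenceMeasures(
            id=sid, oc_front=oc_corrected + oc_back, oc_back=oc_back,
            ec=ec_ref, pm25_mass=noisy(tr.om + tr.ec), pah_table=pah_table,
        )

    return StudyData(samples=samples, blanks=blanks, meta=meta,
                     references=refs, truth=truth, seed=seed)


def generate_anthracene_standards(
    n: int = 12,
    seed: int = 0,
    absorptivity: float = 0.017,
    rel_noise: float = 0.0,
    loading_range: tuple[float, float] = (26.8, 1040.0),
    deposit_area: float = math.pi * 0.5**2,
) -> list[tuple[float, float]]:
    """(height response, µmol CH) pairs emulating anthracene calibration deposits.

    Loadings form an evenly spaced dilution series over `loading_range`
    (µg cm⁻², the way a calibration series is prepared) on a 1 cm diameter
    collection spot; responses follow response = ε·n with optional
    multiplicative noise.
    """
    from .calibration import anthracene_moles_ch

    rng = np.random.default_rng(seed)
    lo, hi = loading_range
    out = []
    for loading in np.linspace(lo, hi, n):
        moles = anthracene_moles_ch(float(loading), deposit_area)
        resp = absorptivity * moles
        if rel_noise > 0:
            resp *= 1.0 + rel_noise * float(rng.normal())
        out.append((resp, moles))
    return out


def write_study(study: StudyData, directory) -> None:
    """Write a study in the on-disk input layout consumed by the pipeline:
    spectra/, blanks/, meta.csv, references.csv, truth.csv."""
    from pathlib import Path

    import pandas as pd

    from .spectra import write_reference_measures, write_sample_meta, write_spectrum

    directory = Path(directory)
    (directory / "spectra").mkdir(parents=True, exist_ok=True)
    (directory / "blanks").mkdir(parents=True, exist_ok=True)
    for s in study.samples:
        write_spectrum(s, directory / "spectra" / f"{s.id}.csv")
    for b in study.blanks:
        write_spectrum(b, directory / "blanks" / f"{b.id}.csv")
    write_sample_meta(study.meta.values(), directory / "meta.csv")
    write_reference_measures(study.references.values(), directory / "references.csv")
    rows = []
    for tr in study.truth.values():
        row = {"id": tr.id, "fuel": tr.fuel, "seed": tr.seed, "ec_ug": tr.ec,
               "oc_ug": tr.oc, "om_ug": tr.om, "pah_ug": tr.pah_mass,
               "ptfe_intensity": tr.ptfe_intensity,
               "baseline_at_4000": tr.baseline_at_4000,
               "noise_sd": tr.noise_sd, "acid": tr.acid}
        row.update({f"mol_{k}_umol": v for k, v in tr.fg_moles.items()})
        rows.append(row)
    pd.DataFrame(rows).to_csv(directory / "truth.csv", index=False)
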