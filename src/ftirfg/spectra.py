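"""Core spectral containers, the canonical wavenumber grid, and file I/O.

Transmission-mode mid-infrared absorbance spectra of particles collected on
PTFE membrane filters are represented as :class:`Spectrum` objects: a strictly
monotone wavenumber grid (cm⁻¹) with matching absorbance values (AU).  The
canonical acquisition grid is 4000 → 400 cm⁻¹ at 4 cm⁻¹ spacing (901 points,
descending), matching a typical transmission-mode FTIR scan; readers can
normalise arbitrary grids onto it via :func:`resample`.

Per-sample metadata (fuel, stove, test phase, sampling geometry) and
collocated reference measurements (thermal–optical OC/EC, gravimetric PM2.5,
GC–MS PAH totals) are carried in :class:`SampleMeta` and
:class:`ReferenceMeasures` and round-trip through one-row-per-sample CSVs.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CANONICAL_GRID",
    "Spectrum",
    "SampleMeta",
    "ReferenceMeasures",
    "read_spectrum",
    "write_spectrum",
    "resample",
    "group_mean_spectrum",
    "read_sample_meta",
    "write_sample_meta",
    "read_reference_measures",
    "write_reference_measures",
]

#: Canonical acquisition grid: 4000 → 400 cm⁻¹, 4 cm⁻¹ spacing, descending.
CANONICAL_GRID: np.ndarray = np.arange(4000.0, 399.0, -4.0)
CANONICAL_GRID.setflags(write=False)

STAGES = ("raw", "baselined", "blank_subtracted")
FILTER_KINDS = ("sample", "blank")
FUELS = ("charcoal", "kerosene", "red_oak", "alcohol", "lpg")
PHASES = ("CS", "HS", "SIM")


class SpectrumError(ValueError):
    """Raised for malformed spectra or grid mismatches."""


class ParseError(SpectrumError):
    """Raised when a spectrum file cannot be parsed; names the offending line."""


@dataclass(frozen=True)
class Spectrum:
    """An absorbance spectrum A(ν̃) on a strictly monotone wavenumber grid.

    Parameters
    ----------
    id : str
        Sample or blank identifier.
    wavenumbers : ndarray
        Wavenumber grid in cm⁻¹, strictly monotone (either direction),
        within [400, 4000].
    absorbance : ndarray
        Absorbance in AU; same length as the grid.  Negative values are
        permitted (they arise legitimately after baseline and blank
        corrections and are never clipped).
    stage : {'raw', 'baselined', 'blank_subtracted'}
        Processing stage.
    filter_kind : {'sample', 'blank'}
        Whether the filter carried a particle deposit or is a blank.
    """

    id: str
    wavenumbers: np.ndarray
    absorbance: np.ndarray
    stage: str = "raw"
    filter_kind: str = "sample"

    def __post_init__(self) -> None:
        wn = np.asarray(self.wavenumbers, dtype=float)
        ab = np.asarray(self.absorbance, dtype=float)
        if wn.ndim != 1 or ab.ndim != 1 or wn.size != ab.size:
            raise SpectrumError(
                f"{self.id}: wavenumbers and absorbance must be equal-length "
                f"1-D arrays (got {wn.shape} and {ab.shape})"
            )
        if wn.size < 2:
            raise SpectrumError(f"{self.id}: spectrum needs at least 2 points")
        d = np.diff(wn)
        if not (np.all(d > 0) or np.all(d < 0)):
            raise SpectrumError(f"{self.id}: wavenumber grid is not strictly monotone")
        if not np.all(np.isfinite(wn)) or not np.all(np.isfinite(ab)):
            raise SpectrumError(f"{self.id}: non-finite values in spectrum")
        if self.stage not in STAGES:
            raise SpectrumError(f"unknown stage {self.stage!r}")
        if self.filter_kind not in FILTER_KINDS:
            raise SpectrumError(f"unknown filter_kind {self.filter_kind!r}")
        wn.setflags(write=False)
        ab.setflags(write=False)
        object.__setattr__(self, "wavenumbers", wn)
        object.__setattr__(self, "absorbance", ab)

    def __len__(self) -> int:
        return self.wavenumbers.size

    @property
    def descending(self) -> bool:
        return self.wavenumbers[0] > self.wavenumbers[-1]

    @property
    def negative_fraction(self) -> float:
        """Fraction of grid points with negative absorbance (quality flag)."""
        return float(np.mean(self.absorbance < 0.0))

    def with_absorbance(self, absorbance: np.ndarray, stage: str | None = None) -> "Spectrum":
        return replace(
            self, absorbance=np.asarray(absorbance, dtype=float),
            stage=self.stage if stage is None else stage,
        )

    def window(self, lo: float, hi: float) -> np.ndarray:
        """Boolean mask of grid points with lo ≤ ν̃ ≤ hi."""
        return (self.wavenumbers >= lo) & (self.wavenumbers <= hi)

    def value_at(self, wavenumber: float) -> float:
        """Absorbance at the grid point nearest to `wavenumber`."""
        i = int(np.argmin(np.abs(self.wavenumbers - wavenumber)))
        return float(self.absorbance[i])


@dataclass(frozen=True)
class SampleMeta:
    """Sampling metadata for one filter sample.

    energy_delivered is in MJ (energy delivered to the cooking pot during the
    water-boiling test phase); sample_flow in L min⁻¹ at the filter;
    tunnel_flow in m³ min⁻¹ in the dilution tunnel; duration in min;
    deposit_area in cm².
    """

    id: str
    fuel: str
    stove: str
    phase: str
    energy_delivered: float
    sample_flow: float
    tunnel_flow: float
    duration: float
    deposit_area: float

    def __post_init__(self) -> None:
        if self.fuel not in FUELS:
            raise ValueError(f"unknown fuel {self.fuel!r}")
        if self.phase not in PHASES:
            raise ValueError(f"unknown phase {self.phase!r}")
        for name in ("energy_delivered", "sample_flow", "tunnel_flow", "deposit_area"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{self.id}: {name} must be > 0")


@dataclass(frozen=True)
class ReferenceMeasures:
    """Collocated reference measurements for one sample (µg on filter).

    oc_front / oc_back are thermal–optical OC on the quartz front and back
    filters (the back filter captures the vapour-adsorption artifact); ec is
    elemental carbon; pm25_mass is gravimetric; pah_table maps compound name
    to µg (GC–MS).  Small negatives from upstream blank subtraction are
    permitted and flagged rather than rejected.
    """

    id: str
    oc_front: float
    oc_back: float
    ec: float
    pm25_mass: float
    pah_table: Mapping[str, float] | None = None

    @property
    def has_negative(self) -> bool:
        vals = [self.oc_front, self.oc_back, self.ec, self.pm25_mass]
        if self.pah_table:
            vals += list(self.pah_table.values())
        return any(v < 0 for v in vals)

    @property
    def pah_total(self) -> float | None:
        if self.pah_table is None:
            return None
        return float(sum(self.pah_table.values()))


# ---------------------------------------------------------------------------
# spectrum file I/O

_CSV_HEADER = "wavenumber_cm-1,absorbance"


def read_spectrum(
    path: str | Path,
    dialect: str = "csv",
    *,
    id: str | None = None,
    stage: str = "raw",
    filter_kind: str = "sample",
) -> Spectrum:
    """Read a spectrum from a two-column CSV or a JCAMP-DX file.

    The grid is left in file order but validated strictly monotone; parse
    failures raise :class:`ParseError` naming the offending line.
    """
    path = Path(path)
    if not path.exists():
        raise ParseError(f"{path}: file does not exist")
    if dialect == "csv":
        wn, ab = _read_csv_xy(path)
    elif dialect == "jcampdx":
        wn, ab = _read_jcampdx(path)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    if wn.size == 0:
        raise ParseError(f"{path}: no data rows")
    try:
        return Spectrum(
            id=id if id is not None else path.stem,
            wavenumbers=wn, absorbance=ab, stage=stage, filter_kind=filter_kind,
        )
    except SpectrumError as exc:
        raise ParseError(f"{path}: {exc}") from exc


def _read_csv_xy(path: Path) -> tuple[np.ndarray, np.ndarray]:
    wn: list[float] = []
    ab: list[float] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if lineno == 1 and re.search(r"[A-Za-z]", line):
                continue  # header row
            parts = line.split(",")
            if len(parts) != 2:
                raise ParseError(f"{path}:{lineno}: expected 2 columns, got {len(parts)}")
            try:
                wn.append(float(parts[0]))
                ab.append(float(parts[1]))
            except ValueError:
                raise ParseError(f"{path}:{lineno}: non-numeric row {line!r}") from None
    return np.array(wn), np.array(ab)


def _read_jcampdx(path: Path) -> tuple[np.ndarray, np.ndarray]:
    """Minimal JCAMP-DX reader: XYPOINTS=(XY..XY) and XYDATA=(X++(Y..Y))."""
    text = path.read_text()
    xfac = yfac = 1.0
    m = re.search(r"##XFACTOR=\s*([-\d.eE+]+)", text)
    if m:
        xfac = float(m.group(1))
    m = re.search(r"##YFACTOR=\s*([-\d.eE+]+)", text)
    if m:
        yfac = float(m.group(1))

    m = re.search(r"##XYPOINTS=[^\n]*\n(.*?)(?=##)", text, re.S)
    if m:
        pairs = re.findall(r"([-\d.eE+]+)\s*,\s*([-\d.eE+]+)", m.group(1))
        if not pairs:
            raise ParseError(f"{path}: empty XYPOINTS block")
        wn = np.array([float(a) for a, _ in pairs]) * xfac
        ab = np.array([float(b) for _, b in pairs]) * yfac
        return wn, ab

    m = re.search(r"##XYDATA=[^\n]*\n(.*?)(?=##)", text, re.S)
    if m:
        xs: list[float] = []
        ys: list[float] = []
        lines = [ln for ln in m.group(1).splitlines() if ln.strip()]
        if len(lines) < 1:
            raise ParseError(f"{path}: empty XYDATA block")
        # infer per-line ΔX from consecutive line-start abscissae
        starts = []
        rows = []
        for ln in lines:
            vals = [float(v) for v in re.findall(r"[-\d.eE+]+", ln)]
            if len(vals) < 2:
                raise ParseError(f"{path}: malformed XYDATA line {ln!r}")
            starts.append(vals[0])
            rows.append(vals[1:])
        if len(lines) > 1:
            dx = (starts[1] - starts[0]) / len(rows[0])
        else:
            dx = 1.0
        for x0, yvals in zip(starts, rows):
            for j, y in enumerate(yvals):
                xs.append((x0 + j * dx) * xfac)
                ys.append(y * yfac)
        return np.array(xs), np.array(ys)

    raise ParseError(f"{path}: no XYPOINTS or XYDATA block found")


def write_spectrum(spectrum: Spectrum, path: str | Path) -> None:
    """Write a spectrum as two-column CSV; full float round-trip precision."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(_CSV_HEADER + "\n")
        for w, a in zip(spectrum.wavenumbers, spectrum.absorbance):
            fh.write(f"{float(w)!r},{float(a)!r}\n")


# ---------------------------------------------------------------------------
# grid operations

def resample(spectrum: Spectrum, target_grid: np.ndarray) -> Spectrum:
    """Linearly interpolate a spectrum onto `target_grid` (no extrapolation).

    Raises :class:`SpectrumError` if the target extends beyond the source
    span.  Monotone direction of the target is preserved.
    """
    target = np.asarray(target_grid, dtype=float)
    lo, hi = spectrum.wavenumbers.min(), spectrum.wavenumbers.max()
    if target.min() < lo - 1e-9 or target.max() > hi + 1e-9:
        raise SpectrumError(
            f"{spectrum.id}: target grid [{target.min()}, {target.max()}] "
            f"outside source span [{lo}, {hi}]"
        )
    # np.interp needs ascending abscissae
    if spectrum.descending:
        xp, fp = spectrum.wavenumbers[::-1], spectrum.absorbance[::-1]
    else:
        xp, fp = spectrum.wavenumbers, spectrum.absorbance
    vals = np.interp(target, xp, fp)
    return Spectrum(
        id=spectrum.id, wavenumbers=target, absorbance=vals,
        stage=spectrum.stage, filter_kind=spectrum.filter_kind,
    )


def to_canonical(spectrum: Spectrum) -> Spectrum:
    """Resample onto the canonical 4000→400 cm⁻¹ grid (identity if already on it)."""
    if spectrum.wavenumbers.shape == CANONICAL_GRID.shape and np.array_equal(
        spectrum.wavenumbers, CANONICAL_GRID
    ):
        return spectrum
    return resample(spectrum, CANONICAL_GRID)


def group_mean_spectrum(
    spectra: Sequence[Spectrum],
    weights: Sequence[float] | None = None,
) -> tuple[Spectrum, Spectrum]:
    """Pointwise mean and sample standard deviation of co-gridded spectra.

    With `weights` each spectrum is first multiplied by its weight; passing
    1/energy_delivered expresses spectra as emission-factor spectra
    (AU MJ⁻¹).  The sd uses the n−1 denominator (the package-wide
    convention); a single spectrum yields sd = 0.
    """
    if not spectra:
        raise ValueError("no spectra given")
    grid = spectra[0].wavenumbers
    for s in spectra[1:]:
        if s.wavenumbers.shape != grid.shape or not np.array_equal(s.wavenumbers, grid):
            raise SpectrumError(f"{s.id}: grid mismatch in group_mean_spectrum")
    mat = np.stack([s.absorbance for s in spectra])
    if weights is not None:
        w = np.asarray(weights, dtype=float)
        if w.size != len(spectra):
            raise ValueError("one weight per spectrum required")
        mat = mat * w[:, None]
    mean = mat.mean(axis=0)
    sd = mat.std(axis=0, ddof=1) if len(spectra) > 1 else np.zeros_like(mean)
    proto = spectra[0]
    return (
        Spectrum(id="mean", wavenumbers=grid, absorbance=mean,
                 stage=proto.stage, filter_kind=proto.filter_kind),
        Spectrum(id="sd", wavenumbers=grid, absorbance=sd,
                 stage=proto.stage, filter_kind=proto.filter_kind),
    )


# ---------------------------------------------------------------------------
# metadata tables

_META_COLS = ["id", "fuel", "stove", "phase", "energy_delivered",
              "sample_flow", "tunnel_flow", "duration", "deposit_area"]


def write_sample_meta(metas: Iterable[SampleMeta], path: str | Path) -> None:
    rows = [{c: getattr(m, c) for c in _META_COLS} for m in metas]
    pd.DataFrame(rows, columns=_META_COLS).to_csv(path, index=False)


def read_sample_meta(path: str | Path) -> dict[str, SampleMeta]:
    df = pd.read_csv(path, dtype={"id": str, "stove": str})
    out: dict[str, SampleMeta] = {}
    for _, row in df.iterrows():
        m = SampleMeta(**{c: row[c] for c in _META_COLS})
        out[m.id] = m
    return out


_REF_COLS = ["id", "oc_front", "oc_back", "ec", "pm25_mass", "pah_table"]


def write_reference_measures(refs: Iterable[ReferenceMeasures], path: str | Path) -> None:
    rows = []
    for r in refs:
        rows.append({
            "id": r.id, "oc_front": r.oc_front, "oc_back": r.oc_back,
            "ec": r.ec, "pm25_mass": r.pm25_mass,
            "pah_table": json.dumps(dict(r.pah_table)) if r.pah_table is not None else "",
        })
    pd.DataFrame(rows, columns=_REF_COLS).to_csv(path, index=False)


def read_reference_measures(path: str | Path) -> dict[str, ReferenceMeasures]:
    df = pd.read_csv(path, dtype={"id": str, "pah_table": str}, keep_default_na=False)
    out: dict[str, ReferenceMeasures] = {}
    for _, row in df.iterrows():
        pah = json.loads(row["pah_table"]) if row["pah_table"] else None
        r = ReferenceMeasures(
            id=row["id"], oc_front=float(row["oc_front"]),
            oc_back=float(row["oc_back"]), ec=float(row["ec"]),
            pm25_mass=float(row["pm25_mass"]), pah_table=pah,
        )
        out[r.id] = r
    return out
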