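"""End-to-end orchestration: raw spectra → composition tables and VIP spectra.

The per-sample chain is: smoothing-spline baseline → blank selection and
scaled subtraction → carboxylic-acid signature check (when the broad acid OH
is present the 2750–2500 cm⁻¹ anchor window sits on its shoulder, so the
baseline and blank subtraction are redone without that anchor) → multi-peak
fitting of every band region → calibration to bond abundances → carbonyl
apportionment → OC/OM/OM:OC/PAH mass and emission factors.

Study-level outputs: the FG-OC vs reference-OC regression, the FTIR/GC–MS
PAH comparison, the EC–baseline diagnostic, PLSR–VIP spectra for OC and the
PAH sum (the PTFE interference window is excluded from the spectra matrix),
and group mean emission-factor spectra per fuel × phase.

Per-sample failures are logged and skipped; study-level failures raise.
All of this is importable; the command-line wrapper in :mod:`ftirfg.cli` is
a thin layer over :func:`run_pipeline`.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .bands import BandDefinition, DEFAULT_BAND_TABLE, read_band_table, write_band_table
from .calibration import (
    CalibrationModel, DEFAULT_ABSORPTIVITIES, abundances_from_fits,
    read_absorptivity_table, write_absorptivity_table,
)
from .chemometrics import band_report, fit_plsr, vip_scores
from .composition import (
    AttributionRow, DEFAULT_ATTRIBUTION, apportion_carbonyl, artifact_correct,
    compare_pah_estimates, emission_factor, fg_to_oc_om, pah_mass,
)
from .peakfit import collect_band_fits, detect_acid_signature, fit_all_regions
from .preprocess import (
    ACID_SENSITIVE_ANCHOR, DEFAULT_ANCHOR_REGIONS, PTFE_WINDOW,
    ec_baseline_regression, fit_baseline, select_blank, subtract_blank,
)
from .spectra import (
    ReferenceMeasures, SampleMeta, Spectrum, group_mean_spectrum,
    read_reference_measures, read_sample_meta, read_spectrum, to_canonical,
    write_spectrum,
)

__all__ = ["RunConfig", "SampleRecord", "StudyResult", "process_sample",
           "analyze_study", "run_pipeline"]


class PipelineError(RuntimeError):
    pass


@dataclass
class RunConfig:
    """Paths and knobs for a file-based pipeline run."""

    input_dir: str                   # layout: spectra/, blanks/, meta.csv, references.csv
    output_dir: str
    band_table_path: str | None = None
    absorptivity_path: str | None = None
    anchor_regions: Sequence[tuple[float, float]] = DEFAULT_ANCHOR_REGIONS
    smoothing: float | str = "auto"
    ptfe_window: tuple[float, float] = PTFE_WINDOW
    vip_threshold: float = 1.0
    vip_components: int | str = 3
    seed: int = 0

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        d["anchor_regions"] = [list(r) for r in self.anchor_regions]
        d["ptfe_window"] = list(self.ptfe_window)
        return json.dumps(d, indent=2, sort_keys=True)


@dataclass
class SampleRecord:
    """Everything computed for one sample."""

    id: str
    corrected: Spectrum                  # blank-subtracted, final
    blank_id: str
    blank_scale: float
    baseline_at_4000: float
    acid: bool
    fg_moles: dict[str, float]           # aCH, rCH, aCOH, COOH, naCO (µmol)
    oc: float
    om: float
    om_oc: float | None
    per_fg_om: dict[str, float]
    pah_mass: float
    ec_tc: float | None = None
    emission_factors: dict[str, float] = field(default_factory=dict)
    fit_rmse: float = 0.0
    converged: bool = True
    flags: list[str] = field(default_factory=list)


def _anchor_contaminated(corrected: Spectrum, noise: float) -> bool:
    """True when the acid-sensitive anchor window carries systematic signal.

    After baselining over the default anchors the corrected spectrum should
    average ≈ 0 inside every anchor window; a positive mean in 2750–2500
    beyond the noise standard error (floored at 5e-4 AU) reveals a broad
    absorption — the dimerized-acid OH shoulder — under that anchor.
    """
    mask = corrected.window(*sorted(ACID_SENSITIVE_ANCHOR))
    if not mask.any():
        return False
    level = float(np.mean(corrected.absorbance[mask]))
    threshold = max(2e-4, 3.0 * noise / np.sqrt(mask.sum()))
    return level > threshold


def process_sample(
    raw: Spectrum,
    blanks_baselined: Sequence[Spectrum],
    band_table: Sequence[BandDefinition] = DEFAULT_BAND_TABLE,
    absorptivities: Mapping[str, CalibrationModel] = DEFAULT_ABSORPTIVITIES,
    attribution: Mapping[str, AttributionRow] = DEFAULT_ATTRIBUTION,
    anchor_regions: Sequence[tuple[float, float]] = DEFAULT_ANCHOR_REGIONS,
    smoothing: float | str = "auto",
    meta: SampleMeta | None = None,
    reference: ReferenceMeasures | None = None,
) -> SampleRecord:
    """Run the full per-sample chain on one raw spectrum."""
    # First pass WITHOUT the acid-sensitive 2750–2500 anchor: if that window
    # carries the broad dimerized-acid OH, a spline anchored there absorbs
    # real band intensity (and erases the 2600 doublet outright).
    reduced = [r for r in anchor_regions
               if tuple(sorted(r)) != tuple(sorted(ACID_SENSITIVE_ANCHOR))]
    bl = fit_baseline(raw, reduced, smoothing)
    blank_map = {b.id: b for b in blanks_baselined}
    chosen = blank_map[select_blank(bl.corrected, list(blanks_baselined))]
    corrected, match = subtract_blank(bl.corrected, chosen)

    acid, _evidence = detect_acid_signature(corrected)
    if (
        not acid
        and not _anchor_contaminated(corrected, _evidence.noise)
        and len(reduced) < len(anchor_regions)
    ):
        # window verified clean — re-anchor there for extra baseline support
        bl = fit_baseline(raw, anchor_regions, smoothing)
        corrected, match = subtract_blank(bl.corrected, chosen)

    results = fit_all_regions(corrected, tuple(band_table))
    fits = collect_band_fits(results)
    raw_ab = abundances_from_fits(fits, absorptivities)
    cooh, naco = apportion_carbonyl(raw_ab.get("carbonyl", 0.0), raw_ab.get("acid_OH", 0.0))
    fg = {"aCH": raw_ab.get("aCH", 0.0), "rCH": raw_ab.get("rCH", 0.0),
          "aCOH": raw_ab.get("aCOH", 0.0), "COOH": cooh, "naCO": naco}

    comp = fg_to_oc_om(fg, attribution)
    pah = pah_mass(fg["rCH"])
    flags = list(comp.flags)

    ec_tc = None
    if reference is not None:
        oc_ref, neg = artifact_correct(reference.oc_front, reference.oc_back)
        if neg:
            flags.append("negative artifact-corrected reference OC")
        tc = reference.ec + max(oc_ref, 0.0)
        ec_tc = reference.ec / tc if tc > 0 else None

    efs: dict[str, float] = {}
    if meta is not None:
        efs = {
            "oc_mg_per_mj": emission_factor(comp.oc, meta),
            "om_mg_per_mj": emission_factor(comp.om, meta),
            "pah_mg_per_mj": emission_factor(pah, meta),
        }

    rmses = [r.rmse for r in results if np.isfinite(r.rmse)]
    return SampleRecord(
        id=raw.id, corrected=corrected, blank_id=match.blank_id,
        blank_scale=match.scale, baseline_at_4000=bl.baseline_at_4000,
        acid=acid, fg_moles=fg, oc=comp.oc, om=comp.om, om_oc=comp.om_oc,
        per_fg_om=comp.per_fg_om, pah_mass=pah, ec_tc=ec_tc,
        emission_factors=efs,
        fit_rmse=float(np.mean(rmses)) if rmses else float("nan"),
        converged=all(r.converged for r in results), flags=flags,
    )


def _through_origin(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    slope = float(x @ y) / float(x @ x)
    ss_res = float(np.sum((y - slope * x) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return slope, r2


@dataclass
class StudyResult:
    """Study-level outputs of :func:`analyze_study`."""

    records: dict[str, SampleRecord]
    per_sample: pd.DataFrame
    fg_oc_slope: float | None = None      # FG OC on artifact-corrected reference OC
    fg_oc_r2: float | None = None
    pah_slope: float | None = None        # FTIR PAH on GC–MS PAH sum
    pah_r2: float | None = None
    pah_ratio: float | None = None
    ec_coef_ratio: float | None = None    # EC/OC coefficient ratio of the baseline fit
    ec_r2: float | None = None
    vip: dict[str, object] = field(default_factory=dict)       # target → VipResult
    vip_reports: dict[str, list] = field(default_factory=dict)
    group_means: dict[tuple[str, str], tuple[Spectrum, Spectrum]] = field(default_factory=dict)
    failures: dict[str, str] = field(default_factory=dict)
    log: list[dict] = field(default_factory=list)


def analyze_study(
    samples: Sequence[Spectrum],
    blanks: Sequence[Spectrum],
    meta: Mapping[str, SampleMeta] | None = None,
    references: Mapping[str, ReferenceMeasures] | None = None,
    band_table: Sequence[BandDefinition] = DEFAULT_BAND_TABLE,
    absorptivities: Mapping[str, CalibrationModel] = DEFAULT_ABSORPTIVITIES,
    attribution: Mapping[str, AttributionRow] = DEFAULT_ATTRIBUTION,
    anchor_regions: Sequence[tuple[float, float]] = DEFAULT_ANCHOR_REGIONS,
    smoothing: float | str = "auto",
    vip_threshold: float = 1.0,
    vip_components: int | str = 3,
    seed: int = 0,
    run_vip: bool = True,
) -> StudyResult:
    """Process every sample and compute the study-level comparisons."""
    meta = meta or {}
    references = references or {}
    log: list[dict] = []

    blanks_baselined = []
    for b in blanks:
        blanks_baselined.append(
            fit_baseline(to_canonical(b), anchor_regions, smoothing).corrected
        )
    if not blanks_baselined:
        raise PipelineError("no blanks provided")

    records: dict[str, SampleRecord] = {}
    failures: dict[str, str] = {}
    for raw in samples:
        try:
            rec = process_sample(
                to_canonical(raw), blanks_baselined, band_table, absorptivities,
                attribution, anchor_regions, smoothing,
                meta.get(raw.id), references.get(raw.id),
            )
            records[rec.id] = rec
            log.append({"event": "sample_done", "id": rec.id,
                        "converged": rec.converged, "acid": rec.acid})
        except Exception as exc:
            failures[raw.id] = repr(exc)
            log.append({"event": "sample_failed", "id": raw.id, "error": repr(exc)})

    rows = []
    for rec in records.values():
        row = {
            "id": rec.id, "oc_ug": rec.oc, "om_ug": rec.om, "om_oc": rec.om_oc,
            "pah_ug": rec.pah_mass, "ec_tc": rec.ec_tc,
            "blank_id": rec.blank_id, "blank_scale": rec.blank_scale,
            "baseline_at_4000": rec.baseline_at_4000, "acid": rec.acid,
            "fit_rmse": rec.fit_rmse, "converged": rec.converged,
        }
        row.update({f"mol_{k}_umol": v for k, v in rec.fg_moles.items()})
        row.update({f"om_{k}_ug": v for k, v in rec.per_fg_om.items()})
        row.update({f"ef_{k}": v for k, v in rec.emission_factors.items()})
        rows.append(row)
    per_sample = pd.DataFrame(rows).set_index("id") if rows else pd.DataFrame()

    result = StudyResult(records=records, per_sample=per_sample,
                         failures=failures, log=log)

    # --- study-level comparisons -------------------------------------------
    ref_oc = {}
    for sid, rec in records.items():
        r = references.get(sid)
        if r is not None:
            oc_ref, _neg = artifact_correct(r.oc_front, r.oc_back)
            ref_oc[sid] = oc_ref
    if len(ref_oc) >= 3:
        ids = sorted(ref_oc)
        x = np.array([ref_oc[i] for i in ids])
        y = np.array([records[i].oc for i in ids])
        if float(x @ x) > 0:
            result.fg_oc_slope, result.fg_oc_r2 = _through_origin(x, y)

    ftir_pah = {sid: rec.pah_mass for sid, rec in records.items()}
    gcms = {sid: r.pah_total for sid, r in references.items()
            if r.pah_total is not None and sid in records}
    if len(set(ftir_pah) & set(gcms)) >= 3:
        result.pah_slope, result.pah_r2, result.pah_ratio = compare_pah_estimates(
            ftir_pah, {k: v for k, v in gcms.items()}
        )

    ec_records = []
    for sid, rec in records.items():
        r = references.get(sid)
        if r is not None:
            oc_ref, _ = artifact_correct(r.oc_front, r.oc_back)
            ec_records.append((rec.baseline_at_4000, oc_ref, r.ec))
    if len(ec_records) >= 3:
        try:
            _, _, result.ec_coef_ratio, result.ec_r2 = ec_baseline_regression(ec_records)
        except Exception as exc:
            log.append({"event": "ec_regression_failed", "error": repr(exc)})

    if run_vip and len(records) >= 8:
        ids = sorted(records)
        grid = records[ids[0]].corrected.wavenumbers
        keep = ~((grid >= PTFE_WINDOW[0]) & (grid <= PTFE_WINDOW[1]))
        X = np.stack([records[i].corrected.absorbance for i in ids])[:, keep]
        wn = grid[keep]
        targets: dict[str, np.ndarray] = {}
        if len(ref_oc) == len(ids):
            targets["oc"] = np.array([ref_oc[i] for i in ids])
        if len(set(gcms)) == len(ids):
            targets["pah_sum"] = np.array([gcms[i] for i in ids])
        for name, yv in targets.items():
            try:
                model = fit_plsr(X, yv, n_components=vip_components, cv_seed=seed)
                vr = vip_scores(model, wavenumbers=wn, threshold=vip_threshold)
                result.vip[name] = vr
                result.vip_reports[name] = band_report(vr, tuple(band_table))
            except Exception as exc:
                log.append({"event": "vip_failed", "target": name, "error": repr(exc)})

    # group mean emission-factor spectra per fuel × phase
    by_group: dict[tuple[str, str], list[str]] = {}
    for sid in records:
        m = meta.get(sid)
        if m is not None:
            by_group.setdefault((m.fuel, m.phase), []).append(sid)
    for key, ids_g in sorted(by_group.items()):
        specs = [records[i].corrected for i in ids_g]
        weights = [1.0 / meta[i].energy_delivered for i in ids_g]
        result.group_means[key] = group_mean_spectrum(specs, weights)

    return result


# ---------------------------------------------------------------------------
# file-based runner

def _load_inputs(input_dir: Path):
    spectra_dir = input_dir / "spectra"
    blanks_dir = input_dir / "blanks"
    if not spectra_dir.is_dir():
        raise PipelineError(f"missing spectra directory: {spectra_dir}")
    if not blanks_dir.is_dir():
        raise PipelineError(f"missing blanks directory: {blanks_dir}")
    samples = [read_spectrum(p) for p in sorted(spectra_dir.glob("*.csv"))]
    blanks = [read_spectrum(p, filter_kind="blank") for p in sorted(blanks_dir.glob("*.csv"))]
    meta = {}
    refs = {}
    if (input_dir / "meta.csv").exists():
        meta = read_sample_meta(input_dir / "meta.csv")
    if (input_dir / "references.csv").exists():
        refs = read_reference_measures(input_dir / "references.csv")
    return samples, blanks, meta, refs


def run_pipeline(config: RunConfig) -> Path:
    """File-based all-in-one run; returns the output directory.

    Outputs: per_sample.csv, study_summary.json, vip_<target>.csv, corrected
    spectra, group mean spectra, the archived config (with its hash) and a
    line-delimited structured log.  Deterministic for fixed inputs/config.
    """
    input_dir = Path(config.input_dir)
    out = Path(config.output_dir)
    samples, blanks, meta, refs = _load_inputs(input_dir)

    band_table = (read_band_table(config.band_table_path)
                  if config.band_table_path else DEFAULT_BAND_TABLE)
    absorptivities = (read_absorptivity_table(config.absorptivity_path)
                      if config.absorptivity_path else DEFAULT_ABSORPTIVITIES)

    result = analyze_study(
        samples, blanks, meta, refs, band_table, absorptivities,
        anchor_regions=config.anchor_regions, smoothing=config.smoothing,
        vip_threshold=config.vip_threshold, vip_components=config.vip_components,
        seed=config.seed,
    )

    out.mkdir(parents=True, exist_ok=True)
    cfg_json = config.to_json()
    (out / "config.json").write_text(cfg_json)

    result.per_sample.to_csv(out / "per_sample.csv")
    summary = {
        "n_samples": len(result.records),
        "n_failures": len(result.failures),
        "fg_oc_slope": result.fg_oc_slope, "fg_oc_r2": result.fg_oc_r2,
        "pah_slope": result.pah_slope, "pah_r2": result.pah_r2,
        "pah_ratio_of_totals": result.pah_ratio,
        "ec_coef_ratio": result.ec_coef_ratio, "ec_r2": result.ec_r2,
        "config_sha256": hashlib.sha256(cfg_json.encode()).hexdigest(),
        "version": __version__,
    }
    (out / "study_summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))

    spec_dir = out / "corrected_spectra"
    spec_dir.mkdir(exist_ok=True)
    for sid, rec in sorted(result.records.items()):
        write_spectrum(rec.corrected, spec_dir / f"{sid}.csv")

    for name, vr in result.vip.items():
        pd.DataFrame({"wavenumber_cm-1": vr.wavenumbers, "vip": vr.vip}).to_csv(
            out / f"vip_{name}.csv", index=False
        )
        pd.DataFrame(result.vip_reports[name]).to_csv(
            out / f"vip_{name}_bands.csv", index=False
        )

    gm_dir = out / "group_means"
    gm_dir.mkdir(exist_ok=True)
    for (fuel, phase), (mean, sd) in sorted(result.group_means.items()):
        write_spectrum(mean, gm_dir / f"{fuel}_{phase}_mean.csv")
        write_spectrum(sd, gm_dir / f"{fuel}_{phase}_sd.csv")

    with open(out / "log.jsonl", "w") as fh:
        for entry in result.log:
            fh.write(json.dumps(entry, sort_keys=True) + "\n")

    return out
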