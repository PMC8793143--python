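"""End-to-end analysis pipelines and run configuration.

Two chains mirror the two experiments the package analyses:

* SMFS kinetics: curves -> baseline correction -> rupture detection ->
  per-experiment QC on the specific-interaction fraction -> MPF and mean
  loading rate per experiment -> Bell-Evans regression -> reference force at
  10 nN/s -> dissociation barrier.
* QCM-D adhesion: trace -> alignment -> frequency change (with and without
  the wash period) -> Voigt areal-density series (Sauerbrey fallback when
  dissipation data are missing) -> stage-wise density sums -> molar surface
  concentration from the peptide's molecular weight.

Reports are plain dicts serialized as JSON with the fully resolved
configuration embedded, so a rerun with the same config and seed is
byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .constants import ARRHENIUS_A, REFERENCE_LOADING_RATE, T_DEFAULT
from .kinetics import (
    DfsPoint,
    MostProbableForce,
    experiment_qc,
    fit_bell_evans,
    kinetic_result,
)
from .peptides import Peptide, lookup
from .qcmd import (
    QcmTrace,
    VoigtFilmModel,
    frequency_change,
    sauerbrey_mass,
    stage_mass_sum,
    surface_concentration,
    AdsorptionResult,
)
from .smfs import RuptureDetector, correct_baseline_and_contact, events_to_frame

__all__ = ["RunConfig", "PipelineError", "run_smfs_pipeline", "run_qcmd_pipeline"]


class PipelineError(RuntimeError):
    """Run-level failure (e.g. every experiment discarded by QC)."""


@dataclass
class RunConfig:
    """All tunables of the two pipelines, with their defaults.

    The resolved config is embedded in every report for provenance.
    """

    temperature: float = T_DEFAULT
    arrhenius_a: float = ARRHENIUS_A
    reference_rate: float = REFERENCE_LOADING_RATE
    # per-peptide QC cutoffs on the specific-interaction fraction
    qc_cutoffs: dict = field(default_factory=lambda: {
        "native": 0.04, "K7A": 0.025, "default": 0.04,
    })
    mpf_mode: str = "auto"
    mpf_min_events: int = 50
    detector: dict = field(default_factory=lambda: {
        "window": 15, "nsigma": 6.0, "min_drop": 20.0,
        "baseline_fraction": 0.3, "loading_fraction": 0.1,
        "quality_threshold": 0.8, "distance_window": (0.5, 1.5),
        "linker_contour": 35.0,
    })
    qcm: dict = field(default_factory=lambda: {
        "f0": 5.0e6, "zq": 8.8e6, "film_density": 1100.0,
        "liquid_density": 1000.0, "liquid_viscosity": 8.9e-4,
        "display_overtone": 9, "smoothing_window": 240.0,
        "endpoint_window": 60.0, "min_density": 2.0,
    })
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls()
        for key, value in raw.items():
            if not hasattr(cfg, key):
                raise ValueError(f"unknown config key {key!r}")
            current = getattr(cfg, key)
            if isinstance(current, dict) and isinstance(value, dict):
                current.update(value)
            else:
                setattr(cfg, key, value)
        return cfg

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _json_default(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, tuple):
        return list(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")


def write_report(report: dict, path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, default=_json_default)
        fh.write("\n")


def run_smfs_pipeline(experiments: dict, peptide: str = "native",
                      config: "RunConfig | None" = None) -> dict:
    """Full SMFS kinetic chain on curves grouped by experiment.

    ``experiments`` maps an experiment label to a list of raw (uncorrected)
    :class:`~forcebind.smfs.ForceCurve`.  Each experiment is one loading-rate
    condition; at least three must survive QC for the Bell-Evans fit.
    """
    cfg = config or RunConfig()
    if not experiments:
        raise PipelineError("no experiments supplied")
    cutoff = cfg.qc_cutoffs.get(peptide, cfg.qc_cutoffs.get("default", 0.04))
    detector = RuptureDetector(temperature=cfg.temperature, **cfg.detector)

    qc_ledger = []
    points = []
    event_tables = {}
    for label in sorted(experiments):
        curves = experiments[label]
        events_by_curve = {}
        n_specific_curves = 0
        forces, rates = [], []
        for curve in curves:
            corrected, _ = correct_baseline_and_contact(
                curve, cfg.detector["baseline_fraction"]
            )
            events = detector.detect(corrected)
            events_by_curve[curve.curve_id] = events
            specific = [e for e in events if e.specific]
            if specific:
                n_specific_curves += 1
                forces.extend(e.rupture_force for e in specific)
                rates.extend(e.apparent_loading_rate for e in specific)
        keep, fraction = experiment_qc(n_specific_curves, len(curves), cutoff)
        entry = {
            "experiment": label,
            "n_curves": len(curves),
            "n_specific_curves": n_specific_curves,
            "specific_fraction": fraction,
            "kept": bool(keep),
        }
        if keep:
            try:
                est = MostProbableForce(
                    mode=cfg.mpf_mode, min_events=cfg.mpf_min_events
                ).fit(forces)
            except ValueError as exc:
                entry["kept"] = False
                entry["reason"] = f"MPF fit: {exc}"
                qc_ledger.append(entry)
                continue
            point = DfsPoint(
                loading_rate=float(np.mean(rates)),
                mpf=est.mpf_, mpf_err=est.mpf_err_,
                n_events=len(forces), specific_fraction=fraction,
            )
            points.append(point)
            entry.update(mpf=est.mpf_, mpf_err=est.mpf_err_,
                         modality=est.modality_,
                         mean_loading_rate=point.loading_rate)
        else:
            entry["reason"] = f"specific fraction {fraction:.3%} below cutoff {cutoff:.3%}"
        qc_ledger.append(entry)
        event_tables[label] = events_to_frame(events_by_curve)

    if not points:
        raise PipelineError(
            "all experiments failed QC; ledger: "
            + json.dumps(qc_ledger, default=_json_default)
        )
    params = fit_bell_evans(points, temperature=cfg.temperature)
    result = kinetic_result(params, cfg.reference_rate, cfg.arrhenius_a)

    return {
        "version": __version__,
        "peptide": peptide,
        "config": cfg.to_dict(),
        "qc_cutoff": cutoff,
        "qc_ledger": qc_ledger,
        "bell_evans_points": [dataclasses.asdict(p) for p in points],
        "kinetics": result.to_dict(),
    }


def run_qcmd_pipeline(trace: QcmTrace, peptide="native",
                      config: "RunConfig | None" = None,
                      ionic_strength_mode: bool = False) -> dict:
    """QCM-D adhesion chain on one aligned-or-raw trace.

    ``ionic_strength_mode`` reports the wash-excluded frequency change as the
    headline number (bulk shifts on washing corrupt the endpoint in
    ionic-strength series); both accounting modes are always computed.
    ``peptide`` is a library label or a :class:`~forcebind.peptides.Peptide`.
    """
    cfg = config or RunConfig()
    q = cfg.qcm
    pep = peptide if isinstance(peptide, Peptide) else lookup(peptide)

    overtone = q["display_overtone"]
    if overtone not in trace.delta_f:
        overtone = trace.overtones[-1]
    df_incl = frequency_change(trace, overtone, "include_wash", q["endpoint_window"])
    df_excl = frequency_change(trace, overtone, "exclude_wash", q["endpoint_window"])

    flags = []
    fit_overtones = tuple(n for n in trace.overtones if n in trace.delta_d)
    if len(fit_overtones) >= 2:
        model = VoigtFilmModel(
            film_density=q["film_density"], f0=q["f0"], zq=q["zq"],
        ).fit(trace)
        density = model.areal_density_
        method = "voigt"
        if model.flags_.any():
            flags.append(f"voigt_interpolated_{int(model.flags_.sum())}_points")
    else:
        density = np.asarray(sauerbrey_mass(
            trace.delta_f[overtone], overtone, q["f0"], q["zq"]
        ))
        method = "sauerbrey"
        flags.append("sauerbrey_fallback")

    stage_deltas = stage_mass_sum(trace.time, density, trace.stages,
                                  q["endpoint_window"])
    total = stage_deltas["total"]
    if abs(total) < q["min_density"]:
        flags.append("no_adsorption")
    conc = surface_concentration(total, pep.mw)
    result = AdsorptionResult(
        stage_area_density={"adsorption": stage_deltas["adsorption"],
                            "wash": stage_deltas["wash"]},
        total_area_density=total,
        surface_concentration=conc,
        peptide=pep.name,
        mw=pep.mw,
    )
    return {
        "version": __version__,
        "config": cfg.to_dict(),
        "mass_method": method,
        "flags": flags,
        "overtone": overtone,
        "frequency_change_Hz": {
            "include_wash": df_incl,
            "exclude_wash": df_excl,
            "reported": df_excl if ionic_strength_mode else df_incl,
            "mode": "exclude_wash" if ionic_strength_mode else "include_wash",
        },
        "adsorption": result.to_dict(),
    }
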