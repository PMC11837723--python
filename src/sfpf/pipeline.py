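"""End-to-end study pipeline: simulate -> match -> classify -> agree -> trend -> convert.

One config (YAML/JSON or :class:`StudyConfig`) drives every stage; the
result is a single machine-readable study report mirroring the analysis
structure: cohort summary, severity distributions per scale and level,
agreement reports at datapoint and admission level, trending report,
oximetry error summary, and the conversion-equation comparison. The
report is a pure function of (config, seed): running twice writes
byte-identical JSON.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from . import conversion as conv
from .agreement import (AgreementReport, bias_precision, binned_bias_profile,
                        curve_deviation)
from .classification import Severity, admission_max_severity, classify_datapoint
from .io import Datapoint, ExclusionReason, load_config, write_cohort, write_datapoints
from .matching import MatchingPolicy, build_datapoints
from .physiology import DEFAULT_CONSTANTS, PhysiologyConstants
from .synthetic import (CohortConfig, OximeterNoiseModel, TitrationPolicy,
                        simulate_cohort)
from .trending import TrendReport, consecutive_pairs

log = logging.getLogger(__name__)

__all__ = ["StudyConfig", "run_pipeline", "label_datapoints", "load_study_config"]


@dataclass(frozen=True)
class TrendingParams:
    max_dt_hours: float = 6.0
    ri_tolerance: float = 0.20
    ri_floor: float = 0.05
    require_fio2_change: bool = True


@dataclass
class StudyConfig:
    cohort: CohortConfig = field(default_factory=CohortConfig)
    matching: MatchingPolicy = field(default_factory=MatchingPolicy)
    physiology: PhysiologyConstants = DEFAULT_CONSTANTS
    trending: TrendingParams = field(default_factory=TrendingParams)
    write_channels: bool = False


def _build(cls, section: dict, **extra):
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = set(section) - known
    if unknown:
        raise ValueError(f"unknown {cls.__name__} key(s): {sorted(unknown)}")
    kw = dict(section)
    for key, sub in extra.items():
        kw[key] = sub
    for key in ("median_window", "abg_interval_hours", "first_abg_hours",
                "paco2_range", "gap_duration_s", "lab_delay_s"):
        if key in kw and isinstance(kw[key], list):
            kw[key] = tuple(kw[key])
    return cls(**kw)


def load_study_config(path=None, seed: Optional[int] = None) -> StudyConfig:
    """Build a StudyConfig from a YAML/JSON file (all sections optional).

    Sections: cohort (with nested noise / policy), matching, physiology,
    trending, plus the top-level flag write_channels. ``seed`` overrides
    the cohort seed.
    """
    raw = load_config(path) if path is not None else {}
    cohort_raw = dict(raw.get("cohort", {}))
    extra = {}
    if "noise" in cohort_raw:
        extra["noise"] = _build(OximeterNoiseModel, cohort_raw.pop("noise"))
    if "policy" in cohort_raw:
        extra["policy"] = _build(TitrationPolicy, cohort_raw.pop("policy"))
    phys = _build(PhysiologyConstants, raw.get("physiology", {}))
    cohort = _build(CohortConfig, cohort_raw, constants=phys, **extra)
    if seed is not None:
        cohort = dataclasses.replace(cohort, seed=int(seed))
    return StudyConfig(
        cohort=cohort,
        matching=_build(MatchingPolicy, raw.get("matching", {})),
        physiology=phys,
        trending=_build(TrendingParams, raw.get("trending", {})),
        write_channels=bool(raw.get("write_channels", False)),
    )


def label_datapoints(datapoints: Sequence[Datapoint]):
    """(valid datapoints, PF labels, SF labels) in stable order."""
    valid = [dp for dp in datapoints if dp.valid]
    pf, sf = [], []
    for dp in valid:
        a, b = classify_datapoint(dp)
        pf.append(a)
        sf.append(b)
    return valid, pf, sf


def _severity_fractions(categories: Sequence[Severity]) -> dict[str, float]:
    n = len(categories)
    return {c.name.lower(): (sum(1 for x in categories if x == c) / n if n else 0.0)
            for c in Severity}


def _round_floats(obj, ndigits: int = 10):
    if isinstance(obj, float):
        return round(obj, ndigits)
    if isinstance(obj, dict):
        return {k: _round_floats(v, ndigits) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, ndigits) for v in obj]
    if isinstance(obj, (np.floating,)):
        return round(float(obj), ndigits)
    if isinstance(obj, (np.integer,)):
        return int(obj)
    return obj


def run_pipeline(config, out_dir) -> dict:
    """Run every stage on a synthetic cohort and write the study report.

    ``config`` is a :class:`StudyConfig` or a path to a config file.
    Writes datapoints.csv, labeled.csv, admissions.csv and report.json
    into ``out_dir`` (plus per-admission channel CSVs when
    write_channels is on) and returns the report as a dict.
    """
    if not isinstance(config, StudyConfig):
        config = load_study_config(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    cohort = simulate_cohort(config.cohort)
    log.info("simulate: %d admissions", len(cohort))
    if config.write_channels:
        write_cohort(cohort, out / "cohort")

    datapoints: list[Datapoint] = []
    for adm in cohort:
        datapoints.extend(build_datapoints(adm, config.matching))
    write_datapoints(datapoints, out / "datapoints.csv")
    by_reason = {r.value: sum(1 for d in datapoints if d.exclusion_reason is r)
                 for r in ExclusionReason if r is not ExclusionReason.NONE}
    log.info("match: %d datapoints (%s excluded)", len(datapoints), by_reason)

    valid, pf_labels, sf_labels = label_datapoints(datapoints)
    _write_labeled(valid, pf_labels, sf_labels, out / "labeled.csv")

    # admission level: most severe sustained category per scale
    adm_ids, adm_pf, adm_sf = [], [], []
    by_adm: dict[str, list[int]] = {}
    for i, dp in enumerate(valid):
        by_adm.setdefault(dp.admission_id, []).append(i)
    for adm_id in sorted(by_adm):
        idx = sorted(by_adm[adm_id], key=lambda i: valid[i].time)
        adm_ids.append(adm_id)
        adm_pf.append(admission_max_severity([pf_labels[i] for i in idx]))
        adm_sf.append(admission_max_severity([sf_labels[i] for i in idx]))
    _write_admissions(adm_ids, adm_pf, adm_sf, out / "admissions.csv")

    report: dict = {"seed": config.cohort.seed, "config": _config_echo(config)}

    dpa = [len(v) for v in by_adm.values()]
    report["cohort"] = {
        "n_admissions": len(cohort),
        "n_abgs": sum(len(a.abgs) for a in cohort),
        "n_datapoints": len(datapoints),
        "n_valid": len(valid),
        "n_admissions_with_valid": len(by_adm),
        "excluded_by_reason": by_reason,
        "datapoints_per_admission_mean": float(np.mean(dpa)) if dpa else 0.0,
        "datapoints_per_admission_sd": float(np.std(dpa, ddof=1)) if len(dpa) > 1 else 0.0,
    }

    report["severity"] = {
        "datapoint": {"PF": _severity_fractions([l.category for l in pf_labels]),
                      "SF": _severity_fractions([l.category for l in sf_labels])},
        "admission": {"PF": _severity_fractions(adm_pf),
                      "SF": _severity_fractions(adm_sf)},
    }

    agreement: dict = {}
    if valid:
        agreement["datapoint"] = AgreementReport.from_labels(
            "datapoint", pf_labels, sf_labels,
            pf_ratios=[l.ratio_value for l in pf_labels],
            sf_ratios=[l.ratio_value for l in sf_labels],
            fio2_fracs=[dp.fio2 for dp in valid]).to_dict()
    if adm_ids:
        agreement["admission"] = AgreementReport.from_labels(
            "admission", adm_pf, adm_sf).to_dict()
    report["agreement"] = agreement

    # oximetry: complete pairs regardless of validity (the error analysis
    # is not restricted to SpO2 <= 97)
    ox_pairs = [(dp.spo2, 100.0 * dp.sao2, dp.pao2) for dp in datapoints
                if dp.spo2 is not None and dp.sao2 is not None and dp.pao2 is not None]
    oximetry: dict = {"n_pairs": len(ox_pairs)}
    if len(ox_pairs) >= 2:
        spo2 = np.array([p[0] for p in ox_pairs])
        sao2 = np.array([p[1] for p in ox_pairs])
        pao2 = np.array([p[2] for p in ox_pairs])
        bias, precision = bias_precision(spo2, sao2)
        profile, crossing = binned_bias_profile(spo2, sao2)
        oximetry.update({
            "bias_pct": bias, "precision_pct": precision,
            "bias_crossing_pct": crossing,
            "bias_profile": [{"spo2_bin": c, "n": n, "mean_bias": b}
                             for c, n, b in profile],
            "rms_curve_deviation_sao2": curve_deviation(pao2, sao2 / 100.0),
            "rms_curve_deviation_spo2": curve_deviation(pao2, spo2 / 100.0),
        })
    report["oximetry"] = oximetry

    pairs = consecutive_pairs(valid, config.physiology)
    tp = config.trending
    trend = TrendReport.from_pairs(pairs, max_dt=tp.max_dt_hours * 3600.0,
                                   ri_tolerance=tp.ri_tolerance,
                                   ri_floor=tp.ri_floor,
                                   require_fio2_change=tp.require_fio2_change)
    report["trending"] = trend.to_dict()
    log.info("trend: %d pairs, %d stable", trend.n_pairs, trend.n_stable)

    convn: list[dict] = []
    if len(valid) >= 3:
        sf_vals = np.array([l.ratio_value for l in sf_labels])
        pf_vals = np.array([l.ratio_value for l in pf_labels])
        eqs = conv.builtin_registry() + [conv.fit_linear(sf_vals, pf_vals),
                                         conv.fit_loglinear(sf_vals, pf_vals)]
        for eq in eqs:
            m = conv.defined_mask(eq, sf_vals)
            try:
                r2, mae = conv.evaluate(eq, sf_vals[m], pf_vals[m])
            except ValueError:
                r2 = mae = None
            convn.append({"name": eq.name, "form": eq.form,
                          "direction": eq.direction, "intercept": eq.intercept,
                          "slope": eq.slope, "n_evaluated": int(m.sum()),
                          "r2": r2, "mae": mae})
    report["conversion"] = convn

    report = _round_floats(report)
    (out / "report.json").write_text(json.dumps(report, indent=1, sort_keys=True))
    return report


def _config_echo(config: StudyConfig) -> dict:
    def enc(obj):
        if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
            return {f.name: enc(getattr(obj, f.name)) for f in dataclasses.fields(obj)}
        if isinstance(obj, tuple):
            return list(obj)
        if hasattr(obj, "value"):  # enums
            return obj.value
        return obj
    return {"cohort": enc(config.cohort), "matching": enc(config.matching),
            "physiology": enc(config.physiology), "trending": enc(config.trending),
            "write_channels": config.write_channels}


def _write_labeled(valid, pf_labels, sf_labels, path) -> None:
    import pandas as pd
    pd.DataFrame({
        "admission_id": [d.admission_id for d in valid],
        "time_s": [d.time for d in valid],
        "pao2_mmhg": [d.pao2 for d in valid],
        "spo2_pct": [d.spo2 for d in valid],
        "fio2_frac": [d.fio2 for d in valid],
        "sao2_frac": [d.sao2 if d.sao2 is not None else "" for d in valid],
        "paco2_mmhg": [d.paco2 if d.paco2 is not None else "" for d in valid],
        "pf_ratio": [l.ratio_value for l in pf_labels],
        "sf_ratio": [l.ratio_value for l in sf_labels],
        "pf_category": [l.category.name.lower() for l in pf_labels],
        "sf_category": [l.category.name.lower() for l in sf_labels],
    }).to_csv(path, index=False)


def _write_admissions(adm_ids, adm_pf, adm_sf, path) -> None:
    import pandas as pd
    pd.DataFrame({
        "admission_id": adm_ids,
        "pf_max_severity": [c.name.lower() for c in adm_pf],
        "sf_max_severity": [c.name.lower() for c in adm_sf],
    }).to_csv(path, index=False)
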