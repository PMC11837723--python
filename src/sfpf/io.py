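"""Domain containers and CSV I/O for ICU oxygenation time-series.

All timestamps are seconds since admission start. SpO2 is carried in
percent, SaO2 as a saturation fraction, FiO2 as a fraction of inspired
oxygen in [0.21, 1.0] -- the units the downstream formulas consume.
Conversions between these conventions are always explicit.

CSV schemas (UTF-8, "." decimal, header required):

* channels:   admission_id, channel, time_s, value, units
* support:    admission_id, start_s, end_s, mode, peep_cmh2o, flow_lpm
* abg:        admission_id, time_s, pao2_mmhg, sao2_frac, paco2_mmhg
* datapoints: one row per :class:`Datapoint`, booleans as true/false
"""

from __future__ import annotations

import enum
import json
import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

log = logging.getLogger(__name__)

__all__ = [
    "SupportMode",
    "ExclusionReason",
    "ChannelSeries",
    "SupportInterval",
    "AbgEvent",
    "AdmissionRecord",
    "Datapoint",
    "SchemaError",
    "normalize_fio2",
    "read_admission",
    "read_cohort",
    "write_cohort",
    "write_datapoints",
    "read_datapoints",
    "load_config",
]


class SchemaError(ValueError):
    """A CSV file does not conform to the expected schema."""


class SupportMode(str, enum.Enum):
    INVASIVE = "invasive_ventilation"
    NIV_CPAP = "niv_cpap"
    HFNO = "hfno"
    NONE = "none"


#: modes whose support criterion is a PEEP level
PEEP_MODES = frozenset({SupportMode.INVASIVE, SupportMode.NIV_CPAP})


class ExclusionReason(str, enum.Enum):
    NONE = "none"
    SPO2_GT_97 = "spo2_gt_97"
    SUPPORT = "support_criteria"
    INCOMPLETE = "incomplete"


@dataclass
class ChannelSeries:
    """One named physiologic signal as parallel (time, value) arrays.

    Times must be strictly increasing and values finite; use
    :meth:`from_samples` for raw rows that may be unsorted or contain
    duplicated timestamps (collapsed to their median).
    """

    name: str
    times: np.ndarray
    values: np.ndarray
    units: str = ""

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.shape != self.values.shape or self.times.ndim != 1:
            raise ValueError(f"channel {self.name}: times/values must be 1-D and equal length")
        if self.times.size and not np.all(np.diff(self.times) > 0):
            raise ValueError(f"channel {self.name}: times must be strictly increasing")
        if not np.all(np.isfinite(self.values)):
            raise ValueError(f"channel {self.name}: values must be finite")

    def __len__(self) -> int:
        return int(self.times.size)

    @classmethod
    def from_samples(cls, name, times, values, units: str = "") -> "ChannelSeries":
        """Build a series from possibly unsorted rows.

        Rows are stably sorted by time; samples sharing a timestamp are
        collapsed to their median value.
        """
        t = np.asarray(times, dtype=float)
        v = np.asarray(values, dtype=float)
        order = np.argsort(t, kind="stable")
        t, v = t[order], v[order]
        if t.size and np.any(np.diff(t) == 0):
            ut, inverse = np.unique(t, return_inverse=True)
            uv = np.empty_like(ut)
            for i in range(ut.size):
                uv[i] = np.median(v[inverse == i])
            t, v = ut, uv
        return cls(name=name, times=t, values=v, units=units)


@dataclass(frozen=True)
class SupportInterval:
    """A contiguous stretch of one respiratory support mode."""

    start: float
    end: float
    mode: SupportMode
    peep: Optional[float] = None
    flow: Optional[float] = None

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError("support interval requires start < end")
        if self.mode in PEEP_MODES and self.peep is None:
            raise ValueError(f"mode {self.mode.value} requires a PEEP level")
        if self.mode is SupportMode.HFNO and self.flow is None:
            raise ValueError("HFNO requires a flow rate")
        if self.mode not in PEEP_MODES and self.peep is not None:
            raise ValueError(f"mode {self.mode.value} must not carry a PEEP level")
        if self.mode is not SupportMode.HFNO and self.flow is not None:
            raise ValueError(f"mode {self.mode.value} must not carry a flow rate")


@dataclass(frozen=True)
class AbgEvent:
    """One arterial blood gas draw (lab timestamp, not the draw time)."""

    nominal_time: float
    pao2: float
    sao2: Optional[float] = None
    paco2: Optional[float] = None

    def __post_init__(self) -> None:
        if not self.pao2 > 0:
            raise ValueError("PaO2 must be positive")
        if self.sao2 is not None and not 0 < self.sao2 <= 1:
            raise ValueError("SaO2 must be a fraction in (0, 1]")
        if self.paco2 is not None and not self.paco2 > 0:
            raise ValueError("PaCO2 must be positive")


RESOLUTION_CLASSES = ("high", "minute", "hourly")


@dataclass
class AdmissionRecord:
    """One ICU admission: channels, support intervals and ABG events."""

    admission_id: str
    channels: dict[str, ChannelSeries]
    support: tuple[SupportInterval, ...]
    abgs: tuple[AbgEvent, ...]
    resolution_class: str = "minute"

    def __post_init__(self) -> None:
        self.support = tuple(self.support)
        self.abgs = tuple(self.abgs)
        for required in ("spo2", "fio2"):
            if required not in self.channels:
                raise ValueError(f"admission {self.admission_id}: missing channel {required!r}")
        if self.resolution_class not in RESOLUTION_CLASSES:
            raise ValueError(f"unknown resolution class {self.resolution_class!r}")
        times = [a.nominal_time for a in self.abgs]
        if any(b < a for a, b in zip(times, times[1:])):
            raise ValueError(f"admission {self.admission_id}: ABGs must be time-ordered")
        ivals = sorted(self.support, key=lambda s: s.start)
        if any(b.start < a.end for a, b in zip(ivals, ivals[1:])):
            raise ValueError(f"admission {self.admission_id}: support intervals overlap")

    def support_at(self, t: float) -> Optional[SupportInterval]:
        """The support interval covering time ``t`` (start inclusive, end exclusive)."""
        for iv in self.support:
            if iv.start <= t < iv.end:
                return iv
        return None


@dataclass
class Datapoint:
    """One time-matched (PaO2, SpO2, FiO2) tuple -- the unit of analysis."""

    admission_id: str
    time: float
    pao2: Optional[float]
    spo2: Optional[float]
    fio2: Optional[float]
    sao2: Optional[float] = None
    paco2: Optional[float] = None
    mode: Optional[SupportMode] = None
    peep: Optional[float] = None
    flow: Optional[float] = None
    valid: bool = False
    exclusion_reason: ExclusionReason = ExclusionReason.INCOMPLETE

    def __post_init__(self) -> None:
        if self.valid != (self.exclusion_reason is ExclusionReason.NONE):
            raise ValueError("valid flag inconsistent with exclusion_reason")
        if self.fio2 is not None and not 0.21 - 1e-9 <= self.fio2 <= 1.0 + 1e-9:
            raise ValueError(f"FiO2 {self.fio2} outside [0.21, 1.0]")
        if self.spo2 is not None and not 0 < self.spo2 <= 100:
            raise ValueError(f"SpO2 {self.spo2} outside (0, 100]")


# ---------------------------------------------------------------------------
# FiO2 unit handling

def normalize_fio2(values):
    """Coerce FiO2 values to fractions.

    Values above 1.0 are treated as percent and divided by 100; values in
    [0.15, 1.0] are fractions already; anything below 0.15 after conversion
    is physiologically impossible and rejected.
    """
    v = np.asarray(values, dtype=float)
    scalar = v.ndim == 0
    v = np.atleast_1d(v).copy()
    pct = v > 1.0
    v[pct] = v[pct] / 100.0
    if np.any(v < 0.15):
        bad = np.atleast_1d(np.asarray(values, dtype=float))[v < 0.15]
        raise ValueError(f"FiO2 value(s) {bad.tolist()} below the plausible range")
    return float(v[0]) if scalar else v


# ---------------------------------------------------------------------------
# CSV readers

CHANNEL_COLUMNS = ["admission_id", "channel", "time_s", "value", "units"]
SUPPORT_COLUMNS = ["admission_id", "start_s", "end_s", "mode", "peep_cmh2o", "flow_lpm"]
ABG_COLUMNS = ["admission_id", "time_s", "pao2_mmhg", "sao2_frac", "paco2_mmhg"]
DATAPOINT_COLUMNS = [
    "admission_id", "time_s", "pao2_mmhg", "spo2_pct", "fio2_frac", "sao2_frac",
    "paco2_mmhg", "mode", "peep_cmh2o", "flow_lpm", "valid", "exclusion_reason",
]


def _read_table(path, columns: Sequence[str], numeric: Sequence[str]) -> pd.DataFrame:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")
    for col in numeric:
        # exact (correctly rounded) parsing; pandas' fast parser can be
        # one ulp off, which would break round-trip identity
        values = np.empty(len(df), dtype=float)
        for i, s in enumerate(df[col].to_numpy()):
            if s == "":
                values[i] = np.nan
                continue
            try:
                values[i] = float(s)
            except ValueError:
                raise SchemaError(f"{path}: non-numeric value {s!r} in column "
                                  f"{col!r} at line {i + 2}") from None
        df[col] = values
    return df


def _infer_resolution(spo2: ChannelSeries) -> str:
    if len(spo2) < 2:
        return "minute"
    dt = float(np.median(np.diff(spo2.times)))
    if dt <= 2.0:
        return "high"
    if dt <= 120.0:
        return "minute"
    return "hourly"


def _opt(x) -> Optional[float]:
    return None if x is None or (isinstance(x, float) and math.isnan(x)) else float(x)


def read_admission(channel_csv_path, support_csv_path, abg_csv_path,
                   resolution_class: Optional[str] = None) -> AdmissionRecord:
    """Read one admission from the three long-format CSV files.

    Channel rows out of time order are sorted and duplicate timestamps
    collapsed to their median. FiO2 values recorded in percent are
    converted to fractions. When ``resolution_class`` is not given it is
    inferred from the SpO2 channel's median sampling interval.
    """
    ch = _read_table(channel_csv_path, CHANNEL_COLUMNS, ["time_s", "value"])
    sup = _read_table(support_csv_path, SUPPORT_COLUMNS,
                      ["start_s", "end_s", "peep_cmh2o", "flow_lpm"])
    abg = _read_table(abg_csv_path, ABG_COLUMNS, ["time_s", "pao2_mmhg", "sao2_frac", "paco2_mmhg"])

    ids = set(ch["admission_id"]) | set(sup["admission_id"]) | set(abg["admission_id"])
    ids.discard("")
    if len(ids) != 1:
        raise SchemaError(f"expected exactly one admission_id, found {sorted(ids)}")
    admission_id = ids.pop()

    channels: dict[str, ChannelSeries] = {}
    for name, grp in ch.groupby("channel", sort=True):
        values = grp["value"].to_numpy()
        units = grp["units"].iloc[0]
        if name == "fio2":
            values = normalize_fio2(values)
            units = "fraction"
        channels[str(name)] = ChannelSeries.from_samples(
            str(name), grp["time_s"].to_numpy(), values, units=str(units))

    support = []
    for _, row in sup.iterrows():
        mode = SupportMode(row["mode"])
        support.append(SupportInterval(
            start=float(row["start_s"]), end=float(row["end_s"]), mode=mode,
            peep=_opt(row["peep_cmh2o"]) if mode in PEEP_MODES else None,
            flow=_opt(row["flow_lpm"]) if mode is SupportMode.HFNO else None))
    support.sort(key=lambda s: s.start)

    abgs = [AbgEvent(nominal_time=float(r["time_s"]), pao2=float(r["pao2_mmhg"]),
                     sao2=_opt(r["sao2_frac"]), paco2=_opt(r["paco2_mmhg"]))
            for _, r in abg.sort_values("time_s", kind="stable").iterrows()]

    if resolution_class is None:
        resolution_class = _infer_resolution(channels["spo2"])
    return AdmissionRecord(admission_id=admission_id, channels=channels,
                           support=tuple(support), abgs=tuple(abgs),
                           resolution_class=resolution_class)


# ---------------------------------------------------------------------------
# Cohort directory layout: per-admission CSV triplets plus a manifest

def write_cohort(cohort: Iterable[AdmissionRecord], out_dir) -> dict:
    """Write each admission as three CSVs plus a ``manifest.json``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, dict] = {}
    for adm in cohort:
        stem = adm.admission_id
        ch_rows = []
        for name in sorted(adm.channels):
            s = adm.channels[name]
            ch_rows.append(pd.DataFrame({
                "admission_id": adm.admission_id, "channel": name,
                "time_s": s.times, "value": s.values, "units": s.units}))
        ch_df = (pd.concat(ch_rows, ignore_index=True) if ch_rows
                 else pd.DataFrame(columns=CHANNEL_COLUMNS))
        ch_df.to_csv(out / f"{stem}_channels.csv", index=False)
        pd.DataFrame([{
            "admission_id": adm.admission_id, "start_s": iv.start, "end_s": iv.end,
            "mode": iv.mode.value,
            "peep_cmh2o": "" if iv.peep is None else iv.peep,
            "flow_lpm": "" if iv.flow is None else iv.flow,
        } for iv in adm.support], columns=SUPPORT_COLUMNS).to_csv(
            out / f"{stem}_support.csv", index=False)
        pd.DataFrame([{
            "admission_id": adm.admission_id, "time_s": a.nominal_time,
            "pao2_mmhg": a.pao2,
            "sao2_frac": "" if a.sao2 is None else a.sao2,
            "paco2_mmhg": "" if a.paco2 is None else a.paco2,
        } for a in adm.abgs], columns=ABG_COLUMNS).to_csv(
            out / f"{stem}_abg.csv", index=False)
        manifest[adm.admission_id] = {
            "resolution_class": adm.resolution_class,
            "channels": f"{stem}_channels.csv",
            "support": f"{stem}_support.csv",
            "abg": f"{stem}_abg.csv",
        }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest


def read_cohort(in_dir) -> list[AdmissionRecord]:
    """Read a cohort written by :func:`write_cohort` (manifest-driven)."""
    root = Path(in_dir)
    manifest = json.loads((root / "manifest.json").read_text())
    cohort = []
    for admission_id in sorted(manifest):
        entry = manifest[admission_id]
        cohort.append(read_admission(
            root / entry["channels"], root / entry["support"], root / entry["abg"],
            resolution_class=entry.get("resolution_class")))
    return cohort


# ---------------------------------------------------------------------------
# Flat datapoint tables

def write_datapoints(datapoints: Sequence[Datapoint], path) -> int:
    """Write datapoints to a flat CSV; returns the number of rows written."""
    rows = []
    for dp in datapoints:
        rows.append({
            "admission_id": dp.admission_id, "time_s": dp.time,
            "pao2_mmhg": "" if dp.pao2 is None else dp.pao2,
            "spo2_pct": "" if dp.spo2 is None else dp.spo2,
            "fio2_frac": "" if dp.fio2 is None else dp.fio2,
            "sao2_frac": "" if dp.sao2 is None else dp.sao2,
            "paco2_mmhg": "" if dp.paco2 is None else dp.paco2,
            "mode": "" if dp.mode is None else dp.mode.value,
            "peep_cmh2o": "" if dp.peep is None else dp.peep,
            "flow_lpm": "" if dp.flow is None else dp.flow,
            "valid": "true" if dp.valid else "false",
            "exclusion_reason": dp.exclusion_reason.value,
        })
    df = pd.DataFrame(rows, columns=DATAPOINT_COLUMNS)
    df.to_csv(path, index=False)
    return len(df)


def read_datapoints(path) -> list[Datapoint]:
    df = _read_table(path, DATAPOINT_COLUMNS,
                     ["time_s", "pao2_mmhg", "spo2_pct", "fio2_frac", "sao2_frac",
                      "paco2_mmhg", "peep_cmh2o", "flow_lpm"])
    out = []
    for _, r in df.iterrows():
        out.append(Datapoint(
            admission_id=str(r["admission_id"]), time=float(r["time_s"]),
            pao2=_opt(r["pao2_mmhg"]), spo2=_opt(r["spo2_pct"]), fio2=_opt(r["fio2_frac"]),
            sao2=_opt(r["sao2_frac"]), paco2=_opt(r["paco2_mmhg"]),
            mode=SupportMode(r["mode"]) if r["mode"] else None,
            peep=_opt(r["peep_cmh2o"]), flow=_opt(r["flow_lpm"]),
            valid=r["valid"] == "true",
            exclusion_reason=ExclusionReason(r["exclusion_reason"]),
        ))
    return out


def load_config(path) -> dict:
    """Load the shared YAML (or JSON) configuration file as a dict."""
    with open(path, "r", encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh)
    if cfg is None:
        cfg = {}
    if not isinstance(cfg, dict):
        raise SchemaError(f"{path}: config root must be a mapping")
    return cfg
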