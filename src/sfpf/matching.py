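"""Time-matching of vital-sign channels to ABG events.

One candidate datapoint is produced per ABG event. The reference time is
the corrected draw time found via gaps in the 1-Hz arterial-pressure
channel (the sampling line is flushed during the draw) when such a gap
exists within 15 min before the lab timestamp; otherwise the nominal lab
timestamp. SpO2 and FiO2 are summarized as the median of samples between
5 and 2 min before the reference time for high/minute-resolution data,
or the nearest sample within 30 min for hourly-resolution data.

The validity filter then keeps datapoints with SpO2 <= 97% recorded
during invasive ventilation / NIV / CPAP with PEEP >= 5 cmH2O or HFNO
with flow >= 30 L/min; everything else is flagged with the first failing
rule (incomplete, spo2_gt_97, support_criteria).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np

from .io import (AdmissionRecord, ChannelSeries, Datapoint, ExclusionReason,
                 PEEP_MODES, SupportMode)

__all__ = [
    "MatchingPolicy",
    "detect_abg_time",
    "window_median",
    "nearest_within",
    "build_datapoints",
    "validity_filter",
]


@dataclass(frozen=True)
class MatchingPolicy:
    """Tunables of the matching stage (all in seconds).

    gap_search_window: how far before the nominal ABG time a pressure gap
        may end and still identify the draw (15 min).
    gap_min_duration: minimum inter-sample spacing of the 1-Hz pressure
        channel that counts as a blood-draw gap (30 s).
    median_window: (start, end) of the summarizing window before the
        reference time, closed on both ends (5 min to 2 min).
    max_offset_minute_res / max_offset_hourly_res: matching tolerance for
        nearest-sample lookup (5 min / 30 min).
    """

    gap_search_window: float = 900.0
    gap_min_duration: float = 30.0
    median_window: tuple[float, float] = (300.0, 120.0)
    max_offset_minute_res: float = 300.0
    max_offset_hourly_res: float = 1800.0

    def __post_init__(self) -> None:
        start, end = self.median_window
        if not (start > end >= 0):
            raise ValueError("median window requires start > end >= 0")
        if min(self.gap_search_window, self.gap_min_duration,
               self.max_offset_minute_res, self.max_offset_hourly_res) <= 0:
            raise ValueError("matching windows must be positive")


DEFAULT_POLICY = MatchingPolicy()


def detect_abg_time(pressure: ChannelSeries, nominal_time: float,
                    policy: MatchingPolicy = DEFAULT_POLICY) -> Optional[float]:
    """Corrected ABG draw time from pressure-waveform gaps, or None.

    Returns the end of the latest inter-sample gap of at least
    ``gap_min_duration`` whose end lies within ``gap_search_window``
    before the nominal lab timestamp. The latest qualifying gap wins
    because the draw immediately precedes the lab result.
    """
    t = pressure.times
    if t.size < 2:
        return None
    ends = t[1:][np.diff(t) >= policy.gap_min_duration]
    ok = ends[(ends >= nominal_time - policy.gap_search_window) & (ends <= nominal_time)]
    return float(ok[-1]) if ok.size else None


def window_median(series: ChannelSeries, reference_time: float,
                  window: tuple[float, float] = DEFAULT_POLICY.median_window,
                  ) -> Optional[float]:
    """Median of samples in [reference - start, reference - end], closed ends."""
    start, end = window
    lo, hi = reference_time - start, reference_time - end
    i0 = int(np.searchsorted(series.times, lo, side="left"))
    i1 = int(np.searchsorted(series.times, hi, side="right"))
    if i1 <= i0:
        return None
    return float(np.median(series.values[i0:i1]))


def nearest_within(series: ChannelSeries, reference_time: float,
                   max_offset: float) -> Optional[float]:
    """Value of the sample nearest the reference time, within max_offset.

    Ties between an earlier and a later sample go to the earlier one.
    """
    if max_offset <= 0:
        raise ValueError("max_offset must be positive")
    t = series.times
    if t.size == 0:
        return None
    i = int(np.searchsorted(t, reference_time, side="left"))
    best = None
    for j in (i - 1, i):  # earlier candidate first so ties keep it
        if 0 <= j < t.size:
            d = abs(t[j] - reference_time)
            if d <= max_offset and (best is None or d < best[0]):
                best = (d, float(series.values[j]))
    return None if best is None else best[1]


def _step_resample(setting: ChannelSeries, grid: np.ndarray) -> ChannelSeries:
    """Forward-fill an event-sampled setting channel onto a sample grid.

    Charted settings such as FiO2 are step functions recorded on change;
    summarizing them with the same windowed statistics as measured
    signals requires sampling the step function on the signal's grid.
    Grid points before the first recorded setting are dropped.
    """
    idx = np.searchsorted(setting.times, grid, side="right") - 1
    keep = idx >= 0
    return ChannelSeries(name=setting.name, times=grid[keep],
                         values=setting.values[idx[keep]], units=setting.units)


def build_datapoints(admission: AdmissionRecord,
                     policy: MatchingPolicy = DEFAULT_POLICY) -> list[Datapoint]:
    """One candidate datapoint per ABG event of one admission.

    Emits exactly one datapoint per ABG; datapoints missing any of
    PaO2/SpO2/FiO2 are emitted with exclusion_reason=incomplete rather
    than dropped. Validity beyond completeness is decided by
    :func:`validity_filter`.
    """
    spo2_ch = admission.channels["spo2"]
    fio2_ch = admission.channels["fio2"]
    pressure = admission.channels.get("abp")
    fio2_grid = _step_resample(fio2_ch, spo2_ch.times) if len(spo2_ch) else fio2_ch

    out: list[Datapoint] = []
    for abg in admission.abgs:
        ref = None
        if pressure is not None:
            ref = detect_abg_time(pressure, abg.nominal_time, policy)
        t = abg.nominal_time if ref is None else ref

        if admission.resolution_class == "hourly":
            spo2 = nearest_within(spo2_ch, t, policy.max_offset_hourly_res)
            fio2 = nearest_within(fio2_grid, t, policy.max_offset_hourly_res)
        else:
            spo2 = window_median(spo2_ch, t, policy.median_window)
            fio2 = window_median(fio2_grid, t, policy.median_window)

        iv = admission.support_at(t)
        out.append(Datapoint(
            admission_id=admission.admission_id, time=t,
            pao2=abg.pao2, spo2=spo2, fio2=fio2,
            sao2=abg.sao2, paco2=abg.paco2,
            mode=None if iv is None else iv.mode,
            peep=None if iv is None else iv.peep,
            flow=None if iv is None else iv.flow,
            valid=False, exclusion_reason=ExclusionReason.INCOMPLETE))
    return validity_filter(out)


def _support_ok(dp: Datapoint) -> bool:
    if dp.mode in PEEP_MODES:
        return dp.peep is not None and dp.peep >= 5.0
    if dp.mode is SupportMode.HFNO:
        return dp.flow is not None and dp.flow >= 30.0
    return False


def validity_filter(datapoints: Sequence[Datapoint]) -> list[Datapoint]:
    """Set valid/exclusion_reason on every datapoint (order-preserving).

    Rules, first failing one recorded: completeness (PaO2, SpO2, FiO2 all
    present), SpO2 <= 97%, support criteria (PEEP >= 5 under
    ventilation/NIV/CPAP, or HFNO flow >= 30 L/min). Idempotent.
    """
    out = []
    for dp in datapoints:
        if dp.pao2 is None or dp.spo2 is None or dp.fio2 is None:
            reason = ExclusionReason.INCOMPLETE
        elif dp.spo2 > 97.0:
            reason = ExclusionReason.SPO2_GT_97
        elif not _support_ok(dp):
            reason = ExclusionReason.SUPPORT
        else:
            reason = ExclusionReason.NONE
        out.append(replace(dp, valid=reason is ExclusionReason.NONE,
                           exclusion_reason=reason))
    return out
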