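"""Physiology-based synthetic ICU cohort generator.

Emulates the statistical structure the downstream analyses assume,
without any access-restricted database: a latent gas-exchange state (the
Respiratory Index, RI) follows a geometric random walk with occasional
worsening jumps; a clinician titration policy adjusts FiO2 every review
interval to keep the observed SpO2 inside a target band; true PaO2
derives from RI and FiO2 through the alveolar gas equation; SaO2 follows
the Severinghaus curve plus co-oximeter noise; and the pulse oximeter
reads SaO2 through a heteroscedastic bias line crossing zero near 94%
saturation plus Gaussian noise and integer rounding. ABGs occur at
random intervals; for high-resolution admissions a 1-Hz arterial
pressure channel carries a gap just before each draw and the lab
timestamp lags the draw.

Everything is driven by one master seed; each admission derives its own
independent generator from (seed, admission index), so cohorts are
reproducible and admissions mutually independent.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from .io import (AbgEvent, AdmissionRecord, ChannelSeries, SupportInterval,
                 SupportMode)
from .physiology import (DEFAULT_CONSTANTS, PhysiologyConstants,
                         severinghaus_sao2)

__all__ = [
    "OximeterNoiseModel",
    "TitrationPolicy",
    "CohortConfig",
    "simulate_ri_path",
    "observe_spo2",
    "simulate_admission",
    "simulate_cohort",
    "reference_saturation_mix",
]


@dataclass(frozen=True)
class OximeterNoiseModel:
    """Heteroscedastic pulse-oximeter error model.

    SpO2 = round(SaO2 + bias_slope * (SaO2 - bias_crossing) + eps) with
    eps ~ Normal(0, sd^2), clamped to (0, clamp_high]. The bias line is
    negative below and positive above the crossing, matching the
    observed error structure of bedside oximeters against co-oximetry
    (error grows toward low saturations). All saturations in percent.

    The default slope was calibrated jointly with the reference
    saturation mix so that, on that mix, the cohort-level mean bias
    lands near +0.5% and the bias-profile zero crossing is recoverable
    near 94% despite the 100% ceiling censoring readings at high
    saturation.
    """

    bias_slope: float = 0.45
    bias_crossing: float = 94.0
    sd: float = 2.0
    rounding: bool = True
    clamp_high: float = 100.0

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError("oximeter noise sd must be >= 0")
        if not 50.0 < self.bias_crossing < 100.0:
            raise ValueError("bias crossing must lie in (50, 100)%")


@dataclass(frozen=True)
class TitrationPolicy:
    """Clinician FiO2 titration toward an SpO2 target band.

    Reviewed every ``review_interval`` seconds on the observed SpO2:
    below the band FiO2 steps up by ``step_up``, above it steps down by
    ``step_down`` (asymmetric: hypoxemia is corrected faster than
    hyperoxia), clamped to [fio2_min, fio2_max].
    """

    target_low: float = 92.0
    target_high: float = 96.0
    step_up: float = 0.10
    step_down: float = 0.05
    review_interval: float = 900.0
    fio2_min: float = 0.21
    fio2_max: float = 1.0

    def __post_init__(self) -> None:
        if not self.target_low < self.target_high:
            raise ValueError("titration targets require low < high")
        if self.step_up <= 0 or self.step_down <= 0:
            raise ValueError("titration steps must be positive")


@dataclass(frozen=True)
class CohortConfig:
    """Study conditions of the synthetic cohort.

    The RI process is parameterized on the log scale: admissions draw an
    initial log-RI from Normal(ri_log_mean, ri_log_sd), then follow a
    random walk with the given hourly standard deviation plus rare
    upward (worsening) jumps. PaCO2 is redrawn i.i.d. at every ABG and
    held piecewise-constant between draws, so the RI computed from an
    ABG equals the latent RI at that moment.
    """

    n_admissions: int = 200
    duration_hours: float = 48.0
    resolution_class: str = "minute"  # high | minute | hourly
    ri_log_mean: float = math.log(4.5)
    ri_log_sd: float = 0.55
    ri_walk_sd_hourly: float = 0.10
    ri_jump_prob_hourly: float = 0.015
    ri_jump_log_magnitude: float = math.log(1.6)
    abg_interval_hours: tuple[float, float] = (1.0, 6.0)
    first_abg_hours: tuple[float, float] = (0.5, 1.5)
    paco2_mean: float = 42.0
    paco2_sd: float = 5.0
    paco2_range: tuple[float, float] = (25.0, 80.0)
    sao2_coox_sd: float = 0.004  # co-oximeter noise, saturation fraction
    pressure_gap_probability: float = 0.9
    gap_duration_s: tuple[float, float] = (45.0, 90.0)
    lab_delay_s: tuple[float, float] = (120.0, 600.0)
    fio2_init: float = 0.5
    support_mode: SupportMode = SupportMode.INVASIVE
    support_peep: Optional[float] = 8.0
    support_flow: Optional[float] = None
    noise: OximeterNoiseModel = field(default_factory=OximeterNoiseModel)
    policy: TitrationPolicy = field(default_factory=TitrationPolicy)
    titration_enabled: bool = True
    constants: PhysiologyConstants = DEFAULT_CONSTANTS
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_admissions < 0 or self.duration_hours <= 0:
            raise ValueError("cohort size/duration must be positive")
        for sd in (self.ri_log_sd, self.ri_walk_sd_hourly, self.paco2_sd,
                   self.sao2_coox_sd):
            if sd < 0:
                raise ValueError("standard deviations must be >= 0")
        if not 0 <= self.ri_jump_prob_hourly <= 1 or not 0 <= self.pressure_gap_probability <= 1:
            raise ValueError("probabilities must lie in [0, 1]")


def simulate_ri_path(config: CohortConfig, rng: np.random.Generator,
                     ) -> ChannelSeries:
    """Latent Respiratory Index path at 1-minute resolution.

    Geometric random walk: per-minute log increments have standard
    deviation ``ri_walk_sd_hourly / sqrt(60)``; each minute carries an
    upward jump of ``ri_jump_log_magnitude`` with hourly probability
    ``ri_jump_prob_hourly`` (worsening events). Strictly positive by
    construction.
    """
    n = int(round(config.duration_hours * 60))
    lr0 = rng.normal(config.ri_log_mean, config.ri_log_sd)
    inc = rng.normal(0.0, config.ri_walk_sd_hourly / math.sqrt(60.0), size=n - 1)
    jumps = (rng.random(n - 1) < config.ri_jump_prob_hourly / 60.0) \
        * config.ri_jump_log_magnitude
    log_ri = lr0 + np.concatenate([[0.0], np.cumsum(inc + jumps)])
    return ChannelSeries(name="ri_true", times=60.0 * np.arange(n),
                         values=np.exp(log_ri), units="dimensionless")


def observe_spo2(sao2_pct, model: OximeterNoiseModel, rng: np.random.Generator):
    """Pulse-oximeter reading(s) for true saturation(s) in percent."""
    sao2 = np.asarray(sao2_pct, dtype=float)
    if np.any(sao2 <= 0) or np.any(sao2 > 100):
        raise ValueError("SaO2 percent must lie in (0, 100]")
    spo2 = sao2 + model.bias_slope * (sao2 - model.bias_crossing)
    if model.sd > 0:
        spo2 = spo2 + rng.normal(0.0, model.sd, size=spo2.shape)
    if model.rounding:
        spo2 = np.rint(spo2)
    spo2 = np.clip(spo2, 1.0, model.clamp_high)
    return float(spo2) if np.ndim(sao2_pct) == 0 else spo2


def reference_saturation_mix(n: int, rng: np.random.Generator) -> np.ndarray:
    """Reference SaO2 mix (percent) for oximeter calibration checks.

    Left-skewed, ICU-like: SaO2 = 100 - X with X = 2 + Exponential(mean
    2.75), truncated at 40 -- mean saturation near 95.3% with a tail of
    desaturated readings and the bulk kept below 98% so the oximeter's
    100% ceiling censors few observations. This is the documented
    default saturation mix against which the noise-model calibration
    (mean bias, precision, crossing recovery) is evaluated.
    """
    x = np.minimum(2.0 + rng.exponential(2.75, size=n), 40.0)
    return 100.0 - x


def _admission_rng(seed: int, index: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), int(index)]))


def simulate_admission(config: CohortConfig, admission_index: int) -> AdmissionRecord:
    """Generate one internally consistent admission record.

    At each minute: FiO2 follows the titration policy evaluated on the
    observed SpO2 at review times; true PaO2 = PAO2(FiO2, PaCO2)/(1+RI);
    SaO2 = Severinghaus(PaO2); the SpO2 channel is the oximeter
    observation emitted at the admission's resolution; ABGs record
    (PaO2, SaO2 + co-oximeter noise, PaCO2). High-resolution admissions
    carry a 1-Hz pressure channel with a gap before each ABG draw and a
    lab-delayed nominal timestamp.
    """
    rng = _admission_rng(config.seed, admission_index)
    pol, noise, k = config.policy, config.noise, config.constants
    n_min = int(round(config.duration_hours * 60))
    duration_s = n_min * 60.0

    ri = simulate_ri_path(config, rng).values

    # ABG schedule (minutes)
    abg_minutes: list[int] = []
    t = rng.uniform(*config.first_abg_hours)
    while t * 60 < n_min - 6:  # leave room for the matching window
        abg_minutes.append(int(round(t * 60)))
        t += rng.uniform(*config.abg_interval_hours)

    # PaCO2: redrawn at t=0 and at each ABG, piecewise-constant between
    lo, hi = config.paco2_range
    draws = np.clip(rng.normal(config.paco2_mean, config.paco2_sd,
                               size=1 + len(abg_minutes)), lo, hi)
    paco2 = np.empty(n_min)
    paco2[: abg_minutes[0] if abg_minutes else n_min] = draws[0]
    for i, m in enumerate(abg_minutes):
        nxt = abg_minutes[i + 1] if i + 1 < len(abg_minutes) else n_min
        paco2[m:nxt] = draws[i + 1]

    # Titration loop over review blocks; state vectorized within a block
    pb = k.barometric_pressure - k.water_vapor_pressure
    rv = max(1, int(round(pol.review_interval / 60.0)))
    fio2_min_arr = np.empty(n_min)
    pao2_min = np.empty(n_min)
    sao2_min = np.empty(n_min)
    spo2_min = np.empty(n_min)
    fio2_events: list[tuple[float, float]] = [(0.0, config.fio2_init)]
    cur = config.fio2_init
    for b0 in range(0, n_min, rv):
        b1 = min(b0 + rv, n_min)
        fio2_min_arr[b0:b1] = cur
        pao2_alv = cur * pb - paco2[b0:b1] / k.respiratory_quotient
        pao2_blk = np.maximum(pao2_alv, 5.0) / (1.0 + ri[b0:b1])
        pao2_min[b0:b1] = pao2_blk
        sao2_min[b0:b1] = severinghaus_sao2(pao2_blk)
        spo2_min[b0:b1] = observe_spo2(100.0 * sao2_min[b0:b1], noise, rng)
        if config.titration_enabled and b1 < n_min:
            last = spo2_min[b1 - 1]
            new = cur
            if last < pol.target_low:
                new = min(cur + pol.step_up, pol.fio2_max)
            elif last > pol.target_high:
                new = max(cur - pol.step_down, pol.fio2_min)
            if new != cur:
                fio2_events.append((b1 * 60.0, new))
                cur = new

    # Channels at the admission's resolution
    minute_times = 60.0 * np.arange(n_min)
    if config.resolution_class == "high":
        sec_times = np.arange(duration_s)
        sao2_sec = np.repeat(sao2_min, 60)[: sec_times.size]
        spo2_series = ChannelSeries("spo2", sec_times,
                                    observe_spo2(100.0 * sao2_sec, noise, rng),
                                    units="%")
    elif config.resolution_class == "hourly":
        idx = np.arange(0, n_min, 60)
        spo2_series = ChannelSeries("spo2", minute_times[idx], spo2_min[idx], units="%")
    else:
        spo2_series = ChannelSeries("spo2", minute_times, spo2_min, units="%")

    ev_t, ev_v = zip(*fio2_events)
    fio2_series = ChannelSeries("fio2", np.asarray(ev_t), np.asarray(ev_v),
                                units="fraction")

    # ABG events (+ pressure gaps / lab delay for high resolution)
    abgs: list[AbgEvent] = []
    gap_spans: list[tuple[float, float]] = []
    for i, m in enumerate(abg_minutes):
        t_draw = m * 60.0
        sao2_meas = float(np.clip(sao2_min[m] + rng.normal(0.0, config.sao2_coox_sd),
                                  0.05, 1.0))
        nominal = t_draw
        if config.resolution_class == "high":
            nominal = t_draw + rng.uniform(*config.lab_delay_s)
            if rng.random() < config.pressure_gap_probability:
                gap_spans.append((t_draw - rng.uniform(*config.gap_duration_s), t_draw))
        abgs.append(AbgEvent(nominal_time=nominal, pao2=float(pao2_min[m]),
                             sao2=sao2_meas, paco2=float(paco2[m])))
    abgs.sort(key=lambda a: a.nominal_time)

    channels = {
        "spo2": spo2_series,
        "fio2": fio2_series,
        "ri_true": ChannelSeries("ri_true", minute_times, ri, units="dimensionless"),
    }
    if config.resolution_class == "high":
        sec_times = np.arange(duration_s)
        keep = np.ones(sec_times.size, dtype=bool)
        for g0, g1 in gap_spans:
            keep &= ~((sec_times > g0) & (sec_times < g1))
        channels["abp"] = ChannelSeries("abp", sec_times[keep],
                                        80.0 + rng.normal(0.0, 3.0, int(keep.sum())),
                                        units="mmHg")

    support = SupportInterval(
        start=0.0, end=duration_s, mode=config.support_mode,
        peep=config.support_peep if config.support_mode in
        (SupportMode.INVASIVE, SupportMode.NIV_CPAP) else None,
        flow=config.support_flow if config.support_mode is SupportMode.HFNO else None)

    return AdmissionRecord(admission_id=f"sim-{admission_index:04d}",
                           channels=channels, support=(support,), abgs=tuple(abgs),
                           resolution_class=config.resolution_class)


def simulate_cohort(config: CohortConfig) -> list[AdmissionRecord]:
    """Generate ``n_admissions`` mutually independent admissions."""
    return [simulate_admission(config, i) for i in range(config.n_admissions)]
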