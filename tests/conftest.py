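import numpy as np
import pytest

from sfpf.io import (AbgEvent, AdmissionRecord, ChannelSeries, Datapoint,
                     ExclusionReason, SupportInterval, SupportMode)
from sfpf.synthetic import CohortConfig, simulate_admission


@pytest.fixture(scope="session")
def minute_admission():
    """One 24 h minute-resolution simulated admission."""
    return simulate_admission(CohortConfig(duration_hours=24.0, seed=11), 0)


@pytest.fixture(scope="session")
def highres_admission():
    """One short high-resolution admission with a pressure channel,
    gaps guaranteed before every ABG draw."""
    cfg = CohortConfig(duration_hours=6.0, resolution_class="high",
                       pressure_gap_probability=1.0, seed=12)
    return simulate_admission(cfg, 0)


@pytest.fixture
def dp_factory():
    """Factory for hand-built datapoints (valid by default)."""

    def make(spo2=94.0, pao2=80.0, fio2=0.5, mode=SupportMode.INVASIVE,
             peep=8.0, flow=None, time=0.0, admission_id="a", sao2=None,
             paco2=40.0, valid=True):
        return Datapoint(
            admission_id=admission_id, time=time, pao2=pao2, spo2=spo2,
            fio2=fio2, sao2=sao2, paco2=paco2, mode=mode, peep=peep, flow=flow,
            valid=valid,
            exclusion_reason=ExclusionReason.NONE if valid
            else ExclusionReason.INCOMPLETE)

    return make


@pytest.fixture
def admission_factory():
    """Factory for small hand-built admissions."""

    def make(spo2=((0, 95), (60, 96), (120, 94)),
             fio2=((0, 0.5),),
             abgs=(300.0,),
             resolution_class="minute",
             pressure_times=None,
             support=None,
             admission_id="adm"):
        channels = {
            "spo2": ChannelSeries.from_samples(
                "spo2", [t for t, _ in spo2], [v for _, v in spo2], units="%"),
            "fio2": ChannelSeries.from_samples(
                "fio2", [t for t, _ in fio2], [v for _, v in fio2], units="fraction"),
        }
        if pressure_times is not None:
            pt = np.asarray(pressure_times, dtype=float)
            channels["abp"] = ChannelSeries("abp", pt, np.full(pt.size, 80.0),
                                            units="mmHg")
        if support is None:
            support = (SupportInterval(0.0, 1e7, SupportMode.INVASIVE, peep=8.0),)
        return AdmissionRecord(
            admission_id=admission_id, channels=channels, support=support,
            abgs=tuple(AbgEvent(nominal_time=float(t), pao2=80.0) for t in abgs),
            resolution_class=resolution_class)

    return make
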