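"""Trending: can the SF ratio track changes in the PF ratio?

Consecutive valid datapoints within an admission form pairs. A pair is
"respiratory-stable" when its time interval is at most 6 h and the
proportional change of the Respiratory Index is within +-20% -- the RI
is nearly FiO2-independent, so a stable RI isolates the effect of FiO2
titration from true gas-exchange change. On stable pairs where FiO2
changed, the correlations of proportional FiO2 change with proportional
PaO2 and SpO2 change quantify the treatment effect; on all pairs, the
transition confusion (down/same/up on each scale) and the detection
rate quantify how often SF reproduces a PF category change.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .classification import classify_datapoint
from .io import Datapoint
from .physiology import DEFAULT_CONSTANTS, PhysiologyConstants, respiratory_index

__all__ = [
    "DatapointPair",
    "TrendReport",
    "consecutive_pairs",
    "stability_gate",
    "change_correlations",
    "change_detection",
]

TRANSITIONS = ("down", "same", "up")


@dataclass
class DatapointPair:
    """Two consecutive valid datapoints of one admission."""

    admission_id: str
    first: Datapoint
    second: Datapoint
    dt: float
    d_fio2: float
    d_pao2: float
    d_spo2: float
    ri_first: Optional[float]
    ri_second: Optional[float]
    ri_change: Optional[float]  # proportional; None when RI unavailable
    pf_transition: str
    sf_transition: str
    stable: bool = False


def _transition(c1: int, c2: int) -> str:
    return "same" if c2 == c1 else ("up" if c2 > c1 else "down")


def consecutive_pairs(datapoints: Sequence[Datapoint],
                      constants: PhysiologyConstants = DEFAULT_CONSTANTS,
                      ) -> list[DatapointPair]:
    """Adjacent valid datapoint pairs, grouped per admission, time-ordered.

    Proportional change of x is (x2 - x1)/x1. The RI of a datapoint
    needs its PaCO2; pairs lacking it carry ri_change=None (they are
    excluded from gated analyses but still usable for change detection).
    Pairs with non-positive time interval are never formed.
    """
    by_adm: dict[str, list[Datapoint]] = {}
    for dp in datapoints:
        if dp.valid:
            by_adm.setdefault(dp.admission_id, []).append(dp)
    pairs: list[DatapointPair] = []
    for adm_id, dps in by_adm.items():
        dps = sorted(dps, key=lambda d: d.time)
        for a, b in zip(dps, dps[1:]):
            dt = b.time - a.time
            if dt <= 0:
                continue
            ri = []
            for dp in (a, b):
                ri.append(None if dp.paco2 is None else
                          respiratory_index(dp.pao2, dp.fio2, dp.paco2, constants))
            ri_change = None
            if ri[0] is not None and ri[1] is not None and ri[0] != 0:
                ri_change = (ri[1] - ri[0]) / ri[0]
            pf1, sf1 = classify_datapoint(a)
            pf2, sf2 = classify_datapoint(b)
            pairs.append(DatapointPair(
                admission_id=adm_id, first=a, second=b, dt=dt,
                d_fio2=(b.fio2 - a.fio2) / a.fio2,
                d_pao2=(b.pao2 - a.pao2) / a.pao2,
                d_spo2=(b.spo2 - a.spo2) / a.spo2,
                ri_first=ri[0], ri_second=ri[1], ri_change=ri_change,
                pf_transition=_transition(pf1.category, pf2.category),
                sf_transition=_transition(sf1.category, sf2.category)))
    return pairs


def stability_gate(pairs: Sequence[DatapointPair], max_dt: float = 6 * 3600.0,
                   ri_tolerance: float = 0.20, ri_floor: float = 0.05,
                   ) -> tuple[list[DatapointPair], dict[str, int]]:
    """Pairs under stable respiratory conditions, plus exclusion counts.

    Stable: time interval <= max_dt AND |proportional RI change| <=
    ri_tolerance. Pairs with missing PaCO2 (no RI) or with a first RI
    below ``ri_floor`` (where a proportional change is numerically
    meaningless) are excluded from the gated set and counted separately.
    Gating sets the pair's ``stable`` flag and never adds pairs.
    """
    gated: list[DatapointPair] = []
    counts = {"missing_paco2": 0, "ri_floor": 0, "dt": 0, "ri_change": 0}
    for p in pairs:
        if p.ri_change is None:
            counts["missing_paco2"] += 1
            continue
        if p.ri_first is None or p.ri_first < ri_floor:
            counts["ri_floor"] += 1
            continue
        if p.dt > max_dt:
            counts["dt"] += 1
            continue
        if abs(p.ri_change) > ri_tolerance:
            counts["ri_change"] += 1
            continue
        p.stable = True
        gated.append(p)
    return gated, counts


def change_correlations(stable_pairs: Sequence[DatapointPair],
                        require_fio2_change: bool = True,
                        ) -> tuple[Optional[float], Optional[float]]:
    """(corr(dFiO2, dPaO2), corr(dFiO2, dSpO2)) on proportional changes.

    Optionally restricted to pairs where FiO2 actually changed. Raises
    when fewer than two pairs remain; a correlation whose component has
    zero variance (e.g. SpO2 pinned by titration) is undefined and
    reported absent (None) rather than as a number.
    """
    from .agreement import pearson_r  # local import avoids a cycle at import time
    ps = [p for p in stable_pairs if not require_fio2_change or p.d_fio2 != 0]
    if len(ps) < 2:
        raise ValueError("need at least two pairs for change correlations")
    d_f = [p.d_fio2 for p in ps]
    out = []
    for other in ([p.d_pao2 for p in ps], [p.d_spo2 for p in ps]):
        try:
            out.append(pearson_r(d_f, other))
        except ValueError:
            out.append(None)
    return out[0], out[1]


def change_detection(pairs: Sequence[DatapointPair],
                     ) -> tuple[np.ndarray, Optional[float]]:
    """3x3 transition confusion (rows = PF, cols = SF) and detection rate.

    The detection rate is, among pairs whose PF category changed, the
    fraction whose SF transition matches the PF transition (same
    direction); absent when no PF changes occurred.
    """
    counts = np.zeros((3, 3), dtype=int)
    for p in pairs:
        counts[TRANSITIONS.index(p.pf_transition),
               TRANSITIONS.index(p.sf_transition)] += 1
    changed = counts[0].sum() + counts[2].sum()
    detected = counts[0, 0] + counts[2, 2]
    rate = detected / changed if changed else None
    return counts, rate


@dataclass
class TrendReport:
    """Machine-readable summary of the trending analysis."""

    n_pairs: int
    n_stable: int
    gate_exclusions: dict[str, int]
    corr_dfio2_dpao2: Optional[float]
    corr_dfio2_dspo2: Optional[float]
    n_correlation_pairs: int
    transition_matrix: np.ndarray
    detection_rate: Optional[float]

    @classmethod
    def from_pairs(cls, pairs: Sequence[DatapointPair], max_dt: float = 6 * 3600.0,
                   ri_tolerance: float = 0.20, ri_floor: float = 0.05,
                   require_fio2_change: bool = True) -> "TrendReport":
        stable, excl = stability_gate(pairs, max_dt, ri_tolerance, ri_floor)
        corr_pairs = [p for p in stable if not require_fio2_change or p.d_fio2 != 0]
        try:
            r_pao2, r_spo2 = change_correlations(stable, require_fio2_change)
        except ValueError:
            r_pao2 = r_spo2 = None
        matrix, rate = change_detection(pairs)
        return cls(n_pairs=len(pairs), n_stable=len(stable), gate_exclusions=excl,
                   corr_dfio2_dpao2=r_pao2, corr_dfio2_dspo2=r_spo2,
                   n_correlation_pairs=len(corr_pairs),
                   transition_matrix=matrix, detection_rate=rate)

    def to_dict(self) -> dict:
        return {
            "n_pairs": self.n_pairs,
            "n_stable": self.n_stable,
            "gate_exclusions": dict(self.gate_exclusions),
            "corr_dfio2_dpao2": self.corr_dfio2_dpao2,
            "corr_dfio2_dspo2": self.corr_dfio2_dspo2,
            "n_correlation_pairs": self.n_correlation_pairs,
            "transition_labels": list(TRANSITIONS),
            "transition_matrix": self.transition_matrix.tolist(),
            "detection_rate": self.detection_rate,
        }
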