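"""ARDS severity labeling from PF and SF ratios.

Thresholds follow the 2024 global definition of ARDS: on the PaO2/FiO2
(PF) scale severe <= 100 < moderate <= 200 < mild <= 300 < none, and on
the SpO2/FiO2 (SF) scale severe <= 148 < moderate <= 235 < mild <= 315
< none. Boundaries are inclusive on the more-severe side; ratio values
are never rounded before thresholding.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Sequence

from .io import Datapoint
from .physiology import pf_ratio, sf_ratio

__all__ = [
    "Severity",
    "SeverityLabel",
    "THRESHOLDS",
    "classify_ratio",
    "classify_datapoint",
    "admission_max_severity",
]


class Severity(enum.IntEnum):
    """Ordinal ARDS category: none < mild < moderate < severe."""

    NONE = 0
    MILD = 1
    MODERATE = 2
    SEVERE = 3


#: upper bounds (inclusive) of severe / moderate / mild per scale
THRESHOLDS: dict[str, tuple[float, float, float]] = {
    "PF": (100.0, 200.0, 300.0),
    "SF": (148.0, 235.0, 315.0),
}


@dataclass(frozen=True)
class SeverityLabel:
    category: Severity
    scale: str  # "PF" or "SF"
    ratio_value: float


def classify_ratio(value: float, scale: str) -> SeverityLabel:
    """Label one PF or SF ratio value."""
    if scale not in THRESHOLDS:
        raise ValueError(f"unknown scale {scale!r}")
    if not value > 0:
        raise ValueError("ratio value must be positive")
    severe, moderate, mild = THRESHOLDS[scale]
    if value <= severe:
        cat = Severity.SEVERE
    elif value <= moderate:
        cat = Severity.MODERATE
    elif value <= mild:
        cat = Severity.MILD
    else:
        cat = Severity.NONE
    return SeverityLabel(category=cat, scale=scale, ratio_value=float(value))


def classify_datapoint(dp: Datapoint) -> tuple[SeverityLabel, SeverityLabel]:
    """(PF label, SF label) for one valid datapoint, sharing its FiO2."""
    if not dp.valid:
        raise ValueError(f"refusing to classify invalid datapoint "
                         f"({dp.exclusion_reason.value}) at t={dp.time}")
    return (classify_ratio(pf_ratio(dp.pao2, dp.fio2), "PF"),
            classify_ratio(sf_ratio(dp.spo2, dp.fio2), "SF"))


def admission_max_severity(labels: Sequence) -> Severity:
    """Most severe sustained category of one admission.

    A category counts only when at least two consecutive classifications
    are equally or more severe, i.e. the result is the largest C such
    that some adjacent pair has both categories >= C -- equivalently the
    maximum over adjacent pairs of the pairwise minimum. A single-label
    sequence falls back to that label's category.

    Accepts :class:`SeverityLabel` objects or bare :class:`Severity` values.
    """
    cats = [l.category if isinstance(l, SeverityLabel) else Severity(l) for l in labels]
    if not cats:
        raise ValueError("admission_max_severity requires at least one label")
    if len(cats) == 1:
        return cats[0]
    return Severity(max(min(a, b) for a, b in zip(cats, cats[1:])))
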