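"""Oxygenation physiology.

The Severinghaus oxyhemoglobin dissociation curve (forward and exact
closed-form inverse), the alveolar gas equation, the alveolar-arterial
(A-a) oxygen gradient, the Respiratory Index, and the two severity
ratios PaO2/FiO2 (PF) and SpO2/FiO2 (SF).

The Severinghaus curve relates oxygen tension P (mmHg) to hemoglobin
saturation S as::

    S = 1 / (23400 * (P^3 + 150*P)^-1 + 1)

a sigmoid with P50 near 26.86 mmHg. pH, PaCO2 and temperature shifts are
not modeled; a scalar left/right-shift hook is provided but defaults to 1
and is outside the validated scope.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "PhysiologyConstants",
    "DEFAULT_CONSTANTS",
    "severinghaus_sao2",
    "severinghaus_pao2",
    "alveolar_po2",
    "aa_gradient",
    "respiratory_index",
    "pao2_given_ri",
    "pf_ratio",
    "sf_ratio",
]


@dataclass(frozen=True)
class PhysiologyConstants:
    """Alveolar-gas constants (sea-level standard values by default).

    barometric_pressure and water_vapor_pressure in mmHg; the respiratory
    quotient is dimensionless. All configurable because any fixed choice
    is an assumption about altitude and metabolism.
    """

    barometric_pressure: float = 760.0
    water_vapor_pressure: float = 47.0
    respiratory_quotient: float = 0.8

    def __post_init__(self) -> None:
        if min(self.barometric_pressure, self.water_vapor_pressure,
               self.respiratory_quotient) <= 0:
            raise ValueError("physiology constants must be strictly positive")
        if not self.water_vapor_pressure < self.barometric_pressure:
            raise ValueError("water vapor pressure must be below barometric pressure")


DEFAULT_CONSTANTS = PhysiologyConstants()

_SEV_A = 23400.0  # curve constant of the cubic form
_SEV_B = 150.0


def severinghaus_sao2(pao2, shift: float = 1.0):
    """Hemoglobin saturation fraction for an oxygen tension in mmHg.

    ``shift`` scales P before the cubic (left/right-shift hook; default 1).
    Accepts scalars or arrays; strictly increasing, bounded in (0, 1).
    """
    p = np.asarray(pao2, dtype=float)
    if np.any(p <= 0):
        raise ValueError("PaO2 must be positive")
    p = p * shift
    s = 1.0 / (_SEV_A / (p ** 3 + _SEV_B * p) + 1.0)
    return float(s) if np.ndim(pao2) == 0 else s


def severinghaus_pao2(sao2, shift: float = 1.0):
    """Exact inverse of :func:`severinghaus_sao2` (Cardano's formula).

    Inverting S = 1/(23400/(P^3+150P)+1) reduces to the depressed cubic
    P^3 + 150 P - K = 0 with K = 23400*S/(1-S), which has a single real
    root for K > 0.
    """
    s = np.asarray(sao2, dtype=float)
    if np.any(s <= 0) or np.any(s >= 1):
        raise ValueError("SaO2 must lie strictly inside (0, 1)")
    k = _SEV_A * s / (1.0 - s)
    d = np.sqrt(k * k / 4.0 + (_SEV_B / 3.0) ** 3)
    p = np.cbrt(k / 2.0 + d) + np.cbrt(k / 2.0 - d)
    p = p / shift
    return float(p) if np.ndim(sao2) == 0 else p


def alveolar_po2(fio2, paco2, constants: PhysiologyConstants = DEFAULT_CONSTANTS):
    """Ideal alveolar oxygen tension (mmHg).

    PAO2 = FiO2 * (Pb - PH2O) - PaCO2 / RQ. Raises when the combination
    is physically impossible (non-positive result).
    """
    f = np.asarray(fio2, dtype=float)
    c = np.asarray(paco2, dtype=float)
    if np.any(f <= 0) or np.any(f > 1):
        raise ValueError("FiO2 must lie in (0, 1]")
    if np.any(c < 0):
        raise ValueError("PaCO2 must be non-negative")
    pao2_alv = f * (constants.barometric_pressure - constants.water_vapor_pressure) \
        - c / constants.respiratory_quotient
    if np.any(pao2_alv <= 0):
        raise ValueError("alveolar PO2 non-positive: degenerate FiO2/PaCO2 combination")
    return float(pao2_alv) if np.ndim(fio2) == 0 and np.ndim(paco2) == 0 else pao2_alv


def aa_gradient(pao2, fio2, paco2, constants: PhysiologyConstants = DEFAULT_CONSTANTS):
    """Alveolar-arterial oxygen gradient PAO2 - PaO2 (mmHg)."""
    return alveolar_po2(fio2, paco2, constants) - np.asarray(pao2, dtype=float)


def respiratory_index(pao2, fio2, paco2,
                      constants: PhysiologyConstants = DEFAULT_CONSTANTS):
    """Respiratory Index: A-a gradient divided by PaO2.

    Less FiO2-dependent than the PF ratio, which is why it serves as the
    stability gate for trending analysis. May be slightly negative on
    noisy inputs (PaO2 measured above the computed PAO2); such values are
    retained, not clipped, and flagged downstream.
    """
    p = np.asarray(pao2, dtype=float)
    if np.any(p <= 0):
        raise ValueError("PaO2 must be positive")
    ri = (alveolar_po2(fio2, paco2, constants) - p) / p
    scalar = np.ndim(pao2) == 0 and np.ndim(fio2) == 0 and np.ndim(paco2) == 0
    return float(ri) if scalar else ri


def pao2_given_ri(ri, fio2, paco2, constants: PhysiologyConstants = DEFAULT_CONSTANTS):
    """Oxygen tension producing a given Respiratory Index: PAO2 / (1 + RI)."""
    r = np.asarray(ri, dtype=float)
    if np.any(r <= -1):
        raise ValueError("Respiratory Index must exceed -1")
    p = alveolar_po2(fio2, paco2, constants) / (1.0 + r)
    scalar = np.ndim(ri) == 0 and np.ndim(fio2) == 0 and np.ndim(paco2) == 0
    return float(p) if scalar else p


def _check_fio2(fio2) -> None:
    f = np.asarray(fio2, dtype=float)
    if np.any(f < 0.21 - 1e-9) or np.any(f > 1.0 + 1e-9):
        raise ValueError("FiO2 must lie in [0.21, 1.0]")


def pf_ratio(pao2, fio2):
    """PaO2/FiO2 ratio in mmHg (PaO2 in mmHg, FiO2 a fraction)."""
    _check_fio2(fio2)
    out = np.asarray(pao2, dtype=float) / np.asarray(fio2, dtype=float)
    return float(out) if np.ndim(pao2) == 0 and np.ndim(fio2) == 0 else out


def sf_ratio(spo2, fio2):
    """SpO2/FiO2 ratio (SpO2 in percent, FiO2 a fraction; dimensionless)."""
    _check_fio2(fio2)
    out = np.asarray(spo2, dtype=float) / np.asarray(fio2, dtype=float)
    return float(out) if np.ndim(spo2) == 0 and np.ndim(fio2) == 0 else out
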