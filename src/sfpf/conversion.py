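"""SF <-> PF imputation equations: registry, fitting, evaluation.

An imputation equation is linear or log-linear (natural log on both
ratios) with a stated direction. The bundled registry ships published
linear equations (Rice 2007: SF = 64 + 0.84*PF; Bilan 2015:
SF = 57 + 0.61*PF) plus a package-derived log-linear reference equation
fitted to Severinghaus-curve-exact SF/PF pairs with SpO2 <= 97% -- a
synthetic, noise-free anchor, labeled as such in its source field.

Fitting is ordinary least squares of PF on SF (raw or log scale);
evaluation reports R^2 and mean absolute error on the PF scale, with
log-linear predictions exponentiated first so the two forms are
comparable.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass
from importlib import resources
from typing import Sequence

import numpy as np
from scipy import stats

__all__ = [
    "ImputationEquation",
    "apply",
    "invert",
    "predict_pf",
    "fit_linear",
    "fit_loglinear",
    "evaluate",
    "builtin_registry",
    "load_registry",
    "write_registry",
]

FORMS = ("linear", "loglinear")
DIRECTIONS = ("sf_from_pf", "pf_from_sf")


@dataclass(frozen=True)
class ImputationEquation:
    """y = intercept + slope * x, on raw or natural-log ratios."""

    name: str
    form: str
    direction: str
    intercept: float
    slope: float
    source: str = ""

    def __post_init__(self) -> None:
        if self.form not in FORMS:
            raise ValueError(f"unknown form {self.form!r}")
        if self.direction not in DIRECTIONS:
            raise ValueError(f"unknown direction {self.direction!r}")
        if self.slope == 0:
            raise ValueError("slope must be nonzero")


def apply(eq: ImputationEquation, value: float):
    """Evaluate the equation in its own direction."""
    v = np.asarray(value, dtype=float)
    if np.any(v <= 0):
        raise ValueError("ratio values must be positive")
    if eq.form == "linear":
        out = eq.intercept + eq.slope * v
    else:
        out = np.exp(eq.intercept + eq.slope * np.log(v))
    return float(out) if np.ndim(value) == 0 else out


def invert(eq: ImputationEquation, value: float):
    """Evaluate the equation backwards (output ratio -> input ratio)."""
    v = np.asarray(value, dtype=float)
    if np.any(v <= 0):
        raise ValueError("ratio values must be positive")
    if eq.form == "linear":
        out = (v - eq.intercept) / eq.slope
    else:
        out = np.exp((np.log(v) - eq.intercept) / eq.slope)
    if np.any(np.asarray(out) <= 0):
        raise ValueError(f"equation {eq.name} not invertible at value {value}")
    return float(out) if np.ndim(value) == 0 else out


def predict_pf(eq: ImputationEquation, sf_values):
    """Predicted PF for observed SF, whichever direction the equation states."""
    return apply(eq, sf_values) if eq.direction == "pf_from_sf" \
        else invert(eq, sf_values)


def defined_mask(eq: ImputationEquation, sf_values) -> np.ndarray:
    """Where a PF prediction from SF is defined and positive.

    Linear sf_from_pf equations with positive slope cannot be inverted
    at SF values at or below their intercept; log-linear forms are
    defined for all positive SF.
    """
    sf = np.atleast_1d(np.asarray(sf_values, dtype=float))
    mask = sf > 0
    if eq.form == "linear" and eq.direction == "sf_from_pf":
        mask &= ((sf - eq.intercept) / eq.slope) > 0
    return mask


def fit_linear(sf_values: Sequence[float], pf_values: Sequence[float],
               name: str = "ols_linear") -> ImputationEquation:
    """OLS of PF on SF (direction pf_from_sf)."""
    sf = np.asarray(sf_values, dtype=float)
    pf = np.asarray(pf_values, dtype=float)
    if sf.size != pf.size or sf.size < 3:
        raise ValueError("need at least 3 paired observations")
    if np.std(sf) == 0:
        raise ValueError("degenerate design: SF has zero variance")
    fit = stats.linregress(sf, pf)
    return ImputationEquation(name=name, form="linear", direction="pf_from_sf",
                              intercept=float(fit.intercept), slope=float(fit.slope),
                              source="fitted")


def fit_loglinear(sf_values: Sequence[float], pf_values: Sequence[float],
                  name: str = "ols_loglinear") -> ImputationEquation:
    """OLS of ln PF on ln SF (direction pf_from_sf)."""
    sf = np.asarray(sf_values, dtype=float)
    pf = np.asarray(pf_values, dtype=float)
    if sf.size != pf.size or sf.size < 3:
        raise ValueError("need at least 3 paired observations")
    if np.any(sf <= 0) or np.any(pf <= 0):
        raise ValueError("log-linear fit requires positive ratios")
    lsf, lpf = np.log(sf), np.log(pf)
    if np.std(lsf) == 0:
        raise ValueError("degenerate design: ln SF has zero variance")
    fit = stats.linregress(lsf, lpf)
    return ImputationEquation(name=name, form="loglinear", direction="pf_from_sf",
                              intercept=float(fit.intercept), slope=float(fit.slope),
                              source="fitted")


def evaluate(eq: ImputationEquation, sf_values: Sequence[float],
             pf_values: Sequence[float]) -> tuple[float, float]:
    """(R^2, MAE) of the equation's PF predictions against observed PF."""
    sf = np.asarray(sf_values, dtype=float)
    pf = np.asarray(pf_values, dtype=float)
    if sf.size != pf.size or sf.size < 2:
        raise ValueError("need at least 2 paired observations")
    ss_tot = float(np.sum((pf - pf.mean()) ** 2))
    if ss_tot == 0:
        raise ValueError("zero total variance: R^2 undefined")
    pred = predict_pf(eq, sf)
    r2 = 1.0 - float(np.sum((pf - pred) ** 2)) / ss_tot
    mae = float(np.mean(np.abs(pf - pred)))
    return r2, mae


_REGISTRY_COLUMNS = ["name", "form", "direction", "intercept", "slope", "source"]


def _rows_to_registry(rows) -> list[ImputationEquation]:
    return [ImputationEquation(name=r["name"], form=r["form"],
                               direction=r["direction"],
                               intercept=float(r["intercept"]),
                               slope=float(r["slope"]),
                               source=r.get("source", ""))
            for r in rows]


def builtin_registry() -> list[ImputationEquation]:
    """The bundled imputation-equation registry."""
    ref = resources.files("sfpf").joinpath("data/imputation_registry.csv")
    with ref.open("r", encoding="utf-8") as fh:
        return _rows_to_registry(csv.DictReader(fh))


def load_registry(path) -> list[ImputationEquation]:
    """Read a user registry CSV (columns name, form, direction, intercept, slope, source)."""
    with open(path, "r", encoding="utf-8", newline="") as fh:
        reader = csv.DictReader(fh)
        missing = [c for c in _REGISTRY_COLUMNS[:5] if c not in (reader.fieldnames or [])]
        if missing:
            raise ValueError(f"{path}: registry missing column(s) {missing}")
        return _rows_to_registry(reader)


def write_registry(equations: Sequence[ImputationEquation], path) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        w = csv.DictWriter(fh, fieldnames=_REGISTRY_COLUMNS)
        w.writeheader()
        for eq in equations:
            w.writerow({"name": eq.name, "form": eq.form, "direction": eq.direction,
                        "intercept": eq.intercept, "slope": eq.slope,
                        "source": eq.source})
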