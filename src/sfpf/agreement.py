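"""Agreement between SF- and PF-based ARDS severity.

Confusion matrices (rows = PF reference, columns = SF test), overall
accuracy, per-category recall, misclassification direction (the SF scale
calling a more or less severe category than PF), FiO2-binned accuracy,
raw-ratio correlation, and the oximetry error analyses (bias/precision
of SpO2 against SaO2, the binned heteroscedastic bias profile with its
zero crossing, and RMS deviation from the Severinghaus curve).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .classification import Severity, SeverityLabel
from .physiology import severinghaus_sao2
from .synthetic import OximeterNoiseModel

__all__ = [
    "ConfusionMatrix",
    "AgreementReport",
    "confusion",
    "accuracy_and_recall",
    "direction_rates",
    "fio2_binned_accuracy",
    "pearson_r",
    "bias_precision",
    "binned_bias_profile",
    "curve_deviation",
    "recover_noise_model",
]

_CATEGORIES = tuple(Severity)  # none, mild, moderate, severe


def _cats(labels: Sequence) -> np.ndarray:
    return np.asarray([l.category if isinstance(l, SeverityLabel) else Severity(l)
                       for l in labels], dtype=int)


@dataclass
class ConfusionMatrix:
    """4x4 ordinal confusion grid; rows = reference (PF), columns = test (SF)."""

    labels: tuple[Severity, ...] = _CATEGORIES
    counts: np.ndarray = field(default_factory=lambda: np.zeros((4, 4), dtype=int))

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def to_dict(self) -> dict:
        return {"labels": [c.name.lower() for c in self.labels],
                "counts": self.counts.tolist()}


def confusion(ref_labels: Sequence, test_labels: Sequence) -> ConfusionMatrix:
    """Cell [i][j] counts pairs with reference category i and test category j."""
    r, t = _cats(ref_labels), _cats(test_labels)
    if r.size != t.size:
        raise ValueError("reference and test label sequences differ in length")
    counts = np.zeros((4, 4), dtype=int)
    np.add.at(counts, (r, t), 1)
    return ConfusionMatrix(counts=counts)


def accuracy_and_recall(matrix: ConfusionMatrix,
                        ) -> tuple[float, dict[Severity, Optional[float]]]:
    """Overall accuracy (trace/total) and per-category recall.

    Recall of a category with an empty reference row is reported as
    absent (None), never as zero.
    """
    total = matrix.total
    if total == 0:
        raise ValueError("empty confusion matrix: accuracy undefined")
    overall = float(np.trace(matrix.counts)) / total
    recall: dict[Severity, Optional[float]] = {}
    for i, cat in enumerate(matrix.labels):
        row = matrix.counts[i].sum()
        recall[cat] = float(matrix.counts[i, i] / row) if row else None
    return overall, recall


def direction_rates(matrix: ConfusionMatrix) -> tuple[float, float, Optional[float]]:
    """(over_rate, under_rate, over_share_among_misclassified).

    over: test (SF) category ordinally above reference (PF); under:
    below. Rates are fractions of the matrix total; the share is over /
    (over + under), absent when nothing is misclassified.
    """
    total = matrix.total
    if total == 0:
        raise ValueError("empty confusion matrix")
    over = int(np.triu(matrix.counts, k=1).sum())
    under = int(np.tril(matrix.counts, k=-1).sum())
    share = over / (over + under) if over + under else None
    return over / total, under / total, share


def fio2_bin_center(fio2_frac, bin_width: float = 5.0):
    """Center (percent) of the FiO2 bin: [c - w/2, c + w/2), c = multiples of w."""
    pct = 100.0 * np.asarray(fio2_frac, dtype=float)
    c = np.floor((pct + bin_width / 2.0) / bin_width) * bin_width
    return float(c) if np.ndim(fio2_frac) == 0 else c


def fio2_binned_accuracy(fio2_fracs: Sequence[float], ref_labels: Sequence,
                         test_labels: Sequence, bin_width: float = 5.0,
                         ) -> list[tuple[float, int, float]]:
    """Classification accuracy per FiO2 bin.

    Bins are centered at multiples of ``bin_width`` percent with
    half-open edges [center - w/2, center + w/2); empty bins are
    omitted. Returns (center_pct, n, accuracy) sorted by center.
    """
    f = np.asarray(fio2_fracs, dtype=float)
    r, t = _cats(ref_labels), _cats(test_labels)
    if not (f.size == r.size == t.size):
        raise ValueError("inputs differ in length")
    centers = fio2_bin_center(f, bin_width)
    out = []
    for c in np.unique(centers):
        m = centers == c
        out.append((float(c), int(m.sum()), float(np.mean(r[m] == t[m]))))
    return out


def pearson_r(x: Sequence[float], y: Sequence[float]) -> float:
    """Product-moment correlation; raises on n < 2 or zero variance."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 2:
        raise ValueError("pearson_r requires two equal-length vectors, n >= 2")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("pearson_r undefined for zero-variance input")
    return float(stats.pearsonr(x, y).statistic)


def bias_precision(spo2_pct: Sequence[float], sao2_pct: Sequence[float],
                   ) -> tuple[float, float]:
    """Mean (bias) and sample SD (precision) of SpO2 - SaO2, in percent."""
    d = np.asarray(spo2_pct, dtype=float) - np.asarray(sao2_pct, dtype=float)
    if d.size < 2:
        raise ValueError("bias_precision requires n >= 2 pairs")
    return float(np.mean(d)), float(np.std(d, ddof=1))


def binned_bias_profile(spo2_pct: Sequence[float], sao2_pct: Sequence[float],
                        bin_width: float = 1.0, min_n_crossing: int = 50,
                        ) -> tuple[list[tuple[float, int, float]], Optional[float]]:
    """Per-SpO2-bin mean bias plus a straight-line zero-crossing estimate.

    Bins of SpO2 (width 1 percentage point by default, centers at
    multiples of the width). The crossing is -intercept/slope of the
    least-squares line of bias on SpO2 over all pairs; absent when the
    slope is ~0 or fewer than ``min_n_crossing`` pairs are available.
    """
    spo2 = np.asarray(spo2_pct, dtype=float)
    bias = spo2 - np.asarray(sao2_pct, dtype=float)
    if spo2.size != bias.size or spo2.size == 0:
        raise ValueError("paired SpO2/SaO2 vectors required")
    centers = np.round(spo2 / bin_width) * bin_width
    profile = [(float(c), int((centers == c).sum()),
                float(bias[centers == c].mean()))
               for c in np.unique(centers)]
    crossing = None
    if spo2.size >= min_n_crossing and np.std(spo2) > 0:
        slope, intercept = np.polyfit(spo2, bias, 1)
        if abs(slope) > 1e-8:
            crossing = float(-intercept / slope)
    return profile, crossing


def curve_deviation(pao2: Sequence[float], saturation_fraction: Sequence[float],
                    ) -> float:
    """RMS deviation of saturations (fractions) from the Severinghaus curve."""
    p = np.asarray(pao2, dtype=float)
    s = np.asarray(saturation_fraction, dtype=float)
    if p.size != s.size or p.size == 0:
        raise ValueError("paired PaO2/saturation vectors required")
    return float(np.sqrt(np.mean((s - severinghaus_sao2(p)) ** 2)))


def recover_noise_model(spo2_pct: Sequence[float], sao2_pct: Sequence[float],
                        ) -> dict:
    """Estimate the oximeter error-model parameters from paired readings.

    bias_slope and sd come from the calibration regression of SpO2 on
    SaO2 (fitted slope minus one; residual standard deviation), which is
    unbiased because SaO2 is the reference measurement. The crossing is
    the zero of the bias-on-SpO2 line from :func:`binned_bias_profile`.
    """
    spo2 = np.asarray(spo2_pct, dtype=float)
    sao2 = np.asarray(sao2_pct, dtype=float)
    if spo2.size < 3:
        raise ValueError("need at least 3 pairs")
    fit = stats.linregress(sao2, spo2)
    resid = spo2 - (fit.intercept + fit.slope * sao2)
    _, crossing = binned_bias_profile(spo2, sao2)
    return {"bias_slope": float(fit.slope - 1.0),
            "sd": float(np.sqrt(np.sum(resid ** 2) / (resid.size - 2))),
            "bias_crossing": crossing}


@dataclass
class AgreementReport:
    """Datapoint- or admission-level SF-vs-PF agreement summary."""

    level: str  # "datapoint" or "admission"
    matrix: ConfusionMatrix
    overall_accuracy: float
    recall_per_category: dict[Severity, Optional[float]]
    over_rate: float
    under_rate: float
    over_share_misclassified: Optional[float]
    pearson_r_sf_pf: Optional[float] = None
    fio2_bins: Optional[list[tuple[float, int, float]]] = None

    @classmethod
    def from_labels(cls, level: str, ref_labels: Sequence, test_labels: Sequence,
                    pf_ratios: Optional[Sequence[float]] = None,
                    sf_ratios: Optional[Sequence[float]] = None,
                    fio2_fracs: Optional[Sequence[float]] = None,
                    ) -> "AgreementReport":
        m = confusion(ref_labels, test_labels)
        overall, recall = accuracy_and_recall(m)
        over, under, share = direction_rates(m)
        r = None
        if pf_ratios is not None and sf_ratios is not None:
            try:
                r = pearson_r(sf_ratios, pf_ratios)
            except ValueError:  # single datapoint or degenerate ratios
                r = None
        bins = None
        if fio2_fracs is not None:
            bins = fio2_binned_accuracy(fio2_fracs, ref_labels, test_labels)
        return cls(level=level, matrix=m, overall_accuracy=overall,
                   recall_per_category=recall, over_rate=over, under_rate=under,
                   over_share_misclassified=share, pearson_r_sf_pf=r,
                   fio2_bins=bins)

    def to_dict(self) -> dict:
        return {
            "level": self.level,
            "confusion": self.matrix.to_dict(),
            "n": self.matrix.total,
            "overall_accuracy": self.overall_accuracy,
            "recall_per_category": {c.name.lower(): v
                                    for c, v in self.recall_per_category.items()},
            "over_rate": self.over_rate,
            "under_rate": self.under_rate,
            "over_share_misclassified": self.over_share_misclassified,
            "pearson_r_sf_pf": self.pearson_r_sf_pf,
            "fio2_bins": None if self.fio2_bins is None else
                [{"center_pct": c, "n": n, "accuracy": a} for c, n, a in self.fio2_bins],
        }
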