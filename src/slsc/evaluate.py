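"""Threshold classification, ROC/AUC, optimal thresholds and Fleiss' kappa.

The clinical question is binary: is a hypoechoic mass fluid-filled (a
benign complicated cyst) or solid (possibly malignant)?  A mass is called
fluid when its gCNR meets or exceeds a threshold (fluid masses have low
spatial coherence, hence high mass/tissue contrast in SLSC images).
Sensitivity is the fraction of fluid masses called fluid, specificity the
fraction of solid masses called solid; mixed masses and simple cysts are
excluded from these statistics.  The ROC sweeps the threshold from 0 to 1
in steps of 0.01 and the AUC is obtained by trapezoidal integration.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from statsmodels.stats.inter_rater import fleiss_kappa as _sm_fleiss_kappa

__all__ = [
    "MassRecord",
    "ConfusionCounts",
    "ROCResult",
    "DEFAULT_THRESHOLD",
    "classify_mass",
    "confusion",
    "sensitivity",
    "specificity",
    "roc_curve",
    "optimal_threshold",
    "fleiss_kappa",
    "kappa_band",
]

#: pre-defined gCNR decision threshold for fluid/solid discrimination
DEFAULT_THRESHOLD = 0.73

ROC_THRESHOLDS = np.round(np.arange(101) / 100.0, 2)


@dataclass
class MassRecord:
    """Per-mass ground truth, gCNR values and classifications."""

    mass_id: str
    ground_truth: str  # fluid | solid | mixed | simple_cyst
    gcnr: dict[str, float] = field(default_factory=dict)  # pathway -> value
    predicted: dict[str, str] = field(default_factory=dict)  # pathway -> call
    reader_calls: dict[str, str] = field(default_factory=dict)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.ground_truth not in ("fluid", "solid", "mixed", "simple_cyst"):
            raise ValueError(f"unknown ground truth {self.ground_truth!r}")
        for pathway, v in self.gcnr.items():
            if not (0.0 <= v <= 1.0 or math.isnan(v)):
                raise ValueError(f"gCNR out of [0,1] for {pathway}: {v}")


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fn: int
    tn: int
    fp: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fn, self.tn, self.fp) < 0:
            raise ValueError("counts must be non-negative")


@dataclass
class ROCResult:
    """Sensitivity / 1-specificity over the 101-point threshold grid."""

    thresholds: np.ndarray
    sensitivity: np.ndarray
    one_minus_specificity: np.ndarray
    auc: float
    pathway: str = ""


def classify_mass(gcnr_value: float, threshold: float = DEFAULT_THRESHOLD) -> str:
    """``fluid`` iff gCNR >= threshold (ties count as fluid), else ``solid``."""
    if not (0.0 <= gcnr_value <= 1.0):
        raise ValueError(f"gCNR must lie in [0,1], got {gcnr_value}")
    return "fluid" if gcnr_value >= threshold else "solid"


def _binary_records(records: list[MassRecord]) -> list[MassRecord]:
    bad = [r.mass_id for r in records if r.ground_truth not in ("fluid", "solid")]
    if bad:
        raise ValueError(
            f"mixed/simple-cyst masses must be excluded before computing "
            f"confusion counts: {bad}"
        )
    return records


def confusion(records: list[MassRecord], pathway: str, threshold: float) -> ConfusionCounts:
    """Confusion counts of the gCNR threshold rule on fluid/solid records."""
    records = _binary_records(records)
    tp = fn = tn = fp = 0
    for r in records:
        call = classify_mass(r.gcnr[pathway], threshold)
        if r.ground_truth == "fluid":
            tp += call == "fluid"
            fn += call == "solid"
        else:
            tn += call == "solid"
            fp += call == "fluid"
    return ConfusionCounts(tp=tp, fn=fn, tn=tn, fp=fp)


def sensitivity(c: ConfusionCounts) -> float:
    """TP / (TP + FN); NaN with a warning when no fluid masses exist."""
    if c.tp + c.fn == 0:
        warnings.warn("sensitivity undefined: no fluid masses")
        return float("nan")
    return c.tp / (c.tp + c.fn)


def specificity(c: ConfusionCounts) -> float:
    """TN / (TN + FP); NaN with a warning when no solid masses exist."""
    if c.tn + c.fp == 0:
        warnings.warn("specificity undefined: no solid masses")
        return float("nan")
    return c.tn / (c.tn + c.fp)


def roc_curve(records: list[MassRecord], pathway: str) -> ROCResult:
    """ROC over thresholds 0.00..1.00 (step 0.01) with trapezoidal AUC.

    Points are sorted by 1-specificity (then sensitivity), deduplicated,
    and anchored at (0,0) and (1,1) before integration.
    """
    records = _binary_records(records)
    truths = [r.ground_truth for r in records]
    if "fluid" not in truths or "solid" not in truths:
        raise ValueError("ROC needs at least one fluid and one solid record")
    sens = np.empty(ROC_THRESHOLDS.size)
    fpr = np.empty(ROC_THRESHOLDS.size)
    for i, t in enumerate(ROC_THRESHOLDS):
        c = confusion(records, pathway, t)
        sens[i] = sensitivity(c)
        fpr[i] = 1.0 - specificity(c)
    pts = np.vstack([np.concatenate([[0.0], fpr, [1.0]]), np.concatenate([[0.0], sens, [1.0]])]).T
    pts = np.unique(pts, axis=0)  # sorts by (fpr, sens) and deduplicates
    auc = float(np.trapezoid(pts[:, 1], pts[:, 0]))
    return ROCResult(
        thresholds=ROC_THRESHOLDS.copy(),
        sensitivity=sens,
        one_minus_specificity=fpr,
        auc=auc,
        pathway=pathway,
    )


def optimal_threshold(roc: ROCResult) -> float:
    """Threshold whose ROC point is closest to the ideal corner (0, 1).

    Ties return the smallest threshold.
    """
    d2 = roc.one_minus_specificity**2 + (1.0 - roc.sensitivity) ** 2
    return float(roc.thresholds[int(np.argmin(d2))])


_KAPPA_BANDS = [
    (0.0, "poor"),
    (0.20, "slight"),
    (0.40, "fair"),
    (0.60, "moderate"),
    (0.80, "substantial"),
]


def kappa_band(kappa: float) -> str:
    """Agreement label: poor (<=0), slight, fair, moderate, substantial,
    almost perfect (>0.80)."""
    if math.isnan(kappa):
        return "undefined"
    for upper, label in _KAPPA_BANDS:
        if kappa <= upper:
            return label
    return "almost perfect"


def fleiss_kappa(table: np.ndarray) -> tuple[float, str]:
    """Fleiss' kappa of an items x categories count table, with its band.

    Every item must be rated by the same number of raters (constant row
    sum >= 2).  Returns ``(kappa, band)``; when expected chance agreement
    is 1 (all ratings in one category) kappa is undefined and NaN is
    returned with a warning.
    """
    table = np.asarray(table, dtype=float)
    if table.ndim != 2 or table.shape[0] < 2 or table.shape[1] < 2:
        raise ValueError("need an items x categories table with >=2 items and >=2 categories")
    rows = table.sum(axis=1)
    if not np.all(rows == rows[0]) or rows[0] < 2:
        raise ValueError("every item must have the same rater count (>= 2)")
    p_cat = table.sum(axis=0) / table.sum()
    pe = float((p_cat**2).sum())
    if pe >= 1.0:
        warnings.warn("all ratings fall in one category; kappa undefined")
        return float("nan"), "undefined"
    kappa = float(_sm_fleiss_kappa(table, method="fleiss"))
    return kappa, kappa_band(kappa)
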