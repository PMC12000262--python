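"""Diagnostic metrics: 3-class rates, benign/malignant merging, ROC, washout.

Implements every statistic the study design reports: the 3-class confusion
matrix with per-class correct rates and their class-size-weighted average;
binary sensitivity/specificity/accuracy after merging HCC and non-HCC
malignancies into "malignant" (merging leaves the benign row untouched, so
binary specificity is identically the benign per-class rate); observer-study
ROC analysis with the Youden-index cutoff; and hyper/iso/hypo washout scoring
of lesion-to-parenchyma intensity ratios per phase.

Reported percentages round half-up to one decimal, matching how the source
tables print.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
from sklearn.metrics import auc as _sk_auc
from sklearn.metrics import confusion_matrix as _sk_confusion
from sklearn.metrics import roc_curve as _sk_roc_curve

from .phantom import CLASS_LABELS, CaseRecord, disk_mask, pixel_to_linear

#: Phases at which a human scorer rates hyper/iso/hypo.
WASHOUT_PHASES = ("AF", "2m", "5m", "10m")

#: Phase columns of the washout count table (1/2/5/10 min).
TABLE_PHASES = ("1m", "2m", "5m", "10m")


def round_half_up(value: float, decimals: int = 1) -> float:
    """Round half away from zero at ``decimals`` places (printed style)."""
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(float(value))).quantize(q, rounding=ROUND_HALF_UP))


def percentage(count: int, total: int, decimals: int = 1) -> float:
    """A printed-style percentage cell, e.g. 11 of 78 -> 14.1."""
    if total <= 0:
        raise ValueError("total must be positive")
    return round_half_up(100.0 * count / total, decimals)


# ---------------------------------------------------------------------------
# confusion matrix and per-class rates
# ---------------------------------------------------------------------------

def confusion_matrix(truths, predictions) -> np.ndarray:
    """3x3 count matrix, rows = truth, cols = predicted, class order
    (benign, HCC, non-HCC-malignant)."""
    truths = list(truths)
    predictions = list(predictions)
    if len(truths) != len(predictions):
        raise ValueError("truths and predictions differ in length")
    bad = (set(truths) | set(predictions)) - set(CLASS_LABELS)
    if bad:
        raise ValueError(f"unknown labels: {sorted(bad)}")
    return _sk_confusion(truths, predictions, labels=list(CLASS_LABELS))


def per_class_rates(cm: np.ndarray) -> np.ndarray:
    """Percent correct per truth class (the Benign/HCC/Meta table rows)."""
    cm = np.asarray(cm)
    rows = cm.sum(axis=1)
    for i, n in enumerate(rows):
        if n == 0:
            raise ValueError(f"class {CLASS_LABELS[i]!r} has no cases")
    return 100.0 * np.diag(cm) / rows


def weighted_average_rate(rates, class_sizes, weighted: bool = True) -> float:
    """The table's "Average" row: class-size-weighted mean of the per-class
    rates (sizes 48/78/55 in the source cohort), rounded half-up to one
    decimal.  ``weighted=False`` gives the plain mean instead."""
    rates = np.asarray(rates, dtype=float)
    sizes = np.asarray(class_sizes, dtype=float)
    if rates.shape != sizes.shape:
        raise ValueError("rates and class_sizes must have matching shapes")
    if np.any(sizes <= 0):
        raise ValueError("class sizes must be positive")
    if weighted:
        value = float((rates * sizes).sum() / sizes.sum())
    else:
        value = float(rates.mean())
    return round_half_up(value, 1)


# ---------------------------------------------------------------------------
# benign/malignant merging
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MergedMetrics:
    sensitivity: float
    specificity: float
    accuracy: float
    weighted_average: float
    class_rates: tuple[float, float, float]


def binary_merge_metrics(cm: np.ndarray) -> MergedMetrics:
    """Merge HCC and non-HCC malignancies into "malignant" and score binary
    sensitivity/specificity/accuracy (percent, unrounded except the weighted
    average which is a printed-style cell).

    Cross-misclassification between the two malignant classes still counts
    as a correct binary call, so binary sensitivity is at least the
    size-weighted mean of the two malignant per-class rates.
    """
    cm = np.asarray(cm)
    if cm.shape != (3, 3) or np.any(cm < 0):
        raise ValueError("expected a non-negative 3x3 count matrix")
    sizes = cm.sum(axis=1)
    if np.any(sizes == 0):
        empty = CLASS_LABELS[int(np.argmin(sizes))]
        raise ValueError(f"class {empty!r} is empty")
    rates = per_class_rates(cm)
    n_mal = sizes[1] + sizes[2]
    tp = cm[1, 1:].sum() + cm[2, 1:].sum()
    tn = cm[0, 0]
    sensitivity = 100.0 * tp / n_mal
    specificity = 100.0 * tn / sizes[0]
    accuracy = 100.0 * (tp + tn) / sizes.sum()
    return MergedMetrics(
        sensitivity=float(sensitivity),
        specificity=float(specificity),
        accuracy=float(accuracy),
        weighted_average=weighted_average_rate(rates, sizes),
        class_rates=tuple(float(r) for r in rates),
    )


def accuracy_from_sens_spec(sens: float, spec: float, n_mal: int, n_ben: int) -> float:
    """Reconstruct binary accuracy from printed sensitivity/specificity and
    the class totals (e.g. 133 malignant / 49 benign in the observer study)."""
    if n_mal <= 0 or n_ben <= 0:
        raise ValueError("class totals must be positive")
    if not (0 <= sens <= 100 and 0 <= spec <= 100):
        raise ValueError("sensitivity/specificity must be percentages")
    tp = round_half_up(sens / 100.0 * n_mal, 0)
    tn = round_half_up(spec / 100.0 * n_ben, 0)
    return round_half_up(100.0 * (tp + tn) / (n_mal + n_ben), 1)


# ---------------------------------------------------------------------------
# observer-study ROC
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RatingRecord:
    """One observer rating in [0, 1] (0 = definitely benign) with its truth."""

    rating: float
    truth: str

    def __post_init__(self) -> None:
        if not 0.0 <= self.rating <= 1.0:
            raise ValueError("rating must lie in [0, 1]")
        if self.truth not in ("benign", "malignant"):
            raise ValueError("truth must be 'benign' or 'malignant'")


@dataclass(frozen=True)
class RocResult:
    cutoff: float
    sensitivity: float
    specificity: float
    auc: float


def roc_youden(records: list[RatingRecord]) -> RocResult:
    """Empirical ROC over all rating thresholds with the Youden-index cutoff.

    A case is called malignant when its rating is >= the cutoff.  The cutoff
    maximizes sensitivity + specificity - 1; ties break toward higher
    specificity.  AUC by the trapezoidal rule.
    """
    y = np.array([1 if r.truth == "malignant" else 0 for r in records])
    scores = np.array([r.rating for r in records])
    if y.min() == y.max():
        raise ValueError("both truth classes must be present")
    fpr, tpr, thresholds = _sk_roc_curve(y, scores, drop_intermediate=False)
    j = tpr - fpr
    # near-ties of J (within float noise) break toward higher specificity:
    # fpr is non-decreasing along the curve, so take the first near-maximal J
    i = int(np.flatnonzero(j >= j.max() - 1e-12)[0])
    cutoff = float(min(thresholds[i], scores.max()))  # sklearn pads with +inf
    return RocResult(cutoff=cutoff,
                     sensitivity=float(100.0 * tpr[i]),
                     specificity=float(100.0 * (1.0 - fpr[i])),
                     auc=float(_sk_auc(fpr, tpr)))


# ---------------------------------------------------------------------------
# washout scoring
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class WashoutScore:
    """Hyper/iso/hypo pattern per scored phase; washout = hypo."""

    patterns: dict[str, str]

    def washout(self, phase: str) -> bool:
        return self.patterns[phase] == "hypo"


def _phase_ratio(case: CaseRecord, phase: str) -> float:
    img = case.images["AF6"] if phase == "AF" else case.images[phase]
    geo = case.geometry
    lesion = disk_mask(geo.image_side, geo.lesion_center, geo.lesion_diameter, scale=0.8)
    background = ~disk_mask(geo.image_side, geo.lesion_center, geo.lesion_diameter, scale=1.3)
    linear = pixel_to_linear(img, case.noise)
    paren_mean = float(linear[background].mean())
    if paren_mean <= 0:
        raise ValueError("parenchyma mean intensity is zero")
    return float(linear[lesion].mean()) / paren_mean


def score_washout(case: CaseRecord, delta: float = 0.10,
                  phases: tuple[str, ...] = WASHOUT_PHASES) -> WashoutScore:
    """Score each phase hyper/iso/hypo from the rendered frames.

    The ratio r of mean lesion-disk to mean parenchyma intensity (in the
    linear domain, inverted from the log-compressed pixels) is scored hypo if
    r < 1 - delta, hyper if r > 1 + delta, else iso.  The AF phase is scored
    on the last AF frame.
    """
    patterns = {}
    for phase in phases:
        r = _phase_ratio(case, phase)
        patterns[phase] = "hypo" if r < 1 - delta else ("hyper" if r > 1 + delta else "iso")
    return WashoutScore(patterns=patterns)


def washout_table(cases: list[CaseRecord], delta: float = 0.10,
                  phases: tuple[str, ...] = TABLE_PHASES) -> pd.DataFrame:
    """Fraction of cases scored washed-out (hypo) per class per phase —
    the structure of the washout count table."""
    rows = {}
    for label in CLASS_LABELS:
        members = [c for c in cases if c.label == label]
        if not members:
            continue
        scores = [score_washout(c, delta=delta, phases=phases) for c in members]
        rows[label] = {ph: float(np.mean([s.washout(ph) for s in scores])) for ph in phases}
    return pd.DataFrame(rows).T[list(phases)]


# ---------------------------------------------------------------------------
# report writers
# ---------------------------------------------------------------------------

def metrics_column(truths, predictions, class_sizes=None) -> dict[str, float]:
    """One column of the diagnostic-performance table for a set of
    predictions: per-class rates, Average, Accuracy, Sensitivity,
    Specificity (printed-style rounding)."""
    cm = confusion_matrix(truths, predictions)
    rates = per_class_rates(cm)
    sizes = cm.sum(axis=1) if class_sizes is None else np.asarray(class_sizes)
    merged = binary_merge_metrics(cm)
    return {
        "Benign": round_half_up(rates[0]),
        "HCC": round_half_up(rates[1]),
        "Meta": round_half_up(rates[2]),
        "Average": weighted_average_rate(rates, sizes),
        "Accuracy": round_half_up(merged.accuracy),
        "Sensitivity": round_half_up(merged.sensitivity),
        "Specificity": round_half_up(merged.specificity),
    }


def write_metrics_table(columns: dict[str, dict[str, float]], path: str) -> pd.DataFrame:
    """Write a diagnostic-performance table (one column per time limit)."""
    table = pd.DataFrame(columns)
    table.index.name = "metric"
    table.to_csv(path)
    return table


def read_predictions(path: str) -> pd.DataFrame:
    """Read a ``case_id,truth,pred,prob0,prob1,prob2`` prediction file."""
    df = pd.read_csv(path)
    needed = {"case_id", "truth", "pred"}
    if not needed.issubset(df.columns):
        raise ValueError(f"prediction file must carry columns {sorted(needed)}")
    return df


def read_ratings(path: str) -> list[RatingRecord]:
    """Read a ``case_id,rating,truth`` observer-rating file."""
    df = pd.read_csv(path)
    return [RatingRecord(rating=float(r.rating), truth=str(r.truth))
            for r in df.itertuples()]
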