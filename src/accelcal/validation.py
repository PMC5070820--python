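"""Hold-out classification agreement between cut points and observation codes.

Applies a calibrated cut-point set to validation epochs, yielding a four-way
intensity label per epoch (sedentary / light / moderate / vigorous, light
being the residual band), and quantifies per-intensity agreement against the
binary observation criterion: sensitivity, specificity, total agreement,
Cohen's kappa with its large-sample standard error, and the customary kappa
interpretation labels (slight ... almost perfect).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from accelcal.calibration import (
    AXIS_COLUMNS,
    DEFAULT_SCHEME,
    BinaryCodingScheme,
    CutPointSet,
    binarize_categories,
)

logger = logging.getLogger(__name__)

FOURWAY_LABELS = ("sedentary", "light", "moderate", "vigorous")

#: Four-way labels counted as predicted-positive per intensity analysis.
#: The moderate analysis pairs predicted {moderate} with criterion {4, 5} by
#: default; the MVPA analysis pools predicted {moderate, vigorous}
#: (equivalently counts >= moderate_lower).
_PREDICTED_POSITIVE = {
    "sedentary": frozenset({"sedentary"}),
    "moderate": frozenset({"moderate"}),
    "vigorous": frozenset({"vigorous"}),
    "mvpa": frozenset({"moderate", "vigorous"}),
}


def classify_counts(counts, cutpoints: CutPointSet) -> np.ndarray:
    """Vectorized four-way intensity classification of 20-s counts."""
    c = np.asarray(counts)
    if c.size and c.min() < 0:
        raise ValueError("counts must be nonnegative")
    return np.select(
        [c <= cutpoints.sedentary_upper, c < cutpoints.moderate_lower, c < cutpoints.vigorous_lower],
        ["sedentary", "light", "moderate"],
        default="vigorous",
    )


def classify(counts_20s: int, cutpoints: CutPointSet) -> str:
    """Intensity label for one 20-s count value.

    Sedentary at or below the sedentary upper bound; vigorous at or above the
    vigorous lower bound; moderate between the moderate bounds inclusive;
    light in the residual interval.
    """
    return str(classify_counts(np.asarray([counts_20s]), cutpoints)[0])


@dataclass(frozen=True)
class ConfusionTable2x2:
    """Accelerometer-versus-criterion confusion counts for one intensity."""

    tp: int
    fn: int
    fp: int
    tn: int

    @property
    def total(self) -> int:
        return self.tp + self.fn + self.fp + self.tn


def binary_confusion(predicted, criterion_categories, intensity: str,
                     scheme: BinaryCodingScheme = DEFAULT_SCHEME,
                     moderate_includes_vigorous: bool = False) -> ConfusionTable2x2:
    """Tally the 2x2 table for one intensity.

    ``predicted`` holds four-way labels from :func:`classify_counts`;
    criterion positives come from the binary coding scheme.  With
    ``moderate_includes_vigorous`` the moderate analysis counts predicted
    vigorous epochs as positive (the alternative pairing; the default keeps
    predicted positives = {moderate} only).
    """
    pred = np.asarray(predicted)
    cats = np.asarray(criterion_categories)
    if pred.shape != cats.shape:
        raise ValueError("predicted and criterion sequences must have equal length")
    pos_labels = set(_PREDICTED_POSITIVE[intensity])
    if intensity == "moderate" and moderate_includes_vigorous:
        pos_labels = {"moderate", "vigorous"}
    pred_pos = np.isin(pred, sorted(pos_labels))
    crit_pos = binarize_categories(cats, intensity, scheme).astype(bool)
    return ConfusionTable2x2(
        tp=int(np.sum(pred_pos & crit_pos)),
        fn=int(np.sum(~pred_pos & crit_pos)),
        fp=int(np.sum(pred_pos & ~crit_pos)),
        tn=int(np.sum(~pred_pos & ~crit_pos)),
    )


@dataclass(frozen=True)
class AgreementStats:
    """Percentages from a 2x2 table; None marks an undefined (empty-margin) ratio."""

    sensitivity_pct: Optional[float]
    specificity_pct: Optional[float]
    total_agreement_pct: float


def agreement_stats(table: ConfusionTable2x2) -> AgreementStats:
    """Sensitivity, specificity and total agreement percentages.

    A ratio with an empty margin (no criterion positives, or no criterion
    negatives) is returned as None rather than a silent zero.
    """
    if table.total <= 0:
        raise ValueError("confusion table is empty")
    sens = 100.0 * table.tp / (table.tp + table.fn) if table.tp + table.fn > 0 else None
    spec = 100.0 * table.tn / (table.tn + table.fp) if table.tn + table.fp > 0 else None
    if sens is None or spec is None:
        logger.warning("agreement ratio undefined: empty criterion margin in %s", table)
    total = 100.0 * (table.tp + table.tn) / table.total
    return AgreementStats(sens, spec, total)


def cohen_kappa(table: ConfusionTable2x2) -> tuple[float, float]:
    """Cohen's kappa and its large-sample standard error for a 2x2 table.

    kappa = (po - pe) / (1 - pe) with po the observed and pe the chance
    agreement from the margins; the SE is the asymptotic (Fleiss-Cohen-
    Everitt) variance for a two-rater table.  Degenerate margins with
    pe = 1 raise.
    """
    n = table.total
    if n <= 0:
        raise ValueError("confusion table is empty")
    # rows: prediction (+, -); columns: criterion (+, -)
    p = np.array([[table.tp, table.fp], [table.fn, table.tn]], dtype=float) / n
    row = p.sum(axis=1)
    col = p.sum(axis=0)
    po = p[0, 0] + p[1, 1]
    pe = float(row @ col)
    if 1 - pe < 1e-12:
        raise ValueError("kappa undefined: chance agreement equals 1 (degenerate margins)")
    kappa = (po - pe) / (1 - pe)

    term1 = sum(
        p[i, i] * (1 - (row[i] + col[i]) * (1 - kappa)) ** 2 for i in range(2)
    )
    term2 = (1 - kappa) ** 2 * sum(
        p[i, j] * (col[i] + row[j]) ** 2 for i in range(2) for j in range(2) if i != j
    )
    term3 = (kappa - pe * (1 - kappa)) ** 2
    var = (term1 + term2 - term3) / (n * (1 - pe) ** 2)
    return float(kappa), float(np.sqrt(max(var, 0.0)))


def interpret_kappa(kappa: float) -> str:
    """Landis-Koch style agreement label for a kappa score."""
    if kappa > 1:
        raise ValueError(f"kappa cannot exceed 1, got {kappa}")
    if kappa < 0:
        return "less than chance"
    if kappa <= 0.20:
        return "slight"
    if kappa <= 0.40:
        return "fair"
    if kappa <= 0.60:
        return "moderate"
    if kappa <= 0.80:
        return "substantial"
    return "almost perfect"


@dataclass(frozen=True)
class AgreementResult:
    """Cross-validation agreement statistics for one intensity."""

    intensity: str
    sensitivity_pct: Optional[float]
    specificity_pct: Optional[float]
    total_agreement_pct: float
    kappa: Optional[float]
    kappa_se: Optional[float]
    kappa_label: str
    table: ConfusionTable2x2

    def to_dict(self) -> dict:
        return {
            "intensity": self.intensity,
            "sensitivity_pct": self.sensitivity_pct,
            "specificity_pct": self.specificity_pct,
            "total_agreement_pct": self.total_agreement_pct,
            "kappa": self.kappa,
            "kappa_se": self.kappa_se,
            "kappa_label": self.kappa_label,
            "tp": self.table.tp,
            "fn": self.table.fn,
            "fp": self.table.fp,
            "tn": self.table.tn,
        }


def _agreement_for(pred: np.ndarray, cats: np.ndarray, intensity: str,
                   scheme: BinaryCodingScheme,
                   moderate_includes_vigorous: bool) -> AgreementResult:
    table = binary_confusion(pred, cats, intensity, scheme, moderate_includes_vigorous)
    stats = agreement_stats(table)
    try:
        kappa, se = cohen_kappa(table)
        label = interpret_kappa(kappa)
    except ValueError:
        kappa, se, label = None, None, "undefined"
        logger.warning("kappa undefined for intensity %s (table %s)", intensity, table)
    return AgreementResult(
        intensity=intensity,
        sensitivity_pct=stats.sensitivity_pct,
        specificity_pct=stats.specificity_pct,
        total_agreement_pct=stats.total_agreement_pct,
        kappa=kappa,
        kappa_se=se,
        kappa_label=label,
        table=table,
    )


def cross_validate(aligned: pd.DataFrame, cutpoints: CutPointSet,
                   scheme: BinaryCodingScheme = DEFAULT_SCHEME,
                   moderate_includes_vigorous: bool = False) -> list[AgreementResult]:
    """Agreement statistics for sedentary, moderate, vigorous and MVPA.

    Epochs are pooled across participants (consistent with minute-total
    reporting).  The MVPA analysis counts epochs at or above the moderate
    lower boundary as predicted positive and criterion categories {4, 5} as
    positive.
    """
    if aligned.empty:
        raise ValueError("validation set is empty")
    counts = aligned[AXIS_COLUMNS[cutpoints.axis]].to_numpy(dtype=np.int64)
    cats = aligned["category"].to_numpy(dtype=np.int64)
    pred = classify_counts(counts, cutpoints)
    return [
        _agreement_for(pred, cats, intensity, scheme, moderate_includes_vigorous)
        for intensity in ("sedentary", "moderate", "vigorous", "mvpa")
    ]


def agreement_table(results: Sequence[AgreementResult], round_like_reports: bool = True) -> pd.DataFrame:
    """Tabulate agreement results (percentages to the integer, kappa to 2 dp).

    Full precision is retained on the :class:`AgreementResult` objects; the
    rounding here mirrors the conventional reporting format.
    """
    rows = []
    for r in results:
        d = r.to_dict()
        if round_like_reports:
            for key in ("sensitivity_pct", "specificity_pct", "total_agreement_pct"):
                if d[key] is not None:
                    d[key] = round(d[key])
            for key in ("kappa", "kappa_se"):
                if d[key] is not None:
                    d[key] = round(d[key], 2)
        rows.append(d)
    return pd.DataFrame(rows)
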