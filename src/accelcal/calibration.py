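"""ROC-curve calibration of activity-count intensity cut points.

Direct-observation calibration proceeds in three steps.  Observation
categories (1 = lying down ... 5 = very active) are collapsed to a binary
criterion for each intensity (sedentary positives {1, 2}; moderate/MVPA
positives {4, 5}; vigorous positives {5}).  An exhaustive ROC curve is then
swept over every distinct observed 20-s count value, computing sensitivity
and specificity from full confusion counts at each candidate threshold, and
the threshold maximizing Youden's index J = sensitivity + specificity - 1 is
selected.  Finally the three per-intensity thresholds are assembled into a
hierarchical cut-point set (sedentary / light / moderate / vigorous), with
the vigorous lower boundary minus one serving as the moderate upper boundary,
expressed both in counts per 20 s and counts per minute.

Sedentary behaviour produces *low* counts, so its ROC is swept with positives
classified at or below the threshold ("positive-low"); moderate, vigorous and
MVPA use "positive-high" (positives at or above the threshold).  The area
under the ROC curve is computed as the rank-sum probability that a randomly
chosen positive epoch lies on the positive side of a randomly chosen negative
epoch (ties counted 1/2), with a Hanley-McNeil standard error and a normal
95% confidence interval clipped to [0, 1].
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as _sps

from accelcal.ingest_align import counts20_to_cpm

logger = logging.getLogger(__name__)

INTENSITIES = ("sedentary", "moderate", "vigorous", "mvpa")

POSITIVE_LOW = "positive-low"
POSITIVE_HIGH = "positive-high"

#: Direction of positivity per intensity, inferred from the inequality signs
#: of the reported boundaries (sedentary <=, all others >=).
DIRECTIONS: Mapping[str, str] = {
    "sedentary": POSITIVE_LOW,
    "moderate": POSITIVE_HIGH,
    "vigorous": POSITIVE_HIGH,
    "mvpa": POSITIVE_HIGH,
}

AXIS_COLUMNS = {"vertical": "vertical_counts_20s", "vm": "vm_counts_20s"}


@dataclass(frozen=True)
class BinaryCodingScheme:
    """Observation categories coded positive for each intensity analysis.

    The complement of each positive set is negative; every category is
    assigned.  The MVPA coding is an alias of the moderate coding: a ROC with
    positives {4, 5} is mathematically the MVPA-versus-rest analysis, and the
    moderate lower boundary doubles as the MVPA boundary.
    """

    positive_sets: Mapping[str, frozenset] = field(
        default_factory=lambda: {
            "sedentary": frozenset({1, 2}),
            "moderate": frozenset({4, 5}),
            "vigorous": frozenset({5}),
            "mvpa": frozenset({4, 5}),
        }
    )

    def positives(self, intensity: str) -> frozenset:
        try:
            return self.positive_sets[intensity]
        except KeyError:
            raise ValueError(f"unknown intensity {intensity!r}") from None


DEFAULT_SCHEME = BinaryCodingScheme()


def binarize(category: int, intensity: str, scheme: BinaryCodingScheme = DEFAULT_SCHEME) -> int:
    """Map one observation category to the binary criterion for *intensity*."""
    if category not in (1, 2, 3, 4, 5):
        raise ValueError(f"category must be in 1..5, got {category}")
    return int(category in scheme.positives(intensity))


def binarize_categories(
    categories, intensity: str, scheme: BinaryCodingScheme = DEFAULT_SCHEME
) -> np.ndarray:
    """Vectorized :func:`binarize` over an array of categories."""
    cats = np.asarray(categories)
    if cats.size and (cats.min() < 1 or cats.max() > 5):
        raise ValueError("categories must be in 1..5")
    return np.isin(cats, list(scheme.positives(intensity))).astype(np.int64)


@dataclass(frozen=True)
class RocPoint:
    """One candidate threshold with its confusion-derived rates."""

    threshold: int
    sensitivity: float
    specificity: float

    @property
    def youden_j(self) -> float:
        return self.sensitivity + self.specificity - 1.0


def _check_two_class(labels: np.ndarray) -> None:
    if labels.size == 0 or labels.min() == labels.max():
        raise ValueError("both classes required: need at least one positive and one negative label")


def _check_counts(counts: np.ndarray) -> None:
    if counts.size and counts.min() < 0:
        raise ValueError("counts must be nonnegative")


def roc_points(counts, labels, direction: str) -> list[RocPoint]:
    """Exhaustive ROC sweep over every distinct observed count value.

    Candidate thresholds are the distinct observed counts plus the degenerate
    all-positive and all-negative endpoints.  For ``positive-low`` a count is
    classified positive when it is <= the threshold; for ``positive-high``
    when it is >= the threshold.
    """
    counts = np.asarray(counts, dtype=np.int64)
    labels = np.asarray(labels, dtype=np.int64)
    if counts.shape != labels.shape:
        raise ValueError("counts and labels must have equal length")
    _check_counts(counts)
    _check_two_class(labels)
    if direction not in (POSITIVE_LOW, POSITIVE_HIGH):
        raise ValueError(f"unknown direction {direction!r}")

    u = np.unique(counts)
    pos = np.sort(counts[labels == 1])
    neg = np.sort(counts[labels == 0])
    n_pos, n_neg = len(pos), len(neg)

    if direction == POSITIVE_LOW:
        # u[0] - 1 predicts nothing positive; u[-1] predicts everything positive.
        thresholds = np.concatenate(([u[0] - 1], u))
        tp = np.searchsorted(pos, thresholds, side="right")
        fp = np.searchsorted(neg, thresholds, side="right")
    else:
        # u[0] predicts everything positive; u[-1] + 1 predicts nothing.
        thresholds = np.concatenate((u, [u[-1] + 1]))
        tp = n_pos - np.searchsorted(pos, thresholds, side="left")
        fp = n_neg - np.searchsorted(neg, thresholds, side="left")

    sens = tp / n_pos
    spec = (n_neg - fp) / n_neg
    return [
        RocPoint(int(t), float(se), float(sp))
        for t, se, sp in zip(thresholds, sens, spec)
    ]


def youden_optimal(points: Sequence[RocPoint], direction: str) -> RocPoint:
    """Select the ROC point maximizing Youden's J.

    Ties in J are broken by higher sensitivity, then by higher threshold for
    ``positive-low`` sweeps and lower threshold for ``positive-high`` sweeps
    (both favour the more sensitive boundary); any tie-break applied is
    logged.
    """
    if not points:
        raise ValueError("nonempty ROC point list required")
    tol = 1e-12
    j = np.array([p.youden_j for p in points])
    j_tied = np.flatnonzero(j >= j.max() - tol)
    tied = j_tied
    if len(tied) > 1:
        sens = np.array([points[i].sensitivity for i in tied])
        tied = tied[sens >= sens.max() - tol]
    if len(tied) > 1:
        thr = np.array([points[i].threshold for i in tied])
        pick = tied[int(np.argmax(thr))] if direction == POSITIVE_LOW else tied[int(np.argmin(thr))]
    else:
        pick = int(tied[0])
    if len(j_tied) > 1:
        logger.info(
            "Youden tie at J=%.6f among thresholds %s; selected %d by sensitivity/%s rule",
            j.max(), [points[i].threshold for i in j_tied], points[pick].threshold, direction,
        )
    return points[int(pick)]


@dataclass(frozen=True)
class AucResult:
    auc: float
    se: float
    ci95: tuple


def auc(counts, labels, direction: str) -> AucResult:
    """Rank-sum AUC with Hanley-McNeil SE and a clipped normal 95% CI.

    The AUC is the probability that a random positive epoch scores on the
    positive side of a random negative epoch, ties counted one half.
    """
    counts = np.asarray(counts, dtype=np.int64)
    labels = np.asarray(labels, dtype=np.int64)
    _check_counts(counts)
    _check_two_class(labels)
    scores = -counts if direction == POSITIVE_LOW else counts
    pos_mask = labels == 1
    n_pos = int(pos_mask.sum())
    n_neg = int(len(labels) - n_pos)
    ranks = _sps.rankdata(scores)
    a = (ranks[pos_mask].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)
    q1 = a / (2 - a)
    q2 = 2 * a * a / (1 + a)
    var = (a * (1 - a) + (n_pos - 1) * (q1 - a * a) + (n_neg - 1) * (q2 - a * a)) / (n_pos * n_neg)
    se = float(np.sqrt(max(var, 0.0)))
    lo = max(0.0, a - 1.96 * se)
    hi = min(1.0, a + 1.96 * se)
    return AucResult(float(a), se, (float(lo), float(hi)))


def interpret_auc(value: float) -> str:
    """Discrimination label for an AUC: excellent / good / fair / poor."""
    if not 0.0 <= value <= 1.0:
        raise ValueError(f"AUC must be in [0, 1], got {value}")
    if value >= 0.90:
        return "excellent"
    if value >= 0.80:
        return "good"
    if value >= 0.70:
        return "fair"
    return "poor"


@dataclass(frozen=True)
class RocAnalysis:
    """Full ROC analysis for one intensity on one axis."""

    intensity: str
    axis: str
    direction: str
    points: tuple
    auc: float
    auc_se: float
    auc_ci95: tuple
    optimal: RocPoint
    optimal_cpm: int

    @property
    def auc_label(self) -> str:
        return interpret_auc(self.auc)

    def to_dict(self) -> dict:
        return {
            "intensity": self.intensity,
            "axis": self.axis,
            "direction": self.direction,
            "auc": self.auc,
            "auc_se": self.auc_se,
            "auc_ci95": list(self.auc_ci95),
            "auc_label": self.auc_label,
            "threshold_counts_20s": self.optimal.threshold,
            "threshold_cpm": self.optimal_cpm,
            "sensitivity": self.optimal.sensitivity,
            "specificity": self.optimal.specificity,
            "youden_j": self.optimal.youden_j,
        }

    def points_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "threshold": [p.threshold for p in self.points],
                "sensitivity": [p.sensitivity for p in self.points],
                "specificity": [p.specificity for p in self.points],
                "youden_j": [p.youden_j for p in self.points],
            }
        )


def analyze_intensity(counts, categories, intensity: str, axis: str,
                      scheme: BinaryCodingScheme = DEFAULT_SCHEME) -> RocAnalysis:
    """Run one complete ROC analysis (sweep, AUC, Youden selection)."""
    direction = DIRECTIONS[intensity]
    labels = binarize_categories(categories, intensity, scheme)
    pts = roc_points(counts, labels, direction)
    best = youden_optimal(pts, direction)
    a = auc(counts, labels, direction)
    return RocAnalysis(
        intensity=intensity,
        axis=axis,
        direction=direction,
        points=tuple(pts),
        auc=a.auc,
        auc_se=a.se,
        auc_ci95=a.ci95,
        optimal=best,
        optimal_cpm=int(counts20_to_cpm(best.threshold)),
    )


@dataclass
class CutPointSet:
    """Hierarchical sedentary/moderate/vigorous boundaries for one axis.

    Boundaries are stored in counts per 20 s; counts-per-minute values are the
    20-s boundaries times three, except the moderate upper bound in cpm which
    is defined as ``vigorous_lower_cpm - 1`` (the reporting convention used by
    field calibration tables, which differs from 3 x the 20-s moderate upper
    bound by two counts).  The light intensity band is the residual interval
    between the sedentary upper and moderate lower boundaries.  The MVPA
    boundary coincides with the moderate lower boundary.
    """

    axis: str
    sedentary_upper: int
    moderate_lower: int
    vigorous_lower: int
    roc: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self) -> None:
        if self.axis not in AXIS_COLUMNS:
            raise ValueError(f"axis must be one of {sorted(AXIS_COLUMNS)}, got {self.axis!r}")
        s, m, v = self.sedentary_upper, self.moderate_lower, self.vigorous_lower
        if not (s < m <= v - 1):
            raise ValueError(
                "non-monotone cut points: require sedentary_upper < moderate_lower "
                f"<= moderate_upper < vigorous_lower, got {s}, {m}, {v}"
            )

    @property
    def moderate_upper(self) -> int:
        return self.vigorous_lower - 1

    @property
    def mvpa_lower(self) -> int:
        return self.moderate_lower

    @property
    def sedentary_upper_cpm(self) -> int:
        return int(counts20_to_cpm(self.sedentary_upper))

    @property
    def moderate_lower_cpm(self) -> int:
        return int(counts20_to_cpm(self.moderate_lower))

    @property
    def vigorous_lower_cpm(self) -> int:
        return int(counts20_to_cpm(self.vigorous_lower))

    @property
    def moderate_upper_cpm(self) -> int:
        return self.vigorous_lower_cpm - 1

    @property
    def mvpa_lower_cpm(self) -> int:
        return self.moderate_lower_cpm

    def to_dict(self) -> dict:
        d = {
            "axis": self.axis,
            "counts_20s": {
                "sedentary_upper": self.sedentary_upper,
                "moderate_lower": self.moderate_lower,
                "moderate_upper": self.moderate_upper,
                "vigorous_lower": self.vigorous_lower,
            },
            "cpm": {
                "sedentary_upper": self.sedentary_upper_cpm,
                "moderate_lower": self.moderate_lower_cpm,
                "moderate_upper": self.moderate_upper_cpm,
                "vigorous_lower": self.vigorous_lower_cpm,
            },
        }
        if self.roc:
            d["roc"] = {name: ra.to_dict() for name, ra in self.roc.items()}
        return d

    def to_json(self, path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True) + "\n")
        return path

    @classmethod
    def from_dict(cls, d: dict) -> "CutPointSet":
        c = d["counts_20s"]
        return cls(
            axis=d["axis"],
            sedentary_upper=int(c["sedentary_upper"]),
            moderate_lower=int(c["moderate_lower"]),
            vigorous_lower=int(c["vigorous_lower"]),
        )

    @classmethod
    def from_json(cls, path) -> "CutPointSet":
        return cls.from_dict(json.loads(Path(path).read_text()))


def calibrate_axis(aligned: pd.DataFrame, axis: str,
                   scheme: BinaryCodingScheme = DEFAULT_SCHEME) -> CutPointSet:
    """Calibrate a full cut-point set for one axis from aligned 20-s epochs.

    Runs three ROC analyses -- sedentary (positive-low, positives {1, 2}),
    moderate (positive-high, positives {4, 5}; identical to the MVPA
    analysis) and vigorous (positive-high, positives {5}) -- and assembles
    the hierarchical :class:`CutPointSet`.  Raises when any intensity lacks
    both criterion classes or when the calibrated boundaries are not
    monotone.
    """
    if axis not in AXIS_COLUMNS:
        raise ValueError(f"axis must be one of {sorted(AXIS_COLUMNS)}, got {axis!r}")
    if aligned.empty:
        raise ValueError("calibration set is empty")
    counts = aligned[AXIS_COLUMNS[axis]].to_numpy(dtype=np.int64)
    categories = aligned["category"].to_numpy(dtype=np.int64)

    analyses = {}
    for intensity in ("sedentary", "moderate", "vigorous"):
        labels = binarize_categories(categories, intensity, scheme)
        if labels.min() == labels.max():
            raise ValueError(
                f"intensity {intensity!r} not represented on both sides of the "
                "binary criterion in the calibration data"
            )
        analyses[intensity] = analyze_intensity(counts, categories, intensity, axis, scheme)

    return CutPointSet(
        axis=axis,
        sedentary_upper=analyses["sedentary"].optimal.threshold,
        moderate_lower=analyses["moderate"].optimal.threshold,
        vigorous_lower=analyses["vigorous"].optimal.threshold,
        roc=analyses,
    )


def plot_roc(analysis: RocAnalysis, path) -> Path:
    """Write a basic ROC curve plot (requires matplotlib)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4.5, 4.5))
    sens = [p.sensitivity for p in analysis.points]
    fpr = [1 - p.specificity for p in analysis.points]
    order = np.argsort(fpr)
    ax.plot(np.asarray(fpr)[order], np.asarray(sens)[order], marker=".", lw=1)
    ax.plot([0, 1], [0, 1], ls="--", color="grey", lw=0.8)
    opt = analysis.optimal
    ax.scatter([1 - opt.specificity], [opt.sensitivity], color="crimson", zorder=3,
               label=f"threshold {opt.threshold} (J={opt.youden_j:.2f})")
    ax.set_xlabel("1 - specificity")
    ax.set_ylabel("sensitivity")
    ax.set_title(f"{analysis.axis} / {analysis.intensity} (AUC {analysis.auc:.2f})")
    ax.legend(loc="lower right", fontsize=8)
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path
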