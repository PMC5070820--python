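"""ROC sweep, AUC, Youden selection and cut-point assembly.

AUC and threshold selection are checked against brute-force oracles
(pairwise comparison over every positive-negative pair; exhaustive confusion
tallies at every candidate threshold) and against scikit-learn's
roc_auc_score as an external reference.
"""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.metrics import roc_auc_score

from accelcal.calibration import (
    DEFAULT_SCHEME,
    POSITIVE_HIGH,
    POSITIVE_LOW,
    CutPointSet,
    RocPoint,
    auc,
    binarize,
    calibrate_axis,
    interpret_auc,
    roc_points,
    youden_optimal,
)
from accelcal.ingest_align import align, screen, sum_to_20s
from accelcal.synthetic_data import simulate_study
from tests.conftest import make_aligned

# ---------------------------------------------------------------------------
# Brute-force oracles (independent of the implementation under test)
# ---------------------------------------------------------------------------


def brute_force_auc(counts, labels, direction):
    pos = counts[labels == 1]
    neg = counts[labels == 0]
    if direction == POSITIVE_LOW:
        wins = (pos[:, None] < neg[None, :]).sum()
    else:
        wins = (pos[:, None] > neg[None, :]).sum()
    ties = (pos[:, None] == neg[None, :]).sum()
    return (wins + 0.5 * ties) / (len(pos) * len(neg))


def brute_force_best(counts, labels, direction):
    """Exhaustive sweep: confusion tallies at every candidate threshold,
    max J, ties by higher sensitivity then the direction-dependent rule."""
    u = np.unique(counts)
    if direction == POSITIVE_LOW:
        candidates = np.concatenate(([u[0] - 1], u))
    else:
        candidates = np.concatenate((u, [u[-1] + 1]))
    best = None
    for t in candidates:
        pred = counts <= t if direction == POSITIVE_LOW else counts >= t
        tp = np.sum(pred & (labels == 1))
        tn = np.sum(~pred & (labels == 0))
        sens = tp / np.sum(labels == 1)
        spec = tn / np.sum(labels == 0)
        j = sens + spec - 1
        if best is None:
            best = (t, sens, spec, j)
            continue
        tol = 1e-12
        if j > best[3] + tol:
            best = (t, sens, spec, j)
        elif abs(j - best[3]) <= tol:
            if sens > best[1] + tol:
                best = (t, sens, spec, j)
            elif abs(sens - best[1]) <= tol:
                better = t > best[0] if direction == POSITIVE_LOW else t < best[0]
                if better:
                    best = (t, sens, spec, j)
    return best


def random_instance(rng, max_n=500):
    n = rng.integers(4, max_n + 1)
    counts = rng.integers(0, rng.integers(5, 80), size=n)
    labels = rng.integers(0, 2, size=n)
    if labels.min() == labels.max():
        labels[0] = 1 - labels[0]
    direction = POSITIVE_LOW if rng.random() < 0.5 else POSITIVE_HIGH
    return counts, labels, direction


# ---------------------------------------------------------------------------


class TestBinarize:
    @pytest.mark.parametrize(
        "category, intensity, expected",
        [
            (1, "sedentary", 1), (2, "sedentary", 1), (3, "sedentary", 0),
            (4, "sedentary", 0), (5, "sedentary", 0),
            (3, "moderate", 0), (4, "moderate", 1), (5, "moderate", 1),
            (4, "vigorous", 0), (5, "vigorous", 1),
            (3, "mvpa", 0), (4, "mvpa", 1), (5, "mvpa", 1),
        ],
    )
    def test_coding_scheme(self, category, intensity, expected):
        assert binarize(category, intensity) == expected

    def test_unknown_intensity_rejected(self):
        with pytest.raises(ValueError, match="unknown intensity"):
            binarize(3, "light")

    def test_category_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            binarize(6, "sedentary")


class TestRocPoints:
    def test_perfect_separation(self):
        pts = roc_points([100, 200, 900, 1000], [1, 1, 0, 0], POSITIVE_LOW)
        at_200 = next(p for p in pts if p.threshold == 200)
        assert at_200.sensitivity == 1.0
        assert at_200.specificity == 1.0
        assert at_200.youden_j == 1.0

    def test_overlapping_example_has_tied_optima(self):
        pts = roc_points([1, 2, 3, 4, 5, 6], [1, 1, 0, 1, 0, 0], POSITIVE_LOW)
        best_j = max(p.youden_j for p in pts)
        assert best_j == pytest.approx(2 / 3)
        tied = sorted(p.threshold for p in pts if p.youden_j == pytest.approx(2 / 3))
        assert tied == [2, 4]

    def test_all_positive_endpoint(self):
        for direction in (POSITIVE_LOW, POSITIVE_HIGH):
            pts = roc_points([3, 8, 8, 15], [0, 1, 0, 1], direction)
            assert any(p.sensitivity == 1.0 and p.specificity == 0.0 for p in pts)
            assert any(p.sensitivity == 0.0 and p.specificity == 1.0 for p in pts)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            roc_points([1, 2, 3], [1, 1, 1], POSITIVE_LOW)

    @given(st.data())
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_monotone_sweep(self, data):
        """Lowering a positive-low threshold can only lose sensitivity and
        gain specificity."""
        n = data.draw(st.integers(4, 60))
        counts = np.array(data.draw(st.lists(st.integers(0, 30), min_size=n, max_size=n)))
        labels = np.array(data.draw(st.lists(st.integers(0, 1), min_size=n, max_size=n)))
        if labels.min() == labels.max():
            labels[0] = 1 - labels[0]
        pts = roc_points(counts, labels, POSITIVE_LOW)  # ascending thresholds
        sens = [p.sensitivity for p in pts]
        spec = [p.specificity for p in pts]
        assert all(a <= b + 1e-12 for a, b in zip(sens, sens[1:]))
        assert all(a >= b - 1e-12 for a, b in zip(spec, spec[1:]))


class TestYoudenOptimal:
    def test_tie_broken_by_sensitivity(self):
        pts = roc_points([1, 2, 3, 4, 5, 6], [1, 1, 0, 1, 0, 0], POSITIVE_LOW)
        best = youden_optimal(pts, POSITIVE_LOW)
        assert best.threshold == 4
        assert best.sensitivity == 1.0

    def test_single_point(self):
        p = RocPoint(5, 0.4, 0.9)
        assert youden_optimal([p], POSITIVE_HIGH) is p

    def test_uninformative_labels_resolve_deterministically(self, caplog):
        counts = np.array([3, 3, 7, 7])
        labels = np.array([1, 0, 1, 0])
        pts = roc_points(counts, labels, POSITIVE_LOW)
        with caplog.at_level("INFO"):
            best = youden_optimal(pts, POSITIVE_LOW)
        assert best.threshold == 7  # all J = 0; max sensitivity, higher threshold
        assert "tie" in caplog.text

    @pytest.mark.parametrize("seed", range(30))
    def test_matches_exhaustive_sweep(self, seed):
        rng = np.random.default_rng(1000 + seed)
        counts, labels, direction = random_instance(rng, max_n=120)
        best = youden_optimal(roc_points(counts, labels, direction), direction)
        t, sens, spec, j = brute_force_best(counts, labels, direction)
        assert best.threshold == t
        assert best.sensitivity == pytest.approx(sens)
        assert best.specificity == pytest.approx(spec)


class TestAuc:
    def test_perfect_separation(self):
        assert auc([1, 2, 9, 10], [1, 1, 0, 0], POSITIVE_LOW).auc == 1.0

    def test_worked_example_eight_ninths(self):
        result = auc([1, 2, 3, 4, 5, 6], [1, 1, 0, 1, 0, 0], POSITIVE_LOW)
        assert result.auc == pytest.approx(8 / 9)

    def test_label_swap_symmetry(self):
        rng = np.random.default_rng(3)
        counts = rng.integers(0, 50, 40)
        labels = rng.integers(0, 2, 40)
        labels[:2] = [0, 1]
        a = auc(counts, labels, POSITIVE_HIGH).auc
        b = auc(counts, 1 - labels, POSITIVE_HIGH).auc
        assert a + b == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", range(30))
    def test_matches_bruteforce_pairwise_probability(self, seed):
        rng = np.random.default_rng(2000 + seed)
        counts, labels, direction = random_instance(rng, max_n=200)
        assert auc(counts, labels, direction).auc == pytest.approx(
            brute_force_auc(counts, labels, direction), abs=1e-12
        )

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_sklearn(self, seed):
        rng = np.random.default_rng(3000 + seed)
        counts, labels, _ = random_instance(rng, max_n=200)
        result = auc(counts, labels, POSITIVE_HIGH)
        assert result.auc == pytest.approx(roc_auc_score(labels, counts), abs=1e-12)

    @given(st.data())
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_invariant_under_strictly_increasing_transform(self, data):
        n = data.draw(st.integers(4, 80))
        counts = np.array(data.draw(st.lists(st.integers(0, 50), min_size=n, max_size=n)))
        labels = np.array(data.draw(st.lists(st.integers(0, 1), min_size=n, max_size=n)))
        if labels.min() == labels.max():
            labels[0] = 1 - labels[0]
        transformed = counts**2 + 3 * counts  # strictly increasing on nonneg ints
        a = auc(counts, labels, POSITIVE_HIGH).auc
        b = auc(transformed, labels, POSITIVE_HIGH).auc
        assert a == pytest.approx(b, abs=1e-12)

    def test_ci_contains_point_estimate_and_is_clipped(self):
        result = auc([1, 2, 9, 10], [1, 1, 0, 0], POSITIVE_LOW)
        lo, hi = result.ci95
        assert 0.0 <= lo <= result.auc <= hi <= 1.0


class TestInterpretAuc:
    @pytest.mark.parametrize(
        "value, label",
        [(0.94, "excellent"), (0.90, "excellent"), (0.87, "good"), (0.80, "good"),
         (0.79, "fair"), (0.70, "fair"), (0.69, "poor"), (0.50, "poor")],
    )
    def test_scale(self, value, label):
        assert interpret_auc(value) == label

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            interpret_auc(1.2)


class TestCutPointSet:
    def test_reported_boundary_arithmetic_vertical(self):
        cp = CutPointSet("vertical", 169, 336, 767)
        assert cp.moderate_upper == 766
        assert (cp.sedentary_upper_cpm, cp.moderate_lower_cpm) == (507, 1008)
        assert (cp.moderate_upper_cpm, cp.vigorous_lower_cpm) == (2300, 2301)
        assert cp.mvpa_lower_cpm == 1008

    def test_reported_boundary_arithmetic_vm(self):
        cp = CutPointSet("vm", 621, 870, 1405)
        assert cp.moderate_upper == 1404
        assert (cp.sedentary_upper_cpm, cp.moderate_lower_cpm) == (1863, 2610)
        assert (cp.moderate_upper_cpm, cp.vigorous_lower_cpm) == (4214, 4215)

    def test_non_monotone_rejected(self):
        with pytest.raises(ValueError, match="non-monotone"):
            CutPointSet("vertical", 400, 336, 767)
        with pytest.raises(ValueError, match="non-monotone"):
            CutPointSet("vertical", 100, 500, 500)

    def test_json_round_trip(self, tmp_path):
        cp = CutPointSet("vm", 621, 870, 1405)
        path = cp.to_json(tmp_path / "cp.json")
        assert CutPointSet.from_json(path) == cp


class TestCalibrateAxis:
    def test_disjoint_classes_recover_generating_gaps(self, separated_config):
        result = simulate_study(separated_config)
        aligned, _ = align(sum_to_20s(result.counts), result.sofit)
        retained, _ = screen(aligned)
        cp = calibrate_axis(retained, "vertical")
        # class 20-s sums cluster near 2x median: 10 / 60 / 300 / 800 / 2400
        assert 60 < cp.sedentary_upper < 300
        assert 300 < cp.moderate_lower <= 800
        assert 800 < cp.vigorous_lower <= 2400
        for analysis in cp.roc.values():
            assert analysis.optimal.youden_j == pytest.approx(1.0)
            assert analysis.auc == pytest.approx(1.0)

    def test_missing_intensity_rejected(self):
        aligned = make_aligned([10, 500, 900], [1, 3, 4])  # no category 5
        with pytest.raises(ValueError, match="vigorous"):
            calibrate_axis(aligned, "vertical")

    def test_unknown_axis_rejected(self):
        aligned = make_aligned([10, 500], [1, 5])
        with pytest.raises(ValueError, match="axis"):
            calibrate_axis(aligned, "axis7")

    def test_inverted_counts_flagged_as_non_monotone(self):
        # counts decrease with category: sedentary boundary above vigorous
        counts = [2000, 2100, 900, 300, 40, 35, 2050, 280]
        cats = [1, 1, 3, 4, 5, 5, 2, 4]
        with pytest.raises(ValueError, match="non-monotone"):
            calibrate_axis(make_aligned(counts, cats), "vertical")
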