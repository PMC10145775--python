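"""Evaluation machinery: margin-based change-point metrics, joint sample-scale
confusion matrix, subject-wise cross-validation folds and the degraded-window
robustness study of the gait criteria.

A predicted change point counts as a true positive when it can be paired
one-to-one with an annotated change point within a temporal margin
(default 3.5 s — the maximum accepted error, which must not exceed the
minimum spacing between true change points).  Precision is TP over the
number of predictions, recall TP over the number of true points.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .regimes import LABELS

logger = logging.getLogger(__name__)

DEFAULT_MARGIN_S = 3.5


@dataclass(frozen=True)
class SegmentationReport:
    tp: int
    K: int        # predicted change points
    K_star: int   # true change points
    precision: float
    recall: float
    f1: float
    margin_s: float = DEFAULT_MARGIN_S


def match_changepoints(true_s, pred_s, margin_s: float = DEFAULT_MARGIN_S) -> int:
    """One-to-one greedy matching by increasing |time difference|.

    Each true and each predicted point is used at most once; a pair only
    counts when |dt| <= margin.  With the margin below the minimum true
    inter-break spacing this coincides with optimal assignment.
    """
    true_s = np.asarray(sorted(true_s), dtype=float)
    pred_s = np.asarray(sorted(pred_s), dtype=float)
    if len(true_s) == 0 or len(pred_s) == 0:
        return 0
    pairs = [
        (abs(t - p), i, j)
        for i, t in enumerate(true_s)
        for j, p in enumerate(pred_s)
        if abs(t - p) <= margin_s
    ]
    pairs.sort()
    used_t, used_p = set(), set()
    tp = 0
    for _, i, j in pairs:
        if i in used_t or j in used_p:
            continue
        used_t.add(i)
        used_p.add(j)
        tp += 1
    return tp


def segmentation_report(true_s, pred_s, margin_s: float = DEFAULT_MARGIN_S) -> SegmentationReport:
    """Precision/recall/F1 of predicted change points at the given margin."""
    tp = match_changepoints(true_s, pred_s, margin_s)
    K, K_star = len(list(pred_s)), len(list(true_s))
    if K == 0 and K_star > 0:
        logger.info("empty prediction with %d true change points: precision set to 0", K_star)
    precision = tp / K if K else 0.0
    recall = tp / K_star if K_star else (1.0 if K == 0 else 0.0)
    f1 = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
    return SegmentationReport(tp=tp, K=K, K_star=K_star, precision=precision,
                              recall=recall, f1=f1, margin_s=margin_s)


@dataclass(frozen=True)
class ConfusionMatrix:
    """Row-normalized percentages over (walking, non_sedentary, sedentary)."""

    matrix: np.ndarray
    counts: np.ndarray
    labels: tuple = LABELS

    def diagonal(self) -> dict:
        return {lab: float(self.matrix[i, i]) for i, lab in enumerate(self.labels)}


def labels_to_samples(breakpoints_s, regime_labels, duration_s: float, fs: float) -> np.ndarray:
    """Per-sample label indices from regime spans (the original sample grid)."""
    n = int(round(duration_s * fs))
    bounds = [0.0, *[float(b) for b in breakpoints_s], duration_s]
    if len(regime_labels) != len(bounds) - 1:
        raise ValueError("need one label per regime")
    out = np.empty(n, dtype=np.int64)
    for lab, a, b in zip(regime_labels, bounds, bounds[1:]):
        if lab not in LABELS:
            raise ValueError(f"label {lab!r} outside the 3-class set")
        out[int(round(a * fs)) : int(round(b * fs))] = LABELS.index(lab)
    return out


def sample_confusion(true_labels, pred_labels) -> ConfusionMatrix:
    """Sample-scale confusion matrix: row i gives, among samples annotated as
    class i, the percentage classified as each class."""
    t = np.asarray(true_labels)
    p = np.asarray(pred_labels)
    if t.shape != p.shape:
        raise ValueError("label sequences must share the time support")
    if t.dtype.kind in "US":
        for arr in (t, p):
            bad = set(arr.tolist()) - set(LABELS)
            if bad:
                raise ValueError(f"labels outside the 3-class set: {bad}")
        t = np.array([LABELS.index(x) for x in t.tolist()])
        p = np.array([LABELS.index(x) for x in p.tolist()])
    counts = np.zeros((3, 3), dtype=np.int64)
    np.add.at(counts, (t, p), 1)
    row = counts.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        pct = np.where(row > 0, 100.0 * counts / row, 0.0)
    return ConfusionMatrix(matrix=pct, counts=counts)


def crossval_splits(subjects, n_folds: int = 3, seed: int = 0) -> list:
    """Subject-disjoint folds balanced on the healthy flag.

    ``subjects`` is a sequence with a boolean ``healthy`` attribute (or
    (id, healthy) pairs).  Returns a list of index lists, one per fold.
    """
    subjects = list(subjects)
    if len(subjects) < n_folds:
        raise ValueError("fewer subjects than folds")

    def is_healthy(s):
        return bool(s.healthy) if hasattr(s, "healthy") else bool(s[1])

    rng = np.random.default_rng(seed)
    healthy = [i for i, s in enumerate(subjects) if is_healthy(s)]
    patho = [i for i, s in enumerate(subjects) if not is_healthy(s)]
    rng.shuffle(healthy)
    rng.shuffle(patho)
    folds = [[] for _ in range(n_folds)]
    for k, i in enumerate(healthy + patho):
        folds[k % n_folds].append(i)
    return [sorted(f) for f in folds]


def degraded_ranges(span: tuple) -> list:
    """The 10 degraded feature-computation windows of one regime.

    Full regime; first 3 / 3.5 / 4 / 5 s; first 40%; three 40% windows
    starting at 20/30/40% of the duration; last 40%.  Absolute prefixes are
    clipped (with a warning) on regimes shorter than 5 s.
    """
    a, b = float(span[0]), float(span[1])
    dur = b - a
    if dur <= 0:
        raise ValueError("empty regime span")
    if dur < 5.0:
        logger.warning("regime of %.2f s: absolute-prefix windows clipped", dur)
    out = [(a, b)]
    for pre in (3.0, 3.5, 4.0, 5.0):
        out.append((a, min(a + pre, b)))
    out.append((a, a + 0.4 * dur))
    for start in (0.2, 0.3, 0.4):
        out.append((a + start * dur, a + (start + 0.4) * dur))
    out.append((b - 0.4 * dur, b))
    return out


@dataclass
class RobustnessEntry:
    span: tuple
    values: dict    # criterion -> list of 10 values over the configurations
    median: dict
    iqr: dict


@dataclass
class RobustnessReport:
    entries: list
    healthy_mean: dict = field(default_factory=dict)
    healthy_p25: dict = field(default_factory=dict)
    healthy_p75: dict = field(default_factory=dict)


def robustness_report(walking_regimes, criteria_fn, healthy_values: dict | None = None) -> RobustnessReport:
    """Recompute each criterion over the 10 degraded windows of each regime.

    ``criteria_fn(recording, start_s, end_s) -> dict`` evaluates the four
    criteria on a sub-span of the (filtered) recording.  ``healthy_values``
    optionally maps criterion -> array of healthy reference values from
    which the cohort overlays (mean, 25th/75th percentiles) are drawn.
    """
    entries = []
    for reg in walking_regimes:
        rec = reg.samples
        vals: dict = {}
        for w0, w1 in degraded_ranges((0.0, rec.duration_s)):
            crit = criteria_fn(rec, w0, w1)
            for k, v in crit.items():
                vals.setdefault(k, []).append(float(v))
        median = {k: float(np.median(v)) for k, v in vals.items()}
        iqr = {
            k: float(np.percentile(v, 75) - np.percentile(v, 25)) for k, v in vals.items()
        }
        entries.append(RobustnessEntry(span=reg.span, values=vals, median=median, iqr=iqr))
    report = RobustnessReport(entries=entries)
    if healthy_values:
        for k, arr in healthy_values.items():
            arr = np.asarray(arr, dtype=float)
            report.healthy_mean[k] = float(arr.mean())
            report.healthy_p25[k] = float(np.percentile(arr, 25))
            report.healthy_p75[k] = float(np.percentile(arr, 75))
    return report


__all__ = [
    "DEFAULT_MARGIN_S",
    "SegmentationReport",
    "ConfusionMatrix",
    "RobustnessEntry",
    "RobustnessReport",
    "match_changepoints",
    "segmentation_report",
    "labels_to_samples",
    "sample_confusion",
    "crossval_splits",
    "degraded_ranges",
    "robustness_report",
]
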