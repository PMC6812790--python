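"""Event-based scoring: bipartite matching, PR curves, recall diagnostics.

A detected timestamp counts as a true positive if it can be paired with a
reference timestamp within a 500 ms tolerance; pairing is a maximum-
cardinality bipartite matching so each reference matches at most one
estimate and vice versa. Sweeping the peak-picking threshold yields a
precision-recall curve and its area (AUPRC).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import maximum_bipartite_matching

from .detector import EventDetectionFunction, EventList, pick_peaks

#: Matching tolerance between reference and estimated timestamps, seconds.
TOLERANCE_S = 0.5


@dataclass
class MatchResult:
    tp: int
    fp: int
    fn: int
    pairs: list                      # (ref index, est index)

    @property
    def precision(self) -> float:
        return self.tp / (self.tp + self.fp) if self.tp + self.fp else 1.0

    @property
    def recall(self) -> float:
        return self.tp / (self.tp + self.fn) if self.tp + self.fn else 0.0

    @property
    def f1(self) -> float:
        p, r = self.precision, self.recall
        return 2 * p * r / (p + r) if p + r else 0.0


@dataclass
class PRCurve:
    thresholds: np.ndarray
    precision: np.ndarray
    recall: np.ndarray
    auprc: float

    def best_f1(self) -> tuple[float, float]:
        """(threshold, F1) of the operating point with maximal F1."""
        with np.errstate(invalid="ignore", divide="ignore"):
            f1 = 2 * self.precision * self.recall / (self.precision + self.recall)
        f1 = np.nan_to_num(f1)
        i = int(np.argmax(f1))
        return float(self.thresholds[i]), float(f1[i])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"threshold": self.thresholds,
                             "precision": self.precision,
                             "recall": self.recall})


def match_events(ref: EventList, est: EventList,
                 tolerance: float = TOLERANCE_S) -> MatchResult:
    """Maximum bipartite matching of reference and estimated timestamps.

    Edges connect pairs within ``tolerance`` seconds. TP is the matching
    cardinality; FP = |est| - TP; FN = |ref| - TP. Any maximum matching
    yields the same counts.
    """
    if tolerance < 0:
        raise ValueError("tolerance must be nonnegative")
    tr, te = ref.timestamps, est.timestamps
    n_ref, n_est = len(tr), len(te)
    if n_ref == 0 or n_est == 0:
        return MatchResult(0, n_est, n_ref, [])
    adj = np.abs(tr[:, None] - te[None, :]) <= tolerance
    match = maximum_bipartite_matching(csr_matrix(adj), perm_type="column")
    pairs = [(i, int(match[i])) for i in range(n_ref) if match[i] >= 0]
    tp = len(pairs)
    return MatchResult(tp, n_est - tp, n_ref - tp, pairs)


def pr_curve(edf: EventDetectionFunction, ref: EventList,
             thresholds: np.ndarray | None = None,
             min_spacing: float = 0.150,
             tolerance: float = TOLERANCE_S) -> PRCurve:
    """Precision-recall curve over a peak-picking threshold sweep.

    Per threshold: pick peaks, match against the reference, report
    P = TP/(TP+FP) (1.0 when nothing is detected) and R = TP/(TP+FN).
    AUPRC is the trapezoidal integral over the recall axis after sorting by
    recall, with the curve extended to recall 0 holding the precision of the
    lowest-recall operating point.
    """
    if len(ref) == 0:
        raise ValueError("undefined recall: empty reference list")
    if thresholds is None:
        thresholds = np.linspace(0.005, 0.995, 100)
    thresholds = np.asarray(thresholds, dtype=np.float64)
    if np.any((thresholds <= 0) | (thresholds >= 1)):
        raise ValueError("thresholds must lie in (0, 1)")
    precision = np.empty_like(thresholds)
    recall = np.empty_like(thresholds)
    for i, tau in enumerate(thresholds):
        est = pick_peaks(edf, tau, min_spacing)
        m = match_events(ref, est, tolerance)
        precision[i], recall[i] = m.precision, m.recall
    return PRCurve(thresholds, precision, recall,
                   auprc=_auprc(precision, recall))


def _auprc(precision: np.ndarray, recall: np.ndarray) -> float:
    order = np.argsort(recall, kind="stable")
    r = np.concatenate(([0.0], recall[order]))
    p = np.concatenate(([precision[order[0]]], precision[order]))
    return float(np.trapezoid(p, r))


def segmented_recall(ref: EventList, est: EventList, duration: float,
                     segment: float = 1800.0, band_split: float = 5000.0,
                     tolerance: float = TOLERANCE_S) -> pd.DataFrame:
    """Recall per (temporal segment, frequency band), from one global match.

    Reference events must carry band labels ("low"/"high" relative to
    ``band_split``). Returns a tidy frame with columns
    (segment_start, band, n_ref, n_matched, recall); recall is NaN for
    empty cells.
    """
    if ref.band_labels is None:
        raise ValueError("reference events must carry band labels")
    m = match_events(ref, est, tolerance)
    matched_ref = np.zeros(len(ref), dtype=bool)
    for i, _ in m.pairs:
        matched_ref[i] = True
    n_seg = max(int(np.ceil(duration / segment)), 1)
    seg_idx = np.minimum((ref.timestamps // segment).astype(int), n_seg - 1)
    rows = []
    for s in range(n_seg):
        for band in ("low", "high"):
            sel = (seg_idx == s) & np.array([b == band for b in ref.band_labels])
            n_ref = int(sel.sum())
            n_match = int(matched_ref[sel].sum())
            rows.append({"segment_start": s * segment, "band": band,
                         "n_ref": n_ref, "n_matched": n_match,
                         "recall": n_match / n_ref if n_ref else np.nan})
    return pd.DataFrame(rows)


def fold_summary(per_sensor_recall: dict) -> dict:
    """Median and interquartile range of a per-sensor metric."""
    vals = np.array(list(per_sensor_recall.values()), dtype=np.float64)
    q1, med, q3 = np.percentile(vals, [25, 50, 75])
    return {"median": float(med), "iqr": float(q3 - q1)}
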