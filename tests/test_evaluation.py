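"""Event matching, PR curves and segmented recall, with brute-force oracles."""

import itertools

import numpy as np
import pytest

from flightcall.detector import EventDetectionFunction, EventList
from flightcall.evaluation import (_auprc, match_events, pr_curve,
                                   segmented_recall)


def brute_force_max_matching(ref, est, tol):
    """Exhaustive maximum-cardinality matching over all pairings."""
    edges = [(i, j) for i in range(len(ref)) for j in range(len(est))
             if abs(ref[i] - est[j]) <= tol]
    best = 0
    for r in range(len(edges), 0, -1):
        for subset in itertools.combinations(edges, r):
            ri = [e[0] for e in subset]
            ei = [e[1] for e in subset]
            if len(set(ri)) == r and len(set(ei)) == r:
                return r
    return best


class TestMatchEvents:
    def test_exact_hit(self):
        m = match_events(EventList([1.0]), EventList([1.0]))
        assert (m.tp, m.fp, m.fn) == (1, 0, 0)

    def test_partial_match_within_tolerance(self):
        m = match_events(EventList([1.0, 2.0]), EventList([1.4, 2.6]))
        assert (m.tp, m.fp, m.fn) == (1, 1, 1)

    def test_chain_case_single_estimate(self):
        m = match_events(EventList([0.0, 0.4]), EventList([0.3]))
        assert (m.tp, m.fn) == (1, 1)

    def test_negative_tolerance_rejected(self):
        with pytest.raises(ValueError):
            match_events(EventList([1.0]), EventList([1.0]), tolerance=-1.0)

    @pytest.mark.parametrize("seed", range(25))
    def test_cardinality_equals_exhaustive_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        ref = np.sort(rng.uniform(0, 5, size=rng.integers(0, 9)))
        est = np.sort(rng.uniform(0, 5, size=rng.integers(0, 9)))
        m = match_events(EventList(ref), EventList(est))
        assert m.tp == brute_force_max_matching(ref, est, 0.5)
        assert m.fp == len(est) - m.tp
        assert m.fn == len(ref) - m.tp

    @pytest.mark.parametrize("seed", range(10))
    def test_swap_symmetry(self, seed):
        rng = np.random.default_rng(100 + seed)
        a = EventList(np.sort(rng.uniform(0, 5, size=6)))
        b = EventList(np.sort(rng.uniform(0, 5, size=4)))
        m1 = match_events(a, b)
        m2 = match_events(b, a)
        assert m1.tp == m2.tp
        assert (m1.fp, m1.fn) == (m2.fn, m2.fp)

    def test_each_index_used_at_most_once(self, rng):
        ref = EventList(np.sort(rng.uniform(0, 3, size=8)))
        est = EventList(np.sort(rng.uniform(0, 3, size=8)))
        m = match_events(ref, est)
        ri = [p[0] for p in m.pairs]
        ei = [p[1] for p in m.pairs]
        assert len(set(ri)) == len(ri) and len(set(ei)) == len(ei)
        for i, j in m.pairs:
            assert abs(ref.timestamps[i] - est.timestamps[j]) <= 0.5


def _ideal_edf(ref_times, duration, value=0.99):
    n = int((duration - 0.150) / 0.050) + 1
    y = np.full(n, 0.01)
    idx = np.round((np.asarray(ref_times) - 0.075) / 0.050).astype(int)
    y[np.clip(idx, 1, n - 2)] = value
    return EventDetectionFunction(y)


class TestPrCurve:
    def test_ideal_detector_has_unit_auprc(self):
        ref = EventList([1.0, 3.0, 5.0, 7.0])
        curve = pr_curve(_ideal_edf(ref.timestamps, 10.0), ref)
        assert curve.auprc == pytest.approx(1.0)
        assert np.all(curve.precision >= 0) and np.all(curve.recall <= 1)

    def test_all_false_peaks_zero_auprc(self):
        ref = EventList([8.0])
        edf = _ideal_edf([1.0, 3.0], 10.0)
        curve = pr_curve(edf, ref)
        assert curve.auprc == pytest.approx(0.0)
        assert np.all(curve.precision[curve.recall == 0] <= 1.0)

    def test_empty_reference_rejected(self):
        with pytest.raises(ValueError, match="undefined recall"):
            pr_curve(_ideal_edf([1.0], 5.0), EventList(np.empty(0)))

    def test_detection_counts_monotone_in_threshold(self, rng):
        y = rng.uniform(size=400)
        edf = EventDetectionFunction(y)
        ref = EventList(np.sort(rng.uniform(0, 20, size=20)))
        curve = pr_curve(edf, ref)
        tp_fn = curve.recall * len(ref)              # TP per threshold
        assert np.all(np.diff(tp_fn) <= 1e-9)

    def test_auprc_matches_independent_recomputation(self, rng):
        # randomized small case: recompute AUPRC from the TP/FP/FN table
        # with an independent trapezoid implementation
        from flightcall.detector import pick_peaks
        from flightcall.evaluation import match_events as me
        y = rng.uniform(size=500)
        edf = EventDetectionFunction(y)
        ref = EventList(np.sort(rng.uniform(0, 25, size=20)))
        curve = pr_curve(edf, ref)
        pts = []
        for tau in curve.thresholds:
            est = pick_peaks(edf, tau, 0.150)
            m = me(ref, est)
            pts.append((m.recall, m.precision))
        pts.sort()
        r = [0.0] + [p[0] for p in pts]
        p = [pts[0][1]] + [p[1] for p in pts]
        expect = sum((r[i + 1] - r[i]) * (p[i + 1] + p[i]) / 2
                     for i in range(len(r) - 1))
        assert curve.auprc == pytest.approx(expect, abs=1e-12)

    def test_auprc_invariant_to_duplicate_thresholds(self):
        ref = EventList([1.0, 3.0])
        edf = _ideal_edf([1.0, 3.0, 6.0], 10.0)
        t = np.linspace(0.1, 0.9, 9)
        c1 = pr_curve(edf, ref, thresholds=t)
        c2 = pr_curve(edf, ref, thresholds=np.repeat(t, 2))
        assert c1.auprc == pytest.approx(c2.auprc)

    def test_best_f1_is_achievable_operating_point(self):
        ref = EventList([1.0, 3.0, 5.0])
        curve = pr_curve(_ideal_edf([1.0, 3.0], 10.0), ref)
        tau, f1 = curve.best_f1()
        assert 0 < tau < 1
        assert f1 == pytest.approx(2 * 1.0 * (2 / 3) / (1.0 + 2 / 3))


class TestSegmentedRecall:
    def test_perfect_detection_full_recall(self):
        ref = EventList([1.0, 10.0, 20.0], band_labels=["low", "high", "low"])
        est = EventList([1.0, 10.0, 20.0])
        df = segmented_recall(ref, est, duration=30.0, segment=15.0)
        filled = df.dropna()
        assert np.allclose(filled["recall"], 1.0)

    def test_missing_band_shows_in_its_cells_only(self):
        ref = EventList([1.0, 2.0, 10.0, 11.0],
                        band_labels=["low", "high", "low", "high"])
        est = EventList([1.0, 10.0])            # all high-band events missed
        df = segmented_recall(ref, est, duration=20.0, segment=20.0)
        low = df[df["band"] == "low"]["recall"].dropna()
        high = df[df["band"] == "high"]["recall"].dropna()
        assert np.allclose(low, 1.0)
        assert np.allclose(high, 0.0)

    def test_programmed_dropout_rate_recovered(self, rng):
        # drop half of the detections in the first half of the night
        times = np.sort(rng.uniform(0, 100, size=200))
        bands = ["low" if b else "high" for b in rng.integers(0, 2, 200)]
        ref = EventList(times, band_labels=bands)
        keep = (times > 50.0) | (np.arange(200) % 2 == 0)
        est = EventList(times[keep])
        df = segmented_recall(ref, est, duration=100.0, segment=50.0)
        first = df[df["segment_start"] == 0.0]
        early = first["n_matched"].sum() / first["n_ref"].sum()
        assert early == pytest.approx(0.5, abs=0.1)

    def test_unlabeled_reference_rejected(self):
        with pytest.raises(ValueError):
            segmented_recall(EventList([1.0]), EventList([1.0]), duration=10.0)


def test_auprc_helper_simple_rectangle():
    # two points at full precision: area is recall extent
    p = np.array([1.0, 1.0])
    r = np.array([0.5, 1.0])
    assert _auprc(p, r) == pytest.approx(1.0)
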