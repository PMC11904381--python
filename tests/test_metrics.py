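"""Metric values against brute-force oracles; CI closed forms and coverage."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import sepsiscreen as ss
from sepsiscreen.metrics import ConfusionCounts


# --------------------------------------------------------------------------
# Independent oracles
# --------------------------------------------------------------------------

def auc_brute(scores, labels):
    """P(score+ > score-) + 0.5 P(tie), all positive-negative pairs."""
    pos = [s for s, y in zip(scores, labels) if y == 1]
    neg = [s for s, y in zip(scores, labels) if y == 0]
    if not pos or not neg:
        return None
    total = 0.0
    for sp in pos:
        for sn in neg:
            total += 1.0 if sp > sn else (0.5 if sp == sn else 0.0)
    return total / (len(pos) * len(neg))


def ap_of_order(labels_in_rank_order):
    """Average precision of one explicit ranking (descending score)."""
    n_pos = sum(labels_in_rank_order)
    total, seen_pos = 0.0, 0
    for i, y in enumerate(labels_in_rank_order, start=1):
        if y == 1:
            seen_pos += 1
            total += seen_pos / i
    return total / n_pos


def ap_brute(scores, labels):
    """Expected average precision over all orderings of tied blocks."""
    if sum(labels) == 0:
        return None
    idx = sorted(range(len(scores)), key=lambda i: -scores[i])
    blocks, start = [], 0
    while start < len(idx):
        stop = start
        while stop < len(idx) and scores[idx[stop]] == scores[idx[start]]:
            stop += 1
        blocks.append([labels[idx[i]] for i in range(start, stop)])
        start = stop
    aps = []
    for perm_labels in itertools.product(
            *[set(itertools.permutations(b)) for b in blocks]):
        order = [y for block in perm_labels for y in block]
        aps.append(ap_of_order(order))
    return float(np.mean(aps))


# --------------------------------------------------------------------------
# Confusion and rate metrics
# --------------------------------------------------------------------------

class TestConfusion:
    def test_hand_counts(self):
        c = ss.confusion([1, 1, 0, 0], [1, 0, 1, 0])
        assert (c.tp, c.fp, c.fn, c.tn) == (1, 1, 1, 1)

    def test_all_correct(self):
        c = ss.confusion([1, 0, 1], [1, 0, 1])
        assert c.fp == c.fn == 0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            ss.confusion([], [])


class TestRateMetrics:
    def test_sensitivity_value(self):
        m = ss.rate_metrics(ConfusionCounts(tp=9, fp=0, tn=0, fn=1))
        assert m["sensitivity"].value == pytest.approx(0.9)

    def test_wald_half_width_closed_form(self):
        # p = 0.5, denominator 100, alpha 0.05: 1.96...*sqrt(0.25/100)
        m = ss.rate_metrics(ConfusionCounts(tp=50, fp=0, tn=0, fn=50), alpha=0.05)
        half = (m["sensitivity"].ci_high - m["sensitivity"].ci_low) / 2
        assert half == pytest.approx(0.09800, abs=5e-5)

    def test_zero_denominator_undefined(self):
        m = ss.rate_metrics(ConfusionCounts(tp=0, fp=3, tn=5, fn=0))
        assert not m["sensitivity"].defined
        assert m["specificity"].defined

    def test_intervals_clipped_and_contain_estimate(self):
        m = ss.rate_metrics(ConfusionCounts(tp=99, fp=1, tn=1, fn=1))
        for est in m.values():
            assert 0.0 <= est.ci_low <= est.value <= est.ci_high <= 1.0


# --------------------------------------------------------------------------
# AUC and A-PPV vs oracles
# --------------------------------------------------------------------------

class TestRankMetricsOracle:
    def test_spec_examples(self):
        assert ss.auc([0.1, 0.4, 0.35, 0.8], [0, 0, 1, 1]).value == pytest.approx(0.75)
        assert ss.average_ppv([0.9, 0.8, 0.7], [1, 0, 1]).value == pytest.approx(
            (1 / 1 + 2 / 3) / 2)
        # single positive ranked last among 5
        assert ss.average_ppv([5, 4, 3, 2, 1], [0, 0, 0, 0, 1]).value == pytest.approx(0.2)
        assert ss.auc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0]).value == 1.0
        assert ss.average_ppv([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0]).value == 1.0

    @pytest.mark.parametrize("n", range(2, 9))
    def test_exhaustive_labelings_distinct_scores(self, n):
        scores = list(np.linspace(0.9, 0.1, n))
        for labels in itertools.product((0, 1), repeat=n):
            expected_auc = auc_brute(scores, labels)
            got_auc = ss.auc(scores, labels)
            if expected_auc is None:
                assert not got_auc.defined
            else:
                assert got_auc.value == pytest.approx(expected_auc, abs=1e-12)
            expected_ap = ap_brute(scores, labels)
            got_ap = ss.average_ppv(scores, labels)
            if expected_ap is None:
                assert not got_ap.defined
            else:
                assert got_ap.value == pytest.approx(expected_ap, abs=1e-12)

    def test_tied_scores_match_permutation_expectation(self):
        # tied blocks resolved in expectation, not by grouped-step shortcuts
        cases = [
            ([0.5, 0.5], [1, 0]),
            ([0.7, 0.5, 0.5, 0.5], [0, 1, 1, 0]),
            ([0.9, 0.9, 0.4, 0.4, 0.4], [1, 0, 1, 0, 0]),
            ([0.3, 0.3, 0.3, 0.3], [1, 1, 0, 0]),
        ]
        for scores, labels in cases:
            assert ss.average_ppv(scores, labels).value == pytest.approx(
                ap_brute(scores, labels), abs=1e-12)
            assert ss.auc(scores, labels).value == pytest.approx(
                auc_brute(scores, labels), abs=1e-12)

    def test_null_scores_auc_near_half(self):
        rng = np.random.default_rng(0)
        scores = rng.random(10_000)
        labels = rng.integers(0, 2, 10_000)
        assert abs(ss.auc(scores, labels).value - 0.5) < 0.02

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.lists(st.floats(0.01, 0.99), min_size=4, max_size=20, unique=True),
           st.data())
    def test_rank_invariance_under_monotone_transform(self, scores, data):
        labels = data.draw(st.lists(st.sampled_from([0, 1]),
                                    min_size=len(scores), max_size=len(scores)))
        if len(set(labels)) < 2:
            return
        transformed = [math.tanh(3 * s) for s in scores]  # strictly monotone
        assert ss.auc(scores, labels).value == pytest.approx(
            ss.auc(transformed, labels).value, abs=1e-12)
        assert ss.average_ppv(scores, labels).value == pytest.approx(
            ss.average_ppv(transformed, labels).value, abs=1e-12)


# --------------------------------------------------------------------------
# Brier and sNB
# --------------------------------------------------------------------------

class TestBrier:
    def test_values(self):
        assert ss.brier([1, 0, 1], [1, 0, 1]).value == 0.0
        assert ss.brier([0.5] * 6, [1, 0, 1, 0, 1, 0]).value == pytest.approx(0.25)

    def test_hoeffding_half_width_closed_form(self):
        m = ss.brier([0.3] * 200, [0] * 200, alpha=0.05)
        half = math.sqrt(math.log(40) / 400)
        assert half == pytest.approx(0.09603, abs=5e-6)
        assert m.ci_high - m.value == pytest.approx(half, abs=1e-12)


class TestSnb:
    def test_perfect_classifier(self):
        c = ConfusionCounts(tp=20, fp=0, tn=80, fn=0)
        assert ss.snb(c, 0.5).value == pytest.approx(1.0)

    def test_flag_nobody(self):
        c = ConfusionCounts(tp=0, fp=0, tn=80, fn=20)
        assert ss.snb(c, 0.5).value == pytest.approx(0.0)

    def test_hand_formula(self):
        # sens 0.8, spec 0.9, pi 0.2, t 0.5 -> (0.16 - 0.08)/0.2 = 0.4
        c = ConfusionCounts(tp=16, fn=4, tn=72, fp=8)
        assert ss.snb(c, 0.5).value == pytest.approx(0.4)

    def test_no_positives_undefined(self):
        assert not ss.snb(ConfusionCounts(tp=0, fp=5, tn=95, fn=0)).defined


# --------------------------------------------------------------------------
# CI simulation properties
# --------------------------------------------------------------------------

class TestCiCoverage:
    def test_wald_coverage_nominal(self):
        # p = 0.3, n = 500, 2000 replicates: empirical coverage in [0.93, 0.97]
        rng = np.random.default_rng(42)
        p, n, reps = 0.3, 500, 2000
        hits = 0
        z = 1.959963984540054
        x = rng.binomial(n, p, size=reps)
        phat = x / n
        half = z * np.sqrt(phat * (1 - phat) / n)
        hits = int(((phat - half <= p) & (p <= phat + half)).sum())
        assert 0.93 <= hits / reps <= 0.97
        # spot-check against the implementation on one replicate
        c = ConfusionCounts(tp=int(x[0]), fn=int(n - x[0]), fp=0, tn=0)
        m = ss.rate_metrics(c)["sensitivity"]
        assert m.ci_low == pytest.approx(max(0, phat[0] - half[0]), abs=1e-12)

    def test_hoeffding_brier_coverage_conservative(self):
        # scores fixed at 0.3, y ~ Bernoulli(0.3): true Brier = 0.21
        rng = np.random.default_rng(43)
        n, reps = 500, 2000
        y = rng.random((reps, n)) < 0.3
        sample_brier = ((0.3 - y) ** 2).mean(axis=1)
        half = math.sqrt(math.log(2 / 0.05) / (2 * n))
        true = 0.3 * 0.49 + 0.7 * 0.09
        cover = ((sample_brier - half <= true) & (true <= sample_brier + half)).mean()
        assert cover >= 0.95
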