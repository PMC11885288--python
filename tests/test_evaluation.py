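"""Agreement statistics against direct, brute-force evaluations."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from scalebp.evaluation import (
    AgreementStats,
    ConfusionCounts,
    bland_altman,
    classification_metrics,
    error_distribution,
    mad,
    pearson,
)


def test_confusion_metrics_reported_example():
    m = classification_metrics(ConfusionCounts(tp=1174, tn=5534, fp=71, fn=7))
    assert round(m["accuracy"], 3) == 0.989
    assert round(m["sensitivity"], 3) == 0.994
    assert round(m["specificity"], 3) == 0.987


def test_confusion_metrics_perfect_and_symmetric():
    perfect = classification_metrics(ConfusionCounts(tp=10, tn=10, fp=0, fn=0))
    assert all(v == 1.0 for v in perfect.values())
    half = classification_metrics(ConfusionCounts(tp=25, tn=25, fp=25, fn=25))
    assert half["accuracy"] == 0.5


def test_accuracy_is_prevalence_weighted_mean():
    c = ConfusionCounts(tp=40, tn=130, fp=20, fn=10)
    m = classification_metrics(c)
    p, n = c.tp + c.fn, c.tn + c.fp
    assert m["accuracy"] == pytest.approx(
        (m["sensitivity"] * p + m["specificity"] * n) / (p + n)
    )


def test_zero_denominator_reports_nan():
    m = classification_metrics(ConfusionCounts(tp=0, tn=5, fp=0, fn=0))
    assert math.isnan(m["sensitivity"])


def test_confusion_from_labels():
    cm = ConfusionCounts.from_labels([1, 1, 0, 0, 1], [1, 0, 0, 1, 1])
    assert (cm.tp, cm.tn, cm.fp, cm.fn) == (2, 1, 1, 1)
    assert cm.total == 5


def test_pearson_examples():
    x = np.arange(10.0)
    assert pearson(x, x) == pytest.approx(1.0)
    assert pearson(x, -2 * x + 5) == pytest.approx(-1.0)
    assert pearson([1, 2, 3], [1, 2, 4]) == pytest.approx(0.9820, abs=5e-5)
    with pytest.raises(ValueError):
        pearson([1, 1, 1], [1, 2, 3])


def _brute_force_pcc(x, y):
    xm, ym = np.mean(x), np.mean(y)
    num = sum((a - xm) * (b - ym) for a, b in zip(x, y))
    den = math.sqrt(sum((a - xm) ** 2 for a in x)) * math.sqrt(
        sum((b - ym) ** 2 for b in y)
    )
    return num / den


@settings(deadline=None, max_examples=50, derandomize=True)
@given(st.integers(0, 10_000))
def test_pearson_matches_brute_force(seed):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(2, 60))
    x = rng.normal(size=n)
    y = rng.normal(size=n) + 0.3 * x
    assert pearson(x, y) == pytest.approx(_brute_force_pcc(x, y), abs=1e-12)


def test_mad_variants():
    assert mad([-2.0, 2.0]) == pytest.approx(2.0)
    assert mad([0.0, 0.0]) == 0.0
    assert mad([0.0, 0.0], variant="rms") == 0.0
    # errors {1, 3}: population S = 1, mean = 2 -> sqrt(1 + 4)
    assert mad([1.0, 3.0], variant="rms") == pytest.approx(math.sqrt(5.0))
    with pytest.raises(ValueError):
        mad([])
    with pytest.raises(ValueError):
        mad([1.0], variant="median")


def test_bland_altman_identity_and_simple_case():
    x = np.arange(5.0) + 100
    stats = bland_altman(x, x)
    assert stats.bias == 0.0 and stats.loa_upper == 0.0 and stats.pct_outside == 0.0
    stats = bland_altman([0.0, 0.0], [-1.0, 1.0])
    assert stats.loa_upper == pytest.approx(1.96)
    assert stats.loa_lower == pytest.approx(-1.96)


@settings(deadline=None, max_examples=50, derandomize=True)
@given(st.integers(0, 10_000))
def test_bland_altman_matches_brute_force(seed):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(2, 80))
    ref = rng.normal(120, 10, n)
    est = ref + rng.normal(0, 5, n)
    stats = bland_altman(ref, est)
    err = [e - r for r, e in zip(ref, est)]
    bias = sum(err) / n
    sd = math.sqrt(sum((e - bias) ** 2 for e in err) / n)
    assert stats.bias == pytest.approx(bias, abs=1e-12)
    assert stats.loa_upper == pytest.approx(bias + 1.96 * sd, abs=1e-12)
    assert stats.loa_lower == pytest.approx(bias - 1.96 * sd, abs=1e-12)
    outside = sum(e < stats.loa_lower or e > stats.loa_upper for e in err)
    assert stats.pct_outside == pytest.approx(100.0 * outside / n, abs=1e-12)


def test_reported_loa_midpoint_consistent_with_bias():
    # printed SBP limits (10.35, -10.10) center on the printed bias 0.13,
    # within the rounding of values reported at two decimals
    assert (10.35 + -10.10) / 2 == pytest.approx(0.13, abs=0.0075)


def test_agreement_stats_invariant():
    with pytest.raises(ValueError):
        AgreementStats(bias=0.0, sd_error=1.0, loa_lower=0.5, loa_upper=2.0,
                       pct_outside=0.0)


def test_error_distribution_counting():
    assert error_distribution([0, 4, 9, 14]) == {5.0: 50.0, 10.0: 75.0, 15.0: 100.0}
    assert error_distribution([0.0, 0.0]) == {5.0: 100.0, 10.0: 100.0, 15.0: 100.0}
    assert error_distribution([6, 6, -6, 6]) == {5.0: 0.0, 10.0: 100.0, 15.0: 100.0}
    # bound is inclusive
    assert error_distribution([5.0])[5.0] == 100.0


@settings(deadline=None, max_examples=30, derandomize=True)
@given(st.lists(st.floats(-30, 30), min_size=1, max_size=100))
def test_error_distribution_monotone(errors):
    out = error_distribution(errors)
    vals = [out[b] for b in sorted(out)]
    assert all(a <= b for a, b in zip(vals, vals[1:]))
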