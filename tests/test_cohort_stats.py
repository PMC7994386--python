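from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import hypergeom, rankdata

from mmclock.cohort_stats import (
    cnv_bin_prevalence, fisher_prevalence, pairwise_wilcoxon_fdr, regress_burden,
)
from mmclock.io_formats import SegmentRecord, segments_to_frame


# ------------------------------------------------------------- oracles

def wilcoxon_enum_p(x, y):
    """Exact two-sided rank-sum p by full enumeration of labelings."""
    pooled = np.concatenate([x, y])
    ranks = rankdata(pooled)
    n = len(x)
    obs = ranks[:n].sum()
    sums = [sum(ranks[list(idx)]) for idx in combinations(range(len(pooled)), n)]
    sums = np.array(sums)
    lo = (sums <= obs + 1e-9).mean()
    hi = (sums >= obs - 1e-9).mean()
    return min(1.0, 2 * min(lo, hi))


def fisher_enum_p(k1, n1, k2, n2):
    """Two-sided point-probability Fisher p by hypergeometric summation."""
    K, N = k1 + k2, n1 + n2
    support = range(max(0, K - n2), min(K, n1) + 1)
    pmf = {k: hypergeom.pmf(k, N, K, n1) for k in support}
    p_obs = pmf[k1]
    return sum(p for p in pmf.values() if p <= p_obs * (1 + 1e-7))


# ------------------------------------------------------------- wilcoxon

def test_identical_distributions_give_p_one():
    res = pairwise_wilcoxon_fdr({"a": [1, 2, 3, 4], "b": [1, 2, 3, 4]}, "f")
    assert res[0].p == pytest.approx(1.0)


def test_extreme_separation_exact_p():
    res = pairwise_wilcoxon_fdr({"a": [1, 2, 3], "b": [10, 11, 12]}, "f")
    assert res[0].p == pytest.approx(0.1, abs=1e-12)
    assert res[0].test == "wilcoxon_exact"


def test_three_groups_yield_three_bh_adjusted_pairs():
    rng = np.random.default_rng(0)
    groups = {g: rng.normal(loc, 1, 8).tolist()
              for g, loc in [("a", 0), ("b", 1), ("c", 3)]}
    res = pairwise_wilcoxon_fdr(groups, "f")
    assert len(res) == 3
    ps = np.array([r.p for r in res])
    qs = np.array([r.q for r in res])
    # BH definition: q_i = min over j>=i of p_(j) * m / j
    order = np.argsort(ps)
    m = len(ps)
    expected = np.minimum.accumulate((ps[order] * m / np.arange(1, m + 1))[::-1])[::-1]
    np.testing.assert_allclose(qs[order], np.minimum(expected, 1.0), atol=1e-12)
    assert (qs >= ps - 1e-12).all() and (qs <= 1).all()


def test_small_group_is_error():
    with pytest.raises(ValueError, match="fewer than 2"):
        pairwise_wilcoxon_fdr({"a": [1], "b": [1, 2]}, "f")


@given(st.data())
@settings(deadline=None, derandomize=True, max_examples=25)
def test_exact_wilcoxon_matches_enumeration(data):
    n1 = data.draw(st.integers(2, 7))
    n2 = data.draw(st.integers(2, 7))
    rng = np.random.default_rng(data.draw(st.integers(0, 10_000)))
    x = rng.normal(size=n1)
    y = rng.normal(size=n2)
    res = pairwise_wilcoxon_fdr({"a": x.tolist(), "b": y.tolist()}, "f")
    assert res[0].p == pytest.approx(wilcoxon_enum_p(x, y), abs=1e-9)


# ------------------------------------------------------------- fisher

def test_fisher_examples():
    c = fisher_prevalence(0, 5, 5, 5)
    assert c.p == pytest.approx(2 / 252, rel=1e-9)
    assert fisher_prevalence(3, 6, 3, 6).p == pytest.approx(1.0)
    degenerate = fisher_prevalence(0, 0, 0, 0)
    assert degenerate.p == 1.0 and degenerate.flags == "degenerate_margins"


@given(st.data())
@settings(deadline=None, derandomize=True, max_examples=40)
def test_fisher_matches_hypergeometric_sum(data):
    n1 = data.draw(st.integers(1, 30))
    n2 = data.draw(st.integers(1, 30))
    k1 = data.draw(st.integers(0, n1))
    k2 = data.draw(st.integers(0, n2))
    if k1 + k2 == 0 or (n1 - k1) + (n2 - k2) == 0:
        return
    c = fisher_prevalence(k1, n1, k2, n2)
    assert c.p == pytest.approx(fisher_enum_p(k1, n1, k2, n2), rel=1e-7)


# ------------------------------------------------------------- CNV prevalence

def _seg_sample(gained):
    segs = [SegmentRecord("1", 1, 10_000_000, 2, 1 if gained else 0)] \
        if gained else [SegmentRecord("1", 1, 10_000_000, 1, 1)]
    return segments_to_frame(segs)


def test_cnv_prevalence_fisher_and_exclusion():
    samples = {f"a{i}": _seg_sample(True) for i in range(10)}
    samples.update({f"b{i}": _seg_sample(False) for i in range(10)})
    groups = {s: s[0] for s in samples}
    intervals = pd.DataFrame([
        {"chrom": "1", "start": 1_000_000, "end": 2_000_000},   # gained in all of a
        {"chrom": "2", "start": 1, "end": 1000},                 # gained nowhere
    ])
    out = cnv_bin_prevalence(samples, intervals, groups, direction="gained")
    signal, silent = out
    assert signal.counts == {"a": 10, "b": 0}
    expected = 2 / len(list(combinations(range(20), 10)))
    assert signal.contrasts[0].p == pytest.approx(expected, rel=1e-6)
    assert silent.excluded
    assert silent.contrasts[0].flags == "no_signal"
    # BH family excludes the silent interval: single test keeps q == p
    assert signal.contrasts[0].q == pytest.approx(signal.contrasts[0].p)


# ------------------------------------------------------------- regression

def test_regression_closed_form_oracle():
    rng = np.random.default_rng(1)
    x = rng.uniform(0, 10, 30)
    y = 2.5 * x + 1.0 + rng.normal(0, 1, 30)
    slope, intercept, r2, p = regress_burden(x, y)
    # normal equations
    X = np.column_stack([x, np.ones_like(x)])
    beta = np.linalg.solve(X.T @ X, X.T @ y)
    assert slope == pytest.approx(beta[0], abs=1e-10)
    assert intercept == pytest.approx(beta[1], abs=1e-10)
    resid = y - X @ beta
    r2_oracle = 1 - resid @ resid / ((y - y.mean()) @ (y - y.mean()))
    assert r2 == pytest.approx(r2_oracle, abs=1e-10)
    assert 0 < p < 1e-10


def test_regression_degenerate_cases():
    x = np.array([1.0, 2.0, 3.0, 4.0])
    slope, _, r2, _ = regress_burden(x, 3 * x + 2)     # collinear
    assert r2 == pytest.approx(1.0)
    slope, intercept, r2, p = regress_burden(x, np.full(4, 7.0))
    assert slope == 0.0 and intercept == 7.0 and r2 == 0.0 and p == 1.0
    with pytest.raises(ValueError):
        regress_burden([1, 2], [1, 2])
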