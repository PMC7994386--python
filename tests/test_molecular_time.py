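import numpy as np
import pandas as pd
import pytest

from mmclock.io_formats import segments_to_frame, SegmentRecord
from mmclock.molecular_time import (
    GainTiming, bootstrap_ci, clock_mutation_weights, clock_time_and_age,
    eligible_gains, group_windows, relative_time, time_gains,
)
from mmclock.synthetic import simulate_gain_counts


@pytest.mark.parametrize("n2,n1,cls,expected", [
    (25, 100, "gain_2_1", 0.5),
    (30, 60, "cnloh_2_0", 0.5),
    (0, 40, "gain_2_1", 0.0),      # no duplicated mutations: gain at time zero
    (0, 40, "cnloh_2_0", 0.0),
    (30, 0, "cnloh_2_0", 1.0),     # no post-gain mutations: gain at sampling
    (30, 0, "gain_2_1", 1.0),      # raw 1.5 clamped to 1
])
def test_relative_time_values(n2, n1, cls, expected):
    assert relative_time(n2, n1, cls) == pytest.approx(expected, abs=1e-12)


def test_relative_time_errors():
    with pytest.raises(ValueError, match="tetrasom"):
        relative_time(10, 10, "tetrasomy_2_2")
    with pytest.raises(ValueError):
        relative_time(0, 0, "gain_2_1")
    with pytest.raises(ValueError):
        relative_time(5, 5, "gain_3_1")


def test_relative_time_monotone_in_n2():
    n1 = 200
    ts = [relative_time(n2, n1, "gain_2_1") for n2 in range(0, 80)]
    assert all(b > a for a, b in zip(ts, ts[1:]))


def test_estimator_unbiased_at_large_counts():
    rng = np.random.default_rng(21)
    for cls in ("gain_2_1", "cnloh_2_0"):
        est = []
        for _ in range(200):
            n2, n1 = simulate_gain_counts(2000.0, 0.5, cls, rng)
            est.append(relative_time(n2, n1, cls))
        assert abs(np.mean(est) - 0.5) < 0.02


def _calls(rows):
    return pd.DataFrame(rows, columns=["chrom", "pos", "multiplicity", "clonal",
                                       "assigned", "context"])


def _mk_calls(chrom, start, n2, n1, clonal=True):
    rows = []
    for i in range(n2):
        rows.append((chrom, start + i, 2, clonal, True, "A[C>T]G"))
    for i in range(n1):
        rows.append((chrom, start + n2 + i, 1, clonal, True, "T[T>C]T"))
    return rows


def test_eligible_gains_filters():
    segs = segments_to_frame([
        SegmentRecord("1", 1, 5_000_001, 2, 1),        # eligible
        SegmentRecord("2", 1, 5_000_001, 2, 2),        # tetrasomy
        SegmentRecord("3", 1, 1_000_000, 2, 1),        # exactly 1 Mb: too short
        SegmentRecord("4", 1, 5_000_001, 2, 1),        # exactly 50 clonal: too few
        SegmentRecord("5", 1, 5_000_001, 1, 1),        # not a gain: no record
        SegmentRecord("X", 1, 5_000_001, 2, 1),        # sex chromosome
    ])
    rows = (_mk_calls("1", 1, 40, 80) + _mk_calls("2", 1, 40, 80)
            + _mk_calls("3", 1, 40, 80) + _mk_calls("4", 1, 20, 30)
            + _mk_calls("5", 1, 40, 80) + _mk_calls("X", 1, 40, 80))
    gains = eligible_gains(segs, _calls(rows))
    by_chrom = {g.chrom: g for g in gains}
    assert set(by_chrom) == {"1", "2", "3", "4", "X"}
    assert by_chrom["1"].eligible and by_chrom["1"].n2 == 40
    assert not by_chrom["2"].eligible and by_chrom["2"].reason == "tetrasomy"
    assert not by_chrom["3"].eligible and by_chrom["3"].reason == "segment_too_short"
    assert not by_chrom["4"].eligible
    assert by_chrom["4"].reason == "too_few_clonal_mutations"
    assert not by_chrom["X"].eligible and by_chrom["X"].reason == "sex_chromosome"


def test_eligible_gains_ignores_subclonal_mutations():
    segs = segments_to_frame([SegmentRecord("1", 1, 5_000_001, 2, 1)])
    rows = _mk_calls("1", 1, 30, 30) + _mk_calls("1", 100_000, 0, 500, clonal=False)
    (g,) = eligible_gains(segs, _calls(rows))
    assert g.n2 == 30 and g.n1 == 30


def test_bootstrap_ci_degenerate_and_deterministic():
    m_all2 = np.full(50, 2)
    lo, hi = bootstrap_ci(m_all2, "cnloh_2_0", rng=np.random.default_rng(0))
    assert (lo, hi) == (1.0, 1.0)
    m = np.array([2] * 30 + [1] * 70)
    a = bootstrap_ci(m, "gain_2_1", rng=np.random.default_rng(5))
    b = bootstrap_ci(m, "gain_2_1", rng=np.random.default_rng(5))
    assert a == b
    with pytest.raises(ValueError, match="10"):
        bootstrap_ci(np.array([1] * 9), "gain_2_1")


def test_bootstrap_ci_narrow_at_large_n():
    m = np.array([2] * 500 + [1] * 500)
    lo, hi = bootstrap_ci(m, "gain_2_1", rng=np.random.default_rng(1))
    assert hi - lo < 0.1
    assert lo <= relative_time(500, 500, "gain_2_1") <= hi


def _gt(t, lo, hi):
    g = GainTiming("1", 1, 2, "gain_2_1", eligible=True)
    g.t, g.ci_low, g.ci_high = t, lo, hi
    return g


def test_group_windows_merging_rules():
    # overlapping CIs merge into one window
    ws = group_windows([_gt(0.30, 0.2, 0.4), _gt(0.35, 0.25, 0.45)])
    assert len(ws) == 1 and len(ws[0].members) == 2 and ws[0].is_earliest
    # disjoint CIs stay separate; the earlier window is marked earliest
    ws = group_windows([_gt(0.8, 0.7, 0.9), _gt(0.2, 0.15, 0.25)])
    assert len(ws) == 2
    assert ws[0].is_earliest and ws[0].t_mean == pytest.approx(0.2)
    # single gain: one window, earliest
    ws = group_windows([_gt(0.5, 0.4, 0.6)])
    assert len(ws) == 1 and ws[0].is_earliest


def _window_setup(n2, n1, cls="gain_2_1"):
    rows = _mk_calls("1", 1, n2, n1)
    calls = _calls(rows)
    g = GainTiming("1", 1, 5_000_001, cls, n2=n2, n1=n1, eligible=True)
    g.t = relative_time(n2, n1, cls) if n2 + n1 else None
    g.ci_low, g.ci_high = 0.0, 1.0
    g.mutation_index = calls.index.to_numpy()
    w = group_windows([g])[0]
    return w, calls


def test_clock_weights_pure_sbs5_are_one(signatures):
    w = clock_mutation_weights(["A[C>T]G", "T[T>C]T"], {"SBS5": 1.0}, signatures)
    np.testing.assert_allclose(w, 1.0)
    with pytest.raises(ValueError, match="SBS1 nor SBS5"):
        clock_mutation_weights(["A[C>T]G"], {"SBS2": 1.0}, signatures)


def test_clock_time_equals_plain_time_for_pure_clock_sample(signatures):
    w, calls = _window_setup(60, 120)
    out = clock_time_and_age(w, calls, {"SBS5": 1.0}, signatures, 60.0,
                             n_boot=200, rng=np.random.default_rng(2))
    assert out.converted
    assert out.t_clock == pytest.approx(relative_time(60, 120, "gain_2_1"), abs=1e-9)
    assert out.age_estimate == pytest.approx(out.t_clock * 60.0)
    assert out.age_ci[0] <= out.age_estimate <= out.age_ci[1]


def test_clock_time_identity_bound_at_t1(signatures):
    # CN-LOH with zero non-duplicated mutations: t_clock = 1, age = sampling age
    w, calls = _window_setup(80, 0, cls="cnloh_2_0")
    out = clock_time_and_age(w, calls, {"SBS5": 1.0}, signatures, 58.0, n_boot=100,
                             rng=np.random.default_rng(3))
    assert out.t_clock == pytest.approx(1.0)
    assert out.age_estimate == pytest.approx(58.0)


def test_window_below_clock_minimum_is_not_converted(signatures):
    w, calls = _window_setup(20, 30)   # 50 clock-weighted mutations exactly
    out = clock_time_and_age(w, calls, {"SBS5": 1.0}, signatures, 60.0,
                             rng=np.random.default_rng(4))
    assert not out.converted
    assert out.reason == "too_few_clock_mutations"
    assert out.age_estimate is None


def test_time_gains_fills_estimates():
    rows = _mk_calls("1", 1, 100, 200)
    calls = _calls(rows)
    segs = segments_to_frame([SegmentRecord("1", 1, 5_000_001, 2, 1)])
    gains = eligible_gains(segs, calls)
    time_gains(gains, calls, n_boot=300, rng=np.random.default_rng(9))
    (g,) = gains
    assert g.t == pytest.approx(0.75)
    assert g.ci_low <= g.t <= g.ci_high
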