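import numpy as np
import pandas as pd
import pytest
from scipy.stats import binom

from mmclock.clonality import (
    assign_multiplicities, assign_multiplicity, expected_vaf, fit_clonal_model,
)
from mmclock.io_formats import MutationRecord, SegmentRecord


@pytest.mark.parametrize("m,ccf,rho,nt,expected", [
    (2, 1.0, 1.0, 3, 2 / 3),     # duplicated mutation in a pure 2:1 gain
    (1, 1.0, 1.0, 3, 1 / 3),     # non-duplicated mutation, same region
    (1, 1.0, 1.0, 2, 0.5),       # clonal heterozygous, pure diploid
    (1, 1.0, 0.5, 2, 0.25),      # purity dilution halves the VAF
])
def test_expected_vaf_values(m, ccf, rho, nt, expected):
    assert expected_vaf(m, ccf, rho, nt) == pytest.approx(expected, abs=1e-12)


def test_expected_vaf_errors_and_ratio_identity():
    with pytest.raises(ValueError):
        expected_vaf(1, 1.0, 1.0, 0)       # no tumor DNA at locus
    with pytest.raises(ValueError):
        expected_vaf(1, 1.0, 0.0, 2)
    for rho in (0.3, 0.7, 1.0):
        for nt in (2, 3, 4):
            r = expected_vaf(2, 0.9, rho, nt) / expected_vaf(1, 0.9, rho, nt)
            assert r == pytest.approx(2.0, abs=1e-12)


def test_expected_vaf_monotonicity():
    grid = np.linspace(0.1, 1.0, 8)
    base = expected_vaf(1, 0.5, 0.5, 3)
    assert all(np.diff([expected_vaf(1, c, 0.5, 3) for c in grid]) > 0)
    assert all(np.diff([expected_vaf(1, 0.5, r, 3) for r in grid]) > 0)
    assert expected_vaf(2, 0.5, 0.5, 3) > base


def _mut(alt, depth, pos=5_000_000):
    penta = "TACAT"
    return MutationRecord.from_raw("S", "1", pos, "C", "T", penta, alt, depth, id="m")


def test_assign_multiplicity_binomial_oracle():
    seg = SegmentRecord("1", 1, 10_000_000, 2, 1)
    # oracle: direct binomial pmf at p=2/3 vs p=1/3
    for alt, depth in [(40, 60), (20, 60), (45, 60), (15, 60)]:
        call = assign_multiplicity(_mut(alt, depth), seg, 1.0)
        l1 = binom.pmf(alt, depth, 1 / 3)
        l2 = binom.pmf(alt, depth, 2 / 3)
        assert call.multiplicity == (2 if l2 > l1 else 1)
        assert call.posterior_m2 == pytest.approx(l2 / (l1 + l2), rel=1e-9)
    assert assign_multiplicity(_mut(40, 60), seg, 1.0).multiplicity == 2
    assert assign_multiplicity(_mut(20, 60), seg, 1.0).multiplicity == 1


def test_assign_multiplicity_tie_goes_to_m1():
    # Binom(30;60,2/3) == Binom(30;60,1/3) by p <-> 1-p symmetry at k = n/2
    seg = SegmentRecord("1", 1, 10_000_000, 2, 1)
    call = assign_multiplicity(_mut(30, 60), seg, 1.0)
    assert call.multiplicity == 1
    assert call.posterior_m2 == pytest.approx(0.5, abs=1e-9)


def test_assign_multiplicity_outside_segment_is_error():
    seg = SegmentRecord("1", 1, 100, 2, 1)
    with pytest.raises(ValueError, match="not inside"):
        assign_multiplicity(_mut(40, 60, pos=500), seg, 1.0)


def test_multiplicity_accuracy_on_simulated_gain():
    """>= 95% accuracy for clonal mutations in 2:1 segments at 40x, rho >= 0.6."""
    rng = np.random.default_rng(77)
    rho, cov, n = 0.65, 40.0, 4000
    truth = rng.integers(1, 3, size=n)
    p = np.array([expected_vaf(m, 1.0, rho, 3) for m in truth])
    depth = np.maximum(1, rng.poisson(cov * (rho * 3 + (1 - rho) * 2) / 2, size=n))
    alt = rng.binomial(depth, p)
    df = pd.DataFrame({"alt_count": alt, "depth": depth})
    calls = assign_multiplicities(df, rho, tumor_cn=3, major_cn=2)
    assert (calls.multiplicity.to_numpy() == truth).mean() >= 0.95


def test_posterior_calibration_on_simulation():
    """Calls with posterior in [0.6, 0.8] are right 55-85% of the time."""
    rng = np.random.default_rng(42)
    rho, cov, n = 0.5, 30.0, 60_000
    truth = rng.integers(1, 3, size=n)
    p = np.array([expected_vaf(m, 1.0, rho, 3) for m in truth])
    depth = np.maximum(1, rng.poisson(cov * (rho * 3 + (1 - rho) * 2) / 2, size=n))
    alt = rng.binomial(depth, p)
    calls = assign_multiplicities(pd.DataFrame({"alt_count": alt, "depth": depth}),
                                  rho, tumor_cn=3, major_cn=2)
    post = calls.posterior_m2.to_numpy()
    sel = (post >= 0.6) & (post <= 0.8)
    assert sel.sum() > 300
    acc = (truth[sel] == 2).mean()
    assert 0.55 <= acc <= 0.85


def _mixture_calls(rng, n_clonal, n_sub, rho=0.8, ccf_sub=0.35, cov=60):
    rows = []
    for n, ccf in [(n_clonal, 1.0), (n_sub, ccf_sub)]:
        p = expected_vaf(1, ccf, rho, 2)
        depth = np.maximum(1, rng.poisson(cov, size=n))
        alt = rng.binomial(depth, p)
        rows.append(pd.DataFrame({
            "alt_count": alt, "depth": depth, "multiplicity": 1,
            "total_cn": 2, "assigned": True}))
    return pd.concat(rows, ignore_index=True)


def test_clonal_model_single_clone():
    rng = np.random.default_rng(3)
    calls = _mixture_calls(rng, 800, 0)
    model = fit_clonal_model(calls, 0.8)
    assert model.n_clusters == 1
    assert model.clonal.mean() >= 0.99
    assert abs(model.centers[0] - 1.0) < 0.05
    assert not model.purity_discordant


def test_clonal_model_recovers_subclone():
    rng = np.random.default_rng(4)
    calls = _mixture_calls(rng, 600, 400)
    model = fit_clonal_model(calls, 0.8)
    assert model.n_clusters == 2
    centers = np.sort(model.centers)
    assert abs(centers[-1] - 1.0) < 0.05
    assert abs(centers[0] - 0.35) < 0.05
    # subclonal cluster falls below the 0.85 CCF clonality threshold
    assert model.clonal.mean() == pytest.approx(0.6, abs=0.1)


def test_clonal_model_minimum_input():
    rng = np.random.default_rng(5)
    calls = _mixture_calls(rng, 10, 0)
    with pytest.raises(ValueError, match="50"):
        fit_clonal_model(calls, 0.8)


def test_clonal_model_flags_discordant_purity():
    rng = np.random.default_rng(6)
    calls = _mixture_calls(rng, 800, 0, rho=0.8)
    model = fit_clonal_model(calls, 0.55)  # supplied purity far from VAF-implied
    assert model.purity_discordant
    assert model.vaf_purity_estimate == pytest.approx(0.8, abs=0.1)
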