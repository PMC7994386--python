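import numpy as np
import pandas as pd
import pytest

from mmclock.contexts import CONTEXT_INDEX
from mmclock.io_formats import MutationRecord
from mmclock.signature_fit import (
    Catalog96, apobec_metrics, backward_eliminate, build_catalog,
    cosine_similarity, fit_exposures,
)
from mmclock.synthetic import _make_mutation


def _catalog_from(p, n, rng, sample="s"):
    return Catalog96(sample, rng.multinomial(n, p))


def test_build_catalog_counts():
    assert build_catalog([], sample_id="x").total == 0
    rec = MutationRecord.from_raw("x", "1", 10, "C", "T", "TACAT", 5, 20, id="m")
    cat = build_catalog([rec])
    assert cat.counts[CONTEXT_INDEX["A[C>T]A"]] == 1 and cat.total == 1
    df = pd.DataFrame({"context": ["A[C>T]A", "A[C>T]A", "T[C>G]A"],
                       "sample_id": ["x"] * 3})
    cat = build_catalog(df)
    assert cat.counts[CONTEXT_INDEX["A[C>T]A"]] == 2 and cat.total == 3


def test_catalog_from_single_signature_resembles_it(signatures):
    rng = np.random.default_rng(0)
    cat = _catalog_from(signatures["SBS1"], 5000, rng)
    assert cosine_similarity(cat.counts, signatures["SBS1"]) >= 0.97


def test_fit_pure_signature(signatures):
    cat = Catalog96("s", 1000 * signatures["SBS5"])
    fit = fit_exposures(cat, signatures.subset(["SBS1", "SBS5"]))
    assert fit.fractions["SBS5"] >= 0.99


def test_fit_single_signature_model_is_identity(signatures):
    rng = np.random.default_rng(1)
    cat = _catalog_from(signatures["SBS1"], 2000, rng)
    fit = fit_exposures(cat, signatures.subset(["SBS1"]))
    assert fit.fractions["SBS1"] == pytest.approx(1.0)
    assert fit.cosine == pytest.approx(
        cosine_similarity(cat.counts, signatures["SBS1"]), abs=1e-12)


def test_fit_errors_on_empty_catalog(signatures):
    with pytest.raises(ValueError, match="empty"):
        fit_exposures(Catalog96("s", np.zeros(96)), signatures)


def test_exposure_conservation_and_determinism(signatures):
    rng = np.random.default_rng(2)
    p = 0.5 * signatures["SBS1"] + 0.3 * signatures["SBS5"] + 0.2 * signatures["SBS13"]
    cat = _catalog_from(p, 4000, rng)
    f1 = fit_exposures(cat, signatures)
    f2 = fit_exposures(cat, signatures)
    assert sum(f1.counts.values()) == pytest.approx(cat.total, abs=1e-6)
    assert f1.fractions == f2.fractions  # no randomness in the fit


def test_mixture_recovery_against_grid_oracle(signatures):
    """EM fractions beat/match a coarse 1-simplex grid search in likelihood."""
    rng = np.random.default_rng(3)
    p = 0.6 * signatures["SBS1"] + 0.4 * signatures["SBS5"]
    cat = _catalog_from(p, 5000, rng)
    model = signatures.subset(["SBS1", "SBS5"])
    fit = fit_exposures(cat, model)
    assert fit.fractions["SBS1"] == pytest.approx(0.6, abs=0.05)
    S = model.values()
    x = cat.counts
    nz = x > 0

    def ll(a):
        mix = S @ np.array([a, 1 - a])
        return float(x[nz] @ np.log(mix[nz]))

    grid_best = max(np.linspace(0.01, 0.99, 99), key=ll)
    assert fit.log_likelihood >= ll(grid_best) - 1e-6
    assert fit.fractions["SBS1"] == pytest.approx(grid_best, abs=0.02)


def test_em_loglikelihood_is_monotone(signatures):
    rng = np.random.default_rng(4)
    p = 0.4 * signatures["SBS1"] + 0.4 * signatures["SBS5"] + 0.2 * signatures["SBS9"]
    cat = _catalog_from(p, 3000, rng)
    _, trace = fit_exposures(cat, signatures, return_trace=True)
    diffs = np.diff(trace)
    assert (diffs >= -1e-9).all()


def test_elimination_removes_absent_apobec(signatures):
    rng = np.random.default_rng(5)
    p = (0.3 * signatures["SBS1"] + 0.5 * signatures["SBS5"]
         + 0.2 * signatures["SBS9"])
    cat = _catalog_from(p, 5000, rng)
    fit = backward_eliminate(cat, signatures)
    assert fit.apobec_fraction == 0.0
    assert {"SBS2", "SBS13"} <= set(fit.removed)


def test_elimination_retains_true_apobec(signatures):
    rng = np.random.default_rng(6)
    p = (0.2 * signatures["SBS1"] + 0.5 * signatures["SBS5"]
         + 0.18 * signatures["SBS2"] + 0.12 * signatures["SBS13"])
    cat = _catalog_from(p, 5000, rng)
    fit = backward_eliminate(cat, signatures)
    assert fit.apobec_fraction == pytest.approx(0.30, abs=0.07)


def test_elimination_keeps_strong_signatures(signatures):
    """A signature at >= 15% true contribution survives elimination."""
    rng = np.random.default_rng(7)
    p = 0.25 * signatures["SBS1"] + 0.60 * signatures["SBS5"] + 0.15 * signatures["SBS9"]
    cat = _catalog_from(p, 4000, rng)
    fit = backward_eliminate(cat, signatures)
    assert "SBS9" not in fit.removed
    assert fit.fractions["SBS9"] > 0.05


def test_elimination_threshold_one_collapses_to_clock(signatures):
    rng = np.random.default_rng(8)
    p = sum(signatures[s] for s in signatures.names) / 7
    cat = _catalog_from(p, 5000, rng)
    fit = backward_eliminate(cat, signatures, threshold=1.0)
    assert set(fit.fractions) == {"SBS1", "SBS5"}


def _apobec_mutations(n, bias, rng, context="T[C>T]A"):
    recs = []
    for i in range(n):
        recs.append(_make_mutation("s", "1", 100 + i, context, 10, 30,
                                   f"m{i}", "SBS2", bias, rng))
    return recs


class _FakeExposures:
    sample_id = "s"

    def __init__(self, apobec):
        self.apobec_fraction = apobec


def test_apobec_ratio_recovers_generation_odds():
    rng = np.random.default_rng(9)
    recs = _apobec_mutations(2000, 4.0, rng)
    out = apobec_metrics(recs, _FakeExposures(0.25))
    assert out.apobec_detected
    assert out.n_ytca + out.n_rtca == 2000
    assert 3.2 <= out.ratio_3a_3b <= 4.8


def test_apobec_ratio_near_one_at_equal_odds():
    rng = np.random.default_rng(10)
    recs = _apobec_mutations(2000, 1.0, rng)
    out = apobec_metrics(recs, _FakeExposures(0.25))
    assert out.ratio_3a_3b == pytest.approx(1.0, abs=0.25)


def test_apobec_ratio_undefined_without_signal():
    rng = np.random.default_rng(11)
    # no tCa mutations at all
    recs = _apobec_mutations(50, 1.0, rng, context="A[C>T]G")
    out = apobec_metrics(recs, _FakeExposures(0.25))
    assert out.ratio_3a_3b is None and out.n_ytca == 0
    # APOBEC not detected after elimination: ratio undefined even with tCa
    recs = _apobec_mutations(50, 1.0, rng)
    out = apobec_metrics(recs, _FakeExposures(0.0))
    assert out.ratio_3a_3b is None and not out.apobec_detected


def test_apobec_requires_pentanucleotide_context():
    df = pd.DataFrame({"context": ["T[C>T]A"], "five_prime2": [None]})
    with pytest.raises(ValueError, match="penta"):
        apobec_metrics(df, _FakeExposures(0.2))
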