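"""Mutational-signature fitting over the 96-context catalog.

Exposures are maximum-likelihood under a multinomial model, fitted by EM
(deterministic, uniform initialization). A backward-elimination pass in the
style of mmsig removes low-contributing signatures whenever refitting
without them costs < 0.01 reconstruction cosine similarity; the clock-like
SBS1/SBS5 are always retained and the APOBEC pair SBS2/SBS13 is removed or
kept jointly (one biological process). APOBEC activity is summarized both
as the SBS2+SBS13 exposure fraction and as the APOBEC3A:3B-discriminating
YTCA:RTCA ratio over tCa-motif mutations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .contexts import CONTEXT_INDEX, SBS96_CONTEXTS
from .synthetic_signatures import APOBEC_SIGNATURES, CLOCK_SIGNATURES

#: tCa-motif context classes counted for the APOBEC3A:3B ratio
APOBEC_TCA_CONTEXTS = frozenset({"T[C>T]A", "T[C>G]A"})


@dataclass
class Catalog96:
    """Per-sample mutation counts over the 96 contexts in canonical order."""

    sample_id: str
    counts: np.ndarray

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.shape != (96,):
            raise ValueError(f"catalog must have 96 entries, got {self.counts.shape}")
        if (self.counts < 0).any():
            raise ValueError("catalog counts must be non-negative")

    @property
    def total(self) -> float:
        return float(self.counts.sum())


@dataclass
class ExposureVector:
    """Fitted signature contributions for one sample."""

    sample_id: str
    counts: dict            # signature -> mutation count
    fractions: dict         # signature -> fraction of catalog
    cosine: float
    log_likelihood: float
    n_iter: int
    removed: list = field(default_factory=list)

    @property
    def apobec_fraction(self) -> float:
        return sum(self.fractions.get(s, 0.0) for s in APOBEC_SIGNATURES)

    def get(self, name, default=0.0):
        return self.fractions.get(name, default)


@dataclass
class ApobecContextSummary:
    sample_id: str
    n_ytca: int
    n_rtca: int
    ratio_3a_3b: float | None
    apobec_detected: bool


def build_catalog(mutations, sample_id: str | None = None) -> Catalog96:
    """Count mutations per 96-context class (contexts already collapsed)."""
    if isinstance(mutations, pd.DataFrame):
        contexts = mutations["context"]
        sid = sample_id or (mutations["sample_id"].iloc[0] if len(mutations) else "")
    else:
        contexts = [m.context for m in mutations]
        sid = sample_id or (mutations[0].sample_id if mutations else "")
    counts = np.zeros(96)
    for c in contexts:
        counts[CONTEXT_INDEX[c]] += 1
    return Catalog96(sample_id=sid, counts=counts)


def cosine_similarity(a, b) -> float:
    a, b = np.asarray(a, float), np.asarray(b, float)
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        return 0.0
    return float(a @ b / (na * nb))


def fit_exposures(catalog: Catalog96, signatures, tol: float = 1e-8,
                  max_iter: int = 10_000, return_trace: bool = False):
    """Maximum-likelihood non-negative exposures by multinomial EM.

    e_k <- e_k * sum_c x_c S_ck / sum_j e_j S_cj / N; log-likelihood is
    non-decreasing and iteration stops when its gain drops below ``tol``.
    With ``return_trace`` also returns the per-iteration log-likelihoods.
    """
    x = catalog.counts
    n = x.sum()
    if n <= 0:
        raise ValueError("cannot fit an empty catalog")
    S = signatures.values()                     # (96, k)
    k = S.shape[1]
    e = np.full(k, 1.0 / k)
    prev_ll = -np.inf
    ll = prev_ll
    nz = x > 0
    trace = []
    for it in range(1, max_iter + 1):
        mix = S @ e                             # (96,)
        ll = float(x[nz] @ np.log(mix[nz]))
        trace.append(ll)
        if ll - prev_ll < tol and it > 1:
            break
        prev_ll = ll
        resp = S * e                            # (96, k)
        resp /= np.clip(mix[:, None], 1e-300, None)
        e = (x @ resp) / n
        e = np.clip(e, 0, None)
        e /= e.sum()
    recon = S @ e
    counts = dict(zip(signatures.names, (e * n)))
    fractions = dict(zip(signatures.names, e))
    result = ExposureVector(sample_id=catalog.sample_id, counts=counts,
                            fractions=fractions,
                            cosine=cosine_similarity(x, recon),
                            log_likelihood=ll, n_iter=it)
    return (result, trace) if return_trace else result


def _removal_groups(names, protected):
    """Candidate removal groups: APOBEC pair moves as one unit."""
    apobec = [n for n in names if n in APOBEC_SIGNATURES]
    groups = [[n] for n in names if n not in protected and n not in APOBEC_SIGNATURES]
    if apobec:
        groups.append(apobec)
    return groups


def backward_eliminate(catalog: Catalog96, signatures, threshold: float = 0.01,
                       protected=CLOCK_SIGNATURES) -> ExposureVector:
    """Iteratively drop low-contributing signatures at negligible cosine cost.

    At each round the fitted model's removable signature (or the SBS2/SBS13
    pair, treated jointly) groups are tried in ascending order of
    contribution; the first whose removal drops reconstruction cosine by
    less than ``threshold`` is eliminated and the loop restarts. SBS1 and
    SBS5 are never removed.
    """
    protected = set(protected)
    current = list(signatures.names)
    fit = fit_exposures(catalog, signatures.subset(current))
    removed_log = []
    while True:
        groups = _removal_groups(current, protected)
        groups.sort(key=lambda g: sum(fit.fractions[n] for n in g))
        accepted = False
        for group in groups:
            reduced = [n for n in current if n not in group]
            if not reduced:
                continue
            trial = fit_exposures(catalog, signatures.subset(reduced))
            if fit.cosine - trial.cosine < threshold:
                current = reduced
                removed_log.extend(group)
                fit = trial
                accepted = True
                break
        if not accepted:
            break
    fit.removed = removed_log
    return fit


def apobec_metrics(mutations, exposures: ExposureVector) -> ApobecContextSummary:
    """YTCA vs RTCA split of tCa-motif mutations: the APOBEC3A:3B ratio.

    APOBEC3A favors YTCA (5'-2 pyrimidine), APOBEC3B RTCA. The ratio is
    undefined (None) when no RTCA mutations exist or when the sample has no
    detectable APOBEC activity after elimination.
    """
    if isinstance(mutations, pd.DataFrame):
        ctx = mutations["context"]
        fp2 = mutations["five_prime2"]
        sid = exposures.sample_id
    else:
        ctx = pd.Series([m.context for m in mutations])
        fp2 = pd.Series([m.five_prime2 for m in mutations])
        sid = exposures.sample_id
    at_tca = ctx.isin(APOBEC_TCA_CONTEXTS)
    if at_tca.any() and fp2[at_tca].isna().any():
        raise ValueError(
            "tCa-motif mutations lack pentanucleotide context; re-extract "
            "contexts with flank >= 2 to compute the APOBEC3A:3B ratio")
    n_ytca = int((at_tca & fp2.isin(["C", "T"])).sum())
    n_rtca = int((at_tca & fp2.isin(["A", "G"])).sum())
    detected = exposures.apobec_fraction > 0
    ratio = n_ytca / n_rtca if (detected and n_rtca > 0) else None
    return ApobecContextSummary(sample_id=sid, n_ytca=n_ytca, n_rtca=n_rtca,
                                ratio_3a_3b=ratio, apobec_detected=detected)


def catalogs_to_frame(catalogs: list[Catalog96]) -> pd.DataFrame:
    """96 x samples TSV-ready table."""
    return pd.DataFrame({c.sample_id: c.counts for c in catalogs},
                        index=list(SBS96_CONTEXTS))


def exposures_to_frame(exposures: list[ExposureVector]) -> pd.DataFrame:
    rows = []
    for e in exposures:
        row = {"sample_id": e.sample_id, "cosine": e.cosine,
               "apobec_fraction": e.apobec_fraction,
               "removed": ";".join(e.removed)}
        row.update({f"{k}_count": v for k, v in e.counts.items()})
        row.update({f"{k}_fraction": v for k, v in e.fractions.items()})
        rows.append(row)
    return pd.DataFrame(rows)
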