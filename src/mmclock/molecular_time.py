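"""Molecular-clock timing of large chromosomal gains.

A clonal mutation acquired before a single-allele gain sits on both copies
of the duplicated allele (multiplicity 2); mutations acquired afterwards,
or on the untouched allele, have multiplicity 1. With a constant per-allele
mutation rate and a gain at relative time t in (0,1] of the clone's life,

    trisomy-like (major=2, minor=1):  E[N2] = mu t, E[N1] = mu t + 3 mu (1-t)
    CN-LOH        (major=2, minor=0):  E[N2] = mu t, E[N1] = 2 mu (1-t)

which invert to  t = 3 N2 / (N1 + 2 N2)  and  t = 2 N2 / (N1 + 2 N2).
Tetrasomies (2,2) cannot be timed (the two gains' order is unidentifiable)
and are excluded, as are segments <= 1 Mb or with <= 50 clonal mutations.
Restricting the counts to the clock-like SBS1+SBS5 burden — which
accumulates roughly linearly with age — converts the earliest multi-gain
event's molecular time into an absolute patient age, with 1000x bootstrap
confidence intervals throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genome import is_sex_chrom
from .synthetic_signatures import CLOCK_SIGNATURES

GAIN_CLASSES = {(2, 1): "gain_2_1", (2, 0): "cnloh_2_0", (2, 2): "tetrasomy_2_2"}
MIN_SEGMENT_LENGTH = 1_000_000     # strictly larger than 1 Mb required
MIN_CLONAL_MUTATIONS = 50          # strictly more than 50 required
MIN_CLOCK_MUTATIONS = 50           # weighted SBS1+SBS5 count for age conversion


@dataclass
class GainTiming:
    """One timed (or excluded) chromosomal-gain segment."""

    chrom: str
    start: int
    end: int
    gain_class: str
    n2: int = 0
    n1: int = 0
    t: float | None = None
    ci_low: float | None = None
    ci_high: float | None = None
    eligible: bool = True
    reason: str = ""
    clamped: bool = False
    mutation_index: np.ndarray | None = None   # row indices of member clonal muts

    @property
    def segment_id(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}"


@dataclass
class MultiGainWindow:
    """Gains whose timing CIs mutually overlap: one multi-gain event."""

    members: list
    t_mean: float
    is_earliest: bool = False
    w2: float | None = None
    w1: float | None = None
    t_clock: float | None = None
    age_estimate: float | None = None
    age_ci: tuple | None = None
    converted: bool = False
    reason: str = ""
    flags: set = field(default_factory=set)


def relative_time(n2: float, n1: float, gain_class: str) -> float:
    """Relative molecular time of a gain from duplicated/non-duplicated counts.

    Clamped to [0, 1]; sampling noise can push the raw ratio above 1.
    """
    if gain_class == "tetrasomy_2_2":
        raise ValueError("tetrasomies are untimeable and must be filtered out")
    if gain_class not in ("gain_2_1", "cnloh_2_0"):
        raise ValueError(f"unknown gain class {gain_class!r}")
    if n2 < 0 or n1 < 0 or n2 + n1 <= 0:
        raise ValueError(f"need N2 + N1 > 0, got N2={n2}, N1={n1}")
    k = 3.0 if gain_class == "gain_2_1" else 2.0
    return float(min(1.0, max(0.0, k * n2 / (n1 + 2.0 * n2))))


def _raw_time(n2, n1, gain_class):
    k = 3.0 if gain_class == "gain_2_1" else 2.0
    return k * n2 / (n1 + 2.0 * n2)


def eligible_gains(segments: pd.DataFrame, calls: pd.DataFrame,
                   min_length: int = MIN_SEGMENT_LENGTH,
                   min_clonal: int = MIN_CLONAL_MUTATIONS,
                   include_sex: bool = False) -> list[GainTiming]:
    """Identify timeable gain segments and record exclusion reasons.

    A segment is a candidate when major_cn == 2 and minor_cn in {0, 1, 2};
    it is eligible when longer than ``min_length``, carrying more than
    ``min_clonal`` clonal mutations, and not a tetrasomy. ``calls`` is the
    per-mutation frame from clonality with multiplicity and clonal columns.
    """
    out = []
    clonal = calls[(calls.get("assigned", True) == True) & calls["clonal"]]  # noqa: E712
    for idx, seg in segments.iterrows():
        key = (int(seg.major_cn), int(seg.minor_cn))
        if key not in GAIN_CLASSES:
            continue
        gt = GainTiming(chrom=seg.chrom, start=int(seg.start), end=int(seg.end),
                        gain_class=GAIN_CLASSES[key])
        inside = clonal[(clonal.chrom == seg.chrom)
                        & (clonal.pos >= seg.start) & (clonal.pos <= seg.end)]
        gt.n2 = int((inside.multiplicity == 2).sum())
        gt.n1 = int((inside.multiplicity == 1).sum())
        gt.mutation_index = inside.index.to_numpy()
        if gt.gain_class == "tetrasomy_2_2":
            gt.eligible, gt.reason = False, "tetrasomy"
        elif not include_sex and is_sex_chrom(seg.chrom):
            gt.eligible, gt.reason = False, "sex_chromosome"
        elif seg.end - seg.start + 1 <= min_length:
            gt.eligible, gt.reason = False, "segment_too_short"
        elif gt.n2 + gt.n1 <= min_clonal:
            gt.eligible, gt.reason = False, "too_few_clonal_mutations"
        out.append(gt)
    return out


def bootstrap_ci(multiplicities, gain_class: str, n_boot: int = 1000,
                 rng: np.random.Generator | None = None,
                 weights=None) -> tuple[float, float]:
    """Percentile bootstrap CI of the relative time over the mutations.

    Mutations are resampled with replacement ``n_boot`` times. For
    unweighted counts the resampled duplicated count is drawn directly as
    Binomial(n, N2/n) — the exact distribution of the count under index
    resampling. With per-mutation weights (SBS1+SBS5 posteriors) indices
    are resampled explicitly.
    """
    rng = rng or np.random.default_rng()
    m = np.asarray(multiplicities)
    n = len(m)
    if n < 10:
        raise ValueError(f"bootstrap_ci requires >= 10 mutations, got {n}")
    if weights is None:
        n2 = int((m == 2).sum())
        n2_star = rng.binomial(n, n2 / n, size=n_boot)
        k = 3.0 if gain_class == "gain_2_1" else 2.0
        with np.errstate(divide="ignore", invalid="ignore"):
            t_star = k * n2_star / ((n - n2_star) + 2.0 * n2_star)
        t_star = np.clip(np.nan_to_num(t_star, nan=0.0), 0.0, 1.0)
    else:
        w = np.asarray(weights, dtype=float)
        idx = rng.integers(0, n, size=(n_boot, n))
        w2 = np.where(m == 2, w, 0.0)[idx].sum(axis=1)
        w1 = np.where(m == 1, w, 0.0)[idx].sum(axis=1)
        k = 3.0 if gain_class == "gain_2_1" else 2.0
        with np.errstate(divide="ignore", invalid="ignore"):
            t_star = k * w2 / (w1 + 2.0 * w2)
        t_star = np.clip(np.nan_to_num(t_star, nan=0.0), 0.0, 1.0)
    lo, hi = np.percentile(t_star, [2.5, 97.5])
    return float(lo), float(hi)


def time_gains(gains: list[GainTiming], calls: pd.DataFrame, n_boot: int = 1000,
               rng: np.random.Generator | None = None) -> list[GainTiming]:
    """Fill t and bootstrap CI for each eligible gain (in place)."""
    rng = rng or np.random.default_rng()
    for g in gains:
        if not g.eligible:
            continue
        g.t = relative_time(g.n2, g.n1, g.gain_class)
        g.clamped = _raw_time(g.n2, g.n1, g.gain_class) > 1.0
        m = calls.loc[g.mutation_index, "multiplicity"].to_numpy()
        g.ci_low, g.ci_high = bootstrap_ci(m, g.gain_class, n_boot=n_boot, rng=rng)
        g.ci_low = min(g.ci_low, g.t)
        g.ci_high = max(g.ci_high, g.t)
    return gains


def group_windows(timings: list[GainTiming]) -> list[MultiGainWindow]:
    """Greedily merge gains whose 95% CIs all mutually overlap.

    Gains are scanned in ascending t; a gain joins the current window only
    if its CI overlaps the CI of every member. The window with the smallest
    mean t is marked earliest.
    """
    timed = sorted([g for g in timings if g.eligible and g.t is not None],
                   key=lambda g: g.t)
    if not timed:
        return []
    windows: list[list[GainTiming]] = []
    for g in timed:
        placed = False
        if windows:
            current = windows[-1]
            if all(g.ci_low <= m.ci_high and m.ci_low <= g.ci_high for m in current):
                current.append(g)
                placed = True
        if not placed:
            windows.append([g])
    out = [MultiGainWindow(members=w, t_mean=float(np.mean([g.t for g in w])))
           for w in windows]
    min(out, key=lambda w: w.t_mean).is_earliest = True
    return out


def clock_mutation_weights(contexts, exposures: dict, signatures) -> np.ndarray:
    """Posterior probability that each mutation arose from SBS1 or SBS5.

    w_i = sum_{k in clock} e_k S_k(c_i) / sum_k e_k S_k(c_i), with e the
    fitted exposure fractions and S the signature profiles.
    """
    names = [n for n in signatures.names if exposures.get(n, 0) > 0]
    clock = [n for n in names if n in CLOCK_SIGNATURES]
    if not clock:
        raise ValueError("exposures contain neither SBS1 nor SBS5; "
                         "clock conversion impossible")
    S = signatures.data[names].values                      # (96, k)
    e = np.array([exposures[n] for n in names])
    ctx_idx = signatures.data.index.get_indexer(list(contexts))
    if (ctx_idx < 0).any():
        raise ValueError("unknown context label among mutations")
    probs = S[ctx_idx] * e                                  # (n, k)
    total = probs.sum(axis=1)
    clock_cols = [names.index(n) for n in clock]
    with np.errstate(invalid="ignore", divide="ignore"):
        w = probs[:, clock_cols].sum(axis=1) / total
    return np.nan_to_num(w, nan=0.0)


def clock_time_and_age(window: MultiGainWindow, calls: pd.DataFrame,
                       exposures: dict, signatures, age_at_sampling: float,
                       n_boot: int = 1000,
                       rng: np.random.Generator | None = None,
                       min_clock: int = MIN_CLOCK_MUTATIONS) -> MultiGainWindow:
    """SBS1/SBS5-weighted molecular time of a multi-gain window, in years.

    Pools clock-weighted duplicated (W2) and non-duplicated (W1) counts over
    all member gains, recomputes the relative time from them, and converts
    it to an absolute age as t_clock x age_at_sampling (assuming a constant
    clock rate from birth to sampling). Windows mixing gain classes combine
    per-member clock times as a (W2+W1)-weighted mean and are flagged.
    Windows with W2 + W1 <= ``min_clock`` are not converted.
    """
    rng = rng or np.random.default_rng()
    idx = np.concatenate([g.mutation_index for g in window.members])
    member_class = np.concatenate([
        np.repeat(i, len(g.mutation_index)) for i, g in enumerate(window.members)])
    classes = [g.gain_class for g in window.members]
    sub = calls.loc[idx]
    w = clock_mutation_weights(sub["context"], exposures, signatures)
    m = sub["multiplicity"].to_numpy()

    def window_t(w, m, member_class):
        if len(set(classes)) == 1:
            w2 = w[m == 2].sum()
            w1 = w[m == 1].sum()
            return window_t_counts(w2, w1, classes[0]), w2, w1
        ts, masses = [], []
        for i, cls in enumerate(classes):
            sel = member_class == i
            w2 = w[sel & (m == 2)].sum()
            w1 = w[sel & (m == 1)].sum()
            if w2 + w1 > 0:
                ts.append(window_t_counts(w2, w1, cls))
                masses.append(w2 + w1)
        return (float(np.average(ts, weights=masses)) if ts else None,
                w[m == 2].sum(), w[m == 1].sum())

    def window_t_counts(w2, w1, cls):
        if w2 + w1 <= 0:
            return 0.0
        k = 3.0 if cls == "gain_2_1" else 2.0
        return float(min(1.0, max(0.0, k * w2 / (w1 + 2.0 * w2))))

    t_clock, w2, w1 = window_t(w, m, member_class)
    window.w2, window.w1, window.t_clock = float(w2), float(w1), t_clock
    if len(set(classes)) > 1:
        window.flags.add("mixed_gain_classes")
    if w2 + w1 <= min_clock:
        window.converted = False
        window.reason = "too_few_clock_mutations"
        return window

    window.age_estimate = t_clock * age_at_sampling
    n = len(idx)
    boots = np.empty(n_boot)
    bidx = rng.integers(0, n, size=(n_boot, n))
    for b in range(n_boot):
        tb, _, _ = window_t(w[bidx[b]], m[bidx[b]], member_class[bidx[b]])
        boots[b] = tb if tb is not None else np.nan
    lo, hi = np.nanpercentile(boots, [2.5, 97.5])
    window.age_ci = (float(lo * age_at_sampling), float(hi * age_at_sampling))
    window.converted = True
    return window


def gains_to_frame(gains: list[GainTiming], sample_id: str = "") -> pd.DataFrame:
    return pd.DataFrame([{
        "sample_id": sample_id, "segment": g.segment_id, "gain_class": g.gain_class,
        "n2": g.n2, "n1": g.n1, "t": g.t, "ci_low": g.ci_low, "ci_high": g.ci_high,
        "eligible": g.eligible, "reason": g.reason, "clamped": g.clamped,
    } for g in gains])


def windows_to_frame(windows: list[MultiGainWindow], sample_id: str = "",
                     age_at_sampling: float | None = None,
                     group: str = "") -> pd.DataFrame:
    return pd.DataFrame([{
        "sample_id": sample_id, "group": group,
        "members": ";".join(g.segment_id for g in w.members),
        "t_mean": w.t_mean, "is_earliest": w.is_earliest,
        "w2": w.w2, "w1": w.w1, "t_clock": w.t_clock,
        "age_estimate": w.age_estimate,
        "age_ci_low": w.age_ci[0] if w.age_ci else None,
        "age_ci_high": w.age_ci[1] if w.age_ci else None,
        "converted": w.converted, "reason": w.reason,
        "age_at_sampling": age_at_sampling,
        "flags": ";".join(sorted(w.flags)),
    } for w in windows])
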