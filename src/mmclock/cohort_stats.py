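"""Cohort-level comparison statistics.

Pairwise two-sided Wilcoxon rank-sum tests with Benjamini-Hochberg FDR
adjustment (exact enumeration when both groups have n <= 25 and no ties,
the R ``pairwise.wilcox.test`` behavior), two-sided Fisher's exact tests by
the point-probability convention, per-interval copy-number prevalence
contrasts, and ordinary least-squares burden regression.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests


@dataclass
class GroupComparison:
    feature: str
    group_a: str
    group_b: str
    statistic: float
    p: float
    q: float | None
    test: str
    flags: str = ""


def _wilcoxon_two_sample(x, y, alternative="two-sided"):
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    combined = np.concatenate([x, y])
    has_ties = len(np.unique(combined)) < len(combined)
    exact = (len(x) <= 25 and len(y) <= 25 and not has_ties)
    res = stats.mannwhitneyu(x, y, alternative=alternative,
                             method="exact" if exact else "asymptotic")
    return float(res.statistic), float(res.pvalue), "wilcoxon_exact" if exact \
        else "wilcoxon_normal"


def pairwise_wilcoxon_fdr(values_by_group: dict, feature: str = "",
                          alternative: str = "two-sided") -> list[GroupComparison]:
    """All pairwise rank-sum tests for one feature, BH-adjusted across pairs."""
    if len(values_by_group) < 2:
        raise ValueError("need >= 2 groups")
    for name, vals in values_by_group.items():
        if len(vals) < 2:
            raise ValueError(f"group {name!r} has fewer than 2 values")
    pairs = list(combinations(sorted(values_by_group), 2))
    results = []
    for a, b in pairs:
        u, p, test = _wilcoxon_two_sample(values_by_group[a], values_by_group[b],
                                          alternative)
        results.append(GroupComparison(feature=feature, group_a=a, group_b=b,
                                       statistic=u, p=p, q=None, test=test))
    qs = multipletests([r.p for r in results], method="fdr_bh")[1]
    for r, q in zip(results, qs):
        r.q = float(q)
    return results


def fisher_prevalence(k1: int, n1: int, k2: int, n2: int,
                      feature: str = "", group_a: str = "a",
                      group_b: str = "b") -> GroupComparison:
    """Two-sided Fisher's exact test on affected/unaffected counts."""
    if not (0 <= k1 <= n1 and 0 <= k2 <= n2):
        raise ValueError("need 0 <= k <= n in both groups")
    table = [[k1, n1 - k1], [k2, n2 - k2]]
    flags = ""
    if n1 == 0 or n2 == 0 or (k1 + k2 == 0) or ((n1 - k1) + (n2 - k2) == 0):
        p, odds = 1.0, float("nan")
        flags = "degenerate_margins"
    else:
        odds, p = stats.fisher_exact(table, alternative="two-sided")
    return GroupComparison(feature=feature, group_a=group_a, group_b=group_b,
                           statistic=float(odds), p=float(p), q=None,
                           test="fisher_exact", flags=flags)


@dataclass
class BinPrevalence:
    interval: str
    direction: str
    counts: dict            # group -> affected count
    sizes: dict             # group -> group size
    contrasts: list         # GroupComparison per pairwise contrast
    excluded: bool = False  # no signal anywhere: kept out of the BH family


def interval_states(segments_by_sample: dict, intervals: pd.DataFrame,
                    neutral_cn: int = 2) -> pd.DataFrame:
    """Per sample x interval gain/loss state from clonal segment overlap.

    gained: any overlapping segment with total CN > neutral; lost: < neutral.
    """
    rows = []
    for sid, segs in segments_by_sample.items():
        for _, iv in intervals.iterrows():
            hit = segs[(segs.chrom == str(iv.chrom)) & (segs.end >= iv.start)
                       & (segs.start <= iv.end)]
            rows.append({
                "sample_id": sid,
                "interval": f"{iv.chrom}:{iv.start}-{iv.end}",
                "gained": bool((hit.total_cn > neutral_cn).any()),
                "lost": bool((hit.total_cn < neutral_cn).any()),
            })
    return pd.DataFrame(rows)


def cnv_bin_prevalence(segments_by_sample: dict, intervals: pd.DataFrame,
                       groups: dict, direction: str = "gained",
                       neutral_cn: int = 2) -> list[BinPrevalence]:
    """Fisher contrasts of per-interval CNV prevalence between groups.

    BH adjustment runs per pairwise contrast across the intervals that show
    the aberration in at least one sample; all-negative intervals are
    excluded from the family and flagged.
    """
    states = interval_states(segments_by_sample, intervals, neutral_cn)
    states["group"] = states.sample_id.map(groups)
    group_names = sorted(set(groups.values()))
    sizes = {g: len({s for s, gg in groups.items() if gg == g}) for g in group_names}
    out = []
    for interval, sub in states.groupby("interval", sort=False):
        counts = sub.groupby("group")[direction].sum().to_dict()
        counts = {g: int(counts.get(g, 0)) for g in group_names}
        bp = BinPrevalence(interval=interval, direction=direction, counts=counts,
                           sizes=sizes, contrasts=[])
        if sum(counts.values()) == 0:
            bp.excluded = True
            for a, b in combinations(group_names, 2):
                bp.contrasts.append(GroupComparison(
                    feature=interval, group_a=a, group_b=b, statistic=float("nan"),
                    p=1.0, q=None, test="fisher_exact", flags="no_signal"))
        else:
            for a, b in combinations(group_names, 2):
                c = fisher_prevalence(counts[a], sizes[a], counts[b], sizes[b],
                                      feature=interval, group_a=a, group_b=b)
                bp.contrasts.append(c)
        out.append(bp)
    # BH per contrast across non-excluded intervals
    for pair_idx in range(len(list(combinations(group_names, 2)))):
        family = [bp.contrasts[pair_idx] for bp in out if not bp.excluded]
        if family:
            qs = multipletests([c.p for c in family], method="fdr_bh")[1]
            for c, q in zip(family, qs):
                c.q = float(q)
    return out


def regress_burden(x, y) -> tuple[float, float, float, float]:
    """OLS of burden on a covariate: (slope, intercept, R^2, two-sided p)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) < 3 or len(x) != len(y):
        raise ValueError("need >= 3 paired points")
    if np.allclose(y, y[0]):
        return 0.0, float(y[0]), 0.0, 1.0
    res = stats.linregress(x, y)
    return (float(res.slope), float(res.intercept),
            float(res.rvalue ** 2), float(res.pvalue))


def comparisons_to_frame(comparisons: list[GroupComparison]) -> pd.DataFrame:
    return pd.DataFrame([{
        "feature": c.feature, "group_a": c.group_a, "group_b": c.group_b,
        "statistic": c.statistic, "p": c.p, "q": c.q, "test": c.test,
        "flags": c.flags,
    } for c in comparisons])
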