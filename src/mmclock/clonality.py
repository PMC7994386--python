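"""Purity-corrected cancer cell fractions, mutation multiplicity, clonality.

A clonal mutation present on ``m`` of the ``n_t`` tumor copies at a locus,
in a tumor of purity rho, is expected at VAF

    rho * m * ccf / (rho * n_t + (1 - rho) * n_n)

with n_n the normal copy number (2 on autosomes). In a pure single-allele
gain (major=2, minor=1) region this puts duplicated (m=2) clonal mutations
at 2/3 and non-duplicated (m=1) ones at 1/3 — the contrast that makes gains
timeable. Multiplicity is called per mutation by a binomial likelihood test
of the two VAF hypotheses, and clonal/subclonal status by a finite binomial
mixture over CCF with BIC model selection (a deterministic stand-in for
Dirichlet-process clustering: downstream timing only needs the
clonal/subclonal split, not the full posterior).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import binom

#: cluster-center CCF above which a cluster is considered clonal
CLONAL_CCF_THRESHOLD = 0.85


def expected_vaf(m: int, ccf: float, purity: float,
                 tumor_total_cn: int, normal_cn: int = 2) -> float:
    """Expected VAF of a mutation on ``m`` copies at cancer cell fraction ``ccf``."""
    if not (0 < purity <= 1):
        raise ValueError(f"purity must be in (0,1], got {purity}")
    if m < 1:
        raise ValueError(f"multiplicity must be >= 1, got {m}")
    if ccf < 0:
        raise ValueError(f"ccf must be >= 0, got {ccf}")
    denom = purity * tumor_total_cn + (1 - purity) * normal_cn
    if denom <= 0:
        raise ValueError(
            f"no sequenceable DNA at locus: purity={purity}, tumor_cn={tumor_total_cn}, "
            f"normal_cn={normal_cn}")
    vaf = purity * m * ccf / denom
    if vaf > 1:
        raise ValueError(
            f"inconsistent parameters (expected VAF {vaf:.3f} > 1): "
            f"m={m}, ccf={ccf}, purity={purity}, tumor_cn={tumor_total_cn}")
    return vaf


@dataclass
class MultiplicityCall:
    mutation_id: str
    multiplicity: int
    posterior_m2: float
    ccf: float
    clonal: bool = True
    flags: set = field(default_factory=set)


def assign_multiplicity(mut, seg, purity: float) -> MultiplicityCall:
    """Call duplicated (m=2) vs non-duplicated (m=1) for one mutation.

    Binomial likelihoods of the observed alt count under the clonal m=1 and
    m=2 expected VAFs, equal priors; m=2 requires major_cn >= 2; exact
    likelihood ties go to m=1 (conservative, biases timing late).
    """
    if not seg.contains(mut.chrom, mut.pos):
        raise ValueError(f"mutation {mut.locus} not inside segment "
                         f"{seg.chrom}:{seg.start}-{seg.end}")
    df = assign_multiplicities(
        pd.DataFrame({"id": [mut.id or mut.locus], "alt_count": [mut.alt_count],
                      "depth": [mut.depth]}),
        purity=purity, tumor_cn=seg.total_cn, major_cn=seg.major_cn)
    row = df.iloc[0]
    return MultiplicityCall(mutation_id=row["id"], multiplicity=int(row.multiplicity),
                            posterior_m2=float(row.posterior_m2), ccf=float(row.ccf))


def assign_multiplicities(muts: pd.DataFrame, purity: float,
                          tumor_cn: int, major_cn: int) -> pd.DataFrame:
    """Vectorized multiplicity calls for mutations sharing one segment."""
    alt = muts["alt_count"].to_numpy()
    depth = muts["depth"].to_numpy()
    p1 = expected_vaf(1, 1.0, purity, tumor_cn)
    out = muts.copy()
    q = purity / (purity * tumor_cn + (1 - purity) * 2)
    with np.errstate(divide="ignore", invalid="ignore"):
        out["ccf"] = np.where(depth > 0, alt / np.maximum(depth, 1) / q, np.nan)
    if major_cn < 2:
        out["multiplicity"] = 1
        out["posterior_m2"] = 0.0
        return out
    p2 = min(expected_vaf(2, 1.0, purity, tumor_cn), 1.0 - 1e-12)
    ll1 = binom.logpmf(alt, depth, p1)
    ll2 = binom.logpmf(alt, depth, p2)
    # ties -> m=1; the tolerance absorbs float noise in analytically equal pmfs
    out["multiplicity"] = np.where(ll2 > ll1 + 1e-9, 2, 1)
    out["posterior_m2"] = 1.0 / (1.0 + np.exp(np.clip(ll1 - ll2, -700, 700)))
    return out


def call_sample(muts: pd.DataFrame, segments: pd.DataFrame, purity: float,
                exclude_sex: bool = True) -> pd.DataFrame:
    """Map each mutation to its copy-number segment and call multiplicity.

    Returns the mutation frame augmented with segment columns, multiplicity,
    posterior, raw CCF and an ``assigned`` flag (mutations outside all
    segments are kept but flagged and excluded downstream).
    """
    out_parts = []
    seg_cols = ["seg_idx", "major_cn", "minor_cn", "total_cn", "seg_start", "seg_end"]
    for chrom, grp in muts.groupby("chrom", sort=False):
        segs = segments[segments.chrom == chrom].sort_values("start")
        if exclude_sex and len(segs) and segs.is_sex.iloc[0]:
            segs = segs  # sex chromosomes still mapped; exclusion happens in timing
        pos = grp["pos"].to_numpy()
        part = grp.copy()
        if not len(segs):
            part["assigned"] = False
            for c in seg_cols:
                part[c] = np.nan
            out_parts.append(part)
            continue
        starts = segs["start"].to_numpy()
        ends = segs["end"].to_numpy()
        idx = np.searchsorted(starts, pos, side="right") - 1
        ok = (idx >= 0) & (pos <= ends[np.clip(idx, 0, len(ends) - 1)])
        part["assigned"] = ok
        safe = np.clip(idx, 0, len(segs) - 1)
        part["seg_idx"] = segs.index.to_numpy()[safe]
        part["major_cn"] = segs["major_cn"].to_numpy()[safe]
        part["minor_cn"] = segs["minor_cn"].to_numpy()[safe]
        part["total_cn"] = segs["total_cn"].to_numpy()[safe]
        part["seg_start"] = segs["start"].to_numpy()[safe]
        part["seg_end"] = segs["end"].to_numpy()[safe]
        out_parts.append(part)
    out = pd.concat(out_parts).loc[muts.index]
    out["multiplicity"] = 1
    out["posterior_m2"] = 0.0
    out["ccf"] = np.nan
    for (tot, maj), grp in out[out.assigned].groupby(["total_cn", "major_cn"]):
        called = assign_multiplicities(grp, purity, int(tot), int(maj))
        out.loc[grp.index, ["multiplicity", "posterior_m2", "ccf"]] = \
            called[["multiplicity", "posterior_m2", "ccf"]]
    return out


# ---------------------------------------------------------------------------
# clonal/subclonal mixture model


@dataclass
class ClonalModel:
    """Finite binomial mixture over CCF: centers, weights, and diagnostics."""

    centers: np.ndarray
    weights: np.ndarray
    n_clusters: int
    purity: float
    log_likelihood: float
    assignments: np.ndarray          # cluster index per mutation
    clonal: np.ndarray               # boolean per mutation
    vaf_purity_estimate: float | None
    purity_discordant: bool
    converged: bool = True

    @property
    def clonal_clusters(self) -> np.ndarray:
        return np.where(self.centers >= CLONAL_CCF_THRESHOLD)[0]

    def to_dict(self) -> dict:
        return {
            "centers": self.centers.round(4).tolist(),
            "weights": self.weights.round(4).tolist(),
            "n_clusters": int(self.n_clusters),
            "purity": self.purity,
            "log_likelihood": float(self.log_likelihood),
            "vaf_purity_estimate": self.vaf_purity_estimate,
            "purity_discordant": bool(self.purity_discordant),
        }


def _mle_ccf(resp, alt, depth, q, lo=1e-4):
    """Per-cluster CCF maximizing the responsibility-weighted binomial LL.

    The score d/dc sum_i r_i [a_i/c - (d_i - a_i) q_i / (1 - q_i c)] is
    strictly decreasing in c, so bisection on it is exact.
    """
    hi = min(0.999 / q.max(), 1.5)
    a = resp * alt
    b = resp * (depth - alt)
    if a.sum() <= 0:
        return lo
    def score(c):
        return a.sum() / c - np.sum(b * q / (1 - q * c))
    if score(hi) >= 0:
        return hi
    clo, chi = lo, hi
    for _ in range(60):
        mid = 0.5 * (clo + chi)
        if score(mid) > 0:
            clo = mid
        else:
            chi = mid
    return 0.5 * (clo + chi)


def fit_clonal_model(calls: pd.DataFrame, purity: float, max_k: int = 4,
                     max_iter: int = 2000, tol: float = 1e-8) -> ClonalModel:
    """Fit binomial mixtures over CCF for K=1..max_k; select K by BIC.

    ``calls`` must carry alt_count, depth, multiplicity, total_cn for
    assigned mutations. Mutations are assigned clonal iff their cluster
    center is >= 0.85 CCF. Also derives a VAF-based purity check as
    2 x median VAF of clonal diploid m=1 mutations, flagged when it
    disagrees with the supplied purity by > 0.1.
    """
    df = calls[calls.get("assigned", True) == True]  # noqa: E712
    if len(df) < 50:
        raise ValueError(f"fit_clonal_model requires >= 50 assigned mutations, got {len(df)}")
    alt = df["alt_count"].to_numpy(float)
    depth = df["depth"].to_numpy(float)
    m = df["multiplicity"].to_numpy(float)
    nt = df["total_cn"].to_numpy(float)
    q = purity * m / (purity * nt + (1 - purity) * 2)  # VAF per unit CCF
    n = len(df)

    best = None
    for k in range(1, max_k + 1):
        centers = np.linspace(1.0, 0.25, k)
        weights = np.full(k, 1.0 / k)
        prev_ll = -np.inf
        converged = False
        for _ in range(max_iter):
            p = np.clip(np.outer(q, centers), 1e-9, 1 - 1e-9)
            logp = (np.log(weights)[None, :] + alt[:, None] * np.log(p)
                    + (depth - alt)[:, None] * np.log1p(-p))
            mx = logp.max(axis=1, keepdims=True)
            lse = mx[:, 0] + np.log(np.exp(logp - mx).sum(axis=1))
            ll = lse.sum()
            resp = np.exp(logp - lse[:, None])
            weights = np.clip(resp.mean(axis=0), 1e-9, None)
            weights /= weights.sum()
            for j in range(k):
                centers[j] = _mle_ccf(resp[:, j], alt, depth, q)
            if abs(ll - prev_ll) < tol * max(1.0, abs(ll)):
                converged = True
                break
            prev_ll = ll
        if not converged:
            raise RuntimeError(
                f"clonal mixture EM did not converge (K={k}, last LL={ll:.3f}, "
                f"previous {prev_ll:.3f})")
        bic = -2 * ll + (2 * k - 1) * np.log(n)
        if best is None or bic < best[0]:
            best = (bic, k, centers.copy(), weights.copy(), ll, resp.argmax(axis=1))

    _, k, centers, weights, ll, assign = best
    clonal = centers[assign] >= CLONAL_CCF_THRESHOLD

    diploid_m1 = (nt == 2) & (m == 1) & clonal & (depth > 0)
    vaf_purity = None
    discordant = False
    if diploid_m1.sum() >= 10:
        vaf_purity = float(2 * np.median(alt[diploid_m1] / depth[diploid_m1]))
        discordant = abs(vaf_purity - purity) > 0.1
    return ClonalModel(centers=centers, weights=weights, n_clusters=k, purity=purity,
                       log_likelihood=float(ll), assignments=assign, clonal=clonal,
                       vaf_purity_estimate=vaf_purity, purity_discordant=discordant)
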