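"""Classification of structural variants into single and complex events.

SVs are chained into candidate events by breakpoint proximity (same
chromosome, within a 1 Mb gap) and shared junctions; each multi-SV
component is then classified by its copy-number footprint:

* chromothripsis — many breakpoints on one chromosome with copy number
  oscillating between few states;
* templated insertion — a chain/cycle of translocations across >= 2
  chromosomes in which every bounded segment is a focal gain;
* chromoplexy — a balanced translocation chain across >= 2 chromosomes
  with copy-number loss (and no gain) at the junctions;
* anything else complex stays ``complex_unclassified``; lone SVs are
  ``single``.

The numeric thresholds are declared defaults (the footprints are
qualitative in origin) and are exposed in :class:`SVThresholds`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genome import CHROM_LENGTHS_GRCH37, make_bins


@dataclass
class SVThresholds:
    max_gap: float = 1_000_000           # breakpoint chaining distance
    min_ct_breakpoints: int = 10         # chromothripsis breakpoint minimum
    max_ct_states: int = 3               # distinct CN states in the oscillation
    min_ct_switches: int = 6             # CN switches along the shattered region
    max_focal_gain: float = 5_000_000    # templated-insertion segment size
    junction_window: float = 2_000_000   # CN footprint search window at junctions


@dataclass
class ComplexEventCall:
    event_id: str
    type: str
    sv_ids: list
    chroms: list
    evidence: dict = field(default_factory=dict)
    incomplete: bool = False


class _UnionFind:
    def __init__(self, n):
        self.parent = list(range(n))

    def find(self, i):
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, a, b):
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[rb] = ra


def chain_svs(svs: list, max_gap: float = 1_000_000) -> list[list]:
    """Group SVs into connected components of nearby/shared breakpoints."""
    if not svs:
        return []
    uf = _UnionFind(len(svs))
    bps = []
    for i, sv in enumerate(svs):
        bps.append((sv.chrom1, sv.pos1, i))
        bps.append((sv.chrom2, sv.pos2, i))
    bps.sort(key=lambda b: (b[0], b[1]))
    for (c1, p1, i1), (c2, p2, i2) in zip(bps, bps[1:]):
        if c1 == c2 and p2 - p1 <= max_gap:
            uf.union(i1, i2)
    comps = {}
    for i in range(len(svs)):
        comps.setdefault(uf.find(i), []).append(svs[i])
    return list(comps.values())


def _cn_at(segments: pd.DataFrame, chrom: str, pos: float) -> float | None:
    hit = segments[(segments.chrom == chrom)
                   & (segments.start <= pos) & (segments.end >= pos)]
    return float(hit.total_cn.iloc[0]) if len(hit) else None


def _cn_track(segments: pd.DataFrame, chrom: str, lo: float, hi: float) -> list[float]:
    sel = segments[(segments.chrom == chrom)
                   & (segments.end >= lo) & (segments.start <= hi)]
    return sel.sort_values("start").total_cn.tolist()


def classify_event(component: list, segments: pd.DataFrame,
                   thresholds: SVThresholds | None = None,
                   event_id: str = "ev") -> ComplexEventCall:
    """Classify one chained SV component by its copy-number footprint."""
    th = thresholds or SVThresholds()
    sv_ids = [sv.id for sv in component]
    chroms = sorted({c for sv in component for c in (sv.chrom1, sv.chrom2)})
    bp_by_chrom: dict[str, list[int]] = {}
    for sv in component:
        bp_by_chrom.setdefault(sv.chrom1, []).append(sv.pos1)
        bp_by_chrom.setdefault(sv.chrom2, []).append(sv.pos2)
    call = ComplexEventCall(event_id=event_id, type="complex_unclassified",
                            sv_ids=sv_ids, chroms=chroms)
    if len(component) == 1:
        call.type = "single"
        return call

    incomplete = False

    # (1) chromothripsis: many breakpoints on one chromosome, oscillating CN
    for chrom, bps in bp_by_chrom.items():
        if len(bps) < th.min_ct_breakpoints:
            continue
        track = _cn_track(segments, chrom, min(bps), max(bps))
        if not track:
            incomplete = True
            continue
        switches = sum(1 for a, b in zip(track, track[1:]) if a != b)
        states = len(set(track))
        call.evidence.update({"ct_chrom": chrom, "ct_breakpoints": len(bps),
                              "cn_states": states, "cn_switches": switches})
        if states <= th.max_ct_states and switches >= th.min_ct_switches:
            call.type = "chromothripsis"
            call.incomplete = incomplete
            return call

    translocations = [sv for sv in component if sv.chrom1 != sv.chrom2]
    multi_chrom = len(chroms) >= 2 and len(translocations) >= 2

    # (2) templated insertion: every bounded segment a focal gain
    if multi_chrom:
        gains, ok = [], True
        for chrom, bps in bp_by_chrom.items():
            lo, hi = min(bps), max(bps)
            if hi - lo > th.max_focal_gain or hi == lo:
                ok = False
                break
            inside = _cn_track(segments, chrom, lo + 1, hi - 1) or \
                _cn_track(segments, chrom, lo, hi)
            flank_vals = [v for v in (_cn_at(segments, chrom, lo - th.junction_window),
                                      _cn_at(segments, chrom, hi + th.junction_window))
                          if v is not None]
            if not inside or not flank_vals:
                incomplete = True
                ok = False
                break
            if not (max(inside) > max(flank_vals)):
                ok = False
                break
            gains.append((chrom, lo, hi))
        if ok and gains:
            call.type = "templated_insertion"
            call.evidence["focal_gains"] = gains
            call.incomplete = incomplete
            return call

    # (3) chromoplexy: junction-adjacent CN loss, no gains
    if multi_chrom:
        losses, gains_near = 0, 0
        covered = True
        for chrom, bps in bp_by_chrom.items():
            for bp in bps:
                track = _cn_track(segments, chrom, bp - th.junction_window,
                                  bp + th.junction_window)
                if not track:
                    covered = False
                    incomplete = True
                    continue
                flank = max(track)
                losses += sum(1 for v in track if v < flank)
                base = _cn_at(segments, chrom, bp - th.junction_window)
                if base is not None:
                    gains_near += sum(1 for v in track if v > base)
        call.evidence.update({"junction_losses": losses, "junction_gains": gains_near})
        if losses >= 1 and gains_near == 0:
            call.type = "chromoplexy"
            call.incomplete = not covered
            return call

    call.incomplete = incomplete
    return call


def classify_sample(svs: list, segments: pd.DataFrame,
                    thresholds: SVThresholds | None = None,
                    sample_id: str = "") -> list[ComplexEventCall]:
    """Chain and classify all SVs of one sample; events partition the SVs."""
    th = thresholds or SVThresholds()
    calls = []
    for i, comp in enumerate(chain_svs(svs, th.max_gap), start=1):
        calls.append(classify_event(comp, segments, th,
                                    event_id=f"{sample_id or 'ev'}_{i}"))
    return calls


@dataclass
class HotspotHit:
    sample_id: str
    hotspot: str
    sv_ids: list


def annotate_hotspots(svs: list, hotspots: list, sample_id: str = "") -> list[HotspotHit]:
    """Hotspots hit by >= 1 breakpoint, deduplicated per sample."""
    hits: dict[str, set] = {}
    for sv in svs:
        for chrom, pos in sv.breakpoints:
            for hs in hotspots:
                if hs.overlaps(chrom, pos):
                    hits.setdefault(hs.name, set()).add(sv.id)
    sid = sample_id or (svs[0].sample_id if svs else "")
    return [HotspotHit(sample_id=sid, hotspot=name, sv_ids=sorted(ids))
            for name, ids in sorted(hits.items())]


def breakpoint_density(svs_by_sample: dict, groups: dict,
                       bin_size: int = 1_000_000,
                       chrom_lengths: dict | None = None) -> pd.DataFrame:
    """Per-bin, per-group counts of patients with >= 1 SV breakpoint.

    Each patient contributes at most 1 to a bin regardless of how many
    breakpoints fall inside it.
    """
    bins = make_bins(bin_size, chrom_lengths or CHROM_LENGTHS_GRCH37)
    group_names = sorted(set(groups.values()))
    counts = {g: np.zeros(len(bins), dtype=int) for g in group_names}
    starts_by_chrom = {c: grp for c, grp in bins.groupby("chrom")}
    for sid, svs in svs_by_sample.items():
        g = groups[sid]
        seen = set()
        for sv in svs:
            for chrom, pos in sv.breakpoints:
                if chrom not in starts_by_chrom:
                    continue
                grp = starts_by_chrom[chrom]
                i = np.searchsorted(grp.start.to_numpy(), pos, side="right") - 1
                if 0 <= i < len(grp):
                    seen.add(grp.index[i])
        for idx in seen:
            counts[g][idx] += 1
    out = bins.copy()
    for g in group_names:
        out[g] = counts[g]
    return out


def events_to_frame(calls: list[ComplexEventCall], sample_id: str = "") -> pd.DataFrame:
    return pd.DataFrame([{
        "sample_id": sample_id, "event_id": c.event_id, "type": c.type,
        "n_svs": len(c.sv_ids), "sv_ids": ";".join(c.sv_ids),
        "chroms": ";".join(c.chroms), "incomplete": c.incomplete,
        "evidence": repr(c.evidence),
    } for c in calls])
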