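"""End-to-end orchestration: simulate/load -> clonality -> signatures ->
gain timing -> SV classification -> cohort statistics.

Every stage draws randomness from a named substream of the single run seed,
so re-running an identical configuration reproduces outputs bit-for-bit.
"""

from __future__ import annotations

import json
import logging
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import clonality, cohort_stats, molecular_time, signature_fit, sv_complex
from .io_formats import (
    mutations_to_frame, read_hotspots, read_metadata, read_mutations,
    read_segments, read_signatures, read_svs, segments_to_frame,
)
from .synthetic import (
    SimProfile, default_cohort_profiles, default_hotspots, simulate_cohort_memory,
)
from .synthetic_signatures import DEFAULT_MODEL, synthetic_signature_reference

log = logging.getLogger("mmclock")


def substream(seed: int, label: str) -> np.random.Generator:
    """Deterministic named child RNG of the run seed."""
    return np.random.default_rng(
        np.random.SeedSequence([int(seed), zlib.crc32(label.encode())]))


@dataclass
class RunConfig:
    seed: int = 0
    outdir: str = "mmclock_run"
    # either a simulation (profiles) or real inputs (input_dir with manifest-style files)
    simulate: bool = True
    profiles: list = field(default_factory=list)       # SimProfile or dicts
    input_dir: str | None = None
    signature_model: tuple = DEFAULT_MODEL
    signature_file: str | None = None                  # COSMIC-format TSV; default: synthetic reference
    hotspot_file: str | None = None
    n_boot: int = 1000
    elimination_threshold: float = 0.01
    clonal_ccf_threshold: float = clonality.CLONAL_CCF_THRESHOLD
    min_segment_length: int = molecular_time.MIN_SEGMENT_LENGTH
    min_clonal_mutations: int = molecular_time.MIN_CLONAL_MUTATIONS
    min_clock_mutations: int = molecular_time.MIN_CLOCK_MUTATIONS
    sv_thresholds: dict = field(default_factory=dict)
    overwrite: bool = False

    def resolved_profiles(self) -> list[SimProfile]:
        if not self.profiles:
            return default_cohort_profiles()
        return [p if isinstance(p, SimProfile) else SimProfile(**p)
                for p in self.profiles]

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**raw)

    def to_manifest(self) -> dict:
        d = asdict(self)
        d["profiles"] = [asdict(p) if isinstance(p, SimProfile) else p
                         for p in self.resolved_profiles()] if self.simulate else []
        return d


class StageError(RuntimeError):
    def __init__(self, stage, message):
        super().__init__(f"stage {stage!r}: {message}")
        self.stage = stage


def _load_inputs(config: RunConfig) -> list[dict]:
    indir = Path(config.input_dir)
    manifest = json.loads((indir / "manifest.json").read_text())
    metas = {m.sample_id: m for m in read_metadata(indir / manifest["metadata"])}
    bundle = []
    for sid, files in manifest["samples"].items():
        if sid not in metas:
            raise StageError("load", f"sample {sid} has no metadata (purity missing)")
        bundle.append({
            "sample_id": sid,
            "mutations": read_mutations(indir / files["vcf"], sid),
            "segments": read_segments(indir / files["segments"]),
            "svs": read_svs(indir / files["bedpe"], sid),
            "meta": metas[sid],
            "truth": None,
        })
    return bundle


def analyze_sample(item: dict, signatures, config: RunConfig, seed: int) -> dict:
    """Run the per-sample stages; returns a dict of tables and summaries."""
    sid = item["sample_id"]
    meta = item["meta"]
    muts = mutations_to_frame(item["mutations"])
    segs = segments_to_frame(item["segments"])

    calls = clonality.call_sample(muts, segs, meta.purity)
    n_unassigned = int((~calls.assigned).sum())
    if n_unassigned:
        log.info("%s: %d mutations outside segments excluded", sid, n_unassigned)
    model = clonality.fit_clonal_model(calls, meta.purity)
    calls["clonal"] = False
    calls.loc[calls.assigned, "clonal"] = model.clonal

    catalog = signature_fit.build_catalog(calls[calls.assigned], sample_id=sid)
    exposures = signature_fit.backward_eliminate(
        catalog, signatures, threshold=config.elimination_threshold)
    apobec = signature_fit.apobec_metrics(calls, exposures)

    gains = molecular_time.eligible_gains(
        segs, calls, min_length=config.min_segment_length,
        min_clonal=config.min_clonal_mutations)
    for g in gains:
        if not g.eligible:
            log.info("%s: gain %s excluded (%s)", sid, g.segment_id, g.reason)
    molecular_time.time_gains(gains, calls, n_boot=config.n_boot,
                              rng=substream(seed, f"timing:{sid}"))
    windows = molecular_time.group_windows(gains)
    for w in windows:
        if w.is_earliest:
            molecular_time.clock_time_and_age(
                w, calls, exposures.fractions, signatures, meta.age_at_sampling,
                n_boot=config.n_boot, rng=substream(seed, f"clock:{sid}"),
                min_clock=config.min_clock_mutations)

    th = sv_complex.SVThresholds(**config.sv_thresholds)
    events = sv_complex.classify_sample(item["svs"], segs, th, sample_id=sid)

    return {"sample_id": sid, "meta": meta, "calls": calls, "model": model,
            "catalog": catalog, "exposures": exposures, "apobec": apobec,
            "gains": gains, "windows": windows, "events": events,
            "n_unassigned": n_unassigned}


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages in dependency order; write tables and a manifest.

    Returns the run summary dict (also written as ``summary.json``).
    """
    outdir = Path(config.outdir)
    if (outdir / "summary.json").exists() and not config.overwrite:
        raise StageError("setup", f"{outdir} already holds a run; set overwrite")
    outdir.mkdir(parents=True, exist_ok=True)

    if config.signature_file:
        signatures = read_signatures(config.signature_file,
                                     subset=list(config.signature_model))
    else:
        signatures = synthetic_signature_reference().subset(
            list(config.signature_model))
    hotspots = (read_hotspots(config.hotspot_file) if config.hotspot_file
                else default_hotspots())

    try:
        if config.simulate:
            bundle = simulate_cohort_memory(config.resolved_profiles(), config.seed)
        else:
            bundle = _load_inputs(config)
    except StageError:
        raise
    except Exception as exc:
        raise StageError("inputs", str(exc)) from exc

    results = []
    for item in bundle:
        try:
            results.append(analyze_sample(item, signatures, config, config.seed))
        except Exception as exc:
            (outdir / "manifest.partial.json").write_text(
                json.dumps({"config": config.to_manifest(),
                            "completed": [r["sample_id"] for r in results]}))
            raise StageError(f"sample:{item['sample_id']}", str(exc)) from exc

    # --- cohort tables
    groups = {r["sample_id"]: r["meta"].group for r in results}
    exposure_tbl = signature_fit.exposures_to_frame([r["exposures"] for r in results])
    gain_tbl = pd.concat([
        molecular_time.gains_to_frame(r["gains"], r["sample_id"]) for r in results],
        ignore_index=True)
    window_tbl = pd.concat([
        molecular_time.windows_to_frame(r["windows"], r["sample_id"],
                                        r["meta"].age_at_sampling, groups[r["sample_id"]])
        for r in results if r["windows"]], ignore_index=True)
    event_tbl = pd.concat([
        sv_complex.events_to_frame(r["events"], r["sample_id"]) for r in results],
        ignore_index=True)
    hotspot_rows = []
    for r, item in zip(results, bundle):
        for hit in sv_complex.annotate_hotspots(item["svs"], hotspots, r["sample_id"]):
            hotspot_rows.append({"sample_id": hit.sample_id, "hotspot": hit.hotspot,
                                 "n_svs": len(hit.sv_ids)})
    hotspot_tbl = pd.DataFrame(hotspot_rows,
                               columns=["sample_id", "hotspot", "n_svs"])
    density = sv_complex.breakpoint_density(
        {item["sample_id"]: item["svs"] for item in bundle}, groups)

    # --- cohort statistics
    burden = {r["sample_id"]: int(len(r["calls"])) for r in results}
    by_group = lambda d: {g: [v for s, v in d.items() if groups[s] == g]
                          for g in sorted(set(groups.values()))}
    comparisons = []
    comparisons += cohort_stats.pairwise_wilcoxon_fdr(by_group(burden), "snv_burden")
    apo = {r["sample_id"]: r["exposures"].apobec_fraction for r in results}
    comparisons += cohort_stats.pairwise_wilcoxon_fdr(by_group(apo), "apobec_fraction")
    ages = {r["sample_id"]: w.age_estimate for r in results
            for w in r["windows"] if w.is_earliest and w.converted}
    age_groups = {g: v for g, v in by_group(ages).items() if len(v) >= 2}
    if len(age_groups) >= 2:
        comparisons += cohort_stats.pairwise_wilcoxon_fdr(age_groups, "gain_age")
    # APOBEC detection prevalence (Fisher), per group pair
    det = {r["sample_id"]: r["exposures"].apobec_fraction > 0 for r in results}
    det_g = by_group(det)
    from itertools import combinations
    for a, b in combinations(sorted(det_g), 2):
        comparisons.append(cohort_stats.fisher_prevalence(
            sum(det_g[a]), len(det_g[a]), sum(det_g[b]), len(det_g[b]),
            feature="apobec_detected", group_a=a, group_b=b))
    comp_tbl = cohort_stats.comparisons_to_frame(comparisons)

    bmpc = {r["sample_id"]: r["meta"].bmpc_percent for r in results
            if r["meta"].bmpc_percent is not None}
    regression = None
    if len(bmpc) >= 3:
        ids = sorted(bmpc)
        slope, intercept, r2, p = cohort_stats.regress_burden(
            [bmpc[s] for s in ids], [burden[s] for s in ids])
        regression = {"slope": slope, "intercept": intercept, "r_squared": r2, "p": p}

    # --- outputs
    exposure_tbl.to_csv(outdir / "exposures.tsv", sep="\t", index=False)
    gain_tbl.to_csv(outdir / "gain_timing.tsv", sep="\t", index=False)
    window_tbl.to_csv(outdir / "multigain_windows.tsv", sep="\t", index=False)
    event_tbl.to_csv(outdir / "sv_events.tsv", sep="\t", index=False)
    hotspot_tbl.to_csv(outdir / "hotspot_hits.tsv", sep="\t", index=False)
    density.to_csv(outdir / "breakpoint_density.tsv", sep="\t", index=False)
    comp_tbl.to_csv(outdir / "comparisons.tsv", sep="\t", index=False)

    group_medians = {
        g: float(np.median(v)) for g, v in by_group(ages).items() if v}
    summary = {
        "n_samples": len(results),
        "groups": {g: sum(1 for s in groups.values() if s == g)
                   for g in sorted(set(groups.values()))},
        "median_burden": {g: float(np.median(v)) for g, v in by_group(burden).items()},
        "median_gain_age": group_medians,
        "apobec_detected": {g: int(sum(v)) for g, v in det_g.items()},
        "sv_event_counts": event_tbl.type.value_counts().to_dict() if len(event_tbl) else {},
        "regression_burden_vs_bmpc": regression,
        "filters": {
            "gains_excluded": gain_tbl[~gain_tbl.eligible].reason.value_counts().to_dict()
            if len(gain_tbl) else {},
            "windows_unconverted": int((~window_tbl.converted).sum())
            if len(window_tbl) else 0,
        },
    }
    (outdir / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    (outdir / "manifest.json").write_text(
        json.dumps({"config": config.to_manifest(), "outputs": sorted(
            p.name for p in outdir.glob("*.tsv"))}, indent=2, sort_keys=True))
    return summary
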