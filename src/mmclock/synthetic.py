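"""Synthetic cohort generator with known ground truth.

Emulates the statistical structure the downstream analyses assume: clonal
and subclonal SNVs drawn from signature mixtures, whole-chromosome gains
placed at known molecular times (so duplicated/non-duplicated counts follow
the implied allele bookkeeping), binomial read sampling at given coverage
and purity, and injected simple/complex SV events with self-consistent
copy-number footprints. Every emitted record is traceable to a ground-truth
entry, which is what makes estimator-recovery tests possible.

Allele bookkeeping for a gain at molecular time t with per-allele full-life
mutation mass mu on the segment:

    gain (2,1):      E[N2] = mu t,   E[N1] = mu t + 3 mu (1 - t)
    CN-LOH (2,0):    E[N2] = mu t,   E[N1] = 2 mu (1 - t)
    tetrasomy (2,2): E[N2] = 2 mu t, E[N1] = 4 mu (1 - t)
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .clonality import expected_vaf
from .contexts import BASES, SBS96_CONTEXTS, parse_context, revcomp, PYRIMIDINES
from .genome import AUTOSOMES, CHROM_LENGTHS_GRCH37
from .io_formats import (
    Interval, MutationRecord, SampleMeta, SegmentRecord, SVRecord,
    write_hotspots, write_metadata, write_mutations, write_segments, write_svs,
)
from .signature_fit import APOBEC_TCA_CONTEXTS
from .synthetic_signatures import (
    APOBEC_SIGNATURES, CLOCK_SIGNATURES, synthetic_signature_reference,
)


@dataclass
class SimProfile:
    """Study conditions for one simulated clinical group."""

    group: str
    n_patients: int
    age_range: tuple = (45.0, 75.0)
    gain_time_range: tuple = (0.2, 0.6)        # molecular time t of the multi-gain event
    clock_yield: float = 60.0                  # SBS1+SBS5 mutations / year / diploid genome
    exposures: dict = field(default_factory=lambda: {"SBS1": 0.25, "SBS5": 0.75})
    ytca_bias: float = 1.0                     # YTCA:RTCA generation odds at tCa motifs
    subclone_fraction: float = 0.25            # subclonal burden relative to clonal
    subclone_ccf: float = 0.35
    coverage: float = 40.0
    purity_range: tuple = (0.65, 0.95)
    n_gains_range: tuple = (3, 5)              # trisomy-like gains in the multi-gain event
    gain_chrom_pool: tuple = ("3", "5", "7", "9", "11", "15", "19", "21")
    cnloh_prob: float = 0.3                    # add a CN-LOH chromosome to the event
    tetrasomy_prob: float = 0.2                # add an (untimeable) tetrasomy
    second_gain_prob: float = 0.4              # later, separate gain event
    sv_menu: dict = field(default_factory=lambda: {
        "single": 3, "chromothripsis": 0, "templated_insertion": 0, "chromoplexy": 0})

    def __post_init__(self):
        total = sum(self.exposures.values())
        if abs(total - 1.0) > 1e-6:
            raise ValueError(f"exposures must sum to 1, got {total}")
        if not any(s in self.exposures for s in CLOCK_SIGNATURES):
            raise ValueError("profile exposures must include SBS1 and/or SBS5; "
                             "clock conversion impossible")
        lo, hi = self.gain_time_range
        if not (0 < lo <= hi <= 1):
            raise ValueError(f"gain_time_range must be within (0,1], got {self.gain_time_range}")
        if self.coverage <= 0:
            raise ValueError("coverage must be > 0")


@dataclass
class GroundTruth:
    """Per-patient truth: gain times, exposures, per-mutation labels, SV events."""

    sample_id: str
    gains: list            # dicts: chrom, start, end, gain_class, t, age_years
    exposures: dict
    mutations: pd.DataFrame   # id, multiplicity, clonal, signature, ccf
    sv_events: list        # dicts: type, sv_ids, chroms

    def to_dict(self) -> dict:
        return {
            "sample_id": self.sample_id,
            "gains": self.gains,
            "exposures": self.exposures,
            "sv_events": self.sv_events,
            "mutations": {c: self.mutations[c].tolist() for c in self.mutations.columns},
        }


TRUTH_REQUIRED_KEYS = ("sample_id", "gains", "exposures", "sv_events", "mutations")
TRUTH_MUTATION_COLUMNS = ("id", "multiplicity", "clonal", "signature")


def validate_truth(truth: dict):
    """Schema check for a serialized ground-truth entry; unique mutation ids."""
    for key in TRUTH_REQUIRED_KEYS:
        if key not in truth:
            raise ValueError(f"ground truth missing key {key!r}")
    for col in TRUTH_MUTATION_COLUMNS:
        if col not in truth["mutations"]:
            raise ValueError(f"ground-truth mutations missing column {col!r}")
    ids = truth["mutations"]["id"]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate mutation ids in ground truth")
    for g in truth["gains"]:
        if not (0 < g["t"] <= 1):
            raise ValueError(f"gain time outside (0,1]: {g}")


# ---------------------------------------------------------------------------
# allele bookkeeping


def expected_gain_counts(mu: float, t: float, gain_class: str) -> tuple[float, float]:
    """Closed-form E[N2], E[N1] for a gain at time t (mass mu per allele)."""
    if gain_class == "gain_2_1":
        return mu * t, mu * t + 3 * mu * (1 - t)
    if gain_class == "cnloh_2_0":
        return mu * t, 2 * mu * (1 - t)
    if gain_class == "tetrasomy_2_2":
        return 2 * mu * t, 4 * mu * (1 - t)
    raise ValueError(f"unknown gain class {gain_class!r}")


def simulate_gain_counts(mu: float, t: float, gain_class: str,
                         rng: np.random.Generator) -> tuple[int, int]:
    """Poisson duplicated/non-duplicated counts for a gain at time t."""
    e2, e1 = expected_gain_counts(mu, t, gain_class)
    return int(rng.poisson(e2)), int(rng.poisson(e1))


# ---------------------------------------------------------------------------
# segment editing


def _apply_cn(segs: list[list], start: int, end: int, major: int, minor: int):
    """Overwrite copy number on [start, end] within a sorted segment list."""
    out = []
    for s, e, M, m in segs:
        if e < start or s > end:
            out.append([s, e, M, m])
            continue
        if s < start:
            out.append([s, start - 1, M, m])
        out.append([max(s, start), min(e, end), major, minor])
        if e > end:
            out.append([end + 1, e, M, m])
    out.sort()
    return out


# ---------------------------------------------------------------------------
# patient simulation


def simulate_patient(profile: SimProfile, rng: np.random.Generator,
                     sample_id: str = "SIM001"):
    """Simulate one patient.

    Returns (mutations, segments, svs, meta, truth) where the first three
    are lists of io_formats records.
    """
    signatures = synthetic_signature_reference()
    age = float(rng.uniform(*profile.age_range))
    purity = float(rng.uniform(*profile.purity_range))
    t_event = float(rng.uniform(*profile.gain_time_range))

    genome_len = sum(CHROM_LENGTHS_GRCH37[c] for c in AUTOSOMES)
    total_rate = profile.clock_yield / sum(
        profile.exposures.get(s, 0.0) for s in CLOCK_SIGNATURES)
    allele_mass_per_bp = total_rate * age / 2.0 / genome_len

    # --- copy-number scaffold and timed gains
    segs = {c: [[1, CHROM_LENGTHS_GRCH37[c], 1, 1]] for c in AUTOSOMES}
    gain_times: dict[str, tuple[float, str]] = {}
    truth_gains = []
    pool = list(profile.gain_chrom_pool)
    rng.shuffle(pool)
    n_gains = int(rng.integers(profile.n_gains_range[0], profile.n_gains_range[1] + 1))
    event_chroms = pool[:n_gains]
    for chrom in event_chroms:
        gain_times[chrom] = (t_event, "gain_2_1")
    rest = pool[n_gains:]
    if rest and rng.random() < profile.cnloh_prob:
        gain_times[rest.pop(0)] = (t_event, "cnloh_2_0")
    if rest and rng.random() < profile.tetrasomy_prob:
        gain_times[rest.pop(0)] = (t_event, "tetrasomy_2_2")
    if rest and rng.random() < profile.second_gain_prob:
        t2 = float(rng.uniform(min(1.0, t_event + 0.25), 1.0)) \
            if t_event + 0.25 < 1.0 else 1.0
        gain_times[rest.pop(0)] = (t2, "gain_2_1")
    cn_of = {"gain_2_1": (2, 1), "cnloh_2_0": (2, 0), "tetrasomy_2_2": (2, 2)}
    for chrom, (t, cls) in gain_times.items():
        M, m = cn_of[cls]
        segs[chrom] = [[1, CHROM_LENGTHS_GRCH37[chrom], M, m]]
        truth_gains.append({"chrom": chrom, "start": 1,
                            "end": CHROM_LENGTHS_GRCH37[chrom], "gain_class": cls,
                            "t": t, "age_years": t * age})

    # --- SV injection on chromosomes without timed gains
    sv_chrom_pool = [c for c in AUTOSOMES if c not in gain_times]
    rng.shuffle(sv_chrom_pool)
    svs, sv_events = _inject_svs(profile.sv_menu, sv_chrom_pool, segs, rng, sample_id)

    # --- mutation emission
    mut_rows = []     # (chrom, pos, m, nt, ccf, label)
    focal_gain_t = 0.95
    for chrom in AUTOSOMES:
        for s, e, M, m in segs[chrom]:
            lam = allele_mass_per_bp * (e - s + 1)
            nt = M + m
            if chrom in gain_times and (M, m) == cn_of[gain_times[chrom][1]]:
                t, cls = gain_times[chrom]
                n2, n1 = simulate_gain_counts(lam, t, cls, rng)
                mut_rows.append((chrom, s, e, 2, nt, 1.0, n2))
                mut_rows.append((chrom, s, e, 1, nt, 1.0, n1))
            elif (M, m) == (1, 1):
                mut_rows.append((chrom, s, e, 1, 2, 1.0, int(rng.poisson(2 * lam))))
            elif (M, m) == (1, 0):
                mut_rows.append((chrom, s, e, 1, 1, 1.0, int(rng.poisson(lam))))
            elif M >= 2:  # focal untimed gain footprint (TI partner / duplication)
                n2, n1 = simulate_gain_counts(lam, focal_gain_t, "gain_2_1", rng)
                mut_rows.append((chrom, s, e, 2, nt, 1.0, n2))
                mut_rows.append((chrom, s, e, 1, nt, 1.0, n1))
            else:
                mut_rows.append((chrom, s, e, 1, max(nt, 1), 1.0, int(rng.poisson(lam))))

    n_clonal = sum(r[-1] for r in mut_rows)
    # subclone on diploid regions
    diploid = [(c, s, e) for c in AUTOSOMES for s, e, M, m in segs[c] if (M, m) == (1, 1)]
    n_sub = int(rng.poisson(profile.subclone_fraction * n_clonal))
    if diploid and n_sub:
        lens = np.array([e - s + 1 for _, s, e in diploid], dtype=float)
        picks = rng.choice(len(diploid), size=n_sub, p=lens / lens.sum())
        for i in range(n_sub):
            c, s, e = diploid[picks[i]]
            mut_rows.append((c, s, e, 1, 2, profile.subclone_ccf, 1))

    sig_names = list(profile.exposures)
    sig_p = np.array([profile.exposures[s] for s in sig_names])
    sig_profiles = {s: signatures[s] for s in sig_names}

    mutations, truth_mut = [], []
    counter = 0
    for chrom, s, e, m, nt, ccf, count in mut_rows:
        if count <= 0:
            continue
        pos = rng.integers(s + 2, max(s + 3, e - 2), size=count)
        sig_idx = rng.choice(len(sig_names), size=count, p=sig_p)
        p_exp = expected_vaf(m, ccf, purity, nt)
        depth = np.maximum(1, rng.poisson(
            profile.coverage * (purity * nt + (1 - purity) * 2) / 2.0, size=count))
        alt = rng.binomial(depth, p_exp)
        for j in range(count):
            sig = sig_names[sig_idx[j]]
            ctx = SBS96_CONTEXTS[rng.choice(96, p=sig_profiles[sig])]
            counter += 1
            mid = f"{sample_id}_m{counter}"
            mutations.append(_make_mutation(
                sample_id, chrom, int(pos[j]), ctx, int(alt[j]), int(depth[j]),
                mid, sig, profile.ytca_bias, rng))
            truth_mut.append((mid, m, ccf >= 0.99, sig, ccf))

    segments = [SegmentRecord(chrom=c, start=s, end=e, major_cn=M, minor_cn=m)
                for c in AUTOSOMES for s, e, M, m in segs[c]]
    meta = SampleMeta(sample_id=sample_id, purity=purity, age_at_sampling=age,
                      group=profile.group,
                      bmpc_percent=float(rng.uniform(*_BMPC_RANGES.get(
                          profile.group, (2.0, 60.0)))))
    truth = GroundTruth(
        sample_id=sample_id, gains=truth_gains, exposures=dict(profile.exposures),
        mutations=pd.DataFrame(truth_mut,
                               columns=["id", "multiplicity", "clonal", "signature", "ccf"]),
        sv_events=sv_events)
    return mutations, segments, svs, meta, truth


_BMPC_RANGES = {"stable": (2.0, 10.0), "progressive": (5.0, 55.0), "MM": (15.0, 90.0)}


def _make_mutation(sample_id, chrom, pos, context, alt, depth, mid, sig,
                   ytca_bias, rng) -> MutationRecord:
    five, ref, a, three = parse_context(context)
    if sig in APOBEC_SIGNATURES and context in APOBEC_TCA_CONTEXTS:
        p_y = ytca_bias / (1.0 + ytca_bias)
        minus2 = rng.choice(list("CT" if rng.random() < p_y else "AG"))
    else:
        minus2 = BASES[rng.integers(4)]
    plus2 = BASES[rng.integers(4)]
    penta_pyr = minus2 + five + ref + three + plus2
    if rng.random() < 0.5:  # emit on the purine reference strand
        penta, ref, a = revcomp(penta_pyr), revcomp(ref), revcomp(a)
    else:
        penta = penta_pyr
    return MutationRecord(sample_id=sample_id, chrom=chrom, pos=pos, ref=ref,
                          alt=a, context=context, alt_count=alt, depth=depth,
                          id=mid, penta=penta)


# ---------------------------------------------------------------------------
# SV injection


def _take_chroms(pool: list, n: int, min_len: int = 60_000_000) -> list:
    picked = []
    for c in list(pool):
        if CHROM_LENGTHS_GRCH37[c] >= min_len:
            picked.append(c)
            pool.remove(c)
        if len(picked) == n:
            return picked
    raise ValueError("not enough free chromosomes for requested SV menu")


def _inject_svs(menu: dict, pool: list, segs: dict, rng, sample_id: str):
    svs, events = [], []
    sv_n = 0

    def new_id():
        nonlocal sv_n
        sv_n += 1
        return f"{sample_id}_sv{sv_n}"

    for _ in range(int(menu.get("chromothripsis", 0))):
        (chrom,) = _take_chroms(pool, 1)
        size = CHROM_LENGTHS_GRCH37[chrom]
        lo = int(rng.integers(5_000_000, size // 3))
        # consecutive gaps < 1 Mb keep the shattered region one chained component
        gaps = rng.uniform(80_000, 900_000, size=19)
        bps = (lo + np.concatenate([[0.0], np.cumsum(gaps)])).astype(int)
        for i in range(1, 20, 2):  # alternate losses between consecutive breakpoints
            segs[chrom] = _apply_cn(segs[chrom], int(bps[i - 1]), int(bps[i]) - 1, 1, 0)
        order = rng.permutation(20)
        ids = []
        for i in range(0, 20, 2):
            p1, p2 = int(bps[order[i]]), int(bps[order[i + 1]])
            ids.append(new_id())
            svs.append(SVRecord(chrom1=chrom, pos1=min(p1, p2),
                                strand1="+-"[rng.integers(2)],
                                chrom2=chrom, pos2=max(p1, p2),
                                strand2="+-"[rng.integers(2)],
                                id=ids[-1], sample_id=sample_id))
        events.append({"type": "chromothripsis", "sv_ids": ids, "chroms": [chrom]})

    for _ in range(int(menu.get("templated_insertion", 0))):
        chroms = _take_chroms(pool, int(rng.integers(2, 4)))
        bounds = []
        for c in chroms:
            s = int(rng.integers(5_000_000, CHROM_LENGTHS_GRCH37[c] - 5_000_000))
            e = s + int(rng.integers(100_000, 400_000))
            segs[c] = _apply_cn(segs[c], s, e, 2, 1)  # focal gain
            bounds.append((c, s, e))
        ids = []
        for i, (c, s, e) in enumerate(bounds):
            c2, s2, _ = bounds[(i + 1) % len(bounds)]
            ids.append(new_id())
            svs.append(SVRecord(chrom1=c, pos1=e, strand1="+", chrom2=c2, pos2=s2,
                                strand2="-", id=ids[-1], sample_id=sample_id))
        events.append({"type": "templated_insertion", "sv_ids": ids,
                       "chroms": [c for c, _, _ in bounds]})

    for _ in range(int(menu.get("chromoplexy", 0))):
        chroms = _take_chroms(pool, 3)
        bps = []
        for c in chroms:
            b = int(rng.integers(5_000_000, CHROM_LENGTHS_GRCH37[c] - 5_000_000))
            bps.append(b)
            segs[c] = _apply_cn(segs[c], b, b + 250_000, 1, 0)  # junction loss
        ids = []
        for i in range(len(chroms) - 1):
            ids.append(new_id())
            svs.append(SVRecord(chrom1=chroms[i], pos1=bps[i], strand1="+",
                                chrom2=chroms[i + 1], pos2=bps[i + 1] + 250_000,
                                strand2="-", id=ids[-1], sample_id=sample_id))
        events.append({"type": "chromoplexy", "sv_ids": ids, "chroms": chroms})

    single_classes = ["deletion", "duplication", "inversion", "translocation"]
    for _ in range(int(menu.get("single", 0))):
        cls = single_classes[rng.integers(4)]
        sid = new_id()
        if cls == "translocation":
            cands = [c for c in pool]
            if len(cands) < 2:
                cands = pool + [c for c in AUTOSOMES if c not in pool]
            c1, c2 = rng.choice(cands, size=2, replace=False)
            svs.append(SVRecord(
                chrom1=c1, pos1=int(rng.integers(3_000_000, CHROM_LENGTHS_GRCH37[c1] // 2)),
                strand1="+", chrom2=c2,
                pos2=int(rng.integers(3_000_000, CHROM_LENGTHS_GRCH37[c2] // 2)),
                strand2="-", id=sid, sample_id=sample_id))
        else:
            (chrom,) = _take_chroms(pool, 1, min_len=40_000_000)
            s = int(rng.integers(3_000_000, CHROM_LENGTHS_GRCH37[chrom] - 4_000_000))
            e = s + int(rng.integers(200_000, 800_000))
            strands = {"deletion": ("+", "-"), "duplication": ("-", "+"),
                       "inversion": ("+", "+")}[cls]
            if cls == "deletion":
                segs[chrom] = _apply_cn(segs[chrom], s, e, 1, 0)
            elif cls == "duplication":
                segs[chrom] = _apply_cn(segs[chrom], s, e, 2, 1)
            svs.append(SVRecord(chrom1=chrom, pos1=s, strand1=strands[0],
                                chrom2=chrom, pos2=e, strand2=strands[1],
                                id=sid, sample_id=sample_id))
        events.append({"type": "single", "sv_ids": [sid],
                       "chroms": [svs[-1].chrom1, svs[-1].chrom2]})
    return svs, events


# ---------------------------------------------------------------------------
# cohort level


def default_cohort_profiles() -> list[SimProfile]:
    """The default study-like cohort: 15 stable, 17 progressive, 20 MM.

    Stable precursors: late gains, mostly clock-like mutagenesis, no APOBEC,
    low SV activity. Progressive precursors and MM: early gains, APOBEC on
    at ~1:1 YTCA:RTCA, higher burden, complex SV events.
    """
    stable = SimProfile(
        group="stable", n_patients=15, gain_time_range=(0.75, 0.95),
        clock_yield=39.0,
        exposures={"SBS1": 0.25, "SBS5": 0.60, "SBS9": 0.10, "SBS18": 0.05},
        sv_menu={"single": 2, "chromothripsis": 0, "templated_insertion": 0,
                 "chromoplexy": 0})
    progressive = SimProfile(
        group="progressive", n_patients=17, gain_time_range=(0.2, 0.6),
        clock_yield=48.0,
        exposures={"SBS1": 0.18, "SBS5": 0.47, "SBS2": 0.07, "SBS13": 0.05,
                   "SBS9": 0.12, "SBS8": 0.06, "SBS18": 0.05},
        ytca_bias=1.0,
        sv_menu={"single": 4, "chromothripsis": 1, "templated_insertion": 1,
                 "chromoplexy": 0})
    mm = SimProfile(
        group="MM", n_patients=20, gain_time_range=(0.15, 0.5),
        clock_yield=48.0,
        exposures={"SBS1": 0.18, "SBS5": 0.47, "SBS2": 0.07, "SBS13": 0.05,
                   "SBS9": 0.12, "SBS8": 0.06, "SBS18": 0.05},
        ytca_bias=1.0,
        sv_menu={"single": 5, "chromothripsis": 1, "templated_insertion": 1,
                 "chromoplexy": 1})
    return [stable, progressive, mm]


def simulate_cohort_memory(profiles: list[SimProfile], seed: int):
    """Simulate all patients in memory; returns a list of per-sample dicts."""
    if not profiles:
        raise ValueError("need at least one profile")
    out = []
    i = 0
    for profile in profiles:
        for _ in range(profile.n_patients):
            i += 1
            sid = f"SIM{i:03d}"
            rng = np.random.default_rng(np.random.SeedSequence([seed, i]))
            muts, segments, svs, meta, truth = simulate_patient(profile, rng, sid)
            out.append({"sample_id": sid, "mutations": muts, "segments": segments,
                        "svs": svs, "meta": meta, "truth": truth})
    return out


def default_hotspots(n: int = 69, seed: int = 7) -> list[Interval]:
    """Synthetic 69-interval SV hotspot catalogue (resource stand-in).

    The first entries carry the names of loci recurrently rearranged in
    myeloma (MYC/PVT1, the IGH partner oncogenes); the remainder are
    deterministic filler intervals.
    """
    named = [("8", 127_500_000, 129_000_000, "MYC_PVT1"),
             ("14", 105_500_000, 106_400_000, "IGH"),
             ("11", 69_000_000, 69_600_000, "CCND1"),
             ("4", 1_800_000, 2_000_000, "MMSET_FGFR3"),
             ("16", 78_000_000, 79_500_000, "MAF"),
             ("20", 39_000_000, 39_400_000, "MAFB"),
             ("6", 41_800_000, 42_100_000, "CCND3"),
             ("12", 6_800_000, 7_000_000, "LTBR_LAG3")]
    rng = np.random.default_rng(seed)
    out = [Interval(chrom=c, start=s, end=e, name=n_) for c, s, e, n_ in named]
    chroms = list(AUTOSOMES)
    while len(out) < n:
        c = chroms[rng.integers(len(chroms))]
        s = int(rng.integers(1_000_000, CHROM_LENGTHS_GRCH37[c] - 2_000_000))
        out.append(Interval(chrom=c, start=s, end=s + int(rng.integers(200_000, 1_200_000)),
                            name=f"hotspot_{len(out) + 1}"))
    return out[:n]


def simulate_cohort(profiles: list[SimProfile], outdir, seed: int,
                    overwrite: bool = False) -> dict:
    """Simulate a cohort and write it to disk in the pipeline's dialects.

    Writes per-sample VCF / segments TSV / BEDPE, a metadata table, the
    synthetic hotspot BED, a ground-truth JSON and a manifest listing all
    files. Returns the manifest dict.
    """
    outdir = Path(outdir)
    manifest_path = outdir / "manifest.json"
    if manifest_path.exists() and not overwrite:
        raise FileExistsError(f"{manifest_path} exists; pass overwrite=True to replace")
    outdir.mkdir(parents=True, exist_ok=True)
    bundle = simulate_cohort_memory(profiles, seed)
    metas, truths, files = [], {}, {}
    for item in bundle:
        sid = item["sample_id"]
        vcf = outdir / f"{sid}.vcf"
        seg = outdir / f"{sid}.segments.tsv"
        bedpe = outdir / f"{sid}.bedpe"
        write_mutations(item["mutations"], vcf, sid)
        write_segments(item["segments"], seg)
        write_svs(item["svs"], bedpe)
        metas.append(item["meta"])
        truths[sid] = item["truth"].to_dict()
        files[sid] = {"vcf": vcf.name, "segments": seg.name, "bedpe": bedpe.name}
    write_metadata(metas, outdir / "metadata.tsv")
    write_hotspots(default_hotspots(), outdir / "hotspots.bed")
    (outdir / "truth.json").write_text(json.dumps(truths))
    manifest = {"seed": seed, "n_samples": len(bundle), "samples": files,
                "metadata": "metadata.tsv", "truth": "truth.json",
                "hotspots": "hotspots.bed",
                "profiles": [asdict(p) for p in profiles]}
    manifest_path.write_text(json.dumps(manifest, indent=2))
    return manifest
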