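"""Readers and writers for the external formats the pipeline touches.

All coordinates are 1-based inclusive internally; BED/BEDPE (0-based
half-open) are converted at the boundary. Somatic SNVs come from VCF with
per-sample allelic depths, allele-specific copy number from Battenberg-like
TSV, structural variants from BEDPE, signature references from
COSMIC-format TSV.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .contexts import (
    CONTEXT_INDEX, PYRIMIDINES, SBS96_CONTEXTS, context_label, revcomp,
)
from .genome import is_sex_chrom, normalize_chrom

log = logging.getLogger(__name__)

VALID_SVCLASSES = ("deletion", "duplication", "inversion", "translocation")


# ---------------------------------------------------------------------------
# domain types


@dataclass
class MutationRecord:
    """One somatic SNV: the atom of all timing and signature computation.

    ``penta`` is the raw reference-strand 5-mer centered on the position
    (middle base equals ``ref``); ``context`` is the pyrimidine-collapsed
    96-class trinucleotide label derived from it.
    """

    sample_id: str
    chrom: str
    pos: int
    ref: str
    alt: str
    context: str
    alt_count: int
    depth: int
    id: str = ""
    penta: str | None = None
    flags: set = field(default_factory=set)

    def __post_init__(self):
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if self.ref == self.alt:
            raise ValueError(f"{self.id or self.locus}: ref == alt")
        if not (0 <= self.alt_count <= self.depth):
            raise ValueError(
                f"{self.id or self.locus}: alt_count {self.alt_count} "
                f"outside [0, depth={self.depth}]")
        if self.context not in CONTEXT_INDEX:
            raise ValueError(f"invalid context label {self.context!r}")

    @property
    def locus(self) -> str:
        return f"{self.chrom}:{self.pos}"

    @property
    def vaf(self) -> float:
        return self.alt_count / self.depth if self.depth else float("nan")

    @property
    def five_prime2(self) -> str | None:
        """Base two positions 5' of the mutated base on the pyrimidine strand."""
        if self.penta is None or len(self.penta) < 5:
            return None
        return self.penta[0] if self.ref.upper() in PYRIMIDINES else revcomp(self.penta)[0]

    @classmethod
    def from_raw(cls, sample_id, chrom, pos, ref, alt, penta,
                 alt_count, depth, id="", flags=None):
        """Build a record from a raw reference-strand 5-mer, deriving context."""
        ctx = context_label(penta[1:4], ref, alt)
        return cls(sample_id=sample_id, chrom=normalize_chrom(chrom), pos=int(pos),
                   ref=ref.upper(), alt=alt.upper(), context=ctx,
                   alt_count=int(alt_count), depth=int(depth), id=id,
                   penta=penta.upper(), flags=flags or set())


@dataclass
class SegmentRecord:
    """A clonal allele-specific copy-number segment (1-based inclusive)."""

    chrom: str
    start: int
    end: int
    major_cn: int
    minor_cn: int

    def __post_init__(self):
        if self.start > self.end:
            raise ValueError(f"segment {self.chrom}:{self.start}-{self.end}: start > end")
        if not (self.major_cn >= self.minor_cn >= 0):
            raise ValueError(
                f"segment {self.chrom}:{self.start}-{self.end}: "
                f"need major_cn >= minor_cn >= 0, got ({self.major_cn},{self.minor_cn})")

    @property
    def total_cn(self) -> int:
        return self.major_cn + self.minor_cn

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def contains(self, chrom: str, pos: int) -> bool:
        return self.chrom == chrom and self.start <= pos <= self.end


@dataclass
class SVRecord:
    """One structural variant as a canonically ordered breakpoint pair."""

    chrom1: str
    pos1: int
    strand1: str
    chrom2: str
    pos2: int
    strand2: str
    svclass: str = ""
    id: str = ""
    sample_id: str = ""

    def __post_init__(self):
        if self.strand1 not in "+-" or self.strand2 not in "+-":
            raise ValueError(f"SV {self.id}: strands must be '+' or '-'")
        self.chrom1 = normalize_chrom(self.chrom1)
        self.chrom2 = normalize_chrom(self.chrom2)
        if _chrom_key(self.chrom2, self.pos2) < _chrom_key(self.chrom1, self.pos1):
            self.chrom1, self.pos1, self.strand1, self.chrom2, self.pos2, self.strand2 = (
                self.chrom2, self.pos2, self.strand2, self.chrom1, self.pos1, self.strand1)
        if not self.svclass:
            self.svclass = infer_svclass(self.chrom1, self.strand1, self.chrom2, self.strand2)
        if self.svclass not in VALID_SVCLASSES:
            raise ValueError(f"SV {self.id}: invalid svclass {self.svclass!r}")

    @property
    def breakpoints(self) -> tuple[tuple[str, int], tuple[str, int]]:
        return (self.chrom1, self.pos1), (self.chrom2, self.pos2)


def _chrom_key(chrom: str, pos: int):
    c = normalize_chrom(chrom)
    order = {**{str(i): i for i in range(1, 23)}, "X": 23, "Y": 24}
    return (order.get(c, 99), c, pos)


def infer_svclass(chrom1: str, strand1: str, chrom2: str, strand2: str) -> str:
    """Paired-end orientation semantics for intrachromosomal SV classes.

    (+,-) reads point toward each other across a missing piece: deletion-like;
    (-,+) duplication-like; equal strands: inversion-like. Different
    chromosomes are translocations regardless of strands.
    """
    if normalize_chrom(chrom1) != normalize_chrom(chrom2):
        return "translocation"
    return {("+", "-"): "deletion", ("-", "+"): "duplication"}.get(
        (strand1, strand2), "inversion")


@dataclass
class SampleMeta:
    """Per-sample metadata: purity, age, clinical group, BMPC infiltration."""

    sample_id: str
    purity: float
    age_at_sampling: float
    group: str
    bmpc_percent: float | None = None

    def __post_init__(self):
        if not (0 < self.purity <= 1):
            raise ValueError(f"{self.sample_id}: purity must be in (0,1], got {self.purity}")
        if self.age_at_sampling <= 0:
            raise ValueError(f"{self.sample_id}: age_at_sampling must be > 0")


@dataclass
class Interval:
    """Generic named genomic interval (1-based inclusive), e.g. an SV hotspot."""

    chrom: str
    start: int
    end: int
    name: str = ""

    def overlaps(self, chrom: str, pos: int) -> bool:
        return normalize_chrom(chrom) == self.chrom and self.start <= pos <= self.end


class SignatureMatrix:
    """96-context signature reference: probability columns in COSMIC order."""

    def __init__(self, data: pd.DataFrame):
        missing = set(SBS96_CONTEXTS) - set(data.index)
        if missing:
            raise ValueError(f"signature matrix missing {len(missing)} context rows, "
                             f"e.g. {sorted(missing)[:3]}")
        data = data.loc[list(SBS96_CONTEXTS)].astype(float)
        if (data.values < 0).any():
            raise ValueError("signature matrix has negative entries")
        sums = data.sum(axis=0)
        bad = sums[(sums - 1.0).abs() > 1e-6]
        if len(bad):
            raise ValueError(f"signature columns do not sum to 1: {dict(bad.round(4))}")
        self.data = data / sums  # renormalize residual float error

    @property
    def names(self) -> list[str]:
        return list(self.data.columns)

    @property
    def contexts(self) -> tuple[str, ...]:
        return SBS96_CONTEXTS

    def values(self) -> np.ndarray:
        """(96, n_signatures) array."""
        return self.data.values

    def subset(self, names) -> "SignatureMatrix":
        names = list(names)
        if not names:
            raise ValueError("empty signature subset: the model must contain >= 1 signature")
        unknown = [n for n in names if n not in self.data.columns]
        if unknown:
            raise ValueError(f"unknown signatures in subset: {unknown}")
        return SignatureMatrix(self.data[names])

    def __getitem__(self, name: str) -> np.ndarray:
        return self.data[name].values


# ---------------------------------------------------------------------------
# VCF


VCF_HEADER = """\
##fileformat=VCFv4.2
##INFO=<ID=PNC,Number=1,Type=String,Description="Reference-strand pentanucleotide context centered on POS">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths (ref,alt)">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{sample}
"""


def write_mutations(records: list[MutationRecord], path, sample_id: str | None = None):
    """Write SNV records as a single-sample VCF with AD/DP and PNC context."""
    if sample_id is None:
        sample_id = records[0].sample_id if records else "SAMPLE"
    lines = [VCF_HEADER.format(sample=sample_id)]
    for r in sorted(records, key=lambda r: _chrom_key(r.chrom, r.pos)):
        info = f"PNC={r.penta}" if r.penta else "."
        lines.append(
            f"{r.chrom}\t{r.pos}\t{r.id or '.'}\t{r.ref}\t{r.alt}\t.\tPASS\t{info}"
            f"\tGT:AD:DP\t0/1:{r.depth - r.alt_count},{r.alt_count}:{r.depth}\n")
    Path(path).write_text("".join(lines))


def read_mutations(vcf_path, sample_id: str | None = None,
                   genome_fasta=None, flank: int = 2) -> list[MutationRecord]:
    """Read biallelic SNVs with allelic depths from a VCF.

    Contexts are taken from an indexed FASTA when provided, else from the
    ``PNC`` INFO field; either way the middle base must match REF. Indels,
    multiallelic sites and records without depth information are skipped
    with a logged count.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(vcf_path))
    samples = vcf.samples
    if sample_id is None:
        if len(samples) != 1:
            raise ValueError(
                f"{vcf_path}: multi-sample VCF ({samples}); pass sample_id to select one")
        sample_id = samples[0]
    if sample_id not in samples:
        raise ValueError(f"{vcf_path}: sample {sample_id!r} not in VCF ({samples})")
    sidx = samples.index(sample_id)

    fasta = None
    if genome_fasta is not None:
        from pyfaidx import Fasta
        fasta = Fasta(str(genome_fasta), as_raw=True, sequence_always_upper=True)

    records, skipped = [], 0
    for v in vcf:
        if not v.is_snp or len(v.ALT) != 1 or len(v.REF) != 1 or len(v.ALT[0]) != 1:
            skipped += 1
            continue
        ad = v.format("AD")
        if ad is None:
            skipped += 1
            continue
        ref_c, alt_c = int(ad[sidx][0]), int(ad[sidx][1])
        if ref_c < 0 or alt_c < 0:
            skipped += 1
            continue
        dp = v.format("DP")
        depth = int(dp[sidx][0]) if dp is not None else ref_c + alt_c
        chrom = normalize_chrom(v.CHROM)
        if fasta is not None:
            seq = str(fasta[v.CHROM][max(0, v.POS - 1 - flank): v.POS + flank])
            penta = seq if len(seq) == 2 * flank + 1 else None
        else:
            penta = v.INFO.get("PNC")
        if penta is None:
            skipped += 1
            continue
        mid = len(penta) // 2
        if penta[mid].upper() != v.REF.upper():
            raise ValueError(
                f"{vcf_path} {chrom}:{v.POS}: context middle base {penta[mid]!r} "
                f"does not match REF {v.REF!r}")
        records.append(MutationRecord.from_raw(
            sample_id=sample_id, chrom=chrom, pos=v.POS, ref=v.REF, alt=v.ALT[0],
            penta=penta, alt_count=alt_c, depth=depth, id=v.ID or ""))
    if skipped:
        log.info("read_mutations(%s): skipped %d non-SNV/incomplete records",
                 vcf_path, skipped)
    records.sort(key=lambda r: _chrom_key(r.chrom, r.pos))
    return records


# ---------------------------------------------------------------------------
# copy-number segments


DEFAULT_SEGMENT_COLUMNS = {
    "chrom": "chrom", "start": "start", "end": "end",
    "major_cn": "major_cn", "minor_cn": "minor_cn",
}
BATTENBERG_COLUMNS = {
    "chrom": "chr", "start": "startpos", "end": "endpos",
    "major_cn": "nMaj1_A", "minor_cn": "nMin1_A",
}


def read_segments(tsv_path, columns: dict | None = None) -> list[SegmentRecord]:
    """Read clonal allele-specific copy-number segments from a TSV.

    ``columns`` maps the internal field names to the file's column names
    (Battenberg-like dialects differ); the default expects chrom/start/end/
    major_cn/minor_cn. Segments must be non-overlapping per chromosome.
    """
    colmap = columns or DEFAULT_SEGMENT_COLUMNS
    df = pd.read_csv(tsv_path, sep="\t", dtype={colmap["chrom"]: str})
    missing = [c for c in colmap.values() if c not in df.columns]
    if missing:
        raise ValueError(f"{tsv_path}: missing segment column(s) {missing}")
    segs = []
    for _, row in df.iterrows():
        major, minor = int(row[colmap["major_cn"]]), int(row[colmap["minor_cn"]])
        if major < 0 or minor < 0:
            raise ValueError(f"{tsv_path}: negative copy number at "
                             f"{row[colmap['chrom']]}:{row[colmap['start']]}")
        segs.append(SegmentRecord(
            chrom=normalize_chrom(row[colmap["chrom"]]),
            start=int(row[colmap["start"]]), end=int(row[colmap["end"]]),
            major_cn=major, minor_cn=minor))
    segs.sort(key=lambda s: _chrom_key(s.chrom, s.start))
    for a, b in zip(segs, segs[1:]):
        if a.chrom == b.chrom and b.start <= a.end:
            raise ValueError(
                f"{tsv_path}: overlapping segments {a.chrom}:{a.start}-{a.end} "
                f"and {b.chrom}:{b.start}-{b.end}")
    return segs


def write_segments(segments: list[SegmentRecord], path):
    rows = [(s.chrom, s.start, s.end, s.major_cn, s.minor_cn) for s in segments]
    pd.DataFrame(rows, columns=["chrom", "start", "end", "major_cn", "minor_cn"]).to_csv(
        path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# structural variants (BEDPE) and hotspots (BED)


def read_svs(bedpe_path, sample_id: str = "") -> list[SVRecord]:
    """Read SVs from BEDPE (0-based half-open); breakpoint = start + 1."""
    svs = []
    with open(bedpe_path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            f = line.split("\t")
            if len(f) < 10:
                raise ValueError(f"{bedpe_path}: expected >= 10 BEDPE columns, got {len(f)}")
            if f[8] not in "+-" or f[9] not in "+-":
                raise ValueError(f"{bedpe_path}: malformed strand field {f[8]!r}/{f[9]!r}")
            svs.append(SVRecord(
                chrom1=f[0], pos1=int(f[1]) + 1, strand1=f[8],
                chrom2=f[3], pos2=int(f[4]) + 1, strand2=f[9],
                id=f[6], sample_id=sample_id))
    return svs


def write_svs(svs: list[SVRecord], path):
    lines = []
    for s in svs:
        lines.append(f"{s.chrom1}\t{s.pos1 - 1}\t{s.pos1}\t{s.chrom2}\t{s.pos2 - 1}"
                     f"\t{s.pos2}\t{s.id}\t.\t{s.strand1}\t{s.strand2}\n")
    Path(path).write_text("".join(lines))


def read_hotspots(bed_path) -> list[Interval]:
    """Read hotspot intervals from BED (0-based half-open) into 1-based form."""
    out = []
    with open(bed_path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            f = line.split("\t")
            name = f[3] if len(f) > 3 else f"{f[0]}:{f[1]}-{f[2]}"
            out.append(Interval(chrom=normalize_chrom(f[0]), start=int(f[1]) + 1,
                                end=int(f[2]), name=name))
    return out


def write_hotspots(intervals: list[Interval], path):
    Path(path).write_text("".join(
        f"{iv.chrom}\t{iv.start - 1}\t{iv.end}\t{iv.name}\n" for iv in intervals))


# ---------------------------------------------------------------------------
# signatures


def read_signatures(tsv_path, subset=None) -> SignatureMatrix:
    """Read a COSMIC-format 96 x k signature TSV; optionally select columns."""
    df = pd.read_csv(tsv_path, sep="\t", index_col=0)
    mat = SignatureMatrix(df)
    return mat.subset(subset) if subset is not None else mat


def write_signatures(matrix: SignatureMatrix, path):
    matrix.data.rename_axis("Type").to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# metadata table and bulk frames


def read_metadata(tsv_path) -> list[SampleMeta]:
    df = pd.read_csv(tsv_path, sep="\t", dtype={"sample_id": str})
    metas = []
    for _, row in df.iterrows():
        bmpc = row.get("bmpc_percent")
        metas.append(SampleMeta(
            sample_id=row["sample_id"], purity=float(row["purity"]),
            age_at_sampling=float(row["age_at_sampling"]), group=str(row["group"]),
            bmpc_percent=None if pd.isna(bmpc) else float(bmpc)))
    return metas


def write_metadata(metas: list[SampleMeta], path):
    pd.DataFrame([
        {"sample_id": m.sample_id, "purity": m.purity,
         "age_at_sampling": m.age_at_sampling, "group": m.group,
         "bmpc_percent": m.bmpc_percent} for m in metas
    ]).to_csv(path, sep="\t", index=False)


def mutations_to_frame(records: list[MutationRecord]) -> pd.DataFrame:
    """Columnar view of mutation records for vectorized computation."""
    return pd.DataFrame({
        "id": [r.id for r in records],
        "sample_id": [r.sample_id for r in records],
        "chrom": [r.chrom for r in records],
        "pos": np.array([r.pos for r in records], dtype=np.int64),
        "ref": [r.ref for r in records],
        "alt": [r.alt for r in records],
        "context": [r.context for r in records],
        "five_prime2": [r.five_prime2 for r in records],
        "alt_count": np.array([r.alt_count for r in records], dtype=np.int64),
        "depth": np.array([r.depth for r in records], dtype=np.int64),
    })


def segments_to_frame(segments: list[SegmentRecord]) -> pd.DataFrame:
    df = pd.DataFrame({
        "chrom": [s.chrom for s in segments],
        "start": np.array([s.start for s in segments], dtype=np.int64),
        "end": np.array([s.end for s in segments], dtype=np.int64),
        "major_cn": np.array([s.major_cn for s in segments], dtype=np.int64),
        "minor_cn": np.array([s.minor_cn for s in segments], dtype=np.int64),
    })
    df["total_cn"] = df.major_cn + df.minor_cn
    df["is_sex"] = [is_sex_chrom(c) for c in df.chrom]
    return df
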