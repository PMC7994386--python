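"""Trinucleotide substitution contexts on the pyrimidine strand.

Somatic single-base substitutions are conventionally collapsed onto the
strand whose mutated base is a pyrimidine (C or T), giving 6 substitution
types x 16 flanking-base combinations = 96 classes. The canonical class
order (C>A block first, flanks sorted A,C,G,T) matches the COSMIC
signature catalogs so that count vectors and signature matrices align.
"""

from __future__ import annotations

BASES = "ACGT"
PYRIMIDINES = frozenset("CT")
PURINES = frozenset("AG")

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")

#: the six pyrimidine-strand substitution types, canonical order
SUBSTITUTIONS: tuple[tuple[str, str], ...] = (
    ("C", "A"), ("C", "G"), ("C", "T"),
    ("T", "A"), ("T", "C"), ("T", "G"),
)

#: 96 context labels, e.g. "A[C>A]A", in canonical (COSMIC) order
SBS96_CONTEXTS: tuple[str, ...] = tuple(
    f"{five}[{ref}>{alt}]{three}"
    for ref, alt in SUBSTITUTIONS
    for five in BASES
    for three in BASES
)

CONTEXT_INDEX: dict[str, int] = {c: i for i, c in enumerate(SBS96_CONTEXTS)}


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string."""
    return seq.translate(_COMPLEMENT)[::-1]


def collapse_snv(kmer: str, ref: str, alt: str) -> tuple[str, str, str]:
    """Collapse a substitution onto the pyrimidine strand.

    ``kmer`` is an odd-length reference sequence centered on the mutated
    base; its middle base must equal ``ref``. Returns the (possibly
    reverse-complemented) kmer together with the pyrimidine-strand ref
    and alt. Already-pyrimidine input is returned unchanged, so the
    operation is an involution.
    """
    if len(kmer) % 2 != 1:
        raise ValueError(f"kmer must have odd length, got {kmer!r}")
    mid = len(kmer) // 2
    kmer = kmer.upper()
    ref = ref.upper()
    alt = alt.upper()
    if kmer[mid] != ref:
        raise ValueError(f"kmer middle base {kmer[mid]!r} does not match ref {ref!r}")
    if ref == alt:
        raise ValueError("ref and alt are identical")
    if ref in PYRIMIDINES:
        return kmer, ref, alt
    return revcomp(kmer), revcomp(ref), revcomp(alt)


def context_label(kmer: str, ref: str, alt: str) -> str:
    """96-class label (e.g. ``A[C>T]A``) for a substitution in ``kmer``."""
    kmer_p, ref_p, alt_p = collapse_snv(kmer, ref, alt)
    mid = len(kmer_p) // 2
    label = f"{kmer_p[mid - 1]}[{ref_p}>{alt_p}]{kmer_p[mid + 1]}"
    if label not in CONTEXT_INDEX:
        raise ValueError(f"non-ACGT context {label!r}")
    return label


def parse_context(label: str) -> tuple[str, str, str, str]:
    """Split ``A[C>T]G`` into (5' base, ref, alt, 3' base)."""
    if label not in CONTEXT_INDEX:
        raise ValueError(f"unknown context label {label!r}")
    return label[0], label[2], label[4], label[6]
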