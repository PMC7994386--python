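"""Reference genome coordinate scaffolding (GRCh37 chromosome sizes, bins)."""

from __future__ import annotations

import pandas as pd

#: GRCh37 chromosome lengths in bp
CHROM_LENGTHS_GRCH37: dict[str, int] = {
    "1": 249250621, "2": 243199373, "3": 198022430, "4": 191154276,
    "5": 180915260, "6": 171115067, "7": 159138663, "8": 146364022,
    "9": 141213431, "10": 135534747, "11": 135006516, "12": 133851895,
    "13": 115169878, "14": 107349540, "15": 102531392, "16": 90354753,
    "17": 81195210, "18": 78077248, "19": 59128983, "20": 63025520,
    "21": 48129895, "22": 51304566, "X": 155270560, "Y": 59373566,
}

AUTOSOMES: tuple[str, ...] = tuple(str(i) for i in range(1, 23))
SEX_CHROMS: frozenset[str] = frozenset({"X", "Y"})


def normalize_chrom(name: str) -> str:
    """Strip a leading ``chr`` prefix; chromosome names are bare internally."""
    name = str(name)
    return name[3:] if name.lower().startswith("chr") else name


def is_sex_chrom(name: str) -> bool:
    return normalize_chrom(name) in SEX_CHROMS


def make_bins(bin_size: int = 1_000_000,
              chrom_lengths: dict[str, int] | None = None,
              chroms: tuple[str, ...] | None = None) -> pd.DataFrame:
    """Tile chromosomes into fixed-size bins (1-based inclusive coordinates)."""
    lengths = chrom_lengths or CHROM_LENGTHS_GRCH37
    if chroms is None:
        chroms = AUTOSOMES if chrom_lengths is None else tuple(lengths)
    rows = []
    for chrom in chroms:
        size = lengths[chrom]
        start = 1
        while start <= size:
            end = min(start + bin_size - 1, size)
            rows.append((chrom, start, end))
            start = end + 1
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])
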