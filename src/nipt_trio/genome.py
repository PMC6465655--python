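"""Reference genome constants (GRCh37 chromosome lengths)."""

from __future__ import annotations

# GRCh37/hg19 primary assembly chromosome lengths in bp.
GRCH37_SIZES: dict[str, int] = {
    "1": 249250621,
    "2": 243199373,
    "3": 198022430,
    "4": 191154276,
    "5": 180915260,
    "6": 171115067,
    "7": 159138663,
    "8": 146364022,
    "9": 141213431,
    "10": 135534747,
    "11": 135006516,
    "12": 133851895,
    "13": 115169878,
    "14": 107349540,
    "15": 102531392,
    "16": 90354753,
    "17": 81195210,
    "18": 78077248,
    "19": 59128983,
    "20": 63025520,
    "21": 48129895,
    "22": 51304566,
    "X": 155270560,
    "Y": 59373566,
}

AUTOSOMES: tuple[str, ...] = tuple(str(i) for i in range(1, 23))
SEX_CHROMS: tuple[str, ...] = ("X", "Y")
ALL_CHROMS: tuple[str, ...] = AUTOSOMES + SEX_CHROMS

_ORDER = {c: i for i, c in enumerate(ALL_CHROMS)}


def chrom_sort_key(chrom: str) -> int:
    """Karyotype ordering: 1..22, X, Y. Unknown names sort last."""
    return _ORDER.get(chrom, len(_ORDER))


def is_autosome(chrom: str) -> bool:
    return chrom in _ORDER and chrom not in ("X", "Y")
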