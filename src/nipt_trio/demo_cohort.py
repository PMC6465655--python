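"""Bundled validation-cohort configurations.

These mirror the clinical evaluation cohort the pipeline is modelled on:
seven aneuploid pregnancies (T13, two T18, two T21, 45,X, 47,XXY), three
pregnancies carrying fetal duplications of 20 Mb or more, and twelve
pregnancies with fetal single-gene-disorder variants in the six panel
genes, each with its reported fetal fraction and average target depth.
Ten variant-free pregnancies at comparable fractions and depths complete
the single-gene arm as negative samples.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .ptg import LocusInfo


@dataclass(frozen=True)
class AneuploidCase:
    sample_id: str
    fetal_fraction: float
    fetal_sex: str  # XX / XY (fetal sex chromosome complement base)
    karyotype: str  # T13 / T18 / T21 / X0 / XXY
    total_depth: float  # reported average target depth (x)


ANEUPLOID_CASES: tuple[AneuploidCase, ...] = (
    AneuploidCase("case-T13-51", 0.1976, "XX", "T13", 195.32),
    AneuploidCase("case-T18-52", 0.1690, "XX", "T18", 149.09),
    AneuploidCase("case-T18-53", 0.1814, "XX", "T18", 185.02),
    AneuploidCase("case-T21-54", 0.1883, "XY", "T21", 154.08),
    AneuploidCase("case-T21-55", 0.2124, "XX", "T21", 213.41),
    AneuploidCase("case-X0-62", 0.1986, "XX", "X0", 239.56),
    AneuploidCase("case-XXY-63", 0.1632, "XY", "XXY", 269.11),
)


@dataclass(frozen=True)
class CNVCase:
    sample_id: str
    fetal_fraction: float
    fetal_sex: str
    chrom: str
    start: int
    end: int
    total_depth: float


#: Three fetal duplications >= 20 Mb at their reported fetal fractions.
CNV_CASES: tuple[CNVCase, ...] = (
    CNVCase("case-dup9-59", 0.1699, "XY", "9", 0, 21_000_000, 270.53),
    CNVCase("case-dup12-58", 0.1796, "XX", "12", 8_000_000, 31_500_000, 278.99),
    CNVCase("case-dup20-60", 0.2022, "XX", "20", 0, 20_000_000, 151.75),
)


@dataclass(frozen=True)
class SGDCase:
    """One single-gene-disorder sample: loci as (locus_id, maternal, fetal)."""

    sample_id: str
    fetal_fraction: float
    mean_depth: float
    loci: tuple[tuple[str, str, str], ...] = field(default_factory=tuple)


#: Twelve variant-carrying pregnancies. Maternal genotype AB marks a
#: carrier mother; AA marks a paternally transmitted fetal allele. The
#: fetus is heterozygous at every listed pathogenic locus.
SGD_CASES: tuple[SGDCase, ...] = (
    SGDCase("sgd-pku-59", 0.2247, 224.77, (("PAH:c.G728A", "AB", "AB"),)),
    SGDCase("sgd-pku-60", 0.2465, 129.88, (("PAH:c.A611G", "AB", "AB"),)),
    SGDCase("sgd-hl-50", 0.2221, 196.73, (("GJB2:c.235delC", "AB", "AB"),)),
    SGDCase("sgd-hl-54", 0.2522, 270.65, (("GJB2:c.G109A", "AB", "AB"),)),
    SGDCase("sgd-hl-62", 0.2266, 166.06,
            (("GJB2:c.299_300del", "AA", "AB"), ("GJB2:c.235delC", "AB", "AB"))),
    SGDCase("sgd-hl-52", 0.1966, 155.13,
            (("GJB2:c.299_300del", "AA", "AB"), ("GJB2:c.235delC", "AB", "AB"))),
    SGDCase("sgd-hl-53", 0.1981, 305.40, (("SLC26A4:c.A1174T", "AB", "AB"),)),
    SGDCase("sgd-bt-45", 0.2118, 130.05, (("HBB:c.126_129del", "AB", "AB"),)),
    SGDCase("sgd-bt-48", 0.2135, 201.09,
            (("HBB:c.126_129del", "AB", "AB"), ("HBB:c.316-197C>T", "AA", "AB"))),
    SGDCase("sgd-bt-61", 0.2042, 195.59, (("HBB:c.126_129del", "AB", "AB"),)),
    SGDCase("sgd-bt-70", 0.1810, 180.86,
            (("HBB:c.316-197C>T", "AB", "AB"), ("HBB:c.126_129del", "AA", "AB"))),
    SGDCase("sgd-bt-80", 0.2103, 241.74, (("HBB:c.A52T", "AB", "AB"),)),
)

#: Ten variant-free pregnancies at comparable fractions and depths. Five
#: have a carrier mother at a monitored locus (the hard negatives: the
#: fetus inherited the reference allele) and five a homozygous-reference
#: mother.
SGD_CONTROLS: tuple[SGDCase, ...] = (
    SGDCase("ctl-01", 0.1750, 180.0, (("GJB2:c.235delC", "AB", "AA"),)),
    SGDCase("ctl-02", 0.1900, 220.0, (("HBB:c.126_129del", "AB", "AA"),)),
    SGDCase("ctl-03", 0.2050, 160.0, (("PAH:c.G728A", "AB", "AA"),)),
    SGDCase("ctl-04", 0.2200, 250.0, (("SLC26A4:c.A1174T", "AB", "AA"),)),
    SGDCase("ctl-05", 0.2400, 140.0, (("GJB2:c.299_300del", "AB", "AA"),)),
    SGDCase("ctl-06", 0.1800, 200.0, (("HBB:c.A52T", "AA", "AA"),)),
    SGDCase("ctl-07", 0.1950, 280.0, (("PAH:c.A611G", "AA", "AA"),)),
    SGDCase("ctl-08", 0.2100, 175.0, (("GJB2:c.G109A", "AA", "AA"),)),
    SGDCase("ctl-09", 0.2300, 300.0, (("HBB:c.316-197C>T", "AA", "AA"),)),
    SGDCase("ctl-10", 0.2500, 130.0, (("SLC26A4:c.A1174T", "AA", "AA"),)),
)

#: Metadata for the pathogenic hotspot loci (population alt frequency 1%).
PATHOGENIC_LOCI: dict[str, LocusInfo] = {
    locus_id: LocusInfo(locus_id, gene=locus_id.split(":")[0],
                        disease=disease, baf=0.01, chrom=chrom, pos=pos)
    for locus_id, disease, chrom, pos in (
        ("PAH:c.G728A", "phenylketonuria", "12", 103246653),
        ("PAH:c.A611G", "phenylketonuria", "12", 103248992),
        ("GJB2:c.235delC", "hearing-loss", "13", 20763486),
        ("GJB2:c.G109A", "hearing-loss", "13", 20763612),
        ("GJB2:c.299_300del", "hearing-loss", "13", 20763421),
        ("SLC26A4:c.A1174T", "hearing-loss", "7", 107323898),
        ("HBB:c.126_129del", "beta-thalassemia", "11", 5248160),
        ("HBB:c.A52T", "beta-thalassemia", "11", 5248233),
        ("HBB:c.316-197C>T", "beta-thalassemia", "11", 5247153),
    )
}
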