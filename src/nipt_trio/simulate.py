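"""Synthetic maternal-fetal cfDNA data generator.

Region read counts follow a copy-dose mixture model: a backbone region
carried at ``m`` maternal and ``c`` fetal copies contributes expected
dose ``(1 - f) * m/2 + f * c/2`` relative to a diploid autosomal region,
where ``f`` is the fetal fraction. A fetal single-copy gain therefore
shifts the dose by ``1 + f/2``, a loss by ``1 - f/2``, and chrY carries
``f/2`` of an autosomal dose for a male fetus (zero for a female).
Counts are drawn multinomially across the backbone regions, optionally
with Dirichlet-multinomial overdispersion: ``dispersion`` inflates the
per-region count variance by a factor of about ``1 + dispersion``
relative to multinomial (0 = exactly multinomial).

Hotspot allele pileups are binomial draws at Poisson-distributed depth,
with the expected alt fraction given by the pseudo-tetraploid mixture
model (:mod:`nipt_trio.ptg`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genome import GRCH37_SIZES, is_autosome
from .panel import Panel
from .ptg import AllelePileup, GENOTYPES, expected_alt_fraction, mendelian_compatible

TRISOMY = "trisomy"
MONOSOMY = "monosomy"
XXY = "XXY"


class SimulationError(ValueError):
    pass


@dataclass(frozen=True)
class RegionCounts:
    """Per-sample unique-read counts over the backbone regions, panel-ordered."""

    sample_id: str
    counts: np.ndarray
    total_reads: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "counts", np.asarray(self.counts, dtype=np.int64))
        if np.any(self.counts < 0):
            raise SimulationError(f"{self.sample_id}: negative counts")
        if int(self.counts.sum()) != self.total_reads:
            raise SimulationError(
                f"{self.sample_id}: counts sum {int(self.counts.sum())} != total_reads {self.total_reads}"
            )


@dataclass
class SampleTruth:
    """Ground-truth configuration of one simulated pregnancy.

    ``aneuploidies`` holds ``(chrom, state)`` pairs with state one of
    ``trisomy``/``monosomy``/``XXY`` (the latter only on chrom X).
    ``cnvs`` holds ``(chrom, start, end, fetal_copy_delta)`` with delta
    +1 (duplication) or -1 (deletion). Genotype maps are per-locus values
    in {AA, AB, BB}; the fetus must share an allele with the mother.
    """

    fetal_fraction: float
    fetal_sex: str = "XX"
    aneuploidies: list[tuple[str, str]] = field(default_factory=list)
    cnvs: list[tuple[str, int, int, int]] = field(default_factory=list)
    maternal_genotypes: dict[str, str] = field(default_factory=dict)
    fetal_genotypes: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0.0 < self.fetal_fraction < 1.0:
            raise SimulationError(f"fetal fraction {self.fetal_fraction} outside (0, 1)")
        if self.fetal_sex not in ("XX", "XY"):
            raise SimulationError(f"fetal_sex must be XX or XY, got {self.fetal_sex!r}")
        for chrom, state in self.aneuploidies:
            if state not in (TRISOMY, MONOSOMY, XXY):
                raise SimulationError(f"unknown aneuploidy state {state!r}")
            if state == XXY and chrom != "X":
                raise SimulationError("XXY state applies to chromosome X")
        for _, start, end, delta in self.cnvs:
            if end <= start:
                raise SimulationError("CNV end must exceed start")
            if delta not in (-1, 1):
                raise SimulationError(f"fetal_copy_delta must be +/-1, got {delta}")
        for locus in self.fetal_genotypes:
            m = self.maternal_genotypes.get(locus)
            fet = self.fetal_genotypes[locus]
            if m not in GENOTYPES or fet not in GENOTYPES:
                raise SimulationError(f"{locus}: genotypes must be in {GENOTYPES}")
            if not mendelian_compatible(m, fet):
                raise SimulationError(
                    f"{locus}: non-Mendelian pair mother {m} / fetus {fet}"
                )

    @property
    def sex_karyotype(self) -> str:
        for chrom, state in self.aneuploidies:
            if chrom == "X" and state == MONOSOMY:
                return "X0"
            if state == XXY:
                return "XXY"
        return self.fetal_sex


def _sex_copies(truth: SampleTruth) -> tuple[int, int]:
    """Fetal (X, Y) copy numbers from sex and sex-chromosome aneuploidy."""
    kt = truth.sex_karyotype
    return {"XX": (2, 0), "XY": (1, 1), "X0": (1, 0), "XXY": (2, 1)}[kt]


def region_doses(panel: Panel, truth: SampleTruth) -> np.ndarray:
    """Expected dose factor per backbone region under the mixture model."""
    f = truth.fetal_fraction
    chroms = panel.backbone_chroms
    starts = panel.backbone_starts
    ends = panel.backbone_ends

    maternal = np.where(chroms == "Y", 0.0, 2.0)
    fetal = np.full(len(chroms), 2.0)
    fx, fy = _sex_copies(truth)
    fetal[chroms == "X"] = fx
    fetal[chroms == "Y"] = fy

    present = set(chroms.tolist())
    for chrom, state in truth.aneuploidies:
        if chrom in ("X", "Y"):
            continue  # handled via sex karyotype
        if chrom not in present:
            raise SimulationError(f"aneuploidy on chromosome {chrom} absent from panel")
        fetal[chroms == chrom] += 1 if state == TRISOMY else -1
    for chrom, start, end, delta in truth.cnvs:
        if chrom not in present:
            raise SimulationError(f"CNV on chromosome {chrom} absent from panel")
        size = GRCH37_SIZES.get(chrom)
        if size is not None and (start < 0 or end > size):
            raise SimulationError(f"CNV {chrom}:{start}-{end} outside chromosome bounds")
        hit = (chroms == chrom) & (starts < end) & (ends > start)
        fetal[hit] += delta
    return (1.0 - f) * maternal / 2.0 + f * fetal / 2.0


def simulate_region_counts(
    panel: Panel,
    truth: SampleTruth,
    total_reads: int,
    dispersion: float = 0.002,
    seed: int = 0,
    sample_id: str = "sample",
) -> RegionCounts:
    """Draw one sample's backbone region counts under the dose model."""
    if total_reads <= 0:
        raise SimulationError("total_reads must be positive")
    if dispersion < 0:
        raise SimulationError("dispersion must be >= 0")
    rng = np.random.default_rng(seed)
    dose = region_doses(panel, truth)
    p = dose / dose.sum()
    if dispersion > 0:
        # Dirichlet-multinomial with concentration s = (n-1)/dispersion,
        # giving per-region variance inflation (n+s)/(1+s) ~ 1 + dispersion.
        s = (total_reads - 1) / dispersion
        p = rng.dirichlet(p * s)
    counts = rng.multinomial(total_reads, p)
    return RegionCounts(sample_id, counts, total_reads)


def simulate_reference_cohort(
    panel: Panel,
    n_samples: int,
    total_reads: int = 2_000_000,
    dispersion: float = 0.002,
    seed: int = 0,
    ff_range: tuple[float, float] = (0.16, 0.22),
    fetal_sex: str | None = None,
) -> list[RegionCounts]:
    """Euploid background cohort with per-sample fetal fraction and sex.

    Fetal fractions are uniform over ``ff_range`` (the observed clinical
    range); fetal sex is random 1:1 unless pinned. Per-sample seeds are
    spawned from the master seed, so the cohort is reproducible.
    """
    if n_samples < 2:
        raise SimulationError("need >= 2 background samples (SD undefined otherwise)")
    master = np.random.default_rng(seed)
    child_seeds = master.integers(0, 2**31 - 1, size=n_samples)
    samples = []
    for i in range(n_samples):
        f = float(master.uniform(*ff_range))
        sex = fetal_sex or ("XY" if master.random() < 0.5 else "XX")
        truth = SampleTruth(fetal_fraction=f, fetal_sex=sex)
        samples.append(
            simulate_region_counts(
                panel, truth, total_reads, dispersion,
                seed=int(child_seeds[i]), sample_id=f"bg{i:03d}",
            )
        )
    return samples


# ---------------------------------------------------------------------------
# hotspot pileups


def simulate_pileups(
    truth: SampleTruth,
    mean_depth: float = 200.0,
    error_rate: float = 0.005,
    seed: int = 0,
) -> list[AllelePileup]:
    """Binomial allele pileups at every locus of the truth genotype maps.

    Depth per locus is Poisson(``mean_depth``); the alt probability is the
    pseudo-tetraploid expected alt fraction clamped to the error floor.
    """
    if not 0.0 <= error_rate < 0.5:
        raise SimulationError(f"error_rate {error_rate} outside [0, 0.5)")
    rng = np.random.default_rng(seed)
    pileups = []
    for locus in truth.fetal_genotypes:
        combo = truth.maternal_genotypes[locus] + truth.fetal_genotypes[locus]
        p = expected_alt_fraction(combo, truth.fetal_fraction)
        p = float(np.clip(p, error_rate, 1.0 - error_rate))
        depth = int(rng.poisson(mean_depth))
        alt = int(rng.binomial(depth, p)) if depth > 0 else 0
        pileups.append(AllelePileup(locus, depth - alt, alt))
    return pileups


def draw_mixture_genotypes(
    loci_baf: dict[str, float], seed: int = 0
) -> tuple[dict[str, str], dict[str, str]]:
    """Draw Hardy-Weinberg maternal genotypes and Mendelian fetal genotypes.

    The fetal genotype combines one uniformly chosen maternal allele with
    a paternal allele drawn at the locus population B-allele frequency.
    """
    rng = np.random.default_rng(seed)
    maternal, fetal = {}, {}
    for locus, q in loci_baf.items():
        u = rng.random()
        if u < (1 - q) ** 2:
            m = "AA"
        elif u < (1 - q) ** 2 + 2 * q * (1 - q):
            m = "AB"
        else:
            m = "BB"
        m_allele = m[rng.integers(0, 2)]
        p_allele = "B" if rng.random() < q else "A"
        fet = "".join(sorted(m_allele + p_allele))
        maternal[locus], fetal[locus] = m, fet
    return maternal, fetal


# ---------------------------------------------------------------------------
# TSV I/O: rows = regions ("chrom:start-end"), columns = samples


def counts_to_frame(samples: list[RegionCounts], panel: Panel) -> pd.DataFrame:
    index = [f"{r.chrom}:{r.start}-{r.end}" for r in panel.backbone]
    data = {s.sample_id: s.counts for s in samples}
    return pd.DataFrame(data, index=pd.Index(index, name="region"))


def write_counts_tsv(samples: list[RegionCounts], panel: Panel, path) -> None:
    counts_to_frame(samples, panel).to_csv(path, sep="\t")


def read_counts_tsv(path, panel: Panel) -> list[RegionCounts]:
    df = pd.read_csv(path, sep="\t", index_col=0)
    expected = [f"{r.chrom}:{r.start}-{r.end}" for r in panel.backbone]
    if list(df.index) != expected:
        raise SimulationError(f"{path}: region rows do not match the panel")
    return [
        RegionCounts(col, df[col].to_numpy(), int(df[col].sum())) for col in df.columns
    ]
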