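"""Pseudo-tetraploid genotyping (PTG) of fetal variants from maternal plasma.

At a biallelic hotspot locus, plasma cfDNA is a mixture of maternal and
fetal DNA, so the observed alleles reflect a four-letter "pseudo-tetraploid"
genotype: two maternal letters followed by two fetal letters over the
alphabet {A, B}, where A is the reference base and B the most frequent
alternative. Mendelian transmission from the mother leaves 7 of the 9
mother-fetus combinations admissible. The expected B-allele fraction of a
combination at fetal fraction ``f`` is

    p(combo, f) = (1 - f) * b_m / 2 + f * b_f / 2

with ``b_m``/``b_f`` the maternal/fetal B-allele counts. Alt read counts
are modelled as Binomial(depth, clamp(p, e, 1-e)) with a sequencing error
floor ``e``. Fetal fraction is estimated by EM over the combination space,
iterating until the change in the estimate drops below 0.001; locus
genotypes are then the maximum a posteriori combinations at the converged
fraction, and disease status follows from the fetal genotypes under an
autosomal-recessive model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.special import logsumexp
from scipy.stats import binom

GENOTYPES = ("AA", "AB", "BB")

#: Canonical order of the admissible pseudo-tetraploid combinations.
COMBOS = ("AAAA", "AAAB", "ABAA", "ABAB", "ABBB", "BBAB", "BBBB")


class PTGError(ValueError):
    pass


@dataclass(frozen=True)
class AllelePileup:
    """Ref/alt read counts at one hotspot locus."""

    locus_id: str
    ref_count: int
    alt_count: int

    def __post_init__(self) -> None:
        if self.ref_count < 0 or self.alt_count < 0:
            raise PTGError(f"{self.locus_id}: negative read count")

    @property
    def depth(self) -> int:
        return self.ref_count + self.alt_count


@dataclass(frozen=True)
class LocusInfo:
    """Per-locus metadata: gene, disease and population B-allele frequency."""

    locus_id: str
    gene: str
    disease: str = ""
    inheritance: str = "AR"
    baf: float = 0.01
    chrom: str = "."
    pos: int = 0


@dataclass
class FetalFractionEstimate:
    f: float
    n_iterations: int
    trajectory: list[float]
    converged: bool
    loglik_trajectory: list[float] = field(default_factory=list)


@dataclass
class LocusGenotypeCall:
    locus_id: str
    posterior: dict[str, float]
    map_combo: str
    fetal_call: str  # AA / AB / BB


@dataclass
class VariantCall:
    locus_id: str
    gene: str
    map_combo: str
    pgc: str  # e.g. "ABab": maternal uppercase, fetal lowercase
    status: str  # "ND" | "heterozygous" | "homozygous"


# ---------------------------------------------------------------------------
# combination space


def mendelian_compatible(maternal: str, fetal: str) -> bool:
    """The fetus inherits one maternal allele: genotypes must share a letter."""
    return bool(set(maternal) & set(fetal))


def pseudo_tetraploid_space() -> list[str]:
    """The 7 admissible mother-fetus combinations, derived by enumeration."""
    return [m + f for m in GENOTYPES for f in GENOTYPES if mendelian_compatible(m, f)]


def expected_alt_fraction(combo: str, f: float) -> float:
    """Expected mixture B-allele fraction of a combination at fetal fraction f."""
    if combo not in COMBOS:
        raise PTGError(f"inadmissible combination {combo!r}")
    if not 0.0 < f < 1.0:
        raise PTGError(f"fetal fraction {f} outside (0, 1)")
    b_m = combo[:2].count("B")
    b_f = combo[2:].count("B")
    return (1.0 - f) * b_m / 2.0 + f * b_f / 2.0


def informative_combinations() -> list[str]:
    """Combinations whose expected alt fraction varies with fetal fraction."""
    return [
        c for c in pseudo_tetraploid_space()
        if expected_alt_fraction(c, 0.1) != expected_alt_fraction(c, 0.3)
    ]


def pgc_string(combo: str) -> str:
    """Display form: maternal letters uppercase, fetal letters lowercase."""
    return combo[:2] + combo[2:].lower()


# ---------------------------------------------------------------------------
# likelihood


def _alt_probs(f: float, error_rate: float) -> np.ndarray:
    p = np.array([expected_alt_fraction(c, f) for c in COMBOS])
    return np.clip(p, error_rate, 1.0 - error_rate)


def locus_log_likelihood(
    pileup: AllelePileup, combo: str, f: float, error_rate: float = 0.005
) -> float:
    """log P(alt_count | combo, f) under the clamped binomial count model.

    Zero-depth pileups are uninformative and return 0 for every combination.
    """
    if not 0.0 <= error_rate < 0.5:
        raise PTGError(f"error_rate {error_rate} outside [0, 0.5)")
    if pileup.depth == 0:
        return 0.0
    p = float(np.clip(expected_alt_fraction(combo, f), error_rate, 1.0 - error_rate))
    return float(binom.logpmf(pileup.alt_count, pileup.depth, p))


def _loglik_matrix(depths: np.ndarray, alts: np.ndarray, f: float, error_rate: float) -> np.ndarray:
    """(n_loci, 7) log-likelihoods; zero-depth rows are all-zero."""
    p = _alt_probs(f, error_rate)
    ll = binom.logpmf(alts[:, None], depths[:, None], p[None, :])
    ll[depths == 0] = 0.0
    return ll


# ---------------------------------------------------------------------------
# priors


def hwe_combo_priors(baf: float) -> np.ndarray:
    """Hardy-Weinberg prior over the 7 combinations.

    Maternal genotype from HWE at population B-allele frequency ``baf``;
    the fetal genotype combines a uniformly drawn maternal allele with a
    paternal allele drawn at the population frequency.
    """
    if not 0.0 < baf < 1.0:
        raise PTGError(f"population allele frequency {baf} outside (0, 1)")
    q, p = baf, 1.0 - baf
    maternal = {"AA": p * p, "AB": 2 * p * q, "BB": q * q}
    fetal_given = {
        "AA": {"AA": p, "AB": q, "BB": 0.0},
        "AB": {"AA": p / 2, "AB": 0.5, "BB": q / 2},
        "BB": {"AA": 0.0, "AB": p, "BB": q},
    }
    out = np.array([maternal[c[:2]] * fetal_given[c[:2]][c[2:]] for c in COMBOS])
    return out / out.sum()


def _prepare_priors(priors, n_loci: int) -> np.ndarray:
    if priors is None:
        priors = np.full(len(COMBOS), 1.0 / len(COMBOS))
    priors = np.asarray(priors, dtype=float)
    if priors.ndim == 1:
        priors = np.broadcast_to(priors, (n_loci, len(COMBOS)))
    if priors.shape != (n_loci, len(COMBOS)):
        raise PTGError(f"priors shape {priors.shape} incompatible with {n_loci} loci")
    if np.any(priors < 0):
        raise PTGError("negative prior probability")
    return priors / priors.sum(axis=1, keepdims=True)


# ---------------------------------------------------------------------------
# EM fetal-fraction estimation

_INFORMATIVE_IDX = np.array([COMBOS.index(c) for c in ("AAAB", "ABAA", "ABBB", "BBAB")])


def estimate_fetal_fraction_em(
    pileups: list[AllelePileup],
    priors: np.ndarray | None = None,
    f_init: float = 0.10,
    tolerance: float = 0.001,
    max_iter: int = 100,
    error_rate: float = 0.005,
    f_bounds: tuple[float, float] = (0.001, 0.499),
) -> FetalFractionEstimate:
    """EM estimate of the fetal fraction from hotspot allele pileups.

    E-step: posterior over the 7 combinations per locus at the current
    fraction. M-step: 1-D maximization of the expected complete-data
    log-likelihood over ``f_bounds``. Iterates until the change in the
    estimate is below ``tolerance`` (default 0.001). The observed-data
    log-likelihood is non-decreasing across iterations.
    """
    if not pileups:
        raise PTGError("need at least one pileup")
    if not 0.0 < f_init < 1.0:
        raise PTGError(f"f_init {f_init} outside (0, 1)")
    depths = np.array([p.depth for p in pileups])
    alts = np.array([p.alt_count for p in pileups])
    log_prior = np.log(_prepare_priors(priors, len(pileups)))

    f = float(f_init)
    trajectory = [f]
    ll_trace: list[float] = []
    converged = False
    for it in range(1, max_iter + 1):
        ll = _loglik_matrix(depths, alts, f, error_rate)
        joint = log_prior + ll
        norm = logsumexp(joint, axis=1)
        ll_trace.append(float(norm.sum()))
        gamma = np.exp(joint - norm[:, None])

        # less than half a locus of posterior mass on the informative
        # combinations means the data carry no usable fraction signal
        if it == 1 and gamma[:, _INFORMATIVE_IDX].sum() < 0.5:
            warnings.warn(
                "no informative loci: all posterior mass on fraction-constant "
                "combinations; fetal fraction not estimable",
                stacklevel=2,
            )
            return FetalFractionEstimate(f, 0, trajectory, False, ll_trace)

        def neg_q(x: float) -> float:
            ll_x = _loglik_matrix(depths, alts, x, error_rate)
            with np.errstate(invalid="ignore"):  # 0 * -inf for excluded combos
                prod = gamma * ll_x
            return -float(np.where(gamma > 0, prod, 0.0).sum())

        res = minimize_scalar(neg_q, bounds=f_bounds, method="bounded",
                              options={"xatol": 1e-5})
        f_new = float(res.x)
        trajectory.append(f_new)
        if abs(f_new - f) < tolerance:
            f = f_new
            converged = True
            break
        f = f_new
    n_iter = len(trajectory) - 1
    return FetalFractionEstimate(f, n_iter, trajectory, converged, ll_trace)


# ---------------------------------------------------------------------------
# MAP genotyping and variant calling


def map_genotypes(
    pileups: list[AllelePileup],
    f: float,
    priors: np.ndarray | None = None,
    error_rate: float = 0.005,
) -> list[LocusGenotypeCall]:
    """Maximum a posteriori combination per locus at fetal fraction ``f``.

    Ties break to the lowest-index combination in canonical order.
    """
    if not 0.0 < f < 1.0:
        raise PTGError(f"fetal fraction {f} outside (0, 1)")
    depths = np.array([p.depth for p in pileups])
    alts = np.array([p.alt_count for p in pileups])
    log_prior = np.log(_prepare_priors(priors, len(pileups)))
    joint = log_prior + _loglik_matrix(depths, alts, f, error_rate)
    post = np.exp(joint - logsumexp(joint, axis=1)[:, None])
    calls = []
    for pileup, row in zip(pileups, post):
        k = int(np.argmax(row))  # argmax takes the first maximum: canonical tie-break
        combo = COMBOS[k]
        calls.append(
            LocusGenotypeCall(
                locus_id=pileup.locus_id,
                posterior=dict(zip(COMBOS, row.tolist())),
                map_combo=combo,
                fetal_call=combo[2:],
            )
        )
    return calls


def call_variants(
    calls: list[LocusGenotypeCall], loci_meta: dict[str, LocusInfo]
) -> list[VariantCall]:
    """Per-locus fetal variant report.

    Fetal genotype BB reports a homozygous variant, AB a heterozygous
    (carrier) allele, AA reports "ND" (not detected).
    """
    out = []
    for call in calls:
        meta = loci_meta.get(call.locus_id)
        if meta is None:
            raise PTGError(f"no inheritance metadata for locus {call.locus_id}")
        status = {"AA": "ND", "AB": "heterozygous", "BB": "homozygous"}[call.fetal_call]
        out.append(
            VariantCall(
                locus_id=call.locus_id,
                gene=meta.gene,
                map_combo=call.map_combo,
                pgc=pgc_string(call.map_combo),
                status=status,
            )
        )
    return out


def disease_status(
    variant_calls: list[VariantCall], loci_meta: dict[str, LocusInfo]
) -> dict[str, str]:
    """Autosomal-recessive status per gene from the called fetal alleles.

    Two pathogenic alleles across a gene's loci (homozygous, or compound
    heterozygous) mean affected; one means carrier; none, non-carrier.
    """
    alleles: dict[str, int] = {}
    for vc in variant_calls:
        gene = vc.gene
        alleles.setdefault(gene, 0)
        if vc.status == "homozygous":
            alleles[gene] += 2
        elif vc.status == "heterozygous":
            alleles[gene] += 1
    for info in loci_meta.values():
        alleles.setdefault(info.gene, 0)
    return {
        gene: "affected" if n >= 2 else ("carrier" if n == 1 else "non-carrier")
        for gene, n in alleles.items()
    }


# ---------------------------------------------------------------------------
# pileup TSV and minimal VCF output


def write_pileups_tsv(pileups: list[AllelePileup], path) -> None:
    with open(path, "w") as fh:
        fh.write("locus_id\tref\talt\tref_count\talt_count\n")
        for p in pileups:
            fh.write(f"{p.locus_id}\tA\tB\t{p.ref_count}\t{p.alt_count}\n")


def read_pileups_tsv(path) -> list[AllelePileup]:
    pileups = []
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("locus_id"):
            raise PTGError(f"{path}: missing pileup header")
        for line in fh:
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 5:
                raise PTGError(f"{path}: expected 5 columns, got {len(fields)}")
            pileups.append(AllelePileup(fields[0], int(fields[3]), int(fields[4])))
    return pileups


def write_variants_vcf(
    variant_calls: list[VariantCall], loci_meta: dict[str, LocusInfo], path
) -> None:
    """Minimal VCF: one record per detected fetal variant."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=GENE,Number=1,Type=String,Description="Gene">\n')
        fh.write('##INFO=<ID=PGC,Number=1,Type=String,Description="Pseudo-tetraploid combination">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Fetal genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tFETUS\n")
        for vc in variant_calls:
            if vc.status == "ND":
                continue
            meta = loci_meta[vc.locus_id]
            gt = "1/1" if vc.status == "homozygous" else "0/1"
            fh.write(
                f"{meta.chrom}\t{meta.pos}\t{vc.locus_id}\tA\tB\t.\tPASS\t"
                f"GENE={vc.gene};PGC={vc.pgc}\tGT\t{gt}\n"
            )
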