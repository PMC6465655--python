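"""Euploid background database for Z-value scoring.

Counts are standardized to one million reads over a scope: the 7,631
autosomal backbone regions for autosomal statistics, the full 8,171
backbone regions for the sex chromosomes. The background database stores
the per-region and per-chromosome mean/SD of those normalized depths
across the reference cohort, chrY summary statistics used for fetal sex
inference, and the 95% interval of background segment medians that the
CNV caller uses as its final criterion.

The chromosome-level X baseline is stratified by the fetal sex of the
background samples (classified internally from their chrY signal),
because a male fetus depresses the X dose by f/2.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .genome import AUTOSOMES
from .panel import Panel
from .simulate import RegionCounts

MILLION = 1_000_000.0


class BaselineError(ValueError):
    pass


def normalize_counts(counts: RegionCounts, scope: np.ndarray) -> np.ndarray:
    """Standardize the counts over ``scope`` indices to one million reads.

    Returns depths over the scope (in scope order); they sum to 1e6.
    """
    sub = counts.counts[scope].astype(float)
    total = sub.sum()
    if total <= 0:
        raise BaselineError(f"{counts.sample_id}: zero total count in scope")
    return sub * (MILLION / total)


def chromosome_statistic(counts: np.ndarray, panel: Panel, chrom: str) -> float:
    """Chromosome-level dosage statistic for one autosome.

    Mean read count of the chromosome's backbone regions divided by the
    median of the other autosomes' mean region counts. Normalizing
    against the median of the remaining chromosomes removes library size
    while staying robust to a dosage change anywhere in the genome: a
    trisomy neither biases its own statistic through the denominator nor
    leaks into any other chromosome's statistic (which a plain shared
    library-size denominator does).
    """
    from .genome import AUTOSOMES, is_autosome

    if not is_autosome(chrom):
        raise BaselineError(f"chromosome statistic is autosomal; got {chrom}")
    counts = np.asarray(counts, dtype=float)
    own = panel.backbone_index(chrom)
    if len(own) == 0:
        raise BaselineError(f"no backbone regions on chromosome {chrom}")
    others = []
    for c in AUTOSOMES:
        if c == chrom:
            continue
        idx = panel.backbone_index(c)
        if len(idx):
            others.append(counts[idx].mean())
    denom = float(np.median(others)) if others else 0.0
    if denom <= 0:
        raise BaselineError(f"zero denominator for chromosome {chrom}")
    return float(counts[own].mean() / denom)


def _floor_sd(sd: np.ndarray) -> np.ndarray:
    """Replace zero SDs by the smallest positive SD (degenerate cohorts only)."""
    sd = sd.copy()
    positive = sd[sd > 0]
    if positive.size:
        sd[sd == 0] = positive.min()
    return sd


@dataclass
class BaselineDB:
    """Background statistics bundle keyed to a panel checksum."""

    panel_checksum: str
    n_samples: int
    region_mean: np.ndarray  # over backbone regions (scope-matched, see module doc)
    region_sd: np.ndarray
    chrom_mean: dict[str, float]  # autosomes
    chrom_sd: dict[str, float]
    x_mean: dict[str, float | None]  # per fetal-sex stratum "XX"/"XY"
    x_sd: dict[str, float | None]
    y_median_mean: float
    y_median_sd: float
    y_mean_mean: float
    y_mean_sd: float
    male_y_reference: float | None  # mean chrY median depth of XY background samples
    background_median_interval: tuple[float, float]
    cohort_sex: list[str] = field(default_factory=list)

    def check_panel(self, panel: Panel) -> None:
        if panel.checksum() != self.panel_checksum:
            raise BaselineError(
                "panel checksum mismatch: baseline was built on a different panel"
            )


def classify_cohort_sex(
    all_depths: np.ndarray, y_idx: np.ndarray, y_positive_frac: float = 0.04
) -> np.ndarray:
    """Fetal sex of background samples from their chrY median depth.

    A sample is called XY when its median chrY depth exceeds
    ``y_positive_frac`` of the mean backbone depth; a female fetus
    contributes no Y dose at all, so the two groups are well separated
    at clinical fetal fractions.
    """
    y_median = np.median(all_depths[:, y_idx], axis=1)
    threshold = y_positive_frac * MILLION / all_depths.shape[1]
    return np.where(y_median > threshold, "XY", "XX")


def build_baseline(
    cohort: list[RegionCounts],
    panel: Panel,
    median_interval: str = "segment",
    y_qc_subset: list[int] | None = None,
    haarseg_kwargs: dict | None = None,
) -> BaselineDB:
    """Construct the background database from a euploid cohort.

    ``median_interval`` selects how the 95% background-median interval is
    computed: ``"segment"`` (default) segments every background sample's
    region Z-values and takes the 2.5th-97.5th percentile of segment
    medians; ``"sample"`` uses per-sample medians of region Z instead.
    ``y_qc_subset`` optionally restricts the chrY baseline to a sample
    subset (all samples by default).
    """
    if len(cohort) < 2:
        raise BaselineError("need >= 2 background samples")
    n_backbone = panel.n_backbone
    for s in cohort:
        if len(s.counts) != n_backbone:
            raise BaselineError(f"{s.sample_id}: counts do not match panel dimensions")

    auto_idx = panel.autosomal_index
    all_idx = panel.backbone_index()
    x_idx = panel.backbone_index("X")
    y_idx = panel.backbone_index("Y")

    auto_depths = np.stack([normalize_counts(s, auto_idx) for s in cohort])
    all_depths = np.stack([normalize_counts(s, all_idx) for s in cohort])

    # Region-level stats: autosomal regions on the autosomal scope,
    # sex-chromosome regions on the whole-panel scope.
    region_mean = np.empty(n_backbone)
    region_sd = np.empty(n_backbone)
    region_mean[auto_idx] = auto_depths.mean(axis=0)
    region_sd[auto_idx] = auto_depths.std(axis=0, ddof=1)
    sex_idx = np.concatenate([x_idx, y_idx])
    region_mean[sex_idx] = all_depths[:, sex_idx].mean(axis=0)
    region_sd[sex_idx] = all_depths[:, sex_idx].std(axis=0, ddof=1)
    region_sd = _floor_sd(region_sd)

    chroms = panel.backbone_chroms
    counts_matrix = np.stack([s.counts.astype(float) for s in cohort])
    chrom_mean, chrom_sd = {}, {}
    for chrom in AUTOSOMES:
        if len(panel.backbone_index(chrom)) == 0:
            continue
        stat = np.array([
            chromosome_statistic(row, panel, chrom) for row in counts_matrix
        ])
        chrom_mean[chrom] = float(stat.mean())
        chrom_sd[chrom] = float(stat.std(ddof=1))
    sds = np.array(list(chrom_sd.values()))
    if (sds > 0).any():
        floor = sds[sds > 0].min()
        chrom_sd = {c: (v if v > 0 else float(floor)) for c, v in chrom_sd.items()}

    # X stratified by background fetal sex; Y summary over XY samples.
    sex = classify_cohort_sex(all_depths, y_idx)
    x_stat = all_depths[:, x_idx].mean(axis=1)
    x_mean: dict[str, float | None] = {}
    x_sd: dict[str, float | None] = {}
    for stratum in ("XX", "XY"):
        rows = np.flatnonzero(sex == stratum)
        if len(rows) >= 2:
            x_mean[stratum] = float(x_stat[rows].mean())
            x_sd[stratum] = float(x_stat[rows].std(ddof=1))
        else:
            x_mean[stratum] = None
            x_sd[stratum] = None

    y_rows = np.flatnonzero(sex == "XY")
    if y_qc_subset is not None:
        y_rows = np.intersect1d(y_rows, np.asarray(y_qc_subset))
    y_median = np.median(all_depths[:, y_idx], axis=1)
    y_mean = all_depths[:, y_idx].mean(axis=1)
    if len(y_rows) >= 2:
        y_stats = (
            float(y_median[y_rows].mean()), float(y_median[y_rows].std(ddof=1)),
            float(y_mean[y_rows].mean()), float(y_mean[y_rows].std(ddof=1)),
        )
        male_ref = float(y_median[y_rows].mean())
    else:
        y_stats = (0.0, 0.0, 0.0, 0.0)
        male_ref = None

    db = BaselineDB(
        panel_checksum=panel.checksum(),
        n_samples=len(cohort),
        region_mean=region_mean,
        region_sd=region_sd,
        chrom_mean=chrom_mean,
        chrom_sd=chrom_sd,
        x_mean=x_mean,
        x_sd=x_sd,
        y_median_mean=y_stats[0],
        y_median_sd=y_stats[1],
        y_mean_mean=y_stats[2],
        y_mean_sd=y_stats[3],
        male_y_reference=male_ref,
        background_median_interval=(0.0, 0.0),
        cohort_sex=sex.tolist(),
    )
    db.background_median_interval = _median_interval(
        db, panel, cohort, auto_depths, method=median_interval,
        haarseg_kwargs=haarseg_kwargs,
    )
    return db


def _median_interval(
    db: BaselineDB,
    panel: Panel,
    cohort: list[RegionCounts],
    auto_depths: np.ndarray,
    method: str,
    haarseg_kwargs: dict | None,
) -> tuple[float, float]:
    auto_idx = panel.autosomal_index
    sd = db.region_sd[auto_idx]
    if not np.any(sd > 0):  # fully degenerate cohort: no Z scale exists
        return (0.0, 0.0)
    z = (auto_depths - db.region_mean[auto_idx]) / sd
    if method == "sample":
        medians = np.median(z, axis=1)
    elif method == "segment":
        from .cnv import haarseg_segment  # lazy: avoids a module cycle

        kwargs = haarseg_kwargs or {}
        chroms = panel.backbone_chroms[auto_idx]
        medians_list = []
        for row in z:
            for chrom in AUTOSOMES:
                cols = np.flatnonzero(chroms == chrom)
                if len(cols) < 2:
                    continue
                for seg in haarseg_segment(row[cols], **kwargs):
                    medians_list.append(seg.median_z)
        medians = np.array(medians_list)
    else:
        raise BaselineError(f"unknown median_interval method {method!r}")
    lo, hi = np.percentile(medians, [2.5, 97.5])
    return (float(lo), float(hi))


# ---------------------------------------------------------------------------
# serialization (single JSON bundle)


def save_baseline(db: BaselineDB, path) -> None:
    payload = {
        "panel_checksum": db.panel_checksum,
        "n_samples": db.n_samples,
        "region_mean": db.region_mean.tolist(),
        "region_sd": db.region_sd.tolist(),
        "chrom_mean": db.chrom_mean,
        "chrom_sd": db.chrom_sd,
        "x_mean": db.x_mean,
        "x_sd": db.x_sd,
        "y_median_mean": db.y_median_mean,
        "y_median_sd": db.y_median_sd,
        "y_mean_mean": db.y_mean_mean,
        "y_mean_sd": db.y_mean_sd,
        "male_y_reference": db.male_y_reference,
        "background_median_interval": list(db.background_median_interval),
        "cohort_sex": db.cohort_sex,
    }
    with open(path, "w") as fh:
        json.dump(payload, fh)


def load_baseline(path) -> BaselineDB:
    with open(path) as fh:
        payload = json.load(fh)
    payload["region_mean"] = np.array(payload["region_mean"])
    payload["region_sd"] = np.array(payload["region_sd"])
    payload["background_median_interval"] = tuple(payload["background_median_interval"])
    return BaselineDB(**payload)
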