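"""Chromosome-level aneuploidy calling from backbone region counts.

For each chromosome the statistic is the mean normalized depth of its
backbone regions; the Z-value standardizes it against the euploid
background. Autosomal trisomy (monosomy) is called at Z >= z_cut
(Z <= -z_cut), with z_cut = 3 by default. Fetal sex is inferred from the
median and mean depth of the 88 chrY regions relative to the male signal
observed in the background cohort, and the sex karyotype (XX, XY, 45,X,
47,XXY) is refined with the chrX Z-value computed against the
fetal-sex-matched background stratum.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .baseline import BaselineDB, chromosome_statistic, normalize_counts
from .genome import AUTOSOMES
from .panel import Panel
from .simulate import RegionCounts

EUPLOID = "euploid"
TRISOMY = "trisomy"
MONOSOMY = "monosomy"


class AneuploidyError(ValueError):
    pass


@dataclass
class ChromosomeZ:
    chrom: str
    statistic: float
    z: float


@dataclass
class AneuploidyCall:
    """Chromosome-level result for one sample."""

    sample_id: str
    calls: list[tuple[str, str]]  # (chrom, state) for non-euploid autosomes
    fetal_sex: str  # XX | XY
    sex_karyotype: str  # XX | XY | X0 | XXY | other
    autosome_z: list[ChromosomeZ] = field(default_factory=list)
    x_z: float | None = None
    y_median: float = 0.0
    y_mean: float = 0.0

    def state(self, chrom: str) -> str:
        for c, s in self.calls:
            if c == chrom:
                return s
        return EUPLOID


def chromosome_z(sample: RegionCounts, baseline: BaselineDB, panel: Panel) -> list[ChromosomeZ]:
    """Autosomal chromosome Z-values against the background."""
    baseline.check_panel(panel)
    out = []
    for chrom in AUTOSOMES:
        if len(panel.backbone_index(chrom)) == 0:
            continue
        stat = chromosome_statistic(sample.counts, panel, chrom)
        sd = baseline.chrom_sd[chrom]
        if sd == 0:
            raise AneuploidyError(f"chromosome {chrom}: zero baseline SD after flooring")
        out.append(ChromosomeZ(chrom, stat, (stat - baseline.chrom_mean[chrom]) / sd))
    return out


def call_autosomal_aneuploidy(zs: list[ChromosomeZ], z_cut: float = 3.0) -> list[tuple[str, str]]:
    """Trisomy at z >= z_cut, monosomy at z <= -z_cut, else euploid."""
    calls = []
    for cz in zs:
        if cz.z >= z_cut:
            calls.append((cz.chrom, TRISOMY))
        elif cz.z <= -z_cut:
            calls.append((cz.chrom, MONOSOMY))
    return calls


def _x_z(stat: float, baseline: BaselineDB, stratum: str) -> float | None:
    mean, sd = baseline.x_mean.get(stratum), baseline.x_sd.get(stratum)
    if mean is None or sd is None or sd == 0:
        return None
    return (stat - mean) / sd


def infer_fetal_sex(
    sample: RegionCounts,
    baseline: BaselineDB,
    panel: Panel,
    male_frac: float = 0.25,
    x_cut: float = 3.0,
) -> tuple[str, str, dict]:
    """Fetal sex and sex karyotype from chrY depth and stratified chrX Z.

    Returns ``(fetal_sex, sex_karyotype, details)``. A sample is
    Y-positive when both the median and mean chrY depth exceed
    ``male_frac`` of the male chrY signal observed in the background
    cohort. Y-positive samples are scored against the XY background
    stratum on X: an X dose back at the two-copy level (Z >= x_cut)
    indicates 47,XXY, while an X dose *below* the male level conflicts
    and is flagged "other". Y-negative samples score against the XX
    stratum: Z <= -x_cut indicates 45,X.
    """
    baseline.check_panel(panel)
    y_idx = panel.backbone_index("Y")
    x_idx = panel.backbone_index("X")
    if len(y_idx) == 0:
        raise AneuploidyError("panel contains no chrY regions")
    all_depths = normalize_counts(sample, panel.backbone_index())
    y_median = float(np.median(all_depths[y_idx]))
    y_mean = float(all_depths[y_idx].mean())
    x_stat = float(all_depths[x_idx].mean()) if len(x_idx) else float("nan")

    if baseline.male_y_reference:
        threshold = male_frac * baseline.male_y_reference
    else:  # no XY samples in background: fall back to an absolute floor
        threshold = 0.04 * 1_000_000.0 / panel.n_backbone
    y_positive = y_median >= threshold and y_mean >= threshold

    stratum = "XY" if y_positive else "XX"
    xz = _x_z(x_stat, baseline, stratum)
    details = {"y_median": y_median, "y_mean": y_mean, "y_threshold": threshold,
               "x_statistic": x_stat, "x_z": xz, "x_stratum": stratum}

    if xz is None:
        karyotype = "XY" if y_positive else "XX"
    elif y_positive:
        if xz >= x_cut:
            karyotype = "XXY"
        elif xz <= -x_cut:
            karyotype = "other"  # Y signal but X below the male level
        else:
            karyotype = "XY"
    else:
        if xz <= -x_cut:
            karyotype = "X0"
        elif xz >= x_cut:
            karyotype = "other"  # extra X dose without Y signal (not modelled)
        else:
            karyotype = "XX"
    fetal_sex = "XY" if y_positive else "XX"
    return fetal_sex, karyotype, details


def call_sample(
    sample: RegionCounts,
    baseline: BaselineDB,
    panel: Panel,
    z_cut: float = 3.0,
    x_cut: float = 3.0,
    male_frac: float = 0.25,
) -> AneuploidyCall:
    """Full chromosome-level screen of one sample."""
    zs = chromosome_z(sample, baseline, panel)
    calls = call_autosomal_aneuploidy(zs, z_cut)
    fetal_sex, karyotype, details = infer_fetal_sex(sample, baseline, panel, male_frac, x_cut)
    return AneuploidyCall(
        sample_id=sample.sample_id,
        calls=calls,
        fetal_sex=fetal_sex,
        sex_karyotype=karyotype,
        autosome_z=zs,
        x_z=details["x_z"],
        y_median=details["y_median"],
        y_mean=details["y_mean"],
    )


#: Autosomes on the clinical trisomy screen (Patau, Edwards, Down).
SCREENED_TRISOMIES = ("13", "18", "21")


def clinical_result(call: AneuploidyCall, screened: tuple[str, ...] = SCREENED_TRISOMIES) -> str:
    """The per-sample screening result the assay reports.

    The clinical screen covers the common viable trisomies (13, 18, 21)
    and the sex karyotype; the full 22-chromosome Z table remains
    available in the call object for review.
    """
    parts = [f"T{c}" for c in screened if call.state(c) == TRISOMY]
    if call.sex_karyotype not in ("XX", "XY"):
        parts.append(call.sex_karyotype)
    return ",".join(parts) if parts else f"euploid {call.sex_karyotype}"


def result_label(call: AneuploidyCall) -> str:
    """Compact clinical-style label, e.g. "T21", "X0", "XXY", "euploid XY"."""
    if call.sex_karyotype in ("X0", "XXY", "other"):
        return call.sex_karyotype
    labels = [("T" if s == TRISOMY else "M") + c for c, s in call.calls]
    return ",".join(labels) if labels else f"euploid {call.sex_karyotype}"


def report_frame(call: AneuploidyCall) -> pd.DataFrame:
    """Per-chromosome report table (statistic, Z) plus a summary row."""
    rows = [
        {"chrom": cz.chrom, "statistic": round(cz.statistic, 3), "z": round(cz.z, 2),
         "call": call.state(cz.chrom)}
        for cz in call.autosome_z
    ]
    rows.append({"chrom": "X", "statistic": float("nan"),
                 "z": round(call.x_z, 2) if call.x_z is not None else float("nan"),
                 "call": call.sex_karyotype})
    rows.append({"chrom": "Y", "statistic": round(call.y_median, 3),
                 "z": float("nan"), "call": call.fetal_sex})
    rows.append({"chrom": "result", "statistic": float("nan"), "z": float("nan"),
                 "call": result_label(call)})
    return pd.DataFrame(rows)
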