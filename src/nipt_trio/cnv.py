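"""Sub-chromosomal CNV detection: region Z-values, Haar-wavelet segmentation,
and duplication/deletion calling.

Segmentation follows the HaarSeg approach: undecimated Haar wavelet
convolution of the region Z profile at dyadic scales, local maxima of the
absolute coefficients as breakpoint candidates, candidate selection by
Benjamini-Hochberg FDR against a robust noise estimate (1.4826 x MAD of
the finest-scale coefficients), and piecewise-constant reconstruction.
Finer scales take precedence when candidates from several scales point at
the same breakpoint, which keeps boundary localization at region
resolution.

A segment becomes a CNV call only when all four criteria hold:
(1) it spans at least 20 consecutive regions AND at least 10 Mb,
(2) its mean Z lies outside [-0.7, 0.7],
(3) its median Z lies outside [-2, 2], and
(4) its median Z lies outside the 95% interval of background segment
medians stored in the baseline.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import norm

from .baseline import BaselineDB, normalize_counts
from .genome import AUTOSOMES, SEX_CHROMS
from .panel import Panel
from .simulate import RegionCounts

DUP = "dup"
DEL = "del"


class CNVError(ValueError):
    pass


@dataclass
class Segment:
    """Half-open run of regions [start_index, end_index) on one chromosome."""

    start_index: int
    end_index: int
    mean_z: float
    median_z: float
    chrom: str = ""

    @property
    def n_regions(self) -> int:
        return self.end_index - self.start_index


@dataclass
class CNVCall:
    chrom: str
    start: int
    end: int
    size: int
    direction: str
    median_z: float
    mean_z: float
    n_regions: int

    def iscn(self) -> str:
        kind = "dup" if self.direction == DUP else "del"
        return f"seq[GRCh37-sim]{kind}({self.chrom})(bands unavailable)"


# ---------------------------------------------------------------------------
# region-level Z


def region_z(sample: RegionCounts, baseline: BaselineDB, panel: Panel) -> dict[str, np.ndarray]:
    """Per-chromosome region Z vectors, panel-ordered.

    Autosomes are normalized on the autosomal scope, X/Y on the whole
    backbone scope, matching how the baseline was built.
    """
    baseline.check_panel(panel)
    auto_idx = panel.autosomal_index
    all_idx = panel.backbone_index()
    depths = np.empty(panel.n_backbone)
    depths[auto_idx] = normalize_counts(sample, auto_idx)
    all_depths = normalize_counts(sample, all_idx)
    chroms = panel.backbone_chroms
    for chrom in SEX_CHROMS:
        idx = panel.backbone_index(chrom)
        depths[idx] = all_depths[idx]
    if np.any(baseline.region_sd == 0):
        raise CNVError("baseline region SD is zero even after flooring")
    z = (depths - baseline.region_mean) / baseline.region_sd
    if not np.all(np.isfinite(z)):
        raise CNVError("non-finite region Z values")
    return {chrom: z[panel.backbone_index(chrom)] for chrom in AUTOSOMES + SEX_CHROMS
            if len(panel.backbone_index(chrom))}


# ---------------------------------------------------------------------------
# HaarSeg-style segmentation


def _haar_coefficients(x: np.ndarray, h: int) -> np.ndarray:
    """Unit-norm Haar wavelet coefficients at half-width ``h``.

    ``W[i]`` contrasts the ``h`` values starting at ``i`` against the
    ``h`` values ending at ``i-1``; a breakpoint *before* index ``i``
    yields a local extremum at ``i``. Positions without a full window
    are NaN.
    """
    n = len(x)
    w = np.full(n, np.nan)
    if n < 2 * h:
        return w
    c = np.concatenate([[0.0], np.cumsum(x)])
    right = c[2 * h:] - c[h:n - h + 1]
    left = c[h:n - h + 1] - c[: n - 2 * h + 1]
    w[h:n - h + 1] = (right - left) / np.sqrt(2 * h)
    return w


def _local_maxima(absw: np.ndarray) -> list[int]:
    """Indices of strict-ish local maxima of |W| (leftmost on plateaus)."""
    peaks = []
    n = len(absw)
    i = 0
    while i < n:
        if not np.isfinite(absw[i]) or absw[i] <= 0:
            i += 1
            continue
        j = i
        while j + 1 < n and absw[j + 1] == absw[i]:
            j += 1
        left_ok = i == 0 or not np.isfinite(absw[i - 1]) or absw[i - 1] < absw[i]
        right_ok = j == n - 1 or not np.isfinite(absw[j + 1]) or absw[j + 1] < absw[i]
        if left_ok and right_ok:
            peaks.append(i)
        i = j + 1
    return peaks


def _bh_keep(pvals: np.ndarray, q: float) -> np.ndarray:
    """Benjamini-Hochberg: boolean mask of rejected (kept) hypotheses."""
    m = len(pvals)
    if m == 0:
        return np.zeros(0, dtype=bool)
    order = np.argsort(pvals)
    ranked = pvals[order]
    below = ranked <= q * (np.arange(1, m + 1) / m)
    if not below.any():
        return np.zeros(m, dtype=bool)
    cutoff = ranked[np.flatnonzero(below).max()]
    return pvals <= cutoff


def haarseg_breakpoints(z: np.ndarray, max_scale: int = 5, fdr_q: float = 0.001) -> list[int]:
    """Significant breakpoint indices (segment starts, excluding 0)."""
    z = np.asarray(z, dtype=float)
    if len(z) < 2:
        return []
    if not np.all(np.isfinite(z)):
        raise CNVError("non-finite entries in Z vector")
    if not 0.0 < fdr_q < 1.0:
        raise CNVError(f"fdr_q {fdr_q} outside (0, 1)")

    w1 = _haar_coefficients(z, 1)
    finite = w1[np.isfinite(w1)]
    sigma = 1.4826 * np.median(np.abs(finite - np.median(finite))) if finite.size else 0.0

    candidates: list[tuple[int, int, float]] = []  # (scale, index, |W|)
    for scale in range(1, max_scale + 1):
        h = 2 ** (scale - 1)
        w = w1 if h == 1 else _haar_coefficients(z, h)
        absw = np.abs(w)
        peaks = _local_maxima(absw)
        if not peaks:
            continue
        stats = absw[peaks]
        if sigma > 0:
            pvals = 2.0 * norm.sf(stats / sigma)
        else:  # noiseless profile: any non-zero contrast is a true step
            pvals = np.where(stats > 0, 0.0, 1.0)
        keep = _bh_keep(pvals, fdr_q)
        candidates.extend(
            (scale, int(p), float(s)) for p, s, k in zip(peaks, stats, keep) if k
        )

    # Unify across scales: finer scales first, then larger |W|; a candidate
    # is dropped if an accepted breakpoint lies within its half-width.
    candidates.sort(key=lambda c: (c[0], -c[2], c[1]))
    accepted: list[tuple[int, int]] = []  # (index, half-width)
    for scale, idx, _ in candidates:
        h = 2 ** (scale - 1)
        if any(abs(idx - a) < max(h, ah) for a, ah in accepted):
            continue
        accepted.append((idx, h))
    return sorted(idx for idx, _ in accepted)


def haarseg_segment(
    z: np.ndarray, max_scale: int = 5, fdr_q: float = 0.001, chrom: str = ""
) -> list[Segment]:
    """Partition a chromosome's region Z vector into constant segments."""
    z = np.asarray(z, dtype=float)
    if len(z) == 0:
        return []
    bounds = [0] + haarseg_breakpoints(z, max_scale, fdr_q) + [len(z)]
    segments = []
    for a, b in zip(bounds[:-1], bounds[1:]):
        if b <= a:
            continue
        chunk = z[a:b]
        segments.append(Segment(a, b, float(chunk.mean()), float(np.median(chunk)), chrom))
    return segments


# ---------------------------------------------------------------------------
# calling


def call_cnvs(
    segments: list[Segment],
    baseline: BaselineDB,
    panel: Panel,
    min_regions: int = 20,
    min_span: int = 10_000_000,
    mean_band: float = 0.7,
    median_band: float = 2.0,
) -> list[CNVCall]:
    """Apply the four calling criteria to candidate segments."""
    lo, hi = baseline.background_median_interval
    calls = []
    for seg in segments:
        idx = panel.backbone_index(seg.chrom)
        if len(idx) == 0:
            raise CNVError(f"segment on chromosome {seg.chrom} absent from panel")
        starts = panel.backbone_starts[idx]
        ends = panel.backbone_ends[idx]
        start = int(starts[seg.start_index])
        end = int(ends[seg.end_index - 1])
        span = end - start
        if seg.n_regions < min_regions or span < min_span:
            continue
        if abs(seg.mean_z) <= mean_band:
            continue
        if abs(seg.median_z) <= median_band:
            continue
        if lo <= seg.median_z <= hi:
            continue
        calls.append(
            CNVCall(
                chrom=seg.chrom,
                start=start,
                end=end,
                size=span,
                direction=DUP if seg.median_z > 0 else DEL,
                median_z=seg.median_z,
                mean_z=seg.mean_z,
                n_regions=seg.n_regions,
            )
        )
    return calls


def call_sample_cnvs(
    sample: RegionCounts,
    baseline: BaselineDB,
    panel: Panel,
    max_scale: int = 5,
    fdr_q: float = 0.001,
    sex_karyotype: str | None = None,
    include_sex_chroms: bool = True,
    skip_chroms: set[str] | None = None,
    **criteria,
) -> list[CNVCall]:
    """Segment every chromosome of a sample and call CNVs.

    Calls on chromosomes already reported as whole-chromosome
    aneuploidies (``skip_chroms``), and on the sex chromosomes when the
    sex karyotype is abnormal, are suppressed so an aneuploidy is not
    reported a second time as a CNV.
    """
    zs = region_z(sample, baseline, panel)
    segments: list[Segment] = []
    skip_sex = (not include_sex_chroms) or (sex_karyotype not in (None, "XX", "XY"))
    for chrom, z in zs.items():
        if chrom in SEX_CHROMS and skip_sex:
            continue
        if skip_chroms and chrom in skip_chroms:
            continue
        segments.extend(haarseg_segment(z, max_scale, fdr_q, chrom=chrom))
    return call_cnvs(segments, baseline, panel, **criteria)
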