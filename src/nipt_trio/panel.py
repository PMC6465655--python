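"""Target capture panel: backbone counting regions and single-gene hotspot regions.

The panel has two kinds of regions. *Backbone* regions are equal-length
windows scattered across all chromosomes in proportion to chromosome
length; their read counts feed the chromosome- and region-level dosage
statistics. *Hotspot* regions tile common pathogenic mutation hotspots
of recessive-disease genes and carry a gene label; they are excluded
from all count-based statistics and only serve the allele-level
genotyping arm.

Coordinates are 0-based half-open throughout (BED convention).
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from functools import cached_property
from pathlib import Path

import numpy as np

from .genome import GRCH37_SIZES, chrom_sort_key, is_autosome

BACKBONE = "backbone"
HOTSPOT = "hotspot"

# Paper-scale design constants: 8,731 regions in total, of which 8,171
# equal-length backbone windows (7,631 autosomal + 452 on X + 88 on Y)
# and 560 variable-length hotspot windows over six recessive-disease genes.
N_BACKBONE = 8171
N_BACKBONE_X = 452
N_BACKBONE_Y = 88
N_HOTSPOT = 560
BACKBONE_LENGTH = 100


class PanelError(ValueError):
    """Malformed or inconsistent panel definition."""


@dataclass(frozen=True)
class TargetRegion:
    """One capture region, 0-based half-open."""

    chrom: str
    start: int
    end: int
    kind: str
    gc: float = 0.5
    gene: str | None = None

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise PanelError(
                f"region {self.chrom}:{self.start}-{self.end}: end must exceed start"
            )
        if not 0.0 <= self.gc <= 1.0:
            raise PanelError(f"gc fraction {self.gc} outside [0, 1]")
        if self.kind not in (BACKBONE, HOTSPOT):
            raise PanelError(f"unknown region kind {self.kind!r}")
        if self.kind == HOTSPOT and not self.gene:
            raise PanelError(
                f"hotspot region {self.chrom}:{self.start}-{self.end} lacks a gene label"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "TargetRegion") -> bool:
        return self.chrom == other.chrom and self.start < other.end and other.start < self.end


@dataclass
class Panel:
    """Sorted collection of target regions with cached backbone index arrays."""

    regions: list[TargetRegion]
    _backbone: list[TargetRegion] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.regions = sorted(
            self.regions, key=lambda r: (chrom_sort_key(r.chrom), r.start, r.end)
        )
        self._backbone = [r for r in self.regions if r.kind == BACKBONE]

    # -- backbone views ------------------------------------------------
    @property
    def backbone(self) -> list[TargetRegion]:
        return self._backbone

    @property
    def n_backbone(self) -> int:
        return len(self._backbone)

    @property
    def n_hotspot(self) -> int:
        return len(self.regions) - len(self._backbone)

    @cached_property
    def backbone_chroms(self) -> np.ndarray:
        return np.array([r.chrom for r in self._backbone])

    @cached_property
    def backbone_starts(self) -> np.ndarray:
        return np.array([r.start for r in self._backbone], dtype=np.int64)

    @cached_property
    def backbone_ends(self) -> np.ndarray:
        return np.array([r.end for r in self._backbone], dtype=np.int64)

    @cached_property
    def _chrom_index(self) -> dict[str, np.ndarray]:
        chroms = self.backbone_chroms
        return {c: np.flatnonzero(chroms == c) for c in dict.fromkeys(chroms.tolist())}

    @cached_property
    def _autosomal_index(self) -> np.ndarray:
        mask = np.array([is_autosome(c) for c in self.backbone_chroms])
        return np.flatnonzero(mask)

    def backbone_index(self, chrom: str | None = None, autosomal: bool = False) -> np.ndarray:
        """Indices into the backbone vector, optionally restricted."""
        if chrom is not None:
            return self._chrom_index.get(chrom, np.array([], dtype=int))
        if autosomal:
            return self._autosomal_index
        return np.arange(len(self._backbone))

    @property
    def autosomal_index(self) -> np.ndarray:
        return self.backbone_index(autosomal=True)

    def chrom_spacing(self, chrom: str) -> float:
        """Typical inter-region spacing (bp) of backbone regions on a chromosome."""
        idx = self.backbone_index(chrom)
        if len(idx) < 2:
            return float("nan")
        starts = self.backbone_starts[idx]
        return float(np.median(np.diff(starts)))

    def checksum(self) -> str:
        """Digest of the full region list; baselines refuse mismatched panels."""
        h = hashlib.sha256()
        for r in self.regions:
            h.update(f"{r.chrom}\t{r.start}\t{r.end}\t{r.kind}\t{r.gene or ''}\n".encode())
        return h.hexdigest()[:16]


# ---------------------------------------------------------------------------
# validation


def validate_panel(panel: Panel) -> list[str]:
    """Report-only validation; an empty list means all invariants hold."""
    findings: list[str] = []
    prev: TargetRegion | None = None
    for r in panel.regions:
        if prev is not None and r.overlaps(prev):
            findings.append(
                f"overlap: {prev.chrom}:{prev.start}-{prev.end} and {r.chrom}:{r.start}-{r.end}"
            )
        prev = r
    lengths = {r.length for r in panel.backbone}
    if len(lengths) > 1:
        findings.append(f"backbone length inconsistency: lengths {sorted(lengths)}")
    for r in panel.regions:
        if r.kind == HOTSPOT and not r.gene:
            findings.append(f"hotspot without gene label: {r.chrom}:{r.start}-{r.end}")
    return findings


# ---------------------------------------------------------------------------
# synthetic layout generation


def largest_remainder(weights: np.ndarray, total: int) -> np.ndarray:
    """Apportion ``total`` integer seats proportionally to ``weights``.

    Largest-remainder (Hamilton) method; seat counts sum to ``total`` exactly.
    """
    weights = np.asarray(weights, dtype=float)
    if weights.sum() <= 0:
        raise ValueError("weights must have positive sum")
    quota = weights / weights.sum() * total
    base = np.floor(quota).astype(int)
    short = total - base.sum()
    order = np.argsort(-(quota - base))
    base[order[:short]] += 1
    return base


def generate_panel_layout(
    chrom_sizes: dict[str, int],
    n_backbone: int,
    backbone_length: int,
    hotspot_spec: dict[str, list[tuple[str, int, int]]] | None = None,
    seed: int = 0,
    chrom_counts: dict[str, int] | None = None,
    gc: float = 0.5,
) -> Panel:
    """Generate an evenly spaced synthetic panel layout.

    Backbone regions are apportioned across chromosomes proportionally to
    chromosome length (largest remainder), then evenly spaced within each
    chromosome. ``chrom_counts`` pins the count of specific chromosomes
    (used for the fixed X/Y split of the default design); the remaining
    regions are apportioned over the other chromosomes. Hotspot windows
    are appended verbatim; backbone windows colliding with a hotspot are
    nudged just past it. The layout is fully deterministic; ``seed`` is
    accepted for interface symmetry with the simulators.
    """
    del seed  # layout is deterministic by construction
    chroms = sorted(chrom_sizes, key=chrom_sort_key)
    if n_backbone < len(chroms):
        raise PanelError("need at least one backbone region per chromosome")
    if backbone_length >= min(chrom_sizes.values()):
        raise PanelError("backbone_length exceeds the smallest chromosome")

    chrom_counts = dict(chrom_counts or {})
    fixed = sum(chrom_counts.values())
    free_chroms = [c for c in chroms if c not in chrom_counts]
    if free_chroms:
        sizes = np.array([chrom_sizes[c] for c in free_chroms], dtype=float)
        counts = largest_remainder(sizes, n_backbone - fixed)
        chrom_counts.update(dict(zip(free_chroms, (int(k) for k in counts))))
    elif fixed != n_backbone:
        raise PanelError("chrom_counts sum must equal n_backbone when all pinned")

    hotspots: list[TargetRegion] = []
    for gene, windows in (hotspot_spec or {}).items():
        for chrom, start, end in windows:
            hotspots.append(TargetRegion(chrom, int(start), int(end), HOTSPOT, gc, gene))
    hot_by_chrom: dict[str, list[TargetRegion]] = {}
    for h in hotspots:
        hot_by_chrom.setdefault(h.chrom, []).append(h)

    regions: list[TargetRegion] = list(hotspots)
    for chrom in chroms:
        m = chrom_counts[chrom]
        if m == 0:
            continue
        size = chrom_sizes[chrom]
        gap = size / m
        if gap <= backbone_length:
            raise PanelError(f"chromosome {chrom}: spacing infeasible for {m} regions")
        blockers = sorted(hot_by_chrom.get(chrom, []), key=lambda r: r.start)
        for i in range(m):
            start = int(round((i + 0.5) * gap - backbone_length / 2))
            start = max(0, min(start, size - backbone_length))
            reg = TargetRegion(chrom, start, start + backbone_length, BACKBONE, gc)
            for b in blockers:  # nudge past any colliding hotspot window
                if reg.overlaps(b):
                    reg = TargetRegion(chrom, b.end + 1, b.end + 1 + backbone_length, BACKBONE, gc)
            regions.append(reg)
    return Panel(regions)


def default_hotspot_spec() -> dict[str, list[tuple[str, int, int]]]:
    """560 hotspot windows tiling six recessive-disease genes.

    Three disorders, six genes: beta-thalassemia (HBB), hereditary hearing
    loss (GJB2, SLC26A4, GJB3) and phenylketonuria (PAH, PTS). Window
    lengths vary (the hotspot windows are deliberately *not* equal length).
    """
    genes = {  # GRCh37 gene loci (approximate gene spans)
        "HBB": ("11", 5246696, 5248301),
        "GJB2": ("13", 20761609, 20767037),
        "SLC26A4": ("7", 107301080, 107358254),
        "GJB3": ("1", 35246000, 35251500),
        "PAH": ("12", 103232104, 103311381),
        "PTS": ("11", 112097088, 112104696),
    }
    per_gene = {"HBB": 90, "GJB2": 95, "SLC26A4": 95, "GJB3": 90, "PAH": 95, "PTS": 95}
    cycle = (70, 100, 130)
    spec: dict[str, list[tuple[str, int, int]]] = {}
    for gene, (chrom, gstart, gend) in genes.items():
        m = per_gene[gene]
        # tile the gene plus flanking sequence when the gene body is too
        # short for m non-overlapping windows
        gend = max(gend, gstart + m * 160)
        step = (gend - gstart) / m
        windows = []
        for i in range(m):
            length = min(cycle[i % len(cycle)], int(step) - 1)
            start = gstart + int(round(i * step))
            windows.append((chrom, start, start + length))
        spec[gene] = windows
    return spec


def default_panel() -> Panel:
    """The bundled paper-scale synthetic design: 8,731 regions."""
    return generate_panel_layout(
        GRCH37_SIZES,
        n_backbone=N_BACKBONE,
        backbone_length=BACKBONE_LENGTH,
        hotspot_spec=default_hotspot_spec(),
        chrom_counts={"X": N_BACKBONE_X, "Y": N_BACKBONE_Y},
    )


# ---------------------------------------------------------------------------
# BED I/O (BED4: chrom, start, end, name; name = "backbone" | "hotspot|GENE")


def write_panel(panel: Panel, path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in panel.regions:
            name = BACKBONE if r.kind == BACKBONE else f"{HOTSPOT}|{r.gene}"
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{name}\n")


def load_panel(path: str | Path) -> Panel:
    """Parse and validate a BED4 panel definition.

    Raises :class:`PanelError` naming the offending line on malformed
    records, and on overlapping backbone regions.
    """
    regions: list[TargetRegion] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise PanelError(f"{path}:{lineno}: expected 4 BED columns, got {len(fields)}")
            chrom, start_s, end_s, name = fields[:4]
            chrom = chrom.removeprefix("chr")
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise PanelError(f"{path}:{lineno}: non-integer coordinate") from exc
            if name == BACKBONE:
                kind, gene = BACKBONE, None
            elif name.startswith(f"{HOTSPOT}|"):
                kind, gene = HOTSPOT, name.split("|", 1)[1]
            else:
                raise PanelError(f"{path}:{lineno}: unrecognized region name {name!r}")
            try:
                regions.append(TargetRegion(chrom, start, end, kind, gene=gene))
            except PanelError as exc:
                raise PanelError(f"{path}:{lineno}: {exc}") from exc
    panel = Panel(regions)
    prev = None
    for r in panel.backbone:
        if prev is not None and r.overlaps(prev):
            raise PanelError(
                f"overlapping backbone regions {prev.chrom}:{prev.start}-{prev.end} "
                f"and {r.chrom}:{r.start}-{r.end}"
            )
        prev = r
    return panel
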