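"""Pipeline orchestration: panel -> simulate -> baseline -> calls from a
single YAML-style configuration mapping, with a JSON run manifest."""

from __future__ import annotations

import hashlib
import json
import sys
from pathlib import Path

import numpy as np
import yaml

from . import __version__, aneuploidy, cnv, ptg
from .baseline import build_baseline, load_baseline, save_baseline
from .demo_cohort import PATHOGENIC_LOCI
from .genome import GRCH37_SIZES
from .panel import (
    Panel,
    default_hotspot_spec,
    generate_panel_layout,
    load_panel,
    validate_panel,
    write_panel,
)
from .simulate import (
    SampleTruth,
    draw_mixture_genotypes,
    simulate_pileups,
    simulate_reference_cohort,
    simulate_region_counts,
    write_counts_tsv,
)


class ConfigError(ValueError):
    pass


DEFAULT_THRESHOLDS = {
    "z_cut": 3.0,
    "x_cut": 3.0,
    "male_frac": 0.25,
    "max_scale": 5,
    "fdr_q": 0.001,
    "min_regions": 20,
    "min_span": 10_000_000,
    "mean_band": 0.7,
    "median_band": 2.0,
    "error_rate": 0.005,
    "em_tolerance": 0.001,
}


def make_demo_config() -> dict:
    """A small, fast demonstration configuration (reduced panel/cohort)."""
    return {
        "seed": 7,
        "panel": {"n_backbone": 2000, "backbone_length": 100,
                  "chrom_counts": {"X": 110, "Y": 22}},
        "background": {"n_samples": 24, "total_reads": 4_000_000, "dispersion": 0.002},
        "thresholds": dict(DEFAULT_THRESHOLDS),
        "ptg": {"mean_depth": 200, "n_snps": 200, "snp_baf": 0.3},
        "samples": [
            {"id": "demo-T21", "fetal_fraction": 0.19, "fetal_sex": "XY",
             "aneuploidies": [["21", "trisomy"]]},
            {"id": "demo-dup9", "fetal_fraction": 0.18, "fetal_sex": "XX",
             "cnvs": [["9", 0, 40_000_000, 1]]},
            {"id": "demo-hbb", "fetal_fraction": 0.21, "fetal_sex": "XY",
             "variants": [["HBB:c.126_129del", "AB", "AB"]]},
        ],
    }


def build_panel_from_config(cfg: dict) -> Panel:
    if "path" in cfg:
        return load_panel(cfg["path"])
    return generate_panel_layout(
        chrom_sizes=cfg.get("chrom_sizes", GRCH37_SIZES),
        n_backbone=int(cfg.get("n_backbone", 8171)),
        backbone_length=int(cfg.get("backbone_length", 100)),
        hotspot_spec=cfg.get("hotspot_spec", default_hotspot_spec()),
        chrom_counts=cfg.get("chrom_counts", {"X": 452, "Y": 88}),
    )


def _truth_from_sample_cfg(s: dict) -> SampleTruth:
    maternal, fetal = {}, {}
    for locus, m, f in s.get("variants", []):
        maternal[locus], fetal[locus] = m, f
    return SampleTruth(
        fetal_fraction=float(s["fetal_fraction"]),
        fetal_sex=s.get("fetal_sex", "XX"),
        aneuploidies=[tuple(a) for a in s.get("aneuploidies", [])],
        cnvs=[tuple(c) for c in s.get("cnvs", [])],
        maternal_genotypes=maternal,
        fetal_genotypes=fetal,
    )


def _reconcile_aneuploidy_and_cnvs(call, cnv_calls, panel, whole_chrom_frac=0.8):
    """Arbitrate between chromosome-level and segment-level calls.

    A dosage shift confined to part of a chromosome can push the whole
    chromosome's Z past the aneuploidy cutoff. If a called CNV spans
    less than ``whole_chrom_frac`` of its chromosome, the event is
    sub-chromosomal: the aneuploidy call on that chromosome is dropped
    and the CNV kept. A CNV spanning essentially the whole chromosome of
    a called aneuploidy is the same event seen twice: the aneuploidy
    call is kept and the CNV suppressed.
    """
    kept_aneu = []
    drop_cnvs = []
    for chrom, state in call.calls:
        explained = False
        for c in cnv_calls:
            if c.chrom != chrom:
                continue
            idx = panel.backbone_index(chrom)
            span = int(panel.backbone_ends[idx][-1] - panel.backbone_starts[idx][0])
            if c.size >= whole_chrom_frac * span:
                drop_cnvs.append(c)
            else:
                explained = True
        if not explained:
            kept_aneu.append((chrom, state))
    call.calls = kept_aneu
    return call, [c for c in cnv_calls if c not in drop_cnvs]


def config_hash(config: dict) -> str:
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def run_pipeline(config: dict, outdir: str | Path, log=sys.stderr) -> dict:
    """Run the full pipeline described by ``config`` into ``outdir``.

    Writes the panel BED, background counts TSV, baseline bundle,
    per-sample aneuploidy/CNV/variant reports, and a JSON run manifest.
    Fully deterministic for a fixed configuration (the master seed
    drives every simulation step).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    thresholds = {**DEFAULT_THRESHOLDS, **config.get("thresholds", {})}
    rng = np.random.default_rng(seed)
    outputs: list[str] = []

    def emit(path: Path) -> Path:
        outputs.append(str(path.relative_to(outdir)))
        return path

    panel = build_panel_from_config(config.get("panel", {}))
    findings = validate_panel(panel)
    if findings:
        raise ConfigError(f"panel validation failed: {findings[:3]}")
    write_panel(panel, emit(outdir / "panel.bed"))
    print(f"[pipeline] panel: {panel.n_backbone} backbone + {panel.n_hotspot} hotspot regions",
          file=log)

    bg = config.get("background", {})
    if "baseline_path" in bg:
        baseline = load_baseline(bg["baseline_path"])
        baseline.check_panel(panel)
    else:
        cohort = simulate_reference_cohort(
            panel,
            n_samples=int(bg.get("n_samples", 68)),
            total_reads=int(bg.get("total_reads", 2_000_000)),
            dispersion=float(bg.get("dispersion", 0.002)),
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        write_counts_tsv(cohort, panel, emit(outdir / "background_counts.tsv"))
        baseline = build_baseline(
            cohort, panel,
            median_interval=bg.get("median_interval", "segment"),
            haarseg_kwargs={"max_scale": thresholds["max_scale"],
                            "fdr_q": thresholds["fdr_q"]},
        )
    save_baseline(baseline, emit(outdir / "baseline.json"))
    print(f"[pipeline] baseline built from {baseline.n_samples} samples", file=log)

    ptg_cfg = config.get("ptg", {})
    summaries = []
    for s in config.get("samples", []):
        sid = s["id"]
        truth = _truth_from_sample_cfg(s)
        sample = simulate_region_counts(
            panel, truth,
            total_reads=int(s.get("total_reads", bg.get("total_reads", 2_000_000))),
            dispersion=float(bg.get("dispersion", 0.002)),
            seed=int(rng.integers(0, 2**31 - 1)),
            sample_id=sid,
        )
        call = aneuploidy.call_sample(
            sample, baseline, panel,
            z_cut=thresholds["z_cut"], x_cut=thresholds["x_cut"],
            male_frac=thresholds["male_frac"],
        )
        aneuploidy.report_frame(call).to_csv(
            emit(outdir / f"{sid}.aneuploidy.tsv"), sep="\t", index=False)

        cnv_calls = cnv.call_sample_cnvs(
            sample, baseline, panel,
            max_scale=thresholds["max_scale"], fdr_q=thresholds["fdr_q"],
            sex_karyotype=call.sex_karyotype,
            min_regions=thresholds["min_regions"], min_span=thresholds["min_span"],
            mean_band=thresholds["mean_band"], median_band=thresholds["median_band"],
        )
        call, cnv_calls = _reconcile_aneuploidy_and_cnvs(call, cnv_calls, panel)
        with open(emit(outdir / f"{sid}.cnv.tsv"), "w") as fh:
            fh.write("chrom\tstart\tend\tsize\tdirection\tmedian_z\tn_regions\tiscn\n")
            for c in cnv_calls:
                fh.write(f"{c.chrom}\t{c.start}\t{c.end}\t{c.size}\t{c.direction}\t"
                         f"{c.median_z:.2f}\t{c.n_regions}\t{c.iscn()}\n")
        with open(emit(outdir / f"{sid}.cnv.bed"), "w") as fh:
            for c in cnv_calls:
                fh.write(f"{c.chrom}\t{c.start}\t{c.end}\t{c.direction}\n")

        variant_report = []
        if truth.fetal_genotypes:
            n_snps = int(ptg_cfg.get("n_snps", 200))
            snp_baf = float(ptg_cfg.get("snp_baf", 0.3))
            bafs = {f"SNP{i:04d}": snp_baf for i in range(n_snps)}
            m_snp, f_snp = draw_mixture_genotypes(bafs, int(rng.integers(0, 2**31 - 1)))
            truth_full = SampleTruth(
                truth.fetal_fraction, truth.fetal_sex,
                maternal_genotypes={**m_snp, **truth.maternal_genotypes},
                fetal_genotypes={**f_snp, **truth.fetal_genotypes},
            )
            pileups = simulate_pileups(
                truth_full, float(ptg_cfg.get("mean_depth", 200)),
                thresholds["error_rate"], int(rng.integers(0, 2**31 - 1)))
            priors = np.stack([
                ptg.hwe_combo_priors(
                    PATHOGENIC_LOCI[p.locus_id].baf if p.locus_id in PATHOGENIC_LOCI
                    else snp_baf)
                for p in pileups])
            est = ptg.estimate_fetal_fraction_em(
                pileups, priors, tolerance=thresholds["em_tolerance"],
                error_rate=thresholds["error_rate"])
            geno = ptg.map_genotypes(pileups, est.f, priors,
                                     error_rate=thresholds["error_rate"])
            hot = [g for g in geno if g.locus_id in PATHOGENIC_LOCI]
            variants = ptg.call_variants(hot, PATHOGENIC_LOCI)
            status = ptg.disease_status(variants, {
                k: v for k, v in PATHOGENIC_LOCI.items()
                if k in {g.locus_id for g in hot}})
            with open(emit(outdir / f"{sid}.variants.tsv"), "w") as fh:
                fh.write("locus_id\tgene\tpgc\tstatus\tfetal_fraction_em\n")
                for v in variants:
                    fh.write(f"{v.locus_id}\t{v.gene}\t{v.pgc}\t{v.status}\t{est.f:.4f}\n")
            ptg.write_variants_vcf(variants, PATHOGENIC_LOCI,
                                   emit(outdir / f"{sid}.variants.vcf"))
            variant_report = [
                {"locus": v.locus_id, "pgc": v.pgc, "status": v.status} for v in variants]
            summaries.append({"sample": sid, "result": aneuploidy.clinical_result(call),
                              "ff_em": round(est.f, 4), "variants": variant_report,
                              "disease_status": status})
        else:
            summaries.append({"sample": sid, "result": aneuploidy.clinical_result(call),
                              "cnvs": [f"{c.chrom}:{c.start}-{c.end}({c.direction})"
                                       for c in cnv_calls]})
        print(f"[pipeline] {sid}: {summaries[-1]}", file=log)

    manifest = {
        "package_version": __version__,
        "seed": seed,
        "config_hash": config_hash(config),
        "thresholds": thresholds,
        "panel_checksum": panel.checksum(),
        "outputs": outputs,
        "samples": summaries,
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ConfigError(f"{path}: configuration must be a mapping")
    return cfg
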