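# nipt-trio

Integrated noninvasive prenatal testing (NIPT) from a single targeted
cfDNA capture run: chromosome aneuploidy, sub-chromosomal copy-number
variants (CNVs), and single-gene disorders, plus the cohort simulator
needed to exercise the whole pipeline on synthetic data.

Conventional NIPT screens trisomies from shallow whole-genome read
counts, while fetal single-gene genotyping needs hundreds-fold depth at
specific loci — so patients end up taking multiple tests. This package
implements the count- and pileup-level analysis of a 3-in-1 targeted
design: a panel of 8,171 equal-length backbone regions scattered across
the genome (for counting) plus 560 mutation-hotspot windows in six
recessive-disease genes — HBB (β-thalassemia), GJB2/SLC26A4/GJB3
(hearing loss), PAH/PTS (phenylketonuria) — captured deeply enough for
allele-level genotyping. It is aimed at bioinformaticians prototyping or
benchmarking cfDNA screening methods; it starts from region read counts
and allele pileups, not raw reads.

## Methods at a glance

- **Aneuploidy** — per chromosome, the mean backbone-region count is
  normalized against the median of the other autosomes and standardized
  against a 68-sample euploid background:
  `z_c = (x_c − μ_c) / σ_c`, trisomy at `z ≥ 3`. Fetal sex and sex
  karyotype (XX, XY, 45,X, 47,XXY) come from the 88 chrY regions'
  median/mean depth and the chrX z against a fetal-sex-stratified
  baseline.
- **CNV** — region-level z-values segmented with a HaarSeg-style Haar
  wavelet transform (dyadic scales, MAD noise estimate, per-scale
  Benjamini–Hochberg FDR on breakpoint candidates); a segment is called
  only if it spans ≥ 20 regions and ≥ 10 Mb, |mean z| > 0.7,
  |median z| > 2, and its median z lies outside the 95% interval of
  background segment medians.
- **Single-gene disorders** — the plasma genotype at a biallelic locus
  is a "pseudo-tetraploid" (maternal + fetal letter pairs, 7 admissible
  combinations). Alt counts are binomial with expected fraction
  `p = (1−f)·b_m/2 + f·b_f/2`; fetal fraction `f` is estimated by EM to
  a 0.001 tolerance, genotypes are per-locus MAP calls under
  Hardy-Weinberg priors, and autosomal-recessive status follows from
  the called fetal alleles.

See `docs/methods.md` for the full model description, parameter
defaults, and known limitations.

## Worked example

Run the bundled demonstration pipeline (a reduced synthetic panel, a
24-sample euploid background, and three case samples — a trisomy-21
male, a 40 Mb chr9 duplication, and an HBB carrier fetus):

```sh
nipt-trio run all --out demo_out --seed 7
```

which logs:

```
[pipeline] panel: 2000 backbone + 560 hotspot regions
[pipeline] baseline built from 24 samples
[pipeline] demo-T21: {'sample': 'demo-T21', 'result': 'T21', 'cnvs': []}
[pipeline] demo-dup9: {'sample': 'demo-dup9', 'result': 'euploid XX',
                       'cnvs': ['9:775848-39570847(dup)']}
[pipeline] demo-hbb: {'sample': 'demo-hbb', 'result': 'euploid XY',
                      'ff_em': 0.2032,
                      'variants': [{'locus': 'HBB:c.126_129del',
                                    'pgc': 'ABab', 'status': 'heterozygous'}],
                      'disease_status': {'HBB': 'carrier'}}
```

Reading the output: `result: T21` means chromosome 21's z-value exceeded
3 against the euploid background (the z table is in
`demo-T21.aneuploidy.tsv`); the CNV line reports a called duplication
covering chr9:0.78–39.6 Mb (simulated truth 0–40 Mb; boundaries resolve
to the region grid, here ~1.4 Mb spacing); and for the HBB sample the
EM fetal-fraction estimate was 0.203 (truth 0.21), the locus posterior
picked the combination `ABab` — carrier mother, heterozygous fetus — so
the fetus is reported as an HBB carrier. `demo_out/` contains
the panel BED, the baseline bundle, per-sample TSV/BED/VCF reports and a
JSON manifest with the seed and configuration hash; rerunning with the
same config reproduces them byte-for-byte.

The same stages are available piecewise (`nipt-trio panel generate`,
`simulate cohort`, `baseline build`, `call aneuploidy|cnv|snv`), and the
library API mirrors them (`nipt_trio.panel`, `.simulate`, `.baseline`,
`.aneuploidy`, `.cnv`, `.ptg`).

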