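# Methods

`nipt-trio` implements an integrated ("3-in-1") noninvasive prenatal
screen from targeted cfDNA capture data. A single sequencing run of
maternal plasma is analysed three ways: chromosome-level Z-values for
aneuploidy, region-level Z-values with Haar-wavelet segmentation for
sub-chromosomal CNVs, and a pseudo-tetraploid binomial mixture model for
single-gene disorder genotyping. A cohort simulator generates the
synthetic data that every end-to-end figure in this package is computed
on.

## Target panel

The capture design holds 8,731 regions: 8,171 equal-length (100 bp)
*backbone* windows scattered over all 24 chromosomes in proportion to
GRCh37 chromosome length (7,631 autosomal, 452 on X, 88 on Y), plus 560
variable-length *hotspot* windows tiling pathogenic mutation hotspots in
six recessive-disease genes (HBB for beta-thalassemia; GJB2, SLC26A4,
GJB3 for hereditary hearing loss; PAH, PTS for phenylketonuria). The
true clinical design's coordinates are proprietary, so the generator
produces a statistically equivalent layout: counts, within-chromosome
even spacing (~370-380 kb between backbone windows), and backbone length
uniformity are preserved; real probe coordinates are not. Backbone
apportionment uses the largest-remainder method, with the X/Y counts
pinned to the published 452/88 split. GC content is modelled as constant
across regions — the design principle of the panel is GC homogeneity —
so no GC-correction stage exists downstream, and hotspot windows are
excluded from all count statistics. Coordinates are 0-based half-open
everywhere (BED convention); 1-based only in human-readable output.

## Count model and simulator

Let `f` be the fetal fraction. A backbone region carried at `m` maternal
and `c` fetal copies has expected dose `(1-f)·m/2 + f·c/2` relative to a
diploid autosomal region: a fetal trisomy scales its chromosome by
`1 + f/2`, a monosomy by `1 - f/2`, a fetal duplication/deletion shifts
only the overlapped regions, chrY carries `f/2` of an autosomal dose for
a male fetus and zero for a female, 45,X gives X dose `1 - f/2`, and
47,XXY keeps the female-level X dose while adding the male Y dose. Region
counts are multinomial over the backbone with probabilities proportional
to dose; a scalar `dispersion` switches to Dirichlet-multinomial sampling
with concentration `s = (total_reads - 1)/dispersion`, inflating the
per-region count variance by a factor of about `1 + dispersion` relative
to multinomial. The default `dispersion = 0.002` keeps euploid
chromosome-level Z-values standard-normal against a cohort-built
baseline while adding a nonzero biological-noise term.

Simulated study conditions (the defaults of `nipt_trio.validation`):

- background: 68 euploid pregnancies, fetal fraction ~ U(0.16, 0.22)
  (the clinical range of the validation cohort), fetal sex 1:1;
- aneuploidy arm: 2,000,000 unique reads per sample (~245 reads per
  region);
- CNV arm: 15,000,000 reads per sample (~1,800 per region). The
  duplication carriers were sequenced at the panel's highest average
  target depths, and region-level resolution requires it: with ~245
  reads per region, counting noise alone (relative SD 6.4%) caps the
  region Z of a fetal duplication at fetal fraction 0.17 near 1.3,
  below the |median Z| > 2 calling criterion. At ~1,800 reads per
  region the affected-region Z lands at 3.3-4.0, matching the 2.6-5.3
  range observed clinically;
- hotspot pileups: depth ~ Poisson(per-sample mean, clinically 130-305x,
  default 200), alt reads ~ Binomial(depth, p) with p the
  pseudo-tetraploid expected alt fraction clamped to the sequencing
  error floor (default 0.005).

What the simulator does *not* emulate: GC and mappability bias (removed
by design in the panel), duplicate reads, maternal CNVs, mosaicism,
capture coverage gaps (the clinical panel under-covers some segments,
which shortened two reported CNV calls; a gap-free synthetic panel
recovers full event lengths), and correlated chromosome-scale noise
(GC waves, batch effects). The last point matters for interpreting the
twins: real data cannot simultaneously show chromosome Z ≈ 4 and region
Z ≈ 3 for the same dosage shift unless region noise is correlated within
chromosomes; the simulator's independent-region noise makes
chromosome-level detection easier than in practice (simulated trisomy Z
≈ 14-22 at clinical fractions), so a passing aneuploidy twin
demonstrates pipeline correctness, not clinical power.

## Aneuploidy calling

Per chromosome the statistic is the mean backbone-region count divided
by the median of the other autosomes' mean region counts. The median
denominator removes library size while staying robust to dosage changes
elsewhere in the genome; a plain "standardize everything to 1M reads"
denominator lets a trisomy depress every other chromosome's statistic
(by `f/2 × chromosome share`), which at the simulator's noise level
produced compensatory false monosomy calls. The Z-value standardizes the
statistic against the 68-sample background (mean/SD, `n-1` denominator;
zero SDs floored to the smallest positive SD to avoid infinite Z in
degenerate noiseless cohorts). Trisomy is called at Z ≥ 3, monosomy at
Z ≤ -3 — the conventional NIPT cutoff; the clinical positives all lie at
|Z| ≥ 3.6.

Fetal sex: a sample is Y-positive when both the median and the mean of
the 88 chrY region depths (whole-panel 1M-read scaling) exceed 25% of
the male Y signal observed in the background cohort's XY-fetus samples.
Sex karyotype refinement uses the chrX Z-value against the fetal-sex
matched background stratum (the X baseline is stratified by background
fetal sex, classified internally from chrY depth, because a male fetus
depresses X dose by f/2): Y-positive with X back at the two-copy level
(Z ≥ 3) → 47,XXY; Y-negative with X below the female level (Z ≤ -3) →
45,X; contradictory combinations are flagged `other` for review rather
than forced into a karyotype. The per-sample clinical result is the
screened-trisomy set (13, 18, 21) plus the sex karyotype; the full
22-autosome Z table is always attached for review.

## CNV calling

Region Z-values use per-region baseline mean/SD (autosomal 1M-read scope
for autosomes, whole-panel scope for X/Y). Segmentation follows the
HaarSeg approach, re-implemented from its published description:
unit-norm undecimated Haar wavelet coefficients at dyadic half-widths
1..2^(max_scale-1) (default max_scale 5); local maxima of |W| as
breakpoint candidates; noise SD estimated robustly as 1.4826 × MAD of
the finest-scale coefficients; per-scale Benjamini-Hochberg FDR
selection of candidates at q = 0.001; cross-scale unification with finer
scales taking precedence (a candidate is dropped when an accepted
breakpoint lies within its half-width), which keeps boundary
localization at single-region resolution; piecewise-constant
reconstruction. When the noise estimate is exactly zero (noiseless
profiles) any non-zero contrast is a breakpoint, so ideal steps are
recovered exactly.

A segment is called a CNV only if all four criteria hold: (1) ≥ 20
consecutive regions AND ≥ 10 Mb genomic span — the conjunctive reading
of the resolution rule, which reproduces the clinical method's inability
to call < 2 Mb events; (2) |mean Z| > 0.7; (3) |median Z| > 2; (4) the
median Z falls outside the 95% interval of background segment medians,
obtained by applying the same segmentation to every background sample
(a simpler per-sample median variant is available by configuration).
Direction is dup for positive median Z, del for negative; the reported
size is the genomic span of the covered regions. Sex-chromosome segments
are suppressed when the sex karyotype is already abnormal, so a
whole-chromosome aneuploidy is not reported twice.

## Pseudo-tetraploid genotyping

At a biallelic locus the plasma genotype is a four-letter
pseudo-tetraploid (maternal pair + fetal pair over {A, B}); Mendelian
transmission from the mother leaves 7 of 9 combinations admissible
(AAAA, AAAB, ABAA, ABAB, ABBB, BBAB, BBBB), of which the 4 whose
expected alt fraction `p = (1-f)·b_m/2 + f·b_f/2` depends on `f` (AAAB,
ABAA, ABBB, BBAB) inform the fetal-fraction estimate. Alt counts are
binomial at `clamp(p, e, 1-e)` with error floor `e = 0.005` — the count
likelihood is this package's concretization; the clinical description
specifies the mixture but not the count distribution.

Fetal fraction is estimated by EM: the E-step computes per-locus
posteriors over the 7 combinations at the current `f`; the M-step
maximizes the expected complete-data log-likelihood over
`f ∈ (0.001, 0.499)` by bounded 1-D search; iteration stops when the
estimate moves by less than 0.001 (the published convergence rule;
`f_init = 0.10`, `max_iter = 100` are this package's defaults). The
observed-data log-likelihood is non-decreasing by the EM property and is
asserted in tests. If less than half a locus of posterior mass falls on
the informative combinations the estimate is flagged unconverged rather
than returned silently.

Genotypes are then the MAP combinations at the converged fraction under
a per-locus prior: Hardy-Weinberg maternal genotype at the locus
population B-allele frequency (default 0.01 for pathogenic hotspots, 0.3
for the polymorphic fraction-informative SNPs) combined with Mendelian
transmission and a population-frequency paternal allele; a uniform prior
is available. Ties break to the canonical combination order. Disease
status is autosomal-recessive: per gene, two called pathogenic alleles
(homozygous or compound heterozygous) → affected, one → carrier, none →
non-carrier; fetal genotype AA at a monitored locus reports "ND".

Accuracy structure: homozygous pileups are essentially always correct;
the balanced heterozygote ABAB is capped near 85% at depth 200 and
f = 0.20 because its 0.45/0.55 decision boundaries against ABAA/ABBB sit
only ~1.4 binomial SDs away. This ABAB↔ABAA/ABBB confusion is exactly
the clinically observed miss pattern (heterozygous fetal calls read as
homozygous-reference at low fractions).

## Validation twins and problem sizes

`nipt_trio.validation` re-creates the clinical evaluation in simulation:
7 aneuploid samples (T13, 2×T18, 2×T21, 45,X, 47,XXY) at their reported
fetal fractions against a fresh 68-sample background at 2M reads; 3
duplication carriers (21, 23.5, 20 Mb — the 23.5 Mb event simulated at
its called coordinates chr12:8.0-31.5 Mb) at 15M reads, scored as
detected only when both boundaries land within one inter-region spacing
of truth; and 22 single-gene samples (the 12 variant carriers with their
reported genotype configurations, fractions and depths, plus 10
variant-free samples — 5 with a carrier mother as hard negatives). Each
single-gene sample carries its pathogenic loci plus 300 polymorphic
SNP loci (B-allele frequency 0.3) for fetal-fraction estimation. These
sizes keep the whole acceptance run under a minute on one CPU.

## Known limitations

- The euploid false-positive rate of the 22-autosome screen at |Z| ≥ 3
  is ~8-11% per sample by construction: with a 68-sample baseline the
  Z-values have t-like tails (per-chromosome two-sided exceedance
  ~0.004), and 1 - (1 - 0.004)^22 ≈ 0.08 even before baseline-specific
  variance fluctuation. A 5% familywise bound is unattainable at this
  cutoff with estimated baselines; clinically one screens the target
  chromosomes (13/18/21, X, Y), which is what the per-sample clinical
  result reports.
- The segmentation over-segments extremely high-SNR events (region
  Z ≫ 5) because plug-in per-region SDs make the in-segment Z spread
  proportional to the Z level; at clinically realistic signal (Z 3-5)
  this does not occur.
- Single-gene specificity is limited by the same ABAB/ABAA ambiguity as
  sensitivity: a carrier-mother locus with a reference fetus is the most
  common false positive.
- Variant identities are passed through as locus labels; no HGVS
  validation, indel realignment or pathogenicity assessment is done.
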