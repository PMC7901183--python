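# Methods

## Problem setting

A maternal plasma cfDNA sample can mix more than the usual two genomes.
`cfmix` models the three-source case: donor-derived hematopoietic DNA after
a bone-marrow transplant from a male first-degree relative (component A,
46,XY), residual maternal cfDNA (B, 46,XX), and placental DNA from a
donor-egg pregnancy (C, here 46,XY), with the fetus genetically unrelated
to the gestational mother. The package provides (i) dosage arithmetic to
quantify the components, (ii) maximum-likelihood joint genotyping of the
mixture, (iii) a relatedness statistic over a SNP panel, and (iv) a
synthetic-data stage that stands in for the unavailable patient data.

## Panel model

The capture panel has 739 regions: 679 autosomal targets each carrying one
common biallelic SNP, concentrated on chr13/18/21 (222/221/194) with 42
spread round-robin over the other autosomes, plus 30 regions each on ZFX
and ZFY used purely for sex-chromosome dosage. Region lengths are
Uniform(60, 140) bp (mean 100); the SNP sits within the last 30 bp of each
region. Population alt-allele frequencies default to Uniform(0.2, 0.5):
mixture-informative panels select common variants, and the exact spectrum
is configurable (`PanelSpec.af_range`). Coordinates are synthetic, 0-based
half-open; probe thermodynamics, repeat content and real genome coordinates
are not modeled — no analysis stage reads sequence content.

## Synthetic data

Founder genotypes are Hardy–Weinberg draws Binomial(2, pop_af) per locus;
children arise by independent Mendelian transmission. The bone-marrow donor
is the mother's full sibling by default (IBD 0/1/2 w.p. 1/4, 1/2, 1/4);
a `parent` mode is provided since a first-degree relative could equally be
a parent. Read counts per locus are n ~ Poisson(depth) (a fixed-n mode
exists for exact tests) with alt ~ Binomial(n, p), p = q(1−ε) + (1−q)ε,
q = Σ_k w_k g_k/2. The per-read substitution error defaults to ε = 0.005,
typical of hybrid-capture sequencing. ZFX/ZFY region depths are
Poisson(depth·CN/2), CN mixed across components by weight. Defaults
throughout encode the study conditions: weights (0.7264, 0.18, 0.0936),
2500× target depth, a 46,XY fetus.

What the simulation does **not** emulate: GC/mappability bias, fragment-
length differences between placental and other cfDNA, placental mosaicism
(the fetal component is the constitutional genotype), index hopping,
alignment artifacts, and a realistic site-frequency spectrum. Passing tests
therefore demonstrate the statistical machinery under the stated model, not
robustness to every real-data failure mode.

## Dosage and fractions

With male-DNA fraction m, CN_X = 2 − m and CN_Y = m; depths are calibrated
by the mean ZFX depth of a known 46,XX sample (the pipeline uses the oral-
mucosa sample), for which CN_X = 2. This reproduces both printed forms of
the case arithmetic simultaneously — shares 0.59:0.41 and m = 82% — and is
chosen over autosomal normalization to keep the dosage model self-contained
on the ZF regions. m is clipped to [0,1] with a logged warning rather than
an error, since Poisson noise puts pure-male samples slightly above 1. Sex
thresholds t_low = 0.05, t_high = 0.95 sit far outside binomial noise at
2500× and are configurable. The placental fraction f is an input (the
fragment-profile regressions that estimate it are trained models external
to this package); `estimate_fractions_ls` is the self-contained
alternative, solving min over the simplex of Σ_l (af_l − Σ_k w_k g_lk/2)²
by non-negative least squares followed by normalization. A rank-deficient
candidate matrix (indistinguishable components) is flagged degenerate with
a warning rather than an error.

## Mixture genotyping

`deconvolve` enumerates all 3^k genotype configurations (k ≤ 3; k = 1 is
plain diploid calling, exposed as `call_diploid`), scoring each with the
binomial read-count likelihood and independent Hardy–Weinberg priors per
component. Components are deliberately modeled as unrelated population
draws even when they are not: relatedness is what the downstream mrs
analysis measures, and encoding it in the prior would circularize that
inference. A flat-prior mode exists for sensitivity checks. Posterior
normalization uses log-sum-exp; MAP ties (possible at symmetric q) break
toward the higher prior, then the lexicographically smallest configuration,
and are logged. Zero-coverage loci are emitted as missing. Genotypes are
only emitted when the MAP posterior reaches 0.9 (configurable): mrs
denominators must not be polluted by coin-flip calls.

The pipeline's major/minor split of the plasma sample defaults to the
three-component model (`split_mode="hexaploid"`): major is the largest-
fraction component's genotype row, minor the smallest (the placental
genome). The two-component alternatives are kept as switches —
`"placental"` splits at (1 − f, f), pooling donor + mother into one
pseudo-diploid component, and `"male"` splits at (m, 1 − m). The pooled
two-component model is exact only where the pooled genomes agree; on a
highly polymorphic panel with a sibling (not identical) donor it is
misspecified at donor≠mother loci, which degrades the minor (fetal) calls —
the reason the three-component split is the default here. Note that
conditioning on confidently deconvolved loci biases the kept-locus set
toward loci where the two minor genomes agree, which inflates the apparent
similarity of the minor row to the maternal genome; the relatedness table
should be read with that in mind (it is the same ambiguity that motivates
the `ambiguous` class).

## Relatedness

mrs(a, b) = (#loci with identical genotypes among common non-reference
loci) / (#common non-reference loci), where "common non-reference" means
called in both samples with **at least one** genotype > 0. The alternative
reading (both non-reference) is available as `mode="both_nonref"` for
sensitivity analysis; the at-least-one convention is the default because it
keeps disagreements where only one sample carries the alt allele in the
denominator while excluding the uninformative hom-ref/hom-ref background.
Classification thresholds are not fixed a priori: `calibrate_thresholds`
simulates duplicate pairs (with 1% per-locus genotyping error), first-
degree pairs (siblings **and** parent–child, pooled — both are first-degree
but parent–child sits lower under this allele-frequency spectrum) and
unrelated pairs, and places each threshold at the midpoint between adjacent
class means, warning when the classes overlap beyond a confusion tolerance.
Class boundaries are closed from below; a configurable margin maps
near-threshold values to `ambiguous`.

The IBS distance is 1 − mean((2 − |g_a − g_b|)/2) over shared called loci;
classical (Torgerson) MDS double-centers the squared distances and
eigendecomposes, truncating negative eigenvalues (IBS distances are not
exactly Euclidean) with a warning. Strict IBD kinship coefficients and
pedigree reconstruction are out of scope — on a sparse 679-SNP panel they
are uninformative, which is precisely why the mrs ranking is used instead.

## Pipeline and reproducibility

`run_case_study` simulates six samples — mother WBC (donor genotype;
post-transplant blood is donor-derived, with a residual-host knob
defaulting to 0), mother plasma (the three-way mixture), mother oral mucosa
(maternal genotype), father WBC and plasma (pure father), fetal amniocytes —
then runs dosage, fractions, deconvolution, relatedness, MDS and MAF
spectra, writing TSV/JSON/Markdown artifacts stamped with a SHA-256 config
hash. All randomness derives from one integer seed through per-stage
substreams; a run is byte-identical given (config, seed). Calibration uses
100 simulated pedigrees by default; the acceptance checks use 20 case-depth
mixtures for fraction recovery and 120 pedigrees for class separation —
sizes at which the Monte-Carlo error is well below the asserted margins.

## Known limitations

* The fetal component is constitutional; confined placental mosaicism would
  decouple plasma dosage from amniocyte genotypes.
* Fraction estimation by least squares assumes the candidate genotype rows
  are the true mixture members; a missing contributor biases all weights.
* mrs levels depend strongly on the panel allele-frequency spectrum;
  absolute values are not transferable between panels, only the
  MZD > 1st > NR ordering is.
* The deconvolution treats loci as independent (no linkage, no haplotype
  phasing) and requires mixture weights to be supplied, not jointly
  estimated with the genotypes.
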