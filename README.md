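# cfmix

Dissecting a cell-free DNA (cfDNA) sample that mixes **three genomes**. The
motivating scenario is a pregnant patient who, years before a donor-egg IVF
pregnancy, received a bone-marrow transplant from a male first-degree
relative. Her plasma cfDNA then carries: **A** — donor-derived hematopoietic
DNA (46,XY), **B** — her own residual cfDNA (46,XX), and **C** — placental
DNA of the fetus (46,XY), genetically unrelated to her. Standard noninvasive
prenatal testing (NIPT) arithmetic breaks down on such a sample; `cfmix`
implements the analysis framework that resolves it, and a synthetic-data
stage that emulates the study design (pedigree, 739-region SNP capture
panel, ~2500× depth) so the whole pipeline is testable end to end.

## What it computes

**Sex-chromosome dosage.** With male-DNA fraction *m*, a mixed sample has
copy numbers CN_X = 2 − *m*, CN_Y = *m*, hence normalized shares
x_share = (2 − *m*)/2 and *m* = 2·y_share. ZFX/ZFY region depths, calibrated
against a known 46,XX sample, give CN estimates, a sex call
(female/male/mixed) and *m*. Shares of 0.59 : 0.41 correspond to *m* = 82%.
Given the placental fraction *f* (an input, e.g. from a read-distribution
predictor) and fetal sex, the component fractions follow by subtraction:
(w_A, w_B, w_C) = (*m* − *f*, 1 − *m*, *f*) for a male fetus — e.g.
(72.64%, 18%, 9.36%). `estimate_fractions_ls` alternatively regresses
plasma allele fractions on candidate genotypes over the SNP panel
(non-negative least squares on the simplex).

**Mixture genotyping.** At a biallelic SNP the expected alt-read fraction of
a k-genome mixture is q = Σ_k w_k g_k / 2 (g_k ∈ {0,1,2}); with per-read
error ε the alt count is Binomial(n, q(1−ε) + (1−q)ε). `deconvolve`
enumerates all 3^k joint genotype configurations with Hardy–Weinberg priors
and reports the full posterior and MAP call per locus — the two-genome
(pseudo-tetraploid) model of fetal+maternal plasma genotyping and its
three-genome (pseudo-hexaploid) extension. `maf_spectrum` quantifies the
mixture signature: a single genome keeps allele fractions in bands at
0/0.5/1, a mixture does not.

**Relatedness.** The match-ratio statistic of a sample pair,

    mrs = #identical genotypes at shared loci / #common non-reference loci,

separates duplicates (MZD), first-degree relatives (1st) and unrelated
pairs (NR); thresholds are calibrated on simulated pairs. An
identity-by-state distance matrix with classical MDS provides the
two-dimensional embedding view.

## Worked example

```python
from cfmix import RunConfig, run_case_study
rep = run_case_study(RunConfig(), outdir="case_out")
```

prints nothing, but `examples/05_case_study.py` summarizes the report:

```
sex calls (ZFX/ZFY dosage):
  mother_wbc     male    male fraction 1.000
  mother_plasma  mixed   male fraction 0.825
  mother_oral    female  male fraction 0.000
  father_wbc     male    male fraction 1.000
  father_plasma  male    male fraction 1.000
  fetus_af       male    male fraction 0.999

male-DNA fraction: 0.8246
components A/B/C: 0.7310 / 0.1754 / 0.0936

top of the relatedness table (mrs, descending):
  father_wbc-father_plasma                 1.000  MZD
  mother_wbc-mother_plasmamajor            1.000  MZD
  fetus_af-mother_plasmaminor              0.990  MZD
  mother_wbc-mother_oral                   0.456  1st
  mother_oral-mother_plasmaminor           0.406  1st
  father_plasma-mother_plasmaminor         0.405  1st
```

Reading this: the mother's white blood cells genotype as a *male* duplicate
of the plasma **major** component (her blood is donor-derived), her oral
mucosa stays female, and the plasma **minor** component — the placental
genome — pairs with the father at first-degree level, a noninvasive
paternity signal. The dosage arithmetic recovers the mixture: 82% male DNA
splitting into ≈72.6% donor / 18% maternal / 9.36% placental. Each other
capability has a short narrative script under `examples/`.

A thin CLI wraps the same stages:

```sh
cfmix run-case --out case_out
cfmix fractions --sex-depths case_out/sex_depths.tsv --panel-bed case_out/panel.bed \
    --sample mother_plasma --female-ref mother_oral \
    --placental-fraction 0.0936 --fetal-sex XY
```

## Scope

The pipeline starts from per-locus allele-depth tables; read alignment,
deduplication and germline variant calling are upstream of it. Shallow-WGS
aneuploidy Z-scores, the seqFF placental-fraction regression (its output is
an input parameter here), and external kinship tools are out of scope.
`docs/methods.md` documents the models, defaults and limitations.
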