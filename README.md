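# cmsrf

**Cytonuclear male-sterility / fertility-restorer segregation analysis for
inter-population plant crosses.**

## The problem

When two diverged hermaphrodite plant populations are crossed, one direction
of the cross can produce male-sterile (MS) hybrids while the reciprocal stays
fertile. The classic cause is cytoplasmic male sterility (CMS): a maternally
inherited mitochondrial factor abolishes pollen production unless the nucleus
supplies a matching restorer-of-fertility (*Rf*) allele. If one population's
cytoplasm carries CMS and the other population lacks effective restorers,
F2 and backcross progenies segregate hermaphrodites (H) and male-sterile
plants in ratios that betray the underlying genetics.

`cmsrf` is a toolkit for analysing such crossing experiments. It is aimed at
plant evolutionary geneticists who have genotype matrices, pollen-count
phenotypes and a pedigree from an F2 / pseudobackcross design and want to

* predict and fit H:MS segregation ratios under a one-restorer-locus model
  with **transmission ratio distortion** (TRD) and **partial restoration**,
* select among classical segregation ratios (3:1, 13:3, 5:3, 1:1, 3:13, ...)
  by chi-square goodness of fit,
* estimate the distorted transmission probability τ and the restoration
  penetrance *r* from observed tables or genotypes,
* run marker-level statistics: TRD scans with Bonferroni correction,
  sterility calling from pollen counts, double-recombination QC, and a
  nonparametric single-marker association scan with permutation thresholds,
* and exercise the whole pipeline on synthetic data from a built-in pedigree
  forward simulator that emulates the study design.

## The model

Let the restorer locus carry a dominant restorer allele *R* and a nonrestorer
allele *m*. A heterozygous parent transmits *m* with probability τ (TRD;
τ = 0.5 is Mendelian, the study system shows τ ≈ 0.575 at the *Rf*-linked
block), so restorer transmission is T_R = 1 − τ. A plant with CMS cytoplasm
is hermaphrodite if it carries at least one *R*; an *mm* plant escapes
sterility with penetrance *r* (≈ 0.4 in this system), modelled as an
independent Bernoulli draw per individual. Without CMS cytoplasm every plant
is fertile.

For chained crosses the model conditions each maternal generation on its
phenotype. Writing F_r for the frequency of genotypically restored plants
among hermaphrodite mothers, the expected hermaphrodite count of a backcross
progeny of H mothers is

```
H(exp) = [ F_r × (T_R + (1 − T_R) × r_R) + (1 − F_r) × r_N ] × N
```

where r_R and r_N are the restoration penetrances for offspring of restored
and of nonrestored (phenocopy) mothers. `cmsrf` propagates the joint
distribution of (offspring genotype, maternal restoration status) through an
arbitrary `CrossChain`, so F2, BC1, BC2(H/MS) and BC3 expectations all come
from the same calculus.

## Worked example

```python
>>> from cmsrf.model import ModelParams, STANDARD_CHAINS, chain_h_prob
>>> from cmsrf.fit import SegCounts, expected_counts, gof_chi2, classic_ratio_fit
>>> params = ModelParams(tau=0.575, r_r=0.4, r_n=0.4)

>>> # F2 with 694 plants: expected cells under the model
>>> p_h = chain_h_prob(STANDARD_CHAINS["F2"](), params)
>>> exp = expected_counts(p_h, 694)
>>> (exp.h_int, exp.ms_int)
(556, 138)

>>> # chi-square of the observed 550:144 against that expectation
>>> round(gof_chi2(SegCounts("F2", 550, 144), exp).p, 3)
0.547

>>> # which classical ratio fits 550:144 best?
>>> classic_ratio_fit(SegCounts("F2", 550, 144)).best.label
'13:3'
```

The expected 556:138 says: with τ = 0.575 and 40% restoration, about 19.8%
of F2 plants should be male-sterile; the observed 550:144 (20.7% MS) is
statistically indistinguishable from that (p ≈ 0.55), while the naive 13:3
label is the closest textbook ratio.

A full synthetic study (reciprocal F2s of 694 and 1317 plants, four BC1
pseudobackcrosses, BC2/BC3 generations, 96 SNPs in 75 genes on 8
chromosomes, 1.6% missing genotypes) is one call:

```python
>>> from cmsrf.simulate import simulate_study
>>> study = simulate_study(seed=11)
>>> study.dataset.genotypes.shape
(5411, 96)
```

or from the shell:

```bash
cmsrf run --seed 11 --out out/          # simulate + reports + scans
cmsrf expect --tau 0.575 --restoration 0.4
```

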