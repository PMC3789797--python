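# Methods

## The cytonuclear model

A single maternally inherited cytoplasmic factor (CMS) abolishes pollen
production; a single nuclear restorer locus (*Rf*) segregates a dominant
restorer allele *R* and a nonrestorer allele *m*. The model has three free
probabilities:

| parameter | meaning | default | unit |
|---|---|---|---|
| `tau` | probability a heterozygote transmits *m* (TRD; `T_R = 1 − tau`) | 0.5 (study value 0.575) | probability |
| `r_r` | restoration penetrance of an *mm* offspring of an R-carrying mother | 0.4 | probability |
| `r_n` | same, for offspring of a nonrestored (phenocopy) mother | 0.4 | probability |

Assumptions: the restorer is strictly dominant; restoration of an *mm* plant
is an independent Bernoulli event per individual (penetrance), not an allele
property — the data that motivated the model cannot distinguish the two, and
penetrance composes cleanly through generations; TRD acts identically
through male and female gametes (`tau_f` can be set separately, defaulting
to `tau`); CMS is a boolean property of a cytoplasm with no quantitative
strength.

Chained crosses are evaluated by propagating the joint distribution of
(offspring genotype, mother-carried-R). The joint state is needed because
the penetrance applied to an *mm* offspring depends on whether its mother
was genotypically restored (`r_r`) or a fertile phenocopy (`r_n`). For a
backcross progeny of hermaphrodite mothers this propagation reduces
analytically to

    P(H) = F_r (T_R + (1 − T_R) r_R) + (1 − F_r) r_N,

with `F_r` the posterior frequency of R-carriers among hermaphrodite
mothers, and the implementation is tested against an independent
path-enumeration oracle for all chains up to three generations.

Conditioning an explicit first-generation mother distribution on phenotype
uses `r_n` (no maternal state exists for founders); none of the standard
chains exercises that corner.

A multi-locus extension (`multi_locus_h_prob`) expresses textbook ratios
such as 13:3 (dominant plus recessive restorer in an F2); it is a closed
form for independent loci and is deliberately not part of the fitting
surface, because the crossing data that motivate the package reject a
second restorer.

## Expected counts, ratio selection and estimation

Expected H:MS cells are reported both as exact reals (summing to N) and as
half-up rounded integers; on an exact .5/.5 tie the cell with the larger
fractional remainder absorbs the difference so the integers always total N.
Goodness of fit is a Pearson chi-square without continuity correction at
1 d.f. for two-cell tables.

Classical-ratio selection minimises the chi-square over a configurable
candidate set {1:0, 15:1, 13:3, 3:1, 5:3, 9:7, 1:1, 7:9, 3:5, 1:3, 3:13,
1:15, 0:1}; ties break toward fewer ratio parts. Degenerate ratios (1:0,
0:1) have a zero expected cell and are treated as exact-match specials:
admissible only when the opposite observed class is at most a tolerance
(default 0). The tolerance also accepts a fraction of N; reports use 0.06
because segregation tables in this kind of experiment routinely label rows
with a handful of off-class plants (contaminants, misscored flowers) as
1:0, up to ~5% of the row.

`fit_model_params` maximises the product of binomial likelihoods
Binom(n_H; N, P(H | params)) over the requested free parameters
(`tau`, `restoration`) by bounded scalar/L-BFGS-B optimisation from several
starts. Identifiability is checked numerically before fitting: the Jacobian
of the per-table P(H) with respect to the free parameters is evaluated at
several interior points and must have full column rank; an F2-only table
with both `tau` and `restoration` free fails this (the likelihood depends
only on τ²(1 − r)) and raises instead of guessing.

Penetrance from genotypes is the fraction of hermaphrodites among *mm*
plants with CMS cytoplasm with a Clopper–Pearson interval; τ from genotype
counts is the *m*-allele frequency (2n_mm + n_Rm)/2N with a binomial CI on
2N transmitted alleles. Heterogeneity across families/fathers is an R×2
contingency chi-square (df = R − 1) without correction.

## The synthetic study

The simulator emulates the crossing design the analysis targets: reciprocal
F2s (694 and 1317 flowering plants), four BC1 pseudobackcrosses (113, 75,
256, 181), BC2 progenies of hermaphrodite and male-sterile BC1 mothers
(1031 and 249, from a pool of 91 mother plants), BC3 progenies (467 and
242, from 37 BC2 mothers), plus parental and F1 control cohorts. All sizes
are configuration.

* **Map**: 8 chromosomes, 75 gene-level markers spaced 10–20 cM with
  densification at the top of chromosome 2, where the *Rf* locus sits as a
  hidden (non-panel) locus at 3.2 cM; 96 SNPs are assigned 1–2 per gene and
  carry the gene's genotype, so SNP-to-gene combination is exercised
  end-to-end. Distances are Kosambi cM (r = ½ tanh(2d), d in Morgans).
* **TRD**: gametic selection at one driving locus per distorted
  chromosome — the favored allele is transmitted by heterozygotes with
  probability τ, and flanking markers are filled outward by interval-wise
  recombination conditional on the drawn allele, so distortion hitchhikes
  and decays with map distance. The template favors S alleles on
  chromosomes 1, 3, 7, 8 and M alleles on chromosomes 2 (the *Rf* block,
  τ = `params.tau`) and 4, with block values inside the 0.39–0.6 range such
  systems show. The per-block values are representative configuration, not
  a reconstruction of an observed genome-wide profile.
* **Phenotypes**: hermaphrodites draw pollen totals from a negative
  binomial (shape 2.5) whose parameters are solved so the median hits the
  calibration target (parents 75.9/109.6 per 0.075 µl subsample; hybrids
  59.7 with Sp cytoplasm, 70.3 with Ma), truncated at ≥ 10 grains;
  male-sterile plants draw from a geometric-weighted distribution on 0–9
  grains. The truncation makes the 10-grain discontinuity exact, so the
  < 10 sterility-calling rule recovers the simulated class for every
  individual. Viable counts are binomial (0.914 Sp / 0.926 Ma cytoplasm).
  F2-calibrated medians stand in for all hybrid generations; bud-to-bud
  replication is collapsed to one count per plant.
* **Missingness**: 1.6% of SNP cells are set to `NA` uniformly at random;
  outlier individuals with 5–13 injected singleton switches are available
  through configuration (default off) for QC testing.

What the simulator does *not* emulate: crossover interference (interval
switches are independent, so apparent double recombinants arise at the
r_left × r_right rate per gamete rather than being suppressed), shared
greenhouse/block environmental structure, genotyping error beyond missing
data, and any sequence-level detail. Passing tests therefore show that the
analysis recovers its generating model under the design's sample sizes and
noise — not that real data meet those assumptions.

Two simulation paths exist deliberately. `simulate_study` reproduces the
realistic clustered pedigree (BC2/BC3 offspring share a small pool of
mothers), so its conditioned-generation H:MS fractions carry extra
between-mother variance beyond binomial error; tests of those cohorts
allow for it. `simulate_design_fraction` draws an independent mother per
final offspring, making the H fraction an exactly binomial estimator of the
chain probability; the simulator-versus-closed-form equivalence checks use
it at n = 10⁵, where agreement within 3 binomial SE is the criterion.

## Marker statistics

* **TRD scan**: per-marker chi-square of genotype-class counts against the
  design null (1:2:1 for F2, 1:1 for backcross), df 2 (F2), with companion
  allele-level (S vs M at 0.5) and heterozygote-excess tests mirroring the
  three readouts such scans plot. The Bonferroni family is the number of
  markers passing the informativeness filter (≥ 20 calls, ≥ 2 classes);
  monomorphic or sparse markers are flagged and excluded.
* **Double-recombination QC**: counts singleton switches (a marker whose
  genotype differs from two identical non-missing flanks) per individual —
  the unphased signature of a double crossover — and flags individuals at
  ≥ 5 events, the bottom of the 5–13 range such outliers show.
* **Association scan**: tie-corrected Kruskal–Wallis rank statistic per
  marker (invariant under monotone phenotype transforms), cross-checked
  against an independent library implementation in the tests. This is a
  declared marker-level substitute for nonparametric interval mapping;
  positions between markers are not scanned. Genome-wide thresholds come
  from permutation of the phenotype vector (default n = 1000, α = 0.05),
  deterministic per seed. Variance explained is rank-based eta squared,
  H/(n − 1).

## Numerical choices and degenerate inputs

Genotype distributions are renormalised after construction and checked to
sum to 1 within 1e-12. Conditioning on a phenotype of probability zero
raises `ImpossibleConditionError` rather than returning NaNs. Restoration
estimates from over-expected MS counts clamp to [0, 1] with a warning
rather than erroring. The negative-binomial median calibration solves by
bisection to the integer median's plateau (hit within ±1 grain). Degenerate
chi-square inputs (zero expected cells, empty tables, constant phenotypes)
raise with specific messages.

## Problem sizes

The default study (≈ 5,400 plants × 96 SNPs) simulates in ~2 s. The test
suite uses n = 10⁵ per design for the simulator-equivalence checks, 200
replicate scans for the TRD family-wise error calibration, and 400
permutations / 400 replicate null scans for the permutation-threshold
calibration — sizes chosen so Monte-Carlo error is well below the tested
tolerances while the whole suite stays fast.

## Known limitations

Only the dominant-restorer model is implemented (`dominant=False` raises).
The BC2/BC3 conditioning assumes mothers are drawn from the model's
conditioned distribution; real pseudobackcross designs reuse few mothers,
which inflates variance (see above) and can bias small progenies. The
association scan's asymptotic chi-square p-values are approximate for
small genotype classes — the permutation threshold is the intended
inference route. The fitting surface treats each observed table as an
independent binomial, ignoring shared parents between crosses.
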