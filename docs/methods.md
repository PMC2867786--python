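# Methods

## Model and testing procedure

The trait is assumed, after transformation and covariate adjustment, to be
multivariate normal with an exchangeable correlation ρ within sibships and
independence across sibships. All association tests are linear-model tests
on the adjusted residual vector.

**Phenotype preparation.** The raw trait (a positive concentration) is
transformed by a Box-Cox power transform; the default is the λ = 0 member
(natural log), the standard choice for right-skewed lipid measures. The
Box-Cox profile likelihood (`boxcox_profile`, normal errors with the
Jacobian term, evaluated on a user grid) is advisory output only — the
pipeline never switches transforms automatically, keeping runs
deterministic. Outlier handling defaults to report-only; removal requires
an explicit z-score or id-list policy, mirroring analyses in which a single
extreme value is removed by hand. Candidate covariates are screened in one
joint OLS fit (coefficient p < 0.05 retained by default) with a `force_in`
escape hatch for covariates kept on substantive grounds despite marginal
p-values. The trait is then residualized on the retained covariates by OLS.
Covariate adjustment and family-correlation handling are deliberately
two-stage: covariates are regressed out once, and ρ enters at test time
through GLS whitening, so per-test work stays O(n).

**Sibship GLS.** Within a sibship of size k, V = (1 − ρ)I + ρJ and

    V^(−1/2) = (1 − ρ)^(−1/2) (I − J/k) + (1 − ρ + kρ)^(−1/2) (J/k).

OLS on whitened response and design is exactly GLS under V (verified
against a dense-matrix solve to 1e−8 in the tests). ρ is estimated once by
the one-way random-effects ANOVA estimator
ρ̂ = (MSB − MSW)/(MSB + (n₀ − 1)MSW), truncated to [0, 0.99]; negative
estimates are truncated at 0 because the whitening form requires
1 − ρ + kρ > 0 for every k. Only sib-sib correlation is modelled —
spousal and parent-offspring covariances are out of scope since only sibs
are observed. A pairwise-deleted subset of a sibship is still exchangeable,
so whitening is rebuilt per test on the retained rows without
approximation.

**Single-locus tests.** A genotype-class-means model is fitted on whitened
data. The genotypic test is the joint F over class-mean differences with
df = k − 1 for the k observed classes (df shrinks at near-monomorphic
SNPs). The additive contrast uses the HWD-tolerant weights
c_A = (−f₀/q, (f₁/2)(1/p − 1/q), f₂/p), i.e. the difference of allelic
conditional means; under Hardy-Weinberg proportions this reduces to
Kempthorne's average effect of allele substitution (tested symbolically in
the suite: c_A'(−a, d, a) = a + (q − p)d). The dominance contrast is fixed
at (−½, 1, −½). Each contrast is tested as t² → F(1, n − k) with variance
c'Cov(μ̂)c from the whitened fit. A contrast whose nonzero weights touch an
empty class is reported not-estimable rather than silently dropped; the
additive weight on an absent homozygote class is automatically zero
because the weights are built from the observed frequencies.

**Pairwise epistasis.** The 3×3 cell-means model is fitted on whitened
data. The two-locus genotypic test is the *interaction* F-test (full
cell-means vs locus-1 + locus-2 main effects, df = rank difference) — the
interaction reading is adopted because the overall 8-df test would be
confounded with the single-locus effects. The four epistasis contrasts are
Kronecker products of the per-locus additive/dominance weights computed
from marginal frequencies. A full gametic-LD weighting would require joint
haplotype frequencies that unphased data only identify up to the
double-heterozygote split; the marginal construction has the correct
HWE/linkage-equilibrium limit (verified against a product-term regression
oracle to 1e−8 under balanced cells) and is deterministic. Combination
tables use composite counting: each individual contributes two allele
units per additive locus, and a double heterozygote splits ½/½ between the
two possible phases. Effects are weighted class means centred on the
overall weighted mean, so Σf = 1 and Σf·effect = 0 hold identically
(checked to 1e−6 on generated data, and to printed rounding, 2e−3, on the
published reference rows bundled with the tests). The subclass filter
requires every occupied class to be supported by ≥ 5 raw individuals
(weighted composite counts are not used for support, as weights < 1 would
overstate sparsity).

**Genomic control and thresholds.** All p-values of a scan (pooled across
effect types, one λ per scan per trait) are mapped to 1-df chi-square
statistics by the quantile transform; λ = median/χ²₁-median (0.45494),
floored at 1.0 so adjustment never strengthens evidence; statistics are
divided by λ and p-values recomputed. For pairwise scans the λ estimate may
use a seeded without-replacement subsample (default 50,000) of the pooled
p-values; the adjustment is still applied to all of them. Thresholds are
pure arithmetic on the configuration: genome-wide single-locus level
7.2×10⁻⁸; epistasis "significant" = α/[4·N_eff(N_eff − 1)/2] with
N_eff = 276,666 and α = 0.05 giving 3.266×10⁻¹³ (four independent effects
per pair, since the interaction test is confounded with one of the
contrasts); epistasis "suggestive" = one expected false positive per scan,
1/[4·C(N_eff, 2)] = 6.532×10⁻¹². Significance calls in the run log use
GC-adjusted p-values.

## Synthetic data generator

`synthetic_data` emulates the structure the pipeline assumes: sibships of
full sibs (two unobserved founders each), founder haplotypes from a
Gaussian-copula first-order process whose lag-one latent correlation r
controls local LD, MAFs uniform on [0.01, 0.5] by default, Mendelian
transmission with Haldane recombination at 1 cM/Mb (effectively complete
linkage at the default 10-kb spacing), an exchangeable sibship random
effect tuned to a target intraclass correlation (default ρ = 0.4),
covariates echoing lipid-study adjustment sets (sex, BMI-like, smoking,
blood-sugar-like) with known coefficients, and planted QTLs in residual-sd
units: additive code (g − 1), dominance code 1{g = 1}, pairwise terms as
products of the per-locus codes of the declared type, so a planted effect
of size s is the direct target of the corresponding contrast. The default
trait scale is log-normal (trait = exp(latent)), so the pipeline's log
transform recovers the latent scale exactly while the raw trait is
right-skewed like observed lipid distributions.

Optional Hardy-Weinberg disequilibrium (`hwd_excess`) collapses each
heterozygous call to a random homozygote with probability F on the emitted
genotypes, preserving allele frequency in expectation. It is applied after
transmission because offspring of random-mating founders would otherwise
return to Hardy-Weinberg proportions; with `hwd_excess > 0`, strict
founder-offspring Mendelian consistency is therefore intentionally relaxed.

What the generator does *not* emulate: realistic genome-wide LD maps,
population stratification and admixture (λ on generated null data is ≈ 1,
so genomic control is exercised but not stressed), genotyping error,
missingness patterns, parent phenotypes, and multi-generation pedigrees.
Passing tests on generated data therefore validate the statistical
machinery under the stated model, not robustness to every feature of real
cohort data.

## Numerical choices

- Missing genotypes: pairwise deletion per test (an individual is dropped
  only for tests involving the missing SNP).
- Allele orientation: the reference (coded) allele is the minor allele at
  load time, alphabetical tie-break at MAF 0.5; effect signs refer to it.
- MAF filter boundary is inclusive (≥), with 1e−12 slack against float
  rounding of count ratios.
- Monomorphic SNPs, constant traits and all-missing columns raise typed
  degenerate-data errors; rank-deficient covariate sets raise an error
  naming the collinear columns.
- Test-count arithmetic uses Python integers (no overflow at genome
  scale); thresholds use exact rational arithmetic before conversion to
  float.
- p = 0 inputs to QQ coordinates are clamped to the smallest positive
  double with a warning; all reported p-values live in (0, 1].
- Determinism: a single configured seed drives the GC subsample and the
  generator; repeated runs produce byte-identical output files.

## Problem sizes used in the test and acceptance suites

Null calibration uses 600 individuals (200 sibships of 3, ρ = 0.4) with
2000 independent null SNPs for the single-locus tests and 2000 disjoint
null pairs, rejection rates compared to the binomial 99% interval around
5% per effect over its estimable tests. Oracle equivalence uses 100 random
instances of n = 300–400 against statsmodels least-squares oracles at
1e−8. Planted-effect recovery uses 100 replicates each: additive 0.3
residual-sd at n ≈ 2000 (MAF 0.2–0.4) and A×A 0.25 residual-sd at
n ≈ 4000 (MAFs 0.3/0.3). ICC recovery averages 20 replicates at 500
sibships of 3 because the single-draw Monte Carlo sd of the ANOVA
estimator (~0.03) is of the same order as the ±0.05 recovery band. These
sizes were chosen so each property is measured with comfortable
Monte Carlo resolution.

## Known limitations

- The equicorrelated-sibship GLS is a plug-in (ρ̂ fixed across tests), not
  per-test REML; standard errors ignore the uncertainty in ρ̂.
- Epistasis contrast weights use marginal per-locus frequencies; under
  strong LD between the tested pair the contrasts remain valid linear
  hypotheses on cell means but lose their strict variance-partition
  interpretation.
- Autosomal biallelic SNPs only; no X-chromosome model, no haplotype or
  three-way interaction tests, no imputation.
- The pairwise scan is a chunked desk-scale implementation; genome-scale
  (10¹¹-pair) runs would need distribution across workers, which the
  deterministic chunk contract permits but the package does not provide.
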