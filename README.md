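# episcan

Family-based genome-wide association scanning for quantitative traits, with
both **single-locus** (genotypic, additive, dominance) and **pairwise
epistasis** (two-locus genotypic, A×A, A×D, D×A, D×D) tests. The package is
aimed at quantitative geneticists analysing sibship-structured cohorts —
the motivating setting is lipid concentrations (total and HDL cholesterol)
measured on thousands of related individuals genotyped on a dense SNP panel.

## The statistics

For one SNP with genotype classes coded 0/1/2 (copies of the minor allele),
class means μ₀, μ₁, μ₂ and observed genotype frequencies (f₀, f₁, f₂) with
allele frequency p = f₂ + f₁/2, q = 1 − p, the tests are built from an
extended Kempthorne partition that tolerates Hardy-Weinberg disequilibrium:

- **additive (average) effect** — the difference of allelic conditional
  means, α = m_A − m_a, estimated by the contrast
  c_A = (−f₀/q, (f₁/2)(1/p − 1/q), f₂/p), which reduces to the classical
  (−q, q − p, p) under Hardy-Weinberg proportions;
- **dominance deviation** — d = μ₁ − (μ₀ + μ₂)/2, contrast
  c_D = (−½, 1, −½);
- **genotypic effect** — the joint F-test over class-mean differences.

For a SNP pair the 3×3 genotype cell means are fitted jointly; the four
epistasis contrasts are Kronecker products of the per-locus weights
(c_A⊗c_A, c_A⊗c_D, c_D⊗c_A, c_D⊗c_D) — the classical allele×allele,
allele×genotype, genotype×allele and genotype×genotype interactions — and
the two-locus genotypic test is the interaction F-test of the cell-means
model against the two-locus main-effects model.

Sib correlation is modelled as an exchangeable covariance within sibships,
V = (1 − ρ)I + ρJ, with ρ estimated once by one-way ANOVA from
covariate-adjusted residuals. Every test runs on whitened data
(V^(−1/2) applied blockwise in closed form), so ordinary least squares on
the whitened problem is exactly GLS. Residual inflation from population
structure is absorbed by genomic control: p-values are mapped to 1-df
chi-square statistics, λ = median/0.4549 (floored at 1), statistics are
divided by λ and p-values recomputed.

Reporting follows linkage-scan conventions: a genome-wide single-locus level
(default 7.2×10⁻⁸), a Bonferroni "significant" epistasis level
α/[4·C(N_eff, 2)] over N_eff effective independent SNPs (3.266×10⁻¹³ at the
defaults), and a "suggestive" level of one expected false positive per scan
(6.532×10⁻¹²). For each reported epistasis effect the package also tabulates
gamete / allele-genotype / genotype-genotype combination frequencies and
effects, using composite counting (double heterozygotes split ½/½ between
phases), with a minimum-support filter (default 5 individuals per occupied
subclass).

## Worked example

```sh
episcan simulate --out-dir fx --n-snps 15 --n-sibships 50 --seed 4
episcan scan-single --ped fx/genotypes.ped --map fx/genotypes.map \
    --pheno fx/phenotypes.tsv --out-dir scan
head -3 scan/single_results.tsv
```

```
snp_id	chr	pos	maf	n	p_genotypic	p_additive	p_dominance	alpha_hat	alpha_se	d_hat	d_se	p_genotypic_gc	p_additive_gc	p_dominance_gc
snp00000	1	10000	0.48	150	0.280217	0.33617	0.168921	0.128986	0.133675	-0.20961	0.151619	0.334426	0.389957	0.218814
snp00001	1	20000	0.266667	150	0.744822	0.699174	0.503067	-0.0501932	0.129634	0.151552	0.225751	0.771102	0.729774	0.549436
```

Each row gives the SNP's minor-allele frequency, the sample actually used
(after pairwise deletion of missing genotypes), raw and GC-adjusted
p-values for the three single-locus tests, and the additive and dominance
estimates ± SE on the adjusted log-trait scale, signed toward the minor
allele. `scan/epi_results.tsv` holds the analogous per-pair table (five
p-values, best epistasis effect with its estimate ± SE, subclass-filter
verdict); `scan/scan.log` records filter counts, the estimated ρ, both
inflation factors, and the thresholds. The same pipeline is available as
library calls (`episcan.scanctl.run_scan`) for scripted use.

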