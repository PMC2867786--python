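"""Synthetic family-structured genotype/phenotype data.

The generator emulates the statistical structure the scan assumes: sibships
of full sibs (two unobserved founder parents per sibship), SNPs with MAF
drawn from a configurable range, local LD from a first-order founder
haplotype process, optional Hardy-Weinberg disequilibrium via homozygote
excess, covariates with known coefficients, planted single-locus and
pairwise QTLs in residual-sd units, an exchangeable sibship random effect
tuned to a target intraclass correlation, and an optional log-normal trait
scale so the pipeline's log transform is exercised on right-skewed data.

Planted effects use the coding additive = (g - 1), dominance = het
indicator, and pairwise terms are products of the per-locus codes matching
the declared effect type, so a planted effect of size ``s`` is the target of
the corresponding contrast estimate downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ParameterError
from .genodata import GenotypeMatrix, SnpMeta, write_ped_map

_ALLELES = ("A", "G")   # ref (planted minor), alt


@dataclass
class CovariateSpec:
    name: str
    kind: str           # "normal" | "bernoulli"
    params: tuple       # (mean, sd) or (prob,)
    coefficient: float


def default_covariates() -> list[CovariateSpec]:
    """Sex, BMI-like, smoking, and blood-sugar-like covariates with modest
    effects on the latent (log-scale) trait, echoing lipid-study adjustment
    sets."""
    return [
        CovariateSpec("sex", "bernoulli", (0.5,), 0.10),
        CovariateSpec("bmi", "normal", (26.0, 4.0), 0.012),
        CovariateSpec("smoking", "bernoulli", (0.25,), 0.06),
        CovariateSpec("blood_sugar", "normal", (95.0, 12.0), 0.002),
    ]


@dataclass
class ArchitectureSpec:
    """Everything the simulator needs; defaults give a desk-scale family
    cohort (sibships of 3, rho = 0.4, MAF uniform on [0.01, 0.5], log-normal
    trait) mirroring the covariate-adjusted lipid-cohort setting."""

    n_snps: int = 200
    n_sibships: int = 200
    sibship_size: int = 3
    maf_range: tuple[float, float] = (0.01, 0.5)
    ld_decay: float = 0.0               # adjacent-SNP founder haplotype correlation r
    hwd_excess: float = 0.0             # founder inbreeding-style homozygote excess
    qtl_single: list[tuple[int, float, float]] = field(default_factory=list)
    qtl_pairs: list[tuple[int, int, str, float]] = field(default_factory=list)
    icc: float = 0.4
    covariates: list[CovariateSpec] = field(default_factory=default_covariates)
    trait_scale: str = "lognormal"      # "lognormal" | "gaussian"
    chromosome: str = "1"
    snp_spacing_bp: int = 10_000
    seed: int = 0

    def validate(self) -> None:
        if not 0.0 <= self.icc <= 0.95:
            raise ParameterError("icc must be in [0, 0.95]")
        if not 0.0 <= self.ld_decay < 1.0:
            raise ParameterError("ld_decay must be in [0, 1)")
        for idx, *_ in self.qtl_single:
            if not 0 <= idx < self.n_snps:
                raise ParameterError(f"qtl_single index {idx} out of range")
        for i, j, eff, _ in self.qtl_pairs:
            if not (0 <= i < self.n_snps and 0 <= j < self.n_snps and i != j):
                raise ParameterError(f"qtl_pairs indices ({i}, {j}) invalid")
            if eff not in ("AA", "AD", "DA", "DD"):
                raise ParameterError(f"unknown pairwise effect type {eff!r}")


def _founder_haplotypes(n_hap: int, mafs: np.ndarray, r: float, rng) -> np.ndarray:
    """Gaussian-copula first-order haplotype process: latent AR(1) with
    lag-one correlation r, thresholded so SNP j carries the reference allele
    with probability mafs[j]."""
    m = mafs.size
    z = np.empty((n_hap, m))
    z[:, 0] = rng.standard_normal(n_hap)
    if m > 1:
        eps = rng.standard_normal((n_hap, m - 1))
        s = (1.0 - r * r) ** 0.5
        for j in range(1, m):
            z[:, j] = r * z[:, j - 1] + s * eps[:, j - 1]
    return (z < stats.norm.ppf(mafs)[None, :]).astype(np.int8)


def simulate_genotypes(spec: ArchitectureSpec, rng=None, return_founders: bool = False):
    """Simulate founder haplotypes and sibship offspring genotypes.

    Returns ``(GenotypeMatrix, pedigree)`` where the pedigree frame carries
    individual_id / family_id / sibship_id for the observed sibs.  Offspring
    receive one recombined haplotype per parent (Haldane map, 1 cM/Mb, so
    essentially complete linkage at default spacing); parents are not
    emitted unless ``return_founders`` is set, in which case the founder
    haplotype array (4 per sibship: mother's two then father's two) is
    appended to the return tuple for transmission checks.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed if rng is None else rng)
    mafs = rng.uniform(*spec.maf_range, size=spec.n_snps)
    m, fams, k = spec.n_snps, spec.n_sibships, spec.sibship_size

    hap = _founder_haplotypes(4 * fams, mafs, spec.ld_decay, rng)  # 2 founders x 2 haps
    positions = (np.arange(m) + 1) * spec.snp_spacing_bp
    d_morgan = np.diff(positions) * 1e-8          # 1 cM per Mb
    theta = 0.5 * (1.0 - np.exp(-2.0 * d_morgan))

    n = fams * k
    codes = np.empty((n, m), dtype=np.int8)
    fam_of = np.repeat(np.arange(fams), k)
    for parent in range(2):
        # switch pattern between adjacent SNPs, per meiosis
        switch = rng.random((n, m - 1)) < theta[None, :] if m > 1 else np.empty((n, 0))
        start = rng.integers(0, 2, size=n)
        choose = np.empty((n, m), dtype=np.int64)
        choose[:, 0] = start
        if m > 1:
            choose[:, 1:] = switch
            choose = np.cumsum(choose, axis=1) % 2
        hap_a = hap[(4 * fam_of + 2 * parent)]
        hap_b = hap[(4 * fam_of + 2 * parent + 1)]
        transmitted = np.where(choose == 0, hap_a, hap_b)
        if parent == 0:
            codes = transmitted.astype(np.int8)
        else:
            codes = codes + transmitted.astype(np.int8)

    if spec.hwd_excess > 0:
        # homozygote excess (inbreeding-style HWD): each heterozygous call
        # collapses to a random homozygote with probability F, preserving the
        # allele frequency in expectation.  Applied to the emitted genotypes
        # because Mendelian transmission from random-mating founders would
        # otherwise restore Hardy-Weinberg proportions in the offspring.
        het = (codes == 1) & (rng.random(codes.shape) < spec.hwd_excess)
        codes[het] = 2 * (rng.random(int(het.sum())) < 0.5).astype(np.int8)

    snps = [
        SnpMeta(f"snp{j:05d}", spec.chromosome, int(positions[j]), *_ALLELES)
        for j in range(m)
    ]
    individual_ids = [f"fam{f:04d}_sib{s}" for f in range(fams) for s in range(k)]
    pedigree = pd.DataFrame({
        "individual_id": individual_ids,
        "family_id": [f"fam{f:04d}" for f in fam_of],
        "sibship_id": [f"fam{f:04d}" for f in fam_of],
    })
    gm = GenotypeMatrix(individual_ids, snps, codes)
    if return_founders:
        return gm, pedigree, hap
    return gm, pedigree


def simulate_phenotype(gm: GenotypeMatrix, pedigree: pd.DataFrame,
                       spec: ArchitectureSpec, rng=None):
    """Simulate the trait given genotypes; returns ``(PhenotypeTable, truth)``.

    The latent trait has unit residual variance split as icc (sibship random
    effect) + 1 - icc (individual noise); covariate and QTL terms add on
    top.  ``lognormal`` returns exp(latent) so the pipeline's log transform
    recovers the latent scale exactly.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed + 1 if rng is None else rng)
    n = gm.n_individuals
    latent = np.zeros(n)

    cov_data = {}
    for c in spec.covariates:
        if c.kind == "normal":
            x = rng.normal(c.params[0], c.params[1], size=n)
        elif c.kind == "bernoulli":
            x = rng.binomial(1, c.params[0], size=n).astype(float)
        else:
            raise ParameterError(f"unknown covariate kind {c.kind!r}")
        cov_data[c.name] = x
        latent += c.coefficient * x

    for idx, a, d in spec.qtl_single:
        g = gm.codes[:, idx].astype(float)
        latent += a * (g - 1.0) + d * (g == 1.0)

    for i, j, eff, size in spec.qtl_pairs:
        gi = gm.codes[:, i].astype(float)
        gj = gm.codes[:, j].astype(float)
        wi = (gi - 1.0) if eff[0] == "A" else (gi == 1.0).astype(float)
        wj = (gj - 1.0) if eff[1] == "A" else (gj == 1.0).astype(float)
        latent += size * wi * wj

    fam_codes, _ = pd.factorize(pedigree["sibship_id"])
    b = rng.normal(0.0, spec.icc**0.5, size=fam_codes.max() + 1)
    latent += b[fam_codes]
    latent += rng.normal(0.0, (1.0 - spec.icc) ** 0.5, size=n)

    trait = np.exp(latent) if spec.trait_scale == "lognormal" else latent
    table = pd.DataFrame({
        "individual_id": gm.individual_ids,
        "family_id": pedigree["family_id"].to_numpy(),
        "sibship_id": pedigree["sibship_id"].to_numpy(),
        "trait": trait,
        **cov_data,
    })
    truth = {
        "icc": spec.icc,
        "trait_scale": spec.trait_scale,
        "qtl_single": [
            {"snp_id": gm.snps[i].snp_id, "additive": a, "dominance": d}
            for i, a, d in spec.qtl_single
        ],
        "qtl_pairs": [
            {"snp1_id": gm.snps[i].snp_id, "snp2_id": gm.snps[j].snp_id,
             "effect_type": e, "size": s}
            for i, j, e, s in spec.qtl_pairs
        ],
        "covariates": {c.name: c.coefficient for c in spec.covariates},
    }
    return table, truth


def write_fixture(gm: GenotypeMatrix, phenotypes: pd.DataFrame, truth: dict, out_dir):
    """Write PED/MAP + phenotype TSV + a truth TSV (the truth file is for
    checking results and is never read by the pipeline)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    fam = dict(zip(phenotypes["individual_id"], phenotypes["family_id"]))
    write_ped_map(gm, out / "genotypes.ped", out / "genotypes.map", family_of=fam)
    phenotypes.to_csv(out / "phenotypes.tsv", sep="\t", index=False, na_rep="NA")

    rows = [
        {"kind": "single", "snp1_id": q["snp_id"], "snp2_id": "NA",
         "effect_type": "A+D", "size": q["additive"], "size2": q["dominance"]}
        for q in truth["qtl_single"]
    ] + [
        {"kind": "pair", "snp1_id": q["snp1_id"], "snp2_id": q["snp2_id"],
         "effect_type": q["effect_type"], "size": q["size"], "size2": 0.0}
        for q in truth["qtl_pairs"]
    ]
    pd.DataFrame(rows, columns=["kind", "snp1_id", "snp2_id", "effect_type", "size", "size2"]) \
        .to_csv(out / "truth.tsv", sep="\t", index=False)
    with open(out / "truth_params.tsv", "w") as fh:
        fh.write("param\tvalue\n")
        fh.write(f"icc\t{truth['icc']}\n")
        fh.write(f"trait_scale\t{truth['trait_scale']}\n")
    return {
        "ped": str(out / "genotypes.ped"), "map": str(out / "genotypes.map"),
        "pheno": str(out / "phenotypes.tsv"), "truth": str(out / "truth.tsv"),
    }
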