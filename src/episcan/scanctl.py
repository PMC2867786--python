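"""Scan orchestration: genomic control, genome-wide significance thresholds,
QQ coordinates, and the end-to-end pipeline runner.

Genomic control maps every p-value to the 1-df chi-square scale, estimates
the inflation factor lambda as the median statistic divided by the null
median (chi-square(1) median, ~0.4549), floors lambda at 1, divides every
statistic by lambda, and recomputes p-values.  For pairwise scans, where a
genome-scale run would pool billions of tests, the lambda estimate may use
a seeded without-replacement subsample of the pooled p-values.

Thresholds follow linkage-scan conventions: a fixed genome-wide single-locus
level, a Bonferroni "significant" level alpha / (4 * C(N_eff, 2)) for the
four independent epistasis effects per pair over N_eff effective independent
SNPs, and a "suggestive" level of one expected false positive per scan,
1 / (4 * C(N_eff, 2)).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from . import assoc_epi, assoc_single, famcorr, genodata, phenoprep
from .errors import DataError, EpiscanError

#: median of the chi-square distribution with 1 df
CHI2_1_MEDIAN = float(stats.chi2.ppf(0.5, 1))


@dataclass
class ScanConfig:
    """All tunables of a scan run; defaults mirror the study conditions."""

    maf_min: float = 0.01
    subclass_min: int = 5
    alpha_genomewide_single: float = 7.2e-8
    n_effective_snps: int = 276_666
    alpha_bonferroni: float = 0.05
    gc_enabled: bool = True
    gc_subsample_size: int = 50_000
    rng_seed: int = 0
    transform_lambda: float = 0.0
    outlier_method: str = "none"
    outlier_k: float = 3.0
    outlier_ids: list = field(default_factory=list)
    covariates: list | None = None          # None = screen every extra column
    force_in: list = field(default_factory=list)
    screen_alpha: float = 0.05
    max_snps_epi: int | None = None         # cap the pairwise scan width

    @classmethod
    def from_yaml(cls, path) -> "ScanConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise DataError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


@dataclass(frozen=True)
class InflationEstimate:
    lambda_gc: float
    n_pvalues_used: int
    subsampled: bool
    seed: int | None


def genomic_control(pvalues, subsample_size: int | None = None, seed: int | None = None):
    """Estimate the inflation factor and return GC-adjusted p-values.

    Returns ``(InflationEstimate, adjusted)`` where ``adjusted`` aligns with
    the input; NaN inputs pass through as NaN.  Lambda is floored at 1 so
    adjustment never makes a p-value smaller.
    """
    p = np.asarray(pvalues, dtype=float)
    finite = np.isfinite(p)
    if not finite.any():
        raise DataError("genomic control needs at least one p-value")
    if np.any((p[finite] <= 0) | (p[finite] > 1)):
        raise DataError("p-values must lie in (0, 1]")

    x = np.full_like(p, np.nan)
    x[finite] = stats.chi2.isf(p[finite], 1)

    pool = x[finite]
    subsampled = False
    if subsample_size is not None and subsample_size < pool.size:
        rng = np.random.default_rng(seed)
        pool = rng.choice(pool, size=subsample_size, replace=False)
        subsampled = True

    med = float(np.median(pool))
    lam = med / CHI2_1_MEDIAN
    if lam < 1.0:
        lam = 1.0
    if med == 0.0:
        warnings.warn("all p-values equal 1: lambda floored at 1")

    adjusted = np.full_like(p, np.nan)
    adjusted[finite] = stats.chi2.sf(x[finite] / lam, 1)
    est = InflationEstimate(lam, int(pool.size), subsampled, seed)
    return est, adjusted


def thresholds(config: ScanConfig) -> dict[str, float]:
    """Significance levels used for reporting (exact rational arithmetic)."""
    n = int(config.n_effective_snps)
    if n < 2:
        raise DataError("n_effective_snps must be >= 2")
    denom = 4 * n * (n - 1) // 2
    sig = Fraction(config.alpha_bonferroni).limit_denominator(10**9) / denom
    return {
        "single_genomewide": float(config.alpha_genomewide_single),
        "epistasis_significant": float(sig),
        "epistasis_suggestive": float(Fraction(1, denom)),
    }


def qq_points(pvalues) -> pd.DataFrame:
    """Expected vs observed -log10 p coordinates for a QQ plot.

    Expected quantiles are -log10(i/(n+1)); the table is sorted ascending.
    Zero p-values are clamped to the smallest positive double with a warning.
    """
    p = np.asarray(pvalues, dtype=float)
    p = p[np.isfinite(p)]
    if p.size == 0:
        raise DataError("qq_points needs at least one p-value")
    if np.any(p == 0):
        warnings.warn("p-values of 0 clamped for -log10")
        p = np.where(p == 0, np.nextafter(0, 1), p)
    n = p.size
    p_sorted = np.sort(p)                       # ascending: most significant first
    expected = -np.log10(np.arange(1, n + 1) / (n + 1.0))
    observed = -np.log10(p_sorted)
    return pd.DataFrame({"expected": expected[::-1], "observed": observed[::-1]})


# ---------------------------------------------------------------------------
# end-to-end runner


def _stage(name):
    def deco(fn):
        def wrapper(*a, **kw):
            try:
                return fn(*a, **kw)
            except EpiscanError as e:
                raise EpiscanError(f"[{name}] {e}") from e
        return wrapper
    return deco


def _float_or_nan(v):
    return float("nan") if v is None else v


def prepare_phenotype(config: ScanConfig, pheno: pd.DataFrame):
    """Transform, outlier-screen, covariate-screen, and adjust the trait.

    Returns ``(AdjustedPhenotype, SibshipStructure, log_lines)``.
    """
    lines = []
    pheno = pheno.dropna(subset=["trait"]).reset_index(drop=True)
    y_raw = pheno["trait"].to_numpy(dtype=float)
    ids = pheno["individual_id"].tolist()
    y_t = phenoprep.apply_transform(y_raw, config.transform_lambda)

    flagged = phenoprep.flag_outliers(
        y_t, ids, method=config.outlier_method, k=config.outlier_k,
        explicit=config.outlier_ids or None,
    )
    lines.append(f"outliers removed: {len(flagged)} ({flagged})")
    keep = ~pheno["individual_id"].isin(flagged)
    pheno = pheno.loc[keep].reset_index(drop=True)
    y_t = y_t[keep.to_numpy()]
    ids = pheno["individual_id"].tolist()

    extra = [c for c in pheno.columns if c not in phenoprep.REQUIRED_COLUMNS]
    candidates = config.covariates if config.covariates is not None else extra
    unknown = [c for c in candidates if c not in pheno.columns]
    if unknown:
        raise DataError(f"covariates not in phenotype table: {unknown}")
    retained: list[str] = []
    if candidates:
        cand_df = pheno[candidates].astype(float)
        ok = ~cand_df.isna().any(axis=1)
        if not ok.all():
            lines.append(f"dropped {int((~ok).sum())} individuals with missing covariates")
            pheno = pheno.loc[ok].reset_index(drop=True)
            y_t = y_t[ok.to_numpy()]
            cand_df = cand_df.loc[ok].reset_index(drop=True)
            ids = pheno["individual_id"].tolist()
        retained, pvals = phenoprep.screen_covariates(
            y_t, cand_df, force_in=config.force_in, alpha=config.screen_alpha
        )
        lines.append("covariate screen p-values: "
                     + ", ".join(f"{c}={pvals[c]:.3g}" for c in candidates))
    lines.append(f"covariates retained: {retained}")

    adj = phenoprep.adjust_phenotype(
        y_t, pheno[retained] if retained else None, ids,
        removed_outliers=[(i, config.outlier_method) for i in flagged],
    )
    structure = famcorr.SibshipStructure.from_frame(pheno)
    return adj, structure, lines


def single_scan(gm: genodata.GenotypeMatrix, resid: np.ndarray,
                structure: famcorr.SibshipStructure, rho: float) -> pd.DataFrame:
    """Run the three single-locus tests for every SNP; one row per SNP."""
    rows = []
    for j, snp in enumerate(gm.snps):
        r = assoc_single.test_single_locus(resid, gm.codes[:, j], structure, rho, snp.snp_id)
        rows.append({
            "snp_id": snp.snp_id, "chr": snp.chromosome, "pos": snp.position,
            "maf": r.freq.maf, "n": r.n_used,
            "p_genotypic": _float_or_nan(r.p_genotypic),
            "p_additive": _float_or_nan(r.p_additive),
            "p_dominance": _float_or_nan(r.p_dominance),
            "alpha_hat": _float_or_nan(r.alpha_hat), "alpha_se": _float_or_nan(r.alpha_se),
            "d_hat": _float_or_nan(r.d_hat), "d_se": _float_or_nan(r.d_se),
        })
    return pd.DataFrame(rows)


def epi_scan(gm: genodata.GenotypeMatrix, resid: np.ndarray,
             structure: famcorr.SibshipStructure, rho: float,
             subclass_min: int = 5, chunk_size: int | None = None) -> pd.DataFrame:
    """Run the five pairwise tests for every SNP pair; one row per pair."""
    rows = []
    for i, j in assoc_epi.iterate_pairs(gm, chunk_size):
        s1, s2 = gm.snps[i], gm.snps[j]
        r = assoc_epi.test_pair(resid, gm.codes[:, i], gm.codes[:, j], structure, rho,
                                s1.snp_id, s2.snp_id, subclass_min=subclass_min)
        best = r.best_effect
        rows.append({
            "snp1": s1.snp_id, "chr1": s1.chromosome, "pos1": s1.position,
            "snp2": s2.snp_id, "chr2": s2.chromosome, "pos2": s2.position,
            "maf1": r.freq1.maf, "maf2": r.freq2.maf, "n": r.n_used,
            "p_two_locus_genotypic": _float_or_nan(r.p_two_locus_genotypic),
            **{f"p_{e}": _float_or_nan(r.effects[e].p) for e in assoc_epi.EFFECTS},
            "best_effect": best or "NA",
            "effect_hat": _float_or_nan(r.effects[best].estimate if best else None),
            "effect_se": _float_or_nan(r.effects[best].se if best else None),
            "subclass_pass": bool(r.subclass.passed) if r.subclass else False,
        })
    return pd.DataFrame(rows)


def attach_gc(df: pd.DataFrame, pcols: list[str], enabled: bool,
              subsample_size: int | None = None, seed: int | None = None):
    """Pool the given p-value columns, estimate one lambda, and append
    ``<col>_gc`` columns.  Returns the InflationEstimate."""
    pooled = np.concatenate([df[c].to_numpy(dtype=float) for c in pcols])
    if not enabled:
        for c in pcols:
            df[c + "_gc"] = df[c]
        return InflationEstimate(1.0, int(np.isfinite(pooled).sum()), False, seed)
    est, _ = genomic_control(pooled[np.isfinite(pooled)], subsample_size, seed)
    for c in pcols:
        x = stats.chi2.isf(df[c].to_numpy(dtype=float), 1)
        df[c + "_gc"] = stats.chi2.sf(x / est.lambda_gc, 1)
    return est


TSV_FLOAT = "%.6g"


def run_scan(config: ScanConfig, ped_path, map_path, pheno_path, out_dir) -> dict:
    """Execute the full pipeline and write result TSVs plus a run log.

    Stages: phenotype prep -> sibship ICC -> single-locus scan -> GC ->
    pairwise scan -> GC -> thresholds -> QQ tables.  Fully deterministic for
    a fixed config (the GC subsample seed derives from ``rng_seed``).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    lines = [f"config: {config}"]

    gm = genodata.load_genotypes(ped_path, map_path)
    lines.append(f"genotypes: {gm.n_individuals} individuals x {gm.n_snps} SNPs")
    gm = genodata.filter_by_maf(gm, config.maf_min)
    lines.append(f"SNPs after MAF >= {config.maf_min} filter: {gm.n_snps}")

    pheno = phenoprep.read_phenotypes(pheno_path)
    adj, structure, prep_lines = prepare_phenotype(config, pheno)
    lines += prep_lines

    # align genotype rows to the prepared phenotype rows
    order = {ind: i for i, ind in enumerate(gm.individual_ids)}
    missing_ids = [i for i in adj.individual_ids if i not in order]
    if missing_ids:
        raise DataError(f"[align] phenotyped individuals absent from PED: {missing_ids[:5]}")
    rows = [order[i] for i in adj.individual_ids]
    gm = genodata.GenotypeMatrix(adj.individual_ids, gm.snps, gm.codes[rows, :])

    icc = famcorr.estimate_icc(adj.residuals, structure)
    lines.append(f"intra-sibship correlation rho = {icc.rho:.4f} over {icc.n_sibships} sibships")

    single = single_scan(gm, adj.residuals, structure, icc.rho)
    est_single = attach_gc(single, ["p_genotypic", "p_additive", "p_dominance"],
                           config.gc_enabled)
    lines.append(f"single-locus lambda_gc = {est_single.lambda_gc:.4f} "
                 f"({est_single.n_pvalues_used} p-values)")

    gm_epi = gm
    if config.max_snps_epi is not None and gm.n_snps > config.max_snps_epi:
        gm_epi = genodata.GenotypeMatrix(gm.individual_ids, gm.snps[: config.max_snps_epi],
                                         gm.codes[:, : config.max_snps_epi])
        lines.append(f"pairwise scan limited to first {config.max_snps_epi} SNPs")
    epi = epi_scan(gm_epi, adj.residuals, structure, icc.rho, config.subclass_min)
    epi_pcols = ["p_two_locus_genotypic"] + [f"p_{e}" for e in assoc_epi.EFFECTS]
    est_epi = attach_gc(epi, epi_pcols, config.gc_enabled,
                        subsample_size=config.gc_subsample_size, seed=config.rng_seed)
    lines.append(f"pairwise lambda_gc = {est_epi.lambda_gc:.4f} "
                 f"({est_epi.n_pvalues_used} p-values"
                 f"{', subsampled' if est_epi.subsampled else ''})")
    lines.append(f"pairs failing subclass filter (min {config.subclass_min}): "
                 f"{int((~epi['subclass_pass']).sum())} of {len(epi)}")

    thr = thresholds(config)
    lines.append("thresholds: " + ", ".join(f"{k}={v:.4g}" for k, v in thr.items()))

    n_sig_single = int((single["p_additive_gc"] < thr["single_genomewide"]).sum())
    epi_best = epi[[f"p_{e}_gc" for e in assoc_epi.EFFECTS]].min(axis=1)
    n_sugg = int(((epi_best < thr["epistasis_suggestive"]) & epi["subclass_pass"]).sum())
    lines.append(f"single-locus additive effects past genome-wide level: {n_sig_single}")
    lines.append(f"epistasis effects past suggestive level (subclass-filtered): {n_sugg}")

    paths = {
        "single": out / "single_results.tsv",
        "epi": out / "epi_results.tsv",
        "qq_single": out / "qq_single.tsv",
        "qq_epi": out / "qq_epi.tsv",
        "log": out / "scan.log",
    }
    single.to_csv(paths["single"], sep="\t", index=False, float_format=TSV_FLOAT)
    epi.to_csv(paths["epi"], sep="\t", index=False, float_format=TSV_FLOAT)
    qq_points(single["p_additive_gc"].dropna()).to_csv(
        paths["qq_single"], sep="\t", index=False, float_format=TSV_FLOAT)
    qq_points(pd.concat([epi[c] for c in epi_pcols]).dropna()).to_csv(
        paths["qq_epi"], sep="\t", index=False, float_format=TSV_FLOAT)
    paths["log"].write_text("\n".join(lines) + "\n")
    return {k: str(v) for k, v in paths.items()}
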