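"""Per-SNP tests of genotypic, additive, and dominance effects.

The model is a genotype-class-means fit on GLS-whitened data.  The additive
contrast follows the extended Kempthorne partition that tolerates
Hardy-Weinberg disequilibrium: with genotype frequencies (f0, f1, f2) and
reference-allele frequency p (q = 1 - p), the additive (average) effect is
the difference of allelic conditional means

    alpha = m_ref - m_alt,  contrast c_A = (-f0/q, (f1/2)(1/p - 1/q), f2/p),

which reduces to the classical (-q, q - p, p) under Hardy-Weinberg
proportions.  The dominance contrast is fixed at (-1/2, 1, -1/2): the
heterozygote mean minus the homozygote midpoint.

Each contrast is tested as t^2 -> F(1, n - k); the genotypic effect is the
joint F over class-mean differences with df = k - 1 for k observed classes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from ._lm import ls_fit
from .errors import DegenerateDataError
from .famcorr import SibshipStructure, whiten_by_codes
from .genodata import MISSING, FreqSummary, summarize_snp

_DOM = np.array([-0.5, 1.0, -0.5])


@dataclass(frozen=True)
class ContrastWeights:
    """Additive and dominance contrast vectors over the class means (mu0, mu1, mu2)."""

    c_additive: np.ndarray
    c_dominance: np.ndarray


@dataclass
class SingleLocusResult:
    snp_id: str
    n_used: int
    freq: FreqSummary
    p_genotypic: float | None
    p_additive: float | None
    p_dominance: float | None
    alpha_hat: float | None
    alpha_se: float | None
    d_hat: float | None
    d_se: float | None
    p_genotypic_gc: float | None = None
    p_additive_gc: float | None = None
    p_dominance_gc: float | None = None


def kempthorne_weights(freq: FreqSummary) -> ContrastWeights:
    """Contrast weights from observed genotype frequencies (HWD tolerated)."""
    p = freq.p_ref
    if not 0.0 < p < 1.0:
        raise DegenerateDataError("monomorphic SNP: contrasts undefined")
    q = 1.0 - p
    f0, f1, f2 = freq.genotype_freqs
    c_add = np.array([-f0 / q, 0.5 * f1 * (1.0 / p - 1.0 / q), f2 / p])
    return ContrastWeights(c_add, _DOM.copy())


def _contrast_test(c_obs, beta, xtx_inv, sigma2, df2):
    est = float(c_obs @ beta)
    var = float(c_obs @ xtx_inv @ c_obs) * sigma2
    if var <= 0 or df2 <= 0:
        return est, None, None
    se = var**0.5
    f = (est / se) ** 2
    return est, se, float(stats.f.sf(f, 1, df2))


def test_single_locus(residuals: np.ndarray, g: np.ndarray,
                      structure: SibshipStructure, rho: float,
                      snp_id: str = "") -> SingleLocusResult:
    """Genotypic / additive / dominance tests for one SNP.

    Individuals missing this genotype are dropped (pairwise deletion); the
    whitening transform is rebuilt on the retained subset, which stays exact
    because sub-blocks of an exchangeable covariance are exchangeable.
    A contrast whose nonzero weights touch an empty genotype class is
    reported as not estimable (None) while the others proceed.
    """
    g = np.asarray(g)
    y = np.asarray(residuals, dtype=float)
    mask = g != MISSING
    gg = g[mask].astype(np.int64)
    yy = y[mask]
    freq = summarize_snp(gg)
    classes = np.unique(gg)
    k = classes.size
    if k < 2:
        raise DegenerateDataError(f"SNP {snp_id or '?'}: fewer than two genotype classes")

    codes = structure.codes[mask]
    n = yy.size
    Z = (gg[:, None] == classes[None, :]).astype(float)
    yw = whiten_by_codes(yy, codes, rho)
    Zw = whiten_by_codes(Z, codes, rho)
    onew = whiten_by_codes(np.ones(n), codes, rho)[:, None]

    fit = ls_fit(Zw, yw, need_cov=True)
    df2 = n - k
    sigma2 = fit.rss / df2 if df2 > 0 else np.nan

    # genotypic: class-means model vs intercept-only, both whitened
    null = ls_fit(onew, yw)
    p_geno = None
    if df2 > 0 and sigma2 > 0:
        f_geno = ((null.rss - fit.rss) / (k - 1)) / sigma2
        p_geno = float(stats.f.sf(f_geno, k - 1, df2))

    w = kempthorne_weights(freq)
    present = np.isin([0, 1, 2], classes)

    def run(c3):
        needed = np.abs(c3) > 1e-14
        if np.any(needed & ~present):
            return None, None, None
        c_obs = c3[classes]
        return _contrast_test(c_obs, fit.beta, fit.xtx_inv, sigma2, df2)

    alpha_hat, alpha_se, p_add = run(w.c_additive)
    d_hat, d_se, p_dom = run(w.c_dominance)

    return SingleLocusResult(
        snp_id=snp_id, n_used=n, freq=freq,
        p_genotypic=p_geno, p_additive=p_add, p_dominance=p_dom,
        alpha_hat=alpha_hat, alpha_se=alpha_se, d_hat=d_hat, d_se=d_se,
    )
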