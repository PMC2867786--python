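"""Pairwise epistasis scan: two-locus genotypic (interaction) test, the four
Kempthorne epistasis contrasts (A x A, A x D, D x A, D x D), subclass-support
filtering, and combination-frequency reporting.

Each pair is analysed through a 3 x 3 genotype cell-means model on whitened
data.  Epistasis contrast vectors are Kronecker products of the per-locus
additive/dominance weights (marginal frequencies, HWD-tolerant), giving the
classical allele x allele, allele x genotype, genotype x allele, and
genotype x genotype interpretations.  Phase of double heterozygotes is
unknown for unphased SNP data, so gamete-level tabulation uses composite
counting: each individual contributes two allele units per locus and a
double heterozygote splits 1/2 - 1/2 between the two phases.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, NamedTuple

import numpy as np
from scipy import stats

from ._lm import ls_fit
from .assoc_single import kempthorne_weights
from .errors import DegenerateDataError
from .famcorr import SibshipStructure, whiten_by_codes
from .genodata import MISSING, FreqSummary, GenotypeMatrix, summarize_snp

EFFECTS = ("AA", "AD", "DA", "DD")


class EffectTest(NamedTuple):
    estimate: float | None
    se: float | None
    p: float | None


@dataclass
class CellMeanGrid:
    """Estimated 3x3 genotype-combination cell means and their covariance.

    ``cov`` is 9x9 in row-major (i*3 + j) order with NaN rows/columns for
    unobserved cells; ``df_resid`` is n - (#observed cells) from the
    whitened fit.
    """

    means: np.ndarray        # 3x3, NaN where counts == 0
    counts: np.ndarray       # 3x3 int
    cov: np.ndarray          # 9x9
    sigma2: float
    df_resid: int


@dataclass
class CombinationTable:
    """Frequencies and effects of gamete / allele-genotype / genotype-genotype
    classes for one epistasis effect.

    ``effect`` is each class's weighted mean residual minus the overall
    weighted mean, so sum(frequency * effect) = 0 by construction;
    ``support`` counts the individuals contributing positive weight.
    """

    granularity: str                  # gamete | allele_genotype | genotype_genotype
    classes: list[str]
    frequency: np.ndarray
    effect: np.ndarray                # NaN for empty classes
    support: np.ndarray               # raw individual counts


class FilterResult(NamedTuple):
    passed: bool
    offending: list[str]


@dataclass
class EpistasisResult:
    snp1_id: str
    snp2_id: str
    n_used: int
    freq1: FreqSummary
    freq2: FreqSummary
    p_two_locus_genotypic: float | None
    effects: dict[str, EffectTest]
    best_effect: str | None
    combination: CombinationTable | None
    subclass: FilterResult | None
    p_two_locus_genotypic_gc: float | None = None
    p_gc: dict[str, float | None] = field(default_factory=dict)


def iterate_pairs(n_or_gm, chunk_size: int | None = None) -> Iterator[tuple[int, int]]:
    """Yield each unordered SNP-index pair (i < j) exactly once, in
    lexicographic order.  ``chunk_size`` only affects internal batching and
    never the emitted sequence, so chunked and unchunked runs agree."""
    n = n_or_gm.n_snps if isinstance(n_or_gm, GenotypeMatrix) else int(n_or_gm)
    for chunk in pair_chunks(n, chunk_size):
        yield from chunk


def pair_chunks(n: int, chunk_size: int | None = None) -> Iterator[list[tuple[int, int]]]:
    """Deterministic partition of the pair stream into work chunks."""
    if n < 2:
        raise DegenerateDataError("pair enumeration requires >= 2 SNPs")
    chunk: list[tuple[int, int]] = []
    limit = chunk_size if chunk_size and chunk_size > 0 else None
    for i in range(n - 1):
        for j in range(i + 1, n):
            chunk.append((i, j))
            if limit and len(chunk) >= limit:
                yield chunk
                chunk = []
    if chunk:
        yield chunk


def _pair_design(g1, g2):
    """Observed-cell indicator matrix and bookkeeping for one pair."""
    cell = g1 * 3 + g2
    counts = np.bincount(cell, minlength=9).reshape(3, 3)
    observed = np.nonzero(counts.ravel() > 0)[0]
    Z = (cell[:, None] == observed[None, :]).astype(float)
    return Z, observed, counts


def fit_cell_means(residuals, g1, g2, structure: SibshipStructure, rho: float):
    """Whitened cell-means fit for one SNP pair (pairwise deletion applied).

    Returns (grid, mask, yw, Zw, observed, main-effects design) where the
    main-effects design spans locus-1 plus locus-2 class indicators.
    """
    g1 = np.asarray(g1)
    g2 = np.asarray(g2)
    y = np.asarray(residuals, dtype=float)
    mask = (g1 != MISSING) & (g2 != MISSING)
    a, b, yy = g1[mask].astype(np.int64), g2[mask].astype(np.int64), y[mask]
    if np.unique(a).size < 2 or np.unique(b).size < 2:
        raise DegenerateDataError("pair test requires >= 2 classes at each locus")
    codes = structure.codes[mask]

    Z, observed, counts = _pair_design(a, b)
    yw = whiten_by_codes(yy, codes, rho)
    Zw = whiten_by_codes(Z, codes, rho)

    fit = ls_fit(Zw, yw, need_cov=True)
    n = yy.size
    k = observed.size
    df_resid = n - k
    sigma2 = fit.rss / df_resid if df_resid > 0 else np.nan

    means = np.full(9, np.nan)
    means[observed] = fit.beta
    cov = np.full((9, 9), np.nan)
    if sigma2 > 0:
        cov[np.ix_(observed, observed)] = sigma2 * fit.xtx_inv
    grid = CellMeanGrid(means.reshape(3, 3), counts, cov, sigma2, df_resid)

    # main-effects (no interaction) design on the same whitened subset
    ZA = (a[:, None] == np.unique(a)[None, :]).astype(float)
    ZB = (b[:, None] == np.unique(b)[None, :]).astype(float)
    main_w = whiten_by_codes(np.hstack([ZA, ZB]), codes, rho)

    return grid, mask, yw, fit, main_w, (a, b, yy)


def two_locus_genotypic_test(residuals, g1, g2, structure: SibshipStructure, rho: float):
    """Interaction F-test: full cell-means model vs locus-1 + locus-2 class
    main effects, df1 = rank(full) - rank(main).  Returns (F, p); (None, None)
    when no interaction degrees of freedom remain."""
    grid, _, yw, fit, main_w, _ = fit_cell_means(residuals, g1, g2, structure, rho)
    return _interaction_test(yw, fit, main_w, grid)


def _interaction_test(yw, fit, main_w, grid: CellMeanGrid):
    main = ls_fit(main_w, yw)
    df1 = fit.rank - main.rank
    if df1 <= 0 or grid.df_resid <= 0 or not grid.sigma2 > 0:
        return None, None
    f = ((main.rss - fit.rss) / df1) / grid.sigma2
    return float(f), float(stats.f.sf(f, df1, grid.df_resid))


def epistasis_contrasts(cells: CellMeanGrid, freq1: FreqSummary, freq2: FreqSummary) -> dict[str, EffectTest]:
    """The four epistasis contrasts applied to the 3x3 cell means.

    Each contrast is the Kronecker product of the per-locus additive or
    dominance weights, tested as t^2 -> F(1, df_resid) with variance from the
    cell-mean covariance.  A contrast touching an empty cell is not estimable.
    """
    w1, w2 = kempthorne_weights(freq1), kempthorne_weights(freq2)
    per_locus = {"A": (w1.c_additive, w2.c_additive), "D": (w1.c_dominance, w2.c_dominance)}
    flat_means = cells.means.ravel()
    observed = ~np.isnan(flat_means)
    out: dict[str, EffectTest] = {}
    for name in EFFECTS:
        c = np.kron(per_locus[name[0]][0], per_locus[name[1]][1])
        needed = np.abs(c) > 1e-14
        if np.any(needed & ~observed):
            out[name] = EffectTest(None, None, None)
            continue
        idx = np.nonzero(needed)[0]
        est = float(c[idx] @ flat_means[idx])
        var = float(c[idx] @ cells.cov[np.ix_(idx, idx)] @ c[idx])
        if var <= 0 or cells.df_resid <= 0:
            out[name] = EffectTest(est, None, None)
            continue
        se = var**0.5
        p = float(stats.f.sf((est / se) ** 2, 1, cells.df_resid))
        out[name] = EffectTest(est, se, p)
    return out


def _allele_weight(g):
    """Probability that a random allele of this genotype is the reference."""
    return g / 2.0


def combination_table(effect: str, residuals, g1, g2,
                      labels1: tuple[str, str] | None = None,
                      labels2: tuple[str, str] | None = None) -> CombinationTable:
    """Tabulate combination frequencies and effects for one epistasis effect.

    A x A uses 4 gamete classes with composite counting (each individual
    contributes 2 allele pairs; double heterozygotes split 1/2 to each
    phase); A x D and D x A use 6 allele-by-genotype classes (allele at the
    additive locus crossed with genotype at the dominance locus); D x D is
    the plain 3 x 3 genotype cross-tabulation.  Effects are weighted class
    means of the residual, centred on the overall weighted mean.
    """
    if effect not in EFFECTS:
        raise DegenerateDataError(f"unknown effect type {effect!r}")
    g1 = np.asarray(g1)
    g2 = np.asarray(g2)
    y = np.asarray(residuals, dtype=float)
    mask = (g1 != MISSING) & (g2 != MISSING)
    a, b, yy = g1[mask].astype(float), g2[mask].astype(float), y[mask]

    r1, a1 = labels1 or ("R1", "r1")
    r2, a2 = labels2 or ("R2", "r2")

    if effect == "AA":
        h1, h2 = _allele_weight(a), _allele_weight(b)
        W = 2.0 * np.column_stack([h1 * h2, h1 * (1 - h2), (1 - h1) * h2, (1 - h1) * (1 - h2)])
        classes = [f"{r1}-{r2}", f"{r1}-{a2}", f"{a1}-{r2}", f"{a1}-{a2}"]
        gran = "gamete"
    elif effect in ("AD", "DA"):
        if effect == "DA":                      # additive locus is locus 2
            a, b = b, a
            (r1, a1), (r2, a2) = (r2, a2), (r1, a1)
        h = _allele_weight(a)
        geno_lab = [f"{a2}{a2}", f"{r2}{a2}", f"{r2}{r2}"]
        cols, classes = [], []
        for allele, hw in ((r1, h), (a1, 1 - h)):
            for gcode, gl in enumerate(geno_lab):
                cols.append(2.0 * hw * (b == gcode))
                classes.append(f"{allele}-{gl}")
        W = np.column_stack(cols)
        gran = "allele_genotype"
    else:  # DD
        lab1 = [f"{a1}{a1}", f"{r1}{a1}", f"{r1}{r1}"]
        lab2 = [f"{a2}{a2}", f"{r2}{a2}", f"{r2}{r2}"]
        cols, classes = [], []
        for i in range(3):
            for j in range(3):
                cols.append(((a == i) & (b == j)).astype(float))
                classes.append(f"{lab1[i]}-{lab2[j]}")
        W = np.column_stack(cols)
        gran = "genotype_genotype"

    total = W.sum()
    colsum = W.sum(axis=0)
    freq = colsum / total
    overall = float(W.sum(axis=1) @ yy) / total
    with np.errstate(invalid="ignore", divide="ignore"):
        class_mean = (W.T @ yy) / colsum
    eff = class_mean - overall
    eff[colsum == 0] = np.nan
    support = (W > 0).sum(axis=0)
    return CombinationTable(gran, classes, freq, eff, support.astype(int))


def subclass_filter(table: CombinationTable, min_count: int = 5) -> FilterResult:
    """Require every occupied class to be supported by >= ``min_count``
    individuals (raw counts, not composite weights)."""
    if min_count < 1:
        raise DegenerateDataError("min_count must be >= 1")
    offending = [
        c for c, f, s in zip(table.classes, table.frequency, table.support)
        if f > 0 and s < min_count
    ]
    return FilterResult(not offending, offending)


def test_pair(residuals, g1, g2, structure: SibshipStructure, rho: float,
              snp1_id: str = "", snp2_id: str = "",
              subclass_min: int = 5, with_combination: bool = True) -> EpistasisResult:
    """Full five-effect analysis of one SNP pair.

    ``best_effect`` is the most significant estimable epistasis contrast
    (smallest p; unchanged by a scan-wide genomic-control rescale, which is
    monotone).  Its combination table and subclass filter verdict are
    attached when ``with_combination`` is set.
    """
    grid, mask, yw, fit, main_w, (a, b, yy) = fit_cell_means(residuals, g1, g2, structure, rho)
    freq1, freq2 = summarize_snp(a), summarize_snp(b)
    _, p_geno = _interaction_test(yw, fit, main_w, grid)
    effects = epistasis_contrasts(grid, freq1, freq2)

    estimable = [e for e in EFFECTS if effects[e].p is not None]
    best = min(estimable, key=lambda e: effects[e].p) if estimable else None

    comb = filt = None
    if best is not None and with_combination:
        comb = combination_table(best, yy, a, b)
        filt = subclass_filter(comb, subclass_min)

    return EpistasisResult(
        snp1_id=snp1_id, snp2_id=snp2_id, n_used=yy.size,
        freq1=freq1, freq2=freq2,
        p_two_locus_genotypic=p_geno, effects=effects,
        best_effect=best, combination=comb, subclass=filt,
    )
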