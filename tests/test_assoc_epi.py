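"""Pairwise epistasis: pair enumeration, the interaction F-test, the four
Kempthorne contrasts, combination tables, and subclass filtering."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from episcan import assoc_epi, genodata
from episcan.assoc_epi import (
    EFFECTS,
    combination_table,
    epistasis_contrasts,
    fit_cell_means,
    iterate_pairs,
    pair_chunks,
    subclass_filter,
)
from episcan.assoc_epi import test_pair as analyse_pair
from episcan.assoc_epi import two_locus_genotypic_test as interaction_test
from episcan.famcorr import SibshipStructure

from _reference_tables import REFERENCE_COMBINATION_ROWS


def singleton_structure(n):
    return SibshipStructure.from_labels([str(i) for i in range(n)], [str(i) for i in range(n)])


def balanced_pair(per_cell=20):
    """All nine genotype combinations with equal counts."""
    g1 = np.repeat([0, 1, 2], 3 * per_cell).astype(np.int8)
    g2 = np.tile(np.repeat([0, 1, 2], per_cell), 3).astype(np.int8)
    return g1, g2


class TestPairEnumeration:
    def test_three_snps(self):
        assert list(iterate_pairs(3)) == [(0, 1), (0, 2), (1, 2)]

    def test_two_hundred_snps_count(self):
        assert len(list(iterate_pairs(200))) == 19_900 == genodata.count_tests(200, "pairs")

    @pytest.mark.parametrize("chunk", [1, 7, 100, None])
    def test_chunking_never_changes_the_stream(self, chunk):
        assert list(iterate_pairs(25, chunk)) == list(iterate_pairs(25))
        flat = [p for c in pair_chunks(25, chunk) for p in c]
        assert flat == list(iterate_pairs(25))


class TestInteractionTest:
    def test_additive_surface_gives_null_interaction(self, rng):
        g1, g2 = balanced_pair(30)
        n = g1.size
        y = 0.4 * g1 + 0.7 * g2 + rng.normal(0, 1.0, size=n)
        f, p = interaction_test(y, g1, g2, singleton_structure(n), 0.0)
        # compare with a plain two-way ANOVA oracle via statsmodels
        df = pd.DataFrame({"y": y, "a": g1.astype(str), "b": g2.astype(str)})
        full = sm.OLS.from_formula("y ~ C(a) * C(b)", df).fit()
        main = sm.OLS.from_formula("y ~ C(a) + C(b)", df).fit()
        f_or = ((main.ssr - full.ssr) / 4) / (full.ssr / full.df_resid)
        from scipy import stats as sps
        p_or = sps.f.sf(f_or, 4, full.df_resid)
        assert p == pytest.approx(p_or, abs=1e-10)

    def test_planted_interaction_detected(self, rng):
        hits = 0
        for rep in range(20):
            r = np.random.default_rng(100 + rep)
            n = 2000
            g1 = r.binomial(2, 0.4, size=n).astype(np.int8)
            g2 = r.binomial(2, 0.4, size=n).astype(np.int8)
            y = r.normal(size=n) + 0.5 * ((g1 == 1) & (g2 == 1))
            _, p = interaction_test(y, g1, g2, singleton_structure(n), 0.0)
            hits += p < 1e-4
        assert hits >= 16  # > 80 percent power


class TestContrasts:
    def test_additive_surface_zeroes_all_contrasts(self, rng):
        g1, g2 = balanced_pair(10)
        n = g1.size
        y = 1.5 * g1 - 0.8 * g2 + 3.0   # exact cell means mu_ij = a_i + b_j
        grid, *_ = fit_cell_means(y, g1, g2, singleton_structure(n), 0.0)
        res = epistasis_contrasts(grid,
                                  genodata.summarize_snp(g1), genodata.summarize_snp(g2))
        for e in EFFECTS:
            assert abs(res[e].estimate) < 1e-12

    def test_double_heterozygote_cell_is_pure_dd(self, rng):
        g1, g2 = balanced_pair(10)
        n = g1.size
        y = ((g1 == 1) & (g2 == 1)).astype(float)   # mu(1,1)=1, others 0
        grid, *_ = fit_cell_means(y, g1, g2, singleton_structure(n), 0.0)
        res = epistasis_contrasts(grid,
                                  genodata.summarize_snp(g1), genodata.summarize_snp(g2))
        assert res["DD"].estimate == pytest.approx(1.0, abs=1e-12)

    def test_aa_contrast_matches_product_regression_oracle(self, rng):
        """With balanced cells the A x A p-value equals the p-value of the
        additive-product coefficient in a saturated regression."""
        g1, g2 = balanced_pair(15)
        n = g1.size
        y = rng.normal(size=n) + 0.3 * (g1 - 1.0) * (g2 - 1.0)
        grid, *_ = fit_cell_means(y, g1, g2, singleton_structure(n), 0.0)
        res = epistasis_contrasts(grid,
                                  genodata.summarize_snp(g1), genodata.summarize_snp(g2))
        a1, d1 = g1 - 1.0, (g1 == 1).astype(float)
        a2, d2 = g2 - 1.0, (g2 == 1).astype(float)
        X = sm.add_constant(np.column_stack(
            [a1, d1, a2, d2, a1 * a2, a1 * d2, d1 * a2, d1 * d2]))
        fit = sm.OLS(y, X).fit()
        assert res["AA"].p == pytest.approx(float(fit.pvalues[5]), abs=1e-8)

    def test_missing_required_cell_not_estimable(self, rng):
        n = 300
        g1 = rng.binomial(2, 0.4, size=n).astype(np.int8)
        g2 = rng.binomial(2, 0.4, size=n).astype(np.int8)
        g2[(g1 == 2)] = np.where(g2[(g1 == 2)] == 2, 1, g2[(g1 == 2)])  # empty (2,2) cell
        y = rng.normal(size=n)
        grid, *_ = fit_cell_means(y, g1, g2, singleton_structure(n), 0.0)
        res = epistasis_contrasts(grid,
                                  genodata.summarize_snp(g1), genodata.summarize_snp(g2))
        # every contrast puts nonzero weight on the double-homozygote cell here
        assert res["AA"].p is None and res["DD"].p is None

    def test_absent_marginal_class_zeroes_additive_weight(self, rng):
        n = 400
        g1 = rng.binomial(1, 0.4, size=n).astype(np.int8)   # no class 2 at locus 1
        g2 = rng.binomial(2, 0.5, size=n).astype(np.int8)
        y = rng.normal(size=n)
        grid, *_ = fit_cell_means(y, g1, g2, singleton_structure(n), 0.0)
        res = epistasis_contrasts(grid,
                                  genodata.summarize_snp(g1), genodata.summarize_snp(g2))
        assert res["AA"].p is not None      # additive weight on the empty row is 0
        assert res["DD"].p is None          # dominance needs the whole 3x3 grid


class TestCombinationTables:
    def test_double_heterozygote_splits_half_to_each_phase(self):
        t = combination_table("AA", np.array([0.0]), np.array([1]), np.array([1]))
        np.testing.assert_allclose(t.frequency, [0.25, 0.25, 0.25, 0.25])
        assert t.granularity == "gamete"
        assert t.support.tolist() == [1, 1, 1, 1]

    def test_published_rows_satisfy_identities(self):
        for name, row in REFERENCE_COMBINATION_ROWS.items():
            f = np.array(row["frequency"])
            e = np.array(row["effect"])
            assert abs(f.sum() - 1.0) < 2e-3, name
            assert abs((f * e).sum()) < 2e-3, name

    @pytest.mark.parametrize("effect", EFFECTS)
    def test_identities_hold_on_simulated_data(self, effect, rng):
        n = 500
        g1 = rng.binomial(2, 0.35, size=n).astype(np.int8)
        g2 = rng.binomial(2, 0.45, size=n).astype(np.int8)
        y = rng.normal(size=n)
        t = combination_table(effect, y, g1, g2)
        occupied = t.frequency > 0
        assert t.frequency.sum() == pytest.approx(1.0, abs=1e-6)
        assert np.nansum(t.frequency[occupied] * t.effect[occupied]) == pytest.approx(0.0, abs=1e-6)
        assert len(t.classes) in (4, 6, 9)

    def test_dd_frequencies_match_crosstab(self, rng):
        n = 400
        g1 = rng.binomial(2, 0.3, size=n).astype(np.int8)
        g2 = rng.binomial(2, 0.4, size=n).astype(np.int8)
        t = combination_table("DD", rng.normal(size=n), g1, g2)
        ct = pd.crosstab(g1, g2).reindex(index=[0, 1, 2], columns=[0, 1, 2], fill_value=0)
        np.testing.assert_allclose(
            t.frequency, (ct.to_numpy() / n).ravel(), atol=1e-12)

    def test_gamete_frequencies_match_composite_count_oracle(self, rng):
        n = 300
        g1 = rng.binomial(2, 0.3, size=n)
        g2 = rng.binomial(2, 0.4, size=n)
        t = combination_table("AA", rng.normal(size=n), g1, g2)
        # brute-force composite counting, one individual at a time
        acc = np.zeros(4)
        for a, b in zip(g1, g2):
            pa, pb = a / 2.0, b / 2.0
            acc += 2 * np.array([pa * pb, pa * (1 - pb), (1 - pa) * pb, (1 - pa) * (1 - pb)])
        np.testing.assert_allclose(t.frequency, acc / acc.sum(), atol=1e-12)


class TestSubclassFilter:
    def test_small_cell_fails_with_name(self, rng):
        g1 = np.array([0] * 50 + [1] * 4).astype(np.int8)
        g2 = np.array([0] * 54).astype(np.int8)
        g2[:10] = 1
        t = combination_table("DD", rng.normal(size=54), g1, g2)
        res = subclass_filter(t, min_count=5)
        assert not res.passed
        assert any("-" in c for c in res.offending)

    def test_all_cells_supported_passes(self, rng):
        g1, g2 = balanced_pair(6)
        t = combination_table("DD", rng.normal(size=g1.size), g1, g2)
        assert subclass_filter(t, 5).passed

    def test_failure_rate_matches_recount_oracle(self, rng):
        fails_mine, fails_oracle = 0, 0
        for rep in range(200):
            r = np.random.default_rng(rep)
            n = 500
            g1 = r.binomial(2, 0.02, size=n).astype(np.int8)
            g2 = r.binomial(2, 0.3, size=n).astype(np.int8)
            t = combination_table("DD", r.normal(size=n), g1, g2)
            fails_mine += not subclass_filter(t, 5).passed
            counts = pd.crosstab(g1, g2).to_numpy().ravel()
            fails_oracle += bool(((counts > 0) & (counts < 5)).any())
        assert fails_mine == fails_oracle


class TestPairPipeline:
    def test_best_effect_attribution_on_planted_aa(self, rng):
        n = 3000
        g1 = rng.binomial(2, 0.3, size=n).astype(np.int8)
        g2 = rng.binomial(2, 0.3, size=n).astype(np.int8)
        y = rng.normal(size=n) + 0.4 * (g1 - 1.0) * (g2 - 1.0)
        r = analyse_pair(y, g1, g2, singleton_structure(n), 0.0, "s1", "s2")
        assert r.best_effect == "AA"
        assert abs(r.effects["AA"].estimate - 0.4) < 2 * r.effects["AA"].se
        assert r.combination is not None and r.combination.granularity == "gamete"

    def test_null_pair_p_values_behave_like_uniforms(self, family_dataset):
        gm, resid, structure, rho, _, _ = family_dataset
        r = analyse_pair(resid, gm.codes[:, 1], gm.codes[:, 2], structure, rho)
        for e in EFFECTS:
            if r.effects[e].p is not None:
                assert 0.0 < r.effects[e].p <= 1.0
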