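import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import special, stats

from methconsist.differential import (
    GeneMethylationMatrix,
    ZeroExpectedError,
    aggregate_genes,
    bh_adjust,
    call_dmg,
    chisq_test,
    fisher_region_test,
    fisher_test,
    poisson_wald_test,
    ratio_tests,
)
from methconsist.scoring import MethylationMatrix, score_sites

from _oracles import bh_oracle, fisher_two_sided_oracle
from conftest import manual_counts, manual_genome


def gene_matrix(data, samples):
    scores = pd.DataFrame(data, columns=samples)
    scores.index = [f"g{i}" for i in range(len(scores))]
    n = scores.notna().astype(int)
    return GeneMethylationMatrix(scores=scores, n_sites=n)


class TestAggregateGenes:
    def test_mean_of_site_levels(self):
        g = manual_genome([10, 20, 30, 500], [(0, 100)])
        levels = pd.DataFrame({"s1": [0.2, 0.4, 0.6, 0.9]}, index=g.sites.index)
        mm = MethylationMatrix(levels=levels, coverage=None, assay="WGBS")
        out = aggregate_genes(mm, g)
        assert out.scores.loc["g0", "s1"] == pytest.approx(0.4)
        assert out.n_sites.loc["g0", "s1"] == 3

    def test_all_sites_missing_gives_missing_gene(self):
        g = manual_genome([10, 20], [(0, 100)])
        levels = pd.DataFrame({"s1": [np.nan, np.nan]}, index=g.sites.index)
        mm = MethylationMatrix(levels=levels, coverage=None, assay="WGBS")
        out = aggregate_genes(mm, g)
        assert np.isnan(out.scores.loc["g0", "s1"])

    def test_mean_is_unweighted_by_coverage(self):
        # 0.0 at coverage 100 and 1.0 at coverage 1 average to 0.5:
        # the contract ignores coverage weights entirely
        g = manual_genome([10, 20], [(0, 100)])
        counts = manual_counts([(0, "t1", 0, 100), (1, "t1", 1, 0)])
        mm = score_sites(counts, min_cov=1)
        out = aggregate_genes(mm, g)
        assert out.scores.loc["g0", "t1"] == pytest.approx(0.5)

    def test_gene_without_sites_is_missing(self):
        g = manual_genome([10], [(0, 5), (50, 60)])
        levels = pd.DataFrame({"s1": [0.4]}, index=g.sites.index)
        mm = MethylationMatrix(levels=levels, coverage=None, assay="WGBS")
        out = aggregate_genes(mm, g)
        assert np.isnan(out.scores.loc["g1", "s1"])


class TestCallDMG:
    def test_fold_change_direction_and_flag(self):
        gm = gene_matrix(
            [[0.2, 0.3, 0.4, 0.6, 0.7, 0.8]],
            ["t1", "t2", "t3", "n1", "n2", "n3"],
        )
        groups = {s: ("tumor" if s.startswith("t") else "normal")
                  for s in gm.scores.columns}
        out = call_dmg(gm, groups, tau=0.15)
        row = out.loc["g0"]
        assert row["fold_change"] == pytest.approx(0.4)
        assert row["direction"] == "hypo"
        assert bool(row["is_dmg"])

    def test_equal_means_not_dmg(self):
        gm = gene_matrix([[0.5, 0.5, 0.5, 0.5]], ["t1", "t2", "n1", "n2"])
        groups = {"t1": "tumor", "t2": "tumor", "n1": "normal", "n2": "normal"}
        out = call_dmg(gm, groups)
        assert out.loc["g0", "fold_change"] == 0.0
        assert not out.loc["g0", "is_dmg"]
        assert pd.isna(out.loc["g0", "direction"])

    def test_all_missing_group_dropped(self):
        gm = gene_matrix(
            [[np.nan, np.nan, 0.5, 0.6], [0.1, 0.2, 0.5, 0.6]],
            ["t1", "t2", "n1", "n2"],
        )
        groups = {"t1": "tumor", "t2": "tumor", "n1": "normal", "n2": "normal"}
        out = call_dmg(gm, groups)
        assert "g0" not in out.index and "g1" in out.index

    def test_tau_validation(self):
        gm = gene_matrix([[0.5, 0.5]], ["t1", "n1"])
        with pytest.raises(ValueError):
            call_dmg(gm, {"t1": "tumor", "n1": "normal"}, tau=0.0)


class TestFisher:
    def test_diagonal_table(self):
        assert fisher_test([[5, 0], [0, 5]]).p_value == pytest.approx(2 / 252)

    def test_symmetric_table_is_null(self):
        assert fisher_test([[3, 3], [3, 3]]).p_value == pytest.approx(1.0)

    def test_empty_margin_flagged(self):
        res = fisher_test([[0, 0], [3, 4]])
        assert np.isnan(res.p_value) and "empty_margin" in res.flags

    @given(st.lists(st.integers(0, 12), min_size=4, max_size=4))
    @settings(max_examples=150, deadline=None, derandomize=True)
    def test_matches_enumeration_oracle(self, cells):
        a, b, c, d = cells
        if a + b == 0 or c + d == 0 or a + c == 0 or b + d == 0:
            return
        p = fisher_test([[a, b], [c, d]]).p_value
        assert p == pytest.approx(fisher_two_sided_oracle(a, b, c, d), abs=1e-12)

    def test_region_pooling(self, small_genome):
        from methconsist.simulate import simulate_counts

        from conftest import constant_truth

        ct = constant_truth(small_genome, 0.5, 2, 2)
        counts = simulate_counts(ct, small_genome, "WGBS", seed=4)
        gene = small_genome.genes.iloc[0]
        res = fisher_region_test(
            counts, (gene["chrom"], gene["start"], gene["end"]), small_genome
        )
        assert res.table.sum() == counts.counts.merge(
            small_genome.sites.loc[
                (small_genome.sites["pos"] >= gene["start"])
                & (small_genome.sites["pos"] < gene["end"])
                & (small_genome.sites["chrom"] == gene["chrom"])
            ].reset_index()[["site_id"]],
            on="site_id",
        )[["C", "T"]].to_numpy().sum()
        assert 0 <= res.p_value <= 1


class TestChisq:
    def test_homogeneous_table(self):
        res = chisq_test([[10, 10], [10, 10]])
        assert res.statistic == 0.0 and res.p_value == pytest.approx(1.0)

    def test_hand_computed_pearson(self):
        # 60*(20*20-10*10)^2 / 30^4 = 6.666..., df=1
        res = chisq_test([[20, 10], [10, 20]])
        assert res.statistic == pytest.approx(20 / 3, abs=1e-9)
        assert res.p_value == pytest.approx(
            float(stats.chi2.sf(20 / 3, 1)), abs=1e-9
        )

    def test_three_groups(self):
        res = chisq_test([[10, 10], [12, 8], [9, 11]])
        assert res.df == 2 and 0 <= res.p_value <= 1

    def test_zero_expected_redirects_to_fisher(self):
        with pytest.raises(ZeroExpectedError, match="Fisher"):
            chisq_test([[0, 10], [0, 20]])


class TestPoissonWald:
    def test_equal_rates(self):
        res = poisson_wald_test((50, 50), (500, 500))
        assert res.statistic == 0.0 and res.p_value == pytest.approx(1.0)

    def test_closed_form(self):
        # z = (ln 0.1 - ln 0.2) / sqrt(1/100 + 1/200)
        res = poisson_wald_test((100, 200), (1000, 1000))
        z = (np.log(0.1) - np.log(0.2)) / np.sqrt(1 / 100 + 1 / 200)
        assert res.statistic == pytest.approx(z, abs=1e-9)
        assert res.p_value == pytest.approx(2 * stats.norm.sf(abs(z)), abs=1e-12)

    def test_zero_count_continuity_correction(self):
        res = poisson_wald_test((0, 10), (100, 100))
        assert "continuity_correction" in res.flags
        assert 0 <= res.p_value <= 1

    def test_zero_exposure_rejected(self):
        with pytest.raises(ValueError):
            poisson_wald_test((1, 1), (0, 10))


class TestRatioTests:
    def test_identical_groups_null(self):
        res = ratio_tests([np.array([0.1, 0.2, 0.3]), np.array([0.1, 0.2, 0.3])])
        assert res.statistic == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_welch_hand_computation(self):
        # t = -0.5/sqrt(0.01/3 + 0.01/3), Welch-Satterthwaite df = 4
        res = ratio_tests(
            [np.array([0.1, 0.2, 0.3]), np.array([0.6, 0.7, 0.8])], "welch_t"
        )
        t = -0.5 / np.sqrt(0.01 / 3 + 0.01 / 3)
        p = 2 * float(special.stdtr(4.0, -abs(t)))
        assert res.statistic == pytest.approx(t, abs=1e-9)
        assert res.df == pytest.approx(4.0, abs=1e-9)
        assert res.p_value == pytest.approx(p, abs=1e-9)

    def test_anova_two_groups_equals_pooled_t_squared(self):
        rng = np.random.default_rng(12)
        for _ in range(20):
            a, b = rng.normal(size=5), rng.normal(0.3, size=6)
            res = ratio_tests([a, b], "anova")
            t, p = stats.ttest_ind(a, b, equal_var=True)
            assert res.statistic == pytest.approx(t**2, rel=1e-9)
            assert res.p_value == pytest.approx(p, rel=1e-9)

    def test_degenerate_zero_variance(self):
        eq = ratio_tests([np.array([0.5, 0.5]), np.array([0.5, 0.5])])
        assert eq.p_value == 1.0 and "degenerate" in eq.flags
        ne = ratio_tests([np.array([0.1, 0.1]), np.array([0.9, 0.9])])
        assert ne.p_value == 0.0 and "degenerate" in ne.flags

    def test_too_few_samples(self):
        with pytest.raises(ValueError):
            ratio_tests([np.array([0.1]), np.array([0.2, 0.3])])


class TestBHAdjust:
    def test_step_up_hand_case(self):
        # m*p/i = (.04, .04, .04, .04) -> running min from the top is .04
        np.testing.assert_allclose(
            bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04] * 4, atol=1e-12
        )

    def test_single_p_unchanged(self):
        assert bh_adjust([0.37])[0] == pytest.approx(0.37)

    def test_empty(self):
        assert bh_adjust([]).size == 0

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=40))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_matches_oracle_and_properties(self, pvals):
        q = bh_adjust(pvals)
        np.testing.assert_allclose(q, bh_oracle(pvals), atol=1e-12)
        assert (q >= np.asarray(pvals) - 1e-12).all()
        order = np.argsort(pvals)
        assert (np.diff(q[order]) >= -1e-12).all()  # monotone in p-rank

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])
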