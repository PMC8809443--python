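import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from _oracles import wilcoxon_exact_enumeration
from redking.stats import (
    InsufficientDataError,
    background_consistency,
    build_summary_table,
    lrt,
    median_ci,
    normality_check,
    selection_screen,
    significance_stars,
    wilcoxon_signed_rank,
)
from redking.trees import LICHENIZED, NON_LICHENIZED


class TestWilcoxon:
    def test_five_positive_differences_exact(self):
        res = wilcoxon_signed_rank(np.array([1.0, 2, 3, 4, 5]), np.zeros(5))
        assert res.p_two_sided == pytest.approx(0.0625)
        assert res.mode == "exact"
        assert res.W == 0.0

    def test_identical_vectors_degenerate(self):
        x = np.arange(8.0)
        res = wilcoxon_signed_rank(x, x)
        assert res.p_two_sided == 1.0
        assert res.n_zero_diffs == 8
        assert res.mode == "degenerate"

    def test_single_nonzero_difference_insufficient(self):
        with pytest.raises(InsufficientDataError):
            wilcoxon_signed_rank(np.array([1.0, 0, 0]), np.zeros(3))

    @pytest.mark.parametrize("seed", range(8))
    def test_exact_p_matches_sign_vector_enumeration(self, seed):
        # random data with ties and zeros, n <= 10
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 11))
        d = rng.integers(-3, 4, n).astype(float)
        if np.count_nonzero(d) < 2:
            d[:2] = [1.0, -2.0]
        res = wilcoxon_signed_rank(d, np.zeros(n))
        assert res.p_two_sided == pytest.approx(wilcoxon_exact_enumeration(d), abs=1e-12)

    def test_matches_scipy_exact_without_ties(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=12)
        ref = sps.wilcoxon(x, mode="exact", alternative="two-sided")
        res = wilcoxon_signed_rank(x, np.zeros(12))
        assert res.p_two_sided == pytest.approx(ref.pvalue, abs=1e-12)

    def test_exact_and_normal_agree_at_crossover(self):
        rng = np.random.default_rng(4)
        for _ in range(10):
            x = rng.normal(0.2, 1.0, 25)
            exact = wilcoxon_signed_rank(x, np.zeros(25), exact_threshold=25)
            approx = wilcoxon_signed_rank(x, np.zeros(25), exact_threshold=0)
            assert approx.mode == "normal-approx"
            # the continuity-corrected normal approximation tracks the exact
            # p to ~1e-2 at n=25 (largest gaps occur at mid-range p)
            assert abs(exact.p_two_sided - approx.p_two_sided) < 0.01

    def test_type_one_error_calibration(self):
        rng = np.random.default_rng(5)
        rejections = 0
        n_reps = 400
        for _ in range(n_reps):
            d = rng.normal(0, 1, 40)
            if wilcoxon_signed_rank(d, np.zeros(40)).p_two_sided < 0.05:
                rejections += 1
        rate = rejections / n_reps
        se = np.sqrt(0.05 * 0.95 / n_reps)
        assert abs(rate - 0.05) < 3 * se


class TestMedianCI:
    def test_order_statistic_structure(self):
        vals = np.arange(1.0, 12.0)
        ci = median_ci(vals)
        assert ci.median == 6.0
        assert ci.ci_low in vals and ci.ci_high in vals
        assert ci.ci_low <= ci.median <= ci.ci_high

    def test_rank_pair_matches_binomial_oracle(self):
        n = 25
        vals = np.sort(np.random.default_rng(0).normal(size=n))
        ci = median_ci(vals)
        # oracle: smallest symmetric k with P(k <= B <= n-k) >= 0.95
        best = None
        for k in range(n // 2, 0, -1):
            cover = sps.binom.cdf(n - k, n, 0.5) - sps.binom.cdf(k - 1, n, 0.5)
            if cover >= 0.95:
                best = k
                break
        assert ci.ci_low == vals[best - 1] and ci.ci_high == vals[n - best]

    def test_coverage_on_lognormal(self):
        rng = np.random.default_rng(1)
        true_median = np.exp(0.0)
        hits = 0
        n_reps = 1000
        for _ in range(n_reps):
            sample = rng.lognormal(0.0, 1.0, 100)
            ci = median_ci(sample)
            hits += int(ci.ci_low <= true_median <= ci.ci_high)
        assert hits / n_reps >= 0.95 - 2 * np.sqrt(0.05 * 0.95 / n_reps)

    def test_small_sample_rejected(self):
        with pytest.raises(InsufficientDataError):
            median_ci([1.0, 2.0, 3.0])


class TestLRT:
    def test_chi_square_reference_point(self):
        res = lrt(-1000.0, -1000.0 + 3.841 / 2, df=1)
        assert res.p == pytest.approx(0.05, abs=5e-4)

    def test_equal_likelihoods(self):
        res = lrt(-10.0, -10.0, df=2)
        assert res.p == 1.0 and res.statistic == 0.0

    def test_small_violation_clamped_large_raises(self):
        res = lrt(-10.0, -10.00001, df=1)
        assert res.statistic == 0.0 and res.clamped
        with pytest.raises(ValueError, match="refit"):
            lrt(-10.0, -11.0, df=1)


class TestNormalityCheck:
    def test_calibration_on_normal_samples(self):
        rng = np.random.default_rng(6)
        rejections = sum(
            normality_check(rng.normal(size=500))[1] < 0.05 for _ in range(300)
        )
        rate = rejections / 300
        assert abs(rate - 0.05) < 3 * np.sqrt(0.05 * 0.95 / 300)

    def test_power_on_lognormal(self):
        rng = np.random.default_rng(7)
        rejections = sum(
            normality_check(rng.lognormal(0, 1, 500))[1] < 0.05 for _ in range(50)
        )
        assert rejections / 50 > 0.5

    def test_degenerate_input(self):
        with pytest.raises(InsufficientDataError):
            normality_check(np.ones(100))


class TestSelectionScreen:
    def _table(self):
        rows = []
        # gene g1 significant for lichenized only, omega2 > 1
        rows.append(dict(gene_id="g1", foreground=LICHENIZED, lnL_null=-100.0,
                         lnL_alt=-90.0, omega2=4.0))
        rows.append(dict(gene_id="g1", foreground=NON_LICHENIZED, lnL_null=-100.0,
                         lnL_alt=-99.9, omega2=1.0))
        # gene g2 significant for both foregrounds
        rows.append(dict(gene_id="g2", foreground=LICHENIZED, lnL_null=-100.0,
                         lnL_alt=-95.0, omega2=1.0005))
        rows.append(dict(gene_id="g2", foreground=NON_LICHENIZED, lnL_null=-100.0,
                         lnL_alt=-95.0, omega2=2.0))
        return pd.DataFrame(rows)

    def test_classification_and_exclusivity(self):
        out = selection_screen(self._table())
        g1l = out[(out.gene_id == "g1") & (out.foreground == LICHENIZED)].iloc[0]
        assert g1l.significant and g1l.exclusive
        assert g1l.classification == "positive_sites"
        g2l = out[(out.gene_id == "g2") & (out.foreground == LICHENIZED)].iloc[0]
        assert g2l.significant and not g2l.exclusive
        assert g2l.classification == "neutral_boundary"

    def test_missing_columns_rejected(self):
        with pytest.raises(ValueError, match="missing columns"):
            selection_screen(pd.DataFrame({"gene_id": []}))


class TestBackgroundConsistency:
    def test_identical_and_disjoint(self):
        assert background_consistency(["a", "b"], ["a", "b"])["jaccard"] == 1.0
        assert background_consistency(["a"], ["b"])["jaccard"] == 0.0

    def test_both_empty_undefined(self):
        assert background_consistency([], [])["defined"] is False

    def test_matches_analytic_expectation_under_independence(self):
        # shared true positives + independent false positives
        rng = np.random.default_rng(8)
        genes = [f"g{i}" for i in range(2000)]
        true_pos = set(genes[:40])
        jaccards = []
        for _ in range(60):
            fp_a = {g for g in genes[40:] if rng.random() < 0.05}
            fp_b = {g for g in genes[40:] if rng.random() < 0.05}
            res = background_consistency(true_pos | fp_a, true_pos | fp_b)
            jaccards.append(res["jaccard"])
        # E|A∩B| ≈ 40 + 1960*0.0025;  E|A∪B| ≈ 40 + 1960*(2*.05 - .0025)
        expected = (40 + 1960 * 0.0025) / (40 + 1960 * (0.1 - 0.0025))
        assert np.mean(jaccards) == pytest.approx(expected, rel=0.1)


class TestSummaryTable:
    @pytest.mark.parametrize("p,stars", [(0.4, ""), (0.04, "*"), (0.004, "**"),
                                          (4e-4, "***"), (4e-5, "****")])
    def test_star_mapping(self, p, stars):
        assert significance_stars(p) == stars

    def test_table_rows_and_stars(self):
        rng = np.random.default_rng(9)
        n = 60
        non = rng.lognormal(-2, 0.3, n)
        tables = {
            "nucleotide rate": pd.DataFrame({
                "gene_id": [f"g{i}" for i in range(n)],
                f"rate_{LICHENIZED}": non * 0.7,
                f"rate_{NON_LICHENIZED}": non,
            }),
            "missing measure": pd.DataFrame(columns=["gene_id"]),
        }
        table = build_summary_table(tables)
        row = table[table.measure == "nucleotide rate"].iloc[0]
        assert row.stars == "****"
        assert row.percent_faster == 0.0
        na_row = table[table.measure == "missing measure"].iloc[0]
        assert na_row.lichenized == "NA"
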