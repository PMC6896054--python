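import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from neofit.config import RunConfig
from neofit.peptides import SomaticVariant
from neofit.stats import (
    GrooveAnnotation,
    bonferroni,
    compare_groups,
    expression_outlier_check,
    flag_groove_mutations,
    ols_slope_ci,
    spearman_rho,
    wilcoxon_rank_sum,
)


def enumeration_oracle(x, y):
    """Two-sided rank-sum p by brute enumeration of group assignments."""
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    nx = len(x)
    w_obs = ranks[:nx].sum()
    sums = [sum(c) for c in itertools.combinations(ranks, nx)]
    lo = sum(s <= w_obs + 1e-9 for s in sums) / len(sums)
    hi = sum(s >= w_obs - 1e-9 for s in sums) / len(sums)
    return min(1.0, 2 * min(lo, hi))


class TestWilcoxon:
    def test_textbook_extreme_case(self):
        w, p = wilcoxon_rank_sum([1, 2], [3, 4], mode="exact")
        assert w == 3.0
        assert p == pytest.approx(1 / 3)

    def test_interleaved_case_matches_enumeration(self):
        _, p = wilcoxon_rank_sum([1, 3], [2, 4], mode="exact")
        assert p == pytest.approx(enumeration_oracle([1, 3], [2, 4]))
        assert p == pytest.approx(2 / 3)

    def test_group_swap_symmetry(self):
        rng = np.random.default_rng(5)
        x, y = rng.normal(size=4), rng.normal(size=5)
        _, p1 = wilcoxon_rank_sum(x, y, mode="exact")
        _, p2 = wilcoxon_rank_sum(y, x, mode="exact")
        assert p1 == pytest.approx(p2)
        _, p1n = wilcoxon_rank_sum(x, y, mode="normal")
        _, p2n = wilcoxon_rank_sum(y, x, mode="normal")
        assert p1n == pytest.approx(p2n)

    def test_exact_matches_enumeration_on_random_small_samples(self):
        rng = np.random.default_rng(1)
        for _ in range(100):
            nx = int(rng.integers(2, 6))
            ny = int(rng.integers(2, 11 - nx))
            # mix of continuous and tied data
            if rng.random() < 0.5:
                x, y = rng.normal(size=nx), rng.normal(size=ny)
            else:
                x = rng.integers(0, 4, size=nx).astype(float)
                y = rng.integers(0, 4, size=ny).astype(float)
            _, p = wilcoxon_rank_sum(x, y, mode="exact")
            assert p == pytest.approx(enumeration_oracle(x, y))

    def test_exact_matches_scipy_on_tie_free_data(self):
        rng = np.random.default_rng(2)
        for _ in range(50):
            x, y = rng.normal(size=3), rng.normal(size=4)
            _, p = wilcoxon_rank_sum(x, y, mode="exact")
            assert p == pytest.approx(sps.mannwhitneyu(x, y, method="exact").pvalue)

    def test_normal_mode_matches_classical_z_without_continuity(self):
        # 3 vs 4 with perfect separation: z = 6/sqrt(8), p = 0.0339
        _, p = wilcoxon_rank_sum([10.0, 11.0, 12.0], [1.0, 2.0, 3.0, 4.0], mode="normal")
        z = 6 / math.sqrt(8)
        assert p == pytest.approx(2 * sps.norm.sf(z))
        assert p == pytest.approx(0.0339, abs=5e-4)

    def test_auto_switches_on_size_and_ties(self):
        x = list(range(6))
        y = [v + 0.5 for v in range(7)]  # combined 13 > 12 -> normal
        _, p_auto = wilcoxon_rank_sum(x, y, mode="auto")
        _, p_norm = wilcoxon_rank_sum(x, y, mode="normal")
        assert p_auto == p_norm
        _, p_small = wilcoxon_rank_sum([1, 2], [3, 4], mode="auto")
        assert p_small == pytest.approx(1 / 3)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_rank_sum([], [1.0])


class TestSpearman:
    def test_perfect_monotone(self):
        assert spearman_rho([1, 2, 3, 4], [10, 20, 30, 40]) == pytest.approx(1.0)
        assert spearman_rho([1, 2, 3, 4], [4, 3, 2, 1]) == pytest.approx(-1.0)

    def test_closed_form_example(self):
        # 1 - 6*sum(d^2)/(n(n^2-1)) with sum(d^2) = 2
        assert spearman_rho([1, 2, 3, 4], [1, 3, 2, 4]) == pytest.approx(0.8)

    def test_constant_vector_returns_none(self):
        assert spearman_rho([1, 2, 3], [5, 5, 5]) is None

    def test_self_and_negated_correlation(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=20)
        assert spearman_rho(x, x) == pytest.approx(1.0)
        assert spearman_rho(x, -x) == pytest.approx(-1.0)


class TestOlsSlope:
    def test_exact_line_collapses_ci(self):
        x = [0.0, 1.0, 2.0, 3.0, 4.0]
        y = [2 * v + 1 for v in x]
        slope, lo, hi, _ = ols_slope_ci(x, y)
        assert slope == pytest.approx(2.0)
        assert lo == pytest.approx(2.0) and hi == pytest.approx(2.0)

    def test_matches_normal_equations_and_t_quantile(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=5)
        y = 1.5 * x + rng.normal(size=5)
        slope, lo, hi, p = ols_slope_ci(x, y)
        # closed-form normal equations
        xc, yc = x - x.mean(), y - y.mean()
        b = (xc * yc).sum() / (xc**2).sum()
        resid = y - (y.mean() + b * xc)
        se = math.sqrt((resid**2).sum() / 3 / (xc**2).sum())
        tq = sps.t.ppf(0.975, 3)
        assert slope == pytest.approx(b)
        assert lo == pytest.approx(b - tq * se) and hi == pytest.approx(b + tq * se)

    def test_constant_response_gives_zero_slope(self):
        slope, *_ = ols_slope_ci([1.0, 2.0, 3.0], [7.0, 7.0, 7.0])
        assert slope == pytest.approx(0.0)

    def test_constant_predictor_rejected(self):
        with pytest.raises(ValueError):
            ols_slope_ci([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestBonferroni:
    @pytest.mark.parametrize("pvals,expected", [
        ([0.01], [0.01]),
        ([0.01, 0.2], [0.02, 0.4]),
        ([0.5, 0.9], [1.0, 1.0]),
    ])
    def test_adjustment(self, pvals, expected):
        assert bonferroni(pvals) == pytest.approx(expected)

    def test_output_dominates_input_and_caps_at_one(self):
        rng = np.random.default_rng(6)
        p = rng.uniform(size=9).tolist()
        adj = bonferroni(p)
        assert all(a >= b for a, b in zip(adj, p))
        assert all(a <= 1.0 for a in adj)

    def test_domain_check(self):
        with pytest.raises(ValueError):
            bonferroni([1.5])


class TestGrooveAnnotation:
    ANN = [GrooveAnnotation(
        gene="HLA-A", chrom="chr6",
        exons={1: (100, 199), 2: (300, 399), 3: (500, 599), 4: (700, 799)},
    )]

    def _variant(self, pos, chrom="chr6"):
        return SomaticVariant(sample_id="S", chrom=chrom, pos=pos, variant_class="snv")

    def test_exon2_hit_is_coding_and_groove(self):
        out = flag_groove_mutations([self._variant(350)], self.ANN)
        assert bool(out.loc[0, "in_coding"]) and bool(out.loc[0, "in_groove"])

    def test_exon4_hit_is_coding_but_not_groove(self):
        out = flag_groove_mutations([self._variant(750)], self.ANN)
        assert bool(out.loc[0, "in_coding"]) and not bool(out.loc[0, "in_groove"])

    def test_intronic_position_is_neither(self):
        out = flag_groove_mutations([self._variant(250)], self.ANN)
        assert not bool(out.loc[0, "in_coding"])

    def test_groove_exons_must_be_exons(self):
        with pytest.raises(ValueError):
            GrooveAnnotation(gene="HLA-B", chrom="chr6", exons={1: (1, 10)}, groove_exons=(2,))


class TestExpressionOutlierCheck:
    def test_value_at_mean_is_within(self):
        assert expression_outlier_check(2.0, [1.0, 2.0, 3.0])

    def test_three_sd_away_is_outside(self):
        cohort = [1.0, 2.0, 3.0]  # mean 2, sample sd 1
        assert not expression_outlier_check(5.0, cohort)

    def test_half_sd_within_two_sd_band(self):
        assert expression_outlier_check(2.5, [1.0, 2.0, 3.0])


class TestCompareGroups:
    def _summaries(self, values_a, values_b):
        rows = []
        for g, vals in (("A", values_a), ("B", values_b)):
            for i, v in enumerate(vals):
                rows.append({
                    "sample_id": f"{g}{i}", "n_somatic_mutations": 100 + i,
                    "n_binding": 30 + i, "n_immunogenic": 10 + i, "n_stringent": 1,
                    "n_peptides_21mer": 10, "n_possible_9mers": 130,
                    "ratio_immunogenic_binding": 0.3, "ratio_stringent_binding": 0.03,
                    "mean_kd_mt": 200.0, "mean_amplitude": 0.8, "mean_recognition": 0.1,
                    "mean_fitness": 0.05, "max_fitness": v, "mean_adjusted_fitness": v / 10,
                    "max_adjusted_fitness": v, "eligible": True,
                })
        return pd.DataFrame(rows)

    def test_identical_groups_give_p_one_for_constant_metrics(self, run_config):
        df = self._summaries([1.0, 1.0, 1.0], [1.0, 1.0, 1.0])
        groups = dict(zip(df["sample_id"], ["A"] * 3 + ["B"] * 3))
        res = compare_groups(df, groups, run_config)
        row = res.metric_tests.set_index("metric").loc["max_adjusted_fitness"]
        assert row["p_value"] == pytest.approx(1.0)

    def test_result_invariant_to_sample_order(self, run_config):
        df = self._summaries([1.0, 2.0, 3.0], [0.5, 0.6, 0.7, 0.8])
        groups = dict(zip(df["sample_id"], ["A"] * 3 + ["B"] * 4))
        res1 = compare_groups(df, groups, run_config)
        res2 = compare_groups(df.iloc[::-1].reset_index(drop=True), groups, run_config)
        pd.testing.assert_frame_equal(res1.metric_tests, res2.metric_tests)

    def test_cell_score_family_gets_bonferroni(self, run_config):
        df = self._summaries([1.0, 2.0, 3.0], [0.5, 0.6, 0.7, 0.8])
        groups = dict(zip(df["sample_id"], ["A"] * 3 + ["B"] * 4))
        rng = np.random.default_rng(7)
        scores = pd.DataFrame(
            rng.uniform(size=(7, 9)),
            index=df["sample_id"],
            columns=[f"cell_{i}" for i in range(9)],
        )
        res = compare_groups(df, groups, run_config, cell_scores=scores)
        fam = res.regressions[res.regressions["family"] == "cell_scores"]
        assert len(fam) == 9
        assert fam["p_adjusted"].tolist() == pytest.approx(
            [min(1.0, 9 * p) for p in fam["p_value"]]
        )

    def test_too_few_eligible_yields_not_computed_rows(self, run_config):
        df = self._summaries([1.0, 2.0], [0.5])
        df.loc[df["sample_id"] == "B0", "eligible"] = False
        groups = dict(zip(df["sample_id"], ["A", "A", "B"]))
        res = compare_groups(df, groups, run_config)
        row = res.metric_tests.set_index("metric").loc["max_adjusted_fitness"]
        assert not row["computed"] and np.isnan(row["p_value"])

    def test_missing_group_label_is_an_error(self, run_config):
        df = self._summaries([1.0], [2.0])
        with pytest.raises(ValueError, match="without group"):
            compare_groups(df, {"A0": "A"}, run_config)
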