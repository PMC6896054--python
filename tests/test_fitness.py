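import numpy as np
import pandas as pd
import pytest

from neofit.config import RunConfig
from neofit.fitness import (
    classify,
    expression_fractions,
    fitness_cost,
    select_eligible_samples,
    summaries_to_frame,
    summarize_sample,
)


def make_records(rows):
    defaults = {
        "sample_id": "S1", "gene": "G", "transcript_id": "TX1", "protein_pos": 10,
        "window_start": 1, "mutant_9mer": "ACDEFGHIK", "wildtype_9mer": "ACDEFGHIL",
        "contains_mutation": True, "kd_mt_nM": 100.0, "kd_wt_nM": 100.0,
        "best_allele_mt": "A", "best_allele_wt": "A", "amplitude": 1.0,
        "is_binding": True, "recognition": 0.1, "fitness": 0.1,
        "is_immunogenic": True, "is_stringent": True,
        "rpkm": np.nan, "expression_fraction": np.nan, "adjusted_fitness": np.nan,
    }
    return pd.DataFrame([{**defaults, **r} for r in rows])


class TestFitnessCost:
    @pytest.mark.parametrize("a,r,f", [
        (5.0, 0.0, 0.0),   # zero recognition annihilates any amplitude
        (1.0, 0.5, 0.5),
        (2.5, 0.4, 1.0),
    ])
    def test_product(self, a, r, f):
        assert fitness_cost(a, r) == pytest.approx(f)

    def test_domain_checks(self):
        with pytest.raises(ValueError):
            fitness_cost(-1.0, 0.5)
        with pytest.raises(ValueError):
            fitness_cost(1.0, 1.0)


class TestClassify:
    def test_flag_hierarchy(self, run_config):
        records = make_records([
            {"kd_mt_nM": 100.0, "is_binding": True, "recognition": 0.0},
            {"kd_mt_nM": 100.0, "is_binding": True, "recognition": 0.009},
            {"kd_mt_nM": 100.0, "is_binding": True, "recognition": 0.5},
            {"kd_mt_nM": 600.0, "is_binding": False, "recognition": np.nan},
        ])
        out = classify(records, run_config)
        assert out["is_immunogenic"].tolist() == [False, True, True, False]
        assert out["is_stringent"].tolist() == [False, False, True, False]

    def test_stringent_boundary_is_inclusive(self, run_config):
        out = classify(make_records([{"recognition": 0.01}]), run_config)
        assert bool(out["is_stringent"].iloc[0])


class TestExpressionFractions:
    def test_singleton_record_gets_full_fraction(self):
        out = expression_fractions(make_records([{"fitness": 0.3}]), {"TX1": 7.0})
        assert out["expression_fraction"].iloc[0] == pytest.approx(1.0)
        assert out["adjusted_fitness"].iloc[0] == pytest.approx(0.3)

    def test_equal_rpkm_splits_evenly(self):
        recs = make_records([
            {"fitness": 0.1, "transcript_id": "TX1"},
            {"fitness": 0.2, "transcript_id": "TX2"},
        ])
        out = expression_fractions(recs, {"TX1": 5.0, "TX2": 5.0})
        assert out["expression_fraction"].tolist() == pytest.approx([0.5, 0.5])

    def test_hand_computed_fractions_and_adjustment(self):
        recs = make_records([
            {"fitness": 1.0, "amplitude": 2.0, "recognition": 0.5, "transcript_id": "TX1"},
            {"fitness": 2.0, "amplitude": 4.0, "recognition": 0.5, "transcript_id": "TX2"},
        ])
        out = expression_fractions(recs, {"TX1": 8.0, "TX2": 2.0})
        assert out["expression_fraction"].tolist() == pytest.approx([0.8, 0.2])
        assert out["adjusted_fitness"].tolist() == pytest.approx([0.8, 0.4])

    def test_zero_fitness_records_excluded_from_denominator(self):
        recs = make_records([
            {"fitness": 1.0, "transcript_id": "TX1"},
            {"fitness": 0.0, "transcript_id": "TX2", "recognition": 0.0,
             "is_immunogenic": False},
        ])
        out = expression_fractions(recs, {"TX1": 1.0, "TX2": 99.0})
        assert out["expression_fraction"].iloc[0] == pytest.approx(1.0)
        assert np.isnan(out["expression_fraction"].iloc[1])

    def test_all_zero_rpkm_leaves_adjustment_undefined(self):
        recs = make_records([{"fitness": 1.0}, {"fitness": 2.0}])
        out = expression_fractions(recs, {"TX1": 0.0})
        assert out["expression_fraction"].isna().all()

    def test_missing_transcript_counts_as_zero_rpkm(self):
        recs = make_records([
            {"fitness": 1.0, "transcript_id": "TX1"},
            {"fitness": 1.0, "transcript_id": "UNSEEN"},
        ])
        out = expression_fractions(recs, {"TX1": 4.0})
        assert out["expression_fraction"].tolist() == pytest.approx([1.0, 0.0])

    def test_fractions_sum_to_one_within_tolerance(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            n = int(rng.integers(2, 30))
            recs = make_records([
                {"fitness": float(rng.uniform(0.01, 5)), "transcript_id": f"T{i}"}
                for i in range(n)
            ])
            rpkm = {f"T{i}": float(rng.lognormal(1, 1)) for i in range(n)}
            out = expression_fractions(recs, rpkm)
            assert out["expression_fraction"].sum() == pytest.approx(1.0, abs=1e-9)


class TestSummaries:
    def test_degenerate_sample_without_binding_records(self, run_config):
        recs = make_records([
            {"is_binding": False, "recognition": np.nan, "fitness": np.nan,
             "is_immunogenic": False, "is_stringent": False},
        ])
        s = summarize_sample(recs, n_somatic_mutations=5, n_peptides_21mer=1, config=run_config)
        assert s.n_binding == 0
        assert s.ratio_immunogenic_binding is None
        assert s.mean_fitness is None and s.max_fitness is None

    def test_ratio_example(self, run_config):
        rows = [{"is_immunogenic": False, "is_stringent": False, "recognition": 0.0,
                 "fitness": 0.0}] * 3 + [{}]
        s = summarize_sample(make_records(rows), 10, 2, run_config)
        assert s.n_binding == 4 and s.n_immunogenic == 1
        assert s.ratio_immunogenic_binding == pytest.approx(0.25)

    def test_three_record_sample_matches_brute_force_reduction(self, run_config):
        recs = make_records([
            {"kd_mt_nM": 50.0, "amplitude": 2.0, "recognition": 0.5, "fitness": 1.0,
             "transcript_id": "T1"},
            {"kd_mt_nM": 150.0, "amplitude": 0.5, "recognition": 0.2, "fitness": 0.1,
             "transcript_id": "T2", "is_stringent": True},
            {"kd_mt_nM": 450.0, "amplitude": 1.0, "recognition": 0.004, "fitness": 0.004,
             "transcript_id": "T3", "is_stringent": False},
        ])
        recs = expression_fractions(recs, {"T1": 2.0, "T2": 1.0, "T3": 1.0})
        s = summarize_sample(recs, 7, 3, run_config)
        # independent reduction by hand
        assert s.mean_kd_mt == pytest.approx((50 + 150 + 450) / 3)
        assert s.mean_amplitude == pytest.approx((2.0 + 0.5 + 1.0) / 3)
        assert s.mean_recognition == pytest.approx((0.5 + 0.2 + 0.004) / 3)
        assert s.mean_fitness == pytest.approx((1.0 + 0.1 + 0.004) / 3)
        assert s.max_fitness == pytest.approx(1.0)
        fr = [2 / 4, 1 / 4, 1 / 4]
        adj = [1.0 * fr[0], 0.1 * fr[1], 0.004 * fr[2]]
        assert s.mean_adjusted_fitness == pytest.approx(sum(adj) / 3)
        assert s.max_adjusted_fitness == pytest.approx(max(adj))
        assert s.n_stringent == 2

    def test_reduction_is_permutation_invariant(self, run_config):
        recs = make_records([
            {"kd_mt_nM": float(k), "fitness": f, "recognition": f}
            for k, f in [(10, 0.5), (20, 0.1), (30, 0.9), (40, 0.2)]
        ])
        s1 = summarize_sample(recs, 4, 4, run_config)
        s2 = summarize_sample(recs.iloc[::-1].reset_index(drop=True), 4, 4, run_config)
        for key, v1 in vars(s1).items():
            v2 = vars(s2)[key]
            if isinstance(v1, float):
                assert v1 == pytest.approx(v2, rel=1e-12)
            else:
                assert v1 == v2

    def test_averaging_set_switch(self):
        cfg_b = RunConfig(averaging_set="binding")
        recs = make_records([
            {"kd_mt_nM": 100.0, "recognition": 0.0, "fitness": 0.0,
             "is_immunogenic": False, "is_stringent": False},
            {"kd_mt_nM": 300.0},
        ])
        s = summarize_sample(recs, 2, 1, cfg_b)
        assert s.mean_kd_mt == pytest.approx(200.0)
        s_imm = summarize_sample(recs, 2, 1, RunConfig())
        assert s_imm.mean_kd_mt == pytest.approx(300.0)


class TestEligibility:
    def _summaries(self, counts, max_f=None):
        rows = []
        for i, c in enumerate(counts):
            rows.append({
                "sample_id": f"S{i}", "n_somatic_mutations": 10, "n_peptides_21mer": 5,
                "n_possible_9mers": 50, "n_binding": max(c, 1), "n_immunogenic": c,
                "n_stringent": 0, "ratio_immunogenic_binding": None,
                "ratio_stringent_binding": None, "mean_kd_mt": None,
                "mean_amplitude": None, "mean_recognition": None, "mean_fitness": None,
                "max_fitness": None if max_f is None else max_f[i],
                "mean_adjusted_fitness": None, "max_adjusted_fitness": None,
                "eligible": False,
            })
        return pd.DataFrame(rows)

    def test_more_than_one_immunogenic_required(self, run_config):
        out = select_eligible_samples(self._summaries([0, 1, 2, 5]), run_config)
        assert out["eligible"].tolist() == [False, False, True, True]

    def test_magnitude_outlier_rule_off_by_default(self, run_config):
        out = select_eligible_samples(
            self._summaries([5, 5, 5], max_f=[1.0, 1.2, 0.001]), run_config
        )
        assert out["eligible"].all()

    def test_magnitude_outlier_dropped_when_enabled(self):
        cfg = RunConfig(drop_magnitude_outliers=True)
        out = select_eligible_samples(
            self._summaries([5, 5, 5], max_f=[1.0, 1.2, 0.001]), cfg
        )
        assert out["eligible"].tolist() == [True, True, False]


def test_summaries_to_frame_keeps_column_contract(run_config):
    s = summarize_sample(make_records([{}]), 1, 1, run_config)
    frame = summaries_to_frame([s])
    assert frame.loc[0, "sample_id"] == "S1"
    assert frame.loc[0, "n_possible_9mers"] == 1
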