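import json
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from svmorph import (
    ClassificationReport,
    accuracy_percent,
    binomial_pvalue,
    generate_cohort,
    outer_roc,
    region_summary,
    roc_points,
    run_outer_loocv,
    summarize,
    SyntheticConfig,
    write_report_files,
)
from svmorph.errors import ValidationError
from svmorph.reporting import p_value_band

from oracles import binomial_tail, pair_counting_auc


class TestAccuracyPercent:
    @pytest.mark.parametrize("nc, nt, expected", [
        (37, 39, 94.87),
        (0, 10, 0.0),
        (10, 10, 100.0),
    ])
    def test_examples(self, nc, nt, expected):
        assert accuracy_percent(nc, nt) == expected

    def test_zero_total_rejected(self):
        with pytest.raises(ValidationError):
            accuracy_percent(0, 0)


class TestBinomialPvalue:
    def test_perfect_score_closed_form(self):
        assert binomial_pvalue(39, 39, 0.5) == 2.0**-39

    def test_exact_combinatorial_tail(self):
        expected = (math.comb(39, 37) + math.comb(39, 38) + math.comb(39, 39)) / 2**39
        assert binomial_pvalue(37, 39, 0.5) == pytest.approx(expected, rel=1e-15)
        assert binomial_pvalue(37, 39, 0.5) <= 0.001

    @given(
        n=st.integers(1, 60),
        k_frac=st.floats(0, 1),
        p=st.floats(0.05, 0.95),
    )
    @settings(max_examples=60, deadline=None)
    def test_tail_complement_and_scipy_agreement(self, n, k_frac, p):
        k = int(round(k_frac * n))
        mine = binomial_pvalue(k, n, p)
        assert mine == pytest.approx(float(stats.binom.sf(k - 1, n, p)), rel=1e-9)
        # exact complement against the lower tail
        lower = float(stats.binom.cdf(k - 1, n, p))
        assert mine + lower == pytest.approx(1.0, abs=1e-12)

    def test_rational_arithmetic_oracle(self):
        assert binomial_pvalue(7, 10, 0.5) == pytest.approx(
            float(binomial_tail(7, 10, 0.5)), rel=1e-15
        )

    def test_monotone_in_n_correct(self):
        vals = [binomial_pvalue(k, 20, 0.5) for k in range(21)]
        assert all(a >= b for a, b in zip(vals, vals[1:]))

    def test_invalid_chance_rejected(self):
        with pytest.raises(ValidationError):
            binomial_pvalue(5, 10, 1.0)

    def test_banding(self):
        assert p_value_band(1.4e-9) == "p<0.001"
        assert p_value_band(0.004) == "p<0.01"
        assert p_value_band(0.2) == "p=0.200"


class TestRocPoints:
    def test_perfect_separation(self):
        roc = roc_points([1, 2, 3, 10, 11, 12], [-1, -1, -1, 1, 1, 1])
        assert roc.auc == 1.0
        assert roc.points[0] == (0.0, 0.0) and roc.points[-1] == (1.0, 1.0)

    def test_inverted_labels_complement(self):
        roc = roc_points([1, 2, 3, 10, 11, 12], [1, 1, 1, -1, -1, -1])
        assert roc.auc == 0.0

    def test_pair_counting_example(self):
        roc = roc_points([1, 2, 3, 4], [-1, 1, -1, 1])
        assert roc.auc == pytest.approx(0.75)

    def test_single_class_rejected(self):
        with pytest.raises(ValidationError):
            roc_points([1.0, 2.0], [1, 1])

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=40, deadline=None)
    def test_auc_equals_concordant_pair_statistic(self, seed):
        rng = np.random.default_rng(seed)
        n = rng.integers(4, 20)
        labels = np.r_[np.ones(2), -np.ones(2), np.sign(rng.normal(size=n - 4) + 1e-9)]
        scores = np.round(rng.normal(size=n), 1)  # rounding induces ties
        roc = roc_points(scores, labels)
        assert roc.auc == pytest.approx(pair_counting_auc(scores, labels), abs=1e-12)

    def test_auc_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(4)
        scores = rng.normal(size=12)
        labels = np.r_[np.ones(6), -np.ones(6)]
        a1 = roc_points(scores, labels).auc
        a2 = roc_points(np.exp(3 * scores) + 7, labels).auc
        assert a1 == pytest.approx(a2)


class TestRegionSummary:
    def test_five_number_summary_linear_interpolation(self, tiny_table):
        tiny_table.X[:4, 1] = [1.0, 2.0, 4.0, 5.0]
        tiny_table.X[:4, 0] = [1.0, 2.0, 3.0, 4.0]
        df = region_summary(tiny_table, ["rA"])
        row = df[(df.region == "rA") & (df.group == "meditator")].iloc[0]
        assert row["median"] == 2.5 and row["q1"] == 1.75 and row["q3"] == 3.25
        assert row["min"] == 1.0 and row["max"] == 4.0

    def test_identical_distributions_auc_near_half(self):
        cfg = SyntheticConfig(n_group_pos=40, n_group_neg=40, n_regions=4,
                              planted_regions=[], effect_size=0.0, seed=2)
        df = region_summary(generate_cohort(cfg), ["region_000"])
        assert 0.3 <= df["auc"].iloc[0] <= 0.7

    def test_planted_region_auc_high(self):
        hits = 0
        for seed in range(10):
            cfg = SyntheticConfig(n_group_pos=20, n_group_neg=20, n_regions=4,
                                  planted_regions=[1], effect_size=2.0,
                                  beta_age_fraction=0.0, beta_sex_fraction=0.0,
                                  seed=seed)
            df = region_summary(generate_cohort(cfg), ["region_001"])
            hits += df["auc"].iloc[0] > 0.8
        assert hits >= 9

    def test_unknown_region_rejected(self, tiny_table):
        with pytest.raises(ValidationError):
            region_summary(tiny_table, ["nope"])


class TestReportFiles:
    def test_report_round_trips_and_roc_written(self, tmp_path, tiny_table):
        res = run_outer_loocv(tiny_table)
        report = write_report_files(tmp_path, res, tiny_table)
        back = ClassificationReport.from_json(tmp_path / "report.json")
        assert back.to_dict() == report.to_dict()
        assert (tmp_path / "roc.csv").exists()
        assert (tmp_path / "selection_frequency.csv").exists()
        assert (tmp_path / "region_summary.csv").exists()
        data = json.loads((tmp_path / "report.json").read_text())
        assert data["n_total"] == tiny_table.n_subjects
        assert data["accuracy"] == pytest.approx(res.accuracy)

    def test_summarize_consistency(self, tiny_table):
        res = run_outer_loocv(tiny_table)
        rep = summarize(res, chance=0.5)
        assert rep.accuracy == res.n_correct / res.n_total
        assert rep.p_value == binomial_pvalue(res.n_correct, res.n_total, 0.5)
        roc = outer_roc(res)
        assert 0.0 <= roc.auc <= 1.0
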