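import itertools
import math
import statistics as pystats
from fractions import Fraction

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from tetermi.formats_io import DitagRecord, GeneModel, GenomicInterval
from tetermi.gene_annotation import TTSRecord
from tetermi.statistics import (
    cell_type_specificity,
    compare_utilization_groups,
    count_terminated_passing,
    extrapolate_total,
    fit_log_trend,
    observed_expected_test,
    orientation_bias_test,
    predict_log_trend,
    rarefaction,
    specificity_eligible,
    transcribed_and_active,
    utilization,
)
from tetermi.tts_discovery import cluster_3prime_ends


class TestCountTerminatedPassing:
    def _setup(self, plus_gene, three_ends):
        (cl,) = cluster_3prime_ends([("chr1", 5000, "+")] * 3 + [("chr1", 5010, "+")])
        rec = TTSRecord(cluster=cl, gene=plus_gene.id, location_class="internal")
        ditags = [
            DitagRecord(("chr1", plus_gene.annotated_tss, "+"), ("chr1", t, "+"), "A")
            for t in three_ends
        ]
        return rec, ditags

    def test_direct_count(self, plus_gene):
        rec, ditags = self._setup(plus_gene, [5001] * 3 + [8000] * 7)
        assert count_terminated_passing(rec, ditags, "A", plus_gene) == (3, 7)

    def test_upstream_enders_count_in_neither(self, plus_gene):
        rec, ditags = self._setup(plus_gene, [3000] * 10)
        assert count_terminated_passing(rec, ditags, "A", plus_gene) == (0, 0)

    def test_five_prime_must_be_upstream_of_cluster(self, plus_gene):
        (cl,) = cluster_3prime_ends([("chr1", 5000, "+")])
        rec = TTSRecord(cluster=cl, gene=plus_gene.id, location_class="internal")
        ditags = [DitagRecord(("chr1", 6000, "+"), ("chr1", 8000, "+"), "A")]
        assert count_terminated_passing(rec, ditags, "A", plus_gene) == (0, 0)


class TestUtilization:
    @pytest.mark.parametrize("rt,rp,expected", [(10, 0, 1.0), (0, 7, 0.0), (3, 9, 0.25)])
    def test_formula(self, rt, rp, expected):
        assert utilization(rt, rp) == expected

    def test_zero_denominator_is_undefined_not_zero(self):
        assert utilization(0, 0) is None

    def test_matches_exact_rational_oracle_on_random_inputs(self):
        rng = np.random.default_rng(3)
        for _ in range(10_000):
            rt, rp = int(rng.integers(0, 1000)), int(rng.integers(0, 1000))
            if rt + rp == 0:
                continue
            assert abs(utilization(rt, rp) - float(Fraction(rt, rt + rp))) < 1e-12


class TestTranscribedAndActive:
    def test_hundred_distinct_regions_give_seventyfive_active(self):
        counts = pd.DataFrame({"A": np.arange(100, 200.0)}, index=range(100))
        transcribed, active = transcribed_and_active(counts)
        assert transcribed["A"].all()
        assert active["A"].sum() == 75

    def test_below_threshold_is_neither(self):
        counts = pd.DataFrame({"A": [19.0, 25.0]})
        transcribed, active = transcribed_and_active(counts)
        assert not transcribed.loc[0, "A"] and not active.loc[0, "A"]
        assert transcribed.loc[1, "A"] and active.loc[1, "A"]

    def test_all_equal_counts_all_active(self):
        counts = pd.DataFrame({"A": [30.0] * 10})
        _, active = transcribed_and_active(counts)
        assert active["A"].all()


class TestSpecificity:
    @pytest.mark.parametrize(
        "utils,expected",
        [((0.8, 0.8, 0.8), 0.0), ((0.9, 0.0, 0.0), 1.0), ((0.6, 0.3, 0.3), 0.5)],
    )
    def test_worked_examples(self, utils, expected):
        assert cell_type_specificity(utils) == pytest.approx(expected)

    def test_matches_closed_form_oracle_on_random_inputs(self):
        # independent algebra: spec = (C*max - sum) / ((C-1) * max)
        rng = np.random.default_rng(4)
        for _ in range(10_000):
            c = int(rng.integers(2, 9))
            utils = rng.uniform(0.01, 1.0, size=c)
            expected = (c * utils.max() - utils.sum()) / ((c - 1) * utils.max())
            assert abs(cell_type_specificity(utils) - expected) < 1e-12

    @settings(max_examples=200, derandomize=True)
    @given(st.lists(st.floats(0.0, 1.0), min_size=2, max_size=8))
    def test_bounded_and_extremes(self, utils):
        if max(utils) <= 0:
            return
        s = cell_type_specificity(utils)
        assert -1e-12 <= s <= 1.0 + 1e-12
        if len(set(utils)) == 1:
            assert s == pytest.approx(0.0)
        if sum(u > 0 for u in utils) == 1:
            assert s == pytest.approx(1.0)

    def test_undefined_cases(self):
        with pytest.raises(ValueError):
            cell_type_specificity([0.5])
        with pytest.raises(ValueError):
            cell_type_specificity([0.0, 0.0])

    @pytest.mark.parametrize(
        "utils,n_active,expected",
        [
            ({"a": 0.5, "b": None}, 4, True),
            ({"a": 0.15, "b": 0.1}, 8, False),   # never reaches 20%
            ({"a": 0.9, "b": 0.9}, 2, False),    # active in too few cell types
        ],
    )
    def test_eligibility(self, utils, n_active, expected):
        active = {f"ct{i}": True for i in range(n_active)}
        assert specificity_eligible(utils, active) is expected


class TestChiSquared:
    def test_hand_computed_orientation_table(self):
        res = orientation_bias_test(90, 10, 50, 50)
        assert res.chi2 == pytest.approx(38.095, abs=5e-4)
        assert res.df == 1
        assert res.ratios == (9.0, 1.0)

    def test_proportional_table_gives_zero(self):
        assert orientation_bias_test(10, 10, 20, 20).chi2 == pytest.approx(0.0)

    def test_zero_marginal_is_undefined(self):
        res = orientation_bias_test(0, 0, 5, 5)
        assert not res.defined
        assert res.chi2 is None and res.p is None

    def test_matches_textbook_oracle_on_random_tables(self):
        rng = np.random.default_rng(9)
        for _ in range(1000):
            a, b, c, d = (int(x) for x in rng.integers(1, 500, size=4))
            res = orientation_bias_test(a, b, c, d)
            chi2, p, dof, _ = sps.chi2_contingency([[a, b], [c, d]], correction=False)
            assert dof == 1
            assert abs(res.chi2 - chi2) < 1e-9
            assert abs(res.p - p) < 1e-9

    def test_hand_computed_observed_expected(self):
        res = observed_expected_test(43, 100, 0.31)
        assert res.chi2 == pytest.approx(144 / 31 + 144 / 69, abs=1e-12)
        assert res.chi2 == pytest.approx(6.732, abs=5e-4)

    def test_observed_equal_expected_gives_zero(self):
        assert observed_expected_test(31, 100, 0.31).chi2 == pytest.approx(0.0)

    def test_degenerate_fraction_rejected(self):
        for frac in (0.0, 1.0):
            with pytest.raises(ValueError):
                observed_expected_test(10, 100, frac)

    def test_observed_expected_matches_scipy_chisquare(self):
        rng = np.random.default_rng(10)
        for _ in range(500):
            total = int(rng.integers(10, 10_000))
            obs = int(rng.integers(0, total + 1))
            frac = float(rng.uniform(0.05, 0.95))
            res = observed_expected_test(obs, total, frac)
            exp = [total * frac, total * (1 - frac)]
            chi2, p = sps.chisquare([obs, total - obs], exp)
            assert abs(res.chi2 - chi2) < 1e-9
            assert abs(res.p - p) < 1e-9


class TestWilcoxon:
    def test_identical_groups_p_one(self):
        _, p = compare_utilization_groups([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert p == pytest.approx(1.0)

    def test_exact_enumeration_small_samples(self):
        u, p = compare_utilization_groups([1, 2, 3], [4, 5, 6])
        assert u == 0
        assert p == pytest.approx(0.1)  # 2 / C(6,3)

    def test_power_on_shifted_distributions(self):
        rng = np.random.default_rng(12)
        hits = 0
        for _ in range(40):
            a = rng.uniform(0, 1, 200)
            b = np.clip(a + 0.3, 0, 1)[rng.permutation(200)]
            _, p = compare_utilization_groups(a, b)
            hits += p < 0.005
        assert hits >= 38  # >= 95% of replicates


def brute_force_rarefaction(sets):
    keys = sorted(sets)
    rows = []
    for k in range(1, len(keys) + 1):
        sizes = [
            len(set().union(*(sets[c] for c in combo)))
            for combo in itertools.combinations(keys, k)
        ]
        rows.append((k, pystats.mean(sizes), pystats.pstdev(sizes)))
    return rows


class TestRarefaction:
    def test_identical_sets_flat_curve(self):
        curve = rarefaction({"a": {1, 2, 3}, "b": {1, 2, 3}, "c": {1, 2, 3}})
        assert list(curve["mean"]) == [3.0, 3.0, 3.0]
        assert list(curve["sd"]) == [0.0, 0.0, 0.0]

    def test_disjoint_sets_add_linearly(self):
        sets = {c: {(c, i) for i in range(5)} for c in "abcd"}
        curve = rarefaction(sets)
        assert list(curve["mean"]) == [5.0, 10.0, 15.0, 20.0]
        assert list(curve["sd"]) == [0.0] * 4

    def test_matches_exhaustive_oracle_on_random_sets(self):
        rng = np.random.default_rng(21)
        sets = {
            f"ct{i}": set(rng.integers(0, 40, size=rng.integers(5, 25)).tolist())
            for i in range(4)
        }
        curve = rarefaction(sets)
        for (k, mean, sd), row in zip(brute_force_rarefaction(sets), curve.itertuples()):
            assert row.k == k
            assert row.mean == pytest.approx(mean, abs=1e-12)
            assert row.sd == pytest.approx(sd, abs=1e-12)

    def test_monotone_and_conserved_at_full_depth(self):
        rng = np.random.default_rng(22)
        sets = {f"ct{i}": set(rng.integers(0, 100, 30).tolist()) for i in range(5)}
        curve = rarefaction(sets)
        assert (np.diff(curve["mean"]) >= -1e-12).all()
        assert curve["mean"].iloc[-1] == len(set().union(*sets.values()))


class TestLogTrend:
    def test_exact_model_recovered(self):
        x = np.arange(1, 9)
        y = 10 * np.log(x) + 5
        fit = fit_log_trend(x, y)
        assert fit.a == pytest.approx(10, abs=1e-9)
        assert fit.b == pytest.approx(5, abs=1e-9)
        assert fit.r == pytest.approx(1.0, abs=1e-9)

    def test_two_points_always_perfect_correlation(self):
        fit = fit_log_trend([1, 4], [3.0, 17.0])
        assert fit.r == pytest.approx(1.0)

    def test_all_x_identical_rejected(self):
        with pytest.raises(ValueError):
            fit_log_trend([2, 2, 2], [1.0, 2.0, 3.0])

    def test_published_fit_evaluated_at_eight_celltypes(self):
        from tetermi.statistics import LogTrendFit

        fit = LogTrendFit(a=31.34, b=33.61, r=0.99)
        y8 = predict_log_trend(fit, 8)
        assert y8 == pytest.approx(31.34 * math.log(8) + 33.61, abs=1e-12)
        assert round(y8, 2) == 98.78

    def test_extrapolation_ratio_for_doubling(self):
        from tetermi.statistics import LogTrendFit

        fit = LogTrendFit(a=31.34, b=33.61, r=0.99)
        pred, ratio = extrapolate_total(fit, 8, 16, observed_total=100.0)
        assert ratio == pytest.approx(1.22, abs=0.005)
        assert pred == pytest.approx(100 * ratio)

    def test_flat_trend_has_unit_ratio(self):
        from tetermi.statistics import LogTrendFit

        fit = LogTrendFit(a=0.0, b=50.0, r=1.0)
        assert extrapolate_total(fit, 8, 16)[1] == pytest.approx(1.0)
        assert extrapolate_total(fit, 8, 8)[1] == pytest.approx(1.0)
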