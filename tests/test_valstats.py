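"""Validation statistics vs hand arithmetic and a naive brute-force oracle."""

import math
import statistics

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pttbp import (
    MeasurementPair,
    aami_criterion1,
    band_percentages,
    bland_altman,
    cv_per_participant,
    diff_stats,
    pearson,
    validation_report,
)
from pttbp.valstats import percentage, round_half_up

from conftest import pairs_from_diffs


class TestDiffStats:
    def test_identical_columns(self):
        pairs = pairs_from_diffs([0.0] * 5)
        assert diff_stats(pairs, "sbp") == (0.0, 0.0)

    def test_hand_example(self):
        pairs = pairs_from_diffs([1.0, 3.0])
        mean, sd = diff_stats(pairs, "sbp")
        assert mean == pytest.approx(2.0)
        assert sd == pytest.approx(math.sqrt(2.0))

    def test_sampling_recovers_population_moments(self):
        rng = np.random.default_rng(12)
        diffs = rng.normal(1.2, 7.1, size=261)
        mean, sd = diff_stats(pairs_from_diffs(diffs), "sbp")
        # normal-theory sampling bounds: SE(mean)=7.1/sqrt(261)=0.44, SE(sd)~0.31
        assert mean == pytest.approx(1.2, abs=1.0)
        assert sd == pytest.approx(7.1, abs=0.8)

    def test_needs_two_pairs(self):
        with pytest.raises(ValueError):
            diff_stats(pairs_from_diffs([1.0]), "sbp")


class TestBands:
    def test_strict_inequality(self):
        pairs = pairs_from_diffs([5.0, -5.0, 4.9])
        counts, _ = band_percentages(pairs, "sbp")
        assert counts[0] == 1  # exactly-5 differences do not count as < 5

    def test_all_zero_diffs(self):
        _, pcts = band_percentages(pairs_from_diffs([0.0] * 10), "sbp")
        assert pcts == (100.0, 100.0, 100.0)

    def test_half_up_rounding(self):
        assert round_half_up(6.25, 1) == 6.3  # banker's rounding would give 6.2
        assert percentage(1, 16) == 6.3
        assert percentage(150, 261) == 57.5

    @given(st.lists(st.floats(-30.0, 30.0), min_size=1, max_size=60))
    @settings(max_examples=100, deadline=None)
    def test_band_monotonicity(self, diffs):
        counts, pcts = band_percentages(pairs_from_diffs(diffs), "sbp")
        assert counts[0] <= counts[1] <= counts[2]
        assert pcts[0] <= pcts[1] <= pcts[2]
        assert all(0.0 <= p <= 100.0 for p in pcts)


class TestBlandAltman:
    def test_identical_columns(self):
        ba = bland_altman(pairs_from_diffs([0.0] * 5), "sbp")
        assert (ba.mean, ba.sd, ba.n_outside) == (0.0, 0.0, 0)

    def test_single_extreme_point_is_outside(self):
        diffs = [0.0] * 260 + [20.0]
        ba = bland_altman(pairs_from_diffs(diffs), "sbp")
        assert ba.n_outside == 1
        assert ba.lower < ba.upper

    def test_coverage_of_normal_differences(self):
        """P(|Z| > 2) = 4.55%; a large seeded sample should sit close."""
        rng = np.random.default_rng(99)
        ba = bland_altman(pairs_from_diffs(rng.normal(0, 5, 10000)), "sbp")
        expected = 2 * (1 - 0.9772498680518208)  # 2*(1-Phi(2)) = 4.55%
        assert ba.pct_outside == pytest.approx(100 * expected, abs=0.6)


class TestPearsonAndCv:
    def test_perfect_correlation(self):
        pairs = [
            MeasurementPair("P1", 100.0 + i, 60.0, 100.0 + i, 62.0) for i in range(5)
        ]
        r, p = pearson(pairs, "sbp")
        assert r == pytest.approx(1.0)

    def test_anticorrelation(self):
        pairs = [
            MeasurementPair("P1", 100.0 + i, 60.0, 110.0 - i, 62.0) for i in range(5)
        ]
        assert pearson(pairs, "sbp")[0] == pytest.approx(-1.0)

    def test_bivariate_normal_in_fisher_interval(self):
        rng = np.random.default_rng(5)
        rho = 0.9
        x = rng.normal(size=200)
        y = rho * x + math.sqrt(1 - rho**2) * rng.normal(size=200)
        pairs = [
            MeasurementPair("P1", 120.0 + a, 80.0, 120.0 + b, 80.0 - 1.0)
            for a, b in zip(10 * x, 10 * y)
        ]
        r, p = pearson(pairs, "sbp")
        assert 0.85 <= r <= 0.94
        assert p < 1e-10

    def test_zero_variance_rejected(self):
        pairs = pairs_from_diffs([0.0] * 5)
        with pytest.raises(ValueError, match="variance"):
            pearson(pairs, "sbp")

    def test_cv_hand_example(self):
        pairs = [
            MeasurementPair("A", 100.0, 60.0, 100.0, 60.0),
            MeasurementPair("A", 110.0, 60.0, 100.0, 60.0),
        ]
        mean_cv, per = cv_per_participant(pairs, "sbp", source="test")
        assert mean_cv == pytest.approx(100 * (10 / math.sqrt(2)) / 105, abs=1e-9)

    def test_cv_identical_repeats_and_averaging(self):
        pairs = []
        for pid in ("A", "B", "C"):
            pairs += [
                MeasurementPair(pid, 100.0, 60.0, 100.0, 60.0),
                MeasurementPair(pid, 110.0, 60.0, 100.0, 60.0),
            ]
        mean_cv, per = cv_per_participant(pairs, "sbp", source="test")
        assert len(per) == 3
        assert mean_cv == pytest.approx(list(per.values())[0])
        assert cv_per_participant(pairs, "sbp", source="ref")[0] == 0.0

    def test_singletons_excluded_with_warning(self):
        pairs = [
            MeasurementPair("A", 100.0, 60.0, 100.0, 60.0),
            MeasurementPair("A", 104.0, 60.0, 100.0, 60.0),
            MeasurementPair("B", 100.0, 60.0, 100.0, 60.0),
        ]
        with pytest.warns(UserWarning, match="excluded"):
            _, per = cv_per_participant(pairs, "sbp")
        assert set(per) == {"A"}


class TestAami:
    @pytest.mark.parametrize(
        "mean, sd, expected",
        [(1.2, 7.1, True), (-1.0, 6.0, True), (5.1, 7.9, False), (5.0, 8.0, True), (0.0, 8.1, False)],
    )
    def test_criterion_boundaries(self, mean, sd, expected):
        assert aami_criterion1(mean, sd) is expected


def naive_stats(rows, quantity):
    """Pure-Python re-computation of every statistic (independent oracle)."""
    test = [r[f"test_{quantity}"] for r in rows]
    ref = [r[f"ref_{quantity}"] for r in rows]
    n = len(rows)
    d = [t - r for t, r in zip(test, ref)]
    mean = sum(d) / n
    sd = math.sqrt(sum((x - mean) ** 2 for x in d) / (n - 1))
    counts = [sum(1 for x in d if abs(x) < th) for th in (5, 10, 15)]
    lower, upper = mean - 2 * sd, mean + 2 * sd
    outside = sum(1 for x in d if x < lower or x > upper)
    return mean, sd, counts, outside


class TestBruteForceOracle:
    def test_statistics_match_naive_recomputation(self):
        """Every statistic agrees with a naive pure-Python oracle on random
        tables (counts exactly; moments to float round-off)."""
        rng = np.random.default_rng(2024)
        for _ in range(100):
            n = int(rng.integers(2, 51))
            rows = []
            for i in range(n):
                ref_sbp = float(rng.uniform(95, 180))
                ref_dbp = float(rng.uniform(55, ref_sbp - 15))
                rows.append(
                    dict(
                        test_sbp=ref_sbp + float(rng.normal(0, 8)),
                        test_dbp=ref_dbp + float(rng.normal(0, 6)),
                        ref_sbp=ref_sbp,
                        ref_dbp=ref_dbp,
                    )
                )
            pairs = [
                MeasurementPair(
                    f"P{i}",
                    max(r["test_sbp"], r["test_dbp"] + 5.0),
                    r["test_dbp"],
                    r["ref_sbp"],
                    r["ref_dbp"],
                )
                for i, r in enumerate(rows)
            ]
            for i, r in enumerate(rows):
                r["test_sbp"] = pairs[i].test_sbp
            for q in ("sbp", "dbp"):
                mean, sd, counts, outside = naive_stats(rows, q)
                got_mean, got_sd = diff_stats(pairs, q)
                assert got_mean == pytest.approx(mean, rel=1e-12, abs=1e-12)
                assert got_sd == pytest.approx(sd, rel=1e-12, abs=1e-12)
                got_counts, got_pcts = band_percentages(pairs, q)
                assert list(got_counts) == counts
                assert got_pcts == tuple(percentage(c, n) for c in counts)
                ba = bland_altman(pairs, q)
                assert ba.n_outside == outside


class TestValidationReport:
    def test_full_report_surface(self):
        rng = np.random.default_rng(3)
        pairs = []
        for pid in range(10):
            for _ in range(3):
                sbp = float(rng.uniform(100, 160))
                dbp = sbp - float(rng.uniform(30, 50))
                pairs.append(
                    MeasurementPair(
                        f"P{pid}",
                        sbp + float(rng.normal(0, 5)),
                        dbp + float(rng.normal(0, 4)),
                        sbp,
                        dbp,
                        test_hr=70.0 + float(rng.normal(0, 3)),
                        ref_hr=70.0 + float(rng.normal(0, 3)),
                    )
                )
        rep = validation_report(pairs)
        assert rep.n_pairs == 30
        assert rep.hr is not None
        assert rep.sbp.cv_test_pct is not None and rep.sbp.cv_test_pct > 0
        assert rep.aami_pass == (rep.sbp.aami_pass and rep.dbp.aami_pass)
        assert rep.sbp.bland_altman.lower < rep.sbp.bland_altman.upper
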