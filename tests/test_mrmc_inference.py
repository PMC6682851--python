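import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as stn
from hypothesis.extra.numpy import arrays
from scipy.stats import norm

from screentriage.errors import EstimationError, ValidationError
from screentriage.mrmc_inference import (
    _psi_matrix,
    _ReaderBlock,
    _ustat_mean_var,
    average_curves,
    compare_scenarios,
    mrmc_variance,
    noninferiority_test,
    reader_curve,
    trapezoidal_auc,
)
from screentriage.triage_engine import partition, reassign_scores

from conftest import brute_force_auc, make_dataset

scores = stn.floats(min_value=-5, max_value=5, allow_nan=False)
score_arrays = arrays(np.float64, stn.integers(1, 30), elements=scores)


class TestTrapezoidalAuc:
    def test_perfect_separation(self):
        assert trapezoidal_auc([2, 3], [0, 1]) == 1.0

    def test_complete_tie(self):
        assert trapezoidal_auc([1], [1]) == 0.5

    def test_mixed_with_ties(self):
        assert trapezoidal_auc([3, 1], [2, 1]) == 0.625

    def test_empty_class_rejected(self):
        with pytest.raises(EstimationError):
            trapezoidal_auc([], [1.0])

    @settings(max_examples=200, deadline=None)
    @given(score_arrays, score_arrays)
    def test_matches_brute_force(self, pos, neg):
        assert trapezoidal_auc(pos, neg) == pytest.approx(
            brute_force_auc(pos, neg), abs=1e-12
        )

    @settings(max_examples=100, deadline=None)
    @given(score_arrays, score_arrays)
    def test_complement_symmetry(self, pos, neg):
        assert trapezoidal_auc(pos, neg) + trapezoidal_auc(-pos, -neg) == pytest.approx(
            1.0, abs=1e-12
        )


class TestReaderCurve:
    def test_perfect_ordering(self):
        curve = reader_curve([4, 5], [1, 2])
        assert curve.auc == pytest.approx(1.0)
        assert [0.0, 1.0] in curve.points.tolist()

    def test_all_identical_scores_diagonal(self):
        curve = reader_curve([2, 2], [2, 2, 2])
        np.testing.assert_allclose(curve.points, [[0, 0], [1, 1]])
        assert curve.auc == pytest.approx(0.5)

    def test_matches_mann_whitney(self):
        curve = reader_curve([3, 1], [2, 1])
        assert curve.auc == pytest.approx(0.625)

    @settings(max_examples=100, deadline=None)
    @given(score_arrays, score_arrays)
    def test_area_equals_pairwise_auc(self, pos, neg):
        curve = reader_curve(pos, neg)
        assert curve.auc == pytest.approx(trapezoidal_auc(pos, neg), abs=1e-12)

    @settings(max_examples=50, deadline=None)
    @given(score_arrays, score_arrays)
    def test_curve_shape_invariants(self, pos, neg):
        pts = reader_curve(pos, neg).points
        np.testing.assert_allclose(pts[0], [0, 0])
        np.testing.assert_allclose(pts[-1], [1, 1])
        assert (np.diff(pts[:, 0]) >= 0).all()
        assert (np.diff(pts[:, 1]) >= 0).all()

    def test_single_class_rejected(self):
        with pytest.raises(EstimationError):
            reader_curve([], [1.0, 2.0])


def _random_curves(rng, k):
    curves = []
    for i in range(k):
        pos = rng.normal(rng.uniform(0, 2), 1, rng.integers(2, 40))
        neg = rng.normal(0, 1, rng.integers(2, 40))
        curves.append(reader_curve(pos, neg, f"r{i}"))
    return curves


class TestAverageCurves:
    def test_single_curve_identity(self):
        curve = reader_curve([3, 1, 4], [2, 1, 0])
        avg = average_curves([curve])
        assert avg.auc == pytest.approx(curve.auc, abs=1e-9)
        # original vertices are reproduced on the averaged polyline
        for x, y in curve.points:
            idx = np.argmin(np.abs(avg.points[:, 0] - x) + np.abs(avg.points[:, 1] - y))
            np.testing.assert_allclose(avg.points[idx], [x, y], atol=1e-9)

    def test_identical_curves_average_to_themselves(self):
        curve = reader_curve([5, 2, 3], [1, 2, 4])
        avg = average_curves([curve] * 4)
        assert avg.auc == pytest.approx(curve.auc, abs=1e-9)

    def test_area_preservation_random(self):
        rng = np.random.default_rng(17)
        for _ in range(20):
            curves = _random_curves(rng, int(rng.integers(2, 8)))
            avg = average_curves(curves)
            assert avg.auc == pytest.approx(
                np.mean([c.auc for c in curves]), abs=1e-6
            )

    def test_averaged_curve_monotone(self):
        rng = np.random.default_rng(3)
        avg = average_curves(_random_curves(rng, 5))
        assert (np.diff(avg.points[:, 0]) >= -1e-12).all()
        assert (np.diff(avg.points[:, 1]) >= -1e-12).all()

    def test_empty_rejected(self):
        with pytest.raises(ValidationError):
            average_curves([])


def _crossed_blocks(rng, n_readers=5, n_pos=20, n_neg=40, mu=1.2):
    pos_ids = np.array([f"p{i}" for i in range(n_pos)])
    neg_ids = np.array([f"n{j}" for j in range(n_neg)])
    pos_lat = mu + rng.normal(0, 1, n_pos)
    neg_lat = rng.normal(0, 1, n_neg)
    blocks = []
    for r in range(n_readers):
        skill = 1 + rng.normal(0, 0.2)
        bias = rng.normal(0, 0.25)
        ps = skill * pos_lat + bias + rng.normal(0, 0.6, n_pos)
        ns = skill * neg_lat + bias + rng.normal(0, 0.6, n_neg)
        blocks.append(_ReaderBlock(f"r{r}", pos_ids, neg_ids, _psi_matrix(ps, ns)))
    return blocks


class TestUStatVariance:
    def test_single_reader_perfect_separation(self):
        ds = make_dataset(
            ["cancer", "cancer", "normal", "normal"],
            [10, 10, 1, 1],
            {"r1": [9.0, 8.0, 2.0, 1.0]},
        )
        result = mrmc_variance(ds)
        assert result.auc_hat == 1.0
        assert result.var_hat == 0.0

    def test_duplicate_readers_match_single_reader(self):
        rng = np.random.default_rng(5)
        single = _crossed_blocks(rng, n_readers=1)
        twin = [
            _ReaderBlock("a", single[0].pos_ids, single[0].neg_ids, single[0].psi),
            _ReaderBlock("b", single[0].pos_ids, single[0].neg_ids, single[0].psi),
        ]
        auc1, var1 = _ustat_mean_var(single)
        auc2, var2 = _ustat_mean_var(twin)
        assert auc2 == pytest.approx(auc1, abs=1e-12)
        assert var2 == pytest.approx(var1, abs=1e-12)

    def test_monte_carlo_sanity_crossed(self):
        # small-n version of the full acceptance check
        rng = np.random.default_rng(99)
        aucs, vars_ = [], []
        for _ in range(400):
            auc, var = _ustat_mean_var(_crossed_blocks(rng))
            aucs.append(auc)
            vars_.append(var)
        assert np.mean(vars_) == pytest.approx(np.var(aucs, ddof=1), rel=0.2)

    def test_dataset_route_matches_block_route(self):
        ds = make_dataset(
            ["cancer", "cancer", "normal", "normal", "normal"],
            [9, 10, 2, 4, 6],
            {"r1": [7.0, 9.0, 2.0, 5.0, 3.0], "r2": [6.0, 8.0, 1.0, 7.0, 2.0]},
        )
        result = mrmc_variance(ds)
        per_reader = [
            trapezoidal_auc([7, 9], [2, 5, 3]),
            trapezoidal_auc([6, 8], [1, 7, 2]),
        ]
        assert result.auc_hat == pytest.approx(np.mean(per_reader), abs=1e-12)

    def test_no_valid_reader_rejected(self):
        ds = make_dataset(["normal", "normal"], [1, 2], {"r1": [1.0, 2.0]})
        with pytest.raises(EstimationError):
            mrmc_variance(ds)

    def test_one_class_reader_dropped_with_warning(self):
        ds = make_dataset(
            ["cancer", "cancer", "normal", "normal"],
            [10, 9, 1, 2],
            {"r1": [9.0, 8.0, 2.0, 3.0]},
        )
        # add a reader who only read one normal exam
        extra = pd.DataFrame(
            [
                {
                    "exam_id": "E002",
                    "reader_id": "r2",
                    "study_id": "B1",
                    "score": 3.0,
                    "scale_min": 1.0,
                    "scale_max": 10.0,
                }
            ]
        )
        ds.readings = pd.concat([ds.readings, extra], ignore_index=True)
        with pytest.warns(UserWarning, match="dropped"):
            result = mrmc_variance(ds)
        assert result.auc_hat == 1.0


class TestNonInferiority:
    def test_zero_delta_zero_variance(self):
        d = noninferiority_test(0.0, 0.0)
        assert (d.ci_low, d.ci_high) == (0.0, 0.0)
        assert d.noninferior

    def test_rule_is_ci_low_above_negative_margin(self):
        assert noninferiority_test(-0.04, 1e-8, margin=0.05).noninferior
        assert not noninferiority_test(-0.06, 1e-8, margin=0.05).noninferior

    def test_bonferroni_quantile(self):
        d = noninferiority_test(-0.02, 0.01**2, margin=0.05, n_comparisons=9)
        z = norm.ppf(1 - 0.05 / 18)
        assert d.ci_low == pytest.approx(-0.02 - z * 0.01, abs=1e-12)
        assert d.noninferior == (d.ci_low > -0.05)
        assert d.level == pytest.approx(1 - 0.05 / 9)

    def test_strict_variant_requires_positive_delta(self):
        d = noninferiority_test(-0.001, 1e-8, require_positive_delta=True)
        assert not d.noninferior
        assert noninferiority_test(0.001, 1e-8, require_positive_delta=True).noninferior

    def test_negative_variance_rejected(self):
        with pytest.raises(ValidationError):
            noninferiority_test(0.0, -1e-6)


class TestCompareScenarios:
    def test_identity_scenario_exact_zero_delta(self):
        # no exam at or below the threshold -> scenario is the original
        ds = make_dataset(
            ["cancer", "cancer", "normal", "normal"],
            [9, 10, 8, 7],
            {"r1": [9.0, 8.0, 3.0, 4.0], "r2": [7.0, 9.0, 2.0, 5.0]},
        )
        results, curves = compare_scenarios(ds, [partition(ds, 5)])
        assert len(results) == 2
        scenario = results[1]
        assert scenario.delta == 0.0
        assert scenario.var_delta == 0.0
        assert scenario.noninferior
        assert set(curves) == {"original", "threshold_5"}

    def test_fixture_ordering_of_degradation(self, fixture_dataset):
        results, _ = compare_scenarios(fixture_dataset)
        by_threshold = {r.threshold: r for r in results if r.threshold}
        assert by_threshold[9].delta < by_threshold[5].delta

    def test_paired_delta_matches_auc_difference(self, fixture_dataset):
        tr = partition(fixture_dataset, 4)
        readings = reassign_scores(fixture_dataset, tr.excluded_exam_ids)
        res = mrmc_variance(fixture_dataset, readings, baseline_readings=fixture_dataset.readings)
        base = mrmc_variance(fixture_dataset)
        assert res.delta == pytest.approx(res.auc_hat - base.auc_hat, abs=1e-12)
        assert res.var_delta >= 0
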