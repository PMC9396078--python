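import numpy as np
import pytest

import opuf
from opuf import (
    Anchor,
    PersonalValueSet,
    aggregate,
    bootstrap_ci,
    dce_accuracy,
    group_tariff,
    rescale_floor,
    reversal_count,
    summary_table,
    validation_report,
)


def make_valueset(eq5d, a, ratings=(100, 75, 50, 25, 0), weights=(100, 100, 100, 100, 100)):
    l = opuf.ratings_to_disutilities(ratings)
    w = opuf.normalize_weights(weights)
    m = opuf.build_matrix(l, w, eq5d)
    return opuf.anchor_matrix(m, a, Anchor.dead_vas(max(0.0, 100 * (1 - a))))


class TestAggregate:
    def test_identical_inputs_are_a_fixed_point(self, eq5d):
        vs = make_valueset(eq5d, 1.2)
        for stat in ("mean", "median"):
            tariff = aggregate([vs] * 50, stat)
            assert np.allclose(tariff.matrix, vs.matrix)
            assert tariff.n == 50

    def test_two_point_mean_and_median(self, eq5d):
        pair = [make_valueset(eq5d, 0.5), make_valueset(eq5d, 1.5)]
        cell = (1, 0)  # slight-level first-dimension coefficient
        lo, hi = pair[0].matrix[cell], pair[1].matrix[cell]
        for stat in ("mean", "median"):
            assert aggregate(pair, stat).matrix[cell] == pytest.approx((lo + hi) / 2)

    def test_outlier_separates_mean_from_median(self, eq5d):
        trio = [make_valueset(eq5d, a) for a in (0.8, 1.0, 4.0)]
        mean_t = aggregate(trio, "mean")
        median_t = aggregate(trio, "median")
        cell = (4, 2)
        assert mean_t.matrix[cell] > median_t.matrix[cell]
        assert median_t.matrix[cell] == pytest.approx(trio[1].matrix[cell])

    def test_permutation_invariance(self, population50):
        _, valuesets = population50
        fwd = aggregate(valuesets).matrix
        rev = aggregate(valuesets[::-1]).matrix
        assert np.allclose(fwd, rev)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            aggregate([])

    def test_mixed_systems_rejected(self, eq5d, toy2x3):
        vs = make_valueset(eq5d, 1.0)
        toy_m = opuf.ScaledCoefficientMatrix(
            np.array([[0.0, 0.0], [0.3, 0.2], [0.6, 0.4]]), toy2x3
        )
        toy_vs = opuf.anchor_matrix(toy_m, 1.0)
        with pytest.raises(ValueError, match="descriptive system"):
            aggregate([vs, toy_vs])


class TestBootstrap:
    def test_zero_variance_gives_zero_width(self, eq5d):
        vs = make_valueset(eq5d, 1.1)
        lo, hi = bootstrap_ci([vs] * 10, n_iter=200, seed=0)
        assert np.allclose(lo, hi)

    def test_deterministic_under_seed(self, population50):
        _, valuesets = population50
        a = bootstrap_ci(valuesets, n_iter=500, seed=11)
        b = bootstrap_ci(valuesets, n_iter=500, seed=11)
        assert np.array_equal(a[0], b[0]) and np.array_equal(a[1], b[1])

    def test_single_respondent_rejected(self, eq5d):
        with pytest.raises(ValueError):
            bootstrap_ci([make_valueset(eq5d, 1.0)])

    def test_ci_contains_point_estimate(self, population50):
        _, valuesets = population50
        tariff = group_tariff(valuesets, n_bootstrap=2000, seed=5)
        assert np.all(tariff.ci_lower <= tariff.matrix + 1e-12)
        assert np.all(tariff.matrix <= tariff.ci_upper + 1e-12)

    def test_width_shrinks_with_sample_size(self, eq5d):
        sims = opuf.simulate_population(100, seed=21, system=eq5d)
        valuesets = [opuf.construct_valueset(s.record, eq5d) for s in sims]
        lo10, hi10 = bootstrap_ci(valuesets[:10], n_iter=2000, seed=1)
        lo100, hi100 = bootstrap_ci(valuesets, n_iter=2000, seed=1)
        assert (hi100 - lo100)[1:].mean() < (hi10 - lo10)[1:].mean()


class TestGroupRecovery:
    def test_tariff_converges_to_latent_mean(self, eq5d):
        """With noiseless responses the group mean tariff should match the
        mean of the latent anchored matrices up to the position-of-dead
        anchoring resolution (3 standard errors per cell)."""
        sims = opuf.simulate_population(200, seed=13, system=eq5d)
        valuesets = [opuf.construct_valueset(s.record, eq5d) for s in sims]
        tariff = aggregate(valuesets)
        latent = np.stack([s.latent.anchored_matrix(eq5d) for s in sims])
        se = latent.std(axis=0, ddof=1) / np.sqrt(len(sims))
        diff = np.abs(tariff.matrix - latent.mean(axis=0))
        assert np.all(diff <= 3 * se + 1e-9)


class TestRescaleFloor:
    def test_linear_map_on_negative_range(self):
        out = rescale_floor(np.array([-3.2, -1.6, 0.5, 1.0]))
        assert out == pytest.approx([-1.0, -0.5, 0.5, 1.0])

    def test_all_positive_is_identity(self):
        vals = np.array([0.1, 0.9])
        assert np.array_equal(rescale_floor(vals), vals)

    def test_minimum_at_floor_is_identity(self):
        vals = np.array([-1.0, 0.2])
        assert np.array_equal(rescale_floor(vals), vals)

    def test_positive_floor_rejected(self):
        with pytest.raises(ValueError):
            rescale_floor([-2.0], floor=0.5)


class TestDceAccuracy:
    def test_noiseless_respondents_are_fully_consistent(self, eq5d):
        cfg = opuf.PopulationConfig(choice_beta=np.inf)
        sims = opuf.simulate_population(20, cfg, seed=2, system=eq5d)
        valuesets = [opuf.construct_valueset(s.record, eq5d) for s in sims]
        report = dce_accuracy(valuesets, [s.record.dce for s in sims])
        assert report.pooled_accuracy == 1.0
        assert report.n_choices == 60

    def test_error_rate_decreases_with_target_distance(self, eq5d):
        sims = opuf.simulate_population(150, seed=4, system=eq5d)
        valuesets = [opuf.construct_valueset(s.record, eq5d) for s in sims]
        report = dce_accuracy(valuesets, [s.record.dce for s in sims])
        errs = [report.error_rate_by_distance[d] for d in (0.1, 0.2, 0.3)]
        assert errs[0] > errs[2]

    def test_mismatched_lengths_rejected(self, eq5d):
        vs = make_valueset(eq5d, 1.0)
        with pytest.raises(ValueError):
            dce_accuracy([vs], [[], []])


class TestReversals:
    @pytest.mark.parametrize(
        "ranking, weights, expected",
        [
            (("MO", "SC", "UA", "PD", "AD"), (100, 80, 60, 40, 20), 0),
            (("MO", "SC", "UA", "PD", "AD"), (100, 100, 100, 100, 100), 0),
            (("MO", "SC", "UA", "PD", "AD"), (100, 50, 60, 40, 30), 1),
            (("AD", "PD", "UA", "SC", "MO"), (100, 80, 60, 40, 20), 10),
        ],
    )
    def test_counts(self, ranking, weights, expected):
        raw = dict(zip(("MO", "SC", "UA", "PD", "AD"), weights))
        assert reversal_count(ranking, raw) == expected


class TestValidationReport:
    def test_full_report_structure(self, population50):
        sims, valuesets = population50
        records = [s.record for s in sims]
        report = validation_report(valuesets, records, seed=0)
        assert 0.0 <= report.pooled_accuracy <= 1.0
        assert all(0.0 <= a <= 1.0 for a in report.per_respondent_accuracy)
        assert all(0 <= r <= 10 for r in report.reversal_counts)
        s = report.worst_value_summary
        assert s["min"] <= s["median"] <= s["max"]
        assert "pooled DCE accuracy" in report.to_table()
        assert "pooled_accuracy" in report.to_json()

    def test_summary_table_layout(self, population50):
        _, valuesets = population50
        table = summary_table(valuesets, n_bootstrap=500, seed=3)
        assert len(table) == 20  # 5 dimensions x levels 2-5
        assert (table["min"] <= table["median"]).all()
        assert (table["ci_lower"] <= table["mean"]).all()
        assert (table["mean"] <= table["ci_upper"]).all()
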