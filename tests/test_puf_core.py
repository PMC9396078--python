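import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import opuf
from opuf import (
    Anchor,
    ScaledCoefficientMatrix,
    anchor_matrix,
    anchoring_factor,
    build_matrix,
    dominates,
    enumerate_states,
    normalize_weights,
    parse_state,
    rank_all_states,
    ratings_to_disutilities,
    round_half_up,
    scaled_value,
)
from conftest import REF_RATINGS, REF_WEIGHTS


@st.composite
def monotone_disutilities(draw, n_levels=5):
    interior = sorted(draw(st.lists(
        st.floats(0.0, 1.0, allow_nan=False), min_size=n_levels - 2, max_size=n_levels - 2
    )))
    return opuf.LevelDisutilities((0.0, *interior, 1.0))


@st.composite
def swing_weights(draw, n_dims=5):
    others = draw(st.lists(st.floats(0.0, 100.0), min_size=n_dims - 1, max_size=n_dims - 1))
    return normalize_weights([100.0, *others])


class TestRatingsToDisutilities:
    @pytest.mark.parametrize(
        "ratings, expected",
        [
            (REF_RATINGS, (0.0, 0.1, 0.5, 0.7, 1.0)),
            ((100, 100, 100, 100, 0), (0.0, 0.0, 0.0, 0.0, 1.0)),
            ((100, 75, 50, 25, 0), (0.0, 0.25, 0.5, 0.75, 1.0)),
        ],
    )
    def test_conversion(self, ratings, expected):
        out = ratings_to_disutilities(ratings)
        assert out.values == pytest.approx(expected, abs=1e-12)

    def test_endpoints_enforced(self):
        with pytest.raises(ValueError, match="endpoint"):
            ratings_to_disutilities((90, 80, 50, 30, 0))

    def test_non_monotone_strict_rejects(self):
        with pytest.raises(ValueError, match="non-increasing"):
            ratings_to_disutilities((100, 50, 90, 30, 0))

    def test_non_monotone_lenient_warns(self):
        with pytest.warns(UserWarning):
            out = ratings_to_disutilities((100, 50, 90, 30, 0), strict=False)
        assert out.values[1] == pytest.approx(0.5)


class TestNormalizeWeights:
    def test_reference_weights(self):
        w = normalize_weights(REF_WEIGHTS)
        assert w.normalized == pytest.approx(
            (100 / 350, 60 / 350, 40 / 350, 80 / 350, 70 / 350), abs=1e-15
        )
        assert [round_half_up(v) for v in w.normalized] == [0.29, 0.17, 0.11, 0.23, 0.2]

    @pytest.mark.parametrize(
        "raw, expected",
        [
            ((100, 100, 100, 100, 100), (0.2,) * 5),
            ((100, 0, 0, 0, 0), (1.0, 0.0, 0.0, 0.0, 0.0)),
        ],
    )
    def test_degenerate_vectors(self, raw, expected):
        assert normalize_weights(raw).normalized == pytest.approx(expected)

    def test_missing_yardstick_strict(self):
        with pytest.raises(ValueError, match="yardstick"):
            normalize_weights((90, 60, 40, 80, 70))

    def test_missing_yardstick_lenient_rescales_by_max(self):
        with pytest.warns(UserWarning):
            w = normalize_weights((90, 45, 45, 45, 45), strict=False)
        assert max(w.raw) == pytest.approx(100.0)
        assert sum(w.normalized) == pytest.approx(1.0, abs=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            normalize_weights((100, 120, 40, 80, 70))


class TestScaledMatrix:
    def test_reference_cells(self, ref_exact_matrix):
        # moderate-level pain/discomfort cell: 0.5 * (80/350)
        assert ref_exact_matrix.values[2, 3] == pytest.approx(0.5 * 80 / 350)
        assert ref_exact_matrix.values[0].sum() == 0.0
        assert ref_exact_matrix.values[-1].sum() == pytest.approx(1.0, abs=1e-12)

    @given(monotone_disutilities(), swing_weights())
    def test_invariants_hold_for_any_valid_inputs(self, eq5d, l, w):
        m = build_matrix(l, w, eq5d)
        assert np.all(m.values[0] == 0.0)
        assert m.values[-1].sum() == pytest.approx(1.0, abs=1e-9)
        assert np.all(np.diff(m.values, axis=0) >= -1e-12)

    def test_display_rounded_matrix_value_chain(self, ref_rounded_matrix):
        assert round_half_up(scaled_value(ref_rounded_matrix, "12345")) == 0.56
        assert scaled_value(ref_rounded_matrix, "11111") == 1.0
        assert scaled_value(ref_rounded_matrix, "55555") == pytest.approx(0.0, abs=1e-12)

    def test_shape_mismatch_rejected(self, eq5d):
        l = ratings_to_disutilities((100, 50, 0))
        w = normalize_weights(REF_WEIGHTS)
        with pytest.raises(ValueError):
            build_matrix(l, w, eq5d)


class TestAnchoring:
    def test_pod_anchor_from_rounded_cells(self, ref_rounded_matrix, eq5d):
        anchor = Anchor.position_of_dead(parse_state("51255", eq5d))
        d = ref_rounded_matrix.disutility("51255")
        assert d == pytest.approx(0.29 + 0.0 + 0.01 + 0.23 + 0.20, abs=1e-12)
        assert anchoring_factor(anchor, ref_rounded_matrix) == pytest.approx(1.0 / d)

    def test_pod_anchor_at_full_health_rejected(self, ref_exact_matrix, eq5d):
        anchor = Anchor.position_of_dead(parse_state("11111", eq5d))
        with pytest.raises(ValueError, match="full health"):
            anchoring_factor(anchor, ref_exact_matrix)

    @pytest.mark.parametrize("vas, a", [(0.0, 1.0), (50.0, 0.5)])
    def test_dead_vas_factor(self, ref_exact_matrix, vas, a):
        assert anchoring_factor(Anchor.dead_vas(vas), ref_exact_matrix) == pytest.approx(a)

    def test_dead_vas_100_degenerate_warns(self, ref_exact_matrix):
        with pytest.warns(UserWarning):
            assert anchoring_factor(Anchor.dead_vas(100.0), ref_exact_matrix) == 0.0

    def test_anchored_valueset_invariants(self, ref_exact_matrix, eq5d):
        anchor = Anchor.position_of_dead(parse_state("51255", eq5d))
        a = anchoring_factor(anchor, ref_exact_matrix)
        vs = anchor_matrix(ref_exact_matrix, a, anchor)
        assert vs.value("11111") == 1.0
        assert vs.value("51255") == pytest.approx(0.0, abs=1e-12)
        assert vs.worst_state_value == pytest.approx(1.0 - a, abs=1e-12)

    def test_vas_round_trip_reproduces_worst_value(self, ref_exact_matrix):
        anchor = Anchor.dead_vas(37.0)
        vs = anchor_matrix(ref_exact_matrix, anchoring_factor(anchor, ref_exact_matrix), anchor)
        assert vs.value("55555") == pytest.approx(0.37, abs=1e-12)

    def test_negative_factor_rejected(self, ref_exact_matrix):
        with pytest.raises(ValueError):
            anchor_matrix(ref_exact_matrix, -0.5)

    @given(st.floats(0.05, 4.0))
    def test_anchoring_preserves_state_ordering(self, ref_exact_matrix, eq5d, a):
        states = enumerate_states(eq5d)[::125]
        scaled = np.array([scaled_value(ref_exact_matrix, s) for s in states])
        vs = anchor_matrix(ref_exact_matrix, a)
        anchored = np.array([vs.value(s) for s in states])
        order = np.argsort(scaled)
        # anchored values must be non-decreasing along the scaled order
        assert np.all(np.diff(anchored[order]) >= -1e-9)


class TestRankAllStates:
    def test_extremes_rank_first_and_last(self, ref_exact_matrix):
        ranking = rank_all_states(ref_exact_matrix, seed=0)
        assert ranking[0].code == "11111"
        assert ranking[-1].code == "55555"

    def test_deterministic_under_seed(self, ref_exact_matrix):
        r1 = rank_all_states(ref_exact_matrix, seed=7)
        r2 = rank_all_states(ref_exact_matrix, seed=7)
        assert [s.code for s in r1] == [s.code for s in r2]

    def test_single_criterion_ties_are_blockwise(self, eq5d):
        # weight only on mobility: 625-way ties per mobility level
        l = ratings_to_disutilities((100, 75, 50, 25, 0))
        w = normalize_weights((100, 0, 0, 0, 0))
        m = build_matrix(l, w, eq5d)
        ranking = rank_all_states(m, seed=3)
        mo_levels = [s.levels[0] for s in ranking]
        assert mo_levels == sorted(mo_levels)
        for lvl in range(1, 6):
            assert mo_levels.count(lvl) == 625
        # tie order differs across seeds but is reproducible
        other = rank_all_states(m, seed=4)
        assert [s.code for s in other] != [s.code for s in ranking]

    def test_dominance_monotone_on_sampled_pairs(self, ref_exact_matrix, eq5d):
        rng = np.random.default_rng(0)
        states = enumerate_states(eq5d)
        for _ in range(300):
            a, b = rng.integers(0, len(states), 2)
            sa, sb = states[a], states[b]
            if dominates(sa, sb):
                assert scaled_value(ref_exact_matrix, sa) > scaled_value(ref_exact_matrix, sb)


class TestRounding:
    @pytest.mark.parametrize(
        "x, expected", [(0.565, 0.57), (0.125, 0.13), (-0.351351, -0.35), (-0.125, -0.13)]
    )
    def test_round_half_up(self, x, expected):
        assert round_half_up(x) == expected
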