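"""Algebra of triangular spherical fuzzy numbers.

Numeric expectations were computed by direct evaluation of the operator
laws on the published scale terms K4 = ((0.29,0.36,0.43);0.70,0.35,0.40)
and K5 = ((0.38,0.45,0.52);0.65,0.40,0.50).
"""

import math

import pytest
from hypothesis import given, settings, strategies as st

from appss import tsfn as T
from appss.tsfn import (TSFN, ZERO, UNIT, MembershipPolicy, PolicyMode,
                        make_tsfn)

APPROX = dict(abs=1e-12)


def tsfns(triple_range=(-5.0, 5.0)):
    f = st.floats(*triple_range, allow_nan=False, allow_infinity=False)
    m = st.floats(0.0, 1.0, allow_nan=False)
    return st.builds(make_tsfn, f, f, f, m, m, m)


class TestConstruction:
    def test_stores_valid_input_unchanged(self):
        x = make_tsfn(0.38, 0.45, 0.52, 0.65, 0.40, 0.50)
        assert x.triple == (0.38, 0.45, 0.52)
        assert x.memberships == (0.65, 0.40, 0.50)
        assert x.sphere_excess < 0

    def test_resorts_disordered_triple(self):
        x = make_tsfn(0.23, 0.09, -0.05, 0.0, 1.0, 1.0)
        assert x.triple == (-0.05, 0.09, 0.23)

    def test_scale_policy_renormalizes_onto_sphere(self):
        pol = MembershipPolicy(mode=PolicyMode.SCALE)
        x = make_tsfn(0.11, 0.16, 0.22, 0.455, 0.61, 0.70, pol)
        sq = x.mu**2 + x.eta**2 + x.nu**2
        assert sq == pytest.approx(1.0, abs=1e-12)
        # direction preserved
        assert x.mu / x.eta == pytest.approx(0.455 / 0.61, abs=1e-12)

    def test_strict_policy_raises_on_excess(self):
        pol = MembershipPolicy(mode=PolicyMode.STRICT)
        with pytest.raises(ValueError, match="spherical"):
            make_tsfn(0, 0, 0, 0.9, 0.9, 0.9, pol)

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            make_tsfn(float("nan"), 0, 0, 0, 0, 0)

    def test_clamp_eps_bounds(self):
        with pytest.raises(ValueError):
            MembershipPolicy(clamp_eps=1e-3)

    @given(tsfns())
    @settings(max_examples=100, derandomize=True)
    def test_always_sorted(self, x):
        assert x.a <= x.b <= x.c

    def test_json_round_trip_is_bit_exact(self):
        x = make_tsfn(1 / 3, 2 / 7, 0.52, 0.65, 0.1234567890123456, 0.5)
        assert TSFN.from_json(x.to_json()) == x


class TestArithmetic:
    def test_add_example(self, K4, K5):
        s = T.add(K4, K5)
        assert s.triple == pytest.approx((0.67, 0.81, 0.95), **APPROX)
        assert s.mu == pytest.approx(0.895, **APPROX)
        assert s.eta == pytest.approx(0.14, **APPROX)
        assert s.nu == pytest.approx(0.20, **APPROX)

    def test_add_zero_element(self, K4):
        s = T.add(K4, ZERO)
        assert s.triple == K4.triple
        assert s.mu == K4.mu and s.eta == 0.0 and s.nu == K4.nu

    def test_multiply_example_violates_sphere_under_allow(self, K4, K5):
        p = T.multiply(K4, K5)
        assert p.triple == pytest.approx((0.1102, 0.162, 0.2236), **APPROX)
        assert p.memberships == pytest.approx((0.455, 0.61, 0.70), **APPROX)
        assert p.sphere_excess == pytest.approx(0.069125, abs=1e-6)

    def test_multiply_identity_and_annihilator(self, K4):
        assert T.multiply(K4, UNIT) == K4
        assert T.multiply(ZERO, K4).triple == (0.0, 0.0, 0.0)

    def test_scalar_multiply_example(self, K4):
        h = T.scalar_multiply(0.5, K4)
        assert h.triple == pytest.approx((0.145, 0.18, 0.215), **APPROX)
        assert h.mu == pytest.approx(1 - math.sqrt(0.30), **APPROX)
        assert h.eta == pytest.approx(math.sqrt(0.35), **APPROX)
        assert h.nu == pytest.approx(math.sqrt(0.40), **APPROX)

    def test_scalar_multiply_rejects_negative(self, K4):
        with pytest.raises(ValueError):
            T.scalar_multiply(-1.0, K4)

    def test_power_example(self, K4):
        sq = T.power(K4, 2)
        assert sq.triple == pytest.approx((0.0841, 0.1296, 0.1849), **APPROX)
        assert sq.memberships == pytest.approx((0.49, 0.5775, 0.64), **APPROX)

    def test_power_resorts_squared_mixed_sign_triple(self):
        x = make_tsfn(-0.05, 0.09, 0.23, 0.5, 0.5, 0.5)
        sq = T.power(x, 2)
        assert sq.triple == pytest.approx((0.0025, 0.0081, 0.0529), **APPROX)

    def test_fractional_power_floors_negative_components(self):
        x = make_tsfn(-0.4, 0.0, 0.09, 0.5, 0.5, 0.5)
        r = T.power(x, 0.5)
        assert r.triple == pytest.approx((0.0, 0.0, 0.3), **APPROX)

    def test_power_one_is_identity(self, K4):
        assert T.power(K4, 1) == K4

    def test_subtract_example_clamps(self, K4, K5):
        d = T.subtract(K5, K4)
        assert d.triple == pytest.approx((-0.05, 0.09, 0.23), **APPROX)
        assert d.memberships == (0.0, 1.0, 1.0)  # all three ratios clamped

    def test_subtract_zero_guard(self, K4):
        d = T.subtract(K4, ZERO)
        assert d.triple == K4.triple
        assert d.mu == K4.mu
        assert d.eta == 1.0  # eta/0 guarded to 1
        assert d.nu == K4.nu

    def test_subtract_self(self, K4):
        d = T.subtract(K4, K4)
        assert d.triple == pytest.approx(
            (K4.a - K4.c, 0.0, K4.c - K4.a), **APPROX)
        assert d.mu == 0.0 and d.eta == 1.0 and d.nu == 1.0

    def test_divide_example(self, K4, K5):
        q = T.divide(K5, K4)
        assert q.triple == pytest.approx(
            (0.38 / 0.43, 0.45 / 0.36, 0.52 / 0.29), **APPROX)
        assert q.mu == pytest.approx(0.65 / 0.70, **APPROX)
        assert q.eta == pytest.approx(0.05 / 0.65, **APPROX)
        assert q.nu == pytest.approx(0.10 / 0.60, **APPROX)

    def test_divide_self_and_zero_numerator(self, K4, K5):
        q = T.divide(K4, K4)
        assert q.b == pytest.approx(1.0, **APPROX)
        assert q.eta == 0.0 and q.nu == 0.0
        z = T.divide(ZERO, K5)
        assert z.triple == (0.0, 0.0, 0.0)
        assert T.score(z) == 0.0


class TestScoreAndOrder:
    def test_score_k5(self, K5):
        assert T.score(K5) == pytest.approx(0.2325, **APPROX)

    def test_score_zero_triple_annihilates(self):
        assert T.score(make_tsfn(0, 0, 0, 0.9, 0.2, 0.1)) == 0.0

    def test_score_unit_triple_half_memberships(self):
        assert T.score(make_tsfn(1, 1, 1, 0.5, 0.5, 0.5)) == pytest.approx(0.5)

    def test_compare_follows_score(self, scale, K4):
        assert T.compare(scale["K6"], K4) == 1
        assert T.compare(K4, K4) == 0
        assert T.compare(ZERO, scale["K0"]) == -1

    def test_compare_tie_breaks_lexicographically(self):
        # equal graded means ((a+c)/12 + b/3 = 0.1), different triples
        x = make_tsfn(-0.3, 0.3, 0.3, 1.0, 1.0, 1.0)
        y = make_tsfn(0.0, 0.24, 0.24, 1.0, 1.0, 1.0)
        assert T.score(x) == pytest.approx(T.score(y))
        assert T.compare(x, y) == -(T.compare(y, x)) != 0

    @given(tsfns(), st.floats(0.1, 3.0))
    @settings(max_examples=50, derandomize=True)
    def test_score_linear_in_triple(self, x, k):
        scaled = TSFN(k * x.a, k * x.b, k * x.c, x.mu, x.eta, x.nu)
        assert T.score(scaled) == pytest.approx(k * T.score(x), rel=1e-9,
                                                abs=1e-12)


class TestAggregation:
    def test_weighted_aggregate_example(self, K4, K5):
        agg = T.weighted_aggregate([K4, K5], [0.5, 0.5])
        assert agg.triple == pytest.approx((0.335, 0.405, 0.475), **APPROX)
        assert agg.mu == pytest.approx(1 - math.sqrt(0.30 * 0.35), **APPROX)
        assert agg.eta == pytest.approx(math.sqrt(0.35 * 0.40), **APPROX)
        assert agg.nu == pytest.approx(math.sqrt(0.40 * 0.50), **APPROX)

    def test_weighted_aggregate_contract_errors(self, K4, K5):
        with pytest.raises(ValueError):
            T.weighted_aggregate([K4, K5], [0.7, 0.7])
        with pytest.raises(ValueError):
            T.weighted_aggregate([K4], [0.5, 0.5])

    @given(tsfns(), st.integers(2, 5))
    @settings(max_examples=50, derandomize=True)
    def test_equal_weight_aggregation_is_idempotent(self, x, m):
        agg = T.weighted_aggregate([x] * m, [1.0 / m] * m)
        for got, want in zip(agg.triple + agg.memberships,
                             x.triple + x.memberships):
            assert got == pytest.approx(want, abs=1e-9)

    def test_singleton_aggregate_is_identity(self, K4):
        agg = T.weighted_aggregate([K4], [1.0])
        assert agg == K4


class TestMeanAndSD:
    def test_mean_of_singleton(self, K4):
        assert T.fuzzy_mean([K4], 1) == K4

    def test_mean_of_two_copies_recovers_term(self, K4):
        m = T.fuzzy_mean([K4, K4], 2)
        for got, want in zip(m.triple + m.memberships,
                             K4.triple + K4.memberships):
            assert got == pytest.approx(want, abs=1e-12)

    def test_mean_of_fixture_column(self, scale):
        # column C2 of the worked-example pairwise matrix
        col = [scale[c] for c in ("K4", "K5", "K4", "K4", "K4")] + [ZERO]
        m = T.fuzzy_mean(col, 6)
        assert m.triple == pytest.approx((1.54 / 6, 1.89 / 6, 2.24 / 6),
                                         **APPROX)

    def test_sd_of_constant_values_is_pure_spread(self, K4):
        # x - x has the symmetric triple (a-c, 0, c-a), so the SD of a
        # constant list reduces to the term's spread: zero left component,
        # equal mode and right components.
        sd = T.fuzzy_sd([K4, K4], K4, 1)
        assert sd.a == 0.0
        assert sd.b == pytest.approx(sd.c, abs=1e-12)
        assert sd.b == pytest.approx(math.sqrt(2) * (K4.c - K4.a), abs=1e-12)

    def test_sd_symmetric_in_argument_order(self, K4, K5):
        center = T.fuzzy_mean([K4, K5], 2)
        a = T.fuzzy_sd([K4, K5], center, 1)
        b = T.fuzzy_sd([K5, K4], center, 1)
        assert a.triple == pytest.approx(b.triple, abs=1e-12)

    def test_sd_of_spread_column_is_positive(self, scale):
        col = [scale[c] for c in ("K4", "K6", "K6", "K7", "K6")]
        center = T.fuzzy_mean(col, 5)
        sd = T.fuzzy_sd(col, center, 4)
        assert sd.b > 0

    def test_empty_inputs_rejected(self, K4):
        with pytest.raises(ValueError):
            T.fuzzy_mean([], 1)
        with pytest.raises(ValueError):
            T.fuzzy_sd([], K4, 1)


class TestAlgebraicLaws:
    @given(tsfns(), tsfns())
    @settings(max_examples=100, derandomize=True)
    def test_add_commutes(self, x, y):
        a, b = T.add(x, y), T.add(y, x)
        assert a.triple == pytest.approx(b.triple, abs=1e-12)
        assert a.memberships == pytest.approx(b.memberships, abs=1e-12)

    @given(tsfns(), tsfns(), tsfns())
    @settings(max_examples=100, derandomize=True)
    def test_add_associates(self, x, y, z):
        a = T.add(T.add(x, y), z)
        b = T.add(x, T.add(y, z))
        assert a.triple == pytest.approx(b.triple, abs=1e-9)
        assert a.memberships == pytest.approx(b.memberships, abs=1e-12)

    @given(tsfns(), st.integers(1, 5))
    @settings(max_examples=100, derandomize=True)
    def test_scalar_multiply_matches_repeated_addition(self, x, n):
        total = x
        for _ in range(n - 1):
            total = T.add(total, x)
        lam = T.scalar_multiply(n, x)
        assert lam.triple == pytest.approx(total.triple, abs=1e-9)
        assert lam.memberships == pytest.approx(total.memberships, abs=1e-9)

    @given(tsfns(), tsfns())
    @settings(max_examples=100, derandomize=True)
    def test_subtract_and_divide_are_total(self, x, y):
        for op in (T.subtract, T.divide):
            r = op(x, y)
            assert 0.0 <= r.mu <= 1.0
            assert 0.0 <= r.eta <= 1.0
            assert 0.0 <= r.nu <= 1.0
            assert r.a <= r.b <= r.c
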