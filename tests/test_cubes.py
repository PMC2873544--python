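import itertools

import numpy as np
import pytest

from hillcube import (
    ContinuousRule,
    CubeError,
    HillParameters,
    UpdateRule,
    boolecube,
    hill,
    hillcube,
    normalized_hillcube,
)

from conftest import random_rule

OR2 = UpdateRule("t", ("a", "b"), np.array([0, 1, 1, 1]))
IDENTITY = UpdateRule("t", ("a",), np.array([0, 1]))


class TestHill:
    def test_half_maximal_at_threshold(self):
        for n in range(1, 17):
            for k in np.arange(0.1, 0.95, 0.1):
                assert hill(k, HillParameters(n, k)) == pytest.approx(0.5)

    def test_zero_at_zero(self):
        assert hill(0.0, HillParameters(4, 0.3)) == 0.0

    def test_value_at_one(self):
        # 1 / (1 + 0.25)
        assert hill(1.0, HillParameters(2, 0.5)) == pytest.approx(0.8)

    def test_invalid_parameters(self):
        with pytest.raises(CubeError):
            HillParameters(0.5, 0.5)
        with pytest.raises(CubeError):
            HillParameters(2, 1.0)


class TestBooleCube:
    def test_corner_agreement_or(self):
        assert boolecube(OR2, (1.0, 0.0)) == pytest.approx(1.0)

    def test_or_at_center(self):
        # corner sum: 0*1/4 + 1/4 + 1/4 + 1/4
        assert boolecube(OR2, (0.5, 0.5)) == pytest.approx(0.75)

    def test_constant_rule(self):
        const = UpdateRule("t", (), np.array([1]))
        assert boolecube(const, ()) == 1.0

    def test_dimension_mismatch(self):
        with pytest.raises(CubeError):
            boolecube(OR2, (0.5,))

    def test_out_of_range_rejected(self):
        with pytest.raises(CubeError):
            boolecube(OR2, (1.5, 0.0))

    def test_multilinearity_second_difference(self):
        """Fixing all but one coordinate gives an affine function: the
        second difference along the free coordinate vanishes."""
        rng = np.random.default_rng(8)
        for _ in range(50):
            rule = random_rule(rng, int(rng.integers(1, 5)))
            x = rng.uniform(0, 1, size=rule.indegree)
            j = int(rng.integers(rule.indegree))
            vals = []
            for xj in (0.1, 0.45, 0.8):
                y = x.copy()
                y[j] = xj
                vals.append(boolecube(rule, y))
            assert vals[2] - 2 * vals[1] + vals[0] == pytest.approx(0.0, abs=1e-12)


class TestHillCube:
    def test_half_threshold_equals_center_boolecube(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            rule = random_rule(rng, int(rng.integers(1, 4)))
            params = tuple(
                HillParameters(float(rng.uniform(1, 8)), float(rng.uniform(0.2, 0.8)))
                for _ in range(rule.indegree)
            )
            crule = ContinuousRule(rule, params, "hillcube")
            at_k = hillcube(crule, [p.k for p in params])
            center = boolecube(rule, [0.5] * rule.indegree)
            assert at_k == pytest.approx(center)

    def test_constant_rule(self):
        crule = ContinuousRule(UpdateRule("t", (), np.array([1])), (), "hillcube")
        assert hillcube(crule, ()) == 1.0

    def test_identity_rule_direct_formula(self):
        crule = ContinuousRule(IDENTITY, (HillParameters(4, 0.5),), "hillcube")
        expected = 0.25**4 / (0.25**4 + 0.5**4)
        assert hillcube(crule, (0.25,)) == pytest.approx(expected)
        assert expected == pytest.approx(0.0588, abs=1e-4)

    def test_parameter_count_mismatch(self):
        with pytest.raises(CubeError):
            ContinuousRule(OR2, (HillParameters(3, 0.5),), "hillcube")


class TestNormalizedHillCube:
    def test_corner_agreement_exhaustive(self):
        rng = np.random.default_rng(2)
        for _ in range(50):
            rule = random_rule(rng, int(rng.integers(0, 5)))
            params = tuple(
                HillParameters(float(rng.uniform(1, 10)), float(rng.uniform(0.1, 0.9)))
                for _ in range(rule.indegree)
            )
            crule = ContinuousRule(rule, params, "hillcubenorm")
            for corner in itertools.product((0, 1), repeat=rule.indegree):
                got = normalized_hillcube(crule, [float(b) for b in corner])
                assert got == pytest.approx(float(rule(corner)), abs=1e-12)

    def test_identity_rule_value(self):
        crule = ContinuousRule(IDENTITY, (HillParameters(2, 0.5),), "hillcubenorm")
        # hill(0.5) / hill(1) = 0.5 / 0.8
        assert normalized_hillcube(crule, (0.5,)) == pytest.approx(0.625)

    def test_sharpness_limit(self):
        """At n = 200, k = 0.5 the transform is within 0.01 of the Boolean
        step applied to the rounded point, for coordinates in {0.1, 0.9}."""
        rng = np.random.default_rng(4)
        for _ in range(20):
            rule = random_rule(rng, int(rng.integers(1, 4)))
            params = tuple(
                HillParameters(200, 0.5) for _ in range(rule.indegree)
            )
            crule = ContinuousRule(rule, params, "hillcubenorm")
            for point in itertools.product((0.1, 0.9), repeat=rule.indegree):
                rounded = tuple(int(v > 0.5) for v in point)
                got = normalized_hillcube(crule, point)
                assert got == pytest.approx(float(rule(rounded)), abs=0.01)


def test_ranges():
    rng = np.random.default_rng(6)
    for _ in range(100):
        rule = random_rule(rng, int(rng.integers(1, 5)))
        params = tuple(
            HillParameters(float(rng.uniform(1, 12)), float(rng.uniform(0.1, 0.9)))
            for _ in range(rule.indegree)
        )
        x = rng.uniform(0.01, 1, size=rule.indegree)
        hc = hillcube(ContinuousRule(rule, params, "hillcube"), x)
        assert 0.0 <= boolecube(rule, x) <= 1.0
        assert 0.0 <= hc <= 1.0
        if not rule.table.all():  # a constant-1 table interpolates to 1 exactly
            assert hc < 1.0
        assert 0.0 <= normalized_hillcube(
            ContinuousRule(rule, params, "hillcubenorm"), x
        ) <= 1.0


def test_monotonicity_follows_table():
    """If B is nondecreasing in input j, all three transforms are
    nondecreasing in that coordinate along a grid."""
    rng = np.random.default_rng(9)
    checked = 0
    while checked < 20:
        rule = random_rule(rng, int(rng.integers(1, 4)))
        d = rule.indegree
        for j in range(d):
            lo = np.take(rule.table, 0, axis=j)
            hi = np.take(rule.table, 1, axis=j)
            if not (hi >= lo).all():
                continue
            params = tuple(
                HillParameters(float(rng.uniform(1, 8)), float(rng.uniform(0.2, 0.8)))
                for _ in range(d)
            )
            base = rng.uniform(0, 1, size=d)
            grid = np.linspace(0, 1, 9)
            for crule, fn in (
                (rule, lambda r, x: boolecube(r, x)),
                (ContinuousRule(rule, params, "hillcube"), hillcube),
                (ContinuousRule(rule, params, "hillcubenorm"), normalized_hillcube),
            ):
                vals = []
                for g in grid:
                    x = base.copy()
                    x[j] = g
                    vals.append(fn(crule, x))
                assert all(b - a >= -1e-12 for a, b in zip(vals, vals[1:]))
            checked += 1
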