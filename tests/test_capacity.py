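"""Capacity algebra, Choquet aggregation and least-squares identification."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tdol.capacity import (
    Capacity,
    ChoquetRegression,
    MobiusCapacity,
    check_monotone,
    choquet,
    choquet_mobius,
    fit_capacity_ls,
    from_mobius,
    interaction_matrix,
    mask_size,
    members,
    scale_minmax,
    shapley,
    to_mobius,
    unscale_minmax,
)
from tdol.exceptions import ValidationError

from conftest import random_monotone_capacity


# ---------------------------------------------------------------------------
# brute-force oracles

def shapley_by_permutations(cap: Capacity) -> np.ndarray:
    """Average marginal contribution over all attribute orderings."""
    n = cap.n
    acc = np.zeros(n)
    for perm in itertools.permutations(range(n)):
        mask = 0
        for i in perm:
            acc[i] += cap.values[mask | (1 << i)] - cap.values[mask]
            mask |= 1 << i
    return acc / math.factorial(n)


def interaction_by_enumeration(cap: Capacity) -> np.ndarray:
    """Weighted second differences over subsets of N \\ {i, j}."""
    n = cap.n
    v = cap.values
    out = np.zeros((n, n))
    fact = [math.factorial(k) for k in range(n + 1)]
    for i, j in itertools.combinations(range(n), 2):
        bi, bj = 1 << i, 1 << j
        acc = 0.0
        for mask in range(1 << n):
            if mask & (bi | bj):
                continue
            s = mask_size(mask)
            w = fact[s] * fact[n - s - 2] / fact[n - 1]
            acc += w * (v[mask | bi | bj] - v[mask | bi] - v[mask | bj] + v[mask])
        out[i, j] = out[j, i] = acc
    return out


def mobius_by_alternating_sum(cap: Capacity) -> np.ndarray:
    n = cap.n
    m = np.zeros_like(cap.values)
    for mask in range(1 << n):
        for sub in range(1 << n):
            if sub & ~mask:
                continue
            m[mask] += (-1) ** (mask_size(mask) - mask_size(sub)) * cap.values[sub]
    return m


# ---------------------------------------------------------------------------
# representation round trips

class TestMobiusTransforms:
    def test_additive_capacity_has_no_higher_order_terms(self):
        cap = Capacity.additive(("a", "b"), [0.5, 0.5])
        m = to_mobius(cap)
        assert m.coefficients[0b01] == pytest.approx(0.5)
        assert m.coefficients[0b10] == pytest.approx(0.5)
        assert m.coefficients[0b11] == pytest.approx(0.0, abs=1e-14)

    def test_single_attribute(self):
        cap = Capacity(("only",), np.array([0.0, 1.0]))
        assert to_mobius(cap).coefficients[1] == pytest.approx(1.0)

    @pytest.mark.parametrize("n", [2, 3, 4, 5, 6])
    def test_round_trip_and_alternating_sum_oracle(self, n, rng):
        for _ in range(5):
            cap = random_monotone_capacity(n, rng)
            mob = to_mobius(cap)
            assert np.allclose(mob.coefficients,
                               mobius_by_alternating_sum(cap), atol=1e-10)
            assert mob.coefficients.sum() == pytest.approx(1.0, abs=1e-10)
            back = from_mobius(mob)
            assert np.allclose(back.values, cap.values, atol=1e-12)

    def test_from_mobius_trivial_cases(self):
        m = np.zeros(4)
        m[0b01] = 1.0
        cap = from_mobius(MobiusCapacity(("a", "b"), m))
        assert cap.value(["a"]) == 1.0
        assert cap.value(["b"]) == 0.0
        assert cap.value(["a", "b"]) == 1.0
        uni = from_mobius(MobiusCapacity(
            ("a", "b", "c"),
            np.array([0, 1 / 3, 1 / 3, 0, 1 / 3, 0, 0, 0.0])))
        for size, subset in [(1, ["a"]), (2, ["a", "c"]), (3, ["a", "b", "c"])]:
            assert uni.value(subset) == pytest.approx(size / 3)

    def test_from_mobius_rejects_non_monotone(self):
        m = np.zeros(4)
        m[0b01], m[0b10], m[0b11] = 1.2, 0.3, -0.5  # v({a}) > v({a,b}) = 1
        with pytest.raises(ValidationError, match="non-monotone"):
            from_mobius(MobiusCapacity(("a", "b"), m))

    def test_capacity_validation_errors(self):
        with pytest.raises(ValidationError, match="v\\(full set\\)"):
            Capacity(("a", "b"), np.array([0.0, 0.3, 0.4, 0.9]))
        with pytest.raises(ValidationError, match="not monotone"):
            Capacity(("a", "b"), np.array([0.0, 0.6, 0.2, 0.5]) / 0.5)


class TestChoquet:
    def test_idempotency_constant_profile(self, rng):
        cap = random_monotone_capacity(3, rng)
        for c in [0.0, 0.3, 1.0]:
            assert choquet(cap, [c, c, c]) == pytest.approx(c, abs=1e-12)

    def test_max_capacity_gives_maximum(self):
        v = np.array([0.0, 1, 1, 1, 1, 1, 1, 1.0])
        cap = Capacity(("a", "b", "c"), v)
        x = [0.2, 0.9, 0.4]
        assert choquet(cap, x) == pytest.approx(0.9)

    @pytest.mark.parametrize("n", [2, 3, 4])
    def test_sorted_increment_equals_mobius_min_form(self, n, rng):
        for _ in range(10):
            cap = random_monotone_capacity(n, rng)
            mob = to_mobius(cap)
            x = rng.random(n)
            assert choquet(cap, x) == pytest.approx(
                choquet_mobius(mob, x), abs=1e-12)

    def test_monotone_in_profile(self, rng):
        cap = random_monotone_capacity(4, rng)
        x = rng.random(4) * 0.8
        x2 = np.minimum(x + rng.random(4) * 0.2, 1.0)
        assert choquet(cap, x2) >= choquet(cap, x) - 1e-12

    def test_rejects_out_of_range_and_mismatch(self, rng):
        cap = random_monotone_capacity(3, rng)
        with pytest.raises(ValidationError):
            choquet(cap, [0.5, 0.5])
        with pytest.raises(ValidationError, match="rescale"):
            choquet(cap, [0.5, 1.5, 0.2])

    @given(st.lists(st.floats(0, 1), min_size=3, max_size=3),
           st.integers(0, 2 ** 31 - 1))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_result_between_min_and_max(self, x, seed):
        cap = random_monotone_capacity(3, np.random.default_rng(seed))
        c = choquet(cap, x)
        assert min(x) - 1e-12 <= c <= max(x) + 1e-12


class TestShapleyAndInteraction:
    @pytest.mark.parametrize("n", [2, 3, 4, 5])
    def test_against_brute_force_oracles(self, n, rng):
        for _ in range(5):
            cap = random_monotone_capacity(n, rng)
            phi = shapley(cap)
            assert np.allclose(phi, shapley_by_permutations(cap), atol=1e-10)
            assert phi.sum() == pytest.approx(1.0, abs=1e-10)
            assert np.all(phi >= -1e-12)
            I = interaction_matrix(cap)
            assert np.allclose(I, interaction_by_enumeration(cap), atol=1e-10)
            assert np.allclose(I, I.T)
            assert np.allclose(np.diag(I), 0.0)
            assert np.all(np.abs(I) <= 1 + 1e-10)
            # Möbius-form computations agree with the direct forms
            mob = to_mobius(cap)
            assert np.allclose(mob.shapley(), phi, atol=1e-10)
            assert np.allclose(mob.interaction_matrix(), I, atol=1e-10)

    def test_additive_capacity_limits(self):
        w = np.array([0.1, 0.2, 0.3, 0.4])
        cap = Capacity.additive(tuple("abcd"), w)
        assert np.allclose(shapley(cap), w, atol=1e-12)
        assert np.allclose(interaction_matrix(cap), 0.0, atol=1e-12)
        x = np.array([0.3, 0.9, 0.1, 0.5])
        assert choquet(cap, x) == pytest.approx(float(w @ x), abs=1e-12)

    def test_shapley_symmetry_under_permutation(self, rng):
        cap = random_monotone_capacity(4, rng)
        perm = [2, 0, 3, 1]
        v2 = np.zeros_like(cap.values)
        for mask in range(16):
            pm = 0
            for i in members(mask, 4):
                pm |= 1 << perm[i]
            v2[pm] = cap.values[mask]
        cap2 = Capacity(tuple(f"b{i}" for i in range(4)), v2)
        phi, phi2 = shapley(cap), shapley(cap2)
        for i in range(4):
            assert phi2[perm[i]] == pytest.approx(phi[i], abs=1e-12)


class TestMonotoneCheck:
    def test_uniform_additive_clean(self):
        cap = Capacity.uniform(tuple("abc"))
        assert check_monotone(cap) == []

    def test_raw_map_reports_single_violation(self):
        viol = check_monotone((("a", "b"), [0.0, 0.6, 0.2, 0.5]), tol=1e-9)
        assert (("a",), ("a", "b")) in viol

    def test_agrees_with_exhaustive_all_pairs_check(self, rng):
        n = 4
        for _ in range(20):
            m = rng.normal(0, 0.4, size=1 << n)
            m[0] = 0.0
            m /= m.sum() if abs(m.sum()) > 1e-6 else 1.0
            v = np.zeros(1 << n)
            for mask in range(1 << n):
                v[mask] = sum(m[sub] for sub in range(1 << n)
                              if not (sub & ~mask))
            attrs = tuple(f"a{i}" for i in range(n))
            covering = check_monotone((attrs, v), tol=1e-9)
            # exhaustive S ⊆ T scan
            exhaustive_clean = True
            for s in range(1 << n):
                for t in range(1 << n):
                    if (s & ~t) == 0 and v[s] > v[t] + 1e-9:
                        exhaustive_clean = False
            assert (covering == []) == exhaustive_clean


class TestScaling:
    def test_identity_on_unit_span(self):
        x = np.array([[0.0], [0.25], [1.0]])
        s, rec = scale_minmax(x)
        assert np.allclose(s, x)
        assert not rec[0].constant

    def test_constant_column_flagged_and_centered(self):
        s, rec = scale_minmax(np.array([[3.0, 1.0], [3.0, 2.0]]))
        assert np.all(s[:, 0] == 0.5)
        assert rec[0].constant
        assert not rec[1].constant

    def test_round_trip(self, rng):
        X = rng.normal(10, 5, size=(20, 3))
        s, rec = scale_minmax(X)
        assert np.allclose(unscale_minmax(s, rec), X, atol=1e-12)


class TestChoquetRegression:
    def test_noiseless_additive_recovery(self, rng):
        w = np.array([0.4, 0.3, 0.2, 0.1])
        cap = Capacity.additive(tuple("abcd"), w)
        X = rng.random((50, 4))
        y = np.array([choquet(cap, x) for x in X])
        fit = fit_capacity_ls(X, y, k_additive=2, ridge=1e-10)
        pred = [choquet_mobius(fit.capacity, x) for x in X]
        assert np.allclose(pred, y, atol=1e-6)
        assert np.allclose(fit.interactions, 0.0, atol=1e-5)
        assert not fit.underdetermined

    def test_two_additive_recovery_within_1e4(self, rng, cap2add):
        cap = from_mobius(cap2add)
        X = rng.random((50, 4))
        y = np.array([choquet(cap, x) for x in X])
        fit = fit_capacity_ls(X, y, k_additive=2, ridge=1e-8)
        assert np.abs(fit.shapley - cap2add.shapley()).max() < 1e-4
        assert fit.shapley.sum() == pytest.approx(1.0, abs=1e-10)

    def test_three_samples_underdetermined_interpolates(self, rng):
        X = rng.random((3, 4))
        y = rng.random(3) * 0.5 + 0.25
        fit = fit_capacity_ls(X, y, k_additive=2, ridge=1e-6)
        assert fit.underdetermined
        assert fit.residual_sse < 1e-8
        assert fit.n_samples == 3
        assert fit.n_parameters == 10

    def test_ridge_zero_underdetermined_raises_unless_allowed(self, rng):
        X, y = rng.random((3, 4)), rng.random(3)
        with pytest.raises(ValidationError, match="non-unique"):
            fit_capacity_ls(X, y, k_additive=2, ridge=0.0)
        fit = fit_capacity_ls(X, y, k_additive=2, ridge=0.0,
                              allow_underdetermined=True)
        assert fit.underdetermined

    def test_objective_monotone_in_ridge(self, rng):
        X = rng.random((10, 3))
        y = rng.random(10)
        sse = []
        for ridge in [1e-1, 1e-3, 1e-6]:
            sse.append(fit_capacity_ls(X, y, k_additive=2, ridge=ridge)
                       .residual_sse)
        assert sse[0] >= sse[1] - 1e-12 >= sse[2] - 2e-12

    def test_estimator_sklearn_interface(self, rng):
        est = ChoquetRegression(k_additive=2, ridge=1e-4)
        params = est.get_params()
        assert params["k_additive"] == 2
        est.set_params(ridge=1e-3)
        X = rng.random((20, 3))
        y = np.clip(X.mean(axis=1), 0, 1)
        est.fit(X, y)
        assert est.shapley_.sum() == pytest.approx(1.0, abs=1e-10)
        r2 = est.score(X, y)
        assert r2 > 0.99
        assert est.predict(X).shape == (20,)

    def test_rejects_unscaled_inputs(self, rng):
        with pytest.raises(ValidationError, match="scale_minmax"):
            fit_capacity_ls(rng.random((5, 3)) * 10, rng.random(5))


class TestSerialization:
    def test_capacity_json_round_trip_bit_exact(self, rng):
        cap = random_monotone_capacity(4, rng)
        back = Capacity.from_json(cap.to_json())
        assert back.attributes == cap.attributes
        assert np.array_equal(back.values, cap.values)

    def test_keys_are_sorted_plus_joined(self):
        cap = Capacity.uniform(("b", "a"))
        assert set(cap.to_dict()["values"]) == {"a", "b", "a+b"}
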