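import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pcbc.core import (DIMState, build_network, dim_step, kl_divergence,
                       solve_steady_state)
from oracles import kl_minimizer


def random_network(rng, n=None, m=None, min_sv=0.0, epsilon2=1e-2):
    """Random small well-formed network; optionally well-conditioned.

    ``min_sv`` rejects near-singular feedback matrices, for which the KL
    minimiser is a flat valley and per-component comparison against an
    oracle is ill-posed.
    """
    while True:
        mm = m or int(rng.integers(2, 5))
        nn = n or int(rng.integers(1, mm + 1))
        net = build_network(rng.uniform(0.05, 1.0, (nn, mm)), epsilon2)
        if min_sv == 0.0 or np.linalg.svd(net.V, compute_uv=False).min() >= min_sv:
            return net


class TestBuildNetwork:
    def test_forced_normalisation_example(self):
        net = build_network([[2, 2], [0, 4]], epsilon2=0.01)
        np.testing.assert_allclose(net.W, [[0.5, 0.5], [0.0, 1.0]])
        np.testing.assert_allclose(net.V, [[1.0, 0.0], [1.0, 1.0]])
        np.testing.assert_allclose(net.v_row_sums, [1.0, 2.0])
        assert net.epsilon1 == pytest.approx(0.005)

    def test_zero_row_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            build_network([[1, 1], [0, 0]])

    def test_row_stochastic_unchanged(self, rng):
        raw = rng.dirichlet(np.ones(4), size=3)
        net = build_network(raw)
        np.testing.assert_allclose(net.W, raw, atol=1e-12)

    def test_negative_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            build_network([[1, -1]])

    def test_invariants(self, rng):
        for _ in range(20):
            net = random_network(rng)
            np.testing.assert_allclose(net.W.sum(axis=1), 1.0, atol=1e-9)
            np.testing.assert_allclose(net.V.max(axis=0), 1.0, atol=1e-9)
            assert net.epsilon1 == pytest.approx(
                net.epsilon2 / net.v_row_sums.max())
            assert np.all(net.W >= 0) and np.all(net.V >= 0)


class TestDimStep:
    def test_zero_in_zero_out(self):
        net = build_network([[1, 1], [1, 0]])
        state = DIMState(x=np.zeros(2), y=np.zeros(2), r=np.zeros(2),
                         e=np.zeros(2))
        out = dim_step(net, state)
        np.testing.assert_array_equal(out.y, 0.0)
        assert out.iteration == 1

    def test_single_neuron_fixed_point(self):
        # y = a reconstructs x = [a, a] exactly: e = 1, W e = 1
        net = build_network([[0.5, 0.5]])
        a = 0.7
        state = DIMState(x=np.array([a, a]), y=np.array([a]),
                         r=np.zeros(2), e=np.zeros(2))
        out = dim_step(net, state)
        assert out.y[0] == pytest.approx(a)
        np.testing.assert_allclose(out.r, [a, a])
        np.testing.assert_allclose(out.e, [1.0, 1.0])

    def test_dimension_mismatch(self):
        net = build_network([[1, 1]])
        state = DIMState(x=np.ones(3), y=np.zeros(1), r=np.zeros(3),
                         e=np.zeros(3))
        with pytest.raises(ValueError):
            dim_step(net, state)

    @given(st.integers(0, 2 ** 31 - 1))
    @settings(max_examples=30, deadline=None)
    def test_nonnegativity_closure(self, seed):
        rng = np.random.default_rng(seed)
        net = random_network(rng)
        state = DIMState(x=rng.uniform(0, 1, net.n_input),
                         y=np.zeros(net.n_prediction),
                         r=np.zeros(net.n_input), e=np.zeros(net.n_input))
        for _ in range(20):
            state = dim_step(net, state)
            for v in (state.y, state.r, state.e):
                assert np.all(v >= 0) and np.all(np.isfinite(v))


class TestSolveSteadyState:
    def test_zero_input(self):
        net = build_network([[1, 1], [1, 0]])
        st_ = solve_steady_state(net, np.zeros(2))
        np.testing.assert_array_equal(st_.y, 0.0)
        np.testing.assert_array_equal(st_.r, 0.0)

    def test_single_element_match(self, rng):
        # x equals one dictionary element scaled by c: its unit responds
        # with ~c and all others fall below the floor.
        # orthogonal elements plus one overlapping composite that must decay
        raw = np.vstack([np.eye(4), [0.5, 0.0, 0.5, 0.0]])
        net = build_network(raw)
        c = 0.8
        x = c * net.V[:, 2]  # element 2's feedback RF, scaled by c
        st_ = solve_steady_state(net, x)
        assert st_.y[2] == pytest.approx(c, rel=0.05)
        # orthogonal units stay exactly zero; the overlapping unit decays
        # to (at most) its epsilon1-scaled baseline
        others = np.delete(st_.y, 2)
        assert np.all(others <= net.epsilon1 + 1e-12)

    def test_floor_then_recompute(self, rng):
        net = random_network(rng)
        x = rng.uniform(0.1, 1.0, net.n_input)
        st_ = solve_steady_state(net, x)
        np.testing.assert_allclose(st_.r, net.V @ st_.y, atol=1e-12)
        assert np.all((st_.y == 0) | (st_.y >= 1e-3))

    def test_degenerate_composite_tie(self):
        # x = e1 + e2 with dictionary {e1, e2, e1+e2}: the KL minimiser
        # set is a continuum and the multiplicative update conserves the
        # symmetric initial ratio, so all three units stay active.
        net = build_network([[1, 0], [0, 1], [1, 1]])
        st_ = solve_steady_state(net, np.array([1.0, 1.0]))
        np.testing.assert_allclose(st_.y, [0.5, 0.5, 0.5], atol=1e-9)
        np.testing.assert_allclose(st_.r, [1.0, 1.0], atol=1e-9)

    def test_oracle_equivalence_small(self, rng):
        for _ in range(20):
            net = random_network(rng, min_sv=0.1, epsilon2=1e-3)
            x = rng.uniform(0.1, 1.0, net.n_input)
            y = solve_steady_state(net, x, n_iter=5000).y
            expected = kl_minimizer(net.V, x)
            np.testing.assert_allclose(y, expected, atol=1e-2)

    def test_perfect_match_calibration(self, rng):
        # input in the span of few dictionary columns: active units have
        # W e ~= 1 at the steady state
        net = build_network(rng.uniform(0.05, 1.0, (3, 6)))
        coef = np.array([0.6, 0.0, 0.9])
        x = net.V @ coef
        st_ = solve_steady_state(net, x, n_iter=500)
        we = net.W @ st_.e
        active = st_.y > 1e-3
        assert active.any()
        np.testing.assert_allclose(we[active], 1.0, atol=0.02)

    def test_epsilon_insensitivity(self, rng):
        # halving both epsilons changes the steady state by < 1 %
        for _ in range(10):
            raw = rng.uniform(0.05, 1.0, (3, 4))
            x = rng.uniform(0.2, 1.0, 4)
            y_a = solve_steady_state(build_network(raw, 1e-2), x).y
            y_b = solve_steady_state(build_network(raw, 5e-3), x).y
            denom = max(np.abs(y_a).max(), 1e-12)
            assert np.abs(y_a - y_b).max() / denom < 0.01


class TestKLDivergence:
    def test_identical_is_zero(self, rng):
        x = rng.uniform(0, 1, 5)
        assert kl_divergence(x, x) == pytest.approx(0.0, abs=1e-12)

    def test_closed_form_example(self):
        assert kl_divergence([1.0, 0.0], [1.0, 1.0]) == pytest.approx(1.0)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            kl_divergence([1.0], [1.0, 2.0])

    def test_nonnegative(self, rng):
        for _ in range(50):
            x = rng.uniform(0, 1, 6)
            r = np.maximum(rng.uniform(0, 1, 6), 1e-2)
            assert kl_divergence(x, r) >= -1e-12

    def test_descent_over_iterations(self, rng):
        for _ in range(30):
            net = random_network(rng)
            x = rng.uniform(0.1, 1.0, net.n_input)
            state = DIMState(x=x, y=np.zeros(net.n_prediction),
                             r=np.zeros(net.n_input), e=np.zeros(net.n_input))
            kls = []
            for _ in range(50):
                state = dim_step(net, state)
                kls.append(kl_divergence(x, net.V @ state.y))
            diffs = np.diff(kls)
            assert np.all(diffs <= 1e-6)
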