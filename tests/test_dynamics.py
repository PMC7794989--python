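"""Shifted Hill identities, steady-state enumeration vs root-finding oracle."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import optimize

import emstem as es
from emstem.dynamics import _dedup_log2, find_steady_states
from emstem.sampler import model_rng
from emstem.topology import Edge, NetworkTopology


class TestShiftedHill:
    @pytest.mark.parametrize("mu,lam,n", [(1.0, 10.0, 1), (16.0, 0.01, 4), (50.0, 3.0, 6)])
    def test_closed_form_identities(self, mu, lam, n):
        assert es.shifted_hill(0.0, mu, lam, n) == pytest.approx(1.0)
        assert es.shifted_hill(mu, mu, lam, n) == pytest.approx((1 + lam) / 2)
        assert es.shifted_hill(1e6 * mu, mu, lam, n) == pytest.approx(lam, rel=1e-4)

    @given(st.floats(0.1, 100.0), st.floats(0.01, 100.0), st.integers(1, 6))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_bounded_and_monotone(self, mu, lam, n):
        p = np.logspace(-3, 4, 60)
        h = es.shifted_hill(p, mu, lam, n)
        assert np.all(h >= min(1, lam) - 1e-12) and np.all(h <= max(1, lam) + 1e-12)
        dh = np.diff(h)
        assert np.all(dh >= -1e-12) if lam > 1 else np.all(dh <= 1e-12)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            es.shifted_hill(1.0, -1.0, 2.0, 2)
        with pytest.raises(ValueError):
            es.shifted_hill(1.0, 1.0, 2.0, 0)


def _isolated_model():
    t = NetworkTopology("one", ("A",), ())
    m = es.ModelParams("one", t.nodes, G=np.array([10.0]), g=np.array([10.0]),
                       k=np.array([1.0]), lam=np.empty(0), mu=np.empty(0),
                       n=np.empty(0, dtype=np.int64))
    return t, m


class TestRhs:
    def test_isolated_node_fixed_point(self):
        t, m = _isolated_model()
        np.testing.assert_allclose(es.rhs(np.array([10.0]), m, t), [0.0], atol=1e-12)
        np.testing.assert_allclose(es.rhs(np.array([1e-9]), m, t), [10.0], rtol=1e-6)

    def test_dimension_mismatch(self):
        t, m = _isolated_model()
        with pytest.raises(ValueError):
            es.rhs(np.array([1.0, 2.0]), m, t)

    def test_jacobian_matches_finite_differences(self):
        t = es.builtin_circuit("base")
        m = es.sample_parameter_set(t, es.SamplingRanges(), rng=model_rng(1, 0, 3))
        p = np.abs(np.random.default_rng(0).normal(10.0, 3.0, t.n_nodes))
        J = es.jacobian(p, m, t)
        eps = 1e-6
        for j in range(t.n_nodes):
            dp = np.zeros(t.n_nodes)
            dp[j] = eps * p[j]
            fd = (es.rhs(p + dp, m, t) - es.rhs(p - dp, m, t)) / (2 * dp[j])
            np.testing.assert_allclose(J[:, j], fd, rtol=1e-4, atol=1e-8)


def _toggle(g=50.0, k=1.0, lam=0.01, mu=16.0, n=4):
    t = NetworkTopology("toggle", ("A", "B"),
                        (Edge("A", "B", -1), Edge("B", "A", -1)))
    m = es.ModelParams("toggle", t.nodes, G=np.array([g, g]), g=np.array([g, g]),
                       k=np.array([k, k]), lam=np.array([lam, lam]),
                       mu=np.array([mu, mu]), n=np.array([n, n], dtype=np.int64))
    return t, m


def _oracle_toggle_roots(g, k, lam, mu, n, grid=40):
    """Exhaustive grid-seeded root finding for the symmetric 2-node toggle.

    Written directly from the model equations (independent of the package's
    rhs/jacobian); stability judged from a finite-difference Jacobian.
    """
    def hill(p):
        return (mu ** n + lam * p ** n) / (mu ** n + p ** n)

    def f(x):
        a, b = x
        return [g * hill(b) - k * a, g * hill(a) - k * b]

    seeds = np.logspace(-3, np.log10(2 * g / k), grid)
    roots = []
    for a0 in seeds:
        for b0 in seeds:
            sol = optimize.root(f, [a0, b0], method="hybr")
            if sol.success and np.all(sol.x > 0) and np.max(np.abs(f(sol.x))) < 1e-9 * g:
                roots.append(sol.x)
    roots = _dedup_log2(np.array(roots), 0.05)
    stable, unstable = [], []
    for r in roots:
        eps = 1e-6
        J = np.empty((2, 2))
        for j in range(2):
            d = np.zeros(2)
            d[j] = eps * r[j]
            J[:, j] = (np.array(f(r + d)) - np.array(f(r - d))) / (2 * d[j])
        (stable if np.max(np.linalg.eigvals(J).real) < 0 else unstable).append(r)
    return np.array(stable), np.array(unstable)


class TestSteadyStates:
    def test_single_node_linear_ode(self):
        t, m = _isolated_model()
        ics = np.array([[0.01], [1.0], [100.0], [5000.0]])
        res = find_steady_states(m, t, ics)
        assert res.n_states == 1
        np.testing.assert_allclose(res.states[0], [10.0], rtol=1e-6)
        assert res.frac_converged == 1.0

    def test_symmetric_toggle_matches_oracle(self):
        """Trajectory enumeration finds exactly the stable roots of the
        exhaustive 2-D root scan: 2 stable branches + 1 unstable saddle."""
        t, m = _toggle()
        stable, unstable = _oracle_toggle_roots(50.0, 1.0, 0.01, 16.0, 4)
        assert len(stable) == 2 and len(unstable) == 1
        ics = es.sample_initial_conditions(m, t, 50, rng=1)
        res = find_steady_states(m, t, ics)
        assert res.n_states == 2
        for s in res.states:
            d = np.min(np.max(np.abs(np.log2(stable) - np.log2(s)), axis=1))
            assert d < 0.05
        # each state has one node on the high branch and the other low
        for s in res.states:
            assert (s.max() > 40) and (s.min() < 2)

    def test_random_two_node_toggles_match_oracle(self):
        """No missed stable roots and no spurious ones across random kinetics."""
        rng = np.random.default_rng(7)
        for _ in range(8):
            g = rng.uniform(5, 100)
            lam = 1 / rng.uniform(1, 100)
            mu = rng.uniform(0.5, 1.5) * g / 2
            n = int(rng.integers(1, 7))
            t, m = _toggle(g=g, k=1.0, lam=lam, mu=mu, n=n)
            stable, _ = _oracle_toggle_roots(g, 1.0, lam, mu, n, grid=25)
            ics = es.sample_initial_conditions(m, t, 80, rng=rng.integers(2**31))
            res = find_steady_states(m, t, ics)
            assert res.n_states == len(stable)

    def test_duplicate_ics_dedup_idempotent(self):
        t, m = _toggle()
        ics = np.array([[50.0, 0.1]] * 10 + [[0.1, 50.0]] * 10)
        res = find_steady_states(m, t, ics)
        assert res.n_states == 2

    def test_states_positive_bounded_and_stable(self):
        t = es.builtin_circuit("base")
        for i in range(10):
            m = es.sample_parameter_set(t, es.SamplingRanges(), rng=model_rng(6, 0, i))
            ics = es.sample_initial_conditions(m, t, 30, rng=model_rng(6, 1, i))
            res = find_steady_states(m, t, ics)
            U = m.G / m.k
            for s in res.states:
                assert np.all(s > 0)
                assert np.all(s <= U * (1 + 1e-6))
                eig = np.linalg.eigvals(es.jacobian(s, m, t))
                assert np.max(eig.real) < 1e-8


class TestClassification:
    @pytest.mark.parametrize("n,label", [
        (1, "monostable"), (2, "bistable"), (3, "tristable"), (4, ">=4-stable"),
        (7, ">=4-stable"),
    ])
    def test_labels(self, n, label):
        assert es.classify_multistability(n) == label

    def test_zero_states_error(self):
        with pytest.raises(ValueError):
            es.classify_multistability(0)


class TestEnsemble:
    def test_deterministic_given_seed(self):
        t = es.builtin_circuit("base")
        e1 = es.run_ensemble(t, n_models=15, n_inits=20, seed=2)
        e2 = es.run_ensemble(t, n_models=15, n_inits=20, seed=2)
        f1, f2 = e1.solutions_frame(), e2.solutions_frame()
        assert f1.equals(f2)

    def test_fractions_sum_to_one(self):
        t = es.builtin_circuit("base")
        ens = es.run_ensemble(t, n_models=40, n_inits=20, seed=4)
        assert ens.multistability_fractions().sum() == pytest.approx(1.0)

    def test_invalid_counts(self):
        t = es.builtin_circuit("base")
        with pytest.raises(ValueError):
            es.run_ensemble(t, n_models=0)
        with pytest.raises(ValueError):
            es.run_ensemble(t, n_models=1, n_inits=0)
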