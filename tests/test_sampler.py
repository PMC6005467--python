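"""Mirror-walk sampler: null-space geometry, reflection arithmetic,
Metropolis rule, uniform-polytope moments, and ensemble summaries."""

import numpy as np
import pytest

from isolim.foodweb import Compartment, FoodWebModel, LIMProblem
from isolim.sampler import (ChainConfig, SampleEnsemble, metropolis_accept,
                            mirror_step, null_space_basis, propose_mirror,
                            run_chain, summarize)

from conftest import simplex_problem


class TestNullSpace:
    def test_one_equation(self):
        Z = null_space_basis(np.array([[1.0, 1.0]]))
        assert Z.shape == (2, 1)
        assert abs(Z[:, 0] @ np.array([1, -1]) / np.sqrt(2)) == pytest.approx(1.0)

    def test_pelagic_web_dimension(self, model):
        E, _, _ = model.mass_balance()
        Z = null_space_basis(E)
        assert Z.shape == (35, 26)
        assert np.abs(E @ Z).max() < 1e-10
        assert np.allclose(Z.T @ Z, np.eye(26), atol=1e-12)

    def test_motion_in_basis_preserves_equalities(self, model):
        E, _, _ = model.mass_balance()
        Z = null_space_basis(E)
        rng = np.random.default_rng(1)
        x = rng.random(35)
        q = rng.standard_normal(26)
        assert E @ (x + Z @ q) == pytest.approx(E @ x, abs=1e-10)


class TestMirrorStep:
    # 1-D interval [0, 1] written as G q >= h
    GZ = np.array([[1.0], [-1.0]])
    HQ = np.array([0.0, -1.0])

    def test_reflection_at_upper_bound(self):
        q, ok = mirror_step(np.array([0.9]), np.array([0.3]), self.GZ, self.HQ)
        assert ok and q[0] == pytest.approx(0.8)

    def test_interior_step_untouched(self):
        q, ok = mirror_step(np.array([0.4]), np.array([0.1]), self.GZ, self.HQ)
        assert ok and q[0] == pytest.approx(0.5)

    def test_long_step_folds_repeatedly(self):
        q, ok = mirror_step(np.array([0.5]), np.array([2.2]), self.GZ, self.HQ)
        assert ok and 0.0 <= q[0] <= 1.0

    def test_triangle_proposals_average_to_centroid(self):
        """10^5 mirrored uniform proposals on the 2-simplex keep its
        symmetry: the mean of proposed points matches (1/3, 1/3, 1/3)."""
        problem = simplex_problem(3)
        E = problem.E
        Z = null_space_basis(E)
        rng = np.random.default_rng(0)
        x = np.full(3, 1 / 3)
        pts = np.empty((10_000, 3))
        for i in range(10_000):
            pts[i] = propose_mirror(x, Z, np.full(2, 0.4), problem.G,
                                    problem.h, rng)
        se = pts.std(axis=0) / np.sqrt(len(pts))
        assert np.all(np.abs(pts.mean(axis=0) - 1 / 3) < 3 * se + 1e-3)


class TestMetropolis:
    def test_downhill_always_accepted(self):
        rng = np.random.default_rng(0)
        assert all(metropolis_accept(5.0, 4.9, rng) for _ in range(100))

    def test_uphill_rate_matches_formula(self):
        rng = np.random.default_rng(0)
        hits = sum(metropolis_accept(1.0, 3.0, rng) for _ in range(40_000))
        assert hits / 40_000 == pytest.approx(np.exp(-1.0), abs=0.01)

    def test_flat_likelihood_always_accepts(self):
        rng = np.random.default_rng(0)
        assert all(metropolis_accept(0.0, 0.0, rng) for _ in range(100))


class TestRunChain:
    def test_uniform_simplex_moments(self):
        """Dirichlet(1,1,1) marginals: mean 1/3, variance 1/18."""
        ens = run_chain(simplex_problem(3),
                        ChainConfig(n_iter=110_000, burn_in=10_000, thin=1,
                                    seed=5))
        n = ens.samples.shape[0]
        mean = ens.flows.mean(axis=0)
        var = ens.flows.var(axis=0)
        se_mean = ens.flows.std(axis=0) / np.sqrt(n)
        # heavy autocorrelation: inflate the naive MC error generously
        assert np.all(np.abs(mean - 1 / 3) < 3 * se_mean * 10 + 0.01)
        assert np.all(np.abs(var - 1 / 18) < 0.01)

    def test_binding_measurement_centres_posterior(self):
        comps = [Compartment("A"), Compartment("S", external=True)]
        m = FoodWebModel(comps, [("S", "A")])
        problem = LIMProblem(
            model=m, E=np.zeros((0, 1)), f=np.zeros(0),
            A=np.array([[1.0]]), b=np.array([0.5]), sigma=np.array([0.02]),
            G=np.array([[1.0], [-1.0]]), h=np.array([0.0, -1.0]))
        ens = run_chain(problem, ChainConfig(n_iter=40_000, burn_in=5_000,
                                             thin=5, seed=3))
        assert ens.flows.mean() == pytest.approx(0.5, abs=0.01)

    def test_same_seed_reproduces_ensemble(self):
        cfg = ChainConfig(n_iter=5_000, burn_in=500, thin=5, seed=11)
        e1 = run_chain(simplex_problem(4), cfg)
        e2 = run_chain(simplex_problem(4), cfg)
        assert np.array_equal(e1.samples, e2.samples)
        assert e1.acceptance_rate == e2.acceptance_rate

    def test_retained_samples_feasible(self, mesohaline_problem):
        ens = run_chain(mesohaline_problem,
                        ChainConfig(n_iter=20_000, burn_in=4_000, thin=20,
                                    seed=2))
        sub = ens.flows[:: max(1, ens.flows.shape[0] // 100)]
        assert (mesohaline_problem.G @ sub.T
                - mesohaline_problem.h[:, None]).min() >= -1e-7
        assert np.abs(mesohaline_problem.E @ sub.T
                      - mesohaline_problem.f[:, None]).max() <= 1e-8

    def test_acceptance_decreases_with_jump_scale(self, mesohaline_problem):
        rates = []
        for scale in (0.01, 0.1, 1.0):
            ens = run_chain(mesohaline_problem,
                            ChainConfig(n_iter=4_000, burn_in=0, thin=10,
                                        seed=9, jump_scale=scale, tune=False))
            rates.append(ens.acceptance_rate)
        assert rates[0] >= rates[1] >= rates[2]


class TestSummarize:
    def test_constant_samples_zero_width(self):
        ens = SampleEnsemble(samples=np.ones((50, 2)), columns=["a", "b"],
                             acceptance_rate=1.0, seed=0, n_flows=2)
        s = summarize(ens)
        assert (s["hi95"] - s["lo95"]).max() == 0.0

    def test_derived_interval_is_per_sample(self):
        rng = np.random.default_rng(0)
        data = rng.normal(size=(4_000, 2))
        ens = SampleEnsemble(samples=data, columns=["a", "b"],
                             acceptance_rate=1.0, seed=0, n_flows=2)
        s = summarize(ens, {"total": lambda row: row[0] + row[1]})
        width_sum = s.loc["total", "hi95"] - s.loc["total", "lo95"]
        width_parts = ((s.loc["a", "hi95"] - s.loc["a", "lo95"])
                       + (s.loc["b", "hi95"] - s.loc["b", "lo95"]))
        assert width_sum < width_parts  # independent errors partially cancel
        assert width_sum == pytest.approx(2 * 1.96 * np.sqrt(2), rel=0.1)

    def test_normal_quantiles_recovered(self):
        rng = np.random.default_rng(1)
        data = rng.standard_normal((50_000, 1))
        ens = SampleEnsemble(samples=data, columns=["z"], acceptance_rate=1.0,
                             seed=0, n_flows=1)
        s = summarize(ens)
        assert s.loc["z", "lo95"] == pytest.approx(-1.96, abs=0.05)
        assert s.loc["z", "hi95"] == pytest.approx(1.96, abs=0.05)

    def test_empty_ensemble_rejected(self):
        ens = SampleEnsemble(samples=np.zeros((0, 2)), columns=["a", "b"],
                             acceptance_rate=0.0, seed=0, n_flows=2)
        with pytest.raises(ValueError):
            summarize(ens)
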