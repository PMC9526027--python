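"""Sampler and diagnostics: known targets, determinism, convergence gates."""
import numpy as np
import pytest

import bmsom as bm
from bmsom.results import ConvergenceReport, OccupancyResults, _ebfmi_per_chain, _rhat
from bmsom.sampler import ChainStats, nuts_sample


def _gauss_target(dim, seed=0):
    rng = np.random.default_rng(seed)
    A = rng.standard_normal((dim, dim))
    cov = A @ A.T / dim + 0.5 * np.eye(dim)
    prec = np.linalg.inv(cov)

    def lg(x):
        return float(-0.5 * x @ prec @ x), -prec @ x

    return lg, cov


class TestNuts:
    def test_recovers_gaussian_moments(self):
        lg, cov = _gauss_target(8)
        d, st = nuts_sample(lg, np.zeros(8), 500, 1500, np.random.default_rng(2))
        se = np.sqrt(np.diag(cov) / 200)  # generous ESS-discounted error
        assert np.all(np.abs(d.mean(0)) < 4 * se * np.sqrt(1500 / 200))
        assert np.allclose(d.var(0), np.diag(cov), rtol=0.25)
        assert st.n_divergent == 0

    def test_deterministic_given_rng(self):
        lg, _ = _gauss_target(4)
        d1, _ = nuts_sample(lg, np.zeros(4), 200, 200, np.random.default_rng(5))
        d2, _ = nuts_sample(lg, np.zeros(4), 200, 200, np.random.default_rng(5))
        np.testing.assert_array_equal(d1, d2)

    def test_rejects_nonfinite_start(self):
        def bad(x):
            return -np.inf, np.zeros_like(x)

        with pytest.raises(ValueError, match="non-finite"):
            nuts_sample(bad, np.zeros(2), 10, 10, np.random.default_rng(0))


class TestFit:
    def test_fit_deterministic_given_seed(self, small_sim):
        spec = bm.ModelSpec.msom()
        bundle = bm.build_covariate_bundle(small_sim.ranges, small_sim.sites, spec)
        model = bm.OccupancyModel(small_sim.history, bundle, spec)
        r1 = model.fit(chains=1, warmup=60, draws=60, seed=9)
        r2 = model.fit(chains=1, warmup=60, draws=60, seed=9)
        np.testing.assert_array_equal(r1.draws, r2.draws)

    def test_single_chain_warns_and_diagnostics_refuse(self, small_sim):
        spec = bm.ModelSpec.msom()
        bundle = bm.build_covariate_bundle(small_sim.ranges, small_sim.sites, spec)
        model = bm.OccupancyModel(small_sim.history, bundle, spec)
        with pytest.warns(UserWarning, match="single chain"):
            res = model.fit(chains=1, warmup=60, draws=60, seed=1)
        assert res.n_draws == 60
        with pytest.raises(ValueError, match="r-hat"):
            res.convergence_report()

    def test_detection_intercept_recovered(self, tiny_fit):
        """Posterior mean of the detection intercept hyper-mean lands within
        3 posterior SDs of the generative truth."""
        sim, model, res = tiny_fit
        mu_c = res.posterior("mu_c").ravel()
        truth = sim.truth.hyperparams["mu_c"]
        assert abs(mu_c.mean() - truth) < 3 * mu_c.std()


class TestConvergenceReport:
    def _mock_results(self, draws_2chain, energy=None, divergent=0):
        class _Lay:
            slices = {"x": slice(0, 1)}

        class _Model:
            layout = _Lay()
            spec = bm.ModelSpec.msom()

        n = draws_2chain.shape[1]
        stats = []
        for ch in range(2):
            e = energy[ch] if energy is not None else np.random.default_rng(ch).normal(0, 1, n)
            div = np.zeros(n, bool)
            div[:divergent] = True if ch == 0 else False
            stats.append(
                ChainStats(
                    energy=e, divergent=div if ch == 0 else np.zeros(n, bool),
                    accept_stat=np.ones(n), treedepth=np.ones(n, int),
                    step_size=0.1, inv_mass=np.ones(1),
                )
            )
        return OccupancyResults(_Model(), draws_2chain[..., None], stats)

    def test_iid_chains_pass(self):
        rng = np.random.default_rng(0)
        d = rng.standard_normal((2, 1000))
        res = self._mock_results(d)
        rep = res.convergence_report()
        assert rep.max_rhat < 1.03
        assert rep.passed

    def test_shifted_chains_fail(self):
        rng = np.random.default_rng(0)
        d = rng.standard_normal((2, 1000))
        d[1] += 10.0
        rep = self._mock_results(d).convergence_report()
        assert rep.max_rhat > 1.03
        assert not rep.passed

    def test_any_divergence_fails_regardless_of_rhat(self):
        rng = np.random.default_rng(0)
        d = rng.standard_normal((2, 1000))
        rep = self._mock_results(d, divergent=3).convergence_report()
        assert rep.max_rhat < 1.03
        assert rep.n_divergent == 3
        assert not rep.passed

    def test_low_ebfmi_fails(self):
        rng = np.random.default_rng(1)
        d = rng.standard_normal((2, 1000))
        # near-constant energy increments against high marginal variance
        walk = np.cumsum(rng.normal(0, 0.05, 1000)) + rng.normal(0, 5)
        rep = self._mock_results(d, energy=[walk, walk]).convergence_report()
        assert rep.min_ebfmi < 0.2
        assert not rep.passed


class TestEbfmi:
    def test_iid_energy_near_two(self):
        rng = np.random.default_rng(0)
        st = ChainStats(
            energy=rng.standard_normal(5000), divergent=np.zeros(5000, bool),
            accept_stat=np.ones(5000), treedepth=np.ones(5000, int),
            step_size=0.1, inv_mass=np.ones(1),
        )
        e = _ebfmi_per_chain([st])[0]
        assert 1.7 < e < 2.3


class TestPointwise:
    def test_sum_matches_dataset_loglik(self, tiny_fit):
        """Per-cell pointwise values at one draw sum to the likelihood part of
        the joint density."""
        sim, model, res = tiny_fit
        pw = res.pointwise_loglik()
        v = res.flat_draws()[0]
        want = model.loglike(v, include_prior=False)
        assert pw.values[0].sum() == pytest.approx(want, abs=1e-8)

    def test_clipped_cells_absent(self, small_sim):
        hist, ranges, sites = small_sim.history, small_sim.ranges, small_sim.sites
        spec = bm.ModelSpec.msom()
        bundle = bm.build_covariate_bundle(ranges, sites, spec)
        d = bm.signed_distance_matrix(ranges, sites)
        mask = bm.clip_by_distance(d, max(bm.max_detection_distance(hist, d), 1.0))
        model = bm.OccupancyModel(hist, bundle, spec, mask=mask)
        res = model.fit(chains=1, warmup=50, draws=50, seed=2)
        pw = res.pointwise_loglik()
        assert pw.n_cells == mask.n_retained

    def test_constant_draws_zero_variance(self, tiny_fit):
        sim, model, res = tiny_fit
        v = res.flat_draws()[0]
        fake = OccupancyResults(model, np.tile(v, (1, 5, 1)), res.chain_stats[:1])
        pw = fake.pointwise_loglik()
        assert np.allclose(pw.values.var(axis=0), 0.0)
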