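"""Likelihood correctness: hand values, exhaustive latent-state oracle,
normalization, nesting, and gradient consistency."""
import itertools

import numpy as np
import pytest

import bmsom as bm
from bmsom.model import augmented_cell_logprob, cell_loglik

from .conftest import disc_range, toy_sites


def brute_force_logprob(psi, theta, y, retained):
    """Independent oracle: per cell, sum P(Y, Z) over Z in {0, 1}."""
    total = 0.0
    S, J, K = y.shape
    for i in range(S):
        for j in range(J):
            if not retained[i, j]:
                continue
            p_det = np.prod(theta[i, j] ** y[i, j] * (1 - theta[i, j]) ** (1 - y[i, j]))
            p0 = (1 - psi[i, j]) * (1.0 if y[i, j].sum() == 0 else 0.0)
            total += np.log(psi[i, j] * p_det + p0)
    return total


def random_instance(rng, S=2, J=3, K=2):
    sites = toy_sites(J, seed=int(rng.integers(1000)))
    ranges = [disc_range(f"sp{i}", 50, 50, 30) for i in range(S)]
    y = rng.integers(0, 2, (S, J, K)).astype(np.int8)
    hist = bm.DetectionHistory(
        y, np.ones((S, J, K), bool), [r.species_id for r in ranges],
        sites["site_id"].tolist(),
    )
    spec = bm.ModelSpec.bmsom()
    bundle = bm.build_covariate_bundle(ranges, sites, spec)
    params = bm.ParameterVector(
        a=rng.normal(0, 1, S),
        c=rng.normal(0, 1, S),
        occ_random={"elev": rng.normal(0, 1, S), "distance": rng.normal(-1, 1, S)},
    )
    return hist, bundle, spec, params


class TestCellLoglik:
    def test_hand_values(self):
        assert cell_loglik(1.0, [0.5, 0.5], [1, 0]) == pytest.approx(np.log(0.25))
        assert cell_loglik(0.5, [0.5], [0]) == pytest.approx(np.log(0.75))
        # all visits masked: unit probability
        assert cell_loglik(0.7, [0.5, 0.5], [0, 0], [False, False]) == 0.0

    def test_detection_with_psi_zero_is_impossible(self):
        with pytest.warns(UserWarning, match="impossible"):
            assert cell_loglik(0.0, [0.5], [1]) == -np.inf

    def test_normalization_over_all_histories(self):
        """Sum over all 2^K possible visit vectors of exp(cell_loglik) is 1."""
        rng = np.random.default_rng(0)
        for _ in range(20):
            K = int(rng.integers(1, 7))
            psi = rng.uniform(0.01, 0.99)
            theta = rng.uniform(0.01, 0.99, K)
            tot = sum(
                np.exp(cell_loglik(psi, theta, np.array(yv)))
                for yv in itertools.product([0, 1], repeat=K)
            )
            assert tot == pytest.approx(1.0, abs=1e-12)


class TestDatasetLogprob:
    def test_matches_exhaustive_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(30):
            hist, bundle, spec, params = random_instance(rng)
            psi, theta = bm.linear_predictors(params, bundle, spec, n_visits=2)
            theta = np.broadcast_to(theta, hist.y.shape)
            got = bm.dataset_logprob(params, bundle, hist, None, spec, include_prior=False)
            want = brute_force_logprob(psi, theta, hist.y, np.ones(psi.shape, bool))
            assert got == pytest.approx(want, abs=1e-10)

    def test_oracle_with_clipped_cell(self):
        rng = np.random.default_rng(7)
        hist, bundle, spec, params = random_instance(rng)
        # remove one detection-free cell
        det = hist.detected_anywhere_by_cell()
        free = np.argwhere(~det)
        if free.size == 0:
            hist.y[0, 0] = 0
            free = np.array([[0, 0]])
        i, j = free[0]
        retained = np.ones(det.shape, bool)
        retained[i, j] = False
        from bmsom.clipping import REASON_GEOGRAPHIC

        mask = bm.ClipMask(
            retained, np.where(retained, 0, REASON_GEOGRAPHIC).astype(np.int8)
        )
        psi, theta = bm.linear_predictors(params, bundle, spec, n_visits=2)
        theta = np.broadcast_to(theta, hist.y.shape)
        got = bm.dataset_logprob(params, bundle, hist, mask, spec, include_prior=False)
        want = brute_force_logprob(psi, theta, hist.y, retained)
        assert got == pytest.approx(want, abs=1e-10)

    def test_bmsom_with_zero_slope_reduces_to_msom(self):
        rng = np.random.default_rng(3)
        hist, bundle, spec_b, params = random_instance(rng)
        params.occ_random["distance"] = np.zeros(2)
        spec_m = bm.ModelSpec.msom()
        bundle_m = bm.build_covariate_bundle(
            [disc_range(s, 50, 50, 30) for s in hist.species_ids],
            toy_sites(3, seed=0),
            spec_m,
        )
        # same site covariates: rebuild both bundles from one site table
        sites = toy_sites(3, seed=1)
        ranges = [disc_range(s, 50, 50, 30) for s in hist.species_ids]
        bundle_b = bm.build_covariate_bundle(ranges, sites, spec_b)
        bundle_m = bm.build_covariate_bundle(ranges, sites, spec_m)
        pm = bm.ParameterVector(
            a=params.a, c=params.c, occ_random={"elev": params.occ_random["elev"]}
        )
        lb = bm.dataset_logprob(params, bundle_b, hist, None, spec_b, include_prior=False)
        lm = bm.dataset_logprob(pm, bundle_m, hist, None, spec_m, include_prior=False)
        assert lb == pytest.approx(lm, abs=1e-12)

    def test_invariant_under_reordering(self):
        rng = np.random.default_rng(11)
        hist, bundle, spec, params = random_instance(rng, S=3, J=4)
        base = bm.dataset_logprob(params, bundle, hist, None, spec, include_prior=False)
        perm = np.array([2, 0, 1])
        hist2 = bm.DetectionHistory(
            hist.y[perm], hist.visit_mask[perm],
            [hist.species_ids[i] for i in perm], hist.site_ids,
        )
        bundle2 = bm.CovariateBundle(
            species_ids=[bundle.species_ids[i] for i in perm],
            site_ids=bundle.site_ids,
            occ_site=bundle.occ_site,
            occ_species_site={
                k: v[perm] for k, v in bundle.occ_species_site.items()
            },
            det_visit=bundle.det_visit,
            scaling=bundle.scaling,
        )
        params2 = bm.ParameterVector(
            a=params.a[perm], c=params.c[perm],
            occ_random={k: v[perm] for k, v in params.occ_random.items()},
        )
        got = bm.dataset_logprob(params2, bundle2, hist2, None, spec, include_prior=False)
        assert got == pytest.approx(base, abs=1e-12)

    def test_clipping_consistency_with_tiny_psi(self):
        """Structural-zero contract: dropping a cell equals keeping it with
        psi ~ 0 and an all-zero history."""
        rng = np.random.default_rng(5)
        psi = rng.uniform(0.2, 0.8, (3, 4))
        theta = rng.uniform(0.2, 0.8, (3, 4, 2))
        y = np.zeros((3, 4, 2), np.int8)
        y[0, 0, 0] = 1  # one detection in a retained cell
        retained = np.ones((3, 4), bool)
        retained[2, 3] = False
        clipped = brute_force_logprob(psi, theta, y, retained)
        psi_eps = psi.copy()
        psi_eps[2, 3] = 1e-12
        unclipped = brute_force_logprob(psi_eps, theta, y, np.ones((3, 4), bool))
        assert clipped == pytest.approx(unclipped, abs=1e-6)


class TestAugmented:
    def test_omega_one_reduces_to_plain_sum(self):
        lls = [-0.3, -1.2]
        assert augmented_cell_logprob(1.0, lls, True) == pytest.approx(sum(lls))
        assert augmented_cell_logprob(1.0, lls, False) == pytest.approx(sum(lls))

    def test_pseudospecies_with_zero_psi_has_unit_probability(self):
        # psi ~ 0 at all sites: all-zero loglik ~ 0, mixture = (1-w) + w = 1
        assert augmented_cell_logprob(0.5, [0.0, 0.0], False) == pytest.approx(0.0)

    def test_hand_enumeration(self):
        ll = cell_loglik(0.5, [0.5], [0])
        got = augmented_cell_logprob(0.5, [ll], False)
        assert got == pytest.approx(np.log(0.5 + 0.5 * 0.75))


class TestGradient:
    @pytest.mark.parametrize("variant", ["bmsom", "msom", "augmented"])
    def test_score_matches_finite_differences(self, variant, small_sim):
        if variant == "bmsom":
            spec = bm.ModelSpec.bmsom()
            spec.det_terms = [bm.Term("time", random=False)]
        elif variant == "msom":
            spec = bm.ModelSpec.msom()
        else:
            spec = bm.ModelSpec.data_augmented(n_pseudospecies=4)
        bundle = bm.build_covariate_bundle(
            small_sim.ranges, small_sim.sites, spec,
            visit_times=small_sim.visit_times if spec.det_terms else None,
        )
        model = bm.OccupancyModel(small_sim.history, bundle, spec)
        rng = np.random.default_rng(1)
        v = 0.4 * rng.standard_normal(model.layout.dim)
        _, g = model.logp_and_grad(v)
        idx = rng.choice(model.layout.dim, size=min(25, model.layout.dim), replace=False)
        eps = 1e-6
        for i in idx:
            vp, vm = v.copy(), v.copy()
            vp[i] += eps
            vm[i] -= eps
            fd = (model.logp(vp) - model.logp(vm)) / (2 * eps)
            assert g[i] == pytest.approx(fd, rel=1e-4, abs=1e-6)

    def test_pack_unpack_round_trip(self, tiny_model):
        rng = np.random.default_rng(0)
        v = 0.5 * rng.standard_normal(tiny_model.layout.dim)
        p = tiny_model.layout.unpack(v)
        v2 = tiny_model.layout.pack(p)
        np.testing.assert_allclose(v, v2, atol=1e-10)


class TestLinearPredictors:
    def test_all_zero_coefficients_give_half(self):
        sites = toy_sites(4)
        ranges = [disc_range("sp1", 50, 50, 30)]
        spec = bm.ModelSpec.msom()
        bundle = bm.build_covariate_bundle(ranges, sites, spec)
        p = bm.ParameterVector(a=[0.0], c=[0.0], occ_random={"elev": [0.0]})
        psi, theta = bm.linear_predictors(p, bundle, spec)
        assert np.allclose(psi, 0.5) and np.allclose(theta, 0.5)

    def test_slope_shifts_logit_linearly(self):
        sites = toy_sites(2)
        ranges = [disc_range("sp1", 50, 50, 30)]
        spec = bm.ModelSpec.bmsom(elev_slope=False)
        bundle = bm.build_covariate_bundle(ranges, sites, spec)
        bundle.occ_species_site["distance"] = np.array([[1.0, 0.0]])
        p = bm.ParameterVector(a=[0.0], c=[0.0], occ_random={"distance": [-4.0]})
        psi, _ = bm.linear_predictors(p, bundle, spec)
        from scipy.special import logit

        assert logit(psi[0, 0]) - logit(psi[0, 1]) == pytest.approx(-4.0)

    def test_matches_scalar_oracle(self):
        rng = np.random.default_rng(9)
        hist, bundle, spec, params = random_instance(rng, S=3, J=4, K=2)
        psi, theta = bm.linear_predictors(params, bundle, spec, n_visits=2)
        from scipy.special import expit

        for i in range(3):
            for j in range(4):
                eta = (
                    params.a[i]
                    + params.occ_random["elev"][i] * bundle.occ_site["elev"][j]
                    + params.occ_random["distance"][i]
                    * bundle.occ_species_site["distance"][i, j]
                )
                assert psi[i, j] == pytest.approx(expit(eta), abs=1e-12)
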