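"""Range-covariate geometry and transforms, with closed-form oracles."""
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from shapely.geometry import MultiPolygon, Point

import bmsom as bm
from bmsom.covariates import unstandardize_elevation

from .conftest import disc_range, toy_sites


class TestSignedDistance:
    def test_disc_center_and_outside(self):
        r = disc_range("sp1", 0.0, 0.0, 100.0, quad_segs=4096)
        assert bm.signed_distance_to_range((0, 0), r) == pytest.approx(-100, abs=1e-3)
        assert bm.signed_distance_to_range((150, 0), r) == pytest.approx(50, abs=1e-3)

    def test_disc_closed_form_small_radius(self):
        """Signed distance agrees with |p - centre| - radius to 1e-6 km on a
        finely discretized disc."""
        r = disc_range("sp1", 3.0, -2.0, 1.0, quad_segs=8192)
        rng = np.random.default_rng(0)
        for _ in range(25):
            p = rng.uniform(-3, 8, 2)
            want = math.hypot(p[0] - 3.0, p[1] + 2.0) - 1.0
            got = bm.signed_distance_to_range(tuple(p), r)
            assert got == pytest.approx(want, abs=1e-6)

    def test_multipolygon_minimum_rule(self):
        """Point between two discs: brute force over a fine boundary
        discretization gives the min-over-parts signed rule."""
        c1, c2 = (0.0, 0.0), (50.0, 0.0)
        rad = 10.0
        geom = MultiPolygon(
            [Point(*c1).buffer(rad, quad_segs=2048), Point(*c2).buffer(rad, quad_segs=2048)]
        )
        rng_info = bm.RangeInfo("sp", geom)
        pts = np.concatenate(
            [
                np.column_stack(
                    [c[0] + rad * np.cos(t), c[1] + rad * np.sin(t)]
                )
                for c in (c1, c2)
                for t in [np.linspace(0, 2 * np.pi, 20000)]
            ]
        )
        for p in [(25.0, 0.0), (12.0, 3.0), (5.0, 5.0), (40.0, -2.0)]:
            brute = np.min(np.hypot(pts[:, 0] - p[0], pts[:, 1] - p[1]))
            inside = geom.covers(Point(*p))
            want = -brute if inside else brute
            got = bm.signed_distance_to_range(p, rng_info)
            assert got == pytest.approx(want, abs=1e-3)

    def test_continuity_across_boundary(self):
        """Finite-difference along a transect crossing the margin: jumps are
        bounded by the step size."""
        r = disc_range("sp1", 0.0, 0.0, 50.0, quad_segs=1024)
        xs = np.linspace(30.0, 70.0, 201)
        vals = [bm.signed_distance_to_range((x, 0.0), r) for x in xs]
        step = xs[1] - xs[0]
        assert np.max(np.abs(np.diff(vals))) <= step + 1e-6

    def test_empty_geometry_errors(self):
        info = bm.RangeInfo("spX", Point(0, 0).buffer(1.0))
        info.geometry = None
        with pytest.raises(ValueError, match="spX"):
            bm.signed_distance_to_range((0, 0), info)


class TestScaledInverseLogit:
    def test_closed_forms(self):
        assert bm.scaled_inverse_logit(0.0, 200.0) == pytest.approx(0.5)
        assert bm.scaled_inverse_logit(0.0, 17.0) == pytest.approx(0.5)
        assert bm.scaled_inverse_logit(200.0, 200.0) == pytest.approx(
            1 / (1 + math.exp(-1)), rel=1e-6
        )
        assert bm.scaled_inverse_logit(-2000.0, 200.0) < 1e-4

    @given(
        d=st.floats(-5000, 5000, allow_nan=False),
        s=st.floats(1.0, 1000.0, allow_nan=False),
    )
    @settings(max_examples=100, deadline=None)
    def test_symmetry_and_monotonicity(self, d, s):
        f = bm.scaled_inverse_logit
        assert f(d, s) + f(-d, s) == pytest.approx(1.0, abs=1e-12)
        if abs(d / s) < 30:  # strictly increasing away from float saturation
            assert f(d + 1.0, s) > f(d, s)
        else:
            assert f(d + 1.0, s) >= f(d, s)

    def test_requires_positive_scale(self):
        with pytest.raises(ValueError):
            bm.scaled_inverse_logit(10.0, 0.0)


class TestStandardizeElevation:
    def test_limits_map_to_unit(self):
        assert bm.standardize_elevation(2000.0, 1000.0, 2000.0) == 1.0
        assert bm.standardize_elevation(1000.0, 1000.0, 2000.0) == -1.0
        assert bm.standardize_elevation(1500.0, 1000.0, 2000.0) == 0.0
        assert bm.standardize_elevation(2500.0, 1000.0, 2000.0) == 2.0

    @given(
        lo=st.floats(-100, 3000),
        width=st.floats(1.0, 3000.0),
        e=st.floats(-500, 6000),
    )
    @settings(max_examples=100, deadline=None)
    def test_round_trip_identity(self, lo, width, e):
        hi = lo + width
        s = bm.standardize_elevation(e, lo, hi)
        back = unstandardize_elevation(s, lo, hi)
        assert back == pytest.approx(e, abs=1e-9 * max(1.0, abs(e)))

    def test_rejects_inverted_limits(self):
        with pytest.raises(ValueError):
            bm.standardize_elevation(100.0, 2000.0, 1000.0)


class TestLinearizationDiagnostic:
    def test_recovers_true_scale(self):
        """Data simulated with a 200 km transform scale select 200 from
        {50, 100, 200, 400} in most seeds."""
        hits = 0
        n_seeds = 10
        for seed in range(n_seeds):
            # moderate-sized ranges put the bulk of species-site distances in
            # the transform's informative band rather than its asymptotes
            cfg = bm.CommunityConfig(
                n_species=60, n_sites=160, seed=seed, frac_never_observable=0.0,
                mu_beta_elev=0.0, sigma_beta_elev=0.0, distance_scale_km=200.0,
                radius_km_log_mean=math.log(250.0), radius_km_log_sd=0.2,
                mu_beta_dist=-4.0, sigma_beta_dist=0.3, mu_a=2.0, sigma_a=0.3,
            )
            sim = bm.simulate_community(cfg)
            _, selected = bm.linearization_diagnostic(
                sim.history, sim.truth.signed_distance_km, [50, 100, 200, 400]
            )
            hits += selected == 200
        assert hits >= 0.9 * n_seeds

    def test_single_bin_errors(self, small_sim):
        d = np.zeros(
            (small_sim.history.n_species, small_sim.history.n_sites)
        )  # degenerate span
        with pytest.raises(ValueError, match="insufficient occupancy variation"):
            bm.linearization_diagnostic(small_sim.history, d, [100.0])

    def test_constant_proportion_tie_breaks_to_smallest(self):
        rng = np.random.default_rng(0)
        S, J = 10, 40
        d = rng.uniform(-300, 300, (S, J))
        # occupancy independent of distance -> no linear signal
        y = (rng.uniform(size=(S, J, 3)) < 0.4).astype(np.int8)
        hist = bm.DetectionHistory(
            y, np.ones_like(y, bool), [f"a{i}" for i in range(S)],
            [f"s{j}" for j in range(J)],
        )
        table, selected = bm.linearization_diagnostic(hist, d, [400.0, 100.0, 50.0])
        if table.attrs["all_scores_equal"]:
            assert selected == 50.0
        else:  # no signal: scores nearly equal, smallest ties win
            assert selected in (50.0, 100.0, 400.0)


class TestBundle:
    def test_model1_has_no_species_site_columns(self, small_sim):
        spec = bm.ModelSpec.msom()
        b = bm.build_covariate_bundle(small_sim.ranges, small_sim.sites, spec)
        assert "elev" in b.occ_site
        assert not b.occ_species_site

    def test_model2_adds_distance_matrix(self, small_sim):
        spec = bm.ModelSpec.bmsom()
        b = bm.build_covariate_bundle(small_sim.ranges, small_sim.sites, spec)
        d = b.occ_species_site["distance"]
        assert d.shape == (10, 30)
        assert ((d > 0) & (d < 1)).all()

    def test_empty_species_list_errors(self, small_sim):
        with pytest.raises(ValueError, match="empty species list"):
            bm.build_covariate_bundle([], small_sim.sites, bm.ModelSpec.msom())

    def test_missing_elev_limits_reported(self):
        sites = toy_sites(5)
        ranges = [disc_range("spA", 50, 50, 30)]  # no elevational limits
        spec = bm.ModelSpec.bmsom(distance=False, std_elev=True)
        with pytest.raises(ValueError, match="spA"):
            bm.build_covariate_bundle(ranges, sites, spec)

    def test_scaling_constants_reused(self, small_sim):
        spec = bm.ModelSpec.bmsom()
        b = bm.build_covariate_bundle(small_sim.ranges, small_sim.sites, spec)
        new_sites = small_sim.sites.iloc[:5].copy()
        b2 = bm.build_covariate_bundle(
            small_sim.ranges, new_sites, spec, reuse_scaling=b.scaling
        )
        m, s = b.scaling["elev"]
        want = (new_sites["elev_m"].to_numpy() - m) / s
        np.testing.assert_allclose(b2.occ_site["elev"], want)
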