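"""Shared fixtures: small synthetic communities and a cheap fitted model."""
import warnings

import numpy as np
import pandas as pd
import pytest
from shapely.geometry import Point

import bmsom as bm

warnings.filterwarnings("ignore", message="single chain")


@pytest.fixture(scope="session")
def small_sim():
    """A small community with both observed and never-observed species."""
    cfg = bm.CommunityConfig(n_species=10, n_sites=30, n_visits=3, seed=42)
    return bm.simulate_community(cfg)


@pytest.fixture(scope="session")
def tiny_model(small_sim):
    """An unfitted bMSOM on the small community."""
    spec = bm.ModelSpec.bmsom()
    spec.det_terms = [bm.Term("time", random=False)]
    bundle = bm.build_covariate_bundle(
        small_sim.ranges, small_sim.sites, spec, visit_times=small_sim.visit_times
    )
    return bm.OccupancyModel(small_sim.history, bundle, spec)


@pytest.fixture(scope="session")
def tiny_fit():
    """A fast 2-chain fit of a very small model, reused across tests."""
    cfg = bm.CommunityConfig(n_species=6, n_sites=18, n_visits=3, seed=7)
    sim = bm.simulate_community(cfg)
    spec = bm.ModelSpec.bmsom()
    bundle = bm.build_covariate_bundle(sim.ranges, sim.sites, spec)
    model = bm.OccupancyModel(sim.history, bundle, spec)
    res = model.fit(chains=2, warmup=150, draws=150, seed=3, target_accept=0.85)
    return sim, model, res


def toy_sites(J, seed=0, extent=100.0):
    rng = np.random.default_rng(seed)
    return pd.DataFrame(
        {
            "site_id": [f"s{j:03d}" for j in range(J)],
            "x_km": rng.uniform(0, extent, J),
            "y_km": rng.uniform(0, extent, J),
            "elev_m": rng.uniform(0, 3000, J),
        }
    )


def disc_range(species_id, cx, cy, radius, quad_segs=256, **kw):
    return bm.RangeInfo(
        species_id, Point(cx, cy).buffer(radius, quad_segs=quad_segs), **kw
    )
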