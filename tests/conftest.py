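import numpy as np
import pytest

import nichedyn as nd
from nichedyn.calibration import shared_range_masks


@pytest.fixture(scope="session")
def geometry():
    return nd.GridGeometry(origin_x=-10.0, origin_y=30.0, cell_size=0.25, nrows=40, ncols=40)


@pytest.fixture(scope="session")
def landscape(geometry):
    return nd.generate_landscape(
        11,
        geometry,
        autocorrelation_range=2.0,
        cross_correlation=nd.default_cross_correlation(),
        n_regions=8,
    )


@pytest.fixture(scope="session")
def species_surfaces(landscape):
    """A null virtual species analysed end-to-end on the session landscape."""
    climate, regions = landscape
    k = len(nd.BASE_VARIABLES)
    native_mask, alien_mask = shared_range_masks(climate.geometry.shape)
    spec = nd.VirtualSpeciesSpec(
        name="fixture_species",
        covariance=np.eye(k) * 0.45**2,
        n_native=150,
        n_alien=150,
        seed=17,
    )
    occ = nd.sample_virtual_species(spec, climate, native_mask, alien_mask)
    occ, background = nd.assign_background(occ, regions, climate)
    env = nd.fit_pca_env(background.pooled_climate(nd.VARIABLES), R=60)
    occ_values = {
        s: climate.values_at(
            occ.loc[occ["status"] == s, "row"],
            occ.loc[occ["status"] == s, "col"],
            nd.VARIABLES,
        )
        for s in ("native", "alien")
    }
    bg_values = {s: background.climate(s, nd.VARIABLES) for s in ("native", "alien")}
    scores = {s: env.transform(v) for s, v in occ_values.items()}
    grids = {
        s: nd.build_niche_grid(env, scores[s], env.transform(bg_values[s]), s)
        for s in ("native", "alien")
    }
    return {
        "climate": climate,
        "regions": regions,
        "occ": occ,
        "background": background,
        "env": env,
        "occ_values": occ_values,
        "bg_values": bg_values,
        "scores": scores,
        "grids": grids,
    }


def random_occupancy(rng, shape=(12, 12)):
    """A random unit-sum surface with some structural zeros."""
    z = rng.random(shape) * (rng.random(shape) > 0.3)
    if z.sum() == 0:
        z[0, 0] = 1.0
    return z / z.sum()
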