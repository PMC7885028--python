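import numpy as np
import pandas as pd
import pytest

from paimpact.forest_change import compute_loss
from paimpact.synthetic_landscape import Landscape, SimulationConfig, generate_landscape

#: covariates used throughout (continuous GRFs + derived initial forest +
#: region dummies)
COVARIATES = ["elevation", "slope", "dist_road", "pop_density", "initial_forest", "region_id"]

#: covariates that are confounded by construction in `confounded_config`
SITING_COEFS = {"elevation": 1.2, "slope": 0.8, "dist_road": 1.0, "initial_forest": 0.8}


def confounded_config(seed=0, grid=30, **kw):
    base = dict(
        grid_nx=grid,
        grid_ny=grid,
        seed=seed,
        pa_siting_coefs=dict(SITING_COEFS),
        loss_coefs={"elevation": -0.03, "dist_road": -0.02, "pop_density": 0.02},
        loss_intercept=0.08,
        pa_fraction=0.15,
        n_regions=3,
        n_municipalities=10,
        pa_clumping_range=12.0,
        pa_clumping_sd=2.0,
    )
    base.update(kw)
    return SimulationConfig(**base)


def null_config(seed=0, grid=20, **kw):
    base = dict(
        grid_nx=grid,
        grid_ny=grid,
        seed=seed,
        pa_siting_coefs={},
        loss_coefs={},
        true_protection_effect=0.0,
        sac_noise_sd=0.0,
        white_noise_sd=0.02,
        pa_clumping_sd=0.0,
        pa_fraction=0.2,
    )
    base.update(kw)
    return SimulationConfig(**base)


@pytest.fixture(scope="session")
def confounded_landscape():
    landscape, truth = generate_landscape(confounded_config())
    return landscape, truth


@pytest.fixture(scope="session")
def confounded_loss(confounded_landscape):
    landscape, _ = confounded_landscape
    return compute_loss(landscape)


def make_landscape(
    protected,
    covariates=None,
    forest_start=None,
    forest_end=None,
    region=None,
    municipality=None,
    nx=None,
):
    """Hand-build a minimal valid Landscape from per-cell arrays."""
    protected = np.asarray(protected, bool)
    n = len(protected)
    nx = nx or int(np.ceil(np.sqrt(n)))
    cells = pd.DataFrame(
        {
            "cell_id": np.arange(n),
            "x": (np.arange(n) % nx).astype(float),
            "y": (np.arange(n) // nx).astype(float),
            "region_id": 0 if region is None else np.asarray(region),
            "municipality_id": 0 if municipality is None else np.asarray(municipality),
            "protected": protected,
            "pa_id": np.where(protected, 1.0, np.nan),
            "iucn_cat": np.where(protected, "II", ""),
        }
    )
    for name, vals in (covariates or {}).items():
        cells[f"cov_{name}"] = np.asarray(vals, float)
    cells["forest_2000"] = 1.0 if forest_start is None else np.asarray(forest_start, float)
    cells["forest_2015"] = 0.5 if forest_end is None else np.asarray(forest_end, float)
    return Landscape(cells, (2000, 2015))
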