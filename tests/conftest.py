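import numpy as np
import pandas as pd
import pytest

from ecocline import synthetic_data as sd

BASE_COV = 0.0016 * (np.full((4, 4), 0.3) + 0.7 * np.eye(4))


@pytest.fixture
def trait_model() -> sd.TraitGenModel:
    """Traits linked to cover (except upper mandible), correlated covariance."""
    return sd.TraitGenModel(
        cover_slopes=(0.0012, 0.0016, 0.0014, 0.0),
        covariance=BASE_COV.copy(),
    )


@pytest.fixture
def flat_model() -> sd.TraitGenModel:
    """No trait-cover association at all."""
    return sd.TraitGenModel(covariance=BASE_COV.copy())


@pytest.fixture
def steep_spec() -> sd.RegionSpec:
    return sd.RegionSpec(
        name="Central",
        lat_range=(2.0, 8.0),
        lon_range=(10.0, 12.0),
        cover_intercept=95.0,
        cover_slope=-14.0,
        noise_sd=4.0,
    )


def make_sites(region: str, cover_forest: float, cover_ecotone: float,
               n_forest_sites: int = 2, n_ecotone_sites: int = 2) -> pd.DataFrame:
    """Minimal site table without going through a raster."""
    rows = []
    for i in range(n_forest_sites):
        rows.append((f"{region}-F{i}", 0.0, 3.0, region, "forest", cover_forest))
    for i in range(n_ecotone_sites):
        rows.append((f"{region}-E{i}", 0.0, 6.0, region, "ecotone", cover_ecotone))
    return pd.DataFrame(rows, columns=sd.SITE_COLUMNS)


def make_two_region_dataset(
    model: sd.TraitGenModel,
    seed: int,
    central_covers=(85.0, 30.0),
    west_covers=(45.0, 40.0),
    n_central: int = 20,
    n_west: int = 10,
) -> pd.DataFrame:
    """Steep reference region + flattened focal region, per-site n individuals."""
    central = make_sites("Central", *central_covers)
    west = make_sites("West", *west_covers)
    morph_c = sd.generate_individuals(central, model, n_central, seed=seed)
    morph_w = sd.generate_individuals(west, model, n_west, seed=seed + 1)
    return pd.concat([morph_c, morph_w], ignore_index=True)
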