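"""Synthetic rasters, sites, and individuals with configurable structure.

The generator produces every input the downstream analysis consumes: a
percent-tree-cover raster with a linear latitudinal trend, noise and
deforestation patches; sampling sites labelled by a potential-forest mask;
and individuals whose log-scale trait means are linear in site tree cover,
with region-specific covariance matrices that are equal, proportional, or
unrelated by configuration.

Traits are lognormal (normal on the log scale) so that the downstream
log-transform regressions are exactly linear in expectation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ecocline._rng import substream
from ecocline.raster import KM_PER_DEGREE, TreeCoverRaster

__all__ = [
    "DEFAULT_TRAITS",
    "RegionSpec",
    "TraitGenModel",
    "HabitatRule",
    "generate_tree_cover_raster",
    "trend_forest_mask",
    "generate_sites",
    "generate_individuals",
    "generate_historical_cohort",
]

DEFAULT_TRAITS = ("tarsus", "wing", "tail", "upper_mandible")

SITE_COLUMNS = ["site_id", "lon", "lat", "region", "habitat", "tree_cover"]
MORPH_COLUMNS = [
    "individual_id",
    "site_id",
    "region",
    "habitat",
    "era",
    "collection_year",
    *DEFAULT_TRAITS,
]


@dataclass(frozen=True)
class RegionSpec:
    """Configuration for one region's tree-cover gradient.

    ``cover_intercept`` is the noise-free cover at the southern edge
    (``lat_range[0]``); cover declines (or rises) linearly with latitude at
    ``cover_slope`` percent per degree.  A fraction of pixels is
    "deforested" by subtracting ``deforestation_depth`` percent.
    """

    name: str
    lat_range: tuple[float, float]
    lon_range: tuple[float, float]
    cover_intercept: float
    cover_slope: float
    noise_sd: float = 0.0
    deforestation_fraction: float = 0.0
    deforestation_depth: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.deforestation_fraction <= 1.0:
            raise ValueError("deforestation_fraction must lie in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.lat_range[1] <= self.lat_range[0]:
            raise ValueError("lat_range must be nondegenerate (min < max)")
        if self.lon_range[1] <= self.lon_range[0]:
            raise ValueError("lon_range must be nondegenerate (min < max)")

    def trend(self, lat: np.ndarray | float) -> np.ndarray | float:
        """Noise-free expected cover at a latitude, before clipping."""
        return self.cover_intercept + self.cover_slope * (lat - self.lat_range[0])


@dataclass(frozen=True)
class TraitGenModel:
    """Lognormal trait model: log-trait mean linear in percent tree cover.

    For region ``scaled_region`` the covariance is multiplied by
    ``region_scale`` (1 = equal matrices, any other positive value =
    proportional matrices).  To emulate *unrelated* covariances, generate
    the regions with two separate models.
    """

    traits: tuple[str, ...] = DEFAULT_TRAITS
    log_intercepts: tuple[float, ...] = (2.95, 4.14, 4.07, 2.40)
    cover_slopes: tuple[float, ...] = (0.0, 0.0, 0.0, 0.0)
    covariance: np.ndarray = field(
        default_factory=lambda: 0.002 * np.eye(len(DEFAULT_TRAITS))
    )
    region_scale: float = 1.0
    scaled_region: str | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        cov = np.asarray(self.covariance, dtype=float)
        object.__setattr__(self, "covariance", cov)
        p = len(self.traits)
        if cov.shape != (p, p):
            raise ValueError("covariance must be trait x trait")
        if not np.allclose(cov, cov.T):
            raise ValueError("covariance must be symmetric")
        try:
            np.linalg.cholesky(cov)
        except np.linalg.LinAlgError as exc:
            raise ValueError("covariance must be positive definite") from exc
        if not self.region_scale > 0:
            raise ValueError("region_scale must be > 0")
        if len(self.log_intercepts) != p or len(self.cover_slopes) != p:
            raise ValueError("per-trait parameter lengths must match traits")

    def mean_log(self, cover: float) -> np.ndarray:
        return np.asarray(self.log_intercepts) + np.asarray(self.cover_slopes) * cover

    def covariance_for(self, region: str | None) -> np.ndarray:
        if self.scaled_region is not None and region == self.scaled_region:
            return self.covariance * self.region_scale
        return self.covariance


# ---------------------------------------------------------------------------
# rasters
# ---------------------------------------------------------------------------


def generate_tree_cover_raster(
    spec: RegionSpec, resolution_km: float, seed: int
) -> TreeCoverRaster:
    """Simulate a percent-tree-cover raster for one region.

    Pixel value = clip(trend(lat) + N(0, noise_sd), 0, 100); afterwards a
    Bernoulli(``deforestation_fraction``) subset of pixels is reduced by
    ``deforestation_depth`` (clipped at 0).  Identical seeds reproduce the
    raster exactly.
    """
    if not resolution_km > 0:
        raise ValueError("resolution_km must be > 0")
    cell = resolution_km / KM_PER_DEGREE
    nrows = int(np.ceil((spec.lat_range[1] - spec.lat_range[0]) / cell))
    ncols = int(np.ceil((spec.lon_range[1] - spec.lon_range[0]) / cell))
    if nrows < 1 or ncols < 1:
        raise ValueError("empty raster extent")

    rng = substream(seed, f"raster:{spec.name}")
    lat_max = spec.lat_range[0] + nrows * cell
    lat_centers = lat_max - (np.arange(nrows) + 0.5) * cell
    trend = np.asarray(spec.trend(lat_centers))[:, None] * np.ones((1, ncols))
    noise = rng.normal(0.0, spec.noise_sd, size=trend.shape) if spec.noise_sd else 0.0
    values = np.clip(trend + noise, 0.0, 100.0)
    if spec.deforestation_fraction > 0 and spec.deforestation_depth != 0:
        hit = rng.random(values.shape) < spec.deforestation_fraction
        values = np.where(hit, values - spec.deforestation_depth, values)
        values = np.clip(values, 0.0, 100.0)
    return TreeCoverRaster(
        values=values,
        lat_min=spec.lat_range[0],
        lon_min=spec.lon_range[0],
        pixel_size=cell,
        region=spec.name,
        epoch=None,
    )


def trend_forest_mask(
    spec: RegionSpec, raster: TreeCoverRaster, forest_min_cover: float = 60.0
) -> np.ndarray:
    """Potential-forest mask from the *noise-free* trend of ``spec``.

    Because the mask depends only on the deterministic trend, habitat labels
    never depend on realized cover noise or deforestation: a deforested
    pixel inside the potential-forest zone is still labelled forest.
    """
    lat = raster.lat_centers()
    trend = np.clip(np.asarray(spec.trend(lat)), 0.0, 100.0)
    return np.repeat((trend >= forest_min_cover)[:, None], raster.ncols, axis=1)


# ---------------------------------------------------------------------------
# sites
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class HabitatRule:
    """Habitat assignment: a potential-forest mask plus a cover threshold.

    ``forest_mask`` marks pixels inside the potential-forest zone; those
    pixels are forest regardless of realized cover.  If no mask is given,
    one is cut from realized cover at ``forest_min_cover`` (documented
    fallback; the mask route is the deterministic one).  Ecotone pixels are
    the complement with cover inside ``ecotone_cover_range``.
    """

    forest_mask: np.ndarray | None = None
    forest_min_cover: float = 60.0
    ecotone_cover_range: tuple[float, float] = (5.0, 60.0)


def generate_sites(
    raster: TreeCoverRaster,
    n_forest: int,
    n_ecotone: int,
    habitat_rule: HabitatRule,
    seed: int,
) -> pd.DataFrame:
    """Sample site locations from a raster under a habitat rule.

    Sites carry the tree-cover value of their pixel.  Raises if a habitat
    has fewer eligible pixels than requested.
    """
    if n_forest < 0 or n_ecotone < 0:
        raise ValueError("site counts must be >= 0")
    values = raster.values
    valid = np.isfinite(values)
    if habitat_rule.forest_mask is not None:
        fmask = np.asarray(habitat_rule.forest_mask, dtype=bool)
        if fmask.shape != values.shape:
            raise ValueError("forest_mask shape must match raster")
    else:
        fmask = values >= habitat_rule.forest_min_cover
    lo, hi = habitat_rule.ecotone_cover_range
    emask = ~fmask & (values >= lo) & (values <= hi)

    rng = substream(seed, "sites")
    lat = raster.lat_centers()
    lon = raster.lon_centers()
    rows = []
    for habitat, mask, n_req in (
        ("forest", fmask & valid, n_forest),
        ("ecotone", emask & valid, n_ecotone),
    ):
        idx = np.flatnonzero(mask.ravel())
        if len(idx) < n_req:
            raise ValueError(
                f"only {len(idx)} eligible {habitat} pixels for {n_req} sites"
            )
        if n_req == 0:
            continue
        chosen = np.sort(rng.choice(idx, size=n_req, replace=False))
        r, c = np.unravel_index(chosen, values.shape)
        for k, (ri, ci) in enumerate(zip(r, c), start=1):
            rows.append(
                {
                    "site_id": f"{raster.region or 'R'}-{habitat[0].upper()}{k:02d}",
                    "lon": lon[ci],
                    "lat": lat[ri],
                    "region": raster.region or "R",
                    "habitat": habitat,
                    "tree_cover": values[ri, ci],
                }
            )
    return pd.DataFrame(rows, columns=SITE_COLUMNS)


# ---------------------------------------------------------------------------
# individuals
# ---------------------------------------------------------------------------


def _draw_log_traits(
    model: TraitGenModel,
    cover: float,
    region: str | None,
    n: int,
    rng: np.random.Generator,
    shift: np.ndarray | None = None,
) -> np.ndarray:
    mean = model.mean_log(cover)
    if shift is not None:
        mean = mean + shift
    cov = model.covariance_for(region)
    return rng.multivariate_normal(mean, cov, size=n, method="cholesky")


def generate_individuals(
    sites: pd.DataFrame,
    model: TraitGenModel,
    n_per_site: int | dict,
    seed: int | None = None,
    era: str = "contemporary",
    collection_year: int = 2000,
) -> pd.DataFrame:
    """Draw individuals at each site from the lognormal trait model.

    Log-traits are multivariate normal with mean linear in site cover;
    traits are reported in mm (exponentiated).
    """
    if seed is None:
        seed = model.seed
    rng = substream(seed, f"individuals:{era}")
    rows: list[pd.DataFrame] = []
    next_id = 1
    for site in sites.itertuples(index=False):
        n = n_per_site[site.site_id] if isinstance(n_per_site, dict) else int(n_per_site)
        if n < 0:
            raise ValueError("per-site counts must be >= 0")
        if n == 0:
            continue
        logs = _draw_log_traits(model, site.tree_cover, site.region, n, rng)
        block = pd.DataFrame(np.exp(logs), columns=list(model.traits))
        block.insert(0, "individual_id", np.arange(next_id, next_id + n))
        block.insert(1, "site_id", site.site_id)
        block.insert(2, "region", site.region)
        block.insert(3, "habitat", site.habitat)
        block.insert(4, "era", era)
        block.insert(5, "collection_year", collection_year)
        rows.append(block)
        next_id += n
    if not rows:
        return pd.DataFrame(columns=MORPH_COLUMNS)
    return pd.concat(rows, ignore_index=True)


def generate_historical_cohort(
    model: TraitGenModel,
    era_shift: np.ndarray | tuple | float,
    n: int,
    seed: int,
    cover: float = 70.0,
    region: str = "Central",
    habitat: str = "forest",
    site_id: str = "museum",
    sites: pd.DataFrame | None = None,
    n_per_site: int | dict | None = None,
) -> pd.DataFrame:
    """Draw a museum cohort from a pre-shift trait model.

    Rows are tagged ``era='historical'`` with collection years strictly
    before 1935; log-trait means are offset by ``era_shift`` (per trait, or
    a scalar applied to all traits).
    """
    if n < 1 and sites is None:
        raise ValueError("n must be >= 1")
    shift = np.broadcast_to(np.asarray(era_shift, dtype=float), (len(model.traits),))
    rng = substream(seed, "historical")

    def _block(cover, region, habitat, site_id, count, start_id):
        logs = _draw_log_traits(model, cover, region, count, rng, shift=shift)
        years = rng.integers(1890, 1935, size=count)
        block = pd.DataFrame(np.exp(logs), columns=list(model.traits))
        block.insert(0, "individual_id", np.arange(start_id, start_id + count))
        block.insert(1, "site_id", site_id)
        block.insert(2, "region", region)
        block.insert(3, "habitat", habitat)
        block.insert(4, "era", "historical")
        block.insert(5, "collection_year", years)
        return block

    if sites is not None:
        if n_per_site is None:
            raise ValueError("n_per_site required when sites are given")
        blocks, next_id = [], 1
        for site in sites.itertuples(index=False):
            cnt = (
                n_per_site[site.site_id]
                if isinstance(n_per_site, dict)
                else int(n_per_site)
            )
            if cnt == 0:
                continue
            blocks.append(
                _block(site.tree_cover, site.region, site.habitat, site.site_id, cnt, next_id)
            )
            next_id += cnt
        return pd.concat(blocks, ignore_index=True)
    return _block(cover, region, habitat, site_id, n, 1)
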