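"""Site-level phenotype-on-cover regressions and raster projection maps."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from ecocline.raster import KM_PER_DEGREE, TreeCoverRaster

__all__ = [
    "TraitModel",
    "ScreenResult",
    "site_trait_means",
    "weighted_trait_regression",
    "project_trait",
    "trait_cover_association_screen",
]


@dataclass
class TraitModel:
    """Weighted least-squares fit of a site-mean trait on percent tree cover."""

    trait: str
    transform: str  # log | none | pc-score
    slope: float
    intercept: float
    slope_se: float
    r_squared: float
    p: float
    n_sites: int
    weight_rule: str = "sample_size"

    def predict(self, cover: np.ndarray) -> np.ndarray:
        return self.intercept + self.slope * np.asarray(cover, dtype=float)


def site_trait_means(
    morph: pd.DataFrame,
    sites: pd.DataFrame,
    value_cols: list[str],
    site_col: str = "site_id",
) -> pd.DataFrame:
    """Per-site means of trait columns with site covariates and sample size.

    Joins the per-site aggregate of ``value_cols`` with the site table's
    coordinates, habitat and tree cover; ``n`` is the individual count.
    """
    agg = morph.groupby(site_col)[value_cols].mean()
    agg["n"] = morph.groupby(site_col).size()
    out = sites.merge(agg, left_on="site_id", right_index=True, how="inner")
    return out.reset_index(drop=True)


def weighted_trait_regression(
    site_means: pd.DataFrame,
    trait: str,
    value_col: str | None = None,
    cover_col: str = "tree_cover",
    weight_col: str = "n",
    transform: str = "log",
) -> TraitModel:
    """WLS of a site-mean trait on site percent cover, weights = sample size.

    ``value_col`` defaults to ``trait``; ``transform`` records the scale the
    site means are on (``log``, ``none`` or ``pc-score``) so projection
    knows whether to back-transform.
    """
    value_col = value_col or trait
    sub = site_means[[value_col, cover_col, weight_col]].dropna()
    if len(sub) < 3:
        raise ValueError("weighted regression needs >= 3 sites")
    w = sub[weight_col].to_numpy(dtype=float)
    if np.any(w <= 0):
        raise ValueError("weights (sample sizes) must be > 0")
    x = sub[cover_col].to_numpy(dtype=float)
    if np.isclose(np.var(x), 0.0):
        raise ValueError("zero tree-cover variance across sites")
    y = sub[value_col].to_numpy(dtype=float)
    fit = sm.WLS(y, sm.add_constant(x), weights=w).fit()
    return TraitModel(
        trait=trait,
        transform=transform,
        slope=float(fit.params[1]),
        intercept=float(fit.params[0]),
        slope_se=float(fit.bse[1]),
        r_squared=float(fit.rsquared),
        p=float(fit.pvalues[1]),
        n_sites=len(sub),
    )


def _block_reduce_mean(values: np.ndarray, factor: int) -> np.ndarray:
    """NaN-aware block mean; partial edge blocks average available pixels."""
    nr, nc = values.shape
    pr = (-nr) % factor
    pc = (-nc) % factor
    padded = np.pad(values, ((0, pr), (0, pc)), constant_values=np.nan)
    blocks = padded.reshape(
        padded.shape[0] // factor, factor, padded.shape[1] // factor, factor
    )
    with np.errstate(invalid="ignore"):
        return np.nanmean(np.nanmean(blocks, axis=3), axis=1)


def project_trait(
    raster: TreeCoverRaster,
    model: TraitModel,
    aggregate_km: float | None = None,
    back_transform_after_aggregation: bool = True,
) -> TreeCoverRaster:
    """Predict the trait per pixel from cover and aggregate by block means.

    Predictions are ``intercept + slope * cover``; for log-scale traits the
    map is back-transformed by exponentiation, after aggregation by default.
    Nodata propagates.  The returned raster reuses the cover raster's grid
    (coarsened by the aggregation factor) and is NOT range-validated as
    cover.
    """
    native_km = raster.pixel_size * KM_PER_DEGREE
    pred = model.predict(raster.values)
    factor = 1
    if aggregate_km is not None:
        if aggregate_km < native_km * (1 - 1e-9):
            raise ValueError("aggregate_km is below the native resolution")
        factor = max(1, int(round(aggregate_km / native_km)))
    if model.transform == "log" and not back_transform_after_aggregation:
        pred = np.exp(pred)
    if factor > 1:
        pred = _block_reduce_mean(pred, factor)
    if model.transform == "log" and back_transform_after_aggregation:
        pred = np.exp(pred)
    out = raster.copy_with(
        values=np.zeros_like(pred),  # placeholder; bypass cover-range validation
        pixel_size=raster.pixel_size * factor,
        epoch=f"projection:{model.trait}",
    )
    out.values = pred
    return out


@dataclass
class ScreenResult:
    kept: list[str]
    excluded: list[str]
    models: dict[str, TraitModel]


def trait_cover_association_screen(
    site_means: pd.DataFrame,
    traits: list[str],
    alpha: float = 0.05,
    transforms: dict[str, str] | None = None,
    **regression_kwargs,
) -> ScreenResult:
    """Keep traits whose cover-regression slope is significant at ``alpha``.

    Traits failing the screen are excluded from divergence testing and
    projection.  Returns the fitted models for audit.
    """
    transforms = transforms or {}
    kept, excluded, models = [], [], {}
    for trait in traits:
        model = weighted_trait_regression(
            site_means,
            trait,
            transform=transforms.get(trait, "log"),
            **regression_kwargs,
        )
        models[trait] = model
        (kept if model.p <= alpha else excluded).append(trait)
    return ScreenResult(kept=kept, excluded=excluded, models=models)
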