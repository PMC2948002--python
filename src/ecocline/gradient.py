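"""Gradient steepness from rasters: latitudinal band means, region
alignment, slope-interaction ANCOVA, and deforestation masking."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf

from ecocline.raster import KM_PER_DEGREE, GridMismatchError, TreeCoverRaster

__all__ = [
    "TreeCoverRaster",
    "AncovaResult",
    "band_means",
    "align_regions",
    "gradient_ancova",
    "deforestation_mask",
]

BAND_COLUMNS = ["region", "band_center_lat", "mean_cover", "n_pixels", "shifted", "shift_deg"]


def band_means(raster: TreeCoverRaster, band_width_km: float) -> pd.DataFrame:
    """Mean cover per latitudinal band of width ``band_width_km``.

    Bands are half-open intervals [low, high) anchored at the raster's
    southern edge (1 degree = 111.32 km).  The mean is the arithmetic mean
    over non-nodata pixels; bands with no valid pixel are omitted.

    Returns a data frame with columns ``region, band_center_lat,
    mean_cover, n_pixels, shifted, shift_deg``.
    """
    if not band_width_km > 0:
        raise ValueError("band_width_km must be > 0")
    if not np.isfinite(raster.values).any():
        raise ValueError("raster is entirely nodata")
    band_deg = band_width_km / KM_PER_DEGREE
    lat = raster.lat_centers()
    band_idx_rows = np.floor((lat - raster.lat_min) / band_deg).astype(int)

    rows = []
    for idx in np.unique(band_idx_rows):
        sel = raster.values[band_idx_rows == idx]
        n = int(np.isfinite(sel).sum())
        if n == 0:
            continue
        rows.append(
            {
                "region": raster.region or "R",
                "band_center_lat": raster.lat_min + (idx + 0.5) * band_deg,
                "mean_cover": float(np.nanmean(sel)),
                "n_pixels": n,
                "shifted": False,
                "shift_deg": 0.0,
            }
        )
    out = pd.DataFrame(rows, columns=BAND_COLUMNS)
    return out.sort_values("band_center_lat", ignore_index=True)


def align_regions(series: pd.DataFrame, shift_deg: float) -> pd.DataFrame:
    """Shift a band series southward by ``shift_deg`` degrees.

    Only ``band_center_lat`` changes; means are untouched.  Shifts
    accumulate in ``shift_deg`` so a +s then -s round trip is the identity.
    """
    out = series.copy()
    out["band_center_lat"] = out["band_center_lat"] - shift_deg
    out["shift_deg"] = out["shift_deg"] + shift_deg
    out["shifted"] = out["shift_deg"] != 0.0
    return out


@dataclass
class AncovaResult:
    """OLS fit of band mean cover on region, latitude and their interaction."""

    intercepts: dict[str, float]
    slopes: dict[str, float]
    anova: pd.DataFrame  # index: region / latitude / interaction; cols: F, p, df
    resid_dof: int
    unit: str = "band_means"

    @property
    def interaction_F(self) -> float:
        return float(self.anova.loc["interaction", "F"])

    @property
    def interaction_p(self) -> float:
        return float(self.anova.loc["interaction", "p"])


def gradient_ancova(series_a: pd.DataFrame, series_b: pd.DataFrame) -> AncovaResult:
    """Test for region-dependent gradient slope on band means.

    Fits ``mean_cover ~ region + latitude + region:latitude`` by ordinary
    least squares and reports partial F tests for each term plus per-region
    slope estimates.  The analysis unit is the band mean (recorded in
    ``unit``).
    """
    df = pd.concat([series_a, series_b], ignore_index=True)
    counts = df.groupby("region")["mean_cover"].count()
    if len(counts) != 2:
        raise ValueError("exactly two regions required")
    if (counts < 3).any():
        raise ValueError("each region needs >= 3 bands")
    for region, sub in df.groupby("region"):
        if np.isclose(sub["band_center_lat"].var(ddof=0), 0.0):
            raise ValueError(f"zero latitude variance in region {region!r}")

    fit = smf.ols("mean_cover ~ C(region) * band_center_lat", data=df).fit()
    an = sm.stats.anova_lm(fit, typ=2)

    regions = sorted(df["region"].unique())
    base, other = regions
    params = fit.params
    inter_key = f"C(region)[T.{other}]:band_center_lat"
    reg_key = f"C(region)[T.{other}]"
    slopes = {
        base: float(params["band_center_lat"]),
        other: float(params["band_center_lat"] + params[inter_key]),
    }
    intercepts = {
        base: float(params["Intercept"]),
        other: float(params["Intercept"] + params[reg_key]),
    }
    rows = {
        "region": "C(region)",
        "latitude": "band_center_lat",
        "interaction": inter_key.replace(f"[T.{other}]", ""),
    }
    anova = pd.DataFrame(
        {
            "F": [float(an.loc[v, "F"]) for v in rows.values()],
            "p": [float(an.loc[v, "PR(>F)"]) for v in rows.values()],
            "df": [float(an.loc[v, "df"]) for v in rows.values()],
        },
        index=list(rows),
    )
    return AncovaResult(
        intercepts=intercepts,
        slopes=slopes,
        anova=anova,
        resid_dof=int(fit.df_resid),
    )


def _nearest_resample(src: TreeCoverRaster, template: TreeCoverRaster) -> np.ndarray:
    """Nearest-neighbour resample of ``src`` onto ``template``'s grid."""
    lat_t = template.lat_centers()
    lon_t = template.lon_centers()
    ri = np.clip(
        np.round((src.lat_max - lat_t) / src.pixel_size - 0.5).astype(int),
        0,
        src.nrows - 1,
    )
    ci = np.clip(
        np.round((lon_t - src.lon_min) / src.pixel_size - 0.5).astype(int),
        0,
        src.ncols - 1,
    )
    return src.values[np.ix_(ri, ci)]


def deforestation_mask(
    cover_t0: TreeCoverRaster,
    cover_t1: TreeCoverRaster,
    threshold_pct: float = 10.0,
    resample: bool = False,
) -> TreeCoverRaster:
    """Binary raster marking pixels whose cover dropped MORE than the threshold.

    The comparison is strict (> threshold): a drop of exactly 10 with
    threshold 10 is not masked.  Nodata in either epoch propagates.  If the
    grids differ, ``resample=True`` resamples t1 onto t0's grid by nearest
    neighbour; otherwise a :class:`GridMismatchError` is raised.
    """
    if cover_t0.same_grid(cover_t1):
        t1_vals = cover_t1.values
    elif resample:
        t1_vals = _nearest_resample(cover_t1, cover_t0)
    else:
        raise GridMismatchError("rasters are not co-registered; pass resample=True")
    drop = cover_t0.values - t1_vals
    mask = np.where(np.isnan(drop), np.nan, (drop > threshold_pct).astype(float))
    return cover_t0.copy_with(values=mask, epoch="deforestation_mask")
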