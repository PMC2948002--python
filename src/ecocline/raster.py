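"""Single-band geographic rasters on a regular lat/lon grid.

Rasters are stored row 0 = northernmost, matching the ESRI ASCII grid
convention used for on-disk interchange.  Nodata is ``NaN`` in memory and a
sentinel value (default -1) on disk.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

__all__ = ["KM_PER_DEGREE", "TreeCoverRaster", "GridMismatchError"]

#: Conversion used for all band widths and resolutions (km per degree latitude).
KM_PER_DEGREE = 111.32


class GridMismatchError(ValueError):
    """Two rasters do not share the same grid (shape, origin, pixel size)."""


@dataclass
class TreeCoverRaster:
    """Percent tree cover (0-100) on a regular geographic grid.

    Parameters
    ----------
    values
        2-D float array, row 0 = northernmost row, NaN = nodata.
    lat_min, lon_min
        Southern / western edge of the grid, in degrees.
    pixel_size
        Pixel edge length in degrees (square pixels).
    region, epoch
        Optional provenance labels.
    """

    values: np.ndarray
    lat_min: float
    lon_min: float
    pixel_size: float
    region: str | None = None
    epoch: str | None = None
    nodata: float = field(default=-1.0, repr=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.size == 0:
            raise ValueError("raster values must be a nonempty 2-D array")
        if not self.pixel_size > 0:
            raise ValueError("pixel size must be > 0")
        finite = self.values[np.isfinite(self.values)]
        if finite.size and (finite.min() < 0 or finite.max() > 100):
            raise ValueError("non-nodata cover values must lie in [0, 100]")

    # -- geometry ----------------------------------------------------------

    @property
    def nrows(self) -> int:
        return self.values.shape[0]

    @property
    def ncols(self) -> int:
        return self.values.shape[1]

    @property
    def lat_max(self) -> float:
        return self.lat_min + self.nrows * self.pixel_size

    @property
    def lon_max(self) -> float:
        return self.lon_min + self.ncols * self.pixel_size

    def lat_centers(self) -> np.ndarray:
        """Latitude of each row centre, in row order (north to south)."""
        return self.lat_max - (np.arange(self.nrows) + 0.5) * self.pixel_size

    def lon_centers(self) -> np.ndarray:
        return self.lon_min + (np.arange(self.ncols) + 0.5) * self.pixel_size

    def same_grid(self, other: "TreeCoverRaster", tol: float = 1e-9) -> bool:
        return (
            self.values.shape == other.values.shape
            and abs(self.lat_min - other.lat_min) <= tol
            and abs(self.lon_min - other.lon_min) <= tol
            and abs(self.pixel_size - other.pixel_size) <= tol
        )

    def copy_with(self, **kwargs) -> "TreeCoverRaster":
        return replace(self, **kwargs)

    # -- I/O (ESRI ASCII grid: plain text, GIS-readable) -------------------

    def write_ascii(self, path: str | Path) -> Path:
        """Write as an ESRI ASCII grid (text; nodata encoded as sentinel)."""
        path = Path(path)
        vals = np.where(np.isfinite(self.values), self.values, self.nodata)
        header = (
            f"ncols {self.ncols}\n"
            f"nrows {self.nrows}\n"
            f"xllcorner {self.lon_min!r}\n"
            f"yllcorner {self.lat_min!r}\n"
            f"cellsize {self.pixel_size!r}\n"
            f"NODATA_value {self.nodata!r}\n"
        )
        with path.open("w") as fh:
            fh.write(header)
            np.savetxt(fh, vals, fmt="%.6g")
        return path

    @classmethod
    def read_ascii(
        cls,
        path: str | Path,
        region: str | None = None,
        epoch: str | None = None,
    ) -> "TreeCoverRaster":
        path = Path(path)
        header: dict[str, float] = {}
        with path.open() as fh:
            for _ in range(6):
                key, val = fh.readline().split()
                header[key.lower()] = float(val)
            vals = np.loadtxt(fh)
        vals = np.atleast_2d(vals)
        nodata = header.get("nodata_value", -1.0)
        vals = np.where(vals == nodata, np.nan, vals)
        return cls(
            values=vals,
            lat_min=header["yllcorner"],
            lon_min=header["xllcorner"],
            pixel_size=header["cellsize"],
            region=region,
            epoch=epoch,
            nodata=nodata,
        )
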