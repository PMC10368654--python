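"""Co-registered environmental grids for one climate period.

An :class:`EnvStack` bundles named benthic predictor layers (temperatures,
nutrients, salinity, ice thickness), bathymetry, and two boolean masks on a
shared north-up lon/lat grid with cell-centre registration:

* ``ocean_mask`` — cells below the period's sea level;
* ``habitat_mask`` — ocean cells within 30 m of the period's sea surface,
  the depth band the modelled species occupies.

Latitude runs north to south along rows, longitude west to east along
columns. Bathymetry is metres relative to *present* sea level (negative
below it), so glacial stacks with lowered sea level shift both masks rather
than the bathymetry itself.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict

import numpy as np
import pandas as pd


class GeometryError(ValueError):
    """Raised when layers or stacks do not share grid geometry."""


@dataclass
class EnvStack:
    layers: Dict[str, np.ndarray]
    bathymetry: np.ndarray
    ocean_mask: np.ndarray
    habitat_mask: np.ndarray
    lon: np.ndarray  # 1-D cell-centre longitudes, ascending
    lat: np.ndarray  # 1-D cell-centre latitudes, descending (north-up)
    period: str = "present"
    attrs: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.lon = np.asarray(self.lon, dtype=float)
        self.lat = np.asarray(self.lat, dtype=float)
        shape = self.shape
        for name, arr in list(self.layers.items()):
            arr = np.asarray(arr, dtype=float)
            if arr.shape != shape:
                raise GeometryError(f"layer {name!r} has shape {arr.shape}, expected {shape}")
            self.layers[name] = arr
        self.bathymetry = np.asarray(self.bathymetry, dtype=float)
        self.ocean_mask = np.asarray(self.ocean_mask, dtype=bool)
        self.habitat_mask = np.asarray(self.habitat_mask, dtype=bool)
        for name, arr in (("bathymetry", self.bathymetry), ("ocean_mask", self.ocean_mask), ("habitat_mask", self.habitat_mask)):
            if arr.shape != shape:
                raise GeometryError(f"{name} has shape {arr.shape}, expected {shape}")
        if np.any(self.habitat_mask & ~self.ocean_mask):
            raise GeometryError("habitat mask must be a subset of the ocean mask")

    # ---------------------------------------------------------------- geometry
    @property
    def shape(self) -> tuple:
        return (self.lat.size, self.lon.size)

    @property
    def resolution(self) -> float:
        if self.lon.size > 1:
            return float(abs(self.lon[1] - self.lon[0]))
        return float(abs(self.lat[1] - self.lat[0]))

    @property
    def predictors(self) -> list:
        return list(self.layers)

    def same_geometry(self, other: "EnvStack") -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.lon, other.lon)
            and np.allclose(self.lat, other.lat)
        )

    def require_same_geometry(self, other: "EnvStack") -> None:
        if not self.same_geometry(other):
            raise GeometryError("stacks do not share grid geometry")

    # ------------------------------------------------------------------ lookup
    def cell_of(self, lon, lat) -> tuple:
        """(row, col) indices of the cells containing the given points."""
        res = self.resolution
        col = np.rint((np.asarray(lon, dtype=float) - self.lon[0]) / res).astype(int)
        row = np.rint((self.lat[0] - np.asarray(lat, dtype=float)) / res).astype(int)
        nrow, ncol = self.shape
        if np.any((col < 0) | (col >= ncol) | (row < 0) | (row >= nrow)):
            raise ValueError("point outside grid extent")
        return row, col

    def extract(self, lon, lat) -> pd.DataFrame:
        """Predictor values at the cells containing the given points."""
        row, col = self.cell_of(lon, lat)
        data = {name: arr[row, col] for name, arr in self.layers.items()}
        return pd.DataFrame(data)

    def habitat_table(self) -> pd.DataFrame:
        """Long table of habitat cells: row, col, lon, lat and predictors."""
        rows, cols = np.nonzero(self.habitat_mask)
        out = pd.DataFrame(
            {
                "row": rows,
                "col": cols,
                "lon": self.lon[cols],
                "lat": self.lat[rows],
            }
        )
        for name, arr in self.layers.items():
            out[name] = arr[rows, cols]
        return out
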