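"""Gridded suitability surfaces and binary ranges on a regular 0.5-degree lattice.

Coordinates are cell centres on a WGS84 lon/lat lattice with exactly
0.5-degree spacing, longitude in (-180, 180], latitude in [-90, 90].
``suitability`` and ``presence`` arrays are indexed ``[lat, lon]``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd

from .errors import InvalidInputError, SchemaError

GRID_STEP = 0.5


def _check_lattice(coords: np.ndarray, name: str) -> None:
    if coords.ndim != 1 or coords.size < 1:
        raise InvalidInputError(f"{name} must be a non-empty 1-D array")
    if coords.size > 1:
        steps = np.diff(coords)
        if not np.allclose(steps, GRID_STEP, atol=1e-9):
            raise SchemaError(
                f"{name} lattice spacing must be exactly {GRID_STEP} degrees; "
                f"found steps {np.unique(np.round(steps, 6))}"
            )


@dataclass
class SuitabilityGrid:
    """Climate-suitability surface for one species, season and scenario.

    Attributes
    ----------
    lon, lat : 1-D arrays of cell-centre coordinates (0.5-degree lattice).
    suitability : 2-D array ``[lat, lon]`` of values in [0, 1].
    mask : 2-D boolean array of valid-domain cells (default all valid).
    species_id, season, scenario : metadata labels.
    attrs : free-form metadata (e.g. the generating blob parameters for
        synthetic surfaces).
    """

    lon: np.ndarray
    lat: np.ndarray
    suitability: np.ndarray
    mask: np.ndarray | None = None
    species_id: str = ""
    season: str = ""
    scenario: str = ""
    attrs: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.lon = np.asarray(self.lon, dtype=float)
        self.lat = np.asarray(self.lat, dtype=float)
        self.suitability = np.asarray(self.suitability, dtype=float)
        _check_lattice(self.lon, "lon")
        _check_lattice(self.lat, "lat")
        if self.suitability.shape != (self.lat.size, self.lon.size):
            raise InvalidInputError(
                f"suitability shape {self.suitability.shape} does not match "
                f"lattice ({self.lat.size}, {self.lon.size})"
            )
        if self.mask is None:
            self.mask = np.ones_like(self.suitability, dtype=bool)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.suitability.shape:
                raise InvalidInputError("mask shape does not match suitability")
        if not self.mask.any():
            raise InvalidInputError("grid has no valid cells")
        valid = self.suitability[self.mask]
        if np.any(valid < -1e-12) or np.any(valid > 1.0 + 1e-12):
            raise InvalidInputError("suitability values must lie in [0, 1]")
        np.clip(self.suitability, 0.0, 1.0, out=self.suitability)

    @property
    def shape(self) -> tuple[int, int]:
        return self.suitability.shape

    def cell_centres(self) -> tuple[np.ndarray, np.ndarray]:
        """Meshgrid of cell-centre (lon, lat), each shaped like ``suitability``."""
        lon2, lat2 = np.meshgrid(self.lon, self.lat)
        return lon2, lat2

    def to_frame(self) -> pd.DataFrame:
        """Long-format view: one row per valid cell (lon, lat, suitability)."""
        lon2, lat2 = self.cell_centres()
        m = self.mask
        return pd.DataFrame(
            {
                "lon": lon2[m],
                "lat": lat2[m],
                "suitability": self.suitability[m],
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame, **metadata: Any) -> "SuitabilityGrid":
        """Build a grid from a long table with columns lon, lat, suitability.

        Cells absent from the table are masked invalid.
        """
        for col in ("lon", "lat", "suitability"):
            if col not in df.columns:
                raise SchemaError(f"grid table missing required column {col!r}")
        lon = np.unique(np.asarray(df["lon"], dtype=float))
        lat = np.unique(np.asarray(df["lat"], dtype=float))
        _check_lattice(lon, "lon")
        _check_lattice(lat, "lat")
        suit = np.zeros((lat.size, lon.size))
        mask = np.zeros((lat.size, lon.size), dtype=bool)
        i = np.searchsorted(lat, np.asarray(df["lat"], dtype=float))
        j = np.searchsorted(lon, np.asarray(df["lon"], dtype=float))
        suit[i, j] = np.asarray(df["suitability"], dtype=float)
        mask[i, j] = True
        return cls(lon=lon, lat=lat, suitability=suit, mask=mask, **metadata)


@dataclass
class BinaryRange:
    """Presence/absence lattice derived from a suitability surface."""

    lon: np.ndarray
    lat: np.ndarray
    presence: np.ndarray
    threshold_used: float

    def __post_init__(self) -> None:
        self.lon = np.asarray(self.lon, dtype=float)
        self.lat = np.asarray(self.lat, dtype=float)
        self.presence = np.asarray(self.presence, dtype=bool)
        _check_lattice(self.lon, "lon")
        _check_lattice(self.lat, "lat")
        if self.presence.shape != (self.lat.size, self.lon.size):
            raise InvalidInputError("presence shape does not match lattice")

    @property
    def n_cells(self) -> int:
        return int(self.presence.sum())

    @property
    def is_empty(self) -> bool:
        return not self.presence.any()
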