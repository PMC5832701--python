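"""Suitability-weighted journey sampling, stopover counting and duration.

A migratory journey is sampled by drawing one non-breeding and one
breeding cell (each weighted by climate suitability within the species'
binary range), flying the great-circle between them, refuelling at
stopovers whenever the on-board fat is exhausted, and summing flight and
stopover time.  Repeating the draw (1000 times by default) yields a
distribution of journeys per species and scenario.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import geo
from .errors import EmptyRangeError, InvalidInputError
from .flight import FlightParams, SpeciesTraits, flight_range
from .grids import GRID_STEP, BinaryRange, SuitabilityGrid

__all__ = [
    "Journey",
    "JourneyEnsemble",
    "species_rng",
    "sample_cell",
    "sample_cells",
    "count_stopovers",
    "journey_duration",
    "simulate_journeys",
    "journey_corridor",
]

JOURNEY_COLUMNS = [
    "species_id", "scenario", "origin_lon", "origin_lat",
    "dest_lon", "dest_lat", "distance_km", "n_stopovers",
    "flight_hours", "duration_days",
]


@dataclass(frozen=True)
class Journey:
    """One sampled migration from a non-breeding to a breeding cell."""

    origin: tuple[float, float]       # (lon, lat)
    destination: tuple[float, float]  # (lon, lat)
    distance_km: float
    n_stopovers: int
    flight_hours: float
    duration_days: float


@dataclass
class JourneyEnsemble:
    """Replicated journey simulation for one species under one scenario.

    ``journeys`` holds one row per replicate with the columns of
    :data:`JOURNEY_COLUMNS`; ``summary`` recomputes means and sample
    standard deviations directly from that table.
    """

    species_id: str
    scenario: str
    journeys: pd.DataFrame
    rng_seed: int | None = None

    @property
    def n_reps(self) -> int:
        return len(self.journeys)

    @property
    def summary(self) -> dict[str, float]:
        out: dict[str, float] = {"species_id_n": float(self.n_reps)}
        for col in ("distance_km", "n_stopovers", "duration_days"):
            v = self.journeys[col].to_numpy(dtype=float)
            out[f"mean_{col}"] = float(v.mean())
            out[f"sd_{col}"] = float(v.std(ddof=1)) if v.size > 1 else 0.0
        return out

    def metric_values(self, metric: str) -> np.ndarray:
        if metric not in self.journeys.columns:
            raise KeyError(metric)
        return self.journeys[metric].to_numpy(dtype=float)


def species_rng(seed: int | None, species_id: str) -> np.random.Generator:
    """Deterministic per-species RNG stream.

    Derived from the top-level seed and a CRC32 of the species label so
    per-species results do not depend on iteration order.
    """
    tag = zlib.crc32(species_id.encode("utf-8"))
    entropy = [tag] if seed is None else [int(seed), tag]
    return np.random.default_rng(np.random.SeedSequence(entropy))


def _presence_weights(grid: SuitabilityGrid, range_: BinaryRange):
    if range_.is_empty:
        raise EmptyRangeError(
            f"{grid.species_id or 'grid'} ({grid.season} {grid.scenario}): "
            "no presence cells to sample from"
        )
    sel = range_.presence & grid.mask
    if not sel.any():
        raise EmptyRangeError("presence cells all fall outside the valid domain")
    lon2, lat2 = grid.cell_centres()
    w = grid.suitability[sel].astype(float)
    if w.sum() <= 0.0:
        w = np.ones_like(w)  # degenerate all-zero weights: fall back to uniform
    return lon2[sel], lat2[sel], w / w.sum()


def sample_cells(grid: SuitabilityGrid, range_: BinaryRange, n: int,
                 rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Draw ``n`` presence-cell centres weighted by suitability (with replacement)."""
    lons, lats, p = _presence_weights(grid, range_)
    idx = rng.choice(lons.size, size=n, replace=True, p=p)
    return lons[idx], lats[idx]


def sample_cell(grid: SuitabilityGrid, range_: BinaryRange,
                rng: np.random.Generator) -> tuple[float, float]:
    """Draw one presence cell, probability proportional to its suitability."""
    lons, lats = sample_cells(grid, range_, 1, rng)
    return float(lons[0]), float(lats[0])


def count_stopovers(distance, range_initial: float, range_post: float):
    """Minimum number of refuelling stopovers to cover ``distance`` km.

    The first leg uses the pre-migration range, every later leg the
    post-stopover range; a bird exactly at its maximum range has arrived.
    Vectorised over ``distance``.
    """
    if not (range_initial > 0 and range_post > 0):
        raise InvalidInputError("flight ranges must be positive")
    d = np.asarray(distance, dtype=float)
    if np.any(d < 0):
        raise InvalidInputError("distance must be non-negative")
    # 1e-9 relative slack keeps exact-boundary floats on the 'arrived' side
    legs = np.ceil((d - range_initial) / range_post - 1e-9)
    n = np.where(d <= range_initial, 0, np.maximum(legs, 0)).astype(int)
    if np.ndim(distance) == 0:
        return int(n)
    return n


def journey_duration(distance, n_stopovers, mean_speed: float,
                     flight_period: str, params: FlightParams):
    """Total migration duration in days (fractional).

    Flight hours are ``distance / (3.6 * mean_speed)``; flying is limited
    to the nightly (9 h) or daily (15 h) window, and each stopover adds
    ``stopover_days``.  Vectorised over distance / stopover count.
    """
    d = np.asarray(distance, dtype=float)
    n = np.asarray(n_stopovers, dtype=float)
    if np.any(d < 0) or np.any(n < 0):
        raise InvalidInputError("distance and stopovers must be non-negative")
    if np.any(d > 0) and not mean_speed > 0:
        raise InvalidInputError("mean_speed must be positive for a non-zero journey")
    hours_per_day = params.daily_flight_hours(flight_period)
    flight_hours = np.where(d > 0, d / (mean_speed * 3.6 if mean_speed > 0 else 1.0), 0.0)
    days = flight_hours / hours_per_day + params.stopover_days * n
    if np.ndim(distance) == 0 and np.ndim(n_stopovers) == 0:
        return float(days)
    return days


def simulate_journeys(
    breeding: tuple[SuitabilityGrid, BinaryRange],
    nonbreeding: tuple[SuitabilityGrid, BinaryRange],
    traits: SpeciesTraits,
    params: FlightParams,
    n_reps: int = 1000,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    scenario: str = "",
    performance: tuple | None = None,
) -> JourneyEnsemble:
    """Sample ``n_reps`` spring journeys (non-breeding -> breeding).

    Stopover counting uses the flight range at the pre-migration fat load
    for the first leg and at the post-stopover fat load for subsequent
    legs; the species' typical speed is the mean speed of the
    pre-migration range simulation.

    ``performance`` may carry precomputed ``(perf_initial, perf_post)``
    FlightPerformance pairs to avoid re-running the flight simulation for
    every scenario of the same species.
    """
    if rng is None:
        rng = species_rng(seed, traits.species_id)
    if performance is None:
        perf_init = flight_range(traits, params.fat_fraction_initial, params)
        perf_post = flight_range(traits, params.fat_fraction_stopover, params)
    else:
        perf_init, perf_post = performance

    b_grid, b_range = breeding
    nb_grid, nb_range = nonbreeding
    try:
        o_lon, o_lat = sample_cells(nb_grid, nb_range, n_reps, rng)
        d_lon, d_lat = sample_cells(b_grid, b_range, n_reps, rng)
    except EmptyRangeError as err:
        raise EmptyRangeError(f"{traits.species_id}: {err}") from err

    dist = np.atleast_1d(geo.great_circle_distance(o_lon, o_lat, d_lon, d_lat))
    n_stop = count_stopovers(dist, perf_init.range_km, perf_post.range_km)
    speed = perf_init.mean_speed
    flight_hours = np.where(dist > 0, dist / (speed * 3.6), 0.0)
    duration = journey_duration(dist, n_stop, speed, traits.flight_period, params)

    table = pd.DataFrame(
        {
            "species_id": traits.species_id,
            "scenario": scenario,
            "origin_lon": o_lon,
            "origin_lat": o_lat,
            "dest_lon": d_lon,
            "dest_lat": d_lat,
            "distance_km": dist,
            "n_stopovers": n_stop,
            "flight_hours": flight_hours,
            "duration_days": np.atleast_1d(duration),
        },
        columns=JOURNEY_COLUMNS,
    )
    return JourneyEnsemble(traits.species_id, scenario, table, rng_seed=seed)


def journey_corridor(ensemble: JourneyEnsemble,
                     longitude_grid: np.ndarray | None = None,
                     lower: float = 5.0, upper: float = 95.0) -> pd.DataFrame:
    """Central journey corridor: per-longitude latitude percentile band.

    For every longitude in ``longitude_grid`` (default: the 0.5-degree
    lattice spanning all journeys), the latitude at which each journey's
    great-circle path crosses that longitude is interpolated; the
    ``lower``-``upper`` percentile interval of those latitudes is the
    corridor.  Longitudes crossed by no journey are returned with
    ``covered=False`` and NaN bounds rather than an error.
    """
    if ensemble.n_reps == 0:
        raise InvalidInputError("empty ensemble")
    j = ensemble.journeys
    o_lon = j["origin_lon"].to_numpy(float)
    o_lat = j["origin_lat"].to_numpy(float)
    d_lon = j["dest_lon"].to_numpy(float)
    d_lat = j["dest_lat"].to_numpy(float)

    if longitude_grid is None:
        lo = math.floor(min(o_lon.min(), d_lon.min()) / GRID_STEP) * GRID_STEP
        hi = math.ceil(max(o_lon.max(), d_lon.max()) / GRID_STEP) * GRID_STEP
        longitude_grid = np.arange(lo, hi + GRID_STEP / 2, GRID_STEP)
    longitude_grid = np.asarray(longitude_grid, dtype=float)

    lon_min = np.minimum(o_lon, d_lon)
    lon_max = np.maximum(o_lon, d_lon)
    rows = []
    for lon in longitude_grid:
        covers = (lon_min <= lon) & (lon <= lon_max)
        lats = geo.gc_latitude_at_longitude(
            o_lon[covers], o_lat[covers], d_lon[covers], d_lat[covers], lon
        )
        lats = np.atleast_1d(lats)
        # meridional journeys (NaN crossing) only cover their own longitude
        same_meridian = covers & (np.abs(o_lon - d_lon) < 1e-9)
        extra = np.concatenate([
            lats[np.isfinite(lats)],
            o_lat[same_meridian & (np.abs(o_lon - lon) < 1e-9)],
        ])
        if extra.size == 0:
            rows.append((lon, np.nan, np.nan, 0, False))
        else:
            lo_lat, hi_lat = np.percentile(extra, [lower, upper])
            rows.append((lon, lo_lat, hi_lat, extra.size, True))
    return pd.DataFrame(
        rows, columns=["lon", "lat_lower", "lat_upper", "n_journeys", "covered"]
    )
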