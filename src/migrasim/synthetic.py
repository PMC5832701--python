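"""Synthetic inputs: trait tables, Gaussian suitability surfaces and mock tracks.

The downstream pipeline consumes only (a) a species trait table,
(b) gridded suitability surfaces per season and scenario, and (c)
observed track summaries.  This module generates all three with
controlled structure: smooth single-blob suitability surfaces whose
centroids can be displaced by a prescribed bearing and distance
(emulating projected range shifts), trait tables with passerine-scale
allometry, and track records derived from a simulated ensemble with
configurable multiplicative bias and noise.

Default geometry places breeding blobs in Europe and non-breeding blobs
either in sub-Saharan Africa (long-distance migrants, journeys of
roughly 4500-5500 km) or around the Mediterranean (short-distance
migrants, roughly 900-1500 km).  Default future shifts displace
long-distance breeding ranges 410 km toward bearing 12.3 degrees and
non-breeding ranges 305 km toward 69.8 degrees — geometry in which the
two ends of the journey move apart; short-distance defaults shift both
seasons identically (parallel equal shifts), leaving journey lengths
essentially unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import geo
from .errors import DomainError, InvalidInputError, InvalidMetricError
from .grids import GRID_STEP, SuitabilityGrid
from .journeys import JourneyEnsemble
from .validation import METRICS, TrackRecord

__all__ = [
    "BlobSpec", "ShiftSpec", "SyntheticScenario",
    "make_species", "make_range_pair", "shift_range", "make_tracks",
    "grid_axes",
]

SEASONS = ("breeding", "non_breeding")
TRAITS_COLUMNS = ["species_id", "empty_mass_kg", "wing_span_m", "wing_area_m2",
                  "flight_period", "strategy"]


@dataclass(frozen=True)
class BlobSpec:
    """A Gaussian suitability blob: centre, spatial scale, peak value and
    the per-species jitter applied to the centre."""

    lon: float
    lat: float
    scale_km: float
    peak: float = 0.95
    jitter_lon: float = 0.0
    jitter_lat: float = 0.0


@dataclass(frozen=True)
class ShiftSpec:
    """Displacement of a blob centre: great-circle bearing and distance."""

    bearing_deg: float
    distance_km: float


@dataclass(frozen=True)
class SyntheticScenario:
    """Full description of a synthetic dataset.

    The default emulates the study system: 77 species (40 short- /
    37 long-distance migrants) on a 0.5-degree Europe-Africa window,
    1000 journeys per species, and season-specific centroid shifts
    between the "current" and "future" scenarios.
    """

    seed: int = 0
    n_species: int = 77
    lon_min: float = -25.0
    lon_max: float = 65.0
    lat_min: float = -35.0
    lat_max: float = 72.0
    breeding: BlobSpec = BlobSpec(12.0, 52.0, 300.0, 0.95, 6.0, 4.0)
    nonbreeding_long: BlobSpec = BlobSpec(8.0, 2.0, 350.0, 0.95, 8.0, 8.0)
    nonbreeding_short: BlobSpec = BlobSpec(12.0, 41.0, 300.0, 0.95, 6.0, 2.0)
    shifts_long: dict = field(default_factory=lambda: {
        "breeding": ShiftSpec(12.3, 410.0),
        "non_breeding": ShiftSpec(69.8, 305.0),
    })
    # the short-distance control: equal parallel (meridional) shifts of
    # both seasonal ranges, which preserve journey distance on the sphere
    shifts_short: dict = field(default_factory=lambda: {
        "breeding": ShiftSpec(0.0, 430.0),
        "non_breeding": ShiftSpec(0.0, 430.0),
    })
    prop_short: float = 40.0 / 77.0
    prop_nocturnal: float = 0.7
    threshold: float = 0.5
    n_reps: int = 1000
    track_bias: float = 1.0
    track_noise_cv: float = 0.1
    track_n_individuals: int = 8

    def __post_init__(self) -> None:
        if not (self.lon_min < self.lon_max and self.lat_min < self.lat_max):
            raise InvalidInputError("invalid bounding box")
        for blob in (self.breeding, self.nonbreeding_long, self.nonbreeding_short):
            if blob.scale_km <= 0:
                raise InvalidInputError("blob scale_km must be > 0")
        for shifts in (self.shifts_long, self.shifts_short):
            if any(s.distance_km < 0 for s in shifts.values()):
                raise InvalidInputError("shift distances must be >= 0")

    def to_flat(self) -> dict:
        """Flatten to a flat key-value mapping (the scenario config format)."""
        out: dict[str, float | int] = {}
        for key in ("seed", "n_species", "lon_min", "lon_max", "lat_min",
                    "lat_max", "prop_short", "prop_nocturnal", "threshold",
                    "n_reps", "track_bias", "track_noise_cv",
                    "track_n_individuals"):
            out[key] = getattr(self, key)
        for name, blob in (("breeding", self.breeding),
                           ("nonbreeding_long", self.nonbreeding_long),
                           ("nonbreeding_short", self.nonbreeding_short)):
            for f in ("lon", "lat", "scale_km", "peak", "jitter_lon", "jitter_lat"):
                out[f"{name}_{f}"] = getattr(blob, f)
        for name, shifts in (("long", self.shifts_long),
                             ("short", self.shifts_short)):
            for season, s in shifts.items():
                out[f"shift_{name}_{season}_bearing_deg"] = s.bearing_deg
                out[f"shift_{name}_{season}_distance_km"] = s.distance_km
        return out

    @classmethod
    def from_flat(cls, flat: dict) -> "SyntheticScenario":
        """Inverse of :meth:`to_flat`; missing keys keep their defaults."""
        base = cls().to_flat()
        unknown = set(flat) - set(base)
        if unknown:
            raise InvalidInputError(f"unknown scenario key(s) {sorted(unknown)}")
        base.update(flat)
        kwargs: dict = {k: base[k] for k in
                        ("seed", "n_species", "lon_min", "lon_max", "lat_min",
                         "lat_max", "prop_short", "prop_nocturnal", "threshold",
                         "n_reps", "track_bias", "track_noise_cv",
                         "track_n_individuals")}
        kwargs["seed"] = int(kwargs["seed"])
        kwargs["n_species"] = int(kwargs["n_species"])
        kwargs["n_reps"] = int(kwargs["n_reps"])
        kwargs["track_n_individuals"] = int(kwargs["track_n_individuals"])
        for name in ("breeding", "nonbreeding_long", "nonbreeding_short"):
            kwargs[name] = BlobSpec(**{f: float(base[f"{name}_{f}"]) for f in
                                       ("lon", "lat", "scale_km", "peak",
                                        "jitter_lon", "jitter_lat")})
        for name in ("long", "short"):
            kwargs[f"shifts_{name}"] = {
                season: ShiftSpec(float(base[f"shift_{name}_{season}_bearing_deg"]),
                                  float(base[f"shift_{name}_{season}_distance_km"]))
                for season in SEASONS
            }
        return cls(**kwargs)

    def nonbreeding_blob(self, strategy: str) -> BlobSpec:
        return (self.nonbreeding_short if strategy == "short_distance"
                else self.nonbreeding_long)

    def shifts(self, strategy: str) -> dict:
        return (self.shifts_short if strategy == "short_distance"
                else self.shifts_long)


def grid_axes(scenario: SyntheticScenario) -> tuple[np.ndarray, np.ndarray]:
    """Cell-centre axes of the scenario's 0.5-degree lattice."""
    lon = np.arange(scenario.lon_min + GRID_STEP / 2, scenario.lon_max, GRID_STEP)
    lat = np.arange(scenario.lat_min + GRID_STEP / 2, scenario.lat_max, GRID_STEP)
    return lon, lat


def make_species(n: int, seed: int | None = None,
                 prop_short: float = 40.0 / 77.0,
                 prop_nocturnal: float = 0.7) -> pd.DataFrame:
    """Generate a synthetic trait table of ``n`` species.

    Fat-free masses are log-uniform on [0.008, 0.3] kg (passerine to
    near-passerine scale); wing span scales allometrically with mass
    (b = 1.05 m^0.36 with lognormal scatter) and wing area follows from a
    lognormal aspect ratio constrained to [4.5, 12].  Migration strategy
    is split in the exact configured proportion; flight period is drawn
    per species.
    """
    if n < 1:
        raise InvalidInputError("n must be >= 1")
    rng = np.random.default_rng(seed)
    mass = np.exp(rng.uniform(np.log(0.008), np.log(0.3), size=n))
    span = 1.05 * mass ** 0.36 * np.exp(rng.normal(0.0, 0.06, size=n))
    aspect = np.clip(np.exp(rng.normal(np.log(7.0), 0.13, size=n)), 4.5, 12.0)
    area = span ** 2 / aspect

    n_short = int(round(n * prop_short))
    strategy = np.array(["short_distance"] * n_short
                        + ["long_distance"] * (n - n_short))
    rng.shuffle(strategy)
    period = np.where(rng.random(n) < prop_nocturnal, "nocturnal", "diurnal")
    return pd.DataFrame(
        {
            "species_id": [f"sp{i:03d}" for i in range(n)],
            "empty_mass_kg": mass,
            "wing_span_m": span,
            "wing_area_m2": area,
            "flight_period": period,
            "strategy": strategy,
        },
        columns=TRAITS_COLUMNS,
    )


def _blob_grid(lon_axis: np.ndarray, lat_axis: np.ndarray,
               centre: tuple[float, float], scale_km: float, peak: float,
               **metadata) -> SuitabilityGrid:
    lon2, lat2 = np.meshgrid(lon_axis, lat_axis)
    d = geo.great_circle_distance(lon2, lat2, centre[0], centre[1])
    suit = np.clip(peak * np.exp(-d ** 2 / (2.0 * scale_km ** 2)), 0.0, 1.0)
    grid = SuitabilityGrid(lon=lon_axis, lat=lat_axis, suitability=suit,
                           **metadata)
    grid.attrs.update(blob_lon=centre[0], blob_lat=centre[1],
                      blob_scale_km=scale_km, blob_peak=peak)
    return grid


def make_range_pair(scenario: SyntheticScenario, season: str,
                    strategy: str = "long_distance",
                    centre: tuple[float, float] | None = None,
                    species_id: str = "",
                    scenario_label: str = "current") -> SuitabilityGrid:
    """Deterministic Gaussian suitability surface for one season.

    Suitability is ``peak * exp(-d^2 / 2 s^2)`` with ``d`` the
    great-circle distance (km) from the blob centre, evaluated at every
    0.5-degree cell centre of the scenario's bounding box.  ``centre``
    overrides the scenario's blob centre (used for per-species jitter).
    """
    if season not in SEASONS:
        raise InvalidInputError(f"unknown season {season!r}")
    blob = scenario.breeding if season == "breeding" else scenario.nonbreeding_blob(strategy)
    c = centre if centre is not None else (blob.lon, blob.lat)
    if not (scenario.lon_min <= c[0] <= scenario.lon_max
            and scenario.lat_min <= c[1] <= scenario.lat_max):
        raise InvalidInputError(
            f"blob centre {c} outside bounding box "
            f"[{scenario.lon_min}, {scenario.lon_max}] x "
            f"[{scenario.lat_min}, {scenario.lat_max}]"
        )
    lon_axis, lat_axis = grid_axes(scenario)
    return _blob_grid(lon_axis, lat_axis, c, blob.scale_km, blob.peak,
                      species_id=species_id, season=season,
                      scenario=scenario_label)


def shift_range(grid: SuitabilityGrid, bearing_deg: float,
                distance_km: float, scenario_label: str = "future") -> SuitabilityGrid:
    """Displace a synthetic blob along a great-circle bearing.

    The blob is regenerated on the same lattice with its centre moved
    ``distance_km`` along the initial bearing.  Only grids generated by
    this module (carrying blob metadata in ``attrs``) can be shifted.
    """
    try:
        c_lon = grid.attrs["blob_lon"]
        c_lat = grid.attrs["blob_lat"]
        scale = grid.attrs["blob_scale_km"]
        peak = grid.attrs["blob_peak"]
    except KeyError as err:
        raise InvalidInputError(
            "grid carries no blob metadata; only synthetic blob grids can be shifted"
        ) from err
    new_lon, new_lat = geo.destination_point(c_lon, c_lat, bearing_deg, distance_km)
    if not (grid.lon.min() - GRID_STEP / 2 <= new_lon <= grid.lon.max() + GRID_STEP / 2
            and grid.lat.min() - GRID_STEP / 2 <= new_lat <= grid.lat.max() + GRID_STEP / 2):
        raise DomainError(
            f"shifted centre ({new_lon:.2f}, {new_lat:.2f}) leaves the grid domain"
        )
    return _blob_grid(grid.lon, grid.lat, (new_lon, new_lat), scale, peak,
                      species_id=grid.species_id, season=grid.season,
                      scenario=scenario_label)


def make_tracks(ensemble: JourneyEnsemble, metric: str,
                bias: float = 1.0, noise_cv: float = 0.0,
                n_individuals: int = 8,
                seed: int | None = None,
                rng: np.random.Generator | None = None) -> TrackRecord:
    """Mock geolocator track summaries drawn from a simulated ensemble.

    Draws ``n_individuals`` values of ``metric`` from the ensemble
    (without replacement when possible), multiplies by ``bias`` and by
    mean-one lognormal noise with the given coefficient of variation.
    """
    if n_individuals < 1:
        raise InvalidInputError("n_individuals must be >= 1")
    if metric not in METRICS:
        raise InvalidMetricError(metric)
    if rng is None:
        rng = np.random.default_rng(seed)
    values = ensemble.metric_values(metric)
    replace_draw = n_individuals > values.size
    draw = rng.choice(values, size=n_individuals, replace=replace_draw)
    draw = draw * bias
    if noise_cv > 0:
        sigma = np.sqrt(np.log1p(noise_cv ** 2))
        draw = draw * np.exp(rng.normal(-sigma ** 2 / 2.0, sigma, size=n_individuals))
    return TrackRecord(species_id=ensemble.species_id, metric=metric,
                       observations=tuple(np.maximum(draw, 0.0)))
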