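"""End-to-end orchestration: synthetic scenario -> journeys, shifts and deltas.

Ties the generator, flight model, journey sampler and shift statistics
together for a whole species table, producing per-species current and
future journey ensembles plus range-shift vectors.  This is the engine
behind the command-line pipeline and the package's own end-to-end
experiments.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .flight import FlightParams, SpeciesTraits, flight_range
from .grids import SuitabilityGrid
from .journeys import JourneyEnsemble, simulate_journeys, species_rng
from .shifts import ShiftVector, range_centre, shift_vector, threshold_grid
from .synthetic import (SEASONS, SyntheticScenario, make_range_pair,
                        make_species, shift_range)

log = logging.getLogger(__name__)

__all__ = ["SpeciesRun", "species_grids", "run_species", "run_scenario",
           "traits_from_row", "scenario_report"]

SCENARIO_LABELS = ("current", "future")


@dataclass
class SpeciesRun:
    """All per-species outputs of one synthetic scenario run."""

    traits: SpeciesTraits
    ensembles: dict[str, JourneyEnsemble]     # scenario label -> ensemble
    shift_vectors: dict[str, ShiftVector]     # season -> shift
    grids: dict[tuple[str, str], SuitabilityGrid] | None = None


def traits_from_row(row) -> SpeciesTraits:
    """Build SpeciesTraits from one trait-table row (CSV schema columns)."""
    return SpeciesTraits(
        species_id=str(row["species_id"]),
        empty_mass=float(row["empty_mass_kg"]),
        wing_span=float(row["wing_span_m"]),
        wing_area=float(row["wing_area_m2"]),
        flight_period=str(row["flight_period"]),
        strategy=str(row["strategy"]),
    )


def species_grids(scenario: SyntheticScenario, traits: SpeciesTraits,
                  rng: np.random.Generator) -> dict[tuple[str, str], SuitabilityGrid]:
    """Current and future suitability grids for one species.

    The species' blob centres are jittered (uniformly, within the
    per-season jitter box) around the scenario's base centres; future
    grids displace the current blobs by the strategy's season-specific
    shift.  Short-distance migrants share one longitude jitter across
    seasons: their journeys run along a meridian, so the equal parallel
    shifts of the control scenario preserve journey distance exactly.
    """
    grids: dict[tuple[str, str], SuitabilityGrid] = {}
    shifts = scenario.shifts(traits.strategy)
    shared_u_lon = rng.uniform(-1.0, 1.0)
    for season in SEASONS:
        blob = (scenario.breeding if season == "breeding"
                else scenario.nonbreeding_blob(traits.strategy))
        if traits.strategy == "short_distance":
            u_lon = shared_u_lon
        else:
            u_lon = rng.uniform(-1.0, 1.0)
        centre = (blob.lon + blob.jitter_lon * u_lon,
                  blob.lat + rng.uniform(-blob.jitter_lat, blob.jitter_lat))
        now = make_range_pair(scenario, season, strategy=traits.strategy,
                              centre=centre, species_id=traits.species_id,
                              scenario_label="current")
        fut = shift_range(now, shifts[season].bearing_deg,
                          shifts[season].distance_km, scenario_label="future")
        grids[(season, "current")] = now
        grids[(season, "future")] = fut
    return grids


def run_species(scenario: SyntheticScenario, traits: SpeciesTraits,
                params: FlightParams, n_reps: int | None = None,
                compute_shifts: bool = True,
                keep_grids: bool = False) -> SpeciesRun:
    """Simulate one species through the whole pipeline."""
    rng = species_rng(scenario.seed, traits.species_id)
    grids = species_grids(scenario, traits, rng)
    ranges = {key: threshold_grid(g, threshold=scenario.threshold)
              for key, g in grids.items()}
    perf = (flight_range(traits, params.fat_fraction_initial, params),
            flight_range(traits, params.fat_fraction_stopover, params))
    n = scenario.n_reps if n_reps is None else n_reps

    ensembles = {}
    for label in SCENARIO_LABELS:
        ensembles[label] = simulate_journeys(
            breeding=(grids[("breeding", label)], ranges[("breeding", label)]),
            nonbreeding=(grids[("non_breeding", label)],
                         ranges[("non_breeding", label)]),
            traits=traits, params=params, n_reps=n, rng=rng,
            scenario=label, performance=perf,
        )

    shift_vectors: dict[str, ShiftVector] = {}
    if compute_shifts:
        for season in SEASONS:
            c_now = range_centre(grids[(season, "current")],
                                 ranges[(season, "current")], rng=rng)
            c_fut = range_centre(grids[(season, "future")],
                                 ranges[(season, "future")], rng=rng)
            shift_vectors[season] = shift_vector(
                c_now, c_fut, species_id=traits.species_id, season=season)
    return SpeciesRun(traits=traits, ensembles=ensembles,
                      shift_vectors=shift_vectors,
                      grids=grids if keep_grids else None)


def run_scenario(scenario: SyntheticScenario,
                 traits_df: pd.DataFrame | None = None,
                 params: FlightParams | None = None,
                 n_reps: int | None = None,
                 compute_shifts: bool = True) -> list[SpeciesRun]:
    """Run every species of a synthetic scenario through the pipeline."""
    if params is None:
        params = FlightParams()
    if traits_df is None:
        traits_df = make_species(scenario.n_species, seed=scenario.seed,
                                 prop_short=scenario.prop_short,
                                 prop_nocturnal=scenario.prop_nocturnal)
    runs = []
    for _, row in traits_df.iterrows():
        traits = traits_from_row(row)
        log.info("simulating %s (%s)", traits.species_id, traits.strategy)
        runs.append(run_species(scenario, traits, params, n_reps=n_reps,
                                compute_shifts=compute_shifts))
    return runs


def scenario_report(runs: list[SpeciesRun]) -> pd.DataFrame:
    """Per-species x scenario summary table of the journey ensembles.

    One row per species and scenario with ensemble means/sds plus the
    current-to-future deltas of mean distance, stopovers and duration.
    """
    rows = []
    for run in runs:
        deltas = {}
        cur = run.ensembles["current"].summary
        fut = run.ensembles["future"].summary
        for col in ("distance_km", "n_stopovers", "duration_days"):
            deltas[f"delta_mean_{col}"] = fut[f"mean_{col}"] - cur[f"mean_{col}"]
        for label, ens in run.ensembles.items():
            s = ens.summary
            rows.append({
                "species_id": run.traits.species_id,
                "strategy": run.traits.strategy,
                "scenario": label,
                "n_journeys": ens.n_reps,
                "mean_distance_km": s["mean_distance_km"],
                "sd_distance_km": s["sd_distance_km"],
                "mean_n_stopovers": s["mean_n_stopovers"],
                "sd_n_stopovers": s["sd_n_stopovers"],
                "mean_duration_days": s["mean_duration_days"],
                "sd_duration_days": s["sd_duration_days"],
                **deltas,
            })
    return pd.DataFrame(rows)
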