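"""Readers and writers for the package's CSV/JSON schemas.

All CSV files are UTF-8, comma-separated with '.' decimal and a
mandatory header row.  Grid tables are long format (lon, lat,
suitability) with coordinates at 0.5-degree cell centres.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import pandas as pd
import yaml

from .errors import SchemaError
from .flight import FlightParams
from .grids import SuitabilityGrid
from .journeys import JOURNEY_COLUMNS, JourneyEnsemble
from .synthetic import TRAITS_COLUMNS
from .validation import ComparisonResult, TrackRecord

TRACKS_COLUMNS = ["species_id", "metric", "individual_id", "value"]


def _require_columns(df: pd.DataFrame, columns, path) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")


def read_traits(path) -> pd.DataFrame:
    """Species trait table (species_id, empty_mass_kg, wing_span_m,
    wing_area_m2, flight_period, strategy)."""
    df = pd.read_csv(path)
    _require_columns(df, TRAITS_COLUMNS, path)
    for i, row in df.iterrows():
        for col in ("empty_mass_kg", "wing_span_m", "wing_area_m2"):
            if not row[col] > 0:
                raise SchemaError(
                    f"{path}: row {i}, column {col!r}: must be positive, "
                    f"got {row[col]!r}"
                )
    return df[TRAITS_COLUMNS]


def write_traits(df: pd.DataFrame, path) -> None:
    df[TRAITS_COLUMNS].to_csv(path, index=False)


def read_grid_csv(path, **metadata) -> SuitabilityGrid:
    """Long-format suitability grid; the lattice must be exactly 0.5 degrees."""
    df = pd.read_csv(path)
    _require_columns(df, ["lon", "lat", "suitability"], path)
    try:
        return SuitabilityGrid.from_frame(df, **metadata)
    except SchemaError as err:
        raise SchemaError(f"{path}: {err}") from err


def write_grid_csv(grid: SuitabilityGrid, path) -> None:
    grid.to_frame().to_csv(path, index=False)


def write_journeys(ensembles: list[JourneyEnsemble], path) -> None:
    """Concatenated journey tables, one row per sampled journey."""
    pd.concat([e.journeys for e in ensembles], ignore_index=True).to_csv(
        path, index=False)


def read_journeys(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require_columns(df, JOURNEY_COLUMNS, path)
    return df


def ensembles_from_frame(df: pd.DataFrame) -> list[JourneyEnsemble]:
    """Regroup a journeys table into per-(species, scenario) ensembles."""
    out = []
    for (sid, scen), sub in df.groupby(["species_id", "scenario"], sort=True):
        out.append(JourneyEnsemble(str(sid), str(scen),
                                   sub.reset_index(drop=True)))
    return out


def read_tracks(path) -> list[TrackRecord]:
    """Track summaries: species_id, metric, individual_id, value."""
    df = pd.read_csv(path)
    _require_columns(df, TRACKS_COLUMNS, path)
    records = []
    for (sid, metric), sub in df.groupby(["species_id", "metric"], sort=True):
        records.append(TrackRecord(str(sid), str(metric),
                                   tuple(sub["value"].astype(float))))
    return records


def write_tracks(records: list[TrackRecord], path) -> None:
    rows = []
    for rec in records:
        for i, v in enumerate(rec.observations):
            rows.append((rec.species_id, rec.metric, i, v))
    pd.DataFrame(rows, columns=TRACKS_COLUMNS).to_csv(path, index=False)


def write_comparisons(results: list[ComparisonResult], path) -> None:
    pd.DataFrame([vars(r) for r in results]).to_csv(path, index=False)


def read_params(path) -> FlightParams:
    """FlightParams from a flat key: value YAML file; unknown keys rejected."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise SchemaError(f"{path}: params file must be a flat mapping")
    valid = set(FlightParams.__dataclass_fields__)
    unknown = set(raw) - valid
    if unknown:
        raise SchemaError(f"{path}: unknown parameter(s) {sorted(unknown)}")
    return FlightParams(**{k: float(v) for k, v in raw.items()})


def write_params(params: FlightParams, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump({k: getattr(params, k)
                        for k in FlightParams.__dataclass_fields__}, fh)


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def sha256_file(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()
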