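"""Data model, validation and CSV readers/writers for airfield wildlife tables.

Four tables describe an airfield monitoring campaign:

* ``zones.csv`` — wildlife-management zones with a proximity measure
  (1 = closest to the runways) and a location-risk weight;
* ``observations.csv`` — per day, species and zone: birds observed on the
  daily count and birds dispersed by harassment operations;
* ``strikes.csv`` — reported collisions (date, species, individuals,
  optional zone, confirmed flag);
* ``weather.csv`` — daily rain, temperature and aircraft movements.

All dates are ISO-8601 calendar dates; sub-day timestamps are truncated,
because every downstream model classifies whole days.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "ZoneEntry",
    "ZoneMap",
    "DailyObservation",
    "StrikeRecord",
    "WeatherRecord",
    "Dataset",
    "SchemaError",
    "ValidationError",
    "read_dataset",
    "write_dataset",
    "build_species_day_table",
]


class SchemaError(ValueError):
    """A CSV file is missing a required column."""


class ValidationError(ValueError):
    """Tables are individually well-formed but mutually inconsistent."""


@dataclass(frozen=True)
class ZoneEntry:
    zone_id: str
    proximity: float
    location_weight: float

    def __post_init__(self) -> None:
        if self.proximity <= 0:
            raise ValidationError(f"zone {self.zone_id!r}: proximity must be > 0")
        if self.location_weight <= 0:
            raise ValidationError(f"zone {self.zone_id!r}: location_weight must be > 0")


class ZoneMap:
    """Zone identifier -> (proximity, location-risk weight); the spatial prior."""

    def __init__(self, entries: Iterable[ZoneEntry]):
        self._entries: dict[str, ZoneEntry] = {}
        for e in entries:
            if e.zone_id in self._entries:
                raise ValidationError(f"duplicate zone id {e.zone_id!r}")
            self._entries[e.zone_id] = e

    def zone_ids(self) -> list[str]:
        return list(self._entries)

    def get(self, zone_id: str) -> ZoneEntry | None:
        return self._entries.get(zone_id)

    def __contains__(self, zone_id: str) -> bool:
        return zone_id in self._entries

    def __len__(self) -> int:
        return len(self._entries)

    def __iter__(self):
        return iter(self._entries.values())

    def __eq__(self, other: object) -> bool:
        return isinstance(other, ZoneMap) and self._entries == other._entries

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "zone": [e.zone_id for e in self],
                "proximity": [e.proximity for e in self],
                "location_weight": [e.location_weight for e in self],
            }
        )


@dataclass(frozen=True)
class DailyObservation:
    date: dt.date
    species: str
    zone_id: str
    observed: int
    harassed: int

    def __post_init__(self) -> None:
        if self.observed < 0 or self.harassed < 0:
            raise ValidationError("observed/harassed counts must be non-negative")


@dataclass(frozen=True)
class StrikeRecord:
    date: dt.date
    species: str
    individuals: int
    zone_id: str | None = None
    confirmed: bool = True

    def __post_init__(self) -> None:
        if self.individuals < 1:
            raise ValidationError("a strike involves at least one individual")


@dataclass(frozen=True)
class WeatherRecord:
    date: dt.date
    rain_mm: float
    temp_c: float
    aircraft_movements: int

    def __post_init__(self) -> None:
        if self.rain_mm < 0:
            raise ValidationError("rain_mm must be non-negative")
        if self.aircraft_movements < 0:
            raise ValidationError("aircraft_movements must be non-negative")


@dataclass
class Dataset:
    """The full campaign: zone map, observations, strikes and daily weather."""

    zone_map: ZoneMap
    observations: list[DailyObservation]
    strikes: list[StrikeRecord]
    weather: list[WeatherRecord]

    species_list: list[str] = field(init=False)
    date_range: tuple[dt.date, dt.date] = field(init=False)

    def __post_init__(self) -> None:
        self._validate()

    def _validate(self) -> None:
        dates = [o.date for o in self.observations] + [w.date for w in self.weather]
        if not dates:
            raise ValidationError("dataset has no dated records")
        self.date_range = (min(dates), max(dates))
        # a species can be struck on a day it was never counted, so strikes
        # contribute to the species universe of an in-memory dataset
        self.species_list = sorted(
            {o.species for o in self.observations} | {s.species for s in self.strikes}
        )

        seen: set[tuple[dt.date, str, str]] = set()
        for o in self.observations:
            if o.zone_id not in self.zone_map:
                raise ValidationError(f"observation references unknown zone {o.zone_id!r}")
            key = (o.date, o.species, o.zone_id)
            if key in seen:
                raise ValidationError(
                    f"duplicate observation for {key}: rows for the same "
                    "(date, species, zone) must be cleaned upstream, not summed"
                )
            seen.add(key)

        for s in self.strikes:
            if not (self.date_range[0] <= s.date <= self.date_range[1]):
                raise ValidationError(f"strike date {s.date} outside dataset range")
            if s.zone_id is not None and s.zone_id not in self.zone_map:
                raise ValidationError(f"strike references unknown zone {s.zone_id!r}")

        wdates = [w.date for w in self.weather]
        if len(set(wdates)) != len(wdates):
            raise ValidationError("weather has more than one record for some date")

    def dates(self) -> list[dt.date]:
        start, end = self.date_range
        return [start + dt.timedelta(days=i) for i in range((end - start).days + 1)]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Dataset):
            return NotImplemented
        return (
            self.zone_map == other.zone_map
            and sorted(self.observations, key=_obs_key) == sorted(other.observations, key=_obs_key)
            and sorted(self.strikes, key=_strike_key) == sorted(other.strikes, key=_strike_key)
            and sorted(self.weather, key=lambda w: w.date) == sorted(other.weather, key=lambda w: w.date)
        )


def _obs_key(o: DailyObservation):
    return (o.date, o.species, o.zone_id)


def _strike_key(s: StrikeRecord):
    return (s.date, s.species, s.zone_id or "", s.individuals)


def _parse_date(value) -> dt.date:
    ts = pd.Timestamp(value)
    return ts.date()


def _parse_bool(value) -> bool:
    if isinstance(value, str):
        low = value.strip().lower()
        if low in ("true", "1", "yes", "y"):
            return True
        if low in ("false", "0", "no", "n"):
            return False
        raise ValidationError(f"cannot interpret {value!r} as a boolean")
    return bool(value)


def _require(df: pd.DataFrame, cols: Sequence[str], name: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SchemaError(f"{name} is missing required column(s): {', '.join(missing)}")


def read_dataset(paths: Mapping[str, str | Path]) -> Dataset:
    """Read and validate the four CSV tables.

    ``paths`` maps the keys ``observations``, ``strikes``, ``zones``,
    ``weather`` to file locations.  Unknown columns are ignored by the data
    model but preserved by pandas round-trips upstream.
    """
    zones_df = pd.read_csv(paths["zones"])
    _require(zones_df, ["zone", "proximity", "location_weight"], "zones.csv")
    zone_map = ZoneMap(
        ZoneEntry(str(r.zone), float(r.proximity), float(r.location_weight))
        for r in zones_df.itertuples()
    )

    obs_df = pd.read_csv(paths["observations"])
    _require(obs_df, ["date", "species", "zone", "observed", "harassed"], "observations.csv")
    observations = [
        DailyObservation(_parse_date(r.date), str(r.species), str(r.zone), int(r.observed), int(r.harassed))
        for r in obs_df.itertuples()
    ]

    strikes_df = pd.read_csv(paths["strikes"])
    _require(strikes_df, ["date", "species", "individuals", "zone", "confirmed"], "strikes.csv")
    strikes = [
        StrikeRecord(
            _parse_date(r.date),
            str(r.species),
            int(r.individuals),
            None if pd.isna(r.zone) else str(r.zone),
            _parse_bool(r.confirmed),
        )
        for r in strikes_df.itertuples()
    ]

    weather_df = pd.read_csv(paths["weather"])
    _require(weather_df, ["date", "rain_mm", "temp_c", "aircraft_movements"], "weather.csv")
    weather = [
        WeatherRecord(_parse_date(r.date), float(r.rain_mm), float(r.temp_c), int(r.aircraft_movements))
        for r in weather_df.itertuples()
    ]

    # file-level referential integrity: the observations table defines the
    # species universe of a CSV export
    observed_species = {o.species for o in observations}
    for s in strikes:
        if s.species not in observed_species:
            raise ValidationError(f"strike references unknown species {s.species!r}")

    return Dataset(zone_map, observations, strikes, weather)


def write_dataset(ds: Dataset, out_dir: str | Path) -> dict[str, Path]:
    """Write the four CSV tables to ``out_dir``; returns the path map."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "zones": out / "zones.csv",
        "observations": out / "observations.csv",
        "strikes": out / "strikes.csv",
        "weather": out / "weather.csv",
    }
    ds.zone_map.to_frame().to_csv(paths["zones"], index=False)
    pd.DataFrame(
        {
            "date": [o.date.isoformat() for o in ds.observations],
            "species": [o.species for o in ds.observations],
            "zone": [o.zone_id for o in ds.observations],
            "observed": [o.observed for o in ds.observations],
            "harassed": [o.harassed for o in ds.observations],
        }
    ).to_csv(paths["observations"], index=False)
    pd.DataFrame(
        {
            "date": [s.date.isoformat() for s in ds.strikes],
            "species": [s.species for s in ds.strikes],
            "individuals": [s.individuals for s in ds.strikes],
            "zone": [s.zone_id if s.zone_id is not None else "" for s in ds.strikes],
            "confirmed": [s.confirmed for s in ds.strikes],
        }
    ).to_csv(paths["strikes"], index=False)
    pd.DataFrame(
        {
            "date": [w.date.isoformat() for w in ds.weather],
            "rain_mm": [w.rain_mm for w in ds.weather],
            "temp_c": [w.temp_c for w in ds.weather],
            "aircraft_movements": [w.aircraft_movements for w in ds.weather],
        }
    ).to_csv(paths["weather"], index=False)
    return paths


def build_species_day_table(ds: Dataset, species: str) -> pd.DataFrame:
    """One row per calendar day for one species, with per-zone counts.

    Days with no observation get zero counts in every zone (non-detection),
    and the ``strike`` flag is True iff at least one strike of the species
    was recorded that day.  Columns: ``date``, ``observed_<zone>`` and
    ``harassed_<zone>`` per zone, weather columns, ``strike``.
    """
    if species not in ds.species_list:
        raise ValidationError(f"unknown species {species!r}; dataset has {ds.species_list}")

    zones = ds.zone_map.zone_ids()
    dates = ds.dates()
    idx = {d: i for i, d in enumerate(dates)}

    table = pd.DataFrame({"date": pd.to_datetime(dates)})
    for z in zones:
        table[f"observed_{z}"] = 0
        table[f"harassed_{z}"] = 0
    for o in ds.observations:
        if o.species != species:
            continue
        i = idx[o.date]
        table.loc[i, f"observed_{o.zone_id}"] = o.observed
        table.loc[i, f"harassed_{o.zone_id}"] = o.harassed

    table["rain_mm"] = float("nan")
    table["temp_c"] = float("nan")
    table["aircraft_movements"] = float("nan")
    for w in ds.weather:
        if w.date in idx:
            i = idx[w.date]
            table.loc[i, ["rain_mm", "temp_c", "aircraft_movements"]] = [
                w.rain_mm,
                w.temp_c,
                w.aircraft_movements,
            ]

    table["strike"] = False
    for s in ds.strikes:
        if s.species == species:
            table.loc[idx[s.date], "strike"] = True
    return table
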