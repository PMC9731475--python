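"""Seasonality transform and proximity-weighted abundance algebra.

A calendar date is mapped to a cyclic "solar day" coordinate relative to a
species-specific marker date, so that dates at opposite ends of the calendar
year are seasonally close.  Daily per-zone counts (observed + harassed) are
aggregated by zone proximity and inverse-proximity weighted into a single
daily abundance figure that up-weights birds near the runways.
"""

from __future__ import annotations

import datetime as dt
import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .data import ZoneMap

__all__ = [
    "SeasonalitySpec",
    "AbundanceResult",
    "day_offset",
    "seasonality",
    "zone_count",
    "proximity_counts",
    "abundance",
    "add_seasonal_features",
]

YEAR_DAYS = 365  # leap days fold into the 365-day cycle

_MODES = ("angular", "literal", "linear")


@dataclass(frozen=True)
class SeasonalitySpec:
    """Marker date (solar day 0) and the convention mapping offsets to a score.

    mode="angular" (default): cos(2*pi*offset/365), range [-1, 1].
    mode="literal": cos(offset/365) — the arc-length reading; always positive
    on wrapped offsets, kept for fidelity audits.
    mode="linear": offset/182.5, the signed solar day rescaled to (-1, 1].
    """

    marker_date: dt.date
    mode: str = "angular"

    def __post_init__(self) -> None:
        if self.mode not in _MODES:
            raise ValueError(f"unknown seasonality mode {self.mode!r}; expected one of {_MODES}")


def day_offset(d: dt.date, m: dt.date) -> int:
    """Signed day offset of ``d`` from marker ``m``, wrapped into (-365/2, 365/2].

    Wrapping makes January and December neighbours: with m = Jan-1,
    Dec-31 of the same year maps to -1.
    """
    raw = (d - m).days
    return (raw + 182) % YEAR_DAYS - 182


def seasonality(d: dt.date, spec: SeasonalitySpec) -> float:
    """Seasonality score of date ``d`` under ``spec`` (see SeasonalitySpec)."""
    off = day_offset(d, spec.marker_date)
    if spec.mode == "angular":
        return math.cos(2.0 * math.pi * off / YEAR_DAYS)
    if spec.mode == "literal":
        return math.cos(off / YEAR_DAYS)
    return off / (YEAR_DAYS / 2.0)


def zone_count(observed: float, harassed: float) -> float:
    """Daily count for one zone: birds seen on the count plus birds harassed."""
    if observed < 0 or harassed < 0:
        raise ValueError("counts must be non-negative")
    return observed + harassed


def proximity_counts(zone_counts: Mapping[str, float], zone_map: ZoneMap) -> dict[float, float]:
    """Group zone counts by identical proximity value and sum within groups."""
    out: dict[float, float] = {}
    for zone, c in zone_counts.items():
        entry = zone_map.get(zone)
        if entry is None:
            raise KeyError(f"zone {zone!r} missing from zone map")
        out[entry.proximity] = out.get(entry.proximity, 0.0) + c
    return out


def abundance(prox_counts: Mapping[float, float]) -> float:
    """Inverse-proximity weighted total: sum of count_q / q over proximities q.

    An empty mapping (non-detection day) gives 0.
    """
    total = 0.0
    for q, c in prox_counts.items():
        if q <= 0:
            raise ValueError(f"proximity must be positive, got {q}")
        total += c / q
    return total


@dataclass
class AbundanceResult:
    """Per-zone counts, per-proximity aggregates, and the weighted abundance."""

    zone_counts: dict[str, float]
    prox_counts: dict[float, float] = field(default_factory=dict)
    abundance: float = 0.0

    @classmethod
    def from_counts(cls, zone_counts: Mapping[str, float], zone_map: ZoneMap) -> "AbundanceResult":
        pc = proximity_counts(zone_counts, zone_map)
        return cls(dict(zone_counts), pc, abundance(pc))


def add_seasonal_features(
    table: pd.DataFrame, zone_map: ZoneMap, spec: SeasonalitySpec
) -> pd.DataFrame:
    """Append ``seasonality`` and ``abundance`` columns to a species-day table.

    The table must carry ``observed_<zone>`` / ``harassed_<zone>`` columns as
    produced by :func:`strikerisk.data.build_species_day_table`.
    """
    out = table.copy()
    dates = pd.to_datetime(out["date"]).dt.date
    out["seasonality"] = [seasonality(d, spec) for d in dates]

    weights = np.array([1.0 / zone_map.get(z).proximity for z in zone_map.zone_ids()])
    obs = out[[f"observed_{z}" for z in zone_map.zone_ids()]].to_numpy(float)
    har = out[[f"harassed_{z}" for z in zone_map.zone_ids()]].to_numpy(float)
    out["abundance"] = (obs + har) @ weights
    return out
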