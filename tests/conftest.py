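import datetime as dt

import pytest

from strikerisk.data import (
    DailyObservation,
    Dataset,
    StrikeRecord,
    WeatherRecord,
    ZoneEntry,
    ZoneMap,
)


@pytest.fixture
def zone_map():
    return ZoneMap(
        [
            ZoneEntry("Z1", 1.0, 1.0),
            ZoneEntry("Z2", 1.0, 1.0),
            ZoneEntry("Z3", 2.0, 0.5),
            ZoneEntry("Z4", 4.0, 0.25),
        ]
    )


@pytest.fixture
def tiny_dataset(zone_map):
    """Three days, two species, sparse observations, one strike day."""
    d0 = dt.date(2018, 1, 1)
    obs = [
        DailyObservation(d0, "egret", "Z1", 5, 3),
        DailyObservation(d0, "egret", "Z3", 4, 0),
        DailyObservation(d0 + dt.timedelta(days=2), "egret", "Z1", 2, 0),
        DailyObservation(d0, "ibis", "Z4", 8, 0),
    ]
    strikes = [
        StrikeRecord(d0, "egret", 1, "Z1", True),
        StrikeRecord(d0, "egret", 2, None, False),
    ]
    weather = [
        WeatherRecord(d0 + dt.timedelta(days=i), 0.0, 20.0 + i, 500 + i) for i in range(3)
    ]
    return Dataset(zone_map, obs, strikes, weather)
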