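"""Fixed feature vocabularies and calendar/weather discretization.

A run's *situation* is a vector of exactly 29 categorical items:

* 3 temporal features (hour-of-day bin, weekday, month),
* 4 weather features (temperature bin, weather type, wind type, humidity type),
* 9 distances to the nearest cell of each landuse class,
* 9 coverage percentages of each landuse class in a 1 km^2 window,
* 4 neighborhood demographics.

Temporal and weather features have fixed vocabularies defined here; the 22
geographic features are discretized by a data-driven
:class:`runsit.geo_context.BinningScheme` (a zero category plus decile bins).
"""

from __future__ import annotations

import datetime as _dt

import numpy as np

#: The nine landuse classes, in canonical order; raster codes are 1-based
#: positions in this list (1 = parks ... 9 = cbd).
LANDUSE_CLASSES = (
    "parks",
    "sports",
    "recreation",
    "forest",
    "water",
    "agriculture",
    "traffic",
    "residential",
    "cbd",
)

LANDUSE_CODE = {name: i + 1 for i, name in enumerate(LANDUSE_CLASSES)}

WEATHER_TYPES = (
    "sunny",
    "half cloudy",
    "cloudy",
    "rainy",
    "windy",
    "thunderstorm",
    "snow",
    "hail",
    "mist",
)
WIND_TYPES = ("windless", "light wind", "moderate wind", "hard wind", "storm")
HUMIDITY_TYPES = ("low humidity", "middle humidity", "high humidity")

WEEKDAYS = (
    "Monday",
    "Tuesday",
    "Wednesday",
    "Thursday",
    "Friday",
    "Saturday",
    "Sunday",
)
MONTHS = (
    "January",
    "February",
    "March",
    "April",
    "May",
    "June",
    "July",
    "August",
    "September",
    "October",
    "November",
    "December",
)

#: Eight 3-hour bins [0,3), [3,6), ..., [21,24).
HOUR_BIN_EDGES = tuple(range(0, 25, 3))
HOUR_BINS = tuple(f"[{a:02d},{b:02d})" for a, b in zip(HOUR_BIN_EDGES[:-1], HOUR_BIN_EDGES[1:]))

#: Five width-8 temperature bins over [-10, 30] C; interior edges half-open,
#: the final bin closed at 30; values outside the range clamp into the
#: boundary bins.
TEMPERATURE_EDGES = (-10.0, -2.0, 6.0, 14.0, 22.0, 30.0)
TEMPERATURE_BINS = tuple(
    f"[{a:g},{b:g})" if i < 4 else f"[{a:g},{b:g}]"
    for i, (a, b) in enumerate(zip(TEMPERATURE_EDGES[:-1], TEMPERATURE_EDGES[1:]))
)

DISTANCE_FEATURES = tuple(f"dist_{c}" for c in LANDUSE_CLASSES)
COVERAGE_FEATURES = tuple(f"cov_{c}" for c in LANDUSE_CLASSES)
DEMOGRAPHIC_FEATURES = (
    "population_density",
    "pct_over_65",
    "pct_one_person",
    "pct_no_child",
)

TEMPORAL_FEATURES = ("hour", "weekday", "month")
WEATHER_FEATURES = ("temperature", "weather", "wind", "humidity")

#: All 29 features in report order.
ALL_FEATURES = (
    TEMPORAL_FEATURES
    + WEATHER_FEATURES
    + DISTANCE_FEATURES
    + COVERAGE_FEATURES
    + DEMOGRAPHIC_FEATURES
)

FEATURE_CATEGORY = {}
for _f in TEMPORAL_FEATURES:
    FEATURE_CATEGORY[_f] = "temporal"
for _f in WEATHER_FEATURES:
    FEATURE_CATEGORY[_f] = "weather"
for _f in DISTANCE_FEATURES + COVERAGE_FEATURES:
    FEATURE_CATEGORY[_f] = "topographical"
for _f in DEMOGRAPHIC_FEATURES:
    FEATURE_CATEGORY[_f] = "demographical"


def hour_bin(hour: float) -> str:
    """Map an hour in [0, 24) to one of the eight 3-hour bins."""
    idx = int(hour) // 3
    if not 0 <= idx < 8:
        raise ValueError(f"hour {hour!r} outside [0, 24)")
    return HOUR_BINS[idx]


def temperature_bin(temp_c: float) -> str:
    """Map a temperature in Celsius to one of the five bins, clamping outside [-10, 30]."""
    idx = int(np.clip(np.floor((temp_c - TEMPERATURE_EDGES[0]) / 8.0), 0, 4))
    return TEMPERATURE_BINS[idx]


def weekday_name(ts: _dt.datetime) -> str:
    return WEEKDAYS[ts.weekday()]


def month_name(ts: _dt.datetime) -> str:
    return MONTHS[ts.month - 1]


def temporal_items(ts: _dt.datetime) -> dict[str, str]:
    """The three temporal (feature, category) items of a start timestamp."""
    return {
        "hour": hour_bin(ts.hour + ts.minute / 60.0),
        "weekday": weekday_name(ts),
        "month": month_name(ts),
    }
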