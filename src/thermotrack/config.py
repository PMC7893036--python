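"""Study configuration: season windows, day conventions, planted effect sizes.

The defaults encode the study design this pipeline targets: two 91-day
hot-dry seasons in the Kalahari (September–November of a drought year and
of the following non-drought year), gemsbok (*Oryx gazella*) as the
reference species and drought as the reference season, and a per-response
table of planted fixed effects (intercept, season, species, interaction)
on an explicit reporting scale:

* ``identity`` — additive on the response's natural units (°C, °C·h),
* ``log`` — additive on log(response) (total 24 h activity),
* ``response-proportion`` — additive on the proportion scale,
* ``response-rate`` — multiplicative: intercept is a rate, other terms
  rate ratios (daily travel-hour and cool-hour counts).
"""

from __future__ import annotations

import dataclasses
import datetime as dt
from dataclasses import dataclass, field
from typing import Mapping

import yaml

__all__ = [
    "SeasonWindow",
    "DayBoundary",
    "PlantedCoefficients",
    "VarianceComponents",
    "SimulationConfig",
    "default_config",
    "load_config",
    "dump_config",
    "RESPONSES",
    "SPECIES",
    "SEASONS",
]

SPECIES = ("gemsbok", "wildebeest")
SEASONS = ("drought", "non-drought")

#: responses analysed by the pipeline, with model family and reporting scale
RESPONSES: dict[str, tuple[str, str]] = {
    "t_min": ("gaussian", "identity"),
    "t_max": ("gaussian", "identity"),
    "t_amplitude": ("gaussian", "identity"),
    "cool_hours": ("poisson", "response-rate"),
    "cumulative_cool_use": ("gaussian", "identity"),
    "travel_hours": ("poisson", "response-rate"),
    "total_activity_24h": ("gaussian", "log"),
    "heat_activity_proportion": ("binomial", "response-proportion"),
}


@dataclass(frozen=True)
class SeasonWindow:
    """A labelled analysis season (civil dates, inclusive)."""

    label: str
    start: dt.date
    end: dt.date
    preceding_wet_rainfall_mm: float | None = None

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"season window {self.label}: start must precede end")

    @property
    def n_days(self) -> int:
        return (self.end - self.start).days + 1

    def dates(self) -> list[dt.date]:
        return [self.start + dt.timedelta(days=i) for i in range(self.n_days)]

    def contains(self, date: dt.date) -> bool:
        return self.start <= date <= self.end


@dataclass(frozen=True)
class DayBoundary:
    """Civil-day convention and completeness rule for daily aggregation.

    Days run local midnight to midnight at a fixed UTC offset (UTC+2 for
    the Kalahari; no DST).  A sensor's daily metric is flagged complete
    only if at least ``completeness`` of the expected records are present.
    """

    utc_offset_hours: float = 2.0
    completeness: float = 0.8

    def __post_init__(self) -> None:
        if not 0.0 < self.completeness <= 1.0:
            raise ValueError("completeness threshold must be in (0, 1]")


@dataclass(frozen=True)
class PlantedCoefficients:
    """Fixed-effect truth for one response, on its reporting scale."""

    intercept: float
    season: float
    species: float
    interaction: float
    scale: str = "identity"

    _SCALES = ("identity", "log", "response-proportion", "response-rate")

    def __post_init__(self) -> None:
        if self.scale not in self._SCALES:
            raise ValueError(f"unknown scale tag {self.scale!r}")

    def linear(self) -> tuple[float, float, float, float]:
        """Coefficients on the model's additive (link) scale.

        ``response-rate`` entries are stored as rates/rate ratios and are
        logged here; ``response-proportion`` tables are additive already
        (cell means are formed by summation) and pass through.
        """
        import math

        if self.scale == "response-rate":
            return (
                math.log(self.intercept),
                math.log(self.season),
                math.log(self.species),
                math.log(self.interaction),
            )
        return (self.intercept, self.season, self.species, self.interaction)

    def cell_mean(self, species: str, season: str) -> float:
        """Planted cell mean on the response scale (reference: gemsbok/drought)."""
        import math

        b0, b_season, b_species, b_int = self.linear()
        eta = b0
        if season == "non-drought":
            eta += b_season
        if species == "wildebeest":
            eta += b_species
        if season == "non-drought" and species == "wildebeest":
            eta += b_int
        if self.scale in ("log", "response-rate"):
            return math.exp(eta)
        return eta


@dataclass(frozen=True)
class VarianceComponents:
    """Random-effect and residual SDs for one response (model scale)."""

    animal_sd: float
    date_sd: float
    residual_sd: float

    def __post_init__(self) -> None:
        for name in ("animal_sd", "date_sd", "residual_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


def _default_windows() -> tuple[SeasonWindow, SeasonWindow]:
    return (
        SeasonWindow("drought", dt.date(2013, 9, 1), dt.date(2013, 11, 30), 132.0),
        SeasonWindow("non-drought", dt.date(2014, 9, 1), dt.date(2014, 11, 30), 277.0),
    )


def _default_coefficients() -> dict[str, PlantedCoefficients]:
    # Fixed-effect tables planted as simulator truth, reference levels
    # drought / gemsbok.  t_max is tied to t_min + t_amplitude so the three
    # body-temperature responses stay mutually consistent.
    return {
        "t_min": PlantedCoefficients(37.64, -0.13, -0.97, 0.90, "identity"),
        "t_amplitude": PlantedCoefficients(2.2, -0.08, 1.0, -1.03, "identity"),
        "t_max": PlantedCoefficients(39.84, -0.21, 0.03, -0.13, "identity"),
        "cool_hours": PlantedCoefficients(5.16, 0.72, 1.0, 1.0, "response-rate"),
        "cumulative_cool_use": PlantedCoefficients(17.38, -8.54, 2.78, -1.45, "identity"),
        "travel_hours": PlantedCoefficients(0.06, 1.57, 4.68, 0.37, "response-rate"),
        "total_activity_24h": PlantedCoefficients(0.89, -0.07, -0.13, 0.52, "log"),
        "heat_activity_proportion": PlantedCoefficients(0.13, 0.05, -0.01, -0.05, "response-proportion"),
    }


def _default_variances() -> dict[str, VarianceComponents]:
    return {
        "t_min": VarianceComponents(0.40, 0.15, 0.35),
        "t_amplitude": VarianceComponents(0.35, 0.12, 0.50),
        "cool_hours": VarianceComponents(0.15, 0.10, 0.0),
        "cumulative_cool_use": VarianceComponents(2.5, 1.0, 2.5),
        "travel_hours": VarianceComponents(0.20, 0.10, 0.0),
        "total_activity_24h": VarianceComponents(0.15, 0.08, 0.25),
        "heat_activity_proportion": VarianceComponents(0.015, 0.008, 0.030),
    }


@dataclass(frozen=True)
class ReferenceGlobeParams:
    """Seasonal envelope for the free-standing (full sun) miniglobe, °C.

    Daily maxima/minima are drawn per day around these means; the SDs are
    across-day SDs of the daily extremes.
    """

    daily_max_mean: float
    daily_max_sd: float
    daily_min_mean: float
    daily_min_sd: float


@dataclass(frozen=True)
class WeatherParams:
    """Seasonal weather-station envelope: dry bulb (°C), solar, wind, rain, NDVI."""

    drybulb_max_mean: float
    drybulb_max_sd: float
    drybulb_min_mean: float
    drybulb_min_sd: float
    solar_mean: float  # mean 24 h solar radiation, W m^-2
    solar_sd: float
    wind_mean: float  # mean 24 h wind speed, m s^-1
    wind_sd: float
    rain_total_mm: float
    rainy_days: int
    ndvi_mean: float
    ndvi_sd: float


def _default_environment() -> dict[str, tuple[ReferenceGlobeParams, WeatherParams]]:
    return {
        "drought": (
            ReferenceGlobeParams(40.2, 5.5, 10.6, 4.0),
            WeatherParams(34.9, 3.8, 10.8, 4.7, 26.8, 4.1, 1.6, 0.1, 22.0, 6, 0.146, 0.005),
        ),
        "non-drought": (
            ReferenceGlobeParams(42.1, 2.8, 9.8, 1.9),
            WeatherParams(35.2, 1.6, 11.7, 3.2, 24.4, 2.8, 1.7, 0.2, 35.0, 11, 0.188, 0.003),
        ),
    }


@dataclass(frozen=True)
class SimulationConfig:
    """Full parameterization of a synthetic bio-logger study."""

    n_gemsbok: int = 5
    n_wildebeest: int = 6
    season_windows: tuple[SeasonWindow, SeasonWindow] = field(default_factory=_default_windows)
    planted_coefficients: Mapping[str, PlantedCoefficients] = field(default_factory=_default_coefficients)
    variance_components: Mapping[str, VarianceComponents] = field(default_factory=_default_variances)
    environment: Mapping[str, tuple[ReferenceGlobeParams, WeatherParams]] = field(
        default_factory=_default_environment
    )
    #: per species-season expected excursion (>1.6 km) hours/day come from
    #: planted_coefficients["travel_hours"]; cool-hours/day from
    #: planted_coefficients["cool_hours"].
    shade_depth_range: tuple[float, float] = (2.0, 4.0)  # °C cooling during shade bouts
    globe_sensor_sd: float = 0.3  # °C noise on the collar miniglobe
    dropout_rate: float = 0.02  # independent per-record missingness
    bodytemp_texture_sd: float = 0.08  # within-day AR(1) texture, °C
    bodytemp_ar1_rho: float = 0.6  # at the 10-min lag
    activity_jitter_cv: float = 0.45  # within-day overdispersion of 5-min counts
    rng_seed: int = 20130901
    latitude: float = -24.35
    longitude: float = 20.62
    boundary: DayBoundary = field(default_factory=DayBoundary)

    def __post_init__(self) -> None:
        if self.n_gemsbok < 0 or self.n_wildebeest < 0:
            raise ValueError("animal counts must be non-negative")
        if self.n_gemsbok + self.n_wildebeest == 0:
            raise ValueError("at least one animal is required")
        w1, w2 = self.season_windows
        if {w1.label, w2.label} != {"drought", "non-drought"}:
            raise ValueError("season windows must be labelled 'drought' and 'non-drought'")
        if not (w1.end < w2.start or w2.end < w1.start):
            raise ValueError("season windows must be disjoint")
        for w in (w1, w2):
            if w.n_days < 28:
                raise ValueError(f"season window {w.label} must span at least 28 days")
        if self.dropout_rate < 0 or self.dropout_rate >= 1:
            raise ValueError("dropout_rate must be in [0, 1)")
        if self.shade_depth_range[0] <= 0.5:
            raise ValueError("shade cooling depth must exceed the 0.5 °C detection threshold")

    @property
    def window(self) -> dict[str, SeasonWindow]:
        return {w.label: w for w in self.season_windows}

    def animals(self) -> list[tuple[str, str]]:
        """Roster as (animal_id, species) pairs."""
        roster = [(f"G{i + 1:02d}", "gemsbok") for i in range(self.n_gemsbok)]
        roster += [(f"W{i + 1:02d}", "wildebeest") for i in range(self.n_wildebeest)]
        return roster

    @property
    def is_zero_noise(self) -> bool:
        return (
            all(
                v.animal_sd == 0 and v.date_sd == 0 and v.residual_sd == 0
                for v in self.variance_components.values()
            )
            and self.globe_sensor_sd == 0
            and self.dropout_rate == 0
            and self.bodytemp_texture_sd == 0
            and self.activity_jitter_cv == 0
        )

    def zero_noise(self) -> "SimulationConfig":
        """Copy of this config with every stochastic component switched off.

        Under the resulting config every derived daily metric equals its
        planted cell mean (count responses: the rounded planted rate),
        and the environmental envelope loses its day-to-day variation.
        """
        vz = {k: VarianceComponents(0.0, 0.0, 0.0) for k in self.variance_components}
        env = {
            label: (
                dataclasses.replace(g, daily_max_sd=0.0, daily_min_sd=0.0),
                dataclasses.replace(
                    w, drybulb_max_sd=0.0, drybulb_min_sd=0.0, solar_sd=0.0, wind_sd=0.0, ndvi_sd=0.0
                ),
            )
            for label, (g, w) in self.environment.items()
        }
        return dataclasses.replace(
            self,
            variance_components=vz,
            environment=env,
            globe_sensor_sd=0.0,
            dropout_rate=0.0,
            bodytemp_texture_sd=0.0,
            activity_jitter_cv=0.0,
        )


def default_config(**overrides) -> SimulationConfig:
    """The study-default configuration, optionally with field overrides."""
    return dataclasses.replace(SimulationConfig(), **overrides) if overrides else SimulationConfig()


# ---------------------------------------------------------------------------
# YAML round-trip (CLI surface)

def dump_config(config: SimulationConfig, path) -> None:
    doc = {
        "n_gemsbok": config.n_gemsbok,
        "n_wildebeest": config.n_wildebeest,
        "rng_seed": config.rng_seed,
        "dropout_rate": config.dropout_rate,
        "globe_sensor_sd": config.globe_sensor_sd,
        "latitude": config.latitude,
        "longitude": config.longitude,
        "season_windows": [
            {
                "label": w.label,
                "start": w.start.isoformat(),
                "end": w.end.isoformat(),
                "preceding_wet_rainfall_mm": w.preceding_wet_rainfall_mm,
            }
            for w in config.season_windows
        ],
        "planted_coefficients": {
            name: {
                "intercept": c.intercept,
                "season": c.season,
                "species": c.species,
                "interaction": c.interaction,
                "scale": c.scale,
            }
            for name, c in config.planted_coefficients.items()
        },
        "variance_components": {
            name: {"animal_sd": v.animal_sd, "date_sd": v.date_sd, "residual_sd": v.residual_sd}
            for name, v in config.variance_components.items()
        },
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def load_config(path) -> SimulationConfig:
    """Load a (possibly partial) YAML config; unlisted fields keep defaults."""
    with open(path) as fh:
        doc = yaml.safe_load(fh) or {}
    kwargs = {}
    for key in (
        "n_gemsbok",
        "n_wildebeest",
        "rng_seed",
        "dropout_rate",
        "globe_sensor_sd",
        "latitude",
        "longitude",
    ):
        if key in doc:
            kwargs[key] = doc[key]
    if "season_windows" in doc:
        kwargs["season_windows"] = tuple(
            SeasonWindow(
                w["label"],
                dt.date.fromisoformat(w["start"]),
                dt.date.fromisoformat(w["end"]),
                w.get("preceding_wet_rainfall_mm"),
            )
            for w in doc["season_windows"]
        )
    if "planted_coefficients" in doc:
        base = _default_coefficients()
        for name, c in doc["planted_coefficients"].items():
            base[name] = PlantedCoefficients(
                c["intercept"], c["season"], c["species"], c["interaction"], c.get("scale", "identity")
            )
        kwargs["planted_coefficients"] = base
    if "variance_components" in doc:
        base_v = _default_variances()
        for name, v in doc["variance_components"].items():
            base_v[name] = VarianceComponents(v["animal_sd"], v["date_sd"], v["residual_sd"])
        kwargs["variance_components"] = base_v
    return default_config(**kwargs)
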