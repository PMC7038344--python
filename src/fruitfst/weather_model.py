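"""Weather-driven fruit surface temperature: station lookup and energy balance.

The weather path to FST mirrors how a field tool works offline from
imagery: locate the nearest automated weather station from GPS
coordinates, pull its 15-minute records (air temperature, dew point,
solar radiation, wind speed, plus surrounding ground temperature), and
solve a steady-state energy balance for the fruit surface temperature.

The balance treats the fruit as a sphere exchanging energy per unit
surface area:

    a_s * S / 4                          absorbed shortwave (projected/
                                         surface area of a sphere = 1/4)
  + eps_f * sigma * (F_sky * eps_sky * T_air^4 + F_gnd * T_gnd^4)
                                         absorbed longwave from sky + ground
  - eps_f * sigma * (F_sky + F_gnd) * T_f^4
                                         emitted fruit thermal radiation
  - h(u) * (T_f - T_air)                 sensible (convective) exchange,
                                         h = h_free + h_base * u^b
  - g_et * (e_sat(T_f) - e_air)          evapotranspiration (0 by default)
  = residual

Sky emissivity follows a Brunt-type clear-sky correlation on the vapour
pressure at the dew point.  The residual is strictly decreasing in T_f,
so the root is unique and found by bracketed root finding.  Internal heat
storage is taken as zero at steady state.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from datetime import datetime
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import brentq

STEFAN_BOLTZMANN = 5.670374419e-8  # W m-2 K-4
EARTH_RADIUS_KM = 6371.0


class ModelConfigurationError(ValueError):
    """Raised when the energy balance cannot bracket a root for a record."""


@dataclass(frozen=True)
class Station:
    station_id: str
    latitude: float
    longitude: float

    def __post_init__(self) -> None:
        if abs(self.latitude) > 90 or abs(self.longitude) > 180:
            raise ValueError(f"invalid coordinates for station {self.station_id}")


@dataclass(frozen=True)
class WeatherRecord:
    """One (typically 15-minute mean) weather observation."""

    timestamp: datetime
    air_temp_c: float
    dew_point_c: float
    ground_temp_c: float
    solar_rad_wm2: float
    wind_speed_ms: float

    def __post_init__(self) -> None:
        if self.dew_point_c > self.air_temp_c + 1e-9:
            raise ValueError(
                f"{self.timestamp}: dew point {self.dew_point_c} degC exceeds "
                f"air temperature {self.air_temp_c} degC"
            )
        if self.solar_rad_wm2 < 0:
            raise ValueError(f"{self.timestamp}: negative solar radiation")
        if self.wind_speed_ms < 0:
            raise ValueError(f"{self.timestamp}: negative wind speed")


@dataclass(frozen=True)
class EnergyBalanceParams:
    """Coefficients of the spherical-fruit steady-state energy balance.

    shortwave_absorptivity : unitless in (0, 1]; apple peel ~0.6.
    fruit_emissivity : unitless in (0, 1]; fruit surfaces ~0.95 (close to
        water, which is why a water bath calibrates the sensor well).
    fruit_diameter_m : m; documents the geometry the convection
        coefficients were chosen for.
    convective_coefficient_base : W m-2 K-1 at 1 m s-1 wind; forced
        convection for an 8 cm sphere gives ~13.
    wind_exponent : forced-convection wind-speed exponent (~0.5 for a
        sphere in the relevant Reynolds range).
    convective_coefficient_free : W m-2 K-1 free-convection floor so heat
        still leaves the fruit in calm air.
    evapotranspiration_conductance : W m-2 kPa-1 on the fruit-to-air
        vapour pressure deficit; 0 disables the term (waxy mature apples
        transpire little).
    sky_view_factor, ground_view_factor : fractions of the longwave field
        seen as sky and as ground; sum <= 1.
    sky_emissivity : override; None derives it from dew point via the
        Brunt correlation.
    """

    shortwave_absorptivity: float = 0.6
    fruit_emissivity: float = 0.95
    fruit_diameter_m: float = 0.08
    convective_coefficient_base: float = 13.0
    wind_exponent: float = 0.5
    convective_coefficient_free: float = 5.0
    evapotranspiration_conductance: float = 0.0
    sky_view_factor: float = 0.5
    ground_view_factor: float = 0.5
    sky_emissivity: float | None = None

    def __post_init__(self) -> None:
        if not (0 < self.shortwave_absorptivity <= 1):
            raise ValueError("shortwave_absorptivity must be in (0, 1]")
        if not (0 < self.fruit_emissivity <= 1):
            raise ValueError("fruit_emissivity must be in (0, 1]")
        if self.fruit_diameter_m <= 0:
            raise ValueError("fruit_diameter_m must be > 0")
        if self.sky_view_factor < 0 or self.ground_view_factor < 0:
            raise ValueError("view factors must be >= 0")
        if self.sky_view_factor + self.ground_view_factor > 1 + 1e-9:
            raise ValueError("view factors must sum to <= 1")


def haversine_km(lat1: float, lon1: float, lat2: float, lon2: float) -> float:
    """Great-circle distance in km (spherical Earth, radius 6371 km)."""
    for lat, lon in ((lat1, lon1), (lat2, lon2)):
        if abs(lat) > 90 or abs(lon) > 180:
            raise ValueError(f"invalid coordinates ({lat}, {lon})")
    p1, p2 = np.radians(lat1), np.radians(lat2)
    dphi = np.radians(lat2 - lat1)
    dlam = np.radians(lon2 - lon1)
    a = np.sin(dphi / 2) ** 2 + np.cos(p1) * np.cos(p2) * np.sin(dlam / 2) ** 2
    return float(2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(a)))


def nearest_station(
    lat: float, lon: float, stations: list[Station]
) -> tuple[Station, float]:
    """The station minimizing great-circle distance; ties break by list order."""
    if not stations:
        raise ValueError("station list is empty")
    best, best_d = None, np.inf
    for s in stations:
        d = haversine_km(lat, lon, s.latitude, s.longitude)
        if d < best_d:
            best, best_d = s, d
    return best, best_d


def saturation_vapor_pressure_kpa(temp_c: float) -> float:
    """Magnus saturation vapour pressure over water, kPa."""
    return 0.6108 * np.exp(17.27 * temp_c / (temp_c + 237.3))


def sky_emissivity_brunt(dew_point_c: float) -> float:
    """Brunt clear-sky emissivity from vapour pressure at the dew point."""
    e_hpa = 10.0 * saturation_vapor_pressure_kpa(dew_point_c)
    return float(min(1.0, 0.605 + 0.048 * np.sqrt(e_hpa)))


def energy_balance_residual(
    fst_c: float, w: WeatherRecord, p: EnergyBalanceParams | None = None
) -> float:
    """Net energy flux (W m-2) into the fruit surface at temperature fst_c.

    Positive residual means the surface would warm; the function is
    strictly decreasing in fst_c (emission, convection and transpiration
    all grow with surface temperature), so its root is the steady-state
    FST.
    """
    p = p or EnergyBalanceParams()
    if not np.isfinite(fst_c):
        raise ValueError("fst_c must be finite")
    tf = fst_c + 273.15
    ta = w.air_temp_c + 273.15
    tg = w.ground_temp_c + 273.15
    eps_sky = (
        p.sky_emissivity
        if p.sky_emissivity is not None
        else sky_emissivity_brunt(w.dew_point_c)
    )
    shortwave = p.shortwave_absorptivity * w.solar_rad_wm2 * 0.25
    lw_in = p.fruit_emissivity * STEFAN_BOLTZMANN * (
        p.sky_view_factor * eps_sky * ta**4 + p.ground_view_factor * tg**4
    )
    lw_out = (
        p.fruit_emissivity
        * STEFAN_BOLTZMANN
        * (p.sky_view_factor + p.ground_view_factor)
        * tf**4
    )
    h = (
        p.convective_coefficient_free
        + p.convective_coefficient_base * w.wind_speed_ms**p.wind_exponent
    )
    sensible = h * (fst_c - w.air_temp_c)
    et = p.evapotranspiration_conductance * max(
        0.0,
        saturation_vapor_pressure_kpa(fst_c)
        - saturation_vapor_pressure_kpa(w.dew_point_c),
    )
    return float(shortwave + lw_in - lw_out - sensible - et)


def solve_fst(
    w: WeatherRecord,
    p: EnergyBalanceParams | None = None,
    tol_c: float = 0.01,
) -> float:
    """Steady-state FST (degC): the unique root of the balance residual.

    Bracketed on [air_temp - 15, air_temp + 40] degC.  A bracket without
    a sign change means the coefficients are inconsistent with the
    record, which is a configuration error, not a numeric one.
    """
    p = p or EnergyBalanceParams()
    lo, hi = w.air_temp_c - 15.0, w.air_temp_c + 40.0
    f_lo = energy_balance_residual(lo, w, p)
    f_hi = energy_balance_residual(hi, w, p)
    if f_lo * f_hi > 0:
        raise ModelConfigurationError(
            f"energy balance has no root in [{lo}, {hi}] degC for record at "
            f"{w.timestamp} (residuals {f_lo:.1f}, {f_hi:.1f} W m-2)"
        )
    xtol = min(tol_c / 10.0, 1e-6)  # residual slope is O(30 W m-2 K-1)
    return float(brentq(energy_balance_residual, lo, hi, args=(w, p), xtol=xtol))


WEATHER_COLUMNS = [
    "timestamp",
    "air_temp_c",
    "dew_point_c",
    "ground_temp_c",
    "solar_rad_wm2",
    "wind_speed_ms",
]


def load_weather_csv(path: str | Path) -> list[WeatherRecord]:
    """Load and validate weather records; returned chronologically sorted.

    The expected cadence is 15-minute means but gaps are tolerated (and
    reported via the module logger at load, not enforced).
    """
    df = pd.read_csv(path, parse_dates=["timestamp"])
    missing = set(WEATHER_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing weather columns {sorted(missing)}")
    records = []
    for i, row in df.iterrows():
        try:
            records.append(
                WeatherRecord(
                    timestamp=row["timestamp"].to_pydatetime(),
                    air_temp_c=float(row["air_temp_c"]),
                    dew_point_c=float(row["dew_point_c"]),
                    ground_temp_c=float(row["ground_temp_c"]),
                    solar_rad_wm2=float(row["solar_rad_wm2"]),
                    wind_speed_ms=float(row["wind_speed_ms"]),
                )
            )
        except ValueError as exc:
            raise ValueError(f"{path}: invalid weather row {i}: {exc}") from exc
    records.sort(key=lambda r: r.timestamp)
    return records


def load_stations_csv(path: str | Path) -> list[Station]:
    """Load a station table: station_id, latitude, longitude."""
    df = pd.read_csv(path)
    return [
        Station(str(r["station_id"]), float(r["latitude"]), float(r["longitude"]))
        for _, r in df.iterrows()
    ]
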