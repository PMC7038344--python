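"""Capture-batch orchestration: imagery FST, weather FST, risk, report.

Reproduces the field workflow end to end: for each capture pair, segment
the fruit and take masked thermal statistics (the imagery path), find the
temporally nearest record from the nearest weather station and solve the
energy balance (the weather path), and classify sunburn risk on the
larger of the imagery maximum and the weather estimate — the imagery
*mean* systematically underestimates the hottest point of the fruit,
while the maximum tracks contact-probe ground truth, so alerting on the
max is the defensible choice.

The report is a pure function of its inputs and configuration: re-running
it reproduces the CSV byte for byte.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from datetime import datetime, timedelta

from .io_formats import CapturePair, export_results
from .risk import RiskThresholds, classify_risk
from .segmentation import SegmentationParams
from .thermal_fst import (
    CalibrationModel,
    RegistrationTransform,
    capture_to_fst,
)
from .weather_model import (
    EnergyBalanceParams,
    ModelConfigurationError,
    Station,
    WeatherRecord,
    nearest_station,
    solve_fst,
)

logger = logging.getLogger("fruitfst")

#: A capture farther than this from any weather record is flagged.
MAX_WEATHER_GAP = timedelta(minutes=30)


@dataclass(frozen=True)
class RunConfig:
    """Everything the batch report depends on; defaults are the published values."""

    segmentation: SegmentationParams = field(default_factory=SegmentationParams)
    registration: RegistrationTransform = field(default_factory=RegistrationTransform)
    calibration: CalibrationModel = field(default_factory=CalibrationModel.identity)
    energy_balance: EnergyBalanceParams = field(default_factory=EnergyBalanceParams)
    risk_thresholds: RiskThresholds = field(default_factory=RiskThresholds)
    max_weather_gap: timedelta = MAX_WEATHER_GAP


def nearest_record(
    when: datetime, records: list[WeatherRecord]
) -> tuple[WeatherRecord | None, timedelta | None]:
    """The weather record temporally nearest to ``when`` and its gap."""
    if not records:
        return None, None
    best = min(records, key=lambda r: abs(r.timestamp - when))
    return best, abs(best.timestamp - when)


def analyze_capture(
    pair: CapturePair,
    weather: list[WeatherRecord],
    stations: list[Station],
    config: RunConfig | None = None,
) -> dict:
    """Analyze one capture pair into a result row (see io_formats.RESULT_COLUMNS).

    Problems (no fruit detected, no weather coverage, unsolvable balance)
    flag the row rather than dropping it — a field report must account
    for every capture.
    """
    cfg = config or RunConfig()
    flags: list[str] = []

    analysis = capture_to_fst(
        pair, cfg.segmentation, cfg.registration, cfg.calibration
    )
    if analysis.fruit_detected:
        mean_fst, max_fst = analysis.fst.mean_fst, analysis.fst.max_fst
    else:
        mean_fst = max_fst = None
        flags.append("no fruit detected")

    station_id = None
    if stations:
        station, dist_km = nearest_station(pair.latitude, pair.longitude, stations)
        station_id = station.station_id
        logger.info("capture %s: station %s at %.2f km", pair.capture_id, station_id, dist_km)

    weather_fst = air_temp = None
    if weather and pair.timestamp is not None:
        rec, gap = nearest_record(pair.timestamp, weather)
        if gap is not None and gap > cfg.max_weather_gap:
            flags.append(f"weather gap {gap}")
        else:
            air_temp = rec.air_temp_c
            try:
                weather_fst = round(solve_fst(rec, cfg.energy_balance), 2)
            except ModelConfigurationError as exc:
                flags.append(str(exc))
    elif weather:
        flags.append("capture has no timestamp")
    else:
        flags.append("no weather records")

    candidates = [x for x in (max_fst, weather_fst) if x is not None]
    risk = classify_risk(max(candidates), cfg.risk_thresholds).risk_class.value if candidates else None

    return {
        "capture_id": pair.capture_id,
        "timestamp": pair.timestamp.isoformat() if pair.timestamp else "",
        "latitude": pair.latitude,
        "longitude": pair.longitude,
        "mean_fst_c": mean_fst,
        "max_fst_c": max_fst,
        "weather_fst_c": weather_fst,
        "air_temp_c": air_temp,
        "risk_class": risk,
        "flag": "; ".join(flags),
    }


def run_report(
    captures: list[CapturePair],
    weather: list[WeatherRecord],
    stations: list[Station],
    config: RunConfig | None = None,
    out_csv: str | None = None,
    out_json: str | None = None,
) -> list[dict]:
    """Analyze a batch of captures and optionally write CSV/JSON reports."""
    rows = [analyze_capture(p, weather, stations, config) for p in captures]
    if out_csv:
        export_results(rows, out_csv, fmt="csv")
    if out_json:
        export_results(rows, out_json, fmt="json")
    return rows
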