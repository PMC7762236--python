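"""Day length, photo-thermal units, and phenology-windowed weather covariates.

All windows are closed intervals: both stage dates contribute, so a
one-day window is never empty.
"""

from __future__ import annotations

import datetime as dt
import logging
import math
from dataclasses import dataclass, fields
from typing import Sequence

import pandas as pd

from .data import (
    DailyWeather,
    DataError,
    Experiment,
    PlotRecord,
    WeatherSeries,
)

logger = logging.getLogger(__name__)

#: civil-twilight daylength coefficient (degrees below horizon)
DEFAULT_TWILIGHT_DEG = 6.0
DEFAULT_T_BASE = 0.0


@dataclass(frozen=True)
class PlotCovariates:
    """The eleven per-plot environmental covariates.

    Covariates whose defining stage date is missing are ``None``.
    """

    site: str
    year: int
    block: int
    genotype_id: str
    tmean_ef: float | None = None
    tmean_fm: float | None = None
    tmax_f: float | None = None
    rmean_ef: float | None = None
    rmean_drf: float | None = None
    rmean_fm: float | None = None
    rac_ef: float | None = None
    dlmean_ef: float | None = None
    dlmean_fm: float | None = None
    ptu_tsf: float | None = None


def day_length(latitude_deg: float, day_of_year: int, daylength_coef_deg: float = DEFAULT_TWILIGHT_DEG) -> float:
    """Photoperiod in hours for a latitude and day of year (CBM model).

    ``daylength_coef_deg`` is the solar-depression angle defining
    "daylight"; 6° includes civil twilight. The acos argument is clamped
    to [-1, 1], so polar day/night return 24 or 0 with a warning.
    """
    if not 1 <= day_of_year <= 366:
        raise DataError(f"day_of_year {day_of_year} out of 1..366")
    j = day_of_year
    theta = 0.2163108 + 2.0 * math.atan(0.9671396 * math.tan(0.00860 * (j - 186)))
    phi = math.asin(0.39795 * math.cos(theta))
    p = math.radians(daylength_coef_deg)
    lat = math.radians(latitude_deg)
    x = (math.sin(p) + math.sin(lat) * math.sin(phi)) / (math.cos(lat) * math.cos(phi))
    if x > 1.0 or x < -1.0:
        logger.warning(
            "day_length clamped at latitude %.2f, day %d (polar day/night)",
            latitude_deg,
            day_of_year,
        )
        x = max(-1.0, min(1.0, x))
    return 24.0 - (24.0 / math.pi) * math.acos(x)


def photothermal_units(
    window: Sequence[DailyWeather],
    latitude_deg: float,
    t_base: float = DEFAULT_T_BASE,
    daylength_coef_deg: float = DEFAULT_TWILIGHT_DEG,
) -> float:
    """Accumulated photo-thermal units (°C·h) over a daily window.

    Each day contributes max(tmean - t_base, 0) × day length; always >= 0.
    """
    total = 0.0
    for rec in window:
        forcing = max(rec.tmean - t_base, 0.0)
        doy = rec.date.timetuple().tm_yday
        total += forcing * day_length(latitude_deg, doy, daylength_coef_deg)
    return total


def _mean(values: Sequence[float]) -> float:
    return sum(values) / len(values)


def window_aggregates(
    record: PlotRecord,
    weather: WeatherSeries,
    latitude_deg: float,
    t_base: float = DEFAULT_T_BASE,
    daylength_coef_deg: float = DEFAULT_TWILIGHT_DEG,
) -> PlotCovariates:
    """Compute all phenology-windowed covariates for one plot.

    Requires flowering and maturity dates; covariates depending on the
    optional double-ridge / terminal-spikelet stages are left absent when
    those dates are missing.
    """
    if record.date_flowering is None or record.date_maturity is None:
        raise DataError(f"plot {record.plot_id()}: flowering/maturity date required")
    site, year = record.site, record.year
    flo, mat = record.date_flowering, record.date_maturity
    out: dict[str, float | None] = {}

    if record.date_emergence is not None:
        ef = weather.window(site, year, record.date_emergence, flo)
        out["tmean_ef"] = _mean([d.tmean for d in ef])
        out["rmean_ef"] = _mean([d.radiation for d in ef])
        out["rac_ef"] = sum(d.radiation for d in ef)
        out["dlmean_ef"] = _mean(
            [
                day_length(latitude_deg, d.date.timetuple().tm_yday, daylength_coef_deg)
                for d in ef
            ]
        )

    fm = weather.window(site, year, flo, mat)
    out["tmean_fm"] = _mean([d.tmean for d in fm])
    out["rmean_fm"] = _mean([d.radiation for d in fm])
    out["dlmean_fm"] = _mean(
        [
            day_length(latitude_deg, d.date.timetuple().tm_yday, daylength_coef_deg)
            for d in fm
        ]
    )

    # 11 days centred on flowering: five before to five after
    win_f = weather.window(
        site, year, flo - dt.timedelta(days=5), flo + dt.timedelta(days=5)
    )
    out["tmax_f"] = _mean([d.tmax for d in win_f])

    if record.date_double_ridge is not None:
        drf = weather.window(site, year, record.date_double_ridge, flo)
        out["rmean_drf"] = _mean([d.radiation for d in drf])

    if record.date_terminal_spikelet is not None:
        tsf = weather.window(site, year, record.date_terminal_spikelet, flo)
        out["ptu_tsf"] = photothermal_units(tsf, latitude_deg, t_base, daylength_coef_deg)

    return PlotCovariates(
        site=site, year=year, block=record.block, genotype_id=record.genotype_id, **out
    )


COVARIATE_COLUMNS = [
    f.name for f in fields(PlotCovariates) if f.name not in ("site", "year", "block", "genotype_id")
]


def covariates_table(
    records: Sequence[PlotRecord],
    weather: WeatherSeries,
    experiments: Sequence[Experiment],
    t_base: float = DEFAULT_T_BASE,
    daylength_coef_deg: float = DEFAULT_TWILIGHT_DEG,
) -> pd.DataFrame:
    """One covariate row per plot, latitudes resolved from experiments."""
    lat = {(e.site, e.year): e.latitude for e in experiments}
    rows = []
    for r in records:
        key = (r.site, r.year)
        if key not in lat:
            raise DataError(f"no experiment metadata for {r.environment_id}")
        cov = window_aggregates(r, weather, lat[key], t_base, daylength_coef_deg)
        row = {
            "site": cov.site,
            "year": cov.year,
            "block": cov.block,
            "genotype": cov.genotype_id,
        }
        for c in COVARIATE_COLUMNS:
            row[c] = getattr(cov, c)
        rows.append(row)
    return pd.DataFrame(rows)
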