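"""Synthetic multi-environment trial generator with known ground truth.

Emulates the study design: 3 sites of contrasting latitude × 5 years ×
23 genotypes in 5 photoperiod-allele combinations (one singleton
combination excluded) × 3 complete blocks. Flowering time is generated
directly in days with additive allele-combination and earliness-per-se
effects; grain weight declines with late flowering; grain number
partially compensates grain weight; a per-genotype sensitivity
multiplier on a shared environment-quality term makes the true joint
regression slopes exactly known.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import json
import logging
import math
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .data import (
    DailyWeather,
    DataError,
    Experiment,
    GenotypeMeta,
    GenotypeTable,
    PlotRecord,
    derive_traits,
    write_experiment_table,
    write_genotype_table,
    write_plot_table,
    write_weather_table,
)
from .covariates import day_length

logger = logging.getLogger(__name__)

SITE_SPAIN = "Spain"
SITE_MEXICO_NORTH = "Mexico-North"
SITE_MEXICO_SOUTH = "Mexico-South"

DEFAULT_YEARS = (2007, 2008, 2010, 2011, 2012)

#: years with the extra growth-stage observations (3 of the 5)
DETAILED_YEARS = (2010, 2011, 2012)

DEFAULT_AC_FLOWERING_EFFECT = {
    "I0I": 0.0,
    "I5I": 2.0,
    "I5S": 5.0,
    "SS": 7.0,
    "SI": 9.0,
    "I0S": 0.0,
}

DEFAULT_AC_GN_EFFECT = {
    "I0I": 0.0,
    "I5I": 0.0,
    "I5S": 1800.0,
    "SS": 1200.0,
    "SI": 0.0,
    "I0S": 0.0,
}


@dataclass(frozen=True)
class SiteWeather:
    tmean_annual: float
    tmean_amplitude: float
    tmean_phase_doy: float
    diurnal_half_range: float
    rad_clear_sky: float
    ar1_rho: float
    ar1_sd: float
    cloud_sd: float


DEFAULT_SITE_WEATHER = {
    SITE_SPAIN: SiteWeather(14.0, 8.0, 108.0, 6.0, 32.0, 0.7, 1.5, 0.15),
    SITE_MEXICO_NORTH: SiteWeather(22.0, 7.0, 108.0, 7.0, 36.0, 0.7, 1.2, 0.10),
    SITE_MEXICO_SOUTH: SiteWeather(16.0, 3.0, 108.0, 6.0, 34.0, 0.7, 1.0, 0.20),
}

DEFAULT_BASE_DAYS = {SITE_SPAIN: 150.0, SITE_MEXICO_NORTH: 110.0, SITE_MEXICO_SOUTH: 70.0}
DEFAULT_FILL_DAYS = {SITE_SPAIN: 42.0, SITE_MEXICO_NORTH: 46.0, SITE_MEXICO_SOUTH: 38.0}
DEFAULT_GN_SITE_EFFECT = {SITE_SPAIN: 3000.0, SITE_MEXICO_NORTH: 0.0, SITE_MEXICO_SOUTH: -3000.0}


def default_experiments(years: Sequence[int] = DEFAULT_YEARS) -> list[Experiment]:
    """The 15 site-year experiments: winter sowing in Spain and
    Mexico-North, spring planting in Mexico-South."""
    exps = []
    for year in years:
        exps.append(Experiment(SITE_SPAIN, year, 41.63, dt.date(year - 1, 11, 25)))
        exps.append(Experiment(SITE_MEXICO_NORTH, year, 27.35, dt.date(year - 1, 12, 10)))
        exps.append(Experiment(SITE_MEXICO_SOUTH, year, 19.52, dt.date(year, 5, 20)))
    return exps


def default_genotypes() -> GenotypeTable:
    """24-genotype roster: combination counts SS 5, SI 5, I5S 4, I5I 6,
    I0I 3 plus the single excluded I0S genotype."""
    spec = [
        ("SS", "Ppd-A1b", "Ppd-B1b", 5),
        ("SI", "Ppd-A1b", "Ppd-B1a", 5),
        ("I5S", "GS105-Ppd-A1a", "Ppd-B1b", 4),
        ("I5I", "GS105-Ppd-A1a", "Ppd-B1a", 6),
        ("I0S", "GS100-Ppd-A1a", "Ppd-B1b", 1),
        ("I0I", "GS100-Ppd-A1a", "Ppd-B1a", 3),
    ]
    metas = []
    for ac, a1, b1, n in spec:
        for k in range(1, n + 1):
            metas.append(GenotypeMeta(f"G-{ac}-{k}", a1, b1))
    return GenotypeTable(metas)


@dataclass
class SimConfig:
    """All tunables of the trial simulator; defaults emulate the study."""

    seed: int = 0
    experiments: list[Experiment] = field(default_factory=default_experiments)
    genotypes: GenotypeTable = field(default_factory=default_genotypes)
    n_blocks: int = 3
    ac_flowering_effect: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_AC_FLOWERING_EFFECT)
    )
    ac_gn_effect: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_AC_GN_EFFECT))
    sigma_eps_days: float = 3.0
    base_days_to_flowering: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_BASE_DAYS))
    grain_fill_days: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_FILL_DAYS))
    days_to_emergence: float = 10.0
    sigma_year_flowering: float = 2.0
    sigma_block_flowering: float = 0.3
    sigma_plot_flowering: float = 1.0
    sigma_genotype_fill: float = 1.5
    sigma_plot_fill: float = 1.0
    gw_base: float = 45.0
    gw_per_day_late: float = -0.5
    sigma_genotype_gw: float = 3.0
    sigma_block_gw: float = 0.5
    sigma_plot_gw: float = 1.5
    gn_base: float = 12000.0
    gn_site_effect: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_GN_SITE_EFFECT))
    sigma_env_quality: float = 2000.0
    sigma_sensitivity: float = 0.12
    gn_gw_compensation: float = 0.4
    gn_per_mg_scale: float = 300.0
    sigma_block_gn: float = 300.0
    sigma_plot_gn: float = 800.0
    spikes_base: float = 380.0
    sigma_plot_spikes: float = 30.0
    spikelets_base: float = 17.0
    spikelets_per_day_late: float = 0.15
    sigma_plot_spikelets: float = 0.8
    fertile_floret_ratio: float = 0.8
    weather: dict[str, SiteWeather] = field(default_factory=lambda: dict(DEFAULT_SITE_WEATHER))
    detailed_years: tuple[int, ...] = DETAILED_YEARS

    def __post_init__(self) -> None:
        for name in (
            "sigma_eps_days", "sigma_year_flowering", "sigma_block_flowering",
            "sigma_plot_flowering", "sigma_genotype_fill", "sigma_plot_fill",
            "sigma_genotype_gw", "sigma_block_gw", "sigma_plot_gw",
            "sigma_env_quality", "sigma_sensitivity", "sigma_block_gn",
            "sigma_plot_gn", "sigma_plot_spikes", "sigma_plot_spikelets",
        ):
            if getattr(self, name) < 0:
                raise DataError(f"{name} must be >= 0")
        for e in self.experiments:
            for table, what in (
                (self.base_days_to_flowering, "base_days_to_flowering"),
                (self.grain_fill_days, "grain_fill_days"),
                (self.gn_site_effect, "gn_site_effect"),
                (self.weather, "weather"),
            ):
                if e.site not in table:
                    raise DataError(f"no {what} entry for site {e.site!r}")


@dataclass
class SimTruth:
    """Ground truth emitted alongside the data, sufficient to score
    recovery of every downstream estimate."""

    eps_days: dict[str, float]
    ac_flowering_effect: dict[str, float]
    gw_genotype_effect: dict[str, float]
    fill_genotype_effect: dict[str, float]
    sensitivity: dict[str, float]
    true_fw_slope: dict[str, float]
    env_quality: dict[str, float]
    variance_components: dict[str, float]
    clipped_plots: int = 0

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "SimTruth":
        return cls(**json.loads(Path(path).read_text()))


def _site_key(site: str) -> int:
    return zlib.crc32(site.encode())


def _experiment_rng(seed: int, exp: Experiment) -> np.random.Generator:
    # one stream per experiment: adding an experiment never perturbs others
    return np.random.default_rng([seed, 2, _site_key(exp.site), exp.year])


def _ar1(rng: np.random.Generator, n: int, rho: float, sd: float) -> np.ndarray:
    eps = rng.normal(0.0, sd, size=n)
    out = np.empty(n)
    out[0] = eps[0] / math.sqrt(max(1.0 - rho**2, 1e-12)) if sd > 0 else 0.0
    for i in range(1, n):
        out[i] = rho * out[i - 1] + eps[i]
    return out


def simulate_weather(config: SimConfig, experiment: Experiment, n_days: int = 335) -> list[DailyWeather]:
    """Daily weather from 5 days before sowing, covering the full season.

    tmean is a site-level sinusoid plus AR(1) noise; tmax/tmin are a fixed
    half-range either side; radiation is a clear-sky scale shaped by a
    daylength-driven seasonal factor and thinned by cloud noise.
    """
    w = config.weather[experiment.site]
    rng = np.random.default_rng(
        [config.seed, 3, _site_key(experiment.site), experiment.year]
    )
    start = experiment.sowing_date - dt.timedelta(days=5)
    noise = _ar1(rng, n_days, w.ar1_rho, w.ar1_sd)
    cloud = np.clip(np.abs(_ar1(rng, n_days, w.ar1_rho, w.cloud_sd)), 0.0, 0.6)
    out = []
    for i in range(n_days):
        date = start + dt.timedelta(days=i)
        doy = date.timetuple().tm_yday
        tmean = (
            w.tmean_annual
            + w.tmean_amplitude * math.sin(2.0 * math.pi * (doy - w.tmean_phase_doy) / 365.0)
            + noise[i]
        )
        dl_frac = day_length(experiment.latitude, doy, 0.0) / 24.0
        rad = max(w.rad_clear_sky * dl_frac**2 * (1.0 - cloud[i]), 0.0)
        out.append(
            DailyWeather(
                site=experiment.site,
                year=experiment.year,
                date=date,
                tmin=tmean - w.diurnal_half_range,
                tmax=tmean + w.diurnal_half_range,
                tmean=tmean,
                radiation=rad,
            )
        )
    return out


def _genotype_effects(config: SimConfig) -> dict[str, dict[str, float]]:
    """Per-genotype latent effects from the genotype-level RNG stream."""
    rng = np.random.default_rng([config.seed, 1])
    effects: dict[str, dict[str, float]] = {}
    for meta in config.genotypes:  # roster order: stable
        effects[meta.genotype_id] = {
            "eps": rng.normal(0.0, config.sigma_eps_days),
            "gw": rng.normal(0.0, config.sigma_genotype_gw),
            "fill": rng.normal(0.0, config.sigma_genotype_fill),
            "sens": 1.0 + rng.normal(0.0, config.sigma_sensitivity),
        }
    return effects


def simulate_trial(
    config: SimConfig,
) -> tuple[list[PlotRecord], list[DailyWeather], SimTruth]:
    """Generate the complete trial: plots, weather, and ground truth.

    Excluded genotypes (singleton allele combinations) are not planted, so
    the default configuration yields 23 × 15 × 3 = 1035 plot records.
    """
    effects = _genotype_effects(config)
    planted = config.genotypes.included
    roster_mean_dev = float(
        np.mean(
            [
                config.ac_flowering_effect[m.allele_combination]
                + effects[m.genotype_id]["eps"]
                for m in planted
            ]
        )
    )

    records: list[PlotRecord] = []
    weather: list[DailyWeather] = []
    env_quality: dict[str, float] = {}
    clipped = 0

    for exp in config.experiments:
        weather.extend(simulate_weather(config, exp))
        rng = _experiment_rng(config.seed, exp)
        year_flo = rng.normal(0.0, config.sigma_year_flowering)
        eq = config.gn_site_effect[exp.site] + rng.normal(0.0, config.sigma_env_quality)
        env_quality[exp.environment_id] = eq
        block_flo = rng.normal(0.0, config.sigma_block_flowering, size=config.n_blocks)
        block_gw = rng.normal(0.0, config.sigma_block_gw, size=config.n_blocks)
        block_gn = rng.normal(0.0, config.sigma_block_gn, size=config.n_blocks)
        emergence = exp.sowing_date + dt.timedelta(days=round(config.days_to_emergence))
        base = config.base_days_to_flowering[exp.site]
        detailed = exp.year in config.detailed_years

        for meta in planted:
            g = effects[meta.genotype_id]
            ac = meta.allele_combination
            for b in range(config.n_blocks):
                days_ef = round(
                    base
                    + config.ac_flowering_effect[ac]
                    + g["eps"]
                    + year_flo
                    + block_flo[b]
                    + rng.normal(0.0, config.sigma_plot_flowering)
                )
                flowering = emergence + dt.timedelta(days=int(days_ef))
                fill = round(
                    config.grain_fill_days[exp.site]
                    + g["fill"]
                    + rng.normal(0.0, config.sigma_plot_fill)
                )
                maturity = flowering + dt.timedelta(days=max(int(fill), 1))

                dev = days_ef - base - roster_mean_dev
                gw = (
                    config.gw_base
                    + config.gw_per_day_late * dev
                    + g["gw"]
                    + block_gw[b]
                    + rng.normal(0.0, config.sigma_plot_gw)
                )
                if gw <= 0:
                    gw = config.gw_base + g["gw"] + rng.normal(0.0, config.sigma_plot_gw)
                    if gw <= 0:
                        gw = 1.0
                        clipped += 1
                gn = (
                    config.gn_base
                    + config.ac_gn_effect[ac]
                    + g["sens"] * eq
                    - config.gn_gw_compensation * (gw - config.gw_base) * config.gn_per_mg_scale
                    + block_gn[b]
                    + rng.normal(0.0, config.sigma_plot_gn)
                )
                if gn <= 0:
                    gn = config.gn_base + rng.normal(0.0, config.sigma_plot_gn)
                    if gn <= 0:
                        gn = 1.0
                        clipped += 1
                gy = gn * gw / 1000.0

                kwargs: dict = {}
                if detailed:
                    kwargs["date_double_ridge"] = emergence + dt.timedelta(
                        days=int(round(0.45 * days_ef))
                    )
                    kwargs["date_terminal_spikelet"] = emergence + dt.timedelta(
                        days=int(round(0.60 * days_ef))
                    )
                    kwargs["date_heading"] = flowering - dt.timedelta(days=5)
                    spikes = config.spikes_base + rng.normal(0.0, config.sigma_plot_spikes)
                    spikes = max(spikes, 50.0)
                    spikelets = (
                        config.spikelets_base
                        + config.spikelets_per_day_late * dev
                        + rng.normal(0.0, config.sigma_plot_spikelets)
                    )
                    spikelets = max(spikelets, 5.0)
                    kwargs["spikes_m2"] = spikes
                    kwargs["spikelets_per_spike"] = spikelets
                    kwargs["grains_per_spike"] = gn / spikes
                    if exp.site == SITE_SPAIN:
                        kwargs["fertile_florets_per_spike"] = (
                            gn / spikes / config.fertile_floret_ratio
                        )
                records.append(
                    derive_traits(
                        PlotRecord(
                            site=exp.site,
                            year=exp.year,
                            block=b + 1,
                            genotype_id=meta.genotype_id,
                            date_emergence=emergence,
                            date_flowering=flowering,
                            date_maturity=maturity,
                            gy_g_m2=gy,
                            gw_mg=gw,
                            **kwargs,
                        )
                    )
                )

    if clipped:
        logger.warning("clipped %d non-positive generated trait values", clipped)

    # expected GW per genotype (constant over environments) -> exact FW slopes
    exp_gw = {
        m.genotype_id: config.gw_base
        + effects[m.genotype_id]["gw"]
        + config.gw_per_day_late
        * (
            config.ac_flowering_effect[m.allele_combination]
            + effects[m.genotype_id]["eps"]
            - roster_mean_dev
        )
        for m in planted
    }
    mean_ws = float(
        np.mean([effects[m.genotype_id]["sens"] * exp_gw[m.genotype_id] for m in planted])
    )
    truth = SimTruth(
        eps_days={m.genotype_id: effects[m.genotype_id]["eps"] for m in planted},
        ac_flowering_effect=dict(config.ac_flowering_effect),
        gw_genotype_effect={m.genotype_id: effects[m.genotype_id]["gw"] for m in planted},
        fill_genotype_effect={m.genotype_id: effects[m.genotype_id]["fill"] for m in planted},
        sensitivity={m.genotype_id: effects[m.genotype_id]["sens"] for m in planted},
        true_fw_slope={
            m.genotype_id: effects[m.genotype_id]["sens"] * exp_gw[m.genotype_id] / mean_ws
            for m in planted
        },
        env_quality=env_quality,
        variance_components={
            "sigma_eps_days": config.sigma_eps_days,
            "sigma_plot_flowering": config.sigma_plot_flowering,
            "sigma_block_flowering": config.sigma_block_flowering,
            "sigma_genotype_gw": config.sigma_genotype_gw,
            "sigma_plot_gw": config.sigma_plot_gw,
        },
        clipped_plots=clipped,
    )
    return records, weather, truth


def write_outputs(
    records: Sequence[PlotRecord],
    weather: Sequence[DailyWeather],
    truth: SimTruth,
    config: SimConfig,
    outdir: str | Path,
) -> None:
    """Write plots.csv, genotypes.csv, weather.csv, experiments.csv, truth.json."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_plot_table(records, outdir / "plots.csv")
    write_genotype_table(config.genotypes, outdir / "genotypes.csv")
    write_weather_table(weather, outdir / "weather.csv")
    write_experiment_table(config.experiments, outdir / "experiments.csv")
    truth.to_json(outdir / "truth.json")


# ---------------------------------------------------------------------------
# YAML config support

_SIMPLE_FIELDS = {
    f.name
    for f in dataclasses.fields(SimConfig)
    if f.name not in ("experiments", "genotypes", "weather")
}


def config_from_dict(doc: dict) -> SimConfig:
    """Build a SimConfig from a flat YAML-style mapping.

    Unknown keys are rejected. ``experiments``, ``genotypes`` and
    ``weather`` accept lists/mappings of plain values.
    """
    kwargs: dict = {}
    for key, value in doc.items():
        if key == "experiments":
            kwargs["experiments"] = [
                Experiment(
                    site=e["site"],
                    year=int(e["year"]),
                    latitude=float(e["latitude_deg"]),
                    sowing_date=dt.date.fromisoformat(e["sowing_date"]),
                )
                for e in value
            ]
        elif key == "genotypes":
            kwargs["genotypes"] = GenotypeTable(
                GenotypeMeta(g["genotype"], g["ppd_a1"], g["ppd_b1"]) for g in value
            )
        elif key == "weather":
            kwargs["weather"] = {
                site: SiteWeather(**params) for site, params in value.items()
            }
        elif key in _SIMPLE_FIELDS:
            kwargs[key] = value
        else:
            raise DataError(f"unknown simulation config key {key!r}")
    if "detailed_years" in kwargs:
        kwargs["detailed_years"] = tuple(kwargs["detailed_years"])
    return SimConfig(**kwargs)
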