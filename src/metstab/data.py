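"""Core data model and CSV readers/writers for the trial pipeline.

Tables handled here:

* ``plots.csv`` — one row per experimental plot (design labels, stage
  dates, trait values).
* ``genotypes.csv`` — genotype → photoperiod-allele metadata.
* ``weather.csv`` — daily weather per site-year.
* ``experiments.csv`` — site-year → latitude and sowing date.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

PPD_A1_ALLELES = ("GS100-Ppd-A1a", "GS105-Ppd-A1a", "Ppd-A1b")
PPD_B1_ALLELES = ("Ppd-B1a", "Ppd-B1b")

#: (ppd_a1, ppd_b1) -> allele-combination acronym
ALLELE_COMBINATIONS: Mapping[tuple[str, str], str] = {
    ("Ppd-A1b", "Ppd-B1b"): "SS",
    ("Ppd-A1b", "Ppd-B1a"): "SI",
    ("GS105-Ppd-A1a", "Ppd-B1b"): "I5S",
    ("GS105-Ppd-A1a", "Ppd-B1a"): "I5I",
    ("GS100-Ppd-A1a", "Ppd-B1b"): "I0S",
    ("GS100-Ppd-A1a", "Ppd-B1a"): "I0I",
}

STAGE_FIELDS = (
    "date_emergence",
    "date_double_ridge",
    "date_terminal_spikelet",
    "date_heading",
    "date_flowering",
    "date_maturity",
)

TRAIT_FIELDS = (
    "gy_g_m2",
    "gw_mg",
    "gn_m2",
    "spikes_m2",
    "grains_per_spike",
    "spikelets_per_spike",
    "grains_per_spikelet",
    "fertile_florets_per_spike",
    "grain_setting",
)


class DataError(ValueError):
    """Raised on any hard validation failure in table handling."""


def allele_combination(ppd_a1: str, ppd_b1: str) -> str:
    """Map the two-locus genotype to its combination acronym."""
    try:
        return ALLELE_COMBINATIONS[(ppd_a1, ppd_b1)]
    except KeyError:
        raise DataError(f"unknown allele pair ({ppd_a1!r}, {ppd_b1!r})") from None


@dataclass(frozen=True)
class GenotypeMeta:
    genotype_id: str
    ppd_a1: str
    ppd_b1: str
    excluded: bool = False

    def __post_init__(self) -> None:
        if self.ppd_a1 not in PPD_A1_ALLELES:
            raise DataError(f"invalid ppd_a1 allele {self.ppd_a1!r}")
        if self.ppd_b1 not in PPD_B1_ALLELES:
            raise DataError(f"invalid ppd_b1 allele {self.ppd_b1!r}")

    @property
    def allele_combination(self) -> str:
        return allele_combination(self.ppd_a1, self.ppd_b1)


class GenotypeTable:
    """Genotype metadata with singleton-combination exclusion applied.

    Combinations represented by fewer than ``min_group_size`` genotypes
    are flagged ``excluded`` and left out of analyses by default.
    """

    def __init__(self, metas: Iterable[GenotypeMeta], min_group_size: int = 2):
        metas = list(metas)
        ids = [m.genotype_id for m in metas]
        if len(set(ids)) != len(ids):
            raise DataError("duplicate genotype ids")
        counts: dict[str, int] = {}
        for m in metas:
            counts[m.allele_combination] = counts.get(m.allele_combination, 0) + 1
        self._metas = {
            m.genotype_id: dataclasses.replace(
                m, excluded=counts[m.allele_combination] < min_group_size
            )
            for m in metas
        }

    def __len__(self) -> int:
        return len(self._metas)

    def __contains__(self, genotype_id: str) -> bool:
        return genotype_id in self._metas

    def __getitem__(self, genotype_id: str) -> GenotypeMeta:
        try:
            return self._metas[genotype_id]
        except KeyError:
            raise DataError(f"unknown genotype id {genotype_id!r}") from None

    def __iter__(self):
        return iter(self._metas.values())

    @property
    def included(self) -> list[GenotypeMeta]:
        return [m for m in self._metas.values() if not m.excluded]

    def combination_of(self, genotype_id: str) -> str:
        return self[genotype_id].allele_combination

    def combinations(self, include_excluded: bool = False) -> list[str]:
        """Acronyms in stable (first-seen) order."""
        seen: list[str] = []
        for m in self._metas.values():
            if m.excluded and not include_excluded:
                continue
            ac = m.allele_combination
            if ac not in seen:
                seen.append(ac)
        return seen

    def members(self, ac: str) -> list[str]:
        return [
            m.genotype_id for m in self._metas.values() if m.allele_combination == ac
        ]


@dataclass(frozen=True)
class PlotRecord:
    """One experimental plot: design labels, phenology and trait values.

    Optional stage dates and traits are ``None`` when absent — never 0.
    """

    site: str
    year: int
    block: int
    genotype_id: str
    date_emergence: dt.date | None = None
    date_double_ridge: dt.date | None = None
    date_terminal_spikelet: dt.date | None = None
    date_heading: dt.date | None = None
    date_flowering: dt.date | None = None
    date_maturity: dt.date | None = None
    gy_g_m2: float | None = None
    gw_mg: float | None = None
    gn_m2: float | None = None
    spikes_m2: float | None = None
    grains_per_spike: float | None = None
    spikelets_per_spike: float | None = None
    grains_per_spikelet: float | None = None
    fertile_florets_per_spike: float | None = None
    grain_setting: float | None = None

    def __post_init__(self) -> None:
        stages = [getattr(self, f) for f in STAGE_FIELDS]
        present = [(f, d) for f, d in zip(STAGE_FIELDS, stages) if d is not None]
        for (fa, da), (fb, db) in zip(present, present[1:]):
            if da > db:
                raise DataError(
                    f"plot {self.plot_id()}: {fa} ({da}) after {fb} ({db})"
                )
        for f in ("gy_g_m2", "gw_mg"):
            v = getattr(self, f)
            if v is not None and v <= 0:
                raise DataError(f"plot {self.plot_id()}: {f} must be > 0, got {v}")

    def plot_id(self) -> str:
        return f"{self.site}-{self.year}-B{self.block}-{self.genotype_id}"

    @property
    def environment_id(self) -> str:
        return environment_id(self.site, self.year)

    @property
    def days_ef(self) -> int | None:
        """Emergence → flowering duration in whole days."""
        if self.date_emergence is None or self.date_flowering is None:
            return None
        return (self.date_flowering - self.date_emergence).days

    @property
    def days_fm(self) -> int | None:
        """Flowering → maturity duration in whole days."""
        if self.date_flowering is None or self.date_maturity is None:
            return None
        return (self.date_maturity - self.date_flowering).days

    def trait(self, name: str) -> float | None:
        if name in ("days_ef", "days_fm"):
            return getattr(self, name)
        if name in TRAIT_FIELDS:
            return getattr(self, name)
        raise DataError(f"unknown trait {name!r}")


@dataclass(frozen=True)
class DailyWeather:
    site: str
    year: int
    date: dt.date
    tmin: float
    tmax: float
    tmean: float
    radiation: float

    def __post_init__(self) -> None:
        if not (self.tmin <= self.tmean <= self.tmax):
            raise DataError(
                f"{self.site}-{self.year} {self.date}: require tmin <= tmean <= tmax"
            )


@dataclass(frozen=True)
class Experiment:
    site: str
    year: int
    latitude: float
    sowing_date: dt.date

    def __post_init__(self) -> None:
        if not -90.0 <= self.latitude <= 90.0:
            raise DataError(f"latitude {self.latitude} out of [-90, 90]")

    @property
    def environment_id(self) -> str:
        return environment_id(self.site, self.year)


def environment_id(site: str, year: int) -> str:
    return f"{site}-{year}"


class WeatherSeries:
    """Gap-free daily weather indexed by (site, year, date)."""

    def __init__(self, records: Iterable[DailyWeather]):
        self._by_exp: dict[tuple[str, int], dict[dt.date, DailyWeather]] = {}
        for r in records:
            self._by_exp.setdefault((r.site, r.year), {})[r.date] = r

    def window(self, site: str, year: int, start: dt.date, end: dt.date) -> list[DailyWeather]:
        """Daily records over the closed interval [start, end]."""
        if start > end:
            raise DataError(f"window start {start} after end {end}")
        series = self._by_exp.get((site, year))
        if series is None:
            raise DataError(f"no weather for {environment_id(site, year)}")
        out = []
        d = start
        while d <= end:
            rec = series.get(d)
            if rec is None:
                raise DataError(
                    f"weather gap for {environment_id(site, year)}: missing {d} "
                    f"(window {start}..{end})"
                )
            out.append(rec)
            d += dt.timedelta(days=1)
        return out


@dataclass
class TwoWayMeans:
    """Entity × environment cell-mean matrix feeding the stability indices."""

    entity_ids: list[str]
    environment_ids: list[str]
    values: np.ndarray  # shape (n_entities, n_environments)
    counts: np.ndarray  # same shape, ints

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.counts = np.asarray(self.counts, dtype=int)
        expected = (len(self.entity_ids), len(self.environment_ids))
        if self.values.shape != expected or self.counts.shape != expected:
            raise DataError(f"matrix shape mismatch, expected {expected}")
        if np.any(self.counts < 1) or np.any(~np.isfinite(self.values)):
            bad = [
                (self.entity_ids[i], self.environment_ids[j])
                for i, j in zip(*np.where((self.counts < 1) | ~np.isfinite(self.values)))
            ]
            raise DataError(f"empty cells for (entity, environment): {bad}")


# ---------------------------------------------------------------------------
# derived traits

def derive_traits(record: PlotRecord) -> PlotRecord:
    """Return an enriched copy with definitional ratio traits filled in.

    GN = 1000·GY/GW (GW in mg/grain), grains/spikelet = grains/spike ÷
    spikelets/spike, grain setting = grains/spike ÷ fertile florets/spike.
    Idempotent; the input record is never mutated.
    """
    updates: dict[str, float] = {}
    if record.gy_g_m2 is not None and record.gw_mg is not None:
        if record.gw_mg == 0:
            raise DataError(f"plot {record.plot_id()}: GW = 0, GN undefined")
        updates["gn_m2"] = 1000.0 * record.gy_g_m2 / record.gw_mg
    if record.grains_per_spike is not None and record.spikelets_per_spike is not None:
        if record.spikelets_per_spike == 0:
            raise DataError(
                f"plot {record.plot_id()}: spikelets/spike = 0, grains/spikelet undefined"
            )
        updates["grains_per_spikelet"] = (
            record.grains_per_spike / record.spikelets_per_spike
        )
    if (
        record.grains_per_spike is not None
        and record.fertile_florets_per_spike is not None
    ):
        if record.fertile_florets_per_spike == 0:
            raise DataError(
                f"plot {record.plot_id()}: fertile florets = 0, grain setting undefined"
            )
        updates["grain_setting"] = (
            record.grains_per_spike / record.fertile_florets_per_spike
        )
    return dataclasses.replace(record, **updates) if updates else record


# ---------------------------------------------------------------------------
# cell means

def cell_means(
    records: Sequence[PlotRecord],
    entity_level: Literal["genotype", "allele_combination"],
    trait: str,
    genotype_meta: GenotypeTable | None = None,
    strict: bool = True,
) -> TwoWayMeans:
    """Entity × environment means over blocks (and member genotypes).

    Strict mode (default) errors on any empty (entity, environment) cell;
    lenient mode averages whatever plots are available.
    """
    if entity_level == "allele_combination" and genotype_meta is None:
        raise DataError("genotype_meta required for allele_combination level")

    def entity_of(r: PlotRecord) -> str | None:
        if entity_level == "genotype":
            return r.genotype_id
        meta = genotype_meta[r.genotype_id]
        return None if meta.excluded else meta.allele_combination

    entities: list[str] = []
    envs: list[str] = []
    sums: dict[tuple[str, str], float] = {}
    ns: dict[tuple[str, str], int] = {}
    for r in records:
        ent = entity_of(r)
        if ent is None:
            continue
        v = r.trait(trait)
        if v is None:
            continue
        env = r.environment_id
        if ent not in entities:
            entities.append(ent)
        if env not in envs:
            envs.append(env)
        key = (ent, env)
        sums[key] = sums.get(key, 0.0) + float(v)
        ns[key] = ns.get(key, 0) + 1

    missing = [
        (e, v) for e in entities for v in envs if (e, v) not in ns
    ]
    if missing:
        raise DataError(f"empty cells for trait {trait!r}: {missing}")
    if strict:
        counts = {ns[(e, v)] for e in entities for v in envs}
        # at AC level balanced counts differ between ACs; check per entity
        for e in entities:
            per_env = {ns[(e, v)] for v in envs}
            if len(per_env) != 1:
                raise DataError(
                    f"unbalanced counts for entity {e!r}: {sorted(per_env)} "
                    "(use strict=False for available-count means)"
                )
        del counts
    values = np.array([[sums[(e, v)] / ns[(e, v)] for v in envs] for e in entities])
    counts_mat = np.array([[ns[(e, v)] for v in envs] for e in entities])
    return TwoWayMeans(entities, envs, values, counts_mat)


# ---------------------------------------------------------------------------
# CSV I/O

_PLOT_COLUMNS = ["site", "year", "block", "genotype", *STAGE_FIELDS, *TRAIT_FIELDS]


def _parse_date(v) -> dt.date | None:
    if v is None or (isinstance(v, float) and np.isnan(v)) or v == "":
        return None
    return dt.date.fromisoformat(str(v))


def _parse_float(v) -> float | None:
    if v is None or v == "":
        return None
    f = float(v)
    if np.isnan(f):
        return None
    return f


def read_genotype_table(path: str | Path) -> GenotypeTable:
    df = pd.read_csv(path, dtype=str)
    required = {"genotype", "ppd_a1", "ppd_b1"}
    if not required.issubset(df.columns):
        raise DataError(f"genotypes.csv missing columns {sorted(required - set(df.columns))}")
    return GenotypeTable(
        GenotypeMeta(row.genotype, row.ppd_a1, row.ppd_b1)
        for row in df.itertuples()
    )


def write_genotype_table(table: GenotypeTable, path: str | Path) -> None:
    rows = [
        {
            "genotype": m.genotype_id,
            "ppd_a1": m.ppd_a1,
            "ppd_b1": m.ppd_b1,
            "allele_combination": m.allele_combination,
            "excluded": int(m.excluded),
        }
        for m in table
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_plot_table(path: str | Path, genotype_meta: GenotypeTable | None = None) -> list[PlotRecord]:
    """Read and validate plots.csv; every row becomes a PlotRecord."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    required = {"site", "year", "block", "genotype", "date_flowering", "date_maturity",
                "date_emergence", "gy_g_m2", "gw_mg"}
    missing = required - set(df.columns)
    if missing:
        raise DataError(f"plots.csv missing columns {sorted(missing)}")
    records = []
    for idx, row in enumerate(df.itertuples(index=False), start=2):
        d = row._asdict()
        gid = d["genotype"]
        if genotype_meta is not None and gid not in genotype_meta:
            raise DataError(f"plots.csv line {idx}: unknown genotype id {gid!r}")
        kwargs: dict = {
            "site": d["site"],
            "year": int(d["year"]),
            "block": int(d["block"]),
            "genotype_id": gid,
        }
        try:
            for f in STAGE_FIELDS:
                kwargs[f] = _parse_date(d.get(f, ""))
            for f in TRAIT_FIELDS:
                kwargs[f] = _parse_float(d.get(f, ""))
            records.append(PlotRecord(**kwargs))
        except DataError as e:
            raise DataError(f"plots.csv line {idx}: {e}") from None
    if not records:
        logger.warning("plot table %s contained no data rows", path)
    return records


def write_plot_table(records: Sequence[PlotRecord], path: str | Path) -> None:
    rows = []
    for r in records:
        row: dict = {
            "site": r.site,
            "year": r.year,
            "block": r.block,
            "genotype": r.genotype_id,
        }
        for f in STAGE_FIELDS:
            v = getattr(r, f)
            row[f] = v.isoformat() if v is not None else ""
        for f in TRAIT_FIELDS:
            v = getattr(r, f)
            row[f] = repr(float(v)) if v is not None else ""
        rows.append(row)
    pd.DataFrame(rows, columns=_PLOT_COLUMNS).to_csv(path, index=False)


def read_weather_table(path: str | Path) -> WeatherSeries:
    df = pd.read_csv(path)
    required = {"site", "year", "date", "tmin_c", "tmax_c", "tmean_c", "rad_mj_m2"}
    missing = required - set(df.columns)
    if missing:
        raise DataError(f"weather.csv missing columns {sorted(missing)}")
    return WeatherSeries(
        DailyWeather(
            site=str(row.site),
            year=int(row.year),
            date=dt.date.fromisoformat(str(row.date)),
            tmin=float(row.tmin_c),
            tmax=float(row.tmax_c),
            tmean=float(row.tmean_c),
            radiation=float(row.rad_mj_m2),
        )
        for row in df.itertuples()
    )


def write_weather_table(records: Sequence[DailyWeather], path: str | Path) -> None:
    rows = [
        {
            "site": r.site,
            "year": r.year,
            "date": r.date.isoformat(),
            "tmin_c": repr(float(r.tmin)),
            "tmax_c": repr(float(r.tmax)),
            "tmean_c": repr(float(r.tmean)),
            "rad_mj_m2": repr(float(r.radiation)),
        }
        for r in records
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_experiment_table(path: str | Path) -> list[Experiment]:
    df = pd.read_csv(path)
    required = {"site", "year", "latitude_deg", "sowing_date"}
    missing = required - set(df.columns)
    if missing:
        raise DataError(f"experiments.csv missing columns {sorted(missing)}")
    exps = [
        Experiment(
            site=str(row.site),
            year=int(row.year),
            latitude=float(row.latitude_deg),
            sowing_date=dt.date.fromisoformat(str(row.sowing_date)),
        )
        for row in df.itertuples()
    ]
    keys = [(e.site, e.year) for e in exps]
    if len(set(keys)) != len(keys):
        raise DataError("duplicate (site, year) in experiments.csv")
    return exps


def write_experiment_table(exps: Sequence[Experiment], path: str | Path) -> None:
    rows = [
        {
            "site": e.site,
            "year": e.year,
            "latitude_deg": repr(float(e.latitude)),
            "sowing_date": e.sowing_date.isoformat(),
        }
        for e in exps
    ]
    pd.DataFrame(rows).to_csv(path, index=False)
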