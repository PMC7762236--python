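"""End-to-end pipeline: simulate → covariates → ANOVA → BLUP → stability
→ PCA, writing plain-CSV stage outputs, a markdown report, and a log."""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd

from . import anova as anova_mod
from . import blup as blup_mod
from . import pca as pca_mod
from . import stability as stab_mod
from .covariates import DEFAULT_T_BASE, DEFAULT_TWILIGHT_DEG, covariates_table
from .data import (
    DataError,
    read_experiment_table,
    read_genotype_table,
    read_plot_table,
    read_weather_table,
)
from .simulate import SimConfig, simulate_trial, write_outputs

logger = logging.getLogger(__name__)

DEFAULT_ANOVA_TRAITS = ("days_ef", "days_fm", "gn_m2", "gw_mg", "gy_g_m2")
DEFAULT_X_TRAITS = ("days_ef", "days_fm")
DEFAULT_Y_TRAITS = (
    "gn_m2",
    "gw_mg",
    "gy_g_m2",
    "spikes_m2",
    "grains_per_spike",
    "spikelets_per_spike",
    "grains_per_spikelet",
)


@dataclass
class RunConfig:
    outdir: str = "met-run"
    seed: int = 0
    simulate: bool = True
    plots: str | None = None
    genotypes: str | None = None
    weather: str | None = None
    experiments: str | None = None
    anova_traits: Sequence[str] = DEFAULT_ANOVA_TRAITS
    x_traits: Sequence[str] = DEFAULT_X_TRAITS
    y_traits: Sequence[str] = DEFAULT_Y_TRAITS
    stability_trait: str = "gy_g_m2"
    alpha: float = 0.05
    level_policy: str = "genotype_then_summarise"
    twilight_deg: float = DEFAULT_TWILIGHT_DEG
    t_base: float = DEFAULT_T_BASE
    collinearity_r_cut: float = 0.95
    strict_balance: bool = True
    sim_overrides: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "outdir": self.outdir,
            "seed": self.seed,
            "simulate": self.simulate,
            "plots": self.plots,
            "genotypes": self.genotypes,
            "weather": self.weather,
            "experiments": self.experiments,
            "anova_traits": list(self.anova_traits),
            "x_traits": list(self.x_traits),
            "y_traits": list(self.y_traits),
            "stability_trait": self.stability_trait,
            "alpha": self.alpha,
            "level_policy": self.level_policy,
            "twilight_deg": self.twilight_deg,
            "t_base": self.t_base,
            "collinearity_r_cut": self.collinearity_r_cut,
            "strict_balance": self.strict_balance,
            "sim_overrides": dict(self.sim_overrides),
        }


def run_pipeline(config: RunConfig) -> Path:
    """Run every stage; returns the report directory.

    Fails fast: a stage error aborts the run with the stage named."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    log_path = out / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("metstab")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    timings: dict[str, float] = {}

    def stage(name):
        class _T:
            def __enter__(self_inner):
                self_inner.t0 = time.perf_counter()
                logger.info("stage %s started", name)
                return self_inner

            def __exit__(self_inner, exc_type, exc, tb):
                dt_s = time.perf_counter() - self_inner.t0
                timings[name] = dt_s
                if exc_type is not None:
                    logger.error("stage %s FAILED after %.2fs: %s", name, dt_s, exc)
                    raise DataError(f"stage {name!r} failed: {exc}") from exc
                logger.info("stage %s finished in %.2fs", name, dt_s)

        return _T()

    try:
        (out / "config.json").write_text(json.dumps(config.to_dict(), indent=1, sort_keys=True))

        if config.simulate:
            with stage("simulate"):
                sim_cfg = SimConfig(seed=config.seed, **config.sim_overrides)
                records, weather_recs, truth = simulate_trial(sim_cfg)
                write_outputs(records, weather_recs, truth, sim_cfg, out)
                genotype_meta = sim_cfg.genotypes
                experiments = sim_cfg.experiments
                from .data import WeatherSeries

                weather = WeatherSeries(weather_recs)
        else:
            with stage("load"):
                for name in ("plots", "genotypes", "weather", "experiments"):
                    path = getattr(config, name)
                    if path is None or not Path(path).exists():
                        raise DataError(f"input {name!r} missing: {path}")
                genotype_meta = read_genotype_table(config.genotypes)
                records = read_plot_table(config.plots, genotype_meta)
                weather = read_weather_table(config.weather)
                experiments = read_experiment_table(config.experiments)

        with stage("envcov"):
            cov = covariates_table(
                records, weather, experiments,
                t_base=config.t_base, daylength_coef_deg=config.twilight_deg,
            )
            cov.to_csv(out / "covariates.csv", index=False)

        with stage("anova"):
            anova_frames = []
            means_frames = []
            for trait in config.anova_traits:
                table = anova_mod.combined_anova(
                    records, trait, genotype_meta, strict=config.strict_balance
                )
                df = table.to_frame()
                df.insert(0, "trait", trait)
                anova_frames.append(df)
                cmp = anova_mod.ac_means_comparison(records, trait, genotype_meta, config.alpha)
                mf = cmp.to_frame()
                mf.insert(0, "trait", trait)
                means_frames.append(mf)
            anova_out = pd.concat(anova_frames, ignore_index=True)
            anova_out.to_csv(out / "anova.csv", index=False)
            pd.concat(means_frames, ignore_index=True).to_csv(out / "means.csv", index=False)

        with stage("eps"):
            traits = sorted(set(config.x_traits) | set(config.y_traits))
            fits = blup_mod.fit_all_experiments(records, traits, genotype_meta)
            blup_rows = []
            for (env, trait), fit in fits.items():
                for gid, v in fit.blups.items():
                    blup_rows.append(
                        {"environment": env, "trait": trait, "genotype": gid, "blup": v}
                    )
            pd.DataFrame(blup_rows).to_csv(out / "blups.csv", index=False)
            corr = blup_mod.eps_correlations(fits, config.x_traits, config.y_traits)
            corr.to_csv(out / "correlations.csv", index=False)

        with stage("stability"):
            report = stab_mod.stability_report(
                records, genotype_meta, config.stability_trait, config.level_policy
            )
            report.genotype.to_csv(out / "stability_genotype.csv", index=False)
            report.ac_summary.to_csv(out / "stability_ac.csv", index=False)
            report.ac_direct.to_csv(out / "stability_ac_direct.csv", index=False)

        with stage("pca"):
            env_table = pca_mod.environment_table(records, cov)
            env_table.to_csv(out / "env_table.csv", index=False)
            result = pca_mod.pca_corr(env_table, config.collinearity_r_cut)
            result.scores_frame().to_csv(out / "pca_scores.csv", index=False)
            result.loadings_frame().to_csv(out / "pca_loadings.csv", index=False)
            pd.DataFrame(
                {
                    "axis": [f"PC{k + 1}" for k in range(len(result.explained_pct))],
                    "explained_pct": result.explained_pct,
                }
            ).to_csv(out / "pca_variance.csv", index=False)

        with stage("report"):
            _write_report(out, config, anova_out, report, result, timings)
    finally:
        root.removeHandler(handler)
        handler.close()
    return out


def _write_report(out: Path, config: RunConfig, anova_out, stab_report, pca_result, timings) -> None:
    lines = ["# Multi-environment trial analysis report", ""]
    lines.append(f"Seed: {config.seed}; outputs in `{out}`.")
    lines.append("")
    lines.append("## Variance partitioning (% of total SS)")
    lines.append("")
    lines.append(anova_out.pivot_table(index="source", columns="trait", values="pct_ss", sort=False).round(2).to_markdown())
    lines.append("")
    lines.append("## Stability indices by allele combination")
    lines.append("")
    lines.append(stab_report.ac_summary.round(3).to_markdown(index=False))
    lines.append("")
    lines.append("## PCA explained variance")
    lines.append("")
    pct = pca_result.explained_pct
    lines.append(f"PC1 {pct[0]:.1f}%, PC2 {pct[1]:.1f}% (two-axis total {pct[0] + pct[1]:.1f}%).")
    lines.append("")
    lines.append("## Stage timings (s)")
    lines.append("")
    for k, v in timings.items():
        lines.append(f"- {k}: {v:.2f}")
    (out / "report.md").write_text("\n".join(lines) + "\n")
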