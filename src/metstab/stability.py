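"""Five yield-stability indices on an entity × environment means matrix.

* joint-regression slope b (with t-test against 1)
* Lin–Binns superiority measure Pi
* Wricke ecovalence Wi²
* Shukla stability variance σ² (a linear transform of Wi²; negative
  values are reported as-is, never truncated)
* Kang rank-sum yield-stability statistic YS with its selection rule
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .anova import combined_anova, lsd_compare, significance_stars
from .data import DataError, GenotypeTable, PlotRecord, TwoWayMeans, cell_means

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ReplicateError:
    """Plot-level pooled error for significance of σ² and the Kang LSD."""

    error_ms: float
    error_df: int
    n_per_mean: int


def finlay_wilkinson(matrix: TwoWayMeans) -> pd.DataFrame:
    """Per-entity joint-regression slope on the environment mean index.

    The environment index is the across-entity mean of each column; the
    slope's t-test is two-sided against H0: b = 1 with q - 2 df.
    """
    x = matrix.values
    p, q = x.shape
    if q < 3:
        raise DataError("joint regression needs >= 3 environments")
    index = x.mean(axis=0)
    sxx = float(((index - index.mean()) ** 2).sum())
    if sxx <= 0:
        raise DataError("degenerate environments: zero variance in the index")
    rows = []
    for i in range(p):
        yi = x[i]
        b = float(((index - index.mean()) * (yi - yi.mean())).sum() / sxx)
        resid = yi - yi.mean() - b * (index - index.mean())
        mse = float((resid**2).sum() / (q - 2))
        se = float(np.sqrt(mse / sxx))
        if se > 0:
            t = (b - 1.0) / se
            pval = 2.0 * float(stats.t.sf(abs(t), q - 2))
        else:
            pval = 1.0 if b == 1.0 else 0.0
        rows.append({"entity": matrix.entity_ids[i], "b": b, "se": se, "p_vs_1": pval})
    return pd.DataFrame(rows)


def lin_binns_pi(matrix: TwoWayMeans) -> pd.DataFrame:
    """Superiority measure: mean squared distance to the per-environment
    maximum, divided by 2q."""
    x = matrix.values
    q = x.shape[1]
    best = x.max(axis=0)
    pi = ((x - best[None, :]) ** 2).sum(axis=1) / (2.0 * q)
    return pd.DataFrame({"entity": matrix.entity_ids, "pi": pi})


def wricke_ecovalence(matrix: TwoWayMeans) -> pd.DataFrame:
    """Ecovalence: each entity's squared contribution to the interaction
    sum of squares of the two-way table."""
    x = matrix.values
    inter = x - x.mean(axis=1, keepdims=True) - x.mean(axis=0, keepdims=True) + x.mean()
    w2 = (inter**2).sum(axis=1)
    return pd.DataFrame({"entity": matrix.entity_ids, "w2": w2})


def shukla_sigma2(
    matrix: TwoWayMeans, replicate_error: ReplicateError | None = None
) -> pd.DataFrame:
    """Shukla stability variance: the unbiasing linear transform of Wi².

    σ²_i = p·Wi² / ((p-2)(q-1)) − ΣW² / ((p-1)(p-2)(q-1)). Negative values
    are retained. When replicate-level error is supplied each σ² is tested
    with an approximate F against the error variance of an entity-
    environment mean, df (q-1, error_df); otherwise stars are omitted.
    """
    x = matrix.values
    p, q = x.shape
    if p < 3:
        raise DataError("Shukla's variance needs >= 3 entities")
    w2 = wricke_ecovalence(matrix)["w2"].to_numpy()
    sigma2 = p * w2 / ((p - 2) * (q - 1)) - w2.sum() / ((p - 1) * (p - 2) * (q - 1))
    out = pd.DataFrame({"entity": matrix.entity_ids, "sigma2": sigma2})
    if replicate_error is not None:
        denom = replicate_error.error_ms / replicate_error.n_per_mean
        f = sigma2 / denom
        pvals = np.where(
            f > 0, stats.f.sf(np.maximum(f, 0.0), q - 1, replicate_error.error_df), 1.0
        )
        out["p"] = pvals
        out["stars"] = [significance_stars(v) for v in pvals]
    else:
        out["p"] = np.nan
        out["stars"] = None
    return out


def _average_ranks(values: np.ndarray) -> np.ndarray:
    """Rank 1..p with the highest value receiving rank p; ties averaged."""
    return stats.rankdata(values, method="average")


def kang_ys(
    matrix: TwoWayMeans, replicate_error: ReplicateError | None = None
) -> pd.DataFrame:
    """Kang's rank-sum yield-stability statistic and selection rule.

    Yield rank (highest mean = p) is adjusted by ±k when the entity mean
    sits more than k LSDs from the grand mean; a stability rating of
    0/−2/−4/−8 penalises σ² significance at ns/0.05/0.01/0.001; entities
    with YS above the mean YS are selected. Without replicate error the
    LSD adjustment is skipped and the output flagged unadjusted.
    """
    x = matrix.values
    p, q = x.shape
    means = x.mean(axis=1)
    yield_rank = _average_ranks(means)
    shukla = shukla_sigma2(matrix, replicate_error)

    adjusted = replicate_error is not None
    adjustment = np.zeros(p, dtype=int)
    if adjusted:
        err = replicate_error
        tcrit = float(stats.t.ppf(0.975, err.error_df))
        lsd = tcrit * np.sqrt(2.0 * err.error_ms / (err.n_per_mean * q))
        grand = means.mean()
        for i in range(p):
            diff = means[i] - grand
            k = int(np.floor(abs(diff) / lsd)) if lsd > 0 else 0
            adjustment[i] = int(np.sign(diff)) * k
    else:
        logger.warning("no replicate error supplied: Kang ranks are unadjusted")

    rating = np.zeros(p, dtype=int)
    if replicate_error is not None:
        pv = shukla["p"].to_numpy()
        rating = np.where(pv < 0.001, -8, np.where(pv < 0.01, -4, np.where(pv < 0.05, -2, 0)))

    ys = yield_rank + adjustment + rating
    selected = ys > ys.mean()
    return pd.DataFrame(
        {
            "entity": matrix.entity_ids,
            "mean": means,
            "yield_rank": yield_rank,
            "rank_adjustment": adjustment,
            "stability_rating": rating,
            "ys": ys,
            "selected": selected,
            "adjusted": adjusted,
        }
    )


def kang_selection(ys: Sequence[float]) -> list[bool]:
    """Selection flags for pre-computed YS values: above-mean entities."""
    arr = np.asarray(ys, dtype=float)
    return [bool(v) for v in arr > arr.mean()]


def stability_table(
    matrix: TwoWayMeans, replicate_error: ReplicateError | None = None
) -> pd.DataFrame:
    """All five indices for one entity × environment matrix."""
    fw = finlay_wilkinson(matrix)
    pi = lin_binns_pi(matrix)
    w2 = wricke_ecovalence(matrix)
    shukla = shukla_sigma2(matrix, replicate_error)
    kang = kang_ys(matrix, replicate_error)
    out = fw.merge(pi, on="entity").merge(w2, on="entity")
    out = out.merge(shukla.rename(columns={"p": "sigma2_p", "stars": "sigma2_stars"}), on="entity")
    out = out.merge(kang, on="entity")
    return out


@dataclass
class StabilityReport:
    genotype: pd.DataFrame  # indices per genotype (23 × 15 matrix)
    ac_summary: pd.DataFrame  # unweighted means of member-genotype indices
    ac_direct: pd.DataFrame  # indices computed on the AC-mean matrix
    ac_letters: dict[str, dict[str, str]]  # per index: AC -> letter group


def stability_report(
    records: Sequence[PlotRecord],
    genotype_meta: GenotypeTable,
    trait: str = "gy_g_m2",
    level_policy: str = "genotype_then_summarise",
) -> StabilityReport:
    """Genotype-level indices with allele-combination summaries.

    Indices are computed per genotype on the genotype × environment matrix
    and summarised per combination as unweighted member means (the direct
    AC-matrix variant is also emitted, labelled). Combination letter
    groups come from an LSD comparison of member-genotype index values.
    """
    if level_policy not in ("genotype_then_summarise", "ac_matrix"):
        raise DataError(f"unknown level_policy {level_policy!r}")
    matrix = cell_means(records, "genotype", trait, genotype_meta)
    anova = combined_anova(records, trait, genotype_meta)
    resid = anova["residual"]
    n_rep = int(matrix.counts[0, 0])
    err = ReplicateError(
        error_ms=float(resid.ms), error_df=int(resid.df), n_per_mean=max(n_rep, 1)
    )
    geno = stability_table(matrix, err)

    ac_of = {
        m.genotype_id: m.allele_combination for m in genotype_meta.included
    }
    geno = geno.assign(ac=[ac_of[g] for g in geno["entity"]])

    index_cols = ["mean", "b", "pi", "sigma2", "w2", "ys"]
    ac_summary = (
        geno.groupby("ac", sort=True)[index_cols].mean().reset_index()
    )
    ac_summary["selected"] = ac_summary["ys"] > geno["ys"].mean()

    ac_matrix = cell_means(records, "allele_combination", trait, genotype_meta)
    ac_err = ReplicateError(
        error_ms=float(resid.ms),
        error_df=int(resid.df),
        n_per_mean=err.n_per_mean,  # per contributing plot basis differs per AC; labelled variant
    )
    ac_direct = stability_table(ac_matrix, ac_err)

    # AC letter groups per index from an LSD on member-genotype values
    letters: dict[str, dict[str, str]] = {}
    acs = sorted(geno["ac"].unique())
    multi = [ac for ac in acs if (geno["ac"] == ac).sum() >= 2]
    for col in index_cols:
        groups = {ac: geno.loc[geno["ac"] == ac, col].to_numpy() for ac in multi}
        k = len(groups)
        if k < 2:
            letters[col] = {ac: "a" for ac in acs}
            continue
        all_vals = np.concatenate(list(groups.values()))
        grand = all_vals.mean()
        ss_between = sum(len(v) * (v.mean() - grand) ** 2 for v in groups.values())
        ss_within = sum(((v - v.mean()) ** 2).sum() for v in groups.values())
        df_b, df_w = k - 1, len(all_vals) - k
        if ss_within <= 0 or df_w <= 0:
            p_protect = 0.0 if ss_between > 0 else 1.0
            ms_w = max(ss_within, 1e-300)
        else:
            ms_w = ss_within / df_w
            f = (ss_between / df_b) / ms_w
            p_protect = float(stats.f.sf(f, df_b, df_w))
        n_h = int(round(stats.hmean([len(v) for v in groups.values()])))
        cmp = lsd_compare(
            multi,
            [groups[ac].mean() for ac in multi],
            error_ms=ms_w,
            error_df=max(df_w, 1),
            n_per_mean=max(n_h, 1),
            protecting_p=p_protect,
        )
        letters[col] = {ac: cmp.letters.get(ac, "") for ac in acs}

    return StabilityReport(
        genotype=geno, ac_summary=ac_summary, ac_direct=ac_direct, ac_letters=letters
    )
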