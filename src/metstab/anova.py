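"""Combined ANOVA across sites and years with the genotype sum-of-squares
split into between- vs. within-allele-combination components, plus
Fisher's protected LSD means comparison.

The design is the balanced crossed layout site × year × genotype with
blocks nested in site × year. On balanced data the sequential sums of
squares computed here from marginal means coincide with Type-III sums of
squares. The between-allele-combination F-test uses the within-combination
mean square as its denominator — the one bespoke error term of the
analysis; every other source is tested against the residual, and each
row's denominator is labelled so quasi-F ratios can be re-formed.
"""

from __future__ import annotations

import logging
import string
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .data import DataError, GenotypeTable, PlotRecord

logger = logging.getLogger(__name__)


def significance_stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


@dataclass
class AnovaRow:
    source: str
    df: int
    ss: float
    pct_ss: float
    ms: float | None = None
    f: float | None = None
    p: float | None = None
    error_term: str | None = None

    @property
    def stars(self) -> str | None:
        return None if self.p is None else significance_stars(self.p)


@dataclass
class AnovaTable:
    trait: str
    rows: list[AnovaRow]
    total_ss: float

    def __getitem__(self, source: str) -> AnovaRow:
        for row in self.rows:
            if row.source == source:
                return row
        raise KeyError(source)

    @property
    def sources(self) -> list[str]:
        return [r.source for r in self.rows]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "source": [r.source for r in self.rows],
                "df": [r.df for r in self.rows],
                "ss": [r.ss for r in self.rows],
                "pct_ss": [r.pct_ss for r in self.rows],
                "ms": [r.ms for r in self.rows],
                "f": [r.f for r in self.rows],
                "p": [r.p for r in self.rows],
                "stars": [r.stars for r in self.rows],
                "error_term": [r.error_term for r in self.rows],
            }
        )


def combined_anova(
    records: Sequence[PlotRecord],
    trait: str,
    genotype_meta: GenotypeTable,
    strict: bool = True,
) -> AnovaTable:
    """Balanced combined ANOVA with the genotype SS split by allele
    combination (main effect, ×site, ×site×year).

    Sources: site, year, site×year, genotype (split), genotype×site
    (split), genotype×year, genotype×site×year (split), block(site×year),
    residual. Requires a complete balanced design in strict mode.
    """
    included = {m.genotype_id for m in genotype_meta.included}
    recs = [r for r in records if r.genotype_id in included and r.trait(trait) is not None]
    if not recs:
        raise DataError(f"no data for trait {trait!r}")

    sites = sorted({r.site for r in recs})
    years = sorted({r.year for r in recs})
    genos = sorted({r.genotype_id for r in recs})
    blocks = sorted({r.block for r in recs})
    s, t, g, b = len(sites), len(years), len(genos), len(blocks)
    si = {v: i for i, v in enumerate(sites)}
    yi = {v: i for i, v in enumerate(years)}
    gi = {v: i for i, v in enumerate(genos)}
    bi = {v: i for i, v in enumerate(blocks)}

    y = np.full((s, t, g, b), np.nan)
    for r in recs:
        cell = (si[r.site], yi[r.year], gi[r.genotype_id], bi[r.block])
        if not np.isnan(y[cell]):
            raise DataError(f"duplicate plot for cell {cell}")
        y[cell] = r.trait(trait)
    if np.isnan(y).any():
        if strict:
            n_missing = int(np.isnan(y).sum())
            raise DataError(
                f"unbalanced design: {n_missing} missing plots for trait {trait!r}"
            )
        logger.warning("filling missing plots with cell means (lenient mode)")
        cell_mean = np.nanmean(y, axis=3, keepdims=True)
        y = np.where(np.isnan(y), np.broadcast_to(cell_mean, y.shape), y)

    grand = y.mean()
    m_s = y.mean(axis=(1, 2, 3))
    m_y = y.mean(axis=(0, 2, 3))
    m_g = y.mean(axis=(0, 1, 3))
    m_sy = y.mean(axis=(2, 3))
    m_gs = y.mean(axis=(1, 3))  # (s, g)
    m_gy = y.mean(axis=(0, 3))  # (t, g)
    m_syg = y.mean(axis=3)  # (s, t, g)
    m_syb = y.mean(axis=2)  # (s, t, b)

    ss_site = t * g * b * float(((m_s - grand) ** 2).sum())
    ss_year = s * g * b * float(((m_y - grand) ** 2).sum())
    ss_sy = g * b * float(
        ((m_sy - m_s[:, None] - m_y[None, :] + grand) ** 2).sum()
    )
    ss_g = s * t * b * float(((m_g - grand) ** 2).sum())
    ss_gs = t * b * float(((m_gs - m_s[:, None] - m_g[None, :] + grand) ** 2).sum())
    ss_gy = s * b * float(((m_gy - m_y[:, None] - m_g[None, :] + grand) ** 2).sum())
    dev_gsy = (
        m_syg
        - m_sy[:, :, None]
        - m_gs[:, None, :]
        - m_gy[None, :, :]
        + m_s[:, None, None]
        + m_y[None, :, None]
        + m_g[None, None, :]
        - grand
    )
    ss_gsy = b * float((dev_gsy**2).sum())
    ss_block = g * float(((m_syb - m_sy[:, :, None]) ** 2).sum())
    ss_total = float(((y - grand) ** 2).sum())
    ss_resid = ss_total - (
        ss_site + ss_year + ss_sy + ss_g + ss_gs + ss_gy + ss_gsy + ss_block
    )

    # ---- allele-combination split of the genotype SS --------------------
    acs = sorted({genotype_meta.combination_of(gid) for gid in genos})
    n_ac = len(acs)
    split = n_ac >= 2
    if not split:
        logger.warning("fewer than 2 allele combinations: genotype SS split skipped")
    ac_members = {ac: [gi[gid] for gid in genos if genotype_meta.combination_of(gid) == ac] for ac in acs}
    n_members = np.array([len(ac_members[ac]) for ac in acs])

    # AC marginal means from genotype means (balanced)
    m_ac = np.array([m_g[idx].mean() for idx in (ac_members[ac] for ac in acs)])
    ss_between = s * t * b * float((n_members * (m_ac - grand) ** 2).sum())
    ss_within = ss_g - ss_between

    m_acs = np.array([[m_gs[i, idx].mean() for idx in (ac_members[ac] for ac in acs)] for i in range(s)])
    ss_between_s = t * b * float(
        (n_members[None, :] * (m_acs - m_s[:, None] - m_ac[None, :] + grand) ** 2).sum()
    )
    ss_within_s = ss_gs - ss_between_s

    m_acsy = np.array(
        [
            [[m_syg[i, j, idx].mean() for idx in (ac_members[ac] for ac in acs)] for j in range(t)]
            for i in range(s)
        ]
    )  # (s, t, n_ac)
    dev_acsy = (
        m_acsy
        - m_sy[:, :, None]
        - m_acs[:, None, :]
        - np.array([[m_gy[j, idx].mean() for idx in (ac_members[ac] for ac in acs)] for j in range(t)])[None, :, :]
        + m_s[:, None, None]
        + m_y[None, :, None]
        + m_ac[None, None, :]
        - grand
    )
    ss_between_sy = b * float((n_members[None, None, :] * dev_acsy**2).sum())
    ss_within_sy = ss_gsy - ss_between_sy

    df_site, df_year = s - 1, t - 1
    df_sy = df_site * df_year
    df_g = g - 1
    df_between = n_ac - 1
    df_within = df_g - df_between
    df_gs = df_g * df_site
    df_gy = df_g * df_year
    df_gsy = df_g * df_sy
    df_block = s * t * (b - 1)
    df_total = s * t * g * b - 1
    df_resid = df_total - (
        df_site + df_year + df_sy + df_g + df_gs + df_gy + df_gsy + df_block
    )

    ms_resid = ss_resid / df_resid if df_resid > 0 else np.nan

    def row(source: str, df: int, ss: float, denom_ms: float | None, denom_df: int | None, denom_name: str | None) -> AnovaRow:
        ms = ss / df if df > 0 else np.nan
        f = p = None
        if denom_ms is not None and denom_ms > 0 and df > 0:
            f = ms / denom_ms
            p = float(stats.f.sf(f, df, denom_df))
        return AnovaRow(
            source=source,
            df=df,
            ss=ss,
            pct_ss=100.0 * ss / ss_total if ss_total > 0 else 0.0,
            ms=ms,
            f=f,
            p=p,
            error_term=denom_name,
        )

    ms_within = ss_within / df_within if split and df_within > 0 else None
    rows = [
        row("site", df_site, ss_site, ms_resid, df_resid, "residual"),
        row("year", df_year, ss_year, ms_resid, df_resid, "residual"),
        row("site:year", df_sy, ss_sy, ms_resid, df_resid, "residual"),
        row("genotype", df_g, ss_g, ms_resid, df_resid, "residual"),
    ]
    if split:
        rows.append(
            row("between_ac", df_between, ss_between, ms_within, df_within, "within_ac")
        )
        rows.append(row("within_ac", df_within, ss_within, ms_resid, df_resid, "residual"))
    rows.append(row("genotype:site", df_gs, ss_gs, ms_resid, df_resid, "residual"))
    if split:
        rows.append(
            row("between_ac:site", df_between * df_site, ss_between_s, ms_resid, df_resid, "residual")
        )
        rows.append(
            row("within_ac:site", df_gs - df_between * df_site, ss_within_s, ms_resid, df_resid, "residual")
        )
    rows.append(row("genotype:year", df_gy, ss_gy, ms_resid, df_resid, "residual"))
    rows.append(row("genotype:site:year", df_gsy, ss_gsy, ms_resid, df_resid, "residual"))
    if split:
        rows.append(
            row("between_ac:site:year", df_between * df_sy, ss_between_sy, ms_resid, df_resid, "residual")
        )
        rows.append(
            row(
                "within_ac:site:year",
                df_gsy - df_between * df_sy,
                ss_within_sy,
                ms_resid,
                df_resid,
                "residual",
            )
        )
    rows.append(row("block", df_block, ss_block, ms_resid, df_resid, "residual"))
    rows.append(row("residual", df_resid, ss_resid, None, None, None))

    return AnovaTable(trait=trait, rows=rows, total_ss=ss_total)


# ---------------------------------------------------------------------------
# Fisher's protected LSD

@dataclass
class MeansComparison:
    entity_ids: list[str]
    means: np.ndarray
    lsd: float
    letters: dict[str, str]
    alpha: float
    protected: bool
    protecting_p: float | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "entity": self.entity_ids,
                "mean": self.means,
                "letters": [self.letters[e] for e in self.entity_ids],
            }
        )


def compact_letter_display(
    entity_ids: Sequence[str], means: np.ndarray, lsd: float
) -> dict[str, str]:
    """Letters by insert-and-absorb over means sorted descending: two
    entities share a letter iff their means differ by at most the LSD.
    'a' marks the highest mean."""
    order = np.argsort(-means, kind="stable")
    sorted_means = means[order]
    n = len(sorted_means)
    # maximal runs of mutually non-significant entities; runs contained in
    # an earlier run are absorbed
    groups: list[tuple[int, int]] = []
    prev_end = -1
    for start in range(n):
        end = start
        while end + 1 < n and sorted_means[start] - sorted_means[end + 1] <= lsd:
            end += 1
        if end > prev_end or not groups:
            groups.append((start, end))
            prev_end = end
    letters = [""] * n
    for k, (lo, hi) in enumerate(groups):
        letter = string.ascii_lowercase[k % 26]
        for i in range(lo, hi + 1):
            letters[i] += letter
    out = {}
    for pos, idx in enumerate(order):
        out[entity_ids[idx]] = letters[pos]
    return out


def lsd_compare(
    entity_ids: Sequence[str],
    means: Sequence[float],
    error_ms: float,
    error_df: int,
    n_per_mean: int,
    alpha: float = 0.05,
    protecting_p: float | None = None,
) -> MeansComparison:
    """Fisher's protected LSD: letters assigned only when the protecting
    F-test is significant; otherwise every entity shares letter 'a'."""
    means = np.asarray(means, dtype=float)
    entity_ids = list(entity_ids)
    tcrit = float(stats.t.ppf(1.0 - alpha / 2.0, error_df))
    lsd = tcrit * np.sqrt(2.0 * error_ms / n_per_mean)
    protected = protecting_p is None or protecting_p < alpha
    if protected:
        letters = compact_letter_display(entity_ids, means, lsd)
    else:
        letters = {e: "a" for e in entity_ids}
    return MeansComparison(
        entity_ids=entity_ids,
        means=means,
        lsd=float(lsd),
        letters=letters,
        alpha=alpha,
        protected=protected,
        protecting_p=protecting_p,
    )


def ac_means_comparison(
    records: Sequence[PlotRecord],
    trait: str,
    genotype_meta: GenotypeTable,
    alpha: float = 0.05,
) -> MeansComparison:
    """Allele-combination means compared with the protected LSD, using the
    within-combination mean square as the error term (the combined-ANOVA
    protecting F-test for combinations)."""
    table = combined_anova(records, trait, genotype_meta)
    between = table["between_ac"]
    within = table["within_ac"]
    included = {m.genotype_id for m in genotype_meta.included}
    by_ac: dict[str, list[float]] = {}
    for r in records:
        v = r.trait(trait)
        if v is None or r.genotype_id not in included:
            continue
        by_ac.setdefault(genotype_meta.combination_of(r.genotype_id), []).append(float(v))
    acs = sorted(by_ac)
    means = [float(np.mean(by_ac[ac])) for ac in acs]
    n_per_mean = int(round(float(np.mean([len(by_ac[ac]) for ac in acs]))))
    return lsd_compare(
        acs,
        means,
        error_ms=float(within.ms),
        error_df=int(within.df),
        n_per_mean=n_per_mean,
        alpha=alpha,
        protecting_p=between.p,
    )
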