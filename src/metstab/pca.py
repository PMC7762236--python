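"""Correlation-matrix PCA of environment-level covariate and trait means,
with a collinearity screen and deterministic biplot coordinates."""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .data import DataError, PlotRecord

logger = logging.getLogger(__name__)

DEFAULT_TRAITS = ("gn_m2", "gw_mg", "gy_g_m2")


@dataclass
class PcaResult:
    variables: list[str]  # retained after the collinearity screen
    loadings: np.ndarray  # (n_vars, n_axes), orthonormal columns
    scores: np.ndarray  # (n_obs, n_axes)
    explained_pct: np.ndarray  # per axis, sums to 100
    correlation: pd.DataFrame
    observation_ids: list[str]

    def scores_frame(self) -> pd.DataFrame:
        cols = {f"PC{k + 1}": self.scores[:, k] for k in range(self.scores.shape[1])}
        return pd.DataFrame({"environment": self.observation_ids, **cols})

    def loadings_frame(self) -> pd.DataFrame:
        cols = {f"PC{k + 1}": self.loadings[:, k] for k in range(self.loadings.shape[1])}
        return pd.DataFrame({"variable": self.variables, **cols})


def environment_table(
    records: Sequence[PlotRecord],
    covariates: pd.DataFrame,
    traits: Sequence[str] = DEFAULT_TRAITS,
) -> pd.DataFrame:
    """Environment × variable means across genotypes and replications.

    One row per site-year; covariate columns that are entirely missing
    for any environment are dropped with a warning.
    """
    cov = covariates.copy()
    cov["environment"] = cov["site"].astype(str) + "-" + cov["year"].astype(str)
    value_cols = [
        c for c in cov.columns if c not in ("site", "year", "block", "genotype", "environment")
    ]
    env_cov = cov.groupby("environment", sort=True)[value_cols].mean()
    drop = [c for c in env_cov.columns if env_cov[c].isna().any()]
    if drop:
        logger.warning("dropping covariates with missing environments: %s", drop)
        env_cov = env_cov.drop(columns=drop)

    rows = []
    for r in records:
        row = {"environment": r.environment_id}
        for t in traits:
            row[t] = r.trait(t)
        rows.append(row)
    env_tr = pd.DataFrame(rows).groupby("environment", sort=True).mean()
    out = env_cov.join(env_tr, how="inner").reset_index()
    if len(out) < 2:
        raise DataError("PCA undefined for a single environment")
    return out


def pca_corr(
    table: pd.DataFrame, collinearity_r_cut: float = 0.95
) -> PcaResult:
    """PCA on the correlation matrix of the environment table.

    Constant columns are dropped; of any pair with |r| above the cut the
    first in column order is kept. Axes are ordered by eigenvalue
    descending, and each loading vector's largest-magnitude element is
    made positive so output is deterministic.
    """
    obs_ids = table["environment"].astype(str).tolist()
    data = table.drop(columns=["environment"])
    n = len(data)
    if n < 3:
        raise DataError("PCA needs >= 3 observations")

    cols = []
    for c in data.columns:
        if np.isclose(data[c].std(ddof=1), 0.0):
            logger.warning("dropping constant column %r", c)
        else:
            cols.append(c)
    data = data[cols]

    corr_full = data.corr()
    keep: list[str] = []
    for c in data.columns:
        if all(abs(corr_full.loc[c, k]) <= collinearity_r_cut for k in keep):
            keep.append(c)
        else:
            logger.warning("pruning collinear column %r (|r| > %.2f)", c, collinearity_r_cut)
    if len(keep) < 2:
        raise DataError("fewer than 2 variables remain after screening")
    data = data[keep]

    z = (data - data.mean()) / data.std(ddof=1)
    corr = z.corr()
    eigvals, eigvecs = np.linalg.eigh(corr.to_numpy())
    order = np.argsort(eigvals)[::-1]
    eigvals = np.clip(eigvals[order], 0.0, None)
    eigvecs = eigvecs[:, order]
    for k in range(eigvecs.shape[1]):
        j = int(np.argmax(np.abs(eigvecs[:, k])))
        if eigvecs[j, k] < 0:
            eigvecs[:, k] = -eigvecs[:, k]
    scores = z.to_numpy() @ eigvecs
    explained = 100.0 * eigvals / eigvals.sum()
    return PcaResult(
        variables=keep,
        loadings=eigvecs,
        scores=scores,
        explained_pct=explained,
        correlation=corr,
        observation_ids=obs_ids,
    )
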