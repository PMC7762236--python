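"""Per-experiment mixed model: fixed allele-combination effect, random
genotype-within-combination effect, random replicate, and residual.

REML is computed on the profiled log-likelihood over the two variance
ratios (genotype/residual and replicate/residual), with the residual
variance profiled out analytically. BLUPs of the genotype-within-
combination effect isolate the earliness-per-se signal: because the
combination is fixed, each BLUP is centred on its combination mean.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .anova import significance_stars
from .data import DataError, GenotypeTable, PlotRecord

logger = logging.getLogger(__name__)


@dataclass
class EpsModelFit:
    environment_id: str
    trait: str
    ac_effects: dict[str, float]
    sigma2_g: float
    sigma2_r: float
    sigma2_e: float
    blups: dict[str, float]
    shrinkage: dict[str, float]
    boundary: bool  # any variance component truncated at zero
    converged: bool


def _reml_neg_loglik(
    gammas: np.ndarray, y: np.ndarray, X: np.ndarray, Zs: list[np.ndarray]
) -> tuple[float, float, np.ndarray]:
    """Profiled REML criterion at variance ratios ``gammas``.

    Returns (-2·profiled restricted log-likelihood up to a constant,
    profiled residual variance, GLS fixed-effect estimate).
    """
    n, p = X.shape
    H = np.eye(n)
    for gamma, Z in zip(gammas, Zs):
        H += gamma * (Z @ Z.T)
    try:
        Hinv = np.linalg.inv(H)
        XtHiX = X.T @ Hinv @ X
        beta = np.linalg.solve(XtHiX, X.T @ Hinv @ y)
    except np.linalg.LinAlgError:
        return np.inf, np.nan, np.full(p, np.nan)
    resid = y - X @ beta
    quad = float(resid @ Hinv @ resid)
    sigma2_e = quad / (n - p)
    sign, logdet_H = np.linalg.slogdet(H)
    sign2, logdet_X = np.linalg.slogdet(XtHiX)
    # exactly-degenerate data (zero residual variance) hits the boundary
    if sign <= 0 or sign2 <= 0 or not np.isfinite(sigma2_e) or sigma2_e <= 1e-300:
        return np.inf, max(sigma2_e, 0.0), beta
    crit = (n - p) * np.log(sigma2_e) + logdet_H + logdet_X
    return crit, sigma2_e, beta


def fit_eps_model(
    records: Sequence[PlotRecord],
    trait: str,
    genotype_meta: GenotypeTable,
    max_iter: int = 200,
) -> EpsModelFit:
    """REML fit for a single experiment's plots.

    Singleton combinations contribute no within-combination information
    (their genotype BLUP is 0 by centring). Raises on non-convergence.
    """
    envs = {r.environment_id for r in records}
    if len(envs) != 1:
        raise DataError(f"fit_eps_model expects one experiment, got {sorted(envs)}")
    env = envs.pop()
    recs = [r for r in records if r.trait(trait) is not None]
    if not recs:
        raise DataError(f"no data for trait {trait!r} in {env}")

    genos = sorted({r.genotype_id for r in recs})
    blocks = sorted({r.block for r in recs})
    acs = sorted({genotype_meta.combination_of(g) for g in genos})
    ac_counts = {ac: sum(1 for g in genos if genotype_meta.combination_of(g) == ac) for ac in acs}
    if max(ac_counts.values()) < 2:
        raise DataError("need at least one combination with >= 2 genotypes")
    for ac, cnt in ac_counts.items():
        if cnt < 2:
            logger.warning(
                "%s: combination %s has a single genotype; its BLUP is 0", env, ac
            )

    gidx = {g: i for i, g in enumerate(genos)}
    bidx = {b: i for i, b in enumerate(blocks)}
    aidx = {a: i for i, a in enumerate(acs)}
    n = len(recs)
    y = np.array([float(r.trait(trait)) for r in recs])
    X = np.zeros((n, len(acs)))
    Zg = np.zeros((n, len(genos)))
    Zr = np.zeros((n, len(blocks)))
    for i, r in enumerate(recs):
        X[i, aidx[genotype_meta.combination_of(r.genotype_id)]] = 1.0
        Zg[i, gidx[r.genotype_id]] = 1.0
        Zr[i, bidx[r.block]] = 1.0

    def objective(log_gammas: np.ndarray) -> float:
        crit, _, _ = _reml_neg_loglik(np.exp(log_gammas), y, X, [Zg, Zr])
        return crit

    # gradient-based on log-ratios, then a derivative-free polish; the
    # boundary (ratio -> 0) is reached as log-gamma -> -inf, capped below
    LOWER = -30.0
    attempts = []
    for start in ([0.0, 0.0], [2.0, -2.0], [-2.0, 2.0]):
        attempts.append(
            optimize.minimize(
                objective,
                np.array(start),
                method="L-BFGS-B",
                bounds=[(LOWER, 12.0)] * 2,
                options={"maxiter": max_iter, "ftol": 1e-14, "gtol": 1e-10},
            )
        )
    best = min(attempts, key=lambda r: r.fun)
    polish = optimize.minimize(
        objective,
        best.x,
        method="Nelder-Mead",
        options={"maxiter": 2000, "xatol": 1e-10, "fatol": 1e-12},
    )
    attempts.append(polish)
    res = min(attempts, key=lambda r: r.fun)
    # converged if any successful attempt reached the best criterion value
    ok = any(a.success and a.fun <= res.fun + 1e-8 for a in attempts)
    if not ok:
        raise DataError(
            f"REML did not converge for {env}/{trait}: last iterate {np.exp(res.x)}"
        )

    gammas = np.exp(np.clip(res.x, LOWER, 12.0))
    boundary = bool((res.x <= LOWER + 1e-6).any())
    gammas = np.where(res.x <= LOWER + 1e-6, 0.0, gammas)
    _, sigma2_e, beta = _reml_neg_loglik(gammas, y, X, [Zg, Zr])
    sigma2_g = float(gammas[0] * sigma2_e)
    sigma2_r = float(gammas[1] * sigma2_e)

    # BLUP: u = sigma2_g Zg' V^{-1} (y - X beta)
    V = sigma2_e * np.eye(n) + sigma2_g * (Zg @ Zg.T) + sigma2_r * (Zr @ Zr.T)
    Vinv = np.linalg.inv(V)
    u = sigma2_g * (Zg.T @ (Vinv @ (y - X @ beta)))
    blups = {g: float(u[gidx[g]]) for g in genos}

    n_rep = len(blocks)
    shrink = sigma2_g / (sigma2_g + sigma2_e / n_rep) if sigma2_g + sigma2_e > 0 else 0.0
    shrinkage = {g: float(np.clip(shrink, 0.0, 1.0)) for g in genos}

    return EpsModelFit(
        environment_id=env,
        trait=trait,
        ac_effects={a: float(beta[aidx[a]]) for a in acs},
        sigma2_g=sigma2_g,
        sigma2_r=sigma2_r,
        sigma2_e=float(sigma2_e),
        blups=blups,
        shrinkage=shrinkage,
        boundary=boundary,
        converged=True,
    )


def fit_all_experiments(
    records: Sequence[PlotRecord],
    traits: Sequence[str],
    genotype_meta: GenotypeTable,
) -> dict[tuple[str, str], EpsModelFit]:
    """Fit the model separately for every (experiment, trait) with data."""
    included = {m.genotype_id for m in genotype_meta.included}
    by_env: dict[str, list[PlotRecord]] = {}
    for r in records:
        if r.genotype_id in included:
            by_env.setdefault(r.environment_id, []).append(r)
    fits: dict[tuple[str, str], EpsModelFit] = {}
    for env in sorted(by_env):
        for trait in traits:
            recs = [r for r in by_env[env] if r.trait(trait) is not None]
            if len({r.genotype_id for r in recs}) < 3:
                continue
            fits[(env, trait)] = fit_eps_model(recs, trait, genotype_meta)
    return fits


def pearson_with_p(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Pearson r with a two-sided p from the t-transform with n-2 df."""
    n = len(x)
    r = float(np.corrcoef(x, y)[0, 1])
    if abs(r) >= 1.0:
        return r, 0.0
    tstat = r * np.sqrt((n - 2) / (1.0 - r * r))
    p = 2.0 * float(stats.t.sf(abs(tstat), n - 2))
    return r, p


def eps_correlations(
    fits: dict[tuple[str, str], EpsModelFit],
    x_traits: Sequence[str],
    y_traits: Sequence[str],
    min_n: int = 4,
    var_tol: float = 1e-12,
) -> pd.DataFrame:
    """Per-experiment Pearson correlations across genotypes between BLUPs.

    Rows with (near-)zero BLUP variance on either side are excluded and
    flagged; correlations with fewer than ``min_n`` genotypes carry an
    unreliable-p flag.
    """
    rows = []
    envs = sorted({env for env, _ in fits})
    for env in envs:
        for xt in x_traits:
            for yt in y_traits:
                fx = fits.get((env, xt))
                fy = fits.get((env, yt))
                if fx is None or fy is None:
                    continue
                common = sorted(set(fx.blups) & set(fy.blups))
                x = np.array([fx.blups[g] for g in common])
                yv = np.array([fy.blups[g] for g in common])
                if np.var(x) <= var_tol or np.var(yv) <= var_tol:
                    logger.warning(
                        "%s: zero BLUP variance for %s~%s, correlation undefined",
                        env, xt, yt,
                    )
                    continue
                r, p = pearson_with_p(x, yv)
                rows.append(
                    {
                        "environment": env,
                        "x_trait": xt,
                        "y_trait": yt,
                        "n": len(common),
                        "r": r,
                        "p": p,
                        "stars": significance_stars(p),
                        "p_reliable": len(common) >= min_n,
                    }
                )
    return pd.DataFrame(
        rows,
        columns=["environment", "x_trait", "y_trait", "n", "r", "p", "stars", "p_reliable"],
    )
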