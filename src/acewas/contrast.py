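"""Monte-Carlo plug-in contrasts: percent-methylation baselines and
exposure-associated changes for a reference individual.

A fitted logit-scale model gives a coefficient vector; plugging in a
reference covariate row X0 (numeric covariates at their means, categorical
at their modes, exposures at zero) and an exposed row X1 yields predicted
methylation fractions through the inverse logit. The difference

    delta = invlogit(theta . X1) - invlogit(theta . X0)

is simulated by drawing the coefficient vector from a multivariate normal
centered at the fit with its estimated covariance; percentile intervals of
3000 draws summarize uncertainty, reported in percentage points.

Models here are fit on M-values (log2-odds), while the inverse logit above
is natural-base; since invlogit(ln2 * M) equals the beta value exactly,
M-scale coefficients are rescaled by ln 2 before the natural-logit
equations are applied. The methylation odds ratio is the exponential of
the natural-scale exposure coefficient (equivalently 2^coef on the M scale).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit

from .ewas import DesignInfo, EwasResult

logger = logging.getLogger(__name__)

LN2 = float(np.log(2.0))


def reference_profile(design: DesignInfo) -> pd.Series:
    """Design row of the reference individual.

    Numeric design columns are set to their observed means, dummy columns
    to the indicator pattern of the modal level of their source categorical
    (ties broken toward the first declared level, logged), and exposure
    columns to zero.
    """
    X = design.matrix
    if len(X) == 0:
        raise ValueError("empty design")
    row = pd.Series(0.0, index=X.columns)
    row["Intercept"] = 1.0

    handled: set[str] = set()
    cat_sources = {}
    for col, (origin, level) in design.column_source.items():
        if level is not None:
            cat_sources.setdefault(origin, []).append((col, level))
    for origin, cols in cat_sources.items():
        # reconstruct level frequencies; the reference level is everything else
        counts = {level: float(X[col].sum()) for col, level in cols}
        ref_count = float(len(X) - sum(counts.values()))
        best_level, best = None, ref_count  # reference level wins ties
        for col, level in cols:
            if counts[level] > best:
                best, best_level = counts[level], level
        ties = [lv for lv in counts if counts[lv] == best] + (
            ["<reference>"] if ref_count == best else []
        )
        if len(ties) > 1:
            logger.info("reference_profile: modal tie for %s among %s; first declared kept", origin, ties)
        for col, level in cols:
            row[col] = 1.0 if level == best_level else 0.0
        handled.update(col for col, _ in cols)

    for col in X.columns:
        if col in handled or col == "Intercept" or col in design.exposure_columns:
            continue
        row[col] = float(X[col].mean())
    for col in design.exposure_columns:
        row[col] = 0.0
    return row


def exposed_profile(x0: pd.Series, design: DesignInfo, exposure: str) -> pd.Series:
    """Exposed counterpart of the reference row.

    For the linear total-count specification the count is incremented by
    one; for indicator exposures exactly that indicator is set to 1.
    """
    x1 = x0.copy()
    if exposure not in design.exposure_columns:
        raise ValueError(f"unknown exposure column {exposure!r}")
    if design.mode == "total_linear":
        x1[exposure] = x0[exposure] + 1.0
    else:
        x1[exposure] = 1.0
    return x1


@dataclass
class ContrastDraws:
    """Monte-Carlo contrast summary for one CpG and one exposure."""

    delta_hat: float  # percentage points
    delta_lo: float
    delta_hi: float
    baseline: float  # percent methylated
    baseline_lo: float
    baseline_hi: float
    methylation_or: float
    draws: np.ndarray  # simulated delta values, percentage points


def _safe_cholesky(sigma: np.ndarray) -> np.ndarray:
    try:
        return np.linalg.cholesky(sigma)
    except np.linalg.LinAlgError:
        logger.info("mc_methylation_contrast: covariance not PD; adding 1e-10 jitter")
        jitter = 1e-10 * np.eye(sigma.shape[0])
        for _ in range(12):
            try:
                return np.linalg.cholesky(sigma + jitter)
            except np.linalg.LinAlgError:
                jitter *= 10.0
        raise


def mc_methylation_contrast(
    coef: np.ndarray,
    sigma: np.ndarray,
    x0: np.ndarray,
    x1: np.ndarray,
    n_draws: int = 3000,
    seed: int = 0,
    scale: str = "m",
    exposure_index: int | None = None,
) -> ContrastDraws:
    """Simulate the percent-methylation difference between exposed and
    reference individuals.

    ``scale="m"`` declares log2-odds coefficients (rescaled by ln 2
    internally); ``scale="natural"`` takes them as natural log-odds. The
    methylation OR is exp of the natural-scale coefficient change, i.e. the
    multiplicative change in methylation odds under exposure.
    """
    coef = np.asarray(coef, dtype=float)
    sigma = np.asarray(sigma, dtype=float)
    x0 = np.asarray(x0, dtype=float)
    x1 = np.asarray(x1, dtype=float)
    if sigma.shape != (coef.size, coef.size) or x0.size != coef.size or x1.size != coef.size:
        raise ValueError("dimension mismatch between coefficients, covariance, and design rows")
    if scale not in ("m", "natural"):
        raise ValueError("scale must be 'm' or 'natural'")
    c = LN2 if scale == "m" else 1.0

    eta0_hat = c * float(x0 @ coef)
    eta1_hat = c * float(x1 @ coef)
    delta_hat = 100.0 * (expit(eta1_hat) - expit(eta0_hat))
    baseline_hat = 100.0 * expit(eta0_hat)

    if np.allclose(sigma, 0.0):
        delta_draws = np.full(n_draws, delta_hat)
        base_draws = np.full(n_draws, baseline_hat)
    else:
        rng = np.random.default_rng(seed)
        L = _safe_cholesky(sigma)
        z = rng.standard_normal(size=(n_draws, coef.size))
        theta = coef + z @ L.T
        eta0 = c * (theta @ x0)
        eta1 = c * (theta @ x1)
        delta_draws = 100.0 * (expit(eta1) - expit(eta0))
        base_draws = 100.0 * expit(eta0)

    lo, hi = np.percentile(delta_draws, [2.5, 97.5])
    blo, bhi = np.percentile(base_draws, [2.5, 97.5])
    or_ = float(np.exp(eta1_hat - eta0_hat))  # odds change under exposure
    if exposure_index is not None:
        or_ = float(np.exp(c * coef[exposure_index] * (x1[exposure_index] - x0[exposure_index])))
    return ContrastDraws(
        delta_hat=float(delta_hat),
        delta_lo=float(lo),
        delta_hi=float(hi),
        baseline=float(baseline_hat),
        baseline_lo=float(blo),
        baseline_hi=float(bhi),
        methylation_or=or_,
        draws=delta_draws,
    )


def contrast_table(
    result: EwasResult,
    cpg_ids: list[str],
    exposures: list[str] | None = None,
    n_draws: int = 3000,
    seed: int = 0,
) -> pd.DataFrame:
    """Monte-Carlo contrasts for selected CpGs of a fitted EWAS.

    The per-CpG coefficient covariance is the moderated residual variance
    times the shared (X'X)^-1.
    """
    design = result.design
    x0 = reference_profile(design).to_numpy()
    cols = list(design.matrix.columns)
    exposures = exposures or design.exposure_columns
    idx_of = {cid: i for i, cid in enumerate(result.coefficients.index)}
    x0_series = reference_profile(design)
    rows = []
    for k, cid in enumerate(cpg_ids):
        g = idx_of[cid]
        coef = result.coefficients.iloc[g].to_numpy()
        sigma = result.s2_post[g] * result.xtx_inv
        for e_i, exp_name in enumerate(exposures):
            x1 = exposed_profile(x0_series, design, exp_name).to_numpy()
            j = cols.index(exp_name)
            cd = mc_methylation_contrast(
                coef, sigma, x0, x1, n_draws=n_draws,
                seed=seed + 1000 * k + e_i, scale="m", exposure_index=j,
            )
            rows.append(
                dict(
                    cpg_id=cid, term=exp_name, methylation_or=cd.methylation_or,
                    baseline_pct=cd.baseline, baseline_lo=cd.baseline_lo, baseline_hi=cd.baseline_hi,
                    delta_pct=cd.delta_hat, delta_lo=cd.delta_lo, delta_hi=cd.delta_hi,
                )
            )
    return pd.DataFrame(rows)
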