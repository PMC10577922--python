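"""Per-CpG moderated linear modeling on M-values under three exposure
specifications, with multiplicity control and inflation diagnostics.

The model for each CpG is ordinary least squares of its M-values on an
intercept, a fixed a-priori covariate set (newborn sex, gestational age,
maternal parity, BMI, age, education, smoking, marital status, and six of
the seven cell-type proportions with granulocytes as reference), and the
exposure terms of the chosen specification. Residual variances are shrunk
toward a common prior by empirical Bayes: per-CpG sample variances are
modeled as scaled F draws, the prior df and scale are recovered by moment
matching on the log scale (digamma/trigamma inversion), and moderated
t-statistics use the posterior variance with augmented degrees of freedom.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import interpolate, special, stats

from .config import ACE_NAMES, CELL_TYPES
from .core import MethylationMatrix

logger = logging.getLogger(__name__)

EXPOSURE_MODES = ("total_linear", "total_categorical", "individual")

#: reference levels for dummy coding; the intercept then corresponds to the
#: cohort's modal profile (female newborn; mother married, never-smoking,
#: education at or below 6th grade)
REFERENCE_LEVELS = {
    "sex": "female",
    "education": "6th_grade_or_lower",
    "smoking": "never",
    "marital_status": "married",
}

COVARIATE_NUMERIC = ("gestational_age_days", "parity", "bmi", "maternal_age")
COVARIATE_CATEGORICAL = ("sex", "education", "smoking", "marital_status")
CELL_REFERENCE = "Gran"  # dropped cell-proportion column


def exposure_terms(mode: str) -> list[str]:
    if mode == "total_linear":
        return ["total_aces"]
    if mode == "total_categorical":
        return ["ace_1_3", "ace_4_10"]
    if mode == "individual":
        return list(ACE_NAMES)
    raise ValueError(f"unknown exposure mode {mode!r}")


@dataclass
class DesignInfo:
    """Design matrix metadata: column provenance for contrasts and profiles."""

    matrix: pd.DataFrame
    mode: str
    exposure_columns: list[str]
    covariate_columns: list[str]
    column_source: dict[str, tuple[str, str | None]]  # col -> (origin column, level)
    vif: pd.Series = field(default=None)
    n_dropped: int = 0


def _dummy_columns(cohort: pd.DataFrame, name: str, reference: str) -> pd.DataFrame:
    col = cohort[name]
    if isinstance(col.dtype, pd.CategoricalDtype):
        levels = list(col.cat.categories)
    else:
        levels = sorted(col.unique())
    if reference not in levels:
        raise ValueError(f"reference level {reference!r} absent from column {name!r}")
    out = {}
    for lev in levels:
        if lev == reference:
            continue
        out[f"{name}[{lev}]"] = (col == lev).astype(float).to_numpy()
    return pd.DataFrame(out, index=cohort.index)


def compute_vif(X: pd.DataFrame) -> pd.Series:
    """Variance inflation factor 1/(1-R^2) per non-intercept column."""
    cols = [c for c in X.columns if c != "Intercept"]
    out = {}
    Xv = X.to_numpy()
    names = list(X.columns)
    for c in cols:
        j = names.index(c)
        y = Xv[:, j]
        others = np.delete(Xv, j, axis=1)
        coef, _, _, _ = np.linalg.lstsq(others, y, rcond=None)
        resid = y - others @ coef
        tss = np.sum((y - y.mean()) ** 2)
        if tss <= 0:
            out[c] = np.inf
            continue
        r2 = 1.0 - resid @ resid / tss
        out[c] = np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    return pd.Series(out, name="vif")


def build_design(
    cohort: pd.DataFrame,
    mode: str,
    cell_proportions: pd.DataFrame | None = None,
) -> DesignInfo:
    """Design matrix for one exposure specification.

    Cell proportions may be passed separately (estimated composition) or be
    present as columns of the cohort table; six of the seven enter the
    design, granulocytes being the reference mixture component. Rows with
    any missing value are dropped (complete-case analysis, count logged).
    """
    work = cohort.copy()
    if cell_proportions is not None:
        work = work.join(cell_proportions, how="inner")
    complete = work.dropna()
    n_dropped = len(work) - len(complete)
    if n_dropped:
        logger.info("build_design: dropped %d incomplete rows", n_dropped)

    X = pd.DataFrame({"Intercept": np.ones(len(complete))}, index=complete.index)
    source: dict[str, tuple[str, str | None]] = {"Intercept": ("Intercept", None)}
    covariate_cols: list[str] = []

    for name in COVARIATE_CATEGORICAL:
        dummies = _dummy_columns(complete, name, REFERENCE_LEVELS[name])
        for c in dummies.columns:
            X[c] = dummies[c]
            source[c] = (name, c.split("[", 1)[1][:-1])
            covariate_cols.append(c)
    for name in COVARIATE_NUMERIC:
        X[name] = np.asarray(complete[name], dtype=float)
        source[name] = (name, None)
        covariate_cols.append(name)
    have_cells = all(ct in complete.columns for ct in CELL_TYPES)
    if not have_cells:
        logger.info("build_design: no cell-proportion columns; fitting without composition adjustment")
    for ct in CELL_TYPES:
        if ct == CELL_REFERENCE or not have_cells:
            continue
        X[ct] = np.asarray(complete[ct], dtype=float)
        source[ct] = (ct, None)
        covariate_cols.append(ct)

    exp_cols = exposure_terms(mode)
    for c in exp_cols:
        X[c] = np.asarray(complete[c], dtype=float)
        source[c] = (c, None)

    for c in list(X.columns):
        if c != "Intercept" and X[c].nunique() <= 1:
            origin, level = source[c]
            if level is not None:
                # unobserved categorical level: drop its dummy rather than fail
                logger.info("build_design: level %r of %r unobserved; dropping column", level, origin)
                X = X.drop(columns=[c])
                covariate_cols.remove(c)
                del source[c]
            else:
                raise ValueError(f"design column {c!r} is constant after subsetting")

    vif = compute_vif(X)
    return DesignInfo(
        matrix=X,
        mode=mode,
        exposure_columns=exp_cols,
        covariate_columns=covariate_cols,
        column_source=source,
        vif=vif,
        n_dropped=n_dropped,
    )


# ---------------------------------------------------------------------------
# empirical Bayes variance moderation


def _trigamma_inverse(y: np.ndarray) -> np.ndarray:
    """Solve trigamma(x) = y by Newton iteration (monotone decreasing)."""
    y = np.asarray(y, dtype=float)
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x = x + dif
        if np.all(np.abs(dif) / np.maximum(x, 1e-12) < 1e-10):
            break
    return x


def fit_f_dist(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Moment-match a scaled F model for sample variances.

    Returns (d0, s0_squared): prior degrees of freedom (may be inf) and
    prior variance. Follows the log-variance moment equations: the variance
    of log s^2 in excess of trigamma(df/2) identifies d0; the mean
    identifies s0^2.
    """
    s2 = np.asarray(s2, dtype=float)
    m = len(s2)
    z = np.log(np.maximum(s2, 1e-300))
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    emean = e.mean()
    if m <= 1:
        return 0.0, float(np.exp(emean))
    evar = np.sum((e - emean) ** 2) / (m - 1) - special.polygamma(1, df / 2.0)
    if evar <= 0:
        # homoscedastic limit: infinite prior df, pooled variance
        logger.warning("fit_f_dist: no excess variability in s^2; prior df set infinite")
        return np.inf, float(np.mean(s2))
    d0 = 2.0 * float(_trigamma_inverse(np.array([evar]))[0])
    s0_2 = float(np.exp(emean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    return d0, s0_2


def squeeze_variances(s2: np.ndarray, df: float) -> tuple[np.ndarray, float, float]:
    """Posterior (shrunk) variances s~^2 = (d0 s0^2 + df s^2)/(d0 + df)."""
    d0, s0_2 = fit_f_dist(s2, df)
    if np.isinf(d0):
        post = np.full_like(np.asarray(s2, float), s0_2)
    else:
        post = (d0 * s0_2 + df * s2) / (d0 + df)
    return post, d0, s0_2


@dataclass
class EwasResult:
    """Per-CpG, per-exposure-term moderated EWAS output."""

    table: pd.DataFrame  # cpg_id, chrom, pos, gene, feature, term, coef, se, t, df, p, q, methylation_or
    design: DesignInfo
    d0: float
    s0_2: float
    residual_df: float
    coefficients: pd.DataFrame  # all model coefficients, CpG x column
    s2_post: np.ndarray
    xtx_inv: np.ndarray
    lambdas: pd.Series = field(default=None)
    pi0: pd.Series = field(default=None)


def fit_moderated(matrix: MethylationMatrix, design: DesignInfo) -> EwasResult:
    """Moderated per-CpG linear fit on the M scale.

    Coefficients are exactly ordinary least squares; the empirical-Bayes
    step only shrinks residual variances and augments degrees of freedom.
    A single-CpG input gets no shrinkage (d0 = 0, ordinary t).
    """
    m = matrix.to_m()
    X = design.matrix
    if list(m.sample_ids) != list(X.index):
        lookup = {s: i for i, s in enumerate(m.sample_ids)}
        try:
            Y = m.values[:, [lookup[s] for s in X.index]]
        except KeyError as exc:
            raise ValueError("samples in matrix and design are not aligned") from exc
    else:
        Y = m.values
    Xv = X.to_numpy()
    n, p = Xv.shape
    rank = np.linalg.matrix_rank(Xv)
    df_resid = n - rank
    if df_resid < 2:
        raise ValueError("fewer than 2 residual degrees of freedom")

    xtx_inv = np.linalg.pinv(Xv.T @ Xv)
    pinv = xtx_inv @ Xv.T
    coefs = Y @ pinv.T  # CpGs x p
    resid = Y - coefs @ Xv.T
    s2 = np.einsum("ij,ij->i", resid, resid) / df_resid

    n_cpgs = coefs.shape[0]
    if n_cpgs == 1:
        s2_post, d0, s0_2 = s2.copy(), 0.0, float(s2[0])
    else:
        s2_post, d0, s0_2 = squeeze_variances(s2, df_resid)
    df_total = df_resid + (d0 if np.isfinite(d0) else 1e9)

    unscaled_sd = np.sqrt(np.diag(xtx_inv))
    rows = []
    ann = m.cpg_annotation
    for term in design.exposure_columns:
        j = list(X.columns).index(term)
        coef = coefs[:, j]
        se = unscaled_sd[j] * np.sqrt(s2_post)
        t = coef / se
        pvals = 2.0 * stats.t.sf(np.abs(t), df_total)
        rows.append(
            pd.DataFrame(
                {
                    "cpg_id": ann.index,
                    "chrom": ann["chrom"].to_numpy(),
                    "pos": ann["pos"].to_numpy(),
                    "gene": ann["gene"].to_numpy(),
                    "feature": ann["feature"].to_numpy(),
                    "term": term,
                    "coef": coef,
                    "se": se,
                    "t": t,
                    "df": df_total,
                    "p": pvals,
                    "methylation_or": np.exp2(coef),
                }
            )
        )
    table = pd.concat(rows, ignore_index=True)

    # one multiplicity family per specification: all terms' p-values together
    q, pi0 = storey_qvalues(table["p"].to_numpy())
    table["q"] = q
    lambdas = table.groupby("term", sort=False)["p"].apply(lambda pv: genomic_lambda(pv.to_numpy()))
    result = EwasResult(
        table=table,
        design=design,
        d0=d0,
        s0_2=s0_2,
        residual_df=df_resid,
        coefficients=pd.DataFrame(coefs, index=ann.index, columns=list(X.columns)),
        s2_post=s2_post,
        xtx_inv=xtx_inv,
        lambdas=lambdas,
        pi0=pd.Series({"all": pi0}),
    )
    return result


def categorical_high_vs_mid_contrast(result: EwasResult) -> pd.DataFrame:
    """The 4-10 vs 1-3 ACE contrast from the categorical specification.

    Computed as the difference of the two fitted indicator coefficients
    with covariance-propagated standard error; equivalent to refitting with
    the 1-3 category as baseline.
    """
    if result.design.mode != "total_categorical":
        raise ValueError("contrast defined only for the categorical specification")
    cols = list(result.design.matrix.columns)
    j1, j2 = cols.index("ace_1_3"), cols.index("ace_4_10")
    coef = result.coefficients.to_numpy()
    diff = coef[:, j2] - coef[:, j1]
    c = np.zeros(len(cols))
    c[j2], c[j1] = 1.0, -1.0
    var_unscaled = float(c @ result.xtx_inv @ c)
    se = np.sqrt(var_unscaled * result.s2_post)
    df_total = result.residual_df + (result.d0 if np.isfinite(result.d0) else 1e9)
    t = diff / se
    p = 2.0 * stats.t.sf(np.abs(t), df_total)
    base = result.table[result.table["term"] == "ace_4_10"][
        ["cpg_id", "chrom", "pos", "gene", "feature"]
    ].reset_index(drop=True)
    out = base.copy()
    out["term"] = "ace_4_10_vs_1_3"
    out["coef"] = diff
    out["se"] = se
    out["t"] = t
    out["df"] = df_total
    out["p"] = p
    out["methylation_or"] = np.exp2(diff)
    return out


# ---------------------------------------------------------------------------
# diagnostics and multiplicity


def genomic_lambda(pvals: np.ndarray) -> float:
    """Genomic inflation factor: median association chi-square over its null median."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value vector")
    if (p <= 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in (0, 1]")
    chi = stats.chi2.isf(p, df=1)
    return float(np.median(chi) / stats.chi2.ppf(0.5, df=1))


def storey_qvalues(
    pvals: np.ndarray, pi0_method: str = "smoother"
) -> tuple[np.ndarray, float]:
    """Storey-Tibshirani q-values with spline-smoothed pi0 estimation.

    pi0 is estimated on the lambda grid 0.05..0.95 (step 0.05) by a cubic
    smoothing spline evaluated at 0.95, clamped to (0, 1]. With
    ``pi0_method="fixed_1"`` the estimate is fixed at 1 and the q-values
    reduce to Benjamini-Hochberg with a cumulative minimum.
    """
    p = np.asarray(pvals, dtype=float)
    m = p.size
    if m == 0:
        raise ValueError("empty p-value vector")
    if pi0_method == "fixed_1":
        pi0 = 1.0
    elif pi0_method == "smoother":
        if m < 100:
            pi0 = 1.0
        else:
            grid = np.arange(0.05, 0.96, 0.05)
            pi0_grid = np.array([np.mean(p > lam) / (1.0 - lam) for lam in grid])
            spl = interpolate.UnivariateSpline(grid, pi0_grid, k=3, s=len(grid) / 3.0)
            pi0 = float(spl(0.95))
            pi0 = min(max(pi0, 1.0 / m), 1.0)
    else:
        raise ValueError("pi0_method must be 'smoother' or 'fixed_1'")

    order = np.argsort(p, kind="mergesort")
    ranked = p[order]
    q_sorted = pi0 * m * ranked / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    # ties share a q-value by construction of the cumulative minimum
    return q, pi0


def bh_fdr(pvals: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values."""
    q, _ = storey_qvalues(pvals, pi0_method="fixed_1")
    return q
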