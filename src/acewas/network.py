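"""Unsigned weighted co-methylation networks: soft-power selection,
topological overlap, module detection, eigengenes, and module-trait tests.

Adjacency between CpGs i and j is |cor(x_i, x_j)|^power (unsigned network);
the topological overlap matrix (TOM) augments direct adjacency with shared
neighborhood. Modules are found by average-linkage hierarchical clustering
on 1 - TOM with a static cut plus eigengene-based merging -- a simplified,
deterministic stand-in for the dynamic-hybrid tree cut. A module eigengene
is the first principal-component score of its standardized CpG profiles
over samples; kME is each CpG's correlation with the eigengene.

Module-trait testing follows three tiers (bivariate Pearson, covariate-
adjusted regression, mutually adjusted across all ten adversity
indicators) with per-specification multiplicity families: BH for the
total-count specifications and a Grenander-density ("Strimmer") q-value
for the individual-indicator family.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import cluster, stats

from .config import ACE_NAMES
from .ewas import DesignInfo, bh_fdr, build_design

logger = logging.getLogger(__name__)

GREY = "grey"
SEX_CHROMS = ("chrX", "chrY", "X", "Y")


def _corr_rows(M: np.ndarray) -> np.ndarray:
    sd = M.std(axis=1)
    if (sd == 0).any():
        bad = np.flatnonzero(sd == 0)[:10]
        raise ValueError(f"constant rows at indices {bad.tolist()}")
    C = np.corrcoef(M)
    if not np.isfinite(C).all():
        raise ValueError("non-finite correlations")
    return C


def scale_free_fit(k: np.ndarray, n_bins: int = 10) -> float:
    """R^2 of log10(frequency) on log10(mean connectivity) over connectivity bins."""
    k = np.asarray(k, dtype=float)
    k = k[k > 0]
    if k.size < n_bins:
        return 0.0
    edges = np.linspace(k.min(), k.max(), n_bins + 1)
    edges[-1] += 1e-9
    xs, ys = [], []
    for b in range(n_bins):
        sel = (k >= edges[b]) & (k < edges[b + 1])
        if sel.sum() == 0:
            continue
        xs.append(np.log10(k[sel].mean()))
        ys.append(np.log10(sel.mean()))
    if len(xs) < 3 or np.std(xs) == 0 or np.std(ys) == 0:
        return 0.0
    slope, intercept, r, _, _ = stats.linregress(xs, ys)
    return float(r**2) if np.isfinite(r) else 0.0


def pick_soft_power(
    M: np.ndarray,
    candidates: tuple[int, ...] = (1, 2, 3, 4, 5, 6, 8, 10, 12),
    r2_threshold: float = 0.8,
) -> tuple[int, dict[int, float]]:
    """Smallest candidate power with scale-free fit R^2 >= threshold.

    Falls back (with a warning) to the power maximizing R^2 when no
    candidate reaches the threshold. Returns the chosen power and the
    per-candidate R^2 values.
    """
    C = np.abs(_corr_rows(np.asarray(M, dtype=float)))
    np.fill_diagonal(C, 0.0)
    fits: dict[int, float] = {}
    for power in candidates:
        k = (C**power).sum(axis=1)
        fits[power] = scale_free_fit(k)
    for power in sorted(candidates):
        if fits[power] >= r2_threshold:
            return power, fits
    best = max(fits, key=lambda pw: fits[pw])
    logger.warning(
        "pick_soft_power: no candidate reached R^2 >= %.2f; using %d (R^2 = %.3f)",
        r2_threshold, best, fits[best],
    )
    return best, fits


def tom_matrix(M: np.ndarray, power: float) -> np.ndarray:
    """Unsigned topological overlap matrix.

    a_ij = |cor|^power with zero diagonal;
    TOM_ij = (sum_u a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 - a_ij), TOM_ii = 1.
    """
    if power < 1:
        raise ValueError("power must be >= 1")
    A = np.abs(_corr_rows(np.asarray(M, dtype=float))) ** power
    np.fill_diagonal(A, 0.0)
    return tom_from_adjacency(A)


def tom_from_adjacency(A: np.ndarray) -> np.ndarray:
    A = np.asarray(A, dtype=float)
    k = A.sum(axis=1)
    shared = A @ A
    denom = np.minimum.outer(k, k) + 1.0 - A
    T = (shared + A) / denom
    np.fill_diagonal(T, 1.0)
    return np.clip(T, 0.0, 1.0)


@dataclass
class ModuleSet:
    """Module assignment plus eigengene summaries."""

    labels: np.ndarray  # per-CpG module label ("grey" = unassigned)
    power: float
    eigengenes: pd.DataFrame = None  # samples x modules, unit variance
    variance_explained: pd.Series = None  # percent, per module
    kme: pd.Series = None  # per CpG, correlation with own module eigengene
    median_abs_kme: pd.Series = None
    excluded_sex_modules: list[str] = field(default_factory=list)

    def module_names(self) -> list[str]:
        return [m for m in pd.unique(self.labels) if m != GREY]


def _cut_adaptive(link: np.ndarray, min_size: int, max_candidates: int = 256) -> np.ndarray:
    """Static cut chosen over candidate heights.

    Among the dendrogram's merge heights (subsampled to at most
    ``max_candidates``), pick the cut maximizing the number of clusters of
    size >= min_size, then the number of CpGs inside such clusters, then
    the lowest height. Fully deterministic.
    """
    heights = np.unique(link[:, 2])
    if heights.size > max_candidates:
        idx = np.linspace(0, heights.size - 1, max_candidates).round().astype(int)
        heights = heights[np.unique(idx)]
    best_key, best_labels = None, None
    for t in heights:
        lab = cluster.hierarchy.fcluster(link, t=t, criterion="distance")
        counts = np.bincount(lab)
        big = counts[counts >= min_size]
        key = (len(big), int(big.sum()), -float(t))
        if best_key is None or key > best_key:
            best_key, best_labels = key, lab
    return best_labels


def detect_modules(
    tom: np.ndarray,
    M: np.ndarray,
    min_size: int = 30,
    merge_threshold: float = 0.75,
    min_kme: float = 0.3,
) -> np.ndarray:
    """Module labels from average-linkage clustering of 1 - TOM.

    The tree is cut at a deterministic data-chosen height (the cut
    maximizing the number of branches of size >= min_size); branches below
    ``min_size`` go to "grey"; modules whose eigengenes correlate above
    ``merge_threshold`` are merged iteratively; finally members whose
    |kME| falls below ``min_kme`` are released to "grey" and undersized
    modules dissolved.
    """
    if min_size < 2:
        raise ValueError("min_size must be >= 2")
    tom = np.asarray(tom, dtype=float)
    D = 1.0 - tom
    np.fill_diagonal(D, 0.0)
    condensed = D[np.triu_indices_from(D, k=1)]
    link = cluster.hierarchy.linkage(condensed, method="average")
    raw = _cut_adaptive(link, min_size)

    labels = np.full(len(raw), GREY, dtype=object)
    order = []
    for lab, count in pd.Series(raw).value_counts().items():
        if count >= min_size:
            order.append(lab)
    # name modules by descending size for stable, readable labels
    for i, lab in enumerate(order):
        labels[raw == lab] = f"M{i + 1}"

    # eigengene-correlation merge
    M = np.asarray(M, dtype=float)
    while True:
        names = [m for m in pd.unique(labels) if m != GREY]
        if len(names) < 2:
            break
        eig = {}
        for name in names:
            eig[name] = _eigengene(M[labels == name])[0]
        merged = False
        best_pair, best_r = None, merge_threshold
        for i in range(len(names)):
            for j in range(i + 1, len(names)):
                r = abs(np.corrcoef(eig[names[i]], eig[names[j]])[0, 1])
                if r > best_r:
                    best_r, best_pair = r, (names[i], names[j])
        if best_pair is None:
            break
        a, b = best_pair
        labels[labels == b] = a

    # kME pruning: release weakly connected members, dissolve small remnants
    for name in [m for m in pd.unique(labels) if m != GREY]:
        sel = labels == name
        pc, _ = _eigengene(M[sel])
        block = M[sel]
        kme = np.array([np.corrcoef(block[g], pc)[0, 1] for g in range(block.shape[0])])
        weak = np.flatnonzero(sel)[np.abs(kme) < min_kme]
        labels[weak] = GREY
        if (labels == name).sum() < min_size:
            labels[labels == name] = GREY
    return labels


def _eigengene(block: np.ndarray) -> tuple[np.ndarray, float]:
    """First PC score over samples of standardized CpG profiles.

    Returns (unit-variance eigengene, percent variance explained). The
    sign is aligned so the eigengene correlates positively with the
    module's mean standardized profile.
    """
    X = np.asarray(block, dtype=float)
    mu = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    Z = (X - mu) / sd
    U, s, Vt = np.linalg.svd(Z, full_matrices=False)
    pc = Vt[0]
    var_expl = 100.0 * s[0] ** 2 / np.sum(s**2)
    mean_profile = Z.mean(axis=0)
    if np.dot(pc, mean_profile) < 0:
        pc = -pc
    sd_pc = pc.std()
    if sd_pc > 0:
        pc = (pc - pc.mean()) / sd_pc
    return pc, float(var_expl)


def module_eigengenes(
    M: np.ndarray,
    labels: np.ndarray,
    sample_ids: list[str],
    power: float = 1.0,
    chroms: np.ndarray | None = None,
    sex_fraction_threshold: float = 0.5,
) -> ModuleSet:
    """Complete a ModuleSet: eigengenes, variance explained, kME.

    Modules with more than ``sex_fraction_threshold`` of their CpGs on a
    sex chromosome are flagged and excluded from the eigengene table.
    """
    labels = np.asarray(labels, dtype=object)
    M = np.asarray(M, dtype=float)
    names = [m for m in pd.unique(labels) if m != GREY]
    excluded = []
    if chroms is not None:
        chroms = np.asarray(chroms)
        for name in list(names):
            frac = np.isin(chroms[labels == name], SEX_CHROMS).mean()
            if frac > sex_fraction_threshold:
                excluded.append(name)
                names.remove(name)
                logger.info("module %s excluded: %.0f%% sex-chromosome CpGs", name, 100 * frac)

    eig, var_expl, med_kme = {}, {}, {}
    kme = np.full(len(labels), np.nan)
    for name in names:
        sel = labels == name
        pc, ve = _eigengene(M[sel])
        eig[name] = pc
        var_expl[name] = ve
        block = M[sel]
        k = np.array([np.corrcoef(block[g], pc)[0, 1] for g in range(block.shape[0])])
        kme[np.flatnonzero(sel)] = k
        med_kme[name] = float(np.median(np.abs(k)))
    return ModuleSet(
        labels=labels,
        power=power,
        eigengenes=pd.DataFrame(eig, index=sample_ids),
        variance_explained=pd.Series(var_expl),
        kme=pd.Series(kme),
        median_abs_kme=pd.Series(med_kme),
        excluded_sex_modules=excluded,
    )


# ---------------------------------------------------------------------------
# Strimmer-style q-values (Grenander density estimate)


def grenander_qvalues(pvals: np.ndarray) -> tuple[np.ndarray, float]:
    """Tail-area q-values from a Grenander (decreasing-density) estimate.

    The empirical p-value CDF is replaced by its least concave majorant
    (pool-adjacent-violators over the ECDF slopes); the null proportion
    eta0 is the fitted density at p = 1, and q_i = eta0 * p_i / F(p_i)
    with a cumulative minimum enforced.
    """
    p = np.asarray(pvals, dtype=float)
    m = p.size
    if m < 10:
        raise ValueError("need at least 10 p-values")
    order = np.argsort(p, kind="mergesort")
    ps = p[order]
    # least concave majorant of ECDF points (0,0), (p_(i), i/(m+1)), (1,1);
    # the (m+1) scaling keeps the density at the right edge positive so the
    # null proportion (the terminal slope) is well defined
    xs = np.concatenate([[0.0], ps, [1.0]])
    ys = np.concatenate([[0.0], np.arange(1, m + 1) / (m + 1), [1.0]])
    hull_x = [xs[0]]
    hull_y = [ys[0]]
    for i in range(1, len(xs)):
        hull_x.append(xs[i])
        hull_y.append(ys[i])
        while len(hull_x) >= 3:
            s1 = (hull_y[-2] - hull_y[-3]) / max(hull_x[-2] - hull_x[-3], 1e-300)
            s2 = (hull_y[-1] - hull_y[-2]) / max(hull_x[-1] - hull_x[-2], 1e-300)
            if s2 > s1 + 1e-12:  # concavity violated: drop middle point
                hull_x.pop(-2)
                hull_y.pop(-2)
            else:
                break
    hx = np.asarray(hull_x)
    hy = np.asarray(hull_y)
    slopes = np.diff(hy) / np.maximum(np.diff(hx), 1e-300)
    # null proportion: fitted density high in the p range, where the
    # decreasing density has flattened to the uniform null level
    j = int(np.searchsorted(hx, 0.95, side="left"))
    j = min(max(j, 1), len(hx) - 1)
    eta0 = float(min(1.0, max(slopes[j - 1], 0.0)))
    # concave-majorant CDF evaluated at each p
    F = np.interp(ps, hx, hy)
    F = np.maximum(F, 1.0 / m)
    q_sorted = np.minimum(eta0 * ps / F, 1.0)
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q = np.empty(m)
    q[order] = q_sorted
    return q, eta0


strimmer_qvalues = grenander_qvalues


# ---------------------------------------------------------------------------
# module-trait association


def me_trait_tests(
    modules: ModuleSet,
    cohort: pd.DataFrame,
    mode: str,
    cell_proportions: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Module-eigengene vs trait association table for one specification.

    Tier 1: bivariate Pearson correlation with two-sided p. Tier 2:
    linear regression of the eigengene on the trait plus the EWAS
    covariate set. Tier 3 (individual mode only): the trait coefficient
    in a model containing all ten indicators plus covariates. FDR within
    the family: BH for total_linear / total_categorical, Grenander
    q-values for individual.
    """
    from .ewas import exposure_terms

    traits = exposure_terms(mode)
    design = build_design(cohort, mode, cell_proportions=cell_proportions)
    X = design.matrix
    me = modules.eigengenes.loc[X.index]
    cols = list(X.columns)

    rows = []
    for mod in me.columns:
        y = me[mod].to_numpy()
        for trait in traits:
            t_vec = np.asarray(X[trait], dtype=float)
            r, p_biv = stats.pearsonr(t_vec, y)

            # adjusted: trait + covariates
            adj_cols = ["Intercept"] + design.covariate_columns + [trait]
            coef_a, se_a, p_a = _ols_term(X[adj_cols].to_numpy(), y, len(adj_cols) - 1)
            if mode == "individual":
                full_cols = ["Intercept"] + design.covariate_columns + traits
                j = full_cols.index(trait)
                coef_m, se_m, p_m = _ols_term(X[full_cols].to_numpy(), y, j)
            else:
                coef_m = se_m = p_m = np.nan
            rows.append(
                dict(
                    module=mod, trait=trait, pearson_r=float(r), p_bivariate=float(p_biv),
                    coef_adjusted=coef_a, se_adjusted=se_a, p_adjusted=p_a,
                    coef_mutual=coef_m, se_mutual=se_m, p_mutual=p_m,
                )
            )
    table = pd.DataFrame(rows)
    if len(table):
        if mode == "individual" and len(table) >= 10:
            q, eta0 = grenander_qvalues(table["p_bivariate"].to_numpy())
            table["q_bivariate"] = q
            table.attrs["eta0"] = eta0
            table.attrs["fdr_method"] = "grenander"
        else:
            table["q_bivariate"] = bh_fdr(table["p_bivariate"].to_numpy())
            table.attrs["fdr_method"] = "bh"
        table.attrs["family_size"] = len(table)
    return table


def _ols_term(X: np.ndarray, y: np.ndarray, j: int) -> tuple[float, float, float]:
    n, p = X.shape
    xtx_inv = np.linalg.pinv(X.T @ X)
    coef = xtx_inv @ X.T @ y
    resid = y - X @ coef
    rank = np.linalg.matrix_rank(X)
    df = n - rank
    if df < 1:
        raise ValueError("singular adjusted design")
    s2 = resid @ resid / df
    se = np.sqrt(s2 * xtx_inv[j, j])
    t = coef[j] / se
    pval = 2.0 * stats.t.sf(abs(t), df)
    return float(coef[j]), float(se), float(pval)
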