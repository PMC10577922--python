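"""Core containers and primitives: beta/M conversion, reference-based
cell-type deconvolution, and cohort descriptive statistics."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

from .config import ACE_NAMES

logger = logging.getLogger(__name__)

BETA_EPS = 1e-6


@dataclass
class MethylationMatrix:
    """CpG x sample methylation values with per-CpG genomic annotation.

    ``scale`` is either ``"beta"`` (fractions in (0,1)) or ``"M"``
    (log2-odds). Annotation positions are 1-based and must be strictly
    increasing within each chromosome.
    """

    values: np.ndarray
    scale: str
    cpg_annotation: pd.DataFrame  # index cpg_id; columns chrom, pos, gene, feature
    sample_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.scale not in ("beta", "M"):
            raise ValueError("scale must be 'beta' or 'M'")
        if len(self.cpg_annotation) != self.values.shape[0]:
            raise ValueError("annotation row count must equal matrix row count")
        if self.scale == "beta" and ((self.values <= 0).any() or (self.values >= 1).any()):
            raise ValueError("beta values must lie strictly in (0, 1)")
        for _, grp in self.cpg_annotation.groupby("chrom", sort=False):
            p = grp["pos"].to_numpy()
            if (np.diff(p) <= 0).any():
                raise ValueError("positions must be strictly increasing within chromosome")

    @property
    def cpg_ids(self) -> np.ndarray:
        return self.cpg_annotation.index.to_numpy()

    def to_m(self) -> "MethylationMatrix":
        if self.scale == "M":
            return self
        return MethylationMatrix(
            beta_to_m(self.values), "M", self.cpg_annotation, list(self.sample_ids)
        )

    def to_beta(self) -> "MethylationMatrix":
        if self.scale == "beta":
            return self
        return MethylationMatrix(
            m_to_beta(self.values), "beta", self.cpg_annotation, list(self.sample_ids)
        )


def beta_to_m(beta: np.ndarray) -> np.ndarray:
    """M = log2(beta / (1 - beta)), clipping beta into [eps, 1 - eps] first."""
    beta = np.asarray(beta, dtype=float)
    n_clip = int(np.sum((beta < BETA_EPS) | (beta > 1 - BETA_EPS)))
    if n_clip:
        logger.info("beta_to_m: clipped %d values to [%g, %g]", n_clip, BETA_EPS, 1 - BETA_EPS)
    b = np.clip(beta, BETA_EPS, 1 - BETA_EPS)
    return np.log2(b / (1.0 - b))


def m_to_beta(m: np.ndarray) -> np.ndarray:
    """Inverse of :func:`beta_to_m`: beta = 2^M / (1 + 2^M), strictly in (0,1)."""
    m = np.asarray(m, dtype=float)
    # numerically stable two-sided logistic
    out = np.empty_like(m, dtype=float)
    posm = m >= 0
    out[posm] = 1.0 / (1.0 + np.exp2(-m[posm]))
    e = np.exp2(m[~posm])
    out[~posm] = e / (1.0 + e)
    return np.clip(out, np.nextafter(0, 1), np.nextafter(1, 0))


def beta_m_convert(values: np.ndarray, direction: str) -> np.ndarray:
    """Convert between beta and M scales; ``direction`` is 'beta_to_m' or 'm_to_beta'."""
    if direction == "beta_to_m":
        return beta_to_m(values)
    if direction == "m_to_beta":
        return m_to_beta(values)
    raise ValueError("direction must be 'beta_to_m' or 'm_to_beta'")


def estimate_cell_proportions(
    sample_values: np.ndarray, reference: pd.DataFrame | np.ndarray
) -> pd.Series | np.ndarray:
    """Reference-based cell-composition estimate for one sample.

    Solves nonnegative least squares of the sample's marker-CpG values
    against the reference columns (one purified cell type each), then
    normalizes the weights to sum to one. Sample and reference must be on
    the same scale.
    """
    ref = reference.to_numpy() if isinstance(reference, pd.DataFrame) else np.asarray(reference)
    y = np.asarray(sample_values, dtype=float)
    if ref.shape[0] != len(y):
        raise ValueError("sample and reference marker counts differ")
    if ref.shape[0] < ref.shape[1]:
        raise ValueError(f"need at least {ref.shape[1]} marker CpGs")
    rank = np.linalg.matrix_rank(ref)
    if rank < ref.shape[1]:
        # name a minimal set of collinear columns for the error message
        cols = list(reference.columns) if isinstance(reference, pd.DataFrame) else list(range(ref.shape[1]))
        bad = [
            cols[j]
            for j in range(ref.shape[1])
            if np.linalg.matrix_rank(np.delete(ref, j, axis=1)) == rank
        ]
        raise ValueError(f"reference matrix is rank-deficient; collinear columns: {bad}")
    w, _ = optimize.nnls(ref, y)
    total = w.sum()
    if total <= 0:
        w = np.full(ref.shape[1], 1.0 / ref.shape[1])
    else:
        w = w / total
    if isinstance(reference, pd.DataFrame):
        return pd.Series(w, index=reference.columns)
    return w


def deconvolve_cohort(matrix: MethylationMatrix, reference: pd.DataFrame) -> pd.DataFrame:
    """Per-sample deconvolution of a cohort matrix on the M scale."""
    m = matrix.to_m()
    common = reference.index.intersection(m.cpg_annotation.index)
    if len(common) < reference.shape[1]:
        raise ValueError("too few marker CpGs shared with the matrix")
    row_idx = m.cpg_annotation.index.get_indexer(common)
    sub = m.values[row_idx]
    ref = reference.loc[common]
    out = np.stack(
        [estimate_cell_proportions(sub[:, j], ref).to_numpy() for j in range(sub.shape[1])]
    )
    return pd.DataFrame(out, index=matrix.sample_ids, columns=reference.columns)


def odds_ratio_2x2(a: float, b: float, c: float, d: float) -> tuple[float, float, float, bool]:
    """OR and Woolf 95% CI for a 2x2 table; Haldane-Anscombe +0.5 when any cell is 0."""
    corrected = min(a, b, c, d) == 0
    if corrected:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    or_ = (a * d) / (b * c)
    se = np.sqrt(1.0 / a + 1.0 / b + 1.0 / c + 1.0 / d)
    lo = float(np.exp(np.log(or_) - 1.959963984540054 * se))
    hi = float(np.exp(np.log(or_) + 1.959963984540054 * se))
    return float(or_), lo, hi, corrected


def pairwise_ace_odds_ratios(cohort: pd.DataFrame, ace_names=ACE_NAMES) -> pd.DataFrame:
    """All pairwise odds ratios among binary ACE indicators.

    Returns a long-format table (ace_a, ace_b, or, ci_lo, ci_hi, corrected,
    reason) with one row per unordered pair plus the diagonal reported as
    missing; the implied square matrix is symmetric.
    """
    rows = []
    for i, na in enumerate(ace_names):
        for j, nb in enumerate(ace_names):
            if j < i:
                continue
            if i == j:
                rows.append(
                    dict(ace_a=na, ace_b=nb, odds_ratio=np.nan, ci_lo=np.nan, ci_hi=np.nan,
                         corrected=False, reason="diagonal")
                )
                continue
            xa = np.asarray(cohort[na], dtype=int)
            xb = np.asarray(cohort[nb], dtype=int)
            if xa.min() == xa.max() or xb.min() == xb.max():
                const = na if xa.min() == xa.max() else nb
                rows.append(
                    dict(ace_a=na, ace_b=nb, odds_ratio=np.nan, ci_lo=np.nan, ci_hi=np.nan,
                         corrected=False, reason=f"constant column {const}")
                )
                continue
            a = int(np.sum((xa == 1) & (xb == 1)))
            b = int(np.sum((xa == 1) & (xb == 0)))
            c = int(np.sum((xa == 0) & (xb == 1)))
            d = int(np.sum((xa == 0) & (xb == 0)))
            or_, lo, hi, corrected = odds_ratio_2x2(a, b, c, d)
            rows.append(
                dict(ace_a=na, ace_b=nb, odds_ratio=or_, ci_lo=lo, ci_hi=hi,
                     corrected=corrected, reason="")
            )
    return pd.DataFrame(rows)


def ace_category_percentages(category_counts: dict[str, int]) -> dict[str, float]:
    """Percentage breakdown of total-ACE categories from raw counts."""
    total = sum(category_counts.values())
    if total == 0:
        raise ValueError("empty category counts")
    return {k: 100.0 * v / total for k, v in category_counts.items()}
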