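"""Synthetic cohort and methylome generators with known planted structure.

The cohort generator draws ten binary adversity indicators from a Gaussian
copula whose per-pair latent correlations are calibrated by root finding so
that realized pairwise odds ratios land in a target range, with covariates
drawn independently from normal/categorical approximations of the modeled
cohort's summary statistics.

The methylome generator composes, per CpG and sample on the M-value
(log2-odds) scale: a cell-type mixture of CpG-specific baselines, planted
exposure effects (single positions, contiguous regions, and latent-factor
co-methylation modules), a small additive batch shift, and heteroscedastic
Gaussian noise. Beta values are the inverse-M transform and therefore lie
strictly in (0, 1). Everything planted is recorded in a TruthRecord.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .config import ACE_NAMES, CohortConfig, MethylomeConfig
from .core import MethylationMatrix, m_to_beta

__all__ = [
    "TruthRecord",
    "simulate_cohort",
    "simulate_methylome",
    "calibrate_latent_correlation",
]


@dataclass
class TruthRecord:
    """Ground truth of a generated methylome, aligned to the matrix rows/samples."""

    is_null: np.ndarray  # bool per CpG: no planted exposure effect
    effects: pd.DataFrame  # columns: cpg_id, kind, exposure, effect
    module_labels: np.ndarray  # str per CpG; "" = no planted module
    cell_proportions: pd.DataFrame  # samples x cell types
    noise_sd: np.ndarray = field(default=None)  # per-CpG residual SD

    def __post_init__(self) -> None:
        if len(self.is_null) != len(self.module_labels):
            raise ValueError("truth arrays misaligned")


# ---------------------------------------------------------------------------
# cohort


def _joint_prob_from_or(p1: float, p2: float, psi: float) -> float:
    """P(both = 1) for margins p1, p2 and odds ratio psi (2x2 table algebra)."""
    if psi == 1.0:
        return p1 * p2
    a = psi - 1.0
    b = -(1.0 + (psi - 1.0) * (p1 + p2))
    c = psi * p1 * p2
    disc = b * b - 4.0 * a * c
    p11 = (-b - np.sqrt(disc)) / (2.0 * a)
    lo, hi = max(0.0, p1 + p2 - 1.0), min(p1, p2)
    if not (lo - 1e-12 <= p11 <= hi + 1e-12):
        p11 = (-b + np.sqrt(disc)) / (2.0 * a)
    return float(np.clip(p11, lo, hi))


def calibrate_latent_correlation(p1: float, p2: float, target_or: float) -> float:
    """Latent Gaussian correlation reproducing a pairwise odds ratio.

    Solves, by root finding on the bivariate-normal cross probability,
    for the correlation r such that thresholding standard normals at the
    (1 - p) quantiles yields P(both exceed) matching the 2x2 cell implied
    by the margins and the target odds ratio.
    """
    p11_target = _joint_prob_from_or(p1, p2, target_or)
    t1 = stats.norm.ppf(1.0 - p1)
    t2 = stats.norm.ppf(1.0 - p2)

    def cross_prob(r: float) -> float:
        cov = np.array([[1.0, r], [r, 1.0]])
        # survival probability P(Z1 > t1, Z2 > t2) by symmetry of the BVN
        return stats.multivariate_normal(mean=[0.0, 0.0], cov=cov, allow_singular=True).cdf(
            [-t1, -t2]
        )

    f = lambda r: cross_prob(r) - p11_target
    lo, hi = -0.999, 0.999
    flo, fhi = f(lo), f(hi)
    if flo * fhi > 0:
        raise ValueError(
            f"no latent correlation in [-0.999, 0.999] achieves OR={target_or:g} "
            f"for prevalences ({p1:g}, {p2:g})"
        )
    return float(optimize.brentq(f, lo, hi, xtol=1e-10))


def _nearest_corr(R: np.ndarray) -> np.ndarray:
    """Eigenvalue-clipped PSD repair, rescaled to unit diagonal."""
    w, V = np.linalg.eigh(R)
    if w.min() >= 1e-10:
        return R
    w = np.clip(w, 1e-10, None)
    R2 = V @ np.diag(w) @ V.T
    d = np.sqrt(np.diag(R2))
    return R2 / np.outer(d, d)


def _draw_numeric(rng: np.random.Generator, n: int, spec: dict) -> np.ndarray:
    x = rng.normal(spec["mean"], spec["sd"], size=n)
    if "min" in spec:
        x = np.clip(x, spec["min"], None)
    return x


def simulate_cohort(config: CohortConfig) -> pd.DataFrame:
    """Generate a sample x (covariates + ACE indicators) table.

    Returns one row per sample with covariate columns, the ten binary ACE
    columns, the total ACE count, and derived 0 / 1-3 / 4-10 category
    encodings (``ace_cat`` plus the two indicator columns used by the
    categorical exposure specification).
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_samples
    prev = np.asarray(config.ace_prevalences, dtype=float)
    k = len(prev)

    # target odds ratios, log-uniform in the configured range
    lo, hi = config.ace_or_range
    R = np.eye(k)
    active = prev > 0
    for i in range(k):
        for j in range(i + 1, k):
            target = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
            if active[i] and active[j]:
                R[i, j] = R[j, i] = calibrate_latent_correlation(prev[i], prev[j], target)
    R = _nearest_corr(R)

    thresholds = stats.norm.ppf(1.0 - np.clip(prev, 1e-12, 1 - 1e-12))
    Z = rng.multivariate_normal(np.zeros(k), R, size=n, method="cholesky")
    aces = (Z > thresholds).astype(np.int64)
    aces[:, ~active] = 0

    data: dict[str, np.ndarray | pd.Series] = {}
    for name, spec in config.covariate_distributions.items():
        if "levels" in spec:
            levels = list(spec["levels"])
            draws = rng.choice(len(levels), size=n, p=np.asarray(spec["probs"], float))
            data[name] = pd.Categorical.from_codes(draws, categories=levels)
        else:
            data[name] = _draw_numeric(rng, n, spec)

    cohort = pd.DataFrame(data, index=[f"S{i:04d}" for i in range(n)])
    for j, name in enumerate(ACE_NAMES):
        cohort[name] = aces[:, j]
    total = aces.sum(axis=1)
    cohort["total_aces"] = total
    cat = np.where(total == 0, "0", np.where(total <= 3, "1-3", "4-10"))
    cohort["ace_cat"] = pd.Categorical(cat, categories=["0", "1-3", "4-10"])
    cohort["ace_1_3"] = (cat == "1-3").astype(np.int64)
    cohort["ace_4_10"] = (cat == "4-10").astype(np.int64)
    cohort.index.name = "sample_id"
    return cohort


# ---------------------------------------------------------------------------
# methylome


def _layout_positions(
    config: MethylomeConfig, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, dict[str, np.ndarray]]:
    """Chromosome labels and 1-based positions, with planted regions inserted.

    Background inter-CpG gaps are exponential with mean ``position_spacing``;
    planted region CpGs sit on a fixed 150-bp grid starting at the requested
    position so that the whole region falls within the DMR caller's gap rule.
    """
    chroms = [f"chr{i + 1}" for i in range(config.n_chromosomes)]
    dmr_sizes = sum(r[2] for r in config.planted_dmrs)
    n_background = config.n_cpgs - dmr_sizes

    per_chrom = np.full(config.n_chromosomes, n_background // config.n_chromosomes)
    per_chrom[: n_background % config.n_chromosomes] += 1

    chrom_col: list[str] = []
    pos_col: list[np.ndarray] = []
    planted_pos: dict[str, np.ndarray] = {}
    for c_idx, chrom in enumerate(chroms):
        gaps = rng.exponential(config.position_spacing, size=per_chrom[c_idx])
        pos = 10_000 + np.cumsum(np.maximum(1, np.round(gaps))).astype(np.int64)
        for r_i, (r_chrom, start, n_r, _, _) in enumerate(config.planted_dmrs):
            if r_chrom != chrom:
                continue
            rpos = start + 150 * np.arange(n_r, dtype=np.int64)
            planted_pos[f"dmr{r_i}"] = rpos
            pos = np.concatenate([pos, rpos])
        pos = np.unique(pos)  # sorted, strictly increasing
        chrom_col.extend([chrom] * len(pos))
        pos_col.append(pos)
    return np.array(chrom_col), np.concatenate(pos_col), planted_pos


def _make_annotation(chrom: np.ndarray, pos: np.ndarray, rng: np.random.Generator) -> pd.DataFrame:
    n = len(pos)
    features = np.array(["TSS200", "TSS1500", "5'UTR", "1st Exon", "Body", "3'UTR", ""])
    gene_block = 10  # consecutive CpGs share a gene label, ~20% intergenic
    genes = np.array([f"GENE{i // gene_block:04d}" for i in range(n)], dtype=object)
    intergenic = rng.random(n) < 0.2
    genes[intergenic] = ""
    ann = pd.DataFrame(
        {
            "chrom": chrom,
            "pos": pos,
            "gene": genes,
            "feature": rng.choice(features, size=n),
        },
        index=[f"cg{i:07d}" for i in range(n)],
    )
    ann.index.name = "cpg_id"
    return ann


def _exposure_vector(cohort: pd.DataFrame, exposure: str) -> np.ndarray:
    if exposure not in cohort.columns:
        raise ValueError(f"planted effect references unknown exposure {exposure!r}")
    v = cohort[exposure]
    if isinstance(v.dtype, pd.CategoricalDtype):
        raise ValueError(f"exposure {exposure!r} is categorical; plant on an indicator column")
    return np.asarray(v, dtype=float)


def simulate_methylome(
    cohort: pd.DataFrame, config: MethylomeConfig
) -> tuple[MethylationMatrix, pd.DataFrame, TruthRecord]:
    """Generate a CpG x sample beta matrix, marker reference profiles, and truth.

    Returns the matrix on the beta scale, a marker-CpG x cell-type reference
    profile table on the M scale (for reference-based deconvolution), and
    the TruthRecord of all planted structure.
    """
    if len(cohort) == 0:
        raise ValueError("cohort is empty")
    rng = np.random.default_rng(config.seed)
    n_samples = len(cohort)
    n_cell = len(config.cell_types)

    chrom, pos, _ = _layout_positions(config, rng)
    n_cpgs = len(pos)
    ann = _make_annotation(chrom, pos, rng)
    cpg_ids = ann.index.to_numpy()

    # per-sample cell proportions: Dirichlet centered on the reference mix
    alpha = np.asarray(config.reference_composition, float) * config.dirichlet_concentration
    props = rng.dirichlet(alpha, size=n_samples)
    cell_props = pd.DataFrame(props, index=cohort.index, columns=list(config.cell_types))

    # cell-type-specific baseline logits; marker CpGs get a wide spread so
    # that deconvolution has informative loci
    mu = rng.normal(0.0, config.baseline_sd, size=n_cpgs)
    spread = np.full(n_cpgs, config.cell_spread)
    n_marker = min(config.n_marker_cpgs, n_cpgs)
    marker_idx = rng.choice(n_cpgs, size=n_marker, replace=False)
    spread[marker_idx] = config.marker_cell_spread
    baselines = mu[:, None] + rng.normal(0.0, 1.0, size=(n_cpgs, n_cell)) * spread[:, None]

    M = props @ baselines.T  # samples x CpGs, mixed on the logit scale
    M = M.T.copy()  # CpGs x samples

    # planted exposure effects
    is_null = np.ones(n_cpgs, dtype=bool)
    effect_rows: list[dict] = []
    pos_by_chrom = {c: np.flatnonzero(chrom == c) for c in np.unique(chrom)}

    for idx, exposure, eff in config.planted_dmps:
        x = _exposure_vector(cohort, exposure)
        M[idx] += eff * x
        is_null[idx] = False
        effect_rows.append({"cpg_id": cpg_ids[idx], "kind": "dmp", "exposure": exposure, "effect": eff})

    for r_chrom, start, n_r, exposure, eff in config.planted_dmrs:
        x = _exposure_vector(cohort, exposure)
        rows = pos_by_chrom[r_chrom]
        rpos = start + 150 * np.arange(n_r, dtype=np.int64)
        sel = rows[np.isin(pos[rows], rpos)]
        M[sel] += eff * x
        is_null[sel] = False
        for s in sel:
            effect_rows.append(
                {"cpg_id": cpg_ids[s], "kind": "dmr", "exposure": exposure, "effect": eff}
            )

    # heteroscedastic residual SDs: scaled inverse-chi-square prior
    d0 = config.noise_prior_df
    sigma = config.noise_sd * np.sqrt(d0 / rng.chisquare(d0, size=n_cpgs))

    # planted co-methylation modules: latent factor shared within the module,
    # optionally tied to a trait; within-module residual correlation loading^2
    module_labels = np.full(n_cpgs, "", dtype=object)
    free = np.flatnonzero(is_null)
    free = free[~np.isin(free, marker_idx)]
    rng.shuffle(free)
    cursor = 0
    noise = rng.normal(size=(n_cpgs, n_samples))
    for m_i, (size, loading, trait, eff) in enumerate(config.planted_modules):
        members = np.sort(free[cursor : cursor + size])
        cursor += size
        name = f"module{m_i}"
        module_labels[members] = name
        f = rng.normal(size=n_samples)
        if trait:
            t = _exposure_vector(cohort, trait)
            t_std = (t - t.mean()) / (t.std() if t.std() > 0 else 1.0)
            eff = float(np.clip(eff, -0.999, 0.999))
            f = eff * t_std + np.sqrt(1.0 - eff**2) * f
        lam = float(np.clip(loading, 0.0, 0.999))
        noise[members] = lam * f + np.sqrt(1.0 - lam**2) * noise[members]

    # batch nuisance: small additive shift per (CpG, batch), not removed later
    if config.batch_levels > 1 and config.batch_sd > 0:
        batch = rng.integers(config.batch_levels, size=n_samples)
        shifts = rng.normal(0.0, config.batch_sd, size=(n_cpgs, config.batch_levels))
        M += shifts[:, batch]

    M += sigma[:, None] * noise

    beta = m_to_beta(M)
    matrix = MethylationMatrix(
        values=beta, scale="beta", cpg_annotation=ann, sample_ids=list(cohort.index)
    )
    reference = pd.DataFrame(
        baselines[np.sort(marker_idx)],
        index=cpg_ids[np.sort(marker_idx)],
        columns=list(config.cell_types),
    )
    reference.index.name = "cpg_id"
    truth = TruthRecord(
        is_null=is_null,
        effects=pd.DataFrame(effect_rows, columns=["cpg_id", "kind", "exposure", "effect"]),
        module_labels=np.asarray(module_labels),
        cell_proportions=cell_props,
        noise_sd=sigma,
    )
    return matrix, reference, truth
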