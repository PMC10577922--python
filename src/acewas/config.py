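"""Configuration objects for the synthetic cohort/methylome generators and pipeline runs.

Defaults encode the study conditions of a cord-blood EWAS cohort of 196
mother/newborn pairs: ten binary adverse-childhood-experience (ACE)
indicators with strong positive pairwise association, a priori covariates
(newborn sex and gestational age, maternal parity, BMI, age, education,
smoking, marital status), and a seven-cell-type cord-blood mixture.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Any

import yaml

ACE_NAMES: tuple[str, ...] = (
    "emotional_abuse",
    "physical_abuse",
    "sexual_abuse",
    "emotional_neglect",
    "physical_neglect",
    "domestic_violence",
    "substance_abuse",
    "mental_illness",
    "incarceration",
    "parental_divorce",
)

#: Observed per-indicator prevalences in the modeled cohort (N = 196).
ACE_PREVALENCES: tuple[float, ...] = (
    0.219, 0.240, 0.138, 0.224, 0.158, 0.168, 0.204, 0.097, 0.087, 0.214,
)

CELL_TYPES: tuple[str, ...] = ("CD8T", "CD4T", "NK", "B", "Mono", "Gran", "nRBC")

#: Reference cord-blood composition (mean estimated proportions): CD8+ T,
#: CD4+ T, NK, B, monocytes, granulocytes, nucleated red blood cells.
REFERENCE_CELL_COMPOSITION: tuple[float, ...] = (
    0.0912, 0.1894, 0.0073, 0.1833, 0.1092, 0.4063, 0.0133,
)

EDUCATION_LEVELS: tuple[str, ...] = ("6th_grade_or_lower", "7-12th_grade", "high_school_graduate")
MARITAL_LEVELS: tuple[str, ...] = ("married", "living_as_married", "separated", "divorced", "single")
SEX_LEVELS: tuple[str, ...] = ("female", "male")
SMOKING_LEVELS: tuple[str, ...] = ("never", "ever")


def _default_covariates() -> dict[str, Any]:
    # Location/scale for numeric covariates, category probabilities otherwise.
    return {
        "sex": {"levels": list(SEX_LEVELS), "probs": [0.520, 0.480]},
        "gestational_age_days": {"mean": 273.36, "sd": 10.5},
        "parity": {"mean": 1.19, "sd": 1.1, "min": 0.0},
        "bmi": {"mean": 27.2, "sd": 5.1, "min": 14.0},
        "maternal_age": {"mean": 25.73, "sd": 4.8, "min": 15.0},
        "education": {"levels": list(EDUCATION_LEVELS), "probs": [0.408, 0.403, 0.189]},
        "smoking": {"levels": list(SMOKING_LEVELS), "probs": [0.959, 0.041]},
        "marital_status": {"levels": list(MARITAL_LEVELS), "probs": [0.434, 0.388, 0.036, 0.015, 0.127]},
    }


@dataclass
class CohortConfig:
    """Parameters of the synthetic cohort generator.

    ``ace_or_range`` gives the interval of target pairwise odds ratios
    between ACE indicators; each pair's target is drawn log-uniformly from
    it and realized through a Gaussian-copula threshold model.
    """

    n_samples: int = 196
    ace_prevalences: tuple[float, ...] = ACE_PREVALENCES
    ace_or_range: tuple[float, float] = (3.4, 51.4)
    covariate_distributions: dict[str, Any] = field(default_factory=_default_covariates)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 2:
            raise ValueError("n_samples must be >= 2")
        if len(self.ace_prevalences) != 10:
            raise ValueError("exactly 10 ACE prevalences required")
        if not all(0.0 <= p < 1.0 for p in self.ace_prevalences):
            raise ValueError("ACE prevalences must lie in [0, 1)")
        lo, hi = self.ace_or_range
        if lo < 1.0 or hi < lo:
            raise ValueError("ace_or_range must satisfy 1 <= lower <= upper")


@dataclass
class MethylomeConfig:
    """Parameters of the synthetic methylome generator.

    All planted effects are on the M-value (log2-odds) scale. ``noise_sd``
    is the prior scale of per-CpG residual SDs; per-CpG variances are drawn
    from a scaled inverse-chi-square so that residual variances are
    heteroscedastic across CpGs, as on real arrays.
    """

    n_cpgs: int = 5000
    n_chromosomes: int = 3
    position_spacing: float = 300.0
    cell_types: tuple[str, ...] = CELL_TYPES
    reference_composition: tuple[float, ...] = REFERENCE_CELL_COMPOSITION
    dirichlet_concentration: float = 80.0
    n_marker_cpgs: int = 200
    marker_cell_spread: float = 2.0
    cell_spread: float = 0.25
    baseline_sd: float = 2.0
    planted_dmps: list[tuple[int, str, float]] = field(default_factory=list)
    planted_dmrs: list[tuple[str, int, int, str, float]] = field(default_factory=list)
    planted_modules: list[tuple[int, float, str, float]] = field(default_factory=list)
    noise_sd: float = 1.0
    noise_prior_df: float = 4.0
    batch_levels: int = 2
    batch_sd: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        planted = sum(r[2] for r in self.planted_dmrs) + sum(s for s, *_ in self.planted_modules)
        if self.n_cpgs < planted + len(self.planted_dmps):
            raise ValueError("n_cpgs smaller than the total planted structure")
        for _, _, eff in self.planted_dmps:
            if not abs(eff) < float("inf"):
                raise ValueError("planted effects must be finite")
        if len(self.reference_composition) != len(self.cell_types):
            raise ValueError("reference composition length must match cell types")


@dataclass
class RunConfig:
    """End-to-end pipeline configuration; defaults match the published analysis."""

    cohort: CohortConfig = field(default_factory=CohortConfig)
    methylome: MethylomeConfig = field(default_factory=MethylomeConfig)
    specs: tuple[str, ...] = ("total_linear", "total_categorical", "individual")
    dmr_max_gap: int = 1000
    dmr_seed_p: float = 1e-3
    dmr_min_cpgs: int = 3
    network_min_module_size: int = 30
    network_merge_threshold: float = 0.75
    n_draws: int = 3000
    n_top_contrasts: int = 5
    master_seed: int = 0
    out_dir: str = "acewas_run"

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cohort = CohortConfig(**_tupled(raw.pop("cohort", {})))
        methylome = MethylomeConfig(**_tupled(raw.pop("methylome", {})))
        raw = _tupled(raw)
        return cls(cohort=cohort, methylome=methylome, **raw)


def _tupled(d: dict[str, Any]) -> dict[str, Any]:
    """YAML round-trips tuples as lists; restore tuples for dataclass fields."""
    out = {}
    for k, v in d.items():
        if isinstance(v, list) and k not in ("planted_dmps", "planted_dmrs", "planted_modules"):
            out[k] = tuple(v)
        elif isinstance(v, list):
            out[k] = [tuple(item) for item in v]
        else:
            out[k] = v
    return out
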