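# Methods

`acewas` reimplements, as a tested library, the statistical chain of an
epigenome-wide association study (EWAS) linking a mother's preconception
adversity burden to her newborn's cord-blood DNA methylation. The cohort
data behind such studies are typically not shareable, so the package pairs
every analysis stage with a synthetic-data generator that reproduces the
statistical structure the analysis assumes; all calibration and power
claims in the test suite refer to that generator, and what that does and
does not imply about real data is spelled out below.

## The synthetic cohort

Ten binary adverse-childhood-experience (ACE) indicators are drawn from a
Gaussian copula threshold model. Each indicator i has marginal prevalence
p_i (defaults: the ten observed prevalences of the modeled cohort,
0.087–0.240, N = 196). For each pair (i, j), a target odds ratio is drawn
log-uniformly from `ace_or_range` (default 3.4–51.4, the printed range of
realized pairwise odds ratios), converted to the joint success probability
by solving the 2×2 margin equations, and then to a latent correlation by
Brent root finding on the bivariate-normal cross probability. The
assembled correlation matrix is repaired to the nearest positive
semidefinite correlation matrix by eigenvalue clipping when needed. An
infeasible prevalence/odds-ratio combination raises an error naming the
pair.

Covariates are drawn independently, as normal or categorical
approximations of the cohort's summary statistics: newborn sex (48% male),
gestational age in days (273.36 ± 10.5 — the weekly-resolution SD of 1.5
weeks converted to days), parity (1.19 ± 1.1, floored at 0), pre-pregnancy
BMI (27.2 ± 5.1), maternal age (25.73 ± 4.8), education (40.8 / 40.3 /
18.9% across three levels), smoking during pregnancy (4.1% ever), and
marital status (43.4 / 38.8 / 3.6 / 1.5 / 12.7%). The distributional
choices beyond the published mean/SD/frequency summaries are the
generator's own. Derived columns give the total ACE count and its 0 /
1–3 / 4–10 categorization.

## The synthetic methylome

Methylation is generated on the M-value scale (log2 odds of methylation)
and returned as beta values via the inverse transform, so values are
strictly inside (0, 1). Per sample, seven cell-type proportions are drawn
from a Dirichlet centered on the published mean cord-blood composition
(CD8T 9.12%, CD4T 18.94%, NK 0.73%, B 18.33%, Mono 10.92%, Gran 40.63%,
nRBC 1.33%) with concentration 80 (per-type SD roughly 1–5 percentage
points). Per CpG, cell-type-specific baseline logits are drawn around a
CpG-level mean (SD 2.0, covering the hypo/hyper-methylated range); a
configurable subset of "marker" CpGs receives a wider between-cell spread
(SD 2.0 vs 0.25) so reference-based deconvolution has informative loci.
The sample signal mixes cell baselines linearly on the logit scale — a
deliberate simplification (real mixtures combine on the beta scale) that
makes the linear model exactly correct and the deconvolution problem
exactly linear on the modeling scale.

Planted structure, all in M-value units per unit of exposure:
single-CpG effects, contiguous regions (CpGs on a 150-bp grid from the
requested start, within the region caller's 1000-bp gap rule), and
co-methylation modules driven by a shared latent factor with loading λ
(within-module residual correlation λ²), optionally tied to a trait.
Residual noise is Gaussian with per-CpG SDs drawn from a scaled
inverse-chi-square (prior df 4, scale `noise_sd` = 1.0) — exactly the
sampling model the empirical-Bayes moderation assumes, and a realistic
heteroscedasticity level for 450K-style M-values. Batch is a small
additive logit shift (SD 0.1, two levels) that is *not* modeled
downstream: it emulates residual technical noise after upstream batch
removal and is deliberately left as unmodeled nuisance realism.

What the generator does not emulate: probe chemistry and type-I/II
effects, detection failures, spatial correlation of null CpGs (background
CpGs are independent given cell composition), skewed/multimodal beta
distributions beyond what the logit-normal produces, and genuine biological
co-methylation beyond planted modules. Passing calibration and power
tests therefore demonstrate correctness of the statistical machinery under
its own assumptions, not performance on real arrays.

## EWAS on M-values with moderated variances

For each exposure specification — total count (linear), total count
categorized (1–3 vs 0 and 4–10 vs 0, with the 4–10 vs 1–3 contrast
derived), and the ten indicators mutually adjusted — each CpG's M-values
are regressed on the exposure terms plus the a-priori covariate set:
newborn sex, gestational age, maternal parity, BMI, age, education,
smoking, marital status, and six of the seven estimated cell proportions
(granulocytes, the largest fraction, is the reference component).
Categorical covariates are dummy-coded against the cohort's modal levels
(female; married; never-smoked; lowest education), so the intercept is
interpretable as the reference individual's logit methylation. Unobserved
categorical levels are dropped from the design with a log message; a
genuinely constant exposure or numeric covariate is an error. Variance
inflation factors are reported for every non-intercept column.

Coefficients are ordinary least squares. Residual variances s²_g (df d)
are modeled as scaled F draws about a prior (d₀, s₀²) estimated by moment
matching on the log scale: the excess of Var(log s²_g) over trigamma(d/2)
identifies d₀ through trigamma inversion (Newton iteration), and the mean
identifies s₀². Posterior variances are the precision-weighted blend
(d₀s₀² + d s²_g)/(d₀ + d); moderated t statistics use them with d + d₀
degrees of freedom. Two limits are handled exactly: a single CpG gets no
shrinkage (d₀ = 0, ordinary t), and when the log-variances show no excess
spread d₀ is infinite and the posterior is the pooled mean of s² — so the
moderated t is then exactly the pooled-variance t.

Methylation odds ratios are 2^coef (M-values are log2 odds, so an
exposure adds `coef` to the log2 odds). Genomic inflation λ is the median
association chi-square over its null median (0.4549). Storey q-values
estimate π₀ on the λ-grid 0.05…0.95 with a cubic smoothing spline
evaluated at 0.95 (fixed at 1 below 100 p-values, where the smoother is
unstable), then apply the adaptive step-up with a cumulative minimum. One
multiplicity family per specification, never pooled across
specifications.

## Monte-Carlo reference-individual contrasts

A reference individual is the design row with numeric covariates at their
means, categoricals at their modes (ties resolved toward the first
declared level and logged), and exposures at zero. The exposed row
increments the total count by one (linear specification) or sets exactly
one indicator to 1. The percent-methylation difference

δ = invlogit(θ·X₁) − invlogit(θ·X₀)

is reported ×100 with percentile intervals from 3000 draws of the
coefficient vector from N(θ̂, Σ̂), where Σ̂ is the moderated residual
variance times (XᵀX)⁻¹ (Cholesky with escalating jitter from 1e-10 if Σ̂
is numerically semidefinite, logged). Because models are fit on log2 odds
while the inverse logit is natural-base, coefficients are multiplied by
ln 2 before the natural-logit equations — invlogit(ln2·M) is identically
the beta value, so δ is invariant to which base carries the coefficients
as long as it is declared (`scale="m"` vs `"natural"`, unit-tested).
Percentile (not normal-approximation) intervals are reported; they
converge to the delta-method interval as Σ̂ → 0 (tested at 1e-6 scale).
Measured coverage of the 95% interval is ≈94.7%.

## Distance-aware DMR calling

The region chain follows the comb-p family. (1) The autocorrelation of
probit scores z = Φ⁻¹(1−p) is estimated in distance bins (default 50 bp
wide out to the 1000-bp maximum gap), pooled over chromosomes; bins with
fewer than 10 pairs inherit their neighbor, and negative correlations are
truncated to 0. (2) Each CpG's p-value is smoothed by a Stouffer–Liptak
combination with all neighbors within the gap, with the combined variance
1ᵀC1 taken from the binned correlations (nearest-PSD repair by eigenvalue
clipping when a window's matrix is indefinite; p clipped to
[1e-300, 1−1e-16]). (3) The seed value 1e-3 is applied as a
Benjamini–Hochberg FDR level on the smoothed p-values — the cited
procedure describes its seed as an FDR threshold for initial selection —
and passing CpGs within the gap of one another are merged into maximal
candidate regions. A raw-threshold mode is retained for the low-level
API. (4) Each region is scored by Stouffer–Liptak over the raw p-values
of *every* CpG in its span (not only the seeds, avoiding selection bias),
with ACF-derived correlation, then Šidák-corrected:
1 − (1−p)^(total span / region width), where the total testable span sums
(last − first position + gap) per chromosome. Calls require ≥3 CpGs and
Šidák p ≤ 0.05; a per-region coefficient-sign agreement fraction is
reported for inspection but never filtered on.

The FDR-based seeding matters: with a raw smoothed-p threshold the chain
reproduces the anticonservatism comb-p is known for (measured ≈20% of
fully null genomes yielding a spurious Šidák-significant call); with FDR
seeding, null genomes produce no calls in 20/20 seeds while a planted
5-CpG region of unit logit effect is recovered in 50/50.

## Co-methylation networks

Unsigned adjacency |cor|^β between CpG M-value profiles; the soft power β
is the smallest candidate whose connectivity distribution fits a
power law with R² ≥ 0.8 (log-frequency on log-mean-connectivity over 10
equal-width connectivity bins), falling back with a warning to the best
R² when none passes. The topological overlap matrix augments adjacency
with shared neighborhood, TOMᵢⱼ = (Σᵤaᵢᵤaᵤⱼ + aᵢⱼ)/(min(kᵢ,kⱼ)+1−aᵢⱼ).

Modules come from average-linkage clustering of 1 − TOM with a
deterministic adaptive static cut: among candidate cut heights (the
dendrogram's merge heights, subsampled to ≤256), choose the cut
maximizing the number of branches of at least `min_size` (default 30)
CpGs, then the number of CpGs in such branches, then the lowest height.
Branches below the minimum go to "grey" (unassigned); modules whose
eigengenes correlate above 0.75 are merged iteratively; and members whose
|kME| < 0.3 are released to grey, dissolving modules that fall below the
minimum. This replaces the dynamic-hybrid tree cut with something fully
deterministic; a plain static cut at a fixed height quantile was tried
first and collapses planted blocks into one branch, because
average-linkage merge heights are strongly bimodal. Modules with more
than half their CpGs on chrX/chrY are flagged and excluded from
downstream testing.

A module eigengene is the first principal-component score over samples of
the module's standardized CpG profiles, sign-aligned to correlate
positively with the module's mean profile and scaled to unit variance;
representativeness is the first-eigenvalue share of variance (percent)
and the median |kME|. Module–trait association runs in three tiers:
bivariate Pearson correlation; a covariate-adjusted regression with the
EWAS covariate set; and, for individual indicators, a mutually adjusted
model with all ten. FDR is estimated only for the bivariate family —
BH for the total-count specifications, and for the individual-indicator
family a Grenander q-value: the least concave majorant of the p-value
ECDF gives a decreasing density estimate; the null proportion η₀ is that
density evaluated at p = 0.95 (the terminal slope itself is an extremely
noisy estimator — observed anywhere in 0.2–0.96 on uniform inputs — while
the density at 0.95 sits in [0.92, 1.0] across seeds); q = η₀·p/F̂(p)
with a cumulative minimum.

## Probe-bias-corrected enrichment

A gene is "selected" when any of its CpGs is selected, so genes carrying
more probes are selected more often by chance. The null distribution of
the set overlap is Wallenius noncentral hypergeometric sampling of the
observed number of selected genes with per-gene odds proportional to CpG
count. Universes small enough to enumerate (≤2000 gene subsets) are
evaluated exactly by numerical integration of the distribution's defining
integral for each subset; larger universes use the standard two-odds
approximation (mean in-set vs mean out-of-set weight) through SciPy's
univariate Wallenius distribution, as the reference enrichment tools do.
With equal weights both routes reduce to the central hypergeometric.
Multi-gene CpGs count toward every annotated gene by default
(`multi_gene="first"` restricts to the first). BH FDR per collection;
sets with FDR ≤ 0.05 are flagged.

## Orchestration and reproducibility

`run_pipeline` chains simulate → deconvolve → descriptives → three EWAS →
Q–Q/λ → Monte-Carlo contrasts for top hits → DMR calling per term →
network/modules/ME tests → enrichment → replication look-up (count of
external CpGs at nominal p < 0.05 per model and term, missing CpGs
reported separately), writing TSVs with parameter header comments and a
JSON manifest. One master seed derives per-stage seeds by CRC32 hashing
of the stage name, so reruns are bit-identical. Report coordinates are
1-based inclusive; BED-like files on disk are 0-based half-open, with the
conversion centralized in the I/O module. Desk-scale defaults (5000 CpGs
across 3 chromosomes, 300-bp mean spacing, 196 samples; networks on at
most 4000 CpGs in a single block) keep a full run under a minute; the
blockwise processing an array-scale analysis would need is out of scope.

## Known limitations

- The adaptive static cut and kME prune are simpler than dynamic-hybrid
  tree cutting; fragmented or nested modules may be merged or greyed.
- The two-odds Wallenius approximation ignores weight heterogeneity
  within the set beyond its mean, like the tools it mirrors.
- Deconvolution assumes the reference profiles are on the same scale as
  the mixture and noise-free; it is validated on the generator's
  logit-linear mixtures, not on real purified references.
- The smoothing/seeding chain controls family-wise spurious region calls
  on independent-null genomes; correlated null structure (e.g., unmodeled
  polygenic covariance) would require the ACF to carry that correlation.
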