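# Methods

This note documents the statistical models implemented in proteoflow, the
defaults and why they were chosen, what the synthetic-data generator does
and does not emulate, and the numerical decisions that affect results.

## Data model

The central object is an `IntensityMatrix`: proteins × samples, `NaN` for
missing cells, a scale tag (`raw`/`log2`) and a provenance tag
(`tmt`/`dia`/`generic`/`synthetic`). Missing-value tokens are the empty
string, `NA` and `NaN` in every dialect; in the DIA dialect a literal `0`
is additionally treated as missing, because label-free protein reports use
zero intensity for non-detection, whereas a multiplexed reporter-ion value
of zero would be a corrupt measurement rather than an absence. Gene and
protein identifiers are matched across datasets by exact string comparison
after uppercasing; unmatched identifiers are dropped with a logged count.

## Preprocessing

*Validity filter.* A protein is retained if it has at least `min_valid`
observed values in at least one condition (defaults 3 or 10 depending on
cohort size; both exposed). Filtering before normalization and imputation
keeps the imputation model from being driven by proteins that are mostly
absent.

*Median normalization.* Each sample is shifted so its observed median
equals the grand median of the pre-normalization sample medians. Anchoring
to the grand median (rather than centering at zero) preserves the absolute
log2-intensity scale, which the variance-trend moderation downstream uses
as its covariate. Within-sample differences are bit-identical before and
after. Whether label-free matrices should also be median-normalized is
exposed as a flag and on by default.

*Left-censored imputation.* Missing values are assumed missing-not-at-
random due to the detection limit. Imputed values for sample *s* are drawn
from `N(m_s − downshift·sd_s, (width·sd_s)²)` with `downshift = 1.8` and
`width = 0.3` (the conventional lower-tail parameterization), where `m_s`
and `sd_s` are the mean and SD of that sample's observed log2 intensities.
The distribution is per sample, so loading differences between samples are
respected. In *selective* mode a protein's missing cells are imputed only
when at least one group reaches `min_valid` observations for it; sporadic
holes inside passing groups are also filled so complete-matrix consumers
(PCA, clustering, PLS-DA) can run. The probability that a draw exceeds the
sample mean is Φ(−1.8/0.3) ≈ 10⁻⁹, i.e. imputation cannot create apparent
abundance.

*QC.* Coefficients of variation are computed per protein within replicate
groups on the linear intensity scale (100·sd/mean of `2^log2`), matching
the usual reporting convention; completeness is the fraction of proteins
with zero missing values.

## Differential abundance

Per protein, ordinary least squares on the observed samples (complete-case
per protein; a protein needs at least rank+1 observations or it is
reported with missing statistics, never silently dropped). The design is
an intercept, a two-level contrast indicator, optional numeric/categorical
covariates and batch dummies. Covariate missingness is handled
complete-case with a logged count.

*Blocking.* When samples are paired within donors, a compound-symmetric
within-block covariance is used. The consensus correlation is estimated by
per-protein REML: the profiled restricted likelihood is maximized over
ρ ∈ (−0.99, 0.99) by bounded scalar optimization — the same-block indicator
matrix is eigendecomposed once per missingness pattern, which turns every
likelihood evaluation into a diagonal reweighting — and the consensus is
`tanh` of the 15 %-trimmed mean of `atanh(ρ_g)`. Fitting then proceeds by
GLS with that single consensus ρ.

*Moderation.* Residual variances are shrunk toward a prior by moment
matching of `e_g = log s²_g − ψ(d_g/2) + log(d_g/2)`: the prior degrees of
freedom solve `ψ′(d₀/2) = 2·(var(e) − mean ψ′(d_g/2))` by Newton inversion
of the trigamma function, and the prior variance is either a scalar or,
with `trend=True` (default), a lowess curve of `e` on average intensity
(span 0.5, 3 robustness iterations). When the moment estimate of excess
spread is non-positive the prior df is infinite and the prior variance is
the plain mean of the residual variances (or the trend curve). The total
df `d₀ + d_g` is capped at the pooled residual df. The implementation was
cross-checked against the reference Bioconductor implementation on
synthetic data (no-trend path agrees to ~1e−5 in t; the trend path differs
only through the lowess span choice).

Two-sided p-values use the t distribution with `d₀ + d_g` df;
multiple-testing control is Benjamini–Hochberg step-up.

## GSEA

A ranked list (descending statistic; ties broken by gene id for
reproducibility, and additionally randomized within tie blocks under the
permutation seed before scoring, to avoid bias from the deterministic
tie-break) is scanned with the weighted Kolmogorov–Smirnov running sum:
hits increment by `|stat|^exponent` normalized over the set's hits
(exponent 1 by default) and misses decrement by `1/(N − N_hit)`. The ES is
the signed maximal deviation; the leading edge is the hits at or before
the maximum (positive ES) or at or after the minimum (negative ES).

The null is gene permutation: size-matched random sets drawn without
replacement. Each tested set receives its own permutation null so that
p-values are independent across sets (sharing nulls across same-size sets
would correlate them and inflate the variance of any tail-rate summary);
permutation workspaces are chunked to bound memory. p is the one-sided
same-sign tail frequency with a +1 pseudocount, `(b+1)/(m+1)`, so finite
permutations never produce p = 0. NES divides ES by the mean |null ES| of
the same sign; a set whose null has no same-sign draws gets an undefined
NES and is flagged. Defaults: 10,000 permutations; minimum set size 20 for
functional collections and 100 for PC-loading scans. Storey q-values are
not computed; BH-adjusted p-values are reported.

## Cell-type markers and assignment

The reference is a pre-aggregated genes × cell-types pair of matrices:
mean log-normalized expression and fraction of cells expressing each gene.
After restricting to the measured universe, per-gene z-scores are computed
across cell types, treating each type as one observation with the n−1
denominator (exposed as a flag; the choice matters little beyond 6 types).
A gene marks a type when z exceeds the threshold (2 ≈ 97.72th percentile;
2.5 ≈ 99.38th) **and** is expressed in at least 25 % of that type's cells.
Genes passing in several types are kept in all passing sets and flagged.

Note a structural ceiling: across *n* cell types the z-score of a single
elevated type cannot exceed `(n−1)/√n` (≈ 2.47 for n = 8), so marker
calling at z > 2 is only sensitive to strong, near-exclusive elevation —
which is what canonical cell-type markers look like in single-cell
references, and what the synthetic reference plants (default elevation 8
between-type SDs).

Primary-type assignment takes, among types passing the fraction filter,
the one with the highest z; ties go to the higher fraction-expressed, then
alphabetical order; proteins absent from the reference or failing the
fraction filter everywhere are `unassigned`.

## Set networks

Enriched sets are compared by the Jaccard index of their gene lists
(leading edges by default). Redundancy reduction is greedy in ascending
adjusted-p order: a set survives only if its Jaccard to every already-kept
set is below the cutoff (default 0.7); ties are resolved by larger |NES|,
then set id. One divergence is deliberate: semantic (ontology-graph)
similarity is not implemented, so Jaccard is used for both simplification
and network edges. Communities are Louvain modularity partitions
(networkx, seeded; labels are renumbered by each community's lexically
smallest member so output is stable). Edges below `min_edge = 0` are not
pruned before community detection.

## Variance partitioning

Per protein, all named factors enter as crossed random effects:
`y = μ + Σ_f u_f + ε`. REML is maximized over the variance ratios
`γ_f = σ²_f/σ²_ε` (log-parameterized; bounded scalar optimization for one
factor, Nelder–Mead with three starts for several), with the residual
variance profiled out analytically. Fitted ratios below 10⁻⁶ are truncated
to exactly zero (the non-negativity boundary). Reported fractions are
`σ̂²_f / (Σ σ̂²_f + σ̂²_ε)`; proteins that are constant, under-observed or
fail to converge are flagged, never zero-filled, and excluded from cohort
summaries (medians and quartiles). On balanced one-factor designs the
interior REML solution coincides with the closed-form ANOVA estimator, and
the test suite asserts agreement to 1e−6.

With few blocks the per-protein fraction estimator is noisy and its median
is slightly below the true fraction (≈ 0.46–0.47 for a true 0.5 with 5
individuals × 3 replicates); cohort medians should be read with that bias
in mind.

## Descriptives

PCA treats samples as observations and proteins as variables, centering
but not scaling by default, via SVD of the centered matrix; percent
variance comes from squared singular values. Hierarchical clustering is
Ward-D2 on Euclidean distances (scipy linkage; equivalent to the classic
`hclust` ward.D2 on a Euclidean distance matrix), verified against a
brute-force Lance–Williams implementation. Pearson correlations are
pairwise-complete with a minimum of 3 shared observations (pairs below the
minimum are flagged undefined). PLS-DA regresses a one-hot group response
on centered, unit-scaled predictors by NIPALS (scikit-learn
`PLSRegression`); a separation ratio (total/within score variance) is
provided for permutation sanity checks. Both descriptive entry points
require a complete matrix and direct the user to imputation or
complete-case filtering otherwise.

## Stereology

A systematic square grid at 62.25 µm spacing (each point standing for
spacing² = 3 875 µm²; spacing is taken as the authoritative parameter) is
overlaid with a deterministic half-spacing offset — chosen over a random
offset for reproducibility; `random_offset` with a seed is available for
unbiased designs. Each point is classified by the pixel it falls in;
background points are excluded from the total, and all-background sections
are flagged empty. Proportions are counts over total (optionally in exact
rational arithmetic) and summarized as medians/IQR per group.

## Synthetic-data generator

`proteoflow.synth` draws log2 intensities from an additive model: protein
means are normal in log2 space (default mean 20, SD 2.5, emulating the
wide dynamic range of tissue proteomes where a small subset of proteins
dominates total signal), plus per-protein random level effects for
individual, workflow, fixation and batch, plus residual noise. Default
variance components (individual 0.11, workflow 0.29, fixation 0.01,
residual 0.59) mirror a paired-preservation benchmark in which processing
workflow dominates and fixation is negligible. Differential abundance is
planted as a fixed ±log2FC on a random subset of proteins in the first
group level; missingness is logistic left-censoring of the latent
intensity, `P(missing|y) = expit(−slope·(y − midpoint))`, so behavior near
the censor boundary is testable (a hard threshold would not exercise the
imputation tail). One `numpy` Generator seeded from the design drives all
draws in a fixed order, making outputs bit-identical under a seed.

What the generator does **not** emulate: peptide-level effects and roll-up,
isotope impurity and ratio compression in multiplexed data, batch×protein
interactions, heavy-tailed or correlated residuals, and shared regulation
across proteins (each protein is independent). Passing recovery tests on
this generator therefore validates the estimators under their assumed
model — normal additive effects with MNAR censoring — not robustness to
every artifact of real acquisitions.

## Problem sizes

The validation suite and `scripts/acceptance.py` use 2,000–5,000 proteins,
5–10 samples per group, 200–1,000 permutations and 10⁵ imputation draws —
sizes at which the Monte-Carlo error of each checked quantity is several
times smaller than its tolerance band, while a full run stays in the
tens of seconds.
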