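# Methods

This note documents the models, the numerical choices and the synthetic
study conditions behind `txdrivers`, and states what the test suite does
and does not demonstrate about real data.

## Dose–response

Viability (percent of vehicle) follows a four-parameter logistic
`v(c) = bottom + (top − bottom)/(1 + (c/ic50)^hill)`. Fitting is bounded
least squares (`scipy.optimize.least_squares`, trust-region reflective) in
`(top, bottom, hill, log10 ic50)` with default box constraints
top ∈ [80, 120], bottom ∈ [0, 50], hill ∈ (0, 10]. The bounds stabilise
IC50 values extrapolated beyond the tested grid — a resistant line with a
true IC50 of ~99 µM only reaches ~66% viability at the top dose of 50 µM,
so an unconstrained top/bottom would trade off against the midpoint.
Whether the original assays constrained the asymptotes is unknown; these
bounds are this package's choice. Initialisation is a multi-start grid of
12 log-spaced IC50 values spanning the dose range extended ×10 on each
side; the lowest residual sum of squares wins, ties broken by the smaller
IC50. Curves whose response range is below 5 percentage points are
declared non-responsive (`converged=False`) rather than fitted. Inhibitory
concentrations at level ℓ come from the closed form
`ic50 · (ℓ/(1−ℓ))^(1/hill)`.

## Normalisation and differential expression

Between-sample normalisation is trimmed mean of M-values: genewise
log-ratios against a reference sample (the one whose upper-quartile of
library-scaled counts is closest to the panel mean), doubly trimmed (30%
of M values, 5% of A values), precision-weighted by the inverse asymptotic
variance of M, factors rescaled to geometric mean 1. The implementation
matches the reference R implementation to ~1e-10 on toy data.

The pre/post test per line is an **exact conditional test under a common
negative-binomial dispersion** (variance μ + φμ²): counts are scaled to
the geometric-mean effective library size (rounded to integers), group
sums follow NB with size n/φ, and conditional on the total the two-sided
p-value doubles the smaller tail (capped at 1). φ = 0 degenerates to a
binomial split. This is a simplification of the edgeR exact test: no
quantile-adjusted pseudo-counts, no empirical-Bayes dispersion moderation.
With replicates, `dispersion="auto"` estimates a common φ by method of
moments (median over genes of (s² − m)/m²); without replicates it falls
back to a fixed prior φ = 0.16 (BCV 0.4, a conventional cell-line value).
Correctness is established against exhaustive enumeration of the
conditional distribution and calibration simulations (type-I fraction
0.049 at nominal 0.05; power 1.0 on 4-fold changes at mean 100,
dispersion 0.05, 3 vs 3). The DE filter is strict as specified:
|fold change| > 2 **and** FDR < 0.05, both strict inequalities, so a gene
at exactly 2-fold or exactly FDR 0.05 is excluded.

## Co-expression networks and condition labels

Samples are cell lines; expression is replicate-averaged log2 CPM
(prior count 1). Unsigned adjacency `|cor|^β` with default β = 6 (the
classic unsigned choice; a scale-free-criterion search is available via
`beta="auto"`), TOM as
`(Σ_u a_iu a_uj + a_ij)/(min(k_i,k_j) + 1 − a_ij)`, diagonal 1.

Two numerical realities of an ~11-sample panel drove design choices:

* **Null correlations are large** (sd ≈ 0.32), so across thousands of
  uninformative genes the adjacency sums dominate TOM connectivity. The
  pipeline therefore restricts the network to the `top_n_genes = 2000`
  most variable genes (mean of pre/post variances), a standard filtering
  step; module-level conclusions apply to that universe.
* **Average linkage chains background genes** at dissimilarities ≈
  0.7–0.98, so a static cut near the root would absorb them into giant
  modules. The static cut is therefore placed at `cut_height = 0.6` of
  the tallest merge — between within-module heights (≲ 0.3 for correlated
  blocks) and the background chaining region — with `min_size = 30`.
  This replaces the dynamic hybrid tree cut of the reference R
  implementation; it is deterministic and reproducible, at the cost of
  less adaptivity on real dendrograms.

The consensus network rescales the post TOM so its 0.95 off-diagonal
quantile matches the pre TOM's and takes the elementwise minimum.
Consensus modules are *unaffected*; a pre (post) module with best Jaccard
overlap strictly below 0.5 against every post (pre) module is *pre-only*
(*post-only*); an overlap exactly at the threshold counts as matched.
Gene labels follow the precedence unaffected > pre_only > post_only.

## Driver calls

Modulator correlation is computed against **log10 IC50** — sensitivities
span more than two orders of magnitude (0.3–99 µM) and a log scale tames
the leverage of resistant lines; whether the original analysis logged the
concentrations is not documented, so this is a recorded divergence risk.
The screen is restricted to unaffected-module genes (a `genome_wide` flag
exists for sensitivity analysis); this restriction is also what protects
the calls from the large null correlations of flat genes. "Assisting"
denotes positive correlation with IC50 (expression high where the drug is
*less* effective) — the printed convention of the emulated screen,
encoded verbatim despite its counter-intuitive reading.

Mediators require a strictly negative essentiality score in
≥ 6 lines ("score < 0", strict: exactly 0 is not essential) and a DE call
in ≥ 1 line. The query signature takes genes DE in the same direction in
≥ 3 lines ("overlapping" is not quantified in the source design; 3 of ~10
is this package's operationalisation, exposed as config), ranked by
supporting lines ↓, median FDR ↑, |median log2 FC| ↓, gene id ↑, top 150
per direction; genes passing in opposite directions in different lines
are excluded from both sides.

## Connectivity scoring

The weighted KS enrichment score ranks reference genes by score
(descending, ties by gene id), increments the running sum by
`|score|^w / Σ|score|^w` at query members (w = 1 by default; w = 0 gives
the classic unweighted statistic) and decrements by `1/(N − |set|)`
elsewhere; ES is the signed extremum. wtcs combines up/down scores by the
opposite-sign rule. No permutation-null normalisation is applied (the
reference platform's normalised scores and FDR machinery are out of
scope); classification uses raw wtcs with τ = 0.9 by default. Raw wtcs
for truly concordant columns plateaus around 0.8–0.9 when the query is a
subset of a larger concordant gene block, so planted-recovery checks use
τ = 0.5; τ remains configuration.

## Synergy

Effects are fractions affected, E = 1 − viability/100, clipped to [0, 1],
computed from replicate means; CI = (E_A + E_B)/E_AB. Because CI = 1 is a
knife edge under replicate noise, |CI − 1| ≤ 0.1 is reported as additive
(band inclusive, configurable) alongside the raw CI and a seeded
percentile bootstrap interval (1000 resamples). Standalone cytotoxicity
is a per-line×agent two-factor fixed-effects ANOVA on viability with
concentration (vehicle included as level 0) and replicate batch as
factors — the factor structure of the original analysis is unstated, so
this choice is config-documented — with treatment p-values pooled across
agents and BH-adjusted, and a direction guard (mean viability at the top
dose below vehicle).

## Synthetic study conditions

The generator's defaults are the emulated study's conditions: 11 lines;
IC50 log-spaced 0.3–99 µM (both extremes always planted); the 12-point
dose grid 0.02–50 µM; 3 viability replicates; 81% of planted
transcriptional responses are inductions; mediators essential in 6–9
lines; 150+150 signature capacity (1000 signature-only DE genes of a
5000-gene universe ≈ 21% DE fraction, keeping the TMM assumption of a
non-DE majority workable); a 10 assisting / 30 impeding modulator split
(impeding-heavy, as in the emulated screen). Expression is a latent
log2-mean model: one shared Gaussian factor per block per line (persistent
blocks share the factor across conditions; condition-specific blocks get
independent per-gene draws in the other condition), a linear term in
standardised log10 IC50 for modulators (present in both conditions),
planted per-line log2 fold changes post-treatment for mediators and
signature-only genes, and N(0, 0.3²) per-sample noise. Counts are
negative binomial via gamma–Poisson (φ = 0.05 default; φ = 0 is Poisson)
with log-normal library-size factors. All randomness flows from one seed,
split by `SeedSequence.generate_state(5)` into per-component streams in
the fixed order panel, expression, viability, essentiality, reference.

Two generator properties exist specifically so that planted-truth
recovery can be *exact* rather than approximate:

* block factors are **orthogonalised against the sensitivity gradient**,
  keeping "module member" and "sensitivity-correlated" disjoint planted
  properties;
* a `deterministic=True` observation mode returns rounded means — with
  only ~11 lines even Poisson jitter creates spurious |r| up to ~0.8
  among hundreds of genes, which no threshold can separate from planted
  signal. Round-trip tests use deterministic counts with latent noise
  0.3, which bounds spurious expression–sensitivity correlations of
  module genes near 0.29, safely below the 0.5 call threshold.

What the generator does **not** emulate: gene-length and GC effects,
count outliers and heavy-tailed dispersions, correlated essentiality
screens, batch structure, or realistic perturbation-reference noise
(planted *like*/*contrary* columns place signature genes at the score
extremes). Passing round-trip tests therefore demonstrates correctness of
the algorithms under the stated model, not robustness to real-data
pathologies. Decorrelating a condition-specific block necessarily changes
per-line expression values with random sign, so those genes legitimately
appear in DE output; direction-balance checks are evaluated on the
treatment-responsive genes.

## Problem sizes and determinism

Tests run the pipeline at 500 genes × 11 lines (seconds); the default
demo configuration is 5000 genes × 11 lines × 3 replicates (~20 s
end-to-end). Pipeline outputs contain no timestamps; a re-run with the
same config and seed is byte-identical, which the suite asserts file by
file.

## Known limitations

* The exact test's no-replicate fallback (φ = 0.16) is a prior, not an
  estimate; single-sample contrasts have correspondingly conservative
  power.
* The static tree cut needs a sensible `cut_height` for the dendrogram at
  hand; 0.6 suits block-structured panels of this sample size but is not
  universal.
* Raw wtcs thresholds are not comparable across reference matrices with
  different score distributions; without a permutation null, τ is a
  design choice.
* Module eigengenes, dynamic tree cut, GLM-based DE, median-effect
  (Chou–Talalay) synergy and response-surface models are out of scope.
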