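# Methods

## Scope and data model

The package analyses island-year × species matrices of newly ringed
trans-Saharan migrant passerines from standardized spring campaigns
(season window 16 April – 15 May by default). The island-year is the
sample unit throughout: repeated annual samples per island are what allow
beta diversity to be split into a between-island and a temporal part, and
they are also why naive per-sample inference on island-level covariates
would be pseudoreplicated (see Ordination below).

Two eligibility filters precede everything. A species is retained if it
was ringed in at least 5 distinct years **or** on at least 5 distinct
islands (a disjunction: a species concentrated in one strong passage year
across many islands still counts). An island-year is eligible if nets were
open on at least 7 distinct days in each half of the season window — the
strictest reading of "a week of ringing in each fortnight", and
configurable, since calendar-week bookkeeping would also be defensible.
Presence for the species filter means count > 0, not merely station
operation. All-zero island-years are removed (with a log entry) rather
than erroring: the chord transform is undefined on them.

## Beta diversity as total variance

Rows are chord-transformed to unit norm; total beta diversity is the total
variance of that matrix, `BD_I,T = SS_Total/(N−1)`, bounded by 1 in chord
space. The partition formulas are in the README. Numerical notes:

- The decomposition `SS_Total = SS_Temp + Σ_i Y_i Σ_j (ȳ_ij − ȳ_j)²` is an
  algebraic identity; the implementation returns its residual
  (`identity_residual`) as a self-check, and tests verify it to 1e-10
  against a naive triple-loop oracle. Note that `SS_I` itself is the
  *unweighted* island sum of squares; only under a balanced design
  (all `Y_i = q`) does `SS_I` equal the weighted between term divided by q.
- If `SS_Total = 0` (all rows identical), LCBD and SCBD are reported
  uniform with a warning instead of NaN, preserving their sum-to-one
  contract through the pipeline.
- Islands with a single sampled year stay in all totals but are excluded
  from `BD_Ti` (denominator `Y_i − 1`), with a warning.
- Per-island LCBD is summarized two ways: the raw mean of yearly LCBD
  (what a summary table prints) and the mean of log LCBD (what the
  between-island ANOVA uses, because yearly LCBD is right-skewed). The
  ANOVA is followed by Tukey HSD on the log values. Correlation helpers
  report two-sided t-approximation p-values and raise on constant input.

## Permutation inference

PERMANOVA is computed directly from sums of squares of the (Euclidean)
chord-transformed matrix; this is identical to the distance-matrix
formulation via Gower double-centering, and tests verify the equivalence
to 1e-10 (scikit-bio's implementation is used as an additional independent
cross-check). Permutations are unrestricted row-label permutations —
yearly samples are treated as exchangeable replicates — with the observed
statistic included in the reference set: `p = (1 + #{F* ≥ F})/(B + 1)`,
default B = 999. The dispersion test uses Euclidean distances to group
centroids (chord space is Euclidean, so centroids rather than spatial
medians), multiplies each group's distances by `sqrt(m/(m−1))` to correct
small-sample bias, takes the one-way ANOVA F on the distances, and builds
the null by permuting raw rows and recomputing centroids and distances.
Pairwise island contrasts run the same PERMANOVA per pair with
Benjamini–Hochberg adjustment across all pairs. Type-I error of both tests
is verified by simulation to sit in [0.03, 0.07] at α = 0.05.

## Ordination

RDA is the PCA (via SVD) of the fitted values of a multivariate regression
of the column-centered response on standardized predictors. Explained
variance uses Ezekiel's adjustment `R²_adj = 1 − (1−R²)(N−1)/(N−m−1)`.
Design choices:

- Island descriptors are natural-log transformed; non-positive values
  (one island sits at kilometre zero of the longitudinal gradient) are
  floored at 0.1 before the log, and the floor is logged.
- Collinearity screening recomputes VIFs after each removal of the current
  worst predictor until all VIFs fall below 10. On the packaged
  descriptors this removes minimum-distance-to-Africa and latitude from
  the geographic block and leaves a maximum VIF near 2, with all habitat
  VIFs below 3 — the behavior expected of these strongly inter-correlated
  distance variables.
- Forward selection adds the candidate with the largest partial pseudo-F
  when its residual-permutation p is below α. An optional adjusted-R²
  "scope" stop (halt when a trial set would exceed the full set's R²_adj)
  is available but off by default: it can reject a genuinely dominant
  single predictor by a razor-thin margin, since noise predictors drag the
  full model's adjusted R² just below that of the true predictor alone.
- Per-axis significance permutes response rows and compares each observed
  canonical eigenvalue with its rank counterpart.
- Axis signs are fixed by orienting each axis so its largest-|loading|
  species loads positively; eigenvector signs are otherwise arbitrary and
  would flip between runs.
- The two-block variance partition reports unique and shared fractions on
  the adjusted scale, using the **rank** of each design (not its column
  count) in the adjustment so overlapping blocks behave correctly; the
  shared fraction is not testable, the unique fractions are, via partial
  RDA with residualized response and predictors.
- Predictor–axis significance comes from regressing island-mean axis
  scores on the island's descriptor value (one point per island). For an
  island-constant descriptor the island is the exchangeability unit;
  treating all island-years as independent inflates significance, which a
  simulation test demonstrates. Species–axis correlations are plain
  Pearson correlations with Bonferroni flagging across species × axes.

## Abundance and species response models

The continental-abundance analysis fits, by OLS, log mean-ringed per
island × species against log continental abundance with island main effect
and interaction, compares the candidates by AICc
(`AIC + 2k(k+1)/(n−k−1)`, k counting the error variance), and fits the
pooled log10–log10 regression of species totals with DFBETA-based
influence flagging (threshold `2/sqrt(n)`). Species absent from an island
are omitted from that island's rows (log of zero), and the log base only
affects the intercept, which is therefore not a comparison surface.

Species response models are count GLMs with log link and an offset: log
total ringed that island-year (percentage mode) or log(hundreds of
net-metres × days) (rate mode; islands flagged as non-comparable in net
placement are excluded from this mode). The original formulation uses
random island and year intercepts; this package replaces them with fixed
effects. Year enters as a fixed factor. An island factor, however, would
be perfectly collinear with any island-constant descriptor, so descriptor
models carry year factors only — the island random intercept has no
fixed-effect counterpart alongside the descriptors and is dropped. The
consequence is that island-level heterogeneity not captured by the tested
descriptor inflates the apparent descriptor evidence somewhat; the
end-to-end recovery test quantifies this as the spurious-effect rate.

Families: Poisson (k = p), nbinom1 (variance linear in the mean) and
nbinom2 (variance quadratic, `μ + μ²/θ`), both with one extra parameter
(k = p + 1), fitted by maximum likelihood through statsmodels; a
dispersion estimate collapsing to zero is flagged "Poisson-like". The
family is chosen on null-model AICc; per descriptor, linear and quadratic
models (on z-scored log descriptors, for conditioning) are retained if
they beat the null's AICc, a quadratic additionally needs a
likelihood-ratio test against the linear model at p < 0.05, and effect
signs come from the linear term, or "intermediate" when a quadratic's
extremum falls inside the observed predictor range. A species' plausible
set is all retained models within ΔAICc ≤ 2 of its best; the summary table
counts species per descriptor from those sets.

## Wing shape and phylogeny

The Kipp index (100 × primary projection / wing length) measures wing
pointedness; wing aspect ratio correlates strongly with it. Group
comparisons use GLS with residual covariance `σ²V(λ)`, V the matrix of
shared root-to-tip path lengths (computed from arbitrary branch lengths —
ultrametry is not required) and λ scaling the off-diagonals. λ is profiled
by ML on a grid with bounded local refinement; the default interval is the
conventional [0, 1]. The positive-definiteness limit of V(λ) is negative,
and `lower="pd"` extends the search there so that negative estimates —
which unbounded GLS machinery does produce on real consensus trees —
remain reachable. The default is restricted because on unit-depth
birth-process trees the PD limit sits very close to zero and the profile
likelihood spikes against that singularity, which would make the
likelihood-ratio test against λ = 0 reject under the null at many times
its nominal level. With the [0, 1] restriction that LRT has a boundary-
mixture null (½χ²₀ + ½χ²₁): asymptotic size 2.5% at α = 0.05, measured
nearer 1% at n = 35 — conservative, never anticonservative, and the
acceptance checks test exactly that. Coefficient t-tests use residual
df = n − p. With two group indicators the interaction is fitted first and
dropped when not significant; the λ-ML model is kept only when the LRT
favors it, otherwise the λ = 0 (OLS) fit is reported.

## Synthetic data generator

The generator emulates the long-run structure of multi-island spring
campaigns: expected counts are log-linear,

    log μ_ijk = log(C_j·s) + β0_j + β_area,j log Area_i
              + β_dsouth,j log MinDSouthLand_i + v_ij + u_ik + log effort_ik

with continental abundance `C_j` log-uniform over 10^4.5–10^7.5 pairs (the
roughly three orders of magnitude separating the commonest from the
rarest eligible migrants), a global catchability `s = 2e-7` putting median
per-island-year counts in the tens, island-year passage intensity `u_ik`
(SD 0.3, shared across species), island × species suitability noise `v_ij`
(SD 0.2), and effort in hundreds of net-metres × days (default 300 m ×
30 days, constant; an imbalance switch varies both). Default conditions:
the nine real island descriptor rows (so the collinearity structure of the
predictors is the real one), 5–16 years per island, 35 species of which 10
respond to area (β = 0.5) and a disjoint 20 to distance-to-southern-land
(β = 0.3), Poisson counts (nbinom2 with θ available). Wing traits follow
`Kipp = 25 + 8 β_area − 8 β_dsouth + N(0, 1.5)` with aspect ratio affine
in Kipp, reproducing a strong positive Kipp–WAR association. Trees are
pure-birth (Yule), crown-started, scaled to unit depth; traits on trees
are multivariate normal with covariance `σ²V(λ)`.

What the generator does **not** emulate — and hence what passing tests do
not certify about real data: compositional year-to-year variation beyond
sampling noise. Because the passage effect `u_ik` is shared across species,
the chord transform cancels it, so the default synthetic temporal
component `BD_T` is much smaller relative to `BD_I` than in real
campaigns, where species-specific annual fluctuations (weather, breeding
output) dominate. Species-level temporal structure can be mimicked with
the nbinom2 family, but no attempt is made to model weather, phenology, or
within-season dynamics; there is also no landing-decision mechanism — the
log-linear response form is an analysis-convenience assumption, not a
behavioral model.

## Problem sizes and determinism

Simulation-based checks use sizes chosen to give stable Monte-Carlo
estimates at interactive runtimes: 500 simulations × 199 permutations for
permutation-test calibration, 300 replicates for GLM coverage, θ recovery
and λ recovery, 100 random matrices for the partition identity, and 3
full end-to-end replicates for the planted-response recovery. Every
stochastic component takes an explicit seed, and a pipeline re-run with
the same seed and inputs reproduces every output byte for byte.

## Known limitations

- No true random-effects (Laplace/adaptive quadrature) estimation; the
  fixed-effect approximation above is the package's position, and its
  costs are measured rather than hidden.
- The dispersion test uses centroids, not the spatial-median variant.
- Forward selection is greedy; its inflation under all-noise predictors is
  measured in tests rather than corrected.
- PGLS assumes Brownian motion scaled by λ; no Ornstein–Uhlenbeck or
  measurement-error models.
- Recaptures, within-season phenology and tape-lure or net-placement
  biases are out of scope; the latter is handled only as an island
  exclusion flag for effort-standardized models.
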