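# Methods

This note documents the models, parameter choices and numerical decisions
behind `hofniche`, and what the synthetic validation experiments do and do
not show.

## Gradient preparation

Environmental variables arrive in heterogeneous units and are rescaled
per variable to x′ = 1 + 99·(x − min)/(max − min) using the *observed*
min/max across sites, so that optima and ecological distances are comparable
across variables. Rescaled values are kept at full float precision; rounding
to integers happens only in display. Missing raw values propagate as missing
rescaled values. A constant variable has no defined rescaling and is
rejected.

The land-use intensity index is
LUI = sqrt(m/m̄ + g/ḡ + f/f̄) with m, g, f the mowing, grazing and
fertilization components and the bars their across-plot means. A component
whose mean is zero (no plot managed that way at all) contributes 0 — the
formula is silent on this edge and 0 is the only continuous completion. LUI
is invariant under rescaling any component across all plots, since the mean
rescales too.

Collinearity screening reports all C(V,2) pairwise Pearson correlations
(pairwise-complete over sites), their mean absolute value and the count above
a threshold (default |r| > 0.7). With 41 variables this is 820 pairs.

## HOF response models

For one OTU along one gradient, the observed data are counts k_i out of n_i
reads at site i. The expected proportion follows one of five shapes (see
README table) with the maximum attainable response fixed at M = 1 and the
gradient mapped internally to the centered interval (x − 50.5)/99 ∈
[−0.5, 0.5]; centering makes the symmetric model IV with a = c peak exactly
at the gradient midpoint and conditions the optimizer. log p(x) is concave
in x for every shape (each factor contributes −log(1 + e^u) with u affine in
x), so every curve is unimodal and optima are unique.

**Error model.** Binomial with per-site totals as trials. The counts are
read counts, so binomial is the natural first choice; the likelihood kernel
k·log p + (n−k)·log(1−p) is also valid for fractional k (fractionated
counts). A Gaussian-on-proportions family is available behind the
`family="gaussian"` flag.

**Fitting.** Bounded L-BFGS-B on the negative log-likelihood with an
analytic gradient, from a deterministic set of coarse starts per shape
(flat level, four signed slopes, five peak positions) plus the best *nested*
solution from simpler shapes — model II starts at model I's solution with
b = 0, III/IV at II's with the extra factor neutralized, V at IV's. This
guarantees the nesting invariant: the maximized log-likelihood never
decreases going I → II → {III, IV, V}. Bounds: intercepts |a|,|c| ≤ 30,
slopes |b|,|d| ≤ 200 on the internal scale.

**Selection.** All five shapes are fitted and compared by AICc. "Ties" use
the field's standard equally-good band: every shape within 2 AICc units of
the minimum is tied, and the tie resolves to the simplest shape (fewest
parameters; at equal parameter count the lower AICc; canonical order
I < II < III < IV < V as the final fallback). Without the band, plain
AIC-type selection abandons the flat model on ~15–20% of truly flat
datasets — the familiar liberality of AIC for one extra parameter — and the
pipeline would report spurious optima at that rate. The choice is then
stabilized on 50 bootstrap resamples of sites (refitted warm-started from the
full-data solutions): the modal bootstrap shape replaces the full-data choice
only when it wins a strict majority of successful refits. A sub-majority
plurality is not a stable signal; letting it override re-introduces exactly
the spurious optima the bootstrap is meant to suppress (measured flat-truth
selection drops from ~93% to ~88%). The fraction of bootstrap refits
agreeing with the final choice is reported as `bootstrap_support_`. An
OTU × variable cell is flagged unmodelable when more than half of the
bootstrap refits fail.

**Optimum and inner niche.** Model I yields no optimum; II/III peak at the
gradient end selected by the sign of b; IV has the closed form
x\* = (c − a)/(2b); V is maximized by bounded scalar minimization of the
concave log-response (tolerance 1e−10, endpoints checked). An interior
argmax outside [1, 100] is clamped and flagged. The inner niche is the
superlevel interval where the response is ≥ e^(−1/2) of its peak — the
curves' log-concavity makes it an interval, found by bisection; the fraction
is a parameter (`inner_fraction`) since the interval's defining constant is a
display convention, not a derived quantity. Sites are put in a canonical
order (by gradient value, then count) before fitting, which makes the
bootstrap — and hence the selected model — invariant to input site order.

## Read assignment

Reads are aligned semi-globally against each candidate reference (read
end-to-end, reference flanks free) with match +1, mismatch −1, gap −2, via
Biopython's `PairwiseAligner`; identity = matching columns / aligned columns,
internal gap columns included in the denominator, and the ≥ 0.99 cutoff is
inclusive (a 100-bp read with one mismatch matches). A k-mer prescreen
(k = 12, at least one shared word) shortlists candidates; at 99% identity a
≥ 50 bp read must share such a word, so the prescreen is lossless at the
default cutoff. A read matching k OTUs contributes 1/k of a count to each,
conserving total read mass; unmatched reads contribute nothing. OTUs
detected (fractional count > 0) in fewer than 25 of 150 sites are dropped
before modeling.

## Niche-space analytics

Ecological divergence is the plain Euclidean distance between complete
optimum vectors. The OTU network joins pairs with Spearman ρ ≥ 0.85
(pairwise-complete variables; OTUs with < 3 usable optima are excluded with
a warning), communities come from seeded Louvain modularity maximization,
and communities of size 1 are not counted as groups. The ρ sweep re-runs
this across the standard grid 0.4 … 0.99. PCA is a column-centered SVD with
deterministic sign convention; missing optima are mean-imputed first
(matching the trait-module rule).

## Phylogenetic signal

Blomberg's K uses the phylogenetic covariance V (shared root-to-MRCA path
lengths; for an ultrametric tree V = h − D/2 with D the patristic distance
matrix): with â the GLS grand mean, K is the ratio of MSE₀/MSE to its
Brownian-motion expectation (tr V − n/1ᵀV⁻¹1)/(n − 1). V enters only
through Cholesky solves, never an explicit inverse. On a star phylogeny
with equal branch lengths K = 1 identically. Significance permutes trait
values across tips and compares the variance of Felsenstein's independent
contrasts (p counts permutations with contrast variance ≤ observed,
add-one corrected); the permutation statistic is a parameter-free convention
and the implementation agrees with the R reference implementation to
numerical precision (cross-checked in the test suite).

The PSR curve regresses the trait (OLS with intercept) on the first j
eigenvectors from classical scaling of the patristic distance matrix and
plots R²_j against the cumulative eigenvalue fraction, (0,0) prepended; the
signed area is the trapezoidal integral of (curve − diagonal). The
patristic distance is treated as the *squared* trait-space distance in the
scaling step — under BM, Var(y_i − y_j) = σ²·D_ij — so the double-centered
−D/2 equals the centered phylogenetic covariance and the PSR curve tracks
the diagonal in expectation for a BM trait (measured mean area ≈ −0.03 over
200 replicates on a 100-tip tree; the small negative offset is the
finite-sample bias of sequential R²). Eigenvalues below 1e−10 of the
largest are truncated, negative ones with a warning.

## Divergence vs relatedness

Terminal-clade pairs are cherries (two tips with a common parent) whose
sequence dissimilarity is ≤ 0.05; within a polytomy every tip pair counts,
flagged. Dissimilarity enters the regressions in percent so the slope reads
per-percent-change. Additive (`divergence ~ dissim_pct + subdivision`) and
interaction models are ordinary least squares (statsmodels), compared by the
exact F-test on the interaction terms and by AIC. Pairwise intercept
contrasts use single-step max-|t| adjustment: the joint distribution of the
contrast t-statistics is multivariate-t with the contrast correlation
matrix, sampled by seeded Monte-Carlo (default 50,000 draws) because the
pairwise-contrast correlation matrix is singular; with a single contrast the
exact Student-t p is used, so two groups reduce to the unadjusted two-sided
t-test. Holm is available as a fallback. Confidence bands evaluate the
additive model at dissimilarities drawn uniformly over each subdivision's
observed range (50 per subdivision by default).

## Trait concordance

Sparse matrices are pruned iteratively, rows (species < 70% complete) before
columns (traits < 50% complete) within each iteration, to a fixed point —
the order matters and is fixed for reproducibility. Species missing more
than 2 of the 41 optima are dropped; remaining gaps are filled with
per-variable means. Bray–Curtis omits, per pair, traits missing in either
row from both sums; codes are used raw (1/2/3), with no standardization, as
a flag-controlled option. NMDS is SMACOF majorization with isotonic
regression (scikit-learn engine, 20 random starts), after which the
configuration is centered, principal-axis rotated, and its Kruskal stress-1
recomputed directly (isotonic regression of configuration distances on the
input dissimilarities). The protest test permutes rows of one
configuration, compares symmetric Procrustes correlations
(corr = sqrt(1 − m²), identical to the R reference to numerical precision),
and averages the add-one permutation p over repeated runs (default 999
permutations × 100 repeats) because a single permutation p is itself noisy.

## Synthetic data: what it emulates, and what it does not

The generator draws each variable uniformly over realistic survey ranges
(pH 4.6–7.5, etc.) — uniform maximizes gradient coverage for testing,
whereas real surveys cover gradients unevenly. True responses are HOF curves
with optima uniform in [10, 90], internal slopes 8–16 and peak expected
proportions 0.02–0.08; counts are multinomial per site at depth 10⁴, with
optional Dirichlet overdispersion. One aggregated constant "background" row
(expectation 2.0) stands in for the rest of the community: a real survey
models a few thousand OTUs whose summed abundance makes per-site denominators
nearly constant, and without the background row the 200-OTU desk-scale
community has a lumpy compositional denominator that shifts realized optima
by several scaled units, so the planted optimum would not be the truth of the
observable relative-abundance curve. Trees come from a constant-rate
pure-birth process rescaled to unit height; traits evolve by exact BM/OU
transition sampling along edges, or i.i.d. for white noise. Trait matrices
plant group-specific 1/2/3 profiles with code-flip noise and random
missingness.

Consequences for interpretation: passing tests demonstrate correct recovery
under binomial/multinomial noise, uniform gradient coverage and independent
sites. They do not demonstrate robustness to overdispersed counts beyond the
optional Dirichlet noise, spatially autocorrelated sites, uneven gradient
coverage, microscale soil heterogeneity, or misassigned reads.

## Validation experiment sizes

The standard conditions are 150 sites, depth 10⁴ and bootstrap = 50
throughout. Optimum recovery uses 200 OTUs; the flat-model control 100
datasets; K and PSR calibration 200 BM replicates on a 100-tip tree; network
recovery 4 × 50 OTUs over 41 variables; the interaction-test size 1000 null
regressions (3 subdivisions × 40 pairs); protest calibration 500 null
configuration pairs (29 species × 6 dimensions, 199 permutations). These
sizes put Monte-Carlo error comfortably inside each test's tolerance while
keeping the full suite and the reproduction script in the minutes range on
one CPU.

## Known limitations

- Model III's plateau parameterization follows the original HOF formulation
  with a constant attenuation factor; other parameterizations exist.
- AICc-based selection, even with the equally-good band and majority
  bootstrap rule, retains a residual ~5–9% rate of spurious non-flat choices
  on flat truth; this is a property of information-criterion selection, not
  of the implementation.
- The assignment stage's alignment engine is exact but not optimized for
  millions of reads; it targets reproducibility, not throughput.
- Group detection depends on the Louvain seed for near-degenerate
  partitions; the seed is explicit and the modularity is reported so runs
  are comparable.
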