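# Methods

This note records the statistical definitions the package implements, the
choices made where several dialects exist, what the synthetic populations do
and do not emulate, and the numerical conventions.

## Data model

A season is a count matrix **X** of individuals × prey taxa (non-negative
integers). Validation drops all-zero rows/columns with a logged warning and
requires at least 2 individuals and 2 taxa. Before any analysis the study
filter removes individuals with fewer than 4 prey items (`filter_min_prey`,
threshold configurable); poorly sampled individuals otherwise dominate every
overlap statistic through pure sampling noise. Matrix orientation is a
contract, not a heuristic: rows are always individuals.

## Inter-individual variation (E)

Diet proportions `p_ij = x_ij / Σ_i x_ij`. Overlap between individuals j, k
is proportional similarity `w_jk = 1 − ½ Σ_i |p_ij − p_ik|` ∈ [0, 1]; `E = 1
− mean_{j<k} w_jk`. Pairs are unweighted in the mean (individuals, not
items, are the unit of replication).

**Diet-bootstrap null.** Each individual redraws its observed number of prey
multinomially from the pooled proportions (column totals / grand total,
focal individual included). Row totals are preserved exactly. The test is
one-sided: specialized iff observed `E` exceeds the 95% null quantile.
P-values use the add-one estimator `p = (1 + #{null ≥ obs}) / (n + 1)`, so
they are never zero and ties count conservatively. A single-taxon matrix
yields a degenerate null (all values 0) and is flagged, never significant.

## Relative clustering (C_ws) and cluster extraction

The pairwise-significance graph joins individuals j, k when their observed
overlap exceeds the 95th percentile of that pair's bootstrap-null overlap
distribution; each pair is judged against its own quantile because pairs
differ in sample size. Dietary clusters are the connected components of
this graph (singletons allowed), labelled deterministically by decreasing
size, then lexically smallest member.

`Cw` is the Onnela-type geometric-mean triangle intensity: a closed triangle
contributes `(w_ij w_ik w_jk)^{1/3}`, averaged per node over its neighbour
pairs (nodes with fewer than two neighbours contribute 0), then over nodes.
Weights already lie in [0, 1], so no max-weight rescaling is applied. For
the `C_ws` test, `Cw` is evaluated **on the significance graph**, and the
null `Cw` distribution applies the identical per-pair thresholds to every
bootstrap replicate, so under the null each pair is an edge ~5% of the time.
This choice is forced: on the *complete* overlap graph the triangle
intensity tracks the mean overlap, so any diet segregation — clustered or
overdispersed alike — lowers it below the bootstrap null mean, and the
statistic cannot distinguish the two arrangements. Thresholding first makes
`Cw` sensitive to whether strong overlaps concentrate into transitive groups.
(The complete-graph `Cw` remains available as
`weighted_clustering_coefficient` for descriptive use.)

`C_ws = (Cw_obs − mean Cw_null) / D` with `D = 1 − mean Cw_null` when the
deviation is positive and `D = mean Cw_null` otherwise, clipping the index
into [−1, +1]. Verdict: clustered above the 97.5% null quantile of `Cw`,
overdispersed below the 2.5% quantile (two-tailed).

## Nestedness (NODF)

For every ordered pair of rows (and of columns) with *strictly* decreasing
marginal totals, the paired overlap is `100 × shared / smaller total`; equal
totals contribute 0. NODF is the mean over all row pairs and column pairs
(row and column components are also reported). The definition is invariant
to input order; ties are resolved by the strict-inequality rule, not by a
sort. Matrices with empty rows or columns are rejected.

**CE null.** Cell (i, j) is occupied independently with probability
`(row_fill_i / n_cols + col_fill_j / n_rows) / 2`. Draws containing an empty
row or column are redrawn (rate logged) so NODF stays defined. One-sided
test at the 95% rule, add-one p-value.

## Checkerboardedness (C-score)

For taxa i, j with `r_i`, `r_j` occurrences and `S_ij` shared occurrences,
the checkerboard unit count is `(r_i − S_ij)(r_j − S_ij)`. The C-score is
the mean unit count over taxon pairs divided by its matrix-level maximum
`⌊R/2⌋⌈R/2⌉` (R = individuals), which bounds it in [0, 1]: 0 when every
pair co-occurs fully, 1 for a perfect checkerboard. Normalising each pair
by `r_i r_j` instead (available as `normalization="pair"`, with the raw
Stone–Roberts mean as `"none"`) makes every never-co-occurring pair score
exactly 1 however weak its data support, so rare taxa dominate the index
and a sparse matrix cannot score low; the matrix-level normalisation is
also the only one numerically consistent with published C-scores of ~0.05
coexisting with a majority of never-co-occurring pairs. The C-score is
computed over prey-taxon pairs (columns); the never-co-occurring census
(`S_ij = 0`, both taxa present) returns both the exclusive and the
co-occurring pair lists.

**Fixed–fixed swap null.** Sequential trial swaps: two random rows and two
random columns are drawn; if the 2×2 submatrix is a checkerboard it is
swapped. This chain is symmetric and therefore uniform over the set of
matrices with the given margins — counting *accepted* swaps instead biases
the sample toward swap-rich matrices (measurably non-uniform on enumerable
3×3 sets), so trial counts are used: burn-in 100×fill trials, 10×fill trials
between samples (typical acceptance ~10%, so several accepted swaps per
retained sample). Margins are preserved exactly by construction. Two-tailed
verdict at the 2.5%/97.5% null quantiles; matrices with no swappable 2×2
submatrix are flagged degenerate.

## Random numbers and reproducibility

All randomness flows through numpy's PCG64. A master seed is expanded with
`SeedSequence.spawn`, one child per (statistic, context) ensemble, so
different statistics never share draws; replicates within an ensemble come
from a single stream so multinomial draws vectorise. Given (scheme, seed,
input), every ensemble is reproducible bit-for-bit; seeds and resample
counts are carried in every result object and CLI report.

## Factor tests

Classical tests delegate to scipy.stats and statsmodels behind stable
result contracts: Pearson correlation of per-taxon predator counts against
**ln**-transformed availability (zero-availability taxa dropped by inner
join); OLS of the percentage of the season's taxa captured on body mass;
one-way ANOVA with Tukey HSD across clusters; Levene's test (mean-centred)
with per-group CVs; paired t-test for first/last-nest niche shift;
two-sample t on |Δ mean prey mass| for never- vs ever-co-occurring pairs;
two-sample t on **square-root**-transformed within- vs between-cluster nest
distances (pairs treated as independent, a deliberate pseudo-replication
caveat carried over from standard practice); per-female mean capture-day
scores (1..17) fed to the cluster ANOVA. Transforms are recorded in each
result. Degenerate inputs (zero variance, missing masses, constant counts)
are flagged or raise informative errors rather than returning NaNs
silently.

## Synthetic populations

Defaults mirror the study regime: 12 individuals (14 where a test pins it),
16 taxa, per-individual totals uniform on 4–30 (≥4 mirrors the study
filter), a dominant taxon at 50% of the pooled diet with a geometric tail
(ratio 0.75). Structures: `null` (rows i.i.d. multinomial from the pooled
diet), `nested` (niche breadth spans 1..n_taxa with a simulated body-mass
covariate; light individuals hold prefix subsets of the abundance ranking),
`competitive_refuge` (clusters share the dominant prey; each cluster ranks
a private block of alternatives), `distinct_preferences` (disjoint
top-ranked blocks per cluster), `checkerboard` (a strength-dependent
fraction of the alternative taxa, most abundant first, is segregated into
two interleaved-rank guilds hunted by alternating individuals — prey
microhabitat exclusivity; cross-guild pairs have zero co-occurrence by
construction).

**Strength semantics.** For nested/clustered structures, strength is
foraging *fidelity*: `round(strength × total)` items follow the
individual's structured preference ranking deterministically
(largest-remainder allocation, ties to the higher rank), the rest are
opportunistic multinomial draws from the pooled diet. Strength 0 is
bit-identical to the null generator under the same seed; strength 1 is
noiseless (e.g. a perfectly stepped binary matrix up to breadth ties for
the nested structure). For the checkerboard structure strength instead
scales how much of the prey spectrum is segregated, and diets stay fully
multinomial: checkerboardedness is a property of diet support, and a
deterministic item core homogenises presence patterns enough to mask the
co-occurrence signal at intermediate strengths.

**What the generators do not emulate.** Real populations combine
between-group diet divergence with substantial *within*-group
heterogeneity; the fidelity core idealises groups as internally
homogeneous. One consequence is deliberate and documented: the E bootstrap
test asks whether diets are more variable than pooled multinomial sampling,
and deterministic cores *under*-disperse individual diets, so E is
conservative (often non-significant) on strongly structured synthetic
populations even while C_ws/NODF/C-score detect their topology. The E
test's calibration is therefore checked by its type-I error on null
populations (nominal 5%), and power statements about E on real data should
not be read off these generators. The C-score's mean response is monotone
in strength across coarse levels (0, 0.5, 1) but can dip slightly at fine
resolution because the segregated-taxon count is discrete. No spatial
foraging, prey dynamics, or observation error is simulated.

## Problem sizes and runtime conventions

Null ensembles default to 10 000 resamples (the decision rules are 95% /
97.5% quantiles). Simulation-based checks in the test suite use 199–600
resamples per replicate and 200 replicates per power estimate, sizes at
which the binomial error of an estimated rate is ~2–3 percentage points;
the acceptance script uses 10 000 resamples for single-season statistics
and 300–600 for replicated rate estimates.

## Known limitations

- Cluster extraction by connected components can chain two true clusters
  through one bridging edge at intermediate segregation; modularity-based
  partitions are a possible refinement.
- The CE redraw rule (rejecting null matrices with empty lines) slightly
  conditions the null toward fuller matrices in very sparse regimes.
- Per-pair significance thresholds are estimated from the same bootstrap
  ensemble for all pairs, so extreme quantiles share Monte-Carlo error.
- The factor tests assume the transforms stated above achieve approximate
  normality; no further diagnostics are applied.
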