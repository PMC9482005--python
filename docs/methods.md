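# Methods

`nichekit` quantifies how a species' realized climatic niche and potential
geographic range differ between its native and introduced distributions. The
pipeline mirrors the standard ordination ("COUE") workflow of invasion
biogeography: occurrence records are spatially thinned, predictors extracted
and pruned for collinearity, a two-dimensional PCA climate space is built,
each range's occupancy of that space is estimated by kernel density
smoothing, and the overlay of the two occupancies yields the
expansion/stability/unfilling partition and the conservatism test. In
parallel, presence/pseudo-absence suitability models are ensembled,
thresholded and compared as maps.

## Niche model

Let `z_k ∈ R²` be occurrence scores in PC space. Each range's density is an
axis-aligned Gaussian KDE evaluated at the centers of a regular grid,

    f(x) = (1/n) Σ_k φ((x₁ − z_k1)/h₁) φ((x₂ − z_k2)/h₂) / (h₁ h₂),

with per-axis Silverman bandwidths `h = 1.06 · sd · n^(−1/5)` (a `fixed`
rule is available). The grid spans the pooled native + introduced score
range padded by three bandwidths per axis, so both ranges live on one
commensurable grid; the discrete mass is renormalized to exactly 1 to absorb
the truncated kernel tails.

The occupied niche at mass quantile `q` (default 0.95) is the smallest set
of cells, taken in descending density order (row-major on ties), whose
summed mass reaches `q`. A pure density > 0 rule would make areas depend on
the grid extent; the highest-density-region rule is stable and is the common
default in hypervolume-style niche estimation. Overlaying the two masks
gives, in PC-units²:

* stability `S` — cells occupied by both ranges,
* expansion `E` — introduced-only cells,
* unfilling `U` — native-only cells,

with `NA_i = E + S`, `NA_n = S + U` holding exactly as cell counts, and

    NAR = NA_i / NA_n,      SI = 2S / (NA_n + NA_i).

Niche conservatism is rejected iff `NAR > 1` and `SI < 0.5`, both strict.
Centroids are density-weighted means over each masked region.

Note an arithmetic consequence of these definitions: `SI = 2S/(2S + E + U)`,
so whenever expansion is at most 1.5·S and unfilling is small, SI exceeds
0.55 and the verdict is necessarily `conservatism_not_rejected`. A scenario
with half of the introduced mass novel but large shared occupancy therefore
rejects on the area ratio yet not on similarity; rejection requires the
introduced area to exceed roughly three times the native area when
unfilling is negligible.

## Suitability models and range dynamics

Pseudo-absences are drawn uniformly without replacement from valid
non-presence cells: 1000 points when there are ≤ 1000 presences, else one
per presence; two independent sets by default. Two reference learners stand
behind a pluggable contract (platform algorithms such as MaxEnt or GBM can
be plugged in but are not reimplemented):

* `logit` — ridge-penalized (λ = 1e-4) logistic discriminant on standardized
  predictors, classes weighted to contribute equally regardless of counts
  (fit via scikit-learn);
* `envelope` — Gaussian envelope `exp(−Mahalanobis²/2)` to the presence mean
  and covariance, rescaled by its presence-set maximum (singular covariances
  get 1e-6·I shrinkage).

Each learner × PA-set combination is evaluated by four-fold repeated
stratified 70/30 split sampling: AUC (rank-based, ties half), plus TSS and
Cohen's kappa at the MSS threshold — the held-out score maximizing
sensitivity + specificity under `score ≥ t`, smallest score on ties.
Evaluations are pooled across PA sets per learner; a learner is retained
when mean TSS > 0.7 or mean AUC > 0.8, and retained fits enter the ensemble
with weights proportional to mean TSS. Ensemble suitability is classified at
0.2 / 0.4 / 0.6 into unsuitable / low / moderate / high bands.

The potential range is the ensemble map binarized at the MSS threshold of
the pooled evaluation data (presences plus all PA points; computing it on
held-out data only is a config switch). Range area sums exact spherical cell
areas `R²·Δλ·(sin φ_top − sin φ_bot)` with R = 6371 km; spans are naive
max − min of masked cell-center coordinates without antimeridian wrapping.
Concordance between two binary maps is the Mapcurves goodness of fit
`GOF = Σ_i C/(B+C) · C/(A+C)` with A and B counted exclusive of the
intersection C — the only reading under which identical maps score 1
(`inclusive=True` gives the literal inclusive count). The out-of-range
comparison is a second call on complement masks.

Variable importance (used to decide which member of a collinear predictor
pair to drop at |r| > 0.70) is permutation importance against the reference
logit learner: one minus the mean Pearson correlation, over five seeded
permutations, between predictions on intact and column-permuted data.

## Synthetic data and what it does (not) show

The virtual-species generator is the test bed. Climate layers are smoothed
white noise (Gaussian filter, σ = min(nrows, ncols)/10 by default) with a
latitudinal gradient mixed into the first layer, and designated collinear
groups sharing a base field (pairwise |r| ≈ 0.99). Every layer is then
rank-uniformized onto [−3, 3]: a strictly monotone transform that preserves
smoothness, collinearity and the gradient while making environment values
uniformly available across cells. That matters because occurrences are
sampled by cell-based rejection (draw a valid in-window cell uniformly,
accept with probability proportional to the bivariate Gaussian niche density
at its environment value, jitter within the cell): with uniform
availability, sampled environments follow the truncated Gaussian itself, so
the analytic truth — expansion fraction = introduced niche mass outside the
native window, unfilling fraction = native mass outside the introduced
window, both by fixed 400×400 midpoint quadrature over center ± 8 sd — is
the exact sampling limit.

The generator emulates spatial autocorrelation, collinearity structure, a
thermal-like gradient, and known niche truncation. It does not emulate real
bioclim marginal distributions, dispersal limitation, sampling bias, or
biotic interactions; passing recovery tests show the estimators are correct
under the stated sampling model, not that real-data results are insensitive
to those factors.

## Defaults, numerics, edge cases

| parameter | default | why |
|---|---|---|
| rarefaction radius | 10 km | matches the ~5 arc-min cell scale of bioclim grids |
| thinning order | ascending id | deterministic; seeded shuffle available for sensitivity |
| collinearity cutoff | r ≤ 0.70 | widely validated niche-modelling threshold |
| PCA | correlation matrix, occurrences pooled | incommensurable predictor units; axes describe occupied climate |
| KDE grid | 200 × 200, Silverman | resolves the 95% region at desk scale |
| mass quantile | 0.95 | standard highest-density occupancy |
| PA rule | 1000 or n-presences, 2 sets | common ensemble-platform practice |
| splits | 70/30 × 4, stratified | balances evaluation variance against cost |
| retention | TSS > 0.7 or AUC > 0.8 | conventional reliability cutoffs |
| ridge λ | 1e-4 | numerical stabilization only |

Numerical conventions: loading columns are sign-fixed so the
largest-magnitude entry is positive; occupancy ties break row-major; the MSS
scan ties to the smallest threshold; collinearity pruning removes the worst
pair first, dropping the lower-importance member (name order on ties);
distances are haversine on a 6371-km sphere; a point on a cell edge belongs
to the higher-index cell, and a point on the native polygon boundary is
native. Degenerate inputs raise: zero-variance PCA columns and KDE axes,
single-class AUC, empty-range spans, NA_n = 0 ratios, and stability
exceeding either niche area.

Welch's t-test (not Student's) compares per-predictor means between ranges,
since range sample sizes and variances differ in typical use; both group
means are returned so either direction of difference can be read off.

The end-to-end suite and recovery checks run on 64–96² grids with 250–2000
points per range, sizes at which every stage's estimate is already stable;
all randomness flows from explicit integer seeds and repeated runs produce
byte-identical reports.

## Known limitations

* Niche areas are reported in PC-units² and depend on the mass quantile and
  (weakly) on grid resolution; they are comparable within an analysis, not
  across differently configured analyses.
* The two reference learners are deliberately simple; ensemble skill on
  complex response surfaces understates what a full algorithm suite reaches.
* Longitude spans are not antimeridian-aware by design; ranges crossing
  ±180° report the naive span.
* Mapcurves is implemented for binary maps (two calls cover in-range and
  out-of-range); multi-category reference weighting is out of scope.
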