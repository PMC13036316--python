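# Methods

`traitscape` implements a complete trait-informed spatial conservation
prioritization workflow for a gridded landscape: joint species
co-occurrence models with phylogenetic and spatial random effects,
Hill-number species and trait diversity layers with coverage-based
extrapolation, budget-constrained minimum-shortfall site selection, and
scenario-ensemble importance scores that separate trait-driven from
species-driven conservation priorities.  Everything is exercised on a
synthetic landscape generator, so the full stack is testable without any
external data; real tables in the same formats (Newick, CSV) can be
substituted stage by stage.

## The co-occurrence model

Presence of species *s* in planning unit *m* (an 11 × 11 km grid cell) is
modeled with a Gaussian likelihood on the 0/1 response (a linear
probability model):

    Y_sm = α + β x_s + γ g_m + δ d_m + ω w_m
           + θ_g x_s g_m + θ_d x_s d_m + θ_w x_s w_m
           + a_s + b_s + c_m + d_m + ε_sm

where `x_s` is one trait (each trait gets its own model run; the null model
drops `x` and the interactions), `g, d, w` are three z-scored environmental
covariates selected by PCA from a candidate set (the variable most
correlated with each of the first three axes), and the random effects are

* `a ~ N(0, σ_a² I_S)` — species identity,
* `b ~ N(0, σ_b² Σ_spp)` — phylogenetically structured species effects,
  with `Σ_spp` the Brownian-motion covariance of the tree standardized to a
  correlation matrix (a raw patristic-distance matrix is not positive
  semi-definite, so it cannot serve as a covariance; the distance matrix is
  still used for the phylogenetic eigenvectors),
* `c ~ N(0, σ_c² I_M)` — unit identity,
* `d ~ N(0, σ_d² Σ_m)` — spatially structured unit effects, with
  `Σ_m[i,j] = exp(−d_ij / d_max)` on centroid distances (the divisor is the
  maximum pairwise distance; configurable),
* `ε ~ N(0, σ_e² I)` — residual.

**Estimation.** Variance components are estimated by maximum likelihood
with fixed effects profiled out by GLS; for a Gaussian model with vague
priors this is essentially the posterior mode/mean a Bayesian fit (e.g.,
via nested Laplace approximations) would return, while being deterministic
and dependency-free.  The marginal covariance of the n = S·M observations,

    V = σ_a²(I_S⊗J_M) + σ_b²(Σ_spp⊗J_M) + σ_c²(J_S⊗I_M) + σ_d²(J_S⊗Σ_m) + σ_e² I,

is a rank-(S+M) update of a diagonal matrix, so solves, log-determinants,
the diagonal of V⁻¹ (for CPO), BLUPs, and held-out conditional expectations
all cost O(n(S+M) + (S+M)³) through the Woodbury identity — no dense n × n
algebra anywhere.  The optimizer is Nelder–Mead on the five log-variances,
initialized at var(Y)/5 for every component, with the best-visited point
returned (so the likelihood never ends below its initialization).
Cross-validation refits can be warm-started from the full-data variance
estimates.

**Model comparison.** 10-fold cross-validation stratified by species (every
species appears in every training set) gives per-fold RMSEs; RMSEs are
min–max scaled within each dataset variant across all models and the null
is subtracted, so negative δRMSE means the trait improved prediction.  The
conditional predictive ordinate (CPO) is the exact leave-one-out Gaussian
density computed from precision identities (conditional variance `1/Q_ii`,
conditional mean `y_i − (Qr)_i/Q_ii`); per-species medians of
CPO_trait − CPO_null are summarized by rarity quartile (quartile 1 =
rarest; quartiles from mean presence counts across the five dataset
variants, ties sharing the lower quartile).

**Why a linear probability model.** The synthetic generator draws presence
as Bernoulli(clip(η, 0, 1)), so the Gaussian fit is correctly specified up
to clipping.  Calibration checks (Wald interval coverage) are run in
regimes where η stays inside the unit interval; with strong effects the
clipping attenuates estimates, which is a known cost of the linear
probability shortcut, not of the implementation.  Fitted surfaces are
min–max rescaled to [0, 1] over the whole run to give relative occurrence
probabilities, then averaged across trait models and the five
presence-background variants.

## Presence-background dataset variants

Five rules convert point records to unit presences: raw points (half-open
cell membership, `[x0, x1) × [y0, y1)`, upper/right landscape boundary
clamped inward), 50-km and 150-km buffers (unit centroid within the radius
of any record; planar Euclidean in synthetic mode), the closed bounding box
of the records, and the bounding-box variant filtered by overlap between
the unit's elevation interval and the species' recorded elevation range
(the filter is a correction for the type-1 errors the box introduces, so it
composes with the bbox variant; starting from raw points is available
behind a flag).

## Diversity layers

Per-unit "abundances" are the summed presences from K = 20 Bernoulli draws
of the averaged occurrence probabilities.  Four features are computed:

* **Species alpha**: richness (q = 0) interpolated/extrapolated to 98.5%
  sample coverage.  Coverage is `1 − (f1/n)·[(n−1)f1/((n−1)f1 + 2f2)]`;
  extrapolation uses the Chao1 unseen-species estimate
  (`f1²/(2f2)`, or `f1(f1−1)/2` when f2 = 0) with the extrapolation size
  m* solved from the coverage equation.  When the observed coverage already
  meets the target the observed richness is returned — diversity is never
  rarefied below what was detected, a deliberate convention for sparse
  tropical samples where every detected species counts.  When f2 = 0 the
  coverage curve cannot reach the target and the asymptotic estimate
  S_obs + f0 is used.
* **Trait alpha**: the same estimator applied to functional entities.
  Entities are complete-linkage clusters of the weighted Gower trait
  distance cut at τ, the abundance-weighted mean pairwise distance of the
  pooled assemblage (τ = Σ p_i p_j d_ij).  Complete linkage means every
  within-entity pair is closer than τ; single linkage was rejected because
  with τ equal to the *mean* distance it chains any realistic species pool
  into a single entity (nearest-neighbour distances are far below the
  mean), which collapses the layer to a constant.
* **Species beta**: one minus the mean Jaccard-type similarity between the
  focal unit and every other non-empty unit.  For a pair, D_γ is pooled
  richness, D_α is the joint species × assemblage item count divided by 2,
  and U = 2/D_β − 1 (q = 0, λ = 1).
* **Trait beta**: as above at q = 2 with the quadratic attribute-diversity
  framework (λ = 2) under τ-truncated distances: FD_γ from the pooled
  relative abundances, FD_α from the 2S half-weighted items, both sharing
  the pooled Rao Q so D_β ∈ [1, 4], and U = (4 − D_β)/3.  Identical
  assemblages give U = 1, fully distinct disjoint ones U = 0.

Gower distances weight each continuous trait 1 and downweight the habit
and flower-color blocks so each block totals the weight of one continuous
trait (1/5 per habit, 1/7 per color).  The alternative reading — each block
equal to the *whole* continuous block — is one constant away in
`GowerWeights`.

## Prioritization

Minimum-shortfall selection: minimize Σ_f max(0, T_f − a_f·x)/T_f +
0.003 × exposed boundary, subject to Σ cost·x ≤ budget and locked-in units,
with T_f = target_fraction × total feature amount.  Shortfalls are
normalized by the target so features on different scales are commensurate.
The boundary term counts cell sides between selected and unselected units,
with outer-perimeter sides weighted by an edge factor of 0.5 (softening the
penalty for coastline units).  Unit cost is the mean of three 0–1 scaled
components (inverse accessibility, human footprint, population density),
floored at 1e-6.  Scenarios: target 30% with a 20% budget and target 70%
with a 35% budget.

Three solvers share the objective: an exact mixed-integer program (HiGHS
via `scipy.optimize.milp`; edge indicators are continuous because the
minimization makes them tight), a randomized greedy heuristic (best
marginal shortfall-minus-penalty gain per jittered cost, random
tie-breaking, seeded), and an exhaustive enumerator for ≤ 20 free units
used as the test oracle.

## Importance and trait impact

For each diversity feature separately, an ensemble of K randomized-greedy
scenarios (lognormal cost jitter, seeded sub-streams) is scored for target
achievement, and each unit gets

    importance = (included − removed) / (included + excluded)

where `included` counts achieving scenarios containing the unit, `removed`
counts those that drop below the target when the unit's amount is
subtracted (no re-solve), and `excluded` counts achieving scenarios without
it.  The formula yields 0 for a unit essential to *every* achieving
scenario; raw counts are always emitted so such units can be audited — the
formula is implemented as stated, not "corrected".  Trait impact is
importance(trait layer) − importance(species layer) for alpha and beta;
units with either delta positive are trait priority, units with both
negative are species priority, everything else (zeros) is neutral.  Carbon
and deforestation-risk importance is compared between the two classes with
a seeded bootstrap interval on the difference of means.

## The synthetic generator

The generator emulates the data structure of a sparse tropical-flora
inventory, not any real landscape's marginals:

* **Phylogeny**: pure-birth (Yule) trees with contemporaneous tips.  A
  hand-built backbone fixture covers every grafting rule for building the
  analysis tree from a genus/family backbone: polytomy at the genus crown,
  halfway insertion on a single-tip genus stem, new-genus binding at the
  midpoint between family stem and crown, the two-thirds rule for long
  family stems (attachment at the stem age minus one-third of the family
  branch), and unresolved reporting.
* **Traits**: five continuous traits are Brownian draws (log scale,
  z-scored); twelve binaries are Brownian draws thresholded at the median,
  so all traits carry phylogenetic signal; missingness is completely at
  random (default 30%, well under the 70% level where gap-filling is known
  to distort diversity indices).
* **Landscape**: all layers are Gaussian fields with an exponential spatial
  kernel.  Elevation is the master gradient: temperature falls with it,
  diversity rises along the occupancy model's environmental effects, and
  the three cost components concentrate in accessible lowlands with a
  right-skewed (exponential-link) distribution — as real scaled
  accessibility/population layers do, where a few peri-urban cells dominate
  the total.  That skew is what makes an ambitious representation target
  affordable, mirroring landscapes where most diversity sits in cheap
  remote uplands.
* **Occurrences**: presences are Bernoulli draws of the clipped linear
  predictor with all four random effects and the residual; one point record
  is placed uniformly inside each presence cell with an elevation uniform
  in the cell's range.  The generating parameters are stored for recovery
  tests.  The default intercept (0.15) puts mean occupancy across the five
  dataset variants in the sparse regime of a poorly collected flora.

What the generator does *not* emulate: collection bias fields, realistic
covariate marginals, mangrove/peatland structure, or geographic
coordinates (planar km geometry throughout).  Tests passing on this
generator show the machinery is correct and the directional findings
(trait × environment signal → negative δRMSE; trait layers reshaping
priorities) are recoverable — not that any particular real landscape
behaves this way.

## Numerical choices and degenerate inputs

* Covariances are floored to PSD by eigenvalue clipping (warning); the BM
  correlation gets a 1e-9 nugget before Cholesky.
* A constant fitted surface rescales to 0.5 everywhere (logged convention).
* A zero-depth tree yields the identity covariance; a single-unit grid a
  1 × 1 spatial covariance.
* σ_e² is floored at 1e-10 inside the optimizer; log-variances are clipped
  to [−30, 10].
* Greedy ties (scores within 1e-12) are broken uniformly at random under
  the scenario seed; without jitter and ties the solution is
  seed-independent.
* Empty units are excluded as beta-diversity partners and contribute 0 to
  the feature layers.
* All-equal trait columns z-score to zero with an sd := 1 guard.
* PCA variable selection skips variables already selected on an earlier
  axis, so the three selected variables are distinct; exact ties break by
  column order.

## Problem sizes used in the shipped checks

The test-suite and acceptance-script simulations run at 20–50 species on
4 × 4 to 10 × 6 grids with 6–20 replicate seeds, and the end-to-end demo at
30 species on an 8 × 8 grid — sizes chosen so the whole battery documents
every claim while staying comfortably interactive.  All components scale as
O(n(S+M) + (S+M)³) per likelihood evaluation, which reaches hundreds of
species and ~10³ units (the scale of a real regional flora analysis)
without algorithmic changes.

## Known limitations

* The Gaussian linear-probability likelihood is a computational shortcut;
  probabilities are only *relative* after rescaling, and calibration
  degrades when the linear predictor leaves the unit interval.
* ML variance components (vs. REML/Bayes) mildly understate fixed-effect
  uncertainty in small samples; the intercept interval is the most
  affected.
* Gower distances after block downweighting are not guaranteed metric;
  symmetry, zero diagonal and the [0, 1] range are asserted instead.
* The importance formula is ensemble-dependent: with a budget too tight for
  any scenario to achieve a feature's target, all importances for that
  feature are zero by construction.
* `brute_force` is exponential and refuses > 20 free units; the MILP is the
  exact solver at scale.
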