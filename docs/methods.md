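# Methods

This note documents the models and procedures implemented in `admkit`, the
design choices made where the design was genuinely open, and what the
synthetic tests do and do not demonstrate about real data.

## ENFA

Ecological Niche Factor Analysis contrasts the environment occupied by a
species against the environment available in the region. All layers are
standardized to global mean 0, sd 1 over valid cells; the standardization
constants are frozen at fit time so serialized models re-score rasters
reproducibly. The presence sample is the set of **distinct presence cells**
(duplicate records within one cell are collapsed: repeated museum records in
the same pixel carry no extra environmental information).

* **Marginality.** `m_i` is the mean standardized value of layer *i* over
  presence cells; the global index is `M = ‖m‖/1.96`. The 1.96 constant is
  the ENFA convention that makes `M ≈ 1` correspond to a ~2σ offset of the
  species mean from the regional mean.
* **Specialization.** The first factor axis is `u₁ = m/‖m‖`. The remaining
  axes maximize the ratio of global to presence variance in the subspace
  orthogonal to `u₁`: with `B` an orthonormal basis of that subspace, the
  generalized symmetric eigenproblem `(BᵀS_G B) v = λ (BᵀS_P B) v` is solved
  and axes are mapped back as `w = Bv`. The marginality axis gets
  `λ₁ = (u₁ᵀS_G u₁)/(u₁ᵀS_P u₁)` by the same ratio. Eigenvalues are clipped
  at 0 against numerical noise. Note that the specialization axes are
  presence-covariance-conjugate rather than mutually orthogonal in the
  Euclidean sense; each is unit-normalized (so per-axis loadings satisfy
  `Σ loading² = 1`) and all are exactly orthogonal to the marginality axis.
* **Tolerance.** `T = 1/√(Σλ_k/V)` with `V` the layer count: `T = 1` when
  the presence cloud is as spread as the region (all ratios 1), small `T`
  for specialists. When the presence sample is the whole region, `S_P = S_G`
  and `T = 1` exactly — this degenerate identity is tested.
* **Degenerate marginality.** If `‖m‖ ≈ 0` (below 1e-9) the species is
  indistinguishable from the regional mean and the first presence principal
  axis substitutes for `u₁`, with a logged warning.
* **Regularization.** Collinear climate layers routinely make the presence
  covariance near-singular; when its smallest eigenvalue falls below
  1e-10 of the largest, a ridge of 1e-6 is added to the diagonal and a
  warning is issued.
* **Retained factors.** The smallest set of factors — always including the
  marginality axis — whose summed |λ| reaches 80 % of the total. This is a
  deterministic stand-in for broken-stick selection; the fraction is a
  constructor parameter.

### Suitability scoring

The continuous 0–100 score uses a median-count ("as-or-more-extreme") rule.
For retained factor *k* with presence scores `s_p` and presence median
`med_k`, a cell `x` scores

    HS_k(x) = #{p : |s_p − med_k| ≥ |score_k(x) − med_k|} / N_presence,

i.e. the fraction of presence cells at least as far from the presence median
as the cell itself, both tails pooled. The combined score is the
|λ|-weighted mean of the `HS_k`, times 100. A cell at the presence median on
every factor scores exactly 100; a cell more extreme than every presence
scores at most `100/N`. Counting uses an absolute tie tolerance of 1e-9 on
the factor-score deviations so that integer counts do not depend on BLAS
evaluation order when a scored cell is itself a presence cell (verified
against an O(cells × presences) brute-force implementation).

## Auxiliary engines

Multi-engine workflows (cross-engine pseudoabsences, engine comparison)
need more than one engine; two simple deterministic ones are provided.

* **Percentile envelope.** Per layer, `score_i = 2·min(F_i, 1−F_i)` with
  `F_i` the mid-rank empirical CDF of the presence sample (mid-ranks make
  the presence median score exactly 1 and values outside the presence range
  exactly 0); the cell score is 100 times the minimum over layers.
* **Mahalanobis.** Squared distance to the presence centroid under the
  (ridge-regularized) presence covariance, rank-normalized over valid cells:
  `100·(1 − rank(d²)/n)` with average ranks for ties. Rank normalization was
  chosen over a χ² transform to avoid distributional assumptions; any
  monotone transform leaves the threshold machinery unchanged.

External rasters enter through an adapter that validates alignment and
scale (continuous values clipped to [0, 100]; ordinal rasters must already
be integers 1–10). Ordinal models are thresholded on their own 1…10
candidate grid.

## Pseudoabsences, metrics, thresholds

Pseudoabsences are drawn uniformly **without replacement** from the cells
another engine predicts absent, excluding cells holding any known presence;
one point is placed at each drawn cell center. The cross-engine pairing is
the caller's responsibility; a same-engine pairing triggers a warning, not
an error. The default design is balanced: as many pseudoabsences as test
presences. Museum records are split 75/25 (train/test) by a seeded shuffle
for every engine, ENFA included, so engines are compared on the same test
data.

Predicted presence at threshold `t` is `score ≥ t`. Candidate thresholds
are a finite scan — default {3, 20, 40, 60, 70, 80, 90} for continuous
scores, {1…10} for ordinal — matching interval-scan practice rather than a
continuous optimizer. Two rules select the binarization cutoff:

* **max-κ**: the candidate maximizing Cohen's κ;
* **ROC closest-point**: the candidate minimizing
  `√((1−sens)² + (1−spec)²)`; Youden's `J = sens + spec − 1` is available
  as a configuration alternative.

Ties go to the lowest threshold in both rules (the more inclusive map).
AUC is the trapezoid over the ROC points of the scan plus the degenerate
endpoints (0,0) and (1,1); with candidates at every distinct score it
equals the Mann-Whitney estimate exactly (tested).

The two threshold sets are compared across species with a Wilcoxon
signed-rank test: zero differences dropped, midranks for ties,
`W = min(W⁺, W⁻)`. For `n ≤ 20` the p-value is exact — the distribution of
`2W⁺` (doubled midranks are integers) is built by convolution, equivalent
to enumerating all 2ⁿ sign assignments — otherwise the normal approximation
with tie correction and continuity correction is used. P-values are
two-sided throughout; no α is hard-coded.

## PDM → ADM reduction

A PDM presence cell survives habitat masking iff the fraction of its
land-cover subcells (the land-cover grid must tile the model grid by an
integer ratio; 250 m inside 1 km gives 16 subcells) whose class is in the
species' habitat set reaches `suitable_fraction`. The default 0.5
(majority) is the neutral reading of "eliminating unsuitable areas" — the
original overlay rule is not documented — and the parameter is exposed;
the reduction is monotone in it. `ADM ⊆ PDM` is asserted on every run.

## Field validation

* **Site procedure.** Field points are collapsed to distinct model cells;
  success is the percentage of those cells the ADM predicts present.
* **Buffer procedure.** Disks of fixed radius (default 1 km) around all
  field points are merged; the buffer cell set is the valid cells whose
  **centers** fall in the union (boundary included). Cell-center membership
  was chosen over any-overlap because it matches pixel-count phrasing and
  is unambiguous; since the radius is at least `cell_size/√2`, each point's
  own cell always belongs to its buffer, so buffer totals dominate site
  totals.
* **Summaries.** Mean and **population** (n-denominator) standard deviation
  over species with at least one field presence cell.
* **Proportionality.** Pearson correlation between per-species museum and
  field counts, p from the t-transform with n−2 df, flags zero-variance
  input instead of dividing by zero.

## Synthetic data generator

The generator produces data with the statistical structure the analysis
assumes; its defaults are the package's study conditions.

* **Environment** (`gen_env_stack`): each layer is a seeded random mixture
  of `n_latent = 3` shared latent fields plus an idiosyncratic field
  (weight 0.35), all Gaussian-smoothed white noise (sd `autocorr_range = 8`
  cells), standardized per layer. The latent-factor construction mimics the
  strong collinearity of bioclimatic variable sets, whose effective
  dimensionality is far below the layer count; without it a planted niche
  of realistic width is empty in 6-D. Default grid 100×100 at 1 km.
* **Virtual species** (`gen_virtual_species`): Gaussian suitability
  `exp(−½Σ((z_i−c_i)/w_i)²)` in standardized space. `‖c‖` is exactly
  `1.96 × marginality_target`; the direction is that of a randomly drawn
  valid cell with norm near the target (a uniformly random direction in
  6-D usually points where no cells exist), and anchors yielding fewer than
  50 cells of suitability > 0.5 are redrawn (up to 25 draws) before the
  degenerate-niche error fires. Widths start at `tolerance_target`
  (default 0.5, the intermediate specialization level typical of dry-forest
  endemics) and are calibrated by fixed-point iteration so the
  suitability-weighted sd per layer ≈ the target.
* **Museum sampling** (`sample_occurrences`): cells drawn with probability
  ∝ truth^γ, γ = 2 by default (detection concentrates in good habitat);
  the point is uniform within its cell; optional hotspot clustering
  multiplies weights by a smooth bump field around seeded centers.
  Because sampling weights toward the niche center while the regional
  distribution pulls the presence mean toward 0, fitted `M` is mildly
  shrunk relative to the planted target (median ≈ 1.0 at target 1.2);
  recovery is assessed against a ±0.25 band and for monotonicity.
* **Land cover** (`gen_landcover`): a smooth field at a `subcell_ratio = 4`
  finer grid cut at area quantiles into `n_classes = 4` contiguous patch
  classes (patch scale 4 model cells ≈ a 4–8 km habitat mosaic at 1-km
  resolution); class 1 plays the focal natural habitat. The dominant class
  of a model cell is the modal subcell class, ties to the lowest code.
* **Field survey** (`simulate_field_survey`): 46 sites (one model cell
  each), up to 30 count points per site packed ≥ 200 m apart by seeded
  rejection sampling, detection Bernoulli(`detection_prob × truth`),
  `detection_prob = 0.8`. Sites are restricted to cells whose dominant
  class is suitable **and** whose truth suitability is ≥ 0.05, and are
  drawn with probability ∝ truth — surveys of this kind are expert-placed
  where the species is expected, and uniform placement over all habitat
  cells leaves narrow-niche species with a handful of field cells, unlike
  the dozens per species such surveys record. `truth_weight = 0` restores
  uniform stratified placement.

**What the generator does not emulate:** observation error in coordinates,
observer effort covariates, spatial sampling bias correlated with access
routes (beyond optional hotspot clustering), temporal land-cover change,
abundance (detections are presence-only), and climate–land-cover
correlation (land cover is independent of the layers). Passing tests
therefore show the pipeline's internal correctness and its behavior under
idealized niche structure, not robustness to these real-data pathologies.

## End-to-end study mirror

`run_study(seed, StudyConfig())` runs, per species: museum sample (n = 120)
→ 75/25 split → ENFA fit → suitability → pseudoabsences from the
percentile-envelope engine's predicted absence (envelope score < 5) →
threshold scan → max-κ binarization (ROC rule available) → habitat masking
(majority rule) → simulated survey → both validation procedures; then
stacked richness and, when threshold pairs differ, the Wilcoxon comparison.
Everything derives from one master seed via `SeedSequence`; reruns are
bit-identical and the resolved configuration is logged.

At these defaults the median site and buffer success over 20 replicates
falls in the 50–85 % range, the range observed in the motivating field
study of twelve dry-forest endemics; the published per-species statistics
bundled in `admkit.datasets` (proportionality r, success-rate mean 68 %,
population sd 8.0) are recomputed exactly from the printed counts.

## Problem sizes and numerical choices

Tests use 30×30 and 60×60 fixtures for oracle equivalence (brute-force
reference implementations are O(cells × presences)); parameter recovery and
the end-to-end mirror use 20 seeded replicates of 100×100 landscapes, the
size at which a 1-km cell study region of ~10⁴ cells is well represented
while the full suite stays under a minute. Exact-equality assertions are
used wherever the quantity is an integer count or a deterministic
transform; stochastic checks assert medians over seeds against bands, never
single draws. Key tolerances: 1e-9 tie tolerance in suitability counting,
1e-6 covariance ridge, 1e-9 zero-marginality cutoff, eigenvalue clipping at
0 with a −1e-8 test tolerance.

## Known limitations

* Suitability scoring reproduces the documented median-count rule, not any
  particular legacy software's numeric output; printed per-species M/T
  values from real studies are treated as qualitative context.
* The ROC "sensitivity maximized, 1−specificity minimized" criterion is not
  a single rule; the closest-to-corner distance is the default
  operationalization and Youden's J the alternative.
* Buffer membership by cell center under-counts partially covered edge
  cells relative to any-overlap rules.
* The Wilcoxon normal approximation (n > 20) differs from the exact tail by
  O(1/√n); exact mode covers every study-sized comparison.
* ENFA specialization axes are conjugate, not orthogonal, across factors
  (see above); variable-importance specialization scores aggregate
  |λ|·|loading| over non-marginality factors and should be read as ranks.
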