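# Methods

## Data model and preprocessing

A tracing dataset is a triple: a T×N FLN matrix (row i = injected target,
column j = source area, entries in [0, 1], zero diagonal for each target's
own column), an N×N symmetric barycenter distance matrix in mm, and an atlas
(ordered area names, region labels, injected subset).  Validation enforces
entry ranges, shape/name consistency and distance symmetry to a relative
tolerance of 10⁻⁶ (distances are estimated path lengths, not exact
geometry).  CSV I/O writes `repr()` floats so a save/load round trip is
bit-identical.

Weights are w = 7 + log₁₀(FLN), zeros left as zeros.  FLN below 10⁻⁷ maps
below 0; such entries are kept (the 0–7 range is empirical, not a
constraint) and flagged with a warning.  Distances are rescaled to
31·D/D_max, which is invariant to uniform rescaling of the input units.
Weight classes use inclusive thresholds (strong w ≥ 5, medium-&-strong
w ≥ 3, medium-&-weak w ≤ 5, weak w ≤ 3), so boundary weights belong to both
adjacent classes.

## Predictors

**Classical scores** are out-neighborhood adaptations of common neighbors,
preferential attachment, Adamic–Adar, resource allocation and Jaccard,
since only out-link information (into injected targets) exists for every
candidate pair.  Conventions where the formulas are underdetermined:

* The out-neighborhood Γo(x) = {z ∈ I_train : w(z, x) > 0} excludes x
  itself by default; a `gamma_includes_self` switch adds x as a zero-weight
  member of its own neighborhood (changing only the PA2 denominator), since
  both readings of "neighbors of u, including itself" are defensible and no
  worked value disambiguates them.
* AA2 skips terms whose out-strength is ≤ 1 (log-denominator ≤ 0),
  mirroring the degree ≥ 2 convention of classical Adamic–Adar; the log is
  natural — base changes only rescale scores and leave rankings, hence
  ROC/AUC, invariant (asserted in tests).
* A PA2 factor with an empty neighborhood is 0, not NaN: an area with no
  observed out-links carries no preferential-attachment mass.
* JA2 returns 0 when numerator and denominator are both 0.

**Feature vectors** follow eight specifications from a single scalar
(weighted common neighbors) to the full FLN-plus-distance vector of length
2·|I_train| + 1.  Per-target entries are interleaved (A(i,u), A(i,v)) with
i ascending in global area order.  Entries indexed by i = u or i = v are
masked to 0: when the pair's own target is a training row, the entry
A(v, u) *is* the label, and masking (rather than dropping, which would
change dimensionality per pair) prevents ground truth from leaking into
training features; an `endpoint_policy` for the alternative is deliberately
not offered because the leakage variant corrupts test-time semantics.
Out-degrees d(x) count strictly positive out-weights into I_train,
excluding the masked rows for the same reason.  Distance entries use the
scaled 0–31 features.

**Learners** are scikit-learn estimators behind a uniform fit/predict
contract: KNN (n_neighbors 5, leaf 30; k shrinks to the training size on
tiny leave-one-out sets), DT (defaults), RF (200 trees, Gini for
classification), MLP (one hidden layer of 100, tol 10⁻⁶, max 20 iterations
— kept that small deliberately; convergence warnings are silenced and an
override exists), GB (100 stages, max depth 7), ADA (defaults), NBA
(Gaussian, classifier only).  Classifier scores are positive-class
probabilities (or min-max-scaled decision values) so ROC curves are
well-defined; regressor outputs outside [0, 7] are flagged, never silently
clipped.  DT/ADA/NBA are supported but excluded from headline reports —
they underperform the other four.

## Cross-validation and evaluation

Folds partition the injected targets (sizes differing by ≤ 1) after a
seeded random permutation, repeated R times; defaults k = 3, R = 100, both
configurable (tests and the acceptance script use R = 5–10: repetitions
narrow the sd of the mean metric but do not move it).  Candidate pairs are
all (u, v) with v injected and u ≠ v; training uses only training-fold rows
for features, scores *and* labels.  A density guard warns when nonlinks are
under 5% of pairs (the mouse regime, 97% dense, where binary classification
is uninformative).

ROC curves sweep unique score thresholds (deterministic, tie-safe); AUC is
the trapezoidal area, verified in tests against a brute-force
concordant-pair oracle to 10⁻¹².  The max-accuracy threshold is found
numerically on each repetition's ROC and averaged.  Per-pair averaged
binary predictions ⟨y_pred⟩ use each repetition's own threshold; the
per-link error is |y_true − ⟨y_pred⟩|.

Weighted runs report MAE and RMAE by stratum (weak, weak-&-medium,
medium-&-strong, strong, all links, nonlinks, both; strict inequalities at
stratum boundaries).  For nonlinks the relative error substitutes the
cutoff w_cut = 0.9 for the ground truth in numerator and denominator
(|w_pred − 0.9|/0.9) — the substitution, not a denominator-only division,
is what makes the published nonlink MAE/RMAE pair mutually consistent; a
`nonlink_rmae="denominator_only"` flag gives the other reading, and a flag
switches 0.9 to the unrounded 7 + log₁₀(8×10⁻⁷).

Class-restricted runs keep in-class links as positives and nonlinks as
negatives, excluding out-of-class links from training labels and scoring
(`within_class`); `train_class_predict_all` restricts training only and
decomposes scored pairs by their true class, skipping classes absent from
the data.  Error matrices align to the (target row, source column) layout
with region×region unweighted block means (self-pairs excluded); error
profiles use 20 equal-width bins by default, flagging bins with fewer than
3 points.  Residual diagnostics report the mean residual and Spearman
correlations of r and |r| with the prediction, declaring the scatter
"featureless" below |ρ| = 0.1 (configurable).  The leave-one-out scaling
analysis draws random subsets of m targets (500 repetitions by default),
predicts each member's out-links within the subset from the other m − 1
rows, and averages internal RMAE per stratum.

## Synthetic data generator

The generator emulates the study conditions, not any particular dataset:

* **Geometry**: uniform points in a box (dimension 3 by default), rescaled
  so the largest pairwise distance hits a target D_max exactly (58.2 mm
  macaque-like, 12 mm mouse-like); regions are k-means clusters of the
  positions — purely to give regional analyses block structure, with no
  anatomical meaning.
* **EDR network**: n projections assigned independently to ordered pairs
  with probability ∝ e^(−λd); per-target counts normalized to FLN rows
  (rows sum to 1), zero-count pairs are nonlinks.  λ = 0 degenerates to
  uniform assignment.  The projection count is calibrated by bisection on
  the *expected* coverage so realized binary density matches the species
  value (0.66 / 0.97) deterministically.
* **Weight spread**: species presets multiply link FLNs by a lognormal
  factor of one decade sd and renormalize rows.  Rationale: a pure count
  model at the calibrated density cannot produce FLN below ~N/n
  (compressing the weak tail), while empirical FLN scatters about a decade
  around the EDR trend; one decade restores the ~10⁻⁷–1 range.  The sd is a
  preset parameter, not a fitted quantity.
* **λ recovery**: the decay rate is estimated by maximizing the exact
  likelihood of the discrete pair-assignment model,
  ℓ(λ) = −λΣl − n·log Σᵢ e^(−λdᵢ); the naive exponential estimator 1/⟨l⟩
  is biased by the finite pair-distance distribution and is not used.
* **Controls**: degree-preserving double-edge swaps (weights travel with
  their link; no self or duplicate links) give a configuration-model null;
  a weight-noise harness perturbs log-weights of existing links only, for
  parameter-recovery studies.

What the generator does **not** emulate — and hence what green tests do not
show about real cortices: weak/long-range links in EDR networks are still
distance-rule generated and therefore predictable (AUC ≈ 0.76–0.84 within
the weak class), whereas in empirical data they sit at chance; regional
blocks are spatial clusters, not lobes; inter-individual variability,
injection-site artifacts and FLNe normalization subtleties are absent.
Relations that do transfer: overall binary AUC far above chance at these
densities, RMAE decreasing from weak to strong links, predictability
collapse under configuration rewiring, and the mouse-like condition's
higher weighted predictability.

## Imputation

A regressor trained on all observed rows (features from observed rows only,
endpoint masking as always) predicts every pair whose target was never
injected.  Observed entries are copied bitwise; the raw regressor channel
is kept alongside a [0, 7]-clipped reporting channel; no thresholding of
weak imputed weights is applied by default.  Repeated fits with derived
seeds give a per-entry spread.  An optional predictability gate refuses
imputation when a quick binary CV's AUC fails to clear a user-set bound,
since imputation is only meaningful on data with demonstrated
predictability.  Weighted imputation is primary; binary imputation via the
max-accuracy threshold is available through the CV report.

## Reproducibility and problem sizes

A single seed expands into per-stage seeds through a fixed 64-bit mixing
scheme (`derive_seed`), so partial reruns reproduce exactly; fold plans,
geometry, network draws and learner seeds are all derived.  Tests and the
acceptance script run the macaque-like condition (29 of 91 areas) with
R = 5–10 repetitions of 3-fold CV and the scaling analysis at small subset
counts — sizes chosen so the whole suite runs in a few minutes while
leaving every metric's mean essentially unchanged.

## Known limitations

* The EDR stand-in is more predictable than real cortical data (binary AUC
  ≈ 0.9 vs 0.8 reported on empirical macaque data); absolute error levels
  on synthetic runs should not be read as empirical estimates.
* MLP at 20 iterations rarely converges; this is by design (the configured
  analysis), not a recommendation.
* Classical scores are symmetric in (u, v) by construction, so they cannot
  distinguish link direction within a pair; direction information enters
  only through the ML features.
* The imputation is the straightforward train-on-all-rows scheme; no
  uncertainty calibration beyond across-sample spread is attempted.
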