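# Methods

## Model

`pcmlab` fits regression models of half-maximal inhibitory potency,
pIC50 = −log₁₀(IC50 [M]), over compound–target *pairs*. Each pair's feature
vector concatenates:

- **Ligand block.** Hashed Morgan count fingerprints: every atom-centered
  circular substructure up to the configured radius (default 2, i.e. a
  diameter of four bonds) is hashed into a fixed-length count vector
  (default 512). Counts rather than bits preserve multiplicity. An
  *unhashed* sparse-identifier mode is available for interpretability, but
  the fixed-length hashed form is the default because a fixed column count
  is what the rest of the pipeline (filters, hat matrix) consumes.
  Physicochemical descriptors come from a pluggable provider; the bundled
  provider computes 20 simple RDKit 2D descriptors (counts, Chi/Kappa
  indices, logP, TPSA, ...). Any external descriptor engine can be
  registered under the same interface, which is how large descriptor sets
  (hundreds of columns) are expected to be supplied in real studies.
- **Protein block.** Each binding-site residue is encoded by the five
  Z-scale principal-property values (Sandberg et al. 1998; shipped as a
  data file with its citation, never typed inline). An L-residue site gives
  5L descriptors named `Z{k}_Aa{position}`, position-major. Positions are
  1-based alignment-column (or residue-number) indices shared across
  targets, so homologous sites occupy the same coordinates — the property
  PCM requires. Site residues can be taken from an alignment directly or
  selected from a structure: a residue is in the cavity iff any of its
  heavy atoms lies within the cutoff (default 10 Å) of the bound ligand's
  unweighted heavy-atom centroid. Centroid-to-residue-atom (rather than
  Cα-only or atom-to-atom) is deliberately inclusive, to avoid missing
  borderline contact residues.

The model assumes one shared descriptor space across targets, additivity of
ligand and protein contributions up to what the learner can represent, and
i.i.d. measurement noise on pIC50.

## Preprocessing

Fixed order: impute → near-zero variance → correlation → center/scale.

- **Imputation**: NA/±Inf → column mean over finite entries; an all-NA
  column becomes 0 and is reported.
- **Near-zero variance**: a column is dropped when
  (count of most frequent value)/(count of runner-up) > 30, or when it is
  constant. Only the frequency-ratio criterion is used; there is no
  unique-value-percentage rule.
- **Correlation filter**: while any pair of remaining columns has
  |Pearson r| ≥ 0.95, the most-correlated pair is found and the member with
  the larger mean absolute correlation to the other remaining columns is
  removed (ties toward the first member). Removal order is returned so the
  decision trail is auditable; the output provably contains no pair at or
  above the cutoff.
- **Scaling**: per-column mean/SD (sample SD, n−1) estimated on training
  rows only and applied unchanged to test rows. Fitting on all rows before
  the split is a documented legacy option (`preprocess_scope="all"`), but
  train-only is the default to avoid leakage. A column that is constant
  *within the training rows* (yet survived the global filters) carries no
  fittable signal and is dropped at this point with a count in the summary.
- **Split**: rows are binned by response quantiles (default quartiles; the
  bin count is a free choice — quartiles are the coarsest stratification
  that still pins the response distribution), shuffled per bin under the
  seed, and apportioned by largest remainder so the global training size is
  exactly round(0.7·n) — 312 pairs always give 218/94.

## Learners and tuning protocol

All three base learners are standard scikit-learn estimators behind a thin
adapter; the package's contribution is the protocol, not the tree/kernel
math. One k-fold assignment (default k = 10, the community convention for
this workflow) is created once and shared by every algorithm and every grid
point. For each grid point the out-of-fold predictions are pooled and the
winner is the point with the smallest pooled-OOF RMSE (ties toward the
earlier grid point); the winner is refit on the full training set. Default
grids bracket common practice and include the reference values: RF mtry ∈
{p/3, 128, 256, p/2} (capped at p, 500 trees); SVM-RBF σ ∈ {0.001, 0.01,
0.1} × C ∈ {1, 3, 10} (σ in the kernlab convention, k(x,y) =
exp(−σ‖x−y‖²), which maps to scikit-learn's `gamma`); GBM 500 trees,
depth 25, 20 minimum node observations, learning rate ∈ {0.04, 0.08, 0.12,
0.16}. Every stochastic fit receives an explicit seed; SVM relies on the
single scaling authority of the features stage rather than rescaling
internally.

Variable importance: impurity importances for the tree models, permutation
importance for SVM; the default report length is the top 21.

## Ensembles

Both combiners train strictly on out-of-fold prediction columns.

**Greedy integer-count selection.** Counts start at zero; at each of
n_iter = 1000 iterations every single-count increment is scored by the RMSE
of the count-weighted mean of OOF columns, and the best one is committed
only if it *strictly* reduces the RMSE (candidate ties toward the lowest
model index). Because a one-count step has size 1/(total+1) in weight
space, a step can overshoot near the optimum and no single increment
improves; the iteration then doubles all counts — leaving the weights and
RMSE untouched — so subsequent steps are finer. This refinement-on-stall
rule keeps the committed-iteration RMSE log strictly decreasing (an
asserted invariant) while converging to the minimum of the RMSE — a convex
function of the weights — over the weight simplex, in the manner of
Frank–Wolfe with step 1/(t+1). Refinement stops once total counts exceed
10⁹ (weight resolution far beyond reported precision). The unconditional
always-commit variant is available (`strict_improvement=False`); its log
need not be monotone. Final counts are normalized to weights summing to 1.

**Stacking.** A meta-model (linear, elastic net, linear SVM or RBF SVM) is
fit on the OOF columns; linear meta-models expose their coefficients as
relative model contributions. "Best"-style ensembles over only the
per-algorithm winners are expressed by passing the model list explicitly.

## Validation suite

For observed/predicted test vectors: R²test is the squared Pearson
correlation (the QSAR convention), k = Σ(y·ŷ)/Σŷ² the through-origin
slope, R²₀ = 1 − Σ(y−kŷ)²/Σ(y−ȳ)², and the Golbraikh–Tropsha flags are
(R²−R²₀)/R² < 0.1 and 0.85 ≤ k ≤ 1.15 (R² = 0 fails the ratio with a
recorded reason). Q²F1/F2/F3 differ in the reference variance (training
mean, test mean, training variance with population denominator). Both
R²test and Q²F2 are reported so the correlation/determination distinction
stays visible. Internal R²꜀ᵥ/RMSE꜀ᵥ are computed from the pooled OOF vector
against the observed training responses (one number, not a fold average).

**Theoretical bounds.** Measurement noise bounds any model's observable
performance: each of n_sim = 1000 replicates simulates pseudo-predictions
ỹ = y_test + N(0, σ²) and records R²₀(y, ỹ) and RMSE(y, ỹ); the summaries
(mean, 5/95% quantiles) describe the best reachable R²₀ and lowest
reachable RMSE. σ defaults to 0.68 pIC50 units — a published estimate of
the reproducibility of heterogeneous public IC50 data — and is
configurable, since E(RMSE floor) ≈ σ makes the choice visible in the
output. σ = 0 gives exactly 1 and 0.

**Applicability domain.** Leverage h = x(XᵀX)⁻¹xᵀ over the scaled training
design, threshold h* = 3p/n (p = descriptor count, n = training rows; when
p/n makes h* ≥ 1 every point is inside on leverage — logged, not
"corrected"). Implementation uses one SVD of X with a single rank cutoff
for both the leverages and the trace, so Σ training leverages = rank(X)
holds to machine precision even for ill-conditioned designs. Standardized
residual s = residual / sample SD of training residuals; the pipeline uses
*out-of-fold* training residuals as the reference scale, because flexible
learners nearly interpolate the training rows and resubstitution residuals
would understate the SD and flag most points as outliers. Flags: outlier
iff |s| > 3; influential iff h > h* and |s| ≤ 3.

## Synthetic studies

The generator emulates the *shape* of a curated two-isoform inhibitor set:

- **Compounds**: scaffolds decorated with 0–3 substituents at random C/N
  attachment points, deduplicated by canonical SMILES until the requested
  count of distinct, valid, organic molecules is reached. Default scaffolds
  (pyrazole, quinoline, oxamate-like, pyridine) echo known inhibitor
  chemotype families of the two-isoform dehydrogenase setting; defaults of
  156 compounds × 2 targets give 312 pairs, a realistic curated-set size.
- **Sites**: two equal-length sequences over the 20 standard letters,
  differing at exactly `n_differing_positions` (default 12 of 88 — a
  minority of cavity positions, as expected for isoforms).
- **Responses**: pIC50 = 6.5 + Σ w_d·d + N(0, noise_sd²) with weights on
  *named* descriptor coordinates (fingerprint bit or Z-scale position), so
  the ground truth is independent of hashing order. By default eight
  high-variance fingerprint bits (|w| ∈ [0.35, 0.70]) and three Z1
  coordinates at differing positions (|w| = 0.3) carry signal; noise_sd
  defaults to 0.4 pIC50 units, within the range of public-database
  reproducibility estimates. Pairing is complete (a sparsity fraction
  exists for sparse designs), and the generating weights, intercept, noise
  SD and noiseless responses are stored with every dataset.

What passing tests on this generator do and do not show: they demonstrate
that the pipeline recovers a known additive signal through the full
featurization/filter/model stack at realistic noise, and that every
bookkeeping contract (determinism, filter order, shared folds, OOF-only
ensembling) holds. They do not show performance on real inhibitor data:
real sets have activity cliffs, nonadditive interactions, assay
heterogeneity, sparse and biased pair coverage, and descriptor/response
correlations the linear generator does not produce.

## Numerical choices and degenerate inputs

- Exact-arithmetic invariants are asserted, not assumed: leverage trace =
  rank (1e-9), weights sum to 1 (1e-12), scaled training columns mean 0/SD 1
  (1e-9).
- Constant prediction vectors: R²test is reported as 0 (no correlation
  signal) rather than NaN; k is NaN only when Σŷ² = 0.
- `h* ≥ 1`, rank-deficient designs, all-NA columns and provider failures
  are all handled by reporting, never by silent correction.
- Tie-breaks are deterministic everywhere (grid order, lowest model index,
  first pair member) so reruns are bit-identical.

## Problem sizes

The shipped study sizes are chosen as the smallest that exercise every code
path at realistic signal-to-noise: unit tests run at 10–120 pairs; the
recovery experiment in `scripts/acceptance.py` uses 600 pairs (300
compounds × 2 targets), 10-fold CV and the reference hyperparameter values
as single-point grids, completing in about a minute on one CPU.

## Known limitations

- No tautomer/protonation normalization, no salt stripping, no 3D
  descriptors or conformers.
- The bundled physicochemical provider is intentionally small; large
  descriptor sets require an external engine behind the provider interface.
- No alignment computation (alignments are consumed, not built) and no
  structure superposition.
- No y-scrambling or bootstrap confidence intervals on metrics.
- Bagged random forests do not interpolate training data (resubstitution
  predictions average out-of-bag trees), so their training R² plateaus
  near 0.98 even on noiseless data; cross-validated and test metrics are
  unaffected.
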