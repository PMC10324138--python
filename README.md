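# pcmlab

Proteochemometric (PCM) modeling of compound–target bioactivity in Python.

QSAR models relate a compound's structure to its potency against one fixed
target. Proteochemometrics generalizes this to the *interaction space* of a
compound series and a protein family: the modeling unit is the
(compound, target) pair, each row of the design matrix concatenates ligand
descriptors with binding-site descriptors, and a single regression model
predicts pIC50 = −log₁₀(IC50 in molar) across all targets at once. This lets
one model interpolate between chemistries *and* between homologous binding
sites — e.g. the two isoforms of an enzyme — and ask what drives selectivity.

`pcmlab` implements the full workflow for medicinal/computational chemists:

- **Curation** — SMILES standardization (canonical-form duplicate removal,
  inorganic filtering that never excludes molecules for halogen count or
  mass), IC50→pIC50 transform, replicate averaging per pair.
- **Ligand descriptors** — hashed Morgan count fingerprints (default length
  512, radius 2 ≙ diameter 4 bonds) plus a pluggable physicochemical
  descriptor provider (a minimal RDKit 2D provider is bundled; any external
  engine can be registered).
- **Binding-site descriptors** — alignment parsing (FASTA/Clustal), optional
  cavity-residue selection from a PDB structure (any residue heavy atom
  within a cutoff of the bound ligand's heavy-atom centroid), and the five
  Z-scale principal-property descriptors per site residue (5L descriptors
  for an L-residue site, named `Z{k}_Aa{position}`).
- **Preprocessing** — mean imputation, near-zero-variance filter
  (frequency-ratio cut-off 30/1), iterative pairwise-correlation filter
  (|r| ≥ 0.95), centering/scaling fit on training rows, stratified 70/30
  split on response quantiles.
- **Models** — random forest, RBF-kernel SVM and gradient boosting tuned
  over explicit grids on one *shared* k-fold assignment, selected by minimum
  RMSE of pooled out-of-fold (OOF) predictions.
- **Ensembles** — greedy integer-count weight selection on the OOF columns
  (weights normalized; committed iterations strictly reduce RMSE) and
  stacking meta-models (linear, elastic net, linear/RBF SVM).
- **Validation** — R²꜀ᵥ/RMSE꜀ᵥ from pooled OOF predictions; external R²,
  through-origin R²₀ and slope k with the Golbraikh–Tropsha criteria
  ((R²−R²₀)/R² < 0.1, 0.85 ≤ k ≤ 1.15); Q²F1/F2/F3; RMSE/MAE; theoretical
  best-case R²₀/RMSE distributions implied by the experimental uncertainty
  of the response; leverage-based applicability domain with h* = 3p/n
  (Williams plot export).
- **Synthetic studies** — a generator producing valid decorated-scaffold
  molecules, two homologous binding sites, and pIC50 values from a known
  linear model over descriptor coordinates plus Gaussian noise, with the
  ground truth stored for recovery testing.

## Worked example

Run an end-to-end synthetic study from Python (or equivalently
`pcmlab run --out rundir` with a YAML config):

```python
from pcmlab.pipeline import RunConfig, run_pipeline

config = RunConfig(
    synthetic={"n_compounds": 60},        # 60 compounds x 2 targets = 120 pairs
    grids={"RF": [{"mtry": 64, "n_trees": 100}],
           "SVM-RBF": [{"sigma": 0.01, "C": 3}],
           "GBM": [{"shrinkage": 0.16, "n_trees": 100}]},
    cv_k=5, ensemble_n_iter=100, bounds_n_sim=100, seed=11,
)
summary = run_pipeline(config, "demo_run")
```

which prints (via `pcmlab run`) and stores in `demo_run/summary.json`:

```
columns: {'raw': 972, 'post_nzv': 241, 'post_correlation': 166}
split: {'n_train': 84, 'n_test': 36}
RF: R2cv=0.685 RMSEcv=0.971 R2test=0.789 RMSEtest=0.928
SVM-RBF: R2cv=0.091 RMSEcv=1.579 R2test=0.313 RMSEtest=1.481
GBM: R2cv=0.794 RMSEcv=0.739 R2test=0.766 RMSEtest=0.842
EN greedy: R2cv=0.794 RMSEcv=0.739 R2test=0.766 RMSEtest=0.842
EN stacking linear: R2cv=0.796 RMSEcv=0.728 R2test=0.778 RMSEtest=0.822
```

Reading the output: the raw pair matrix has 972 descriptor columns
(512 fingerprint + 20 bundled physicochemical + 440 Z-scale); the
near-zero-variance filter removes sparse fingerprint bits and conserved
Z-scale positions (972→241) and the correlation filter collapses redundant
blocks (241→166). The 120 pairs split 84/36 (70/30, stratified on pIC50).
GBM is the best single model by cross-validated RMSE; the greedy ensemble
puts all its weight on it, while linear stacking squeezes out a slightly
lower test RMSE (0.822 vs 0.842). The run directory also contains the
Williams-plot data (`williams_plot.csv`: leverage, standardized residual and
h* per pair), the theoretical performance bounds, the per-stage artifacts
and a content-hash manifest; re-running the same config reproduces every
number.

Real data enter through the same `RunConfig` with `bioactivity_csv`,
`smiles_file` and `site_files` instead of the `synthetic` block.

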