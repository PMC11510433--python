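# dessol

Solubility modeling of active pharmaceutical ingredients (APIs) in choline
chloride- and betaine-based deep eutectic solvents (DESs), built from
COSMO-RS-style σ-potential descriptors.

The package covers the full modeling pipeline:

- **`sigma_profiles`** — σ-potential curves on the canonical 61-point grid
  (−0.03 … +0.03 e/Å², step 0.001): mixture weighting by solute-free mole
  fractions, relative (solute − solvent) potentials, 6/12-bin step-function
  coarse graining, HBA/HYD/HBD region decomposition, plain-text I/O.
- **`thermo`** — ideal solubility of the pure solid from fusion data
  (Tm, ΔHfus) with the ΔCp ≈ ΔHfus/Tm approximation (overridable).
- **`dataset`** — solubility records (log10 mole fraction), subset
  classification (neat / binary / dry DES / wet DES), CSV I/O, seeded 80/20
  splitting, per-subset and per-HBA counting, coverage maps.
- **`descriptors`** — the six descriptor sets (A1=12, A2=11, B1=18, B2=17,
  C1=62, C2=61 values) assembled from binned relative σ-potentials, five
  relative interaction-energy terms and an optional computed-solubility
  feature.
- **`scoring`** — RMSD, MAPE, 3σ-outlier percentage, and a composite loss
  that penalizes positive log-solubility predictions, outliers, and the
  train/validation gap of a five-point, five-fold-CV learning curve.
- **`model_search`** — a registry of regressor families (nuSVR, ε-SVR,
  random forest, gradient boosting, k-NN, ridge/lasso/linear, MLP) with
  declared search spaces, tuned by a small seeded tree-structured Parzen
  estimator (`dessol._tpe`, self-contained), plus held-out evaluation, an
  overfitting screen, and the published nuSVR hyperparameter preset
  (C=6.8251, degree=8, gamma=0.8358, max_iter=61378442, nu=0.4754).
- **`labcalc`** — shake-flask assay arithmetic: calibration lines, ICH
  LOD/LOQ, absorbance → concentration, molar masses from molecular formulas,
  concentration → mole-fraction conversion in 1:2 HBA:HBD eutectics.
- **`synthetic_data`** — archetypal σ-potential generators and a
  ground-truth-driven dataset simulator, so every stage is testable without
  proprietary inputs or the (non-deposited) measured dataset.

## CLI

```sh
# synthetic dataset with known ground truth
dessol simulate --solutes 12 --systems 20 --temps 25,30,35,40 --noise 0.15 --seed 3 --out sim/

# tune regressors on synthetic data and report train/test metrics
dessol tune --set B2 --trials 50 --seed 7 --regressors nusvr,ridge --out report.json

# calibration-curve fitting and concentration readout
dessol labcalc --curve pc.csv --absorbance 0.27728 --dilution 1
```

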