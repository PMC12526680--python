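# cropstack

Physics-aware crop recommendation from tabular soil/climate records
(N, P, K, temperature, humidity, pH, rainfall).

The core idea: each crop has an ideal temperature and soil pH, recorded as a
per-crop (mean, standard deviation) table — the *knowledge base*.  An
observation is scored against a crop's optimum with an unnormalised Gaussian
kernel (1 at the optimum, decaying with deviation).  A three-layer ReLU
classifier is trained with a composite loss

```
total = cross_entropy + lambda_physics * physics_penalty
```

where the penalty `1 - p(crop) * temp_score * ph_score` (averaged over
samples and crops) discourages confidence in crops that are physically
implausible for the sample's raw temperature/pH.  That network joins random
forest, extra trees and gradient-boosted trees as base learners of a stacking
ensemble whose out-of-fold class probabilities feed a multinomial logistic
meta-learner.

Also included:

- **`cropstack.synthetic`** — seeded, class-conditional synthetic dataset
  generator (balanced classes, temperature/pH clustered at knowledge-base
  optima) plus a label/feature corruption tool, so the whole pipeline is
  testable without any external download.
- **`cropstack.data_prep`** — CSV reading with validation, train-only min-max
  scaling (leakage-free), stratified splits and k-fold plans.
- **`cropstack.evaluation`** — confusion matrices, macro precision/recall,
  stratified cross-validation reports (mean ± population std over folds).
- **`cropstack.search`** — hyperparameter search: exhaustive grid, seeded
  random sampling, and an adaptive tree-structured Parzen strategy.
- A `cropstack` CLI wiring everything into reproducible runs.

A 22-crop illustrative knowledge base ships with the package
(`cropstack/data/default_kb.json`); every run records its SHA-256 hash for
provenance.  For real analyses supply a curated table (JSON or CSV with
columns `label, mu_temp, sigma_temp, mu_ph, sigma_ph`).

## CLI

```bash
# synthetic dataset + paired knowledge base
cropstack simulate --out-dir sim --seed 42

# 5-fold CV + final fit of the physics stacking ensemble
cropstack train --dataset sim/dataset.csv --kb sim/knowledge_base.json \
    --out-dir run --model stacking --seed 42

# constraint-penalised network only; --lambda-physics 0 gives the plain network
cropstack train --dataset sim/dataset.csv --kb sim/knowledge_base.json \
    --out-dir run-pinn --model pinn --lambda-physics 0.1

# hyperparameter search (grid / random / adaptive)
cropstack tune --config search.yaml --dataset sim/dataset.csv \
    --kb sim/knowledge_base.json --strategy adaptive --budget 25

# score a saved model; write metrics JSON + confusion CSV
cropstack evaluate --model run-pinn/model.json --dataset sim/dataset.csv

cropstack predict --model run-pinn/model.json --dataset sim/dataset.csv --out preds.csv
```

Example `search.yaml`:

```yaml
search:
  space:
    n_estimators: {type: int, low: 50, high: 500}
    max_depth: [4, 8, 16]
    learning_rate: {type: float, low: 0.01, high: 0.5, log: true}
```

## Notes on conventions

- Suitability scores always use raw physical units; the scaled features feed
  only the network input.
- Scalers are fitted on the training partition of each split/fold only.
- Per-class precision with no predicted positives contributes 0 (with a
  warning); fold std is population (ddof=0).
- `physics_mode` selects between penalising all crops (default) or only the
  true class.
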