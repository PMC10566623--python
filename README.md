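# fvsdecode

Automatic model ranking and greedy forward variable selection (FVS) for
tabular decoding problems — e.g. predicting age or sex from a table of
regional gray-matter volumes.

The pipeline has two stages:

1. **Rank** — every model in a fixed zoo (11 regression families, 7
   classification families) is tuned by k-fold cross-validated grid or
   random search on the training rows, refit, and evaluated on a held-out
   test split; the result is a ranking table and a recommended model.
2. **Select** — greedy forward variable selection with the chosen model:
   at each iteration the samples are re-split 70/30, every remaining
   feature is scored by tuning/refitting the model on the current set
   plus that feature, and the best candidate is kept while it improves
   held-out performance. A Boruta-style shadow-feature selector is
   provided as an all-relevant counterpart.

Nuisance covariates (e.g. total intracranial volume) are removed by
per-feature OLS residualization fit on training rows only. Candidate
evaluation parallelizes over worker processes with per-candidate seeds
derived from `(master_seed, iteration, feature_index)`, so results are
identical for any worker count.

## CLI

```sh
# make a synthetic ROI-style table with 5 planted signal features
fvsdecode simulate --n 300 --m 100 --k 5 --effect 2 --seed 7 \
    --out sim.csv --truth-out truth.json

# stage 1: rank the zoo
fvsdecode rank --input sim.csv --target target --task regression \
    --covariates TIV --seed 1 --out ranking.csv

# stage 2: forward selection with the chosen model
fvsdecode fvs --input sim.csv --target target --task regression \
    --covariates TIV --model lassolar --n-selected-features 100 \
    --workers 4 --seed 1 --out trace.csv

# counterpart all-relevant selector
fvsdecode boruta --input sim.csv --target target --task classification \
    --alpha 0.05 --max-iter 100 --seed 1 --out boruta.csv

# evaluate one model on an explicit feature subset
fvsdecode evaluate --input sim.csv --target target --task regression \
    --model lassolar --features-file selected_features.txt \
    --seed 1 --out metrics.json

fvsdecode --list-models     # print the registry
```

Every command writes a `manifest.json` (config, master seed, input
digest, timestamps) next to its outputs. Hyperparameter spaces can be
overridden per model with `--config models.yaml`:

```yaml
models:
  ridge: {param_space: {alpha: [0.01, 1.0, 100.0]}}
  random_forest: {n_random_draws: 10}
```

## Python API

```python
import fvsdecode as fd

ds = fd.load_table("sim.csv", target_column="target",
                   covariate_columns=["TIV"], task="regression")
split = fd.make_split(ds, fd.SplitConfig(seed=1))
ds = fd.residualize_covariates(ds, split)

table = fd.rank_models(ds, split, fd.RankConfig(seed=1))
best = table.best.model

trace = fd.forward_select(ds, fd.FvsConfig(model_name=best,
                                           n_selected_features=100,
                                           master_seed=1, n_workers=4))
print(trace.selected_features, trace.stop_reason)
```

## Tests and acceptance report

```sh
python -m pytest tests/
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

The acceptance script re-runs the end-to-end property checks (planted
feature recovery, FVS-vs-all-features improvement, Boruta null control,
registry shape) on package-generated synthetic data and prints the
results; it writes an empty JSON object since the artifact has no
offline-reproducible numeric reference targets.

## Notes

- How the original covariate adjustment was performed is not documented
  upstream; this package residualizes features on the covariates with
  train-only OLS, which is standard practice and leakage-safe.
- The `extreme_gradient_boosting` entry is backed by scikit-learn's
  histogram gradient booster (the xgboost library is not a dependency).
- Classification tuning optimizes accuracy by default; forward selection
  accepts `--criterion auc`, which is often the more stable choice for
  small test splits.
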