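# enus

Engineered up-sampling (ENUS) for imbalanced two-class tabular data, plus
the comparative-evaluation harness used to benchmark it.

ENUS balances a training set by synthesizing new minority-class records:
each synthesis picks a random existing minority record (the *centroid*),
finds its k nearest minority neighbors, chooses one, and interpolates
feature-wise between centroid and neighbor with independent U[0,1)
weights, repeating until the classes are equal in size. A duplication
baseline (resampling minority records with replacement) is included.

The harness reproduces a full benchmarking protocol around the sampler:

- **data handling** — the UCI Wisconsin breast-cancer comma-separated
  dialect (11 columns, `?` for missing) and a headered CSV variant;
  missing-value removal with reports; stratified 80/20 splits;
  ratio-controlled imbalanced subsets (ceiling rule).
- **metrics** — accuracy, balanced accuracy, sensitivity, specificity,
  precision, F1 with the minority class as positive.
- **models** — one adapter surface over eight classifier configurations
  (kNN, DT, RF, two neural networks, radial SVM, two gradient-boosting
  setups) with published default hyperparameters, CV tuning where the
  protocol requires it, an SVM grid search, and per-model feature
  importance (impurity / gain / uniform).
- **stats** — Spearman correlation screening for collinear features and
  Welch's independent t-test for model comparison.
- **experiment** — four training configurations (balance × feature
  removal), repeated seeded trials, imbalance-ratio sweeps, top-3
  importance-frequency ensembling, and tidy CSV/JSON reports.
- **synthetic data** — a seeded generator for Wisconsin-like ordinal
  tables with controlled imbalance, class separation, and a calibrated
  rank-correlated feature pair, so everything is testable offline.

## CLI

```sh
# generate Wisconsin-like synthetic data
enus synth --n 700 --ratio 0.35 --seed 1 --out synth.csv

# drop incomplete records from the raw UCI dialect
enus clean --input data/breast-cancer-wisconsin.data --wisconsin \
    --output cleaned.csv --report removal.json

# balance a training CSV with ENUS, keeping a per-record trace
enus balance --input train.csv --k 5 --seed 42 \
    --output balanced.csv --trace trace.jsonl

# metrics / statistics
enus metrics --input predictions.csv
enus corr --input cleaned.csv --out corr.json
enus ttest --a runsA.csv --b runsB.csv

# repeated-trials experiment over models and configurations
enus evaluate --data cleaned.csv --models all --configs BN,BY,ON,OY \
    --trials 100 --seed 7 --out results/

# imbalance-ratio sweep
enus sweep --data cleaned.csv --ratios 0.05:0.5:0.05 \
    --models RF,XGBTree --configs BN,ON --trials 20 --seed 7 --out sweep.csv
```

Training configurations: `B*` applies ENUS to the training partition
only, `O*` leaves it as drawn; `*Y` removes the collinear `Cell_Size`
feature before fitting, `*N` keeps it.

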