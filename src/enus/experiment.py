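"""Experiment orchestration: configurations, repeated trials, sweeps.

Four training configurations cross two axes — balance the training
partition with ENUS (B) or leave it original (O), and remove the
collinear feature (Y) or keep it (N):

    BN  balanced, no removal       ON  original, no removal
    BY  balanced, feature removed  OY  original, feature removed

Each trial re-splits the data 80/20, preprocesses the *training*
partition only, fits, and evaluates once on the held-out validation
partition.
"""

from __future__ import annotations

import hashlib
import json
import time
import warnings
from dataclasses import dataclass, replace

import pandas as pd

from .dataset import Dataset, drop_feature, make_ratio_subset, stratified_split
from .metrics import METRIC_NAMES, MetricSet, confusion_counts, metric_set
from .models import ModelConfig, ImportanceRanking, feature_importance, fit_model, predict_labels
from .sampler import SamplerConfig, enus_balance
from .stats import TTestResult, welch_t_test

__all__ = [
    "TRAINING_CONFIGS",
    "TrialResult",
    "ExperimentSummary",
    "derive_seed",
    "run_trial",
    "run_repeated_experiment",
    "ratio_sweep",
    "importance_frequency",
    "measure_runtime",
]

TRAINING_CONFIGS = ("BN", "BY", "ON", "OY")
DEFAULT_DROP_FEATURE = "Cell_Size"


@dataclass(frozen=True)
class TrialResult:
    trial: int
    seed: int
    config: str
    model_id: str
    metrics: MetricSet
    importance: ImportanceRanking
    fit_seconds: float

    def row(self) -> dict:
        out = {
            "trial": self.trial,
            "seed": self.seed,
            "config": self.config,
            "model_id": self.model_id,
            "fit_seconds": self.fit_seconds,
        }
        out.update(self.metrics.to_dict())
        return out


@dataclass
class ExperimentSummary:
    trials: list[TrialResult]
    summary: pd.DataFrame  # one row per (model, config, metric): mean/min/max
    ttests: dict[str, dict[str, TTestResult]]  # model -> metric -> vs reference
    importance: dict  # importance_frequency output
    reference_model: str | None = None

    def cell(self, model_id: str, config: str, metric: str) -> dict:
        s = self.summary
        row = s[(s.model_id == model_id) & (s.config == config) & (s.metric == metric)]
        if row.empty:
            raise KeyError((model_id, config, metric))
        return row.iloc[0][["mean", "min", "max"]].to_dict()

    def mean(self, model_id: str, config: str, metric: str) -> float:
        return float(self.cell(model_id, config, metric)["mean"])

    def to_json(self, path) -> None:
        payload = {
            "summary": self.summary.to_dict("records"),
            "ttests": {
                m: {k: t.to_dict() for k, t in per.items()}
                for m, per in self.ttests.items()
            },
            "importance": self.importance,
            "reference_model": self.reference_model,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)

    def trials_frame(self) -> pd.DataFrame:
        return pd.DataFrame([t.row() for t in self.trials])


def derive_seed(base_seed: int, *parts) -> int:
    """Stable per-(trial, model, config) seed; adding a model never
    perturbs another model's random stream."""
    key = ":".join([str(base_seed), *map(str, parts)]).encode()
    return int.from_bytes(hashlib.sha256(key).digest()[:4], "big")


def measure_runtime(stage) -> tuple[object, float]:
    """Run a callable, returning (result, monotonic elapsed seconds)."""
    t0 = time.perf_counter()
    result = stage()
    return result, time.perf_counter() - t0


def run_trial(
    data: Dataset,
    model: ModelConfig,
    config: str,
    seed: int,
    split_fraction: float = 0.8,
    sampler: SamplerConfig | None = None,
    drop_name: str = DEFAULT_DROP_FEATURE,
) -> TrialResult:
    """One trial: split, preprocess training partition, fit, evaluate.

    The validation partition is never touched by balancing or fitting;
    this is asserted via id-set checks before evaluation.
    """
    if config not in TRAINING_CONFIGS:
        raise ValueError(f"config must be one of {TRAINING_CONFIGS}, got {config!r}")
    if data.frame.isna().any().any():
        raise ValueError("run_trial expects cleaned data (no missing values)")
    pair = stratified_split(data, split_fraction, seed)
    train, validation = pair.train, pair.validation
    original_val_ids = set(validation.ids)
    if config[1] == "Y":
        if drop_name in train.feature_names:
            train = drop_feature(train, drop_name)
            validation = drop_feature(validation, drop_name)
        else:
            warnings.warn(f"feature {drop_name!r} not present; nothing removed")
    if config[0] == "B":
        cfg = sampler or SamplerConfig()
        train = enus_balance(train, replace(cfg, seed=derive_seed(seed, "balance")))
    # leakage guard: no validation record may reach the training partition
    if set(train.ids) & original_val_ids:
        raise AssertionError("validation records leaked into training partition")
    model_cfg = replace(model, seed=derive_seed(seed, "fit", model.model_id))
    fitted, fit_seconds = measure_runtime(lambda: fit_model(model_cfg, train))
    predicted = predict_labels(fitted, validation)
    counts = confusion_counts(
        list(validation.labels), predicted, positive=data.positive_class
    )
    return TrialResult(
        trial=-1,
        seed=seed,
        config=config,
        model_id=model.model_id,
        metrics=metric_set(counts),
        importance=feature_importance(fitted),
        fit_seconds=fit_seconds,
    )


def _aggregate(trials: list[TrialResult]) -> pd.DataFrame:
    rows = []
    frame = pd.DataFrame([t.row() for t in trials])
    for (model_id, config), grp in frame.groupby(["model_id", "config"], sort=False):
        for metric in METRIC_NAMES:
            rows.append(
                {
                    "model_id": model_id,
                    "config": config,
                    "metric": metric,
                    "mean": float(grp[metric].mean()),
                    "min": float(grp[metric].min()),
                    "max": float(grp[metric].max()),
                    "n_trials": int(len(grp)),
                }
            )
    return pd.DataFrame(rows)


def run_repeated_experiment(
    data: Dataset,
    models: list[ModelConfig],
    configs: list[str] | tuple[str, ...] = TRAINING_CONFIGS,
    n_trials: int = 100,
    base_seed: int = 0,
    reference_model: str | None = "XGBTree",
    sampler: SamplerConfig | None = None,
    drop_name: str = DEFAULT_DROP_FEATURE,
) -> ExperimentSummary:
    """Repeat independent trials per (model, config) and aggregate.

    Each trial gets a seed derived from (base_seed, trial, model, config),
    so results for one model are unchanged by adding or reordering the
    others. Pairwise t-tests compare each model's per-trial metric values
    (pooled across configs) against the reference model's.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    trials: list[TrialResult] = []
    for model in models:
        for config in configs:
            for i in range(n_trials):
                seed = derive_seed(base_seed, i, model.model_id, config)
                result = run_trial(
                    data, model, config, seed, sampler=sampler, drop_name=drop_name
                )
                trials.append(replace(result, trial=i))
    summary = _aggregate(trials)
    ttests: dict[str, dict[str, TTestResult]] = {}
    model_ids = [m.model_id for m in models]
    if reference_model in model_ids and len(trials) > 0:
        frame = pd.DataFrame([t.row() for t in trials])
        ref = frame[frame.model_id == reference_model]
        for mid in model_ids:
            if mid == reference_model:
                continue
            other = frame[frame.model_id == mid]
            if len(ref) < 2 or len(other) < 2:
                continue
            ttests[mid] = {
                metric: welch_t_test(ref[metric], other[metric])
                for metric in METRIC_NAMES
            }
    return ExperimentSummary(
        trials=trials,
        summary=summary,
        ttests=ttests,
        importance=importance_frequency(trials),
        reference_model=reference_model,
    )


def ratio_sweep(
    data: Dataset,
    ratios,
    models: list[ModelConfig],
    configs=TRAINING_CONFIGS,
    n_trials: int = 100,
    base_seed: int = 0,
    sampler: SamplerConfig | None = None,
    drop_name: str = DEFAULT_DROP_FEATURE,
) -> pd.DataFrame:
    """Evaluate the harness across imbalance ratios.

    For each feasible ratio a ratio-controlled subset is drawn and a full
    repeated experiment is run on it; infeasible ratios are skipped with
    a warning. Returns a tidy table, one row per
    (ratio, model, config, metric).
    """
    rows = []
    for ratio in ratios:
        try:
            subset = make_ratio_subset(data, ratio, seed=derive_seed(base_seed, "ratio", ratio))
        except ValueError as err:
            warnings.warn(f"skipping ratio {ratio}: {err}")
            continue
        summary = run_repeated_experiment(
            subset,
            models,
            configs,
            n_trials=n_trials,
            base_seed=derive_seed(base_seed, "sweep", ratio),
            reference_model=None,
            sampler=sampler,
            drop_name=drop_name,
        )
        block = summary.summary.copy()
        block.insert(0, "ratio", ratio)
        rows.append(block)
    if not rows:
        return pd.DataFrame(
            columns=["ratio", "model_id", "config", "metric", "mean", "min", "max", "n_trials"]
        )
    return pd.concat(rows, ignore_index=True)


def importance_frequency(trials) -> dict:
    """Per model: how often each feature lands at importance rank 1-3.

    Models whose rankings are tagged ``uniform`` carry no ordering
    information and are excluded. Fractions are over the included trials
    of that model only. Returns ``{model_id: {feature: {"1": f, "2": f,
    "3": f, "top3": f}}}``.
    """
    per_model: dict[str, list[ImportanceRanking]] = {}
    for t in trials:
        if t.importance.method == "uniform":
            continue
        per_model.setdefault(t.model_id, []).append(t.importance)
    if not per_model:
        warnings.warn("no rankable trials; importance summary is empty")
        return {}
    out: dict[str, dict] = {}
    for mid, rankings in per_model.items():
        n = len(rankings)
        counts: dict[str, dict[str, int]] = {}
        for ranking in rankings:
            for pos, feat in enumerate(ranking.features[:3], start=1):
                slot = counts.setdefault(feat, {"1": 0, "2": 0, "3": 0, "top3": 0})
                slot[str(pos)] += 1
                slot["top3"] += 1
        out[mid] = {
            feat: {key: cnt / n for key, cnt in slots.items()}
            for feat, slots in counts.items()
        }
    return out
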