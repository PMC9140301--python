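"""Uniform adapter layer over the benchmarked classifier families.

Eight model ids share one fit/predict/importance surface:

====================  =============================================
model_id              backing estimator
====================  =============================================
kNN                   KNeighborsClassifier (k tuned 5..45 by CV)
DT                    DecisionTreeClassifier (cost-complexity tuned)
RF                    RandomForestClassifier
NNet                  MLPClassifier with no hidden layer
NNet-ML               MLPClassifier with one hidden layer (8 units)
SVM                   SVC, radial kernel
XGBTree               gradient boosting, fixed hyperparameters
XGBTree-Grid          gradient boosting, alternative fixed set
====================  =============================================

XGBTree uses the ``xgboost`` package when importable and falls back to
scikit-learn's GradientBoostingClassifier otherwise (the ``gamma``
min-loss-reduction knob has no exact fallback analog; this is recorded
in the fit metadata).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.model_selection import GridSearchCV, StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .dataset import Dataset

try:  # pragma: no cover - exercised only where xgboost is installed
    from xgboost import XGBClassifier

    _HAVE_XGBOOST = True
except ImportError:  # pragma: no cover
    _HAVE_XGBOOST = False

__all__ = [
    "MODEL_IDS",
    "TABLE_DEFAULTS",
    "ModelConfig",
    "TrainedModel",
    "ImportanceRanking",
    "fit_model",
    "predict_labels",
    "svm_grid_search",
    "feature_importance",
    "load_model_registry",
]

MODEL_IDS = ("kNN", "DT", "RF", "NNet", "NNet-ML", "SVM", "XGBTree", "XGBTree-Grid")

# Published optimal hyperparameters for each model family.
TABLE_DEFAULTS: dict[str, dict] = {
    "kNN": {"k": 20, "k_search": [5, 45]},
    "DT": {"cp": 0.01, "tune_length": 10},
    "RF": {"mtry": 3, "ntree": 500},
    "NNet": {
        "init_rand_weight": 0.5,
        "decay": 5e-4,
        "max_iteration": 5000,
        "activation_func": "ReLU",
    },
    "NNet-ML": {
        "hidden_layer_num": 8,
        "max_step": 100000,
        "learning_rate": 0.1,
        "threshold": 0.01,
        "activation_func": "ReLU",
    },
    "SVM": {"method": "svmRadial", "gamma": 0.1, "cost": 1.0},
    "XGBTree": {"learning_rate": 0.01, "max_depth": 5, "gamma": 3, "n_rounds": 150},
    "XGBTree-Grid": {"learning_rate": 0.1, "max_depth": 7, "gamma": 5, "n_rounds": 150},
}

UNIFORM_IMPORTANCE_MODELS = frozenset({"kNN", "NNet", "NNet-ML", "SVM"})


@dataclass(frozen=True)
class ModelConfig:
    """A model id plus its hyperparameters and training protocol."""

    model_id: str
    hyperparameters: dict = field(default_factory=dict)
    cv_folds: int = 10
    seed: int = 0
    tune: bool = True  # CV tuning where the protocol specifies it (kNN, DT)

    def __post_init__(self) -> None:
        if self.model_id not in MODEL_IDS:
            raise ValueError(f"unknown model_id {self.model_id!r}; choose from {MODEL_IDS}")
        merged = dict(TABLE_DEFAULTS[self.model_id])
        merged.update(self.hyperparameters)
        object.__setattr__(self, "hyperparameters", merged)


@dataclass
class TrainedModel:
    model_id: str
    estimator: object
    feature_names: list[str]
    classes: list[str]
    metadata: dict = field(default_factory=dict)


@dataclass(frozen=True)
class ImportanceRanking:
    """Features in non-increasing importance order with normalized scores."""

    features: tuple[str, ...]
    scores: tuple[float, ...]
    method: str  # impurity | gain | uniform

    def top(self, n: int = 3) -> tuple[str, ...]:
        return self.features[:n]


def load_model_registry(path) -> dict[str, ModelConfig]:
    """Load a YAML model registry: model_id -> hyperparameter map."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return {mid: ModelConfig(model_id=mid, hyperparameters=hp or {}) for mid, hp in raw.items()}


def _cv(config: ModelConfig, y: pd.Series):
    min_class = int(y.value_counts().min())
    folds = min(config.cv_folds, min_class)
    if folds < config.cv_folds:
        warnings.warn(
            f"reducing cv folds {config.cv_folds} -> {folds} (smallest class has "
            f"{min_class} records)",
            stacklevel=3,
        )
    return StratifiedKFold(n_splits=max(folds, 2), shuffle=True, random_state=config.seed)


def _build_estimator(config: ModelConfig, y: pd.Series):
    hp = config.hyperparameters
    mid = config.model_id
    meta: dict = {}
    if mid == "kNN":
        base = KNeighborsClassifier(n_neighbors=int(hp["k"]))
        if config.tune:
            lo, hi = hp["k_search"]
            grid = {"n_neighbors": list(range(int(lo), int(hi) + 1, 5))}
            return GridSearchCV(base, grid, cv=_cv(config, y), scoring="accuracy"), meta
        return base, meta
    if mid == "DT":
        base = DecisionTreeClassifier(ccp_alpha=float(hp["cp"]), random_state=config.seed)
        if config.tune:
            grid = {"ccp_alpha": np.linspace(0.0, 0.05, int(hp["tune_length"])).tolist()}
            return GridSearchCV(base, grid, cv=_cv(config, y), scoring="accuracy"), meta
        return base, meta
    if mid == "RF":
        return (
            RandomForestClassifier(
                n_estimators=int(hp["ntree"]),
                max_features=int(hp["mtry"]),
                random_state=config.seed,
            ),
            meta,
        )
    if mid == "NNet":
        return (
            MLPClassifier(
                hidden_layer_sizes=(),
                activation="relu",
                alpha=float(hp["decay"]),
                max_iter=int(hp["max_iteration"]),
                random_state=config.seed,
            ),
            meta,
        )
    if mid == "NNet-ML":
        return (
            MLPClassifier(
                hidden_layer_sizes=(int(hp["hidden_layer_num"]),),
                activation="relu",
                learning_rate_init=float(hp["learning_rate"]),
                tol=float(hp["threshold"]),
                max_iter=min(int(hp["max_step"]), 10000),
                random_state=config.seed,
            ),
            meta,
        )
    if mid == "SVM":
        return (
            SVC(kernel="rbf", gamma=float(hp["gamma"]), C=float(hp["cost"]),
                random_state=config.seed),
            meta,
        )
    if mid in ("XGBTree", "XGBTree-Grid"):
        if _HAVE_XGBOOST:  # pragma: no cover
            return (
                XGBClassifier(
                    learning_rate=float(hp["learning_rate"]),
                    max_depth=int(hp["max_depth"]),
                    gamma=float(hp["gamma"]),
                    n_estimators=int(hp["n_rounds"]),
                    random_state=config.seed,
                    use_label_encoder=False,
                    eval_metric="logloss",
                ),
                {"backend": "xgboost"},
            )
        meta = {"backend": "sklearn-gbm", "gamma_unmapped": float(hp["gamma"])}
        return (
            GradientBoostingClassifier(
                learning_rate=float(hp["learning_rate"]),
                max_depth=int(hp["max_depth"]),
                n_estimators=int(hp["n_rounds"]),
                random_state=config.seed,
            ),
            meta,
        )
    raise ValueError(f"unknown model_id {mid!r}")  # unreachable


def fit_model(config: ModelConfig, train: Dataset) -> TrainedModel:
    """Fit one model; CV-tuned where the protocol specifies tuning."""
    if train.n_records == 0:
        raise ValueError("cannot fit on an empty dataset")
    y = train.labels
    if y.nunique() < 2:
        raise ValueError("training data must contain both classes")
    estimator, meta = _build_estimator(config, y)
    X = train.matrix()
    if _HAVE_XGBOOST and meta.get("backend") == "xgboost":  # pragma: no cover
        # xgboost wants integer-coded labels
        classes = sorted(y.unique())
        estimator.fit(X, y.map({c: i for i, c in enumerate(classes)}))
        meta["label_classes"] = classes
    else:
        estimator.fit(X, y)
    if isinstance(estimator, GridSearchCV):
        meta["best_params"] = estimator.best_params_
        meta["cv_accuracy"] = float(estimator.best_score_)
    return TrainedModel(
        model_id=config.model_id,
        estimator=estimator,
        feature_names=train.feature_names,
        classes=sorted(y.unique()),
        metadata=meta,
    )


def predict_labels(model: TrainedModel, data: Dataset) -> list:
    """Predict one label per record; the schema must match training."""
    if data.feature_names != model.feature_names:
        missing = set(model.feature_names) - set(data.feature_names)
        extra = set(data.feature_names) - set(model.feature_names)
        raise ValueError(
            f"schema mismatch: missing features {sorted(missing)}, "
            f"unexpected features {sorted(extra)}"
        )
    if data.n_records == 0:
        return []
    raw = model.estimator.predict(data.matrix())
    if model.metadata.get("backend") == "xgboost":  # pragma: no cover
        classes = model.metadata["label_classes"]
        return [classes[int(i)] for i in raw]
    return list(raw)


def svm_grid_search(
    train: Dataset,
    cost_range: tuple[float, float] = (0.5, 8.0),
    gamma_range: tuple[float, float] = (0.0, 0.25),
    grid_points: int = 5,
    seed: int = 0,
) -> tuple[float, float, pd.DataFrame]:
    """Grid search for radial-kernel SVM (cost, gamma).

    Fits one SVM per grid cell and scores *training-set* accuracy,
    mirroring the reference search procedure; ties resolve to the first
    cell in grid order (cost varying fastest). A gamma of exactly 0 is
    replaced by a tiny positive value the backend accepts.
    """
    if grid_points < 1:
        raise ValueError("grid_points must be >= 1")
    if cost_range[0] > cost_range[1] or gamma_range[0] > gamma_range[1]:
        raise ValueError("ranges must be non-degenerate (lo <= hi)")
    costs = np.linspace(*cost_range, grid_points)
    gammas = np.linspace(*gamma_range, grid_points)
    X, y = train.matrix(), train.labels
    rows = []
    for g in gammas:  # expand.grid order: first factor (cost) varies fastest
        for c in costs:
            eff_g = max(float(g), 1e-6)
            clf = SVC(kernel="rbf", C=float(c), gamma=eff_g, random_state=seed)
            clf.fit(X, y)
            acc = float((clf.predict(X) == y.to_numpy()).mean())
            rows.append({"cost": float(c), "gamma": float(g), "train_accuracy": acc})
    table = pd.DataFrame(rows)
    best = table["train_accuracy"].to_numpy()
    idx = int(np.flatnonzero(best == best.max())[0])
    return table.loc[idx, "cost"], table.loc[idx, "gamma"], table


def _normalize(scores: np.ndarray) -> np.ndarray:
    total = scores.sum()
    return scores / total if total > 0 else np.full_like(scores, 1.0 / len(scores))


def feature_importance(model: TrainedModel) -> ImportanceRanking:
    """Per-feature importance, normalized to sum to 1.

    Tree models report mean decrease in impurity (tag ``impurity``),
    gradient boosting reports gain (tag ``gain``); distance- and
    weight-based models carry no comparable per-feature score and are
    tagged ``uniform`` with all-equal scores and features left in schema
    order.
    """
    names = model.feature_names
    est = model.estimator
    if isinstance(est, GridSearchCV):
        est = est.best_estimator_
    if model.model_id in UNIFORM_IMPORTANCE_MODELS:
        uniform = tuple(1.0 / len(names) for _ in names)
        return ImportanceRanking(features=tuple(names), scores=uniform, method="uniform")
    if not hasattr(est, "feature_importances_"):
        raise ValueError(f"model {model.model_id!r} is not fitted")
    scores = _normalize(np.asarray(est.feature_importances_, dtype=float))
    order = np.argsort(-scores, kind="stable")
    method = "gain" if model.model_id.startswith("XGBTree") else "impurity"
    return ImportanceRanking(
        features=tuple(names[i] for i in order),
        scores=tuple(float(scores[i]) for i in order),
        method=method,
    )
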