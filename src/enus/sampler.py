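"""Engineered up-sampling (ENUS) and the duplication baseline.

ENUS balances a two-class training set by synthesizing new minority
records: each synthesis picks a random existing minority record (the
*centroid*), finds its k nearest minority neighbors, chooses one, and
interpolates feature-wise between centroid and neighbor with independent
U[0,1) weights. Duplication up-sampling resamples existing minority
records with replacement.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dataset import Dataset

__all__ = [
    "SamplerConfig",
    "SynthesisTrace",
    "OperationCounter",
    "find_k_nearest_minority",
    "synthesize_record",
    "enus_balance",
    "duplicate_balance",
]

NEIGHBOR_CHOICES = ("uniform-among-k", "strict-nearest")
FALLBACKS = ("duplicate", "error")


@dataclass(frozen=True)
class SamplerConfig:
    """ENUS parameters.

    ``k`` is the requested neighbor count; the effective count is
    ``min(k, m - 1)`` where ``m`` is the minority size. ``neighbor_choice``
    selects the interpolation partner among the k nearest: uniformly at
    random (default) or always the single nearest. When the minority class
    has fewer than two members, ``fallback`` applies.
    """

    k: int = 5
    seed: int = 0
    distance: str = "euclidean"
    clip_to_range: bool = True
    value_range: tuple[float, float] = (1.0, 10.0)
    neighbor_choice: str = "uniform-among-k"
    fallback: str = "duplicate"
    round_to_ordinal: bool = False

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError(f"k must be >= 1, got {self.k}")
        if self.neighbor_choice not in NEIGHBOR_CHOICES:
            raise ValueError(f"neighbor_choice must be one of {NEIGHBOR_CHOICES}")
        if self.fallback not in FALLBACKS:
            raise ValueError(f"fallback must be one of {FALLBACKS}")
        if self.distance != "euclidean":
            raise ValueError("only the euclidean distance is supported")


@dataclass(frozen=True)
class SynthesisTrace:
    """Provenance of one synthetic record."""

    synthetic_id: str
    centroid_id: object
    neighbor_id: object
    u: dict[str, float]
    values: dict[str, float]

    def to_dict(self) -> dict:
        return {
            "synthetic_id": self.synthetic_id,
            "centroid_id": self.centroid_id,
            "neighbor_id": self.neighbor_id,
            "u": self.u,
            "values": self.values,
        }


@dataclass
class OperationCounter:
    """Counts elementary work done by the sampler (complexity checks)."""

    feature_diff_ops: int = 0
    distance_evals: int = 0
    sorts: int = 0
    syntheses: int = 0


def _minority_positions(data: Dataset) -> np.ndarray:
    return np.flatnonzero((data.labels == data.minority_class).to_numpy())


def find_k_nearest_minority(
    data: Dataset,
    centroid_position: int,
    k: int,
    counter: OperationCounter | None = None,
) -> np.ndarray:
    """Positions of the min(k, m-1) minority records nearest the centroid.

    The centroid record itself (by position, not by value) is excluded.
    Ordered by non-decreasing Euclidean distance; ties broken by record
    order via a stable sort.
    """
    minority = _minority_positions(data)
    if centroid_position not in minority:
        raise ValueError(f"position {centroid_position} is not a minority record")
    if len(minority) < 2:
        raise ValueError("minority class needs at least 2 records for neighbor search")
    others = minority[minority != centroid_position]
    X = data.matrix()
    diffs = X[others] - X[centroid_position]
    dists = np.sqrt((diffs * diffs).sum(axis=1))
    if counter is not None:
        counter.feature_diff_ops += diffs.size
        counter.distance_evals += len(others)
        counter.sorts += 1
    order = np.argsort(dists, kind="stable")
    return others[order[: min(k, len(others))]]


def synthesize_record(
    centroid: pd.Series,
    neighbor: pd.Series,
    centroid_id: object,
    neighbor_id: object,
    synthetic_id: str,
    rng: np.random.Generator,
    config: SamplerConfig,
) -> tuple[pd.Series, SynthesisTrace]:
    """Interpolate one synthetic record between centroid and neighbor.

    For each feature f: ``value_f = centroid_f + u_f * (neighbor_f -
    centroid_f)`` with an independent ``u_f ~ U[0,1)`` per feature, so the
    result lies in the per-feature interval between the two parents.
    """
    if list(centroid.index) != list(neighbor.index):
        raise ValueError("centroid and neighbor have mismatched schemas")
    u = rng.random(len(centroid))
    values = centroid.to_numpy(dtype=float) + u * (
        neighbor.to_numpy(dtype=float) - centroid.to_numpy(dtype=float)
    )
    if config.round_to_ordinal:
        values = np.rint(values)
    if config.clip_to_range:
        values = np.clip(values, *config.value_range)
    out = pd.Series(values, index=centroid.index)
    trace = SynthesisTrace(
        synthetic_id=synthetic_id,
        centroid_id=centroid_id,
        neighbor_id=neighbor_id,
        u=dict(zip(centroid.index, u.tolist())),
        values=dict(zip(centroid.index, values.tolist())),
    )
    return out, trace


def _check_two_classes(train: Dataset, who: str) -> tuple[str, str, int]:
    counts = train.class_counts()
    if len(counts) < 2:
        raise ValueError(f"{who} requires both classes in the training data")
    minority = train.minority_class
    majority = train.majority_class
    deficit = counts[majority] - counts[minority]
    return minority, majority, deficit


def _append_synthetic(
    train: Dataset, rows: list[pd.Series], ids: list[str], label: str
) -> Dataset:
    if not rows:
        return train.copy()
    frame = pd.concat([train.frame, pd.DataFrame(rows)], ignore_index=True)
    new_ids = pd.concat(
        [train.ids, pd.Series(ids, name=train.ids.name)], ignore_index=True
    )
    labels = pd.concat(
        [train.labels, pd.Series([label] * len(rows), name=train.labels.name)],
        ignore_index=True,
    )
    return Dataset(
        frame=frame,
        ids=new_ids,
        labels=labels,
        positive_class=train.positive_class,
        provenance=train.provenance,
    )


def enus_balance(
    train: Dataset,
    config: SamplerConfig | None = None,
    return_trace: bool = False,
    counter: OperationCounter | None = None,
):
    """Append ENUS-synthesized minority records until the classes balance.

    Each synthesis independently redraws a random centroid from the
    *original* minority records and an interpolation partner among its k
    nearest original minority neighbors. Original records are never
    modified. With ``return_trace=True`` a list of
    :class:`SynthesisTrace` is returned alongside the balanced dataset.
    """
    config = config or SamplerConfig()
    minority, majority, deficit = _check_two_classes(train, "enus_balance")
    rng = np.random.default_rng(config.seed)
    min_pos = _minority_positions(train)
    feature_names = train.feature_names
    # minority feature block precomputed once; neighbor search and
    # interpolation run on it directly (same semantics as the per-record
    # operations find_k_nearest_minority / synthesize_record)
    Xmin = train.frame.iloc[min_pos].to_numpy(dtype=float)
    min_ids = train.ids.iloc[min_pos].to_list()
    m = len(min_pos)
    rows: list[np.ndarray] = []
    ids: list[str] = []
    traces: list[SynthesisTrace] = []
    for i in range(deficit):
        sid = f"synthetic-{i}"
        if m < 2:
            if config.fallback == "error":
                raise ValueError("minority class has < 2 records and fallback='error'")
            rows.append(Xmin[0].copy())
            ids.append(sid)
            if return_trace:
                traces.append(
                    SynthesisTrace(
                        synthetic_id=sid,
                        centroid_id=min_ids[0],
                        neighbor_id=min_ids[0],
                        u={},
                        values=dict(zip(feature_names, Xmin[0].tolist())),
                    )
                )
            continue
        ci = int(rng.integers(m))
        others = np.concatenate([np.arange(ci), np.arange(ci + 1, m)])
        diffs = Xmin[others] - Xmin[ci]
        dists = np.sqrt((diffs * diffs).sum(axis=1))
        if counter is not None:
            counter.feature_diff_ops += diffs.size
            counter.distance_evals += len(others)
            counter.sorts += 1
        order = np.argsort(dists, kind="stable")
        k_eff = min(config.k, m - 1)
        if config.neighbor_choice == "strict-nearest":
            ni = int(others[order[0]])
        else:
            ni = int(others[order[int(rng.integers(k_eff))]])
        u = rng.random(len(feature_names))
        values = Xmin[ci] + u * (Xmin[ni] - Xmin[ci])
        if config.round_to_ordinal:
            values = np.rint(values)
        if config.clip_to_range:
            values = np.clip(values, *config.value_range)
        rows.append(values)
        ids.append(sid)
        if return_trace:
            traces.append(
                SynthesisTrace(
                    synthetic_id=sid,
                    centroid_id=min_ids[ci],
                    neighbor_id=min_ids[ni],
                    u=dict(zip(feature_names, u.tolist())),
                    values=dict(zip(feature_names, values.tolist())),
                )
            )
        if counter is not None:
            counter.syntheses += 1
    series_rows = [pd.Series(r, index=feature_names) for r in rows]
    balanced = _append_synthetic(train, series_rows, ids, minority)
    return (balanced, traces) if return_trace else balanced


def duplicate_balance(train: Dataset, seed: int = 0) -> Dataset:
    """Baseline: resample minority records with replacement until balance."""
    minority, majority, deficit = _check_two_classes(train, "duplicate_balance")
    rng = np.random.default_rng(seed)
    min_pos = _minority_positions(train)
    picks = rng.choice(min_pos, size=deficit, replace=True)
    rows = [train.frame.iloc[int(p)].copy() for p in picks]
    ids = [f"duplicate-{i}" for i in range(deficit)]
    return _append_synthetic(train, rows, ids, minority)
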