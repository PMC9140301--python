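"""Tabular dataset handling for ordinal clinical tables.

Reads the UCI Wisconsin comma-separated dialect (11 columns, no header,
``?`` for missing values), a headered CSV variant with a declared target
column, and provides the cleaning / subsetting / splitting primitives the
evaluation harness is built on.
"""

from __future__ import annotations

import csv
import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "TableSchema",
    "WISCONSIN_SCHEMA",
    "Record",
    "Dataset",
    "RemovalReport",
    "SplitPair",
    "ParseError",
    "parse_wbc_file",
    "read_csv",
    "write_csv",
    "drop_incomplete",
    "drop_feature",
    "stratified_split",
    "make_ratio_subset",
]


class ParseError(ValueError):
    """Raised when an input file violates the declared dialect."""


@dataclass(frozen=True)
class TableSchema:
    """Column specification for an ordinal binary-classification table.

    Parameters
    ----------
    columns : list of str
        Ordered column names, including the id and target columns.
    id_column : str
        Name of the opaque identifier column (never used as a predictor).
    target_column : str
        Name of the class-label column.
    class_map : dict
        Mapping from raw class codes (as strings) to canonical labels,
        e.g. ``{"2": "B", "4": "M"}``.
    positive_class : str
        Canonical label of the minority / disease class.
    missing_token : str
        Token denoting a missing value in the raw file.
    ordinal_range : tuple or None
        Inclusive value range enforced for feature columns; ``None``
        relaxes the check for general numeric tables.
    """

    columns: tuple[str, ...]
    id_column: str = "ID"
    target_column: str = "Class"
    class_map: dict[str, str] = field(default_factory=lambda: {"2": "B", "4": "M"})
    positive_class: str = "M"
    missing_token: str = "?"
    ordinal_range: tuple[float, float] | None = (1, 10)

    @property
    def feature_names(self) -> list[str]:
        return [c for c in self.columns if c not in (self.id_column, self.target_column)]


WISCONSIN_COLUMNS = (
    "ID",
    "Clump_Thickness",
    "Cell_Size",
    "Cell_Shape",
    "Adhesion",
    "Epi_Cell_Size",
    "Nuclei",
    "Chromatin",
    "Nucleoli",
    "Mitoses",
    "Class",
)

WISCONSIN_SCHEMA = TableSchema(columns=WISCONSIN_COLUMNS)


@dataclass(frozen=True)
class Record:
    """One observation: id, feature mapping (NaN = missing), class label."""

    id: object
    features: dict[str, float]
    label: str

    def is_complete(self) -> bool:
        return not any(pd.isna(v) for v in self.features.values())


@dataclass
class Dataset:
    """Schema-consistent collection of records backed by a DataFrame.

    ``frame`` holds only feature columns (float dtype, NaN for missing);
    ``ids`` and ``labels`` are positionally aligned with it.
    """

    frame: pd.DataFrame
    ids: pd.Series
    labels: pd.Series
    positive_class: str = "M"
    provenance: str = ""

    def __post_init__(self) -> None:
        if len(self.frame) != len(self.labels) or len(self.frame) != len(self.ids):
            raise ValueError("frame, ids and labels must be positionally aligned")
        self.frame = self.frame.reset_index(drop=True)
        self.ids = self.ids.reset_index(drop=True)
        self.labels = self.labels.reset_index(drop=True)

    # -- basic views ---------------------------------------------------
    @property
    def feature_names(self) -> list[str]:
        return list(self.frame.columns)

    @property
    def n_records(self) -> int:
        return len(self.frame)

    def __len__(self) -> int:
        return self.n_records

    @property
    def classes(self) -> list[str]:
        return sorted(self.labels.unique())

    def class_counts(self) -> dict[str, int]:
        return self.labels.value_counts().to_dict()

    @property
    def minority_class(self) -> str:
        """Class with the fewest records; ties resolve to positive_class."""
        counts = self.class_counts()
        if len(counts) == 1:
            return next(iter(counts))
        lo = min(counts.values())
        tied = [c for c, v in counts.items() if v == lo]
        return self.positive_class if self.positive_class in tied else tied[0]

    @property
    def majority_class(self) -> str:
        counts = self.class_counts()
        minority = self.minority_class
        others = [c for c in counts if c != minority]
        return others[0] if others else minority

    def records(self) -> list[Record]:
        feats = self.frame.to_dict("records")
        return [
            Record(id=i, features=f, label=lab)
            for i, f, lab in zip(self.ids, feats, self.labels)
        ]

    def matrix(self) -> np.ndarray:
        return self.frame.to_numpy(dtype=float)

    # -- subsetting ----------------------------------------------------
    def take(self, positions: np.ndarray | list[int], provenance: str | None = None) -> "Dataset":
        pos = np.asarray(positions, dtype=int)
        return Dataset(
            frame=self.frame.iloc[pos],
            ids=self.ids.iloc[pos],
            labels=self.labels.iloc[pos],
            positive_class=self.positive_class,
            provenance=provenance if provenance is not None else self.provenance,
        )

    def copy(self) -> "Dataset":
        return Dataset(
            frame=self.frame.copy(),
            ids=self.ids.copy(),
            labels=self.labels.copy(),
            positive_class=self.positive_class,
            provenance=self.provenance,
        )


@dataclass(frozen=True)
class RemovalReport:
    removed_ids: tuple
    n_removed: int

    def to_dict(self) -> dict:
        return {"removed_ids": list(self.removed_ids), "n_removed": self.n_removed}


@dataclass(frozen=True)
class SplitPair:
    train: Dataset
    validation: Dataset
    split_fraction: float
    seed: int


# ---------------------------------------------------------------------
# parsing
# ---------------------------------------------------------------------

def _parse_value(token: str, schema: TableSchema, line_no: int, col: str) -> float:
    token = token.strip()
    if token == schema.missing_token:
        return float("nan")
    try:
        value = float(token)
    except ValueError:
        raise ParseError(
            f"line {line_no}: column {col!r} has non-numeric value {token!r}"
        ) from None
    if schema.ordinal_range is not None:
        lo, hi = schema.ordinal_range
        if not (lo <= value <= hi) or value != int(value):
            raise ParseError(
                f"line {line_no}: column {col!r} value {token!r} outside ordinal "
                f"range [{lo}, {hi}]"
            )
    return value


def parse_wbc_file(
    path, schema: TableSchema = WISCONSIN_SCHEMA, skip_first_row: bool = False
) -> Dataset:
    """Parse a file in the Wisconsin comma-separated dialect.

    Every line must have exactly ``len(schema.columns)`` fields; the
    missing token is mapped to NaN, class codes are mapped through
    ``schema.class_map``. No rows are dropped silently; malformed lines
    raise :class:`ParseError` naming the line number.

    ``skip_first_row`` reproduces the convention of header-expecting CSV
    readers that consume the first data line of this headerless format:
    the first row is dropped (explicitly, never silently).
    """
    n_cols = len(schema.columns)
    feat_names = schema.feature_names
    ids: list = []
    labels: list = []
    rows: list[list[float]] = []
    with open(path, newline="") as fh:
        for line_no, row in enumerate(csv.reader(fh), start=1):
            if line_no == 1 and skip_first_row:
                continue
            if not row or (len(row) == 1 and not row[0].strip()):
                continue  # tolerate trailing blank lines
            if len(row) != n_cols:
                raise ParseError(
                    f"line {line_no}: expected {n_cols} comma-separated fields, "
                    f"got {len(row)}"
                )
            named = dict(zip(schema.columns, row))
            raw_label = named[schema.target_column].strip()
            if raw_label in schema.class_map:
                label = schema.class_map[raw_label]
            elif raw_label in schema.class_map.values():
                label = raw_label
            else:
                raise ParseError(
                    f"line {line_no}: unknown class code {raw_label!r}"
                )
            ids.append(named[schema.id_column].strip())
            labels.append(label)
            rows.append(
                [_parse_value(named[c], schema, line_no, c) for c in feat_names]
            )
    dupes = pd.Series(ids).duplicated()
    if dupes.any():
        warnings.warn(
            f"{int(dupes.sum())} duplicate ids in {path}", stacklevel=2
        )
    return Dataset(
        frame=pd.DataFrame(rows, columns=feat_names, dtype=float),
        ids=pd.Series(ids, name=schema.id_column),
        labels=pd.Series(labels, name=schema.target_column),
        positive_class=schema.positive_class,
        provenance=str(path),
    )


def read_csv(
    path,
    target_column: str = "Class",
    id_column: str | None = "ID",
    positive_class: str = "M",
    missing_token: str = "?",
) -> Dataset:
    """Read the headered CSV variant with a declared target column."""
    df = pd.read_csv(path, na_values=[missing_token], dtype={target_column: str})
    if target_column not in df.columns:
        raise ParseError(f"target column {target_column!r} not found in {path}")
    labels = df[target_column].astype(str)
    drop = [target_column]
    if id_column is not None and id_column in df.columns:
        ids = df[id_column]
        drop.append(id_column)
    else:
        ids = pd.Series(np.arange(len(df)), name="ID")
    frame = df.drop(columns=drop).astype(float)
    return Dataset(
        frame=frame,
        ids=ids,
        labels=labels,
        positive_class=positive_class,
        provenance=str(path),
    )


def write_csv(data: Dataset, path, missing_token: str = "?") -> None:
    """Emit a headered CSV; round-trips through :func:`read_csv`."""
    out = data.frame.copy()
    out.insert(0, data.ids.name or "ID", data.ids.to_numpy())
    out[data.labels.name or "Class"] = data.labels.to_numpy()
    out.to_csv(path, index=False, na_rep=missing_token)


# ---------------------------------------------------------------------
# cleaning / subsetting
# ---------------------------------------------------------------------

def drop_incomplete(data: Dataset) -> tuple[Dataset, RemovalReport]:
    """Remove every record containing a missing value.

    Returns the filtered dataset and a report listing removed ids.
    """
    complete = ~data.frame.isna().any(axis=1)
    removed = data.ids[~complete]
    kept = data.take(np.flatnonzero(complete.to_numpy()))
    return kept, RemovalReport(tuple(removed), int((~complete).sum()))


def drop_feature(data: Dataset, name: str) -> Dataset:
    """Remove one feature column from the schema and every record."""
    if name not in data.frame.columns:
        raise KeyError(f"unknown feature {name!r}; have {list(data.frame.columns)}")
    return Dataset(
        frame=data.frame.drop(columns=[name]),
        ids=data.ids,
        labels=data.labels,
        positive_class=data.positive_class,
        provenance=data.provenance,
    )


def _largest_remainder_allocation(counts: dict[str, int], fraction: float) -> dict[str, int]:
    """Per-class train counts: floors, then distribute the shortfall to the
    classes with the largest fractional remainders (ties by class order)."""
    total_target = int(round(fraction * sum(counts.values())))
    floors = {c: math.floor(fraction * n) for c, n in counts.items()}
    remainders = {c: fraction * n - floors[c] for c, n in counts.items()}
    shortfall = total_target - sum(floors.values())
    order = sorted(counts, key=lambda c: (-remainders[c], list(counts).index(c)))
    alloc = dict(floors)
    for c in order[:shortfall]:
        alloc[c] += 1
    return alloc


def stratified_split(data: Dataset, fraction: float, seed: int) -> SplitPair:
    """Class-stratified random split into train / validation partitions.

    Per-class train counts follow a largest-remainder allocation of
    ``fraction``; the same seed always yields the identical id partition.
    """
    if not (0.0 < fraction < 1.0):
        raise ValueError(f"fraction must be in (0, 1), got {fraction}")
    counts = {c: int((data.labels == c).sum()) for c in data.labels.unique()}
    if any(n < 1 for n in counts.values()):
        raise ValueError("each class needs at least one record")
    alloc = _largest_remainder_allocation(counts, fraction)
    rng = np.random.default_rng(seed)
    train_pos: list[int] = []
    val_pos: list[int] = []
    for cls in counts:
        pos = np.flatnonzero((data.labels == cls).to_numpy())
        perm = rng.permutation(pos)
        train_pos.extend(perm[: alloc[cls]])
        val_pos.extend(perm[alloc[cls]:])
    return SplitPair(
        train=data.take(sorted(train_pos), provenance=data.provenance + " [train]"),
        validation=data.take(sorted(val_pos), provenance=data.provenance + " [validation]"),
        split_fraction=fraction,
        seed=seed,
    )


def make_ratio_subset(data: Dataset, ratio: float, seed: int) -> Dataset:
    """Construct an imbalanced variant with a target minority:majority ratio.

    All majority records are retained; exactly ``ceil(ratio * n_majority)``
    minority records are sampled without replacement (the smallest count
    achieving at least the requested ratio).
    """
    if not (0.0 < ratio <= 1.0):
        raise ValueError(f"ratio must be in (0, 1], got {ratio}")
    minority, majority = data.minority_class, data.majority_class
    maj_pos = np.flatnonzero((data.labels == majority).to_numpy())
    min_pos = np.flatnonzero((data.labels == minority).to_numpy())
    needed = math.ceil(ratio * len(maj_pos))
    if needed > len(min_pos):
        raise ValueError(
            f"infeasible ratio {ratio}: needs {needed} minority records, "
            f"only {len(min_pos)} available"
        )
    rng = np.random.default_rng(seed)
    chosen = rng.choice(min_pos, size=needed, replace=False)
    return data.take(
        sorted(np.concatenate([maj_pos, chosen])),
        provenance=data.provenance + f" [ratio={ratio}]",
    )
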