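from pathlib import Path

import numpy as np
import pandas as pd
import pytest

from enus.dataset import Dataset

REPO_ROOT = Path(__file__).resolve().parent.parent
WBC_FILE = REPO_ROOT / "data" / "breast-cancer-wisconsin.data"


def build_dataset(features: dict, labels, ids=None, positive="M") -> Dataset:
    """Construct a Dataset from plain columns; ids default to row numbers."""
    frame = pd.DataFrame(features, dtype=float)
    n = len(frame)
    if ids is None:
        ids = [f"r{i}" for i in range(n)]
    return Dataset(
        frame=frame,
        ids=pd.Series(ids, name="ID"),
        labels=pd.Series(list(labels), name="Class"),
        positive_class=positive,
    )


@pytest.fixture
def fig6_toy() -> Dataset:
    """Nine records, 3 minority (M) and 6 majority (B), two features."""
    return build_dataset(
        {
            "f1": [1, 2, 2, 3, 4, 5, 7, 8, 9],
            "f2": [2, 1, 3, 2, 4, 5, 8, 7, 9],
        },
        labels=["B", "B", "B", "B", "B", "B", "M", "M", "M"],
    )


@pytest.fixture
def fig6_train() -> Dataset:
    """The toy training partition: 2 minority, 5 majority."""
    return build_dataset(
        {
            "f1": [1, 2, 2, 3, 4, 7, 9],
            "f2": [2, 1, 3, 2, 4, 8, 9],
        },
        labels=["B", "B", "B", "B", "B", "M", "M"],
    )


@pytest.fixture(scope="session")
def wbc_path() -> Path:
    assert WBC_FILE.exists(), "bundled Wisconsin data file is missing"
    return WBC_FILE


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
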