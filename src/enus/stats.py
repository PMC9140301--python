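"""Spearman correlation screening and the two-sample t-test.

Used for collinearity detection before modeling (rank-based correlation
is appropriate for ordinal, non-normal features) and for significance
testing of per-model metric differences across repeated trials.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import stats as sps

from .dataset import Dataset

__all__ = [
    "CorrelationMatrix",
    "TTestResult",
    "spearman_matrix",
    "welch_t_test",
]

EXACT_PERMUTATION_MAX_N = 7


@dataclass
class CorrelationMatrix:
    """Pairwise Spearman rho and p-values over a feature table."""

    rho: pd.DataFrame
    p_value: pd.DataFrame
    collinear_pairs: list[tuple[str, str, float]]
    threshold: float
    method: str = "spearman"

    def get(self, a: str, b: str) -> tuple[float, float]:
        return float(self.rho.loc[a, b]), float(self.p_value.loc[a, b])


@dataclass(frozen=True)
class TTestResult:
    statistic: float
    df: float
    p_value: float
    conf_level: float
    mean_a: float
    mean_b: float
    conf_interval: tuple[float, float]

    def to_dict(self) -> dict:
        return {
            "statistic": self.statistic,
            "df": self.df,
            "p_value": self.p_value,
            "conf_level": self.conf_level,
            "mean_a": self.mean_a,
            "mean_b": self.mean_b,
            "conf_interval": list(self.conf_interval),
        }


def _spearman_rho(x: np.ndarray, y: np.ndarray) -> float:
    rx = sps.rankdata(x)  # average ranks for ties
    ry = sps.rankdata(y)
    if np.ptp(rx) == 0 or np.ptp(ry) == 0:
        return float("nan")
    return float(np.corrcoef(rx, ry)[0, 1])


@lru_cache(maxsize=8)
def _all_permutations(n: int) -> np.ndarray:
    return np.array(list(itertools.permutations(range(n))), dtype=np.intp)


def _exact_p(x: np.ndarray, y: np.ndarray, observed: float) -> float:
    """Exact two-sided permutation p-value for small samples.

    Permuting one variable's ranks leaves their mean and spread fixed, so
    rho is affine in the rank dot-product and all n! correlations can be
    evaluated as one matrix product.
    """
    rx, ry = sps.rankdata(x), sps.rankdata(y)
    cx, cy = rx - rx.mean(), ry - ry.mean()
    denom = math.sqrt((cx * cx).sum() * (cy * cy).sum())
    perms = _all_permutations(len(x))
    rhos = (cx[perms] @ cy) / denom
    return float((np.abs(rhos) >= abs(observed) - 1e-12).mean())


def _approx_p(rho: float, n: int) -> float:
    # t-approximation: t = rho * sqrt((n-2)/(1-rho^2))
    if abs(rho) >= 1.0:
        return 0.0
    t = rho * math.sqrt((n - 2) / (1.0 - rho * rho))
    return float(2.0 * sps.t.sf(abs(t), df=n - 2))


def spearman_matrix(data: Dataset, collinear_threshold: float = 0.9) -> CorrelationMatrix:
    """Pairwise Spearman correlations with tie-aware average ranks.

    p-values use an exact permutation test for very small samples and the
    t-approximation otherwise. Pairs with |rho| above the threshold are
    flagged for removal-candidate screening. Constant features yield NaN
    rho for their pairs.
    """
    X = data.frame.dropna()
    n = len(X)
    if n < 3:
        raise ValueError(f"need >= 3 complete records, have {n}")
    names = data.feature_names
    rho = pd.DataFrame(np.eye(len(names)), index=names, columns=names)
    pval = pd.DataFrame(np.zeros((len(names), len(names))), index=names, columns=names)
    flagged: list[tuple[str, str, float]] = []
    for a, b in itertools.combinations(names, 2):
        x, y = X[a].to_numpy(), X[b].to_numpy()
        r = _spearman_rho(x, y)
        if math.isnan(r):
            p = float("nan")
        elif n <= EXACT_PERMUTATION_MAX_N:
            p = _exact_p(x, y, r)
        else:
            p = _approx_p(r, n)
        rho.loc[a, b] = rho.loc[b, a] = r
        pval.loc[a, b] = pval.loc[b, a] = p
        if not math.isnan(r) and abs(r) >= collinear_threshold:
            flagged.append((a, b, r))
    return CorrelationMatrix(
        rho=rho, p_value=pval, collinear_pairs=flagged, threshold=collinear_threshold
    )


def welch_t_test(
    a, b, conf: float = 0.95, pooled: bool = False
) -> TTestResult:
    """Independent two-sample t-test (Welch by default).

    Welch's unequal-variance statistic with Welch-Satterthwaite degrees
    of freedom and a two-sided p-value; ``pooled=True`` switches to the
    equal-variance variant.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each sample needs at least 2 observations")
    if a.var(ddof=1) == 0.0 and b.var(ddof=1) == 0.0:
        # degenerate: both samples constant
        df = float(len(a) + len(b) - 2)
        if a.mean() == b.mean():
            t, p = 0.0, 1.0
        else:
            t = math.copysign(math.inf, a.mean() - b.mean())
            p = 0.0
        delta = a.mean() - b.mean()
        return TTestResult(
            statistic=t, df=df, p_value=p, conf_level=conf,
            mean_a=float(a.mean()), mean_b=float(b.mean()),
            conf_interval=(delta, delta),
        )
    res = sps.ttest_ind(a, b, equal_var=pooled)
    ci = res.confidence_interval(confidence_level=conf)
    return TTestResult(
        statistic=float(res.statistic),
        df=float(res.df),
        p_value=float(res.pvalue),
        conf_level=conf,
        mean_a=float(a.mean()),
        mean_b=float(b.mean()),
        conf_interval=(float(ci.low), float(ci.high)),
    )
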