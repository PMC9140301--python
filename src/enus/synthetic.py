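"""Generator for Wisconsin-like ordinal tabular datasets.

Produces two-class tables with 1-10 ordinal features, controlled class
imbalance, class-conditional mean separation, one strongly rank-
correlated feature pair (Gaussian-copula latent, calibrated to a target
Spearman rho on the emitted data), and class-independent weak features.
Everything downstream is testable against these without external data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.optimize import brentq

from .dataset import Dataset

__all__ = ["SyntheticSpec", "generate_synthetic_dataset", "wbc_like_spec"]

WBC_FEATURES = (
    "Clump_Thickness",
    "Cell_Size",
    "Cell_Shape",
    "Adhesion",
    "Epi_Cell_Size",
    "Nuclei",
    "Chromatin",
    "Nucleoli",
    "Mitoses",
)


@dataclass(frozen=True)
class SyntheticSpec:
    """Recipe for one synthetic dataset.

    ``class_locations`` maps label -> feature -> target class-conditional
    mean (post truncation); features absent from it are *weak*: drawn from
    one class-independent distribution. ``correlated_pair`` requests a
    target Spearman rho between two features on the full emitted table.
    """

    n_total: int = 700
    imbalance_ratio: float = 0.54  # minority/majority, ~65:35 overall
    feature_names: tuple[str, ...] = WBC_FEATURES
    negative_class: str = "B"
    positive_class: str = "M"
    class_locations: dict = field(
        default_factory=lambda: {
            "B": {f: 1.9 for f in WBC_FEATURES if f not in ("Clump_Thickness", "Mitoses")},
            "M": {f: 5.5 for f in WBC_FEATURES if f not in ("Clump_Thickness", "Mitoses")},
        }
    )
    class_scales: dict = field(default_factory=lambda: {"B": 1.1, "M": 2.4})
    weak_location: float = 3.0
    weak_scale: float = 2.0
    correlated_pair: tuple[str, str, float] = ("Cell_Shape", "Cell_Size", 0.91)
    seed: int = 0
    round_to_ordinal: bool = True
    value_range: tuple[float, float] = (1.0, 10.0)

    @classmethod
    def from_dict(cls, raw: dict) -> "SyntheticSpec":
        """Build a spec from a YAML/JSON mapping (lists become tuples)."""
        raw = dict(raw)
        for key in ("feature_names", "correlated_pair", "value_range"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    @property
    def weak_features(self) -> tuple[str, ...]:
        informative = set().union(*(m.keys() for m in self.class_locations.values()))
        return tuple(f for f in self.feature_names if f not in informative)

    def validate(self) -> None:
        if self.n_total < 10:
            raise ValueError("n_total must be >= 10")
        if not (0.0 < self.imbalance_ratio <= 1.0):
            raise ValueError("imbalance_ratio must be in (0, 1]")
        rho = self.correlated_pair[2]
        if not (-1.0 <= rho <= 1.0):
            raise ValueError("target rho must be in [-1, 1]")
        lo, hi = self.value_range
        for cls, locs in self.class_locations.items():
            for f, loc in locs.items():
                if not (lo <= loc <= hi):
                    raise ValueError(f"location {loc} for {cls}/{f} outside range")
                if f not in self.feature_names:
                    raise ValueError(f"unknown feature {f!r} in class_locations")


def _class_counts(n_total: int, ratio: float) -> tuple[int, int]:
    """(majority, minority) summing to n_total.

    Majority is the largest count whose ceiling-rule total fits, so the
    minority count is within one record of ceil(ratio * majority).
    """
    majority = int(n_total / (1.0 + ratio))
    while majority + math.ceil(ratio * majority) > n_total:
        majority -= 1
    while majority + 1 + math.ceil(ratio * (majority + 1)) <= n_total:
        majority += 1
    return majority, n_total - majority


@lru_cache(maxsize=256)
def _solve_truncnorm_loc(target_mean: float, scale: float, lo: float, hi: float) -> float:
    """Location parameter whose [lo,hi]-truncated normal mean hits target."""

    def truncated_mean(loc: float) -> float:
        a, b = (lo - loc) / scale, (hi - loc) / scale
        return float(sps.truncnorm.mean(a, b, loc=loc, scale=scale))

    return brentq(
        lambda loc: truncated_mean(loc) - target_mean,
        lo - 6 * scale,
        hi + 6 * scale,
        xtol=1e-10,
    )


def _truncnorm_from_normal(z: np.ndarray, loc: float, scale: float,
                           lo: float, hi: float) -> np.ndarray:
    """Map standard-normal draws through the truncated-normal quantile."""
    a, b = (lo - loc) / scale, (hi - loc) / scale
    u = sps.norm.cdf(z)
    # keep strictly inside (0,1) so ppf stays finite
    u = np.clip(u, 1e-12, 1.0 - 1e-12)
    return sps.truncnorm.ppf(u, a, b, loc=loc, scale=scale)


def _finalize(values: np.ndarray, spec: SyntheticSpec) -> np.ndarray:
    if spec.round_to_ordinal:
        values = np.rint(values)
    return np.clip(values, *spec.value_range)


def _emit(spec: SyntheticSpec, latent_rho: float, draws: dict) -> pd.DataFrame:
    """Assemble the feature table for a given latent pair correlation."""
    lo, hi = spec.value_range
    fa, fb, _ = spec.correlated_pair
    cols: dict[str, np.ndarray] = {}
    labels = draws["labels"]
    for f in spec.feature_names:
        if f == fb and fa in spec.feature_names:
            z = latent_rho * draws["z"][fa] + math.sqrt(1 - latent_rho**2) * draws["eps"]
        else:
            z = draws["z"][f]
        out = np.empty(len(labels))
        for cls in (spec.negative_class, spec.positive_class):
            mask = labels == cls
            if f in spec.class_locations.get(cls, {}):
                target = spec.class_locations[cls][f]
                scale = spec.class_scales[cls]
            else:
                target = spec.weak_location
                scale = spec.weak_scale
            loc = _solve_truncnorm_loc(target, scale, lo, hi)
            out[mask] = _truncnorm_from_normal(z[mask], loc, scale, lo, hi)
        cols[f] = _finalize(out, spec)
    return pd.DataFrame(cols, columns=list(spec.feature_names))


def _spearman(x: np.ndarray, y: np.ndarray) -> float:
    rx, ry = sps.rankdata(x), sps.rankdata(y)
    if np.ptp(rx) == 0 or np.ptp(ry) == 0:
        return 0.0
    return float(np.corrcoef(rx, ry)[0, 1])


def generate_synthetic_dataset(spec: SyntheticSpec) -> Dataset:
    """Generate one dataset per the spec; fully seed-deterministic.

    Class counts honor ``minority = ceil(ratio * majority)``. Informative
    features are truncated normals whose location is solved analytically
    so the class-conditional mean matches the requested target. The
    correlated pair shares a Gaussian latent whose correlation is
    calibrated by bisection against the empirical Spearman rho of the
    emitted (rounded, clipped) columns.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n_major, n_minor = _class_counts(spec.n_total, spec.imbalance_ratio)
    labels = np.array(
        [spec.negative_class] * n_major + [spec.positive_class] * n_minor
    )
    # one latent normal per feature + one extra for the correlated partner;
    # reused across calibration iterations so rho is monotone in latent_rho
    draws = {
        "labels": labels,
        "z": {f: rng.standard_normal(len(labels)) for f in spec.feature_names},
        "eps": rng.standard_normal(len(labels)),
    }
    fa, fb, target_rho = spec.correlated_pair
    latent = 0.0
    if fa in spec.feature_names and fb in spec.feature_names and target_rho != 0.0:
        def rho_error(latent_rho: float) -> float:
            frame = _emit(spec, latent_rho, draws)
            return _spearman(frame[fa].to_numpy(), frame[fb].to_numpy()) - target_rho

        lo_err, hi_err = rho_error(-0.999), rho_error(0.999)
        if lo_err * hi_err > 0:  # target unreachable; take the closest endpoint
            latent = -0.999 if abs(lo_err) < abs(hi_err) else 0.999
        else:
            latent = brentq(rho_error, -0.999, 0.999, xtol=1e-3)
    frame = _emit(spec, latent, draws)
    # shuffle record order so class blocks are not contiguous
    perm = rng.permutation(len(labels))
    frame = frame.iloc[perm].reset_index(drop=True)
    labels = labels[perm]
    return Dataset(
        frame=frame,
        ids=pd.Series([f"synth-{i}" for i in range(len(labels))], name="ID"),
        labels=pd.Series(labels, name="Class"),
        positive_class=spec.positive_class,
        provenance=f"synthetic(seed={spec.seed}, ratio={spec.imbalance_ratio})",
    )


def wbc_like_spec(**overrides) -> SyntheticSpec:
    """The default Wisconsin-like recipe with optional field overrides."""
    return SyntheticSpec(**overrides)


def hard_imbalanced_spec(
    seed: int = 0, n_total: int = 800, ratio: float = 0.10
) -> SyntheticSpec:
    """A deliberately hard imbalanced recipe for resampling benchmarks.

    Three informative features, a compact minority cluster inside a broad
    majority cloud: classifiers trained on the raw imbalance miss most
    minority records, leaving headroom for up-sampling to recover
    sensitivity. Used by the directional-effect evaluations.
    """
    inform = ("Cell_Shape", "Cell_Size", "Nuclei")
    return SyntheticSpec(
        n_total=n_total,
        imbalance_ratio=ratio,
        seed=seed,
        class_locations={
            "B": {f: 2.8 for f in inform},
            "M": {f: 4.2 for f in inform},
        },
        class_scales={"B": 2.6, "M": 1.4},
    )
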