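import numpy as np
import pandas as pd
import pytest

from enus.sampler import (
    OperationCounter,
    SamplerConfig,
    duplicate_balance,
    enus_balance,
    find_k_nearest_minority,
    synthesize_record,
)

from conftest import build_dataset


# ----------------------------------------------------------- neighbor search
def test_neighbor_1d_simple():
    data = build_dataset(
        {"x": [2, 3, 9, 1, 1, 1, 1]},
        labels=["M", "M", "M", "B", "B", "B", "B"],
    )
    nearest = find_k_nearest_minority(data, centroid_position=0, k=1)
    assert list(nearest) == [1]  # value 3 is closer to 2 than 9 is


def test_neighbor_k_exceeding_m_returns_all_others():
    data = build_dataset(
        {"x": [2, 3, 9, 1, 1, 1, 1]},
        labels=["M", "M", "M", "B", "B", "B", "B"],
    )
    nearest = find_k_nearest_minority(data, centroid_position=0, k=50)
    assert sorted(nearest) == [1, 2]


def test_neighbor_tie_break_by_record_order():
    # two minority records equidistant from the centroid
    data = build_dataset(
        {"x": [5, 4, 6, 1, 1, 1, 1]},
        labels=["M", "M", "M", "B", "B", "B", "B"],
    )
    nearest = find_k_nearest_minority(data, centroid_position=0, k=2)
    assert list(nearest) == [1, 2]  # earlier record first on a tie


def test_neighbor_requires_minority_centroid(fig6_train):
    with pytest.raises(ValueError, match="not a minority record"):
        find_k_nearest_minority(fig6_train, centroid_position=0, k=1)


def test_neighbor_single_minority_signals_fallback():
    data = build_dataset({"x": [1, 2, 3]}, labels=["M", "B", "B"])
    with pytest.raises(ValueError, match="at least 2"):
        find_k_nearest_minority(data, centroid_position=0, k=1)


def brute_force_neighbors(X, minority_pos, centroid, k):
    others = [p for p in minority_pos if p != centroid]
    dists = [(np.linalg.norm(X[p] - X[centroid]), i, p) for i, p in enumerate(others)]
    dists.sort()  # distance, then original order
    return [p for _, _, p in dists[:k]]


def test_neighbor_matches_brute_force_on_random_instances(rng):
    for _ in range(100):
        n = int(rng.integers(6, 25))
        d = int(rng.integers(1, 5))
        n_min = int(rng.integers(2, (n - 1) // 2 + 1))  # strict minority
        labels = ["M"] * n_min + ["B"] * (n - n_min)
        # low-cardinality values force plenty of distance ties
        X = rng.integers(1, 5, size=(n, d)).astype(float)
        data = build_dataset(
            {f"f{j}": X[:, j] for j in range(d)}, labels=labels
        )
        centroid = int(rng.integers(0, n_min))
        k = int(rng.integers(1, n_min + 2))
        got = list(find_k_nearest_minority(data, centroid, k))
        expected = brute_force_neighbors(X, list(range(n_min)), centroid, k)
        assert got == expected


# -------------------------------------------------------------- synthesis
class HalfRng:
    """Stub generator: every uniform draw is 0.5."""

    def random(self, n):
        return np.full(n, 0.5)


def test_synthesize_forced_u_half():
    c = pd.Series({"x": 2.0})
    n = pd.Series({"x": 6.0})
    out, trace = synthesize_record(
        c, n, "c", "n", "synthetic-0", HalfRng(), SamplerConfig()
    )
    assert out["x"] == pytest.approx(4.0)
    assert trace.u["x"] == 0.5


def test_synthesize_identical_parents_copies_centroid(rng):
    c = pd.Series({"x": 3.0, "y": 7.0})
    out, _ = synthesize_record(
        c, c.copy(), "a", "b", "synthetic-0", rng, SamplerConfig()
    )
    assert out.tolist() == [3.0, 7.0]


def test_synthesize_schema_mismatch():
    with pytest.raises(ValueError, match="schema"):
        synthesize_record(
            pd.Series({"x": 1.0}),
            pd.Series({"y": 1.0}),
            "a",
            "b",
            "s",
            np.random.default_rng(0),
            SamplerConfig(),
        )


def test_synthetic_values_respect_parent_envelope(rng):
    """10,000 traced syntheses stay inside the per-feature parent interval."""
    n_min, deficit = 12, 10_000
    data = build_dataset(
        {
            "a": np.concatenate([rng.uniform(1, 10, n_min), rng.uniform(1, 10, n_min + deficit)]),
            "b": np.concatenate([rng.uniform(1, 10, n_min), rng.uniform(1, 10, n_min + deficit)]),
        },
        labels=["M"] * n_min + ["B"] * (n_min + deficit),
    )
    _, traces = enus_balance(data, SamplerConfig(seed=8), return_trace=True)
    assert len(traces) == deficit
    by_id = dict(zip(data.ids, data.frame.to_dict("records")))
    for t in traces:
        c, nb = by_id[t.centroid_id], by_id[t.neighbor_id]
        for f in ("a", "b"):
            lo, hi = min(c[f], nb[f]), max(c[f], nb[f])
            assert lo <= t.values[f] <= hi
            assert 0.0 <= t.u[f] < 1.0


# -------------------------------------------------------------- balancing
def test_fig6_toy_balance_counts(fig6_train):
    balanced = enus_balance(fig6_train, SamplerConfig(seed=1))
    assert len(balanced) == 10
    assert balanced.class_counts() == {"B": 5, "M": 5}


def test_balance_preserves_originals(fig6_train):
    balanced = enus_balance(fig6_train, SamplerConfig(seed=1))
    pd.testing.assert_frame_equal(
        balanced.frame.iloc[: len(fig6_train)], fig6_train.frame
    )
    assert list(balanced.ids[: len(fig6_train)]) == list(fig6_train.ids)


def test_balance_trace_envelope(fig6_train):
    balanced, traces = enus_balance(
        fig6_train, SamplerConfig(seed=7), return_trace=True
    )
    assert len(traces) == 3
    by_id = dict(zip(fig6_train.ids, fig6_train.frame.to_dict("records")))
    for t in traces:
        c, n = by_id[t.centroid_id], by_id[t.neighbor_id]
        for f, v in t.values.items():
            assert min(c[f], n[f]) <= v <= max(c[f], n[f])


def test_already_balanced_returned_unchanged():
    data = build_dataset({"x": [1, 2, 8, 9]}, labels=["B", "B", "M", "M"])
    balanced = enus_balance(data, SamplerConfig(seed=0))
    pd.testing.assert_frame_equal(balanced.frame, data.frame)
    assert list(balanced.labels) == list(data.labels)


def test_single_minority_fallback_duplicates():
    data = build_dataset(
        {"x": [5, 1, 2, 3, 4]}, labels=["M", "B", "B", "B", "B"]
    )
    balanced = enus_balance(data, SamplerConfig(seed=0))
    assert balanced.class_counts() == {"B": 4, "M": 4}
    synth = balanced.frame.iloc[-3:]
    assert (synth["x"] == 5.0).all()


def test_single_minority_fallback_error_policy():
    data = build_dataset({"x": [5, 1, 2]}, labels=["M", "B", "B"])
    with pytest.raises(ValueError, match="fallback"):
        enus_balance(data, SamplerConfig(seed=0, fallback="error"))


def test_single_class_input_errors():
    data = build_dataset({"x": [1, 2]}, labels=["B", "B"])
    with pytest.raises(ValueError, match="both classes"):
        enus_balance(data)
    with pytest.raises(ValueError, match="both classes"):
        duplicate_balance(data)


def test_seed_determinism_byte_identical(fig6_train):
    a = enus_balance(fig6_train, SamplerConfig(seed=99))
    b = enus_balance(fig6_train, SamplerConfig(seed=99))
    assert a.frame.equals(b.frame)
    assert list(a.ids) == list(b.ids)
    assert a.frame.to_csv() == b.frame.to_csv()


def test_different_seeds_differ(fig6_train):
    a = enus_balance(fig6_train, SamplerConfig(seed=1))
    b = enus_balance(fig6_train, SamplerConfig(seed=2))
    assert not a.frame.equals(b.frame)


def test_strict_nearest_policy_uses_first_neighbor():
    data = build_dataset(
        {"x": [2.0, 3.0, 9.0, 1, 1, 1, 1]},
        labels=["M", "M", "M", "B", "B", "B", "B"],
    )
    _, traces = enus_balance(
        data,
        SamplerConfig(seed=0, neighbor_choice="strict-nearest", k=2),
        return_trace=True,
    )
    for t in traces:
        if t.centroid_id == "r0":
            assert t.neighbor_id == "r1"
        elif t.centroid_id == "r1":
            assert t.neighbor_id == "r0"
        else:  # centroid 9 -> nearest is 3
            assert t.neighbor_id == "r1"


def test_round_to_ordinal_yields_integers(fig6_train):
    balanced = enus_balance(
        fig6_train, SamplerConfig(seed=5, round_to_ordinal=True)
    )
    synth = balanced.frame.iloc[len(fig6_train):]
    assert (synth == synth.round()).all().all()
    assert synth.ge(1).all().all() and synth.le(10).all().all()


def test_duplicate_balance_fig6_counts_and_membership(fig6_train):
    balanced = duplicate_balance(fig6_train, seed=4)
    assert len(balanced) == 10
    assert balanced.class_counts() == {"B": 5, "M": 5}
    originals = set(map(tuple, fig6_train.frame.to_numpy().tolist()))
    for row in balanced.frame.iloc[len(fig6_train):].to_numpy():
        assert tuple(row) in originals


def test_duplicate_balance_noop_when_balanced():
    data = build_dataset({"x": [1, 9]}, labels=["B", "M"])
    balanced = duplicate_balance(data, seed=0)
    pd.testing.assert_frame_equal(balanced.frame, data.frame)


def test_degenerate_equivalence_identical_minority():
    """All-identical minority: interpolation and duplication coincide."""
    data = build_dataset(
        {"x": [4, 4, 4, 1, 2, 3, 1, 2], "y": [6, 6, 6, 1, 1, 2, 2, 1]},
        labels=["M", "M", "M", "B", "B", "B", "B", "B"],
    )
    a = enus_balance(data, SamplerConfig(seed=3))
    b = duplicate_balance(data, seed=3)
    pd.testing.assert_frame_equal(a.frame, b.frame)
    assert list(a.labels) == list(b.labels)


def test_operation_counter_matches_complexity_derivation():
    """Each synthesis scans all m-1 other minority records across d features."""
    m, d = 6, 3
    n_major = 10
    rng = np.random.default_rng(0)
    data = build_dataset(
        {f"f{j}": rng.uniform(1, 10, m + n_major) for j in range(d)},
        labels=["M"] * m + ["B"] * n_major,
    )
    counter = OperationCounter()
    enus_balance(data, SamplerConfig(seed=0), counter=counter)
    deficit = n_major - m
    assert counter.syntheses == deficit
    assert counter.feature_diff_ops == deficit * d * (m - 1)
    assert counter.distance_evals == deficit * (m - 1)
    assert counter.sorts == deficit


def test_balance_property_randomized(rng):
    for _ in range(20):
        n_min = int(rng.integers(2, 8))
        n_maj = int(rng.integers(n_min, 20))
        data = build_dataset(
            {"x": rng.uniform(1, 10, n_min + n_maj)},
            labels=["M"] * n_min + ["B"] * n_maj,
        )
        for balanced in (
            enus_balance(data, SamplerConfig(seed=1)),
            duplicate_balance(data, seed=1),
        ):
            counts = balanced.class_counts()
            assert counts["M"] == counts["B"] == n_maj
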