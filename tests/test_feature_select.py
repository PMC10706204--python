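"""Selection cascade: ANOVA, redundancy filter, backward OLS, gini ranking."""

import numpy as np
import pandas as pd
import pytest

from cfsgrade.feature_select import (
    FeatureTable,
    SelectionConfig,
    anova_filter,
    backward_elimination,
    build_signatures,
    pearson_redundancy_filter,
    run_selection,
    tree_importance,
)


def _table(columns: dict, labels) -> FeatureTable:
    return FeatureTable.from_raw(pd.DataFrame(columns), np.asarray(labels))


@pytest.fixture(scope="module")
def labeled_rng():
    return np.random.default_rng(42)


def test_anova_keeps_signal_drops_noise_and_constant(labeled_rng):
    rng = labeled_rng
    n = 500
    y = np.repeat(np.arange(5), n // 5)
    tbl = _table(
        {
            "signal": y + rng.normal(0, 0.3, n),
            "noise": rng.normal(0, 1, n),
            "constant": np.zeros(n),
        },
        y,
    )
    kept = anova_filter(tbl, alpha=0.05)
    assert "signal" in kept
    assert "constant" not in kept


def test_anova_null_calibration(labeled_rng):
    # a label-independent feature survives with probability ~alpha
    rng = labeled_rng
    n = 500
    y = np.repeat(np.arange(5), n // 5)
    kept = 0
    reps = 40
    for _ in range(reps):
        tbl = _table({"noise": rng.normal(0, 1, n)}, y)
        kept += len(anova_filter(tbl, alpha=0.05))
    assert kept <= 8  # Binomial(40, 0.05): P(X > 8) < 1e-3


def test_anova_requires_two_populated_classes():
    with pytest.raises(ValueError):
        anova_filter(_table({"a": [1.0, 2.0, 3.0]}, [0, 0, 0]), 0.05)
    with pytest.raises(ValueError):
        anova_filter(_table({"a": [1.0, 2.0, 3.0]}, [0, 0, 1]), 0.05)


def test_prbf_removes_duplicates_and_negations(labeled_rng):
    rng = labeled_rng
    n = 200
    y = np.repeat(np.arange(2), n // 2)
    base = y + rng.normal(0, 0.5, n)
    tbl = _table({"f": base, "f_copy": base.copy(), "f_neg": -base}, y)
    kept = pearson_redundancy_filter(tbl, ["f", "f_copy", "f_neg"], threshold=0.9)
    assert len(kept) == 1


def test_prbf_keeps_independent_features(labeled_rng):
    rng = labeled_rng
    n = 200
    y = rng.integers(0, 2, n)
    tbl = _table({"a": rng.normal(size=n), "b": rng.normal(size=n)}, y)
    kept = pearson_redundancy_filter(tbl, ["a", "b"], threshold=0.9)
    assert sorted(kept) == ["a", "b"]


def test_backward_elimination_finds_true_predictor(labeled_rng):
    rng = labeled_rng
    n = 300
    f1 = rng.normal(size=n)
    y = 2.0 * f1 + rng.normal(0, 0.5, n)
    cols = {"f1": f1}
    for i in range(10):
        cols[f"noise{i}"] = rng.normal(size=n)
    tbl = _table(cols, y)
    kept = backward_elimination(tbl, list(cols), p_out=0.05)
    assert "f1" in kept
    assert len(kept) <= 4  # nearly all noise removed (floor is 2 features)


def test_backward_elimination_all_noise_hits_floor(labeled_rng):
    rng = labeled_rng
    n = 300
    y = rng.normal(size=n)
    cols = {f"n{i}": rng.normal(size=n) for i in range(8)}
    kept = backward_elimination(_table(cols, y), list(cols), p_out=0.05)
    assert len(kept) <= 3


def test_backward_elimination_single_feature_unchanged(labeled_rng):
    rng = labeled_rng
    tbl = _table({"only": rng.normal(size=50)}, rng.integers(0, 5, 50))
    assert backward_elimination(tbl, ["only"], 0.05) == ["only"]


def test_backward_elimination_drops_exact_collinears(labeled_rng):
    rng = labeled_rng
    n = 100
    a = rng.normal(size=n)
    y = a + rng.normal(0, 0.2, n)
    tbl = _table({"a": a, "b": 2 * a, "c": rng.normal(size=n)}, y)
    kept = backward_elimination(tbl, ["a", "b", "c"], 0.05)
    assert not {"a", "b"} <= set(kept)  # at most one of the collinear pair


def test_tree_importance_ranks_separating_feature_first(labeled_rng):
    rng = labeled_rng
    n = 200
    y = np.repeat(np.arange(4), n // 4)
    cols = {"perfect": y.astype(float)}
    for i in range(5):
        cols[f"noise{i}"] = rng.normal(size=n)
    sig = tree_importance(_table(cols, y), list(cols), seed=0)
    assert sig.names[0] == "perfect"
    assert sig.importance["perfect"] > 0.9
    # unused features have zero importance
    assert min(sig.importance.values()) == 0.0
    # importance non-increasing in rank
    vals = [sig.importance[n_] for n_ in sig.names]
    assert all(a >= b for a, b in zip(vals, vals[1:]))


def test_tree_importance_splits_between_identical_twins(labeled_rng):
    rng = labeled_rng
    n = 400
    y = np.repeat(np.arange(2), n // 2)
    informative = y + rng.normal(0, 0.1, n)
    cols = {"twin_a": informative, "twin_b": informative.copy(),
            "noise": rng.normal(size=n)}
    sig = tree_importance(_table(cols, y), list(cols), seed=1)
    both = sig.importance["twin_a"] + sig.importance["twin_b"]
    assert both > sig.importance["noise"]
    assert set(sig.names[:1]) <= {"twin_a", "twin_b"}


def test_build_signatures_category_filters():
    names = [
        "topology-1-1", "topology-2-1", "texture-1-1", "morphology-1",
        "topology-3-4", "texture-2-5", "topology-4-2", "topology-5-5",
        "morphology-5", "texture-3-7", "topology-6-6",
    ]
    sig_in = type("S", (), {})()
    from cfsgrade.feature_select import Signature

    sig = Signature(names=names, importance={n: 1.0 / (i + 1) for i, n in enumerate(names)})
    subs = build_signatures(sig)
    assert subs["A-10"].names == names[:10]
    assert len(subs["T-5"].names) == 5
    assert all(n.startswith("topology-") for n in subs["T-5"].names)
    assert not any(n.startswith("topology-") for n in subs["NT-5"].names)
    assert not any(n.startswith("topology-") for n in subs["NT-10"].names)
    # six topological features in the top seven stay in A-10
    topo_in_top7 = [n for n in names[:7] if n.startswith("topology-")]
    assert set(topo_in_top7) <= set(subs["A-10"].names)


def test_build_signatures_warns_when_short():
    from cfsgrade.feature_select import Signature

    sig = Signature(names=["texture-1-1", "topology-1-1"],
                    importance={"texture-1-1": 1.0, "topology-1-1": 0.5})
    with pytest.warns(UserWarning):
        subs = build_signatures(sig)
    assert subs["T-5"].names == ["topology-1-1"]


def test_cascade_nesting_property(labeled_rng):
    rng = labeled_rng
    n = 250
    y = np.repeat(np.arange(5), n // 5)
    cols = {f"f{i}": (y if i < 4 else 0) + rng.normal(0, 1, n) for i in range(20)}
    cols["dup"] = cols["f0"].copy()
    tbl = _table(cols, y)
    sig, stages = run_selection(tbl, SelectionConfig(seed=0))
    assert set(stages["prbf"]) <= set(stages["anova"])
    assert set(stages["backward"]) <= set(stages["prbf"])
    assert set(sig.names) == set(stages["backward"])


def test_normalization_statistics_frozen():
    df = pd.DataFrame({"a": [1.0, 2.0, 3.0, 4.0], "b": [10.0, 10.0, 30.0, 30.0]})
    tbl = FeatureTable.from_raw(df, np.array([0, 0, 1, 1]))
    assert np.allclose(tbl.data.mean(), 0, atol=1e-12)
    assert np.allclose(tbl.data.std(ddof=0), 1, atol=1e-12)
    held_out = pd.DataFrame({"a": [2.5], "b": [20.0]})
    z = tbl.apply_normalization(held_out)
    assert np.allclose(z.values, [[0.0, 0.0]], atol=1e-12)
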