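"""Upsampling, OOB tuning and the random-forest cascade."""

import collections

import numpy as np
import pandas as pd
import pytest

from gutenz import models
from gutenz.models import (UNCLASSIFIED, CascadeModel, default_mtry,
                           select_ntree, train_cascade, tune_mtry, upsample)


def test_upsample_balances_and_preserves_originals():
    X = np.arange(14).reshape(-1, 1)
    y = np.array(["A"] * 10 + ["B"] * 4)
    Xb, yb = upsample(X, y, seed=0)
    counts = collections.Counter(yb)
    assert counts == {"A": 10, "B": 10}
    b_rows = set(Xb[yb == "B"].ravel().tolist())
    assert {10, 11, 12, 13} <= b_rows  # all four originals present


def test_upsample_balanced_input_unchanged_and_single_class_errors():
    X = np.arange(8).reshape(-1, 1)
    y = np.array(["A", "B"] * 4)
    Xb, yb = upsample(X, y, seed=1)
    assert sorted(Xb.ravel().tolist()) == list(range(8))
    with pytest.raises(ValueError):
        upsample(X, np.array(["A"] * 8), seed=0)


def test_upsample_count_audit_three_classes():
    rng = np.random.default_rng(0)
    X = rng.random((110, 3))
    y = np.array(["A"] * 100 + ["B"] * 7 + ["C"] * 3)
    Xb, yb = upsample(X, y, seed=5)
    assert collections.Counter(yb) == {"A": 100, "B": 100, "C": 100}
    # duplicates can only come from the minority classes
    a_rows = Xb[yb == "A"]
    assert len(np.unique(a_rows, axis=0)) == 100
    for cls, orig in (("B", X[100:107]), ("C", X[107:])):
        rows = Xb[yb == cls]
        assert {tuple(r) for r in rows} <= {tuple(r) for r in orig}


@pytest.mark.parametrize("p,expected", [(219, 15), (1, 1), (4, 2), (20, 4)])
def test_mtry_start_is_round_half_up_sqrt(p, expected):
    assert default_mtry(p) == expected


def _separable(rng, n=90, p=24):
    y = rng.integers(0, 3, n)
    X = rng.integers(0, 2, (n, p)).astype(float)
    for k in range(3):
        X[y == k, k] = 1.0
        X[y != k, k] = 0.0
    return X, y


def test_tune_mtry_trace_structure_and_determinism():
    rng = np.random.default_rng(6)
    X, y = _separable(rng)
    res = tune_mtry(X, y, seed=3)
    assert res.search_trace[0][0] == default_mtry(X.shape[1])
    traced = dict(res.search_trace)
    assert traced[res.mtry] == res.oob_error_percent
    assert res.oob_error_percent == min(err for _, err in res.search_trace)
    # step factor 2: every probe is a round-half-up double/half chain from start
    reachable = {default_mtry(X.shape[1])}
    for _ in range(12):
        reachable |= {models.round_half_up(m * 2) for m in reachable}
        reachable |= {max(1, models.round_half_up(m / 2)) for m in reachable}
    assert {m for m, _ in res.search_trace} <= reachable
    res2 = tune_mtry(X, y, seed=3)
    assert res2.search_trace == res.search_trace


def test_tune_mtry_single_column():
    rng = np.random.default_rng(1)
    y = rng.integers(0, 2, 40)
    X = y.reshape(-1, 1).astype(float)
    assert tune_mtry(X, y, seed=0).mtry == 1


def test_select_ntree_tie_goes_to_largest_and_single_grid():
    rng = np.random.default_rng(2)
    X, y = _separable(rng)  # flat zero OOB error across the grid
    assert select_ntree(X, y, mtry=5, seed=0) == 500
    assert select_ntree(X, y, mtry=5, grid=[200], seed=0) == 200


def test_cascade_structure_and_consistency(sep_cascade, sep_db, sep_features):
    assert sorted(sep_cascade.subclass_models) == [1, 2, 3, 4, 5, 6]
    assert set(sep_cascade.training_counts["class"].values()) == {60}
    X = sep_features.loc[:, sep_cascade.hybrid_spec.selected]
    row = X.iloc[0].to_numpy()
    cls, probs = sep_cascade.predict_class(row)
    assert sum(probs.values()) == pytest.approx(1.0, abs=1e-9)
    sub, sprobs = sep_cascade.predict_subclass(cls, row)
    assert sub in sprobs  # reported subclass drawn from this class's model
    assert cls in range(1, 7)


def test_upsampling_mode_recorded_and_without_mode_uses_raw_counts(sep_db, sep_hybrid, sep_features):
    m = train_cascade(sep_db, sep_hybrid, sampling=models.WITHOUT_UPSAMPLING,
                      seed=0, features=sep_features, tune=False)
    assert m.sampling == models.WITHOUT_UPSAMPLING
    raw = {c: len(ids) for c, ids in sep_db.class_index.items()}
    assert m.training_counts["class"] == raw


def test_prediction_threshold_boundary(sep_cascade, sep_features):
    row = sep_features.loc[:, sep_cascade.hybrid_spec.selected].iloc[0].to_numpy()
    label, _ = sep_cascade.predict_class(row, threshold=1.01)
    assert label == UNCLASSIFIED
    missing, probs = sep_cascade.predict_subclass(99, row)
    assert missing == "no-subclass-model" and probs == {}


def test_dimension_mismatch_fatal(sep_cascade):
    with pytest.raises(ValueError, match="dimension"):
        sep_cascade.predict_class(np.zeros(3))


def test_save_load_reproduces_predictions(tmp_path, sep_cascade, sep_features):
    sep_cascade.save(str(tmp_path / "m"))
    back = CascadeModel.load(str(tmp_path / "m"))
    X = sep_features.loc[:, sep_cascade.hybrid_spec.selected].to_numpy()
    for row in X[::60]:
        assert back.predict_class(row) == sep_cascade.predict_class(row)
    assert back.hybrid_spec.content_hash == sep_cascade.hybrid_spec.content_hash


def test_seeded_determinism_of_training(sep_db, sep_hybrid, sep_features):
    a = train_cascade(sep_db, sep_hybrid, seed=4, features=sep_features, tune=False)
    b = train_cascade(sep_db, sep_hybrid, seed=4, features=sep_features, tune=False)
    row = sep_features.loc[:, sep_hybrid.selected].iloc[17].to_numpy()
    assert a.predict_class(row) == b.predict_class(row)
    assert a.tuning["class"].oob_error_percent == b.tuning["class"].oob_error_percent
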