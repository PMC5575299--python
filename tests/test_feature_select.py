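"""Dominance screening, CFS merit and best-first subset search."""

import itertools

import numpy as np
import pandas as pd
import pytest

from gutenz.feature_select import (HybridSpec, best_first_select, build_hybrid,
                                   cfs_merit, project, remove_useless,
                                   symmetric_uncertainty)


def _random_table(rng, n_rows, n_cols, prefix="f"):
    data = (rng.random((n_rows, n_cols)) < rng.uniform(0.05, 0.6, n_cols)).astype(np.uint8)
    return pd.DataFrame(data, columns=[f"{prefix}:{i}" for i in range(n_cols)])


def test_remove_useless_drops_constant_and_dominated_columns():
    n = 1000
    table = pd.DataFrame({
        "a:0": np.zeros(n, dtype=np.uint8),                      # constant
        "a:1": np.r_[1, np.zeros(n - 1)].astype(np.uint8),       # 0.999 > 0.99
        "a:2": np.r_[np.ones(n // 2), np.zeros(n // 2)].astype(np.uint8),
    })
    assert remove_useless(table) == ["a:2"]


def test_remove_useless_matches_frequency_scan_oracle():
    rng = np.random.default_rng(4)
    table = _random_table(rng, 200, 60)
    survivors = remove_useless(table, max_dominance=0.9)
    freq = table.mean(axis=0)
    expected = [c for c in table.columns
                if max(freq[c], 1 - freq[c]) <= 0.9]
    assert survivors == expected


def test_remove_useless_all_removed_is_fatal():
    table = pd.DataFrame({"a:0": np.zeros(10, dtype=np.uint8)})
    with pytest.raises(ValueError):
        remove_useless(table)


def test_symmetric_uncertainty_limits():
    rng = np.random.default_rng(0)
    x = rng.integers(0, 2, 200)
    assert symmetric_uncertainty(x, x) == pytest.approx(1.0)
    assert symmetric_uncertainty(x, 1 - x) == pytest.approx(1.0)  # bijection
    assert symmetric_uncertainty(x, np.zeros_like(x)) == 0.0
    y = rng.integers(0, 2, 200)
    su = symmetric_uncertainty(x, y)
    assert 0.0 <= su < 0.1  # independent draws: near zero


def test_cfs_merit_perfect_column_and_redundant_copy():
    rng = np.random.default_rng(1)
    y = rng.integers(0, 2, 100)
    table = pd.DataFrame({"a:0": y.astype(np.uint8),
                          "a:1": y.astype(np.uint8),
                          "a:2": rng.integers(0, 2, 100).astype(np.uint8)})
    single = cfs_merit(["a:0"], table, y)
    assert single == pytest.approx(1.0)
    # a duplicated perfect column neither helps nor hurts (r_ff = 1):
    # merit stays k·1/sqrt(k + k(k-1)) = 1
    assert cfs_merit(["a:0", "a:1"], table, y) == pytest.approx(single)
    # an uncorrelated noise column dilutes the merit
    assert cfs_merit(["a:0", "a:2"], table, y) < single
    with pytest.raises(ValueError):
        cfs_merit([], table, y)


def test_best_first_matches_exhaustive_search_on_small_table():
    rng = np.random.default_rng(9)
    n = 120
    y = rng.integers(0, 2, n)
    cols = {}
    for i in range(10):
        noise = rng.random(n) < 0.25
        cols[f"f:{i}"] = np.where(noise, 1 - y, y).astype(np.uint8) \
            if i < 3 else rng.integers(0, 2, n).astype(np.uint8)
    table = pd.DataFrame(cols)
    best_merit = max(
        cfs_merit(list(sub), table, y)
        for r in range(1, 11)
        for sub in itertools.combinations(table.columns, r))
    found = best_first_select(table, y)
    assert cfs_merit(found, table, y) == pytest.approx(best_merit)


def test_planted_signal_recovered_among_noise_and_deterministic():
    rng = np.random.default_rng(12)
    n = 300
    y = rng.integers(0, 3, n)
    planted = {f"p:{k}": (y == k).astype(np.uint8) for k in range(3)}
    noise = {f"n:{i}": rng.integers(0, 2, n).astype(np.uint8) for i in range(60)}
    table = pd.DataFrame({**planted, **noise})
    found = best_first_select(table, y)
    assert set(planted) <= set(found)
    assert best_first_select(table, y) == found  # rerun: identical
    # merit of result beats every singleton
    best_single = max(cfs_merit([c], table, y) for c in table.columns)
    assert cfs_merit(found, table, y) >= best_single


def test_selection_invariant_to_row_order():
    rng = np.random.default_rng(8)
    n = 150
    y = rng.integers(0, 2, n)
    table = _random_table(rng, n, 12)
    table.iloc[:, 0] = y
    perm = rng.permutation(n)
    assert best_first_select(table, y) == \
        best_first_select(table.iloc[perm].reset_index(drop=True), y[perm])


def test_build_hybrid_combines_per_family_selections():
    rng = np.random.default_rng(21)
    n = 200
    y = rng.integers(0, 2, n)
    tables = {}
    planted_ids = []
    for fam in ("famA", "famB"):
        cid = f"{fam}:0"
        planted_ids.append(cid)
        flip = rng.random(n) < 0.05
        cols = {cid: np.where(flip, 1 - y, y).astype(np.uint8)}
        for k in range(1, 20):
            cols[f"{fam}:{k}"] = rng.integers(0, 2, n).astype(np.uint8)
        tables[fam] = pd.DataFrame(cols)
    spec = build_hybrid(tables, y)
    assert set(planted_ids) <= set(spec.selected)
    assert spec.built_from == ["famA", "famB"]
    combined = pd.concat(tables.values(), axis=1)
    projected = project(combined, spec)
    assert list(projected.columns) == spec.selected
    assert projected.shape[1] == len(spec)


def test_hybrid_spec_rejects_duplicates_and_roundtrips(tmp_path):
    with pytest.raises(ValueError):
        HybridSpec(selected=["a:0", "a:0"], built_from=["a"])
    spec = HybridSpec(selected=["a:0", "b:3"], built_from=["a", "b"],
                      selection_params={"max_stale": 5})
    path = tmp_path / "spec.json"
    spec.to_json(str(path))
    back = HybridSpec.from_json(str(path))
    assert back.selected == spec.selected
    assert back.content_hash == spec.content_hash
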