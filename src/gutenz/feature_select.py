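"""Hybrid-fingerprint construction by correlation-based feature selection.

Per fingerprint family, two stages run on the binary feature table:

1. *remove useless* — constant bits and bits whose majority value covers
   more than ``max_dominance`` of the rows carry (almost) no information
   and are dropped;
2. *CFS with best-first search* — a subset S of k bits is scored by the
   merit  k·r̄_cf / sqrt(k + k(k−1)·r̄_ff),  where r̄_cf is the mean
   symmetric uncertainty between member bits and the class label and r̄_ff
   the mean pairwise symmetric uncertainty among member bits; high merit
   means discriminative yet mutually non-redundant bits.  The search
   starts from the empty set, expands states by single-bit addition or
   removal in best-merit-first order, and stops after ``max_stale``
   consecutive expansions without improving the best merit found.

The per-family selections are concatenated, in family registration order,
into a :class:`HybridSpec` — an ordered list of ``family:bitindex``
column ids plus the parameters needed to reproduce it.
"""

from __future__ import annotations

import hashlib
import heapq
import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import fingerprints

logger = logging.getLogger(__name__)

DEFAULT_MAX_DOMINANCE = 0.99
DEFAULT_MAX_STALE = 5


@dataclass
class HybridSpec:
    """Ordered hybrid-fingerprint column ids plus reproduction metadata."""

    selected: list[str]
    built_from: list[str]
    selection_params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.selected) != len(set(self.selected)):
            raise ValueError("duplicate column ids in hybrid spec")

    def __len__(self) -> int:
        return len(self.selected)

    @property
    def content_hash(self) -> str:
        payload = json.dumps([self.selected, self.built_from,
                              self.selection_params], sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    def to_json(self, path: str) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump({"selected": self.selected, "built_from": self.built_from,
                       "selection_params": self.selection_params,
                       "provider_version": fingerprints.PROVIDER_VERSION},
                      fh, indent=1)

    @classmethod
    def from_json(cls, path: str) -> "HybridSpec":
        with open(path, encoding="utf-8") as fh:
            d = json.load(fh)
        return cls(selected=d["selected"], built_from=d["built_from"],
                   selection_params=d.get("selection_params", {}))


def project(table: pd.DataFrame, spec: HybridSpec) -> pd.DataFrame:
    """Restrict a feature table to exactly the hybrid's columns, in order."""
    missing = [c for c in spec.selected if c not in table.columns]
    if missing:
        raise KeyError(f"feature table lacks hybrid columns: {missing[:5]}...")
    return table.loc[:, spec.selected]


# --------------------------------------------------------------------------
# stage 1: remove useless bits
# --------------------------------------------------------------------------

def remove_useless(
    table: pd.DataFrame,
    class_labels=None,
    max_dominance: float = DEFAULT_MAX_DOMINANCE,
) -> list[str]:
    """Column ids surviving the constancy/dominance screen, original order."""
    if table.shape[1] == 0:
        raise ValueError("empty feature table")
    X = table.to_numpy()
    n = X.shape[0]
    ones = X.sum(axis=0)
    majority = np.maximum(ones, n - ones) / n
    keep = majority <= max_dominance  # strictly-greater dominance removes
    survivors = [c for c, k in zip(table.columns, keep) if k]
    if not survivors:
        raise ValueError(
            f"all {table.shape[1]} columns removed as uninformative "
            f"(max_dominance={max_dominance}, n={n})")
    return survivors


# --------------------------------------------------------------------------
# symmetric uncertainty and CFS merit
# --------------------------------------------------------------------------

def _entropy(counts: np.ndarray) -> float:
    p = counts[counts > 0] / counts.sum()
    return float(-(p * np.log2(p)).sum())


def symmetric_uncertainty(x: np.ndarray, y: np.ndarray) -> float:
    """2·MI(X;Y) / (H(X)+H(Y)) for discrete vectors; 0 when both constant."""
    x = np.asarray(x)
    y = np.asarray(y)
    _, xi = np.unique(x, return_inverse=True)
    _, yi = np.unique(y, return_inverse=True)
    nx, ny = xi.max() + 1, yi.max() + 1
    joint = np.bincount(xi * ny + yi, minlength=nx * ny).reshape(nx, ny).astype(float)
    hx = _entropy(joint.sum(axis=1))
    hy = _entropy(joint.sum(axis=0))
    hxy = _entropy(joint.ravel())
    if hx + hy == 0:
        return 0.0
    mi = hx + hy - hxy
    return max(0.0, 2.0 * mi / (hx + hy))


class _SUCache:
    """Lazy symmetric-uncertainty cache over a fixed table."""

    def __init__(self, table: pd.DataFrame, labels: np.ndarray):
        self.cols = list(table.columns)
        self.X = table.to_numpy()
        self.y = np.asarray(labels)
        self.idx = {c: i for i, c in enumerate(self.cols)}
        self._cf: dict[int, float] = {}
        self._ff: dict[tuple[int, int], float] = {}

    def cf(self, col: str) -> float:
        i = self.idx[col]
        if i not in self._cf:
            self._cf[i] = symmetric_uncertainty(self.X[:, i], self.y)
        return self._cf[i]

    def ff(self, a: str, b: str) -> float:
        i, j = sorted((self.idx[a], self.idx[b]))
        if (i, j) not in self._ff:
            self._ff[(i, j)] = symmetric_uncertainty(self.X[:, i], self.X[:, j])
        return self._ff[(i, j)]


def _merit(subset: tuple[str, ...], cache: _SUCache) -> float:
    k = len(subset)
    if k == 0:
        return 0.0
    r_cf = float(np.mean([cache.cf(c) for c in subset]))
    if k == 1:
        return r_cf
    pairs = [cache.ff(a, b) for idx, a in enumerate(subset) for b in subset[idx + 1:]]
    r_ff = float(np.mean(pairs))
    denom = np.sqrt(k + k * (k - 1) * r_ff)
    return k * r_cf / denom if denom > 0 else 0.0


def cfs_merit(subset: list[str], table: pd.DataFrame, class_labels) -> float:
    """CFS merit of a column subset (deterministic; empty subset invalid)."""
    if not subset:
        raise ValueError("subset must be non-empty")
    cache = _SUCache(table.loc[:, list(subset)], np.asarray(class_labels))
    return _merit(tuple(subset), cache)


# --------------------------------------------------------------------------
# stage 2: best-first subset search
# --------------------------------------------------------------------------

def best_first_select(
    table: pd.DataFrame,
    class_labels,
    max_stale: int = DEFAULT_MAX_STALE,
) -> list[str]:
    """Best-first CFS search; returns the best subset, in column order.

    States are column subsets; neighbours differ by one column added or
    removed.  A priority queue keyed by merit drives expansion; the search
    stops after ``max_stale`` consecutive expansions that fail to improve
    the best merit seen.  Fully deterministic: ties in the queue resolve
    by insertion order.
    """
    if table.shape[1] == 0:
        raise ValueError("no columns to select from")
    cache = _SUCache(table, np.asarray(class_labels))
    cols = list(table.columns)
    col_pos = {c: i for i, c in enumerate(cols)}

    def merit_from_sums(k: int, sum_cf: float, sum_ff: float) -> float:
        if k == 0:
            return 0.0
        r_cf = sum_cf / k
        if k == 1:
            return r_cf
        r_ff = sum_ff / (k * (k - 1) / 2)
        denom = np.sqrt(k + k * (k - 1) * r_ff)
        return k * r_cf / denom if denom > 0 else 0.0

    start: tuple[str, ...] = ()
    best_subset, best_merit = start, 0.0
    counter = 0
    # heap entries carry the subset plus its Σ su(col, class) and Σ pairwise
    # su so that a child's merit is an O(k) update, not an O(k²) recompute
    heap: list[tuple[float, int, tuple[str, ...], float, float]] = [(0.0, 0, start, 0.0, 0.0)]
    visited = {start}
    stale = 0
    while heap and stale < max_stale:
        _, _, state, sum_cf, sum_ff = heapq.heappop(heap)
        improved = False
        members = set(state)
        for col in cols:
            if col in members:
                child = tuple(c for c in state if c != col)
                c_cf = sum_cf - cache.cf(col)
                c_ff = sum_ff - sum(cache.ff(col, c) for c in state if c != col)
            else:
                child = tuple(sorted(state + (col,), key=col_pos.__getitem__))
                c_cf = sum_cf + cache.cf(col)
                c_ff = sum_ff + sum(cache.ff(col, c) for c in state)
            if child in visited or not child:
                continue
            visited.add(child)
            m = merit_from_sums(len(child), c_cf, c_ff)
            counter += 1
            heapq.heappush(heap, (-m, counter, child, c_cf, c_ff))
            if m > best_merit + 1e-12:
                best_merit, best_subset = m, child
                improved = True
        stale = 0 if improved else stale + 1
    return sorted(best_subset, key=col_pos.__getitem__)


# --------------------------------------------------------------------------
# hybrid assembly
# --------------------------------------------------------------------------

def _split_by_family(table: pd.DataFrame) -> dict[str, pd.DataFrame]:
    fams: dict[str, list[str]] = {}
    for c in table.columns:
        fams.setdefault(c.split(":", 1)[0], []).append(c)
    return {f: table.loc[:, cs] for f, cs in fams.items()}


def build_hybrid(
    tables: dict[str, pd.DataFrame] | pd.DataFrame,
    class_labels,
    max_dominance: float = DEFAULT_MAX_DOMINANCE,
    max_stale: int = DEFAULT_MAX_STALE,
) -> HybridSpec:
    """Per family: remove_useless then best_first_select; concatenate.

    ``tables`` is either a mapping family -> feature table or one combined
    table whose column ids are ``family:bitindex``.  Families contributing
    zero bits are allowed (logged).  Family order in the concatenation is
    fingerprint registration order.
    """
    if isinstance(tables, pd.DataFrame):
        tables = _split_by_family(tables)
    if not tables:
        raise ValueError("no fingerprint families supplied")
    reg_order = [f for f in fingerprints.REGISTRY if f in tables]
    reg_order += [f for f in tables if f not in reg_order]
    selected: list[str] = []
    for fam in reg_order:
        tab = tables[fam]
        try:
            survivors = remove_useless(tab, class_labels, max_dominance)
        except ValueError:
            logger.info("family %s: no bits survive the dominance screen", fam)
            continue
        chosen = best_first_select(tab.loc[:, survivors], class_labels, max_stale)
        if not chosen:
            logger.info("family %s contributes zero bits", fam)
        selected.extend(chosen)
    return HybridSpec(
        selected=selected,
        built_from=reg_order,
        selection_params={"max_dominance": max_dominance, "max_stale": max_stale},
    )
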