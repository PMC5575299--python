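"""Two-level random-forest cascade over the EC hierarchy.

One forest classifies a query molecule into an EC class (1–6); per class,
a second forest classifies into that class's subclasses.  Training data
are hybrid-fingerprint features of the curated substrate database.

Class imbalance is handled by optional upsampling: minority classes are
random-sampled with replacement up to the majority count, keeping every
original row.  Hyperparameters are tuned per model against the forest's
out-of-bag (OOB) error: mtry (features considered per split) by an
outward search from round(sqrt(p)) with a multiplicative step factor,
continuing in a direction only while the relative OOB improvement reaches
the ``improve`` fraction; ntree over the grid 100..500 (step 100) with
ties resolved toward the largest value, reading the OOB saturation.
"""

from __future__ import annotations

import json
import logging
import math
import os
import warnings
from dataclasses import dataclass, field

import joblib
import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier

from . import fingerprints
from .feature_select import HybridSpec, project
from .substrate_db import SubstrateDB, SubstrateRecord

logger = logging.getLogger(__name__)

UNCLASSIFIED = "unclassified"
WITH_UPSAMPLING = "with_upsampling"
WITHOUT_UPSAMPLING = "without_upsampling"
DEFAULT_NTREE_GRID = (100, 200, 300, 400, 500)
DEFAULT_NTREE = 500
MIN_SUBCLASS_N = 2


def round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def default_mtry(p: int) -> int:
    """Starting mtry: round-half-up of sqrt(number of features)."""
    return min(max(1, round_half_up(math.sqrt(p))), p)


# --------------------------------------------------------------------------
# upsampling
# --------------------------------------------------------------------------

def upsample(rows, labels, seed: int):
    """Balance classes by sampling with replacement up to the majority count.

    All original rows are retained; added rows are drawn (with
    replacement) from their own class.  Row containers can be a DataFrame
    or an ndarray; labels anything array-like.
    """
    y = np.asarray(labels)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("upsampling needs at least two classes")
    target = counts.max()
    rng = np.random.default_rng(seed)
    extra_idx: list[np.ndarray] = []
    for cls, cnt in zip(classes, counts):
        if cnt < target:
            members = np.flatnonzero(y == cls)
            extra_idx.append(rng.choice(members, size=target - cnt, replace=True))
    order = np.concatenate([np.arange(len(y))] + extra_idx) if extra_idx \
        else np.arange(len(y))
    if isinstance(rows, pd.DataFrame):
        return rows.iloc[order], y[order]
    return np.asarray(rows)[order], y[order]


# --------------------------------------------------------------------------
# forests and OOB error
# --------------------------------------------------------------------------

def fit_forest(X, y, mtry: int, ntree: int, seed: int,
               oob: bool = True) -> RandomForestClassifier:
    rf = RandomForestClassifier(
        n_estimators=ntree, max_features=min(int(mtry), X.shape[1]),
        oob_score=oob, bootstrap=True, random_state=int(seed) % (2**31), n_jobs=1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        rf.fit(np.asarray(X), np.asarray(y))
    return rf


def oob_error_percent(X, y, mtry: int, ntree: int, seed: int) -> float:
    """OOB misclassification rate, in percent, from out-of-bag votes.

    Rows that were in-bag for every tree (possible at small ntree) carry
    no OOB vote and are excluded from the rate.
    """
    rf = fit_forest(X, y, mtry, ntree, seed)
    votes = rf.oob_decision_function_
    voted = votes.sum(axis=1) > 0
    if not voted.any():
        raise ValueError("no out-of-bag votes; increase ntree")
    pred = rf.classes_[votes[voted].argmax(axis=1)]
    err = float(np.mean(pred != np.asarray(y)[voted]))
    return 100.0 * err


@dataclass
class TuningResult:
    mtry: int
    ntree: int
    oob_error_percent: float
    search_trace: list[tuple[int, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.search_trace:
            best = min(err for _, err in self.search_trace)
            if self.oob_error_percent > best + 1e-9:
                raise ValueError("chosen parameters do not attain the trace minimum")


def tune_mtry(table, labels, ntree_probe: int = 100, step_factor: float = 2,
              improve: float = 0.05, seed: int = 0) -> TuningResult:
    """Outward OOB search for mtry around round(sqrt(p)).

    Starting at round(sqrt(p)), candidate values move outward dividing or
    multiplying by ``step_factor``; a direction is pursued only while the
    relative OOB improvement over the previous probe in that direction is
    at least ``improve``.  Every probe lands in the search trace; the
    returned mtry minimises OOB error in the trace (ties to the smaller
    value probed first).
    """
    X = np.asarray(table)
    p = X.shape[1]
    if p == 0:
        raise ValueError("feature table has no columns")
    start = default_mtry(p)
    probed: dict[int, float] = {}

    def probe(m: int) -> float:
        if m not in probed:
            probed[m] = oob_error_percent(X, labels, m, ntree_probe, seed)
        return probed[m]

    trace: list[tuple[int, float]] = [(start, probe(start))]
    for direction in (-1, +1):
        prev_m, prev_err = start, trace[0][1]
        while True:
            m_new = round_half_up(prev_m / step_factor) if direction < 0 \
                else round_half_up(prev_m * step_factor)
            m_new = min(max(1, m_new), p)
            if m_new == prev_m or m_new in probed:
                break
            err = probe(m_new)
            trace.append((m_new, err))
            rel = (prev_err - err) / prev_err if prev_err > 0 else 0.0
            if rel < improve:
                break
            prev_m, prev_err = m_new, err
    best_mtry, best_err = min(trace, key=lambda t: (t[1], t[0]))
    return TuningResult(mtry=best_mtry, ntree=ntree_probe,
                        oob_error_percent=best_err, search_trace=trace)


def select_ntree(table, labels, mtry: int, grid=DEFAULT_NTREE_GRID,
                 seed: int = 0) -> int:
    """Grid value with the lowest OOB error; ties go to the largest ntree
    (reading OOB saturation)."""
    grid = list(grid)
    if not grid:
        raise ValueError("empty ntree grid")
    best_nt, best_err = None, None
    for nt in grid:
        err = oob_error_percent(np.asarray(table), labels, mtry, nt, seed)
        if best_err is None or err < best_err - 1e-12 or \
                (abs(err - best_err) <= 1e-12 and nt > best_nt):
            best_nt, best_err = nt, err
    return best_nt


# --------------------------------------------------------------------------
# the cascade
# --------------------------------------------------------------------------

def record_class_label(rec: SubstrateRecord) -> int:
    return rec.class_digit


def record_subclass_label(rec: SubstrateRecord) -> int:
    # a curated record can carry several same-class tags; the smallest
    # subclass digit is the deterministic training label
    return min(rec.subclass_digits)


def features_for_records(records: list[SubstrateRecord],
                         spec: HybridSpec) -> pd.DataFrame:
    families = sorted({c.split(":", 1)[0] for c in spec.selected},
                      key=list(fingerprints.REGISTRY).index)
    table, failures = fingerprints.fingerprint_matrix(
        [r.molecule for r in records], families)
    if failures:
        raise ValueError(f"fingerprint failures on training molecules: {failures}")
    return project(table, spec)


@dataclass
class CascadeModel:
    class_model: RandomForestClassifier
    subclass_models: dict[int, RandomForestClassifier]
    hybrid_spec: HybridSpec
    sampling: str
    tuning: dict[str, TuningResult]
    seed: int
    training_counts: dict[str, dict] = field(default_factory=dict)

    # -- prediction --------------------------------------------------------
    def _predict(self, rf: RandomForestClassifier, fp_row: np.ndarray,
                 threshold: float):
        fp_row = np.asarray(fp_row, dtype=float).reshape(1, -1)
        if fp_row.shape[1] != rf.n_features_in_:
            raise ValueError(
                f"feature dimension {fp_row.shape[1]} != model's {rf.n_features_in_}")
        probs = rf.predict_proba(fp_row)[0]
        prob_map = {int(c): float(p) for c, p in zip(rf.classes_, probs)}
        best = int(rf.classes_[int(np.argmax(probs))])
        if probs.max() < threshold:
            return UNCLASSIFIED, prob_map
        return best, prob_map

    def predict_class(self, fp_row, threshold: float = 0.0):
        """EC class digit (or 'unclassified') plus the probability map."""
        return self._predict(self.class_model, fp_row, threshold)

    def predict_subclass(self, class_digit: int, fp_row, threshold: float = 0.0):
        """EC subclass within ``class_digit``; 'no-subclass-model' when the
        class had too few records to train one."""
        rf = self.subclass_models.get(class_digit)
        if rf is None:
            return "no-subclass-model", {}
        return self._predict(rf, fp_row, threshold)

    # -- serialization -----------------------------------------------------
    def save(self, directory: str) -> None:
        os.makedirs(directory, exist_ok=True)
        joblib.dump(self.class_model, os.path.join(directory, "class_model.joblib"))
        for c, rf in self.subclass_models.items():
            joblib.dump(rf, os.path.join(directory, f"subclass_model_{c}.joblib"))
        self.hybrid_spec.to_json(os.path.join(directory, "hybrid_spec.json"))
        manifest = {
            "hybrid_hash": self.hybrid_spec.content_hash,
            "sampling": self.sampling,
            "seed": self.seed,
            "training_counts": self.training_counts,
            "tuning": {name: {"mtry": t.mtry, "ntree": t.ntree,
                              "oob_error_percent": t.oob_error_percent,
                              "search_trace": t.search_trace}
                       for name, t in self.tuning.items()},
            "subclass_models": sorted(self.subclass_models),
        }
        with open(os.path.join(directory, "manifest.json"), "w", encoding="utf-8") as fh:
            json.dump(manifest, fh, indent=1)

    @classmethod
    def load(cls, directory: str) -> "CascadeModel":
        with open(os.path.join(directory, "manifest.json"), encoding="utf-8") as fh:
            manifest = json.load(fh)
        spec = HybridSpec.from_json(os.path.join(directory, "hybrid_spec.json"))
        if spec.content_hash != manifest["hybrid_hash"]:
            raise ValueError("hybrid spec hash mismatch; model bundle corrupt")
        class_model = joblib.load(os.path.join(directory, "class_model.joblib"))
        sub = {c: joblib.load(os.path.join(directory, f"subclass_model_{c}.joblib"))
               for c in manifest["subclass_models"]}
        tuning = {name: TuningResult(d["mtry"], d["ntree"], d["oob_error_percent"],
                                     [tuple(t) for t in d["search_trace"]])
                  for name, d in manifest["tuning"].items()}
        return cls(class_model=class_model, subclass_models=sub, hybrid_spec=spec,
                   sampling=manifest["sampling"], tuning=tuning,
                   seed=manifest["seed"],
                   training_counts=manifest.get("training_counts", {}))


def _train_one(X: pd.DataFrame, y: np.ndarray, sampling: str, seed: int,
               tune: bool, ntree_probe: int, ntree_grid) -> tuple[RandomForestClassifier, TuningResult]:
    if sampling == WITH_UPSAMPLING and len(np.unique(y)) > 1:
        X, y = upsample(X, y, seed)
    if tune:
        tr = tune_mtry(X, y, ntree_probe=ntree_probe, seed=seed)
        ntree = select_ntree(X, y, tr.mtry, grid=ntree_grid, seed=seed)
        mtry = tr.mtry
        trace = tr.search_trace
    else:
        mtry, ntree, trace = default_mtry(X.shape[1]), DEFAULT_NTREE, []
    rf = fit_forest(X, y, mtry, ntree, seed)
    oob = oob_error_percent(X, y, mtry, ntree, seed)
    result = TuningResult(mtry=mtry, ntree=ntree, oob_error_percent=oob,
                          search_trace=trace + [(mtry, oob)])
    return rf, result


def train_cascade(db: SubstrateDB, hybrid_spec: HybridSpec,
                  sampling: str = WITH_UPSAMPLING, seed: int = 0,
                  tune: bool = False, ntree_probe: int = 100,
                  ntree_grid=DEFAULT_NTREE_GRID,
                  min_subclass_n: int = MIN_SUBCLASS_N,
                  features: pd.DataFrame | None = None) -> CascadeModel:
    """Train the EC-class forest plus one subclass forest per EC class.

    The class model trains on all curated records labelled by class
    digit; subclass model k trains only on class-k records, excluding
    subclasses with fewer than ``min_subclass_n`` records (a one-record
    subclass cannot be validated; its records remain available to the
    similarity stage).  Upsampling, when requested, applies per model.
    With ``tune`` the mtry/ntree search runs per model; otherwise
    round(sqrt(p)) and ntree=500 are used directly.
    """
    if sampling not in (WITH_UPSAMPLING, WITHOUT_UPSAMPLING):
        raise ValueError(f"unknown sampling mode {sampling!r}")
    X = features_for_records(db.records, hybrid_spec) if features is None \
        else project(features, hybrid_spec)
    y_class = np.array([record_class_label(r) for r in db.records])
    if len(np.unique(y_class)) < 2:
        raise ValueError("cascade needs records from at least two EC classes")

    tuning: dict[str, TuningResult] = {}
    counts: dict[str, dict] = {"class": {int(c): int(n) for c, n in
                                         zip(*np.unique(y_class, return_counts=True))}}
    class_rf, tuning["class"] = _train_one(X, y_class, sampling, seed, tune,
                                           ntree_probe, ntree_grid)

    subclass_models: dict[int, RandomForestClassifier] = {}
    for c in sorted(set(y_class.tolist())):
        recs = [r for r in db.records if record_class_label(r) == c]
        y_sub = np.array([record_subclass_label(r) for r in recs])
        labels, n_per = np.unique(y_sub, return_counts=True)
        keep_labels = set(labels[n_per >= min_subclass_n].tolist())
        mask = np.array([lab in keep_labels for lab in y_sub])
        dropped = int((~mask).sum())
        if dropped:
            logger.warning("class %d: %d record(s) in singleton subclasses "
                           "excluded from subclass training", c, dropped)
        if len(keep_labels) < 2 or mask.sum() < 2:
            logger.warning("class %d: not enough subclass diversity; "
                           "no subclass model (falls back to class output)", c)
            continue
        Xc = X.loc[[r.id for r, m in zip(recs, mask) if m]]
        rf, tr = _train_one(Xc, y_sub[mask], sampling, seed + c, tune,
                            ntree_probe, ntree_grid)
        subclass_models[c] = rf
        tuning[f"subclass_{c}"] = tr
        counts[f"subclass_{c}"] = {int(l): int(n) for l, n in
                                   zip(*np.unique(y_sub[mask], return_counts=True))}

    return CascadeModel(class_model=class_rf, subclass_models=subclass_models,
                        hybrid_spec=hybrid_spec, sampling=sampling,
                        tuning=tuning, seed=seed, training_counts=counts)
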