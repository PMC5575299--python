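"""Performance metrics and validation protocols for the EC cascade.

Metrics are the classical confusion-matrix quantities — sensitivity
(TPR), specificity (TNR), precision (PPV) and accuracy, reported in
percent, plus the Matthews correlation coefficient:

    TPR = TP/(TP+FN)        TNR = TN/(TN+FP)       PPV = TP/(TP+FP)
    ACC = (TP+TN)/(TP+FP+FN+TN)
    MCC = (TP·TN − FP·FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN))

Multi-class results are scored one-vs-rest per class and macro-averaged.
Three protocols are provided: stratified 10-fold cross-validation, a
stratified 75/25 split, and a blind protocol that withdraws 10% of each
class before any training, scores once on the withheld set, and then
retrains the production model on the full data.  Upsampling, when
requested, is applied inside each training partition only, so duplicated
rows can never leak into a paired evaluation partition.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.model_selection import StratifiedKFold, train_test_split

from . import models as _models
from .feature_select import HybridSpec
from .models import (WITH_UPSAMPLING, default_mtry, fit_forest,
                     record_class_label, record_subclass_label, upsample)
from .substrate_db import SubstrateDB

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(self.tp + other.tp, self.fp + other.fp,
                               self.fn + other.fn, self.tn + other.tn)


@dataclass(frozen=True)
class MetricSet:
    tpr: float  # percent
    tnr: float  # percent
    ppv: float  # percent
    acc: float  # percent
    mcc: float  # [-1, 1]


def _ratio(num: int, den: int) -> float:
    return num / den if den else 0.0


def metrics(counts: ConfusionCounts) -> MetricSet:
    """Exact confusion-matrix metrics; 0/0 rates and MCC default to 0."""
    if counts.total == 0:
        raise ValueError("no evaluated instances")
    tp, fp, fn, tn = counts.tp, counts.fp, counts.fn, counts.tn
    denom = math.sqrt((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    mcc = (tp * tn - fp * fn) / denom if denom else 0.0
    return MetricSet(
        tpr=100.0 * _ratio(tp, tp + fn),
        tnr=100.0 * _ratio(tn, tn + fp),
        ppv=100.0 * _ratio(tp, tp + fp),
        acc=100.0 * _ratio(tp + tn, counts.total),
        mcc=mcc,
    )


def one_vs_rest_counts(y_true, y_pred, positive) -> ConfusionCounts:
    yt = np.asarray(y_true) == positive
    yp = np.asarray(y_pred) == positive
    return ConfusionCounts(tp=int((yt & yp).sum()), fp=int((~yt & yp).sum()),
                           fn=int((yt & ~yp).sum()), tn=int((~yt & ~yp).sum()))


def summarize(per_class_counts: dict[int, ConfusionCounts]) -> dict:
    """Per-class MetricSets plus a macro average over classes."""
    per_class = {c: metrics(cnt) for c, cnt in sorted(per_class_counts.items())}
    macro = MetricSet(*(float(np.mean([getattr(m, f) for m in per_class.values()]))
                        for f in ("tpr", "tnr", "ppv", "acc", "mcc")))
    return {"per_class": per_class, "macro": macro}


# --------------------------------------------------------------------------
# shared plumbing for the protocols
# --------------------------------------------------------------------------

def _labelled_features(db: SubstrateDB, spec: HybridSpec, level,
                       features: pd.DataFrame | None):
    """(X, y, ids) for class-level or (subclass, c)-level evaluation."""
    if level == "class":
        recs = db.records
        y = np.array([record_class_label(r) for r in recs])
    else:
        _, c = level
        recs = db.class_records(c)
        y = np.array([record_subclass_label(r) for r in recs])
    ids = [r.id for r in recs]
    if features is None:
        X = _models.features_for_records(recs, spec)
    else:
        X = features.loc[ids, spec.selected]
    return X, y, ids


def _fit_and_score(X_tr, y_tr, X_te, y_te, sampling, seed, mtry, ntree):
    if sampling == WITH_UPSAMPLING and len(np.unique(y_tr)) > 1:
        X_tr, y_tr = upsample(X_tr, y_tr, seed)
    rf = fit_forest(X_tr, y_tr, mtry or default_mtry(X_tr.shape[1]), ntree,
                    seed, oob=False)
    return rf.predict(np.asarray(X_te))


def cross_validate(db: SubstrateDB, spec: HybridSpec,
                   sampling: str = WITH_UPSAMPLING, folds: int = 10,
                   seed: int = 0, level="class", mtry: int | None = None,
                   ntree: int = _models.DEFAULT_NTREE,
                   features: pd.DataFrame | None = None) -> dict:
    """Stratified k-fold cross-validation; counts pooled over folds."""
    if folds < 2:
        raise ValueError("cross-validation needs at least 2 folds")
    X, y, _ = _labelled_features(db, spec, level, features)
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    pooled: dict[int, ConfusionCounts] = {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        for k, (tr, te) in enumerate(skf.split(np.asarray(X), y)):
            pred = _fit_and_score(X.iloc[tr], y[tr], X.iloc[te], y[te],
                                  sampling, seed + k, mtry, ntree)
            for c in np.unique(y):
                cnt = one_vs_rest_counts(y[te], pred, c)
                pooled[int(c)] = pooled.get(int(c), ConfusionCounts(0, 0, 0, 0)) + cnt
    return summarize(pooled)


def split_and_test(db: SubstrateDB, spec: HybridSpec,
                   sampling: str = WITH_UPSAMPLING, train_frac: float = 0.75,
                   seed: int = 0, level="class", mtry: int | None = None,
                   ntree: int = _models.DEFAULT_NTREE,
                   features: pd.DataFrame | None = None) -> dict:
    """Stratified train/test split (default 75/25); metrics on the held-out part."""
    X, y, _ = _labelled_features(db, spec, level, features)
    idx = np.arange(len(y))
    tr, te = train_test_split(idx, train_size=train_frac, stratify=y,
                              random_state=seed)
    pred = _fit_and_score(X.iloc[tr], y[tr], X.iloc[te], y[te],
                          sampling, seed, mtry, ntree)
    counts = {}
    for c in np.unique(y):
        if (y[te] == c).sum() == 0:
            logger.warning("class %s has no test members; excluded from report", c)
            continue
        counts[int(c)] = one_vs_rest_counts(y[te], pred, c)
    return summarize(counts)


def blind_allocation(y: np.ndarray, frac: float, seed: int) -> np.ndarray:
    """Per-class blind indices: round-half-up of frac·n, at least one when
    the class has ≥2 members, none from singleton classes."""
    if not 0 < frac < 1:
        raise ValueError("frac must be in (0, 1)")
    rng = np.random.default_rng(seed)
    chosen: list[np.ndarray] = []
    for c in np.unique(y):
        members = np.flatnonzero(y == c)
        n = len(members)
        if n < 2:
            logger.info("class %s has a single record; no blind member", c)
            continue
        k = max(1, _models.round_half_up(frac * n))
        chosen.append(rng.choice(members, size=min(k, n - 1), replace=False))
    return np.sort(np.concatenate(chosen)) if chosen else np.array([], dtype=int)


def blind_protocol(db: SubstrateDB, spec: HybridSpec,
                   sampling: str = WITH_UPSAMPLING, frac: float = 0.10,
                   seed: int = 0, level="class", mtry: int | None = None,
                   ntree: int = _models.DEFAULT_NTREE,
                   features: pd.DataFrame | None = None) -> tuple[dict, list[str]]:
    """Withdraw frac of each class before training; score once; the caller
    then retrains the production model on the full data.

    Returns (report, blind record ids).
    """
    X, y, ids = _labelled_features(db, spec, level, features)
    blind_idx = blind_allocation(y, frac, seed)
    blind_ids = [ids[i] for i in blind_idx]
    mask = np.ones(len(y), dtype=bool)
    mask[blind_idx] = False
    pred = _fit_and_score(X.iloc[mask], y[mask], X.iloc[blind_idx], y[blind_idx],
                          sampling, seed, mtry, ntree)
    counts = {}
    for c in np.unique(y):
        if (y[blind_idx] == c).sum() == 0:
            continue
        counts[int(c)] = one_vs_rest_counts(y[blind_idx], pred, c)
    return summarize(counts), blind_ids


# --------------------------------------------------------------------------
# PCA diversity diagnostic
# --------------------------------------------------------------------------

def pca_diagnostic(table: pd.DataFrame, n_components: int = 2):
    """Variance fractions and 2-D coordinates of the (centered) feature table.

    Used to gauge how diverse/spread the substrate set is across EC
    classes: slowly decaying variance fractions mean no small subspace
    captures the data, i.e. a genuinely heterogeneous training set.
    """
    X = np.asarray(table, dtype=float)
    if X.shape[0] < 2:
        raise ValueError("PCA needs at least two rows")
    if np.allclose(X.var(axis=0), 0):
        raise ValueError("constant feature matrix; PCA undefined")
    n_components = min(n_components, X.shape[0] - 1, X.shape[1])
    pca = PCA(n_components=n_components, svd_solver="full")
    coords = pca.fit_transform(X)
    return pca.explained_variance_ratio_, coords[:, :2]
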