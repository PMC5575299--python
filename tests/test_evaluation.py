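"""Confusion-matrix metrics, validation protocols, PCA diagnostic."""

import numpy as np
import pandas as pd
import pytest

from gutenz.evaluation import (ConfusionCounts, blind_allocation, blind_protocol,
                               cross_validate, metrics, one_vs_rest_counts,
                               pca_diagnostic, split_and_test)


def _instance_oracle(counts):
    """Brute-force metrics from enumerated instance labels."""
    y_true = [1] * counts.tp + [0] * counts.fp + [1] * counts.fn + [0] * counts.tn
    y_pred = [1] * counts.tp + [1] * counts.fp + [0] * counts.fn + [0] * counts.tn
    yt, yp = np.array(y_true), np.array(y_pred)
    tp = int(((yt == 1) & (yp == 1)).sum())
    fp = int(((yt == 0) & (yp == 1)).sum())
    fn = int(((yt == 1) & (yp == 0)).sum())
    tn = int(((yt == 0) & (yp == 0)).sum())
    tpr = 100 * tp / (tp + fn) if tp + fn else 0.0
    tnr = 100 * tn / (tn + fp) if tn + fp else 0.0
    ppv = 100 * tp / (tp + fp) if tp + fp else 0.0
    acc = 100 * (tp + tn) / len(yt)
    den = np.sqrt(float((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)))
    mcc = (tp * tn - fp * fn) / den if den else 0.0
    return tpr, tnr, ppv, acc, mcc


def test_perfect_and_antiperfect_classifiers():
    perfect = metrics(ConfusionCounts(10, 0, 0, 10))
    assert perfect.acc == 100.0 and perfect.mcc == pytest.approx(1.0)
    anti = metrics(ConfusionCounts(0, 10, 10, 0))
    assert anti.acc == 0.0 and anti.mcc == pytest.approx(-1.0)


def test_metrics_match_instance_level_oracle():
    cases = [ConfusionCounts(52, 9, 11, 128)]
    rng = np.random.default_rng(0)
    cases += [ConfusionCounts(*rng.integers(0, 60, 4)) for _ in range(50)]
    for c in cases:
        if c.total == 0:
            continue
        m = metrics(c)
        tpr, tnr, ppv, acc, mcc = _instance_oracle(c)
        assert m.tpr == pytest.approx(tpr, abs=1e-12)
        assert m.tnr == pytest.approx(tnr, abs=1e-12)
        assert m.ppv == pytest.approx(ppv, abs=1e-12)
        assert m.acc == pytest.approx(acc, abs=1e-12)
        assert m.mcc == pytest.approx(mcc, abs=1e-12)


def test_acc_is_prevalence_weighted_mix_of_tpr_tnr():
    rng = np.random.default_rng(1)
    for _ in range(20):
        c = ConfusionCounts(*(int(x) for x in rng.integers(1, 80, 4)))
        m = metrics(c)
        prev = (c.tp + c.fn) / c.total
        assert m.acc == pytest.approx(prev * m.tpr + (1 - prev) * m.tnr)


def test_zero_total_fatal_and_mcc_zero_convention():
    with pytest.raises(ValueError):
        metrics(ConfusionCounts(0, 0, 0, 0))
    assert metrics(ConfusionCounts(0, 0, 5, 5)).mcc == 0.0


def test_one_vs_rest_counts_total_invariant():
    y_true = np.array([1, 1, 2, 3, 2, 1])
    y_pred = np.array([1, 2, 2, 3, 1, 1])
    for c in (1, 2, 3):
        assert one_vs_rest_counts(y_true, y_pred, c).total == 6


def test_cross_validation_on_separable_fixture(sep_db, sep_hybrid, sep_features):
    report = cross_validate(sep_db, sep_hybrid, folds=10, seed=1,
                            features=sep_features, ntree=300)
    assert report["macro"].acc >= 95.0
    assert set(report["per_class"]) == {1, 2, 3, 4, 5, 6}
    # pooled counts cover every record exactly once per one-vs-rest view
    rerun = cross_validate(sep_db, sep_hybrid, folds=10, seed=1,
                           features=sep_features, ntree=300)
    assert rerun["macro"] == report["macro"]  # seeded determinism


def test_split_protocol_stratified_and_seeded(sep_db, sep_hybrid, sep_features):
    r1 = split_and_test(sep_db, sep_hybrid, seed=2, features=sep_features,
                        ntree=300)
    r2 = split_and_test(sep_db, sep_hybrid, seed=2, features=sep_features,
                        ntree=300)
    assert r1["macro"] == r2["macro"]
    assert r1["macro"].acc >= 95.0


def test_blind_allocation_round_half_up_and_papers_total():
    # a 1,609-record class composition consistent with the documented skew
    sizes = {1: 529, 2: 529, 3: 271, 4: 170, 5: 55, 6: 55}
    y = np.concatenate([[c] * n for c, n in sizes.items()])
    idx = blind_allocation(y, frac=0.10, seed=0)
    assert len(idx) == 162
    per_class = {c: int((y[idx] == c).sum()) for c in sizes}
    assert per_class == {1: 53, 2: 53, 3: 27, 4: 17, 5: 6, 6: 6}
    # singleton classes contribute nothing; tiny classes still give one
    y2 = np.array([1] * 9 + [2])
    idx2 = blind_allocation(y2, 0.10, seed=0)
    assert set(y2[idx2]) == {1} and len(idx2) == 1


def test_blind_protocol_no_leak_and_close_to_cv(sep_db, sep_hybrid, sep_features):
    report, blind_ids = blind_protocol(sep_db, sep_hybrid, seed=3,
                                       features=sep_features, ntree=300)
    all_ids = [r.id for r in sep_db.records]
    assert set(blind_ids) <= set(all_ids)
    assert len(blind_ids) == 36  # 10% of 60 per class, 6 classes
    assert report["macro"].acc >= 90.0


def test_pca_ordering_sum_and_eigen_oracle():
    rng = np.random.default_rng(7)
    clusterA = rng.normal(0, 0.1, (20, 4)) + [5, 0, 0, 0]
    clusterB = rng.normal(0, 0.1, (20, 4)) - [5, 0, 0, 0]
    frac, coords = pca_diagnostic(pd.DataFrame(np.vstack([clusterA, clusterB])), 4)
    assert frac[0] > frac[1]
    assert np.all(np.diff(frac) <= 1e-12)
    assert np.sum(frac) == pytest.approx(1.0)
    assert coords.shape == (40, 2)
    # 6x8 toy matrix vs direct eigendecomposition of the covariance
    X = rng.normal(size=(6, 8))
    frac2, _ = pca_diagnostic(pd.DataFrame(X), 5)
    cov = np.cov(X - X.mean(axis=0), rowvar=False)
    eig = np.sort(np.linalg.eigvalsh(cov))[::-1]
    expected = eig[:5] / eig[eig > 1e-12].sum()
    assert np.allclose(frac2, expected[: len(frac2)], atol=1e-9)
    with pytest.raises(ValueError):
        pca_diagnostic(pd.DataFrame(np.ones((5, 3))))
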