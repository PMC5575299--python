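"""Curation filters and substrate-database construction."""

import numpy as np
import pytest

from gutenz import fingerprints, substrate_db
from gutenz.chem_io import from_smiles
from gutenz.ec import ECLabel
from gutenz.substrate_db import (SubstrateRecord, build_substrate_db,
                                 filter_cofactors, filter_multiclass,
                                 remove_redundancy)


def rec(smiles, rid, *ecs):
    return SubstrateRecord(from_smiles(smiles, rid),
                           frozenset(ECLabel.parse(e) for e in ecs))


def test_cofactor_filter_removes_water_and_atp_by_default():
    records = [rec("O", "water", "1.1.1.1"),
               rec("Nc1ncnc2c1ncn2C1OC(COP(=O)(O)OP(=O)(O)OP(=O)(O)O)C(O)C1O",
                   "atp", "2.7.1.1"),
               rec("CC(=O)Oc1ccccc1C(=O)O", "aspirin", "3.1.1.1")]
    kept, removed = filter_cofactors(records)
    assert [r.id for r in kept] == ["aspirin"]
    assert {r.id for r in removed} == {"water", "atp"}


def test_cofactor_filter_empty_list_is_noop_and_all_cofactors_warns():
    records = [rec("O", "water", "1.1.1.1")]
    kept, removed = filter_cofactors(records, cofactor_keys=set())
    assert kept == records and removed == []
    with pytest.warns(UserWarning, match="every record"):
        kept, _ = filter_cofactors([rec("O", "w", "1.1.1.1")])
    assert kept == []


def test_multiclass_filter_rules():
    cross = rec("CCO", "cross", "1.1.1.1", "2.4.1.17")
    same = rec("CCN", "same", "1.1.1.1", "1.14.13.2")
    kept, removed = filter_multiclass([cross, same])
    assert [r.id for r in kept] == ["same"]
    assert removed[0].id == "cross"


def test_multiclass_filter_matches_bruteforce_on_mixed_set():
    rng = np.random.default_rng(3)
    smiles = ["C" * (i + 1) + "O" for i in range(10)]
    records = []
    for i, s in enumerate(smiles):
        if i < 3:  # planted multi-class rows
            tags = (f"{1 + i}.1.1.1", f"{4 + i}.1.1.1")
        else:
            c = int(rng.integers(1, 7))
            tags = (f"{c}.1.1.1", f"{c}.{int(rng.integers(1, 5))}.1.2")
        records.append(rec(s, f"r{i}", *tags))
    kept, removed = filter_multiclass(records)
    expected = [r.id for r in records if len({e.class_digit for e in r.ec_tags}) == 1]
    assert [r.id for r in kept] == expected
    assert len(kept) == 7 and len(removed) == 3


def _greedy_leader_oracle(ids, tc_matrix, threshold):
    """Independent all-pairs oracle for leader clustering in input order."""
    reps, clusters = [], {}
    for i, rid in enumerate(ids):
        for leader in reps:
            if tc_matrix[ids.index(leader), i] > threshold:
                clusters[leader].append(rid)
                break
        else:
            reps.append(rid)
            clusters[rid] = [rid]
    return reps, clusters


def test_redundancy_identical_pair_and_below_threshold_pass():
    a, b = rec("CCO", "a", "1.1.1.1"), rec("CCO", "b", "1.1.1.1")
    far = rec("c1ccc2ccccc2c1", "far", "1.1.1.1")
    reps, cmap = remove_redundancy([a, b, far])
    assert [r.id for r in reps] == ["a", "far"]
    assert cmap["a"] == ["a", "b"]
    reps2, _ = remove_redundancy([a, far])
    assert [r.id for r in reps2] == ["a", "far"]  # TC <= 0.95: untouched


def test_redundancy_matches_allpairs_oracle_on_duplicate_groups():
    # 4 groups x 3 identical members interleaved
    bases = ["CC(=O)Oc1ccccc1C(=O)O", "OCC1OC(O)C(O)C(O)C1O",
             "NC(=O)c1ccc[nH]1", "Cc1ccncc1"]
    records = [rec(bases[g], f"g{g}_{k}", "1.1.1.1")
               for k in range(3) for g in range(4)]
    ids = [r.id for r in records]
    bits = [fingerprints.compute_fingerprint(r.molecule, "path1024").bits
            for r in records]
    n = len(records)
    tc = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            inter = int(np.bitwise_and(bits[i], bits[j]).sum())
            tc[i, j] = inter / (bits[i].sum() + bits[j].sum() - inter)
    exp_reps, exp_clusters = _greedy_leader_oracle(ids, tc, 0.95)
    reps, cmap = remove_redundancy(records)
    assert [r.id for r in reps] == exp_reps
    assert cmap == exp_clusters
    assert len(reps) == 4
    # all-pairs audit on the survivors
    rep_idx = [ids.index(r.id) for r in reps]
    for ii, i in enumerate(rep_idx):
        for j in rep_idx[ii + 1:]:
            assert tc[i, j] <= 0.95


def test_build_pipeline_recovers_fixture_ground_truth(sep_world, sep_db):
    _, truth = sep_world
    assert sorted(r.id for r in sep_db.records) == sorted(truth.survivor_ids)
    sc = sep_db.stage_counts
    assert sc["raw"] - sc["after_cofactor_filter"] == len(truth.cofactor_ids)
    assert sc["after_cofactor_filter"] - sc["after_multiclass_filter"] == \
        len(truth.multiclass_ids)
    assert sc["after_multiclass_filter"] - sc["after_redundancy_removal"] == \
        len(truth.duplicate_map)


def test_class_partition_and_subclass_cover(sep_db):
    assert sum(len(v) for v in sep_db.class_index.values()) == len(sep_db.records)
    covered = {i for ids in sep_db.subclass_index.values() for i in ids}
    assert covered == {r.id for r in sep_db.records}


def test_curation_idempotent_on_curated_db(sep_db):
    again = build_substrate_db(list(sep_db.records))
    assert [r.id for r in again.records] == [r.id for r in sep_db.records]


def test_save_load_roundtrip(tmp_path, sep_db):
    sep_db.save(str(tmp_path / "db"))
    back = substrate_db.SubstrateDB.load(str(tmp_path / "db"))
    assert [r.id for r in back.records] == [r.id for r in sep_db.records]
    assert [r.molecule.canonical_key for r in back.records] == \
        [r.molecule.canonical_key for r in sep_db.records]
    assert {r.id: sorted(map(str, r.ec_tags)) for r in back.records} == \
        {r.id: sorted(map(str, r.ec_tags)) for r in sep_db.records}


def test_empty_result_is_fatal():
    with pytest.raises(ValueError, match="no records"):
        build_substrate_db([rec("O", "w", "1.1.1.1")])
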