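"""Shared fixtures: one separable synthetic world, built once per session."""

import numpy as np
import pytest

from gutenz import enzyme_db, feature_select, fingerprints, fixtures, models, substrate_db

FIXTURE_SEED = 7
HYBRID_FAMILIES = ["maccs166", "pattern1024"]


@pytest.fixture(scope="session")
def sep_spec():
    return fixtures.preset("separable6", seed=FIXTURE_SEED)


@pytest.fixture(scope="session")
def sep_world(sep_spec):
    table, truth = fixtures.generate_substrates(sep_spec)
    return table, truth


@pytest.fixture(scope="session")
def sep_db(sep_world):
    table, _ = sep_world
    return substrate_db.build_substrate_db(table)


@pytest.fixture(scope="session")
def sep_features(sep_db):
    X, failures = fingerprints.fingerprint_matrix(
        [r.molecule for r in sep_db.records], HYBRID_FAMILIES)
    assert not failures
    return X


@pytest.fixture(scope="session")
def sep_hybrid(sep_db, sep_features):
    y = np.array([10 * r.class_digit + min(r.subclass_digits)
                  for r in sep_db.records])
    return feature_select.build_hybrid(sep_features, y)


@pytest.fixture(scope="session")
def sep_cascade(sep_db, sep_hybrid, sep_features):
    return models.train_cascade(sep_db, sep_hybrid, seed=1,
                                features=sep_features, tune=False)


@pytest.fixture(scope="session")
def enzyme_world(sep_spec, tmp_path_factory):
    world = fixtures.generate_enzyme_world(sep_spec)
    path = tmp_path_factory.mktemp("enz") / "hits.tsv"
    world.hits.to_csv(path, sep="\t", index=False, header=False)
    hits = enzyme_db.read_hits(str(path), world.query_lengths)
    return world, hits


@pytest.fixture(scope="session")
def sep_enzyme_db(enzyme_world):
    world, hits = enzyme_world
    best = enzyme_db.filter_best_hits(hits)
    db, errors = enzyme_db.build_enzyme_db(best, world.protein_to_genome,
                                           world.genome_taxonomy)
    assert not errors
    return db
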