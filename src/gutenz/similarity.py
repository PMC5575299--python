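"""Tanimoto similarity search with a three-fingerprint consensus rule.

After the cascade has placed a query in an EC subclass, the most similar
curated substrate of that subclass is found by Tanimoto search under
three fingerprint families (path-based, substructure-pattern and MACCS
keys).  The consensus rule: if at least two families agree on the top
candidate, that candidate wins — even when the dissenting family assigns
a higher coefficient elsewhere; a three-way split resolves to the
candidate with the globally highest coefficient.  The winning substrate's
EC tags within the predicted subclass are the assigned EC numbers (a
substrate of several same-subclass enzymes yields all of them).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import fingerprints
from .chem_io import Molecule
from .ec import ECLabel
from .fingerprints import SIMILARITY_FAMILIES, BitFingerprint
from .substrate_db import SubstrateDB

NO_CONFIDENT_EC = "no-confident-EC"
EMPTY_DATABASE = "empty-database"
ASSIGNED = "assigned"
DEFAULT_TC_CUTOFF = 0.5


def tanimoto(fp_x: BitFingerprint, fp_y: BitFingerprint) -> float:
    """TC = z/(x+y−z) on same-family bit vectors; undefined when both are
    all-zero (raised as an error)."""
    if fp_x.family != fp_y.family or fp_x.length != fp_y.length:
        raise ValueError(
            f"fingerprints not comparable: {fp_x.family}/{fp_x.length} "
            f"vs {fp_y.family}/{fp_y.length}")
    x = fp_x.popcount()
    y = fp_y.popcount()
    if x == 0 and y == 0:
        raise ValueError("Tanimoto undefined for two all-zero fingerprints")
    z = int(np.bitwise_and(fp_x.bits, fp_y.bits).sum())
    return z / (x + y - z)


@dataclass
class SimilarityHit:
    substrate_id: str
    per_family_tc: dict[str, float]
    consensus_family_count: int
    winning_tc: float
    ec_tags: frozenset[ECLabel] = field(default_factory=frozenset)


def consensus_top_hit(query: Molecule, candidates: list,
                      families=SIMILARITY_FAMILIES) -> SimilarityHit:
    """Consensus winner among candidates ``[(id, Molecule, ec_tags), ...]``.

    Per family, candidates rank by Tanimoto coefficient, ties broken by
    lexicographic substrate id.  Candidate/family pairs whose coefficient
    is undefined (both vectors empty) are skipped; if nothing is
    comparable at all, an error is raised.
    """
    if not candidates:
        raise ValueError("no candidates to search")
    q_fps = {fam: fingerprints.compute_fingerprint(query, fam) for fam in families}
    tc_table: dict[str, dict[str, float]] = {fam: {} for fam in families}
    for cand_id, cand_mol, _tags in candidates:
        for fam in families:
            c_fp = fingerprints.compute_fingerprint(cand_mol, fam)
            try:
                tc_table[fam][cand_id] = tanimoto(q_fps[fam], c_fp)
            except ValueError:
                continue  # undefined pair under this family
    top_per_family: dict[str, str] = {}
    for fam in families:
        if tc_table[fam]:
            top_per_family[fam] = min(tc_table[fam],
                                      key=lambda cid: (-tc_table[fam][cid], cid))
    if not top_per_family:
        raise ValueError("Tanimoto undefined for every candidate/family pair")

    votes: dict[str, int] = {}
    for cid in top_per_family.values():
        votes[cid] = votes.get(cid, 0) + 1
    best_vote = max(votes.values())
    if best_vote >= 2:
        winner = min(c for c, v in votes.items() if v == best_vote)
        consensus = best_vote
    else:  # full split: highest coefficient anywhere wins
        winner, _fam = min(
            ((cid, fam) for fam, cid in top_per_family.items()),
            key=lambda t: (-tc_table[t[1]][t[0]], t[0]))
        consensus = 1
    per_family = {fam: tc_table[fam].get(winner, float("nan")) for fam in families}
    winning_tc = max(v for v in per_family.values() if not np.isnan(v))
    tags = next(tags for cid, _m, tags in candidates if cid == winner)
    return SimilarityHit(substrate_id=winner, per_family_tc=per_family,
                         consensus_family_count=consensus, winning_tc=winning_tc,
                         ec_tags=frozenset(tags))


@dataclass
class ECAssignment:
    status: str  # assigned | no-confident-EC | empty-database
    ecs: list[ECLabel]
    hit: SimilarityHit | None


def assign_ec(query: Molecule, db: SubstrateDB, predicted_class: int,
              predicted_subclass: int, tc_cutoff: float = DEFAULT_TC_CUTOFF,
              families=SIMILARITY_FAMILIES) -> ECAssignment:
    """Four-digit EC(s) for the query via consensus search restricted to
    the predicted (class, subclass) substrate subset.

    A winner below ``tc_cutoff`` yields status ``no-confident-EC`` but
    still carries the best sub-threshold hit for transparency.  Only EC
    tags inside the predicted subclass are ever returned.
    """
    records = db.subclass_records(predicted_class, predicted_subclass)
    if not records:
        return ECAssignment(status=EMPTY_DATABASE, ecs=[], hit=None)
    candidates = [(r.id, r.molecule, r.ec_tags) for r in records]
    hit = consensus_top_hit(query, candidates, families)
    in_subclass = sorted(
        ec for ec in hit.ec_tags
        if ec.class_digit == predicted_class and ec.subclass_digit == predicted_subclass)
    hit.ec_tags = frozenset(in_subclass)
    if hit.winning_tc < tc_cutoff:
        return ECAssignment(status=NO_CONFIDENT_EC, ecs=[], hit=hit)
    return ECAssignment(status=ASSIGNED, ecs=in_subclass, hit=hit)
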