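"""End-to-end three-step prediction workflow.

Step 1: the class forest places the query molecule in an EC class.
Step 2: that class's subclass forest refines it to an EC subclass.
Step 3: consensus Tanimoto search within the predicted subclass's
substrate subset assigns the four-digit EC number(s), and the enzyme
database returns every gut-bacterial protein/genome/lineage carrying
them.  Any stage can halt early ("unclassified", "no-subclass-model",
"no-confident-EC", "empty-database"); the result then carries empty
downstream fields and an explicit stage log, never a silent gap.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import fingerprints
from .chem_io import Molecule
from .ec import ECLabel
from .enzyme_db import EnzymeDB, EnzymeRecord, lookup_ec
from .feature_select import project
from .models import UNCLASSIFIED, CascadeModel
from .similarity import ASSIGNED, DEFAULT_TC_CUTOFF, SimilarityHit, assign_ec
from .substrate_db import SubstrateDB


@dataclass
class PredictConfig:
    class_threshold: float = 0.0
    subclass_threshold: float = 0.0
    tc_cutoff: float = DEFAULT_TC_CUTOFF
    allow_partial_ec: bool = True
    expected_hybrid_hash: str | None = None


@dataclass
class PredictionResult:
    query_id: str
    predicted_class: int | None = None
    class_probability: float | None = None
    predicted_subclass: int | None = None
    subclass_probability: float | None = None
    similarity: SimilarityHit | None = None
    assigned_ecs: list[ECLabel] = field(default_factory=list)
    enzymes: list[EnzymeRecord] = field(default_factory=list)
    provenance: list[str] = field(default_factory=list)


def _query_features(query: Molecule, model: CascadeModel) -> np.ndarray:
    families = sorted({c.split(":", 1)[0] for c in model.hybrid_spec.selected},
                      key=list(fingerprints.REGISTRY).index)
    table, failures = fingerprints.fingerprint_matrix([query], families)
    if failures:
        raise ValueError(f"fingerprinting failed for query {query.id!r}: {failures}")
    return project(table, model.hybrid_spec).to_numpy()[0]


def predict(query: Molecule, model: CascadeModel, sdb: SubstrateDB,
            edb: EnzymeDB | None = None,
            config: PredictConfig | None = None) -> PredictionResult:
    """Run the three-step workflow for one query molecule."""
    cfg = config or PredictConfig()
    if cfg.expected_hybrid_hash is not None and \
            cfg.expected_hybrid_hash != model.hybrid_spec.content_hash:
        raise ValueError("hybrid spec hash mismatch between model and config")
    res = PredictionResult(query_id=query.id)
    fp_row = _query_features(query, model)

    cls, cls_probs = model.predict_class(fp_row, threshold=cfg.class_threshold)
    if cls == UNCLASSIFIED:
        res.provenance.append(
            f"step1: unclassified (max p {max(cls_probs.values()):.3f} "
            f"< threshold {cfg.class_threshold})")
        return res
    res.predicted_class = cls
    res.class_probability = cls_probs[cls]
    res.provenance.append(f"step1: EC class {cls} (p={cls_probs[cls]:.3f})")

    sub, sub_probs = model.predict_subclass(cls, fp_row,
                                            threshold=cfg.subclass_threshold)
    if sub in (UNCLASSIFIED, "no-subclass-model"):
        res.provenance.append(f"step2: {sub}")
        return res
    res.predicted_subclass = sub
    res.subclass_probability = sub_probs[sub]
    res.provenance.append(f"step2: EC subclass {cls}.{sub} (p={sub_probs[sub]:.3f})")

    assignment = assign_ec(query, sdb, cls, sub, tc_cutoff=cfg.tc_cutoff)
    res.similarity = assignment.hit
    res.provenance.append(f"step3: {assignment.status}")
    if assignment.status != ASSIGNED:
        return res
    res.assigned_ecs = assignment.ecs
    res.provenance.append(
        "step3: EC " + ", ".join(str(e) for e in assignment.ecs) +
        f" via substrate {assignment.hit.substrate_id} "
        f"(TC={assignment.hit.winning_tc:.3f}, "
        f"consensus {assignment.hit.consensus_family_count}/3)")

    if edb is not None:
        for ec in assignment.ecs:
            recs = lookup_ec(edb, ec, allow_partial=cfg.allow_partial_ec and
                             not ec.is_complete)
            res.enzymes.extend(recs)
        res.provenance.append(f"step4: {len(res.enzymes)} enzyme record(s)")
    return res


def predict_batch(queries: list[Molecule], model: CascadeModel,
                  sdb: SubstrateDB, edb: EnzymeDB | None = None,
                  config: PredictConfig | None = None) -> list[PredictionResult]:
    """N queries in, N results out, input order preserved."""
    return [predict(q, model, sdb, edb, config) for q in queries]
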