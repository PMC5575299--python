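"""EC-tagged substrate database construction and curation.

Training a hierarchical EC classifier requires a clean, non-redundant
substrate set.  Three curation filters run in a fixed order:

1. cofactor removal — water, metal ions, ATP, NAD(P)(H) and similar
   supporting species are reaction participants, not principal substrates;
2. multi-class exclusion — a molecule metabolized by enzymes from several
   EC *classes* carries contradictory labels for a class-level model;
3. redundancy removal — near-duplicates (Tanimoto > 0.95 by default) are
   collapsed to one representative via greedy leader clustering, so the
   training set is non-overlapping.

The first two filters are per-record predicates and commute; redundancy
removal must run last because the representative choice depends on the
surviving set.  The curated database is partitioned into EC-class- and
EC-subclass-specific subsets via indexes.
"""

from __future__ import annotations

import json
import logging
import os
import warnings
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

from . import fingerprints
from .chem_io import Molecule, from_smiles
from .ec import ECLabel

logger = logging.getLogger(__name__)

DEFAULT_REDUNDANCY_TC = 0.95
DEFAULT_REDUNDANCY_FAMILY = "path1024"


@dataclass
class SubstrateRecord:
    molecule: Molecule
    ec_tags: frozenset[ECLabel]
    provenance: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.ec_tags:
            raise ValueError(f"record {self.molecule.id!r} has no EC tags")

    @property
    def id(self) -> str:
        return self.molecule.id

    @property
    def class_digits(self) -> set[int]:
        return {ec.class_digit for ec in self.ec_tags}

    @property
    def class_digit(self) -> int:
        digits = self.class_digits
        if len(digits) != 1:
            raise ValueError(f"record {self.id!r} spans EC classes {sorted(digits)}")
        return next(iter(digits))

    @property
    def subclass_digits(self) -> set[int]:
        return {ec.subclass_digit for ec in self.ec_tags if ec.subclass_digit is not None}


def load_default_cofactors() -> set[str]:
    """Canonical keys of the packaged cofactor exclusion list."""
    keys: set[str] = set()
    text = resources.files("gutenz.data").joinpath("cofactors.smi").read_text("utf-8")
    for line in text.splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        smiles = line.split("\t")[0].strip()
        keys.add(from_smiles(smiles, "cofactor").canonical_key)
    return keys


# --------------------------------------------------------------------------
# curation filters
# --------------------------------------------------------------------------

def filter_cofactors(
    records: list[SubstrateRecord], cofactor_keys: set[str] | None = None
) -> tuple[list[SubstrateRecord], list[SubstrateRecord]]:
    """Drop records whose structure is on the cofactor list.

    Returns (kept, removed).  An empty list is a no-op; removals are logged
    and recorded in each removed record's provenance.
    """
    if cofactor_keys is None:
        cofactor_keys = load_default_cofactors()
    kept, removed = [], []
    for rec in records:
        if rec.molecule.canonical_key in cofactor_keys:
            rec.provenance.append("removed: cofactor/supporting molecule")
            removed.append(rec)
        else:
            kept.append(rec)
    if records and not kept:
        warnings.warn("cofactor filter removed every record", stacklevel=2)
    logger.info("cofactor filter: %d kept, %d removed", len(kept), len(removed))
    return kept, removed


def filter_multiclass(
    records: list[SubstrateRecord],
) -> tuple[list[SubstrateRecord], list[SubstrateRecord]]:
    """Drop records tagged with ECs from more than one EC class."""
    kept, removed = [], []
    for rec in records:
        classes = rec.class_digits
        if len(classes) > 1:
            rec.provenance.append(f"removed: spans EC classes {sorted(classes)}")
            removed.append(rec)
        else:
            kept.append(rec)
    logger.info("multi-class filter: %d kept, %d removed", len(kept), len(removed))
    return kept, removed


def remove_redundancy(
    records: list[SubstrateRecord],
    tc_threshold: float = DEFAULT_REDUNDANCY_TC,
    fp_family: str = DEFAULT_REDUNDANCY_FAMILY,
) -> tuple[list[SubstrateRecord], dict[str, list[str]]]:
    """Greedy leader clustering; strict-greater merges (TC == threshold kept).

    Records are scanned in stable input order; the first member of each
    cluster is its representative.  Returns (representatives, cluster_map)
    where cluster_map maps representative id -> all member ids (leader
    first).  Records with an all-zero fingerprint have an undefined
    Tanimoto against everything and are excluded with a warning.
    """
    if not 0 < tc_threshold <= 1:
        raise ValueError(f"tc_threshold must be in (0, 1], got {tc_threshold}")
    reps: list[SubstrateRecord] = []
    rep_bits: list[np.ndarray] = []
    cluster_map: dict[str, list[str]] = {}
    for rec in records:
        bits = fingerprints.compute_fingerprint(rec.molecule, fp_family).bits
        pop = int(bits.sum())
        if pop == 0:
            warnings.warn(
                f"record {rec.id!r}: all-zero {fp_family} fingerprint; "
                "Tanimoto undefined, record excluded from clustering", stacklevel=2)
            rec.provenance.append("removed: all-zero fingerprint (Tanimoto undefined)")
            continue
        assigned = False
        for leader, lbits in zip(reps, rep_bits):
            inter = int(np.bitwise_and(bits, lbits).sum())
            tc = inter / (pop + int(lbits.sum()) - inter)
            if tc > tc_threshold:
                cluster_map[leader.id].append(rec.id)
                rec.provenance.append(
                    f"removed: redundant with {leader.id} (TC {tc:.3f} > {tc_threshold})")
                assigned = True
                break
        if not assigned:
            reps.append(rec)
            rep_bits.append(bits)
            cluster_map[rec.id] = [rec.id]
    logger.info("redundancy removal: %d of %d kept as representatives",
                len(reps), len(records))
    return reps, cluster_map


# --------------------------------------------------------------------------
# database
# --------------------------------------------------------------------------

@dataclass
class SubstrateDB:
    """Curated records plus EC-class and EC-subclass partitions."""

    records: list[SubstrateRecord]
    class_index: dict[int, list[str]] = field(default_factory=dict)
    subclass_index: dict[tuple[int, int], list[str]] = field(default_factory=dict)
    stage_counts: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.class_index and self.records:
            self._build_indexes()
        keys = [r.molecule.canonical_key for r in self.records]
        if len(keys) != len(set(keys)):
            raise ValueError("duplicate canonical keys in curated database")

    def _build_indexes(self) -> None:
        self.class_index = {}
        self.subclass_index = {}
        for rec in self.records:
            c = rec.class_digit  # raises if a record still spans classes
            self.class_index.setdefault(c, []).append(rec.id)
            for s in sorted(rec.subclass_digits):
                self.subclass_index.setdefault((c, s), []).append(rec.id)

    def __len__(self) -> int:
        return len(self.records)

    def by_id(self, rec_id: str) -> SubstrateRecord:
        return self._id_map()[rec_id]

    def _id_map(self) -> dict[str, SubstrateRecord]:
        return {r.id: r for r in self.records}

    def class_records(self, class_digit: int) -> list[SubstrateRecord]:
        idmap = self._id_map()
        return [idmap[i] for i in self.class_index.get(class_digit, [])]

    def subclass_records(self, class_digit: int, subclass_digit: int) -> list[SubstrateRecord]:
        idmap = self._id_map()
        return [idmap[i] for i in self.subclass_index.get((class_digit, subclass_digit), [])]

    # -- serialization -----------------------------------------------------
    def save(self, directory: str) -> None:
        os.makedirs(directory, exist_ok=True)
        with open(os.path.join(directory, "molecules.smi"), "w", encoding="utf-8") as fh:
            fh.write("# smiles\tid\n")
            for r in self.records:
                fh.write(f"{r.molecule.canonical_key}\t{r.id}\n")
        with open(os.path.join(directory, "records.tsv"), "w", encoding="utf-8") as fh:
            fh.write("id\tec_tags\tprovenance\n")
            for r in self.records:
                tags = ";".join(str(e) for e in sorted(r.ec_tags))
                prov = " | ".join(r.molecule.provenance + r.provenance)
                fh.write(f"{r.id}\t{tags}\t{prov}\n")
        payload = {
            "class_index": {str(k): v for k, v in sorted(self.class_index.items())},
            "subclass_index": {f"{c}.{s}": v for (c, s), v in sorted(self.subclass_index.items())},
            "stage_counts": self.stage_counts,
        }
        with open(os.path.join(directory, "indexes.json"), "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)

    @classmethod
    def load(cls, directory: str) -> "SubstrateDB":
        # '#' appears inside SMILES (triple bonds), so comment lines are
        # stripped by prefix rather than via the parser's comment char
        smi = pd.read_csv(os.path.join(directory, "molecules.smi"), sep="\t",
                          names=["smiles", "id"], dtype=str)
        smi = smi[~smi["smiles"].str.startswith("#")]
        recs = pd.read_csv(os.path.join(directory, "records.tsv"), sep="\t", dtype=str)
        tag_map = dict(zip(recs["id"], recs["ec_tags"]))
        records = []
        for smiles, rec_id in zip(smi["smiles"], smi["id"]):
            tags = frozenset(ECLabel.parse(t) for t in tag_map[rec_id].split(";"))
            records.append(SubstrateRecord(from_smiles(smiles, rec_id), tags))
        with open(os.path.join(directory, "indexes.json"), encoding="utf-8") as fh:
            payload = json.load(fh)
        return cls(records=records, stage_counts=payload.get("stage_counts", {}))


def records_from_table(table: pd.DataFrame) -> tuple[list[SubstrateRecord], list[str]]:
    """Parse a raw TSV-style table (smiles, id, ec_list ';'-separated)."""
    records, errors = [], []
    for _, row in table.iterrows():
        try:
            mol = from_smiles(str(row["smiles"]), str(row["id"]))
            tags = frozenset(ECLabel.parse(t) for t in str(row["ec_list"]).split(";") if t)
            records.append(SubstrateRecord(mol, tags))
        except Exception as exc:
            errors.append(f"{row.get('id', '?')}: {exc}")
    return records, errors


def build_substrate_db(
    raw: pd.DataFrame | list[SubstrateRecord],
    cofactor_keys: set[str] | None = None,
    tc_threshold: float = DEFAULT_REDUNDANCY_TC,
    fp_family: str = DEFAULT_REDUNDANCY_FAMILY,
) -> SubstrateDB:
    """Run the full curation pipeline and index the survivors.

    Order: cofactor filter -> multi-class filter -> redundancy removal ->
    index construction.  Stage-wise counts are kept on the returned
    database; an empty result after filtering is fatal.
    """
    if isinstance(raw, pd.DataFrame):
        records, errors = records_from_table(raw)
        for e in errors:
            logger.warning("unparseable raw record: %s", e)
    else:
        records = list(raw)
    counts = {"raw": len(records)}
    records, removed_cof = filter_cofactors(records, cofactor_keys)
    counts["after_cofactor_filter"] = len(records)
    records, removed_mc = filter_multiclass(records)
    counts["after_multiclass_filter"] = len(records)
    records, cluster_map = remove_redundancy(records, tc_threshold, fp_family)
    counts["after_redundancy_removal"] = len(records)
    if not records:
        raise ValueError(f"curation left no records; stage counts: {counts}")
    db = SubstrateDB(records=records, stage_counts=counts)
    db.stage_counts = counts
    return db
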